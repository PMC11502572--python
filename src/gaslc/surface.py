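"""Rectangular age x year mortality surfaces."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MortalitySurface"]


@dataclass
class MortalitySurface:
    """Deaths, central exposures and (optionally) start-of-year populations
    on a rectangular age-group x calendar-year grid.

    Parameters
    ----------
    ages : sequence of str
        Age-group labels, ordered (e.g. ``"0", "1-4", ..., "90+"``).
    years : sequence of int
        Calendar years, ordered and contiguous.
    deaths : (N, T) array
        Death counts d_xt (non-negative).
    exposures : (N, T) array
        Central exposures L_xt in person-years (positive).
    start_populations : (N, T) array, optional
        Start-of-year populations l_xt (the binomial denominator).
    """

    ages: list[str]
    years: list[int]
    deaths: np.ndarray
    exposures: np.ndarray
    start_populations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ages = [str(a) for a in self.ages]
        self.years = [int(y) for y in self.years]
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.exposures = np.asarray(self.exposures, dtype=float)
        n, t = len(self.ages), len(self.years)
        if n < 2 or t < 3:
            raise ValueError(f"surface needs at least 2 ages and 3 years (got {n} x {t})")
        for name, arr in (("deaths", self.deaths), ("exposures", self.exposures)):
            if arr.shape != (n, t):
                raise ValueError(f"{name} must have shape ({n}, {t}), got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains missing or non-finite cells")
        if np.any(self.deaths < 0):
            raise ValueError("deaths must be non-negative")
        if np.any(self.exposures <= 0):
            raise ValueError("exposures must be positive")
        if self.start_populations is not None:
            self.start_populations = np.asarray(self.start_populations, dtype=float)
            if self.start_populations.shape != (n, t):
                raise ValueError("start_populations shape mismatch")
            if np.any(self.start_populations <= 0):
                raise ValueError("start_populations must be positive")
            if np.any(self.deaths > self.start_populations):
                raise ValueError("deaths exceed start-of-year populations")

    # -- basic geometry ----------------------------------------------------

    @property
    def n_ages(self) -> int:
        return len(self.ages)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_ages, self.n_years)

    @property
    def rates(self) -> np.ndarray:
        """Central mortality rates m_xt = d_xt / L_xt."""
        return self.deaths / self.exposures

    # -- constructors / views ----------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MortalitySurface":
        """Build a surface from a long table with columns
        ``year, age, deaths, exposure`` and optionally ``population``."""
        required = {"year", "age", "deaths", "exposure"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        ages = list(dict.fromkeys(df["age"].astype(str)))
        years = sorted(df["year"].unique())
        d = df.pivot_table(index="age", columns="year", values="deaths", sort=False)
        e = df.pivot_table(index="age", columns="year", values="exposure", sort=False)
        d = d.loc[ages, years]
        e = e.loc[ages, years]
        pops = None
        if "population" in df.columns and df["population"].notna().all():
            pops = (
                df.pivot_table(index="age", columns="year", values="population", sort=False)
                .loc[ages, years]
                .to_numpy()
            )
        return cls(ages, [int(y) for y in years], d.to_numpy(), e.to_numpy(), pops)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format view: one row per (year, age) cell."""
        n, t = self.shape
        out = pd.DataFrame(
            {
                "year": np.repeat(self.years, n),
                "age": np.tile(self.ages, t),
                "deaths": self.deaths.T.ravel(),
                "exposure": self.exposures.T.ravel(),
            }
        )
        if self.start_populations is not None:
            out["population"] = self.start_populations.T.ravel()
        return out

    def subset_years(self, first: int, last: int) -> "MortalitySurface":
        """Restrict the surface to years ``first..last`` (inclusive)."""
        idx = [i for i, y in enumerate(self.years) if first <= y <= last]
        if not idx:
            raise ValueError(f"no years in [{first}, {last}]")
        sl = np.asarray(idx)
        pops = None if self.start_populations is None else self.start_populations[:, sl]
        return MortalitySurface(
            self.ages,
            [self.years[i] for i in idx],
            self.deaths[:, sl],
            self.exposures[:, sl],
            pops,
        )
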