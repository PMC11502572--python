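"""Readers and writers for HMD-style period 1x1 mortality text files.

The layout is the Human Mortality Database period format: a free-text
header line, a blank line, then whitespace-aligned columns
``Year Age Female Male Total`` with ages ``0, 1, ..., 110+`` (grouped age
labels such as ``1-4`` and open groups such as ``90+`` are also accepted)
and ``.`` marking missing values.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .surface import MortalitySurface

__all__ = [
    "LongMortalityTable",
    "read_hmd_tables",
    "write_hmd",
    "group_ages",
    "split_sample",
    "default_boundaries",
    "SPLIT_SCENARIOS",
]

logger = logging.getLogger("gaslc")

#: in-sample end year per the three standard split scenarios
SPLIT_SCENARIOS = {1: 2004, 2: 2009, 3: 2014}

_SEX_COLUMNS = {"female": 2, "male": 3, "total": 4}


@dataclass
class LongMortalityTable:
    """Long-form (year, age) mortality records with unique keys."""

    data: pd.DataFrame  # columns: year, age, deaths, exposure, [population]

    def __post_init__(self) -> None:
        df = self.data
        if df.duplicated(["year", "age"]).any():
            raise ValueError("duplicate (year, age) records")
        years = np.sort(df["year"].unique())
        if years.size > 1 and not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
            raise ValueError(f"year range {years[0]}-{years[-1]} is not contiguous")

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique())

    @property
    def ages(self) -> list[str]:
        return list(dict.fromkeys(self.data["age"]))

    @property
    def has_missing(self) -> bool:
        cols = [c for c in ("deaths", "exposure", "population") if c in self.data.columns]
        return bool(self.data[cols].isna().any().any())


def _parse_hmd_file(path, sex: str) -> pd.DataFrame:
    """One HMD file -> DataFrame(year, age, value); value NaN for '.'."""
    col = _SEX_COLUMNS.get(sex.lower())
    if col is None:
        raise ValueError(f"sex must be one of {sorted(_SEX_COLUMNS)}, got {sex!r}")
    path = Path(path)
    rows = []
    with open(path) as fh:
        lines = fh.readlines()
    # skip the free-text header and any blank lines before the column header
    start = None
    for i, line in enumerate(lines):
        if re.match(r"\s*Year\s+Age\s+Female\s+Male\s+Total\s*$", line):
            start = i + 1
            break
    if start is None:
        raise ValueError(f"{path.name}: malformed header, no 'Year Age Female Male Total' line")
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{path.name}:{lineno}: expected 5 columns, got {len(parts)}")
        try:
            year = int(parts[0])
        except ValueError as err:
            raise ValueError(f"{path.name}:{lineno}: bad year {parts[0]!r}") from err
        raw = parts[col]
        if raw == ".":
            value = np.nan
        else:
            try:
                value = float(raw)
            except ValueError as err:
                raise ValueError(f"{path.name}:{lineno}: bad value {raw!r}") from err
            if value < 0:
                raise ValueError(f"{path.name}:{lineno}: negative count {value}")
        rows.append((year, parts[1], value))
    return pd.DataFrame(rows, columns=["year", "age", "value"])


def read_hmd_tables(
    deaths_path,
    exposures_path,
    populations_path=None,
    sex: str = "total",
) -> LongMortalityTable:
    """Read matching deaths / exposures (and optional start-of-year
    population) files into a validated long table."""
    d = _parse_hmd_file(deaths_path, sex).rename(columns={"value": "deaths"})
    e = _parse_hmd_file(exposures_path, sex).rename(columns={"value": "exposure"})
    dy, ey = (sorted(d["year"].unique()), sorted(e["year"].unique()))
    if dy != ey:
        raise ValueError(
            f"deaths cover {dy[0]}-{dy[-1]} but exposures cover {ey[0]}-{ey[-1]}"
        )
    d_keys = set(zip(d["year"], d["age"]))
    e_keys = set(zip(e["year"], e["age"]))
    if d_keys != e_keys:
        raise ValueError("deaths and exposures files cover different (year, age) cells")
    # left-merge onto the deaths file to preserve its row order
    merged = d.merge(e, on=["year", "age"], how="left", validate="one_to_one")
    if populations_path is not None:
        p = _parse_hmd_file(populations_path, sex).rename(columns={"value": "population"})
        merged = merged.merge(p, on=["year", "age"], how="left", validate="one_to_one")
    return LongMortalityTable(merged)


def write_hmd(surface: MortalitySurface, directory, name: str = "synthetic") -> dict[str, Path]:
    """Write a surface in the HMD-like text layout (synthetic data header).

    Deaths and exposures (and populations when present) go to separate
    files; the single modelled series fills the Total column and the sex
    columns carry the missing marker.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    blocks = {"Deaths": surface.deaths, "Exposures": surface.exposures}
    if surface.start_populations is not None:
        blocks["Population"] = surface.start_populations
    for kind, mat in blocks.items():
        path = directory / f"{name}_{kind}_1x1.txt"
        with open(path, "w") as fh:
            fh.write(f"{name}, {kind} (period 1x1), synthetic surface\n\n")
            fh.write("  Year          Age             Female            Male           Total\n")
            for j, year in enumerate(surface.years):
                for i, age in enumerate(surface.ages):
                    fh.write(
                        f"  {year}          {age:<10}      .                 .       "
                        f"{mat[i, j]:.10g}\n"
                    )
        out[kind.lower()] = path
    return out


# --------------------------------------------------------------------------
# age grouping
# --------------------------------------------------------------------------


def default_boundaries() -> list[int]:
    """Lower bounds of the standard 20 groups: 0, 1-4, 5-9, ..., 85-89, 90+."""
    return [0, 1] + list(range(5, 95, 5))


def _boundary_labels(bounds: list[int]) -> list[str]:
    labels = []
    for i, lo in enumerate(bounds):
        if i + 1 < len(bounds):
            hi = bounds[i + 1] - 1
            labels.append(str(lo) if hi == lo else f"{lo}-{hi}")
        else:
            labels.append(f"{lo}+")
    return labels


def _age_start(label: str) -> int:
    m = re.fullmatch(r"(\d+)(?:[-+]\d*|\+)?", label.strip())
    if not m:
        raise ValueError(f"unparseable age label {label!r}")
    return int(m.group(1))


def group_ages(
    table: LongMortalityTable,
    boundaries: list[int] | str | None = None,
    impute_missing: bool = False,
) -> MortalitySurface:
    """Aggregate a long table into an age-grouped surface.

    ``boundaries`` lists the lower bound of each group (strictly increasing,
    starting at the youngest age present); the last group is open-ended.
    ``boundaries="identity"`` keeps the table's own age rows.  Deaths,
    exposures and populations are summed within groups, so the group rate is
    summed deaths over summed exposures (constant force within the group).
    """
    df = table.data.copy()
    if table.has_missing:
        if not impute_missing:
            raise ValueError(
                "table contains missing cells; set impute_missing=True to zero-fill"
            )
        logger.warning("imputing missing cells as zero before grouping")
        df = df.fillna(0.0)

    years = table.years
    if boundaries == "identity":
        group_of = {a: a for a in table.ages}
        labels = table.ages
    else:
        bounds = default_boundaries() if boundaries is None else list(boundaries)
        if sorted(set(bounds)) != bounds:
            raise ValueError("boundaries must be strictly increasing and unique")
        labels = _boundary_labels(bounds)
        starts = {a: _age_start(a) for a in table.ages}
        min_age = min(starts.values())
        if bounds[0] > min_age:
            raise ValueError(f"boundaries start at {bounds[0]} but ages start at {min_age}")
        group_of = {}
        edges = np.asarray(bounds)
        for a, s in starts.items():
            group_of[a] = labels[int(np.searchsorted(edges, s, side="right")) - 1]
    df["group"] = df["age"].map(group_of)
    agg = {"deaths": "sum", "exposure": "sum"}
    if "population" in df.columns:
        agg["population"] = "sum"
    g = df.groupby(["group", "year"], sort=False).agg(agg).reset_index()
    piv_d = g.pivot(index="group", columns="year", values="deaths").loc[labels, years]
    piv_e = g.pivot(index="group", columns="year", values="exposure").loc[labels, years]
    pops = None
    if "population" in g.columns and g["population"].notna().all():
        pops = g.pivot(index="group", columns="year", values="population").loc[labels, years].to_numpy()
    return MortalitySurface(labels, years, piv_d.to_numpy(), piv_e.to_numpy(), pops)


def attach_start_populations(surface: MortalitySurface) -> MortalitySurface:
    """Approximate missing start-of-year populations as L + d/2 (logged)."""
    if surface.start_populations is not None:
        return surface
    logger.warning(
        "no start-of-year populations supplied; approximating l = L + d/2"
    )
    pops = surface.exposures + 0.5 * surface.deaths
    return MortalitySurface(surface.ages, surface.years, surface.deaths,
                            surface.exposures, pops)


# --------------------------------------------------------------------------
# sample splitting
# --------------------------------------------------------------------------


def split_sample(
    surface: MortalitySurface,
    scenario: int | None = None,
    split_year: int | None = None,
) -> tuple[MortalitySurface, MortalitySurface]:
    """Split into in-sample (through the split year) and out-of-sample parts.

    Scenario 1/2/3 end the in-sample period in 2004/2009/2014; alternatively
    pass an explicit last in-sample year.
    """
    if (scenario is None) == (split_year is None):
        raise ValueError("give exactly one of scenario or split_year")
    if scenario is not None:
        if scenario not in SPLIT_SCENARIOS:
            raise ValueError(f"scenario must be one of {sorted(SPLIT_SCENARIOS)}")
        split_year = SPLIT_SCENARIOS[scenario]
    first, last = surface.years[0], surface.years[-1]
    if not first <= split_year < last:
        raise ValueError(
            f"split year {split_year} must lie inside {first}-{last} with a non-empty out-sample"
        )
    return (
        surface.subset_years(first, split_year),
        surface.subset_years(split_year + 1, last),
    )
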