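"""Reading and writing surveillance tables.

Input tables are evenly spaced time series of case counts and populations at
risk, optionally stratified by demographic group and age stratum.  Two
dialects are supported:

``plain``
    An ordinary comma-separated file with a single header row.

``wonder``
    The tab-separated export produced by the CDC Wonder database: a header
    row, data rows (fields may be quoted), and a trailing footer of notes.
    The footer starts at the first line beginning with ``"---"`` or
    ``"Notes"`` and is discarded, as are rows whose time field is empty.

Counts reported as ``Suppressed``/``Missing`` (or left blank) are hard
errors: the models have no missing-data pathway, and silently dropping
suppressed cells would bias every downstream rate.
"""

from __future__ import annotations

import io as _stdio
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CaseSeries",
    "SurveillanceFormatError",
    "SurveillanceStructureError",
    "read_surveillance",
    "write_summary",
    "read_summary",
]

#: tokens that mark a censored or absent count in registry exports
SUPPRESSED_TOKENS = frozenset({"suppressed", "missing", "not applicable", ""})

#: default header names, matching CDC Wonder exports
DEFAULT_COLUMNS = {
    "time": "Year",
    "count": "Count",
    "population": "Population",
    "group": "Group",
    "age": "Age Group",
}


class SurveillanceFormatError(ValueError):
    """A cell could not be parsed (bad numeric, suppressed token, ...)."""


class SurveillanceStructureError(ValueError):
    """The table is not a rectangular, evenly spaced panel."""


@dataclass(frozen=True)
class CaseSeries:
    """Time-indexed case counts and populations at risk.

    Arrays are indexed ``(time, group, stratum)``.  ``counts`` holds the
    observed events y_t and ``populations`` the population at risk P_t.
    The panel must be rectangular: every (group, stratum) cell observed in
    every period, with populations strictly positive.
    """

    time_labels: tuple
    groups: tuple
    strata: tuple
    counts: np.ndarray
    populations: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        pops = np.asarray(self.populations, dtype=float)
        expected = (len(self.time_labels), len(self.groups), len(self.strata))
        if counts.shape != expected or pops.shape != expected:
            raise SurveillanceStructureError(
                f"counts/populations must have shape {expected} (time, group, "
                f"stratum); got {counts.shape} and {pops.shape}"
            )
        if counts.size == 0:
            raise SurveillanceStructureError("empty series")
        if not np.all(np.isfinite(counts)) or np.any(counts < 0):
            raise SurveillanceFormatError("counts must be finite and nonnegative")
        if np.any(counts != np.floor(counts)):
            raise SurveillanceFormatError("counts must be integral")
        if not np.all(np.isfinite(pops)) or np.any(pops <= 0):
            raise SurveillanceFormatError("populations must be finite and > 0")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "populations", pops)
        object.__setattr__(self, "time_labels", tuple(self.time_labels))
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "strata", tuple(self.strata))
        _check_time_spacing(self.time_labels)

    # -- convenience ------------------------------------------------------
    @property
    def n_periods(self) -> int:
        return len(self.time_labels)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_strata(self) -> int:
        return len(self.strata)

    def group_index(self, group) -> int:
        try:
            return self.groups.index(group)
        except ValueError:
            raise KeyError(f"unknown group {group!r}; have {self.groups}") from None

    def stratum_index(self, stratum) -> int:
        try:
            return self.strata.index(stratum)
        except ValueError:
            raise KeyError(
                f"unknown stratum {stratum!r}; have {self.strata}"
            ) from None

    def crude_rates(self, per: float = 1.0) -> np.ndarray:
        """Observed counts / population, scaled by ``per``."""
        return per * self.counts / self.populations

    def to_frame(self) -> pd.DataFrame:
        """Long-format view with one row per (time, group, stratum)."""
        n, k, m = self.counts.shape
        idx = pd.MultiIndex.from_product(
            [self.time_labels, self.groups, self.strata],
            names=["time", "group", "stratum"],
        )
        return pd.DataFrame(
            {
                "count": self.counts.reshape(-1),
                "population": self.populations.reshape(-1),
            },
            index=idx,
        ).reset_index()

    def write_csv(self, path, dialect: str = "plain",
                  column_map: Mapping[str, str] | None = None) -> None:
        """Write the panel back out in either input dialect."""
        cols = dict(DEFAULT_COLUMNS)
        if column_map:
            cols.update(column_map)
        df = self.to_frame().rename(
            columns={
                "time": cols["time"],
                "group": cols["group"],
                "stratum": cols["age"],
                "count": cols["count"],
                "population": cols["population"],
            }
        )
        if self.n_groups == 1 and self.groups[0] == "all":
            df = df.drop(columns=[cols["group"]])
        if self.n_strata == 1 and self.strata[0] == "all":
            df = df.drop(columns=[cols["age"]])
        sep = "\t" if dialect == "wonder" else ","
        df.to_csv(path, sep=sep, index=False)


def _check_time_spacing(labels: Sequence) -> None:
    """Periods must be evenly spaced and strictly increasing.

    The check is only enforceable when labels parse as integers (calendar
    years); opaque labels are accepted with a warning.
    """
    try:
        years = [int(str(lab)) for lab in labels]
    except ValueError:
        if len(labels) > 1:
            warnings.warn(
                "time labels are not integers; even spacing assumed",
                stacklevel=3,
            )
        if len(set(labels)) != len(labels):
            raise SurveillanceStructureError("duplicate time labels")
        return
    diffs = np.diff(years)
    if len(years) > 1:
        if np.any(diffs <= 0):
            raise SurveillanceStructureError(
                f"time labels must be strictly increasing; got {years}"
            )
        if np.any(diffs != 1):
            # calendar years must be consecutive: a jump is a missing
            # period, not a coarser (but still even) spacing
            raise SurveillanceStructureError(
                f"unevenly spaced periods {years}: spacings "
                f"{sorted(set(int(d) for d in diffs))} (gap or duplicate)"
            )


def _strip_footer(lines: list[str]) -> list[str]:
    """Drop the Wonder notes footer (first line starting '---' or 'Notes')."""
    out = []
    for line in lines:
        bare = line.strip().strip('"')
        if bare.startswith("---") or bare.startswith("Notes"):
            break
        out.append(line)
    return out


def _parse_count(token: str, row: int, col: str) -> int:
    bare = str(token).strip()
    if bare.lower() in SUPPRESSED_TOKENS or bare.lower() == "nan":
        raise SurveillanceFormatError(
            f"row {row}: count column {col!r} has suppressed/missing value "
            f"{bare!r}; suppressed cells are not supported"
        )
    try:
        val = float(bare.replace(",", ""))
    except ValueError:
        raise SurveillanceFormatError(
            f"row {row}: cannot parse count {bare!r} in column {col!r}"
        ) from None
    if val < 0 or val != int(val):
        raise SurveillanceFormatError(
            f"row {row}: count must be a nonnegative integer, got {bare!r}"
        )
    return int(val)


def _parse_population(token: str, row: int, col: str) -> float:
    bare = str(token).strip()
    if bare.lower() in SUPPRESSED_TOKENS or bare.lower() == "nan":
        raise SurveillanceFormatError(
            f"row {row}: population column {col!r} has missing value {bare!r}"
        )
    try:
        val = float(bare.replace(",", ""))
    except ValueError:
        raise SurveillanceFormatError(
            f"row {row}: cannot parse population {bare!r} in column {col!r}"
        ) from None
    if not np.isfinite(val) or val <= 0:
        raise SurveillanceFormatError(
            f"row {row}: population must be > 0, got {bare!r}"
        )
    return val


def read_surveillance(
    path,
    dialect: str = "plain",
    column_map: Mapping[str, str] | None = None,
) -> CaseSeries:
    """Read a surveillance table into a :class:`CaseSeries`.

    Parameters
    ----------
    path
        Delimited text file.  Tab-separated for ``dialect="wonder"``,
        comma-separated for ``dialect="plain"``.  Auto-detection is
        deliberately not attempted.
    dialect
        ``"wonder"`` or ``"plain"``.
    column_map
        Overrides for the header names, keys among ``time``, ``count``,
        ``population``, ``group``, ``age``.

    Raises
    ------
    SurveillanceFormatError
        Unparseable or suppressed cells (with the offending row number).
    SurveillanceStructureError
        Missing (period, group, stratum) cells or unevenly spaced periods.
    """
    if dialect not in ("wonder", "plain"):
        raise ValueError(f"unknown dialect {dialect!r}; use 'wonder' or 'plain'")
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(cols)
        if unknown:
            raise ValueError(f"unknown column_map keys {sorted(unknown)}")
        cols.update(column_map)

    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if dialect == "wonder":
        lines = _strip_footer(lines)
    if not lines:
        raise SurveillanceFormatError(f"{path}: no data")
    sep = "\t" if dialect == "wonder" else ","
    df = pd.read_csv(
        _stdio.StringIO("\n".join(lines)), sep=sep, dtype=str,
        skip_blank_lines=True,
    )
    df.columns = [c.strip() for c in df.columns]

    for key in ("time", "count", "population"):
        if cols[key] not in df.columns:
            raise SurveillanceFormatError(
                f"{path}: required column {cols[key]!r} ({key}) not in header "
                f"{list(df.columns)}"
            )
    time_col, count_col, pop_col = cols["time"], cols["count"], cols["population"]
    group_col = cols["group"] if cols["group"] in df.columns else None
    age_col = cols["age"] if cols["age"] in df.columns else None

    # Wonder exports carry blank time labels on total/annotation rows.
    time_raw = df[time_col].astype(str).str.strip().str.strip('"')
    if dialect == "wonder":
        keep = ~(time_raw.isin(("", "nan")) | df[time_col].isna())
        df = df[keep]
        time_raw = time_raw[keep]
    if df.empty:
        raise SurveillanceFormatError(f"{path}: no data rows")

    records = []
    for pos, (idx, row) in enumerate(df.iterrows(), start=2):
        t = str(row[time_col]).strip().strip('"')
        g = str(row[group_col]).strip().strip('"') if group_col else "all"
        a = str(row[age_col]).strip().strip('"') if age_col else "all"
        y = _parse_count(row[count_col], pos, count_col)
        p = _parse_population(row[pop_col], pos, pop_col)
        records.append((t, g, a, y, p))

    times = list(dict.fromkeys(r[0] for r in records))
    groups = list(dict.fromkeys(r[1] for r in records))
    strata = list(dict.fromkeys(r[2] for r in records))
    try:
        times.sort(key=lambda s: int(s))
    except ValueError:
        pass  # opaque labels keep file order

    n, k, m = len(times), len(groups), len(strata)
    counts = np.full((n, k, m), -1, dtype=np.int64)
    pops = np.full((n, k, m), np.nan)
    for t, g, a, y, p in records:
        i, j, s = times.index(t), groups.index(g), strata.index(a)
        if counts[i, j, s] != -1:
            raise SurveillanceStructureError(
                f"{path}: duplicate cell (time={t}, group={g}, stratum={a})"
            )
        counts[i, j, s] = y
        pops[i, j, s] = p
    missing = np.argwhere(counts < 0)
    if missing.size:
        cells = [
            f"(time={times[i]}, group={groups[j]}, stratum={strata[s]})"
            for i, j, s in missing[:10]
        ]
        raise SurveillanceStructureError(
            f"{path}: non-rectangular panel; missing cells: {', '.join(cells)}"
            + (" ..." if len(missing) > 10 else "")
        )
    return CaseSeries(
        time_labels=tuple(times),
        groups=tuple(groups),
        strata=tuple(strata),
        counts=counts,
        populations=pops,
    )


# ---------------------------------------------------------------------------
# summary output

SUMMARY_COLUMNS = ["time", "group", "stratum", "quantity", "mean",
                   "lwr_2.5", "upr_97.5"]


def write_summary(summaries: Iterable, path) -> None:
    """Write a collection of rate summaries to a tidy CSV.

    One row per summary, columns ``time, group, stratum, quantity, mean,
    lwr_2.5, upr_97.5``.  Round-trips through :func:`read_summary` to within
    1e-9.
    """
    rows = []
    for s in summaries:
        rows.append(
            {
                "time": s.time,
                "group": s.group,
                "stratum": s.stratum,
                "quantity": s.quantity,
                "mean": repr(float(s.mean)),
                "lwr_2.5": repr(float(s.lwr)),
                "upr_97.5": repr(float(s.upr)),
            }
        )
    if not rows:
        raise ValueError("write_summary: empty collection of summaries")
    pd.DataFrame(rows, columns=SUMMARY_COLUMNS).to_csv(path, index=False)


def read_summary(path) -> pd.DataFrame:
    """Read back a summary CSV written by :func:`write_summary`."""
    df = pd.read_csv(path, dtype={"time": str})
    missing = set(SUMMARY_COLUMNS) - set(df.columns)
    if missing:
        raise SurveillanceFormatError(
            f"{path}: summary CSV missing columns {sorted(missing)}"
        )
    return df
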