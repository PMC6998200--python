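"""Data structures and file I/O for spontaneous-report tables.

The unit of analysis is the drug--event combination (DEC): a pair of a drug
identifier and an adverse-drug-reaction (ADR) identifier.  A spontaneous
reporting dataset is modelled as a flat sequence of (drug, adr) report
occurrences (:class:`ReportSet`); most computation happens on the aggregated
per-DEC count table (:class:`DECCountTable`).  A :class:`ReferenceDB` is the
gold-standard set of known DECs used for evaluation, and a *signal table* is
the per-DEC output of a detection run.

File formats are delimited text with a header row: comma-separated by
default, tab-separated on request.  Identifiers are stripped of surrounding
whitespace on load; case is preserved (no dictionary normalisation is
attempted).  Duplicate report rows are legitimate data -- multiple reports of
the same DEC -- and are never deduplicated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: Column order of a serialized signal table.
SIGNAL_COLUMNS = ("drug", "adr", "stratum", "n11", "expected", "ic", "ic025", "positive")


def _check_identifier_series(s: pd.Series, name: str) -> pd.Series:
    s = s.astype(str).str.strip()
    if (s == "").any():
        bad = int(np.flatnonzero((s == "").to_numpy())[0])
        raise ValidationError(f"empty {name} identifier at row {bad}")
    return s


@dataclass(frozen=True)
class ReportSet:
    """A spontaneous-reporting dataset: one row per (drug, adr) occurrence.

    Parameters
    ----------
    records : pandas.DataFrame
        Two string columns, ``drug`` and ``adr``.  Row order is preserved
        but carries no meaning; counts are the signal.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in ("drug", "adr") if c not in df.columns]
        if missing:
            raise FormatError(f"report table missing column(s): {', '.join(missing)}")
        df = df[["drug", "adr"]].reset_index(drop=True)
        df["drug"] = _check_identifier_series(df["drug"], "drug")
        df["adr"] = _check_identifier_series(df["adr"], "adr")
        object.__setattr__(self, "records", df)

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_records(cls, pairs: Iterable[tuple[str, str]]) -> "ReportSet":
        return cls(pd.DataFrame(list(pairs), columns=["drug", "adr"]))

    @classmethod
    def from_counts(cls, counts: "DECCountTable") -> "ReportSet":
        """Expand an aggregated count table into individual report rows."""
        s = counts.counts
        idx = s.index.repeat(s.to_numpy())
        df = pd.DataFrame({"drug": idx.get_level_values("drug"),
                           "adr": idx.get_level_values("adr")})
        return cls(df)

    def to_counts(self) -> "DECCountTable":
        return aggregate(self)


@dataclass(frozen=True)
class DECCountTable:
    """Aggregated per-DEC report counts.

    Wraps a pandas Series of positive integers indexed by a
    ``(drug, adr)`` MultiIndex.  The sum of all counts equals the number of
    report records the table was derived from.
    """

    counts: pd.Series

    def __post_init__(self) -> None:
        s = self.counts
        if not isinstance(s.index, pd.MultiIndex) or list(s.index.names) != ["drug", "adr"]:
            raise ValidationError("counts must be indexed by a (drug, adr) MultiIndex")
        if len(s) and (s.to_numpy() < 1).any():
            raise ValidationError("every DEC count must be >= 1")
        s = s.astype(np.int64)
        s.name = "count"
        object.__setattr__(self, "counts", s)

    @classmethod
    def from_mapping(cls, entries: Mapping[tuple[str, str], int]) -> "DECCountTable":
        idx = pd.MultiIndex.from_tuples(list(entries.keys()) or [], names=["drug", "adr"])
        return cls(pd.Series(list(entries.values()), index=idx, dtype=np.int64))

    def __len__(self) -> int:
        return len(self.counts)

    def total(self) -> int:
        """Number of report records represented (sum of all counts)."""
        return int(self.counts.sum())

    def drug_margins(self) -> pd.Series:
        """Per-drug total report frequency within this table's scope."""
        return self.counts.groupby(level="drug").sum()

    def adr_margins(self) -> pd.Series:
        return self.counts.groupby(level="adr").sum()

    def to_dict(self) -> dict[tuple[str, str], int]:
        return {(d, a): int(c) for (d, a), c in self.counts.items()}


@dataclass(frozen=True)
class ReferenceDB:
    """Gold-standard set of known drug--event combinations."""

    known: frozenset = field(default_factory=frozenset)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "ReferenceDB":
        return cls(frozenset((str(d).strip(), str(a).strip()) for d, a in pairs))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self.known

    def __len__(self) -> int:
        return len(self.known)


def _read_table(path: str | Path, sep: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True,
                       comment="#")


def read_reports(path: str | Path, format: str = "per-report", sep: str = ",") -> ReportSet:
    """Load a report table.

    ``format="per-report"`` expects one row per report occurrence with
    columns ``drug, adr`` (an optional ``report_id`` column is ignored);
    ``format="aggregated"`` expects ``drug, adr, count`` and expands each
    row into ``count`` records.
    """
    if format not in ("per-report", "aggregated"):
        raise ValueError(f"unknown report format: {format!r}")
    df = _read_table(path, sep)
    required = ["drug", "adr"] + (["count"] if format == "aggregated" else [])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    if format == "per-report":
        return ReportSet(df)
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts <= 0) | (counts != counts.round())
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{path}: count must be a positive integer at data row {row + 1}")
    df = df.assign(count=counts.astype(np.int64))
    agg = (df.assign(drug=df["drug"].str.strip(), adr=df["adr"].str.strip())
             .groupby(["drug", "adr"], sort=True)["count"].sum())
    return ReportSet.from_counts(DECCountTable(agg))


def aggregate(reports: ReportSet) -> DECCountTable:
    """Tally reports into a per-DEC count table (sum of counts = record count)."""
    if len(reports) == 0:
        return DECCountTable.from_mapping({})
    counts = reports.records.groupby(["drug", "adr"], sort=True).size()
    counts.index.names = ["drug", "adr"]
    return DECCountTable(counts)


def read_reference(path: str | Path, sep: str = ",") -> ReferenceDB:
    """Load a reference database of known DECs; duplicate rows collapse."""
    df = _read_table(path, sep)
    missing = [c for c in ("drug", "adr") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    return ReferenceDB.from_pairs(zip(df["drug"], df["adr"]))


def write_reports(reports: ReportSet, path: str | Path, aggregated: bool = True,
                  sep: str = ",") -> None:
    """Serialize a ReportSet, by default in the compact aggregated format."""
    if aggregated:
        counts = aggregate(reports).counts
        df = counts.reset_index()
    else:
        df = reports.records
    df.to_csv(path, sep=sep, index=False)


def make_signal_table(rows: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a signal table DataFrame.

    Enforces the signal-table invariants: fixed column set, one row per
    DEC, ``ic025 <= ic``, and deterministic row order (stratum path, then
    drug, then adr).
    """
    missing = [c for c in SIGNAL_COLUMNS if c not in rows.columns]
    if missing:
        raise FormatError(f"signal table missing column(s): {', '.join(missing)}")
    df = rows.loc[:, list(SIGNAL_COLUMNS)].copy()
    if df.duplicated(subset=["drug", "adr"]).any():
        dup = df[df.duplicated(subset=["drug", "adr"])].iloc[0]
        raise ValidationError(f"duplicate DEC in signal table: ({dup.drug}, {dup.adr})")
    if len(df) and (df["ic025"].to_numpy() > df["ic"].to_numpy() + 1e-12).any():
        raise ValidationError("signal table violates ic025 <= ic")
    df = df.sort_values(["stratum", "drug", "adr"], kind="mergesort").reset_index(drop=True)
    df["n11"] = df["n11"].astype(np.int64)
    df["positive"] = df["positive"].astype(bool)
    return df


def write_signals(signals: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a signal table; floats keep >= 6 significant digits."""
    df = make_signal_table(signals)
    df.to_csv(path, sep=sep, index=False, float_format="%.9g")


def read_signals(path: str | Path, sep: str = ",") -> pd.DataFrame:
    df = _read_table(path, sep)
    missing = [c for c in SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    for col in ("n11",):
        df[col] = df[col].astype(np.int64)
    for col in ("expected", "ic", "ic025"):
        df[col] = df[col].astype(float)
    df["positive"] = df["positive"].astype(str).str.lower().isin(("true", "1"))
    return make_signal_table(df)


def write_reference(reference: ReferenceDB, path: str | Path, sep: str = ",") -> None:
    df = pd.DataFrame(sorted(reference.known), columns=["drug", "adr"])
    df.to_csv(path, sep=sep, index=False)
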