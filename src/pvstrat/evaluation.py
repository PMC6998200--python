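"""Evaluation of detection runs against a reference database.

Known DECs are those present both in the reference database *and* in the
dataset under study; reference pairs never reported cannot be detected and
are excluded from the evaluation universe.  The four-way split of
(known?, positive?) gives TP/FP/FN/TN, from which Precision, Recall and the
F-measure follow.  A precision-recall curve ranks DECs by IC_025, and the
masking diagnostic quantifies how much less frequent the entities behind
masked signals are than average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import DECCountTable, ReferenceDB


class ConfusionCounts(NamedTuple):
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n_known(self) -> int:
        return self.tp + self.fn

    @property
    def n_total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


class Metrics(NamedTuple):
    """Precision, recall and F-measure as fractions in [0, 1]."""

    precision: float
    recall: float
    f_measure: float

    def as_percent(self, ndigits: int = 2) -> "Metrics":
        return Metrics(*(round(100 * v, ndigits) for v in self))


@dataclass(frozen=True)
class MaskingDiagnostic:
    """Mean report frequencies of masked-signal entities vs. overall.

    One row per axis (drug, adr, dec): the unweighted mean frequency over
    all distinct entities on that axis, the mean over the distinct entities
    involved in masked DECs, and the percentage decline between the two.
    Absent (NaN) when no DEC is masked.
    """

    table: pd.DataFrame  # index: axis; columns: overall_mean, masked_mean, decline_rate

    def decline_rate(self, axis: str) -> float:
        return float(self.table.loc[axis, "decline_rate"])


def _known_mask(signals: pd.DataFrame, reference: ReferenceDB) -> np.ndarray:
    pairs = list(zip(signals["drug"], signals["adr"]))
    return np.fromiter((p in reference for p in pairs), dtype=bool, count=len(pairs))


def confusion(signals: pd.DataFrame, reference: ReferenceDB) -> ConfusionCounts:
    """TP/FP/FN/TN of a signal table against the reference database."""
    known = _known_mask(signals, reference)
    positive = signals["positive"].to_numpy(dtype=bool)
    return ConfusionCounts(
        tp=int((known & positive).sum()),
        fp=int((~known & positive).sum()),
        fn=int((known & ~positive).sum()),
        tn=int((~known & ~positive).sum()),
    )


def metrics(c: ConfusionCounts) -> Metrics:
    """Precision, Recall and their harmonic mean (0 where undefined)."""
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    f = (2 * precision * recall / (precision + recall)
         if (precision + recall) else 0.0)
    return Metrics(precision, recall, f)


def relative_change(old: float, new: float) -> float:
    """Percentage change from `old` to `new`, on the values as given."""
    if old == 0:
        raise ValueError("relative_change undefined for old == 0")
    return (new - old) / old * 100.0


def pr_curve(signals: pd.DataFrame, reference: ReferenceDB) -> pd.DataFrame:
    """Cumulative precision-recall along the IC_025 ranking.

    DECs are sorted by IC_025 descending (ties broken by drug then adr,
    lexicographic); after each DEC the cumulative precision and recall over
    the DECs seen so far are recorded.  Recall is non-decreasing.
    """
    if signals.empty:
        raise ValueError("pr_curve requires a non-empty signal table")
    df = signals.sort_values(["ic025", "drug", "adr"],
                             ascending=[False, True, True],
                             kind="mergesort").reset_index(drop=True)
    known = _known_mask(df, reference)
    n_known = int(known.sum())
    cum_tp = np.cumsum(known)
    rank = np.arange(1, len(df) + 1)
    return pd.DataFrame({
        "rank": rank,
        "drug": df["drug"],
        "adr": df["adr"],
        "ic025": df["ic025"],
        "cum_precision": cum_tp / rank,
        "cum_recall": cum_tp / n_known if n_known else np.zeros(len(df)),
    })


def plot_pr_curve(curves: dict[str, pd.DataFrame], ax=None):
    """Plot one or more precision-recall curves (label -> pr_curve frame)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, c in curves.items():
        ax.plot(c["cum_recall"], c["cum_precision"], label=label)
    ax.set_xlabel("Recall")
    ax.set_ylabel("Precision")
    ax.legend()
    return ax


def masked_frequency_diagnostic(baseline_signals: pd.DataFrame,
                                reference: ReferenceDB,
                                counts: DECCountTable) -> MaskingDiagnostic:
    """How much rarer are the entities behind masked signals than average?

    Masked DECs are known DECs flagged negative by the *non-stratified*
    detector.  For each axis the masked mean is the unweighted mean
    frequency of the distinct drugs / ADRs / DECs involved in masked DECs;
    the decline rate is (overall - masked) / overall x 100.
    """
    known = _known_mask(baseline_signals, reference)
    positive = baseline_signals["positive"].to_numpy(dtype=bool)
    masked = baseline_signals.loc[known & ~positive]

    dm = counts.drug_margins()
    am = counts.adr_margins()
    dec = counts.counts

    def axis_row(overall: pd.Series, masked_ids) -> tuple[float, float, float]:
        overall_mean = float(overall.mean())
        if len(masked_ids) == 0:
            return overall_mean, float("nan"), float("nan")
        masked_mean = float(overall.loc[list(masked_ids)].mean())
        return overall_mean, masked_mean, (overall_mean - masked_mean) / overall_mean * 100.0

    rows = {
        "drug": axis_row(dm, set(masked["drug"])),
        "adr": axis_row(am, set(masked["adr"])),
        "dec": axis_row(dec, set(zip(masked["drug"], masked["adr"]))),
    }
    table = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["overall_mean", "masked_mean", "decline_rate"])
    table.index.name = "axis"
    return MaskingDiagnostic(table)
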