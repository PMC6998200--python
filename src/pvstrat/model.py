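"""Model/Results front end for signal detection.

`SignalDetectionModel` binds a spontaneous-reporting dataset (and optionally
a reference database) to a detection configuration; `fit()` runs the chosen
arm -- whole-dataset IC or frequency-stratified IC -- and returns a
`SignalDetectionResults` carrying the per-DEC signal table, the stratum
tree, evaluation helpers and a text summary.

Example
-------
>>> from pvstrat import SignalDetectionModel, masking_scenario
>>> ds = masking_scenario(seed=7)
>>> res = SignalDetectionModel(ds.reports, reference=ds.truth, stratify=True).fit()
>>> res.confusion()          # doctest: +SKIP
ConfusionCounts(tp=..., fp=..., fn=..., tn=...)
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import evaluation
from .io import DECCountTable, ReferenceDB, ReportSet, aggregate
from .pipeline import (DetectionConfig, compare_detectors,
                       detect_nonstratified, detect_stratified)
from .stratification import StratificationConfig, StratumTree, stratify_hierarchical


class SignalDetectionModel:
    """IC disproportionality detector over a reporting dataset.

    Parameters
    ----------
    data : ReportSet or DECCountTable
        The reports to screen.
    reference : ReferenceDB, optional
        Gold-standard known DECs; enables confusion counts and metrics on
        the results object.
    stratify : bool
        Score within frequency strata (True) or against whole-dataset
        margins (False).
    config : DetectionConfig, optional
        Threshold, IC variant and stratification settings.
    """

    def __init__(self, data: ReportSet | DECCountTable,
                 reference: ReferenceDB | None = None,
                 stratify: bool = True,
                 config: DetectionConfig | None = None):
        self.counts = aggregate(data) if isinstance(data, ReportSet) else data
        if len(self.counts) == 0:
            raise ValueError("dataset is empty")
        self.reference = reference
        self.stratify = bool(stratify)
        self.config = config or DetectionConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, drug_col: str = "drug",
                       adr_col: str = "adr", count_col: str | None = None,
                       **kwargs) -> "SignalDetectionModel":
        """Build from a tidy DataFrame (per-report rows, or aggregated if
        `count_col` is given)."""
        sub = df.rename(columns={drug_col: "drug", adr_col: "adr"})
        if count_col is None:
            data = ReportSet(sub[["drug", "adr"]])
        else:
            s = sub.set_index(["drug", "adr"])[count_col]
            s = s.groupby(level=["drug", "adr"]).sum()
            data = DECCountTable(s)
        return cls(data, **kwargs)

    def fit(self) -> "SignalDetectionResults":
        tree = None
        if self.stratify:
            tree = stratify_hierarchical(self.counts, self.config.stratification)
            signals = detect_stratified(self.counts, self.config, tree=tree)
        else:
            signals = detect_nonstratified(self.counts, self.config)
        return SignalDetectionResults(self, signals, tree)


@dataclass
class SignalDetectionResults:
    """Fitted per-DEC IC estimates with evaluation and plotting helpers."""

    model: SignalDetectionModel
    signals: pd.DataFrame
    tree: StratumTree | None = None

    @property
    def n_positive(self) -> int:
        return int(self.signals["positive"].sum())

    def confusion(self, reference: ReferenceDB | None = None) -> evaluation.ConfusionCounts:
        ref = reference or self.model.reference
        if ref is None:
            raise ValueError("no reference database supplied")
        return evaluation.confusion(self.signals, ref)

    def metrics(self, reference: ReferenceDB | None = None) -> evaluation.Metrics:
        return evaluation.metrics(self.confusion(reference))

    def pr_curve(self, reference: ReferenceDB | None = None) -> pd.DataFrame:
        ref = reference or self.model.reference
        if ref is None:
            raise ValueError("no reference database supplied")
        return evaluation.pr_curve(self.signals, ref)

    def plot_pr(self, reference: ReferenceDB | None = None, ax=None, label=None):
        curve = self.pr_curve(reference)
        name = label or ("stratified" if self.model.stratify else "non-stratified")
        return evaluation.plot_pr_curve({name: curve}, ax=ax)

    def compare(self, other: "SignalDetectionResults") -> pd.DataFrame:
        """Side-by-side comparison; `self` is the stratified arm, `other`
        the baseline."""
        return compare_detectors(other.signals, self.signals,
                                 self.model.counts, self.model.config.threshold)

    def summary(self) -> str:
        """Plain-text run summary in the style of a model-results table."""
        counts = self.model.counts
        lines = ["Signal detection results", "=" * 44]
        lines.append(f"{'Arm:':<28}{'stratified' if self.model.stratify else 'non-stratified'}")
        lines.append(f"{'IC variant:':<28}{self.model.config.ic_variant}")
        lines.append(f"{'Threshold (IC_025 >):':<28}{self.model.config.threshold:g}")
        lines.append(f"{'Reports:':<28}{counts.total()}")
        lines.append(f"{'Drugs / ADRs / DECs:':<28}"
                     f"{counts.drug_margins().size} / {counts.adr_margins().size} / {len(counts)}")
        if self.tree is not None:
            lines.append(f"{'Strata (leaves):':<28}{self.tree.n_leaves()}")
        lines.append(f"{'Positive signals:':<28}{self.n_positive}")
        if self.model.reference is not None:
            c = self.confusion()
            m = self.metrics().as_percent()
            lines.append(f"{'TP / FP / FN / TN:':<28}{c.tp} / {c.fp} / {c.fn} / {c.tn}")
            lines.append(f"{'Precision / Recall / F (%):':<28}"
                         f"{m.precision:.2f} / {m.recall:.2f} / {m.f_measure:.2f}")
        return "\n".join(lines)
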