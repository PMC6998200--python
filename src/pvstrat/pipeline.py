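"""Detection orchestration: baseline, stratified, and side-by-side comparison.

`detect_nonstratified` scores every DEC against margins from the whole
dataset (stratum path "root").  `detect_stratified` first builds the
three-level frequency stratum tree and scores each DEC against margins
computed inside its leaf only.  Both emit one row per DEC; a DEC whose leaf
contains nothing else yields a saturated table (IC = 0, negative) and is
reported rather than dropped, so the two detectors always cover the same
DEC universe and can be joined row-for-row by `compare_detectors`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .disproportionality import ic_scores
from .errors import ConsistencyError
from .io import DECCountTable, ReportSet, aggregate, make_signal_table
from .stratification import StratificationConfig, StratumTree, stratify_hierarchical

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionConfig:
    """Signal-detection settings shared by both arms.

    threshold
        Decision cut on IC_025 (strictly greater than; default 0 bits).
    ic_variant
        "shrinkage" (default observed-to-expected form) or "bcpnn"
        (Bate-1998 full Bayes).
    ic_lower_method
        "approx" closed form or "gamma" exact posterior quantile
        (shrinkage variant only).
    """

    threshold: float = 0.0
    ic_variant: str = "shrinkage"
    ic_lower_method: str = "approx"
    stratification: StratificationConfig = field(default_factory=StratificationConfig)

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


def _as_counts(data: ReportSet | DECCountTable) -> DECCountTable:
    return aggregate(data) if isinstance(data, ReportSet) else data


def _score_scope(counts: pd.Series, stratum: str, cfg: DetectionConfig) -> pd.DataFrame:
    n11 = counts.to_numpy(dtype=float)
    dm = counts.groupby(level="drug").sum()
    am = counts.groupby(level="adr").sum()
    n_drug = dm.reindex(counts.index.get_level_values("drug")).to_numpy(dtype=float)
    n_adr = am.reindex(counts.index.get_level_values("adr")).to_numpy(dtype=float)
    total = float(counts.sum())
    expected, ic, ic025 = ic_scores(n11, n_drug, n_adr, total,
                                    variant=cfg.ic_variant,
                                    lower_method=cfg.ic_lower_method)
    return pd.DataFrame({
        "drug": counts.index.get_level_values("drug"),
        "adr": counts.index.get_level_values("adr"),
        "stratum": stratum,
        "n11": counts.to_numpy(),
        "expected": expected,
        "ic": ic,
        "ic025": ic025,
        "positive": ic025 > cfg.threshold,
    })


def detect_nonstratified(data: ReportSet | DECCountTable,
                         cfg: DetectionConfig | None = None) -> pd.DataFrame:
    """Score every DEC against whole-dataset margins; one row per DEC."""
    cfg = cfg or DetectionConfig()
    counts = _as_counts(data).counts
    if counts.empty:
        raise ValueError("cannot run detection on an empty dataset")
    return make_signal_table(_score_scope(counts, "root", cfg))


def detect_stratified(data: ReportSet | DECCountTable,
                      cfg: DetectionConfig | None = None,
                      tree: StratumTree | None = None) -> pd.DataFrame:
    """Score every DEC within its frequency stratum.

    A pre-built `tree` may be passed to reuse a stratification; otherwise
    one is built from `cfg.stratification`.
    """
    cfg = cfg or DetectionConfig()
    table = _as_counts(data)
    if tree is None:
        tree = stratify_hierarchical(table, cfg.stratification)
    logger.info("stratified into %d leaves; sizes: %s", tree.n_leaves(),
                tree.leaf_sizes().to_dict())
    frames = [_score_scope(leaf, path, cfg) for path, leaf in sorted(tree.leaves.items())]
    return make_signal_table(pd.concat(frames, ignore_index=True))


def compare_detectors(base: pd.DataFrame, strat: pd.DataFrame,
                      counts: DECCountTable, threshold: float = 0.0) -> pd.DataFrame:
    """Join the two arms per DEC and flag newly unmasked signals.

    A DEC is *newly unmasked* when its baseline IC_025 is at or below the
    threshold while its stratified IC_025 exceeds it.  Rows are sorted by
    stratified IC_025 descending within drug.
    """
    b = base.set_index(["drug", "adr"])
    s = strat.set_index(["drug", "adr"])
    if set(b.index) != set(s.index):
        only_b = set(b.index) - set(s.index)
        only_s = set(s.index) - set(b.index)
        raise ConsistencyError(
            f"detector outputs cover different DEC universes "
            f"({len(only_b)} only in baseline, {len(only_s)} only in stratified)")
    dm = counts.drug_margins()
    idx = b.index
    out = pd.DataFrame({
        "drug": idx.get_level_values("drug"),
        "drug_total_frequency": dm.reindex(idx.get_level_values("drug")).to_numpy(),
        "adr": idx.get_level_values("adr"),
        "dec_frequency": b["n11"].to_numpy(),
        "ic025_nonstratified": b["ic025"].to_numpy(),
        "ic025_stratified": s["ic025"].reindex(idx).to_numpy(),
    })
    out["newly_unmasked"] = ((out["ic025_nonstratified"] <= threshold)
                             & (out["ic025_stratified"] > threshold))
    out = out.sort_values(["drug", "ic025_stratified"],
                          ascending=[True, False], kind="mergesort")
    return out.reset_index(drop=True)
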