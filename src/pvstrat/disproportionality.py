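"""Information Component (IC) disproportionality statistics.

For each drug--event combination (DEC) within a scope (the whole dataset or
one stratum) a 2x2 contingency summary is built:

* ``n11``    -- reports of the DEC itself,
* ``n_drug`` -- all reports mentioning the drug in scope,
* ``n_adr``  -- all reports mentioning the ADR in scope,
* ``n_total``-- all reports in scope.

Under drug--ADR independence the expected DEC count is
``E = n_drug * n_adr / n_total``.  The Information Component is the
shrinkage observed-to-expected log-ratio used to screen the WHO VigiBase::

    IC     = log2((n11 + 0.5) / (E + 0.5))
    IC_025 = IC - 3.3 (n11 + 0.5)^(-1/2) - 2 (n11 + 0.5)^(-3/2)

IC_025, the lower endpoint of the 95% credibility interval, is the decision
statistic: a DEC with IC_025 strictly above the threshold (default 0) is a
suspected signal.  The additive 0.5 shrinks small counts toward the null and
keeps every quantity finite.

Two alternative formulations are available: an exact gamma-quantile lower
bound (the posterior of the observed/expected rate is Gamma(n11 + 0.5) with
rate E + 0.5), and the original full-Bayes BCPNN (Bate et al. 1998) with its
delta-method variance.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
from scipy import stats

from .io import DECCountTable


class ContingencyTable(NamedTuple):
    """Per-DEC 2x2 summary within one scope."""

    n11: int
    n_drug: int
    n_adr: int
    n_total: int

    def validate(self) -> "ContingencyTable":
        if not (1 <= self.n11 <= min(self.n_drug, self.n_adr)):
            raise ValueError(f"invalid contingency table: {self}")
        if self.n_drug + self.n_adr - self.n11 > self.n_total:
            raise ValueError(f"margins exceed scope total: {self}")
        return self

    @property
    def expected(self) -> float:
        return self.n_drug * self.n_adr / self.n_total


class ICResult(NamedTuple):
    ic: float
    ic025: float
    expected: float


def build_tables(counts: DECCountTable) -> dict[tuple[str, str], ContingencyTable]:
    """One contingency table per DEC, margins computed within `counts` only."""
    s = counts.counts
    dm = counts.drug_margins()
    am = counts.adr_margins()
    total = counts.total()
    out = {}
    for (drug, adr), n11 in s.items():
        out[(drug, adr)] = ContingencyTable(int(n11), int(dm[drug]), int(am[adr]), total)
    return out


def ic_point(t: ContingencyTable) -> float:
    """Shrinkage IC point estimate in bits."""
    return math.log2((t.n11 + 0.5) / (t.expected + 0.5))


def ic_lower_bound(t: ContingencyTable, level: float = 0.975,
                   method: str = "approx") -> float:
    """Lower endpoint of the IC credibility interval, in bits.

    ``method="approx"`` uses the standard closed-form penalty (calibrated
    for the default 95% two-sided interval, i.e. ``level=0.975``);
    ``method="gamma"`` evaluates the exact gamma posterior quantile at
    probability ``1 - level``.
    """
    if method == "approx":
        s = t.n11 + 0.5
        return ic_point(t) - 3.3 * s ** -0.5 - 2.0 * s ** -1.5
    if method == "gamma":
        q = stats.gamma.ppf(1.0 - level, a=t.n11 + 0.5, scale=1.0 / (t.expected + 0.5))
        return math.log2(q)
    raise ValueError(f"unknown IC lower-bound method: {method!r}")


def ic_result(t: ContingencyTable, level: float = 0.975,
              method: str = "approx") -> ICResult:
    return ICResult(ic=ic_point(t), ic025=ic_lower_bound(t, level, method),
                    expected=t.expected)


def classify(ic025: float, threshold: float = 0.0) -> bool:
    """Suspected-signal rule: IC_025 strictly greater than the threshold."""
    return bool(ic025 > threshold)


# ---------------------------------------------------------------------------
# vectorized kernels used by the detection pipeline


def ic_scores(n11: np.ndarray, n_drug: np.ndarray, n_adr: np.ndarray,
              n_total: float, variant: str = "shrinkage",
              lower_method: str = "approx") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (expected, ic, ic025) for arrays of contingency margins.

    ``variant="shrinkage"`` is the default observed-to-expected form above;
    ``variant="bcpnn"`` is the Bate et al. (1998) full-Bayes posterior
    expectation with IC_025 = E(IC) - 1.96 sd(IC).
    """
    n11 = np.asarray(n11, dtype=float)
    n_drug = np.asarray(n_drug, dtype=float)
    n_adr = np.asarray(n_adr, dtype=float)
    expected = n_drug * n_adr / n_total
    if variant == "shrinkage":
        ic = np.log2((n11 + 0.5) / (expected + 0.5))
        if lower_method == "approx":
            s = n11 + 0.5
            ic025 = ic - 3.3 * s ** -0.5 - 2.0 * s ** -1.5
        elif lower_method == "gamma":
            q = stats.gamma.ppf(0.025, a=n11 + 0.5, scale=1.0 / (expected + 0.5))
            ic025 = np.log2(q)
        else:
            raise ValueError(f"unknown IC lower-bound method: {lower_method!r}")
        return expected, ic, ic025
    if variant == "bcpnn":
        ic, ic025 = _bcpnn_scores(n11, n_drug, n_adr, float(n_total))
        return expected, ic, ic025
    raise ValueError(f"unknown IC variant: {variant!r}")


def _bcpnn_scores(n11, n1_, n_1, n):
    """Bate et al. 1998 BCPNN IC posterior mean and 2.5% normal bound."""
    a1 = b1 = 1.0
    a = b = 2.0
    g11 = 1.0
    g = g11 * (n + a) * (n + b) / ((n1_ + a1) * (n_1 + b1))
    ic = np.log2((n11 + g11) * (n + a) * (n + b)
                 / ((n + g) * (n1_ + a1) * (n_1 + b1)))
    var = ((n - n11 + g - g11) / ((n11 + g11) * (1 + n + g))
           + (n - n1_ + a - a1) / ((n1_ + a1) * (1 + n + a))
           + (n - n_1 + b - b1) / ((n_1 + b1) * (1 + n + b))) / (math.log(2) ** 2)
    return ic, ic - 1.96 * np.sqrt(var)
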