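# Methods

## Disproportionality model

Within any scope (the full dataset or one stratum) each drug–event
combination (DEC) is summarised by a 2×2 contingency margin set: `n11`
reports of the DEC, `n_drug` reports of the drug, `n_adr` reports of the
ADR, and `N` reports in the scope. Under independence the expected DEC
count is `E = n_drug·n_adr/N`. The default statistic is the shrinkage
Information Component

    IC     = log2((n11 + 0.5)/(E + 0.5))
    IC_025 = IC − 3.3(n11 + 0.5)^(−1/2) − 2(n11 + 0.5)^(−3/2)

the form adopted by the Uppsala Monitoring Centre for routine VigiBase
screening. The additive 0.5 keeps all quantities finite and shrinks small
counts toward the null; the IC_025 penalty is the standard closed-form
approximation to the 2.5% posterior quantile. A DEC is a suspected signal
iff `IC_025 > threshold` — strictly greater, with threshold 0 bits by
default. Two alternatives are selectable:

* **Exact gamma lower bound** (`ic_lower_method="gamma"`): the posterior of
  the observed/expected rate is `Gamma(shape = n11 + 0.5, rate = E + 0.5)`;
  IC_025 is log2 of its 2.5% quantile (scipy). The closed form tracks it
  within 0.15 bits for `n11 ≥ 5` (tested); they diverge only at very small
  counts, where both are far below 0.
* **Full-Bayes BCPNN** (`ic_variant="bcpnn"`): the Bate et al. (1998)
  Dirichlet posterior expectation of IC with its delta-method variance,
  IC_025 = E(IC) − 1.96·sd(IC). Offered because older screens used it; the
  shrinkage form is the default since it is today's de facto standard.

DECs with `n11 = 0` in a scope do not exist in that scope's table set; no
zero rows are fabricated. A DEC alone in its stratum yields a saturated
table (`n11 = n_drug = n_adr = N`), hence IC = 0 and a negative call; it is
reported rather than dropped so both detection arms always cover the same
DEC universe.

## Stratification procedure

Masking operates through the margins: over-reported entities inflate `E`
for every combination they touch. Stratification partitions the dataset
into clusters of similar reporting magnitude and recomputes margins within
each cluster, in the fixed order **drugs → ADRs → DECs** (the axis order of
decreasing masking leverage). At each level, within the current scope:

1. per-entity report frequencies are computed **within the scope** (ADR and
   DEC frequencies are therefore conditional on the parent cluster — the
   only reading under which "divide each cluster by ADR frequency" is
   well-defined);
2. frequencies are ln-transformed (compressing, e.g., a 3…111,335 range
   into roughly [1.1, 11.6]);
3. a histogram with bin width 0.5 (ln units), origin at the scope minimum,
   is scanned for peaks: a peak is a maximal run of equal counts strictly
   greater than both flanking counts, boundary runs needing only to exceed
   their single neighbour; a flat histogram counts as one peak. The peak
   count, clamped to `max_k` (default 5), sets k. No smoothing is applied:
   the clamp is the only guard against noise-driven oversplitting;
4. scopes with fewer than `min_entities` (default 10) distinct entities are
   not split (k forced to 1): a tiny scope cannot support a meaningful
   histogram, and real stratifications do visibly leave some strata
   unsplit;
5. one-dimensional k-means is solved **exactly** by dynamic programming
   over the sorted distinct values with multiplicities as weights (optimal
   1-D clusters are contiguous, so an O(k·m²) DP over m distinct values
   finds the global optimum). This replaces randomly-seeded Lloyd
   iteration deliberately: it is deterministic, reproducible, and its
   objective is never worse than any Lloyd run (cross-checked against
   scikit-learn in the tests). Entities with identical ln-frequency always
   share a cluster. Labels are 1-based in ascending cluster-centre order.

Leaves are labelled `i-j-l` by the three levels' labels; they partition the
records, and each DEC occurs in exactly one leaf (drug fixes level 1, ADR
level 2, its count level 3). Forcing `max_k = 1` collapses the tree to the
single leaf `1-1-1` and makes stratified detection bit-identical to the
whole-dataset baseline (tested).

## Evaluation

Known DECs are reference-database pairs *present in the dataset*; reference
pairs never reported are outside the evaluation universe (they can never be
detected, and including them would deflate recall arbitrarily). The
four-way split of (known, positive) gives TP/FP/FN/TN; Precision =
TP/(TP+FP), Recall = TP/(TP+FN), F their harmonic mean, all 0 when
undefined. Percentages are reported at 2 decimals; raw fractions are kept
internally. Relative changes between arms are computed on values as given
(applied to 2-dp percentages they reproduce published-style rounded
changes). The precision–recall curve sorts DECs by IC_025 descending, ties
broken lexicographically by (drug, adr), and accumulates precision and
recall after each DEC.

The masking diagnostic defines masked DECs as known DECs called negative by
the **non-stratified** detector. For each axis (drug, ADR, DEC) it compares
the unweighted mean report frequency over the distinct entities involved in
masked DECs against the unweighted mean over all distinct entities, and
reports the percentage decline. Unweighted distinct-entity means were
chosen because the overall drug mean of a real dataset (total records /
number of drugs) matches that convention; weighting by masked-DEC
multiplicity is a defensible alternative the package does not implement.
With no masked DECs the masked means are reported absent (NaN).

## Synthetic data

The generator emulates the structural features of a national SRS that the
method depends on, with full ground truth:

* **Marginals**: drug and ADR report propensities are drawn from lognormal
  mixtures and normalised. Defaults: 300 drugs from three components
  (weights .45/.40/.15, ln-means 0/2.5/5.0, ln-sd 0.6) — a mass of rare
  drugs, a mid tier and a short head, reproducing the multi-peaked
  ln-frequency histograms seen in real data — and 150 ADRs from two
  components (.60/.40, ln-means 0.5/3.5, ln-sd 0.7); 50,000 reports, the
  scale at which peak counting and rank-correlation recovery are reliable
  while a full pipeline run stays under a few seconds.
* **Baseline reports** are multinomial over the independence joint
  `p_drug ⊗ q_adr`.
* **Planted signals** multiply their cell probability by a risk multiplier
  (> 1) before renormalisation — the generative analogue of an elevated
  observed-to-expected ratio. Generation retries (bounded) until every
  planted DEC is reported at least once.
* **Blockbusters** append a fixed extra count to chosen cells after
  sampling, making masking strength exactly controllable.

One seeded `numpy` Generator drives everything; identical config + seed
gives byte-identical output files.

`masking_scenario(seed)` is the canned masking study: 120 drugs and 60 ADRs
with unimodal baseline propensities, 30,000 baseline reports, three
blockbuster drugs each over-reported 8,000× on one common ADR (inflating
that ADR's margin ~50-fold), and six true signals (risk 8) pairing ordinary
drugs with that same ADR. Globally the inflated ADR margin pushes the
planted signals' IC_025 below 0; inside the ordinary-drug stratum the
blockbuster mass is absent and they resurface. The construction is
*verified at generation time* by running both detectors: at least one truth
DEC must flip negative→positive and the stratified arm must recover
strictly more truth; otherwise the dataset is resampled with a derived seed
(bounded retries, then an error).

What passing on synthetic data does **not** show: fidelity to any real
database's generating process (report quality, duplicate reports, temporal
dynamics, coding noise, report-level covariates are all absent), so
measured precision/recall levels are scenario properties, not forecasts for
real data. The claims that do transfer are structural: the partition
invariants, the determinism, the k=1 equivalence, and the direction of the
unmasking effect under margin inflation.

## Numerical and design notes

* Histograms use half-open bins `[origin + i·w, origin + (i+1)·w)` with the
  last bin closed, so counts are conserved.
* The k-means DP works on distinct values with weights; complexity is
  O(k·m²) in the number of distinct ln-frequencies, which for count data is
  far below the number of entities.
* `relative_change` refuses a zero baseline; metric denominators of zero
  yield 0 by convention.
* Signal tables serialise floats at 9 significant digits; row order is
  (stratum, drug, adr) lexicographic, making outputs diffable.
* File identifiers are whitespace-stripped but case-preserved: without a
  terminology dictionary, aggressive normalisation risks merging distinct
  terms. Duplicate report rows are counted, never deduplicated.
* The detection threshold comparison is strict (`>`), so an IC_025 of
  exactly 0 is negative.

## Known limitations

* The peak-counting rule is a simple formalisation; ragged histograms near
  the `max_k` clamp can change k with small data perturbations (the
  stratification is deterministic but not perturbation-stable).
* The choice that ADR/DEC frequencies are scoped to the parent cluster is a
  design decision; a global-frequency variant would give different trees.
* Stratification can in principle also *lose* signals (a DEC dominant in
  its small stratum saturates toward IC = 0); the package reports such
  rows rather than hiding them, and no superset guarantee is claimed for
  stratified positives.
* BCPNN and gamma-bound variants share the pipeline but not the closed-form
  test oracle; they are validated by sanity properties (finiteness, bound
  below point estimate, near-zero IC at independence) and cross-agreement.
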