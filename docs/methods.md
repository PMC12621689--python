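# Methods

## Signature model and data levels

The package operates on dense genes × signatures matrices of
differential-expression Z-scores. A Z-score here expresses *confidence* in
a gene's regulation, not effect size on a fold-change scale; this is why
the aggregation below is a weighted mean rather than a meta-analytic
combination that would inflate magnitudes with replication depth.

Genes are partitioned into confidence classes: **LM** (landmark, directly
measured; the ~978-gene space in which all correlations are computed),
**BING** (best-inferred imputed genes), and **INFERRED** (remaining imputed
genes). The class assignment is supplied as a two-column TSV rather than a
hard-coded list, so the tool is agnostic to compendium version.

Data levels follow the L1000 convention: L4 per-replicate Z-scores, L5
replicate-collapsed signatures, L6 consensus genetic signatures (CGS; shRNA
sequences collapsed per gene × cell × time × dose), and CS — the
cross-context consensus this package produces.

## MODZ aggregation

Given n signatures of one perturbagen, the weight of signature i is

    α_i ∝ Σ_{j≠i} max(ρ_ij, 0.01),   Σ α_i = 1,

with ρ the Spearman correlation over LM rows. Numerical conventions, all
pinned so results are bit-stable:

- **Ties** receive average ranks (ties are essentially absent in real
  Z-score data; the choice is visible only on synthetic integer toys).
- **Floor placement**: the 0.01 clip is applied to each pairwise term
  *before* summation, never to the summed weight. The floor guarantees
  every weight is strictly positive.
- **n = 1**: the pairwise sum is empty; the convention is weight 1.0 and
  the signature passes through unchanged. Single-member groups occur in
  sparse metadata and are reported, not dropped.
- Weights are computed on LM rows only and then applied to **all** genes,
  including imputed ones.
- A rank-constant column has no defined Spearman correlation and is
  rejected with the column named; under the opt-in missing-value policy,
  correlations become pairwise-complete and require ≥ 3 shared finite rows.

The implementation is checked against a brute-force oracle that evaluates
the same formula in exact rational arithmetic (Fractions end to end, with
floating point entering only in the final square root of the rank-variance
product); agreement is required to 1e-10 on an enumeration of 500 small
integer matrices.

## Consistency QC

A signature group passes the gold-standard gate when the 75th percentile
of its pairwise Spearman correlations is **at least** 0.2 (inclusive at the
boundary, matching the stated criterion). The percentile uses linear
interpolation between order statistics (numpy's default, the "type 7"
estimator); whether the original LINCS computation interpolated or used
nearest ranks is not documented, so this convention is pinned but not
claimed to match byte-for-byte.

Cross-context consistency extends the same gate across cell lines: within
each (perturbagen × time × dose [× shRNA sequence]) group spanning ≥ 2
cell lines, only pairs from *different* cell lines enter the q75 —
within-cell replicate pairs would inflate the score with ordinary replicate
reproducibility. Groups with fewer than two contexts are skipped and
counted. No distinctness test is applied anywhere, deliberately.

Representativeness of a consensus is the median Spearman correlation (LM
genes) between the consensus vector and each of its components.

## Consensus construction

Compound CS pools **all** of a perturbagen's Level-5 signatures — every
cell, time, and dose — into one MODZ group; an optional flag restricts to
the modal dose instead. Knockdown CS aggregates Level-6 CGS, which are
themselves MODZ collapses of Level-5 signatures over shRNA sequences
within (gene, cell, time, dose). Eligibility requires signatures in ≥ 4
distinct cell lines (cells, not signatures, are counted; the boundary is
inclusive). A consensus failing the gold gate is still returned, flagged
non-gold, so callers decide whether to filter.

The subset sweep rebuilds each perturbagen's CS from every non-empty
subset of a cell-line panel and summarizes the distribution of
inter-perturbagen Spearman correlations by subset size. Enumeration is
exhaustive up to 4096 subsets; larger panels fall back to uniform sampling
per size under the run seed. For a 9-cell panel there are 511 non-empty
subsets (2⁹ = 512 counts the empty set; the tool enumerates non-empty
subsets only).

The self-knockdown screen extracts, for each knockdown CS, the Z-score of
its own target gene. The significance rule is configurable and defaults to
a robust z-score within the CS column: |z − median| / (1.4826·MAD) ≥ 2,
direction from the sign. Knockdown resistance — a *positive* outlying
self-Z where down-regulation is expected — is the phenotype of interest.

## Statistics

One-sided Mann–Whitney U tests ("greater") are exact for pooled sample
sizes m + n ≤ 10, by enumeration of all C(m+n, m) label assignments with
the half-credit U statistic, which handles ties exactly; larger samples
use the normal approximation with tie and continuity corrections. AUROC
uses the midrank formulation, equivalent to pair counting with half credit
for tied scores — the convention under which flipping all score signs maps
AUROC to 1 − AUROC exactly. Genes with zero Z or zero log2FC carry no
sign and are excluded from direction labels and agreement splits, with
counts reported. Class-similarity reports add a Benjamini–Hochberg column,
but downstream logic uses raw p-values.

## Synthetic compendium generator

The generator draws each observed signature as

    s = a_p · CS_p + ε_c + ε_t + ε_d [+ ε_seq] + ε_obs

with CS_p standard normal per gene (signal sd 1), offsets drawn once per
perturbagen × coordinate from N(0, σ²) at the configured scales, and
i.i.d. per-entry observation noise. Defaults are the study conditions used
throughout the tests: 978 genes, the 9 core cell lines (A375, A549, HA1E,
HCC515, HEPG2, HT29, MCF7, PC3, VCAP), time points 6 h and 24 h, a
four-point dose range up to 10 µM, and all context noise scales at 0.5
(half the signal sd) with observation noise 0.2. Offsets are
per-perturbagen by default; a flag shares cell offsets across perturbagens
to emulate cell-line identity effects (both readings of "noise indexed by
coordinate" are plausible; the per-perturbagen default is the weaker
assumption). Optional class structure mixes a shared class profile into
member perturbagens at a stated variance fraction. The per-perturbagen
activity amplitude a_p defaults to 1; TAS, when simulated, is a clipped
monotone function of activity and dose rank plus noise — enough to give
the TAS diagnostics realistic inputs, with no claim to the real TAS
formula, which the package never computes.

All randomness flows from a single integer seed through named
sub-streams, so identical configs reproduce matrices bit for bit.

What the generator does **not** emulate: gene–gene covariance, heavy-tailed
noise, batch effects, dose–response saturation, or the L1000 imputation
process. Passing tests on this synthetic data therefore demonstrate
correctness of the aggregation and analysis machinery under the additive
model — not that real compendia satisfy that model.

## Validation analyses and their problem sizes

- **Zero-noise recovery**: with all σ = 0 every component equals CS_p, so
  the consensus must equal the truth to float-summation tolerance (1e-12);
  run at 978 genes, 5 perturbagens, 9 cells, 2 times, 2 doses.
- **Noisy recovery**: σ_c = σ_t = σ_d = 0.5, 978 genes, 8 cells, 2 times,
  2 doses, 12 perturbagens, 20 seeds. Two claims are checked: the
  seed-averaged curve of median Spearman(CS, truth) versus number of
  integrated cell lines is non-decreasing, and the full CS beats the best
  single-context component median in ≥ 95% of seeds. (Per-seed strict
  monotonicity across all eight sizes is deliberately not the claim;
  adjacent increments at large cell counts are smaller than per-seed
  noise, which is why monotonicity is a property of the averaged curve.)
- **Null control**: per-cell, per-gene normal moments are fitted from a
  base compendium and fresh independent signatures are sampled from them;
  the subset sweep over the 9 cells must keep the mean inter-perturbagen
  correlation within ±0.05 of zero at every subset size (20 null
  perturbagens, 978 genes). The base compendium uses 200 perturbagens: the
  fitted per-cell mean vector carries the base's average true profile with
  variance ~1/n_perturbagens, and a small base would leak that average into
  every null signature as a shared component that MODZ then amplifies — an
  artifact of the base size, not a property of MODZ. Real compendia fit
  this regime: per-gene Z means over thousands of perturbagens are ~0.
- **Gate semantics**: engineered rank permutations of 1..9 with pairwise
  Spearman exactly (0.1, 0.1, 0.4) give q75 = 0.25 (pass); all-0.1 groups
  fail; the 0.2 boundary is inclusive.
- **Statistical oracles**: Mann–Whitney exact p-values are compared to a
  rank-sum enumeration oracle on every (m, n) with m + n ≤ 10 including
  tied pools; AUROC is compared to explicit pair counting on inputs up to
  12 pairs.

These sizes keep the full validation run around half a minute while
leaving each stochastic check several standard errors of headroom.

## Known limitations

- Dose unit harmonization (normalization to µM, equality within 1e-6
  relative tolerance) is this package's convention; source compendia do
  not document theirs.
- TAS is consumed as metadata only; records lacking TAS are excluded from
  TAS analyses but never from consensus construction.
- The intra-class single-cell analysis pools all signature-pair
  correlations between distinct class members rather than collapsing per
  drug pair first; the alternative reading is noted but not implemented.
- GCTX support covers the matrix and id datasets, not the full metadata
  group layout; GCT 1.3 text is the reference dialect.
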