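# Methods

This note records the model, the numerical choices, and the open design
decisions behind `emaplink`, in the spirit of a statistical-software methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The prediction model and its assumptions

The method assumes that genes with correlated interaction profiles within
one screen have globally similar profiles, so a well-correlated overlap gene
can stand in for a gene absent from the other screen. This can fail for
multi-functional genes whose similarity is local to one screen's theme; the
high default similarity threshold is the guard against such spurious
neighbors. The method never imputes values *within* a screen — it only
scores pairs that were measured in neither screen, and only when it can do
so through a qualifying neighbor.

Definitions used throughout:

- **Interaction profile** of gene g: the vector of measured S-scores
  between g and all other genes in its screen.
- **Similarity**: Pearson correlation over partners measured for both
  genes. Two positions are always excluded: each gene's own column, and the
  mutual cell of the two genes being compared. The mutual-cell exclusion is
  a deliberate conservative choice: a single directly measured interaction
  between two genes must not inflate their profile similarity. Its
  practical effect is small (one point out of ≥70) but it also makes the
  leave-one-out algebra clean (withholding the cell (i, s) cannot change
  the correlation between i and s themselves).
- **Nearest neighbor**: the anchor with maximal r. Exact ties are broken by
  larger support, then lexicographically smaller identifier — deterministic
  and seed-free. Raising the similarity threshold never changes which
  anchor is nearest, only whether it qualifies; the threshold-sweep and
  monotonicity guarantees rest on this.
- **Sources**: only the single nearest neighbor per gene is consulted
  (K = 1). If it qualifies but the needed cell is missing, that side simply
  contributes nothing; there is no fallback to the second-nearest anchor.
  When both sources exist they are averaged even if they disagree in sign;
  both sources are recorded in the output so users can filter.

### Tunable parameters

| parameter | default | meaning |
|---|---|---|
| similarity threshold | 0.6 | minimum neighbor correlation (dimensionless, in [−1, 1]); the operating point trading fewer, more accurate predictions against many less accurate ones |
| min_support | 70 | minimum co-measured partners behind a correlation; at n = 70, r = 0.6 has two-sided p < 1e-7 via the t transformation, so chance neighbors are negligible |
| positive_min / negative_max | 2.0 / −2.5 | S-score cutoffs for strong positive/negative epistasis (conventional E-MAP values; asymmetric because the S-score null is asymmetric) |
| permutation n_samples | 10^6 | null sample count for complex links; reducible (tests and the acceptance script use 400–10^4 and state so below) |
| alpha | 0.001 | per-direction significance for complex links |

## Numerical choices

- **Correlations from sufficient statistics.** Similarity is computed from
  (n, Σx, Σy, Σxy, Σx², Σy²) over the joint measurement mask rather than
  from centered vectors. Two consequences: (1) leave-one-out withholding is
  an O(#anchors) downdate — subtract the withheld column's contribution —
  which a brute-force full-recompute oracle in the test suite matches to
  1e-10; (2) bitwise-identical profiles give r = num/sqrt(num·num), which
  in IEEE-754 double arithmetic is exactly 1.0, so noise-free duplicate
  fixtures are recovered *exactly*, not approximately. The elementwise
  operations are arranged so the x- and y-statistics of identical vectors
  are themselves bitwise identical.
- **Constant profiles.** A restricted profile whose variance term is below
  1e-12 of its scale is treated as constant and the correlation is
  *absent*, never 0 or ±1 — similarity is not fabricated for degenerate
  vectors.
- **NRMSE.** RMSE divided by the sample standard deviation (ddof = 1) of
  the observed values; the normalizer is configurable to `range`. With a
  degenerate normalizer the value is absent rather than infinite.
- **Classification boundaries are strict**: S = 2.0 and S = −2.5 are
  neutral.
- **Asymmetric input cells.** Real TSV matrices sometimes carry unequal
  values above and below the diagonal. The default dialect averages them
  with a logged warning; a strict dialect raises an error listing the
  offending pairs.
- **Merging rules** for the combined matrix: measured values are averaged
  across screens; a measured value always beats a prediction; multiple
  predictions for one pair are averaged. Provenance (`measured`,
  `measured_multi`, `predicted`) is recorded per pair.
- **Permutation null.** Samples of k interactions are drawn *without
  replacement* from the pool of all present values of the combined matrix
  (the global pool; a same-row-restricted pool was considered and rejected
  as under-specified). Each tail's p-value uses the add-one correction
  (1 + #extreme)/(1 + N), so p is never 0 and the floor is 1/(N + 1). The
  reported p is the smaller tail with its polarity; calibration is per
  direction (the min-tail fires at ~2α under the null, which is why both
  tail p-values are exposed on the result). Null medians are cached per
  bridge size k with a (seed, k)-keyed substream, so a catalog-wide scan
  and a single-pair test agree exactly.
- **Shared subunits.** Genes belonging to both complexes of a tested pair
  are excluded from the bridge, so intra-complex values never masquerade as
  inter-complex evidence.
- **Enrichment** uses the one-sided hypergeometric upper tail against the
  universe of all predicted pairs from the same run — enrichment is judged
  against what the method could have called, not against all conceivable
  pairs (an alternative universe can be supplied). Raw p-values are
  reported, with a Benjamini–Hochberg column alongside; no correction is
  applied to the primary values.

## The synthetic generator

The generator emulates the structure the method exploits, not any specific
organism. Genes are assigned uniformly to latent modules; a sparse subset
of module pairs carries a nonzero mean S-score (planted monochromatic
blocks); every gene pair adds an iid Gaussian residual; each screen
observes truth plus iid Gaussian noise under an independent uniform
missingness mask. All randomness flows from one seed through named
SeedSequence children.

Defaults (chosen once to land in the regimes reported for real screen
pairs, and not revisited): 100 shared genes with 150 screen-specific genes
per side; missing fractions 0.30 and 0.15 (real screens span ~12–35%);
20 modules; block density 0.10 with magnitudes U(2.5, 6), 70% negative
(negative epistasis dominates real data); residual sd 1.0; screen noise sd
1.2. With these, Var(truth) ≈ 2.9 per pair and the expected cross-screen
correlation over co-measured pairs is Var(T)/(Var(T) + σ²) ≈ 0.65,
matching the ≈0.5–0.7 observed for real overlapping screens.

What the generator does *not* model — and hence what passing tests do not
establish about real data: allele-specific effects (two alleles of one gene
behave identically here), screen-level batch structure, the exact empirical
S-score distribution (real tails are heavier than Gaussian residuals),
row-correlated missingness (a row-biased mask option exists but is off by
default), and genes whose module membership differs between biological
contexts. Results on synthetic data demonstrate correctness of the
machinery and calibration of the statistics, not field accuracy.

## Problem sizes used by the tests and acceptance script

Simulation-heavy checks run at deliberately modest sizes chosen as adequate
for their statistical purpose: oracle-equivalence screens of ≤15 genes
(100 seeds), leave-one-out on the 250 + 250 allele default pair,
permutation calibration with 200 repetitions of 400 null samples (p
resolution 1/401 at α = 0.05), planted-block recovery at 10^4 samples, and
a 10^5-draw Monte-Carlo check of the hypergeometric tail. The permutation
default of 10^6 samples remains the recommendation for real catalog scans.

## Known limitations

- Leave-one-out re-derives the withheld gene's neighbor per cell but keeps
  the partner-screen neighbor table fixed (the withheld cell cannot affect
  it); if both screens measured the same pair, that duplication is not
  exploited.
- The second leave-one-out source mirrors the symmetric prediction rule by
  routing through the overlap gene's neighbor in the partner screen; other
  conventions (e.g. within-screen only) would change the record count
  slightly at a given threshold.
- Complex-link p-values at a shared bridge size reuse one null sample; this
  is a variance-reduction/caching choice, not an approximation of the test
  itself.
- No ROC/AUC machinery and no K > 1 weighted-neighbor variant are provided.
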