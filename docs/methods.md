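# Methods

## The analysis problem

A locus-wide MeDIP-chip study asks whether ~1-kb stretches of a candidate
gene's neighborhood are differentially methylated between two groups of
subjects, and whether methylation there tracks a continuous plasma
phenotype. Signals are weak (fractions of a log2 unit), groups are small
and unbalanced (8 cases vs 12 controls here), and thousands of 100-bp
probes are tested — so the method combines probe-level evidence sharing
(variance moderation), region-level aggregation (rank-sum enrichment) and
family-wise FDR control, with a final probe-level effect-size filter for
biological relevance.

## Normalization

Per array, `M = log2(bound/input)`. Arrays of one cell type are
quantile-normalized jointly (every array's order statistics are forced
onto the across-array mean of order statistics; within-array ties receive
the mean of the reference quantiles they span), then the technical
replicate arrays of each sample are averaged (arithmetic mean by default,
median by option). Cell types are normalized and analyzed separately
throughout: sorted T cells and monocytes have genuinely different
methylomes, and normalizing them together would dilute both. Non-positive
channel intensities are a hard error, never silently offset — they signal
an upstream conversion problem.

With within-column ties, the equal-distribution property of quantile
normalization holds only approximately (tie groups share averaged
quantiles); the tests therefore assert exact equality on tie-free data and
the documented averaging rule on a tied example.

## Moderated t and its hyperparameters

The pooled two-sample variance of each probe is shrunk toward a prior:
`s̃² = (d0·s0² + df·s²)/(d0 + df)`, `t = Δ/(s̃·sqrt(1/nA+1/nB))`, two-sided
p from t with `d0 + df` degrees of freedom. `(d0, s0²)` are estimated by
method of moments on `z = log s²`: the excess of `Var(z)` over the
trigamma sampling term gives `d0` by trigamma inversion (Newton), and the
corrected mean of `z` gives `s0²`. When the observed spread of `z` does
not exceed its pure-sampling expectation there is no evidence of variance
heterogeneity: `d0 = ∞` and `s0²` is set to the geometric mean of the
observed variances, so that in the fully degenerate case (all variances
equal) posterior variances equal the common variance exactly. The unit of
analysis is the replicate-averaged subject column, not the individual
array — triplicates are technical, and treating them as units would
pseudo-replicate. The implementation is cross-checked in the test suite
against frozen output of the limma reference implementation
(lmFit/eBayes, limma 3.58.1) on a 30-probe fixture, agreeing to ~1e-13.

## Region calling

Windows of exactly 1000 bp are anchored at the first tiled position of
each locus; the last window is truncated at the end of the tiled span.
Probes are assigned by start coordinate; windows with fewer than 3 probes
are untestable and excluded from the FDR family (not assigned p = 1),
since a rank-sum test on one or two probes is powerless.

The region statistic is a Wilcoxon rank-sum test of the region's probe
scores against background probes, run as two one-sided tests combined by
`p = min(1, 2·min(p⁺, p⁻))`. This doubling construction, rather than a
single two-sided test on |t|, preserves a per-region direction. Midranks
handle ties. When region + background ≤ 25 probes the permutation null is
enumerated exactly by a subset-sum counting recursion over doubled
midranks (both one-sided p-values inclusive of the observed statistic);
larger families use the normal approximation with the standard tie
correction and a 0.5 continuity correction. The exact path is
property-tested against brute-force enumeration of all subsets for every
split of up to 12 probes.

The background is all other probes of the same locus by default
(config-switchable to array-wide). Locus-restricted background avoids
confounding a region's shift with locus-to-locus differences in the score
distribution; with several loci on one array either choice is defensible,
and the option records that openness. BH-FDR runs once over all testable
regions of a cell type, across loci, per statistic kind.

A region is called only if `q ≤ region_fdr_max` (default 0.2) *and* some
in-region probe is individually significant (`p ≤ 0.05`), has
`|lfc| ≥ 0.25` (or `|r| ≥ 0.5` in the correlation arm), and agrees in sign
with the region direction. The sign-concordance requirement prevents
calling a region "higher in cases" on the strength of an opposite-sign
probe. The reported `mean_lfc`/`mean_r` averages all in-region probes so
users can impose a stricter region-level effect filter (e.g. 0.5) without
re-running.

## Phenotype correlation arm

Per probe, Pearson r over subjects present in both tables (pairwise
deletion of missing phenotypes; ≥ 3 pairs required), two-sided p from the
exact t transform on n − 2 degrees of freedom. A constant phenotype is an
error; a constant probe row yields an undefined correlation (NaN) and is
excluded from region scoring. Region aggregation, FDR and calling are
identical to the contrast arm with directions positive/negative.

## Annotation

Distance is measured from the region midpoint to the TSS — region tables
report a single signed distance per region, which implies a point anchor;
the nearest-edge alternative is a config option. Distances are
strand-oriented (negative = upstream on the gene's strand) and the
promoter flag tests the midpoint against the inclusive window
[TSS − 2000, TSS + 1000]. A region whose midpoint sits at −2042 bp is
therefore *not* promoter-proximal. Ties in nearest-gene assignment break
lexicographically for determinism. Element overlap is binary at ≥ 1 bp on
half-open intervals with no reciprocal-fraction requirement, matching the
binary "coincides with" usage of regulatory-track summaries; the interval
index is cross-checked against brute-force all-pairs intersection.

## Pyrosequencing validation statistics

Technical replicates are averaged within subject first, making all group
statistics invariant to replicate-count imbalance; group mean and SEM
(sd/√n over subjects) are reported per CpG and for the mean over all CpGs
of the region, compared by a two-sided equal-variance Student t-test
(Welch by flag). Significance tiers are marked at p ≤ 0.1 ('#') and
p ≤ 0.05 ('*'). The per-subject region mean can be correlated with a
plasma level (Pearson, pairwise-complete, ≥ 3 pairs).

## Synthetic-data generator

The generator emulates the study design this pipeline targets: 8 vs 12
subjects, 2 cell types, 3 replicate arrays per sample, probes at 100-bp
spacing tiling 100–180-kb loci, planted DMRs of ~1000 bp with log2
effects, and phenotypes linked linearly to a planted region's true
methylation.

Signal model, per cell type, subject i, replicate r, probe p:

```
M[i,r,p] = baseline[p] + effect[p]·1{i in group A}
           + u[i,p] + a[i,r] + e[i,r,p]
u ~ N(0, subject_sd²)    per-subject biological deviation (default 0.3)
a ~ N(0, replicate_sd²)  per-array technical offset      (default 0.2)
e ~ N(0, probe_noise_sd²) per-measurement noise           (default 0.3)
```

all in log2 units. The baseline is a smooth per-locus sinusoid (amplitude
0.5, period 25 kb, deterministic phase), mimicking slowly varying average
methylation without affecting group differences. The noise magnitudes are
engineering defaults chosen once at values typical of replicated
two-channel arrays — they produce a replicate-averaged per-subject probe
SD of ≈ 0.37 log2 units, so a planted 1.0-log2 effect is comfortably but
not trivially detectable at n = 8 vs 12, and sub-threshold effects are
not. Channels are built as a log-normal input (log2 brightness
N(10, 0.5)) with `bound = input·2^M`, guaranteeing positive intensities
and exact planted log-ratios. One master seed drives deterministic
sub-streams per cell type/subject/array, so regeneration is bit-identical
and partial structures are reproducible.

What the generator does *not* emulate: CpG-density-dependent MeDIP
enrichment bias, dye bias, spatial array artifacts, or correlated probe
noise along the genome. Passing recovery/calibration tests therefore
demonstrates correctness of the statistical machinery under the stated
noise model, not robustness to those real-data artifacts.

## Operating characteristics and problem sizes

`tilemeth.benchmarks` measures, over 50 seeded studies each (two 30-kb
loci per study — the replication problem size chosen to make 50-fold
Monte-Carlo cheap while preserving region/background geometry):

* **Null calibration** — with no planted effects, every call is false;
  the mean false-discovery proportion at nominal region FDR 0.2 is ~0.1
  in the committed runs, within the expected envelope (mean FDP ≤ 0.25).
* **Recovery** — planted ±1.0 log2 regions are recovered with the correct
  direction with sensitivity 1.0 under default noise; a slope-1,
  low-noise phenotype link is likewise recovered by the correlation arm.

`scripts/acceptance.py` recomputes these plus a single full-scale
eight-locus, two-cell-type study (≈ 11,200 probes, 120 arrays) end to end.

## Known limitations

* Replicate-level (array-as-unit) analysis is supported only via the
  replicate-reduction options, not as a separate inference mode.
* No covariate adjustment, variance trends, or multi-factor designs in
  the moderated-t model.
* Windows are fixed and disjoint; no sliding windows or merging of
  adjacent called regions.
* Scanner-native file formats (e.g. Agilent feature extraction) are out
  of scope; inputs are the documented TSV dialects.
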