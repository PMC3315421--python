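# Methods

## qPCR model and the Ct–Ct estimator

The simulator and estimator share one model of real-time PCR. A reaction
with starting template *Q* (arbitrary units) and per-cycle amplification
efficiency *E* ∈ (1, 2] crosses a common fluorescence-equivalent threshold
*T* at

    Ct = (log10 T − log10 Q) / log10 E  (+ Gaussian cycle noise).

All logarithms are base 10: the base cancels in ratios, but base 10 matches
the dilution-decade convention in which a standard curve's slope is
−1/log10 E cycles per decade (−3.32 at perfect doubling). Target and
control genes of one sample share the input amount: the control gene sees
`Q_c = A_s` and the target `Q_g = R·A_s`, where `R` is the condition's true
relative expression. Per-sample inputs are log-normal,
`A_s = q0·10^N(0, s²)`; Ct noise is additive Gaussian on the cycle scale,
applied after the deterministic Ct. Under this model the (Ct_c, Ct_g)
points of a condition lie exactly on

    Ct_g = m·Ct_c − log10(R)/log10(E_g),    m = log(E_c)/log(E_g),

so the Y-intercept measures R once E_g is known, and the whole analysis is
a regression problem. The threshold *T* is assumed shared between target
and control within a run; without that assumption the intercept picks up a
constant offset `(log T_g/log E_g − m·log T_c/log E_c)`-style term that
cannot be separated from R. The generator makes the assumption explicit
rather than guessing an offset.

### Slope handling during quantification

The Ct–Ct plot is drawn as an ordinary least-squares fit of Ct_target on
Ct_control (not an errors-in-variables fit; both axes carry noise, and this
choice — fidelity to how such plots are read — biases the *slope* toward
zero when control-side noise is non-negligible). The freely fitted slope is
used only as QC: each fit is flagged when it deviates from the theoretical
`log(E_c)/log(E_g)` by more than 0.1.

For the fold change itself the intercept is re-estimated with the slope
*fixed* at its theoretical value, `Y = mean(Ct_g) − m·mean(Ct_c)`, whenever
both efficiencies are available from standard curves. The reason is
quantitative: with Cts near 20 cycles the free-fit intercept is an
extrapolation ~20 cycles outside the data, so its variance is
σ²(1/n + x̄²/Sxx) — on the order of whole cycles for realistic designs
(σ = 0.3 cycles, five samples spanning ±1 decade of input). Exponentiating
a cycle-scale error produces a heavy-tailed, badly biased linear fold
change. Fixing the slope removes the leverage term: the intercept error
falls to σ√((1+m²)/n) ≈ 0.2 cycles and per-group fold changes acquire the
sub-30% spread that replicate-group SEMs in this literature actually show.
The two estimators coincide exactly on noise-free data, so every round-trip
identity holds either way; at E_g = E_c the fixed-slope estimator is
algebraically identical to `2^(−ΔΔCt)` with per-condition mean ΔCt.

### Time-course assembly

Fold changes are estimated per replicate group (one Ct–Ct fit per condition
per group), and a time point is summarised as the mean ± SEM of the group
fold changes — SEM over groups, not a delta-method SE, mirroring how such
experiments report "mean ± SEM (n = groups)". SEM is omitted at n = 1.
Undetermined (non-finite) Cts are excluded pairwise, never imputed; a
sample enters a fit only with both genes measured.

Identification requires input-amount spread: if all control Cts of a group
coincide, the slope (and with it the plot) is undefined and the fit raises
rather than guessing. The generator's default per-sample spread is
0.5 log10 units (samples spanning roughly a decade of input), a realistic
dissection-to-dissection range for whole-ganglia RNA yields; its default
Ct noise is 0.2 cycles, typical replicate-level qPCR precision.

## Microarray pipeline

The pipeline order is fixed: per-array 75th-percentile scaling on the
linear scale → log2 → median collapse of replicate probes to genes →
per-gene two-sided equal-variance Student t-test → raw p < α (default 0.05)
combined with a |fold| ≥ 2 cutoff. Percentiles use the linear-interpolation
definition, so normalization is idempotent and every array's 75th
percentile is exactly 1 after scaling. The equal-variance test (rather than
Welch) matches the df conventions of the era's array software and of
small-n designs generally; no multiple-testing correction is applied to the
calls, because the regulated-gene definition this package reproduces is a
raw-p-plus-fold filter — Benjamini–Hochberg q-values are computed and
reported alongside for modern context, clearly labelled as informational.

Collapsing before testing (rather than testing probes) is a documented
choice; the alternative changes the effective replication of duplicated
probes. Fold changes are reported both as log2 differences and in the
signed-ratio convention (−2 means 2-fold down; genes with log2 FC = 0 get
+1).

Heat-map ordering uses agglomerative clustering with Pearson-correlation
distance (1 − r) and average linkage — spotted-array-era defaults. A
zero-variance gene has no defined correlation; its distance to every other
gene is set to 1 (maximal dissimilarity) and the gene is listed in the
result so callers can log it. Merge heights are non-decreasing for this
metric/linkage combination, and the merge tree is checked in the test suite
against an O(n³) brute-force agglomerator. Trees serialize to Newick via
scikit-bio so standard tree tools can consume them.

The generator emulates the target study design — 4 sham vs 4 crush
one-color arrays, unique probes plus duplicated-probe groups and 9-fold
technical replicates, per-array multiplicative scale factors (log-normal,
SD 0.25 log2 units by default), per-probe log2-normal noise (default SD
0.25), and gene baselines drawn N(8, 2) on the log2 scale, a typical
one-color intensity range. Truth (the spiked genes and realized scale
factors) is emitted as a separate record so pipelines cannot see it. What
the generator does **not** emulate: probe-sequence effects, spatial
artifacts, background, intensity-dependent variance, and cross-gene
correlation. Passing calibration tests therefore shows the statistics are
correct under the model's assumptions, not that real arrays meet them.

## Outcome statistics

Net neurite change is `length(t) − length(baseline)` per neurite, negative
for retraction, and is translation-invariant by construction. One-way ANOVA
from raw data is the classic fixed-effects decomposition (the 0/0 case of
identical constant groups is guarded to F = 0, p = 1). The
summary-statistics form reconstructs the same decomposition from per-group
(mean, SEM, n), recovering group variances as n·sem² and weighting the
grand mean by n; it is algebraically identical to the raw-data ANOVA on any
dataset having exactly those summaries, which the test suite verifies with
affine-adjusted draws. All-zero SEMs with unequal means are reported as an
infinite-F flag rather than an exception.

Reconstruction from *printed* summaries inherits their rounding: for the
distal-neurite figures (4 groups, n = 14, two printed significant figures)
the reconstructed F values land within ~1% of the printed 14.4 / 20.1 /
29.7 (exact at the printed precision at 24 h), so a 2.5% relative tolerance
is the appropriate audit band. Two published claims do not reconstruct and
are treated as data quirks, not targets: the three-time-point expression
ANOVA "F(2,12) = 17.4" (the printed means/SEMs give 23.3, implying an
unstated comparison structure), and the day-10 locomotion asterisk (the
six-group omnibus from the printed summaries is F(5,23) = 1.41, p = 0.26;
only pairwise comparisons such as crush knockdown vs crush control reach
p < 0.05). The locomotion group sizes are likewise taken as data — the
bundled table uses the Results-section n = 3 for the crush-knockdown group
where the figure caption says n = 5.

Post hoc testing follows the SigmaStat convention named in this
literature: after a significant omnibus F, all pairwise t-tests on the
pooled MS_within with df_within, adjusted by Holm–Šidák step-down
(adjusted p₍ᵢ₎ = maxⱼ≤ᵢ 1 − (1 − p₍ⱼ₎)^(m−j+1), clipped to 1). Adjusted
p-values never fall below raw ones and rejections are contiguous from the
smallest p.

## Numerical and design choices

- Least squares via `scipy.stats.linregress`; t-tests via
  `scipy.stats.ttest_ind(equal_var=True)`; Holm–Šidák and BH via
  `statsmodels.stats.multitest.multipletests`; clustering via
  `scipy.cluster.hierarchy`. Test-suite oracles (normal equations,
  sort-based percentiles, exhaustive step-down, O(n³) agglomeration) are
  independent implementations.
- Percentages in DE summaries round half-up (not banker's rounding), to one
  decimal by default and to whole percent when audited against figures
  printed without decimals.
- Standard curves are fitted on log10 relative template amount
  (−log10 dilution factor), giving the conventional negative slope;
  efficiencies above 2.1 are flagged as implausible but not rejected, and
  non-negative slopes are rejected as degenerate.
- Simulation problem sizes in the test suite and reproduction script —
  1,000-gene null arrays × 100 batches (10⁵ gene-level trials), 200
  replicate time-course simulations, 2,000-probe spiked designs — were
  chosen to put Monte-Carlo error well inside the assertion bands while
  keeping a full run in the tens of seconds.

## Known limitations

- The Ct–Ct slope from free OLS is attenuated when control-gene Ct noise is
  comparable to the input-amount spread; the QC flag, not the quantification,
  depends on it.
- Efficiency estimates assume the standard-curve template behaves like the
  samples (no inhibitor gradients across dilutions).
- The DE pipeline models no intensity-dependent (heteroskedastic) noise and
  therefore needs no variance stabilization; real one-color data may.
- `anova_from_summary` trusts the printed n and SEM; a mislabelled SEM
  (e.g., SD printed as SEM) scales F by n and cannot be detected from the
  summary alone.
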