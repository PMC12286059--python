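# Methods

## Data model and preprocessing

The pipeline's unit of input is a modkit-style bedMethyl row: chromosome,
0-based start, modification code (`m` = 5mC, `h` = 5hmC), strand, valid
coverage, percent modified and, in full output, the raw call counts. β is
taken as Nmod/Nvalid_cov when the count columns are present, else
percent/100; the count form is preferred because the percent column is
rounded to two decimals. Rows with other modification codes (e.g. `a`, 6mA)
are skipped and counted, not errors. The default tokenizer splits on any
whitespace run because modkit has emitted both all-tab and tab+space
variants; the format is column-order-defined, so this is safe.

Internally every coordinate is 0-based half-open. Report files carry both
`pos0` and `pos1` columns so that downstream joins never depend on guessing
the basing of a site label.

Per modification code, cohort aggregation is an outer join over sites
(union, sorted by chromosome and position), with samples ordered by
ascending age. Two filters follow, in order: entries with coverage below 5
reads are masked, then CpGs not observed in every donor are dropped
(complete cases). Both filters are idempotent and only ever shrink the
matrix; the pipeline records per-stage row counts in its run manifest and
the test suite asserts their monotonicity. Strand collapsing of the CpG
dinucleotide (merging a minus-strand record at p with the plus-strand record
at p−1, summing counts) is available but **off** by default: per-strand
records are the raw observable, and collapsing is an interpretation layer.
No normalization or imputation is applied at any point.

## Per-CpG regression

For each site with observed β values y over ages x, ordinary least squares
gives slope = Sxy/Sxx, intercept = ȳ − slope·x̄, R² = Sxy²/(Sxx·Syy). The
p-value is the two-sided slope t-test,

    t = sign(slope) · sqrt(R² (n−2) / (1−R²)),  p = 2 P(T_{n−2} ≥ |t|),

equivalent to the test on the Pearson correlation. Two-sided is the natural
choice because hypo- and hypermethylation are both of interest. The
computation is vectorized across rows via masked sums but is algebraically
the per-row normal equations; the suite verifies agreement with independent
per-row fits to 1e−10. Degenerate rows are defined, not special-cased
errors: constant β gives slope 0, R² 0, p 1; rows with fewer than three
observations or tied ages are skipped with a logged count. Benjamini–
Hochberg q-values are attached for reporting but filters run on raw p and
R² (defaults R² ≥ 0.8, p < 0.001), since with cohorts this small the screen
is a strong-effect filter, not an FDR procedure.

`slope_p_from_r2(r2, n)` exposes the deterministic p↔R² relation directly;
it is strictly decreasing in both arguments, and for n = 6 (df = 4) it has
the algebraic survival form 2·(1/2 − (3/4)u + (1/4)u³), u = t/√(t²+4),
which the tests use as an independent oracle.

The direction summary reports hypo-/hypermethylating fractions among
non-flat rows (they sum to 1) and the flat fraction separately; `flat` means
|slope| below a configurable epsilon, 0 by default.

## Elastic-net CpG selection

Age is regressed on the full β matrix under the elastic-net penalty

    (1/2n) Σ_j (age_j − c − Σ_i w_i z_ij)² + λ [α Σ|w_i| + (1−α)/2 Σ w_i²]

with predictors standardized to zero mean, unit (population) variance, and
α = 0.5. The λ path is log-spaced over three decades down from
λ_max = max_i |Σ_j z_ij (age_j − āge)| / (n α), the smallest penalty at
which all coefficients vanish. The solver is warm-started cyclic coordinate
descent with soft-thresholding and covariance updates (Gram matrix
precomputed once per fit), with glmnet's schedule of full passes and
active-set passes. Convergence is max coefficient change < 1e−7, with a
per-penalty cap of 1000 cycles: in the p ≫ n tail of the path far below the
cross-validation optimum the problem is rank-degenerate and polishing it to
full tolerance is pointless; the cap never binds in the region where λ is
chosen, and the λ = 0 limit reproduces OLS to 1e−6 whenever n > p. The
scalar loop is JIT-compiled with numba; a pure-Python fallback computes the
identical iterate sequence.

Cross-validation is leave-one-out by default — with seven donors, k-fold is
ill-posed, and LOO is deterministic. k-fold (seeded shuffle, default seed
17) and the 1-SE rule are available. λ is chosen at the CV-MSE minimum by
default; fold fits share the full-data λ grid. Coordinate order is the site
sort order, making results deterministic even with duplicated predictors.
Sparsity along the path grows monotonically as λ relaxes until the active
set saturates near the sample rank; beyond that coordinates may swap, so the
monotonicity check in the tests allows small dips past saturation.

`selected_with_stats` joins the selected panel back to the univariate rows
and re-filters (default R² ≥ 0.8, p < 0.0005) — the post-hoc per-CpG report
for a selected panel, not a second selection step.

## Genomic context and enrichment

A CpG is intragenic if its position falls within the gene-body span
[start, end) of at least one `gene` feature, strand ignored, any biotype;
there is no separate promoter/shore classification. Gene lookup uses an
interval tree per chromosome. Biotype tallies count a site once per distinct
overlapping biotype; a single representative label uses the precedence
protein_coding > lncRNA > transcribed_unprocessed_pseudogene >
unprocessed_pseudogene.

GO over-representation is the exact upper-tail hypergeometric test
(including the observed table), BH-corrected within each namespace
(BP/MF/CC). The gene universe is the set of genes overlapping any analyzed
(post-filter, pre-significance) CpG rather than the whole genome: with an
adaptive-sampling target panel, genome-wide universes would import
ascertainment bias. No GO-graph propagation is performed; term lists are
annotation-version-dependent and deliberately outside the tested surface.

## Clock harmonization

Published clock manifests carry Illumina probe IDs with hg18/hg19
coordinates; manifests are user-supplied TSVs (probe, clock, build,
chromosome, 1-based position), keeping the package download-free. Liftover
is implemented natively from the UCSC chain format: chains are parsed with
their block sums verified against the header spans; a target position inside
an aligned block maps at the block offset, positions in target gaps are
unmapped ("deleted"), minus-strand query coordinates are flipped with
q_size − 1 − pos, and where several chains cover a position the
highest-scoring one wins. Unmapped probes are reported with reasons, never
raised. The test suite walks every fixture chain by hand and also compares
against Bioconductor rtracklayer's `liftOver` as an independent reference.

Overlap between lifted clock CpGs and nanopore CpGs requires the same
chromosome and |Δpos| ≤ 1 bp by default: array annotations mark the C on one
strand of the CpG dinucleotide while bedMethyl records may sit on either
strand. Each probe matches its nearest site (ties to the lower position) and
a probe shared by several clocks counts once per clock.

## Synthetic cohorts

The generator emulates the *structure* of a small nanopore ageing cohort,
not its genome: sites live on a toy chromosome at fixed spacing, and both
`m` and `h` records are emitted at every site so both analysis paths are
exercised. Per site i and donor j,

    β_ij = clip(a_i + b_i·age_j + ε_ij, 0, 1),  ε ~ N(0, σ²),

with b_i = 0 at null sites and |b_i| ~ U(0.002, 0.008) β/year at planted
sites; intercepts are placed uniformly so the noiseless trajectory stays
inside [0.02, 0.98] at every sampled age (infeasible slopes are an error).
Coverage is 1 + Poisson(λ−1) with λ = 30 (so depth ≥ 1), modified counts are
Binomial(coverage, β), and the emitted percent column carries the resulting
counting noise. Defaults: seven donors aged 5, 13, 24, 46, 60, 75, 91
(spanning the 5–91 range of a realistic blood cohort), σ = 0.02, 500 null +
100 positive + 100 negative sites per modification, no missingness.
Everything derives from one seeded generator; runs are byte-reproducible.

The linear-then-clip trajectory matches the linear-in-β analysis model; it
is not a claim about methylation biology (real trajectories saturate
smoothly, and real data add strand effects, correlated neighboring CpGs,
batch and cell-composition structure that the generator does not model).
Passing recovery tests therefore demonstrates correctness of the statistics,
not performance on real cohorts.

Calibration facts the suite verifies at these defaults: null p-values are
KS-uniform at n = 10,000; the type-I rate at p < 0.001 stays ≤ 0.004; slope
estimates are unbiased (mean error within the Monte-Carlo CI of 0 across 20
seeds). Detection power at the (R² ≥ 0.8, p < 0.05) screen depends strongly
on the planted slope: with n = 7 and total residual sd ≈ 0.08 (Gaussian plus
binomial at 30×), R² ≥ 0.8 requires |b| ≳ 0.0045 β/year, so sites at the low
end of the default slope range are individually undetectable by design; the
tests assert the monotone power profile and planted-vs-null enrichment
rather than a uniform detection rate.

## Pipeline and problem sizes

`run_pipeline` executes aggregate → coverage filter → complete cases →
per-modification regression → filters/rankings/direction split →
elastic-net selection → annotation + enrichment → clock harmonization +
overlap, writing every intermediate TSV and a JSON run manifest (package
version, config hash — paths to outputs excluded — seed, per-stage row
counts). Reruns with the same configuration are byte-identical.

Test and acceptance workloads use deliberately small problem sizes — cohorts
of 100–700 sites, 20-sample × 205-site elastic-net replicates, 10,000-site
null calibrations — chosen so the full suite exercises every code path in a
few minutes while keeping every statistical check well-powered.

## Known limitations

- The "both modifications" matrix sums m+h counts per site; all headline
  statistics use the per-code matrices.
- No age transformation (e.g. log-linear in childhood) and no mixed or
  robust regression models.
- The elastic-net model is a selection device here; the package does not
  produce calibrated age predictions with uncertainty.
- Liftover handles points only, not intervals, and does not attempt
  multi-chain reconciliation beyond the highest-score rule.
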