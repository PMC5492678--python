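# Methods

## Study design emulated by the generator

The synthetic cross mimics a *C. elegans* N2 × CB4856 recombinant inbred
panel: 48 homozygous strains, six chromosomes of 13.8–20.9 Mb, expression
measured as log₂ microarray intensities for the same strains under three
treatments (control, heat stress, recovery). Each strain is a mosaic of the
two founder genomes: per chromosome the leftmost allele is a fair coin, the
crossover count is Poisson (default mean 0.7 per chromosome), and crossover
positions are uniform, snapped to 10 kb bin starts. Crossover interference
is not modelled beyond an optional minimum spacing of 10 bins (100 kb),
which matches the resolution of the density-based map rule — events closer
than that are unrecoverable by construction, so simulating them would only
add unmeasurable noise. Breakpoints are also kept ≥ 11 bins from telomeres
for the same reason; real terminal events would be silently lost, which the
builder's documented terminal relaxation (≥ 5 bins) partially mitigates.

SNP calls are emitted only inside CB4856-like blocks at ~1 SNP / 2 kb
(Poisson counts, uniform positions). With `snp_noise_rate > 0`, isolated
false-positive bins (1–3 SNPs, ≥ 10 empty bins on each flank) are planted in
N2-like blocks to exercise the island-suppression rule.

Expression for spot *i*, strain *s*, treatment *T* is

    y = baseline_i + treatmentEffect_iT + Σ_k b_k · x_sk + slope_i·(age − 48) + ε,
    ε ~ N(0, noise_sd²),  noise_sd = 1

with genotype coded parent-A (N2) = 1, parent-B = 0. Planted QTL classes:
cis (gene within 1 Mb of its marker, active in **all** treatments), trans
(gene on another chromosome; two thirds active in exactly one treatment, the
designed "cryptic" fraction, one third in all), and trans-band hubs (many
targets of one marker, one treatment, one shared effect direction). Effect
sizes are drawn as variance-explained fractions in 0.30–0.60 — bracketing
the ~0.34 (trans) to ~0.52 (cis) averages such designs report — and
converted via `b = 2·σ·√(v/(1−v))`. Treatment main effects are N(0, 0.5)
per spot; ruler genes get positive slopes (0.5–1.5 log₂/h), no treatment
main effect, and true ages 48 / 49 / 49.3 h (± 0.2 h per sample) for
control / heat / recovery. One master seed feeds named substreams
(genotypes, snps, expression, …), so stages are independently reproducible.

What the generator does **not** emulate: probe-level artifacts (notably cis
mis-hybridization, which biases real cis directions toward the reference
allele — the package makes no claim about that direction split), array
normalization, correlated noise between spots, and linkage between planted
QTL positions and gene density. Passing tests therefore demonstrate the
statistical machinery on a faithful additive model, not robustness to array
chemistry.

## Genetic map construction

SNP density per strain per chromosome is tallied in half-open, 0-based,
fixed 10 kb bins (final partial bin kept). Occupancy runs are merged
iteratively: any interior run shorter than 10 bins is flipped into its
neighbours (shortest first, leftmost on ties), so an island shorter than the
window loses both of its transitions — the only reading under which "a
transition requires 10 empty bins" and "no two events within 10 bins" are
mutually consistent. Terminal runs need only 5 bins (a documented
relaxation; the rule's behaviour at chromosome ends is otherwise
undefined). Events sit at the first bin of the new state; the first
segment's state (occupied ⇒ CB4856) phases the chromosome, a leading
sub-window island being ignored. Markers are the union of event bins across
strains — "informative" means at least one strain recombines there, so a
marker may in principle be monomorphic if every recombining strain switches
to the same allele; such markers are NaN-flagged downstream rather than an
error. Genotypes at a strain's own event bin carry the *new* allele, which
makes constructed and truth maps agree exactly at event bins.

## Differential expression and age

The three-level model y ~ treatment is operationalized as three pairwise
pooled-variance two-group tests because the thresholds of interest are
per-comparison; Benjamini–Yekutieli adjustment is applied within each
comparison across all spots. Spot-level significance collapses to genes by
"any spot significant" (configurable: any | all | best), a choice the data
cannot arbitrate; Venn groups then partition the ever-significant genes into
the seven patterns. The age estimator is deliberately the simplest one
consistent with a "strong positive linear response": per sample, the
slope-normalized mean of ruler-gene expression, shifted so the control mean
is exactly 48 h. It is validated by parameter recovery (planted 1 h and
1.3 h offsets recovered within ±0.2 h at default noise), not by comparison
with the published ruler, whose gene set and slopes are not public.

## eQTL scans and thresholds

The scan is the exact two-group F test (1, n−2 df), vectorized as matrix
products; markers with a genotype group of < 2 strains are NaN-flagged,
constant traits get p = 1, and perfect separation is capped at
−log₁₀(p) = 300. The permutation threshold shuffles intensities
independently per spot across strains (10 permutations), evaluates
candidates only at the observed per-spot peak scores (the FDS/RDS ratio
changes nowhere else), and accepts the smallest t with
FDS/RDS ≤ ((m−RDS)/m)·q·log(m), natural log, FDS **averaged** over the
permutations (FDS must estimate expected false discoveries per dataset for
the ratio to estimate FDR). The multiplicative log(m) follows the printed
empirical-FDR rule, reading log(m) as the harmonic-sum approximation of the
dependency correction; the canonical variant that divides q by Σ1/i is
implemented (`variant="by"`) and is strictly more conservative. Peaks are
one per spot per chromosome (argmax, leftmost on ties) — the minimal rule
consistent with multi-chromosome eQTL profiles; the confidence interval is
the maximal contiguous marker run within 1.5 −log₁₀(p) of the peak, and R²
is SS_between/SS_total at the peak marker, computed per peak rather than in
a joint model. On the default 2000-spot fixture the permutation rule lands
near −log₁₀(p) ≈ 3; the threshold scales with the number of spots (m), so
genome-scale arrays (m ≈ 45,000) land near 3.5–3.9.

## cis/trans, bands, cross-treatment

cis means: same chromosome and gene **midpoint** within 1 Mb of the peak, or
midpoint inside the CI (midpoint is the documented choice; start vs edge is
unspecified in the field's informal usage). Trans-band rate λ = trans spots
/ occupied 0.5 Mb bins (bins holding ≥ 1 peak; the all-bins denominator is a
flag). The minimal significant count k* is the smallest k with
P(Poisson(λ) > k) < 0.001 — the `ppois(k, lower.tail=FALSE)` convention,
which reproduces the canonical calibration triple 20/36/20 at
λ = 9.16/20.64/9.01; the ≥-tail convention does not. Adjacent significant
bins merge into one band.

Cross-treatment "same locus" uses CI intersection with a same-chromosome
fallback, both reported. The power-versus-absence attribution takes each
trans-eQTL seen in exactly one treatment, converts its observed same-marker
effect in the other treatments to a variance fraction (balanced coding,
unit noise), and evaluates the analytic power curve there; the mean of those
detection probabilities is the fraction attributable to limited power, the
remainder cryptic. This is a reconstruction — the original procedure is not
fully specified anywhere — validated by recovering a planted 70/30
absent/underpowered mixture within 10 points. Its known bias: observed
near-threshold effects inflate attribution slightly (winner's curse on the
cross-treatment estimate), and truly-zero effects contribute ~0.

## Power

Balanced 0/1 coding fixes the calibration v = (b²/4)/(b²/4+σ²) (peak size 1
⇔ 20% at σ = 1). The closed-form oracle is the noncentral F(1, n−2,
λ = b²·p(1−p)·n) upper tail beyond the central-F critical value at
p = 10^(−threshold); at v = 0.35, n = 48, threshold 3.9 it equals 0.8003.
In the simulation study a "correct detection" requires the 1.5-drop CI to
cover the simulated marker — the strictest defensible reading of
correct/false/undetected; a same-chromosome rule is available. Ten reps per
(marker, level) mirror the design's own audit; rate-level assertions in the
tests pool ≥ 1000 reps.

## Enrichment

Hypergeometric upper tail on gene names with strict filters (category size
> 3, overlap > 2), Bonferroni per database by default (whether correction
should pool databases is genuinely open; per-database is flagged and
configurable). The universe is the annotated ∩ assayed gene set. The
polymorphism comparison is Pearson chi-squared without continuity
correction.

## Numerical and engineering choices

Coordinates are 0-based half-open throughout; marker ids are
`chrom:binstart`; BED output follows BED conventions. p-values are computed
on the log scale (`logsf`) to survive far-tail scores. All tables are
validated TSV with row-located errors; unknown config keys fail fast; every
pipeline run writes a manifest with the config hash and seed, and rerunning
with the same seed is byte-identical. Problem sizes used by the shipped
analysis: 2000 spots, ~170 markers, 48 strains, 10 permutations — the full
chain runs in well under ten minutes on one CPU; the test fixture uses 400
spots for the same architecture.

## Known limitations

- The map builder cannot see events within 10 bins of each other or ~10
  bins of telomeres; the generator respects the same limits, so map accuracy
  on real data with dense double-crossovers would be lower.
- The permutation threshold depends on m; comparisons of absolute
  thresholds across experiments of different size are not meaningful.
- The power-vs-absence attribution ignores selection effects from
  conditioning on single-treatment detection.
- Enrichment uses a synthetic annotation; nothing is claimed about real
  functional categories.
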