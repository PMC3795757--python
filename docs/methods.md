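# Methods

## Disease model and genotype distributions

Each locus is biallelic with minor allele frequency q ∈ (0, 0.5] and
Hardy-Weinberg genotype frequencies g = ((1−q)², 2q(1−q), q²) in the
population. Penetrances follow one of two single-locus forms with relative
risk γ > 0 for the minor allele: dominant, f = f₀·(1, γ, γ); or
multiplicative (log-additive), f = f₀·(1, γ, γ²). The baseline f₀ is fixed
by the prevalence constraint Σ fᵢgᵢ = K, so f₀ = K / Σ wᵢgᵢ. A parameter
combination whose implied penetrance exceeds 1 (e.g. K = 0.1, q = 0.01,
γ = 10 multiplicative) is rejected with an explicit error rather than
truncated — truncation would silently break the prevalence constraint, and
downstream grid runners flag such cells instead of dropping them.

Cases are distributed as P(g∣affected) = fᵢgᵢ/K. Controls are drawn from
the *unaffected* population, P(g∣unaffected) = (1−fᵢ)gᵢ/(1−K), not the
general population: at the prevalences studied the two are nearly
identical, but the unaffected definition keeps the law of total probability
exact (K·case + (1−K)·control = g to 1e-12, which the tests assert).
Contaminated case groups are the elementwise mixture
(1−β)·case + β·control; allele frequency is linear in β, so the expected
allelic odds ratio declines non-linearly toward 1 as β → 1.

## Association statistics

All tests act on the 2×3 case/control dosage count table:

- **Trend (CATT)**, weights (0, 1, 2):
  T = N·(N·Σwn − R·Σwt)² / (R·S·(N·Σw²t − (Σwt)²)), 1 df. Affine
  changes of the weights leave T unchanged; zero trend variance returns
  statistic 0, p = 1, flagged degenerate.
- **Genotype χ²**: Pearson on the 2×k table after dropping columns empty in
  both groups (df = k−1).
- **Allelic χ²**: Pearson, 1 df, on the collapsed 2×2 allele table — the
  basic single-marker scan statistic.
- **Allelic OR** with Wald 95% CI on the log scale; a zero cell triggers
  the Haldane-Anscombe +0.5 on all four cells and sets a `corrected` flag
  so clean tables are never altered.

No continuity corrections anywhere, matching genome-wide practice. The
trend statistic is verified against three independent routes in the tests:
the individual-level identity T = N·corr(dosage, status)², a Monte-Carlo
permutation of case labels, and statsmodels' linear-by-linear score test
(which differs by the known (N−1)/N factor).

## Power and minimum sample size

`mc_power` draws replicate tables at the count level — one 3-category
multinomial per group — which is identical in law to per-individual
assignment and orders of magnitude faster; the rejection fraction at α
estimates power with binomial standard error √(p(1−p)/reps).

`analytic_power` evaluates the same 1-df statistic on expected counts
(nᵢ = n·admixedᵢ, mᵢ = n·controlᵢ). Because these are score statistics,
that value is the non-centrality parameter and scales linearly in n; power
is the upper tail of χ²₁(ncp) at the central critical value. The tests
require Monte-Carlo and analytic power to agree within 4 MC standard
errors over a 20-setting grid.

`min_sample_size` reports the smallest equal per-group n whose Monte-Carlo
power reaches the target (default 0.9) at α (default 5×10⁻⁸), capped at
1,000,000 total. The analytic inversion seeds the bracket [n*/2, 2n*]; the
bracket is validated (doubling/halving as needed) and refined by integer
binary search to a width of max(1, 1% of n). Each candidate n is evaluated
with a generator seeded deterministically from (seed, n), so the search is
replayable and monotone-power ties break upward. Default replicates per
evaluation: 1,000 (configurable; the fixed-n study design uses 10,000
cases/controls and is cheap at any rep count because sampling is
count-level). With contamination the per-sample non-centrality shrinks
roughly like (1−β)² in the allele-frequency contrast, so required n grows
convexly — about 3–4× at β = 0.5 for γ ≥ 1.5 — which the acceptance tests
check as positive second differences across β.

## The synthetic two-disease case-swap experiment

The generator emulates a two-disease case-control design sharing one
control pool: cohort A with 1,963 cases, cohort B with 1,924, and 2,938
shared controls. Default prevalences are 0.005 for disease A and 0.05 for
disease B — chosen once as realistic for an autoimmune-type versus a
common metabolic-type disease; the case distributions are nearly invariant
to K at these magnitudes. The default panel holds 500 independent SNPs: 20
A-specific and 20 B-specific (γ evenly spaced over 1.3–2.0), one
shared-effect SNP with γ = 3 under both diseases (the analog of a locus
associated with both phenotypes), and 459 null SNPs; MAFs are drawn from
{0.05, …, 0.50} under a fixed panel seed so the shipped experiment is a
constant. Shared controls are drawn from the unaffected-by-both
distribution p ∝ gᵢ(1−fᵢᴬ)(1−fᵢᴮ), which collapses to the single-disease
control distribution when the other γ is 1.

The mix-scan replaces k = round(Nβ) (half away from zero) randomly chosen
primary cases with other-disease cases — both draws without replacement,
fresh per resample — rescans every SNP against the controls with the 1-df
allelic χ² (the conventional basic scan test), and averages −log₁₀ p (base
10, the GWAS convention) over 100 resamples at each β ∈ {0, 0.1, …, 0.9}.
Disease-specific signals decay monotonically toward the null background
E[−log₁₀ U] = 1/ln 10 ≈ 0.434, while the shared-effect SNP is essentially
flat in β because both mixture components carry its effect.

What the generator does **not** emulate: linkage disequilibrium between
markers (all SNPs independent), population stratification, genotyping
error or missingness, and covariates. Passing tests therefore show the
statistical consequences of case-group contamination under a clean
marginal-SNP model, not the quality-control realities of a genotyping-array
study.

## Numerical and design choices

- Randomness: one top-level integer seed; every routine derives a named
  substream via `SeedSequence` spawn keys (no global state), so identical
  configurations give byte-identical result tables.
- Equal case/control groups throughout the search; reported sizes are
  totals (cases + controls).
- The trend test is the default for power/sample size (1-df convention for
  this design); the scan default is the allelic χ². Both are configurable.
- Degenerate tables yield p = 1 inside Monte-Carlo loops rather than
  raising.
- Problem sizes in the shipped analyses — 1,000 replicates per
  binary-search evaluation, 200-replicate OR/power sweeps, the 500-SNP
  panel at 100 resamples — are the package's desk-scale defaults; every
  routine accepts larger values.
- Outputs are TSV with a `# params:` JSON provenance line carrying the
  resolved configuration including the seed; re-reading reproduces the
  table exactly.

## Limitations

Single-locus models only (no epistasis, no LD, no covariates or
stratification adjustment); unequal group sizes are accepted by the power
routines but not optimised over; the analytic oracle covers the two 1-df
tests, not the 2-df genotype χ². The binary search assumes power is
monotone in n, which holds for these tests away from degenerate
parameters. Monte-Carlo minimum sample sizes carry the resolution of the
1% bracket and the per-evaluation replicate count; at α = 5×10⁻⁸ with
1,000 replicates the achieved-power estimate at the returned n has a
standard error of about 0.01.
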