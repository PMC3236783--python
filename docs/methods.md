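# Methods

## Scope

`cnvassay` implements, end to end, the two PCR-based copy-number genotyping
strategies used in population CNV screening — relative quantification by
real-time qPCR (ddCt with maximum-likelihood integer assignment) and the
paralog ratio test (PRT) — together with a generative simulator of both
assays and the agreement statistics used to compare them (concordance
matrix and rates, replicate reproducibility, Bland–Altman, distributional
chi-square). The simulator exists because per-sample Ct and peak-area data
for such studies are rarely deposited: every downstream stage is exercised
on synthetic cohorts whose ground truth is known.

## The measurement models

### qPCR

A reaction starting from `N` amplifiable template molecules grows as
`N (1+E)^c` and crosses the detection threshold `T` at

    Ct = (log10 T − log10 N) / log10(1 + E).

`E` is the per-cycle amplification efficiency (1.0 = perfect doubling); the
dilution-curve slope is therefore `m = −1/log10(1+E)` and, inversely,
`E = 10^(−1/m) − 1`, which is how `fit_standard_curve` estimates it from a
Ct-versus-log-input series. `T` is fixed at 1e10 molecule-equivalents;
only Ct *differences* matter downstream, so its absolute scale is
arbitrary. Template molecules per reaction are `input_mass × 303`
haploid-genome equivalents per ng (3.3 pg per haploid human genome), times
`true_cn/2` for the target locus or 1 for the two-copy reference locus.

Calling inverts the chain under the conventional assumption that both
assays run at 100% efficiency:

    dCt_i = mean Ct_target − mean Ct_reference   (per sample, over usable replicates)
    CN_i  = modal_cn × 2^(−dCt_i) / median_j 2^(−dCt_j)

The cohort median continuous call equals the modal copy number exactly, by
construction; the median is taken on the copy-number scale (not the dCt
scale) so the identity also holds for even-sized cohorts. An
efficiency-corrected variant (base `1+E` instead of 2) is available for
contrast experiments.

**Input-amount bias.** When `E_target ≠ E_reference` the two dilution
slopes differ and dCt drifts by `m_target − m_reference` cycles per decade
of input DNA (`predict_dct_drift`). The sign follows directly from the Ct
model: a *more efficient* assay has the *shallower* slope, so if the target
is the more efficient assay its dCt rises with input and base-2 calling
deflates the copy number; a more efficient *reference* inflates it. The
published observation this package emulates — called copy numbers rising
with input amount when target and reference differ by ~6% in efficiency —
therefore pins the unstated direction of that gap: the reference must be
the faster assay. The bundled `nonnormalized` scenario encodes this
(target 108.23%, reference 114.18%); the drift magnitude is ~0.116
cycles/decade, i.e. ~8% copy-number inflation per tenfold input, ~15%
across a 2–120 ng cohort.

### PRT

One primer pair amplifies the copy-variable locus and a fixed-copy paralog
for a fixed pre-plateau cycle count (default 26), so both products share
one efficiency and the expected area ratio is
`true_cn / reference_copies` regardless of efficiency or input amount.
Peak areas are modelled at the ratio-relevant level:
`area = N_intact × (1+E)^cycles × (1 + ε)`, `ε ~ Normal(0, area_noise_cv)`.
Calling mirrors the qPCR arm: per-sample mean replicate ratio, anchored so
the cohort median continuous call equals the modal copy number, then ML
integer assignment.

The per-sample *ratio* `A_t/A_p` carries a second-order Jensen bias
`≈ (cn/ref) × CV(A_p)²` (about 0.2% at a 300 bp fragment length); the exact
unbiasedness statement is on expected areas, `E[A_t]/E[A_p] = cn/ref`, and
that is what the test suite asserts. The median calibration removes the
residual shared bias from the calls in any case.

### Degradation

Random fragmentation with mean fragment length `λ` leaves a fraction
`exp(−L/λ)` of templates intact across an `L` bp amplicon; the number of
amplifiable molecules is a Poisson draw around
`copies × exp(−L/λ)` (switchable off for closed-form tests). This is why
long PRT amplicons (299/443 bp) suffer far more from degraded DNA than
short qPCR amplicons (107/127 bp against an 87 bp reference): at
`λ = 300 bp` the PRT amplicon retains ~37% of templates versus ~70% for
the qPCR target, and the extra Poisson spread widens the continuous calls
without biasing their mean.

Degraded cohorts are heterogeneous by default: each sample's `λ` is drawn
lognormally with the configured median and log-scale SD 0.5
(`sigma_log: 0` restores a homogeneous cohort). This reflects how archival
or poorly preserved sample sets actually look — integrity varies widely
between extractions — and it is also the mechanism by which degradation
visibly widens *qPCR* calls: because the target and reference amplicons
differ in length (107 vs 87 bp), a sample-specific `λ` shifts each
sample's dCt by `(L_t/λ)/ln(1+E_t) − (L_r/λ)/ln(1+E_r)`, which no
calibration removes. For PRT the two loci share an amplicon length, so
heterogeneity adds spread only through template sampling.

## Integer assignment

Both arms share one maximum-likelihood engine. A continuous estimate `v`
is scored against candidate integers `k = 0..k_max` with the Gaussian
density `N(v; k, σ(k))`, `σ(k) = sigma0 + cv·k`; the call is the argmax
(ties to the smaller `k`) and the confidence is the call's normalized
likelihood, so candidate posteriors sum to 1 per sample. The affine σ
encodes multiplicative assay noise — spread grows with copy number, which
is why published concordance tables widen off the diagonal at high CN.
With `cv = 0` the rule reduces exactly to nearest-integer rounding with
half-points assigned downward; with `cv > 0` boundaries sit below the
midpoints. Defaults: `sigma0 = 0.1` copies, `cv = 0.05`, `k_max = 10`
(comfortably above the 8 copies observed for β-defensin-type loci; 0 is a
valid call for deletion homozygotes). A ratio of exactly 0 (target
dropout, or a true zero-copy genotype) is accepted and scored against
`k = 0` like any other value.

## Simulator defaults and what they represent

| parameter | default | meaning / rationale |
|---|---|---|
| normalized input | 5 ng/reaction | 2.5 ng/µl × 2 µl, the normalization level used in practice |
| non-normalized input | lognormal, mean 13.28 ng, `sigma_log` 0.7 | reproduces a ~2–120 ng spread around a 13.28 ng mean |
| genome equivalents | 303 /ng | 3.3 pg per haploid genome |
| Ct noise | 0.08 cycles SD, additive | typical well-to-well technical scatter for TaqMan triplicates |
| peak-area noise | 2% CV, multiplicative | capillary-electrophoresis quantification scatter per peak |
| qPCR replicates | 3 | assays run in triplicate |
| PRT replicates | 1 | one PRT reaction per sample per run; reproducibility is assessed across runs |
| PRT cycles | 26 | pre-plateau yield |
| degraded `λ` | median 300 bp, `sigma_log` 0.5 | heterogeneous poorly-preserved cohort |
| detection threshold | 1e10 | arbitrary scale; only dCt matters |

The area-noise CV and the single PRT replicate were fixed together from a
closed-form error budget: with one 5 ng reaction per sample the Poisson
template term alone contributes ~2.6% CV per peak, and a 2% instrument CV
keeps clean-cohort integer accuracy above 95% at modal copy number 4 while
leaving degradation (which multiplies the Poisson term several-fold) the
dominant source of PRT spread — the regime the method comparison is about.
A 5% instrument CV would swamp the degradation signal and push modal-4
accuracy below 90%, which does not match how PRT performs on high-quality
normalized DNA.

Missing Cts (no amplifiable template, or threshold beyond 40 cycles)
propagate as empty CSV fields; replicates missing either Ct are dropped
and counted, and samples with no usable replicate are excluded with a
logged reason code (`NO_USABLE_REPLICATES`, `ZERO_PARALOG_AREA`,
`NON_FINITE_CN`).

## Agreement statistics

* **Concordance matrix**: rows = method A, columns = method B, with labels
  recorded so "B higher" is always the above-diagonal mass. Rates are
  exact fractions; rounding to whole percent happens only at reporting.
* **Bland–Altman**: differences (B − A) of *continuous* calls, mean ± 1.96
  SD limits of agreement, and the fraction of pairs with |difference| < 1
  copy.
* **Replicate agreement**: integer concordance plus Pearson correlation of
  continuous calls across two runs of the same cohort.
* **Distributional chi-square**: Pearson chi-square on the 2 × K table of
  predicted-CN frequencies, pooling adjacent categories from the tails
  inward (the sparser tail first, ties toward low CN) until every expected
  count reaches 5; df = K_pooled − 1.

## What the simulation does and does not show

The generator reproduces the mechanisms (efficiency-mismatch × input,
degradation × amplicon length, multiplicative ratio noise) but not every
feature of real data: no PCR plateau or inhibitor effects, no digestion
or electrophoresis artifacts, no between-plate batch structure, no
pipetting covariance between target and reference wells, and real
degradation is not a pure uniform-breakage process. Passing tests
therefore validate the calling and comparison machinery and the
*direction and ordering* of the failure modes, not instrument-specific
error magnitudes. Published per-sample statistics that depend on the
original raw data (specific correlation coefficients, replicate
concordance percentages, the exact Bland–Altman fraction) are emulated
qualitatively, not targeted numerically.

## Problem sizes

Simulation-based checks use cohorts of 400 (input-bias runs, 100 seeds),
500 (degradation contrast) and 1000 samples (integer recovery), sizes at
which the tested orderings are stable across seeds (verified over 20–100
independent seeds during development); the whole suite runs in a few
seconds.
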