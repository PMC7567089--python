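# Methods

## Isotope arithmetic

Enrichment is carried as atom fractions throughout. δ values are stored in
‰; atom fractions and excess enrichments are dimensionless; no percent-atom
representation is exposed, which avoids a classic ×100 confusion. Two δ→F
conversions are provided. The default, `exact`, is the atom-fraction
definition F = R/(1+R). The alternative, `paper_approx`, evaluates
F ≈ (δ/1000 + 1)·R_ref — a shortcut that appears in parts of the tracer
literature and equals R rather than R/(1+R); it overestimates F by exactly
the factor (1+R), about 1.1 % for carbon near natural abundance and
correspondingly more for strongly enriched material. Because every
downstream rate is linear in E, a single `isotope_mode` switch in the
pipeline config flips the whole analysis between the two conventions for
sensitivity checks. Negative excess values (noisy near-background samples)
are preserved and QC-flagged, never clamped.

## Bulk rates

Tissue is measured once, after the last feeding pulse, so assimilated
tracer cannot be attributed to individual pulses; tracer masses accumulate
and the rate denominator is the cumulative substrate-exposure time
(3 × 8 h → 1 d, 2 × 24 h → 2 d). Respiration is resolved per pulse from
paired t₀/t_end DIC samples (replicates averaged), using the t_end DIC
concentration as the pool size by default (conservative; a config option
averages t₀ and t_end). When sponge-free control incubations are present —
recognized as incubation ids without a specimen record — their mean
whole-series tracer production is subtracted from every specimen chamber of
the same food source; tissue assimilation is never control-corrected, as
controls contain no tissue. Efficiency is computed per specimen and then
averaged within groups (never as a ratio of group means): with
heterogeneous individuals the two differ substantially, and the
per-specimen form is the one that matches reported species-level
efficiencies. Rates are expressed per tracer atom (µmol ¹³C or ¹⁵N); no
division by the food source's atom-fraction excess is applied by default.

## PLFA layer

Fatty-acid names are parsed from the CX:YωZ grammar with i/ai/Me/Cy
prefixes, tolerating case variants, optional hyphens, an ASCII `w` for ω
and a missing `:Y` (read as saturated). Classification is table-first,
rules-second: an explicit two-column CSV overrides everything; otherwise
cyclopropyl and mid-methyl acids below C22 and iso/anteiso branches up to
C19 are bacterial, chain length ≥ 22 (the demospongic-acid range, branched
long-chain acids included) is sponge-specific, and the remainder is
unspecific. The rule set reproduces all named assignments in the deep-sea
sponge literature this package targets, including the hexactinellid marker
C30:3ω7 as sponge-specific.

Per-acid backgrounds come from unlabelled specimens of the same species,
pooled as concentration-weighted means of the methanol-corrected δ¹³C; a
labelled acid with no background falls back to a configurable
natural-abundance default (−25 ‰) with a QC warning. The whole-specimen
PLFA carbon pool is concentration × total dry mass, converted to µmol with
12.011 g mol⁻¹. An acid counts as "labelled" above an excess-enrichment
detection threshold of 1e−5 atom fraction — an invented but reported
default, chosen to sit an order of magnitude above the enrichment
equivalent of the δ measurement noise (0.2 ‰ ≈ 2e−6) — and de novo
synthesis is flagged for labelled acids absent from the food-source
profile.

## Permutational statistics

PERMANOVA partitions sums of squares on Euclidean distances with partial
(type III) term SS, computed from effect-coded least-squares projections;
an equivalent Gower-centred trace route, tr(H·G), is kept as an internal
cross-check (the two agree to machine precision for Euclidean data, and
the raw route equals classical ANOVA F for univariate designs). The
permutation scheme is unrestricted permutation of raw observations,
including for interaction terms; p_perm uses the (b+1)/(m+1) estimator with
ties counted as ≥ observed. For one-factor designs whose distinct group
relabelings number fewer than the requested permutations the null
distribution is enumerated exactly and the relabeling count reported (10
for two groups of three, 35 for three against four) — "unique permutations"
counts distinct partitions, with equal-sized groups unordered. p_MC is the
parametric tail of F(df_term, df_residual) (t with residual df for pairwise
comparisons), the standard stand-in when tiny designs make permutation
p-values too granular; it is exact for the univariate Gaussian case, and an
approximation of the commercial implementation's Monte Carlo draw
otherwise. Welch's t (with Satterthwaite df) wraps the scipy
implementation.

## Synthetic experiment generator

The generator emulates the study structure end to end: 3–4 individuals per
species × food source, 2 L stirred chambers, multi-pulse schedules, DOM at
80 µmol C L⁻¹ per pulse (atom fraction ≈ 0.99 ¹³C; 0.80 ¹⁵N for diatom
DOM, reflecting 80 % ¹⁵N-nitrate labelling) or bacteria at 12–16 µmol C
L⁻¹, duplicate DIC samples per pulse at 0.05 ‰ precision, and
species-specific PLFA profiles with an internal C19:0 standard.

Per-specimen ground truth is drawn as total C processing rate
(lognormal; mean and CV from the reported group mean ± SD) and efficiency
(Beta; reported mean, SD chosen consistent with the reported pairwise
t-statistics), coupled by a Gaussian copula. The copula correlation per
preset was calibrated once — numerically, against the implied mean
respiration E[(1−e)·t] — and frozen in the preset table. This
parameterization exists because the reported group summaries are not
mutually consistent under a ratio of means: for the HMA-demosponge DOM
group, mean total 0.7 and mean respiration 0.09 imply an efficiency of
means of 87 %, while the reported mean per-specimen efficiency is 77 %.
Heterogeneous individuals reconcile the two, and a positive
rate–efficiency correlation (ρ = 0.841 for that preset) reproduces all
three reported means simultaneously. For three groups
(LMA-demosponge DOM, hexactinellid DOM and bacteria) no correlation can
reconcile the reported respiration with the reported total and efficiency
(one reported respiration even exceeds the reported total); there the
correlation is clipped at |ρ| = 0.99 and the realized mean respiration is
recorded in the preset's `expected` block. Nitrogen assimilation follows
from a per-specimen assimilation C:N ratio (lognormal, CV 0.2, means
derived from the reported C and N rates per group); PLFA incorporation
totals are lognormal around the reported means, allocated across acids
with fixed shares for source-present acids and sponge-specific acids
(matching the reported label partitioning) and the rest to
bacterial/unspecific acids.

The forward model inverts exactly the formulas the pipeline applies:
tissue E = rate × duration / 1000, DIC ΔF = respired tracer / (DIC pool),
peak areas from the concentration formula, FAME δ from the inverse methanol
mixing. Measurement noise is Gaussian in δ space (0.2 ‰ background SD plus
a proportional 0.5 % of the enrichment above background; 0.05 ‰ for DIC)
and lognormal with mean one on peak areas (CV 0.12); a single `noise`
multiplier scales all of it, and zero gives machine-precision round trips.
Between-individual truth variation is part of the truth, not the noise. A
mass-balance guard caps each specimen's per-pulse uptake at 90 % of the
tracer fed that pulse — lognormal tails at the reported rates can otherwise
exceed supply at the bacterial dose — flagging capped specimens; at the
default conditions the cap binds in well under 2 % of draws and biases
group means by < 1 %.

What the generator does **not** emulate: chamber hydrodynamics and
concentration depletion within a pulse (doses are treated as bolus
supplies, DIC concentration as constant), DI¹⁵N release or isotope
dilution, IRMS drift, chromatographic co-elution, or real biological
covariance structure beyond the single rate–efficiency copula. Passing
recovery tests therefore demonstrates that the analysis inverts its own
measurement model under realistic noise — not that the field measurements
themselves were unbiased.

## Numerical choices and degenerate inputs

- δ ≤ −1000 ‰, non-positive ratios and out-of-range atom fractions raise
  typed domain errors; element mismatches raise a typed error.
- A constant response in PERMANOVA (0/0 pseudo-F) is guarded: statistic
  NaN, p = 1. Pairwise t of identical groups is 0 with p = 1. Welch's test
  on two zero-variance equal-mean samples returns p = 1.
- Efficiency with both rates zero, and C:N with a zero N rate, return NaN
  markers rather than raising.
- Missing t₀/t_end DIC samples raise a structured error listing every
  (pulse, time point) gap.
- All simulation and permutation randomness flows from explicit seeds
  (numpy Generator); enumerated permutation p-values are bit-exact.

## Problem sizes

Recovery checks use 200 replicate simulated experiments per preset at the
study sample sizes (n = 3–4 labelled specimens plus 3 controls and 3
unlabelled background specimens each), which puts the Monte Carlo error of
recovered grand means near 2–3 % of truth; statistical calibration uses
1000 simulated Gaussian null datasets (3 groups × 4) at 199 permutations.
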