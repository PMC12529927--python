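# Methods

This note records the models implemented in `seedless`, the defaults and
their rationale, what the synthetic-data generators do and do not emulate,
and the numerical choices that matter for reproducing results.

## Site grammar

A guide is an 18–26-nt RNA indexed 1-based from its 5′ end; the seed is
positions 2–7, the subseed 2–5, and the 3′ region runs from
`min_3p_start` (default 9 — registers beginning at position 9 occur
throughout the analyses, even though position 9 pairing is
conformationally disfavored) to the guide 3′ end. All complementarity is
strict Watson–Crick; G:U wobble is excluded from every site definition
(a config flag exists but raises until a wobble-aware matcher is needed,
so it cannot silently change results).

Canonical classes are ranked 8mer > 7mer-m8 > 7mer-A1 > 6mer > 6mer-m8 >
6mer-A1. The A1 interaction is an adenosine across from guide position 1,
recognized by AGO rather than paired, so it is modelled as a literal `A`
on the target, not a complement of g1.

3′ matches are maximal contiguous complementary runs between the read and
the guide 3′ region (k-mer indexed, then extended; the reference
implementation is a diagonal scan used in the tests). Maximality is
defined within the allowed guide region — a run abutting the boundary is
maximal even if the next guide position could pair. Overlapping maximal
runs (possible in repetitive sequence) are reduced to a non-overlapping
set, longest first, ties left-most.

**Offset.** For a 3′ segment starting at guide position X and a downstream
seed run ending at guide position E, bridged by `n` target nucleotides,
`offset = n − (X − E)`. The worked identity m13_20 with an 8-nt bridge to
m2_7 gives 8 − (13 − 7) = +2. Positive offsets bulge the target, negative
offsets bulge the guide.

**Read assignment** returns exactly one site per read: compound beats
3′-only beats canonical; among compounds, longer 3′ register, then longer
seed run, then left-most; among seed runs for a given 3′ match, longest,
then smallest |offset|, then left-most, then the run ending nearest guide
position 8 (this last tie-break resolves target words that can be read
against two guide registers, e.g. a CU dinucleotide pairing either g3–g4
or g7–g8 of let-7a). Seed runs are searched strictly downstream of the 3′
segment; a run directly abutting it (bridge 0) is maximal by construction,
because the adjacent target nucleotide is already engaged in the 3′
duplex. Ties at the top of the precedence order set an `ambiguous` flag
instead of failing.

Two presets exist: `rbns` (min 3′ run 8 nt, 3′-only tolerates ≤1 nt of
contiguous seed pairing, offset window −8..+16) and `survey` (min 3′ run
10 nt, 3′-only requires <3 nt of seed pairing, 3–5-nt runs at offsets
−4..+6 form the 3′+microseed class, offset-6mer canonical classes are not
counted).

## Relative K<sub>d</sub> from bind-n-seq

Bound-sample read counts are multinomial with class frequencies
`g_ij = f_j p_ij / Σ_k f_k p_ik`, where `f` are input-library frequencies
(plug-in estimates from the input sample with pseudocount 1) and
`p_ij = a_i/(a_i + κ_j)` is the equilibrium occupancy of class `j` at
free-AGO scale `a_i`, with all κ expressed relative to the no-site class
(κ_none ≡ 1 — the model is invariant under joint rescaling of all κ and
all a, so one κ must be pinned). The fit maximizes the multinomial
log-likelihood over log-parameters with an analytic gradient (L-BFGS-B,
relative tolerance 10⁻¹²; non-convergence raises with diagnostics).

Two practical options matter:

- **Dilution tying.** With independent per-sample `a_i` the likelihood
  has a soft ridge — adding a constant to every `a_i` and to the smallest
  κ values changes `g` only through weak saturation terms — which inflates
  errors on the tightest sites severalfold. When the bound samples form a
  known dilution series (the usual design), `FitOptions(dilutions=...)`
  constrains `a_i = A·d_i` with a single latent stock scale, which removes
  the ridge; all recovery tests use this mode.
- **Curated site lists.** `RbnsCountTable.from_reads(..., site_list=...)`
  assigns reads outside the list to the no-site background. Fitting every
  incidentally observed class (thousands of low-count compound classes)
  lets their noisy κ estimates soak up free AGO and bias the shared
  parameters; a curated list against a pooled background avoids this.

Sites with fewer than `min_reads` (default 50) total bound reads are
reported not-determined. CIs are percentile intervals from a
nonparametric bootstrap over reads (multinomial resampling of every
sample at its original depth; default 200 replicates, seeded; at most 10%
of replicates may fail).

**Flank stratification** splits a 3′-only register mX_Y into four
subclasses by the target base across from guide position X−1. By
maximality, a complementary flank means the read is classified as
m(X−1)_Y, so that register's reads are folded into the
complementary-flank subclass; all remaining reads form the background row.
Relative κ between flank subclasses is meaningful; their absolute scale
absorbs whatever real sites were folded into the background.

## Multiplicative compound-site model

`−log₁₀(κ) = A_threep · B_seed · C_offset` is fit as ordinary least
squares on `log y` with one-hot categorical design (optionally weighted).
Sites with κ ≥ 1 cannot enter the log model and are reported as rejects.
The two within-family scale freedoms are fixed by max(A) = max(B) = 1 with
the residual scale absorbed into C; min-max rescaled copies in [0, 1] are
emitted for display alongside the raw coefficients (whose absolute
magnitude carries no biochemical meaning). A union-find check rejects
disconnected coefficient designs by naming an offending level, and
prediction refuses unseen levels rather than extrapolating.

## Binding curves, kinetics, energetics

Saturation fits use θ = c/(c+K<sub>d</sub>) in log-K<sub>d</sub> space.
Curves with θ < 0.2 everywhere are reported as a K<sub>d</sub> lower bound
of 10 nM; curves with mean θ ≥ 0.8 at the lowest concentration as an upper
bound of 5 pM (thresholds configurable; these operationalize "negligible"
and "saturated"). Association fits use
AR(t) = AR<sub>eq</sub>(1−exp(−k<sub>on</sub>·A<sub>T</sub>·t)) with
A<sub>T</sub> ≥ 80 pM enforced as the pseudo-first-order guard; a pooled
variant shares one k<sub>on</sub> across series at different
A<sub>T</sub>. CIs for both are parametric bootstraps (refit under
Gaussian noise at the residual sd, 200 draws, seeded) — chosen because the
replicate counts typical of these assays are too small for a
nonparametric bootstrap. k<sub>off</sub> = K<sub>d</sub>·k<sub>on</sub>,
with bound flags propagated rather than silently converted to point
estimates.

Observed binding energies are ΔG° = RT ln κ with R = 1.9872×10⁻³
kcal/(mol·K) and T = 310.15 K (37 °C assays). Predicted energies for the
equivalent duplex free in solution sum Turner-style Watson–Crick stack
terms (shipped as a package TSV; the contract is the summation rule —
stacks over adjacent pairs, one duplex-initiation term, a terminal-AU
penalty per A-U-closed end — not a particular parameter vintage). Sites
with a non-pairing A1 interaction (8mer, 7mer-A1, 6mer-A1) are excluded
from the comparison since no in-solution duplex is equivalent. For
compound sites the two segments are summed with a single initiation term.

## Probing quantification

Relative reactivity is (S−Q)/(N−Q) on *lane fractions* (band over total
lane signal), with S the probed sample, Q the pre-quenched control, and N
the free guide. Positions where N ≤ Q are not determined (the free-guide
ceiling must exceed background for the ratio to mean anything); values
outside [0, 1] are reported as computed and flagged, not clipped.
Replicates aggregate as mean with range for n ≤ 2 and a t-based 95% CI
for n ≥ 3.

## Reporter (MPRA) modelling

The design builder expands per-miRNA site lists into (site × context)
variants and validates the library arithmetic: 6 canonical classes × 5
upstream pads + 3′-only registers (20 for the miR-155-style design, 15
for miR-124-style) + 168 compound sites (3 3′ patterns × 28 seed patterns
of length 2–8 × 2 offsets) + 5 no-site controls, each in 20 contexts —
8,820 variants over the two miRNAs. Pad, flank, and no-site sequences are
deterministic synthetic stand-ins (seeded, rejection-sampled to avoid >3-nt
complementary runs to any guide); the originals are inputs where available.
Bridge fillers inside synthesized compound sites are chosen base-by-base
so they can neither extend the flanking duplexes nor seed a ≥2-nt
complementary run against the guide seed region.

Fold-changes: counts → CPM per sample → summed per site across its 20
contexts → per-replicate ratio (miRNA/mock) → normalized to the median
ratio of the no-site architectures (median for robustness over five
controls) → log₂, with mean and SEM over replicates. Zero-mock sites are
flagged, not dropped silently.

The occupancy model predicts log₂FC = −log₂(1 + b·N) with
N = a_free/(a_free + κ): repression is interpreted as fold-decrease of
steady-state reporter mRNA. (b, a_free) are fit by least squares in
log-parameter space from a 3×3 grid of starts (the surface can be
bimodal when a_free trades against b); preconditions require ≥5 sites
spanning ≥100-fold in κ. The hierarchical bootstrap for (b, a_free)
resamples replicate columns (common-mode transfection/normalization
noise) and sites jointly, inflating deviations by √(B/(B−1)) to correct
the (B−1)/B variance bias of resampling B replicates.

Slicing detection compares each zero-offset compound architecture with
its positive-offset counterpart: Tukey's HSD on replicate log₂FC values
per pair, Bonferroni-corrected across all tested pairs, flagged only when
the zero-offset variant is more repressed (positive offsets otherwise
bind and repress better, so the reversal is diagnostic of cleavage).
Pairs with <3 replicates are skipped with a warning. Grouping is
per-pair; a family-wise ANOVA grouping would also be defensible, but
per-pair keeps the test valid when architectures differ in variance.

## UTR survey

UTRs (DNA accepted, T→U) are scanned sense-strand only. Candidates are
canonical occurrences (strongest class per position) plus ≥10-nt 3′
matches resolved by their downstream seed run: <3 nt → 3′-only, 3–5 nt at
offset −4..+6 → 3′+microseed, ≥6 nt → canonical territory (the canonical
scan annotates the seed site, flagged `supplementary_3p`). Overlap
resolution is greedy with category priority (3′ classes, then canonical
rank), then left-most, then longest; displaced candidates that still fit
are kept, and sites whose span was contested carry an `ambiguous` flag
rather than being dropped. The expected background rate of a k-nt site
class is ~L/4^k, so class ratios follow `chance_ratio` (4^k1/4^k2);
empirical background counts additionally carry (3/4) maximality factors
per extendable run boundary, which the acceptance checks account for.

## Expression response

log₂FC per gene = (logTPM in the miRNA's sample − mean logTPM in the
other samples) × log₂10. Note the leave-one-out design cancels any shift
common to all samples; cohorts must be miRNA-specific for signal to
survive. Control cohorts are drawn from no-site genes stratified by
deciles of the cohort's UTR-length distribution (seeded; dry strata spill
to nearest lengths with a warning). The repression test is the one-sided
two-sample KS test with the alternative that the cohort's CDF lies above
the controls' (shifted toward repression), asymptotic p-values; cohorts
under 10 genes are flagged low-power, not suppressed.

## Synthetic data

Generators are deterministic given (config, seed) and return a `SimTruth`
with every parameter used.

- **RBNS pools**: 40-mer molecules, half fully random, half programmed
  with a central 8-nt segment complementary to a guide 3′ window (default
  13–20); every molecule is classified with the same grammar used for
  analysis, and bound pools draw molecules with probability ∝ a/(a+κ) of
  their assigned class (equivalent to rejection sampling against the
  occupancy model, but each molecule is classified exactly once). Classes
  missing from the κ map fall back to background with a tally. The 3′
  constant region of a real library is assumed blocked and is not
  modelled. Not emulated: sequencing error, position-specific base
  composition, filter-retention efficiency — so passing recovery tests
  demonstrates correctness of the inference, not robustness to real
  library artifacts.
- **MPRA counts**: lognormal variant abundances, miRNA-sample abundances
  divided by 1 + b·N(κ), negative-binomial counts with dispersion 0.05
  (typical reporter overdispersion; variance μ + 0.05μ²), 4 replicates
  emulating 2 plates × 2 experiments.
- **UTRs**: uniform random backgrounds; with plants, backgrounds are
  rejection-sampled to be free of every survey category and the planted
  UTR is re-scanned until the annotation set equals exactly the planted
  sites (accidental seed runs next to a planted 3′ segment would
  otherwise recategorize it). Without plants, no rejection — accidental
  sites are the object of background-rate studies.
- **Binding data**: forward evaluation of the saturation and association
  equations plus Gaussian noise; θ clipped to [0, 1] with clip counts
  recorded.
- **Expression**: per-gene baseline ~N(1.5, 0.5) log₁₀TPM, per-sample
  noise (default sd 0.05 log₁₀ units), shifts specified in log₂ and
  converted.

## Problem sizes used in the checks

Recovery and calibration checks run at: 10⁵-read RBNS pools × 4 bound
samples (κ spanning 10⁻³–1; 2-fold recovery, exact rank order); 5,000
compound sites at 5% noise (Spearman ≥ 0.95 per coefficient family); 200
seeded curve-fit replicates (K<sub>d</sub> median error ≤ 20%, ≥ 90% CI
coverage; k<sub>on</sub> within 2-fold); 100 seeded MPRA runs (bootstrap
CIs cover (b, a_free) ≥ 90%); 10⁶ nt of survey background (class counts
within 3 Poisson SD of closed form) with 100% plant-and-recover; 1,000
null KS draws (type-I ≤ nominal) and 200 power draws (≥ 80% power for a
−0.3 log₂ shift on a 100-gene cohort).

## Known limitations

- Bind-n-seq fits assume equilibrium; systems with very slow association
  (as expected for the strongest 3′-only sites) will have their affinity
  underestimated by any equilibrium-assumed analysis, and no kinetic
  correction is applied.
- No bulges, internal mismatches, or wobbles inside complementary
  segments; site elements are perfect runs by construction.
- The NN energy table covers Watson–Crick stacks only (no dangling ends,
  coaxial stacking, or loop terms); compound-site predictions ignore the
  bridged loop entirely.
- Read-to-variant assignment for reporter libraries is exact-match only.
- The survey reports sequence-based site incidence; conservation,
  UTR-isoform choice, and site accessibility are out of scope.
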