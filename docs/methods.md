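# Methods

This note documents the models, rules and numerical choices behind
`mdxmet`, and what the synthetic cohorts do and do not establish about
real microdialysate data.

## Data model

A cohort is a metabolite × sample matrix of chromatographic peak areas
with a sample metadata table (animal, tissue ∈ {tumor, brain}, timepoint ∈
{baseline, h72}, treatment ∈ {vehicle, TMZ, none}). Peak areas are
positive; a zero or empty cell means *not detected* — below the detection
limit, not zero abundance — and is carried as an explicit MISSING value
throughout. The distinction is load-bearing: longitudinal fold changes
divide by the baseline value, and a metabolite undetected at baseline has
no finite fold change at all, which triggers its own ranking rule rather
than a division by a small number.

## Preprocessing

**Detection filter.** A metabolite is retained when detected in at least
⌈t·n⌉ samples (default t = 0.9; with n = 33 that is 30). "At least" with
integer counts forces the ceiling. The filter defines the analysis
universe and by default runs before normalization; a flag reverses the
order, and the order is recorded in the report because the median scale
depends (weakly) on which metabolites are present.

**Median normalization.** Each sample is divided by the median of its
*detected* values, so every sample's detected median becomes exactly 1.
The phrase "median = 1 across metabolites for each sample" admits a
per-metabolite reading as well; per-sample scaling is the default because
it matches the sentence literally and because multiplicative per-sample
effects (injection volume, catheter recovery efficiency) are the dominant
nuisance in microdialysate data. `mode="per_metabolite_median"` provides
the alternative. Normalization is idempotent and preserves missingness.
Raw values travel with the normalized matrix because one downstream rule
(below) is defined on raw peak areas.

## Ranked lists

**Group fold-change lists.** FC = mean(numerator group) / mean(denominator
group) per metabolite, ranked descending. MISSING contributes 0 to group
means by default, which keeps group means monotone in detection; a flag
switches to detected-only means (after a 90 % detection filter the two
readings rarely differ). Metabolites with denominator mean 0 but detected
in the numerator have no finite FC and form a top block ordered by
descending numerator mean; metabolites absent from both groups are
dropped. All ties break lexicographically by metabolite id, here and
everywhere, so output order is reproducible.

**Per-animal longitudinal lists** (72 h vs baseline for one animal)
concatenate three blocks:

1. metabolites detected only at 72 h, ordered by descending **raw** 72 h
   peak area (the reference case: two appearing metabolites with raw peaks
   585,283 and 90,433 take ranks 1 and 2);
2. metabolites detected at both timepoints, ordered by descending
   normalized fold change;
3. metabolites detected only at baseline, ordered by descending raw
   baseline peak area, below everything else.

Block 3 is this package's symmetric extension — disappearance as the
mirror extreme of appearance; only the appearing-metabolite rule has an
external reference. The within-block order (descending raw baseline area)
follows the same magnitude convention as block 1; the alternative
(ascending, putting the largest disappearance last) would be equally
defensible, and the choice is recorded in each list's provenance.
Metabolites detected at neither timepoint are excluded. These lists are
*rank-only*: their scores for downstream weighting are reversed ranks
N + 1 − rank, since the blocks make raw scores incommensurable.

**Mean-rank aggregation** averages each metabolite's rank over the
per-animal lists that contain it (available-case averaging, flagged in
provenance) and orders by ascending mean rank. Aggregates are rank-only as
well.

**Set libraries.** For each named list of length N ≥ 2k, the library gets
`<name>_top{k}` (ranks 1..k) and `<name>_bottom{k}` (ranks N−k+1..N);
k = 35 by default, giving the customary top/bottom-35 signature sets.

## Enrichment engine

Preranked, weighted-KS running sum: walking the list from rank 1 down, a
set member adds |s_i|^w / Σ_hits |s_j|^w, a non-member subtracts 1/(N−k);
ES is the running-sum value of maximum magnitude (first such index on
exact ties), in [−1, 1], with ES = 1 exactly when all members precede all
non-members. The leading edge is the members at or before the extremum
(positive ES) or at or after it (negative ES).

Defaults: w = 1 on |score|, with score = FC for fold-change lists and
reversed rank for rank-only lists; w = 0 gives the classic unweighted
statistic. Fold changes are used unlogged by default, matching how such
lists are ranked; `log2_scores=True` is exposed because a single extreme
fold change (a 20× marker) otherwise dominates the weighted sum.

**Null model.** A preranked list has no sample labels to permute, so the
null is size-matched uniformly random metabolite sets (default 1000 draws,
seed mandatory; draws are reproducible given (seed, N, k) only, so
identical lists share identical nulls regardless of naming).
NES = ES / mean(same-sign null ES); NES of a zero ES is 0. Nominal p is
the same-sign tail fraction with add-one smoothing — the smallest
reportable value at 1000 permutations is 1/1001, rendered "< 0.001" in
text output. FDR q for NES\* is

  q = [ share of pooled sign-matched null NES with |NES| ≥ |NES\*| ] /
      [ share of observed sign-matched NES with |NES| ≥ |NES\*| ],

clipped to [0, 1] and made monotone within each sign (step-up: each set
takes the minimum of its own and all weaker sets' raw q). FDR is estimated
within one library query, matching how one ranked list is run against one
library.

**Numerical tie handling.** On short lists the running sum's largest
positive and negative deviations can tie exactly; which one ES takes then
rests on last-ulp arithmetic. Two measures keep scalar and vectorized
paths identical: sampled hit indices are sorted so weights accumulate in
list order, and all tail counts use a relative tolerance of 1e-9 so a true
tie always falls inside the tail. Calibration holds: nominal p is uniform
under random sets (KS check), and under a global null of 12-set libraries
the fraction of q ≤ 0.05 stays below 0.07.

## Differential statistics

Mann–Whitney U (unpaired) and Wilcoxon signed-rank (paired) run exactly —
full enumeration of the permutation null, via scipy — whenever both sizes
are ≤ 25 and ties permit, otherwise the tie-corrected normal
approximation; the method used is recorded. Zero paired differences are
dropped (noted on the result); all-constant input returns p = 1 with a
degenerate flag instead of raising. Two consequences worth knowing: with
complete separation at n = 9 vs 12 the two-sided p is exactly
2/C(21,9) ≈ 6.8 × 10⁻⁶, the smallest attainable; and with n = 3 pairs the
minimum two-sided Wilcoxon p is 0.25, so no individual metabolite can
reach p < 0.05 in a three-animal arm — set-level enrichment is the only
statistic with power there.

Volcano classification is strict: up iff FC > 1.5 and p < 0.05, down iff
FC < 1/1.5 and p < 0.05 (reciprocal symmetry, so swapping the groups swaps
the up and down counts). No multiple-testing correction is applied to
volcano p-values; the FDR ≤ 0.05 criterion belongs to enrichment. The
normality screen (D'Agostino–Pearson omnibus, minimum n = 8 per group)
justifies the nonparametric choice but never gates it. Groups of NES
values are compared by one-way ANOVA with Tukey HSD post-hoc — the
post-hoc procedure is a package choice; nothing external pins it down.

## Synthetic cohorts

`simulate_cohort` draws
value(m, j) = 10^μ_m · s_j · a_{m,animal(j)} · effect(m, cell(j)) · ε_mj
with μ_m ~ N(5.3, 0.6) in log10 (peak areas of ~10⁵ spanning orders of
magnitude), per-sample scale s_j log-normal(σ = 0.3), residual ε
log-normal(σ = 0.25), and an animal-level effect (σ = residual/2) shared
by one animal's baseline and 72 h samples so within-animal fold changes
are less noisy than between-animal ones. Values below the global 10 %
quantile become MISSING. Planted effects: 38 tumor-up and 33 tumor-down
metabolites at FC 1.5–4× (log-uniform) plus one oncometabolite-like marker
at 20×, planted at the center of the abundance distribution — a marker is
only a marker if it is quantifiable across the cohort; 40
injury-responsive metabolites at FC 1.5–3× applied to brain samples at
72 h, of which a fraction ρ = 0.5 are drawn from the tumor-up set (the
injury-resembles-tumor structure); under TMZ the injury log-effects are
multiplied by α = 0.3. The default design is 9 + 12 baseline animals with
3 per tissue × treatment arm resampled at 72 h — 33 samples. The ground
truth (identities and log effects) is serialized beside every cohort.

The generator emulates multiplicative structure, detection-limit
missingness, paired sampling and overlapping signatures. It does **not**
emulate batch or drift effects, per-metabolite detection limits,
correlated metabolite modules, identification ambiguity, or heavy-tailed
biological variation — so passing recovery tests demonstrates that the
pipeline's logic is correct under its assumed noise model, not that the
assumptions hold for any particular instrument or cohort.

Two presets matter for validation. The default configuration is the
realistic condition: under it the vehicle arm's aggregated injury list is
significantly enriched (FDR ≤ 0.05) for the baseline tumor top-35 in
≥ 95 % of cohorts while the TMZ arm's rate is strictly lower, and the
planted 20× marker ranks first essentially always. The
`noise_controlled_config` preset (residual σ = 0.05, planted FC 2–4×, no
detection dropout) is the condition under which exact volcano recovery of
the planting record is achievable at the (1.5, 0.05) cut-offs; with
planted fold changes touching the 1.5 boundary, exact recovery is
impossible in principle, noise or no noise.

## Pipeline and reproducibility

`run_analysis` derives per-stage seeds from the global seed with a
counter-based scheme (adding a stage never perturbs earlier stages'
draws), hashes every output file into `manifest.json`, and records the
decision log (tie policy, normalization mode, block rules, weighting,
thresholds). Reruns with the same config are bit-identical, including
enrichment tables, because the permutation null is fully seeded. Problem
sizes used in the validation suite — 50,000-draw nulls against exhaustive
enumeration at N ≤ 12, 500 null libraries for FDR calibration, 100 cohorts
for the injury-enrichment rates, 50 for volcano recovery — were chosen as
the smallest sizes at which Monte-Carlo error is negligible relative to
the tested margins.
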