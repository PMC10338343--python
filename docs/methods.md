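# Methods

`piwikit` implements the quantitative machinery used to establish that
PIWI-clade Argonaute proteins bind and slice partially complementary
targets: equilibrium-binding estimation from Bind-'n-Seq data, burst
kinetics from Cleave-'n-Seq time courses, the in vivo fraction-cleaved
statistic from degradome (5'-monophosphate) sequencing, a logistic
decision function over pairing features, and a transposon-mutagenesis
escape simulator. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic generators do and
do not emulate.

## Coordinates and pairing conventions

Guide positions are 1-based (g1 = 5' end); t_i is the target nucleotide
opposite g_i, and the duplex is antiparallel, so a target read 5'→3'
visits tN…t1. Transcript coordinates are 0-based half-open. Slicing
hydrolyses the bond between t10 and t11: if t10 sits at transcript index
c, then t_i sits at c + 10 − i, the 3' cleavage product starts at c (and
carries the diagnostic 5' monophosphate), and a fully paired N-nt guide
covers [c + 10 − N, c + 10).

G:U wobbles are a configurable convention: they count as *paired* for
contiguity, candidate-site matching and energy (default), and as
*mismatches* for mismatch-geometry labelling and for the
mutagenesis-competence rules, where the rules speak of mismatches with
no wobble carve-out.

## Duplex free energy

`predict_duplex_energy` is a Turner-style nearest-neighbour sum:
duplex initiation (+4.09 kcal/mol), stacking terms over adjacent paired
positions within each contiguous block (the 16 Watson–Crick/Watson–Crick
stacks carry Turner 2004 values; wobble-containing stacks use flat
defaults of −1.2/−0.5 kcal/mol), a +0.45 kcal/mol terminal penalty for
A:U or G:U closing pairs, and an internal-loop charge of 1.7 + 1.1·m
kcal/mol for a run of m mismatched positions between blocks. An empty
pairing has energy 0 by convention. The parameter set is a frozen
dataclass, so any external predictor can be substituted through the same
interface; accessibility terms of the target are deliberately out of
scope. `kd_to_energy` converts a dissociation constant with
ΔG⁰ = RT ln(K_d/1 M) at a default T = 306.15 K, the 33 °C binding-assay
temperature.

## Bind-'n-Seq K_d estimation

Reads follow the library layout GAUC + N20 + UGGA and are assigned to
non-overlapping site types: contiguous complementarity windows (≤10 nt
windows require non-complementary flanks on both sides, 11-nt windows
only opposite the guide-5' flank, ≥12 nt none) plus the canonical 8-mer
(seed g2–g8 with t1A) and a no-site class. Reads containing more than
one motif occurrence are rejected. Because t1A can also satisfy the
g2–g8 flank rule, overlapping 8-mer/seed hits resolve to the 8-mer so
the classes stay disjoint.

The binding model is equilibrium competition: site type i at library
concentration S_i = f_i·S_total (S_total = 100 nM) is occupied with
θ_i = E_free/(E_free + K_d,i), where E_free solves the total-RISC
conservation E_T = E_free + Σ S_i θ_i (monotone; solved by bisection to
relative tolerance 1e-13). Bound-sample compositions are multinomial
with p_i ∝ f_i θ_i, across the six-point active-piRISC series
0.003–1 nM.

The likelihood is maximized **jointly** over log10 K_d per site type, a
log10 stock-concentration scale (the true active concentration at the
top dilution), and the library frequencies f (softmax-parameterized
around the observed input composition, with the input sample's own
multinomial term in the objective). The joint treatment matters: the
absolute K_d scale is only weakly identified (it rides on the depletion
nonlinearity of the titration), and plugging in noisy observed input
frequencies as constants at 10⁶-read depth biased every K_d several-fold
along that soft direction. With frequencies free, planted K_ds spanning
5–1000 pM are recovered within ~1.2-fold.

Optimization is bounded L-BFGS-B in log10 space (K_d ∈ [1e-6, 1e4] nM)
with a 1e-5 finite-difference step — large enough to stay above the
inner root-solver noise — started from all 49 combinations of 7 stock
guesses × 7 no-site-K_d guesses (0.1, 0.2, 0.5, 1, 2, 5, 10 nM);
enriched-site starts are seeded from top-sample enrichment. The median
of the 49 per-start estimates is reported; the result is flagged if more
than half the starts fail or pin at the box bounds. Sites ≥15 nt are
excluded from fitting (long enough to be sliced; the binding reactions
omit the GTSF1 cofactor precisely so that shorter sites are
cleavage-free).

The double-filter binding assay uses the closed-form quadratic solution
f(E_T) = ((E_T+S_T+K_d) − √((E_T+S_T+K_d)² − 4 E_T S_T))/(2 S_T), fit by
least squares in log10 K_d; flat titrations are flagged unidentifiable.
`energy_regression` reports OLS r² and a two-tailed label-permutation P
for Pearson's r with the add-one convention.

## Cleave-'n-Seq kinetics

Counts per variant × timepoint × trial are scaled to ppm and divided by
the summed ppm of normalizer variants (≤7-nt complementarity, not
cleaved), which absorbs both depth and overall library loss. The
relative cleaved product is P_rel = (v₀ − v_t)/v₀; negative values from
counting noise are retained so least squares sees symmetric errors.

All trials and both timepoint subsets (0, 1, 2, 4, 8 min and 0, 20, 60,
120, 240, 480, 960 min; three trials each) are pooled into one bounded
trust-region fit of the single-turnover burst-and-steady-state form

  P_rel(t) = E_rel · [(k₂/(k₂+k₃))² (1 − e^−(k₂+k₃)t) + k₂k₃/(k₂+k₃)·t]

with 0.5 ≤ E_rel ≤ 1, 0 ≤ k₂ ≤ 100 min⁻¹, 0 ≤ k₃ ≤ 1e-4 min⁻¹ (the k₃
bound asserts the single-turnover regime), ≤10,000 function evaluations,
and a small multi-start over k₂ initializations. The amplitude is
applied once: a squared amplitude would allow the burst phase to exceed
the cleavable fraction. k = k₂ + k₃ is the pre-steady-state cleavage
rate; parameter standard deviations come from the fit covariance (not
across-trial spread) and are labelled as such. Diagnostics flag null
signal, fits pinned at the k₂ bounds, and saturated fast phases (every
sampled point already at the burst plateau identifies only a lower bound
on k).

A rate is considered identifiable when the sampling grid brackets it:
k between −ln(0.95)/960 ≈ 5e-5 and −ln(0.05)/1 ≈ 3 min⁻¹; the recovery
tests draw k log-uniformly over [1e-3, 10] min⁻¹ and require 25% accuracy
only inside that window. Fold-change summaries divide the
matched perfect-site k by each variant k and report medians and IQRs per
grouping. Cut-site mapping locates each barcode-resolved 3'-product
read's 5' end in its variant by exact prefix search and histograms the
offset from t10; spiked 5'-monophosphorylated control oligos (t10_index
at their own 5' end) report trimming/non-templated addition as nonzero
offsets.

## In vivo fraction cleaved

Small-RNA reads are grouped by their 25-nt 5' prefix (3'-trimming makes
piRNA 3' ends heterogeneous); a group is retained if it maps uniquely
and is ≥1 ppm in all 12 control replicates, and is *targeted*
(eliminated by the mutation) if its mean mutant abundance is ≤0.1 ppm.
All thresholds are inclusive. Spike-in oligos calibrate reads →
molecules linearly; molarity uses a default 0.6 pL cell volume (1 ppm ≈
10 molecules per cell ≈ 28 pM), exposed as a parameter.

A 5'-monoP species at transcript coordinate c is a candidate cleavage
product of a retained piRNA if the antiparallel pairing placing t10 at c
satisfies the queried configuration (contiguous g2–gX, or with stated
mismatches) *and* the guide position immediately after the paired region
is unpaired — the non-overlap rule that keeps g2–gX disjoint from
g2–g(X+1). Sites explained by several piRNAs are counted once, with the
cumulative explaining abundance recorded for concentration binning
(bins <30, 30–50, 50–100, 100–500, >500 pM, lower-inclusive).

For each of the 16 control×mutant single-animal pairings (4×4 degradome
replicates), f_decreased is the fraction of candidate sites whose
abundance falls ≥8-fold (zero mutant abundance always counts; otherwise
the ratio uses a one-read-equivalent floor, default 0.01 ppm), and

  f_cleaved = f_decreased(targeted piRNAs) − f_decreased(control piRNAs)

per pairing, the control set measuring the sampling error of short-lived
fragments. The headline value is the median over the 16 pairings; the
95% CI is a percentile bootstrap over candidate sites (targeted and
control resampled independently, 10,000 iterations, median over pairings
recomputed per iteration).

## Logistic decision function

Candidate sites with ≥19 paired nucleotides in g2–g25, abundance
≥0.1 ppm and no indels yield 35 features: 24 per-position pairing
indicators, total paired count, abundance and −ΔG⁰ (each min–max
rescaled to [0,1]), four t1-identity one-vs-rest indicators and four
region indicators. The ensemble fits 5×-repeated stratified 5-fold
cross-validation inside each of 16 cohort permutations (400 models) with
L-BFGS, ≤1,000 iterations, balanced class weights, and L2 penalty λ = 1
in the scikit-learn convention (C = 1/λ). Continuous features are
rescaled on each training fold and the scale applied (clipped) to its
held-out fold, avoiding leakage; the dataset-level rescaling used for
descriptive feature tables is kept alongside. PR-AUC is trapezoidal over
threshold-wise precision–recall points with stable tie handling, per
model on held-out folds and optionally on an independent cohort
(400×16 values).

## Mutagenesis escape simulation

A transposon consensus accrues 1,000 accepted single-nucleotide
substitutions per lineage, 100 lineages. Proposals draw a position
uniformly and a replacement from the mutation spectrum row of the
current base (default 2:1 transition:transversion, any 12-entry spectrum
accepted); a proposal inside an ORF must be synonymous in **every** ORF
containing it or it is redrawn. Guides are evaluated at fixed anchors
(their exact-match position on the unmutated consensus — substitutions
never shift coordinates): a 26-nt piRNA remains cleavage-competent with
≤6 total mismatches; its 21-nt 5'-prefix "siRNA" requires ≤5 total, ≤1
in the seed g2–g8, and none at g9, g10, g11 or g13. Decay is the
least-squares slope of fraction-competent versus substitution count in
% of guides per substitution; both the slope of the mean trajectory and
the mean/median of per-lineage slopes are reported, since the two
aggregation orders differ in general.

## k-mer sharing

For each k, the fraction of transcripts containing at least one exact
k-mer from the consensus set (sense strand by default, both strands
optionally; windows containing ambiguity codes are skipped). The
fraction is non-increasing in k, and the hash-set scan is tested against
a quadratic-time substring search.

## Synthetic data: what it does and does not emulate

All generators draw every random quantity from one seed and emit the
exact formats the analysis functions read. They emulate: the six-point
RBNS concentration series with equilibrium-binding structure and
realistic random-20-mer motif frequencies; exponential depletion over
both CNS timepoint subsets with multinomial counting noise and
uncleavable normalizer variants; degradome cohorts of 4 control + 4
mutant animals (12/9 small-RNA replicates) with log-normal piRNA
abundances, planted target sites realizing exact pairing configurations,
and a planted decreased fraction φ for targeted sites versus a
background rate for control sites (so the expected statistic is
φ − background; φ can depend on piRNA concentration); and antisense
guide repertoires that start fully competent.

The logistic recovery cohorts draw abundance uniformly rather than
log-normally: coefficient-ordering recovery is the estimand there, and a
heavy-tailed abundance would tie the fold-level min–max feature scale to
an unstable extreme order statistic, confounding the check.

They do **not** emulate read-level artifacts: adapter content,
sequencing error, UMI duplication, alignment ambiguity (uniqueness is a
truth flag), rRNA contamination, or overdispersion beyond multinomial
counting (a switchable log-normal replicate CV stands in for
animal-to-animal variation). Passing tests therefore validate the
estimators against their own statistical assumptions, not the upstream
read processing, which this package deliberately leaves to standard
aligners.

## Problem sizes

The default validation sizes are 500 CNS variants at 1e5 reads/sample,
5 RBNS site types at 1e6 reads/sample, degradome cohorts of 120 targeted
+ 120 control candidate sites, 3,000-site logistic cohorts, 10⁴
random instances per brute-force rule oracle, and 100×1,000-step
mutagenesis lineages — sizes at which every recovery criterion is
statistically meaningful while a full run completes in minutes on one
core.
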