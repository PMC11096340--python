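# Methods

This note documents the models, the parameter choices, the synthetic-data
generator, and the numerical decisions behind `aa_phenoscreen`, in the order
the pipeline runs.

## Startle battery and analysis windows

The battery is acclimation (default 3600 s, dark), then `n_cycles = 5`
repeats of a 60-s acoustic/light string followed by a 1740-s intermission.
The default event list reconstructs the printed tap/light program: six 10-s
light epochs (darkness, red, blue, purple, white, flicker) tile the minute,
and 46 taps in seven runs (6 L, 4 H, 8 L, 2 L, 10 H, 2 H, 14 H) are laid out
with the stated pauses (1, 4, 1, 8, 0, 7, 13, 3 s). The pauses sum to 37 s,
so the reconstruction assigns each tap a 0.5-s slot (the tap plus its
inter-tap break), which makes the program tile exactly 60 s. Event timing is
metadata; the simulator keys its startle gain off the six 10-s epochs, which
also serve as the default P1–P6 peak windows — the only printed six-way
partition of the startle minute.

Per cycle, SRB is the 60-s string and PSRB the first `psrb_s = 600` s of the
intermission. When a configuration uses a shorter intermission (the test
suite does, to keep runs small), PSRB is clipped to the intermission so the
windows remain disjoint and ordered.

## Feature definitions and edge cases

Frame *i* belongs to a window if `start ≤ t[i] < end`. Step quantities
(distance, heading change) are attributed to the frame they end on, so the
step *into* the first window frame is counted whenever a preceding frame
exists; the first frame of a whole track carries step 0 by definition.

* Turning uses the heading channel, not displacement vectors; frames with
  zero step still contribute heading changes. Turning is normalized by the
  distance travelled *in the same window* (the alternative — whole-run
  distance — would make the feature depend on behaviour outside the window).
* Pausing counts frames with step distance ≤ `eps`; `eps = 0` by default
  (exact zeros, as trackers emit for a stationary fish), configurable for
  noisy trackers.
* A movement bout is a maximal run of non-pause frames; spurt velocity is the
  mean of per-bout maxima of frame velocity (`step · frame_rate`).
* Thigmotaxis classifies each frame by its own endpoint position, strictly
  outside the centred inner rectangle whose sides are `inner_fraction = 0.40`
  of the well's. For spatially uniform positions the expected time ratio is
  `1 − 0.40² = 0.84`, which the tests verify by Monte Carlo.
* Undefined features (turning/spurt/distance-thigmotaxis of a fish that
  never moved) are *missing*, excluded pairwise from group statistics; in
  the classifier matrix they are imputed as 0% change with a companion
  missingness-indicator column, so "never moved" remains visible to the
  models.

Normalization: percent change versus the mean of same-plate dose-0 controls,
computed separately per window label and cycle. A plate without controls is
an error; a zero control mean leaves the feature undefined for that group.

## Group statistics

Dose groups are compared to plate controls with the two-sided Wilcoxon
rank-sum test (exact null for tie-free samples up to n = 20, normal
approximation with tie correction otherwise — the groups are different fish,
so the unpaired test is the correct reading), with Benjamini–Hochberg
adjustment across each window's whole feature × dose family. One-way
ANOVA + Tukey and two-way ANOVA + Dunnett post-hocs are provided for the
motility-index panels and delegate to scipy/statsmodels; the package's
contract is the table shape and family-wise control, both covered by
simulation tests (type-I rate ≈ α under the null).

## Classifier and paired-control ROC

The matrix holds fish × cycle rows: six normalized features, six missingness
indicators, and the ordinal dose level (0–3; concentrations differ in units
across drugs, so the ordinal level is the comparable covariate). Models:

* elastic-net logistic regression (`saga`, `l1_ratio = 0.5`, C grid
  0.01–10),
* SVM with a polynomial kernel (degree 3, C grid 0.1–10), decision values
  mapped through a logistic link so all scores live on (0, 1),
* random forest (300 trees, leaf-size grid).

Hyperparameters are selected by stratified 5-fold cross-validation *grouped
by fish* — all cycles of one fish share a fold — to avoid leakage between
folds; class imbalance is handled by class weights. Both resubstitution and
grouped-CV accuracy are reported, since "training accuracy" is ambiguous
between the two. Scores are P(AA) (probabilistic models) or the logistic of
the SVM decision value; the ROC/AUC of a test drug is computed on its pooled
observations labelled with the putative class plus the paired opposite-class
control drug's observations (ketamine for putative-AA, fluoxetine for
putative-other). The AUC equals the Mann–Whitney concordance of the same
scores; a property test holds them together to 1e-9.

## Rank-product differential test

Comparisons are the replicate pairs KO_i vs WT_i (three comparisons), not
all nine KO×WT pairings: with disjoint replicate pairs the comparisons are
independent under the null, so the classic permutation null — an independent
uniformly random rank per comparison — is exact. (With all nine pairings the
comparisons share replicates and the same null is measurably
anti-conservative: we observed a type-I rate of ≈ 0.15 at a nominal 0.05 in
null simulations, which is why the paired design is used.) The rank product
is the geometric mean of the entry's per-comparison fold-change ranks
(rank 1 = most extreme in the tested direction), missing comparisons are
skipped, and `p = (1 + #{permuted RP ≤ observed}) / (B + 1)` per direction.
Both directions are tested; the differential set requires the mean KO/WT
ratio beyond the fold threshold *and* the direction-matched p below the p
threshold. The fold threshold defaults to 2 (the stricter of the two values
that appear in the source material's text — 1.5 is sometimes quoted — and is
a parameter). Protein-centric mode collapses to unique accessions keeping
each protein's most significant peptide; peptide-centric mode keeps all.

## Hub analysis

Candidates default to differential-set members (an optional user-supplied
gene list can restrict the pool, standing in for proprietary disease-gene
lists). Selection uses the printed thresholds verbatim: ≥ 7 interactions
with the differential set, or strictly more than 3 interactions of weight
strictly above 0.04. Significance is dual:

* empirical — B (default 1000) random same-size protein sets drawn uniformly
  from the universe excluding the candidate itself (to avoid self-counting),
  recording the candidate's edge count into each set;
  `p_emp = (1 + #{null ≥ observed}) / (B + 1)`;
* analytic — the hypergeometric upper tail with N = universe size, K = the
  candidate's degree within the universe, n = differential-set size. On a
  star-graph oracle the empirical null is exactly hypergeometric, verified by
  chi-square at B = 5000.

BH adjustment across candidates is applied to the hypergeometric p: the
empirical p cannot fall below 1/(B+1), a floor that no candidate can survive
after BH across hundreds of candidates at B = 1000, so the empirical null is
reported as per-candidate evidence (the boxplot view) rather than adjusted.

## Synthetic-data generator

Trajectories are a paused/spurting correlated random walk with wall bias at
the acquisition frame rate (default 60 fps):

* per frame the fish pauses with probability `p_pause` (baseline 0.35), so
  bout lengths are geometric;
* a moving fish turns by Gaussian heading noise (baseline SD 25° per frame)
  plus a drift of strength |b| toward the nearest wall (b > 0) or the well
  centre (b < 0), where `b = 0.20·m_thigmo − 0.16` maps the archetype's
  thigmotaxis multiplier to a signed wall preference (control: mild wall
  attraction; multipliers below ~0.8 flip to centre attraction — a pure
  attraction-strength parameter cannot push the time ratio below the
  uniform-occupancy floor of 0.84, so the sign must flip);
* frame speed is lognormal-noisy around a cruise speed (baseline 1.2 mm/s,
  per-fish lognormal heterogeneity σ = 0.08) with spurt spikes (probability
  0.05, factor 4), multiplied during the startle by a per-epoch gain
  (baseline 2.5/3.0/2.2/2.0/1.8/2.6 for P1–P6);
* walls are reflective; the fish cannot leave the 8-mm square well.

Archetypes scale these parameters multiplicatively, linearly in dose level
(dose 0 is always unperturbed): AA = speed ×0.70, pausing ×1.30, turning
×1.40, spurting ×0.80, thigmotaxis ×0.75 at top dose; "other" reverses the
pattern; "stressor" mimics osmotic-stress hyperlocomotion. The AA direction
pattern (distance, thigmotaxis and spurting down; turning and pausing up)
follows the published behavioural signature of clinically proven AA drugs;
the magnitudes are generator choices calibrated once so that the classifier
reaches high-90s AUC for AA-phenocopying compounds, mirroring the performance
regime reported for the real screen. They were not revisited afterwards.

The phosphoproteome generator draws per-entry log intensities from
N(14, 1) (natural log, arbitrary intensity units) with replicate noise
σ = 0.25, plants `n_true` entries shifted by `effect_fold` in KO (half up,
half down by default), applies missingness completely at random, and splits
a fraction of entries across two gel slices to exercise the merge.

The network generator builds an Erdős–Rényi background (defaults: 500
nodes, mean degree 50 — a deliberately dense regime in which a 3× connectivity
boost is detectable by the hypergeometric test after BH across ~100
candidates) with uniform weights on (0, 0.1]. Planted hubs are wired to a
fixed `round(boost · p_edge · |diff|)` number of differential-set neighbours
(topping up background edges) rather than independently boosted Bernoulli
edges: the deterministic count gives the same expected connectivity without
binomial noise in the planted signal, which would otherwise make hub
recovery erratic at desk scale. At `boost = 1` the target equals the
background expectation and the planted flags carry no signal.

### What the generator does and does not emulate

It reproduces the data *structure* (tracking time series around a stimulus
schedule, plate layout with internal controls, dose ladders, replicate
intensity tables, weighted interaction networks) and the *direction pattern*
of drug effects. It does not emulate C-start escape kinematics,
habituation across cycles, circadian or age effects, fish-level behavioural
syndromes (cycles are conditionally independent given the archetype),
intensity-dependent missingness, or the degree heterogeneity of real
interaction databases. Passing tests therefore demonstrate correctness of
the pipeline's statistics and recovery of planted effects under the stated
model — not performance on real screen data, which is not publicly
deposited.

## Problem sizes

Defaults match the study conditions (60 fps, 3600-s acclimation, five
60 + 1740 s cycles). The test suite and the acceptance script run the same
code at reduced size as the package's own benchmark configuration: 10–20
frames/s, 0–60 s acclimation, 600-s intermissions, ~40 fish per drug across
three dose levels (plus 40 plate controls), 100 effect-free replicates for
the null AUC, 100–200 null simulations for the rank-product type-I rate,
and 5–20 seeded networks for hub recovery. These sizes are stated here so
results are interpreted at the scale they were computed.

## Known limitations

* The pause threshold interacts with frame rate; features extracted at
  different acquisition rates are not directly comparable.
* The rank-product permutation p has resolution 1/(B+1); with the default
  B = 1000 the smallest attainable p is ~0.001.
* The hypergeometric hub p treats the differential set as a uniform draw
  from the universe, which real differential sets are not; the empirical
  background null is the primary evidence and the analytic p its
  well-calibrated surrogate under that assumption.
* `anova_posthoc`'s two-way Dunnett mode fits an additive two-factor model;
  interaction terms are out of scope.
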