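# aa-phenoscreen

Phenotypic drug screening in zebrafish larvae, with a phosphoproteomic
signalling-hub arm. The package is aimed at researchers building behavioural
screens for antidepressant/anxiolytic ("AA") drug action and at analysts who
need the matching statistics: trajectory feature extraction, plate-normalized
group comparisons, classifier-based phenotype calls with paired-control ROC,
rank-product differential phosphoproteomics, and interaction-network hub
over-representation against random background networks.

## The science

**Behaviour arm.** Larvae are held individually in square wells, acclimatised
in the dark, and exposed to five cycles of a 60-s acoustic/light startle
string (low/high taps interleaved with 10-s light epochs: darkness, red,
blue, purple, white, flicker), each followed by a long recovery. From the
tracked trajectory, six behavioural *syllables* are extracted per fish and
per analysis window — the startle minute (SRB) and the first 10 minutes of
recovery (PSRB):

* total **distance** travelled (mm);
* **relative turning** — the summed magnitude of heading changes, each folded
  to the smaller angle `|((Δh + 180) mod 360) − 180| ∈ [0, 180]`, divided by
  distance travelled (deg/mm);
* **pause time** — total time at zero step distance (s);
* **spurt velocity** — the mean over movement bouts of each bout's peak frame
  velocity (mm/s);
* **thigmotaxis** by time and by distance — the fraction of time/distance
  spent outside a centred inner zone sized at 40% of the well's width and
  length (wall-hugging, a conserved anxiety-like behaviour).

Features are expressed as percent change versus same-plate zero-dose
controls, which absorbs plate-to-plate baseline differences; group motility
is summarised by the relative motility index
`MI_R(c_x) [%] = 100 · (Mc_x − Mc_0) / Mc_0`
overall and within six peak windows P1–P6 of the startle minute.

Classification: rows are fish × cycle observations of the six normalized
syllables plus the ordinal dose level. Three model families (elastic-net
logistic regression, polynomial-kernel SVM, random forest) are trained to
separate AA-class training drugs (diazepam, fluoxetine, imipramine, LiCl)
from "other" (ketamine, MK801), per window. A held-out test drug is scored
with the **paired-control ROC** scheme: its observations (labelled with its
putative class) are pooled with an opposite-class control drug's observations
(ketamine for putative-AA drugs, fluoxetine for putative-other), and the
AUC of the AA score against those labels measures how cleanly the drug
separates from the opposite phenotype.

**Phospho arm.** Starting from an identified-phosphopeptide intensity table
(two genotypes × three replicates, five gel slices), entries are pooled
across slices, identical phosphopeptides merged by summing intensities, and
entries with more than one missing replicate in either genotype removed.
Differential abundance is tested per direction with the rank product — the
geometric mean of an entry's fold-change ranks over the replicate-pair
comparisons — against a permutation null, with the differential set gated at
mean ratio > 2 (either direction) and direction-matched p < 0.05. Candidate
hubs (≥ 7 interactions with the differential set, or > 3 interactions of
weight > 0.04) are then tested for over-connectivity: an empirical null from
1000 random same-size protein sets drawn from the phosphoproteome universe,
alongside the hypergeometric upper tail P(X ≥ k) with N = universe size,
K = candidate degree, n = differential-set size, BH-adjusted across
candidates.

**Synthetic data.** All inputs can be generated with planted ground truth:
trajectories from a paused/spurting correlated random walk with wall bias
whose sufficient statistics are exactly the six syllables, drug archetypes as
multiplicative parameter effects scaled by dose, log-normal phosphopeptide
tables with planted fold changes, and Erdős–Rényi networks with planted
high-connectivity hubs.

## Worked example

Run a complete synthetic screen — simulate a training panel shaped like the
published design plus a held-out test compound, extract and normalize
features, train the three models per window, and score the test drug with
the paired-control ROC:

```python
from aa_phenoscreen import screen

res = screen.run_synthetic_screen(seed=1, test_drugs={"jnk_inhibitor": "AA"})
print(res.accuracy.to_string(index=False))
print(res.auc.to_string(index=False))
```

```
window_label         model  training_accuracy  cv_accuracy
         SRB penalized_glm           0.996581     0.996577
         SRB      svm_poly           0.998291     0.996577
         SRB random_forest           1.000000     0.994875
        PSRB penalized_glm           1.000000     1.000000
        PSRB      svm_poly           1.000000     1.000000
        PSRB random_forest           1.000000     0.994043

    test_drug control_drug         model window_label putative_class      auc call  n_test
jnk_inhibitor     ketamine penalized_glm          SRB             AA 0.999974   AA     195
jnk_inhibitor     ketamine      svm_poly          SRB             AA 1.000000   AA     195
jnk_inhibitor     ketamine random_forest          SRB             AA 1.000000   AA     195
jnk_inhibitor     ketamine penalized_glm         PSRB             AA 1.000000   AA     195
jnk_inhibitor     ketamine      svm_poly         PSRB             AA 1.000000   AA     195
jnk_inhibitor     ketamine random_forest         PSRB             AA 1.000000   AA     195
```

Reading the output: training accuracy is resubstitution accuracy on the six
training drugs, `cv_accuracy` the grouped 5-fold cross-validated accuracy
(all cycles of one fish stay in one fold). Each AUC row is one paired-control
ROC: the held-out AA-archetype compound against ketamine's "other"-labelled
observations — an AUC near 1 means the compound's behavioural fingerprint is
cleanly AA-like, near 0.5 means indistinguishable from its paired control.
`n_test` counts the pooled fish × cycle observations of the test drug.

The same pipeline runs from files via the CLI:

```sh
aa-phenoscreen simulate plate --n-fish 8 --acclimation 0 --intermission 600 \
    --frame-rate 10 --seed 1 --out run_inputs
aa-phenoscreen behavior --config run.yaml --out run_out
aa-phenoscreen phospho  --config run.yaml --out phospho_out
aa-phenoscreen hubscan --network net.tsv --diff diff.txt --universe all.txt \
    -B 1000 --seed 1 --out hubs.tsv
```

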