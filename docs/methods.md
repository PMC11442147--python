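# Methods

`cellpanel` classifies patients from annotated single-cell RNA-seq cohorts
and distills the decision into a small, assayable gene panel. This note
describes the statistical procedure, the synthetic cohorts the test suite
is built on, and the numerical choices made where the design was open.

## Problem setting

Input is a cells × genes count matrix in which every cell carries three
labels: a patient (donor) id, a binary condition constant within a patient
(0 = reference, 1 = perturbed — disease vs. control, responder vs.
non-responder, …), and a cell type. The patient, not the cell, is the
experimental unit: cells from one donor are strongly correlated through
donor-specific expression, so every split in the pipeline — the outer
train/test split, the internal validation split of the cell-type scorer,
and the cross-validation folds of the gene selector — partitions
*patients*, never cells. The practical consequence is demonstrated in the
test suite: switching the internal split to cell-wise inflates the
apparent responsiveness of cell types that carry no perturbation signal
at all, because the classifier recognises donors instead.

## Stage 1 — responsive cell-type ranking

Perturbations rarely touch all cell populations equally, so the pipeline
first asks, per cell type: how well can a classifier separate perturbed
from reference cells? For each retained cell type and each of `n_repeats`
(default 20) rounds, an equal number of cells (default 20) is drawn
without replacement from every patient, a condition-stratified 75/25
patient split is made, a random forest (100 trees, minority condition
weighted by `n_total / (2 n_c)`) is fit on the training patients' cells,
and AUROC is measured on the held-out patients' cells. The mean held-out
AUROC over repeats is the type's responsiveness score; types are ranked by
it (ties: more cells, then name). Scores near 0.5 mean the type carries no
signal; the equal-per-patient draw stops large donors from dominating.

Cell types are only scored when, in each condition separately, at least 3
patients contribute at least 20 cells (`filter_cell_types`); counts are
depth-normalized to 10,000 per cell and log1p-transformed first, unless
the input is tagged as externally batch-corrected, in which case it is
used as-is.

## Stage 2 — sparse panel selection (SVM-RFE + elbow)

Within the chosen cell type, a linear SVM (C = 1, class-balanced) is fit
on standardized expression of all genes, and the genes with the smallest
squared weights are removed — 3% of the surviving genes per step, at
least one — until a single gene remains. Running this inside a
patient-grouped, condition-stratified k-fold cross-validation (default
k = 5, lowered when the cohort is small; k = 2 is supported) gives, per
panel size on the elimination schedule, a mean held-out balanced accuracy.
Balanced accuracy is used because minority-class weighting pervades the
rest of the method. The held-out score at each size is produced by the
same SVM that drives that elimination step: at every point of the
schedule the surviving genes *are* the fold's top genes, so no separate
refit is needed.

The panel size is chosen by the perpendicular-line rule on the mean
curve: order points by increasing gene count, draw the chord between the
endpoints, and take the point with the maximal perpendicular distance to
it; exact ties resolve to the smaller count (the sparser panel), and a
collinear curve falls back to the smallest count with a warning. The
final panel is the top-`n_opt` genes of an elimination ranking computed on
all training cells of the type; per-fold rankings are used only to build
an honest accuracy curve. A panel is flagged low-confidence when the
curve never reaches 0.7 — downstream numbers from such a panel should not
be trusted.

Stable mode repeats the whole selection on `n_subsets` (default 20)
patient-level downsamples (80% of the patients per condition, drawn
without replacement within a subset) and keeps the genes selected in
strictly more than `freq_threshold` (default 0.5) of the subsets, ordered
by selection frequency and then mean within-panel rank. This trades a
little sparsity for robustness to cohort composition.

## Stage 3 — ensemble classification and patient aggregation

Five cell-level classifiers are trained on the selected type restricted
to the panel (features standardized with training statistics, which are
stored and re-applied at prediction time): L2 logistic regression, a
linear SVM with Platt-calibrated probabilities, a random forest, a
distance-weighted kNN (k = 15), and a two-layer graph attention network.
The GAT is a compact NumPy implementation (8 heads × 8 hidden features,
ELU, dropout 0.4, Adam 5e-3 with weight decay 5e-4, weighted
cross-entropy, early stopping with patience 20 on a patient-held-out
split) operating on a symmetrized 15-nearest-neighbour cell graph with
deterministic index-order tie-breaking; its analytic gradients are checked
against finite differences in the test suite. Prediction on a new cohort
is inductive: the graph is rebuilt within the new data. All members
except kNN (which has no sample-weight notion) are trained with cell
weights `w_i = N / (2 P_c n_p)` — each patient then contributes equal
total weight within its condition and both conditions contribute equally.

The per-cell consensus is the elementwise median of the members'
probabilities. A patient's score is

    AUC_p = (#{cells with consensus > 0.5} + 0.5 · #{= 0.5}) / n_cells,

i.e. the rank statistic of the patient's cells against the 0.5 decision
reference; `AUC_p > 0.5` calls the patient perturbed, exactly 0.5 is
flagged undetermined and counted as reference. Significance against 0.5
comes from a one-sided bootstrap over the patient's own cells (B = 1000,
add-one corrected; an observed AUC of exactly 0.5 gives p = 1). This
within-patient bootstrap quantifies the *consistency* of the call across
the patient's cells, not cohort-level significance — a caveat worth
remembering when reading per-patient p-values. Cohort accuracy,
precision, sensitivity, specificity and F1 are computed on the hard
labels with perturbed as the positive class; vacuous denominators (e.g.
specificity with no reference patients) read as 1.0.

## Synthetic cohorts

All recovery and calibration tests run on simulated cohorts with known
ground truth. Counts are negative-binomial (size 2.0) with log-normal
gene means (log-mean −0.7, log-sd 1.0), gene-specific multiplicative
per-donor random effects (log-sd 0.3 per patient × gene — a scalar
per-donor factor would be indistinguishable from library size and vanish
under depth normalization), and per-cell library factors (log-sd 0.2). One cell type is responsive: in perturbed patients its
marker genes' means are multiplied by `2^log2FC`. Marker baseline means
are drawn from the upper half of the gene-mean distribution because
plausible biomarkers are detectably expressed. The default ("strong")
cohort has 10 patients per condition, 3 cell types, 60 cells per patient
per type, 300 genes, 12 markers and log2FC = 2; "null" is identical with
log2FC = 0, "imbalanced" has 15 vs 5 patients, and "tiny" (4+4 patients,
2 types, 60 genes) keeps unit tests fast.

The per-patient random effect is deliberate: it creates exactly the
donor-identity leakage that patient-wise splitting guards against, which
lets the suite measure the inflation a cell-wise split would produce.
The simulator omits gene–gene correlation, batch structure and
trajectory effects, so passing tests show that the pipeline recovers
planted signal under realistic overdispersion and donor variation — not
that it is robust to batch effects (batch-corrected input is accepted but
correction itself is out of scope) or to correlated marker modules.

## Problem sizes and numerical choices

Recovery and calibration checks use 20 independently simulated default
cohorts (3,600 cells × 300 genes each); the reproduction script uses 10.
The liblinear solver runs primal with tolerance 1e-2 — elimination
ordering is driven by squared-weight *ranks*, which are insensitive to
the last digits of the coefficients. Zero-variance genes get unit scale
during standardization. Elbow distances are compared with exact float
equality so that the tie rule is reproducible. All randomness flows from
a single seed through named, independent substreams per stage; per-cell-
type substreams are keyed by a CRC of the type name, so scoring one type
is unaffected by which others are present.

## Known limitations

Binary conditions only; one responsive type is selected (`--top-n` can
emit more, but panels are per-type). No internal batch correction: cross-
cohort prediction requires externally integrated expression. The
bootstrap p-value is within-patient, as discussed above. Cohorts with
very few patients per condition (< 3) cannot be scored reliably, and the
retention filter will refuse types that are sparsely sampled per donor.
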