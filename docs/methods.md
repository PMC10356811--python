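# Methods

This note documents the models, rules and numerical choices implemented in
`ecgbench`, the reasoning behind the open design decisions, and what the
synthetic data does and does not establish.

## Label unification and tasks

Raw annotation symbols are unified by an exact-lookup dictionary keyed on
`(dataset, raw_symbol, kind)`, where `kind` distinguishes beat symbols from
rhythm symbols (the same raw character can legitimately mean different
things in the two roles, e.g. `N` as a normal beat vs normal sinus rhythm).
The unified vocabulary is closed: beat codes N, LBBB, RBBB, PAC, PVC,
FUSION, PACED, UNKNOWN plus rhythm codes SINUS, AFIB, AFL, STACH, SBRAD,
SVTA and the non-diagnostic NOISE.  Unknown raw symbols are skipped with a
logged warning rather than failing, because real annotation streams carry
non-diagnostic markers; there is deliberately no fuzzy matching.

The AAMI form grouping ships as: N = {N, LBBB, RBBB}, SVEB = {PAC},
VEB = {PVC}; fusion, paced and unknown beats are excluded by default.
This keeps the three-class task clean and is overridable through a task
CSV.  The reduced rhythm task routes every rhythm code other than AFIB and
SINUS into an explicit other-rhythms class.

## On-disk dataset layout

Records are stored as plain text: a JSON header (patient, sampling
frequency, lead names), a whitespace signal matrix with one column per
lead, and an annotation CSV of `(sample, kind, symbol)` rows.  Rhythm
annotations are stored as change-point markers and converted at read time
to half-open `[start, end)` episodes, the final episode closing at the
record end.  All indices are 0-based; episodes are validated non-
overlapping.  Recording-level datasets add a `labels.csv` table
(`record_id, patient_id, labels`); when a record carries several labels the
first listed one is used for single-label tasks and the rest are logged.

## Segmentation semantics

* **Heartbeat windows** hold `w = round(duration_s * fs)` samples starting
  at `R - w//2` (integer floor-centering).  Beats whose window would cross
  a record boundary are dropped rather than padded: padding would fabricate
  signal inside a morphology window.
* **Sliding windows** use `w = round(window_s * fs)` and stride
  `s = round(w * (1 - overlap))`; the window count is
  `floor((L - w)/s) + 1` for `L >= w`.  The overlap policy is bound to the
  evaluation scheme — 0.5 for patient-disjoint schemes, 0.0 for
  intra-patient splitting, where overlapping windows would leak nearly
  identical signal across the train/test boundary — and remains
  config-overridable.
* **Window labels.**  Rhythm tasks: coverage voting — the task class whose
  episodes cover the largest part of the window wins; an exact tie goes to
  the class of the earlier-starting contributing episode (deterministic).
  Form tasks: abnormal priority — one abnormal beat labels the window with
  that abnormal class even if all other beats are normal.  When a window
  holds several distinct abnormal classes, the globally rarer class (by
  dataset-wide beat counts) wins, maximizing recall on minority classes;
  remaining ties go to the lowest class index.  A window with no resolvable
  evidence (no mappable beats under a form task, no covering episode under
  a rhythm task) is excluded rather than defaulted to normal: the
  annotations contain no evidence for any label.
* **Aggregation** of window predictions to one recording-level prediction
  uses majority voting, ties to the lowest class index.

The sliding-window labeler is verified exactly against an independent
brute-force rule applier on 1,000 random annotation streams (test suite and
acceptance script).

## Signal preparation

Segments are band-limited resampled (Fourier method, output length
`round(n * to_fs / from_fs)`) to the architecture's input frequency, then
cropped (head-aligned) or zero-padded (at the tail) to the exact input
length.  Head-crop/tail-pad is the least surprising convention and is
applied uniformly.  No filtering, baseline correction or normalization is
performed; the networks consume near-raw signal.

## Evaluation schemes

Inter-patient cross-validation treats each patient's segments as one
indivisible group.  Groups are assigned to `k` folds greedily: visited in
descending total segment count (ties by id — placing large groups first is
the standard greedy-balancing order), each group goes to the fold that
minimizes the objective `J` = mean over classes of the standard deviation
over folds of per-class counts, evaluated after tentative placement.  The
heuristic is deliberately greedy and can be suboptimal; on instances small
enough to enumerate it matches the exhaustive optimum, and on random
instances it beats the median of 1,000 uniformly random group-preserving
partitions (both checked in the acceptance suite).  For split `i` the test
set is fold `i`, the validation set fold `(i+1) mod k` (deterministic, and
every fold serves as validation exactly once), the rest train.  A verifier
asserts patient-disjointness of every emitted split; the experiment runner
treats a violation as a hard error, not a warning.

Intra-patient cross-validation is a seeded, class-stratified segment-level
k-fold (scikit-learn's `StratifiedKFold` behind the module surface).
Leave-one-patient-out uses a round-robin validation patient.  Holdout
carves one stratified patient fold for testing and one for validation
(early stopping needs a validation set).  Predefined record-to-fold
assignments are honored exactly; a 2-valued assignment is interpreted as
holdout with a 10% patient carve-out for validation.

## Architectures

All four networks run on an in-package NumPy reverse-mode autodiff engine —
a deliberately small, dependency-free implementation whose every gradient
(convolution, pooling, batch-norm, GRU backpropagation-through-time,
additive attention, softmax/cross-entropy) is verified against central
finite differences in the test suite.  The recurrent and attention layers
are single graph nodes with hand-written backward passes, so long sequences
do not inflate the graph.

* **CNN** (360 Hz): three blocks of conv + leaky-ReLU + max-pool stride 2
  with (filters, size) = (5,3), (10,4), (20,4); dense 30 → 20 → C with
  leaky-ReLU, softmax output.
* **ResNet** (250 Hz): stem conv (64 filters, size 3) + four blocks of two
  size-3 convs with (64, 128, 256, 256) filters, batch-norm and dropout
  between the convs, a size-1 projection shortcut around every block, a
  max-pool stride 2 after blocks 1–3 (downsampling placement was
  unspecified and is our choice), global average pooling, softmax.  The
  counted depth is 9 convolutions (stem + 8; projections not counted).
* **GRUAttNet** (500 Hz): five blocks of three 12-filter convs with lengths
  (3, 3, 24) and leaky-ReLU, dropout per block; a bidirectional GRU of 12
  units per direction (the per-direction reading of "12 GRU units" is our
  choice); additive attention with a learned context vector pooling the
  sequence; dense softmax head.
* **RTA-CNN** (300 Hz): six residual temporal-attention blocks combined as
  `trunk * (1 + attention)` — the identity path guarantees that zeroed
  attention leaves the trunk output unchanged.  The trunk is two convs with
  batch-norm; the attention branch downsamples (max-pool), applies two
  convs, upsamples (nearest-neighbour), applies a size-1 conv and a sigmoid,
  yielding per-time-step weights in [0, 1].  Filter lengths per block are
  (32, 16, 9, 9, 3, 3).  The published filter-count list has five entries
  for six blocks; we repeat 64, giving (16, 32, 64, 64, 64, 128), and both
  lists are overridable.  Max-pool and dropout follow each block; a
  100-unit dense layer precedes the softmax.

Leaky-ReLU slope is 0.3 throughout.  Dropout defaults to 0.2 where used.
Training hyperparameters (not fixed by the original pipelines, exposed in
`TrainConfig`): Adam, learning rate 1e-3, batch 32, max 100 epochs, early
stopping with patience 10 on validation loss (validation macro F1
selectable), best-validation parameters restored.  The **EN loss** is
implemented as `mean(exp(beta * (1 - p_true)) * (-log p_true))` with
`beta = 1` — a monotone transform of the cross-entropy term that up-weights
hard examples; cross-entropy is the default loss.  The true-class
probability is clamped at 1e-7 before the log.  The majority-class baseline
(`dummy_mv`) predicts the most frequent training class with probability 1,
ties to the lowest index.

Determinism: all initialization, batch shuffling and dropout randomness
derives from the config seed via `numpy.random.Generator`; repeated runs of
the same experiment produce bit-identical results tables.

## Metrics

Per-class precision/recall/F1 with the 0-convention for empty denominators;
macro F1 is the unweighted mean over classes.  A class absent from both the
truth and the predictions of a fold is excluded from that fold's macro
average and logged — scoring it 0 would penalize folds that legitimately
lack a rare class, scoring it 1 would reward vacuous perfection.  Per-fold
metrics are computed first and then averaged over folds (fold-then-average,
rather than pooling all test predictions).  The implementation is an
independent NumPy computation checked against scikit-learn to 1e-12.

## Synthetic data: what it emulates and what it does not

Beats are sums of Gaussian bumps (P wave, biphasic QRS pair, T wave); PVCs
are wide and polarity-inverted with no P wave, PACs near-normal in shape
but 20% premature in timing.  Rhythm classes are encoded through RR
statistics: sinus regular around 0.8 s, tachycardia regular < 0.6 s,
bradycardia regular > 1.0 s, atrial fibrillation gamma-distributed RR with
coefficient of variation 0.25 (≥ 0.15 by construction).  Episode plans are
sampled from per-patient class mixtures (Dirichlet-perturbed around the
configured mixture, concentration 12) so patients genuinely differ — the
property that makes stratified patient splitting non-trivial.  Defaults:
40 patients, 60 s records at 250 Hz, noise SD 0.05, PVC rate 0.08, PAC
rate 0.04.  Annotations are exact ground truth for the rendered signal and
round-trip bit-identically through the I/O layer.

Not emulated: realistic ECG morphology variation, baseline wander, muscle
or electrode noise, QRS-detection errors, inter-lead differences.
Consequently, passing tests demonstrate the correctness of the pipeline
mechanics (label routing, windowing arithmetic, split guarantees, learning
dynamics on separable classes) — they do not predict classification scores
on clinical recordings.  The 1-nearest-neighbour separability check
(accuracy ≥ 0.9 for N vs PVC at noise SD ≤ 0.05 on 0.72 s windows)
guarantees that the training smoke tests are meaningful.

## Problem sizes used in tests and acceptance runs

The acceptance run synthesizes a 40-patient beat-level dataset for the
split-guarantee check, uses 100 random stratification instances against
1,000 random partitions each, 1,000 random annotation streams for the
window-labeling oracle, 1,000 random label vectors for the metrics oracle,
and trains the CNN (and a ResNet scaled to 16/32/64/64 filters, as wide
residual stacks are unnecessary for the separability check) on 200 segments
per class for up to 50 epochs.  The end-to-end determinism check repeats a
3-fold inter-patient CNN experiment on a 12-patient dataset at two epochs —
small sizes chosen so the whole acceptance run completes in minutes on one
CPU while still exercising every stage.

## Known limitations

* Episode segmentation is provided for completeness but, like the headline
  experiments it supports, is not a realistic deployment scenario (episode
  boundaries are unknown in unannotated signal).
* The greedy stratifier optimizes absolute per-class counts, not
  proportions; with wildly different fold sizes the objective can prefer
  balanced counts over balanced prevalences.
* The NumPy training stack is single-threaded and intended for
  method-comparison experiments at moderate scale, not for training on
  hours of Holter data.
* Multi-label windows are out of scope: windows receive exactly one label
  by voting.
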