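# Methods

This note documents the models, the synthetic-data generator, the numerical
and design choices behind `eboxnet`, and what the package's tests do and do
not establish.

## Dataset protocol

Peaks are treated as BED/narrowPeak 0-based half-open intervals. The window
for a peak is `[mid − 150, mid + 151)` where `mid = ⌊(start + end)/2⌋`; the
narrowPeak summit column is ignored in favour of the interval midpoint, and
peaks are unstranded (forward-strand sequence only). Windows that overrun a
chromosome end are skipped with a logged warning, never padded. Positives
with more than 10% ambiguous bases are dropped; remaining `N`s are replaced
by a seeded random base before shuffling (the Eulerian construction needs a
concrete alphabet) and encoded as uniform 0.25 columns for the models.

Negatives are dinucleotide-preserving shuffles of their parent positive —
the Altschul–Erickson scheme: the sequence is an Eulerian path on the
base-transition multigraph; a uniformly random spanning arborescence toward
the final base is drawn by rejection, remaining out-edges are permuted, and
the path is walked from the original first base. This preserves all 16
dinucleotide counts, the first and last base, and the length exactly, and
samples uniformly over valid arrangements (checked against exhaustive
enumeration on small cases). Two negatives per positive is the default;
negatives are fixed at dataset-build time, not regenerated per epoch, and
each replicate's RNG is seeded by hashing (dataset seed, parent id,
replicate) so datasets are bit-reproducible while shuffles stay independent.

Splits are 70/20/10 by default, assigned at the level of a *family* (a
positive and its shuffled negatives) so no shuffle parent straddles a split
boundary; validation and test take `⌊fraction × n⌋` families each and the
remainder trains.

## Models

All three architectures share a first stage: a 1-D convolution over the
encoded sequence (filters of length 24 by default — wide enough to hold a
6-nt core plus context — 16 filters) followed by a DeepBind-style rectifier
`max(0, x − b)` with one learnable threshold `b` per filter.

* **cnn** — global max pooling (optionally max + mean) over positions, then
  a small fully connected head with a leaky rectifier, dropout, and a single
  sigmoid output.
* **cnn_lstm** — the rectified filter-response sequence is locally
  max-pooled (width = stride = 4 positions) and fed to two stacked LSTM
  layers (hidden size 16); the final hidden state feeds the same head. The
  local pooling is a deliberate choice: with 301-nt windows the unpooled
  response sequence is 278 steps long, and credit from a last-hidden-state
  readout does not reach the convolution in any reasonable training budget
  (validation AUC stays at chance). Pooling to ~69 steps preserves the
  order/spacing information the recurrence is meant to model while making
  the optimisation tractable; `lstm_pool=1` restores the unpooled layout.
* **cnn_embed** — overlapping 3-mers are mapped through a learned embedding
  (dimension 8, trained end-to-end with the rest of the network, with a
  dedicated index for N-containing 3-mers) before a dense-input convolution
  and the cnn head.

The engine is pure NumPy in float32. Gradients are hand-written per layer
and verified against directional finite differences in the test suite.
Initialisation is Glorot-uniform, seeded; the LSTM forget-gate bias starts
at 3 (initial forget gate ≈ 0.95) so information can persist across steps
before the gates are learned; the classifier head uses a leaky rectifier
(slope 0.1) so its small fully connected layers cannot die irrecoverably
under adaptive-moment updates.

### Training

Binary cross-entropy, Adam (β₁ = 0.9, β₂ = 0.999), default learning rate
2 × 10⁻³, batch size 64, at most 30 epochs with early stopping after 5 epochs
without validation-AUC improvement; the best-validation-epoch weights are
restored. Validation AUC and precision at 0.5 are recorded every epoch.
Training is deterministic given the configuration seed (batch order and
dropout masks derive from it).

`cnn_lstm` trains in two stages, following the DeeperBind lineage in which
the convolutional filters come from a trained DeepBind model: the
convolution and thresholds are first trained for ~250 optimizer steps
(rounded up to whole epochs, so the budget adapts to dataset size) under a
plain CNN/max-pool objective at learning rate 5 × 10⁻³ with L2 weight decay
10⁻⁴ on weight matrices, then transplanted into the full recurrent model,
which trains without weight decay. Both choices are empirical and
documented because they matter: without the warm start the recurrent model
never finds the motif (the conv gradient through the recurrence is
effectively zero at initialisation), and weight decay during the recurrent
phase destroys the warmed filters (Adam renders the decay term a full-size
update while the task gradient is still near zero). The warmup weight decay
is kept because it suppresses the random flanking columns of motif-bearing
filters, which otherwise blur the scoring margin.

## Calibration

Phase one samples 40 configurations independently per field (architecture,
filter count/length, pooling, LSTM width, head width, dropout uniform on
[0, 0.5], learning rate log-uniform on [10⁻⁴, 10⁻²], batch size) and trains
each with a truncated budget of 5 epochs. Phase two retrains the best
configuration 6 times at full budget under distinct derived seeds and keeps
the best finalist. The selection metric is validation AUC by default;
validation precision at 0.5 is recorded alongside and can be selected
instead (`selection_metric="precision"`; a run with no predicted positives
has undefined precision and can never be selected). A dry-run mode samples
and counts without training, for fast protocol checks. All trial and
finalist seeds derive from one root seed, so a calibration is reproducible
end to end.

## Evaluation

AUC is computed from midranks: `(Σ ranks of positives − n₊(n₊+1)/2)/(n₊ n₋)`,
which equals P(score₊ > score₋) + ½ P(tie) and equals the trapezoidal area
under the ROC curve. Ties are handled by midranks throughout. Precision at a
threshold with no predicted positives raises an error rather than reporting
zero — the quantity is undefined.

## Interpretation

Filter → PPM uses the alignment-and-count procedure: all windows (from the
positive training sequences) whose rectified activation exceeds 0.5 × the
filter's global maximum are stacked; base counts get a pseudocount of 0.5
per cell and columns are normalised. For the embedding model the counted
window is the full receptive field (filter length + k − 1 nt). PPM → PWM
uses base-2 logarithms against a uniform background with pseudocount 0.001.
Scanning is forward-strand only by default (the E-box is its own reverse
complement; the composite motif is not, so a `both_strands` flag exists and
defaults to off); `N` bases contribute the background-weighted mean column
entry; the best window's score and smallest-offset argmax are reported.

Filters are ranked by their most conserved column (peak per-column
information content, with total IC as tie-break) rather than total IC: a
broad low-complexity preference can accumulate more total IC across 24
columns than a sharp 6-nt motif, while peak conservation separates the two
cleanly. Filter identity (canonical vs non-canonical) is assigned by
greedily matching each filter's consensus against the target consensus
strings, enforcing distinct filters.

The comparison table counts, per target sequence, strict wins of one PWM's
best sliding score over the other's; exact ties are reported separately. The
score is the maximum over offsets (not a sum over windows), and PWM (not
PPM) scoring is used.

## Synthetic data

The generator emulates the study inputs with known ground truth:

* **Genome** — i.i.d. bases at a specified GC content (default 0.41,
  human-like). No repeats, no chromatin context, no methylation.
* **Peaks** — disjoint 301-nt neighbourhoods (midpoints jittered on a
  452-nt grid, ≥ 250 nt from chromosome ends; interval widths uniform in
  [150, 500]). Each peak receives, with probability `plant_probability`
  (default 1), a motif instance sampled column-wise from a ground-truth PPM,
  written into the genome within 150 nt of the midpoint. The canonical PPM
  is CACGTG with 0.9 on the consensus base per column; the non-canonical PPM
  is a 13-column composite — a (G/T)GGGCGG-style G/C-box, a uniform 1-nt
  spacer, then TGGGA — standing in for the SP1/MIZ-1 repressive signature
  (the spacing and orientation of the two parts within one composite is a
  fixture, not a biological claim). A `noncanonical_fraction` (default 0)
  routes that share of planted peaks to the composite motif.
* **Scores** — `score_scale × (instance log-likelihood − the PWM's maximum
  achievable log-likelihood) + Gaussian noise (σ = 1)`: a fidelity deficit,
  zero for a consensus-perfect instance, comparable across motifs of
  different widths, so top-k selection behaves like selecting the strongest
  binding events. Unplanted peaks are scored by their window's best
  canonical-PWM hit, so they rank low but not degenerately.
* **Target sets** — fresh background sequences of length 301 with one
  planted instance each: canonical for activation targets, composite for
  repression targets. The planted instance is the motif *consensus*: these
  sets emulate curated, experimentally validated targets, i.e. strong sites,
  in contrast to the fidelity spread of the peak training data. (With
  0.9-fidelity sampled instances instead, even the ground-truth PWM beats a
  shuffled control on only ~71% of activation sequences; with consensus
  instances ~96%, matching what one expects of validated sites.)

Every generator output is a pure function of the `SyntheticSpec`, including
its seed (one root seed, spawned per stage).

### What the synthetic surface does and does not show

Passing on this surface shows the pipeline's machinery is correct: windows
are where they should be, shuffles conserve what they must, training
recovers a planted motif and ranks held-out positives above negatives, the
filter calculus (PPM/PWM/consensus/scan) is exact against brute force, and
the two-motif discrimination is directionally recoverable from learned
filters. It does not show performance on real chromatin: real peaks carry
repeats, GC structure, cofactor motifs, and methylation effects that the
i.i.d. background lacks, and real "activation/repression" labels are far
noisier than consensus-planted targets.

## Study sizes used by the tests and the acceptance script

The motif-recovery study uses 6000 scored peaks on a 3-Mnt chromosome with
the top 3000 selected — the pipeline's own sort-by-score protocol; the
selection step matters, because sampled 0.9-fidelity instances without
selection cap even the ground-truth PWM near AUC 0.80, whereas the
high-score subset is consensus-enriched (ceiling ≈ 0.98). Training runs use
`cnn_lstm` with 12 epochs / patience 5; five fixed seeds for the recovery
check; the mixed-motif directionality run plants the two motifs 50/50 and
compares the learned PWMs on 53 activation and 21 repression targets.

## Known limitations

* The recurrent model needs its convolutional warm start; cold-started
  CNN-LSTM training on 301-nt windows is not expected to converge in this
  engine's budgets.
* Training quality at very small dataset sizes (a few hundred positives) is
  seed-sensitive; the calibration protocol, not a single run, is the
  intended interface there.
* Forward-strand scanning understates hits for non-palindromic motifs on
  the reverse strand unless `both_strands` is enabled.
* The NumPy engine is single-threaded-friendly but not GPU-capable; it is
  sized for desk-scale studies (thousands of 301-nt sequences), not
  genome-scale training.
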