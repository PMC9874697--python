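# Methods

`fcpredict` reimplements, end to end, an analysis pipeline for cultured
neuronal networks on high-density microelectrode arrays (HD-MEAs): from
spike-sorted baseline activity it extracts single-neuron features and
functional connectivity (FC), quantifies perturbation-induced firing-rate
fold changes, and asks whether graph neural networks (GNNs) that combine
node features with FC predict per-neuron responses better than models using
features alone. Because the original recordings are not required, a
synthetic-data module generates studies with the same statistical structure
and full ground truth; every downstream stage is validated against that
ground truth.

## Single-neuron features and quality control

Each sorted unit is reduced to seven features.

Waveform features come from the unit's electrical footprint (averaged
extracellular waveforms across electrodes). The footprint is high-pass
filtered (3rd-order Butterworth, 500 Hz, zero-phase) per electrode; the
electrode whose filtered trace has the largest peak-to-peak amplitude is
the peak electrode (tie → lowest index). The *unfiltered* waveform of that
electrode is upsampled ×2 by cubic spline (81 → 162 samples for 4 ms at
20 kHz) and z-scored. Landmarks: trough = global minimum, A = maximum
before the trough, B = maximum after it. Features: peak-to-trough duration,
trough-to-peak duration, AB ratio = (B−A)/(B+A), and the half width of the
trough at half its depth relative to the z-scored zero line (crossings
located by linear interpolation between samples). Amplitude scaling cancels
in all four features.

Firing-pattern features come from the inter-spike-interval (ISI) histogram
(1-ms bins, up to 100 ms) and the spike-train autocorrelogram (ACG, 1-ms
bins, ±50 ms, zero-lag self-pairs excluded, outer edge inclusive, bin b
covering [b, b+1) ms with the negative side mirrored). Burstiness is the
fraction of ISI entries below 6 ms (a `count_spikes` switch divides by
n+1 spikes instead of n intervals). The ACG's positive side is smoothed
with a 5-ms moving average, its refractory period estimated as the first
bin whose first difference (bin 0 to the peak bin) exceeds one standard
deviation of those differences (fallback 1 ms when no bin qualifies, e.g. a
strictly linear rise), and fitted with the clamped triple exponential

    ACG(x) = max(c·e^{−(x−t_r)/τ_decay} − d·e^{−(x−t_r)/τ_rise}
                 + h·e^{−(x−t_r)/τ_burst} + asymptote, 0).

τ_rise and τ_decay are the exported features.

**Fitting.** The model is linear in (c, d, h, asymptote) once the time
constants are fixed, so the fit uses variable projection: non-negative
least squares over a deterministic grid of (τ_decay, τ_rise, τ_burst)
triples, followed by a bounded trust-region polish of all seven parameters
from the best grid candidates. Residuals are weighted by the inverse bin
count — ACGs are count data with roughly multiplicative noise, and relative
weighting keeps the slow tail (which identifies τ_decay) from being
drowned out by the peak. Bins below the refractory period carry no
information and are excluded from the residuals. The r² gate (≥ 0.8 vs the
smoothed ACG over the fitted range) removes units whose ACG the model does
not describe.

**Identifiability.** Sums of overlapping exponentials over a 50-bin window
are classically ill-posed: when τ_burst and τ_decay are of similar scale,
parameter sets far from the truth fit noisy data *better* than the true
parameters, so no estimator can recover them. The package's recovery
protocol (`validation.acg_recovery_errors`) therefore draws from the regime
where the model is identifiable and which matches bursty-neuron ACG
scales — τ_decay ∈ [8, 20] ms (several decay constants inside the window),
τ_burst ∈ [2, 6] ms, τ_rise ∈ [0.5, 3] ms, modest burst amplitude, 1%
multiplicative noise — where the median relative error of τ_decay is ≈ 3%.
Because the c/τ_decay and h/τ_burst terms enter the model symmetrically,
fitted parameters are canonicalized to τ_decay ≥ τ_burst (an exact
symmetry of the curve) before being reported.

QC applies, in order: firing rate within [0.05, 30] Hz; refractory-period
violation ratio (ACG mass in ±2 ms over ±50 ms) ≤ 0.3; waveform exclusion
(total trough width > 1.5 ms OR AB ratio outside [−0.3, 0.6]; a
conjunctive switch exists); ACG-fit r² ≥ 0.8. Per-rule drop counts are
reported so order effects stay visible.

## Functional connectivity

**Undirected.** Pearson correlations (PCC) of 20-ms binned counts
(half-open bins, trailing partial bin dropped) and spike-time tiling
coefficients (STTC, dt = 10 ms; tiling windows merged and clipped to the
recording; a degenerate denominator contributes 0). Both are corrected with
ISI-shuffled surrogates: each unit gets 100 surrogate trains (ISIs
permuted, first spike kept), *both* members of a pair are shuffled, and
surrogates are paired by index; the pair's corrected weight is
raw − max(surrogate values), floored at 0, with non-positive raw values
set to 0 directly. Isolated nodes are dropped. On independent Poisson
trains this leaves <5% spurious edges.

**Directed.** Cross-correlograms (1-ms bins, ±25 ms) for every ordered
pair; the 25 positive-lag ("postsynaptic") bins are mean-subtracted and
the largest-|value| bin labels the pair excitatory (peak) or inhibitory
(trough; exact tie → excitatory). Pairs whose peak lag is too short for an
action potential at 400 mm/s (= 400 µm/ms) to cover the inter-electrode
distance are discarded, as are non-positive lags. Surviving pairs are
thresholded per label class at μ + γσ of |peak value| (strict inequality;
γ ∈ {0, 0.5, 1, 1.5, 2}), Dale's law removes each source's minority
out-relation (tie → keep excitatory), and only the largest *weakly*
connected component of the relation union is kept (message passing needs
contact, not strong connectivity). Peer statistics are computed per
network, not pooled across the study.

## Network characterization

Participation ratio: 20-ms binned trains are z-scored, and
PR = (Σλ)²/Σλ² over the eigenvalues of their correlation matrix;
PR/N ∈ [1/N, 1] measures effective dimensionality (constant binned trains
are dropped with a warning). Degree strength is the column sum of the FC
weight matrix. Average shortest path uses Dijkstra over 1/weight distances
for weighted graphs (zero weights are non-edges, unordered pairs) and hop
counts for directed graphs (ordered pairs); unreachable pairs are excluded
and counted. Networks with fewer than 30 nodes after pruning are excluded
from the prediction task.

## Fold-change targets

The two baseline recordings are pooled into one baseline window. The
network fold change is Δfch = max perturbation population rate / baseline
population rate. The per-neuron differential fold change is
Δfch′ = (max FR − baseline FR)/baseline FR, with the max taken over the
first two perturbation timepoints ("immediate" task; a `mean` statistic
switch exists because the two operationalizations both appear in practice)
or all timepoints ("maximum" task). The differential form keeps suppressed
neurons visible (Δfch′ ∈ [−1, ∞)).

## Prediction models and evaluation

Features and targets are standard-scaled per train/test split with the
scaler fitted on the training split only. Models: baseline (training-target
mean), ordinary least squares, random-forest regression with a seeded inner
grid search, and GNNs — GCN (symmetric-normalized convolution with
self-loops over the weighted undirected FC), GraphSAGE with mean or
elementwise-max pooling of edge-weighted neighbor features, and RGCN with
per-relation in-neighbor means over the binary excitatory/inhibitory
graphs. Up to three convolutions, each followed by dropout and ReLU; all
layer embeddings are concatenated into a linear head that outputs one
scalar per node. Training is full-batch Adam (default lr 1e-3 in the
config class; the validation benchmark uses 0.01 with 150 epochs at its
problem size) on node-wise MSE over all training networks jointly — an
inductive setup in which test graphs are never seen. The layers and
backpropagation are implemented directly in numpy; gradients are
hand-derived (max pooling routes gradients through stored argmax indices)
and verified against finite differences in the test suite. Empty
neighborhoods aggregate to the zero vector.

Evaluation is leave-one-network-out with chip exclusion: when a network is
held out, all networks from its chip leave the training set. Deterministic
models run once; stochastic models (forest, GNNs) run 30 seeded times and
per-neuron squared errors are averaged over runs before a two-sided paired
t-test against the baseline (α = 0.01; zero-variance differences make the
test undefined and are flagged, not called significant). Model selection,
when a grid with more than one candidate is supplied, uses inner
leave-one-network-out over the training networks; the shipped defaults use
single-candidate grids so the 30-run protocol stays tractable at desk
scale.

Ablations replace the FC graph (fully connected U[0,1] weights; edge
shuffle; degree-preserving double-edge swaps ≥ 10·|E|, weights traveling
with edges; spanning tree) or the node features (training-target average;
i.i.d. U[0,1]; per-column permutation). The spanning tree is computed on
*inverted* weights — a maximum-weight backbone, matching the intent of
testing whether a skeleton of the strongest edges suffices — with a
`mst_on="raw_weights"` switch for the literal reading. Feature ablations
are applied after scaling; the target-average ablation uses the unscaled
training-target mean.

## The synthetic-data generator

The generator's defaults define the study conditions: 4 chips × 3
sub-networks of 45–75 neurons, two 20-min baseline recordings plus seven
perturbation recordings, ~20% inhibitory neurons, connection probability
0.15, synaptic delays uniform in [2, 10] ms, Dale-consistent edge signs.
Tests and the reproduction script run reduced instances (typically 3
chips × 2 networks, 35–55 neurons, 4–5-min recordings) chosen so each
stage's statistics are stable at desk scale; the structure is unchanged.

**Spiking** is a Poisson-cluster (branching) construction equivalent to a
discrete-time conditional-intensity process: lognormal per-neuron
background rates (median 0.5 Hz); population bursts at 20/min, each adding
~3 × participation spikes per neuron with 25-ms jitter (the common drive
that makes normalized PR fall well below 0.5); excitatory edges spawn
offspring spikes at the edge delay + 0.5-ms jitter with probability
coupling × |gain| (subcriticality enforced via the spectral radius of the
offspring matrix); inhibitory edges delete target spikes within ±2 ms of
the delayed source spike; a 1.5-ms absolute refractory period is applied.
This yields Hz-scale rates, CCH peaks at the planted delays, and
low-dimensional population activity, at a fraction of the cost of stepping
a 1-ms intensity grid.

**Footprints** are parametric biphasic templates (Gaussian trough of
50–150 µV depth and 0.2–0.45 ms half-width, flanking peaks at 0.35–0.8 ms
offsets with amplitude ratios that keep the AB ratio inside the QC window)
decaying as exp(−distance/25 µm) over the nearest electrodes of a
17.5-µm-pitch lattice, plus Gaussian noise. The template geometry is stored
as ground truth for feature-recovery tests.

**Planted responses.** Each neuron's true Δfch′ is

    response_i = φ_i + neighbor_weight · max_j(w_ij · φ_j) + noise,

where φ_i is *linear* in the neuron's standardized true features
(dominated by the heavy-tailed lognormal burst-participation feature),
shifted so its `decrease_fraction` (default 9%) quantile is zero and scaled
to a mean of 5.9 — matching the skewed fold-change distributions seen under
GABA_A-antagonist disinhibition, where a small minority of neurons is
suppressed while the population rate rises. The neighborhood term is a
strongest-neighbor drive over the coupling graph. Three deliberate design
choices:

* φ linear in features — so the own-feature part of the signal is fully
  learnable by a linear model, and any advantage of a graph model is
  attributable to the neighborhood term, not to model capacity. (An earlier
  log-linear φ let the GNN beat feature-only models even with no planted
  neighborhood effect, purely through better extrapolation.)
* the score standardized over the *pooled study* — per-network
  standardization would encode network context that only graph models can
  read, again faking a graph advantage.
* a max (strongest-neighbor) aggregate rather than a mean — a mean over
  neighbors is nearly constant on dense graphs, so randomized dense graphs
  would carry it equally well; the max is specific to who the neighbors
  are, and is also the operation the best-performing model family
  (GraphSAGE-max) can represent, which is precisely what a planted-signal
  validation of that family requires.

Perturbation recordings are regenerated as Poisson trains at
(1 + response) × the measured combined-baseline rate, constant across
perturbation timepoints — this keeps the measured Δfch′ equal to the
planted value in expectation for increases and decreases alike (a
time-varying profile would make a suppressed neuron's max track the
profile's minimum instead). Consequences worth knowing: perturbation-window
trains lose burst correlation structure (FC is inferred from baseline only,
so nothing downstream consumes it), and every neuron peaks at the same
timepoint (the immediate/maximum task distinction exists but is less sharp
than in real data).

**What the synthetic studies do not emulate:** spike-sorting errors and
unit contamination; electrode drift; dose–response or time-constant
structure of the perturbation; distance-dependent connectivity; the
network-to-network diversity of real cultures. Passing the planted-signal
benchmark shows the pipeline recovers the kinds of structure it assumes —
not that real recordings contain that structure.

## Validation benchmarks

`validation.planted_signal_benchmark` runs the full protocol over ≥10
independent study seeds. With a planted neighborhood effect
(neighbor_weight = 1), GraphSAGE-max on the true coupling graph attains a
far lower averaged MSE than the baseline, linear and forest models and
every FC/feature ablation (paired t-tests across seeds); with
neighbor_weight = 0 its advantage over the best feature-only model
vanishes (the linear model, which the linear planted signal makes
near-optimal, wins). `validation.directed_edge_recovery` scores every
ordered pair by its velocity-filtered |CCH peak| and reports the ROC AUC
against the planted directed edges (≈ 0.85–0.95 on strongly coupled
networks). Numerical conventions used throughout: half-open bins with a
10⁻⁹-ms slack so exact bin edges land deterministically despite float
rounding; strict inequalities at peer thresholds; documented tie-breaks
(lowest electrode index, excitatory over inhibitory, lowest node id).

## Known limitations

* The ACG fit's time constants are only trustworthy in the identifiable
  regime described above; the r² gate does not protect against the
  τ_burst/τ_decay trade-off, which preserves fit quality while moving
  parameters.
* STTC surrogate correction is O(n² · n_surrogates) pair evaluations;
  for large networks PCC is the cheap default.
* The GNN implementation is full-batch and dense (O(n²) per graph) —
  appropriate for networks of tens to hundreds of neurons, not for
  thousands.
* The paper-scale MSE tables on real recordings are not reproducible here
  by construction; the benchmark reproduces the qualitative ordering on
  planted-signal studies.
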