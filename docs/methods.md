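# Methods

`probcell` detects cells in 3D fluorescence microscopy volumes as peaks of
regressed density maps, attaches a calibrated probability to each detection,
and propagates those probabilities into Monte Carlo spatial statistics.  This
note records the model, the tunable parameters, the numerical choices, and
what the synthetic benchmark does and does not establish.

## Density maps and peak detection

Annotations `C = {c_i}` (continuous positions in um) are turned into a
regression target on a 1 um isotropic grid.  Each annotation deposits an
isotropic Gaussian `G_sigma(s) = exp(-s^2 / 2 sigma^2) / (sigma sqrt(2 pi))`,
evaluated at voxel centers and truncated at `l_g = 16` um (inclusive; the
neglected tail at 16 um is below e^-8 of the peak for sigma = 4).  Kernels
from different annotations are compounded either by summation (`K_sum`) or by
the voxel-wise maximum (`K_max`).  `K_max` is the default: it keeps every
cell's peak at a fixed amplitude regardless of crowding, so one detection
threshold means the same thing everywhere.  Maps are stored peak-normalized
(divided by `G_sigma(0)`), making thresholds interpretable as fractions
(0..1) of an isolated kernel's peak; the raw scale is retained behind a flag.

Coordinate convention: voxel `(i, j, k)` covers the half-open cell
`[i, i+1) x [j, j+1) x [k, k+1)` um with center at `i + 0.5`; distances are
measured between voxel centers and continuous annotation positions.  Reported
detections sit at peak-voxel centers without sub-voxel interpolation — the
discretization error (at most sqrt(3)/2 um) is small against the 4 um
matching tolerance.

Non-maximum suppression (NMS) detects peaks: candidates are the local maxima
of the map within an exclusive ball of radius `min_distance` (default 4 um,
the average cell radius); candidates are visited in descending value — ties
broken toward the lexicographically smallest voxel index, making the result
independent of scan order — and accepted unless an accepted peak lies closer
than `min_distance`.  Candidates are local maxima rather than bare voxels:
greedy selection over all voxels would, at threshold 0, re-detect rings of
the Gaussian slope at radii 4, 8, 12 um around every isolated cell, which is
plainly not "a peak".  With a threshold `t`, only candidates strictly above
`t` are considered, and the result provably equals filtering the threshold-0
result by peak value (suppression is only ever exerted by higher-valued
accepted peaks), which the threshold-sweep code exploits.

## Tiling

Volumes are Gaussian-normalized (mean 0, SD 1, computed before resampling),
resampled to 1 um isotropic (trilinear for intensities, nearest for masks),
and zero-padded.  Input patches of side `l_in` produce output patches
`l_out = l_in - 2 * conv_margin`; the `M_peak` strategy crops a further
4-voxel margin per side (equal to the NMS radius) to form the core tile that
owns its detections.  Interior cores are adjacent; the last core per axis is
shifted inward so no core exceeds the sample, and where border cores overlap
the lexicographically smallest tile origin owns the point (half-open core
regions).  The 4 um peak margin is exactly what is needed: an output-patch
voxel at least 4 voxels from the patch border has its full NMS ball inside
the patch, so every spurious border local-maximum falls in the cropped
margin.  Default desk-scale geometry is `l_in = 40^3` with `conv_margin = 8`
(core 16^3); the planner accepts any geometry.

## Density regressors

Two regressors share a two-level residual U-Net backbone
(`C -> MP -> 2C -> MP -> 4C -> UP -> 2C -> UP -> C -> head`, 3x3x3 kernels,
2x2x2 max-pooling and nearest-neighbour upsampling, skip connections by
concatenation).  Each block applies two convolutions with rectified
activations and a residual shortcut; when the channel count changes at block
entry the shortcut uses a 1x1x1 projection.  `base_channels = 16` gives the
reference 16/32/64 widths; the desk-scale benchmark uses 4/8/16.
Convolutions are zero-padded, and the output is cropped by a configurable
`conv_margin` (default 8 voxels per side) before any loss or detection is
computed, discarding border voxels whose receptive field sticks out of the
patch.

The networks are implemented directly in NumPy (im2col convolutions + BLAS,
explicit backward passes, Adam); gradient correctness is verified against
finite differences in the test suite.

The deterministic network has one output head trained with the summed L2
loss.  The heteroscedastic ("Bayes") variant has two heads — density
`y_hat` and aleatoric variance `u_a` (rectified) — trained with

    L = sum_k (y_k - y_hat_k)^2 / u_a,k + 0.5 * log u_a,k .

Epistemic uncertainty comes from Monte Carlo dropout: per-channel spatial
dropout (rate 0.2) on every block output except the final layer stays active
at inference; `mc_samples` stochastic passes (default 50) are averaged for
`y_hat` and `u_a`, and the per-voxel SD of the density samples is `u_e`.
Dropout is per-channel rather than per-voxel: dropping feature maps is the
natural volumetric analogue of deleting convolutional units, and per-voxel
dropout on smooth density targets is nearly averaged away by the 3^3 kernels.

Numerical choices for the attenuated loss, which is singular at `u_a = 0`
and unstable when the variance head absorbs residuals before the mean head
has converged:

* the variance head is parametrized as `u_a = ReLU(raw) + 0.01`, bounding the
  `1/u_a` gradient amplification at 100x (the standalone loss function
  additionally clamps at 1e-6);
* training starts with a plain-L2 warm-up (default a quarter of the
  schedule) during which the variance head receives no gradient, and the
  optimizer is restarted with a 0.3x step size when the attenuated loss takes
  over.  Without these, desk-scale runs showed the mean drifting while
  `u_a` grew to compensate (validation F1 collapsing to 0);
* the variance head bias starts at 1.0 so the rectifier is initially active
  everywhere.

Training uses Adam (lr 1e-3, batch 4); model selection keeps the epoch with
the highest validation F1, computed by NMS-detecting predicted validation
patches over a threshold grid (0.1..0.9) and Hungarian-matching at 4 um
against the peaks of the target patches.  The best threshold found this way
also serves as the deterministic read-out threshold of that checkpoint.
Non-finite losses abort with a diagnostic.

## Proposal classification

Threshold-free detection runs NMS at threshold 0 (high recall, low
precision) and delegates the accept/reject decision to a supervised
classifier over summary statistics.  Features per proposal: for each map
(DM, and when present `u_a`, `u_e`) and each cubic window of side 4, 8, 16,
32 um centered on the proposal (clipped at borders): five percentiles
uniformly from the 1st to the 99th ({1, 25.5, 50, 74.5, 99}); the fraction
of voxels above five thresholds; and mean, SD, skewness, excess kurtosis
(the last two defined as 0 for constant windows).  Vector length is
`n_maps * 4 * 14` (56 DM-only, 168 with uncertainties).  Exceedance
thresholds default to five uniform fractions of each map's global maximum
over [0.1, 0.9]; fixed absolute ranges are available as a configuration
preset, since an absolute scale is only meaningful for a particular map
normalization.

Classifiers: a random forest (128 trees, Gini criterion) fit on the pooled
train+validation proposals, and an MLP (hidden layers 50/50/20/20, ReLU,
log-loss, Adam, up to 200 epochs with per-epoch checkpoint selection by
validation accuracy).  Training labels come from Hungarian-matching
proposals to annotations at 4 um (each annotation labels at most one
proposal positive).  Downstream, the positive set is `p >= 0.5` (inclusive).

## Evaluation

Predictions are matched one-to-one to annotations by minimizing total
Euclidean distance (rectangular assignment; the smaller set is fully
assigned).  Pairs within `t_match = 4` um (inclusive) are TP; a farther pair
contributes one FP and one FN, as do unmatched predictions and annotations.
Precision, recall, and F1 follow the usual formulas with 0/0 defined as 0.
Matching and scoring operate on whole reconstructed samples, not patches.

Calibration is scored over the union of annotations (reference probability
1) and false-positive predictions (reference 0), each paired with its
counterpart's predicted probability (0 when absent): the Brier score is the
mean squared difference and the NLL the mean negative log-likelihood
(natural log, probabilities clamped to [1e-12, 1 - 1e-12] so deterministic
p in {0, 1} predictions score finitely).  Deterministic detectors are scored
under the convention p = 1 for every prediction.  For probabilistic
detectors, detection counts use the `p >= 0.5` positives while calibration
uses all proposals with their probabilities — a missed cell whose best
proposal carries p = 0.3 is a detection FN but still earns partial
calibration credit.

## Spatial analysis

The empty-space distance (ESD) sample holds, for every tissue voxel outside
the structure, the Euclidean distance (exact distance transform) to the
nearest structure voxel; cells are read at their containing voxel, cells
inside the structure scoring 0 and cells outside the tissue excluded with a
warning.  CDFs are Gaussian-KDE estimates (Scott bandwidth) evaluated in
closed form on a shared grid from 0 to the maximum observed distance in
0.5 um steps, clipped to [0, 1]; an empirical CDF is available as an
alternative.  The probabilistic analysis draws T = 50 replicates — each
proposal included independently with its probability p — and resamples each
replicate's ESD as `w ~ Pois(N)` draws with replacement from the empirical
ESD pool; pointwise min/max of replicate CDFs form envelopes at significance
`alpha = 2 / (T + 1)` (0.0392 for T = 50, conventionally printed 0.04).
Summary statistics: cell density per mm^3 of tissue; the percentage of cells
at structure distance < 4 um (strict); and the percentage of background
voxels with ESD < 4 um as the volume-availability reference.

## Synthetic data

The generator emulates the statistical structure of a GFP-reporter stromal
volume: `n_cells` dart-thrown coordinates with a minimum pairwise spacing
(default 35 cells at >= 9 um in a 64^3 um field — denser than typical
stromal tissue so that desk-scale volumes contain enough positives to learn
from); Gaussian intensity blobs (sigma 3 um, i.e. an apparent cell radius
near 4 um) with per-cell amplitudes jittered +-30 %; additive Gaussian noise
of SD 0.15 by default (peak SNR ~5-9 across the amplitude range), optionally
depth-varying (0.5x to 1.5x along the first axis); and tubular structures as
randomly oriented cylinders (radius 5 um) inside a tissue mask that excludes
a 2-voxel shell.  The attraction scenario places cells over background
voxels with weight `exp(-d / strength)`, recovering uniform placement as
`strength -> inf`.

What the generator does not model: anisotropic PSFs, autofluorescence,
depth attenuation, aggregated or touching cells, irregular cell shapes, and
segmentation errors in the structure masks.  Passing the synthetic benchmark
therefore demonstrates that the pipeline's logic is sound — maps, tiling,
detection, calibration, and spatial testing compose correctly and the
probabilistic read-out is better calibrated than thresholding on this data —
not that the trained desk-scale weights transfer to real microscopy.

## Benchmark problem sizes

The end-to-end benchmark trains the heteroscedastic regressor at channel
widths 4/8/16 on 30 patches of 32^3 (10 from each of three 64^3 volumes,
35 cells each), validates on 6 patches of a fourth volume, 64 epochs
(24 warm-up), and evaluates on a fifth, held-out volume with 16 Monte Carlo
samples and single-tile inference (`l_in = 88`).  The RF classifier trains
on threshold-free proposals from the three non-test volumes.  The
ground-truth tiling benchmark uses 200 cells spaced >= 13 um in a 128^3
volume, sigma in {2, 4, 6} um, and thresholds 0..90 %.  The spatial
benchmark uses 3 tubes in a 96^3 scene, 300 cells, and T = 50 replicates.

## Known limitations

* The NumPy networks are memory-bandwidth-bound on CPU; the reference
  channel widths (16/32/64) train but are slow, so the defaults here are
  deliberate desk-scale reductions.
* The attenuated-loss stabilizers were chosen for robustness at small
  widths; at other widths the schedule may need adjustment (a 6-channel
  configuration was observed to still destabilize after warm-up).
* KDE-based CDFs smooth over the 0-distance atom of cells lying on the
  structure; at very short distances the empirical CDF is the sharper tool.
* Sub-voxel peak localization is not attempted; localization error is
  bounded by the voxel geometry.
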