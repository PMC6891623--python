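# Methods

## Model and procedure

SAIS treats carrier-induced interference as a *distribution shift between
two domains* measured by the same d-sensor array: a labeled source domain
(bacteria in culture solution) and an unlabeled target domain (the same
bacterial classes on a different carrier). Each domain is summarized by the
orthonormal basis of its top-D principal directions, `S_S` and `S_T`
(d × D, `S_Sᵀ S_S = S_Tᵀ S_T = I_D`), fitted by PCA on the standardized
feature matrix. The alignment map is the D × D matrix minimizing the
Bregman matrix divergence `F(M) = ‖S_S − S_T M‖²_F`; with orthonormal bases
the global minimizer is closed-form, `M* = S_Tᵀ S_S`, and needs no
regularization term. The full pipeline is:

1. standardize the source feature matrix; fit `S_S`; represent source
   samples as `X_S S_S`;
2. standardize the target feature matrix (its own statistics — this is part
   of the correction); fit `S_T`, optionally on a subset of n target
   samples per class; form `S_a = S_T M* = S_T S_Tᵀ S_S` and represent
   target samples as `X_T S_a`;
3. train the classifier on the projected source training set and predict
   the projected target.

Two exact identities are worth noting, and are enforced by tests:
`X_T S_a` depends on `S_T` only through the projector `S_T S_Tᵀ` (so
eigenvector sign or ordering of the target basis is irrelevant), and
`F(M*) = D − ‖S_Tᵀ S_S‖²_F`. A further identity sometimes claimed for this
construction — that `‖S_S − S_T M‖²_F` equals `‖S_Tᵀ S_S − M‖²_F` for all M
— does **not** hold in general for D < d (the component of the residual
outside the target subspace is dropped by `S_Tᵀ`); both objectives do share
the minimizer `M*`, which is the property this package verifies and relies
on.

## Classifier

The Extreme Learning Machine is a single-hidden-layer network with fixed
random hidden weights: `H = sigmoid(X Wᵀ + b)`, `W ~ U(−1, 1)`,
`b ~ U(0, 1)` from a seeded generator, output weights
`β = pinv(H) · one_hot(y)`, prediction by arg-max (ties to the lowest class
id). Defaults: L = 200 hidden nodes, sigmoid activation, SVD pseudo-inverse
with the default cutoff. Everything is deterministic given (seed, L, D).

## Preprocessing

Raw response cycles (d sensors × 840 points at 1 Hz; phases 180 s baseline,
180 s sample, 480 s purge) are smoothed with a Butterworth low-pass filter,
cutoff 0.1 Hz, order 2, applied forward–backward so the filter is zero-phase
and the location of the response maximum — the per-sensor feature — is not
delayed. The per-sample feature vector is the maximum of each sensor's
filtered series over the cycle; optional baseline correction subtracts the
baseline-phase mean first (off by default; the plain maximum is the
reference definition). Feature matrices are z-scored column-wise with the
sample (n−1) standard deviation; a per-sample (row) normalization variant
exists behind a flag but is not the default. Zero-variance columns raise an
error naming the offending sensor.

**Standardization and the baseline arms.** Within SAIS each domain is
standardized with its own statistics: the target scaler is fitted on all
available unlabeled target samples even when only a subset feeds the
subspace. The `none` and `pca_source` baseline arms instead standardize
incoming target data with the *source-fitted* scaler. This is deliberate:
it is the deployment situation those baselines model (a fielded instrument
applies its training pipeline to new data), and fitting the target domain's
own statistics is already a partial domain correction — per-sensor gain and
offset changes are exactly an affine map per column, which a per-domain
z-score would silently remove, crediting the baseline with correction it
does not perform.

## Subspace size and rank capping

D defaults to 25 (of d = 31). When the requested D exceeds the rank
achievable from the data used to fit either subspace — e.g. a 5-per-class
target subset (25 samples) supports at most rank 24 — both subspaces are
capped at the common achievable size with a warning rather than failing, so
the SAIS(n) sweep runs for every n. Eigenvector signs follow the
largest-entry-positive convention for determinism; classification results
are invariant to target-side sign choices (projector property).

The subset count n is interpreted per class: in simulations the subset is
drawn class-balanced using the evaluation labels purely as a sampling
design (the transform itself never sees them); in unlabeled deployment the
subset is simply the first n samples.

## Kennard–Stone splitting

The source domain is split ~2:1 into train and test by the classic
sequential max–min rule in Euclidean distance (first the maximum-distance
pair, then repeatedly the candidate farthest from the selected set; ties to
the lowest index), applied within each class so per-class proportions are
preserved. Per-class train counts use half-up rounding of
`train_fraction × n_class` guarded against float representation (0.7 × 65
counts as 45.5 and rounds to 46).

## Synthetic carrier-shift generator

No public dataset accompanies the culture/wound study design, so the
generator emulates its structure: C = 5 classes, d = 31 sensors, class
signatures `z_c` drawn standard-normal in an 8-dimensional latent space
with a minimum mutual distance of 3.0 enforced by rejection, a loading
matrix A (sensors × latent), and

    source sample:  A z_c + ε
    target sample:  G R (A z_c) + b + ε

with per-sensor gains `G = diag(U(0.5, 1.5))`, a rotation R interpolated
toward the identity (geodesic interpolation `expm(s · logm(Q))` of a Haar
rotation Q, default strength s = 0.3), a per-sensor background offset
`b ~ N(0, 1)`, and iid sensor noise `ε ~ N(0, 0.2²)`. Sample sizes default
to 60 source and 80 target samples per class, the order of the real
datasets the design mirrors (282 + 121 source, 401 target).

Loading entries are scaled `N(0, 0.8²/latent_dim)` so the per-sensor signal
standard deviation sits slightly *below* the unit background offset scale —
the interference-dominated regime that motivates the method in the first
place (the carrier background is comparable to or stronger than the
bacterial VOC signal). This family is exactly the assumption class of the
method: a linear, class-independent carrier map. Defaults are chosen once
as the package's study conditions and are not tuned per experiment.

What the generator does *not* emulate: sensor drift over time,
humidity/temperature coupling, nonlinear sensor saturation, heavy-tailed
within-class variation, or per-animal background variability. Passing tests
therefore demonstrate that the implementation realizes the method's
guarantees and recovers linear carrier shifts — not that SAIS handles every
distortion of real wound data.

Raw response cycles are generated as baseline level + first-order
exponential rise toward baseline + amplitude during the sample phase (time
constant 30 s, so the plateau is within 0.3% of baseline + amplitude by the
phase end) and exponential purge decay (60 s), with white noise; they exist
so the preprocessing chain can be exercised end to end.

## Evaluation harness

`run_experiment` runs, per seed: Kennard–Stone 2:1 split of the
standardized source per class; the `none` arm (ELM on standardized source,
target through the source scaler); the `pca_source` arm (both domains
projected on `S_S`); and the `sais` arm for each n in the sweep plus "all".
Accuracies are reported overall and per class (overall equals the
sample-weighted per-class mean by construction). All randomness — ELM
initialization and subset draws — derives from the experiment seed; two
identical calls give identical reports. Multi-seed summaries report mean
and standard deviation over 10 generator seeds by default.

With the default conditions the regime is: source test accuracy ~100%,
no-correction target accuracy ~30–50%, SAIS-aligned accuracy ~85%, and the
`pca_source` baseline ties with no correction rather than with SAIS. The
SAIS(n) sweep is nearly flat from n = 5 per class upward: with iid
within-class noise of 0.2 the target subspace is already well estimated
from 25 samples, so the accuracy-vs-n trend of noisier real data appears
here only as non-degradation (the trend check allows a 5-point band).

## Numerical choices and degenerate inputs

- PCA re-centers defensively even on z-scored input (a no-op there, but
  correct when the per-sample normalization variant is enabled).
- Effective rank uses `numpy.linalg.matrix_rank` on the centered matrix
  with the default tolerance; requesting D beyond it raises an error that
  reports the achievable maximum (direct `pca_subspace` calls) or caps with
  a warning (inside `sais_transform`).
- Filter preconditions: the cutoff must lie strictly inside (0, Nyquist);
  non-finite samples are rejected before filtering.
- z-scoring requires at least two observations and rejects zero-variance
  columns; the standardized flag on datasets is validated at construction
  to 1e-9.
- The ELM rejects single-class labels, L < 1, and fewer samples than
  classes; prediction ties break to the lowest class id via the sorted
  class-id table.
- Problem sizes in the shipped experiments (300 + 400 samples, 31 sensors,
  10 seeds) keep the full suite and the acceptance script in the order of
  seconds on one CPU.

## Known limitations

- The alignment model is strictly linear and class-independent; shifts that
  reorder which directions carry class information, or class-conditional
  carrier effects, are outside its guarantees (and outside the generator).
- SAIS with D close to d approaches a plain projection onto the source
  subspace: the projector `S_T S_Tᵀ` discards only d − D directions. The
  method's leverage comes from the standardization steps plus alignment at
  meaningful D; D ≥ rank collapses the distinction between arms.
- The ELM's least-squares fit is sensitive to its random initialization at
  small training sizes; single-seed accuracies carry a few points of
  initialization noise, which is why multi-seed summaries are the default
  reporting mode.
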