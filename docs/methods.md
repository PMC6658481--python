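# Methods

## Model

The map is a bounded `width x height` grid of hexagons in odd-row
horizontal-offset layout; distances between cells are exact hex-grid
step counts computed through cube coordinates. Neuron order is
row-major, and that order is the tie-break for every argmin/argmax in
the package (BMU ties, class-weight ties). The grid is deliberately
non-toroidal: edge neurons have fewer neighbours, which is what lets
class blocks anchor against map edges.

Each neuron holds a spectrum weight `w ∈ R^P` and a class weight
`c ∈ R^K`. BMU search uses the Euclidean distance between the input
spectrum and `w` only; `c` never influences matching. (The squared
distance is used internally for the argmin — a monotone transform — and
the reported distance is the true root.)

**Unsupervised round.** One presentation draws a sample uniformly at
random with replacement (an epoch-shuffled mode exists but is not the
default), finds the BMU, and updates *all* neurons:

    s_n = exp(-d(BMU,n)^2 / (2 σ(t)^2)) · α(t),
    w_n += s_n (i - w_n),    c_n += s_n (j - c_n).

Since `s_n ∈ [0,1]` and `j` is one-hot, each `c` entry stays in `[0,1]`
throughout this round and converges toward the fraction of local
activations belonging to each class — the class planes.

**SOMDI.** For class `k`, with `N_k = {n : argmax c_n = k}`:

    SOMDI_k = (1/|N_k|) Σ_{n∈N_k} c_{n,k} · w_n.

The `c_{n,k}` weighting damps the contribution of marginal neurons; an
unweighted mean over `N_k` is available via `compute_somdi(...,
weighted=False)`. A class owning no neurons yields a zero curve and is
flagged rather than raising. By default the SOMDI is computed from the
final (post-refinement) map, since that is the model actually used for
prediction; pass the round-1 map to inspect the unsupervised planes.
Peak reporting (`top_features`) uses strict single-channel local maxima
with no smoothing: the SOMDI is already an average over neurons, each
of which averages many spectra.

**Supervised round (the SKiNET refinement).** The update rule switches
to learning-vector-quantisation form: only the BMU changes, with a
small constant rate `α_lvq`; attraction when `argmax j = argmax c_BMU`,
otherwise sign-flipped repulsion on both `w` and `c`. The match branch
is arithmetically identical to a BMU-only unsupervised step, so a map
that already classifies its training stream correctly is only
consolidated. Prediction = argmax class weight of the BMU; evaluation
is a plain K×K confusion matrix (rows true, columns predicted).

## Parameter defaults and why

| parameter | default | rationale |
|---|---|---|
| map size | 16×16 | ~3 training spectra per neuron at the default study size; small data fits well on 8–12 per side |
| `T` (round 1) | 20 × n_train | presentations, not epochs; doubling it changes results marginally |
| `α0` | 0.5 | linear decay to exactly 0 at `t = T` |
| `σ0` | max(width, height)/2 | neighbourhood initially spans the map |
| `σ_min` | 0.5 | floor; at σ=0.5 the Gaussian at d=1 is ≈0.14, so late training is effectively BMU-local |
| σ decay | linear σ0 → σ_min over T | simplest monotone schedule; configurable |
| weight init | uniform, rescaled per channel to the training-data range | much faster settling on standardised spectra; raw [0,1) kept for strict reproduction (`init_from_data_range=False`) |
| `α_lvq` | 0.05 | a tenth of `α0`: the refinement is meant to be a fine perturbation, not a retraining |
| `T2` (round 2) | 5 × n_train | the round converges quickly; more steps mostly shuffle boundary neurons |
| `clamp_c` | on | repulsive updates can push `c` outside [0,1]; clamping keeps the argmax read-out on its natural scale. Switchable, since an unclamped map is equally valid mathematically |

Standardisation is per spectrum (each sample centred and scaled by its
*own* mean and population SD — the SNV convention; `ddof=1` switchable).
Test spectra are standardised with their own statistics too: the
transform is per-sample by construction, so no training statistics leak
into it. Zero-variance spectra raise rather than silently becoming
zeros.

Stratified partitioning allocates per-class test counts as
`floor(f·n_k)` plus remainders assigned by largest fractional part
(ties: larger class, then lower index); splits and 10-fold CV
(delegated to scikit-learn's `StratifiedKFold`, shuffled and seeded)
are exact set partitions. Class indices are always the lexicographic
order of class names, so one-hot encodings are stable across files and
runs.

All randomness flows from explicit integer seeds through
`numpy.random.Generator`; `skinet_train` spawns three independent
streams (init, round 1, round 2) from one seed. Maps serialise to JSON
using `repr` floats, which round-trip bit-exactly; the CSV reader uses
round-trip float parsing for the same reason.

## The synthetic data, and what passing tests do and do not show

The generator emulates the statistical regime of short-acquisition,
low-power tissue Raman spectra after instrument-side baseline
subtraction: 1015 channels over 550–1670 cm⁻¹, five classes, per
spectrum

    y = gain · (Σ_b A_b profile_b + quadratic baseline) + N(0, noise_sd²),

with Gaussian/Lorentzian lines of given FWHM and unit-peak-height
amplitude, log-normal amplitude jitter (σ=0.15), log-normal gain
(σ=0.25), quadratic baseline coefficients ~N(0, 0.15), and
`noise_sd = 0.35` against exclusive-band heights near 1.0 — headline
bands ≈3× the channel noise, deliberately low SNR. The default class
signatures are the characteristic tissue bands: cornea 938/1241 plus
the 854/858 proline doublet shared with vitreous; lens 1005; vitreous
832/1044/1049 (weak) with its strongest weight on the shared doublet;
retina 1658; optic nerve 1441/1297; three broad bands common to all
classes (1130, 1260, 1460) guarantee genuine spectral overlap. The
vitreous profile intentionally puts its largest weight on a *shared*
band, so its SOMDI maximum is expected to sit at 856 rather than on an
exclusive band — which is why the band-recovery check asks for 4 of 5
classes, not 5 of 5.

What the synthetic study does **not** capture: correlated (pink/shot)
noise, cosmic-ray spikes, wavenumber miscalibration, peak-shape
distortion, instrument response, and — most importantly — the
between-animal, between-scan covariance structure of real tissue maps.
Synthetic accuracies therefore validate the *mechanics* (the map
separates overlapping classes at low SNR, the SOMDI recovers the bands
that were planted, the LVQ round does not damage a good map); they are
not a claim about accuracy on any real instrument's data.

Default problem sizes used by the test suite and the acceptance script
— 200 spectra per class (1000 total), 16×16 map for classification,
12×12 for band recovery, 3–5 seeded replicates — are the package's
standard desk-scale study; a `full_scale=True` preset switches the
generator to 968 spectra per class for full-size runs.

## Numerical and design notes

* **BMU distance.** The matching criterion is the Euclidean distance
  between input and weight vector, `sqrt(Σ_p (i_p − w_p)²)` — the only
  definition under which matching depends on their difference.
* **Ties.** First-minimum (`argmin`) semantics everywhere, i.e.
  row-major for neurons and lowest-index for classes; engineered-tie
  tests pin this down.
* **Modal class.** A neuron's modal class requires a *strict* majority
  among the training hits; tied pluralities and zero-hit neurons are
  unlabelled (drawn white in map figures). Classification does not use
  the modal class — it reads argmax `c` — but both read-outs are
  reported by the acceptance script for comparison.
* **Benchmark harness.** Baselines are scikit-learn calls sharing one
  partition and one fold set: PCA+kNN, PCA+SVM(RBF), PCA+PLS-DA
  (PLS regression on one-hot targets, argmax decoding — the standard
  chemometrics construction) over a component grid, and an MLP on raw
  channels. Small hyper-parameter grids (k ∈ {1,3,5,7}, C ∈ {1,10,100})
  are tuned by the shared stratified CV on the training portion only.
  These defaults are this package's choices, tuned for a fair
  qualitative comparison, not a reproduction of any specific published
  configuration.
* **Degenerate inputs.** Zero-variance spectra, unlabelled samples in
  training, empty datasets, out-of-bounds coordinates and schedule
  steps all raise typed errors (`skinet.errors`); the CLI maps them to
  exit code 3.

## Known limitations

* Training is presentation-serial (the classic online algorithm); no
  batch-SOM mode. A 16×16 map over 1015 channels trains in seconds to
  tens of seconds at desk scale, so this has not been worth
  parallelising.
* Only one LVQ variant is implemented (BMU-only, constant rate). Window
  rules (LVQ2/3) and adaptive map sizing are out of scope.
* Maps do not support resuming round 2, only round 1 (`t_done`).
* The hit-map and prediction paths scan all neurons per sample; fine at
  these sizes, quadratic-feeling beyond ~10⁵ samples.
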