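# skinet

Self-organising Kohonen maps with class-index planes (SOMDI) and an
LVQ refinement round, for projecting, feature-extracting and classifying
noisy vibrational spectra — built around the regime of *in-vivo*-style
Raman measurements of eye tissue, where short acquisitions and low laser
power leave individual spectra heavily noise-dominated.

## Who this is for

Chemometricians and spectroscopists who want a single mathematical
object to do three jobs that are usually handled by separate methods
(PCA scores, PCA loadings, PLS-DA):

1. **Projection** — a 2-D hexagonal map on which similar spectra
   activate nearby neurons;
2. **Feature extraction** — per-class discriminant spectra (SOMDI)
   showing *which wavenumbers* drive the separation;
3. **Classification** — a supervised refinement of the same map that
   predicts the class of an unseen spectrum.

## The method

A self-organising map is a `width x height` hex grid of neurons. Each
neuron `n` carries a spectrum weight `w` (length `P`, the number of
wavenumber channels) and a class weight `c` (length `K`, the number of
classes); both start random.

**Round 1 (unsupervised).** Repeatedly draw a labelled training sample
`(i, j)` (`j` one-hot). The best matching unit (BMU) is the neuron
minimising the Euclidean distance `d = sqrt(sum_p (i_p - w_p)^2)` —
class weights play no role in matching. Every neuron is then pulled
toward the sample:

    s_n = exp(-dist(BMU, n)^2 / (2 sigma(t)^2)) * alpha(t)
    w_n <- w_n + s_n (i - w_n)
    c_n <- c_n + s_n (j - c_n)

with `alpha(t) = alpha0 (1 - t/T)` decaying linearly and the
neighbourhood radius `sigma(t)` shrinking linearly over the run. The
class weights converge toward the local class mix, defining per-class
"class planes" over the map.

**SOMDI.** For class `k`, over the neurons whose class weight identifies
them as `k` (`argmax c = k`):

    SOMDI_k = mean_n ( c_{n,k} * w_n )

— one curve per class over the wavenumber axis; peaks mark the Raman
bands that make the class recognisable.

**Round 2 (SKiNET = LVQ refinement).** Samples are drawn again, but only
the BMU is updated, with a small constant rate: attractively when the
BMU's class (argmax `c`) matches the sample's, repulsively (sign
flipped, on both `w` and `c`) when it does not. Prediction for a new
spectrum is the argmax class weight of its BMU.

Because the real tissue dataset behind this problem is not freely
redistributable, the package ships a synthetic generator
(`skinet.synth`) that plants the published band signatures of five eye
tissues (cornea, lens, vitreous humour, retina, optic nerve) on the
standard 550–1670 cm⁻¹ / 1015-channel axis, with low signal-to-noise,
per-spectrum gain scatter and residual baselines — so every stage is
testable end to end with known ground truth.

## Worked example

```python
from skinet import (default_eye_profile, generate_dataset, standardize_dataset,
                    stratified_partition, PartitionSpec, skinet_train,
                    evaluate, compute_somdi, top_features)

config = default_eye_profile(n_per_class=100, seed=0)
data = standardize_dataset(generate_dataset(config))       # SNV per spectrum
train, test = stratified_partition(data, PartitionSpec(test_fraction=0.25, seed=0))
som = skinet_train(train, 12, 12, seed=0)                  # SOM round + LVQ round
cm = evaluate(som, test)
print(f"test accuracy: {cm.accuracy:.3f}")
somdi = compute_somdi(som)
for k, name in enumerate(somdi.class_names):
    (wn, height), *_ = top_features(somdi, k, n_peaks=1)
    print(f"{name:12s} strongest SOMDI band at {wn:7.1f} cm^-1")
```

prints

```
test accuracy: 0.888
cornea       strongest SOMDI band at  1242.5 cm^-1
lens         strongest SOMDI band at  1005.1 cm^-1
optic_nerve  strongest SOMDI band at  1441.4 cm^-1
retina       strongest SOMDI band at  1659.0 cm^-1
vitreous     strongest SOMDI band at   856.0 cm^-1
```

The SOMDI maxima land on the planted class signatures: cornea's amide
III band (1241 cm⁻¹), the lens phenylalanine mode (1005), the optic
nerve lipid band (1441), the retina amide I band (1658), and — exactly
as intended by the profile — vitreous peaks on the 854/858 proline
doublet it shares with cornea rather than on one of its own weak
exclusive bands. At this deliberately small training size (75 spectra
per class) hold-out accuracy is 0.888; with 200 per class and a 16×16
map it reaches the low-to-mid 90s percent (see below). Retina, whose
single band sits under the heaviest spectral overlap, is the main
source of confusion — visible in `cm.to_frame()`.

The same pipeline is scriptable from the shell:

```sh
skinet simulate --seed 0 --out run/
skinet train    --data run/dataset.csv --seed 0 --out run/
skinet somdi    --model run/model.json --out run/
skinet evaluate --model run/model.json --data run/dataset.csv --out run/
skinet benchmark --data run/dataset.csv --seed 0 --out run/
```

Every command writes a `manifest.json` (parameters, seeds, SHA-256 of
all artifacts) so runs can be reproduced bit-exactly.

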