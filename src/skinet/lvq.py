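"""Round 2: LVQ refinement of a trained map, prediction and evaluation.

After unsupervised training has laid out the map, a second learning
round applies a learning-vector-quantisation rule: a training sample is
matched to its BMU exactly as before (spectrum weights only), and *only
the BMU* is updated. When the BMU's class weight already identifies the
sample's class, the update is the ordinary attractive step — identical
behaviour to the unsupervised rule — so a map that already classifies
its training data correctly is merely consolidated ("self-optimising").
When the classes disagree, the sign flips and both the spectrum weight
and the class weight of the BMU are pushed away:

    match    (argmax j == argmax c):  w += a*(i-w);  c += a*(j-c)
    mismatch (otherwise):             w -= a*(i-w);  c -= a*(j-c)

with a small constant rate ``a`` — a fine perturbation of an otherwise
settled map. Repulsive steps can drive class-weight entries outside
[0, 1]; by default they are clamped back so the argmax class read-out
stays on its natural scale.

Prediction assigns a spectrum the class of its BMU, read from the class
weights (argmax of c).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset import SpectralDataset, Spectrum
from .errors import DimensionError, FormatError, SkinetError
from .hexmap import SOMMap, TrainingSchedule, init_map
from .som import _as_vector, _bmu_index, train_som
from .somdi import neuron_class

__all__ = ["LVQSchedule", "lvq_step", "train_lvq", "skinet_train",
           "predict", "predict_dataset", "evaluate", "ConfusionMatrix"]


@dataclass(frozen=True)
class LVQSchedule:
    """Refinement-round parameters.

    ``alpha_lvq`` is constant over the round and should stay small
    relative to the round-1 initial rate; ``T2`` defaults to 5 passes
    worth of presentations (5 x n_train) when left as None.
    """

    T2: int | None = None
    alpha_lvq: float = 0.05
    clamp_c: bool = True

    def __post_init__(self) -> None:
        if self.T2 is not None and self.T2 < 0:
            raise FormatError("T2 must be >= 0")
        if not 0.0 < self.alpha_lvq < 1.0:
            raise FormatError("alpha_lvq must lie in (0, 1)")

    def resolve(self, n_train: int) -> "LVQSchedule":
        T2 = self.T2 if self.T2 is not None else 5 * n_train
        return LVQSchedule(T2=T2, alpha_lvq=self.alpha_lvq, clamp_c=self.clamp_c)


def lvq_step(som: SOMMap, sample: Spectrum, schedule: LVQSchedule,
             label: np.ndarray | None = None) -> int:
    """One supervised step in place; returns the BMU row-major index.

    Only the BMU changes; every other neuron is bit-identical after the
    call.
    """
    x = _as_vector(sample)
    if isinstance(sample, Spectrum) and label is None:
        label = sample.label
    if label is None:
        raise SkinetError("LVQ step needs a labelled sample")
    j = np.asarray(label, dtype=float)
    if x.size != som.P or j.size != som.K:
        raise DimensionError("sample/label lengths do not match map P/K")
    bmu, _ = _bmu_index(som, x)
    a = schedule.alpha_lvq
    sign = 1.0 if neuron_class(j) == neuron_class(som.C[bmu]) else -1.0
    som.W[bmu] += sign * a * (x - som.W[bmu])
    som.C[bmu] += sign * a * (j - som.C[bmu])
    if schedule.clamp_c:
        np.clip(som.C[bmu], 0.0, 1.0, out=som.C[bmu])
    return bmu


def train_lvq(dataset: SpectralDataset, som: SOMMap, schedule: LVQSchedule,
              seed: int | None = None,
              rng: np.random.Generator | None = None) -> SOMMap:
    """Run the refinement round: T2 seeded random draws, BMU-only updates."""
    if len(dataset) == 0:
        raise SkinetError("cannot refine on an empty dataset")
    if not dataset.fully_labelled:
        raise SkinetError("LVQ round requires every spectrum labelled")
    schedule = schedule.resolve(len(dataset))
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    J = dataset.onehot()
    n = len(dataset)
    a = schedule.alpha_lvq
    for _ in range(schedule.T2):
        k = int(rng.integers(n))
        x = dataset.X[k]
        diff = som.W - x
        d2 = np.einsum("np,np->n", diff, diff)
        bmu = int(np.argmin(d2))
        sign = 1.0 if int(np.argmax(J[k])) == int(np.argmax(som.C[bmu])) else -1.0
        som.W[bmu] -= sign * a * diff[bmu]
        som.C[bmu] += sign * a * (J[k] - som.C[bmu])
        if schedule.clamp_c:
            np.clip(som.C[bmu], 0.0, 1.0, out=som.C[bmu])
    return som


def skinet_train(
    dataset: SpectralDataset,
    width: int = 16,
    height: int = 16,
    schedule: TrainingSchedule | None = None,
    lvq_schedule: LVQSchedule | None = None,
    seed: int = 0,
    init_from_data_range: bool = True,
    sample_order: str = "replacement",
) -> SOMMap:
    """Full two-round training: unsupervised layout, then LVQ refinement.

    All randomness (weight init, round-1 draws, round-2 draws) derives
    from ``seed`` through independent spawned streams, so the final map
    is bit-reproducible.
    """
    if len(dataset) == 0:
        raise SkinetError("cannot train on an empty dataset")
    schedule = (schedule or TrainingSchedule()).resolve(len(dataset), width, height)
    lvq_schedule = (lvq_schedule or LVQSchedule()).resolve(len(dataset))
    ss_init, ss_r1, ss_r2 = np.random.SeedSequence(seed).spawn(3)
    init_seed = int(ss_init.generate_state(1)[0] % (2 ** 31))
    low = high = None
    if init_from_data_range:
        low = dataset.X.min(axis=0)
        high = dataset.X.max(axis=0)
    som = init_map(width, height, dataset.n_channels, dataset.n_classes,
                   init_seed, low=low, high=high, schedule=schedule)
    train_som(dataset, som, rng=np.random.default_rng(ss_r1),
              sample_order=sample_order)
    train_lvq(dataset, som, lvq_schedule, rng=np.random.default_rng(ss_r2))
    return som


def predict(som: SOMMap, spectrum: Spectrum | np.ndarray) -> int:
    """Class index of a spectrum: argmax class weight of its BMU."""
    x = _as_vector(spectrum)
    if x.size != som.P:
        raise DimensionError(f"spectrum has {x.size} channels, map expects {som.P}")
    bmu, _ = _bmu_index(som, x)
    return neuron_class(som.C[bmu])


def predict_dataset(som: SOMMap, dataset: SpectralDataset) -> np.ndarray:
    """Vector of predicted class indices for every row of a dataset."""
    if dataset.n_channels != som.P:
        raise DimensionError("dataset channel count does not match map")
    return np.array([predict(som, dataset.X[i]) for i in range(len(dataset))])


@dataclass
class ConfusionMatrix:
    """K x K counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: list[str]

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    @property
    def per_class_recall(self) -> np.ndarray:
        totals = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, np.diag(self.counts) / totals, np.nan)

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd
        return pd.DataFrame(self.counts, index=self.class_names,
                            columns=self.class_names)

    def metrics_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({
            "accuracy": self.accuracy,
            "per_class_recall": {name: float(r) for name, r in
                                 zip(self.class_names, self.per_class_recall)},
            "n_test": int(self.counts.sum()),
        })
        if path is not None:
            Path(path).write_text(text)
        return text


def evaluate(som: SOMMap, test: SpectralDataset) -> ConfusionMatrix:
    """Confusion matrix of SKiNET predictions on a labelled test set."""
    if len(test) == 0:
        raise SkinetError("cannot evaluate on an empty test set")
    if not test.fully_labelled:
        raise SkinetError("evaluation requires every test spectrum labelled")
    pred = predict_dataset(som, test)
    K = test.n_classes
    counts = np.zeros((K, K), dtype=int)
    np.add.at(counts, (test.labels, pred), 1)
    return ConfusionMatrix(counts, list(test.class_names))
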