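"""Round 1: unsupervised Kohonen training with joint spectrum/class updates.

Each presentation draws one labelled sample, finds the best matching unit
(BMU) by Euclidean distance between the input spectrum and every neuron's
spectrum weight ``w`` (class weights play no role in matching), then
updates *every* neuron's ``w`` and ``c`` toward the input and its one-hot
label, scaled by the product of the Gaussian neighbourhood around the BMU
and the linearly decaying learning rate:

    s_n = neighbourhood(BMU, n, t) * learning_rate(t)
    w_n <- w_n + s_n * (i - w_n)
    c_n <- c_n + s_n * (j - c_n)

Because s_n lies in [0, 1] and labels are one-hot, every class-weight
entry stays inside [0, 1] throughout this round, and a neuron's ``c``
drifts toward the empirical class mix of the samples it and its
neighbours attract — the class planes read out later by the SOMDI.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable

import numpy as np

from .dataset import SpectralDataset, Spectrum
from .errors import DimensionError, SkinetError
from .hexmap import HexCoord, SOMMap

__all__ = ["find_bmu", "som_update", "train_som", "quantization_error"]


def _as_vector(spectrum: Spectrum | np.ndarray) -> np.ndarray:
    if isinstance(spectrum, Spectrum):
        return spectrum.intensities
    return np.asarray(spectrum, dtype=float)


def _bmu_index(som: SOMMap, x: np.ndarray) -> tuple[int, float]:
    """Row-major index of the closest neuron and its squared distance.

    np.argmin returns the first minimum, which is exactly the row-major
    tie-break the map contract requires.
    """
    diff = som.W - x
    d2 = np.einsum("np,np->n", diff, diff)
    i = int(np.argmin(d2))
    return i, float(d2[i])


def find_bmu(som: SOMMap, spectrum: Spectrum | np.ndarray) -> tuple[HexCoord, float]:
    """Best matching unit and its Euclidean distance to the input."""
    x = _as_vector(spectrum)
    if x.size != som.P:
        raise DimensionError(f"spectrum has {x.size} channels, map expects {som.P}")
    i, d2 = _bmu_index(som, x)
    return som.coord(i), float(np.sqrt(d2))


def som_update(som: SOMMap, sample: Spectrum, t: int,
               label: np.ndarray | None = None) -> HexCoord:
    """Apply one unsupervised update in place; returns the BMU position.

    ``sample`` may be a labelled Spectrum, or a raw vector with ``label``
    given separately as a one-hot vector.
    """
    x = _as_vector(sample)
    if isinstance(sample, Spectrum) and label is None:
        label = sample.label
    if label is None:
        raise SkinetError("unsupervised update needs a labelled sample "
                          "(class weights are trained jointly)")
    j = np.asarray(label, dtype=float)
    if x.size != som.P or j.size != som.K:
        raise DimensionError("sample/label lengths do not match map P/K")
    bmu, _ = _bmu_index(som, x)
    _apply_neighbourhood_update(som, x, j, t, bmu)
    return som.coord(bmu)


def _apply_neighbourhood_update(som: SOMMap, x: np.ndarray, j: np.ndarray,
                                t: int, bmu: int) -> None:
    sched = som.schedule
    alpha = sched.alpha(t)
    sig = sched.sigma(t)
    d2 = som.squared_distance_matrix()[bmu]
    s = alpha * np.exp(-d2 / (2.0 * sig * sig))
    som.W += s[:, None] * (x - som.W)
    som.C += s[:, None] * (j - som.C)


def quantization_error(som: SOMMap, X: np.ndarray) -> float:
    """Mean BMU distance over a probe matrix — a convergence diagnostic."""
    X = np.atleast_2d(X)
    d = np.empty(X.shape[0])
    for i, x in enumerate(X):
        _, d2 = _bmu_index(som, x)
        d[i] = np.sqrt(d2)
    return float(d.mean())


def train_som(
    dataset: SpectralDataset,
    som: SOMMap,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    sample_order: str = "replacement",
    log_path: str | Path | None = None,
    log_every: int | None = None,
    probe_size: int = 64,
    callback: Callable[[int, SOMMap], None] | None = None,
) -> SOMMap:
    """Run round 1 for ``schedule.T`` presentations; trains in place.

    Samples are drawn uniformly with replacement (default) or in
    per-epoch shuffled order (``sample_order="epoch"``); both are
    bit-reproducible for a fixed seed. Resumes from ``som.t_done``.
    """
    if len(dataset) == 0:
        raise SkinetError("cannot train on an empty dataset")
    if not dataset.fully_labelled:
        raise SkinetError("round-1 training requires every spectrum labelled")
    if dataset.n_channels != som.P or dataset.n_classes != som.K:
        raise DimensionError("dataset P/K do not match map P/K")
    if som.schedule is None or som.schedule.T is None or som.schedule.sigma0 is None:
        raise SkinetError("map needs a resolved TrainingSchedule before training")
    if sample_order not in ("replacement", "epoch"):
        raise SkinetError(f"unknown sample_order {sample_order!r}")
    if rng is None:
        rng = np.random.default_rng(som.seed if seed is None else seed)

    X = dataset.X
    J = dataset.onehot()
    n = len(dataset)
    T = som.schedule.T
    d2mat = som.squared_distance_matrix()
    sched = som.schedule

    log_rows: list[tuple] = []
    probe = None
    if log_path is not None:
        if log_every is None:
            log_every = max(T // 20, 1)
        probe_idx = np.random.default_rng(0).choice(n, min(probe_size, n),
                                                    replace=False)
        probe = X[probe_idx]

    epoch_order = None
    for t in range(som.t_done, T):
        if sample_order == "epoch":
            pos = t % n
            if pos == 0:
                epoch_order = rng.permutation(n)
            k = int(epoch_order[pos])
        else:
            k = int(rng.integers(n))
        x = X[k]
        diff = som.W - x
        d2 = np.einsum("np,np->n", diff, diff)
        bmu = int(np.argmin(d2))
        alpha = sched.alpha(t)
        sig = sched.sigma(t)
        s = alpha * np.exp(-d2mat[bmu] / (2.0 * sig * sig))
        som.W -= s[:, None] * diff
        som.C += s[:, None] * (J[k] - som.C)
        if probe is not None and (t % log_every == 0 or t == T - 1):
            log_rows.append((t, quantization_error(som, probe), alpha, sig))
        if callback is not None:
            callback(t, som)
    som.t_done = T
    som.axis = dataset.axis.copy()
    som.class_names = list(dataset.class_names)

    if log_path is not None:
        header = "t\tquantization_error\tlearning_rate\tsigma\n"
        lines = [f"{t}\t{q!r}\t{a!r}\t{s!r}" for t, q, a, s in log_rows]
        Path(log_path).write_text(header + "\n".join(lines) + "\n")
    return som
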