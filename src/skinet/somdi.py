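"""Class identification of neurons, hit-map summaries and the SOMDI.

The self-organising map discriminant index (SOMDI) condenses a trained
map into one spectrum-length curve per class: for class k it averages the
spectrum weights of the neurons whose class weight identifies them as k,
each weighted by how strongly it does so,

    SOMDI_k = (1/|N_k|) * sum_{n in N_k} c_{n,k} * w_n,

where N_k = {neurons with argmax(c_n) == k}. High SOMDI intensity at a
wavenumber channel marks that channel as important for the class — the
feature-extraction readout of the map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import SpectralDataset
from .hexmap import SOMMap
from .som import _bmu_index

__all__ = ["neuron_class", "MapSummary", "map_summary", "SOMDIResult",
           "compute_somdi", "top_features"]

NO_CLASS = -1


def neuron_class(c: np.ndarray) -> int:
    """Class identified by a class-weight vector: argmax, ties to the
    lowest class index."""
    return int(np.argmax(np.asarray(c)))


@dataclass
class MapSummary:
    """Per-neuron hit histogram and class labels for a placed dataset.

    ``modal_class`` is the strict-majority training class per neuron and
    ``NO_CLASS`` (-1) for neurons with zero hits or a tied plurality —
    the neurons drawn white in a map figure. ``argmax_c_class`` is the
    label read from the class weights instead of the hits.
    """

    width: int
    height: int
    hits: np.ndarray                 # (n_neurons, K) int
    modal_class: np.ndarray          # (n_neurons,) int, NO_CLASS = none
    argmax_c_class: np.ndarray       # (n_neurons,) int
    class_names: list[str] = field(default_factory=list)

    @property
    def total_hits(self) -> int:
        return int(self.hits.sum())

    def purity(self) -> np.ndarray:
        """max hit fraction per neuron (nan where a neuron has no hits)."""
        tot = self.hits.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.hits.max(axis=1) / tot, np.nan)

    def to_json(self, path: str | Path | None = None) -> str:
        rows = []
        for i in range(self.hits.shape[0]):
            rows.append({
                "col": i % self.width,
                "row": i // self.width,
                "modal_class": None if self.modal_class[i] == NO_CLASS
                else int(self.modal_class[i]),
                "argmax_c_class": int(self.argmax_c_class[i]),
                "hits": {self.class_names[k] if self.class_names else str(k):
                         int(v) for k, v in enumerate(self.hits[i]) if v},
            })
        text = json.dumps({"width": self.width, "height": self.height,
                           "class_names": self.class_names, "neurons": rows})
        if path is not None:
            Path(path).write_text(text)
        return text


def map_summary(som: SOMMap, dataset: SpectralDataset) -> MapSummary:
    """Place every sample on its BMU and tally per-neuron class hits."""
    hits = np.zeros((som.n_neurons, som.K), dtype=int)
    for i in range(len(dataset)):
        bmu, _ = _bmu_index(som, dataset.X[i])
        k = dataset.labels[i]
        if k >= 0:
            hits[bmu, k] += 1
    modal = np.full(som.n_neurons, NO_CLASS, dtype=int)
    for n in range(som.n_neurons):
        row = hits[n]
        if row.sum() == 0:
            continue
        best = int(np.argmax(row))
        # strict majority among hits: a tied plurality stays unlabelled
        if np.count_nonzero(row == row[best]) == 1:
            modal[n] = best
    argmax_c = np.argmax(som.C, axis=1)
    return MapSummary(som.width, som.height, hits, modal, argmax_c,
                      list(dataset.class_names))


@dataclass
class SOMDIResult:
    """Per-class discriminant-index curves over the wavenumber axis."""

    values: np.ndarray               # (K, P)
    axis: np.ndarray                 # (P,)
    class_names: list[str]
    empty_classes: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"wavenumber": self.axis})
        for k, name in enumerate(self.class_names):
            df[name] = self.values[k]
        return df

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def compute_somdi(som: SOMMap, weighted: bool = True) -> SOMDIResult:
    """SOMDI curves from a trained map.

    ``weighted=True`` (default) weights each owned neuron's ``w`` by its
    class-weight entry c_{n,k}; ``weighted=False`` takes the plain mean
    over owned neurons. A class owning no neurons yields a zero curve and
    is flagged in ``empty_classes``.
    """
    owner = np.argmax(som.C, axis=1)
    K, P = som.K, som.P
    values = np.zeros((K, P))
    empty = []
    for k in range(K):
        members = np.nonzero(owner == k)[0]
        if members.size == 0:
            empty.append(k)
            continue
        if weighted:
            values[k] = (som.C[members, k][:, None] * som.W[members]).mean(axis=0)
        else:
            values[k] = som.W[members].mean(axis=0)
    axis = som.axis if som.axis is not None else np.arange(P, dtype=float)
    names = som.class_names if som.class_names else [str(k) for k in range(K)]
    return SOMDIResult(values, axis, list(names), empty)


def top_features(somdi: SOMDIResult, class_index: int,
                 n_peaks: int = 5) -> list[tuple[float, float]]:
    """The ``n_peaks`` highest strict local maxima of one class's curve,
    as (wavenumber, intensity) pairs sorted by descending intensity.

    A channel counts as a peak only if it strictly exceeds both
    neighbours; a flat or monotone curve therefore yields no peaks.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    v = somdi.values[class_index]
    interior = np.arange(1, v.size - 1)
    is_peak = (v[interior] > v[interior - 1]) & (v[interior] > v[interior + 1])
    peaks = interior[is_peak]
    order = peaks[np.argsort(-v[peaks], kind="stable")][:n_peaks]
    return [(float(somdi.axis[p]), float(v[p])) for p in order]
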