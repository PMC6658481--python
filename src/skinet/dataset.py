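"""Labelled spectral datasets: IO, per-spectrum standardisation, stratified splits.

A dataset is a matrix of spectra (rows) on one shared wavenumber axis
(columns), with an optional class label per row. Labels are stored as
integer indices into ``class_names``; class indexing is always the
lexicographic order of the class names so that one-hot encodings are
reproducible across runs and files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .errors import DegenerateInputError, DimensionError, FormatError, SkinetError

UNLABELLED = -1


@dataclass
class Spectrum:
    """One spectrum: intensities over a strictly increasing wavenumber axis.

    ``label``, when present, is a one-hot vector of length K (number of
    classes): exactly one entry is 1, the rest 0.
    """

    intensities: np.ndarray
    axis: np.ndarray
    label: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if self.intensities.shape != self.axis.shape or self.intensities.ndim != 1:
            raise DimensionError(
                f"intensities {self.intensities.shape} and axis {self.axis.shape} "
                "must be 1-D and equal length"
            )
        if self.axis.size > 1 and not np.all(np.diff(self.axis) > 0):
            raise FormatError("wavenumber axis must be strictly increasing")
        if self.label is not None:
            self.label = np.asarray(self.label, dtype=float)
            if not (np.count_nonzero(self.label == 1.0) == 1
                    and np.count_nonzero(self.label) == 1):
                raise FormatError("label must be one-hot (exactly one 1, rest 0)")

    @property
    def n_channels(self) -> int:
        return self.intensities.size

    @property
    def class_index(self) -> int | None:
        if self.label is None:
            return None
        return int(np.argmax(self.label))


class SpectralDataset:
    """Ordered collection of spectra sharing one axis, with class labels.

    Internally a dense ``(n, P)`` float matrix plus an integer label per
    row (``-1`` marks unlabelled rows). Class order is fixed at
    construction and must already be sorted lexicographically.
    """

    def __init__(
        self,
        intensities: np.ndarray,
        axis: np.ndarray,
        labels: np.ndarray | Sequence[int],
        class_names: Sequence[str],
        provenance: str = "",
    ) -> None:
        self.X = np.atleast_2d(np.asarray(intensities, dtype=float))
        self.axis = np.asarray(axis, dtype=float)
        self.labels = np.asarray(labels, dtype=int)
        self.class_names = list(class_names)
        self.provenance = provenance
        if self.X.shape[1] != self.axis.size:
            raise DimensionError("intensity matrix width must match axis length")
        if self.axis.size > 1 and not np.all(np.diff(self.axis) > 0):
            raise FormatError("wavenumber axis must be strictly increasing")
        if self.labels.shape != (self.X.shape[0],):
            raise DimensionError("one label per spectrum required (-1 = unlabelled)")
        if list(self.class_names) != sorted(self.class_names):
            raise FormatError("class_names must be lexicographically sorted")
        if self.labels.size and (self.labels.max(initial=UNLABELLED) >= self.n_classes
                                 or self.labels.min(initial=UNLABELLED) < UNLABELLED):
            raise FormatError("label index out of range")

    # -- basic queries -------------------------------------------------

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_channels(self) -> int:
        return self.axis.size

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def fully_labelled(self) -> bool:
        return bool(np.all(self.labels != UNLABELLED))

    def class_counts(self) -> np.ndarray:
        """Number of spectra per class, in class-index order."""
        return np.bincount(self.labels[self.labels != UNLABELLED],
                           minlength=self.n_classes)

    def onehot(self) -> np.ndarray:
        """(n, K) one-hot label matrix; unlabelled rows are all-zero."""
        out = np.zeros((len(self), self.n_classes))
        ok = self.labels != UNLABELLED
        out[np.nonzero(ok)[0], self.labels[ok]] = 1.0
        return out

    def spectrum(self, i: int) -> Spectrum:
        lab = None
        if self.labels[i] != UNLABELLED:
            lab = np.zeros(self.n_classes)
            lab[self.labels[i]] = 1.0
        return Spectrum(self.X[i].copy(), self.axis, lab)

    def __iter__(self) -> Iterator[Spectrum]:
        return (self.spectrum(i) for i in range(len(self)))

    def subset(self, indices: np.ndarray | Sequence[int]) -> "SpectralDataset":
        idx = np.asarray(indices, dtype=int)
        return SpectralDataset(self.X[idx], self.axis, self.labels[idx],
                               self.class_names, self.provenance)

    # -- IO ------------------------------------------------------------

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        names = [self.class_names[l] if l != UNLABELLED else "" for l in self.labels]
        df = pd.DataFrame(self.X, columns=[str(w) for w in self.axis])
        df.insert(0, label_column, names)
        return df

    def save(self, path: str | Path, label_column: str = "label") -> None:
        # repr() floats round-trip bit-exactly through float(); pandas'
        # to_csv formatting does not, so rows are written directly
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(label_column + ","
                     + ",".join(repr(float(w)) for w in self.axis) + "\n")
            for i in range(len(self)):
                name = ("" if self.labels[i] == UNLABELLED
                        else self.class_names[self.labels[i]])
                fh.write(name + ","
                         + ",".join(repr(float(v)) for v in self.X[i]) + "\n")


@dataclass(frozen=True)
class PartitionSpec:
    """Hold-out fraction, CV fold count and the seed that fixes both."""

    test_fraction: float = 0.25
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise FormatError("test_fraction must lie in (0, 1)")
        if self.n_folds < 1:
            raise FormatError("n_folds must be a positive integer")


def load_dataset(path: str | Path, label_column: str = "label") -> SpectralDataset:
    """Read a delimited-text dataset.

    The header row holds the label-column name plus numeric wavenumbers;
    each data row holds a class name (may be empty for unlabelled rows)
    followed by intensities. Class indices are assigned by sorting the
    unique class names lexicographically.
    """
    try:
        # round_trip parsing so save -> load reproduces bit-exact floats
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if label_column not in df.columns:
        raise KeyError(f"label column {label_column!r} not found in {path}")
    spectral_cols = [c for c in df.columns if c != label_column]
    try:
        axis = np.array([float(c) for c in spectral_cols])
    except ValueError as exc:
        raise FormatError(f"non-numeric wavenumber header in {path}: {exc}") from exc
    if axis.size > 1 and not np.all(np.diff(axis) > 0):
        raise FormatError(f"wavenumber header of {path} is not strictly increasing")
    raw = df[spectral_cols].to_numpy()
    if not np.issubdtype(raw.dtype, np.number):
        raise FormatError(f"non-numeric intensity values in {path}")
    if np.isnan(raw).any():
        raise FormatError(f"ragged rows or missing intensity values in {path}")
    names = df[label_column].fillna("").astype(str)
    class_names = sorted(set(names) - {""})
    lut = {name: k for k, name in enumerate(class_names)}
    labels = np.array([lut.get(n, UNLABELLED) for n in names])
    return SpectralDataset(raw.astype(float), axis, labels, class_names,
                           provenance=f"file:{path}")


def save_dataset(dataset: SpectralDataset, path: str | Path,
                 label_column: str = "label") -> None:
    dataset.save(path, label_column)


# -- standardisation ---------------------------------------------------


def standardize_array(X: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Row-wise standardisation: each spectrum to mean 0, SD 1.

    This is per-spectrum scaling (each sample uses its own statistics),
    the standard-normal-variate convention of vibrational spectroscopy.
    ``ddof=0`` uses the population SD; pass ``ddof=1`` for the sample SD.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] < 2:
        raise DegenerateInputError("standardisation needs at least 2 channels")
    sd = X.std(axis=1, ddof=ddof)
    if np.any(sd == 0):
        raise DegenerateInputError("zero-variance spectrum cannot be standardised")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def standardize(spectrum: Spectrum, ddof: int = 0) -> Spectrum:
    """Standardise one spectrum to mean 0, SD 1 (its own statistics)."""
    out = standardize_array(spectrum.intensities[None, :], ddof=ddof)[0]
    return Spectrum(out, spectrum.axis, spectrum.label)


def standardize_dataset(dataset: SpectralDataset, ddof: int = 0) -> SpectralDataset:
    return SpectralDataset(standardize_array(dataset.X, ddof=ddof), dataset.axis,
                           dataset.labels, dataset.class_names, dataset.provenance)


# -- stratified partitioning ------------------------------------------


def _allocate_test_counts(class_sizes: np.ndarray, fraction: float) -> np.ndarray:
    """Per-class test counts: floor(fraction*size), remainders to the
    classes with the largest fractional part (ties: larger class first,
    then lower class index)."""
    exact = fraction * class_sizes
    counts = np.floor(exact).astype(int)
    total = int(round(fraction * class_sizes.sum()))
    deficit = total - counts.sum()
    if deficit > 0:
        frac = exact - counts
        order = sorted(range(len(class_sizes)),
                       key=lambda k: (-frac[k], -class_sizes[k], k))
        for k in order[:deficit]:
            counts[k] += 1
    return counts


def stratified_partition(
    dataset: SpectralDataset, spec: PartitionSpec
) -> tuple[SpectralDataset, SpectralDataset]:
    """Random stratified hold-out split, reproducible under ``spec.seed``.

    Per-class test counts follow :func:`_allocate_test_counts`; the split
    is an exact partition (disjoint, exhaustive) of the dataset rows.
    """
    train_idx, test_idx = stratified_partition_indices(dataset, spec)
    return dataset.subset(train_idx), dataset.subset(test_idx)


def stratified_partition_indices(
    dataset: SpectralDataset, spec: PartitionSpec
) -> tuple[np.ndarray, np.ndarray]:
    if not dataset.fully_labelled:
        raise SkinetError("stratified partition requires every spectrum labelled")
    sizes = dataset.class_counts()
    if np.any(sizes * spec.test_fraction < 1):
        raise SkinetError("every class needs at least 1/test_fraction members")
    counts = _allocate_test_counts(sizes, spec.test_fraction)
    rng = np.random.default_rng(spec.seed)
    test_parts, train_parts = [], []
    for k in range(dataset.n_classes):
        idx = np.nonzero(dataset.labels == k)[0]
        rng.shuffle(idx)
        test_parts.append(idx[: counts[k]])
        train_parts.append(idx[counts[k]:])
    train_idx = np.sort(np.concatenate(train_parts))
    test_idx = np.sort(np.concatenate(test_parts))
    return train_idx, test_idx


def stratified_folds(
    dataset: SpectralDataset, spec: PartitionSpec
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold CV index pairs (train, validation).

    Every sample lands in exactly one validation set; per-fold class
    counts stay within +/-1 of proportional.
    """
    if not dataset.fully_labelled:
        raise SkinetError("stratified folds require every spectrum labelled")
    if int(dataset.class_counts().min()) < spec.n_folds:
        raise SkinetError(
            f"smallest class ({int(dataset.class_counts().min())}) is smaller "
            f"than n_folds ({spec.n_folds})"
        )
    skf = StratifiedKFold(n_splits=spec.n_folds, shuffle=True,
                          random_state=spec.seed)
    return [(tr, va) for tr, va in skf.split(dataset.X, dataset.labels)]
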