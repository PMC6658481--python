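"""Hexagonal map substrate: grid geometry, neuron weights, schedules.

The map is a bounded ``width x height`` grid of hexagons in odd-row
horizontal-offset layout (odd rows shifted half a cell to the right).
Neuron order is row-major — index ``row*width + col`` — and that order is
the tie-breaking rule everywhere an argmin/argmax can tie.

Each neuron carries two weight vectors:

* ``w`` — a spectrum weight of length P (number of wavenumber channels),
  which alone drives best-matching-unit search, and
* ``c`` — a class weight of length K (number of classes), updated jointly
  with ``w`` during training and read out as the neuron's class label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .errors import BoundsError, DimensionError, FormatError


@dataclass(frozen=True, order=True)
class HexCoord:
    """Grid position in odd-row offset coordinates (col, row >= 0)."""

    col: int
    row: int

    def to_cube(self) -> tuple[int, int, int]:
        x = self.col - ((self.row - (self.row & 1)) >> 1)
        z = self.row
        return x, -x - z, z

    @staticmethod
    def from_cube(x: int, y: int, z: int) -> "HexCoord":
        return HexCoord(col=x + ((z - (z & 1)) >> 1), row=z)


def grid_distance(a: HexCoord, b: HexCoord) -> int:
    """Hex-grid distance between two cells (number of steps)."""
    ax, ay, az = a.to_cube()
    bx, by, bz = b.to_cube()
    return max(abs(ax - bx), abs(ay - by), abs(az - bz))


@dataclass(frozen=True)
class TrainingSchedule:
    """Annealing schedule for the unsupervised round.

    The learning rate decays linearly from ``alpha0`` to 0 over ``T``
    presentations; the Gaussian neighbourhood radius decays linearly from
    ``sigma0`` (grid units) to ``sigma_min``. ``T`` and ``sigma0`` may be
    left as None and resolved against the training set / map dimensions.
    """

    T: int | None = None
    alpha0: float = 0.5
    sigma0: float | None = None
    sigma_min: float = 0.5

    def __post_init__(self) -> None:
        if self.T is not None and self.T <= 0:
            raise FormatError("T must be a positive integer")
        if not 0.0 < self.alpha0 <= 1.0:
            raise FormatError("alpha0 must lie in (0, 1]")
        if self.sigma0 is not None and self.sigma0 <= 0:
            raise FormatError("sigma0 must be > 0")
        if self.sigma_min <= 0:
            raise FormatError("sigma_min must be > 0")

    def resolve(self, n_train: int, width: int, height: int) -> "TrainingSchedule":
        """Fill unset fields: T = 20 x n_train, sigma0 = max(dims)/2."""
        T = self.T if self.T is not None else 20 * n_train
        sigma0 = self.sigma0 if self.sigma0 is not None else max(width, height) / 2.0
        return TrainingSchedule(T=T, alpha0=self.alpha0, sigma0=sigma0,
                                sigma_min=self.sigma_min)

    def _check_resolved(self) -> None:
        if self.T is None or self.sigma0 is None:
            raise FormatError("schedule not resolved: T and sigma0 must be set")

    def alpha(self, t: int) -> float:
        """Learning rate alpha0 * (1 - t/T); defined for 0 <= t <= T."""
        self._check_resolved()
        if not 0 <= t <= self.T:
            raise BoundsError(f"step t={t} outside [0, T={self.T}]")
        return self.alpha0 * (1.0 - t / self.T)

    def sigma(self, t: int) -> float:
        """Neighbourhood radius, linear sigma0 -> sigma_min, floored."""
        self._check_resolved()
        if not 0 <= t <= self.T:
            raise BoundsError(f"step t={t} outside [0, T={self.T}]")
        value = self.sigma0 + (self.sigma_min - self.sigma0) * (t / self.T)
        return max(value, self.sigma_min)


def learning_rate(t: int, schedule: TrainingSchedule) -> float:
    return schedule.alpha(t)


def neighborhood(bmu: HexCoord, n: HexCoord, t: int,
                 schedule: TrainingSchedule) -> float:
    """Gaussian neighbourhood exp(-d^2 / (2 sigma(t)^2)); 1 at the BMU."""
    d = grid_distance(bmu, n)
    s = schedule.sigma(t)
    return float(np.exp(-(d * d) / (2.0 * s * s)))


class SOMMap:
    """Bounded hexagonal self-organising map.

    Weights live in two dense arrays: ``W`` of shape (n_neurons, P) and
    ``C`` of shape (n_neurons, K), in row-major neuron order.
    """

    def __init__(
        self,
        width: int,
        height: int,
        W: np.ndarray,
        C: np.ndarray,
        seed: int,
        schedule: TrainingSchedule | None = None,
        t_done: int = 0,
        axis: np.ndarray | None = None,
        class_names: list[str] | None = None,
    ) -> None:
        if width <= 0 or height <= 0:
            raise DimensionError("map dimensions must be positive")
        self.width = int(width)
        self.height = int(height)
        self.W = np.asarray(W, dtype=float)
        self.C = np.asarray(C, dtype=float)
        n = self.width * self.height
        if self.W.shape[0] != n or self.C.shape[0] != n:
            raise DimensionError("need width*height rows in W and C")
        if not (np.all(np.isfinite(self.W)) and np.all(np.isfinite(self.C))):
            raise FormatError("neuron weights must be finite")
        self.seed = int(seed)
        self.schedule = schedule
        self.t_done = int(t_done)
        self.axis = None if axis is None else np.asarray(axis, dtype=float)
        self.class_names = class_names
        self._dist2: np.ndarray | None = None

    # -- geometry ------------------------------------------------------

    @property
    def n_neurons(self) -> int:
        return self.width * self.height

    @property
    def P(self) -> int:
        return self.W.shape[1]

    @property
    def K(self) -> int:
        return self.C.shape[1]

    def contains(self, coord: HexCoord) -> bool:
        return 0 <= coord.col < self.width and 0 <= coord.row < self.height

    def coord(self, index: int) -> HexCoord:
        if not 0 <= index < self.n_neurons:
            raise BoundsError(f"neuron index {index} out of range")
        return HexCoord(col=index % self.width, row=index // self.width)

    def index(self, coord: HexCoord) -> int:
        if not self.contains(coord):
            raise BoundsError(f"{coord} outside {self.width}x{self.height} grid")
        return coord.row * self.width + coord.col

    def grid_distance(self, a: HexCoord, b: HexCoord) -> int:
        """Bounds-checked hex distance between two on-map cells."""
        if not (self.contains(a) and self.contains(b)):
            raise BoundsError(f"{a} or {b} outside {self.width}x{self.height} grid")
        return grid_distance(a, b)

    def squared_distance_matrix(self) -> np.ndarray:
        """(n, n) matrix of squared grid distances, cached."""
        if self._dist2 is None:
            coords = [self.coord(i) for i in range(self.n_neurons)]
            d = np.empty((self.n_neurons, self.n_neurons))
            for i, a in enumerate(coords):
                for j, b in enumerate(coords):
                    d[i, j] = grid_distance(a, b)
            self._dist2 = d * d
        return self._dist2

    # -- lifecycle -----------------------------------------------------

    def copy(self) -> "SOMMap":
        m = SOMMap(self.width, self.height, self.W.copy(), self.C.copy(),
                   self.seed, self.schedule, self.t_done,
                   None if self.axis is None else self.axis.copy(),
                   None if self.class_names is None else list(self.class_names))
        m._dist2 = self._dist2
        return m

    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "height": self.height,
            "P": self.P,
            "K": self.K,
            "seed": self.seed,
            "t_done": self.t_done,
            "schedule": None if self.schedule is None else asdict(self.schedule),
            "axis": None if self.axis is None else self.axis.tolist(),
            "class_names": self.class_names,
            "W": self.W.tolist(),
            "C": self.C.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SOMMap":
        sched = None
        if d.get("schedule") is not None:
            sched = TrainingSchedule(**d["schedule"])
        return cls(d["width"], d["height"], np.array(d["W"], dtype=float),
                   np.array(d["C"], dtype=float), d["seed"], sched,
                   d.get("t_done", 0),
                   None if d.get("axis") is None else np.array(d["axis"]),
                   d.get("class_names"))

    def save(self, path: str | Path) -> None:
        """Serialise to JSON; float repr round-trips bit-exactly."""
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "SOMMap":
        try:
            return cls.from_dict(json.loads(Path(path).read_text()))
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise FormatError(f"cannot read map artifact {path}: {exc}") from exc


def init_map(
    width: int,
    height: int,
    P: int,
    K: int,
    seed: int,
    low: np.ndarray | float | None = None,
    high: np.ndarray | float | None = None,
    schedule: TrainingSchedule | None = None,
) -> SOMMap:
    """Random map initialisation, reproducible under ``seed``.

    ``w`` entries are i.i.d. uniform on [0, 1); when ``low``/``high``
    per-channel bounds are given, each channel is rescaled into that range
    (the usual data-range initialisation for standardised spectra).
    ``c`` entries are i.i.d. uniform on [0, 1).
    """
    if min(width, height, P, K) <= 0:
        raise DimensionError("all map dimensions must be positive")
    rng = np.random.default_rng(seed)
    W = rng.random((width * height, P))
    if low is not None or high is not None:
        lo = np.zeros(P) if low is None else np.broadcast_to(np.asarray(low, float), (P,))
        hi = np.ones(P) if high is None else np.broadcast_to(np.asarray(high, float), (P,))
        W = lo + W * (hi - lo)
    C = rng.random((width * height, K))
    return SOMMap(width, height, W, C, seed, schedule)
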