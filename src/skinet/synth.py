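"""Synthetic Raman-like spectra with known class structure.

The generator emulates the statistical character of low-power,
short-acquisition tissue Raman measurements: a handful of vibrational
bands per class (some exclusive to a class, some shared between classes,
some common to all tissue), large spectrum-to-spectrum intensity
scatter, a smooth residual baseline and strong additive channel noise.
Because every band position is planted, downstream feature extraction
can be tested for exact recovery.

Per spectrum the model is

    y(x) = gain * ( sum_b A_b * profile_b(x) + baseline(x) ) + noise(x)

* ``profile_b`` — Gaussian or Lorentzian line of given FWHM, unit peak
  height, so ``amplitude`` is the band's mean peak height;
* ``A_b`` — log-normal per-spectrum jitter around the mean amplitude
  (biological intensity scatter);
* ``baseline`` — random quadratic with small coefficients (the residue
  left after instrument-side baseline subtraction);
* ``gain`` — log-normal per-spectrum multiplicative scatter;
* ``noise`` — i.i.d. Gaussian per channel (detector-dominated regime).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .dataset import SpectralDataset, Spectrum
from .errors import FormatError

__all__ = ["BandSpec", "ClassProfile", "SyntheticConfig", "render_spectrum",
           "generate_dataset", "default_eye_profile"]


@dataclass(frozen=True)
class BandSpec:
    """One vibrational band: centre (cm^-1), FWHM (cm^-1), mean peak
    height, log-normal jitter sigma, and line shape."""

    centre: float
    width: float = 10.0
    amplitude: float = 1.0
    amp_sigma: float = 0.15
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise FormatError("band width must be > 0")
        if self.amplitude <= 0:
            raise FormatError("band amplitude mean must be > 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise FormatError(f"unknown band shape {self.shape!r}")

    def profile(self, axis: np.ndarray) -> np.ndarray:
        """Unit-peak-height line profile on the given axis."""
        u = (axis - self.centre) / self.width
        if self.shape == "gaussian":
            return np.exp(-4.0 * np.log(2.0) * u * u)
        return 1.0 / (1.0 + 4.0 * u * u)


@dataclass(frozen=True)
class ClassProfile:
    """Band signature of one class: exclusive plus shared bands."""

    name: str
    exclusive: tuple[BandSpec, ...] = ()
    shared: tuple[BandSpec, ...] = ()

    @property
    def bands(self) -> tuple[BandSpec, ...]:
        return self.exclusive + self.shared


@dataclass(frozen=True)
class SyntheticConfig:
    """Full recipe for a labelled synthetic dataset.

    The default axis matches the fingerprint window of the target
    application: 1015 channels spanning 550-1670 cm^-1.
    """

    classes: tuple[ClassProfile, ...]
    axis_start: float = 550.0
    axis_stop: float = 1670.0
    n_channels: int = 1015
    n_per_class: int = 200
    noise_sd: float = 0.35
    baseline_scale: float = 0.15
    gain_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise FormatError("n_per_class must be >= 1")
        if self.noise_sd < 0:
            raise FormatError("noise_sd must be >= 0")
        if self.n_channels < 2 or self.axis_stop <= self.axis_start:
            raise FormatError("axis must have >= 2 channels, stop > start")
        for cp in self.classes:
            for band in cp.bands:
                if not self.axis_start <= band.centre <= self.axis_stop:
                    raise FormatError(
                        f"band centre {band.centre} of class {cp.name!r} "
                        f"outside axis [{self.axis_start}, {self.axis_stop}]")

    def axis(self) -> np.ndarray:
        return np.linspace(self.axis_start, self.axis_stop, self.n_channels)

    def class_names(self) -> list[str]:
        return [c.name for c in self.classes]

    def ground_truth(self) -> dict:
        """Planted band table keyed by class name, for recovery tests."""
        return {
            cp.name: {
                "exclusive": [asdict(b) for b in cp.exclusive],
                "shared": [asdict(b) for b in cp.shared],
            }
            for cp in self.classes
        }

    def save_truth(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.ground_truth(), indent=1))


def render_spectrum(bands: tuple[BandSpec, ...] | list[BandSpec],
                    config: SyntheticConfig,
                    rng: np.random.Generator) -> Spectrum:
    """Draw one raw (unstandardised, unlabelled) spectrum."""
    axis = config.axis()
    y = np.zeros_like(axis)
    for band in bands:
        amp = band.amplitude
        if band.amp_sigma > 0:
            amp *= rng.lognormal(mean=0.0, sigma=band.amp_sigma)
        y += amp * band.profile(axis)
    if config.baseline_scale > 0:
        u = np.linspace(-1.0, 1.0, axis.size)
        coeffs = rng.normal(0.0, config.baseline_scale, size=3)
        y += coeffs[0] + coeffs[1] * u + coeffs[2] * u * u
    if config.gain_sigma > 0:
        y *= rng.lognormal(mean=0.0, sigma=config.gain_sigma)
    if config.noise_sd > 0:
        y += rng.normal(0.0, config.noise_sd, size=axis.size)
    return Spectrum(y, axis)


def generate_dataset(config: SyntheticConfig) -> SpectralDataset:
    """Labelled dataset of ``n_per_class`` spectra per class.

    Class indexing follows the lexicographic class-name order (the same
    convention the file loader uses), regardless of the order profiles
    appear in the config. Bit-reproducible under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    axis = config.axis()
    names = sorted(config.class_names())
    if len(set(names)) != len(names):
        raise FormatError("class names must be unique")
    by_name = {c.name: c for c in config.classes}
    X = np.empty((config.n_per_class * len(names), axis.size))
    labels = np.empty(X.shape[0], dtype=int)
    row = 0
    for k, name in enumerate(names):
        for _ in range(config.n_per_class):
            X[row] = render_spectrum(by_name[name].bands, config, rng).intensities
            labels[row] = k
            row += 1
    return SpectralDataset(X, axis, labels, names,
                           provenance=f"synthetic:seed={config.seed}")


def default_eye_profile(
    n_per_class: int = 200,
    noise_sd: float = 0.35,
    seed: int = 0,
    full_scale: bool = False,
) -> SyntheticConfig:
    """Five-class anatomical-eye-tissue profile.

    Band signatures follow the characteristic tissue assignments:
    cornea — collagen backbone / amide III (938, 1241 cm^-1) plus the
    proline doublet (854, 858) shared with vitreous humour; lens — the
    very strong phenylalanine ring mode (1005); vitreous humour — weak
    distinct bands (832, 1044, 1049) with its strongest weight on the
    shared 854/858 doublet; retina — amide I alpha-helix (1658); optic
    nerve — lipid CH2 modes (1441, 1297). Three broad bands common to
    all classes (1130, 1260, 1460) keep the classes spectrally
    overlapping rather than trivially separable.

    Exclusive-band peak heights sit near 1.0 against the default noise
    SD of 0.35, i.e. headline bands are roughly 3x the channel noise —
    deliberately low signal-to-noise. ``full_scale=True`` switches to
    968 spectra per class (the 4840-spectrum regime).
    """
    common = (
        BandSpec(1130.0, width=35.0, amplitude=0.40),
        BandSpec(1260.0, width=45.0, amplitude=0.45),
        BandSpec(1460.0, width=30.0, amplitude=0.45),
    )
    proline_doublet = (BandSpec(854.0, width=10.0, amplitude=0.55),
                       BandSpec(858.0, width=10.0, amplitude=0.50))
    proline_doublet_strong = (BandSpec(854.0, width=10.0, amplitude=0.90),
                              BandSpec(858.0, width=10.0, amplitude=0.85))
    classes = (
        ClassProfile(
            "cornea",
            exclusive=(BandSpec(938.0, width=12.0, amplitude=1.0),
                       BandSpec(1241.0, width=16.0, amplitude=0.9)),
            shared=proline_doublet + common,
        ),
        ClassProfile(
            "lens",
            exclusive=(BandSpec(1005.0, width=8.0, amplitude=1.2),),
            shared=common,
        ),
        ClassProfile(
            "vitreous",
            exclusive=(BandSpec(832.0, width=9.0, amplitude=0.65),
                       BandSpec(1044.0, width=9.0, amplitude=0.60),
                       BandSpec(1049.0, width=9.0, amplitude=0.60)),
            shared=proline_doublet_strong + common,
        ),
        ClassProfile(
            "retina",
            exclusive=(BandSpec(1658.0, width=14.0, amplitude=1.0),),
            shared=common,
        ),
        ClassProfile(
            "optic_nerve",
            exclusive=(BandSpec(1441.0, width=13.0, amplitude=1.0),
                       BandSpec(1297.0, width=12.0, amplitude=0.85)),
            shared=common,
        ),
    )
    return SyntheticConfig(
        classes=classes,
        n_per_class=968 if full_scale else n_per_class,
        noise_sd=noise_sd,
        seed=seed,
    )
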