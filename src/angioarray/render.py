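"""Render ground-truth cohorts into dual-exposure membrane images.

The forward model of one chemiluminescent membrane is deliberately
simple: each spotted disk emits a noiseless intensity

    I_spot = min(cap, gain(exposure) * level + background_mean)

on top of a flat background, reference spots carry a fixed known
concentration, additive Gaussian pixel noise is applied last and the
result is clipped to ``[0, cap]``.  The saturation cap (default 110
arbitrary units) reproduces the plateau seen on overexposed films: any
two levels whose noiseless signal exceeds the cap render identically.
Images are produced pre-inverted (signal bright on dark background), so
the densitometry inversion step is a no-op toggle for synthetic data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image as PILImage

from .errors import ParameterError
from .layout import ArrayLayout

__all__ = [
    "EXPOSURES",
    "RenderConfig",
    "MembraneImage",
    "render_membrane",
    "write_image",
    "read_image",
]

#: canonical exposure labels: 3-minute and 30-minute film exposures
EXPOSURES = ("short_3min", "long_30min")
_EXPOSURE_ALIASES = {
    "short": "short_3min",
    "short_3min": "short_3min",
    "long": "long_30min",
    "long_30min": "long_30min",
}


def canonical_exposure(label: str) -> str:
    try:
        return _EXPOSURE_ALIASES[label]
    except KeyError:
        raise ParameterError(f"unknown exposure label {label!r}; expected one of {EXPOSURES}") from None


@dataclass(frozen=True)
class RenderConfig:
    """Physical parameters of the synthetic film/scan.

    gain_short, gain_long
        intensity units per concentration unit at the 3 and 30 minute
        exposures; gain_long must exceed gain_short.
    background_mean, noise_sd
        flat background level and additive pixel noise, intensity units.
    saturation_cap
        maximum recordable pixel intensity (arbitrary units).
    reference_concentration
        known concentration of the six positive reference spots; must be
        sub-saturated even at the long exposure, mirroring the choice of
        exposure times short enough to keep reference spots quantifiable.
    """

    gain_short: float = 1.0
    gain_long: float = 10.0
    background_mean: float = 5.0
    noise_sd: float = 1.0
    saturation_cap: float = 110.0
    reference_concentration: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.gain_short < self.gain_long):
            raise ParameterError("need 0 < gain_short < gain_long")
        if not (self.saturation_cap > self.background_mean >= 0):
            raise ParameterError("need saturation_cap > background_mean >= 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        ref_peak = self.gain_long * self.reference_concentration + self.background_mean
        if ref_peak >= self.saturation_cap:
            raise ParameterError(
                f"reference spots would saturate at the long exposure "
                f"({ref_peak} >= cap {self.saturation_cap})"
            )

    def gain(self, exposure: str) -> float:
        return self.gain_short if canonical_exposure(exposure) == "short_3min" else self.gain_long


@dataclass
class MembraneImage:
    """A capped-intensity pixel raster plus acquisition metadata."""

    pixels: np.ndarray  # float64, shape = layout.membrane_shape
    patient: str
    timepoint: str  # BL | SOM | EOT
    exposure: str  # short_3min | long_30min
    saturation_cap: float
    layout: ArrayLayout | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.patient or not self.timepoint:
            raise ParameterError("patient and timepoint metadata must be non-empty")
        self.exposure = canonical_exposure(self.exposure)


def _disk_indices(shape: tuple[int, int], center: tuple[float, float], radius: float):
    """Integer pixel coordinates whose centres lie within the disk."""
    cr, cc = center
    r0 = max(int(np.floor(cr - radius)), 0)
    r1 = min(int(np.ceil(cr + radius)), shape[0] - 1)
    c0 = max(int(np.floor(cc - radius)), 0)
    c1 = min(int(np.ceil(cc + radius)), shape[1] - 1)
    rr, cc_ = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    mask = (rr - cr) ** 2 + (cc_ - cc) ** 2 <= radius**2
    return rr[mask], cc_[mask]


def render_membrane(
    truth,
    patient: str,
    timepoint: str,
    exposure: str,
    layout: ArrayLayout,
    config: RenderConfig,
    rng: np.random.Generator | None = None,
) -> MembraneImage:
    """Render one patient x time point x exposure membrane.

    ``truth`` is a :class:`~angioarray.simulate.CohortTruth`.  With
    ``rng=None`` a deterministic per-membrane stream is derived from
    ``config.seed`` and the membrane's identity, so re-rendering the
    same membrane reproduces the same pixels.
    """
    exposure = canonical_exposure(exposure)
    gain = config.gain(exposure)
    cap = config.saturation_cap
    img = np.full(layout.membrane_shape, config.background_mean, dtype=float)
    for spot in layout.spots:
        if spot.role == "reference":
            level = config.reference_concentration
        else:
            level = truth.level(patient, spot.analyte_index, timepoint)
        value = min(cap, gain * level + config.background_mean)
        rr, cc = _disk_indices(layout.membrane_shape, spot.center, spot.radius)
        img[rr, cc] = value
    if config.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(
                [
                    config.seed,
                    truth.patient_index(patient),
                    truth.TIMEPOINTS.index(timepoint),
                    EXPOSURES.index(exposure),
                ]
            )
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    np.clip(img, 0.0, cap, out=img)
    return MembraneImage(
        pixels=img,
        patient=patient,
        timepoint=timepoint,
        exposure=exposure,
        saturation_cap=cap,
        layout=layout,
    )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(image: MembraneImage, path: str | Path) -> None:
    """Write the raster as 16-bit grayscale TIFF (or PNG) with a JSON
    metadata sidecar.  Intensities are quantized as
    ``round(pixel / cap * 65535)``."""
    path = Path(path)
    cap = image.saturation_cap
    quant = np.round(np.clip(image.pixels, 0, cap) / cap * 65535.0).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, quant)
    elif path.suffix.lower() == ".png":
        PILImage.fromarray(quant).save(path)
    else:
        raise ParameterError(f"unsupported image format {path.suffix!r}; use .tif or .png")
    meta = {
        "patient": image.patient,
        "timepoint": image.timepoint,
        "exposure": image.exposure,
        "saturation_cap": cap,
        "quantization": "uint16",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1), encoding="utf-8")


def read_image(path: str | Path) -> MembraneImage:
    """Read a membrane raster and its sidecar; rescale integer pixel
    codes back onto the ``[0, cap]`` intensity scale (8-bit inputs use
    the factor ``cap / 255``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"metadata sidecar not found: expected {sidecar} next to {path}"
        )
    meta = json.loads(sidecar.read_text(encoding="utf-8"))
    cap = float(meta["saturation_cap"])
    if path.suffix.lower() in (".tif", ".tiff"):
        raw = np.asarray(tifffile.imread(path))
    else:
        raw = np.array(PILImage.open(path))
    if raw.dtype == np.uint8:
        pixels = raw.astype(float) * (cap / 255.0)
    elif raw.dtype in (np.uint16, np.int32):
        pixels = raw.astype(float) * (cap / 65535.0)
    else:
        pixels = raw.astype(float)
    return MembraneImage(
        pixels=pixels,
        patient=str(meta["patient"]),
        timepoint=str(meta["timepoint"]),
        exposure=str(meta["exposure"]),
        saturation_cap=cap,
    )


def render_config_to_dict(config: RenderConfig) -> dict:
    return asdict(config)
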