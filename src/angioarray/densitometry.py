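"""Spot densitometry: from a membrane raster to normalized protein levels.

The quantification chain mirrors classic template-based blot analysis:

1. (optionally) invert the scan so signal is bright,
2. mean pixel intensity per spot ROI (pixel-centre-in-disk membership),
3. arithmetic mean of the two replicate spots per analyte,
4. subtraction of the mean of a clear background rectangle,
5. division by the background-subtracted mean of the six positive
   reference spots.

The resulting dimensionless ratio is the semi-quantitative "protein
level".  Background-subtracting the reference average before dividing is
what makes the ratio invariant under a global gain change of the scan,
a property the test-suite verifies numerically.

There is no instrument-given detection limit, so detectability uses a
signal-above-blank rule: a protein is detectable iff its
background-subtracted duplicate mean exceeds ``detection_k`` times the
pixel SD of the background region (default k = 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, GeometryError, QualityControlError
from .layout import ArrayLayout, SpotDef
from .render import MembraneImage, _disk_indices

__all__ = [
    "DensitometryConfig",
    "SpotSignals",
    "ProteinLevel",
    "invert_image",
    "quantify_spots",
    "average_duplicates",
    "normalize",
    "quantify_membrane",
]


@dataclass(frozen=True)
class DensitometryConfig:
    detection_k: float = 3.0  # signal-above-blank multiplier
    saturation_fraction: float = 0.5  # fraction of ROI pixels at cap that flags a spot
    invert: bool = False  # synthetic images are pre-inverted, so default off
    subtract_reference_background: bool = True


def invert_image(image: MembraneImage) -> MembraneImage:
    """Photometric inversion ``pixel -> cap - pixel`` (an involution);
    used when the scan encodes signal as dark on bright."""
    return MembraneImage(
        pixels=image.saturation_cap - image.pixels,
        patient=image.patient,
        timepoint=image.timepoint,
        exposure=image.exposure,
        saturation_cap=image.saturation_cap,
        layout=image.layout,
    )


@dataclass
class SpotSignals:
    """Raw per-spot quantification of one membrane."""

    spots: tuple[SpotDef, ...]
    spot_means: np.ndarray  # aligned with spots
    spot_saturated: np.ndarray  # bool, aligned with spots
    background_mean: float
    background_sd: float
    reference_mean: float  # mean of the six reference-spot means (raw scale)
    saturation_cap: float
    meta: dict = field(default_factory=dict)

    def replicate_means(self, analyte_index: int) -> tuple[float, float]:
        got = {
            s.replicate_id: float(m)
            for s, m in zip(self.spots, self.spot_means)
            if s.role == "analyte" and s.analyte_index == analyte_index
        }
        if sorted(got) != [1, 2]:
            raise DataError(f"analyte {analyte_index}: missing replicate(s), found {sorted(got)}")
        return got[1], got[2]


def quantify_spots(
    image: MembraneImage,
    layout: ArrayLayout,
    config: DensitometryConfig | None = None,
) -> SpotSignals:
    """Mean pixel intensity per spot ROI plus background and reference
    statistics.  ROI membership: pixels whose integer centre lies within
    the spot disk."""
    config = config or DensitometryConfig()
    if config.invert:
        image = invert_image(image)
    pixels = image.pixels
    h, w = pixels.shape
    lh, lw = layout.membrane_shape
    if lh > h or lw > w:
        raise GeometryError(
            f"layout ({lh}x{lw}) exceeds image bounds ({h}x{w})"
        )
    cap = image.saturation_cap
    means = np.empty(len(layout.spots))
    saturated = np.zeros(len(layout.spots), dtype=bool)
    for i, spot in enumerate(layout.spots):
        rr, cc = _disk_indices((h, w), spot.center, spot.radius)
        if rr.size == 0:
            raise GeometryError(f"spot at {spot.center} covers no pixel centre")
        roi = pixels[rr, cc]
        means[i] = roi.mean()
        saturated[i] = np.mean(roi >= cap) >= config.saturation_fraction
    r0, c0, r1, c1 = layout.background_region
    bg = pixels[int(np.ceil(r0)) : int(np.floor(r1)) + 1, int(np.ceil(c0)) : int(np.floor(c1)) + 1]
    if bg.size == 0:
        raise GeometryError("background region covers no pixel")
    ref = [m for s, m in zip(layout.spots, means) if s.role == "reference"]
    return SpotSignals(
        spots=layout.spots,
        spot_means=means,
        spot_saturated=saturated,
        background_mean=float(bg.mean()),
        background_sd=float(bg.std(ddof=0)),
        reference_mean=float(np.mean(ref)),
        saturation_cap=cap,
        meta={
            "patient": image.patient,
            "timepoint": image.timepoint,
            "exposure": image.exposure,
        },
    )


def average_duplicates(signals: SpotSignals) -> dict[int, float]:
    """Arithmetic mean of the two replicate spot means, per analyte."""
    out: dict[int, float] = {}
    for s in signals.spots:
        if s.role == "analyte" and s.analyte_index not in out:
            a, b = signals.replicate_means(s.analyte_index)
            out[s.analyte_index] = 0.5 * (a + b)
    return out


@dataclass(frozen=True)
class ProteinLevel:
    """One normalized measurement.  ``level`` is the dimensionless ratio;
    a non-detectable measurement keeps its (clamped, possibly zero)
    ratio but is marked ``detectable=False`` — downstream analysis must
    treat it as below-limit, never as a measured zero."""

    protein: str
    patient: str
    timepoint: str
    exposure: str
    level: float
    detectable: bool
    saturated: bool
    background: float
    reference_mean: float


def normalize(
    signals: SpotSignals,
    panel,
    config: DensitometryConfig | None = None,
) -> list[ProteinLevel]:
    """Background-subtract, reference-normalize and flag each analyte.

    level = max(0, duplicate_mean - background) / (reference_mean' - 0)
    where reference_mean' is background-subtracted by default.  A
    non-positive reference denominator rejects the whole membrane.
    """
    config = config or DensitometryConfig()
    bg = signals.background_mean
    denom = signals.reference_mean - bg if config.subtract_reference_background else signals.reference_mean
    if denom <= 0:
        raise QualityControlError(
            f"membrane rejected: reference mean {signals.reference_mean:.3f} does not exceed "
            f"background {bg:.3f}"
        )
    dup = average_duplicates(signals)
    sat_by_analyte: dict[int, bool] = {}
    for s, flag in zip(signals.spots, signals.spot_saturated):
        if s.role == "analyte":
            sat_by_analyte[s.analyte_index] = sat_by_analyte.get(s.analyte_index, False) or bool(flag)
    threshold = config.detection_k * signals.background_sd
    out = []
    for entry in panel:
        net = dup[entry.index] - bg
        out.append(
            ProteinLevel(
                protein=entry.name,
                patient=signals.meta.get("patient", ""),
                timepoint=signals.meta.get("timepoint", ""),
                exposure=signals.meta.get("exposure", ""),
                level=max(0.0, net) / denom,
                detectable=net > threshold and net > 0,
                saturated=sat_by_analyte[entry.index],
                background=bg,
                reference_mean=signals.reference_mean,
            )
        )
    return out


def quantify_membrane(
    image: MembraneImage,
    layout: ArrayLayout,
    panel,
    config: DensitometryConfig | None = None,
) -> pd.DataFrame:
    """Convenience: quantify + normalize one membrane into a long-format
    DataFrame of protein levels."""
    signals = quantify_spots(image, layout, config)
    rows = normalize(signals, panel, config)
    return pd.DataFrame([r.__dict__ for r in rows])
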