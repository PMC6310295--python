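"""Membrane geometry: spot template and background region.

The membrane is modelled the way a densitometry template treats it: a
fixed grid of circular regions of interest (one disk per spotted
antibody, two replicate disks per analyte), six positive reference
spots, and one clear rectangle used for background estimation.  All
coordinates are 0-based ``(row, col)`` pixels with the origin at the
top-left corner.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParameterError, SchemaError
from .panel import ProteinPanel

__all__ = [
    "SpotDef",
    "ArrayLayout",
    "build_default_layout",
    "write_layout",
    "read_layout",
]

N_REFERENCE_SPOTS = 6


@dataclass(frozen=True)
class SpotDef:
    """One circular ROI.  ``analyte_index``/``replicate_id`` are ``None``
    for reference spots and mandatory for analyte spots."""

    center: tuple[float, float]  # (row_px, col_px)
    radius: float
    role: str  # "analyte" | "reference"
    analyte_index: int | None = None
    replicate_id: int | None = None

    def __post_init__(self) -> None:
        if self.role not in ("analyte", "reference"):
            raise SchemaError(f"unknown spot role {self.role!r}")
        if self.radius <= 0:
            raise SchemaError("spot radius must be positive")
        if self.role == "analyte":
            if self.analyte_index is None or self.replicate_id not in (1, 2):
                raise SchemaError("analyte spot needs analyte_index and replicate_id in {1, 2}")
        elif self.analyte_index is not None or self.replicate_id is not None:
            raise SchemaError("reference spot must not carry analyte fields")


@dataclass(frozen=True)
class ArrayLayout:
    membrane_shape: tuple[int, int]  # (height_px, width_px)
    spots: tuple[SpotDef, ...]
    background_region: tuple[float, float, float, float]  # (row0, col0, row1, col1)

    def __post_init__(self) -> None:
        validate_layout(self)

    @property
    def reference_spots(self) -> list[SpotDef]:
        return [s for s in self.spots if s.role == "reference"]

    @property
    def analyte_spots(self) -> list[SpotDef]:
        return [s for s in self.spots if s.role == "analyte"]

    @property
    def analyte_indices(self) -> list[int]:
        return sorted({s.analyte_index for s in self.analyte_spots})


def validate_layout(layout: ArrayLayout) -> None:
    """Enforce the layout invariants; raise :class:`SchemaError` otherwise.

    Invariants: exactly six reference spots; every analyte present as
    exactly two replicate disks; all disks inside the membrane; no two
    disks overlap; the background rectangle is inside the membrane and
    disjoint from every disk.
    """
    h, w = layout.membrane_shape
    if h <= 0 or w <= 0:
        raise SchemaError("membrane_shape must be positive")
    refs = layout.reference_spots
    if len(refs) != N_REFERENCE_SPOTS:
        raise SchemaError(f"expected {N_REFERENCE_SPOTS} reference spots, found {len(refs)}")
    per_analyte: dict[int, list[int]] = {}
    for s in layout.analyte_spots:
        per_analyte.setdefault(s.analyte_index, []).append(s.replicate_id)
    for idx, reps in per_analyte.items():
        if sorted(reps) != [1, 2]:
            raise SchemaError(f"analyte {idx} must have exactly replicates 1 and 2, got {sorted(reps)}")

    centers = np.array([s.center for s in layout.spots], dtype=float)
    radii = np.array([s.radius for s in layout.spots], dtype=float)
    if np.any(centers[:, 0] - radii < 0) or np.any(centers[:, 0] + radii > h - 1) \
            or np.any(centers[:, 1] - radii < 0) or np.any(centers[:, 1] + radii > w - 1):
        raise SchemaError("spot disk extends outside the membrane bounds")

    # pairwise non-overlap: centre distance must reach the radius sum
    d2 = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    rsum = radii[:, None] + radii[None, :]
    mask = ~np.eye(len(radii), dtype=bool)
    if np.any(d2[mask] < (rsum[mask] ** 2) * (1 - 1e-12)):
        raise SchemaError("two spot disks overlap")

    r0, c0, r1, c1 = layout.background_region
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise SchemaError("background_region outside membrane or empty")
    # disk/rectangle disjointness via closest-point distance
    cr = np.clip(centers[:, 0], r0, r1)
    cc = np.clip(centers[:, 1], c0, c1)
    dist2 = (centers[:, 0] - cr) ** 2 + (centers[:, 1] - cc) ** 2
    if np.any(dist2 < radii**2 * (1 - 1e-12)):
        raise SchemaError("background_region intersects a spot disk")


def build_default_layout(
    panel: ProteinPanel,
    spot_radius: float = 6.0,
    pitch: float = 20.0,
    analytes_per_row: int = 11,
) -> ArrayLayout:
    """Grid template: a top row with the six reference spots, then rows of
    horizontally adjacent duplicate pairs (two disks per analyte).

    The background rectangle occupies the clear right-hand end of the
    reference row.  The commercial membrane's true geometry is not
    public; this template is a functional stand-in with the same
    accounting structure (55 x 2 analyte disks + 6 reference disks).
    """
    if spot_radius <= 0 or pitch <= 0:
        raise ParameterError("spot_radius and pitch must be positive")
    if spot_radius >= pitch / 2:
        raise ParameterError(
            f"spot_radius {spot_radius} incompatible with pitch {pitch}: adjacent disks would overlap"
        )
    margin = pitch
    n = len(panel)
    n_rows = math.ceil(n / analytes_per_row)
    n_cols = 2 * analytes_per_row
    height = int(math.ceil(margin + (n_rows + 1 - 1) * pitch + margin))  # ref row + analyte rows
    width = int(math.ceil(margin + (n_cols - 1) * pitch + margin))

    def center(row_i: int, col_i: int) -> tuple[float, float]:
        return (margin + row_i * pitch, margin + col_i * pitch)

    spots: list[SpotDef] = []
    for k in range(N_REFERENCE_SPOTS):
        spots.append(SpotDef(center=center(0, k), radius=spot_radius, role="reference"))
    for i, entry in enumerate(panel):
        row_i = 1 + i // analytes_per_row
        pair = i % analytes_per_row
        for rep in (1, 2):
            spots.append(
                SpotDef(
                    center=center(row_i, 2 * pair + (rep - 1)),
                    radius=spot_radius,
                    role="analyte",
                    analyte_index=entry.index,
                    replicate_id=rep,
                )
            )
    # clear zone right of the reference spots, vertically centred on their row
    bg_row, _ = center(0, 0)
    bg_col0 = center(0, N_REFERENCE_SPOTS + 1)[1] + spot_radius
    background = (bg_row - spot_radius, bg_col0, bg_row + spot_radius, width - margin / 2)
    return ArrayLayout(
        membrane_shape=(height, width),
        spots=tuple(spots),
        background_region=background,
    )


def write_layout(layout: ArrayLayout, path: str | Path) -> None:
    """Serialize a layout to JSON (pixel units)."""
    doc = {
        "units": "px",
        "membrane_shape": list(layout.membrane_shape),
        "background_region": list(layout.background_region),
        "spots": [
            {
                "center": list(s.center),
                "radius": s.radius,
                "role": s.role,
                **(
                    {"analyte_index": s.analyte_index, "replicate_id": s.replicate_id}
                    if s.role == "analyte"
                    else {}
                ),
            }
            for s in layout.spots
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def read_layout(path: str | Path) -> ArrayLayout:
    """Read a layout JSON and re-validate every invariant."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"layout file {path} is not valid JSON: {exc}") from None
    try:
        spots = tuple(
            SpotDef(
                center=(float(s["center"][0]), float(s["center"][1])),
                radius=float(s["radius"]),
                role=s["role"],
                analyte_index=s.get("analyte_index"),
                replicate_id=s.get("replicate_id"),
            )
            for s in doc["spots"]
        )
        return ArrayLayout(
            membrane_shape=(int(doc["membrane_shape"][0]), int(doc["membrane_shape"][1])),
            spots=spots,
            background_region=tuple(float(v) for v in doc["background_region"]),
        )
    except (KeyError, TypeError, IndexError) as exc:
        raise SchemaError(f"layout file {path} misses required fields: {exc}") from None
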