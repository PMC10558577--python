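"""Key-point geometry: radiographic implant dimensions from three landmarks.

A periapical radiograph of a bone level implant is annotated with three key
points: A and B span the implant body diameter at the platform (threads
excluded) and C marks the apex.  The apparent, *radiographic* diameter D is
the Euclidean length of segment AB in pixels; the triangle ABC has shoelace
area S, and since S = D*L/2 the radiographic length L follows as L = 2S/D —
the perpendicular height of the apex over the platform chord.  Pixel values
are converted to millimetres with the detector's imager pixel spacing.

Radiographic dimensions are deliberately *not* corrected for magnification
or angular foreshortening; the downstream classifier operates on the
distorted measurements directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import pandas as pd

from .errors import CollinearPointsError, ConfigurationError, DegenerateSegmentError

if TYPE_CHECKING:  # pragma: no cover
    from .annotations import AnnotationRecord

Point = Sequence[float]

#: Triangles with area below this (px^2) are treated as collinear.
COLLINEAR_AREA_PX2 = 1e-9


def radiographic_diameter(a: Point, b: Point) -> float:
    """Euclidean distance |AB| in pixels (the apparent platform diameter).

    Raises :class:`DegenerateSegmentError` if A and B coincide.
    """
    d = math.hypot(b[0] - a[0], b[1] - a[1])
    if d <= 0.0:
        raise DegenerateSegmentError("points A and B coincide; diameter undefined")
    return d


def triangle_area(a: Point, b: Point, c: Point) -> float:
    """Absolute shoelace area of triangle ABC in px^2.

    Degenerate (collinear) triples return 0; flagging them is left to the
    caller so the primitive stays total.
    """
    x1, y1 = a[0], a[1]
    x2, y2 = b[0], b[1]
    x3, y3 = c[0], c[1]
    return 0.5 * abs(x1 * y2 + x2 * y3 + x3 * y1 - x2 * y1 - x3 * y2 - x1 * y3)


def radiographic_length(a: Point, b: Point, c: Point) -> float:
    """Height of apex C over the platform chord AB, in pixels: L = 2S/D.

    Equivalently the perpendicular point-to-line distance from C to line AB;
    the apex may project outside the segment AB.
    """
    return 2.0 * triangle_area(a, b, c) / radiographic_diameter(a, b)


@dataclass(frozen=True)
class RadiographicMeasurement:
    """Radiographic dimensions of one implant, in pixels and millimetres.

    Satisfies S = D*L/2 (to float tolerance) and the mm fields are the px
    fields scaled by the record's pixel spacing.
    """

    image_id: str
    D_px: float
    S_px2: float
    L_px: float
    D_mm: float
    L_mm: float
    true_code: str | None = None


def extract_feature(record: "AnnotationRecord") -> RadiographicMeasurement:
    """Compute D, S, L for one annotated implant and scale to millimetres."""
    if record.pixel_spacing_mm is None:
        raise ConfigurationError(
            f"record {record.image_id!r} has no pixel spacing; "
            "read it from DICOM metadata or a sidecar first"
        )
    a, b, c = record.point_a, record.point_b, record.point_c
    s = triangle_area(a, b, c)
    if s < COLLINEAR_AREA_PX2:
        raise CollinearPointsError(
            f"record {record.image_id!r}: key points are collinear (area {s:g} px^2)"
        )
    d = radiographic_diameter(a, b)
    length = 2.0 * s / d
    spacing = record.pixel_spacing_mm
    return RadiographicMeasurement(
        image_id=record.image_id,
        D_px=d,
        S_px2=s,
        L_px=length,
        D_mm=d * spacing,
        L_mm=length * spacing,
        true_code=record.true_label.code if record.true_label is not None else None,
    )


def features_frame(measurements: Iterable[RadiographicMeasurement]) -> pd.DataFrame:
    """Tabulate measurements as the canonical features table.

    Columns: image_id, D_mm, L_mm, true_code (empty when unknown).
    """
    rows = [
        {
            "image_id": m.image_id,
            "D_mm": m.D_mm,
            "L_mm": m.L_mm,
            "true_code": m.true_code if m.true_code is not None else "",
        }
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=["image_id", "D_mm", "L_mm", "true_code"])


def read_features_csv(path) -> pd.DataFrame:
    """Read a features table written by :func:`features_frame`/the CLI."""
    df = pd.read_csv(path, comment="#", dtype={"image_id": str, "true_code": str})
    df["true_code"] = df["true_code"].fillna("")
    return df
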