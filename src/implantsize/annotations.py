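"""Annotation, pixel-spacing and manifest I/O plus the stratified split.

Key points are stored as LabelMe-style JSON files holding exactly one
polygon with three vertices, taken in file order as A, B (platform chord)
and C (apex).  Physical pixel spacing comes either from a DICOM file's
Imager Pixel Spacing attribute (0018,1164) or from a flat key-value sidecar
file with key ``pixel_spacing_mm``.  A dataset is described by a manifest
CSV with columns ``image_id,annotation_path,spacing_source,true_code,split``.
"""

from __future__ import annotations

import csv
import io
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pydicom

from . import geometry
from .errors import (
    AnisotropicSpacingError,
    AnnotationFormatError,
    CollinearPointsError,
    InsufficientDataError,
    VertexCountError,
)
from .labels import SizeLabel

#: Relative tolerance for row/column pixel-spacing mismatch.
SPACING_ANISOTROPY_RTOL = 0.005

SPLIT_TAGS = ("train", "validation", "test", "unassigned")

MANIFEST_COLUMNS = ("image_id", "annotation_path", "spacing_source", "true_code", "split")


@dataclass
class AnnotationRecord:
    """Three key points for one implant image, plus calibration and label.

    Coordinates are continuous pixel positions (x right, y down, origin at
    the image's top-left corner); annotation tools emit sub-pixel vertices.
    """

    image_id: str
    point_a: tuple[float, float]
    point_b: tuple[float, float]
    point_c: tuple[float, float]
    pixel_spacing_mm: float | None = None
    true_label: SizeLabel | None = None

    def validate(self) -> None:
        """Check geometric invariants; warn if the triangle looks rotated.

        All nine catalogue sizes are longer than they are wide, so a
        measured length not exceeding the measured diameter usually means
        the vertices were annotated in an unexpected order — worth a
        warning, but plausible under extreme foreshortening, so not an
        error.
        """
        if self.pixel_spacing_mm is not None and not self.pixel_spacing_mm > 0:
            raise ValueError(
                f"record {self.image_id!r}: pixel spacing must be positive, "
                f"got {self.pixel_spacing_mm}"
            )
        area = geometry.triangle_area(self.point_a, self.point_b, self.point_c)
        if area < geometry.COLLINEAR_AREA_PX2:
            raise CollinearPointsError(
                f"record {self.image_id!r}: key points are collinear"
            )
        d = geometry.radiographic_diameter(self.point_a, self.point_b)
        length = 2.0 * area / d
        if length <= d:
            warnings.warn(
                f"record {self.image_id!r}: measured length ({length:.1f} px) "
                f"<= diameter ({d:.1f} px); check A,B,C vertex order",
                stacklevel=2,
            )


def read_labelme_annotation(path) -> AnnotationRecord:
    """Read one LabelMe-style JSON annotation into an :class:`AnnotationRecord`.

    The file must contain exactly one polygon shape with exactly three
    vertices; they are taken in file order as A, B, C.  Pixel spacing is
    left unset (fill it with :func:`read_pixel_spacing`).
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    shapes = data.get("shapes")
    if not isinstance(shapes, list):
        raise AnnotationFormatError(f"{path}: no 'shapes' list")
    polygons = [s for s in shapes if s.get("shape_type", "polygon") == "polygon"]
    if len(polygons) != 1:
        raise AnnotationFormatError(
            f"{path}: expected exactly one polygon shape, found {len(polygons)}"
        )
    points = polygons[0].get("points")
    if points is None or len(points) != 3:
        n = 0 if points is None else len(points)
        raise VertexCountError(f"{path}: polygon has {n} vertices, expected 3")
    a, b, c = (tuple(float(v) for v in p) for p in points)
    image_id = str(data.get("imagePath") or path.stem)
    image_id = Path(image_id).stem
    record = AnnotationRecord(image_id=image_id, point_a=a, point_b=b, point_c=c)
    record.validate()
    return record


def write_labelme_annotation(record: AnnotationRecord, path) -> None:
    """Write a record back to LabelMe-style JSON (one 3-vertex polygon)."""
    path = Path(path)
    doc = {
        "version": "5.2.1",
        "flags": {},
        "shapes": [
            {
                "label": "implant",
                "points": [list(p) for p in (record.point_a, record.point_b, record.point_c)],
                "group_id": None,
                "shape_type": "polygon",
                "flags": {},
            }
        ],
        "imagePath": f"{record.image_id}.png",
        "imageData": None,
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def _spacing_from_pair(row: float, col: float, source: str) -> float:
    row, col = float(row), float(col)
    if row <= 0 or col <= 0:
        raise ValueError(f"{source}: non-positive pixel spacing ({row}, {col})")
    mean = 0.5 * (row + col)
    if abs(row - col) / mean > SPACING_ANISOTROPY_RTOL:
        raise AnisotropicSpacingError(
            f"{source}: row/column spacing ({row}, {col}) differ by more than "
            f"{SPACING_ANISOTROPY_RTOL:.1%}; anisotropic detectors are unsupported"
        )
    return mean


def read_pixel_spacing(source) -> float:
    """Return the scalar pixel spacing (mm/px) from DICOM or sidecar metadata.

    DICOM sources must carry Imager Pixel Spacing (0018,1164); row and
    column values within 0.5% relative are averaged, larger anisotropy is
    an error.  Sidecar files are flat ``key = value`` text with key
    ``pixel_spacing_mm`` (a scalar or a row,col pair).
    """
    source = Path(source)
    if source.suffix.lower() in {".dcm", ".dicom"}:
        ds = pydicom.dcmread(source, stop_before_pixels=True)
        value = ds.get("ImagerPixelSpacing")
        if value is None:
            raise AnnotationFormatError(f"{source}: no Imager Pixel Spacing attribute")
        return _spacing_from_pair(value[0], value[1], str(source))
    # sidecar: flat key-value lines
    pairs: dict[str, str] = {}
    for line in source.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        pairs[key.strip()] = val.strip()
    if "pixel_spacing_mm" not in pairs:
        raise AnnotationFormatError(f"{source}: no pixel_spacing_mm key")
    raw = pairs["pixel_spacing_mm"]
    parts = [p for p in raw.replace(",", " ").split() if p]
    if len(parts) == 1:
        value = float(parts[0])
        if value <= 0:
            raise ValueError(f"{source}: non-positive pixel spacing {value}")
        return value
    return _spacing_from_pair(float(parts[0]), float(parts[1]), str(source))


@dataclass
class ManifestEntry:
    """One dataset row: where the annotation and calibration live."""

    image_id: str
    annotation_path: str
    spacing_source: str
    true_code: str = ""
    split: str = "unassigned"


@dataclass
class DatasetManifest:
    """Ordered collection of manifest entries with unique image ids."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.image_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate image_ids in manifest: {dupes[:5]}")
        for e in self.entries:
            if e.split not in SPLIT_TAGS:
                raise ValueError(f"invalid split tag {e.split!r} for {e.image_id!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest([e for e in self.entries if e.split == split])

    def counts_by_split(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.entries:
            out[e.split] = out.get(e.split, 0) + 1
        return out


def write_manifest(manifest: DatasetManifest, path, header_comment: str | None = None) -> None:
    """Write the manifest CSV (LF line endings, fixed column order)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = io.StringIO()
    if header_comment:
        for line in header_comment.splitlines():
            buf.write(f"# {line}\n")
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(MANIFEST_COLUMNS)
    for e in manifest.entries:
        writer.writerow([e.image_id, e.annotation_path, e.spacing_source, e.true_code, e.split])
    path.write_text(buf.getvalue(), encoding="utf-8")


def read_manifest(path) -> DatasetManifest:
    """Read a manifest CSV written by :func:`write_manifest`."""
    path = Path(path)
    lines = [ln for ln in path.read_text(encoding="utf-8").splitlines() if not ln.startswith("#")]
    reader = csv.reader(lines)
    rows = list(reader)
    if not rows or tuple(rows[0]) != MANIFEST_COLUMNS:
        raise AnnotationFormatError(
            f"{path}: bad manifest header {rows[0] if rows else '(empty)'}"
        )
    entries = [
        ManifestEntry(
            image_id=r[0],
            annotation_path=r[1],
            spacing_source=r[2],
            true_code=r[3],
            split=r[4] if r[4] else "unassigned",
        )
        for r in rows[1:]
        if r
    ]
    return DatasetManifest(entries)


def stratified_split(
    manifest: DatasetManifest,
    n_val_per_class: int,
    n_test_per_class: int,
    seed: int | None = None,
) -> DatasetManifest:
    """Tag each entry train/validation/test with exact per-class counts.

    Each class (true_code) contributes exactly ``n_val_per_class`` records
    to validation and ``n_test_per_class`` to test, sampled without
    replacement with a seeded generator; everything else is train.  Record
    order is preserved.  Raises :class:`InsufficientDataError` if any class
    is too small.
    """
    if n_val_per_class < 0 or n_test_per_class < 0:
        raise ValueError("per-class counts must be non-negative")
    by_class: dict[str, list[int]] = {}
    for i, e in enumerate(manifest.entries):
        if not e.true_code:
            raise InsufficientDataError(
                f"record {e.image_id!r} has no true_code; cannot stratify"
            )
        by_class.setdefault(e.true_code, []).append(i)
    need = n_val_per_class + n_test_per_class
    rng = np.random.default_rng(seed)
    tags = ["train"] * len(manifest.entries)
    for code in sorted(by_class):
        idx = by_class[code]
        if len(idx) < need:
            raise InsufficientDataError(
                f"class {code}: {len(idx)} records < required {need} "
                f"({n_val_per_class} validation + {n_test_per_class} test)"
            )
        perm = rng.permutation(len(idx))
        for j in perm[:n_val_per_class]:
            tags[idx[j]] = "validation"
        for j in perm[n_val_per_class:need]:
            tags[idx[j]] = "test"
    return DatasetManifest(
        [replace(e, split=t) for e, t in zip(manifest.entries, tags)]
    )


def load_records(
    manifest: DatasetManifest, base_dir, splits: Sequence[str] | None = None
) -> list[AnnotationRecord]:
    """Materialise annotation records (with spacing and labels) from disk."""
    base = Path(base_dir)
    records = []
    for e in manifest.entries:
        if splits is not None and e.split not in splits:
            continue
        rec = read_labelme_annotation(base / e.annotation_path)
        rec.image_id = e.image_id
        rec.pixel_spacing_mm = read_pixel_spacing(base / e.spacing_source)
        rec.true_label = SizeLabel.from_code(e.true_code) if e.true_code else None
        records.append(rec)
    return records
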