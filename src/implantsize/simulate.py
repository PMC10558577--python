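"""Synthetic key-point annotation generator.

Clinical periapical radiographs of implants cannot be redistributed, so
this module generates annotation datasets with the same geometric and
statistical structure the pipeline assumes.  Each synthetic implant of
catalogue size (d, l) is projected onto the detector plane as

    D_rad = d * m            (magnification m)
    L_rad = l * m * cos(theta)   (foreshortening by sensor-implant angle theta)

— magnification scales both dimensions, while tilting the implant's long
axis relative to the sensor shortens only the projected length; the
platform chord is taken to lie (approximately) parallel to the sensor.
The projected implant is placed at a uniformly random canvas position with
a random in-plane rotation, converted to pixels with the detector pixel
spacing, and i.i.d. Gaussian noise is added to all six key-point
coordinates to emulate annotator imprecision.

Only key points and metadata are generated — no radiograph pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .annotations import (
    AnnotationRecord,
    DatasetManifest,
    ManifestEntry,
    write_labelme_annotation,
    write_manifest,
)
from .errors import ConfigurationError
from .labels import CODES, SizeLabel


def _near_balanced_counts(total: int) -> dict[str, int]:
    base, extra = divmod(total, len(CODES))
    return {code: base + (1 if i < extra else 0) for i, code in enumerate(CODES)}


@dataclass(frozen=True)
class SimulationConfig:
    """Distributions governing the generator.

    Defaults emulate intraoral paralleling-technique imaging: modest
    magnification (uniform on [1.05, 1.20]), sensor-implant angulation
    normal with mean 0 and sd 8 degrees truncated at +/-25, in-plane
    rotation uniform on [-20, 20] degrees, 0.5 px annotator noise per
    coordinate, 0.04 mm/px detector spacing on a 768x1024 px canvas.
    """

    per_class_counts: dict[str, int] = field(
        default_factory=lambda: {code: 40 for code in CODES}
    )
    magnification_range: tuple[float, float] = (1.05, 1.20)
    angulation_sd_deg: float = 8.0
    angulation_max_deg: float = 25.0
    inplane_rotation_range_deg: tuple[float, float] = (-20.0, 20.0)
    keypoint_noise_px: float = 0.5
    pixel_spacing_mm: float = 0.04
    image_extent_px: tuple[float, float] = (768.0, 1024.0)
    seed: int | None = None

    def validate(self) -> None:
        if any(c < 0 for c in self.per_class_counts.values()):
            raise ConfigurationError("per-class counts must be non-negative")
        unknown = set(self.per_class_counts) - set(CODES)
        if unknown:
            raise ConfigurationError(f"unknown size codes in config: {sorted(unknown)}")
        lo, hi = self.magnification_range
        if not (0 < lo <= hi):
            raise ConfigurationError(f"bad magnification range ({lo}, {hi})")
        if self.keypoint_noise_px < 0 or self.angulation_sd_deg < 0:
            raise ConfigurationError("noise parameters must be non-negative")
        if not self.pixel_spacing_mm > 0:
            raise ConfigurationError("pixel spacing must be positive")
        if min(self.image_extent_px) <= 0:
            raise ConfigurationError("canvas extent must be positive")

    @property
    def total(self) -> int:
        return sum(self.per_class_counts.values())


def paper_scale_preset(seed: int | None = None) -> SimulationConfig:
    """Default distributions at clinical-benchmark scale: 1320 records.

    Counts are near-balanced over the nine codes (147 for six codes, 146
    for three), so a 20+20 per-class stratified split yields the canonical
    960/180/180 train/validation/test partition.
    """
    return SimulationConfig(per_class_counts=_near_balanced_counts(1320), seed=seed)


def low_noise_preset(
    per_class: int = 60, seed: int | None = None
) -> SimulationConfig:
    """Nearly ideal imaging: magnification within +/-2%, small angulation,
    0.25 px annotator noise.  Classes are then almost separable and the
    tuned pipeline should recover labels near-perfectly."""
    return SimulationConfig(
        per_class_counts={code: per_class for code in CODES},
        magnification_range=(0.98, 1.02),
        angulation_sd_deg=2.0,
        angulation_max_deg=5.0,
        keypoint_noise_px=0.25,
        seed=seed,
    )


def noiseless_config(per_class: int = 5, seed: int | None = None) -> SimulationConfig:
    """Degenerate generator: unit magnification, zero angle, zero noise.

    Geometry extraction then recovers catalogue dimensions exactly; used
    for round-trip validation.
    """
    return SimulationConfig(
        per_class_counts={code: per_class for code in CODES},
        magnification_range=(1.0, 1.0),
        angulation_sd_deg=0.0,
        angulation_max_deg=0.0,
        keypoint_noise_px=0.0,
        seed=seed,
    )


@dataclass(frozen=True)
class GroundTruthRecord:
    """A generated record plus the latent draws that produced it."""

    record: AnnotationRecord
    magnification: float
    angulation_deg: float
    rotation_deg: float
    clean_points: np.ndarray  # (3, 2) noiseless A, B, C in px


def projected_dimensions(
    label: SizeLabel | str, magnification: float, angulation_deg: float
) -> tuple[float, float]:
    """Radiographic (D_rad, L_rad) in mm for given magnification and tilt.

    Magnification scales both axes; tilting the long axis by ``theta``
    relative to the sensor plane foreshortens only the length, by
    cos(theta).  The platform chord is modelled as sensor-parallel, so the
    diameter is unaffected by the tilt.
    """
    if isinstance(label, str):
        label = SizeLabel.from_code(label)
    cos_t = math.cos(math.radians(angulation_deg))
    return label.diameter_mm * magnification, label.length_mm * magnification * cos_t


def _draw_truncated_normal(
    rng: np.random.Generator, sd: float, bound: float
) -> float:
    if sd == 0.0 or bound == 0.0:
        return 0.0
    while True:
        x = rng.normal(0.0, sd)
        if abs(x) <= bound:
            return float(x)


def sample_record(
    label: SizeLabel | str,
    config: SimulationConfig,
    rng: np.random.Generator,
    image_id: str | None = None,
    max_position_retries: int = 100,
) -> GroundTruthRecord:
    """Generate one synthetic annotated implant of the given catalogue size.

    Draws magnification m, angulation theta and in-plane rotation phi,
    projects the implant, places its platform midpoint uniformly on the
    canvas (resampling the position up to ``max_position_retries`` times if
    the implant would leave the canvas), and perturbs the key points with
    Gaussian noise.
    """
    if isinstance(label, str):
        label = SizeLabel.from_code(label)
    config.validate()
    m = float(rng.uniform(*config.magnification_range))
    theta = _draw_truncated_normal(rng, config.angulation_sd_deg, config.angulation_max_deg)
    phi = float(rng.uniform(*config.inplane_rotation_range_deg))

    s = config.pixel_spacing_mm
    d_rad, l_rad = projected_dimensions(label, m, theta)
    half_d_px = d_rad / (2.0 * s)
    l_px = l_rad / s

    phi_r = math.radians(phi)
    u = np.array([math.sin(phi_r), math.cos(phi_r)])  # apex direction (down at phi=0)
    v = np.array([math.cos(phi_r), -math.sin(phi_r)])  # platform chord direction
    w_px, h_px = config.image_extent_px

    for _ in range(max_position_retries):
        p = np.array([rng.uniform(0, w_px), rng.uniform(0, h_px)])
        pts = np.stack([p - half_d_px * v, p + half_d_px * v, p + l_px * u])
        if (pts[:, 0] >= 0).all() and (pts[:, 0] <= w_px).all() and (
            pts[:, 1] >= 0
        ).all() and (pts[:, 1] <= h_px).all():
            break
    else:
        raise ConfigurationError(
            f"implant {label.code} (projected {l_px:.0f} px) does not fit the "
            f"{w_px:.0f}x{h_px:.0f} canvas after {max_position_retries} placements"
        )

    noisy = pts + rng.normal(0.0, config.keypoint_noise_px, size=(3, 2)) \
        if config.keypoint_noise_px > 0 else pts.copy()
    record = AnnotationRecord(
        image_id=image_id or f"{label.code}_{int(rng.integers(1 << 30)):08x}",
        point_a=tuple(noisy[0]),
        point_b=tuple(noisy[1]),
        point_c=tuple(noisy[2]),
        pixel_spacing_mm=s,
        true_label=label,
    )
    return GroundTruthRecord(
        record=record,
        magnification=m,
        angulation_deg=theta,
        rotation_deg=phi,
        clean_points=pts,
    )


def generate_records(config: SimulationConfig) -> list[GroundTruthRecord]:
    """Generate the full in-memory dataset described by the config.

    Deterministic for a fixed ``config.seed``; records are ordered by
    ascending size code, then index.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    out: list[GroundTruthRecord] = []
    for code in CODES:
        count = config.per_class_counts.get(code, 0)
        for i in range(count):
            out.append(
                sample_record(code, config, rng, image_id=f"{code}_{i:04d}")
            )
    return out


def generate_dataset(config: SimulationConfig, out_dir) -> DatasetManifest:
    """Generate and write a complete on-disk dataset.

    Produces one LabelMe-style JSON per record under ``annotations/``, one
    pixel-spacing sidecar under ``spacing/``, and ``manifest.csv`` at the
    root of ``out_dir``.  Byte-identical across runs with the same config.
    """
    out_dir = Path(out_dir)
    records = generate_records(config)
    entries = []
    for gt in records:
        rec = gt.record
        ann_rel = f"annotations/{rec.image_id}.json"
        spc_rel = f"spacing/{rec.image_id}.txt"
        write_labelme_annotation(rec, out_dir / ann_rel)
        spc_path = out_dir / spc_rel
        spc_path.parent.mkdir(parents=True, exist_ok=True)
        spc_path.write_text(
            f"pixel_spacing_mm = {rec.pixel_spacing_mm!r}\n", encoding="utf-8"
        )
        entries.append(
            ManifestEntry(
                image_id=rec.image_id,
                annotation_path=ann_rel,
                spacing_source=spc_rel,
                true_code=rec.true_label.code,
            )
        )
    manifest = DatasetManifest(entries)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def features_and_codes(
    records: Iterable[GroundTruthRecord],
) -> tuple[np.ndarray, list[str]]:
    """Extract (D_mm, L_mm) features and true codes from generated records."""
    from .geometry import extract_feature

    feats, codes = [], []
    for gt in records:
        meas = extract_feature(gt.record)
        feats.append([meas.D_mm, meas.L_mm])
        codes.append(gt.record.true_label.code)
    return np.array(feats), codes
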