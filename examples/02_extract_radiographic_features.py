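"""Turn three key points into radiographic diameter and length in mm.

D is the pixel length of the platform chord AB; the triangle ABC has
shoelace area S = D*L/2, so the radiographic length L = 2S/D is the
perpendicular height of the apex C over AB.  Multiplying by the detector's
imager pixel spacing converts both to millimetres.
"""

from implantsize import geometry
from implantsize.annotations import AnnotationRecord
from implantsize.labels import SizeLabel

# an axis-aligned 4.1 x 10 mm implant at 0.04 mm/px: chord 100 px, apex 250 px
record = AnnotationRecord(
    image_id="demo",
    point_a=(0.0, 0.0),
    point_b=(100.0, 0.0),
    point_c=(50.0, 250.0),
    pixel_spacing_mm=0.04,
    true_label=SizeLabel.from_code("4110"),
)
m = geometry.extract_feature(record)
print(f"D = {m.D_px:.1f} px = {m.D_mm:.2f} mm")
print(f"S = {m.S_px2:.1f} px^2  (equals D*L/2 = {0.5 * m.D_px * m.L_px:.1f})")
print(f"L = {m.L_px:.1f} px = {m.L_mm:.2f} mm")
# prints D = 4.00 mm, L = 10.00 mm: the record matches catalogue size 4110
# exactly because this synthetic triangle has no magnification or tilt.

# the measurement is invariant under image rotation and translation:
import numpy as np

theta = np.radians(33.0)
rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
pts = np.array([record.point_a, record.point_b, record.point_c]) @ rot.T + [80, 50]
rotated = AnnotationRecord(
    image_id="demo_rot",
    point_a=tuple(pts[0]), point_b=tuple(pts[1]), point_c=tuple(pts[2]),
    pixel_spacing_mm=0.04,
)
r = geometry.extract_feature(rotated)
print(f"rotated 33 deg + translated: D = {r.D_mm:.2f} mm, L = {r.L_mm:.2f} mm")
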