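"""Implant size labels.

Bone level implants come in a small catalogue of sizes; here the nine
combinations of body diameter {3.3, 4.1, 4.8} mm and length {8, 10, 12} mm.
Each size is named by a four-digit code: the first two digits are the
diameter in tenths of a millimetre and the last two the length in
millimetres (3.3 mm x 8 mm -> "3308").
"""

from __future__ import annotations

from dataclasses import dataclass

DIAMETERS_MM = (3.3, 4.1, 4.8)
LENGTHS_MM = (8.0, 10.0, 12.0)


@dataclass(frozen=True, order=True)
class SizeLabel:
    """One catalogue implant size."""

    code: str
    diameter_mm: float
    length_mm: float

    def __post_init__(self) -> None:
        expected = f"{round(self.diameter_mm * 10):02d}{round(self.length_mm):02d}"
        if self.code != expected:
            raise ValueError(
                f"code {self.code!r} inconsistent with "
                f"diameter {self.diameter_mm} mm / length {self.length_mm} mm"
            )

    @classmethod
    def from_code(cls, code: str) -> "SizeLabel":
        code = str(code)
        if code not in _BY_CODE:
            raise ValueError(f"unknown size code {code!r}; expected one of {CODES}")
        return _BY_CODE[code]


CATALOGUE: tuple[SizeLabel, ...] = tuple(
    SizeLabel(f"{round(d * 10):02d}{round(length):02d}", d, length)
    for d in DIAMETERS_MM
    for length in LENGTHS_MM
)
_BY_CODE = {lab.code: lab for lab in CATALOGUE}

#: The nine valid codes in ascending order (the fixed label order everywhere).
CODES: tuple[str, ...] = tuple(sorted(_BY_CODE))
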