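"""The unit of the study: one annotated tooth surface."""
from __future__ import annotations

import dataclasses

from .annotation import SurfaceCurve
from .mesh import LongAxis, TriangleMesh
from .registration import LandmarkTriplet

TOOTH_TYPES = ("central", "lateral", "canine")
SIDES = ("right", "left")


@dataclasses.dataclass
class ToothModel:
    """Tooth mesh with its landmarks, long axis and gingival margin curve."""

    individual_id: str
    tooth_type: str  # central | lateral | canine
    side: str  # right | left
    mesh: TriangleMesh
    landmarks: LandmarkTriplet
    gingival_margin: SurfaceCurve
    long_axis: LongAxis

    def __post_init__(self) -> None:
        if self.tooth_type not in TOOTH_TYPES:
            raise ValueError(f"unknown tooth type {self.tooth_type!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")

    @property
    def tooth_id(self) -> str:
        return f"{self.individual_id}:{self.tooth_type}:{self.side}"
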