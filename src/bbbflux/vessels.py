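"""Cerebral microvessel taxonomy and geometry.

The cortical vascular tree is divided into six categories: pial arterioles
and venules running along the brain surface (in-plane in a horizontal
imaging volume), penetrating arterioles and ascending venules diving
perpendicular to the surface (through-plane), and the capillary bed with
its post-capillary venules. Capillaries are bounded above by 6 um diameter;
the remaining default diameter bands are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

CATEGORIES: tuple[str, ...] = (
    "pial_arteriole",
    "penetrating_arteriole",
    "capillary",
    "post_capillary_venule",
    "ascending_venule",
    "pial_venule",
)

#: Default diameter bands in um, half-open [lo, hi).
DIAMETER_RANGES_UM: dict[str, tuple[float, float]] = {
    "capillary": (3.0, 6.0),
    "post_capillary_venule": (6.0, 10.0),
    "penetrating_arteriole": (10.0, 25.0),
    "ascending_venule": (10.0, 25.0),
    "pial_arteriole": (25.0, 60.0),
    "pial_venule": (25.0, 100.0),
}

#: Axis orientation of each category relative to the imaging plane.
ORIENTATIONS: dict[str, str] = {
    "pial_arteriole": "in_plane",
    "pial_venule": "in_plane",
    "capillary": "in_plane",
    "post_capillary_venule": "in_plane",
    "penetrating_arteriole": "through_plane",
    "ascending_venule": "through_plane",
}

#: Arterial (True) vs venous (False) side of the tree. Capillaries sit
#: between the two; the flag is False by convention and never used to
#: classify them.
ARTERIAL: dict[str, bool] = {
    "pial_arteriole": True,
    "penetrating_arteriole": True,
    "capillary": False,
    "post_capillary_venule": False,
    "ascending_venule": False,
    "pial_venule": False,
}

#: Categories located at the brain surface (pial).
SURFACE: frozenset[str] = frozenset({"pial_arteriole", "pial_venule"})


@dataclass(frozen=True)
class VesselSegment:
    """One vessel segment with its category and cylinder geometry.

    ``label`` is the integer value identifying this segment's voxels in the
    accompanying label volume.
    """

    id: int
    category: str
    diameter_um: float
    length_um: float
    orientation: str
    arterial: bool
    label: int

    def __post_init__(self):
        if self.diameter_um <= 0 or self.length_um <= 0:
            raise ValueError(
                f"segment {self.id}: diameter and length must be positive"
            )
        if self.category not in CATEGORIES and self.category != "unclassified":
            raise ValueError(f"unknown vessel category {self.category!r}")

    @property
    def surface_area_um2(self) -> float:
        """Lateral cylinder surface pi * d * L in um^2."""
        return math.pi * self.diameter_um * self.length_um


def vessel_surface_area(diameter_um: float, length_um: float) -> float:
    """Surface area of a cylindrical vessel segment, pi * d * L (um^2)."""
    if diameter_um <= 0 or length_um <= 0:
        raise ValueError("diameter_um and length_um must be > 0")
    area = math.pi * diameter_um * length_um
    if not math.isfinite(area):
        raise ValueError("non-finite surface area")
    return area


def classify_vessel(
    diameter_um: float,
    orientation: str | None = None,
    arterial: bool | None = None,
    surface_position: bool | None = None,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> str:
    """Assign a vessel category from diameter, orientation and side.

    Decision table (defaults; bands configurable via ``ranges``):

    * d < 6 um -> capillary (regardless of flags)
    * 6 <= d < 10 um, venous -> post-capillary venule
    * 10 <= d < 25 um, through-plane: arterial -> penetrating arteriole,
      venous -> ascending venule
    * d >= 25 um, in-plane (pial surface): arterial (d < 60) -> pial
      arteriole, venous (d < 100) -> pial venule

    The arterial/venous flag must be supplied for vessels above the
    capillary band; morphology alone cannot decide it. Anything outside the
    table returns ``"unclassified"`` rather than being dropped.
    """
    r = dict(DIAMETER_RANGES_UM)
    if ranges:
        r.update(ranges)
    d = float(diameter_um)
    if d <= 0 or not math.isfinite(d):
        return "unclassified"
    if d < r["capillary"][1]:
        return "capillary"
    lo, hi = r["post_capillary_venule"]
    if lo <= d < hi and arterial is False:
        return "post_capillary_venule"
    if orientation == "through_plane" and arterial is not None:
        cat = "penetrating_arteriole" if arterial else "ascending_venule"
        lo, hi = r[cat]
        if lo <= d < hi:
            return cat
    if orientation == "in_plane" and arterial is not None and (
        surface_position is None or surface_position
    ):
        cat = "pial_arteriole" if arterial else "pial_venule"
        lo, hi = r[cat]
        if lo <= d < hi:
            return cat
    return "unclassified"
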