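"""Vessel-wall morphometry on cross-sectional label images.

On a high-resolution vessel-wall image, the outer (blood-to-adventitia)
boundary encloses the vessel area (VA) and the inner (blood-to-intima)
boundary encloses the lumen area (LA); the wall area is WA = VA - LA.
Luminal stenosis is graded against a nearby normal reference lumen:

    stenosis % = (1 - LA_target / LA_reference) * 100

with < 50% mild, 50-70% moderate, > 70% severe, and occlusion above a
configurable threshold (90% by default, 99% as a stricter variant). The
lesion's longitudinal extent along the M1 segment is classed focal
(<= 1/3 of the segment), segmental (1/3 to 2/3) or full-length (>= 2/3).

Areas are obtained by pixel counting (count * pixel_spacing^2); no
sub-pixel contour integration is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LUMEN_LABEL",
    "WALL_LABEL",
    "VesselMorphometry",
    "measure_cross_section",
    "stenosis_degree",
    "grade_stenosis",
    "classify_extent",
]

LUMEN_LABEL = 1
WALL_LABEL = 2

GRADES = ("mild", "moderate", "severe", "occlusion")
EXTENTS = ("focal", "segmental", "full_length")


@dataclass
class VesselMorphometry:
    """Areas and classifications for one vessel cross-section."""

    va: float  # mm^2, outer-boundary (vessel) area
    la: float  # mm^2, lumen area
    wa: float  # mm^2, wall area = va - la
    stenosis_pct: float | None = None
    grade: str | None = None
    extent: str | None = None

    def __post_init__(self) -> None:
        if not (self.va >= self.la >= 0):
            raise ValueError("areas must satisfy va >= la >= 0")
        if abs(self.wa - (self.va - self.la)) > 1e-9:
            raise ValueError("wa must equal va - la")
        if self.stenosis_pct is not None and not 0 <= self.stenosis_pct <= 100:
            raise ValueError("stenosis_pct must lie in [0, 100]")
        if self.grade is not None and self.grade not in GRADES:
            raise ValueError(f"unknown grade {self.grade!r}")
        if self.extent is not None and self.extent not in EXTENTS:
            raise ValueError(f"unknown extent {self.extent!r}")


def measure_cross_section(
    labeled: np.ndarray,
    pixel_spacing: float,
    lumen_label: int = LUMEN_LABEL,
    wall_label: int = WALL_LABEL,
) -> tuple[float, float, float]:
    """Pixel-count areas (va, la, wa) in mm^2 from a labeled cross-section.

    The lumen label must be present; an empty wall label simply gives
    wa = 0 (degenerate wall).
    """
    labeled = np.asarray(labeled)
    if pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be positive")
    n_lumen = int(np.count_nonzero(labeled == lumen_label))
    n_wall = int(np.count_nonzero(labeled == wall_label))
    if n_lumen == 0 and n_wall == 0:
        raise ValueError("image contains neither lumen nor wall labels")
    px = pixel_spacing**2
    la = n_lumen * px
    va = (n_lumen + n_wall) * px
    return va, la, va - la


def stenosis_degree(la_target: float, la_reference: float) -> float:
    """Percent luminal narrowing of the target relative to the reference.

    Defined as (1 - LA_target/LA_reference) * 100 clipped to [0, 100]: 0%
    means no narrowing, 100% total occlusion. (The complement LA ratio
    itself is sometimes loosely called "stenosis"; the grading thresholds
    below only make sense for the narrowing percentage, which is the
    standard convention.)
    """
    if la_reference <= 0:
        raise ValueError("la_reference must be positive")
    if la_target < 0:
        raise ValueError("la_target must be non-negative")
    return float(np.clip((1.0 - la_target / la_reference) * 100.0, 0.0, 100.0))


def grade_stenosis(stenosis_pct: float, occlusion_threshold: float = 90.0) -> str:
    """Grade a stenosis percentage: mild < 50 <= moderate <= 70 < severe,
    with occlusion above ``occlusion_threshold`` (default 90, a stricter
    99 is in clinical use)."""
    if not 0 <= stenosis_pct <= 100:
        raise ValueError("stenosis_pct must lie in [0, 100]")
    if stenosis_pct > occlusion_threshold:
        return "occlusion"
    if stenosis_pct > 70.0:
        return "severe"
    if stenosis_pct >= 50.0:
        return "moderate"
    return "mild"


def classify_extent(lesion_length: float, m1_length: float) -> str:
    """Class the lesion's longitudinal extent along the M1 segment.

    fraction <= 1/3 -> focal; 1/3 < fraction < 2/3 -> segmental;
    fraction >= 2/3 -> full_length. Boundaries follow the inclusive
    conventions at 1/3 (focal) and 2/3 (full-length).
    """
    if m1_length <= 0:
        raise ValueError("m1_length must be positive")
    if not 0 <= lesion_length <= m1_length:
        raise ValueError("lesion_length must lie in [0, m1_length]")
    f = lesion_length / m1_length
    if f <= 1.0 / 3.0:
        return "focal"
    if f < 2.0 / 3.0:
        return "segmental"
    return "full_length"
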