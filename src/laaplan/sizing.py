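"""Landing-zone sizing metrics for occluder device selection.

Four diameters characterize one cross-section of the appendage at the
landing zone:

* ``d_max`` — maximum caliper diameter,
* ``d_min`` — minimum caliper width,
* ``d_peri = p / pi`` — diameter of the circle with the section's
  perimeter ``p``,
* ``d_area = 2 sqrt(a / pi)`` — diameter of the circle with the
  section's area ``a``.

All four coincide on a circular section; their spread quantifies how
oval the section is, summarized as ``ovality = d_max - d_min``.  For a
convex section the ordering ``d_min <= d_area <= d_peri <= d_max``
always holds (isoperimetric inequality for the middle pair, Cauchy's
mean-width bounds for the outer ones).

Perimeter and area are taken on the raw contour; the caliper diameters
are taken on its convex hull, matching how calipers are placed on an
image (this choice is surfaced in the report for traceability).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from .mesh_ops import (
    PlanarSection,
    polygon_area,
    polygon_max_diameter,
    polygon_min_width,
    polygon_perimeter,
)

__all__ = ["SizingReport", "sizing_from_section", "ovality", "device_lookup"]


@dataclass(frozen=True)
class SizingReport:
    """All sizing metrics (mm) for one cross-section.

    ``source`` tags the provenance: ``"d"`` for prospectively planned
    sections, ``"d'"`` for sections located from an XR annotation.
    """

    d_max_mm: float
    d_min_mm: float
    d_peri_mm: float
    d_area_mm: float
    ovality_mm: float
    perimeter_mm: float
    area_mm2: float
    source: str = "d"

    def __post_init__(self):
        for f in ("d_max_mm", "d_min_mm", "d_peri_mm", "d_area_mm",
                  "perimeter_mm", "area_mm2"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if self.d_min_mm > self.d_max_mm + 1e-9:
            raise ValueError("d_min exceeds d_max")

    def to_dict(self) -> dict:
        return asdict(self)


def ovality(d_max: float, d_min: float) -> float:
    """Ovality of a cross-section: d_max - d_min (mm, >= 0; 0 = circular)."""
    if not (d_max >= d_min > 0):
        raise ValueError(f"need d_max >= d_min > 0, got d_max={d_max}, d_min={d_min}")
    return d_max - d_min


def sizing_from_section(section: PlanarSection, source: str = "d") -> SizingReport:
    """Compute the full sizing report from a cross-section's primary loop."""
    poly = section.polygons[0]
    p = polygon_perimeter(poly)
    a = polygon_area(poly)
    d_max, _ = polygon_max_diameter(poly)
    d_min = polygon_min_width(poly)
    return SizingReport(
        d_max_mm=d_max,
        d_min_mm=d_min,
        d_peri_mm=p / math.pi,
        d_area_mm=2.0 * math.sqrt(a / math.pi),
        ovality_mm=ovality(d_max, d_min),
        perimeter_mm=p,
        area_mm2=a,
        source=source,
    )


def device_lookup(diameter_mm: float, chart) -> str:
    """Look up a device size label from a user-supplied sizing chart.

    ``chart`` is a list of ``(lower_mm, upper_mm, label)`` with
    non-overlapping, half-open ``[lower, upper)`` intervals; a diameter
    outside every interval returns ``"no device"``.  Charts are
    deliberately user-supplied configuration: published charts are tied
    to the echo-based measurement convention and must not be baked in.
    """
    rows = [(float(lo), float(hi), str(label)) for lo, hi, label in chart]
    for lo, hi, _ in rows:
        if not lo < hi:
            raise ValueError(f"malformed chart interval [{lo}, {hi})")
    rows.sort()
    for (lo1, hi1, _), (lo2, _, _) in zip(rows, rows[1:]):
        if lo2 < hi1:
            raise ValueError(f"overlapping chart intervals at {lo2} mm")
    for lo, hi, label in rows:
        if lo <= diameter_mm < hi:
            return label
    return "no device"
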