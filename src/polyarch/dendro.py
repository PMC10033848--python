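"""Tree-ring (increment core) corrections for cores that miss the pith.

A core drilled at breast height does not always intercept the pith. When the
innermost measured ring arcs around the (missed) pith, the missed portion of
the radius can be recovered from circle geometry: the arcing latewood boundary
is treated as a circular arc of chord ``length`` and sagitta ``height``, whose
circle radius is ``L^2/(8h) + h/2``. The number of missed rings is the missed
radius divided by the mean width of the three innermost measured rings.

Heartwood/sapwood accounting follows the convention that sapwood rings are
counted from the bark inward; heartwood is everything else, and for cores
missing the bark no correction is attempted (totals are minimum estimates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass
class RingSeries:
    """Per-year ring widths (mm), oldest (pith side) to bark.

    ``arc_length``/``arc_height`` are the chord and sagitta (mm) of the arcing
    innermost ring when the pith was missed; both ``None`` when the core
    intercepted the pith.
    """

    widths: list[float]
    years: list[int] | None = None
    earlywood: list[float] | None = None
    latewood: list[float] | None = None
    arc_length: float | None = None
    arc_height: float | None = None
    bark_present: bool = True
    sapwood_rings: int = 0
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.widths):
            raise ValueError("ring widths must be non-negative")
        if self.sapwood_rings > len(self.widths):
            raise ValueError("sapwood ring count exceeds measured ring count")

    @property
    def pith_intercepted(self) -> bool:
        return self.arc_length is None


@dataclass
class DendroSummary:
    """Corrected whole-core totals derived from one :class:`RingSeries`."""

    missed_radius: float
    missed_rings: int
    pith_age: int
    total_rings: int
    total_radius: float
    sapwood_rings: int
    sapwood_radius: float
    heartwood_rings: int
    heartwood_radius: float
    sapwood_heartwood_ratio: float
    minimum_estimate: bool


def missed_radius(length: float, height: float) -> float:
    """Missed portion of the radius (mm) from the arcing inner ring.

    ``length`` is the chord and ``height`` the sagitta of the arc, both > 0.
    Returns the chord-sagitta circle radius ``L^2/(8h) + h/2``; for a
    semicircular arc (chord ``2r``, height ``r``) this returns ``r`` exactly.
    """
    if height <= 0:
        raise ValueError("arc height must be > 0")
    if length <= 0:
        raise ValueError("arc length must be > 0")
    return length * length / (8.0 * height) + height / 2.0


def missed_ring_count(missed: float, inner_three_widths) -> int:
    """Number of missed rings: missed radius over the mean inner-ring width.

    The divisor is the mean of the three measured rings closest to the pith;
    the quotient is rounded to the nearest integer, half away from zero.
    """
    if missed < 0:
        raise ValueError("missed radius must be >= 0")
    if missed == 0:
        return 0
    ws = list(inner_three_widths)
    if len(ws) < 3:
        raise ValueError("need the three innermost ring widths")
    mean_w = sum(ws[:3]) / 3.0
    if mean_w <= 0:
        raise ValueError("mean inner ring width must be > 0")
    return int(math.floor(missed / mean_w + 0.5))


def summarize_core(rs: RingSeries) -> DendroSummary:
    """Apply pith corrections and heartwood/sapwood accounting to one core."""
    if not rs.widths:
        raise ValueError("empty ring series")
    if rs.pith_intercepted:
        missed = 0.0
        n_missed = 0
    else:
        missed = missed_radius(rs.arc_length, rs.arc_height)
        n_missed = missed_ring_count(missed, rs.widths[:3])
    measured_radius = float(sum(rs.widths))
    total_radius = measured_radius + missed
    total_rings = len(rs.widths) + n_missed
    sap_n = rs.sapwood_rings
    if sap_n > total_rings:
        raise ValueError("sapwood ring count exceeds corrected total rings")
    sap_radius = float(sum(rs.widths[len(rs.widths) - sap_n:])) if sap_n else 0.0
    hw_rings = total_rings - sap_n
    hw_radius = total_radius - sap_radius
    ratio = sap_radius / hw_radius if hw_radius > 0 else math.inf
    return DendroSummary(
        missed_radius=missed,
        missed_rings=n_missed,
        pith_age=total_rings,
        total_rings=total_rings,
        total_radius=total_radius,
        sapwood_rings=sap_n,
        sapwood_radius=sap_radius,
        heartwood_rings=hw_rings,
        heartwood_radius=hw_radius,
        sapwood_heartwood_ratio=ratio,
        minimum_estimate=not rs.bark_present,
    )
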