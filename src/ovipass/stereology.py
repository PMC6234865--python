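"""Stereological estimators of total symbiont cells in an egg's symbiont ball.

Two routes from a microscopy count to a whole-ball cell number:

* **Box route** — count cells inside a sub-box of known volume (typically
  about 50 x 50 x 10 um) within the tissue and extrapolate by the ratio of
  ball volume to box volume, modelling the ball as a sphere or spheroid with
  uniformly distributed cells.  A second species intermixed in the same ball
  is then co-estimated from the two species' count ratio on a single slice.

* **Section route** — from a single 2-D cross-section count ``n`` alone.
  For a spherical ball of radius ``R`` sectioned at depth fraction ``f`` of
  the ball length (``f = 0.5`` is the great circle), the section disc has
  radius ``r = R * sqrt(4 f (1 - f))``.  The areal density on the disc,
  ``sigma = n / (pi r^2)``, converts to a volumetric density by the
  mean-spacing argument ``rho = sigma^(3/2)``, and ``N = rho * (4/3) pi R^3``
  — in which ``R`` cancels, leaving

      N = (4/3) n^(3/2) / ( sqrt(pi) * (4 f (1 - f))^(3/2) )

  Because the section position is unknown, the estimate is reported as a
  range: the lower value assumes a central section (``f = 0.5``), the upper
  assumes a section at 25% of the ball length (``f = 0.25``); their ratio is
  exactly ``(4/3)^(3/2) ~ 1.5396``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .errors import ValidationError

__all__ = [
    "BallGeometry",
    "BoxCount",
    "SectionCount",
    "CellCountEstimate",
    "ball_volume",
    "total_from_box",
    "coestimate_from_ratio",
    "total_from_section",
    "section_range",
    "average_replicates",
]


@dataclass(frozen=True)
class BallGeometry:
    """Sphere/spheroid envelope of a symbiont ball, semi-axes in um."""

    semi_axes: tuple[float, float, float]

    def __post_init__(self) -> None:
        axes = tuple(float(a) for a in self.semi_axes)
        if len(axes) != 3 or any(a <= 0 or not math.isfinite(a) for a in axes):
            raise ValidationError(f"semi-axes must be three positive numbers, got {self.semi_axes}")
        object.__setattr__(self, "semi_axes", axes)

    @classmethod
    def sphere(cls, radius: float) -> "BallGeometry":
        return cls((radius, radius, radius))

    @property
    def shape(self) -> str:
        a, b, c = self.semi_axes
        return "sphere" if a == b == c else "spheroid"

    @property
    def volume(self) -> float:
        """Envelope volume in um^3: (4/3) pi a b c."""
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * math.pi * a * b * c


@dataclass(frozen=True)
class BoxCount:
    """Cells counted inside a rectangular sub-volume (dimensions in um)."""

    cells_in_box: float
    box_dimensions: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.cells_in_box < 0:
            raise ValidationError(f"cells_in_box must be >= 0, got {self.cells_in_box}")
        dims = tuple(float(d) for d in self.box_dimensions)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ValidationError(f"box dimensions must be three positive numbers, got {self.box_dimensions}")
        object.__setattr__(self, "box_dimensions", dims)

    @property
    def volume(self) -> float:
        x, y, z = self.box_dimensions
        return x * y * z


@dataclass(frozen=True)
class SectionCount:
    """Cells observed on one cross-section of a ball.

    ``n`` may be fractional (published counts are sometimes approximate).
    ``position_fraction`` is the section's depth as a fraction of the ball
    length measured from the nearer edge, in (0, 0.5]; 0.5 is a section
    through the center.
    """

    n: float
    position_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValidationError(f"section count must be >= 0, got {self.n}")
        if not 0.0 < self.position_fraction <= 0.5:
            raise ValidationError(
                f"position_fraction must be in (0, 0.5], got {self.position_fraction}"
            )


@dataclass(frozen=True)
class CellCountEstimate:
    """Point estimate and bounds of total cells in a ball, with provenance."""

    point_estimate: float
    lower: float
    upper: float
    method: str  # box | section | ratio
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.lower <= self.point_estimate <= self.upper):
            raise ValidationError(
                f"estimate bounds must satisfy 0 <= lower <= point <= upper, got "
                f"({self.lower}, {self.point_estimate}, {self.upper})"
            )

    def to_dict(self) -> dict:
        return {
            "point_estimate": self.point_estimate,
            "lower": self.lower,
            "upper": self.upper,
            "method": self.method,
            "inputs": self.inputs,
        }


def ball_volume(geometry: BallGeometry) -> float:
    """Volume of the ball envelope in um^3."""
    return geometry.volume


def total_from_box(box: BoxCount, geometry: BallGeometry) -> CellCountEstimate:
    """Extrapolate a sub-box count to the whole ball by the volume ratio.

    Assumes cells are uniformly distributed, so the whole-ball total is
    ``cells_in_box * V_ball / V_box``.  The box and ball must share units.
    """
    if box.volume > geometry.volume:
        raise ValidationError(
            f"box volume {box.volume:.4g} um^3 exceeds ball volume {geometry.volume:.4g} um^3"
        )
    estimate = box.cells_in_box * geometry.volume / box.volume
    return CellCountEstimate(
        point_estimate=estimate,
        lower=estimate,
        upper=estimate,
        method="box",
        inputs={
            "cells_in_box": box.cells_in_box,
            "box_dimensions": box.box_dimensions,
            "semi_axes": geometry.semi_axes,
        },
    )


def coestimate_from_ratio(n_reference: float, ratio_target_to_reference: float) -> float:
    """Estimate a second, intermixed species from the reference-species total.

    Given the whole-ball count of a reference species and the target:reference
    cell ratio observed on a single slice, the target total is simply
    ``n_reference * ratio``.
    """
    if n_reference < 0:
        raise ValidationError(f"n_reference must be >= 0, got {n_reference}")
    if ratio_target_to_reference <= 0:
        raise ValidationError(f"ratio must be > 0, got {ratio_target_to_reference}")
    return n_reference * ratio_target_to_reference


def total_from_section(
    n: float | SectionCount, position_fraction: float = 0.5, *, rounded: bool = True
) -> float:
    """Total cells in a spherical ball from a single cross-section count.

    ``N = (4/3) n^(3/2) / (sqrt(pi) * (4 f (1-f))^(3/2))`` with ``f`` the
    section's depth fraction (see module docstring for the derivation).
    Rounded to the nearest integer by default.
    """
    if isinstance(n, SectionCount):
        section = n
    else:
        section = SectionCount(n=float(n), position_fraction=position_fraction)
    f = section.position_fraction
    disc = 4.0 * f * (1.0 - f)  # (r/R)^2 for a sphere sectioned at depth f
    estimate = (4.0 / 3.0) * section.n**1.5 / (math.sqrt(math.pi) * disc**1.5)
    return float(round(estimate)) if rounded else estimate


def section_range(n: float) -> CellCountEstimate:
    """Lower/upper whole-ball estimate from one section of unknown position.

    Lower bound: central section (``f = 0.5``); upper bound: section at 25%
    of the ball length (``f = 0.25``).  The point estimate is by convention
    the lower, central-section value.
    """
    if n < 0:
        raise ValidationError(f"section count must be >= 0, got {n}")
    lower = total_from_section(n, 0.5)
    upper = total_from_section(n, 0.25)
    return CellCountEstimate(
        point_estimate=lower,
        lower=lower,
        upper=upper,
        method="section",
        inputs={"n": n, "f_lower": 0.5, "f_upper": 0.25},
    )


def average_replicates(estimates: Sequence[CellCountEstimate]) -> CellCountEstimate:
    """Arithmetic mean of replicate estimates (same method required)."""
    if not estimates:
        raise ValidationError("cannot average an empty list of estimates")
    methods = {e.method for e in estimates}
    if len(methods) > 1:
        raise ValidationError(f"cannot average estimates from mixed methods: {sorted(methods)}")
    k = len(estimates)
    return CellCountEstimate(
        point_estimate=sum(e.point_estimate for e in estimates) / k,
        lower=sum(e.lower for e in estimates) / k,
        upper=sum(e.upper for e in estimates) / k,
        method=methods.pop(),
        inputs={"n_replicates": k, "replicates": [e.inputs for e in estimates]},
    )
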