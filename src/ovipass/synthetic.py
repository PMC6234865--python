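"""Synthetic data with the statistical structure the estimators assume.

Two generators:

* 3-D point-cloud "symbiont balls": two intermixed cell species placed
  uniformly at random inside a sphere or spheroid, with virtual sectioning
  (a thin slab) and virtual box extraction so the stereological estimators
  can be exercised against a known ground truth.
* Egg-composition tables: independent multinomial draws from a lineage
  profile, the raw material of the transmission simulator.

Uniform sampling inside an ellipsoid is done exactly by drawing uniformly in
the unit ball (isotropic direction times a cube-root-distributed radius) and
scaling each axis by its semi-axis; no rejection, so output is seed-stable
and cheap.  Cells are points: no diameter, overlap or optical-blur model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .profiles import LineageProfile
from .stereology import BallGeometry, BoxCount, SectionCount

__all__ = [
    "SyntheticBall",
    "EggCompositionTable",
    "generate_ball",
    "virtual_section",
    "virtual_box",
    "generate_egg_table",
]


@dataclass(frozen=True)
class SyntheticBall:
    """Point-cloud ball of two cell species inside a known envelope (um)."""

    geometry: BallGeometry
    points_a: np.ndarray  # (N_a, 3)
    points_b: np.ndarray  # (N_b, 3)
    seed: int

    @property
    def n_a(self) -> int:
        return len(self.points_a)

    @property
    def n_b(self) -> int:
        return len(self.points_b)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: species, x, y, z."""
        frames = []
        for species, pts in (("A", self.points_a), ("B", self.points_b)):
            df = pd.DataFrame(pts, columns=["x", "y", "z"])
            df.insert(0, "species", species)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class EggCompositionTable:
    """Per-egg lineage compositions: rows are eggs, columns are lineages."""

    table: pd.DataFrame
    profile: LineageProfile
    n_cells: int
    seed: int


def _uniform_in_unit_ball(n: int, rng: np.random.Generator) -> np.ndarray:
    if n == 0:
        return np.empty((0, 3))
    direction = rng.normal(size=(n, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    radius = rng.random(n) ** (1.0 / 3.0)
    return direction * radius[:, None]


def generate_ball(
    n_a: int, n_b: int, geometry: BallGeometry, seed: int = 0
) -> SyntheticBall:
    """Ball with ``n_a`` species-A and ``n_b`` species-B cells, uniform in the envelope."""
    if n_a < 0 or n_b < 0:
        raise ValidationError(f"cell counts must be >= 0, got ({n_a}, {n_b})")
    rng = np.random.default_rng(seed)
    axes = np.asarray(geometry.semi_axes)
    points_a = _uniform_in_unit_ball(n_a, rng) * axes
    points_b = _uniform_in_unit_ball(n_b, rng) * axes
    return SyntheticBall(geometry=geometry, points_a=points_a, points_b=points_b, seed=seed)


def virtual_section(
    ball: SyntheticBall, f: float, thickness: float
) -> tuple[SectionCount, SectionCount]:
    """Counts of each species in a thin slab at depth fraction ``f`` of the ball.

    The slab is perpendicular to the z-axis, centered at depth ``f`` of the
    ball's z-extent measured from the lower edge (``f = 0.5`` is central),
    with the given thickness in um.  A slab outside the envelope simply
    counts zero.
    """
    if not 0.0 < f <= 0.5:
        raise ValidationError(f"section position must be in (0, 0.5], got {f}")
    if thickness <= 0:
        raise ValidationError(f"slab thickness must be > 0, got {thickness}")
    c = ball.geometry.semi_axes[2]
    z_center = -c + f * 2.0 * c
    lo, hi = z_center - thickness / 2.0, z_center + thickness / 2.0

    def count(points: np.ndarray) -> int:
        if len(points) == 0:
            return 0
        z = points[:, 2]
        return int(np.count_nonzero((z >= lo) & (z <= hi)))

    return (
        SectionCount(n=count(ball.points_a), position_fraction=f),
        SectionCount(n=count(ball.points_b), position_fraction=f),
    )


def virtual_box(
    ball: SyntheticBall,
    origin: tuple[float, float, float],
    dimensions: tuple[float, float, float],
) -> tuple[BoxCount, BoxCount]:
    """Exact per-species counts inside an axis-aligned box (corner at ``origin``).

    The box must lie entirely inside the ball envelope (all eight corners
    inside the ellipsoid), mirroring a counting box placed within the tissue.
    """
    origin = np.asarray(origin, dtype=float)
    dims = np.asarray(dimensions, dtype=float)
    if dims.shape != (3,) or (dims <= 0).any():
        raise ValidationError(f"box dimensions must be three positive numbers, got {dimensions}")
    axes = np.asarray(ball.geometry.semi_axes)
    corners = origin + dims * np.array(np.meshgrid([0, 1], [0, 1], [0, 1])).T.reshape(-1, 3)
    if (np.sum((corners / axes) ** 2, axis=1) > 1.0 + 1e-12).any():
        raise ValidationError(
            f"box origin={tuple(origin)} dims={tuple(dims)} is not fully inside "
            f"the ball envelope with semi-axes {ball.geometry.semi_axes}"
        )
    lo, hi = origin, origin + dims

    def count(points: np.ndarray) -> int:
        if len(points) == 0:
            return 0
        inside = ((points >= lo) & (points <= hi)).all(axis=1)
        return int(np.count_nonzero(inside))

    dims_t = tuple(float(d) for d in dims)
    return (
        BoxCount(cells_in_box=count(ball.points_a), box_dimensions=dims_t),
        BoxCount(cells_in_box=count(ball.points_b), box_dimensions=dims_t),
    )


def generate_egg_table(
    profile: LineageProfile, n_cells: int, n_eggs: int, seed: int = 0
) -> EggCompositionTable:
    """Table of ``n_eggs`` independent multinomial egg compositions.

    Each row is one egg's per-lineage cell counts and sums to ``n_cells``.
    """
    if n_cells < 0 or n_eggs < 0:
        raise ValidationError(f"n_cells and n_eggs must be >= 0, got ({n_cells}, {n_eggs})")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_cells, profile.as_array(), size=n_eggs)
    table = pd.DataFrame(counts, columns=list(profile.labels))
    return EggCompositionTable(table=table, profile=profile, n_cells=n_cells, seed=seed)
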