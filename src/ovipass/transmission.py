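"""Monte-Carlo model of symbiont transmission to eggs.

The model: a mother transmits ``N`` symbiont cells to each egg, each cell
drawn independently from her lineage-abundance profile ``p`` (sampling with
replacement).  The egg's per-lineage composition is therefore one multinomial
draw of size ``N`` — implemented as such, which is distributionally identical
to sequential categorical sampling and far faster.  An egg is *viable* when
it received at least ``k_i`` cells of every lineage ``i`` (the classic
coupon-collector requirement, generalized to ``k`` copies per coupon).

The central question is the minimal transmission number: the smallest ``N``
at which *all* simulated eggs (10,000 by default) are viable.  Exact oracles
are provided alongside the simulator — an inclusion–exclusion closed form
for the ``k = 1`` criterion and a brute-force enumeration over egg
compositions for tiny instances — so the Monte-Carlo path is independently
checkable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CapabilityError, ValidationError
from .profiles import LineageProfile

__all__ = [
    "ViabilityCriterion",
    "SimulationConfig",
    "CurvePoint",
    "ViabilityCurve",
    "MinimalTransmission",
    "simulate_egg",
    "simulate_eggs",
    "is_viable",
    "proportion_viable",
    "viability_sweep",
    "analytic_viability_k1",
    "brute_force_viability",
    "minimal_cells_for_all_viable",
    "fold_difference",
    "expected_rare_cells",
]

#: Number of simulated eggs per grid point.
DEFAULT_ITERATIONS = 10_000
#: Grid of transmitted-cell counts: start, ceiling and step.
DEFAULT_GRID_START = 1
DEFAULT_GRID_MAX = 2_000
DEFAULT_GRID_STEP = 20
#: Eggs are simulated in blocks so an all-viable check can stop at the first
#: failing block; block layout is fixed so results are seed-stable.
_EGG_BLOCK = 1_000

# subset enumeration is O(2^L); beyond this many lineages use the simulator
_MAX_ANALYTIC_LINEAGES = 25
# brute force enumerates C(N+L-1, L-1) compositions
_MAX_BRUTE_FORCE_OUTCOMES = 1_000_000


@dataclass(frozen=True)
class ViabilityCriterion:
    """Minimum cells of each lineage an egg must receive to be viable.

    ``min_cells`` is either one integer applied to every lineage or a
    per-lineage vector.
    """

    min_cells: int | tuple[int, ...] = 1

    def __post_init__(self) -> None:
        mc = self.min_cells
        if isinstance(mc, Iterable) and not isinstance(mc, (str, bytes)):
            mc = tuple(int(k) for k in mc)
        else:
            mc = int(mc)
        ks = mc if isinstance(mc, tuple) else (mc,)
        if any(k < 1 for k in ks):
            raise ValidationError(f"every per-lineage minimum must be >= 1, got {mc}")
        object.__setattr__(self, "min_cells", mc)

    def thresholds(self, n_lineages: int) -> np.ndarray:
        """Per-lineage thresholds ``k_i`` as an int vector of length ``n_lineages``."""
        if isinstance(self.min_cells, tuple):
            if len(self.min_cells) != n_lineages:
                raise ValidationError(
                    f"criterion has {len(self.min_cells)} thresholds but profile has "
                    f"{n_lineages} lineages"
                )
            return np.asarray(self.min_cells, dtype=np.int64)
        return np.full(n_lineages, self.min_cells, dtype=np.int64)

    def describe(self) -> int | list[int]:
        return list(self.min_cells) if isinstance(self.min_cells, tuple) else self.min_cells


@dataclass(frozen=True)
class SimulationConfig:
    """Grid and replication settings for a viability sweep."""

    iterations: int = DEFAULT_ITERATIONS
    cell_grid: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValidationError(f"iterations must be >= 1, got {self.iterations}")
        grid = tuple(int(n) for n in self.cell_grid)
        if not grid:
            grid = tuple(range(DEFAULT_GRID_START, DEFAULT_GRID_MAX + 1, DEFAULT_GRID_STEP))
        if any(n < 1 for n in grid) or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValidationError("cell_grid must be strictly increasing with all N >= 1")
        object.__setattr__(self, "cell_grid", grid)


@dataclass(frozen=True)
class CurvePoint:
    """One grid point of a viability curve."""

    n_cells: int
    proportion_viable: float
    viable_count: int
    iterations: int


@dataclass(frozen=True)
class ViabilityCurve:
    """Proportion of viable eggs as a function of cells transmitted."""

    points: tuple[CurvePoint, ...]
    profile_labels: tuple[str, ...]
    criterion: ViabilityCriterion
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_cells": [p.n_cells for p in self.points],
                "proportion_viable": [p.proportion_viable for p in self.points],
                "viable_count": [p.viable_count for p in self.points],
                "iterations": [p.iterations for p in self.points],
            }
        )


@dataclass(frozen=True)
class MinimalTransmission:
    """Smallest grid value of N at which every simulated egg was viable.

    ``found`` is False when no grid point up to ``grid_max`` was all-viable;
    then ``n_min`` is None (a sentinel result, not an error, so sweeps over
    harsh criteria complete).  ``recheck_proportion`` is the viable fraction
    observed when the returned N was re-simulated with an independent seed.
    """

    n_min: int | None
    found: bool
    criterion: ViabilityCriterion
    iterations: int
    seed: int
    grid_step: int
    grid_start: int
    grid_max: int
    recheck_proportion: float | None = None

    def to_dict(self) -> dict:
        return {
            "n_min": self.n_min,
            "found": self.found,
            "min_cells": self.criterion.describe(),
            "iterations": self.iterations,
            "seed": self.seed,
            "grid_start": self.grid_start,
            "grid_step": self.grid_step,
            "grid_max": self.grid_max,
            "recheck_proportion": self.recheck_proportion,
        }


# ---------------------------------------------------------------------------
# sampling


def _point_rng(seed: int, n_cells: int, salt: int = 0) -> np.random.Generator:
    # independent, reproducible stream per (seed, grid point): changing the
    # grid layout or iteration count never reshuffles other points' eggs
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(salt), int(n_cells)]))


def simulate_egg(
    profile: LineageProfile, n_cells: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-lineage cell counts of one egg: a multinomial draw of size ``n_cells``."""
    if n_cells < 0:
        raise ValidationError(f"cannot transmit a negative number of cells: {n_cells}")
    return rng.multinomial(n_cells, profile.as_array())


def simulate_eggs(
    profile: LineageProfile, n_cells: int, n_eggs: int, rng: np.random.Generator
) -> np.ndarray:
    """Compositions of ``n_eggs`` independent eggs, shape ``(n_eggs, n_lineages)``."""
    if n_cells < 0:
        raise ValidationError(f"cannot transmit a negative number of cells: {n_cells}")
    if n_eggs < 0:
        raise ValidationError(f"n_eggs must be >= 0, got {n_eggs}")
    return rng.multinomial(n_cells, profile.as_array(), size=n_eggs)


def is_viable(
    counts: Sequence[int] | np.ndarray, criterion: ViabilityCriterion | int = 1
) -> bool | np.ndarray:
    """Whether an egg (or each row of a batch) meets the viability criterion.

    ``counts`` is a per-lineage count vector or a 2-D array of eggs x lineages.
    """
    if not isinstance(criterion, ViabilityCriterion):
        criterion = ViabilityCriterion(criterion)
    arr = np.asarray(counts)
    ks = criterion.thresholds(arr.shape[-1])
    ok = (arr >= ks).all(axis=-1)
    return bool(ok) if arr.ndim == 1 else ok


def proportion_viable(
    profile: LineageProfile,
    n_cells: int,
    criterion: ViabilityCriterion | int = 1,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
) -> CurvePoint:
    """Simulated fraction of viable eggs at one transmitted-cell count."""
    if not isinstance(criterion, ViabilityCriterion):
        criterion = ViabilityCriterion(criterion)
    rng = _point_rng(seed, n_cells)
    eggs = simulate_eggs(profile, n_cells, iterations, rng)
    viable = int(np.count_nonzero(is_viable(eggs, criterion)))
    return CurvePoint(
        n_cells=int(n_cells),
        proportion_viable=viable / iterations,
        viable_count=viable,
        iterations=iterations,
    )


def viability_sweep(
    profiles: Sequence[LineageProfile] | LineageProfile,
    config: SimulationConfig | None = None,
    criterion: ViabilityCriterion | int = 1,
) -> list[ViabilityCurve]:
    """One viability curve per profile over the config's cell grid."""
    if isinstance(profiles, LineageProfile):
        profiles = [profiles]
    config = config or SimulationConfig()
    if not isinstance(criterion, ViabilityCriterion):
        criterion = ViabilityCriterion(criterion)
    curves = []
    for profile in profiles:
        points = tuple(
            proportion_viable(profile, n, criterion, config.iterations, config.seed)
            for n in config.cell_grid
        )
        curves.append(
            ViabilityCurve(
                points=points,
                profile_labels=profile.labels,
                criterion=criterion,
                seed=config.seed,
            )
        )
    return curves


def sweep_frame(curves: Sequence[ViabilityCurve], names: Sequence[str] | None = None) -> pd.DataFrame:
    """Long-format table of several viability curves (CSV-ready)."""
    frames = []
    for i, curve in enumerate(curves):
        df = curve.to_frame()
        df.insert(0, "profile", names[i] if names is not None else f"profile_{i + 1}")
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# exact oracles


def analytic_viability_k1(profile: LineageProfile, n_cells: int) -> float:
    """Exact probability that ``n_cells`` multinomial draws cover every lineage.

    Inclusion–exclusion over lineage subsets S:
    ``P = sum_S (-1)^|S| (1 - sum_{i in S} p_i)^N``.  Applies only to the
    ``k = 1`` criterion; O(2^L), guarded at L = 25.
    """
    if n_cells < 0:
        raise ValidationError(f"n_cells must be >= 0, got {n_cells}")
    L = len(profile)
    if L > _MAX_ANALYTIC_LINEAGES:
        raise CapabilityError(
            f"inclusion-exclusion over 2^{L} subsets is infeasible; "
            "use proportion_viable (Monte-Carlo) instead"
        )
    p = profile.as_array()
    total = 0.0
    for size in range(L + 1):
        sign = -1.0 if size % 2 else 1.0
        for subset in itertools.combinations(range(L), size):
            miss = 1.0 - p[list(subset)].sum()
            # 0^0 = 1: the full-lineage subset still contributes when N = 0
            term = miss**n_cells if (miss > 0.0 or n_cells == 0) else 0.0
            total += sign * term
    return min(max(total, 0.0), 1.0)


def brute_force_viability(
    profile: LineageProfile, n_cells: int, criterion: ViabilityCriterion | int = 1
) -> float:
    """Exact viability probability by enumerating every egg composition.

    Sums the multinomial pmf over all compositions of ``n_cells`` into
    ``n_lineages`` parts that satisfy the criterion.  Only for tiny instances
    (guard: at most 10^6 compositions).
    """
    if not isinstance(criterion, ViabilityCriterion):
        criterion = ViabilityCriterion(criterion)
    if n_cells < 0:
        raise ValidationError(f"n_cells must be >= 0, got {n_cells}")
    L = len(profile)
    n_outcomes = math.comb(n_cells + L - 1, L - 1)
    if n_outcomes > _MAX_BRUTE_FORCE_OUTCOMES:
        raise CapabilityError(
            f"{n_outcomes} egg compositions exceed the enumeration guard "
            f"({_MAX_BRUTE_FORCE_OUTCOMES}); use the simulator or the analytic oracle"
        )
    ks = criterion.thresholds(L)
    if ks.sum() > n_cells:
        return 0.0
    p = profile.as_array()
    dist = stats.multinomial(n_cells, p)

    def compositions(total: int, parts: int):
        if parts == 1:
            yield (total,)
            return
        for head in range(total + 1):
            for tail in compositions(total - head, parts - 1):
                yield (head, *tail)

    viable = [c for c in compositions(n_cells, L) if all(ci >= ki for ci, ki in zip(c, ks))]
    if not viable:
        return 0.0
    return float(np.sum(dist.pmf(np.asarray(viable))))


# ---------------------------------------------------------------------------
# minimal transmission number


def _all_viable(
    profile: LineageProfile,
    n_cells: int,
    ks: np.ndarray,
    iterations: int,
    seed: int,
    salt: int = 0,
) -> bool:
    """True iff every one of ``iterations`` eggs meets the thresholds.

    Eggs are drawn in fixed-size blocks; the check stops at the first block
    containing a failing egg.  The block layout is deterministic, so the
    outcome for a given (seed, N) never depends on other grid points.
    """
    rng = _point_rng(seed, n_cells, salt)
    p = profile.as_array()
    remaining = iterations
    while remaining > 0:
        block = min(_EGG_BLOCK, remaining)
        eggs = rng.multinomial(n_cells, p, size=block)
        if not (eggs >= ks).all():
            return False
        remaining -= block
    return True


def minimal_cells_for_all_viable(
    profile: LineageProfile,
    criterion: ViabilityCriterion | int = 1,
    iterations: int = DEFAULT_ITERATIONS,
    grid_step: int = DEFAULT_GRID_STEP,
    seed: int = 0,
    grid_start: int = DEFAULT_GRID_START,
    grid_max: int = DEFAULT_GRID_MAX,
    auto_extend: bool = True,
    recheck: bool = True,
) -> MinimalTransmission:
    """Smallest grid value of N at which all simulated eggs are viable.

    Scans N upward from ``grid_start`` in steps of ``grid_step``; at each N,
    ``iterations`` eggs are simulated and the first N with no failing egg is
    returned.  When ``auto_extend`` is set the grid ceiling doubles until the
    answer is found (harsh criteria need far more than the default 2,000-cell
    ceiling); otherwise an unreachable criterion yields a sentinel result
    with ``found=False``.

    With ``recheck`` the returned N is re-simulated once under an independent
    seed and the observed viable fraction reported, as a guard against a
    lucky all-viable grid point.
    """
    if not isinstance(criterion, ViabilityCriterion):
        criterion = ViabilityCriterion(criterion)
    if grid_step < 1:
        raise ValidationError(f"grid_step must be >= 1, got {grid_step}")
    ks = criterion.thresholds(len(profile))
    ceiling = grid_max
    n = grid_start
    n_min: int | None = None
    while True:
        while n <= ceiling:
            # eggs with fewer cells than the summed thresholds can never be viable
            if n >= int(ks.sum()) and _all_viable(profile, n, ks, iterations, seed):
                n_min = n
                break
            n += grid_step
        if n_min is not None or not auto_extend:
            break
        ceiling *= 2

    recheck_prop = None
    if n_min is not None and recheck:
        point = proportion_viable(profile, n_min, criterion, iterations, seed=seed + 1)
        recheck_prop = point.proportion_viable

    return MinimalTransmission(
        n_min=n_min,
        found=n_min is not None,
        criterion=criterion,
        iterations=iterations,
        seed=seed,
        grid_step=grid_step,
        grid_start=grid_start,
        grid_max=ceiling,
        recheck_proportion=recheck_prop,
    )


def fold_difference(a: MinimalTransmission, b: MinimalTransmission) -> float:
    """Ratio of two minimal transmission numbers, ``a.n_min / b.n_min``."""
    if not (a.found and b.found):
        raise ValidationError("fold_difference requires both minimal-N searches to have succeeded")
    return a.n_min / b.n_min


def expected_rare_cells(total_cells: float, p_min: float) -> float:
    """Expected cells of the rarest lineage among ``total_cells`` transmitted.

    Under multinomial sampling the expectation is simply ``total_cells * p_min``;
    e.g. a lineage at 0.8% of a 10,000-cell transmission averages 80 cells.
    """
    if not 0.0 < p_min <= 1.0:
        raise ValidationError(f"p_min must be in (0, 1], got {p_min}")
    return total_cells * p_min
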