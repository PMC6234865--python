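"""Lineage-abundance profiles.

A :class:`LineageProfile` holds the relative abundances ``p_i`` of the
cellular lineages of an endosymbiont population in a mother insect.  These
proportions drive the multinomial egg-provisioning model in
:mod:`ovipass.transmission`: each cell placed into an egg belongs to lineage
``i`` with probability ``p_i``.

Profiles can be constructed from raw (unnormalized) weights such as
sequencing coverages, built synthetically as geometric abundance ladders
constrained only by lineage count and fold-range, and round-tripped through
TSV or JSON files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ProfileParseError, ValidationError

__all__ = [
    "LineageProfile",
    "normalize",
    "make_geometric_profile",
    "abundance_range",
    "read_profile",
    "write_profile",
]

#: Tolerance on ``sum(p_i) == 1`` after normalization.
SUM_TOLERANCE = 1e-9


@dataclass(frozen=True)
class LineageProfile:
    """Ordered relative abundances of symbiont lineages.

    Parameters
    ----------
    labels
        One identifier per lineage.
    proportions
        Relative abundances ``p_i``; strictly positive, summing to 1.
    """

    labels: tuple[str, ...]
    proportions: tuple[float, ...]

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        props = tuple(float(x) for x in self.proportions)
        if len(labels) != len(props) or len(props) < 1:
            raise ValidationError(
                "labels and proportions must have equal, non-zero length; "
                f"got {len(labels)} labels and {len(props)} proportions"
            )
        if len(set(labels)) != len(labels):
            raise ValidationError(f"duplicate lineage labels in {labels}")
        if any(p <= 0 or not math.isfinite(p) for p in props):
            raise ValidationError(f"all proportions must be positive and finite, got {props}")
        if abs(sum(props) - 1.0) > SUM_TOLERANCE:
            raise ValidationError(
                f"proportions must sum to 1 within {SUM_TOLERANCE}; got sum {sum(props)!r}. "
                "Use ovipass.profiles.normalize() to build a profile from raw weights."
            )
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "proportions", props)

    def __len__(self) -> int:
        return len(self.proportions)

    def as_array(self) -> np.ndarray:
        """Proportions as a float ndarray (a copy)."""
        return np.asarray(self.proportions, dtype=float)

    @property
    def n_lineages(self) -> int:
        return len(self.proportions)

    @property
    def p_min(self) -> float:
        """Proportion of the least abundant lineage."""
        return min(self.proportions)

    def permuted(self, order: Sequence[int]) -> "LineageProfile":
        """Return the profile with lineages reordered by ``order`` (a permutation)."""
        if sorted(order) != list(range(len(self))):
            raise ValidationError(f"{order!r} is not a permutation of 0..{len(self) - 1}")
        return LineageProfile(
            labels=tuple(self.labels[i] for i in order),
            proportions=tuple(self.proportions[i] for i in order),
        )


def normalize(
    raw_weights: Iterable[float], labels: Sequence[str] | None = None
) -> LineageProfile:
    """Build a profile from positive raw weights (e.g. sequencing coverages).

    Order is preserved; weights are divided by their sum.  Labels default to
    ``L1, L2, ...``.
    """
    weights = [float(w) for w in raw_weights]
    if not weights:
        raise ValidationError("cannot build a profile from an empty weight list")
    if any(w <= 0 or not math.isfinite(w) for w in weights):
        raise ValidationError(f"all weights must be positive and finite, got {weights}")
    if labels is None:
        labels = tuple(f"L{i + 1}" for i in range(len(weights)))
    total = math.fsum(weights)
    props = [w / total for w in weights]
    # fsum-based renormalization leaves a residual below 1e-15; fold it into
    # the largest entry so the stored tuple sums to 1 as exactly as floats allow
    residual = 1.0 - math.fsum(props)
    if residual != 0.0:
        i = props.index(max(props))
        props[i] += residual
    return LineageProfile(labels=tuple(labels), proportions=tuple(props))


def make_geometric_profile(n_lineages: int, fold_range: float) -> LineageProfile:
    """Synthetic profile whose proportions form a geometric ladder.

    The ladder is the canonical stand-in when only the lineage count and the
    fold-range (``max(p_i)/min(p_i)``) of a community are known, e.g. "30
    lineages spanning a 74-fold abundance range".  Proportions are stored
    most-abundant-first.

    Parameters
    ----------
    n_lineages
        Number of lineages, >= 1.
    fold_range
        Ratio of the most to the least abundant lineage, >= 1.  Must be 1
        when ``n_lineages`` is 1.
    """
    if n_lineages < 1:
        raise ValidationError(f"n_lineages must be >= 1, got {n_lineages}")
    if fold_range < 1:
        raise ValidationError(f"fold_range must be >= 1, got {fold_range}")
    if n_lineages == 1:
        if fold_range != 1:
            raise ValidationError("a single-lineage profile cannot have fold_range > 1")
        return normalize([1.0])
    ratio = fold_range ** (-1.0 / (n_lineages - 1))
    weights = [ratio**i for i in range(n_lineages)]
    return normalize(weights)


def abundance_range(profile: LineageProfile) -> float:
    """Fold-range of the profile: ``max(p_i) / min(p_i)``."""
    return max(profile.proportions) / min(profile.proportions)


TSV_HEADER = "lineage\tweight"


def write_profile(profile: LineageProfile, path: str | Path) -> None:
    """Write a profile as TSV (``lineage<TAB>weight``) or JSON, by file suffix."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {"labels": list(profile.labels), "weights": list(profile.proportions)}
        path.write_text(json.dumps(doc, indent=1) + "\n")
    else:
        lines = [TSV_HEADER]
        lines += [f"{lab}\t{p!r}" for lab, p in zip(profile.labels, profile.proportions)]
        path.write_text("\n".join(lines) + "\n")


def read_profile(path: str | Path) -> LineageProfile:
    """Read a profile from TSV or JSON; weights are renormalized.

    Raises :class:`ProfileParseError` naming the offending line for malformed
    rows, duplicate labels, or non-positive / non-numeric weights.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ProfileParseError(f"{path}: invalid JSON: {exc}") from exc
        if not isinstance(doc, dict) or "weights" not in doc:
            raise ProfileParseError(f'{path}: JSON profile must be {{"labels": [...], "weights": [...]}}')
        labels = doc.get("labels") or [f"L{i + 1}" for i in range(len(doc["weights"]))]
        try:
            return normalize(doc["weights"], labels=labels)
        except ValidationError as exc:
            raise ProfileParseError(f"{path}: {exc}") from exc

    labels: list[str] = []
    weights: list[float] = []
    lines = path.read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if lineno == 1 and line.strip().lower().replace(" ", "") in ("lineage\tweight", "lineage weight"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ProfileParseError(f"{path}:{lineno}: expected 2 tab-separated fields, got {len(parts)}: {line!r}")
        label, raw = parts[0].strip(), parts[1].strip()
        try:
            weight = float(raw)
        except ValueError as exc:
            raise ProfileParseError(f"{path}:{lineno}: non-numeric weight {raw!r}") from exc
        if weight <= 0:
            raise ProfileParseError(f"{path}:{lineno}: weight must be positive, got {raw!r}")
        if label in labels:
            raise ProfileParseError(f"{path}:{lineno}: duplicate lineage label {label!r}")
        labels.append(label)
        weights.append(weight)
    if not labels:
        raise ProfileParseError(f"{path}: no lineage rows found")
    return normalize(weights, labels=labels)
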