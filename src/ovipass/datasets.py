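"""Built-in reference inputs.

``SIX_LINEAGE_PROFILE`` is the canonical six-lineage *Hodgkinia* abundance
vector (69-fold range, rarest lineage 0.9%) used throughout as the
*Tettigades chilensis*-like community; ``thirty_lineage_profile()`` builds
the *Magicicada*-like stand-in, a 30-lineage geometric ladder spanning a
74-fold range (only the lineage count and fold-range of that community are
published, not the full coverage vector).

``CROSS_SECTION_COMPENDIUM`` collects published symbiont-ball cross-section
counts for hemipteran insects together with the whole-ball estimate ranges
printed alongside them, for checking the single-section estimator.  Rows
whose printed count carries a "~" are approximate; for those the printed
bounds can sit a few cells off any integer-count prediction because the
underlying unrounded counts were not published.
"""

from __future__ import annotations

from dataclasses import dataclass

from .profiles import LineageProfile, make_geometric_profile, normalize

__all__ = [
    "SIX_LINEAGE_PROFILE",
    "thirty_lineage_profile",
    "CrossSectionRecord",
    "CROSS_SECTION_COMPENDIUM",
]

#: Six-lineage community, most-abundant-first; fold-range 0.621/0.009 = 69.
SIX_LINEAGE_PROFILE: LineageProfile = normalize(
    [0.621, 0.18, 0.10, 0.06, 0.03, 0.009],
    labels=("hodg1", "hodg2", "hodg3", "hodg4", "hodg5", "hodg6"),
)


def thirty_lineage_profile() -> LineageProfile:
    """30-lineage geometric ladder with a 74-fold abundance range."""
    return make_geometric_profile(30, 74.0)


@dataclass(frozen=True)
class CrossSectionRecord:
    """One published single-section count with its printed whole-ball range."""

    host: str
    symbionts: str
    n: int  # cells counted on the cross-section
    printed_lower: int  # printed central-section estimate
    printed_upper: int  # printed 25%-depth estimate
    approximate: bool = False  # printed count carried a "~"


#: Published single-cross-section counts and printed estimate ranges.
CROSS_SECTION_COMPENDIUM: tuple[CrossSectionRecord, ...] = (
    CrossSectionRecord("Ceroputo pilosellae", "Tremblaya phenacola", 20, 67, 104),
    CrossSectionRecord("Phenacoccus aceris", "Tremblaya phenacola", 21, 72, 111),
    CrossSectionRecord("Trionymus thulensis", "Tremblaya princeps", 21, 72, 111),
    CrossSectionRecord("Greenisca brachypodii", "Kotejella + Arsenophonus", 100, 750, 1158, True),
    CrossSectionRecord("Psylla alni", "two unknown species", 64, 384, 593),
    CrossSectionRecord("Cacopsylla melanoneura", "two unknown species", 46, 234, 361),
    CrossSectionRecord("Ommatidiotus dissimilis", "Sulcia + Vidania + Sodalis", 81, 547, 844),
    CrossSectionRecord("Dictyophara europaea", "Sulcia + Vidania + Sodalis", 218, 2416, 3728, True),
    CrossSectionRecord("Macrosteles laevis", "Sulcia + Nasuia", 118, 962, 1485),
    CrossSectionRecord("Graphocraerus ventralis", "Sulcia + yeast", 135, 1177, 1817),
    CrossSectionRecord("Cicadula quadrinotata", "Sulcia only", 56, 315, 485),
    CrossSectionRecord("Deltocephalus pulicaris", "Sulcia + Nasuia", 162, 1548, 2388, True),
    CrossSectionRecord("Jassargus pseudocellaris", "Sulcia + Nasuia", 96, 706, 1089),
    CrossSectionRecord("Arthaldeus pascuellus", "Sulcia + Nasuia", 81, 547, 844),
    CrossSectionRecord("Centrotus cornutus", "four unknown species", 210, 2284, 3525, True),
    CrossSectionRecord("Tettigades lacertosa", "Sulcia + Hodgkinia (three)", 630, 11895, 18314),
    CrossSectionRecord("Magicicada septendecim", "Sulcia + Hodgkinia (complex)", 1750, 55071, 84787, True),
)
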