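"""Statistics over crystal energy landscapes.

Implements the survey-style analyses: energy ranking of matches to
reference structures (ΔE above the global minimum, Sohncke-restricted for
single-enantiomer chiral molecules), cumulative match curves, space-group
frequency tables under three selectors, and the chiral-resolution
comparison of enantiopure (Sohncke) versus racemic packings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crystal import MinimizedCrystal

__all__ = [
    "Landscape",
    "MatchRecord",
    "ChiralityRecord",
    "AnalysisConfig",
    "delta_e",
    "match_summary",
    "spacegroup_frequencies",
    "chirality_analysis",
]

# default analysis windows, kJ mol⁻¹: the usual polymorphism energy limit
# and the estimated thermal (lattice-vibrational) uncertainty window
POLYMORPH_WINDOW = 7.2
THERMAL_WINDOW = 2.0


class EmptyReferenceError(ValueError):
    """No admissible reference structures for a ΔE computation."""


class NotChiralError(ValueError):
    """Chirality analysis requested for an achiral molecule."""


@dataclass(frozen=True)
class AnalysisConfig:
    polymorph_window: float = POLYMORPH_WINDOW
    thermal_window: float = THERMAL_WINDOW
    selector: str = "global_min"   # global_min | densest | window

    def __post_init__(self):
        if self.polymorph_window <= 0 or self.thermal_window <= 0:
            raise ValueError("analysis windows must be positive")


class Landscape:
    """A deduplicated set of minimised structures for one molecule, sorted
    ascending in lattice energy (entry 0 is the global minimum)."""

    def __init__(self, molecule_name: str, structures: list[MinimizedCrystal]):
        self.molecule_name = molecule_name
        self.structures = sorted(structures, key=lambda s: s.e_latt)

    def __len__(self):
        return len(self.structures)

    def __iter__(self):
        return iter(self.structures)

    def __getitem__(self, i):
        return self.structures[i]

    @property
    def global_minimum(self) -> MinimizedCrystal:
        if not self.structures:
            raise EmptyReferenceError("empty landscape")
        return self.structures[0]

    @property
    def energies(self) -> np.ndarray:
        return np.array([s.e_latt for s in self.structures])

    @property
    def densities(self) -> np.ndarray:
        return np.array([s.density for s in self.structures])

    def densest(self) -> MinimizedCrystal:
        if not self.structures:
            raise EmptyReferenceError("empty landscape")
        return max(self.structures, key=lambda s: s.density)


@dataclass(frozen=True)
class MatchRecord:
    """Energy rank of a reference match within its landscape."""

    matched: bool
    delta_e: float | None = None   # kJ/mol above the (restricted) minimum
    rank: int | None = None        # 1-based position by energy
    rmsd_30: float | None = None


@dataclass(frozen=True)
class ChiralityRecord:
    """Spontaneous-resolution propensity from a chiral molecule's landscape.

    ΔE_latt = E_min(Sohncke) − E_min(racemic): positive means the racemate
    is favoured.  Δρ is the percentage density difference of the Sohncke
    minimum relative to the racemic minimum (negative = enantiopure less
    dense, the Wallach direction).
    """

    delta_e_latt: float
    delta_rho_percent: float
    resolution_predicted: bool     # strict ΔE_latt < 0


def delta_e(landscape: Landscape, structure: MinimizedCrystal,
            chiral_restriction: bool = False) -> float:
    """Energy of ``structure`` above the landscape's reference minimum.

    With the chiral restriction active (single-enantiomer molecules), the
    reference minimum is taken over Sohncke-group structures only.
    """
    pool = [s for s in landscape
            if not chiral_restriction or s.group.sohncke]
    if not pool:
        raise EmptyReferenceError("no admissible reference structures")
    ref = min(s.e_latt for s in pool)
    return float(structure.e_latt - ref)


def match_summary(match_records: list[MatchRecord],
                  config: AnalysisConfig | None = None,
                  bin_width: float = 0.5,
                  upper: float = 8.0) -> dict:
    """Histogram and cumulative curve of match ΔE values.

    Returns the binned counts, the cumulative fraction matched at ΔE ≤ x
    (normalised by the total number of landscapes, so unmatched landscapes
    lower the asymptote), and counts at ΔE = 0 / within the thermal window
    / within ``upper``.
    """
    config = config or AnalysisConfig()
    n_total = len(match_records)
    des = np.array([r.delta_e for r in match_records
                    if r.matched and r.delta_e is not None])
    edges = np.arange(0.0, upper + bin_width, bin_width)
    hist, _ = np.histogram(des, bins=edges)
    xs = edges[1:]
    cumulative = np.array([(des <= x).sum() for x in xs]) / max(n_total, 1)
    return {
        "bin_edges": edges,
        "histogram": hist,
        "cumulative_x": xs,
        "cumulative_fraction": cumulative,
        "n_landscapes": n_total,
        "n_matched": int(len(des)),
        "n_at_global_min": int((des <= 1e-9).sum()),
        "n_within_thermal": int((des <= config.thermal_window).sum()),
        "n_within_upper": int((des <= upper).sum()),
    }


def spacegroup_frequencies(landscapes: list[Landscape], selector: str = "global_min",
                           window: float = POLYMORPH_WINDOW,
                           per_landscape: bool = False) -> pd.Series:
    """Space-group frequency table under one of three selectors.

    ``global_min``: one count per landscape at its minimum's group;
    ``densest``: one count per landscape at its densest structure's group;
    ``window``: pooled counts of every unique structure with ΔE ≤ window
    (or, with ``per_landscape``, each landscape's window counts normalised
    before pooling).  Frequencies sum to 1.
    """
    if not landscapes:
        raise ValueError("need at least one landscape")
    counts: dict[str, float] = {}
    for ls in landscapes:
        if selector == "global_min":
            picks = {ls.global_minimum.group.symbol: 1.0}
        elif selector == "densest":
            picks = {ls.densest().group.symbol: 1.0}
        elif selector == "window":
            ref = ls.global_minimum.e_latt
            grp = [s.group.symbol for s in ls if s.e_latt - ref <= window]
            if per_landscape and grp:
                picks = {}
                for g in grp:
                    picks[g] = picks.get(g, 0.0) + 1.0 / len(grp)
            else:
                picks = {}
                for g in grp:
                    picks[g] = picks.get(g, 0.0) + 1.0
        else:
            raise ValueError(f"unknown selector {selector!r}")
        for g, w in picks.items():
            counts[g] = counts.get(g, 0.0) + w
    s = pd.Series(counts, dtype=float).sort_values(ascending=False)
    return s / s.sum()


def chirality_analysis(landscape: Landscape) -> ChiralityRecord:
    """Compare the best enantiopure (Sohncke) and racemic packings.

    Requires a chiral molecule and at least one structure in each class.
    A tie (ΔE_latt = 0) does not predict resolution (strict inequality).
    """
    if not landscape.structures:
        raise EmptyReferenceError("empty landscape")
    if not landscape.structures[0].molecule.is_chiral:
        raise NotChiralError(
            f"molecule {landscape.molecule_name!r} is not chiral"
        )
    sohncke = [s for s in landscape if s.group.sohncke]
    racemic = [s for s in landscape if not s.group.sohncke]
    if not sohncke or not racemic:
        raise EmptyReferenceError(
            "both Sohncke and racemic structures are required"
        )
    s_min = min(sohncke, key=lambda s: s.e_latt)
    r_min = min(racemic, key=lambda s: s.e_latt)
    d_e = float(s_min.e_latt - r_min.e_latt)
    d_rho = float(100.0 * (s_min.density - r_min.density) / r_min.density)
    return ChiralityRecord(
        delta_e_latt=d_e,
        delta_rho_percent=d_rho,
        resolution_predicted=bool(d_e < 0.0),
    )
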