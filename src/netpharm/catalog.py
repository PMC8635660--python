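"""Compound catalogs, ADMET screening, PPI expansion and gene-set intersection.

The candidate compounds of a multi-herb formula are screened on two
pharmacokinetic properties: oral bioavailability (OB, a percentage) and
drug-likeness (DL, a unitless score in [0, 1]).  The default thresholds are
OB >= 30% and DL >= 0.18, both inclusive.  Direct protein targets of the
retained compounds are expanded by one neighbourhood round over a
confidence-scored protein–protein interaction (PPI) table, keeping only edges
whose score strictly exceeds a cutoff (0.850 by default).  The disease arm,
the syndrome arm (differentially expressed genes) and the formula-target arm
are then intersected to define the disease-relevant target space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

log = logging.getLogger(__name__)

OB_MIN_DEFAULT = 30.0
DL_MIN_DEFAULT = 0.18
PPI_SCORE_MIN_DEFAULT = 0.850


@dataclass(frozen=True)
class CompoundRecord:
    """One candidate compound with its herb(s) of origin and ADMET properties."""

    compound_id: str
    name: str
    herbs: frozenset[str]
    ob: float  # oral bioavailability, percent in [0, 100]
    dl: float  # drug-likeness, unitless in [0, 1]

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be non-empty")
        if not self.herbs:
            raise ValueError(f"{self.compound_id}: herbs must be non-empty")
        for attr in ("ob", "dl"):
            v = getattr(self, attr)
            if not isinstance(v, (int, float)) or v != v or v in (float("inf"), float("-inf")):
                raise ValueError(f"{self.compound_id}: {attr} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"{self.compound_id}: {attr} must be non-negative, got {v!r}")


@dataclass(frozen=True)
class PPIEdge:
    """Undirected scored protein–protein interaction."""

    protein_a: str
    protein_b: str
    score: float

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValueError(f"PPI self-loop on {self.protein_a!r}")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"PPI score must be in [0, 1], got {self.score!r}")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.protein_a, self.protein_b))


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: whitespace-stripped, upper-cased."""
    return symbol.strip().upper()


def filter_compounds_admet(
    catalog: Iterable[CompoundRecord],
    ob_min: float = OB_MIN_DEFAULT,
    dl_min: float = DL_MIN_DEFAULT,
) -> list[CompoundRecord]:
    """Retain compounds with ob >= ob_min and dl >= dl_min (both inclusive).

    Input order is preserved.  Records with non-finite or negative OB/DL are
    rejected with a logged validation error rather than raising, so one bad
    catalog row does not abort a screen.
    """
    out: list[CompoundRecord] = []
    for rec in catalog:
        try:
            ob, dl = float(rec.ob), float(rec.dl)
            if ob != ob or dl != dl or ob < 0 or dl < 0:
                raise ValueError("non-finite or negative OB/DL")
        except (TypeError, ValueError) as exc:
            log.error("rejecting compound %r: %s", getattr(rec, "compound_id", rec), exc)
            continue
        if ob >= ob_min and dl >= dl_min:
            out.append(rec)
    return out


def expand_targets_ppi(
    seed_targets: Iterable[str],
    ppi: Iterable[PPIEdge],
    score_min: float = PPI_SCORE_MIN_DEFAULT,
) -> set[str]:
    """One-round neighbourhood expansion of seed targets over a scored PPI table.

    Returns the seeds plus every protein linked to a seed by an edge with
    score strictly greater than ``score_min``.  Exactly one round: neighbours
    of neighbours are not pulled in (a transitive closure over a
    score-filtered interactome would absorb most of the proteome).
    """
    if not (0.0 <= score_min <= 1.0):
        raise ValueError(f"score_min must be in [0, 1], got {score_min!r}")
    seeds = {normalize_symbol(s) for s in seed_targets}
    expanded = set(seeds)
    n_skipped = 0
    for edge in ppi:
        a, b = normalize_symbol(edge.protein_a), normalize_symbol(edge.protein_b)
        if not a or not b:
            n_skipped += 1
            continue
        if edge.score > score_min:
            if a in seeds:
                expanded.add(b)
            if b in seeds:
                expanded.add(a)
    if n_skipped:
        log.warning("expand_targets_ppi: skipped %d edges with empty symbols", n_skipped)
    return expanded


def _normalized_sets(sets: Mapping[str, Iterable[str]]) -> dict[str, set[str]]:
    return {name: {normalize_symbol(s) for s in members} for name, members in sets.items()}


def intersect_target_sets(sets: Mapping[str, Iterable[str]]) -> set[str]:
    """k-way intersection of named gene-symbol sets (case/whitespace tolerant)."""
    if len(sets) < 2:
        raise ValueError(f"need at least two named sets, got {len(sets)}")
    norm = _normalized_sets(sets)
    out: set[str] | None = None
    for members in norm.values():
        out = set(members) if out is None else (out & members)
    assert out is not None
    return out


def venn_regions(sets: Mapping[str, Iterable[str]]) -> dict[str, int]:
    """Cardinality of every exclusive Venn region of the named sets.

    Region keys are "&"-joined sorted member-set names; a region counts the
    symbols in exactly those sets and no other.
    """
    if len(sets) < 2:
        raise ValueError(f"need at least two named sets, got {len(sets)}")
    norm = _normalized_sets(sets)
    names = sorted(norm)
    regions: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for inside in combinations(names, r):
            members = set.intersection(*(norm[n] for n in inside))
            for n in names:
                if n not in inside:
                    members -= norm[n]
            regions["&".join(inside)] = len(members)
    return regions
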