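"""Compound-knockout simulation on the pharmacology network.

Knocking out a compound (or a combination of compounds) deletes the compound
node(s) and every target protein adjacent to any compound in the set — shared
targets included, since removing the compound removes its pharmacology on all
of its targets.  The four stability indicators (NC, CPL, NH, R) are then
computed on the surviving graph, with N = original node count and
Nr = removed count for the robustness denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .network import PharmNetwork
from .topology import StabilityIndicators, stability_indicators

log = logging.getLogger(__name__)

INDICATOR_COLUMNS = ("nc", "cpl", "nh", "r")

# Orientation of each indicator when the matrix is min–max normalized for
# entropy weighting.  "positive": larger raw value -> larger evaluation
# value; "inverse": smaller raw value -> larger evaluation value.  The
# defaults make a *destabilising* knockout score high: a compound whose
# removal stretches paths (high CPL), skews degrees (high NH), fragments the
# survivors (low R) and de-centralises the hub structure (low NC) is an
# important compound.
DEFAULT_ORIENTATION: dict[str, str] = {
    "nc": "inverse",
    "cpl": "positive",
    "nh": "positive",
    "r": "inverse",
}


class KnockoutUndefinedError(ValueError):
    """Knockout left a graph on which the indicators are undefined."""


@dataclass(frozen=True)
class KnockoutResult:
    entity_id: str
    removed_nodes: frozenset[str]
    indicators: StabilityIndicators


@dataclass
class IndicatorMatrix:
    """n entities x 4 indicators, with per-column orientation flags.

    ``values`` is a DataFrame indexed by entity id with columns nc, cpl, nh,
    r; ``orientation`` maps each column to "positive" or "inverse".
    """

    values: pd.DataFrame
    orientation: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_ORIENTATION))

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(INDICATOR_COLUMNS):
            raise ValueError(f"columns must be {INDICATOR_COLUMNS}, got {list(self.values.columns)}")
        if len(self.values) < 2:
            raise ValueError("entropy weighting needs at least 2 entity rows")
        if self.values.isna().any().any():
            raise ValueError("indicator matrix has missing cells")
        bad = {c: o for c, o in self.orientation.items() if o not in ("positive", "inverse")}
        if bad or set(self.orientation) != set(INDICATOR_COLUMNS):
            raise ValueError(f"orientation must flag each of {INDICATOR_COLUMNS} "
                             f"as positive/inverse, got {dict(self.orientation)}")


def removal_set(
    net: PharmNetwork,
    compounds: Iterable[str],
    target_map: Mapping[str, Iterable[str]] | None = None,
    shared_targets: bool = True,
) -> frozenset[str]:
    """Nodes deleted by knocking out a set of compounds.

    ``target_map`` overrides the compound→target adjacency of the network
    (by default the adjacent target nodes are used).  With
    ``shared_targets=False``, targets also hit by a surviving compound are
    spared.
    """
    compounds = sorted(set(compounds))
    if not compounds:
        raise ValueError("knockout needs at least one compound")
    for c in compounds:
        if c not in net:
            raise KeyError(f"compound {c!r} not in network")
    if target_map is None:
        hit = {c: net.targets_of_compound(c) for c in compounds}
    else:
        hit = {c: {t for t in target_map.get(c, ()) if t in net} for c in compounds}
    removed = set(compounds)
    targets = set().union(*hit.values()) if hit else set()
    if not shared_targets:
        survivors = set(net.compounds) - set(compounds)
        if target_map is None:
            spared = {t for s in survivors for t in net.targets_of_compound(s)}
        else:
            spared = {t for s in survivors for t in target_map.get(s, ())}
        targets -= spared
    removed |= targets
    return frozenset(removed)


def knockout_entity(
    net: PharmNetwork,
    compounds: Iterable[str],
    target_map: Mapping[str, Iterable[str]] | None = None,
    entity_id: str | None = None,
    shared_targets: bool = True,
) -> KnockoutResult:
    """Delete compounds plus their adjacent targets; indicators on the survivors."""
    compounds = sorted(set(compounds))
    removed = removal_set(net, compounds, target_map, shared_targets)
    n_original = len(net)
    survivor = net.graph.copy()
    survivor.remove_nodes_from(removed)
    if survivor.number_of_nodes() == 0:
        raise KnockoutUndefinedError(f"knockout of {compounds} empties the network")
    try:
        ind = stability_indicators(survivor, n_original=n_original, n_removed=len(removed))
    except ValueError as exc:
        raise KnockoutUndefinedError(f"knockout of {compounds}: {exc}") from exc
    return KnockoutResult(
        entity_id=entity_id if entity_id is not None else "+".join(compounds),
        removed_nodes=removed,
        indicators=ind,
    )


def build_indicator_matrix(
    net: PharmNetwork,
    entities: Sequence[Iterable[str]],
    target_map: Mapping[str, Iterable[str]] | None = None,
    orientation: Mapping[str, str] | None = None,
    shared_targets: bool = True,
) -> tuple[IndicatorMatrix, list[str]]:
    """One indicator row per knockout entity (a set of compound ids).

    Entities whose knockout leaves a graph on which an indicator is undefined
    (emptied, edgeless or sub-3-node survivors) are excluded; their ids are
    returned so callers can surface the exclusions in reports.
    """
    if len(entities) < 2:
        raise ValueError("need at least 2 entities for an indicator matrix")
    ids: list[str] = []
    rows: list[dict[str, float]] = []
    excluded: list[str] = []
    for ent in entities:
        compounds = sorted(set(ent))
        eid = "+".join(compounds)
        try:
            res = knockout_entity(net, compounds, target_map, entity_id=eid,
                                  shared_targets=shared_targets)
        except KnockoutUndefinedError as exc:
            log.warning("excluding knockout entity %s: %s", eid, exc)
            excluded.append(eid)
            continue
        ids.append(eid)
        rows.append(res.indicators.as_dict())
    if len(rows) < 2:
        raise ValueError("fewer than 2 entities produced defined indicator rows")
    values = pd.DataFrame(rows, index=ids)[list(INDICATOR_COLUMNS)]
    orient = dict(DEFAULT_ORIENTATION if orientation is None else orientation)
    return IndicatorMatrix(values=values, orientation=orient), excluded
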