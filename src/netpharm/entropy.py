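"""Entropy weighting, contribution scores and combination ranking.

Given an indicator matrix X (n knockout entities x m indicators) and a
per-column orientation, every column is min–max normalized to an evaluation
value z_ij in [0, 1]:

    positive indicator:  z_ij = (x_ij - min_j) / (max_j - min_j)
    inverse  indicator:  z_ij = (max_j - x_ij) / (max_j - min_j)

Entropy weighting then measures how much each indicator discriminates
between entities:

    b_ij = z_ij / sum_i z_ij          (column proportions)
    e_j  = -k * sum_i b_ij ln b_ij,   k = 1/ln(n), 0·ln(0) := 0
    d_j  = 1 - e_j                    (difference coefficient)
    w_j  = d_j / sum_j d_j            (weights over the m indicators)

A column that is constant across entities carries no information: its z is
all zeros and it is assigned e = 1, d = 0, w = 0.

The contribution score of an entity doubles the robustness term:

    score_i = z_nc·w_nc + z_cpl·w_cpl + z_nh·w_nh + z_r·(w_r × 2)

Scores are computed on the normalized z values so the four indicators are
commensurate (a raw-value mode mirrors the formula on raw indicators).
Combinations of p core compounds are enumerated exhaustively (2^p - 1
non-empty subsets), each scored by joint knockout, with entropy weights
recomputed across the combination rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations as _combinations
from math import ceil, log as _ln
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .knockout import (
    DEFAULT_ORIENTATION,
    INDICATOR_COLUMNS,
    IndicatorMatrix,
    build_indicator_matrix,
)
from .network import PharmNetwork

log = logging.getLogger(__name__)

ROBUSTNESS_WEIGHT_FACTOR = 2.0


@dataclass
class EntropyWeights:
    """Normalized values, proportions, entropies and the derived weights."""

    z: pd.DataFrame             # n x m evaluation values in [0, 1]
    b: pd.DataFrame             # n x m column proportions
    e: pd.Series                # m entropy values in [0, 1]
    d: pd.Series                # m difference coefficients, 1 - e
    w: pd.Series                # m weights, d / sum(d)
    constant_columns: list[str] = field(default_factory=list)


def minmax_normalize(matrix: IndicatorMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Per-column min–max normalization honouring each column's orientation.

    Returns the z-value frame and the list of constant columns (those were
    mapped to all-zeros and are flagged so entropy weighting can zero them).
    """
    x = matrix.values.astype(float)
    z = pd.DataFrame(index=x.index, columns=x.columns, dtype=float)
    constant: list[str] = []
    for col in x.columns:
        lo, hi = x[col].min(), x[col].max()
        span = hi - lo
        if span == 0:
            z[col] = 0.0
            constant.append(col)
            continue
        if matrix.orientation[col] == "positive":
            z[col] = (x[col] - lo) / span
        else:
            z[col] = (hi - x[col]) / span
    return z, constant


def entropy_weights(
    z: pd.DataFrame,
    constant_columns: Iterable[str] = (),
) -> EntropyWeights:
    """Entropy, difference coefficients and weights from normalized values."""
    n = len(z)
    if n < 2:
        raise ValueError("entropy weighting needs at least 2 rows")
    constant = set(constant_columns)
    k = 1.0 / _ln(n)
    b = pd.DataFrame(index=z.index, columns=z.columns, dtype=float)
    e = pd.Series(index=z.columns, dtype=float)
    for col in z.columns:
        colsum = z[col].sum()
        if col in constant or colsum == 0:
            # uninformative indicator: uniform-by-convention, maximum entropy
            b[col] = 0.0
            e[col] = 1.0
            continue
        p = (z[col] / colsum).to_numpy()
        b[col] = p
        nz = p[p > 0]
        e[col] = float(-k * np.sum(nz * np.log(nz)))
    d = 1.0 - e
    dsum = d.sum()
    if dsum <= 0:
        raise ValueError("all indicator columns are uninformative (sum of "
                         "difference coefficients is 0)")
    w = d / dsum
    return EntropyWeights(z=z, b=b, e=e, d=d, w=w,
                          constant_columns=sorted(constant | {c for c in z.columns
                                                              if z[c].sum() == 0}))


def contribution_scores(
    weights: EntropyWeights,
    matrix: IndicatorMatrix | None = None,
    raw_values: bool = False,
) -> pd.DataFrame:
    """Weighted-sum contribution score per entity, robustness weight doubled.

    Returns a DataFrame with columns ``score`` (doubled-R formula) and
    ``score_undoubled`` (plain weighted sum, reported for transparency).
    With ``raw_values=True`` the raw indicator values are used in place of z
    (requires ``matrix``).
    """
    if raw_values:
        if matrix is None:
            raise ValueError("raw_values mode needs the indicator matrix")
        vals = matrix.values.astype(float)
    else:
        vals = weights.z
    if list(vals.columns) != list(weights.w.index):
        raise ValueError("weights and values have mismatched indicator columns")
    w = weights.w
    plain = vals.mul(w, axis=1).sum(axis=1)
    doubled = plain + vals["r"] * w["r"] * (ROBUSTNESS_WEIGHT_FACTOR - 1.0)
    return pd.DataFrame({"score": doubled, "score_undoubled": plain})


def enumerate_combinations(
    compounds: Sequence[str],
    min_size: int = 1,
) -> list[tuple[str, ...]]:
    """All subsets of size >= min_size, ordered by size then lexicographically."""
    if len(set(compounds)) != len(compounds):
        raise ValueError("duplicate compound ids in combination enumeration")
    if not 1 <= min_size <= len(compounds):
        raise ValueError(f"min_size must be in [1, {len(compounds)}], got {min_size}")
    ordered = sorted(compounds)
    out: list[tuple[str, ...]] = []
    for size in range(min_size, len(ordered) + 1):
        out.extend(_combinations(ordered, size))
    return out


def select_core_compounds(
    matrix: IndicatorMatrix,
    fraction: float = 0.5,
    mode: str = "per_indicator",
) -> set[str]:
    """Venn-style retention of the top-``fraction`` scorers.

    ``per_indicator`` (default): for each indicator column take the entities
    in the top ``fraction`` by evaluation value z (ties at the cutoff all
    retained) and intersect the per-indicator sets.  If the intersection is
    empty, fall back — with a logged warning — to the top ceil(fraction*n)
    entities by contribution score.  ``score`` mode thresholds the combined
    contribution score directly at its top ``fraction``.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if mode not in ("per_indicator", "score"):
        raise ValueError(f"unknown mode {mode!r}")
    z, constant = minmax_normalize(matrix)
    ew = entropy_weights(z, constant)
    n = len(z)
    k = ceil(fraction * n)

    def top_by(series: pd.Series, k_min: int = 1) -> set[str]:
        kk = max(k, k_min)
        cutoff = series.sort_values(ascending=False).iloc[kk - 1]
        return set(series.index[series >= cutoff])

    if mode == "score":
        scores = contribution_scores(ew)["score"]
        return top_by(scores)

    kept: set[str] | None = None
    for col in z.columns:
        if col in ew.constant_columns:
            continue  # an uninformative indicator cannot rank entities
        sel = top_by(z[col])
        kept = sel if kept is None else (kept & sel)
    if kept:
        return kept
    log.warning("per-indicator Venn retention is empty; falling back to the "
                "top %d entities by contribution score", k)
    scores = contribution_scores(ew)["score"]
    return top_by(scores, k_min=2)


@dataclass
class CombinationRanking:
    """Ranked combinations with full scoring provenance."""

    table: pd.DataFrame           # columns: combination, size, score, score_undoubled,
                                  # nc, cpl, nh, r (raw indicator values)
    weights: EntropyWeights
    orientation: dict[str, str]
    excluded: list[str] = field(default_factory=list)

    def top(self, k: int) -> pd.DataFrame:
        return self.table.head(k)


def rank_combinations(
    net: PharmNetwork,
    core_compounds: Iterable[str],
    target_map: Mapping[str, Iterable[str]] | None = None,
    top_k: int | None = None,
    min_size: int = 1,
    orientation: Mapping[str, str] | None = None,
    shared_targets: bool = True,
    raw_score_mode: bool = False,
) -> CombinationRanking:
    """Enumerate, knock out and rank all combinations of the core compounds.

    Entropy weights are recomputed across the combination rows themselves —
    combinations are scored on their own scale, not with the single-compound
    weights.  Ranking is by descending score with the "+"-joined combination
    id as a deterministic tie-break.  ``top_k`` only truncates the returned
    table; scoring always uses every combination.
    """
    core = sorted(set(core_compounds))
    if len(core) < 2:
        raise ValueError("need at least 2 core compounds to rank combinations")
    combos = enumerate_combinations(core, min_size=min_size)
    matrix, excluded = build_indicator_matrix(
        net, combos, target_map=target_map, orientation=orientation,
        shared_targets=shared_targets,
    )
    z, constant = minmax_normalize(matrix)
    ew = entropy_weights(z, constant)
    scores = contribution_scores(ew, matrix, raw_values=raw_score_mode)
    table = pd.concat([scores, matrix.values], axis=1)
    table.insert(0, "combination", table.index)
    table.insert(1, "size", [len(c.split("+")) for c in table.index])
    table = table.sort_values(["score", "combination"],
                              ascending=[False, True], kind="mergesort")
    table = table.reset_index(drop=True)
    if top_k is not None:
        table = table.head(top_k)
    return CombinationRanking(
        table=table,
        weights=ew,
        orientation=dict(matrix.orientation),
        excluded=excluded,
    )
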