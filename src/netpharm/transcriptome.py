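"""Two-group expression filtering: quantile normalization, DEG calling,
and generic over-representation against user-supplied gene sets.

The differential filter mirrors a standard microarray screen: intensities
are quantile-normalized, log2-transformed, and each gene is tested with a
two-sided two-sample location test on the log2 values (Welch by default).
The fold change is the ratio of group geometric means; a gene passes at
(fc_min, p_max) iff its fold change exceeds fc_min in either direction AND
its raw p value is below p_max — both comparisons strict.  No multiplicity
correction gates the pass rule; a Benjamini–Hochberg column is reported
alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import normalize_symbol

log = logging.getLogger(__name__)

FC_MIN_DEFAULT = 1.5       # patient-array criterion; tissue arrays often use 2.0
P_MAX_DEFAULT = 0.05
PSEUDO_INTENSITY = 1.0     # offset applied before log2 when zeros are present


@dataclass
class ExpressionMatrix:
    """Genes x samples intensity matrix (linear scale) with 2-group labels."""

    values: pd.DataFrame              # rows: genes, columns: samples
    groups: pd.Series                 # per-sample group label (exactly 2 levels)

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        if list(self.groups.index) != list(self.values.columns):
            self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")
        levels = self.groups.unique()
        if len(levels) != 2:
            raise ValueError(f"exactly 2 groups required, got {list(levels)}")
        if (self.groups.value_counts() < 2).any():
            raise ValueError("each group needs at least 2 samples")
        if self.values.isna().any().any():
            raise ValueError("expression matrix has missing cells")
        if not self.values.index.is_unique:
            raise ValueError("gene ids must be unique")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def group_levels(self) -> tuple[str, str]:
        """The two group labels in lexicographic order; fold changes are
        group_levels[0] / group_levels[1]."""
        a, b = sorted(self.groups.unique())
        return a, b


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common (rank-mean) intensity distribution.

    After normalization each column's sorted values equal the vector of
    row-wise means of the column-sorted input; tied ranks receive the mean
    of the reference values they span.
    """
    x = matrix.values
    if x.shape[1] < 2:
        log.warning("quantile normalization of a single-sample matrix is the identity")
        return ExpressionMatrix(x.copy(), matrix.groups.copy())
    arr = x.to_numpy(dtype=float)
    ref = np.sort(arr, axis=0).mean(axis=1)
    positions = np.arange(1, arr.shape[0] + 1, dtype=float)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, ref)
    return ExpressionMatrix(pd.DataFrame(out, index=x.index, columns=x.columns),
                            matrix.groups.copy())


def two_group_deg(
    matrix: ExpressionMatrix,
    fc_min: float = FC_MIN_DEFAULT,
    p_max: float = P_MAX_DEFAULT,
    equal_var: bool = False,
    pseudo: float = PSEUDO_INTENSITY,
) -> pd.DataFrame:
    """Per-gene fold change, p value and pass flag for a two-group design.

    Fold change is group1/group2 on geometric means (log2 arithmetic
    internally); p is from a two-sided two-sample t test on log2 intensities
    (Welch unless ``equal_var``).  A gene passes iff
    (fc > fc_min OR fc < 1/fc_min) AND p < p_max, strict comparisons.
    Zero intensities are offset by ``pseudo`` before the log, and the offset
    is recorded in the returned frame's attrs.
    """
    if fc_min <= 1:
        raise ValueError(f"fc_min must exceed 1, got {fc_min}")
    g1, g2 = matrix.group_levels
    x = matrix.values.to_numpy(dtype=float)
    offset_applied = bool((x == 0).any())
    if offset_applied:
        log.info("zero intensities present; applying pseudo-offset %g before log2", pseudo)
        x = x + pseudo
    logx = np.log2(x)
    m1 = logx[:, (matrix.groups == g1).to_numpy()]
    m2 = logx[:, (matrix.groups == g2).to_numpy()]
    log2fc = m1.mean(axis=1) - m2.mean(axis=1)
    tstat, pvals = stats.ttest_ind(m1, m2, axis=1, equal_var=equal_var)
    pvals = np.nan_to_num(pvals, nan=1.0)  # zero-variance ties
    fc = np.exp2(log2fc)
    passes = ((fc > fc_min) | (fc < 1.0 / fc_min)) & (pvals < p_max)
    out = pd.DataFrame(
        {
            "fold_change": fc,
            "log2_fold_change": log2fc,
            "p_value": pvals,
            "p_adjusted": multipletests(pvals, method="fdr_bh")[1],
            "passes": passes,
        },
        index=matrix.values.index,
    )
    out.attrs["fc_min"] = fc_min
    out.attrs["p_max"] = p_max
    out.attrs["pseudo_offset"] = pseudo if offset_applied else 0.0
    out.attrs["group_order"] = (g1, g2)
    return out


def hypergeometric_enrichment(
    selected: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``selected`` in each set.

    Annotation sets are intersected with the universe first; the p value for
    a set of size K with overlap x among N universe genes and n selected is
    P(X >= x) under the hypergeometric null.  A Benjamini–Hochberg adjusted
    column is included.
    """
    uni = {normalize_symbol(g) for g in universe}
    if not uni:
        raise ValueError("empty universe")
    sel = {normalize_symbol(g) for g in selected}
    if not sel <= uni:
        raise ValueError("selected genes must be a subset of the universe")
    rows = []
    for name in sorted(annotation):
        members = {normalize_symbol(g) for g in annotation[name]} & uni
        overlap = sel & members
        # P(X >= |overlap|), X ~ Hypergeom(N=|uni|, K=|members|, n=|sel|)
        p = float(stats.hypergeom.sf(len(overlap) - 1, len(uni), len(members), len(sel)))
        rows.append({
            "set_name": name,
            "set_size": len(members),
            "overlap": len(overlap),
            "overlap_genes": ";".join(sorted(overlap)),
            "p_value": min(p, 1.0),
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out = out.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)
    return out
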