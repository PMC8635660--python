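"""Canonical simulation experiments run against the synthetic generators.

These functions define the package's reference study conditions — the
configurations under which the pipeline's operating characteristics
(planted-compound recovery, DEG sensitivity and specificity, null
calibration) are measured.  They are used by the example scripts and by the
acceptance machinery, and they are deliberately deterministic: the base
seed fixes every replicate.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import replace
from pathlib import Path

import numpy as np

from .pipeline import RunConfig, run_pipeline
from .synthetic import ExpressionDesign, SynthConfig, synth_expression, write_synthetic_bundle
from .transcriptome import quantile_normalize, two_group_deg

log = logging.getLogger(__name__)

# Desk-scale network for the recovery experiment: one boosted-hub compound
# among 17 candidates (the knockout-cohort size of a realistic core
# network), 300 targets so that a single knockout removes a modest fraction
# of the core rather than obliterating it.
RECOVERY_CONFIG = SynthConfig(
    n_herbs=6,
    n_compounds=17,
    n_targets=300,
    n_decoy_compounds=8,
    targets_per_compound=(3, 8),
    n_planted_hubs=1,
    planted_hub_boost=5.0,
    expr_design=ExpressionDesign(n_genes=600, n_per_group=16, n_deg=250),
)

# DEG operating-characteristic conditions: 16-vs-16 groups, 1000 genes with
# 100 planted at |log2FC| = 1.5 and sigma = 0.5.
DEG_CONFIG = SynthConfig(
    expr_design=ExpressionDesign(n_genes=1000, n_per_group=16, n_deg=100,
                                 log2fc=1.5, sigma=0.5),
)


def _derive_seed(base_seed: int, i: int) -> int:
    return int((base_seed * 100_003 + i) % 2**31)


def recovery_experiment(
    n_seeds: int = 100,
    base_seed: int = 0,
    config: SynthConfig = RECOVERY_CONFIG,
    workdir: str | Path | None = None,
) -> tuple[int, int]:
    """Full-pipeline planted-compound recovery rate.

    For each replicate: generate a synthetic input bundle with one
    boosted-hub compound, run the complete protocol at its default
    thresholds, and score a hit when the planted compound is a member of the
    top-ranked combination.  Returns (hits, n_seeds).
    """
    hits = 0
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        for i in range(n_seeds):
            seed = _derive_seed(base_seed, i)
            cfg = replace(config, seed=seed)
            bundle = Path(tmp) / f"bundle_{i}"
            truth = write_synthetic_bundle(cfg, bundle)
            rc = RunConfig(
                catalog=str(bundle / "compound_catalog.tsv"),
                compound_target=str(bundle / "compound_target.tsv"),
                ppi=str(bundle / "ppi.tsv"),
                disease_targets=str(bundle / "disease_targets.txt"),
                expression=str(bundle / "expression.tsv"),
                groups=str(bundle / "groups.tsv"),
                outdir=str(bundle / "run"),
                seed=seed,
            )
            manifest = run_pipeline(rc)
            top = set(manifest["stages"]["rank"]["top_combination"].split("+"))
            if set(truth["planted_compounds"]) & top:
                hits += 1
    return hits, n_seeds


def deg_performance(
    n_seeds: int = 20,
    base_seed: int = 0,
    config: SynthConfig = DEG_CONFIG,
    fc_min: float = 1.5,
    p_max: float = 0.05,
    normalize: bool = True,
) -> tuple[float, float]:
    """Mean sensitivity and false-positive rate of the DEG filter.

    Each replicate plants DEGs at the design's |log2FC| and calls the filter
    at (fc_min, p_max); sensitivity and FPR are measured against the planted
    truth and averaged over replicates.
    """
    sens, fpr = [], []
    for i in range(n_seeds):
        cfg = replace(config, seed=_derive_seed(base_seed, i))
        matrix, planted = synth_expression(cfg)
        if normalize:
            matrix = quantile_normalize(matrix)
        table = two_group_deg(matrix, fc_min=fc_min, p_max=p_max)
        truth = set(planted)
        called = set(table.index[table["passes"]])
        n_null = len(table) - len(truth)
        sens.append(len(called & truth) / len(truth))
        fpr.append(len(called - truth) / n_null)
    return float(np.mean(sens)), float(np.mean(fpr))


def null_calibration(
    n_seeds: int = 20,
    base_seed: int = 0,
    config: SynthConfig = DEG_CONFIG,
) -> float:
    """Fraction of genes at p < 0.05 under the global null (no planted DEGs).

    With well-calibrated p values this fraction sits within binomial error
    of 0.05.
    """
    null_cfg = replace(config, expr_design=replace(config.expr_design, n_deg=0))
    fractions = []
    for i in range(n_seeds):
        cfg = replace(null_cfg, seed=_derive_seed(base_seed, i))
        matrix, _ = synth_expression(cfg)
        table = two_group_deg(matrix)
        fractions.append(float((table["p_value"] < 0.05).mean()))
    return float(np.mean(fractions))
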