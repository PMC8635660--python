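"""End-to-end orchestration: ingest → DEG filter → Venn → network build →
core extraction → knockouts → core-compound selection → combination ranking.

A run is described by a single config (YAML on disk or a
:class:`RunConfig`); every stage writes its artifact under the output
directory and the run closes with a manifest (config echo, library
versions, per-stage row counts, wall time).  The default thresholds are the
standard protocol values: OB >= 30, DL >= 0.18, PPI score > 0.850,
fold change > 1.5 at p < 0.05, top-50% retention, top-10 report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import io as npio
from .catalog import (
    filter_compounds_admet, expand_targets_ppi, intersect_target_sets,
    venn_regions,
)
from .entropy import (
    contribution_scores, entropy_weights, minmax_normalize,
    rank_combinations, select_core_compounds,
)
from .knockout import DEFAULT_ORIENTATION, build_indicator_matrix
from .network import PharmNetwork, build_pharm_network
from .topology import extract_core_network, node_topology_profiles
from .transcriptome import quantile_normalize, two_group_deg

log = logging.getLogger(__name__)

STAGES = ("ingest", "deg", "venn", "network", "core", "knockout", "select", "rank")

_THRESHOLD_DOMAINS = {
    "ob_min": (0.0, 100.0),
    "dl_min": (0.0, 1.0),
    "ppi_score_min": (0.0, 1.0),
    "fc_min": (1.0, float("inf")),
    "p_max": (0.0, 1.0),
    "fraction": (0.0, 1.0),
}


@dataclass
class RunConfig:
    """Validated run description; defaults are the standard protocol."""

    catalog: str = ""
    compound_target: str = ""
    ppi: str = ""
    disease_targets: str = ""
    expression: str = ""
    groups: str = ""
    outdir: str = "netpharm_run"
    ob_min: float = 30.0
    dl_min: float = 0.18
    ppi_score_min: float = 0.850
    fc_min: float = 1.5
    p_max: float = 0.05
    fraction: float = 0.5
    min_size: int = 1
    top_k: int = 10
    selection_mode: str = "score"  # or "per_indicator" (Venn over the 4 columns)
    orientation: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ORIENTATION))
    seed: int = 0

    def validate(self, check_files: bool = True) -> list[str]:
        errors: list[str] = []
        for key, (lo, hi) in _THRESHOLD_DOMAINS.items():
            v = getattr(self, key)
            if not isinstance(v, (int, float)) or not lo <= v <= hi:
                errors.append(f"{key}={v!r} outside its domain [{lo}, {hi}]")
        if self.fraction == 0:
            errors.append("fraction=0 outside its domain (0, 1]")
        if self.fc_min <= 1:
            errors.append(f"fc_min={self.fc_min!r} must exceed 1")
        if not (isinstance(self.min_size, int) and self.min_size >= 1):
            errors.append(f"min_size={self.min_size!r} must be a positive integer")
        if not (isinstance(self.top_k, int) and self.top_k >= 1):
            errors.append(f"top_k={self.top_k!r} must be a positive integer")
        if self.selection_mode not in ("score", "per_indicator"):
            errors.append(f"selection_mode={self.selection_mode!r} must be "
                          "'score' or 'per_indicator'")
        for col, o in self.orientation.items():
            if col not in DEFAULT_ORIENTATION or o not in ("positive", "inverse"):
                errors.append(f"orientation[{col!r}]={o!r} invalid "
                              f"(columns {sorted(DEFAULT_ORIENTATION)}, "
                              f"values positive/inverse)")
        if check_files:
            for key in ("catalog", "compound_target", "ppi",
                        "disease_targets", "expression", "groups"):
                p = getattr(self, key)
                if not p or not Path(p).exists():
                    errors.append(f"{key}: file {p!r} does not exist")
        return errors


def validate_config(path, check_files: bool = True) -> RunConfig:
    """Load a YAML run config; raises ValueError listing every violation."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    defaults_applied = sorted(known - set(raw))
    if "orientation" not in raw:
        log.info("orientation map not given; defaults applied: %s",
                 dict(DEFAULT_ORIENTATION))
    cfg = RunConfig(**raw)
    errors = cfg.validate(check_files=check_files)
    if errors:
        raise ValueError(f"{path}: invalid config:\n  " + "\n  ".join(errors))
    if defaults_applied:
        log.info("defaults applied for: %s", defaults_applied)
    return cfg


def _versions() -> dict[str, str]:
    import networkx, numpy, pandas, scipy
    from . import __version__
    return {
        "netpharm": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "networkx": networkx.__version__,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    errors = config.validate()
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "config": {k: v for k, v in asdict(config).items()},
        "versions": _versions(),
        "seed": config.seed,
        "stages": {},
    }

    stage = "ingest"
    try:
        catalog = npio.read_compound_catalog(config.catalog)
        active = filter_compounds_admet(catalog, config.ob_min, config.dl_min)
        active_ids = {r.compound_id for r in active}
        npio.write_compound_catalog(active, outdir / "active_compounds.tsv")
        manifest["stages"][stage] = {
            "n_catalog": len(catalog), "n_active": len(active)}

        stage = "deg"
        expr = npio.read_expression(config.expression, config.groups)
        expr = quantile_normalize(expr)
        deg_table = two_group_deg(expr, fc_min=config.fc_min, p_max=config.p_max)
        deg_table.to_csv(outdir / "deg_table.tsv", sep="\t",
                         index_label="gene", float_format="%.6g")
        syndrome = set(deg_table.index[deg_table["passes"]])
        npio.write_gene_list(syndrome, outdir / "syndrome_degs.txt")
        manifest["stages"][stage] = {
            "n_genes": len(deg_table), "n_degs": len(syndrome)}

        stage = "venn"
        ct_edges = [(c, t) for c, t in npio.read_edge_table(config.compound_target)
                    if c in active_ids]
        direct_targets = {t for _, t in ct_edges}
        ppi = npio.read_ppi_table(config.ppi)
        formula_targets = expand_targets_ppi(direct_targets, ppi,
                                             config.ppi_score_min)
        disease = npio.read_gene_list(config.disease_targets)
        named = {"disease": disease, "syndrome": syndrome,
                 "formula": formula_targets}
        core_targets = intersect_target_sets(named)
        if not core_targets:
            raise ValueError("the disease/syndrome/formula intersection is "
                             "empty; nothing downstream is defined")
        regions = venn_regions(named)
        npio.write_json(regions, outdir / "venn_regions.json")
        npio.write_gene_list(core_targets, outdir / "venn_intersection.txt")
        manifest["stages"][stage] = {
            "n_direct_targets": len(direct_targets),
            "n_formula_targets": len(formula_targets),
            "n_disease": len(disease),
            "n_syndrome": len(syndrome),
            "n_intersection": len(core_targets),
        }

        stage = "network"
        kept_ct = [(c, t) for c, t in ct_edges if t in core_targets]
        kept_compounds = {c for c, _ in kept_ct}
        hc_edges = sorted({(h, r.compound_id) for r in active
                           if r.compound_id in kept_compounds
                           for h in r.herbs})
        tt_edges = sorted({tuple(sorted((e.protein_a, e.protein_b)))
                           for e in ppi
                           if e.score > config.ppi_score_min
                           and e.protein_a in core_targets
                           and e.protein_b in core_targets})
        net = build_pharm_network(hc_edges, sorted(set(kept_ct)), tt_edges)
        npio.write_sif(net, outdir / "network.sif")
        npio.write_graphml(net, outdir / "network.graphml")
        manifest["stages"][stage] = {
            "n_nodes": len(net), "n_edges": net.graph.number_of_edges(),
            "n_compounds": len(net.compounds), "n_targets": len(net.targets)}

        stage = "core"
        profiles = node_topology_profiles(net)
        npio.write_profiles(profiles, outdir / "topology_profiles.tsv")
        core_net, core_rule = _extract_core_with_fallback(net, profiles)
        npio.write_sif(core_net, outdir / "core_network.sif")
        manifest["stages"][stage] = {
            "rule": core_rule, "n_nodes": len(core_net),
            "n_compounds": len(core_net.compounds)}

        stage = "knockout"
        knockout_compounds = sorted(core_net.compounds)
        matrix, excluded = build_indicator_matrix(
            core_net, [[c] for c in knockout_compounds],
            orientation=config.orientation)
        matrix.values.to_csv(outdir / "indicator_matrix.tsv", sep="\t",
                             index_label="entity", float_format="%.8f")
        manifest["stages"][stage] = {
            "n_entities": len(matrix.values), "excluded": excluded}

        stage = "select"
        z, constant = minmax_normalize(matrix)
        ew = entropy_weights(z, constant)
        compound_scores = contribution_scores(ew)
        compound_scores.to_csv(outdir / "compound_scores.tsv", sep="\t",
                               index_label="compound", float_format="%.8f")
        mode = "per_indicator" if config.selection_mode == "per_indicator" else "score"
        selected = select_core_compounds(matrix, fraction=config.fraction, mode=mode)
        if len(selected) < 2:
            log.warning("retention kept %d compound(s); combination ranking "
                        "needs >= 2 — widening to the top 2 by score",
                        len(selected))
            scores_all = compound_scores["score"].sort_values(ascending=False)
            selected = set(scores_all.index[:2]) | selected
        npio.write_gene_list(selected, outdir / "core_compounds.txt")
        manifest["stages"][stage] = {
            "weights": {k: float(v) for k, v in ew.w.items()},
            "n_selected": len(selected)}

        stage = "rank"
        ranking = rank_combinations(
            core_net, selected, min_size=config.min_size,
            orientation=config.orientation)
        npio.write_ranking(ranking.table, outdir / "combination_ranking.tsv")
        npio.write_ranking(ranking.table.head(config.top_k),
                           outdir / "combination_ranking_top.tsv")
        npio.write_json(
            {
                "orientation": ranking.orientation,
                "weights": {k: float(v) for k, v in ranking.weights.w.items()},
                "excluded": ranking.excluded,
                "seed": config.seed,
                "top": [
                    {"combination": r.combination, "score": float(r.score)}
                    for r in ranking.table.head(config.top_k).itertuples()
                ],
            },
            outdir / "combination_ranking_meta.json",
        )
        manifest["stages"][stage] = {
            "n_combinations": len(ranking.table),
            "n_excluded": len(ranking.excluded),
            "top_combination": ranking.table.iloc[0]["combination"],
            "top_score": float(ranking.table.iloc[0]["score"]),
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        npio.write_json(manifest, outdir / "manifest.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["wall_time_s"] = round(time.time() - t0, 3)
    manifest["completed_stages"] = list(STAGES)
    npio.write_json(manifest, outdir / "manifest.json")
    return manifest


def _extract_core_with_fallback(net: PharmNetwork, profiles):
    """Median-rule core; relaxes to >= then to the full network if the rule
    leaves fewer than 2 compounds (knockouts need compound entities)."""
    for rule, kwargs in (
        ("median_strict", {"strict": True}),
        ("median_ties", {"strict": False}),
    ):
        try:
            core = extract_core_network(net, profiles, **kwargs)
        except ValueError:
            continue
        if len(core.compounds) >= 2 and core.graph.number_of_edges() >= 1:
            return core, rule
    log.warning("core extraction left < 2 compounds; using the full network")
    return net, "full_network"
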