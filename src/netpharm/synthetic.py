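"""Synthetic study inputs with planted ground truth.

Every input the pipeline consumes can be generated here so that each stage
has a known answer: a tripartite herb–compound–target network whose
target–target layer is scale-free and in which a small set of planted
compounds attach to the top-degree hub targets (so their knockout is, by
construction, the most destabilising); three gene lists whose Venn regions
are set exactly by design; and a two-group expression matrix with planted
differentially expressed genes.

The defaults emulate a realistic desk-scale study of an eight-herb formula:
8 herbs, 170 screened-active compounds over ~800 targets, a 16-vs-16 blood
transcriptome with ~1000 planted DEGs at |log2FC| = 1.5 and σ = 0.5 on the
log2 scale (typical microarray noise), and gene-list sizes of about 1200
disease genes, 1100 syndrome DEGs and 860 formula targets overlapping in a
~180-gene triple intersection.

All generators are pure functions of their config (the seed fixes every
stochastic choice); generated artifacts satisfy the invariants of the types
they instantiate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .catalog import CompoundRecord, PPIEdge
from .network import PharmNetwork, build_pharm_network
from .transcriptome import ExpressionMatrix

_REGION_KEYS = (
    "disease", "syndrome", "formula",
    "disease&syndrome", "disease&formula", "syndrome&formula",
    "disease&syndrome&formula",
)

# Exclusive Venn region sizes consistent with list magnitudes of ~1191
# disease genes, ~1116 syndrome DEGs, ~859 formula targets and a 181-gene
# triple intersection.
DEFAULT_OVERLAP_DESIGN: dict[str, int] = {
    "disease": 740,
    "syndrome": 685,
    "formula": 458,
    "disease&syndrome": 150,
    "disease&formula": 120,
    "syndrome&formula": 100,
    "disease&syndrome&formula": 181,
}


@dataclass(frozen=True)
class ExpressionDesign:
    """Two-group expression-matrix design (log2-scale effect and noise)."""

    n_genes: int = 10_000
    n_per_group: int = 16
    n_deg: int = 1_000
    log2fc: float = 1.5
    sigma: float = 0.5

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_per_group) < 2 or self.n_deg < 0:
            raise ValueError("expression design needs n_genes, n_per_group >= 2 and n_deg >= 0")
        if self.n_deg > self.n_genes:
            raise ValueError(f"n_deg ({self.n_deg}) exceeds n_genes ({self.n_genes})")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class SynthConfig:
    """Study-design knobs for all synthetic inputs."""

    n_herbs: int = 8
    n_compounds: int = 170          # screened-active compounds in the network
    n_targets: int = 800
    degree_model: str = "scale-free"    # or "uniform"
    ba_attachment: int = 2              # edges per new node (scale-free model)
    edge_prob: float = 0.005            # uniform-model edge probability
    targets_per_compound: tuple[int, int] = (3, 8)
    n_planted_hubs: int = 1
    planted_hub_boost: float = 5.0      # multiplier on planted compounds' target count
    n_decoy_compounds: int = 170        # catalog rows failing the ADMET screen
    overlap_design: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_OVERLAP_DESIGN))
    expr_design: ExpressionDesign = field(default_factory=ExpressionDesign)
    target_list_prob: float = 0.7       # P(ordinary target joins each study list)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_herbs", "n_compounds", "n_targets"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.degree_model not in ("scale-free", "uniform"):
            raise ValueError(f"unknown degree_model {self.degree_model!r}")
        lo, hi = self.targets_per_compound
        if not 1 <= lo <= hi <= self.n_targets:
            raise ValueError("targets_per_compound range must satisfy "
                             f"1 <= lo <= hi <= n_targets, got {lo, hi}")
        if self.planted_hub_boost < 1:
            raise ValueError("planted_hub_boost must be >= 1")
        if self.n_planted_hubs > self.n_compounds:
            raise ValueError("more planted hubs than compounds")
        n_planted_targets = int(round(self.planted_hub_boost * (lo + hi) / 2))
        if self.n_planted_hubs and n_planted_targets > self.n_targets:
            raise ValueError(
                f"planted compounds demand {n_planted_targets} targets but only "
                f"{self.n_targets} exist (planted_hub_boost too large)")
        missing = set(_REGION_KEYS) - set(self.overlap_design)
        if missing:
            raise ValueError(f"overlap_design missing regions: {sorted(missing)}")
        if any(v < 0 for v in self.overlap_design.values()):
            raise ValueError("overlap_design region sizes must be non-negative")
        if not 0 <= self.target_list_prob <= 1:
            raise ValueError("target_list_prob must be a probability")


def _gene_symbol(i: int) -> str:
    return f"G{i:05d}"


def _target_symbols(config: SynthConfig) -> list[str]:
    return [_gene_symbol(i + 1) for i in range(config.n_targets)]


def _target_layer(config: SynthConfig, rng: np.random.Generator) -> nx.Graph:
    n = config.n_targets
    gseed = int(rng.integers(2**31))
    if config.degree_model == "scale-free":
        g = nx.barabasi_albert_graph(n, min(config.ba_attachment, n - 1), seed=gseed)
    else:
        g = nx.gnp_random_graph(n, config.edge_prob, seed=gseed)
    return nx.relabel_nodes(g, {i: _gene_symbol(i + 1) for i in range(n)})


def synth_pharm_network(config: SynthConfig) -> tuple[PharmNetwork, list[str]]:
    """Tripartite herb–compound–target network with planted hub compounds.

    Planted compounds attach to the targets with the highest degree in the
    target–target (PPI) layer, and attach to ``planted_hub_boost`` times as
    many of them as an ordinary compound's mean target count.  Returns the
    network and the planted compound ids (the recovery ground truth).
    """
    rng = np.random.default_rng(config.seed)
    tt = _target_layer(config, rng)
    targets = _target_symbols(config)
    by_degree = sorted(targets, key=lambda t: (-tt.degree(t), t))

    lo, hi = config.targets_per_compound
    compound_ids = [f"C{i + 1:04d}" for i in range(config.n_compounds)]
    planted = compound_ids[: config.n_planted_hubs]
    n_planted_targets = int(round(config.planted_hub_boost * (lo + hi) / 2))

    ct_edges: list[tuple[str, str]] = []
    for cid in compound_ids:
        if cid in planted:
            chosen = by_degree[:n_planted_targets]
        else:
            k = int(rng.integers(lo, hi + 1))
            chosen = [targets[i] for i in rng.choice(config.n_targets, size=k, replace=False)]
        ct_edges.extend((cid, t) for t in chosen)

    herb_ids = [f"H{i + 1:02d}" for i in range(config.n_herbs)]
    hc_edges: list[tuple[str, str]] = []
    for cid in compound_ids:
        n_herbs = int(rng.integers(1, min(2, config.n_herbs) + 1))
        for h in rng.choice(config.n_herbs, size=n_herbs, replace=False):
            hc_edges.append((herb_ids[h], cid))

    net = build_pharm_network(hc_edges, ct_edges, list(tt.edges()))
    return net, planted


def synth_compound_catalog(
    config: SynthConfig,
    net: PharmNetwork,
    planted: Sequence[str],
) -> list[CompoundRecord]:
    """Catalog rows for the network's active compounds plus failing decoys.

    Active compounds (planted ones included) draw OB from U(30, 100) and DL
    from U(0.18, 1.0), so they pass the OB >= 30 / DL >= 0.18 screen; decoys
    fail at least one criterion.
    """
    rng = np.random.default_rng(config.seed + 1)
    herbs_of = {
        c: frozenset(n for n in net.graph.neighbors(c) if net.kind_of(n) == "herb")
        for c in net.compounds
    }
    records = [
        CompoundRecord(
            compound_id=c,
            name=f"compound-{c.lower()}",
            herbs=herbs_of[c],
            ob=float(rng.uniform(30.0, 100.0)),
            dl=float(rng.uniform(0.18, 1.0)),
        )
        for c in sorted(net.compounds)
    ]
    herb_ids = sorted(net.herbs)
    for i in range(config.n_decoy_compounds):
        fail_mode = int(rng.integers(3))  # 0: low OB, 1: low DL, 2: both
        ob = float(rng.uniform(0.0, 29.9)) if fail_mode != 1 else float(rng.uniform(30.0, 100.0))
        dl = float(rng.uniform(0.0, 0.179)) if fail_mode != 0 else float(rng.uniform(0.18, 1.0))
        records.append(CompoundRecord(
            compound_id=f"D{i + 1:04d}",
            name=f"decoy-d{i + 1:04d}",
            herbs=frozenset({herb_ids[int(rng.integers(len(herb_ids)))]}),
            ob=ob,
            dl=dl,
        ))
    return records


def synth_ppi_edges(
    config: SynthConfig,
    net: PharmNetwork,
    score_min: float = 0.850,
    n_low_confidence: int | None = None,
) -> list[PPIEdge]:
    """Scored PPI table whose high-confidence part is the target layer.

    True target–target edges get scores strictly above ``score_min``;
    additional random non-edges get sub-threshold scores, so filtering at
    the threshold recovers exactly the planted interactome.
    """
    rng = np.random.default_rng(config.seed + 2)
    targets = sorted(net.targets)
    edges = [
        PPIEdge(u, v, float(rng.uniform(score_min + 0.005, 1.0)))
        for u, v in sorted(
            (tuple(sorted((u, v))) for u, v in net.graph.edges())
        )
        if net.kind_of(u) == "target" and net.kind_of(v) == "target"
    ]
    n_low = len(edges) // 2 if n_low_confidence is None else n_low_confidence
    existing = {frozenset((e.protein_a, e.protein_b)) for e in edges}
    n_added = 0
    while n_added < n_low and len(targets) >= 2:
        u, v = (targets[i] for i in rng.choice(len(targets), size=2, replace=False))
        pair = frozenset((u, v))
        if u == v or pair in existing:
            continue
        edges.append(PPIEdge(u, v, float(rng.uniform(0.15, score_min - 0.005))))
        existing.add(pair)
        n_added += 1
    return edges


def synth_gene_lists(
    config: SynthConfig,
) -> tuple[set[str], set[str], set[str], dict[str, int]]:
    """Three gene lists whose seven exclusive Venn regions match the design.

    Returns (disease, syndrome, formula-target, realized-region-table);
    symbols are drawn from a synthetic universe disjoint from none of the
    lists (each region gets its own block of fresh symbols).
    """
    design = dict(config.overlap_design)
    sets: dict[str, set[str]] = {"disease": set(), "syndrome": set(), "formula": set()}
    counter = 0
    for region in _REGION_KEYS:
        members = region.split("&")
        for _ in range(design[region]):
            counter += 1
            sym = f"V{counter:05d}"
            for m in members:
                sets[m].add(sym)
    return sets["disease"], sets["syndrome"], sets["formula"], design


def synth_expression(
    config: SynthConfig,
    gene_ids: Sequence[str] | None = None,
    planted_genes: Iterable[str] | None = None,
) -> tuple[ExpressionMatrix, list[str]]:
    """Two-group log-normal expression matrix with planted DEGs.

    Baseline log2 abundance per gene is U(6, 12); samples add N(0, sigma)
    noise on the log2 scale, and planted genes are shifted by ``log2fc`` in
    group 1 ("case") — half of them up and half down, so every planted gene
    has |log2 fold change| = log2fc while the sample-wide intensity
    distributions stay comparable (planting everything in one direction
    breaks the equal-distribution assumption of quantile normalization).
    ``planted_genes`` forces specific gene ids to be differentially
    expressed (topped up at random to ``n_deg``); by default the planted set
    is a random draw of size ``n_deg``.
    """
    d = config.expr_design
    rng = np.random.default_rng(config.seed + 3)
    if gene_ids is None:
        gene_ids = [_gene_symbol(i + 1) for i in range(d.n_genes)]
    else:
        gene_ids = list(gene_ids)
        if len(gene_ids) != d.n_genes:
            raise ValueError(f"gene_ids has {len(gene_ids)} entries, expected {d.n_genes}")
    if planted_genes is None:
        planted = sorted(gene_ids[i] for i in
                         rng.choice(d.n_genes, size=d.n_deg, replace=False))
    else:
        planted = sorted(set(planted_genes))
        unknown = set(planted) - set(gene_ids)
        if unknown:
            raise ValueError(f"planted genes not in the matrix: {sorted(unknown)[:5]} ...")
        if len(planted) < d.n_deg:
            pool = sorted(set(gene_ids) - set(planted))
            extra = rng.choice(len(pool), size=d.n_deg - len(planted), replace=False)
            planted = sorted(planted + [pool[i] for i in extra])

    n = d.n_per_group
    samples = [f"case_{i + 1:02d}" for i in range(n)] + \
              [f"ctrl_{i + 1:02d}" for i in range(n)]
    groups = pd.Series(["case"] * n + ["control"] * n, index=samples)
    base = rng.uniform(6.0, 12.0, size=len(gene_ids))
    log2x = base[:, None] + rng.normal(0.0, d.sigma, size=(len(gene_ids), 2 * n))
    planted_idx = [i for i, g in enumerate(gene_ids) if g in set(planted)]
    signs = np.where(np.arange(len(planted_idx)) % 2 == 0, 1.0, -1.0)
    rng.shuffle(signs)
    for idx, sign in zip(planted_idx, signs):
        log2x[idx, :n] += sign * d.log2fc
    matrix = ExpressionMatrix(
        values=pd.DataFrame(np.exp2(log2x), index=gene_ids, columns=samples),
        groups=groups,
    )
    return matrix, planted


def synth_study_gene_lists(
    config: SynthConfig,
    net: PharmNetwork,
    planted: Sequence[str],
) -> tuple[set[str], set[str]]:
    """Disease list and to-be-planted DEG targets, coherent with the network.

    Planted compounds are disease-relevant by construction: every one of
    their targets joins both the disease list and the planted-DEG set.
    Each ordinary network target joins each list independently with
    probability ``target_list_prob``; the disease list additionally carries
    off-network filler genes, as a real curated disease list would.
    """
    rng = np.random.default_rng(config.seed + 4)
    hub_targets: set[str] = set()
    for c in planted:
        hub_targets |= net.targets_of_compound(c)
    ordinary = sorted(set(net.targets) - hub_targets)
    p = config.target_list_prob
    disease = set(hub_targets)
    deg_targets = set(hub_targets)
    draws = rng.random((len(ordinary), 2))
    for (u1, u2), t in zip(draws, ordinary):
        if u1 < p:
            disease.add(t)
        if u2 < p:
            deg_targets.add(t)
    n_filler = config.n_targets // 2
    filler = [f"X{i + 1:05d}" for i in range(n_filler)]
    disease |= set(filler)
    return disease, deg_targets


def write_synthetic_bundle(config: SynthConfig, outdir) -> dict:
    """Generate and write every pipeline input file; returns the truth record.

    Emits exactly the formats the ingest stage reads: compound catalog TSV,
    compound→target and PPI edge TSVs, a disease gene list, an expression
    matrix with its group-assignment file, and a truth JSON naming the
    planted compounds, hub targets and DEGs.
    """
    import json
    from pathlib import Path

    from . import io as npio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    net, planted = synth_pharm_network(config)
    catalog = synth_compound_catalog(config, net, planted)
    ppi = synth_ppi_edges(config, net)
    disease, deg_targets = synth_study_gene_lists(config, net, planted)

    d = config.expr_design
    targets = _target_symbols(config)
    if d.n_genes < config.n_targets:
        raise ValueError("expr_design.n_genes must cover all network targets")
    fillers = [f"F{i + 1:05d}" for i in range(d.n_genes - config.n_targets)]
    matrix, planted_degs = synth_expression(
        config, gene_ids=targets + fillers, planted_genes=sorted(deg_targets))

    ct_edges = sorted(
        (c, t) for c in net.compounds for t in net.targets_of_compound(c))

    npio.write_compound_catalog(catalog, outdir / "compound_catalog.tsv")
    npio.write_edge_table(ct_edges, outdir / "compound_target.tsv",
                          columns=("compound_id", "gene_symbol"))
    npio.write_ppi_table(ppi, outdir / "ppi.tsv")
    npio.write_gene_list(sorted(disease), outdir / "disease_targets.txt")
    npio.write_expression(matrix, outdir / "expression.tsv",
                          outdir / "groups.tsv")

    truth = {
        "planted_compounds": list(planted),
        "planted_hub_targets": sorted(
            set().union(*(net.targets_of_compound(c) for c in planted))
        ) if planted else [],
        "planted_degs": planted_degs,
        "n_network_nodes": len(net),
        "n_network_edges": net.graph.number_of_edges(),
        "seed": config.seed,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    return truth
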