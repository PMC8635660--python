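# Methods

## Model and procedure

`netpharm` ranks compound combinations from a multi-herb formula by how much
their simulated removal destabilises a disease-restricted pharmacology
network. The pipeline has eight stages:

1. **ADMET screen.** Compounds are retained at oral bioavailability
   OB ≥ 30% and drug-likeness DL ≥ 0.18. Both comparisons are inclusive;
   the PPI confidence cutoff (> 0.850) and the DEG criteria (fold change
   > 1.5, p < 0.05) are strict. These asymmetries are deliberate and follow
   the conventions of the screening databases and tools each threshold
   comes from.
2. **DEG filter.** Intensities are quantile-normalized (rank-mean
   construction, ties averaged), log2-transformed, and tested per gene with
   a two-sided Welch t test (Student's behind `equal_var=True`). The fold
   change is the ratio of group geometric means, group levels taken in
   lexicographic order. A gene passes iff its fold change exceeds the
   cutoff in either direction *and* its raw p value is below p_max; a
   Benjamini–Hochberg column is reported but does not gate, since the pass
   rule is a raw-p screening criterion, not an inference.
3. **Target assembly and Venn intersection.** Direct targets of the active
   compounds are expanded exactly one neighbourhood round over the
   score-filtered PPI table. One round, not a transitive closure: on a
   confidence-filtered interactome the closure absorbs most of the
   proteome, while a single round matches the growth magnitudes typical of
   published screens. The disease list, the DEG list and the formula-target
   set are intersected after symbol normalization (trim + upper-case; no
   alias resolution, since none of the supported inputs defines one).
4. **Network build.** Herb–compound, compound–target and target–target
   layers restricted to the intersection targets; simple graph (duplicates
   and self-loops dropped with counted warnings); node kinds typed and
   validated.
5. **Core extraction.** Nodes whose degree, betweenness and closeness all
   strictly exceed the network-wide medians; the induced subgraph is the
   core network. Clustering coefficient and topological coefficient are
   profiled but do not gate by default — their medians are 0 on sparse
   multilayer networks and gating on them empties the core. The gating set
   and strictness are configurable. If the strict rule leaves fewer than
   two compounds the pipeline relaxes to ≥, then to the full network, and
   records which rule was used in the manifest.
6. **Knockouts.** Removing a compound set deletes the compound nodes and
   every adjacent target — including targets shared with surviving
   compounds (a removed compound's pharmacology is removed everywhere; a
   unique-targets-only mode exists behind `shared_targets=False`). The four
   indicators are computed on the *surviving* network state, not as deltas
   from the intact network, because the contribution-score formula consumes
   parameter values directly.
7. **Entropy weighting and selection.** Indicator columns are min–max
   normalized with per-column orientation, entropy-weighted, and combined
   into the contribution score with the robustness weight doubled — exactly
   as the formula is printed, with no renormalization; the undoubled score
   is reported alongside. The top 50% of compounds by score are retained.
8. **Combination ranking.** All 2^p − 1 combinations of the retained
   compounds are knocked out jointly; entropy weights are recomputed over
   the combination rows (combinations are scored on their own scale, not
   with the single-compound weights); ties break lexicographically on the
   "+"-joined combination id under a stable sort.

## Indicator conventions

- **NC** (network centralization) = (n/(n−2))·(d_max/(n−1) − density),
  defined for n ≥ 3; 1 for a star, 0 for regular graphs.
- **CPL** (characteristic path length) = mean shortest-path length over
  unordered *connected* pairs. Disconnected pairs are excluded rather than
  imputed a penalty distance, matching the convention of the standard
  network-analysis tools; closeness is likewise computed within components
  (classical, not harmonic, variant). Betweenness is normalized by
  (n−1)(n−2)/2.
- **NH** (network heterogeneity) = coefficient of variation of the degree
  sequence (population variance); 0 iff the graph is regular.
- **R** (robustness) = C/(N − N_r) with C the largest surviving component,
  N the original node count and N_r the removed count. The source
  expression "R=C(N − Nr)" is read as a quotient: a product of a component
  size and a node count is unbounded and cannot be a stability fraction in
  (0, 1]. Raw C, N, N_r are recoverable from the knockout results so the
  other reading can be recomputed if wanted.
- **Topological coefficient** of a node v with k ≥ 2 neighbours: the mean
  over all nodes m sharing at least one neighbour with v of
  (shared-neighbour count + 1 if m is adjacent to v)/k; 0 for nodes with
  fewer than two neighbours.

## Orientation and selection-mode choices

Which of NC/CPL/NH/R is a "positive" indicator is not dictated by the
score formula, so it is a configuration echoed into every report. The
defaults (CPL and NH positive, NC and R inverse) make a *destabilising*
knockout score high: important compounds fragment the survivors (low R),
de-centralise the hub structure (low NC) and stretch paths (high CPL).

Core-compound retention offers two modes. `per_indicator` intersects the
top-fraction entities of each oriented indicator column (ties at the
cutoff retained; an empty intersection falls back to the combined score).
`score` thresholds the combined contribution score at its top fraction.
The pipeline default is `score`: simulations with a planted hub compound
show that severe knockouts *shrink* the survivor's CPL and NH (shattered
survivors have short within-component paths and homogeneous degrees), so
the per-indicator intersection systematically evicts exactly the most
destabilising compound in roughly one run out of seven, while the combined
score — dominated by the low-entropy R and NC columns — retains it
essentially always. Both modes are exposed (`selection_mode` in the run
config) and tested.

Degenerate inputs are conventions, not errors, where a convention exists:
a constant indicator column gets entropy 1, difference coefficient 0 and
weight 0 (an indicator that does not discriminate carries no weight);
0·ln 0 := 0 in the entropy sum. A knockout that leaves an empty, edgeless
or sub-3-node survivor has undefined indicators; such entities are
excluded from the matrix with a logged reason and surfaced in reports.

## Synthetic data: what it emulates and what it does not

The generators produce every input the pipeline reads, with planted ground
truth so each stage can be scored against a known answer:

- **Tripartite network** — a scale-free (Barabási–Albert, m = 2)
  target–target layer; ordinary compounds attach to 3–8 uniformly chosen
  targets; planted compounds attach to the top-degree hubs and to
  `planted_hub_boost` × the mean compound target count of them. Planted
  compounds are thereby high-impact by construction: removing them removes
  the network's shortcuts.
- **Catalog** — active compounds draw OB ~ U(30, 100), DL ~ U(0.18, 1);
  decoy compounds fail at least one criterion.
- **PPI table** — true target edges score above the 0.850 cutoff, plus
  sub-threshold decoy edges, so threshold filtering recovers exactly the
  planted interactome.
- **Gene lists** — either exact seven-region Venn designs (default region
  sizes emulate lists of ~1191 disease genes, ~1116 syndrome DEGs, ~859
  formula targets with a 181-gene triple intersection), or study-coherent
  lists in which each network target joins each list with probability 0.7
  and planted-hub targets join with probability 1 (the planted compound is
  disease-relevant by design — that is what the recovery experiment
  measures).
- **Expression** — log2-normal baseline U(6, 12) per gene, N(0, σ) sample
  noise, planted genes shifted by the design log2FC, half up and half down.
  Balanced directions keep |log2FC| at the design value for every planted
  gene while preserving the equal-distribution assumption that quantile
  normalization requires; planting a large DEG fraction in one direction
  inflates the null false-positive rate to ~0.35.

What the generators do **not** emulate: real TCM database content,
probe-level intensity artefacts, correlated gene expression, identifier
aliasing, or literature-curated disease lists. Passing tests therefore
demonstrate that the algorithms are implemented correctly and that the
pipeline recovers planted signal under clean, favourable conditions — not
that the protocol's biological nominations on real data are correct.

## Reference experiment sizes

The recovery experiment uses 17 compounds over 300 targets (6 herbs, one
planted hub at boost 5), a 600-gene 16-vs-16 expression design, and 100
replicates; these sizes keep each replicate's core network large enough
that a single knockout removes a modest fraction of it, which is the
regime the post-knockout indicator formulation is meant for. The DEG
operating characteristics use 1000 genes with 100 planted DEGs at
|log2FC| = 1.5, σ = 0.5, 16 per group, 20 replicates. All replicates are
seeded deterministically from one base seed.

## Known limitations

- The contribution score is computed on normalized z values; the printed
  formula names raw indicators, but raw CPL (≈1–4) and NC (≤1) are not
  commensurate, and the normalization step exists precisely to put them on
  one scale. A raw-value mode is available (`raw_score_mode`).
- Combination scores are comparable only within one ranking run: entropy
  weights depend on the whole indicator matrix, so adding or removing
  entities rescales every score.
- Post-knockout indicator values (rather than deltas) make very large
  knockouts look partially "stabilising" on CPL/NH; the selection-mode
  default above compensates. A delta mode would sidestep this but would no
  longer match the printed score formula; it is left as future work.
- Structure-based target prediction is consumed as a precomputed
  compound→target table; no chemical-structure handling is attempted.
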