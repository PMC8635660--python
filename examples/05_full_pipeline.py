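"""The complete protocol, end to end, from generated input files.

Writes a synthetic input bundle (compound catalog, compound-target map,
scored PPI table, disease gene list, expression matrix), runs every
pipeline stage at the default thresholds, and reports the ranked
combinations alongside the planted ground truth.
"""

import tempfile
from pathlib import Path

from netpharm import RunConfig, SynthConfig, ExpressionDesign, run_pipeline
from netpharm.synthetic import write_synthetic_bundle

config = SynthConfig(
    n_herbs=6, n_compounds=17, n_targets=300, n_decoy_compounds=8,
    targets_per_compound=(3, 8), n_planted_hubs=1, planted_hub_boost=5.0,
    expr_design=ExpressionDesign(n_genes=600, n_per_group=16, n_deg=250),
    seed=2024,
)

with tempfile.TemporaryDirectory() as tmp:
    bundle = Path(tmp) / "bundle"
    truth = write_synthetic_bundle(config, bundle)
    print(f"planted hub compound: {truth['planted_compounds'][0]} "
          f"({len(truth['planted_hub_targets'])} hub targets)")

    rc = RunConfig(
        catalog=str(bundle / "compound_catalog.tsv"),
        compound_target=str(bundle / "compound_target.tsv"),
        ppi=str(bundle / "ppi.tsv"),
        disease_targets=str(bundle / "disease_targets.txt"),
        expression=str(bundle / "expression.tsv"),
        groups=str(bundle / "groups.tsv"),
        outdir=str(Path(tmp) / "run"),
        seed=2024,
    )
    manifest = run_pipeline(rc)

    for stage, info in manifest["stages"].items():
        print(f"  {stage:<9} {info}")
    top = manifest["stages"]["rank"]["top_combination"]
    print(f"\ntop-ranked combination: {top}")
    print(f"planted compound recovered: "
          f"{truth['planted_compounds'][0] in top.split('+')}")
    print("The pipeline screened the catalog, called DEGs, intersected the")
    print("three target lists, built and cored the network, knocked out each")
    print("core compound, and ranked all combinations of the retained")
    print("compounds by entropy-weighted contribution score.")
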