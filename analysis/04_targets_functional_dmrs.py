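"""Map DMR target genes and define functional DMRs and seDMRs.

Promoter targets are the downstream gene (one-to-one); enhancer targets
come from the PET-filtered interaction map (many-to-many). A functional
DMR's target is a DEG changing in the opposite direction. Super-enhancer
DMRs are super-enhancers overlapping called eDMRs. Precision/recall of the
functional pairs is scored against the planted coupling.
"""

from pathlib import Path

from regmeth.cohort import read_cohort
from regmeth.evaluate import functional_pair_recovery
from regmeth.pipeline import PipelineConfig, stage_deg, stage_dmr, stage_targets

COHORT = Path("results/cohort")
OUT = Path("results")


def main() -> None:
    bundle = read_cohort(COHORT)
    config = PipelineConfig(input_dir=str(COHORT))
    dmr_out = stage_dmr(bundle, config)
    degs = stage_deg(bundle, config)
    targets = stage_targets(bundle, dmr_out, degs, config)
    for name in ("targets", "functional_pairs", "functional_dmrs", "sedmrs"):
        targets[name].to_csv(OUT / f"{name}.tsv", sep="\t", index=False, float_format="%.6g")
    pairs = targets["functional_pairs"]
    per_kind = pairs[pairs["is_functional"]].groupby("kind")["region_id"].nunique()
    print(f"target links: {len(targets['targets'])}")
    print(
        f"functional DMRs: {per_kind.get('promoter', 0)} promoter / "
        f"{per_kind.get('enhancer', 0)} enhancer"
    )
    print(f"seDMRs: {len(targets['sedmrs'])}")
    scores = functional_pair_recovery(pairs, bundle.truth.true_functional)
    print(
        f"functional pairs vs truth: precision {scores['precision']:.3f}, "
        f"recall {scores['recall']:.3f}"
    )


if __name__ == "__main__":
    main()
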