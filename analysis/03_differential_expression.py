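"""Call differentially expressed genes on the simulated cohort.

Median-of-ratios normalization, paired t on log2(normalized + 1), BH;
DEG = |log2FC| > 2 (strict) and q < 0.01. The called set should be
dominated by the genes planted with inverse methylation coupling.
"""

from pathlib import Path

from regmeth.cohort import read_cohort
from regmeth.pipeline import PipelineConfig, stage_deg

COHORT = Path("results/cohort")


def main() -> None:
    bundle = read_cohort(COHORT)
    degs = stage_deg(bundle, PipelineConfig(input_dir=str(COHORT)))
    degs.to_csv("results/degs.tsv", sep="\t", index=False, float_format="%.6g")
    called = degs[degs["is_deg"]]
    up = (called["direction"] == "up").sum()
    print(f"DEGs: {len(called)} of {len(degs)} genes ({up} up / {len(called) - up} down)")
    planted = set(bundle.truth.true_functional["gene_id"])
    print(
        f"planted coupled genes recovered: "
        f"{len(planted & set(called['gene_id']))} / {len(planted)}"
    )


if __name__ == "__main__":
    main()
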