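"""Generate the default synthetic cohort and write every input table.

Emits a 37-pair tumor/normal cohort (2000 promoters, 3000 enhancers, ~50k
CpGs) with planted DMRs (hypomethylation-dominant), inverse
methylation-expression coupling, infiltration coupling biased toward
enhancer DMRs, and risk SNPs placed near DMRs — plus the ground-truth
tables the later scripts score against.
"""

from pathlib import Path

from regmeth.cohort import SyntheticConfig, generate_cohort, write_cohort

OUT = Path("results/cohort")


def main() -> None:
    cfg = SyntheticConfig(seed=1)
    bundle = generate_cohort(cfg)
    manifest = write_cohort(bundle, OUT)
    truth = bundle.truth.true_dmrs
    print(f"wrote {len(manifest)} files to {OUT}")
    print(f"samples: {len(bundle.samples)} ({cfg.n_pairs} pairs); CpGs: {len(bundle.cpgs)}")
    for kind in ("promoter", "enhancer"):
        sub = truth[truth["kind"] == kind]["direction"].value_counts()
        print(
            f"planted {kind} DMRs: {sub.sum()} "
            f"({sub.get('hypo', 0)} hypo / {sub.get('hyper', 0)} hyper)"
        )
    print(f"planted functional pairs: {len(bundle.truth.true_functional)}")
    print(f"planted infiltration couplings: {len(bundle.truth.true_imr)}")


if __name__ == "__main__":
    main()
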