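"""Scoring of pipeline calls against the generator's planted truth."""

from __future__ import annotations

import pandas as pd


def dmr_recovery(dmrs: pd.DataFrame, true_dmrs: pd.DataFrame) -> dict:
    """Sensitivity, observed FDR, and direction accuracy of DMR calls.

    ``dmrs`` may be the concatenation of the promoter and enhancer tables;
    sensitivity is over planted regions present in the tested universe.
    """
    truth_dir = dict(zip(true_dmrs["region_id"], true_dmrs["direction"]))
    tested = dmrs[dmrs["testable"]] if "testable" in dmrs else dmrs
    called = tested[tested["is_dmr"]]
    planted_tested = tested[tested["region_id"].isin(truth_dir)]
    n_true_called = int(called["region_id"].isin(truth_dir).sum())
    sensitivity = (
        n_true_called / len(planted_tested) if len(planted_tested) else float("nan")
    )
    fdr = (
        (len(called) - n_true_called) / len(called) if len(called) else 0.0
    )
    true_calls = called[called["region_id"].isin(truth_dir)]
    if len(true_calls):
        correct = sum(
            d == truth_dir[r]
            for r, d in zip(true_calls["region_id"], true_calls["direction"])
        )
        direction_accuracy = correct / len(true_calls)
    else:
        direction_accuracy = float("nan")
    return {
        "n_planted": len(planted_tested),
        "n_called": len(called),
        "n_true_called": n_true_called,
        "sensitivity": sensitivity,
        "fdr": fdr,
        "direction_accuracy": direction_accuracy,
    }


def functional_pair_recovery(
    functional_pairs: pd.DataFrame, true_functional: pd.DataFrame
) -> dict:
    """Precision/recall of called functional (DMR, gene) pairs vs planted pairs."""
    called = {
        (r, g)
        for r, g, f in functional_pairs[
            ["region_id", "gene_id", "is_functional"]
        ].itertuples(index=False)
        if f
    }
    planted = set(
        true_functional[["region_id", "gene_id"]].itertuples(index=False, name=None)
    )
    tp = len(called & planted)
    precision = tp / len(called) if called else float("nan")
    recall = tp / len(planted) if planted else float("nan")
    return {
        "n_called": len(called),
        "n_planted": len(planted),
        "n_true": tp,
        "precision": precision,
        "recall": recall,
    }


def imr_recovery(imrs: pd.DataFrame, true_imr: pd.DataFrame) -> dict:
    """Recall of planted (region, cell type) couplings among called IMR pairs."""
    called = {
        (r, c)
        for r, c, f in imrs[["region_id", "cell_type", "is_imr"]].itertuples(index=False)
        if f
    }
    planted = set(
        true_imr[["region_id", "cell_type"]].itertuples(index=False, name=None)
    )
    tp = len(called & planted)
    return {
        "n_called": len(called),
        "n_planted": len(planted),
        "n_true": tp,
        "recall": tp / len(planted) if planted else float("nan"),
        "precision": tp / len(called) if called else float("nan"),
    }
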