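"""Score pipeline calls against the simulator's ground truth.

Each function returns a flat dict of counts and rates so results can be
serialized directly (TSV/JSON).  Sensitivity = called planted features /
planted features; the false-call rate is computed over unplanted features
(the null part of the cohort).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["evaluate_ir", "evaluate_deg", "evaluate_as"]


def evaluate_ir(ir_classified: pd.DataFrame, intron_truth: pd.DataFrame) -> dict:
    """Confusion summary for IR/MES intron calls."""
    merged = ir_classified.merge(
        intron_truth[["gene_id", "intron_index", "planted"]],
        on=["gene_id", "intron_index"],
        how="left",
    )
    merged["planted"] = merged["planted"].fillna("none")
    out: dict[str, float] = {}
    for label in ("IR", "MES"):
        planted = merged["planted"] == label
        n_planted = int(planted.sum())
        tp = int((planted & (merged["call"] == label)).sum())
        out[f"n_planted_{label}"] = n_planted
        out[f"n_detected_{label}"] = tp
        out[f"sensitivity_{label}"] = tp / n_planted if n_planted else float("nan")
    unplanted = merged["planted"] == "none"
    false_calls = int((unplanted & (merged["call"] != "none")).sum())
    out["n_unplanted"] = int(unplanted.sum())
    out["n_false_calls"] = false_calls
    out["false_call_rate"] = (
        false_calls / int(unplanted.sum()) if unplanted.any() else float("nan")
    )
    return out


def evaluate_deg(deg_table: pd.DataFrame, deg_truth: pd.DataFrame) -> dict:
    """Confusion summary for up/down DEG calls."""
    merged = deg_table.reset_index().merge(
        deg_truth[["gene_id", "planted"]], on="gene_id", how="left"
    )
    merged["planted"] = merged["planted"].fillna("none")
    out: dict[str, float] = {}
    for label in ("up", "down"):
        planted = merged["planted"] == label
        n_planted = int(planted.sum())
        tp = int((planted & (merged["call"] == label)).sum())
        out[f"n_planted_{label}"] = n_planted
        out[f"n_detected_{label}"] = tp
        out[f"sensitivity_{label}"] = tp / n_planted if n_planted else float("nan")
    unplanted = merged["planted"] == "none"
    false_calls = int((unplanted & (merged["call"] != "none")).sum())
    out["n_unplanted"] = int(unplanted.sum())
    out["n_false_calls"] = false_calls
    out["false_call_rate"] = (
        false_calls / int(unplanted.sum()) if unplanted.any() else float("nan")
    )
    return out


def evaluate_as(
    as_table: pd.DataFrame,
    alt_truth: pd.DataFrame,
    exon_truth: pd.DataFrame,
) -> dict:
    """Detection summary for planted alternative-junction and skip events."""
    out: dict[str, float] = {}
    reported = as_table[as_table["reported"]] if len(as_table) else as_table

    n_alt = len(alt_truth)
    detected_alt = 0
    for row in alt_truth.itertuples():
        hit = reported[
            (reported["gene_id"] == row.gene_id)
            & (reported["donor"] == row.alt_donor)
            & (reported["acceptor"] == row.alt_acceptor)
        ]
        detected_alt += int(len(hit) > 0)
    out["n_planted_alt"] = n_alt
    out["n_detected_alt"] = detected_alt
    out["sensitivity_alt"] = detected_alt / n_alt if n_alt else float("nan")

    planted_exons = exon_truth[exon_truth["planted"]]
    n_es = len(planted_exons)
    detected_es = 0
    for row in planted_exons.itertuples():
        hit = reported[
            (reported["gene_id"] == row.gene_id)
            & (reported["event_type"] == "exon_skip")
            & (reported["feature_start"] == row.exon_start)
            & (reported["feature_end"] == row.exon_end)
        ]
        detected_es += int(len(hit) > 0)
    out["n_planted_es"] = n_es
    out["n_detected_es"] = detected_es
    out["sensitivity_es"] = detected_es / n_es if n_es else float("nan")

    # reported events not matching any planted alt/skip feature
    truth_keys = {
        (r.gene_id, r.alt_donor, r.alt_acceptor) for r in alt_truth.itertuples()
    } | {
        (r.gene_id, "ES", r.exon_start, r.exon_end)
        for r in planted_exons.itertuples()
    }
    n_false = 0
    for row in reported.itertuples():
        if row.event_type == "exon_skip":
            key = (row.gene_id, "ES", row.feature_start, row.feature_end)
        else:
            key = (row.gene_id, row.donor, row.acceptor)
        if key not in truth_keys:
            n_false += 1
    out["n_false_reported"] = n_false
    return out
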