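"""Differential splicing statistics between two conditions.

Two families of tests, both two-condition Welch t-tests across biological
replicates:

* **Intron retention.**  Each intron's retention ratio in a replicate is its
  mean per-base read depth divided by the mean per-base depth of its two
  neighboring exons (pooled base-wise).  An intron is called IR (retention
  up in the mutant) or MES (more efficient splicing — retention down) when
  the t-test p-value is below the cutoff and the mutant group mean is at
  least ``fold``-times higher resp. lower than the wild-type mean.

* **Junction-defined events** (exon skipping, alternative donor/acceptor).
  Candidates come from observed junctions that disagree with the
  annotation.  Two evidence channels are tested: the AS ratio
  (supporting / non-supporting junction reads) and the expression ratio
  (supporting reads / reads unique to the gene), each with a pseudocount,
  log2-transformed.  An event is reported only when BOTH p-values pass,
  and classified enhanced/reduced from the mutant:wild-type fold of the
  mean expression ratio.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignments import DepthProfile
from .annotation import AnnotationSet, GeneModel, neighboring_exons
from .stats import welch_ttest_rows

__all__ = [
    "intron_retention_ratio",
    "intron_retention_table",
    "classify_introns",
    "as_ratio",
    "expression_ratio",
    "enumerate_as_events",
    "classify_as_events",
    "summarize_events",
    "ExclusionList",
]

JunctionCounts = dict[tuple[str, int, int], int]


class ExclusionList:
    """Genomic intervals whose introns/junctions are dropped before testing.

    Stands in for removing loci whose splice sites carry confounding
    second-site mutations discovered by genome re-sequencing.
    """

    def __init__(self, intervals: list[tuple[str, int, int]] | None = None):
        self.intervals = sorted(intervals or [])

    @classmethod
    def from_tsv(cls, path) -> "ExclusionList":
        ivs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                chrom, start, end = line.split("\t")[:3]
                ivs.append((chrom, int(start), int(end)))
        return cls(ivs)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return any(
            c == chrom and s <= end and start <= e
            for c, s, e in self.intervals
        )

    def __len__(self) -> int:
        return len(self.intervals)


def intron_retention_ratio(
    depth: DepthProfile,
    gene: GeneModel,
    intron_index: int,
    pool_flanks: bool = True,
) -> float:
    """Retention ratio of one intron in one replicate.

    Mean per-base depth over the intron divided by the mean per-base depth
    of the two neighboring exons.  By default the flanks are pooled
    base-wise (one average over all flank bases); ``pool_flanks=False``
    averages the two per-exon means instead.  Returns NaN (a flag, never a
    coerced 0 or inf) when the flank depth is zero.
    """
    intron = gene.introns[intron_index].interval
    up, down = neighboring_exons(gene, intron_index)
    intron_depth = depth.mean_depth(gene.chrom, intron.start, intron.end)
    if pool_flanks:
        flank_depth = depth.mean_depth_intervals(
            gene.chrom, [(up.start, up.end), (down.start, down.end)]
        )
    else:
        flank_depth = 0.5 * (
            depth.mean_depth(gene.chrom, up.start, up.end)
            + depth.mean_depth(gene.chrom, down.start, down.end)
        )
    if flank_depth == 0.0:
        return float("nan")
    return intron_depth / flank_depth


def intron_retention_table(
    depths: dict[str, DepthProfile],
    annotation: AnnotationSet,
    pool_flanks: bool = True,
) -> pd.DataFrame:
    """Per-intron retention ratios for every sample.

    One row per (gene, intron); ratio columns are named ``ratio_<sample>``.
    """
    rows = []
    samples = list(depths)
    for gene in annotation:
        for idx, intron in enumerate(gene.introns):
            row = {
                "gene_id": gene.gene_id,
                "chrom": gene.chrom,
                "strand": gene.strand,
                "intron_index": idx,
                "start": intron.interval.start,
                "end": intron.interval.end,
            }
            for sample in samples:
                row[f"ratio_{sample}"] = intron_retention_ratio(
                    depths[sample], gene, idx, pool_flanks=pool_flanks
                )
            rows.append(row)
    cols = ["gene_id", "chrom", "strand", "intron_index", "start", "end"] + [
        f"ratio_{s}" for s in samples
    ]
    return pd.DataFrame(rows, columns=cols)


def classify_introns(
    table: pd.DataFrame,
    groups: dict[str, str],
    wildtype: str = "wt",
    mutant: str = "mut",
    p_threshold: float = 0.01,
    fold_threshold: float = 2.0,
    use_log: bool = True,
    log_eps: float = 1e-6,
    exclusion: ExclusionList | None = None,
) -> pd.DataFrame:
    """Attach group means, Welch p-values and IR/MES calls to a ratio table.

    The t-test runs on log2 ratios by default: retention ratios are
    positive with multiplicative noise, and the log transform stabilizes
    the variance across retention levels, which matters at n = 3 where the
    Welch degrees of freedom collapse when one group's variance dominates
    (``use_log=False`` tests the raw ratios instead).  The fold gate always
    compares the raw group means.

    Introns with any undefined (NaN) replicate ratio, or on the exclusion
    list, are excluded from testing; the returned frame keeps them with
    ``excluded_reason`` set so nothing is silently dropped.
    """
    wt_cols = [f"ratio_{s}" for s, g in groups.items() if g == wildtype]
    mut_cols = [f"ratio_{s}" for s, g in groups.items() if g == mutant]
    if len(wt_cols) < 2 or len(mut_cols) < 2:
        raise ValueError("need >= 2 replicates per group")
    out = table.copy()
    wt = out[wt_cols].to_numpy(dtype=float)
    mut = out[mut_cols].to_numpy(dtype=float)
    flagged = np.isnan(wt).any(axis=1) | np.isnan(mut).any(axis=1)
    excluded_reason = np.where(flagged, "undefined_ratio", "")
    if exclusion is not None and len(exclusion):
        on_list = np.array(
            [
                exclusion.overlaps(r.chrom, r.start, r.end)
                for r in out.itertuples()
            ]
        )
        excluded_reason = np.where(on_list, "exclusion_list", excluded_reason)
        flagged = flagged | on_list

    mean_wt = np.where(flagged, np.nan, wt.mean(axis=1))
    mean_mut = np.where(flagged, np.nan, mut.mean(axis=1))
    p = np.full(len(out), np.nan)
    ok = ~flagged
    if ok.any():
        if use_log:
            _, p_ok = welch_ttest_rows(
                np.log2(mut[ok] + log_eps), np.log2(wt[ok] + log_eps)
            )
        else:
            _, p_ok = welch_ttest_rows(mut[ok], wt[ok])
        p[ok] = p_ok
    with np.errstate(divide="ignore", invalid="ignore"):
        fold_up = mean_mut >= fold_threshold * mean_wt
        fold_down = mean_mut <= mean_wt / fold_threshold
    call = np.full(len(out), "none", dtype=object)
    sig = ok & (p < p_threshold)
    call[sig & fold_up] = "IR"
    call[sig & fold_down] = "MES"
    out["mean_ratio_wt"] = np.where(flagged, np.nan, mean_wt)
    out["mean_ratio_mut"] = np.where(flagged, np.nan, mean_mut)
    out["p_value"] = p
    out["call"] = call
    out["excluded_reason"] = excluded_reason
    return out


def as_ratio(supporting: float, non_supporting: float, pseudocount: float = 1.0) -> float:
    """(supporting + c) / (non_supporting + c); with c=0 this is the plain
    supporting/non-supporting ratio."""
    return (supporting + pseudocount) / (non_supporting + pseudocount)


def expression_ratio(
    supporting: float, unique_gene_reads: float, pseudocount: float = 1.0
) -> float:
    """(supporting + c) / (unique gene reads + c)."""
    return (supporting + pseudocount) / (unique_gene_reads + pseudocount)


@dataclass
class _JunctionIndex:
    """Observed junctions on one chromosome, sorted by donor boundary."""

    donors: list[int]
    items: list[tuple[int, int]]  # (donor, acceptor), sorted

    def in_donor_range(self, lo: int, hi: int) -> list[tuple[int, int]]:
        i = bisect.bisect_left(self.donors, lo)
        j = bisect.bisect_right(self.donors, hi)
        return self.items[i:j]


def _build_junction_universe(
    junctions: dict[str, JunctionCounts],
) -> dict[str, _JunctionIndex]:
    universe: set[tuple[str, int, int]] = set()
    for counts in junctions.values():
        universe.update(k for k, v in counts.items() if v > 0)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, donor, acceptor in universe:
        by_chrom.setdefault(chrom, []).append((donor, acceptor))
    out = {}
    for chrom, items in by_chrom.items():
        items.sort()
        out[chrom] = _JunctionIndex([d for d, _ in items], items)
    return out


def _alt_side(strand: str, donor_differs: bool, acceptor_differs: bool) -> str:
    """Strand-aware event label: the left genomic boundary is the donor
    (5' splice site) on '+' and the acceptor (3' splice site) on '-'."""
    if donor_differs and acceptor_differs:
        return "alt_both"
    left_differs = donor_differs
    if strand == "+":
        return "alt_donor" if left_differs else "alt_acceptor"
    return "alt_acceptor" if left_differs else "alt_donor"


def enumerate_as_events(
    junctions: dict[str, JunctionCounts],
    annotation: AnnotationSet,
    exclusion: ExclusionList | None = None,
) -> pd.DataFrame:
    """Candidate junction-defined events with per-sample evidence counts.

    Exon skipping: for every internal exon, a candidate exists when at
    least one read joins its two flanking exons directly; supporting reads
    are those skip junctions, non-supporting reads are junctions linking
    the skipped exon to either flank.

    Alternative donor/acceptor: for every annotated intron, any observed
    junction over the same exon pair (both endpoints within the flanking
    exons or the intron) that differs from the annotated boundaries is a
    candidate; supporting = novel junction, non-supporting = annotated
    junction.  The side label (5'/3' splice site) is strand-aware;
    ``alt_both`` when both boundaries differ.
    """
    samples = list(junctions)
    index = _build_junction_universe(junctions)
    rows: list[dict] = []
    seen: set[tuple] = set()

    def counts_for(chrom: str, donor: int, acceptor: int) -> dict[str, int]:
        key = (chrom, donor, acceptor)
        return {s: junctions[s].get(key, 0) for s in samples}

    for gene in annotation:
        chrom_index = index.get(gene.chrom)
        if chrom_index is None:
            continue
        # --- exon skipping -------------------------------------------------
        for t_idx, exons in enumerate(gene.transcripts):
            for k in range(1, len(exons) - 1):
                prev_e, exon, next_e = exons[k - 1], exons[k], exons[k + 1]
                skip_key = (gene.chrom, prev_e.end, next_e.start)
                supp = counts_for(*skip_key)
                if sum(supp.values()) == 0:
                    continue
                dedup = ("ES", gene.gene_id, prev_e.end, next_e.start)
                if dedup in seen:
                    continue
                seen.add(dedup)
                left = counts_for(gene.chrom, prev_e.end, exon.start)
                right = counts_for(gene.chrom, exon.end, next_e.start)
                row = {
                    "gene_id": gene.gene_id,
                    "chrom": gene.chrom,
                    "strand": gene.strand,
                    "event_type": "exon_skip",
                    "donor": prev_e.end,
                    "acceptor": next_e.start,
                    "ref_donor": prev_e.end,
                    "ref_acceptor": next_e.start,
                    "feature_start": exon.start,
                    "feature_end": exon.end,
                }
                for s in samples:
                    row[f"supp_{s}"] = supp[s]
                    row[f"nonsupp_{s}"] = left[s] + right[s]
                rows.append(row)
        # --- alternative donor/acceptor ------------------------------------
        for idx, intron in enumerate(gene.introns):
            iv = intron.interval
            up, down = neighboring_exons(gene, idx)
            ref_donor, ref_acceptor = up.end, down.start
            for donor, acceptor in chrom_index.in_donor_range(up.start, iv.end):
                if acceptor < iv.start or acceptor > down.end:
                    continue
                if donor == ref_donor and acceptor == ref_acceptor:
                    continue
                # exclude junctions that are exactly another annotated intron
                if any(
                    donor == i2.interval.start - 1 and acceptor == i2.interval.end + 1
                    for i2 in gene.introns
                ):
                    continue
                dedup = ("ALT", gene.gene_id, iv.start, iv.end, donor, acceptor)
                if dedup in seen:
                    continue
                seen.add(dedup)
                supp = counts_for(gene.chrom, donor, acceptor)
                nonsupp = counts_for(gene.chrom, ref_donor, ref_acceptor)
                row = {
                    "gene_id": gene.gene_id,
                    "chrom": gene.chrom,
                    "strand": gene.strand,
                    "event_type": _alt_side(
                        gene.strand, donor != ref_donor, acceptor != ref_acceptor
                    ),
                    "donor": donor,
                    "acceptor": acceptor,
                    "ref_donor": ref_donor,
                    "ref_acceptor": ref_acceptor,
                    "feature_start": iv.start,
                    "feature_end": iv.end,
                }
                for s in samples:
                    row[f"supp_{s}"] = supp[s]
                    row[f"nonsupp_{s}"] = nonsupp[s]
                rows.append(row)

    cols = [
        "gene_id",
        "chrom",
        "strand",
        "event_type",
        "donor",
        "acceptor",
        "ref_donor",
        "ref_acceptor",
        "feature_start",
        "feature_end",
    ] + [f"supp_{s}" for s in samples] + [f"nonsupp_{s}" for s in samples]
    df = pd.DataFrame(rows, columns=cols)
    if exclusion is not None and len(exclusion) and len(df):
        keep = [
            not exclusion.overlaps(r.chrom, min(r.donor, r.ref_donor),
                                   max(r.acceptor, r.ref_acceptor))
            for r in df.itertuples()
        ]
        df = df[keep].reset_index(drop=True)
    return df.sort_values(
        ["chrom", "feature_start", "gene_id", "event_type", "donor", "acceptor"]
    ).reset_index(drop=True)


def classify_as_events(
    candidates: pd.DataFrame,
    gene_unique: pd.DataFrame,
    groups: dict[str, str],
    wildtype: str = "wt",
    mutant: str = "mut",
    p_threshold: float = 0.01,
    fold_threshold: float = 2.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Test candidates with the dual AS-ratio / expression-ratio t-tests.

    ``gene_unique`` is a genes x samples frame of unique read counts.
    Events are ``reported`` when both Welch p-values (on log2 ratios) are
    below the threshold; ``call`` is enhanced/reduced from the mean raw
    expression-ratio fold in mutant vs wild type, else ``none``.
    """
    samples = list(groups)
    wt_s = [s for s in samples if groups[s] == wildtype]
    mut_s = [s for s in samples if groups[s] == mutant]
    if len(wt_s) < 2 or len(mut_s) < 2:
        raise ValueError("need >= 2 replicates per group")
    out = candidates.copy()
    if not len(out):
        for col in (
            "p_as",
            "p_expr",
            "mean_expr_ratio_wt",
            "mean_expr_ratio_mut",
        ):
            out[col] = pd.Series(dtype=float)
        out["reported"] = pd.Series(dtype=bool)
        out["call"] = pd.Series(dtype=object)
        return out

    supp = out[[f"supp_{s}" for s in samples]].to_numpy(dtype=float)
    nonsupp = out[[f"nonsupp_{s}" for s in samples]].to_numpy(dtype=float)
    uniq = gene_unique.loc[out["gene_id"], samples].to_numpy(dtype=float)

    asr = (supp + pseudocount) / (nonsupp + pseudocount)
    expr = (supp + pseudocount) / (uniq + pseudocount)
    wt_idx = [samples.index(s) for s in wt_s]
    mut_idx = [samples.index(s) for s in mut_s]
    _, p_as = welch_ttest_rows(np.log2(asr[:, mut_idx]), np.log2(asr[:, wt_idx]))
    _, p_expr = welch_ttest_rows(np.log2(expr[:, mut_idx]), np.log2(expr[:, wt_idx]))
    mean_wt = expr[:, wt_idx].mean(axis=1)
    mean_mut = expr[:, mut_idx].mean(axis=1)
    reported = (p_as < p_threshold) & (p_expr < p_threshold)
    call = np.full(len(out), "none", dtype=object)
    call[reported & (mean_mut >= fold_threshold * mean_wt)] = "enhanced"
    call[reported & (mean_mut <= mean_wt / fold_threshold)] = "reduced"
    out["p_as"] = p_as
    out["p_expr"] = p_expr
    out["mean_expr_ratio_wt"] = mean_wt
    out["mean_expr_ratio_mut"] = mean_mut
    out["reported"] = reported
    out["call"] = call
    return out


def summarize_events(
    annotation: AnnotationSet,
    deg_table: pd.DataFrame | None = None,
    ir_table: pd.DataFrame | None = None,
    as_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Summary counts per event class with percentages of the annotated
    feature universe (introns for IR/MES/alt-site classes, internal exons
    for exon skipping).  DEG rows carry no percentage."""
    n_introns = annotation.total_introns
    n_internal = annotation.total_internal_exons

    def pct(count: int, denom: int) -> float:
        return 100.0 * count / denom if denom else float("nan")

    rows = []
    if deg_table is not None:
        rows.append(("DEG_up", int((deg_table["call"] == "up").sum()), np.nan))
        rows.append(("DEG_down", int((deg_table["call"] == "down").sum()), np.nan))
    if ir_table is not None:
        n_ir = int((ir_table["call"] == "IR").sum())
        n_mes = int((ir_table["call"] == "MES").sum())
        rows.append(("IR", n_ir, pct(n_ir, n_introns)))
        rows.append(("MES", n_mes, pct(n_mes, n_introns)))
    if as_table is not None:
        rep = as_table[as_table["reported"]] if len(as_table) else as_table
        n_es = int((rep["event_type"] == "exon_skip").sum()) if len(rep) else 0
        n_5 = int((rep["event_type"] == "alt_donor").sum()) if len(rep) else 0
        n_3 = int((rep["event_type"] == "alt_acceptor").sum()) if len(rep) else 0
        n_b = int((rep["event_type"] == "alt_both").sum()) if len(rep) else 0
        rows.append(("ES", n_es, pct(n_es, n_internal)))
        rows.append(("alt_5ss", n_5, pct(n_5, n_introns)))
        rows.append(("alt_3ss", n_3, pct(n_3, n_introns)))
        rows.append(("alt_both", n_b, pct(n_b, n_introns)))
    return pd.DataFrame(rows, columns=["category", "count", "percent"])
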