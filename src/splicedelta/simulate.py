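"""Synthetic two-condition RNA-seq cohort with known splicing ground truth.

The generator emulates the design of a mutant-vs-wild-type splicing study:
two conditions with three biological replicates each, multi-exon genes,
intron-retention-dominated differential splicing, and an optional dual-
intron reporter locus whose two 3' splice sites lie a few nt apart.  Every
fragment independently realizes its splicing structure (exon skips, intron
retention, alternative junction usage), so all downstream statistics have a
recoverable generative truth.

Generative model per gene, condition and replicate:

* fragment count ~ Poisson(expression x DEG multiplier x 2^N(0, sd)) —
  the log-normal term creates realistic between-replicate variance;
* each internal exon is skipped with its per-condition probability; a
  skipped exon forces a direct junction between annotated flank boundaries;
* each remaining intron is retained with its per-condition probability
  (retained introns yield contiguous coverage, spliced ones N-gap CIGARs);
* a spliced intron with a planted alternative junction uses the shifted
  donor/acceptor boundaries with its per-condition usage fraction;
* fragment start positions are uniform along the realized transcript;
  single-end reads of fixed length.

Reads carry NM/MD tags consistent with a perfect alignment, so the
acceptance filters see identity 1.0 and full terminal match runs.
Ground-truth tables (per-intron retention, planted events, per-read
junction logs, fragment counts) are returned in memory and written as TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, GeneModel, GenomicInterval, write_gff3

__all__ = [
    "AltJunctionSpec",
    "ReporterLocusSpec",
    "SpliceScenario",
    "Cohort",
    "generate_annotation",
    "simulate_cohort",
]


class ScenarioError(ValueError):
    """Infeasible or inconsistent scenario configuration."""


def _per_condition(value, conditions) -> dict[str, float]:
    if isinstance(value, dict):
        return {c: float(value[c]) for c in conditions}
    return {c: float(value) for c in conditions}


@dataclass(frozen=True)
class AltJunctionSpec:
    """A planted alternative donor/acceptor on one intron.

    ``offset`` nt of the intron stay in the mature transcript on the
    shifted side(s); ``usage`` is the fraction of spliced fragments using
    the alternative junction, per condition.
    """

    side: str  # "donor" | "acceptor" | "both"
    offset: int = 3
    usage: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.side not in ("donor", "acceptor", "both"):
            raise ScenarioError(f"unknown alt-junction side {self.side!r}")
        if self.offset < 1:
            raise ScenarioError("alt-junction offset must be >= 1")


@dataclass(frozen=True)
class ReporterLocusSpec:
    """The dual-intron reporter: three transcript classes per condition.

    ``proportions[cond]`` = (unspliced, canonical, non_canonical), summing
    to 1.  The defaults are the variant shares observed for the GFP
    reporter: roughly balanced in wild type, with the translatable
    non-canonical variant collapsing and the canonical variant rising in
    the splicing-factor mutant.
    """

    proportions: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "wt": (0.55, 0.22, 0.23),
            "mut": (0.51 / 1.01, 0.47 / 1.01, 0.03 / 1.01),
        }
    )
    acceptor_offset: int = 3
    donor_offset: int = 70
    fragments_per_replicate: int = 2000
    gene_id: str = "GFP"
    chrom: str = "chrR"

    def __post_init__(self) -> None:
        if self.acceptor_offset < 1:
            raise ScenarioError("acceptor_offset must be >= 1")
        for cond, props in self.proportions.items():
            if len(props) != 3 or abs(sum(props) - 1.0) > 1e-9:
                raise ScenarioError(
                    f"reporter proportions for {cond!r} must be 3 values "
                    f"summing to 1, got {props}"
                )
            if any(p < 0 for p in props):
                raise ScenarioError("reporter proportions must be >= 0")


@dataclass
class SpliceScenario:
    """Full generative parameterization of the synthetic cohort.

    Defaults describe the emulated study design: two conditions (wild type
    vs splicing-factor mutant) in biological triplicate, 100 nt single-end
    reads, a low baseline intron-retention level, and log-normal
    between-replicate expression noise.
    """

    n_genes: int = 60
    exons_per_gene: tuple[int, int] = (2, 4)
    exon_len: tuple[int, int] = (200, 400)
    intron_len: tuple[int, int] = (200, 300)
    expression: float = 425.0  # mean fragments per gene per replicate (~50x exons)
    expression_log2_sd: float = 0.1
    retention_frac: dict[str, float] | float = 0.2
    skip_frac: dict[str, float] | float = 0.0
    replicates: int = 3
    conditions: tuple[str, str] = ("wt", "mut")
    read_len: int = 100
    seed: int = 0
    annotation_seed: int | None = None  # pin to keep annotation fixed across seeds
    # planted differential structure -------------------------------------
    n_ir: int = 0  # introns with retention x ir_fold in the mutant
    n_mes: int = 0  # introns with retention x ir_fold in the wild type
    ir_fold: float = 5.0
    n_es: int = 0  # internal exons with differential skipping
    es_usage: dict[str, float] = field(
        default_factory=lambda: {"wt": 0.05, "mut": 0.5}
    )
    n_alt_acceptor: int = 0
    n_alt_donor: int = 0
    alt_offset: int = 3
    alt_usage: dict[str, float] = field(
        default_factory=lambda: {"wt": 0.1, "mut": 0.6}
    )
    n_deg_up: int = 0
    n_deg_down: int = 0
    deg_fold: float = 4.0
    reporter: ReporterLocusSpec | None = None

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ScenarioError("replicates must be >= 2 (t-tests need variance)")
        if len(self.conditions) != 2:
            raise ScenarioError("exactly two conditions are required")
        for frac in (self.retention_frac, self.skip_frac):
            vals = frac.values() if isinstance(frac, dict) else [frac]
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise ScenarioError("fractions must be in [0, 1]")
        if self.exon_len[0] < 8:
            raise ScenarioError("exons shorter than 8 nt cannot carry a block")
        if 2 * self.exon_len[0] < self.read_len:
            raise ScenarioError(
                "read_len exceeds the shortest possible spliced transcript "
                f"(2 x {self.exon_len[0]} nt)"
            )
        if self.alt_offset >= self.intron_len[0]:
            raise ScenarioError("alt_offset must be smaller than the shortest intron")

    @property
    def samples(self) -> list[str]:
        return [
            f"{cond}_{rep + 1}"
            for cond in self.conditions
            for rep in range(self.replicates)
        ]

    @property
    def groups(self) -> dict[str, str]:
        return {s: s.rsplit("_", 1)[0] for s in self.samples}


@dataclass
class Cohort:
    """All outputs of one simulation: file paths plus in-memory truth."""

    scenario: SpliceScenario
    outdir: Path
    annotation: AnnotationSet
    chrom_lengths: dict[str, int]
    gff3_path: Path
    sam_paths: dict[str, Path]  # sample -> path
    groups: dict[str, str]
    intron_truth: pd.DataFrame
    exon_truth: pd.DataFrame
    alt_truth: pd.DataFrame
    deg_truth: pd.DataFrame
    junction_logs: dict[str, dict[tuple[str, int, int], int]]
    fragment_counts: pd.DataFrame  # genes x samples
    reporter_truth: pd.DataFrame | None
    reporter_coords: dict  # canonical/noncanonical intron coords, if any


# --------------------------------------------------------------------------
# annotation


def _reporter_gene(spec: ReporterLocusSpec) -> tuple[GeneModel, int, dict]:
    """Build the reporter gene model and its coordinate bookkeeping."""
    base = 1000
    exon_u = (base, base + 399)
    canon = (exon_u[1] + 1, exon_u[1] + 300)  # canonical intron
    exon_d = (canon[1] + 1, canon[1] + 400)
    noncanon = (canon[0] - spec.donor_offset, canon[1] + spec.acceptor_offset)
    if noncanon[0] <= exon_u[0] + 8:
        raise ScenarioError("reporter donor_offset larger than upstream exon")
    if noncanon[1] >= exon_d[1] - 8:
        raise ScenarioError("reporter acceptor_offset larger than downstream exon")
    c = spec.chrom
    gene = GeneModel(
        spec.gene_id,
        c,
        "+",
        transcripts=[
            [
                GenomicInterval(c, exon_u[0], exon_u[1]),
                GenomicInterval(c, exon_d[0], exon_d[1]),
            ],
            [
                GenomicInterval(c, exon_u[0], noncanon[0] - 1),
                GenomicInterval(c, noncanon[1] + 1, exon_d[1]),
            ],
        ],
        transcript_ids=[f"{spec.gene_id}.canonical", f"{spec.gene_id}.noncanonical"],
    )
    coords = {
        "span": (exon_u[0], exon_d[1]),
        "canonical": canon,
        "noncanonical": noncanon,
        "donor_boundary": canon[0] - 1,
    }
    return gene, exon_d[1] + 1000, coords


def generate_annotation(
    scenario: SpliceScenario,
) -> tuple[AnnotationSet, dict[str, int], dict]:
    """Deterministically generate gene models (and the reporter locus).

    Returns (annotation, chromosome lengths, reporter coordinates or {}).
    Driven solely by ``annotation_seed`` (default: ``seed``), so read seeds
    can vary while the annotation stays fixed.
    """
    seed = scenario.annotation_seed if scenario.annotation_seed is not None else scenario.seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    genes: list[GeneModel] = []
    cursor = 1001
    chrom = "chr1"
    for g in range(scenario.n_genes):
        n_ex = int(rng.integers(scenario.exons_per_gene[0], scenario.exons_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = cursor
        for k in range(n_ex):
            elen = int(rng.integers(scenario.exon_len[0], scenario.exon_len[1] + 1))
            exons.append(GenomicInterval(chrom, pos, pos + elen - 1, strand))
            pos += elen
            if k < n_ex - 1:
                ilen = int(rng.integers(scenario.intron_len[0], scenario.intron_len[1] + 1))
                pos += ilen
        genes.append(GeneModel(f"G{g + 1:04d}", chrom, strand, [exons]))
        cursor = pos + 300  # intergenic gap
    chrom_lengths = {chrom: cursor + 1000}
    reporter_coords: dict = {}
    if scenario.reporter is not None:
        rgene, rlen, reporter_coords = _reporter_gene(scenario.reporter)
        genes.append(rgene)
        chrom_lengths[scenario.reporter.chrom] = rlen
    return AnnotationSet(genes), chrom_lengths, reporter_coords


# --------------------------------------------------------------------------
# ground-truth parameter assignment


def _assign_truth(
    scenario: SpliceScenario, annotation: AnnotationSet
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Plant differential structure on randomly chosen disjoint features."""
    conds = scenario.conditions
    wt, mut = conds
    rng = np.random.default_rng(np.random.SeedSequence([int(scenario.seed), 22]))
    base_ret = _per_condition(scenario.retention_frac, conds)
    base_skip = _per_condition(scenario.skip_frac, conds)
    reporter_id = scenario.reporter.gene_id if scenario.reporter else None

    genes = [g for g in annotation if g.gene_id != reporter_id]
    all_introns = [
        (g.gene_id, idx) for g in genes for idx in range(len(g.introns))
    ]
    n_plant = scenario.n_ir + scenario.n_mes + scenario.n_alt_acceptor + scenario.n_alt_donor
    if n_plant > len(all_introns):
        raise ScenarioError(
            f"cannot plant {n_plant} intron events in {len(all_introns)} introns"
        )
    order = rng.permutation(len(all_introns))
    picked = [all_introns[i] for i in order]
    ir_set = set(picked[: scenario.n_ir])
    mes_set = set(picked[scenario.n_ir : scenario.n_ir + scenario.n_mes])
    off = scenario.n_ir + scenario.n_mes
    alt_acc = picked[off : off + scenario.n_alt_acceptor]
    alt_don = picked[off + scenario.n_alt_acceptor : off + scenario.n_alt_acceptor + scenario.n_alt_donor]

    intron_rows = []
    alt_rows = []
    alt_map: dict[tuple[str, int], AltJunctionSpec] = {}
    for gene in genes:
        for idx, intron in enumerate(gene.introns):
            key = (gene.gene_id, idx)
            ret = dict(base_ret)
            planted = "none"
            if key in ir_set:
                ret[mut] = min(1.0, ret[mut] * scenario.ir_fold)
                planted = "IR"
            elif key in mes_set:
                ret[wt] = min(1.0, ret[wt] * scenario.ir_fold)
                planted = "MES"
            intron_rows.append(
                {
                    "gene_id": gene.gene_id,
                    "intron_index": idx,
                    "start": intron.interval.start,
                    "end": intron.interval.end,
                    f"retention_{wt}": ret[wt],
                    f"retention_{mut}": ret[mut],
                    "planted": planted,
                }
            )
    for key_list, side in ((alt_acc, "acceptor"), (alt_don, "donor")):
        for gid, idx in key_list:
            gene = annotation[gid]
            intron = gene.introns[idx].interval
            # genomic side carrying the offset: label is strand-aware
            genomic_side = side
            if gene.strand == "-":
                genomic_side = "acceptor" if side == "donor" else "donor"
            spec = AltJunctionSpec(
                side=genomic_side,
                offset=scenario.alt_offset,
                usage=dict(_per_condition(scenario.alt_usage, conds)),
            )
            alt_map[(gid, idx)] = spec
            donor = intron.start - 1
            acceptor = intron.end + 1
            if genomic_side in ("donor", "both"):
                donor = intron.start - 1 + spec.offset
            if genomic_side in ("acceptor", "both"):
                acceptor = intron.end + 1 - spec.offset
            alt_rows.append(
                {
                    "gene_id": gid,
                    "intron_index": idx,
                    "intron_start": intron.start,
                    "intron_end": intron.end,
                    "event_side": side,  # strand-aware label (5'/3' ss)
                    "genomic_side": genomic_side,
                    "offset": spec.offset,
                    "alt_donor": donor,
                    "alt_acceptor": acceptor,
                    f"usage_{wt}": spec.usage[wt],
                    f"usage_{mut}": spec.usage[mut],
                }
            )

    # exon skipping: internal exons from genes without planted introns
    used_genes = {gid for gid, _ in ir_set | mes_set | set(alt_acc) | set(alt_don)}
    candidates = [
        (g.gene_id, t_idx, exon)
        for g in genes
        if g.gene_id not in used_genes
        for t_idx, exon in g.internal_exons()
    ]
    if scenario.n_es > len(candidates):
        raise ScenarioError(
            f"cannot plant {scenario.n_es} skipping events in "
            f"{len(candidates)} internal exons of unused genes"
        )
    es_order = rng.permutation(len(candidates))
    es_picked = [candidates[i] for i in es_order[: scenario.n_es]]
    es_keys = {(gid, exon.start, exon.end) for gid, _, exon in es_picked}
    exon_rows = []
    for gene in genes:
        for t_idx, exon in gene.internal_exons():
            key = (gene.gene_id, exon.start, exon.end)
            planted = key in es_keys
            skip = {
                c: (scenario.es_usage[c] if planted else base_skip[c])
                for c in conds
            }
            exon_rows.append(
                {
                    "gene_id": gene.gene_id,
                    "exon_start": exon.start,
                    "exon_end": exon.end,
                    f"skip_{wt}": skip[wt],
                    f"skip_{mut}": skip[mut],
                    "planted": planted,
                }
            )

    # DEG planting on genes untouched by splicing events
    free_genes = [
        g.gene_id
        for g in genes
        if g.gene_id not in used_genes
        and g.gene_id not in {gid for gid, _, _ in es_picked}
    ]
    if scenario.n_deg_up + scenario.n_deg_down > len(free_genes):
        raise ScenarioError("not enough unused genes to plant DEGs")
    deg_order = rng.permutation(len(free_genes))
    up_set = {free_genes[i] for i in deg_order[: scenario.n_deg_up]}
    down_set = {
        free_genes[i]
        for i in deg_order[scenario.n_deg_up : scenario.n_deg_up + scenario.n_deg_down]
    }
    deg_rows = []
    for gene in genes:
        mult = 1.0
        planted = "none"
        if gene.gene_id in up_set:
            mult, planted = scenario.deg_fold, "up"
        elif gene.gene_id in down_set:
            mult, planted = 1.0 / scenario.deg_fold, "down"
        deg_rows.append(
            {
                "gene_id": gene.gene_id,
                f"multiplier_{wt}": 1.0,
                f"multiplier_{mut}": mult,
                "planted": planted,
            }
        )
    intron_cols = ["gene_id", "intron_index", "start", "end",
                   f"retention_{wt}", f"retention_{mut}", "planted"]
    exon_cols = ["gene_id", "exon_start", "exon_end",
                 f"skip_{wt}", f"skip_{mut}", "planted"]
    alt_cols = ["gene_id", "intron_index", "intron_start", "intron_end",
                "event_side", "genomic_side", "offset", "alt_donor",
                "alt_acceptor", f"usage_{wt}", f"usage_{mut}"]
    deg_cols = ["gene_id", f"multiplier_{wt}", f"multiplier_{mut}", "planted"]
    return (
        pd.DataFrame(intron_rows, columns=intron_cols),
        pd.DataFrame(exon_rows, columns=exon_cols),
        pd.DataFrame(alt_rows, columns=alt_cols),
        pd.DataFrame(deg_rows, columns=deg_cols),
        alt_map,
    )


# --------------------------------------------------------------------------
# read simulation


def _random_genome(chrom_lengths: dict[str, int], seed: int) -> dict[str, str]:
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 33]))
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return {
        chrom: alphabet[rng.integers(0, 4, size=length)].tobytes().decode()
        for chrom, length in chrom_lengths.items()
    }


def _realized_blocks(
    gene: GeneModel,
    skip_bits: tuple[int, ...],
    ret_bits: tuple[int, ...],
    alt_bits: tuple[int, ...],
    alt_map: dict[tuple[str, int], AltJunctionSpec],
) -> list[tuple[int, int]]:
    """Genomic blocks of one realized transcript molecule."""
    exons = gene.transcripts[0]
    k = len(exons)
    included = [0] + [
        j for j in range(1, k - 1) if not skip_bits[j - 1]
    ] + ([k - 1] if k > 1 else [])
    blocks: list[tuple[int, int]] = []

    def push(start: int, end: int) -> None:
        if blocks and blocks[-1][1] + 1 == start:
            blocks[-1] = (blocks[-1][0], end)
        else:
            blocks.append((start, end))

    prev = included[0]
    push(exons[prev].start, exons[prev].end)
    for cur in included[1:]:
        if cur == prev + 1:
            i = prev  # intron index between exon prev and cur
            if ret_bits[i]:
                push(exons[prev].end + 1, exons[cur].start - 1)  # merge intron
                push(exons[cur].start, exons[cur].end)
            elif alt_bits[i]:
                spec = alt_map[(gene.gene_id, _pooled_intron_index(gene, i))]
                left_end = exons[prev].end
                right_start = exons[cur].start
                if spec.side in ("donor", "both"):
                    left_end += spec.offset
                    blocks[-1] = (blocks[-1][0], left_end)
                if spec.side in ("acceptor", "both"):
                    right_start -= spec.offset
                push(right_start, exons[cur].end)
            else:
                push(exons[cur].start, exons[cur].end)
        else:
            push(exons[cur].start, exons[cur].end)  # skip junction
        prev = cur
    return blocks


def _pooled_intron_index(gene: GeneModel, chain_index: int) -> int:
    """Map an intron's position in transcript 0 to its pooled index."""
    exons = gene.transcripts[0]
    start = exons[chain_index].end + 1
    for idx, intron in enumerate(gene.introns):
        if intron.interval.start == start:
            return idx
    raise KeyError(f"no pooled intron starting at {start} in {gene.gene_id}")


def _emit_read(
    out,
    genome: dict[str, str],
    chrom: str,
    qname: str,
    blocks: list[tuple[int, int]],
    junction_log: dict[tuple[str, int, int], int],
) -> None:
    cigar_parts = []
    seq_parts = []
    aligned = 0
    for i, (s, e) in enumerate(blocks):
        if i:
            gap = s - blocks[i - 1][1] - 1
            cigar_parts.append(f"{gap}N")
            key = (chrom, blocks[i - 1][1], s)
            junction_log[key] = junction_log.get(key, 0) + 1
        cigar_parts.append(f"{e - s + 1}M")
        seq_parts.append(genome[chrom][s - 1 : e])
        aligned += e - s + 1
    out.write(
        f"{qname}\t0\t{chrom}\t{blocks[0][0]}\t255\t{''.join(cigar_parts)}"
        f"\t*\t0\t0\t{''.join(seq_parts)}\t*\tNM:i:0\tMD:Z:{aligned}\n"
    )


def _read_blocks_from_transcript(
    tblocks: list[tuple[int, int]],
    cum: np.ndarray,
    s0: int,
    read_len: int,
) -> list[tuple[int, int]]:
    """Genomic blocks covered by read [s0, s0+read_len-1] in transcript
    coordinates (0-based)."""
    e0 = s0 + read_len - 1
    first = int(np.searchsorted(cum, s0, side="right"))
    out = []
    pos = s0
    for i in range(first, len(tblocks)):
        blk_start_t = int(cum[i - 1]) if i else 0
        g_start, g_end = tblocks[i]
        off = pos - blk_start_t
        take = min(e0, int(cum[i]) - 1) - pos + 1
        out.append((g_start + off, g_start + off + take - 1))
        pos += take
        if pos > e0:
            break
    return out


def simulate_alignments(
    scenario: SpliceScenario,
    annotation: AnnotationSet,
    chrom_lengths: dict[str, int],
    genome: dict[str, str],
    truth_tables,
    alt_map: dict[tuple[str, int], AltJunctionSpec],
    reporter_coords: dict,
    condition: str,
    replicate: int,
    path: Path,
) -> tuple[dict[tuple[str, int, int], int], dict[str, int]]:
    """Write one replicate's SAM file; return (junction log, fragment counts)."""
    intron_truth, exon_truth, deg_truth = truth_tables
    conds = scenario.conditions
    cond_idx = conds.index(condition)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(scenario.seed), 44, cond_idx, replicate])
    )
    L = scenario.read_len
    junction_log: dict[tuple[str, int, int], int] = {}
    frag_counts: dict[str, int] = {}
    reporter_id = scenario.reporter.gene_id if scenario.reporter else None

    ret_by_gene: dict[str, np.ndarray] = {}
    for gid, grp in intron_truth.groupby("gene_id", sort=False):
        ret_by_gene[gid] = grp.sort_values("intron_index")[
            f"retention_{condition}"
        ].to_numpy()
    skip_by_gene: dict[str, dict[tuple[int, int], float]] = {}
    for row in exon_truth.itertuples():
        skip_by_gene.setdefault(row.gene_id, {})[
            (row.exon_start, row.exon_end)
        ] = getattr(row, f"skip_{condition}")
    mult_by_gene = dict(
        zip(deg_truth["gene_id"], deg_truth[f"multiplier_{condition}"])
    )

    with open(path, "w") as out:
        out.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, length in chrom_lengths.items():
            out.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        out.write(f"@RG\tID:{condition}_{replicate + 1}\tSM:{condition}\n")

        for gene in annotation:
            if gene.gene_id == reporter_id:
                continue
            exons = gene.transcripts[0]
            k = len(exons)
            noise = 2.0 ** rng.normal(0.0, scenario.expression_log2_sd)
            lam = scenario.expression * mult_by_gene[gene.gene_id] * noise
            n = int(rng.poisson(lam))
            frag_counts[gene.gene_id] = n
            if n == 0:
                continue
            p_skip = np.array(
                [
                    skip_by_gene.get(gene.gene_id, {}).get(
                        (exons[j].start, exons[j].end), 0.0
                    )
                    for j in range(1, k - 1)
                ]
            )
            p_ret = ret_by_gene.get(gene.gene_id, np.zeros(0))
            p_alt = np.zeros(k - 1)
            for i in range(k - 1):
                spec = alt_map.get((gene.gene_id, _pooled_intron_index(gene, i)))
                if spec is not None:
                    p_alt[i] = spec.usage[condition]
            skips = rng.random((n, max(k - 2, 0))) < p_skip
            rets = rng.random((n, k - 1)) < p_ret
            alts = rng.random((n, k - 1)) < p_alt
            # a skipped exon silences retention/alt on its flanking introns;
            # alt applies only to spliced introns
            adj = np.zeros((n, k - 1), dtype=bool)
            if k > 2:
                adj[:, :-1] |= skips
                adj[:, 1:] |= skips
            rets &= ~adj
            alts &= ~adj & ~rets
            # group fragments by realized structure
            sig = np.zeros(n, dtype=np.int64)
            bit = 0
            for arr in (skips, rets, alts):
                for col in range(arr.shape[1]):
                    sig |= arr[:, col].astype(np.int64) << bit
                    bit += 1
            uniq, inverse = np.unique(sig, return_inverse=True)
            frag_idx = 0
            for u_i, u in enumerate(uniq):
                members = np.flatnonzero(inverse == u_i)
                bits = [(u >> b) & 1 for b in range(bit)]
                nb_skip = max(k - 2, 0)
                skip_bits = tuple(bits[:nb_skip])
                ret_bits = tuple(bits[nb_skip : nb_skip + k - 1])
                alt_bits = tuple(bits[nb_skip + k - 1 : nb_skip + 2 * (k - 1)])
                tblocks = _realized_blocks(
                    gene, skip_bits, ret_bits, alt_bits, alt_map
                )
                lens = np.array([e - s + 1 for s, e in tblocks])
                cum = np.cumsum(lens)
                T = int(cum[-1])
                if T < L:
                    raise ScenarioError(
                        f"read length {L} exceeds realized transcript "
                        f"({T} nt) of {gene.gene_id}"
                    )
                starts = rng.integers(0, T - L + 1, size=members.size)
                for s0 in starts:
                    rblocks = _read_blocks_from_transcript(tblocks, cum, int(s0), L)
                    qname = f"{gene.gene_id}:{condition}:{replicate + 1}:{frag_idx}"
                    frag_idx += 1
                    _emit_read(out, genome, gene.chrom, qname, rblocks, junction_log)

        if scenario.reporter is not None:
            spec = scenario.reporter
            props = spec.proportions[condition]
            n = spec.fragments_per_replicate
            frag_counts[spec.gene_id] = n
            counts = rng.multinomial(n, props)
            canon = reporter_coords["canonical"]
            noncanon = reporter_coords["noncanonical"]
            donor_b = reporter_coords["donor_boundary"]
            chrom = spec.chrom
            idx = 0
            # diagnostic, junction-anchored reads: every fragment yields one
            # classifiable read, so class counts are multinomial in the
            # class proportions
            for cls, m in zip(("unspliced", "canonical", "non_canonical"), counts):
                if m == 0:
                    continue
                overhangs = rng.integers(8, L - 8 + 1, size=m)
                for o in overhangs:
                    o = int(o)
                    if cls == "unspliced":
                        blocks = [(donor_b - o + 1, donor_b - o + L)]
                    elif cls == "canonical":
                        blocks = [
                            (canon[0] - o, canon[0] - 1),
                            (canon[1] + 1, canon[1] + (L - o)),
                        ]
                    else:
                        blocks = [
                            (noncanon[0] - o, noncanon[0] - 1),
                            (noncanon[1] + 1, noncanon[1] + (L - o)),
                        ]
                    qname = f"{spec.gene_id}:{cls}:{condition}:{replicate + 1}:{idx}"
                    idx += 1
                    _emit_read(out, genome, chrom, qname, blocks, junction_log)
    return junction_log, frag_counts


# --------------------------------------------------------------------------
# cohort driver


def simulate_cohort(scenario: SpliceScenario, outdir) -> Cohort:
    """Generate annotation, truth tables and per-replicate SAM files.

    Fully deterministic given the scenario (including its seed): rerunning
    with identical parameters produces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation, chrom_lengths, reporter_coords = generate_annotation(scenario)
    gff3_path = outdir / "annotation.gff3"
    write_gff3(annotation, gff3_path)
    genome = _random_genome(chrom_lengths, scenario.seed if scenario.annotation_seed is None else scenario.annotation_seed)

    intron_truth, exon_truth, alt_truth, deg_truth, alt_map = _assign_truth(
        scenario, annotation
    )
    sam_paths: dict[str, Path] = {}
    junction_logs: dict[str, dict[tuple[str, int, int], int]] = {}
    frag_frames: dict[str, dict[str, int]] = {}
    for cond in scenario.conditions:
        for rep in range(scenario.replicates):
            sample = f"{cond}_{rep + 1}"
            path = outdir / f"{sample}.sam"
            jlog, fc = simulate_alignments(
                scenario,
                annotation,
                chrom_lengths,
                genome,
                (intron_truth, exon_truth, deg_truth),
                alt_map,
                reporter_coords,
                cond,
                rep,
                path,
            )
            sam_paths[sample] = path
            junction_logs[sample] = jlog
            frag_frames[sample] = fc
    fragment_counts = pd.DataFrame(frag_frames).fillna(0).astype(int).sort_index()
    fragment_counts.index.name = "gene_id"

    reporter_truth = None
    if scenario.reporter is not None:
        spec = scenario.reporter
        rows = []
        for cond in scenario.conditions:
            u, c, nc = spec.proportions[cond]
            rows.append(
                {"condition": cond, "unspliced": u, "canonical": c,
                 "non_canonical": nc}
            )
        reporter_truth = pd.DataFrame(rows)
        reporter_truth.to_csv(outdir / "reporter_truth.tsv", sep="\t", index=False)

    intron_truth.to_csv(outdir / "intron_truth.tsv", sep="\t", index=False)
    exon_truth.to_csv(outdir / "exon_truth.tsv", sep="\t", index=False)
    alt_truth.to_csv(outdir / "alt_truth.tsv", sep="\t", index=False)
    deg_truth.to_csv(outdir / "deg_truth.tsv", sep="\t", index=False)
    fragment_counts.to_csv(outdir / "fragment_counts.tsv", sep="\t")
    for sample, jlog in junction_logs.items():
        with open(outdir / f"junctions_{sample}.tsv", "w") as fh:
            fh.write("chrom\tdonor\tacceptor\tcount\n")
            for (chrom, d, a), cnt in sorted(jlog.items()):
                fh.write(f"{chrom}\t{d}\t{a}\t{cnt}\n")

    return Cohort(
        scenario=scenario,
        outdir=outdir,
        annotation=annotation,
        chrom_lengths=chrom_lengths,
        gff3_path=gff3_path,
        sam_paths=sam_paths,
        groups=scenario.groups,
        intron_truth=intron_truth,
        exon_truth=exon_truth,
        alt_truth=alt_truth,
        deg_truth=deg_truth,
        junction_logs=junction_logs,
        fragment_counts=fragment_counts,
        reporter_truth=reporter_truth,
        reporter_coords=reporter_coords,
    )
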