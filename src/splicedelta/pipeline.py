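"""End-to-end orchestration: ingest -> evidence layers -> statistics -> TSVs.

The pipeline consumes a GFF3 annotation plus one SAM file per biological
replicate in each of two conditions, applies the alignment acceptance
filters, builds the three evidence layers (depth, junctions, gene counts),
and runs the differential-expression, intron-retention, junction-event and
reporter-variant analyses.  All outputs are TSV files carrying a header
with the package version, a configuration hash and the seed, and are
byte-identical across reruns of the same configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam
import yaml

from . import __version__
from .alignments import (
    apply_filters,
    compute_depth,
    count_gene_reads,
    extract_junctions,
    read_sam,
    _GeneIndex,
)
from .annotation import AnnotationSet, GenomicInterval, read_gff3
from .events import (
    ExclusionList,
    classify_as_events,
    classify_introns,
    enumerate_as_events,
    intron_retention_table,
    summarize_events,
)
from .expression import CountMatrix, call_degs, logcpm, rpkm_from_logcpm, tmm_factors
from .reporter import quantify_variants_by_sample

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class Thresholds:
    """Every tunable cutoff, defaulted to the analysis contract's values."""

    p_value: float = 0.01
    fold: float = 2.0
    identity: float = 0.95
    end_match: int = 4
    min_block: int = 8
    pseudocount: float = 1.0
    logcpm_prior: float = 0.5
    reporter_min_overhang: int = 8
    ir_use_log: bool = True  # t-test IR ratios on log2 scale (False: raw)
    deg_log: bool = False  # t-test RPKM on log2 scale

    def __post_init__(self) -> None:
        for name in ("p_value", "fold", "identity", "pseudocount", "logcpm_prior"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"threshold {name} must be positive")
        if self.end_match < 0 or self.min_block < 1:
            raise PipelineError("end_match must be >= 0 and min_block >= 1")


@dataclass
class ReporterConfig:
    gene_id: str
    chrom: str
    canonical: tuple[int, int]  # intron start, end (1-based inclusive)
    noncanonical: tuple[int, int]


@dataclass
class PipelineConfig:
    annotation: Path
    samples: dict[str, list[Path]]  # condition -> replicate SAM paths
    outdir: Path
    wildtype: str | None = None  # defaults: first / second condition key
    mutant: str | None = None
    exclusion: Path | None = None
    reporter: ReporterConfig | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0

    def __post_init__(self) -> None:
        self.annotation = Path(self.annotation)
        self.outdir = Path(self.outdir)
        self.samples = {
            cond: [Path(p) for p in paths] for cond, paths in self.samples.items()
        }
        conds = list(self.samples)
        if len(conds) != 2:
            raise PipelineError(f"need exactly 2 conditions, got {conds}")
        # conventional names win over dict order (YAML mappings may be sorted)
        if self.wildtype is None:
            self.wildtype = "wt" if set(conds) == {"wt", "mut"} else conds[0]
        if self.mutant is None:
            self.mutant = next(c for c in conds if c != self.wildtype)
        for cond, paths in self.samples.items():
            if not paths:
                raise PipelineError(f"condition {cond!r} has no replicates")
        sizes = {len(p) for p in self.samples.values()}
        if len(sizes) > 1:
            log.warning("unbalanced replicate counts across conditions: %s",
                        {c: len(p) for c, p in self.samples.items()})

    def validate_paths(self) -> None:
        """Fail before any compute if an input is missing."""
        missing = [str(self.annotation)] if not self.annotation.exists() else []
        for paths in self.samples.values():
            missing += [str(p) for p in paths if not p.exists()]
        if self.exclusion is not None and not Path(self.exclusion).exists():
            missing.append(str(self.exclusion))
        if missing:
            raise PipelineError(f"missing input file(s): {missing}")

    @property
    def sample_names(self) -> list[str]:
        return [
            f"{cond}_{i + 1}"
            for cond, paths in self.samples.items()
            for i in range(len(paths))
        ]

    @property
    def groups(self) -> dict[str, str]:
        return {s: s.rsplit("_", 1)[0] for s in self.sample_names}

    def config_hash(self) -> str:
        payload = {
            "annotation": str(self.annotation),
            "samples": {c: [str(p) for p in v] for c, v in self.samples.items()},
            "wildtype": self.wildtype,
            "mutant": self.mutant,
            "exclusion": str(self.exclusion) if self.exclusion else None,
            "reporter": (
                {
                    "gene_id": self.reporter.gene_id,
                    "chrom": self.reporter.chrom,
                    "canonical": list(self.reporter.canonical),
                    "noncanonical": list(self.reporter.noncanonical),
                }
                if self.reporter
                else None
            ),
            "thresholds": vars(self.thresholds),
            "seed": self.seed,
        }
        return hashlib.sha1(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thresholds = Thresholds(**raw.get("thresholds", {}))
        reporter = None
        if raw.get("reporter"):
            r = raw["reporter"]
            reporter = ReporterConfig(
                gene_id=r["gene_id"],
                chrom=r["chrom"],
                canonical=tuple(r["canonical"]),
                noncanonical=tuple(r["noncanonical"]),
            )
        return cls(
            annotation=raw["annotation"],
            samples=raw["samples"],
            outdir=raw.get("outdir", "splicedelta_out"),
            wildtype=raw.get("wildtype"),
            mutant=raw.get("mutant"),
            exclusion=raw.get("exclusion"),
            reporter=reporter,
            thresholds=thresholds,
            seed=int(raw.get("seed", 0)),
        )


@dataclass
class PipelineResult:
    config: PipelineConfig
    annotation: AnnotationSet
    gene_counts: pd.DataFrame  # genes x samples (unique); totals alongside
    gene_totals: pd.DataFrame
    tmm: pd.Series
    rpkm: pd.DataFrame
    deg: pd.DataFrame
    ir: pd.DataFrame
    as_events: pd.DataFrame
    reporter: pd.DataFrame | None
    summary: pd.DataFrame
    filter_stats: pd.DataFrame
    output_files: list[Path]


def _chrom_lengths_from_sam(path: Path) -> dict[str, int]:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        return dict(zip(sam.references, sam.lengths))


def _write_table(
    df: pd.DataFrame, path: Path, config: PipelineConfig, index: bool = False
) -> Path:
    with open(path, "w") as fh:
        fh.write(f"# splicedelta {__version__}\n")
        fh.write(f"# config_hash={config.config_hash()} seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=index)
    return path


def run_pipeline(
    config: PipelineConfig,
    stages: tuple[str, ...] = ("deg", "splice", "gfp"),
) -> PipelineResult:
    """Execute the pipeline and write the report bundle to ``config.outdir``."""
    config.validate_paths()
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds

    try:
        annotation = read_gff3(config.annotation)
    except Exception as exc:
        raise PipelineError(f"stage=annotation: {exc}") from exc
    if annotation.rejected:
        log.warning("rejected %d gene(s): %s", len(annotation.rejected),
                    annotation.rejected[:5])

    exclusion = (
        ExclusionList.from_tsv(config.exclusion) if config.exclusion else None
    )

    first_sam = next(iter(config.samples.values()))[0]
    chrom_lengths = _chrom_lengths_from_sam(first_sam)
    gene_index = _GeneIndex(annotation)

    depths = {}
    junctions = {}
    uniq_counts = {}
    total_counts = {}
    reporter_records: dict[str, list] = {}
    stats_rows = []
    sample_paths = [
        (f"{cond}_{i + 1}", p)
        for cond, paths in config.samples.items()
        for i, p in enumerate(paths)
    ]
    for sample, path in sample_paths:
        try:
            read_stats: dict = {}
            filt_stats: dict = {}
            records = apply_filters(
                read_sam(path, stats=read_stats),
                min_identity=thr.identity,
                min_end_match=thr.end_match,
                min_block=thr.min_block,
                stats=filt_stats,
            )
            depths[sample] = compute_depth(records, chrom_lengths)
            junctions[sample] = extract_junctions(records)
            gc = count_gene_reads(records, annotation, index=gene_index)
            uniq_counts[sample] = gc["unique"]
            total_counts[sample] = gc["total"]
            if config.reporter is not None:
                reporter_records[sample] = [
                    r for r in records if r.chrom == config.reporter.chrom
                ]
            stats_rows.append({"sample": sample, **read_stats, **filt_stats})
        except Exception as exc:
            raise PipelineError(f"stage=ingest sample={sample}: {exc}") from exc

    filter_stats = pd.DataFrame(stats_rows)
    gene_counts = pd.DataFrame(uniq_counts)
    gene_totals = pd.DataFrame(total_counts)
    groups = config.groups
    outputs: list[Path] = []

    # differential expression ------------------------------------------------
    tmm = rpkm_mat = deg = None
    if "deg" in stages:
        try:
            lengths = pd.Series(
                {g.gene_id: g.exonic_length for g in annotation}, name="length"
            )
            cm = CountMatrix(gene_counts, lengths)
            tmm = tmm_factors(cm.counts, cm.lib_sizes)
            lc = logcpm(cm.counts, tmm, cm.lib_sizes, prior=thr.logcpm_prior)
            rpkm_mat = rpkm_from_logcpm(lc, cm.gene_lengths)
            deg = call_degs(
                rpkm_mat,
                groups,
                wildtype=config.wildtype,
                mutant=config.mutant,
                p_threshold=thr.p_value,
                fold_threshold=thr.fold,
                log_transform=thr.deg_log,
            )
        except Exception as exc:
            raise PipelineError(f"stage=deg: {exc}") from exc

    # splicing ---------------------------------------------------------------
    ir = as_events = None
    if "splice" in stages:
        try:
            ir_ratios = intron_retention_table(depths, annotation)
            ir = classify_introns(
                ir_ratios,
                groups,
                wildtype=config.wildtype,
                mutant=config.mutant,
                p_threshold=thr.p_value,
                fold_threshold=thr.fold,
                use_log=thr.ir_use_log,
                exclusion=exclusion,
            )
            candidates = enumerate_as_events(junctions, annotation, exclusion)
            as_events = classify_as_events(
                candidates,
                gene_counts,
                groups,
                wildtype=config.wildtype,
                mutant=config.mutant,
                p_threshold=thr.p_value,
                fold_threshold=thr.fold,
                pseudocount=thr.pseudocount,
            )
        except Exception as exc:
            raise PipelineError(f"stage=splice: {exc}") from exc

    # reporter ---------------------------------------------------------------
    reporter_table = None
    if "gfp" in stages and config.reporter is not None:
        try:
            rc = config.reporter
            reporter_table = quantify_variants_by_sample(
                reporter_records,
                GenomicInterval(rc.chrom, *rc.canonical),
                GenomicInterval(rc.chrom, *rc.noncanonical),
                groups=groups,
                min_overhang=thr.reporter_min_overhang,
            )
        except Exception as exc:
            raise PipelineError(f"stage=gfp: {exc}") from exc

    summary = summarize_events(annotation, deg, ir, as_events)

    # report bundle ----------------------------------------------------------
    counts_out = gene_counts.copy()
    counts_out.columns = [f"unique_{c}" for c in counts_out.columns]
    for c in gene_totals.columns:
        counts_out[f"total_{c}"] = gene_totals[c]
    outputs.append(
        _write_table(counts_out.rename_axis("gene_id"),
                     outdir / "gene_counts.tsv", config, index=True)
    )
    outputs.append(
        _write_table(filter_stats, outdir / "filter_stats.tsv", config)
    )
    if deg is not None:
        outputs.append(_write_table(deg, outdir / "deg.tsv", config, index=True))
    if ir is not None:
        outputs.append(_write_table(ir, outdir / "intron_retention.tsv", config))
    if as_events is not None:
        outputs.append(_write_table(as_events, outdir / "as_events.tsv", config))
    if reporter_table is not None:
        outputs.append(
            _write_table(reporter_table, outdir / "reporter_variants.tsv", config)
        )
    outputs.append(_write_table(summary, outdir / "summary.tsv", config))
    manifest = outdir / "run_manifest.txt"
    with open(manifest, "w") as fh:
        fh.write(f"splicedelta {__version__}\n")
        fh.write(f"config_hash={config.config_hash()}\nseed={config.seed}\n")
        fh.write(f"stages={','.join(stages)}\n")
        for p in outputs:
            fh.write(f"output={p.name}\n")
    outputs.append(manifest)

    return PipelineResult(
        config=config,
        annotation=annotation,
        gene_counts=gene_counts,
        gene_totals=gene_totals,
        tmm=tmm,
        rpkm=rpkm_mat,
        deg=deg,
        ir=ir,
        as_events=as_events,
        reporter=reporter_table,
        summary=summary,
        filter_stats=filter_stats,
        output_files=outputs,
    )


def config_from_cohort(cohort, outdir, **threshold_overrides) -> PipelineConfig:
    """Build a PipelineConfig pointing at a simulated cohort's files."""
    scenario = cohort.scenario
    samples = {
        cond: [cohort.sam_paths[f"{cond}_{i + 1}"] for i in range(scenario.replicates)]
        for cond in scenario.conditions
    }
    reporter = None
    if cohort.reporter_coords:
        rc = cohort.reporter_coords
        reporter = ReporterConfig(
            gene_id=scenario.reporter.gene_id,
            chrom=scenario.reporter.chrom,
            canonical=rc["canonical"],
            noncanonical=rc["noncanonical"],
        )
    return PipelineConfig(
        annotation=cohort.gff3_path,
        samples=samples,
        outdir=Path(outdir),
        wildtype=scenario.conditions[0],
        mutant=scenario.conditions[1],
        reporter=reporter,
        thresholds=Thresholds(**threshold_overrides),
        seed=scenario.seed,
    )
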