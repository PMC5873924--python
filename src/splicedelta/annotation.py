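"""Gene models: GFF3 parsing, intron derivation, and neighborhood queries.

All coordinates are 1-based and inclusive at the API surface (the GFF3/SAM
convention).  A gene model is a set of transcripts, each an ordered chain of
non-overlapping exons; introns are exactly the gaps between consecutive exons
of one transcript.  Because intron-level statistics are computed per intron
(not per isoform), introns from all transcripts of a gene are pooled and
deduplicated by coordinates; each retains a pointer to the transcript that
contributed it so that "neighboring exons" are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "GenomicInterval",
    "Intron",
    "GeneModel",
    "AnnotationSet",
    "Gff3ParseError",
    "Gff3StructureError",
    "read_gff3",
    "write_gff3",
    "neighboring_exons",
]


class Gff3ParseError(ValueError):
    """A GFF3 line could not be parsed; the message names the line number."""


class Gff3StructureError(ValueError):
    """Features are individually well-formed but structurally inconsistent."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed genomic interval [start, end] on one strand of a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass(frozen=True)
class Intron:
    """One pooled intron of a gene, with its contributing transcript."""

    interval: GenomicInterval
    transcript_index: int  # transcript that contributed this intron
    position: int  # 0-based index along that transcript's intron chain


@dataclass
class GeneModel:
    """A gene with ordered exon chains per transcript and derived introns."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[list[GenomicInterval]]
    transcript_ids: list[str] = field(default_factory=list)
    introns: list[Intron] = field(init=False, default_factory=list)

    def __post_init__(self) -> None:
        if not self.transcript_ids:
            self.transcript_ids = [
                f"{self.gene_id}.{i + 1}" for i in range(len(self.transcripts))
            ]
        for t_idx, exons in enumerate(self.transcripts):
            if not exons:
                raise Gff3StructureError(
                    f"transcript {self.transcript_ids[t_idx]} of {self.gene_id} "
                    "has no exons"
                )
            for a, b in zip(exons, exons[1:]):
                if b.start <= a.end:
                    raise Gff3StructureError(
                        f"exons of {self.transcript_ids[t_idx]} are unsorted or "
                        f"overlapping at {a.end}/{b.start}"
                    )
        self.introns = self._derive_introns()

    def _derive_introns(self) -> list[Intron]:
        seen: dict[tuple[int, int], Intron] = {}
        for t_idx, exons in enumerate(self.transcripts):
            for pos, (a, b) in enumerate(zip(exons, exons[1:])):
                key = (a.end + 1, b.start - 1)
                if key not in seen:
                    seen[key] = Intron(
                        GenomicInterval(self.chrom, key[0], key[1], self.strand),
                        transcript_index=t_idx,
                        position=pos,
                    )
        return sorted(seen.values(), key=lambda i: (i.interval.start, i.interval.end))

    @property
    def span(self) -> GenomicInterval:
        start = min(e.start for t in self.transcripts for e in t)
        end = max(e.end for t in self.transcripts for e in t)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def exonic_length(self) -> int:
        """Number of bases in the union of all exons (the RPKM denominator)."""
        ivs = sorted(
            (e.start, e.end) for t in self.transcripts for e in t
        )
        total = 0
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        total += cur_e - cur_s + 1
        return total

    def internal_exons(self) -> list[tuple[int, GenomicInterval]]:
        """All (transcript_index, exon) pairs where the exon is internal,
        deduplicated by exon coordinates."""
        seen: dict[tuple[int, int], tuple[int, GenomicInterval]] = {}
        for t_idx, exons in enumerate(self.transcripts):
            for exon in exons[1:-1]:
                key = (exon.start, exon.end)
                if key not in seen:
                    seen[key] = (t_idx, exon)
        return sorted(seen.values(), key=lambda p: (p[1].start, p[1].end))


def neighboring_exons(
    gene: GeneModel, intron_index: int
) -> tuple[GenomicInterval, GenomicInterval]:
    """Exons immediately upstream and downstream (in genomic order) of the
    intron with pooled index ``intron_index``.

    The flanking exons are taken from the transcript that contributed the
    intron, so their boundaries abut the intron exactly (off by one base).
    """
    try:
        intron = gene.introns[intron_index]
    except IndexError:
        raise LookupError(
            f"gene {gene.gene_id} has {len(gene.introns)} introns; "
            f"index {intron_index} out of range"
        ) from None
    exons = gene.transcripts[intron.transcript_index]
    return exons[intron.position], exons[intron.position + 1]


class AnnotationSet:
    """A collection of validated GeneModels plus a rejection report.

    Genes whose features violate the model invariants are not silently
    dropped: they are listed in ``rejected`` as (gene_id, reason) pairs.
    """

    def __init__(
        self,
        genes: Iterable[GeneModel],
        rejected: list[tuple[str, str]] | None = None,
    ):
        self.genes: list[GeneModel] = sorted(
            genes, key=lambda g: (g.chrom, g.span.start, g.gene_id)
        )
        self.rejected: list[tuple[str, str]] = rejected or []
        self._by_id = {g.gene_id: g for g in self.genes}

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def total_introns(self) -> int:
        return sum(len(g.introns) for g in self.genes)

    @property
    def total_internal_exons(self) -> int:
        return sum(len(g.internal_exons()) for g in self.genes)


def _parse_attributes(raw: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in raw.rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise Gff3ParseError(
                f"line {lineno}: malformed attribute {part!r} (expected key=value)"
            )
        key, _, value = part.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(path) -> AnnotationSet:
    """Parse a GFF3 file into an :class:`AnnotationSet`.

    Recognized feature types are ``gene``, ``mRNA``/``transcript`` and
    ``exon``; everything else is ignored.  ``ID`` and ``Parent`` attributes
    define the hierarchy.  Malformed lines raise :class:`Gff3ParseError`
    naming the line number; an exon without a resolvable parent raises
    :class:`Gff3StructureError`.  Genes that fail model invariants (e.g.
    overlapping exons within a transcript) go to the rejection report.
    """
    genes_meta: dict[str, tuple[str, str]] = {}  # gene_id -> (chrom, strand)
    mrna_parent: dict[str, str] = {}  # mrna_id -> gene_id
    mrna_meta: dict[str, tuple[str, str]] = {}
    exons_by_mrna: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []  # gene ids in file order

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise Gff3ParseError(
                    f"line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, raw = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise Gff3ParseError(
                    f"line {lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from None
            if ftype == "gene":
                attrs = _parse_attributes(raw, lineno)
                gid = attrs.get("ID")
                if gid is None:
                    raise Gff3ParseError(f"line {lineno}: gene feature lacks ID")
                genes_meta[gid] = (chrom, strand)
                order.append(gid)
            elif ftype in ("mRNA", "transcript"):
                attrs = _parse_attributes(raw, lineno)
                mid = attrs.get("ID")
                parent = attrs.get("Parent")
                if mid is None or parent is None:
                    raise Gff3ParseError(
                        f"line {lineno}: {ftype} feature needs ID and Parent"
                    )
                mrna_parent[mid] = parent
                mrna_meta[mid] = (chrom, strand)
            elif ftype == "exon":
                attrs = _parse_attributes(raw, lineno)
                parent = attrs.get("Parent")
                if parent is None:
                    raise Gff3StructureError(
                        f"line {lineno}: exon feature has no Parent"
                    )
                if start > end:
                    raise Gff3ParseError(
                        f"line {lineno}: exon start {start} > end {end}"
                    )
                for pid in parent.split(","):
                    exons_by_mrna.setdefault(pid, []).append(
                        GenomicInterval(chrom, start, end, strand)
                    )

    # exons attached to unknown parents are a structural error, not silence
    known = set(mrna_parent)
    orphans = [mid for mid in exons_by_mrna if mid not in known]
    if orphans:
        raise Gff3StructureError(
            f"exons reference unknown mRNA parent(s): {sorted(orphans)[:5]}"
        )

    genes: list[GeneModel] = []
    rejected: list[tuple[str, str]] = []
    mrnas_by_gene: dict[str, list[str]] = {}
    for mid, gid in mrna_parent.items():
        mrnas_by_gene.setdefault(gid, []).append(mid)
        if gid not in genes_meta:
            # mRNA without an explicit gene line: promote it
            genes_meta[gid] = mrna_meta[mid]
            order.append(gid)

    for gid in order:
        chrom, strand = genes_meta[gid]
        mids = sorted(mrnas_by_gene.get(gid, []))
        if not mids:
            rejected.append((gid, "gene has no mRNA children"))
            continue
        transcripts = []
        for mid in mids:
            exons = sorted(
                exons_by_mrna.get(mid, []), key=lambda e: (e.start, e.end)
            )
            if not exons:
                rejected.append((gid, f"mRNA {mid} has no exons"))
                transcripts = []
                break
            transcripts.append(exons)
        if not transcripts:
            continue
        try:
            genes.append(
                GeneModel(gid, chrom, strand, transcripts, transcript_ids=mids)
            )
        except (Gff3StructureError, ValueError) as exc:
            rejected.append((gid, str(exc)))
    return AnnotationSet(genes, rejected)


def write_gff3(annotation: Iterable[GeneModel], path) -> None:
    """Serialize gene models as GFF3 (gene/mRNA/exon hierarchy)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in annotation:
            span = gene.span
            fh.write(
                f"{gene.chrom}\tsplicedelta\tgene\t{span.start}\t{span.end}\t."
                f"\t{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            for mid, exons in zip(gene.transcript_ids, gene.transcripts):
                fh.write(
                    f"{gene.chrom}\tsplicedelta\tmRNA\t{exons[0].start}\t"
                    f"{exons[-1].end}\t.\t{gene.strand}\t.\t"
                    f"ID={mid};Parent={gene.gene_id}\n"
                )
                for exon in exons:
                    fh.write(
                        f"{gene.chrom}\tsplicedelta\texon\t{exon.start}\t"
                        f"{exon.end}\t.\t{gene.strand}\t.\tParent={mid}\n"
                    )
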