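"""Alignment ingest: SAM reading, acceptance filters, and evidence layers.

Reads arrive pre-aligned (the pipeline never invokes an aligner).  Each
record is reduced to its ordered genomic blocks plus two pieces of quality
metadata used by the acceptance filters:

* ``identity`` — fraction of aligned bases matching the reference, derived
  from the NM tag when present, else from MD;
* ``end_match`` — lengths (nt) of the exact-match runs at the two ends of
  the alignment, derived from MD and capped by clipping/insertions.

Three evidence layers feed every downstream statistic: per-base depth
(:func:`compute_depth`), junction counts (:func:`extract_junctions`), and
per-gene total/unique read counts (:func:`count_gene_reads`).
"""

from __future__ import annotations

import bisect
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import pysam

from .annotation import AnnotationSet

__all__ = [
    "AlignmentBlockRecord",
    "DepthProfile",
    "read_sam",
    "filter_transcriptome_pass",
    "filter_short_blocks",
    "apply_filters",
    "compute_depth",
    "extract_junctions",
    "count_gene_reads",
]

log = logging.getLogger(__name__)

_REF_CONSUMING_IN_BLOCK = {0, 2, 7, 8}  # M, D, =, X
_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


@dataclass(slots=True)
class AlignmentBlockRecord:
    """One aligned read as ordered genomic blocks plus filter metadata.

    ``blocks`` are (start, end) pairs, 1-based inclusive, sorted and
    non-overlapping; consecutive blocks are separated by an N gap (a
    candidate splice junction).
    """

    read_id: str
    chrom: str
    blocks: list[tuple[int, int]]
    identity: float = 1.0
    end_match: tuple[int, int] = (0, 0)
    mapped_transcript: str | None = None

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def aligned_length(self) -> int:
        return sum(e - s + 1 for s, e in self.blocks)


def _blocks_from_cigar(pos1: int, cigartuples) -> list[tuple[int, int]]:
    """Split a CIGAR into genomic blocks at N operations.

    M/=/X and D extend the current block (a deletion does not signal a
    junction); N closes it; I/S/H/P do not consume reference.
    """
    blocks: list[tuple[int, int]] = []
    ref = pos1
    block_start = pos1
    open_block = False
    for op, length in cigartuples:
        if op in _REF_CONSUMING_IN_BLOCK:
            if not open_block:
                block_start = ref
                open_block = True
            ref += length
        elif op == 3:  # N: splice gap
            if open_block:
                blocks.append((block_start, ref - 1))
                open_block = False
            ref += length
    if open_block:
        blocks.append((block_start, ref - 1))
    return blocks


def _md_mismatches_and_runs(md: str) -> tuple[int, int, int]:
    """(n_mismatches, leading_match_run, trailing_match_run) from an MD tag."""
    mismatches = 0
    runs: list[int] = []  # alternating structure; we need first and last match run
    first_run = None
    last_run = 0
    leading = True
    for m in _MD_TOKEN.finditer(md):
        num, deletion, sub = m.group(1), m.group(2), m.group(3)
        if num is not None:
            n = int(num)
            if leading and first_run is None:
                first_run = n
            last_run = n
        else:
            if first_run is None:
                first_run = 0
            last_run = 0
            leading = False
            if sub is not None:
                mismatches += 1
            # deletions (^...) are not mismatching aligned bases
    return mismatches, first_run or 0, last_run


def read_sam(
    path,
    stats: dict | None = None,
) -> Iterator[AlignmentBlockRecord]:
    """Stream accepted-format records from a SAM/BAM file.

    Unmapped, secondary and supplementary records are skipped (tallied in
    ``stats`` when a dict is passed); records without a CIGAR are skipped
    with a warning.  No quality filtering happens here — the acceptance
    filters are separate, pure predicates.
    """
    counts = stats if stats is not None else {}
    for key in ("records", "unmapped", "secondary", "no_cigar"):
        counts.setdefault(key, 0)
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                counts["unmapped"] += 1
                continue
            if aln.is_secondary or aln.is_supplementary:
                counts["secondary"] += 1
                continue
            cig = aln.cigartuples
            if not cig:
                counts["no_cigar"] += 1
                log.warning("record %s has no CIGAR; skipped", aln.query_name)
                continue
            blocks = _blocks_from_cigar(aln.reference_start + 1, cig)
            aligned = sum(l for op, l in cig if op in (0, 7, 8))
            md = aln.get_tag("MD") if aln.has_tag("MD") else None
            if aln.has_tag("NM"):
                nm = aln.get_tag("NM")
            elif md is not None:
                nm = _md_mismatches_and_runs(md)[0]
            else:
                nm = 0
            identity = 1.0 - nm / aligned if aligned else 0.0
            if md is not None:
                _, left, right = _md_mismatches_and_runs(md)
            else:
                left = right = aligned if nm == 0 else 0
            # a clipped end is by definition not an exact terminal match
            if cig[0][0] in (4, 5):
                left = 0
            if cig[-1][0] in (4, 5):
                right = 0
            counts["records"] += 1
            yield AlignmentBlockRecord(
                read_id=aln.query_name,
                chrom=aln.reference_name,
                blocks=blocks,
                identity=identity,
                end_match=(left, right),
                mapped_transcript=(
                    aln.get_tag("XT") if aln.has_tag("XT") else None
                ),
            )


def filter_transcriptome_pass(
    record: AlignmentBlockRecord,
    mate: AlignmentBlockRecord | None = None,
    min_identity: float = 0.95,
    min_end_match: int = 4,
) -> bool:
    """Transcriptome-stage acceptance rule (pure predicate).

    Accept iff identity is strictly above ``min_identity`` and both terminal
    exact-match runs are at least ``min_end_match`` nt.  In paired mode the
    mate must satisfy the same rule and both mates must map to the same
    transcript.
    """
    ok = (
        record.identity > min_identity
        and record.end_match[0] >= min_end_match
        and record.end_match[1] >= min_end_match
    )
    if ok and mate is not None:
        ok = (
            filter_transcriptome_pass(
                mate, None, min_identity=min_identity, min_end_match=min_end_match
            )
            and record.mapped_transcript is not None
            and record.mapped_transcript == mate.mapped_transcript
        )
    return ok


def filter_short_blocks(record: AlignmentBlockRecord, min_block: int = 8) -> bool:
    """Genome-stage block-credibility rule: reject if any block is shorter
    than ``min_block`` nt (a block of exactly ``min_block`` is kept)."""
    return all(e - s + 1 >= min_block for s, e in record.blocks)


def apply_filters(
    records: Iterable[AlignmentBlockRecord],
    min_identity: float = 0.95,
    min_end_match: int = 4,
    min_block: int = 8,
    stats: dict | None = None,
) -> list[AlignmentBlockRecord]:
    """Apply both acceptance filters; order-insensitive by construction."""
    counts = stats if stats is not None else {}
    counts.setdefault("accepted", 0)
    counts.setdefault("rejected_identity_or_ends", 0)
    counts.setdefault("rejected_short_block", 0)
    out = []
    for rec in records:
        if not filter_transcriptome_pass(
            rec, min_identity=min_identity, min_end_match=min_end_match
        ):
            counts["rejected_identity_or_ends"] += 1
            continue
        if not filter_short_blocks(rec, min_block=min_block):
            counts["rejected_short_block"] += 1
            continue
        counts["accepted"] += 1
        out.append(rec)
    return out


class DepthProfile:
    """Per-base coverage arrays for one replicate, keyed by chromosome.

    Index 0 of each array corresponds to base 1.
    """

    def __init__(self, chrom_lengths: dict[str, int]):
        self.depth: dict[str, np.ndarray] = {
            chrom: np.zeros(length, dtype=np.int64)
            for chrom, length in chrom_lengths.items()
        }

    def mean_depth(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base depth over [start, end] (1-based inclusive)."""
        arr = self.depth[chrom]
        if start < 1 or end > arr.size:
            raise IndexError(
                f"interval {chrom}:{start}-{end} outside chromosome "
                f"(length {arr.size})"
            )
        return float(arr[start - 1 : end].mean())

    def mean_depth_intervals(self, chrom: str, intervals) -> float:
        """Mean per-base depth pooling all bases of several intervals."""
        arr = self.depth[chrom]
        total = 0
        nbases = 0
        for start, end in intervals:
            if start < 1 or end > arr.size:
                raise IndexError(
                    f"interval {chrom}:{start}-{end} outside chromosome"
                )
            total += int(arr[start - 1 : end].sum())
            nbases += end - start + 1
        return total / nbases

    @property
    def total(self) -> int:
        return int(sum(arr.sum() for arr in self.depth.values()))


def compute_depth(
    records: Iterable[AlignmentBlockRecord],
    chrom_lengths: dict[str, int],
) -> DepthProfile:
    """Per-base depth: each base covered by a block increments by one.

    Conservation holds by construction: the grand total equals the sum of
    block lengths over all records.
    """
    profile = DepthProfile(chrom_lengths)
    starts: dict[str, list[int]] = {c: [] for c in chrom_lengths}
    ends: dict[str, list[int]] = {c: [] for c in chrom_lengths}
    for rec in records:
        try:
            s_list, e_list = starts[rec.chrom], ends[rec.chrom]
        except KeyError:
            raise KeyError(f"record on unknown chromosome {rec.chrom!r}") from None
        for s, e in rec.blocks:
            if s < 1 or e > chrom_lengths[rec.chrom]:
                raise IndexError(
                    f"block {rec.chrom}:{s}-{e} beyond chromosome length "
                    f"{chrom_lengths[rec.chrom]}"
                )
            s_list.append(s)
            e_list.append(e)
    for chrom, length in chrom_lengths.items():
        if not starts[chrom]:
            continue
        delta = np.zeros(length + 1, dtype=np.int64)
        np.add.at(delta, np.asarray(starts[chrom]) - 1, 1)
        np.add.at(delta, np.asarray(ends[chrom]), -1)
        profile.depth[chrom] = np.cumsum(delta[:-1])
    return profile


def extract_junctions(
    records: Iterable[AlignmentBlockRecord],
) -> dict[tuple[str, int, int], int]:
    """Junction counts keyed by (chrom, donor_boundary, acceptor_boundary).

    The donor boundary is the last base of the upstream block, the acceptor
    boundary the first base of the downstream block; every adjacent block
    pair of every record contributes one count, so a read spanning two
    junctions contributes to both.
    """
    counts: dict[tuple[str, int, int], int] = {}
    for rec in records:
        blocks = rec.blocks
        for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
            key = (rec.chrom, e1, s2)
            counts[key] = counts.get(key, 0) + 1
    return counts


class _GeneIndex:
    """Per-chromosome stabbing index over (possibly overlapping) gene spans."""

    def __init__(self, annotation: AnnotationSet):
        self._by_chrom: dict[str, tuple[list[int], list[int], list[int], list[str]]] = {}
        spans: dict[str, list[tuple[int, int, str]]] = {}
        for gene in annotation:
            span = gene.span
            spans.setdefault(gene.chrom, []).append(
                (span.start, span.end, gene.gene_id)
            )
        for chrom, items in spans.items():
            items.sort()
            starts = [s for s, _, _ in items]
            ends = [e for _, e, _ in items]
            ids = [g for _, _, g in items]
            cummax = []
            m = 0
            for e in ends:
                m = max(m, e)
                cummax.append(m)
            self._by_chrom[chrom] = (starts, ends, cummax, ids)

    def overlapping(self, chrom: str, qstart: int, qend: int) -> list[tuple[str, int, int]]:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        starts, ends, cummax, ids = entry
        hi = bisect.bisect_right(starts, qend)
        hits = []
        i = hi - 1
        while i >= 0 and cummax[i] >= qstart:
            if ends[i] >= qstart:
                hits.append((ids[i], starts[i], ends[i]))
            i -= 1
        hits.reverse()
        return hits


def count_gene_reads(
    records: Iterable[AlignmentBlockRecord],
    annotation: AnnotationSet,
    index: "_GeneIndex | None" = None,
) -> pd.DataFrame:
    """Per-gene (total, unique) read counts for one replicate.

    ``total`` counts every read overlapping the gene span; ``unique``
    counts a read for a gene only when all its blocks fall within that
    gene's span and it overlaps no other gene — the conservative
    denominator for expression ratios.
    """
    if index is None:
        index = _GeneIndex(annotation)
    total = {g.gene_id: 0 for g in annotation}
    unique = {g.gene_id: 0 for g in annotation}
    for rec in records:
        hits = index.overlapping(rec.chrom, rec.start, rec.end)
        for gid, _, _ in hits:
            total[gid] += 1
        if len(hits) == 1:
            gid, gstart, gend = hits[0]
            if rec.start >= gstart and rec.end <= gend:
                unique[gid] += 1
    return pd.DataFrame(
        {"total": pd.Series(total), "unique": pd.Series(unique)}
    ).rename_axis("gene_id")
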