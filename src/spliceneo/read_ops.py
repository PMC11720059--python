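"""Extraction of junction-spanning / region-overlapping reads and mates.

Junction mode selects a read iff its CIGAR contains a skipped-region
(``N``) operation whose reference span equals the event's intron
exactly; region mode selects any read whose aligned span overlaps the
region by at least one base. In both modes the mate of every selected
read is included regardless of its own placement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

import pysam

from .junction_io import JunctionEvent

logger = logging.getLogger(__name__)

BAM_CREF_SKIP = 3  # CIGAR 'N'
_CONSUMES_REF = {0, 2, 3, 7, 8}  # M, D, N, =, X


class UnknownContigError(ValueError):
    """Target contig absent from the alignment header."""


@dataclass(frozen=True)
class ReadRecord:
    name: str
    sequence: str
    cigar: str
    reference_start: int  # 0-based
    is_read2: bool


@dataclass
class ReadSet:
    sample_id: str
    reads: list[ReadRecord] = field(default_factory=list)
    source_mode: str = "junction"

    def __len__(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class Region:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int


def _spans_junction(aln: pysam.AlignedSegment, intron_start: int, intron_end: int) -> bool:
    """True iff an N operation covers exactly [intron_start, intron_end] (1-based)."""
    if aln.cigartuples is None:
        return False
    pos = aln.reference_start  # 0-based
    for op, length in aln.cigartuples:
        if op == BAM_CREF_SKIP:
            if pos + 1 == intron_start and pos + length == intron_end:
                return True
        if op in _CONSUMES_REF:
            pos += length
    return False


def _overlaps_region(aln: pysam.AlignedSegment, start: int, end: int) -> bool:
    """True iff the aligned reference span overlaps [start, end] (1-based) by >=1 base."""
    ref_end = aln.reference_end  # 0-based exclusive
    if ref_end is None:
        return False
    return aln.reference_start < end and ref_end > start - 1


def extract_reads(
    alignments: Union[str, Path, pysam.AlignmentFile],
    target: Union[JunctionEvent, Region],
    mode: str = "junction",
    sample_id: str = "",
    include_secondary: bool = False,
    include_duplicates: bool = False,
) -> ReadSet:
    """Extract target-supporting reads and their mates from an alignment file.

    Accepts SAM or BAM. The whole file is scanned once (toy-scale inputs;
    no index required), selecting reads per ``mode`` and then pulling in
    every selected read's mate by name. Secondary/supplementary and
    duplicate-flagged alignments are excluded by default.
    """
    if mode not in ("junction", "region"):
        raise ValueError(f"mode must be 'junction' or 'region', got {mode!r}")

    own_handle = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        own_handle = True
    try:
        chrom = target.chrom
        if chrom not in alignments.references:
            raise UnknownContigError(
                f"contig {chrom!r} not present in alignment header"
            )
        if mode == "junction":
            start, end = target.intron_start, target.intron_end
        else:
            start, end = target.start, target.end

        records: dict[tuple[str, bool], ReadRecord] = {}
        selected_names: set[str] = set()
        for aln in alignments.fetch(until_eof=True):
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            if not include_secondary and (aln.is_secondary or aln.is_supplementary):
                continue
            if not include_duplicates and aln.is_duplicate:
                continue
            rec_key = (aln.query_name, aln.is_read2)
            if rec_key not in records:
                records[rec_key] = ReadRecord(
                    name=aln.query_name,
                    sequence=aln.query_sequence.upper(),
                    cigar=aln.cigarstring or "",
                    reference_start=aln.reference_start,
                    is_read2=bool(aln.is_read2),
                )
            if aln.reference_name != chrom:
                continue
            if mode == "junction":
                hit = _spans_junction(aln, start, end)
            else:
                hit = _overlaps_region(aln, start, end)
            if hit:
                selected_names.add(aln.query_name)
    finally:
        if own_handle:
            alignments.close()

    out = [rec for key, rec in records.items() if rec.name in selected_names]
    out.sort(key=lambda r: (r.name, r.is_read2))
    return ReadSet(sample_id=sample_id, reads=out, source_mode=mode)


def boost_reads(reads: ReadSet, factor: int) -> ReadSet:
    """Duplicate every read ``factor`` times to aid low-coverage assembly.

    Replicates beyond the first are suffixed with a replicate index in
    the read name. ``factor=1`` is the identity.
    """
    if factor < 1:
        raise ValueError(f"boost factor must be >= 1, got {factor}")
    if factor == 1:
        return ReadSet(
            sample_id=reads.sample_id,
            reads=list(reads.reads),
            source_mode=reads.source_mode,
        )
    boosted: list[ReadRecord] = []
    for rec in reads.reads:
        boosted.append(rec)
        for i in range(2, factor + 1):
            boosted.append(replace(rec, name=f"{rec.name}/rep{i}"))
    return ReadSet(
        sample_id=reads.sample_id, reads=boosted, source_mode=reads.source_mode
    )


def write_fasta(reads: ReadSet, path: str | Path) -> None:
    """Write extracted reads as FASTA for the assembler stage."""
    with open(path, "w") as fh:
        for rec in reads.reads:
            mate = "2" if rec.is_read2 else "1"
            fh.write(f">{rec.name}/{mate}\n{rec.sequence}\n")
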