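from __future__ import annotations

from pathlib import Path

import pytest

from spliceneo.read_ops import ReadRecord, ReadSet
from spliceneo.synthetic import EventSpec, generate_cohort

SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:{chrom}\tLN:{length}\n"


def write_sam(path: Path, records, chrom: str = "chr1", length: int = 10000):
    """Write minimal SAM records: (name, flag, pos, cigar, seq[, rname])."""
    with open(path, "w") as fh:
        fh.write(SAM_HEADER.format(chrom=chrom, length=length))
        for rec in records:
            name, flag, pos, cigar, seq = rec[:5]
            rname = rec[5] if len(rec) > 5 else chrom
            fh.write(
                f"{name}\t{flag}\t{rname}\t{pos}\t60\t{cigar}\t*\t0\t0\t"
                f"{seq}\t*\n"
            )
    return path


def readset_from_seqs(seqs, sample_id="S1", mode="junction") -> ReadSet:
    return ReadSet(
        sample_id=sample_id,
        reads=[
            ReadRecord(
                name=f"r{i:03d}", sequence=s, cigar=f"{len(s)}M",
                reference_start=0, is_read2=False,
            )
            for i, s in enumerate(seqs)
        ],
        source_mode=mode,
    )


def tile_reads(sequence: str, read_length: int, step: int) -> list[str]:
    """Error-free reads tiling a sequence, always covering the final base."""
    starts = list(range(0, len(sequence) - read_length + 1, step))
    last = len(sequence) - read_length
    if starts[-1] != last:
        starts.append(last)
    return [sequence[s : s + read_length] for s in starts]


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """Shared single-allele synthetic cohort with one planted exon-skip."""
    root = tmp_path_factory.mktemp("cohort")
    return generate_cohort(
        seed=7,
        n_tumor=3,
        n_normal=2,
        events=[EventSpec(expressing_fraction=1.0)],
        out_dir=root,
        class1_alleles=["HLA-A02:01"],
        class2_alleles=["DRB1_01:01"],
    )
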