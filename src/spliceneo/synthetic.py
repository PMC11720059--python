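"""Seed-deterministic synthetic cohorts and packaged value tables.

The generator emits a toy genome with configurable exon-skip events, per
sample spliced SAM alignments, STAR-style SJ.out.tab catalogs derived
from the emitted CIGARs (so catalogs agree with reads by construction),
HLA genotype and event tables, and a planted-event registry carrying
independently computed ground truth (transcripts, junction peptide,
expected junction-spanning k-mers).

Packaged tables transcribe the published candidate and responder
comparison PHBR values used by the worked-example acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .junction_io import JunctionEvent
from .phbr import MockRankPredictor

_BASES = np.array(list("ACGT"))
_STOP_CODONS = {"TAA", "TAG", "TGA"}
_SAFE_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP_CODONS
)

DEFAULT_CLASS1_ALLELES = (
    "HLA-A01:01",
    "HLA-A02:01",
    "HLA-B07:02",
    "HLA-B08:01",
    "HLA-C07:01",
    "HLA-C07:02",
)
DEFAULT_CLASS2_ALLELES = ("DRB1_01:01", "DRB1_04:01")


@dataclass
class EventSpec:
    """Specification of one planted exon-skip event."""

    gene_index: int = 0
    kind: str = "exon_skip"
    expressing_fraction: float = 1.0
    outlier_fraction: Optional[float] = None  # defaults to expressing set


@dataclass
class GeneModel:
    symbol: str
    chrom: str
    start: int  # 0-based genomic start of exon 1
    exon_lengths: tuple[int, ...]
    intron_lengths: tuple[int, ...]

    @property
    def exons(self) -> list[tuple[int, int]]:
        """0-based half-open exon intervals."""
        out = []
        pos = self.start
        for i, length in enumerate(self.exon_lengths):
            out.append((pos, pos + length))
            pos += length
            if i < len(self.intron_lengths):
                pos += self.intron_lengths[i]
        return out

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class PlantedEvent:
    event: JunctionEvent
    gene: GeneModel
    wt_junctions: list[tuple[int, int]]  # 1-based intron (first, last) pairs
    wt_transcript: str
    skip_transcript: str
    expected_peptide: str
    breakpoint_nt: int  # 0-based offset of the junction in skip_transcript
    expressing: list[str] = field(default_factory=list)

    @property
    def breakpoint_residues(self) -> frozenset[int]:
        bp = self.breakpoint_nt
        return frozenset({(bp - 1) // 3 + 1, bp // 3 + 1})

    def expected_kmers(self, size: int) -> list[str]:
        """Junction-spanning k-mers by direct string enumeration."""
        pep = self.expected_peptide
        lo, hi = min(self.breakpoint_residues), max(self.breakpoint_residues)
        out = []
        for start in range(1, len(pep) - size + 2):
            if start <= lo and start + size - 1 >= hi:
                out.append(pep[start - 1 : start + size - 1])
        return out


@dataclass
class SyntheticCohort:
    root: Path
    chrom: str
    reference_fasta: Path
    wt_protein_fasta: Path
    alignments_dir: Path
    normal_sj_dir: Path
    tumor_sj_dir: Path
    genotypes_path: Path
    events_path: Path
    tumor_samples: list[str]
    normal_samples: list[str]
    genes: list[GeneModel]
    registry: list[PlantedEvent]


def mock_rank_predictor(
    seed: int = 0,
    plants: Optional[dict[tuple[str, str], float]] = None,
    default_rank: Optional[float] = None,
) -> MockRankPredictor:
    """Deterministic rank predictor (stable hash with plant overrides)."""
    return MockRankPredictor(seed=seed, plants=plants, default_rank=default_rank)


def _random_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(
        _SAFE_CODONS[i] for i in rng.integers(0, len(_SAFE_CODONS), size=n)
    )


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _transcript_blocks(
    exons: Sequence[tuple[int, int]], t0: int, t1: int
) -> list[tuple[int, int]]:
    """Genomic blocks (0-based half-open) for transcript interval [t0, t1)."""
    blocks = []
    offset = 0
    for g_start, g_end in exons:
        length = g_end - g_start
        lo = max(t0, offset)
        hi = min(t1, offset + length)
        if lo < hi:
            blocks.append((g_start + lo - offset, g_start + hi - offset))
        offset += length
    return blocks


def _cigar(blocks: Sequence[tuple[int, int]]) -> str:
    parts = []
    for i, (start, end) in enumerate(blocks):
        if i > 0:
            parts.append(f"{start - blocks[i - 1][1]}N")
        parts.append(f"{end - start}M")
    return "".join(parts)


def _junctions(blocks: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """1-based (first, last) intron bases skipped between blocks."""
    return [
        (blocks[i][1] + 1, blocks[i + 1][0])
        for i in range(len(blocks) - 1)
    ]


def generate_cohort(
    seed: int,
    n_tumor: int,
    n_normal: int,
    events: Optional[Sequence[EventSpec]] = None,
    out_dir: str | Path = ".",
    read_length: int = 100,
    fragment_length: int = 200,
    tile_step: int = 10,
    n_genes: int = 2,
    class1_alleles: Sequence[str] = DEFAULT_CLASS1_ALLELES,
    class2_alleles: Sequence[str] = DEFAULT_CLASS2_ALLELES,
) -> SyntheticCohort:
    """Generate a fully synthetic cohort under ``out_dir``.

    Tumor samples listed as expressing an event carry spliced reads for
    its aberrant (exon-skip) isoform; all other samples carry wild-type
    isoform reads. Outputs are fully determined by ``seed``.
    """
    if n_tumor < 1 or n_normal < 1:
        raise ValueError("n_tumor and n_normal must be >= 1")
    if events is None:
        events = [EventSpec(gene_index=0)]
    for spec in events:
        if spec.kind != "exon_skip":
            raise ValueError(f"unsupported event kind {spec.kind!r}")
        if not 0 <= spec.gene_index < n_genes:
            raise ValueError(
                f"event gene_index {spec.gene_index} outside [0, {n_genes})"
            )

    rng = np.random.default_rng(seed)
    root = Path(out_dir)
    chrom = "chrT"

    # --- toy genome -------------------------------------------------------
    exon_lengths = (120, 90, 120)
    intron_lengths = (150, 180)
    gene_span = sum(exon_lengths) + sum(intron_lengths)
    genes = [
        GeneModel(
            symbol=f"GENE{i + 1}",
            chrom=chrom,
            start=100 + i * (gene_span + 400),
            exon_lengths=exon_lengths,
            intron_lengths=intron_lengths,
        )
        for i in range(n_genes)
    ]
    genome_len = genes[-1].end + 200
    genome = list(_random_bases(rng, genome_len))
    gene_cds: dict[int, str] = {}
    for gi, gene in enumerate(genes):
        cds = "ATG" + _random_codons(rng, sum(exon_lengths) // 3 - 1)
        gene_cds[gi] = cds
        offset = 0
        for (g_start, g_end) in gene.exons:
            genome[g_start:g_end] = cds[offset : offset + (g_end - g_start)]
            offset += g_end - g_start
    genome_seq = "".join(genome)

    # --- planted events ---------------------------------------------------
    tumor_samples = [f"T{i + 1:02d}" for i in range(n_tumor)]
    normal_samples = [f"N{i + 1:02d}" for i in range(n_normal)]
    registry: list[PlantedEvent] = []
    for spec in events:
        gene = genes[spec.gene_index]
        exons = gene.exons
        wt_blocks = exons
        skip_blocks = [exons[0], exons[2]]
        wt_tx = "".join(genome_seq[a:b] for a, b in wt_blocks)
        skip_tx = "".join(genome_seq[a:b] for a, b in skip_blocks)
        peptide = str(Seq(skip_tx[: 3 * (len(skip_tx) // 3)]).translate())
        if "*" in peptide:  # cannot happen: exon lengths are codon-aligned
            raise AssertionError("stop codon in planted skip transcript")
        sj_start, sj_end = _junctions(skip_blocks)[0]

        n_expr = int(round(spec.expressing_fraction * n_tumor))
        expressing = sorted(
            rng.choice(tumor_samples, size=n_expr, replace=False).tolist()
        )
        if spec.outlier_fraction is None:
            outliers = list(expressing)
        else:
            n_oe = int(round(spec.outlier_fraction * n_tumor))
            outliers = sorted(
                rng.choice(tumor_samples, size=n_oe, replace=False).tolist()
            )
        event = JunctionEvent(
            chrom=chrom,
            intron_start=sj_start,
            intron_end=sj_end,
            strand="+",
            gene_symbol=gene.symbol,
            expressing_samples=frozenset(expressing),
            outlier_overexpressed_samples=frozenset(outliers),
        )
        registry.append(
            PlantedEvent(
                event=event,
                gene=gene,
                wt_junctions=_junctions(wt_blocks),
                wt_transcript=wt_tx,
                skip_transcript=skip_tx,
                expected_peptide=peptide,
                breakpoint_nt=exon_lengths[0],
                expressing=expressing,
            )
        )

    # --- per-sample reads and catalogs ------------------------------------
    root.mkdir(parents=True, exist_ok=True)
    alignments_dir = root / "alignments"
    normal_sj_dir = root / "sj" / "normals"
    tumor_sj_dir = root / "sj" / "tumors"
    for d in (alignments_dir, normal_sj_dir, tumor_sj_dir):
        d.mkdir(parents=True, exist_ok=True)

    def isoforms_for(sample: str) -> list[tuple[Sequence[tuple[int, int]], str]]:
        chosen = []
        for gi, gene in enumerate(genes):
            planted = [p for p in registry if p.gene is gene]
            expressed_skip = any(
                sample in p.expressing for p in planted
            ) and sample.startswith("T")
            blocks = (
                [gene.exons[0], gene.exons[2]] if expressed_skip else gene.exons
            )
            tx = "".join(genome_seq[a:b] for a, b in blocks)
            chosen.append((blocks, tx))
        return chosen

    for sample in tumor_samples + normal_samples:
        sam_path = alignments_dir / f"{sample}.sam"
        sj_counts: dict[tuple[int, int], int] = {}
        records = []
        frag_idx = 0
        for blocks, tx in isoforms_for(sample):
            max_start = len(tx) - fragment_length
            for t0 in range(0, max_start + 1, tile_step):
                frag_idx += 1
                name = f"{sample}.frag{frag_idx:04d}"
                r1 = (t0, t0 + read_length)
                r2 = (t0 + fragment_length - read_length, t0 + fragment_length)
                mate_blocks = [
                    _transcript_blocks(blocks, a, b) for a, b in (r1, r2)
                ]
                for mate, mb in enumerate(mate_blocks):
                    for j in _junctions(mb):
                        sj_counts[j] = sj_counts.get(j, 0) + 1
                pos1 = mate_blocks[0][0][0] + 1
                pos2 = mate_blocks[1][0][0] + 1
                seqs = [tx[a:b] for a, b in (r1, r2)]
                flags = (67, 131)  # paired, proper, read1 / read2
                for mate in (0, 1):
                    records.append(
                        (
                            mate_blocks[mate][0][0],
                            "\t".join(
                                [
                                    name,
                                    str(flags[mate]),
                                    chrom,
                                    str((pos1, pos2)[mate]),
                                    "60",
                                    _cigar(mate_blocks[mate]),
                                    "=",
                                    str((pos2, pos1)[mate]),
                                    "0",
                                    seqs[mate],
                                    "*",
                                ]
                            ),
                        )
                    )
        records.sort(key=lambda r: (r[0], r[1]))
        with open(sam_path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:coordinate\n")
            fh.write(f"@SQ\tSN:{chrom}\tLN:{genome_len}\n")
            for _, line in records:
                fh.write(line + "\n")

        sj_dir = normal_sj_dir if sample.startswith("N") else tumor_sj_dir
        with open(sj_dir / f"{sample}.SJ.out.tab", "w") as fh:
            for (j_start, j_end) in sorted(sj_counts):
                fh.write(
                    "\t".join(
                        [
                            chrom,
                            str(j_start),
                            str(j_end),
                            "1",  # + strand
                            "1",
                            "0",
                            str(sj_counts[(j_start, j_end)]),
                            "0",
                            "30",
                        ]
                    )
                    + "\n"
                )

    # --- reference, proteins, genotypes, events ---------------------------
    reference_fasta = root / "reference.fasta"
    with open(reference_fasta, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, genome_len, 70):
            fh.write(genome_seq[i : i + 70] + "\n")

    wt_protein_fasta = root / "wt_proteins.fasta"
    with open(wt_protein_fasta, "w") as fh:
        for gi, gene in enumerate(genes):
            protein = str(Seq(gene_cds[gi]).translate())
            fh.write(f">{gene.symbol}\n{protein}\n")

    genotypes_path = root / "genotypes.tsv"
    with open(genotypes_path, "w") as fh:
        fh.write("patient_id\tclass\tallele\n")
        for sample in tumor_samples:
            for allele in class1_alleles:
                fh.write(f"{sample}\tI\t{allele}\n")
            for allele in class2_alleles:
                fh.write(f"{sample}\tII\t{allele}\n")

    events_path = root / "events.tsv"
    with open(events_path, "w") as fh:
        fh.write(
            "chrom\tintron_start\tintron_end\tstrand\tgene\t"
            "expressing_samples\toutlier_oe_samples\n"
        )
        for planted in registry:
            ev = planted.event
            fh.write(
                "\t".join(
                    [
                        ev.chrom,
                        str(ev.intron_start),
                        str(ev.intron_end),
                        ev.strand,
                        ev.gene_symbol or "",
                        ",".join(sorted(ev.expressing_samples)),
                        ",".join(sorted(ev.outlier_overexpressed_samples)),
                    ]
                )
                + "\n"
            )

    return SyntheticCohort(
        root=root,
        chrom=chrom,
        reference_fasta=reference_fasta,
        wt_protein_fasta=wt_protein_fasta,
        alignments_dir=alignments_dir,
        normal_sj_dir=normal_sj_dir,
        tumor_sj_dir=tumor_sj_dir,
        genotypes_path=genotypes_path,
        events_path=events_path,
        tumor_samples=tumor_samples,
        normal_samples=normal_samples,
        genes=genes,
        registry=registry,
    )


def _data_path(name: str):
    return resources.files("spliceneo.data").joinpath(name)


def load_candidate_table() -> pd.DataFrame:
    """Published candidate-event PHBR values (12 events, MHC-I)."""
    with resources.as_file(_data_path("opscc_candidates.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def load_region_comparison_table() -> pd.DataFrame:
    """Published responder/nonresponder region PHBR values (30 events)."""
    with resources.as_file(_data_path("melanoma_region_comparison.tsv")) as path:
        df = pd.read_csv(path, sep="\t")
    df["nonresponder_phbr"] = pd.to_numeric(
        df["nonresponder_phbr"], errors="coerce"
    )
    return df


def packaged_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Both packaged value tables (candidates, region comparison)."""
    return load_candidate_table(), load_region_comparison_table()
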