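"""Frame selection, junction breakpoint location, and peptide k-mers.

Contigs are translated in all reading frames (six by default), truncated
at the first stop codon, and the frame with the best local alignment to
the wild-type protein is retained per sample. The junction breakpoint is
located by ungapped anchoring of the reference exonic flanks, and all
peptide substrings of the requested binding lengths that span the
breakpoint residues are enumerated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .assembly import Contig, revcomp

logger = logging.getLogger(__name__)

MHC_I_KMER_SIZES = (8, 9, 10, 11)
MHC_II_KMER_SIZES = (15,)

SIX_FRAMES = (1, 2, 3, -1, -2, -3)
FORWARD_FRAMES = (1, 2, 3)
REVERSE_FRAMES = (-1, -2, -3)

# Local alignment scoring used for frame selection: +2 identity, -5
# mismatch, -1 on a gap's first symbol, -0.5 on each further symbol.
_ALIGNER = PairwiseAligner()
_ALIGNER.mode = "local"
_ALIGNER.match_score = 2.0
_ALIGNER.mismatch_score = -5.0
_ALIGNER.open_gap_score = -1.0
_ALIGNER.extend_gap_score = -0.5
_ALIGNER.wildcard = None  # 'X' scores as a plain mismatch


@dataclass
class IsoformCall:
    """Per-sample selected isoform contig and its translation."""

    sample_id: str
    contig: Optional[Contig] = None
    frame: Optional[int] = None
    peptide: str = ""
    alignment_score: float = 0.0
    breakpoint_nt: Optional[int] = None
    region_end_nt: Optional[int] = None
    breakpoint_residues: Optional[frozenset[int]] = None
    premature_stop: bool = False
    excluded: bool = False
    exclusion_reason: Optional[str] = None

    def exclude(self, reason: str) -> "IsoformCall":
        self.excluded = True
        self.exclusion_reason = reason
        return self


@dataclass
class KmerSet:
    """Junction-spanning peptide k-mers for one sample at one event."""

    event_id: str
    sample_id: str
    kmers: list[tuple[str, int, int]] = field(default_factory=list)
    class_mode: str = "I"

    @property
    def peptides(self) -> list[str]:
        return [p for p, _, _ in self.kmers]

    def __len__(self) -> int:
        return len(self.kmers)


def local_align(a: str, b: str):
    """Best local alignment score and aligned spans for two proteins.

    Scoring: match +2, mismatch -5, gap open -1 (charged on the gap's
    first symbol), gap extend -0.5. Returns ``(score, spans)`` where
    spans is ``((a_start, a_end), (b_start, b_end))`` (0-based,
    end-exclusive) or ``None`` when no positive-scoring alignment exists.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    score = float(_ALIGNER.score(a, b))
    if score <= 0:
        return 0.0, None
    aln = next(iter(_ALIGNER.align(a, b)))
    a_blocks, b_blocks = aln.aligned
    spans = (
        (int(a_blocks[0][0]), int(a_blocks[-1][1])),
        (int(b_blocks[0][0]), int(b_blocks[-1][1])),
    )
    return score, spans


def translate_frame(sequence: str, frame: int) -> tuple[str, bool]:
    """Translate one reading frame, truncating at the first stop codon.

    Frames are 1..3 on the given sequence and -1..-3 on its reverse
    complement. Returns ``(peptide, stop_seen)``.
    """
    if frame not in SIX_FRAMES:
        raise ValueError(f"invalid frame {frame}")
    oriented = sequence if frame > 0 else revcomp(sequence)
    offset = abs(frame) - 1
    usable = oriented[offset : offset + 3 * ((len(oriented) - offset) // 3)]
    if not usable:
        return "", False
    protein = str(Seq(usable).translate())
    stop_idx = protein.find("*")
    if stop_idx == -1:
        return protein, False
    return protein[:stop_idx], True


def select_best_isoform(
    contigs: Sequence[Contig],
    wt_protein: str,
    frames: Iterable[int] = SIX_FRAMES,
    sample_id: str = "",
) -> IsoformCall:
    """Pick the (contig, frame) whose translation best matches the WT protein.

    Ties are broken by longer peptide, then by contig order (contigs are
    expected pre-sorted by length desc / lexicographic, the assembler's
    deterministic order). An empty contig list yields an excluded call
    with reason ``assembly_failure``.
    """
    if not wt_protein:
        raise ValueError("wt_protein must be non-empty")
    contigs = list(contigs)
    if not contigs:
        return IsoformCall(sample_id=sample_id).exclude("assembly_failure")

    best: Optional[IsoformCall] = None
    best_key = None
    for order, contig in enumerate(contigs):
        for frame in frames:
            peptide, stop_seen = translate_frame(contig.sequence, frame)
            if not peptide:
                continue
            score, _ = local_align(peptide, wt_protein)
            key = (-score, -len(peptide), order, _frame_order(frame))
            if best_key is None or key < best_key:
                best_key = key
                best = IsoformCall(
                    sample_id=sample_id,
                    contig=contig,
                    frame=frame,
                    peptide=peptide,
                    alignment_score=score,
                    premature_stop=stop_seen,
                )
    if best is None:
        return IsoformCall(sample_id=sample_id).exclude("assembly_failure")
    return best


def _frame_order(frame: int) -> int:
    return SIX_FRAMES.index(frame)


def _best_end_anchor(flank: str, seq: str) -> tuple[float, int]:
    """Best ungapped placement of ``flank`` ending at some position of ``seq``.

    Returns ``(score, end)`` with end in [1, len(seq)]; +1 per match,
    -1 per mismatch over the overlapping suffix of the flank.
    """
    best_score, best_end = float("-inf"), 0
    for end in range(1, len(seq) + 1):
        ov = min(len(flank), end)
        score = 0
        f_off = len(flank) - ov
        s_off = end - ov
        for i in range(ov):
            score += 1 if flank[f_off + i] == seq[s_off + i] else -1
        if score > best_score:
            best_score, best_end = score, end
    return best_score, best_end


def _best_start_anchor(flank: str, seq: str) -> tuple[float, int]:
    """Best ungapped placement of ``flank`` starting at some position of ``seq``."""
    best_score, best_start = float("-inf"), 0
    for start in range(len(seq)):
        ov = min(len(flank), len(seq) - start)
        score = 0
        for i in range(ov):
            score += 1 if flank[i] == seq[start + i] else -1
        if score > best_score:
            best_score, best_start = score, start
    return best_score, best_start


def locate_breakpoint(
    call: IsoformCall,
    upstream_flank: str,
    downstream_flank: str,
    anchor_fraction: float = 0.5,
) -> IsoformCall:
    """Locate the junction position within the selected contig.

    ``upstream_flank``/``downstream_flank`` are the reference exonic
    sequences immediately preceding/following the intron (genomic plus
    orientation); both contig orientations are tried. ``breakpoint_nt``
    is the 0-based contig offset where the upstream anchor ends (= the
    first downstream/novel nucleotide); ``breakpoint_residues`` are the
    1-based peptide positions whose codons cover the two nucleotides
    flanking that offset.

    A flank whose best anchor scores below ``anchor_fraction`` of its
    maximum marks the call excluded with reason ``breakpoint_unresolved``.
    """
    if call.excluded:
        return call
    if len(upstream_flank) < 20 or len(downstream_flank) < 20:
        raise ValueError("flanks must be at least 20 nt")
    if call.contig is None or call.frame is None:
        return call.exclude("assembly_failure")

    seq = call.contig.sequence
    upstream_flank = upstream_flank.upper()
    downstream_flank = downstream_flank.upper()

    candidates = []
    for up, down in (
        (upstream_flank, downstream_flank),  # contig in genomic orientation
        (revcomp(downstream_flank), revcomp(upstream_flank)),  # contig flipped
    ):
        u_score, u_end = _best_end_anchor(up, seq)
        d_score, d_start = _best_start_anchor(down, seq)
        anchored = (
            u_score >= anchor_fraction * len(up)
            and d_score >= anchor_fraction * len(down)
        )
        candidates.append((u_score + d_score, anchored, u_end, d_start))
    candidates.sort(key=lambda c: -c[0])
    total, anchored, u_end, d_start = candidates[0]
    if not anchored:
        return call.exclude("breakpoint_unresolved")

    call.breakpoint_nt = u_end
    call.region_end_nt = max(d_start, u_end)
    residues = _breakpoint_residues(call)
    if not residues:
        reason = "premature_stop" if call.premature_stop else "short_peptide"
        return call.exclude(reason)
    call.breakpoint_residues = frozenset(residues)
    return call


def _breakpoint_residues(call: IsoformCall) -> set[int]:
    """Peptide positions (1-based) covering the two junction-flanking nts."""
    seq_len = len(call.contig.sequence)
    bp = call.breakpoint_nt
    if call.frame > 0:
        pair = (bp - 1, bp)
        offset = call.frame - 1
    else:
        # position i in the contig maps to seq_len - 1 - i in the revcomp
        pair = (seq_len - 1 - bp, seq_len - bp)
        offset = -call.frame - 1
    residues: set[int] = set()
    for pos in pair:
        if pos < offset or pos >= seq_len:
            continue
        res = (pos - offset) // 3 + 1
        if 1 <= res <= len(call.peptide):
            residues.add(res)
    return residues


def region_residue_range(call: IsoformCall) -> Optional[tuple[int, int]]:
    """1-based peptide residue interval covered by the anchored region.

    Spans the nucleotides between the upstream and downstream flank
    anchors (inclusive of the two boundary nucleotides); collapses to
    the breakpoint residue pair when the anchors abut or overlap.
    """
    if call.breakpoint_nt is None:
        return None
    seq_len = len(call.contig.sequence)
    end_nt = call.region_end_nt if call.region_end_nt is not None else call.breakpoint_nt
    if call.frame > 0:
        positions = (call.breakpoint_nt - 1, end_nt)
        offset = call.frame - 1
    else:
        positions = (seq_len - 1 - end_nt, seq_len - call.breakpoint_nt)
        offset = -call.frame - 1
    lo_pos, hi_pos = sorted(positions)
    lo = max(1, (max(lo_pos, offset) - offset) // 3 + 1)
    hi = (min(hi_pos, seq_len - 1) - offset) // 3 + 1
    lo, hi = max(1, lo), min(len(call.peptide), hi)
    if lo > hi:
        if call.breakpoint_residues:
            return (
                min(call.breakpoint_residues),
                max(call.breakpoint_residues),
            )
        return None
    return lo, hi


def junction_kmers(
    call: IsoformCall,
    sizes: Sequence[int] = MHC_I_KMER_SIZES,
    event_id: str = "",
    class_mode: str = "I",
    region_residues: Optional[tuple[int, int]] = None,
) -> KmerSet:
    """Enumerate peptide k-mers spanning the junction breakpoint.

    A k-mer of length ``k`` starting at 1-based residue ``i`` qualifies
    when it contains every breakpoint residue (junction mode) or when it
    overlaps ``region_residues = (lo, hi)`` by at least one residue
    (region mode). Duplicate peptide strings are removed. A peptide too
    short for any requested size marks the call excluded with reason
    ``short_peptide``.
    """
    if call.excluded:
        raise ValueError(f"call is excluded ({call.exclusion_reason})")
    if region_residues is None and not call.breakpoint_residues:
        raise ValueError("breakpoint_residues not populated")
    peptide = call.peptide
    result = KmerSet(event_id=event_id, sample_id=call.sample_id,
                     class_mode=class_mode)
    if not sizes:
        raise ValueError("sizes must be non-empty")
    if len(peptide) < min(sizes):
        call.exclude("short_peptide")
        return result

    if region_residues is not None:
        lo, hi = region_residues
    else:
        lo = min(call.breakpoint_residues)
        hi = max(call.breakpoint_residues)

    seen: set[str] = set()
    for k in sorted(sizes):
        if k > len(peptide):
            continue
        for start in range(1, len(peptide) - k + 2):
            end = start + k - 1
            if region_residues is not None:
                ok = start <= hi and end >= lo
            else:
                ok = start <= lo and end >= hi
            if not ok:
                continue
            pep = peptide[start - 1 : end]
            if pep in seen:
                continue
            seen.add(pep)
            result.kmers.append((pep, start, k))
    if not result.kmers:
        call.exclude("short_peptide")
    return result


def longest_orf(sequence: str, frames: Iterable[int] = SIX_FRAMES) -> str:
    """Longest ATG-initiated ORF protein across frames.

    Falls back to the longest stop-free translated stretch when no
    ATG-initiated ORF exists. Used as the wild-type protein stand-in when
    no protein FASTA is supplied.
    """
    best = ""
    for frame in frames:
        oriented = sequence if frame > 0 else revcomp(sequence)
        offset = abs(frame) - 1
        usable = oriented[offset : offset + 3 * ((len(oriented) - offset) // 3)]
        if len(usable) < 3:
            continue
        protein = str(Seq(usable).translate())
        for chunk in protein.split("*"):
            m_idx = chunk.find("M")
            orf = chunk[m_idx:] if m_idx >= 0 else ""
            if len(orf) > len(best):
                best = orf
    if best:
        return best
    # no ATG anywhere: longest stop-free stretch
    for frame in frames:
        oriented = sequence if frame > 0 else revcomp(sequence)
        offset = abs(frame) - 1
        usable = oriented[offset : offset + 3 * ((len(oriented) - offset) // 3)]
        if len(usable) < 3:
            continue
        protein = str(Seq(usable).translate())
        for chunk in protein.split("*"):
            if len(chunk) > len(best):
                best = chunk
    return best
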