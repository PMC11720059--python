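"""Small de Bruijn contig assembler plus an external-assembler adapter.

The built-in assembler exists so tests and desk-scale runs need no
external binary; production runs may swap in any executable mapping a
reads FASTA to a contigs FASTA via :func:`run_external_assembler`.

Both read orientations are indexed (each read contributes its k-mers and
their reverse complements), low-coverage k-mers are pruned, unbranched
paths are collapsed into unitigs, and every maximal simple source-to-sink
path of the compacted graph is emitted as a contig. Contigs are
deduplicated by canonical orientation (lexicographic minimum of sequence
and reverse complement) and ordered by length descending, then
lexicographically.
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .read_ops import ReadSet, write_fasta

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGT")

#: Cap on enumerated simple paths before falling back to unitig output.
MAX_PATHS = 256


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Contig:
    sample_id: str
    sequence: str
    support: int
    assembler_id: str = "builtin-dbg"

    def __len__(self) -> int:
        return len(self.sequence)


def assemble_contigs(
    reads: ReadSet,
    k: int = 25,
    min_kmer_count: Optional[int] = None,
    max_paths: int = MAX_PATHS,
) -> list[Contig]:
    """Assemble a read set into contigs with a de Bruijn graph.

    Parameters
    ----------
    k:
        Odd k-mer size in [15, 31].
    min_kmer_count:
        Coverage floor; k-mers seen fewer times (counting both read
        orientations) are pruned. Defaults to 1: with distinct read start
        positions the source sequence's terminal k-mers occur exactly
        once, so any higher unconditional floor truncates contig ends.

    Returns an empty list (with a warning) when no read contains a valid
    k-mer, mirroring the upstream assembler-failure exclusion.
    """
    if k < 15 or k > 31 or k % 2 == 0:
        raise ValueError(f"k must be odd and within [15, 31], got {k}")
    if not reads.reads:
        raise ValueError("reads must be non-empty")
    floor = 1 if min_kmer_count is None else int(min_kmer_count)

    counts: dict[str, int] = {}
    for rec in reads.reads:
        seq = rec.sequence.upper()
        for oriented in (seq, revcomp(seq)):
            for i in range(len(oriented) - k + 1):
                km = oriented[i : i + k]
                if set(km) <= _VALID:
                    counts[km] = counts.get(km, 0) + 1

    kmers = {km for km, c in counts.items() if c >= floor}
    if not kmers:
        logger.warning(
            "assembly failed for sample %s: no k-mer of size %d survives "
            "(%d reads)",
            reads.sample_id,
            k,
            len(reads.reads),
        )
        return []

    def successors(km: str) -> list[str]:
        stem = km[1:]
        return [stem + b for b in "ACGT" if stem + b in kmers]

    def predecessors(km: str) -> list[str]:
        stem = km[:-1]
        return [b + stem for b in "ACGT" if b + stem in kmers]

    unitigs = _compact(kmers, successors, predecessors, k)
    paths = _enumerate_paths(unitigs, max_paths)
    if paths is None:  # blow-up: fall back to unitigs
        logger.warning(
            "path enumeration exceeded %d paths for sample %s; emitting "
            "unitigs instead",
            max_paths,
            reads.sample_id,
        )
        sequences = [u.seq for u in unitigs]
    else:
        sequences = paths

    # Reverse-complement twins are present by construction; keep canonical.
    canonical: dict[str, str] = {}
    for seq in sequences:
        if len(seq) < k:
            continue
        rc = revcomp(seq)
        canon = min(seq, rc)
        canonical.setdefault(canon, canon)
    contigs = sorted(canonical, key=lambda s: (-len(s), s))

    out = []
    for seq in contigs:
        contig_kmers = {seq[i : i + k] for i in range(len(seq) - k + 1)}
        contig_kmers |= {revcomp(km) for km in contig_kmers}
        support = sum(
            1
            for rec in reads.reads
            if any(
                rec.sequence[i : i + k] in contig_kmers
                for i in range(len(rec.sequence) - k + 1)
            )
        )
        out.append(
            Contig(sample_id=reads.sample_id, sequence=seq, support=support)
        )
    return out


@dataclass
class _Unitig:
    seq: str
    first: str  # first k-mer
    last: str  # last k-mer


def _compact(kmers, successors, predecessors, k) -> list[_Unitig]:
    """Collapse maximal non-branching k-mer paths into unitigs."""

    def is_path_start(km: str) -> bool:
        preds = predecessors(km)
        if len(preds) != 1:
            return True
        return len(successors(preds[0])) != 1

    unitigs: list[_Unitig] = []
    visited: set[str] = set()
    for km in sorted(kmers):
        if km in visited or not is_path_start(km):
            continue
        path = [km]
        visited.add(km)
        cur = km
        while True:
            succ = successors(cur)
            if len(succ) != 1:
                break
            nxt = succ[0]
            if len(predecessors(nxt)) != 1 or nxt in visited:
                break
            path.append(nxt)
            visited.add(nxt)
            cur = nxt
        seq = path[0] + "".join(p[-1] for p in path[1:])
        unitigs.append(_Unitig(seq=seq, first=path[0], last=path[-1]))
    # isolated cycles: every node has in/out degree 1; pick deterministic entry
    for km in sorted(kmers):
        if km not in visited:
            path = [km]
            visited.add(km)
            cur = km
            while True:
                succ = successors(cur)
                if len(succ) != 1:
                    break
                nxt = succ[0]
                if nxt in visited:
                    break
                path.append(nxt)
                visited.add(nxt)
                cur = nxt
            seq = path[0] + "".join(p[-1] for p in path[1:])
            unitigs.append(_Unitig(seq=seq, first=path[0], last=path[-1]))
    return unitigs


def _enumerate_paths(unitigs: list[_Unitig], max_paths: int) -> Optional[list[str]]:
    """All maximal simple paths through the unitig graph, or None on blow-up."""
    by_first = {u.first: i for i, u in enumerate(unitigs)}
    k = len(unitigs[0].first) if unitigs else 0
    edges: dict[int, list[int]] = {i: [] for i in range(len(unitigs))}
    indeg = {i: 0 for i in range(len(unitigs))}
    for i, u in enumerate(unitigs):
        stem = u.last[1:]
        for b in "ACGT":
            j = by_first.get(stem + b)
            if j is not None:
                edges[i].append(j)
                indeg[j] += 1

    sources = [i for i in range(len(unitigs)) if indeg[i] == 0]
    if not sources:  # fully cyclic component(s)
        sources = list(range(len(unitigs)))

    results: list[str] = []

    def dfs(node: int, seq: str, visited: frozenset[int]) -> bool:
        nexts = [j for j in edges[node] if j not in visited]
        if not nexts:
            results.append(seq)
            return len(results) <= max_paths
        for j in sorted(nexts):
            ext = seq + unitigs[j].seq[k - 1 :]
            if not dfs(j, ext, visited | {j}):
                return False
        return True

    for s in sorted(sources):
        if not dfs(s, unitigs[s].seq, frozenset([s])):
            return None
    return results


def run_external_assembler(
    command: str,
    reads: ReadSet,
    workdir: Optional[str | Path] = None,
    timeout: Optional[float] = None,
    extra_args: str = "",
) -> list[Contig]:
    """Invoke an external assembler executable on a read set.

    ``command`` is a template containing ``{input}`` and ``{output}``
    placeholders for the reads FASTA and contigs FASTA paths; any
    ``extra_args`` are appended verbatim. The adapter preserves the
    built-in assembler's contract: FASTA reads in, FASTA contigs out.
    """
    if "{input}" not in command or "{output}" not in command:
        raise ValueError("command template must contain {input} and {output}")
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        in_path = Path(tmp) / "reads.fasta"
        out_path = Path(tmp) / "contigs.fasta"
        write_fasta(reads, in_path)
        cmd = command.format(input=in_path, output=out_path)
        if extra_args:
            cmd = f"{cmd} {extra_args}"
        subprocess.run(cmd, shell=True, check=True, timeout=timeout)
        if not out_path.exists():
            logger.warning("external assembler produced no output for %s",
                           reads.sample_id)
            return []
        contigs = []
        for name, seq in _read_fasta(out_path):
            contigs.append(
                Contig(
                    sample_id=reads.sample_id,
                    sequence=seq.upper(),
                    support=len(reads.reads),
                    assembler_id="external",
                )
            )
        contigs.sort(key=lambda c: (-len(c.sequence), c.sequence))
        return contigs


def _read_fasta(path: Path):
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    yield name, "".join(chunks)
                name, chunks = line[1:], []
            elif line:
                chunks.append(line)
    if name is not None:
        yield name, "".join(chunks)
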