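"""Splice-junction catalog parsing and wild-type junction identification.

All junction coordinates follow the STAR ``SJ.out.tab`` convention:
1-based positions of the first and last base of the intron. Event lists
are TSV files with the header ``chrom, intron_start, intron_end, strand,
gene, expressing_samples, outlier_oe_samples`` where the two sample
columns are comma-separated sample IDs (may be empty).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

logger = logging.getLogger(__name__)

#: STAR strand column codes.
STRAND_CODES = {"0": ".", "1": "+", "2": "-"}


class SJParseError(ValueError):
    """Raised for a malformed SJ.out.tab or event-table line."""


@dataclass(frozen=True)
class SJRecord:
    """One splice junction observed in one sample."""

    strand: str
    unique_reads: int
    multimapped_reads: int = 0
    max_overhang: int = 0


@dataclass
class JunctionCatalog:
    """Per-sample splice-junction catalog (one parsed SJ.out.tab)."""

    sample_id: str
    records: dict[tuple[str, int, int], SJRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class JunctionEvent:
    """An alternative splicing event or wild-type junction.

    ``intron_start``/``intron_end`` are the 1-based first and last intron
    bases. Sample annotations come from the upstream outlier caller and
    are consumed as-is.
    """

    chrom: str
    intron_start: int
    intron_end: int
    strand: str = "."
    gene_symbol: Optional[str] = None
    expressing_samples: frozenset[str] = frozenset()
    outlier_overexpressed_samples: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.intron_start <= 0 or self.intron_end <= 0:
            raise ValueError(
                f"intron coordinates must be positive, got "
                f"({self.intron_start}, {self.intron_end})"
            )
        if self.intron_start >= self.intron_end:
            raise ValueError(
                f"intron_start must be < intron_end, got "
                f"({self.intron_start}, {self.intron_end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.intron_start, self.intron_end)

    @property
    def event_id(self) -> str:
        return f"{self.chrom}:{self.intron_start}-{self.intron_end}"


@dataclass
class WTJunctionCall:
    """Result of looking up an event's wild-type alternative junction."""

    found: bool
    wt_junction: Optional[JunctionEvent] = None
    shared_site: Optional[str] = None  # "start" | "end"
    n_expressing_normals: int = 0
    total_unique_reads: int = 0


def parse_sj_file(path: str | Path, sample_id: str) -> JunctionCatalog:
    """Parse a STAR ``SJ.out.tab`` file into a :class:`JunctionCatalog`.

    Parameters
    ----------
    path:
        Tab-separated file with at least 9 columns per the STAR format.
    sample_id:
        Identifier attached to the resulting catalog.

    Raises
    ------
    SJParseError
        On a line with fewer than 9 columns or non-integer coordinates;
        the error message names the offending line number.
    """
    catalog = JunctionCatalog(sample_id=sample_id)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise SJParseError(
                    f"{path}: line {lineno}: expected >=9 tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                strand = STRAND_CODES.get(fields[3], ".")
                unique = int(fields[6])
                multi = int(fields[7])
                overhang = int(fields[8])
            except ValueError as exc:
                raise SJParseError(
                    f"{path}: line {lineno}: non-integer field ({exc})"
                ) from None
            catalog.records[(chrom, start, end)] = SJRecord(
                strand=strand,
                unique_reads=unique,
                multimapped_reads=multi,
                max_overhang=overhang,
            )
    return catalog


def parse_event_table(path: str | Path) -> list[JunctionEvent]:
    """Parse an event-list TSV into :class:`JunctionEvent` objects."""
    events: list[JunctionEvent] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["chrom", "intron_start", "intron_end"]
        for col in required:
            if col not in header:
                raise SJParseError(f"{path}: missing required column {col!r}")
        idx = {name: i for i, name in enumerate(header)}

        def _get(fields: list[str], col: str, default: str = "") -> str:
            i = idx.get(col)
            if i is None or i >= len(fields):
                return default
            return fields[i]

        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            try:
                event = JunctionEvent(
                    chrom=_get(fields, "chrom"),
                    intron_start=int(_get(fields, "intron_start")),
                    intron_end=int(_get(fields, "intron_end")),
                    strand=_get(fields, "strand", ".") or ".",
                    gene_symbol=_get(fields, "gene") or None,
                    expressing_samples=_split_samples(
                        _get(fields, "expressing_samples")
                    ),
                    outlier_overexpressed_samples=_split_samples(
                        _get(fields, "outlier_oe_samples")
                    ),
                )
            except ValueError as exc:
                raise SJParseError(f"{path}: line {lineno}: {exc}") from None
            events.append(event)
    return events


def _split_samples(text: str) -> frozenset[str]:
    return frozenset(s for s in (t.strip() for t in text.split(",")) if s)


def identify_wt_junction(
    ase: JunctionEvent,
    normals: Iterable[JunctionCatalog],
    min_reads: int = 1,
    require_strand_match: bool = True,
    site: Optional[str] = None,
) -> WTJunctionCall:
    """Find the wild-type alternative junction for an event.

    Among all normal-catalog junctions sharing the event's intron start
    OR end (but not identical to it), returns the one expressed with
    ``unique_reads >= min_reads`` in the greatest number of normal
    samples. Ties are broken by total unique reads across normals, then
    lexicographically by (chrom, start, end). Multimapped reads are
    ignored. Absence of any candidate is a valid result (``found=False``).

    Parameters
    ----------
    site:
        ``"start"`` or ``"end"`` restricts candidates to junctions
        sharing that coordinate; ``None`` (default) pools both.
    require_strand_match:
        When both the event and a catalog record carry a known strand,
        mismatching records are excluded.
    """
    normals = list(normals)
    if not normals:
        raise ValueError("normals must be non-empty")
    if site not in (None, "start", "end"):
        raise ValueError(f"site must be None, 'start' or 'end', got {site!r}")

    # key -> [n_expressing_samples, total_unique_reads, strand]
    tally: dict[tuple[str, int, int], list] = {}
    for catalog in normals:
        for key, rec in catalog.records.items():
            chrom, start, end = key
            if chrom != ase.chrom or key == ase.key:
                continue
            shares_start = start == ase.intron_start
            shares_end = end == ase.intron_end
            if site == "start":
                shares_end = False
            elif site == "end":
                shares_start = False
            if not (shares_start or shares_end):
                continue
            if (
                require_strand_match
                and ase.strand in "+-"
                and rec.strand in "+-"
                and rec.strand != ase.strand
            ):
                logger.debug(
                    "wt-scan %s: skipping strand-discordant candidate %s",
                    ase.event_id,
                    key,
                )
                continue
            if rec.unique_reads < min_reads:
                continue
            entry = tally.setdefault(key, [0, 0, rec.strand])
            entry[0] += 1
            entry[1] += rec.unique_reads

    if not tally:
        return WTJunctionCall(found=False)

    best_key = min(
        tally, key=lambda k: (-tally[k][0], -tally[k][1], k[0], k[1], k[2])
    )
    n_samples, total_reads, strand = tally[best_key]
    shared = "start" if best_key[1] == ase.intron_start else "end"
    wt = JunctionEvent(
        chrom=best_key[0],
        intron_start=best_key[1],
        intron_end=best_key[2],
        strand=strand,
        gene_symbol=ase.gene_symbol,
    )
    return WTJunctionCall(
        found=True,
        wt_junction=wt,
        shared_site=shared,
        n_expressing_normals=n_samples,
        total_unique_reads=total_reads,
    )
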