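"""End-to-end orchestration: events × samples → PHBR summaries and reports.

For each event the pipeline identifies the wild-type alternative junction
(junction mode), extracts junction-spanning (or region-overlapping) reads
and mates per tumor sample, optionally boosts them, assembles contigs,
selects the best-aligned reading frame, locates the junction breakpoint,
enumerates binding-size k-mers and computes per-sample PHBR; events are
then summarized, filtered, and written as TSV reports with a JSON run
manifest. Any stage's hard error aborts that event only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from pyfaidx import Fasta

from . import __version__
from .assembly import assemble_contigs, run_external_assembler
from .candidates_report import (
    CandidateRow,
    filter_candidates,
    write_event_report,
)
from .junction_io import (
    JunctionEvent,
    identify_wt_junction,
    parse_event_table,
    parse_sj_file,
)
from .peptides import (
    MHC_I_KMER_SIZES,
    MHC_II_KMER_SIZES,
    IsoformCall,
    junction_kmers,
    locate_breakpoint,
    longest_orf,
    region_residue_range,
    select_best_isoform,
)
from .phbr import (
    EventSummary,
    ExternalRankPredictor,
    HLAGenotype,
    MockRankPredictor,
    PHBRResult,
    load_genotypes,
    sample_phbr,
    summarize_event,
)
from .read_ops import Region, boost_reads, extract_reads

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    events_path: str
    alignments_dir: str
    reference_fasta: str
    genotypes_path: str
    output_dir: str
    normal_sj_dir: Optional[str] = None
    wt_protein_fasta: Optional[str] = None
    mode: str = "junction"  # junction | region
    mhc_class: str = "I"  # I | II
    assembler: str = "builtin"  # builtin | external
    assembler_command: Optional[str] = None
    predictor: str = "mock"  # mock | external
    predictor_command: Optional[str] = None
    predictor_seed: int = 0
    read_boost_factor: int = 1
    flank_length: int = 100
    assembly_k: int = 25
    min_kmer_count: Optional[int] = None
    kmer_sizes: Optional[tuple[int, ...]] = None
    wt_min_reads: int = 1
    min_pct_samples: float = 0.5
    min_pct_oe: float = 0.0
    require_strand_match: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("junction", "region"):
            raise ValueError(f"invalid mode {self.mode!r}")
        if self.mhc_class not in ("I", "II"):
            raise ValueError(f"invalid mhc_class {self.mhc_class!r}")
        if self.read_boost_factor < 1:
            raise ValueError("read_boost_factor must be >= 1")
        required = [self.events_path, self.alignments_dir,
                    self.reference_fasta, self.genotypes_path]
        if self.mode == "junction":
            if self.normal_sj_dir is None:
                raise ValueError("junction mode requires normal_sj_dir")
            required.append(self.normal_sj_dir)
        for path in required:
            if not Path(path).exists():
                raise FileNotFoundError(f"required path does not exist: {path}")
        if self.assembler == "external" and not self.assembler_command:
            raise ValueError("external assembler requires assembler_command")
        if self.predictor == "external" and not self.predictor_command:
            raise ValueError("external predictor requires predictor_command")

    @property
    def sizes(self) -> tuple[int, ...]:
        if self.kmer_sizes:
            return tuple(self.kmer_sizes)
        return MHC_I_KMER_SIZES if self.mhc_class == "I" else MHC_II_KMER_SIZES


@dataclass
class EventResult:
    event: JunctionEvent
    summary: EventSummary
    per_sample: list[PHBRResult] = field(default_factory=list)
    wt_per_sample: list[PHBRResult] = field(default_factory=list)
    exclusions: list[tuple[str, str]] = field(default_factory=list)
    wt_junction_id: Optional[str] = None
    error: Optional[str] = None


@dataclass
class PipelineResult:
    config: RunConfig
    events: list[EventResult]
    candidates: list[CandidateRow]
    manifest: dict


def _flanks(ref: Fasta, event: JunctionEvent, flank: int) -> tuple[str, str]:
    """Reference exonic sequences immediately flanking the intron."""
    chrom = ref[event.chrom]
    up_start = max(0, event.intron_start - 1 - flank)
    upstream = str(chrom[up_start : event.intron_start - 1]).upper()
    downstream = str(chrom[event.intron_end : event.intron_end + flank]).upper()
    return upstream, downstream


def _find_alignment(alignments_dir: Path, sample: str) -> Optional[Path]:
    for ext in (".sam", ".bam", ".cram"):
        path = alignments_dir / f"{sample}{ext}"
        if path.exists():
            return path
    return None


def _make_predictor(config: RunConfig, plants=None, default_rank=None):
    if config.predictor == "mock":
        return MockRankPredictor(
            seed=config.predictor_seed, plants=plants, default_rank=default_rank
        )
    return ExternalRankPredictor(config.predictor_command)


def _assemble(config: RunConfig, reads):
    if config.assembler == "external":
        return run_external_assembler(config.assembler_command, reads)
    return assemble_contigs(
        reads, k=config.assembly_k, min_kmer_count=config.min_kmer_count
    )


def _wt_protein_for(
    event: JunctionEvent,
    proteins: Optional[dict[str, str]],
    ref: Fasta,
    wt_event: Optional[JunctionEvent],
    flank: int,
) -> str:
    """WT protein from the supplied FASTA, else longest-ORF fallback."""
    if proteins and event.gene_symbol and event.gene_symbol in proteins:
        return proteins[event.gene_symbol]
    source = wt_event if wt_event is not None else event
    up, down = _flanks(ref, source, flank)
    protein = longest_orf(up + down)
    if not protein:
        raise ValueError(
            f"no wild-type protein available for event {event.event_id}"
        )
    return protein


def _score_call(
    call: IsoformCall,
    event: JunctionEvent,
    genotype: HLAGenotype,
    predictor,
    config: RunConfig,
    region_residues=None,
) -> tuple[Optional[PHBRResult], Optional[str]]:
    """K-mers + PHBR for a resolved isoform call; returns (result, reason)."""
    if call.excluded:
        return None, call.exclusion_reason
    kmers = junction_kmers(
        call,
        sizes=config.sizes,
        event_id=event.event_id,
        class_mode=config.mhc_class,
        region_residues=region_residues,
    )
    if call.excluded:
        return None, call.exclusion_reason
    result = sample_phbr(kmers, genotype, predictor, class_mode=config.mhc_class)
    return result, None


def _region_residues_for(call: IsoformCall) -> Optional[tuple[int, int]]:
    """Residue interval covered by the region between the two flank anchors."""
    return region_residue_range(call)


def run_pipeline(
    config: RunConfig,
    predictor=None,
) -> PipelineResult:
    """Run the full pipeline; an injected ``predictor`` overrides config."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    events = parse_event_table(config.events_path)
    genotypes = load_genotypes(config.genotypes_path)
    cohort = sorted(genotypes)
    cohort_size = len(cohort)
    ref = Fasta(str(config.reference_fasta))
    if predictor is None:
        predictor = _make_predictor(config)

    proteins: Optional[dict[str, str]] = None
    if config.wt_protein_fasta:
        proteins = {
            name: str(rec[:]).upper()
            for name, rec in Fasta(str(config.wt_protein_fasta)).items()
        }

    normals = []
    if config.mode == "junction":
        sj_dir = Path(config.normal_sj_dir)
        for path in sorted(sj_dir.glob("*")):
            if path.suffix in (".tab", ".tsv") or path.name.endswith("SJ.out.tab"):
                sample = path.name.split(".")[0]
                normals.append(parse_sj_file(path, sample))
        if not normals:
            raise FileNotFoundError(
                f"no SJ.out.tab catalogs found under {sj_dir}"
            )

    results: list[EventResult] = []
    for event in events:
        try:
            results.append(
                _run_event(
                    event, config, ref, proteins, normals, genotypes,
                    cohort, predictor,
                )
            )
        except Exception as exc:  # per-event isolation
            logger.exception("event %s aborted: %s", event.event_id, exc)
            summary = EventSummary(
                event_id=event.event_id,
                ase_avg_phbr=None,
                wt_avg_phbr=None,
                pct_samples=0.0,
                class_mode=config.mhc_class,
                gene_symbol=event.gene_symbol,
                reportable=False,
            )
            results.append(
                EventResult(event=event, summary=summary, error=str(exc))
            )

    candidates = filter_candidates(
        [r.summary for r in results],
        min_pct_samples=config.min_pct_samples,
        min_pct_oe=config.min_pct_oe,
    )

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "n_events": len(results),
        "n_candidates": sum(1 for c in candidates if c.principal),
        "events": {
            r.event.event_id: {
                "wt_junction": r.wt_junction_id,
                "n_scored": len(r.per_sample),
                "exclusions": [
                    {"sample": s, "reason": reason}
                    for s, reason in r.exclusions
                ],
                "error": r.error,
            }
            for r in results
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if candidates:
        write_event_report(candidates, out_dir / "candidates.tsv")
    _write_summaries(results, out_dir / "event_summaries.tsv")
    return PipelineResult(
        config=config, events=results, candidates=candidates, manifest=manifest
    )


def _run_event(
    event: JunctionEvent,
    config: RunConfig,
    ref: Fasta,
    proteins,
    normals,
    genotypes,
    cohort,
    predictor,
) -> EventResult:
    wt_call = None
    wt_event = None
    if config.mode == "junction":
        wt = identify_wt_junction(
            event,
            normals,
            min_reads=config.wt_min_reads,
            require_strand_match=config.require_strand_match,
        )
        if wt.found:
            wt_call, wt_event = wt, wt.wt_junction

    wt_protein = _wt_protein_for(
        event, proteins, ref, wt_event, config.flank_length
    )
    up_flank, down_flank = _flanks(ref, event, config.flank_length)

    per_sample: list[PHBRResult] = []
    exclusions: list[tuple[str, str]] = []
    alignments_dir = Path(config.alignments_dir)
    target = (
        event
        if config.mode == "junction"
        else Region(event.chrom, event.intron_start, event.intron_end)
    )
    for sample in sorted(event.expressing_samples):
        genotype = genotypes.get(sample)
        if genotype is None:
            logger.warning("no genotype for sample %s; skipping", sample)
            continue
        sam_path = _find_alignment(alignments_dir, sample)
        if sam_path is None:
            logger.warning("no alignment file for sample %s; skipping", sample)
            continue
        reads = extract_reads(
            sam_path, target, mode=config.mode, sample_id=sample
        )
        if config.read_boost_factor > 1:
            reads = boost_reads(reads, config.read_boost_factor)
        if not reads.reads:
            exclusions.append((sample, "assembly_failure"))
            continue
        contigs = _assemble(config, reads)
        call = select_best_isoform(contigs, wt_protein, sample_id=sample)
        if not call.excluded:
            call = locate_breakpoint(call, up_flank, down_flank)
        region_residues = (
            _region_residues_for(call) if config.mode == "region" else None
        )
        result, reason = _score_call(
            call, event, genotype, predictor, config,
            region_residues=region_residues,
        )
        if result is None:
            exclusions.append((sample, reason or "unknown"))
        else:
            per_sample.append(result)

    wt_per_sample: list[PHBRResult] = []
    if wt_event is not None:
        wt_up, wt_down = _flanks(ref, wt_event, config.flank_length)
        from .assembly import Contig  # local import to avoid cycle noise

        wt_contig = Contig(
            sample_id="WT",
            sequence=wt_up + wt_down,
            support=wt_call.total_unique_reads,
            assembler_id="reference-flanks",
        )
        wt_isoform = select_best_isoform([wt_contig], wt_protein, sample_id="WT")
        if not wt_isoform.excluded:
            wt_isoform = locate_breakpoint(wt_isoform, wt_up, wt_down)
        if not wt_isoform.excluded:
            wt_kmers = junction_kmers(
                wt_isoform,
                sizes=config.sizes,
                event_id=wt_event.event_id,
                class_mode=config.mhc_class,
            )
            if not wt_isoform.excluded:
                for patient in cohort:
                    wt_kmers.sample_id = patient
                    wt_per_sample.append(
                        sample_phbr(
                            wt_kmers,
                            genotypes[patient],
                            predictor,
                            class_mode=config.mhc_class,
                        )
                    )

    summary = summarize_event(
        per_sample,
        wt_per_sample,
        cohort_size=len(cohort),
        event=event,
        exclusions=exclusions,
        class_mode=config.mhc_class,
        wt_found=wt_event is not None,
    )
    return EventResult(
        event=event,
        summary=summary,
        per_sample=per_sample,
        wt_per_sample=wt_per_sample,
        exclusions=exclusions,
        wt_junction_id=wt_event.event_id if wt_event is not None else None,
    )


def _write_summaries(results: list[EventResult], path: Path) -> None:
    columns = [
        "event_id", "gene_symbol", "class_mode", "ase_avg_phbr", "wt_avg_phbr",
        "binder_class", "best_peptide", "best_allele", "pct_samples",
        "pct_outlier_oe", "wt_junction", "n_samples", "n_excluded",
        "reportable",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for r in results:
            s = r.summary
            fh.write(
                "\t".join(
                    [
                        s.event_id,
                        s.gene_symbol or "",
                        s.class_mode,
                        "NA" if s.ase_avg_phbr is None else f"{s.ase_avg_phbr:.4f}",
                        "NA" if s.wt_avg_phbr is None else f"{s.wt_avg_phbr:.4f}",
                        s.binder_class,
                        s.best_peptide,
                        s.best_allele,
                        f"{s.pct_samples:.4f}",
                        f"{s.pct_outlier_oe:.4f}",
                        r.wt_junction_id or "NA",
                        str(s.n_samples),
                        str(sum(s.exclusions.values())),
                        str(s.reportable),
                    ]
                )
                + "\n"
            )
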