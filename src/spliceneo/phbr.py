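"""Patient harmonic-mean best-rank (PHBR) scoring and binder classes.

Each peptide k-mer is scored against every HLA allele of a patient by a
pluggable binding-rank predictor; per allele the best (minimum) rank is
kept and the harmonic mean of per-allele best ranks is the patient's
PHBR for the event. Homozygous class-I alleles are listed twice and
count twice. Lower PHBR = better presentation.

Classification thresholds (strict on the left, values at a threshold
fall to the weaker class):

* MHC-I: strong < 0.5, weak < 2, otherwise non-binder.
* MHC-II: strong < 1, relevant < 5, otherwise non-binder.
"""

from __future__ import annotations

import hashlib
import logging
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Protocol, Sequence

from .junction_io import JunctionEvent
from .peptides import KmerSet

logger = logging.getLogger(__name__)

RANK_FLOOR = 0.001

MHC_I_THRESHOLDS = (0.5, 2.0)  # strong, weak
MHC_II_THRESHOLDS = (1.0, 5.0)  # strong, relevant

#: Strength order used for differential comparisons.
BINDER_STRENGTH = {"strong": 2, "weak": 1, "relevant": 1, "non": 0}


class PredictorError(RuntimeError):
    """A (peptide, allele) pair could not be scored."""


@dataclass
class HLAGenotype:
    """Patient HLA genotype; homozygous alleles appear twice in class I."""

    patient_id: str
    class1_alleles: list[str] = field(default_factory=list)
    class2_alleles: list[str] = field(default_factory=list)

    def alleles(self, class_mode: str) -> list[str]:
        alleles = self.class1_alleles if class_mode == "I" else self.class2_alleles
        if not alleles:
            raise ValueError(
                f"patient {self.patient_id} has no class {class_mode} alleles"
            )
        if class_mode == "I" and len(alleles) > 6:
            raise ValueError(
                f"patient {self.patient_id}: class I genotype exceeds 6 alleles"
            )
        return alleles


@dataclass
class PHBRResult:
    event_id: str
    sample_id: str
    phbr: float
    best_peptide: str
    best_allele: str
    best_rank: float
    binder_class: str
    class_mode: str = "I"


@dataclass
class EventSummary:
    """Cohort-level aggregation of per-sample PHBR results for one event."""

    event_id: str
    ase_avg_phbr: Optional[float]
    wt_avg_phbr: Optional[float]
    pct_samples: float
    best_peptide: str = ""
    best_allele: str = ""
    binder_class: str = "non"
    class_mode: str = "I"
    gene_symbol: Optional[str] = None
    pct_outlier_oe: float = 0.0
    wt_found: bool = False
    reportable: bool = True
    n_samples: int = 0
    exclusions: dict[str, int] = field(default_factory=dict)


class RankPredictor(Protocol):
    def predict(
        self, peptides: Sequence[str], alleles: Sequence[str]
    ) -> Mapping[tuple[str, str], float]: ...


class MockRankPredictor:
    """Deterministic stand-in for an external binding-rank predictor.

    The rank of an unplanted (peptide, allele) pair is a stable hash of
    the pair (salted with ``seed``) mapped to [0.05, 100], or the
    ``default_rank`` constant when one is given. A plant-override table
    pins chosen pairs to exact ranks for tests.
    """

    def __init__(
        self,
        seed: int = 0,
        plants: Optional[Mapping[tuple[str, str], float]] = None,
        default_rank: Optional[float] = None,
    ):
        self.seed = seed
        self.plants = dict(plants or {})
        for (pep, allele), rank in self.plants.items():
            if rank <= 0:
                raise ValueError(f"planted rank must be > 0 for {(pep, allele)}")
        self.default_rank = default_rank

    def rank(self, peptide: str, allele: str) -> float:
        planted = self.plants.get((peptide, allele))
        if planted is not None:
            return planted
        if self.default_rank is not None:
            return self.default_rank
        digest = hashlib.sha256(
            f"{self.seed}|{peptide}|{allele}".encode()
        ).digest()
        frac = int.from_bytes(digest[:8], "big") / 2**64
        return 0.05 + frac * (100.0 - 0.05)

    def predict(self, peptides, alleles):
        return {
            (p, a): self.rank(p, a) for p in peptides for a in alleles
        }


class ExternalRankPredictor:
    """Adapter for an external predictor executable.

    ``command`` is a template with ``{peptides}``, ``{alleles}`` and
    ``{output}`` placeholders; the adapter writes the peptide list (one
    per line), passes the alleles comma-joined, and parses the tool's
    output as TSV lines ``peptide<TAB>allele<TAB>rank``. A missing pair
    is a hard error (no silent imputation).
    """

    def __init__(self, command: str, timeout: Optional[float] = None):
        for placeholder in ("{peptides}", "{alleles}", "{output}"):
            if placeholder not in command:
                raise ValueError(f"command template must contain {placeholder}")
        self.command = command
        self.timeout = timeout

    def predict(self, peptides, alleles):
        with tempfile.TemporaryDirectory() as tmp:
            pep_path = Path(tmp) / "peptides.txt"
            out_path = Path(tmp) / "ranks.tsv"
            pep_path.write_text("".join(f"{p}\n" for p in peptides))
            cmd = self.command.format(
                peptides=pep_path, alleles=",".join(alleles), output=out_path
            )
            subprocess.run(cmd, shell=True, check=True, timeout=self.timeout)
            table: dict[tuple[str, str], float] = {}
            with open(out_path) as fh:
                for line in fh:
                    if not line.strip():
                        continue
                    pep, allele, rank = line.rstrip("\n").split("\t")[:3]
                    table[(pep, allele)] = float(rank)
        for p in peptides:
            for a in alleles:
                if (p, a) not in table:
                    raise PredictorError(
                        f"predictor returned no rank for peptide {p!r} / "
                        f"allele {a!r}"
                    )
        return table


def compute_phbr(best_ranks: Sequence[float], floor: float = RANK_FLOOR) -> float:
    """Harmonic mean of per-allele best ranks: ``n / sum(1/r_i)``.

    Non-positive ranks are clamped to ``floor`` with a warning to keep
    the harmonic mean finite.
    """
    ranks = list(best_ranks)
    if not ranks:
        raise ValueError("best_ranks must be non-empty")
    clamped = []
    for r in ranks:
        if r <= 0:
            logger.warning("rank %.6g <= 0 clamped to %.3g", r, floor)
            r = floor
        clamped.append(r)
    return len(clamped) / sum(1.0 / r for r in clamped)


def classify_binder(phbr: float, class_mode: str = "I") -> str:
    """Map a PHBR score to its binder class for the given MHC class."""
    if phbr <= 0:
        raise ValueError(f"PHBR must be > 0, got {phbr}")
    if class_mode == "I":
        strong, weak = MHC_I_THRESHOLDS
        middle = "weak"
    elif class_mode == "II":
        strong, weak = MHC_II_THRESHOLDS
        middle = "relevant"
    else:
        raise ValueError(f"class_mode must be 'I' or 'II', got {class_mode!r}")
    if phbr < strong:
        return "strong"
    if phbr < weak:
        return middle
    return "non"


def sample_phbr(
    kmers: KmerSet,
    genotype: HLAGenotype,
    predictor: RankPredictor,
    class_mode: Optional[str] = None,
) -> PHBRResult:
    """Score one sample's k-mer set against one patient genotype.

    Per allele the best rank is the minimum over all k-mers; the PHBR is
    the harmonic mean over the genotype's allele list (homozygous
    duplicates counted twice). The best peptide/allele pair attains the
    global minimum rank, ties broken lexicographically by peptide then
    allele.
    """
    if not kmers.kmers:
        raise ValueError("kmers must be non-empty")
    class_mode = class_mode or kmers.class_mode
    alleles = genotype.alleles(class_mode)
    peptides = sorted(set(kmers.peptides))
    table = predictor.predict(peptides, sorted(set(alleles)))
    for p in peptides:
        for a in alleles:
            if (p, a) not in table:
                raise PredictorError(
                    f"no rank for peptide {p!r} / allele {a!r}"
                )

    per_allele_best = [min(table[(p, a)] for p in peptides) for a in alleles]
    phbr = compute_phbr(per_allele_best)
    best_pep, best_allele = min(
        ((p, a) for p in peptides for a in alleles),
        key=lambda pa: (table[pa], pa[0], pa[1]),
    )
    return PHBRResult(
        event_id=kmers.event_id,
        sample_id=kmers.sample_id,
        phbr=phbr,
        best_peptide=best_pep,
        best_allele=best_allele,
        best_rank=table[(best_pep, best_allele)],
        binder_class=classify_binder(phbr, class_mode),
        class_mode=class_mode,
    )


def summarize_event(
    per_sample: Sequence[PHBRResult],
    wt_per_sample: Sequence[PHBRResult],
    cohort_size: int,
    event: Optional[JunctionEvent] = None,
    exclusions: Iterable[tuple[str, str]] = (),
    class_mode: str = "I",
    wt_found: bool = False,
) -> EventSummary:
    """Aggregate per-sample PHBR results into an event summary.

    The event average is the arithmetic mean over non-excluded expressing
    samples; the WT average is the mean of WT-k-mer PHBR over all tumor
    genotypes. ``pct_samples`` is non-excluded samples / cohort size.
    When every sample is excluded the summary is marked unreportable
    with an exclusion tally.
    """
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    exclusion_tally: dict[str, int] = {}
    for _, reason in exclusions:
        exclusion_tally[reason] = exclusion_tally.get(reason, 0) + 1

    event_id = event.event_id if event is not None else (
        per_sample[0].event_id if per_sample else ""
    )
    summary = EventSummary(
        event_id=event_id,
        ase_avg_phbr=None,
        wt_avg_phbr=None,
        pct_samples=len(per_sample) / cohort_size,
        class_mode=class_mode,
        gene_symbol=event.gene_symbol if event is not None else None,
        pct_outlier_oe=(
            len(event.outlier_overexpressed_samples) / cohort_size
            if event is not None
            else 0.0
        ),
        wt_found=wt_found or bool(wt_per_sample),
        n_samples=len(per_sample),
        exclusions=exclusion_tally,
    )
    if not per_sample:
        summary.reportable = False
        return summary

    summary.ase_avg_phbr = sum(r.phbr for r in per_sample) / len(per_sample)
    summary.binder_class = classify_binder(summary.ase_avg_phbr, class_mode)
    best = min(per_sample, key=lambda r: (r.best_rank, r.best_peptide, r.best_allele))
    summary.best_peptide = best.best_peptide
    summary.best_allele = best.best_allele
    if wt_per_sample:
        summary.wt_avg_phbr = sum(r.phbr for r in wt_per_sample) / len(wt_per_sample)
    return summary


def load_genotypes(path: str | Path) -> dict[str, HLAGenotype]:
    """Read HLA genotypes from a TSV with columns patient_id, class, allele."""
    genotypes: dict[str, HLAGenotype] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["patient_id", "class", "allele"]:
            raise ValueError(
                f"{path}: expected header patient_id<TAB>class<TAB>allele"
            )
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            patient, cls, allele = fields[0], fields[1].upper(), fields[2]
            geno = genotypes.setdefault(patient, HLAGenotype(patient_id=patient))
            if cls == "I":
                geno.class1_alleles.append(allele)
            elif cls == "II":
                geno.class2_alleles.append(allele)
            else:
                raise ValueError(
                    f"{path}: line {lineno}: class must be 'I' or 'II'"
                )
    return genotypes
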