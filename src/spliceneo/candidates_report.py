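"""Principal-candidate filtering, responder differential binding, and reports.

A principal candidate event binds MHC (event average PHBR below the
relevant threshold), has an identified wild-type alternative junction
with a strictly larger average PHBR, occurs in a majority of tumor
samples, and shows outlier overexpression. Responder/nonresponder
comparisons flag events that bind only in responders or bind in a
strictly stronger category there. Loss-of-expression association uses a
two-sided Fisher exact test per event with Benjamini-Hochberg adjustment
across events plus a pooled test on the summed table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .phbr import BINDER_STRENGTH, EventSummary, PHBRResult, classify_binder

logger = logging.getLogger(__name__)


@dataclass
class CandidateRow:
    event_id: str
    ase_phbr: float
    wt_phbr: Optional[float]
    best_peptide_hla: str
    pct_samples: float
    gene_symbol: Optional[str]
    pct_outlier_oe: float
    binder_class: str
    principal: bool


@dataclass
class GroupComparison:
    event_id: str
    responder_avg_phbr: Optional[float]
    nonresponder_avg_phbr: Optional[float]
    responder_best_peptide_hla: str = ""
    gene_symbol: Optional[str] = None
    flags: frozenset[str] = frozenset()
    excluded_samples: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class LossTestResult:
    event_ids: list[str]
    p_values: list[float]
    p_adjusted: list[float]
    tables: list[tuple[tuple[int, int], tuple[int, int]]]
    pooled_table: tuple[tuple[int, int], tuple[int, int]]
    pooled_p: float


def filter_candidates(
    summaries: Sequence[EventSummary],
    min_pct_samples: float = 0.5,
    min_pct_oe: float = 0.0,
) -> list[CandidateRow]:
    """Apply the principal-candidate criteria to event summaries.

    ``principal`` is set exactly for events that (a) classify as binders
    for their MHC class, (b) have a WT alternative whose average PHBR is
    strictly larger, (c) occur in more than ``min_pct_samples`` of the
    cohort, and (d) have outlier overexpression above ``min_pct_oe``.
    Rows are sorted by ascending event PHBR; unreportable summaries are
    skipped.
    """
    rows: list[CandidateRow] = []
    for s in summaries:
        if not s.reportable or s.ase_avg_phbr is None:
            continue
        binder = classify_binder(s.ase_avg_phbr, s.class_mode) != "non"
        principal = (
            binder
            and s.wt_avg_phbr is not None
            and s.wt_avg_phbr > s.ase_avg_phbr
            and s.pct_samples > min_pct_samples
            and s.pct_outlier_oe > min_pct_oe
        )
        rows.append(
            CandidateRow(
                event_id=s.event_id,
                ase_phbr=s.ase_avg_phbr,
                wt_phbr=s.wt_avg_phbr,
                best_peptide_hla=f"{s.best_peptide} {s.best_allele}".strip(),
                pct_samples=s.pct_samples,
                gene_symbol=s.gene_symbol,
                pct_outlier_oe=s.pct_outlier_oe,
                binder_class=s.binder_class,
                principal=principal,
            )
        )
    rows.sort(key=lambda r: (r.ase_phbr, r.event_id))
    return rows


def differential_binding(
    r_avg: float,
    nr_avg: Optional[float],
    class_mode: str = "I",
) -> frozenset[str]:
    """Flags comparing responder vs nonresponder average PHBR.

    ``binder_in_R_only``: responders bind (non-"non" class) while the
    nonresponder average is absent or classifies as non-binding.
    ``stronger_category_in_R``: the responder class is strictly stronger
    under strong > weak/relevant > non.
    """
    if r_avg <= 0:
        raise ValueError("responder average PHBR must be > 0")
    r_class = classify_binder(r_avg, class_mode)
    flags = set()
    if nr_avg is None:
        if r_class != "non":
            flags.add("binder_in_R_only")
        return frozenset(flags)
    nr_class = classify_binder(nr_avg, class_mode)
    if r_class != "non" and nr_class == "non":
        flags.add("binder_in_R_only")
    if BINDER_STRENGTH[r_class] > BINDER_STRENGTH[nr_class]:
        flags.add("stronger_category_in_R")
    return frozenset(flags)


def cohort_group_average(
    per_sample: Sequence[PHBRResult],
    group_members: Iterable[str],
    exclusions: Mapping[str, str] | Iterable[tuple[str, str]] = (),
) -> Optional[float]:
    """Mean PHBR over group members after exclusions; None if all excluded.

    ``exclusions`` maps sample ID to exclusion reason (premature stop,
    short peptide, assembly failure); excluded members never contribute.
    """
    members = set(group_members)
    excluded = dict(exclusions)
    values = [
        r.phbr
        for r in per_sample
        if r.sample_id in members and r.sample_id not in excluded
    ]
    if not values:
        return None
    return sum(values) / len(values)


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Point-probability method: the sum of hypergeometric probabilities of
    all tables (with the observed margins) no more likely than the
    observed one. Degenerate margins give p = 1.
    """
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("table must be a 2x2 array of non-negative counts")
    if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
        logger.info("degenerate margin in %s; p = 1 by convention", arr.tolist())
        return 1.0
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(p)


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values."""
    if len(p_values) == 0:
        return []
    return list(stats.false_discovery_control(np.asarray(p_values), method="bh"))


def loss_association_test(
    loss_matrix: Mapping[str, Mapping[str, str]],
    response: Mapping[str, str],
) -> LossTestResult:
    """Fisher exact + BH over per-event expression-loss tables.

    ``loss_matrix`` maps event id -> {sample id -> "lost" | "maintained"
    | "absent"}; ``response`` maps sample id -> "responder" |
    "nonresponder". "absent" samples are dropped from the table. The
    pooled test sums all per-event tables.
    """
    event_ids = sorted(loss_matrix)
    tables = []
    p_values = []
    pooled = np.zeros((2, 2), dtype=int)
    for event_id in event_ids:
        flags = loss_matrix[event_id]
        table = np.zeros((2, 2), dtype=int)
        for sample, status in flags.items():
            if status == "absent":
                continue
            if status not in ("lost", "maintained"):
                raise ValueError(
                    f"invalid loss flag {status!r} for {event_id}/{sample}"
                )
            group = response.get(sample)
            if group not in ("responder", "nonresponder"):
                raise ValueError(f"no response label for sample {sample!r}")
            row = 0 if status == "lost" else 1
            col = 0 if group == "responder" else 1
            table[row, col] += 1
        pooled += table
        tables.append(((int(table[0, 0]), int(table[0, 1])),
                       (int(table[1, 0]), int(table[1, 1]))))
        p_values.append(fisher_exact_two_sided(table))
    return LossTestResult(
        event_ids=event_ids,
        p_values=p_values,
        p_adjusted=benjamini_hochberg(p_values),
        tables=tables,
        pooled_table=(
            (int(pooled[0, 0]), int(pooled[0, 1])),
            (int(pooled[1, 0]), int(pooled[1, 1])),
        ),
        pooled_p=fisher_exact_two_sided(pooled),
    )


def _fmt_pct(value: float) -> str:
    text = f"{100 * value:.1f}".rstrip("0").rstrip(".")
    return f"{text}%"


def _fmt_phbr(value: Optional[float]) -> str:
    return "NA" if value is None else f"{value:.2f}"


CANDIDATE_COLUMNS = [
    "event_id",
    "ase_phbr",
    "wt_phbr",
    "best_peptide_hla",
    "pct_samples",
    "gene_symbol",
    "pct_outlier_oe",
]

COMPARISON_COLUMNS = [
    "event_id",
    "responder_phbr",
    "responder_best_peptide_hla",
    "nonresponder_phbr",
    "gene_symbol",
]


def write_event_report(
    rows: Sequence[CandidateRow] | Sequence[GroupComparison],
    path: str | Path,
) -> None:
    """Write candidate or comparison rows as a fixed-layout TSV.

    Candidate rows yield the 7-column candidate layout; group
    comparisons yield the 5-column responder/nonresponder layout. PHBR
    values are printed to 2 decimals; absent values print as NA. Rows
    must be non-empty and of a single type.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("rows must be non-empty")
    with open(path, "w") as fh:
        if isinstance(rows[0], CandidateRow):
            fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
            for r in rows:
                fh.write(
                    "\t".join(
                        [
                            r.event_id,
                            _fmt_phbr(r.ase_phbr),
                            _fmt_phbr(r.wt_phbr),
                            r.best_peptide_hla,
                            _fmt_pct(r.pct_samples),
                            r.gene_symbol or "",
                            _fmt_pct(r.pct_outlier_oe),
                        ]
                    )
                    + "\n"
                )
        elif isinstance(rows[0], GroupComparison):
            fh.write("\t".join(COMPARISON_COLUMNS) + "\n")
            for r in rows:
                fh.write(
                    "\t".join(
                        [
                            r.event_id,
                            _fmt_phbr(r.responder_avg_phbr),
                            r.responder_best_peptide_hla,
                            _fmt_phbr(r.nonresponder_avg_phbr),
                            r.gene_symbol or "",
                        ]
                    )
                    + "\n"
                )
        else:
            raise TypeError(f"unsupported row type {type(rows[0]).__name__}")
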