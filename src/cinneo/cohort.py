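"""Cohort-level descriptive statistics over the per-sample summary table.

Carrier frequencies use the whole group as denominator, including samples
whose HLA typing is unavailable — the convention the per-stage frequencies
are quoted under. Wildcard alleles (unresolved second field, e.g. "67:*")
match no specific four-digit allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .variants import CohortTable, ValidatedNeoantigenRow, _expand_groups

__all__ = [
    "OverlapReport",
    "hla_carrier_frequency",
    "burden_summary",
    "mutation_neoantigen_correlation",
    "db_overlap",
]

SOURCE_PRECEDENCE = ("TSNAdb-CESC", "IEDB", "CTAs")


def hla_carrier_frequency(
    ct: CohortTable, locus: str, allele: str, groups
) -> float:
    """Percentage of group samples carrying an exact four-digit allele.

    Each sample counts once however many copies it carries; untyped
    samples stay in the denominator.
    """
    if locus not in ("A", "B", "C"):
        raise ValueError(f"locus must be A, B or C, got {locus!r}")
    wanted = _expand_groups(groups)
    known = {"CIN1", "CIN2", "CIN3", "CC"}
    if not wanted <= known:
        raise ValueError(f"unknown group(s) {sorted(wanted - known)}")
    members = [r for r in ct if r.meta.group in wanted]
    if not members:
        raise ValueError(f"no samples in groups {sorted(wanted)}")
    carriers = sum(allele in r.meta.alleles(locus) for r in members)
    return 100.0 * carriers / len(members)


@dataclass(frozen=True)
class BurdenSummary:
    mean: float
    median: float
    min: int
    max: int
    n: int


def burden_summary(ct: CohortTable, groups, which: str) -> BurdenSummary:
    """Mean/median/min/max of a count column over a group subset.

    ``which`` is ``"n_neoantigens"`` or ``"n_nonsynonymous"``. The mean is
    reported to full precision; round to one decimal for display.
    """
    if which not in ("n_neoantigens", "n_nonsynonymous"):
        raise ValueError(f"unknown field {which!r}")
    rows = ct.subset(groups).rows
    if not rows:
        raise ValueError(f"empty group {groups!r}")
    vals = np.array([getattr(r, which) for r in rows])
    return BurdenSummary(
        mean=float(vals.mean()),
        median=float(np.median(vals)),
        min=int(vals.min()),
        max=int(vals.max()),
        n=len(vals),
    )


def mutation_neoantigen_correlation(ct: CohortTable) -> tuple:
    """Pearson correlation (r, p) between mutation and neoantigen counts."""
    if len(ct) < 3:
        raise ValueError("need at least 3 samples")
    x = np.array([r.n_nonsynonymous for r in ct], dtype=float)
    y = np.array([r.n_neoantigens for r in ct], dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined: zero variance")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class OverlapReport:
    """Counts of candidates matched per external validation source."""

    by_source: dict = field(default_factory=dict)
    proteins_by_source: dict = field(default_factory=dict)
    distinct_proteins: int = 0

    @property
    def total(self) -> int:
        return sum(self.by_source.values())


def db_overlap(
    candidates: Sequence,
    source_lists: Mapping[str, Iterable],
    precedence: Sequence[str] = SOURCE_PRECEDENCE,
) -> OverlapReport:
    """Count candidates matched by each external source.

    Peptide-sequence exact match for epitope databases; protein-symbol
    membership for the cancer/testis-antigen list. A candidate matching
    several sources is assigned to the first in ``precedence``, keeping
    the per-source counts disjoint. Candidates need ``peptide`` and a
    protein symbol (``protein`` or ``gene`` attribute).
    """
    sets = {k: set(v) for k, v in source_lists.items()}
    report = OverlapReport(
        by_source={k: 0 for k in precedence if k in sets},
        proteins_by_source={k: set() for k in precedence if k in sets},
    )
    all_proteins = set()
    for c in candidates:
        protein = getattr(c, "protein", "") or getattr(c, "gene", "")
        for source in precedence:
            if source not in sets:
                continue
            matched = (
                protein in sets[source] if source == "CTAs" else c.peptide in sets[source]
            )
            if matched:
                report.by_source[source] += 1
                report.proteins_by_source[source].add(protein)
                all_proteins.add(protein)
                break
    report.distinct_proteins = len(all_proteins)
    return report


def sources_from_validated_rows(rows: Sequence[ValidatedNeoantigenRow]) -> dict:
    """Build db_overlap source lists out of annotated validated rows."""
    out = {"TSNAdb-CESC": set(), "IEDB": set(), "CTAs": set()}
    for r in rows:
        if r.validated_source == "CTAs":
            out["CTAs"].add(r.protein)
        else:
            out[r.validated_source].add(r.peptide)
    return out
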