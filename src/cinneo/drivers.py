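"""Driver-gene enumeration by strict recurrence rules.

Small cohorts cannot power background-model driver tests, so genes are
called drivers by enumeration: a gene qualifies iff it is (I) mutated in a
minimum number of distinct samples, (II) a member of a curated driver
catalog, and (III) carries at least one mutation that is truncating or
voted deleterious by two of three effect predictors (SIFT, PolyPhen-2,
MutationTaster). Genes one sample short of rule I are surfaced separately
as near-threshold candidates rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "PredictorCalls",
    "DriverCallConfig",
    "DriverCall",
    "deleteriousness_vote",
    "enumerate_drivers",
    "parse_predictor_cell",
]

# SIFT: D deleterious (score <= 0.05), T tolerated.
# PolyPhen-2 (HVAR): D probably damaging (>= 0.909), P possibly damaging, B benign.
# MutationTaster: A disease_causing_automatic, D disease_causing, N/P polymorphism.
SIFT_DELETERIOUS_MAX = 0.05
POLYPHEN_DAMAGING_MIN = 0.909


@dataclass(frozen=True)
class PredictorCalls:
    """Effect-predictor categories (and optional scores) for one mutation."""

    sift_score: Optional[float] = None
    sift_cat: Optional[str] = None            # {"D", "T"}
    polyphen_score: Optional[float] = None
    polyphen_cat: Optional[str] = None        # {"D", "P", "B"}
    mutation_taster_cat: Optional[str] = None  # {"A", "D", "N", "P"}
    is_truncating: bool = False

    def __post_init__(self):
        if self.sift_score is not None and self.sift_cat is not None:
            expect = "D" if self.sift_score <= SIFT_DELETERIOUS_MAX else "T"
            if self.sift_cat != expect:
                raise ValueError(
                    f"SIFT category {self.sift_cat} inconsistent with score {self.sift_score}"
                )
        if self.polyphen_score is not None and self.polyphen_cat == "D":
            if self.polyphen_score < POLYPHEN_DAMAGING_MIN:
                raise ValueError(
                    f"PolyPhen D category inconsistent with score {self.polyphen_score}"
                )


def parse_predictor_cell(cell: str) -> tuple:
    """Parse a 'score(CAT)' annotation cell; '.' or '' means no call."""
    cell = cell.strip()
    if cell in (".", "", "–", "-"):
        return None, None
    if "(" in cell:
        score, cat = cell.rstrip(")").split("(")
        return float(score), cat
    return float(cell), None


def deleteriousness_vote(
    p: PredictorCalls, count_polyphen_possibly: bool = False
) -> bool:
    """True iff the mutation is truncating or voted deleterious 2-of-3.

    Deleterious votes: SIFT category D; PolyPhen category D (and P only if
    ``count_polyphen_possibly``); MutationTaster category A or D. A
    mutation with no predictor call and no truncating flag is
    indeterminate and fails.
    """
    if p.is_truncating:
        return True
    votes = 0
    if p.sift_cat == "D":
        votes += 1
    damaging = ("D", "P") if count_polyphen_possibly else ("D",)
    if p.polyphen_cat in damaging:
        votes += 1
    if p.mutation_taster_cat in ("A", "D"):
        votes += 1
    return votes >= 2


@dataclass(frozen=True)
class DriverCallConfig:
    min_cases: int = 3
    driver_catalog: frozenset = frozenset()
    count_polyphen_possibly: bool = False

    def __post_init__(self):
        if self.min_cases < 1:
            raise ValueError("min_cases must be >= 1")


@dataclass
class DriverCall:
    """One reported gene with its supporting evidence."""

    gene: str
    n_cases: int
    samples: list = field(default_factory=list)
    n_deleterious: int = 0
    in_catalog: bool = True


def enumerate_drivers(
    mutations: Sequence[Mapping], cfg: DriverCallConfig
) -> tuple:
    """Apply rules I-III over per-mutation records.

    Each record needs keys ``gene``, ``sample_id`` and ``predictor``
    (a :class:`PredictorCalls`). Returns ``(drivers, near_threshold)``:
    drivers satisfy rules I-III strictly; the near-threshold report
    surfaces genes with a qualifying mutation at exactly
    ``min_cases - 1`` distinct samples whatever their catalog status
    (``in_catalog`` records it), so recurrence just under the bar is
    never silently lost. Ordering is case count descending then gene
    symbol ascending, stable across runs.
    """
    if not cfg.driver_catalog:
        raise ValueError("driver catalog is empty; configuration error")
    by_gene: dict = {}
    for m in mutations:
        by_gene.setdefault(m["gene"], []).append(m)

    drivers, near = [], []
    for gene in sorted(by_gene):
        muts = by_gene[gene]
        samples = sorted({m["sample_id"] for m in muts})
        n_del = sum(
            deleteriousness_vote(m["predictor"], cfg.count_polyphen_possibly)
            for m in muts
        )
        if n_del < 1:
            continue
        call = DriverCall(
            gene=gene,
            n_cases=len(samples),
            samples=samples,
            n_deleterious=n_del,
            in_catalog=gene in cfg.driver_catalog,
        )
        if len(samples) >= cfg.min_cases and call.in_catalog:
            drivers.append(call)
        elif len(samples) == cfg.min_cases - 1:
            near.append(call)
    key = lambda c: (-c.n_cases, c.gene)
    return sorted(drivers, key=key), sorted(near, key=key)
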