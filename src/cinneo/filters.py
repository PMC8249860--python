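"""Four-criterion tumor/normal read-support filter and consequence retention.

A call survives only when all four criteria hold:

  I.   tumor depth >= 14 and matched-normal depth >= 8
  II.  >= 5 reads supporting the alternate allele in the tumor
  III. tumor VAF >= 5% and normal VAF < 3%
  IV.  tumor VAF at least four-fold the normal VAF

Comparison strictness follows the criteria's wording: "no less than" is
inclusive, "less than 3%" is strict, "four-fold or more" is inclusive.
A normal VAF of exactly zero satisfies criterion IV outright — zero
contamination in the control is the strongest evidence of somatic origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .variants import Variant

__all__ = [
    "FilterThresholds",
    "FilterResult",
    "ClassTally",
    "passes_read_support",
    "apply_read_support_filter",
    "retain_consequences",
    "tally_classes",
    "RETAINED_CONSEQUENCES",
]

RETAINED_CONSEQUENCES = frozenset({"missense", "nonsense", "frameshift", "splice_site"})


@dataclass(frozen=True)
class FilterThresholds:
    min_tumor_depth: int = 14
    min_normal_depth: int = 8
    min_tumor_alt: int = 5
    min_tumor_vaf: float = 0.05
    max_normal_vaf: float = 0.03
    min_vaf_fold: float = 4.0

    def __post_init__(self):
        vals = (
            self.min_tumor_depth,
            self.min_normal_depth,
            self.min_tumor_alt,
            self.min_tumor_vaf,
            self.max_normal_vaf,
            self.min_vaf_fold,
        )
        if any(v < 0 for v in vals):
            raise ValueError("thresholds must be nonnegative")
        if self.min_tumor_vaf <= self.max_normal_vaf:
            raise ValueError("min_tumor_vaf must exceed max_normal_vaf")


@dataclass(frozen=True)
class FilterResult:
    """Overall verdict plus one flag per criterion (True = criterion met)."""

    depth_ok: bool       # criterion I
    alt_count_ok: bool   # criterion II
    vaf_ok: bool         # criterion III
    fold_ok: bool        # criterion IV

    @property
    def passed(self) -> bool:
        return self.depth_ok and self.alt_count_ok and self.vaf_ok and self.fold_ok


def passes_read_support(v: Variant, t: FilterThresholds = FilterThresholds()) -> FilterResult:
    """Evaluate the four read-support criteria on one variant."""
    if v.tumor_depth == 0:
        raise ValueError(f"invalid record at {v.chrom}:{v.pos}: zero tumor depth")
    tumor_vaf = v.tumor_alt / v.tumor_depth
    normal_vaf = v.normal_alt / v.normal_depth if v.normal_depth else 0.0

    depth_ok = v.tumor_depth >= t.min_tumor_depth and v.normal_depth >= t.min_normal_depth
    alt_ok = v.tumor_alt >= t.min_tumor_alt
    vaf_ok = tumor_vaf >= t.min_tumor_vaf and normal_vaf < t.max_normal_vaf
    fold_ok = normal_vaf == 0.0 or tumor_vaf >= t.min_vaf_fold * normal_vaf
    return FilterResult(depth_ok, alt_ok, vaf_ok, fold_ok)


def apply_read_support_filter(
    variants: Iterable[Variant], t: FilterThresholds = FilterThresholds()
) -> tuple:
    """Split variants into (passing, failing-with-results).

    Returns ``(passed, failed)`` where ``failed`` pairs each rejected
    variant with its per-criterion :class:`FilterResult` so stage reports
    can attribute every drop to a criterion.
    """
    passed, failed = [], []
    for v in variants:
        res = passes_read_support(v, t)
        (passed if res.passed else failed).append((v, res) if not res.passed else v)
    return passed, failed


def retain_consequences(variants: Sequence[Variant]) -> tuple:
    """Keep missense / nonsense / frameshift / splice-site calls only.

    Synonymous, intronic, in-frame-indel and other classes are dropped;
    variants with no assigned consequence go to a quarantine list rather
    than being silently discarded. Returns ``(retained, quarantined)``.
    """
    retained, quarantined = [], []
    for v in variants:
        if not v.consequence:
            quarantined.append(v)
        elif v.consequence in RETAINED_CONSEQUENCES:
            retained.append(v)
    return retained, quarantined


@dataclass
class ClassTally:
    """Mutation counts per functional class plus the non-silent total."""

    nonsynonymous_snv: int = 0
    synonymous_snv: int = 0
    nonsense: int = 0
    splice_site: int = 0
    frameshift: int = 0
    inframe_indel: int = 0
    other: int = 0
    n_genes: int = 0
    genes: set = field(default_factory=set)

    @property
    def non_silent(self) -> int:
        return self.nonsynonymous_snv + self.nonsense + self.splice_site + self.frameshift

    @property
    def total(self) -> int:
        return (
            self.nonsynonymous_snv
            + self.synonymous_snv
            + self.nonsense
            + self.splice_site
            + self.frameshift
            + self.inframe_indel
            + self.other
        )


_TALLY_FIELD = {
    "missense": "nonsynonymous_snv",
    "synonymous": "synonymous_snv",
    "nonsense": "nonsense",
    "splice_site": "splice_site",
    "frameshift": "frameshift",
    "inframe_indel": "inframe_indel",
}


def tally_classes(variants: Iterable[Variant]) -> ClassTally:
    """Count variants per consequence class and distinct mutated genes."""
    tally = ClassTally()
    for v in variants:
        attr = _TALLY_FIELD.get(v.consequence, "other")
        setattr(tally, attr, getattr(tally, attr) + 1)
        if v.gene:
            tally.genes.add(v.gene)
    tally.n_genes = len(tally.genes)
    return tally
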