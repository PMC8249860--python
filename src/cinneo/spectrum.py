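"""Six-class substitution spectrum and 96-trinucleotide-context catalogs.

Substitutions with a purine (A/G) reference base are reverse-complemented
onto the pyrimidine strand, so the six reported classes are C>A, C>G, C>T,
T>A, T>C and T>G; flanking bases are complemented and swapped accordingly.
The 96-category ordering is class-major, then 5' flank A/C/G/T, then 3'
flank A/C/G/T — the ordering external signature matrices export — so those
matrices load without any remapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .variants import Variant

__all__ = [
    "SIX_CLASSES",
    "CONTEXT_LABELS",
    "MutationCatalog",
    "StageSpectrum",
    "classify_substitution",
    "context_index",
    "build_catalog",
    "stage_spectra",
    "stage_trend",
]

SIX_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: 96 context labels, e.g. "A[C>A]A", in class-major order.
CONTEXT_LABELS = tuple(
    f"{l}[{cls}]{r}" for cls in SIX_CLASSES for l in _BASES for r in _BASES
)

STAGES = ("CIN1", "CIN2", "CIN3", "CC")


class UnclassifiableBase(ValueError):
    """Raised for non-ACGT bases; callers count these, they never crash."""


def classify_substitution(ref: str, alt: str, left: str, right: str) -> tuple:
    """Map a strand-specific SNV to its (six-class label, 96-context index)."""
    for b in (ref, alt, left, right):
        if b not in _COMPLEMENT:
            raise UnclassifiableBase(f"non-ACGT base {b!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref in "AG":  # purine reference: fold onto the pyrimidine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        left, right = _COMPLEMENT[right], _COMPLEMENT[left]
    cls = f"{ref}>{alt}"
    idx = SIX_CLASSES.index(cls) * 16 + _BASES.index(left) * 4 + _BASES.index(right)
    return cls, idx


def context_index(label: str) -> int:
    return CONTEXT_LABELS.index(label)


@dataclass
class MutationCatalog:
    """Per-sample substitution counts over 6 classes and 96 contexts."""

    sample_id: str
    context96: np.ndarray = field(default_factory=lambda: np.zeros(96, dtype=np.int64))
    n_unclassifiable: int = 0

    @property
    def six_class(self) -> dict:
        by_class = self.context96.reshape(6, 16).sum(axis=1)
        return dict(zip(SIX_CLASSES, by_class.tolist()))

    @property
    def n_classified(self) -> int:
        return int(self.context96.sum())

    def add(self, ref: str, alt: str, left: str, right: str) -> None:
        _, idx = classify_substitution(ref, alt, left, right)
        self.context96[idx] += 1

    def probabilities(self) -> np.ndarray:
        total = self.context96.sum()
        if total == 0:
            raise ValueError("empty catalog has no context distribution")
        return self.context96 / total


def build_catalog(
    variants: Iterable[Variant], reference: Mapping[str, str], sample_id: str = ""
) -> MutationCatalog:
    """Count a sample's SNVs into a 96-context catalog.

    ``reference`` maps contig id to its sequence. Indels are skipped; SNVs
    at contig ends (no flank) or with non-ACGT context go to the
    unclassifiable bucket. A mismatch between a variant's REF allele and
    the reference sequence is a hard error — it means the catalog would be
    built against the wrong genome.
    """
    cat = MutationCatalog(sample_id=sample_id)
    for v in variants:
        if v.variant_class != "SNV":
            continue
        seq = reference[v.chrom]
        i = v.pos - 1  # 1-based closed -> 0-based
        ref_base = seq[i].upper()
        if ref_base != v.ref.upper():
            raise ValueError(
                f"reference mismatch at {v.chrom}:{v.pos}: "
                f"variant REF {v.ref} vs sequence {ref_base}"
            )
        if i == 0 or i == len(seq) - 1:
            cat.n_unclassifiable += 1
            continue
        try:
            cat.add(v.ref.upper(), v.alt.upper(), seq[i - 1].upper(), seq[i + 1].upper())
        except UnclassifiableBase:
            cat.n_unclassifiable += 1
    return cat


@dataclass
class StageSpectrum:
    """Pooled six-class proportions for one stage group."""

    group: str
    proportions: dict  # class label -> fraction, summing to 1

    def __post_init__(self):
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, not 1")


def stage_spectra(
    catalogs_by_group: Mapping[str, Sequence[MutationCatalog]],
    per_sample_average: bool = False,
) -> list:
    """Six-class proportions per stage, pooling counts across samples.

    Pooling (the default) sums counts over a group's samples before
    normalizing, giving one percentage per stage; ``per_sample_average``
    instead averages each sample's own proportions.
    Groups with no classified SNV are reported as missing (skipped).
    """
    out = []
    for group, cats in catalogs_by_group.items():
        if per_sample_average:
            rows = [c.context96.reshape(6, 16).sum(axis=1) for c in cats if c.n_classified]
            if not rows:
                continue
            props = np.mean([r / r.sum() for r in rows], axis=0)
        else:
            pooled = np.sum([c.context96 for c in cats], axis=0).reshape(6, 16).sum(axis=1)
            if pooled.sum() == 0:
                continue
            props = pooled / pooled.sum()
        out.append(StageSpectrum(group, dict(zip(SIX_CLASSES, props.tolist()))))
    return out


def stage_trend(spectra: Sequence[StageSpectrum], order: Sequence[str] = STAGES) -> dict:
    """Classify each substitution class as increasing/decreasing/non-monotonic
    across the ordered stages.

    Increasing means weakly increasing step-to-step with a strict overall
    rise; decreasing is symmetric. Everything else (including constant) is
    non-monotonic. All stages must be present.
    """
    by_group = {s.group: s for s in spectra}
    missing = [g for g in order if g not in by_group]
    if missing:
        raise ValueError(f"trend undefined: missing stages {missing}")
    trend = {}
    for cls in SIX_CLASSES:
        vals = [by_group[g].proportions[cls] for g in order]
        diffs = np.diff(vals)
        if np.all(diffs >= 0) and vals[-1] > vals[0]:
            trend[cls] = "increasing"
        elif np.all(diffs <= 0) and vals[-1] < vals[0]:
            trend[cls] = "decreasing"
        else:
            trend[cls] = "non-monotonic"
    return trend
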