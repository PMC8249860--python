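"""Mutant-peptide construction, 8-11mer enumeration and binding thresholds.

Each coding missense SNV is expanded into a peptide context of up to 22
residues around the altered amino acid (10 upstream + site + 11 downstream
— exact centering of an even-length window is impossible; the choice never
changes the set of mutation-covering 8-11mers at interior sites). Frameshift
indels contribute the novel translated tail from the shift point to the
first stop, preceded by up to 10 wild-type residues. Sliding windows of
length 8-11 that cover at least one altered/novel residue are scored
against the patient's HLA class I alleles by a pluggable predictor, and
candidates are retained under strict IC50 < 500 nM and %Rank < 2 rules,
optionally annotated with a tumor-expression flag
(tumor FPKM >= 0.5 and |log2(tumor/normal)| >= 0.1).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio.Seq import Seq

from .variants import Variant

__all__ = [
    "TranscriptModel",
    "MutantPeptideSet",
    "SkipRecord",
    "BindingPrediction",
    "NeoantigenCandidate",
    "MockBindingPredictor",
    "NetMHCpanOutputAdapter",
    "mutant_context_peptide",
    "frameshift_peptides",
    "enumerate_windows",
    "predict_binding",
    "call_neoantigens",
    "count_neoantigens",
    "expression_filter",
]

UPSTREAM_CONTEXT = 10
DOWNSTREAM_CONTEXT = 11
WINDOW_LENGTHS = (8, 9, 10, 11)


def _translate(nt: str) -> str:
    return str(Seq(nt[: len(nt) - len(nt) % 3]).translate())


@dataclass
class TranscriptModel:
    """A coding transcript: CDS intervals on the reference plus its sequence.

    ``cds_ranges`` are 1-based closed intervals in genomic order; for minus
    -strand transcripts the cached ``cds_seq`` is the reverse complement of
    the concatenated reference slices. The CDS includes the stop codon.
    """

    transcript_id: str
    gene: str
    chrom: str
    strand: str
    cds_ranges: list  # [(start, end)], 1-based closed
    cds_seq: str = ""

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.cds_seq:
            self.validate()

    @classmethod
    def from_reference(cls, transcript_id, gene, chrom, strand, cds_ranges, reference):
        seq = "".join(
            reference[chrom][s - 1 : e] for s, e in sorted(cds_ranges)
        ).upper()
        if strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return cls(transcript_id, gene, chrom, strand, sorted(cds_ranges), seq)

    def validate(self):
        if len(self.cds_seq) % 3 != 0:
            raise ValueError(f"{self.transcript_id}: CDS length not divisible by 3")
        prot = _translate(self.cds_seq)
        if "*" in prot[:-1]:
            raise ValueError(f"{self.transcript_id}: internal stop codon")

    @property
    def protein(self) -> str:
        return _translate(self.cds_seq).rstrip("*")

    def cds_offset(self, pos: int) -> int:
        """0-based offset within the CDS of a genomic position."""
        off = 0
        for s, e in self.cds_ranges:
            if s <= pos <= e:
                off += pos - s
                break
            off += e - s + 1
        else:
            raise ValueError(f"position {pos} outside CDS of {self.transcript_id}")
        if self.strand == "-":
            total = sum(e - s + 1 for s, e in self.cds_ranges)
            off = total - 1 - off
        return off


@dataclass
class SkipRecord:
    """Why a variant produced no peptide context (never a silent drop)."""

    variant: Variant
    reason: str


@dataclass
class MutantPeptideSet:
    """Mutant peptide context for one variant, with altered residues marked."""

    variant: Variant
    wt_context: str
    mut_context: str
    mutated_indices: frozenset  # 0-based indices into mut_context

    def __post_init__(self):
        if len(self.mut_context) > 22 and self.variant.variant_class == "SNV":
            raise ValueError("SNV context exceeds 22 residues")

    @property
    def mut_index_1based(self) -> int:
        return min(self.mutated_indices) + 1


def _apply_snv(tm: TranscriptModel, v: Variant) -> str:
    off = tm.cds_offset(v.pos)
    ref, alt = v.ref.upper(), v.alt.upper()
    if tm.strand == "-":
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        ref, alt = comp[ref], comp[alt]
    if tm.cds_seq[off] != ref:
        raise ValueError(f"REF mismatch at CDS offset {off} of {tm.transcript_id}")
    return tm.cds_seq[:off] + alt + tm.cds_seq[off + 1 :], off


def mutant_context_peptide(tm: TranscriptModel, v: Variant):
    """Context peptide for a coding missense SNV.

    Returns a :class:`MutantPeptideSet`, or a :class:`SkipRecord` when the
    variant maps to a stop codon, is synonymous at protein level, or falls
    outside the CDS.
    """
    if v.variant_class != "SNV":
        raise ValueError("mutant_context_peptide handles SNVs only")
    try:
        mut_cds, off = _apply_snv(tm, v)
    except ValueError as exc:
        return SkipRecord(v, str(exc))
    pi = off // 3
    wt_prot = tm.protein
    mut_prot = _translate(mut_cds).rstrip("*")
    if pi >= len(wt_prot):
        return SkipRecord(v, "maps to the stop codon")
    mut_aa = _translate(mut_cds[pi * 3 : pi * 3 + 3])
    if mut_aa == "*":
        return SkipRecord(v, "creates a stop codon (nonsense)")
    if mut_aa == wt_prot[pi]:
        return SkipRecord(v, "synonymous at protein level")
    start = max(0, pi - UPSTREAM_CONTEXT)
    end = min(len(wt_prot), pi + DOWNSTREAM_CONTEXT + 1)
    return MutantPeptideSet(
        variant=v,
        wt_context=wt_prot[start:end],
        mut_context=mut_prot[start:end],
        mutated_indices=frozenset({pi - start}),
    )


def _apply_indel(tm: TranscriptModel, v: Variant) -> tuple:
    """Apply a VCF-anchored indel to the CDS; returns (mut_cds, shift_offset)."""
    if tm.strand == "-":
        raise NotImplementedError("indel application implemented for + strand CDS")
    off = tm.cds_offset(v.pos)
    ref, alt = v.ref.upper(), v.alt.upper()
    if tm.cds_seq[off : off + len(ref)] != ref:
        raise ValueError(f"REF mismatch at CDS offset {off} of {tm.transcript_id}")
    mut = tm.cds_seq[:off] + alt + tm.cds_seq[off + len(ref) :]
    # first base actually altered: the anchor base is shared
    return mut, off + 1


def frameshift_peptides(tm: TranscriptModel, v: Variant):
    """Novel-tail context for a coding frameshift indel.

    The shifted frame is translated from the indel codon to the first stop
    (or CDS end); the novel tail plus up to 10 preceding wild-type
    residues form the context, every tail residue marked novel. In-frame
    indels are routed to a substitution-like context around the junction
    instead of frameshift logic.
    """
    if v.variant_class not in ("insertion", "deletion"):
        raise ValueError("frameshift_peptides handles indels only")
    try:
        mut_cds, shift_off = _apply_indel(tm, v)
    except ValueError as exc:
        return SkipRecord(v, str(exc))

    wt_prot = tm.protein
    frame_shift = (len(v.alt) - len(v.ref)) % 3
    if frame_shift == 0:
        return _inframe_context(tm, v, mut_cds)

    shift_codon = shift_off // 3
    mut_prot_full = _translate(mut_cds)
    stop = mut_prot_full.find("*", shift_codon)
    tail = mut_prot_full[shift_codon : stop if stop != -1 else len(mut_prot_full)]
    if not tail:
        return SkipRecord(v, "immediate stop after frameshift")
    start = max(0, shift_codon - UPSTREAM_CONTEXT)
    upstream = wt_prot[start:shift_codon]
    context = upstream + tail
    return MutantPeptideSet(
        variant=v,
        wt_context=wt_prot[start : shift_codon + len(tail)],
        mut_context=context,
        mutated_indices=frozenset(range(len(upstream), len(context))),
    )


def _inframe_context(tm: TranscriptModel, v: Variant, mut_cds: str):
    wt_prot = tm.protein
    mut_prot = _translate(mut_cds).rstrip("*")
    # first differing residue marks the junction
    pj = next(
        (i for i, (a, b) in enumerate(zip(mut_prot, wt_prot)) if a != b),
        min(len(mut_prot), len(wt_prot)),
    )
    if pj >= len(mut_prot):
        return SkipRecord(v, "in-frame indel leaves no altered residue")
    start = max(0, pj - UPSTREAM_CONTEXT)
    end = min(len(mut_prot), pj + DOWNSTREAM_CONTEXT + 1)
    return MutantPeptideSet(
        variant=v,
        wt_context=wt_prot[start : min(len(wt_prot), end)],
        mut_context=mut_prot[start:end],
        mutated_indices=frozenset({pj - start}),
    )


def enumerate_windows(
    mp: MutantPeptideSet, lengths: Sequence[int] = WINDOW_LENGTHS
) -> list:
    """All 8-11mer windows of the context covering an altered residue.

    Deduplicated by peptide sequence; deterministic order (length
    ascending, start ascending). A context shorter than the smallest
    window length yields an empty list.
    """
    ctx = mp.mut_context
    seen, out = set(), []
    for k in sorted(lengths):
        for s in range(0, len(ctx) - k + 1):
            if any(s <= i < s + k for i in mp.mutated_indices):
                pep = ctx[s : s + k]
                if pep not in seen:
                    seen.add(pep)
                    out.append(pep)
    return out


@dataclass(frozen=True)
class BindingPrediction:
    peptide: str
    hla_allele: str
    ic50_nM: float
    rank_pct: float

    def __post_init__(self):
        if self.ic50_nM <= 0:
            raise ValueError("ic50 must be positive")
        if not 0 < self.rank_pct <= 100:
            raise ValueError("rank_pct outside (0, 100]")


class MockBindingPredictor:
    """Deterministic stand-in predictor driven by keyed hashing.

    Scores derive from a SHA-256 digest of (seed, peptide, allele), so a
    given pair always scores identically regardless of batch order, and a
    configurable fraction of pairs falls under both binder thresholds.
    """

    def __init__(self, seed: int = 0, binder_fraction: float = 0.2):
        if not 0 <= binder_fraction <= 1:
            raise ValueError("binder_fraction must lie in [0, 1]")
        self.seed = int(seed)
        self.binder_fraction = binder_fraction

    def predict(self, peptide: str, allele: str) -> BindingPrediction:
        digest = hashlib.sha256(f"{self.seed}|{peptide}|{allele}".encode()).digest()
        u1 = int.from_bytes(digest[0:8], "big") / 2**64
        u2 = int.from_bytes(digest[8:16], "big") / 2**64
        u3 = int.from_bytes(digest[16:24], "big") / 2**64
        if u1 < self.binder_fraction:
            ic50 = 1.0 + u2 * 498.0        # < 500
            rank = 0.001 + u3 * 1.998      # < 2
        else:
            ic50 = 500.0 + u2 * 20000.0
            rank = 2.0 + u3 * 50.0
        return BindingPrediction(peptide, allele, round(ic50, 4), round(rank, 4))


class NetMHCpanOutputAdapter:
    """Reads a predictor's native whitespace-delimited output table.

    Accepts the conventional layout: comment lines start with '#', a
    header line names at least ``Peptide``, an allele column (``MHC`` or
    ``HLA``), ``Aff(nM)`` and ``%Rank`` columns; separator/footer lines
    are ignored.
    """

    def __init__(self, path):
        self.table: dict = {}
        header = None
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "-")):
                    continue
                fields = line.split()
                if header is None:
                    if "Peptide" in fields:
                        header = {name: i for i, name in enumerate(fields)}
                    continue
                try:
                    pep = fields[header["Peptide"]]
                    allele_col = header.get("MHC", header.get("HLA"))
                    allele = fields[allele_col]
                    ic50 = float(fields[header["Aff(nM)"]])
                    rank = float(fields[header["%Rank"]])
                except (IndexError, ValueError, TypeError):
                    continue
                self.table[(pep, allele)] = (ic50, rank)
        if header is None:
            raise ValueError(f"no header line with a Peptide column in {path}")

    def predict(self, peptide: str, allele: str) -> Optional[BindingPrediction]:
        hit = self.table.get((peptide, allele))
        if hit is None:
            return None
        return BindingPrediction(peptide, allele, hit[0], hit[1])


def predict_binding(peptides: Sequence[str], alleles: Sequence[str], predictor) -> tuple:
    """Score every (peptide, allele) pair; returns (predictions, missing).

    Homozygous genotypes are deduplicated so each distinct allele scores a
    peptide once. Pairs the predictor cannot score are reported per allele
    in ``missing`` instead of raising.
    """
    distinct = list(dict.fromkeys(alleles))
    predictions, missing = [], {}
    for allele in distinct:
        for pep in peptides:
            pred = predictor.predict(pep, allele)
            if pred is None:
                missing.setdefault(allele, []).append(pep)
            else:
                predictions.append(pred)
    return predictions, missing


@dataclass
class NeoantigenCandidate:
    """A retained (sample, peptide, HLA allele) binder with its provenance."""

    sample_id: str
    prediction: BindingPrediction
    gene: str = ""
    mutation_aa: str = ""
    expressed: Optional[bool] = None

    @property
    def peptide(self) -> str:
        return self.prediction.peptide

    @property
    def hla_allele(self) -> str:
        return self.prediction.hla_allele


def call_neoantigens(
    predictions: Iterable[BindingPrediction],
    ic50_max: float = 500.0,
    rank_max: float = 2.0,
    sample_id: str = "",
    gene: str = "",
    mutation_aa: str = "",
) -> list:
    """Retain predictions with IC50 < ic50_max AND %Rank < rank_max (strict)."""
    return [
        NeoantigenCandidate(sample_id, p, gene, mutation_aa)
        for p in predictions
        if p.ic50_nM < ic50_max and p.rank_pct < rank_max
    ]


def count_neoantigens(candidates: Sequence[NeoantigenCandidate], by_peptide: bool = False) -> int:
    """Candidate count per the (sample, peptide, allele) identity.

    ``by_peptide`` collapses alleles, counting each (sample, peptide)
    once — the alternative identity convention for per-sample burdens.
    """
    if by_peptide:
        return len({(c.sample_id, c.peptide) for c in candidates})
    return len({(c.sample_id, c.peptide, c.hla_allele) for c in candidates})


def expression_filter(
    candidates: Sequence[NeoantigenCandidate],
    fpkm_table: pd.DataFrame,
    min_tumor_fpkm: float = 0.5,
    min_abs_log2_ratio: float = 0.1,
    pseudocount: float = 1e-3,
) -> list:
    """Flag candidates whose source gene is expressed in the tumor.

    Expressed iff tumor FPKM >= 0.5 and |log2(tumor/normal)| >= 0.1; the
    ratio uses a small pseudocount so zero normal expression is
    well-defined. Genes absent from the table leave the flag unset and
    are returned in the missing-gene report.
    """
    table = fpkm_table.set_index("gene") if "gene" in fpkm_table.columns else fpkm_table
    missing = []
    for c in candidates:
        if c.gene not in table.index:
            c.expressed = None
            missing.append(c.gene)
            continue
        row = table.loc[c.gene]
        tumor, normal = float(row["tumor_fpkm"]), float(row["normal_fpkm"])
        ratio = math.log2((tumor + pseudocount) / (normal + pseudocount))
        c.expressed = tumor >= min_tumor_fpkm and abs(ratio) >= min_abs_log2_ratio
    return sorted(set(missing))
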