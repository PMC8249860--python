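"""Synthetic cohort generator: reference, mutations, HLA calls, expression.

Everything the pipeline consumes can be generated here with known ground
truth, so every stage is testable offline. Defaults emulate the cohort the
pipeline was designed around: four stages (CIN1, CIN2, CIN3, CC) with
10/9/6/14 samples, stage mutation burdens rising steeply into carcinoma,
stage-specific signature mixtures with one APOBEC-like signature present
only in the carcinoma group, a 2% binder fraction (the definitional mass
under a %Rank < 2 threshold), and roughly half of candidate genes passing
the expression rule. All randomness flows through one integer seed;
outputs are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .filters import FilterThresholds, passes_read_support
from .spectrum import CONTEXT_LABELS, SIX_CLASSES
from .variants import CohortRow, CohortTable, SampleMeta, Variant
from .neoantigens import TranscriptModel

__all__ = [
    "SimConfig",
    "synthetic_signature_matrix",
    "confusable_signature_matrix",
    "make_reference",
    "sample_mutations",
    "make_cohort_fixture",
    "write_fasta",
    "write_gff",
    "write_snv_vcf",
    "write_indel_vcf",
]

STAGES = ("CIN1", "CIN2", "CIN3", "CC")

_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [c for c in _CODONS if c not in _STOPS]
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimConfig:
    """Study-condition knobs for the generator; defaults mirror the cohort."""

    seed: int = 0
    n_samples: dict = dc_field(
        default_factory=lambda: {"CIN1": 10, "CIN2": 9, "CIN3": 6, "CC": 14}
    )
    # mean somatic mutations per sample per stage (negative binomial)
    mutation_mean: dict = dc_field(
        default_factory=lambda: {"CIN1": 6.45, "CIN2": 6.8, "CIN3": 9.67, "CC": 330.5}
    )
    mutation_dispersion: float = 2.0
    # per-stage exposure mixtures over the synthetic signature set; the
    # APOBEC-like component (sig2) appears only in the carcinoma group
    signature_mixture: dict = dc_field(
        default_factory=lambda: {
            "CIN1": {"sig1": 0.6, "sig3": 0.4},
            "CIN2": {"sig1": 0.4, "sig3": 0.3, "sig4": 0.3},
            "CIN3": {"sig1": 0.5, "sig4": 0.5},
            "CC": {"sig2": 0.55, "sig1": 0.35, "sig4": 0.1},
        }
    )
    # annotation-class composition of generated mutations
    class_proportions: dict = dc_field(
        default_factory=lambda: {
            "missense": 0.596,
            "synonymous": 0.278,
            "nonsense": 0.058,
            "splice_site": 0.015,
            "frameshift": 0.040,
            "inframe_indel": 0.013,
        }
    )
    # probability that a generated call is built to break each criterion
    filter_fail_fracs: dict = dc_field(
        default_factory=lambda: {"I": 0.1, "II": 0.1, "III": 0.1, "IV": 0.1}
    )
    binder_fraction: float = 0.02
    # cohort-fixture neoantigen model: n_neo ~ rate * n_nonsyn + noise
    neo_per_mutation: float = 1.08
    neo_noise_sd: float = 2.0
    expressed_fraction: float = 0.5


# ---------------------------------------------------------------------------
# synthetic signature matrices
# ---------------------------------------------------------------------------

def synthetic_signature_matrix(k: int = 5, seed: int = 0, block_mass: float = 0.85):
    """K well-separated synthetic signatures over the 96 contexts.

    Each signature concentrates ``block_mass`` of its probability on its
    own disjoint block of contexts, with the remainder spread uniformly,
    keeping pairwise cosines low so exposure recovery is well-conditioned.
    """
    from .signatures import SignatureMatrix

    rng = np.random.default_rng(seed)
    blocks = np.array_split(rng.permutation(96), k)
    cols = {}
    for i, block in enumerate(blocks):
        col = np.full(96, (1 - block_mass) / 96)
        in_block = rng.dirichlet(np.ones(len(block)) * 2.0) * block_mass
        col[block] += in_block
        cols[f"sig{i + 1}"] = col / col.sum()
    return SignatureMatrix(pd.DataFrame(cols, index=list(CONTEXT_LABELS)))


def confusable_signature_matrix(seed: int = 0, overlap: float = 0.8):
    """Two signatures sharing most of their mass (cosine ~ overlap).

    Exercises cutoff behavior when exposures are poorly identified.
    """
    from .signatures import SignatureMatrix

    rng = np.random.default_rng(seed)
    base = rng.dirichlet(np.ones(96) * 0.5)
    perturb_a = rng.dirichlet(np.ones(96) * 0.5)
    perturb_b = rng.dirichlet(np.ones(96) * 0.5)
    a = overlap * base + (1 - overlap) * perturb_a
    b = overlap * base + (1 - overlap) * perturb_b
    return SignatureMatrix(
        pd.DataFrame({"sigX": a / a.sum(), "sigY": b / b.sum()}, index=list(CONTEXT_LABELS))
    )


# ---------------------------------------------------------------------------
# reference + transcript models
# ---------------------------------------------------------------------------

FLANK = 30  # non-coding padding either side of each CDS


def make_reference(
    n_genes: int = 8, cds_length_range: tuple = (300, 900), seed: int = 0
) -> tuple:
    """Random single-exon coding genes, one contig each.

    Returns ``(reference, transcripts)`` where ``reference`` maps contig id
    to sequence and each transcript's CDS (start codon ... stop codon, no
    internal stops) sits between non-coding flanks.
    """
    lo, hi = cds_length_range
    if lo % 3 or hi % 3:
        raise ValueError("cds_length_range bounds must be divisible by 3")
    rng = np.random.default_rng(seed)
    reference, transcripts = {}, []
    for g in range(1, n_genes + 1):
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        body = "".join(rng.choice(_SENSE_CODONS) for _ in range(n_codons - 2))
        cds = "ATG" + body + str(rng.choice(sorted(_STOPS)))
        flank5 = "".join(rng.choice(list("ACGT"), FLANK))
        flank3 = "".join(rng.choice(list("ACGT"), FLANK))
        chrom = f"chr_g{g}"
        reference[chrom] = flank5 + cds + flank3
        transcripts.append(
            TranscriptModel(
                transcript_id=f"tx{g}",
                gene=f"GENE{g}",
                chrom=chrom,
                strand="+",
                cds_ranges=[(FLANK + 1, FLANK + len(cds))],
                cds_seq=cds,
            )
        )
    return reference, transcripts


def _context_position_index(reference: Mapping[str, str]) -> dict:
    """Map each pyrimidine-strand trinucleotide to its genomic positions."""
    index: dict = {}
    for chrom, seq in reference.items():
        for i in range(1, len(seq) - 1):
            tri = seq[i - 1 : i + 2]
            if any(b not in "ACGT" for b in tri):
                continue
            if tri[1] in "AG":
                tri = "".join(_COMPLEMENT[b] for b in reversed(tri))
            index.setdefault(tri, []).append((chrom, i + 1))  # 1-based
    return index


def _draw_read_support(rng, fail: dict) -> tuple:
    """Read counts engineered to break exactly the criteria flagged in ``fail``."""
    t_depth = int(rng.integers(40, 101))
    t_vaf = float(rng.uniform(0.12, 0.35))
    n_depth = int(rng.integers(20, 61))
    n_alt = 0
    if fail["I"]:
        t_depth = int(rng.integers(5, 14))
    if fail["II"]:
        t_alt = int(rng.integers(1, 5))
    else:
        t_alt = max(5, round(t_vaf * t_depth))
    if fail["III"]:
        n_alt = max(1, int(np.ceil(n_depth * rng.uniform(0.035, 0.1))))
    elif fail["IV"]:
        # contamination below 3% but tumor VAF under the four-fold bar:
        # pick tumor VAF ~3x the normal VAF with enough depth for alt >= 5
        n_depth = 100
        n_alt = int(rng.integers(2, 3))          # normal VAF 0.02
        if not fail["I"]:
            t_depth = int(rng.integers(90, 121))
        if not fail["II"]:
            t_alt = round(3.0 * (n_alt / n_depth) * t_depth)
    t_alt = min(t_alt, t_depth)
    return t_depth, t_alt, n_depth, n_alt


def sample_mutations(
    cfg: SimConfig, reference: Mapping[str, str], transcripts: Sequence[TranscriptModel],
    signatures=None,
) -> tuple:
    """Generate per-sample somatic calls plus a truth table.

    SNV contexts are drawn from each stage's signature mixture and
    realized at reference positions carrying the matching trinucleotide;
    read support is engineered so a configured fraction of calls breaks
    each filter criterion. Returns ``(variants_by_sample, truth)`` where
    ``truth`` records the class, 96-context and evaluated per-criterion
    outcome for every call.
    """
    if signatures is None:
        signatures = synthetic_signature_matrix(seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    pos_index = _context_position_index(reference)
    tx_by_chrom = {t.chrom: t for t in transcripts}
    classes = list(cfg.class_proportions)
    class_p = np.array([cfg.class_proportions[c] for c in classes])
    class_p = class_p / class_p.sum()
    disp = cfg.mutation_dispersion

    variants_by_sample: dict = {}
    truth_rows = []
    for stage in STAGES:
        mix = cfg.signature_mixture[stage]
        mix_names = list(mix)
        mix_p = np.array([mix[n] for n in mix_names])
        mix_p = mix_p / mix_p.sum()
        sig_cols = {n: signatures.values[:, signatures.names.index(n)] for n in mix_names}
        for si in range(cfg.n_samples[stage]):
            sample_id = f"{stage}-S{si + 1}"
            mean = cfg.mutation_mean[stage]
            n_mut = int(rng.negative_binomial(disp, disp / (disp + mean)))
            variants = []
            for _ in range(n_mut):
                csq = classes[int(rng.choice(len(classes), p=class_p))]
                fail = {
                    c: bool(rng.random() < cfg.filter_fail_fracs[c])
                    for c in ("I", "II", "III", "IV")
                }
                if csq in ("frameshift", "inframe_indel"):
                    v, ctx_idx = _make_indel(rng, reference, tx_by_chrom, csq, fail, sample_id)
                else:
                    v, ctx_idx = _make_snv(
                        rng, reference, tx_by_chrom, pos_index,
                        mix_names, mix_p, sig_cols, csq, fail, sample_id,
                    )
                variants.append(v)
                res = passes_read_support(v, FilterThresholds())
                truth_rows.append(
                    {
                        "sample_id": sample_id,
                        "group": stage,
                        "chrom": v.chrom,
                        "pos": v.pos,
                        "consequence": csq,
                        "context_idx": ctx_idx,
                        "fail_I": fail["I"],
                        "fail_II": fail["II"],
                        "fail_III": fail["III"],
                        "fail_IV": fail["IV"],
                        "crit_I": res.depth_ok,
                        "crit_II": res.alt_count_ok,
                        "crit_III": res.vaf_ok,
                        "crit_IV": res.fold_ok,
                        "passed": res.passed,
                    }
                )
            variants_by_sample[sample_id] = variants
    return variants_by_sample, pd.DataFrame(truth_rows)


def _make_snv(rng, reference, tx_by_chrom, pos_index, mix_names, mix_p, sig_cols,
              csq, fail, sample_id) -> tuple:
    sig = mix_names[int(rng.choice(len(mix_names), p=mix_p))]
    col = sig_cols[sig]
    for _ in range(50):  # resample contexts absent from the reference
        ctx_idx = int(rng.choice(96, p=col))
        label = CONTEXT_LABELS[ctx_idx]
        left, cls, right = label[0], label[2:5], label[6]
        tri = left + cls[0] + right
        if tri in pos_index:
            break
    else:
        raise RuntimeError(f"no reference position for any context of {sig}")
    chrom, pos = pos_index[tri][int(rng.integers(len(pos_index[tri])))]
    ref_base = reference[chrom][pos - 1]
    if ref_base in "CT":
        ref, alt = cls[0], cls[2]
    else:
        ref, alt = _COMPLEMENT[cls[0]], _COMPLEMENT[cls[2]]
    t_depth, t_alt, n_depth, n_alt = _draw_read_support(rng, fail)
    tx = tx_by_chrom[chrom]
    return (
        Variant(
            chrom=chrom, pos=pos, ref=ref, alt=alt, variant_class="SNV",
            tumor_depth=t_depth, tumor_alt=t_alt,
            normal_depth=n_depth, normal_alt=n_alt,
            gene=tx.gene, transcript_id=tx.transcript_id,
            consequence=csq, sample_id=sample_id,
        ),
        ctx_idx,
    )


def _make_indel(rng, reference, tx_by_chrom, csq, fail, sample_id) -> tuple:
    chrom = list(reference)[int(rng.integers(len(reference)))]
    tx = tx_by_chrom[chrom]
    (cds_s, cds_e), = tx.cds_ranges
    size = 3 if csq == "inframe_indel" else int(rng.integers(1, 3))
    # anchor inside the CDS body, clear of start/stop codons
    pos = int(rng.integers(cds_s + 3, cds_e - 3 - size))
    seq = reference[chrom]
    if rng.random() < 0.5 and csq == "frameshift":  # insertion
        ref = seq[pos - 1]
        ins = "".join(rng.choice(list("ACGT"), size))
        alt = ref + ins
        vclass = "insertion"
    else:
        ref = seq[pos - 1 : pos - 1 + 1 + size]
        alt = seq[pos - 1]
        vclass = "deletion"
    t_depth, t_alt, n_depth, n_alt = _draw_read_support(rng, fail)
    return (
        Variant(
            chrom=chrom, pos=pos, ref=ref, alt=alt, variant_class=vclass,
            tumor_depth=t_depth, tumor_alt=t_alt,
            normal_depth=n_depth, normal_alt=n_alt,
            gene=tx.gene, transcript_id=tx.transcript_id,
            consequence=csq, sample_id=sample_id,
        ),
        -1,
    )


# ---------------------------------------------------------------------------
# cohort fixture: counts, HLA genotypes, expression
# ---------------------------------------------------------------------------

HLA_POOLS = {
    "A": ["26:01", "03:01", "11:01", "02:01", "24:02", "23:01", "34:01", "01:02"],
    "B": ["15:18", "40:01", "07:02", "37:01", "67:01", "15:01", "55:02", "35:01"],
    "C": ["07:02", "12:03", "03:03", "01:02", "14:02", "12:02", "03:04", "07:03"],
}

#: stage-conditional frequency bumps for focal alleles (rest of pool uniform)
HLA_STAGE_FREQ = {
    ("B", "15:18"): {"CC": 0.36, "CIN1": 0.02, "CIN2": 0.02, "CIN3": 0.05},
    ("A", "26:01"): {"CC": 0.43, "CIN1": 0.2, "CIN2": 0.2, "CIN3": 0.2},
    ("C", "07:02"): {"CC": 0.43, "CIN1": 0.2, "CIN2": 0.2, "CIN3": 0.2},
}


def _draw_allele(rng, locus, stage):
    pool = HLA_POOLS[locus]
    probs = np.full(len(pool), 1.0)
    for (loc, allele), by_stage in HLA_STAGE_FREQ.items():
        if loc == locus and allele in pool:
            i = pool.index(allele)
            p = by_stage[stage]
            probs[i] = 0.0
            probs = probs / probs.sum() * (1 - p)
            probs[i] = p
    probs = probs / probs.sum()
    return pool[int(rng.choice(len(pool), p=probs))]


def make_cohort_fixture(cfg: SimConfig) -> tuple:
    """Synthetic cohort table, HLA genotype table and per-gene FPKM table.

    Neoantigen counts follow a linear rate per nonsynonymous mutation with
    Gaussian noise (``neo_noise_sd = 0`` gives exact proportionality);
    HLA genotypes are drawn from a small allele pool with stage-specific
    focal-allele frequencies; the FPKM table satisfies the expression rule
    for a programmed fraction of genes.
    """
    rng = np.random.default_rng(cfg.seed)
    disp = cfg.mutation_dispersion
    rows = []
    for stage in STAGES:
        for si in range(cfg.n_samples[stage]):
            mean = max(cfg.mutation_mean[stage] * 0.6, 1.0)
            n_nonsyn = int(rng.negative_binomial(disp, disp / (disp + mean)))
            n_neo = max(
                0,
                int(round(cfg.neo_per_mutation * n_nonsyn + rng.normal(0, cfg.neo_noise_sd))),
            )
            meta = SampleMeta(
                sample_id=f"{stage}-S{si + 1}",
                group=stage,
                hla_a=sorted({_draw_allele(rng, "A", stage) for _ in range(2)}),
                hla_b=sorted({_draw_allele(rng, "B", stage) for _ in range(2)}),
                hla_c=sorted({_draw_allele(rng, "C", stage) for _ in range(2)}),
            )
            rows.append(CohortRow(meta=meta, n_nonsynonymous=n_nonsyn, n_neoantigens=n_neo))
    cohort = CohortTable(rows)

    hla_frame = pd.DataFrame(
        {
            "sample_id": [r.meta.sample_id for r in rows],
            "group": [r.meta.group for r in rows],
            "hla_a": ["/".join(r.meta.hla_a) for r in rows],
            "hla_b": ["/".join(r.meta.hla_b) for r in rows],
            "hla_c": ["/".join(r.meta.hla_c) for r in rows],
        }
    )

    n_genes = 200
    genes = [f"GENE{i + 1}" for i in range(n_genes)]
    expressed = rng.random(n_genes) < cfg.expressed_fraction
    tumor = np.where(
        expressed,
        np.exp(rng.normal(1.0, 0.8, n_genes)) + 0.5,   # comfortably >= 0.5
        np.exp(rng.normal(-2.5, 0.5, n_genes)),        # < 0.5
    )
    ratio_shift = np.where(expressed, rng.uniform(0.3, 1.5, n_genes), 0.0)
    normal = tumor / np.exp2(ratio_shift)
    fpkm = pd.DataFrame(
        {"gene": genes, "tumor_fpkm": tumor, "normal_fpkm": normal, "expressed_truth": expressed}
    )
    return cohort, hla_frame, fpkm


# ---------------------------------------------------------------------------
# plain-text writers
# ---------------------------------------------------------------------------

def write_fasta(reference: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_gff(transcripts: Sequence[TranscriptModel], path) -> None:
    """GFF3-like CDS records whose coordinates slice the FASTA to the CDS."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts:
            for s, e in t.cds_ranges:
                fh.write(
                    f"{t.chrom}\tcinneo_sim\tCDS\t{s}\t{e}\t.\t{t.strand}\t0\t"
                    f"ID={t.transcript_id};gene={t.gene}\n"
                )


def _contig_lines(variants: Sequence[Variant]) -> str:
    chroms = sorted({v.chrom for v in variants})
    return "".join(f"##contig=<ID={c}>\n" for c in chroms)


_VCF_SNV_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=TRANSCRIPT,Number=1,Type=String,Description="Transcript id">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">
##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample id">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AU,Number=2,Type=Integer,Description="A tier1,tier2 counts">
##FORMAT=<ID=CU,Number=2,Type=Integer,Description="C tier1,tier2 counts">
##FORMAT=<ID=GU,Number=2,Type=Integer,Description="G tier1,tier2 counts">
##FORMAT=<ID=TU,Number=2,Type=Integer,Description="T tier1,tier2 counts">
"""

_VCF_INDEL_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=TRANSCRIPT,Number=1,Type=String,Description="Transcript id">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">
##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample id">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=RD,Number=1,Type=Integer,Description="Reference support">
##FORMAT=<ID=AD,Number=.,Type=Integer,Description="Alternate support">
"""


def _info(v: Variant) -> str:
    parts = []
    for key, val in (
        ("GENE", v.gene), ("TRANSCRIPT", v.transcript_id),
        ("CSQ", v.consequence), ("SAMPLE", v.sample_id),
    ):
        if val:
            parts.append(f"{key}={val}")
    return ";".join(parts) or "."


def write_snv_vcf(variants: Sequence[Variant], path) -> None:
    """Tiered-base-count (SNV caller) dialect; SNVs only."""
    with open(path, "w") as fh:
        fh.write(_VCF_SNV_HEADER)
        fh.write(_contig_lines(variants))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNORMAL\tTUMOR\n")
        for v in sorted(variants, key=lambda x: (x.chrom, x.pos)):
            samples = []
            for depth, alt_n in ((v.normal_depth, v.normal_alt), (v.tumor_depth, v.tumor_alt)):
                c = {b: [0, 0] for b in "ACGT"}
                c[v.alt][0] = alt_n
                c[v.ref][0] = depth - alt_n
                samples.append(
                    f"{depth}:" + ":".join(f"{c[b][0]},{c[b][1]}" for b in "ACGT")
                )
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{_info(v)}\t"
                f"DP:AU:CU:GU:TU\t{samples[0]}\t{samples[1]}\n"
            )


def write_indel_vcf(variants: Sequence[Variant], path) -> None:
    """DP/AD (indel caller) dialect."""
    with open(path, "w") as fh:
        fh.write(_VCF_INDEL_HEADER)
        fh.write(_contig_lines(variants))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNORMAL\tTUMOR\n")
        for v in sorted(variants, key=lambda x: (x.chrom, x.pos)):
            norm = f"{v.normal_depth}:{v.normal_depth - v.normal_alt}:{v.normal_alt}"
            tum = f"{v.tumor_depth}:{v.tumor_depth - v.tumor_alt}:{v.tumor_alt}"
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{_info(v)}\t"
                f"DP:RD:AD\t{norm}\t{tum}\n"
            )
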