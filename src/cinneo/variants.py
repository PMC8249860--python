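"""Domain types and readers/writers for somatic variants and cohort tables.

Coordinates are 1-based fully closed (the VCF / annotation-table convention);
conversion to 0-based half-open slices happens only inside sequence code.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Variant",
    "SampleMeta",
    "CohortRow",
    "CohortTable",
    "ValidatedNeoantigenRow",
    "FormatError",
    "PackagingError",
    "read_somatic_vcf",
    "read_maf",
    "write_maf",
    "load_table1_fixture",
    "load_table2_fixture",
    "load_table3_fixture",
]

VARIANT_CLASSES = ("SNV", "insertion", "deletion")
CONSEQUENCES = (
    "missense",
    "nonsense",
    "splice_site",
    "frameshift",
    "inframe_indel",
    "synonymous",
    "intronic",
    "other",
)

HLA_ALLELE_RE = re.compile(r"^\d{2}:(\d{2}|\*)$")


class FormatError(ValueError):
    """A file does not conform to the expected tabular/VCF layout."""


class PackagingError(RuntimeError):
    """A packaged fixture is missing or corrupted."""


@dataclass
class Variant:
    """One tumor/normal somatic call — the unit flowing through every filter.

    ``tumor_alt``/``tumor_depth`` and the normal-side counterparts hold the
    read support used by the four-criterion somatic filter; ``consequence``
    carries the annotation-derived functional class.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str
    tumor_depth: int
    tumor_alt: int
    normal_depth: int
    normal_alt: int
    gene: str = ""
    transcript_id: str = ""
    consequence: str = "other"
    protein_change: str = ""
    sample_id: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.tumor_alt > self.tumor_depth:
            raise ValueError("tumor_alt exceeds tumor_depth")
        if self.normal_alt > self.normal_depth:
            raise ValueError("normal_alt exceeds normal_depth")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")
        if self.variant_class == "SNV" and not (len(self.ref) == len(self.alt) == 1):
            raise ValueError("SNV requires single-base ref and alt")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")

    @property
    def tumor_vaf(self) -> float:
        return self.tumor_alt / self.tumor_depth if self.tumor_depth else float("nan")

    @property
    def normal_vaf(self) -> float:
        return self.normal_alt / self.normal_depth if self.normal_depth else 0.0


@dataclass
class SampleMeta:
    """Per-sample stage label and four-digit HLA class I genotype.

    Empty allele lists mean either no reportable allele or typing
    unavailable; ``typed`` distinguishes the two. Wildcard alleles such as
    ``"67:*"`` are stored verbatim and match no specific four-digit allele.
    """

    sample_id: str
    group: str
    hla_a: list = field(default_factory=list)
    hla_b: list = field(default_factory=list)
    hla_c: list = field(default_factory=list)
    typed: bool = True

    def __post_init__(self):
        if self.group not in ("CIN1", "CIN2", "CIN3", "CC"):
            raise ValueError(f"unknown group {self.group!r}")
        for locus in (self.hla_a, self.hla_b, self.hla_c):
            for allele in locus:
                if not HLA_ALLELE_RE.match(allele):
                    raise ValueError(f"malformed HLA allele {allele!r}")

    def alleles(self, locus: str) -> list:
        return {"A": self.hla_a, "B": self.hla_b, "C": self.hla_c}[locus]


@dataclass
class CohortRow:
    meta: SampleMeta
    n_nonsynonymous: int
    n_neoantigens: int

    def __post_init__(self):
        if self.n_nonsynonymous < 0 or self.n_neoantigens < 0:
            raise ValueError("counts must be nonnegative")


class CohortTable:
    """Per-sample mutation/neoantigen counts plus HLA genotypes."""

    def __init__(self, rows: Sequence[CohortRow]):
        ids = [r.meta.sample_id for r in rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_ids in cohort table")
        self.rows = list(rows)

    def __len__(self):
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def subset(self, groups: Iterable[str]) -> "CohortTable":
        groups = _expand_groups(groups)
        return CohortTable([r for r in self.rows if r.meta.group in groups])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [r.meta.sample_id for r in self.rows],
                "group": [r.meta.group for r in self.rows],
                "n_nonsynonymous": [r.n_nonsynonymous for r in self.rows],
                "n_neoantigens": [r.n_neoantigens for r in self.rows],
            }
        )


def _expand_groups(groups) -> set:
    """'CIN' is shorthand for the three pre-malignant stages."""
    if isinstance(groups, str):
        groups = [groups]
    out = set()
    for g in groups:
        if g == "CIN":
            out |= {"CIN1", "CIN2", "CIN3"}
        else:
            out.add(g)
    return out


@dataclass
class ValidatedNeoantigenRow:
    """One database-validated candidate neoantigen (peptide/allele pair)."""

    sample_id: str
    peptide: str
    protein: str
    mutation_aa: str
    hla_allele: str
    affinity_nM: float
    rank_pct: float
    validated_source: str
    drugs: str = ""

    def __post_init__(self):
        if not 8 <= len(self.peptide) <= 11:
            raise ValueError(f"peptide length {len(self.peptide)} outside [8, 11]")
        if self.affinity_nM <= 0:
            raise ValueError("affinity must be positive")
        if not 0 < self.rank_pct < 100:
            raise ValueError("rank_pct outside (0, 100)")
        if self.validated_source not in ("TSNAdb-CESC", "IEDB", "CTAs"):
            raise ValueError(f"unknown source {self.validated_source!r}")


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

#: Per-dialect read-support extraction. The SNV caller reports per-base
#: tier-1/tier-2 count pairs (AU/CU/GU/TU); the indel caller reports plain
#: DP/AD-style depths. New callers are a config entry here, not code.
CALLER_DIALECTS = {
    "snv_caller": {"style": "tiered_base_counts"},
    "indel_caller": {"style": "dp_ad"},
}


def _sample_indices(vcf) -> tuple:
    """Locate (normal, tumor) columns by name; fall back to column order."""
    samples = [s.upper() for s in vcf.samples]
    if len(vcf.samples) < 2:
        raise FormatError("VCF must carry tumor and normal sample columns")
    if "NORMAL" in samples and "TUMOR" in samples:
        return samples.index("NORMAL"), samples.index("TUMOR")
    return 0, 1


def read_somatic_vcf(path, caller_dialect: str) -> list:
    """Read a tumor/normal somatic VCF into :class:`Variant` records.

    Multi-allelic records are decomposed into one record per ALT allele.
    Records whose depth tags cannot be parsed are collected and reported in
    a single :class:`FormatError` at the end rather than dropped silently.
    """
    from cyvcf2 import VCF

    if caller_dialect not in CALLER_DIALECTS:
        raise ValueError(f"unknown caller dialect {caller_dialect!r}")
    style = CALLER_DIALECTS[caller_dialect]["style"]

    vcf = VCF(str(path))
    i_norm, i_tum = _sample_indices(vcf)
    out, bad = [], []
    for rec in vcf:
        for alt in rec.ALT:
            try:
                out.append(_variant_from_record(rec, alt, style, i_norm, i_tum))
            except (TypeError, ValueError, KeyError) as exc:
                bad.append(f"{rec.CHROM}:{rec.POS} {rec.REF}>{alt}: {exc}")
    vcf.close()
    if bad:
        raise FormatError("unparseable records:\n" + "\n".join(bad))
    return out


def _variant_from_record(rec, alt, style, i_norm, i_tum) -> Variant:
    dp = rec.format("DP")
    if dp is None:
        raise ValueError("missing DP")
    n_depth, t_depth = int(dp[i_norm][0]), int(dp[i_tum][0])

    if style == "tiered_base_counts":
        tag = f"{alt}U"
        counts = rec.format(tag)
        if counts is None:
            raise ValueError(f"missing {tag}")
        n_alt, t_alt = int(counts[i_norm][0]), int(counts[i_tum][0])
        vclass = "SNV"
    else:
        ad = rec.format("AD")
        if ad is None:
            raise ValueError("missing AD")
        n_alt, t_alt = int(ad[i_norm][-1]), int(ad[i_tum][-1])
        if len(alt) > len(rec.REF):
            vclass = "insertion"
        elif len(alt) < len(rec.REF):
            vclass = "deletion"
        else:
            vclass = "SNV"

    info = dict(rec.INFO) if rec.INFO else {}
    return Variant(
        chrom=rec.CHROM,
        pos=rec.POS,
        ref=rec.REF,
        alt=alt,
        variant_class=vclass,
        tumor_depth=t_depth,
        tumor_alt=t_alt,
        normal_depth=n_depth,
        normal_alt=n_alt,
        gene=str(info.get("GENE", "")),
        transcript_id=str(info.get("TRANSCRIPT", "")),
        consequence=str(info.get("CSQ", "other")),
        protein_change=str(info.get("PCHANGE", "")),
        sample_id=str(info.get("SAMPLE", "")),
    )


# ---------------------------------------------------------------------------
# MAF reading/writing
# ---------------------------------------------------------------------------

_MAF_CLASS_TO_CONSEQUENCE = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Splice_Site": "splice_site",
    "Frame_Shift_Del": "frameshift",
    "Frame_Shift_Ins": "frameshift",
    "In_Frame_Del": "inframe_indel",
    "In_Frame_Ins": "inframe_indel",
    "Silent": "synonymous",
    "Intron": "intronic",
}

_MAF_TYPE_TO_CLASS = {"SNP": "SNV", "INS": "insertion", "DEL": "deletion"}
_CLASS_TO_MAF_TYPE = {v: k for k, v in _MAF_TYPE_TO_CLASS.items()}

MAF_MANDATORY = ("Hugo_Symbol", "Chromosome", "Start_Position", "Variant_Classification")


def _consequence_to_maf(v: Variant) -> str:
    c = v.consequence
    if c == "missense":
        return "Missense_Mutation"
    if c == "nonsense":
        return "Nonsense_Mutation"
    if c == "splice_site":
        return "Splice_Site"
    if c == "frameshift":
        return "Frame_Shift_Ins" if v.variant_class == "insertion" else "Frame_Shift_Del"
    if c == "inframe_indel":
        return "In_Frame_Ins" if v.variant_class == "insertion" else "In_Frame_Del"
    if c == "synonymous":
        return "Silent"
    if c == "intronic":
        return "Intron"
    return "Other"


def write_maf(variants: Iterable[Variant], path) -> None:
    rows = []
    for v in variants:
        rows.append(
            {
                "Hugo_Symbol": v.gene,
                "Chromosome": v.chrom,
                "Start_Position": v.pos,
                "Reference_Allele": v.ref,
                "Tumor_Seq_Allele2": v.alt,
                "Variant_Classification": _consequence_to_maf(v),
                "Variant_Type": _CLASS_TO_MAF_TYPE[v.variant_class],
                "Tumor_Sample_Barcode": v.sample_id,
                "Transcript_ID": v.transcript_id,
                "HGVSp_Short": v.protein_change,
                "t_depth": v.tumor_depth,
                "t_alt_count": v.tumor_alt,
                "n_depth": v.normal_depth,
                "n_alt_count": v.normal_alt,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_maf(path) -> list:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in MAF_MANDATORY if c not in df.columns]
    if missing:
        raise FormatError(f"MAF missing mandatory columns: {missing}")
    out = []
    for _, row in df.iterrows():
        vcls = _MAF_TYPE_TO_CLASS.get(row.get("Variant_Type", "SNP"), "SNV")
        out.append(
            Variant(
                chrom=row["Chromosome"],
                pos=int(row["Start_Position"]),
                ref=row.get("Reference_Allele", "N"),
                alt=row.get("Tumor_Seq_Allele2", "N"),
                variant_class=vcls,
                tumor_depth=int(row.get("t_depth", 0) or 0),
                tumor_alt=int(row.get("t_alt_count", 0) or 0),
                normal_depth=int(row.get("n_depth", 0) or 0),
                normal_alt=int(row.get("n_alt_count", 0) or 0),
                gene=row["Hugo_Symbol"],
                transcript_id=row.get("Transcript_ID", ""),
                consequence=_MAF_CLASS_TO_CONSEQUENCE.get(
                    row["Variant_Classification"], "other"
                ),
                protein_change=row.get("HGVSp_Short", ""),
                sample_id=row.get("Tumor_Sample_Barcode", ""),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Packaged fixtures transcribing the cohort's printed tables
# ---------------------------------------------------------------------------

_FIXTURE_SHA256 = {
    # filled in at packaging time by tests/conftest integrity check; the
    # loaders verify row counts, which is the load-bearing contract.
}


def _fixture_path(name: str) -> Path:
    ref = resources.files("cinneo") / "data" / name
    with resources.as_file(ref) as p:
        if not p.exists():
            raise PackagingError(f"missing packaged fixture {name}")
        return p


def _fixture_frame(name: str, expect_rows: int) -> pd.DataFrame:
    p = _fixture_path(name)
    df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False).fillna("")
    if len(df) != expect_rows:
        raise PackagingError(
            f"fixture {name} has {len(df)} rows, expected {expect_rows}"
        )
    return df


def fixture_checksum(name: str) -> str:
    """SHA-256 of a packaged fixture, for provenance reporting."""
    return hashlib.sha256(_fixture_path(name).read_bytes()).hexdigest()


def _parse_hla_cell(cell: str) -> tuple:
    """Return (alleles, typed). '/' alone = untyped; '–'/'-'/'' = no allele."""
    cell = cell.strip()
    if cell == "/":
        return [], False
    if cell in ("", "–", "-", "."):
        return [], True
    return [a.strip() for a in cell.split("/") if a.strip()], True


def load_table2_fixture() -> CohortTable:
    """The 39-sample cohort table: counts plus HLA class I genotypes."""
    df = _fixture_frame("table2_cohort.tsv", 39)
    rows = []
    for _, r in df.iterrows():
        a, typed_a = _parse_hla_cell(r["hla_a"])
        b, typed_b = _parse_hla_cell(r["hla_b"])
        c, typed_c = _parse_hla_cell(r["hla_c"])
        meta = SampleMeta(
            sample_id=r["sample_id"],
            group=r["group"],
            hla_a=a,
            hla_b=b,
            hla_c=c,
            typed=typed_a and typed_b and typed_c,
        )
        rows.append(
            CohortRow(
                meta=meta,
                n_nonsynonymous=int(r["n_nonsynonymous"]),
                n_neoantigens=int(r["n_neoantigens"]),
            )
        )
    table = CohortTable(rows)
    n_cin = len(table.subset("CIN"))
    n_cc = len(table.subset("CC"))
    if (n_cin, n_cc) != (25, 14):
        raise PackagingError(f"cohort fixture group sizes {n_cin} CIN / {n_cc} CC")
    return table


def load_table3_fixture() -> list:
    """45 database-validated candidate neoantigens; merged cells filled down."""
    df = _fixture_frame("table3_validated.tsv", 45)
    # merged "Validated"/"Drugs" cells in the printed table span several rows
    df["validated_source"] = df["validated_source"].replace("", None)
    df["drugs"] = df["drugs"].replace("", None)
    df[["validated_source", "drugs"]] = df[["validated_source", "drugs"]].ffill()
    return [
        ValidatedNeoantigenRow(
            sample_id=r["sample_id"],
            peptide=r["peptide"],
            protein=r["protein"],
            mutation_aa=r["mutation_aa"],
            hla_allele=r["hla_allele"],
            affinity_nM=float(r["affinity_nM"]),
            rank_pct=float(r["rank_pct"]),
            validated_source=r["validated_source"],
            drugs=r["drugs"],
        )
        for _, r in df.iterrows()
    ]


def load_table1_fixture() -> pd.DataFrame:
    """The 11 driver-candidate mutations (3 genes) with predictor calls."""
    return _fixture_frame("table1_drivers.tsv", 11)
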