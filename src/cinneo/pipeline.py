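"""Sequential end-to-end orchestration of the analysis stages.

``run_all`` executes ingest -> filter -> spectrum -> signatures -> drivers
-> neoantigens -> summarize over a simulation-layout input directory and
emits a machine-readable run report (per-stage record counts, thresholds,
seed) plus all stage outputs. Reruns with identical inputs and config are
byte-identical except file timestamps. Stage failures abort with the stage
name attached; filtered records land in quarantine tables, never silent
drops.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import burden_summary, hla_carrier_frequency, mutation_neoantigen_correlation
from .config import RunConfig
from .drivers import DriverCallConfig, PredictorCalls, enumerate_drivers
from .filters import apply_read_support_filter, retain_consequences, tally_classes
from .neoantigens import (
    MockBindingPredictor,
    MutantPeptideSet,
    TranscriptModel,
    call_neoantigens,
    count_neoantigens,
    enumerate_windows,
    expression_filter,
    frameshift_peptides,
    mutant_context_peptide,
    predict_binding,
)
from .signatures import SignatureMatrix, cohort_signature_summary, refit
from .spectrum import build_catalog, stage_spectra, stage_trend
from .variants import (
    CohortRow,
    CohortTable,
    SampleMeta,
    read_somatic_vcf,
    write_maf,
)

__all__ = ["run_all", "read_fasta", "read_transcripts_gff", "read_hla_tsv"]


class StageError(RuntimeError):
    def __init__(self, stage, exc):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def read_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_transcripts_gff(path, reference) -> list:
    """Parse the GFF3-like CDS table into transcript models."""
    by_tx: dict = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _, feat, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            if feat != "CDS":
                continue
            kv = dict(item.split("=", 1) for item in attrs.split(";") if "=" in item)
            tid = kv.get("ID", "")
            entry = by_tx.setdefault(
                tid, {"gene": kv.get("gene", ""), "chrom": chrom, "strand": strand, "ranges": []}
            )
            entry["ranges"].append((int(start), int(end)))
    return [
        TranscriptModel.from_reference(
            tid, e["gene"], e["chrom"], e["strand"], e["ranges"], reference
        )
        for tid, e in by_tx.items()
    ]


def read_hla_tsv(path) -> dict:
    """sample_id -> {locus: [alleles]} from a genotype TSV ('a/b' lists)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = {}
    for _, r in df.iterrows():
        out[r["sample_id"]] = {
            "group": r.get("group", ""),
            "A": [a for a in r.get("hla_a", "").split("/") if a],
            "B": [a for a in r.get("hla_b", "").split("/") if a],
            "C": [a for a in r.get("hla_c", "").split("/") if a],
        }
    return out


def _group_of(sample_id: str) -> str:
    return sample_id.split("-")[0]


def run_all(cfg: RunConfig) -> dict:
    """Run every stage over ``cfg.input_dir``; returns the run report."""
    indir = Path(cfg.input_dir)
    outdir = Path(cfg.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {"version": __version__, "seed": cfg.seed, "stages": {}}

    # --- ingest ------------------------------------------------------------
    try:
        reference = read_fasta(indir / "reference.fa")
        transcripts = read_transcripts_gff(indir / "models.gff3", reference)
        variants = []
        for vcf in sorted((indir / "snv").glob("*.vcf")):
            variants += read_somatic_vcf(vcf, "snv_caller")
        for vcf in sorted((indir / "indel").glob("*.vcf")):
            variants += read_somatic_vcf(vcf, "indel_caller")
        write_maf(variants, outdir / "ingested.maf")
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise StageError("ingest", exc)
    report["stages"]["ingest"] = {"n_variants": len(variants)}

    # --- somatic filter ----------------------------------------------------
    try:
        passed, failed = apply_read_support_filter(variants, cfg.filter_thresholds())
        retained, quarantined = retain_consequences(passed)
        tally = tally_classes(retained)
        write_maf(retained, outdir / "filtered.maf")
        pd.DataFrame(
            [
                {
                    "chrom": v.chrom, "pos": v.pos, "sample_id": v.sample_id,
                    "crit_I": r.depth_ok, "crit_II": r.alt_count_ok,
                    "crit_III": r.vaf_ok, "crit_IV": r.fold_ok,
                }
                for v, r in failed
            ]
        ).to_csv(outdir / "filter_quarantine.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("filter", exc)
    report["stages"]["filter"] = {
        "n_in": len(variants),
        "n_read_support_pass": len(passed),
        "n_read_support_fail": len(failed),
        "n_retained": len(retained),
        "n_quarantined_consequence": len(quarantined),
        "class_tally": {
            "nonsynonymous_snv": tally.nonsynonymous_snv,
            "nonsense": tally.nonsense,
            "splice_site": tally.splice_site,
            "frameshift": tally.frameshift,
            "non_silent": tally.non_silent,
        },
        "thresholds": {
            "min_tumor_depth": cfg.min_tumor_depth,
            "min_normal_depth": cfg.min_normal_depth,
            "min_tumor_alt": cfg.min_tumor_alt,
            "min_tumor_vaf": cfg.min_tumor_vaf,
            "max_normal_vaf": cfg.max_normal_vaf,
            "min_vaf_fold": cfg.min_vaf_fold,
        },
    }

    # --- spectrum ----------------------------------------------------------
    try:
        samples = sorted({v.sample_id for v in passed})
        catalogs = {
            s: build_catalog([v for v in passed if v.sample_id == s], reference, s)
            for s in samples
        }
        by_group: dict = {}
        for s, cat in catalogs.items():
            by_group.setdefault(_group_of(s), []).append(cat)
        spectra = stage_spectra(by_group)
        cohort_matrix = pd.DataFrame(
            {s: c.context96 for s, c in catalogs.items()}, index=range(96)
        )
        cohort_matrix.to_csv(outdir / "context96_matrix.tsv", sep="\t")
        trend = (
            stage_trend(spectra)
            if {sp.group for sp in spectra} >= {"CIN1", "CIN2", "CIN3", "CC"}
            else {}
        )
    except Exception as exc:
        raise StageError("spectrum", exc)
    report["stages"]["spectrum"] = {
        "n_samples": len(catalogs),
        "groups": sorted(by_group),
        "trend": trend,
    }

    # --- signatures ---------------------------------------------------------
    if cfg.run_signatures and (indir / "signatures.tsv").exists():
        try:
            sigs = SignatureMatrix.from_tsv(indir / "signatures.tsv")
            results = [
                refit(cat, sigs, cfg.weight_cutoff, cfg.improvement_tol)
                for cat in catalogs.values()
                if cat.n_classified > 0
            ]
            summary = cohort_signature_summary(
                results, {r.sample_id: _group_of(r.sample_id) for r in results}
            )
            summary.to_csv(outdir / "signature_summary.tsv", sep="\t")
            report["stages"]["signatures"] = {
                "n_fitted": len(results),
                "group_exposures": {
                    g: {k: round(v, 4) for k, v in row.items() if v > 0}
                    for g, row in summary.iterrows()
                },
            }
        except Exception as exc:
            raise StageError("signatures", exc)

    # --- drivers -------------------------------------------------------------
    try:
        if cfg.driver_catalog_path:
            catalog = frozenset(
                pd.read_csv(cfg.driver_catalog_path, sep="\t", header=None)[0]
            )
        else:
            catalog = frozenset(v.gene for v in retained if v.gene)
        records = [
            {
                "gene": v.gene,
                "sample_id": v.sample_id,
                "predictor": PredictorCalls(
                    is_truncating=v.consequence in ("nonsense", "frameshift")
                ),
            }
            for v in retained
            if v.gene
        ]
        driver_calls, near = enumerate_drivers(
            records, DriverCallConfig(min_cases=cfg.min_cases, driver_catalog=catalog)
        )
        pd.DataFrame(
            [
                {"gene": d.gene, "n_cases": d.n_cases, "n_deleterious": d.n_deleterious}
                for d in driver_calls
            ]
        ).to_csv(outdir / "drivers.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("drivers", exc)
    report["stages"]["drivers"] = {
        "n_drivers": len(driver_calls),
        "n_near_threshold": len(near),
        "genes": [d.gene for d in driver_calls],
    }

    # --- neoantigens ---------------------------------------------------------
    try:
        hla = read_hla_tsv(indir / "hla.tsv") if (indir / "hla.tsv").exists() else {}
        fpkm = (
            pd.read_csv(indir / "fpkm.tsv", sep="\t")
            if (indir / "fpkm.tsv").exists()
            else None
        )
        predictor = MockBindingPredictor(cfg.seed, cfg.binder_fraction)
        tx_by_id = {t.transcript_id: t for t in transcripts}
        candidates = []
        skips = []
        for v in retained:
            tm = tx_by_id.get(v.transcript_id)
            genotype = hla.get(v.sample_id)
            if tm is None or genotype is None:
                continue
            alleles = sorted(
                {f"HLA-{loc}{a}" for loc in "ABC" for a in genotype[loc] if "*" not in a}
            )
            if not alleles:
                continue
            if v.variant_class == "SNV" and v.consequence == "missense":
                mp = mutant_context_peptide(tm, v)
            elif v.variant_class != "SNV" and v.consequence in ("frameshift", "inframe_indel"):
                mp = frameshift_peptides(tm, v)
            else:
                continue
            if not isinstance(mp, MutantPeptideSet):
                skips.append({"sample_id": v.sample_id, "pos": v.pos, "reason": mp.reason})
                continue
            windows = enumerate_windows(mp)
            preds, _missing = predict_binding(windows, alleles, predictor)
            candidates += call_neoantigens(
                preds, cfg.ic50_max, cfg.rank_max,
                sample_id=v.sample_id, gene=v.gene, mutation_aa=v.protein_change,
            )
        missing_genes = []
        if cfg.run_expression_filter and fpkm is not None:
            missing_genes = expression_filter(
                candidates, fpkm, cfg.min_tumor_fpkm, cfg.min_abs_log2_ratio
            )
        pd.DataFrame(
            [
                {
                    "Sample": c.sample_id, "Identity": c.peptide, "Protein": c.gene,
                    "Mutation AA": c.mutation_aa, "HLA types": c.hla_allele,
                    "Affinity(nM)": c.prediction.ic50_nM, "%Rank": c.prediction.rank_pct,
                    "Expressed": c.expressed,
                }
                for c in candidates
            ]
        ).to_csv(outdir / "neoantigens.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("neoantigens", exc)
    report["stages"]["neoantigens"] = {
        "n_candidates": count_neoantigens(candidates),
        "n_candidates_by_peptide": count_neoantigens(candidates, by_peptide=True),
        "n_skipped_contexts": len(skips),
        "n_expression_missing_genes": len(missing_genes),
        "n_expressed": sum(1 for c in candidates if c.expressed),
    }

    # --- summarize -----------------------------------------------------------
    try:
        neo_by_sample = {
            s: count_neoantigens([c for c in candidates if c.sample_id == s])
            for s in samples
        }
        nonsyn_by_sample = {
            s: sum(1 for v in retained if v.sample_id == s and v.consequence == "missense")
            for s in samples
        }
        rows = []
        for s in samples:
            g = hla.get(s, {})
            rows.append(
                CohortRow(
                    meta=SampleMeta(
                        sample_id=s,
                        group=_group_of(s),
                        hla_a=g.get("A", []),
                        hla_b=g.get("B", []),
                        hla_c=g.get("C", []),
                    ),
                    n_nonsynonymous=nonsyn_by_sample[s],
                    n_neoantigens=neo_by_sample[s],
                )
            )
        table = CohortTable(rows)
        summary: dict = {}
        for grp in ("CC", "CIN"):
            if len(table.subset(grp)):
                bs = burden_summary(table, grp, "n_neoantigens")
                summary[f"{grp}_neoantigens"] = {
                    "mean": round(bs.mean, 1), "min": bs.min, "max": bs.max,
                }
        nz = [r for r in rows if r.n_nonsynonymous or r.n_neoantigens]
        if len(nz) >= 3:
            xs = np.array([r.n_nonsynonymous for r in rows], dtype=float)
            ys = np.array([r.n_neoantigens for r in rows], dtype=float)
            if xs.std() > 0 and ys.std() > 0:
                r_val, _p = mutation_neoantigen_correlation(table)
                summary["mutation_neoantigen_r"] = round(r_val, 4)
        summary["hla_B_1518_CC_pct"] = (
            round(hla_carrier_frequency(table, "B", "15:18", "CC"), 2)
            if len(table.subset("CC"))
            else None
        )
        table.to_frame().to_csv(outdir / "cohort_summary.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("summarize", exc)
    report["stages"]["summarize"] = summary

    cfg.to_yaml(outdir / "run_config.yaml")
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
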