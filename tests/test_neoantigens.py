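"""Peptide contexts, window enumeration, binding prediction, thresholds."""

import numpy as np
import pytest
from Bio.Seq import Seq

from cinneo.neoantigens import (
    BindingPrediction,
    MockBindingPredictor,
    MutantPeptideSet,
    NetMHCpanOutputAdapter,
    SkipRecord,
    TranscriptModel,
    call_neoantigens,
    count_neoantigens,
    enumerate_windows,
    expression_filter,
    frameshift_peptides,
    mutant_context_peptide,
    predict_binding,
)
from cinneo.simulate import FLANK, make_reference
from cinneo.variants import Variant

CODON_FOR = {  # one codon per amino acid used below
    "M": "ATG", "A": "GCT", "H": "CAT", "L": "CTT", "G": "GGT", "K": "AAA",
}


def _transcript_for_protein(protein: str) -> TranscriptModel:
    """Build a single-exon transcript encoding exactly ``protein``."""
    cds = "".join(CODON_FOR.get(aa, str(Seq("NNN"))) for aa in protein)
    assert "N" not in cds
    cds += "TAA"
    chrom_seq = "T" * FLANK + cds + "T" * FLANK
    tm = TranscriptModel(
        transcript_id="txP", gene="GENEP", chrom="chrP", strand="+",
        cds_ranges=[(FLANK + 1, FLANK + len(cds))], cds_seq=cds,
    )
    return tm, chrom_seq


def _snv_at_protein_pos(tm: TranscriptModel, pi0: int, ref_base_off: int = 1):
    """A missense SNV in codon ``pi0`` (0-based), genomic coordinates."""
    off = pi0 * 3 + ref_base_off
    genomic_pos = tm.cds_ranges[0][0] + off
    ref = tm.cds_seq[off]
    for alt in "ACGT":
        if alt == ref:
            continue
        codon = tm.cds_seq[pi0 * 3 : pi0 * 3 + 3]
        mutated = codon[:ref_base_off] + alt + codon[ref_base_off + 1 :]
        old_aa, new_aa = str(Seq(codon).translate()), str(Seq(mutated).translate())
        if new_aa not in ("*", old_aa):
            return Variant(
                chrom=tm.chrom, pos=genomic_pos, ref=ref, alt=alt, variant_class="SNV",
                tumor_depth=50, tumor_alt=20, normal_depth=30, normal_alt=0,
                gene=tm.gene, transcript_id=tm.transcript_id,
                consequence="missense", sample_id="S1",
            ), new_aa
    raise AssertionError("no missense alt at this codon")


@pytest.fixture(scope="module")
def long_transcript():
    protein = ("MAHLGK" * 70)[:400]  # 400-aa protein
    tm, _ = _transcript_for_protein(protein)
    return tm


class TestMissenseContext:
    def test_interior_mutation_gives_22mer_centered_at_index_11(self, long_transcript):
        v, new_aa = _snv_at_protein_pos(long_transcript, 199)  # protein position 200
        mp = mutant_context_peptide(long_transcript, v)
        assert isinstance(mp, MutantPeptideSet)
        assert len(mp.mut_context) == 22
        assert mp.mut_index_1based == 11
        assert mp.mut_context[10] == new_aa
        # exactly one residue differs from wild type
        diffs = [i for i, (a, b) in enumerate(zip(mp.wt_context, mp.mut_context)) if a != b]
        assert diffs == [10]

    def test_near_n_terminus_context_is_truncated(self):
        tm, _ = _transcript_for_protein("MAHLGKAHLGKAH")  # 13-aa protein
        v, _ = _snv_at_protein_pos(tm, 2)  # protein position 3
        mp = mutant_context_peptide(tm, v)
        assert len(mp.mut_context) == 13  # 2 upstream + site + 10 (bounded)
        assert mp.mut_index_1based == 3

    def test_annotated_hotspot_context_shows_substitution(self):
        """An H->L missense yields a context whose central residue is L
        where the wild-type counterpart has H."""
        protein = "MA" + "G" * 1044 + "H" + "K" * 20  # H at protein position 1047
        tm, _ = _transcript_for_protein(protein)
        off = 1046 * 3  # codon CAT; C->T at first base -> TAT? ensure H->L via CTT
        # mutate CAT (H) second base A->T gives CTT (L)
        pos = tm.cds_ranges[0][0] + off + 1
        v = Variant(
            chrom=tm.chrom, pos=pos, ref="A", alt="T", variant_class="SNV",
            tumor_depth=50, tumor_alt=20, normal_depth=30, normal_alt=0,
            gene="PIK3CA", transcript_id=tm.transcript_id,
            consequence="missense", sample_id="T9",
        )
        mp = mutant_context_peptide(tm, v)
        i = mp.mut_index_1based - 1
        assert mp.wt_context[i] == "H" and mp.mut_context[i] == "L"

    def test_stop_creating_snv_is_skip_record(self, long_transcript):
        tm = long_transcript
        # mutate a K codon AAA -> TAA
        pi0 = next(i for i, aa in enumerate(tm.protein) if aa == "K")
        pos = tm.cds_ranges[0][0] + pi0 * 3
        v = Variant(
            chrom=tm.chrom, pos=pos, ref="A", alt="T", variant_class="SNV",
            tumor_depth=50, tumor_alt=20, normal_depth=30, normal_alt=0,
            transcript_id=tm.transcript_id, consequence="missense", sample_id="S1",
        )
        out = mutant_context_peptide(tm, v)
        assert isinstance(out, SkipRecord)
        assert "stop" in out.reason


class TestFrameshift:
    def test_novel_tail_matches_independent_translation(self, long_transcript):
        tm = long_transcript
        # 1-bp deletion mid-CDS
        off = 300
        pos = tm.cds_ranges[0][0] + off
        ref = tm.cds_seq[off : off + 2]
        v = Variant(
            chrom=tm.chrom, pos=pos, ref=ref, alt=ref[0], variant_class="deletion",
            tumor_depth=50, tumor_alt=20, normal_depth=30, normal_alt=0,
            transcript_id=tm.transcript_id, consequence="frameshift", sample_id="S1",
        )
        mp = frameshift_peptides(tm, v)
        assert isinstance(mp, MutantPeptideSet)
        # independent oracle: translate the mutated CDS directly
        mut_cds = tm.cds_seq[: off + 1] + tm.cds_seq[off + 2 :]
        shift_codon = (off + 1) // 3
        oracle_prot = str(Seq(mut_cds[: len(mut_cds) - len(mut_cds) % 3]).translate())
        stop = oracle_prot.find("*", shift_codon)
        oracle_tail = oracle_prot[shift_codon : stop if stop != -1 else None]
        n_up = min(10, shift_codon)
        assert mp.mut_context == tm.protein[shift_codon - n_up : shift_codon] + oracle_tail
        assert mp.mutated_indices == frozenset(range(n_up, n_up + len(oracle_tail)))

    def test_inframe_deletion_routes_to_substitution_like_context(self, long_transcript):
        tm = long_transcript
        off = 299  # codon boundary at 297; 3-bp deletion
        pos = tm.cds_ranges[0][0] + off
        ref = tm.cds_seq[off : off + 4]
        v = Variant(
            chrom=tm.chrom, pos=pos, ref=ref, alt=ref[0], variant_class="deletion",
            tumor_depth=50, tumor_alt=20, normal_depth=30, normal_alt=0,
            transcript_id=tm.transcript_id, consequence="inframe_indel", sample_id="S1",
        )
        mp = frameshift_peptides(tm, v)
        assert isinstance(mp, MutantPeptideSet)
        assert len(mp.mutated_indices) == 1
        assert len(mp.mut_context) <= 22


class TestWindows:
    def _mps(self, context, mutated):
        # frameshift-class carrier so contexts longer than 22 are allowed
        v = Variant(
            chrom="c", pos=1, ref="CT", alt="C", variant_class="deletion",
            tumor_depth=50, tumor_alt=20, normal_depth=30, normal_alt=0,
        )
        return MutantPeptideSet(v, context, context, frozenset(mutated))

    def test_interior_missense_full_context_yields_38_windows(self):
        ctx = "ABCDEFGHIJKLMNOPQRSTUV"  # 22 distinct residues, site at index 10
        windows = enumerate_windows(self._mps(ctx, {10}))
        assert len(windows) == 8 + 9 + 10 + 11

    def test_mutation_at_context_start_yields_one_window_per_length(self):
        ctx = "ABCDEFGHIJKLMNOPQRSTUV"
        windows = enumerate_windows(self._mps(ctx, {0}))
        assert len(windows) == 4
        assert all(w.startswith("A") for w in windows)

    def test_homopolymer_windows_deduplicate(self):
        windows = enumerate_windows(self._mps("A" * 22, {10}))
        assert windows == ["A" * k for k in (8, 9, 10, 11)]

    def test_short_context_yields_nothing(self):
        assert enumerate_windows(self._mps("ABCDEFG", {3})) == []

    def test_equals_brute_force_substring_oracle(self, rng):
        """Window enumeration matches generate-all-substrings-then-filter
        on 200 random contexts."""
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(200):
            n = int(rng.integers(5, 30))
            ctx = "".join(rng.choice(letters, n))
            mut = {int(rng.integers(n))}
            got = enumerate_windows(self._mps(ctx, mut))
            brute = []
            for k in (8, 9, 10, 11):
                for s in range(n - k + 1):
                    pep = ctx[s : s + k]
                    if any(s <= i < s + k for i in mut) and pep not in brute:
                        brute.append(pep)
            assert got == brute

    def test_every_window_covers_the_mutation(self, long_transcript):
        v, _ = _snv_at_protein_pos(long_transcript, 120)
        mp = mutant_context_peptide(long_transcript, v)
        wt = mp.wt_context
        for w in enumerate_windows(mp):
            assert w in mp.mut_context
            assert w not in wt  # SNV windows always differ from wild type


NETMHC_OUTPUT = """\
# NetMHCpan-like output
---------------------------------------------------
 Pos         MHC        Peptide    Core Of Gp Gl Ip Il        Icore        Identity  Score   Aff(nM)   %Rank  BindLevel
---------------------------------------------------
   1  HLA-B15:18      LHGGWTTKM LHGGWTTKM  0  0  0  0  0    LHGGWTTKM     PIK3CA_H1047L 0.42  490.2144  0.1622 <= WB
   2  HLA-B15:18      AAAAAAAA  AAAAAAAA   0  0  0  0  0    AAAAAAAA      decoy         0.01  12000.0   55.0
"""


class TestPredictors:
    def test_mock_predictor_reproducible_and_order_independent(self):
        m1, m2 = MockBindingPredictor(7, 0.3), MockBindingPredictor(7, 0.3)
        p1 = m1.predict("SIINFEKL", "HLA-A02:01")
        p2 = m2.predict("SIINFEKL", "HLA-A02:01")
        assert p1 == p2
        # different seed gives a different stream
        assert MockBindingPredictor(8, 0.3).predict("SIINFEKL", "HLA-A02:01") != p1

    def test_every_peptide_scored_once_per_distinct_allele(self):
        peptides = ["PEPTIDEA", "PEPTIDEB", "PEPTIDEC"]
        alleles = ["HLA-A02:01", "HLA-B15:18", "HLA-A02:01"]  # homozygous dedup
        preds, missing = predict_binding(peptides, alleles, MockBindingPredictor(1))
        assert len(preds) == 3 * 2
        assert not missing

    def test_binder_fraction_recovered(self, rng):
        """With binder fraction f, the retained fraction under the strict
        thresholds falls within 3 binomial standard errors of f."""
        f = 0.1
        predictor = MockBindingPredictor(3, binder_fraction=f)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        peptides = ["".join(rng.choice(letters, 9)) for _ in range(2000)]
        preds, _ = predict_binding(peptides, ["HLA-A02:01"], predictor)
        kept = call_neoantigens(preds)
        se = (f * (1 - f) / len(preds)) ** 0.5
        assert abs(len(kept) / len(preds) - f) <= 3 * se

    def test_adapter_parses_native_output(self, tmp_path):
        p = tmp_path / "out.txt"
        p.write_text(NETMHC_OUTPUT)
        adapter = NetMHCpanOutputAdapter(p)
        pred = adapter.predict("LHGGWTTKM", "HLA-B15:18")
        assert pred.ic50_nM == pytest.approx(490.2144)
        assert pred.rank_pct == pytest.approx(0.1622)
        assert adapter.predict("MISSING", "HLA-B15:18") is None

    def test_adapter_missing_allele_reported(self, tmp_path):
        p = tmp_path / "out.txt"
        p.write_text(NETMHC_OUTPUT)
        preds, missing = predict_binding(
            ["LHGGWTTKM"], ["HLA-B15:18", "HLA-C07:02"], NetMHCpanOutputAdapter(p)
        )
        assert len(preds) == 1
        assert list(missing) == ["HLA-C07:02"]


class TestThresholds:
    def test_strong_binder_retained(self):
        pred = BindingPrediction("LHGGWTTKM", "HLA-B15:18", 490.2144, 0.1622)
        assert len(call_neoantigens([pred])) == 1

    def test_boundary_ic50_rejected(self):
        pred = BindingPrediction("PEPTIDEX", "HLA-A02:01", 500.0, 0.5)
        assert call_neoantigens([pred]) == []

    def test_raising_thresholds_is_monotone(self, rng):
        preds = [
            BindingPrediction(
                f"PEP{i:05d}AA", "HLA-A02:01",
                float(rng.uniform(1, 2000)), float(rng.uniform(0.01, 10)),
            )
            for i in range(500)
        ]
        n1 = len(call_neoantigens(preds, 500, 2))
        n2 = len(call_neoantigens(preds, 1000, 2))
        n3 = len(call_neoantigens(preds, 1000, 5))
        assert n1 <= n2 <= n3

    def test_counting_conventions(self):
        preds = [
            BindingPrediction("PEPTIDEA", "HLA-A02:01", 10, 0.1),
            BindingPrediction("PEPTIDEA", "HLA-B15:18", 10, 0.1),
        ]
        cands = call_neoantigens(preds, sample_id="S1")
        assert count_neoantigens(cands) == 2  # one per (peptide, allele)
        assert count_neoantigens(cands, by_peptide=True) == 1


class TestExpressionFilter:
    def _cands(self, gene):
        pred = BindingPrediction("PEPTIDEA", "HLA-A02:01", 10, 0.1)
        return call_neoantigens([pred], sample_id="S", gene=gene)

    @pytest.mark.parametrize(
        "tumor,normal,expected",
        [
            (0.5, 0.4, True),    # log2 ratio 0.32 over the 0.1 bar
            (1.0, 1.0, False),   # ratio 0
            (0.4, 0.1, False),   # fails tumor >= 0.5 despite large ratio
            (2.0, 0.0, True),    # zero normal handled via pseudocount
        ],
    )
    def test_rule(self, tumor, normal, expected):
        import pandas as pd

        cands = self._cands("G1")
        fpkm = pd.DataFrame({"gene": ["G1"], "tumor_fpkm": [tumor], "normal_fpkm": [normal]})
        missing = expression_filter(cands, fpkm)
        assert missing == []
        assert cands[0].expressed is expected

    def test_missing_gene_leaves_flag_unset(self):
        import pandas as pd

        cands = self._cands("ABSENT")
        fpkm = pd.DataFrame({"gene": ["G1"], "tumor_fpkm": [1.0], "normal_fpkm": [0.1]})
        missing = expression_filter(cands, fpkm)
        assert missing == ["ABSENT"]
        assert cands[0].expressed is None
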