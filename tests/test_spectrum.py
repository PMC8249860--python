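"""Pyrimidine-normalized classification, 96-context catalogs, stage trends."""

import itertools

import numpy as np
import pytest

from cinneo.spectrum import (
    CONTEXT_LABELS,
    SIX_CLASSES,
    MutationCatalog,
    StageSpectrum,
    UnclassifiableBase,
    build_catalog,
    classify_substitution,
    stage_spectra,
    stage_trend,
)
from cinneo.variants import Variant

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class TestClassification:
    def test_purine_reference_folds_to_pyrimidine_strand(self):
        cls, idx = classify_substitution("G", "A", "T", "C")
        assert cls == "C>T"
        assert CONTEXT_LABELS[idx] == "G[C>T]A"

    def test_pyrimidine_reference_kept_as_is(self):
        cls, idx = classify_substitution("C", "T", "A", "G")
        assert cls == "C>T"
        assert CONTEXT_LABELS[idx] == "A[C>T]G"

    def test_all_192_strand_specific_combinations_collapse_to_96(self):
        hits = np.zeros(96, dtype=int)
        for ref in "ACGT":
            for alt in "ACGT":
                if alt == ref:
                    continue
                for left, right in itertools.product("ACGT", repeat=2):
                    _, idx = classify_substitution(ref, alt, left, right)
                    hits[idx] += 1
        # 12 substitutions x 16 flank pairs = 192 inputs, 2 per category
        assert hits.sum() == 192
        assert (hits == 2).all()

    def test_strand_symmetry(self, rng):
        for _ in range(300):
            ref = rng.choice(list("ACGT"))
            alt = rng.choice([b for b in "ACGT" if b != ref])
            left, right = rng.choice(list("ACGT")), rng.choice(list("ACGT"))
            fwd = classify_substitution(ref, alt, left, right)
            rev = classify_substitution(COMP[ref], COMP[alt], COMP[right], COMP[left])
            assert fwd == rev

    def test_non_acgt_base_is_unclassifiable(self):
        with pytest.raises(UnclassifiableBase):
            classify_substitution("N", "T", "A", "A")


def _snv(chrom, pos, ref, alt, sample="S1"):
    return Variant(
        chrom=chrom, pos=pos, ref=ref, alt=alt, variant_class="SNV",
        tumor_depth=50, tumor_alt=10, normal_depth=30, normal_alt=0,
        consequence="missense", sample_id=sample,
    )


class TestCatalog:
    def test_single_snv_single_count(self):
        ref = {"c": "AACGTT"}
        cat = build_catalog([_snv("c", 3, "C", "T")], ref)
        assert cat.n_classified == 1
        assert (cat.context96 > 0).sum() == 1
        assert cat.six_class["C>T"] == 1

    def test_reference_mismatch_is_hard_error(self):
        ref = {"c": "AAAGTT"}
        with pytest.raises(ValueError, match="reference mismatch"):
            build_catalog([_snv("c", 3, "C", "T")], ref)

    def test_contig_end_goes_to_unclassifiable(self):
        ref = {"c": "CAT"}
        cat = build_catalog([_snv("c", 1, "C", "T")], ref)
        assert cat.n_classified == 0 and cat.n_unclassifiable == 1

    def test_conservation_classified_plus_unclassifiable(self, small_cohort, toy_reference):
        reference, _ = toy_reference
        _, variants_by_sample, _ = small_cohort
        for sample, variants in variants_by_sample.items():
            snvs = [v for v in variants if v.variant_class == "SNV"]
            cat = build_catalog(snvs, reference, sample)
            assert cat.n_classified + cat.n_unclassifiable == len(snvs)

    def test_marginal_consistency(self, small_cohort, toy_reference):
        reference, _ = toy_reference
        _, variants_by_sample, _ = small_cohort
        variants = [v for vs in variants_by_sample.values() for v in vs]
        cat = build_catalog(variants, reference)
        assert sum(cat.six_class.values()) == cat.n_classified

    def test_empirical_context_frequencies_track_generator_distribution(self, toy_reference):
        """A 2000-SNV sample drawn from one signature reproduces that
        signature's context distribution to within sampling error."""
        from cinneo.simulate import SimConfig, sample_mutations, synthetic_signature_matrix

        reference, transcripts = toy_reference
        sigs = synthetic_signature_matrix(seed=5)
        cfg = SimConfig(
            seed=5,
            n_samples={"CIN1": 0, "CIN2": 0, "CIN3": 0, "CC": 1},
            mutation_mean={"CIN1": 1, "CIN2": 1, "CIN3": 1, "CC": 2000},
            mutation_dispersion=1e6,  # essentially fixed n
            signature_mixture={
                "CIN1": {"sig1": 1.0}, "CIN2": {"sig1": 1.0},
                "CIN3": {"sig1": 1.0}, "CC": {"sig1": 1.0},
            },
            class_proportions={"missense": 1.0},
            filter_fail_fracs={"I": 0, "II": 0, "III": 0, "IV": 0},
        )
        vbs, truth = sample_mutations(cfg, reference, transcripts, sigs)
        (variants,) = vbs.values()
        cat = build_catalog(variants, reference)
        n = cat.n_classified
        p = sigs.values[:, 0]
        emp = cat.context96 / n
        se = np.sqrt(p * (1 - p) / n)
        within = np.abs(emp - p) <= 3 * se + 1e-12
        # a handful of 3-SE excursions is expected over 96 cells
        assert within.sum() >= 93


class TestStageSpectra:
    def _catalog_with(self, counts_by_class, sample="S"):
        cat = MutationCatalog(sample_id=sample)
        for cls, n in counts_by_class.items():
            idx = SIX_CLASSES.index(cls) * 16
            cat.context96[idx] += n
        return cat

    def test_proportions(self):
        cat = self._catalog_with({"C>T": 9, "T>A": 1})
        (sp,) = stage_spectra({"CC": [cat]})
        assert sp.proportions["C>T"] == pytest.approx(0.9)
        assert sp.proportions["T>A"] == pytest.approx(0.1)

    def test_identical_catalogs_identical_spectra(self):
        cat = self._catalog_with({"C>A": 3, "C>T": 7})
        spectra = stage_spectra({"CIN1": [cat], "CIN2": [cat]})
        assert spectra[0].proportions == spectra[1].proportions

    def test_proportions_sum_to_one(self, small_cohort, toy_reference):
        reference, _ = toy_reference
        _, variants_by_sample, _ = small_cohort
        by_group = {}
        for s, vs in variants_by_sample.items():
            by_group.setdefault(s.split("-")[0], []).append(
                build_catalog([v for v in vs if v.variant_class == "SNV"], reference, s)
            )
        for sp in stage_spectra(by_group):
            assert sum(sp.proportions.values()) == pytest.approx(1.0, abs=1e-9)


class TestStageTrend:
    @staticmethod
    def _spectra(values_by_class):
        stages = ("CIN1", "CIN2", "CIN3", "CC")
        out = []
        for i, g in enumerate(stages):
            props = {}
            for cls in SIX_CLASSES:
                props[cls] = values_by_class.get(cls, [0, 0, 0, 0])[i]
            rest = 1 - sum(props.values())
            # park remaining mass in a class not under test
            filler = next(c for c in SIX_CLASSES if c not in values_by_class)
            props[filler] += rest
            out.append(StageSpectrum(g, props))
        return out

    def test_reported_transition_fractions_are_increasing(self):
        """The dominant-transition fractions 56% / 56.25% / 61.22% / 63.47%
        across the four stages classify as a gradual increase."""
        spectra = self._spectra({"C>T": [0.56, 0.5625, 0.6122, 0.6347]})
        assert stage_trend(spectra)["C>T"] == "increasing"

    def test_constant_is_non_monotonic(self):
        spectra = self._spectra({"C>T": [0.3, 0.3, 0.3, 0.3]})
        assert stage_trend(spectra)["C>T"] == "non-monotonic"

    def test_zigzag_is_non_monotonic(self):
        spectra = self._spectra({"C>A": [0.3, 0.1, 0.2, 0.4]})
        assert stage_trend(spectra)["C>A"] == "non-monotonic"

    def test_missing_stage_is_error(self):
        spectra = self._spectra({"C>T": [0.3, 0.4, 0.5, 0.6]})[:3]
        with pytest.raises(ValueError, match="missing stages"):
            stage_trend(spectra)

    def test_programmed_rising_fraction_detected(self, toy_reference):
        """Stage mixtures programmed so one signature's dominant contexts
        rise toward carcinoma yield an increasing trend call."""
        from cinneo.simulate import SimConfig, sample_mutations, synthetic_signature_matrix

        reference, transcripts = toy_reference
        sigs = synthetic_signature_matrix(seed=2)
        # sig columns differ in C>T mass; ramp exposure of the heaviest
        col_ct = sigs.values[32:48, :].sum(axis=0)
        hi = f"sig{int(np.argmax(col_ct)) + 1}"
        lo = f"sig{int(np.argmin(col_ct)) + 1}"
        ramps = [0.05, 0.35, 0.65, 0.95]
        mixture = {
            stage: {hi: w, lo: 1 - w}
            for stage, w in zip(("CIN1", "CIN2", "CIN3", "CC"), ramps)
        }
        cfg = SimConfig(
            seed=2,
            n_samples={s: 1 for s in mixture},
            mutation_mean={s: 3000 for s in mixture},
            mutation_dispersion=1e6,
            signature_mixture=mixture,
            class_proportions={"missense": 1.0},
            filter_fail_fracs={"I": 0, "II": 0, "III": 0, "IV": 0},
        )
        vbs, _ = sample_mutations(cfg, reference, transcripts, sigs)
        by_group = {
            s.split("-")[0]: [build_catalog(vs, reference, s)] for s, vs in vbs.items()
        }
        trend = stage_trend(stage_spectra(by_group))
        assert trend["C>T"] == "increasing"
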