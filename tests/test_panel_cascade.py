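"""Filter cascade: stage semantics, ledger conservation, boundaries."""

import warnings

import pytest

from editscreen.panel_cascade import (
    FilterLedger,
    PipelineThresholds,
    filter_germline,
    filter_synonymous,
    flag_chip_genes,
    reproducible_variants,
    run_panel_cascade,
    strict_cas9_filter,
    subtract_mock,
)
from editscreen.variant_model import SampleRecord, VariantCall, VariantKey


def _call(pos, ref="A", alt="G", alt_reads=50, depth=100, **kw):
    return VariantCall("chr1", pos, ref, alt, alt_reads, depth, **kw)


def _sample(variants, replicate=1, treatment="MOCK", donor="D1", timepoint=4):
    return SampleRecord(
        sample_id=f"{donor}_{treatment}_d{timepoint}_r{replicate}",
        donor=donor,
        treatment=treatment,
        timepoint_days=timepoint,
        replicate=replicate,
        variants=variants,
        median_exon_coverage=3000.0,
    )


class TestReproducibleVariants:
    def test_identical_replicates_fully_concordant(self):
        reps = [_sample([_call(100), _call(200)], replicate=i) for i in (1, 2, 3)]
        pooled, concordance = reproducible_variants(reps)
        assert concordance == 1.0
        assert {v.key.pos for v in pooled} == {100, 200}

    def test_partial_overlap_hand_computed(self):
        # {A,B}, {A,B}, {A}: intersection {A}, union {A,B} -> 0.5
        a, b = _call(100), _call(200)
        reps = [
            _sample([a, b], 1),
            _sample([a, b], 2),
            _sample([a], 3),
        ]
        pooled, concordance = reproducible_variants(reps)
        assert [v.key.pos for v in pooled] == [100]
        assert concordance == 0.5

    def test_disjoint_replicates_empty(self):
        reps = [_sample([_call(100)], 1), _sample([_call(200)], 2)]
        pooled, concordance = reproducible_variants(reps)
        assert pooled == [] and concordance == 0.0

    def test_depths_pooled_by_summation(self):
        reps = [
            _sample([_call(100, alt_reads=10, depth=1000)], 1),
            _sample([_call(100, alt_reads=14, depth=1200)], 2),
        ]
        pooled, _ = reproducible_variants(reps)
        assert pooled[0].alt_reads == 24 and pooled[0].depth == 2200

    def test_mixed_conditions_rejected(self):
        reps = [
            _sample([_call(100)], 1, donor="D1"),
            _sample([_call(100)], 1, donor="D2"),
        ]
        with pytest.raises(ValueError, match="mixed"):
            reproducible_variants(reps)

    def test_single_replicate_is_identity(self):
        sample = _sample([_call(100)])
        pooled, concordance = reproducible_variants([sample])
        assert concordance == 1.0 and len(pooled) == 1


class TestPerVariantFilters:
    def test_synonymous_removed_others_kept(self):
        variants = [
            _call(1, effect="synonymous"),
            _call(2, effect="missense"),
            _call(3, ref="AT", alt="A", effect="frameshift"),
            _call(4, effect="noncoding"),
        ]
        kept, removed = filter_synonymous(variants)
        assert [v.pos for v in kept] == [2, 3, 4]
        assert [k.pos for k, _ in removed] == [1]

    def test_unannotated_passes_with_warning(self):
        with pytest.warns(UserWarning, match="no effect annotation"):
            kept, removed = filter_synonymous([_call(1)])
        assert len(kept) == 1 and not removed

    def test_germline_boundary_is_strictly_greater_than(self):
        """Occurrence count 10 is retained, 11 removed, at threshold 10."""
        v10, v11, v_absent = _call(1), _call(2), _call(3)
        db = {v10.key: 10, v11.key: 11}
        kept, removed = filter_germline([v10, v11, v_absent], db, 10)
        assert [v.pos for v in kept] == [1, 3]
        assert [k.pos for k, _ in removed] == [2]

    def test_mock_subtraction_is_key_exact(self):
        treated = [_call(100, alt="G"), _call(200)]
        mock_keys = [VariantKey("chr1", 100, "A", "T")]  # different ALT
        kept, removed = subtract_mock(treated, mock_keys)
        assert len(kept) == 2 and not removed
        kept, removed = subtract_mock(treated, [treated[0].key])
        assert [v.pos for v in kept] == [200]

    def test_mock_subtraction_ignores_vaf(self):
        treated = [_call(100, alt_reads=90, depth=100)]  # VAF 0.9
        kept, removed = subtract_mock(treated, [treated[0].key])
        assert not kept and removed[0][1] == "present_in_mock"

    def test_chip_flagging_is_annotation_only(self):
        variants = [_call(1, gene="DNMT3A"), _call(2, gene="TP53"), _call(3)]
        flagged = flag_chip_genes(variants, {"DNMT3A", "TET2"})
        assert [v.pos for v in flagged] == [1]
        assert flag_chip_genes(variants, set()) == []


class TestStrictFilter:
    def test_snvs_removed_even_with_perfect_homology(self):
        from editscreen.guide_homology import GuideRNA

        spacer = "C" * 20
        seq = "A" * 50 + spacer + "TGG" + "A" * 50
        guide = GuideRNA("g", spacer, "NGG", "chr1", 67, "+")
        snv = _call(60, ref=seq[59], alt="T")
        indel = VariantCall("chr1", 60, seq[59], seq[59] + "TT", 30, 100)
        far_indel_seq = {"chr1": "A" * 200}
        kept, removed = strict_cas9_filter([snv, indel], guide, {"chr1": seq})
        assert [v.variant_class for v in kept] == ["INS"]
        assert removed[0][1] == "strict:SNV"
        # a non-homologous indel is removed too
        lone = VariantCall("chr1", 100, "A", "ATT", 30, 100)
        kept, removed = strict_cas9_filter([lone], guide, far_indel_seq)
        assert not kept and "no_homology" in removed[0][1]


class TestLedger:
    def test_conservation_enforced(self):
        ledger = FilterLedger()
        variants = [_call(1), _call(2)]
        with pytest.raises(AssertionError, match="ledger stage"):
            ledger.record("bad", variants, [variants[0]], [])

    def test_counts_non_increasing(self):
        ledger = FilterLedger()
        a, b = _call(1), _call(2)
        ledger.record("s1", [a, b], [a], [(b.key, "x")])
        with pytest.raises(AssertionError, match="exceeds previous"):
            ledger.record("s2", [a, b], [a, b], [])


class TestFullCascade:
    @staticmethod
    def _run(bundle, **kw):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return run_panel_cascade(
                bundle.samples,
                PipelineThresholds(),
                bundle.guides,
                bundle.reference,
                bundle.germline_db,
                **kw,
            )

    def test_ledger_conserves_and_decreases_everywhere(self, small_bundle):
        results = self._run(small_bundle)
        for res in results.values():
            counts = []
            for stage in res.ledger.stages:
                assert stage.input_count == stage.output_count + len(stage.removed)
                counts.append((stage.input_count, stage.output_count))
            for (_, out_prev), (in_next, _) in zip(counts, counts[1:]):
                assert in_next <= out_prev

    def test_synonymous_and_germline_stages_commute(self, small_bundle):
        """Both are per-variant predicates: order cannot change the result."""
        from editscreen.panel_cascade import reproducible_variants

        samples = [
            s
            for s in small_bundle.samples
            if s.donor == "D1" and s.treatment == "MOCK" and s.timepoint_days == 10
        ]
        pooled, _ = reproducible_variants(samples)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a1, _ = filter_synonymous(pooled)
            a2, _ = filter_germline(a1, small_bundle.germline_db)
            b1, _ = filter_germline(pooled, small_bundle.germline_db)
            b2, _ = filter_synonymous(b1)
        assert {v.key for v in a2} == {v.key for v in b2}

    def test_planted_homologous_off_target_survives_all_stages(self, small_bundle):
        results = self._run(small_bundle, strict=True)
        off_keys = {
            r.key
            for r in small_bundle.truth.by_category("off_target_edit")
        }
        res = results[("D1", "ZFPM2", 10)]
        final_keys = {v.key for v in res.final_variants}
        assert off_keys <= final_keys

    def test_missing_mock_arm_raises(self, small_bundle):
        treated_only = [s for s in small_bundle.samples if s.treatment != "MOCK"]
        with pytest.raises(ValueError, match="no Mock arm"):
            self._run(
                type(small_bundle)(
                    **{**small_bundle.__dict__, "samples": treated_only}
                )
            )

    def test_germline_only_cohort_fully_filtered(self, edit_free_config):
        import dataclasses

        from editscreen.synthetic_cohort import generate_cohort

        cfg = dataclasses.replace(
            edit_free_config,
            noise_rate=0.0,
            chimerism_per_donor=0,
            germline_db_holdout_fraction=0.0,
            n_germline_per_donor=150,
        )
        bundle = generate_cohort(cfg)
        results = self._run(bundle)
        for res in results.values():
            assert res.final_variants == []
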