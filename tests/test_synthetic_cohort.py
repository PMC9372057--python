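"""Synthetic cohort generator: determinism, calibration, truth integrity."""

import dataclasses
import os

import numpy as np
import pytest

from editscreen.guide_homology import best_homology
from editscreen.synthetic_cohort import (
    CohortConfig,
    PlantedEdit,
    generate_cohort,
    simulate_reference,
    write_cohort,
)


def test_cohort_size_matches_design(small_bundle):
    """3 donors x 4 treatments x {4,10} x 3 reps + 3 day-0 Mock = 75."""
    assert len(small_bundle.samples) == 75
    day0 = [s for s in small_bundle.samples if s.timepoint_days == 0]
    assert len(day0) == 3
    assert all(s.treatment == "MOCK" and s.replicate == 1 for s in day0)


def test_same_seed_byte_identical_files(tmp_path, small_config):
    out_a, out_b = str(tmp_path / "a"), str(tmp_path / "b")
    write_cohort(generate_cohort(small_config), out_a)
    write_cohort(generate_cohort(small_config), out_b)
    for root, _, files in os.walk(out_a):
        for name in files:
            rel = os.path.relpath(os.path.join(root, name), out_a)
            with open(os.path.join(out_a, rel), "rb") as fa, open(
                os.path.join(out_b, rel), "rb"
            ) as fb:
                assert fa.read() == fb.read(), rel


def test_different_seed_differs(small_config):
    other = generate_cohort(dataclasses.replace(small_config, seed=8))
    base = generate_cohort(small_config)
    assert base.reference != other.reference


def test_gene_models_satisfy_invariants(small_bundle):
    for model in small_bundle.gene_models:
        assert model.cds_length % 3 == 0
        model.validate_against(small_bundle.reference)  # ATG start, stop end


def test_engineered_off_target_scores_requested_match_count():
    cfg = CohortConfig(
        seed=5,
        guide_names=("AAVS1",),
        planted_edits=(
            PlantedEdit(guide="AAVS1", kind="on_target"),
            PlantedEdit(
                guide="AAVS1",
                kind="off_target",
                homology_match_count=22,
                vaf_by_timepoint={4: 0.1, 10: 0.1},
            ),
        ),
    )
    reference, _, guides, sites = simulate_reference(cfg)
    guide = guides["AAVS1"]
    off = [s for s in sites if s.edit.kind == "off_target"][0]
    seq = reference[cfg.chrom]
    window = seq[off.cut_pos - 40 : off.cut_pos + 40]
    count, _, _ = best_homology(window, guide.spacer, guide.pam)
    assert count == 22


def test_on_target_site_is_perfect_match(small_bundle):
    for guide in small_bundle.guides.values():
        seq = small_bundle.reference[guide.target_chrom]
        window = seq[guide.cut_pos - 40 : guide.cut_pos + 40]
        assert best_homology(window, guide.spacer, guide.pam)[0] == 23


def test_truth_categories_unique_and_conserved(small_bundle):
    cfg = small_bundle.config
    seen = set()
    for r in small_bundle.truth.records:
        ident = (r.donor, r.key)
        assert ident not in seen
        seen.add(ident)
    germline = [
        r
        for r in small_bundle.truth.records
        if r.category in ("germline_het", "germline_hom")
    ]
    assert len(germline) == cfg.n_germline_per_donor * cfg.n_donors
    chim = small_bundle.truth.by_category("chimerism")
    assert len(chim) == cfg.chimerism_per_donor * cfg.n_donors


def test_germline_hets_have_true_vaf_half_and_homs_one(small_bundle):
    for r in small_bundle.truth.by_category("germline_het"):
        assert r.true_vaf == 0.5
    for r in small_bundle.truth.by_category("germline_hom"):
        assert r.true_vaf == 1.0


def test_mock_samples_contain_no_edit_keys(small_bundle):
    edit_keys = {
        r.key
        for r in small_bundle.truth.records
        if r.category.endswith("_edit")
    }
    for s in small_bundle.samples:
        if s.treatment == "MOCK":
            assert not (s.key_set & edit_keys)


def test_zero_noise_mock_emits_only_planted_truth(edit_free_config):
    cfg = dataclasses.replace(edit_free_config, noise_rate=0.0)
    bundle = generate_cohort(cfg)
    truth_keys = {r.key for r in bundle.truth.records}
    for s in bundle.samples:
        assert s.key_set <= truth_keys


def test_germline_vaf_calibration_binomial_clt(default_bundle):
    """Mean observed het VAF within 0.5 +/- 3*sqrt(0.25/2000) at depth >= 2000."""
    het_keys = {r.key for r in default_bundle.truth.by_category("germline_het")}
    vafs = [
        v.vaf
        for s in default_bundle.samples
        for v in s.variants
        if v.key in het_keys and v.depth >= 2000
    ]
    assert len(vafs) >= 100
    n_eff = 2000  # conservative: every included call has at least this depth
    assert abs(np.mean(vafs) - 0.5) < 3 * np.sqrt(0.25 / n_eff)


def test_observed_edit_vaf_tracks_planted_trajectory(default_bundle):
    """Pooled off-target VAF stays inside the 99% binomial envelope."""
    off = default_bundle.truth.by_category("off_target_edit")
    by_tp = {4: 0.0, 10: 0.0}
    for tp in by_tp:
        total = 0.0
        n = 0
        for s in default_bundle.samples:
            if s.treatment != "ZFPM2" or s.timepoint_days != tp:
                continue
            by_key = s.by_key()
            total += sum(by_key[r.key].vaf for r in off if r.key in by_key)
            n += 1
        assert n > 0
        by_tp[tp] = total / n
    assert by_tp[4] == pytest.approx(0.217, abs=0.02)
    assert by_tp[10] == pytest.approx(0.169, abs=0.02)


def test_config_round_trips_through_yaml(tmp_path, small_config):
    import yaml

    path = tmp_path / "cfg.yaml"
    path.write_text(yaml.safe_dump(small_config.to_dict()))
    back = CohortConfig.from_dict(yaml.safe_load(path.read_text()))
    assert back == small_config


def test_unknown_config_keys_rejected():
    with pytest.raises(ValueError, match="unknown config keys"):
        CohortConfig.from_dict({"n_donor": 3})


def test_config_referencing_unknown_guide_rejected():
    with pytest.raises(ValueError, match="unknown guide"):
        CohortConfig(
            guide_names=("AAVS1",),
            planted_edits=(PlantedEdit(guide="HBB", kind="on_target"),),
        )
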