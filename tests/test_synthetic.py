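"""Generator contracts: defining formulas, determinism, label conservation."""

import numpy as np
import pandas as pd
import pytest

from scnscreen.synthetic import (
    AtlasDesign,
    CircadianDesign,
    condition_label,
    generate_actogram,
    generate_circadian_timecourse,
    generate_light_pulse_set,
    generate_mua,
    generate_tissue_atlas,
    random_light_effects,
    _trajectory,
)


def _single_cycler_truth(period=24.0, phase=6.0, amp=50.0, baseline=100.0):
    return pd.DataFrame(
        {
            "is_cycler": [True],
            "true_period": [period],
            "true_phase": [phase],
            "true_amplitude": [amp],
            "baseline": [baseline],
        },
        index=pd.Index(["ps_00000"], name="probeset"),
    )


class TestCircadianTimecourse:
    def test_noiseless_cosine_peak(self, ct_times):
        """A noiseless 24-h cycler peaking at CT6 reads exactly
        baseline + amplitude at CT30."""
        signal = _trajectory(_single_cycler_truth(), ct_times)
        at_ct30 = signal[0, list(ct_times).index(30.0)]
        assert at_ct30 == pytest.approx(150.0, abs=1e-12)
        # trough at CT18 and CT42
        assert signal[0, 0] == pytest.approx(50.0, abs=1e-12)

    def test_noiseless_matrix_matches_trajectory(self):
        design = CircadianDesign(n_probesets=20, frac_cyclers=1.0,
                                 noise_cv=0.0, seed=3)
        matrix, truth = generate_circadian_timecourse(design)
        expected = _trajectory(truth, design.times)
        np.testing.assert_allclose(matrix.to_numpy(), expected, rtol=1e-14)

    def test_no_cyclers_means_flat_rows(self):
        design = CircadianDesign(n_probesets=50, frac_cyclers=0.0,
                                 noise_cv=0.0, seed=0)
        matrix, truth = generate_circadian_timecourse(design)
        assert truth["is_cycler"].sum() == 0
        assert np.allclose(matrix.std(axis=1), 0.0)

    def test_determinism(self):
        design = CircadianDesign(n_probesets=30, seed=1)
        m1, t1 = generate_circadian_timecourse(design)
        m2, t2 = generate_circadian_timecourse(design)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_labels_cover_every_probeset(self):
        design = CircadianDesign(n_probesets=77, seed=5)
        matrix, truth = generate_circadian_timecourse(design)
        assert list(matrix.index) == list(truth.index)
        assert len(truth) == 77

    def test_all_intensities_positive(self):
        design = CircadianDesign(n_probesets=200, noise_cv=0.3,
                                 amplitude_rel=0.9, seed=2)
        matrix, _ = generate_circadian_timecourse(design)
        assert (matrix.to_numpy() > 0).all()

    def test_columns_span_ct18_to_ct64(self):
        matrix, _ = generate_circadian_timecourse(CircadianDesign(n_probesets=1))
        assert matrix.columns[0] == "CT18"
        assert matrix.columns[-1] == "CT64"
        assert matrix.shape[1] == 24

    def test_amplitude_rel_of_one_rejected(self):
        with pytest.raises(ValueError, match="amplitude_rel"):
            CircadianDesign(amplitude_rel=1.0)


class TestLightPulseSet:
    def test_identity_when_no_effects_and_no_noise(self):
        design = CircadianDesign(n_probesets=10, noise_cv=0.0, seed=0)
        pairs, truth = generate_light_pulse_set(design)
        for cond in {c for c, _ in pairs.columns}:
            np.testing.assert_array_equal(pairs[(cond, "light")],
                                          pairs[(cond, "dark")])
        assert not truth["any_induced"].any()
        assert (truth.filter(like="fold:") == 1.0).all().all()

    def test_planted_fold_appears_only_at_its_condition(self):
        design = CircadianDesign(n_probesets=5, noise_cv=0.0, seed=0)
        target = condition_label(40, 1)
        pairs, truth = generate_light_pulse_set(
            design, {"ps_00002": {target: 3.0}})
        ratios = {
            cond: pairs.loc["ps_00002", (cond, "light")]
            / pairs.loc["ps_00002", (cond, "dark")]
            for cond in {c for c, _ in pairs.columns}
        }
        assert ratios.pop(target) == pytest.approx(3.0, rel=1e-12)
        assert all(r == pytest.approx(1.0, rel=1e-12) for r in ratios.values())
        assert truth.loc["ps_00002", f"class:{target}"] == "induced"

    def test_nine_paired_conditions(self):
        pairs, _ = generate_light_pulse_set(
            CircadianDesign(n_probesets=3, seed=0))
        assert len({c for c, _ in pairs.columns}) == 9
        assert pairs.shape[1] == 18

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError, match="fold"):
            generate_light_pulse_set(
                CircadianDesign(n_probesets=3),
                {"ps_00000": {condition_label(30, 1): 0.0}},
            )

    def test_random_effects_disjoint_sets(self):
        ids = [f"ps_{i:05d}" for i in range(50)]
        effects = random_light_effects(ids, n_induced=10, n_suppressed=10, seed=4)
        assert len(effects) == 20
        folds = {f for m in effects.values() for f in m.values()}
        assert folds == {3.0, 0.25}


class TestTissueAtlas:
    def test_noiseless_enrichment_factor(self):
        design = CircadianDesign(n_probesets=30, frac_cyclers=0.0,
                                 noise_cv=0.0, seed=1)
        matrix, _ = generate_circadian_timecourse(design)
        atlas = generate_tissue_atlas(
            AtlasDesign(frac_enriched=0.5, enrichment_factor=10.0,
                        noise_cv=0.0, seed=1),
            matrix,
        )
        enr = atlas.truth["is_scn_enriched"].to_numpy()
        scn = atlas.values["SCN"].to_numpy()
        other = atlas.values.drop(columns="SCN").to_numpy()
        np.testing.assert_allclose(other[enr] / scn[enr][:, None], 0.1,
                                   rtol=1e-12)
        np.testing.assert_allclose(other[~enr] / scn[~enr][:, None], 1.0,
                                   rtol=1e-12)

    def test_scn_column_is_timecourse_median(self):
        design = CircadianDesign(n_probesets=12, seed=7)
        matrix, _ = generate_circadian_timecourse(design)
        atlas = generate_tissue_atlas(AtlasDesign(seed=7), matrix)
        np.testing.assert_array_equal(atlas.values["SCN"],
                                      matrix.median(axis=1))

    def test_column_structure(self):
        matrix, _ = generate_circadian_timecourse(
            CircadianDesign(n_probesets=2, seed=0))
        atlas = generate_tissue_atlas(AtlasDesign(seed=0), matrix)
        assert atlas.values.shape[1] == 165  # 82 x 2 + SCN
        meta = atlas.tissues
        assert meta["is_scn"].sum() == 1
        assert meta["is_hypothalamus"].sum() == 2
        assert meta["is_neural"].sum() == 2 * 14 + 1  # incl. SCN

    def test_wrong_replicate_count_rejected(self):
        with pytest.raises(ValueError, match="82 x 2"):
            AtlasDesign(replicates=3)


class TestActogram:
    def test_ld_onsets_at_lights_off(self):
        res = generate_actogram(schedule="LD", n_days=5, deterministic=True)
        assert np.allclose(res.true_onsets_h % 24.0, 12.0)

    def test_dd_onsets_spaced_by_tau(self):
        res = generate_actogram(schedule="DD", tau=23.6, n_days=8,
                                deterministic=True)
        assert np.allclose(np.diff(res.true_onsets_h), 23.6)

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            generate_actogram(bin_min=7)

    def test_determinism(self):
        a = generate_actogram(seed=9)
        b = generate_actogram(seed=9)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_shift_moves_onset_at_reentrain_rate(self):
        res = generate_actogram(schedule="LD", n_days=20, shift_h=-8.0,
                                shift_day=5, reentrain_rate=1.0,
                                deterministic=True)
        phases = res.true_onsets_h % 24.0
        # 1 h/day toward the 8-h advance, saturating at the new phase
        expected = np.concatenate([np.full(5, 12.0),
                                   12.0 - np.minimum(np.arange(15), 8)])
        np.testing.assert_allclose(phases, expected)


class TestMUA:
    def test_synchronous_population_has_unit_resultant(self):
        res = generate_mua(n_channels=10, phase_sd=0.0, desync_rate=0.0,
                           n_days=3, seed=0)
        for d in range(3):
            ang = res.phases[d] * 2 * np.pi / 24.0
            R = np.abs(np.exp(1j * ang).mean())
            assert R == pytest.approx(1.0, abs=1e-12)

    def test_label_conservation_and_positivity(self):
        res = generate_mua(n_channels=7, n_days=2, noise_sd=2.0, seed=1)
        assert res.data.shape[1] == 7
        assert res.phases.shape == (2, 7)
        assert (res.data.to_numpy() >= 0).all()

    def test_desync_spreads_phases(self):
        res = generate_mua(n_channels=200, phase_sd=0.5, desync_rate=2.0,
                           n_days=4, seed=2)
        spreads = [np.std(res.phases[d]) for d in range(4)]
        assert spreads == sorted(spreads)

    def test_resync_event_contracts_phases(self):
        kw = dict(n_channels=100, phase_sd=4.0, desync_rate=0.0, n_days=2, seed=3)
        free = generate_mua(**kw)
        rescued = generate_mua(resync_schedule=[1], resync_factor=0.8, **kw)
        assert np.std(rescued.phases[1]) < np.std(free.phases[1])

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError, match="channels"):
            generate_mua(n_channels=1)
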