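"""SCN enrichment Z-scores, shortlist thresholds and tissue clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scnscreen.enrichment import (
    EnrichmentThresholds,
    TissueEnrichmentScorer,
    enrichment_scores,
    nearest_tissue,
    passes_thresholds,
    scn_summary_value,
    shortlist_enriched,
)
from scnscreen.synthetic import AtlasDesign, CircadianDesign, \
    generate_circadian_timecourse, generate_tissue_atlas


def _atlas(scn: float, others: float, n_probesets: int = 1):
    meta = AtlasDesign().tissue_table()
    vals = pd.DataFrame(others, index=[f"ps_{i}" for i in range(n_probesets)],
                        columns=meta.index[~meta["is_scn"]])
    vals["SCN"] = scn
    return vals, meta


class TestScnSummary:
    def test_constant_row(self):
        assert scn_summary_value(np.full(24, 100.0)) == 100.0

    def test_even_count_median(self):
        assert scn_summary_value(np.arange(1, 25)) == 12.5

    def test_noiseless_cycler_median_near_mesor(self, ct_times):
        y = 150.0 + 50.0 * np.cos(2 * np.pi * (ct_times - 6.0) / 24.0)
        assert scn_summary_value(y) == pytest.approx(150.0, abs=10.0)
        assert scn_summary_value(y) == np.median(y)

    def test_wrong_sample_count_rejected(self):
        with pytest.raises(ValueError, match="24"):
            scn_summary_value(np.ones(23))


class TestEnrichmentScores:
    def test_flat_probeset_scores_zero(self):
        vals, meta = _atlas(scn=100.0, others=100.0)
        s = enrichment_scores(vals, meta).iloc[0]
        assert s["z_all"] == 0.0
        assert s["z_neural"] == 0.0
        assert s["ratio_scn_hyp"] == 1.0
        assert not s["passes"]

    def test_hand_arithmetic_on_stated_vectors(self):
        """SCN=1000 over a flat background of 100: z computed by direct
        arithmetic on the 165- and 29-value vectors."""
        vals, meta = _atlas(scn=1000.0, others=100.0)
        s = enrichment_scores(vals, meta).iloc[0]
        v_all = np.array([100.0] * 164 + [1000.0])
        v_neu = np.array([100.0] * 28 + [1000.0])
        assert s["z_all"] == pytest.approx(
            (1000 - v_all.mean()) / v_all.std(ddof=1), rel=1e-12)
        assert s["z_neural"] == pytest.approx(
            (1000 - v_neu.mean()) / v_neu.std(ddof=1), rel=1e-12)
        assert s["ratio_scn_hyp"] == pytest.approx(10.0, rel=1e-12)
        assert s["passes"]

    def test_boundary_threshold_semantics(self):
        # >= for the three scores, strict > for the median
        assert passes_thresholds(1.63, 1.44, 6.0, 200.1)
        assert not passes_thresholds(1.63, 1.44, 6.0, 200.0)
        assert not passes_thresholds(1.6299, 1.44, 6.0, 300.0)
        assert not passes_thresholds(1.63, 1.4399, 6.0, 300.0)
        assert not passes_thresholds(1.63, 1.44, 5.999, 300.0)

    def test_population_sd_option_changes_z(self):
        vals, meta = _atlas(scn=1000.0, others=100.0)
        z1 = enrichment_scores(vals, meta, ddof=1).iloc[0]["z_all"]
        z0 = enrichment_scores(vals, meta, ddof=0).iloc[0]["z_all"]
        assert z0 > z1  # population SD is smaller

    @given(st.floats(min_value=0.01, max_value=1000.0))
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(0)
        meta = AtlasDesign().tissue_table()
        row = rng.uniform(50, 500, len(meta))
        vals = pd.DataFrame([row], index=["ps"], columns=meta.index)
        s1 = enrichment_scores(vals, meta).iloc[0]
        s2 = enrichment_scores(vals * c, meta).iloc[0]
        assert s2["z_all"] == pytest.approx(s1["z_all"], rel=1e-9)
        assert s2["z_neural"] == pytest.approx(s1["z_neural"], rel=1e-9)
        assert s2["ratio_scn_hyp"] == pytest.approx(s1["ratio_scn_hyp"], rel=1e-9)


class TestShortlist:
    def test_noiseless_planted_set_recovered_exactly(self):
        design = CircadianDesign(n_probesets=60, frac_cyclers=0.0,
                                 noise_cv=0.0,
                                 baseline_log_mean=np.log(1000.0), seed=2)
        matrix, _ = generate_circadian_timecourse(design)
        atlas = generate_tissue_atlas(
            AtlasDesign(frac_enriched=0.2, noise_cv=0.0, seed=2), matrix)
        short = shortlist_enriched(atlas.values, atlas.tissues)
        planted = set(atlas.truth.index[atlas.truth["is_scn_enriched"]])
        assert set(short.index) == planted

    def test_empty_planted_set_gives_empty_shortlist(self):
        design = CircadianDesign(n_probesets=30, frac_cyclers=0.0,
                                 noise_cv=0.0, seed=3)
        matrix, _ = generate_circadian_timecourse(design)
        atlas = generate_tissue_atlas(
            AtlasDesign(frac_enriched=0.0, noise_cv=0.0, seed=3), matrix)
        assert len(shortlist_enriched(atlas.values, atlas.tissues)) == 0

    def test_ordering_by_descending_z_all(self):
        design = CircadianDesign(n_probesets=100, frac_cyclers=0.0,
                                 baseline_log_mean=np.log(1000.0), seed=4)
        matrix, _ = generate_circadian_timecourse(design)
        atlas = generate_tissue_atlas(AtlasDesign(frac_enriched=0.3, seed=4),
                                      matrix)
        short = shortlist_enriched(atlas.values, atlas.tissues)
        z = short["z_all"].to_numpy()
        assert (np.diff(z) <= 1e-12).all()

    def test_recall_monotone_in_enrichment_factor(self):
        design = CircadianDesign(n_probesets=150, frac_cyclers=0.0,
                                 baseline_log_mean=np.log(1000.0), seed=5)
        matrix, _ = generate_circadian_timecourse(design)
        recalls = []
        for factor in (2.0, 5.0, 10.0):
            atlas = generate_tissue_atlas(
                AtlasDesign(frac_enriched=0.2, enrichment_factor=factor,
                            seed=5), matrix)
            short = shortlist_enriched(atlas.values, atlas.tissues)
            planted = set(atlas.truth.index[atlas.truth["is_scn_enriched"]])
            recalls.append(len(set(short.index) & planted) / len(planted))
        assert recalls == sorted(recalls)


class TestNearestTissue:
    def _random_atlas(self, seed=0, hyp_like_scn=True):
        rng = np.random.default_rng(seed)
        meta = AtlasDesign().tissue_table()
        n_genes = 40
        scn_prof = rng.uniform(100, 1000, n_genes)
        vals = pd.DataFrame(index=[f"ps_{i}" for i in range(n_genes)],
                            columns=meta.index, dtype=float)
        for col, row in meta.iterrows():
            if row["is_scn"]:
                vals[col] = scn_prof
            elif row["is_hypothalamus"] and hyp_like_scn:
                vals[col] = scn_prof + rng.normal(0, 10, n_genes)
            else:
                vals[col] = rng.uniform(100, 1000, n_genes)
        return vals, meta

    def test_hypothalamus_is_nearest_when_correlated(self):
        vals, meta = self._random_atlas()
        nearest, ranking, tree = nearest_tissue(vals, meta)
        assert nearest == "hypothalamus"
        assert ranking.index[0] == "hypothalamus"

    def test_anticorrelated_tissue_ranks_last(self):
        vals, meta = self._random_atlas(seed=1)
        anti_col = [c for c in meta.index if c.startswith("tissue_20")]
        for c in anti_col:
            vals[c] = 1100.0 - vals["SCN"]
        _, ranking, _ = nearest_tissue(vals, meta)
        assert ranking.index[-1] == "tissue_20"

    def test_identical_tissues_merge_at_zero_distance(self):
        vals, meta = self._random_atlas(seed=2)
        for c in meta.index[meta["tissue"] == "tissue_30"]:
            vals[c] = vals["tissue_31_r1"]
        for c in meta.index[meta["tissue"] == "tissue_31"]:
            vals[c] = vals["tissue_31_r1"]
        _, _, tree = nearest_tissue(vals, meta)
        a = tree.find("tissue_30")
        b = tree.find("tissue_31")
        assert a.parent is b.parent
        assert a.length == pytest.approx(0.0, abs=1e-12)

    def test_newick_roundtrip(self, tmp_path):
        from scnscreen.io import write_newick
        from skbio import TreeNode
        vals, meta = self._random_atlas(seed=3)
        _, _, tree = nearest_tissue(vals, meta)
        path = tmp_path / "tree.nwk"
        write_newick(tree, path)
        reread = TreeNode.read(str(path))
        assert {t.name for t in reread.tips()} == \
            set(meta["tissue"].unique())
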