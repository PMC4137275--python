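"""End-to-end orchestration of the SCN candidate-gene screen.

The screen intersects three probeset sets computed from the same universe:
circadian cyclers (cosinor + periodicity tests on the 48-h time course),
light-regulated probesets (fold-change classification over the 9
light-pulse conditions) and SCN-enriched probesets (atlas Z-scoring).
Candidate regulators are the light-suppressed, SCN-enriched transcription
factors.  All tables are written as TSV, summaries and provenance as
JSON; a fixed seed makes a run byte-identical.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .enrichment import TissueEnrichmentScorer, intersect_tf
from .light import LightResponseClassifier
from .rhythms import CyclerDetector
from .synthetic import (
    AtlasDesign,
    CircadianDesign,
    LIGHT_CONDITIONS,
    condition_label,
    generate_circadian_timecourse,
    generate_light_pulse_set,
    generate_tissue_atlas,
)

__all__ = ["ScreenConfig", "ScreenSummary", "run_screen", "venn_counts",
           "round_percent"]


def round_percent(num: float, den: float) -> int:
    """Percentage rounded half away from zero (84/508 -> 17)."""
    if den == 0:
        return 0
    x = 100.0 * num / den
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def venn_counts(set_a, set_b, set_c=None) -> dict[str, int]:
    """Region cardinalities of a 2- or 3-set Venn diagram.

    Inclusion-exclusion identities are verified internally.
    """
    A, B = set(set_a), set(set_b)
    if set_c is None:
        counts = {
            "A": len(A), "B": len(B),
            "A_only": len(A - B), "B_only": len(B - A),
            "AB": len(A & B), "union": len(A | B),
        }
        assert counts["union"] == counts["A"] + counts["B"] - counts["AB"]
        return counts
    C = set(set_c)
    counts = {
        "A": len(A), "B": len(B), "C": len(C),
        "AB": len(A & B), "AC": len(A & C), "BC": len(B & C),
        "ABC": len(A & B & C), "union": len(A | B | C),
    }
    assert counts["union"] == (
        counts["A"] + counts["B"] + counts["C"]
        - counts["AB"] - counts["AC"] - counts["BC"] + counts["ABC"]
    )
    return counts


@dataclass
class ScreenConfig:
    """Synthetic-screen configuration: designs, planted sets and cutoffs."""

    n_probesets: int = 400
    noise_cv: float = 0.15
    frac_cyclers: float = 0.25
    baseline_log_mean: float = math.log(1000.0)
    baseline_log_sd: float = 0.3
    amplitude_rel: float = 0.5
    n_induced: int = 30
    n_suppressed: int = 30
    fold_induced: float = 3.0
    fold_suppressed: float = 0.25
    frac_enriched: float = 0.1
    enrichment_factor: float = 10.0
    frac_tf: float = 0.25
    n_candidates: int = 6          # forced light-suppressed & enriched & TF genes
    n_permutations: int = 200
    fc_cutoff: float = 2.0
    seed: int = 0

    def circadian_design(self) -> CircadianDesign:
        return CircadianDesign(
            n_probesets=self.n_probesets,
            frac_cyclers=self.frac_cyclers,
            amplitude_rel=self.amplitude_rel,
            baseline_log_mean=self.baseline_log_mean,
            baseline_log_sd=self.baseline_log_sd,
            noise_cv=self.noise_cv,
            seed=self.seed,
        )

    def atlas_design(self) -> AtlasDesign:
        return AtlasDesign(
            frac_enriched=self.frac_enriched,
            enrichment_factor=self.enrichment_factor,
            noise_cv=self.noise_cv,
            seed=self.seed + 1,
        )


@dataclass
class ScreenSummary:
    n_probesets: int
    n_cyclers: int
    n_light_regulated: int
    n_induced: int
    n_suppressed: int
    n_enriched: int
    n_tf_enriched: int
    n_candidates: int
    venn_cycler_light: dict
    venn_induced_suppressed_enriched: dict
    overlap_percent: int
    candidates: list[str]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _plant_screen_truth(config: ScreenConfig):
    """Generate all inputs with forced candidate overlap.

    Returns (timecourse, truth, pairs, light_truth, atlas, tf_set).
    Candidates (first ``n_candidates`` probesets after a seeded shuffle of
    the planted sets) are made light-suppressed, SCN-enriched and TF.
    """
    design = config.circadian_design()
    matrix, truth = generate_circadian_timecourse(design)
    probesets = list(matrix.index)
    rng = np.random.default_rng(config.seed + 2)

    order = rng.permutation(len(probesets))
    cand = [probesets[i] for i in order[: config.n_candidates]]
    rest = [probesets[i] for i in order[config.n_candidates :]]

    n_sup_extra = max(0, config.n_suppressed - len(cand))
    induced = rest[: config.n_induced]
    suppressed = cand + rest[config.n_induced : config.n_induced + n_sup_extra]

    labels = [condition_label(*c) for c in LIGHT_CONDITIONS]
    effects: dict[str, dict[str, float]] = {}
    for g in induced:
        conds = rng.choice(len(labels), size=3, replace=False)
        effects[g] = {labels[c]: config.fold_induced for c in conds}
    for g in suppressed:
        conds = rng.choice(len(labels), size=3, replace=False)
        effects[g] = {labels[c]: config.fold_suppressed for c in conds}
    pairs, light_truth = generate_light_pulse_set(design, effects,
                                                  seed=config.seed + 3)

    # enriched set: candidates plus a random filler up to frac_enriched
    n_enr = max(len(cand), int(round(config.frac_enriched * len(probesets))))
    filler = [p for p in rest if p not in set(induced)]
    enriched = set(cand) | set(filler[: n_enr - len(cand)])
    atlas = _atlas_with_planted(config, matrix, enriched)

    n_tf = max(len(cand), int(round(config.frac_tf * len(probesets))))
    tf_set = set(cand) | set(rng.choice(rest, size=n_tf - len(cand),
                                        replace=False).tolist())
    return matrix, truth, pairs, light_truth, atlas, tf_set


def _atlas_with_planted(config: ScreenConfig, matrix: pd.DataFrame,
                        enriched: set[str]):
    """Atlas generation with an explicit enriched set (not a random draw)."""
    from .synthetic import AtlasResult, _lognormal_factors

    design = config.atlas_design()
    rng = np.random.default_rng(design.seed)
    scn = matrix.median(axis=1).to_numpy()
    mask = matrix.index.isin(list(enriched))
    background = np.where(mask, scn / design.enrichment_factor, scn)
    meta = design.tissue_table()
    other_cols = meta.index[~meta["is_scn"]]
    vals = background[:, None] * _lognormal_factors(
        rng, design.noise_cv, (len(matrix), len(other_cols))
    )
    values = pd.DataFrame(vals, index=matrix.index, columns=other_cols)
    values["SCN"] = scn
    truth = pd.DataFrame(
        {"is_scn_enriched": mask,
         "enrichment_factor": np.where(mask, design.enrichment_factor, 1.0)},
        index=matrix.index,
    )
    return AtlasResult(values, meta, truth)


def run_screen(config: ScreenConfig, out_dir: str | Path | None = None
               ) -> ScreenSummary:
    """Run the full synthetic screen and intersect the three gene sets."""
    matrix, truth, pairs, light_truth, atlas, tf_set = _plant_screen_truth(config)

    detector = CyclerDetector(n_permutations=config.n_permutations,
                              random_state=config.seed + 4)
    detector.fit(matrix)
    cyclers = set(detector.results_.index[detector.results_["is_cycler"]])

    light = LightResponseClassifier(cutoff=config.fc_cutoff).fit(pairs)
    regulated = set(light.light_regulated_.index[light.light_regulated_])
    induced = set(light.classes_.index[(light.classes_ == "induced").any(axis=1)])
    suppressed = set(
        light.classes_.index[(light.classes_ == "suppressed").any(axis=1)]
    )

    scorer = TissueEnrichmentScorer().fit(atlas.values, tissues=atlas.tissues)
    enriched = set(scorer.shortlist_.index)
    tf_enriched = intersect_tf(scorer.shortlist_, tf_set)
    candidates = [p for p in tf_enriched if p in suppressed]

    venn_cl = venn_counts(cyclers, regulated)
    venn_ise = venn_counts(induced, suppressed, enriched)
    summary = ScreenSummary(
        n_probesets=len(matrix),
        n_cyclers=len(cyclers),
        n_light_regulated=len(regulated),
        n_induced=len(induced),
        n_suppressed=len(suppressed),
        n_enriched=len(enriched),
        n_tf_enriched=len(tf_enriched),
        n_candidates=len(candidates),
        venn_cycler_light=venn_cl,
        venn_induced_suppressed_enriched=venn_ise,
        overlap_percent=round_percent(venn_cl["AB"], venn_cl["B"]),
        candidates=sorted(candidates),
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sio.write_table(matrix, out / "timecourse.tsv")
        sio.write_table(truth, out / "timecourse_truth.tsv")
        sio.write_light_pulse_set(pairs, out / "light_pulse.tsv")
        sio.write_table(light_truth, out / "light_truth.tsv")
        sio.write_table(atlas.values, out / "atlas.tsv")
        sio.write_table(atlas.tissues, out / "atlas_tissues.tsv")
        sio.write_table(atlas.truth, out / "atlas_truth.tsv")
        sio.write_table(detector.results_, out / "rhythm_results.tsv")
        sio.write_table(light.fold_changes_, out / "light_fold_changes.tsv")
        sio.write_table(light.classes_, out / "light_classes.tsv")
        sio.write_table(light.gating_profile_, out / "gating_profile.tsv")
        sio.write_table(scorer.scores_, out / "enrichment_scores.tsv")
        sio.write_table(scorer.shortlist_, out / "enrichment_shortlist.tsv")
        sio.write_json(summary.to_dict(), out / "screen_summary.json")
        sio.write_json(
            {
                "config": dataclasses.asdict(config),
                "thresholds": {
                    "alpha_mmc": detector.alpha_mmc,
                    "alpha_fgt": detector.alpha_fgt,
                    "min_median": detector.min_median,
                    "period_band_h": [detector.period_lo, detector.period_hi],
                    "fc_cutoff": config.fc_cutoff,
                    "z_all": scorer.th_all,
                    "z_neural": scorer.th_neural,
                    "ratio_scn_hyp": scorer.th_ratio,
                    "median_scn": scorer.th_median,
                },
                "seed": config.seed,
            },
            out / "provenance.json",
        )
    return summary
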