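"""SCN tissue-enrichment scoring against a multi-tissue expression atlas.

Each probeset is compared against an 83-tissue atlas in which the SCN is
represented by a single summary column (the median of its 24 circadian
samples) and every other tissue by a duplicate pair, 165 columns in all.
Two Z-scores measure how many standard deviations the SCN value sits
above the rest of the atlas:

    Z(all)    = (SCN - mean of the 165 values) / SD of the 165 values
    Z(neural) = (SCN - mean of the 29 neural values) / SD of the 29 values

where the neural vector is the 14 neural tissues in duplicate plus the
SCN itself.  A third criterion is the ratio of the SCN value to the mean
of the hypothalamus duplicate pair (the anatomically closest tissue), and
a fourth is a floor on the SCN median itself.  The default shortlist
thresholds are Z(all) >= 1.63, Z(neural) >= 1.44, SCN/hypothalamus >= 6
and SCN median > 200.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from skbio import TreeNode

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentThresholds",
    "TissueEnrichmentScorer",
    "scn_summary_value",
    "passes_thresholds",
    "enrichment_scores",
    "shortlist_enriched",
    "nearest_tissue",
    "intersect_tf",
    "collapse_to_genes",
]


@dataclass
class EnrichmentThresholds:
    th_all: float = 1.63
    th_neural: float = 1.44
    th_ratio: float = 6.0
    th_median: float = 200.0

    def __post_init__(self) -> None:
        if min(self.th_all, self.th_neural, self.th_ratio, self.th_median) <= 0:
            raise ValueError("thresholds must be positive")


def passes_thresholds(
    z_all: float, z_neural: float, ratio: float, median_scn: float,
    thresholds: EnrichmentThresholds | None = None,
) -> bool:
    """Shortlist predicate: Z >= thresholds (inclusive) and median strictly >."""
    th = thresholds or EnrichmentThresholds()
    return bool(
        z_all >= th.th_all and z_neural >= th.th_neural
        and ratio >= th.th_ratio and median_scn > th.th_median
    )


def scn_summary_value(timecourse_row) -> float:
    """SCN summary: median of the 24 circadian samples of one probeset."""
    values = np.asarray(timecourse_row, dtype=float)
    if values.size != 24:
        raise ValueError(f"expected 24 circadian samples, got {values.size}")
    return float(np.median(values))


def _column_groups(tissues: pd.DataFrame):
    scn_cols = tissues.index[tissues["is_scn"]]
    if len(scn_cols) != 1:
        raise ValueError("atlas must contain exactly one SCN summary column")
    neural_cols = tissues.index[tissues["is_neural"]]
    hyp_cols = tissues.index[tissues["is_hypothalamus"]]
    if len(hyp_cols) == 0:
        raise ValueError("atlas metadata marks no hypothalamus columns")
    return scn_cols[0], list(neural_cols), list(hyp_cols)


def enrichment_scores(
    atlas: pd.DataFrame,
    tissues: pd.DataFrame,
    probeset: str | None = None,
    thresholds: EnrichmentThresholds | None = None,
    ddof: int = 1,
    eps: float = 1e-9,
) -> pd.DataFrame | pd.Series:
    """Z(all), Z(neural), SCN/hypothalamus ratio and pass flag per probeset.

    ``atlas`` is probesets x 165 columns; ``tissues`` is the per-column
    metadata (tissue, replicate, is_neural, is_hypothalamus, is_scn).
    The SD uses the sample (``ddof=1``) form by default; set ``ddof=0``
    for the population form.
    """
    thresholds = thresholds or EnrichmentThresholds()
    scn_col, neural_cols, hyp_cols = _column_groups(tissues)
    missing = [c for c in tissues.index if c not in atlas.columns]
    if missing:
        raise KeyError(f"atlas is missing columns: {missing[:5]}")

    all_vals = atlas.loc[:, list(tissues.index)].to_numpy(float)
    neural_vals = atlas.loc[:, neural_cols].to_numpy(float)
    scn = atlas[scn_col].to_numpy(float)
    hyp = atlas.loc[:, hyp_cols].to_numpy(float).mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        z_all = (scn - all_vals.mean(axis=1)) / all_vals.std(axis=1, ddof=ddof)
        z_neural = (scn - neural_vals.mean(axis=1)) / neural_vals.std(axis=1, ddof=ddof)
    z_all = np.nan_to_num(z_all, nan=0.0)
    z_neural = np.nan_to_num(z_neural, nan=0.0)

    small = hyp <= eps
    if np.any(small):
        logger.warning("hypothalamus mean <= %g for %d probeset(s); "
                       "ratio uses the floor", eps, int(small.sum()))
    ratio = scn / np.maximum(hyp, eps)

    passes = np.array([
        passes_thresholds(za, zn, r, m, thresholds)
        for za, zn, r, m in zip(z_all, z_neural, ratio, scn)
    ])
    out = pd.DataFrame(
        {
            "z_all": z_all,
            "z_neural": z_neural,
            "ratio_scn_hyp": ratio,
            "median_scn": scn,
            "passes": passes,
        },
        index=atlas.index,
    )
    if probeset is not None:
        return out.loc[probeset]
    return out


def shortlist_enriched(
    atlas: pd.DataFrame,
    tissues: pd.DataFrame,
    thresholds: EnrichmentThresholds | None = None,
    ddof: int = 1,
) -> pd.DataFrame:
    """All probesets passing the four criteria, ordered by descending Z(all)."""
    scores = enrichment_scores(atlas, tissues, thresholds=thresholds, ddof=ddof)
    short = scores[scores["passes"]].sort_values(
        ["z_all", "median_scn"], ascending=False, kind="mergesort"
    )
    return short


def nearest_tissue(
    atlas: pd.DataFrame,
    tissues: pd.DataFrame,
) -> tuple[str, pd.Series, TreeNode]:
    """Hierarchically cluster tissues and rank them by proximity to the SCN.

    Replicates are averaged first; the distance is 1 - Pearson correlation
    between tissue expression profiles, with average linkage.  Returns the
    nearest non-SCN tissue name, the full correlation-distance ranking
    (ascending), and the dendrogram as a ``skbio.TreeNode``.
    """
    profiles = {}
    for name, grp in tissues.groupby("tissue"):
        prof = atlas.loc[:, list(grp.index)].to_numpy(float).mean(axis=1)
        if np.std(prof) == 0:
            warnings.warn(f"excluding zero-variance tissue profile {name!r}")
            continue
        profiles[name] = prof
    if len(profiles) < 3:
        raise ValueError("need at least 3 usable tissues to cluster")
    if "SCN" not in profiles:
        raise ValueError("SCN profile missing or flat")
    names = list(profiles)
    mat = np.array([profiles[t] for t in names])
    corr = np.corrcoef(mat)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    tree = TreeNode.from_linkage_matrix(Z, names)
    i_scn = names.index("SCN")
    ranking = pd.Series(
        {t: dist[i_scn, j] for j, t in enumerate(names) if t != "SCN"},
        name="dist_to_scn",
    ).sort_values(kind="mergesort")
    return str(ranking.index[0]), ranking, tree


def intersect_tf(shortlist: pd.DataFrame | pd.Index, tf_annotation) -> list[str]:
    """Sub-shortlist of transcription factors, preserving shortlist order."""
    ids = shortlist.index if isinstance(shortlist, pd.DataFrame) else shortlist
    tf = set(tf_annotation)
    return [p for p in ids if p in tf]


def collapse_to_genes(probesets, mapping: dict) -> list[str]:
    """Collapse probesets to genes; a gene is kept if any probeset maps to it."""
    genes, seen = [], set()
    for p in probesets:
        g = mapping.get(p)
        if g is not None and g not in seen:
            seen.add(g)
            genes.append(g)
    return genes


class TissueEnrichmentScorer(BaseEstimator):
    """Score SCN enrichment of every probeset in a tissue atlas.

    Parameters are the four shortlist thresholds and the SD convention
    (``ddof=1`` sample form by default).  After ``fit(atlas, tissues)``:

    Attributes
    ----------
    scores_ : DataFrame with z_all, z_neural, ratio_scn_hyp, median_scn, passes.
    shortlist_ : passing probesets ordered by descending z_all.
    labels_ : boolean ndarray of pass flags.
    """

    def __init__(
        self,
        th_all: float = 1.63,
        th_neural: float = 1.44,
        th_ratio: float = 6.0,
        th_median: float = 200.0,
        ddof: int = 1,
    ):
        self.th_all = th_all
        self.th_neural = th_neural
        self.th_ratio = th_ratio
        self.th_median = th_median
        self.ddof = ddof

    def _thresholds(self) -> EnrichmentThresholds:
        return EnrichmentThresholds(self.th_all, self.th_neural,
                                    self.th_ratio, self.th_median)

    def fit(self, X: pd.DataFrame, y=None, tissues: pd.DataFrame | None = None):
        if tissues is None:
            raise ValueError("tissue metadata is required")
        self.scores_ = enrichment_scores(
            X, tissues, thresholds=self._thresholds(), ddof=self.ddof
        )
        self.shortlist_ = self.scores_[self.scores_["passes"]].sort_values(
            ["z_all", "median_scn"], ascending=False, kind="mergesort"
        )
        self.labels_ = self.scores_["passes"].to_numpy()
        return self

    def fit_predict(self, X, y=None, **kw) -> np.ndarray:
        return self.fit(X, **kw).labels_
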