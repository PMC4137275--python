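"""Classification of light-induced and light-suppressed transcripts.

For each probeset the mean expression after a 1-h light pulse is compared
with the paired dark control at the 9 conditions (pulse beginning at
CT30, CT40 or CT46; samples 1, 2 and 4 h after pulse start).  A condition
is called *induced* when the light/dark fold change is at least the
cutoff (default 2, boundary inclusive) and *suppressed* when it is at
most the reciprocal; a probeset is light-regulated when any condition is
non-none.  The per-condition tallies of induced and suppressed calls
form the circadian "gating" profile of the light response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .synthetic import LIGHT_CONDITIONS, condition_label

logger = logging.getLogger(__name__)

__all__ = [
    "CONDITION_LABELS",
    "LightResponseClassifier",
    "fold_changes",
    "classify_light_regulation",
    "gating_profile",
]

#: Fixed condition order: (CT30: +1,+2,+4; CT40: +1,+2,+4; CT46: +1,+2,+4).
CONDITION_LABELS: tuple[str, ...] = tuple(condition_label(*c) for c in LIGHT_CONDITIONS)


def _floored(values: np.ndarray, floor: float, what: str) -> np.ndarray:
    low = values < floor
    if np.any(low):
        logger.warning("raised %d %s value(s) below %g to the floor",
                       int(low.sum()), what, floor)
    return np.maximum(values, floor)


def fold_changes(
    pairs: pd.DataFrame,
    probeset: str | None = None,
    floor: float = 1.0,
) -> pd.DataFrame | pd.Series:
    """Light/dark fold change at each of the 9 conditions.

    ``pairs`` has MultiIndex columns ``(condition, 'light'|'dark')``.
    Values below ``floor`` (one intensity unit by default; near-background
    array intensities are unreliable) are raised to it on both arms, which
    keeps the light/dark swap symmetry exact.  Returns a probesets x 9
    DataFrame, or a Series for a single probeset.
    """
    for cond in CONDITION_LABELS:
        for arm in ("light", "dark"):
            if (cond, arm) not in pairs.columns:
                raise KeyError(f"missing condition {cond!r} ({arm} arm)")
    light = _floored(
        pairs.loc[:, [(c, "light") for c in CONDITION_LABELS]].to_numpy(float),
        floor, "light")
    dark = _floored(
        pairs.loc[:, [(c, "dark") for c in CONDITION_LABELS]].to_numpy(float),
        floor, "dark")
    fc = pd.DataFrame(light / dark, index=pairs.index, columns=list(CONDITION_LABELS))
    if probeset is not None:
        return fc.loc[probeset]
    return fc


def classify_light_regulation(fcs, cutoff: float = 2.0) -> pd.DataFrame:
    """Classify per-condition fold changes as induced / suppressed / none.

    Induced iff ``FC >= cutoff``; suppressed iff ``FC <= 1/cutoff``
    (symmetric, boundaries inclusive).  Accepts a length-9 vector, a
    Series, or a probesets x 9 DataFrame; always returns a DataFrame with
    the 9 class columns plus a boolean ``light_regulated`` column.
    """
    if cutoff <= 1:
        raise ValueError("cutoff must exceed 1")
    if isinstance(fcs, pd.DataFrame):
        fc = fcs.loc[:, list(CONDITION_LABELS)]
    else:
        arr = np.asarray(fcs, dtype=float).reshape(1, -1)
        if arr.shape[1] != 9:
            raise ValueError("expected 9 fold changes")
        fc = pd.DataFrame(arr, columns=list(CONDITION_LABELS))
    vals = fc.to_numpy(float)
    if np.any(vals <= 0):
        raise ValueError("fold changes must be positive")
    classes = np.where(vals >= cutoff, "induced",
                       np.where(vals <= 1.0 / cutoff, "suppressed", "none"))
    out = pd.DataFrame(classes, index=fc.index, columns=fc.columns)
    out["light_regulated"] = (classes != "none").any(axis=1)
    return out


def gating_profile(classes: pd.DataFrame) -> pd.DataFrame:
    """Per-condition counts of induced and suppressed probesets."""
    rows = []
    for cond in CONDITION_LABELS:
        col = classes[cond] if cond in classes.columns else pd.Series(dtype=object)
        rows.append(
            (cond, int((col == "induced").sum()), int((col == "suppressed").sum()))
        )
    return pd.DataFrame(rows, columns=["condition", "n_induced", "n_suppressed"]
                        ).set_index("condition")


class LightResponseClassifier(BaseEstimator):
    """Call light-induced and light-suppressed probesets by fold change.

    Parameters
    ----------
    cutoff : float
        Fold-change threshold (induced at ``FC >= cutoff``, suppressed at
        ``FC <= 1/cutoff``; boundaries inclusive).
    floor : float
        Intensity floor applied to both arms before forming ratios.

    Attributes
    ----------
    fold_changes_ : DataFrame, probesets x 9 conditions.
    classes_ : DataFrame of per-condition class labels.
    light_regulated_ : boolean Series (any condition non-none).
    gating_profile_ : per-condition induced/suppressed tallies.
    """

    def __init__(self, cutoff: float = 2.0, floor: float = 1.0):
        self.cutoff = cutoff
        self.floor = floor

    def fit(self, X: pd.DataFrame, y=None):
        fc = fold_changes(X, floor=self.floor)
        res = classify_light_regulation(fc, cutoff=self.cutoff)
        self.fold_changes_ = fc
        self.light_regulated_ = res.pop("light_regulated")
        self.classes_ = res
        self.gating_profile_ = gating_profile(res)
        return self

    def fit_predict(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).light_regulated_.to_numpy()
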