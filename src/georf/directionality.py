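"""Risk/protective directionality of ranked features.

A regression tree on 0/1 labels summarizes, at every split on a
feature, how the case proportion differs between the two sides of the
cut.  Pooling the two children of every such split across all trees of
the final-iteration forest gives a cloud of (mean feature value, mean
outcome) points weighted by child size; the sign of the weighted
least-squares slope through that cloud says whether higher feature
values predict attempts (risk) or controls (protective), and the
weighted R-squared says how consistently the splits agree on a linear
effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .irf import IterativeRandomForestRegressor

logger = logging.getLogger("georf")


@dataclass
class DirectionalityResult:
    feature: str
    slope: float
    r_squared: float
    direction: str  # "risk" | "protective" | "undetermined"
    n_splits: int


def collect_split_effects(model: IterativeRandomForestRegressor, feature: str):
    """(x, y, weight) points from every final-forest split on ``feature``.

    Each split emits its two children: (child mean feature value, child
    mean outcome, child weighted count).
    """
    names = list(model.feature_names_in_)
    if feature not in names:
        raise ValueError(f"feature {feature!r} not in model")
    f_idx = names.index(feature)
    xs, ys, ws = [], [], []
    for fi, tree, nd in model.final_forest_.iter_splits():
        if fi != f_idx:
            continue
        xs.extend((tree.mean_x_left[nd], tree.mean_x_right[nd]))
        ys.extend((tree.mean_y_left[nd], tree.mean_y_right[nd]))
        ws.extend((tree.weight_left[nd], tree.weight_right[nd]))
    return np.asarray(xs), np.asarray(ys), np.asarray(ws)


def weighted_line_fit(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares line; returns (slope, r_squared) or None
    when the slope is undefined (all x equal)."""
    wsum = w.sum()
    xm = np.sum(w * x) / wsum
    ym = np.sum(w * y) / wsum
    sxx = np.sum(w * (x - xm) ** 2)
    if sxx <= 0:
        return None
    sxy = np.sum(w * (x - xm) * (y - ym))
    slope = sxy / sxx
    sst = np.sum(w * (y - ym) ** 2)
    if sst <= 0:
        # outcome means identical everywhere: a flat, perfectly fitted line
        return slope, 1.0
    resid = y - (ym + slope * (x - xm))
    r2 = 1.0 - np.sum(w * resid**2) / sst
    return slope, float(min(max(r2, 0.0), 1.0))


def effect_direction(model: IterativeRandomForestRegressor,
                     feature: str) -> DirectionalityResult:
    """Classify one feature as risk, protective, or undetermined."""
    x, y, w = collect_split_effects(model, feature)
    n_splits = x.size // 2
    if n_splits == 0:
        return DirectionalityResult(feature, 0.0, 0.0, "undetermined", 0)
    fit = weighted_line_fit(x, y, w)
    if fit is None:
        logger.warning(
            "feature %s: all split points share one value, slope undefined",
            feature,
        )
        return DirectionalityResult(feature, 0.0, 0.0, "undetermined", n_splits)
    slope, r2 = fit
    if slope > 0:
        direction = "risk"
    elif slope < 0:
        direction = "protective"
    else:
        direction = "undetermined"
    return DirectionalityResult(feature, float(slope), r2, direction, n_splits)


def directionality_table(model: IterativeRandomForestRegressor,
                         features=None) -> pd.DataFrame:
    """Per-feature direction table (feature, slope, r_squared, direction,
    n_splits, importance), ordered by descending final importance."""
    if features is None:
        features = model.ranking_
    imp = dict(zip(model.feature_names_in_, model.feature_importances_))
    rows = []
    for f in features:
        r = effect_direction(model, f)
        rows.append(
            {
                "feature": r.feature,
                "slope": r.slope,
                "r_squared": r.r_squared,
                "direction": r.direction,
                "n_splits": r.n_splits,
                "importance": imp[f],
            }
        )
    return pd.DataFrame(rows)
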