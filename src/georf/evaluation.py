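"""Group-shuffled cross-validation with AUPRC, and reduced-model selection.

Accuracy is the area under the precision-recall curve, the right metric
for rare outcomes: a ranking no better than chance scores the positive
prevalence, so lift above the prevalence baseline is directly readable.
Cross-validation shuffles *ZIP codes*, not patients, so no ZIP
contributes to both training and test data and geospatial leakage is
ruled out: each of five repeats assigns ZIPs at random to a test side
holding as close to 20% of patients as group boundaries allow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .irf import IterativeRandomForestRegressor
from .preprocess import DesignMatrix

logger = logging.getLogger("georf")


@dataclass
class PRCurve:
    """Precision-recall points over descending score thresholds.

    Points are computed once per distinct score (tied scores form one
    block), recall is nondecreasing and ends at 1.
    """

    recall: np.ndarray
    precision: np.ndarray
    thresholds: np.ndarray
    n_positive: int
    n_total: int


def pr_curve(scores, labels) -> PRCurve:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise ValueError("cannot build a precision-recall curve with no positives")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    tp = np.cumsum(labels[order] == 1)
    # block boundaries: last index of each tied-score run
    last = np.flatnonzero(np.r_[s[1:] != s[:-1], True])
    precision = tp[last] / (last + 1)
    recall = tp[last] / n_pos
    return PRCurve(recall=recall, precision=precision, thresholds=s[last],
                   n_positive=n_pos, n_total=len(labels))


def auprc(curve: PRCurve) -> float:
    """Average-precision step sum: sum of (delta recall) * precision.

    No interpolation between points — linear interpolation is biased for
    precision-recall curves.
    """
    r = np.r_[0.0, curve.recall]
    return float(np.sum((r[1:] - r[:-1]) * curve.precision))


def average_precision(scores, labels) -> float:
    return auprc(pr_curve(scores, labels))


def _one_group_split(group_sizes: np.ndarray, test_fraction: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Random permutation prefix of groups whose patient mass is closest
    to the test fraction; returns a boolean test mask over groups."""
    G = group_sizes.size
    perm = rng.permutation(G)
    cum = np.cumsum(group_sizes[perm])
    target = test_fraction * cum[-1]
    k_opts = np.arange(1, G)  # both sides keep >= 1 group
    k = k_opts[np.argmin(np.abs(cum[:-1] - target))]
    mask = np.zeros(G, dtype=bool)
    mask[perm[:k]] = True
    return mask


def group_shuffle_split(groups, test_fraction: float = 0.2,
                        n_repeats: int = 5, seed: int = 0):
    """Repeated random group partitions into train/test index arrays.

    Groups (not samples) are shuffled each repeat; the test side receives
    whole groups totalling the achievable patient fraction closest to
    ``test_fraction``, and no group ever sits on both sides.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    groups = np.asarray(groups)
    uniq, inv = np.unique(groups, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("cannot group-split a single group")
    sizes = np.bincount(inv).astype(np.float64)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    splits = []
    for _ in range(n_repeats):
        test_groups = _one_group_split(sizes, test_fraction, rng)
        test_mask = test_groups[inv]
        splits.append((np.flatnonzero(~test_mask), np.flatnonzero(test_mask)))
    return splits


@dataclass
class CVResult:
    """Per-repeat AUPRC values with their prevalence baselines."""

    auprcs: list[float]
    baselines: list[float]
    model_tag: str = "all_features"
    curves: list[PRCurve] = field(default_factory=list)

    @property
    def mean_auprc(self) -> float:
        return float(np.mean(self.auprcs))

    @property
    def baseline(self) -> float:
        """Mean test-set positive fraction: the random-chance AUPRC."""
        return float(np.mean(self.baselines))

    @property
    def n_repeats(self) -> int:
        return len(self.auprcs)


def _estimator_from_config(config, seed) -> IterativeRandomForestRegressor:
    return IterativeRandomForestRegressor(
        n_trees=config.n_trees, min_leaf=config.min_leaf,
        mtry_fraction=config.mtry_fraction, n_iterations=config.n_iterations,
        bootstrap=config.bootstrap, random_state=seed,
    )


def cross_validate(design: DesignMatrix, config, features=None,
                   model_tag: str = "all_features", seed=None,
                   max_redraws: int = 10) -> CVResult:
    """Group-shuffled repeated evaluation of the iterated forest.

    For each repeat: fit on the training ZIPs, score the held-out ZIPs,
    record AUPRC and the test prevalence.  A drawn test side with zero
    cases (possible at desk scale) is redrawn with a logged warning, at
    most ``max_redraws`` times per repeat.
    """
    if features is not None:
        design = design.subset_features(list(features))
    base_seed = config.seed if seed is None else seed
    uniq, inv = np.unique(design.groups, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("cannot group-split a single group")
    sizes = np.bincount(inv).astype(np.float64)
    ss = np.random.SeedSequence([int(base_seed), 17])
    rng = np.random.default_rng(ss)
    fit_seeds = ss.spawn(config.n_repeats)
    y = design.labels
    result = CVResult(auprcs=[], baselines=[], model_tag=model_tag)
    for rep in range(config.n_repeats):
        for attempt in range(max_redraws + 1):
            test_groups = _one_group_split(sizes, config.test_fraction, rng)
            test_mask = test_groups[inv]
            if y[test_mask].sum() > 0:
                break
            logger.warning("repeat %d: test fold drew zero cases, redrawing", rep)
        else:
            raise RuntimeError(
                f"repeat {rep}: no test fold with positives after "
                f"{max_redraws} redraws"
            )
        tr = np.flatnonzero(~test_mask)
        te = np.flatnonzero(test_mask)
        est = _estimator_from_config(
            config, int(fit_seeds[rep].generate_state(1)[0] % (2**31))
        )
        est.fit(design.features.iloc[tr], y[tr], groups=design.groups[tr])
        scores = est.predict(design.features.iloc[te])
        curve = pr_curve(scores, y[te])
        result.auprcs.append(auprc(curve))
        result.baselines.append(float(y[te].mean()))
        result.curves.append(curve)
    return result


@dataclass
class ReducedModelResult:
    """Outcome of the top-k + forced-vendor model comparison."""

    reduced_features: list[str]
    cv_all: CVResult
    cv_reduced: CVResult
    full_model: IterativeRandomForestRegressor

    def __iter__(self):  # unpack as (features, cv_all, cv_reduced)
        return iter((self.reduced_features, self.cv_all, self.cv_reduced))


def reduced_model(design: DesignMatrix, config) -> ReducedModelResult:
    """Top-k + forced-vendor model against the all-features model.

    Fits the iterated forest on the full stratum to obtain the ranking,
    forms the reduced set as the top ``config.top_k`` features united
    with the forced vendor features, and cross-validates both models.
    The ranking is fitted on the full stratum (mirroring a
    select-then-validate workflow), which carries a known optimistic
    bias for the reduced model's absolute score.
    """
    forced = [f for f in config.forced_features]
    missing = [f for f in forced if f not in design.feature_names]
    if missing:
        raise ValueError(f"forced features absent from design: {missing}")
    if len(design.feature_names) < config.top_k:
        raise ValueError(
            f"need at least {config.top_k} features, got {len(design.feature_names)}"
        )
    est = _estimator_from_config(config, int(config.seed) % (2**31))
    est.fit(design.features, design.labels, groups=design.groups)
    top = est.top_features(config.top_k)
    reduced = top + [f for f in forced if f not in top]
    reduced = [f for f in design.feature_names if f in set(reduced)]
    cv_all = cross_validate(design, config, model_tag="all_features")
    cv_red = cross_validate(design, config, features=reduced, model_tag="reduced")
    return ReducedModelResult(reduced, cv_all, cv_red, est)
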