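"""All-against-all feature network inference (leave-one-out prediction).

Every feature of the (pruned) ZIP-level table takes a turn as the
regression target of an iterated forest fitted on all remaining
features, with ZIP codes as samples.  The target model's final
normalized importance vector becomes directed, weighted edges
predictor -> target, so an arrow shows which feature predicts which.
Filtering to the top fraction of candidate edges (1% by default) keeps
the strongest relationships, from which first-neighbor subnetworks
around a focal feature (e.g. alcohol vendors per 10,000 residents) can
be extracted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .irf import IterativeRandomForestRegressor

logger = logging.getLogger("georf")


@dataclass
class LoopNetwork:
    """Directed weighted feature-to-feature edge list.

    ``n_candidate_edges`` is F*(F-1) over all features of the input
    table (ordered pairs, no self-edges); it is preserved by filtering
    so that "top 1%" always refers to the same denominator.
    """

    edges: pd.DataFrame  # columns: source, target, weight
    nodes: list[str]
    n_candidate_edges: int
    skipped_targets: list[str] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def sorted_edges(self) -> pd.DataFrame:
        """Descending weight, ties broken lexicographically by (source, target)."""
        e = self.edges.sort_values(
            ["weight", "source", "target"], ascending=[False, True, True],
            kind="mergesort",
        )
        return e.reset_index(drop=True)

    def incoming_weight_sum(self, target: str) -> float:
        return float(self.edges.loc[self.edges["target"] == target, "weight"].sum())

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for s, t, w in self.edges.itertuples(index=False):
            g.add_edge(s, t, weight=float(w))
        return g


def loop_infer(zips: pd.DataFrame, config, id_columns=("zip_id",)) -> LoopNetwork:
    """Fit one iterated forest per target feature; collect importance edges.

    ``zips`` should already be correlation-pruned (near-duplicate
    features would otherwise trade importance arbitrarily).  Constant
    target columns are skipped with a warning — no model can be fitted
    on them.  Per-target seeds are derived deterministically from
    ``config.seed`` and the target index.
    """
    feats = [c for c in zips.columns if c not in id_columns]
    if len(feats) < 3:
        raise ValueError("need at least 3 features for all-against-all inference")
    X = zips[feats].to_numpy(dtype=np.float64)
    n_candidate = len(feats) * (len(feats) - 1)
    rows = []
    skipped = []
    for j, target in enumerate(feats):
        y = X[:, j]
        if y.std() == 0:
            logger.warning("skipping constant target column %s", target)
            skipped.append(target)
            continue
        others = [f for f in feats if f != target]
        seed = int(
            np.random.SeedSequence([int(config.seed), 23, j]).generate_state(1)[0]
            % (2**31)
        )
        est = IterativeRandomForestRegressor(
            n_trees=config.loop_n_trees, min_leaf=config.loop_min_leaf,
            mtry_fraction=config.mtry_fraction,
            n_iterations=config.loop_n_iterations, bootstrap=config.bootstrap,
            random_state=seed,
        )
        est.fit(zips[others], y)
        imp = est.feature_importances_
        for name, wgt in zip(others, imp):
            if wgt > 0:
                rows.append((name, target, float(wgt)))
    edges = pd.DataFrame(rows, columns=["source", "target", "weight"])
    return LoopNetwork(edges=edges, nodes=list(feats),
                       n_candidate_edges=n_candidate, skipped_targets=skipped)


def filter_top_edges(net: LoopNetwork, fraction: float) -> LoopNetwork:
    """Keep the floor(fraction * candidate-edge-count) heaviest edges.

    Weight ties break lexicographically by (source, target) so the
    retained set is reproducible; the node set shrinks to the edge
    endpoints.  Filtering is monotone in ``fraction``.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    k = int(np.floor(fraction * net.n_candidate_edges))
    kept = net.sorted_edges().head(k)
    nodes = sorted(set(kept["source"]) | set(kept["target"]))
    return LoopNetwork(edges=kept.reset_index(drop=True), nodes=nodes,
                       n_candidate_edges=net.n_candidate_edges,
                       skipped_targets=list(net.skipped_targets))


def first_neighbors(net: LoopNetwork, node: str) -> LoopNetwork:
    """Subnetwork of a focal feature and its in/out neighbors.

    Keeps every edge incident to the focal node plus all edges among its
    neighbors (the induced first-neighborhood).
    """
    if node not in net.nodes:
        raise ValueError(f"unknown node {node!r}")
    e = net.edges
    incident = (e["source"] == node) | (e["target"] == node)
    neigh = set(e.loc[incident, "source"]) | set(e.loc[incident, "target"])
    neigh.add(node)
    within = e["source"].isin(neigh) & e["target"].isin(neigh)
    sub = e.loc[within].reset_index(drop=True)
    return LoopNetwork(edges=sub, nodes=sorted(neigh),
                       n_candidate_edges=net.n_candidate_edges)
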