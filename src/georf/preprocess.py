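"""Correlation pruning, patient/ZIP join, and the age-60 cohort split.

Near-duplicate covariates dilute forest importance: when several columns
carry the same signal, splits distribute among them and each looks
unimportant.  Pruning therefore builds the graph whose edges connect
feature pairs with sample |Pearson r| at or above a threshold (0.90 by
default, boundary inclusive), takes connected components as the
correlated groups, and keeps one representative per group — the member
with the highest sample variance, ties broken by lexicographically
smallest name.  Zero-variance columns are dropped outright (their
correlation is undefined and no split can use them).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, TransformerMixin

from .synthetic import AGE_CUTOFF

logger = logging.getLogger("georf")


@dataclass
class CorrelationGroups:
    """Audit record of the pruning: groups, representatives, dropped columns."""

    groups: list[dict] = field(default_factory=list)  # {members, representative}
    removed: list[str] = field(default_factory=list)
    zero_variance: list[str] = field(default_factory=list)
    threshold: float = 0.90

    @property
    def n_removed(self) -> int:
        return len(self.removed) + len(self.zero_variance)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "groups": [
                {"members": list(g["members"]),
                 "representative": g["representative"]}
                for g in self.groups
            ],
            "removed": list(self.removed),
            "zero_variance": list(self.zero_variance),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CorrelationGroups":
        return cls(groups=[{"members": list(g["members"]),
                            "representative": g["representative"]}
                           for g in d["groups"]],
                   removed=list(d["removed"]),
                   zero_variance=list(d["zero_variance"]),
                   threshold=float(d["threshold"]))


class CorrelationPruner(BaseEstimator, TransformerMixin):
    """Drop all but one representative of each correlated feature group.

    A scikit-learn transformer over DataFrames: ``fit`` learns the groups
    on ZIP-level rows, ``transform`` selects the retained columns.
    ``id_columns`` are passed through untouched (the ZIP identifier).
    """

    def __init__(self, threshold: float = 0.90, id_columns: tuple = ("zip_id",)):
        self.threshold = threshold
        self.id_columns = id_columns

    def fit(self, X: pd.DataFrame, y=None):
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must be in (0, 1]")
        if len(X) < 2:
            raise ValueError("need >= 2 rows to estimate correlations")
        feats = [c for c in X.columns if c not in self.id_columns]
        M = X[feats].to_numpy(dtype=np.float64)
        sd = M.std(axis=0, ddof=0)
        zero_var = [feats[i] for i in np.flatnonzero(sd == 0)]
        if zero_var:
            logger.warning(
                "excluding %d zero-variance features from correlation graph: %s",
                len(zero_var), zero_var,
            )
        live = np.flatnonzero(sd > 0)
        names = [feats[i] for i in live]
        groups = CorrelationGroups(threshold=self.threshold, zero_variance=zero_var)
        keep: list[str] = []
        if live.size:
            R = np.corrcoef(M[:, live], rowvar=False)
            if R.ndim == 0:  # single live feature
                R = np.array([[1.0]])
            adj = np.abs(R) >= self.threshold
            np.fill_diagonal(adj, False)
            n_comp, labels = connected_components(
                csr_matrix(adj), directed=False
            )
            var = M[:, live].var(axis=0, ddof=0)
            for comp in range(n_comp):
                members = np.flatnonzero(labels == comp)
                if members.size == 1:
                    keep.append(names[members[0]])
                    continue
                member_names = sorted(names[i] for i in members)
                # representative: highest variance, ties -> smallest name
                best = min(members, key=lambda i: (-var[i], names[i]))
                rep = names[best]
                keep.append(rep)
                groups.groups.append(
                    {"members": member_names, "representative": rep}
                )
                groups.removed.extend(m for m in member_names if m != rep)
        self.retained_features_ = [c for c in feats if c in set(keep)]
        self.groups_ = groups
        self.feature_names_in_ = np.asarray(feats, dtype=object)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        ids = [c for c in self.id_columns if c in X.columns]
        return X[ids + self.retained_features_].copy()

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.retained_features_, dtype=object)


def prune_correlated(
    zips: pd.DataFrame, threshold: float = 0.90
) -> tuple[pd.DataFrame, CorrelationGroups]:
    """Prune the ZIP feature table; returns (pruned table, audit groups)."""
    pruner = CorrelationPruner(threshold=threshold).fit(zips)
    return pruner.transform(zips), pruner.groups_


@dataclass
class DesignMatrix:
    """Patient-level modelling matrix for one age stratum.

    ``features`` carries one row per patient holding that patient's ZIP
    covariates; ``groups`` is the per-patient ZIP code, the grouping
    factor of the cross-validation (and the collapse key of the weighted
    forest fit).
    """

    patient_ids: np.ndarray
    labels: np.ndarray
    features: pd.DataFrame
    groups: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.patient_ids)
        if not (len(self.labels) == len(self.features) == len(self.groups) == n):
            raise ValueError("parallel fields of DesignMatrix differ in length")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_cases(self) -> int:
        return int(self.labels.sum())

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def subset_features(self, names: list[str]) -> "DesignMatrix":
        missing = [n for n in names if n not in self.features.columns]
        if missing:
            raise ValueError(f"unknown features: {missing}")
        return DesignMatrix(self.patient_ids, self.labels,
                            self.features[names], self.groups)


def build_design(patients: pd.DataFrame, zips: pd.DataFrame) -> DesignMatrix:
    """Attach ZIP covariates to every patient without splitting by age."""
    known = set(zips["zip_id"])
    unknown = patients.loc[~patients["zip_id"].isin(known), "zip_id"]
    if len(unknown):
        ids = sorted(unknown.unique().tolist())
        raise ValueError(f"patients reference unknown ZIP codes: {ids}")
    feat_cols = [c for c in zips.columns if c != "zip_id"]
    feats = (
        zips.set_index("zip_id").loc[patients["zip_id"], feat_cols]
        .reset_index(drop=True)
    )
    return DesignMatrix(
        patient_ids=patients["patient_id"].to_numpy(),
        labels=patients["label"].to_numpy(dtype=np.int64),
        features=feats,
        groups=patients["zip_id"].to_numpy(),
    )


def join_and_split(
    patients: pd.DataFrame, zips: pd.DataFrame, age_cutoff: int = AGE_CUTOFF
) -> tuple[DesignMatrix, DesignMatrix]:
    """Attach ZIP covariates to patients and split the cohort at the cutoff.

    Returns ``(older, younger)`` where the older stratum contains
    patients of age >= ``age_cutoff`` (the boundary patient is old) and
    the younger the rest; the two strata partition the input.
    """
    known = set(zips["zip_id"])
    unknown = patients.loc[~patients["zip_id"].isin(known), "zip_id"]
    if len(unknown):
        ids = sorted(unknown.unique().tolist())
        raise ValueError(f"patients reference unknown ZIP codes: {ids}")
    feat_cols = [c for c in zips.columns if c != "zip_id"]
    zz = zips.set_index("zip_id")
    out = []
    for mask in (patients["age"] >= age_cutoff, patients["age"] < age_cutoff):
        sub = patients.loc[mask]
        feats = zz.loc[sub["zip_id"], feat_cols].reset_index(drop=True)
        out.append(
            DesignMatrix(
                patient_ids=sub["patient_id"].to_numpy(),
                labels=sub["label"].to_numpy(dtype=np.int64),
                features=feats,
                groups=sub["zip_id"].to_numpy(),
            )
        )
    return out[0], out[1]
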