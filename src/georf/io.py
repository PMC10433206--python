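"""On-disk contracts: TSV tables, network files, YAML run configuration.

TSV (tab-delimited, header row, '.' decimals, UTF-8) is the canonical
dialect — demographic variable names may contain commas.  Readers reject
rather than impute: a missing or non-numeric cell is an error naming the
offending row and column, and duplicated ZIP identifiers are refused.
Writers are deterministic (stable sort orders), so identical inputs give
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("georf")


@dataclass
class RunConfig:
    """Forest, cross-validation, pruning and network hyperparameters.

    Forest defaults are desk-scale (100 trees, 50-patient leaves); a
    national-scale reproduction would set 1,000/1,000.  ``loop_*``
    override the per-target forests of the all-against-all stage, which
    otherwise would dominate the run time.
    """

    n_trees: int = 100
    min_leaf: int = 50
    n_iterations: int = 5
    mtry_fraction: float | None = None
    bootstrap: bool = True
    test_fraction: float = 0.2
    n_repeats: int = 5
    seed: int = 0
    prune_threshold: float = 0.90
    top_k: int = 20
    forced_features: tuple = ("firearms_per_10k", "alcohol_per_10k")
    loop_edge_fraction: float = 0.01
    loop_n_trees: int = 20
    loop_min_leaf: int = 50
    loop_n_iterations: int = 5

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.loop_n_trees < 1:
            raise ValueError("tree counts must be >= 1")
        if self.min_leaf < 1 or self.loop_min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if self.n_iterations < 1 or self.loop_n_iterations < 1:
            raise ValueError("iteration counts must be >= 1")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if not 0.0 < self.loop_edge_fraction <= 1.0:
            raise ValueError("loop_edge_fraction must be in (0, 1]")
        if not 0.0 < self.prune_threshold <= 1.0:
            raise ValueError("prune_threshold must be in (0, 1]")
        self.forced_features = tuple(self.forced_features)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown run-config keys: {unknown}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ValueError("run config must be a YAML mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["forced_features"] = list(self.forced_features)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype={0: str})


def _check_numeric(df: pd.DataFrame, feature_cols, path) -> pd.DataFrame:
    for col in feature_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} "
                f"in column {col!r}, row {row}"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna())[0])
            raise ValueError(f"{path}: missing value in column {col!r}, row {row}")
        df[col] = numeric
    return df


def read_feature_table(path) -> pd.DataFrame:
    """Read a ZIP feature table; first column must be ``zip_id``."""
    df = _read_table(path)
    if df.columns[0] != "zip_id":
        raise ValueError(f"{path}: first column must be 'zip_id', got {df.columns[0]!r}")
    dup = df["zip_id"][df["zip_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicated zip_id {sorted(dup.unique())}")
    if df["zip_id"].isna().any():
        raise ValueError(f"{path}: missing zip_id")
    return _check_numeric(df, df.columns[1:], path)


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_patient_table(path) -> pd.DataFrame:
    """Read a patient table (patient_id, zip_id, age, label)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"patient_id": str, "zip_id": str})
    required = ["patient_id", "zip_id", "age", "label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df[required].isna().any().any():
        col = df[required].isna().any().idxmax()
        raise ValueError(f"{path}: missing values in column {col!r}")
    df = _check_numeric(df, ["age", "label"], path)
    if not df["label"].isin((0, 1)).all():
        raise ValueError(f"{path}: labels must be 0 or 1")
    df["age"] = df["age"].astype(np.int64)
    df["label"] = df["label"].astype(np.int64)
    return df


def write_patient_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_network(net, path, graphml: bool = False) -> None:
    """Write a network as 3-column TSV sorted by descending weight
    (ties: lexicographic source, target); optionally also GraphML."""
    edges = net.sorted_edges()
    if edges["weight"].isna().any():
        raise ValueError("network contains NaN edge weights")
    edges.to_csv(path, sep="\t", index=False)
    if graphml:
        import networkx as nx

        nx.write_graphml(net.to_networkx(), str(Path(path).with_suffix(".graphml")))


def read_network(path):
    from .loop import LoopNetwork

    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["source", "target", "weight"]:
        raise ValueError(f"{path}: expected columns source, target, weight")
    nodes = sorted(set(df["source"]) | set(df["target"]))
    return LoopNetwork(edges=df, nodes=nodes,
                       n_candidate_edges=len(nodes) * max(len(nodes) - 1, 0))


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def setup_logging(run_dir=None, level=logging.INFO) -> None:
    """Timestamped log lines to stderr and, if given, a run log file."""
    root = logging.getLogger("georf")
    root.setLevel(level)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    for h in list(root.handlers):
        root.removeHandler(h)
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    root.addHandler(sh)
    if run_dir is not None:
        fh = logging.FileHandler(Path(run_dir) / "run.log")
        fh.setFormatter(fmt)
        root.addHandler(fh)
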