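"""One-command orchestration: generate/read -> prune -> split -> model ->
explain -> network, with a provenance manifest.

The run configuration is a single YAML mapping with a ``run`` block (see
:class:`georf.io.RunConfig`) and either a ``synthetic`` block (see
:class:`georf.synthetic.SyntheticConfig`) or an ``inputs`` block naming
a ZIP feature table and a patient table on disk.  All randomness flows
from the configured seeds through named substreams, so a rerun with the
same configuration reproduces byte-identical result files.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .directionality import directionality_table
from .evaluation import reduced_model
from .irf import IterativeRandomForestRegressor
from .loop import filter_top_edges, first_neighbors, loop_infer
from .preprocess import join_and_split, prune_correlated
from .synthetic import (
    CausalFeature,
    CorrGroup,
    SyntheticConfig,
    generate_patients,
    generate_zip_features,
)

logger = logging.getLogger("georf")

__version__ = "0.1.0"

STRATA = ("60_plus", "under_60")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict
    timings: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    version: str = __version__
    status: str = "complete"

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seeds": self.seeds,
            "timings": self.timings,
            "outputs": self.outputs,
            "version": self.version,
            "status": self.status,
        }


def synthetic_config_from_dict(d: dict) -> SyntheticConfig:
    d = dict(d)
    if "causal_features" in d:
        d["causal_features"] = tuple(
            CausalFeature(*c) if isinstance(c, (list, tuple)) else CausalFeature(**c)
            for c in d["causal_features"]
        )
    if "corr_groups" in d:
        d["corr_groups"] = tuple(
            CorrGroup(*g) if isinstance(g, (list, tuple)) else CorrGroup(**g)
            for g in d["corr_groups"]
        )
    import dataclasses

    known = {f.name for f in dataclasses.fields(SyntheticConfig)}
    unknown = sorted(set(d) - known)
    if unknown:
        raise ValueError(f"unknown synthetic-config keys: {unknown}")
    return SyntheticConfig(**d)


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    unknown = sorted(set(raw) - {"run", "synthetic", "inputs"})
    if unknown:
        raise ValueError(f"unknown top-level config keys: {unknown}")
    cfg = {"run": gio.RunConfig.from_dict(raw.get("run", {}))}
    if "synthetic" in raw:
        cfg["synthetic"] = synthetic_config_from_dict(raw["synthetic"])
    elif "inputs" in raw:
        inputs = raw["inputs"]
        missing = {"zip_features", "patients"} - set(inputs)
        if missing:
            raise ValueError(f"inputs block missing keys: {sorted(missing)}")
        cfg["inputs"] = inputs
    else:
        raise ValueError("config needs either a 'synthetic' or an 'inputs' block")
    return cfg


def _write_cv(cv, path: Path) -> None:
    pd.DataFrame(
        {
            "repeat": np.arange(cv.n_repeats),
            "auprc": cv.auprcs,
            "baseline": cv.baselines,
        }
    ).to_csv(path, sep="\t", index=False)


def _write_curves(cv, path: Path) -> None:
    frames = []
    for i, c in enumerate(cv.curves):
        frames.append(
            pd.DataFrame(
                {
                    "repeat": i,
                    "threshold": c.thresholds,
                    "recall": c.recall,
                    "precision": c.precision,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def run_all(config, out_dir) -> RunManifest:
    """Execute the full analysis; returns (and writes) the run manifest.

    Stages: generate or load tables; correlation-prune the ZIP table;
    join and split the cohort at age 60; per stratum fit the full model,
    select and cross-validate the reduced (top-k + vendors) model, and
    estimate feature directionality from the reduced model; finally run
    the all-against-all network stage on the pruned table and extract
    the alcohol-vendor first-neighbor subnetwork.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    run_cfg: gio.RunConfig = config["run"]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gio.setup_logging(out)

    seeds = {"run": run_cfg.seed}
    manifest = RunManifest(config_hash=run_cfg.config_hash(), seeds=seeds,
                           status="running")
    timings = manifest.timings
    outputs = manifest.outputs

    def stage(name):
        class _Ctx:
            def __enter__(self):
                logger.info("stage %s: start", name)
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    manifest.status = f"failed:{name}"
                    gio.write_json(manifest.to_dict(), out / "manifest.json")
                    logger.error("stage %s failed; outputs are stale", name)
                    raise StageError(name, exc) from exc
                timings[name] = round(time.perf_counter() - self.t0, 3)
                logger.info("stage %s: done in %.1fs", name, timings[name])

        return _Ctx()

    with stage("data"):
        if "synthetic" in config:
            syn: SyntheticConfig = config["synthetic"]
            seeds["synthetic"] = syn.seed
            zips = generate_zip_features(syn)
            patients, truth = generate_patients(zips, syn)
            gio.write_json(truth.to_dict(), out / "truth.json")
        else:
            zips = gio.read_feature_table(config["inputs"]["zip_features"])
            patients = gio.read_patient_table(config["inputs"]["patients"])
        gio.write_feature_table(zips, out / "zips.tsv")
        gio.write_patient_table(patients, out / "patients.tsv")

    with stage("prune"):
        pruned, groups = prune_correlated(zips, run_cfg.prune_threshold)
        gio.write_feature_table(pruned, out / "pruned.tsv")
        gio.write_json(groups.to_dict(), out / "groups.json")

    with stage("split"):
        older, younger = join_and_split(patients, pruned)
        strata = {"60_plus": older, "under_60": younger}

    for name, design in strata.items():
        sdir = out / name
        sdir.mkdir(exist_ok=True)
        with stage(f"model:{name}"):
            res = reduced_model(design, run_cfg)
            full = res.full_model
            imp = pd.DataFrame(
                full.importances_.T,
                index=pd.Index(full.feature_names_in_, name="feature"),
                columns=[f"iteration_{i + 1}" for i in range(full.importances_.shape[0])],
            )
            imp.sort_values(imp.columns[-1], ascending=False).to_csv(
                sdir / "importance.tsv", sep="\t"
            )
            (sdir / "reduced_features.txt").write_text(
                "\n".join(res.reduced_features) + "\n"
            )
            _write_cv(res.cv_all, sdir / "cv_all.tsv")
            _write_cv(res.cv_reduced, sdir / "cv_reduced.tsv")
            _write_curves(res.cv_all, sdir / "pr_curves_all.tsv")
            _write_curves(res.cv_reduced, sdir / "pr_curves_reduced.tsv")
        with stage(f"directions:{name}"):
            expl = IterativeRandomForestRegressor(
                n_trees=run_cfg.n_trees, min_leaf=run_cfg.min_leaf,
                mtry_fraction=run_cfg.mtry_fraction,
                n_iterations=run_cfg.n_iterations, bootstrap=run_cfg.bootstrap,
                random_state=(run_cfg.seed + 1) % (2**31),
            )
            expl.fit(design.features[res.reduced_features], design.labels,
                     groups=design.groups)
            directionality_table(expl).to_csv(
                sdir / "directions.tsv", sep="\t", index=False
            )

    with stage("loop"):
        net = loop_infer(pruned, run_cfg)
        top = filter_top_edges(net, run_cfg.loop_edge_fraction)
        gio.write_network(top, out / "network.tsv")
        focal = "alcohol_per_10k"
        if focal in net.nodes:
            sub_source = top if focal in top.nodes else net
            if focal in sub_source.nodes:
                gio.write_network(
                    first_neighbors(sub_source, focal),
                    out / "subnetwork_alcohol.tsv",
                )

    with stage("manifest"):
        for p in sorted(out.rglob("*")):
            if p.is_file() and p.name not in ("manifest.json", "run.log"):
                outputs[str(p.relative_to(out))] = gio.file_digest(p)
        manifest.status = "complete"
        gio.write_json(manifest.to_dict(), out / "manifest.json")
    return manifest


def report(out_dir) -> str:
    """Assemble the tabular run summary; raises if artifacts are missing.

    The document lists, per stratum, the AUPRC of every repeat for both
    models against the prevalence baseline, the top-feature table with
    directions, and network summary statistics.  Regeneration is
    idempotent: it only reads completed artifacts.
    """
    out = Path(out_dir)
    required = ["manifest.json", "network.tsv"] + [
        f"{s}/{f}" for s in STRATA
        for f in ("cv_all.tsv", "cv_reduced.tsv", "directions.tsv")
    ]
    missing = [f for f in required if not (out / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run, missing artifacts: {missing}")
    manifest = gio.read_json(out / "manifest.json")
    if manifest["status"] != "complete":
        raise RuntimeError(f"run status is {manifest['status']!r}, not complete")

    lines = ["# Run summary", "", f"config hash: {manifest['config_hash']}", ""]
    for s in STRATA:
        lines.append(f"## Stratum {s}")
        for tag in ("all", "reduced"):
            cv = pd.read_csv(out / s / f"cv_{tag}.tsv", sep="\t")
            vals = ", ".join(f"{v:.4f}" for v in cv["auprc"])
            lines.append(
                f"- {tag}: AUPRC per repeat [{vals}], "
                f"mean {cv['auprc'].mean():.4f}, "
                f"baseline {cv['baseline'].mean():.4f}"
            )
        d = pd.read_csv(out / s / "directions.tsv", sep="\t")
        lines.append("")
        lines.append("| feature | importance | direction | slope | r2 |")
        lines.append("|---|---|---|---|---|")
        for _, r in d.head(25).iterrows():
            lines.append(
                f"| {r['feature']} | {r['importance']:.4f} | {r['direction']} "
                f"| {r['slope']:.4g} | {r['r_squared']:.3f} |"
            )
        lines.append("")
    net = pd.read_csv(out / "network.tsv", sep="\t")
    nodes = set(net["source"]) | set(net["target"])
    lines.append("## Feature network")
    lines.append(
        f"- retained edges: {len(net)}; nodes: {len(nodes)}; "
        f"max weight {net['weight'].max():.4f}" if len(net)
        else "- retained edges: 0"
    )
    text = "\n".join(lines) + "\n"
    (out / "report.md").write_text(text)
    return text
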