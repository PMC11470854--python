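"""End-to-end experiment runner: encode -> split -> train -> evaluate.

`run_experiment` wires the whole pipeline from a single config mapping
(typically loaded from YAML): encode the labelled sequences under the
requested schemes, hold out a stratified test split, score every
scheme x kernel combination, run (repeated) 10-fold cross-validation,
optionally grid-search C x gamma, rank features by mutual information,
and score the baseline classifiers — writing table-layout CSVs plus a
run manifest for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .baselines import BASELINE_MODELS, BaselineConfig, comparison_table, train_and_score_baseline
from .encoders import SCHEMES, encode_dataset
from .evaluation import CVConfig, grid_search, kfold_cv, repeated_kfold_cv
from .feature_selection import mi_ranking, top_k
from .metrics import KERNELS, SplitConfig, SVMConfig, evaluate_model, train_svm
from .sequence_io import LabeledDataset, load_labeled_fasta, validate_and_filter
from .synthetic import SyntheticConfig, generate

log = logging.getLogger("patatinpred")

DEFAULT_CONFIG: dict = {
    "schemes": list(SCHEMES),
    "kernels": list(KERNELS),
    "train_fraction": 0.8,
    "cv": {"k": 10, "repeats": 10},
    "grid_search": {"enabled": False, "kernel": "rbf"},
    "mi": {"enabled": True, "scheme": "DPC", "top_k": 10},
    "baselines": {"enabled": True, "scheme": "DPC"},
    "seed": 0,
}


@dataclass
class RunManifest:
    """Provenance snapshot written next to every result bundle."""

    config: dict
    seed: int
    versions: dict[str, str]
    input_checksums: dict[str, str]
    timestamp: str

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _versions() -> dict[str, str]:
    import sklearn

    return {
        "patatinpred": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
            log.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


@_stage("load")
def _load_dataset(config: dict) -> tuple[LabeledDataset, dict[str, str]]:
    checksums: dict[str, str] = {}
    if "positive_fasta" in config:
        pos, neg = Path(config["positive_fasta"]), Path(config["negative_fasta"])
        records = load_labeled_fasta(pos, neg)
        checksums = {str(pos): _sha256(pos), str(neg): _sha256(neg)}
        data, report = validate_and_filter(records, policy=config.get("residue_policy", "drop"))
        log.info("loaded %d records (%d removed by filtering)", len(data), report.total_removed)
    else:
        synth = config.get("synthetic", {})
        cfg = SyntheticConfig(seed=config.get("seed", 0), **synth)
        data = generate(cfg)
        log.info("generated synthetic dataset: %s", data.class_counts)
    return data, checksums


def run_experiment(config: dict, outdir: str | Path) -> dict:
    """Execute the configured pipeline; returns the results as a dict.

    `config` keys (all optional except an input source): either
    `positive_fasta` + `negative_fasta`, or `synthetic` (kwargs of
    SyntheticConfig); plus `schemes`, `kernels`, `train_fraction`,
    `cv: {k, repeats}`, `grid_search: {enabled, kernel}`, `mi`,
    `baselines`, `seed`.
    """
    cfg = {**DEFAULT_CONFIG, **config}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    data, checksums = _load_dataset(cfg)

    matrices = {}
    for scheme in cfg["schemes"]:
        matrices[scheme] = _stage(f"encode:{scheme}")(encode_dataset)(data, scheme)

    split_cfg = SplitConfig(train_fraction=cfg["train_fraction"], seed=seed)
    from .metrics import split_dataset

    results: dict = {"holdout": [], "cv": [], "repeated_cv": []}
    splits = {
        scheme: _stage("split")(split_dataset)(m, split_cfg)
        for scheme, m in matrices.items()
    }

    for scheme, (train, test) in splits.items():
        for kernel in cfg["kernels"]:
            model = _stage(f"train:{scheme}:{kernel}")(train_svm)(
                train, SVMConfig(kernel=kernel, seed=seed)
            )
            report = evaluate_model(model, test)
            for metric, value in report.as_dict().items():
                results["holdout"].append(
                    {"scheme": scheme, "kernel": kernel, "metric": metric, "value": value}
                )

    cv_cfg = CVConfig(k=cfg["cv"]["k"], seed=seed)
    rep_cfg = CVConfig(k=cfg["cv"]["k"], repeats=cfg["cv"]["repeats"], seed=seed)
    for scheme, matrix in matrices.items():
        for kernel in cfg["kernels"]:
            model_cfg = SVMConfig(kernel=kernel, seed=seed)
            single = _stage(f"cv:{scheme}:{kernel}")(kfold_cv)(matrix, model_cfg, cv_cfg)
            results["cv"].append(
                {"scheme": scheme, "kernel": kernel, "mean": single.mean, "sd": single.sd}
            )
            if rep_cfg.repeats >= 2:
                rep = _stage(f"rcv:{scheme}:{kernel}")(repeated_kfold_cv)(
                    matrix, model_cfg, rep_cfg
                )
                results["repeated_cv"].append(
                    {"scheme": scheme, "kernel": kernel, "mean": rep.mean, "sd": rep.sd}
                )

    if cfg["grid_search"]["enabled"]:
        gs_kernel = cfg["grid_search"].get("kernel", "rbf")
        gs_scheme = cfg["grid_search"].get("scheme", "DPC")
        gs = _stage("gridsearch")(grid_search)(matrices[gs_scheme], gs_kernel, cv_cfg)
        gs.surface().to_csv(outdir / f"grid_{gs_scheme}_{gs_kernel}.csv")
        results["grid_search"] = {
            "kernel": gs_kernel,
            "scheme": gs_scheme,
            "best_C": gs.best_params[0],
            "best_gamma": gs.best_params[1],
            "best_score": gs.best_score,
        }

    if cfg["mi"]["enabled"]:
        scheme = cfg["mi"].get("scheme", "DPC")
        ranking = _stage("mi")(mi_ranking)(matrices[scheme], seed=seed)
        ranking.to_frame().to_csv(outdir / f"mi_{scheme}.csv", index=False)
        results["mi_top"] = top_k(ranking, cfg["mi"].get("top_k", 10))

    if cfg["baselines"]["enabled"]:
        scheme = cfg["baselines"].get("scheme", "DPC")
        train, test = splits[scheme]
        reports = {
            name: _stage(f"baseline:{name}")(train_and_score_baseline)(
                train, test, BaselineConfig(model_type=name, seed=seed)
            )
            for name in BASELINE_MODELS
        }
        table = comparison_table(reports)
        table.to_csv(outdir / "baselines.csv", index=False)
        results["baselines"] = table.to_dict(orient="records")

    pd.DataFrame(results["holdout"]).to_csv(outdir / "holdout_metrics.csv", index=False)
    pd.DataFrame(results["cv"]).to_csv(outdir / "cv_scores.csv", index=False)
    if results["repeated_cv"]:
        pd.DataFrame(results["repeated_cv"]).to_csv(outdir / "repeated_cv_scores.csv", index=False)

    manifest = RunManifest(
        config=cfg,
        seed=seed,
        versions=_versions(),
        input_checksums=checksums,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    manifest.write(outdir / "manifest.json")
    return results
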