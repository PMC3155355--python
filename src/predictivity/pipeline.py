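"""End-to-end workflow: split, filter, search, fit, validate, diagnose.

``run_full_pipeline`` wires the modules together the way a full model-
identification study runs: load the property table, (re)split it, build
or load a descriptor matrix, apply the validity filters, search for the
best descriptor subset, fit and LOO-validate it, compute the correlation
battery, dichotomize observed and estimated properties, and produce the
diagnostic reports.  All randomness flows from ``RunConfig.seed`` so a
rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import correlation, dataset, diagnostics, regression, synthetic

logger = logging.getLogger("predictivity")

__all__ = ["RunConfig", "run_full_pipeline"]


@dataclass
class RunConfig:
    """Parameters controlling one reproducible pipeline run."""

    seed: int = 0
    threshold: float = 0.0
    alpha: float = 0.05
    ci_method: str = "clopper_pearson"
    train_fraction: float = 2 / 3
    max_k: int = 4
    resplit: bool = False
    property_table: str = "table4"
    descriptor_csv: str | None = None
    # synthesis parameters, used when no descriptor CSV is given
    n_descriptors: int = 10
    k_signal: int = 4
    r2_target: float = 0.61
    collinearity: float = 0.2
    corr_max: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.train_fraction < 1:
            raise ValueError(
                f"train_fraction must be in (0, 1), got {self.train_fraction}"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a flat key: value config (YAML-subset / INI-style)."""
        values: dict[str, Any] = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, raw = line.partition(":")
            key, raw = key.strip(), raw.strip()
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            if raw.lower() in ("true", "false"):
                values[key] = raw.lower() == "true"
            else:
                try:
                    values[key] = int(raw)
                except ValueError:
                    try:
                        values[key] = float(raw)
                    except ValueError:
                        values[key] = raw
        return cls(**values)


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute the complete workflow and return the report bundle.

    The bundle is a plain JSON-serializable dict with sections:
    ``config``, ``summaries`` (per-set descriptive statistics),
    ``filter`` (surviving descriptor names), ``best_model`` (fit + LOO),
    ``correlation`` (the seven-coefficient battery on the training set),
    ``durbin_watson`` and ``diagnostics`` (training and test 2x2
    reports plus the rendered text table).
    """
    cfg = config

    def stage(name):
        logger.info("pipeline stage: %s", name)

    stage("load")
    try:
        records = dataset.load_property_table(cfg.property_table)
    except Exception as exc:
        raise RuntimeError(f"stage 'load' failed: {exc}") from exc

    stage("split")
    if cfg.resplit:
        train, test = dataset.random_split(
            records, cfg.train_fraction, seed=cfg.seed, require_normal=True
        )
    else:
        train = [r for r in records if r.set_label == "training"]
        test = [r for r in records if r.set_label == "test"]
        if not train or not test:
            train, test = dataset.random_split(
                records, cfg.train_fraction, seed=cfg.seed
            )

    summaries = {
        name: dataclasses.asdict(dataset.summarize_set(sub, "all"))
        for name, sub in (("training", train), ("test", test))
    }

    stage("descriptors")
    y_train = np.array([r.logbb for r in train])
    if cfg.descriptor_csv:
        X_all = synthetic.DescriptorMatrix.from_csv(cfg.descriptor_csv)
        ids = list(X_all.compound_ids)
        try:
            X_train = synthetic.DescriptorMatrix(
                tuple(r.compound_id for r in train), X_all.names,
                X_all.values[[ids.index(r.compound_id) for r in train]],
            )
            X_test = synthetic.DescriptorMatrix(
                tuple(r.compound_id for r in test), X_all.names,
                X_all.values[[ids.index(r.compound_id) for r in test]],
            )
            y_test = np.array([r.logbb for r in test])
        except ValueError as exc:
            raise RuntimeError(f"stage 'descriptors' failed: {exc}") from exc
    else:
        # Synthetic stand-in: generated per set with a shared seed stream.
        X_train, y_train = synthetic.generate(
            n=len(train), m=cfg.n_descriptors, k_signal=cfg.k_signal,
            r2_target=cfg.r2_target, collinearity=cfg.collinearity, seed=cfg.seed,
        )
        rng_test_seed = cfg.seed + 1
        X_test_full, y_test = synthetic.generate(
            n=len(test), m=cfg.n_descriptors, k_signal=cfg.k_signal,
            r2_target=cfg.r2_target, collinearity=cfg.collinearity,
            seed=rng_test_seed,
        )
        X_test = synthetic.DescriptorMatrix(
            X_test_full.compound_ids, X_train.names, X_test_full.values
        )

    stage("filter")
    X_valid = synthetic.filter_valid(X_train, y_train, corr_max=cfg.corr_max)

    stage("search")
    candidates = regression.search_models(X_valid, y_train, max_k=cfg.max_k)
    best = candidates[0]

    stage("fit+loo")
    model, loo = best.model, best.loo
    dw = regression.durbin_watson(model.residuals)

    stage("correlate")
    suite = correlation.correlation_suite(y_train, model.fitted)

    stage("diagnose")
    reports = {}
    for name, y_obs, X_mat, est in (
        ("training", y_train, None, model.fitted),
        ("test", y_test, X_test, None),
    ):
        if est is None:
            est = model.predict(X_mat.select(list(best.descriptor_names)).values)
        obs_lab = diagnostics.dichotomize(y_obs, cfg.threshold)
        est_lab = diagnostics.dichotomize(est, cfg.threshold)
        table = diagnostics.build_table(obs_lab, est_lab)
        reports[name] = diagnostics.diagnose(
            table, alpha=cfg.alpha, ci_method=cfg.ci_method
        )

    text = diagnostics.render_report(reports)
    return {
        "config": dataclasses.asdict(cfg),
        "summaries": summaries,
        "filter": {"kept": list(X_valid.names)},
        "best_model": best.to_dict(),
        "durbin_watson": dw,
        "correlation": suite.to_dict(),
        "diagnostics": {k: v.to_dict() for k, v in reports.items()},
        "report_text": text,
    }


def bundle_to_json(bundle: dict, **kwargs) -> str:
    return json.dumps(bundle, sort_keys=True, **kwargs)
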