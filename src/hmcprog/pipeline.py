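"""End-to-end orchestration: simulate -> normalize -> differential -> select
-> model, with per-stage seeds fanned out from a master seed and a run report.

Each stage seed is derived by hashing the stage name together with the master
seed, so a stage is reproducible in isolation without manual seed bookkeeping.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential as diffmod
from . import normalize as normmod
from . import riskmodel as riskmod
from . import selection as selmod
from .simulate import HmcSimConfig, simulate_counts

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Stage toggles and per-stage settings for a full synthetic run."""

    seed: int = 0
    outdir: str | None = None
    sim: HmcSimConfig = field(default_factory=lambda: HmcSimConfig(n_features=2000))
    use_combat: bool = False
    pseudocount: float = 1.0
    thresholds: diffmod.DifferentialThresholds = field(
        default_factory=diffmod.DifferentialThresholds
    )
    screen_p: float = 0.01
    selection: selmod.SelectionConfig = field(default_factory=selmod.SelectionConfig)
    split_ratio: float = 2 / 3
    min_specificity: float = 0.90
    n_boot_ci: int = 500
    stages: tuple[str, ...] = ("simulate", "normalize", "diff", "select", "model")

    def config_hash(self) -> str:
        def _enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if hasattr(o, "__dict__"):
                return vars(o)
            return str(o)

        payload = json.dumps(asdict(self), default=_enc, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-stage record counts, the retained panel and model metrics."""

    config_hash: str
    seed: int
    stage_counts: dict = field(default_factory=dict)
    panel: list = field(default_factory=list)
    metrics: dict = field(default_factory=dict)
    elapsed: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "stage_counts": self.stage_counts,
                "panel": self.panel,
                "metrics": self.metrics,
            },
            indent=2,
            sort_keys=True,
        )


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the enabled stages in order on simulated data.

    Stages must form a prefix-consistent chain: each enabled stage requires
    its upstream products and raises a stage-named error otherwise.
    """
    report = RunReport(config_hash=config.config_hash(), seed=config.seed)
    state: dict = {}

    def _timed(stage, fn):
        t0 = _time.perf_counter()
        logger.info("stage=%s seed=%s start", stage, stage_seed(config.seed, stage))
        try:
            fn()
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise StageError(stage, str(exc)) from exc
        report.elapsed[stage] = _time.perf_counter() - t0
        logger.info("stage=%s elapsed=%.2fs", stage, report.elapsed[stage])

    if "simulate" in config.stages:
        def _simulate():
            sim_cfg = config.sim
            sim_cfg.seed = stage_seed(config.seed, "simulate")
            counts, meta, truth = simulate_counts(sim_cfg)
            state.update(counts=counts, meta=meta, truth=truth)
            report.stage_counts["features_simulated"] = len(counts)
        _timed("simulate", _simulate)

    if "normalize" in config.stages:
        if "counts" not in state:
            raise StageError("normalize", "no counts available (simulate stage disabled?)")
        def _normalize():
            factors = normmod.size_factors(state["counts"])
            norm = normmod.normalize_log(state["counts"], factors, config.pseudocount)
            if config.use_combat:
                covars = state["meta"][["group", "age", "gender"]]
                norm, _ = normmod.combat_adjust(norm, state["meta"]["batch"], covars)
            state["norm"] = norm
            state["scaled"] = state["counts"] / factors
            report.stage_counts["features_normalized"] = len(norm.values)
        _timed("normalize", _normalize)

    if "diff" in config.stages:
        if "norm" not in state:
            raise StageError("diff", "no normalized matrix (normalize stage disabled?)")
        def _diff():
            meta = state["meta"]
            table = diffmod.differential_table(state["scaled"], meta["group"], config.pseudocount)
            table = diffmod.call_differential(table, config.thresholds)
            screen = diffmod.covariate_screen(
                state["norm"].values, meta["group"], meta["age"], meta["gender"], config.screen_p
            )
            state["diff_table"] = table
            state["candidates"] = list(screen.loc[screen["candidate"], "feature_id"])
            report.stage_counts["features_called"] = int((table["direction"] != "ns").sum())
            report.stage_counts["candidates"] = len(state["candidates"])
        _timed("diff", _diff)

    if "select" in config.stages:
        if "candidates" not in state:
            raise StageError("select", "no candidate features (diff stage disabled?)")
        def _select():
            if not state["candidates"]:
                raise ValueError("candidate list is empty")
            meta = state["meta"]
            split = riskmod.split_train_valid(
                meta, config.split_ratio, stage_seed(config.seed, "split")
            )
            state["split"] = split
            X = state["norm"].values.loc[state["candidates"]].T  # samples x features
            tr = split == "train"
            sel_cfg = config.selection
            sel_cfg.seed = stage_seed(config.seed, "select")
            y = (meta["group"] == "case").astype(int)
            result = selmod.stability_select(X.loc[tr.to_numpy()], y[tr.to_numpy()], sel_cfg)
            state["selection"] = result
            report.panel = list(result.panel)
            report.stage_counts["panel"] = len(result.panel)
        _timed("select", _select)

    if "model" in config.stages:
        if "selection" not in state:
            raise StageError("model", "no selection result (select stage disabled?)")
        def _model():
            panel = state["selection"].panel
            if not panel:
                raise ValueError("empty panel; cannot fit the risk model")
            meta = state["meta"]
            X = state["norm"].values.loc[panel].T
            fit = riskmod.end_to_end(
                X,
                meta,
                state["split"],
                min_specificity=config.min_specificity,
                n_boot=config.n_boot_ci,
                seed=stage_seed(config.seed, "model"),
            )
            state["fit"] = fit
            report.metrics = {
                "train_auc": fit.train_auc,
                "train_auc_ci": list(fit.train_auc_ci),
                "valid_auc": fit.valid_auc,
                "valid_auc_ci": list(fit.valid_auc_ci),
                "cutoff": fit.cutoff,
                "sensitivity_all": fit.sensitivity_all,
                "specificity_all": fit.specificity_all,
            }
        _timed("model", _model)

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "run_report.json").write_text(report.to_json())
        if "diff_table" in state:
            state["diff_table"].to_csv(outdir / "differential.tsv", sep="\t", index=False)
        if "selection" in state:
            state["selection"].frequencies.to_csv(outdir / "selection_frequencies.tsv", sep="\t")
    report.metrics["report_hash"] = hashlib.sha256(report.to_json().encode()).hexdigest()[:16]
    return report
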