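"""YAML/JSON experiment configuration loading."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .bayes import BayesConfig
from .cascade import CascadeParams
from .decision import DecisionParams
from .experiments import ExperimentConfig
from .surprise import SurpriseParams
from .tasks import BlockSchedule, Segment, VISchedule

__all__ = ["load_config", "config_from_dict"]


def _cascade_from(d: dict) -> CascadeParams:
    if "base" in d:
        return CascadeParams.geometric(d["base"], d["m"],
                                       gamma=d.get("gamma", 0.0),
                                       nr_shift=d.get("nr_shift", 0))
    if "alpha" in d:  # single fixed rate
        return CascadeParams.single(d["alpha"], gamma=d.get("gamma", 0.0))
    return CascadeParams(
        alpha_r=np.asarray(d["alpha_r"], dtype=float),
        alpha_nr=np.asarray(d.get("alpha_nr", d["alpha_r"]), dtype=float),
        p_r=np.asarray(d["p_r"], dtype=float),
        p_nr=np.asarray(d.get("p_nr", d["p_r"]), dtype=float),
        gamma=d.get("gamma", 0.0),
    )


def _schedule_from(d: dict) -> BlockSchedule:
    if "segments" in d:
        segs = tuple(Segment(s["type"], tuple(s["values"]), s["length"],
                             s.get("isi_units", 0)) for s in d["segments"])
        return BlockSchedule(segs)
    kind = d["type"].upper()
    block = d.get("block", d.get("length"))
    n_blocks = d.get("n_blocks", 1)
    if kind == "VI":
        return BlockSchedule.reversal_vi(d["total_rate"], d["ratio"], block,
                                         n_blocks, d.get("isi_units", 0))
    probs = d["reward_probs"]
    return BlockSchedule.rotating_vr(max(probs), min(probs), len(probs),
                                     [block] * n_blocks)


def config_from_dict(d: dict, seed: int | None = None) -> ExperimentConfig:
    run = d.get("run", {})
    surprise_cfg = d.get("surprise")
    kw = dict(
        schedule=_schedule_from(d["task"]),
        model=d.get("model", "cascade+surprise"),
        decision=DecisionParams(**d.get("decision", {})),
        n_runs=run.get("n_runs", 1),
        seed=seed if seed is not None else run.get("seed", 0),
        record_monitors=run.get("record_monitors", False),
    )
    if "cascade" in d:
        kw["cascade"] = _cascade_from(d["cascade"])
    if surprise_cfg:
        levels = surprise_cfg.pop("monitor_levels", None)
        kw["surprise"] = SurpriseParams(**surprise_cfg)
        if levels is not None:
            kw["monitor_levels"] = tuple(levels)
    elif surprise_cfg is None and kw["model"] == "cascade+surprise" and "surprise" in d:
        kw["model"] = "cascade"
    if "bayes" in d:
        kw["bayes"] = BayesConfig(**d["bayes"])
    return ExperimentConfig(**kw)


def load_config(path, seed: int | None = None) -> ExperimentConfig:
    text = Path(path).read_text()
    d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return config_from_dict(d, seed=seed)
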