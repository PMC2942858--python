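"""Experiment configuration, orchestration and result serialization.

A power experiment is a list of scenarios, each pairing a simulation design
with a classifier and a metric.  Null distributions are cached and shared
across scenarios that agree on everything the null depends on (classifier,
metric, class sizes, feature count, biomarker fraction, distribution family
and biomarker correlation) — the null never depends on delta.  Everything is
reproducible from (config, seed): per-dataset seeds are fixed before any
work is dispatched, so results are independent of worker count.
"""

from __future__ import annotations

import logging
import sys
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from joblib import Parallel, delayed

from .classifiers import CLASSIFIER_KINDS, ClassifierSpec
from .datasets import SimulationDesign, effect_to_delta
from .evaluation import METRIC_KINDS
from .power import build_null, estimate_power, results_row, results_table

log = logging.getLogger("classpower")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)

_SCENARIO_KEYS = {
    "id", "classifier", "metric", "n_case", "n_control", "n_per_class",
    "n_features", "k", "n_biomarkers", "effect_size", "delta", "dist",
    "rho", "prior_policy", "knn_k", "rf_trees", "nsc_n_thresholds",
    "sigma2", "tail_prob", "c1", "c2",
}
_TOP_KEYS = {"seed", "n_sim", "n_null", "out", "workers", "scenarios"}


@dataclass
class Scenario:
    scenario_id: str
    spec: ClassifierSpec
    design: SimulationDesign
    metric_kind: str
    effect_size: float


@dataclass
class ExperimentConfig:
    scenarios: list[Scenario]
    seed: int
    n_sim: int = 100
    n_null: int = 100
    out: Optional[str] = None
    workers: int = 1


def _build_scenario(raw: dict, index: int) -> Scenario:
    where = f"scenarios[{index}]"
    unknown = set(raw) - _SCENARIO_KEYS
    if unknown:
        raise ValueError(f"{where}: unknown keys {sorted(unknown)}")

    kind = raw.get("classifier", "nsc")
    if kind not in CLASSIFIER_KINDS:
        raise ValueError(f"{where}.classifier: unknown classifier {kind!r}")
    metric = raw.get("metric", "accuracy")
    if metric not in METRIC_KINDS:
        raise ValueError(f"{where}.metric: unknown metric {metric!r}")

    if "n_per_class" in raw:
        n_case = n_control = int(raw["n_per_class"])
    else:
        try:
            n_case = int(raw["n_case"])
            n_control = int(raw["n_control"])
        except KeyError as exc:
            raise ValueError(f"{where}: missing sample size key {exc}") from exc
    n_features = int(raw.get("n_features", 1000))
    if "n_biomarkers" in raw:
        n_biomarkers = int(raw["n_biomarkers"])
    else:
        n_biomarkers = int(round(float(raw.get("k", 0.01)) * n_features))
    dist = raw.get("dist", "gaussian")
    if "delta" in raw:
        delta = float(raw["delta"])
        effect = delta / np.sqrt(0.8 if dist == "mixture" else 0.2)
    else:
        effect = float(raw.get("effect_size", 0.0))
        delta = effect_to_delta(effect, dist)

    spec = ClassifierSpec(
        kind=kind,
        knn_k=int(raw.get("knn_k", 5)),
        rf_trees=int(raw.get("rf_trees", 500)),
        nsc_n_thresholds=int(raw.get("nsc_n_thresholds", 30)),
        prior_policy=raw.get("prior_policy", "empirical"),
    )
    design = SimulationDesign(
        n_case=n_case,
        n_control=n_control,
        n_features=n_features,
        n_biomarkers=n_biomarkers,
        delta=delta,
        sigma2=float(raw.get("sigma2", 0.2)),
        dist_kind=dist,
        tail_prob=float(raw.get("tail_prob", 0.1)),
        c1=float(raw.get("c1", 3.0)),
        c2=float(raw.get("c2", 6.7)),
        biomarker_correlation=float(raw.get("rho", 0.0)),
    )
    return Scenario(
        scenario_id=str(raw.get("id", f"scenario_{index}")),
        spec=spec, design=design, metric_kind=metric,
        effect_size=float(effect),
    )


def config_from_dict(doc: dict) -> ExperimentConfig:
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown top-level keys {sorted(unknown)}")
    if "seed" not in doc:
        raise ValueError("config must set a seed")
    raw_scen = doc.get("scenarios", [])
    if not raw_scen:
        raise ValueError("config must define at least one scenario")
    scenarios = [_build_scenario(s, i) for i, s in enumerate(raw_scen)]
    return ExperimentConfig(
        scenarios=scenarios,
        seed=int(doc["seed"]),
        n_sim=int(doc.get("n_sim", 100)),
        n_null=int(doc.get("n_null", 100)),
        out=doc.get("out"),
        workers=int(doc.get("workers", 1)),
    )


def parse_config(path) -> ExperimentConfig:
    """Parse a YAML (or JSON) experiment configuration with defaults filled."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValueError("config root must be a mapping")
    return config_from_dict(doc)


def _null_key(s: Scenario) -> tuple:
    return (
        s.spec.kind, s.spec.prior_policy, s.spec.rf_trees, s.spec.knn_k,
        s.spec.nsc_n_thresholds, s.metric_kind,
        s.design.n_case, s.design.n_control, s.design.n_features,
        s.design.n_biomarkers, s.design.dist_kind,
        s.design.biomarker_correlation,
    )


def _scenario_seed(root: int, key: tuple, offset: int) -> int:
    # stable across processes (builtin hash() is salted per run)
    digest = zlib.crc32(repr(key).encode())
    h = np.random.SeedSequence(entropy=int(root), spawn_key=(digest, offset))
    return int(h.generate_state(1, dtype=np.uint64)[0] % 2**31)


def run_power_experiment(config: ExperimentConfig):
    """Run every scenario, reusing cached nulls; returns the results table.

    Scenarios sharing a null key run in the same worker group so the null is
    built once.  With ``config.out`` set, the CSV is (re)written after every
    completed scenario, so partial results survive interruption.
    """
    import time

    groups: dict[tuple, list[Scenario]] = {}
    for s in config.scenarios:
        groups.setdefault(_null_key(s), []).append(s)

    def run_group(key: tuple, members: list[Scenario]) -> list[dict]:
        null_seed = _scenario_seed(config.seed, key, 0)
        t0 = time.time()
        null = build_null(
            members[0].spec, members[0].design, members[0].metric_kind,
            n_null=config.n_null, seed=null_seed,
        )
        log.info(
            "null %s built in %.1fs (threshold %.4f)",
            key, time.time() - t0, null.threshold,
        )
        rows = []
        for s in members:
            t0 = time.time()
            res = estimate_power(
                s.spec, s.design, s.metric_kind, null=null,
                n_sim=config.n_sim,
                seed=_scenario_seed(config.seed, key, 1 + members.index(s)),
            )
            log.info(
                "scenario %s: power %.2f [%.2f, %.2f] in %.1fs",
                s.scenario_id, res.power, res.ci_low, res.ci_high,
                time.time() - t0,
            )
            rows.append(
                results_row(s.scenario_id, s.spec, s.design, s.metric_kind,
                            s.effect_size, res, config.seed)
            )
        return rows

    all_rows: list[dict] = []
    if config.workers > 1:
        chunks = Parallel(n_jobs=config.workers)(
            delayed(run_group)(key, members) for key, members in groups.items()
        )
        for chunk in chunks:
            all_rows.extend(chunk)
    else:
        for key, members in groups.items():
            all_rows.extend(run_group(key, members))
            if config.out:
                results_table(all_rows).to_csv(config.out, index=False)

    order = {s.scenario_id: i for i, s in enumerate(config.scenarios)}
    all_rows.sort(key=lambda r: order[r["scenario"]])
    table = results_table(all_rows)
    if config.out:
        table.to_csv(config.out, index=False)
    return table
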