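"""End-to-end orchestration: cohort -> risk -> strategies -> Markov -> CEA.

``run_pipeline`` performs the full deterministic base-case analysis and
writes publication-shaped CSV outputs (a cost-effectiveness table ordered
by QALYs, a benefit-harm table, the efficiency frontier) plus a manifest
with the seed and config digest so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from . import __version__
from ._synthetic import synthetic_hazard_ratio_table, synthetic_rate_table
from .cea import benefit_harm_table, cea_table
from .cohort import TABLE2_SPEC, CohortSpec, generate_cohort
from .config import RunConfig
from .economics import EconParams
from .markov import ModelParams, build_strata, run_all_strategies
from .risk import (HazardRateTable, bruzzi_params_from_cohort, cohort_absolute_risk,
                   stratify)
from .strategies import STATUS_QUO, enumerate_strategies, parse_strategy

__all__ = ["prepare_inputs", "run_pipeline", "make_runner"]


def _load_tables(config: RunConfig):
    rates = (HazardRateTable.from_csv(config.rate_table)
             if config.rate_table else synthetic_rate_table())
    hr = (pd.read_csv(config.hazard_ratio_table)
          if config.hazard_ratio_table else synthetic_hazard_ratio_table())
    return rates, hr


def _model_econ(config: RunConfig):
    model = ModelParams(adherence=config.adherence, **config.model_overrides)
    econ = EconParams(discount_rate=config.discount_rate, wtp=config.wtp,
                      **config.econ_overrides)
    return model, econ


def _select_strategies(config: RunConfig):
    if config.strategies == "all":
        return enumerate_strategies()
    names = (config.strategies.split(",") if isinstance(config.strategies, str)
             else list(config.strategies))
    return [parse_strategy(n.strip()) for n in names]


def prepare_inputs(config: RunConfig, spec: CohortSpec | None = None):
    """Build cohort, risk parameters and Markov strata from a config."""
    spec = spec or TABLE2_SPEC
    rates, hr_table = _load_tables(config)
    cohort = generate_cohort(spec, seed=config.seed)
    risk_params = bruzzi_params_from_cohort(
        cohort.individuals, hr_table, spec.group_incidence_density)
    scored = cohort_absolute_risk(cohort.individuals, rates, risk_params)
    strata = build_strata(
        scored, rates, risk_params, horizon=config.horizon,
        quit_smoking=config.quit_smoking,
        group_densities=spec.group_incidence_density)
    return {"cohort": scored, "rates": rates, "risk_params": risk_params,
            "strata": strata, "spec": spec}


def make_runner(strata, strategies):
    """Closure rerunning every strategy for given parameter draws (PSA/OWSA)."""
    def runner(model, econ):
        outcomes = run_all_strategies(strategies, strata, model, econ)
        return pd.DataFrame(
            {"strategy": [o.strategy for o in outcomes],
             "cost": [o.total_cost for o in outcomes],
             "qaly": [o.total_qalys for o in outcomes]})
    return runner


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the base-case analysis; optionally write CSV outputs."""
    inputs = prepare_inputs(config)
    model, econ = _model_econ(config)
    strategies = _select_strategies(config)
    outcomes = run_all_strategies(strategies, inputs["strata"], model, econ)

    names = {s.name for s in strategies}
    result = {"outcomes": outcomes, "inputs": inputs, "model": model, "econ": econ}
    if STATUS_QUO in names and len(outcomes) > 1:
        result["cea_table"] = cea_table(outcomes, STATUS_QUO, wtp=econ.wtp)
    if "no_screening" in names and len(outcomes) > 1:
        result["benefit_harm"] = benefit_harm_table(outcomes, "no_screening")
    strat = stratify(inputs["cohort"]["abs_risk_5yr"].to_numpy(), mode="quartile")
    result["quartile_thresholds"] = strat.thresholds

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if "cea_table" in result:
            result["cea_table"].to_csv(out / "cea_table.csv", index=False)
            pd.DataFrame({"strategy": result["cea_table"].attrs["frontier"]}).to_csv(
                out / "frontier.csv", index=False)
        if "benefit_harm" in result:
            result["benefit_harm"].to_csv(out / "benefit_harm.csv", index=False)
        pd.DataFrame([dataclasses.asdict(o) for o in outcomes]).to_csv(
            out / "outcomes.csv", index=False)
        manifest = {"seed": config.seed, "config_digest": config.digest(),
                    "version": __version__, "n_strategies": len(strategies),
                    "par": inputs["risk_params"].par}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
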