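"""One-way and probabilistic sensitivity analysis.

Parameter uncertainty follows the conventional health-economic choices:
Beta distributions for probabilities and utilities, Gamma for costs,
Triangle for adherence and the discount rate.  For parameters whose
uncertainty is stated as "+/- 50%", the method-of-moments fit takes the
half-width as a 95% margin, i.e. CV = 0.5 / 1.96 ~ 0.2551, which gives
every such Gamma a shape of 1/CV^2 ~ 15.37 and determines Beta (a, b)
from the mean and that variance.  Probabilistic sensitivity analysis is a
second-order Monte Carlo: each iteration draws one value per uncertain
parameter (independently), reruns every strategy, and stores per-strategy
discounted cost and QALYs; cost-effectiveness acceptability curves (CEAC)
report, per willingness-to-pay value, the fraction of iterations in which
one strategy's pairwise incremental net monetary benefit is positive.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .economics import EconParams
from .markov import ModelParams

__all__ = ["ParamDistribution", "fit_distribution", "parameter_distributions",
           "sample_params", "one_way", "psa", "ceac", "CV_HALF_RANGE"]

#: Coefficient of variation implied by a +/-50% range read as 1.96 sigma.
CV_HALF_RANGE = 0.5 / 1.96


@dataclass(frozen=True)
class ParamDistribution:
    """A sampled model parameter: beta(a, b), gamma(shape, rate),
    triangle(min, mode, max) or fixed."""

    kind: str
    args: tuple
    base: float

    def __post_init__(self):
        k, a = self.kind, self.args
        if k == "beta":
            if a[0] <= 0 or a[1] <= 0:
                raise ValueError("beta parameters must be positive")
        elif k == "gamma":
            if a[0] <= 0 or a[1] <= 0:
                raise ValueError("gamma shape and rate must be positive")
        elif k == "triangle":
            if not a[0] <= a[1] <= a[2]:
                raise ValueError("triangle needs min <= mode <= max")
        elif k != "fixed":
            raise ValueError(f"unknown distribution kind {k!r}")

    def mean(self) -> float:
        if self.kind == "beta":
            a, b = self.args
            return a / (a + b)
        if self.kind == "gamma":
            shape, rate = self.args
            return shape / rate
        if self.kind == "triangle":
            return sum(self.args) / 3.0
        return self.base

    def sample(self, rng: np.random.Generator, size=None):
        if self.kind == "beta":
            return rng.beta(*self.args, size=size)
        if self.kind == "gamma":
            shape, rate = self.args
            return rng.gamma(shape, 1.0 / rate, size=size)
        if self.kind == "triangle":
            lo, mode, hi = self.args
            if lo == hi:
                return np.full(size, lo) if size else lo
            return rng.triangular(lo, mode, hi, size=size)
        return np.full(size, self.base) if size else self.base


def fit_distribution(base: float, kind: str, cv: float = CV_HALF_RANGE,
                     args: tuple | None = None) -> ParamDistribution:
    """Method-of-moments fit for a +/-50% parameter, or verbatim arguments.

    With explicit ``args`` the printed distribution parameters are used as
    given.  Otherwise ``gamma`` gets shape 1/cv^2 and rate shape/mean, and
    ``beta`` gets (a, b) matching mean ``base`` and variance (cv*base)^2.
    """
    if args is not None:
        return ParamDistribution(kind=kind, args=tuple(args), base=base)
    if kind == "fixed":
        return ParamDistribution(kind="fixed", args=(), base=base)
    if kind == "gamma":
        if base <= 0:
            raise ValueError("gamma base must be positive")
        shape = 1.0 / cv**2
        return ParamDistribution(kind="gamma", args=(shape, shape / base), base=base)
    if kind == "beta":
        if not 0 < base < 1:
            raise ValueError("beta base must lie in (0, 1)")
        var = (cv * base) ** 2
        nu = base * (1 - base) / var - 1.0
        if nu <= 0:
            raise ValueError(f"infeasible beta variance for mean {base} and cv {cv}")
        return ParamDistribution(kind="beta", args=(base * nu, (1 - base) * nu), base=base)
    raise ValueError(f"cannot fit distribution kind {kind!r}")


def _beta50(base: float) -> ParamDistribution:
    return fit_distribution(base, "beta")


def _gamma50(base: float) -> ParamDistribution:
    return fit_distribution(base, "gamma")


def parameter_distributions() -> dict:
    """Uncertainty distribution per (target, field, key).

    Keys are dotted paths into :class:`ModelParams` ('model.') or
    :class:`EconParams` ('econ.').  Test characteristics with published
    exact Beta parameters use them verbatim; +/-50% parameters use the
    method-of-moments fit; adherence and discount rate use Triangles.
    """
    d: dict[str, ParamDistribution] = {}
    mp, ep = ModelParams(), EconParams()
    for key, p in mp.progression.items():
        d[f"model.progression.{key[0]}->{key[1]}"] = _beta50(p)
    for s, p in mp.lc_death_undetected.items():
        d[f"model.lc_death_undetected.{s}"] = _beta50(p)
    for s, p in mp.aftercare_death.items():
        d[f"model.aftercare_death.{s}"] = _beta50(p)
    for s, p in mp.clinical_detection.items():
        d[f"model.clinical_detection.{s}"] = _beta50(p)
    d["model.sensitivity"] = ParamDistribution("beta", (649, 44), mp.sensitivity)
    d["model.specificity"] = ParamDistribution("beta", (56_936, 17_497), mp.specificity)
    d["model.overdiagnosis_rate"] = _beta50(mp.overdiagnosis_rate)
    d["model.excess_rr_per_screen"] = ParamDistribution("beta", (6, 5995), mp.excess_rr_per_screen)
    d["model.adherence"] = ParamDistribution("triangle", (0.5, 1.0, 1.0), mp.adherence)
    for name in ("cost_pre_diagnosis", "cost_ldct", "cost_biopsy", "cost_background"):
        d[f"econ.{name}"] = _gamma50(getattr(ep, name))
    for s, c in ep.cost_stage_first_year.items():
        d[f"econ.cost_stage_first_year.{s}"] = _gamma50(c)
    for s, c in ep.cost_stage_subsequent.items():
        d[f"econ.cost_stage_subsequent.{s}"] = _gamma50(c)
    for s, u in ep.utility_stage.items():
        d[f"econ.utility_stage.{s}"] = _beta50(u)
    d["econ.disutility_tb"] = _beta50(ep.disutility_tb)
    d["econ.disutility_emphysema"] = _beta50(ep.disutility_emphysema)
    d["econ.fp_disutility"] = _beta50(ep.fp_disutility)
    d["econ.discount_rate"] = ParamDistribution("triangle", (0.0, 0.05, 0.08), ep.discount_rate)
    return d


def _set_path(mp: ModelParams, ep: EconParams, path: str, value: float):
    target, rest = path.split(".", 1)
    obj = mp if target == "model" else ep
    if "." in rest:
        fieldname, key = rest.split(".", 1)
        container = dict(getattr(obj, fieldname))
        if fieldname == "progression":
            a, b = key.split("->")
            container[(a, b)] = value
        else:
            container[key] = value
        return replace(obj, **{fieldname: container}) if target == "model" else (
            dataclasses.replace(obj, **{fieldname: container}))
    return replace(obj, **{rest: value})


def sample_params(rng: np.random.Generator, dists: dict | None = None
                  ) -> tuple[ModelParams, EconParams, dict]:
    """Draw one joint parameter set (independent sampling)."""
    dists = dists or parameter_distributions()
    mp, ep = ModelParams(), EconParams()
    drawn = {}
    for path, dist in dists.items():
        value = float(dist.sample(rng))
        if path == "econ.discount_rate":
            value = min(max(value, 0.0), 0.08)
        drawn[path] = value
        out = _set_path(mp, ep, path, value)
        if path.startswith("model."):
            mp = out
        else:
            ep = out
    return mp, ep, drawn


def one_way(param_path: str, low: float, high: float, model_runner,
            focal: str, comparators: tuple) -> dict:
    """One-way sensitivity entry: rerun all strategies at ``low`` and ``high``.

    ``model_runner(mp, ep)`` must return a DataFrame with columns
    (strategy, cost, qaly).  Records the focal strategy's iNMB and ICER vs
    each comparator at both ends for tornado plotting.
    """
    from .cea import icer, inmb  # local import to avoid cycles

    if low > high:
        raise ValueError("low must not exceed high")
    dists = parameter_distributions()
    if param_path not in dists and param_path != "econ.wtp":
        raise KeyError(f"unknown parameter {param_path!r}")
    entry = {"parameter": param_path, "low": low, "high": high}
    for tag, value in (("low", low), ("high", high)):
        mp, ep = ModelParams(), EconParams()
        out = _set_path(mp, ep, param_path, value)
        if param_path.startswith("model."):
            mp = out
        else:
            ep = out
        res = model_runner(mp, ep).set_index("strategy")
        for comp in comparators:
            dc = res.loc[focal, "cost"] - res.loc[comp, "cost"]
            dq = res.loc[focal, "qaly"] - res.loc[comp, "qaly"]
            entry[f"inmb_{comp}_{tag}"] = inmb(dq, dc, ep.wtp)
            entry[f"icer_{comp}_{tag}"] = icer(dc, dq)
    return entry


def psa(n_iter: int, seed: int, model_runner, dists: dict | None = None,
        progress: bool = False) -> pd.DataFrame:
    """Second-order Monte Carlo PSA.

    Returns a tidy DataFrame with columns (iteration, strategy, cost,
    qaly).  Reproducible for a given seed; scale ``n_iter`` up to the
    published 100,000 when compute allows.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    dists = dists or parameter_distributions()
    frames = []
    for it in range(n_iter):
        mp, ep, _ = sample_params(rng, dists)
        res = model_runner(mp, ep)
        res = res.assign(iteration=it)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def ceac(draws: pd.DataFrame, strategy_a: str, strategy_b: str, wtp_grid) -> pd.DataFrame:
    """Fraction of PSA iterations in which A is cost-effective vs B.

    For each WTP: fraction of iterations with pairwise
    iNMB(A vs B) = dQALY x WTP - dCost > 0 (strict inequality; identical
    strategies therefore score 0).
    """
    if draws.empty:
        raise ValueError("no PSA draws supplied")
    piv_c = draws.pivot(index="iteration", columns="strategy", values="cost")
    piv_q = draws.pivot(index="iteration", columns="strategy", values="qaly")
    for s in (strategy_a, strategy_b):
        if s not in piv_c.columns:
            raise KeyError(f"strategy {s!r} absent from PSA draws")
    dc = (piv_c[strategy_a] - piv_c[strategy_b]).to_numpy()
    dq = (piv_q[strategy_a] - piv_q[strategy_b]).to_numpy()
    rows = [{"wtp": float(w), "p_cost_effective": float(np.mean(dq * w - dc > 0))}
            for w in np.asarray(wtp_grid, dtype=float)]
    return pd.DataFrame(rows)
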