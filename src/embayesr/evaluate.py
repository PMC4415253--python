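"""Prediction metrics and the packaged simulation experiments.

Accuracy is the Pearson correlation between GEBV and true breeding values;
the bias slope is the ordinary least-squares regression coefficient of TBV
on GEBV (1 means unbiased predictions).

``run_scenario`` reproduces the benchmark recipes: simulate replicates of a
named genetic architecture, fit any subset of the methods on the reference
split (sharing one REML/PEV computation per replicate), and evaluate on the
validation split.  ``prior_sensitivity`` refits the EM model on one shared
replicate under different Dirichlet pseudo-count vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .em import EMBayesR
from .gblup import GBLUP, SNPBLUP, build_grm, compute_pev, reml_fit
from .genotypes import standardize
from .gibbs import BayesRGibbs
from .simulate import SimConfig, SimReplicate, simulate_replicate

__all__ = [
    "EvaluationResult",
    "accuracy",
    "bias_slope",
    "SCENARIOS",
    "run_scenario",
    "prior_sensitivity",
]

#: named study conditions: architecture and heritability of each benchmark
SCENARIOS = {
    "HD_Mix_45": dict(architecture="mixture", h2=0.45),
    "HD_Mix_10": dict(architecture="mixture", h2=0.10),
    "HD_One_45": dict(architecture="single_normal", h2=0.45),
    "HD_One_10": dict(architecture="single_normal", h2=0.10),
}

DEFAULT_METHODS = ("embayesr", "embayesr_nopev", "gblup")


@dataclass
class EvaluationResult:
    scenario: str
    replicate_id: int
    method: str
    accuracy: float
    bias_slope: float
    n_validation: int


def accuracy(gebv, tbv) -> float:
    """Pearson correlation of GEBV with (true) breeding values."""
    gebv = np.asarray(gebv, dtype=float).ravel()
    tbv = np.asarray(tbv, dtype=float).ravel()
    if gebv.size != tbv.size or gebv.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if np.std(gebv) == 0 or np.std(tbv) == 0:
        raise ValueError("zero variance in GEBV or TBV")
    return float(np.corrcoef(gebv, tbv)[0, 1])


def bias_slope(gebv, tbv) -> float:
    """OLS slope of TBV on GEBV."""
    gebv = np.asarray(gebv, dtype=float).ravel()
    tbv = np.asarray(tbv, dtype=float).ravel()
    if np.var(gebv) == 0:
        raise ValueError("zero variance in GEBV")
    return float(np.cov(tbv, gebv, ddof=1)[0, 1] / np.var(gebv, ddof=1))


def scenario_config(name: str, seed: int, **overrides) -> SimConfig:
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    kw = dict(SCENARIOS[name])
    kw.update(overrides)
    return SimConfig(seed=seed, **kw)


def _sub_seed(master: int, *parts) -> int:
    """Deterministic sub-seed: SeedSequence over the master seed and a
    stable (crc32) hash of each label, reduced below 2**31."""
    import zlib

    keys = [zlib.crc32(str(p).encode()) for p in parts]
    return int(
        np.random.SeedSequence([int(master), *keys]).generate_state(1)[0] % 2**31
    )


def make_method(name: str, seed: int = 0, **kwargs):
    """Estimator registry used by the scenario runner and the CLI."""
    name = name.lower().replace("-", "_")
    if name == "embayesr":
        return EMBayesR(**kwargs)
    if name in ("embayesr_nopev", "embayesr_without_pev"):
        return EMBayesR(use_pev=False, **kwargs)
    if name == "embayesr_mean":
        return EMBayesR(estimator="mean", **kwargs)
    if name in ("bayesr", "bayesr_gibbs"):
        return BayesRGibbs(random_state=seed, **kwargs)
    if name == "gblup":
        return GBLUP(**kwargs)
    if name == "snpblup":
        return SNPBLUP(**kwargs)
    raise ValueError(f"unknown method {name!r}")


def fit_replicate_methods(
    rep: SimReplicate, methods, seed: int = 0, em_kwargs=None, return_models=False
):
    """Fit each method on the reference split of one replicate.

    One REML fit and one PEV summary are computed on the reference set and
    shared across methods so that differences between methods are purely
    algorithmic.  Returns a list of :class:`EvaluationResult` (plus models
    when requested).
    """
    em_kwargs = dict(em_kwargs or {})
    ref, val = rep.reference_idx, rep.validation_idx
    X_ref = rep.genotypes.dosages[ref]
    X_val = rep.genotypes.dosages[val]
    y_ref = rep.phenotypes[ref]
    tbv_val = rep.tbv[val]

    g_ref = rep.genotypes.subset_samples(ref)
    sg_ref = standardize(g_ref)
    grm = build_grm(sg_ref)
    vc = reml_fit(grm, y_ref)
    pev = compute_pev(grm, vc, sg_ref)

    results, models = [], {}
    for method in methods:
        mseed = _sub_seed(seed, method)
        model = make_method(method, seed=mseed, **em_kwargs)
        if isinstance(model, EMBayesR):
            model.fit(
                X_ref, y_ref, variance_components=vc, pev=pev if model.use_pev else None
            )
        elif isinstance(model, BayesRGibbs):
            model.fit(X_ref, y_ref, variance_components=vc)
        else:
            model.set_params(sigma_g2=vc.sigma_g2, sigma_e2=vc.sigma_e2)
            model.fit(X_ref, y_ref)
        gebv = model.gebv(X_val)
        results.append(
            EvaluationResult(
                scenario=rep.config.architecture,
                replicate_id=rep.config.seed,
                method=method,
                accuracy=accuracy(gebv, tbv_val),
                bias_slope=bias_slope(gebv, tbv_val),
                n_validation=val.size,
            )
        )
        models[method] = model
    if return_models:
        return results, models, vc, pev
    return results


def run_scenario(
    scenario: str,
    methods=DEFAULT_METHODS,
    n_replicates: int = 5,
    seed: int = 0,
    sim_overrides=None,
    em_kwargs=None,
):
    """Simulate replicates, fit methods, evaluate on validation sets.

    Returns ``(per_replicate, summary)`` DataFrames; the summary holds
    mean +/- sd of accuracy and bias per method.  A method failure on one
    replicate is recorded (NaN metrics) and the scenario continues.
    """
    rows = []
    for r in range(n_replicates):
        rep_seed = _sub_seed(seed, scenario, "replicate", r)
        cfg = scenario_config(scenario, seed=rep_seed, **(sim_overrides or {}))
        rep = simulate_replicate(cfg)
        for method in methods:
            try:
                res = fit_replicate_methods(rep, [method], seed=rep_seed, em_kwargs=em_kwargs)
                rows.append(
                    dict(
                        scenario=scenario,
                        replicate=r,
                        method=method,
                        accuracy=res[0].accuracy,
                        bias_slope=res[0].bias_slope,
                        n_validation=res[0].n_validation,
                    )
                )
            except Exception as exc:  # record and continue
                rows.append(
                    dict(
                        scenario=scenario,
                        replicate=r,
                        method=method,
                        accuracy=np.nan,
                        bias_slope=np.nan,
                        n_validation=0,
                        error=str(exc),
                    )
                )
    per_rep = pd.DataFrame(rows)
    summary = (
        per_rep.groupby("method", sort=False)[["accuracy", "bias_slope"]]
        .agg(["mean", "std"])
        .reset_index()
    )
    summary.columns = ["_".join(c).rstrip("_") for c in summary.columns]
    return per_rep, summary


def prior_sensitivity(
    alphas,
    scenario: str = "HD_Mix_45",
    seed: int = 0,
    sim_overrides=None,
    em_kwargs=None,
):
    """Refit the EM model per Dirichlet pseudo-count vector on one replicate."""
    em_kwargs = dict(em_kwargs or {})
    rep_seed = _sub_seed(seed, scenario, "replicate", 0)
    cfg = scenario_config(scenario, seed=rep_seed, **(sim_overrides or {}))
    rep = simulate_replicate(cfg)

    ref, val = rep.reference_idx, rep.validation_idx
    g_ref = rep.genotypes.subset_samples(ref)
    sg_ref = standardize(g_ref)
    grm = build_grm(sg_ref)
    y_ref = rep.phenotypes[ref]
    vc = reml_fit(grm, y_ref)
    pev = compute_pev(grm, vc, sg_ref)

    rows = []
    for alpha in alphas:
        model = EMBayesR(alpha=tuple(alpha), **em_kwargs)
        model.fit(
            rep.genotypes.dosages[ref],
            y_ref,
            variance_components=vc,
            pev=pev if model.use_pev else None,
        )
        gebv = model.gebv(rep.genotypes.dosages[val])
        pr = model.mixing_proportions_
        rows.append(
            dict(
                alpha=str(tuple(alpha)),
                accuracy=accuracy(gebv, rep.tbv[val]),
                pr1=pr[0],
                pr2=pr[1],
                pr3=pr[2],
                pr4=pr[3],
                n_iter=model.n_iter_,
            )
        )
    return pd.DataFrame(rows)
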