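"""MCMC BayesR: the Gibbs-sampling reference for the same mixture model.

Exactly the model fitted by the EM algorithm — four-component normal
mixture on standardized marker effects (one component a point mass at
zero), Dirichlet prior on the mixing proportions, fixed variance ladder
``sigma_k2 = coeffs * sigma_g2`` — but with every unknown sampled from its
full conditional instead of maximized.  Uncertainty in the other markers'
effects is handled by the sampling itself, so no prediction-error
correction enters; the error variance uses a flat prior (scaled
inverse-chi-square conditional).

Posterior means of the thinned post-burn-in draws summarize effects,
component memberships, mixing proportions, the error variance and the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from ._base import GenomicPredictionMixin
from .em import INIT_PR, MixturePrior, PRIOR_PROFILES
from .gblup import VarianceComponents, build_grm, reml_fit
from .genotypes import StandardizedGenotypes

__all__ = ["GibbsConfig", "PosteriorSummary", "run_gibbs", "gibbs_gebv", "BayesRGibbs"]


@dataclass
class GibbsConfig:
    """Chain length controls (desk-scale defaults)."""

    n_iter: int = 10_000
    burn_in: int = 2_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorSummary:
    """Posterior means over the kept draws."""

    g_mean: np.ndarray
    P_mean: np.ndarray
    Pr_mean: np.ndarray
    sigma_e2_mean: float
    mu_mean: float
    samples_kept: int


def run_gibbs(
    y, Z, prior: MixturePrior, cfg: GibbsConfig, vc: VarianceComponents
) -> PosteriorSummary:
    """Run the sampler; fixed seed gives a bit-identical summary.

    ``vc`` supplies ``sigma_g2`` for the fixed variance ladder and the
    starting error variance.
    """
    Zm = Z.Z if isinstance(Z, StandardizedGenotypes) else np.asarray(Z, float)
    Zm = np.asfortranarray(Zm, dtype=np.float64)
    y = np.asarray(y, dtype=float).ravel()
    n, m = Zm.shape
    zz = np.einsum("ij,ij->j", Zm, Zm)

    g0 = np.zeros(m)
    mu0 = float(np.mean(y))
    resid = y - mu0
    out = _kernels.gibbs_chain(
        Zm,
        resid,
        g0,
        zz,
        prior.sigma_k2(vc.sigma_g2),
        np.asarray(prior.alpha, dtype=float),
        np.asarray(INIT_PR, dtype=float),
        float(vc.sigma_e2),
        mu0,
        int(cfg.n_iter),
        int(cfg.burn_in),
        int(cfg.thin),
        int(cfg.seed),
    )
    g_sum, P_cnt, pr_sum, se_sum, mu_sum, kept, bad_iter = out
    if bad_iter >= 0:
        raise FloatingPointError(
            f"non-finite sample in Gibbs chain at iteration {bad_iter}"
        )
    if kept == 0:
        raise RuntimeError("no post-burn-in samples kept; lengthen the chain")
    return PosteriorSummary(
        g_mean=g_sum / kept,
        P_mean=P_cnt / kept,
        Pr_mean=pr_sum / kept,
        sigma_e2_mean=se_sum / kept,
        mu_mean=mu_sum / kept,
        samples_kept=int(kept),
    )


def gibbs_gebv(Z_target, summary: PosteriorSummary) -> np.ndarray:
    Zm = (
        Z_target.Z
        if isinstance(Z_target, StandardizedGenotypes)
        else np.asarray(Z_target, float)
    )
    return Zm @ summary.g_mean


class BayesRGibbs(GenomicPredictionMixin):
    """Gibbs-sampled BayesR with posterior-mean effects.

    Shares the prior parametrization of :class:`~embayesr.em.EMBayesR`;
    ``sigma_g2`` (for the variance ladder) comes from REML unless supplied.

    Attributes
    ----------
    coef_: posterior-mean marker effects on the standardized scale.
    posterior_probs_: m x 4 posterior component-membership frequencies.
    mixing_proportions_: posterior mean of ``Pr``.
    sigma_e2_, mu_: posterior means.
    """

    def __init__(
        self,
        prior_profile: str = "simulated",
        coeffs=None,
        alpha=(1.0, 1.0, 1.0, 1.0),
        n_iter: int = 10_000,
        burn_in: int = 2_000,
        thin: int = 10,
        random_state: int = 0,
        sigma_g2=None,
        sigma_e2=None,
    ):
        self.prior_profile = prior_profile
        self.coeffs = coeffs
        self.alpha = alpha
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.random_state = random_state
        self.sigma_g2 = sigma_g2
        self.sigma_e2 = sigma_e2

    def fit(self, X, y, variance_components=None):
        sg, y = self._standardize_train(X, y)
        coeffs = (
            tuple(self.coeffs)
            if self.coeffs is not None
            else PRIOR_PROFILES[self.prior_profile]
        )
        prior = MixturePrior(coeffs=coeffs, alpha=tuple(self.alpha))
        vc = variance_components
        if vc is None:
            if self.sigma_g2 is not None and self.sigma_e2 is not None:
                vc = VarianceComponents(float(self.sigma_g2), float(self.sigma_e2))
            else:
                vc = reml_fit(build_grm(sg), y)
        cfg = GibbsConfig(
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.random_state,
        )
        summary = run_gibbs(y, sg, prior, cfg, vc)
        coef = np.zeros(self.n_features_in_)
        coef[self.kept_markers_] = summary.g_mean
        self.coef_ = coef
        self.posterior_probs_ = summary.P_mean
        self.mixing_proportions_ = summary.Pr_mean
        self.sigma_e2_ = summary.sigma_e2_mean
        self.mu_ = summary.mu_mean
        self.variance_components_ = vc
        self.posterior_summary_ = summary
        return self
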