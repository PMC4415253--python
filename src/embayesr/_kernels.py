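"""Compiled inner loops for the EM and Gibbs samplers.

Both algorithms sweep the markers in fixed ascending order, Gauss-Seidel
style: the statistic ``r_i = Z_i' y_dagger`` is obtained from a running
residual (``r_i = Z_i' resid + Z_i'Z_i g_i``) and the residual is updated
in place whenever an effect changes, so one sweep costs O(n m).

The design matrix must be Fortran-ordered float64 so column slices are
contiguous.
"""

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def em_sweep(Z, resid, g, zz, w, log_pr, sigma_k2, sigma_e2, mean_update):
    """One EM sweep over all markers; updates ``g`` and ``resid`` in place.

    ``w`` holds the per-marker PEV quadratic forms (zeros when the PEV
    correction is off).  ``mean_update`` selects the posterior-mean effect
    update instead of the posterior-mode one.  Returns the m x 4 matrix of
    component posterior probabilities from this sweep.
    """
    n, m = Z.shape
    P = np.empty((m, 4))
    ll = np.empty(4)
    for i in range(m):
        zi = Z[:, i]
        r = 0.0
        for t in range(n):
            r += zi[t] * resid[t]
        r += zz[i] * g[i]

        for k in range(4):
            v = zz[i] * zz[i] * sigma_k2[k] + zz[i] * sigma_e2 + w[i]
            ll[k] = log_pr[k] - 0.5 * (np.log(v) + r * r / v)
        mx = ll[0]
        for k in range(1, 4):
            if ll[k] > mx:
                mx = ll[k]
        s = 0.0
        for k in range(4):
            ll[k] = np.exp(ll[k] - mx)
            s += ll[k]
        for k in range(4):
            P[i, k] = ll[k] / s

        if mean_update:
            g_new = 0.0
            for k in range(1, 4):
                g_new += P[i, k] * r / (zz[i] + sigma_e2 / sigma_k2[k])
        else:
            # spike-aware posterior mode: slab mode damped by slab mass
            denom = zz[i]
            slab = 0.0
            for k in range(1, 4):
                denom += P[i, k] * sigma_e2 / sigma_k2[k]
                slab += P[i, k]
            g_new = slab * r / denom

        delta = g_new - g[i]
        if delta != 0.0:
            for t in range(n):
                resid[t] -= zi[t] * delta
        g[i] = g_new
    return P


@njit(cache=True)
def _dirichlet(shape_params):
    out = np.empty(shape_params.size)
    s = 0.0
    for k in range(shape_params.size):
        out[k] = np.random.standard_gamma(shape_params[k])
        s += out[k]
    for k in range(shape_params.size):
        out[k] /= s
    return out


@njit(cache=True, fastmath=True)
def gibbs_chain(
    Z, resid, g, zz, sigma_k2, alpha, pr0, sigma_e2_0, mu_0,
    n_iter, burn_in, thin, seed,
):
    """BayesR Gibbs sampler; returns post-burn-in thinned posterior means.

    Component indicators, effects, mixing proportions, the error variance
    (flat prior, scaled inverse chi-square conditional) and the mean are
    sampled in turn each iteration.  ``resid`` must equal
    ``y - Z g - mu_0`` on entry and is updated in place.

    Returns ``(g_mean, P_mean, pr_mean, sigma_e2_mean, mu_mean,
    samples_kept, bad_iter)``; ``bad_iter >= 0`` flags the first iteration
    at which a non-finite sample appeared.
    """
    np.random.seed(seed)
    n, m = Z.shape
    pr = pr0.copy()
    log_pr = np.log(pr)
    sigma_e2 = sigma_e2_0
    mu = mu_0

    g_sum = np.zeros(m)
    P_cnt = np.zeros((m, 4))
    pr_sum = np.zeros(4)
    se_sum = 0.0
    mu_sum = 0.0
    kept = 0

    lw = np.empty(4)
    counts = np.empty(4)
    for it in range(n_iter):
        counts[:] = 0.0
        keep = it >= burn_in and (it - burn_in) % thin == 0
        for i in range(m):
            zi = Z[:, i]
            r = 0.0
            for t in range(n):
                r += zi[t] * resid[t]
            r += zz[i] * g[i]

            for k in range(4):
                v = zz[i] * zz[i] * sigma_k2[k] + zz[i] * sigma_e2
                lw[k] = log_pr[k] - 0.5 * (np.log(v) + r * r / v)
            mx = lw[0]
            for k in range(1, 4):
                if lw[k] > mx:
                    mx = lw[k]
            s = 0.0
            for k in range(4):
                lw[k] = np.exp(lw[k] - mx)
                s += lw[k]
            u = np.random.random() * s
            acc = 0.0
            comp = 3
            for k in range(4):
                acc += lw[k]
                if u < acc:
                    comp = k
                    break

            if comp == 0:
                g_new = 0.0
            else:
                c = zz[i] + sigma_e2 / sigma_k2[comp]
                g_new = r / c + np.random.normal() * np.sqrt(sigma_e2 / c)
            if not np.isfinite(g_new):
                return g_sum, P_cnt, pr_sum, se_sum, mu_sum, kept, it
            delta = g_new - g[i]
            if delta != 0.0:
                for t in range(n):
                    resid[t] -= zi[t] * delta
            g[i] = g_new
            counts[comp] += 1.0
            if keep:
                P_cnt[i, comp] += 1.0

        pr = _dirichlet(alpha + counts)
        for k in range(4):
            log_pr[k] = np.log(pr[k])

        ssr = 0.0
        rsum = 0.0
        for t in range(n):
            ssr += resid[t] * resid[t]
            rsum += resid[t]
        sigma_e2 = ssr / (2.0 * np.random.standard_gamma(0.5 * (n - 2)))

        mu_new = mu + rsum / n + np.random.normal() * np.sqrt(sigma_e2 / n)
        dmu = mu_new - mu
        for t in range(n):
            resid[t] -= dmu
        mu = mu_new
        if not (np.isfinite(sigma_e2) and np.isfinite(mu)):
            return g_sum, P_cnt, pr_sum, se_sum, mu_sum, kept, it

        if keep:
            kept += 1
            for i in range(m):
                g_sum[i] += g[i]
            for k in range(4):
                pr_sum[k] += pr[k]
            se_sum += sigma_e2
            mu_sum += mu

    return g_sum, P_cnt, pr_sum, se_sum, mu_sum, kept, -1
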