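"""Numba-compiled inner loops for the choice likelihood.

The sampler evaluates the joint likelihood thousands of times per fit on
small (subjects x trials) arrays, where interpreter overhead dominates; these
kernels compute the same quantities as the vectorised numpy path in
``value_models.LikelihoodEngine`` (which remains the reference
implementation, cross-checked in the test suite).  If numba is unavailable
the engine silently falls back to numpy.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        return wrap


DISC_CODE = {"linear": 0, "parabolic": 1, "hyperbolic": 2}
INFO_CODE = {"none": 0, "shannon": 1, "renyi": 2, "card_count": 3}


@njit(cache=True, fastmath=True)
def _log_sigmoid(x: float) -> float:
    if x >= 0.0:
        return -np.log1p(np.exp(-x))
    return x - np.log1p(np.exp(x))


@njit(cache=True, fastmath=True)
def _discounted(code: int, reward: float, k_e: float, effort: float) -> float:
    if code == 0:
        return reward - k_e * effort
    if code == 1:
        return reward - k_e * effort * effort
    return reward / (1.0 + k_e * effort)


@njit(cache=True, fastmath=True)
def _content(code: int, pr: float, alpha: float, hfrac: float, h_sh: float) -> float:
    if code == 1:
        return h_sh
    if code == 2:
        if pr <= 0.0 or pr >= 1.0:
            return 0.0
        if abs(alpha - 1.0) < 1e-6:
            return h_sh
        return np.log(pr**alpha + (1.0 - pr) ** alpha) / (1.0 - alpha)
    return hfrac


@njit(cache=True, fastmath=True)
def loglik_kernel(
    k_e,
    beta,
    alpha,
    k_i,
    k_w,
    disc,
    info,
    r_o,
    e_o,
    r_b,
    e_b,
    pr,
    hfrac,
    e_i,
    e_n,
    h_sh,
    sign_e,
    sign_i,
    pointwise,
    out_subject,
    out_point,
):
    """Joint log-likelihood; fills per-subject sums and (optionally) pointwise.

    ``k_w`` carries the tied coefficient too (callers pass k_i there for the
    constrained model); ``info`` < 0 means no information terms at all.
    Record order for ``out_point``: all effort records subject-major, then
    all information records subject-major.
    """

    S = k_e.shape[0]
    Te = r_o.shape[0]
    Ti = pr.shape[0]
    for s in range(S):
        acc = 0.0
        for t in range(Te):
            dv = _discounted(disc, r_o[t], k_e[s], e_o[t]) - _discounted(
                disc, r_b[t], k_e[s], e_b[t]
            )
            lp = _log_sigmoid(sign_e[s, t] * beta[s] * dv)
            acc += lp
            if pointwise:
                out_point[s * Te + t] = lp
        for t in range(Ti):
            dv = _discounted(disc, 5.0, k_e[s], e_i[t]) - _discounted(
                disc, 5.0, k_e[s], e_n[t]
            )
            if info > 0:
                c = _content(info, pr[t], alpha[s], hfrac[t], h_sh[t])
                dv += k_i[s] * c + k_w[s] * (pr[t] - 0.5)
            lp = _log_sigmoid(sign_i[s, t] * beta[s] * dv)
            acc += lp
            if pointwise:
                out_point[S * Te + s * Ti + t] = lp
        out_subject[s] = acc


_SQRT2 = math.sqrt(2.0)


@njit(cache=True, fastmath=True)
def _phi(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / _SQRT2))


@njit(cache=True, fastmath=True)
def _subject_ll(
    th, idx, disc, info,
    r_o, e_o, r_b, e_b, pr, hfrac, e_i, e_n, h_sh,
    sign_e_s, sign_i_s,
):
    """Log-likelihood of one subject given their raw parameter row ``th``.

    ``idx`` holds the raw-column index of (k_e, beta, alpha, k_i, k_w); -1
    marks a parameter absent from the model; the tied model passes the same
    column for k_i and k_w.
    """

    k_e = 100.0 * _phi(th[idx[0]])
    beta = 20.0 * _phi(th[idx[1]])
    alpha = 50.0 * _phi(th[idx[2]]) if idx[2] >= 0 else 1.0
    k_i = th[idx[3]] if idx[3] >= 0 else 0.0
    k_w = th[idx[4]] if idx[4] >= 0 else 0.0
    acc = 0.0
    for t in range(r_o.shape[0]):
        dv = _discounted(disc, r_o[t], k_e, e_o[t]) - _discounted(
            disc, r_b[t], k_e, e_b[t]
        )
        acc += _log_sigmoid(sign_e_s[t] * beta * dv)
    for t in range(pr.shape[0]):
        dv = _discounted(disc, 5.0, k_e, e_i[t]) - _discounted(disc, 5.0, k_e, e_n[t])
        if info > 0:
            c = _content(info, pr[t], alpha, hfrac[t], h_sh[t])
            dv += k_i * c + k_w * (pr[t] - 0.5)
        acc += _log_sigmoid(sign_i_s[t] * beta * dv)
    return acc


@njit(cache=True, fastmath=True)
def _pointwise_raw(
    theta, idx, disc, info,
    r_o, e_o, r_b, e_b, pr, hfrac, e_i, e_n, h_sh,
    sign_e, sign_i, out_point,
):
    """Canonical-order pointwise log-likelihood from raw subject parameters."""
    S = theta.shape[0]
    Te = r_o.shape[0]
    Ti = pr.shape[0]
    for s in range(S):
        k_e = 100.0 * _phi(theta[s, idx[0]])
        beta = 20.0 * _phi(theta[s, idx[1]])
        alpha = 50.0 * _phi(theta[s, idx[2]]) if idx[2] >= 0 else 1.0
        k_i = theta[s, idx[3]] if idx[3] >= 0 else 0.0
        k_w = theta[s, idx[4]] if idx[4] >= 0 else 0.0
        for t in range(Te):
            dv = _discounted(disc, r_o[t], k_e, e_o[t]) - _discounted(
                disc, r_b[t], k_e, e_b[t]
            )
            out_point[s * Te + t] = _log_sigmoid(sign_e[s, t] * beta * dv)
        for t in range(Ti):
            dv = _discounted(disc, 5.0, k_e, e_i[t]) - _discounted(
                disc, 5.0, k_e, e_n[t]
            )
            if info > 0:
                c = _content(info, pr[t], alpha, hfrac[t], h_sh[t])
                dv += k_i * c + k_w * (pr[t] - 0.5)
            out_point[S * Te + s * Ti + t] = _log_sigmoid(sign_i[s, t] * beta * dv)


@njit(cache=True)
def chain_kernel(
    seed, warmup, draws, substeps, m0, s0, scale_sd,
    idx, disc, info,
    r_o, e_o, r_b, e_b, pr, hfrac, e_i, e_n, h_sh,
    sign_e, sign_i,
    raw_out, loc_out, scale_out, ll_out, acc_out,
):
    """One MCMC chain of the hierarchical model (adaptive Metropolis-within-Gibbs).

    Moves per iteration: (1) ``substeps`` random-walk Metropolis sweeps over
    subject blocks with warmup-adapted proposal covariances; (2) an
    independence refresh of one rotating coordinate from the group prior,
    giving global jumps along weakly identified directions; (3) conjugate
    Gibbs for the group locations; (4) adaptive log-scale Metropolis for the
    group scales; (5) an interweaved non-centred joint update of each
    (mu_j, sigma_j) that rescales the whole subject column, stepping across
    the funnel that traps purely centred kernels when a group scale is small.
    """

    np.random.seed(seed)
    S, d = sign_e.shape[0], raw_out.shape[2]

    # greedy accept-if-better search: land each subject near its mode
    theta = 0.5 * np.random.standard_normal((S, d))
    best = np.empty(S)
    for s in range(S):
        best[s] = _subject_ll(
            theta[s], idx, disc, info, r_o, e_o, r_b, e_b, pr, hfrac, e_i, e_n,
            h_sh, sign_e[s], sign_i[s],
        ) - 0.5 * (theta[s] ** 2).sum()
    n_init = 150
    for i in range(n_init):
        step = 0.5 * 0.1 ** (i / (n_init - 1))
        for s in range(S):
            prop = theta[s] + step * np.random.standard_normal(d)
            val = _subject_ll(
                prop, idx, disc, info, r_o, e_o, r_b, e_b, pr, hfrac, e_i, e_n,
                h_sh, sign_e[s], sign_i[s],
            ) - 0.5 * (prop**2).sum()
            if val > best[s]:
                theta[s] = prop
                best[s] = val

    mu = np.empty(d)
    sigma = np.empty(d)
    for j in range(d):
        mu[j] = theta[:, j].mean()
        sigma[j] = min(max(theta[:, j].std(), 0.1), 2.0)

    log_step = np.full(S, np.log(0.2))
    chol = np.zeros((S, d, d))
    for s in range(S):
        for j in range(d):
            chol[s, j, j] = 1.0
    log_step_sigma = np.full(d, np.log(0.3))
    log_step_iw = np.full(d, np.log(0.2))
    cur_ll = np.empty(S)
    for s in range(S):
        cur_ll[s] = _subject_ll(
            theta[s], idx, disc, info, r_o, e_o, r_b, e_b, pr, hfrac, e_i, e_n,
            h_sh, sign_e[s], sign_i[s],
        )
    n_accept = np.zeros(S)
    history = np.empty((warmup, S, d))
    target = 0.3

    for it in range(warmup + draws):
        warming = it < warmup
        gamma = 0.1 if warming else 0.0

        for _ in range(substeps):
            for s in range(S):
                z = np.random.standard_normal(d)
                prop = theta[s] + np.exp(log_step[s]) * (chol[s] @ z)
                prop_ll = _subject_ll(
                    prop, idx, disc, info, r_o, e_o, r_b, e_b, pr, hfrac, e_i,
                    e_n, h_sh, sign_e[s], sign_i[s],
                )
                lp_cur = 0.0
                lp_prop = 0.0
                for j in range(d):
                    lp_cur -= 0.5 * ((theta[s, j] - mu[j]) / sigma[j]) ** 2
                    lp_prop -= 0.5 * ((prop[j] - mu[j]) / sigma[j]) ** 2
                ok = np.log(np.random.random()) < (prop_ll + lp_prop) - (
                    cur_ll[s] + lp_cur
                )
                if ok:
                    theta[s] = prop
                    cur_ll[s] = prop_ll
                if warming:
                    log_step[s] += gamma * ((1.0 if ok else 0.0) - target)
                else:
                    n_accept[s] += (1.0 if ok else 0.0) / substeps

        # independence refresh of one rotating coordinate
        j_ref = it % d
        for s in range(S):
            prop = theta[s].copy()
            prop[j_ref] = mu[j_ref] + sigma[j_ref] * np.random.standard_normal()
            prop_ll = _subject_ll(
                prop, idx, disc, info, r_o, e_o, r_b, e_b, pr, hfrac, e_i, e_n,
                h_sh, sign_e[s], sign_i[s],
            )
            if np.log(np.random.random()) < prop_ll - cur_ll[s]:
                theta[s] = prop
                cur_ll[s] = prop_ll

        if warming:
            history[it] = theta
            if it >= 150 and it % 100 == 0:
                lo = max(0, it - 500)
                window = history[lo:it]
                n_w = window.shape[0]
                for s in range(S):
                    cov = np.empty((d, d))
                    means = np.empty(d)
                    for j in range(d):
                        means[j] = window[:, s, j].mean()
                    for j in range(d):
                        for k2 in range(j + 1):
                            c = 0.0
                            for t in range(n_w):
                                c += (window[t, s, j] - means[j]) * (
                                    window[t, s, k2] - means[k2]
                                )
                            c /= n_w - 1
                            cov[j, k2] = c
                            cov[k2, j] = c
                    for j in range(d):
                        cov[j, j] += 1e-6
                    chol[s] = np.linalg.cholesky(cov)

        # group locations: conjugate normal Gibbs
        for j in range(d):
            prec = 1.0 / s0**2 + S / sigma[j] ** 2
            mean = (m0 / s0**2 + theta[:, j].sum() / sigma[j] ** 2) / prec
            mu[j] = np.random.normal(mean, 1.0 / np.sqrt(prec))

        # group scales: adaptive log-scale Metropolis
        for j in range(d):
            sp = sigma[j] * np.exp(
                np.exp(log_step_sigma[j]) * np.random.standard_normal()
            )
            dev2 = ((theta[:, j] - mu[j]) ** 2).sum()
            ll_c = -S * np.log(sigma[j]) - 0.5 * dev2 / sigma[j] ** 2
            ll_p = -S * np.log(sp) - 0.5 * dev2 / sp**2
            la = (ll_p - 0.5 * (sp / scale_sd) ** 2 + np.log(sp)) - (
                ll_c - 0.5 * (sigma[j] / scale_sd) ** 2 + np.log(sigma[j])
            )
            ok = np.log(np.random.random()) < la
            if ok:
                sigma[j] = sp
            if warming:
                log_step_sigma[j] += gamma * ((1.0 if ok else 0.0) - 0.44)

        # interweaved non-centred (mu_j, sigma_j) update
        for j in range(d):
            step = np.exp(log_step_iw[j])
            mu_p = mu[j] + step * np.random.standard_normal()
            sigma_p = sigma[j] * np.exp(step * np.random.standard_normal())
            theta_prop = theta.copy()
            for s in range(S):
                zj = (theta[s, j] - mu[j]) / sigma[j]
                theta_prop[s, j] = mu_p + sigma_p * zj
            prop_lls = np.empty(S)
            prop_sum = 0.0
            for s in range(S):
                prop_lls[s] = _subject_ll(
                    theta_prop[s], idx, disc, info, r_o, e_o, r_b, e_b, pr,
                    hfrac, e_i, e_n, h_sh, sign_e[s], sign_i[s],
                )
                prop_sum += prop_lls[s]
            la = (
                prop_sum
                - cur_ll.sum()
                - 0.5 * ((mu_p - m0) / s0) ** 2
                + 0.5 * ((mu[j] - m0) / s0) ** 2
                - 0.5 * (sigma_p / scale_sd) ** 2
                + 0.5 * (sigma[j] / scale_sd) ** 2
                + np.log(sigma_p)
                - np.log(sigma[j])
            )
            ok = np.log(np.random.random()) < la
            if ok:
                mu[j] = mu_p
                sigma[j] = sigma_p
                theta = theta_prop
                cur_ll = prop_lls
            if warming:
                log_step_iw[j] += gamma * ((1.0 if ok else 0.0) - target)

        if not warming:
            k = it - warmup
            raw_out[k] = theta
            loc_out[k] = mu
            scale_out[k] = sigma
            _pointwise_raw(
                theta, idx, disc, info, r_o, e_o, r_b, e_b, pr, hfrac, e_i,
                e_n, h_sh, sign_e, sign_i, ll_out[k],
            )

    for s in range(S):
        acc_out[s] = n_accept[s] / draws
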