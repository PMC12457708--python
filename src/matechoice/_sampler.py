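"""Numba MCMC core for the joint 4-context Bernoulli-logit model.

Linear predictor per binary row (context k = 0..3 in the order
V+C+, V-C+, V+C-, V-C-):

    noncompetitive (k = 2, 3):  logit p = mu_k + a[m, k] + b[f, k-2]
    competitive    (k = 0, 1):  logit p = mu_k + gamma_color + a[m, k]

with male-strain effect rows a[s, :] ~ MVN(0, diag(sig) R diag(sig))
shared across contexts, female effects b[f, j] ~ N(0, sigb_j^2)
independent per noncompetitive context, half-Student-t(3, 0, 2.5) priors
on all SDs, Student-t(3, 0, 2.5) on intercepts, flat priors on color
contrasts and an LKJ(1) (uniform over correlation matrices) prior on R.

Sampling is adaptive Metropolis-within-Gibbs on a non-centered
parameterization (a = diag(sig) chol(R) z with z ~ N(0, I)), which keeps
mixing healthy when the data pull sig toward zero.  Step sizes adapt by
Robbins-Monro during warmup only.  Everything is compiled with numba so a
full-design fit (a few thousand rows) takes seconds.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# storage layout offsets (before the a/b blocks, which depend on S)
N_FIXED = 20  # sig(4) + r(6) + mu(4) + gamma(4) + sigb(2)

# off-diagonal order of the correlation entries
R_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@njit(cache=True)
def _log1pexp(x):
    if x > 35.0:
        return x
    if x < -35.0:
        return np.exp(x)
    return np.log1p(np.exp(x))


@njit(cache=True)
def _chol4(R, L):
    """Lower Cholesky of a 4x4 matrix; returns False if not PD."""
    for i in range(4):
        for j in range(i + 1):
            s = R[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 1e-12:
                    return False
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
        for j in range(i + 1, 4):
            L[i, j] = 0.0
    return True


@njit(cache=True)
def _half_t_lp(s, scale, df):
    return -0.5 * (df + 1.0) * np.log1p((s / scale) ** 2 / df)


@njit(cache=True)
def _ll_subset(rows, y, ctx, midx, fidx, cidx, mu, a, bmat, gamma):
    total = 0.0
    for i in range(rows.shape[0]):
        r = rows[i]
        k = ctx[r]
        eta = mu[k] + a[midx[r], k]
        c = cidx[r]
        if c >= 0:
            eta += gamma[c]
        f = fidx[r]
        if f >= 0:
            eta += bmat[f, k - 2]
        total += y[r] * eta - _log1pexp(eta)
    return total


@njit(cache=True)
def _update_a_col(z, L0, sig, a, k):
    S = z.shape[0]
    for s in range(S):
        acc = 0.0
        for j in range(k + 1):
            acc += L0[k, j] * z[s, j]
        a[s, k] = sig[k] * acc


@njit(cache=True)
def _update_a_row(z_s, L0, sig, out):
    for k in range(4):
        acc = 0.0
        for j in range(k + 1):
            acc += L0[k, j] * z_s[j]
        out[k] = sig[k] * acc


@njit(cache=True)
def run_chain(
    y, ctx, midx, fidx, cidx, S,
    strain_off, strain_rows,
    fk_off, fk_rows,
    ctx_off, ctx_rows,
    col_off, col_rows,
    n_iter, n_warmup, thin, seed,
    sd_scale, sd_df, int_scale, int_df,
):
    """One MCMC chain; returns (n_keep, N_FIXED + 6*S) draw matrix."""
    np.random.seed(seed)
    n = y.shape[0]

    # ---- initial state (mildly overdispersed around the data) ----
    mu = np.zeros(4)
    for k in range(4):
        nk = ctx_off[k + 1] - ctx_off[k]
        if nk > 0:
            sy = 0.0
            for i in range(ctx_off[k], ctx_off[k + 1]):
                sy += y[ctx_rows[i]]
            p = (sy + 1.0) / (nk + 2.0)
            mu[k] = np.log(p / (1.0 - p)) + 0.2 * np.random.standard_normal()
    z = 0.5 * np.random.standard_normal((S, 4))
    zb = 0.5 * np.random.standard_normal((S, 2))
    logsig = np.log(0.3) + 0.5 * np.random.standard_normal(4)
    logsigb = np.log(0.3) + 0.5 * np.random.standard_normal(2)
    rvec = np.zeros(6)
    gamma = np.zeros(4)

    sig = np.exp(logsig)
    sigb = np.exp(logsigb)
    R = np.eye(4)
    L0 = np.eye(4)
    a = np.zeros((S, 4))
    for k in range(4):
        _update_a_col(z, L0, sig, a, k)
    bmat = np.empty((S, 2))
    for s in range(S):
        for j in range(2):
            bmat[s, j] = sigb[j] * zb[s, j]

    # ---- adaptive step sizes ----
    st_z = np.full(S, 0.4)
    st_zb = np.full((S, 2), 0.8)
    st_mu = np.full(4, 0.3)
    st_gamma = np.full(4, 0.3)
    st_sig = np.full(4, 0.5)
    st_sigb = np.full(2, 0.5)
    st_r = np.full(6, 0.15)
    t_vec = 0.25
    t_sca = 0.44

    has_col = np.zeros(4, dtype=np.bool_)
    for c in range(4):
        has_col[c] = (col_off[c + 1] - col_off[c]) > 0

    n_keep = (n_iter - n_warmup) // thin
    npar = N_FIXED + 6 * S
    draws = np.empty((n_keep, npar))
    keep = 0

    z_prop = np.empty(4)
    a_row = np.empty(4)
    Rp = np.empty((4, 4))
    L0p = np.empty((4, 4))

    for it in range(n_iter):
        adapting = it < n_warmup
        gain = 1.0 / (1.0 + it) ** 0.6

        # ---- strain blocks z[s] (4-d random walk) ----
        for s in range(S):
            rows = strain_rows[strain_off[s]:strain_off[s + 1]]
            lp0 = 0.0
            lp1 = 0.0
            for j in range(4):
                z_prop[j] = z[s, j] + st_z[s] * np.random.standard_normal()
                lp0 -= 0.5 * z[s, j] ** 2
                lp1 -= 0.5 * z_prop[j] ** 2
            _update_a_row(z_prop, L0, sig, a_row)
            ll0 = _ll_subset(rows, y, ctx, midx, fidx, cidx, mu, a, bmat, gamma)
            old = a[s].copy()
            a[s] = a_row
            ll1 = _ll_subset(rows, y, ctx, midx, fidx, cidx, mu, a, bmat, gamma)
            lr = lp1 + ll1 - lp0 - ll0
            if np.log(np.random.rand()) < lr:
                for j in range(4):
                    z[s, j] = z_prop[j]
                alpha = min(1.0, np.exp(lr))
            else:
                a[s] = old
                alpha = min(1.0, np.exp(lr)) if lr < 0 else 1.0
            if adapting:
                st_z[s] = np.exp(np.log(st_z[s]) + gain * (alpha - t_vec))

        # ---- female blocks zb[f, j] ----
        for f in range(S):
            for j in range(2):
                rows = fk_rows[fk_off[f * 2 + j]:fk_off[f * 2 + j + 1]]
                if rows.shape[0] == 0:
                    continue
                prop = zb[f, j] + st_zb[f, j] * np.random.standard_normal()
                lp = -0.5 * (prop ** 2 - zb[f, j] ** 2)
                old = bmat[f, j]
                ll0 = _ll_subset(rows, y, ctx, midx, fidx, cidx, mu, a, bmat, gamma)
                bmat[f, j] = sigb[j] * prop
                ll1 = _ll_subset(rows, y, ctx, midx, fidx, cidx, mu, a, bmat, gamma)
                lr = lp + ll1 - ll0
                if np.log(np.random.rand()) < lr:
                    zb[f, j] = prop
                else:
                    bmat[f, j] = old
                alpha = min(1.0, np.exp(lr))
                if adapting:
                    st_zb[f, j] = np.exp(
                        np.log(st_zb[f, j]) + gain * (alpha - t_sca)
                    )

        # ---- intercepts mu[k] ----
        for k in range(4):
            rows = ctx_rows[ctx_off[k]:ctx_off[k + 1]]
            if rows.shape[0] == 0:
                continue
            prop = mu[k] + st_mu[k] * np.random.standard_normal()
            lp = _half_t_lp(np.abs(prop), int_scale, int_df) - _half_t_lp(
                np.abs(mu[k]), int_scale, int_df
            )
            old = mu[k]
            ll0 = _ll_subset(rows, y, ctx, midx, fidx, cidx, mu, a, bmat, gamma)
            mu[k] = prop
            ll1 = _ll_subset(rows, y, ctx, midx, fidx, cidx, mu, a, bmat, gamma)
            lr = lp + ll1 - ll0
            if np.log(np.random.rand()) < lr:
                pass
            else:
                mu[k] = old
            alpha = min(1.0, np.exp(lr))
            if adapting:
                st_mu[k] = np.exp(np.log(st_mu[k]) + gain * (alpha - t_sca))

        # ---- color contrasts gamma[c], c >= 1, flat prior ----
        for c in range(1, 4):
            if not has_col[c]:
                continue
            rows = col_rows[col_off[c]:col_off[c + 1]]
            prop = gamma[c] + st_gamma[c] * np.random.standard_normal()
            old = gamma[c]
            ll0 = _ll_subset(rows, y, ctx, midx, fidx, cidx, mu, a, bmat, gamma)
            gamma[c] = prop
            ll1 = _ll_subset(rows, y, ctx, midx, fidx, cidx, mu, a, bmat, gamma)
            lr = ll1 - ll0
            if np.log(np.random.rand()) >= lr:
                gamma[c] = old
            alpha = min(1.0, np.exp(lr))
            if adapting:
                st_gamma[c] = np.exp(np.log(st_gamma[c]) + gain * (alpha - t_sca))

        # ---- strain-effect SDs sig[k] (log random walk) ----
        for k in range(4):
            rows = ctx_rows[ctx_off[k]:ctx_off[k + 1]]
            lprop = logsig[k] + st_sig[k] * np.random.standard_normal()
            sprop = np.exp(lprop)
            # half-t prior + log-scale Jacobian
            lp = (
                _half_t_lp(sprop, sd_scale, sd_df)
                - _half_t_lp(sig[k], sd_scale, sd_df)
                + lprop
                - logsig[k]
            )
            old_col = a[:, k].copy()
            old_sig = sig[k]
            ll0 = _ll_subset(rows, y, ctx, midx, fidx, cidx, mu, a, bmat, gamma)
            sig[k] = sprop
            _update_a_col(z, L0, sig, a, k)
            ll1 = _ll_subset(rows, y, ctx, midx, fidx, cidx, mu, a, bmat, gamma)
            lr = lp + ll1 - ll0
            if np.log(np.random.rand()) < lr:
                logsig[k] = lprop
            else:
                sig[k] = old_sig
                a[:, k] = old_col
            alpha = min(1.0, np.exp(lr))
            if adapting:
                st_sig[k] = np.exp(np.log(st_sig[k]) + gain * (alpha - t_sca))

        # ---- female SDs sigb[j] ----
        for j in range(2):
            rows = ctx_rows[ctx_off[2 + j]:ctx_off[3 + j]]
            if rows.shape[0] == 0:
                continue
            lprop = logsigb[j] + st_sigb[j] * np.random.standard_normal()
            sprop = np.exp(lprop)
            lp = (
                _half_t_lp(sprop, sd_scale, sd_df)
                - _half_t_lp(sigb[j], sd_scale, sd_df)
                + lprop
                - logsigb[j]
            )
            old_col = bmat[:, j].copy()
            old_s = sigb[j]
            ll0 = _ll_subset(rows, y, ctx, midx, fidx, cidx, mu, a, bmat, gamma)
            sigb[j] = sprop
            for s in range(S):
                bmat[s, j] = sigb[j] * zb[s, j]
            ll1 = _ll_subset(rows, y, ctx, midx, fidx, cidx, mu, a, bmat, gamma)
            lr = lp + ll1 - ll0
            if np.log(np.random.rand()) < lr:
                logsigb[j] = lprop
            else:
                sigb[j] = old_s
                bmat[:, j] = old_col
            alpha = min(1.0, np.exp(lr))
            if adapting:
                st_sigb[j] = np.exp(np.log(st_sigb[j]) + gain * (alpha - t_sca))

        # ---- correlations r (uniform-over-PD prior) ----
        for e in range(6):
            i0 = R_PAIRS[e][0]
            j0 = R_PAIRS[e][1]
            prop = rvec[e] + st_r[e] * np.random.standard_normal()
            if prop <= -1.0 or prop >= 1.0:
                alpha = 0.0
                if adapting:
                    st_r[e] = np.exp(np.log(st_r[e]) + gain * (alpha - t_sca))
                continue
            for ii in range(4):
                for jj in range(4):
                    Rp[ii, jj] = R[ii, jj]
            Rp[i0, j0] = prop
            Rp[j0, i0] = prop
            if not _chol4(Rp, L0p):
                alpha = 0.0
                if adapting:
                    st_r[e] = np.exp(np.log(st_r[e]) + gain * (alpha - t_sca))
                continue
            # Cholesky rows >= j0 change => contexts j0..3 affected
            kmin = j0
            ll0 = 0.0
            ll1 = 0.0
            old_cols = a[:, kmin:].copy()
            for k in range(kmin, 4):
                rows = ctx_rows[ctx_off[k]:ctx_off[k + 1]]
                ll0 += _ll_subset(
                    rows, y, ctx, midx, fidx, cidx, mu, a, bmat, gamma
                )
            for k in range(kmin, 4):
                _update_a_col(z, L0p, sig, a, k)
            for k in range(kmin, 4):
                rows = ctx_rows[ctx_off[k]:ctx_off[k + 1]]
                ll1 += _ll_subset(
                    rows, y, ctx, midx, fidx, cidx, mu, a, bmat, gamma
                )
            lr = ll1 - ll0
            if np.log(np.random.rand()) < lr:
                rvec[e] = prop
                R[i0, j0] = prop
                R[j0, i0] = prop
                for ii in range(4):
                    for jj in range(4):
                        L0[ii, jj] = L0p[ii, jj]
            else:
                a[:, kmin:] = old_cols
            alpha = min(1.0, np.exp(lr))
            if adapting:
                st_r[e] = np.exp(np.log(st_r[e]) + gain * (alpha - t_sca))

        # ---- store ----
        if it >= n_warmup and (it - n_warmup) % thin == thin - 1:
            row = draws[keep]
            for k in range(4):
                row[k] = sig[k]
            for e in range(6):
                row[4 + e] = rvec[e]
            for k in range(4):
                row[10 + k] = mu[k]
            for c in range(4):
                row[14 + c] = gamma[c]
            for j in range(2):
                row[18 + j] = sigb[j]
            pos = N_FIXED
            for s in range(S):
                for k in range(4):
                    row[pos] = a[s, k]
                    pos += 1
            for s in range(S):
                for j in range(2):
                    row[pos] = bmat[s, j]
                    pos += 1
            keep += 1

    return draws
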