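"""Numba kernel for the BYM Metropolis-within-Gibbs sampler.

Single-site random-walk Metropolis updates for the intercept, the quintile
coefficients and both random-effect vectors, with conjugate inverse-gamma
Gibbs draws for the two variance components.  Proposal scales adapt
multiplicatively during burn-in towards 40-50% acceptance and are frozen
afterwards.  All randomness flows through numpy's legacy global generator,
seeded once at entry, so a chain is fully reproducible from its seed.
"""

import numpy as np
from numba import njit

ADAPT_WINDOW = 100
ADAPT_LO = 0.4
ADAPT_HI = 0.5
SCALE_MIN = 1e-3
SCALE_MAX = 10.0


@njit(cache=True)
def _adapt(scale, rate):
    if rate < ADAPT_LO:
        scale *= 0.9
    elif rate > ADAPT_HI:
        scale *= 1.1
    if scale < SCALE_MIN:
        scale = SCALE_MIN
    elif scale > SCALE_MAX:
        scale = SCALE_MAX
    return scale


@njit(cache=True)
def run_chain(
    y,            # (n,) observed counts (may be fractional if allowed upstream)
    E,            # (n,) expected counts, all > 0
    qptr, qidx,   # CSR-style covariate groups: areas of quintile j are
                  # qidx[qptr[j]:qptr[j+1]] for j = 0..p-1 (quintiles 2..5)
    indptr, indices,  # CSR adjacency (symmetric, zero diagonal)
    comp, comp_sizes,  # connected-component label per area, component sizes
    prior_var_alpha, prior_var_beta, ig_shape, ig_scale,
    n_iter, n_burnin, thin, seed,
    s2u_init, s2v_init, update_u, update_v, update_variances,
):
    np.random.seed(seed)
    n = y.shape[0]
    p = qptr.shape[0] - 1
    n_comp = comp_sizes.shape[0]
    deg = indptr[1:] - indptr[:-1]

    sumy = y.sum()
    sumy_q = np.zeros(p)
    for j in range(p):
        for k in range(qptr[j], qptr[j + 1]):
            sumy_q[j] += y[qidx[k]]

    alpha = np.log(max(sumy, 0.5) / E.sum())
    beta = np.zeros(p)
    u = np.zeros(n)
    v = np.zeros(n)
    s2u = s2u_init
    s2v = s2v_init
    mu = np.full(n, alpha)

    scale_a = 0.1
    scale_b = np.full(p, 0.1)
    scale_u = np.full(n, 0.1)
    scale_v = np.full(n, 0.1)
    acc_a = 0.0
    acc_b = np.zeros(p)
    acc_u = np.zeros(n)
    acc_v = np.zeros(n)

    n_keep = (n_iter - n_burnin + thin - 1) // thin
    alpha_d = np.empty(n_keep)
    beta_d = np.empty((n_keep, p))
    u_d = np.empty((n_keep, n))
    v_d = np.empty((n_keep, n))
    s2u_d = np.empty(n_keep)
    s2v_d = np.empty(n_keep)

    # pairwise sum of structured-effect information, only over non-singleton
    # components (singletons are centred to zero every iteration)
    n_pairs_info = n - n_comp  # rank of the intrinsic CAR precision

    keep = 0
    for t in range(n_iter):
        if t == n_burnin:  # report acceptance over the sampling phase only
            acc_a = 0.0
            acc_b[:] = 0.0
            acc_u[:] = 0.0
            acc_v[:] = 0.0

        # --- structured effects u (single-site Metropolis, CAR conditional prior)
        for i in range(n if update_u else 0):
            d = deg[i]
            if d > 0:
                s = 0.0
                for k in range(indptr[i], indptr[i + 1]):
                    s += u[indices[k]]
                m = s / d
                prec = d / s2u
            else:
                m = 0.0
                prec = 1.0 / s2u
            prop = u[i] + scale_u[i] * np.random.normal()
            dmu = prop - u[i]
            la = y[i] * dmu - E[i] * (np.exp(mu[i] + dmu) - np.exp(mu[i]))
            la -= 0.5 * prec * ((prop - m) ** 2 - (u[i] - m) ** 2)
            if np.log(np.random.random()) < la:
                u[i] = prop
                mu[i] += dmu
                acc_u[i] += 1.0

        # per-component mean-centring (identifiability of the intrinsic CAR)
        cmean = np.zeros(n_comp)
        for i in range(n):
            cmean[comp[i]] += u[i]
        for c in range(n_comp):
            cmean[c] /= comp_sizes[c]
        for i in range(n):
            u[i] -= cmean[comp[i]]
            mu[i] -= cmean[comp[i]]

        # --- unstructured effects v
        for i in range(n if update_v else 0):
            prop = v[i] + scale_v[i] * np.random.normal()
            dmu = prop - v[i]
            la = y[i] * dmu - E[i] * (np.exp(mu[i] + dmu) - np.exp(mu[i]))
            la -= 0.5 * (prop * prop - v[i] * v[i]) / s2v
            if np.log(np.random.random()) < la:
                v[i] = prop
                mu[i] += dmu
                acc_v[i] += 1.0

        # --- intercept
        S = 0.0
        for i in range(n):
            S += E[i] * np.exp(mu[i])
        da = scale_a * np.random.normal()
        la = sumy * da - (np.exp(da) - 1.0) * S
        la -= 0.5 * ((alpha + da) ** 2 - alpha * alpha) / prior_var_alpha
        if np.log(np.random.random()) < la:
            alpha += da
            for i in range(n):
                mu[i] += da
            acc_a += 1.0

        # --- quintile coefficients (each touches only its member areas)
        for j in range(p):
            Sj = 0.0
            for k in range(qptr[j], qptr[j + 1]):
                i = qidx[k]
                Sj += E[i] * np.exp(mu[i])
            db = scale_b[j] * np.random.normal()
            la = sumy_q[j] * db - (np.exp(db) - 1.0) * Sj
            la -= 0.5 * ((beta[j] + db) ** 2 - beta[j] * beta[j]) / prior_var_beta
            if np.log(np.random.random()) < la:
                beta[j] += db
                for k in range(qptr[j], qptr[j + 1]):
                    mu[qidx[k]] += db
                acc_b[j] += 1.0

        # --- conjugate variance draws
        if update_variances:
            if n_pairs_info > 0:
                pairsum = 0.0
                for i in range(n):
                    for k in range(indptr[i], indptr[i + 1]):
                        jj = indices[k]
                        if jj > i:
                            diff = u[i] - u[jj]
                            pairsum += diff * diff
                g = np.random.gamma(ig_shape + 0.5 * n_pairs_info,
                                    1.0 / (ig_scale + 0.5 * pairsum))
            else:  # no structured information at all: fall back to the prior
                g = np.random.gamma(ig_shape, 1.0 / ig_scale)
            s2u = max(1.0 / g, 1e-12)

            sv = 0.0
            for i in range(n):
                sv += v[i] * v[i]
            g = np.random.gamma(ig_shape + 0.5 * n, 1.0 / (ig_scale + 0.5 * sv))
            s2v = max(1.0 / g, 1e-12)

        # --- burn-in adaptation
        if t < n_burnin and (t + 1) % ADAPT_WINDOW == 0:
            scale_a = _adapt(scale_a, acc_a / ADAPT_WINDOW)
            acc_a = 0.0
            for j in range(p):
                scale_b[j] = _adapt(scale_b[j], acc_b[j] / ADAPT_WINDOW)
                acc_b[j] = 0.0
            for i in range(n):
                scale_u[i] = _adapt(scale_u[i], acc_u[i] / ADAPT_WINDOW)
                acc_u[i] = 0.0
                scale_v[i] = _adapt(scale_v[i], acc_v[i] / ADAPT_WINDOW)
                acc_v[i] = 0.0

        # --- storage
        if t >= n_burnin and (t - n_burnin) % thin == 0:
            alpha_d[keep] = alpha
            for j in range(p):
                beta_d[keep, j] = beta[j]
            for i in range(n):
                u_d[keep, i] = u[i]
                v_d[keep, i] = v[i]
            s2u_d[keep] = s2u
            s2v_d[keep] = s2v
            keep += 1

    n_post = float(n_iter - n_burnin)
    acc_rate_a = acc_a / n_post
    acc_rate_b = acc_b / n_post
    acc_rate_u = acc_u / n_post
    acc_rate_v = acc_v / n_post
    return (alpha_d, beta_d, u_d, v_d, s2u_d, s2v_d,
            acc_rate_a, acc_rate_b, acc_rate_u, acc_rate_v)
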