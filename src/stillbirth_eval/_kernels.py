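"""Numba kernels for the threshold-model Gibbs sampler.

Everything in the per-iteration hot loop lives here: standard-normal
CDF/quantile primitives (math.erfc plus Acklam's rational approximation
with one Halley refinement, giving ~1e-14 accuracy), one-sided
truncated-normal draws by the inverse-CDF method with tail-safe
complementary branches, a Bartlett-decomposition 2x2 inverse-Wishart
draw, and the full Gibbs sweep over liabilities, fixed/herd-year factor
blocks, per-bull (sire, MGS) 2-vectors, and the variance components.
"""

import math

import numpy as np
from numba import njit

SQRT2 = math.sqrt(2.0)


@njit(cache=True)
def ndtr(x):
    return 0.5 * math.erfc(-x / SQRT2)


@njit(cache=True)
def _ndtri_acklam(p):
    # rational approximation; relative error < 1.15e-9 before refinement
    a = (-3.969683028665376e01, 2.209460984245205e02, -2.759285104469687e02,
         1.383577518672690e02, -3.066479806614716e01, 2.506628277459239e00)
    b = (-5.447609879822406e01, 1.615858368580409e02, -1.556989798598866e02,
         6.680131188771972e01, -1.328068155288572e01)
    c = (-7.784894002430293e-03, -3.223964580411365e-01, -2.400758277161838e00,
         -2.549732539343734e00, 4.374664141464968e00, 2.938163982698783e00)
    d = (7.784695709041462e-03, 3.224671290700398e-01, 2.445134137142996e00,
         3.754408661907416e00)
    p_low = 0.02425
    if p < p_low:
        q = math.sqrt(-2.0 * math.log(p))
        return (((((c[0] * q + c[1]) * q + c[2]) * q + c[3]) * q + c[4]) * q + c[5]) / \
               ((((d[0] * q + d[1]) * q + d[2]) * q + d[3]) * q + 1.0)
    if p <= 1.0 - p_low:
        q = p - 0.5
        r = q * q
        return (((((a[0] * r + a[1]) * r + a[2]) * r + a[3]) * r + a[4]) * r + a[5]) * q / \
               (((((b[0] * r + b[1]) * r + b[2]) * r + b[3]) * r + b[4]) * r + 1.0)
    q = math.sqrt(-2.0 * math.log(1.0 - p))
    return -(((((c[0] * q + c[1]) * q + c[2]) * q + c[3]) * q + c[4]) * q + c[5]) / \
        ((((d[0] * q + d[1]) * q + d[2]) * q + d[3]) * q + 1.0)


@njit(cache=True)
def ndtri(p):
    if p <= 0.0:
        return -np.inf
    if p >= 1.0:
        return np.inf
    x = _ndtri_acklam(p)
    # one Halley step against the erfc-based CDF
    e = ndtr(x) - p
    u = e * math.sqrt(2.0 * math.pi) * math.exp(0.5 * x * x)
    x = x - u / (1.0 + 0.5 * x * u)
    return x


@njit(cache=True)
def trunc_normal_above(mu, bound, u):
    """Draw from N(mu,1) restricted to (bound, inf) via inverse CDF, u~U(0,1)."""
    a = bound - mu
    if a < 0.0:
        # lots of mass above: work on the lower CDF
        pa = ndtr(a)
        return mu + ndtri(pa + u * (1.0 - pa))
    # tail: work with complementary probabilities for accuracy
    qa = 0.5 * math.erfc(a / SQRT2)
    q = qa * u
    if q <= 0.0:
        q = 1e-300
    return mu - ndtri(q)


@njit(cache=True)
def trunc_normal_below(mu, bound, u):
    """Draw from N(mu,1) restricted to (-inf, bound]."""
    return 2.0 * mu - trunc_normal_above(mu, 2.0 * mu - bound, u)


@njit(cache=True)
def inv_wishart_2x2(df, S, out):
    """Draw G ~ IW(df, S) for 2x2 scale S: G = W^{-1}, W ~ Wishart(df, S^{-1})."""
    det = S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
    v00 = S[1, 1] / det
    v01 = -S[0, 1] / det
    v11 = S[0, 0] / det
    # Cholesky of V = S^{-1}
    l00 = math.sqrt(v00)
    l10 = v01 / l00
    l11 = math.sqrt(v11 - l10 * l10)
    # Bartlett factor
    c00 = math.sqrt(np.random.chisquare(df))
    c10 = np.random.standard_normal()
    c11 = math.sqrt(np.random.chisquare(df - 1.0))
    # B = L @ C (lower triangular), W = B B'
    b00 = l00 * c00
    b10 = l10 * c00 + l11 * c10
    b11 = l11 * c11
    w00 = b00 * b00
    w01 = b00 * b10
    w11 = b10 * b10 + b11 * b11
    detw = w00 * w11 - w01 * w01
    out[0, 0] = w11 / detw
    out[0, 1] = -w01 / detw
    out[1, 0] = -w01 / detw
    out[1, 1] = w00 / detw


@njit(cache=True)
def gibbs_kernel(
    seed,
    sb2,            # uint8[n]: 1 if stillbirth
    fcodes,         # int32[F, n]: absolute loc column per record per factor
    f_off,          # int32[F+1]: factor column offsets into loc
    is_hy,          # uint8[F]
    free,           # uint8[P]
    ncol,           # float64[P]: records per loc column
    sire_code,      # int32[n]
    mgs_code,       # int32[n]
    s_indptr, s_rec,  # CSR bull -> records where bull is sire
    m_indptr, m_rec,  # CSR bull -> records where bull is MGS
    n_both,         # float64[nb]: records where sire == mgs == bull
    ai_indptr, ai_idx, ai_val, ai_diag,  # A^{-1} CSR (full symmetric rows)
    g0_start, hy_var_start,
    nu_g, S0, nu_hy, s0_hy,
    n_iter, burn_in, thin,
    sample_liab, sample_noise, fix_var,
    liab_init,      # float64[n]
):
    np.random.seed(seed)
    n = sb2.shape[0]
    F = fcodes.shape[0]
    P = f_off[F]
    nb = ai_diag.shape[0]

    loc = np.zeros(P)
    s = np.zeros(nb)
    m = np.zeros(nb)
    mu = np.zeros(n)
    l = liab_init.copy()
    g0 = g0_start.copy()
    g0inv = np.empty((2, 2))
    hyv = hy_var_start

    n_keep = (n_iter - burn_in) // thin
    var_out = np.empty((n_keep, 4))
    loc_out = np.empty((n_keep, P + 2 * nb))
    k_out = 0

    maxlev = 0
    for f in range(F):
        w = f_off[f + 1] - f_off[f]
        if w > maxlev:
            maxlev = w
    ssum = np.empty(maxlev)
    dloc = np.empty(maxlev)

    Su = np.empty((2, 2))

    for t in range(n_iter):
        # (a) liabilities: N(mean, 1) truncated by the observed category
        if sample_liab == 1:
            for r in range(n):
                u = np.random.random()
                if sb2[r] == 1:
                    l[r] = trunc_normal_above(mu[r], 0.0, u)
                else:
                    l[r] = trunc_normal_below(mu[r], 0.0, u)

        # (b) factor blocks (levels within a factor are conditionally independent)
        for f in range(F):
            off0 = f_off[f]
            width = f_off[f + 1] - off0
            for j in range(width):
                ssum[j] = 0.0
            for r in range(n):
                c = fcodes[f, r]
                ssum[c - off0] += l[r] - mu[r] + loc[c]
            lam = 0.0
            if is_hy[f] == 1:
                lam = 1.0 / hyv
            for j in range(width):
                c = off0 + j
                if free[c] == 0:
                    dloc[j] = 0.0
                    continue
                prec = ncol[c] + lam
                mean = ssum[j] / prec
                newv = mean
                if sample_noise == 1:
                    newv += np.random.standard_normal() / math.sqrt(prec)
                dloc[j] = newv - loc[c]
                loc[c] = newv
            for r in range(n):
                mu[r] += dloc[fcodes[f, r] - off0]

        # (c) per-bull joint (s, m) updates under G0^{-1} x A^{-1}
        det = g0[0, 0] * g0[1, 1] - g0[0, 1] * g0[1, 0]
        g0inv[0, 0] = g0[1, 1] / det
        g0inv[0, 1] = -g0[0, 1] / det
        g0inv[1, 0] = -g0[1, 0] / det
        g0inv[1, 1] = g0[0, 0] / det
        for b in range(nb):
            ns = float(s_indptr[b + 1] - s_indptr[b])
            nm = float(m_indptr[b + 1] - m_indptr[b])
            rhs0 = ns * s[b] + n_both[b] * m[b]
            for k in range(s_indptr[b], s_indptr[b + 1]):
                r = s_rec[k]
                rhs0 += l[r] - mu[r]
            rhs1 = nm * m[b] + n_both[b] * s[b]
            for k in range(m_indptr[b], m_indptr[b + 1]):
                r = m_rec[k]
                rhs1 += l[r] - mu[r]
            gs = 0.0
            gm = 0.0
            for k in range(ai_indptr[b], ai_indptr[b + 1]):
                j = ai_idx[k]
                if j == b:
                    continue
                gs += ai_val[k] * s[j]
                gm += ai_val[k] * m[j]
            rhs0 -= g0inv[0, 0] * gs + g0inv[0, 1] * gm
            rhs1 -= g0inv[1, 0] * gs + g0inv[1, 1] * gm
            p00 = ns + ai_diag[b] * g0inv[0, 0]
            p01 = n_both[b] + ai_diag[b] * g0inv[0, 1]
            p11 = nm + ai_diag[b] * g0inv[1, 1]
            detp = p00 * p11 - p01 * p01
            mean0 = (p11 * rhs0 - p01 * rhs1) / detp
            mean1 = (p00 * rhs1 - p01 * rhs0) / detp
            new0 = mean0
            new1 = mean1
            if sample_noise == 1:
                # w ~ N(0, P^{-1}) via back-solve of the precision Cholesky
                l00 = math.sqrt(p00)
                l10 = p01 / l00
                l11 = math.sqrt(p11 - l10 * l10)
                z0 = np.random.standard_normal()
                z1 = np.random.standard_normal()
                w1 = z1 / l11
                w0 = (z0 - l10 * w1) / l00
                new0 += w0
                new1 += w1
            ds = new0 - s[b]
            dm = new1 - m[b]
            for k in range(s_indptr[b], s_indptr[b + 1]):
                mu[s_rec[k]] += ds
            for k in range(m_indptr[b], m_indptr[b + 1]):
                mu[m_rec[k]] += dm
            s[b] = new0
            m[b] = new1

        # (d) variance components
        if fix_var == 0:
            sshy = 0.0
            qhy = 0.0
            for f in range(F):
                if is_hy[f] == 1:
                    for c in range(f_off[f], f_off[f + 1]):
                        if free[c] == 1:
                            sshy += loc[c] * loc[c]
                            qhy += 1.0
            hyv = (nu_hy * s0_hy + sshy) / np.random.chisquare(nu_hy + qhy)

            q00 = 0.0
            q01 = 0.0
            q11 = 0.0
            for b in range(nb):
                for k in range(ai_indptr[b], ai_indptr[b + 1]):
                    j = ai_idx[k]
                    v = ai_val[k]
                    q00 += v * s[b] * s[j]
                    q01 += v * s[b] * m[j]
                    q11 += v * m[b] * m[j]
            Su[0, 0] = S0[0, 0] + q00
            Su[0, 1] = S0[0, 1] + q01
            Su[1, 0] = S0[1, 0] + q01
            Su[1, 1] = S0[1, 1] + q11
            inv_wishart_2x2(nu_g + nb, Su, g0)

        if not np.isfinite(mu[0]):
            raise RuntimeError("Gibbs sampler diverged (non-finite liability mean)")

        if t >= burn_in and (t - burn_in + 1) % thin == 0 and k_out < n_keep:
            var_out[k_out, 0] = g0[0, 0]
            var_out[k_out, 1] = g0[1, 1]
            var_out[k_out, 2] = g0[0, 1]
            var_out[k_out, 3] = hyv
            for c in range(P):
                loc_out[k_out, c] = loc[c]
            for b in range(nb):
                loc_out[k_out, P + b] = s[b]
                loc_out[k_out, P + nb + b] = m[b]
            k_out += 1

    return var_out, loc_out
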