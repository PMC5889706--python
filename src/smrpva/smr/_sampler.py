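"""Compiled Metropolis-within-Gibbs core for the spatial mark-resight model.

One call runs one chain.  The state is the parameter vector
(beta0, beta1, delta0, delta1, delta2, alpha1, sigma_f, sigma_m, psi, phi)
plus, for each of the ``M`` augmented individuals, an inclusion flag ``z``,
a sex code and a state-space cell index ``g``.  Scalar parameters move by
adaptive random-walk Metropolis (adaptation frozen after burn-in), ``psi``
and ``phi`` by conjugate Beta draws, ``z`` and latent sex by exact Gibbs,
and activity centers by a mixture of local grid moves and independence
draws from the point-process prior.

The unmarked count at a station-occasion is Poisson-binomial over the live
unmarked individuals' resight probabilities; the pmf tables ``f`` (one row
per station-occasion with a positive count) are maintained incrementally
with O(n) add/remove updates, so single-individual Gibbs ratios are exact
and cheap.

Speed notes, all exact up to ~1e-14: occasions sharing a days-since-baiting
value are collapsed through per-camera day histograms (the resight logit
depends on the occasion only through that covariate), observed detections
re-enter as sparse corrections, and camera/trap rows whose half-normal
kernel is below exp(-68) ~ 3e-30 are skipped.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e300
# Parameter layout of the init vector and of each output row.
N_PAR_OUT = 12  # b0 b1 d0 d1 d2 a1 sigf sigm psi phi N n_habitat


@njit(cache=True)
def _expit(x):
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def _cap_ll_i(g, p0, s2, D2t, Ktrapf, capt_j, capt_y, lo, hi):
    """Binomial capture log-likelihood of one individual at cell g.

    Row loop covers the zero part K_j*log(1-p); entries [lo, hi) of the
    sparse capture list convert y_ij of those nights to log p.
    """
    ll = 0.0
    thr = 68.0 * s2
    J = Ktrapf.shape[0]
    for j in range(J):
        d2 = D2t[g, j]
        if d2 > thr:
            continue
        p = p0 * np.exp(-d2 / (2.0 * s2))
        ll += Ktrapf[j] * np.log1p(-p)
    for t in range(lo, hi):
        j = capt_j[t]
        p = p0 * np.exp(-D2t[g, j] / (2.0 * s2))
        if p < 1.0e-300:
            ll += capt_y[t] * (-690.0)
        else:
            ll += capt_y[t] * (np.log(p) - np.log1p(-p))
    return ll


@njit(cache=True)
def _cam_hist_ll_i(g, s2, base_d, D2c, hist):
    """Sum of log(1 - p) over the occasions counted in ``hist`` (C x D)."""
    ll = 0.0
    thr = 68.0 * s2
    C, D = hist.shape
    for j in range(C):
        d2 = D2c[g, j]
        if d2 > thr:
            continue
        kern = np.exp(-d2 / (2.0 * s2))
        for d in range(D):
            cnt = hist[j, d]
            if cnt > 0.0:
                ll += cnt * np.log1p(-kern * base_d[d])
    return ll


@njit(cache=True)
def _cam_det_corr_i(g, s2, base_d, D2c, det_j, det_didx, lo, hi):
    """Convert the log(1-p) terms of observed detections into log p."""
    ll = 0.0
    for t in range(lo, hi):
        j = det_j[t]
        p = base_d[det_didx[t]] * np.exp(-D2c[g, j] / (2.0 * s2))
        if p < 1.0e-300:
            ll += -690.0
        else:
            ll += np.log(p) - np.log1p(-p)
    return ll


@njit(cache=True)
def _tel_ll_i(i, g, s2, cx, cy, tel_n, tel_sx, tel_sy, tel_ss):
    n = tel_n[i]
    if n <= 0.0:
        return 0.0
    q = (
        tel_ss[i]
        - 2.0 * cx[g] * tel_sx[i]
        - 2.0 * cy[g] * tel_sy[i]
        + n * (cx[g] * cx[g] + cy[g] * cy[g])
    )
    return -n * np.log(2.0 * np.pi * s2) - q / (2.0 * s2)


@njit(cache=True)
def _pos_p_i(g, s2, base_d, D2c, pos_j, pos_didx, out):
    for c in range(pos_j.shape[0]):
        out[c] = base_d[pos_didx[c]] * np.exp(-D2c[g, pos_j[c]] / (2.0 * s2))


@njit(cache=True)
def _pb_add(f, p):
    P, W = f.shape
    for c in range(P):
        pc = p[c]
        for k in range(W - 1, 0, -1):
            f[c, k] = f[c, k] * (1.0 - pc) + f[c, k - 1] * pc
        f[c, 0] *= 1.0 - pc


@njit(cache=True)
def _pb_remove(f, p):
    P, W = f.shape
    for c in range(P):
        pc = p[c]
        q = 1.0 - pc
        f[c, 0] /= q
        for k in range(1, W):
            f[c, k] = (f[c, k] - pc * f[c, k - 1]) / q


@njit(cache=True)
def _pb_w(f, p, pos_n):
    """Sum_c log((1-p_c) f[c, n_c] + p_c f[c, n_c - 1]): include-one likelihood."""
    ll = 0.0
    for c in range(pos_n.shape[0]):
        n = pos_n[c]
        v = (1.0 - p[c]) * f[c, n]
        if n >= 1:
            v += p[c] * f[c, n - 1]
        ll += np.log(v) if v > 0.0 else NEG
    return ll


@njit(cache=True)
def _pb_base(f, pos_n):
    ll = 0.0
    for c in range(pos_n.shape[0]):
        v = f[c, pos_n[c]]
        ll += np.log(v) if v > 0.0 else NEG
    return ll


@njit(cache=True)
def _pb_full(
    basef_d, basem_d, s2f, s2m, g, z, sexv, nm, M, D2c, pos_j, pos_didx, pos_n, f
):
    """Rebuild the Poisson-binomial tables from scratch; return their log-lik."""
    P, W = f.shape
    for c in range(P):
        f[c, 0] = 1.0
        for k in range(1, W):
            f[c, k] = 0.0
    p = np.empty(P)
    for i in range(nm, M):
        if z[i] == 0:
            continue
        if sexv[i] == 1:
            _pos_p_i(g[i], s2f, basef_d, D2c, pos_j, pos_didx, p)
        else:
            _pos_p_i(g[i], s2m, basem_d, D2c, pos_j, pos_didx, p)
        _pb_add(f, p)
    return _pb_base(f, pos_n)


@njit(cache=True)
def _cap_part(
    sexsel, p0, s2, g, z, sexv, nm, M, D2t, Ktrapf, capt_j, capt_y, capt_ptr, sex_m
):
    ll = 0.0
    for i in range(nm):
        if sex_m[i] == sexsel:
            ll += _cap_ll_i(
                g[i], p0, s2, D2t, Ktrapf, capt_j, capt_y, capt_ptr[i], capt_ptr[i + 1]
            )
    for i in range(nm, M):
        if z[i] == 1 and sexv[i] == sexsel:
            ll += _cap_ll_i(g[i], p0, s2, D2t, Ktrapf, capt_j, capt_y, 0, 0)
    return ll


@njit(cache=True)
def _camM_part(
    sexsel, base_d, s2, g, nm, D2c, histc_all, det_j, det_didx, det_ptr, sex_m
):
    ll = 0.0
    for i in range(nm):
        if sex_m[i] == sexsel:
            ll += _cam_hist_ll_i(g[i], s2, base_d, D2c, histc_all)
            ll += _cam_det_corr_i(
                g[i], s2, base_d, D2c, det_j, det_didx, det_ptr[i], det_ptr[i + 1]
            )
    return ll


@njit(cache=True)
def _camZ_part(sexsel, base_d, s2, g, z, sexv, nm, M, D2c, histc_zero):
    ll = 0.0
    for i in range(nm, M):
        if z[i] == 1 and sexv[i] == sexsel:
            ll += _cam_hist_ll_i(g[i], s2, base_d, D2c, histc_zero)
    return ll


@njit(cache=True)
def _tel_part(sexsel, s2, g, nm, sex_m, cx, cy, tel_n, tel_sx, tel_sy, tel_ss):
    ll = 0.0
    for i in range(nm):
        if sex_m[i] == sexsel:
            ll += _tel_ll_i(i, g[i], s2, cx, cy, tel_n, tel_sx, tel_sy, tel_ss)
    return ll


@njit(cache=True)
def _logZ_pp(a1, veg, log_area):
    G = veg.shape[0]
    mx = NEG
    for gg in range(G):
        v = log_area[gg] + a1 * veg[gg]
        if v > mx:
            mx = v
    s = 0.0
    for gg in range(G):
        s += np.exp(log_area[gg] + a1 * veg[gg] - mx)
    return mx + np.log(s)


@njit(cache=True)
def _refresh_pg(a1, veg, log_area, logp_g, cum_pg):
    logZ = _logZ_pp(a1, veg, log_area)
    G = veg.shape[0]
    acc = 0.0
    for gg in range(G):
        logp_g[gg] = log_area[gg] + a1 * veg[gg] - logZ
        acc += np.exp(logp_g[gg])
        cum_pg[gg] = acc


@njit(cache=True)
def _cat_draw(cum_pg):
    u = np.random.random() * cum_pg[cum_pg.shape[0] - 1]
    lo, hi = 0, cum_pg.shape[0] - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if cum_pg[mid] < u:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=True)
def run_chain(
    seed,
    n_iter,
    burn,
    thin,
    # state space
    cx,
    cy,
    veg,
    log_area,
    habitat_u8,
    cell_row,
    cell_col,
    grid_idx,
    # trapping
    D2t,
    Ktrapf,
    capt_j,
    capt_y,
    capt_ptr,
    # cameras
    D2c,
    dvals,
    histc_all,
    histc_zero,
    det_j,
    det_didx,
    det_ptr,
    # marked individuals
    sex_m,
    tel_n,
    tel_sx,
    tel_sy,
    tel_ss,
    # unmarked counts (positive cells)
    pos_j,
    pos_didx,
    pos_n,
    # augmentation and priors
    M,
    sd_beta,
    sd_delta,
    sd_alpha,
    sigma_max,
    # proposals
    base_scales,
    local_sd,
    p_global,
    # inits
    init_par,
    init_g,
):
    np.random.seed(seed)
    nm = sex_m.shape[0]
    G = veg.shape[0]
    P = pos_j.shape[0]
    D = dvals.shape[0]
    nrow, ncol = grid_idx.shape

    b0, b1 = init_par[0], init_par[1]
    d0, d1, d2c = init_par[2], init_par[3], init_par[4]
    a1 = init_par[5]
    sigf, sigm = init_par[6], init_par[7]
    psi, phi = init_par[8], init_par[9]
    s2f, s2m = sigf * sigf, sigm * sigm

    g = init_g.copy()
    z = np.ones(M, dtype=np.uint8)
    sexv = np.empty(M, dtype=np.int64)
    for i in range(nm):
        sexv[i] = sex_m[i]
    for i in range(nm, M):
        sexv[i] = 1 if np.random.random() < 0.5 else 0

    nmax = 0
    for c in range(P):
        if pos_n[c] > nmax:
            nmax = pos_n[c]
    f = np.zeros((P, nmax + 1))
    f_tmp = np.zeros((P, nmax + 1))
    p_buf = np.empty(P)
    p_buf2 = np.empty(P)

    logp_g = np.empty(G)
    cum_pg = np.empty(G)
    _refresh_pg(a1, veg, log_area, logp_g, cum_pg)

    basef_d = np.empty(D)
    basem_d = np.empty(D)
    for d in range(D):
        basef_d[d] = _expit(d0 + d1 + d2c * dvals[d])
        basem_d[d] = _expit(d0 + d2c * dvals[d])

    # cached log-likelihood parts:
    # 0 capF 1 capM 2 camM_F 3 camM_M 4 camZ_F 5 camZ_M 6 telF 7 telM 8 pb
    parts = np.zeros(9)

    # adaptive multipliers, one per scalar block:
    # 0 b0, 1 b1, 2 d0, 3 d1, 4 d2, 5 a1, 6 log sig_f, 7 log sig_m
    mult = np.ones(8)
    acc = np.zeros(8)
    att = np.zeros(8)

    n_keep = (n_iter - burn) // thin
    out = np.empty((n_keep, N_PAR_OUT))
    kept = 0

    for it in range(n_iter):
        # ---- refresh cached parts for current state
        p0f = _expit(b0 + b1)
        p0m = _expit(b0)
        parts[0] = _cap_part(
            1, p0f, s2f, g, z, sexv, nm, M, D2t, Ktrapf, capt_j, capt_y, capt_ptr, sex_m
        )
        parts[1] = _cap_part(
            0, p0m, s2m, g, z, sexv, nm, M, D2t, Ktrapf, capt_j, capt_y, capt_ptr, sex_m
        )
        parts[2] = _camM_part(
            1, basef_d, s2f, g, nm, D2c, histc_all, det_j, det_didx, det_ptr, sex_m
        )
        parts[3] = _camM_part(
            0, basem_d, s2m, g, nm, D2c, histc_all, det_j, det_didx, det_ptr, sex_m
        )
        parts[4] = _camZ_part(1, basef_d, s2f, g, z, sexv, nm, M, D2c, histc_zero)
        parts[5] = _camZ_part(0, basem_d, s2m, g, z, sexv, nm, M, D2c, histc_zero)
        parts[6] = _tel_part(1, s2f, g, nm, sex_m, cx, cy, tel_n, tel_sx, tel_sy, tel_ss)
        parts[7] = _tel_part(0, s2m, g, nm, sex_m, cx, cy, tel_n, tel_sx, tel_sy, tel_ss)
        parts[8] = _pb_full(
            basef_d, basem_d, s2f, s2m, g, z, sexv, nm, M, D2c, pos_j, pos_didx, pos_n, f
        )

        # ---- capture coefficients (per-parameter adaptive random walks)
        for b in range(2):
            att[b] += 1.0
            eps = mult[b] * base_scales[b] * np.random.normal(0.0, 1.0)
            nb0 = b0 + eps if b == 0 else b0
            nb1 = b1 + eps if b == 1 else b1
            np0f = _expit(nb0 + nb1)
            np0m = _expit(nb0)
            capF = _cap_part(
                1, np0f, s2f, g, z, sexv, nm, M, D2t, Ktrapf, capt_j, capt_y,
                capt_ptr, sex_m,
            )
            capM = _cap_part(
                0, np0m, s2m, g, z, sexv, nm, M, D2t, Ktrapf, capt_j, capt_y,
                capt_ptr, sex_m,
            )
            logr = (capF + capM - parts[0] - parts[1]) + (
                b0 * b0 - nb0 * nb0 + b1 * b1 - nb1 * nb1
            ) / (2.0 * sd_beta * sd_beta)
            if np.log(np.random.random()) < logr:
                b0, b1, p0f, p0m = nb0, nb1, np0f, np0m
                parts[0], parts[1] = capF, capM
                acc[b] += 1.0

        # ---- resight coefficients (per-parameter adaptive random walks)
        for b in range(2, 5):
            att[b] += 1.0
            eps = mult[b] * base_scales[b] * np.random.normal(0.0, 1.0)
            nd0 = d0 + eps if b == 2 else d0
            nd1 = d1 + eps if b == 3 else d1
            nd2 = d2c + eps if b == 4 else d2c
            nbasef = np.empty(D)
            nbasem = np.empty(D)
            for d in range(D):
                nbasef[d] = _expit(nd0 + nd1 + nd2 * dvals[d])
                nbasem[d] = _expit(nd0 + nd2 * dvals[d])
            camMF = _camM_part(
                1, nbasef, s2f, g, nm, D2c, histc_all, det_j, det_didx, det_ptr, sex_m
            )
            camMM = _camM_part(
                0, nbasem, s2m, g, nm, D2c, histc_all, det_j, det_didx, det_ptr, sex_m
            )
            camZF = _camZ_part(1, nbasef, s2f, g, z, sexv, nm, M, D2c, histc_zero)
            camZM = _camZ_part(0, nbasem, s2m, g, z, sexv, nm, M, D2c, histc_zero)
            pb = _pb_full(
                nbasef, nbasem, s2f, s2m, g, z, sexv, nm, M, D2c, pos_j, pos_didx,
                pos_n, f_tmp,
            )
            logr = (
                camMF + camMM + camZF + camZM + pb
                - parts[2] - parts[3] - parts[4] - parts[5] - parts[8]
            ) + (
                d0 * d0 - nd0 * nd0 + d1 * d1 - nd1 * nd1 + d2c * d2c - nd2 * nd2
            ) / (2.0 * sd_delta * sd_delta)
            if np.log(np.random.random()) < logr:
                d0, d1, d2c = nd0, nd1, nd2
                basef_d, basem_d = nbasef, nbasem
                parts[2], parts[3], parts[4], parts[5], parts[8] = (
                    camMF, camMM, camZF, camZM, pb,
                )
                tmp = f
                f = f_tmp
                f_tmp = tmp
                acc[b] += 1.0

        # ---- movement scales (log-scale random walks, one per sex)
        for sexsel in (1, 0):
            bi = 6 if sexsel == 1 else 7
            att[bi] += 1.0
            sig = sigf if sexsel == 1 else sigm
            nsig = sig * np.exp(mult[bi] * base_scales[6 + (0 if sexsel == 1 else 1)]
                                * np.random.normal(0.0, 1.0))
            if nsig < sigma_max:
                ns2 = nsig * nsig
                base_d = basef_d if sexsel == 1 else basem_d
                p0s = p0f if sexsel == 1 else p0m
                o = 0 if sexsel == 1 else 1
                capS = _cap_part(
                    sexsel, p0s, ns2, g, z, sexv, nm, M, D2t, Ktrapf, capt_j, capt_y,
                    capt_ptr, sex_m,
                )
                camMS = _camM_part(
                    sexsel, base_d, ns2, g, nm, D2c, histc_all, det_j, det_didx,
                    det_ptr, sex_m,
                )
                camZS = _camZ_part(sexsel, base_d, ns2, g, z, sexv, nm, M, D2c, histc_zero)
                telS = _tel_part(
                    sexsel, ns2, g, nm, sex_m, cx, cy, tel_n, tel_sx, tel_sy, tel_ss
                )
                if sexsel == 1:
                    pb = _pb_full(
                        basef_d, basem_d, ns2, s2m, g, z, sexv, nm, M, D2c, pos_j,
                        pos_didx, pos_n, f_tmp,
                    )
                else:
                    pb = _pb_full(
                        basef_d, basem_d, s2f, ns2, g, z, sexv, nm, M, D2c, pos_j,
                        pos_didx, pos_n, f_tmp,
                    )
                logr = (
                    capS + camMS + camZS + telS + pb
                    - parts[0 + o] - parts[2 + o] - parts[4 + o] - parts[6 + o]
                    - parts[8]
                ) + np.log(nsig / sig)
                if np.log(np.random.random()) < logr:
                    if sexsel == 1:
                        sigf, s2f = nsig, ns2
                    else:
                        sigm, s2m = nsig, ns2
                    parts[0 + o], parts[2 + o], parts[4 + o], parts[6 + o] = (
                        capS, camMS, camZS, telS,
                    )
                    parts[8] = pb
                    tmp = f
                    f = f_tmp
                    f_tmp = tmp
                    acc[bi] += 1.0

        # ---- vegetation effect on the activity-center point process
        att[5] += 1.0
        na1 = a1 + mult[5] * base_scales[5] * np.random.normal(0.0, 1.0)
        sum_veg = 0.0
        for i in range(M):
            sum_veg += veg[g[i]]
        logZ_cur = _logZ_pp(a1, veg, log_area)
        logZ_new = _logZ_pp(na1, veg, log_area)
        logr = (
            (na1 - a1) * sum_veg
            - M * (logZ_new - logZ_cur)
            + (a1 * a1 - na1 * na1) / (2.0 * sd_alpha * sd_alpha)
        )
        if np.log(np.random.random()) < logr:
            a1 = na1
            _refresh_pg(a1, veg, log_area, logp_g, cum_pg)
            acc[5] += 1.0

        # ---- inclusion and sex mixture weights (conjugate Beta draws)
        Nz = 0.0
        for i in range(M):
            Nz += z[i]
        psi = np.random.beta(1.0 + Nz, 1.0 + M - Nz)
        nf = 0.0
        for i in range(M):
            nf += sexv[i]
        phi = np.random.beta(1.0 + nf, 1.0 + M - nf)

        # ---- inclusion flags z (exact Gibbs, Poisson-binomial maintained)
        lpsi = np.log(psi)
        lpsi0 = np.log(1.0 - psi)
        for i in range(nm, M):
            s2 = s2f if sexv[i] == 1 else s2m
            base_d = basef_d if sexv[i] == 1 else basem_d
            p0s = p0f if sexv[i] == 1 else p0m
            _pos_p_i(g[i], s2, base_d, D2c, pos_j, pos_didx, p_buf)
            if z[i] == 1:
                _pb_remove(f, p_buf)
            l1 = (
                lpsi
                + _cap_ll_i(g[i], p0s, s2, D2t, Ktrapf, capt_j, capt_y, 0, 0)
                + _cam_hist_ll_i(g[i], s2, base_d, D2c, histc_zero)
                + _pb_w(f, p_buf, pos_n)
            )
            l0 = lpsi0 + _pb_base(f, pos_n)
            dl = l0 - l1
            if dl > 700.0:
                pr1 = 0.0
            elif dl < -700.0:
                pr1 = 1.0
            else:
                pr1 = 1.0 / (1.0 + np.exp(dl))
            z[i] = 1 if np.random.random() < pr1 else 0
            if z[i] == 1:
                _pb_add(f, p_buf)

        # ---- latent sex of augmented individuals (exact Gibbs)
        lphi = np.log(phi)
        lphi0 = np.log(1.0 - phi)
        for i in range(nm, M):
            if z[i] == 0:
                sexv[i] = 1 if np.random.random() < phi else 0
                continue
            s2 = s2f if sexv[i] == 1 else s2m
            base_d = basef_d if sexv[i] == 1 else basem_d
            _pos_p_i(g[i], s2, base_d, D2c, pos_j, pos_didx, p_buf)
            _pb_remove(f, p_buf)
            _pos_p_i(g[i], s2f, basef_d, D2c, pos_j, pos_didx, p_buf)
            lf = (
                lphi
                + _cap_ll_i(g[i], p0f, s2f, D2t, Ktrapf, capt_j, capt_y, 0, 0)
                + _cam_hist_ll_i(g[i], s2f, basef_d, D2c, histc_zero)
                + _pb_w(f, p_buf, pos_n)
            )
            _pos_p_i(g[i], s2m, basem_d, D2c, pos_j, pos_didx, p_buf2)
            lm = (
                lphi0
                + _cap_ll_i(g[i], p0m, s2m, D2t, Ktrapf, capt_j, capt_y, 0, 0)
                + _cam_hist_ll_i(g[i], s2m, basem_d, D2c, histc_zero)
                + _pb_w(f, p_buf2, pos_n)
            )
            dl = lm - lf
            if dl > 700.0:
                prf = 0.0
            elif dl < -700.0:
                prf = 1.0
            else:
                prf = 1.0 / (1.0 + np.exp(dl))
            if np.random.random() < prf:
                sexv[i] = 1
                _pb_add(f, p_buf)
            else:
                sexv[i] = 0
                _pb_add(f, p_buf2)

        # ---- activity centers
        for i in range(nm):
            s2 = s2f if sex_m[i] == 1 else s2m
            base_d = basef_d if sex_m[i] == 1 else basem_d
            p0s = p0f if sex_m[i] == 1 else p0m
            use_global = np.random.random() < p_global
            if use_global:
                gp = _cat_draw(cum_pg)
                prior_diff = 0.0  # prior and proposal cancel
            else:
                dr = int(round(local_sd * np.random.normal(0.0, 1.0)))
                dc = int(round(local_sd * np.random.normal(0.0, 1.0)))
                rr = cell_row[g[i]] + dr
                cc = cell_col[g[i]] + dc
                if rr < 0 or rr >= nrow or cc < 0 or cc >= ncol:
                    continue
                gp = grid_idx[rr, cc]
                if gp < 0:
                    continue
                prior_diff = logp_g[gp] - logp_g[g[i]]
            if gp == g[i]:
                continue
            ll_cur = (
                _cap_ll_i(g[i], p0s, s2, D2t, Ktrapf, capt_j, capt_y,
                          capt_ptr[i], capt_ptr[i + 1])
                + _cam_hist_ll_i(g[i], s2, base_d, D2c, histc_all)
                + _cam_det_corr_i(g[i], s2, base_d, D2c, det_j, det_didx,
                                  det_ptr[i], det_ptr[i + 1])
                + _tel_ll_i(i, g[i], s2, cx, cy, tel_n, tel_sx, tel_sy, tel_ss)
            )
            ll_new = (
                _cap_ll_i(gp, p0s, s2, D2t, Ktrapf, capt_j, capt_y,
                          capt_ptr[i], capt_ptr[i + 1])
                + _cam_hist_ll_i(gp, s2, base_d, D2c, histc_all)
                + _cam_det_corr_i(gp, s2, base_d, D2c, det_j, det_didx,
                                  det_ptr[i], det_ptr[i + 1])
                + _tel_ll_i(i, gp, s2, cx, cy, tel_n, tel_sx, tel_sy, tel_ss)
            )
            if np.log(np.random.random()) < ll_new - ll_cur + prior_diff:
                g[i] = gp

        for i in range(nm, M):
            if z[i] == 0:
                g[i] = _cat_draw(cum_pg)
                continue
            s2 = s2f if sexv[i] == 1 else s2m
            base_d = basef_d if sexv[i] == 1 else basem_d
            p0s = p0f if sexv[i] == 1 else p0m
            use_global = np.random.random() < p_global
            if use_global:
                gp = _cat_draw(cum_pg)
                prior_diff = 0.0
            else:
                dr = int(round(local_sd * np.random.normal(0.0, 1.0)))
                dc = int(round(local_sd * np.random.normal(0.0, 1.0)))
                rr = cell_row[g[i]] + dr
                cc = cell_col[g[i]] + dc
                if rr < 0 or rr >= nrow or cc < 0 or cc >= ncol:
                    continue
                gp = grid_idx[rr, cc]
                if gp < 0:
                    continue
                prior_diff = logp_g[gp] - logp_g[g[i]]
            if gp == g[i]:
                continue
            _pos_p_i(g[i], s2, base_d, D2c, pos_j, pos_didx, p_buf)
            _pb_remove(f, p_buf)
            ll_cur = (
                _cap_ll_i(g[i], p0s, s2, D2t, Ktrapf, capt_j, capt_y, 0, 0)
                + _cam_hist_ll_i(g[i], s2, base_d, D2c, histc_zero)
                + _pb_w(f, p_buf, pos_n)
            )
            _pos_p_i(gp, s2, base_d, D2c, pos_j, pos_didx, p_buf2)
            ll_new = (
                _cap_ll_i(gp, p0s, s2, D2t, Ktrapf, capt_j, capt_y, 0, 0)
                + _cam_hist_ll_i(gp, s2, base_d, D2c, histc_zero)
                + _pb_w(f, p_buf2, pos_n)
            )
            if np.log(np.random.random()) < ll_new - ll_cur + prior_diff:
                g[i] = gp
                _pb_add(f, p_buf2)
            else:
                _pb_add(f, p_buf)

        # ---- adapt proposal scales during burn-in
        if it < burn and (it + 1) % 50 == 0:
            for b in range(8):
                if att[b] > 0.0:
                    rate = acc[b] / att[b]
                    mult[b] *= np.exp(1.2 * (rate - 0.35))
                    if mult[b] < 1.0e-3:
                        mult[b] = 1.0e-3
                    elif mult[b] > 1.0e3:
                        mult[b] = 1.0e3
                acc[b] = 0.0
                att[b] = 0.0

        # ---- record
        if it >= burn and (it - burn) % thin == 0 and kept < n_keep:
            nhab = 0.0
            Ntot = 0.0
            for i in range(M):
                if z[i] == 1:
                    Ntot += 1.0
                    if habitat_u8[g[i]] == 1:
                        nhab += 1.0
            out[kept, 0] = b0
            out[kept, 1] = b1
            out[kept, 2] = d0
            out[kept, 3] = d1
            out[kept, 4] = d2c
            out[kept, 5] = a1
            out[kept, 6] = sigf
            out[kept, 7] = sigm
            out[kept, 8] = psi
            out[kept, 9] = phi
            out[kept, 10] = Ntot
            out[kept, 11] = nhab
            kept += 1

    return out
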