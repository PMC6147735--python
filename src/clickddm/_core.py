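"""Numba kernels: Fokker-Planck propagation (with forward-mode tangents)
and Monte Carlo path simulation for the bounded click accumulator.

Discretization
--------------
The accumulator axis is discretized into ``ni`` interior bins of width
``dx = 2B/(ni+1)`` whose centers tile (-B, B) symmetrically about 0 (``ni``
odd, center bin exactly at a=0), plus two absorbing "sticky" masses at
+/-B.  Time advances in steps of ``dt``; clicks are snapped to the nearest
step boundary (adaptation uses exact click times).

Each time step applies (i) deterministic drift, moving every bin center by
the exact linear-ODE factor ``exp(lam*dt)`` with a mean-preserving two-bin
split, and (ii) diffusion, by convolution with a discrete Gaussian kernel
obtained from CDF differences.  Two numerical corrections keep the first
two moments of the propagated distribution essentially exact:

* the kernel's target variance is reduced by 1/12 bin^2 (Sheppard's
  correction for the variance added by binning a continuous kernel), and
* the spurious variance injected by each two-bin split (r(1-r) bin^2 per
  unit mass) is subtracted from a running "pending variance" budget, which
  also defers convolution until at least ~0.33 bin^2 of variance has
  accumulated, so that narrow kernels are never built.

Clicks displace mass by a Gaussian kernel whose mean is the adapted,
gain-scaled click magnitude and whose SD is magnitude * sigma_s for the
click's side, merged with any pending diffusion variance.

Gradients are propagated alongside the mass vector as eight tangent rows
(lam, sigma2_a, sigma2_s ipsi/contra, B, phi, tau_phi, g_w); the threshold
and lapse partials are obtained analytically at readout.  Dependence on B
enters only through scalar factors (everything is computed in bin units),
which keeps the tangents exact.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# tangent row order (rows 1..8 of the work arrays)
# 0 lam, 1 sigma2_a, 2 sigma2_s_ipsi, 3 sigma2_s_contra, 4 B, 5 phi, 6 tau_phi, 7 g_w
NTAN = 8

# minimum pending variance (bin^2) before a convolution is performed;
# 1/12 is consumed by the Sheppard correction, 0.25 keeps kernels resolvable
S2MIN = 1.0 / 12.0 + 0.25

_SQRT1_2 = 0.7071067811865476
_INV_SQRT_2PI = 0.3989422804014327


@njit(cache=True)
def _ncdf(x):
    return 0.5 * (1.0 + math.erf(x * _SQRT1_2))


@njit(cache=True, fastmath=True)
def _build_kernel(mu, s2_eff, kbuf, dmu, ds2, maxoff):
    """Discrete Gaussian kernel over integer offsets [omin, omin+n-1].

    ``kbuf[j]`` is the probability that a N(mu, s2_eff) displacement falls
    in bin ``omin+j``; tails are folded into the end bins so the kernel sums
    to exactly 1.  ``dmu``/``ds2`` receive the partials w.r.t. the mean and
    the (effective) variance.  Returns (omin, n).
    """
    s = math.sqrt(s2_eff)
    w = 4.0 * s
    omin = int(math.floor(mu - w))
    omax = int(math.ceil(mu + w))
    if omax - omin + 1 > 2 * maxoff + 1:
        c = int(math.floor(mu))
        omin = c - maxoff
        omax = c + maxoff
    n = omax - omin + 1
    if n <= 1:
        kbuf[0] = 1.0
        dmu[0] = 0.0
        ds2[0] = 0.0
        return omin, 1
    inv_s = 1.0 / s
    inv_2s2 = 1.0 / (2.0 * s2_eff)
    prev_c = 0.0
    prev_dm = 0.0
    prev_ds = 0.0
    for j in range(n - 1):
        e = (omin + j + 0.5 - mu) * inv_s
        c = _ncdf(e)
        pdf = _INV_SQRT_2PI * math.exp(-0.5 * e * e)
        dm = -pdf * inv_s
        dsv = -pdf * e * inv_2s2
        kbuf[j] = c - prev_c
        dmu[j] = dm - prev_dm
        ds2[j] = dsv - prev_ds
        prev_c = c
        prev_dm = dm
        prev_ds = dsv
    kbuf[n - 1] = 1.0 - prev_c
    dmu[n - 1] = -prev_dm
    ds2[n - 1] = -prev_ds
    return omin, n


@njit(cache=True, fastmath=True)
def _conv_row(srcrow, dstrow, stk, r, lo, hi, ni, kern, omin, nk):
    """dstrow[i+omin+j] += srcrow[i]*kern[j]; out-of-grid mass -> stk[r, 0/1]."""
    if lo + omin >= 0 and hi + omin + nk <= ni:
        # fully interior: accumulate one kernel tap at a time over the
        # contiguous source range (vectorizable)
        for j in range(nk):
            k = kern[j]
            off = omin + j
            for i in range(lo, hi + 1):
                dstrow[i + off] += k * srcrow[i]
        return
    for i in range(lo, hi + 1):
        v = srcrow[i]
        if v == 0.0:
            continue
        base = i + omin
        if base >= 0 and base + nk <= ni:
            for j in range(nk):
                dstrow[base + j] += v * kern[j]
        else:
            for j in range(nk):
                d = base + j
                if d < 0:
                    stk[r, 0] += v * kern[j]
                elif d >= ni:
                    stk[r, 1] += v * kern[j]
                else:
                    dstrow[d] += v * kern[j]


@njit(cache=True)
def _adaptation(nc, click_t, phi, tau, Cb, dCp, dCt):
    """Per-click adapted amplitudes C with partials w.r.t. phi and tau_phi.

    C relaxes to 1 between clicks (closed-form exponential) and is
    multiplied by phi immediately *after* each click, so the first click of
    a train always has unit amplitude and each click's impact uses the
    pre-multiplication value.
    """
    Ca = 1.0
    dCa_p = 0.0
    dCa_t = 0.0
    t_prev = -1.0e300
    for j in range(nc):
        d = click_t[j] - t_prev
        x = d / tau
        E = math.exp(-x) if x < 700.0 else 0.0
        cb = 1.0 + (Ca - 1.0) * E
        dE_t = E * d / (tau * tau)
        db_p = dCa_p * E
        db_t = dCa_t * E + (Ca - 1.0) * dE_t
        Cb[j] = cb
        dCp[j] = db_p
        dCt[j] = db_t
        Ca = phi * cb
        dCa_p = cb + phi * db_p
        dCa_t = phi * db_t
        t_prev = click_t[j]


@njit(cache=True, fastmath=True)
def _fp_trial(
    ni,
    dt,
    n_steps,
    lam,
    s2a,
    s2sI,
    s2sC,
    B,
    phi,
    tau,
    gw,
    thresh,
    nc,
    click_t,
    click_step,
    click_sign,
    click_ipsi,
    ngrad,
    A,
    SA,
    Bf,
    SB,
    kbuf,
    dmubuf,
    ds2buf,
    grad_out,
    record,
    rec_out,
    var_mode,
):
    """Propagate one trial; returns P(a(T) > thresh) before lapse mixing.

    ``var_mode`` selects the click-noise scaling: 0 -> click SD =
    magnitude * sigma_s (displayed-equation semantics, default); 1 ->
    click variance = magnitude * sigma_s^2 (the alternative reading in
    which the variance, not the SD, scales with the adapted amplitude).

    ``A``/``Bf`` are (NTAN+3, ni) work arrays: row 0 mass, rows 1..8
    tangents, rows 9/10 scratch for the kernel mean/variance source terms.
    ``SA``/``SB`` are the matching (NTAN+3, 2) sticky accumulators
    (column 0: -B, column 1: +B).  ``grad_out`` (length 11) receives the
    partials of the returned probability in internal coordinate order; the
    kappa entries stay 0 (lapse mixing happens downstream).
    """
    h = (ni - 1) // 2
    dx = 2.0 * B / (ni + 1.0)
    inv_dx2 = 1.0 / (dx * dx)
    nrow = 1 + (NTAN if ngrad != 0 else 0)
    maxoff = ni

    for r in range(NTAN + 3):
        for i in range(ni):
            A[r, i] = 0.0
            Bf[r, i] = 0.0
        SA[r, 0] = 0.0
        SA[r, 1] = 0.0
        SB[r, 0] = 0.0
        SB[r, 1] = 0.0
    A[0, h] = 1.0
    lo = h
    hi = h

    # adaptation amplitudes (exact click times)
    Cb = np.empty(nc)
    dCp = np.empty(nc)
    dCt = np.empty(nc)
    _adaptation(nc, click_t, phi, tau, Cb, dCp, dCt)

    pending = 0.0
    dpending = np.zeros(NTAN)
    dmu_th = np.zeros(NTAN)
    ds2_th = np.zeros(NTAN)

    g = math.exp(lam * dt)
    # exact OU variance injected per step: s2a*(e^{2*lam*dt}-1)/(2*lam)
    x2 = 2.0 * lam * dt
    if abs(x2) > 1e-4:
        fvar = (math.exp(x2) - 1.0) / (2.0 * lam)
        dfvar = dt * math.exp(x2) / lam - (math.exp(x2) - 1.0) / (2.0 * lam * lam)
    else:
        fvar = dt * (1.0 + lam * dt + (2.0 / 3.0) * lam * lam * dt * dt)
        dfvar = dt * dt * (1.0 + (4.0 / 3.0) * lam * dt)
    base_var = s2a * fvar * inv_dx2
    dbase_lam = s2a * dfvar * inv_dx2
    dead = False

    cur = A
    scur = SA
    nxt = Bf
    snxt = SB

    if record:
        rec_out[0, 0] = scur[0, 0]
        for i in range(ni):
            rec_out[0, 1 + i] = cur[0, i]
        rec_out[0, ni + 1] = scur[0, 1]

    ic = 0
    # clicks snapped to step 0 are applied to the initial delta
    for step in range(0, n_steps + 1):
        if step > 0 and not dead:
            # ---------------- drift ----------------
            pl = (lo - h) * g + h
            ph = (hi - h) * g + h
            lo2 = int(math.floor(min(pl, ph)))
            hi2 = int(math.floor(max(pl, ph))) + 1
            if lo2 < 0:
                lo2 = 0
            if hi2 > ni - 1:
                hi2 = ni - 1
            for r in range(nrow):
                for i in range(lo2, hi2 + 1):
                    nxt[r, i] = 0.0
                snxt[r, 0] = scur[r, 0]
                snxt[r, 1] = scur[r, 1]
            sv = 0.0
            dsv = np.zeros(NTAN)
            for i in range(lo, hi + 1):
                v = cur[0, i]
                pos = (i - h) * g + h
                f0 = math.floor(pos)
                rr = pos - f0
                i0 = int(f0)
                i1 = i0 + 1
                w0 = 1.0 - rr
                if v != 0.0 or ngrad != 0:
                    if i0 < 0:
                        snxt[0, 0] += v * w0
                    elif i0 > ni - 1:
                        snxt[0, 1] += v * w0
                    else:
                        nxt[0, i0] += v * w0
                    if i1 < 0:
                        snxt[0, 0] += v * rr
                    elif i1 > ni - 1:
                        snxt[0, 1] += v * rr
                    else:
                        nxt[0, i1] += v * rr
                    sv += v * rr * w0
                    if ngrad != 0:
                        dpos = (i - h) * g * dt  # d(pos)/d(lam)
                        dsv[0] += cur[1, i] * rr * w0 + v * (1.0 - 2.0 * rr) * dpos
                        for p in range(1, NTAN):
                            dsv[p] += cur[1 + p, i] * rr * w0
                        for p in range(NTAN):
                            tv = cur[1 + p, i]
                            e0 = tv * w0
                            e1 = tv * rr
                            if p == 0:
                                e0 -= v * dpos
                                e1 += v * dpos
                            if i0 < 0:
                                snxt[1 + p, 0] += e0
                            elif i0 > ni - 1:
                                snxt[1 + p, 1] += e0
                            else:
                                nxt[1 + p, i0] += e0
                            if i1 < 0:
                                snxt[1 + p, 0] += e1
                            elif i1 > ni - 1:
                                snxt[1 + p, 1] += e1
                            else:
                                nxt[1 + p, i1] += e1
            lo = lo2
            hi = hi2
            tmp = cur
            cur = nxt
            nxt = tmp
            stmp = scur
            scur = snxt
            snxt = stmp

            # interior mass (for per-unit-mass variance bookkeeping)
            m_int = 0.0
            for i in range(lo, hi + 1):
                m_int += cur[0, i]
            if m_int > 1e-13:
                pending += base_var - sv / m_int
                if ngrad != 0:
                    dpending[0] += dbase_lam
                    dpending[1] += fvar * inv_dx2
                    dpending[4] += -2.0 * base_var / B
                    inv_m = 1.0 / m_int
                    for p in range(NTAN):
                        dm = 0.0
                        for i in range(lo, hi + 1):
                            dm += cur[1 + p, i]
                        dpending[p] -= (dsv[p] - sv * inv_m * dm) * inv_m
            else:
                dead = True

            # ---------------- diffusion ----------------
            if not dead and pending >= S2MIN:
                omin, nk = _build_kernel(0.0, pending - 1.0 / 12.0, kbuf, dmubuf, ds2buf, maxoff)
                lo2 = lo + omin
                hi2 = hi + omin + nk - 1
                if lo2 < 0:
                    lo2 = 0
                if hi2 > ni - 1:
                    hi2 = ni - 1
                nsrc = nrow + 1 if ngrad != 0 else nrow
                for r in range(nsrc):
                    for i in range(lo2, hi2 + 1):
                        nxt[r, i] = 0.0
                    snxt[r, 0] = scur[r, 0] if r < nrow else 0.0
                    snxt[r, 1] = scur[r, 1] if r < nrow else 0.0
                for r in range(nrow):
                    _conv_row(cur[r], nxt[r], snxt, r, lo, hi, ni, kbuf, omin, nk)
                if ngrad != 0:
                    _conv_row(cur[0], nxt[nrow], snxt, nrow, lo, hi, ni, ds2buf, omin, nk)
                    for p in range(NTAN):
                        dp = dpending[p]
                        if dp != 0.0:
                            for i in range(lo2, hi2 + 1):
                                nxt[1 + p, i] += dp * nxt[nrow, i]
                            snxt[1 + p, 0] += dp * snxt[nrow, 0]
                            snxt[1 + p, 1] += dp * snxt[nrow, 1]
                pending = 0.0
                for p in range(NTAN):
                    dpending[p] = 0.0
                lo = lo2
                hi = hi2
                tmp = cur
                cur = nxt
                nxt = tmp
                stmp = scur
                scur = snxt
                snxt = stmp

        # ---------------- clicks snapped to this step ----------------
        while ic < nc and click_step[ic] == step:
            if dead:
                ic += 1
                continue
            sgn = click_sign[ic]
            if click_ipsi[ic] != 0:
                wside = gw
                dw = 1.0
                s2s = s2sI
                s2s_row = 2
            else:
                wside = 1.0 - gw
                dw = -1.0
                s2s = s2sC
                s2s_row = 3
            mag = 2.0 * wside * Cb[ic]
            mu = sgn * mag / dx
            if var_mode == 0:
                s2c = mag * mag * s2s * inv_dx2
            else:
                s2c = abs(mag) * s2s * inv_dx2
            for p in range(NTAN):
                dmu_th[p] = 0.0
                ds2_th[p] = 0.0
            if ngrad != 0:
                dmag_p = 2.0 * wside * dCp[ic]
                dmag_t = 2.0 * wside * dCt[ic]
                dmag_g = 2.0 * dw * Cb[ic]
                dmu_th[4] = -mu / B
                dmu_th[5] = sgn * dmag_p / dx
                dmu_th[6] = sgn * dmag_t / dx
                dmu_th[7] = sgn * dmag_g / dx
                if var_mode == 0:
                    ds2_th[s2s_row] = mag * mag * inv_dx2
                    dvar_dmag = 2.0 * mag * s2s * inv_dx2
                else:
                    ds2_th[s2s_row] = abs(mag) * inv_dx2
                    dvar_dmag = (1.0 if mag >= 0 else -1.0) * s2s * inv_dx2
                ds2_th[4] = -2.0 * s2c / B
                ds2_th[5] = dvar_dmag * dmag_p
                ds2_th[6] = dvar_dmag * dmag_t
                ds2_th[7] = dvar_dmag * dmag_g
            s2_tot = s2c + pending
            if ngrad != 0:
                for p in range(NTAN):
                    ds2_th[p] += dpending[p]
            if s2_tot >= S2MIN:
                omin, nk = _build_kernel(mu, s2_tot - 1.0 / 12.0, kbuf, dmubuf, ds2buf, maxoff)
                lo2 = lo + omin
                hi2 = hi + omin + nk - 1
                if lo2 < 0:
                    lo2 = 0
                if hi2 > ni - 1:
                    hi2 = ni - 1
                if lo2 > hi2:
                    # entire kernel off-grid: all interior mass absorbs
                    lo2 = lo
                    hi2 = lo
                nsrc = nrow + 2 if ngrad != 0 else nrow
                for r in range(nsrc):
                    for i in range(lo2, hi2 + 1):
                        nxt[r, i] = 0.0
                    snxt[r, 0] = scur[r, 0] if r < nrow else 0.0
                    snxt[r, 1] = scur[r, 1] if r < nrow else 0.0
                for r in range(nrow):
                    _conv_row(cur[r], nxt[r], snxt, r, lo, hi, ni, kbuf, omin, nk)
                if ngrad != 0:
                    _conv_row(cur[0], nxt[nrow], snxt, nrow, lo, hi, ni, dmubuf, omin, nk)
                    _conv_row(cur[0], nxt[nrow + 1], snxt, nrow + 1, lo, hi, ni, ds2buf, omin, nk)
                    for p in range(NTAN):
                        cm = dmu_th[p]
                        cs = ds2_th[p]
                        if cm != 0.0 or cs != 0.0:
                            for i in range(lo2, hi2 + 1):
                                nxt[1 + p, i] += cm * nxt[nrow, i] + cs * nxt[nrow + 1, i]
                            snxt[1 + p, 0] += cm * snxt[nrow, 0] + cs * snxt[nrow + 1, 0]
                            snxt[1 + p, 1] += cm * snxt[nrow, 1] + cs * snxt[nrow + 1, 1]
                pending = 0.0
                for p in range(NTAN):
                    dpending[p] = 0.0
                lo = lo2
                hi = hi2
            else:
                # narrow click: mean-preserving shift, variance deferred
                q = int(math.floor(mu))
                rr = mu - q
                w0 = 1.0 - rr
                lo2 = lo + q
                hi2 = hi + q + 1
                if lo2 < 0:
                    lo2 = 0
                if hi2 > ni - 1:
                    hi2 = ni - 1
                if lo2 > hi2:
                    lo2 = lo
                    hi2 = lo
                for r in range(nrow):
                    for i in range(lo2, hi2 + 1):
                        nxt[r, i] = 0.0
                    snxt[r, 0] = scur[r, 0]
                    snxt[r, 1] = scur[r, 1]
                for i in range(lo, hi + 1):
                    v = cur[0, i]
                    i0 = i + q
                    i1 = i0 + 1
                    if i0 < 0:
                        snxt[0, 0] += v * w0
                    elif i0 > ni - 1:
                        snxt[0, 1] += v * w0
                    else:
                        nxt[0, i0] += v * w0
                    if i1 < 0:
                        snxt[0, 0] += v * rr
                    elif i1 > ni - 1:
                        snxt[0, 1] += v * rr
                    else:
                        nxt[0, i1] += v * rr
                    if ngrad != 0:
                        for p in range(NTAN):
                            tv = cur[1 + p, i]
                            e0 = tv * w0 - v * dmu_th[p]
                            e1 = tv * rr + v * dmu_th[p]
                            if i0 < 0:
                                snxt[1 + p, 0] += e0
                            elif i0 > ni - 1:
                                snxt[1 + p, 1] += e0
                            else:
                                nxt[1 + p, i0] += e0
                            if i1 < 0:
                                snxt[1 + p, 0] += e1
                            elif i1 > ni - 1:
                                snxt[1 + p, 1] += e1
                            else:
                                nxt[1 + p, i1] += e1
                pending = s2_tot - rr * w0
                if ngrad != 0:
                    for p in range(NTAN):
                        dpending[p] = ds2_th[p] - (1.0 - 2.0 * rr) * dmu_th[p]
                lo = lo2
                hi = hi2
            tmp = cur
            cur = nxt
            nxt = tmp
            stmp = scur
            scur = snxt
            snxt = stmp
            ic += 1

        if record:
            rec_out[step, 0] = scur[0, 0]
            for i in range(ni):
                rec_out[step, 1 + i] = 0.0
            for i in range(lo, hi + 1):
                rec_out[step, 1 + i] = cur[0, i]
            rec_out[step, ni + 1] = scur[0, 1]

    # ---------------- residual pending variance ----------------
    if not dead and pending > 1.0 / 12.0 + 1e-12:
        omin, nk = _build_kernel(0.0, pending - 1.0 / 12.0, kbuf, dmubuf, ds2buf, maxoff)
        lo2 = lo + omin
        hi2 = hi + omin + nk - 1
        if lo2 < 0:
            lo2 = 0
        if hi2 > ni - 1:
            hi2 = ni - 1
        nsrc = nrow + 1 if ngrad != 0 else nrow
        for r in range(nsrc):
            for i in range(lo2, hi2 + 1):
                nxt[r, i] = 0.0
            snxt[r, 0] = scur[r, 0] if r < nrow else 0.0
            snxt[r, 1] = scur[r, 1] if r < nrow else 0.0
        for r in range(nrow):
            _conv_row(cur[r], nxt[r], snxt, r, lo, hi, ni, kbuf, omin, nk)
        if ngrad != 0:
            _conv_row(cur[0], nxt[nrow], snxt, nrow, lo, hi, ni, ds2buf, omin, nk)
            for p in range(NTAN):
                dp = dpending[p]
                if dp != 0.0:
                    for i in range(lo2, hi2 + 1):
                        nxt[1 + p, i] += dp * nxt[nrow, i]
                    snxt[1 + p, 0] += dp * snxt[nrow, 0]
                    snxt[1 + p, 1] += dp * snxt[nrow, 1]
        lo = lo2
        hi = hi2
        tmp = cur
        cur = nxt
        nxt = tmp
        stmp = scur
        scur = snxt
        snxt = stmp
        if record:
            rec_out[n_steps, 0] = scur[0, 0]
            for i in range(ni):
                rec_out[n_steps, 1 + i] = 0.0
            for i in range(lo, hi + 1):
                rec_out[n_steps, 1 + i] = cur[0, i]
            rec_out[n_steps, ni + 1] = scur[0, 1]

    # ---------------- readout: P(a > thresh) ----------------
    pth = thresh / dx  # threshold in bin units (a = (i - h) * dx)
    p = scur[0, 1]
    s_partial = 0.0
    for i in range(lo, hi + 1):
        frac = (i - h) + 0.5 - pth
        if frac <= 0.0:
            continue
        if frac >= 1.0:
            p += cur[0, i]
        else:
            p += cur[0, i] * frac
            s_partial += cur[0, i]
    for j in range(11):
        grad_out[j] = 0.0
    if ngrad != 0:
        for p_i in range(NTAN):
            gsum = scur[1 + p_i, 1]
            for i in range(lo, hi + 1):
                frac = (i - h) + 0.5 - pth
                if frac <= 0.0:
                    continue
                if frac >= 1.0:
                    gsum += cur[1 + p_i, i]
                else:
                    gsum += cur[1 + p_i, i] * frac
            grad_out[p_i if p_i < 7 else 10] = gsum
        # d frac / dB = +pth/B on partial bins; d frac / d thresh = -1/dx
        grad_out[4] += s_partial * pth / B
        grad_out[7] = -s_partial / dx
    return p


@njit(cache=True)
def fp_dataset(
    ni,
    dt,
    lam,
    s2a,
    s2sI,
    s2sC,
    B,
    phi,
    tau,
    gw,
    thresh,
    n_steps,
    click_ptr,
    click_t,
    click_step,
    click_sign,
    click_ipsi,
    ngrad,
    p_out,
    g_out,
    var_mode,
):
    """Propagate every trial of a packed dataset.

    ``p_out[t]`` receives P(a(T) > thresh) for trial t; when ``ngrad`` is
    nonzero ``g_out[t]`` receives the 11 internal-coordinate partials
    (kappa entries zero; mixed downstream).
    """
    nt = n_steps.shape[0]
    A = np.zeros((NTAN + 3, ni))
    SA = np.zeros((NTAN + 3, 2))
    Bf = np.zeros((NTAN + 3, ni))
    SB = np.zeros((NTAN + 3, 2))
    kbuf = np.zeros(2 * ni + 3)
    dmubuf = np.zeros(2 * ni + 3)
    ds2buf = np.zeros(2 * ni + 3)
    grad = np.zeros(11)
    rec_dummy = np.zeros((1, ni + 2))
    for t in range(nt):
        a0 = click_ptr[t]
        a1 = click_ptr[t + 1]
        p = _fp_trial(
            ni,
            dt,
            n_steps[t],
            lam,
            s2a,
            s2sI,
            s2sC,
            B,
            phi,
            tau,
            gw,
            thresh,
            a1 - a0,
            click_t[a0:a1],
            click_step[a0:a1],
            click_sign[a0:a1],
            click_ipsi[a0:a1],
            ngrad,
            A,
            SA,
            Bf,
            SB,
            kbuf,
            dmubuf,
            ds2buf,
            grad,
            False,
            rec_dummy,
            var_mode,
        )
        p_out[t] = p
        if ngrad != 0:
            for j in range(11):
                g_out[t, j] = grad[j]


@njit(cache=True)
def fp_trial_record(
    ni,
    dt,
    n_steps,
    lam,
    s2a,
    s2sI,
    s2sC,
    B,
    phi,
    tau,
    gw,
    thresh,
    click_t,
    click_step,
    click_sign,
    click_ipsi,
    rec_out,
    var_mode,
):
    """Single-trial propagation recording P(a, t) at every step.

    ``rec_out`` has shape (n_steps+1, ni+2): column 0 holds the -B sticky
    mass, columns 1..ni the interior bins, column ni+1 the +B sticky mass.
    Returns P(a(T) > thresh).
    """
    A = np.zeros((NTAN + 3, ni))
    SA = np.zeros((NTAN + 3, 2))
    Bf = np.zeros((NTAN + 3, ni))
    SB = np.zeros((NTAN + 3, 2))
    kbuf = np.zeros(2 * ni + 3)
    dmubuf = np.zeros(2 * ni + 3)
    ds2buf = np.zeros(2 * ni + 3)
    grad = np.zeros(11)
    return _fp_trial(
        ni,
        dt,
        n_steps,
        lam,
        s2a,
        s2sI,
        s2sC,
        B,
        phi,
        tau,
        gw,
        thresh,
        click_t.shape[0],
        click_t,
        click_step,
        click_sign,
        click_ipsi,
        0,
        A,
        SA,
        Bf,
        SB,
        kbuf,
        dmubuf,
        ds2buf,
        grad,
        True,
        rec_out,
        var_mode,
    )


# ----------------------------------------------------------------------
# Monte Carlo simulator (Euler-Maruyama with exact click times)
# ----------------------------------------------------------------------


@njit(cache=True)
def sim_a_end(
    n_samples,
    duration,
    dt,
    lam,
    sig_a,
    B,
    click_t,
    click_mean,
    click_sd,
    a0,
    seed,
    a_end,
    hit,
):
    """Sample a(T) for one trial.  Clicks are applied at their exact times
    between Euler steps; per-click noise is drawn independently per sample.
    Paths freeze (clamped to +/-B) once |a| >= B."""
    np.random.seed(seed)
    nc = click_t.shape[0]
    n_steps = int(round(duration / dt))
    if n_steps < 1:
        n_steps = 1
    hdt = duration / n_steps
    for s in range(n_samples):
        a = a0
        stuck = False
        if abs(a) >= B:
            a = B if a > 0 else -B
            stuck = True
        ic = 0
        t = 0.0
        for k in range(n_steps):
            t1 = (k + 1) * hdt
            # clicks inside (t, t1]
            while ic < nc and click_t[ic] <= t1 + 1e-12:
                tc = click_t[ic]
                if not stuck:
                    dtt = tc - t
                    if dtt > 0.0:
                        a += lam * a * dtt + sig_a * math.sqrt(dtt) * np.random.normal()
                        if abs(a) >= B:
                            a = B if a > 0 else -B
                            stuck = True
                    if not stuck:
                        a += click_mean[ic] + click_sd[ic] * np.random.normal()
                        if abs(a) >= B:
                            a = B if a > 0 else -B
                            stuck = True
                t = tc if tc > t else t
                ic += 1
            if not stuck and t1 > t:
                dtt = t1 - t
                a += lam * a * dtt + sig_a * math.sqrt(dtt) * np.random.normal()
                if abs(a) >= B:
                    a = B if a > 0 else -B
                    stuck = True
            t = t1
        a_end[s] = a
        hit[s] = stuck


@njit(cache=True)
def sim_paths(
    n_samples,
    duration,
    dt,
    lam,
    sig_a,
    B,
    click_t,
    click_mean,
    click_sd,
    a0,
    seed,
    paths,
    hit,
):
    """Like :func:`sim_a_end` but records a at every step boundary.

    ``paths`` has shape (n_samples, n_steps+1) with n_steps=round(T/dt).
    """
    np.random.seed(seed)
    nc = click_t.shape[0]
    n_steps = paths.shape[1] - 1
    hdt = duration / n_steps
    for s in range(n_samples):
        a = a0
        stuck = False
        if abs(a) >= B:
            a = B if a > 0 else -B
            stuck = True
        paths[s, 0] = a
        ic = 0
        t = 0.0
        for k in range(n_steps):
            t1 = (k + 1) * hdt
            while ic < nc and click_t[ic] <= t1 + 1e-12:
                tc = click_t[ic]
                if not stuck:
                    dtt = tc - t
                    if dtt > 0.0:
                        a += lam * a * dtt + sig_a * math.sqrt(dtt) * np.random.normal()
                        if abs(a) >= B:
                            a = B if a > 0 else -B
                            stuck = True
                    if not stuck:
                        a += click_mean[ic] + click_sd[ic] * np.random.normal()
                        if abs(a) >= B:
                            a = B if a > 0 else -B
                            stuck = True
                t = tc if tc > t else t
                ic += 1
            if not stuck and t1 > t:
                dtt = t1 - t
                a += lam * a * dtt + sig_a * math.sqrt(dtt) * np.random.normal()
                if abs(a) >= B:
                    a = B if a > 0 else -B
                    stuck = True
            t = t1
            paths[s, k + 1] = a
        hit[s] = stuck
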