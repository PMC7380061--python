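"""Compiled integration kernels.

The box and discrete models are integrated by numba-compiled RK4 loops.
The nominal step is the caller's ``dt``; each step is additionally
bounded by (a) positivity — uptake may consume at most half of a
dissolved pool per step, which prevents stepping over a bloom-drawdown
cliff — and (b) stability — the linearised uptake rate constant
(d uptake / d pool, summed over consumers) times the step stays well
inside the RK4 real-axis stability region.  Bloom drawdowns into
oligotrophy are genuinely stiff here (effective rates of order
100 d^-1), so these guards are what keep fixed nominal stepping both
stable and affordable.

Parameter packing (positional layout shared with the wrappers):

``ap``: mu0, alpha_mu, beta_mu, K0_N, alpha_K, K0_fer, alpha_fer,
alpha0_c, alpha_I, Q_min, Q_max.

``ev``: g_max, K_p, gge, unassim, mort_z, mort_p, remin, export,
fe_n_ratio, scavenging, mixing, N_deep, fer_deep, excretion.

``fc``: supply_mean, amplitude, omega, phase, light_mean,
light_amplitude, light_phase, temperature_mean, temperature_amplitude,
fer_supply_mean.

Error codes returned by the kernels: 0 ok, 1 non-finite state (when not
masking), 2 tracer excursion below the instability threshold.
"""

from __future__ import annotations

import numpy as np
from numba import njit

P_FLOOR = 1.0e-6
V_FLOOR = 1.0e-4
DERIV_H = 1.0e-3
INSTAB = -0.1
#: Target for (linearised uptake rate x step): comfortably inside the RK4
#: real-axis stability region (~2.78) with headroom for within-step
#: drawdown of the limiting pool.
LAM_TARGET = 1.2
#: Cliff guard: one step may consume at most this fraction of
#: (pool + half-saturation), so RK4 stage evaluations never reach the
#: Monod pole at pool = -K.  Inactive in the oligotrophic quasi-steady
#: regime, where uptake itself vanishes with the pool.
CLIFF_SAFETY = 0.6
#: Absolute step floor, days.  At an empty pool in quasi-equilibrium the
#: positivity bound becomes arbitrarily small although nothing material
#: happens; below this step the (mass-conserving) clamp absorbs the
#: residual stiff jitter instead.
H_MIN = 1.0e-4
CARBON = 12.0


@njit(cache=True)
def _supply(t, fc):
    return fc[0] * (1.0 + fc[1] * np.sin(fc[2] * t + fc[3]))


@njit(cache=True)
def _fer_supply(t, fc):
    return fc[9] * (1.0 + fc[1] * np.sin(fc[2] * t + fc[3]))


@njit(cache=True)
def _light(t, fc):
    return fc[4] * (1.0 + fc[5] * np.sin(fc[2] * t + fc[3] + fc[6]))


@njit(cache=True)
def _temperature(t, fc):
    return fc[7] + fc[8] * np.sin(fc[2] * t + fc[3] + fc[6])


@njit(cache=True)
def _mu_Q(l, N, fer, I, tf, nlim, ap):
    """Growth rate and quota at trait l with the Liebig branch frozen."""
    mu_m = ap[0] * np.exp(ap[1] * l + ap[2] * l * l) * tf
    if nlim:
        lim = N / (N + ap[3] * np.exp(ap[4] * l))
    else:
        lim = fer / (fer + ap[5] * np.exp(ap[6] * l))
    light = 1.0 - np.exp(-ap[7] * np.exp(ap[8] * l) * I / mu_m)
    mu = mu_m * lim * light
    Q = ap[9] / (1.0 - (1.0 - ap[9] / ap[10]) * lim)
    return mu, Q


@njit(cache=True)
def _profile(lbar, N, fer, I, tf, ap):
    """mu, mu', mu'', mu/Q, (mu/Q)'', Q at lbar (limiter chosen at lbar)."""
    KN = ap[3] * np.exp(ap[4] * lbar)
    KF = ap[5] * np.exp(ap[6] * lbar)
    nlim = N / (N + KN) <= fer / (fer + KF)
    mu_m, Q_m = _mu_Q(lbar - DERIV_H, N, fer, I, tf, nlim, ap)
    mu_0, Q_0 = _mu_Q(lbar, N, fer, I, tf, nlim, ap)
    mu_p, Q_p = _mu_Q(lbar + DERIV_H, N, fer, I, tf, nlim, ap)
    cg_m, cg_0, cg_p = mu_m / Q_m, mu_0 / Q_0, mu_p / Q_p
    mu1 = (mu_p - mu_m) / (2.0 * DERIV_H)
    mu2 = (mu_p - 2.0 * mu_0 + mu_m) / (DERIV_H * DERIV_H)
    cg2 = (cg_p - 2.0 * cg_0 + cg_m) / (DERIV_H * DERIV_H)
    return mu_0, mu1, mu2, cg_0, cg2, Q_0


@njit(cache=True)
def _rhs_box(y, dy, Nsup, fersup, I, tf, ap, ev, u, a_g, fixed_variance):
    m = y.shape[1]
    for j in range(m):
        N = y[0, j]
        P = y[1, j]
        Z = y[2, j]
        D = y[3, j]
        fer = y[4, j]
        DETFe = y[5, j]
        Ps = P if P > P_FLOOR else P_FLOOR
        lbar = y[6, j] / Ps
        v = y[7, j] / Ps - lbar * lbar
        if v < V_FLOOR:
            v = V_FLOOR

        mu, mu1, mu2, cg, cg2, Q = _profile(lbar, N, fer, I, tf, ap)

        mu_com = mu + 0.5 * v * mu2
        uptake = P * mu_com
        G = ev[0] * Z * P * P / (ev[1] * ev[1] + P * P)
        zmort = ev[4] * Z * Z
        pmort = ev[5] * P

        dN = ev[6] * D + ev[13] * G + ev[10] * (Nsup - N) - uptake
        dP = uptake - G - pmort
        dZ = ev[2] * G - zmort
        dD = ev[3] * G + pmort + zmort - (ev[6] + ev[7]) * D
        R = ev[8]
        dfer = (
            ev[6] * DETFe + ev[13] * G * R + ev[10] * (fersup - fer)
            - uptake * R - ev[9] * fer
        )
        dDETFe = (ev[3] * G + pmort + zmort) * R - (ev[6] + ev[7]) * DETFe

        dl = v * mu1
        if fixed_variance:
            dv = 0.0
        else:
            gsp = 0.0 if P <= P_FLOOR else G / Ps
            dv = v * v * mu2 + gsp * v * a_g / (1.0 + a_g) + 2.0 * u * mu

        dy[0, j] = dN
        dy[1, j] = dP
        dy[2, j] = dZ
        dy[3, j] = dD
        dy[4, j] = dfer
        dy[5, j] = dDETFe
        dy[6, j] = dP * lbar + P * dl
        dy[7, j] = dP * (lbar * lbar + v) + P * (2.0 * lbar * dl + dv)
    return dy


@njit(cache=True)
def integrate_box(y, v0, ndays, dt, fixed_variance, mask_on_nan, temp_effect,
                  ap, ev, u, a_g, fc, out, failed):
    """Main box-model loop; fills ``out`` (ndays, 15, m), returns status.

    out channels: 0-7 daily-mean tracers, 8 mean_l, 9 var_v, 10 mu, 11 QN,
    12 NPP, 13 I, 14 d2(mu/Q)/dl2.  Returns (clamp_events, code, err_time).
    """
    m = y.shape[1]
    clamps = 0
    dy1 = np.empty((8, m))
    dy2 = np.empty((8, m))
    dy3 = np.empty((8, m))
    dy4 = np.empty((8, m))
    ytmp = np.empty((8, m))
    acc = np.empty((8, m))

    for day in range(ndays):
        for i in range(8):
            for j in range(m):
                acc[i, j] = 0.0
        t = float(day)
        t_end = day + 1.0
        while t < t_end - 1.0e-9:
            # step bound per column: positivity (no more than half a pool
            # consumed per step) and stability (linearised uptake rate
            # inside the RK4 region)
            h = dt
            for j in range(m):
                if failed[j]:
                    continue
                P = y[1, j]
                if P <= 0.0:
                    continue
                Ps = P if P > P_FLOOR else P_FLOOR
                lbar = y[6, j] / Ps
                mu_m = ap[0] * np.exp(ap[1] * lbar + ap[2] * lbar * lbar)
                flux = P * mu_m
                if flux <= 0.0:
                    continue
                KN = ap[3] * np.exp(ap[4] * lbar)
                N = y[0, j] if y[0, j] > 0.0 else 0.0
                dN = N + KN
                lamN = flux * KN / (dN * dN)
                if lamN * h > LAM_TARGET:
                    h = LAM_TARGET / lamN
                uptN = flux * N / dN
                if uptN > 0.0:
                    hN = CLIFF_SAFETY * dN / uptN
                    if hN < h:
                        h = hN
                if ev[8] > 0.0:
                    KF = ap[5] * np.exp(ap[6] * lbar)
                    fer = y[4, j] if y[4, j] > 0.0 else 0.0
                    fluxF = flux * ev[8]
                    dF = fer + KF
                    lamF = fluxF * KF / (dF * dF)
                    if lamF * h > LAM_TARGET:
                        h = LAM_TARGET / lamF
                    uptF = fluxF * fer / dF
                    if uptF > 0.0:
                        hF = CLIFF_SAFETY * dF / uptF
                        if hF < h:
                            h = hF
            at_floor = False
            if h < H_MIN:
                h = H_MIN
                at_floor = True
            if h > t_end - t:
                h = t_end - t
            half = 0.5 * h
            for i in range(8):
                for j in range(m):
                    acc[i, j] += 0.5 * h * y[i, j]

            tf0 = np.exp(0.063 * (_temperature(t, fc) - 15.0)) if temp_effect else 1.0
            tfh = np.exp(0.063 * (_temperature(t + half, fc) - 15.0)) if temp_effect else 1.0
            tf1 = np.exp(0.063 * (_temperature(t + h, fc) - 15.0)) if temp_effect else 1.0
            _rhs_box(y, dy1, _supply(t, fc), _fer_supply(t, fc), _light(t, fc),
                     tf0, ap, ev, u, a_g, fixed_variance)
            for i in range(8):
                for j in range(m):
                    ytmp[i, j] = y[i, j] + half * dy1[i, j]
            _rhs_box(ytmp, dy2, _supply(t + half, fc), _fer_supply(t + half, fc),
                     _light(t + half, fc), tfh, ap, ev, u, a_g, fixed_variance)
            for i in range(8):
                for j in range(m):
                    ytmp[i, j] = y[i, j] + half * dy2[i, j]
            _rhs_box(ytmp, dy3, _supply(t + half, fc), _fer_supply(t + half, fc),
                     _light(t + half, fc), tfh, ap, ev, u, a_g, fixed_variance)
            for i in range(8):
                for j in range(m):
                    ytmp[i, j] = y[i, j] + h * dy3[i, j]
            _rhs_box(ytmp, dy4, _supply(t + h, fc), _fer_supply(t + h, fc),
                     _light(t + h, fc), tf1, ap, ev, u, a_g, fixed_variance)
            h6 = h / 6.0
            for i in range(8):
                for j in range(m):
                    y[i, j] = y[i, j] + h6 * (
                        dy1[i, j] + 2.0 * dy2[i, j] + 2.0 * dy3[i, j] + dy4[i, j]
                    )
            t = t + h

            # per-column checks, clamping, moment consistency
            for j in range(m):
                if failed[j]:
                    continue
                finite = True
                for i in range(8):
                    if not np.isfinite(y[i, j]):
                        finite = False
                        break
                if not finite:
                    if mask_on_nan:
                        failed[j] = True
                        for i in range(8):
                            y[i, j] = np.nan
                        continue
                    return clamps, 1, t
                if not at_floor:
                    for i in range(6):
                        if y[i, j] < INSTAB:
                            return clamps, 2, t

                # nitrogen pools: clip negatives, charge the largest pool
                deficit = 0.0
                for i in range(4):
                    if y[i, j] < 0.0:
                        deficit += y[i, j]
                        y[i, j] = 0.0
                        clamps += 1
                if deficit < 0.0:
                    big = 0
                    for i in range(1, 4):
                        if y[i, j] > y[big, j]:
                            big = i
                    y[big, j] += deficit
                    if y[big, j] < 0.0:
                        y[big, j] = 0.0
                # iron pools
                if y[4, j] < 0.0:
                    y[5, j] += y[4, j]
                    y[4, j] = 0.0
                    clamps += 1
                    if y[5, j] < 0.0:
                        y[5, j] = 0.0
                if y[5, j] < 0.0:
                    y[4, j] += y[5, j]
                    y[5, j] = 0.0
                    clamps += 1
                    if y[4, j] < 0.0:
                        y[4, j] = 0.0

                # raw-moment consistency; mean trait from pre-floor biomass
                P_pre = y[1, j]
                Ps = P_pre if P_pre > 0.0 else P_FLOOR
                lbar = y[6, j] / Ps
                if fixed_variance:
                    v = v0[j]
                else:
                    v = y[7, j] / Ps - lbar * lbar
                    if v < V_FLOOR:
                        v = V_FLOOR
                if P_pre < P_FLOOR:
                    raise_amt = P_FLOOR - P_pre
                    y[1, j] = P_FLOOR
                    big = 0
                    if y[2, j] > y[big, j]:
                        big = 2
                    if y[3, j] > y[big, j]:
                        big = 3
                    y[big, j] -= raise_amt
                    if y[big, j] < 0.0:
                        y[big, j] = 0.0
                y[6, j] = y[1, j] * lbar
                y[7, j] = y[1, j] * (lbar * lbar + v)

            for i in range(8):
                for j in range(m):
                    acc[i, j] += 0.5 * h * y[i, j]  # trapezoidal daily mean

        # daily diagnostics at the daily-mean state, mid-day forcing
        t_mid = day + 0.5
        I_mid = _light(t_mid, fc)
        tf_mid = np.exp(0.063 * (_temperature(t_mid, fc) - 15.0)) if temp_effect else 1.0
        for j in range(m):
            for i in range(8):
                out[day, i, j] = acc[i, j]
            P = acc[1, j]
            Ps = P if P > P_FLOOR else P_FLOOR
            lbar = acc[6, j] / Ps
            if fixed_variance:
                v = v0[j]
            else:
                v = acc[7, j] / Ps - lbar * lbar
                if v < V_FLOOR:
                    v = V_FLOOR
            mu, mu1, mu2, cg, cg2, Q = _profile(lbar, acc[0, j], acc[4, j], I_mid, tf_mid, ap)
            out[day, 8, j] = lbar
            out[day, 9, j] = v
            out[day, 10, j] = mu
            out[day, 11, j] = Q
            out[day, 12, j] = CARBON * P * (cg + 0.5 * v * cg2)
            out[day, 13, j] = I_mid
            out[day, 14, j] = cg2
    return clamps, 0, -1.0


@njit(cache=True)
def _rhs_discrete(B, pools, dB, dpools, sizes_mu_m, sizes_KN, sizes_KF, sizes_ac,
                  Nsup, fersup, I, ap, ev, a_g):
    m, n = B.shape
    qfac = 1.0 - ap[9] / ap[10]
    for j in range(m):
        N = pools[0, j]
        Z = pools[1, j]
        D = pools[2, j]
        fer = pools[3, j]
        DETFe = pools[4, j]
        uptake = 0.0
        P_tot = 0.0
        wtot = 0.0
        for i in range(n):
            P_tot += B[j, i]
            if B[j, i] > 0.0:
                wtot += B[j, i] ** (1.0 + a_g)
        G = ev[0] * Z * P_tot * P_tot / (ev[1] * ev[1] + P_tot * P_tot)
        pmort = 0.0
        for i in range(n):
            mu_m = sizes_mu_m[j, i]
            limN = N / (N + sizes_KN[j, i])
            limF = fer / (fer + sizes_KF[j, i])
            lim = limN if limN < limF else limF
            light = 1.0 - np.exp(-sizes_ac[j, i] * I / mu_m)
            mu = mu_m * lim * light
            up = B[j, i] * mu
            uptake += up
            g_i = 0.0
            if wtot > 0.0 and B[j, i] > 0.0:
                g_i = G * (B[j, i] ** (1.0 + a_g)) / wtot
            pm = ev[5] * B[j, i]
            pmort += pm
            dB[j, i] = up - g_i - pm
        zmort = ev[4] * Z * Z
        R = ev[8]
        dpools[0, j] = ev[6] * D + ev[13] * G + ev[10] * (Nsup - N) - uptake
        dpools[1, j] = ev[2] * G - zmort
        dpools[2, j] = ev[3] * G + pmort + zmort - (ev[6] + ev[7]) * D
        dpools[3, j] = (
            ev[6] * DETFe + ev[13] * G * R + ev[10] * (fersup - fer)
            - uptake * R - ev[9] * fer
        )
        dpools[4, j] = (ev[3] * G + pmort + zmort) * R - (ev[6] + ev[7]) * DETFe
    return dB, dpools


@njit(cache=True)
def integrate_discrete_core(B, pools, sizes, ndays, dt, mask_on_nan,
                            ap, ev, a_g, fc, out, species_out, record_species,
                            failed):
    """Discrete-model loop; out channels: 0 N, 1 P_tot, 2 Z, 3 D, 4 fer,
    5 DETFe, 6 mean_l, 7 var_v, 8 mu_bar, 9 Q_bar, 10 NPP, 11 I."""
    m, n = B.shape
    mu_m = np.empty((m, n))
    KN = np.empty((m, n))
    KF = np.empty((m, n))
    ac = np.empty((m, n))
    for j in range(m):
        for i in range(n):
            l = sizes[j, i]
            mu_m[j, i] = ap[0] * np.exp(ap[1] * l + ap[2] * l * l)
            KN[j, i] = ap[3] * np.exp(ap[4] * l)
            KF[j, i] = ap[5] * np.exp(ap[6] * l)
            ac[j, i] = ap[7] * np.exp(ap[8] * l)

    dB1 = np.empty((m, n)); dp1 = np.empty((5, m))
    dB2 = np.empty((m, n)); dp2 = np.empty((5, m))
    dB3 = np.empty((m, n)); dp3 = np.empty((5, m))
    dB4 = np.empty((m, n)); dp4 = np.empty((5, m))
    Btmp = np.empty((m, n)); ptmp = np.empty((5, m))
    accB = np.empty((m, n)); accp = np.empty((5, m))
    qfac = 1.0 - ap[9] / ap[10]
    clamps = 0

    for day in range(ndays):
        accB[:] = 0.0
        accp[:] = 0.0
        t = float(day)
        t_end = day + 1.0
        while t < t_end - 1.0e-9:
            # step bound per column (see integrate_box), with uptake and
            # its nutrient derivative summed over species
            h = dt
            for j in range(m):
                if failed[j]:
                    continue
                N = pools[0, j] if pools[0, j] > 0.0 else 0.0
                fer = pools[3, j] if pools[3, j] > 0.0 else 0.0
                uptN = 0.0
                lamN = 0.0
                uptF = 0.0
                lamF = 0.0
                KNmin = 1.0e300
                KFmin = 1.0e300
                for i in range(n):
                    if B[j, i] <= 0.0:
                        continue
                    bf = B[j, i] * mu_m[j, i]
                    dN_i = N + KN[j, i]
                    uptN += bf * N / dN_i
                    lamN += bf * KN[j, i] / (dN_i * dN_i)
                    if KN[j, i] < KNmin:
                        KNmin = KN[j, i]
                    if ev[8] > 0.0:
                        dF_i = fer + KF[j, i]
                        uptF += bf * ev[8] * fer / dF_i
                        lamF += bf * ev[8] * KF[j, i] / (dF_i * dF_i)
                        if KF[j, i] < KFmin:
                            KFmin = KF[j, i]
                if lamN * h > LAM_TARGET:
                    h = LAM_TARGET / lamN
                if uptN > 0.0:
                    hN = CLIFF_SAFETY * (N + KNmin) / uptN
                    if hN < h:
                        h = hN
                if lamF * h > LAM_TARGET:
                    h = LAM_TARGET / lamF
                if uptF > 0.0:
                    hF = CLIFF_SAFETY * (fer + KFmin) / uptF
                    if hF < h:
                        h = hF
            at_floor = False
            if h < H_MIN:
                h = H_MIN
                at_floor = True
            if h > t_end - t:
                h = t_end - t
            half = 0.5 * h
            for j in range(m):
                for i in range(n):
                    accB[j, i] += 0.5 * h * B[j, i]
            for i in range(5):
                for j in range(m):
                    accp[i, j] += 0.5 * h * pools[i, j]

            _rhs_discrete(B, pools, dB1, dp1, mu_m, KN, KF, ac,
                          _supply(t, fc), _fer_supply(t, fc), _light(t, fc), ap, ev, a_g)
            for j in range(m):
                for i in range(n):
                    Btmp[j, i] = B[j, i] + half * dB1[j, i]
            for i in range(5):
                for j in range(m):
                    ptmp[i, j] = pools[i, j] + half * dp1[i, j]
            _rhs_discrete(Btmp, ptmp, dB2, dp2, mu_m, KN, KF, ac,
                          _supply(t + half, fc), _fer_supply(t + half, fc),
                          _light(t + half, fc), ap, ev, a_g)
            for j in range(m):
                for i in range(n):
                    Btmp[j, i] = B[j, i] + half * dB2[j, i]
            for i in range(5):
                for j in range(m):
                    ptmp[i, j] = pools[i, j] + half * dp2[i, j]
            _rhs_discrete(Btmp, ptmp, dB3, dp3, mu_m, KN, KF, ac,
                          _supply(t + half, fc), _fer_supply(t + half, fc),
                          _light(t + half, fc), ap, ev, a_g)
            for j in range(m):
                for i in range(n):
                    Btmp[j, i] = B[j, i] + h * dB3[j, i]
            for i in range(5):
                for j in range(m):
                    ptmp[i, j] = pools[i, j] + h * dp3[i, j]
            _rhs_discrete(Btmp, ptmp, dB4, dp4, mu_m, KN, KF, ac,
                          _supply(t + h, fc), _fer_supply(t + h, fc),
                          _light(t + h, fc), ap, ev, a_g)
            h6 = h / 6.0
            for j in range(m):
                for i in range(n):
                    B[j, i] = B[j, i] + h6 * (
                        dB1[j, i] + 2.0 * dB2[j, i] + 2.0 * dB3[j, i] + dB4[j, i]
                    )
            for i in range(5):
                for j in range(m):
                    pools[i, j] = pools[i, j] + h6 * (
                        dp1[i, j] + 2.0 * dp2[i, j] + 2.0 * dp3[i, j] + dp4[i, j]
                    )
            t = t + h

            for j in range(m):
                if failed[j]:
                    continue
                finite = True
                for i in range(n):
                    if not np.isfinite(B[j, i]):
                        finite = False
                        break
                if finite:
                    for i in range(5):
                        if not np.isfinite(pools[i, j]):
                            finite = False
                            break
                if not finite:
                    if mask_on_nan:
                        failed[j] = True
                        for i in range(n):
                            B[j, i] = np.nan
                        for i in range(5):
                            pools[i, j] = np.nan
                        continue
                    return clamps, 1, t
                if not at_floor:
                    for i in range(5):
                        if pools[i, j] < INSTAB:
                            return clamps, 2, t
                    for i in range(n):
                        if B[j, i] < INSTAB:
                            return clamps, 2, t
                # clamp: negative species biomass charged to dissolved N
                for i in range(n):
                    if B[j, i] < 0.0:
                        pools[0, j] += B[j, i]
                        B[j, i] = 0.0
                        clamps += 1
                # nitrogen pools N, Z, D
                deficit = 0.0
                for i in range(3):
                    if pools[i, j] < 0.0:
                        deficit += pools[i, j]
                        pools[i, j] = 0.0
                        clamps += 1
                if deficit < 0.0:
                    big = 0
                    for i in range(1, 3):
                        if pools[i, j] > pools[big, j]:
                            big = i
                    pools[big, j] += deficit
                    if pools[big, j] < 0.0:
                        pools[big, j] = 0.0
                for i in range(3, 5):
                    if pools[i, j] < 0.0:
                        pools[i, j] = 0.0
                        clamps += 1

            for j in range(m):
                for i in range(n):
                    accB[j, i] += 0.5 * h * B[j, i]
            for i in range(5):
                for j in range(m):
                    accp[i, j] += 0.5 * h * pools[i, j]

        t_mid = day + 0.5
        I_mid = _light(t_mid, fc)
        for j in range(m):
            N = accp[0, j]
            fer = accp[3, j]
            P_tot = 0.0
            m1 = 0.0
            for i in range(n):
                P_tot += accB[j, i]
                m1 += accB[j, i] * sizes[j, i]
            Ps = P_tot if P_tot > P_FLOOR else P_FLOOR
            mean_l = m1 / Ps
            var_v = 0.0
            mu_bar = 0.0
            Q_bar = 0.0
            npp = 0.0
            for i in range(n):
                d = sizes[j, i] - mean_l
                var_v += accB[j, i] * d * d
                limN = N / (N + KN[j, i])
                limF = fer / (fer + KF[j, i])
                lim = limN if limN < limF else limF
                light = 1.0 - np.exp(-ac[j, i] * I_mid / mu_m[j, i])
                mu = mu_m[j, i] * lim * light
                Q = ap[9] / (1.0 - qfac * lim)
                mu_bar += accB[j, i] * mu
                Q_bar += accB[j, i] * Q
                npp += accB[j, i] * mu / Q
            out[day, 0, j] = N
            out[day, 1, j] = P_tot
            out[day, 2, j] = accp[1, j]
            out[day, 3, j] = accp[2, j]
            out[day, 4, j] = fer
            out[day, 5, j] = accp[4, j]
            out[day, 6, j] = mean_l
            out[day, 7, j] = var_v / Ps
            out[day, 8, j] = mu_bar / Ps
            out[day, 9, j] = Q_bar / Ps
            out[day, 10, j] = CARBON * npp
            out[day, 11, j] = I_mid
            if record_species:
                for i in range(n):
                    species_out[day, j, i] = accB[j, i]
    return clamps, 0, -1.0
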