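"""ten Tusscher-Panfilov (2006) human ventricular myocyte model.

Full 19-state formulation with endocardial, midmyocardial (M) and
epicardial variants: fast/late Na+ (m, h, j), L-type Ca2+ with subspace
gating (d, f, f2, fCaSS), transient outward (r, s), rapid and slow delayed
rectifiers (Xr1, Xr2, Xs), inward rectifier, Na+/K+ pump, Na+/Ca2+
exchanger, sarcolemmal Ca2+ pump and background currents, plus CICR
calcium cycling (bulk myoplasm, SR and dyadic subspace with analytic
steady-state buffering).  Cell types differ in IKs and Ito conductances and
the s-gate kinetics; M cells have small IKs, hence the longest APD — the
transmural gradient that shapes the T wave.

Integration is operator-split: Rush-Larsen exponential updates for the 12
Hodgkin-Huxley-type gates and the RyR recovery variable, forward Euler for
voltage and concentrations (dt <= 0.02 ms recommended, <= 0.05 ms with
Rush-Larsen).  Kernels are numba-compiled and shared by the single-cell and
cable drivers.  Drug-induced IKr block is a single multiplier
``gkr_scale`` on the IKr maximal conductance (0.5 = IC50-dose block).

State vector layout (index: variable, units):
0 V [mV]; 1 m; 2 h; 3 j; 4 d; 5 f; 6 f2; 7 fCaSS; 8 r; 9 s; 10 Xr1;
11 Xr2; 12 Xs; 13 Rq (RyR); 14 Cai [mM]; 15 CaSR [mM]; 16 CaSS [mM];
17 Nai [mM]; 18 Ki [mM].
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["N_STATES", "CELL_TYPES", "initial_state", "resting_state",
           "pace_single_cell", "apd90_from_trace", "STIM_AMPLITUDE",
           "STIM_DURATION_MS"]

N_STATES = 19
CELL_TYPES = {"endo": 0, "M": 1, "epi": 2}

#: stimulus convention of the published code: negative = depolarizing
STIM_AMPLITUDE = -52.0  # pA/pF
STIM_DURATION_MS = 1.0

# physical constants
_R, _T, _F = 8314.472, 310.0, 96485.3415
_RTONF = _R * _T / _F
_CAP = 0.185
_Vc, _Vsr, _Vss = 0.016404, 0.001094, 0.00005468
_Ko, _Nao, _Cao = 5.4, 140.0, 2.0
_pKNa = 0.03
_GNa, _GbNa = 14.838, 0.00029
_GCaL, _GbCa = 3.980e-5, 0.000592
_Gkr, _GK1, _GpK = 0.153, 5.405, 0.0146
_knak, _KmK, _KmNa = 2.724, 1.0, 40.0
_knaca, _KmNai, _KmCa, _ksat, _gam = 1000.0, 87.5, 1.38, 0.1, 0.35
_GpCa, _KpCa = 0.1238, 0.0005
_Bufc, _Kbufc = 0.2, 0.001
_Bufsr, _Kbufsr = 10.0, 0.3
_Bufss, _Kbufss = 0.4, 0.00025
_Vmaxup, _Kup = 0.006375, 0.00025
_Vrel, _k1p, _k2p, _k3, _k4 = 0.102, 0.15, 0.045, 0.060, 0.005
_EC, _maxsr, _minsr = 1.5, 2.5, 1.0
_Vleak, _Vxfer = 0.00036, 0.0038

# cell-type conductances: [endo, M, epi]
_GKS = np.array([0.392, 0.098, 0.392])
_GTO = np.array([0.073, 0.294, 0.294])


def initial_state() -> np.ndarray:
    """Published model initial conditions (approximate rest)."""
    y = np.empty(N_STATES)
    y[0] = -86.2
    y[1], y[2], y[3] = 0.0, 0.75, 0.75
    y[4], y[5], y[6], y[7] = 0.0, 1.0, 1.0, 1.0
    y[8], y[9] = 0.0, 1.0
    y[10], y[11], y[12] = 0.0, 1.0, 0.0
    y[13] = 1.0
    y[14], y[15], y[16] = 0.00007, 1.3, 0.00007
    y[17], y[18] = 7.67, 138.3
    return y


@njit(cache=True, fastmath=True)
def _step_cell(y, ctype, dt, istim, gkr_scale, gks, gto):
    """One operator-split step; updates y in place, returns dV/dt [mV/ms]."""
    V = y[0]
    m, h, j = y[1], y[2], y[3]
    d, f, f2, fcass = y[4], y[5], y[6], y[7]
    r, s = y[8], y[9]
    xr1, xr2, xs = y[10], y[11], y[12]
    rq = y[13]
    cai, casr, cass = y[14], y[15], y[16]
    nai, ki = y[17], y[18]

    ek = _RTONF * np.log(_Ko / ki)
    ena = _RTONF * np.log(_Nao / nai)
    eks = _RTONF * np.log((_Ko + _pKNa * _Nao) / (ki + _pKNa * nai))
    eca = 0.5 * _RTONF * np.log(_Cao / cai)

    ak1 = 0.1 / (1.0 + np.exp(0.06 * (V - ek - 200.0)))
    bk1 = (3.0 * np.exp(0.0002 * (V - ek + 100.0))
           + np.exp(0.1 * (V - ek - 10.0))) / (1.0 + np.exp(-0.5 * (V - ek)))
    ik1 = _GK1 * ak1 / (ak1 + bk1) * (V - ek)

    ina = _GNa * m * m * m * h * j * (V - ena)
    vf_rt = V * _F / (_R * _T)

    vm15 = V - 15.0
    expo = np.exp(2.0 * vm15 * _F / (_R * _T))
    if np.abs(vm15) < 1e-6:
        # limit of x/(e^x - 1) as x -> 0
        ical = _GCaL * d * f * f2 * fcass * 2.0 * _F * (0.25 * cass - _Cao)
    else:
        ical = (_GCaL * d * f * f2 * fcass * 4.0 * vm15 * (_F * _F / (_R * _T))
                * (0.25 * expo * cass - _Cao) / (expo - 1.0))

    ito = gto * r * s * (V - ek)
    ikr = gkr_scale * _Gkr * np.sqrt(_Ko / 5.4) * xr1 * xr2 * (V - ek)
    iks = gks * xs * xs * (V - eks)
    inaca = (_knaca
             * (np.exp(_gam * vf_rt) * nai**3 * _Cao
                - np.exp((_gam - 1.0) * vf_rt) * _Nao**3 * cai * 2.5)
             / ((_KmNai**3 + _Nao**3) * (_KmCa + _Cao)
                * (1.0 + _ksat * np.exp((_gam - 1.0) * vf_rt))))
    inak = (_knak * (_Ko / (_Ko + _KmK)) * (nai / (nai + _KmNa))
            / (1.0 + 0.1245 * np.exp(-0.1 * vf_rt) + 0.0353 * np.exp(-vf_rt)))
    ipca = _GpCa * cai / (_KpCa + cai)
    ipk = _GpK * (V - ek) / (1.0 + np.exp((25.0 - V) / 5.98))
    ibna = _GbNa * (V - ena)
    ibca = _GbCa * (V - eca)

    i_ion = (ik1 + ito + ikr + iks + ical + inak + ina + ibna + inaca
             + ibca + ipk + ipca)
    dvdt = -(i_ion + istim)

    # ---- calcium cycling ----
    kcasr = _maxsr - (_maxsr - _minsr) / (1.0 + (_EC / casr) ** 2)
    k1 = _k1p / kcasr
    k2 = _k2p * kcasr
    # RyR recovery variable (linear ODE -> exact exponential update)
    rq_inf = _k4 / (_k4 + k2 * cass)
    tau_rq = 1.0 / (_k4 + k2 * cass)
    y[13] = rq_inf + (rq - rq_inf) * np.exp(-dt / tau_rq)
    so = k1 * cass * cass * rq / (_k3 + k1 * cass * cass)

    irel = _Vrel * so * (casr - cass)
    ileak = _Vleak * (casr - cai)
    iup = _Vmaxup / (1.0 + (_Kup * _Kup) / (cai * cai))
    ixfer = _Vxfer * (cass - cai)

    # analytic steady-state buffering (quadratic update, as published)
    cacsqn = _Bufsr * casr / (casr + _Kbufsr)
    dcasr = dt * (iup - irel - ileak)
    bjsr = _Bufsr - cacsqn - dcasr - casr + _Kbufsr
    cjsr = _Kbufsr * (cacsqn + dcasr + casr)
    y[15] = (np.sqrt(bjsr * bjsr + 4.0 * cjsr) - bjsr) / 2.0

    cassbuf = _Bufss * cass / (cass + _Kbufss)
    dcass = dt * (-ixfer * (_Vc / _Vss) + irel * (_Vsr / _Vss)
                  - ical * _CAP / (2.0 * _Vss * _F))
    bcss = _Bufss - cassbuf - dcass - cass + _Kbufss
    ccss = _Kbufss * (cassbuf + dcass + cass)
    y[16] = (np.sqrt(bcss * bcss + 4.0 * ccss) - bcss) / 2.0

    cabuf = _Bufc * cai / (cai + _Kbufc)
    dcai = dt * (-(ibca + ipca - 2.0 * inaca) * _CAP / (2.0 * _Vc * _F)
                 - (iup - ileak) * (_Vsr / _Vc) + ixfer)
    bc = _Bufc - cabuf - dcai - cai + _Kbufc
    cc = _Kbufc * (cabuf + dcai + cai)
    y[14] = (np.sqrt(bc * bc + 4.0 * cc) - bc) / 2.0

    y[17] = nai + dt * (-(ina + ibna + 3.0 * inak + 3.0 * inaca)
                        * _CAP / (_Vc * _F))
    y[18] = ki + dt * (-(istim + ik1 + ito + ikr + iks - 2.0 * inak + ipk)
                       * _CAP / (_Vc * _F))

    # ---- gates (Rush-Larsen) ----
    m_inf = 1.0 / (1.0 + np.exp((-56.86 - V) / 9.03)) ** 2
    am = 1.0 / (1.0 + np.exp((-60.0 - V) / 5.0))
    bm = 0.1 / (1.0 + np.exp((V + 35.0) / 5.0)) + 0.1 / (1.0 + np.exp((V - 50.0) / 200.0))
    tau_m = am * bm

    h_inf = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    if V >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
    else:
        ah = 0.057 * np.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V)
    tau_h = 1.0 / (ah + bh)

    j_inf = h_inf
    if V >= -40.0:
        aj = 0.0
        bj = 0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
    else:
        aj = ((-2.5428e4 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V))
              * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))))
        bj = 0.02424 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14)))
    tau_j = 1.0 / (aj + bj)

    xr1_inf = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
    tau_xr1 = (450.0 / (1.0 + np.exp((-45.0 - V) / 10.0))
               * 6.0 / (1.0 + np.exp((V + 30.0) / 11.5)))
    xr2_inf = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
    tau_xr2 = (3.0 / (1.0 + np.exp((-60.0 - V) / 20.0))
               * 1.12 / (1.0 + np.exp((V - 60.0) / 20.0)))

    xs_inf = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))
    tau_xs = (1400.0 / np.sqrt(1.0 + np.exp((5.0 - V) / 6.0))
              * 1.0 / (1.0 + np.exp((V - 35.0) / 15.0)) + 80.0)

    r_inf = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
    tau_r = 9.5 * np.exp(-(V + 40.0) ** 2 / 1800.0) + 0.8
    if ctype == 0:  # endo
        s_inf = 1.0 / (1.0 + np.exp((V + 28.0) / 5.0))
        tau_s = 1000.0 * np.exp(-(V + 67.0) ** 2 / 1000.0) + 8.0
    else:  # M and epi share the s gate
        s_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 5.0))
        tau_s = (85.0 * np.exp(-(V + 45.0) ** 2 / 320.0)
                 + 5.0 / (1.0 + np.exp((V - 20.0) / 5.0)) + 3.0)

    d_inf = 1.0 / (1.0 + np.exp((-8.0 - V) / 7.5))
    ad = 1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + np.exp((V + 5.0) / 5.0))
    cd = 1.0 / (1.0 + np.exp((50.0 - V) / 20.0))
    tau_d = ad * bd + cd

    f_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
    tau_f = (1102.5 * np.exp(-((V + 27.0) ** 2) / 225.0)
             + 200.0 / (1.0 + np.exp((13.0 - V) / 10.0))
             + 180.0 / (1.0 + np.exp((V + 30.0) / 10.0)) + 20.0)
    f2_inf = 0.67 / (1.0 + np.exp((V + 35.0) / 7.0)) + 0.33
    tau_f2 = (562.0 * np.exp(-((V + 27.0) ** 2) / 240.0)
              + 31.0 / (1.0 + np.exp((25.0 - V) / 10.0))
              + 80.0 / (1.0 + np.exp((V + 30.0) / 10.0)))
    fcass_inf = 0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4
    tau_fcass = 80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0

    y[1] = m_inf + (m - m_inf) * np.exp(-dt / tau_m)
    y[2] = h_inf + (h - h_inf) * np.exp(-dt / tau_h)
    y[3] = j_inf + (j - j_inf) * np.exp(-dt / tau_j)
    y[4] = d_inf + (d - d_inf) * np.exp(-dt / tau_d)
    y[5] = f_inf + (f - f_inf) * np.exp(-dt / tau_f)
    y[6] = f2_inf + (f2 - f2_inf) * np.exp(-dt / tau_f2)
    y[7] = fcass_inf + (fcass - fcass_inf) * np.exp(-dt / tau_fcass)
    y[8] = r_inf + (r - r_inf) * np.exp(-dt / tau_r)
    y[9] = s_inf + (s - s_inf) * np.exp(-dt / tau_s)
    y[10] = xr1_inf + (xr1 - xr1_inf) * np.exp(-dt / tau_xr1)
    y[11] = xr2_inf + (xr2 - xr2_inf) * np.exp(-dt / tau_xr2)
    y[12] = xs_inf + (xs - xs_inf) * np.exp(-dt / tau_xs)

    return dvdt


@njit(cache=True, fastmath=True)
def _run_single(y, ctype, dt, n_steps, stim_starts, stim_dur, stim_amp,
                gkr_scale, gks, gto, record_stride):
    n_rec = n_steps // record_stride + 1
    v_out = np.empty(n_rec)
    t_out = np.empty(n_rec)
    k_rec = 0
    s_idx = 0
    n_stim = len(stim_starts)
    for k in range(n_steps):
        t = k * dt
        istim = 0.0
        while s_idx < n_stim and t >= stim_starts[s_idx] + stim_dur:
            s_idx += 1
        if s_idx < n_stim and stim_starts[s_idx] <= t < stim_starts[s_idx] + stim_dur:
            istim = stim_amp
        if k % record_stride == 0:
            v_out[k_rec] = y[0]
            t_out[k_rec] = t
            k_rec += 1
        dvdt = _step_cell(y, ctype, dt, istim, gkr_scale, gks, gto)
        y[0] += dt * dvdt
    return t_out[:k_rec], v_out[:k_rec]


def pace_single_cell(cell_type: str = "epi", cl_ms: float = 1000.0,
                     n_beats: int = 50, dt: float = 0.02,
                     gkr_scale: float = 1.0, y0: np.ndarray | None = None,
                     record_ms: float = 0.5, record_last: int = 2):
    """Pace one myocyte at a fixed cycle length; return the last beats.

    Returns ``(t_ms, v_mV, y_final)`` where the trace covers the final
    ``record_last`` beats (time restarts at 0 at the first recorded
    stimulus) sampled every ``record_ms``.
    """
    if gkr_scale <= 0 or gkr_scale > 1:
        raise ValueError("gkr_scale must be in (0, 1]")
    ct = CELL_TYPES[cell_type]
    y = initial_state() if y0 is None else y0.copy()
    gks, gto = _GKS[ct], _GTO[ct]
    stride = max(1, int(round(record_ms / dt)))

    n_pre = max(0, n_beats - record_last)
    if n_pre:
        steps = int(round(n_pre * cl_ms / dt))
        starts = np.arange(n_pre) * cl_ms
        _run_single(y, ct, dt, steps, starts, STIM_DURATION_MS,
                    STIM_AMPLITUDE, gkr_scale, gks, gto, steps + 1)
    steps = int(round(record_last * cl_ms / dt))
    starts = np.arange(record_last) * cl_ms
    t, v = _run_single(y, ct, dt, steps, starts, STIM_DURATION_MS,
                       STIM_AMPLITUDE, gkr_scale, gks, gto, stride)
    _check_physiological(v)
    return t, v, y


def _check_physiological(v: np.ndarray) -> None:
    if not np.all(np.isfinite(v)) or v.min() < -100.0 or v.max() > 60.0:
        raise FloatingPointError(
            f"membrane potential left physiological bounds "
            f"([{v.min():.1f}, {v.max():.1f}] mV): integration failure")


def apd90_from_trace(t_ms: np.ndarray, v: np.ndarray,
                     stim_time_ms: float = 0.0) -> float:
    """APD90 of the beat launched at ``stim_time_ms``.

    Activation is the maximal dV/dt after the stimulus; APD90 ends where V
    falls below rest + 10 % of the amplitude (linear interpolation between
    samples).  Rest is the potential just before the stimulus.
    """
    t_ms = np.asarray(t_ms, float)
    v = np.asarray(v, float)
    pre = v[t_ms <= stim_time_ms]
    v_rest = pre[-1] if len(pre) else v[0]
    sel = t_ms >= stim_time_ms
    ts, vs = t_ms[sel], v[sel]
    if len(ts) < 5:
        return np.nan
    dv = np.gradient(vs, ts)
    up_idx = int(np.argmax(dv))
    v_peak = float(np.max(vs[up_idx:]))
    v90 = v_peak - 0.9 * (v_peak - v_rest)
    below = np.where(vs[up_idx:] < v90)[0]
    # first downward crossing after the peak
    peak_idx = up_idx + int(np.argmax(vs[up_idx:]))
    below = below[below + up_idx > peak_idx]
    if len(below) == 0:
        return np.nan
    i1 = up_idx + below[0]
    i0 = i1 - 1
    if vs[i0] == vs[i1]:
        t_cross = ts[i1]
    else:
        t_cross = ts[i0] + (vs[i0] - v90) / (vs[i0] - vs[i1]) * (ts[i1] - ts[i0])
    return float(t_cross - ts[up_idx])


def resting_state(cell_type: str = "epi", settle_s: float = 100.0,
                  dt: float = 0.02) -> np.ndarray:
    """Equilibrate the unstimulated model and return the settled state."""
    ct = CELL_TYPES[cell_type]
    y = initial_state()
    steps = int(round(settle_s * 1000.0 / dt))
    _run_single(y, ct, dt, steps, np.empty(0), STIM_DURATION_MS, 0.0,
                1.0, _GKS[ct], _GTO[ct], steps + 1)
    return y
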