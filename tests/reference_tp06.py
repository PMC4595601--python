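"""Independent reference implementation of the 2006 human ventricular
myocyte model (ten Tusscher & Panfilov), used only as a test oracle.

Deliberately a second, separate transcription of the published equations:
plain-Python right-hand side in a different state ordering and algebraic
arrangement than the package kernel, integrated with an adaptive implicit
solver (LSODA via scipy.solve_ivp) instead of fixed-step Rush-Larsen.
Agreement between the two routes checks both the equation transcription
and the integrator.
"""

import numpy as np
from scipy.integrate import solve_ivp

R_GAS, TEMP, FARADAY = 8314.472, 310.0, 96485.3415
RTF = R_GAS * TEMP / FARADAY
CM = 0.185
V_CYT, V_SR, V_SS = 0.016404, 0.001094, 0.00005468
KO, NAO, CAO = 5.4, 140.0, 2.0

# state order (differs from the package kernel on purpose):
# [V, Nai, Ki, Cai, CaSR, CaSS, Rq, m, h, j, d, f, f2, fcass, r, s, xr1, xr2, xs]
Y0 = np.array([-86.2, 7.67, 138.3, 0.00007, 1.3, 0.00007, 1.0,
               0.0, 0.75, 0.75, 0.0, 1.0, 1.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0])

PARAMS = {
    "endo": dict(g_ks=0.392, g_to=0.073, s_endo=True),
    "M": dict(g_ks=0.098, g_to=0.294, s_endo=False),
    "epi": dict(g_ks=0.392, g_to=0.294, s_endo=False),
}


def rhs(t, y, cell, gkr_scale=1.0, i_stim=0.0):
    (v, nai, ki, cai, casr, cass, rq,
     m, h, jj, d, f, f2, fcass, r, s, xr1, xr2, xs) = y
    p = PARAMS[cell]

    e_na = RTF * np.log(NAO / nai)
    e_k = RTF * np.log(KO / ki)
    e_ks = RTF * np.log((KO + 0.03 * NAO) / (ki + 0.03 * nai))
    e_ca = 0.5 * RTF * np.log(CAO / cai)

    i_na = 14.838 * m**3 * h * jj * (v - e_na)
    i_bna = 0.00029 * (v - e_na)

    x = 2.0 * (v - 15.0) / RTF
    if abs(x) < 1e-7:
        drive = FARADAY * (0.25 * cass - CAO) * (1.0 + x / 2.0)
    else:
        drive = FARADAY * x * (0.25 * cass * np.exp(x) - CAO) / (np.exp(x) - 1.0)
    i_cal = 3.980e-5 * d * f * f2 * fcass * 2.0 * drive

    i_to = p["g_to"] * r * s * (v - e_k)
    i_kr = gkr_scale * 0.153 * np.sqrt(KO / 5.4) * xr1 * xr2 * (v - e_k)
    i_ks = p["g_ks"] * xs**2 * (v - e_ks)

    a1 = 0.1 / (1.0 + np.exp(0.06 * (v - e_k - 200.0)))
    b1 = (3.0 * np.exp(0.0002 * (v - e_k + 100.0)) + np.exp(0.1 * (v - e_k - 10.0))) \
        / (1.0 + np.exp(-0.5 * (v - e_k)))
    i_k1 = 5.405 * (a1 / (a1 + b1)) * (v - e_k)

    i_nak = 2.724 * KO * nai / ((KO + 1.0) * (nai + 40.0)) \
        / (1.0 + 0.1245 * np.exp(-0.1 * v / RTF) + 0.0353 * np.exp(-v / RTF))
    e1 = np.exp(0.35 * v / RTF)
    e2 = np.exp(-0.65 * v / RTF)
    i_naca = 1000.0 * (e1 * nai**3 * CAO - e2 * NAO**3 * cai * 2.5) \
        / ((87.5**3 + NAO**3) * (1.38 + CAO) * (1.0 + 0.1 * e2))
    i_pca = 0.1238 * cai / (cai + 0.0005)
    i_pk = 0.0146 * (v - e_k) / (1.0 + np.exp((25.0 - v) / 5.98))
    i_bca = 0.000592 * (v - e_ca)

    dv = -(i_na + i_bna + i_cal + i_to + i_kr + i_ks + i_k1 + i_nak
           + i_naca + i_pca + i_pk + i_bca + i_stim)

    # calcium handling
    k_casr = 2.5 - 1.5 / (1.0 + (1.5 / casr)**2)
    o_rel = (0.15 / k_casr) * cass**2 * rq / (0.060 + (0.15 / k_casr) * cass**2)
    j_rel = 0.102 * o_rel * (casr - cass)
    j_leak = 0.00036 * (casr - cai)
    j_up = 0.006375 / (1.0 + (0.00025 / cai)**2)
    j_xfer = 0.0038 * (cass - cai)
    d_rq = 0.005 * (1.0 - rq) - 0.045 * k_casr * cass * rq

    buf_c = 1.0 / (1.0 + 0.2 * 0.001 / (cai + 0.001)**2)
    buf_sr = 1.0 / (1.0 + 10.0 * 0.3 / (casr + 0.3)**2)
    buf_ss = 1.0 / (1.0 + 0.4 * 0.00025 / (cass + 0.00025)**2)
    d_cai = buf_c * (-(i_bca + i_pca - 2.0 * i_naca) * CM / (2.0 * V_CYT * FARADAY)
                     - (j_up - j_leak) * V_SR / V_CYT + j_xfer)
    d_casr = buf_sr * (j_up - j_rel - j_leak)
    d_cass = buf_ss * (-j_xfer * V_CYT / V_SS + j_rel * V_SR / V_SS
                       - i_cal * CM / (2.0 * V_SS * FARADAY))

    d_nai = -(i_na + i_bna + 3.0 * i_nak + 3.0 * i_naca) * CM / (V_CYT * FARADAY)
    d_ki = -(i_stim + i_k1 + i_to + i_kr + i_ks - 2.0 * i_nak + i_pk) \
        * CM / (V_CYT * FARADAY)

    # gating kinetics
    def gate(inf, tau, g):
        return (inf - g) / tau

    m_inf = (1.0 + np.exp((-56.86 - v) / 9.03))**-2
    tau_m = (1.0 / (1.0 + np.exp((-60.0 - v) / 5.0))) \
        * (0.1 / (1.0 + np.exp((v + 35.0) / 5.0))
           + 0.1 / (1.0 + np.exp((v - 50.0) / 200.0)))

    h_inf = (1.0 + np.exp((v + 71.55) / 7.43))**-2
    if v >= -40.0:
        tau_h = 1.0 / (0.77 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1))))
    else:
        tau_h = 1.0 / (0.057 * np.exp(-(v + 80.0) / 6.8)
                       + 2.7 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.3485 * v))
    j_inf = h_inf
    if v >= -40.0:
        tau_j = 1.0 / (0.6 * np.exp(0.057 * v) / (1.0 + np.exp(-0.1 * (v + 32.0))))
    else:
        a_j = ((-2.5428e4 * np.exp(0.2444 * v) - 6.948e-6 * np.exp(-0.04391 * v))
               * (v + 37.78) / (1.0 + np.exp(0.311 * (v + 79.23))))
        b_j = 0.02424 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14)))
        tau_j = 1.0 / (a_j + b_j)

    d_inf = 1.0 / (1.0 + np.exp((-8.0 - v) / 7.5))
    tau_d = (1.4 / (1.0 + np.exp((-35.0 - v) / 13.0)) + 0.25) \
        * (1.4 / (1.0 + np.exp((v + 5.0) / 5.0))) \
        + 1.0 / (1.0 + np.exp((50.0 - v) / 20.0))
    f_inf = 1.0 / (1.0 + np.exp((v + 20.0) / 7.0))
    tau_f = (1102.5 * np.exp(-(v + 27.0)**2 / 225.0)
             + 200.0 / (1.0 + np.exp((13.0 - v) / 10.0))
             + 180.0 / (1.0 + np.exp((v + 30.0) / 10.0)) + 20.0)
    f2_inf = 0.67 / (1.0 + np.exp((v + 35.0) / 7.0)) + 0.33
    tau_f2 = (562.0 * np.exp(-(v + 27.0)**2 / 240.0)
              + 31.0 / (1.0 + np.exp((25.0 - v) / 10.0))
              + 80.0 / (1.0 + np.exp((v + 30.0) / 10.0)))
    fcass_inf = 0.6 / (1.0 + (cass / 0.05)**2) + 0.4
    tau_fcass = 80.0 / (1.0 + (cass / 0.05)**2) + 2.0

    r_inf = 1.0 / (1.0 + np.exp((20.0 - v) / 6.0))
    tau_r = 9.5 * np.exp(-(v + 40.0)**2 / 1800.0) + 0.8
    if p["s_endo"]:
        s_inf = 1.0 / (1.0 + np.exp((v + 28.0) / 5.0))
        tau_s = 1000.0 * np.exp(-(v + 67.0)**2 / 1000.0) + 8.0
    else:
        s_inf = 1.0 / (1.0 + np.exp((v + 20.0) / 5.0))
        tau_s = (85.0 * np.exp(-(v + 45.0)**2 / 320.0)
                 + 5.0 / (1.0 + np.exp((v - 20.0) / 5.0)) + 3.0)

    xr1_inf = 1.0 / (1.0 + np.exp((-26.0 - v) / 7.0))
    tau_xr1 = (450.0 / (1.0 + np.exp((-45.0 - v) / 10.0))) \
        * (6.0 / (1.0 + np.exp((v + 30.0) / 11.5)))
    xr2_inf = 1.0 / (1.0 + np.exp((v + 88.0) / 24.0))
    tau_xr2 = (3.0 / (1.0 + np.exp((-60.0 - v) / 20.0))) \
        * (1.12 / (1.0 + np.exp((v - 60.0) / 20.0)))
    xs_inf = 1.0 / (1.0 + np.exp((-5.0 - v) / 14.0))
    tau_xs = (1400.0 / np.sqrt(1.0 + np.exp((5.0 - v) / 6.0))) \
        * (1.0 / (1.0 + np.exp((v - 35.0) / 15.0))) + 80.0

    return np.array([
        dv, d_nai, d_ki, d_cai, d_casr, d_cass, d_rq,
        gate(m_inf, tau_m, m), gate(h_inf, tau_h, h), gate(j_inf, tau_j, jj),
        gate(d_inf, tau_d, d), gate(f_inf, tau_f, f), gate(f2_inf, tau_f2, f2),
        gate(fcass_inf, tau_fcass, fcass), gate(r_inf, tau_r, r),
        gate(s_inf, tau_s, s), gate(xr1_inf, tau_xr1, xr1),
        gate(xr2_inf, tau_xr2, xr2), gate(xs_inf, tau_xs, xs),
    ])


def pace_reference(cell="epi", cl_ms=1000.0, n_beats=8, stim_amp=-52.0,
                   stim_dur=1.0, gkr_scale=1.0, rtol=1e-6, atol=1e-8):
    """Pace the reference model; return (t_ms, v_mV) of the final beat.

    Integrates each stimulus-on and stimulus-off window separately so the
    discontinuous stimulus never crosses a solver step boundary unnoticed.
    """
    y = Y0.copy()
    t_out, v_out = [], []
    for beat in range(n_beats):
        last = beat == n_beats - 1
        sol = solve_ivp(rhs, (0.0, stim_dur), y, args=(cell, gkr_scale, stim_amp),
                        method="LSODA", rtol=rtol, atol=atol, max_step=0.5,
                        dense_output=False,
                        t_eval=np.arange(0.0, stim_dur, 0.25) if last else None)
        y = sol.y[:, -1]
        if last:
            t_out.append(sol.t)
            v_out.append(sol.y[0])
        sol = solve_ivp(rhs, (stim_dur, cl_ms), y, args=(cell, gkr_scale, 0.0),
                        method="LSODA", rtol=rtol, atol=atol,
                        t_eval=np.arange(stim_dur, cl_ms, 0.25) if last else None)
        y = sol.y[:, -1]
        if last:
            t_out.append(sol.t)
            v_out.append(sol.y[0])
    return np.concatenate(t_out), np.concatenate(v_out)
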