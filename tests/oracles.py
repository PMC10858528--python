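"""Independent closed-form oracles used by the tests.

These recompute expected results by routes that do not share code with the
package: one-cycle transition matrices assembled directly from exponential
rates and advanced by matrix powers, and quadrature over hazard functions.
"""

import numpy as np


def stm3_matrix_power(rate_ttnt, rate_dpf, rate_dpp, T, c):
    """Occupancy of the time-homogeneous three-state chain implied by
    exponential driving curves, via matrix powers of the one-cycle matrix."""
    q_tot = 1.0 - np.exp(-rate_ttnt * c)
    q_d = 1.0 - np.exp(-rate_dpf * c)
    tp1 = max(q_tot - q_d, 0.0)
    q3 = 1.0 - np.exp(-rate_dpp * c)
    P = np.array(
        [
            [1.0 - tp1 - q_d, tp1, q_d],
            [0.0, 1.0 - q3, q3],
            [0.0, 0.0, 1.0],
        ]
    )
    occ = np.zeros((T + 1, 3))
    v = np.array([1.0, 0.0, 0.0])
    for k in range(T + 1):
        occ[k] = v
        v = v @ P
    return occ


def stm5_matrix_power(rates, f, T, c):
    """Five-state analogue.  ``rates`` maps the eight curve names to
    exponential rates.  The competing-exit algebra is written out directly
    from the rates (for exponentials the cause-specific cycle hazard is
    exactly rate x cycle, so the hazard-split allocation is proportional to
    the rates themselves)."""
    q_nt = 1.0 - np.exp(-rates["ttnt_from_pf"] * c)
    q_d = 1.0 - np.exp(-rates["death_from_pf"] * c)
    q_bm = 1.0 - np.exp(-rates["bm_from_pf"] * c)
    q_eff = max(q_nt, q_d)
    lam_nt = -np.log1p(-q_eff)
    lam_bm = -np.log1p(-q_bm)
    if lam_nt + lam_bm > 0 and lam_bm > 0:
        q_total = 1.0 - np.exp(-(lam_nt + lam_bm))
        Q_nt = q_total * lam_nt / (lam_nt + lam_bm)
        Q_bm = q_total * lam_bm / (lam_nt + lam_bm)
    else:
        Q_nt, Q_bm = q_eff, q_bm
    if q_eff > 0:
        Q_pf_d = Q_nt * q_d / q_eff
        Q_pf_pp = Q_nt * max(q_nt - q_d, 0.0) / q_eff
    else:
        Q_pf_d = Q_pf_pp = 0.0

    r3, r5 = rates["death_from_pp"], rates["bm_from_pp"]
    tot = 1.0 - np.exp(-(r3 + r5) * c)
    Q_pp_d = tot * r3 / (r3 + r5) if r3 + r5 > 0 else 0.0
    Q_pp_bm = tot * r5 / (r3 + r5) if r3 + r5 > 0 else 0.0

    q_ntb = 1.0 - np.exp(-rates["ttnt_in_bmit"] * c)
    q7 = 1.0 - np.exp(-rates["death_in_bmit"] * c)
    Q_bmit_sw = max(q_ntb - q7, 0.0)
    Q_bmit_d = q7

    Q_bmst_d = 1.0 - np.exp(-rates["death_in_bmst"] * c)

    # states: PF, PP, BMIT, BMST, Death
    P = np.array(
        [
            [1 - Q_pf_pp - Q_bm - Q_pf_d, Q_pf_pp, Q_bm, 0.0, Q_pf_d],
            [0.0, 1 - Q_pp_bm - Q_pp_d, 0.0, Q_pp_bm, Q_pp_d],
            [0.0, 0.0, 1 - Q_bmit_sw - Q_bmit_d, Q_bmit_sw, Q_bmit_d],
            [0.0, 0.0, 0.0, 1 - Q_bmst_d, Q_bmst_d],
            [0.0, 0.0, 0.0, 0.0, 1.0],
        ]
    )
    occ = np.zeros((T + 1, 5))
    v = np.array([1.0 - f, 0.0, f, 0.0, 0.0])
    for k in range(T + 1):
        occ[k] = v
        v = v @ P
    return occ


def exit_probability_by_quadrature(hazard, t, c):
    """1 - exp(-integral of the hazard over (t, t+c)) by adaptive quadrature."""
    from scipy.integrate import quad

    integral, _ = quad(hazard, t, t + c, epsabs=1e-13, epsrel=1e-13)
    return 1.0 - np.exp(-integral)
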