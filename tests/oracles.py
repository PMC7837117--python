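"""Independent reference implementations used as oracles in the tests.

These are deliberately literal, scalar, step-by-step translations of the
model update rules and decision rule, kept free of any code from the package
(no numba, no vectorisation) so that agreement with the package is a genuine
two-route check.
"""

import math


def oracle_session_loglik(p: dict, choices, seconds, outcomes) -> float:
    """Literal trial-by-trial evaluation of the RL mixture model likelihood.

    ``p`` maps parameter names (alpha_Q, f_Q, lam, alpha_T, f_T, alpha_c,
    alpha_m, G_mf, G_mo, G_mb, B_c, B_r, P_c, P_m) to floats.  Choices are
    coded 1 = top / 0 = bottom, second steps 1 = left / 0 = right.
    """
    Q_mf = {0: 0.5, 1: 0.5}
    V = {0: 0.5, 1: 0.5}
    P = {(1, 1): 0.5, (0, 1): 0.5, (1, 0): 0.5, (0, 0): 0.5}  # P[(s, c)]
    Q_mo = {(c, sp): 0.5 for c in (0, 1) for sp in (0, 1)}
    c_bar = 0.0
    m_bar = {0: 0.0, 1: 0.0}
    s_prev = None

    loglik = 0.0
    for c, s, r in zip(choices, seconds, outcomes):
        # model-based values: Q_mb(c) = sum_s P(s|c) V(s)
        Q_mb = {cc: P[(1, cc)] * V[1] + P[(0, cc)] * V[0] for cc in (0, 1)}
        # net values and bias/perseveration offset (top only)
        X_top = p["B_c"] + p["P_c"] * c_bar
        Q_net = {}
        for cc in (0, 1):
            Q_net[cc] = p["G_mf"] * Q_mf[cc] + p["G_mb"] * Q_mb[cc]
        if s_prev is not None:
            X_top += p["B_r"] * (s_prev - 0.5) + p["P_m"] * m_bar[s_prev]
            for cc in (0, 1):
                Q_net[cc] += p["G_mo"] * Q_mo[(cc, s_prev)]
        Q_net[1] += X_top
        # softmax
        denom = math.exp(Q_net[0]) + math.exp(Q_net[1])
        loglik += math.log(math.exp(Q_net[c]) / denom)

        # updates
        target = p["lam"] * r + (1 - p["lam"]) * V[s]
        Q_mf[c] = (1 - p["alpha_Q"]) * Q_mf[c] + p["alpha_Q"] * target
        V[s] = (1 - p["alpha_Q"]) * V[s] + p["alpha_Q"] * r
        Q_mf[1 - c] = (1 - p["f_Q"]) * Q_mf[1 - c]
        V[1 - s] = (1 - p["f_Q"]) * V[1 - s]

        P[(s, c)] = (1 - p["alpha_T"]) * P[(s, c)] + p["alpha_T"]
        P[(1 - s, c)] = (1 - p["alpha_T"]) * P[(1 - s, c)]
        for ss in (0, 1):
            P[(ss, 1 - c)] = (1 - p["f_T"]) * P[(ss, 1 - c)] + 0.5 * p["f_T"]

        if s_prev is not None:
            Q_mo[(c, s_prev)] = ((1 - p["alpha_Q"]) * Q_mo[(c, s_prev)]
                                 + p["alpha_Q"] * target)
            for key in Q_mo:
                if key != (c, s_prev):
                    Q_mo[key] = (1 - p["f_Q"]) * Q_mo[key]

        c_bar = (1 - p["alpha_c"]) * c_bar + p["alpha_c"] * (c - 0.5)
        if s_prev is not None:
            m_bar[s_prev] = ((1 - p["alpha_m"]) * m_bar[s_prev]
                             + p["alpha_m"] * (c - 0.5))
        s_prev = s
    return loglik


def oracle_rescorla_wagner(alpha, choices, outcomes):
    """First-step Rescorla-Wagner values (no forgetting, lambda = 1)."""
    q = {0: 0.5, 1: 0.5}
    history = []
    for c, r in zip(choices, outcomes):
        q[c] = q[c] + alpha * (r - q[c])
        history.append(dict(q))
    return history
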