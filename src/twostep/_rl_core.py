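"""Numba kernels for the reinforcement-learning model likelihood.

The forward pass evolves the agent's latent variables trial by trial from the
observed (choice, second step, outcome) sequence and accumulates the softmax
log-likelihood of the observed choices.  The parameter vector is the full
14-parameter model in natural space, ordered as in
:data:`twostep.agents.PARAM_NAMES`; component models are evaluated through the
same kernel with masked (fixed) parameters.
"""

import numpy as np
from numba import njit

# Parameter vector layout (natural space).
I_ALPHA_Q, I_F_Q, I_LAM, I_ALPHA_T, I_F_T, I_ALPHA_C, I_ALPHA_M = 0, 1, 2, 3, 4, 5, 6
I_G_MF, I_G_MO, I_G_MB, I_B_C, I_B_R, I_P_C, I_P_M = 7, 8, 9, 10, 11, 12, 13
N_PARAMS = 14


@njit(cache=True)
def _softplus(x):
    # log(1 + exp(x)), overflow safe
    if x > 35.0:
        return x
    if x < -35.0:
        return np.exp(x)
    return np.log1p(np.exp(x))


@njit(cache=True)
def rl_loglik(theta, choices, seconds, outcomes):
    """Log-likelihood of one session's choices under the RL model.

    choices: 1 = top, 0 = bottom; seconds: 1 = left, 0 = right; outcomes 0/1.
    """
    a_q = theta[I_ALPHA_Q]
    f_q = theta[I_F_Q]
    lam = theta[I_LAM]
    a_t = theta[I_ALPHA_T]
    f_t = theta[I_F_T]
    a_c = theta[I_ALPHA_C]
    a_m = theta[I_ALPHA_M]
    g_mf = theta[I_G_MF]
    g_mo = theta[I_G_MO]
    g_mb = theta[I_G_MB]
    b_c = theta[I_B_C]
    b_r = theta[I_B_R]
    p_c = theta[I_P_C]
    p_m = theta[I_P_M]

    q_mf = np.full(2, 0.5)          # indexed by choice
    v = np.full(2, 0.5)             # indexed by second-step state
    p_left = np.full(2, 0.5)        # P(left | choice)
    q_mo = np.full((2, 2), 0.5)     # [choice, previous second step]
    c_bar = 0.0
    m_bar = np.zeros(2)             # indexed by previous second step
    s_prev = -1

    loglik = 0.0
    n = choices.shape[0]
    for t in range(n):
        c = choices[t]
        s = seconds[t]
        r = outcomes[t]

        # Net action values: Q_net(c) = Gmf Qmf + Gmo Qmo + Gmb Qmb + X(c)
        q_mb_top = p_left[1] * v[1] + (1.0 - p_left[1]) * v[0]
        q_mb_bot = p_left[0] * v[1] + (1.0 - p_left[0]) * v[0]
        q_top = g_mf * q_mf[1] + g_mb * q_mb_top + b_c + p_c * c_bar
        q_bot = g_mf * q_mf[0] + g_mb * q_mb_bot
        if s_prev >= 0:
            q_top += g_mo * q_mo[1, s_prev] + b_r * (s_prev - 0.5) + p_m * m_bar[s_prev]
            q_bot += g_mo * q_mo[0, s_prev]
        d = q_top - q_bot
        if c == 1:
            loglik -= _softplus(-d)
        else:
            loglik -= _softplus(d)

        # Value updates (second-step value read before its own update).
        v_s = v[s]
        target = lam * r + (1.0 - lam) * v_s
        q_mf[c] = (1.0 - a_q) * q_mf[c] + a_q * target
        v[s] = (1.0 - a_q) * v_s + a_q * r
        q_mf[1 - c] *= (1.0 - f_q)
        v[1 - s] *= (1.0 - f_q)

        # Transition-probability updates; P(left|c) + P(right|c) = 1 by construction.
        if s == 1:
            p_left[c] = (1.0 - a_t) * p_left[c] + a_t
        else:
            p_left[c] = (1.0 - a_t) * p_left[c]
        p_left[1 - c] = (1.0 - f_t) * p_left[1 - c] + 0.5 * f_t

        # Motor-level values: update the taken (choice, previous-state) entry,
        # decay all others.  No motor action exists on the first trial.
        if s_prev >= 0:
            for cc in range(2):
                for ss in range(2):
                    if cc == c and ss == s_prev:
                        q_mo[cc, ss] = (1.0 - a_q) * q_mo[cc, ss] + a_q * target
                    else:
                        q_mo[cc, ss] *= (1.0 - f_q)

        # Perseveration histories.
        c_bar = (1.0 - a_c) * c_bar + a_c * (c - 0.5)
        if s_prev >= 0:
            m_bar[s_prev] = (1.0 - a_m) * m_bar[s_prev] + a_m * (c - 0.5)

        s_prev = s
    return loglik


@njit(cache=True)
def rl_loglik_batch(thetas, choices, seconds, outcomes):
    """Evaluate ``rl_loglik`` for a batch of parameter vectors (B, 14)."""
    n = thetas.shape[0]
    out = np.empty(n)
    for i in range(n):
        out[i] = rl_loglik(thetas[i], choices, seconds, outcomes)
    return out


@njit(cache=True)
def rl_loglik_multisession(theta, choices, seconds, outcomes, starts):
    """Summed log-likelihood over concatenated sessions.

    ``starts`` holds session start offsets plus the total length as the final
    entry; agent state is re-initialised at each session boundary.
    """
    total = 0.0
    for k in range(starts.shape[0] - 1):
        a, b = starts[k], starts[k + 1]
        total += rl_loglik(theta, choices[a:b], seconds[a:b], outcomes[a:b])
    return total


@njit(cache=True)
def rl_loglik_multisession_batch(thetas, choices, seconds, outcomes, starts):
    n = thetas.shape[0]
    out = np.empty(n)
    for i in range(n):
        out[i] = rl_loglik_multisession(thetas[i], choices, seconds, outcomes, starts)
    return out
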