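"""Compiled trial-replay likelihood kernels.

The hierarchical EM fit and the Monte-Carlo integrated-BIC estimator both
replay every session thousands to hundreds of thousands of times with
different parameter vectors.  The replay itself is a tight sequential loop
over trials (each trial's Q-update depends on the previous one), so it is
implemented here as numba-compiled kernels operating on integer-coded
session arrays.  `rl_models.session_nll` is a thin wrapper; the pure-Python
operations in `rl_models` (`action_probabilities`, `apply_update`) define
the same model and serve as an independent replay route in the test suite.

Session coding: stimulus in {0, 1}; action in {0 hand, 1 foot, -1 none};
reward in {0, 1, -1 NA}.  Parameter row layout (natural space):
[alpha_pos, alpha_neg, beta, bias, lapse, decay, perseverance].
"""

import numpy as np
from numba import njit

#: column order of the full natural-space parameter row used by the kernels
PARAM_ROW = ("alpha_pos", "alpha_neg", "beta", "bias", "lapse", "decay",
             "perseverance")


@njit(cache=False, fastmath=True)
def session_nll_core(stim, act, rew, alpha_pos, alpha_neg, beta, bias,
                     lapse, decay, kappa):  # pragma: no cover - compiled
    q = np.full((2, 2), 0.5)
    last = np.full(2, -1, dtype=np.int64)
    nll = 0.0
    for t in range(stim.shape[0]):
        s = stim[t]
        a = act[t]
        if a >= 0:
            u0 = beta * q[s, 0] + bias
            u1 = beta * q[s, 1]
            if last[s] == 0:
                u0 += kappa
            elif last[s] == 1:
                u1 += kappa
            x = u0 - u1 if a == 0 else u1 - u0
            # numerically stable logistic: exp argument always <= 0
            if x >= 0.0:
                p = 1.0 / (1.0 + np.exp(-x))
            else:
                e = np.exp(x)
                p = e / (1.0 + e)
            p = lapse + (1.0 - 2.0 * lapse) * p
            if p < 1e-300:
                p = 1e-300
            nll -= np.log(p)
            r = rew[t]
            alpha = alpha_pos if r == 1 else alpha_neg
            q[s, a] += alpha * (r - q[s, a])
            if decay > 0.0:
                for si in range(2):
                    for ai in range(2):
                        if si != s or ai != a:
                            q[si, ai] += decay * (0.5 - q[si, ai])
            last[s] = a
        else:
            # abort or missed trial: no choice likelihood, values decay
            if decay > 0.0:
                for si in range(2):
                    for ai in range(2):
                        q[si, ai] += decay * (0.5 - q[si, ai])
    return nll


@njit(cache=False, fastmath=True)
def session_nll_batch(stim, act, rew, params):  # pragma: no cover - compiled
    """NLL of one session for a [K, 7] batch of natural-space parameters."""
    out = np.empty(params.shape[0])
    for k in range(params.shape[0]):
        out[k] = session_nll_core(
            stim, act, rew,
            params[k, 0], params[k, 1], params[k, 2], params[k, 3],
            params[k, 4], params[k, 5], params[k, 6])
    return out


def warmup() -> None:
    """Trigger JIT compilation on a two-trial dummy session."""
    stim = np.zeros(2, dtype=np.int64)
    act = np.array([0, -1], dtype=np.int64)
    rew = np.array([1, -1], dtype=np.int64)
    session_nll_core(stim, act, rew, 0.5, 0.5, 1.0, 0.0, 0.0, 0.1, 0.0)
    session_nll_batch(stim, act, rew, np.full((2, 7), 0.25))
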