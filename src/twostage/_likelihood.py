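"""Compiled likelihood kernel for the hybrid learner.

The sequential replay of a session cannot be vectorised, so the inner loop
is JIT-compiled with numba; multistart Nelder-Mead fitting calls it tens of
thousands of times.  The pure-Python learner in :mod:`twostage.agents` is
the readable reference; the two paths are cross-checked in the test suite.

Stage-specific learning rates and temperatures are supported so the same
kernel serves both the 5-parameter model (``alpha1 == alpha2``,
``beta1 == beta2``) and the 7-parameter two-rate/two-temperature variant.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _log_softmax2(x0: float, x1: float) -> tuple[float, float]:
    m = x0 if x0 > x1 else x1
    z = np.log(np.exp(x0 - m) + np.exp(x1 - m))
    return x0 - m - z, x1 - m - z


@njit(cache=True)
def nll_kernel(
    a1: np.ndarray,
    s2: np.ndarray,
    a2: np.ndarray,
    r: np.ndarray,
    dev: np.ndarray,
    common_state: np.ndarray,
    alpha1: float,
    alpha2: float,
    beta1: float,
    beta2: float,
    lam: float,
    p_stick: float,
    w: float,
    v: float,
    condition: int,
) -> float:
    """Negative log-likelihood of both stage choices under the hybrid model.

    Arrays are per-trial: ``a1``/``a2`` action indices, ``s2`` state
    indices, ``r`` rewards, ``dev[t, symbol]`` colour deviations and
    ``common_state[symbol]`` the state index each symbol commonly leads to
    (the latter two used only when ``condition == 2``).
    """
    T = a1.shape[0]
    q2 = np.zeros((2, 2))
    q1 = np.zeros(2)
    n = np.zeros((2, 2))
    prev = -1
    nll = 0.0
    for t in range(T):
        v_blue = q2[0, 0] if q2[0, 0] > q2[0, 1] else q2[0, 1]
        v_purple = q2[1, 0] if q2[1, 0] > q2[1, 1] else q2[1, 1]
        vmax = np.empty(2)
        vmax[0] = v_blue
        vmax[1] = v_purple
        x = np.empty(2)
        for a in range(2):
            p_blue = (n[a, 0] + 1.0) / (n[a, 0] + n[a, 1] + 2.0)
            q_mb = p_blue * v_blue + (1.0 - p_blue) * v_purple
            if condition == 2:
                cs = common_state[a]
                dq = dev[t, a] * (vmax[cs] - vmax[1 - cs])
                qh = w * q_mb + v * dq + (1.0 - w - v) * q1[a]
            else:
                qh = w * q_mb + (1.0 - w) * q1[a]
            x[a] = beta1 * qh
            if a == prev:
                x[a] += p_stick
        lp0, lp1 = _log_softmax2(x[0], x[1])
        nll -= lp0 if a1[t] == 0 else lp1
        st = s2[t]
        lq0, lq1 = _log_softmax2(beta2 * q2[st, 0], beta2 * q2[st, 1])
        nll -= lq0 if a2[t] == 0 else lq1
        # learning: stage-1 MF update first (pre-update q2), then stage 2
        q2v = q2[st, a2[t]]
        q1[a1[t]] += alpha1 * (q2v - q1[a1[t]]) + alpha1 * lam * (r[t] - q2v)
        q2[st, a2[t]] += alpha2 * (r[t] - q2[st, a2[t]])
        n[a1[t], st] += 1.0
        prev = a1[t]
    return nll
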