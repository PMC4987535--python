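"""Model-free, model-based, and hybrid learners with softmax choice.

The learner keeps second-stage action values ``q2`` updated by a delta
rule, first-stage model-free values ``q1_mf`` updated with an eligibility
trace, and Beta-Binomial transition counts that feed the model-based
valuation.  First-stage choice combines the two value systems with weight
``w`` (plus a colour-cue correction weighted by ``v`` in condition 2) and
passes through a softmax with inverse temperature ``beta`` and a
perseveration bonus ``p_stick`` for repeating the previous choice.

Within a trial the order of operations is fixed: choice probabilities come
from the pre-trial state; after the outcome the first-stage model-free
update runs first (using the pre-update ``q2``), then the second-stage
update, then the transition-count increment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from twostage.task_engine import (
    STATES,
    SYMBOLS,
    SessionPolicy,
    SymbolMap,
    TaskConfig,
    TrialRecord,
    TrialState,
    generate_session,
    records_to_frame,
)

_SYM_IDX = {s: i for i, s in enumerate(SYMBOLS)}
_STATE_IDX = {s: i for i, s in enumerate(STATES)}


@dataclass(frozen=True)
class AgentParams:
    """Free parameters of the hybrid learner.

    ``v`` (the colour-cue weight) only matters in condition 2, where
    ``w + v <= 1`` is required for the convex combination.
    """

    alpha: float
    beta: float
    lam: float
    p_stick: float
    w: float
    v: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not 0 <= self.lam <= 1:
            raise ValueError("lam must lie in [0, 1]")
        if not 0 <= self.w <= 1:
            raise ValueError("w must lie in [0, 1]")
        if not 0 <= self.v <= 1:
            raise ValueError("v must lie in [0, 1]")
        if self.w + self.v > 1 + 1e-12:
            raise ValueError("w + v must be <= 1")

    def as_dict(self) -> dict[str, float]:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "lam": self.lam,
            "p_stick": self.p_stick,
            "w": self.w,
            "v": self.v,
        }


@dataclass
class LearnerState:
    """Evolving state of the learner mid-session.

    ``q2[state, action]`` are second-stage values, ``q1_mf[symbol]`` the
    first-stage model-free values, ``n_trans[symbol, state]`` the observed
    transition counts, all zero-initialised.
    """

    q2: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    q1_mf: np.ndarray = field(default_factory=lambda: np.zeros(2))
    n_trans: np.ndarray = field(default_factory=lambda: np.zeros((2, 2), dtype=int))
    prev_a1: str | None = None

    def copy(self) -> "LearnerState":
        return LearnerState(
            q2=self.q2.copy(),
            q1_mf=self.q1_mf.copy(),
            n_trans=self.n_trans.copy(),
            prev_a1=self.prev_a1,
        )


def update_stage2(
    state: LearnerState, s2: str, a2: int, r: float, params: AgentParams
) -> LearnerState:
    """Delta-rule update of the chosen second-stage value (in place)."""
    si = _STATE_IDX[s2]
    state.q2[si, a2] += params.alpha * (r - state.q2[si, a2])
    return state


def update_stage1_mf(
    state: LearnerState, a1: str, s2: str, a2: int, r: float, params: AgentParams
) -> LearnerState:
    """Eligibility-trace update of the first-stage model-free value.

    Uses both the state-value prediction error (expected value of the
    reached second-stage choice minus the current first-stage value) and
    the reward prediction error, the latter scaled by ``lam``.  Must be
    applied before :func:`update_stage2` for this trial.
    """
    ai = _SYM_IDX[a1]
    si = _STATE_IDX[s2]
    q2v = state.q2[si, a2]
    state.q1_mf[ai] += params.alpha * (q2v - state.q1_mf[ai]) + params.alpha * params.lam * (
        r - q2v
    )
    return state


def transition_posterior(n_blue: int, n_purple: int) -> float:
    """Posterior-mean probability of the blue state under a Beta(1,1) prior."""
    if n_blue < 0 or n_purple < 0:
        raise ValueError("counts must be non-negative")
    return (n_blue + 1) / (n_blue + n_purple + 2)


def model_based_q(
    state: LearnerState, a1: str, symbol_map: SymbolMap | None = None
) -> float:
    """Forward-looking value of ``a1`` using the learned transition posterior."""
    ai = _SYM_IDX[a1]
    p_blue = transition_posterior(state.n_trans[ai, 0], state.n_trans[ai, 1])
    v_blue = state.q2[0].max()
    v_purple = state.q2[1].max()
    return p_blue * v_blue + (1 - p_blue) * v_purple


def hybrid_q(
    state: LearnerState,
    a1: str,
    params: AgentParams,
    condition: int = 1,
    colour_dev: float | None = None,
    symbol_map: SymbolMap | None = None,
) -> float:
    """Convex combination of model-based and model-free first-stage values.

    Condition 1: ``w * Q_mb + (1 - w) * Q_mf``.  Condition 2 adds the
    colour-cue correction ``v * dp * (V_common - V_rare)`` where ``dp`` is
    the symbol's colour deviation and V the best second-stage value of its
    common/rare state, with model-free weight ``1 - w - v``.
    """
    ai = _SYM_IDX[a1]
    q_mb = model_based_q(state, a1)
    q_mf = state.q1_mf[ai]
    if condition == 1:
        return params.w * q_mb + (1 - params.w) * q_mf
    if colour_dev is None:
        raise ValueError("condition-2 hybrid value requires colour_dev")
    if symbol_map is None:
        symbol_map = SymbolMap()
    cs = _STATE_IDX[symbol_map.common_state(a1)]
    dq = colour_dev * (state.q2[cs].max() - state.q2[1 - cs].max())
    return params.w * q_mb + params.v * dq + (1 - params.w - params.v) * q_mf


def _softmax2(x0: float, x1: float) -> tuple[float, float]:
    """Two-way softmax, stable for large arguments."""
    m = max(x0, x1)
    e0 = np.exp(x0 - m)
    e1 = np.exp(x1 - m)
    z = e0 + e1
    return float(e0 / z), float(e1 / z)


def choice_prob_stage1(
    qA: float, qB: float, prev_a1: str | None, params: AgentParams
) -> dict[str, float]:
    """First-stage softmax with a stickiness bonus for the previous choice."""
    xA = params.beta * qA + (params.p_stick if prev_a1 == "A" else 0.0)
    xB = params.beta * qB + (params.p_stick if prev_a1 == "B" else 0.0)
    pA, pB = _softmax2(xA, xB)
    return {"A": pA, "B": pB}


def choice_prob_stage2(q_pair: np.ndarray, params: AgentParams) -> np.ndarray:
    """Second-stage softmax over the two symbols of the reached state."""
    p0, p1 = _softmax2(params.beta * q_pair[0], params.beta * q_pair[1])
    return np.array([p0, p1])


class HybridAgent(SessionPolicy):
    """A hybrid learner usable as a session policy.

    Records a per-trial trace of the component and hybrid Q-values that
    underlie each first-stage choice.
    """

    def __init__(
        self,
        params: AgentParams,
        condition: int = 1,
        rng: np.random.Generator | None = None,
        symbol_map: SymbolMap | None = None,
    ):
        self.params = params
        self.condition = condition
        self.rng = rng if rng is not None else np.random.default_rng()
        self.symbol_map = symbol_map if symbol_map is not None else SymbolMap()
        self.state = LearnerState()
        self.trace: list[dict[str, float]] = []

    def reset_values(self, keep_transition_counts: bool = True, keep_prev: bool = True) -> None:
        """Re-initialise values between conditions.

        Reward contingencies are re-drawn between conditions, so Q-values
        restart at zero; symbols keep their transition structure, so the
        counts (and the previous choice, for stickiness) persist by default.
        """
        old = self.state
        self.state = LearnerState()
        if keep_transition_counts:
            self.state.n_trans = old.n_trans.copy()
        if keep_prev:
            self.state.prev_a1 = old.prev_a1

    def q_values(self, colour_dev: dict[str, float] | None) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for sym in SYMBOLS:
            dev = colour_dev[sym] if colour_dev is not None else None
            out[sym] = {
                "mf": float(self.state.q1_mf[_SYM_IDX[sym]]),
                "mb": model_based_q(self.state, sym),
                "hybrid": hybrid_q(
                    self.state,
                    sym,
                    self.params,
                    condition=self.condition,
                    colour_dev=dev,
                    symbol_map=self.symbol_map,
                ),
            }
        return out

    def choose_stage1(self, state: TrialState, colour_dev: dict[str, float] | None) -> str:
        qs = self.q_values(colour_dev)
        probs = choice_prob_stage1(
            qs["A"]["hybrid"], qs["B"]["hybrid"], self.state.prev_a1, self.params
        )
        self.trace.append(
            {
                "qA_mf": qs["A"]["mf"],
                "qB_mf": qs["B"]["mf"],
                "qA_mb": qs["A"]["mb"],
                "qB_mb": qs["B"]["mb"],
                "qA_hybrid": qs["A"]["hybrid"],
                "qB_hybrid": qs["B"]["hybrid"],
                "pA": probs["A"],
            }
        )
        return "A" if self.rng.random() < probs["A"] else "B"

    def choose_stage2(self, state: TrialState, s2: str) -> int:
        probs = choice_prob_stage2(self.state.q2[_STATE_IDX[s2]], self.params)
        return 0 if self.rng.random() < probs[0] else 1

    def learn(self, record: TrialRecord) -> None:
        update_stage1_mf(
            self.state, record.a1, record.s2, record.a2, record.r, self.params
        )
        update_stage2(self.state, record.s2, record.a2, record.r, self.params)
        self.state.n_trans[_SYM_IDX[record.a1], _STATE_IDX[record.s2]] += 1
        self.state.prev_a1 = record.a1


def simulate_agent(
    params: AgentParams,
    config: TaskConfig,
    rng: np.random.Generator | None = None,
    subject_id: str = "s0",
    symbol_map: SymbolMap | None = None,
    agent: HybridAgent | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Roll a hybrid learner through a generated session.

    Returns the trials table and a per-trial Q-value trace (pre-choice
    values of both first-stage symbols under each value system).  Passing a
    pre-built ``agent`` allows carrying learner state across conditions.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if agent is None:
        agent = HybridAgent(
            params, condition=config.condition, rng=rng, symbol_map=symbol_map
        )
    records = generate_session(
        config, agent, rng=rng, symbol_map=agent.symbol_map, subject_id=subject_id
    )
    trials = records_to_frame(records, subject_id=subject_id, condition=config.condition)
    trace = pd.DataFrame(agent.trace[-config.n_trials :])
    trace.insert(0, "trial", np.arange(config.n_trials))
    trace.insert(0, "subject_id", subject_id)
    return trials, trace
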