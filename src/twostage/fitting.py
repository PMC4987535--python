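"""Per-subject maximum-likelihood estimation and model comparison.

Parameters are fitted by multistart Nelder-Mead in a smoothly
reparameterised space: logit transforms keep ``alpha``, ``lam`` and ``w``
(and, via stick-breaking, the condition-2 pair ``(w, v)`` with
``w + v <= 1``) inside the unit interval, a log transform keeps ``beta``
positive, and the stickiness coordinate is softly clamped to [-10, 10]
logit units.  BIC counts both stage choices as observations
(``n_obs = 2 * T``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from twostage._likelihood import nll_kernel
from twostage.agents import (
    AgentParams,
    LearnerState,
    choice_prob_stage1,
    choice_prob_stage2,
    hybrid_q,
    model_based_q,
    update_stage1_mf,
    update_stage2,
)
from twostage.task_engine import STATES, SYMBOLS, SymbolMap

_SYM_IDX = {s: i for i, s in enumerate(SYMBOLS)}
_STATE_IDX = {s: i for i, s in enumerate(STATES)}

MODELS = ("cond1_hybrid", "cond2_hybrid", "cond1_two_rates")

_N_PARAMS = {"cond1_hybrid": 5, "cond2_hybrid": 6, "cond1_two_rates": 7}


@dataclass(frozen=True)
class FitConfig:
    """Multistart optimisation settings (paper-scale default is 10,000 starts)."""

    n_starts: int = 50
    max_iter: int = 2000
    tolerance: float = 1e-6
    seed: int = 0
    model: str = "cond1_hybrid"

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")


@dataclass
class FitResult:
    params: dict[str, float]
    nll: float
    bic: float
    n_params: int
    n_trials: int
    converged: bool
    best_start_index: int
    model: str

    def agent_params(self) -> AgentParams:
        p = self.params
        return AgentParams(
            alpha=p.get("alpha", p.get("alpha1")),
            beta=p.get("beta", p.get("beta1")),
            lam=p["lam"],
            p_stick=p["p_stick"],
            w=p["w"],
            v=p.get("v", 0.0),
        )


def infer_symbol_map(trials: pd.DataFrame) -> SymbolMap:
    """Recover the symbol→common-state map from observed transition labels."""
    if len(trials) == 0:
        raise ValueError("empty trials table; cannot infer the symbol map")
    row = trials.iloc[0]
    other = STATES[1] if row["s2"] == STATES[0] else STATES[0]
    state_of_chosen = row["s2"] if row["transition_type"] == "common" else other
    if row["a1"] == "A":
        return SymbolMap(common_state_A=state_of_chosen)
    # B's common state pins down A's by the bijection
    return SymbolMap(
        common_state_A=STATES[1] if state_of_chosen == STATES[0] else STATES[0]
    )


def trials_to_arrays(
    trials: pd.DataFrame, symbol_map: SymbolMap | None = None
) -> dict[str, np.ndarray]:
    """Pack a trials table into the arrays consumed by the likelihood kernel."""
    if symbol_map is None:
        symbol_map = infer_symbol_map(trials)
    a1 = trials["a1"].map(_SYM_IDX).to_numpy(dtype=np.int64)
    s2 = trials["s2"].map(_STATE_IDX).to_numpy(dtype=np.int64)
    a2 = trials["a2"].to_numpy(dtype=np.int64)
    r = trials["reward"].to_numpy(dtype=np.float64)
    if {"colour_dev_A", "colour_dev_B"} <= set(trials.columns):
        dev = trials[["colour_dev_A", "colour_dev_B"]].to_numpy(dtype=np.float64)
    else:
        dev = np.zeros((len(trials), 2))
    common_state = np.array(
        [_STATE_IDX[symbol_map.common_state(s)] for s in SYMBOLS], dtype=np.int64
    )
    return {"a1": a1, "s2": s2, "a2": a2, "r": r, "dev": dev, "common_state": common_state}


def negative_log_likelihood(
    params: AgentParams | dict[str, float],
    trials: pd.DataFrame,
    condition: int = 1,
    symbol_map: SymbolMap | None = None,
) -> float:
    """-sum of log choice probabilities (both stages) along the observed history."""
    if isinstance(params, AgentParams):
        p = params.as_dict()
    else:
        p = dict(params)
    arrs = trials_to_arrays(trials, symbol_map)
    nll = nll_kernel(
        arrs["a1"],
        arrs["s2"],
        arrs["a2"],
        arrs["r"],
        arrs["dev"],
        arrs["common_state"],
        *_kernel_args(p),
        condition,
    )
    if not np.isfinite(nll):
        raise FloatingPointError("non-finite likelihood: invalid parameters")
    return float(nll)


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    from scipy.special import expit

    return expit(x)


def _soft_clamp(x: float, bound: float = 10.0) -> float:
    return bound * np.tanh(x / bound)


def _theta_to_params(theta: np.ndarray, model: str) -> dict[str, float]:
    if model == "cond1_hybrid":
        return {
            "alpha": float(_sigmoid(theta[0])),
            "beta": float(np.exp(theta[1])),
            "lam": float(_sigmoid(theta[2])),
            "p_stick": float(_soft_clamp(theta[3])),
            "w": float(_sigmoid(theta[4])),
        }
    if model == "cond2_hybrid":
        w = float(_sigmoid(theta[4]))
        # stick-breaking: v takes a fraction of the remaining 1 - w
        v = float((1.0 - w) * _sigmoid(theta[5]))
        return {
            "alpha": float(_sigmoid(theta[0])),
            "beta": float(np.exp(theta[1])),
            "lam": float(_sigmoid(theta[2])),
            "p_stick": float(_soft_clamp(theta[3])),
            "w": w,
            "v": v,
        }
    if model == "cond1_two_rates":
        return {
            "alpha1": float(_sigmoid(theta[0])),
            "alpha2": float(_sigmoid(theta[1])),
            "beta1": float(np.exp(theta[2])),
            "beta2": float(np.exp(theta[3])),
            "lam": float(_sigmoid(theta[4])),
            "p_stick": float(_soft_clamp(theta[5])),
            "w": float(_sigmoid(theta[6])),
        }
    raise ValueError(f"unknown model {model!r}")


def _model_condition(model: str) -> int:
    return 2 if model == "cond2_hybrid" else 1


def _kernel_args(p: dict[str, float]) -> tuple[float, ...]:
    return (
        p.get("alpha", p.get("alpha1")),
        p.get("alpha", p.get("alpha2")),
        p.get("beta", p.get("beta1")),
        p.get("beta", p.get("beta2")),
        p["lam"],
        p["p_stick"],
        p["w"],
        p.get("v", 0.0),
    )


def fit_subject(
    trials: pd.DataFrame,
    config: FitConfig,
    symbol_map: SymbolMap | None = None,
) -> FitResult:
    """Multistart Nelder-Mead ML fit of one subject's session.

    Start points are drawn uniformly in the transformed (unconstrained)
    space from a seeded generator, so refits are deterministic.  The
    lowest-NLL converged solution wins; if no start converges the best
    point found is returned with ``converged=False``.
    """
    if len(trials) < 2:
        raise ValueError("need at least 2 trials to fit")
    model = config.model
    condition = _model_condition(model)
    k = _N_PARAMS[model]
    arrs = trials_to_arrays(trials, symbol_map)

    def objective(theta: np.ndarray) -> float:
        p = _theta_to_params(theta, model)
        val = nll_kernel(
            arrs["a1"], arrs["s2"], arrs["a2"], arrs["r"],
            arrs["dev"], arrs["common_state"], *_kernel_args(p), condition,
        )
        return val if np.isfinite(val) else 1e12

    rng = np.random.default_rng(config.seed)
    starts = rng.uniform(-2.5, 2.5, size=(config.n_starts, k))
    # keep log-beta starts in a plausible range (beta ~ 0.3 .. 20)
    beta_cols = (2, 3) if model == "cond1_two_rates" else (1,)
    for c in beta_cols:
        starts[:, c] = rng.uniform(np.log(0.3), np.log(20.0), size=config.n_starts)

    best_nll = np.inf
    best_theta = starts[0]
    best_idx = 0
    any_converged = False
    for i, x0 in enumerate(starts):
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={
                "maxiter": config.max_iter,
                "xatol": config.tolerance,
                "fatol": config.tolerance,
            },
        )
        if res.fun < best_nll:
            best_nll = float(res.fun)
            best_theta = res.x
            best_idx = i
            any_converged = any_converged or bool(res.success)
        elif res.success:
            any_converged = True

    params = _theta_to_params(best_theta, model)
    n_obs = 2 * len(trials)
    bic = k * np.log(n_obs) + 2.0 * best_nll
    return FitResult(
        params=params,
        nll=best_nll,
        bic=float(bic),
        n_params=k,
        n_trials=len(trials),
        converged=any_converged,
        best_start_index=best_idx,
        model=model,
    )


def compare_models(results: dict[str, FitResult]) -> str:
    """Name of the preferred (lowest-BIC) model; ties go to fewer parameters."""
    if len({res.n_trials for res in results.values()}) > 1:
        raise ValueError("models were fitted on different trial counts")
    return min(results.items(), key=lambda kv: (kv[1].bic, kv[1].n_params))[0]


def derive_q_trajectory(
    params: AgentParams,
    trials: pd.DataFrame,
    condition: int = 1,
    symbol_map: SymbolMap | None = None,
) -> pd.DataFrame:
    """Replay the observed history and emit pre-choice Q-values per trial.

    Uses the pure-Python learner, so it doubles as a cross-check of the
    compiled likelihood kernel.
    """
    if symbol_map is None:
        symbol_map = infer_symbol_map(trials)
    state = LearnerState()
    rows = []
    for _, row in trials.iterrows():
        devs = {
            "A": float(row.get("colour_dev_A", 0.0)),
            "B": float(row.get("colour_dev_B", 0.0)),
        }
        rec: dict[str, float] = {"trial": int(row["trial"])}
        for sym in SYMBOLS:
            dev = devs[sym] if condition == 2 else None
            rec[f"q{sym}_mf"] = float(state.q1_mf[_SYM_IDX[sym]])
            rec[f"q{sym}_mb"] = model_based_q(state, sym)
            rec[f"q{sym}_hybrid"] = hybrid_q(
                state, sym, params, condition=condition,
                colour_dev=dev, symbol_map=symbol_map,
            )
        p1 = choice_prob_stage1(
            rec["qA_hybrid"], rec["qB_hybrid"], state.prev_a1, params
        )
        rec["pA"] = p1["A"]
        si = _STATE_IDX[row["s2"]]
        p2 = choice_prob_stage2(state.q2[si], params)
        rec["p_a2"] = float(p2[int(row["a2"])])
        rows.append(rec)
        update_stage1_mf(state, row["a1"], row["s2"], int(row["a2"]), float(row["reward"]), params)
        update_stage2(state, row["s2"], int(row["a2"]), float(row["reward"]), params)
        state.n_trans[_SYM_IDX[row["a1"]], si] += 1
        state.prev_a1 = row["a1"]
    return pd.DataFrame(rows)


def classify_subjects(w_values: pd.Series | np.ndarray) -> pd.Series:
    """Median split on the model-based weight.

    Subjects at or above the sample median are labelled ``model_based``,
    the rest ``model_free``.  A degenerate (all-equal) split labels every
    subject model-based and warns.
    """
    w = pd.Series(w_values, dtype=float)
    if len(w) < 2:
        raise ValueError("need at least 2 subjects")
    med = w.median()
    labels = pd.Series(
        np.where(w >= med, "model_based", "model_free"), index=w.index
    )
    if labels.nunique() == 1:
        import warnings

        warnings.warn("degenerate median split: all subjects on one side", stacklevel=2)
    return labels
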