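"""Generation and validation of two-stage task sessions.

Each trial offers a first-stage choice between two symbols (``A``/``B``)
that lead stochastically to one of two second-stage states (``blue``/
``purple``), where a second binary choice yields a binary reward.  Per-trial
common-transition probabilities are sampled uniformly from [0.4, 1]
(mean 0.7); the four second-stage reward probabilities drift as reflected
Gaussian walks (sd 0.025) inside [0.25, 0.75].

Both experimental conditions share one generator: condition 2 displays the
per-trial transition-probability deviations ("colour deviations") as bar
cues, condition 1 merely hides them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

SYMBOLS = ("A", "B")
STATES = ("blue", "purple")

#: Column order of the tabular session export.
TRIALS_COLUMNS = [
    "subject_id",
    "condition",
    "trial",
    "a1",
    "p_common_A",
    "p_common_B",
    "s2",
    "transition_type",
    "a2",
    "reward",
    "colour_dev_A",
    "colour_dev_B",
    "rprob_blue0",
    "rprob_blue1",
    "rprob_purple0",
    "rprob_purple1",
    "side_A",
]


@dataclass(frozen=True)
class TaskConfig:
    """Design constants of one session of the two-stage task."""

    n_trials: int = 150
    common_prob_mean: float = 0.7
    transition_prob_low: float = 0.4
    transition_prob_high: float = 1.0
    reward_prob_low: float = 0.25
    reward_prob_high: float = 0.75
    reward_walk_sd: float = 0.025
    condition: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0 <= self.transition_prob_low < self.transition_prob_high <= 1:
            raise ValueError("require 0 <= transition_prob_low < transition_prob_high <= 1")
        if not 0 <= self.reward_prob_low < self.reward_prob_high <= 1:
            raise ValueError("require 0 <= reward_prob_low < reward_prob_high <= 1")
        if self.reward_walk_sd <= 0:
            raise ValueError("reward_walk_sd must be > 0")
        if self.condition not in (1, 2):
            raise ValueError("condition must be 1 or 2")


@dataclass(frozen=True)
class SymbolMap:
    """Bijection from first-stage symbol to its common second-stage state."""

    common_state_A: str = "blue"

    def __post_init__(self) -> None:
        if self.common_state_A not in STATES:
            raise ValueError(f"unknown state {self.common_state_A!r}")

    def common_state(self, symbol: str) -> str:
        if symbol == "A":
            return self.common_state_A
        if symbol == "B":
            return STATES[1] if self.common_state_A == STATES[0] else STATES[0]
        raise ValueError(f"unknown symbol {symbol!r}")

    def rare_state(self, symbol: str) -> str:
        common = self.common_state(symbol)
        return STATES[1] if common == STATES[0] else STATES[0]


@dataclass
class TrialState:
    """Latent task state of a single trial.

    ``p_common`` maps each first-stage symbol to this trial's probability of
    its common transition; ``reward_probs`` maps (state, symbol-index) to the
    current reward probability.
    """

    p_common: dict[str, float]
    reward_probs: dict[tuple[str, int], float]


@dataclass
class TrialRecord:
    """One completed two-stage trial."""

    t: int
    a1: str
    s2: str
    transition_type: str
    a2: int
    r: int
    p_common: dict[str, float]
    colour_dev: dict[str, float]
    reward_probs: dict[tuple[str, int], float] = field(default_factory=dict)
    side_A: str = "left"


def sample_transition_probs(
    config: TaskConfig, rng: np.random.Generator
) -> dict[str, float]:
    """Draw this trial's common-transition probability for each symbol.

    Independent draws from Uniform(low, high) per first-stage symbol.
    """
    lo, hi = config.transition_prob_low, config.transition_prob_high
    draws = rng.uniform(lo, hi, size=2)
    return {"A": float(draws[0]), "B": float(draws[1])}


def _reflect(x: float, lo: float, hi: float) -> float:
    """Fold ``x`` back into [lo, hi] by repeated reflection at the bounds."""
    width = hi - lo
    y = (x - lo) % (2.0 * width)
    if y > width:
        y = 2.0 * width - y
    return lo + y


def step_reward_walk(
    current: Sequence[float] | np.ndarray,
    config: TaskConfig,
    rng: np.random.Generator,
    return_increments: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Advance the reward-probability walk by one Gaussian step per entry.

    Each probability is perturbed by an independent N(0, sd) increment and
    mapped back into [low, high] by reflection at the bounds.  With
    ``return_increments`` the raw pre-reflection steps are returned too.
    """
    lo, hi = config.reward_prob_low, config.reward_prob_high
    cur = np.asarray(current, dtype=float)
    if np.any(cur < lo) or np.any(cur > hi):
        raise ValueError(f"reward probabilities must lie in [{lo}, {hi}]")
    steps = rng.normal(0.0, config.reward_walk_sd, size=cur.shape)
    nxt = np.array([_reflect(v, lo, hi) for v in cur + steps])
    if return_increments:
        return nxt, steps
    return nxt


def simulate_reward_walk(
    n_steps: int,
    config: TaskConfig,
    rng: np.random.Generator,
    start: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Run a reward-probability walk, returning (trajectory, increments).

    ``trajectory`` has shape (n_steps + 1, 4) and includes the start point;
    ``increments`` are the raw Gaussian steps, shape (n_steps, 4).
    """
    if start is None:
        cur = rng.uniform(config.reward_prob_low, config.reward_prob_high, size=4)
    else:
        cur = np.asarray(start, dtype=float)
    traj = [cur.copy()]
    incs = []
    for _ in range(n_steps):
        cur, step = step_reward_walk(cur, config, rng, return_increments=True)
        traj.append(cur.copy())
        incs.append(step)
    return np.asarray(traj), np.asarray(incs)


def resolve_transition(
    a1: str,
    trial_state: TrialState,
    symbol_map: SymbolMap,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Sample the second-stage state reached after choosing ``a1``.

    Returns ``(s2, transition_type)`` where the common state of ``a1`` is
    reached with this trial's ``p_common`` and the other state otherwise.
    """
    if a1 not in SYMBOLS:
        raise ValueError(f"unknown symbol {a1!r}")
    p = trial_state.p_common[a1]
    if rng.random() < p:
        return symbol_map.common_state(a1), "common"
    return symbol_map.rare_state(a1), "rare"


def colour_deviation(p_trial: float, mean: float = 0.7) -> float:
    """Signed deviation of a trial transition probability from its mean."""
    return p_trial - mean


def generate_session(
    config: TaskConfig,
    policy: "SessionPolicy",
    rng: np.random.Generator | None = None,
    symbol_map: SymbolMap | None = None,
    subject_id: str = "s0",
    initial_reward_probs: dict[tuple[str, int], float] | None = None,
) -> list[TrialRecord]:
    """Generate one full session, consulting ``policy`` for both choices.

    The reward walk advances once per trial; transition probabilities are
    re-sampled each trial.  Colour deviations are generated for both
    conditions — condition 1 simply does not display them (callers use the
    ``condition`` field of the config to decide what the agent sees).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if symbol_map is None:
        symbol_map = SymbolMap()
    if initial_reward_probs is None:
        draws = rng.uniform(config.reward_prob_low, config.reward_prob_high, size=4)
        reward_probs = {
            ("blue", 0): float(draws[0]),
            ("blue", 1): float(draws[1]),
            ("purple", 0): float(draws[2]),
            ("purple", 1): float(draws[3]),
        }
    else:
        reward_probs = dict(initial_reward_probs)

    records: list[TrialRecord] = []
    for t in range(config.n_trials):
        p_common = sample_transition_probs(config, rng)
        dev = {
            sym: colour_deviation(p_common[sym], config.common_prob_mean)
            for sym in SYMBOLS
        }
        state = TrialState(p_common=p_common, reward_probs=dict(reward_probs))
        side_A = "left" if rng.random() < 0.5 else "right"
        try:
            a1 = policy.choose_stage1(state, dev if config.condition == 2 else None)
            s2, ttype = resolve_transition(a1, state, symbol_map, rng)
            a2 = policy.choose_stage2(state, s2)
        except Exception as exc:  # noqa: BLE001 - annotate with trial index
            raise RuntimeError(f"policy failed on trial {t}") from exc
        r = int(rng.random() < reward_probs[(s2, a2)])
        rec = TrialRecord(
            t=t,
            a1=a1,
            s2=s2,
            transition_type=ttype,
            a2=a2,
            r=r,
            p_common=p_common,
            colour_dev=dev,
            reward_probs=dict(reward_probs),
            side_A=side_A,
        )
        policy.learn(rec)
        records.append(rec)
        arr = np.array(
            [
                reward_probs[("blue", 0)],
                reward_probs[("blue", 1)],
                reward_probs[("purple", 0)],
                reward_probs[("purple", 1)],
            ]
        )
        arr = step_reward_walk(arr, config, rng)
        reward_probs = {
            ("blue", 0): float(arr[0]),
            ("blue", 1): float(arr[1]),
            ("purple", 0): float(arr[2]),
            ("purple", 1): float(arr[3]),
        }
    return records


class SessionPolicy:
    """Choice rule consulted by :func:`generate_session`.

    Subclasses implement the two choice points and, optionally, learning
    from the completed trial record.
    """

    def choose_stage1(
        self, state: TrialState, colour_dev: dict[str, float] | None
    ) -> str:
        raise NotImplementedError

    def choose_stage2(self, state: TrialState, s2: str) -> int:
        raise NotImplementedError

    def learn(self, record: TrialRecord) -> None:  # pragma: no cover - optional
        pass


class UniformPolicy(SessionPolicy):
    """Chooses uniformly at random at both stages (testing baseline)."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng

    def choose_stage1(self, state, colour_dev):
        return SYMBOLS[int(self.rng.random() < 0.5)]

    def choose_stage2(self, state, s2):
        return int(self.rng.random() < 0.5)


class FixedPolicy(SessionPolicy):
    """Always picks the same actions (testing baseline)."""

    def __init__(self, a1: str = "A", a2: int = 0):
        self.a1, self.a2 = a1, a2

    def choose_stage1(self, state, colour_dev):
        return self.a1

    def choose_stage2(self, state, s2):
        return self.a2


def records_to_frame(
    records: Sequence[TrialRecord], subject_id: str = "s0", condition: int = 1
) -> pd.DataFrame:
    """Flatten trial records into the tabular ``trials.csv`` schema."""
    rows = []
    for rec in records:
        rows.append(
            {
                "subject_id": subject_id,
                "condition": condition,
                "trial": rec.t,
                "a1": rec.a1,
                "p_common_A": rec.p_common["A"],
                "p_common_B": rec.p_common["B"],
                "s2": rec.s2,
                "transition_type": rec.transition_type,
                "a2": rec.a2,
                "reward": rec.r,
                "colour_dev_A": rec.colour_dev["A"],
                "colour_dev_B": rec.colour_dev["B"],
                "rprob_blue0": rec.reward_probs.get(("blue", 0), np.nan),
                "rprob_blue1": rec.reward_probs.get(("blue", 1), np.nan),
                "rprob_purple0": rec.reward_probs.get(("purple", 0), np.nan),
                "rprob_purple1": rec.reward_probs.get(("purple", 1), np.nan),
                "side_A": rec.side_A,
            }
        )
    return pd.DataFrame(rows, columns=TRIALS_COLUMNS)
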