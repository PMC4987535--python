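"""Synthetic studies: agents with known parameters, sessions, gaze streams.

Choices come from the hybrid learner; gaze streams come from one of two
descriptive generative processes.  The ``comparison`` process mimics a
value-comparison (sequential sampling) signature: the first gaze lands on
either symbol at random, trials mostly contain two or more alternating
gazes, middle-gaze dwells shrink as the choice gets easier, and the chosen
symbol is biased toward the last gaze and toward the dwell-time advantage.
The ``search`` process mimics directed visual search: the first gaze lands
on the to-be-chosen (higher-value) symbol with probability increasing in
the value difference, single-gaze trials are common, and dwell effects are
weak.  Neither is a fitted accumulation model; they are pattern generators
for testing the analysis pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from twostage.agents import AgentParams, HybridAgent, simulate_agent
from twostage.gaze_pipeline import GazeEvent, ScreenGeometry, events_to_frame
from twostage.task_engine import TaskConfig, generate_session, records_to_frame

_GAP_MS = 30.0  # inter-gaze saccade gap
_FIXATION_MS = 200.0  # central pre-trial fixation block in rasterised samples
_TRIAL_START_MS = 2000.0  # choice screen onset after the forced fixation


@dataclass(frozen=True)
class GazeParams:
    """Knobs of the descriptive gaze generators."""

    mean_dwell_ms: float = 500.0
    dwell_dispersion: float = 0.35  # lognormal sigma
    value_sensitivity: float = 1.2  # middle-dwell shrink per |dQ| unit
    last_gaze_bias: float = 0.75  # P(last gaze on the chosen symbol)
    dwell_advantage_bias: float = 0.5  # extra dwell share on the chosen symbol
    single_gaze_prob: float = 0.32
    no_gaze_rate: float = 20.0 / 150.0
    first_gaze_intercept: float = 0.4  # search only: logit of first-on-best
    first_gaze_slope: float = 2.5  # search only: increase with |dQ|

    def __post_init__(self) -> None:
        if not 0 <= self.no_gaze_rate <= 1:
            raise ValueError("no_gaze_rate must lie in [0, 1]")
        if not 0 <= self.single_gaze_prob < 1:
            raise ValueError("single_gaze_prob must lie in [0, 1)")
        if self.mean_dwell_ms <= 0 or self.dwell_dispersion <= 0:
            raise ValueError("dwell parameters must be positive")


@dataclass(frozen=True)
class SubjectSpec:
    """Ground truth for one synthetic subject."""

    subject_id: str
    agent: AgentParams
    gaze_process: str  # {"comparison", "search"}
    gaze_params: GazeParams = field(default_factory=GazeParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaze_process not in ("comparison", "search"):
            raise ValueError("gaze_process must be 'comparison' or 'search'")


@dataclass
class SyntheticStudy:
    specs: list[SubjectSpec]
    trials: pd.DataFrame
    q_traces: pd.DataFrame
    gaze_events: pd.DataFrame
    ground_truth: pd.DataFrame
    manifest: dict


def sample_subject_specs(
    n: int,
    rng: np.random.Generator,
    priors: dict | None = None,
    comparison_if_w_below: float = 0.5,
) -> list[SubjectSpec]:
    """Draw subjects from documented priors.

    Defaults: alpha, lam, w ~ Uniform(0,1); v ~ Uniform(0, 1-w) (so the
    condition-2 pair lives on the simplex); beta ~ LogNormal(log 4, 0.4);
    p_stick ~ Normal(0, 1).  The gaze process defaults to ``comparison``
    for subjects with w below 0.5 and ``search`` otherwise.

    ``priors`` overrides individual parameters with either a point mass
    (scalar) or a Uniform(low, high) range (2-tuple).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    priors = priors or {}

    def draw(name: str, default):
        if name in priors:
            val = priors[name]
            if isinstance(val, (tuple, list)):
                return float(rng.uniform(*val))
            return float(val)
        return float(default())

    specs = []
    for i in range(n):
        alpha = draw("alpha", rng.uniform)
        lam = draw("lam", rng.uniform)
        w = draw("w", rng.uniform)
        v = draw("v", lambda: rng.uniform(0.0, 1.0 - w))
        v = min(v, 1.0 - w)
        beta = draw("beta", lambda: rng.lognormal(np.log(4.0), 0.4))
        p_stick = draw("p_stick", lambda: rng.normal(0.0, 1.0))
        agent = AgentParams(alpha=alpha, beta=beta, lam=lam, p_stick=p_stick, w=w, v=v)
        process = "comparison" if w < comparison_if_w_below else "search"
        specs.append(
            SubjectSpec(
                subject_id=f"sub{i:03d}",
                agent=agent,
                gaze_process=process,
                gaze_params=GazeParams(
                    single_gaze_prob=0.32 if process == "comparison" else 0.45,
                    dwell_advantage_bias=0.5 if process == "comparison" else 0.1,
                ),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def generate_choices(
    spec: SubjectSpec,
    config: TaskConfig,
    agent: HybridAgent | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One full session for a subject (delegates to the hybrid learner)."""
    rng = np.random.default_rng((spec.seed, config.condition))
    return simulate_agent(
        spec.agent, config, rng=rng, subject_id=spec.subject_id, agent=agent
    )


def _draw_n_gazes(process: str, single_prob: float, rng: np.random.Generator) -> int:
    if rng.random() < single_prob:
        return 1
    if process == "search":
        support, probs = (2, 3, 4), (0.7, 0.2, 0.1)
    else:
        support, probs = (2, 3, 4, 5, 6), (0.38, 0.3, 0.18, 0.09, 0.05)
    return int(rng.choice(support, p=probs))


def generate_gaze(
    spec: SubjectSpec,
    trials: pd.DataFrame,
    q_trace: pd.DataFrame,
    rng: np.random.Generator | None = None,
    condition: int = 1,
) -> dict[int, list[GazeEvent]]:
    """Cleaned-style gaze events per trial for one subject's session.

    Requires the per-trial hybrid Q-values (``q_trace``) to couple gaze
    structure to choice difficulty.  In condition 2 bar gazes are
    interleaved with a dwell share that increases with the subject's
    ground-truth w and v, coupling cue attention to model-basedness.
    """
    if rng is None:
        rng = np.random.default_rng((spec.seed, 17, condition))
    gp = spec.gaze_params
    merged = trials.merge(
        q_trace[["trial", "qA_hybrid", "qB_hybrid"]], on="trial", how="left"
    )
    out: dict[int, list[GazeEvent]] = {}
    for _, row in merged.iterrows():
        trial = int(row["trial"])
        if rng.random() < gp.no_gaze_rate:
            out[trial] = []
            continue
        dq = float(row["qB_hybrid"] - row["qA_hybrid"])
        chosen = row["a1"]
        other = "B" if chosen == "A" else "A"
        best = "B" if dq > 0 else "A"
        n = _draw_n_gazes(spec.gaze_process, gp.single_gaze_prob, rng)
        if spec.gaze_process == "search":
            p_first_best = 1.0 / (
                1.0 + np.exp(-(gp.first_gaze_intercept + gp.first_gaze_slope * abs(dq)))
            )
            first = best if rng.random() < p_first_best else (
                "A" if best == "B" else "B"
            )
        else:
            first = "A" if rng.random() < 0.5 else "B"
        if n == 1:
            symbols = [first]
        else:
            last = chosen if rng.random() < gp.last_gaze_bias else other
            # strict alternation fixes parity; stretch by one gaze if needed
            if (n % 2 == 1) != (first == last):
                n += 1
            symbols = [first if i % 2 == 0 else ("A" if first == "B" else "B") for i in range(n)]
            symbols[-1] = last
        # dwells: lognormal; middle gazes shrink with easier choices
        mu_base = np.log(gp.mean_dwell_ms)
        dwells = []
        for i, sym in enumerate(symbols):
            mu = mu_base
            if 0 < i < len(symbols) - 1:
                mu = mu_base - gp.value_sensitivity * abs(dq)
            d = rng.lognormal(mu, gp.dwell_dispersion)
            if sym == chosen:
                d *= 1.0 + gp.dwell_advantage_bias * rng.random()
            dwells.append(d)
        side_A = row.get("side_A", "left")
        side_of = {"A": side_A, "B": "right" if side_A == "left" else "left"}
        events: list[GazeEvent] = []
        t = _TRIAL_START_MS
        # condition-2 bar attention grows with ground-truth w and v
        bar_share = 0.0
        if condition == 2:
            bar_share = float(
                np.clip(0.25 + 0.55 * (spec.agent.w + spec.agent.v), 0.05, 0.9)
            )
        bar_budget = bar_share / (1.0 - bar_share) * sum(dwells) if bar_share else 0.0
        for i, (sym, d) in enumerate(zip(symbols, dwells)):
            events.append(GazeEvent(roi=f"{side_of[sym]}_symbol", onset=t, offset=t + d))
            t += d + _GAP_MS
            if bar_budget > 0 and i < len(symbols):
                bd = bar_budget / len(symbols)
                side = side_of[sym]
                events.append(GazeEvent(roi=f"{side}_bar", onset=t, offset=t + bd))
                t += bd + _GAP_MS
        out[trial] = events
    return out


def rasterize_samples(
    trial_events: dict[int, list[GazeEvent]],
    geometry: ScreenGeometry | None = None,
    rng: np.random.Generator | None = None,
    blink_prob: float = 0.0,
    blink_ms: float = 60.0,
    subject_id: str = "s0",
) -> pd.DataFrame:
    """Rasterise events into 1000-Hz samples, with optional blink gaps.

    Every trial starts with a block of samples at screen center (the
    forced fixation, outside all ROIs); between-gaze gaps also sit at
    center.  With ``blink_prob``, long gazes are split by an off-screen
    blink, which the cleaning stage is expected to merge back.
    """
    if geometry is None:
        geometry = ScreenGeometry()
    if rng is None:
        rng = np.random.default_rng()
    cx, cy = geometry.screen_w / 2, geometry.screen_h / 2
    rows = []

    def emit(trial: int, t0: float, t1: float, x: float, y: float) -> None:
        for t in np.arange(np.ceil(t0), t1):
            rows.append(
                {"subject_id": subject_id, "trial": trial, "t_ms": float(t),
                 "x_px": x, "y_px": y}
            )

    for trial, events in trial_events.items():
        emit(trial, 0.0, _FIXATION_MS, cx, cy)
        prev_end = _FIXATION_MS
        shift = 0.0  # blinks stretch the timeline so dwell is conserved
        for ev in events:
            onset = ev.onset + shift
            if onset > prev_end:
                emit(trial, prev_end, onset, cx, cy)
            x, y = geometry.roi_center(ev.roi)
            span = ev.offset - ev.onset
            if blink_prob > 0 and span > 3 * blink_ms and rng.random() < blink_prob:
                cut = onset + span / 2
                emit(trial, onset, cut, x, y)
                emit(trial, cut, cut + blink_ms, -100.0, -100.0)  # off-screen
                emit(trial, cut + blink_ms, onset + span + blink_ms, x, y)
                shift += blink_ms
                prev_end = onset + span + blink_ms
            else:
                emit(trial, onset, onset + span, x, y)
                prev_end = onset + span
    return pd.DataFrame(rows, columns=["subject_id", "trial", "t_ms", "x_px", "y_px"])


def generate_study(
    n_subjects: int = 43,
    seed: int = 0,
    conditions: tuple[int, ...] = (1, 2),
    task_kwargs: dict | None = None,
    priors: dict | None = None,
    carry_state_across_conditions: bool = True,
) -> SyntheticStudy:
    """End-to-end synthetic dataset: subjects, sessions, gaze, ground truth.

    When both conditions are generated and ``carry_state_across_conditions``
    is set, each subject's learner resets its Q-values between conditions
    (reward contingencies are re-drawn) but keeps its transition counts and
    previous choice, mirroring the within-subject design.
    """
    rng = np.random.default_rng(seed)
    specs = sample_subject_specs(n_subjects, rng, priors=priors)
    task_kwargs = task_kwargs or {}
    all_trials, all_traces, all_gaze = [], [], []
    for spec in specs:
        agent = None
        for condition in conditions:
            config = TaskConfig(condition=condition, **task_kwargs)
            sub_rng = np.random.default_rng((seed, spec.seed, condition))
            if agent is None:
                agent = HybridAgent(spec.agent, condition=condition, rng=sub_rng)
            else:
                agent.condition = condition
                agent.rng = sub_rng
                if carry_state_across_conditions:
                    agent.reset_values()
                else:
                    agent.reset_values(keep_transition_counts=False, keep_prev=False)
            trials, trace = simulate_agent(
                spec.agent, config, rng=sub_rng, subject_id=spec.subject_id, agent=agent
            )
            events = generate_gaze(
                spec, trials, trace,
                rng=np.random.default_rng((seed, spec.seed, 17, condition)),
                condition=condition,
            )
            gaze = events_to_frame(events, subject_id=spec.subject_id)
            gaze.insert(1, "condition", condition)
            trace.insert(1, "condition", condition)
            all_trials.append(trials)
            all_traces.append(trace)
            all_gaze.append(gaze)
    truth = pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                **s.agent.as_dict(),
                "gaze_process": s.gaze_process,
                "seed": s.seed,
            }
            for s in specs
        ]
    )
    return SyntheticStudy(
        specs=specs,
        trials=pd.concat(all_trials, ignore_index=True),
        q_traces=pd.concat(all_traces, ignore_index=True),
        gaze_events=pd.concat(all_gaze, ignore_index=True),
        ground_truth=truth,
        manifest={
            "seed": seed,
            "n_subjects": n_subjects,
            "conditions": list(conditions),
            "carry_state_across_conditions": carry_state_across_conditions,
            "priors": "alpha,lam,w~U(0,1); v~U(0,1-w); beta~LogN(log4,0.4); p_stick~N(0,1)",
        },
    )
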