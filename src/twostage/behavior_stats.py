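"""Stay-probability tables and choice regressions.

The original analyses use hierarchical (mixed-effects) logistic models;
here each regression is fitted per subject by maximum likelihood and the
coefficients are tested at the group level with one-sample t-tests — a
documented random-effects surrogate.  The pooled gaze-choice regression is
instead estimated once with subject-clustered standard errors, because it
contains subject-constant predictors (group dummy / continuous w).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

#: condition-1 stay design; condition 2 appends the colour terms
COND1_TERMS = ["reward", "transition", "reward:transition"]
COND2_TERMS = COND1_TERMS + [
    "colour",
    "reward:colour",
    "transition:colour",
    "reward:transition:colour",
]

_SEPARATION_CUTOFF = 15.0  # |logit coef| beyond this flags quasi-separation


@dataclass
class RegressionResult:
    """Group-level summary of per-subject logistic fits."""

    terms: list[str]
    per_subject: pd.DataFrame  # one row per subject, one column per term
    table: pd.DataFrame  # term, mean, se, tstat, pvalue, n_subjects
    n_subjects: int
    n_rows: int
    metadata: dict = field(default_factory=dict)


def build_stay_design(trials: pd.DataFrame, condition: int = 1) -> pd.DataFrame:
    """One row per trial t >= 2: did the subject repeat the previous choice?

    ``reward`` and ``transition`` describe the previous trial; ``colour``
    (condition 2) is the current-trial colour-deviation difference seen
    from the previously chosen symbol: its own common-colour deviation
    minus that colour's deviation in the other symbol's bar.
    """
    rows = []
    for subject, grp in trials.groupby("subject_id", sort=False):
        grp = grp.sort_values("trial")
        prev = None
        for _, row in grp.iterrows():
            if prev is not None:
                rec = {
                    "subject_id": subject,
                    "trial": int(row["trial"]),
                    "stay": int(row["a1"] == prev["a1"]),
                    "reward": int(prev["reward"]),
                    "transition": int(prev["transition_type"] == "common"),
                }
                if condition == 2:
                    chosen = prev["a1"]
                    other = "B" if chosen == "A" else "A"
                    # the other bar shows the complementary colour, hence "+"
                    rec["colour"] = float(
                        row[f"colour_dev_{chosen}"] + row[f"colour_dev_{other}"]
                    )
                rows.append(rec)
            prev = row
    cols = ["subject_id", "trial", "stay", "reward", "transition"]
    if condition == 2:
        cols.append("colour")
    return pd.DataFrame(rows, columns=cols)


def stay_probability_table(stay_rows: pd.DataFrame) -> pd.DataFrame:
    """P(stay) per previous-reward x previous-transition cell.

    Subject means are aggregated first; the table reports their mean and
    the across-subject (cluster) standard error.  Cells missing for every
    subject come back with NaN and ``n_subjects == 0``.
    """
    per_subj = (
        stay_rows.groupby(["subject_id", "reward", "transition"])["stay"]
        .mean()
        .reset_index()
    )
    rows = []
    for reward in (0, 1):
        for transition in (0, 1):
            cell = per_subj[
                (per_subj["reward"] == reward) & (per_subj["transition"] == transition)
            ]["stay"]
            n = len(cell)
            rows.append(
                {
                    "reward": reward,
                    "transition": transition,
                    "p_stay": cell.mean() if n else np.nan,
                    "se": cell.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                    "n_subjects": n,
                }
            )
    return pd.DataFrame(rows)


def _design_matrix(rows: pd.DataFrame, terms: list[str]) -> np.ndarray:
    cols = [np.ones(len(rows))]
    for term in terms:
        parts = term.split(":")
        col = np.ones(len(rows))
        for part in parts:
            col = col * rows[part].to_numpy(dtype=float)
        cols.append(col)
    return np.column_stack(cols)


def fit_stay_regression(
    stay_rows: pd.DataFrame,
    terms: list[str] | None = None,
    min_rows: int = 10,
) -> RegressionResult:
    """Per-subject logistic fits of stay behaviour + group-level t-tests.

    Subjects with quasi-separated fits (runaway coefficients or failed
    convergence) are excluded from the group test for the affected term,
    with a warning.
    """
    if terms is None:
        terms = COND2_TERMS if "colour" in stay_rows.columns else COND1_TERMS
    coefs: list[dict[str, float]] = []
    n_dropped = 0
    for subject, grp in stay_rows.groupby("subject_id", sort=False):
        if len(grp) < min_rows:
            n_dropped += 1
            continue
        X = _design_matrix(grp, terms)
        y = grp["stay"].to_numpy(dtype=float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            params = res.params
        except Exception:  # noqa: BLE001 - any optimisation failure
            n_dropped += 1
            continue
        rec = {"subject_id": subject}
        for i, term in enumerate(terms):
            coef = params[i + 1]
            rec[term] = coef if abs(coef) < _SEPARATION_CUTOFF else np.nan
        rec["intercept"] = params[0]
        coefs.append(rec)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} subject(s) dropped (too few rows or failed fit)",
            stacklevel=2,
        )
    per_subject = pd.DataFrame(coefs)
    table_rows = []
    for term in terms:
        vals = per_subject[term].dropna() if len(per_subject) else pd.Series(dtype=float)
        if len(vals) > 1:
            t, p = sps.ttest_1samp(vals, 0.0)
            se = vals.std(ddof=1) / np.sqrt(len(vals))
        else:
            t, p, se = np.nan, np.nan, np.nan
        table_rows.append(
            {
                "term": term,
                "mean": vals.mean() if len(vals) else np.nan,
                "se": se,
                "tstat": t,
                "pvalue": p,
                "n_subjects": len(vals),
            }
        )
    return RegressionResult(
        terms=terms,
        per_subject=per_subject,
        table=pd.DataFrame(table_rows),
        n_subjects=len(per_subject),
        n_rows=len(stay_rows),
        metadata={
            "estimator": "per-subject ML logit + one-sample t-test surrogate "
            "for a mixed-effects model",
            "separation_cutoff": _SEPARATION_CUTOFF,
        },
    )


#: Table-1-style gaze-choice design terms (group = dummy or continuous w)
CHOICE_TERMS = [
    "qdiff",
    "prev_B",
    "first_gaze_B",
    "last_gaze_B",
    "last_dwell_z",
    "group",
    "last_dwell_z:last_gaze_B",
    "group:last_gaze_B",
    "group:last_dwell_z",
    "group:last_gaze_B:last_dwell_z",
]


def build_choice_gaze_design(
    trials: pd.DataFrame,
    gaze_stats: pd.DataFrame,
    q_trajectories: pd.DataFrame,
    group_values: pd.Series | dict,
    gaze_filter: str = "two_or_more",
) -> pd.DataFrame:
    """Trial-level design for the first-stage choice-vs-gaze regression.

    Dependent: symbol B chosen.  Predictors: hybrid Q-value difference,
    previous-trial B choice, first/last gaze on B, the last-gaze dwell
    time standardized within subject, and a per-subject group value
    (dummy or continuous w).  ``gaze_filter`` selects ``two_or_more``
    gazes or ``exactly_two`` (one gaze per symbol).  Trials dropped by the
    gaze pipeline are absent from ``gaze_stats`` and hence excluded.
    """
    if gaze_filter not in ("two_or_more", "exactly_two"):
        raise ValueError("gaze_filter must be 'two_or_more' or 'exactly_two'")
    merged = trials.merge(gaze_stats, on=["subject_id", "trial"], how="inner")
    merged = merged.merge(q_trajectories, on=["subject_id", "trial"], how="inner")
    rows = []
    for subject, grp in merged.groupby("subject_id", sort=False):
        grp = grp.sort_values("trial")
        dwell = grp["last_dwell"].to_numpy(dtype=float)
        mu, sd = np.nanmean(dwell), np.nanstd(dwell)
        dwell_z = (dwell - mu) / sd if sd > 0 else np.zeros_like(dwell)
        prev_choice = grp["a1"].shift(1)
        for i, (_, row) in enumerate(grp.iterrows()):
            if row["n_gazes"] < 2:
                continue
            if gaze_filter == "exactly_two" and not (
                row["n_gazes"] == 2 and row["unique_symbols_viewed"] == 2
            ):
                continue
            if pd.isna(prev_choice.iloc[i]):
                continue
            rows.append(
                {
                    "subject_id": subject,
                    "trial": int(row["trial"]),
                    "chose_B": int(row["a1"] == "B"),
                    "qdiff": float(row["qB_hybrid"] - row["qA_hybrid"]),
                    "prev_B": int(prev_choice.iloc[i] == "B"),
                    "first_gaze_B": int(row["first_symbol"] == "B"),
                    "last_gaze_B": int(row["last_symbol"] == "B"),
                    "last_dwell_z": float(dwell_z[i]),
                    "group": float(
                        group_values[subject]
                        if not isinstance(group_values, pd.Series)
                        else group_values.loc[subject]
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "trial", "chose_B", "qdiff", "prev_B",
            "first_gaze_B", "last_gaze_B", "last_dwell_z", "group",
        ],
    )


def fit_choice_regression(
    design: pd.DataFrame, terms: list[str] | None = None
) -> pd.DataFrame:
    """Pooled logit of the gaze-choice design with subject-clustered SEs.

    Used in place of the mixed-effects model because the design contains
    subject-constant predictors that per-subject fits cannot identify.
    """
    if terms is None:
        terms = CHOICE_TERMS
    X = _design_matrix(design, terms)
    y = design["chose_B"].to_numpy(dtype=float)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(
            cov_type="cluster", cov_kwds={"groups": design["subject_id"].to_numpy()}
        )
    out = pd.DataFrame(
        {
            "term": ["intercept"] + terms,
            "coef": res.params,
            "se": res.bse,
            "pvalue": res.pvalues,
        }
    )
    return out
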