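"""Behavioral read-outs: per-rule accuracy, learning criterion, go probability.

All metrics are computed over *eligible* trials — completed trials with a
defined match/non-match configuration — so the two rules are always scored on
identical trial sets.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from schema_mux.data import (
    CUE_REWARDED_ODORS,
    CUEID_RULE,
    GO,
    MATCH,
    NONMATCH,
    ODOR_IDS,
    eligible_trials,
    reward_flag,
)


@dataclasses.dataclass
class BehaviorSummary:
    """Per-session behavioral summary (one row of behavior_summary.csv)."""

    session_id: str
    accuracy_nm: float
    accuracy_ci: float
    trials_to_criterion_nm: int | None
    trials_to_criterion_ci: int | None
    go_prob_match: float
    go_prob_nonmatch: float
    n_eligible: int


def _correct(trials: pd.DataFrame, rule: str) -> np.ndarray:
    """Per-trial correctness under `rule`: go on rewarded, no-go on unrewarded."""
    flag = reward_flag(trials, rule).to_numpy()
    go = (trials["choice"] == GO).to_numpy()
    return (go & flag) | (~go & ~flag)


def accuracy_by_rule(trials: pd.DataFrame, rule: str) -> float:
    """Fraction of eligible trials on which the choice was correct under `rule`.

    Raises ``ValueError`` when no eligible trials exist.
    """
    elig = eligible_trials(trials)
    if len(elig) == 0:
        raise ValueError("no eligible trials to score")
    return float(_correct(elig, rule).mean())


def trials_to_criterion(
    trials: pd.DataFrame,
    rule: str,
    threshold: float = 0.80,
    window: int = 30,
) -> int | None:
    """First eligible-trial ordinal whose trailing-window accuracy reaches threshold.

    Returns the smallest t >= window such that the accuracy over eligible
    trials (t-window, t] is >= threshold, or None if the criterion is never
    reached.  The window trails (ends at) t.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    elig = eligible_trials(trials).sort_values("trial_index")
    correct = _correct(elig, rule).astype(int)
    if len(correct) < window:
        return None
    csum = np.concatenate([[0], np.cumsum(correct)])
    win_acc = (csum[window:] - csum[:-window]) / window
    hits = np.flatnonzero(win_acc >= threshold)
    return int(hits[0] + window) if hits.size else None


def go_probability_by_type(trials: pd.DataFrame) -> pd.DataFrame:
    """Go probability per (odor, configuration) trial type, with counts.

    Returns a 16-row DataFrame (odors 1-8 x match/nonmatch) with columns
    ``odor_id, config, n, go_prob``; cells with no eligible trials get
    ``go_prob = NaN`` (absent), never 0.
    """
    elig = eligible_trials(trials)
    rows = []
    for config in (MATCH, NONMATCH):
        for odor in ODOR_IDS:
            cell = elig[(elig["odor_id"] == odor) & (elig["config"] == config)]
            n = len(cell)
            p = float((cell["choice"] == GO).mean()) if n else np.nan
            rows.append({"odor_id": odor, "config": config, "n": n, "go_prob": p})
    return pd.DataFrame(rows)


def go_probability_by_config(trials: pd.DataFrame) -> tuple[float, float]:
    """(go probability on match trials, go probability on nonmatch trials)."""
    elig = eligible_trials(trials)
    out = []
    for config in (MATCH, NONMATCH):
        sub = elig[elig["config"] == config]
        out.append(float((sub["choice"] == GO).mean()) if len(sub) else np.nan)
    return out[0], out[1]


def config_error_bias(trials: pd.DataFrame) -> tuple[float, float]:
    """Go rates on error-relevant trials under the cue-identity rule.

    Restricted to cue-nonrewarded odors (where 'go' is always an error under
    the cue-identity rule), returns the go probability on non-match trials
    and on match trials.  A higher first element is the signature of residual
    non-match-rule influence on errors.  Cells with no trials return NaN.
    """
    elig = eligible_trials(trials)
    elig = elig[elig["rule_in_effect"] == CUEID_RULE]
    if len(elig) == 0:
        raise ValueError("config_error_bias requires cueid_rule trials")
    nonrew = elig[~elig["odor_id"].isin(CUE_REWARDED_ODORS)]
    out = []
    for config in (NONMATCH, MATCH):
        sub = nonrew[nonrew["config"] == config]
        out.append(float((sub["choice"] == GO).mean()) if len(sub) else np.nan)
    return out[0], out[1]


def summarize_session(trials: pd.DataFrame) -> BehaviorSummary:
    """Compute the full behavioral summary for one session."""
    p_match, p_nonmatch = go_probability_by_config(trials)
    return BehaviorSummary(
        session_id=str(trials["session_id"].iloc[0]),
        accuracy_nm=accuracy_by_rule(trials, "nonmatch_rule"),
        accuracy_ci=accuracy_by_rule(trials, "cueid_rule"),
        trials_to_criterion_nm=trials_to_criterion(trials, "nonmatch_rule"),
        trials_to_criterion_ci=trials_to_criterion(trials, "cueid_rule"),
        go_prob_match=p_match,
        go_prob_nonmatch=p_nonmatch,
        n_eligible=len(eligible_trials(trials)),
    )
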