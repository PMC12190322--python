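"""Brain-behavior coupling: decoder-behavior correlations and P(ignore).

Session-level couplings relate how well each rule can be read out of the
population (binary decoder accuracy) to how well the animal follows that
rule (behavioral accuracy).  The trial-level ignore-probability asks, on
*incongruent* trials (non-match configuration, cue-nonrewarded odor — the
two rules prescribe opposite actions), how often the animal withholds
despite the old-rule decoder flagging the trial as rewarded.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from schema_mux.data import CUE_REWARDED_ODORS, CUEID_RULE, NOGO, NONMATCH, eligible_trials


@dataclasses.dataclass
class SessionCoupling:
    """Per-session decoder and behavior accuracies plus held-out predictions."""

    session_id: str
    decoder_accuracy_nm: float
    decoder_accuracy_ci: float
    behavior_accuracy_nm: float
    behavior_accuracy_ci: float
    p_ignore: float | None = None
    n_ignore_denominator: int = 0


def decoder_behavior_correlation(
    sessions: list[SessionCoupling] | pd.DataFrame,
    decoder_rule: str = "nonmatch_rule",
    behavior_rule: str | None = None,
    method: str = "pearson",
) -> tuple[float, float, int]:
    """Correlation of decoder vs behavioral accuracy across sessions.

    ``behavior_rule`` defaults to ``decoder_rule``; passing the other rule
    gives the cross-rule variant.  ``method`` is ``pearson`` (default,
    matching the linear session plots) or ``spearman``.  Returns (r, p, n).
    Raises ``ValueError`` for fewer than 3 sessions or a zero-variance axis.
    """
    df = _as_frame(sessions)
    behavior_rule = behavior_rule or decoder_rule
    x = df[_col("decoder", decoder_rule)].to_numpy(dtype=float)
    y = df[_col("behavior", behavior_rule)].to_numpy(dtype=float)
    return _correlate(x, y, method)


def _col(kind: str, rule: str) -> str:
    suffix = {"nonmatch_rule": "nm", "cueid_rule": "ci"}[rule]
    return f"{kind}_accuracy_{suffix}"


def _as_frame(sessions) -> pd.DataFrame:
    if isinstance(sessions, pd.DataFrame):
        return sessions
    return pd.DataFrame([dataclasses.asdict(s) for s in sessions])


def _correlate(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> tuple[float, float, int]:
    if len(x) < 3:
        raise ValueError("need >= 3 sessions")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance on one axis; correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p), len(x)


def ignore_probability(
    trials: pd.DataFrame,
    nm_predictions: np.ndarray,
) -> tuple[float | None, int, int]:
    """Probability of ignoring the old rule's 'go' prediction.

    ``nm_predictions`` are held-out non-match-decoder labels (1 = predicted
    rewarded under the non-match rule) aligned with the session's eligible
    trials.  Among incongruent trials (non-match configuration AND
    cue-nonrewarded odor) that the decoder labels rewarded, returns the
    fraction on which the animal chose no-go, with (numerator, denominator)
    counts.  Returns (None, 0, 0) when the denominator is empty.
    """
    elig = eligible_trials(trials)
    if not (elig["rule_in_effect"] == CUEID_RULE).all():
        raise ValueError("ignore probability is defined for cueid_rule sessions")
    preds = np.asarray(nm_predictions).astype(int)
    if len(preds) != len(elig):
        raise ValueError("predictions must align with eligible trials")
    incongruent = (
        (elig["config"] == NONMATCH)
        & ~elig["odor_id"].isin(CUE_REWARDED_ODORS)
    ).to_numpy()
    flagged = incongruent & (preds == 1)
    denom = int(flagged.sum())
    if denom == 0:
        return None, 0, 0
    withheld = flagged & (elig["choice"] == NOGO).to_numpy()
    num = int(withheld.sum())
    return num / denom, num, denom


def fidelity_ignore_correlation(
    sessions: list[SessionCoupling] | pd.DataFrame,
    method: str = "pearson",
) -> tuple[float, float, int]:
    """Correlation between old-rule decoder fidelity and P(ignore).

    Pearson correlation across sessions between the non-match decoder's
    accuracy and the probability of ignoring its 'go' prediction; a positive
    r is the facilitation direction (a more faithful old-rule representation
    accompanies more expert ignoring of it).
    """
    df = _as_frame(sessions)
    df = df[df["p_ignore"].notna()]
    x = df["decoder_accuracy_nm"].to_numpy(dtype=float)
    y = df["p_ignore"].to_numpy(dtype=float)
    return _correlate(x, y, method)
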