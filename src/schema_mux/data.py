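"""Shared data model: trial tables, spike-train sets, aligned count tensors.

A *trial table* is a pandas DataFrame with one row per trial and a fixed
column schema (see :data:`TRIAL_COLUMNS`).  It is the join key for every
analysis stage.  A *spike-train set* holds per-unit spike timestamps for one
session, in session-relative seconds.  An *aligned counts* tensor holds
units x trials x time-bins spike counts around an alignment event.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

#: Odor identities within one odor set.
ODOR_IDS = tuple(range(1, 9))

#: Odors rewarded under the cue-identity rule (the "go" odors).
CUE_REWARDED_ODORS = frozenset({1, 2, 3, 4})

NONMATCH_RULE = "nonmatch_rule"
CUEID_RULE = "cueid_rule"
RULES = (NONMATCH_RULE, CUEID_RULE)

MATCH = "match"
NONMATCH = "nonmatch"
UNDEFINED = "undefined"

GO = "go"
NOGO = "nogo"

#: Required trial-table columns, in canonical order.
TRIAL_COLUMNS = (
    "session_id",
    "rat_id",
    "trial_index",
    "odor_id",
    "odor_set",
    "config",
    "rule_in_effect",
    "reward_by_nonmatch",
    "reward_by_cueid",
    "choice",
    "outcome",
    "t_trial_start",
    "t_poke_in",
    "t_odor_on",
    "t_unpoke",
    "t_well",
    "completed",
)

ALIGN_EVENT_COLUMNS = {
    "unpoke": "t_unpoke",
    "trial_start": "t_trial_start",
    "poke_in": "t_poke_in",
}


class TrialTableFormatError(ValueError):
    """A trial table file or frame does not conform to the schema."""


class TrialTableConsistencyError(ValueError):
    """A trial table violates a cross-column invariant."""


def recompute_config(trials: pd.DataFrame) -> pd.Series:
    """Recompute the match/non-match configuration from the odor sequence.

    The configuration compares each completed trial's odor with the previous
    *completed* trial's odor; aborted trials deliver the odor only partially
    and do not advance the comparison.  The first completed trial of a
    session, and every non-completed trial, get ``undefined``.
    """
    trials = trials.sort_values("trial_index")
    config = pd.Series(UNDEFINED, index=trials.index, dtype=object)
    completed = trials["completed"].astype(bool)
    odors = trials.loc[completed, "odor_id"].to_numpy()
    idx = trials.index[completed]
    if len(odors) > 1:
        same = odors[1:] == odors[:-1]
        config.loc[idx[1:]] = np.where(same, MATCH, NONMATCH)
    return config.reindex(trials.index)


def reward_flag(trials: pd.DataFrame, rule: str) -> pd.Series:
    """Boolean series: would a 'go' be rewarded on each trial under `rule`."""
    if rule == NONMATCH_RULE:
        return trials["reward_by_nonmatch"].astype(bool)
    if rule == CUEID_RULE:
        return trials["reward_by_cueid"].astype(bool)
    raise ValueError(f"unknown rule: {rule!r}")


def fill_derived_columns(trials: pd.DataFrame) -> pd.DataFrame:
    """Fill config, reward flags, and outcome from the primitive columns."""
    out = trials.copy()
    out["config"] = recompute_config(out)
    out["reward_by_nonmatch"] = out["config"] == NONMATCH
    out["reward_by_cueid"] = out["odor_id"].isin(CUE_REWARDED_ODORS)
    rewarded = (out["choice"] == GO) & out.apply(
        lambda r: r["reward_by_nonmatch"]
        if r["rule_in_effect"] == NONMATCH_RULE
        else r["reward_by_cueid"],
        axis=1,
    )
    out["outcome"] = np.where(rewarded, "rewarded", "none")
    return out


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table against the schema and its invariants.

    Returns the table with columns in canonical order.  Raises
    :class:`TrialTableFormatError` on schema problems and
    :class:`TrialTableConsistencyError` on invariant violations, naming the
    offending trial where applicable.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise TrialTableFormatError(f"trial table missing columns: {missing}")
    trials = trials[list(TRIAL_COLUMNS)].copy()

    if not trials["odor_id"].isin(ODOR_IDS).all():
        bad = trials.loc[~trials["odor_id"].isin(ODOR_IDS), "trial_index"].tolist()
        raise TrialTableConsistencyError(f"odor_id outside 1-8 on trials {bad}")

    expected = recompute_config(trials)
    mismatch = trials["config"].astype(str) != expected
    if mismatch.any():
        first = trials.loc[mismatch, "trial_index"].iloc[0]
        raise TrialTableConsistencyError(
            f"stored config contradicts recomputed config at trial_index {first}"
        )

    if (trials["reward_by_nonmatch"].astype(bool) != (trials["config"] == NONMATCH)).any():
        raise TrialTableConsistencyError("reward_by_nonmatch inconsistent with config")
    if (
        trials["reward_by_cueid"].astype(bool)
        != trials["odor_id"].isin(CUE_REWARDED_ODORS)
    ).any():
        raise TrialTableConsistencyError("reward_by_cueid inconsistent with odor_id")

    flag = np.where(
        trials["rule_in_effect"] == NONMATCH_RULE,
        trials["reward_by_nonmatch"].astype(bool),
        trials["reward_by_cueid"].astype(bool),
    )
    rewarded = (trials["choice"] == GO) & flag
    if ((trials["outcome"] == "rewarded") != rewarded).any():
        bad = trials.loc[(trials["outcome"] == "rewarded") != rewarded, "trial_index"]
        raise TrialTableConsistencyError(
            f"outcome inconsistent with choice and rule at trial_index {bad.iloc[0]}"
        )

    comp = trials["completed"].astype(bool)
    t = trials.loc[comp]
    ordered = (
        (t["t_trial_start"] < t["t_poke_in"])
        & (t["t_poke_in"] < t["t_odor_on"])
        & (t["t_odor_on"] < t["t_unpoke"])
    )
    if not ordered.all():
        bad = t.loc[~ordered, "trial_index"].iloc[0]
        raise TrialTableConsistencyError(
            f"event timestamps out of order at trial_index {bad}"
        )
    return trials


def eligible_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Completed trials with a defined match/non-match configuration.

    This is the trial set every rule-conditioned analysis operates on, so the
    two rules are always scored on identical trials.
    """
    return trials[(trials["completed"].astype(bool)) & (trials["config"] != UNDEFINED)]


@dataclasses.dataclass
class SpikeTrainSet:
    """Per-unit spike timestamps for one session.

    Spike times are session-relative seconds, sorted and nonnegative; unit
    ids are unique within the session.
    """

    session_id: str
    units: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for uid, times in self.units.items():
            arr = np.asarray(times, dtype=float)
            if arr.size and arr.min() < 0:
                raise ValueError(f"unit {uid}: negative spike time")
            clean[str(uid)] = np.sort(arr)
        self.units = clean

    @property
    def unit_ids(self) -> list[str]:
        return list(self.units)

    @property
    def n_units(self) -> int:
        return len(self.units)

    def __len__(self) -> int:
        return len(self.units)


@dataclasses.dataclass
class AlignedCounts:
    """Spike-count tensor units x trials x bins around an alignment event.

    ``bin_edges`` are seconds relative to the event; bins are half-open
    ``[edge_b, edge_{b+1})``.  Only completed trials are included.
    """

    unit_ids: list[str]
    trial_indices: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    align_event: str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        expected = (len(self.unit_ids), len(self.trial_indices), len(self.bin_edges) - 1)
        if self.counts.shape != expected:
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with ids/edges {expected}"
            )
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, widths[0]):
            raise ValueError("bin width must be constant")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def unit(self, unit_id: str) -> np.ndarray:
        """Trials x bins count matrix for one unit."""
        return self.counts[self.unit_ids.index(unit_id)]
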