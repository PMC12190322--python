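"""Shared fixtures: hand-built trial tables and small planted scenarios."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from schema_mux.data import (
    CUE_REWARDED_ODORS,
    GO,
    NOGO,
    TRIAL_COLUMNS,
    fill_derived_columns,
)


def build_trials(
    odors,
    choices=None,
    rule="nonmatch_rule",
    completed=None,
    session_id="s01",
) -> pd.DataFrame:
    """Construct a minimal valid trial table from an odor sequence.

    Timestamps follow the task's event chain with fixed spacings; choices
    default to no-go.  Derived columns (config, reward flags, outcome) are
    filled from the primitives.
    """
    n = len(odors)
    if choices is None:
        choices = [NOGO] * n
    if completed is None:
        completed = [True] * n
    t_start = 2.0 + 8.0 * np.arange(n)
    t_poke = t_start + 0.8
    t_odor = t_poke + 0.5
    t_unpoke = t_odor + 0.6
    t_well = t_unpoke + 0.5
    df = pd.DataFrame(
        {
            "session_id": session_id,
            "rat_id": "rat01",
            "trial_index": np.arange(1, n + 1),
            "odor_id": list(odors),
            "odor_set": "A",
            "config": "undefined",
            "rule_in_effect": rule,
            "reward_by_nonmatch": False,
            "reward_by_cueid": False,
            "choice": list(choices),
            "outcome": "none",
            "t_trial_start": t_start,
            "t_poke_in": t_poke,
            "t_odor_on": t_odor,
            "t_unpoke": t_unpoke,
            "t_well": t_well,
            "completed": list(completed),
        }
    )
    return fill_derived_columns(df)[list(TRIAL_COLUMNS)]


def odor_sequence_with_configs(configs, rng=None):
    """Odor sequence whose defined-config pattern matches `configs`.

    ``configs`` is a sequence of 'match'/'nonmatch' for trials 2..n+1; trial
    1 is prepended (undefined).
    """
    rng = rng or np.random.default_rng(0)
    odors = [int(rng.integers(1, 9))]
    for c in configs:
        if c == "match":
            odors.append(odors[-1])
        else:
            others = [o for o in range(1, 9) if o != odors[-1]]
            odors.append(int(rng.choice(others)))
    return odors


@pytest.fixture(scope="session")
def nm_expert_session():
    """One non-match-expert session: 300 trials, 40 units, planted 25% nm gain."""
    from schema_mux.simulate import Scenario, make_scenario

    return make_scenario(
        Scenario("nm_expert", n_sessions=1, n_trials_per_session=300, n_units=40, seed=42)
    )[0]


@pytest.fixture(scope="session")
def nm_expert_features(nm_expert_session):
    """Eligible-trial response-rate features and trial-type labels for it."""
    from schema_mux.binning import response_rates
    from schema_mux.data import eligible_trials
    from schema_mux.geometry import trial_type_index

    s = nm_expert_session
    elig = eligible_trials(s["trials"])
    X = response_rates(s["spikes"], s["trials"]).loc[elig["trial_index"].to_numpy()]
    labels = trial_type_index(elig["odor_id"], elig["config"])
    return s["trials"], X.to_numpy(), labels
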