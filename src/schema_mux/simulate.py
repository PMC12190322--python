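"""Synthetic task, agent, and Poisson-population generator.

Stands in for the recorded dataset: 8-odor go/no-go sessions governed by two
orthogonal reward rules, behavioral agents whose choices mix the two rules
(with optional trial-by-trial learning), and populations of units whose
firing carries configurable amounts of odor-identity, match/non-match-state,
cue-identity-reward, and choice information with Poisson noise.

Timing emulates the behavioral apparatus: a nose-poke is followed by a 500 ms
delay before odor onset, the animal must sample for at least 300 ms, and a
4-second light-off inter-trial interval follows each trial.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from os import PathLike
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from schema_mux.data import (
    CUE_REWARDED_ODORS,
    CUEID_RULE,
    GO,
    MATCH,
    NOGO,
    NONMATCH,
    NONMATCH_RULE,
    ODOR_IDS,
    TRIAL_COLUMNS,
    SpikeTrainSet,
    fill_derived_columns,
)
from schema_mux.io import write_spike_table, write_trial_table

ODOR_DELAY = 0.5  # s, poke-in to odor onset
ITI_LIGHT_OFF = 4.0  # s


@dataclasses.dataclass
class AgentPolicy:
    """Logistic go/no-go policy mixing the two rule evidences.

    go-probability = lapse/2 + (1-lapse) * logistic(bias + w_nm*x_nm + w_ci*x_ci)
    with x_nm = +1 on non-match / -1 on match trials (0 when undefined) and
    x_ci = +1 on cue-rewarded odors / -1 otherwise.  ``lr_nm``/``lr_ci`` are
    delta-rule learning rates applied when simulating with learning on.
    """

    w_nm: float = 0.0
    w_ci: float = 0.0
    bias: float = 0.0
    lapse: float = 0.0
    lr_nm: float = 0.0
    lr_ci: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must be in [0, 1]")
        if self.lr_nm < 0 or self.lr_ci < 0:
            raise ValueError("learning rates must be >= 0")

    def go_probability(self, x_nm: np.ndarray, x_ci: np.ndarray) -> np.ndarray:
        p = expit(self.bias + self.w_nm * np.asarray(x_nm) + self.w_ci * np.asarray(x_ci))
        return self.lapse / 2.0 + (1.0 - self.lapse) * p


@dataclasses.dataclass
class NeuralModel:
    """Poisson population with multiplicative mixed-selectivity gains.

    Each unit fires at ``baseline_hz`` outside the odor-sampling period.
    Within it the rate is baseline x odor_gain[odor] x nm_gain (non-match
    trials only) x ci_gain (cue-rewarded odors only) x choice_gain (go trials
    only).  Gains of 1 mean no modulation; gains multiply, which keeps rates
    nonnegative and makes planted standardized effects predictable.
    """

    baseline_hz: np.ndarray
    odor_gain: np.ndarray  # (n_units, 8)
    nm_gain: np.ndarray
    ci_gain: np.ndarray
    choice_gain: np.ndarray

    def __post_init__(self) -> None:
        self.baseline_hz = np.asarray(self.baseline_hz, dtype=float)
        self.odor_gain = np.asarray(self.odor_gain, dtype=float)
        self.nm_gain = np.asarray(self.nm_gain, dtype=float)
        self.ci_gain = np.asarray(self.ci_gain, dtype=float)
        self.choice_gain = np.asarray(self.choice_gain, dtype=float)
        n = self.n_units
        if self.odor_gain.shape != (n, 8):
            raise ValueError("odor_gain must have shape (n_units, 8)")
        for name in ("nm_gain", "ci_gain", "choice_gain"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have shape (n_units,)")
        if (self.baseline_hz <= 0).any():
            raise ValueError("baseline rates must be positive")

    @property
    def n_units(self) -> int:
        return len(self.baseline_hz)

    @property
    def nm_selective_mask(self) -> np.ndarray:
        return self.nm_gain != 1.0

    @property
    def ci_selective_mask(self) -> np.ndarray:
        return self.ci_gain != 1.0

    @classmethod
    def sample(
        cls,
        n_units: int,
        rng: np.random.Generator,
        baseline_hz: float = 8.0,
        odor_tuning_sd: float = 0.15,
        frac_nm: float = 0.0,
        nm_gain: float = 2.0,
        frac_ci: float = 0.0,
        ci_gain: float = 2.0,
        frac_choice: float = 0.0,
        choice_gain: float = 1.5,
        suppressed_fraction: float = 0.5,
    ) -> "NeuralModel":
        """Draw a random population with planted selective fractions.

        Selected units receive the stated gain; among them a
        ``suppressed_fraction`` get the reciprocal gain (suppressed
        responses), mirroring the enhanced/suppressed mixture of real
        populations.  Non-selected units keep gain 1.
        """
        base = baseline_hz * rng.lognormal(0.0, 0.3, size=n_units)
        odor = rng.lognormal(0.0, odor_tuning_sd, size=(n_units, 8))

        def planted(frac: float, gain: float) -> np.ndarray:
            g = np.ones(n_units)
            k = int(round(frac * n_units))
            sel = rng.choice(n_units, size=k, replace=False)
            n_sup = int(round(suppressed_fraction * k))
            sup = rng.choice(sel, size=n_sup, replace=False) if k else np.array([], int)
            g[sel] = gain
            g[sup] = 1.0 / gain
            return g

        return cls(
            baseline_hz=base,
            odor_gain=odor,
            nm_gain=planted(frac_nm, nm_gain),
            ci_gain=planted(frac_ci, ci_gain),
            choice_gain=planted(frac_choice, choice_gain),
        )


def generate_trial_sequence(
    n_trials: int,
    rule: str = NONMATCH_RULE,
    seed: int = 0,
    p_repeat: float = 0.5,
    session_id: str = "s01",
    rat_id: str = "rat01",
    odor_set: str = "A",
) -> pd.DataFrame:
    """Generate a trial-table skeleton (odors, timing, rule; no choices yet).

    At each step the previous odor repeats with probability ``p_repeat``
    (producing a match trial), otherwise a uniformly random *different* odor
    is drawn.  The default 0.5 balances match and non-match trials so all 16
    trial types are populated.  Choices are initialized to no-go.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    if not 0.0 < p_repeat < 1.0:
        raise ValueError("p_repeat must be in (0, 1)")
    if rule not in (NONMATCH_RULE, CUEID_RULE):
        raise ValueError(f"unknown rule {rule!r}")
    rng = np.random.default_rng(seed)

    odors = np.empty(n_trials, dtype=int)
    odors[0] = rng.choice(ODOR_IDS)
    for i in range(1, n_trials):
        if rng.random() < p_repeat:
            odors[i] = odors[i - 1]
        else:
            others = [o for o in ODOR_IDS if o != odors[i - 1]]
            odors[i] = rng.choice(others)

    # event chain per trial; session-relative seconds
    poke_lat = rng.uniform(0.4, 1.2, size=n_trials)
    sampling = rng.uniform(0.5, 0.8, size=n_trials)  # >= 300 ms minimum hold
    well_lat = rng.uniform(0.4, 0.8, size=n_trials)
    iti_jitter = rng.uniform(0.0, 0.5, size=n_trials)

    t_start = np.empty(n_trials)
    t_start[0] = 2.0
    t_poke = np.empty(n_trials)
    t_odor = np.empty(n_trials)
    t_unpoke = np.empty(n_trials)
    t_well = np.empty(n_trials)
    for i in range(n_trials):
        t_poke[i] = t_start[i] + poke_lat[i]
        t_odor[i] = t_poke[i] + ODOR_DELAY
        t_unpoke[i] = t_odor[i] + sampling[i]
        t_well[i] = t_unpoke[i] + well_lat[i]
        if i + 1 < n_trials:
            t_start[i + 1] = t_well[i] + ITI_LIGHT_OFF + iti_jitter[i]

    df = pd.DataFrame(
        {
            "session_id": session_id,
            "rat_id": rat_id,
            "trial_index": np.arange(1, n_trials + 1),
            "odor_id": odors,
            "odor_set": odor_set,
            "config": "undefined",
            "rule_in_effect": rule,
            "reward_by_nonmatch": False,
            "reward_by_cueid": False,
            "choice": NOGO,
            "outcome": "none",
            "t_trial_start": t_start,
            "t_poke_in": t_poke,
            "t_odor_on": t_odor,
            "t_unpoke": t_unpoke,
            "t_well": t_well,
            "completed": True,
        }
    )
    return fill_derived_columns(df)[list(TRIAL_COLUMNS)]


def simulate_choices(
    trials: pd.DataFrame,
    policy: AgentPolicy,
    seed: int = 0,
    learn: bool = False,
) -> tuple[pd.DataFrame, AgentPolicy]:
    """Draw a go/no-go choice per trial from the agent policy.

    With ``learn=True`` the rule weights are updated after every trial by a
    delta rule toward the action rewarded under the rule in effect:
    ``w += lr * (target - p_go) * x`` with target 1 on rule-rewarded trials.
    Returns the completed trial table and the (possibly updated) policy.
    """
    out = trials.copy()
    x_nm = np.where(
        out["config"] == NONMATCH, 1.0, np.where(out["config"] == MATCH, -1.0, 0.0)
    )
    x_ci = np.where(out["odor_id"].isin(CUE_REWARDED_ODORS), 1.0, -1.0)
    rng = np.random.default_rng(seed)

    if learn:
        pol = dataclasses.replace(policy)
        target = np.where(
            out["rule_in_effect"] == NONMATCH_RULE,
            out["reward_by_nonmatch"].astype(float),
            out["reward_by_cueid"].astype(float),
        )
        go = np.empty(len(out), dtype=bool)
        for i in range(len(out)):
            p = float(pol.go_probability(x_nm[i], x_ci[i]))
            go[i] = rng.random() < p
            pol.w_nm += pol.lr_nm * (target[i] - p) * x_nm[i]
            pol.w_ci += pol.lr_ci * (target[i] - p) * x_ci[i]
        final = pol
    else:
        p_go = policy.go_probability(x_nm, x_ci)
        go = rng.random(len(out)) < p_go
        final = policy

    out["choice"] = np.where(go, GO, NOGO)
    return fill_derived_columns(out)[list(TRIAL_COLUMNS)], final


def simulate_spikes(
    trials: pd.DataFrame,
    model: NeuralModel,
    seed: int = 0,
) -> SpikeTrainSet:
    """Draw inhomogeneous-Poisson spike trains for every unit.

    The rate is piecewise constant: baseline everywhere except during the
    odor-sampling period (odor onset to un-poke) of each completed trial,
    where the multiplicative gains of :class:`NeuralModel` apply.  Rates that
    would fall below zero are floored at zero with a warning counter.
    """
    rng = np.random.default_rng(seed)
    comp = trials[trials["completed"].astype(bool)].sort_values("trial_index")
    t_on = comp["t_odor_on"].to_numpy(dtype=float)
    t_off = comp["t_unpoke"].to_numpy(dtype=float)
    odor_idx = comp["odor_id"].to_numpy(dtype=int) - 1
    is_nm = (comp["config"] == NONMATCH).to_numpy()
    is_ci = comp["odor_id"].isin(CUE_REWARDED_ODORS).to_numpy()
    is_go = (comp["choice"] == GO).to_numpy()

    span_start = comp["t_trial_start"].min() - 1.5
    span_end = t_off.max() + 1.0
    # interleave: gap before trial 1, window 1, gap, window 2, ..., final gap
    seg_starts = np.empty(2 * len(comp) + 1)
    seg_ends = np.empty_like(seg_starts)
    seg_starts[0] = span_start
    seg_starts[1::2] = t_on
    seg_starts[2::2] = t_off
    seg_ends[-1] = span_end
    seg_ends[:-1:2] = t_on
    seg_ends[1::2] = t_off
    durations = seg_ends - seg_starts
    in_window = np.zeros(len(seg_starts), dtype=bool)
    in_window[1::2] = True

    n_floored = 0
    units: dict[str, np.ndarray] = {}
    for u in range(model.n_units):
        mod = (
            model.odor_gain[u, odor_idx]
            * np.where(is_nm, model.nm_gain[u], 1.0)
            * np.where(is_ci, model.ci_gain[u], 1.0)
            * np.where(is_go, model.choice_gain[u], 1.0)
        )
        rates = np.full(len(seg_starts), model.baseline_hz[u])
        rates[1::2] = model.baseline_hz[u] * mod
        n_floored += int((rates < 0).sum())
        rates = np.clip(rates, 0.0, None)
        counts = rng.poisson(rates * durations)
        times = np.repeat(seg_starts, counts) + rng.random(counts.sum()) * np.repeat(
            durations, counts
        )
        units[f"u{u:03d}"] = np.sort(times)
    if n_floored:
        warnings.warn(f"{n_floored} negative segment rates floored to 0", stacklevel=2)
    sid = str(comp["session_id"].iloc[0]) if len(comp) else "session"
    return SpikeTrainSet(session_id=sid, units=units)


SCENARIO_NAMES = ("naive", "nm_expert", "switch", "control_cueid")


@dataclasses.dataclass
class Scenario:
    """A named training regime: per-session agent policies and neural gains.

    The four named scenarios reproduce the study's regimes: ``naive``
    (untrained, indiscriminate responding), ``nm_expert`` (trained on the
    non-match rule), ``switch`` (non-match training followed by cue-identity
    sessions, with the non-match signal fading but persisting), and
    ``control_cueid`` (trained solely on the cue-identity rule; no non-match
    signal at all).
    """

    name: str
    n_sessions: int = 3
    n_trials_per_session: int = 300
    n_units: int = 40
    seed: int = 0
    p_repeat: float = 0.5
    baseline_hz: float = 8.0
    odor_tuning_sd: float = 0.15
    frac_selective: float = 0.25
    rule_gain: float = 2.2

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.name!r}; options {SCENARIO_NAMES}")

    def session_rule(self, s: int) -> str:
        return NONMATCH_RULE if self.name in ("naive", "nm_expert") else CUEID_RULE

    def session_policy(self, s: int) -> AgentPolicy:
        if self.name == "naive":
            return AgentPolicy(bias=3.0, lapse=0.05)
        if self.name == "nm_expert":
            return AgentPolicy(w_nm=4.0, lapse=0.05)
        if self.name == "switch":
            # residual non-match weight decays as cue-id compliance grows
            frac = s / max(self.n_sessions - 1, 1)
            return AgentPolicy(w_ci=4.0, w_nm=1.2 * (1.0 - 0.6 * frac), lapse=0.05)
        return AgentPolicy(w_ci=4.0, lapse=0.05)  # control_cueid

    def session_gains(self, s: int) -> dict[str, float]:
        g = self.rule_gain
        if self.name == "naive":
            return {"frac_nm": 0.0, "nm_gain": 1.0, "frac_ci": 0.0, "ci_gain": 1.0}
        if self.name == "nm_expert":
            return {"frac_nm": self.frac_selective, "nm_gain": g, "frac_ci": 0.0, "ci_gain": 1.0}
        if self.name == "switch":
            # non-match gain fades across cue-id sessions but persists
            frac = s / max(self.n_sessions - 1, 1)
            return {
                "frac_nm": self.frac_selective,
                "nm_gain": 1.0 + (g - 1.0) * (1.0 - 0.4 * frac),
                "frac_ci": self.frac_selective,
                "ci_gain": g,
            }
        return {"frac_nm": 0.0, "nm_gain": 1.0, "frac_ci": self.frac_selective, "ci_gain": g}


def make_scenario(
    scenario: Scenario | str,
    out_dir: str | PathLike | None = None,
    seed: int | None = None,
) -> list[dict]:
    """Generate the sessions of a named scenario.

    Returns a list of session dicts with keys ``trials`` (trial table),
    ``spikes`` (:class:`SpikeTrainSet`), ``model`` (:class:`NeuralModel`) and
    ``session_id``.  If ``out_dir`` is given, each session is written as
    ``session_XX/trials.csv`` + ``session_XX/spikes.csv``, with a
    ``ground_truth.json`` of planted parameters for recovery tests.
    """
    if isinstance(scenario, str):
        scenario = Scenario(name=scenario, seed=seed if seed is not None else 0)
    elif seed is not None:
        scenario = dataclasses.replace(scenario, seed=seed)

    sessions = []
    truth: dict = {"scenario": scenario.name, "seed": scenario.seed, "sessions": []}
    for s in range(scenario.n_sessions):
        base = scenario.seed + 101 * s  # fixed per-session offsets
        sid = f"session_{s + 1:02d}"
        trials = generate_trial_sequence(
            scenario.n_trials_per_session,
            rule=scenario.session_rule(s),
            seed=base,
            p_repeat=scenario.p_repeat,
            session_id=sid,
            rat_id=f"rat_{scenario.name}",
        )
        policy = scenario.session_policy(s)
        trials, _ = simulate_choices(trials, policy, seed=base + 1)
        gains = scenario.session_gains(s)
        rng = np.random.default_rng(base + 2)
        model = NeuralModel.sample(
            scenario.n_units,
            rng,
            baseline_hz=scenario.baseline_hz,
            odor_tuning_sd=scenario.odor_tuning_sd,
            **gains,
        )
        spikes = simulate_spikes(trials, model, seed=base + 3)
        sessions.append(
            {"session_id": sid, "trials": trials, "spikes": spikes, "model": model}
        )
        truth["sessions"].append(
            {
                "session_id": sid,
                "rule": scenario.session_rule(s),
                "policy": dataclasses.asdict(policy),
                "gains": gains,
                "nm_selective_units": np.flatnonzero(model.nm_selective_mask).tolist(),
                "ci_selective_units": np.flatnonzero(model.ci_selective_mask).tolist(),
                "nm_gain_per_unit": model.nm_gain.tolist(),
                "ci_gain_per_unit": model.ci_gain.tolist(),
            }
        )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sess in sessions:
            d = out / sess["session_id"]
            write_trial_table(sess["trials"], d / "trials.csv")
            write_spike_table(sess["spikes"], d / "spikes.csv")
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
    return sessions
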