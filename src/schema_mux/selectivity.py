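"""Per-unit response characterization and rule-selectivity testing.

The responsiveness and selectivity tests are "ZETA-style" temporal-deviation
permutation tests: the statistic is the maximum absolute deviation of the
cumulative spike count over the analysis window from its null expectation
(a uniform-rate line, or the other condition's cumulative), and the null
distribution is built by permutation — circular per-trial shifts for
responsiveness, condition-label permutation for selectivity.  Permutation
p-values use the add-one rule p = (1 + #{T_perm >= T_obs}) / (1 + n_perm),
so the smallest attainable p is 1/(n_perm + 1).
"""

from __future__ import annotations

import dataclasses
from itertools import combinations

import numpy as np
import pandas as pd

from schema_mux.binning import align_counts, baseline_rates, response_rates
from schema_mux.data import (
    AlignedCounts,
    SpikeTrainSet,
    eligible_trials,
    reward_flag,
)

EPS_BASELINE_SD = 1e-9


class InsufficientData(ValueError):
    """Too few trials (or an empty condition) to run a test."""


def smooth_uniform(trace: np.ndarray, size: int = 5) -> np.ndarray:
    """Moving-average smoothing with a uniform window, truncated at the edges.

    Interior bins average `size` neighbors; edge bins average only the bins
    that exist (truncated support), so a constant trace is a fixed point.
    """
    trace = np.asarray(trace, dtype=float)
    kernel = np.ones(size)
    num = np.convolve(trace, kernel, mode="same")
    den = np.convolve(np.ones_like(trace), kernel, mode="same")
    return num / den


def compute_psth(
    counts: AlignedCounts,
    condition_masks: dict[str, np.ndarray] | None = None,
    smooth_bins: int = 5,
) -> dict[str, np.ndarray]:
    """Smoothed PSTH (Hz) per condition, for every unit.

    Mean spike count per bin across the condition's trials, divided by the
    bin width, then smoothed with a 5-bin uniform moving average.  Returns a
    mapping condition -> (units x bins) array; empty conditions are absent.
    """
    if condition_masks is None:
        condition_masks = {"all": np.ones(len(counts.trial_indices), dtype=bool)}
    out: dict[str, np.ndarray] = {}
    for name, mask in condition_masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() == 0:
            continue
        rate = counts.counts[:, mask, :].mean(axis=1) / counts.bin_width
        out[name] = np.apply_along_axis(smooth_uniform, 1, rate, smooth_bins)
    return out


def zscore_by_condition(
    resp_rates_: np.ndarray,
    base_rates_: np.ndarray,
    is_rewarded: np.ndarray,
) -> tuple[float, float]:
    """Standardized response per reward condition, for one unit.

    z_c = (mean response-window rate over condition-c trials - mean baseline
    rate over all trials) / SD of per-trial baseline rates.  The SD is
    computed across *all* trials so both conditions share one normalizer
    (required for the delta z-score's antisymmetry).  Returns NaN for both
    when the baseline SD is below floor (degenerate unit).
    """
    resp = np.asarray(resp_rates_, dtype=float)
    base = np.asarray(base_rates_, dtype=float)
    is_rewarded = np.asarray(is_rewarded, dtype=bool)
    if is_rewarded.sum() < 2 or (~is_rewarded).sum() < 2:
        raise InsufficientData("need >= 2 trials per condition")
    sd = base.std(ddof=1)
    if sd < EPS_BASELINE_SD:
        return (np.nan, np.nan)
    mu = base.mean()
    z_rew = (resp[is_rewarded].mean() - mu) / sd
    z_non = (resp[~is_rewarded].mean() - mu) / sd
    return (float(z_rew), float(z_non))


def delta_zscore(
    resp_rates_: np.ndarray,
    base_rates_: np.ndarray,
    is_rewarded: np.ndarray,
) -> float:
    """Rewarded-minus-nonrewarded standardized response (delta z-score)."""
    z_rew, z_non = zscore_by_condition(resp_rates_, base_rates_, is_rewarded)
    return z_rew - z_non


def responsiveness_test(
    counts2d: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Temporal-deviation permutation test for an evoked response.

    The statistic is the maximum absolute deviation of the pooled cumulative
    spike fraction across the window's bins from the uniform-rate line.  The
    null is built by circularly shifting each trial's bin counts by an
    independent uniform offset, which preserves each trial's spike count but
    destroys trial-locked timing.
    """
    counts2d = np.asarray(counts2d)
    n_trials, n_bins = counts2d.shape
    if n_trials < 10:
        raise InsufficientData("responsiveness test needs >= 10 trials")
    total = counts2d.sum(axis=0)
    n_spikes = total.sum()
    if n_spikes == 0:
        return 1.0
    uniform = np.arange(1, n_bins + 1) / n_bins
    t_obs = np.abs(np.cumsum(total) / n_spikes - uniform).max()

    rng = np.random.default_rng(seed)
    shifts = rng.integers(0, n_bins, size=(n_perm, n_trials))
    idx = (np.arange(n_bins)[None, None, :] - shifts[:, :, None]) % n_bins
    shifted = np.take_along_axis(
        np.broadcast_to(counts2d, (n_perm, n_trials, n_bins)), idx, axis=2
    )
    pooled = shifted.sum(axis=1)
    t_perm = np.abs(np.cumsum(pooled, axis=1) / n_spikes - uniform[None, :]).max(axis=1)
    return float((1 + (t_perm >= t_obs).sum()) / (1 + n_perm))


def _two_sample_stat(cum: np.ndarray, mask: np.ndarray) -> float:
    n1 = int(mask.sum())
    n0 = len(mask) - n1
    f1 = cum[mask].sum(axis=0) / n1
    f0 = cum[~mask].sum(axis=0) / n0
    return float(np.abs(f1 - f0).max())


def condition_selectivity_test(
    counts2d: np.ndarray,
    is_rewarded: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    exact: bool = False,
) -> float:
    """Two-sample temporal-deviation permutation test between conditions.

    D = max over bins of |F_rew(b) - F_nonrew(b)| where F_c is the
    condition's cumulative spike count over the window normalized by that
    condition's trial count (so both timing and rate differences register).
    The null permutes the trial condition labels.  With ``exact=True`` all
    distinct label assignments are enumerated and the p-value is the exact
    fraction of assignments with D >= D_obs (feasible for small trial
    counts).
    """
    counts2d = np.asarray(counts2d)
    mask = np.asarray(is_rewarded, dtype=bool)
    n_trials = len(mask)
    if counts2d.shape[0] != n_trials:
        raise ValueError("counts and labels disagree on trial count")
    n_rew = int(mask.sum())
    if n_rew == 0 or n_rew == n_trials:
        raise InsufficientData("one condition is empty")
    if not exact and (n_rew < 5 or n_trials - n_rew < 5):
        raise InsufficientData("need >= 5 trials per condition")

    cum = np.cumsum(counts2d, axis=1)
    d_obs = _two_sample_stat(cum, mask)

    if exact:
        count = 0
        total = 0
        m = np.zeros(n_trials, dtype=bool)
        for combo in combinations(range(n_trials), n_rew):
            m[:] = False
            m[list(combo)] = True
            if _two_sample_stat(cum, m) >= d_obs - 1e-12:
                count += 1
            total += 1
        return count / total

    rng = np.random.default_rng(seed)
    # random subsets of size n_rew, one per permutation
    order = rng.random((n_perm, n_trials)).argsort(axis=1)
    masks = order < n_rew
    tot_cum = cum.sum(axis=0)
    s_rew = masks.astype(float) @ cum
    f_rew = s_rew / n_rew
    f_non = (tot_cum[None, :] - s_rew) / (n_trials - n_rew)
    d_perm = np.abs(f_rew - f_non).max(axis=1)
    return float((1 + (d_perm >= d_obs).sum()) / (1 + n_perm))


@dataclasses.dataclass
class SelectivityParams:
    """Windows and test settings for per-unit characterization."""

    response_window: float = 0.5
    baseline_window: float = 1.0
    align_window: tuple[float, float] = (-1.5, 0.0)
    bin_width: float = 0.05
    n_permutations: int = 1000
    alpha: float = 0.05


def characterize_units(
    spikes: SpikeTrainSet,
    trials: pd.DataFrame,
    params: SelectivityParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Full per-unit selectivity table for one session.

    For every unit: z-scores and delta z-scores under both reward splits
    (non-match and cue-identity), the responsiveness p-value, per-rule
    selectivity p-values, and selectivity flags.  A unit is selective for a
    rule when it is both responsive and differentially firing under that
    rule's reward split (both p <= alpha).
    """
    if params is None:
        params = SelectivityParams()
    elig = eligible_trials(trials)
    aligned = align_counts(
        spikes, trials, "unpoke", params.align_window, params.bin_width
    )
    in_elig = np.isin(aligned.trial_indices, elig["trial_index"].to_numpy())
    elig = elig.set_index("trial_index").loc[aligned.trial_indices[in_elig]]

    resp = response_rates(spikes, trials, params.response_window)
    # baseline statistics use every completed trial; condition means use
    # eligible (defined-configuration) trials only
    base = baseline_rates(spikes, trials, params.baseline_window)
    resp = resp.loc[elig.index]

    splits = {
        "nm": reward_flag(elig, "nonmatch_rule").to_numpy(),
        "ci": reward_flag(elig, "cueid_rule").to_numpy(),
    }

    rows = []
    for u, uid in enumerate(aligned.unit_ids):
        counts2d = aligned.counts[u][in_elig]
        row: dict = {"unit_id": uid}
        degenerate = False
        for name, is_rew in splits.items():
            z_rew, z_non = zscore_by_condition(
                resp[uid].to_numpy(), base[uid].to_numpy(), is_rew
            )
            degenerate = degenerate or np.isnan(z_rew)
            row[f"z_rew_{name}"] = z_rew
            row[f"z_nonrew_{name}"] = z_non
            row[f"delta_z_{name}"] = z_rew - z_non
        row["degenerate"] = degenerate
        row["p_responsive"] = responsiveness_test(
            counts2d, params.n_permutations, seed=seed + 7919 * u
        )
        for j, (name, is_rew) in enumerate(splits.items()):
            row[f"p_{name}"] = condition_selectivity_test(
                counts2d, is_rew, params.n_permutations, seed=seed + 7919 * u + j + 1
            )
        row["selective_nm"] = (
            row["p_responsive"] <= params.alpha and row["p_nm"] <= params.alpha
        )
        row["selective_ci"] = (
            row["p_responsive"] <= params.alpha and row["p_ci"] <= params.alpha
        )
        row["selective_both"] = row["selective_nm"] and row["selective_ci"]
        rows.append(row)
    return pd.DataFrame(rows)


def selective_fraction(
    units: pd.DataFrame, alpha: float | None = None
) -> dict[str, float]:
    """Population proportions of rule-selective units.

    Returns the mutually exclusive partition (nm_only, ci_only, both,
    neither) plus the marginal totals (nm = nm_only + both, ci likewise).
    If ``alpha`` is given, flags are recomputed from the p-value columns.
    """
    if len(units) == 0:
        raise ValueError("empty population")
    if alpha is not None:
        resp = units["p_responsive"] <= alpha
        nm = resp & (units["p_nm"] <= alpha)
        ci = resp & (units["p_ci"] <= alpha)
    else:
        nm = units["selective_nm"].astype(bool)
        ci = units["selective_ci"].astype(bool)
    n = len(units)
    both = nm & ci
    return {
        "nm_only": float((nm & ~ci).sum() / n),
        "ci_only": float((ci & ~nm).sum() / n),
        "both": float(both.sum() / n),
        "neither": float((~nm & ~ci).sum() / n),
        "nm": float(nm.sum() / n),
        "ci": float(ci.sum() / n),
    }
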