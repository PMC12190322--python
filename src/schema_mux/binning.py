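"""Event-aligned spike binning and window rate extraction."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from schema_mux.data import ALIGN_EVENT_COLUMNS, AlignedCounts, SpikeTrainSet


def align_counts(
    spikes: SpikeTrainSet,
    trials: pd.DataFrame,
    align_event: str = "unpoke",
    window: tuple[float, float] = (-1.5, 0.0),
    bin_width: float = 0.05,
) -> AlignedCounts:
    """Bin each unit's spikes around an alignment event, per completed trial.

    ``counts[u, i, b]`` is the number of spikes of unit ``u`` in the half-open
    interval ``[event_i + edge_b, event_i + edge_{b+1})``.  Default bin width
    is 50 ms.  Only completed trials are included.  If the window is wider
    than the smallest inter-event spacing, adjacent-trial spikes can appear in
    two windows; that raises a warning, not an error.
    """
    if align_event not in ALIGN_EVENT_COLUMNS:
        raise ValueError(f"unknown align_event {align_event!r}")
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window must have positive length")
    comp = trials[trials["completed"].astype(bool)].sort_values("trial_index")
    events = comp[ALIGN_EVENT_COLUMNS[align_event]].to_numpy(dtype=float)
    if np.isnan(events).any():
        raise ValueError(f"missing {align_event} timestamp on a completed trial")
    if len(events) > 1 and (t1 - t0) > np.diff(np.sort(events)).min():
        warnings.warn("alignment window wider than inter-event spacing", stacklevel=2)

    n_bins = int(round((t1 - t0) / bin_width))
    edges = t0 + np.arange(n_bins + 1) * bin_width
    unit_ids = spikes.unit_ids
    counts = np.zeros((len(unit_ids), len(events), n_bins), dtype=np.int64)
    # absolute bin edges per trial; searchsorted on the sorted train gives
    # cumulative spike counts at the edges, differences are per-bin counts
    abs_edges = events[:, None] + edges[None, :]
    for u, uid in enumerate(unit_ids):
        train = spikes.units[uid]
        cum = np.searchsorted(train, abs_edges, side="left")
        counts[u] = np.diff(cum, axis=1)
    return AlignedCounts(
        unit_ids=unit_ids,
        trial_indices=comp["trial_index"].to_numpy(),
        bin_edges=edges,
        counts=counts,
        align_event=align_event,
    )


def response_rates(
    spikes: SpikeTrainSet,
    trials: pd.DataFrame,
    window: float = 0.5,
) -> pd.DataFrame:
    """Per-trial firing rate (Hz) in the response window before odor un-poke.

    Returns a trials x units DataFrame indexed by trial_index; these are the
    feature vectors for the population analyses.
    """
    aligned = align_counts(
        spikes, trials, align_event="unpoke", window=(-window, 0.0), bin_width=window
    )
    rates = aligned.counts[:, :, 0].T / window
    return pd.DataFrame(rates, index=aligned.trial_indices, columns=aligned.unit_ids)


def baseline_rates(
    spikes: SpikeTrainSet,
    trials: pd.DataFrame,
    window: float = 1.0,
) -> pd.DataFrame:
    """Per-trial firing rate (Hz) in the baseline window before trial start."""
    aligned = align_counts(
        spikes,
        trials,
        align_event="trial_start",
        window=(-window, 0.0),
        bin_width=window,
    )
    rates = aligned.counts[:, :, 0].T / window
    return pd.DataFrame(rates, index=aligned.trial_indices, columns=aligned.unit_ids)
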