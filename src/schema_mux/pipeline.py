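"""Pipeline orchestrator: run every analysis stage and write the result bundle.

Stages: behavior -> selectivity -> geometry -> decoding -> coupling.  Each
stochastic stage receives a seed derived from the master seed by a fixed
offset, so a run is idempotent for a fixed configuration: running twice
produces byte-identical numeric outputs.  Any stage failure aborts with the
stage name and session id.
"""

from __future__ import annotations

import dataclasses
import json
from os import PathLike
from pathlib import Path

import numpy as np
import pandas as pd

import schema_mux
from schema_mux.behavior import summarize_session
from schema_mux.binning import response_rates
from schema_mux.config import PipelineConfig
from schema_mux.coupling import (
    SessionCoupling,
    decoder_behavior_correlation,
    fidelity_ignore_correlation,
    ignore_probability,
)
from schema_mux.binning import align_counts
from schema_mux.data import CUEID_RULE, eligible_trials, reward_flag
from schema_mux.decoding import (
    binary_rule_decoder,
    diagonal_ratio,
    loo_confusion,
    make_template,
    template_permutation_test,
)
from schema_mux.geometry import (
    build_pseudoensemble,
    centroid_distances,
    contrast_distance,
    distance_permutation_test,
    embed_population,
    linkage_to_newick,
    trial_type_index,
    ward_linkage,
)
from schema_mux.io import read_spike_table, read_trial_table
from schema_mux.selectivity import (
    SelectivityParams,
    characterize_units,
    compute_psth,
    selective_fraction,
)
from schema_mux.simulate import make_scenario

# fixed per-stage seed offsets from the master seed
STAGE_SEED_OFFSETS = {
    "simulate": 0,
    "selectivity": 10_000,
    "geometry": 20_000,
    "decoding": 30_000,
    "coupling": 40_000,
}


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and session."""


def _load_sessions(config: PipelineConfig) -> list[dict]:
    if config.scenario is not None:
        from schema_mux.simulate import Scenario

        scenario = Scenario(
            name=config.scenario,
            n_sessions=config.n_sessions,
            n_trials_per_session=config.n_trials_per_session,
            n_units=config.n_units,
            seed=config.seed + STAGE_SEED_OFFSETS["simulate"],
        )
        return make_scenario(scenario)
    if config.data_dir is None:
        raise ValueError("config must name either a scenario or a data_dir")
    root = Path(config.data_dir)
    sessions = []
    for d in sorted(p for p in root.iterdir() if p.is_dir()):
        trials_path = d / "trials.csv"
        spikes_path = d / "spikes.csv"
        for p in (trials_path, spikes_path):
            if not p.exists():
                raise FileNotFoundError(f"missing session file: {p}")
        sessions.append(
            {
                "session_id": d.name,
                "trials": read_trial_table(trials_path),
                "spikes": read_spike_table(spikes_path),
            }
        )
    if not sessions:
        raise FileNotFoundError(f"no session directories under {root}")
    return sessions


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the result bundle under ``config.out_dir``.

    Returns a dict with the in-memory stage outputs.  The bundle contains
    behavior_summary.csv, unit_selectivity.csv, psth_traces.csv,
    geometry_result.csv (+ centroid_distances.csv, linkage.nwk),
    confusion.csv, template_scores.csv, decoder_results.csv, coupling.csv,
    correlations.csv and manifest.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sessions = _load_sessions(config)
    results: dict = {"sessions": [s["session_id"] for s in sessions]}

    def run_stage(name: str, session_id: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrap with context
            raise StageError(
                f"stage {name!r} failed for session {session_id!r}: {exc}"
            ) from exc

    # ---- behavior ----------------------------------------------------
    summaries = [
        run_stage("behavior", s["session_id"], summarize_session, s["trials"])
        for s in sessions
    ]
    behavior_df = pd.DataFrame([dataclasses.asdict(b) for b in summaries])
    behavior_df.to_csv(out / "behavior_summary.csv", index=False)
    results["behavior"] = behavior_df

    # ---- per-unit selectivity ---------------------------------------
    sel_params = SelectivityParams(
        response_window=config.response_window,
        baseline_window=config.baseline_window,
        align_window=config.align_window,
        bin_width=config.bin_width,
        n_permutations=config.n_permutations,
        alpha=config.alpha,
    )
    sel_frames = []
    for i, s in enumerate(sessions):
        df = run_stage(
            "selectivity",
            s["session_id"],
            characterize_units,
            s["spikes"],
            s["trials"],
            sel_params,
            seed=config.seed + STAGE_SEED_OFFSETS["selectivity"] + i,
        )
        df.insert(0, "session_id", s["session_id"])
        sel_frames.append(df)
    sel_df = pd.concat(sel_frames, ignore_index=True)
    sel_df.to_csv(out / "unit_selectivity.csv", index=False)
    results["selectivity"] = sel_df
    results["selective_fraction"] = selective_fraction(sel_df)

    # tidy PSTH traces, split by reward under the rule in effect
    psth_rows = []
    for s in sessions:
        trials = s["trials"]
        aligned = align_counts(
            s["spikes"], trials, "unpoke", config.align_window, config.bin_width
        )
        elig = eligible_trials(trials)
        in_elig = np.isin(aligned.trial_indices, elig["trial_index"].to_numpy())
        rule = str(trials["rule_in_effect"].iloc[0])
        flag = reward_flag(
            elig.set_index("trial_index").loc[aligned.trial_indices[in_elig]], rule
        ).to_numpy()
        rew_mask = np.zeros(len(aligned.trial_indices), dtype=bool)
        rew_mask[in_elig] = flag
        non_mask = np.zeros_like(rew_mask)
        non_mask[in_elig] = ~flag
        traces = compute_psth(aligned, {"rewarded": rew_mask, "nonrewarded": non_mask})
        centers = (aligned.bin_edges[:-1] + aligned.bin_edges[1:]) / 2
        for cond, tr in traces.items():
            for u, uid in enumerate(aligned.unit_ids):
                psth_rows.extend(
                    {
                        "session_id": s["session_id"],
                        "unit_id": uid,
                        "condition": cond,
                        "time_s": float(t),
                        "rate_hz": float(r),
                    }
                    for t, r in zip(centers, tr[u])
                )
    pd.DataFrame(psth_rows).to_csv(out / "psth_traces.csv", index=False)

    # ---- population geometry ----------------------------------------
    feats = {
        s["session_id"]: response_rates(s["spikes"], s["trials"], config.response_window)
        for s in sessions
    }
    geo_seed = config.seed + STAGE_SEED_OFFSETS["geometry"]
    pseudo = run_stage(
        "geometry",
        "all",
        build_pseudoensemble,
        [(s["trials"], feats[s["session_id"]]) for s in sessions],
        config.n_per_type,
        seed=geo_seed,
    )
    coords = embed_population(
        pseudo.matrix, config.embedding_method, config.embedding_dims, seed=geo_seed
    )
    dist, type_ids = centroid_distances(coords, pseudo.labels)
    linkage = ward_linkage(dist)
    (out / "linkage.nwk").write_text(
        linkage_to_newick(linkage, [f"type{t:02d}" for t in type_ids])
    )
    geo_rows = []
    for contrast in ("nm_config", "ci_reward"):
        obs, null_mean, p = distance_permutation_test(
            coords,
            pseudo.labels,
            contrast,
            n_perm=config.n_permutations,
            seed=geo_seed + 1,
        )
        geo_rows.append(
            {"contrast": contrast, "observed": obs, "null_mean": null_mean, "p": p}
        )
    geometry_df = pd.DataFrame(geo_rows)
    geometry_df.to_csv(out / "geometry_result.csv", index=False)
    dist_df = pd.DataFrame(dist, index=type_ids, columns=type_ids)
    dist_df.to_csv(out / "centroid_distances.csv")
    results["geometry"] = geometry_df
    results["centroid_distances"] = dist_df

    # ---- decoding ----------------------------------------------------
    conf_rows, score_rows, decoder_rows = [], [], []
    couplings = []
    dec_seed = config.seed + STAGE_SEED_OFFSETS["decoding"]
    templates = {k: make_template(k) for k in ("nonmatch", "cueid", "both_rules")}
    for i, s in enumerate(sessions):
        sid = s["session_id"]
        trials = s["trials"]
        elig = eligible_trials(trials)
        X = feats[sid].loc[elig["trial_index"].to_numpy()].to_numpy()
        labels = trial_type_index(elig["odor_id"], elig["config"])
        conf = run_stage(
            "decoding", sid, loo_confusion, X, labels, c=config.svm_c, seed=dec_seed + i
        )
        for r in range(16):
            for col in range(16):
                conf_rows.append(
                    {
                        "session_id": sid,
                        "true_type": r,
                        "predicted_type": col,
                        "probability": conf.matrix[r, col],
                        "n_trials": conf.counts[r],
                    }
                )
        for kind, tmpl in templates.items():
            s_obs, p = template_permutation_test(
                conf, tmpl, n_perm=config.n_permutations, seed=dec_seed + i
            )
            score_rows.append(
                {"session_id": sid, "template": kind, "similarity": s_obs, "p": p}
            )
        score_rows.append(
            {
                "session_id": sid,
                "template": "diagonal_ratio",
                "similarity": diagonal_ratio(conf),
                "p": np.nan,
            }
        )
        dec_results = {}
        for rule in ("nonmatch_rule", "cueid_rule"):
            res = run_stage(
                "decoding",
                sid,
                binary_rule_decoder,
                X,
                trials,
                rule,
                n_perm=config.n_permutations,
                seed=dec_seed + i,
                c=config.svm_c,
            )
            dec_results[rule] = res
            decoder_rows.append(
                {
                    "session_id": sid,
                    "rule": rule,
                    "accuracy": res.accuracy,
                    "p": res.p_value,
                }
            )
        summary = summaries[i]
        p_ignore, n_num, n_den = (None, 0, 0)
        if (trials["rule_in_effect"] == CUEID_RULE).all():
            p_ignore, n_num, n_den = run_stage(
                "coupling",
                sid,
                ignore_probability,
                trials,
                dec_results["nonmatch_rule"].predictions,
            )
        couplings.append(
            SessionCoupling(
                session_id=sid,
                decoder_accuracy_nm=dec_results["nonmatch_rule"].accuracy,
                decoder_accuracy_ci=dec_results["cueid_rule"].accuracy,
                behavior_accuracy_nm=summary.accuracy_nm,
                behavior_accuracy_ci=summary.accuracy_ci,
                p_ignore=p_ignore,
                n_ignore_denominator=n_den,
            )
        )
    pd.DataFrame(conf_rows).to_csv(out / "confusion.csv", index=False)
    template_df = pd.DataFrame(score_rows)
    template_df.to_csv(out / "template_scores.csv", index=False)
    decoder_df = pd.DataFrame(decoder_rows)
    decoder_df.to_csv(out / "decoder_results.csv", index=False)
    results["template_scores"] = template_df
    results["decoders"] = decoder_df

    # ---- brain-behavior coupling ------------------------------------
    coupling_df = pd.DataFrame([dataclasses.asdict(c) for c in couplings])
    coupling_df.to_csv(out / "coupling.csv", index=False)
    results["coupling"] = coupling_df
    corr_rows = []
    if len(couplings) >= 3:
        for rule in ("nonmatch_rule", "cueid_rule"):
            try:
                r, p, n = decoder_behavior_correlation(couplings, rule)
                corr_rows.append({"measure": f"decoder_behavior_{rule}", "r": r, "p": p, "n": n})
            except ValueError:
                pass
        try:
            r, p, n = fidelity_ignore_correlation(couplings)
            corr_rows.append({"measure": "fidelity_ignore", "r": r, "p": p, "n": n})
        except ValueError:
            pass
    corr_df = pd.DataFrame(corr_rows, columns=["measure", "r", "p", "n"])
    corr_df.to_csv(out / "correlations.csv", index=False)
    results["correlations"] = corr_df

    manifest = {
        "package_version": schema_mux.__version__,
        "config": config.to_dict(),
        "stage_seeds": {
            k: config.seed + v for k, v in STAGE_SEED_OFFSETS.items()
        },
        "sessions": results["sessions"],
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return results
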