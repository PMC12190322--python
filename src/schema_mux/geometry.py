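"""Pseudo-ensemble construction and population-geometry statistics.

Pseudo-ensembles concatenate units recorded in different sessions by
aligning trials of the same type (odor x match/non-match configuration, 16
classes).  The ensemble is embedded in three dimensions (a deterministic
linear map by default, a neighbor embedding optionally), trial-type
centroids are compared with a normalized Euclidean distance, hierarchical
structure is summarized by a Ward dendrogram, and contrast distances are
tested against a label-permutation null.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from schema_mux.data import MATCH, NONMATCH, CUE_REWARDED_ODORS, ODOR_IDS, eligible_trials

#: Canonical trial-type order: odors 1-8 in match configuration, then 1-8 in
#: nonmatch configuration.
TRIAL_TYPES: tuple[tuple[int, str], ...] = tuple(
    (odor, config) for config in (MATCH, NONMATCH) for odor in ODOR_IDS
)

EPS_VAR = 1e-12


def trial_type_index(odor_id: np.ndarray, config: np.ndarray) -> np.ndarray:
    """Map (odor, configuration) to the canonical 0-15 trial-type index."""
    odor_id = np.asarray(odor_id, dtype=int)
    config = np.asarray(config)
    return (odor_id - 1) + 8 * (config == NONMATCH).astype(int)


@dataclasses.dataclass
class PseudoEnsemble:
    """Trials x units matrix of standardized response rates, type-aligned.

    ``matrix`` holds one row per pseudo-trial (equal counts per populated
    trial type) and one column per unit across all source sessions; each
    column is standardized (mean 0, SD 1) over the included trials.
    """

    matrix: np.ndarray
    labels: np.ndarray  # trial-type index 0-15 per row
    unit_ids: list[str]
    source_sessions: list[str]
    seed: int

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_units(self) -> int:
        return self.matrix.shape[1]


def build_pseudoensemble(
    sessions: list[tuple[pd.DataFrame, pd.DataFrame]],
    n_per_type: int,
    seed: int = 0,
    strict: bool = False,
) -> PseudoEnsemble:
    """Build a pseudo-ensemble from (trials, features) session pairs.

    ``features`` is a trials x units DataFrame of response-window rates
    indexed by trial_index (as from :func:`schema_mux.binning.response_rates`).
    Per session, ``n_per_type`` trials of each populated type are subsampled
    (seeded) and unit columns are concatenated across sessions by type-aligned
    trial slots.  Columns are standardized over the included trials;
    zero-variance units are dropped with a warning.  Types missing from any
    session are dropped globally with a warning (error in strict mode).
    """
    per_session: list[dict[int, np.ndarray]] = []
    unit_ids: list[str] = []
    session_ids: list[str] = []
    type_sets = []
    for s, (trials, feats) in enumerate(sessions):
        elig = eligible_trials(trials)
        feats = feats.loc[elig["trial_index"].to_numpy()]
        types = trial_type_index(elig["odor_id"], elig["config"])
        groups: dict[int, np.ndarray] = {}
        for t in range(16):
            rows = feats.to_numpy()[types == t]
            if len(rows) >= n_per_type:
                groups[t] = rows
        per_session.append(groups)
        sid = str(trials["session_id"].iloc[0])
        session_ids.append(sid)
        unit_ids.extend(f"{sid}/{c}" for c in feats.columns)
        type_sets.append(set(groups))

    common = set.intersection(*type_sets)
    dropped = set(range(16)) - common
    if dropped:
        msg = f"trial types dropped globally (insufficient trials): {sorted(dropped)}"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    if not common:
        raise ValueError("no trial type populated in every session")
    kept_types = sorted(common)

    blocks = []
    for groups in per_session:
        # per-session generator from the same seed: identical sessions get
        # identical subsamples (type-aligned slots stay comparable)
        rng = np.random.default_rng(seed)
        rows = []
        for t in kept_types:
            pool = groups[t]
            pick = rng.choice(len(pool), size=n_per_type, replace=False)
            rows.append(pool[np.sort(pick)])
        blocks.append(np.vstack(rows))
    matrix = np.hstack(blocks)
    labels = np.repeat(kept_types, n_per_type)

    # standardize over the included trials so each unit column is exactly
    # mean 0 / SD 1 in the ensemble; zero-variance units carry no geometry
    mu = matrix.mean(axis=0)
    sd = matrix.std(axis=0)
    keep = sd > EPS_VAR
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance unit(s)", stacklevel=2
        )
    matrix = (matrix[:, keep] - mu[keep]) / sd[keep]
    unit_ids = [u for u, k in zip(unit_ids, keep) if k]
    return PseudoEnsemble(
        matrix=matrix,
        labels=labels,
        unit_ids=unit_ids,
        source_sessions=session_ids,
        seed=seed,
    )


def embed_population(
    matrix: np.ndarray,
    method: str = "linear-fallback",
    dims: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Embed trials in a low-dimensional space.

    ``linear-fallback`` projects onto the top principal directions — fully
    deterministic, the test and acceptance surface.  ``neighbor-embedding``
    runs UMAP with a fixed random state (figures only; its stochastic,
    nonconvex output is not a stable test surface).  If the data rank is
    below ``dims`` the missing dimensions are zero-padded with a warning.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < dims + 1:
        raise ValueError("need at least dims + 1 trials")
    if method == "linear-fallback":
        centered = matrix - matrix.mean(axis=0)
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        rank = int((s > 1e-10 * s[0]).sum()) if s.size else 0
        k = min(dims, rank)
        # deterministic sign convention: largest-|loading| entry positive
        for j in range(k):
            pivot = np.argmax(np.abs(vt[j]))
            if vt[j, pivot] < 0:
                vt[j] = -vt[j]
                u[:, j] = -u[:, j]
        coords = u[:, :k] * s[:k]
        if k < dims:
            warnings.warn(f"rank {rank} < dims {dims}; zero-padding", stacklevel=2)
            coords = np.hstack([coords, np.zeros((matrix.shape[0], dims - k))])
        return coords
    if method == "neighbor-embedding":
        import umap

        reducer = umap.UMAP(n_components=dims, random_state=seed)
        return np.asarray(reducer.fit_transform(matrix), dtype=float)
    raise ValueError(f"unknown embedding method {method!r}")


def _pooled_within_var(coords: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Pooled within-type variance per dimension (the distance normalizer)."""
    resid = []
    for lab in np.unique(labels):
        pts = coords[labels == lab]
        resid.append(pts - pts.mean(axis=0))
    r = np.vstack(resid)
    return np.maximum(r.var(axis=0), EPS_VAR)


def centroid_distances(
    coords: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized Euclidean distances between trial-type centroids.

    d(a, b) = sqrt(sum_dim (mu_a - mu_b)^2 / s2_dim) where s2_dim is the
    pooled within-type variance on that dimension, so the metric accounts for
    the spread within each trial type.  Singleton types are excluded with a
    warning.  Returns (distance matrix, type labels in matrix order).
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    singles = uniq[counts < 2]
    if singles.size:
        warnings.warn(f"excluding singleton types {singles.tolist()}", stacklevel=2)
        keep = ~np.isin(labels, singles)
        coords, labels = coords[keep], labels[keep]
        uniq = uniq[counts >= 2]
    s2 = _pooled_within_var(coords, labels)
    cents = np.vstack([coords[labels == lab].mean(axis=0) for lab in uniq])
    diff = cents[:, None, :] - cents[None, :, :]
    dist = np.sqrt((diff**2 / s2[None, None, :]).sum(axis=2))
    return dist, uniq


def ward_linkage(distmat: np.ndarray) -> np.ndarray:
    """Ward-criterion agglomerative linkage from a distance matrix."""
    distmat = np.asarray(distmat, dtype=float)
    if not np.allclose(distmat, distmat.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    return hierarchy.linkage(squareform(distmat, checks=False), method="ward")


def linkage_leaf_order(linkage: np.ndarray) -> list[int]:
    """Dendrogram leaf order for plotting."""
    return hierarchy.leaves_list(linkage).tolist()


def linkage_to_newick(linkage: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a linkage tree as a newick string with merge heights."""
    tree = hierarchy.to_tree(linkage)

    def rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def contrast_distance(
    coords: np.ndarray, labels: np.ndarray, contrast: str
) -> float:
    """Mean centroid separation along one task contrast.

    ``nm_config``: mean over odors of the distance between the odor's match
    and nonmatch centroids.  ``ci_reward``: mean over cross-group odor pairs
    (cue-rewarded vs cue-nonrewarded) of the centroid distance, collapsing
    configurations.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels, dtype=int)
    s2 = _pooled_within_var(coords, labels)

    def centroid(mask: np.ndarray) -> np.ndarray | None:
        return coords[mask].mean(axis=0) if mask.any() else None

    def ndist(a: np.ndarray, b: np.ndarray) -> float:
        return float(np.sqrt(((a - b) ** 2 / s2).sum()))

    odor = labels % 8 + 1
    config_nm = labels >= 8
    if contrast == "nm_config":
        dists = []
        for o in ODOR_IDS:
            cm = centroid((odor == o) & ~config_nm)
            cn = centroid((odor == o) & config_nm)
            if cm is not None and cn is not None:
                dists.append(ndist(cm, cn))
        if not dists:
            raise ValueError("no odor has both configurations populated")
        return float(np.mean(dists))
    if contrast == "ci_reward":
        rewarded = sorted(CUE_REWARDED_ODORS)
        nonrewarded = [o for o in ODOR_IDS if o not in CUE_REWARDED_ODORS]
        dists = []
        for a in rewarded:
            ca = centroid(odor == a)
            for b in nonrewarded:
                cb = centroid(odor == b)
                if ca is not None and cb is not None:
                    dists.append(ndist(ca, cb))
        if not dists:
            raise ValueError("a cue-reward group is unpopulated")
        return float(np.mean(dists))
    raise ValueError(f"unknown contrast {contrast!r}")


def distance_permutation_test(
    coords: np.ndarray,
    labels: np.ndarray,
    contrast: str,
    n_perm: int = 1000,
    seed: int = 0,
    session_ids: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Label-permutation test of a contrast distance.

    Trial labels are shuffled uniformly (within each session when
    ``session_ids`` is given) and the contrast recomputed; returns
    (observed, null mean, p) with p = (1 + #{null >= obs}) / (1 + n_perm).
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse p-value", stacklevel=2)
    labels = np.asarray(labels)
    observed = contrast_distance(coords, labels, contrast)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = labels.copy()
        if session_ids is None:
            rng.shuffle(perm)
        else:
            for sid in np.unique(session_ids):
                m = session_ids == sid
                perm[m] = rng.permutation(perm[m])
        null[i] = contrast_distance(coords, perm, contrast)
    p = float((1 + (null >= observed).sum()) / (1 + n_perm))
    return observed, float(null.mean()), p
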