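"""Trial-type decoding, template analysis, and choice residualization.

A linear max-margin (SVM) classifier decodes the 16 trial types from
response-window population rates, leave-one-out cross-validated; the held-out
predictions are tallied into a row-stochastic confusion matrix (rows: true
type, columns: predicted type, ordered odors 1-8 match then 1-8 nonmatch).
Confusion matrices are compared with binary rule templates by a scoring
contrast whose null distribution comes from jointly relabeling rows and
columns.  Binary per-rule decoders and the diagonal-ratio asymmetry index
complete the surface.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from schema_mux.data import CUE_REWARDED_ODORS, GO, eligible_trials, reward_flag

N_TYPES = 16
EPS_RATIO = 1e-9


@dataclasses.dataclass
class ConfusionMatrix:
    """Row-stochastic 16x16 decoder confusion matrix with per-type counts.

    ``matrix[i, j]`` is the probability of predicting type ``j`` given the
    population activity of a true type-``i`` trial.  Rows with no trials are
    left as all-NaN.
    """

    matrix: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.matrix.shape != (N_TYPES, N_TYPES) or self.counts.shape != (N_TYPES,):
            raise ValueError("confusion matrix must be 16x16 with 16 counts")
        populated = self.counts > 0
        sums = self.matrix[populated].sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("populated rows must sum to 1")


@dataclasses.dataclass
class TemplateMatrix:
    """Binary symmetric similarity hypothesis between the 16 trial types."""

    matrix: np.ndarray
    kind: str


@dataclasses.dataclass
class DecoderResult:
    """Binary rule-decoder output: held-out predictions, accuracy, p-value."""

    predictions: np.ndarray
    accuracy: float
    p_value: float
    rule: str
    n_permutations: int
    seed: int
    held_out: bool = True  # provenance flag: predictions are leave-one-out


try:  # low-level libsvm binding: same solver as SVC, used in hot loops
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
    _HAVE_LIBSVM = True
except ImportError:  # pragma: no cover - depends on sklearn internals
    _HAVE_LIBSVM = False


def _standardize(features: np.ndarray) -> np.ndarray:
    """Per-unit z-scoring of the feature matrix (standard scaling).

    Decoders run on standardized responses; this also conditions the SVM
    problem so the solver converges quickly.  Zero-variance columns become
    zero.
    """
    features = np.asarray(features, dtype=float)
    sd = features.std(axis=0)
    sd[sd < 1e-12] = 1.0
    return (features - features.mean(axis=0)) / sd


def _balanced_weights(labels: np.ndarray) -> dict:
    """Inverse-class-frequency weights, computed once on the full sample.

    Weights are held fixed across leave-one-out folds so that removing a
    non-support vector provably leaves the solution unchanged (the basis of
    the exact LOO shortcut below).
    """
    classes, counts = np.unique(labels, return_counts=True)
    n, k = len(labels), len(classes)
    return {c: n / (k * cnt) for c, cnt in zip(classes, counts)}


def loo_predictions(
    features: np.ndarray, labels: np.ndarray, c: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Leave-one-out held-out prediction per trial.

    Equivalent to refitting the classifier n times with one trial held out
    (the brute-force loop), but exact shortcuts are applied: the Gram matrix
    is precomputed, and trials that are not support vectors of the full-data
    fit keep the full-data prediction, since removing a point with zero dual
    coefficient does not change the optimum.  Ties in the one-vs-one voting
    break toward the lowest label index.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    weights = _balanced_weights(labels)
    gram = np.ascontiguousarray(features @ features.T)
    full = SVC(kernel="precomputed", C=c, class_weight=weights, random_state=seed)
    full.fit(gram, labels)
    preds = full.predict(gram)
    idx = np.arange(n)
    for i in full.support_:
        m = idx != i
        clf = SVC(kernel="precomputed", C=c, class_weight=weights, random_state=seed)
        clf.fit(np.ascontiguousarray(gram[np.ix_(m, m)]), labels[m])
        preds[i] = clf.predict(gram[i, m][None, :])[0]
    return preds


def _binary_loo_preds_fast(gram: np.ndarray, labels01: np.ndarray, c: float) -> np.ndarray:
    """Exact binary LOO predictions via the low-level libsvm binding.

    Same optimization problem as the public path (C-SVC, precomputed linear
    kernel, fixed balanced weights); the raw libsvm decision value is the
    negative of sklearn's, so class 1 is predicted when -dec > 0.
    """
    yf = labels01.astype(np.float64)
    w = _balanced_weights(labels01)
    w_arr = np.array([w[0], w[1]], dtype=np.float64)

    def fit_dec(g_train: np.ndarray, y_train: np.ndarray, g_test_row: np.ndarray) -> float:
        out = _libsvm.fit(
            g_train, y_train, svm_type=0, kernel="precomputed", C=c, class_weight=w_arr
        )
        support, coef, intercept = out[0], out[3], out[4]
        return float(g_test_row[support] @ coef[0] + intercept[0])

    n = len(yf)
    idx = np.arange(n)
    out = _libsvm.fit(
        gram, yf, svm_type=0, kernel="precomputed", C=c, class_weight=w_arr
    )
    support, coef, intercept = out[0], out[3], out[4]
    dec_full = gram[:, support] @ coef[0] + intercept[0]
    preds = (-dec_full > 0).astype(int)
    for i in support:
        m = idx != i
        g_train = np.ascontiguousarray(gram[np.ix_(m, m)])
        dec = fit_dec(g_train, yf[m], gram[i, m])
        preds[i] = int(-dec > 0)
    return preds


def _binary_loo_preds(gram_or_features: np.ndarray, labels01: np.ndarray, c: float) -> np.ndarray:
    if _HAVE_LIBSVM:
        return _binary_loo_preds_fast(gram_or_features, labels01, c)
    # fallback: public-API path on the same precomputed kernel
    n = len(labels01)
    weights = _balanced_weights(labels01)
    idx = np.arange(n)
    preds = np.empty(n, dtype=int)
    for i in range(n):
        m = idx != i
        clf = SVC(kernel="precomputed", C=c, class_weight=weights)
        clf.fit(np.ascontiguousarray(gram_or_features[np.ix_(m, m)]), labels01[m])
        preds[i] = clf.predict(gram_or_features[i, m][None, :])[0]
    return preds


def loo_confusion(
    features: np.ndarray, labels: np.ndarray, c: float = 1.0, seed: int = 0
) -> ConfusionMatrix:
    """Leave-one-out confusion matrix over the 16 trial types.

    ``labels`` are canonical type indices 0-15.  Classes with a single trial
    cannot be held out meaningfully and are dropped with a warning.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    uniq, counts = np.unique(labels, return_counts=True)
    single = uniq[counts < 2]
    if single.size:
        warnings.warn(f"dropping single-trial classes {single.tolist()}", stacklevel=2)
        keep = ~np.isin(labels, single)
        features, labels = features[keep], labels[keep]
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes with >= 2 trials")

    preds = loo_predictions(_standardize(features), labels, c=c, seed=seed)
    tally = np.zeros((N_TYPES, N_TYPES))
    for t, p in zip(labels, preds):
        tally[t, p] += 1
    row_counts = tally.sum(axis=1)
    matrix = np.full((N_TYPES, N_TYPES), np.nan)
    populated = row_counts > 0
    matrix[populated] = tally[populated] / row_counts[populated, None]
    return ConfusionMatrix(matrix=matrix, counts=row_counts.astype(int))


def make_template(kind: str) -> TemplateMatrix:
    """Binary rule template over the 16 trial types.

    ``nonmatch``: types are similar iff they share the match/non-match
    configuration.  ``cueid``: similar iff their odors share the cue-reward
    group, regardless of configuration.  ``both_rules``: elementwise AND.
    """
    config = np.arange(N_TYPES) // 8
    odor = np.arange(N_TYPES) % 8 + 1
    cue_group = np.isin(odor, sorted(CUE_REWARDED_ODORS)).astype(int)
    if kind == "nonmatch":
        m = (config[:, None] == config[None, :]).astype(int)
    elif kind == "cueid":
        m = (cue_group[:, None] == cue_group[None, :]).astype(int)
    elif kind == "both_rules":
        m = (
            (config[:, None] == config[None, :])
            & (cue_group[:, None] == cue_group[None, :])
        ).astype(int)
    else:
        raise ValueError(f"unknown template kind {kind!r}")
    np.fill_diagonal(m, 1)
    return TemplateMatrix(matrix=m, kind=kind)


def template_similarity(conf: ConfusionMatrix | np.ndarray, tmpl: TemplateMatrix) -> float:
    """Scoring-matrix similarity between a confusion matrix and a template.

    Off-diagonal cells are scored +1 where the template is 1 and -1 where it
    is 0; the raw contrast (mean in-template minus mean out-of-template
    off-diagonal probability) is normalized by the maximum contrast a
    row-stochastic matrix can attain (all off-diagonal mass inside the
    template), so the score lies in [-1, 1]: 1 for confusion concentrated in
    the template blocks, 0 for the identity or a uniform matrix.
    """
    P = conf.matrix if isinstance(conf, ConfusionMatrix) else np.asarray(conf, float)
    T = tmpl.matrix
    if P.shape != T.shape:
        raise ValueError("confusion and template dimensions differ")
    off = ~np.eye(N_TYPES, dtype=bool)
    valid = off & ~np.isnan(P)
    in_cells = valid & (T == 1)
    out_cells = valid & (T == 0)
    n_in = int(in_cells.sum())
    if n_in == 0:
        raise ValueError("template has no off-diagonal 1-cells")
    mean_in = P[in_cells].mean()
    mean_out = P[out_cells].mean() if out_cells.any() else 0.0
    n_rows = int((~np.isnan(P).all(axis=1)).sum())
    max_contrast = n_rows / n_in
    return float((mean_in - mean_out) / max_contrast)


def template_permutation_test(
    conf: ConfusionMatrix,
    tmpl: TemplateMatrix,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Row/column-shuffle permutation test of template similarity.

    Each permutation draws one random relabeling of the 16 trial types and
    applies it jointly to rows and columns, preserving the matrix's identity
    as a confusion matrix of (relabeled) classes.  Returns (observed S, p).
    """
    s_obs = template_similarity(conf, tmpl)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(N_TYPES)
        permuted = conf.matrix[np.ix_(perm, perm)]
        if template_similarity(permuted, tmpl) >= s_obs - 1e-12:
            exceed += 1
    return s_obs, float((1 + exceed) / (1 + n_perm))


def diagonal_ratio(conf: ConfusionMatrix) -> float:
    """Main-diagonal vs side-diagonal classification asymmetry.

    R = mean correct-classification probability divided by the mean
    probability of confusing a type with its same-odor opposite-configuration
    partner (the +/-8 offset side diagonals).  R ~ 1 when configuration is
    ignored (pure cue-identity coding); R > 1 when configuration coding
    separates the partners.  Returns +inf when the side diagonal is empty.
    """
    P = conf.matrix
    idx = np.arange(N_TYPES)
    partner = (idx + 8) % N_TYPES
    diag = P[idx, idx]
    side = P[idx, partner]
    num = np.nanmean(diag)
    den = np.nanmean(side)
    if den < EPS_RATIO:
        return float("inf")
    return float(num / den)


def loo_accuracy(
    features: np.ndarray, labels: np.ndarray, c: float = 1.0, seed: int = 0
) -> tuple[float, np.ndarray]:
    preds = loo_predictions(features, labels, c=c, seed=seed)
    return float((preds == labels).mean()), preds


def binary_rule_decoder(
    features: np.ndarray,
    trials: pd.DataFrame,
    rule: str,
    n_perm: int = 1000,
    seed: int = 0,
    c: float = 1.0,
) -> DecoderResult:
    """Decode rewarded vs non-rewarded trials under one rule.

    Linear max-margin classifier, leave-one-out accuracy; the permutation
    null shuffles the binary labels and recomputes the leave-one-out
    accuracy.  ``features`` rows must align with the eligible trials of
    ``trials``.  Held-out per-trial predictions are retained for the
    brain-behavior analyses.
    """
    elig = eligible_trials(trials)
    labels = reward_flag(elig, rule).to_numpy().astype(int)
    features = np.asarray(features, dtype=float)
    if len(features) != len(labels):
        raise ValueError("features rows must match eligible trials")
    n_pos = labels.sum()
    if n_pos < 5 or len(labels) - n_pos < 5:
        raise ValueError("need >= 5 trials per class")

    features = _standardize(features)
    gram = np.ascontiguousarray(features @ features.T)
    preds = _binary_loo_preds(gram, labels, c)
    accuracy = float((preds == labels).mean())
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            shuffled = rng.permutation(labels)
            acc_p = float((_binary_loo_preds(gram, shuffled, c) == shuffled).mean())
            if acc_p >= accuracy - 1e-12:
                exceed += 1
        p_value = float((1 + exceed) / (1 + n_perm))
    else:  # n_perm=0: accuracy and predictions only, no significance test
        p_value = float("nan")
    return DecoderResult(
        predictions=preds,
        accuracy=accuracy,
        p_value=p_value,
        rule=rule,
        n_permutations=n_perm,
        seed=seed,
    )


def residualize_choice(features: np.ndarray, choices: np.ndarray) -> np.ndarray:
    """Regress the go/no-go choice out of every unit's response.

    Ordinary least squares of each unit's response on {intercept, go
    indicator}; the residuals are returned.  Residual columns have zero mean
    and are orthogonal to the choice indicator.  If only one choice is
    present the features are centered only, with a warning.
    """
    features = np.asarray(features, dtype=float)
    choices = np.asarray(choices)
    go = (choices == GO).astype(float) if choices.dtype.kind in "OUS" else choices.astype(float)
    if len(go) != len(features):
        raise ValueError("choices must align with feature rows")
    if np.all(go == go[0]):
        warnings.warn("all choices identical; centering only", stacklevel=2)
        return features - features.mean(axis=0)
    X = np.column_stack([np.ones_like(go), go])
    beta, *_ = np.linalg.lstsq(X, features, rcond=None)
    return features - X @ beta
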