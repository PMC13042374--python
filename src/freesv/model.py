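"""Feature assembly, nested cross-validation, and diagnostic reporting.

The base feature vector has 101 entries: the 96 normalized mutation
channel frequencies plus the five Mut-minus-Wt contrasts (Diff-size,
Diff-CCCA, Diff-CTCC, Diff-nucleosome, and Diff-methylation for
gene-body CpGs).  The extended vector appends four externally supplied
genome-wide summary columns (methylation, fragment size, end motif,
copy number), for 105 features.

Classification uses gradient-boosted decision trees under a stratified
10-fold nested cross-validation scheme: hyperparameters are tuned by
inner resampling within each training split, the held-out fold is
scored by a model that never saw it, and the whole procedure is
repeated with fresh fold assignments; each sample's prediction score is
the average over repeats.  Performance is summarized by the AUC (with a
Hanley-McNeil Z-test against 0.5) and by sensitivity at a fixed
specificity (default 99%) with an exact Clopper-Pearson 95% interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .fragmentomics import DiffFeatures
from .signatures import CONTEXT_96, MutationProfile

DIFF_FEATURES = ("diff_size", "diff_ccca", "diff_ctcc", "diff_nucleosome",
                 "diff_methylation")
GENOMEWIDE_FEATURES = ("gw_methylation", "gw_size", "gw_motif", "gw_copy_number")
N_FEATURES_BASE = 101
N_FEATURES_PLUS = 105

#: Small default tuning grid; override per study through ``tuning_grid``.
DEFAULT_TUNING_GRID: tuple[dict, ...] = (
    {"n_estimators": 100, "max_depth": 2, "learning_rate": 0.1},
    {"n_estimators": 300, "max_depth": 1, "learning_rate": 0.1},
)


@dataclass
class CVResult:
    """Averaged out-of-fold prediction scores from repeated nested CV."""

    sample_ids: list[str]
    labels: np.ndarray  # 1 = cancer, 0 = control
    scores: np.ndarray  # averaged over repeats, one per sample
    fold_assignments: np.ndarray  # (repeats, samples) fold index per repeat
    seed: int = 0

    @property
    def auc(self) -> float:
        return float(roc_auc_score(self.labels, self.scores))


@dataclass
class DiagnosticReport:
    """ROC summary at a fixed-specificity operating point."""

    auc: float
    auc_p: float
    target_specificity: float
    threshold: float
    specificity: float
    sensitivity: float
    ci_low: float
    ci_high: float
    n_cancer: int
    n_detected: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.sensitivity <= self.ci_high:
            raise ValueError("CI must bracket the sensitivity estimate")


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------

def feature_names(mode: str = "freesv") -> list[str]:
    names = list(CONTEXT_96) + list(DIFF_FEATURES)
    if mode == "freesv_plus":
        names += list(GENOMEWIDE_FEATURES)
    elif mode != "freesv":
        raise ValueError("mode must be 'freesv' or 'freesv_plus'")
    return names


def assemble_features(
    profiles: Mapping[str, MutationProfile],
    diffs: Mapping[str, DiffFeatures],
    mode: str = "freesv",
    genomewide: Optional[pd.DataFrame] = None,
    labels: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Build the samples x features matrix (101 or 105 named columns).

    Undefined Diff entries become NaN here and are median-imputed inside
    each training fold during cross-validation, never across folds.  A
    ``label`` column (control/cancer) is attached when labels are given.
    When ``mode='freesv_plus'``, ``genomewide`` must provide the four
    genome-wide summary columns indexed by sample id.
    """
    if mode == "freesv_plus" and genomewide is None:
        raise ValueError("freesv_plus mode requires the genomewide table")
    sample_ids = list(profiles)
    rows = []
    for sid in sample_ids:
        if sid not in diffs:
            raise KeyError(f"no Diff features for sample {sid!r}")
        row = dict(zip(CONTEXT_96, profiles[sid].frequencies))
        for name in DIFF_FEATURES:
            value = getattr(diffs[sid], name)
            row[name] = np.nan if value is None else float(value)
        if mode == "freesv_plus":
            if sid not in genomewide.index:
                raise KeyError(f"no genomewide features for sample {sid!r}")
            for name in GENOMEWIDE_FEATURES:
                row[name] = float(genomewide.loc[sid, name])
        rows.append(row)
    frame = pd.DataFrame(rows, index=sample_ids)[feature_names(mode)]
    expected = N_FEATURES_PLUS if mode == "freesv_plus" else N_FEATURES_BASE
    assert frame.shape[1] == expected
    if labels is not None:
        frame["label"] = [labels[sid] for sid in sample_ids]
    return frame


def _split_xy(features: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    if "label" not in features.columns:
        raise ValueError("feature frame must carry a 'label' column")
    y = (features["label"].to_numpy() == "cancer").astype(int)
    x = features.drop(columns="label")
    return x, y


def _impute_train_median(
    train: np.ndarray, test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Replace NaN by the training-fold median, column-wise."""
    train = train.copy()
    test = test.copy()
    medians = np.nanmedian(train, axis=0)
    medians = np.where(np.isnan(medians), 0.0, medians)
    for j in range(train.shape[1]):
        train[np.isnan(train[:, j]), j] = medians[j]
        test[np.isnan(test[:, j]), j] = medians[j]
    return train, test


def _tune_and_fit(
    x_train: np.ndarray,
    y_train: np.ndarray,
    tuning_grid: Sequence[dict],
    seed: int,
    inner_folds: int = 3,
) -> GradientBoostingClassifier:
    """Pick the grid point with the best inner-resampling AUC and refit."""
    best_params, best_auc = None, -np.inf
    if len(tuning_grid) == 1:
        best_params = tuning_grid[0]
    else:
        inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
        for params in tuning_grid:
            aucs = []
            for tr_idx, va_idx in inner.split(x_train, y_train):
                xt, xv = _impute_train_median(x_train[tr_idx], x_train[va_idx])
                clf = GradientBoostingClassifier(random_state=seed, **params)
                clf.fit(xt, y_train[tr_idx])
                if len(np.unique(y_train[va_idx])) < 2:
                    continue
                aucs.append(roc_auc_score(
                    y_train[va_idx], clf.predict_proba(xv)[:, 1]
                ))
            mean_auc = float(np.mean(aucs)) if aucs else -np.inf
            if mean_auc > best_auc:
                best_auc, best_params = mean_auc, params
    xt, _ = _impute_train_median(x_train, x_train)
    model = GradientBoostingClassifier(random_state=seed, **best_params)
    model.fit(xt, y_train)
    model._train_medians = np.nanmedian(x_train, axis=0)  # for later imputation
    return model


def _predict(model: GradientBoostingClassifier, x: np.ndarray) -> np.ndarray:
    x = x.copy()
    medians = np.where(np.isnan(model._train_medians), 0.0, model._train_medians)
    for j in range(x.shape[1]):
        x[np.isnan(x[:, j]), j] = medians[j]
    return model.predict_proba(x)[:, 1]


def nested_cv(
    features: pd.DataFrame,
    folds: int = 10,
    repeats: int = 100,
    seed: int = 0,
    tuning_grid: Sequence[dict] = DEFAULT_TUNING_GRID,
) -> CVResult:
    """Repeated stratified nested cross-validation.

    Per repeat, samples are split into ``folds`` stratified subsets;
    each subset is scored by a tuned gradient-boosted model trained on
    the other subsets.  Per-repeat fold seeds derive from one master
    seed, so results are fully reproducible.  Scores are averaged over
    repeats.
    """
    x_frame, y = _split_xy(features)
    if min(np.bincount(y, minlength=2)) < 2:
        raise ValueError("need at least 2 samples per class")
    x = x_frame.to_numpy(dtype=float)
    n = len(y)
    score_sum = np.zeros(n)
    fold_assignments = np.zeros((repeats, n), dtype=np.int32)
    child_seeds = np.random.SeedSequence(seed).spawn(repeats)
    for rep in range(repeats):
        rep_seed = int(child_seeds[rep].generate_state(1)[0] % (2**31 - 1))
        outer = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        for fold_idx, (tr_idx, te_idx) in enumerate(outer.split(x, y)):
            fold_assignments[rep, te_idx] = fold_idx
            model = _tune_and_fit(x[tr_idx], y[tr_idx], tuning_grid, rep_seed)
            score_sum[te_idx] += _predict(model, x[te_idx])
    return CVResult(
        sample_ids=list(x_frame.index),
        labels=y,
        scores=score_sum / repeats,
        fold_assignments=fold_assignments,
        seed=seed,
    )


def train_apply(
    train_features: pd.DataFrame,
    test_features: pd.DataFrame,
    seed: int = 0,
    tuning_grid: Sequence[dict] = DEFAULT_TUNING_GRID,
) -> np.ndarray:
    """Fit one tuned model on the training group, score the test group.

    Sample ids must be disjoint between the two groups.
    """
    overlap = set(train_features.index) & set(test_features.index)
    if overlap:
        raise ValueError(f"train/test sample ids overlap: {sorted(overlap)[:3]}")
    x_train, y_train = _split_xy(train_features)
    x_test = (test_features.drop(columns="label")
              if "label" in test_features.columns else test_features)
    if list(x_test.columns) != list(x_train.columns):
        raise ValueError("train and test feature columns differ")
    model = _tune_and_fit(
        x_train.to_numpy(dtype=float), y_train, tuning_grid, seed
    )
    return _predict(model, x_test.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def clopper_pearson(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for k successes out of n."""
    if not 0 <= k <= n or n == 0:
        raise ValueError("require 0 <= k <= n with n > 0")
    alpha = 1.0 - confidence
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def _auc_p_value(auc: float, n_pos: int, n_neg: int) -> float:
    """Two-sided Z-test of AUC against 0.5 (Hanley-McNeil variance)."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    if var <= 0:
        return 0.0
    z = (auc - 0.5) / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def roc_report(
    scores: np.ndarray,
    labels: np.ndarray,
    target_specificity: float = 0.99,
    threshold: Optional[float] = None,
) -> DiagnosticReport:
    """AUC and sensitivity at fixed specificity, with an exact 95% CI.

    The operating threshold is the smallest score cutoff achieving at
    least the target specificity on the controls of this score set; pass
    ``threshold`` to reuse a cutoff frozen on another group (the
    train-then-apply protocol).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(labels, scores))

    if threshold is None:
        threshold = pick_threshold(scores[labels == 0], target_specificity)
    control_scores = scores[labels == 0]
    specificity = float((control_scores < threshold).mean())
    detected = int((scores[labels == 1] >= threshold).sum())
    sensitivity = detected / n_pos
    ci_low, ci_high = clopper_pearson(detected, n_pos)
    return DiagnosticReport(
        auc=auc,
        auc_p=_auc_p_value(auc, n_pos, n_neg),
        target_specificity=target_specificity,
        threshold=float(threshold),
        specificity=specificity,
        sensitivity=sensitivity,
        ci_low=ci_low,
        ci_high=ci_high,
        n_cancer=n_pos,
        n_detected=detected,
    )


def pick_threshold(control_scores: np.ndarray, target_specificity: float) -> float:
    """Smallest cutoff classifying >= target fraction of controls negative.

    A sample is called positive when its score is >= the threshold.
    """
    control_scores = np.sort(np.asarray(control_scores, dtype=float))
    n = len(control_scores)
    # need ceil(target * n) controls strictly below the threshold
    need = int(np.ceil(target_specificity * n))
    if need == 0:
        return -np.inf
    if need >= n:
        return float(np.nextafter(control_scores[-1], np.inf))
    return float(np.nextafter(control_scores[need - 1], np.inf))
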