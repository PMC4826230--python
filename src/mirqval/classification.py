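"""Multivariate marker-panel evaluation with RBF-kernel support vector machines.

The protocol follows the repeated-cross-validation design common in
biomarker validation: for each requested panel size k, ten independent
repetitions of stratified 10-fold cross-validation are run; inside every
training fold, markers are ranked by two-group t-test significance in a
stepwise-forward filter and the top k are used to train an RBF-SVM; the
held-out fold is predicted and per-repetition metrics (accuracy,
sensitivity, specificity, AUC from pooled decision values) are pooled from
the fold predictions.  95% confidence intervals are the mean +/- 1.96 SD of
the ten repetition-level metrics.  A permutation null repeats the entire
procedure — including the within-fold marker selection — on randomly
reassigned class labels, exposing overtraining: a sound pipeline scores at
the majority-class rate under permutation.

Feature selection always happens inside the training portion of each fold.
A ``preselect=True`` escape hatch reproduces the optimistic variant that
ranks markers once on the full dataset before cross-validation; it is off by
default because it leaks test information into the ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .normalization import DeltaCtMatrix

__all__ = [
    "ClassificationError",
    "ClassifierConfig",
    "PanelResult",
    "ClassificationResult",
    "PermutationNull",
    "forward_filter_select",
    "cross_validate",
    "permutation_null",
]


class ClassificationError(ValueError):
    pass


@dataclass
class ClassifierConfig:
    """Hyperparameters of the panel-classification protocol.

    ``svm_gamma`` may be the string ``"scale"`` (kernel width
    1 / (n_features * variance), the package default) or a positive float.
    """

    panel_sizes: tuple[int, ...] = (5, 10, 50)
    n_repetitions: int = 10
    n_folds: int = 10
    svm_cost: float = 1.0
    svm_gamma: float | str = "scale"
    n_permutations: int = 10
    seed: int = 0
    preselect: bool = False

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ClassificationError("n_folds must be >= 2")
        if self.n_repetitions < 1:
            raise ClassificationError("n_repetitions must be >= 1")
        if self.svm_cost <= 0:
            raise ClassificationError("svm_cost must be > 0")
        if isinstance(self.svm_gamma, (int, float)) and self.svm_gamma <= 0:
            raise ClassificationError("svm_gamma must be > 0")
        if any(k < 1 for k in self.panel_sizes):
            raise ClassificationError("panel sizes must be >= 1")


@dataclass
class PanelResult:
    """Cross-validation metrics for one panel size (percent scale for rates)."""

    panel_size: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    ci_accuracy: tuple[float, float]
    ci_sensitivity: tuple[float, float]
    ci_specificity: tuple[float, float]
    ci_auc: tuple[float, float]
    per_repetition: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)
    selection_frequency: pd.Series = field(repr=False, default_factory=pd.Series)

    def consensus_panel(self) -> list[str]:
        """Markers ordered by how often the fold-level filter selected them."""
        return list(self.selection_frequency.index)


@dataclass
class ClassificationResult:
    """Results per panel size; ``positive`` names the sensitivity class."""

    panels: dict[int, PanelResult]
    contrast: tuple[str, str]
    positive: str


@dataclass
class PermutationNull:
    """Permutation-null distribution for one panel size."""

    panel_size: int
    accuracies: np.ndarray
    aucs: np.ndarray
    observed_accuracy: float
    empirical_p: float


def forward_filter_select(
    x: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    k: int,
    feature_ids: Sequence[str] | None = None,
) -> list:
    """Rank features stepwise-forward by t-test significance; return the top k.

    Features are ordered by ascending two-group Welch t-test p-value; ties are
    broken by descending |AUC - 0.5| and then lexicographically by feature id.
    Computed on whatever data is passed in — callers are responsible for
    passing training data only.
    """
    if isinstance(x, pd.DataFrame):
        feature_ids = list(x.columns)
        x = x.to_numpy(dtype=float)
    n_features = x.shape[1]
    if feature_ids is None:
        feature_ids = list(range(n_features))
    if k > n_features:
        raise ClassificationError(f"k={k} exceeds the {n_features} available markers")
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ClassificationError("filter selection needs exactly two classes")
    xa = x[y == classes[0]]
    xb = x[y == classes[1]]
    p = stats.ttest_ind(xa, xb, axis=0, equal_var=False).pvalue
    p = np.where(np.isnan(p), 1.0, p)

    n1, n2 = xa.shape[0], xb.shape[0]
    u = stats.mannwhitneyu(xa, xb, axis=0, alternative="two-sided").statistic
    auc_dev = np.abs(u / (n1 * n2) - 0.5)

    order = sorted(
        range(n_features), key=lambda i: (p[i], -auc_dev[i], str(feature_ids[i]))
    )
    return [feature_ids[i] for i in order[:k]]


def _metrics(y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray) -> dict:
    tp = np.sum((y_true == 1) & (y_pred == 1))
    tn = np.sum((y_true == 0) & (y_pred == 0))
    fp = np.sum((y_true == 0) & (y_pred == 1))
    fn = np.sum((y_true == 1) & (y_pred == 0))
    acc = 100.0 * (tp + tn) / len(y_true)
    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    pos, neg = scores[y_true == 1], scores[y_true == 0]
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return {
        "accuracy": acc,
        "sensitivity": sens,
        "specificity": spec,
        "auc": float(u / (len(pos) * len(neg))),
    }


def _ci(values: np.ndarray) -> tuple[float, float]:
    m = float(np.mean(values))
    s = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return (m - 1.96 * s, m + 1.96 * s)


def _run_cv(
    x: np.ndarray,
    y: np.ndarray,
    feature_ids: list,
    k: int,
    config: ClassifierConfig,
    rep_seeds: np.ndarray,
    corrupt_test: Callable | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """One panel size: repeated stratified CV with within-fold selection."""
    id_to_col = {f: i for i, f in enumerate(feature_ids)}
    preselected = None
    if config.preselect:
        preselected = forward_filter_select(x, y, k, feature_ids)

    rep_rows = []
    sel_counts: dict = {}
    for rep, seed in enumerate(rep_seeds):
        skf = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=int(seed)
        )
        y_pred = np.empty_like(y)
        scores = np.empty(len(y), dtype=float)
        for train_idx, test_idx in skf.split(x, y):
            if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
                raise ClassificationError(
                    "a fold contains a single class; use fewer folds for small data"
                )
            x_train, x_test = x[train_idx], x[test_idx]
            if corrupt_test is not None:
                x_test = corrupt_test(x_test, y[test_idx])
            sel = preselected or forward_filter_select(
                x_train, y[train_idx], k, feature_ids
            )
            cols = [id_to_col[f] for f in sel]
            for f in sel:
                sel_counts[f] = sel_counts.get(f, 0) + 1
            clf = SVC(
                kernel="rbf", C=config.svm_cost, gamma=config.svm_gamma
            )
            clf.fit(x_train[:, cols], y[train_idx])
            y_pred[test_idx] = clf.predict(x_test[:, cols])
            dec = clf.decision_function(x_test[:, cols])
            # orient decision values toward class 1
            scores[test_idx] = dec if clf.classes_[1] == 1 else -dec
        rep_rows.append(_metrics(y, y_pred, scores))

    per_rep = pd.DataFrame(rep_rows)
    freq = pd.Series(sel_counts, dtype=float).sort_values(ascending=False)
    freq /= config.n_repetitions * config.n_folds
    return per_rep, freq


def _prepare(delta, groups: pd.Series, contrast: tuple[str, str]):
    df = delta.values if isinstance(delta, DeltaCtMatrix) else delta
    groups = groups.reindex(df.columns)
    keep = groups.isin(contrast).to_numpy()
    if (groups == contrast[0]).sum() == 0 or (groups == contrast[1]).sum() == 0:
        raise ClassificationError(f"both groups of contrast {contrast} must be present")
    x = df.to_numpy(dtype=float).T[keep]
    y = (groups.to_numpy()[keep] == contrast[0]).astype(int)  # positive = first-named
    return x, y, list(df.index)


def cross_validate(
    delta,
    groups: pd.Series,
    contrast: tuple[str, str],
    config: ClassifierConfig | None = None,
    _corrupt_test: Callable | None = None,
) -> ClassificationResult:
    """Repeated stratified k-fold evaluation of marker panels for a contrast.

    The positive class (for sensitivity and the decision-value AUC) is the
    first-named group of the contrast.  Deterministic for a fixed config
    seed: repetition fold seeds are spawned from it, so results are
    reproducible run-to-run.  ``_corrupt_test`` is a test-only hook applied
    to held-out fold data before prediction (used by the leakage probe).
    """
    config = config or ClassifierConfig()
    x, y, feature_ids = _prepare(delta, groups, contrast)

    ss = np.random.SeedSequence(config.seed)
    panels: dict[int, PanelResult] = {}
    for k in config.panel_sizes:
        if k > len(feature_ids):
            raise ClassificationError(
                f"panel size {k} exceeds the {len(feature_ids)} available markers"
            )
        rep_seeds = ss.spawn(1)[0].generate_state(config.n_repetitions) % (2**31)
        per_rep, freq = _run_cv(
            x, y, feature_ids, k, config, rep_seeds, corrupt_test=_corrupt_test
        )
        panels[k] = PanelResult(
            panel_size=k,
            accuracy=float(per_rep["accuracy"].mean()),
            sensitivity=float(per_rep["sensitivity"].mean()),
            specificity=float(per_rep["specificity"].mean()),
            auc=float(per_rep["auc"].mean()),
            ci_accuracy=_ci(per_rep["accuracy"].to_numpy()),
            ci_sensitivity=_ci(per_rep["sensitivity"].to_numpy()),
            ci_specificity=_ci(per_rep["specificity"].to_numpy()),
            ci_auc=_ci(per_rep["auc"].to_numpy()),
            per_repetition=per_rep,
            selection_frequency=freq,
        )
    return ClassificationResult(panels=panels, contrast=contrast, positive=contrast[0])


def permutation_null(
    delta,
    groups: pd.Series,
    contrast: tuple[str, str],
    config: ClassifierConfig | None = None,
    panel_size: int | None = None,
) -> PermutationNull:
    """Rerun the whole cross-validation on permuted labels.

    Labels are shuffled once per permutation; feature selection, training and
    evaluation all see only the permuted labels, so the null captures every
    source of optimism in the pipeline.  The empirical p-value for the
    observed accuracy uses the add-one rule (1 + #null >= observed) /
    (n_permutations + 1).
    """
    config = config or ClassifierConfig()
    if config.n_permutations < 1:
        raise ClassificationError("n_permutations must be >= 1")
    k = panel_size if panel_size is not None else config.panel_sizes[0]

    observed = cross_validate(
        delta, groups, contrast,
        ClassifierConfig(**{**config.__dict__, "panel_sizes": (k,)}),
    )
    obs_acc = observed.panels[k].accuracy

    # permute labels among the contrast samples only, keeping group sizes
    df = delta.values if isinstance(delta, DeltaCtMatrix) else delta
    groups = groups.reindex(df.columns)
    keep = groups.isin(contrast)
    df = df.loc[:, keep.index[keep]]
    groups = groups[keep]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    accs, aucs = [], []
    for perm in range(config.n_permutations):
        perm_groups = pd.Series(rng.permutation(groups.to_numpy()), index=df.columns)
        res = cross_validate(
            df, perm_groups, contrast,
            ClassifierConfig(
                **{**config.__dict__, "panel_sizes": (k,), "seed": config.seed + perm + 1}
            ),
        )
        accs.append(res.panels[k].accuracy)
        aucs.append(res.panels[k].auc)

    accs_arr = np.asarray(accs)
    p_emp = (1.0 + np.sum(accs_arr >= obs_acc)) / (config.n_permutations + 1.0)
    return PermutationNull(
        panel_size=k,
        accuracies=accs_arr,
        aucs=np.asarray(aucs),
        observed_accuracy=obs_acc,
        empirical_p=float(p_emp),
    )
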