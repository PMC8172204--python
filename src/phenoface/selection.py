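"""Class-balanced SVM-RFE feature selection and LOOCV evaluation.

The classification protocol mirrors a standard imbalanced two-class
diagnostic design:

1. Per-sample weights balance the total contribution of the two diagnostic
   classes to a linear support vector machine (weight ``N / (2 * N_c)`` for a
   sample of class ``c``).
2. Recursive feature elimination (RFE) repeatedly fits the weighted linear
   SVM on z-scored features and discards the features with the smallest
   absolute coefficients, producing a full discriminative ranking.
3. Leave-one-out cross-validation (LOOCV) scores every subject with models
   trained on the remaining subjects, for an increasing number of top-ranked
   features; the optimal count ``k*`` is the smallest at which the ROC AUC
   of the held-out decision values has converged (within ``epsilon`` of the
   maximum over the evaluated grid).
4. The protocol runs once on the pooled cohort (global model) and once per
   ethnicity stratum (specific models); per-stratum accuracies are compared
   with two-sided Fisher's exact tests and summarized as relative
   improvements.

Per-feature discriminative power is screened with the nonparametric
Mann-Whitney U test (exact for small tie-free samples, otherwise the
normal approximation with tie and continuity corrections).

Two LOOCV protocols are available. ``nested`` (default) recomputes the RFE
ranking inside every training fold, so feature selection never sees the
held-out subject. ``flat`` ranks once on the full data and only refits the
SVM per fold; it is cheaper and replicates designs that report a single
feature list, at the cost of some selection leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.svm import LinearSVC

logger = logging.getLogger(__name__)

#: below this many remaining features, RFE eliminates one feature per round
RFE_FINE_THRESHOLD = 64


@dataclass
class SelectionConfig:
    """Knobs of the selection/evaluation protocol."""

    protocol: str = "nested"          # "nested" | "flat"
    C: float = 1.0                    # SVM regularization constant
    epsilon: float = 0.005            # AUC convergence tolerance for k*
    coarse_step: float = 0.1          # fraction of remaining features removed per coarse round
    fine_threshold: int = RFE_FINE_THRESHOLD
    k_grid: tuple[int, ...] | None = None
    seed: int = 0                     # recorded in reports (protocol itself is deterministic)

    def __post_init__(self) -> None:
        if self.protocol not in ("nested", "flat"):
            raise ValueError(f"unknown protocol {self.protocol!r}")


@dataclass
class SelectionResult:
    """RFE ranking, LOOCV curves, and the chosen operating point."""

    ranking: list[str]                    # best feature first (rank 1 = last eliminated)
    curves: pd.DataFrame                  # indexed by k: accuracy, accuracy_<class>..., auc
    k_star: int
    selected_features: list[str]
    predictions: pd.DataFrame             # subject_id, true, predicted, decision (at k_star)
    classes: tuple[str, str]
    config: SelectionConfig

    @property
    def accuracy(self) -> float:
        return float((self.predictions["true"] == self.predictions["predicted"]).mean())

    def per_class_accuracy(self) -> dict[str, float]:
        out = {}
        for c in self.classes:
            mask = self.predictions["true"] == c
            out[c] = float((self.predictions.loc[mask, "predicted"] == c).mean())
        return out

    def to_dict(self) -> dict:
        return {
            "ranking": list(self.ranking),
            "k_star": int(self.k_star),
            "selected_features": list(self.selected_features),
            "accuracy": self.accuracy,
            "per_class_accuracy": self.per_class_accuracy(),
            "auc": float(self.curves.loc[self.k_star, "auc"]),
            "curves": {
                str(int(k)): {c: float(v) for c, v in row.items()}
                for k, row in self.curves.iterrows()
            },
            "predictions": self.predictions.to_dict(orient="records"),
            "protocol": self.config.protocol,
            "seed": int(self.config.seed),
        }


@dataclass
class ModelComparison:
    """Fisher-exact comparison of two models' correct/incorrect counts."""

    counts: tuple[tuple[int, int], tuple[int, int]]   # [[correct_a, wrong_a], [correct_b, wrong_b]]
    p_value: float
    accuracy_a: float                                 # percent
    accuracy_b: float                                 # percent
    relative_improvement_pct: float                   # of b over a

    def to_dict(self) -> dict:
        return {
            "counts": [list(r) for r in self.counts],
            "p_value": self.p_value,
            "accuracy_a_pct": self.accuracy_a,
            "accuracy_b_pct": self.accuracy_b,
            "relative_improvement_pct": self.relative_improvement_pct,
        }


# --- elementary pieces ------------------------------------------------------

def balanced_class_weights(labels: Sequence) -> np.ndarray:
    """Per-sample weights ``N / (2 * N_c)`` equalizing the class totals.

    The summed weight of each class equals ``N / 2``.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("balanced weighting needs two nonempty classes")
    if len(classes) > 2:
        raise ValueError(f"expected two classes, got {len(classes)}")
    per_class = {c: len(y) / (2.0 * n) for c, n in zip(classes, counts)}
    return np.array([per_class[c] for c in y])


def _zscore_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return mu, sd


def _fit_svm(X: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None, C: float) -> LinearSVC:
    clf = LinearSVC(C=C, dual=False, tol=1e-5, max_iter=5000)
    clf.fit(X, y, sample_weight=sample_weight)
    return clf


def svm_rfe_ranking(
    X: pd.DataFrame,
    y: Sequence,
    sample_weight: np.ndarray | None = None,
    *,
    C: float = 1.0,
    coarse_step: float = 0.1,
    fine_threshold: int = RFE_FINE_THRESHOLD,
) -> list[str]:
    """Full RFE elimination order, best feature first.

    Each round fits the weighted linear SVM on the z-scored remaining
    features and eliminates the features with smallest ``|coefficient|``:
    ``max(1, coarse_step * remaining)`` at a time while more than
    ``fine_threshold`` features remain, then one per round. Ties on
    ``|coefficient|`` are broken lexicographically (the alphabetically
    earlier feature name is retained longer), which makes the ranking
    deterministic.
    """
    values = X.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        bad = X.columns[~np.isfinite(values).all(axis=0)]
        raise ValueError(f"non-finite feature values in {list(bad)[:5]}")
    y = np.asarray(y)
    names = list(X.columns)
    remaining = list(range(len(names)))
    eliminated: list[str] = []
    while remaining:
        if len(remaining) == 1:
            eliminated.append(names[remaining.pop()])
            break
        sub = values[:, remaining]
        mu, sd = _zscore_params(sub)
        clf = _fit_svm((sub - mu) / sd, y, sample_weight, C)
        coef = np.abs(np.asarray(clf.coef_).ravel())
        n = len(remaining)
        m = 1 if n <= fine_threshold else max(1, int(coarse_step * n))
        m = min(m, n - 1) if n > 1 else 1
        # ties on |coef|: alphabetically later names are eliminated first
        by_name_desc = sorted(range(n), key=lambda j: names[remaining[j]], reverse=True)
        order = sorted(by_name_desc, key=lambda j: coef[j])  # stable
        drop_local = order[:m]
        for j in drop_local:
            eliminated.append(names[remaining[j]])
        keep = set(drop_local)
        remaining = [idx for j, idx in enumerate(remaining) if j not in keep]
    return eliminated[::-1]


def default_k_grid(n_features: int, k_max_dense: int = 40) -> tuple[int, ...]:
    """1..min(40, p) plus powers of two up to p, plus p itself."""
    ks = set(range(1, min(k_max_dense, n_features) + 1))
    k = 64
    while k < n_features:
        ks.add(k)
        k *= 2
    ks.add(n_features)
    return tuple(sorted(ks))


def optimal_k(auc_by_k: Mapping[int, float], epsilon: float = 0.005) -> int:
    """Smallest feature count whose AUC is within ``epsilon`` of the maximum."""
    if not auc_by_k:
        raise ValueError("empty AUC curve")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    target = max(auc_by_k.values()) - epsilon
    for k in sorted(auc_by_k):
        if auc_by_k[k] >= target:
            return int(k)
    return int(max(auc_by_k))  # unreachable


# --- LOOCV ------------------------------------------------------------------

def loocv_curve(
    X: pd.DataFrame,
    y: pd.Series | Sequence,
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """LOOCV accuracy/AUC curves over feature counts, plus the final model.

    For every left-out subject, standardization parameters, the RFE ranking
    (under the ``nested`` protocol), and every SVM fit are computed on the
    remaining subjects only. The reported feature list is the full-data RFE
    ranking truncated at ``k*``.
    """
    cfg = config if config is not None else SelectionConfig()
    y = pd.Series(np.asarray(y), index=X.index)
    n = len(X)
    if n < 10:
        raise ValueError(f"LOOCV needs a cohort of at least 10 subjects, got {n}")
    classes = tuple(sorted(pd.unique(y)))
    if len(classes) != 2:
        raise ValueError(f"expected two classes, got {classes}")
    counts = y.value_counts()
    if counts.min() < 2:
        raise ValueError(
            "each class needs at least 2 subjects so no training fold loses a class"
        )
    pos = classes[1]
    values = X.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite feature values")
    p = X.shape[1]
    k_grid = tuple(k for k in (cfg.k_grid or default_k_grid(p)) if 1 <= k <= p)
    name_to_col = {c: i for i, c in enumerate(X.columns)}
    yv = y.to_numpy()

    full_weights = balanced_class_weights(yv)
    full_ranking = svm_rfe_ranking(
        X, yv, full_weights, C=cfg.C, coarse_step=cfg.coarse_step,
        fine_threshold=cfg.fine_threshold,
    )

    decisions = np.zeros((n, len(k_grid)))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = values[mask], yv[mask]
        wtr = balanced_class_weights(ytr)
        if cfg.protocol == "nested":
            ranking_i = svm_rfe_ranking(
                pd.DataFrame(Xtr, columns=X.columns), ytr, wtr,
                C=cfg.C, coarse_step=cfg.coarse_step, fine_threshold=cfg.fine_threshold,
            )
        else:
            ranking_i = full_ranking
        cols_order = [name_to_col[f] for f in ranking_i]
        mu, sd = _zscore_params(Xtr)
        Ztr = (Xtr - mu) / sd
        zte = (values[i] - mu) / sd
        for kj, k in enumerate(k_grid):
            cols = cols_order[:k]
            clf = _fit_svm(Ztr[:, cols], ytr, wtr, cfg.C)
            d = float(clf.decision_function(zte[cols].reshape(1, -1))[0])
            # orient the decision value toward the lexicographically larger class
            if clf.classes_[1] != pos:
                d = -d
            decisions[i, kj] = d

    y_bin = (yv == pos).astype(int)
    rows = []
    for kj, k in enumerate(k_grid):
        pred = np.where(decisions[:, kj] > 0, pos, classes[0])
        row = {"accuracy": float((pred == yv).mean())}
        for c in classes:
            m = yv == c
            row[f"accuracy_{c}"] = float((pred[m] == c).mean())
        row["auc"] = float(roc_auc_score(y_bin, decisions[:, kj]))
        rows.append(row)
    curves = pd.DataFrame(rows, index=pd.Index(k_grid, name="k"))

    k_star = optimal_k(dict(zip(k_grid, curves["auc"])), cfg.epsilon)
    kj_star = list(k_grid).index(k_star)
    pred_star = np.where(decisions[:, kj_star] > 0, pos, classes[0])
    predictions = pd.DataFrame(
        {
            "subject_id": list(X.index),
            "true": yv,
            "predicted": pred_star,
            "decision": decisions[:, kj_star],
        }
    )
    return SelectionResult(
        ranking=full_ranking,
        curves=curves,
        k_star=int(k_star),
        selected_features=full_ranking[:k_star],
        predictions=predictions,
        classes=classes,
        config=cfg,
    )


# --- univariate screening and model comparison ------------------------------

def mann_whitney(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (for group a) and two-sided p-value.

    Exact by enumeration for tie-free samples with ``n_a + n_b <= 20``,
    otherwise the normal approximation with tie and continuity corrections.
    Identical groups return p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2.0), 1.0
    n = a.size + b.size
    has_ties = np.unique(pooled).size < n
    method = "exact" if (n <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(1.0, res.pvalue))


def feature_screening(X: pd.DataFrame, y: Sequence) -> pd.DataFrame:
    """Per-feature Mann-Whitney screening between the two classes.

    Returns a DataFrame indexed by feature with columns ``U``, ``p`` (raw)
    and ``q`` (Benjamini-Hochberg adjusted).
    """
    y = np.asarray(y)
    classes = sorted(pd.unique(y))
    if len(classes) != 2:
        raise ValueError(f"expected two classes, got {classes}")
    mask_a = y == classes[0]
    rows = {}
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        u, p = mann_whitney(v[mask_a], v[~mask_a])
        rows[col] = (u, p)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["U", "p"])
    out.index.name = "feature"
    out["q"] = stats.false_discovery_control(out["p"].to_numpy(), method="bh")
    return out


def relative_improvement(acc_global: float, acc_specific: float) -> float:
    """Relative accuracy improvement, percent: ``100 (a_s - a_g) / a_g``."""
    if acc_global <= 0:
        raise ValueError("baseline accuracy must be positive")
    return 100.0 * (acc_specific - acc_global) / acc_global


def fisher_compare(correct_a: int, total_a: int, correct_b: int, total_b: int) -> ModelComparison:
    """Two-sided Fisher's exact comparison of two correct/incorrect counts.

    The two-sided p-value sums hypergeometric probabilities of all tables at
    most as probable as the observed one (scipy's convention).
    """
    for c, t in ((correct_a, total_a), (correct_b, total_b)):
        if t <= 0:
            raise ValueError("totals must be positive")
        if not 0 <= c <= t:
            raise ValueError(f"correct count {c} outside [0, {t}]")
    table = [[correct_a, total_a - correct_a], [correct_b, total_b - correct_b]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    acc_a = 100.0 * correct_a / total_a
    acc_b = 100.0 * correct_b / total_b
    return ModelComparison(
        counts=((correct_a, total_a - correct_a), (correct_b, total_b - correct_b)),
        p_value=float(min(1.0, p)),
        accuracy_a=acc_a,
        accuracy_b=acc_b,
        relative_improvement_pct=relative_improvement(acc_a, acc_b) if acc_a > 0 else float("nan"),
    )


def overall_from_group_accuracies(
    accuracies_pct: Sequence[float], group_sizes: Sequence[int]
) -> tuple[int, int, float]:
    """Recombine per-group percentage accuracies into pooled counts.

    Each group's correct count is recovered as ``round(acc * n / 100)``;
    returns ``(correct, total, overall_accuracy_pct)``. This is the
    accounting used to check that stratified accuracy tables are consistent
    with their printed overall figures.
    """
    if len(accuracies_pct) != len(group_sizes):
        raise ValueError("accuracies and group sizes must align")
    correct = int(sum(int(round(a * n / 100.0)) for a, n in zip(accuracies_pct, group_sizes)))
    total = int(sum(group_sizes))
    return correct, total, 100.0 * correct / total


# --- stratified evaluation --------------------------------------------------

def stratified_evaluation(
    X: pd.DataFrame,
    y: Sequence,
    strata: Sequence,
    config: SelectionConfig | None = None,
) -> dict:
    """Global vs. stratum-specific selection/LOOCV protocol.

    Runs the full protocol once on the pooled cohort and once per stratum,
    then compares the global model's per-stratum accuracy against each
    specific model with Fisher's exact test and relative improvement, and
    pools the specific models' correct counts into an overall accuracy.
    Strata missing a class (or with fewer than 2 subjects in one) are
    skipped with a warning. Returns a JSON-serializable report.
    """
    cfg = config if config is not None else SelectionConfig()
    y = pd.Series(np.asarray(y), index=X.index)
    strata = pd.Series(np.asarray(strata), index=X.index)

    global_res = loocv_curve(X, y, cfg)
    gpred = global_res.predictions.set_index("subject_id")
    gcorrect = gpred["true"] == gpred["predicted"]

    report: dict = {
        "protocol": cfg.protocol,
        "seed": int(cfg.seed),
        "classes": list(global_res.classes),
        "global": global_res.to_dict(),
        "strata": {},
        "comparison": {},
    }

    evaluated: list[str] = []
    pooled_specific_correct = 0
    pooled_global_correct = 0
    pooled_n = 0
    for s in sorted(pd.unique(strata)):
        mask = strata == s
        ys = y[mask]
        vc = ys.value_counts()
        if len(vc) < 2 or vc.min() < 2:
            logger.warning(
                "stratum %r skipped: needs both classes with >= 2 subjects (have %s)",
                s, vc.to_dict(),
            )
            continue
        res_s = loocv_curve(X.loc[mask], ys, cfg)
        spred = res_s.predictions.set_index("subject_id")
        n_s = int(mask.sum())
        correct_specific = int((spred["true"] == spred["predicted"]).sum())
        correct_global = int(gcorrect.loc[X.index[mask]].sum())
        cmp_s = fisher_compare(correct_global, n_s, correct_specific, n_s)
        report["strata"][str(s)] = res_s.to_dict()
        report["comparison"][str(s)] = {
            "n": n_s,
            "global_accuracy_pct": cmp_s.accuracy_a,
            "specific_accuracy_pct": cmp_s.accuracy_b,
            "improvement_pct": cmp_s.relative_improvement_pct,
            "fisher_p": cmp_s.p_value,
        }
        evaluated.append(str(s))
        pooled_specific_correct += correct_specific
        pooled_global_correct += correct_global
        pooled_n += n_s

    if pooled_n:
        cmp_all = fisher_compare(pooled_global_correct, pooled_n, pooled_specific_correct, pooled_n)
        report["comparison"]["overall"] = {
            "n": pooled_n,
            "strata": evaluated,
            "global_accuracy_pct": cmp_all.accuracy_a,
            "specific_accuracy_pct": cmp_all.accuracy_b,
            "improvement_pct": cmp_all.relative_improvement_pct,
            "fisher_p": cmp_all.p_value,
        }
        # the same overall figures, recombined from the per-stratum accuracies
        accs_g = [report["comparison"][s]["global_accuracy_pct"] for s in evaluated]
        accs_s = [report["comparison"][s]["specific_accuracy_pct"] for s in evaluated]
        ns = [report["comparison"][s]["n"] for s in evaluated]
        cg, tg, ag = overall_from_group_accuracies(accs_g, ns)
        cs, ts, a_s = overall_from_group_accuracies(accs_s, ns)
        report["comparison"]["overall_recombined"] = {
            "global": {"correct": cg, "total": tg, "accuracy_pct": ag},
            "specific": {"correct": cs, "total": ts, "accuracy_pct": a_s},
        }
    return report
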