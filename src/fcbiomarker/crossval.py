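"""Nested feature-selection + leave-one-out cross-validation, inference, and
generalisation.

For each held-out subject the candidate FC set is chosen by L1-SCCA on the
remaining subjects only (5 inner folds × a 5-point sparsity grid, pooled),
the ARD sparse logistic model is fitted on those subjects, and the held-out
subject is scored — so no information from the held-out subject enters
feature selection, standardisation, or fitting.  Across the N folds the
importance of edge kappa is its cumulative absolute weight

    c^kappa = sum_{i=1}^{N} |W_i^kappa|,

where W_i^kappa is the weight edge kappa received in fold i (zero when not
selected).  Significance of the classifier is assessed by a label-permutation
test that re-runs the entire nested procedure per permutation; the final
biomarker is the ARD-surviving feature set of a full-training-set fit on the
union of ever-selected candidates, and generalisation is measured by applying
that frozen model — standardisation constants included — to an independent
cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataset import FCDataset
from .scca import SCCAParams, select_features
from .slr import SLRModel, TrainOptions, slr_fit, slr_predict

__all__ = [
    "CVConfig",
    "CVResult",
    "PermutationResult",
    "CVError",
    "loocv_run",
    "cumulative_weights",
    "performance",
    "permutation_test",
    "final_model",
    "wilcoxon_weights",
    "generalize",
]


class CVError(ValueError):
    pass


@dataclass
class CVConfig:
    scca: SCCAParams = field(default_factory=SCCAParams)
    slr: TrainOptions = field(default_factory=TrainOptions)
    seed: int = 0
    threshold: float = 0.5


@dataclass
class CVResult:
    """Outcome of one nested LOOCV run."""

    n_subjects: int
    n_features: int
    selected: list                 # per fold: candidate edge ids (np arrays)
    weights: np.ndarray            # folds × E, zero where not selected/pruned
    predictions: np.ndarray        # per-subject held-out P(StD)
    labels: np.ndarray
    fold_standardization: list     # per fold: (mean over candidates, sd) for audit
    accuracy: float = float("nan")
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    auc: float = float("nan")

    @property
    def ever_selected(self) -> np.ndarray:
        """Edges that entered the candidate set in at least one LOOCV fold."""
        s: set[int] = set()
        for sel in self.selected:
            s.update(np.asarray(sel).tolist())
        return np.array(sorted(s), dtype=int)

    @property
    def cumulative(self) -> np.ndarray:
        """c^kappa = sum_i |W_i^kappa| for every edge."""
        return np.abs(self.weights).sum(axis=0)


@dataclass
class PermutationResult:
    observed: float
    permuted: np.ndarray
    p_value: float
    statistic: str
    seed: int


def performance(predictions: np.ndarray, labels: np.ndarray,
                threshold: float = 0.5) -> tuple:
    """(accuracy, sensitivity, specificity, AUC) with StD (label 1) positive.

    Decisions are probability > threshold (ties negative).  AUC uses the rank
    (Mann–Whitney) formula with half credit for tied scores.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise CVError("predictions and labels misaligned")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise CVError("AUC undefined: one class is empty")
    pred = (p > threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    accuracy = (tp + tn) / len(y)
    sensitivity = tp / n_pos
    specificity = tn / n_neg
    ranks = stats.rankdata(p)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return accuracy, sensitivity, specificity, float(auc)


def roc_points(predictions: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Empirical ROC curve: rows of (threshold, fpr, tpr), thresholds from
    +inf down through every distinct score (prediction >= threshold = StD)."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise CVError("ROC undefined: one class is empty")
    thresholds = np.concatenate([[np.inf], np.unique(p)[::-1]])
    rows = [(t, float(np.mean(p[y == 0] >= t)), float(np.mean(p[y == 1] >= t)))
            for t in thresholds]
    return np.array(rows)


def loocv_run(ds: FCDataset, config: CVConfig | None = None) -> CVResult:
    """Leave-one-out CV with per-fold nested feature selection.

    Deterministic given ``config.seed``: the inner-fold assignment of fold i
    uses a seed derived from (config.seed, i).
    """
    config = config or CVConfig()
    y = ds.y
    if min(np.bincount(y, minlength=2)) < 2:
        raise CVError("need at least 2 subjects per class for LOOCV")
    n, E = ds.n_subjects, ds.n_features
    weights = np.zeros((n, E))
    predictions = np.empty(n)
    selected: list[np.ndarray] = []
    fold_standardization: list = []
    base = np.random.SeedSequence([int(config.seed), 911])
    fold_seeds = base.generate_state(n) % (2**31 - 1)

    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        y_tr = y[tr]
        if len(np.unique(y_tr)) < 2:
            raise CVError(f"fold {i}: a class is absent from the training subset")
        cand = select_features(ds.X[tr], y_tr, np.asarray(ds.age)[tr],
                               np.asarray(ds.sex)[tr], config.scca,
                               seed=int(fold_seeds[i]))
        selected.append(cand)
        if cand.size == 0:
            # nothing selected even after fallback: intercept-only prediction
            predictions[i] = float(y_tr.mean())
            fold_standardization.append((np.array([]), np.array([])))
            continue
        model = slr_fit(ds.X[tr][:, cand], y_tr, config.slr)
        predictions[i] = slr_predict(model, ds.X[i, cand])
        weights[i, cand[model.feature_ids]] = model.weights
        fold_standardization.append((model.mean_.copy(), model.scale_.copy()))

    acc, sens, spec, auc = performance(predictions, y, config.threshold)
    return CVResult(
        n_subjects=n,
        n_features=E,
        selected=selected,
        weights=weights,
        predictions=predictions,
        labels=y.copy(),
        fold_standardization=fold_standardization,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
    )


def cumulative_weights(cv: CVResult) -> list:
    """Edges ranked by cumulative absolute weight c^kappa, descending.

    Returns (edge id, c) pairs; ties broken by ascending edge id.
    """
    c = cv.cumulative
    order = np.lexsort((np.arange(len(c)), -c))
    return [(int(k), float(c[k])) for k in order]


def permutation_test(ds: FCDataset, config: CVConfig | None = None,
                     n_perm: int = 100, statistic: str = "accuracy",
                     seed: int | None = None) -> PermutationResult:
    """Label-permutation test of LOOCV performance.

    Labels are permuted over the whole training set and the entire nested
    pipeline (selection + fitting + LOOCV) is re-run per permutation;
    p = (1 + #{permuted >= observed}) / (n_perm + 1).
    """
    if n_perm < 19:
        raise CVError("n_perm must be >= 19")
    if statistic not in ("accuracy", "auc"):
        raise CVError(f"unknown statistic {statistic!r}")
    config = config or CVConfig()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 727]))

    def stat_of(result: CVResult) -> float:
        return result.accuracy if statistic == "accuracy" else result.auc

    observed = stat_of(loocv_run(ds, config))
    permuted = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(ds.n_subjects)
        ds_b = FCDataset(
            X=ds.X, y=ds.y[perm], age=np.asarray(ds.age)[perm],
            sex=np.asarray(ds.sex)[perm], subject_ids=ds.subject_ids,
            n_regions=ds.n_regions, scale=ds.scale,
        )
        permuted[b] = stat_of(loocv_run(ds_b, config))
    p = (1.0 + np.sum(permuted >= observed)) / (n_perm + 1.0)
    return PermutationResult(observed=float(observed), permuted=permuted,
                             p_value=float(p), statistic=statistic, seed=int(seed))


def final_model(ds: FCDataset, cv: CVResult, config: CVConfig | None = None,
                identify: str = "ard",
                min_selection_fraction: float = 0.5) -> tuple:
    """Fit the deployable classifier and identify the surviving FC set.

    The full training set is fitted (ARD logistic) on the union of candidates
    ever selected during LOOCV.  With ``identify="ard"`` (default) the
    identified FCs are the features surviving ARD pruning in that fit; with
    ``identify="frequency"`` they are the edges selected in at least
    ``min_selection_fraction`` of the LOOCV folds — useful when the union
    exceeds the sample size and relevance-determination pruning is weak.
    Returns ``(model, identified_edge_ids)`` where the model's
    ``feature_ids`` index into the ever-selected union and
    ``identified_edge_ids`` are canonical edge ids.
    """
    config = config or CVConfig()
    union = cv.ever_selected
    if union.size == 0:
        raise CVError("ever-selected candidate union is empty")
    model = slr_fit(ds.X[:, union], ds.y, config.slr)
    if identify == "ard":
        identified = union[model.feature_ids]
    elif identify == "frequency":
        counts = np.zeros(cv.n_features)
        for sel in cv.selected:
            counts[np.asarray(sel, dtype=int)] += 1
        identified = union[counts[union] >= min_selection_fraction * len(cv.selected)]
    else:
        raise CVError(f"unknown identification rule {identify!r}")
    model.edge_ids = union          # columns the model expects, as edge ids
    return model, identified


def wilcoxon_weights(cv: CVResult, fc_ids) -> dict:
    """Two-sided Wilcoxon signed-rank test of the fold weights of each FC.

    Tests whether an edge's weights across the LOOCV folds are symmetrically
    distributed about zero.  Zero fold weights are dropped (Wilcoxon
    convention); the exact null distribution is used for up to 25 nonzero
    weights, a tie-corrected normal approximation above.  Edges whose fold
    weights are all zero get p = 1.0 and are flagged.

    Returns {edge id: {"p": float, "n_nonzero": int, "flagged": bool}}.
    """
    out = {}
    for k in np.atleast_1d(np.asarray(fc_ids, dtype=int)):
        w = cv.weights[:, k]
        nz = w[w != 0.0]
        if nz.size == 0:
            out[int(k)] = {"p": 1.0, "n_nonzero": 0, "flagged": True}
            continue
        if nz.size < 6:
            out[int(k)] = {"p": 1.0, "n_nonzero": int(nz.size), "flagged": True}
            continue
        has_ties = len(np.unique(np.abs(nz))) < nz.size
        method = "exact" if (nz.size <= 25 and not has_ties) else "approx"
        res = stats.wilcoxon(nz, alternative="two-sided", method=method)
        out[int(k)] = {"p": float(res.pvalue), "n_nonzero": int(nz.size),
                       "flagged": False}
    return out


def generalize(model: SLRModel, external: FCDataset,
               threshold: float = 0.5) -> tuple:
    """Apply a frozen classifier to an independent cohort; no refitting.

    The model's training standardisation constants are reused unchanged.  The
    model must have been produced by :func:`final_model` (it carries the edge
    ids of its input columns); the external cohort must share the canonical
    edge indexing.  Returns (accuracy, sensitivity, specificity, AUC).
    """
    edge_ids = getattr(model, "edge_ids", None)
    if edge_ids is None:
        raise CVError("model does not carry edge ids; fit it with final_model")
    if external.n_features <= int(np.max(edge_ids)):
        raise CVError(
            f"edge-index mismatch: model expects edges up to {int(np.max(edge_ids))} "
            f"but external cohort has {external.n_features}"
        )
    preds = slr_predict(model, external.X[:, edge_ids])
    return performance(np.asarray(preds), external.y, threshold)
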