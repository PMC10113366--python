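"""Post-hoc statistics around the classifier.

Covers the descriptive and inferential analyses that accompany the biomarker:
the contribution index (rStD − rHC) × weight of each identified FC, group
mean correlations, mass-univariate two-sample t tests over all edges with
Bonferroni control at 0.05/E, demographics comparisons (two-tailed t test for
continuous variables, Pearson chi-squared for sex), the BDI-II anhedonic
subscore (items 4, 12, 15, 21), and FC–clinical-score correlations where the
correlation method is gated by a normality test and significance uses a
Bonferroni-adjusted level (0.05/8 = 0.006 for eight identified FCs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import FCDataset
from .synthcohort import ANHEDONIA_ITEMS

__all__ = [
    "ContributionRecord",
    "ClinStatsError",
    "contribution_index",
    "group_mean_fc",
    "mass_univariate_ttest",
    "demographics_tests",
    "bdi_anhedonia",
    "clinical_correlation",
    "contribution_table",
]


class ClinStatsError(ValueError):
    pass


@dataclass
class ContributionRecord:
    fc_id: int
    r_std: float
    r_hc: float
    weight: float
    contribution: float


def contribution_index(r_std: float, r_hc: float, weight: float) -> float:
    """(rStD − rHC) × weight: an edge's signed contribution to discrimination.

    Positive when the weight points in the direction of the group difference;
    swapping the group means flips the sign.
    """
    if not (-1.0 <= r_std <= 1.0) or not (-1.0 <= r_hc <= 1.0):
        raise ClinStatsError("group mean correlations must lie in [-1, 1]")
    return (r_std - r_hc) * weight


def group_mean_fc(ds: FCDataset, fc_id: int, group: str) -> float:
    """Mean Pearson correlation of one edge within one group.

    Averaging is done on the r scale (back-transforming from Fisher z when
    the dataset is stored on the z scale), matching how group means are
    conventionally tabulated.
    """
    if group == "StD":
        rows = ds.y == 1
    elif group == "HC":
        rows = ds.y == 0
    else:
        raise ClinStatsError(f"unknown group {group!r}")
    if not rows.any():
        raise ClinStatsError(f"group {group} is empty")
    vals = ds.X[rows, fc_id]
    if ds.scale == "fisher_z":
        vals = np.tanh(vals)
    return float(vals.mean())


def contribution_table(ds: FCDataset, edge_ids, weights) -> list:
    """ContributionRecord per identified edge, from group means and weights."""
    out = []
    for k, w in zip(np.atleast_1d(edge_ids), np.atleast_1d(weights)):
        r_s = group_mean_fc(ds, int(k), "StD")
        r_h = group_mean_fc(ds, int(k), "HC")
        out.append(ContributionRecord(int(k), r_s, r_h, float(w),
                                      contribution_index(r_s, r_h, float(w))))
    out.sort(key=lambda rec: -abs(rec.contribution))
    return out


def mass_univariate_ttest(ds: FCDataset, alpha: float = 0.05) -> pd.DataFrame:
    """Pooled-variance two-sample t test per edge, Bonferroni at alpha/E.

    Run on the Fisher-z values.  Edges with zero pooled variance get t = 0,
    p = 1 and a ``degenerate`` flag.
    """
    a, b = ds.X[ds.y == 1], ds.X[ds.y == 0]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ClinStatsError("both groups need >= 2 subjects")
    res = stats.ttest_ind(a, b, axis=0, equal_var=True)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(t)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    E = ds.n_features
    return pd.DataFrame({
        "edge_id": np.arange(E),
        "t": t,
        "p": p,
        "significant": p < alpha / E,
        "degenerate": degenerate,
    })


def demographics_tests(meta: pd.DataFrame) -> pd.DataFrame:
    """Group comparisons of the metadata table (StD vs HC).

    Continuous variables (age, BDI-II total) use a pooled two-tailed t test;
    sex uses the Pearson chi-squared test on the 2×2 male/female table with
    df = 1 and no continuity correction.  ``meta`` needs columns ``group``
    (StD/HC), ``age``, ``bdi_total``, ``sex`` (male/female).
    """
    for col in ("group", "age", "bdi_total", "sex"):
        if col not in meta.columns:
            raise ClinStatsError(f"metadata is missing column {col!r}")
    g_std = meta[meta["group"] == "StD"]
    g_hc = meta[meta["group"] == "HC"]
    if len(g_std) == 0 or len(g_hc) == 0:
        raise ClinStatsError("both groups must be present")
    rows = []
    for col, label in (("age", "Age (years)"), ("bdi_total", "BDI-II")):
        res = stats.ttest_ind(g_std[col], g_hc[col], equal_var=True)
        rows.append({"variable": label, "test": "t",
                     "statistic": float(res.statistic), "p": float(res.pvalue)})
    table = np.array([
        [(g_std["sex"] == "male").sum(), (g_std["sex"] == "female").sum()],
        [(g_hc["sex"] == "male").sum(), (g_hc["sex"] == "female").sum()],
    ])
    if (table.sum(axis=0) == 0).any():
        raise ClinStatsError("a sex category is empty in both groups (expected count 0)")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    rows.append({"variable": "Sex (male/female)", "test": "chi2",
                 "statistic": float(chi2), "p": float(p)})
    return pd.DataFrame(rows)


def bdi_anhedonia(items) -> int:
    """BDI-II anhedonic subscore: items #4, #12, #15, #21 (1-based), range 0–12."""
    items = list(items)
    if len(items) != 21:
        raise ClinStatsError(f"expected 21 BDI-II items, got {len(items)}")
    for k, v in enumerate(items, start=1):
        if not (0 <= int(v) <= 3) or int(v) != v:
            raise ClinStatsError(f"item #{k} out of range 0..3: {v!r}")
    return int(sum(items[k - 1] for k in ANHEDONIA_ITEMS))


def clinical_correlation(fc_values, scores, n_tests: int = 8,
                         normality_alpha: float = 0.05,
                         alpha: float = 0.05) -> dict:
    """Correlate one FC with one clinical score, normality-gated.

    Shapiro–Wilk is run on both variables at ``normality_alpha``; if neither
    rejects, Pearson's r is used, otherwise Spearman's rank rho.  The
    significance flag applies a Bonferroni-adjusted level alpha/n_tests
    (0.05/8 ≈ 0.006 for the eight identified FCs).
    """
    x = np.asarray(fc_values, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ClinStatsError("fc values and scores must be paired 1-D arrays")
    if x.size < 4:
        raise ClinStatsError("need at least 4 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ClinStatsError("constant variable: correlation undefined")
    normal = (stats.shapiro(x).pvalue > normality_alpha
              and stats.shapiro(y).pvalue > normality_alpha)
    if normal:
        r, p = stats.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = stats.spearmanr(x, y)
        method = "spearman"
    threshold = alpha / n_tests
    return {"method": method, "r": float(r), "p": float(p),
            "threshold": threshold, "significant": bool(p < threshold)}
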