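"""Cirrhosis-vs-HCC marker statistics.

Implements the gender-balanced three-subset testing procedure (Welch t and
Wilcoxon rank-sum per subset, Bonferroni ×3, significance required in every
subset), nonparametric ROC-AUC with DeLong or bootstrap confidence
intervals, in-sample logistic marker combination, and Pareto-scaled PCA.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression

from .synthetic import HCC, PatientRecord

__all__ = [
    "StatsConfig",
    "TestResult",
    "RocResult",
    "gender_balanced_subsets",
    "differential_tests",
    "roc_auc",
    "combine_markers",
    "pca_scores",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    n_subsets: int = 3
    bonferroni_n: int = 3
    subset_seed: int = 12345
    roc_ci_level: float = 0.95
    roc_ci_method: str = "delong"      # delong | bootstrap
    n_bootstrap: int = 2000
    pca_scaling: str = "pareto"        # pareto | autoscale
    welch: bool = True                 # False -> pooled-variance Student's t
    subset_rule: str = "all"           # all | any | majority

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class TestResult:
    feature: str
    t_p: tuple[float, ...]             # raw t-test p per subset
    wilcoxon_p: tuple[float, ...]      # raw rank-sum p per subset
    corrected_p: tuple[float, ...]     # Bonferroni-corrected t-test p per subset
    significant: bool
    flagged: bool = False              # constant feature in both groups


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    flipped: bool = False

    def __post_init__(self) -> None:
        if not self.ci_low <= self.auc <= self.ci_high:
            raise ValueError("confidence interval must bracket the AUC")


def gender_balanced_subsets(
    patients: Sequence[PatientRecord], config: StatsConfig | None = None
) -> list[list[str]]:
    """Gender-balanced patient subsets for the repeated testing procedure.

    Both groups are subsampled (without replacement, seeded) to the
    per-gender minimum counts across groups, so the two arms end with
    identical M and F counts — e.g. 3M/12F vs 7M/8F becomes 3M/8F in each
    arm. Already-balanced cohorts pass through unchanged in every subset.
    """
    config = config or StatsConfig()
    pools: dict[tuple[str, str], list[str]] = {}
    for p in patients:
        pools.setdefault((p.group, p.gender), []).append(p.patient_id)
    groups = sorted({p.group for p in patients})
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    for g in groups:
        for gender in ("M", "F"):
            if not pools.get((g, gender)):
                raise ValueError(
                    f"group {g!r} has no {gender} patients; "
                    "choose explicit gender ratio targets instead"
                )
    target = {
        gender: min(len(pools[(g, gender)]) for g in groups) for gender in ("M", "F")
    }
    balanced = all(
        len(pools[(g, gender)]) == target[gender] for g in groups for gender in ("M", "F")
    )
    rng = np.random.default_rng(config.subset_seed)
    subsets: list[list[str]] = []
    for _ in range(config.n_subsets):
        chosen: list[str] = []
        for g in groups:
            for gender in ("M", "F"):
                pool = pools[(g, gender)]
                if balanced or len(pool) == target[gender]:
                    chosen.extend(pool)
                else:
                    chosen.extend(rng.choice(pool, size=target[gender], replace=False))
        subsets.append(sorted(chosen))
    if not balanced:
        logger.info(
            "gender balancing: %d subsets of %d patients (%dM/%dF per arm)",
            config.n_subsets,
            len(subsets[0]),
            target["M"],
            target["F"],
        )
    return subsets


def _two_sample_p(x: np.ndarray, y: np.ndarray, welch: bool) -> tuple[float, float]:
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0, 1.0
    t_p = sps.ttest_ind(x, y, equal_var=not welch).pvalue
    w_p = sps.ranksums(x, y).pvalue
    return float(t_p), float(w_p)


def differential_tests(
    rel: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    subsets: Sequence[Sequence[str]],
    config: StatsConfig | None = None,
) -> list[TestResult]:
    """Per-feature two-sample tests on every gender-balanced subset.

    For each feature and subset a two-sided Welch t-test (or pooled
    Student's t) and a Wilcoxon rank-sum test compare the two groups'
    relative abundances; t-test p-values are Bonferroni-corrected
    (×``bonferroni_n``, capped at 1). A feature is significant when the
    corrected t-test p beats alpha in the configured fraction of subsets
    (default: all of them). Features constant in both groups get p = 1 and
    a flag.
    """
    config = config or StatsConfig()
    groups = pd.Series(dict(groups))
    results: list[TestResult] = []
    group_names = sorted(groups.unique())
    for feature in rel.columns:
        t_ps, w_ps, corr = [], [], []
        flagged = False
        for subset in subsets:
            ids = [pid for pid in subset if pid in rel.index]
            vals = rel.loc[ids, feature]
            x = vals[groups[ids] == group_names[0]].to_numpy(dtype=float)
            y = vals[groups[ids] == group_names[1]].to_numpy(dtype=float)
            if len(x) < 2 or len(y) < 2:
                raise ValueError("each group needs >= 2 patients per subset")
            t_p, w_p = _two_sample_p(x, y, config.welch)
            flagged = flagged or (t_p == 1.0 and w_p == 1.0 and np.ptp(np.r_[x, y]) == 0)
            t_ps.append(t_p)
            w_ps.append(w_p)
            corr.append(min(1.0, t_p * config.bonferroni_n))
        hits = sum(c < config.alpha for c in corr)
        if config.subset_rule == "all":
            significant = hits == len(subsets)
        elif config.subset_rule == "any":
            significant = hits >= 1
        else:  # majority
            significant = hits > len(subsets) / 2
        results.append(
            TestResult(
                feature=feature,
                t_p=tuple(t_ps),
                wilcoxon_p=tuple(w_ps),
                corrected_p=tuple(corr),
                significant=significant,
                flagged=flagged,
            )
        )
    return results


def test_results_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    """Flatten test results into the per-feature results table."""
    rows = []
    for r in results:
        row: dict[str, object] = {"feature": r.feature, "significant": r.significant}
        for i, (t_p, w_p, c_p) in enumerate(zip(r.t_p, r.wilcoxon_p, r.corrected_p), 1):
            row[f"t_p_subset{i}"] = t_p
            row[f"wilcoxon_p_subset{i}"] = w_p
            row[f"corrected_p_subset{i}"] = c_p
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")


def _auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    # Mann-Whitney U with half credit for ties, via midranks.
    all_scores = np.concatenate([pos, neg])
    ranks = sps.rankdata(all_scores)
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    m, n = len(pos), len(neg)
    # placements via midranks (DeLong's structural components)
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[int] | Sequence[bool],
    config: StatsConfig | None = None,
    auto_flip: bool = True,
) -> RocResult:
    """Nonparametric ROC-AUC with a confidence interval.

    AUC is the Mann-Whitney statistic (ties get half credit), oriented so a
    larger score indicates the positive (HCC) class; a feature with the
    opposite direction is flipped and flagged when ``auto_flip``. CI by
    DeLong's method (default) or a seeded percentile bootstrap.
    """
    config = config or StatsConfig()
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    auc = _auc_mann_whitney(pos, neg)
    flipped = False
    if auto_flip and auc < 0.5:
        scores, pos, neg = -scores, -pos, -neg
        auc = 1.0 - auc
        flipped = True
        logger.info("ROC orientation flipped (marker decreases in the positive class)")
    z = sps.norm.ppf(0.5 + config.roc_ci_level / 2)
    if config.roc_ci_method == "delong":
        se = math.sqrt(_delong_variance(pos, neg))
        lo, hi = auc - z * se, auc + z * se
    elif config.roc_ci_method == "bootstrap":
        rng = np.random.default_rng(config.subset_seed)
        boots = []
        for _ in range(config.n_bootstrap):
            p = rng.choice(pos, size=len(pos), replace=True)
            q = rng.choice(neg, size=len(neg), replace=True)
            boots.append(_auc_mann_whitney(p, q))
        alpha = 1 - config.roc_ci_level
        lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    else:
        raise ValueError(f"unknown roc_ci_method {config.roc_ci_method!r}")
    return RocResult(
        auc=auc,
        ci_low=float(min(max(lo, 0.0), auc)),
        ci_high=float(max(min(hi, 1.0), auc)),
        n_pos=len(pos),
        n_neg=len(neg),
        flipped=flipped,
    )


def combine_markers(
    features: pd.DataFrame,
    labels: Sequence[int] | Sequence[bool],
    config: StatsConfig | None = None,
    log_transform: Sequence[str] = ("afp_ng_ml",),
) -> tuple[np.ndarray, RocResult]:
    """In-sample logistic combination of a marker panel.

    Features are standardized (AFP log-transformed first) and fit with an
    unpenalized binary logistic regression; the combined score is the linear
    predictor and its AUC is computed in-sample on the fitting cohort (the
    optimistic convention of panel-building with ROC software). Missing
    values are imputed with the feature median (logged). Perfect separation
    falls back to a ridge-penalized fit.
    """
    config = config or StatsConfig()
    labels = np.asarray(labels).astype(int)
    X = features.astype(float).copy()
    for col in log_transform:
        if col in X.columns:
            X[col] = np.log(X[col].clip(lower=1e-12))
    if X.isna().any().any():
        logger.info("imputing missing feature values with the feature median")
        X = X.fillna(X.median())
    mu, sd = X.mean(), X.std(ddof=0).replace(0.0, 1.0)
    Xs = ((X - mu) / sd).to_numpy()
    try:
        model = LogisticRegression(C=np.inf, max_iter=10_000)
        model.fit(Xs, labels)
        if np.abs(model.coef_).max() > 1e4:  # runaway coefficients: separation
            raise ValueError("perfect separation")
    except Exception:
        logger.info("logistic fit degenerate (separation?); refitting with ridge penalty")
        model = LogisticRegression(C=1.0, max_iter=10_000)
        model.fit(Xs, labels)
    score = Xs @ model.coef_.ravel() + model.intercept_[0]
    return score, roc_auc(score, labels, config, auto_flip=False)


def pca_scores(
    rel: pd.DataFrame, config: StatsConfig | None = None, n_components: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Mean-centered, Pareto-scaled principal components of one site's table.

    Pareto scaling (divide by the square root of each feature's standard
    deviation, the MarkerView convention) softens the dominance of abundant
    glycoforms without the noise inflation of full autoscaling. Returns
    (scores, loadings, explained-variance fractions); loadings are
    orthonormal and the variance fractions are non-increasing.
    """
    config = config or StatsConfig()
    if len(rel) < 3:
        raise ValueError("PCA needs at least three patients")
    X = rel.astype(float).to_numpy()
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    if config.pca_scaling == "pareto":
        X = X / np.sqrt(sd)
    elif config.pca_scaling == "autoscale":
        X = X / sd
    else:
        raise ValueError(f"unknown pca_scaling {config.pca_scaling!r}")
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if len(s) else 0
    k = rank if n_components is None else min(n_components, rank)
    if n_components is not None and n_components > rank:
        logger.info("requested %d components, rank is %d; truncating", n_components, rank)
    explained = (s[:k] ** 2) / np.sum(s**2)
    scores = pd.DataFrame(
        u[:, :k] * s[:k], index=rel.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    loadings = pd.DataFrame(
        vt[:k].T, index=rel.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return scores, loadings, explained
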