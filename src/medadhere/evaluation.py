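"""Model scoring and statistical comparison.

ROC AUC is computed from midranks (ties credited 1/2, i.e. the concordance
probability).  Paired AUCs on the same test set are compared with DeLong's
nonparametric test using the structural-components (placement value)
covariance estimator, with a two-sided normal p-value.  Families of
pairwise comparisons are Bonferroni-adjusted.  Sensitivity analysis
bootstrap-resamples the test set with replacement and compares the
per-model AUC distributions with two-sample Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats


@dataclass
class ScoredTestSet:
    """Labels and per-model continuous scores on one held-out test set."""

    labels: np.ndarray
    scores: dict  # model name -> score array (higher = more likely class 1)
    patient_ids: Optional[list] = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        for name, s in self.scores.items():
            s = np.asarray(s, dtype=float)
            if len(s) != len(self.labels):
                raise ValueError(f"score length mismatch for {name!r}")
            self.scores[name] = s
        if len(np.unique(self.labels)) < 2:
            raise ValueError("test set must contain both classes")


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc(scores, labels) -> float:
    """Concordance-probability AUC with ties credited 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("roc_auc requires both classes")
    ranks = _midrank(np.concatenate([pos, neg]))
    m = len(pos)
    return float((ranks[:m].sum() - m * (m + 1) / 2) / (m * len(neg)))


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    z: float
    p: float
    degenerate: bool = False


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """Paired DeLong test for two correlated ROC AUCs.

    Variance and covariance of the AUCs come from the placement-value
    (structural components) estimator with midrank tie handling; the
    p-value is two-sided normal.  A zero-variance difference with equal
    AUCs is a self-comparison (z=0, p=1); with unequal AUCs the result is
    flagged degenerate.
    """
    labels = np.asarray(labels, dtype=int)
    S, aucs = _delong_cov(np.vstack([scores_a, scores_b]), labels)
    var = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    diff = aucs[0] - aucs[1]
    if var <= 0:
        if abs(diff) < 1e-15:
            return DeLongResult(aucs[0], aucs[1], 0.0, 1.0)
        return DeLongResult(aucs[0], aucs[1],
                            np.sign(diff) * np.inf, 0.0, degenerate=True)
    z = diff / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return DeLongResult(aucs[0], aucs[1], float(z), float(p))


def _delong_cov(score_matrix: np.ndarray, labels: np.ndarray):
    """Placement-value covariance of k paired AUCs; positives first."""
    pos_mask = labels == 1
    m = int(pos_mask.sum())
    n = int((~pos_mask).sum())
    if m == 0 or n == 0:
        raise ValueError("both classes required")
    k = score_matrix.shape[0]
    v01 = np.empty((k, m))
    v10 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        pos = score_matrix[r][pos_mask]
        neg = score_matrix[r][~pos_mask]
        tx = _midrank(pos)
        ty = _midrank(neg)
        tz = _midrank(np.concatenate([pos, neg]))
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
        v01[r] = (tz[:m] - tx) / n
        v10[r] = 1.0 - (tz[m:] - ty) / m
    s01 = np.cov(v01) if k > 1 else np.atleast_2d(np.var(v01, ddof=1))
    s10 = np.cov(v10) if k > 1 else np.atleast_2d(np.var(v10, ddof=1))
    S = np.atleast_2d(s01) / m + np.atleast_2d(s10) / n
    return S, aucs


def bonferroni_threshold(alpha: float, n_models: int) -> tuple[int, float]:
    """Number of pairwise comparisons and the adjusted significance level."""
    if n_models < 2:
        raise ValueError("need at least two models")
    m = n_models * (n_models - 1) // 2
    return m, alpha / m


def ks_two_sample(x, y, exact: bool = False) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, method="exact" if exact else "asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class BootstrapResult:
    n_reps: int
    resample_size: int
    auc_samples: dict          # model name -> (n_reps,) AUC array
    ks_p: dict = field(default_factory=dict)  # (a, b) -> p-value
    n_redraws: int = 0

    def to_json_dict(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "resample_size": self.resample_size,
            "n_redraws": self.n_redraws,
            "auc_samples": {k: list(map(float, v))
                            for k, v in sorted(self.auc_samples.items())},
            "ks_p": {f"{a}|{b}": p for (a, b), p in sorted(self.ks_p.items())},
        }


def bootstrap_auc(scored: ScoredTestSet, n_reps: int = 1000,
                  seed: int = 0, resample_size: Optional[int] = None
                  ) -> BootstrapResult:
    """Bootstrap sensitivity analysis of every model's AUC.

    Each repetition draws a full-size resample of the test set with
    replacement and records each model's AUC on it.  Resamples containing
    a single class are redrawn (count reported).  Seeded and reproducible.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(scored.labels)
    size = resample_size or n
    names = sorted(scored.scores)
    samples = {name: np.empty(n_reps) for name in names}
    redraws = 0
    for rep in range(n_reps):
        while True:
            idx = rng.integers(0, n, size=size)
            lab = scored.labels[idx]
            if lab.min() != lab.max():
                break
            redraws += 1
        for name in names:
            samples[name][rep] = roc_auc(scored.scores[name][idx], lab)
    result = BootstrapResult(n_reps=n_reps, resample_size=size,
                             auc_samples=samples, n_redraws=redraws)
    for a, b in combinations(names, 2):
        _, p = ks_two_sample(samples[a], samples[b])
        result.ks_p[(a, b)] = p
    return result


@dataclass
class ComparisonReport:
    """AUCs plus pairwise DeLong p-values with Bonferroni adjustment."""

    model_names: list
    auc: dict                     # name -> AUC
    p_values: dict                # (a, b) -> two-sided p
    z_values: dict
    alpha: float
    m: int
    bonferroni_threshold: float

    def significant(self, a: str, b: str, adjusted: bool = True) -> bool:
        key = (a, b) if (a, b) in self.p_values else (b, a)
        thr = self.bonferroni_threshold if adjusted else self.alpha
        return self.p_values[key] < thr

    def to_json_dict(self) -> dict:
        return {
            "model_names": list(self.model_names),
            "auc": {k: self.auc[k] for k in sorted(self.auc)},
            "p_values": {f"{a}|{b}": p
                         for (a, b), p in sorted(self.p_values.items())},
            "z_values": {f"{a}|{b}": z
                         for (a, b), z in sorted(self.z_values.items())},
            "alpha": self.alpha,
            "m": self.m,
            "bonferroni_threshold": self.bonferroni_threshold,
            "significant_adjusted": {
                f"{a}|{b}": bool(p < self.bonferroni_threshold)
                for (a, b), p in sorted(self.p_values.items())},
            "significant_raw": {
                f"{a}|{b}": bool(p < self.alpha)
                for (a, b), p in sorted(self.p_values.items())},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), indent=2, sort_keys=True)


def compare_models(scored: ScoredTestSet, alpha: float = 0.05
                   ) -> ComparisonReport:
    """All-pairs DeLong comparison with Bonferroni-adjusted significance."""
    names = list(scored.scores)
    if len(names) < 2:  # nothing to compare; report AUCs only
        m, thr = 0, alpha
    else:
        m, thr = bonferroni_threshold(alpha, len(names))
    aucs = {name: roc_auc(scored.scores[name], scored.labels)
            for name in names}
    p_values, z_values = {}, {}
    for a, b in combinations(names, 2):
        res = delong_test(scored.scores[a], scored.scores[b], scored.labels)
        p_values[(a, b)] = res.p
        z_values[(a, b)] = res.z
    return ComparisonReport(model_names=names, auc=aucs, p_values=p_values,
                            z_values=z_values, alpha=alpha, m=m,
                            bonferroni_threshold=thr)


def roc_curve_points(scores, labels) -> np.ndarray:
    """(FPR, TPR) pairs at every threshold, for CSV export / plotting."""
    from sklearn.metrics import roc_curve as _sk_roc_curve

    fpr, tpr, _ = _sk_roc_curve(labels, scores)
    return np.column_stack([fpr, tpr])
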