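"""Arm-level aberration calls and the diagnostic statistics layer.

Covers the cohort evaluation surface: Stouffer-aggregated arm Z calls at
|Z| >= 3, Wilcoxon rank-sum / signed-rank group comparisons, ROC with the
Mann-Whitney AUC identity and a stratified bootstrap CI, Youden-index
cutoffs, and the confusion-matrix metrics (sensitivity, specificity, PPV,
NPV, accuracy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import ZProfile
from .genome import GenomeBins

Z_THRESHOLD = 3.0
MIN_ARM_BINS = 5

__all__ = [
    "AberrationCall",
    "DiagnosticResult",
    "GroupComparison",
    "arm_calls",
    "wilcoxon_ranksum",
    "wilcoxon_signed_rank",
    "roc",
    "youden_cutoff",
    "confusion_metrics",
    "evaluate_group",
    "paired_tfx_report",
]


@dataclass(frozen=True)
class AberrationCall:
    chrom: str
    arm: str
    aggregate_z: float
    direction: str  # gain | loss | none
    n_bins: int
    low_confidence: bool = False


@dataclass(frozen=True)
class GroupComparison:
    group1: str
    group2: str
    n1: int
    n2: int
    statistic: float
    p: float


@dataclass(frozen=True)
class DiagnosticResult:
    group: str
    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None
    accuracy: float
    tp: int
    fp: int
    tn: int
    fn: int
    curve: pd.DataFrame | None = field(default=None, compare=False, repr=False)

    def rounded(self, ndigits: int = 2) -> dict:
        """Reporting-layer view with 2-dp rounding."""
        rnd = lambda v: None if v is None else round(v + 1e-12, ndigits)
        return {
            "group": self.group,
            "auc": rnd(self.auc),
            "sensitivity": rnd(self.sensitivity),
            "specificity": rnd(self.specificity),
            "ppv": rnd(self.ppv),
            "npv": rnd(self.npv),
            "accuracy": rnd(self.accuracy),
        }


def arm_calls(zp: ZProfile, bins: GenomeBins,
              z_threshold: float = Z_THRESHOLD) -> list[AberrationCall]:
    """Aggregate per-bin Z over each chromosome arm (Stouffer: sum/sqrt(n)).

    Arms with fewer than 5 unmasked bins are reported as direction 'none'
    with the low_confidence flag set.
    """
    t = bins.table
    calls = []
    for (chrom, arm), grp in t.groupby(["chrom", "arm"], sort=False):
        idx = grp.index.to_numpy()
        z = zp.z[idx]
        z = z[np.isfinite(z)]
        n = len(z)
        if n < MIN_ARM_BINS:
            calls.append(AberrationCall(str(chrom), str(arm), float("nan"),
                                        "none", n, low_confidence=True))
            continue
        agg = float(z.sum() / np.sqrt(n))
        if agg >= z_threshold:
            direction = "gain"
        elif agg <= -z_threshold:
            direction = "loss"
        else:
            direction = "none"
        calls.append(AberrationCall(str(chrom), str(arm), agg, direction, n))
    return calls


def arm_calls_frame(calls: list[AberrationCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])


def wilcoxon_ranksum(x, y, group1: str = "group1",
                     group2: str = "group2") -> GroupComparison:
    """Two-sided Mann-Whitney rank-sum comparison of independent groups.

    Exact enumeration for n1+n2 <= 12 without ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across groups; p set to 1")
        return GroupComparison(group1, group2, len(x), len(y),
                               float(len(x) * len(y) / 2.0), 1.0)
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) + len(y) <= 12 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return GroupComparison(group1, group2, len(x), len(y),
                           float(res.statistic), float(min(res.pvalue, 1.0)))


def wilcoxon_signed_rank(pre, post, group1: str = "pre",
                         group2: str = "post") -> GroupComparison:
    """Two-sided paired signed-rank test; exact for n <= 15 without ties."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if len(pre) != len(post):
        raise ValueError("paired vectors must have equal length")
    diff = pre - post
    nonzero = diff[diff != 0]
    if len(nonzero) == 0:
        warnings.warn("all paired differences are zero; p set to 1")
        return GroupComparison(group1, group2, len(pre), len(post), 0.0, 1.0)
    # scipy's exact path handles tied ranks; switch to the normal
    # approximation only when enumeration gets expensive
    method = "exact" if len(nonzero) <= 25 else "approx"
    res = stats.wilcoxon(pre, post, alternative="two-sided", method=method,
                         zero_method="wilcox")
    return GroupComparison(group1, group2, len(pre), len(post),
                           float(res.statistic), float(min(res.pvalue, 1.0)))


def _auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the Mann-Whitney identity; tied scores count 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def roc(scores, labels, group: str = "", n_boot: int = 2000,
        seed: int = 0, compute_ci: bool = True) -> DiagnosticResult:
    """ROC evaluation of a score against binary labels.

    AUC comes from the rank identity; the CI is a stratified percentile
    bootstrap (class sizes preserved in every resample). The confusion
    metrics are evaluated at the Youden-optimal cutoff with the rule
    "positive if score >= cutoff".
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    auc = _auc_rank(scores, labels)

    if compute_ci:
        rng = np.random.default_rng(seed)
        pos_idx = np.flatnonzero(labels == 1)
        neg_idx = np.flatnonzero(labels == 0)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            pi = rng.choice(pos_idx, size=len(pos_idx), replace=True)
            ni = rng.choice(neg_idx, size=len(neg_idx), replace=True)
            idx = np.concatenate([pi, ni])
            boots[b] = _auc_rank(scores[idx], labels[idx])
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo, hi = float("nan"), float("nan")

    cutoff = youden_cutoff(scores, labels)
    pred = scores >= cutoff
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    metrics = confusion_metrics(tp, fp, tn, fn, group=group)

    order = np.argsort(-scores, kind="stable")
    thresh = scores[order]
    tps = np.cumsum(labels[order] == 1)
    fps = np.cumsum(labels[order] == 0)
    curve = pd.DataFrame({
        "threshold": thresh,
        "tpr": tps / max(tps[-1], 1),
        "fpr": fps / max(fps[-1], 1),
    })
    return DiagnosticResult(
        group=group, auc=auc, auc_ci=(float(lo), float(hi)), cutoff=float(cutoff),
        sensitivity=metrics.sensitivity, specificity=metrics.specificity,
        ppv=metrics.ppv, npv=metrics.npv, accuracy=metrics.accuracy,
        tp=tp, fp=fp, tn=tn, fn=fn, curve=curve,
    )


def youden_cutoff(scores, labels) -> float:
    """Observed score maximizing J = sensitivity + specificity - 1.

    Rule: predict positive when score >= cutoff. J ties break toward higher
    specificity, then toward the lower cutoff value. Brute force over the
    finite set of observed scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    best = None
    for c in np.unique(scores):
        pred = scores >= c
        sens = np.sum(pred & (labels == 1)) / n_pos
        spec = np.sum(~pred & (labels == 0)) / n_neg
        key = (sens + spec - 1.0, spec, -c)  # maximize J, then spec, then low cutoff
        if best is None or key > best[0]:
            best = (key, float(c))
    return best[1]


def confusion_metrics(tp: int, fp: int, tn: int, fn: int,
                      group: str = "") -> DiagnosticResult:
    """The five confusion-matrix ratios from integer counts.

    PPV/NPV with a zero denominator come back as None rather than raising.
    Values are full precision; rounding belongs to the reporting layer.
    """
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if tp + fn < 1 or tn + fp < 1:
        raise ValueError("need at least one actual positive and one actual negative")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv = tp / (tp + fp) if tp + fp > 0 else None
    npv = tn / (tn + fn) if tn + fn > 0 else None
    acc = (tp + tn) / (tp + fp + tn + fn)
    return DiagnosticResult(
        group=group, auc=float("nan"), auc_ci=(float("nan"), float("nan")),
        cutoff=float("nan"), sensitivity=sens, specificity=spec,
        ppv=ppv, npv=npv, accuracy=acc, tp=tp, fp=fp, tn=tn, fn=fn,
    )


def evaluate_group(cohort: pd.DataFrame, positives, negatives,
                   score_col: str = "tfx", group: str = "",
                   n_boot: int = 2000, seed: int = 0) -> DiagnosticResult:
    """One performance-table row: ROC + Youden cutoff + confusion metrics.

    ``positives``/``negatives`` are boolean masks or pandas queries over the
    cohort table; the score column (TFx by default) is the classifier.
    """
    pos_mask = cohort.eval(positives) if isinstance(positives, str) else np.asarray(positives)
    neg_mask = cohort.eval(negatives) if isinstance(negatives, str) else np.asarray(negatives)
    pos_mask = np.asarray(pos_mask, dtype=bool)
    neg_mask = np.asarray(neg_mask, dtype=bool)
    if (pos_mask & neg_mask).any():
        raise ValueError("positive and negative definitions overlap")
    if pos_mask.sum() < 1 or neg_mask.sum() < 1:
        raise ValueError("need at least one sample on each side")
    sel = pos_mask | neg_mask
    scores = cohort.loc[sel, score_col].to_numpy(dtype=float)
    labels = pos_mask[sel].astype(int)
    return roc(scores, labels, group=group, n_boot=n_boot, seed=seed)


def paired_tfx_report(pairs: pd.DataFrame, pre_col: str = "tfx_pre",
                      post_col: str = "tfx_post") -> dict:
    """Summary of paired pre/post tumor fractions.

    Returns medians, ranges, and the two-sided signed-rank p-value. Median
    of an even-sized sample is the mean of the central pair. With fewer
    than 5 pairs the test is skipped (descriptive output only).
    """
    pre = pairs[pre_col].to_numpy(dtype=float)
    post = pairs[post_col].to_numpy(dtype=float)
    out = {
        "n_pairs": len(pre),
        "pre_median": float(np.median(pre)),
        "pre_range": (float(pre.min()), float(pre.max())),
        "post_median": float(np.median(post)),
        "post_range": (float(post.min()), float(post.max())),
        "median_change": float(np.median(post - pre)),
    }
    if len(pre) >= 5:
        cmp = wilcoxon_signed_rank(pre, post)
        out["p"] = cmp.p
        out["statistic"] = cmp.statistic
    else:
        warnings.warn("fewer than 5 pairs; skipping the signed-rank test")
        out["p"] = None
    return out
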