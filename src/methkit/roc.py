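"""Per-marker diagnostic evaluation: ROC/AUC, bootstrap CI, optimal cutoff.

AUC is computed as the Mann-Whitney concordance probability
(ties count one half), 95% confidence intervals by class-stratified
percentile bootstrap, and the optimal cutoff by Youden's
J = sensitivity + specificity - 1 with ties broken toward higher
specificity. Marker orientation records whether high values indicate
tumor (hypermethylated markers) or normal (hypomethylated markers);
scores are flipped accordingly so AUC >= 0.5 for a marker evaluated in
its discovery direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .utils import log


def _split(scores, labels, orientation):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if orientation == "tumor_low":
        s = -s
    elif orientation != "tumor_high":
        raise ValueError("orientation must be 'tumor_high' or 'tumor_low'")
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def auc(scores, labels, orientation: str = "tumor_high") -> float:
    """Mann-Whitney AUC: P(pos > neg) + 0.5 P(pos = neg)."""
    pos, neg = _split(scores, labels, orientation)
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def bootstrap_auc_ci(
    scores,
    labels,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    orientation: str = "tumor_high",
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC, resampling within each class
    so every replicate keeps both classes."""
    pos, neg = _split(scores, labels, orientation)
    rng = np.random.default_rng(seed)
    n_p, n_n = pos.size, neg.size
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        bp = pos[rng.integers(0, n_p, n_p)]
        bn = neg[rng.integers(0, n_n, n_n)]
        ranks = rankdata(np.concatenate([bp, bn]))
        u = ranks[:n_p].sum() - n_p * (n_p + 1) / 2.0
        aucs[b] = u / (n_p * n_n)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def optimal_cutoff(scores, labels, orientation: str = "tumor_high"):
    """Cutoff maximizing Youden's J; returns (cutoff, sensitivity,
    specificity).

    Candidate cutoffs sit midway between adjacent distinct scores (plus
    open ends); a sample is called positive when its (oriented) score
    exceeds the cutoff. Ties in J are broken toward higher specificity.
    The returned cutoff is on the oriented scale (negated input scale for
    tumor_low markers).
    """
    pos, neg = _split(scores, labels, orientation)
    values = np.unique(np.concatenate([pos, neg]))
    if values.size == 1:
        return float(values[0]), float((pos > values[0]).mean()), float(
            (neg <= values[0]).mean()
        )
    candidates = np.concatenate(
        [[values[0] - 1.0], (values[:-1] + values[1:]) / 2.0, [values[-1] + 1.0]]
    )
    best = None
    for c in candidates:
        sens = float((pos > c).mean())
        spec = float((neg <= c).mean())
        j = sens + spec - 1.0
        key = (j, spec)
        if best is None or key > best[0]:
            best = (key, float(c), sens, spec)
    _, cut, sens, spec = best
    return cut, sens, spec


@dataclass
class ROCResult:
    marker_id: str
    auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    cutoff: float
    sensitivity: float
    specificity: float
    orientation: str


def evaluate_marker(
    marker_id: str,
    scores,
    labels,
    orientation: str = "tumor_high",
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> ROCResult:
    """Full single-marker evaluation: AUC, bootstrap CI, optimal cutoff."""
    a = auc(scores, labels, orientation)
    lo, hi = bootstrap_auc_ci(
        scores, labels, n_boot=n_boot, level=level, seed=seed, orientation=orientation
    )
    cut, sens, spec = optimal_cutoff(scores, labels, orientation)
    if not lo <= a <= hi:
        log.info("point AUC outside percentile CI for %s (small n_boot?)", marker_id)
    return ROCResult(
        marker_id=marker_id,
        auc=a,
        ci_low=lo,
        ci_high=hi,
        n_boot=n_boot,
        cutoff=cut,
        sensitivity=sens,
        specificity=spec,
        orientation=orientation,
    )


def roc_points(scores, labels, orientation: str = "tumor_high"):
    """ROC curve as (fpr, tpr) arrays from exhaustive threshold scan."""
    pos, neg = _split(scores, labels, orientation)
    thresholds = np.concatenate([[np.inf], np.unique(np.concatenate([pos, neg]))[::-1]])
    fpr = [(neg > t).mean() for t in thresholds]
    tpr = [(pos > t).mean() for t in thresholds]
    # closing point: everything called positive
    fpr.append(1.0)
    tpr.append(1.0)
    return np.asarray(fpr), np.asarray(tpr)
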