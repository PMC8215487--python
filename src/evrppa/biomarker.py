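"""ROC-based marker evaluation, optimal cut-offs and composite k-of-n scoring.

The AUC is the tie-aware empirical (Mann-Whitney) statistic; its 95% CI and
the p-value against AUC = 0.5 come from DeLong's asymptotic variance, with a
seeded bootstrap fallback when the DeLong variance degenerates (e.g. perfect
separation).  The "optimal cut-off" maximizes the Youden index
J = sensitivity + specificity - 1 over midpoints between adjacent distinct
scores, breaking ties toward higher specificity.

Composite scoring follows the k-of-n rule: a sample is signature-positive when
at least k of the n endpoints lie beyond their respective cut-offs in the
case-enriched direction (lower levels can count as exceedance for markers
depleted in cases).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GREATER = "greater"
LESS = "less"


@dataclass(frozen=True)
class RocResult:
    """Univariate (or combined-score) ROC summary for one endpoint."""

    endpoint: str
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    cutoff: float | None
    direction: str
    sensitivity: float
    specificity: float
    n_cases: int
    n_controls: int
    degenerate: bool = False  # constant scores: AUC 0.5, no usable cutoff


@dataclass(frozen=True)
class CompositeSignature:
    """n endpoints with directional cut-offs and a k-of-n positivity rule."""

    endpoints: tuple[str, ...]
    cutoffs: tuple[float, ...]
    directions: tuple[str, ...]
    k: int

    def __post_init__(self):
        object.__setattr__(self, "endpoints", tuple(self.endpoints))
        object.__setattr__(self, "cutoffs", tuple(self.cutoffs))
        object.__setattr__(self, "directions", tuple(self.directions))
        n = len(self.endpoints)
        if not (len(self.cutoffs) == len(self.directions) == n):
            raise ValueError("endpoints, cutoffs and directions must have equal length")
        if not 1 <= self.k <= n:
            raise ValueError("k must satisfy 1 <= k <= n")
        if any(d not in (GREATER, LESS) for d in self.directions):
            raise ValueError("directions must be 'greater' or 'less'")


def _empirical_auc(cases: np.ndarray, controls: np.ndarray) -> float:
    """Tie-aware pair-counting AUC via midranks (direction: cases high)."""
    pooled = np.concatenate([cases, controls])
    ranks = stats.rankdata(pooled)
    n1, n0 = cases.size, controls.size
    r1 = ranks[:n1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _delong_variance(cases: np.ndarray, controls: np.ndarray) -> float:
    """DeLong's structural-components variance of the empirical AUC."""
    n1, n0 = cases.size, controls.size
    # V10[i] = P(control < case_i) + 0.5 P(tie); V01[j] likewise
    all_ranks = stats.rankdata(np.concatenate([cases, controls]))
    case_ranks = stats.rankdata(cases)
    control_ranks = stats.rankdata(controls)
    v10 = (all_ranks[:n1] - case_ranks) / n0
    v01 = 1.0 - (all_ranks[n1:] - control_ranks) / n1
    s10 = v10.var(ddof=1) if n1 > 1 else 0.0
    s01 = v01.var(ddof=1) if n0 > 1 else 0.0
    return float(s10 / n1 + s01 / n0)


def _bootstrap_ci(
    cases: np.ndarray, controls: np.ndarray, n_boot: int = 500, seed: int = 0
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for i in range(n_boot):
        c1 = rng.choice(cases, cases.size, replace=True)
        c0 = rng.choice(controls, controls.size, replace=True)
        aucs[i] = _empirical_auc(c1, c0)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def _candidate_cutoffs(scores: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct score values."""
    distinct = np.unique(scores)
    return (distinct[:-1] + distinct[1:]) / 2.0


def _sens_spec(
    scores: np.ndarray, labels: np.ndarray, cutoff: float, direction: str
) -> tuple[float, float]:
    positive = scores > cutoff if direction == GREATER else scores < cutoff
    cases = labels == 1
    sens = positive[cases].mean() if cases.any() else 0.0
    spec = (~positive[~cases]).mean() if (~cases).any() else 0.0
    return float(sens), float(spec)


def roc_analysis(
    scores, labels, endpoint: str = "", boot_seed: int = 0, n_boot: int = 500
) -> RocResult:
    """Empirical ROC of one score vector against binary case/control labels.

    Direction is chosen so AUC >= 0.5.  Cut-off maximizes Youden J over
    midpoints of adjacent distinct scores; ties broken toward maximal
    specificity, then toward the lower cutoff.  CI and p-value by DeLong,
    bootstrap CI fallback when the DeLong variance is degenerate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    keep = np.isfinite(scores)
    scores, labels = scores[keep], labels[keep]
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    if cases.size < 2 or controls.size < 2:
        raise ValueError("roc_analysis needs >= 2 samples in each class")

    auc_greater = _empirical_auc(cases, controls)
    direction = GREATER if auc_greater >= 0.5 else LESS
    auc = auc_greater if direction == GREATER else 1.0 - auc_greater

    if np.unique(scores).size == 1:
        return RocResult(
            endpoint=endpoint, auc=0.5, ci_low=0.5, ci_high=0.5, p_value=1.0,
            cutoff=None, direction=GREATER, sensitivity=0.0, specificity=1.0,
            n_cases=cases.size, n_controls=controls.size, degenerate=True,
        )

    var = _delong_variance(cases, controls)
    if var > 0:
        se = np.sqrt(var)
        z = (auc_greater - 0.5) / se
        p = float(2.0 * stats.norm.sf(abs(z)))
        ci_low = max(0.0, auc - 1.96 * se)
        ci_high = min(1.0, auc + 1.96 * se)
    else:
        # degenerate ties / perfect separation: seeded bootstrap CI,
        # exact rank-sum p-value
        lo, hi = _bootstrap_ci(cases, controls, n_boot=n_boot, seed=boot_seed)
        if direction == LESS:
            lo, hi = 1.0 - hi, 1.0 - lo
        ci_low, ci_high = max(0.0, lo), min(1.0, hi)
        ci_low, ci_high = min(ci_low, auc), max(ci_high, auc)
        p = float(stats.mannwhitneyu(cases, controls, alternative="two-sided").pvalue)

    best = None  # (J, spec, -cutoff) maximized
    for c in _candidate_cutoffs(scores):
        sens, spec = _sens_spec(scores, labels, c, direction)
        j = sens + spec - 1.0
        key = (round(j, 12), round(spec, 12), -c)
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    _, cutoff, sens, spec = best

    return RocResult(
        endpoint=endpoint, auc=auc, ci_low=ci_low, ci_high=ci_high, p_value=p,
        cutoff=float(cutoff), direction=direction,
        sensitivity=sens, specificity=spec,
        n_cases=int(cases.size), n_controls=int(controls.size),
    )


def signature_from_matrix(
    matrix: pd.DataFrame, endpoints, labels, k: int
) -> CompositeSignature:
    """Derive per-endpoint cut-offs and case-enriched directions by univariate ROC."""
    labels = np.asarray(labels, dtype=int)
    cutoffs, directions = [], []
    for ep in endpoints:
        if ep not in matrix.columns:
            raise ValueError(f"endpoint {ep!r} missing from matrix")
        r = roc_analysis(matrix[ep].to_numpy(dtype=float), labels, endpoint=ep)
        if r.degenerate:
            # constant marker: impossible cutoff so it never contributes
            cutoffs.append(float("inf"))
            directions.append(GREATER)
        else:
            cutoffs.append(r.cutoff)
            directions.append(r.direction)
    return CompositeSignature(
        endpoints=tuple(endpoints), cutoffs=tuple(cutoffs),
        directions=tuple(directions), k=k,
    )


def composite_score(
    matrix: pd.DataFrame, signature: CompositeSignature
) -> pd.DataFrame:
    """Per-sample exceedance count and k-of-n positivity.

    Missing endpoint values contribute 0 and are tallied per sample in the
    ``n_missing`` column.
    """
    for ep in signature.endpoints:
        if ep not in matrix.columns:
            raise ValueError(f"endpoint {ep!r} missing from matrix")
    score = np.zeros(len(matrix), dtype=int)
    n_missing = np.zeros(len(matrix), dtype=int)
    for ep, cut, direction in zip(signature.endpoints, signature.cutoffs, signature.directions):
        vals = matrix[ep].to_numpy(dtype=float)
        miss = ~np.isfinite(vals)
        n_missing += miss.astype(int)
        beyond = np.where(
            miss, False, vals > cut if direction == GREATER else vals < cut
        )
        score += beyond.astype(int)
    return pd.DataFrame(
        {
            "score": score,
            "positive": score >= signature.k,
            "n_missing": n_missing,
        },
        index=matrix.index,
    )


def combine_candidates(
    matrix: pd.DataFrame, endpoints, labels, method: str = "exceedance",
) -> RocResult:
    """ROC of a combined diagnostic score over several candidate markers.

    ``"exceedance"`` (default): per-sample count of markers beyond their
    univariate cut-offs in the case-enriched direction — consistent with the
    k-of-n prognostic rule.  ``"logistic"``: in-sample logistic-regression
    probability, a non-canonical alternative.
    """
    labels = np.asarray(labels, dtype=int)
    if len(endpoints) < 2:
        raise ValueError("combine_candidates needs >= 2 endpoints")
    if method == "exceedance":
        sig = signature_from_matrix(matrix, endpoints, labels, k=1)
        combined = composite_score(matrix, sig)["score"].to_numpy(dtype=float)
    elif method == "logistic":
        from sklearn.linear_model import LogisticRegression

        X = matrix[list(endpoints)].to_numpy(dtype=float)
        model = LogisticRegression(max_iter=1000)
        model.fit(X, labels)
        combined = model.predict_proba(X)[:, 1]
    else:
        raise ValueError("method must be 'exceedance' or 'logistic'")
    return roc_analysis(combined, labels, endpoint="+".join(endpoints))


def evaluate_signature(
    matrix: pd.DataFrame, signature: CompositeSignature, labels
) -> tuple[RocResult, dict]:
    """ROC of the integer composite score plus the 2x2 table at the k rule."""
    labels = np.asarray(labels, dtype=int)
    scored = composite_score(matrix, signature)
    roc = roc_analysis(
        scored["score"].to_numpy(dtype=float), labels, endpoint="composite_score"
    )
    pos = scored["positive"].to_numpy()
    cases = labels == 1
    tp = int((pos & cases).sum())
    fn = int((~pos & cases).sum())
    fp = int((pos & ~cases).sum())
    tn = int((~pos & ~cases).sum())
    confusion = {
        "tp": tp, "fn": fn, "fp": fp, "tn": tn,
        "sensitivity": tp / (tp + fn) if (tp + fn) else 0.0,
        "specificity": tn / (tn + fp) if (tn + fp) else 0.0,
        "k": signature.k,
    }
    return roc, confusion
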