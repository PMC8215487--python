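"""Cohort comparisons, comparison-set intersections and clinical classification rules.

Group differences in normalized RPPA intensity are tested per endpoint with a
two-sided Student's t or Wilcoxon rank-sum test; effect size is reported as
log2 of the ratio of arithmetic group means.  Raw p-values at alpha = 0.05 are
the primary significance call, with Benjamini-Hochberg q-values reported
alongside.

Clinical rules cover D'Amico-style risk stratification from Gleason grade and
pathological TNM stage, the PSA 4-10 ng/mL diagnostic gray zone, and
percentile-based over-expression flags.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

GLEASON_ORDER = ["6", "7(3+4)", "7(4+3)", "8", "9", "10"]
PTNM_ORDER = ["T1a", "T1b", "T1c", "T2a", "T2b", "T2c", "T3a", "T3b", "T4"]

LOW = "low"
LOW_INTERMEDIATE = "low_intermediate"
HIGH = "high"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ComparisonResult:
    """One endpoint's two-group comparison."""

    endpoint: str
    group_a: str
    group_b: str
    log2fc: float  # log2(mean_a / mean_b)
    p_value: float
    q_value: float
    test: str
    n_a: int
    n_b: int
    significant: bool
    testable: bool = True


@dataclass(frozen=True)
class ClinicalRecord:
    """Clinical covariates of one patient sample."""

    sample_id: str
    gleason: str | None = None
    ptnm: str | None = None
    psa_ng_ml: float | None = None
    group: str | None = None
    recurrent: int | None = None

    def __post_init__(self):
        if self.psa_ng_ml is not None and self.psa_ng_ml < 0:
            raise ValueError("PSA must be >= 0")
        if self.gleason is not None and self.gleason not in GLEASON_ORDER:
            raise ValueError(f"unknown Gleason category {self.gleason!r}")
        if self.ptnm is not None and self.ptnm not in PTNM_ORDER:
            raise ValueError(f"pTNM stage {self.ptnm!r} outside declared ordering")


def _test_pair(a: np.ndarray, b: np.ndarray, test: str) -> float:
    if test == "t":
        res = stats.ttest_ind(a, b, equal_var=True)
    elif test == "wilcoxon":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}; use 't' or 'wilcoxon'")
    return float(res.pvalue)


def compare_groups(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    group_a: str,
    group_b: str,
    test: str = "t",
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Per-endpoint two-group comparison on a samples x endpoints matrix.

    ``annotation`` must carry ``sample_id`` and ``group`` columns.  Endpoints
    with fewer than two finite values in either group are returned as
    non-testable rather than dropped.
    """
    groups = annotation.set_index("sample_id")["group"]
    for g in (group_a, group_b):
        if g not in set(groups):
            raise ValueError(f"unknown group label {g!r}")
    ids_a = [s for s in matrix.index if groups.get(s) == group_a]
    ids_b = [s for s in matrix.index if groups.get(s) == group_b]

    raw_results = []
    for ep in matrix.columns:
        a = matrix.loc[ids_a, ep].dropna().to_numpy(dtype=float)
        b = matrix.loc[ids_b, ep].dropna().to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            raw_results.append((ep, np.nan, np.nan, a.size, b.size, False))
            continue
        mean_a, mean_b = a.mean(), b.mean()
        if mean_b == 0 or mean_a == 0:
            logger.warning("zero group mean for %s; log2fc set to +/-inf", ep)
            log2fc = np.inf if mean_a > mean_b else (-np.inf if mean_a < mean_b else 0.0)
        else:
            log2fc = float(np.log2(mean_a / mean_b))
        p = _test_pair(a, b, test)
        raw_results.append((ep, log2fc, p, a.size, b.size, True))

    pvals = [r[2] for r in raw_results if r[5]]
    qmap: dict[str, float] = {}
    if pvals:
        q = multipletests(pvals, method="fdr_bh")[1]
        qmap = {r[0]: float(qi) for r, qi in zip([r for r in raw_results if r[5]], q)}

    out = []
    for ep, log2fc, p, n_a, n_b, testable in raw_results:
        out.append(
            ComparisonResult(
                endpoint=ep, group_a=group_a, group_b=group_b,
                log2fc=float(log2fc), p_value=float(p),
                q_value=qmap.get(ep, float("nan")),
                test=test, n_a=n_a, n_b=n_b,
                significant=bool(testable and p <= alpha),
                testable=testable,
            )
        )
    return out


def results_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def comparison_intersections(significant_sets: dict[str, set]) -> pd.DataFrame:
    """Exact-combination (UpSet-style) counts over comparison sets.

    For every non-empty combination of comparison labels, counts the endpoints
    significant in exactly that combination; counts partition the union.
    """
    if len(significant_sets) < 2:
        raise ValueError("need at least 2 comparison sets")
    labels = list(significant_sets)
    membership: dict[str, frozenset] = {}
    for ep in set().union(*significant_sets.values()):
        membership[ep] = frozenset(l for l in labels if ep in significant_sets[l])
    rows = []
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            key = frozenset(combo)
            count = sum(1 for m in membership.values() if m == key)
            members = sorted(str(ep) for ep, m in membership.items() if m == key)
            rows.append({
                "combination": "&".join(combo),
                "degree": r,
                "count": count,
                "endpoints": ";".join(members),
            })
    return pd.DataFrame(rows)


def classify_risk(record: ClinicalRecord) -> str:
    """D'Amico-style risk class from Gleason grade and pTNM stage.

    Low: Gleason 6 and pTNM <= T2a.  Low/Intermediate: Gleason <= 7(3+4) and
    pTNM T2b-T2c.  High: Gleason 7(4+3) with T2c, and any Gleason with
    pTNM >= T3a.  Combinations the rule does not cover (e.g. Gleason 8 with
    T2a) return ``"unclassified"`` rather than a guessed class.
    """
    if record.gleason is None or record.ptnm is None:
        raise ValueError("classify_risk requires both gleason and ptnm")
    g = GLEASON_ORDER.index(record.gleason)
    t = PTNM_ORDER.index(record.ptnm)
    g_7_34 = GLEASON_ORDER.index("7(3+4)")
    g_7_43 = GLEASON_ORDER.index("7(4+3)")
    t2a, t2b, t2c, t3a = (PTNM_ORDER.index(s) for s in ("T2a", "T2b", "T2c", "T3a"))

    if t >= t3a:
        return HIGH
    if g == g_7_43 and t == t2c:
        return HIGH
    if g <= g_7_34 and t in (t2b, t2c):
        return LOW_INTERMEDIATE
    if record.gleason == "6" and t <= t2a:
        return LOW
    return UNCLASSIFIED


def gray_zone_filter(
    annotation: pd.DataFrame, low: float = 4.0, high: float = 10.0
) -> tuple[pd.DataFrame, int]:
    """Samples whose PSA lies in [low, high] ng/mL (the diagnostic gray zone).

    Returns (subset, number of samples excluded for missing PSA).
    """
    if low > high:
        raise ValueError("gray-zone lower bound exceeds upper bound")
    psa = pd.to_numeric(annotation["psa_ng_ml"], errors="coerce")
    n_missing = int(psa.isna().sum())
    if n_missing:
        logger.warning("gray-zone filter excluded %d samples with missing PSA", n_missing)
    keep = psa.notna() & (psa >= low) & (psa <= high)
    return annotation[keep], n_missing


def percentile_flag(values, pct: float = 65.0) -> tuple[np.ndarray, float]:
    """Flag values strictly above the pct-th percentile (linear interpolation).

    Returns (boolean flags aligned to input order, threshold used).
    """
    if not 0 <= pct <= 100:
        raise ValueError("pct must lie in [0, 100]")
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 2:
        raise ValueError("percentile_flag needs >= 2 finite values")
    threshold = float(np.percentile(finite, pct, method="linear"))
    flags = np.where(np.isfinite(arr), arr > threshold, False)
    return flags, threshold


def spearman_trend(values, ordered_stage) -> tuple[float, float]:
    """Spearman correlation of endpoint level with an ordered clinical stage.

    Exploratory only: rank correlation against the declared pTNM ordering; no
    claim of a specific trend statistic.
    """
    codes = [PTNM_ORDER.index(s) for s in ordered_stage]
    rho, p = stats.spearmanr(values, codes)
    return float(rho), float(p)
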