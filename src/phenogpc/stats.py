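"""Statistical procedures for genotype-phenotype comparison.

Four tests cover the four kinds of clinical data: Fisher's exact test for
categorical observed/excluded contingency tables (2x2, or k x 2 via the
Freeman-Halton extension), the Mann-Whitney U test for phenotype severity
scores, the unpaired two-sided t-test for numeric measurements, and the
logrank test for right-censored time-to-event endpoints.  Multiple-testing
correction (Benjamini-Hochberg by default, ten classical alternatives, or
none) is applied only to the categorical family; score, measurement and
survival tests are reported raw alongside the number of tests performed.

Associations with p < 0.05 are flagged significant.  Tests drop a data
point when its phenotypic or genotypic information is unavailable; the
callers tally those exclusions.
"""

from __future__ import annotations

import enum
import functools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _scipy_stats
from lifelines.statistics import logrank_test as _lifelines_logrank
from statsmodels.stats.multitest import multipletests as _multipletests

__all__ = [
    "ALPHA",
    "MtcMethod",
    "GpcResult",
    "fisher_exact",
    "adjust_pvalues",
    "mann_whitney_u",
    "t_test",
    "logrank",
]

#: significance threshold applied throughout
ALPHA = 0.05


class MtcMethod(enum.Enum):
    """Multiple-testing correction procedures (BH is the default)."""

    BONFERRONI = "bonferroni"
    SIDAK = "sidak"
    HOLM = "holm"
    HOLM_SIDAK = "holm-sidak"
    HOCHBERG = "simes-hochberg"
    HOMMEL = "hommel"
    BH = "fdr_bh"
    BY = "fdr_by"
    TWO_STAGE_BH = "fdr_tsbh"
    FDR_TSBKY = "fdr_tsbky"
    NONE = "none"

    @classmethod
    def from_name(cls, name: str) -> "MtcMethod":
        try:
            return cls[name.upper().replace("-", "_")]
        except KeyError:
            raise ValueError(f"unknown MTC method {name!r}") from None


@dataclass(frozen=True)
class GpcResult:
    """One tested genotype-phenotype hypothesis.

    ``p_adjusted`` is set only for categorical tests that went through
    multiple-testing correction; otherwise it is None and significance is
    judged on the raw p-value.
    """

    hypothesis: str
    kind: str
    class_summaries: tuple[str, ...]
    statistic: Optional[float]
    p_raw: Optional[float]
    p_adjusted: Optional[float] = None
    n_used: int = 0
    n_excluded: int = 0
    note: str = ""

    @property
    def performed(self) -> bool:
        return self.p_raw is not None

    @property
    def significant(self) -> bool:
        p = self.p_adjusted if self.p_adjusted is not None else self.p_raw
        return p is not None and p < ALPHA


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided exact p for a k x 2 contingency table (k in {2, 3}).

    Rows are genotype classes, columns (observed, excluded).  For 2x2 the
    p-value sums hypergeometric probabilities of all same-margin tables
    whose point probability does not exceed the observed one; for k > 2 the
    Freeman-Halton extension enumerates all margin-preserving tables.  A
    degenerate table (a zero row or column margin) returns p = 1 by
    convention.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[1] != 2 or t.shape[0] < 2:
        raise ValueError(f"expected a k x 2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("contingency table entries must be non-negative")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        return 1.0
    return _fisher_exact_cached(tuple(map(tuple, t.tolist())))


@functools.lru_cache(maxsize=200_000)
def _fisher_exact_cached(key: tuple[tuple[int, int], ...]) -> float:
    t = np.asarray(key, dtype=np.int64)
    if t.shape[0] == 2:
        return float(_scipy_stats.fisher_exact(t).pvalue)
    return _freeman_halton_kx2(t)


def _freeman_halton_kx2(t: np.ndarray) -> float:
    """Exact Freeman-Halton p for a k x 2 table by full table enumeration.

    Walks every non-negative first-column vector compatible with the row
    margins and the first column margin, accumulating the conditional
    (multivariate hypergeometric) probability of each table whose point
    probability does not exceed the observed one.  Probabilities are
    computed in log space; the comparison uses a 1 + 1e-7 relative
    tolerance to avoid float-boundary flips.
    """
    rows = t.sum(axis=1)
    c1 = int(t[:, 0].sum())
    n = int(rows.sum())
    lgamma = math.lgamma

    def log_choose(nn: int, kk: int) -> float:
        return lgamma(nn + 1) - lgamma(kk + 1) - lgamma(nn - kk + 1)

    log_denom = log_choose(n, c1)

    def log_prob(first_col: tuple[int, ...]) -> float:
        return sum(log_choose(int(r), x) for r, x in zip(rows, first_col)) - log_denom

    log_p_obs = log_prob(tuple(int(x) for x in t[:, 0]))
    cutoff = log_p_obs + math.log1p(1e-7)

    total = 0.0
    k = len(rows)

    def walk(i: int, remaining: int, acc: list[int]) -> None:
        nonlocal total
        if i == k - 1:
            if 0 <= remaining <= rows[i]:
                lp = log_prob(tuple(acc + [remaining]))
                if lp <= cutoff:
                    total += math.exp(lp)
            return
        for x in range(0, min(int(rows[i]), remaining) + 1):
            walk(i + 1, remaining - x, acc + [x])

    walk(0, c1, [])
    return min(1.0, total)


def adjust_pvalues(p_values: Sequence[float], method: MtcMethod = MtcMethod.BH) -> list[float]:
    """Adjust raw p-values for multiplicity; preserves input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method is MtcMethod.NONE:
        return [float(x) for x in p]
    _, adjusted, _, _ = _multipletests(p, alpha=ALPHA, method=method.value)
    return [float(x) for x in adjusted]


def mann_whitney_u(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> Optional[tuple[float, float]]:
    """Two-sided Mann-Whitney U (Wilcoxon rank-sum) test.

    NaN scores are dropped.  Uses the exact null distribution when both
    groups have at most 8 values and there are no ties, and the normal
    approximation with tie and continuity corrections otherwise.  Returns
    ``(U, p)``, or None when a group is empty after NaN removal.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        return None
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and no_ties) else "asymptotic"
    res = _scipy_stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def t_test(
    values_a: Sequence[float], values_b: Sequence[float], welch: bool = False
) -> Optional[tuple[float, float]]:
    """Unpaired two-sided t-test (pooled-variance Student by default).

    Returns ``(t, p)``; None if either group has fewer than 2 values.
    Two zero-variance groups with equal means give ``(0, 1)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        return None
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    res = _scipy_stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def logrank(
    durations_a: Sequence[float],
    events_a: Sequence[bool],
    durations_b: Sequence[float],
    events_b: Sequence[bool],
) -> Optional[tuple[float, float]]:
    """Logrank test on two right-censored samples.

    ``durations`` are positive times (days); ``events`` flags whether the
    event was observed (False = censored).  Ties are handled with the
    hypergeometric variance formula.  Returns ``(chi2, p)``, or None when
    neither group contains an observed event.
    """
    da, db = np.asarray(durations_a, float), np.asarray(durations_b, float)
    ea = np.asarray(events_a, bool)
    eb = np.asarray(events_b, bool)
    if da.size == 0 or db.size == 0:
        return None
    if (da <= 0).any() or (db <= 0).any():
        raise ValueError("durations must be positive")
    if not ea.any() and not eb.any():
        return None
    res = _lifelines_logrank(da, db, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)
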