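"""Two-group statistics: pooled t-tests, Cohen's d, correlation with p.

Cohen's d uses the absolute-value convention with the pooled SD

    d = |mu1 - mu2| / s,   s^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2)

with sample SDs (divisor n-1). The t-test is Student's pooled two-sample
test (equal-variance framing, consistent with the pooled SD in d); Welch's
correction is available via ``welch=True``. Correlation p-values use the
t-approximation t = r sqrt(n-2) / sqrt(1-r^2) with df = n-2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.stats import rankdata

from .core_data import ValidationError, register_report_kind

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "compare_groups",
    "compare_from_summaries",
    "correlation",
]


@register_report_kind
@dataclass
class GroupComparison:
    mu1: float
    mu2: float
    sd1: float
    sd2: float
    n1: int
    n2: int
    pooled_s: float
    t_stat: float
    df: float
    p_two_sided: float
    cohens_d: float


@register_report_kind
@dataclass
class CorrelationResult:
    r: float
    n: int
    p_two_sided: float
    method: str


def _comparison(
    mu1: float, sd1: float, n1: int, mu2: float, sd2: float, n2: int,
    welch: bool = False,
) -> GroupComparison:
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs at least 2 members")
    if sd1 < 0 or sd2 < 0:
        raise ValidationError("SDs must be nonnegative")
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    sp = math.sqrt(sp2)
    diff = mu1 - mu2
    d = abs(diff) / sp if sp > 0 else 0.0

    if welch:
        se2 = sd1**2 / n1 + sd2**2 / n2
        se = math.sqrt(se2)
        if se == 0:
            t, df, p = 0.0, float(n1 + n2 - 2), 1.0
        else:
            t = diff / se
            df = se2**2 / (
                (sd1**2 / n1) ** 2 / (n1 - 1) + (sd2**2 / n2) ** 2 / (n2 - 1)
            )
            p = 2 * float(sps.t.sf(abs(t), df))
    else:
        df = float(n1 + n2 - 2)
        se = sp * math.sqrt(1 / n1 + 1 / n2)
        if se == 0:
            t, p = 0.0, 1.0
        else:
            t = diff / se
            p = 2 * float(sps.t.sf(abs(t), df))
    return GroupComparison(
        mu1=float(mu1), mu2=float(mu2), sd1=float(sd1), sd2=float(sd2),
        n1=int(n1), n2=int(n2), pooled_s=sp, t_stat=float(t), df=float(df),
        p_two_sided=min(p, 1.0), cohens_d=float(d),
    )


def compare_groups(
    values: np.ndarray, labels: np.ndarray, welch: bool = False
) -> GroupComparison:
    """Compare ``values`` between the two groups flagged by binary ``labels``.

    Group 1 is ``labels == 1`` (attractants by convention), group 2 the rest.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    g1 = values[labels == 1]
    g2 = values[labels == 0]
    if len(g1) < 2 or len(g2) < 2:
        raise ValidationError(
            f"each group needs >= 2 members (got {len(g1)} and {len(g2)})"
        )
    return _comparison(
        g1.mean(), g1.std(ddof=1), len(g1),
        g2.mean(), g2.std(ddof=1), len(g2),
        welch=welch,
    )


def compare_from_summaries(
    mu1: float, sd1: float, n1: int, mu2: float, sd2: float, n2: int,
    welch: bool = False,
) -> GroupComparison:
    """Same statistics computed from printed summary moments."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValidationError("summary SDs must be > 0")
    return _comparison(mu1, sd1, n1, mu2, sd2, n2, welch=welch)


def correlation(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation with a two-sided t-approximate p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D and of equal length")
    n = len(x)
    if n < 3:
        raise ValidationError("correlation requires n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in input")
    if method == "spearman":
        x, y = rankdata(x), rankdata(y)
    elif method != "pearson":
        raise ValidationError(f"unknown method {method!r}")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValidationError("zero variance in x or y")
    r = float(np.clip(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy), -1, 1))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
        p = 2 * float(sps.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, n=n, p_two_sided=min(p, 1.0), method=method)
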