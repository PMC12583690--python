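"""Reliability and validity checks: Cronbach's alpha, KMO sampling adequacy,
and Bartlett's test of sphericity, applied to the coded forward scores, the
coded reverse scores, and their column concatenation ("overall")."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .candy_core import code_answer
from .survey_io import ResponseSet

__all__ = [
    "ReliabilityReport",
    "cronbach_alpha",
    "kmo",
    "bartlett",
    "reliability_report",
    "score_matrix",
]


@dataclass(frozen=True)
class ReliabilityReport:
    scope: Literal["overall", "forward", "reverse"]
    alpha: float
    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "cronbach_alpha": self.alpha,
            "kmo": self.kmo,
            "bartlett_chi2": self.bartlett_chi2,
            "bartlett_df": self.bartlett_df,
            "bartlett_p": self.bartlett_p,
        }


def _as_matrix(scores) -> np.ndarray:
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2:
        raise ValueError("scores must be a 2-D respondents x items matrix")
    if np.isnan(x).any():
        raise ValueError("scores contain missing values; apply listwise deletion first")
    return x


def cronbach_alpha(scores) -> float:
    """alpha = k/(k-1) * (1 - sum of item variances / variance of total score)."""
    x = _as_matrix(scores)
    n, k = x.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 items and 2 respondents")
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance: alpha undefined")
    return float(k / (k - 1) * (1 - item_vars.sum() / total_var))


def _corr(x: np.ndarray) -> np.ndarray:
    r = np.corrcoef(x, rowvar=False)
    if np.isnan(r).any():
        raise ValueError("constant item column: correlation matrix undefined")
    return r


def kmo(scores) -> float:
    """Overall Kaiser-Meyer-Olkin measure.

    KMO = sum(r^2) / (sum(r^2) + sum(partial^2)) over off-diagonal entries,
    with partial correlations taken from the inverse correlation matrix.
    """
    x = _as_matrix(scores)
    r = _corr(x)
    try:
        rinv = np.linalg.inv(r)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular correlation matrix: KMO undefined") from exc
    d = np.sqrt(np.outer(np.diag(rinv), np.diag(rinv)))
    partial = -rinv / d
    off = ~np.eye(r.shape[0], dtype=bool)
    r2 = (r[off] ** 2).sum()
    p2 = (partial[off] ** 2).sum()
    return float(r2 / (r2 + p2))


def bartlett(scores) -> tuple[float, int, float]:
    """Bartlett's sphericity test: chi2 = -(n-1-(2k+5)/6) * ln det(R)."""
    x = _as_matrix(scores)
    n, k = x.shape
    if n <= k:
        raise ValueError("need more respondents than items for Bartlett's test")
    r = _corr(x)
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise ValueError("correlation matrix not positive definite")
    chi2 = -(n - 1 - (2 * k + 5) / 6.0) * logdet
    df = k * (k - 1) // 2
    p = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), p


def score_matrix(
    rs: ResponseSet, scope: Literal["overall", "forward", "reverse"]
) -> np.ndarray:
    """Coded score matrix for a scope, with listwise deletion of incomplete rows."""
    codes = rs.codes
    rows = []
    for rec in rs.records:
        fwd = [rec.forward.get(c) for c in codes]
        rev = [rec.reverse.get(c) for c in codes]
        if scope in ("forward", "overall") and any(v is None for v in fwd):
            continue
        if scope in ("reverse", "overall") and any(v is None for v in rev):
            continue
        if scope == "forward":
            rows.append([code_answer(v, "forward") for v in fwd])
        elif scope == "reverse":
            rows.append([code_answer(v, "reverse") for v in rev])
        else:
            rows.append(
                [code_answer(v, "forward") for v in fwd]
                + [code_answer(v, "reverse") for v in rev]
            )
    return np.asarray(rows, dtype=float)


def reliability_report(rs: ResponseSet) -> list[ReliabilityReport]:
    """Alpha/KMO/Bartlett for the forward, reverse and overall score matrices."""
    reports = []
    for scope in ("forward", "reverse", "overall"):
        x = score_matrix(rs, scope)
        chi2, df, p = bartlett(x)
        reports.append(
            ReliabilityReport(
                scope=scope,
                alpha=cronbach_alpha(x),
                kmo=kmo(x),
                bartlett_chi2=chi2,
                bartlett_df=df,
                bartlett_p=p,
            )
        )
    return reports
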