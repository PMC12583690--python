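"""Importance summaries per requirement category / service group, priority
ordering, and importance-satisfaction correlation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._round import round_half_up
from .candy_core import ClassificationResult, SatisfactionProfile
from .survey_io import ServiceItem

__all__ = [
    "GroupSummary",
    "ImportanceSummary",
    "CorrelationReport",
    "category_importance_summary",
    "service_group_summary",
    "priority_check",
    "importance_satisfaction_correlation",
]

#: Expected priority ordering of requirement categories, most critical first.
PRIORITY_ORDER = ("C", "M", "O", "A", "I")


@dataclass
class GroupSummary:
    """Ranking and importance statistics of one group of items."""

    ranking: list[str]
    max: float
    min: float
    average: float
    labels: dict[str, str] = field(default_factory=dict)


@dataclass
class ImportanceSummary:
    grouping: Literal["by_requirement_category", "by_service_category"]
    groups: dict[str, GroupSummary]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, g in self.groups.items():
            ranked = " > ".join(
                f"{c}({g.labels[c]})" if c in g.labels else c for c in g.ranking
            )
            rows.append(
                {"group": name, "ranking": ranked, "max": g.max, "min": g.min,
                 "average": g.average}
            )
        return pd.DataFrame(rows)


def _rank(codes: Sequence[str], imp: Mapping[str, float]) -> list[str]:
    # descending importance, ties broken by item code for determinism
    return sorted(codes, key=lambda c: (-imp[c], c))


def _summary(codes: Sequence[str], imp: Mapping[str, float], ndigits: int = 4) -> GroupSummary:
    vals = [imp[c] for c in codes]
    return GroupSummary(
        ranking=_rank(codes, imp),
        max=round_half_up(max(vals), ndigits),
        min=round_half_up(min(vals), ndigits),
        average=round_half_up(float(np.mean(vals)), ndigits),
    )


def category_importance_summary(
    labels: ClassificationResult, imp: Mapping[str, float]
) -> ImportanceSummary:
    """Per requirement category: descending ranking, max, min, mean importance."""
    missing = [c for c in labels.labels if c not in imp or imp[c] is None]
    if missing:
        raise KeyError(f"items without importance values: {missing}")
    groups: dict[str, GroupSummary] = {}
    for cat in PRIORITY_ORDER:
        codes = [c for c, lab in labels.labels.items() if lab == cat]
        if codes:
            groups[cat] = _summary(codes, imp)
    return ImportanceSummary(grouping="by_requirement_category", groups=groups)


def service_group_summary(
    catalog: Sequence[ServiceItem],
    imp: Mapping[str, float],
    labels: ClassificationResult | None = None,
) -> ImportanceSummary:
    """Per service category: importance ranking (with requirement labels when
    given) and mean importance."""
    groups: dict[str, GroupSummary] = {}
    for cat in dict.fromkeys(item.service_category for item in catalog):
        codes = [it.code for it in catalog if it.service_category == cat]
        g = _summary(codes, imp)
        if labels is not None:
            g.labels = {c: labels.labels[c] for c in codes if c in labels.labels}
        groups[cat] = g
    return ImportanceSummary(grouping="by_service_category", groups=groups)


def priority_check(summary: ImportanceSummary) -> tuple[list[str], bool]:
    """Categories sorted by mean importance; True iff the order respects
    C >= M >= O >= A >= I (absent categories are skipped)."""
    present = [c for c in PRIORITY_ORDER if c in summary.groups]
    observed = sorted(present, key=lambda c: (-summary.groups[c].average, PRIORITY_ORDER.index(c)))
    means = [summary.groups[c].average for c in present]
    ok = all(a >= b for a, b in zip(means, means[1:]))
    return observed, ok


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson correlations of importance with scaled satisfaction measures."""

    r_satisfaction: float
    r_dissatisfaction: float
    r_sum: float
    n: int
    p_values: dict[str, float]
    ci: dict[str, tuple[float, float]]
    ci_method: str

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "ci_method": self.ci_method,
            "satisfaction": {"r": self.r_satisfaction, "p": self.p_values["satisfaction"],
                             "ci": list(self.ci["satisfaction"])},
            "dissatisfaction": {"r": self.r_dissatisfaction,
                                "p": self.p_values["dissatisfaction"],
                                "ci": list(self.ci["dissatisfaction"])},
            "sum": {"r": self.r_sum, "p": self.p_values["sum"], "ci": list(self.ci["sum"])},
        }


def _fisher_ci(r: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(n - 3)
    zc = stats.norm.ppf(1 - alpha / 2)
    return float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se))


def _bootstrap_ci(
    x: np.ndarray, y: np.ndarray, n_boot: int, seed: int | None, alpha: float = 0.05
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    n = len(x)
    rs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        rs[b] = stats.pearsonr(x[idx], y[idx])[0]
    lo, hi = np.quantile(rs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def importance_satisfaction_correlation(
    p: SatisfactionProfile,
    ci_method: Literal["fisher", "bootstrap"] = "fisher",
    n_boot: int = 2000,
    seed: int | None = None,
) -> CorrelationReport:
    """Pearson r of importance vs 100*beta+, 100*beta-, 100*(beta+ + beta-).

    The x100 scaling matches the published analysis; Pearson r is scale
    invariant so it does not change the coefficients.
    """
    if p.n < 3:
        raise ValueError("need at least 3 items for a correlation")
    imp = np.array([p.importance_mean[c] for c in p.codes], dtype=float)
    bp = 100 * np.array([p.beta_pos[c] for c in p.codes], dtype=float)
    bn = 100 * np.array([p.beta_neg[c] for c in p.codes], dtype=float)
    if np.std(imp) == 0 or np.std(bp) == 0 or np.std(bn) == 0:
        raise ValueError("zero variance: correlation undefined")

    rvals, pvals, cis = {}, {}, {}
    for name, y in (("satisfaction", bp), ("dissatisfaction", bn), ("sum", bp + bn)):
        r, pv = stats.pearsonr(imp, y)
        rvals[name], pvals[name] = float(r), float(pv)
        if ci_method == "fisher":
            cis[name] = _fisher_ci(r, p.n)
        elif ci_method == "bootstrap":
            cis[name] = _bootstrap_ci(imp, y, n_boot, seed)
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
    return CorrelationReport(
        r_satisfaction=rvals["satisfaction"],
        r_dissatisfaction=rvals["dissatisfaction"],
        r_sum=rvals["sum"],
        n=p.n,
        p_values=pvals,
        ci=cis,
        ci_method=ci_method,
    )
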