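"""Scoring, ratio normalization, interval thresholds and the ratio-quadrant
and interval ("Candy") classifiers.

Pipeline: answers are coded per direction (forward score = option, reverse
score = 6 - option), summed per item into alpha scores, normalized across
items into relative satisfaction/dissatisfaction shares beta+ and beta-
(each direction sums to 1), and classified against the grand mean
theta = 1/n or the interval [theta - v*phi, theta + v*phi], where phi is
the range of the combined 2n beta values and v the floating ratio
(default 1/6).

Interval classification regions, evaluated in order (first match wins,
interval membership boundary-inclusive):

* O — both betas inside the interval
* C — both above the upper bound
* I — both below the lower bound
* A — beta+ at/above the lower bound and beta- at/below the upper bound
* M — everything else

The ordering resolves the syntactic overlap of the A and M conditions and
makes the classifier a total function on the positive quadrant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import pandas as pd

from .survey_io import ResponseSet

__all__ = [
    "DEFAULT_V",
    "LikertCoding",
    "AggregateScores",
    "SatisfactionProfile",
    "IntervalThresholds",
    "ClassificationResult",
    "code_answer",
    "aggregate",
    "normalize",
    "compute_thresholds",
    "classify_ratio",
    "classify_candy",
    "classify_all",
    "count_categories",
]

#: Default floating ratio for the interval half-width.
DEFAULT_V = 1.0 / 6.0

Direction = Literal["forward", "reverse"]


def code_answer(option: int, direction: Direction) -> int:
    """Score one answer: identity for forward questions, 6 - option for reverse."""
    if option not in (1, 2, 3, 4, 5):
        raise ValueError(f"option must be in 1..5, got {option!r}")
    if direction == "forward":
        return option
    if direction == "reverse":
        return 6 - option
    raise ValueError(f"direction must be 'forward' or 'reverse', got {direction!r}")


@dataclass(frozen=True)
class LikertCoding:
    """Option -> score bijection for one question direction."""

    direction: Direction

    @property
    def mapping(self) -> dict[int, int]:
        return {i: code_answer(i, self.direction) for i in range(1, 6)}

    def __call__(self, option: int) -> int:
        return code_answer(option, self.direction)


@dataclass
class AggregateScores:
    """Per-item sums of coded scores (and importance bookkeeping).

    ``q_pos``/``q_neg`` track, per item, how many respondents contributed
    to each direction; respondents missing an answer are excluded from
    that item and direction only.
    """

    codes: list[str]
    alpha_pos: dict[str, float]
    alpha_neg: dict[str, float]
    q_pos: dict[str, int]
    q_neg: dict[str, int]
    importance_sum: dict[str, float] = field(default_factory=dict)
    q_imp: dict[str, int] = field(default_factory=dict)


@dataclass
class SatisfactionProfile:
    """Relative satisfaction beta+ and dissatisfaction beta- per item.

    Each beta vector sums to 1 across items; ``importance_mean`` holds the
    per-item mean importance rating on the 1..5 scale.
    """

    codes: list[str]
    beta_pos: dict[str, float]
    beta_neg: dict[str, float]
    importance_mean: dict[str, float] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.codes)

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "SatisfactionProfile":
        """Build from a table with columns code, beta_pos, beta_neg[, importance]."""
        codes = df["code"].tolist()
        return cls(
            codes=codes,
            beta_pos=dict(zip(codes, df["beta_pos"].astype(float))),
            beta_neg=dict(zip(codes, df["beta_neg"].astype(float))),
            importance_mean=dict(zip(codes, df["importance"].astype(float)))
            if "importance" in df
            else {},
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "code": self.codes,
                "importance": [self.importance_mean.get(c) for c in self.codes],
                "beta_pos": [self.beta_pos[c] for c in self.codes],
                "beta_neg": [self.beta_neg[c] for c in self.codes],
            }
        )


@dataclass(frozen=True)
class IntervalThresholds:
    """Quadrant geometry: grand mean theta = 1/n and interval theta -/+ v*phi."""

    n: int
    theta: float
    phi: float
    v: float
    theta_low: float
    theta_up: float

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError("phi must be non-negative")
        if not (self.theta_low <= self.theta <= self.theta_up):
            raise ValueError("interval must bracket theta")

    def to_dict(self) -> dict[str, float]:
        return {
            "n": self.n,
            "theta": self.theta,
            "phi": self.phi,
            "v": self.v,
            "theta_low": self.theta_low,
            "theta_up": self.theta_up,
        }


@dataclass
class ClassificationResult:
    """Per-item labels produced by one named method."""

    method: str
    labels: dict[str, str]
    params: dict = field(default_factory=dict)


def aggregate(rs: ResponseSet) -> AggregateScores:
    """Sum coded forward/reverse scores per item over all respondents."""
    if not rs.records:
        raise ValueError("cannot aggregate an empty ResponseSet")
    codes = rs.codes
    ap = dict.fromkeys(codes, 0.0)
    an = dict.fromkeys(codes, 0.0)
    qp = dict.fromkeys(codes, 0)
    qn = dict.fromkeys(codes, 0)
    isum = dict.fromkeys(codes, 0.0)
    qi = dict.fromkeys(codes, 0)
    for rec in rs.records:
        for c in codes:
            f = rec.forward.get(c)
            if f is not None:
                ap[c] += code_answer(f, "forward")
                qp[c] += 1
            r = rec.reverse.get(c)
            if r is not None:
                an[c] += code_answer(r, "reverse")
                qn[c] += 1
            imp = rec.importance.get(c)
            if imp is not None:
                isum[c] += imp
                qi[c] += 1
    return AggregateScores(
        codes=codes, alpha_pos=ap, alpha_neg=an, q_pos=qp, q_neg=qn,
        importance_sum=isum, q_imp=qi,
    )


def normalize(a: AggregateScores) -> SatisfactionProfile:
    """Convert absolute alpha scores to relative betas (each direction sums to 1)."""
    if any(a.alpha_pos[c] <= 0 for c in a.codes) or any(
        a.alpha_neg[c] <= 0 for c in a.codes
    ):
        raise ValueError("all alpha scores must be positive to normalize")
    tot_p = sum(a.alpha_pos.values())
    tot_n = sum(a.alpha_neg.values())
    imp = {
        c: a.importance_sum[c] / a.q_imp[c]
        for c in a.codes
        if a.q_imp.get(c)
    }
    return SatisfactionProfile(
        codes=list(a.codes),
        beta_pos={c: a.alpha_pos[c] / tot_p for c in a.codes},
        beta_neg={c: a.alpha_neg[c] / tot_n for c in a.codes},
        importance_mean=imp,
    )


def compute_thresholds(p: SatisfactionProfile, v: float = DEFAULT_V) -> IntervalThresholds:
    """Interval geometry from a profile: theta = 1/n, phi = range of all 2n betas."""
    if p.n == 0:
        raise ValueError("profile is empty")
    if v < 0:
        raise ValueError("v must be non-negative")
    betas = [*p.beta_pos.values(), *p.beta_neg.values()]
    phi = max(betas) - min(betas)
    theta = 1.0 / p.n
    return IntervalThresholds(
        n=p.n, theta=theta, phi=phi, v=v,
        theta_low=theta - v * phi, theta_up=theta + v * phi,
    )


def classify_ratio(beta_pos: float, beta_neg: float, theta: float) -> str:
    """Point-threshold quadrant rule; boundary assigned to the lower side."""
    hi_p, hi_n = beta_pos > theta, beta_neg > theta
    if hi_p and hi_n:
        return "O"
    if hi_p:
        return "A"
    if hi_n:
        return "M"
    return "I"


def classify_candy(beta_pos: float, beta_neg: float, t: IntervalThresholds) -> str:
    """Interval five-category rule (see module docstring for the regions)."""
    lo, up = t.theta_low, t.theta_up
    p_in = lo <= beta_pos <= up
    n_in = lo <= beta_neg <= up
    if p_in and n_in:
        return "O"
    if beta_pos > up and beta_neg > up:
        return "C"
    if beta_pos < lo and beta_neg < lo:
        return "I"
    if beta_pos >= lo and beta_neg <= up:
        return "A"
    return "M"


def classify_all(
    p: SatisfactionProfile,
    method: Literal["ratio", "candy"] = "candy",
    params: Mapping | None = None,
) -> ClassificationResult:
    """Label every item of a profile with the ratio or candy classifier.

    ``params`` may supply ``theta`` (ratio), ``thresholds`` or ``v``
    (candy); anything absent is computed from the profile.
    """
    params = dict(params or {})
    if method == "ratio":
        theta = params.get("theta", 1.0 / p.n)
        labels = {c: classify_ratio(p.beta_pos[c], p.beta_neg[c], theta) for c in p.codes}
        return ClassificationResult(method="ratio", labels=labels, params={"theta": theta})
    if method == "candy":
        t = params.get("thresholds")
        if t is None:
            t = compute_thresholds(p, v=params.get("v", DEFAULT_V))
        labels = {c: classify_candy(p.beta_pos[c], p.beta_neg[c], t) for c in p.codes}
        return ClassificationResult(method="candy", labels=labels, params=t.to_dict())
    raise ValueError(f"unknown method {method!r}; expected 'ratio' or 'candy'")


def count_categories(r: ClassificationResult) -> dict[str, int]:
    """Label -> item count over a classification result."""
    out: dict[str, int] = {}
    for lab in r.labels.values():
        out[lab] = out.get(lab, 0) + 1
    return out
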