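"""Traditional Kano machinery: evaluation-table classification, the modal
(frequency) method, and Better-Worse coefficients."""

from __future__ import annotations

from dataclasses import dataclass, field

from .survey_io import ResponseSet

__all__ = [
    "LABELS",
    "EvaluationMatrix",
    "DEFAULT_MATRIX",
    "CategoryCounts",
    "BWCoefficients",
    "classify_pair",
    "tabulate_item",
    "frequency_classify",
    "bw_coefficients",
    "bw_classify",
]

#: Per-response outcome labels of the evaluation table.
LABELS = ("A", "O", "M", "I", "R", "Q")

# Modified Kano evaluation table: row = forward option, column = reverse
# option, both 1..5 with 1 = "I don't like it" ... 5 = "Be fond of".
_DEFAULT_GRID = (
    ("Q", "R", "R", "R", "R"),
    ("M", "I", "I", "I", "R"),
    ("M", "I", "I", "I", "R"),
    ("M", "I", "I", "I", "R"),
    ("O", "A", "A", "A", "Q"),
)


@dataclass(frozen=True)
class EvaluationMatrix:
    """5x5 (forward option, reverse option) -> label grid."""

    grid: tuple[tuple[str, ...], ...] = _DEFAULT_GRID

    def __post_init__(self) -> None:
        if len(self.grid) != 5 or any(len(row) != 5 for row in self.grid):
            raise ValueError("evaluation matrix must be 5x5")
        bad = {c for row in self.grid for c in row} - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels in matrix: {sorted(bad)}")

    @classmethod
    def from_table(cls, df) -> "EvaluationMatrix":
        """Build from the packaged ``evaluation_matrix_table3`` layout."""
        rows = df.sort_values("forward")
        grid = tuple(
            tuple(r[f"reverse_{j}"] for j in range(1, 6)) for _, r in rows.iterrows()
        )
        return cls(grid=grid)


DEFAULT_MATRIX = EvaluationMatrix()


@dataclass
class CategoryCounts:
    """Per-item tally of evaluation-table outcomes over respondents."""

    item: str
    counts: dict[str, int] = field(default_factory=lambda: dict.fromkeys(LABELS, 0))

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def functional_total(self) -> int:
        """A+O+M+I — the Better-Worse denominator (R and Q excluded)."""
        return sum(self.counts.get(k, 0) for k in "AOMI")


@dataclass(frozen=True)
class BWCoefficients:
    """Better (SI) and Worse (DSI) satisfaction coefficients."""

    SI: float
    DSI: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.SI <= 1.0):
            raise ValueError(f"SI out of [0,1]: {self.SI}")
        if not (-1.0 <= self.DSI <= 0.0):
            raise ValueError(f"DSI out of [-1,0]: {self.DSI}")


def classify_pair(forward: int, reverse: int, matrix: EvaluationMatrix = DEFAULT_MATRIX) -> str:
    """Label one (forward, reverse) answer pair via the evaluation table."""
    if forward not in (1, 2, 3, 4, 5) or reverse not in (1, 2, 3, 4, 5):
        raise ValueError(f"options must be in 1..5, got ({forward}, {reverse})")
    return matrix.grid[forward - 1][reverse - 1]


def tabulate_item(
    rs: ResponseSet, item: str, matrix: EvaluationMatrix = DEFAULT_MATRIX
) -> CategoryCounts:
    """Count evaluation-table outcomes for one item.

    Respondents missing either the forward or the reverse answer for the
    item are excluded.
    """
    if item not in rs.codes:
        raise KeyError(f"unknown item {item!r}")
    cc = CategoryCounts(item=item)
    for rec in rs.records:
        f, r = rec.forward.get(item), rec.reverse.get(item)
        if f is None or r is None:
            continue
        cc.counts[classify_pair(f, r, matrix)] += 1
    return cc


# Tie-break priority for the frequency method (worst-case-first ordering
# from the Kano literature: M > O > A > I, with R and Q last).
_FREQ_PRIORITY = ("M", "O", "A", "I", "R", "Q")


def frequency_classify(c: CategoryCounts) -> str:
    """Modal category of an item; ties broken by M > O > A > I > R > Q."""
    if c.total == 0:
        raise ValueError(f"no responses tallied for item {c.item!r}")
    return max(_FREQ_PRIORITY, key=lambda lab: (c.counts.get(lab, 0), -_FREQ_PRIORITY.index(lab)))


def bw_coefficients(c: CategoryCounts) -> BWCoefficients:
    """SI = (A+O)/(A+O+M+I), DSI = -(O+M)/(A+O+M+I)."""
    denom = c.functional_total
    if denom == 0:
        raise ZeroDivisionError(
            f"item {c.item!r}: A+O+M+I is zero, Better-Worse coefficients undefined"
        )
    a, o, m = (c.counts.get(k, 0) for k in "AOM")
    return BWCoefficients(SI=(a + o) / denom, DSI=-(o + m) / denom)


def bw_classify(b: BWCoefficients, cut: float = 0.5) -> str:
    """Quadrant rule on (SI, |DSI|) with a boundary-inclusive cutoff.

    The published comparison does not state its cutoff; 0.5 is the
    conventional choice and is exposed as a parameter.
    """
    if not (0.0 < cut < 1.0):
        raise ValueError(f"cut must be in (0,1), got {cut}")
    hi_si = b.SI >= cut
    hi_dsi = abs(b.DSI) >= cut
    if hi_si and hi_dsi:
        return "O"
    if hi_si:
        return "A"
    if hi_dsi:
        return "M"
    return "I"
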