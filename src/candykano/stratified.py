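"""Subgroup re-classification, difference flagging, and life-cycle chain
distances along I -> A -> O(C) -> M."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .candy_core import (
    DEFAULT_V,
    aggregate,
    classify_all,
    compute_thresholds,
    normalize,
)
from .survey_io import ResponseSet

__all__ = [
    "CHAIN_POSITION",
    "StratifiedComparison",
    "stratify_classify",
    "chain_distance",
    "adjacency_report",
    "comparison_from_table",
]

# Life-cycle chain positions; O and C share a stage ("O(C)").
CHAIN_POSITION = {"I": 0, "A": 1, "O": 2, "C": 2, "M": 3}


@dataclass
class StratifiedComparison:
    """Per-subgroup classifications of the same items plus difference flags."""

    grouping: str
    groups: list[str]
    sizes: dict[str, int]
    labels: dict[str, dict[str, str]]  # item -> group -> label
    method: str
    params: dict[str, dict] = field(default_factory=dict)

    @property
    def flags(self) -> dict[str, bool]:
        """item -> True iff the per-group labels are not all identical."""
        return {
            item: len(set(per_group.values())) > 1
            for item, per_group in self.labels.items()
        }

    @property
    def chain_distances(self) -> dict[str, int]:
        """item -> max pairwise chain distance among its group labels."""
        out = {}
        for item, per_group in self.labels.items():
            labs = list(per_group.values())
            out[item] = max(
                chain_distance(a, b) for a in labs for b in labs
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        dists = self.chain_distances
        flags = self.flags
        for item, per_group in self.labels.items():
            row = {"code": item, **per_group, "flag": flags[item],
                   "chain_distance": dists[item]}
            rows.append(row)
        return pd.DataFrame(rows)


def _split_records(
    rs: ResponseSet, attribute: str, binning: Mapping[str, str] | None
) -> dict[str, list]:
    groups: dict[str, list] = {}
    for rec in rs.records:
        raw = rec.demographics.get(attribute)
        if raw is None:
            continue  # missing demographics exclude only from this stratification
        label = binning.get(raw) if binning is not None else raw
        if label is None:
            continue
        groups.setdefault(label, []).append(rec)
    return groups


def stratify_classify(
    rs: ResponseSet,
    attribute: str,
    method: str = "candy",
    params: Mapping | None = None,
    binning: Mapping[str, str] | None = None,
    pooled_thresholds: bool = False,
) -> StratifiedComparison:
    """Run the full pipeline (aggregate -> normalize -> thresholds -> classify)
    independently inside each subgroup of ``attribute``.

    ``binning`` optionally maps raw demographic values onto coarser group
    labels (e.g. five income brackets -> low/high); unmapped values are
    dropped.  By default interval thresholds are recomputed per subgroup,
    since betas are relative within a population; ``pooled_thresholds=True``
    reuses the pooled-sample interval instead.
    """
    if not any(attribute in rec.demographics for rec in rs.records):
        raise KeyError(f"attribute {attribute!r} not present in any record")
    split = _split_records(rs, attribute, binning)
    if not split:
        raise ValueError(f"no subgroup received any record for {attribute!r}")
    for name, recs in split.items():
        if not recs:
            raise ValueError(f"subgroup {name!r} of {attribute!r} is empty")

    params = dict(params or {})
    if pooled_thresholds and method == "candy" and "thresholds" not in params:
        pooled_profile = normalize(aggregate(rs))
        params["thresholds"] = compute_thresholds(
            pooled_profile, v=params.get("v", DEFAULT_V)
        )

    group_names = sorted(split)
    labels: dict[str, dict[str, str]] = {c: {} for c in rs.codes}
    used_params: dict[str, dict] = {}
    for name in group_names:
        sub = ResponseSet(catalog=rs.catalog, records=split[name])
        profile = normalize(aggregate(sub))
        result = classify_all(profile, method=method, params=params)
        used_params[name] = result.params
        for item, lab in result.labels.items():
            labels[item][name] = lab

    return StratifiedComparison(
        grouping=attribute,
        groups=group_names,
        sizes={name: len(split[name]) for name in group_names},
        labels=labels,
        method=method,
        params=used_params,
    )


def chain_distance(a: str, b: str) -> int:
    """Absolute difference of life-cycle chain positions of two labels."""
    try:
        return abs(CHAIN_POSITION[a] - CHAIN_POSITION[b])
    except KeyError as exc:
        raise ValueError(
            f"labels must be in {sorted(CHAIN_POSITION)}, got ({a!r}, {b!r})"
        ) from exc


@dataclass(frozen=True)
class AdjacencySummary:
    n_flagged: int
    n_adjacent: int
    fraction_adjacent: float
    violators: tuple[str, ...]


def adjacency_report(sc: StratifiedComparison) -> AdjacencySummary:
    """Among items whose labels differ across groups, the share whose labels
    sit at most one stage apart on the I -> A -> O(C) -> M chain."""
    flags = sc.flags
    dists = sc.chain_distances
    flagged = [item for item, f in flags.items() if f]
    adjacent = [item for item in flagged if dists[item] <= 1]
    violators = tuple(sorted(item for item in flagged if dists[item] > 1))
    frac = len(adjacent) / len(flagged) if flagged else float("nan")
    return AdjacencySummary(
        n_flagged=len(flagged),
        n_adjacent=len(adjacent),
        fraction_adjacent=frac,
        violators=violators,
    )


def comparison_from_table(df: pd.DataFrame, pairs: Sequence[tuple[str, str, str]]) -> list[StratifiedComparison]:
    """Build comparisons from a wide label table (``differences_table13``
    layout: one ``code`` column plus one label column per stratum).

    ``pairs`` lists (grouping_name, column_a, column_b) triples.
    """
    out = []
    for grouping, col_a, col_b in pairs:
        labels = {
            r["code"]: {col_a: r[col_a], col_b: r[col_b]} for _, r in df.iterrows()
        }
        out.append(
            StratifiedComparison(
                grouping=grouping,
                groups=[col_a, col_b],
                sizes={},
                labels=labels,
                method="fixture",
            )
        )
    return out
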