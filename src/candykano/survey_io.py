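"""Questionnaire data model, tabular I/O, response filtering and packaged fixtures.

The on-disk layout is one row per respondent in wide format: for every
service item ``<code>`` there are three columns ``<code>_f`` (forward
question: how do you feel if the service IS provided), ``<code>_r``
(reverse question: service absent) and ``<code>_imp`` (importance rating),
all on a 1..5 scale.  Column naming is configurable through
:class:`Schema`.  Out-of-range or unparseable cells are loaded as missing,
never silently dropped.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "SERVICE_CATEGORIES",
    "FIXTURE_NAMES",
    "ServiceItem",
    "ResponseRecord",
    "ResponseSet",
    "PreprocessSummary",
    "Schema",
    "FilterRules",
    "SchemaError",
    "ValidationError",
    "load_responses",
    "write_responses",
    "filter_invalid",
    "get_fixture",
    "fixture_catalog",
]

#: Closed set of service categories.
SERVICE_CATEGORIES = frozenset({"life", "intelligent", "health", "security", "spiritual"})

#: Names accepted by :func:`get_fixture`.
FIXTURE_NAMES = (
    "catalog_table5",
    "profiles_table9",
    "evaluation_matrix_table3",
    "differences_table13",
)

# Item-code prefix -> service category used when a catalog must be inferred
# from column names alone.
_PREFIX_CATEGORY = {
    "A": "life",
    "B": "intelligent",
    "C": "health",
    "D": "security",
    "E": "spiritual",
}


class SchemaError(ValueError):
    """Raised when a column-mapping schema is inconsistent with the file."""


class ValidationError(ValueError):
    """Raised when response data violates a structural invariant."""


@dataclass(frozen=True)
class ServiceItem:
    """One service item of the questionnaire catalog."""

    code: str
    label: str
    service_category: str

    def __post_init__(self) -> None:
        if self.service_category not in SERVICE_CATEGORIES:
            raise ValidationError(
                f"service_category {self.service_category!r} not in {sorted(SERVICE_CATEGORIES)}"
            )


@dataclass
class ResponseRecord:
    """One respondent: paired Kano answers, importance ratings, demographics.

    Answer maps use ``None`` for missing values; keys are item codes.
    """

    respondent_id: str
    forward: dict[str, int | None] = field(default_factory=dict)
    reverse: dict[str, int | None] = field(default_factory=dict)
    importance: dict[str, int | None] = field(default_factory=dict)
    demographics: dict[str, str] = field(default_factory=dict)

    def is_complete(self, codes: Iterable[str]) -> bool:
        """True iff every Kano answer and importance rating is present."""
        return all(
            self.forward.get(c) is not None
            and self.reverse.get(c) is not None
            and self.importance.get(c) is not None
            for c in codes
        )


@dataclass
class ResponseSet:
    """A catalog plus the records validated against it."""

    catalog: list[ServiceItem]
    records: list[ResponseRecord]

    @property
    def codes(self) -> list[str]:
        return [item.code for item in self.catalog]

    def __post_init__(self) -> None:
        codes = self.codes
        if len(set(codes)) != len(codes):
            raise ValidationError("duplicate item codes in catalog")
        ids = [r.respondent_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate respondent_id in records")
        known = set(codes)
        for rec in self.records:
            for answers in (rec.forward, rec.reverse, rec.importance):
                unknown = set(answers) - known
                if unknown:
                    raise ValidationError(
                        f"record {rec.respondent_id!r} references unknown items {sorted(unknown)}"
                    )


@dataclass
class PreprocessSummary:
    """Bookkeeping of the raw -> valid questionnaire reduction."""

    n_received: int
    n_completed: int
    n_valid: int
    removal_reasons: dict[str, int] = field(default_factory=dict)
    warning: str | None = None

    @property
    def effective_rate(self) -> float:
        """Valid share of completed questionnaires (370/425 convention)."""
        return self.n_valid / self.n_completed

    def __post_init__(self) -> None:
        if not (self.n_valid <= self.n_completed <= self.n_received):
            raise ValidationError("expected n_valid <= n_completed <= n_received")


@dataclass(frozen=True)
class Schema:
    """Column mapping for the wide CSV layout."""

    id_column: str = "respondent_id"
    forward_suffix: str = "_f"
    reverse_suffix: str = "_r"
    importance_suffix: str = "_imp"
    #: demographic column names; None means "every non-item, non-id column".
    demographics: tuple[str, ...] | None = None

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "Schema":
        demo = cfg.get("demographics")
        return cls(
            id_column=cfg.get("id_column", "respondent_id"),
            forward_suffix=cfg.get("forward_suffix", "_f"),
            reverse_suffix=cfg.get("reverse_suffix", "_r"),
            importance_suffix=cfg.get("importance_suffix", "_imp"),
            demographics=tuple(demo) if demo is not None else None,
        )


@dataclass(frozen=True)
class FilterRules:
    """Which validity filters :func:`filter_invalid` applies.

    The published study reports 425 completed -> 370 valid without stating
    its criteria; these three rules are standard survey hygiene and each
    can be switched off.
    """

    completeness: bool = True
    straight_line: bool = True
    q_dominance: bool = True
    q_threshold: float = 0.5  # fraction of item pairs classified Q that invalidates

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "FilterRules":
        return cls(
            completeness=bool(cfg.get("completeness", True)),
            straight_line=bool(cfg.get("straight_line", True)),
            q_dominance=bool(cfg.get("q_dominance", True)),
            q_threshold=float(cfg.get("q_threshold", 0.5)),
        )


def _parse_answer(raw: str | None) -> int | None:
    """Parse a 1..5 cell; anything else (blank, junk, out of range) is missing."""
    if raw is None:
        return None
    raw = raw.strip()
    if not raw:
        return None
    try:
        value = int(float(raw))
    except ValueError:
        return None
    return value if 1 <= value <= 5 else None


def _infer_catalog(codes: list[str]) -> list[ServiceItem]:
    return [
        ServiceItem(code=c, label=c, service_category=_PREFIX_CATEGORY.get(c[:1], "life"))
        for c in codes
    ]


def load_responses(
    path: str | Path,
    schema: Schema | Mapping | None = None,
    catalog: list[ServiceItem] | None = None,
) -> ResponseSet:
    """Read a wide-format response CSV into a raw (unfiltered) :class:`ResponseSet`.

    Item codes are taken from ``catalog`` when given, otherwise inferred
    from the forward columns.  Cells that do not parse to an integer in
    1..5 are flagged missing.

    Raises
    ------
    FileNotFoundError
        if ``path`` does not exist.
    SchemaError
        if a catalog item has no forward column in the file.
    ValidationError
        on duplicate respondent ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if schema is None:
        schema = Schema()
    elif not isinstance(schema, Schema):
        schema = Schema.from_mapping(schema)

    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        rows = list(reader)

    fs, rs_, imps = schema.forward_suffix, schema.reverse_suffix, schema.importance_suffix
    file_codes = [c[: -len(fs)] for c in header if c.endswith(fs)]
    if catalog is None:
        if not file_codes:
            raise SchemaError(f"no forward columns ending in {fs!r} found in {path}")
        catalog = _infer_catalog(file_codes)
    else:
        missing = [it.code for it in catalog if f"{it.code}{fs}" not in header]
        if missing:
            raise SchemaError(f"catalog items without forward columns: {missing}")
    codes = [it.code for it in catalog]

    item_cols = {f"{c}{s}" for c in codes for s in (fs, rs_, imps)}
    if schema.demographics is None:
        demo_cols = [c for c in header if c != schema.id_column and c not in item_cols]
    else:
        demo_cols = list(schema.demographics)
        absent = [c for c in demo_cols if c not in header]
        if absent:
            raise SchemaError(f"demographic columns not in file: {absent}")

    records = []
    for i, row in enumerate(rows):
        rid = (row.get(schema.id_column) or "").strip() or f"row{i + 1}"
        records.append(
            ResponseRecord(
                respondent_id=rid,
                forward={c: _parse_answer(row.get(f"{c}{fs}")) for c in codes},
                reverse={c: _parse_answer(row.get(f"{c}{rs_}")) for c in codes},
                importance={c: _parse_answer(row.get(f"{c}{imps}")) for c in codes},
                demographics={
                    d: row[d].strip() for d in demo_cols if row.get(d) and row[d].strip()
                },
            )
        )
    return ResponseSet(catalog=catalog, records=records)


def write_responses(
    rs: ResponseSet,
    path: str | Path,
    schema: Schema | Mapping | None = None,
) -> None:
    """Write a :class:`ResponseSet` in the wide CSV layout (round-trips with loader)."""
    if schema is None:
        schema = Schema()
    elif not isinstance(schema, Schema):
        schema = Schema.from_mapping(schema)
    codes = rs.codes
    demo_cols = sorted({k for rec in rs.records for k in rec.demographics})
    header = [schema.id_column]
    for c in codes:
        header += [
            f"{c}{schema.forward_suffix}",
            f"{c}{schema.reverse_suffix}",
            f"{c}{schema.importance_suffix}",
        ]
    header += demo_cols

    def cell(v: int | None) -> str:
        return "" if v is None else str(v)

    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec in rs.records:
            row = [rec.respondent_id]
            for c in codes:
                row += [
                    cell(rec.forward.get(c)),
                    cell(rec.reverse.get(c)),
                    cell(rec.importance.get(c)),
                ]
            row += [rec.demographics.get(d, "") for d in demo_cols]
            writer.writerow(row)


def _is_straight_liner(rec: ResponseRecord, codes: list[str]) -> bool:
    fwd = {rec.forward.get(c) for c in codes}
    rev = {rec.reverse.get(c) for c in codes}
    return (
        len(fwd) == 1
        and len(rev) == 1
        and None not in fwd
        and None not in rev
    )


def _q_share(rec: ResponseRecord, codes: list[str]) -> float:
    # local import: kano_traditional depends on this module's types
    from .kano_traditional import DEFAULT_MATRIX, classify_pair

    pairs = [
        (rec.forward.get(c), rec.reverse.get(c))
        for c in codes
        if rec.forward.get(c) is not None and rec.reverse.get(c) is not None
    ]
    if not pairs:
        return 0.0
    n_q = sum(1 for f, r in pairs if classify_pair(f, r, DEFAULT_MATRIX) == "Q")
    return n_q / len(pairs)


def filter_invalid(
    rs: ResponseSet,
    rules: FilterRules | Mapping | None = None,
    n_received: int | None = None,
) -> tuple[ResponseSet, PreprocessSummary]:
    """Drop invalid questionnaires and summarise the reduction.

    A record is removed by the first enabled rule it trips (checked in the
    order completeness, straight-lining, Q-dominance), so the per-rule
    counts in the summary sum to the number removed.
    """
    if not rs.records:
        raise ValidationError("cannot filter an empty ResponseSet")
    if rules is None:
        rules = FilterRules()
    elif not isinstance(rules, FilterRules):
        rules = FilterRules.from_mapping(rules)

    codes = rs.codes
    reasons = {"incomplete": 0, "straight_line": 0, "q_dominance": 0}
    kept = []
    for rec in rs.records:
        if rules.completeness and not rec.is_complete(codes):
            reasons["incomplete"] += 1
        elif rules.straight_line and _is_straight_liner(rec, codes):
            reasons["straight_line"] += 1
        elif rules.q_dominance and _q_share(rec, codes) > rules.q_threshold:
            reasons["q_dominance"] += 1
        else:
            kept.append(rec)

    n_completed = len(rs.records)
    summary = PreprocessSummary(
        n_received=n_received if n_received is not None else n_completed,
        n_completed=n_completed,
        n_valid=len(kept),
        removal_reasons={k: v for k, v in reasons.items() if v},
        warning="all records removed" if not kept else None,
    )
    return ResponseSet(catalog=rs.catalog, records=kept), summary


def get_fixture(name: str) -> pd.DataFrame:
    """Return a packaged in-paper table as a DataFrame.

    ``catalog_table5``           46-item service catalog.
    ``profiles_table9``          per-item importance, beta+/-, four method labels.
    ``evaluation_matrix_table3`` 5x5 forward x reverse evaluation grid.
    ``differences_table13``      per-subgroup category labels for ten strata.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    ref = resources.files("candykano").joinpath("data", f"{name}.csv")
    with resources.as_file(ref) as p:
        return pd.read_csv(p)


def fixture_catalog() -> list[ServiceItem]:
    """The packaged 46-item catalog as :class:`ServiceItem` objects."""
    df = get_fixture("catalog_table5")
    return [
        ServiceItem(code=r.code, label=r.label, service_category=r.service_category)
        for r in df.itertuples()
    ]
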