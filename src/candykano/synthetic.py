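"""Seedable questionnaire-population generator with plantable answer
archetypes and subgroup effects.

Each of the five requirement categories has a "pure" pair of answer
distributions over the five options; ``archetype`` linearly interpolates
between the uniform distribution (strength 0) and the pure pattern
(strength 1).  ``generate`` draws independent multinomial answers per
respondent and item, and ``recovery_experiment`` measures how often the
interval classifier recovers the planted labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .candy_core import DEFAULT_V, aggregate, classify_all, normalize
from .survey_io import ResponseRecord, ResponseSet, ServiceItem

__all__ = [
    "ARCHETYPES",
    "DEFAULT_MIX",
    "ItemDesign",
    "SubgroupDesign",
    "SyntheticDesign",
    "archetype",
    "default_design",
    "generate",
    "recovery_experiment",
]

#: Planted category mix matching the published 5C/7M/21O/6A/7I split.
DEFAULT_MIX = ("C",) * 5 + ("M",) * 7 + ("O",) * 21 + ("A",) * 6 + ("I",) * 7

_UNIFORM = np.full(5, 0.2)

# Pure answer patterns (forward probabilities, reverse probabilities).
# C: delighted if present, upset if absent — extreme in both directions.
# A: delighted if present, tolerant of absence (reverse uninformative).
# M: presence taken for granted (forward uninformative), upset if absent.
# O: moderate mass on both extremes of both questions.
# I: "doesn't matter" either way.
ARCHETYPES: dict[str, tuple[np.ndarray, np.ndarray]] = {
    "C": (np.array([0, 0, 0, 0, 1.0]), np.array([1.0, 0, 0, 0, 0])),
    "A": (np.array([0, 0, 0, 0, 1.0]), _UNIFORM.copy()),
    "M": (_UNIFORM.copy(), np.array([1.0, 0, 0, 0, 0])),
    "O": (np.array([0.25, 0, 0, 0, 0.75]), np.array([0.75, 0, 0, 0, 0.25])),
    "I": (np.array([0, 0, 1.0, 0, 0]), np.array([0, 0, 1.0, 0, 0])),
}


def archetype(label: str, strength: float) -> tuple[np.ndarray, np.ndarray]:
    """Forward/reverse answer distributions for a planted category.

    ``strength`` interpolates linearly from uniform (0) to the pure
    pattern (1).
    """
    if label not in ARCHETYPES:
        raise KeyError(f"unknown archetype {label!r}; choose from {sorted(ARCHETYPES)}")
    if not 0.0 <= strength <= 1.0:
        raise ValueError(f"strength must be in [0,1], got {strength}")
    pf, pr = ARCHETYPES[label]
    fwd = (1 - strength) * _UNIFORM + strength * pf
    rev = (1 - strength) * _UNIFORM + strength * pr
    return fwd, rev


def _check_probs(p: np.ndarray, what: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (5,) or (p < 0).any() or not np.isclose(p.sum(), 1.0):
        raise ValueError(f"{what}: probabilities must be a non-negative 5-vector summing to 1")
    return p


@dataclass
class ItemDesign:
    """Answer distributions for one item, with optional per-subgroup overrides."""

    forward: np.ndarray
    reverse: np.ndarray
    importance: np.ndarray = field(default_factory=lambda: _UNIFORM.copy())
    target: str | None = None  # planted category, if any
    overrides: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_archetype(cls, label: str, strength: float, **kw) -> "ItemDesign":
        fwd, rev = archetype(label, strength)
        return cls(forward=fwd, reverse=rev, target=label, **kw)

    def distributions(self, subgroup: str | None) -> tuple[np.ndarray, np.ndarray]:
        if subgroup is not None and subgroup in self.overrides:
            return self.overrides[subgroup]
        return self.forward, self.reverse


@dataclass
class SubgroupDesign:
    name: str
    size: int
    demographics: dict[str, str] = field(default_factory=dict)


@dataclass
class SyntheticDesign:
    """Full specification of a synthetic questionnaire population."""

    catalog: list[ServiceItem]
    items: dict[str, ItemDesign]
    subgroups: list[SubgroupDesign] = field(default_factory=list)
    seed: int = 0
    #: 0 = importance independent of Kano answers; 1 = importance pinned to
    #: the item's mean answer sensitivity (emulates the observed strong
    #: importance-sensitivity correlation).
    importance_coupling: float = 0.0

    def __post_init__(self) -> None:
        codes = {it.code for it in self.catalog}
        if set(self.items) != codes:
            raise ValueError("items must cover exactly the catalog codes")
        for code, item in self.items.items():
            _check_probs(item.forward, f"{code} forward")
            _check_probs(item.reverse, f"{code} reverse")
            _check_probs(item.importance, f"{code} importance")
            for g, (f, r) in item.overrides.items():
                _check_probs(f, f"{code}/{g} forward")
                _check_probs(r, f"{code}/{g} reverse")

    @property
    def targets(self) -> dict[str, str]:
        return {c: it.target for c, it in self.items.items() if it.target is not None}


def _importance_probs(design: SyntheticDesign, item: ItemDesign) -> np.ndarray:
    c = design.importance_coupling
    if c <= 0:
        return item.importance
    options = np.arange(1, 6)
    mean_sens = float(0.5 * (item.forward @ options + item.reverse @ options[::-1]))
    # split mass between the neighbouring ratings so E[importance] = mean_sens
    lo = int(np.clip(np.floor(mean_sens), 1, 5))
    hi = min(lo + 1, 5)
    frac = mean_sens - lo if hi > lo else 0.0
    pinned = np.zeros(5)
    pinned[lo - 1] = 1.0 - frac
    pinned[hi - 1] += frac
    return (1 - c) * item.importance + c * pinned


def _allocate(sizes: list[int], q: int) -> list[int]:
    """Largest-remainder allocation of q respondents across subgroup weights."""
    total = sum(sizes)
    raw = [s * q / total for s in sizes]
    alloc = [int(x) for x in raw]
    rema = sorted(range(len(raw)), key=lambda i: raw[i] - alloc[i], reverse=True)
    for i in rema[: q - sum(alloc)]:
        alloc[i] += 1
    return alloc


def generate(design: SyntheticDesign, q: int | None = None) -> ResponseSet:
    """Draw a deterministic (seeded) population from the design.

    ``q`` defaults to the sum of subgroup sizes; if it differs, respondents
    are allocated to subgroups proportionally (largest remainder).
    """
    subgroups = design.subgroups or [SubgroupDesign(name="all", size=1)]
    if q is None:
        q = sum(g.size for g in subgroups)
    if q < 1:
        raise ValueError("q must be >= 1")
    alloc = _allocate([g.size for g in subgroups], q)

    rng = np.random.default_rng(design.seed)
    codes = [it.code for it in design.catalog]
    records: list[ResponseRecord] = []
    rid = 0
    for group, n in zip(subgroups, alloc):
        if n == 0:
            continue
        fwd_draws: dict[str, np.ndarray] = {}
        rev_draws: dict[str, np.ndarray] = {}
        imp_draws: dict[str, np.ndarray] = {}
        for code in codes:
            item = design.items[code]
            pf, pr = item.distributions(group.name)
            fwd_draws[code] = rng.choice(5, size=n, p=_check_probs(pf, code)) + 1
            rev_draws[code] = rng.choice(5, size=n, p=_check_probs(pr, code)) + 1
            imp_draws[code] = (
                rng.choice(5, size=n, p=_importance_probs(design, item)) + 1
            )
        for i in range(n):
            rid += 1
            records.append(
                ResponseRecord(
                    respondent_id=f"S{rid:05d}",
                    forward={c: int(fwd_draws[c][i]) for c in codes},
                    reverse={c: int(rev_draws[c][i]) for c in codes},
                    importance={c: int(imp_draws[c][i]) for c in codes},
                    demographics={"subgroup": group.name, **group.demographics},
                )
            )
    return ResponseSet(catalog=list(design.catalog), records=records)


def default_design(
    strength: float = 0.9,
    seed: int = 0,
    subgroups: list[SubgroupDesign] | None = None,
    importance_coupling: float = 0.0,
) -> SyntheticDesign:
    """Design over the packaged 46-item catalog planting the default mix."""
    from .survey_io import fixture_catalog

    catalog = fixture_catalog()
    items = {
        it.code: ItemDesign.from_archetype(label, strength)
        for it, label in zip(catalog, DEFAULT_MIX)
    }
    return SyntheticDesign(
        catalog=catalog,
        items=items,
        subgroups=subgroups or [],
        seed=seed,
        importance_coupling=importance_coupling,
    )


def recovery_experiment(
    design: SyntheticDesign,
    q: int,
    reps: int,
    seed: int | None = None,
    v: float = DEFAULT_V,
) -> dict[str, float]:
    """Fraction of replicates in which the interval classifier returns each
    item's planted label.  Items without a target are skipped."""
    targets = design.targets
    if not targets:
        raise ValueError("design plants no target labels")
    base_seed = design.seed if seed is None else seed
    hits = dict.fromkeys(targets, 0)
    for rep in range(reps):
        d = SyntheticDesign(
            catalog=design.catalog,
            items=design.items,
            subgroups=design.subgroups,
            seed=int(np.random.SeedSequence([base_seed, rep]).generate_state(1)[0]),
            importance_coupling=design.importance_coupling,
        )
        rs = generate(d, q=q)
        result = classify_all(normalize(aggregate(rs)), method="candy", params={"v": v})
        for code, want in targets.items():
            if result.labels[code] == want:
                hits[code] += 1
    return {code: hits[code] / reps for code in targets}
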