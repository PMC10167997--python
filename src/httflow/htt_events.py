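"""From significant pairwise signals to weighted, dated HTT events.

A single horizontal transfer can produce several significant pairwise
signals (e.g. a transfer involving the ancestor of two sister species shows
up in both descendants). Signals are therefore grouped per TE family and
converted into *events*, each standardized to a total weight of four spread
over the alternative donor/acceptor scenarios:

* two species involved: a single undirected scenario, weight 2 per species;
* more than two species: two alternative scenarios, each summing 2 —
  (a) a direct transfer between the significant pair with the lowest dS
  (weight 1 each), and (b) a transfer involving the ancestor of a clade of
  species that are vertically connected among themselves (all their mutual
  pairs non-significant): weight 1 to the external partner and the remaining
  weight 1 split equally among the clade members (0.5/0.5 for a sister
  pair).

Summing each species' weights over events and dividing by four yields its
event count. Direction is never asserted; scenarios are bookkeeping only.

Events are dated with the strict-clock formula ``T = k / (2 r)`` where ``k``
is the event's minimum significant pairwise dS and ``r`` a synonymous rate
calibrated from the mean reference-gene dS of a species pair of known age.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .core_io import SpeciesTree
from .htt_detection import PairSignal, ReferenceSet

logger = logging.getLogger("httflow")

#: two dS values count as "similar" (ancestral scenario admissible) when
#: their absolute difference is at most this fraction of the larger one
SIMILAR_DS_REL_TOL = 0.10


class CannotResolveError(ValueError):
    """Scenario enumeration failed (missing dS or species not in tree)."""


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class Scenario:
    """One hypothesized donor/acceptor configuration of an event.

    Weights sum to 2 per hypothesized direction; the undirected two-species
    scenario covers both directions at once and carries weight 2 per species.
    """

    description: str
    weights: dict[str, float]


@dataclass
class EventGroup:
    """All signals of one TE family, split into significant / vertical pairs."""

    family: str
    superfamily: str
    order: str
    significant: dict[tuple[str, str], float]  # pair -> dS
    vertical: set[tuple[str, str]]  # tested, non-significant pairs

    @property
    def species(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.significant:
            out.update((a, b))
        return out


@dataclass
class HTTEvent:
    """A weighted HTT event; per-species weights across scenarios sum to 4."""

    family: str
    superfamily: str
    order: str
    species: set[str]
    scenarios: list[Scenario]
    weights: dict[str, float]
    min_ds: float
    significant_pairs: set[tuple[str, str]] = field(default_factory=set)
    date: float | None = None
    ambiguous: bool = False
    generalized: bool = False

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if not math.isclose(total, 4.0, abs_tol=1e-9):
            raise ValueError(f"{self.family}: event weights sum to {total}, not 4")


@dataclass
class RateCalibration:
    """Synonymous substitution rate from a dated calibration pair."""

    species_pair: tuple[str, str]
    calibration_age: float
    mean_ds: float
    rate: float = field(init=False)

    def __post_init__(self) -> None:
        if self.calibration_age <= 0:
            raise ValueError("calibration age must be positive")
        self.rate = self.mean_ds / (2.0 * self.calibration_age)
        if self.rate == 0:
            logger.warning("calibration dS is 0: rate is 0, dating impossible")


def group_signals(signals: list[PairSignal]) -> list[EventGroup]:
    """Group signals by (family, superfamily); one group per putative event.

    A group's species set is the union of species in its significant pairs;
    groups without any significant pair are dropped.
    """
    by_family: dict[tuple[str, str], EventGroup] = {}
    for s in signals:
        key = (s.family, s.superfamily)
        g = by_family.setdefault(
            key,
            EventGroup(
                family=s.family, superfamily=s.superfamily, order=s.order,
                significant={}, vertical=set(),
            ),
        )
        pair = _pair_key(*s.species_pair)
        if s.significant:
            g.significant[pair] = s.ds
        else:
            g.vertical.add(pair)
    return [
        g for _, g in sorted(by_family.items()) if g.significant
    ]


def _ancestral_candidates(
    group: EventGroup, tree: SpeciesTree, similar_tol: float
) -> list[tuple[frozenset[str], str, float]]:
    """(clade, external partner, min dS) triples admissible for scenario (b).

    A clade qualifies when all its internal pairs are vertical
    (non-significant), it is monophyletic in the species tree, and one
    external species has significant signals of similar dS to every member.
    """
    species = sorted(group.species)
    out = []
    for size in range(2, len(species)):
        for clade in itertools.combinations(species, size):
            cset = set(clade)
            internal = [_pair_key(a, b) for a, b in itertools.combinations(clade, 2)]
            if any(p in group.significant for p in internal):
                continue
            if not all(p in group.vertical for p in internal):
                continue  # untested pairs cannot support vertical inheritance
            if not tree.is_clade(cset):
                continue
            for ext in species:
                if ext in cset:
                    continue
                ds_values = []
                for member in clade:
                    p = _pair_key(ext, member)
                    if p not in group.significant:
                        break
                    ds_values.append(group.significant[p])
                else:
                    dmax = max(ds_values)
                    if dmax > 0 and (dmax - min(ds_values)) > similar_tol * dmax:
                        continue
                    out.append((frozenset(cset), ext, min(ds_values)))
    return out


def enumerate_scenarios(
    group: EventGroup,
    tree: SpeciesTree,
    similar_tol: float = SIMILAR_DS_REL_TOL,
) -> HTTEvent:
    """Build the weighted event for one signal group (total weight 4)."""
    species = sorted(group.species)
    if len(species) < 2:
        raise CannotResolveError(f"{group.family}: fewer than two species")
    for sp in species:
        if sp not in tree.taxa:
            raise CannotResolveError(f"{group.family}: {sp!r} not in species tree")
    for pair, ds in group.significant.items():
        if not math.isfinite(ds):
            raise CannotResolveError(f"{group.family}: dS missing for pair {pair}")
    min_ds = min(group.significant.values())

    if len(species) == 2:
        a, b = species
        scenario = Scenario(
            description=f"undirected transfer between {a} and {b}",
            weights={a: 2.0, b: 2.0},
        )
        return HTTEvent(
            family=group.family, superfamily=group.superfamily,
            order=group.order, species=set(species), scenarios=[scenario],
            weights={a: 2.0, b: 2.0}, min_ds=min_ds,
            significant_pairs=set(group.significant),
        )

    # scenario (a): direct transfer between the lowest-dS significant pair
    by_ds = sorted(group.significant.items(), key=lambda kv: (kv[1], kv[0]))
    (pa, pb), _ = by_ds[0]
    scenario_a = Scenario(
        description=f"direct transfer between {pa} and {pb} (lowest dS)",
        weights={pa: 1.0, pb: 1.0},
    )

    candidates = _ancestral_candidates(group, tree, similar_tol)
    ambiguous = len(candidates) > 1
    if ambiguous:
        logger.info(
            "%s: %d equally admissible ancestral scenarios; keeping the "
            "best-supported (lowest dS, then lexicographic)",
            group.family, len(candidates),
        )
    if candidates:
        candidates.sort(key=lambda c: (c[2], c[1], tuple(sorted(c[0]))))
        clade, ext, _ = candidates[0]
        share = 1.0 / len(clade)
        weights_b = {m: share for m in sorted(clade)}
        weights_b[ext] = 1.0
        scenario_b = Scenario(
            description=(
                f"transfer involving {ext} and the ancestor of "
                f"{{{', '.join(sorted(clade))}}}"
            ),
            weights=weights_b,
        )
    else:
        # no admissible ancestral configuration: second-best direct pair
        if len(by_ds) < 2:
            raise CannotResolveError(
                f"{group.family}: >2 species but a single significant pair"
            )
        (qa, qb), _ = by_ds[1]
        scenario_b = Scenario(
            description=f"direct transfer between {qa} and {qb} (second-lowest dS)",
            weights={qa: 1.0, qb: 1.0},
        )

    weights: dict[str, float] = {}
    for sc in (scenario_a, scenario_b):
        for sp, w in sc.weights.items():
            weights[sp] = weights.get(sp, 0.0) + w
    return HTTEvent(
        family=group.family, superfamily=group.superfamily, order=group.order,
        species=set(species), scenarios=[scenario_a, scenario_b],
        weights=weights, min_ds=min_ds,
        significant_pairs=set(group.significant),
        ambiguous=ambiguous, generalized=len(species) > 3,
    )


def build_events(
    signals: list[PairSignal],
    tree: SpeciesTree,
    similar_tol: float = SIMILAR_DS_REL_TOL,
) -> list[HTTEvent]:
    """Group signals and enumerate scenarios for every group."""
    events = []
    for group in group_signals(signals):
        events.append(enumerate_scenarios(group, tree, similar_tol=similar_tol))
    return events


def count_events(
    events: list[HTTEvent], species_order: list[str] | None = None
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-species event counts and a superfamily x species-pair matrix.

    Species counts are summed weights divided by four (so each event
    contributes one event in total); the pair matrix counts, per
    superfamily, the events whose significant species pairs include the
    pair.
    """
    species: set[str] = set()
    for ev in events:
        species.update(ev.weights)
    order = species_order or sorted(species)
    counts = pd.Series(0.0, index=order, name="events")
    pair_cols = [
        f"{a}x{b}" for i, a in enumerate(order) for b in order[i + 1 :]
    ]
    pair_of = {
        _pair_key(a, b): f"{a}x{b}"
        for i, a in enumerate(order)
        for b in order[i + 1 :]
    }
    superfamilies = sorted({ev.superfamily for ev in events})
    matrix = pd.DataFrame(0, index=superfamilies, columns=pair_cols, dtype=int)
    for ev in events:
        for sp, w in ev.weights.items():
            counts[sp] += w / 4.0
        for pair in ev.significant_pairs:
            col = pair_of.get(pair)
            if col is not None:
                matrix.loc[ev.superfamily, col] += 1
    return counts, matrix


def calibrate_rate(
    refs: ReferenceSet,
    sp_a: str,
    sp_b: str,
    calibration_age: float = 17.5,
) -> RateCalibration:
    """Rate r = mean reference dS / (2 x calibration age in Mya)."""
    table = [g for g in refs.pair_table(sp_a, sp_b) if not g.saturated]
    if not table:
        raise ValueError(f"no unsaturated reference genes for ({sp_a}, {sp_b})")
    mean_ds = sum(g.ds for g in table) / len(table)
    return RateCalibration(
        species_pair=_pair_key(sp_a, sp_b),
        calibration_age=calibration_age,
        mean_ds=mean_ds,
    )


def date_event(k: float, rate: float) -> float:
    """Strict-clock event age T = k / (2 r) in Mya."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    if k < 0:
        raise ValueError("dS must be non-negative")
    return k / (2.0 * rate)


def date_events(events: list[HTTEvent], rate: float) -> None:
    """Assign ``date`` in place from each event's minimum significant dS."""
    for ev in events:
        ev.date = date_event(ev.min_ds, rate)


def events_frame(events: list[HTTEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        rows.append(
            [
                ev.family, ev.superfamily, ev.order,
                ",".join(sorted(ev.species)),
                ";".join(
                    "+".join(f"{sp}:{w:g}" for sp, w in sorted(sc.weights.items()))
                    for sc in ev.scenarios
                ),
                "+".join(f"{sp}:{w:g}" for sp, w in sorted(ev.weights.items())),
                ev.min_ds, ev.date, ev.ambiguous, ev.generalized,
            ]
        )
    return pd.DataFrame(
        rows,
        columns=[
            "family", "superfamily", "order", "species", "scenarios",
            "weights", "min_ds", "date_mya", "ambiguous", "generalized",
        ],
    )
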