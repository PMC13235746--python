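"""Invasion analysis, assembly-order experiments, and priority effects.

An invader is tested at the resident community's converged equilibrium
with resources frozen (standard adaptive-dynamics practice): it succeeds
when its Liebig growth rate at those concentrations exceeds the dilution
rate.  Assembly experiments inoculate types one at a time at a small
density and re-equilibrate after each arrival; multistability (a priority
effect) is detected by running a canonical battery of arrival orders and
clustering the final states, then verifying that each distinct outcome is
non-invasible by the excluded types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import (
    EXTINCTION_THRESHOLD,
    INOCULUM,
    SWEEP_INOCULUM,
    EquilibriumResult,
    find_equilibrium,
)
from .model import CommunityState, SupplySpec, compute_fluxes
from .traits import TYPES, TraitSet, type_index

__all__ = [
    "InvasionOutcome",
    "AssemblyRecord",
    "MultistabilityResult",
    "invasion_rate",
    "assemble",
    "detect_multistability",
]


@dataclass(frozen=True)
class InvasionOutcome:
    residents: frozenset
    invader: str
    invasion_rate: float  # per-capita growth at the resident equilibrium, d^-1
    success: bool         # invasion_rate > dilution


@dataclass
class AssemblyRecord:
    order: tuple[str, ...]
    history: list[EquilibriumResult] = field(default_factory=list)

    @property
    def final(self) -> EquilibriumResult:
        return self.history[-1]


@dataclass
class MultistabilityResult:
    equilibria: list[EquilibriumResult]   # one representative per cluster
    bistable: bool
    mutually_noninvasible: bool
    records: list[AssemblyRecord]

    @property
    def persistent_sets(self) -> list[frozenset]:
        return [eq.persistent_set for eq in self.equilibria]


def invasion_rate(
    t: TraitSet, resident_eq: EquilibriumResult, invader: int | str
) -> InvasionOutcome:
    """Per-capita growth of a rare invader at a converged resident state."""
    if not resident_eq.converged:
        raise ValueError("invasion analysis requires a converged resident equilibrium")
    ii = type_index(invader) if isinstance(invader, str) else invader
    fr = compute_fluxes(t, resident_eq.state)
    rate = float(fr.mu[ii])
    return InvasionOutcome(
        residents=resident_eq.persistent_set,
        invader=TYPES[ii],
        invasion_rate=rate,
        success=rate > t.dilution,
    )


def assemble(
    t: TraitSet,
    order: tuple[str, ...],
    supply: SupplySpec,
    inoculum: float = INOCULUM,
    **eq_kwargs,
) -> AssemblyRecord:
    """Sequentially inoculate types and re-equilibrate after each arrival.

    Starts from the washout state (B = 0, R = s).  Each arriving type is
    added at the inoculation density; the community is integrated to
    equilibrium before the next arrival.
    """
    if not order:
        raise ValueError("assembly order must list at least one type")
    rec = AssemblyRecord(order=tuple(order))
    state = supply.washout_state()
    for tp in order:
        ii = type_index(tp)
        B = state.B.copy()
        B[ii] += inoculum
        eq = find_equilibrium(t, CommunityState(B, state.R.copy()), supply, **eq_kwargs)
        rec.history.append(eq)
        state = eq.state
    return rec


def _canonical_orders(subsystem: tuple[str, ...]) -> list[tuple[str, ...] | None]:
    """Each member first (rest in index order), plus the all-at-once start."""
    members = tuple(sorted(subsystem, key=type_index))
    orders: list[tuple[str, ...] | None] = []
    for first in members:
        rest = tuple(m for m in members if m != first)
        orders.append((first,) + rest)
    orders.append(None)  # sentinel: simultaneous start
    return orders


def detect_multistability(
    t: TraitSet,
    supply: SupplySpec,
    subsystem: tuple[str, ...],
    state_rtol: float = 1e-4,
    **eq_kwargs,
) -> MultistabilityResult:
    """Run the canonical arrival-order battery and cluster final states.

    Clusters first on the identity of the persistent set (biologically
    distinct outcomes are defined by composition), then on relative state
    distance.  The result is flagged bistable when ≥ 2 clusters remain,
    and each cluster representative is checked for non-invasibility by
    every subsystem type absent from it.
    """
    records: list[AssemblyRecord] = []
    finals: list[EquilibriumResult] = []
    for order in _canonical_orders(tuple(subsystem)):
        if order is None:
            B = np.zeros(7)
            for tp in subsystem:
                B[type_index(tp)] = SWEEP_INOCULUM
            eq = find_equilibrium(
                t, CommunityState(B, supply.s.copy()), supply, **eq_kwargs
            )
            records.append(AssemblyRecord(order=("all",), history=[eq]))
        else:
            rec = assemble(t, order, supply, **eq_kwargs)
            records.append(rec)
            eq = rec.final
        finals.append(eq)

    clusters: list[EquilibriumResult] = []
    for eq in finals:
        if not eq.converged:
            continue
        matched = False
        for rep in clusters:
            if eq.persistent_set != rep.persistent_set:
                continue
            x, y = eq.state.as_vector(), rep.state.as_vector()
            if np.max(np.abs(x - y) / (np.abs(y) + 1e-6)) <= state_rtol:
                matched = True
                break
        if not matched:
            clusters.append(eq)

    noninv = True
    for rep in clusters:
        for tp in subsystem:
            if tp in rep.persistent_set:
                continue
            out = invasion_rate(t, rep, tp)
            if out.invasion_rate > t.dilution + 1e-6:
                noninv = False
    return MultistabilityResult(
        equilibria=clusters,
        bistable=len(clusters) >= 2,
        mutually_noninvasible=noninv,
        records=records,
    )
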