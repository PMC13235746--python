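"""2D OM × NO3- supply-space sweeps: community and nitrogen-loss regimes.

For each point (s1, s2) of a supply grid, the selected subsystem is
started "all present" (every member at 1e-3 μM N, resources at inflow)
and integrated to equilibrium.  Each cell is labelled by its persistent
community (canonical "B1+B3" strings) and by its nitrogen-loss regime:

* ``conserved``            — no gaseous loss; all N stays bioavailable.
* ``N2_only``              — N2 produced, no N2O formation.
* ``N2O_no_consumption``   — N2O produced but no consumer persists: the
  accumulation-potential regime (in the ocean, this N2O may build up or
  be exported).
* ``N2O_cycled_with_N2``   — N2O produced and consumed en route to N2.

Supply axes store the inflow concentrations s_j of the chemostat
(μM N); the corresponding supply *rate* is a·s_j, so plots showing rates
only rescale the axes by the dilution rate.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import SWEEP_INOCULUM, EquilibriumResult, find_equilibrium
from .model import CommunityState, FluxRecord, SupplySpec
from .traits import TYPES, TraitSet, type_index

__all__ = [
    "FLUX_ZERO",
    "NLOSS_LABELS",
    "RegimeCell",
    "RegimeMap",
    "classify_community",
    "classify_nloss",
    "default_axis",
    "run_grid",
    "run_transect",
    "niche_breadth",
]

FLUX_ZERO = 1e-10  # μM N d^-1: fluxes below this count as zero
NLOSS_LABELS = ("conserved", "N2_only", "N2O_no_consumption", "N2O_cycled_with_N2")

DEFAULT_S1 = (0.05, 30.0)
DEFAULT_S2 = (0.05, 30.0)
DEFAULT_N = 61


def default_axis(lo: float = 0.05, hi: float = 30.0, n: int = DEFAULT_N) -> np.ndarray:
    """Default supply axis: log-spaced so that supply *ratios* — which
    organize the regimes — are sampled evenly, and the subsistence corner
    at low joint supply is resolved."""
    return np.geomspace(lo, hi, n)


def classify_community(
    eq: EquilibriumResult | None = None,
    persistent_sets: list[frozenset] | None = None,
) -> str:
    """Canonical community label: "B1+B3", "none", "nonstationary", or
    "bistable:{B1+B3|B2}" for multiple coexisting attractors."""

    def label(s: frozenset) -> str:
        if not s:
            return "none"
        return "+".join(sorted(s, key=type_index))

    if persistent_sets is not None:
        uniq = sorted({label(s) for s in persistent_sets})
        if len(uniq) == 1:
            return uniq[0]
        return "bistable:{" + "|".join(uniq) + "}"
    if eq is None:
        raise ValueError("provide an equilibrium or a list of persistent sets")
    if not eq.converged:
        return "nonstationary"
    return label(eq.persistent_set)


def classify_nloss(fluxes: FluxRecord, tol: float = FLUX_ZERO) -> str:
    """Nitrogen-loss regime from the equilibrium gas fluxes."""
    n2 = fluxes.gas_n2 > tol
    prod = fluxes.gas_n2o_prod > tol
    cons = fluxes.gas_n2o_cons > tol
    if not n2 and not prod:
        return "conserved"
    if n2 and not prod:
        return "N2_only"
    if prod and not cons:
        return "N2O_no_consumption"
    return "N2O_cycled_with_N2"


@dataclass
class RegimeCell:
    s1: float
    s2: float
    community_label: str
    nloss_label: str
    n2_flux: float
    net_n2o_flux: float  # production minus consumption, μM N d^-1
    persistent: np.ndarray
    converged: bool


@dataclass
class RegimeMap:
    """Grid of supply points with community and nitrogen-loss labels."""

    s1_values: np.ndarray
    s2_values: np.ndarray
    cells: list  # row-major list of RegimeCell, s2 outer, s1 inner
    subsystem: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def cell(self, i2: int, i1: int) -> RegimeCell:
        return self.cells[i2 * len(self.s1_values) + i1]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            row = {
                "s1": c.s1, "s2": c.s2,
                "community_label": c.community_label,
                "nloss_label": c.nloss_label,
                "N2_flux": c.n2_flux, "netN2O_flux": c.net_n2o_flux,
                "converged": c.converged,
            }
            for k, tp in enumerate(TYPES):
                row[tp] = bool(c.persistent[k])
            rows.append(row)
        return pd.DataFrame(rows)

    def export(self, directory: str | Path, stem: str = "regime_map") -> None:
        """Write the long-format table plus a JSON metadata sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(directory / f"{stem}.csv", index=False)
        with open(directory / f"{stem}.meta.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, default=str)


def _trait_hash(t: TraitSet) -> str:
    h = hashlib.sha256()
    for arr in (t.vmax, t.K, t.y, t.usage.astype(float)):
        h.update(np.nan_to_num(arr).tobytes())
    h.update(repr((t.dilution, t.nh4_fraction)).encode())
    return h.hexdigest()[:16]


def run_grid(
    t: TraitSet,
    subsystem: tuple[str, ...],
    s1_values: np.ndarray | None = None,
    s2_values: np.ndarray | None = None,
    detect_bistability: bool = False,
    **eq_kwargs,
) -> RegimeMap:
    """Sweep the OM × NO3- supply grid for a subsystem.

    Each cell starts from the all-present state.  With
    ``detect_bistability=True`` every cell additionally runs the
    assembly-order battery (≈ 8× cost) and bistable cells are labelled
    ``bistable:{...}``.  Solver failures are recorded as nonstationary
    cells, never fatal.  Deterministic given identical settings.
    """
    from .assembly import detect_multistability  # local: avoid import cycle

    if s1_values is None:
        s1_values = default_axis(*DEFAULT_S1)
    if s2_values is None:
        s2_values = default_axis(*DEFAULT_S2)
    s1_values = np.asarray(s1_values, dtype=float)
    s2_values = np.asarray(s2_values, dtype=float)
    members = [type_index(tp) for tp in subsystem]

    cells: list[RegimeCell] = []
    for s2 in s2_values:
        for s1 in s1_values:
            supply = SupplySpec.om_no3(s1, s2)
            B = np.zeros(7)
            B[members] = SWEEP_INOCULUM
            init = CommunityState(B, supply.s.copy())
            try:
                eq = find_equilibrium(t, init, supply, **eq_kwargs)
            except Exception as err:  # record, don't abort the sweep
                cells.append(RegimeCell(s1, s2, "nonstationary", "conserved",
                                        np.nan, np.nan, np.zeros(7, bool), False))
                cells[-1].community_label = f"error:{type(err).__name__}"
                continue
            label = classify_community(eq)
            if detect_bistability and eq.converged:
                ms = detect_multistability(t, supply, tuple(subsystem), **eq_kwargs)
                if ms.bistable:
                    label = classify_community(persistent_sets=ms.persistent_sets)
            cells.append(
                RegimeCell(
                    s1=float(s1), s2=float(s2),
                    community_label=label,
                    nloss_label=classify_nloss(eq.fluxes),
                    n2_flux=eq.fluxes.gas_n2,
                    net_n2o_flux=eq.fluxes.gas_n2o_prod - eq.fluxes.gas_n2o_cons,
                    persistent=eq.persistent.copy(),
                    converged=eq.converged,
                )
            )
    return RegimeMap(
        s1_values=s1_values, s2_values=s2_values, cells=cells,
        subsystem=tuple(subsystem),
        metadata={
            "trait_hash": _trait_hash(t),
            "dilution": t.dilution,
            "subsystem": list(subsystem),
            "grid": [len(s1_values), len(s2_values)],
            "s1_range": [float(s1_values[0]), float(s1_values[-1])],
            "s2_range": [float(s2_values[0]), float(s2_values[-1])],
            "detect_bistability": detect_bistability,
            "eq_kwargs": dict(eq_kwargs),
        },
    )


def run_transect(
    t: TraitSet,
    subsystem: tuple[str, ...],
    s1_values: np.ndarray,
    s2: float,
    **kwargs,
) -> RegimeMap:
    """One fixed-s2 row of the supply grid."""
    return run_grid(t, subsystem, s1_values=s1_values, s2_values=np.array([s2]), **kwargs)


def niche_breadth(regime_map: RegimeMap, i: int | str) -> float:
    """Fraction of converged grid cells where type i persists.

    Bistable cells count when the type appears in any branch (persistence
    flags are taken from the all-present equilibrium; the branch union is
    reflected in the cell label).
    """
    ii = type_index(i) if isinstance(i, str) else i
    tp = TYPES[ii]
    conv = [c for c in regime_map.cells if c.converged]
    if not conv:
        return 0.0
    n = 0
    for c in conv:
        if c.community_label.startswith("bistable:"):
            inside = c.community_label[len("bistable:{"):-1]
            present = any(tp in branch.split("+") for branch in inside.split("|"))
            n += int(present or bool(c.persistent[ii]))
        else:
            n += int(bool(c.persistent[ii]))
    return n / len(conv)
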