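"""Physiological trait parameterization of the anaerobic N-cycling guild.

Seven microbial functional types interact through five dissolved nitrogen
pools in a virtual chemostat:

====  ==================  =========================================
type  transformation      role
====  ==================  =========================================
B1    NO3- -> NO2-        heterotrophic nitrate reducer (feeder)
B2    NO3- -> N2O         heterotrophic incomplete denitrifier
B3    NO2- -> N2          heterotrophic nitrite reducer (recipient)
B4    N2O  -> N2          heterotrophic N2O reducer (recipient)
B5    anammox             autotroph: NH4+ + NO2- -> N2
B6    NO2- -> N2O         heterotrophic nitrite reducer
B7    NO3- -> N2          complete denitrifier
====  ==================  =========================================

Resources (all in μM of nitrogen atoms): OM (organic matter nitrogen),
NO3-, NO2-, N2O (N-atom units), NH4+.  Each type requires two essential,
non-substitutable resources: an electron donor (OM, or NH4+ for anammox)
and an electron acceptor.  A trait set holds, for every used
(type, resource) pair, the maximal specific uptake rate ``vmax``
(mol resource-N per mol biomass-N per day), the half-saturation
concentration ``K`` (μM N), and the biomass yield ``y``
(mol biomass-N per mol resource-N), plus the chemostat dilution rate
``dilution`` (per day).

The built-in fixture carries the literature parameterization of this
guild; the default dilution rate 0.04 / d is the value that makes the
subsistence concentrations K·a/(y·Vm − a) consistent with the published
subsistence column (published yields are rounded, so back-computed
subsistence values agree to a few percent, not exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "RESOURCES",
    "TYPES",
    "TYPE_REACTIONS",
    "HETEROTROPHS",
    "PRODUCT_ROUTES",
    "TraitSet",
    "builtin_trait_fixture",
    "load_trait_table",
    "write_trait_table",
    "validate_traits",
    "resource_index",
    "type_index",
]

RESOURCES: tuple[str, ...] = ("OM", "NO3", "NO2", "N2O", "NH4")
TYPES: tuple[str, ...] = ("B1", "B2", "B3", "B4", "B5", "B6", "B7")

TYPE_REACTIONS: dict[str, str] = {
    "B1": "NO3->NO2",
    "B2": "NO3->N2O",
    "B3": "NO2->N2",
    "B4": "N2O->N2",
    "B5": "anammox",
    "B6": "NO2->N2O",
    "B7": "NO3->N2",
}

#: heterotrophs use OM as electron donor and remineralize NH4+
HETEROTROPHS: tuple[str, ...] = ("B1", "B2", "B3", "B4", "B6", "B7")

#: feeder excretion routes: type -> (acceptor consumed, product excreted).
#: All acceptor-N taken up by these types reappears as the tracked product;
#: the other types route their acceptor-N to N2 gas (B5 additionally routes
#: the non-assimilated fraction of both substrates to N2).
PRODUCT_ROUTES: dict[str, tuple[str, str]] = {
    "B1": ("NO3", "NO2"),
    "B2": ("NO3", "N2O"),
    "B6": ("NO2", "N2O"),
}

# canonical resource-usage matrix (rows = B1..B7, columns = OM..NH4)
_USAGE = np.array(
    [
        [1, 1, 0, 0, 0],  # B1: OM + NO3
        [1, 1, 0, 0, 0],  # B2: OM + NO3
        [1, 0, 1, 0, 0],  # B3: OM + NO2
        [1, 0, 0, 1, 0],  # B4: OM + N2O
        [0, 0, 1, 0, 1],  # B5: NO2 + NH4 (anammox)
        [1, 0, 1, 0, 0],  # B6: OM + NO2
        [1, 1, 0, 0, 0],  # B7: OM + NO3
    ],
    dtype=bool,
)

# (type, resource, vmax, yield, K) — the built-in guild parameterization
_FIXTURE_ROWS: tuple[tuple[str, str, float, float, float], ...] = (
    ("B1", "OM", 1.377, 0.15, 0.1),
    ("B1", "NO3", 50.8, 0.011, 4.0),
    ("B2", "OM", 1.377, 0.148, 0.1),
    ("B2", "NO3", 50.8, 0.023, 4.0),
    ("B3", "OM", 1.377, 0.197, 0.1),
    ("B3", "NO2", 50.8, 0.024, 4.0),
    ("B4", "OM", 1.377, 0.298, 0.1),
    ("B4", "N2O", 50.8, 0.013, 0.6),
    ("B5", "NH4", 50.8, 0.013, 0.45),
    ("B5", "NO2", 50.8, 0.011, 0.45),
    ("B6", "OM", 1.377, 0.201, 0.1),
    ("B6", "NO2", 50.8, 0.016, 4.0),
    ("B7", "OM", 1.377, 0.138, 0.1),
    ("B7", "NO3", 50.8, 0.026, 4.0),
)

#: published subsistence-concentration column (μM N) for the fixture,
#: kept for validation and documentation; computed values are always
#: derived from the kinetic parameters.
PUBLISHED_RSTAR: dict[tuple[str, str], float] = {
    ("B1", "OM"): 0.024,
    ("B1", "NO3"): 0.295,
    ("B2", "OM"): 0.0245,
    ("B2", "NO3"): 0.144,
    ("B3", "OM"): 0.0172,
    ("B3", "NO2"): 0.138,
    ("B4", "OM"): 0.0108,
    ("B4", "N2O"): 0.039,
    ("B5", "NH4"): 0.028,
    ("B5", "NO2"): 0.034,
    ("B6", "OM"): 0.0169,
    ("B6", "NO2"): 0.2066,
    ("B7", "OM"): 0.0268,
    ("B7", "NO3"): 0.124,
}

DEFAULT_DILUTION = 0.04  # d^-1


def resource_index(name: str) -> int:
    """Column index of a resource name (case-insensitive)."""
    try:
        return RESOURCES.index(name.upper().replace("+", "").replace("-", ""))
    except ValueError:
        raise KeyError(f"unknown resource {name!r}; expected one of {RESOURCES}") from None


def type_index(name: str) -> int:
    """Row index of a functional-type name ('B1'..'B7')."""
    try:
        return TYPES.index(name.upper())
    except ValueError:
        raise KeyError(f"unknown functional type {name!r}; expected one of {TYPES}") from None


@dataclass(frozen=True)
class TraitSet:
    """All physiological parameters of the community.

    Arrays are 7×5 (type × resource); entries where ``usage`` is False are
    NaN.  ``dilution`` is the chemostat dilution rate in d⁻¹.
    """

    vmax: np.ndarray
    K: np.ndarray
    y: np.ndarray
    usage: np.ndarray
    dilution: float = DEFAULT_DILUTION
    nh4_fraction: float = field(default=1.0)
    """Scalar multiplier on the NH4+ remineralization closure (sensitivity knob)."""

    def __post_init__(self) -> None:
        for name in ("vmax", "K", "y"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (7, 5):
                raise ValueError(f"{name} must be 7x5, got {arr.shape}")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "usage", np.asarray(self.usage, dtype=bool))

    def used_pairs(self) -> Iterator[tuple[str, str]]:
        for i, t in enumerate(TYPES):
            for j, r in enumerate(RESOURCES):
                if self.usage[i, j]:
                    yield t, r

    def with_dilution(self, a: float) -> "TraitSet":
        return replace(self, dilution=float(a))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with one row per used (type, resource) pair."""
        rows = []
        for t, r in self.used_pairs():
            i, j = type_index(t), resource_index(r)
            rows.append(
                {"type": t, "resource": r, "vmax": self.vmax[i, j],
                 "K": self.K[i, j], "yield": self.y[i, j]}
            )
        return pd.DataFrame(rows)

    def __eq__(self, other: object) -> bool:  # value equality, NaN-aware
        if not isinstance(other, TraitSet):
            return NotImplemented
        same = (
            np.array_equal(self.usage, other.usage)
            and self.dilution == other.dilution
            and self.nh4_fraction == other.nh4_fraction
        )
        if not same:
            return False
        m = self.usage
        return all(
            np.array_equal(getattr(self, n)[m], getattr(other, n)[m])
            for n in ("vmax", "K", "y")
        )


def _build(rows, usage, dilution) -> TraitSet:
    vmax = np.full((7, 5), np.nan)
    K = np.full((7, 5), np.nan)
    y = np.full((7, 5), np.nan)
    for t, r, v, yy, k in rows:
        i, j = type_index(t), resource_index(r)
        vmax[i, j], y[i, j], K[i, j] = v, yy, k
    return TraitSet(vmax=vmax, K=K, y=y, usage=usage, dilution=dilution)


def builtin_trait_fixture(dilution: float = DEFAULT_DILUTION) -> TraitSet:
    """The built-in guild parameterization (14 used type×resource pairs)."""
    return _build(_FIXTURE_ROWS, _USAGE.copy(), dilution)


def validate_traits(t: TraitSet) -> list[str]:
    """Check trait-set invariants; returns a list of violation messages.

    An empty list means the trait set is internally consistent:
    parameters are strictly positive exactly on the used pairs, anammox
    (B5) does not use OM, and every used pair satisfies the persistence
    condition a < y·Vm (otherwise the subsistence concentration is
    undefined and the population can never balance dilution).
    """
    v: list[str] = []
    if t.usage.shape != (7, 5):
        return [f"usage matrix must be 7x5, got {t.usage.shape}"]
    if t.usage[type_index("B5"), resource_index("OM")]:
        v.append("B5 must not use OM (anammox is the only non-heterotroph)")
    for i, tp in enumerate(TYPES):
        if t.usage[i].sum() != 2:
            v.append(f"{tp} must use exactly two essential resources, uses {int(t.usage[i].sum())}")
    for i, tp in enumerate(TYPES):
        for j, r in enumerate(RESOURCES):
            if t.usage[i, j]:
                for name in ("vmax", "K", "y"):
                    x = getattr(t, name)[i, j]
                    if not np.isfinite(x) or x <= 0:
                        v.append(f"({tp}, {r}): {name} must be strictly positive, got {x}")
                if np.isfinite(t.y[i, j]) and np.isfinite(t.vmax[i, j]):
                    if t.dilution >= t.y[i, j] * t.vmax[i, j]:
                        v.append(
                            f"({tp}, {r}): dilution a={t.dilution} >= y*Vm="
                            f"{t.y[i, j] * t.vmax[i, j]:.6g}; subsistence concentration "
                            "is undefined and the population cannot persist"
                        )
            else:
                for name in ("vmax", "K", "y"):
                    if np.isfinite(getattr(t, name)[i, j]):
                        v.append(f"({tp}, {r}): {name} defined but pair is unused")
    if t.dilution < 0:
        v.append(f"dilution must be non-negative, got {t.dilution}")
    return v


def write_trait_table(t: TraitSet, path: str | Path) -> None:
    """Write the long-format trait CSV (columns type,resource,vmax,K,yield).

    Floats are written with repr-style shortest round-trip formatting so a
    write/load cycle is bit-identical.
    """
    df = t.to_frame()
    with open(path, "w") as fh:
        fh.write("type,resource,vmax,K,yield\n")
        for _, row in df.iterrows():
            fh.write(
                f"{row['type']},{row['resource']},{row['vmax']!r},"
                f"{row['K']!r},{row['yield']!r}\n"
            )


def load_trait_table(path: str | Path, dilution: float = DEFAULT_DILUTION) -> TraitSet:
    """Load a trait CSV written by :func:`write_trait_table`.

    Raises ``ValueError`` naming the offending row on a missing column,
    duplicate (type, resource) pair, non-positive parameter, or a pair
    violating the persistence condition a < y·Vm.
    """
    df = pd.read_csv(path)
    required = {"type", "resource", "vmax", "K", "yield"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trait table {path}: missing column(s) {sorted(missing)}")
    seen: set[tuple[str, str]] = set()
    usage = np.zeros((7, 5), dtype=bool)
    rows = []
    for n, row in df.iterrows():
        key = (str(row["type"]).upper(), str(row["resource"]).upper())
        if key in seen:
            raise ValueError(f"trait table {path}, row {n}: duplicate pair {key}")
        seen.add(key)
        i, j = type_index(key[0]), resource_index(key[1])
        for col in ("vmax", "K", "yield"):
            if not np.isfinite(row[col]) or row[col] <= 0:
                raise ValueError(
                    f"trait table {path}, row {n} ({key[0]}, {key[1]}): "
                    f"{col}={row[col]} must be strictly positive"
                )
        if dilution >= row["yield"] * row["vmax"]:
            raise ValueError(
                f"trait table {path}, row {n} ({key[0]}, {key[1]}): "
                f"a={dilution} >= y*Vm={row['yield'] * row['vmax']:.6g} violates the "
                "persistence condition a < y*Vm (subsistence concentration undefined)"
            )
        usage[i, j] = True
        rows.append((key[0], key[1], float(row["vmax"]), float(row["yield"]), float(row["K"])))
    t = _build(rows, usage, dilution)
    problems = validate_traits(t)
    if problems:
        raise ValueError(f"trait table {path}: " + "; ".join(problems))
    return t
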