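"""Closed-form resource-ratio analysis: R*, consumption vectors, ZNGIs.

The subsistence concentration of type i on resource j,

    R*_ij = K_ij a / (y_ij Vm_ij − a),

is the concentration at which growth on j exactly balances dilution; the
population with the lowest R* wins pairwise competition when that
resource limits.  For a heterotroph using OM and one nitrogen acceptor,
the consumption vector

    c_i = y_i,OM / y_i,acceptor

is the ratio of acceptor-N to OM-N drawn down per unit growth (the slope
of the depletion trajectory in the acceptor-vs-OM plane).  A tightly
coupled feeder–recipient pair (the recipient consumes the feeder's
excreted acceptor plus OM) consumes with the composite vector

    c_pair = c_feeder / (1 + c_feeder / c_recipient),

always shallower (more OM-intensive) than the feeder alone.  A recipient
can invade only once its feeder's equilibrium biomass exceeds the
threshold  a · y_feeder,acceptor / μ_recipient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traits import (
    PRODUCT_ROUTES,
    RESOURCES,
    TYPES,
    TraitSet,
    resource_index,
    type_index,
)

__all__ = [
    "subsistence_concentration",
    "rstar_table",
    "ConsumptionVector",
    "consumption_vector",
    "consortium_consumption_vector",
    "feeder_threshold_biomass",
    "ZNGIPolyline",
    "zngi",
    "anammox_supply_zngi",
]

_ACCEPTORS = ("NO3", "NO2", "N2O")


class NonPersistenceError(ValueError):
    """Raised when a ≥ y·Vm and the subsistence concentration is undefined."""


def subsistence_concentration(t: TraitSet, i: int | str, j: int | str) -> float:
    """R*_ij = K a/(y Vm − a), μM N; 0 when a = 0; error when a ≥ y Vm."""
    ii = type_index(i) if isinstance(i, str) else i
    jj = resource_index(j) if isinstance(j, str) else j
    if not t.usage[ii, jj]:
        raise ValueError(f"{TYPES[ii]} does not use {RESOURCES[jj]}")
    a = t.dilution
    if a == 0:
        return 0.0
    denom = t.y[ii, jj] * t.vmax[ii, jj] - a
    if denom <= 0:
        raise NonPersistenceError(
            f"({TYPES[ii]}, {RESOURCES[jj]}): a={a} >= y*Vm="
            f"{t.y[ii, jj] * t.vmax[ii, jj]:.6g}; no concentration can sustain growth"
        )
    return float(t.K[ii, jj] * a / denom)


def rstar_table(t: TraitSet) -> pd.DataFrame:
    """Subsistence concentrations for every used (type, resource) pair."""
    rows = [
        {"type": tp, "resource": r,
         "rstar": subsistence_concentration(t, tp, r)}
        for tp, r in t.used_pairs()
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ConsumptionVector:
    """Acceptor-N consumed per OM-N consumed (= y_OM / y_acceptor).

    Note the orientation: although written as a ratio of yields with OM on
    top, the number measures how much *acceptor* is drawn down per unit of
    OM, because per-biomass uptake is μ/y.  B1's value ≈ 13.6 means each
    μmol of OM-N consumed pulls down ≈ 13.6 μmol of NO3-N.
    """

    value: float
    members: tuple[str, ...]


def _acceptor_of(t: TraitSet, ii: int) -> int:
    used = [j for j in np.flatnonzero(t.usage[ii]) if RESOURCES[j] in _ACCEPTORS]
    if len(used) != 1 or not t.usage[ii, resource_index("OM")]:
        raise ValueError(
            f"{TYPES[ii]} does not use OM plus exactly one N acceptor; "
            "consumption vectors are defined for heterotrophic denitrifier modules only"
        )
    return int(used[0])


def consumption_vector(t: TraitSet, i: int | str) -> ConsumptionVector:
    """c_i = y_OM / y_acceptor for a heterotroph using OM + one acceptor."""
    ii = type_index(i) if isinstance(i, str) else i
    jacc = _acceptor_of(t, ii)
    jom = resource_index("OM")
    return ConsumptionVector(
        value=float(t.y[ii, jom] / t.y[ii, jacc]), members=(TYPES[ii],)
    )


def _check_dependency(t: TraitSet, fi: int, ri: int) -> None:
    tp = TYPES[fi]
    if tp not in PRODUCT_ROUTES:
        raise ValueError(f"{tp} excretes no tracked nitrogen product; it cannot feed")
    product = PRODUCT_ROUTES[tp][1]
    if not t.usage[ri, resource_index(product)]:
        raise ValueError(
            f"{TYPES[ri]} does not consume {product}, the product of {tp}; "
            "not a feeder-recipient pair"
        )


def consortium_consumption_vector(
    t: TraitSet, feeder: int | str, recipient: int | str
) -> ConsumptionVector:
    """Composite vector of a feeder–recipient pair, c_f / (1 + c_f/c_r).

    Defined when the recipient consumes the feeder's excreted acceptor
    plus OM (e.g. B1→B3 via NO2-, B2→B4 via N2O).  Always strictly below
    the feeder's own vector: the pair consumes relatively more OM.
    """
    fi = type_index(feeder) if isinstance(feeder, str) else feeder
    ri = type_index(recipient) if isinstance(recipient, str) else recipient
    _check_dependency(t, fi, ri)
    cf = consumption_vector(t, fi).value
    cr = consumption_vector(t, ri).value
    return ConsumptionVector(
        value=float(cf / (1.0 + cf / cr)), members=(TYPES[fi], TYPES[ri])
    )


def feeder_threshold_biomass(
    t: TraitSet, feeder: int | str, recipient: int | str, mu_recipient: float
) -> float:
    """Minimum feeder equilibrium biomass sustaining a recipient (μM N).

    threshold = a · y_feeder,acceptor / μ_recipient.  The recipient must
    consume the feeder's excreted product (for anammox, B1's NO2-).
    """
    fi = type_index(feeder) if isinstance(feeder, str) else feeder
    ri = type_index(recipient) if isinstance(recipient, str) else recipient
    if mu_recipient <= 0:
        raise ValueError(f"recipient growth rate must be positive, got {mu_recipient}")
    tp = TYPES[fi]
    if tp not in PRODUCT_ROUTES:
        raise ValueError(f"{tp} excretes no tracked nitrogen product; it cannot feed")
    acc, product = PRODUCT_ROUTES[tp]
    if not t.usage[ri, resource_index(product)]:
        raise ValueError(
            f"{TYPES[ri]} does not consume {product}, the product of {tp}"
        )
    return float(t.dilution * t.y[fi, resource_index(acc)] / mu_recipient)


@dataclass(frozen=True)
class ZNGIPolyline:
    """A zero-net-growth isocline traced as an ordered polyline."""

    axes: tuple[str, str]
    vertices: np.ndarray  # (n, 2)
    type_name: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.vertices, columns=list(self.axes))


def zngi(
    t: TraitSet, i: int | str, axes: tuple[str, str], extent: float = 30.0
) -> ZNGIPolyline:
    """L-shaped ZNGI of a type over two resources it uses.

    For two essential resources the isocline is the corner at
    (R*_x, R*_y): growth balances dilution along both arms, and the
    population grows only in the quadrant above/right of the corner.
    """
    ii = type_index(i) if isinstance(i, str) else i
    jx, jy = (resource_index(ax) for ax in axes)
    for jj in (jx, jy):
        if not t.usage[ii, jj]:
            raise ValueError(f"{TYPES[ii]} does not use {RESOURCES[jj]}")
    rx = subsistence_concentration(t, ii, jx)
    ry = subsistence_concentration(t, ii, jy)
    verts = np.array([[rx, extent], [rx, ry], [extent, ry]])
    return ZNGIPolyline(axes=(RESOURCES[jx], RESOURCES[jy]), vertices=verts,
                        type_name=TYPES[ii])


def anammox_supply_zngi(
    t: TraitSet,
    s2_values: np.ndarray,
    s1_max: float = 30.0,
    xtol: float = 1e-6,
) -> ZNGIPolyline:
    """Anammox persistence boundary in the (OM, NO3-) *supply* plane.

    Anammox (B5) uses neither OM nor NO3- directly, but depends on NO2-
    excreted by B1, so its effective supply-space isocline is the curve
    where the B1 single-species equilibrium biomass first reaches the
    feeder threshold a·y(B1,NO3)/μ5 with μ5 = a (recipient at equilibrium).
    Located by bisection on s1 at each fixed s2 using the closed-form B1
    equilibrium.  The curve lies strictly above B1's own persistence
    boundary: anammox needs B1 not merely present but sufficiently dense.
    """
    from .dynamics import single_species_closed_form  # local: avoid cycle
    from .model import SupplySpec

    i1 = type_index("B1")
    thresh = feeder_threshold_biomass(t, "B1", "B5", t.dilution)

    def b1hat(s1: float, s2: float) -> float:
        st = single_species_closed_form(t, i1, SupplySpec.om_no3(s1, s2))
        return float(st.B[i1])

    pts = []
    for s2 in np.atleast_1d(s2_values):
        lo, hi = 0.0, s1_max
        if b1hat(hi, s2) < thresh:
            continue  # boundary outside the domain at this s2
        while hi - lo > xtol:
            mid = 0.5 * (lo + hi)
            if b1hat(mid, s2) >= thresh:
                hi = mid
            else:
                lo = mid
        pts.append([0.5 * (lo + hi), float(s2)])
    return ZNGIPolyline(axes=("OM", "NO3"), vertices=np.array(pts), type_name="B5")
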