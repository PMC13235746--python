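"""Instantaneous chemostat model: growth, uptake, excretion, gas fluxes.

State is (B, R): seven biomasses and five resource concentrations, all in
μM N.  Dynamics:

    dB_i/dt = (μ_i − a) B_i
    dR_j/dt = a (s_j − R_j) + Σ_i E_ij B_i − Σ_i V^r_ij B_i

Growth follows Liebig's law of the minimum over the two essential
resources of each type.  The potential growth rate on resource j is
μ_ij = y_ij Vm_ij R_j/(R_j + K_ij); the realized growth rate is
μ_i = min_j μ_ij and realized uptake of every used resource is slaved to
it, V^r_ij = μ_i / y_ij.

Excretion routes (per-biomass rates):

* B1 excretes NO2- at μ1/y(B1,NO3): all reduced nitrate-N.
* B2 and B6 excrete N2O at μ/y(acceptor): all reduced acceptor-N.
* every heterotroph remineralizes NH4+ at e = μ (1/y_OM − 1), the
  nitrogen-balance closure: OM-N uptake = biomass synthesis + NH4+
  release.  With the built-in yields this makes NH4+ regeneration
  70%–86% of OM-N uptake.
* anammox (B5) excretes nothing; its non-assimilated substrate N leaves
  as N2.

N2 (and only N2) leaves the nitrogen budget; N2O is a tracked pool, so
"N2O production" and "N2O consumption" are internal fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .traits import (
    HETEROTROPHS,
    PRODUCT_ROUTES,
    RESOURCES,
    TYPES,
    TraitSet,
    resource_index,
    type_index,
)

__all__ = [
    "CommunityState",
    "SupplySpec",
    "FluxRecord",
    "compute_fluxes",
    "potential_growth",
    "realized_growth",
    "excretion_fluxes",
    "gas_fluxes",
    "rhs",
    "rhs_vector",
    "nitrogen_budget_residual",
]

_OM = resource_index("OM")
_NH4 = resource_index("NH4")
_COLIM_RTOL = 1e-9


@dataclass
class CommunityState:
    """Biomasses ``B`` (7,) and resource concentrations ``R`` (5,), μM N."""

    B: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float).reshape(7)
        self.R = np.asarray(self.R, dtype=float).reshape(5)

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "CommunityState":
        x = np.asarray(x, dtype=float)
        return cls(B=x[:7], R=x[7:12])

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.B, self.R])

    def copy(self) -> "CommunityState":
        return CommunityState(self.B.copy(), self.R.copy())


@dataclass
class SupplySpec:
    """Inflow concentrations s_j (μM N); by default only OM and NO3- flow in."""

    s: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float).reshape(5)
        if np.any(self.s < 0):
            raise ValueError(f"supply concentrations must be non-negative, got {self.s}")

    @classmethod
    def om_no3(cls, s_om: float, s_no3: float) -> "SupplySpec":
        s = np.zeros(5)
        s[0], s[1] = s_om, s_no3
        return cls(s)

    def washout_state(self) -> CommunityState:
        return CommunityState(B=np.zeros(7), R=self.s.copy())


@dataclass
class FluxRecord:
    """All per-state fluxes: growth, uptake, excretion, and gas production."""

    mu: np.ndarray             # (7,) realized growth rates, d^-1
    mu_pot: np.ndarray         # (7,5) potential growth rates (NaN where unused)
    limiting: np.ndarray       # (7,) index of the minimizing resource
    colimited: np.ndarray      # (7,) True when >= 2 resources tie at the minimum
    Vr: np.ndarray             # (7,5) realized uptake rates (0 where unused)
    E: np.ndarray              # (7,5) excretion rates (per biomass)
    gas_n2: float = 0.0        # total N2 production, μM N d^-1
    gas_n2o_prod: float = 0.0  # N2O production (excretion into the pool)
    gas_n2o_cons: float = 0.0  # N2O consumption (uptake by B4)
    limiting_name: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.limiting_name:
            self.limiting_name = [RESOURCES[k] for k in self.limiting]


def compute_fluxes(t: TraitSet, state: CommunityState) -> FluxRecord:
    """Evaluate growth, uptake, excretion, and gas fluxes at a state."""
    R = np.maximum(state.R, 0.0)
    B = np.maximum(state.B, 0.0)
    with np.errstate(invalid="ignore"):
        monod = R[None, :] / (R[None, :] + t.K)
    mu_pot = t.y * t.vmax * monod
    mu_masked = np.where(t.usage, mu_pot, np.inf)
    mu = mu_masked.min(axis=1)
    limiting = mu_masked.argmin(axis=1)
    # co-limitation: a second used resource within relative tolerance of the min
    tol = _COLIM_RTOL * np.maximum(mu, 1e-300)
    colimited = (np.abs(mu_masked - mu[:, None]) <= tol[:, None]).sum(axis=1) >= 2
    with np.errstate(invalid="ignore"):
        Vr = np.where(t.usage, mu[:, None] / t.y, 0.0)

    E = np.zeros((7, 5))
    for tp, (acc, prod) in PRODUCT_ROUTES.items():
        i = type_index(tp)
        E[i, resource_index(prod)] = mu[i] / t.y[i, resource_index(acc)]
    for tp in HETEROTROPHS:
        i = type_index(tp)
        E[i, _NH4] = t.nh4_fraction * mu[i] * (1.0 / t.y[i, _OM] - 1.0)

    fr = FluxRecord(mu=mu, mu_pot=np.where(t.usage, mu_pot, np.nan),
                    limiting=limiting, colimited=colimited, Vr=Vr, E=E)
    fr.gas_n2, fr.gas_n2o_prod, fr.gas_n2o_cons = _gas(t, B, fr)
    return fr


def _gas(t: TraitSet, B: np.ndarray, fr: FluxRecord) -> tuple[float, float, float]:
    i3, i4, i5, i7 = (type_index(x) for x in ("B3", "B4", "B5", "B7"))
    jno3, jno2, jn2o, jnh4 = (resource_index(x) for x in ("NO3", "NO2", "N2O", "NH4"))
    n2 = (
        fr.Vr[i3, jno2] * B[i3]
        + fr.Vr[i4, jn2o] * B[i4]
        + fr.Vr[i7, jno3] * B[i7]
        + (fr.Vr[i5, jno2] + fr.Vr[i5, jnh4] - fr.mu[i5]) * B[i5]
    )
    i2, i6 = type_index("B2"), type_index("B6")
    n2o_prod = fr.E[i2, jn2o] * B[i2] + fr.E[i6, jn2o] * B[i6]
    n2o_cons = fr.Vr[i4, jn2o] * B[i4]
    return float(n2), float(n2o_prod), float(n2o_cons)


def potential_growth(t: TraitSet, state: CommunityState, i: int | str, j: int | str) -> float:
    """Potential growth rate μ_ij = y Vm R/(R+K) of type i on resource j (d⁻¹)."""
    ii = type_index(i) if isinstance(i, str) else i
    jj = resource_index(j) if isinstance(j, str) else j
    if not t.usage[ii, jj]:
        raise ValueError(f"{TYPES[ii]} does not use {RESOURCES[jj]}")
    R = max(float(state.R[jj]), 0.0)
    return float(t.y[ii, jj] * t.vmax[ii, jj] * R / (R + t.K[ii, jj]))


def realized_growth(t: TraitSet, state: CommunityState, i: int | str) -> tuple[float, str, bool]:
    """Liebig growth of type i: (rate, limiting resource name, co-limited flag).

    Ties report the lowest resource index and set the co-limitation flag.
    """
    ii = type_index(i) if isinstance(i, str) else i
    fr = compute_fluxes(t, state)
    return float(fr.mu[ii]), RESOURCES[int(fr.limiting[ii])], bool(fr.colimited[ii])


def excretion_fluxes(t: TraitSet, flux: FluxRecord, i: int | str) -> np.ndarray:
    """Per-biomass excretion rates of type i over the five resources."""
    ii = type_index(i) if isinstance(i, str) else i
    return flux.E[ii].copy()


def gas_fluxes(t: TraitSet, state: CommunityState, flux: FluxRecord) -> tuple[float, float, float]:
    """(N2 production, N2O production, N2O consumption) in μM N d⁻¹."""
    return _gas(t, np.maximum(state.B, 0.0), flux)


def rhs(
    t: TraitSet, state: CommunityState, supply: SupplySpec
) -> tuple[np.ndarray, np.ndarray, FluxRecord]:
    """Right-hand side of the chemostat ODEs: (dB/dt, dR/dt, fluxes)."""
    if np.any(state.B < -1e-12) or np.any(state.R < -1e-12):
        raise ValueError(
            f"state has negative entries beyond tolerance: B={state.B}, R={state.R}"
        )
    fr = compute_fluxes(t, state)
    B = np.maximum(state.B, 0.0)
    dB = (fr.mu - t.dilution) * B
    dR = t.dilution * (supply.s - state.R) + fr.E.T @ B - fr.Vr.T @ B
    return dB, dR, fr


def rhs_vector(t: TraitSet, supply: SupplySpec, active: np.ndarray | None = None):
    """ODE right-hand side as f(time, x) over x = (B, R), for the integrators.

    ``active`` masks the populations present in the run: biomasses outside
    the mask are pinned to zero so that solver round-off cannot seed a
    spurious invasion by an absent type (a washed-out or never-inoculated
    population has no propagule source in a chemostat).
    """
    s = supply.s
    a = t.dilution
    mask = np.ones(7, dtype=bool) if active is None else np.asarray(active, dtype=bool)

    # precomputed constants for the hot loop
    used = t.usage.copy()
    yv = np.where(used, t.y * t.vmax, 0.0)            # growth ceiling per pair
    K = np.where(used, t.K, 1.0)
    inv_y = np.where(t.usage, 1.0 / np.where(t.usage, t.y, 1.0), 0.0)
    route_i = np.array([type_index(tp) for tp in PRODUCT_ROUTES])
    route_jp = np.array([resource_index(p) for _, p in PRODUCT_ROUTES.values()])
    route_inv_y = np.array(
        [1.0 / t.y[type_index(tp), resource_index(acc)]
         for tp, (acc, _p) in PRODUCT_ROUTES.items()]
    )
    het_i = np.array([type_index(tp) for tp in HETEROTROPHS])
    het_coef = t.nh4_fraction * (1.0 / t.y[het_i, _OM] - 1.0)

    def f(_time: float, x: np.ndarray) -> np.ndarray:
        B = np.where(mask, np.maximum(x[:7], 0.0), 0.0)
        R = np.maximum(x[7:12], 0.0)
        mu = np.where(used, yv * (R[None, :] / (R[None, :] + K)), np.inf).min(axis=1)
        dx = np.empty(12)
        dx[:7] = (mu - a) * B
        muB = mu * B
        dx[7:] = a * (s - x[7:12]) - (inv_y * muB[:, None]).sum(axis=0)
        np.add.at(dx[7:], route_jp, muB[route_i] * route_inv_y)
        dx[7 + _NH4] += (muB[het_i] * het_coef).sum()
        return dx

    return f


def nitrogen_budget_residual(
    t: TraitSet, state: CommunityState, supply: SupplySpec
) -> float:
    """Relative nitrogen-budget closure error at a state.

    The instantaneous budget  a Σs − a(ΣR + ΣB) − d/dt(ΣR + ΣB) − N2flux
    must vanish: every N atom entering either accumulates, flows out with
    the dilution, or leaves as N2 (N2O is a tracked pool, not a loss term
    here).  Returns the residual scaled by the largest term.
    """
    dB, dR, fr = rhs(t, state, supply)
    inflow = t.dilution * supply.s.sum()
    outflow = t.dilution * (state.R.sum() + np.maximum(state.B, 0.0).sum())
    accum = dB.sum() + dR.sum()
    resid = inflow - outflow - accum - fr.gas_n2
    scale = max(abs(inflow), abs(outflow), abs(accum), abs(fr.gas_n2), 1e-30)
    return float(resid / scale)
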