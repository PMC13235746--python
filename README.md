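# nitrocrm

A trait-based consumer–resource chemostat model of anaerobic marine
nitrogen cycling, for microbial ecologists and biogeochemical modelers
studying oxygen-deficient waters. Seven microbial functional types — six
denitrifier modules (NO₃⁻→NO₂⁻, NO₃⁻→N₂O, NO₂⁻→N₂, N₂O→N₂, NO₂⁻→N₂O,
and the complete denitrifier NO₃⁻→N₂) plus anammox — compete for, and
cross-feed, five dissolved nitrogen pools (organic-matter N, NO₃⁻, NO₂⁻,
N₂O, NH₄⁺). The package answers: which communities assemble at a given
organic-matter and nitrate supply, when does the outcome depend on
arrival order, and does fixed nitrogen leave as N₂ or as the greenhouse
gas N₂O?

## Model

Biomasses B_i and resources R_j (all μM N) evolve in a chemostat with
dilution rate a:

```
dB_i/dt = (μ_i − a) B_i
dR_j/dt = a (s_j − R_j) + Σ_i E_ij B_i − Σ_i V^r_ij B_i
```

Each type needs two essential, non-substitutable resources (electron
donor + acceptor). Growth follows Liebig's law of the minimum over Monod
kinetics, μ_i = min_j y_ij V^m_ij R_j/(R_j + K_ij), and uptake of every
used resource is slaved to it, V^r_ij = μ_i/y_ij. Excretion creates the
dependency network: the NO₃⁻→NO₂⁻ reducer releases all reduced nitrate-N
as nitrite; the NO₃⁻→N₂O and NO₂⁻→N₂O reducers release N₂O; every
heterotroph remineralizes NH₄⁺ at μ(1/y_OM − 1) (nitrogen balance), which
feeds the autotrophic anammox. N₂ is the only nitrogen loss; N₂O is a
tracked pool.

The analysis layer provides the classic resource-ratio quantities in
closed form — subsistence concentrations R* = K a/(y V^m − a),
consumption vectors c = y_OM/y_acceptor and their feeder–recipient
composites c_fr = c_f/(1 + c_f/c_r), feeder-biomass invasion thresholds,
and ZNGIs — plus numerical machinery: equilibrium finding with extinction
handling, invasion analysis, assembly-order experiments with
multistability detection, and 2D supply-space regime maps.

## Worked example

```python
import numpy as np
from nitrocrm import (CommunityState, SupplySpec, builtin_trait_fixture,
                      find_equilibrium)

traits = builtin_trait_fixture()          # published trait table, a = 0.04/d
supply = SupplySpec.om_no3(1.0, 30.0)     # 1 μM OM-N, 30 μM NO3-N inflow
B0 = np.zeros(7); B0[0] = 1e-3            # inoculate the NO3->NO2 reducer
eq = find_equilibrium(traits, CommunityState(B0, supply.s.copy()), supply)
print(eq.state.B[0], eq.state.R)
```

prints

```
0.14639747822548305 [ 0.02401681 16.69113834 13.30886166  0.          0.82958571]
```

B1 is OM-limited: it draws OM to its subsistence value R* = 0.024 μM,
reaches biomass y(s − R*) = 0.1464 μM N, leaves 16.69 μM nitrate,
accumulates 13.31 μM nitrite (all reduced nitrate-N, available to
downstream recipients), and regenerates 0.83 μM NH₄⁺ — an NH₄⁺ flux equal
to 83% of the OM supply flux. The `examples/` scripts walk through the
other capabilities: subsistence table, consumption-vector algebra,
priority effects, and the full regime map. A thin CLI mirrors them:
`nitrocrm rstar`, `nitrocrm simulate`, `nitrocrm sweep`,
`nitrocrm assembly`, `nitrocrm fixture`.

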