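"""Priority effects: assembly order decides the outcome.

In a band of supply ratios between the consortium vector c13 = 5.12 and
B2's vector c2 = 6.43, the {B1,B2,B3} subsystem is bistable.  If the
feeder-recipient pair (B1 feeding nitrite to B3) establishes first, it
holds OM low enough to exclude the N2O producer B2; if B2 establishes
first it is nitrate-limited and cannot be invaded.  Nitrogen then leaves
as N2 in one history and as N2O in the other — the biogeochemical fate
depends on who arrived first.
"""

from nitrocrm import SupplySpec, assemble, builtin_trait_fixture, detect_multistability

traits = builtin_trait_fixture()
supply = SupplySpec.om_no3(5.0, 30.0)  # NO3:OM supply ratio = 6

for order in (("B1", "B3", "B2"), ("B2", "B1", "B3")):
    eq = assemble(traits, order, supply).final
    members = "+".join(sorted(eq.persistent_set)) or "none"
    print(f"arrival order {'->'.join(order):12s} -> {members:6s} "
          f"(N2 {eq.fluxes.gas_n2:.4f}, N2O {eq.fluxes.gas_n2o_prod:.4f} μM N/d)")

ms = detect_multistability(traits, supply, ("B1", "B2", "B3"))
print(f"\ncanonical order battery: bistable: {ms.bistable}; "
      f"mutually non-invasible: {ms.mutually_noninvasible}")
for eq in ms.equilibria:
    print("  stable state:", "+".join(sorted(eq.persistent_set)) or "none")
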