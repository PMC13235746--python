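"""Built-in trait table and subsistence concentrations (R*).

Prints the physiological traits of the seven anaerobic N-cycling
functional types and the resource concentration at which each population's
growth exactly balances the chemostat dilution rate (0.04/d).  A lower R*
means a stronger competitor when that resource is limiting: B1 beats B2 on
organic matter (0.024 < 0.0244 μM N) but loses on nitrate (0.308 > 0.142),
the trade-off that structures the whole system.
"""

from nitrocrm import builtin_trait_fixture, rstar_table

traits = builtin_trait_fixture()
table = traits.to_frame().merge(rstar_table(traits), on=["type", "resource"])
print(table.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
print(f"\ndilution rate a = {traits.dilution} / d")
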