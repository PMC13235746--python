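"""Supply-space regime map of the full seven-type system (coarse grid).

Sweeps OM and NO3- inflow over a log-spaced 13x13 grid and labels each
cell with its equilibrium community and nitrogen-loss pathway.  Expected
structure: no cell supports all seven types; the complete denitrifier B7
rules the OM-rich half; the B1-anchored consortium (with anammox and B3)
rules the nitrate-rich half; B6 is excluded everywhere; N2O escapes
net-free only where its producer B2 persists.  Takes ~20 s.
"""

from nitrocrm import TYPES, builtin_trait_fixture, niche_breadth, run_grid
from nitrocrm.sweep import default_axis

traits = builtin_trait_fixture()
rm = run_grid(traits, TYPES, default_axis(n=13), default_axis(n=13))
df = rm.to_dataframe()

print("community regimes (cells):")
print(df.community_label.value_counts().to_string())
print("\nnitrogen-loss regimes (cells):")
print(df.nloss_label.value_counts().to_string())
print("\nniche breadth (fraction of cells where the type persists):")
for tp in TYPES:
    print(f"  {tp}: {niche_breadth(rm, tp):.3f}")
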