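"""One-way (tornado) sensitivity analysis of the ICER.

Reruns the full lifetime pipeline with every scalar input at 90% and 110%
of its base value and ranks parameters by the width of the resulting ICER
interval — the classic tornado ordering.
"""
from bpcea import SyntheticProfile, generate_inputs, one_way_tornado

inputs = generate_inputs(SyntheticProfile(country="CN", seed=0))
table = one_way_tornado(inputs, fraction=0.10)

print(f"{len(table)} parameters perturbed ±10%; top 8 ICER drivers:")
for _, row in table.head(8).iterrows():
    print(f"  {row.parameter:42s} ICER {row.icer_low:>10,.0f} .. "
          f"{row.icer_high:>10,.0f}  (width {row.width:,.0f})")
# The yearly cost of intensive blood-pressure treatment tops the ranking:
# it feeds the cost increment every single cycle, while most event
# parameters touch only a slice of the cohort.
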