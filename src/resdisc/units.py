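"""Unit conventions and physical constants.

The whole package works in a single consistent unit system:

==========  ==========================
length      mm
force       N
stress      MPa  (N/mm^2)
time        s
permeability  mm^4/(N s)
concentration mM  (mmol/L == mol/m^3, treated as osmotically active species)
temperature K
==========  ==========================

Osmotic pressures are computed as R*T*c with c in mol/m^3, giving Pa, and
converted to MPa through :data:`PA_TO_MPA`.
"""

GAS_CONSTANT = 8.314462618  # J/(mol K)
PA_TO_MPA = 1e-6
#: R*T*c with c in mM (= mol/m^3) yields Pa; multiply by this to get MPa.
MM_TO_MOL_PER_M3 = 1.0

BODY_TEMPERATURE_K = 310.0
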