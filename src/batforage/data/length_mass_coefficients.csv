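# Editable per-order length-mass power laws: dry mass_mg = a * length_mm^b.
# Values are typical insect allometries on the mg/mm scale; replace with
# regressions appropriate to the study region if available.
order,a,b
Carabidae,0.0312,2.62
Orthoptera,0.0656,2.21
Diptera,0.0421,2.26
Lepidoptera,0.0268,2.25
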