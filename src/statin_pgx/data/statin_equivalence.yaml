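# Simvastatin-equivalence potency ratios: multiply a statin's daily dose
# (mg) by its ratio to obtain the simvastatin dose of comparable
# LDL-lowering effect. Editable — dosing references differ; these are
# conventional round-number defaults, not hard-coded anywhere in code.
simvastatin: 1.0
atorvastatin: 2.0
rosuvastatin: 4.0
pravastatin: 0.5
fluvastatin: 0.5
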