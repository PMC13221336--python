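# Default substructure rules for the panel-selection report.
# Each entry maps a rule name to a SMARTS pattern.
nitrovinyl: C=C[N+](=O)[O-]
nitro: "[N+](=O)[O-]"
vinyl: C=C
phenyl: c1ccccc1
carboxyl: C(=O)[OX2H1]
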