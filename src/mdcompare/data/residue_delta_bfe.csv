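comparison,residue,delta_bfe_kjmol
holo-G323E,323,29.6
holo-p,Y281,3.32
holo-p,F280,2.41
holo-p,H248,2.27
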