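# Classic five-residue SPOP-binding consensus (SBC): phi-pi-S-S/T-S/T.
# Position +1 is the first SBC residue.
name = classic_sbc
+1 = phi
+2 = pi
+3 = S
+4 = S/T
+5 = S/T
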