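# Expanded long SPOP degron: lambda-Q-X-X-X-phi-pi-S-X-X over -5..+5.
# Combines the Q-motif (-5/-4, invariant Gln at -4) with an SBC whose
# +4/+5 positions are unconstrained.
name = long_degron
-5 = lambda
-4 = Q
-3 = X
-2 = X
-1 = X
+1 = phi
+2 = pi
+3 = S
+4 = X
+5 = X
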