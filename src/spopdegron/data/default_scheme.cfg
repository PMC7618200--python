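# Default residue-class scheme for SPOP degron consensus models.
# phi: nonpolar; pi: polar; lambda: medium-or-large (all 20 minus G, A, S, C).
# X (any residue) is implicit.
name = default
phi = GAVLIPFMWC
pi = STNQDEHKRY
lambda = DEFHIKLMNPQRTVWY
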