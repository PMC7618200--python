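# 17-residue search motif over positions -9..+8, constrained only at the
# Q-motif (-5: LVIEDQN; -4: QNE) and the first three SBC residues
# (+1 phi, +2 pi, +3 S); all other positions allow any residue.
name = search_motif_17
-9 = X
-8 = X
-7 = X
-6 = X
-5 = L/V/I/E/D/Q/N
-4 = Q/N/E
-3 = X
-2 = X
-1 = X
+1 = phi
+2 = pi
+3 = S
+4 = X
+5 = X
+6 = X
+7 = X
+8 = X
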