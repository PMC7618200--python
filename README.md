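# spopdegron

Tools for finding and characterizing SPOP-binding degrons in protein
sequences and structures.

SPOP is the substrate adaptor of a Cullin-3 E3 ubiquitin ligase.  Its MATH
domain recognizes short linear degrons in substrate proteins.  The classic
five-residue SPOP-binding consensus (SBC) is

```
φ-π-S-S/T-S/T        (positions +1 … +5; φ nonpolar, π polar)
```

High-affinity substrates such as MyD88 carry an additional N-terminal
element, the **Q-motif**, with an invariant glutamine at signed position
−4 (no position 0 exists; +1 is the first SBC residue).  Combining both
elements gives the expanded **long degron**

```
λ-Q-X-X-X-φ-π-S-X-X  (positions −5 … +5; λ medium-or-large, X any residue)
```

This package is aimed at anyone hunting new E3-ligase substrates or
quantifying degron binding: it provides

* **Consensus models** (`spopdegron.motifs`) — position-indexed
  allowed-residue sets compiled from compact strings (`"λ-Q-X-X-X-φ-π-S-X-X"`),
  three packaged built-ins (`CLASSIC_SBC`, `LONG_DEGRON`, the 17-residue
  `SEARCH_MOTIF_17`), consensus derivation from aligned degron windows, and
  per-anchor random-match probabilities.
* **A sequence scanner** (`spopdegron.scanner`) — FASTA in, TSV/BED out,
  with SBC-anchored signed coordinates honoring printed peptide numbering.
* **Binding-isotherm fits** (`spopdegron.affinity`) — FP saturation
  (one-site total binding → K_d), FP competition (four-parameter variable
  slope logistic → IC50), and ITC (one-set-of-sites → n, K_a, ΔH with
  K_d = 1/K_a), plus percent-FP normalization and replicate mean ± SD
  aggregation.
* **Interface geometry** (`spopdegron.structure`) — PDB/mmCIF loading,
  Kabsch superposition, paired-Cα RMSD after presuperposition,
  deterministic Shrake–Rupley SASA, buried surface area, hydrogen-bond and
  hydrophobic-contact inventories mapped to signed degron positions.
* **Synthetic data** (`spopdegron.synth`) — implanted-degron proteomes
  with brute-force truth tables, noisy binding curves and ITC heats from
  known parameters, and toy coordinate sets with closed-form geometry.

## Worked example

Scan the MyD88 degron peptide (residues 125–141) for the long degron:

```python
from spopdegron import LONG_DEGRON, SequenceRecord, scan_sequence

record = SequenceRecord("MyD88", "AEKPLQVAAVDSSVPRT", first_residue_number=125)
(match,) = scan_sequence(record, LONG_DEGRON)
print(match.anchor, match.per_position[-4], match.window)
```

prints

```
134 Q LQVAAVDSSV
```

i.e. the single long-degron match anchors its SBC at Val134 (+1), the
Q-motif glutamine is Gln130 at index −4, and the matched −5…+5 window is
`LQVAAVDSSV`.  The same scan from the shell:

```sh
spopdegron scan --fasta myd88.fa --motif long --first-residue-number 125 --out matches.tsv
```

Fitting a simulated saturation curve round-trips the dissociation
constant:

```python
from spopdegron import fit_one_site_total, simulate_saturation_fp

curve = simulate_saturation_fp(kd=0.26, bmax=100.0, noise_sd=0.0)
print(round(fit_one_site_total(curve)["Kd"], 4))   # 0.26
```

Measured affinities from the accompanying study (e.g. K_d = 0.26 µM for
the long MyD88 peptide, 32.25 µM for the minimal SBC peptide, 1.1 µM for
Puc) ship as annotation only — they are wet-lab quantities, not outputs of
this software.

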