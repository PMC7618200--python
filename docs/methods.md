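# Methods

## Coordinate system and consensus models

Degron positions are numbered relative to the SPOP-binding consensus
(SBC): +1 is the first SBC residue, −1 the residue immediately N-terminal
to it; position 0 does not exist.  Sequence coordinates are 1-based
inclusive and honor an explicit `first_residue_number`, so peptide
fragments keep their published numbering (the MyD88 17-mer spans 125–141
and its anchor is reported as 134, not 10).

A consensus is an ordered list of `(signed index, allowed residue set)`
pairs.  Three built-ins ship as plain-text configs and as compiled
constants:

| motif | positions | constrained positions |
|---|---|---|
| `CLASSIC_SBC` | +1…+5 | +1 φ, +2 π, +3 {S}, +4 {S,T}, +5 {S,T} |
| `LONG_DEGRON` | −5…+5 | −5 λ, −4 {Q}, +1 φ, +2 π, +3 {S} |
| `SEARCH_MOTIF_17` | −9…+8 | −5 {L,V,I,E,D,Q,N}, −4 {Q,N,E}, +1 φ, +2 π, +3 {S} |

Residue classes are a configurable scheme.  The default, chosen to cover
every residue observed at the corresponding positions of characterized
degrons (+1 ∈ {V,I}, +2 ∈ {D,T,S}, −5 ∈ {L,V,E,T}):

* φ (nonpolar) = {G,A,V,L,I,P,F,M,W,C}
* π (polar) = {S,T,N,Q,D,E,H,K,R,Y}
* λ (medium-or-large) = all 20 minus {G,A,S,C}
* X = any of the 20 standard residues

Class boundaries for borderline residues (is Cys nonpolar? is Tyr polar?)
are genuinely conventional; the scheme is therefore a config file, not a
constant.  Note one consequence kept deliberately: `SEARCH_MOTIF_17`
carries its −5 set verbatim, which excludes Thr — so it does not match the
Caprin1 degron (Thr430 at −5) even though `LONG_DEGRON` (λ at −5) does.
The discrepancy is in the source definitions, and we do not silently widen
the set.

### Consensus derivation

`consensus_from_alignment` summarizes each column of aligned degron
windows by the most specific symbol from the fixed vocabulary

```
literal residue  →  S/T  →  φ  →  π  →  λ  →  X
```

whose set covers every observed residue (the ordering makes ties
impossible, and re-deriving from the expanded output reproduces it —
idempotence is property-tested).  Manually assembled consensus strings are
often looser than the observed windows; when a reference string is
supplied and the derivation is strictly tighter at any position, the
function warns instead of silently differing.  On the four printed −5…+5
substrate windows the derivation yields `λ-Q-X-φ-X-φ-π-S-π-X`, tighter
than the published `λ-Q-X-X-X-φ-π-S-X-X` at −2 and +4 — expected, since
four windows undersample the allowed variability.

### Random-match probability

For an i.i.d. background, the per-anchor match probability is the product
over constrained positions of the summed background frequency of the
allowed set.  Under the uniform background the classic SBC gives
(10/20)(10/20)(1/20)(2/20)(2/20) = 1.25 × 10⁻⁴ per anchor; the scanner's
empirical rate over 10⁶ positions is checked against a 99 % binomial
interval around this value.

## Scanner

A match requires every constrained position in-bounds and satisfied;
unconstrained (X) flanks may overhang the termini, because only the
contacted residues are biologically constrained and demanding the full
window would miss near-terminal degrons.  All overlapping matches are
reported.  Lowercase is uppercased, `*` stripped, and other non-standard
letters never satisfy a constrained position.  TSV output is 1-based
inclusive; BED output converts the constrained span to 0-based half-open.
The scanner is validated against an independently coded brute-force
checker (also the generator of synthetic truth tables) on 1,000 seeded
random sequences.

## Binding models

The study names its fit models (one-site total binding; inhibitor vs
response, variable slope; One Set of Sites) without printing equations;
the implementations use the standard definitions of those model families.

**FP saturation.**  y = B_max·x/(K_d + x) + NS·x + baseline, fit by
least squares.  The nonspecific slope NS is optional (`include_ns`) since
whether the original fits included it is not stated.  Percent-FP
normalization maps the no-protein control to 0 % and the top reference to
100 %; values outside [0, 100] are permitted noise.  Initial guesses are
data-driven and deterministic: baseline from the lowest-dose signal,
B_max from the signal range, K_d from the dose nearest half-maximum.  A
fitted K_d more than 100× beyond the sampled range, or an amplitude
indistinguishable from zero, is flagged unconverged rather than reported.

**FP competition.**  y = bottom + (top − bottom)/(1 + 10^((log₁₀ IC50 −
log₁₀ x)·h)) with Hill slope h < 0 for inhibition; IC50 is the dose
halfway between the plateaus.  x = 0 points are excluded from the
log-domain fit but seed the top-plateau estimate.  A rising dose-response
(no inhibition) is reported as not determined, mirroring the "ND"
convention of the assay.

**ITC.**  One-set-of-sites total-heat model with the standard
cumulative-displacement dilution correction for a perfusion cell:
M_t = M₀(1 − ΔV/2V₀)/(1 + ΔV/2V₀), X_t = X₀(ΔV/V₀)/(1 + ΔV/2V₀), total
heat Q from the binding quadratic, and per-injection heat
ΔQ_i = Q_i − Q_{i−1} + (dV_i/V₀)(Q_i + Q_{i−1})/2.  The default schedule
is a 0.5 µl pre-injection followed by 19 × 2 µl injections of 300 µM
titrant into 30 µM cell species in a 200 µl cell (the instrument-typical
volume; the source does not state it).  The titration direction is
inverted relative to common practice — the *protein* is injected into the
*peptide* — so the fitter treats the cell species as the "macromolecule".
Heats are expected pre-corrected against a dilution control
(`subtract_dilution_control` is provided as a utility).  K_d is reported
as 1/K_a.  The forward model is verified against an independently coded
per-injection re-derivation to 10⁻⁹, and the fitter against coarse-grid
oracles with the nonlinear parameters on a grid and the linear ones
solved exactly.

Replicate aggregation is the arithmetic mean ± sample standard deviation
(n − 1), requiring at least two converged fits of the same model.

## Structural geometry

* **Superposition** is closed-form Kabsch (SVD with reflection
  correction, det = +1), cross-checked against a brute-force
  quaternion-grid minimizer to 10⁻⁶.
* **Paired-Cα RMSD** superposes on one selection (e.g. the MATH domains)
  and evaluates RMSD on another (the peptides) *without refitting* —
  the convention for comparing peptide poses across crystal structures.
  The cross-substrate comparison uses the −6…+5 register: MyD88 residues
  128–138 paired with Pdx1 223–233 (11 Cα), since the exact published
  atom set is not enumerated.
* **SASA** is Shrake–Rupley on a deterministic golden-spiral point set
  (default 960 points/atom; bit-stable across runs; doubling the count
  changes per-atom areas by < 0.5 %).  Radii: C 1.70, N 1.55, O 1.52,
  S 1.80, P 1.80, H 1.20 Å, configurable; unknown elements require an
  explicit default radius.  The implementation is validated against the
  isolated-sphere and two-sphere spherical-cap closed forms and
  cross-checked against mdtraj's independent implementation (< 1 %).
* **Buried surface area** = SASA(A) + SASA(B) − SASA(A∪B), waters
  excluded.  Published buried-area figures use either the summed or the
  halved convention without saying which; both are reported
  (`bsa_total`, `interface_area`).
* **H-bonds**: donor-heavy-atom–acceptor distance ≤ 3.5 Å, both role
  assignments enumerated, plus a D–H…A angle ≥ 120° when explicit
  hydrogens exist.  The criterion is a common convention (the source does
  not state one) and both thresholds are flags.  Water-mediated bridges
  are not searched by default.
* **Hydrophobic contacts**: C–C ≤ 4.5 Å where neither carbon is bonded
  to N/O, per a static residue-topology table.
* Contacts map to signed degron indices via the anchor
  (residue 130 with anchor 134 → −4); peptide residues outside the motif
  span are labeled `flank`.

## Synthetic data

Generators emulate: i.i.d. proteomes (uniform background by default — the
simplest null for match-rate analytics — with a vertebrate-like
composition table as an alternative config); degron implantation by
substring overwrite with generation-time validation; FP and ITC data from
the forward models above with Gaussian noise; and toy coordinate sets
with closed-form truth.  All are pure functions of their arguments
including the seed.  Truth tables are produced by the brute-force
checker, never by the production scanner, keeping oracle and subject
separate.

What synthetic data does *not* emulate: real disorder context around
degrons, compositional correlation along sequences, instrument drift or
baseline artifacts in binding assays, and crystallographic noise.
Passing tests therefore demonstrate correctness of the algorithms under
their stated models, not performance on proteome-scale discovery.

## Problem sizes and determinism

The test suite uses 1,000 random sequences (length ≤ 200) for the
scanner-oracle battery, ~10⁶ positions for the match-rate check, 200
simulated curves each for the K_d and IC50 recovery suites (σ = 2 %FP or
mP), and three ITC replicates at 2 % heat noise under the standard
injection schedule — sizes chosen to make the statistical assertions
sharp while keeping the suite fast.  Every random draw is seeded; fits
are deterministic given identical input bytes.

## Known limitations

* No PWM/PSSM scoring, information content, or learned degron predictors;
  the models are hard set-membership by design.
* No multivalent (multi-degron) binding model, and no quantitative model
  of SBC affinity differences between substrates.
* No Cheng–Prusoff IC50→K_i conversion and no global multi-curve fitting.
* The H-bond and hydrophobic-contact criteria are geometric conventions,
  not energy models; water-mediated networks are out of scope by default.
* The structural acceptance checks require the deposited PDB entries and
  network access; all other functionality is download-free.
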