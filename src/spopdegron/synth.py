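"""Synthetic fixtures with machine-readable ground truth.

Every stage of the pipeline can be exercised without any download:

* random proteomes from an i.i.d. residue background, with degron windows
  implanted at known coordinates and a truth table of all matches
  (implants plus incidental background hits) enumerated by a deliberately
  naive brute-force checker, kept separate from the production scanner;
* FP saturation and competition curves generated from known Kd / IC50 with
  Gaussian noise;
* ITC injection heats from the one-set-of-sites forward model under the
  standard titration schedule (a 0.5 ul pre-injection followed by 19 x 2 ul
  injections of 300 uM titrant into 30 uM cell species);
* toy atomic coordinate sets whose SASA / buried area / RMSD / hydrogen
  bond content is known in closed form.

All generators are pure functions of their arguments including the seed:
reruns are byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .affinity import (
    BindingCurve,
    CompetitionCurve,
    ITCExperiment,
    four_param_logistic,
    itc_injection_heats,
    one_site_total,
)
from .motifs import AA20, DegronConsensus, uniform_background
from .scanner import DegronMatch, SequenceRecord
from .structure import DEFAULT_RADII, AtomRecord, StructureModel

__all__ = [
    "brute_force_scan",
    "make_random_proteome",
    "implant_degrons",
    "twofold_dilution_series",
    "simulate_saturation_fp",
    "simulate_competition_fp",
    "STANDARD_ITC_SCHEDULE",
    "simulate_itc",
    "make_toy_complex",
    "write_fasta",
    "write_truth_table",
]


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def brute_force_scan(record: SequenceRecord, consensus: DegronConsensus) -> List[DegronMatch]:
    """Independent naive reference scanner (position-by-position loops).

    Used to build truth tables and as the oracle against the production
    scanner; intentionally written in the most literal way possible.
    """
    hits = []
    seq = record.residues
    constrained = [p for p in consensus.positions if p.allowed != AA20]
    if not constrained:
        constrained = list(consensus.positions)
    lo = min(p.offset for p in constrained)
    hi = max(p.offset for p in constrained)
    reach = max(abs(p.offset) for p in consensus.positions)
    for i in range(-reach, len(seq) + reach + 1):
        ok = True
        for p in constrained:
            j = i + p.offset
            if j < 0 or j >= len(seq):
                ok = False
                break
            if seq[j] not in p.allowed:
                ok = False
                break
        if not ok:
            continue
        per_position = {}
        for p in consensus.positions:
            j = i + p.offset
            if 0 <= j < len(seq):
                per_position[p.index] = seq[j]
        anchor = record.first_residue_number + i
        window = "".join(per_position[k] for k in sorted(per_position))
        hits.append(
            DegronMatch(
                sequence_id=record.id,
                motif_name=consensus.name,
                anchor=anchor,
                span_start=anchor + lo,
                span_end=anchor + hi,
                window=window,
                per_position=per_position,
            )
        )
    return hits


def _truth_rows(records, motifs, implanted=()):
    implanted_set = set(implanted)
    rows = []
    for record in records:
        for motif in motifs:
            for m in brute_force_scan(record, motif):
                rows.append(
                    {
                        "sequence_id": m.sequence_id,
                        "motif": m.motif_name,
                        "anchor": m.anchor,
                        "implanted": (m.sequence_id, m.motif_name, m.anchor) in implanted_set,
                    }
                )
    return pd.DataFrame(rows, columns=["sequence_id", "motif", "anchor", "implanted"])


def make_random_proteome(
    n: int,
    length: int,
    background: Mapping[str, float] = None,
    seed: int = 0,
    motifs: Sequence[DegronConsensus] = (),
    id_prefix: str = "synth",
) -> Tuple[List[SequenceRecord], pd.DataFrame]:
    """n i.i.d. random sequences plus a brute-force truth table.

    The truth table enumerates every (incidental) match of the given motifs
    in the generated sequences; with no motifs it is empty.
    """
    if n < 1 or length < 1:
        raise ValueError("n and length must be >= 1")
    freqs = background or uniform_background()
    letters = sorted(freqs)
    probs = np.array([freqs[a] for a in letters], dtype=float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-6 or set(letters) != set(AA20):
        raise ValueError("background must be non-negative frequencies over the 20 residues summing to 1")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        seq = "".join(rng.choice(letters, size=length, p=probs))
        records.append(SequenceRecord(id=f"{id_prefix}_{i:04d}", residues=seq))
    return records, _truth_rows(records, motifs)


def implant_degrons(
    records: Sequence[SequenceRecord],
    implants: Sequence[Tuple[str, str, int]],
    motif: DegronConsensus,
    extra_motifs: Sequence[DegronConsensus] = (),
) -> Tuple[List[SequenceRecord], pd.DataFrame]:
    """Overwrite degron windows into sequences at known coordinates.

    ``implants`` is a list of ``(sequence_id, window, start)`` with
    ``start`` the 1-based coordinate (in the record's numbering) of the
    window's first residue.  Each window must itself match ``motif``
    (validated at generation time via the brute-force checker); the truth
    table lists the resulting anchor of every implant, flagged
    ``implanted``, together with any incidental matches found by brute
    force.
    """
    by_id = {r.id: r for r in records}
    new_seqs = {r.id: list(r.residues) for r in records}
    implanted_keys = []
    for seq_id, window, start in implants:
        if seq_id not in by_id:
            raise ValueError(f"unknown sequence id {seq_id!r}")
        probe = SequenceRecord(id="probe", residues=window)
        window_hits = brute_force_scan(probe, motif)
        if not window_hits:
            raise ValueError(f"window {window!r} does not satisfy motif {motif.name!r}")
        rec = by_id[seq_id]
        i0 = start - rec.first_residue_number
        if i0 < 0 or i0 + len(window) > len(rec.residues):
            raise ValueError(
                f"implant {window!r} at {start} does not fit in {seq_id!r} "
                f"({rec.first_residue_number}..{rec.first_residue_number + len(rec.residues) - 1})"
            )
        new_seqs[seq_id][i0 : i0 + len(window)] = window.upper()
        for h in window_hits:
            implanted_keys.append((seq_id, motif.name, start + (h.anchor - 1)))
    out = [
        SequenceRecord(
            id=r.id,
            residues="".join(new_seqs[r.id]),
            description=r.description,
            first_residue_number=r.first_residue_number,
        )
        for r in records
    ]
    truth = _truth_rows(out, [motif, *extra_motifs], implanted=implanted_keys)
    return out, truth


def write_fasta(records: Sequence[SequenceRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for r in records:
            header = f">{r.id}" + (f" {r.description}" if r.description else "")
            fh.write(header + "\n")
            for i in range(0, len(r.residues), width):
                fh.write(r.residues[i : i + width] + "\n")


def write_truth_table(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Binding curves
# ---------------------------------------------------------------------------

def twofold_dilution_series(top: float, n: int) -> np.ndarray:
    """A descending two-fold dilution series, mirroring plate-assay design."""
    if top <= 0 or n < 1:
        raise ValueError("top must be positive and n >= 1")
    return top / (2.0 ** np.arange(n))[::-1]


def simulate_saturation_fp(
    kd: float,
    bmax: float = 100.0,
    ns: float = 0.0,
    baseline: float = 0.0,
    concentrations: Sequence[float] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    replicate_id: str = "sim",
) -> BindingCurve:
    """FP saturation curve from the one-site total forward model + noise."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    x = np.asarray(
        concentrations if concentrations is not None else twofold_dilution_series(100.0, 12),
        dtype=float,
    )
    if len(x) < 5:
        raise ValueError("need at least 5 concentrations")
    y = one_site_total(x, kd, bmax, ns, baseline)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(x))
    return BindingCurve(x, y, replicate_id=replicate_id, normalized=True)


def simulate_competition_fp(
    ic50: float,
    hill: float = -1.0,
    top: float = 200.0,
    bottom: float = 50.0,
    concentrations: Sequence[float] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    probe_conc: float = 0.05,
    receptor_conc: float = 5.0,
    replicate_id: str = "sim",
) -> CompetitionCurve:
    """FP competition curve from the 4PL forward model + noise."""
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    x = np.asarray(
        concentrations if concentrations is not None else twofold_dilution_series(200.0, 18),
        dtype=float,
    )
    y = four_param_logistic(x, ic50, hill, top, bottom)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(x))
    return CompetitionCurve(
        x, y, probe_conc=probe_conc, receptor_conc=receptor_conc, replicate_id=replicate_id
    )


#: Default titration schedule: one 0.5 ul pre-injection then 19 x 2 ul.
STANDARD_ITC_SCHEDULE = np.array([0.5] + [2.0] * 19)


def simulate_itc(
    n: float = 1.0,
    ka: float = 2e6,
    dh: float = -1e4,
    cell_conc: float = 30.0,
    syringe_conc: float = 300.0,
    injection_volumes: Sequence[float] = None,
    cell_volume: float = 200.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ITCExperiment:
    """ITC experiment from the one-set-of-sites forward model + noise.

    Defaults mirror a typical degron titration: 300 uM protein into 30 uM
    peptide in a 200 ul cell, 0.5 ul then 19 x 2 ul injections.  ``ka`` in
    1/M, ``dh`` in cal/mol, concentrations in uM, volumes in ul, heats in
    ucal.
    """
    if n <= 0 or ka <= 0:
        raise ValueError("n and ka must be positive")
    vols = np.asarray(
        injection_volumes if injection_volumes is not None else STANDARD_ITC_SCHEDULE, dtype=float
    )
    exp = ITCExperiment(
        cell_species_conc=cell_conc,
        syringe_species_conc=syringe_conc,
        injection_volumes=vols,
        heats=np.zeros(len(vols)),
        cell_volume=cell_volume,
    )
    heats = itc_injection_heats(exp, n, ka, dh)
    if noise_sd > 0:
        heats = heats + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(heats))
    exp.heats = heats
    return exp


# ---------------------------------------------------------------------------
# Toy coordinate sets with analytic truth
# ---------------------------------------------------------------------------

def _two_sphere_truth(d: float, r1: float, r2: float, probe: float) -> dict:
    """Closed-form SASA/BSA for two spheres (spherical-cap overlap)."""
    R1, R2 = r1 + probe, r2 + probe
    iso1, iso2 = 4.0 * math.pi * R1**2, 4.0 * math.pi * R2**2
    if d >= R1 + R2:
        cap1 = cap2 = 0.0
    elif d <= abs(R1 - R2):
        # one expanded sphere enclosed by the other
        cap1, cap2 = (iso1, 0.0) if R1 <= R2 else (0.0, iso2)
    else:
        h1 = R1 - (d * d + R1 * R1 - R2 * R2) / (2.0 * d)
        h2 = R2 - (d * d + R2 * R2 - R1 * R1) / (2.0 * d)
        cap1 = 2.0 * math.pi * R1 * h1
        cap2 = 2.0 * math.pi * R2 * h2
    return {
        "sasa": [iso1 - cap1, iso2 - cap2],
        "sasa_isolated": [iso1, iso2],
        "bsa_total": cap1 + cap2,
    }


def _rotation_from_seed(rng) -> np.ndarray:
    # QR of a random Gaussian matrix, sign-fixed to a proper rotation
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def make_toy_complex(recipe: str, seed: int = 0, **params) -> Tuple[StructureModel, dict]:
    """Toy coordinate sets with analytically known geometry.

    Recipes
    -------
    ``isolated_atoms``: ``n`` carbon atoms spaced far apart; truth: each
    atom's SASA is the full expanded sphere ``4*pi*(r+probe)**2``.

    ``two_spheres``: two atoms (default carbons) at distance ``d`` on
    separate chains; truth: per-atom SASA and buried area from the
    spherical-cap closed form.

    ``point_cloud_pair``: ``n`` random CA atoms (chain A) and the same
    cloud under a known rigid transform (chain B); truth: the transform and
    RMSD 0 after superposition.

    ``donor_acceptor``: a backbone amide N (chain A) facing a backbone
    carbonyl O (chain B) at distance ``r``; truth: 1 hydrogen bond iff
    ``r <= 3.5``.
    """
    rng = np.random.default_rng(seed)
    probe = params.get("probe_radius", 1.4)
    if recipe == "isolated_atoms":
        n = params.get("n", 3)
        spacing = params.get("spacing", 100.0)
        atoms = [
            AtomRecord("A", i + 1, "UNK", "C1", "C", i * spacing, 0.0, 0.0)
            for i in range(n)
        ]
        iso = 4.0 * math.pi * (DEFAULT_RADII["C"] + probe) ** 2
        return StructureModel(atoms, "toy_isolated"), {"sasa": [iso] * n}
    if recipe == "two_spheres":
        d = params.get("d", 2.0)
        el1 = params.get("element_a", "C")
        el2 = params.get("element_b", "C")
        r1 = DEFAULT_RADII[el1]
        r2 = DEFAULT_RADII[el2]
        atoms = [
            AtomRecord("A", 1, "UNK", f"{el1}1", el1, 0.0, 0.0, 0.0),
            AtomRecord("B", 1, "UNK", f"{el2}1", el2, d, 0.0, 0.0),
        ]
        return StructureModel(atoms, "toy_two_spheres"), _two_sphere_truth(d, r1, r2, probe)
    if recipe == "point_cloud_pair":
        n = params.get("n", 10)
        cloud = rng.normal(scale=5.0, size=(n, 3))
        R = _rotation_from_seed(rng)
        t = rng.normal(scale=10.0, size=3)
        moved = cloud @ R.T + t
        atoms = [
            AtomRecord("A", i + 1, "GLY", "CA", "C", *map(float, cloud[i])) for i in range(n)
        ] + [
            AtomRecord("B", i + 1, "GLY", "CA", "C", *map(float, moved[i])) for i in range(n)
        ]
        return (
            StructureModel(atoms, "toy_cloud_pair"),
            {"rotation": R, "translation": t, "rmsd": 0.0},
        )
    if recipe == "donor_acceptor":
        r = params.get("r", 2.9)
        atoms = [
            AtomRecord("A", 1, "ALA", "N", "N", 0.0, 0.0, 0.0),
            AtomRecord("A", 1, "ALA", "CA", "C", 1.46, 0.0, 0.0),
            AtomRecord("B", 2, "ALA", "C", "C", -r - 1.23, 0.0, 0.0),
            AtomRecord("B", 2, "ALA", "O", "O", -r, 0.0, 0.0),
        ]
        return (
            StructureModel(atoms, "toy_donor_acceptor"),
            {"n_hbonds": 1 if r <= 3.5 else 0, "distance": r},
        )
    raise ValueError(f"unknown recipe {recipe!r}")
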