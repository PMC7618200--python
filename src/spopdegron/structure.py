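"""Geometry engine for peptide-MATH domain complexes.

Provides the structural operations used to characterize how degron
peptides engage the SPOP MATH domain: PDB/mmCIF loading, Kabsch
superposition and paired-Calpha RMSD, Shrake-Rupley solvent-accessible
surface area (SASA) with a deterministic golden-spiral point set, buried
surface area (BSA) of an interface, hydrogen-bond and hydrophobic-contact
inventories, and mapping of contacts onto signed degron position indices.

Conventions
-----------
* van der Waals radii (Angstrom): C 1.70, N 1.55, O 1.52, S 1.80, P 1.80,
  H 1.20 (configurable).
* H-bond: donor-heavy-atom to acceptor distance <= 3.5 A; when explicit
  hydrogens are present a D-H...A angle >= 120 degrees is additionally
  required.
* Hydrophobic contact: carbon-carbon <= 4.5 A where neither carbon is
  bonded to N or O.
* BSA = SASA(A alone) + SASA(B alone) - SASA(complex), waters excluded;
  the halved "interface area" convention is reported alongside, since
  published buried-area figures use either convention.
"""

from __future__ import annotations

import json
import math
import urllib.request
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "AtomRecord",
    "StructureModel",
    "SuperpositionResult",
    "HBond",
    "Contact",
    "InterfaceReport",
    "Selection",
    "DEFAULT_RADII",
    "load_structure",
    "fetch_structure",
    "write_pdb",
    "kabsch_superpose",
    "ca_rmsd_paired",
    "sphere_points",
    "sasa",
    "buried_surface_area",
    "detect_hbonds",
    "hydrophobic_contacts",
    "interface_report",
    "map_interface_to_degron",
]

#: Default van der Waals radii (Angstrom) by element.
DEFAULT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20}

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass(frozen=True)
class AtomRecord:
    chain: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    alt_loc: str = ""
    insertion_code: str = ""

    def __post_init__(self):
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError("atom coordinates must be finite")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def is_water(self) -> bool:
        return self.residue_name.upper() in WATER_NAMES

    @property
    def key(self):
        return (self.chain, self.residue_number, self.insertion_code, self.atom_name, self.alt_loc)

    def label(self) -> str:
        return f"{self.chain}/{self.residue_name}{self.residue_number}/{self.atom_name}"


@dataclass
class StructureModel:
    """An atomic model: a flat list of atoms plus provenance."""

    atoms: List[AtomRecord]
    source_id: str = ""
    model_number: int = 1

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("a structure model must contain at least one atom")
        keys = [a.key for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate atom keys in structure model")

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms])

    def subset(self, predicate) -> "StructureModel":
        sel = [a for a in self.atoms if predicate(a)]
        if not sel:
            raise ValueError("selection matched no atoms")
        return StructureModel(sel, self.source_id, self.model_number)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        xyz = self.coords() @ np.asarray(rotation).T + np.asarray(translation)
        atoms = [
            replace(a, x=float(p[0]), y=float(p[1]), z=float(p[2]))
            for a, p in zip(self.atoms, xyz)
        ]
        return StructureModel(atoms, self.source_id, self.model_number)

    def find_atom(self, chain: str, residue_number: int, atom_name: str) -> AtomRecord:
        hits = [
            a
            for a in self.atoms
            if a.chain == chain and a.residue_number == residue_number and a.atom_name == atom_name
        ]
        if len(hits) != 1:
            raise LookupError(
                f"expected exactly one {atom_name} in {chain}/{residue_number}, found {len(hits)}"
            )
        return hits[0]


@dataclass(frozen=True)
class Selection:
    """A simple atom predicate: by chain, residue range/set, atom names."""

    chain: Optional[str] = None
    residues: Optional[frozenset] = None
    atom_names: Optional[frozenset] = None
    include_waters: bool = False

    def __call__(self, atom: AtomRecord) -> bool:
        if atom.is_water and not self.include_waters:
            return False
        if self.chain is not None and atom.chain != self.chain:
            return False
        if self.residues is not None and atom.residue_number not in self.residues:
            return False
        if self.atom_names is not None and atom.atom_name not in self.atom_names:
            return False
        return True

    @classmethod
    def parse(cls, text: str) -> "Selection":
        """Parse e.g. ``chain=B`` or ``chain=B,residues=125-141``."""
        kwargs = {}
        for part in text.split(","):
            key, _, value = part.partition("=")
            key = key.strip().lower()
            value = value.strip()
            if key == "chain":
                kwargs["chain"] = value
            elif key == "residues":
                if "-" in value.lstrip("-")[0:]:
                    lo, hi = value.split("-", 1) if not value.startswith("-") else value.rsplit("-", 1)
                    kwargs["residues"] = frozenset(range(int(lo), int(hi) + 1))
                else:
                    kwargs["residues"] = frozenset(int(v) for v in value.split("+"))
            else:
                raise ValueError(f"unknown selection key {key!r}")
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_structure(
    path,
    model: int = 1,
    altloc_policy: str = "highest_occupancy",
) -> StructureModel:
    """Load a PDB or mmCIF file into a :class:`StructureModel`.

    Keeps model 1 by default, retains the highest-occupancy alternate
    location per atom (ties broken by alt-loc identifier), keeps waters
    (flagged via :attr:`AtomRecord.is_water`) and hydrogens if present.
    """
    import gemmi

    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:
        raise IOError(f"failed to parse {path}: {exc}")
    if model < 1 or model > len(st):
        raise IOError(f"{path}: model {model} not present ({len(st)} model(s))")
    gmodel = st[model - 1]
    best = {}
    order = []
    for chain in gmodel:
        for residue in chain:
            for atom in residue:
                key = (chain.name, residue.seqid.num, residue.seqid.icode.strip(), atom.name)
                rec = AtomRecord(
                    chain=chain.name,
                    residue_number=residue.seqid.num,
                    residue_name=residue.name,
                    atom_name=atom.name,
                    element=atom.element.name,
                    x=atom.pos.x,
                    y=atom.pos.y,
                    z=atom.pos.z,
                    occupancy=min(max(atom.occ, 0.0), 1.0),
                    alt_loc=atom.altloc.strip() if isinstance(atom.altloc, str) else (atom.altloc or ""),
                    insertion_code=residue.seqid.icode.strip(),
                )
                if key not in best:
                    best[key] = rec
                    order.append(key)
                elif altloc_policy == "highest_occupancy":
                    cur = best[key]
                    if (rec.occupancy, -ord(rec.alt_loc or "A")) > (cur.occupancy, -ord(cur.alt_loc or "A")):
                        best[key] = rec
    atoms = [replace(best[k], alt_loc="") for k in order]
    return StructureModel(atoms, source_id=path.stem, model_number=model)


def fetch_structure(pdb_id: str, cache_dir=None, timeout: float = 10.0) -> StructureModel:
    """Download deposited coordinates (mmCIF) from the PDB and load them.

    Files are cached under ``cache_dir`` (default ``~/.cache/spopdegron``).
    Requires network access; raises :class:`IOError` when offline.
    """
    pdb_id = pdb_id.lower()
    cache = Path(cache_dir) if cache_dir else Path.home() / ".cache" / "spopdegron"
    cache.mkdir(parents=True, exist_ok=True)
    target = cache / f"{pdb_id}.cif"
    if not target.exists():
        url = f"https://files.rcsb.org/download/{pdb_id.upper()}.cif"
        try:
            with urllib.request.urlopen(url, timeout=timeout) as resp:
                target.write_bytes(resp.read())
        except Exception as exc:
            raise IOError(f"could not fetch {pdb_id.upper()} from the PDB: {exc}")
    return load_structure(target)


def write_pdb(model: StructureModel, path) -> None:
    """Write a minimal PDB file (ATOM/HETATM records only)."""
    lines = []
    for i, a in enumerate(model.atoms, start=1):
        record = "HETATM" if a.is_water else "ATOM  "
        name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3}"
        lines.append(
            f"{record}{i:5d} {name}{a.alt_loc or ' ':1}{a.residue_name:>3} "
            f"{a.chain[:1]:1}{a.residue_number:4d}{a.insertion_code or ' ':1}   "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
            f"          {a.element:>2}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Superposition / RMSD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det=+1
    translation: np.ndarray  # applied as x_fixed = R @ x_moving + t
    rmsd: float
    n_atoms: int


def kabsch_superpose(moving: np.ndarray, fixed: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal rigid superposition (Kabsch, SVD form).

    Returns the proper rotation (reflections corrected, det = +1) and
    translation mapping ``moving`` onto ``fixed``, plus the post-transform
    RMSD.
    """
    P = np.asarray(moving, dtype=float)
    Q = np.asarray(fixed, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("moving and fixed must be equal-shape (n, 3) arrays")
    if len(P) < 3:
        raise ValueError("need at least 3 points to superpose")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return SuperpositionResult(R, t, rmsd, len(P))


def ca_rmsd_paired(
    model_a: StructureModel,
    model_b: StructureModel,
    residue_pairs: Sequence[Tuple[Tuple[str, int], Tuple[str, int]]],
    presuperpose_on: Sequence[Tuple[Tuple[str, int], Tuple[str, int]]] = None,
) -> float:
    """RMSD over paired Calpha atoms after superposing on a separate selection.

    ``residue_pairs`` and ``presuperpose_on`` are sequences of
    ``((chain_a, resnum_a), (chain_b, resnum_b))`` pairs.  Model B is
    superposed onto model A using the Calpha atoms of ``presuperpose_on``
    (e.g. the MATH domains); the RMSD is then evaluated over
    ``residue_pairs`` (e.g. the peptides) WITHOUT refitting on them.  When
    ``presuperpose_on`` is None the models are compared as-is.
    """

    def ca(model, ref):
        chain, resnum = ref
        try:
            return model.find_atom(chain, resnum, "CA").coordinates
        except LookupError:
            raise LookupError(f"missing Calpha for {chain}/{resnum} in {model.source_id or 'model'}")

    if presuperpose_on:
        fit_b = np.array([ca(model_b, pb) for _, pb in presuperpose_on])
        fit_a = np.array([ca(model_a, pa) for pa, _ in presuperpose_on])
        sup = kabsch_superpose(fit_b, fit_a)
        R, t = sup.rotation, sup.translation
    else:
        R, t = np.eye(3), np.zeros(3)
    A = np.array([ca(model_a, pa) for pa, _ in residue_pairs])
    B = np.array([ca(model_b, pb) for _, pb in residue_pairs]) @ R.T + t
    diff = A - B
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


# ---------------------------------------------------------------------------
# SASA / BSA (Shrake-Rupley, deterministic golden-spiral sphere points)
# ---------------------------------------------------------------------------

def sphere_points(n: int) -> np.ndarray:
    """n points quasi-uniformly distributed on the unit sphere (Fibonacci
    golden-spiral lattice; fully deterministic)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = k * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _radii_for(model: StructureModel, radii: dict, default_radius: float = None) -> np.ndarray:
    out = np.empty(len(model.atoms))
    for i, a in enumerate(model.atoms):
        el = a.element.upper() or a.atom_name[:1].upper()
        if el in radii:
            out[i] = radii[el]
        elif default_radius is not None:
            out[i] = default_radius
        else:
            raise ValueError(
                f"no van der Waals radius for element {el!r} ({a.label()}); "
                "pass default_radius to assign one"
            )
    return out


def sasa(
    model: StructureModel,
    probe_radius: float = 1.4,
    points_per_atom: int = 960,
    radii: dict = None,
    default_radius: float = None,
    ignore_waters: bool = True,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Shrake-Rupley), A^2.

    Each atom's area is the accessible fraction of its expanded sphere
    (radius + probe) times ``4*pi*(radius+probe)**2``, estimated on a
    deterministic golden-spiral point set, so results are bit-stable across
    runs.  Waters are excluded by default (their areas report as 0).
    """
    radii = radii or DEFAULT_RADII
    keep = np.array([not (ignore_waters and a.is_water) for a in model.atoms])
    xyz = model.coords()
    rads = _radii_for(model, radii, default_radius)
    R = rads + probe_radius
    areas = np.zeros(len(model.atoms))
    idx = np.where(keep)[0]
    if len(idx) == 0:
        return areas
    pts = sphere_points(points_per_atom)
    sub_xyz, sub_R = xyz[idx], R[idx]
    tree = cKDTree(sub_xyz)
    rmax = float(sub_R.max())
    for j, i in enumerate(idx):
        neighbors = [k for k in tree.query_ball_point(sub_xyz[j], sub_R[j] + rmax) if k != j]
        surface = sub_xyz[j] + sub_R[j] * pts
        if neighbors:
            nb_xyz = sub_xyz[neighbors]
            nb_R = sub_R[neighbors]
            d2 = np.sum((surface[:, None, :] - nb_xyz[None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < (nb_R**2)[None, :], axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * math.pi * sub_R[j] ** 2
    return areas


def buried_surface_area(
    complex_model: StructureModel,
    selection_a,
    selection_b,
    probe_radius: float = 1.4,
    points_per_atom: int = 960,
    radii: dict = None,
    default_radius: float = None,
) -> dict:
    """Buried surface area of an interface: SASA(A) + SASA(B) - SASA(A+B).

    Waters are always excluded.  Returns both the summed total and the
    halved "interface area" convention, since published figures use either.
    """
    sel_a = _as_predicate(selection_a)
    sel_b = _as_predicate(selection_b)
    atoms_a = [a for a in complex_model.atoms if not a.is_water and sel_a(a)]
    atoms_b = [a for a in complex_model.atoms if not a.is_water and sel_b(a)]
    if not atoms_a or not atoms_b:
        raise ValueError("both selections must be non-empty")
    keys_a = {a.key for a in atoms_a}
    if any(a.key in keys_a for a in atoms_b):
        raise ValueError("selections must be disjoint")
    kw = dict(
        probe_radius=probe_radius,
        points_per_atom=points_per_atom,
        radii=radii,
        default_radius=default_radius,
        ignore_waters=True,
    )
    src = complex_model.source_id
    sasa_a = float(np.sum(sasa(StructureModel(atoms_a, src), **kw)))
    sasa_b = float(np.sum(sasa(StructureModel(atoms_b, src), **kw)))
    sasa_ab = float(np.sum(sasa(StructureModel(atoms_a + atoms_b, src), **kw)))
    bsa = sasa_a + sasa_b - sasa_ab
    return {
        "bsa_total": bsa,
        "interface_area": bsa / 2.0,
        "sasa_a": sasa_a,
        "sasa_b": sasa_b,
        "sasa_complex": sasa_ab,
    }


# ---------------------------------------------------------------------------
# H-bonds and hydrophobic contacts
# ---------------------------------------------------------------------------

# Donor heavy atoms (the attached hydrogen points at the acceptor).
_SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TRP": {"NE1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
}
_SIDECHAIN_ACCEPTORS = {
    "ASN": {"OD1"},
    "ASP": {"OD1", "OD2"},
    "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "MET": {"SD"},
}

# Carbons bonded to N or O (excluded from hydrophobic contacts), by residue;
# the backbone carbonyl C and CA (bonded to N) are excluded for all residues.
_POLAR_CARBONS = {
    "ARG": {"CD", "CZ"},
    "ASN": {"CG"},
    "ASP": {"CG"},
    "GLN": {"CD"},
    "GLU": {"CD"},
    "HIS": {"CG", "CD2", "CE1"},
    "LYS": {"CE"},
    "PRO": {"CD"},
    "SER": {"CB"},
    "THR": {"CB"},
    "TRP": {"CD1", "CE2"},
    "TYR": {"CZ"},
}


def _is_donor(a: AtomRecord) -> bool:
    if a.is_water:
        return False
    if a.atom_name == "N" and a.residue_name != "PRO":
        return True
    return a.atom_name in _SIDECHAIN_DONORS.get(a.residue_name, ())


def _is_acceptor(a: AtomRecord) -> bool:
    if a.is_water:
        return False
    if a.atom_name in ("O", "OXT"):
        return True
    return a.atom_name in _SIDECHAIN_ACCEPTORS.get(a.residue_name, ())


def _is_apolar_carbon(a: AtomRecord) -> bool:
    if a.element.upper() != "C" or a.is_water:
        return False
    if a.atom_name in ("C", "CA"):
        return False
    return a.atom_name not in _POLAR_CARBONS.get(a.residue_name, ())


@dataclass(frozen=True)
class HBond:
    donor: AtomRecord
    acceptor: AtomRecord
    distance: float


@dataclass(frozen=True)
class Contact:
    atom_a: AtomRecord
    atom_b: AtomRecord
    distance: float


def _as_predicate(selection) -> Callable[[AtomRecord], bool]:
    if callable(selection):
        return selection
    if isinstance(selection, str):
        return Selection.parse(selection)
    raise TypeError("selection must be a callable or a selection string")


def _attached_hydrogens(model: StructureModel, donor: AtomRecord) -> list:
    out = []
    for a in model.atoms:
        if (
            a.element.upper() == "H"
            and a.chain == donor.chain
            and a.residue_number == donor.residue_number
        ):
            if float(np.linalg.norm(a.coordinates - donor.coordinates)) < 1.3:
                out.append(a)
    return out


def detect_hbonds(
    model: StructureModel,
    selection_a,
    selection_b,
    max_da_distance: float = 3.5,
    min_dha_angle: float = 120.0,
) -> List[HBond]:
    """Hydrogen bonds between two selections.

    Donor and acceptor roles are enumerated both ways (A-donor/B-acceptor
    and vice versa), so the result is symmetric in the selections.  With
    explicit hydrogens present on a donor, at least one attached H must
    give a D-H...A angle >= ``min_dha_angle``.
    """
    sel_a = _as_predicate(selection_a)
    sel_b = _as_predicate(selection_b)
    group_a = [a for a in model.atoms if sel_a(a)]
    group_b = [a for a in model.atoms if sel_b(a)]
    bonds = []
    seen = set()
    for donors, acceptors in ((group_a, group_b), (group_b, group_a)):
        for d in donors:
            if not _is_donor(d):
                continue
            hydrogens = _attached_hydrogens(model, d)
            for acc in acceptors:
                if not _is_acceptor(acc):
                    continue
                dist = float(np.linalg.norm(d.coordinates - acc.coordinates))
                if dist > max_da_distance or dist < 0.5:
                    continue
                if hydrogens:
                    ok = False
                    for h in hydrogens:
                        v1 = d.coordinates - h.coordinates
                        v2 = acc.coordinates - h.coordinates
                        cosang = float(
                            np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                        )
                        angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                        if angle >= min_dha_angle:
                            ok = True
                            break
                    if not ok:
                        continue
                pair = (d.key, acc.key)
                if pair in seen:
                    continue
                seen.add(pair)
                bonds.append(HBond(d, acc, dist))
    bonds.sort(key=lambda b: (b.donor.key, b.acceptor.key))
    return bonds


def hydrophobic_contacts(
    model: StructureModel,
    selection_a,
    selection_b,
    cutoff: float = 4.5,
) -> List[Contact]:
    """Carbon-carbon contacts <= cutoff where neither carbon is bonded to
    N or O (per the built-in residue topology table)."""
    sel_a = _as_predicate(selection_a)
    sel_b = _as_predicate(selection_b)
    group_a = [a for a in model.atoms if sel_a(a) and _is_apolar_carbon(a)]
    group_b = [a for a in model.atoms if sel_b(a) and _is_apolar_carbon(a)]
    contacts = []
    for a in group_a:
        for b in group_b:
            dist = float(np.linalg.norm(a.coordinates - b.coordinates))
            if dist <= cutoff:
                contacts.append(Contact(a, b, dist))
    contacts.sort(key=lambda c: (c.atom_a.key, c.atom_b.key))
    return contacts


# ---------------------------------------------------------------------------
# Interface report and degron-position mapping
# ---------------------------------------------------------------------------

@dataclass
class InterfaceReport:
    buried_area_total: float
    interface_area: float
    sasa_a: float
    sasa_b: float
    sasa_complex: float
    hbonds: List[HBond]
    hydrophobic_contacts: List[Contact]
    per_degron_position: Optional[pd.DataFrame] = None

    def to_json(self, path=None) -> str:
        payload = {
            "buried_area_total": self.buried_area_total,
            "interface_area": self.interface_area,
            "sasa_a": self.sasa_a,
            "sasa_b": self.sasa_b,
            "sasa_complex": self.sasa_complex,
            "hbonds": [
                {"donor": b.donor.label(), "acceptor": b.acceptor.label(), "distance": b.distance}
                for b in self.hbonds
            ],
            "hydrophobic_contacts": [
                {"atom_a": c.atom_a.label(), "atom_b": c.atom_b.label(), "distance": c.distance}
                for c in self.hydrophobic_contacts
            ],
        }
        if self.per_degron_position is not None:
            payload["per_degron_position"] = self.per_degron_position.to_dict(orient="records")
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def contacts_table(self) -> pd.DataFrame:
        rows = [
            {"kind": "hbond", "atom_a": b.donor.label(), "atom_b": b.acceptor.label(), "distance": b.distance}
            for b in self.hbonds
        ] + [
            {"kind": "hydrophobic", "atom_a": c.atom_a.label(), "atom_b": c.atom_b.label(), "distance": c.distance}
            for c in self.hydrophobic_contacts
        ]
        return pd.DataFrame(rows, columns=["kind", "atom_a", "atom_b", "distance"])


def interface_report(
    complex_model: StructureModel,
    selection_a,
    selection_b,
    probe_radius: float = 1.4,
    points_per_atom: int = 960,
    max_da_distance: float = 3.5,
    contact_cutoff: float = 4.5,
    radii: dict = None,
    default_radius: float = None,
) -> InterfaceReport:
    """Full interface inventory: BSA, hydrogen bonds, hydrophobic contacts."""
    areas = buried_surface_area(
        complex_model,
        selection_a,
        selection_b,
        probe_radius=probe_radius,
        points_per_atom=points_per_atom,
        radii=radii,
        default_radius=default_radius,
    )
    return InterfaceReport(
        buried_area_total=areas["bsa_total"],
        interface_area=areas["interface_area"],
        sasa_a=areas["sasa_a"],
        sasa_b=areas["sasa_b"],
        sasa_complex=areas["sasa_complex"],
        hbonds=detect_hbonds(complex_model, selection_a, selection_b, max_da_distance),
        hydrophobic_contacts=hydrophobic_contacts(
            complex_model, selection_a, selection_b, contact_cutoff
        ),
    )


def degron_index(residue_number: int, anchor: int) -> int:
    """Signed degron index of a residue relative to the +1 anchor (no 0)."""
    return residue_number - anchor + 1 if residue_number >= anchor else residue_number - anchor


def map_interface_to_degron(
    report: InterfaceReport,
    anchor: int,
    peptide_selection,
    motif_indices: Sequence[int] = None,
) -> pd.DataFrame:
    """Label each contact with the signed degron index of its peptide residue.

    ``anchor`` is the 1-based coordinate of position +1 (from a scanner
    match or given directly).  Contacts whose peptide residue falls outside
    ``motif_indices`` (when provided) are labeled ``flank`` rather than
    rejected.  Returns a per-position summary and stores it on the report.
    """
    sel = _as_predicate(peptide_selection)
    counters = {}

    def bump(atom: AtomRecord, kind: str):
        idx = degron_index(atom.residue_number, anchor)
        if motif_indices is not None and idx not in motif_indices:
            label = "flank"
        else:
            label = f"{idx:+d}"
        entry = counters.setdefault(
            (idx, label), {"index": label, "residue": f"{atom.residue_name}{atom.residue_number}", "hbonds": 0, "hydrophobic_contacts": 0}
        )
        entry[kind] += 1

    for b in report.hbonds:
        pep = b.donor if sel(b.donor) else (b.acceptor if sel(b.acceptor) else None)
        if pep is not None:
            bump(pep, "hbonds")
    for c in report.hydrophobic_contacts:
        pep = c.atom_a if sel(c.atom_a) else (c.atom_b if sel(c.atom_b) else None)
        if pep is not None:
            bump(pep, "hydrophobic_contacts")
    rows = [counters[k] for k in sorted(counters)]
    table = pd.DataFrame(rows, columns=["index", "residue", "hbonds", "hydrophobic_contacts"])
    report.per_degron_position = table
    return table
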