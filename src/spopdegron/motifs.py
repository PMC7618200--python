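"""Position-specific degron consensus models for the SPOP MATH domain.

SPOP, the substrate adaptor of a Cullin-3 E3 ubiquitin ligase, recognizes
short linear degrons through its MATH domain.  The classic five-residue
SPOP-binding consensus (SBC) is phi-pi-S-S/T-S/T, where phi is a nonpolar
and pi a polar residue.  High-affinity substrates such as MyD88 carry an
additional N-terminal element, the Q-motif, with an invariant glutamine at
signed position -4.  This module defines the residue-class schemes and the
position-indexed consensus models ("degron consensus") used to describe
both, compiles them from compact dash-delimited specification strings, and
derives consensus strings from aligned degron windows.

Coordinate convention
---------------------
Degron positions are numbered relative to the SBC: the first SBC residue is
position +1, positions N-terminal to it are -1, -2, ... There is no
position 0.  Sequence coordinates elsewhere in the package are 1-based
inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AA20",
    "ResidueClassScheme",
    "ConsensusPosition",
    "DegronConsensus",
    "DEFAULT_SCHEME",
    "CLASSIC_SBC",
    "LONG_DEGRON",
    "SEARCH_MOTIF_17",
    "compile_consensus",
    "classify_residue",
    "consensus_from_alignment",
    "random_match_probability",
    "load_scheme",
    "load_motif",
    "builtin_motif",
    "load_background",
    "builtin_background",
    "uniform_background",
]

#: The 20 standard amino acids, one-letter codes.
AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")

# Greek class symbols with ASCII aliases accepted in spec strings / configs.
PHI = "φ"  # φ nonpolar
PI = "π"  # π polar
LAM = "λ"  # λ medium-or-large
_SYMBOL_ALIASES = {
    "phi": PHI,
    "pi": PI,
    "lambda": LAM,
    "lam": LAM,
    "Φ": PHI,  # upper-case phi
    "Π": PI,  # upper-case pi
    "Λ": LAM,
    "x": "X",
}


class MotifSpecError(ValueError):
    """Raised for malformed consensus specification strings or schemes."""


def _canonical_symbol(token: str) -> str:
    return _SYMBOL_ALIASES.get(token, _SYMBOL_ALIASES.get(token.lower(), token))


@dataclass(frozen=True)
class ResidueClassScheme:
    """A named mapping from class symbols to residue sets.

    Invariants: every member is one of the 20 standard residues; ``X`` maps
    to the full 20-residue set; phi/pi/lambda are non-empty proper subsets.
    """

    name: str
    classes: Mapping[str, frozenset]

    def __post_init__(self):
        cls = {k: frozenset(v) for k, v in self.classes.items()}
        object.__setattr__(self, "classes", cls)
        for sym, members in cls.items():
            if not members <= AA20:
                bad = sorted(members - AA20)
                raise MotifSpecError(
                    f"scheme {self.name!r}: class {sym!r} contains non-standard "
                    f"residues {bad}"
                )
        if cls.get("X") != AA20:
            raise MotifSpecError(f"scheme {self.name!r}: class X must be all 20 residues")
        for sym in (PHI, PI, LAM):
            members = cls.get(sym, frozenset())
            if not members or members == AA20:
                raise MotifSpecError(
                    f"scheme {self.name!r}: class {sym!r} must be a non-empty "
                    "proper subset of the 20 residues"
                )

    def __contains__(self, symbol: str) -> bool:
        return _canonical_symbol(symbol) in self.classes

    def members(self, symbol: str) -> frozenset:
        sym = _canonical_symbol(symbol)
        try:
            return self.classes[sym]
        except KeyError:
            raise MotifSpecError(f"unknown class symbol {symbol!r} in scheme {self.name!r}")


def _default_scheme() -> ResidueClassScheme:
    # phi covers every +1 residue seen in SPOP degrons (V, I, ...); pi covers
    # +2 instances (D, T, S, ...); lambda ("medium or large") is everything
    # except the small side chains G, A, S and C.
    phi = frozenset("GAVLIPFMWC")
    pi = frozenset("STNQDEHKRY")
    lam = AA20 - frozenset("GASC")
    return ResidueClassScheme("default", {PHI: phi, PI: pi, LAM: lam, "X": AA20})


DEFAULT_SCHEME = _default_scheme()


@dataclass(frozen=True)
class ConsensusPosition:
    """One motif column: a signed index, its allowed residues, and the
    symbol it was compiled from (kept for verbatim serialization)."""

    index: int
    allowed: frozenset
    symbol: str

    @property
    def offset(self) -> int:
        """0-based offset from the +1 anchor (no position 0 exists)."""
        return self.index - 1 if self.index > 0 else self.index


@dataclass(frozen=True)
class DegronConsensus:
    """A position-indexed degron model in SBC-anchored coordinates."""

    name: str
    positions: tuple

    def __post_init__(self):
        object.__setattr__(self, "positions", tuple(self.positions))
        idx = [p.index for p in self.positions]
        if 0 in idx:
            raise MotifSpecError("position index 0 is not part of the coordinate system")
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise MotifSpecError("position indices must be strictly increasing")
        if 1 not in idx:
            raise MotifSpecError("the +1 anchor position must be present")
        for p in self.positions:
            if not p.allowed or not p.allowed <= AA20:
                raise MotifSpecError(
                    f"position {p.index:+d}: allowed set must be a non-empty "
                    "subset of the 20 standard residues"
                )

    def __getitem__(self, index: int) -> ConsensusPosition:
        for p in self.positions:
            if p.index == index:
                return p
        raise KeyError(index)

    @property
    def indices(self) -> tuple:
        return tuple(p.index for p in self.positions)

    @property
    def constrained(self) -> tuple:
        """Positions whose allowed set is smaller than all 20 residues."""
        return tuple(p for p in self.positions if p.allowed != AA20)

    def to_spec_string(self) -> str:
        """Serialize back to the dash-delimited token form."""
        return "-".join(p.symbol for p in self.positions)

    def allowed_at(self, index: int) -> frozenset:
        return self[index].allowed


def _resolve_token(token: str, scheme: ResidueClassScheme) -> tuple:
    """Resolve one spec token to (allowed set, canonical symbol)."""
    token = token.strip()
    if not token:
        raise MotifSpecError("empty token in specification string")
    sym = _canonical_symbol(token)
    if sym in scheme.classes:
        return scheme.classes[sym], sym
    if "/" in token:
        alts = [a.strip().upper() for a in token.split("/")]
        if not all(len(a) == 1 and a in AA20 for a in alts):
            raise MotifSpecError(f"unknown token {token!r}")
        return frozenset(alts), "/".join(alts)
    if len(token) == 1 and token.upper() in AA20:
        return frozenset(token.upper()), token.upper()
    raise MotifSpecError(f"unknown token {token!r}")


def _index_run(first_index: int, n: int) -> list:
    """n consecutive signed indices starting at first_index, skipping 0."""
    if first_index == 0:
        raise MotifSpecError("first_index must not be 0 (no position 0 exists)")
    out, i = [], first_index
    while len(out) < n:
        if i != 0:
            out.append(i)
        i += 1
    return out


def compile_consensus(
    spec: str,
    scheme: ResidueClassScheme = DEFAULT_SCHEME,
    first_index: int = 1,
    name: str = None,
) -> DegronConsensus:
    """Compile a dash-delimited consensus string into a :class:`DegronConsensus`.

    Tokens are class symbols known to the scheme (``φ``/``phi``, ``π``/``pi``,
    ``λ``/``lambda``, ``X``), single residues (``Q``), or slash-joined
    alternatives (``S/T``).  Position indices run consecutively from
    ``first_index``, skipping 0.

    >>> m = compile_consensus("φ-π-S-S/T-S/T", first_index=1)
    >>> m.indices
    (1, 2, 3, 4, 5)
    """
    tokens = spec.split("-")
    indices = _index_run(first_index, len(tokens))
    positions = []
    for idx, tok in zip(indices, tokens):
        allowed, sym = _resolve_token(tok, scheme)
        positions.append(ConsensusPosition(idx, allowed, sym))
    return DegronConsensus(name or spec, tuple(positions))


def classify_residue(residue: str, class_symbol: str, scheme: ResidueClassScheme = DEFAULT_SCHEME) -> bool:
    """True iff ``residue`` belongs to the class.

    Non-standard letters (B, J, O, U, X, Z, ...) are members of no class
    except ``X`` — and not even ``X``, which maps to the 20 standard
    residues only; an unknown residue therefore never satisfies any class.
    """
    members = scheme.members(class_symbol)
    return residue.upper() in members


# Specificity-ordered vocabulary for consensus derivation: a column is
# summarized by the FIRST entry whose residue set covers everything observed.
def _vocabulary(scheme: ResidueClassScheme):
    yield None, None  # placeholder: literal handled separately
    yield "S/T", frozenset("ST")
    yield PHI, scheme.members(PHI)
    yield PI, scheme.members(PI)
    yield LAM, scheme.members(LAM)
    yield "X", AA20


def consensus_from_alignment(
    windows: Sequence[str],
    first_index: int,
    scheme: ResidueClassScheme = DEFAULT_SCHEME,
    reference: str = None,
) -> str:
    """Derive a dash-delimited consensus string from aligned degron windows.

    All windows must be the same length and anchored on the same +1
    coordinate.  Each column is summarized by the most specific symbol from
    the fixed vocabulary [literal residue, S/T, phi, pi, lambda, X] whose
    residue set contains every observed residue; the ordering makes ties
    impossible.

    If ``reference`` (a spec string over the same positions) is supplied and
    the derived consensus is strictly more specific at any position, a
    warning is emitted — manually assembled consensus strings are often
    deliberately looser than the observed windows.
    """
    if not windows:
        raise ValueError("at least one window is required")
    length = len(windows[0])
    if any(len(w) != length for w in windows):
        raise ValueError("all windows must have equal length")
    ups = [w.upper() for w in windows]
    for w in ups:
        if not set(w) <= AA20:
            raise ValueError(f"window {w!r} contains non-standard residues")
    _index_run(first_index, length)  # validates first_index
    tokens = []
    for col in range(length):
        observed = frozenset(w[col] for w in ups)
        if len(observed) == 1:
            tokens.append(next(iter(observed)))
            continue
        for sym, members in _vocabulary(scheme):
            if sym is not None and observed <= members:
                tokens.append(sym)
                break
    result = "-".join(tokens)
    if reference is not None:
        ref = compile_consensus(reference, scheme, first_index)
        got = compile_consensus(result, scheme, first_index)
        tighter = [
            p.index
            for p, q in zip(got.positions, ref.positions)
            if p.allowed < q.allowed
        ]
        if tighter:
            warnings.warn(
                "derived consensus is more specific than the reference at "
                f"position(s) {tighter}: derived {result!r} vs reference {reference!r}",
                stacklevel=2,
            )
    return result


def _validate_background(background: Mapping[str, float]) -> dict:
    freqs = {k.upper(): float(v) for k, v in background.items()}
    if set(freqs) != set(AA20):
        raise ValueError("background must assign a frequency to each of the 20 residues")
    if any(v < 0 for v in freqs.values()):
        raise ValueError("background frequencies must be non-negative")
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"background frequencies must sum to 1 (got {total})")
    return freqs


def uniform_background() -> dict:
    return {aa: 1.0 / 20.0 for aa in sorted(AA20)}


def random_match_probability(
    consensus: DegronConsensus, background: Mapping[str, float] = None
) -> float:
    """Probability that an i.i.d. background sequence matches at one anchor.

    The product over constrained positions of the summed background
    frequency of each position's allowed set; unconstrained (X) positions
    contribute a factor of 1.
    """
    freqs = _validate_background(background or uniform_background())
    p = 1.0
    for pos in consensus.constrained:
        p *= sum(freqs[aa] for aa in pos.allowed)
    return p


# ---------------------------------------------------------------------------
# Plain-text configs (key = value), shipped built-ins
# ---------------------------------------------------------------------------

def _parse_config_lines(lines: Iterable[str]) -> dict:
    out = {}
    for raw in lines:
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise MotifSpecError(f"malformed config line: {raw.rstrip()!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        out[key] = value
    return out


def load_scheme(path) -> ResidueClassScheme:
    """Load a residue-class scheme from a plain-text config.

    Keys are class symbols (Greek or ASCII aliases), values are residue
    strings; ``name`` is optional.  ``X`` defaults to all 20 residues.
    """
    entries = _parse_config_lines(Path(path).read_text().splitlines())
    name = entries.pop("name", Path(path).stem)
    classes = {"X": AA20}
    for key, value in entries.items():
        classes[_canonical_symbol(key)] = frozenset(value.replace(" ", "").upper())
    return ResidueClassScheme(name, classes)


def load_motif(path, scheme: ResidueClassScheme = DEFAULT_SCHEME) -> DegronConsensus:
    """Load a motif from a plain-text config mapping position index to a
    residue set or class symbol (``-4 = Q``, ``+1 = φ``, ``+4 = S/T``)."""
    entries = _parse_config_lines(Path(path).read_text().splitlines())
    name = entries.pop("name", Path(path).stem)
    positions = []
    for key, value in entries.items():
        try:
            idx = int(key)
        except ValueError:
            raise MotifSpecError(f"motif config key {key!r} is not a position index")
        allowed, sym = _resolve_token(value, scheme)
        positions.append(ConsensusPosition(idx, allowed, sym))
    positions.sort(key=lambda p: p.index)
    return DegronConsensus(name, tuple(positions))


def load_background(path) -> dict:
    """Load a residue-frequency table from a plain-text config (``A = 0.07``)."""
    entries = _parse_config_lines(Path(path).read_text().splitlines())
    entries.pop("name", None)
    return _validate_background({k: float(v) for k, v in entries.items()})


def builtin_background(name: str = "vertebrate") -> dict:
    files = {"vertebrate": "vertebrate_background.cfg"}
    with resources.as_file(resources.files("spopdegron.data") / files[name]) as p:
        return load_background(p)


def builtin_motif(name: str, scheme: ResidueClassScheme = DEFAULT_SCHEME) -> DegronConsensus:
    """Load one of the packaged motifs: ``sbc``, ``long`` or ``search17``."""
    files = {"sbc": "classic_sbc.cfg", "long": "long_degron.cfg", "search17": "search_motif_17.cfg"}
    try:
        fname = files[name]
    except KeyError:
        raise MotifSpecError(f"unknown built-in motif {name!r}; choose from {sorted(files)}")
    with resources.as_file(resources.files("spopdegron.data") / fname) as p:
        return load_motif(p, scheme)


#: The classic five-residue SBC, phi-pi-S-S/T-S/T at positions +1..+5.
CLASSIC_SBC = compile_consensus("φ-π-S-S/T-S/T", DEFAULT_SCHEME, first_index=1, name="classic_sbc")

#: The expanded ten-residue long degron, lambda-Q-X-X-X-phi-pi-S-X-X at -5..+5,
#: combining the Q-motif (-5/-4) with an SBC whose +4/+5 are unconstrained.
LONG_DEGRON = compile_consensus("λ-Q-X-X-X-φ-π-S-X-X", DEFAULT_SCHEME, first_index=-5, name="long_degron")


def _search_motif_17() -> DegronConsensus:
    # 17 positions -9..+8; constrained only at -5 (LVIEDQN), -4 (QNE),
    # +1 (phi), +2 (pi), +3 (S); every other position allows any residue.
    tokens = ["X"] * 4 + ["L/V/I/E/D/Q/N", "Q/N/E"] + ["X"] * 3 + ["φ", "π", "S"] + ["X"] * 5
    return compile_consensus("-".join(tokens), DEFAULT_SCHEME, first_index=-9, name="search_motif_17")


#: The 17-residue search motif used to find Q-motif substrates, -9..+8.
SEARCH_MOTIF_17 = _search_motif_17()
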