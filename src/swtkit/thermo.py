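"""Nearest-neighbor RNA thermodynamics: folding, complex partition functions
(complex size <= 2), and dilute test-tube equilibrium concentrations.

The physical engine behind all SWT screening.  The model is a loop-based
nearest-neighbor free-energy model at a fixed temperature (default 37 C):

* stacked pairs score Watson-Crick / wobble stack free energies,
* hairpin / bulge / internal loops score size-dependent initiation penalties
  (logarithmically extrapolated beyond the tabulated sizes),
* multiloops score an affine penalty per loop and per branch,
* a bimolecular complex pays one duplex-initiation penalty,
* in a two-strand complex any loop whose face contains the strand nick is
  scored as an exterior loop (zero penalty, no constraint on its size).

Simplifications relative to a full Turner model (no dangles, no coaxial
stacking, no terminal-AU penalties, no single-bulge stack, no homodimer
symmetry corrections, no pseudoknots) are deliberate and documented; only
orderings and qualitative screens are claimed relative to reference engines.

Dynamic programs (O(n^3)-ish, numba-compiled) compute minimum free energy and
partition functions; :func:`enumerate_structures` is an independent exhaustive
oracle for short inputs, against which the DP is tested exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from numba import njit

from .core_seq import NucSeq, as_rna

GAS_CONSTANT_KCAL = 0.0019872  # kcal / (mol K)

_INF = 1e18

__all__ = [
    "EnergyModel",
    "SecondaryStructure",
    "StructureError",
    "NumericalError",
    "TubeSpec",
    "TubeResult",
    "UnstructuredReport",
    "structure_energy",
    "enumerate_structures",
    "fold_mfe",
    "partition_function",
    "duplex_dG",
    "equilibrium_concentrations",
    "is_unstructured",
]


class StructureError(ValueError):
    """A secondary structure is invalid for the given strands."""


class NumericalError(RuntimeError):
    """The equilibrium solver failed to converge."""


# ---------------------------------------------------------------------------
# Energy model
# ---------------------------------------------------------------------------

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
_PAIR_INDEX = {"AU": 0, "UA": 1, "CG": 2, "GC": 3, "GU": 4, "UG": 5}

_HAIRPIN_ARR_SIZE = 4096  # supports transcripts up to ~4 kb


def encode(seq: NucSeq) -> np.ndarray:
    """Integer-encode an RNA sequence (A=0, C=1, G=2, U=3)."""
    return np.array([_BASE_CODE[ch] for ch in as_rna(seq)], dtype=np.int64)


@dataclass
class EnergyModel:
    """Nearest-neighbor parameter set plus temperature.

    ``stack[p1, p2]`` is the stack free energy (kcal/mol) for closing pair
    ``p1 = (i, j)`` over inner pair ``p2 = (i+1, j-1)`` with pair types indexed
    AU, UA, CG, GC, GU, UG.  Loop arrays are indexed by unpaired loop size.
    ``RT`` is derived from the temperature and never hard-coded.
    """

    temperature: float
    stack: np.ndarray
    hairpin_arr: np.ndarray
    bulge_arr: np.ndarray
    internal_arr: np.ndarray
    ml_closing: float
    ml_branch: float
    ml_unpaired: float
    duplex_init: float
    max_interior: int
    min_hairpin: int
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        # the dynamic programs assume free multiloop unpaired bases
        if self.ml_unpaired != 0.0:
            raise ValueError("only ml_unpaired == 0 is supported")
        self.ptype = np.full((4, 4), -1, dtype=np.int64)
        for pair, idx in _PAIR_INDEX.items():
            self.ptype[_BASE_CODE[pair[0]], _BASE_CODE[pair[1]]] = idx
        # memos keyed by normalized sequence(s); screening revisits the same
        # strands and duplexes many times
        self._pf_cache: dict[tuple[str, ...], tuple[float, float]] = {}
        self._mfe_cache: dict[str, tuple["SecondaryStructure", float]] = {}

    @property
    def RT(self) -> float:
        return GAS_CONSTANT_KCAL * self.temperature

    @classmethod
    def default(cls, temperature: float = 310.15) -> "EnergyModel":
        """The bundled Turner-style table at the given temperature (K)."""
        raw = json.loads(
            resources.files("swtkit.data").joinpath("nn_parameters.json").read_text()
        )
        RT = GAS_CONSTANT_KCAL * temperature
        coeff = raw["loop_extrapolation_coeff"]

        stack = np.zeros((6, 6))
        for key, val in raw["stack_dG"].items():
            p1, p2 = key.split(".")
            stack[_PAIR_INDEX[p1], _PAIR_INDEX[p2]] = val

        def build(table: dict, size: int) -> np.ndarray:
            arr = np.full(size, _INF)
            sizes = sorted(int(k) for k in table)
            for s in sizes:
                arr[s] = table[str(s)]
            nmax, vmax = sizes[-1], table[str(sizes[-1])]
            for s in range(nmax + 1, size):
                arr[s] = vmax + coeff * RT * math.log(s / nmax)
            return arr

        model = cls(
            temperature=temperature,
            stack=stack,
            hairpin_arr=build(raw["hairpin_loop_dG"], _HAIRPIN_ARR_SIZE),
            bulge_arr=build(raw["bulge_dG"], raw["max_interior_size"] + 1),
            internal_arr=build(raw["internal_loop_dG"], raw["max_interior_size"] + 1),
            ml_closing=raw["multiloop_dG"]["closing"],
            ml_branch=raw["multiloop_dG"]["branch"],
            ml_unpaired=raw["multiloop_dG"]["unpaired"],
            duplex_init=raw["duplex_init_dG"],
            max_interior=raw["max_interior_size"],
            min_hairpin=raw["min_hairpin_loop"],
            name=raw["name"],
        )
        return model

    # -- python-side loop energies (used by the explicit evaluator/oracle) --

    def pair_type(self, a: str, b: str) -> int:
        return int(self.ptype[_BASE_CODE[a], _BASE_CODE[b]])

    def can_pair(self, a: str, b: str) -> bool:
        return self.pair_type(a, b) >= 0

    def hairpin_dG(self, n: int) -> float:
        if n < self.min_hairpin:
            raise StructureError(f"hairpin loop of size {n} < {self.min_hairpin}")
        return float(self.hairpin_arr[n])

    def bulge_dG(self, n: int) -> float:
        n = min(n, len(self.bulge_arr) - 1)
        return float(self.bulge_arr[n])

    def internal_dG(self, n: int) -> float:
        n = min(n, len(self.internal_arr) - 1)
        return float(self.internal_arr[n])


# ---------------------------------------------------------------------------
# Secondary structures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free secondary structure over one or two ordered strands.

    ``pairs`` holds (i, j) index pairs, i < j, over the strand concatenation;
    ``strand_lengths`` records where the nick sits.  The textual form uses
    dot-bracket notation with ``&`` separating strands.
    """

    strand_lengths: tuple[int, ...]
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        if not 1 <= len(self.strand_lengths) <= 2:
            raise StructureError("only 1 or 2 strands are supported")
        n = sum(self.strand_lengths)
        seen: set[int] = set()
        for (i, j) in self.pairs:
            if not (0 <= i < j < n):
                raise StructureError(f"pair ({i},{j}) out of range")
            if i in seen or j in seen:
                raise StructureError("an index occurs in more than one pair")
            seen.update((i, j))
        plist = sorted(self.pairs)
        for a in range(len(plist)):
            i, j = plist[a]
            for (k, l) in plist[a + 1 :]:
                if i < k <= j < l:
                    raise StructureError(
                        f"pairs ({i},{j}) and ({k},{l}) cross (pseudoknot)"
                    )

    @property
    def nick(self) -> int | None:
        """Index of the first base of the second strand, or None."""
        return self.strand_lengths[0] if len(self.strand_lengths) == 2 else None

    @property
    def n_total(self) -> int:
        return sum(self.strand_lengths)

    @property
    def dot_bracket(self) -> str:
        n = self.n_total
        chars = ["."] * n
        for (i, j) in self.pairs:
            chars[i], chars[j] = "(", ")"
        s = "".join(chars)
        if self.nick is not None:
            s = s[: self.nick] + "&" + s[self.nick :]
        return s

    @classmethod
    def from_dot_bracket(cls, db: str) -> "SecondaryStructure":
        parts = db.split("&")
        if len(parts) > 2:
            raise StructureError("at most one '&' (two strands) is supported")
        lengths = tuple(len(p) for p in parts)
        flat = "".join(parts)
        stack: list[int] = []
        pairs = set()
        for i, ch in enumerate(flat):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                if not stack:
                    raise StructureError(f"unbalanced ')' at position {i}")
                pairs.add((stack.pop(), i))
            elif ch != ".":
                raise StructureError(f"invalid dot-bracket character {ch!r}")
        if stack:
            raise StructureError("unbalanced '(' in dot-bracket string")
        return cls(strand_lengths=lengths, pairs=frozenset(pairs))

    def is_connected(self) -> bool:
        """True when a two-strand structure has >= 1 inter-strand pair
        (trivially true for a single strand)."""
        nick = self.nick
        if nick is None:
            return True
        return any(i < nick <= j for (i, j) in self.pairs)


def _children_map(pairs: list[tuple[int, int]]) -> dict:
    """Map each closing pair (and the virtual root None) to its directly
    nested child pairs, exploiting non-crossing order."""
    children: dict = {None: []}
    stack: list[tuple[int, int]] = []
    for pair in sorted(pairs):
        while stack and pair[0] > stack[-1][1]:
            stack.pop()
        parent = stack[-1] if stack else None
        children.setdefault(pair, [])
        children[parent].append(pair)
        stack.append(pair)
    return children


def _validate_for_strands(
    strands: list[NucSeq], structure: SecondaryStructure, model: EnergyModel
) -> str:
    seq = "".join(as_rna(s) for s in strands)
    if tuple(len(s) for s in strands) != structure.strand_lengths:
        raise StructureError("structure strand lengths do not match the strands")
    nick = structure.nick
    for (i, j) in structure.pairs:
        if not model.can_pair(seq[i], seq[j]):
            raise StructureError(f"{seq[i]}-{seq[j]} at ({i},{j}) is not a valid pair")
    if nick is not None and structure.pairs and not structure.is_connected():
        raise StructureError("two-strand structure has no inter-strand pair")
    return seq


def structure_energy(
    strands: list[NucSeq] | NucSeq,
    structure: SecondaryStructure,
    model: EnergyModel,
) -> float:
    """Free energy (kcal/mol) of an explicit structure by loop decomposition.

    The unpaired open chain scores 0 (the reference state); a two-strand
    complex pays ``duplex_init`` once.  This evaluator is independent of the
    dynamic programs and doubles as the test oracle's energy function.
    """
    if isinstance(strands, str):
        strands = [strands]
    seq = _validate_for_strands(strands, structure, model)
    nick = structure.nick
    pairs = sorted(structure.pairs)
    children = _children_map(pairs)

    def nick_on_face(i: int, j: int, kids: list[tuple[int, int]]) -> bool:
        if nick is None or not (i < nick <= j):
            return False
        return not any(k < nick <= l for (k, l) in kids)

    energy = 0.0
    for (i, j) in pairs:
        kids = children[(i, j)]
        if nick_on_face(i, j, kids):
            continue  # exterior-like face: no penalty, no stack
        if not kids:
            n_unpaired = j - i - 1
            if n_unpaired < model.min_hairpin:
                raise StructureError(
                    f"hairpin closed by ({i},{j}) has loop {n_unpaired} < "
                    f"{model.min_hairpin}"
                )
            energy += model.hairpin_dG(n_unpaired)
        elif len(kids) == 1:
            (k, l) = kids[0]
            s1, s2 = k - i - 1, j - l - 1
            if s1 == 0 and s2 == 0:
                p1 = model.pair_type(seq[i], seq[j])
                p2 = model.pair_type(seq[k], seq[l])
                energy += float(model.stack[p1, p2])
            elif s1 == 0 or s2 == 0:
                energy += model.bulge_dG(s1 + s2)
            else:
                energy += model.internal_dG(s1 + s2)
        else:
            n_unpaired = (j - i - 1) - sum(l - k + 1 for (k, l) in kids)
            energy += (
                model.ml_closing
                + model.ml_branch * (len(kids) + 1)
                + model.ml_unpaired * n_unpaired
            )
    if len(strands) == 2 and pairs:
        energy += model.duplex_init
    return energy


# ---------------------------------------------------------------------------
# Exhaustive enumeration (independent oracle)
# ---------------------------------------------------------------------------

MAX_ENUMERATION_LEN = 20


def enumerate_structures(
    strands: list[NucSeq] | NucSeq,
    model: EnergyModel,
    max_total_len: int = MAX_ENUMERATION_LEN,
) -> list[tuple[SecondaryStructure, float]]:
    """Every valid secondary structure of the input, exactly once, with its
    energy.  For two strands, only connected structures (the complex ensemble)
    are returned.  Guarded to short inputs; this is the brute-force oracle the
    dynamic programs are validated against."""
    if isinstance(strands, str):
        strands = [strands]
    seq = "".join(as_rna(s) for s in strands)
    n = len(seq)
    if n > max_total_len or n > MAX_ENUMERATION_LEN:
        raise StructureError(
            f"enumeration limited to total length {min(max_total_len, MAX_ENUMERATION_LEN)}"
        )
    nick = len(strands[0]) if len(strands) == 2 else None
    lengths = tuple(len(s) for s in strands)

    def pair_ok(i: int, k: int) -> bool:
        if not model.can_pair(seq[i], seq[k]):
            return False
        if k - i - 1 >= model.min_hairpin:
            return True
        return nick is not None and i < nick <= k

    def gen(i: int, j: int):
        if i > j:
            yield ()
            return
        for rest in gen(i + 1, j):
            yield rest
        for k in range(i + 1, j + 1):
            if pair_ok(i, k):
                for inner in gen(i + 1, k - 1):
                    for outer in gen(k + 1, j):
                        yield ((i, k),) + inner + outer

    out = []
    for pairset in gen(0, n - 1):
        struct = SecondaryStructure(strand_lengths=lengths, pairs=frozenset(pairset))
        if nick is not None and not struct.is_connected():
            continue
        out.append((struct, structure_energy(strands, struct, model)))
    return out


# ---------------------------------------------------------------------------
# Dynamic programming kernels (numba)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _interior_energy(s1, s2, p_out, p_in, stack, bulge, internal):
    if s1 == 0 and s2 == 0:
        return stack[p_out, p_in]
    if s1 == 0 or s2 == 0:
        return bulge[s1 + s2]
    return internal[s1 + s2]


@njit(cache=True)
def _fill_mfe_single(codes, ptype, stack, hairpin, bulge, internal,
                     ml_a, ml_c, max_int, min_hp):
    n = codes.shape[0]
    V = np.full((n, n), _INF)
    Wm = np.full((n, n), _INF)
    Wm1 = np.full((n, n), _INF)
    We = np.zeros((n + 1, n + 1))  # We[i, j+1] over [i, j]; empty = 0
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            # V(i, j): minimum energy given (i, j) paired
            p_out = ptype[codes[i], codes[j]]
            if p_out >= 0:
                best = _INF
                if j - i - 1 >= min_hp:
                    best = hairpin[j - i - 1]
                kmax = min(j - 1, i + max_int + 1)
                for k in range(i + 1, kmax + 1):
                    s1 = k - i - 1
                    lmin = max(k + 1, j - 1 - (max_int - s1))
                    for l in range(lmin, j):
                        p_in = ptype[codes[k], codes[l]]
                        if p_in >= 0 and V[k, l] < _INF / 2:
                            e = _interior_energy(s1, j - l - 1, p_out, p_in,
                                                 stack, bulge, internal) + V[k, l]
                            if e < best:
                                best = e
                for k in range(i + 2, j - 1):
                    if Wm[i + 1, k - 1] < _INF / 2 and Wm1[k, j - 1] < _INF / 2:
                        e = ml_a + ml_c + Wm[i + 1, k - 1] + Wm1[k, j - 1]
                        if e < best:
                            best = e
                V[i, j] = best
            # Wm1(i, j): one branch starting at i, tail unpaired
            best = Wm1[i, j - 1] if j - 1 > i else _INF
            if V[i, j] < _INF / 2 and V[i, j] + ml_c < best:
                best = V[i, j] + ml_c
            Wm1[i, j] = best
            # Wm(i, j): >= 1 branch; decompose on the last branch start k
            best = _INF
            for k in range(i, j):
                if Wm1[k, j] >= _INF / 2:
                    continue
                pref = 0.0
                if k > i and Wm[i, k - 1] < 0.0:
                    pref = Wm[i, k - 1]
                e = pref + Wm1[k, j]
                if e < best:
                    best = e
            Wm[i, j] = best
    for j in range(n):
        best = We[0, j]  # j unpaired
        for k in range(j):
            if V[k, j] < _INF / 2:
                e = We[0, k] + V[k, j]
                if e < best:
                    best = e
        if j > 0 and V[0, j] < _INF / 2 and V[0, j] < best:
            best = V[0, j]
        We[0, j + 1] = best
    # full exterior over arbitrary prefixes is enough for single-strand MFE
    return V, Wm, Wm1, We[0]


@njit(cache=True)
def _fill_pf_single(codes, ptype, stack, hairpin, bulge, internal,
                    ml_a, ml_c, max_int, min_hp, RT):
    n = codes.shape[0]
    Qb = np.zeros((n, n))
    Qm = np.zeros((n, n))
    Qm1 = np.zeros((n, n))
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            p_out = ptype[codes[i], codes[j]]
            if p_out >= 0:
                q = 0.0
                if j - i - 1 >= min_hp:
                    q += math.exp(-hairpin[j - i - 1] / RT)
                kmax = min(j - 1, i + max_int + 1)
                for k in range(i + 1, kmax + 1):
                    s1 = k - i - 1
                    lmin = max(k + 1, j - 1 - (max_int - s1))
                    for l in range(lmin, j):
                        if Qb[k, l] > 0.0:
                            p_in = ptype[codes[k], codes[l]]
                            e = _interior_energy(s1, j - l - 1, p_out, p_in,
                                                 stack, bulge, internal)
                            q += math.exp(-e / RT) * Qb[k, l]
                for k in range(i + 2, j - 1):
                    if Qm[i + 1, k - 1] > 0.0 and Qm1[k, j - 1] > 0.0:
                        q += math.exp(-(ml_a + ml_c) / RT) * Qm[i + 1, k - 1] * Qm1[k, j - 1]
                Qb[i, j] = q
            # Qm1
            q = Qm1[i, j - 1] if j - 1 > i else 0.0
            if Qb[i, j] > 0.0:
                q += math.exp(-ml_c / RT) * Qb[i, j]
            Qm1[i, j] = q
            # Qm: last branch starts at k
            q = 0.0
            for k in range(i, j):
                if Qm1[k, j] > 0.0:
                    pref = 1.0
                    if k > i:
                        pref = 1.0 + Qm[i, k - 1]
                    q += pref * Qm1[k, j]
            Qm[i, j] = q
    # exterior
    Qx = np.ones(n + 1)
    for j in range(n):
        q = Qx[j]  # j unpaired
        for k in range(j + 1):
            if Qb[k, j] > 0.0:
                q += Qx[k] * Qb[k, j]
        Qx[j + 1] = q
    return Qx[n]


@njit(cache=True)
def _fill_dimer_tables_pf(codes, nick, ptype, stack, hairpin, bulge, internal,
                          ml_a, ml_c, max_int, min_hp, RT):
    """Within-strand Qb/Qm/Qm1 plus the 2-D exterior table Qe.

    Pairs crossing the nick are excluded here; they are handled by the
    nick-aware recursion in :func:`_pf_dimer`.
    """
    n = codes.shape[0]
    Qb = np.zeros((n, n))
    Qm = np.zeros((n, n))
    Qm1 = np.zeros((n, n))
    Qe = np.ones((n + 1, n))  # Qe[i, j] over [i, j]; row n unused guard
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            crosses = i < nick <= j
            p_out = ptype[codes[i], codes[j]]
            if p_out >= 0 and not crosses:
                q = 0.0
                if j - i - 1 >= min_hp:
                    q += math.exp(-hairpin[j - i - 1] / RT)
                kmax = min(j - 1, i + max_int + 1)
                for k in range(i + 1, kmax + 1):
                    s1 = k - i - 1
                    lmin = max(k + 1, j - 1 - (max_int - s1))
                    for l in range(lmin, j):
                        if Qb[k, l] > 0.0:
                            p_in = ptype[codes[k], codes[l]]
                            e = _interior_energy(s1, j - l - 1, p_out, p_in,
                                                 stack, bulge, internal)
                            q += math.exp(-e / RT) * Qb[k, l]
                for k in range(i + 2, j - 1):
                    if Qm[i + 1, k - 1] > 0.0 and Qm1[k, j - 1] > 0.0:
                        q += math.exp(-(ml_a + ml_c) / RT) * Qm[i + 1, k - 1] * Qm1[k, j - 1]
                Qb[i, j] = q
            q = Qm1[i, j - 1] if j - 1 > i else 0.0
            if Qb[i, j] > 0.0:
                q += math.exp(-ml_c / RT) * Qb[i, j]
            Qm1[i, j] = q
            q = 0.0
            for k in range(i, j):
                if Qm1[k, j] > 0.0:
                    pref = 1.0
                    if k > i:
                        pref = 1.0 + Qm[i, k - 1]
                    q += pref * Qm1[k, j]
            Qm[i, j] = q
    # 2-D exterior (within-strand segments are the only reads, but the full
    # table is cheap to fill)
    for i in range(n):
        for j in range(i, n):
            q = Qe[i, j - 1] if j > i else 1.0
            for k in range(i, j):
                pref = Qe[i, k - 1] if k > i else 1.0
                if Qb[k, j] > 0.0:
                    q += pref * Qb[k, j]
            Qe[i, j] = q
    return Qb, Qm, Qm1, Qe


@njit(cache=True)
def _pf_dimer(codes, nick, ptype, stack, hairpin, bulge, internal,
              ml_a, ml_c, max_int, min_hp, RT, duplex_init):
    """Partition function over *connected* two-strand structures.

    Decomposition: every connected structure has a unique outermost pair
    spanning the nick, and the nick lies on the face of the unique innermost
    spanning pair, which is scored as an exterior (zero-energy) loop.
    """
    n = codes.shape[0]
    Qb, Qm, Qm1, Qe = _fill_dimer_tables_pf(
        codes, nick, ptype, stack, hairpin, bulge, internal,
        ml_a, ml_c, max_int, min_hp, RT)

    def qe(i, j):
        if i > j:
            return 1.0
        return Qe[i, j]

    Qbn = np.zeros((n, n))  # pair (p, q) spanning the nick, nick-aware inside
    for p in range(nick - 1, -1, -1):
        for q in range(nick, n):
            if ptype[codes[p], codes[q]] < 0:
                continue
            p_out = ptype[codes[p], codes[q]]
            # nick on this face: both sides are exterior-style segments
            term = qe(p + 1, nick - 1) * qe(nick, q - 1)
            for k in range(p + 1, nick):
                for l in range(nick, q):
                    if Qbn[k, l] <= 0.0:
                        continue
                    p_in = ptype[codes[k], codes[l]]
                    s1 = k - p - 1
                    s2 = q - l - 1
                    if s1 + s2 <= max_int:
                        e = _interior_energy(s1, s2, p_out, p_in,
                                             stack, bulge, internal)
                        term += math.exp(-e / RT) * Qbn[k, l]
                    # multiloop: (k, l) is the spanning branch; >= 1 more branch
                    left = Qm[p + 1, k - 1] if k - 1 >= p + 1 else 0.0
                    right = Qm[l + 1, q - 1] if q - 1 >= l + 1 else 0.0
                    extra = left * (1.0 + right) + right
                    if extra > 0.0:
                        term += math.exp(-(ml_a + 2.0 * ml_c) / RT) * Qbn[k, l] * extra
            Qbn[p, q] = term

    Q = 0.0
    for p in range(0, nick):
        left = qe(0, p - 1)
        for q in range(nick, n):
            if Qbn[p, q] > 0.0:
                Q += left * Qbn[p, q] * qe(q + 1, n - 1)
    return Q * math.exp(-duplex_init / RT)


@njit(cache=True)
def _fill_dimer_tables_mfe(codes, nick, ptype, stack, hairpin, bulge, internal,
                           ml_a, ml_c, max_int, min_hp):
    n = codes.shape[0]
    V = np.full((n, n), _INF)
    Wm = np.full((n, n), _INF)
    Wm1 = np.full((n, n), _INF)
    We = np.zeros((n + 1, n))
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            crosses = i < nick <= j
            p_out = ptype[codes[i], codes[j]]
            if p_out >= 0 and not crosses:
                best = _INF
                if j - i - 1 >= min_hp:
                    best = hairpin[j - i - 1]
                kmax = min(j - 1, i + max_int + 1)
                for k in range(i + 1, kmax + 1):
                    s1 = k - i - 1
                    lmin = max(k + 1, j - 1 - (max_int - s1))
                    for l in range(lmin, j):
                        p_in = ptype[codes[k], codes[l]]
                        if p_in >= 0 and V[k, l] < _INF / 2:
                            e = _interior_energy(s1, j - l - 1, p_out, p_in,
                                                 stack, bulge, internal) + V[k, l]
                            if e < best:
                                best = e
                for k in range(i + 2, j - 1):
                    if Wm[i + 1, k - 1] < _INF / 2 and Wm1[k, j - 1] < _INF / 2:
                        e = ml_a + ml_c + Wm[i + 1, k - 1] + Wm1[k, j - 1]
                        if e < best:
                            best = e
                V[i, j] = best
            best = Wm1[i, j - 1] if j - 1 > i else _INF
            if V[i, j] < _INF / 2 and V[i, j] + ml_c < best:
                best = V[i, j] + ml_c
            Wm1[i, j] = best
            best = _INF
            for k in range(i, j):
                if Wm1[k, j] >= _INF / 2:
                    continue
                pref = 0.0
                if k > i and Wm[i, k - 1] < 0.0:
                    pref = Wm[i, k - 1]
                e = pref + Wm1[k, j]
                if e < best:
                    best = e
            Wm[i, j] = best
    for i in range(n):
        for j in range(i, n):
            best = We[i, j - 1] if j > i else 0.0
            for k in range(i, j + 1):
                pref = We[i, k - 1] if k > i else 0.0
                if V[k, j] < _INF / 2:
                    e = pref + V[k, j]
                    if e < best:
                        best = e
            We[i, j] = best
    return V, Wm, Wm1, We


@njit(cache=True)
def _fill_dimer_all_mfe(codes, nick, ptype, stack, hairpin, bulge, internal,
                        ml_a, ml_c, max_int, min_hp):
    """All MFE tables for a nicked dimer, including the nick-spanning Vbn."""
    n = codes.shape[0]
    V, Wm, Wm1, We = _fill_dimer_tables_mfe(
        codes, nick, ptype, stack, hairpin, bulge, internal,
        ml_a, ml_c, max_int, min_hp)

    def we(i, j):
        if i > j:
            return 0.0
        return We[i, j]

    Vbn = np.full((n, n), _INF)
    for p in range(nick - 1, -1, -1):
        for q in range(nick, n):
            p_out = ptype[codes[p], codes[q]]
            if p_out < 0:
                continue
            best = we(p + 1, nick - 1) + we(nick, q - 1)
            for k in range(p + 1, nick):
                for l in range(nick, q):
                    if Vbn[k, l] >= _INF / 2:
                        continue
                    p_in = ptype[codes[k], codes[l]]
                    s1 = k - p - 1
                    s2 = q - l - 1
                    if s1 + s2 <= max_int:
                        e = _interior_energy(s1, s2, p_out, p_in,
                                             stack, bulge, internal) + Vbn[k, l]
                        if e < best:
                            best = e
                    left = Wm[p + 1, k - 1] if k - 1 >= p + 1 else _INF
                    right = Wm[l + 1, q - 1] if q - 1 >= l + 1 else _INF
                    extra = _INF
                    if left < _INF / 2:
                        r = right if (right < _INF / 2 and right < 0.0) else 0.0
                        extra = left + r
                    if right < _INF / 2 and right < extra:
                        extra = right
                    if extra < _INF / 2:
                        e = ml_a + 2.0 * ml_c + Vbn[k, l] + extra
                        if e < best:
                            best = e
            Vbn[p, q] = best
    return V, Wm, Wm1, We, Vbn


def _dimer_tables(a_codes, b_codes, model):
    codes = np.concatenate([a_codes, b_codes])
    nick = a_codes.shape[0]
    V, Wm, Wm1, We, Vbn = _fill_dimer_all_mfe(
        codes, nick, model.ptype, model.stack, model.hairpin_arr,
        model.bulge_arr, model.internal_arr, model.ml_closing, model.ml_branch,
        model.max_interior, model.min_hairpin)
    return codes, nick, V, Wm, Wm1, We, Vbn


def _dimer_min(We, Vbn, nick):
    """(E, p, q) minimizing exterior-left + Vbn + exterior-right."""
    n = Vbn.shape[0]
    best, bp, bq = _INF, -1, -1
    for p in range(nick):
        left = We[0, p - 1] if p > 0 else 0.0
        for q in range(nick, n):
            if Vbn[p, q] < _INF / 2:
                right = We[q + 1, n - 1] if q + 1 <= n - 1 else 0.0
                e = left + Vbn[p, q] + right
                if e < best:
                    best, bp, bq = e, p, q
    return best, bp, bq


@njit(cache=True)
def _longest_run_kernel(a, b, pairable):
    """Longest antiparallel complementary run between two strands."""
    n, mlen = a.shape[0], b.shape[0]
    best = 0
    prev = np.zeros(mlen, dtype=np.int64)
    cur = np.zeros(mlen, dtype=np.int64)
    for i in range(n):
        for j in range(mlen):
            if pairable[a[i], b[j]]:
                ext = prev[j + 1] if j + 1 < mlen else 0
                cur[j] = ext + 1
                if cur[j] > best:
                    best = cur[j]
            else:
                cur[j] = 0
        prev, cur = cur, prev
    return best


@njit(cache=True)
def _best_helix_kernel(a, b, ok_a, ok_b, ptype, stack):
    """Most stable single contiguous antiparallel helix between two strands
    (sum of stack terms; kcal/mol, <= 0), restricted to allowed positions."""
    n, mlen = a.shape[0], b.shape[0]
    best = 0.0
    prev = np.zeros(mlen)
    cur = np.zeros(mlen)
    pprev = np.full(mlen, -1, dtype=np.int64)
    pcur = np.full(mlen, -1, dtype=np.int64)
    for i in range(n):
        for j in range(mlen):
            p = ptype[a[i], b[j]] if (ok_a[i] and ok_b[j]) else -1
            pcur[j] = p
            if p >= 0:
                e = 0.0
                if j + 1 < mlen and pprev[j + 1] >= 0:
                    ext = prev[j + 1] + stack[pprev[j + 1], p]
                    if ext < e:
                        e = ext
                cur[j] = e
                if e < best:
                    best = e
            else:
                cur[j] = 0.0
        prev, cur = cur, prev
        pprev, pcur = pcur, pprev
    return best


def exterior_unpaired_mask(seq: NucSeq, model: EnergyModel) -> np.ndarray:
    """Boolean mask of positions outside every pair span of the sequence's
    MFE structure — the positions an inter-strand helix can use without
    crossing the intramolecular fold."""
    struct, _ = fold_mfe(seq, model)
    mask = np.ones(len(as_rna(seq)), dtype=np.bool_)
    for (i, j) in struct.pairs:
        mask[i:j + 1] = False
    return mask


def best_cross_helix_bound(a: NucSeq, b: NucSeq, model: EnergyModel) -> float:
    """Upper bound on the a.b dimer ensemble free energy from one admissible
    structure: each strand in its own MFE fold plus the best contiguous
    inter-strand helix between their exterior-unpaired regions (plus the
    duplex-initiation penalty)."""
    _, mfe_a = fold_mfe(a, model)
    _, mfe_b = fold_mfe(b, model)
    helix = _best_helix_kernel(
        encode(a), encode(b),
        exterior_unpaired_mask(a, model), exterior_unpaired_mask(b, model),
        model.ptype, model.stack)
    return mfe_a + mfe_b + float(helix) + model.duplex_init


def longest_complementary_run(
    a: NucSeq, b: NucSeq, model: EnergyModel, *, include_wobble: bool = False
) -> int:
    """Length of the longest contiguous antiparallel duplex two strands could
    form — a cheap combinatorial bound on their binding.  By default only
    Watson-Crick pairs count (wobble-rich runs can still be weak)."""
    if include_wobble:
        pairable = model.ptype >= 0
    else:
        pairable = (model.ptype >= 0) & (model.ptype < 4)
    return int(_longest_run_kernel(encode(a), encode(b), pairable))


def _model_args(model: EnergyModel):
    return (model.ptype, model.stack, model.hairpin_arr, model.bulge_arr,
            model.internal_arr, model.ml_closing, model.ml_branch,
            model.max_interior, model.min_hairpin)


# ---------------------------------------------------------------------------
# Public folding API
# ---------------------------------------------------------------------------

_EPS = 1e-9


@dataclass(frozen=True)
class UnstructuredReport:
    """Result of :func:`is_unstructured`: truthiness plus diagnostics."""

    unstructured: bool
    mfe_dot_bracket: str = ""
    mfe_dG: float = 0.0

    def __bool__(self) -> bool:
        return self.unstructured


def fold_mfe(seq: NucSeq, model: EnergyModel) -> tuple[SecondaryStructure, float]:
    """Minimum-free-energy structure and energy of a single strand.

    The open chain (0 kcal/mol) is always available, so the reported energy is
    <= 0.  Ties are broken deterministically by the traceback order.
    """
    s = as_rna(seq)
    cached = model._mfe_cache.get(s)
    if cached is not None:
        return cached
    n = len(s)
    if n < 2:
        out = (SecondaryStructure((n,), frozenset()), 0.0)
    else:
        codes = encode(s)
        V, Wm, Wm1, Wext = _fill_mfe_single(codes, *_model_args(model))
        dG = float(Wext[n])
        if dG >= -_EPS:
            out = (SecondaryStructure((n,), frozenset()), 0.0)
        else:
            pairs = _traceback_single(codes, model, V, Wm, Wm1, Wext)
            out = (SecondaryStructure((n,), frozenset(pairs)), dG)
    model._mfe_cache[s] = out
    return out


def _traceback_single(codes, model, V, Wm, Wm1, Wext) -> set[tuple[int, int]]:
    n = len(codes)
    stack_tab = model.stack
    ptype = model.ptype
    eps = 1e-6
    pairs: set[tuple[int, int]] = set()
    tasks: list[tuple] = [("ext", n)]

    def interior_e(i, j, k, l):
        s1, s2 = k - i - 1, j - l - 1
        if s1 == 0 and s2 == 0:
            return float(stack_tab[ptype[codes[i], codes[j]], ptype[codes[k], codes[l]]])
        if s1 == 0 or s2 == 0:
            return model.bulge_dG(s1 + s2)
        return model.internal_dG(s1 + s2)

    while tasks:
        task = tasks.pop()
        kind = task[0]
        if kind == "ext":
            j1 = task[1]  # exterior over [0, j1)
            if j1 <= 0:
                continue
            j = j1 - 1
            if abs(Wext[j1] - Wext[j1 - 1]) < eps:
                tasks.append(("ext", j1 - 1))
                continue
            done = False
            for k in range(j + 1):
                if V[k, j] < _INF / 2 and abs(Wext[j1] - (Wext[k] + V[k, j])) < eps:
                    tasks.append(("ext", k))
                    tasks.append(("V", k, j))
                    done = True
                    break
            if not done:  # pragma: no cover - defensive
                raise RuntimeError("exterior traceback failed")
        elif kind == "V":
            i, j = task[1], task[2]
            pairs.add((i, j))
            e = V[i, j]
            if j - i - 1 >= model.min_hairpin and abs(e - model.hairpin_dG(j - i - 1)) < eps:
                continue
            done = False
            kmax = min(j - 1, i + model.max_interior + 1)
            for k in range(i + 1, kmax + 1):
                s1 = k - i - 1
                lmin = max(k + 1, j - 1 - (model.max_interior - s1))
                for l in range(lmin, j):
                    if (ptype[codes[k], codes[l]] >= 0 and V[k, l] < _INF / 2
                            and abs(e - (interior_e(i, j, k, l) + V[k, l])) < eps):
                        tasks.append(("V", k, l))
                        done = True
                        break
                if done:
                    break
            if done:
                continue
            for k in range(i + 2, j - 1):
                if (Wm[i + 1, k - 1] < _INF / 2 and Wm1[k, j - 1] < _INF / 2
                        and abs(e - (model.ml_closing + model.ml_branch
                                     + Wm[i + 1, k - 1] + Wm1[k, j - 1])) < eps):
                    tasks.append(("Wm", i + 1, k - 1))
                    tasks.append(("Wm1", k, j - 1))
                    done = True
                    break
            if not done:  # pragma: no cover - defensive
                raise RuntimeError(f"V traceback failed at ({i},{j})")
        elif kind == "Wm1":
            i, j = task[1], task[2]
            e = Wm1[i, j]
            for l in range(i + 1, j + 1):
                if V[i, l] < _INF / 2 and abs(e - (V[i, l] + model.ml_branch)) < eps:
                    tasks.append(("V", i, l))
                    break
            else:  # pragma: no cover - defensive
                raise RuntimeError(f"Wm1 traceback failed at ({i},{j})")
        else:  # Wm
            i, j = task[1], task[2]
            e = Wm[i, j]
            done = False
            for k in range(i, j):
                if Wm1[k, j] >= _INF / 2:
                    continue
                if abs(e - Wm1[k, j]) < eps:
                    tasks.append(("Wm1", k, j))
                    done = True
                    break
                if k > i and Wm[i, k - 1] < _INF / 2 and abs(
                        e - (Wm[i, k - 1] + Wm1[k, j])) < eps:
                    tasks.append(("Wm", i, k - 1))
                    tasks.append(("Wm1", k, j))
                    done = True
                    break
            if not done:  # pragma: no cover - defensive
                raise RuntimeError(f"Wm traceback failed at ({i},{j})")
    return pairs


def mfe_energy(strands: list[NucSeq] | NucSeq, model: EnergyModel) -> float:
    """Minimum free energy (kcal/mol) of one strand or a connected dimer."""
    if isinstance(strands, str):
        strands = [strands]
    if len(strands) == 1:
        return fold_mfe(strands[0], model)[1]
    _, nick, _, _, _, We, Vbn = _dimer_tables(
        encode(strands[0]), encode(strands[1]), model)
    e, _, _ = _dimer_min(We, Vbn, nick)
    return float(e) + model.duplex_init if e < _INF / 2 else math.inf


class _DimerTraceback:
    """Recover one MFE structure of a nicked dimer from the DP tables by
    re-deriving each decomposition choice (tolerance 1e-6)."""

    eps = 1e-6

    def __init__(self, codes, nick, model, V, Wm, Wm1, We, Vbn):
        self.codes, self.nick, self.model = codes, nick, model
        self.V, self.Wm, self.Wm1, self.We, self.Vbn = V, Wm, Wm1, We, Vbn
        self.pairs: set[tuple[int, int]] = set()

    def _interior_e(self, i, j, k, l):
        m, codes = self.model, self.codes
        s1, s2 = k - i - 1, j - l - 1
        if s1 == 0 and s2 == 0:
            return float(m.stack[m.ptype[codes[i], codes[j]],
                                 m.ptype[codes[k], codes[l]]])
        if s1 == 0 or s2 == 0:
            return m.bulge_dG(s1 + s2)
        return m.internal_dG(s1 + s2)

    def _we(self, i, j):
        return float(self.We[i, j]) if i <= j else 0.0

    def _wm(self, i, j):
        return float(self.Wm[i, j]) if i <= j else _INF

    def run(self, p, q):
        tasks = [("we", 0, p - 1), ("vbn", p, q), ("we", q + 1, len(self.codes) - 1)]
        while tasks:
            kind, i, j = tasks.pop()
            getattr(self, "_t_" + kind)(i, j, tasks)
        return self.pairs

    def _t_we(self, i, j, tasks):
        if i > j:
            return
        if abs(self.We[i, j] - self._we(i, j - 1)) < self.eps:
            tasks.append(("we", i, j - 1))
            return
        for k in range(i, j + 1):
            pref = self._we(i, k - 1)
            if self.V[k, j] < _INF / 2 and abs(
                    self.We[i, j] - (pref + self.V[k, j])) < self.eps:
                tasks.append(("we", i, k - 1))
                tasks.append(("v", k, j))
                return
        raise RuntimeError(f"exterior traceback failed on [{i},{j}]")

    def _t_v(self, i, j, tasks):
        m = self.model
        self.pairs.add((i, j))
        e = self.V[i, j]
        if j - i - 1 >= m.min_hairpin and abs(e - m.hairpin_dG(j - i - 1)) < self.eps:
            return
        kmax = min(j - 1, i + m.max_interior + 1)
        for k in range(i + 1, kmax + 1):
            s1 = k - i - 1
            lmin = max(k + 1, j - 1 - (m.max_interior - s1))
            for l in range(lmin, j):
                if self.V[k, l] < _INF / 2 and abs(
                        e - (self._interior_e(i, j, k, l) + self.V[k, l])) < self.eps:
                    tasks.append(("v", k, l))
                    return
        for k in range(i + 2, j - 1):
            if (self.Wm[i + 1, k - 1] < _INF / 2 and self.Wm1[k, j - 1] < _INF / 2
                    and abs(e - (m.ml_closing + m.ml_branch + self.Wm[i + 1, k - 1]
                                 + self.Wm1[k, j - 1])) < self.eps):
                tasks.append(("wm", i + 1, k - 1))
                tasks.append(("wm1", k, j - 1))
                return
        raise RuntimeError(f"V traceback failed at ({i},{j})")

    def _t_wm1(self, i, j, tasks):
        for l in range(i + 1, j + 1):
            if self.V[i, l] < _INF / 2 and abs(
                    self.Wm1[i, j] - (self.V[i, l] + self.model.ml_branch)) < self.eps:
                tasks.append(("v", i, l))
                return
        raise RuntimeError(f"Wm1 traceback failed at ({i},{j})")

    def _t_wm(self, i, j, tasks):
        e = self.Wm[i, j]
        for k in range(i, j):
            if self.Wm1[k, j] >= _INF / 2:
                continue
            if abs(e - self.Wm1[k, j]) < self.eps:
                tasks.append(("wm1", k, j))
                return
            if k > i and self.Wm[i, k - 1] < _INF / 2 and abs(
                    e - (self.Wm[i, k - 1] + self.Wm1[k, j])) < self.eps:
                tasks.append(("wm", i, k - 1))
                tasks.append(("wm1", k, j))
                return
        raise RuntimeError(f"Wm traceback failed at ({i},{j})")

    def _t_vbn(self, p, q, tasks):
        m = self.model
        self.pairs.add((p, q))
        e = self.Vbn[p, q]
        nick = self.nick
        if abs(e - (self._we(p + 1, nick - 1) + self._we(nick, q - 1))) < self.eps:
            tasks.append(("we", p + 1, nick - 1))
            tasks.append(("we", nick, q - 1))
            return
        for k in range(p + 1, nick):
            for l in range(nick, q):
                if self.Vbn[k, l] >= _INF / 2:
                    continue
                s1, s2 = k - p - 1, q - l - 1
                if s1 + s2 <= m.max_interior and abs(
                        e - (self._interior_e(p, q, k, l) + self.Vbn[k, l])) < self.eps:
                    tasks.append(("vbn", k, l))
                    return
                base = m.ml_closing + 2.0 * m.ml_branch + self.Vbn[k, l]
                left = self._wm(p + 1, k - 1)
                right = self._wm(l + 1, q - 1)
                if left < _INF / 2 and right < _INF / 2 and abs(
                        e - (base + left + right)) < self.eps:
                    tasks.append(("vbn", k, l))
                    tasks.append(("wm", p + 1, k - 1))
                    tasks.append(("wm", l + 1, q - 1))
                    return
                if left < _INF / 2 and abs(e - (base + left)) < self.eps:
                    tasks.append(("vbn", k, l))
                    tasks.append(("wm", p + 1, k - 1))
                    return
                if right < _INF / 2 and abs(e - (base + right)) < self.eps:
                    tasks.append(("vbn", k, l))
                    tasks.append(("wm", l + 1, q - 1))
                    return
        raise RuntimeError(f"Vbn traceback failed at ({p},{q})")


def fold_mfe_dimer(
    a: NucSeq, b: NucSeq, model: EnergyModel
) -> tuple[SecondaryStructure | None, float]:
    """MFE structure and energy of the connected a.b dimer.

    Returns ``(None, +inf)`` when the strands cannot form any inter-strand
    pair.  The reported energy includes the duplex-initiation penalty.
    """
    a_codes, b_codes = encode(a), encode(b)
    codes, nick, V, Wm, Wm1, We, Vbn = _dimer_tables(a_codes, b_codes, model)
    e, p, q = _dimer_min(We, Vbn, nick)
    if e >= _INF / 2:
        return None, math.inf
    tb = _DimerTraceback(codes, nick, model, V, Wm, Wm1, We, Vbn)
    pairs = tb.run(p, q)
    struct = SecondaryStructure(
        strand_lengths=(len(a_codes), len(b_codes)), pairs=frozenset(pairs))
    return struct, float(e) + model.duplex_init


def partition_function(
    strands: list[NucSeq] | NucSeq, model: EnergyModel
) -> tuple[float, float]:
    """(Q, dG_ensemble) for one strand or an ordered two-strand complex.

    Single strand: Q sums exp(-dG/RT) over all structures including the open
    chain, so Q >= 1 and dG_ensemble <= 0.  Two strands: the sum runs over
    connected structures only and includes the duplex-initiation penalty; with
    no complementarity Q = 0 and dG_ensemble = +inf.
    """
    if isinstance(strands, str):
        strands = [strands]
    if len(strands) not in (1, 2):
        raise ValueError("partition_function supports 1 or 2 strands")
    key = tuple(as_rna(s) for s in strands)
    cached = model._pf_cache.get(key)
    if cached is not None:
        return cached
    RT = model.RT
    if len(key) == 1:
        s = key[0]
        if len(s) < 2:
            out = (1.0, 0.0)
        else:
            Q = float(_fill_pf_single(encode(s), *_model_args(model), RT))
            out = (Q, -RT * math.log(Q))
    else:
        codes = np.concatenate([encode(key[0]), encode(key[1])])
        Q = float(_pf_dimer(codes, len(key[0]), *_model_args(model), RT,
                            model.duplex_init))
        out = (Q, -RT * math.log(Q) if Q > 0 else math.inf)
    model._pf_cache[key] = out
    return out


def duplex_dG(a: NucSeq, b: NucSeq, model: EnergyModel) -> float:
    """Ensemble free energy of the a.b dimer (+inf when no complex can form)."""
    return partition_function([a, b], model)[1]


def is_unstructured(seq: NucSeq, model: EnergyModel) -> UnstructuredReport:
    """True iff the MFE of ``seq`` is the open chain (dG = 0), i.e. no
    secondary structure is thermodynamically favorable."""
    structure, dG = fold_mfe(seq, model)
    if dG >= -_EPS:
        return UnstructuredReport(True)
    return UnstructuredReport(False, structure.dot_bracket, dG)


# ---------------------------------------------------------------------------
# Test-tube equilibrium
# ---------------------------------------------------------------------------

DEFAULT_CONCENTRATION = 1e-8  # 10 nM, the screening condition


@dataclass(frozen=True)
class TubeSpec:
    """A dilute-solution ensemble: named strands with total concentrations
    (molar) and the maximum complex size (1 or 2)."""

    species: tuple[tuple[str, NucSeq], ...]
    concentrations: tuple[float, ...] | None = None
    max_complex_size: int = 2

    def __post_init__(self) -> None:
        if self.max_complex_size not in (1, 2):
            raise ValueError("max_complex_size must be 1 or 2")
        names = [n for n, _ in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        for _, seq in self.species:
            as_rna(seq)
        conc = self.concentrations
        if conc is None:
            object.__setattr__(
                self, "concentrations",
                tuple(DEFAULT_CONCENTRATION for _ in self.species))
        else:
            if len(conc) != len(self.species):
                raise ValueError("one concentration per species required")
            if any(c <= 0 for c in conc):
                raise ValueError("concentrations must be positive")
            object.__setattr__(self, "concentrations", tuple(float(c) for c in conc))


@dataclass(frozen=True)
class TubeResult:
    """Equilibrium concentrations (molar) of every monomer and dimer, plus the
    free-monomer fractions and the mass-conservation residual."""

    monomers: dict[str, float]
    dimers: dict[tuple[str, str], float]
    free_fraction: dict[str, float]
    totals: dict[str, float]
    residual: float  # max relative mass-conservation violation

    def bound_fraction(self, a: str, b: str) -> float:
        """Fraction of strand ``a``'s total bound in the a.b complex."""
        key = (a, b) if (a, b) in self.dimers else (b, a)
        conc = self.dimers.get(key, 0.0)
        if a == b:
            conc = 2.0 * conc
        # clamp solver rounding (residual ~1e-12 relative) into [0, 1]
        return min(1.0, max(0.0, conc / self.totals[a]))


def equilibrium_concentrations(
    tube: TubeSpec, model: EnergyModel, *,
    tol: float = 1e-12, max_iter: int = 500,
) -> TubeResult:
    """Equilibrium concentrations of all complexes of size <= 2.

    Law of mass action relative to monomer ensembles: for species i, j the
    complex constant is K_ij = exp(-(dG_ij - dG_i - dG_j)/RT) (1/M, with the
    1 M reference absorbed in the duplex-initiation term).  Free monomer
    concentrations are solved by damped Newton iteration on log-concentrations;
    mass is conserved to ``tol`` relative (default 1e-12, well inside the
    guaranteed 1e-9).
    """
    names = [n for n, _ in tube.species]
    seqs = [s for _, s in tube.species]
    totals = np.array(tube.concentrations, dtype=float)
    n = len(names)
    RT = model.RT

    dG_mono = np.array([partition_function(s, model)[1] for s in seqs])
    K = np.zeros((n, n))
    if tube.max_complex_size == 2:
        for i in range(n):
            for j in range(i, n):
                dG_dim = duplex_dG(seqs[i], seqs[j], model)
                if math.isfinite(dG_dim):
                    ddg = dG_dim - dG_mono[i] - dG_mono[j]
                    K[i, j] = K[j, i] = math.exp(-ddg / RT)

    y = np.log(totals)

    def residual_vec(yv: np.ndarray) -> np.ndarray:
        x = np.exp(yv)
        pair = K * np.outer(x, x)  # pair[i, j] = K_ij x_i x_j
        bound = pair.sum(axis=1) + np.diag(pair)  # homodimers consume 2 strands
        return x + bound - totals

    def rel_err(yv: np.ndarray) -> float:
        return float(np.max(np.abs(residual_vec(yv)) / totals))

    # Phase 1: damped fixed point in log space.  The complex constants of
    # designed duplexes are astronomically large, so starting Newton from
    # x = totals would face a numerically rank-deficient Jacobian; a few
    # damped mass-action sweeps reach the basin where pair terms are O(total).
    for _ in range(400):
        if rel_err(y) < 1e-2:
            break
        x = np.exp(y)
        denom = 1.0 + (K @ x - np.diag(K) * x) + 2.0 * np.diag(K) * x
        y = y + 0.5 * (np.log(totals / denom) - y)

    # Phase 2: damped Newton on log-concentrations, Levenberg fallback.
    err = rel_err(y)
    for it in range(max_iter):
        F = residual_vec(y)
        err = float(np.max(np.abs(F) / totals))
        if err < tol:
            break
        x = np.exp(y)
        pair = K * np.outer(x, x)
        J = pair.copy()
        np.fill_diagonal(J, x + pair.sum(axis=1) + 3.0 * np.diag(pair))
        dy = None
        lam = 0.0
        for _ in range(12):
            try:
                Jd = J if lam == 0.0 else J + lam * np.diag(np.diag(J))
                dy = np.linalg.solve(Jd, -F)
                break
            except np.linalg.LinAlgError:
                lam = 1e-10 if lam == 0.0 else lam * 100.0
        if dy is None:  # pragma: no cover - defensive
            raise NumericalError(f"singular Jacobian at iteration {it}")
        dy = np.clip(dy, -50.0, 50.0)
        alpha, base = 1.0, float(np.linalg.norm(F / totals))
        improved = False
        for _ in range(60):
            cand = y + alpha * dy
            if float(np.linalg.norm(residual_vec(cand) / totals)) < base:
                y = cand
                improved = True
                break
            alpha *= 0.5
        if not improved:
            # fall back to one strongly damped fixed-point sweep
            x = np.exp(y)
            denom = 1.0 + (K @ x - np.diag(K) * x) + 2.0 * np.diag(K) * x
            y = y + 0.25 * (np.log(totals / denom) - y)
    else:
        raise NumericalError(
            f"no convergence after {max_iter} iterations (residual {err:.3e})")

    x = np.exp(y)
    pair = K * np.outer(x, x)
    dimers = {
        (names[i], names[j]): float(pair[i, j])
        for i in range(n) for j in range(i, n) if pair[i, j] > 0.0
    }
    F = residual_vec(y)
    return TubeResult(
        monomers={names[i]: float(x[i]) for i in range(n)},
        dimers=dimers,
        free_fraction={names[i]: float(x[i] / totals[i]) for i in range(n)},
        totals={names[i]: float(totals[i]) for i in range(n)},
        residual=float(np.max(np.abs(F) / totals)),
    )
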