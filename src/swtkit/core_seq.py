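"""Sequence primitives for switchable transcription terminators (SWTs).

A SWT transcript is a linear toehold followed by an intrinsic (rho-independent)
terminator: a GC-rich hairpin stem, a small loop, and a poly-U tract.  A trigger
RNA is the reverse complement of a chosen set of SWT domains; when it invades
the hairpin by toehold-mediated strand displacement the terminator is disrupted
and transcription reads through.

All sequences are RNA (A, C, G, U), written 5'->3'.  DNA input (with T) is
transcribed on read by the I/O layer.  Coordinates are 0-based, half-open.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from math import comb

import numpy as np

RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

__all__ = [
    "RNA_ALPHABET",
    "AlphabetError",
    "ConstraintError",
    "NucSeq",
    "TriggerMode",
    "SWTDesign",
    "TriggerDesign",
    "StemSpaceQuery",
    "as_rna",
    "reverse_complement",
    "gc_fraction",
    "assemble_swt",
    "derive_trigger",
    "count_stem_space",
    "enumerate_stem_space",
    "enumerate_stem_variants",
]


class AlphabetError(ValueError):
    """A sequence contains a character outside the RNA alphabet."""


class ConstraintError(ValueError):
    """A design constraint (lengths, GC windows, poly-U length ...) is violated."""


def as_rna(seq: str, *, name: str = "sequence") -> str:
    """Validate ``seq`` as RNA and return it uppercased.

    Raises :class:`AlphabetError` naming the first offending position.
    """
    s = str(seq).upper()
    if not s:
        raise AlphabetError(f"{name} is empty")
    for i, ch in enumerate(s):
        if ch not in RNA_ALPHABET:
            raise AlphabetError(
                f"{name} has invalid character {ch!r} at position {i} "
                f"(alphabet is A/C/G/U)"
            )
    return s


# ``NucSeq`` is a plain validated ``str``; the alias documents intent in
# signatures without wrapping every string in a class.
NucSeq = str


def reverse_complement(seq: NucSeq) -> NucSeq:
    """Watson-Crick complement of ``seq``, reversed (RNA, 5'->3' in and out)."""
    s = as_rna(seq)
    return s.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: NucSeq) -> float:
    """Fraction of G+C residues, in [0, 1]."""
    s = as_rna(seq)
    return (s.count("G") + s.count("C")) / len(s)


class TriggerMode(str, Enum):
    """Which SWT domains the trigger is complementary to.

    The wet-lab screen of trigger variants found that toehold-only and
    stem-only triggers cannot disrupt the terminator, the toehold+stem trigger
    switches efficiently, and extending into the loop slightly degrades
    activation; TOEHOLD_STEM is therefore the default throughout.
    """

    TOEHOLD_ONLY = "TOEHOLD_ONLY"
    STEM_ONLY = "STEM_ONLY"
    TOEHOLD_STEM = "TOEHOLD_STEM"
    TOEHOLD_STEM_LOOP = "TOEHOLD_STEM_LOOP"


@dataclass(frozen=True)
class SWTDesign:
    """A switchable transcription terminator decomposed into its domains.

    transcript = toehold | stem5 | loop | stem3 | polyU (5'->3'), with
    ``stem3 == reverse_complement(stem5)``.
    """

    name: str
    toehold: NucSeq
    stem5: NucSeq
    loop: NucSeq
    stem3: NucSeq
    polyU: NucSeq

    def __post_init__(self) -> None:
        for fld in ("toehold", "stem5", "loop", "stem3", "polyU"):
            as_rna(getattr(self, fld), name=fld)
        if self.stem3 != reverse_complement(self.stem5):
            raise ConstraintError(
                f"{self.name}: stem3 must be the reverse complement of stem5"
            )
        if set(self.polyU) != {"U"} or len(self.polyU) < 6:
            raise ConstraintError(
                f"{self.name}: poly-U tract must be all-U of length >= 6 "
                f"(got {self.polyU!r})"
            )

    @property
    def transcript(self) -> NucSeq:
        return self.toehold + self.stem5 + self.loop + self.stem3 + self.polyU

    @property
    def domains(self) -> dict[str, tuple[int, int]]:
        """0-based half-open coordinates of each domain on the transcript."""
        bounds = {}
        pos = 0
        for fld in ("toehold", "stem5", "loop", "stem3", "polyU"):
            seq = getattr(self, fld)
            bounds[fld] = (pos, pos + len(seq))
            pos += len(seq)
        return bounds

    @property
    def stem_pairs(self) -> list[tuple[int, int]]:
        """Designed hairpin base pairs as transcript index pairs (i, j), i < j."""
        (s5_lo, s5_hi) = self.domains["stem5"]
        (s3_lo, s3_hi) = self.domains["stem3"]
        n = len(self.stem5)
        return [(s5_lo + k, s3_hi - 1 - k) for k in range(n)]


@dataclass(frozen=True)
class TriggerDesign:
    """An input RNA derived as the reverse complement of selected SWT domains."""

    name: str
    mode: TriggerMode
    sequence: NucSeq
    cognate: str  # name of the SWT this trigger was derived from

    def __post_init__(self) -> None:
        as_rna(self.sequence, name="trigger sequence")


def assemble_swt(
    name: str,
    toehold: NucSeq,
    stem5: NucSeq,
    loop: NucSeq,
    polyU_len: int = 8,
    *,
    expected_toehold_len: int | None = None,
) -> SWTDesign:
    """Build a :class:`SWTDesign`; stem3 is derived automatically.

    Parameters
    ----------
    polyU_len:
        Length of the poly-U tract (>= 6; default 8, typical for a strong
        intrinsic terminator).
    expected_toehold_len:
        If given, the toehold length is enforced (pass ``None`` to skip the
        check, e.g. for deliberately short demo constructs).
    """
    toehold = as_rna(toehold, name="toehold")
    stem5 = as_rna(stem5, name="stem5")
    loop = as_rna(loop, name="loop")
    if polyU_len < 6:
        raise ConstraintError(f"poly-U length must be >= 6, got {polyU_len}")
    if expected_toehold_len is not None and len(toehold) != expected_toehold_len:
        raise ConstraintError(
            f"toehold length {len(toehold)} != configured {expected_toehold_len} "
            f"(pass expected_toehold_len=None to override)"
        )
    return SWTDesign(
        name=name,
        toehold=toehold,
        stem5=stem5,
        loop=loop,
        stem3=reverse_complement(stem5),
        polyU="U" * polyU_len,
    )


def derive_trigger(
    swt: SWTDesign, mode: TriggerMode = TriggerMode.TOEHOLD_STEM, *, name: str | None = None
) -> TriggerDesign:
    """Derive the trigger RNA for ``swt`` under the given mode.

    The trigger is the reverse complement of the concatenated target domains,
    so it hybridizes end-to-end with them (toehold first, then branch
    migration into the stem).
    """
    mode = TriggerMode(mode)
    if mode is TriggerMode.TOEHOLD_ONLY:
        target = swt.toehold
    elif mode is TriggerMode.STEM_ONLY:
        target = swt.stem5
    elif mode is TriggerMode.TOEHOLD_STEM:
        target = swt.toehold + swt.stem5
    elif mode is TriggerMode.TOEHOLD_STEM_LOOP:
        target = swt.toehold + swt.stem5 + swt.loop
    else:  # pragma: no cover - Enum() already rejects unknown values
        raise ValueError(f"unknown trigger mode {mode!r}")
    return TriggerDesign(
        name=name or f"T_{swt.name}",
        mode=mode,
        sequence=reverse_complement(target),
        cognate=swt.name,
    )


def trigger_target_span(swt: SWTDesign, mode: TriggerMode) -> tuple[int, int]:
    """Transcript coordinates (0-based half-open) the trigger binds under ``mode``."""
    mode = TriggerMode(mode)
    d = swt.domains
    if mode is TriggerMode.TOEHOLD_ONLY:
        return d["toehold"][0], d["toehold"][1]
    if mode is TriggerMode.STEM_ONLY:
        return d["stem5"][0], d["stem5"][1]
    if mode is TriggerMode.TOEHOLD_STEM:
        return d["toehold"][0], d["stem5"][1]
    return d["toehold"][0], d["loop"][1]


@dataclass(frozen=True)
class StemSpaceQuery:
    """Size of the stem design space: ``length`` bp with exactly ``n_nonGC``
    A-U/U-A pairs (the rest G-C/C-G)."""

    length: int
    n_nonGC: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ConstraintError("stem length must be >= 1")
        if not 0 <= self.n_nonGC <= self.length:
            raise ConstraintError("n_nonGC must be within [0, length]")


def count_stem_space(q: StemSpaceQuery) -> int:
    """Number of distinct Watson-Crick stem duplexes matching ``q``.

    Each of the ``length`` positions carries one WC pair; ``n_nonGC`` positions
    (chosen freely) hold A-U or U-A, the rest G-C or C-G.  Every position has 2
    orientation choices, hence C(length, n_nonGC) * 2**length.  The redesign of
    the terminator stem from 7 bp all-GC to 10 bp with exactly one non-GC pair
    expands this space 80-fold.
    """
    return comb(q.length, q.n_nonGC) * 2**q.length


def enumerate_stem_space(q: StemSpaceQuery) -> list[NucSeq]:
    """Brute-force list of all 5' stem arms matching ``q`` (exponential; small
    lengths only).  Each arm determines the duplex since the 3' arm is its
    reverse complement."""
    if q.length > 12:
        raise ConstraintError("enumerate_stem_space is limited to length <= 12")
    arms = []
    for arm in itertools.product("ACGU", repeat=q.length):
        non_gc = sum(1 for ch in arm if ch in "AU")
        if non_gc == q.n_nonGC:
            arms.append("".join(arm))
    return arms


def enumerate_stem_variants(
    base_stem: NucSeq,
    lengths: list[int],
    gc_fracs: list[float],
    rng_seed: int = 0,
    *,
    n_per_combo: int = 8,
) -> list[dict]:
    """Seeded sample of 5' stem arms for each (length, GC fraction) combination.

    Emulates the stem-space exploration: starting from a base stem, lengths are
    extended in steps while arm GC content is varied (e.g. 70-100%).  Each
    returned record has ``name``, ``length``, ``gc_fraction`` (realized, within
    +-1/length of target) and ``sequence``.

    Raises :class:`ConstraintError` for infeasible combinations.
    """
    as_rna(base_stem, name="base_stem")
    rng = np.random.default_rng(rng_seed)
    out: list[dict] = []
    for length in lengths:
        if length < 4:
            raise ConstraintError(f"stem length must be >= 4, got {length}")
        for gc in gc_fracs:
            if not 0.0 <= gc <= 1.0:
                raise ConstraintError(f"GC fraction must be in [0,1], got {gc}")
            n_gc = round(gc * length)
            if abs(n_gc / length - gc) > 1.0 / length:
                raise ConstraintError(
                    f"GC fraction {gc} unreachable at length {length}"
                )
            seen: set[str] = set()
            for k in range(n_per_combo):
                positions = rng.permutation(length)
                arm = [""] * length
                for p in positions[:n_gc]:
                    arm[p] = "GC"[rng.integers(2)]
                for p in positions[n_gc:]:
                    arm[p] = "AU"[rng.integers(2)]
                seq = "".join(arm)
                if seq in seen:
                    continue
                seen.add(seq)
                out.append(
                    {
                        "name": f"stem_L{length}_GC{int(round(gc * 100))}_{k}",
                        "length": length,
                        "gc_fraction": n_gc / length,
                        "sequence": seq,
                    }
                )
    return out
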