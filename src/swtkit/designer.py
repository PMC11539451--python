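"""Automated design of orthogonal SWT/trigger libraries.

The algorithm mirrors the published design procedure: toeholds are random
40-mers with 50-60% GC and no secondary structure, the terminator stem is a
10-bp GC-rich hairpin (exactly one A-U/U-A pair by default), triggers are the
reverse complement of toehold+stem and must be linear, and candidates are
screened in silico at 10 nM with complexes up to size 2.  Orthogonality is
scored on the equilibrium bound fraction of each SWT with each trigger (the
in-silico analogue of the experimental ON/OFF matrix; the model cannot predict
fluorescence).  Acceptance is greedy and fully seeded: a candidate joins the
library only if its cognate activation clears ``cognate_min_activation`` and
every cross-activation against the already-accepted pairs (both directions)
stays below ``crosstalk_threshold``.

Each SWT here carries its own stem sequence drawn from the expanded stem
space; distinct stems are what make the trigger's stem-binding segment
specific to its cognate switch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_seq import (
    ConstraintError,
    NucSeq,
    SWTDesign,
    TriggerDesign,
    TriggerMode,
    assemble_swt,
    derive_trigger,
    gc_fraction,
    reverse_complement,
    trigger_target_span,
)
from .thermo import (
    EnergyModel,
    SecondaryStructure,
    TubeResult,
    TubeSpec,
    duplex_dG,
    equilibrium_concentrations,
    fold_mfe,
    is_unstructured,
    mfe_energy,
    structure_energy,
)

__all__ = [
    "DesignConstraints",
    "DesignError",
    "CheckResult",
    "CandidatePair",
    "CrosstalkMatrix",
    "LibraryDesign",
    "sample_toehold",
    "sample_stem5",
    "make_candidate",
    "check_candidate",
    "predicted_activation",
    "activation_tube",
    "crosstalk_matrix",
    "design_library",
    "multi_tube_defect",
]


logger = logging.getLogger(__name__)


class DesignError(RuntimeError):
    """The sampling budget was exhausted before the constraints were met."""

    def __init__(self, message: str, partial: "LibraryDesign | None" = None):
        super().__init__(message)
        self.partial = partial


@dataclass(frozen=True)
class DesignConstraints:
    """All tunable knobs of the design loop (defaults = study conditions)."""

    toehold_length: int = 40
    toehold_gc_window: tuple[float, float] = (0.50, 0.60)
    stem_length: int = 10
    stem_nonGC_pairs: int = 1
    loop: NucSeq = "GAAA"
    polyU_length: int = 8
    require_unstructured_toehold: bool = True
    trigger_mode: TriggerMode = TriggerMode.TOEHOLD_STEM
    trigger_linear_required: bool = True
    # a trigger counts as linear when its MFE is above this floor (kcal/mol):
    # the stem-complement segment of a toehold+stem trigger almost always
    # finds some weak helix, and structure this marginal cannot resist
    # toehold-nucleated displacement
    trigger_mfe_min: float = -2.0
    concentration: float = 1e-8  # molar; 10 nM screening condition
    crosstalk_threshold: float = 0.05
    cognate_min_activation: float = 0.90
    trigger_duplex_warn_dG: float = -8.0  # kcal/mol; trigger-trigger warning
    max_candidates_per_slot: int = 10_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.toehold_gc_window
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConstraintError("toehold_gc_window must be within [0, 1]")
        if not 0 <= self.stem_nonGC_pairs <= self.stem_length:
            raise ConstraintError("stem_nonGC_pairs must be within [0, stem_length]")
        if self.concentration <= 0:
            raise ConstraintError("concentration must be positive")
        if not self.crosstalk_threshold < self.cognate_min_activation:
            raise ConstraintError(
                "crosstalk_threshold must be below cognate_min_activation")


@dataclass(frozen=True)
class CheckResult:
    passed: bool
    value: float | str | None = None
    detail: str = ""


@dataclass(frozen=True)
class CandidatePair:
    """A SWT with its cognate trigger and per-constraint diagnostics."""

    swt: SWTDesign
    trigger: TriggerDesign
    diagnostics: dict[str, CheckResult] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trigger.cognate != self.swt.name:
            raise ConstraintError(
                f"trigger {self.trigger.name} is not cognate to {self.swt.name}")

    @property
    def all_passed(self) -> bool:
        return all(r.passed for r in self.diagnostics.values())


@dataclass(frozen=True)
class CrosstalkMatrix:
    """n x m predicted activation of every SWT (rows) by every trigger (cols)."""

    swt_names: tuple[str, ...]
    trigger_names: tuple[str, ...]
    activation: np.ndarray  # shape (n_swt, n_trigger), entries in [0, 1]

    def __post_init__(self) -> None:
        a = np.asarray(self.activation, dtype=float)
        if a.shape != (len(self.swt_names), len(self.trigger_names)):
            raise ValueError("activation shape does not match the labels")
        if np.any(a < 0) or np.any(a > 1):
            raise ValueError("activation entries must lie in [0, 1]")
        object.__setattr__(self, "activation", a)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.activation, index=list(self.swt_names),
            columns=list(self.trigger_names))

    @property
    def diagonal_min(self) -> float:
        return float(np.min(np.diag(self.activation)))

    @property
    def offdiagonal_max(self) -> float:
        a = self.activation
        if a.shape[0] < 2:
            return 0.0
        mask = ~np.eye(a.shape[0], dtype=bool)
        return float(np.max(a[mask]))


@dataclass(frozen=True)
class LibraryDesign:
    """An accepted orthogonal library with its crosstalk audit."""

    pairs: tuple[CandidatePair, ...]
    crosstalk: CrosstalkMatrix
    tube_reports: dict
    defect: float
    seed: int
    constraints: DesignConstraints


# ---------------------------------------------------------------------------
# Candidate generation
# ---------------------------------------------------------------------------


def sample_toehold(
    rng: np.random.Generator,
    constraints: DesignConstraints,
    model: EnergyModel,
    *,
    budget: int = 10_000,
) -> NucSeq:
    """Draw a random toehold: configured length, GC inside the window, and
    (when required) no secondary structure at the model's MFE.

    The GC count is drawn uniformly from the integers realizing the window and
    the bases placed uniformly, then the structure constraint is enforced by
    rejection.  Deterministic for a given generator state.
    """
    L = constraints.toehold_length
    lo, hi = constraints.toehold_gc_window
    gc_lo, gc_hi = int(np.ceil(lo * L - 1e-9)), int(np.floor(hi * L + 1e-9))
    if gc_lo > gc_hi:
        raise ConstraintError(
            f"no integer GC count realizes window {constraints.toehold_gc_window} "
            f"at length {L}")
    for _ in range(budget):
        n_gc = int(rng.integers(gc_lo, gc_hi + 1))
        bases = np.empty(L, dtype="<U1")
        pos = rng.permutation(L)
        gc_choices = rng.integers(0, 2, size=n_gc)
        au_choices = rng.integers(0, 2, size=L - n_gc)
        for idx, p in enumerate(pos[:n_gc]):
            bases[p] = "GC"[gc_choices[idx]]
        for idx, p in enumerate(pos[n_gc:]):
            bases[p] = "AU"[au_choices[idx]]
        seq = "".join(bases)
        if not constraints.require_unstructured_toehold or is_unstructured(seq, model):
            return seq
    raise DesignError(
        f"no unstructured toehold found in {budget} samples; consider relaxing "
        f"the GC window or require_unstructured_toehold")


def sample_stem5(rng: np.random.Generator, constraints: DesignConstraints) -> NucSeq:
    """Draw a 5' stem arm: ``stem_length`` bases with exactly
    ``stem_nonGC_pairs`` positions from {A, U} (the rest {G, C})."""
    L, k = constraints.stem_length, constraints.stem_nonGC_pairs
    arm = np.empty(L, dtype="<U1")
    pos = rng.permutation(L)
    au = rng.integers(0, 2, size=k)
    gc = rng.integers(0, 2, size=L - k)
    for idx, p in enumerate(pos[:k]):
        arm[p] = "AU"[au[idx]]
    for idx, p in enumerate(pos[k:]):
        arm[p] = "GC"[gc[idx]]
    return "".join(arm)


def make_candidate(
    name: str,
    toehold: NucSeq,
    stem5: NucSeq,
    constraints: DesignConstraints,
    model: EnergyModel,
    *,
    fail_fast: bool = False,
    skip_cognate: bool = False,
) -> CandidatePair:
    """Assemble the SWT + cognate trigger and attach diagnostics."""
    swt = assemble_swt(
        name, toehold, stem5, constraints.loop, constraints.polyU_length,
        expected_toehold_len=constraints.toehold_length)
    trigger = derive_trigger(swt, constraints.trigger_mode)
    pair = CandidatePair(swt=swt, trigger=trigger)
    return replace(
        pair,
        diagnostics=check_candidate(
            pair, constraints, model, fail_fast=fail_fast,
            skip_cognate=skip_cognate))


def _target_complex(pair: CandidatePair) -> tuple[list[NucSeq], SecondaryStructure]:
    """The fully-hybridized SWT-trigger complex: the trigger paired end-to-end
    with its target domains, everything else unpaired."""
    swt, trig = pair.swt, pair.trigger
    lo, hi = trigger_target_span(swt, trig.mode)
    n1 = len(swt.transcript)
    lt = len(trig.sequence)
    assert hi - lo == lt
    pairs = frozenset(
        (lo + k, n1 + (lt - 1 - k)) for k in range(lt))
    return (
        [swt.transcript, trig.sequence],
        SecondaryStructure(strand_lengths=(n1, lt), pairs=pairs),
    )


def check_candidate(
    pair: CandidatePair,
    constraints: DesignConstraints,
    model: EnergyModel,
    *,
    fail_fast: bool = False,
    skip_cognate: bool = False,
) -> dict[str, CheckResult]:
    """Evaluate every sequence/structure constraint; failures are recorded,
    never raised.  With ``fail_fast`` the remaining (more expensive) checks
    are skipped after the first failure; ``skip_cognate`` defers the costly
    dimer-MFE check (used in the optimizer's inner loop)."""
    swt, trig = pair.swt, pair.trigger
    diag: dict[str, CheckResult] = {}

    def failed() -> bool:
        return fail_fast and not all(r.passed for r in diag.values())

    gc = gc_fraction(swt.toehold)
    lo, hi = constraints.toehold_gc_window
    diag["toehold_gc"] = CheckResult(lo - 1e-9 <= gc <= hi + 1e-9, gc)
    if failed():
        return diag

    rep = is_unstructured(swt.toehold, model)
    diag["toehold_unstructured"] = CheckResult(
        bool(rep) or not constraints.require_unstructured_toehold,
        rep.mfe_dG, rep.mfe_dot_bracket)
    if failed():
        return diag

    trig_struct, trig_dG = fold_mfe(trig.sequence, model)
    diag["trigger_linear"] = CheckResult(
        trig_dG >= constraints.trigger_mfe_min
        or not constraints.trigger_linear_required,
        trig_dG, trig_struct.dot_bracket)
    if failed():
        return diag

    # the SWT's own MFE must be the terminator hairpin with the toehold free
    mfe_struct, mfe_dG = fold_mfe(swt.transcript, model)
    t_lo, t_hi = swt.domains["toehold"]
    paired_idx = {i for p in mfe_struct.pairs for i in p}
    toehold_free = all(i not in paired_idx for i in range(t_lo, t_hi))
    hairpin_formed = set(swt.stem_pairs) <= set(mfe_struct.pairs)
    diag["toehold_unpaired_in_swt"] = CheckResult(
        toehold_free, mfe_dG, mfe_struct.dot_bracket)
    diag["terminator_hairpin_is_mfe"] = CheckResult(
        hairpin_formed, mfe_dG, mfe_struct.dot_bracket)
    if failed():
        return diag

    if skip_cognate:
        return diag

    # the fully-hybridized complex over the targeted region (plus the optimal
    # fold of the SWT's remaining free 3' tail, which sits on a nicked,
    # penalty-free face) must be the dimer MFE
    lo, hi = trigger_target_span(swt, trig.mode)
    if trig.sequence != reverse_complement(swt.transcript[lo:hi]):
        diag["cognate_duplex_is_mfe"] = CheckResult(
            False, None, "trigger is not the exact complement of its target span")
        return diag
    strands, target = _target_complex(pair)
    tail = swt.transcript[hi:]
    e_target = structure_energy(strands, target, model)
    if len(tail) >= 2:
        e_target += fold_mfe(tail, model)[1]
    e_mfe = mfe_energy(strands, model)
    diag["cognate_duplex_is_mfe"] = CheckResult(
        e_target <= e_mfe + 1e-6, e_mfe - e_target,
        f"target {e_target:.2f} vs dimer MFE {e_mfe:.2f} kcal/mol")
    return diag


# ---------------------------------------------------------------------------
# Activation scoring
# ---------------------------------------------------------------------------


def activation_tube(
    swt: SWTDesign,
    trigger: TriggerDesign,
    constraints: DesignConstraints,
    model: EnergyModel,
) -> TubeResult:
    """Equilibrium of the 2-species screening tube (each strand at the
    configured concentration, complexes up to dimers)."""
    tube = TubeSpec(
        species=(("swt", swt.transcript), ("trigger", trigger.sequence)),
        concentrations=(constraints.concentration, constraints.concentration),
        max_complex_size=2,
    )
    return equilibrium_concentrations(tube, model)


def predicted_activation(
    swt: SWTDesign,
    trigger: TriggerDesign,
    constraints: DesignConstraints,
    model: EnergyModel,
) -> float:
    """Fraction of the SWT strand bound in a duplex with the trigger at
    equilibrium, in [0, 1] — the equilibrium surrogate for the ON state.

    Near-cognate pairs saturate within double precision; the complementary
    free-monomer fraction (``activation_tube(...).free_fraction``) is the
    numerically resolvable quantity there.
    """
    return activation_tube(swt, trigger, constraints, model).bound_fraction(
        "swt", "trigger")


def crosstalk_matrix(
    swts: list[SWTDesign],
    triggers: list[TriggerDesign],
    constraints: DesignConstraints,
    model: EnergyModel,
) -> tuple[CrosstalkMatrix, dict]:
    """All pairwise activations plus the three tube-category reports:
    individual constructs, pooled SWTs / pooled triggers, and every SWT-trigger
    pair tube."""
    n, m = len(swts), len(triggers)
    act = np.zeros((n, m))
    pair_tubes: dict[tuple[str, str], TubeResult] = {}
    for i, s in enumerate(swts):
        for j, t in enumerate(triggers):
            res = activation_tube(s, t, constraints, model)
            act[i, j] = res.bound_fraction("swt", "trigger")
            pair_tubes[(s.name, t.name)] = res

    c = constraints.concentration
    # deduplicate by name so a species listed twice is screened once
    swt_species = dict((s.name, s.transcript) for s in swts)
    trig_species = dict((t.name, t.sequence) for t in triggers)
    individual = {}
    for name, seq in {**swt_species, **trig_species}.items():
        individual[name] = equilibrium_concentrations(
            TubeSpec(species=((name, seq),), concentrations=(c,)), model)
    pooled = {}
    if swt_species:
        pooled["swts"] = equilibrium_concentrations(
            TubeSpec(species=tuple(swt_species.items()),
                     concentrations=tuple(c for _ in swt_species)), model)
    if trig_species:
        pooled["triggers"] = equilibrium_concentrations(
            TubeSpec(species=tuple(trig_species.items()),
                     concentrations=tuple(c for _ in trig_species)), model)

    matrix = CrosstalkMatrix(
        swt_names=tuple(s.name for s in swts),
        trigger_names=tuple(t.name for t in triggers),
        activation=act,
    )
    reports = {"individual": individual, "pooled": pooled, "pairs": pair_tubes}
    return matrix, reports


# ---------------------------------------------------------------------------
# Greedy library assembly
# ---------------------------------------------------------------------------


def _cross_ddG(swt: SWTDesign, trigger: TriggerDesign, model: EnergyModel) -> float:
    """Binding free energy of the swt.trigger complex relative to the free
    monomer ensembles (kcal/mol; +inf when no complex forms)."""
    from .thermo import partition_function

    dg_dim = duplex_dG(swt.transcript, trigger.sequence, model)
    if not np.isfinite(dg_dim):
        return np.inf
    dg_s = partition_function(swt.transcript, model)[1]
    dg_t = partition_function(trigger.sequence, model)[1]
    return dg_dim - dg_s - dg_t


def _required_cross_ddG(constraints: DesignConstraints, model: EnergyModel) -> float:
    """ddG above which the off-target bound fraction stays under the
    threshold at the screening concentration (two-state estimate)."""
    thr, c = constraints.crosstalk_threshold, constraints.concentration
    return -model.RT * np.log(thr / ((1.0 - thr) * c))


def _cross_ddG_bound(swt: SWTDesign, trigger: TriggerDesign, model: EnergyModel) -> float:
    """Cheap upper bound on the cross binding ddG: an admissible dimer
    structure (both MFE folds plus the best exterior helix) upper-bounds the
    dimer ensemble free energy, so this value can only overestimate ddG
    (underestimate binding)."""
    from .thermo import best_cross_helix_bound, partition_function

    return (best_cross_helix_bound(swt.transcript, trigger.sequence, model)
            - partition_function(swt.transcript, model)[1]
            - partition_function(trigger.sequence, model)[1])


def _cross_score(
    cand: CandidatePair,
    accepted: list[CandidatePair],
    constraints: DesignConstraints,
    model: EnergyModel,
    *,
    abort_above: float = np.inf,
) -> float:
    """Sum over both-direction cross pairs of the positive binding margin
    (required - ddG)+; 0 means every off-target interaction is weak enough.
    Summing (rather than taking the max) keeps a descent signal from every
    offending pair.

    A helix-bound pre-pass gives per-pair margin lower bounds in microseconds;
    the expensive ensemble evaluation runs only when the bounds cannot already
    reject, worst pair first.  Aborts early (returning a lower bound) once the
    score provably exceeds ``abort_above``."""
    req = _required_cross_ddG(constraints, model)
    pairs = [
        pair for prev in accepted
        for pair in ((prev.swt, cand.trigger), (cand.swt, prev.trigger))
    ]
    if not pairs:
        return 0.0
    bounds = [
        max(0.0, req - _cross_ddG_bound(s, t, model)) for (s, t) in pairs]
    remaining = sum(bounds)
    if remaining > abort_above:
        return remaining
    score = 0.0
    for idx in sorted(range(len(pairs)), key=lambda k: -bounds[k]):
        remaining -= bounds[idx]
        s, t = pairs[idx]
        score += max(0.0, req - _cross_ddG(s, t, model))
        if score + remaining > abort_above:
            return score + remaining
    return score


def _max_complementary_run(
    cand: CandidatePair,
    accepted: list[CandidatePair],
    model: EnergyModel,
) -> int:
    """Longest contiguous duplex the candidate could form with any accepted
    partner sequence (cheap prefilter before the DP evaluation)."""
    from .thermo import longest_complementary_run

    worst = 0
    for prev in accepted:
        worst = max(
            worst,
            longest_complementary_run(
                prev.swt.transcript, cand.trigger.sequence, model),
            longest_complementary_run(
                cand.swt.transcript, prev.trigger.sequence, model),
        )
    return worst


def _offending_positions(
    cand: CandidatePair,
    accepted: list[CandidatePair],
    constraints: DesignConstraints,
    model: EnergyModel,
) -> tuple[dict[int, str], bool]:
    """Candidate toehold positions engaged in inter-strand pairs of the worst
    off-target complex (from its MFE structure), mapped to the replacement
    bases that would *recreate* a pair there (and should hence be avoided),
    plus a flag for stem involvement."""
    from .thermo import fold_mfe_dimer

    req = _required_cross_ddG(constraints, model)
    worst, worst_margin = None, 0.0
    for prev in accepted:
        for s, t, cand_is_swt in (
                (prev.swt, cand.trigger, False), (cand.swt, prev.trigger, True)):
            margin = req - _cross_ddG(s, t, model)
            if margin > worst_margin:
                worst_margin, worst = margin, (s, t, cand_is_swt)
    if worst is None:
        return {}, False
    s, t, cand_is_swt = worst
    struct, _ = fold_mfe_dimer(s.transcript, t.sequence, model)
    if struct is None:
        return {}, False
    seq = s.transcript + t.sequence
    nick = len(s.transcript)
    Lt, Ls = len(cand.swt.toehold), len(cand.swt.stem5)
    d = cand.swt.domains
    hot: dict[int, str] = {}
    stem_hot = False
    for (i, j) in struct.pairs:
        if not (i < nick <= j):
            continue
        if cand_is_swt:
            if i < Lt:
                hot[i] = _PAIRS_WITH[seq[j]]
            elif d["stem5"][0] <= i < d["stem5"][1] or d["stem3"][0] <= i < d["stem3"][1]:
                stem_hot = True
        else:
            tgt = (Lt + Ls) - 1 - (j - nick)
            if 0 <= tgt < Lt:
                # the trigger carries the complement of this toehold position;
                # forbid toehold bases whose complement re-pairs the partner
                hot[tgt] = "".join(
                    _COMPLEMENT_OF[y] for y in _PAIRS_WITH[seq[i]])
            elif tgt >= Lt:
                stem_hot = True
    return hot, stem_hot


_COMPLEMENT_OF = {"A": "U", "C": "G", "G": "C", "U": "A"}
# bases that can pair (WC or wobble) with the key base
_PAIRS_WITH = {"A": "U", "C": "G", "G": "CU", "U": "AG"}


def _mutate(
    cand: CandidatePair,
    rng: np.random.Generator,
    constraints: DesignConstraints,
    model: EnergyModel,
    name: str,
    hot: dict[int, str] | None = None,
    stem_hot: bool = False,
) -> CandidatePair:
    """Propose a neighbor: substitute 1-4 toehold bases — biased toward the
    positions driving the worst off-target complex, avoiding bases that would
    recreate the offending pair — or resample the stem arm (whose complement
    rides on the trigger)."""
    p_stem = 0.5 if stem_hot else 0.15
    if rng.random() < p_stem:
        stem5 = sample_stem5(rng, constraints)
        toehold = cand.swt.toehold
    else:
        stem5 = cand.swt.stem5
        th = list(cand.swt.toehold)
        targeted = bool(hot) and rng.random() < 0.75
        pool = sorted(hot) if targeted else None
        for _ in range(int(rng.integers(1, 5))):
            if pool:
                pos = pool[int(rng.integers(len(pool)))]
                allowed = [b for b in "ACGU" if b not in hot[pos]]
            else:
                pos = int(rng.integers(len(th)))
                allowed = list("ACGU")
            th[pos] = allowed[int(rng.integers(len(allowed)))]
        toehold = "".join(th)
    return make_candidate(
        name, toehold, stem5, constraints, model,
        fail_fast=True, skip_cognate=True)


def _verify_set(
    members: list[CandidatePair],
    constraints: DesignConstraints,
    model: EnergyModel,
) -> list[CandidatePair] | None:
    """Full diagnostics, cognate activation and exact pairwise cross bound
    fractions for a whole tentative library; None when anything fails."""
    out = []
    for m in members:
        full = replace(m, diagnostics=check_candidate(m, constraints, model))
        if not full.all_passed:
            return None
        act = predicted_activation(full.swt, full.trigger, constraints, model)
        if act < constraints.cognate_min_activation:
            return None
        out.append(full)
    for i, a in enumerate(out):
        for j, b in enumerate(out):
            if i != j and predicted_activation(
                    a.swt, b.trigger, constraints, model
            ) > constraints.crosstalk_threshold:
                return None
    return out


def _joint_repair(
    members: list[CandidatePair],
    rng: np.random.Generator,
    constraints: DesignConstraints,
    model: EnergyModel,
    *,
    budget: int,
) -> list[CandidatePair] | None:
    """Anneal the whole tentative library jointly until every cross margin
    clears, then verify exactly.

    The sequential loop moves only the newest candidate; when that stalls,
    distributing the remaining conflicts across all members (multi-tube
    co-design) is far more effective.  Margins are delta-updated: a mutation
    of member k only touches the 2(n-1) pairs involving k.  Deterministic
    for a given generator state.  Returns the repaired members or None.
    """
    req = _required_cross_ddG(constraints, model)
    n = len(members)
    members = list(members)

    def margin(s: SWTDesign, t: TriggerDesign) -> float:
        return max(0.0, req - _cross_ddG(s, t, model))

    margins: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(n):
            if i != j:
                margins[(i, j)] = margin(members[i].swt, members[j].trigger)
    total = sum(margins.values())
    logger.debug("joint repair of %d members: initial total %.2f", n, total)

    hot_cache: dict[int, tuple[str, dict[int, str], bool]] = {}
    spent = 0
    stall = 0
    checked_at = np.inf
    while spent < budget and stall < 5000:
        if total <= 0.3 and total < checked_at - 1e-9:
            checked_at = total
            verified = _verify_set(members, constraints, model)
            if verified is not None:
                logger.debug("joint repair converged at spent=%d", spent)
                return verified
            stall += 300
        # mutate a member drawn by its share of the remaining conflicts
        contrib = np.array([
            sum(v for (i, j), v in margins.items() if i == k or j == k)
            for k in range(n)])
        if contrib.sum() > 0:
            w = contrib + 1e-6
            k = int(rng.choice(n, p=w / w.sum()))
        else:
            k = int(rng.integers(n))
        others = members[:k] + members[k + 1:]
        key = members[k].swt.toehold + members[k].swt.stem5
        cached = hot_cache.get(k)
        if cached is None or cached[0] != key:
            hot, stem_hot = _offending_positions(
                members[k], others, constraints, model)
            hot_cache[k] = (key, hot, stem_hot)
        else:
            _, hot, stem_hot = cached
        anneal_T = 1.0 if total > 1.0 else 0.1
        spent += 1
        stall += 1
        mut = _mutate(members[k], rng, constraints, model,
                      members[k].swt.name, hot, stem_hot)
        if not mut.all_passed:
            continue
        if _max_complementary_run(mut, others, model) >= 9:
            continue
        old_sum = sum(
            margins[(k, j)] + margins[(j, k)] for j in range(n) if j != k)
        # certain-violation prescreen before any ensemble evaluation
        lb = 0.0
        for j in range(n):
            if j == k:
                continue
            lb += max(0.0, req - _cross_ddG_bound(
                mut.swt, members[j].trigger, model))
            lb += max(0.0, req - _cross_ddG_bound(
                members[j].swt, mut.trigger, model))
        if lb - old_sum > 3.0 * anneal_T:
            continue
        new_m: dict[tuple[int, int], float] = {}
        for j in range(n):
            if j == k:
                continue
            new_m[(k, j)] = margin(mut.swt, members[j].trigger)
            new_m[(j, k)] = margin(members[j].swt, mut.trigger)
        delta = sum(new_m.values()) - old_sum
        if delta < -1e-9 or (delta <= 3.0 * anneal_T
                             and rng.random() < np.exp(-delta / anneal_T)):
            members[k] = mut
            margins.update(new_m)
            total += delta
            hot_cache.pop(k, None)
            if delta < -1e-9:
                stall = 0
    logger.debug("joint repair gave up at spent=%d total %.2f", spent, total)
    return None


def design_library(
    n: int,
    constraints: DesignConstraints | None = None,
    model: EnergyModel | None = None,
) -> LibraryDesign:
    """Assemble ``n`` mutually orthogonal SWT/trigger pairs.

    Per slot the loop first rejection-samples a candidate satisfying all
    sequence/structure constraints, then — because random non-cognate pairs
    bind far too strongly at the screening concentration — descends on the
    worst off-target binding margin by seeded point mutations (the in-house
    counterpart of multi-tube ensemble-defect optimization).  A candidate is
    accepted once its cognate activation clears ``cognate_min_activation`` and
    every cross bound fraction (both directions, verified by the exact
    equilibrium solve) stays under ``crosstalk_threshold``.  Fully
    reproducible from the seed.
    """
    if n < 1:
        raise ConstraintError("library size must be >= 1")
    constraints = constraints or DesignConstraints()
    model = model or EnergyModel.default()
    rng = np.random.default_rng(constraints.rng_seed)
    accepted: list[CandidatePair] = []
    name_counter = 0  # monotone member naming across joint repairs

    def cross_ok(cand: CandidatePair) -> bool:
        for prev in accepted:
            if (predicted_activation(prev.swt, cand.trigger, constraints, model)
                    > constraints.crosstalk_threshold):
                return False
            if (predicted_activation(cand.swt, prev.trigger, constraints, model)
                    > constraints.crosstalk_threshold):
                return False
        return True

    def exact_accept(cand: CandidatePair) -> CandidatePair | None:
        """Full (non-fail-fast) diagnostics + exact equilibrium verification."""
        full = replace(
            cand, diagnostics=check_candidate(cand, constraints, model))
        act = predicted_activation(full.swt, full.trigger, constraints, model)
        if (full.all_passed and act >= constraints.cognate_min_activation
                and cross_ok(full)):
            return full
        return None

    while len(accepted) < n:
        slot = len(accepted) + 1
        name_counter += 1
        name = f"S{name_counter}"
        # later slots face 2(slot-1) simultaneous off-target constraints, so
        # their proposal budget grows with the constraint count
        budget = constraints.max_candidates_per_slot * (1 + max(0, slot - 3))
        spent = 0
        found: CandidatePair | None = None

        best_cand: CandidatePair | None = None
        best_score = np.inf

        while spent < budget and found is None:
            cand, score = None, np.inf
            # basin hop: usually restart from a kicked copy of the slot's best
            if best_cand is not None and best_score < 25.0 and rng.random() < 0.7:
                for _ in range(20):
                    spent += 1
                    kicked = best_cand
                    for _ in range(3):
                        kicked = _mutate(kicked, rng, constraints, model, name)
                    if kicked.all_passed:
                        cand = kicked
                        score = _cross_score(cand, accepted, constraints, model)
                        break
            if cand is None:
                # phase A: fresh valid seeds; keep the least-binding one
                seeds = 0
                while spent < budget and seeds < 4:
                    spent += 1
                    toehold = sample_toehold(rng, constraints, model)
                    stem5 = sample_stem5(rng, constraints)
                    c0 = make_candidate(
                        name, toehold, stem5, constraints, model,
                        fail_fast=True)
                    if not c0.all_passed:
                        continue
                    seeds += 1
                    s0 = _cross_score(c0, accepted, constraints, model,
                                      abort_above=score)
                    if s0 < score:
                        cand, score = c0, s0
                    if score <= 0.0:
                        break
            if cand is None:
                break
            # phase B: anneal the summed cross-binding margin down with
            # seeded, structure-targeted point mutations; stall counts
            # proposals since the last strict improvement.  The two-state
            # margin is slightly conservative, so the exact equilibrium check
            # runs as soon as the surrogate gets close.
            if score < best_score:
                best_cand, best_score = cand, score
            hot, stem_hot = _offending_positions(cand, accepted, constraints, model)
            logger.debug("slot %d: seed at spent=%d, score %.2f", slot, spent, score)
            stall = 0
            checked_at = np.inf  # lowest score already exact-checked
            while spent < budget and stall < 1500:
                if score <= 0.3 and score < checked_at - 1e-9:
                    checked_at = score
                    found = exact_accept(cand)
                    if found is not None:
                        break
                    logger.debug(
                        "slot %d: score %.2f but exact check failed",
                        slot, score)
                    stall += 100 if score > 0 else 300
                # hot exploration until the last kcal, then greedy finishing
                anneal_T = 1.0 if score > 1.0 else 0.1
                spent += 1
                stall += 1
                mut = _mutate(cand, rng, constraints, model, name, hot, stem_hot)
                if not mut.all_passed:
                    continue
                if _max_complementary_run(mut, accepted, model) >= 9:
                    continue  # a >=9 bp contiguous WC duplex cannot be weak enough
                abort = score + 3.0 * anneal_T
                s2 = _cross_score(
                    mut, accepted, constraints, model, abort_above=abort)
                if s2 < score - 1e-9:
                    cand, score, stall = mut, s2, 0
                    if score < best_score:
                        best_cand, best_score = cand, score
                    hot, stem_hot = _offending_positions(
                        cand, accepted, constraints, model)
                elif s2 <= abort and rng.random() < np.exp(-(s2 - score) / anneal_T):
                    # annealing move: keep the (slightly stale) hot positions;
                    # they are refreshed on the next strict improvement
                    cand, score = mut, s2
            logger.debug(
                "slot %d: phase B ended at spent=%d score %.2f found=%s",
                slot, spent, score, found is not None)
            # no luck: restart phase A with fresh seed candidates

        if found is None and accepted and best_cand is not None:
            # the remaining constraints could not be satisfied by moving the
            # new candidate alone: repair the whole tentative set jointly
            # (the sequential loop's counterpart of multi-tube co-design)
            members = accepted + [best_cand]
            repaired = _joint_repair(members, rng, constraints, model,
                                     budget=budget)
            if repaired is not None:
                accepted = repaired[:-1]
                found = repaired[-1]
        if found is None:
            partial = _finalize(accepted, constraints, model) if accepted else None
            raise DesignError(
                f"budget of {budget} candidates exhausted at slot {slot} "
                f"({len(accepted)} accepted)", partial=partial)
        for prev in accepted:
            dg_tt = duplex_dG(prev.trigger.sequence, found.trigger.sequence, model)
            if dg_tt < constraints.trigger_duplex_warn_dG:
                warnings.warn(
                    f"trigger-trigger duplex {prev.trigger.name}/"
                    f"{found.trigger.name} at {dg_tt:.2f} kcal/mol",
                    stacklevel=2)
        accepted.append(found)
    return _finalize(accepted, constraints, model)


def _finalize(
    pairs: list[CandidatePair],
    constraints: DesignConstraints,
    model: EnergyModel,
) -> LibraryDesign:
    matrix, reports = crosstalk_matrix(
        [p.swt for p in pairs], [p.trigger for p in pairs], constraints, model)
    lib = LibraryDesign(
        pairs=tuple(pairs),
        crosstalk=matrix,
        tube_reports=reports,
        defect=0.0,
        seed=constraints.rng_seed,
        constraints=constraints,
    )
    defect = multi_tube_defect(lib, constraints, model)
    return replace(lib, defect=defect)


def multi_tube_defect(
    library: LibraryDesign,
    constraints: DesignConstraints | None = None,
    model: EnergyModel | None = None,
) -> float:
    """Concentration-weighted off-target score summed over the declared tubes.

    Tube categories follow the screening setup: individual-construct tubes
    (on-target: the free monomer), the pooled all-SWTs and all-triggers tubes
    (on-target: free monomers), and every SWT x trigger pair tube (on-target:
    the cognate duplex for cognate pairs, free monomers otherwise).  For each
    strand in each tube the fraction of its total allocated to complexes other
    than its on-target is accumulated; a perfectly orthogonal library scores ~0.
    """
    constraints = constraints or library.constraints
    model = model or EnergyModel.default()
    swts = [p.swt for p in library.pairs]
    triggers = [p.trigger for p in library.pairs]
    cognate = {(p.swt.name, p.trigger.name) for p in library.pairs}
    _, reports = (library.crosstalk, library.tube_reports)
    if not reports:  # pragma: no cover - reports always built by _finalize
        _, reports = crosstalk_matrix(swts, triggers, constraints, model)

    defect = 0.0
    for res in reports["individual"].values():
        for name in res.totals:
            defect += 1.0 - res.free_fraction[name]
    for res in reports["pooled"].values():
        for name in res.totals:
            defect += 1.0 - res.free_fraction[name]
    for (s_name, t_name), res in reports["pairs"].items():
        on_duplex = (s_name, t_name) in cognate
        for strand in res.totals:
            if on_duplex:
                defect += 1.0 - res.bound_fraction("swt", "trigger")
            else:
                defect += 1.0 - res.free_fraction[strand]
    return defect
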