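"""Composition and in-silico audit of multilayered SWT circuits.

A circuit layer couples a switch (SWT) to an output signal: either a trigger
for a downstream layer (the layer's transcript would encode it after the
terminator) or the fluorescent reporter.  Cascades chain layers so each
switch, once activated, emits the trigger of the next; the two-input OR gate
uses two converter layers emitting one common trigger that drives a single
reporter layer.

Evaluation is Boolean-threshold at equilibrium: a switch is ON when some
present upstream signal activates it past ``theta_on`` (predicted bound
fraction).  This deliberately models composition logic, not transcription
kinetics.  Internal signals are matched by sequence identity, not by name.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .core_seq import NucSeq, SWTDesign, TriggerDesign
from .designer import (
    CandidatePair,
    DesignConstraints,
    predicted_activation,
)
from .thermo import EnergyModel, TubeSpec, equilibrium_concentrations

__all__ = [
    "WiringError",
    "REPORTER",
    "CircuitLayer",
    "Circuit",
    "TruthTable",
    "compose_cascade",
    "compose_or_gate",
    "remove_layer",
    "evaluate_circuit",
    "truth_table",
    "circuit_crosstalk_audit",
]


class WiringError(ValueError):
    """Circuit layers do not connect into a valid signal path."""


REPORTER = "REPORTER"


@dataclass(frozen=True)
class CircuitLayer:
    """One switch layer: the SWT it carries and the signal it emits when ON
    (a TriggerDesign, or the REPORTER marker for the terminal layer)."""

    switch: SWTDesign
    output: TriggerDesign | str

    @property
    def emits_reporter(self) -> bool:
        return isinstance(self.output, str) and self.output == REPORTER


@dataclass(frozen=True)
class Circuit:
    """A DAG of switch layers driven by named external input triggers.

    With ``strict=False`` the exactly-one-consumer and reporter-reachability
    checks are skipped so deliberately broken assemblies (leave-one-out
    controls) can still be evaluated; cycle and duplication checks remain.
    """

    layers: tuple[CircuitLayer, ...]
    inputs: tuple[TriggerDesign, ...]
    cognate_triggers: dict[str, NucSeq] = field(default_factory=dict)
    # cognate_triggers maps each switch name to the trigger sequence that
    # activates it (wiring is validated on sequences, not names)
    strict: bool = True

    def __post_init__(self) -> None:
        if not self.layers:
            raise WiringError("a circuit needs at least one switch layer")
        reporters = [l for l in self.layers if l.emits_reporter]
        if len(reporters) != 1:
            raise WiringError("exactly one layer must emit the reporter")
        names = [l.switch.name for l in self.layers]
        if len(set(names)) != len(names):
            raise WiringError("switch names must be unique")
        self._validate_wiring()

    def _validate_wiring(self) -> None:
        cognate = dict(self.cognate_triggers)
        internal = [l.output for l in self.layers if not l.emits_reporter]
        # every internal signal must be cognate to exactly one downstream switch
        for sig in internal:
            matches = [
                l.switch.name for l in self.layers
                if cognate.get(l.switch.name) == sig.sequence
            ]
            if len(matches) > 1 or (self.strict and not matches):
                raise WiringError(
                    f"internal signal {sig.name} must drive exactly one switch "
                    f"(drives {matches or 'none'})")
        # no switch may emit its own activating signal (self-loop)
        for layer in self.layers:
            if (not layer.emits_reporter
                    and cognate.get(layer.switch.name) == layer.output.sequence):
                raise WiringError(
                    f"layer {layer.switch.name} emits its own trigger (cycle)")
        # the reporter layer must be reachable from every input
        order = self._topological_order()
        reachable = {sig.sequence for sig in self.inputs}
        reached_reporter = set()
        for layer in order:
            if cognate.get(layer.switch.name) in reachable:
                if layer.emits_reporter:
                    reached_reporter.add(layer.switch.name)
                else:
                    reachable.add(layer.output.sequence)
        if self.strict and self.inputs and not reached_reporter:
            raise WiringError("the reporter is not reachable from the inputs")

    def _topological_order(self) -> list[CircuitLayer]:
        """Layers sorted so producers precede consumers; cycles rejected."""
        cognate = dict(self.cognate_triggers)
        producers: dict[str, list[int]] = {}
        for idx, layer in enumerate(self.layers):
            if not layer.emits_reporter:
                producers.setdefault(layer.output.sequence, []).append(idx)
        order: list[int] = []
        state = [0] * len(self.layers)  # 0 new, 1 visiting, 2 done

        def visit(idx: int) -> None:
            if state[idx] == 2:
                return
            if state[idx] == 1:
                raise WiringError("circuit contains a cycle")
            state[idx] = 1
            sig = cognate.get(self.layers[idx].switch.name)
            for up in producers.get(sig, []):
                visit(up)
            state[idx] = 2
            order.append(idx)

        for idx in range(len(self.layers)):
            visit(idx)
        return [self.layers[i] for i in order]


def _cognate_map(pairs: list[CandidatePair]) -> dict[str, NucSeq]:
    return {p.swt.name: p.trigger.sequence for p in pairs}


def compose_cascade(pairs: list[CandidatePair]) -> Circuit:
    """Chain library pairs into a cascade: the external input is the first
    pair's trigger; layer i emits layer i+1's trigger; the last layer emits
    the reporter.

    With L pairs this is an (L+1)-layer circuit counting the input layer.
    Raises :class:`WiringError` for duplicate switches or triggers shared
    between roles.
    """
    if not pairs:
        raise WiringError("a cascade needs at least one pair")
    seqs = [p.trigger.sequence for p in pairs]
    if len(set(seqs)) != len(seqs):
        raise WiringError("cascade pairs must have distinct trigger sequences")
    layers = []
    for i, pair in enumerate(pairs):
        output = pairs[i + 1].trigger if i + 1 < len(pairs) else REPORTER
        layers.append(CircuitLayer(switch=pair.swt, output=output))
    return Circuit(
        layers=tuple(layers),
        inputs=(pairs[0].trigger,),
        cognate_triggers=_cognate_map(pairs),
    )


def compose_or_gate(
    converter_a: CandidatePair,
    converter_b: CandidatePair,
    output: CandidatePair,
    *,
    emit_a: TriggerDesign | None = None,
    emit_b: TriggerDesign | None = None,
) -> Circuit:
    """Two-input, three-layer OR gate: each converter switch, activated by its
    own external input, emits the output switch's cognate trigger; the output
    switch emits the reporter.

    ``emit_a``/``emit_b`` override the converters' emitted signals (both must
    equal the output pair's trigger, by sequence).
    """
    emit_a = emit_a if emit_a is not None else output.trigger
    emit_b = emit_b if emit_b is not None else output.trigger
    if emit_a.sequence != emit_b.sequence:
        raise WiringError("the two converters must emit the same signal")
    if emit_a.sequence != output.trigger.sequence:
        raise WiringError(
            "converters must emit the output switch's cognate trigger")
    names = {converter_a.swt.name, converter_b.swt.name, output.swt.name}
    if len(names) != 3:
        raise WiringError("OR gate requires three distinct switches")
    if output.swt.name in (converter_a.swt.name, converter_b.swt.name):
        raise WiringError("a converter cannot double as the output switch")
    layers = (
        CircuitLayer(switch=converter_a.swt, output=emit_a),
        CircuitLayer(switch=converter_b.swt, output=emit_b),
        CircuitLayer(switch=output.swt, output=REPORTER),
    )
    return Circuit(
        layers=layers,
        inputs=(converter_a.trigger, converter_b.trigger),
        cognate_triggers=_cognate_map([converter_a, converter_b, output]),
    )


def remove_layer(circuit: Circuit, switch_name: str) -> Circuit:
    """Leave-one-out control: the circuit with one (non-reporter) switch layer
    removed, returned non-strict so the broken signal chain can still be
    evaluated (it should report OFF for every input)."""
    kept = tuple(l for l in circuit.layers if l.switch.name != switch_name)
    if len(kept) == len(circuit.layers):
        raise WiringError(f"no layer carries switch {switch_name!r}")
    return Circuit(
        layers=kept,
        inputs=circuit.inputs,
        cognate_triggers={
            k: v for k, v in circuit.cognate_triggers.items() if k != switch_name},
        strict=False,
    )


@dataclass(frozen=True)
class TruthTable:
    """2^k rows of (input presence -> reporter state), with the per-layer
    activation fractions retained for inspection."""

    input_names: tuple[str, ...]
    rows: tuple[dict, ...]

    def __post_init__(self) -> None:
        if len(self.rows) != 2 ** len(self.input_names):
            raise ValueError("a truth table needs 2^k rows")

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for row in self.rows:
            rec = dict(zip(self.input_names, row["inputs"]))
            rec["reporter"] = "ON" if row["reporter_on"] else "OFF"
            recs.append(rec)
        return pd.DataFrame(recs)

    def reporter_states(self) -> list[bool]:
        return [bool(r["reporter_on"]) for r in self.rows]


def evaluate_circuit(
    circuit: Circuit,
    input_presence: dict[str, bool],
    constraints: DesignConstraints | None = None,
    model: EnergyModel | None = None,
    theta_on: float = 0.5,
) -> dict:
    """One truth-table row: propagate the present inputs through the layers.

    A switch turns ON when any present signal's predicted activation (bound
    fraction at the screening concentration) reaches ``theta_on``; an ON layer
    adds its output signal to the present set.  The reporter state is the
    terminal switch's state.
    """
    constraints = constraints or DesignConstraints()
    model = model or EnergyModel.default()
    present: dict[NucSeq, str] = {
        t.sequence: t.name for t in circuit.inputs if input_presence.get(t.name)
    }
    layer_activation: dict[str, float] = {}
    layer_state: dict[str, bool] = {}
    reporter_on = False
    for layer in circuit._topological_order():
        best = 0.0
        for seq in present:
            trig = TriggerDesign(
                name=present[seq], mode=circuit.inputs[0].mode,
                sequence=seq, cognate=layer.switch.name)
            best = max(
                best,
                predicted_activation(layer.switch, trig, constraints, model))
        on = best >= theta_on
        layer_activation[layer.switch.name] = best
        layer_state[layer.switch.name] = on
        if on:
            if layer.emits_reporter:
                reporter_on = True
            else:
                present.setdefault(layer.output.sequence, layer.output.name)
    return {
        "inputs": tuple(
            bool(input_presence.get(t.name)) for t in circuit.inputs),
        "reporter_on": reporter_on,
        "layer_activation": layer_activation,
        "layer_state": layer_state,
    }


def truth_table(
    circuit: Circuit,
    constraints: DesignConstraints | None = None,
    model: EnergyModel | None = None,
    theta_on: float = 0.5,
) -> TruthTable:
    """Evaluate all 2^k input combinations."""
    names = tuple(t.name for t in circuit.inputs)
    rows = []
    for combo in itertools.product([False, True], repeat=len(names)):
        rows.append(
            evaluate_circuit(
                circuit, dict(zip(names, combo)), constraints, model, theta_on))
    return TruthTable(input_names=names, rows=tuple(rows))


def circuit_crosstalk_audit(
    circuit: Circuit,
    constraints: DesignConstraints | None = None,
    model: EnergyModel | None = None,
) -> dict:
    """Pool every circuit species in one tube and flag each non-cognate pair
    whose bound fraction exceeds the crosstalk threshold.

    This is the model-level analogue of combining all cascade components in
    one reaction, the condition under which higher-order circuits were
    observed to accumulate crosstalk.
    """
    constraints = constraints or DesignConstraints()
    model = model or EnergyModel.default()
    cognate = dict(circuit.cognate_triggers)

    species: dict[str, NucSeq] = {}
    for t in circuit.inputs:
        species.setdefault(t.name, t.sequence)
    for layer in circuit.layers:
        species.setdefault(layer.switch.name, layer.switch.transcript)
        if not layer.emits_reporter:
            species.setdefault(layer.output.name, layer.output.sequence)

    names = sorted(species)
    tube = TubeSpec(
        species=tuple((n, species[n]) for n in names),
        concentrations=tuple(constraints.concentration for _ in names),
    )
    result = equilibrium_concentrations(tube, model)

    cognate_pairs = set()
    for layer in circuit.layers:
        sig = cognate.get(layer.switch.name)
        for n in names:
            if species[n] == sig:
                cognate_pairs.add(frozenset((layer.switch.name, n)))

    flagged = []
    seen = set()
    for i, a in enumerate(names):
        for b in names[i:]:
            key = frozenset((a, b)) if a != b else frozenset((a,))
            if key in seen or key in cognate_pairs:
                continue
            seen.add(key)
            frac = max(result.bound_fraction(a, b), result.bound_fraction(b, a))
            if frac > constraints.crosstalk_threshold:
                flagged.append({"pair": (a, b), "bound_fraction": frac})
    flagged.sort(key=lambda r: -r["bound_fraction"])
    return {"tube": result, "flagged": flagged, "species": names}
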