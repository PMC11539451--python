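# Methods

`swtkit` designs and audits switchable transcription terminators (SWTs):
RNA elements in which a linear toehold precedes an intrinsic (rho-independent)
terminator — a GC-rich hairpin stem, a small loop, and a poly-U tract.  In the
OFF state the hairpin halts RNA polymerase; a cognate trigger RNA complementary
to the toehold and the 5' stem arm invades the hairpin by toehold-mediated
strand displacement and switches transcription ON.  This note records the
models, the numerical choices, and the limits of what the package's tests can
show.

## Sequence model

All sequences are RNA (A/C/G/U), 5'→3'; DNA input is transcribed on read.
Coordinates are 0-based, half-open.  An SWT decomposes as
`toehold | stem5 | loop | stem3 | polyU` with `stem3 = revcomp(stem5)`.
Trigger variants are reverse complements of selected domains: toehold-only,
stem-only, toehold+stem (default — the variant screen found partial triggers
cannot disrupt the terminator, and extending into the loop slightly hurts),
and toehold+stem+loop.

The stem design space for a query of length *L* with exactly *k* A-U/U-A pairs
is `C(L, k) · 2^L` distinct duplexes (each position has two orientations).
Moving from the 7-bp all-GC stem to a 10-bp stem with exactly one non-GC pair
expands the space `C(10,1)·2^10 / 2^7 = 80`-fold.  "Exactly one" (not "at
most one") is the operational reading that reproduces this count.

Defaults that the source material leaves open, chosen once: poly-U length 8 nt
(typical for a strong intrinsic terminator), loop `GAAA` (a stable tetraloop
of the right size).  The named stem-loop presets of specific published
constructs live in supplementary tables we do not ship; the package therefore
provides its own synthetic default rather than guessing them.

## Thermodynamic engine

A self-contained nearest-neighbor free-energy model at fixed temperature
(default 310.15 K; `RT` is always derived from the temperature):

* Watson-Crick stack free energies follow the Turner 2004 37 °C set; wobble
  (G·U) stacks are approximate published values.  The stack table satisfies
  the strand-flip symmetry `S[p1][p2] = S[flip(p2)][flip(p1)]` exactly.
* Hairpin (≥ 3 nt), bulge and internal loops carry size-dependent initiation
  penalties, logarithmically extrapolated (`ΔG(n) = ΔG(n_max) +
  1.75·RT·ln(n/n_max)`) beyond the tables; interior/bulge loops are capped at
  total size 30 in the dynamic programs (standard practice).
* Multiloops are affine: 3.4 kcal/mol per loop + 0.4 per branch (closing pair
  included), unpaired bases free.
* A bimolecular complex pays one duplex-initiation penalty (4.09 kcal/mol,
  1 M reference).
* Deliberate simplifications: no dangles, no coaxial stacking, no terminal-AU
  penalties, no single-bulge stack term, no loop-sequence bonuses, no
  homodimer symmetry corrections, no pseudoknots.  Consequently absolute
  energies differ from full Turner/NUPACK values; only orderings and
  qualitative screens are claimed.

Minimum free energy and partition functions are computed by O(n³)-class
dynamic programs (numba-compiled).  Two-strand complexes are handled by a
nick-aware decomposition: every connected dimer structure has a unique
outermost nick-spanning pair, and the nick lies on the face of the unique
innermost spanning pair; any loop face containing the nick scores zero (an
exterior-like loop).  The dimer ensemble sums connected structures only, so a
pair with no complementarity has Q = 0 and ΔG = +∞.

The independent oracle is `enumerate_structures`: brute-force generation of
every pseudoknot-free structure (≤ 20 nt total) scored by the explicit
loop-decomposition evaluator `structure_energy`.  The test suite checks the
DP partition function against the enumerated sum to 10⁻⁶ relative and the DP
MFE against the enumerated minimum on hundreds of random strands and pairs,
plus hand-summed fixtures.

## Test-tube equilibria

A tube is a set of strands with total concentrations (default 10 nM each)
and complexes up to dimers.  Mass-action constants come from ensemble free
energies, `K_ij = exp(−(ΔG_ij − ΔG_i − ΔG_j)/RT)` (1/M).  Free monomer
concentrations are solved by damped Newton iteration on log-concentrations
with a Levenberg fallback, preceded by damped fixed-point sweeps: designed
duplexes have K up to ~10⁵⁵ M⁻¹, and Newton started at `x = totals` would
face a numerically rank-deficient Jacobian.  Convergence tolerance is 10⁻¹²
relative mass residual (bound 10⁻⁹ asserted everywhere); free-monomer
fractions down to ~10⁻³⁰ remain meaningful because the solve is logarithmic.
Bound fractions are clamped to [0, 1] against ~10⁻¹⁴ solver rounding.

Near-cognate pairs saturate: at 10 nM a 50-bp perfect duplex leaves a free
fraction ~10⁻²⁶, so the bound fraction is exactly 1.0 in double precision.
Where an ordering among saturated activations matters (the trigger-variant
comparison), the package asserts it on the complementary free-monomer
fraction, which is the numerically resolvable form of the same inequality.

## Orthogonal library design

Candidate constraints (defaults are the screening conditions): toehold 40 nt,
GC in [0.50, 0.60], structurally open at the MFE; stem 10 bp with exactly one
A-U/U-A pair; trigger = revcomp(toehold+stem5), "linear" meaning trigger MFE
≥ −2 kcal/mol (a strict MFE = 0 requirement is unsatisfiable once the GC-rich
stem complement rides on the trigger, and structure that marginal cannot
resist toehold-nucleated displacement); the SWT's own MFE must contain the
designed hairpin with the toehold unpaired; and the fully-hybridized
SWT·trigger complex — allowing the free 3' tail (loop+stem3+polyU) to fold on
its penalty-free nicked face — must be the dimer MFE.

Activation is the equilibrium bound fraction of the SWT in a two-species tube
at the screening concentration: the in-silico analogue of the experimental
ON/OFF matrix (the model cannot predict fluorescence).  A library is accepted
when every diagonal activation ≥ 0.90 and every off-diagonal ≤ 0.05.

Plain rejection sampling cannot reach this: random non-cognate 50–72-nt pairs
bind at ΔΔG ≈ −20…−30 kcal/mol (bound fraction ≈ 1 at 10 nM), while the
threshold requires ΔΔG ≥ −9.5.  The design loop is therefore an optimizer,
the package's counterpart of multi-tube ensemble-defect sequence design:

1. seed each slot with valid random candidates (best of several);
2. anneal the summed positive cross-binding margin over all accepted pairs
   (both directions) with seeded point mutations at T = 1 kcal/mol (0.1 in
   the last kcal), biased toward the candidate positions engaged in
   inter-strand pairs of the worst off-target complex's MFE structure and
   away from bases that would recreate those pairs;
3. prescreen mutants with a certain-violation bound (each strand's MFE fold
   plus the best contiguous exterior helix is an admissible dimer structure,
   hence an upper bound on the dimer ensemble ΔG) and a ≥ 9-bp contiguous
   WC-complementarity cutoff;
4. verify near-threshold candidates with the exact equilibrium solve (the
   two-state margin surrogate is slightly conservative);
5. basin-hop from the slot's best candidate when progress stalls, and, if a
   slot exhausts its budget, switch to a joint repair stage: anneal the whole
   tentative library at once (mutations may hit any member, drawn by its
   share of the remaining conflicts, with delta-updated pair margins).  A
   single new member often cannot absorb all remaining conflicts, but
   distributing them across the set — the essence of multi-tube co-design —
   resolves them in a few hundred to a few thousand proposals.

The per-slot proposal budget is 10,000, scaled up beyond slot 3 where the
number of simultaneous cross constraints grows.  Everything is driven by one
seeded generator, so a rerun with the same seed is byte-identical.
Trigger-trigger duplexes are reported as warnings above a configurable bound
rather than constrained — they do not affect switching directly but do
contribute to the multi-tube defect.

The multi-tube defect aggregates, over the three declared tube categories
(individual constructs; pooled SWTs and pooled triggers; every SWT×trigger
pair), the fraction of each strand's concentration allocated to complexes
other than its on-target (the cognate duplex in cognate pair tubes, the free
monomer everywhere else).  A perfectly orthogonal library scores ≈ 0; real
libraries carry a nonzero defect dominated by trigger-trigger association in
the pooled tube.

## Circuits

Cascades chain accepted pairs: the external input is the first pair's
trigger, each switch layer emits the next pair's trigger, the last layer
emits the reporter.  The two-input OR gate wires two converter switches to a
common output trigger feeding one reporter switch.  Wiring is validated on
sequence identity (one producer-consumer match per internal signal, acyclic,
reporter reachable); `strict=False` plus `remove_layer` supports
leave-one-out controls that are deliberately broken but still evaluable.

Evaluation is Boolean-threshold at equilibrium: a switch is ON when any
present signal's activation reaches `theta_on` (default 0.5); an ON layer's
output joins the present signal set; the truth table iterates all 2^k input
combinations.  This models composition logic only — no transcription rates,
no kinetics, no fluorescence magnitudes.  The pooled crosstalk audit puts all
circuit species in one tube and flags every non-cognate pair whose bound
fraction exceeds the crosstalk threshold.

## Assay statistics

Normalized fluorescence subtracts the batch mean of the no-template control
rows; the fold change divides the normalized ON mean by the normalized OFF
mean (`ratio_of_means` default, `mean_of_ratios` exposed because published
fold changes do not always state the convention).  A normalized OFF mean ≤ 0
makes the fold change undefined and raises, never clamps.  Endpoint analysis
uses the 2 h timepoint by default.  Welch's unequal-variance t-test (scipy)
provides significance with Welch–Satterthwaite degrees of freedom.

The plate simulator draws `rfu = mean · (1 + cv · z)` with standard normal
`z`, seeded — multiplicative noise because plate-reader scatter scales with
signal; this is a fixture choice, not an instrument model.  The ratio-of-means
estimator carries an O(CV_den²) positive bias where CV_den is the relative
error of the background-subtracted OFF denominator; with an OFF signal close
to background it can exceed 2% even at cv = 0.05.  The recovery tests
therefore use a well-separated OFF signal (ON/OFF/background =
3700/400/100 RFU, programmed fold 12), the regime in which the estimator is
effectively unbiased; parameter recovery there is within ~0.3% over 1000
seeded plates.

## Problem sizes and determinism

The test suite and the acceptance script use: exhaustive-oracle comparisons
on ≥ 200 random inputs of ≤ 18 nt; a designed 3-member library (plus a
byte-identical rerun and one 5-member run) at the full 40-nt toehold study
conditions; truth tables over all input combinations of the designed
circuits; and 1000 seeded plate simulations.  Every stochastic step flows
from an explicit integer seed; the acceptance script derives all of its seeds
from `--seed` and retries the design with deterministically shifted seeds if
a particular seed's search exhausts its budget.

## Known limitations

* Energies are model-specific: no dangle/coaxial/terminal corrections, so
  absolute ΔG values are not comparable to full Turner implementations.
* Orthogonality is an equilibrium bound-fraction statement at 10 nM with
  complexes ≤ 2; it says nothing about transcription kinetics, polymerase
  occlusion, or co-transcriptional folding.
* Circuit evaluation is Boolean and steady-state; it cannot reproduce
  time courses or quantitative fold changes of layered reactions.
* The plate simulator emulates replicate scatter around programmed means
  only; passing recovery tests demonstrates the analysis pipeline, not
  instrument behavior.
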