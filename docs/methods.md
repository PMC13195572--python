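# Methods

This note records the models implemented in `tdnkit`, their assumptions,
the defaults that matter, and what the synthetic designs do and do not
emulate.

## Strand and design model

Strands are ordered nucleotides with a base (A/C/G/T/U), a sugar chemistry
(DNA, RNA, LNA, 2′-O-Me) and the backbone linkage on the 3′ side (PO or
PS). Positions are 1-based and inclusive; all ranges are closed intervals.
Pairing is strictly Watson–Crick (A–T, A–U, G–C); G·U wobble is rejected,
because the designs analyzed here are fully complementary by construction.
Base-identity conventions follow common synthesis practice: LNA carries T,
RNA and 2′-O-Me carry U; the choice affects only which nearest-neighbor
table row is read, never the chemistry rules.

The tetrahedron is the classic four-strand, six-edge design: every
unordered pair of strands shares exactly one duplex edge, each strand
traverses three edges, and short unpaired hinges sit at the two interior
vertices each strand turns through. Defaults are 20 bp per edge and 2-nt
hinges, giving 3×20 + 2×2 = 64-nt strands — consistent with the device's
printed 64–66-nt strand lengths, and forced exactly for the RNA-containing
strand by the cleavage arithmetic below (64 − 13 = 51). A regular
tetrahedron with 20-bp edges has height 20 × 0.34 nm × √(2/3) ≈ 5.6 nm.
The helix diameter is deliberately not added to that estimate; treat it as
a lower bound when comparing with AFM apparent heights.

The gapmer chemistry scheme is a symmetric wing pattern around a central
unmodified-DNA block. The default (gapmer B) is 20 nt with wings of four
LNA then two 2′-O-Me from each end, leaving an 8-nt DNA gap, and three PS
linkages at each end. A fully modified steric blocker is the same type with
wings meeting in the middle (empty gap).

## RNase H cleavage rule

RNase H cleaves the RNA strand of an RNA:DNA heteroduplex but is blocked by
2′-sugar modifications on either strand of the local duplex. The model is
deliberately minimal: linkage *i* (between nucleotides *i* and *i*+1 of the
cleaved strand) is competent iff nucleotide *i* is RNA and the base pairs
at *i* and *i*+1 both exist and contain no LNA or 2′-O-Me nucleotide. The
main cut is the 3′-most competent linkage — immediately before the first
modified base pair toward the RNA 3′ end, matching the known 3′-directed
cut pattern on gapmer substrates. PS linkages do not block cleavage in this
model (fully-PS gapmers are active); they only carry a small thermodynamic
increment.

On the default layout (RNA block at strand positions 7–16, gapmer DNA gap
pairing positions 7–14) this rule yields competent linkages 7|8 … 13|14:
possible 5′ fragments of 7–13 nt, a main fragment of 13 nt, a retained
7-bp segment, and a covalent remainder of 51–57 nt for the 64-nt strand.
These integers depend only on the layout, never on drawn sequences. Minor
cuts are enumerated but not weighted: no sequence-specific cleavage
preference is modeled, and only the main cut feeds the downstream
landscape and kinetics analyses.

## Nearest-neighbor thermodynamics

Stacks use the unified DNA:DNA ΔH/ΔS set and a published RNA:DNA hybrid
set, temperature-adjusted (default 310.15 K) with a uniform per-stack
monovalent-salt entropy correction 0.368·ln[Na⁺] cal/(mol·K) (default
150 mM). Modifications are additive free-energy increments per base pair —
defaults LNA −1.0, 2′-O-Me −0.2 kcal/mol, split half-and-half between the
two stacks a pair touches, and PS +0.1 kcal/mol per linkage at its stack.
The increment ordering (LNA strongest stabilizer) matches the field's
affinity ranking; the magnitudes are defaults, not fits, and every
downstream result that depends on them is either an ordering/monotonicity
statement or explicitly calibrated (below). Dangling ends and coaxial
stacking at nicks are neglected; duplex initiation is a single penalty
(default 2.0 kcal/mol), with a separate tethered-segment initiation
(default 2.0 kcal/mol) for closing the first base pair of a segment held
covalently by the framework.

## Landscapes

**Fraying (toehold exposure).** The retained 7-bp segment opens as a
single-coordinate zipper from the cleavage-created free end; interior
bubbles are excluded, which keeps the state space exactly enumerable and
mirrors a 1-D reaction coordinate in intact base pairs. State *s* holds the
*s* pairs nearest the anchored end; E(0) = 0 and E(s ≥ 1) = tether
initiation + cumulative stacks. The tether term appears only when at least
one pair is closed, so the landscape exhibits an entropic barrier to
rebinding the first base pair from the open state — and the open state
itself pays no initiation. "Toehold available" means all pairs open
(s = 0); a partial-availability definition (any set of open coordinates)
is available as an option.

The bound-vs-open difference ΔG_open is reported between the landscape
endpoints. With default increments the default design gives ΔG_open ≈ 6.6
kcal/mol; a calibration mode rescales the modification increments by one
bracketed-bisection factor so ΔG_open matches a user-supplied value (for
this device, 3 kcal/mol, where the two-state occupancy at 310.15 K is
0.76% — under 1%). Calibration is always explicit: it returns a new model
object and is surfaced on the CLI as `--calibrate`.

**Strand displacement.** The coordinate is invader base pairs formed,
m = 0 … toehold + incumbent. Toehold zippering pays one initiation then
accrues invader stacks. Each branch-migration step exchanges one incumbent
stack for one invader stack and passes over an intermediate plateau at
coordinate m − 0.5, sitting `bm_plateau_dG` (default 2.0 kcal/mol, in line
with measured branch-migration barriers) above the higher neighbor state.
Because the incumbent fragment sat against a nick at the toehold junction,
the invader ends up with one more stack than the incumbent had; that
junction stack is realized at the commitment step together with the
incumbent's initiation refund. This bookkeeping makes the migration region
exactly level for identical chemistries and keeps the landscape total
independent of step order. With a 7-nt toehold and a 13-nt incumbent the
global minimum is full displacement (m = 20): the reaction is driven
thermodynamically by the toehold, and the committed state is where the
catalytic cycle's displacement step fires.

## Monte Carlo verification

Because each landscape is a small finite state space, its Boltzmann
occupancy is computed exactly; the samplers exist to verify the
umbrella-sampling methodology against that oracle, not to estimate
anything unreachable. The Metropolis chain proposes ±1 moves with
rejection at the ends (detailed balance under the symmetric proposal).
Umbrella windows add per-state biases; the default layout is one discrete
harmonic bias ½k(s − c)² per coordinate value with stiffness k = 2.0
kcal/mol per step², chosen so each window concentrates on its center while
neighboring windows overlap (acceptance between neighbors ~ exp(−k/2RT)).
Reweighting iterates the discrete multi-histogram (WHAM) equations to a
1e-8 kcal/mol tolerance on window shifts and raises an error when windows
are not connected through co-visited states. At 1e5 steps per window the
round trip recovers constructed landscapes to well within 0.1 kcal/mol per
state; at 1e6 unbiased steps the empirical distribution of the 8-state
fraying landscape sits within 0.02 total variation of the exact one. All
samplers take one integer seed and record it in their outputs.

## Catalytic-cycle kinetics

Species: intact site, cleaved-closed, toehold-open, target-bound,
target-duplex (displacement complete, target now a cleavable hybrid), free
target, cleaved target, free 13-nt fragment. Two exact conservation laws —
total sites and total targets — are declared on the network and re-checked
on every trajectory. RNase H is implicit: cleavage of either heteroduplex
is pseudo-first-order, because no enzyme concentration or turnover number
is available for this system. Opening/closing satisfies
k_open/k_close = exp(−ΔG_open/RT) by construction; the displacement rate
is an Arrhenius prefactor times exp(−barrier/RT) with the barrier read off
the displacement landscape; binding is mass-action through an effective
volume. After target cleavage both product fragments dissociate instantly
and the site regenerates to toehold-open; fragment rebinding is neglected
(its rates are unknowable here).

Default rate placeholders: cleavage 0.05 /s, closing 1e3 /s, binding
1e6 /(M·s) in a 1.66e-16 L effective volume (100 targets ≈ 1 µM),
displacement prefactor 1e2 /s. None is fitted; they are chosen to put the
system in the regime the device analysis identifies — toehold availability
limiting — while keeping a 600-s trajectory at tens of thousands of events
on one CPU. With sites:targets at 1:10 and the calibrated 3 kcal/mol
toehold, each site cleaves several targets in 600 s (turnover > 1), the
stochastic analog of complete target consumption under excess.

The rate-limiting report lumps the closed/open flicker as one
"toehold presentation and binding" waiting state and attributes
time-integrated site occupancy to each cycle step; the step whose waiting
state holds the largest share of post-activation time is flagged. Under
defaults that is toehold presentation; accelerating opening ~100× moves
the flag to target cleavage.

Mean-field ODEs integrate the identical network with LSODA (rtol 1e-8);
the SSA ensemble mean agrees with the ODE within sampling error (checked
at counts of order 10³ on a decay network where 60 replicates give a
sub-percent standard error).

## Synthetic designs: what they emulate, and what they don't

The generator reproduces the published *layout* — strand count, edge
length, gapmer position and chemistry, RNA-block register, heteroduplex
edge, 64-nt strand length — with random sequences under per-edge GC bounds
(0.3–0.7) and a crosstalk screen rejecting unintended antiparallel
complementary runs ≥ 8 nt between any strand pair (including
self-complementarity), with bounded retries. It does not reproduce the
device's actual sequences (not available), its NUPACK-optimized ensemble
properties, hinge sequence identity, or any tertiary-structure effect.
Consequently, passing tests demonstrate the layout-determined results
(cleavage arithmetic, landscape shapes, cycle behavior) and the
methodology (sampling vs exact enumeration); they do not certify
sequence-specific folding or orthogonality of the real device beyond the
k-mer screen.

## Numerical choices and degenerate inputs

- Gas constant R = 1.98720425e-3 kcal/(mol·K); probabilities normalized to
  1 within 1e-12.
- Landscape reference states carry dG exactly 0; coordinates are strictly
  increasing, with half-integer coordinates reserved for branch-migration
  plateau intermediates.
- Duplex energy requires ≥ 2 bp; fraying requires ≥ 2 bp; an RNA-free
  duplex has an empty competent set (not an error) while cut prediction on
  an empty set raises.
- Metropolis acceptance is computed as 1 for downhill moves to avoid
  overflow under extreme biases; WHAM treats never-visited states as a
  non-overlap error rather than returning infinities.
- The crosstalk screen normalizes U→T before complement matching, so an
  RNA block cannot hide a DNA-level complementary run.
- Calibration brackets the scale factor in [−50, 50] and bisects to 1e-9
  kcal/mol.

## Known limitations

- The cleavage model is a chemistry rule; it predicts *where* cuts can
  occur, not their relative frequencies.
- Thermodynamic defaults are literature-shaped placeholders; quantitative
  landscape magnitudes should be read only after explicit calibration, and
  the 3-D mechanics of the tetrahedron enter only through two scalar
  initiation parameters.
- Cycle rate constants are placeholders; the simulator supports regime
  exploration and consistency checks, not kinetic prediction.
- DLS conversion assumes the Rayleigh d⁶ regime and bin independence;
  tetrahedron height ignores helix diameter and vertex geometry.
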