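# Model and methods

## The system being modelled

Glycoprotein VI (GPVI) is the collagen receptor of platelets and
megakaryocytes.  Monomeric GPVI binds collagen weakly; dimerisation
raises the ligand affinity, so the fraction of receptors in dimeric
form is a proxy for the membrane's readiness to signal.  Two features
of the platelet plasma membrane plausibly control that fraction:
cholesterol/glycolipid-enriched nanodomains ("lipid rafts") in which
lateral diffusion is slower, and crowding by the many other
transmembrane proteins.  `raftsim` is an agent-based model of exactly
this: hard discs diffusing on a small periodic patch of membrane, with
a stochastic monomer-dimer interconversion rule and static circular
low-diffusivity domains.

## Geometry and units

The simulation box is a square torus of side `L = 30` dimensionless
units; distances use the minimal-image convention.  The scaling module
anchors these units to measurements: assuming a spherical platelet of
volume 7.4 fl, the membrane area is 1.8x10^-11 m^2; with rafts of
diameter 200 nm covering 35% of it there are ~205 raft-sized patches
per platelet, so one box (one central raft) is ~0.3 um across, holds
47 of the platelet's ~9600 GPVI copies, and a receptor disc (crystal
long axis 114 A) spans 3.8% of the box.  With the measured diffusivity
0.091 um^2/s, the expected per-tick displacement of 12.5 nm fixes the
tick at ~0.43 ms via MSD = 4Dt.  A mouse preset (4.7 fl, 7800 copies)
ships alongside; surface densities come out at ~533 (human, printed
area) and ~575 (mouse) molecules/um^2.  All intermediates are carried
unrounded; a regression test checks that working from printed
(2-significant-figure) intermediates moves no derived output by more
than 3%.

## Agents and motion

Agents are discs: monomers (radius 0.57 = 3.8% of L / 2), dimers
(radius sqrt(2) x monomer, conserving disc area exactly), and optional
inert crowders (radius 0.75, i.e. diameter 5% of L).  Each tick every
agent, visited in a fresh uniform random order, proposes one jump:
direction uniform, length `sqrt(D) |N(0,1)|` (half-normal; a Rayleigh
law of scale sqrt(D) is available via `step_length_law` because the
expected-step calibration uses the Rayleigh mean (pi/2)^1/2 — the two
differ only in the shape of the step-length distribution, and the
half-normal reading of the Wiener-process rule is the default).
Dimers move slower by 2^(-1/4) (Stokes-Einstein: D ~ 1/R, step ~
sqrt(D)); crowders by a factor 0.5.  `D` is `d_in` when the agent's
centre lies in any confined domain (closed disc, evaluated at the
start position — boundary crossings within a tick are not
sub-resolved) and `d_out` otherwise.  A jump whose destination would
overlap any other disc (strict inequality; tangency allowed) is
rejected and the agent keeps its position for that tick; rejected
moves are not re-drawn, which would otherwise inflate the effective
diffusivity in crowded states.

Confined domains are static circles, fixed for a whole run: one circle
at the box centre, or `n` equal circles (equal total area) placed by
uniform non-overlapping rejection sampling.  Membership is wrap-aware,
so swept areas up to 80% run unchanged even though such a circle's
radius exceeds L/2 (its nominal area is then marginally above the true
covered area — only the top end of the area sweep is affected).
Whether crowders should also slow down inside domains is not
specified by any measurement; they are subject to the same d_in/d_out
field as receptors, which is irrelevant in the shipped experiments
(crowding runs have no domains).

## Reactions

Two monomers whose rim-to-rim gap is at most 10% of a monomer diameter
are capture candidates (a centre-to-centre reading of that threshold
would be geometrically impossible for non-overlapping discs).  Each
tick, a monomer with at least one candidate dimerises with probability
`k_b` (one draw per focal molecule, applied to the nearest candidate;
ties broken uniformly at random); the two monomers are replaced by one
dimer at their minimal-image midpoint.  A dimer dissociates with
probability `k_d`.  Defaults are k_b = 0.05 and k_d = 0.01 per tick,
chosen so neither species disappears at equilibrium.  Molecule count
(n_monomers + 2 n_dimers) and total receptor disc area are conserved
by construction at every event.

**Dissociation placement.**  Two placements are implemented.

* `cocentric` (default): both product monomers appear at the dimer's
  centre, forming a transient *encounter pair*.  Each product fits
  inside the old dimer footprint, so the event never fails; the pair
  overlaps only each other and separates when one of them draws a jump
  long enough to clear its partner (or rebinds first — the pair is
  within capture range while co-located).  This makes the effective
  dissociation rate strongly diffusion-dependent: at low D the escape
  jump is many standard deviations long, dissociations are almost
  always undone, and the dimer fraction climbs — which is what gives
  the model its strong dependence of dimerisation on diffusivity,
  confinement contrast and crowding.
* `tangent`: products are placed rim-to-rim along a uniformly random
  axis, retried up to 20 axes against the excluded-volume constraint,
  and deferred (dimer kept, counter logged) if no axis fits.  Under
  this placement the reaction is nearly microscopically reversible and
  the equilibrium dimer fraction is almost independent of diffusivity
  — a scientifically instructive contrast, kept fully tested.

Similarly, `reaction_overlap_veto` (default off) controls whether a
conversion is abandoned when the newly placed disc would overlap a
bystander.  With the veto off (default), excluded volume is enforced
by movement rejection only, matching a scheduler in which only the
random-walk step is overlap-checked; reaction-created overlaps relax
diffusively within a few ticks.  With the veto on, every visited state
is a strict hard-disc configuration, and the all-pairs no-overlap
oracle holds exactly — the property suite exercises both regimes.

## Protocol and observables

A run starts from uniformly placed crowders, then monomers (rejection
sampling; a packing failure names the achieved count), with no dimers.
The standard protocol is 200,000 ticks; observables are recorded every
10 ticks (`thin`) and averaged over the final 50,000 ticks; every
configuration is repeated over 3 replicate seeds (seed, seed+1, ...)
and reported as mean +/- sample SD.  Observables: monomer and dimer
counts, the dimeric fraction 2 n_dimers / (n_monomers + 2 n_dimers),
and the molecule-weighted fraction of receptors whose centre lies
inside a domain.  Runs are bit-reproducible for a given seed (the tick
loop is a single-threaded, seeded numba kernel; a pure-Python
reference scheduler implements the identical rules and is
cross-checked statistically against the kernel).

## The ten experiments

Presets 1-10 sweep, in order: (1) localisation vs D_out:D_in contrast
(1..2^10, no reactions); (2) dimerisation vs contrast; (3) dimerisation
vs domain area (0-80%) x contrast (1..2^5); (4) domain merging — fold f
merges a reference layout of 8 equal domains into round(8/f) domains
at fixed 35% total area (results are insensitive to this convention,
which is the point of the experiment); (5) 0-200 inert crowders, no
domain; (6) crowder disintegration — one crowder disc of diameter L/2
split into 1..256 equal-area discs; (7) global D over 2^-5..2^5, no
domain; (8) fraction-inside vs domain area 15-22% at 10:1 contrast
with k_b in {0, 0.01, ..., 0.000625} and k_d = k_b/5; (9) receptor
density 25-200% of the 47-copy default; (10) a 9x9 grid of k_b x k_d
at 60-140% of defaults.  The confined-area estimate inverts an
ordinary-least-squares fit of fraction-inside vs area at 50%; a
non-positive slope or a crossing outside the swept range +/- 25%
attaches an explicit warning.

## Numerical choices

* Overlap tests use a relative tolerance of 1e-12 so that exactly
  tangent discs (as produced by tangent dissociation) never count as
  overlapping.
* Neighbour searches use a cell-list grid (cell size >= the largest
  interaction distance); boxes too small for a 3x3 grid fall back to
  all-pairs scans.  A 500-configuration test pins the grid to the
  brute-force oracle.
* Agents created mid-tick are stamped and skipped until the next tick,
  preventing double updates; a slot freed and re-used within one tick
  can therefore never be visited twice.
* The kernel checks molecule conservation at every record and the run
  aborts (rather than repairing) on violation.
* Replicate seeds are consecutive integers from the master seed;
  output directories embed the config echo, seeds and per-file
  checksums sufficient for bit-exact re-runs.

## What the model does and does not capture

The generator emulates a single raft-scale membrane patch with
identical, non-interacting receptor copies and purely probabilistic
reaction rules.  It omits cytoskeletal fences and pickets, raft
birth/death and mobility (domains are static within a run; merging is
modelled across runs), higher-order clusters (no trimers+), explicit
collagen ligand — ligand effects enter only through the k_b/k_d grid —
and any receptor-crowder specific interaction.  Consequently, passing
tests show that confinement, crowding and slow diffusion *can*
reproduce the observed enrichment and dimerisation levels under these
assumptions, not that the real membrane achieves them this way.

Known limitations.  The strength of localisation at *intermediate*
diffusivity contrasts is the least constrained feature of this class
of model: it is set by the stationary density ratio of a jump process
with position-dependent step length across a sharp boundary, which is
sensitive to exactly how and where the step length is evaluated.  In
this implementation (step drawn from the start position's D) the
fraction inside a 35% domain crosses 50% at a contrast of ~2.5 and
localisation at 10:1 is correspondingly strong; consequences are a
slightly lower confined-area estimate (~19% rather than 20-21%) —
still below the 21% bound, and conservative in the direction that
estimate is used — a mid-range dimerisation curve that rises earlier than the
endpoint calibration suggests, and a modest (+7 pp across the full
fold range) merging trend where near-invariance is expected.  Endpoint
behaviour (ratio 1, extreme contrast, no-domain baselines) is
insensitive to this choice.
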