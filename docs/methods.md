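# Methods

## Model and assumptions

The middle ear is reduced to six lumped degrees of freedom moving along a
single horizontal axis. The skull (M0) carries the stimulus; everything
else hangs from it through springs and dashpots. The malleus and incus
are rigid pendulums hinged to the skull along the anterior–posterior
axis; their tip motions X3, X4 stand in for the rotations via the
small-angle substitutions θ₃ = (X3−X0)/L3, θ₄ = (X4−X0)/L4 (vertical tip
motion is second-order and dropped). The cochlear fluid is a point mass
rigidly co-moving with the stapes, restrained by the round-window
stiffness and a velocity-proportional fluid resistance. Assumptions worth
keeping in mind:

* **Linear, harmonic, small-displacement.** Each frequency is solved
  independently; no transients, no amplitude dependence.
* **Skull one-way coupling.** The skull row keeps only M0·Ẍ0 = F0; the
  soft-tissue reaction forces on a ~5 kg skull are negligible. This is
  why the assembled [C] and [K] are symmetric only over the moving-node
  block — column X0 is one-sided by construction.
* **Rotation-only ossicles.** The malleus/incus suspensions are assumed
  translationally rigid. Real ears show a second resonance anywhere in
  3–10 kHz that likely involves translational ossicle motion; this model
  instead places its second umbo resonance near 9 kHz (see Limitations).
* **No cochlear travelling wave.** The cochlea enters only as mass,
  resistance and window compliances; intracochlear pressures and
  compressional bone-conduction mechanisms are out of scope.

## Parameters

All values are SI. Torsional quantities carry an `_t` suffix (N·m/rad,
N·m·s/rad) so they cannot be mixed with translational stiffnesses (N/m).
Four built-in sets:

* `fitted` — the bone-conduction-fitted values; the reference set.
* `feng_gan_2004`, `oconnor_puria_2008`, `rosowski_merchant_1995` —
  transcribed from three published air-conduction models, converted with
  the lever lengths Lm = 6.28 mm, Li = 4.83 mm and areas
  A_fp = 3.2 mm², A_tm = 60 mm² (e.g. a published ossicle mass M becomes
  the moment of inertia I = M·Lm²; an acoustic compliance C becomes a
  stiffness A²/C).

Entries the sources do not provide are filled deterministically and
logged at load time: absent stiffness/damping couplings become 0; absent
masses take the Feng–Gan values (the published substitution rule for M1,
extended to M2/M6 because a zero mass is physically meaningless here);
the skull mass, absent from all three adopted columns, takes the fitted
5 kg — under BC forcing the relative transfer functions are analytically
independent of M0, so this choice is observable only in absolute motion.
The Rosowski–Merchant incudomalleolar joint is published as rigidly
fused and is represented by 10⁶ × the fitted joint stiffness/damping; a
test verifies the response is insensitive to a 10× change of that
constant (max |Δ| < 0.05 dB).

Field-name reconciliations, fixed once: the round-window stiffness is
stored as `K9` (some sources label it K10 — same element, the only
compliance besides the annular ligament tying the fluid back to the
skull); the 5 kg skull mass is stored as `M0`.

`A_canal` (default 4×10⁻⁵ m², a typical adult canal cross-section) is
**not** part of any published column; it only converts ear-canal pressure
to force for AC runs and is configurable per parameter set.

User parameter files are YAML with keys equal to the field names; a
`base:` key naming a built-in set supplies defaults for omitted fields.

## Virtual ear conditions

The seven conditions mirror the published cadaver protocol; each is a
pure edit list applied to a parameter set (composable, base untouched):

| condition | rule |
|---|---|
| `stapes_glued` | K8 := 5×10⁴ N/m |
| `malleus_glued` | K̃m := 0.8 N·m/rad |
| `mass_100mg_umbo` | M2 += 10⁻⁴ kg, C1 := 0.4 N·s/m |
| `is_joint_cut` | K8 := 0, C6 := 0 (published rule; see below) |
| `mass_on_stapes` | M5 += 20 mg (7.5 mg also exercised) |
| `cochlea_drained` | C9 := 0, K9 := 0 (after `is_joint_cut`) |

**The joint-cut ambiguity.** The published simulation rule for cutting
the incudostapedial joint is printed as "K8 = 0 and C6 = 0", which zeroes
the annular ligament but leaves the joint stiffness K6 connected — a
physically surprising rendering of a joint separation (the literal one
would be K6 = 0, C6 = 0). Neither variant is chosen silently: the default
follows the printed rule, and `isjc_variant="k6"` (CLI `--isjc-variant
k6`) switches to the literal one everywhere, including the composed
post-cut conditions. The choice matters mostly for the post-cut stapes
curves: under the printed rule the drained-cochlea stapes resonates near
1.7 kHz and sits above the normal curve at all grid frequencies (no
crossover); under the k6 variant it resonates near 2.5 kHz, likewise
without a crossover. Neither reproduces the ~4 kHz drained-cochlea
resonance and ~2 kHz crossover described alongside the original model,
which we could not reproduce from the printed rules under any variant;
the discrepancy is deliberately left visible rather than patched with an
unpublished rule.

## Numerical choices

* **Grid**: 512 log-spaced points over 0.1–10 kHz (the band in which BC
  middle-ear data are reported). With quadratic peak refinement this
  keeps peak-localization error below 0.5 % of the peak frequency. The
  normal umbo curve's second resonance sits close enough to 10 kHz that
  its right flank is clipped by the default window; analyses of that
  feature extend the grid to 16 kHz (640 points).
* **Solve**: dense complex `numpy.linalg.solve` per frequency; ω = 0 is
  excluded by precondition (the skull row has no stiffness, so the static
  system is singular). The condition number is logged above 10¹⁰ —
  never approached by the built-in scenarios at 6×6, but kept for
  user-supplied extremes.
* **dB convention**: 20·log₁₀|velocity ratio|; exact zeros are floored at
  −300 dB. Phase is unwrapped along increasing frequency and reported in
  cycles.
* **Peak picking**: local extrema of the dB curve with prominence
  ≥ 0.5 dB (catches the shallow ~1.6 kHz peak of the 20-mg-loaded stapes
  while rejecting grid ripple), refined by a 3-point parabola in
  log-frequency. Threshold configurable.
* **Crossovers**: sign changes of the dB difference, located by linear
  interpolation in log-frequency; reporting starts above 200 Hz, where
  both curves are clear of the rigid-body floor.
* **Exact identities**: the absolute transfer function is formed as
  relative + 1 so the pointwise identity between the two kinds holds to
  the last bit; V = iωX by construction.
* **Randomized tests** draw parameter scalings in [0.2, 5] around the
  fitted set with a fixed seed (20260928) and check the assembled
  matrices row-by-row against an independent transcription of the six
  force/torque balances at 10⁻¹² relative tolerance.

## What the simulations show — and what they do not

The model reproduces the qualitative BC phenomenology: umbo and stapes
relative motion vanishing ∝ f² at low frequency (+12 dB/octave), a first
resonance near 2 kHz for both, suppression of stapes motion by stapes
fixation at all frequencies, near-insensitivity of the umbo to a joint
cut, downward resonance shifts under mass loading, and a stiffness-to-
mass crossover when the malleus is glued. The AC cross-check inherits the
same ~2 kHz first resonance. These are deterministic consequences of the
fitted parameters, not fits performed by this package: no optimization
ships here, and simulated curves are compared with published *described
features* (peak and crossover frequencies), not with digitized
measurement curves, which are not distributed.

## Limitations

* One resonance mechanism per pendulum: the measured inter-ear variation
  of the second (3–10 kHz) resonance, attributed to translational
  ossicle motion, cannot be represented.
* The drained-cochlea manipulation could not be reconciled with the
  published description under the printed rules (see above); results for
  that condition should be interpreted with the `--isjc-variant` switch
  in mind.
* The fitted eardrum mass M2 is 5× the typical literature value — a
  property of the fitted set itself (verified by
  `parameter_ratio_report`), retained verbatim.
* Phases are computed but have no published measured counterpart to
  compare against.
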