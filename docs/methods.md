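# Methods

## Scope and model structure

`spinfrac` models one lane of a centrifugal density-gradient fractionation
disk as a one-dimensional radial system: an ordered stack of media sections
`[r_p, r_d)` from the sample chamber (proximal) to the disk rim (distal),
with a capillary burst valve at each internal boundary.  Three physical
sub-models are chained:

1. **Valve statics** (Young–Laplace): holding pressure of a pinned meniscus
   vs the centrifugal pressure of the liquid column behind it, giving a
   burst rotation rate per valve.
2. **Sedimentation kinetics** (Stokes drag, low Reynolds number): each cell
   species moves radially outward with velocity
   `v = (2/9) R_eff² (ρ − ρ°) a / η`, where `a = ω² r` is the local
   centrifugal acceleration.  At constant angular velocity this integrates
   to an exponential trajectory and the logarithmic transit-time closed
   form; a medium with ρ° ≥ ρ is non-traversable and the cell bands at its
   proximal interface.
3. **Count-table statistics**: retention/exclusion/enrichment of measured
   or synthetic fraction counts, summarized across replicate disks.

Lanes are independent (no lane-to-lane coupling), media are homogeneous
within a section, and there is no diffusion, hindered settling, or
interface broadening — each cell is an isolated Stokes sphere.

## Constant-speed approximation vs the trajectory integrator

The closed form uses a single angular velocity for the whole lane,
converted from the protocol's plateau RCF at one reference radius (default:
the lane's outer rim, 60 mm).  In reality RCF varies with local radius;
only the numerical integrator (`spinfrac.trajectory`) uses the local
`ω² r` acceleration and time-varying ω(t).  Oracle comparisons between the
two are therefore run at constant ω with matched conventions, where they
agree to better than 0.1% relative (typically ~1e-7%).

## Ramp correction and ramp shapes

Spin-up and spin-down deliver less ω²-exposure than plateau time.  For a
ramp of duration t that is linear in RPM (ω ∝ t), ∫ω²dt = t·ω_p²/3, i.e.
one third of plateau-equivalent exposure; for a ramp linear in RCF
(ω² ∝ t) it is one half.  Both are asserted numerically in the test suite.
The closed-form schedule adds the wall-clock correction `2(t_a + t_d)/3`
once per lane total, which is exact for linear-in-RPM ramps: needing τ
seconds of plateau-equivalent sedimentation costs `τ + 2(t_a + t_d)/3`
seconds of wall clock when the crossing falls on the plateau.  Because
ramp rates are quoted in RCF/min, the simulator's default ramp shape is
linear-in-RCF (`ramp_shape="rcf"`), with `"rpm"` available; the two
readings differ by `(t_a + t_d)/6` of effective time and neither is
singled out as ground truth.

## Partition assignment and the trapped-interface convention

`predict_partitions` advances each species through the sections for the
effective plateau-equivalent time `t_a + plateau + t_d − 2(t_a + t_d)/3`
and assigns the section containing its final radius under the half-open
`[r_p, r_d)` convention.  A cell blocked by a dense medium rests exactly at
the blocking interface radius, which this convention assigns to the
*blocking* (distal-side) section.  This is deliberate: the banded layer
sits at the top of the blocking section's fluid and is retrieved by opening
that section's ports — e.g. leukocytes floating on the first
Histopaque-1077 section are counted with that section.  The same rule
handles the degenerate case of a sample that cannot leave the sample
chamber at all (the chamber itself is the blocking section).
`MigrationResult.terminal_section` follows the same convention, so schedule
and partition reports never disagree about where a cell ends up.

## Parameters and defaults

| Parameter | Default | Units | Why |
|---|---|---|---|
| Disk radius | 60 | mm | stock disk geometry |
| Section radial extent | 7 | mm | stock disk geometry, 6 sections F→A tiling 18–60 mm |
| Valve footprint | 1 × 7 | mm | stock geometry; contained within the section boundary so the radial extents still tile the disk |
| Channel height | 0.67 | mm | sum of the bonded adhesive-stack layers (0.05 + 0.28 + 0.34 mm); configurable |
| Medium density (Histopaque-1077) | 1.077 | g/mL | vendor specification |
| Medium viscosity | 1.5 | mPa·s | vendor-typical value for Ficoll-based media at room temperature; not a device-specific measurement, config-overridable |
| Blood σ / θ_A / ρ / η | 58 mN/m / 110° / 1.06 g/mL / 4 mPa·s | | literature-typical whole-blood values on acrylic; not device-specific, config-overridable |
| Protocol | 500 RCF plateau, 4 min, +500 / −322 RCF/min | | stock separation protocol |
| Cell panel | six species, range midpoints | g/mL, μm | published density/radius ranges are collapsed to their midpoints (single printed value for the red cell); any species can be overridden per config |
| RCF↔RPM anchor | lane outer radius | m | one quoted RCF must map to one ω; the rim is where the quoted RCF is largest and matches how bench centrifuges are specified |
| g | 9.80665 | m/s² | exact by convention |

Representative-value caveat: the basophil range (1.072–1.078 g/mL)
straddles the 1.077 g/mL medium, so whether basophils migrate depends
entirely on the chosen representative density; with the 1.075 midpoint they
do not.  Density ties (ρ = ρ°) are treated as non-traversable (zero Stokes
velocity).

With midpoint densities the model predicts that granulocytes
(ρ > 1.077 g/mL) eventually pass the first gradient section, while single
(non-aggregated) red cells — small and only slightly denser than the
medium — stall mid-lane.  Red-cell clearance to the rim in the modelled
4-minute protocol requires rouleaux aggregation, expressed as an
`agglutination_factor` multiplying the effective radius (3 in the examples:
time scales as 1/R², a 9× speed-up).  The closed-loop demonstration
therefore represents the leukocyte class by its mononuclear species
(lymphocyte-like, 1.075 g/mL): a short-spin model cannot simultaneously
keep midpoint-density granulocytes in the first section, and this
divergence between the isolated-sphere model and measured whole-blood
behaviour (where ~95% of all leukocytes stay proximal) is a known
limitation, not a bug.

## Synthetic count tables

The generator samples each (disk, class) count vector from a multinomial
over sections — totals per class are exact, so per-section retention sums
to 100% by construction — with one seed per spec and per-disk streams
derived by fixed unit increments (disk *d* uses `seed + d`, so a disk's
counts do not depend on how many disks were requested).
`generate_prediction_fixture` converts a predicted partition into a
probability spec with mass 1−ε on the predicted section and ε (default
0.02, a plausible carry-over/misbanding allowance) spread uniformly over
the rest.  What the generator emulates is counting noise around a fixed
banking pattern; it does not emulate the physics of partial banding,
section cross-contamination during extraction, or counting bias, so tests
built on it validate the metric and bookkeeping pipeline, not the
biological fidelity of the partition itself.

## Numerical choices

* Integrator: scipy `solve_ivp` RK45, rtol 1e-9 / atol 1e-14 m by default,
  section-by-section with a terminal event at each distal boundary, and
  integration split at ramp corners so the adaptive stepper never straddles
  a kink.  Velocity is clamped at zero in a blocking medium (no flotation
  modelling).
* The driving-pressure formula is used as a magnitude,
  `½ρω²|r_d² − r_p²|`, so an outward column always yields a positive
  driving pressure.
* Section contiguity and disk-fit checks use a 1 nm absolute tolerance;
  transit additivity over split sections holds to floating precision
  because the logarithm factorizes.
* Wetting fluids (θ_A ≤ 90°) yield a zero burst threshold with an explicit
  `DegenerateValveWarning` rather than a negative pressure.
* Config units are bench units (mm, g/mL, mPa·s, mN/m, degrees, μm)
  converted once at the I/O boundary; the writer divides by exactly the
  factors the reader multiplies by, so write-then-read round-trips are
  bit-identical.  A g/mL field above 100 is rejected as a probable kg/m³
  value.

## Problem sizes

Randomized oracle comparisons use 50 single-section instances; burst-root
cross-checks 100 instances; synthetic-table convergence uses 10⁶ counts per
class and the closed-loop demonstration 10⁶ counts × 3 disks — sizes at
which multinomial sampling error (≲0.05 percentage points) is negligible
against the 0.5-point assertions.

## Known limitations

* Single-particle Stokes motion: no hindered settling at hematocrit-level
  concentrations, no cell–cell interactions, no interface band width.
* The agglutination factor is a static multiplier; real rouleaux form and
  break dynamically during the spin.
* Valve statics only: no meniscus dynamics, contact-angle hysteresis, or
  re-pinning after burst.
* The closed form's single-ω convention understates speeds proximal to the
  reference radius; use the trajectory integrator when local-radius
  accuracy matters.
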