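# Model and methods

`mitosim` simulates the onset of mitosis in a budding yeast with semi-open
mitosis and cytoplasmic microtubule-organising centres (MTOCs): many MTOCs
scattered over the nuclear envelope (NE) coalesce into a single spindle
pole body (SPB) while the nucleus is carried from the mother cell into the
growing daughter bud.  Both processes are driven by cytoplasmic
microtubules (cMTs) interacting with cortical force generators — dynein,
which pulls on cortex-penetrating cMT segments, and the plus-end tracker
Bim1, which biases cortex-engaged plus ends toward the septin ring.

## Geometry

The cell is the union of two spheres ("snowman"): the mother (radius
`r_mother` = 3 um, fixed) and the daughter bud, whose radius grows linearly
in time until the budding index (bud diameter over mother diameter) reaches
`final_budding_index` = 0.8 at `bud_growth_duration` = 42 min.  The septin
ring is the circle where the two spheres intersect; its radius is held at
`neck_fraction` = 0.85 of the current bud radius, and the bud centre is
placed on the (random, per-cell) bud axis so both surfaces pass through the
ring.  The cortex is the shell of width `w_cor` inside the boundary.  The
bud site, the initial nucleus position (uniform over full containment) and
the 14 founding MTOCs (uniform on the NE, non-overlapping) are the random
initial conditions; each cell is one seed.

An optional septum constriction (an annulus in the septin plane that the
nucleus must clear, fields `septin_ring_radius`, `k_septum`) is available
but disabled by default (`k_septum = 0`): with the default two-sphere
geometry the neck is wide enough for passage once the bud matures, and the
constriction suppressed migration indiscriminately in all scenarios.

## Cytoplasmic microtubules

Each cMT is a straight, zero-thickness rod pivoting freely about its
minus-end anchor (an MTOC or SPB on the NE).  Plus ends follow two-state
dynamic instability (growth `v_g` = 10.4 um/min, shrinkage `v_s` =
28.6 um/min, catastrophe `f_c` = 1/min wild type, rescue `f_r` = 0.02/min);
a fully depolymerised rod renucleates with a fresh random orientation in
the outward hemisphere.  In free space the stationary length distribution
is exponential with mean `v_g*v_s/(v_s*f_c − v_g*f_r)` ≈ 10.5 um, which the
test suite verifies against a vectorised stochastic oracle; in the
confined cell the realised mean length is ~2.3 um, close to the measured
wild-type mean of 2.63 um.

Load modulation follows the standard force-velocity forms,

    v_g(f) = v_g0 exp(−f/f_stall)
    f_c(f) = f_c_stall / (1 + (f_c_stall/f_c0 − 1) exp(−f/f_stall)),

with `f` the *net* axial load opposing growth: compression from the cortex
minus the tension applied by engaged dynein.  The tension term, capped at
one stall force, means a motor-gripped tip catastrophises more slowly than
a free one — the standard cortical-capture behaviour.  (We read the
exponents as exp(−f/f_stall) so that growth stalls and catastrophe rises
toward `f_c_stall` under compressive load; the source prints the exponent
with the opposite sign, which would make loaded tips grow faster — the
only physically consistent reading is the one used here.)

At the cortex:

* **push** — elastic compression `l_cor * K_cor` inward along the rod,
  where `l_cor` is the tip penetration depth into the shell (bounded by
  `w_cor`).  A tip stalled against the hard boundary transmits at most the
  weaker of the combined elastic + first-order Euler buckling response
  (`pi^2 kappa / L^2`) and the polymerisation stall force — a tip cannot
  push harder than it can grow.
* **pull** — collective dynein, `l_seg * lambda * f_dyn` outward along the
  rod, where `l_seg` is the length of the rod segment lying inside the
  cortical shell (the chord, capped at 1.5 um to bound the number of
  engaged motors) and `lambda` the local dynein density.
* **wall impulse** — a rod that switches to shrinkage at the boundary
  delivers a ~1 pN inward impulse.
* **sliding** — a tip reaching the boundary at shallow incidence
  (< `sliding_angle_deg` = 30 deg from the surface) tracks the cortex
  surface; sliding is sticky (a tracking tip keeps following the surface,
  across the neck into the daughter cortex) until catastrophe.  In the
  mother cortex the sliding direction is a mixture of the incident
  tangential direction and the tangent toward the nearest septin-ring
  point, weighted by the local competition between Bim1 and dynein,
  `beta = B * lambda_bim1 / (lambda_bim1 + lambda_dyn_mother)`.  Tips that
  reach the ring carry straight on across the neck.

Bim1 acts at the plus end with a dynein-like force law
`B * l_cor * lambda_bim1 * f_dyn` directed tangentially toward the ring.
Because the rod pivots about its anchor, this tip force mostly *reorients*
the rod (tip mobility from slender-body theory, `xi_tip ≈ c_perp L / 3`);
a small fraction (0.25) is transmitted down the rod to the anchor and the
nucleus.  Cortical forces otherwise act axially and are applied to both
the anchoring MTOC/SPB and the nucleus, as the equations of motion
prescribe.

Two recruitment processes gate the motor forces: per-engagement maturation
(Bim1/dynein accumulate at a plus end while it dwells in the cortex, ramp
time `dynein_engagement_time` = 60 s — this selects persistent, sliding
engagements over brief stalls) and a global build-up of cortical motor
copy number proportional to bud growth (factor `t/bud_growth_duration`,
capped at 1).  The daughter-cortex dynein pull acts on cMTs only after SPB
duplication, when the mature poles nucleate their full complement of cMTs;
before that, daughter contacts are steric only.

## Cortical program and scenarios

Dynein density is `lambda_dyn` = 6/um on the mother cortex (times
`mother_dynein_multiplier`), and in the daughter `lambda_dynein_patch` (in
a condensed spherical cap of 10 % of the daughter area centred on the bud
apex) or `lambda_dynein_rest` elsewhere; with both multipliers at 1 (the
default) the field is uniform.  Bim1 (`lambda_bim1` = 6/um) lives only on
the mother cortex.

The bias scale `B in [0, 1]` equals 1 in the wild type.  With the
length-dependent bias enabled (Ipl1 depletion), each cell's B is
`min(1, exp((l − l_wt_ref)/bias_length_const))` with `l` the cell's
unconfined mean cMT length implied by its catastrophe frequency and
`l_wt_ref` = 2.63 um; B scales the Bim1 force, the sliding bias weight
and — in the Ipl1 scenarios — the mother-cortex dynein pull ("effective
cortical bias mediated by Bim1 and dynein").

Scenarios: `wild_type_cib` (Table defaults); `ipl1_heterogeneous`
(per-cell `f_c ~ Uniform(1, 21)` per min plus length-dependent bias);
`ipl1_homogeneous` (uniformly destabilised cMTs at fixed `f_c`, uniform
bias); `bim1_delta` (`lambda_bim1 = 0`); `dyn1_oe` (mother dynein x3);
`dynein_puncta_scan` (grid over the daughter patch/background
multipliers).

## Nuclear spindle

MTOC bodies in surface contact merge at their volume-weighted midpoint
(re-projected on the NE) with volume-conserving radius; clustering is
complete when one body holds all 14 founders, which triggers SPB
duplication (two half-volume bodies offset by `2 r_spb` on the NE).  Each
of 14 kinetochores is tethered beneath its founding MTOC by a soft spring
pre-duplication; afterwards each binds a kMT from the nearer pole.
Growing kMT tips push with `l_pen * K_fibril`, shrinking tips pull through
a connector spring `l_gap * K_c` (gap capped at 0.2 um so spring forces
stay bounded); kMT catastrophe rises linearly with length (`h_kmt`,
default 50 /min/um, chosen so the stationary kMT length is about half the
pole-pole separation).  Interpolar MTs (two per pole) generate the
kinesin-5 sliding force `l_overlap * lambda_ipmt * f_kinesin5`; sister
kinetochores are linked by cohesin springs and all kinetochores repel on
overlap (1 pN/um).  All internal forces are applied in equal and opposite
pairs.

## Equations of motion

All bodies are overdamped: `dX/dt = F/xi`, Euler integration at
`dt` = 0.05 s.  Drags follow Stokes' law `6 pi eta r` with cytoplasm
(5 pN s/um^2) for the nucleus, the NE effective viscosity (10) for
MTOCs/SPBs, and nucleoplasm (10) for kinetochores (radius 0.1 um).
MTOCs/SPBs are advected with the nucleus (they ride on the envelope),
moved by their own forces, then re-projected radially onto the NE sphere
(residual < 1e-6 um each step); kinetochores are confined inside the
nucleus; the nucleus is confined in the cell by a soft penalty sampled
over 64 fixed directions (stiffness 10 x `K_cor` per violating sample,
compensating the sparse sampling).  Thermal noise is omitted; all
randomness enters through dynamic instability and the initial
configuration, so trajectories are bit-reproducible per seed.  The
integrator aborts if any per-step displacement exceeds `r_spb`; the
nominal bookkeeping bound of `0.1 r_spb` can legitimately be exceeded for
single steps when several motors engage one low-drag SPB at once, so only
order-of-magnitude violations abort.

## Observables

Clustering time: first time (since bud emergence, t = 0) one body holds
all founders.  Migration time: first time the signed neck-to-nucleus
distance (septin plane to nucleus centre, positive toward the daughter)
exceeds `r_nuc` — the centre a full radius past the plane.  Runs without
an event are censored at the 60-min cutoff; censored runs are excluded
from means and included in completion fractions.  Population summaries
report means with SEM, completion fractions, and histograms of the final
neck-to-nucleus distance.

## Calibration and problem sizes

Measured parameters are taken as given.  Gap constants were fixed as
follows: `w_cor` = 0.18 um, `kappa_mt` = 0.2 pN um^2 and
`dynein_engagement_time` = 60 s set the push/pull balance and were
calibrated, together with the bud growth schedule (42 min to budding
index 0.8, close to the experimental ~35 min time scale), against the
wild-type clustering (~23 min) and migration (~38 min) means — they are
calibration-consistency checks, not predictions.  `bias_length_const`
= 0.65 um is the designated calibration constant of the exponential bias;
within this implementation its leverage on the Ipl1 population statistics
turned out to be small (see limitations).  One cMT per interphase MTOC
and 20 per mature SPB; 100-cell populations run in about one minute.

Acceptance-scale runs use n = 50–100 cells instead of the 2000 used for
the published population statistics, so population means carry SEMs of
roughly 1 min.

## What the simulated populations do and do not show

The generator *is* the study system here: each run is a synthetic cell
drawn from the stated initial-condition distributions.  Passing the
desk-scale checks shows the mechanical scheme reproduces the in-silico
population statistics at reduced n; it does not validate the coarse
graining against real cells beyond the features the model encodes (no
explicit motor binding kinetics, no membrane deformation, no thermal
noise, no chromosome arms, no anaphase).

Known limitations:

* In the Ipl1-depletion scenario, cells with strongly destabilised cMTs
  (roughly `f_c` > 5/min) almost never complete migration within the
  60-min cutoff in this implementation: the migration delay manifests as
  censoring (~85–90 % of mutant cells) rather than as late completion.
  The mean migration time over *uncensored* mutant runs (~35 min)
  therefore under-represents the delay and falls below the published
  ~47 min; the delay is unambiguous in censoring-aware statistics
  (completion 10–15 % vs ~85 % wild type; cutoff-substituted mean ~57 vs
  ~42 min).  The same selection effect makes the uncensored-mean ordering
  between mutant and wild type unreliable, which is why the ordering
  checks use cutoff-substituted times.
* Migration is not abolished when the daughter-cortex dynein density is
  set to zero: in this implementation the Bim1-biased mother-cortex
  program plus cortical pushing can still carry the nucleus through the
  (wide) mature neck.  The daughter pull accelerates and stabilises
  migration but is not strictly required, contrary to the source model's
  zero-pull prediction.
* Roughly 5–15 % of wild-type runs complete migration slightly before the
  final MTOC fusion event; the population summary flags this ordering
  statistic rather than enforcing it.
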