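# Methods

`icbsim` is a reduced quantitative-systems-pharmacology (QSP) simulator of
immune-checkpoint blockade in metastatic melanoma.  One virtual patient is a
deterministic stiff ODE system of 28 cellular/molecular states plus five
pharmacokinetic states per administered antibody; a virtual clinical trial
is a Latin-hypercube sample of patients run through the same system.  This
note records the model, its assumptions, the parameters that matter, and
the numerical choices, in the order the signal flows through the system.

## Molecular layer: receptor occupancy and combined effect

Checkpoint receptor–ligand pairs ("axes": PD1–PDL1, PD1–PDL2, CD80–PDL1 in
the cancer-cell/effector synapse; CTLA4–CD80, CTLA4–CD86 and the
costimulatory CD28 axis in the mAPC/T-cell priming synapse) bind at
equilibrium inside a synapse volume (default 1e-15 L).  Inputs per axis are
copy numbers per cell pair, a dissociation constant `Kd` (molar) and the
volume; the bound fraction (receptor occupancy, RO) is the exact
two-species quadratic solution, written in its cancellation-free form.

A blocking antibody is present at its bulk free tissue concentration: the
drug pool in a tissue is orders of magnitude larger than what synapses can
sequester, so the antibody is not depleted by synapse binding.  Under that
bath assumption, masking either partner of an axis rescales the axis Kd to
`Kd * (1 + [Ab]/Kd_ab)` (both factors multiply when two drugs mask the two
partners), and the three-species competition collapses exactly to the
two-species quadratic.  We use that closed form in the ODE right-hand side
(it is evaluated ~10^4 times per patient); the test suite checks it against
a bracketed root-finder on the full conservation equations to 1e-10.

Anti-PD-1 masks PD-1 and therefore neutralises both PD1–PDL1 and PD1–PDL2;
anti-PD-L1 masks PD-L1 (PD1–PDL1 and CD80–PDL1) but cannot touch PD1–PDL2,
which is why PD-L2 expression partially rescues tumors from PD-L1 blockade;
anti-CTLA-4 masks CTLA-4.

Simultaneously engaged axes combine through a median-effect (mutually
exclusive drugs) form:

    f_a = S^m / (1 + S^m),   S = sum_i w_i (RO/RO_max)_i,
    w_i = RO_max,i / sum_j RO_max,j

with Hill coefficient `m = 2` by default (any m > 1 is admissible; m > 1
encodes the sigmoid dose–effect of a higher-order signaling system).
`RO_max` is interpreted as the drug-free equilibrium occupancy of the axis
at full densities, so S = 1 and f_a = 1/2 with no drug on board; f_a is
confined to [0, 1/2] and is non-decreasing in every RO.

## Tumor heterogeneity: the subtype lattice

Four checkpoints are expressed on cancer cells (PD-1, PD-L1, PD-L2, CD80)
at per-checkpoint fractions, independently distributed across the tumor,
giving 2^4 = 16 subtypes with Bernoulli-product weights.  An axis is
engaged on a subtype only if the subtype expresses its cancer-side
partner(s): PD1–PDL1 when the subtype expresses PD-L1 (or PD-1, the
mirrored orientation against effector PD-L1), PD1–PDL2 when it expresses
PD-L2, CD80–PDL1 when it expresses both CD80 and PD-L1.  Per-subtype f_a
values are averaged with the lattice weights into a killing multiplier
`max(1 - 1.6*f_a, 0)` and an effector-death multiplier `1 + 8*f_a`.  Cells
expressing none of the modeled checkpoints are not freely killable either:
they retain a residual resistance factor (default 0.25) standing for
inhibitory pathways outside the modeled panel.  Killing removes cells
proportionally from every subtype, so the fractional composition of the
tumor is constant in time; tumor Tregs and MDSCs (algebraic populations:
fractions of the cancer-cell count, MDSC = 3x Treg) contribute additional
PD-L1 engagement in proportion to their abundance.

## Lymph-node priming and proliferation

The priming cascade in one representative tumor-draining lymph node (TDLN)
follows the three-stage picture from intravital microscopy.  Stage-1
association of naive T cells (NT) with non-interacting mAPCs is

    dNT1/dt = k_assoc,P1 * NT * P1 * SigCD28,
    P1 = 1 - exp(-4*pi*D_T*Diff_T*mAPC_nInt*[T]*phi_NT*Antigen
                 / (TClonality*S_NT_mAPC) * t_max)

where `mAPC_nInt` is the mAPC pool minus those already engaged in
complexes, `[T]` the total TDLN T-cell count, `phi_NT` the fraction
available for priming, `Antigen` in [0.1, 1.0] (0.8–1.0 for melanoma), and
`S_NT_mAPC` a dimensionless encounter scaling that absorbs the lymph-node
geometry (so the stated formula can be used with counts directly).
Unsuccessful complexes dissociate back to the naive pool; stage 2 - the
maturation of an already-formed conjugate - proceeds without a second
encounter probability (re-applying P1 there would square its
clonality penalty and invert the clinical clonality-response relation); activated cells enter a three-compartment transit chain with
mean residence five days.  Proliferation is applied as a cohort-expansion
multiplier on the chain output, `2^(3 divisions/day * 5 days * stim)` — up
to 2^15 at maximal stimulation, the closed-form solution of exponential
doubling — rather than as in-chain exponential growth, because a growth
term faster than the transit rate in a short Erlang chain is unstable and
badly distorts the net amplification.  The stimulation `stim` is the CD28
occupancy, reduced by LN-Treg costimulation sequestration
`(1 - 0.5*treg_ln_frac)` and by the integrated CTLA-4 signal
`(1 - 1.4*f_a)`;
anti-CTLA-4 therefore acts twice, on the association flux and on the number
of divisions, which is what produces its wide, graded dose response.  The
effector output flux into blood is multiplied by the number of TDLNs
(default 32, each assumed identical and receiving an equal share of the
draining antigen and mAPCs).  The naive pool is clonal: its homeostatic
target is `copies_per_clone * TClonality`, so clonality scales the
recruitable precursor mass, while P1 decreases with clonality (each clone
has fewer copies of its cognate antigen encounter) — together these
reproduce the clinical pattern that high clonality favors response without
making P1 itself the only lever.

## Trafficking, killing, and the antigen cycle

Effectors traffic from blood through lung, liver, spleen and tumor
(reversible vascular binding -> irreversible arrest -> extravasation) and
through GI, lymph-node and peripheral pools (direct exchange); interstitial
cells return via the lymph except in the tumor, whose interstitium is
absorbing.  Elimination acts everywhere at a baseline death rate, extra in
the lung, and checkpoint-dependent in the tumor.  Tumor vascular binding
scales with surface area (diameter squared); the chemokine factor (50–500,
default 200) multiplies the tumor arrest rate.

Killing follows the saturating fractional-association law

    dT/dt = -d * (E/T)^lambda / (s + (E/T)^lambda) * T

with d = 0.26/day, lambda = 1.2, s = 0.05 after calibration (below).  Dead
cells — killed or naturally turning over at 0.005/day — each release 100
tumor-associated antigens (TAA).  Tumor APCs (recruited monocytes,
saturating influx 1e6/day) capture TAA and mature into mAPCs (100 TAA per
mAPC; a fraction, default 0.5, is inactivated by the tumor
microenvironment); mAPCs and uncaptured TAA drain to the TDLNs, closing the
feed-forward loop: killing releases antigen, antigen fuels priming, priming
supplies killers.  This loop is the engine of delayed and non-monotonic
responses: it ignites when killing minus growth turns positive and winds
down as the shrinking tumor stops feeding it.

## Tumor growth and geometry

The tumor is an ellipsoid with axes (d, 0.75 d, 0.5 d) along the longest
diameter and 1e5 cells/mm^3, giving a bijective diameter <-> cell-count
map.  Intrinsic growth is Gompertzian by default,
`dC/dt = a*C*ln(K/C)` with a = 0.0017/day and K at a 200 mm capacity
(a logistic alternative is a config switch).  Gompertz was chosen over
logistic because the specific growth rate must rise for small tumors: with
a size-independent rate, the most immunogenic corner of the virtual-patient
ranges (15 mm, high clonality, low PD-L1) is eliminated by its own baseline
immune response before therapy could start, i.e. such patients could never
have presented with a measurable tumor; under Gompertz every patient in the
stated ranges is enrollable.

## Antibody pharmacokinetics

Each antibody follows a minimal PBPK layout: zero-order IV infusion (1 h;
1.5 h for anti-CTLA-4) into a central compartment, first-order clearance,
lymph-flow-limited distribution into tight and leaky tissue (vascular
reflection 0.95/0.70), return through a lymph compartment, and tumor
exchange through a permeability-surface-area product that scales with the
current tumor surface (the tumor PK volume tracks the true tumor size); the
influx/efflux permeability asymmetry (0.025 vs 0.10 L/day/dm^2) produces
the enhanced-permeability-and-retention behavior of a tumor-to-plasma
ratio approaching ~25% over days.  The TDLN site concentration is taken
as 0.35x the tumor concentration.  Target-mediated drug disposition applies to
anti-CTLA-4 only, in its quasi-equilibrium (Michaelis–Menten) limit:
`k_int * R_tot * C/(Kd + C)` saturable elimination from plasma, giving
supra-proportional exposure at higher doses.  PK constants approximate
published population PK of nivolumab, durvalumab and ipilimumab (half-life
two to four weeks, central volume ~3.5 L); they are surrogates, not fits
to serum curves, and all are config-overridable.

## Initialization and integration

A run starts drug-free at 95% of the therapy-start diameter and integrates
until the tumor grows to the start diameter, which lets the immune loop
equilibrate against the growing tumor.  "Quasi-steady" here means no immune
species is on a fast transient at handoff: the pools still track the
slowly growing tumor at a few percent per day (they cannot be stiller than
their driver), and the engine tests assert drift < 0.1/day against every
species' much faster intrinsic turnover.  If the tumor cannot reach the
start diameter within five years the initialization fails, naming the
growth rate as the limiting parameter.

Integration uses BDF with absolute/relative tolerances 1e-9/1e-8 and is
restarted at every infusion-window edge so each segment sees a constant
zero-order infusion rate; the segment end is always evaluated exactly even
when it falls off the daily output grid.  A maximum step of 7 days keeps
the multistep predictor from extrapolating across the sharp
regression/regrowth turning points; a terminal event stops integration when
the last cancer cell is gone (the cured state is held for the remaining
horizon); a failed segment is retried once with a 1-day step cap.  The
right-hand side exists twice: a readable reference composed from the module
functions, and a numba-compiled kernel used for production runs; a test
asserts they agree to round-off at random states.  Halving both tolerances
moves the final diameter by far less than 0.1%.

## Virtual trials

Cohorts are Latin-hypercube samples over the trial ranges: tumor diameter
15–80 mm, antigen strength 0.8–1.0, clonality 10–130, LN Tregs 5–35%,
tumor Tregs 0–0.25%, %PD-L1 40–90% (MDSC multiplier fixed at 3, range 2–4
exposed).  Response classes use RECIST-1.1-style thresholds on the longest
diameter — CR below a 2 mm detectability floor, PR at best change <= -30%,
progressive disease (NR) at >= +20%, SD otherwise — because the source
response categories are named without printed cut-offs.  Two response rates
are reported: PR/CR (the ORR proper) and "any response" (PR/CR plus
regressing SD, best change < -10%), since the benchmark statistics
distinguish a 43% responder class from a 34% PR/CR class without defining
the former.  Patients whose integration fails are recorded as failed
non-responders and counted.  Responder-vs-non-responder comparisons are
Mann–Whitney tests per varied parameter with Benjamini–Hochberg adjustment
across parameters.

Supporting constants (kill-law constants, encounter scaling, APC influx,
tumor homing, antibody affinities, expression fractions of the non-varied
checkpoints) were calibrated once so that the four benchmark regimens
land on their trial-level statistics — anti-PD-1 3 mg/kg Q2W n=200:
~43% responders / ~34% PR/CR; anti-CTLA-4 3 mg/kg: ~20%; anti-PD-L1
20 mg/kg Q2W: ~35%; anti-PD-1 1 mg/kg + anti-CTLA-4 3 mg/kg n=47: ~85%
PR/CR — and then frozen; the varied-parameter ranges and cohort sizes were
never altered.  The class structure that emerges is a sharp
ignition/escape boundary (killing vs growth) softened by the kinetics of
the feed-forward loop, which is also what yields delayed responders and
regrow-after-nadir trajectories.

## Sensitivity and fitting

Global sensitivity uses Latin-hypercube designs over the extended ranges
(checkpoint expressions 1–100%, antigen per cell 10–1e5, clonality 5–130,
mAPC inactivation 5–95%, chemokine 50–500, mAPC activation 0.1–1.0,
diameter 5–80 mm) and partial rank correlation coefficients (PRCC) with
t-distributed significance and BH adjustment per readout; readouts are the
time-averaged tumor diameter, the maximum tumor effector density and the
time-averaged TDLN mAPC density over the horizon.  PRCC was chosen because
it is the standard rank-based global statistic for monotone ODE responses
and is invariant to the monotone transforms that pervade this system.

Parameter fitting is bounded trust-region-reflective least squares from a
seeded Latin-hypercube dispersion of starts; all local minima are ranked so
competing basins remain visible.  Residuals are linear by default with a
log option for PK fits.

## What the virtual population does and does not emulate

The generator reproduces the documented physiological ranges and their
stratified coverage; it does not model parameter correlations (all
parameters are sampled independently), measurement error in tumor
diameters, inter-lesion heterogeneity, drop-out, immune-related toxicity,
or time-varying patient parameters.  Passing trial-level checks therefore
shows that the mechanism plus the stated ranges reproduce cohort
statistics; it does not validate per-patient predictive accuracy.

## Identifiability and benchmark evaluation choices

Two findings from exercising the statistical machinery are worth stating
as properties of the model rather than of any test.  First, clonality and
%PD-L1 trade off along a flat ridge of the response surface: a single
anti-PD-1 diameter trajectory cannot identify them jointly (several
parameter combinations give the same response), and above roughly 100
clones the effector supply saturates so clonality is unidentifiable in
principle.  Joint observation under both drug classes — anti-CTLA-4
response rises with clonality but falls with %PD-L1 — breaks the
degeneracy, and the recovery check fits both trajectories at once.
Second, the two sequential induction orders converge to similar deep
responses by one year in this reduced model; the ordering claim (anti-PD-1
first outperforms) is evaluated at the week-25 induction endpoint of the
comparison setting, where the separation is clear.

Relatedly, %PD-L1's *marginal* association with response class is weak in
this reduced model even though its conditional effect is strong (a median
patient moves from progression to complete response across the 40-90%
range): low-PD-L1 patients still benefit partially from anti-PD-1 through
their PD-L2/PD-1-expressing subtypes and land in stable disease rather
than progression, which a non-responder-versus-PR/CR rank comparison
cannot see past the dominant diameter and clonality effects.

## Known limitations

No intratumoral effector proliferation (lymph nodes are the sole producers
of response); no helper T cells, NK cells, macrophages or fibroblasts;
Tregs/MDSCs act only through checkpoint ligands; no antigen processing
detail (a scalar antigen strength stands in); equilibrium rather than
kinetic synapse binding; no immunogenicity or anti-drug antibodies; the
supplementary parameterisation of the original 282-ODE system is not
reproduced — this is a reduced system faithful to the stated mechanisms,
with surrogate constants calibrated at the trial level.

## Problem sizes used by the test suite

Trial checks run the cohort sizes of the benchmarks (200, 200, 200, 47);
qualitative orderings use a median patient (dose–response) and 24-patient
paired cohorts (sequential order); monotonicity checks use 25-patient
cohorts at range endpoints; parameter recovery fits two parameters to a
150-day synthetic trajectory from 6 multistarts; the PRCC null check uses
100 full simulations over a 70-day horizon.
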