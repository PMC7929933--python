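# Methods

## The model

The ventral neural tube is patterned by graded Sonic Hedgehog (Shh)
signalling acting, through its Gli effectors, on a small cross-repressive
transcription-factor circuit.  We model the Pax6–Olig2–Nkx2.2 core that
positions the boundary between motor-neuron progenitors (pMN; Olig2+/Pax6+)
and V3 progenitors (p3; Nkx2.2+).  Each gene obeys

    dx_i/dt = α_i · G_i(s, x) − δ_i · x_i

where `G_i ∈ [0, 1]` multiplies one term per regulatory input.  An
activating input `u` contributes `1 − w + w·u^m/(u^m + K^m)` and a
repressive input `x_j` contributes `1 − w + w·K^n/(K^n + x_j^n)`; the
weight `w ∈ (0, 1]` is the strength of the interaction (`w = 1` is a pure
Hill term).  Signal targets carry a factor `w_b + w_s·s^m/(s^m + K_s^m)`
so a basal (Sox2-like) activity can coexist with the graded input.  The
wiring follows the established circuit: Nkx2.2 is repressed by Pax6 and
Olig2 and represses both; Olig2 weakly represses Pax6; Shh/Gli activates
Olig2 (low threshold, with a basal component) and Nkx2.2 (higher
threshold).  Signal level at axis fraction `r ∈ [0, 1]` (0 = ventral pole)
is `s(r) = s_max·exp(−r/λ)` with `λ = 0.15` of tissue length; optional
multiplicative Gaussian noise on `s` models gradient noise.

Intrinsic expression noise is chemical-Langevin: each gene receives an
independent Wiener increment with amplitude
`sqrt((α_i G_i + δ_i x_i)/Ω)`, so production and degradation contribute
shot noise scaled by the system size Ω (molecules per concentration unit).
Integration is Euler–Maruyama (default dt = 0.02 h) with reflection at
zero; a constant-diffusion mode is available for benchmark systems.

### Parameter provenance

All constants live in `src/grnprecision/data/neural_tube.yaml` (schema
versioned).  They are this package's own calibration: values were chosen,
by deterministic bifurcation analysis and stochastic simulation, so that
the model reproduces the qualitative biology —

* a bistable pMN/p3 switch with hysteresis across an intermediate band of
  signal levels, with the pMN state reached under gradual (adiabatic)
  gradient onset;
* a Pax6 null (α_Pax6 = 0) that remains bistable but loses the pMN state
  at a more dorsal position and shows a much wider, dorsally displaced
  stochastic boundary;
* an Olig2-enhancer mutant — the three enhancer-mediated terms
  (Gli→Olig2, basal→Olig2, Nkx2.2⊣Olig2) scaled by (0.85, 0.85, 0.9) —
  with delayed Olig2 induction and boundary width and effective barrier
  between wild type and the Pax6 null;
* fate jumps on developmental timescales (≤ ~50 h) confined to a narrow
  band of positions in the wild type (Ω = 220).

The enhancer scalings are per-term rather than a single factor because a
uniform 0.5 knockdown destroys the mutant's bistable switch in this
parameterisation; "reduction, not elimination" with the phenotype as the
constraint fixes the milder factors.  Units: time in hours (δ = 1/h, i.e.
protein lifetimes of ~1 h set the relaxation scale); concentrations in
units where α/δ is a gene's fully-induced level; the signal axis is Gli
activity in arbitrary units.

### Initial condition of tissue simulations

Cells start on the attractor obtained by continuing the signal-free dorsal
state ventralward position by position (`dorsal_branch_states`).  This is
the state reached when the gradient forms slowly relative to gene
expression kinetics, and it realises the defining behaviour of the switch:
inside the bistable band every cell begins in the pMN state and leaves it
only by a stochastic fluctuation.  Starting all cells from the signal-free
rest state instead (available via `x0=`) lets the Nkx2.2 induction race
overtake Olig2 at ventral positions — in the Pax6 null the entire bistable
band then converts deterministically, which is a statement about sudden
signal onset, not about noise-driven precision.

## Minimum action paths

In the small-noise limit, transition trajectories concentrate on the
minimiser of the Freidlin–Wentzell action; we minimise the geometric
(time-reparameterisation-invariant) form

    S[φ] = ∫ ( |φ'|_a |b|_a − ⟨φ', b⟩_a ) dα ,   ⟨u,v⟩_a = Σ_i u_i v_i / a_i(x)

over discretised paths pinned at the pMN attractor and the transition
point (saddle), with the state-dependent diagonal metric
`a_i = α_i G_i + δ_i x_i` taken from the Langevin amplitudes (unit metric
for gradient benchmarks).  Paths are optimised with L-BFGS-B (vectorised
batched finite-difference gradients) and re-parameterised to equal arc
length between outer iterations until the action changes by < tol.  The
descent from the saddle to the p3 attractor follows the deterministic flow
and is appended with zero action.  On gradient systems with unit diffusion
the computed uphill action reproduces `2·ΔV` to better than 1% (quartic
double well, 2-D double well), and direct escape-time simulations scale as
`ln τ ≈ Ω·S` (slope within 15% on a three-point Ω grid).

Path metrics:

* **barrier** — cumulative action at the transition point (the effective
  energy barrier; sets the exponential scale of the fate jump time);
* **curvature** — arc-length excess of the uphill leg over the straight
  chord, in coordinates scaled per gene by α/δ (0 = straight; the
  perpendicular-deviation variant is reported as a diagnostic);
* **signal sensitivity** — |d‖x_stable − x_saddle‖/ds|, centred
  differences in the same scaled coordinates;
* **third-node contribution** — the scaled coordinate range of the node
  without direct morphogen input divided by the summed ranges.

Fate jump times are measured two ways and cross-checked: directly, as
ensemble first-passage times into a ball of radius 10% of the scaled
inter-attractor distance around the target attractor (censoring-aware; the
reported `mean_exposure` is the exponential maximum-likelihood estimate,
total observation time over events); and via `τ = C·exp(Ω·S)` with the
prefactor calibrated at one reference position.

## The computational screen

Three-node networks are drawn with all nine ordered interactions sampled
uniformly from {activation, repression, absent} and the morphogen entering
nodes 1 and 2 (sign sampled); rates and thresholds are log-uniform
(α ∈ [2, 5], K ∈ [0.2, 2.5], Hill exponents in {2, 3, 4},
K_s ∈ [0.3, 2.0]), and consecutive indices share a topology in blocks of
four so per-topology precision fractions are estimable.  The α band is
deliberately narrow: the action of an escape path scales with the absolute
expression level, so at a shared Ω a wide α range makes boundary width a
readout of expression scale rather than of network geometry.  The screen's
Ω is 50 — smaller than the neural-tube model's — so that boundary widths
across the ensemble sit above the readout resolution; the comparisons are
relative, within the shared noise scale.  A
network is accepted when the dorsally-continued branch is lost at a fold
inside the tissue, the two end states are distinct, and ≥ 80% of cells
switch discontinuously across the axis within 50 h.  Accepted networks are
scored for boundary width (stochastic tissue simulation read out on a fine
grid around the fold — the global grid would quantise sharp boundaries),
and for curvature, signal sensitivity and third-node contribution at a
reference position 0.1 axis fractions dorsal of the fold.  Networks whose
third-node contribution falls below 0.05 are classified as effectively
two-dimensional.  Topologies are never collapsed under node relabelling
(the input wiring distinguishes nodes 1, 2 from 3).

At the default scale (several thousand samples, ~5% acceptance) the screen
reproduces the central association — sharper boundaries co-occur with more
strongly curved transition paths (negative Spearman rank correlation) —
and the sharper half of accepted networks is enriched for inhibition of
node 3 by node 2 and depleted of repression of node 2 by node 3.

**Known limitation.**  The packaged neural-tube parameterisation passes the
screen pipeline (bistable switch, boundary near the fold) but its own MAP
curvature (~0.01, because Pax6 is already partially repressed by Olig2
near the fold, leaving only a shallow bend) sits *below* the accepted-set
median rather than above it.  The wild-type network's precision here is
carried by the steep growth of its barrier with position (Pax6-mediated
signal sensitivity) more than by path curvature; calibrations that forced
a strongly curved wild-type path broke the mutant orderings (the Pax6-null
toggle loses bistability when Nkx2.2 is strong enough to make Pax6 the
gating variable).  The corresponding screen assertion is expected to fail
and is left in place.

## Image quantification

Per-cell tables (embryo id, x/y in µm, DAPI/Nkx2.2/Olig2/Pax6 mean
intensities, ventral+dorsal reference points) are processed exactly in
this order: (1) rigid alignment (ventral pole → origin, dorsoventral axis
→ +y); (2) removal of cells with DAPI below mean − 2 s.d. (per embryo);
(3) per-channel flooring of intensities below mean − 2 s.d. to a
configured minimum (default 0); (4) Nkx2.2/Olig2 rescaled affinely so
min → 0 and the 40% quantile → 0.08; (5) Pax6 scaled so the 60% quantile
→ 0.6.  Cells are then typed (floor plate / p3 / pMN / Irx3+ / other)
from Nkx2.2 and Olig2 intensities plus dorsoventral windows; Pax6 is
deliberately excluded so Pax6-null sections are scored without bias.

Boundary measurement fits a binary Gaussian-process classifier (p3 vs pMN;
constant mean, squared-exponential kernel with independent x/y length
scales, logistic link, Laplace posterior, hyperparameters by marginal
likelihood) to cell positions and reads the boundary geometrically on an
evaluation grid (columns every 2 µm): position = mean dorsoventral 50%
crossing, width = mean extent of the 11–89% probability band.  The
probability field applies the logistic transfer to the GP posterior-mean
latent; integrating the logistic over the Laplace posterior instead
(scikit-learn's default `predict_proba`) regresses probabilities toward
0.5 between cells and inflates sharp boundaries by tens of µm, so it is
kept only as an option.  Restricting the fit to the two flanking classes
keeps the field monotone across the interface (the full five-class tissue
would put a second 50% contour at the floor-plate/p3 interface).

## Synthetic data

The embryo generator emulates a quantified E9.5 cross-section: four
dorsoventral domains with span fractions (0.06, 0.16, 0.24, 0.54) of a
300 µm axis (the E9.5 staging window is 250–350 µm), cell positions
uniform, log-normal channel intensities per type (CV 0.3), a per-embryo
multiplicative gain (s.d. 0.15 in log) emulating batch effects, 5%
low-DAPI artefact nuclei, and a raw frame that is translated and tilted so
alignment is exercised.  Type assignment near the p3/pMN interface is a
position-dependent Bernoulli draw with a logistic profile whose 11–89%
extent *is* the configured true width (scale = width / (2·ln(0.89/0.11))),
i.e. the generator's truth is expressed in the same geometry the estimator
reports.  What the generator does not emulate: spatial intensity
gradients within domains, segmentation errors beyond the DAPI artefacts,
left-right asymmetries, and non-log-normal expression tails — so
parameter-recovery results bound estimator behaviour on well-behaved
sections, not on every real image.

Benchmark systems (quartic double well, 2-D gradient double well, fold
normal form, two-node toggle switch) carry their closed forms (ΔV,
actions, fold location) and serve as oracles for the action and
first-passage machinery.

## Numerical choices and degenerate inputs

* Fixed-point finding: multistart Newton (corner states of the expression
  cube plus log-uniform draws), roots merged within 1e-6 of the largest
  α/δ scale, stability from Jacobian eigenvalues (tolerance 1e-7 on real
  parts); an empty result warns rather than raises.
* Branch continuation seeds each grid point from the previous roots and
  falls back to multistart before declaring a fold.
* State classification of simulated cells: nearest labelled attractor in
  log-concentration space, with a configurable tie band (default 0.12 of
  the inter-attractor distance) labelled "other"; with two stable states
  the p3/pMN identities are assigned comparatively (Nkx2.2- vs
  Olig2-dominated).
* Occupancy profiles are monotonised (isotonic regression) before the 50%
  crossing and 11–89% band are interpolated; a profile that never crosses
  50% yields an undefined-with-reason record.
* Non-negativity in the SDE is enforced by reflection (absolute value),
  avoiding an absorbing artefact at zero; blow-up (non-finite or > 1e6 ×
  scale) raises an error naming dt.
* Preprocessing applied twice reproduces alignment and quantile anchors
  exactly; the relative DAPI cut may trim at most a sliver (< 3%) of the
  remaining lower tail on re-application.

## Reported scales

Default problem sizes — 40–56 axis positions × 40–60 cells × 50 h at
dt = 0.02 h for tissues; 150–200 cells for first-passage ensembles;
several-thousand-network screens; cohorts of 6–8 synthetic embryos of
1000 cells — were chosen so each analysis resolves its contrast with
replicate-level significance while a full run of the test-suite and the
analysis scripts stays inexpensive on a single CPU.  The statistic
"combined fluctuation magnitude similar between WT and O2e33" is asserted
as an effect-size bound (rms ratio within 25%) rather than a rank test:
for a seeded simulation any fixed nonzero difference becomes
"statistically significant" once enough replicates are drawn, so a p-value
criterion would measure the replicate count, not the biology.
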