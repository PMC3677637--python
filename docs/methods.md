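# Methods

## The biological problem and the model

When the osmolarity of the medium rises, a yeast cell loses water within
seconds, its osmotically active volume shrinks, and turgor pressure
collapses. *Saccharomyces cerevisiae* restores volume and turgor by
accumulating glycerol as a compatible solute, controlled through several
cooperating mechanisms: activation of the Hog1 stress kinase (modelled here
as a two-reaction phosphorylation cycle driven by relative turgor loss),
Hog1-dependent transcription of *GPD1* and *STL1*, allosteric stimulation
of glycolytic flux through Pfk26/27 and fructose-2,6-bisphosphate, closure
of the Fps1 glycerol channel, and a transient growth arrest that frees
glycolytic carbon for osmolyte production.

`osmoadapt` implements this system as a single 29-state ODE model with six
coupled layers:

1. **Biophysics.** The cell is a basal solid volume `Vb` plus an
   osmotically active volume `Vos`. Water flux follows
   `dVos/dt = Lp_A (Pi_i - Pi_e - Pi_t)` with internal osmolarity
   `Pi_i = (n0 + sum of metabolite amounts)/Vos`, external osmolarity from
   the medium composition plus `i_vh * NaCl`, and turgor a piecewise-linear
   function of `Vos` clipped to `[0, Pi_t0]` (vanishing at `V_lp`). The
   Hog1 input signal is the relative turgor loss
   `u = (Pi_t0 - Pi_t)/Pi_t0`.
2. **Signaling.** Two reactions: `v_ph = k_ph u Hog1u`,
   `v_dp = k_dp Hog1PP`.
3. **Gene expression.** *GPD1* mRNA has basal, Hog1-dependent
   (`k_h1 Hog1PP`) and Hog1-independent osmotic (`k_o1 u`) transcription;
   Gpd1 is translated as a monomer and is active only as a dimer
   (mass-action dimerization), which makes its arrival sigmoidal in time.
   Gpd2 is a lumped basal protein pool with a small osmotic boost. *STL1*
   is glucose-repressed and strongly Hog1-induced.
4. **Glycolysis.** Lumped reactions from glucose uptake through hexose
   phosphates, FBP and triose phosphates to the glycerol
   (Gpd1/Gpd2 -> G3P -> glycerol), trehalose, and ethanol/acetate
   branches, Michaelis–Menten for enzymatic steps and mass action for
   aldolase. F26DP raises the Pfk1 Vmax by up to a factor `1 + aF`.
5. **Transport.** Passive gradient-driven exchange for glycerol (through
   the open-Fps1 fraction), ethanol, acetate and a slow trehalose leak;
   irreversible Stl1 glycerol–proton symport; a reversible symmetric
   facilitated-diffusion carrier for glucose. External pools evolve with
   the cell-density correction `dC_ex/dt = 1e-12 CD v` (amol/min/cell times
   cells/mL gives mM/min).
6. **Growth and biomass.** `mu = mu0 * f_V(Vos) * (1 - theta_H
   Hog1PP/(K_gH + Hog1PP))`: growth needs both volume above `V_gmin` and
   release from Hog1-dependent cell-cycle arrest. Growth drains
   `gamma_bm mu` glucose-equivalents of hexose phosphate per minute
   (modulated by HexP availability) and dilutes every per-cell pool at
   rate `mu`.

Units: amol/cell for intracellular amounts (1 amol/fL = 1 mM), fL for
volumes, mM for external concentrations (NaCl in M), minutes for time.

### Two stability-motivated rate-law choices

Classical "turbo design" pathologies appear if upper glycolysis is modelled
with irreversible uptake and an unregulated hexokinase: when the Hog1
branch is removed, hexose phosphates (and then internal glucose) accumulate
without bound and act as spurious osmolytes. The model therefore gives
hexokinase product inhibition by HexP (`K_iHK`, the physiological
trehalose-6-phosphate brake on Hxk2) and uses a reversible carrier law for
glucose uptake. Likewise, the biomass carbon drain is modulated by HexP
availability (`K_bm`) and Pfk1 runs substrate-saturated (small `KPFK`);
without these, hexose-phosphate homeostasis would cancel the F26DP Vmax
boost and the Pfk26/27 flux-rerouting signature (positive response
coefficients on lower glycolysis, negative on trehalose and biomass) could
not arise.

### Smoothed switches

The clips in turgor, signal and the growth volume factor use a C1 clip
with quadratic corners of half-width 0.01 (in normalized units) instead of
hard `min`/`max`. This keeps the Jacobian continuous, which the forward
sensitivity system and the finite-difference response-coefficient oracle
need to agree to better than 1%. Boundary identities such as
`Pi_t(V_lp) = 0` consequently hold to 2.5e-3 relative, not exactly.

## Reference parameterization

The shipped parameter set (the `ModelParameters` defaults) was hand-tuned
in stages: first the pre-stress quasi-steady state (uptake ~4.9 fmol
glucose/min/cell at OD ~0.8, ~16% of carbon to biomass, low basal glycerol
~14 mM, basal Hog1PP ~1% of total), then signaling and gating kinetics
(full Hog1 phosphorylation within 2 min of a 0.4 M NaCl step, Fps1 closure
dominated by active Hog1), then the glycerol-flux layer (wild-type
intracellular glycerol peaking in the 40–50 min range at ~850 mM, volume
recovery to within a few percent without perfect adaptation, hog1 deletion
rising past half its final level only after ~60 min through the delayed
Hog1-independent GPD1/dimer route, gpd1 deletion rescued by Gpd2 and by
Stl1 uptake that visibly depletes external glycerol). The background
osmotically active amount `n0` is calibrated last so the pre-stress fixed
point sits exactly at `Vos0`.

Key defaults and why: `i_vh = 2` (NaCl dissociation), `Lp_A = 20 fL/min/Osm`
(volume equilibrates within ~2 min), `Pi_t0 = 0.2 Osm` and `V_lp = 28 fL`
(turgor lost at ~10% volume loss), `mu0 = 0.0077/min` (90-min doubling),
`theta_H = 0.5` (partial Hog1 growth arrest; the volume factor supplies
the rest), `sigma_rel = 0.15` for synthetic noise (typical blot/HPLC
replicate scatter).

## Numerical choices

* Stiff integration with LSODA; default tolerances rtol 1e-8 / atol 1e-10;
  the NaCl step is a discrete event handled by stopping and restarting the
  integrator (no smoothing).
* The pre-stress state is a root-solve of the intracellular subsystem with
  external pools and cell density frozen at their configured values.
  Because growth dilution acts on the conserved Hog1 moiety (which has no
  synthesis term), the Hog1u balance is replaced by the moiety condition
  `Hog1u + Hog1PP = Hog1tot`; the returned state zeroes every other
  intracellular derivative to < 1e-8 relative. The quadratic dimerization
  admits a spurious negative-monomer mirror fixed point; the solver
  restarts from the reflected iterate when it lands there.
* Forward sensitivities integrate `dS/dt = J S + df/dq` with a central
  finite-difference Jacobian (relative step 1e-6); initial sensitivities
  come from re-equilibration differencing so RCs start from the adapted
  pre-stress condition (zero initialization is available). Scaled RCs mask
  entries where `|x| < 1e-9` rather than clipping, to avoid spurious
  spikes.
* The fit objective runs at rtol 1e-6 with a minimum step of 1e-7 min so
  pathological parameter draws fail fast into the penalized value
  (1e10 + residual count) instead of stalling the optimizer.
* Optimization is in log10 space, bounds ±2 decades around the reference
  values (capped at 1 for fractions), with seeded Latin-hypercube starts
  and a cascaded trust-region refinement (triage of the most promising
  starts, deep refinement of the best few, final polish).

## Synthetic data

The generator emulates the structure of the study's dataset: tidy records
(strain, variable, compartment, time, replicate, value, unit, method) for
14 observed variables — phosphorylated Hog1, total Gpd1, *GPD1* and *STL1*
mRNA (arbitrary units), intra/extracellular glucose, glycerol, ethanol,
intracellular trehalose, external acetate and trehalose, and cell density —
on metabolite (9-point) and protein (10-point) schedules over 0–240 min.
Noise is multiplicative lognormal with CV exactly `sigma_rel` and unbiased
mean, preserving positivity; `sigma_rel = 0` reproduces the simulation
bit-for-bit. The phenomenological mode instead emits closed-form wild-type
template curves carrying the qualitative features described for the real
data, including a two-bump trehalose course with noise-free local maxima
exactly at 45 and 180 min. The two-peak trehalose behaviour is a generator
feature only; the mechanistic model is required to produce net trehalose
accumulation under stress, not two peaks.

What passing tests on synthetic data do **not** show: the generator shares
the simulator's rate laws (model-based mode) or idealized shapes
(phenomenological mode), so recovery results demonstrate the estimator's
correctness and the subset's identifiability, not that the model fits real
measurements; real data carry systematic errors (extraction efficiency,
OD-to-cell-number calibration, blot nonlinearity) that the lognormal noise
model does not emulate.

## The parameter-recovery experiment

Criterion: from three-strain (wild type, gpd1 and hog1 deletions) noisy
synthetic data (CV 15%, 3 replicates, seed 1), refit the designated
10-parameter subset (`mu0, theta_H, Lp_A, k_dp, k_h1, d_m1, kcatGpd1,
k_fps, k_cH, kTPSh`) from 20 multistarts. Each member has a distinct data
signature — pre-stress growth slope, stress growth dip, volume kinetics,
Hog1 pulse decay, GPD1 induction amplitude and mRNA decay shape, Gpd1
catalytic capacity, glycerol leak, Hog1-dependent channel closure,
trehalose amplitude — and the three-strain design breaks the residual
transcription/catalysis trade-off.

Two optimizer details proved decisive and are worth recording. First, the
finite-difference step of the trust-region refinement must sit well above
the ODE integration noise floor: with the library default step (~1e-8
relative) the Jacobian is pure integration noise at rtol 1e-6 and every
start stalls immediately in a compensated pseudo-minimum; an explicit
relative step of 3e-3 in log10 space restores clean descent across
decades. Second, a *flat* failure penalty strands starts on infeasible
plateaus where no finite-difference direction improves; adding a mild
pull toward the (feasible) box centre to the penalty restores a descent
direction. With both in place the cascaded 20-start fit recovers the
subset with ~10% median relative error and a refit objective slightly
below the generating parameters' own chi-square, in a few minutes.

## Known limitations

* No NAD/NADH or ATP/ADP dynamics: redox-driven regulation of Gpd2 is
  lumped into its basal/osmotic production terms.
* No mechanistic two-peak trehalose dynamics and no Sln1/Sho1 branch or
  nuclear/cytosolic Hog1 compartments.
* The unstressed batch culture is deliberately not at steady state:
  glucose is consumed, ethanol and acetate accumulate, and passively
  equilibrating intracellular pools track them, so "pre-stress constancy"
  holds for glycolytic intermediates over tens of minutes, not hours.
* The constitutively open Fps1 strain reproduces the qualitative
  sustained-efflux phenotype, but no attempt is made to model the
  additional pre-adaptation or copy-number effects of that construct.
* Simulation output beyond ~120 min inherits the usual caveat of lumped
  adaptation models: slower processes outside the model's scope (other
  osmolytes, expression remodeling) are not represented, so late-time
  behaviour should be read qualitatively.
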