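# Methods

`ptsei` implements a kinetic model of Enzyme I (EI), the first protein of
the *Escherichia coli* phosphoenolpyruvate:carbohydrate phosphotransferase
system (PTS).  EI exists as a monomer and a dimer; only the dimer
autophosphorylates on His-189 from subunit-bound PEP, and the phosphoryl
group is passed on to the carrier protein HPr either by the phosphorylated
monomer or by the singly/doubly phosphorylated dimer.  The package builds
the full elementary catalytic cycle, reduces it under a rapid-equilibrium
binding assumption to a five-pool ODE system, transforms constants to
experimental temperature and pH, fits parameters to heterogeneous data with
a staged Hooke–Jeeves protocol, and discriminates the four candidate
phosphotransfer mechanisms by AIC.

Units are mM for concentrations (dimer pools in dimer units), seconds for
time, K for temperature (°C at the user-facing constructors) and J·mol⁻¹
for energies with R = 8.314 J·mol⁻¹·K⁻¹.

## The catalytic cycle and its parameterization

Each EI subunit carries a phosphorylation flag and a C-terminal ligand site
that can be empty or hold PEP or pyruvate (Pyr).  Canonicalizing the two
subunits of a dimer as interchangeable yields 27 micro-states (monomer
pools Y and YP with 3 states each; dimer pools Z, ZP, ZP2 with 6, 9 and 6
states) connected by 76 reversible reactions: 28 ligand binding steps, 21
dimerizations/dissociations, 6 phosphorylation steps (a PEP-bound subunit
of Z or ZP becomes a phospho-subunit with bound Pyr), and 21 HPr-transfer
steps (any phospho-subunit donates to HPr; variants restrict the allowed
donor pools).

Statistical weight factors are not assigned by hand: every merged state is
backed by its labeled (subunit-distinguishable) configurations, and the
apparent constant of a merged reaction is `sigma * K_site`, where the shared
per-site constant `K_site` lives on the labeled reactions and `sigma` is the
ratio of labeled multiplicities across the reaction.  PEP dissociation from
the doubly PEP-loaded dimer, for example, automatically acquires the
classical factor 2.  Equilibrium constants are oriented in the dissociation
direction (complex → parts); rate constants refer to the same forward
direction (dissociation for dimers, s⁻¹; phosphorylation forward, s⁻¹;
transfer forward, mM⁻¹·s⁻¹).

### Sharing map: 63 equilibrium constants, 46 rate constants

The binding, dimerization and phosphorylation reactions each carry their
own equilibrium constant (55 identifiers).  The 21 transfer reactions share
8 equilibrium-constant classes: Pyr occupancy is taken not to alter the
transfer constants (Pyr binds the C-terminal domain while transfer is
carried by the N-terminal domain), and for the doubly phosphorylated dimer
the spectator subunit's occupancy is ignored as well.  That gives 63
distinct equilibrium constants.  On the kinetic side, two rate-constant
identifications (Pyr on the donor site is equivalent to an empty donor site
when the partner subunit is empty, for ZP and ZP2 donors) reduce 48 kinetic
reactions to 46 rate constants.  Applying the Pyr-blindness equalities to
the rate constants during fitting leaves 37 free; activation energies are
shared in 25 classes (one per dimerization family, one per phosphorylation
step × spectator ligand, one per transfer class) and reaction enthalpies
attach to the 31 independent equilibrium constants (dependent constants
inherit theirs through the resolution identities), so the full thermal
bookkeeping is 63 + 12 = 75 enthalpy slots with 31 independent, and 46 Ea
slots with 25 independent.  The whole sharing map is generated
deterministically and shipped as `data/sharing_map.json`; a test pins the
package to that file.

### Detailed balance: 31 independent constants

The declared Wegscheider constraint system is (i) the complete cycle
closure of the binding/dimerization/phosphorylation core, computed as the
null space of the labeled stoichiometric matrix and projected onto the
constant classes (rank 29 over the 55 core constants), plus (ii) three
PEP-exchange ratio conditions linking the PEP-substituted transfer classes
to their base classes through the adjacent binding constants.  The system
has rank exactly 32, leaving 31 independent constants; each dependent
constant is an explicit rational-power product of independent ones, and
every declared cycle product of resolved constants equals one to machine
precision.

A deliberate asymmetry: the Pyr analogues of the transfer ratio conditions
are *not* closed.  Pyr-blindness of the transfer constants is imposed as an
equality regardless of the Pyr-binding constants — exactly the role of the
simplifying assumption it encodes.  Closing every transfer cycle as well
would tie the transfer constants completely to the core thermodynamics and
leave only ~27 independent constants; the chosen system reproduces the
63 → 31 reduction while keeping the closed (no-transfer) cycle
thermodynamically consistent, which is what the equilibrium tests probe.
The default ground-truth parameter sets are nevertheless generated from
micro-state free energies and therefore satisfy *all* cycles, including the
undeclared ones.

## Quasi-equilibrium reduction

Binding is much faster than dimerization, phosphorylation and transfer, so
within each pool the micro-states follow the binding equilibrium at the
current free PEP and Pyr.  Within-pool weights are
`w = c · PEP^nE · Pyr^nY`, with `c` accumulated along a spanning path of
binding reactions from the ligand-free root (statistical factors included);
path independence is guaranteed by the cycle closure.  Lumped rates
V1…V8 are fraction-weighted sums of the merged elementary rates rather
than transcribed closed forms, which makes them robust to any change of the
topology configuration; V9 = k9·HPrP is first-order HPrP hydrolysis with
k9 = ln(1/0.15)/1800 s⁻¹ ≈ 1.054·10⁻³ s⁻¹ (temperature- and
pH-independent), chosen so that pure hydrolysis leaves 15% of the initial
HPrP after 30 minutes.

Model I integrates (Y, Z, ZP, YP, HPrP, Pi); ZP2 follows from EI
conservation, HPr from the HPr moiety, and the *free* PEP and Pyr from the
phosphoryl and three-carbon-backbone conservation laws with the
enzyme-bound ligand subtracted.  The pyruvate closure carries a `+Pi` term:
each hydrolysis event removes a phosphoryl from the protein pool without
consuming a backbone, so `Pyr = Pyr(0) + (PTSP − PTSP(0)) + Pi − EI∘Pyr`.
(Without this term the backbone conservation law is violated as soon as Pi
accumulates — the discrepancy was isolated with the elementary-system
oracle below; the simpler closure is recovered exactly whenever Pi = 0.)
Free ligands are solved at every right-hand-side evaluation by a damped
Newton iteration with an analytic covariance Jacobian and a bracketed
bisection fallback, to a tolerance of 10⁻¹¹ relative in the ligand balance.
Model II clamps free PEP, Pyr and HPr, fixes HPrP = Pi = 0 (no product
rebinding, no reverse transfer) and keeps the four enzyme-pool equations.

The reduction is validated against an independent oracle: the full
mass-action system on all 27 micro-states with explicit binding kinetics.
With binding association at 3·10⁶–10⁷ mM⁻¹s⁻¹ (so that even the tightest
site's off-rate sits well above the fastest slow step) the pooled
trajectories agree with the reduced model to a few tenths of a percent
after the boundary layer.

Integration uses LSODA with per-experiment relative tolerance (10⁻⁸ by
default, 10⁻⁶ inside fitting loops) and absolute tolerance scaled to the
experiment's concentrations; pool undershoots are clipped at zero with a
warning beyond 10⁻⁹ relative, and a negative algebraic closure beyond 10⁻³
relative raises.

## Simulated experiments

* **Time courses** (Model I or II) on an arbitrary grid, with observables
  phospho-EI = ZP + 2·ZP2 + YP (monomer equivalents), HPrP, total
  phosphorylated protein, or free-monomer concentration.
* **Steady states** (Model II) by damped Newton from an integrated warm
  start (10⁴ s, long-integration fallback), residual below 10⁻¹² mM/s, with
  the transfer flux decomposed by donor (monomer / ZP / ZP2); the
  components sum to the total to 10⁻¹⁰ relative.
* **Initial rates**: the slope of cumulative phosphoryl transfer over the
  earliest window [t1, 4·t1] (t1 doubling from 0.1 s) on which the two
  half-window slopes agree within 1% — an operational "linear to 1%"
  criterion that tolerates slowly settling enzyme distributions.
* **2-D PEP × Pyr response surfaces** of the steady rate, the free-monomer
  level or a decomposition component, with per-cell failure flags and a
  validity warning below 1 µM PEP, where the rapid-binding reduction itself
  becomes questionable.
* **Knockouts**: named parameter sets with the monomer transfer, the second
  dimer phosphorylation, the unphosphorylated-dimer dissociation, or both
  dimer transfer routes zeroed.

## Temperature and pH

Independent equilibrium constants follow the van't Hoff relation
`K(T) = K(T0)·exp(ΔH·(T0−T)/(R·T·T0))` and are then re-resolved, so
dependent constants transform consistently; rate constants follow the
Arrhenius analogue with shared activation energies.  pH enters through the
Cornish-Bowden dibasic-acid picture: each of six sites (three dimerization
families, two phosphorylation steps, one transfer site; 12 pKa values with
pKa1 > pKa2) contributes a bell-shaped active fraction, normalized at the
reference pH.  Dimerization *dissociation* constants scale with the inverse
squared factor (two independently protonating monomers must be active);
phosphorylation and transfer *rate* constants carry a single factor.
Whether the historical model attached the factors to equilibrium or rate
constants is not recoverable; this assignment is the package's declared
choice, recorded in the sharing map.  k9 is exempt.  Reference condition:
T0 = 298.15 K, pH 7.0, unless the parameter table declares otherwise.

## Synthetic data

No machine-readable datasets exist for the historical experiments, so the
generator emulates the four fitted families at their printed designs:
EI-phosphorylation time courses (0.06/0.23 mg/mL EI — converted with a
63.5 kDa monomer mass — at 20-fold PEP excess, 23 °C pH 6.5, plus a
sub-saturating run at EI 140 nM / PEP 44 µM), mixed EI+HPr time courses
(PEP 160 µM, HPr 24.4 µM, EI 157 nM and 1.57 µM at 37 °C pH 7.4, plus a
low-concentration run at EI 32.8 nM, PEP 390 nM), equilibrium phospho-EI
titrations against PEP, and v0(HPr) initial-rate curves at EI 1.3 µM and
two PEP levels (25 °C pH 7.2) — about 50 points in total at desk scale.

The ground truth is constructed from micro-state free energies, so it is
thermodynamically consistent by construction while honoring the qualitative
orderings of the historical fit: dimer dissociation 3.8·10⁻⁴ mM bare,
8·10⁻⁵ mM with one PEP, 9.7·10⁻⁸ mM with two; phosphorylation stabilizes
the dimer (ZP2 < ZP ≪ Z); monomeric PEP binding at 0.37 mM; transfer
blocked when PEP occupies the unphosphorylated subunit of ZP.  Pyruvate
binding is uniform across phosphorylation states, which makes the Pyr-blind
transfer sharing exact.  Dimerization rate constants use a linear
free-energy split: ligand stabilization accelerates association and slows
dissociation in equal measure, anchored at root dissociation rates of
0.003 s⁻¹ (Z) and 0.43 s⁻¹ (ZP2).  Noise is multiplicative lognormal,
default 2% relative; because the noise is multiplicative, emitted datasets
carry 1/v² generalized-least-squares weights (floored at 5% of the dataset
maximum) so that experiments on nanomolar and millimolar scales contribute
comparable information.  The fitting machinery itself defaults to unit
weights.

What the generator does *not* emulate: measurement-specific baselines and
calibration drift, correlated errors within a time course, Mg²⁺ variation,
buffer effects, or enzyme preparations with partial activity.  Passing the
recovery tests therefore shows that the pipeline is self-consistent and
that the mechanisms are discriminable under the printed designs — not that
the historical data would yield the same constants.

## Fitting and model comparison

The objective is the plain sum of squared deviations over all points
(optional weights are allowed and logged).  Minimization uses the classic
Hooke–Jeeves exploratory/pattern search on log₁₀-transformed parameters in
the box [10⁻¹⁴, 10⁶] (the lower bound mirrors the historical sensitivity
scan floor), with the step halved on failed sweeps and the search restarted
from its own best point (fresh step) until no further improvement —
strongly correlated constants form curved valleys that a single cycle can
stall in.

The three-step protocol: stage 1 fits PEP→EI parameters on EI-only
phosphorylation data; stage 2 fixes them and fits the transfer-to-HPr
parameters on the HPr data; stage 3 frees everything on the pooled data.
At desk scale, stage 1 frees only the core constants the EI-only time
courses actually determine (the ZP2 dissociation and second-phosphorylation
rates); the remaining core constants join at stage 3 — freeing them earlier
lets the search slide along compensation valleys that the EI-only objective
cannot resolve.  Equilibrium titrations sit in their own stage group: they
constrain equilibrium constants only, and none are free at desk scale.
After the final stage, rate constants within two decades of the lower bound
are fixed to zero when that does not worsen the objective, and drop out of
the free-parameter count q.  Single-parameter sensitivity ranges bracket the
values at which the objective doubles, by log-scale bisection; sides where
doubling is never reached are reported open at the scan bounds.

Mechanism comparison fits each variant (monomer only; ZP2 only; ZP and
ZP2; all forms) with its own staged plan and ranks by
AIC = ln(s²/n) + 2q, with s² = Σ((vᵢ−v̄ᵢ)/vᵢ)² normalized by the
*predicted* value — an unusual normalization, implemented exactly as
defined, with zero-prediction points excluded under a warning.  n counts
all points across datasets; both f and s² are reported since their units
differ.  The desk-scale free sets hold the ZP2 transfer constant at its
prior whenever the ZP route is also active: the two dimer routes carry
largely interchangeable flux at these designs, so freeing both would leave
neither determined.  The four variants' full parameter complements are
strictly ordered (3 < 8 < 16 < 19 transfer rate constants), mirroring the
mechanism comparison at full scale.

## Problem sizes and known limitations

Desk-scale defaults: ~50 synthetic points across 10 datasets, ≤ 7 free
parameters, Hooke–Jeeves budgets of a few hundred evaluations per stage;
the reduction oracle runs 10 parameter draws at binding acceleration
3·10⁶ mM⁻¹·s⁻¹ over a 100 s horizon; conservation sweeps use 100 random
Model I trajectories.  These sizes are the package's validation scale, not
statements about the historical fit (175 points, 137 → 90 parameters).

Limitations: Mg²⁺ is not a variable; no explicit EI–HPr complex; no
conformational sub-states; protonation is implicit (pH factors are applied
to designated constants rather than through explicit proton-binding
species, so cycle closure is asserted at the reference pH); sub-micromolar
PEP predictions are flagged as outside the reduction's domain of validity;
and the steady transfer flux is superlinear in total EI over much of the
µM range because dimerization is rate-limiting — a genuine property of this
parameterization, which is why the enzyme-proportionality check is run with
dissociative recycling disabled.
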