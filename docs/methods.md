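# Methods

`rimsys` models the post-translational control loop in which the glutamyl
ligase RimK extends the C-terminus of ribosomal protein RpsF with
poly-glutamate, the protease RimB trims those tails back to a floor of four
residues, and the phosphodiesterase RimA together with the second messenger
cyclic-di-GMP (cdG) tunes RimK activity. This note records the models, the
numerical choices behind them, and what the synthetic data generators do and
do not emulate.

## Binding networks and steady states (`rimsys.network`, `rimsys.models`)

Protein-ligand regulation is represented as a network of reversible
bimolecular binding reactions `A + B <=> AB` under mass-action kinetics.
Units: concentrations in uM throughout; forward rate constants are entered
in M^-1 s^-1 (default 1e9, the diffusion limit) and converted internally to
uM^-1 s^-1 so that reverse rates `k_r = k_f * K_d` stay well scaled at uM
concentrations. `K_d` is the only thermodynamic free parameter per
reaction; `k_r` is always derived.

Conserved moieties (each free protein or ligand together with every complex
containing it) are identified structurally, and conservation is asserted in
integer arithmetic at network construction: the moiety-count matrix
annihilates the stoichiometry matrix exactly, so conservation under the ODE
flow holds by construction, not merely to integrator tolerance.

Thermodynamic consistency: every closed binding cycle must satisfy detailed
balance, i.e. the product of `K_d` values is route independent. Cycles are
found as integer basis vectors of the left nullspace of the reaction
stoichiometry; `check_thermodynamic_consistency` reports the folded route
ratio for each (pass at relative tolerance 1e-9). The pre-built models
impose the constraint at construction — in each cycle one `K_d` is derived
from the others through a single cooperativity factor (default 1.0,
independent sites) — which also reduces the number of free fit parameters.

Steady states are computed two ways:

* `solve_steady_state` integrates the ODEs with DOP853 (high-accuracy
  explicit Runge-Kutta, appropriate for this fast-relaxing non-stiff
  chemistry) at `rtol = 1e-8`, `atol = 1e-10`, in doubling time windows
  starting at 1 us. Diffusion-limited binding at uM scale relaxes within
  milliseconds; integration stops when the derivative infinity norm stalls
  or falls below a coarse threshold, and a bounded least-squares polish on
  the derivative residuals augmented with the moiety-total constraints
  brings the infinity-norm residual below `atol` (the constraint rows are
  needed because the equilibrium manifold is derivative-degenerate along
  conserved directions). If the polish fails the error names the species
  with the worst residual.
* `equilibrium_concentrations` solves the same equilibrium algebraically:
  unknowns are free moiety concentrations in log space, complexes follow
  from `[AB] = [A][B]/K_d` along each formation route, and the moiety
  totals are solved by damped Newton iteration with the analytic symmetric
  Jacobian `d T_m / d ln x_m' = sum_s n_sm n_sm' [s]`. This route is ~50x
  faster and fully independent of the integrator; the two are
  cross-checked against each other (and against the closed-form quadratic
  for one-reaction networks) in the test suite.

### Model variants

* `two_state`: basal RimK plus one shared active conformation reached by
  binding either cdG or RimA; full square topology, two distinct activity
  states, one free `K_d` per ligand.
* `four_state`: apo, `.cdG`, `.RimA` and `.cdG.RimA` each with its own
  `k_cat`/`K_m`. Defaults: `K_d(cdG) = 1` uM (the measured affinity),
  `K_d(RimA) = 0.2` uM.
* `rimb_extended`: adds a `RimK.RimB` complex carrying a further activity
  state. The literature does not specify whether RimB-containing states
  cycle with cdG/RimA; here RimB binds apo RimK only, an implementer
  choice that keeps the added state orthogonal to the square.
* `trigger`: adds the inhibitory `RimA.cdG` complex (`K_d = 5` uM) that
  sequesters RimA away from RimK. Experimentally the switch of RimA from
  RimK activator to cdG sink requires RimB, and a pure equilibrium binding
  model cannot express a catalytic gate, so the sequestration reaction is
  included only when RimB is present at non-zero concentration; with RimB
  absent the variant reduces exactly to `four_state`. The complex
  arrangement is deliberately exposed as a switch: `"sequester"` (default;
  `RimA.cdG` never touches RimK) or `"ternary"` (an additional,
  catalytically basal `RimK.RimA.cdG_A` complex, cycle-constrained).

## Composite ATPase kinetics and fitting (`rimsys.enzymology`)

The observed rate under a ligand condition is the occupancy-weighted sum of
per-state Michaelis-Menten terms,

    v(S) = sum_s w_s * kcat_s * S / (Km_s + S),

with `w_s` the steady-state concentration of state `s`. `michaelis_menten_fit`
provides the plain single-state `(Vmax, Km)` fit used for raw assay curves.

`fit_model_params` fits a variant's free `K_d`s and per-state kinetics to
all rate datasets jointly. Free parameters are searched by differential
evolution (seeded; `updating="deferred"`, single worker, Latin-hypercube
init, followed by an L-BFGS-B polish) over `log10 K_d in [-3, 3]` and
`log10 Km in [0, 5]`; `kcat in [0, 1e5] min^-1` enters the model linearly
and is therefore profiled out exactly by non-negative least squares at
every objective evaluation (variable projection). This keeps the
stochastic search 3-5 dimensional and removes the `w_s x kcat_s` ridge
that makes the joint search ill-conditioned. Identical seed, data and
bounds give bitwise-identical results. State occupancies inside the fit
loop use the algebraic equilibrium route for speed.

Identifiability: with a shared `Km`, rate curves measured at fixed ligand
concentrations collapse to one effective `Vmax` per condition, which cannot
pin the `K_d`s. Dose dependence does: the default synthetic assay panel
therefore contains cdG and RimA titration series bracketing the `K_d`
scale in addition to the four headline conditions (basal, +RimA, +cdG,
+both) — mirroring how the activation was actually mapped, via
concentration-ratio series. `compare_models` reports residuals, parameter
counts and the residual difference only; no significance test is attached
because none is defined for this design.

Specific activity: the package works in per-uM-enzyme rate units;
`specific_activity` converts `min^-1` to nmol ATP/min/mg via a declared
molar mass (default 33 kDa for RimK).

## Stochastic chain dynamics (`rimsys.chains`)

A glutamate tail is a discrete-time Markov chain: per step add one unit
(`p_add`), remove one (`p_cut`), release the chain (`release_prob`,
processive mode), or idle. The protease:ligase activity ratio
`rho = p_cut / p_add` is the user-facing control, because the mapping from
species concentrations to step probabilities is not specified by the
biology beyond "RimK-state and RimB dependent"; an adapter from
steady-state occupancies to probabilities would add only a single scale
factor and is left to the caller. Structural rules:

* cleavage is a no-op at length <= 4 (the experimentally observed floor);
* additions are no-ops at the cap of 100 units, so processive-mode
  probability mass accumulates at 100 rather than being renormalised (the
  capped-geometric oracle `P(L=k) = q^k (1-q)`, mass `q^100` at the cap,
  uses the same convention);
* released chains leave the simulation with their final length (whether
  released chains remain protease substrates is unspecified; this is the
  simplest convention and is documented rather than hidden);
* protease-mode runs record at a fixed step horizon (default 1e4 steps);
  the stopping rule is otherwise unspecified.

Replicate-chain distributions default to 1e5 chains in the tests (the
cell-scale study this emulates used 1e6; `n_sims` is a config field, and
1e5 keeps every distributional check comfortably inside a minute while the
multinomial error at 1e5 is already far below the assertion tolerances).
The mode tie-break is the smaller length, for determinism.

Population mode couples one RimABK complex to `n_rpsf = 500` chains (the
estimated cellular ratio) through a finite shared glutamate pool: the
complex binds one chain, works on it processively, and on release rebinds
a uniformly random chain; cleaved glutamate returns to the pool (re-use of
liberated glutamate is experimentally observed). `sum(lengths) + pool` is
conserved exactly at every event. A per-event uniformly-random chain
choice *without* processivity was rejected because it cannot produce the
observed low-protease regime (few long chains, most RpsF unmodified).

## Ribo-seq quantification (`rimsys.riboseq`)

Conventions, in order of application:

* alignment span is the CIGAR reference span (soft clips excluded;
  footprints essentially never contain indels, and reference span is
  well-defined when they do);
* footprints kept iff `23 <= span <= 41`, bounds inclusive;
* centre-weighted coverage: a kept read covering 0-based `[s, s+l)`
  increments `[s+11, s+l-11)` by one — `l - 22` positions — with strands
  accumulated separately; windows clipped at reference ends are logged;
* per-gene count = own-strand coverage summed inside the gene interval
  (SAM 1-based and GFF3 1-based inclusive are both converted to 0-based
  half-open internally; reads overlapping a gene partially contribute only
  their in-gene positions);
* `RPKM = count / (gene_kb * total_counted_positions_in_millions)`, where
  the denominator is the genome-wide both-strand total, including
  positions outside annotated genes (a convention choice; the alternative
  — genic-only totals — rescales all RPKMs by a common factor and leaves
  ranks and contrasts unchanged);
* log2 contrasts add a pseudocount of 0.5 RPKM to both sides;
* regulon partition at `tau = 1.0` log2 with strict inequality: class 1
  (deletion only), class 2 (concordant), class 3 (discordant — the direct
  glutamation-regulon candidates), glutamation-only, unaffected; the five
  labels are exhaustive and mutually exclusive, with missing contrasts
  reported as unclassifiable;
* proteomic filter: >= 2 unique peptides, >= 1 log2 difference of
  regulation between wild type and mutant, and `min(p_wt, p_mut) <= 0.05`.
  The p-values are consumed as provided (they arrive already
  Benjamini-Hochberg adjusted upstream); "at least one p-value" is
  implemented as the minimum over the provided pair.

## Synthetic data (`rimsys.synthetic`)

The generators emulate the statistical structure each pipeline stage
assumes, with ground truth returned beside the data; all are
seed-deterministic (same seed, bitwise-identical output).

* Rate data: composite-rate forward model times `1 + noise * N(0,1)`
  (default 2% multiplicative Gaussian; heavier-tailed noise is not
  modelled). The A340 progress curves use the NADH extinction coefficient
  6220 M^-1 cm^-1, 0.4 mM initial NADH, a configurable effective path
  length (default 0.55 cm for a 100 uL plate well), and one NADH oxidised
  per ATP through the PK/LDH couple, in the linear (substrate-unlimited)
  regime.
* Footprints: a uniform-random toy genome with evenly spaced,
  alternating-strand genes; read counts multinomial in rate x length,
  uniform starts within genes, lengths discrete-triangular peaked at 30 nt
  over 23..41, plus a 2% out-of-window contaminant fraction. Written as
  valid SAM (via pysam) and GFF3.
* Contrast and protein tables: effects drawn strictly beyond or strictly
  inside the thresholds by a configurable margin, so exact label recovery
  is the correct expectation.

What the generators do **not** emulate — and hence what passing tests do
not establish about real data: rRNA contamination and its depletion,
sequence-dependent mappability or ligation bias, overdispersed biological
replicates, operon structure and overlapping genes, ramp/pause structure
within ORFs, and batch effects in proteomic ratios. Tests on this
synthetic data validate the *computations* (filters, counting,
normalisation, classification, fitting), not the upstream measurement
process.

## Known limitations

* Binding models are equilibrium-only: catalysis (RimA's phosphodiesterase
  activity consuming cdG, RimK's ATP turnover) is not part of the species
  dynamics, which is why the trigger variant gates on RimB structurally
  rather than kinetically.
* The chain simulator's probabilities are not derived from the kinetic
  models; `rho` must be supplied.
* The unidentified "reset" protease that returns RpsF to the unmodified
  ground state is not modelled (an extra removal channel would be a
  one-line extension but there is nothing to calibrate it against).
* Residual comparison between model variants is descriptive; no
  information criterion or likelihood-ratio machinery is provided.
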