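# Methods

## The deconvolution problem

Mass spectrometry resolves a metabolite's *isotopologues* — species
differing in how many heavy-isotope atoms they carry — but not where those
atoms sit. For a composite metabolite such as UDP-GlcNAc, which is
assembled from four moieties (glucose, ribose, acetyl, uracil) through
converging biosynthetic pathways, the isotopologue profile mixes the
enrichment of all four subunits. moietykit deconvolutes such profiles: it
models each moiety as occupying one of a small set of joint
isotope-enrichment states (e.g. glucose with six ¹³C, written
`glucose[13C_6]`), whose fractional abundances are the model parameters.

The forward model is multiplicative. For a one-state-per-moiety
combination *v*, the component intensity is the product of the involved
state fractions, and the calculated intensity at isotope content *x* sums
all components whose contents add to *x*:

    I_x,calc = Σ_{v : content(v) = x}  Π_j moiety_state_{j, v_j}

Because each moiety's fractions sum to one, feasible parameter sets always
produce a normalized profile. Fitting minimizes an objective comparing
`I_calc` with the observed profile — a non-convex, bounded inverse problem
(products of parameters), solved here by a hybrid simulated-annealing /
genetic-algorithm search (SAGA) with optional local polishing, or by
scipy's bounded local methods (TNC, SLSQP, L-BFGS-B) from random feasible
starts.

## Model structure and the free-parameter space

* Each moiety's **first listed state** (by convention the unlabeled one)
  is the *default-dependent* state absorbing the sum-to-one constraint.
  Some state must play this role and the choice is otherwise arbitrary;
  putting it on the unlabeled state matches how these models are drawn
  (the labeled-state fractions are the natural free variables).
* **Relationships** are linear: `dependent = Σ cᵢ·(moiety, state)ᵢ`. This
  covers identity ties (g6 = r5), scaled single terms (g0 = 2·a2) and
  multi-term sums (g3 = r2 + r3). Non-linear operators are not supported.
  Relationship-dependent states may not be default-dependent states, and
  chains are resolved in topological order; cycles are a model-definition
  error.
* `k = Σ_moieties (|states| − 1) − #relationships`.
* Infeasible expansions (any state fraction outside [0, 1]) are reported
  by flag, not exception; optimizers map them to a penalty energy of 1e6.
  This keeps stochastic search alive near the simplex boundary and gives
  gradient-free search a visible feasibility boundary.

## The content grid

The isotopologue grid is derived from the **molecule-level**
`total_labellable_atoms`, not from the union of moiety states: the grid
size is Π (atoms_e + 1) over tracked isotopes. Unreachable grid entries
carry zero calculated intensity but are part of the measured (and
simulated) vector.

For the dual-tracer (¹³C/¹⁸O) UDP-GlcNAc fixtures two oxygen budgets
appear, deliberately:

* `expert_multi_full_grid` counts **all 17 oxygens** of the metabolite,
  giving the 18 × 18 = **324**-isotopologue grid — the number of
  isotopologues a dual-tracer measurement of UDP-GlcNAc can in principle
  distinguish.
* `expert_multi`, the **simulation fixture**, counts only the **12
  tracer-accessible oxygens** implied by the atom mapping from labeled
  glucose (glucose 5, ribose 4, acetyl 1, uracil 2), giving an 18 × 13 =
  234-entry grid. This is the grid on which the error-propagation study
  operates: oxygens that cannot receive label from the tracer do not
  generate spurious near-detection-limit channels. With the full 324-entry
  grid the σ = 0.01 and σ = 0.1 propagated-error averages come out ~20–35%
  higher (≈2.06 and ≈13.6 instead of ≈1.73 and ≈9.97), because ~90 extra
  always-empty channels each have a chance of drawing noise above the
  detection limit.

## The SAGA optimizer

The published hyperparameters (100 000 steps, temperature step 100,
α = 1, crossover rate 0.05, mutation rate 3, population 20, start
temperature 0.5) name the knobs but not the schedule, selection or
acceptance rules. moietykit's choices, all visible in `saga.py`:

* **Cooling law** `T = T₀·(1 − t/step_number)^α`, updated every
  `temperature_step_size` steps — a linear-power schedule that consumes
  α and the step budget naturally and reaches T → 0 at the end.
* **Mutation** perturbs a Poisson(mutation_rate)-distributed number of
  elements (at least one; rate 3 is read as a rate, not a probability),
  each displaced by `uniform(−1,1)·(T/T₀)·(high − low)` and clamped to its
  bounds. Annealing thus lives inside the mutation operator: the mutation
  magnitude decays with temperature.
* **Crossover**: uniform (switch the source parent with probability
  `crossover_rate` at each element) or single-point.
* **Acceptance**: each step crosses two uniformly chosen parents, mutates
  the child, and compares it with the current *worst* population member —
  replacing it if ΔE ≤ 0, else with Metropolis probability exp(−ΔE/T).
  Non-finite energies are treated as +∞ and never accepted.

These rules reproduce the method's *behavior* (population annealing with
temperature-attenuated mutation, reproducible from a seed); trajectory
equality with any other implementation is not a goal. Repetition *r* of
dataset block *d* is seeded from the tuple `(seed, d, r)`, so repetitions
are independent and the whole run is bit-reproducible.

## Objectives and fitting modes

Three objectives: absolute difference Σ|o−c|, square difference Σ(o−c)²,
and log difference Σ|ln max(o,ε) − ln max(c,ε)|, natural log. The ε-floor
(package default 1e−10) guards zeros; it matters: observed zeros produced
by detection-limit censoring otherwise dominate the log objective (|ln ε −
ln c| ≈ 16 per censored entry at ε = 1e−10), dragging fits far from the
truth. When fitting data that contains censored zeros, the floor should be
set to the detection limit itself (ε = 0.005 in the synthetic studies), so
that values the instrument could not have distinguished from zero compare
as equal. Observed profiles are compared as given (a `renormalize_observed`
switch exists).

*Split* mode fits an independent k-parameter block per dataset; *combined*
mode performs one joint search over concatenated per-dataset blocks. A
`combined_shared` switch shares a single block across datasets instead —
the default keeps per-dataset blocks because timepoints genuinely differ
in enrichment.

## Repetition summaries and model selection

Information criteria are computed from the **best-energy repetition** (the
criterion estimates the fit quality of the optimized model, not of the
repetition average); a switch to other conventions is deliberate future
surface, and the per-parameter mean/sd/min/max across repetitions is
always reported. In split mode `k` counts all fitted parameters
(k_model × #datasets, the `per_dataset` convention) and `n` counts all
grid observations across datasets; a `model` convention (count k once) is
available since the original convention is not printed. RSS = 0 (possible
on noiseless synthetic data) yields a −∞ sentinel with a warning rather
than a crash; such models rank first, which is the correct limit.

## The simulated-data generator

`simulate` emulates the published synthetic study:

1. the base profile is computed from the fixture's reference state values
   (rounded values from an optimized experimental timepoint: glucose
   0.1/0.9, ribose 0.1/0.9, acetyl 0.7/0.3, uracil 0.2/0.2/0.5/0.1, with
   joint ¹³C/¹⁸O analogues for the multi-tracer model);
2. independent Normal(0, σ) error is added to **every** grid entry
   (σ ∈ {0.001, 0.01, 0.1} in the study conditions);
3. entries **strictly below** the detection limit (default 0.005) are
   zeroed — this includes all negatives; values exactly at the limit are
   kept (arbitrary; documented);
4. the profile is renormalized to sum to one. The pre-renormalization sum,
   averaged over a 100-dataset collection, is the error-propagation
   diagnostic; degenerate all-zero draws are regenerated from the next
   substream.

`timecourse_state_values(fixture, fraction)` supplies reference values for
intermediate labeling timepoints by scaling every labeled-state fraction
by `fraction` (unlabeled states absorb the remainder), emulating a
timecourse in which the tracer progressively saturates the moiety pools.

What the generator does **not** emulate: natural isotope abundance,
shot/proportional MS noise, peak-integration artifacts, or correlations
between isotopologues. Passing the synthetic studies therefore shows the
*method* behaves as published under its stated noise model, not that any
particular experimental dataset will be fit well.

## The model-selection study

Six models compete: the expert UDP-GlcNAc model (k = 6) and five
over-parameterized variants, each adding one extra zero-abundance moiety
state (g1, g5, r4, u4, a1; k = 7). Ten replicates are run; in each, three
datasets are generated at enrichment fractions 0.5 / 0.75 / 1.0 of the
reference values (σ = 0.001, no detection censoring), every model is fit
in split mode (10 repetitions of SAGA 1000 steps + L-BFGS-B polish per
dataset block), and models are ranked by AICc with the `per_dataset` k
convention (k = 18 vs 21 over n = 54 points).

Two design findings, both verified empirically and worth knowing before
trusting any AICc ranking from this kind of data:

* **The timecourse matters.** With all three datasets at the endpoint
  values, the low-content isotopologues sit at or below the detection
  limit; thresholding plus renormalization then injects *systematic*
  model error that an extra state absorbs, and AICc — correctly, given
  the data — prefers the over-parameterized variants. Earlier timepoints
  populate the low-content channels well above the noise scale. The
  selection experiment therefore uses uncensored timecourse data, so that
  the expert model is exactly the data-generating model.
* **The objective must match the noise.** Under the square-difference
  objective — the maximum-likelihood estimator for additive Gaussian
  noise — AICc recovers the expert model essentially always (10/10
  replicates across disjoint seed sets; expert RSS at the noise floor),
  and the absolute-difference objective does equally well (10/10), so the
  result is not an artifact of quadratic fitting.
  Under the log-difference objective the same experiment succeeds in only
  ~4/10 replicates *at any optimization budget*: the log objective
  weights entries by inverse intensity, so for additive noise it is
  misspecified; its optimum carries a model-dependent RSS inflation
  (~2× the noise floor) that an extra parameter systematically shrinks,
  and the RSS-based AICc comparison then favors the bigger model. This is
  a property of the estimator/noise pairing, not of the optimizer — at
  full convergence a variant's RSS can sit 40% below the expert's. On
  experimental MS data, whose error is closer to multiplicative, the log
  objective is the appropriate choice; on additive-noise simulations it
  is not. Both configurations ship in the test suite and acceptance
  script so the contrast is reproducible.

## Problem sizes and numerical choices

* Synthetic studies use 100 datasets per error-propagation condition, 10
  optimization repetitions per model block, SAGA budgets of 5000 steps
  (recovery) / 1000 steps (selection, where the L-BFGS-B polish does the
  final convergence), and 10 selection replicates — sizes chosen so the
  full suite re-runs in minutes on one core while leaving every
  statistical margin comfortable.
* Feasibility tolerance for expansions: 1e−9 on [0, 1] bounds; per-moiety
  sums are exact by construction (the default state is assigned the
  complement).
* Local refinement never worsens: if the polished energy exceeds the
  starting energy (beyond 1e−12) or scipy fails, the start is returned.
* Ties in model ranking break lexicographically by model name; models
  with undefined criteria rank last, flagged.
* Random starts for scipy local methods are drawn per-moiety from a flat
  Dirichlet (uniform box draws are infeasible with high probability and
  strand gradient methods on the penalty plateau); the SAGA population is
  initialized uniformly in the box as specified.

## Known limitations

* Moiety decompositions and atom mappings are user input; nothing infers
  them from a metabolic network.
* No natural-abundance correction: inputs must be corrected relative
  isotopologue profiles.
* Single-tracer UDP-GlcNAc fits are multimodal (several parameter sets
  reproduce the 18-point profile almost exactly); parameter-level
  interpretation needs the multi-tracer design or external constraints.
  The recovery tests therefore assert profile recovery for the
  single-tracer model and parameter recovery only for the multi-tracer
  model.
* Time dependence across datasets is not modeled; each dataset is fit
  independently (or jointly but with independent blocks).
* No parallel execution; all runs are single-process and deterministic.
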