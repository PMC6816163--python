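# moietykit

Moiety-model deconvolution of mass-spectrometry isotopologue profiles.

## The problem

Stable-isotope tracing experiments feed a labeled precursor (e.g.
[U-¹³C]-glucose) to cells and measure, by MS, the *isotopologue profile*
of downstream metabolites — the relative intensities I₀ … I_N of species
carrying 0 … N heavy atoms. For a composite metabolite such as UDP-GlcNAc,
built from four moieties (glucose, ribose, acetyl, uracil) by converging
biosynthetic pathways, that profile convolves the isotope enrichment of
every subunit. moietykit deconvolutes it: each moiety *j* occupies one of
a few joint enrichment states *i* (e.g. `glucose[13C_6]`,
`uracil[13C_2.18O_1]`) with fractional abundance
*moiety_state*₍ⱼ,ᵢ₎ ∈ [0, 1], summing to one per moiety, and the
calculated profile is

&nbsp;&nbsp;&nbsp;&nbsp;I₍ₓ,calc₎ = Σ₍v : content(v) = x₎ ∏ⱼ *moiety_state*₍ⱼ,ᵥⱼ₎

Fitting the state fractions to an observed profile is a bounded,
non-convex inverse problem. moietykit solves it with **SAGA**, a hybrid
simulated-annealing/genetic-algorithm minimizer (population evolution with
temperature-attenuated mutation and Metropolis replace-the-worst
acceptance), optionally polished by scipy's bounded local methods, and
chooses between competing moiety decompositions with information criteria

&nbsp;&nbsp;&nbsp;&nbsp;AIC = 2k + n·ln(RSS/n), AICc = AIC + (2k² + 2k)/(n − k − 1), BIC = n·ln(RSS/n) + k·ln(n).

It is written for SIRM (stable isotope-resolved metabolomics)
practitioners who have natural-abundance-corrected isotopologue profiles
of composite metabolites and candidate moiety decompositions, for single
or multiple (¹³C/¹⁸O) tracers.

## Worked example

Fit the expert-derived UDP-GlcNAc model to a noiseless profile computed
from its own reference state values, then summarize:

```python
import moietykit as mk
from moietykit import analysis, simulate

model, truth = mk.build_fixture("expert_single")     # 4 moieties, k = 6
molecule = model.molecules[0]
profile = mk.calc_intensity_profile(molecule, truth)
print(mk.possible_isotopologue_count(molecule))      # 18
print(round(profile.as_dict()[(16,)], 4))            # 0.0243  (= 0.9*0.9*0.3*0.1)

dataset = simulate.profile_to_dataset(profile, "demo")
settings = mk.OptimizationSettings(
    method="SAGA", saga=mk.SagaSettings(step_number=5000),
    repetitions=10, objective=mk.ObjectiveSpec("absolute_difference"),
    seed=2026, polish=True,
)
result = mk.optimize(model, [dataset], settings)
summary = analysis.summarize_repetitions(result, model, [dataset])
print(f"best absolute loss: {result.best('demo').energy:.2e}")   # 9.43e-09
print(f"RSS: {summary.rss:.2e}")                                 # 1.43e-17
```

The fitted profile reproduces the input to ~1e-8 — the inverse problem is
solvable exactly on noiseless data. (On single-tracer data the *parameters*
are not unique — several state assignments generate the same 18-point
profile — which is why multi-tracer designs exist; see
[docs/methods.md](docs/methods.md).)

The same workflow runs from the shell:

```sh
moietykit simulate --fixture expert_single --sigma 0.001 --n 3 --seed 7 --out sim/
moietykit modeling --models sim/expert_single_model.json \
    --datasets datasets.json --optimizations opt.json --out results/
moietykit analyze --manifest results/resultPaths.txt \
    --models sim/expert_single_model.json --datasets datasets.json --out analyses/
moietykit rank --manifest analyses/analysisPaths.txt --criterion AICc
```

## Layout

| module | responsibility |
|---|---|
| `moietykit.model` | moieties, joint states, relationships, molecules; free-parameter ↔ state-value mapping |
| `moietykit.profile` | forward calculation of isotopologue profiles |
| `moietykit.saga` | the annealing/genetic optimizer (standalone, any box-bounded energy) |
| `moietykit.modeling` | objectives, datasets, split/combined fitting drivers |
| `moietykit.analysis` | repetition statistics, AIC/AICc/BIC, model ranking |
| `moietykit.simulate` | reference fixtures, noisy-dataset generation, error-propagation diagnostics |
| `moietykit.io` / `moietykit.cli` / `moietykit.plot` | JSON schemas, manifests, command line, figures |

Methodological details, parameter conventions and known limitations are in
[docs/methods.md](docs/methods.md).
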