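# anisokin

Depletion-aware analysis of fluorescence-anisotropy (FA) ligand-binding
assays, for people who characterize receptor–ligand interactions on
membrane particles (e.g. budded-baculovirus preparations displaying a
GPCR) in 384-well plate readers.

In an FA assay a fluorescent probe's anisotropy rises when it binds a
large particle.  Getting quantitative affinities and rate constants out of
such data is awkward precisely where the assay works best: the bound
fraction of probe must be large, so **ligand depletion** breaks the usual
free≈total shortcuts (Cheng–Prusoff, hyperbolic saturation, pseudo-first-
order kinetics).  `anisokin` therefore treats everything through the full
mass-action system

```
R + L   <=> RL        kon_L / koff_L       (probe)
R + C   <=> RC        kon_C / koff_C       (unlabeled competitor)
NBV + L <=> NBVL      kon_NS / koff_NS     (non-specific sites)
```

with the observation model
`FA = (L·FA_free + RL·FA_bound + NBVL·FA_ns) / (L + RL + NBVL)` and
`FA = (I_par − I_perp)/(I_par + 2 I_perp)` on blank-corrected channels.

What it does:

* simulate the reaction system (stiff ODE, timed reagent additions) and
  solve its exact equilibrium;
* globally fit kinetic parameters (kon, Kd, stock concentrations,
  intrinsic anisotropies) to multi-well FA time courses with a seeded
  Nelder–Mead/simulated-annealing hybrid and time-weighted MSE loss;
* saturation analysis, three/four-parameter dose–response fits,
  depletion-corrected Ki (exact equilibrium inversion, with the
  Cheng–Prusoff limit), Z′ screening quality;
* Log(IC50)-vs-time analysis with the single-phase exponential
  stabilization fit (half-life of IC50 drift — tells you when your
  endpoint is trustworthy and whether the competitor binds faster or
  slower than the probe);
* generate complete synthetic 384-well experiments (raw polarized
  intensities + well maps + ground truth) so the whole pipeline is
  testable end-to-end.

See `docs/methods.md` for the model, the numerics and the design choices.

## Worked example

Simulate a saturation-kinetics plate (probe at 0.5 and 3 nM, two-fold BBV
dilution series, 90-min association then an excess-blocker chase) and
re-estimate the generating parameters from the raw intensities:

```python
from anisokin import (FitConfig, NoiseModel, dataset_from_plate, fit_global,
                      generate_experiment, saturation_kinetic_design)
from anisokin.synthetic_data import DEFAULT_TRUE_PARAMS
from anisokin.benchmarks import SATURATION_FREE_PARAMS, staged_start_params

design = saturation_kinetic_design(replicates=2)
plate, well_map, truth = generate_experiment(
    design, DEFAULT_TRUE_PARAMS, NoiseModel(rel_sd=0.01, seed=1))

dataset = dataset_from_plate(plate, well_map, design)
config = FitConfig(seed=1, free=SATURATION_FREE_PARAMS, n_uncertainty=0)
result = fit_global(dataset, config, staged_start_params(dataset, design))
for name in ("kon_L", "Kd_L", "R_stock", "FA_free"):
    print(f"{name:8s} truth {truth['params'][name]:<8.3g}"
          f" fitted {result.estimates[name]:.3g}")
```

Output of this exact script (seed 1):

```
kon_L    truth 0.00042  fitted 0.000416
Kd_L     truth 0.667    fitted 0.662
R_stock  truth 20       fitted 21.5
FA_free  truth 0.081    fitted 0.0814
```

i.e. from ~1%-noise raw channel data the fit recovers the probe's
association rate, its affinity, the undiluted receptor-stock concentration
and the free-probe anisotropy to a few percent.

The same pipeline is scriptable from the shell:

```
anisokin simulate --out run --seed 11 --config cfg.yaml
anisokin fit-kinetic --out fit --seed 2 --plate run/plate.csv \
    --well-map run/well_map.csv --design run/design.yaml
anisokin zprime --out z --plate run/plate.csv --well-map run/well_map.csv
```

Subcommands: `simulate`, `fit-saturation`, `fit-competition`,
`fit-kinetic`, `ic50-timecourse`, `zprime`; every run writes JSON results,
CSV tables and a log echoing the package version, seed, all parameters and
a config hash.

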