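# Methods

## The measurement and the model

Fluorescence anisotropy (FA) reports the rotational mobility of a
fluorescent ligand ("probe"): free probe tumbles fast and is nearly
depolarized, probe bound to a large membrane particle tumbles slowly and
keeps its polarization.  A plate reader records parallel and perpendicular
emission intensities per well per time point; after channel-wise blank
subtraction the anisotropy is

    FA = (I_par - I_perp) / (I_par + 2 I_perp).

The receptor source is a membrane nanoparticle preparation (budded
baculovirus, BBV) displaying the receptor at a stock concentration
`R_stock`; each well sees the stock at a known dilution.  Because useful FA
signal requires the bound fraction of probe to be substantial, the assay
operates under **ligand depletion**: free concentrations cannot be
approximated by totals, and all analysis here goes through the full
mass-action treatment.

The reaction system has three reversible steps —

    R + L   <-> RL      (probe binding,          kon_L / koff_L)
    R + C   <-> RC      (competitor binding,     kon_C / koff_C)
    NBV + L <-> NBVL    (non-specific binding,   kon_NS / koff_NS)

— and the predicted anisotropy of a well is the concentration-weighted
mean of the intrinsic anisotropies of the probe's three states:

    FA = (L*FA_free + RL*FA_bound + NBVL*FA_ns) / (L + RL + NBVL).

Units are fixed package-wide: nM, seconds, 1/(nM·s) and 1/s.  Affinities
are carried as (kon, Kd) with koff = kon·Kd derived, and optimizers work on
log10 of positive parameters.

## Numerical core

*Kinetics.*  The seven-species mass-action ODE system is integrated with
LSODA (stiff-capable; relative tolerance 1e-8, absolute 1e-10 nM) with an
analytic Jacobian.  Reagent additions are instantaneous concentration
steps; integration restarts at each addition, and a sample coinciding with
an addition time is reported pre-addition.  An optional per-event dilution
factor rescales all concentrations (default 1: added volumes are neglected,
as in the excess-blocker chase where the added volume is not specified).
Inside the global-fit loop, wells sharing one time grid and event schedule
are stacked into a single block-diagonal system integrated with a banded
Jacobian (numba-compiled right-hand side); this is numerically identical to
the per-well path (verified in the tests to the integration tolerance) and
about an order of magnitude faster.

*Equilibrium.*  The coupled equilibria reduce to one scalar equation in
free probe `L`: the receptor/competitor sub-system is eliminated through a
closed-form quadratic, non-specific sites through their isotherm, and the
probe balance `L(1 + R(L)/Kd + NBV(L)/K_NS) = L_tot` is solved with Brent's
method on the bracket [0, L_tot], where the residual provably changes sign.
Residuals at the returned state are checked to 1e-9 of the largest total
(in practice machine precision).  Irreversible non-specific binding
(koff_NS = 0) has no finite equilibrium and is rejected explicitly.

## Estimation procedures

*Global kinetic fit.*  The loss is the mean over all (well, time) points of
`w(t) · (FA_pred - FA_obs)^2`.  The default time weighting
`w(t) = 1/(1 + t/tau)` with `tau = 600 s` (normalized to mean 1)
down-weights late, slowly-changing points in favour of the information-rich
early kinetics; it is a declared surrogate for the "less timescaling"
weighting of commercial systems-biology tooling, whose exact form is not
public, and reports label it as such.  A `uniform` scheme is available.

Optimization is a Nelder-Mead simplex embedded in simulated annealing: the
temperature ladder starts at 1000, spends 10^3 loss evaluations per
temperature, and is multiplied by 0.2 until it falls below 0.1 (so the
ladder is 1000, 200, 40, 8, 1.6, 0.32).  At each temperature, a simplex
search restarts from a point perturbed around the current iterate with a
Gaussian whose scale is proportional to temperature on the log-parameter
scale (one log10 unit at the start temperature by default); its result is
accepted by the Metropolis criterion with the loss scale anchored to the
incumbent best (at the start temperature a move costing about the best
loss is acceptable; near the stop temperature only improvements are), and
each cooling step re-centers the walk on the incumbent optimum.  A plain
simplex polish follows the ladder.  The published description of this
optimizer names the algorithm family and the schedule but not the
restart/acceptance mechanics; the hybrid above is this package's own
concrete realization, chosen to be fully seeded — identical seed, config
and dataset give bit-identical results.

For the saturation-kinetics pipeline the fit starts from a staged,
data-driven initialization (the standard practice for systems models):
the free-probe anisotropy from the free-ligand wells, the affinity /
stock / anisotropy scales from a quick equilibrium fit of the last
pre-chase time point, and the association rate from the time-to-half-
signal of the strongest total-binding well.  The annealing then only has
to refine within the physically sensible basin rather than locate it from
scratch.

Parameter uncertainty is the spread (sample SD) of 25 simplex refits on
parametric-bootstrap replicates of the dataset — predictions at the
optimum re-noised with the fitted per-trace residual SD — so the SE
measures how much the data constrain each parameter (refits from merely
perturbed starting points collapse back to the identical optimum and
would report zero).  The bootstrap noise is i.i.d. Gaussian per point;
autocorrelated residuals would make these SEs optimistic.  Parameters are
bounded in log space (rates 1e-8..1e2, concentrations 1e-3..1e4 nM);
intrinsic anisotropies are bounded to the physical plausibility window
(-0.2, 0.5), which also prevents the optimizer escaping along the
R_stock/FA_bound sloppiness ridge to non-physical anisotropies above the
photoselection limit (~0.4).

By default the non-specific dissociation rate `koff_NS` is *fixed* and only
`kon_NS` is free (the reduced parameterization in which the NS site
strength is effectively one free scale); freeing `koff_NS` is a one-line
config change.

*Saturation analysis (equilibrium).*  Total and non-specific wells at two
probe concentrations over a BBV dilution series are fitted globally with
one parameter set (Kd, R_stock, NBV_stock, three anisotropies) through the
exact equilibrium — full depletion, no free≈total shortcut.  At
equilibrium only the ratio NBV_stock/K_NS is identifiable, so K_NS is held
fixed and the site concentration absorbs the scale.  Standard errors are
asymptotic (Gauss-Newton covariance).

*Dose-response and Ki.*  Competition endpoints are fitted with the
log(inhibitor)-vs-response logistic, Hill slope fixed at 1 (three-parameter)
or free (four-parameter); zero-concentration wells anchor the top plateau
exactly.  The depletion-corrected Ki inverts the exact equilibrium: Ki is
the competitor constant at which competitor total = IC50 halves the
specific signal relative to the competitor-free equilibrium, found by
Brent's method on log Ki over [-12, 12].  This inversion is exact by
construction rather than a closed-form approximation, and it reduces to
Cheng-Prusoff `Ki = IC50/(1 + L/Kd)` as the receptor concentration
vanishes (the non-specific pathway is not part of this inversion: the
specific signal is defined on RL).  IC50 values below the depletion floor —
where even an infinitely potent competitor cannot halve the signal — are
rejected with a dedicated error.

*Log(IC50) time course.*  At every time point the model (or the data) is
profiled across the competitor series with the three-parameter logistic;
failed per-time fits are flagged missing, never interpolated.  The
approach to equilibrium is summarized with the single-phase exponential
`Log(IC50)(t) = (Log(IC50)_0 - Log(IC50)_eq) e^{-kt} + Log(IC50)_eq`,
fitted by weighted least squares with per-time SEs (weighting on by
default, switchable) and reported as a half-life ln2/k in minutes.  Time
zero is the reaction-initiating (BBV addition) event.  One physical
subtlety: at very early times the receptor is not yet limiting, so *no*
competitor concentration can halve the specific signal and the apparent
IC50 is transiently inflated for any competitor — the direction law
(faster-than-probe competitor: rising Log(IC50); slower: falling;
kinetically matched: flat) therefore applies to the post-transient part of
the course, which is also where the assay's endpoint readouts live.

*Screening quality.*  `Z' = 1 - 3(sigma_pos + sigma_neg)/|mu_pos - mu_neg|`
with sample (n-1) standard deviations.  Cross-experiment summaries use
inverse-variance weighted means with weighted SDs.

## The synthetic-data generator

The generator emulates the three assay designs end-to-end on a 384-well
layout (row-major fill, each BBV dilution's blank adjacent to its wells and
recorded explicitly in the well map):

* **Saturation kinetics** — probe at 0.5 and 3 nM against a two-fold BBV
  dilution series starting at 1/30 (1 uL of stock in a 30 uL well, i.e.
  0.67 nM receptor from a 20 nM stock), total and non-specific (50 uM
  blocker) wells, 90 min association, then a 333 uM blocker chase followed
  for another 120 min, sampled every 5 min.  Default four dilutions in
  duplicate — duplicates match bench practice and are what makes the
  receptor-stock scale well-determined at 1% channel noise.
* **Competition kinetics** — 0.5-1 nM probe, fixed 1/30 BBV, a competitor
  dilution series plus a competitor-free well, sampled every 5 min for 5 h.
* **Saturation endpoint** — the same plate read at a single equilibrium
  time.

Intensities are produced by inverting the anisotropy equation at a total
brightness of 3000 a.u. per nM probe, adding a blank baseline proportional
to the BBV dilution on both channels (9000 a.u. per channel per unit
dilution — an autofluorescence/scatter surrogate), and applying
multiplicative Gaussian noise per channel (default 1% CV; plate readers
show roughly constant CV at these intensities).  Channels are emitted as
already calibrated (instrument G-factor 1).  Blank wells carry baseline
and noise but no probe.  Generation is deterministic per seed, and the
ground truth (parameters, design, noise model) is serialized next to the
data.

Default ground truth for recovery studies is the probe's globally fitted
parameter set — kon 4.2e-4 1/(nM·s), koff 2.8e-4 1/s (Kd 0.67 nM), stock
20 nM, free-probe anisotropy 0.081 — with non-specific binding set so that
roughly 8% of probe is non-specifically bound at the standard dilution
(kon_NS 1e-5, koff_NS 4e-4, NBV_stock 100 nM) and bound/NS anisotropies of
0.35/0.15, which reproduce the assay's ~0.12 FA window between total and
non-specific wells.

What the generator does **not** model: evaporation and photobleaching
(negligible over <= 5 h in this assay format), shot noise (a Poisson mode
is deliberately out of scope), pipetting/liquid-handling errors, spectral
bleed-through, and G-factor miscalibration.  Passing recovery tests
therefore demonstrate correctness of the estimation machinery under the
stated noise model, not robustness to every instrumental artifact of real
plates.

## Problem sizes and reproducibility

The recovery benchmark fits five seeded experiments (36 measurement wells
each, 43 time points per well) with the full annealing schedule, about
9,000 loss evaluations per fit; a study runs in roughly eight minutes on
one CPU.  The
larger-scale characterizations (e.g. twenty-experiment bias studies) use
the same harness with a shortened ladder, chosen as a deliberate
problem-size reduction for routine testing.  Every stochastic component —
noise generation, annealing, uncertainty refits — flows from explicit
integer seeds, and rerunning any entry point with the same seed reproduces
results bit-for-bit.

## Known limitations

* One-site binding only: no cooperativity, multiple receptor conformations,
  ternary complexes, or receptor internalization.
* The Metropolis/restart mechanics of the annealed simplex and the
  time-weighting form are this package's own concrete choices within the
  published algorithm family; other realizations would differ in trajectory
  though not (empirically) in the optimum reached.
* Asymptotic and refit-spread standard errors understate uncertainty on
  sloppy ridges (notably kon_NS·NBV_stock, and R_stock vs FA_bound when no
  well approaches receptor excess); the published uncertainties for the
  analogous quantities are similarly wide.
* The depletion-aware Ki inversion defines "specific signal" as RL; if
  non-specific binding responded to the competitor, that contribution would
  be misattributed.
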