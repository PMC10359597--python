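# Methods notes

## Scanning/reinitiation model

The leader is a 1-based lattice of 1-nt sites; `UtrLayout` places uORF1
(start/stop), uORF4 and the GCN4 start.  The default geometry
(`utr_length = 577`, d1 = 350 nt, d2 = 150 nt, a 9-nt uORF1 ending at
position 77) approximates the native spacing of the *GCN4* leader; the
exact native coordinates are not pinned down here and every field is a
configuration value.  uORF2 and uORF3 are deliberately omitted: the
leader's regulatory behaviour is largely retained without them, and the
model treats uORF4 termination as terminal (no second reinitiation).

Kinetics: 43S complexes enter at site 1 at rate α if the first
`footprint` sites are clear, hop +1 nt at rate v under hard-core
exclusion (gap ≥ footprint), initiate at uORF1 with probability 1 (no
leaky scanning there), dwell for an exponential time with mean
`uorf_dwell`, and resume at the uORF1 stop with probability η as TC-less
40S.  A 40S carrying TC initiates at the first start codon it reaches;
TC-less 40S pass uORF4 and are scored as runoff if they reach the GCN4
start without TC (there are no further start codons, so any later binding
is irrelevant to fate).

**TC binding is distance-based.**  A TC-less 40S acquires TC on each
completed hop with probability 1 − e^{−λ/v}, so the probability of
acquiring TC across d nt is exactly 1 − e^{−(λ/v)d}.  A literal
time-rate-λ clock racing exponential hops would instead give
(v/(v+λ))^d = e^{−d ln(1+λ/v)}, a systematic O((λ/v)²d) deviation from
the model's closed forms that is visible at 10⁵ Monte Carlo scanners.
The distance form is the continuum-limit behaviour the closed forms
express, and it makes the lattice simulation and the analytic layer two
views of the same process (the simulation still adds exclusion, entry
blocking and dwell queueing on top).  Consequence: a blocked or dwelling
scanner does not accumulate TC-binding probability — only scanned
distance counts.

Defaults: `footprint = 30` nt (≈40S footprint), `uorf_dwell = 2` s
(three codons plus termination).  Both matter only at high density; the
dwell is exponential to keep the simulation a pure CTMC.  Fate-count
standard errors are binomial.  At the repressed defaults the simulated
mean occupancy is ≈1 scanning complex, consistent with ribosome-density
measurements of roughly one (repressed) to two (derepressed) complexes;
the occupancy test uses a loose 0.5–2 band around "approximately one".

The low-density assumption (α ≪ v) is validated by the suite: at
α = 0.08 s⁻¹ the simulated p_GCN4 stays within a few percent of the
analytic value, and occupancy obeys Little's law to 10%.

## Expression model

Bursts arrive at rate k_b and deposit Geometric(mean b, support {0,1,…})
mRNAs, so stationary mRNA is negative binomial with r = k_b/δ_m and
Fano factor 1 + b (b → 0 recovers Poisson).  Protein is produced at
c·flux per mRNA and removed at δ_p.  Stationary moments:

    <m> = k_b b / δ_m,   Var m = <m>(1 + b)
    <p> = c·flux·<m>/δ_p
    Var p = <p> + (c·flux)² Var m / (δ_p (δ_m + δ_p))

Defaults (k_b = 0.01 s⁻¹, b = 4, δ_m = 0.002 s⁻¹ i.e. ~8 min mRNA
lifetime, δ_p = 1.28×10⁻⁴ s⁻¹ i.e. dilution at ~90 min doubling,
c = 75) give ⟨m⟩ = 20 and ~10³ reporter proteins per repressed cell —
about 10× autofluorescence on the fluorescence scale, with intrinsic
CV ≈ 13%.  No absolute rates are claimed; these are realistic yeast
orders of magnitude chosen once.

Population-scale sampling uses a gamma distribution matched to the exact
stationary mean/variance (the continuous stationary limit of the bursty
cascade); `method="ssa"` runs the exact Gillespie chain with a burn-in of
8 protein lifetimes (initialization bias < 0.1%) and is the oracle the
gamma path is tested against.  Fluorescence is
F = autofluor + s·protein·S^γ with S the shared lognormal size factor
(σ_S = 0.2) carrying the extrinsic component; γ = 0 decouples it.

## Population layer

Per-cell Gcn2 activity is lognormal (μ_G = 0, σ_G = 1).  The threshold
G* is back-solved from the configured stationary exceedance (default
0.03, the observed SET fraction) rather than asserted in activity units,
because only the exceedance is observable.  λ(G) is a two-state map:
λ_repressed = 0.54 s⁻¹ at or below G* (the boundary is assigned to the
repressed state), λ_derepressed = 0.33 s⁻¹ above it, never exceeding the
repressed ceiling — rate control by other initiation factors caps λ from
above, which is what skews the population asymmetrically rather than
symmetrically.  A graded log-linear variant over one decade above G* is
available behind `graded=True` but off by default.

Generational memory is an OU process on log G with autocorrelation time
τ_G = 1 generation.  τ_G has no directly measured value; one generation
is the choice that lets a sorted population relax within the observed
≤10 generations while still making the SET state persistent enough to
sort.  It is exposed in configuration for sensitivity analysis.  The
induction time course raises the log-mean activity by `drift` per hour
(default 1.1, i.e. ~1.05 σ_G/h) while G* stays at its uninduced value;
that default takes the above-threshold fraction from 3% to >99% at 4 h,
matching the observed complete transition.

Mutant presets: `uorf1_ata` bypasses uORF1 entirely (the 43S keeps its
TC to uORF4 and initiates there; GCN4 is reached only through a leak
ε = 0.02, a placeholder magnitude), `uorf1_to_uorf4` sets η → 0.02,
`gcn2_delta` and `eif2a_s51a` pin λ at the ceiling for every cell,
`no_uorf_control` initiates at GCN4 with probability 1.  The per-cell
ground truth label is `lambda < lambda_repressed`, which coincides with
G > G* whenever the gating map is intact and is identically false for
the pinned presets.

## Cytometry analysis

All gate boundaries are inclusive ("within the radius").  The density
centre is the peak of a 64×64 2-D histogram with three-point parabolic
refinement — deterministic and adequate for mode finding.  %CV is
100·σ/μ with the (n−1) sample standard deviation; radii capturing fewer
than 30 events are flagged, not dropped.  The dual-reporter estimators
are the standard covariance decomposition computed on mean-scaled
channels, so η_int² + η_ext² = η_tot² holds algebraically (verified to
1e-12).

Distribution fitting and the model-based SET classifier operate on log10
fluorescence: cytometric intensity distributions are approximately
lognormal, and the log scale makes the two modes comparable in width.
The mixture is EM (scikit-learn GaussianMixture) with 10 seeded
restarts; skew-normal is direct likelihood maximization with
method-of-moments initialization; families are ranked by BIC, and
non-convergence flags a fit instead of raising.  The model-based
classifier fits a robust location/scale (median, scaled MAD) to the
central mass below the 97th percentile and flags cells above
location + 3·scale.

## Synthetic data: what it does and does not emulate

The generator reproduces the statistical structure the analysis assumes:
negative-binomial mRNA behind a gamma/SSA protein stage, a shared size
factor coupling FSC/SSC and fluorescence, lognormal autofluorescence
(the no-reporter control strain is generatable), uniform arrival times,
a ~3% well-separated high mode, and dual reporters sharing extrinsic
state with independent intrinsic draws.  It does not emulate instrument
artefacts (saturation, carryover, spillover), doublets, cell-cycle
structure, fluorophore maturation, or the correlated history of real
lineages; passing tests therefore demonstrate correctness of the
analysis chain on the modelled data-generating process, not performance
on any particular instrument's files.  FSC/SSC scales are centred near
the manual gating centre (59 000 / 27 000) so the standard rectangular
gate keeps most events.

The dual-reporter calibration generator is a separate, purely
multiplicative lognormal construction whose log-variances are solved so
the estimator expectations hit an exactly specified extrinsic fraction;
it provides known ground truth for estimator-consistency checks,
independent of the mechanistic generator.

## Problem sizes and numerics

Default analysis sizes — 10⁵ scanners per Monte Carlo check, 5×10⁴-cell
populations for mixture recovery, 10⁴ cells × 10 replicates for the
regrowth relaxation — were chosen so that binomial/sampling error is
well below the effect sizes being asserted.  Monte Carlo checks compare
at 3 binomial standard errors with a +3/n guard for fates whose expected
counts are in the Poisson regime.  Seeds are explicit everywhere; the
pipeline derives per-stage sub-seeds from the global seed with a
counter scheme so stages are independently reproducible.

## Known limitations

- No elongation dynamics on the main ORF, no eIF2B exchange kinetics, no
  leaky AUG recognition, no uORF2/3.
- The λ(G) threshold map is a deliberate caricature of
  Gcn2→eIF2α-P→TC-level coupling; the graded variant only softens it.
- The mechanism of Gcn2 hyperactivity (abundance vs partial activation)
  is not modelled — only its distributional consequence.
- Absolute expression/fluorescence scales are representative, not
  fitted; only ratios and population shapes are meaningful.
- FCS ingestion is a thin optional adapter (requires `fcsparser` or
  `flowio`); CSV is the tested interchange format.
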