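# gcn4set

Stochastic modelling and noise analysis of translation initiation on the
yeast *GCN4* 5'UTR, built around the **SET^GCN4** phenomenon: in an
exponentially growing, non-starved *S. cerevisiae* population, a small
subpopulation (~3% of cells) spontaneously expresses a *GCN4* 5'UTR
reporter at starvation-like levels — a stochastically enhanced translation
state that is re-established within ~10 generations after sorting it away.

The package is aimed at quantitative/systems biologists who want a fully
synthetic, seedable test bed for this regulatory system: every analysis it
implements runs on data it generates itself.

## What is inside

**Scanning/reinitiation model** (`gcn4set.scanning_model`).  The 5'UTR is a
1-nt lattice scanned 5'→3' by small ribosomal subunits (a TASEP-class
exclusion process).  43S complexes load at the cap at rate α, scan at
speed v, translate uORF1, and with probability η stay on the message as
TC-less 40S.  Ternary complex (TC) rebinds at rate λ while scanning, so a
40S initiates at uORF4 (and is lost) or — if it slipped past uORF4
TC-less — at the *GCN4* start.  In the low-density limit:

    p_uORF4 = η (1 − e^{−(λ/v) d1})
    p_GCN4  = η e^{−(λ/v) d1} (1 − e^{−(λ/v) d2})
    flux    = α · p_GCN4

with d1, d2 the uORF1→uORF4 and uORF4→GCN4 spacings.  Repressed defaults:
λ/v = 0.018, η = 0.62, λ = 0.54 s⁻¹ (so v = 30 nt/s), α = 0.08 s⁻¹;
derepressed: λ/v = 0.011, λ = 0.33 s⁻¹.  `simulate_tasep` is the exclusion
Monte Carlo that independently checks the closed forms and reports
occupancy (≈1 scanning complex on the repressed leader).

**Two-step expression model** (`gcn4set.expression_model`).  Bursty
transcription (negative-binomial mRNA), translation at rate c·flux per
mRNA, protein decay/dilution; exact stationary moments, a Gillespie SSA,
and fast moment-matched stationary sampling.

**Gcn2-gated population layer** (`gcn4set.population_model`).  Per-cell
Gcn2 kinase activity G is lognormal; above a threshold G* (back-solved
from the 3% exceedance) λ switches from its repressed ceiling 0.54 s⁻¹ to
0.33 s⁻¹ — negative Gcn2 fluctuations can never push λ above the ceiling,
which is what makes the population distribution asymmetric.  log G evolves
across generations as an Ornstein–Uhlenbeck process (τ_G = 1 generation),
giving the sort/regrowth relaxation.  Mutant presets: `wild_type`,
`uorf1_ata`, `uorf1_to_uorf4`, `gcn2_delta`, `eif2a_s51a`,
`gcn2_overexpression`, `no_uorf_control`.

**Cytometry noise analysis** (`gcn4set.cytometry_noise`).  Time trimming,
inclusive FSC/SSC rectangular gating (40–100k / 10–90k), density-centre
radial gating, %CV-vs-radius curves, the dual-reporter decomposition
η_tot² = η_int² + η_ext², percentile and model-based SET classification,
and normal / skew-normal / two-component-mixture fits ranked by BIC.

**Synthetic cytometry** (`gcn4set.synthetic_cytometry`) renders model
populations as event tables (time, FSC, SSC, fl1[, fl2], ground-truth
labels) with a shared latent size factor, and round-trips them through CSV.

**Pipeline/CLI** (`gcn4set.pipeline`, `gcn4` console script) wires the
stages into a seeded, end-to-end reproduction run.

## Worked example

```python
import gcn4set as g

lay = g.UtrLayout()                       # d1 = 350 nt, d2 = 150 nt
rep = g.ScanParams.repressed()            # lam = 0.54 1/s
der = g.ScanParams.derepressed()          # lam = 0.33 1/s

g.reinit_probabilities(rep, lay).p_gcn4   # 0.001062
g.reinit_probabilities(der, lay).p_gcn4   # 0.01066  (~10x derepression)
g.gcn4_flux(rep, lay)                     # 8.5e-05 initiations/s per mRNA

pop = g.sample_population("wild_type", 50_000, seed=0)
pop["set_truth"].mean()                   # 0.0297  (truth SET fraction)
labels, frac = g.classify_set(pop["fluorescence"].to_numpy(),
                              method="model_based")
frac                                      # 0.0308  (recovered from data)

fr = g.regrowth_simulation("set", 12, g.Gcn2Model(), seed=0)
fr[:5]                                    # [1.0, 0.132, 0.057, 0.039, 0.031]
```

Reading: derepression (λ 0.54 → 0.33 s⁻¹) raises the probability that a
reinitiating 40S reaches the *GCN4* start about tenfold, which is the
~10× fluorescence separation between the main population and the SET
subpopulation; a sorted all-SET population relaxes back to the ~3%
stationary fraction within a handful of generations.

The same analyses are available from the shell, e.g.

```sh
gcn4 scan
gcn4 sweep --lam-max 5 --out sweep.csv
gcn4 make-synthetic --preset wild_type --n 50000 --seed 1 --out ev.csv
gcn4 classify-set --events ev.csv --method model_based
gcn4 reproduce --out run_dir --seed 7
```

## Layout

    src/gcn4set/        model + analysis modules
    tests/              pytest suite (all synthetic, seeded)
    scripts/acceptance.py
    docs/methods.md     model assumptions, parameter choices, limitations
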