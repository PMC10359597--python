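"""End-to-end reproduction workflow: config, seeding, stages, summary.

``run_reproduction`` chains the model's headline analyses on synthetic
data -- the lambda sweep of reinitiation probabilities, the asymmetric
wild-type population with its ~3% derepressed subpopulation, the CV-vs-
radius gating curves with the SET subset's reduced noise, the induction
time course and the sort/regrowth relaxation -- writing CSV tables, plots
and a machine-readable JSON summary.  Every random stage derives its own
sub-seed from the global seed so stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gcn4set import (
    GateSpec,
    Gcn2Model,
    LatticeConfig,
    ScanParams,
    SynthConfig,
    UtrLayout,
    classify_set,
    cv_curve,
    density_centre,
    dual_reporter_noise,
    fit_population_distributions,
    generate_dual_reporter,
    generate_events,
    generate_induction_series,
    lambda_sweep,
    rectangular_gate,
    regrowth_simulation,
    trim_events,
    write_events,
)
from gcn4set.expression_model import ExpressionParams, FluorescenceParams

log = logging.getLogger("gcn4set")

_SECTION_TYPES = {
    "scan": ScanParams,
    "layout": UtrLayout,
    "gcn2": Gcn2Model,
    "expression": ExpressionParams,
    "fluorescence": FluorescenceParams,
    "lattice": LatticeConfig,
}
_SCALAR_KEYS = {
    "seed": int,
    "out_dir": str,
    "n_cells": int,
    "preset": str,
    "hours": list,
    "drift": float,
    "n_generations": int,
    "radii": list,
    "lam_max": float,
    "lam_points": int,
    "verbosity": str,
    "make_plots": bool,
}


@dataclass
class RunConfig:
    """Validated configuration of a reproduction run."""

    seed: int = 0
    out_dir: str = "gcn4_run"
    n_cells: int = 20_000
    preset: str = "wild_type"
    hours: list = field(default_factory=lambda: [0, 1, 2, 3, 4])
    drift: float = 1.1
    n_generations: int = 12
    radii: list = field(default_factory=lambda: list(
        np.linspace(2000, 40000, 12)))
    lam_max: float = 5.0
    lam_points: int = 200
    verbosity: str = "info"
    make_plots: bool = True
    scan: ScanParams = field(default_factory=ScanParams.repressed)
    layout: UtrLayout = field(default_factory=UtrLayout)
    gcn2: Gcn2Model = field(default_factory=Gcn2Model)
    expression: ExpressionParams = field(default_factory=ExpressionParams)
    fluorescence: FluorescenceParams = field(
        default_factory=FluorescenceParams)
    lattice: LatticeConfig = field(default_factory=LatticeConfig)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = {}
        for key, value in raw.items():
            if key in _SECTION_TYPES:
                if not isinstance(value, dict):
                    raise ValueError(f"config section '{key}' must be a "
                                     "mapping")
                typ = _SECTION_TYPES[key]
                known = {f.name for f in dataclasses.fields(typ)}
                bad = set(value) - known
                if bad:
                    raise ValueError(
                        f"unknown keys {sorted(bad)} in config section "
                        f"'{key}' (valid: {sorted(known)})")
                kwargs[key] = typ(**value)
            elif key in _SCALAR_KEYS:
                kwargs[key] = value
            else:
                raise ValueError(
                    f"unknown config key '{key}' (valid sections: "
                    f"{sorted(_SECTION_TYPES)}, scalars: "
                    f"{sorted(_SCALAR_KEYS)})")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


def derive_seed(global_seed: int, stage_index: int) -> int:
    """Counter-based sub-seed so each stage is independently rerunnable."""
    return int((global_seed * 100_003 + 9_973 * stage_index) % (2**31 - 1))


def _stage(name):
    def wrap(fn):
        def inner(cfg, out, summary, *a, **kw):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                fn(cfg, out, summary, *a, **kw)
            except Exception as exc:
                raise RuntimeError(
                    f"stage '{name}' failed (seed={cfg.seed}, "
                    f"preset={cfg.preset}): {exc}") from exc
            log.info("stage %s: done in %.1fs", name, time.time() - t0)
        return inner
    return wrap


@_stage("lambda_sweep")
def _run_sweep(cfg: RunConfig, out: Path, summary: dict) -> None:
    grid = np.linspace(0.0, cfg.lam_max, cfg.lam_points)
    table = lambda_sweep(cfg.layout, cfg.scan, grid)
    table.to_csv(out / "lambda_sweep.csv", index=False)
    peak = table.loc[table["p_gcn4"].idxmax()]
    summary["lambda_sweep"] = {
        "lam_at_max_p_gcn4": float(peak["lam"]),
        "max_p_gcn4": float(peak["p_gcn4"]),
        "p_gcn4_repressed": float(np.interp(cfg.scan.lam, table["lam"],
                                            table["p_gcn4"])),
    }
    if cfg.make_plots:
        _plot_sweep(table, out / "lambda_sweep.png")


@_stage("population")
def _run_population(cfg: RunConfig, out: Path, summary: dict) -> None:
    seed = derive_seed(cfg.seed, 1)
    events = generate_events(SynthConfig(n_events=cfg.n_cells,
                                         preset=cfg.preset, seed=seed))
    write_events(events, out / "population_events.csv")
    gated = rectangular_gate(trim_events(events))
    labels, frac = classify_set(gated, method="model_based")
    truth = float(gated["set_truth"].mean())
    logfl = np.log10(gated["fl1"].to_numpy())
    fits = fit_population_distributions(logfl, seed=seed)
    summary["population"] = {
        "seed": seed,
        "preset": cfg.preset,
        "n_gated": int(len(gated)),
        "set_fraction_truth": truth,
        "set_fraction_model_based": float(frac),
        "distribution_ranking": [f.model for f in fits],
        "bic": {f.model: f.bic for f in fits},
        "mixture_weights": list(next(
            (f.weights for f in fits if f.model == "two_component_mixture"),
            ())),
    }
    if cfg.make_plots:
        _plot_population(gated, out / "population_hist.png")


@_stage("noise_gating")
def _run_noise(cfg: RunConfig, out: Path, summary: dict) -> None:
    seed = derive_seed(cfg.seed, 2)
    events = generate_dual_reporter(SynthConfig(
        n_events=cfg.n_cells, preset=cfg.preset, dual_reporter=True,
        seed=seed))
    gated = rectangular_gate(trim_events(events))
    centre = density_centre(gated)
    curve_all = cv_curve(gated, cfg.radii, centre=centre)
    sub = gated[gated["set_truth"]]
    curve_set = cv_curve(sub, cfg.radii, centre=centre) \
        if len(sub) >= 30 else None
    curve_all.to_csv(out / "cv_curve_population.csv", index=False)
    if curve_set is not None:
        curve_set.to_csv(out / "cv_curve_set_subset.csv", index=False)
    noise_all = dual_reporter_noise(gated)
    summary["noise"] = {
        "seed": seed,
        "density_centre": [float(c) for c in centre],
        "eta_int_sq": noise_all.eta_int_sq,
        "eta_ext_sq": noise_all.eta_ext_sq,
        "eta_tot_sq": noise_all.eta_tot_sq,
        "cv_percent_largest_radius": float(
            curve_all["cv_percent"].iloc[-1]),
    }
    if len(sub) >= 30:
        noise_set = dual_reporter_noise(sub)
        summary["noise"]["set_subset"] = {
            "eta_ext_sq": noise_set.eta_ext_sq,
            "cv_percent_largest_radius": float(
                curve_set["cv_percent"].iloc[-1]),
        }
    if cfg.make_plots:
        _plot_cv(curve_all, curve_set, out / "cv_curves.png")


@_stage("induction")
def _run_induction(cfg: RunConfig, out: Path, summary: dict) -> None:
    seed = derive_seed(cfg.seed, 3)
    series = generate_induction_series(
        SynthConfig(n_events=cfg.n_cells, preset=cfg.preset, seed=seed),
        cfg.hours, drift=cfg.drift)
    rows = [(h, float(t["fl1"].mean()), float(t["set_truth"].mean()))
            for h, t in series.items()]
    table = pd.DataFrame(rows, columns=["hour", "mean_fl1",
                                        "fraction_derepressed"])
    table.to_csv(out / "induction_timecourse.csv", index=False)
    summary["induction"] = {
        "seed": seed,
        "hours": [r[0] for r in rows],
        "mean_fl1": [r[1] for r in rows],
        "fraction_derepressed": [r[2] for r in rows],
    }


@_stage("regrowth")
def _run_regrowth(cfg: RunConfig, out: Path, summary: dict) -> None:
    seed = derive_seed(cfg.seed, 4)
    fractions = regrowth_simulation("set", cfg.n_generations, cfg.gcn2,
                                    seed=seed, n_cells=cfg.n_cells)
    pd.DataFrame({"generation": np.arange(len(fractions)),
                  "set_fraction": fractions}).to_csv(
        out / "regrowth.csv", index=False)
    summary["regrowth"] = {
        "seed": seed,
        "set_fraction_by_generation": [float(f) for f in fractions],
        "stationary_exceedance": cfg.gcn2.exceed_prob,
    }


def run_reproduction(cfg: RunConfig) -> dict:
    """Run every stage; returns (and writes) the JSON summary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=getattr(logging, cfg.verbosity.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    log.info("reproduction run: global seed %d, out %s", cfg.seed, out)
    summary: dict = {"seed": cfg.seed, "preset": cfg.preset}
    _run_sweep(cfg, out, summary)
    _run_population(cfg, out, summary)
    _run_noise(cfg, out, summary)
    _run_induction(cfg, out, summary)
    _run_regrowth(cfg, out, summary)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _plot_sweep(table: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(table["lam"], table["p_uorf4"], label="reinitiation at uORF4")
    ax.plot(table["lam"], table["p_gcn4"], label="initiation at GCN4")
    ax.set_xlabel("TC binding rate $\\lambda$ (1/s)")
    ax.set_ylabel("probability")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_population(events: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    logfl = np.log10(events["fl1"])
    ax.hist(logfl, bins=120, color="0.6")
    ax.hist(logfl[events["set_truth"]], bins=120, color="crimson")
    ax.set_xlabel("log10 fluorescence (AU)")
    ax.set_ylabel("cells")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_cv(curve_all, curve_set, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ok = ~curve_all["flagged"]
    ax.plot(curve_all["radius"][ok], curve_all["cv_percent"][ok], "o-",
            color="crimson", label="whole population")
    if curve_set is not None:
        ok = ~curve_set["flagged"]
        ax.plot(curve_set["radius"][ok], curve_set["cv_percent"][ok], "o-",
                color="navy", label="SET subset")
    ax.set_xlabel("gate radius (AU)")
    ax.set_ylabel("%CV")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
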