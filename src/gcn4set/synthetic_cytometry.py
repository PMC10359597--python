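"""Synthetic flow-cytometry event generator.

Realizes populations from :mod:`gcn4set.population_model` as cytometer
event tables carrying the statistical structure the analysis chain
assumes: FSC/SSC scale with a latent per-cell size factor (correlated
lognormals centred so the bulk sits inside the standard rectangular gate,
near the manual centre FSC 59 000 / SSC 27 000), fluorescence couples to
the same size factor through the extrinsic exponent gamma, autofluorescence
is lognormal, and arrival times are uniform over the acquisition window.
Ground-truth derepression labels are always carried along so downstream
tests never have to re-infer them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from gcn4set.cytometry_noise import EVENT_COLUMNS, validate_events
from gcn4set.population_model import (
    apply_mutant_preset,
    induction_timecourse,
    sample_population,
)

__all__ = [
    "SynthConfig", "generate_events", "generate_dual_reporter",
    "generate_induction_series", "dual_reporter_calibration",
    "write_events", "read_events", "read_fcs",
]


@dataclass(frozen=True)
class SynthConfig:
    """Settings for synthetic event generation.

    ``preset`` names a population preset; ``reporter=False`` emulates the
    autofluorescence-only control strain (no genomic reporter).  FSC/SSC
    are lognormal around the stated centres, with exponents coupling them
    to the latent size factor and residual instrument spread.
    """

    n_events: int = 50_000
    acquisition_seconds: float = 10.0
    preset: str = "wild_type"
    reporter: bool = True
    dual_reporter: bool = False
    fsc_centre: float = 59_000.0
    ssc_centre: float = 27_000.0
    fsc_size_exp: float = 1.0
    ssc_size_exp: float = 0.8
    fsc_resid_sigma: float = 0.12
    ssc_resid_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        for name in ("acquisition_seconds", "fsc_centre", "ssc_centre"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def _scatter_from_size(cfg: SynthConfig, size: np.ndarray,
                       rng: np.random.Generator) -> tuple[np.ndarray,
                                                          np.ndarray]:
    n = size.size
    fsc = cfg.fsc_centre * size**cfg.fsc_size_exp * np.exp(
        rng.normal(0.0, cfg.fsc_resid_sigma, size=n))
    ssc = cfg.ssc_centre * size**cfg.ssc_size_exp * np.exp(
        rng.normal(0.0, cfg.ssc_resid_sigma, size=n))
    return fsc, ssc


def _arrival_times(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    return np.sort(rng.uniform(0.0, cfg.acquisition_seconds,
                               size=cfg.n_events))


def generate_events(cfg: SynthConfig) -> pd.DataFrame:
    """One synthetic acquisition: columns time, fsc, ssc, fl1, set_truth.

    Cells are drawn from the population model under ``cfg.preset``; the
    latent size factor drives FSC/SSC and (through gamma) fl1.  With
    ``reporter=False`` fl1 is pure autofluorescence (control strain).
    """
    rng = np.random.default_rng(cfg.seed)
    bundle = apply_mutant_preset(cfg.preset)
    pop = sample_population(bundle, cfg.n_events,
                            seed=int(rng.integers(2**31 - 1)))
    fsc, ssc = _scatter_from_size(cfg, pop["size_factor"].to_numpy(), rng)
    if cfg.reporter:
        fl1 = pop["fluorescence"].to_numpy()
    else:
        fl = bundle.fluor
        fl1 = fl.autofluor_mean * np.exp(rng.normal(
            -0.5 * fl.autofluor_sigma**2, fl.autofluor_sigma,
            size=cfg.n_events))
    events = pd.DataFrame({
        "time": _arrival_times(cfg, rng),
        "fsc": fsc,
        "ssc": ssc,
        "fl1": fl1,
        "set_truth": pop["set_truth"].to_numpy() if cfg.reporter
        else np.zeros(cfg.n_events, dtype=bool),
    })
    events.attrs["preset"] = cfg.preset
    events.attrs["seed"] = cfg.seed
    return events


def generate_dual_reporter(cfg: SynthConfig) -> pd.DataFrame:
    """Dual-colour acquisition sharing each cell's extrinsic variables.

    fl1 and fl2 see the same Gcn2 state (hence the same flux), the same
    size factor and the same fluorescence map, but take independent
    stationary expression draws -- the construction under which the
    covariance between channels measures extrinsic noise.  The implied
    ground-truth extrinsic variance fraction (from the generator's own
    conditional moments, autofluorescence excluded as an independent
    additive term per channel) is stored in ``attrs['extrinsic_fraction']``.
    """
    if not cfg.dual_reporter:
        raise ValueError("cfg.dual_reporter must be True")
    from gcn4set.expression_model import sample_protein_levels

    rng = np.random.default_rng(cfg.seed)
    bundle = apply_mutant_preset(cfg.preset)
    pop = sample_population(bundle, cfg.n_events,
                            seed=int(rng.integers(2**31 - 1)))
    flux = pop["flux"].to_numpy()
    size = pop["size_factor"].to_numpy()
    fl = bundle.fluor
    szg = size**fl.gamma

    channels = []
    for _ in range(2):
        protein = sample_protein_levels(bundle.expr, flux,
                                        seed=int(rng.integers(2**31 - 1)))
        auto = fl.autofluor_mean * np.exp(rng.normal(
            -0.5 * fl.autofluor_sigma**2, fl.autofluor_sigma,
            size=cfg.n_events))
        channels.append(auto + fl.scale * protein * szg)

    # ground-truth decomposition from the generator's conditional moments
    expr = bundle.expr
    m_mean = expr.mean_mrna
    m_var = m_mean * (1.0 + expr.b)
    k_p = expr.c * flux
    p_mean = k_p * m_mean / expr.delta_p
    p_var = p_mean + k_p**2 * m_var / (expr.delta_p
                                       * (expr.delta_m + expr.delta_p))
    cond_mean = fl.autofluor_mean + fl.scale * szg * p_mean
    auto_var = (fl.autofluor_mean**2
                * (np.exp(fl.autofluor_sigma**2) - 1.0))
    cond_var = auto_var + (fl.scale * szg)**2 * p_var
    ext_var = float(np.var(cond_mean))
    int_var = float(np.mean(cond_var))
    fsc, ssc = _scatter_from_size(cfg, size, rng)
    events = pd.DataFrame({
        "time": _arrival_times(cfg, rng),
        "fsc": fsc,
        "ssc": ssc,
        "fl1": channels[0],
        "fl2": channels[1],
        "set_truth": pop["set_truth"].to_numpy(),
    })
    events.attrs["preset"] = cfg.preset
    events.attrs["seed"] = cfg.seed
    events.attrs["extrinsic_fraction"] = ext_var / (ext_var + int_var)
    return events


def dual_reporter_calibration(n: int, extrinsic_fraction: float,
                              cv_total: float = 0.25, mean: float = 1000.0,
                              seed: int = 0) -> pd.DataFrame:
    """Dual-reporter benchmark with an exactly known extrinsic fraction.

    Builds fl_k = mean * E * I_k with one shared and two independent
    lognormal factors whose log-variances are solved so that the
    dual-reporter estimators have expectations
    eta_ext^2 = f * V and eta_int^2 = (1 - f) * V with V = cv_total^2.
    Used to validate estimator consistency on known ground truth.
    """
    if not 0.0 <= extrinsic_fraction <= 1.0:
        raise ValueError("extrinsic_fraction must lie in [0, 1]")
    V = cv_total**2
    f = extrinsic_fraction
    sig_e2 = np.log1p(f * V)
    sig_i2 = np.log1p((1.0 - f) * V / (1.0 + f * V))
    rng = np.random.default_rng(seed)
    E = np.exp(rng.normal(-0.5 * sig_e2, np.sqrt(sig_e2), size=n))
    fls = [mean * E * np.exp(rng.normal(-0.5 * sig_i2, np.sqrt(sig_i2),
                                        size=n)) for _ in range(2)]
    events = pd.DataFrame({
        "time": np.sort(rng.uniform(0.0, 10.0, size=n)),
        "fsc": np.full(n, 59_000.0),
        "ssc": np.full(n, 27_000.0),
        "fl1": fls[0],
        "fl2": fls[1],
    })
    events.attrs["extrinsic_fraction"] = f
    events.attrs["cv_total"] = cv_total
    return events


def generate_induction_series(cfg: SynthConfig, hours: Sequence[float],
                              drift: float = 1.1) -> dict[float,
                                                          pd.DataFrame]:
    """One event table per induction time point, identical settings.

    Populations come from the induction time course (log-mean Gcn2 activity
    drifting upward); each is rendered as events with the same cytometer
    model and acquisition length.
    """
    rng = np.random.default_rng(cfg.seed)
    pops = induction_timecourse(cfg.preset, list(hours), drift=drift,
                                n_cells=cfg.n_events,
                                seed=int(rng.integers(2**31 - 1)))
    out = {}
    for h, pop in pops.items():
        fsc, ssc = _scatter_from_size(cfg, pop["size_factor"].to_numpy(),
                                      rng)
        events = pd.DataFrame({
            "time": _arrival_times(cfg, rng),
            "fsc": fsc,
            "ssc": ssc,
            "fl1": pop["fluorescence"].to_numpy(),
            "set_truth": pop["set_truth"].to_numpy(),
        })
        events.attrs["preset"] = cfg.preset
        events.attrs["hour"] = h
        out[h] = events
    return out


def write_events(events: pd.DataFrame, path) -> None:
    """Write an event table as CSV (12 significant digits, lossless for
    the analysis chain)."""
    validate_events(events, require=("time", "fsc", "ssc", "fl1"))
    events.to_csv(path, index=False, float_format="%.12g")


def read_events(path) -> pd.DataFrame:
    """Read a CSV event table, checking the canonical columns."""
    try:
        events = pd.read_csv(path)
    except Exception as exc:  # surface file/parse context
        raise ValueError(f"could not parse event table {path}: {exc}") from exc
    for col in EVENT_COLUMNS:
        if col not in events.columns:
            raise ValueError(
                f"event table {path} is missing column '{col}'")
    if "set_truth" in events.columns and len(events):
        events["set_truth"] = events["set_truth"].astype(bool)
    return events


def read_fcs(path) -> pd.DataFrame:
    """Thin FCS3.0 adapter -> canonical event table.

    Maps Time/FSC-A/SSC-A and the first one or two fluorescence channels to
    the canonical columns; 2^18-resolution values pass through unchanged.
    Requires the optional ``fcsparser`` (or ``flowio``) package.
    """
    try:
        import fcsparser
    except ImportError:
        try:
            import flowio
        except ImportError as exc:
            raise ImportError(
                "reading FCS files requires the optional 'fcsparser' or "
                "'flowio' package; export to CSV instead") from exc
        fd = flowio.FlowData(str(path))
        data = np.reshape(fd.events, (-1, fd.channel_count))
        names = [fd.channels[str(i + 1)].get("PnN", f"ch{i + 1}")
                 for i in range(fd.channel_count)]
        frame = pd.DataFrame(data, columns=names)
    else:
        _, frame = fcsparser.parse(str(path))
    rename = {}
    for col in frame.columns:
        low = str(col).lower()
        if low.startswith("time"):
            rename[col] = "time"
        elif low.startswith("fsc"):
            rename[col] = "fsc"
        elif low.startswith("ssc"):
            rename[col] = "ssc"
    frame = frame.rename(columns=rename)
    fl_cols = [c for c in frame.columns
               if c not in ("time", "fsc", "ssc")]
    for i, col in enumerate(fl_cols[:2], start=1):
        frame = frame.rename(columns={col: f"fl{i}"})
    validate_events(frame, require=EVENT_COLUMNS)
    return frame
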