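"""Scanning/reinitiation model of translation initiation on the GCN4 leader.

The 5'UTR is a 1-nt lattice.  43S pre-initiation complexes (small subunit +
ternary complex, TC) load at the cap at rate ``alpha``, scan 5'->3' at rate
``v`` and initiate at uORF1 with probability 1.  After uORF1 termination the
40S stays on the message with probability ``eta`` and resumes scanning
TC-less; it reacquires TC at rate ``lam`` while covering the downstream
leader.  A 40S that carries TC when it reaches the next start codon
initiates there: at uORF4 (``d1`` nt downstream of the uORF1 stop, a fate
that removes the ribosome from the message) or, if it slipped past uORF4
TC-less, at the GCN4 main ORF (``d2`` nt further).  A 40S that reaches the
GCN4 start still TC-less runs off.  uORF2 and uORF3 are deliberately absent
from this model version.

In the low-density limit the four fates have the closed forms

    p_dissoc = 1 - eta
    p_uorf4  = eta (1 - e^{-(lam/v) d1})
    p_gcn4   = eta e^{-(lam/v) d1} (1 - e^{-(lam/v) d2})
    p_runoff = eta e^{-(lam/v)(d1 + d2)}

and the GCN4 initiation flux per mRNA is ``alpha * p_gcn4``.  The Monte
Carlo (:func:`simulate_tasep`) adds hard-core exclusion between scanning
complexes and serves as the independent check of those forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from gcn4set._tasep import STATUS_OVERFLOW, STATUS_TIME_EXCEEDED, run_tasep

__all__ = [
    "UtrLayout", "ScanParams", "ScanOutcome", "LatticeConfig", "SimResult",
    "UnderSampledError", "p_tc_bind_within", "reinit_probabilities",
    "gcn4_flux", "lambda_sweep", "simulate_tasep", "occupancy_stats",
]

FATE_NAMES = ("dissoc_uorf1", "uorf4", "gcn4", "runoff")


class UnderSampledError(RuntimeError):
    """Raised when max_time elapses before the requested scanners complete."""


@dataclass(frozen=True)
class UtrLayout:
    """Geometry of the GCN4 leader lattice (positions in nt, 1-based).

    Defaults approximate the native spacing: a ~9-nt uORF1 ending 350 nt
    upstream of uORF4, which sits 150 nt upstream of the GCN4 start.  They
    are placeholders for the exact native coordinates and every field is
    overridable from configuration.
    """

    utr_length: int = 577
    uorf1_start: int = 68
    uorf1_stop: int = 77
    uorf4_start: int = 427
    gcn4_start: int = 577

    def __post_init__(self) -> None:
        if not (1 <= self.uorf1_start < self.uorf1_stop < self.uorf4_start
                < self.gcn4_start <= self.utr_length):
            raise ValueError(
                "layout must satisfy 1 <= uorf1_start < uorf1_stop < "
                f"uorf4_start < gcn4_start <= utr_length, got {self}")

    @property
    def d1(self) -> int:
        """uORF1 stop -> uORF4 start distance (nt)."""
        return self.uorf4_start - self.uorf1_stop

    @property
    def d2(self) -> int:
        """uORF4 start -> GCN4 start distance (nt)."""
        return self.gcn4_start - self.uorf4_start


@dataclass(frozen=True)
class ScanParams:
    """Kinetic rates of the scanning model.

    alpha : 43S cap-loading rate (1/s)
    v     : scanning speed (nt/s)
    lam   : TC binding rate to a scanning 40S (1/s)
    eta   : probability the 40S is retained after uORF1 termination

    Defaults are the repressed-condition estimates (lam/v = 0.018,
    eta = 0.62, lam = 0.54 1/s, hence v = 30 nt/s, alpha = 0.08 1/s).
    """

    alpha: float = 0.08
    v: float = 30.0
    lam: float = 0.54
    eta: float = 0.62

    def __post_init__(self) -> None:
        if self.v <= 0:
            raise ValueError(f"scanning speed v must be > 0, got {self.v}")
        if self.alpha < 0 or self.lam < 0:
            raise ValueError("rates alpha and lam must be >= 0")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"eta must lie in [0, 1], got {self.eta}")

    @classmethod
    def repressed(cls, alpha: float = 0.08) -> "ScanParams":
        return cls(alpha=alpha, v=30.0, lam=0.54, eta=0.62)

    @classmethod
    def derepressed(cls, alpha: float = 0.08) -> "ScanParams":
        # lam/v = 0.011 at the same scanning speed
        return cls(alpha=alpha, v=30.0, lam=0.33, eta=0.62)


@dataclass(frozen=True)
class ScanOutcome:
    """Terminal-fate probabilities of a single loaded 43S complex."""

    p_uorf4: float
    p_gcn4: float
    p_runoff: float
    p_dissoc_uorf1: float

    def __post_init__(self) -> None:
        total = (self.p_uorf4 + self.p_gcn4 + self.p_runoff
                 + self.p_dissoc_uorf1)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"fate probabilities sum to {total!r}, not 1")
        for name, p in self.as_dict().items():
            if not -1e-15 <= p <= 1 + 1e-15:
                raise ValueError(f"{name}={p} outside [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {
            "p_uorf4": self.p_uorf4,
            "p_gcn4": self.p_gcn4,
            "p_runoff": self.p_runoff,
            "p_dissoc_uorf1": self.p_dissoc_uorf1,
        }


@dataclass(frozen=True)
class LatticeConfig:
    """Monte Carlo settings for :func:`simulate_tasep`.

    footprint   : nt occupied by one scanning complex (exclusion range)
    uorf_dwell  : mean time (s) spent translating/terminating a 3-codon uORF
    max_time    : wall-clock limit of simulated time; None -> generous auto
    n_replicates: number of scanners that must reach a terminal fate
    """

    footprint: int = 30
    uorf_dwell: float = 2.0
    max_time: float | None = None
    n_replicates: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.footprint < 1:
            raise ValueError("footprint must be >= 1 nt")
        if self.uorf_dwell < 0:
            raise ValueError("uorf_dwell must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class SimResult:
    """Outcome of a lattice simulation."""

    outcome_counts: dict[str, int]
    probabilities: dict[str, float]
    se_estimates: dict[str, float]
    mean_occupancy: float
    occupancy_variance: float
    flux_gcn4: float
    total_time: float
    n_completed: int
    n_entered: int
    mean_residence_time: float
    seed: int = 0


def p_tc_bind_within(d: float, lam: float, v: float) -> float:
    """Probability a TC-less 40S acquires TC while scanning ``d`` nt.

    Equals ``1 - exp(-(lam/v) * d)``: the scanning time for d nt is d/v and
    TC arrives at rate lam.
    """
    if v <= 0:
        raise ValueError(f"scanning speed v must be > 0, got {v}")
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    if d < 0:
        raise ValueError(f"distance d must be >= 0, got {d}")
    return -math.expm1(-(lam / v) * d)


def reinit_probabilities(params: ScanParams, layout: UtrLayout) -> ScanOutcome:
    """Closed-form low-density fate probabilities for one 43S complex."""
    x = params.lam / params.v
    eta = params.eta
    s1 = math.exp(-x * layout.d1)          # no TC across d1
    s2 = math.exp(-x * layout.d2)          # no TC across d2
    p_uorf4 = eta * (1.0 - s1)
    p_gcn4 = eta * s1 * (1.0 - s2)
    p_runoff = eta * s1 * s2
    return ScanOutcome(p_uorf4=p_uorf4, p_gcn4=p_gcn4, p_runoff=p_runoff,
                       p_dissoc_uorf1=1.0 - eta)


def gcn4_flux(params: ScanParams, layout: UtrLayout) -> float:
    """GCN4 initiations per second per mRNA (low-density approximation)."""
    return params.alpha * reinit_probabilities(params, layout).p_gcn4


def lambda_sweep(layout: UtrLayout, params: ScanParams,
                 lam_grid: Sequence[float]) -> pd.DataFrame:
    """Fate probabilities across a grid of TC binding rates.

    Returns a frame with columns ``lam``, ``p_uorf4``, ``p_gcn4``.
    p_uorf4 rises monotonically with lam; p_gcn4 vanishes at both extremes
    with a single interior maximum at lam/v = ln(1 + d2/d1) / d2.
    """
    lam_grid = np.asarray(list(lam_grid), dtype=float)
    if lam_grid.size == 0:
        raise ValueError("lam_grid must be non-empty")
    if np.any(lam_grid < 0):
        raise ValueError("lam_grid entries must be >= 0")
    rows = []
    for lam in lam_grid:
        p = ScanParams(alpha=params.alpha, v=params.v, lam=float(lam),
                       eta=params.eta)
        out = reinit_probabilities(p, layout)
        rows.append((float(lam), out.p_uorf4, out.p_gcn4))
    return pd.DataFrame(rows, columns=["lam", "p_uorf4", "p_gcn4"])


def _auto_max_time(params: ScanParams, layout: UtrLayout,
                   cfg: LatticeConfig) -> float:
    # ~10x the expected wall time: entries are ~Poisson(alpha) apart and a
    # scanner resides O(L/v + dwell) seconds
    entry = (cfg.n_replicates + 10) / max(params.alpha, 1e-300)
    residence = layout.gcn4_start / params.v + 10.0 * cfg.uorf_dwell
    return 10.0 * (entry + residence)


def simulate_tasep(params: ScanParams, layout: UtrLayout,
                   cfg: LatticeConfig) -> SimResult:
    """Continuous-time Monte Carlo of the exclusion scanning model.

    Runs until ``cfg.n_replicates`` scanners reach a terminal fate and
    reports empirical fate probabilities with binomial standard errors,
    time-averaged occupancy moments, the realized GCN4 flux and the mean
    residence time of completed scanners.  Reproducible given ``cfg.seed``.
    """
    if params.alpha == 0:
        # nothing ever loads: an empty lattice observed for max_time
        t = cfg.max_time if cfg.max_time is not None else 1e4
        return SimResult(outcome_counts={n: 0 for n in FATE_NAMES},
                         probabilities={n: 0.0 for n in FATE_NAMES},
                         se_estimates={n: 0.0 for n in FATE_NAMES},
                         mean_occupancy=0.0, occupancy_variance=0.0,
                         flux_gcn4=0.0, total_time=t, n_completed=0,
                         n_entered=0, mean_residence_time=0.0, seed=cfg.seed)
    max_time = cfg.max_time if cfg.max_time is not None else \
        _auto_max_time(params, layout, cfg)
    p_bind = -math.expm1(-params.lam / params.v)
    dwell_rate = 1.0 / cfg.uorf_dwell if cfg.uorf_dwell > 0 else 1e12
    counts, occ_int, occ2_int, t, completed, entered, resid_sum, status = \
        run_tasep(params.alpha, params.v, p_bind, params.eta,
                  layout.uorf1_start, layout.uorf1_stop, layout.uorf4_start,
                  layout.gcn4_start, cfg.footprint, dwell_rate,
                  max_time, cfg.n_replicates, cfg.seed % 2**31)
    if status == STATUS_TIME_EXCEEDED:
        raise UnderSampledError(
            f"max_time={max_time:g}s elapsed after only {completed} of "
            f"{cfg.n_replicates} scanners completed; increase max_time")
    if status == STATUS_OVERFLOW:
        raise RuntimeError("scanner capacity exceeded (pathological jam)")

    n = int(completed)
    probs = {name: counts[i] / n for i, name in enumerate(FATE_NAMES)}
    se = {name: math.sqrt(p * (1.0 - p) / n) for name, p in probs.items()}
    mean_occ = occ_int / t
    var_occ = occ2_int / t - mean_occ**2
    return SimResult(
        outcome_counts={name: int(counts[i])
                        for i, name in enumerate(FATE_NAMES)},
        probabilities=probs,
        se_estimates=se,
        mean_occupancy=mean_occ,
        occupancy_variance=max(var_occ, 0.0),
        flux_gcn4=counts[2] / t,
        total_time=t,
        n_completed=n,
        n_entered=int(entered),
        mean_residence_time=resid_sum / n,
        seed=cfg.seed,
    )


def occupancy_stats(result: SimResult) -> dict[str, float]:
    """Time-averaged moments of the concurrent scanner count."""
    if result.total_time <= 0:
        raise ValueError("occupancy_stats requires a completed simulation")
    return {"mean": result.mean_occupancy,
            "variance": result.occupancy_variance}
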