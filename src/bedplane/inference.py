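"""Monte-Carlo envelopes and the DCLF goodness-of-fit test.

The DCLF statistic for curve i (observed or simulated) is

    u_i = Σ_k ( H_i(r_k) − H̄_{(−i)}(r_k) )² Δr,

where H̄_{(−i)} is the mean of all *other* curves, so the observed
pattern is treated symmetrically with the simulations.  The Monte-Carlo
p-value is (1 + #{u_sim ≥ u_obs}) / (n_sim + 1); ties count toward the
"≥" set.  With n_sim = 99 the smallest attainable p is 0.01.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .models import FittedModel, simulate_model, _spec_of
from .pattern_core import PointPattern
from .summaries import default_r_grid, k_translation, l_from_k, pair_correlation

__all__ = ["EnvelopeResult", "GofTestResult", "mc_envelope", "dclf_test"]

log = logging.getLogger(__name__)

_RETRY_CAP = 50


@dataclass
class EnvelopeResult:
    r: np.ndarray
    observed: np.ndarray
    sim_mean: np.ndarray
    lower: np.ndarray       # pointwise minimum of the simulations
    upper: np.ndarray       # pointwise maximum
    n_sim: int
    statistic: str
    model: str
    seed: int | None = None

    def observed_inside(self) -> bool:
        """True if the observed curve lies inside [lower, upper] everywhere."""
        return bool(np.all((self.observed >= self.lower)
                           & (self.observed <= self.upper)))

    def to_json(self) -> dict:
        return {
            "statistic": self.statistic, "model": self.model,
            "n_sim": self.n_sim, "seed": self.seed,
            "r": self.r.tolist(), "observed": self.observed.tolist(),
            "mean": self.sim_mean.tolist(),
            "lower": self.lower.tolist(), "upper": self.upper.tolist(),
        }

    def plot(self, path=None, ax=None):
        """Observed curve, CSR-style reference (simulation mean) and band."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(self.r, self.lower, self.upper, alpha=0.3,
                        color="grey", label=f"envelope (n={self.n_sim})")
        ax.plot(self.r, self.sim_mean, "k--", label="simulation mean")
        ax.plot(self.r, self.observed, "k-", label="observed")
        ax.set_xlabel("r (m)")
        ax.set_ylabel(self.statistic)
        ax.legend()
        ax.set_title(self.model)
        if path is not None:
            ax.figure.savefig(path, bbox_inches="tight")
            plt.close(ax.figure)
        return ax


@dataclass
class GofTestResult:
    u_observed: float
    u_simulated: np.ndarray
    p_value: float
    n_sim: int
    statistic: str
    r_range: tuple[float, float]
    seed: int | None = None

    def to_json(self) -> dict:
        return {
            "u_observed": self.u_observed,
            "u_simulated": list(map(float, self.u_simulated)),
            "p_value": self.p_value, "n_sim": self.n_sim,
            "statistic": self.statistic, "r_range": list(self.r_range),
            "seed": self.seed,
        }


def _summary_curve(pattern: PointPattern, statistic: str, r: np.ndarray,
                   pcf_bandwidth: float | None = None) -> np.ndarray:
    if statistic == "K":
        return k_translation(pattern, r).values
    if statistic == "L":
        return l_from_k(k_translation(pattern, r)).values
    if statistic == "g":
        return pair_correlation(pattern, r, bandwidth=pcf_bandwidth).values
    raise ValueError(f"unknown statistic {statistic!r}")


def _simulate_curves(pattern: PointPattern, model, statistic: str,
                     n_sim: int, r: np.ndarray, seed,
                     pcf_bandwidth: float | None):
    """n_sim summary curves from the model; degenerate draws are resampled."""
    spec = _spec_of(model)
    ss = np.random.SeedSequence(seed)
    curves = np.empty((n_sim, len(r)))
    for i in range(n_sim):
        for attempt in range(_RETRY_CAP):
            sim = simulate_model(spec, pattern.window,
                                 seed=np.random.default_rng(ss.spawn(1)[0]))
            if sim.n >= 2:
                break
            log.info("simulation with n < 2 resampled (attempt %d)", attempt + 1)
        else:
            raise RuntimeError(
                f"model produced {_RETRY_CAP} consecutive degenerate patterns")
        curves[i] = _summary_curve(sim, statistic, r, pcf_bandwidth)
    return curves


def _model_label(model) -> str:
    spec = _spec_of(model)
    return type(spec).__name__


def mc_envelope(pattern: PointPattern, model, statistic: str = "L",
                n_sim: int = 99, seed: int | None = None,
                r: np.ndarray | None = None,
                pcf_bandwidth: float | None = None) -> EnvelopeResult:
    """Pointwise min/mean/max envelope of ``n_sim`` simulated summaries."""
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if statistic not in ("L", "g"):
        raise ValueError("envelope statistic must be 'L' or 'g'")
    if r is None:
        r = default_r_grid(pattern.window)
    if statistic == "g" and pcf_bandwidth is None:
        # use the observed pattern's bandwidth for all curves
        from .summaries import stoyan_bandwidth
        pcf_bandwidth = stoyan_bandwidth(pattern)
    observed = _summary_curve(pattern, statistic, r, pcf_bandwidth)
    curves = _simulate_curves(pattern, model, statistic, n_sim, r, seed,
                              pcf_bandwidth)
    return EnvelopeResult(r=r, observed=observed, sim_mean=curves.mean(axis=0),
                          lower=curves.min(axis=0), upper=curves.max(axis=0),
                          n_sim=n_sim, statistic=statistic,
                          model=_model_label(model), seed=seed)


def dclf_test(pattern: PointPattern, model, statistic: str = "L",
              n_sim: int = 99, r_range: tuple[float, float] | None = None,
              seed: int | None = None, r: np.ndarray | None = None,
              pcf_bandwidth: float | None = None) -> GofTestResult:
    """Monte-Carlo DCLF goodness-of-fit test of ``model`` for ``pattern``."""
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if statistic not in ("K", "L", "g"):
        raise ValueError("statistic must be 'K', 'L' or 'g'")
    if r is None:
        r = default_r_grid(pattern.window)
    if statistic == "g" and pcf_bandwidth is None:
        from .summaries import stoyan_bandwidth
        pcf_bandwidth = stoyan_bandwidth(pattern)

    observed = _summary_curve(pattern, statistic, r, pcf_bandwidth)
    curves = _simulate_curves(pattern, model, statistic, n_sim, r, seed,
                              pcf_bandwidth)
    if r_range is not None:
        # curves are estimated on the full grid (K/L are cumulative from 0);
        # only the integration of the deviation is restricted
        keep = (r >= r_range[0]) & (r <= r_range[1])
        if keep.sum() < 2:
            raise ValueError("r_range leaves fewer than 2 grid points")
        r = r[keep]
        observed = observed[keep]
        curves = curves[:, keep]
    allc = np.vstack([observed, curves])          # row 0 = observed
    m = len(allc)
    dr = float(r[1] - r[0])
    total = allc.sum(axis=0)
    u = np.empty(m)
    for i in range(m):
        loo_mean = (total - allc[i]) / (m - 1)
        u[i] = float(((allc[i] - loo_mean) ** 2).sum() * dr)
    u_obs, u_sim = u[0], u[1:]
    p = (1.0 + np.count_nonzero(u_sim >= u_obs)) / (n_sim + 1.0)
    return GofTestResult(u_observed=float(u_obs), u_simulated=u_sim,
                         p_value=float(p), n_sim=n_sim, statistic=statistic,
                         r_range=(float(r[0]), float(r[-1])), seed=seed)
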