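"""Circular statistics for shell-orientation data.

Angles are stored in degrees and computed in radians.  The "angular
standard deviation" is the circular standard deviation
v = sqrt(−2 ln R̄) (in degrees), which is the definition consistent with
the summary values this package reports (R̄ = 0.18 ↦ v = 106°), not the
alternative sqrt(2 (1 − R̄)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CircularSummary",
    "KuiperResult",
    "circular_summary",
    "angular_std_deg",
    "kuiper_test",
    "rose_diagram",
]


@dataclass
class CircularSummary:
    n: int
    resultant_length: float     # R̄ in [0, 1]
    mean_direction_deg: float   # θ̄ in [0, 360); NaN when R̄ = 0
    angular_std_deg: float      # v; NaN (undefined) when R̄ = 0

    @property
    def undefined_direction(self) -> bool:
        return self.resultant_length == 0.0


@dataclass
class KuiperResult:
    V: float
    V_star: float
    p_value: float
    n: int


def angular_std_deg(resultant_length: float) -> float:
    """Circular standard deviation sqrt(−2 ln R̄), converted to degrees."""
    if not 0.0 <= resultant_length <= 1.0:
        raise ValueError("mean resultant length must lie in [0, 1]")
    if resultant_length == 0.0:
        return float("nan")
    return float(np.degrees(np.sqrt(-2.0 * np.log(resultant_length))))


def circular_summary(angles_deg) -> CircularSummary:
    """Mean resultant length, mean direction and angular SD of a sample."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("need at least one angle")
    C = np.cos(a).mean()
    S = np.sin(a).mean()
    R = float(np.hypot(C, S))
    R = min(R, 1.0)  # guard rounding just above 1
    if R == 0.0:
        theta = float("nan")
    else:
        theta = float(np.degrees(np.arctan2(S, C)) % 360.0)
    return CircularSummary(n=a.size, resultant_length=R,
                           mean_direction_deg=theta,
                           angular_std_deg=angular_std_deg(R))


def _kuiper_p(v_star: float, max_terms: int = 100, tol: float = 1e-10) -> float:
    """Asymptotic upper tail Σ_m 2 (4 m² V*² − 1) exp(−2 m² V*²)."""
    p = 0.0
    for m in range(1, max_terms + 1):
        term = 2.0 * (4.0 * m ** 2 * v_star ** 2 - 1.0) * np.exp(-2.0 * m ** 2 * v_star ** 2)
        p += term
        # the m = 1 term vanishes at V* = 0.5; never stop on it
        if m > 1 and abs(term) < tol:
            break
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


def kuiper_test(angles_deg) -> KuiperResult:
    """Kuiper's V_n test of circular uniformity with the finite-sample
    modification V* = V (√n + 0.155 + 0.24/√n).

    The statistic is invariant under rotation of all angles by a common
    offset.  A sample of identical angles yields an effectively zero
    p-value (no error is raised).
    """
    a = np.asarray(angles_deg, dtype=float) % 360.0
    n = a.size
    if n < 5:
        raise ValueError("Kuiper test requires at least 5 angles")
    u = np.sort(a / 360.0)
    i = np.arange(1, n + 1)
    d_plus = float(np.max(i / n - u))
    d_minus = float(np.max(u - (i - 1) / n))
    V = d_plus + d_minus
    v_star = V * (np.sqrt(n) + 0.155 + 0.24 / np.sqrt(n))
    return KuiperResult(V=float(V), V_star=float(v_star),
                        p_value=_kuiper_p(v_star), n=n)


def rose_diagram(angles_deg, path=None, bin_width_deg: float = 10.0, ax=None):
    """Optional rose-diagram plot (counts per angular bin)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    a = np.asarray(angles_deg, dtype=float) % 360.0
    edges = np.arange(0.0, 360.0 + bin_width_deg, bin_width_deg)
    counts, _ = np.histogram(a, bins=edges)
    if ax is None:
        fig = plt.figure()
        ax = fig.add_subplot(projection="polar")
    centres = np.radians(edges[:-1] + bin_width_deg / 2.0)
    ax.bar(centres, counts, width=np.radians(bin_width_deg),
           edgecolor="black", alpha=0.7)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
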