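"""Mono-exponential dissociation-rate estimation from contact durations.

For Markovian unbinding, contact durations are exponentially distributed
and the histogram of durations decays as N(t) = A exp(-k_off t).  k_off is
estimated by weighted nonlinear least squares on that histogram, with a
case-resampling bootstrap confidence interval and a closed-form cross-check
(the maximum-likelihood exponential rate 1 / mean duration).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .contacts import DurationProfile

__all__ = [
    "KineticFit",
    "TooFewEventsError",
    "DegenerateDurationsError",
    "fit_koff",
    "site_koff",
]


class TooFewEventsError(ValueError):
    """Fewer uncensored durations than the configured floor."""


class DegenerateDurationsError(ValueError):
    """All durations identical; the decay histogram is a single spike."""


@dataclass
class KineticFit:
    """Result of the mono-exponential fit N(t) = A exp(-k_off t)."""

    A: float
    k_off_per_us: float
    ci_per_us: tuple[float, float]
    n_events: int
    residual_norm: float
    rate_from_mean_per_us: float  # closed-form 1/mean cross-check
    bin_width_us: float

    def evaluate(self, t_us: np.ndarray | float) -> np.ndarray | float:
        """The fitted decay curve; equals A at t=0 by construction."""
        return self.A * np.exp(-self.k_off_per_us * np.asarray(t_us, dtype=float))


def _decay(t: np.ndarray, A: float, k: float) -> np.ndarray:
    return A * np.exp(-k * t)


def fit_koff(
    durations_ns: Sequence[float] | np.ndarray,
    bin_width_ns: float | None = None,
    density: str = "counts",
    min_events: int = 50,
    n_boot: int = 200,
    seed: int = 0,
) -> KineticFit:
    """Fit k_off from a sample of uncensored contact durations.

    A histogram (raw counts by default, ``density="pdf"`` for a normalized
    density) is built over the durations with bin width defaulting to
    max(duration)/30, and A exp(-k_off t) is fitted by weighted nonlinear
    least squares with Poisson (sqrt-count) weights.  The confidence
    interval is a percentile case-resampling bootstrap over the durations.

    Durations are supplied in ns; rates are reported in us^-1.
    """
    durations_us = np.asarray(durations_ns, dtype=float) * 1e-3
    n = len(durations_us)
    if n < min_events:
        raise TooFewEventsError(f"{n} durations < floor of {min_events}")
    if np.ptp(durations_us) == 0.0:
        raise DegenerateDurationsError("all durations identical")
    if bin_width_ns is None:
        bin_width_us = durations_us.max() / 30.0
    else:
        bin_width_us = bin_width_ns * 1e-3

    A, k, resid = _fit_histogram(durations_us, bin_width_us, density)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        sample = durations_us[rng.integers(0, n, size=n)]
        if np.ptp(sample) == 0.0:
            continue
        try:
            _, kb, _ = _fit_histogram(sample, bin_width_us, density)
        except RuntimeError:
            continue
        boots.append(kb)
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
        ci = (min(float(lo), k), max(float(hi), k))
    else:
        ci = (k, k)
    return KineticFit(
        A=A,
        k_off_per_us=k,
        ci_per_us=ci,
        n_events=n,
        residual_norm=resid,
        rate_from_mean_per_us=1.0 / durations_us.mean(),
        bin_width_us=bin_width_us,
    )


def _fit_histogram(
    durations_us: np.ndarray, bin_width_us: float, density: str
) -> tuple[float, float, float]:
    edges = np.arange(0.0, durations_us.max() + bin_width_us, bin_width_us)
    if len(edges) < 3:
        edges = np.linspace(0.0, durations_us.max(), 4)
    counts, edges = np.histogram(durations_us, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    y = counts.astype(float)
    if density == "pdf":
        y = y / (y.sum() * np.diff(edges))
    keep = counts > 0
    sigma = np.sqrt(np.maximum(counts[keep], 1.0))
    if density == "pdf":
        sigma = sigma / (counts[keep].sum() * np.diff(edges)[keep])
    k0 = 1.0 / durations_us.mean()
    popt, _ = curve_fit(
        _decay,
        centers[keep],
        y[keep],
        p0=(y[keep][0], k0),
        sigma=sigma,
        absolute_sigma=True,
        maxfev=10000,
        bounds=((0.0, 1e-9), (np.inf, np.inf)),
    )
    resid = float(np.linalg.norm(y[keep] - _decay(centers[keep], *popt)))
    return float(popt[0]), float(popt[1]), resid


def site_koff(
    profile: DurationProfile,
    site_residues: Sequence[int],
    species: str | None = None,
    top_n: int = 1,
    **fit_kwargs,
) -> KineticFit:
    """k_off of a binding site from its strongest-interacting residue(s).

    Within the site, the ``top_n`` residues with the largest mean contact
    duration (for the given species, or pooled over species) are selected
    and their duration samples pooled for the mono-exponential fit.
    """
    site_residues = list(site_residues)
    if not site_residues:
        raise ValueError("site residue set is empty")
    sub = profile.table[profile.table.residue_id.isin(site_residues)]
    if species is not None:
        sub = sub[sub.species == species]
    sub = sub[sub.n_events > 0]
    if sub.empty:
        raise ValueError("site has zero contact events")
    ranked = sub.sort_values("mean_duration_ns", ascending=False)
    chosen = ranked.head(top_n)[["residue_id", "species"]].itertuples(index=False)
    pooled = np.concatenate(
        [profile.durations[(int(rid), sp)] for rid, sp in chosen]
    )
    return fit_koff(pooled, **fit_kwargs)
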