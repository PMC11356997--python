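"""The three observables: MSD diffusion fit, first-passage survival, exit angles.

* ``compute_msd`` / ``fit_diffusion``: ensemble mean squared displacement of
  the particle center from its starting point, fitted as
  ``msd(t) = 2 D t**alpha`` (log-log ordinary least squares) over
  ``[0.01 * tmin, tmin]`` where ``tmin`` is the minimal observed
  first-passage time — the window where every trajectory still contributes
  and neither boundary distorts the curve.  ``alpha = 1`` is normal
  diffusion; smaller / larger is sub- / superdiffusion.
* ``survival_curve`` / ``fit_lambda``: Kaplan-Meier estimate of the fraction
  S(t) of particles still inside the channel, and a least-squares fit of its
  exponential tail ``S(t) ~ A exp(-lambda t)``.
* ``angle_distribution`` / ``angle_sigma``: histogram of the exit angle
  theta between the particle axis and the channel axis, reweighted by the
  sphere measure (each bin divided by its integral of sin theta) so that an
  isotropically oriented particle gives a flat density on [0, pi]; the
  orientation spread is summarized by the second moment
  ``sigma = sqrt(int theta^2 p(theta) dtheta)``, which equals
  ``pi / sqrt(3) ~ 1.814`` for the flat density.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from lifelines import KaplanMeierFitter

from .dynamics import EnsembleResult

UNIFORM_SIGMA = math.pi / math.sqrt(3.0)


# ---------------------------------------------------------------------------
# mean squared displacement
# ---------------------------------------------------------------------------

@dataclass
class MsdCurve:
    t: np.ndarray        #: step-count grid (record-stride multiples, includes 0)
    msd: np.ndarray      #: mean |x(t) - x(0)|^2 over trajectories still inside
    n_alive: np.ndarray  #: number of trajectories contributing at each t


@dataclass
class DiffusionFit:
    D: float
    alpha: float
    window: tuple[float, float]
    n_points: int
    rms_log_residual: float


def compute_msd(ensemble: EnsembleResult, t_max: Optional[int] = None) -> MsdCurve:
    """Ensemble MSD on the recording grid.

    Trajectories start at the origin, so the squared displacement is simply
    |x(t)|^2.  A trajectory contributes at time t only while it is still in
    the channel; ``n_alive`` records the attrition so fits can be restricted
    to the fully populated window.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    stride = ensemble.config.record_stride
    n_grid = max(tr.positions.shape[0] for tr in ensemble.trajectories)
    if t_max is not None:
        n_grid = min(n_grid, t_max // stride + 1)
    total = np.zeros(n_grid)
    alive = np.zeros(n_grid, dtype=np.int64)
    for tr in ensemble.trajectories:
        pos = tr.positions
        k = min(pos.shape[0], n_grid)
        sq = pos[:k, 1] ** 2 + pos[:k, 2] ** 2 + pos[:k, 3] ** 2
        total[:k] += sq
        alive[:k] += 1
    msd = np.divide(total, alive, out=np.zeros(n_grid), where=alive > 0)
    t = np.arange(n_grid, dtype=np.int64) * stride
    return MsdCurve(t=t, msd=msd, n_alive=alive)


def fit_diffusion(curve: MsdCurve, tmin: int) -> DiffusionFit:
    """Fit ``log msd = log(2 D) + alpha log t`` over ``[0.01 * tmin, tmin]``."""
    lo, hi = 0.01 * tmin, float(tmin)
    sel = (curve.t >= lo) & (curve.t <= hi) & (curve.t > 0) & (curve.msd > 0)
    if sel.sum() < 5:
        raise ValueError(
            f"fit window [{lo:g}, {hi:g}] contains {int(sel.sum())} grid points (< 5)"
        )
    x = np.log(curve.t[sel].astype(float))
    y = np.log(curve.msd[sel])
    alpha, intercept = np.polyfit(x, y, 1)
    resid = y - (alpha * x + intercept)
    return DiffusionFit(
        D=0.5 * math.exp(intercept),
        alpha=float(alpha),
        window=(lo, hi),
        n_points=int(sel.sum()),
        rms_log_residual=float(np.sqrt(np.mean(resid**2))),
    )


# ---------------------------------------------------------------------------
# first-passage survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    t: np.ndarray   #: event-time grid, starting at 0
    S: np.ndarray   #: Kaplan-Meier survival estimate, S(0) == 1
    samples: Optional[np.ndarray] = None  #: uncensored FPT samples, if known
    n_censored: int = 0


@dataclass
class SurvivalFit:
    lambda_: float      #: tail decay rate, 1/steps
    A: float            #: tail prefactor
    median_fpt: float   #: median of the uncensored first-passage times
    tail_window: tuple[float, float]
    n_points: int


def survival_curve(durations: np.ndarray, events: Optional[np.ndarray] = None) -> SurvivalCurve:
    """Kaplan-Meier estimate of S(t) from (possibly right-censored) samples.

    With no censoring this reduces to ``1 - ECDF``.
    """
    durations = np.asarray(durations, dtype=float)
    if events is None:
        events = np.ones(durations.shape, dtype=bool)
    events = np.asarray(events, dtype=bool)
    if durations.size == 0 or not events.any():
        raise ValueError("survival estimate needs at least one uncensored sample")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    sf = kmf.survival_function_
    return SurvivalCurve(
        t=sf.index.to_numpy(dtype=float),
        S=sf.iloc[:, 0].to_numpy(dtype=float),
        samples=durations[events],
        n_censored=int((~events).sum()),
    )


def survival_from_ensemble(ensemble: EnsembleResult) -> SurvivalCurve:
    durations, events = ensemble.durations_events()
    return survival_curve(durations, events)


def fit_lambda(curve: SurvivalCurve, tail_start: Optional[float] = None,
               trim_frac: float = 0.01) -> SurvivalFit:
    """Exponential-tail fit ``log S(t) = log A - lambda t``.

    The tail window defaults to ``t > median FPT``; the last ``trim_frac`` of
    the grid points (where the estimate jumps between its last few values)
    and any points with ``S <= 0`` are excluded.
    """
    if curve.samples is not None and curve.samples.size:
        median = float(np.median(curve.samples))
    else:
        below = curve.t[curve.S <= 0.5]
        if below.size == 0:
            raise ValueError("survival curve never reaches 0.5: cannot set tail window")
        median = float(below[0])
    if tail_start is None:
        tail_start = median
    n_trim = max(1, int(math.ceil(trim_frac * curve.t.size)))
    t = curve.t[:-n_trim]
    S = curve.S[:-n_trim]
    sel = (t > tail_start) & (S > 0)
    if sel.sum() < 10:
        raise ValueError(f"exponential tail window has {int(sel.sum())} points (< 10)")
    slope, intercept = np.polyfit(t[sel], np.log(S[sel]), 1)
    return SurvivalFit(
        lambda_=-float(slope),
        A=float(math.exp(intercept)),
        median_fpt=median,
        tail_window=(float(t[sel].min()), float(t[sel].max())),
        n_points=int(sel.sum()),
    )


# ---------------------------------------------------------------------------
# exit-orientation statistics
# ---------------------------------------------------------------------------

@dataclass
class AngleSummary:
    bin_edges: np.ndarray  #: n_bins + 1 edges on [0, pi]
    p_theta: np.ndarray    #: sphere-measure-reweighted density, integrates to 1
    p_raw: np.ndarray      #: plain histogram density, integrates to 1
    n_samples: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def angle_distribution(exit_thetas: np.ndarray, n_bins: int = 36) -> AngleSummary:
    """Sphere-measure-reweighted density of exit angles on [0, pi].

    Each bin count is divided by the exact bin integral of sin(theta)
    (the solid-angle weight of that polar band), so isotropic orientations
    yield a flat density 1/pi; the result is then normalized to unit integral.
    Using the exact integral rather than sin(bin center) keeps the end bins
    at theta ~ 0, pi well behaved.
    """
    thetas = np.asarray(exit_thetas, dtype=float)
    if thetas.size == 0:
        raise ValueError("no exit angles to histogram")
    counts, edges = np.histogram(thetas, bins=n_bins, range=(0.0, math.pi))
    widths = np.diff(edges)
    sin_weight = np.cos(edges[:-1]) - np.cos(edges[1:])  # int_bin sin(theta) dtheta
    dens = counts / sin_weight
    p = dens / np.sum(dens * widths)
    p_raw = counts / (counts.sum() * widths)
    return AngleSummary(bin_edges=edges, p_theta=p, p_raw=p_raw, n_samples=int(thetas.size))


def uniform_orientation_density(n_bins: int = 360) -> AngleSummary:
    """The exact flat density p(theta) = 1/pi on a histogram grid (the
    orientation distribution of an isotropically oriented particle)."""
    edges = np.linspace(0.0, math.pi, n_bins + 1)
    p = np.full(n_bins, 1.0 / math.pi)
    return AngleSummary(bin_edges=edges, p_theta=p, p_raw=p.copy(), n_samples=0)


def angle_sigma(summary: AngleSummary) -> float:
    """Second-moment spread sqrt(int theta^2 p(theta) dtheta), by midpoint
    quadrature on the histogram.  Flat density -> pi/sqrt(3) ~ 1.814."""
    widths = np.diff(summary.bin_edges)
    c = summary.bin_centers
    return float(np.sqrt(np.sum(c * c * summary.p_theta * widths)))


# ---------------------------------------------------------------------------
# one-shot ensemble summary
# ---------------------------------------------------------------------------

def summarize(ensemble: EnsembleResult, n_bins: int = 36) -> dict:
    """All five observables (D, alpha, lambda, median FPT, sigma_theta) for
    one ensemble, as written to ``fits.json`` by the CLI."""
    fpt = ensemble.fpt_steps
    if (fpt >= 0).sum() < 2:
        raise ValueError("insufficient ensemble: need >= 2 uncensored trajectories")
    tmin = ensemble.tmin
    curve = compute_msd(ensemble)
    dfit = fit_diffusion(curve, tmin)
    sfit = fit_lambda(survival_from_ensemble(ensemble))
    asum = angle_distribution(ensemble.exit_thetas, n_bins=n_bins)
    return {
        "D": dfit.D,
        "alpha": dfit.alpha,
        "msd_window": list(dfit.window),
        "lambda": sfit.lambda_,
        "median_fpt": sfit.median_fpt,
        "tail_window": list(sfit.tail_window),
        "sigma_theta": angle_sigma(asum),
        "tmin": tmin,
        "n_traj": len(ensemble),
        "n_censored": ensemble.n_censored,
    }
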