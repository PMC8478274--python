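"""Equilibrium analysis: heat capacity, T_m, WHAM and F(Q) profiles.

All quantities are in reduced units (energies in units of the contact
well depth, Boltzmann constant = 1).  The heat capacity at a sampled
temperature follows from the energy fluctuations,

    Cv* = (<E*^2> - <E*>^2) / T*^2,

and the melting temperature T_m is the absolute maximum of the Cv*
curve.  The weighted histogram analysis method (WHAM) combines the
energy histograms of every rung of the parallel-tempering ladder into
one density of states, which is then reweighted to any temperature to
produce free-energy profiles F*(Q) along the folding coordinate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .engine import EnergyTrace

logger = logging.getLogger(__name__)

__all__ = [
    "CvCurve",
    "WhamResult",
    "FreeEnergyProfile",
    "heat_capacity",
    "cv_curve",
    "melting_temperature",
    "pool_runs",
    "wham",
    "reweighted_mean_energy",
    "free_energy_profile",
]


@dataclass
class CvCurve:
    temperatures: np.ndarray
    cv: np.ndarray
    errors: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        if len(self.errors) == 0:
            self.errors = np.zeros_like(self.cv)
        if not (len(self.temperatures) == len(self.cv) == len(self.errors)):
            raise ValueError("grid length mismatch")
        if (self.errors < 0).any():
            raise ValueError("errors must be non-negative")


@dataclass
class WhamResult:
    """Self-consistent multi-histogram solution.

    ``log_dos`` is the log density of states on the energy-bin grid
    (arbitrary additive constant); ``log_normalizers`` are the per-
    temperature log partition-function estimates f_k = -ln Z_k used in
    sample reweighting.
    """

    bin_edges: np.ndarray
    log_dos: np.ndarray
    temperatures: np.ndarray
    log_normalizers: np.ndarray
    n_samples: np.ndarray
    n_iterations: int
    converged: bool
    min_adjacent_overlap: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class FreeEnergyProfile:
    q_centers: np.ndarray
    f: np.ndarray                 # reduced free energy, min = 0; NaN in empty bins
    temperature: float
    empty_bins: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


def heat_capacity(trace: EnergyTrace) -> float:
    """Reduced heat capacity from energy fluctuations at one temperature."""
    if len(trace) < 2:
        raise ValueError("need at least 2 energy samples")
    e = trace.energies
    return float(e.var() / trace.temperature**2)


def cv_curve(traces_by_run: list[list[EnergyTrace]]) -> CvCurve:
    """Cv* over the ladder, averaged over independent runs.

    Errors are standard errors of the mean across runs (zero for a
    single run).
    """
    if not traces_by_run:
        raise ValueError("no traces")
    temps = np.array([t.temperature for t in traces_by_run[0]])
    vals = np.array([[heat_capacity(t) for t in run] for run in traces_by_run])
    mean = vals.mean(axis=0)
    if len(traces_by_run) > 1:
        err = vals.std(axis=0, ddof=1) / np.sqrt(len(traces_by_run))
    else:
        err = np.zeros_like(mean)
    return CvCurve(temperatures=temps, cv=mean, errors=err)


def melting_temperature(curve: CvCurve) -> float:
    """T* of the absolute Cv* maximum, parabolically refined.

    The peak must be interior to the grid; a monotone curve (maximum at
    either edge) indicates the ladder does not bracket the transition
    and raises.  Ties resolve to the lower-temperature peak.
    """
    t, cv = curve.temperatures, curve.cv
    if len(t) < 3:
        raise ValueError("need at least 3 grid points")
    k = int(np.argmax(cv))  # argmax returns the first (lowest-T) maximum
    if (cv == cv[k]).sum() > 1:
        warnings.warn("duplicate Cv maxima; returning the lower-temperature peak")
    if k == 0 or k == len(t) - 1:
        raise ValueError(
            "heat capacity maximum at the grid edge: no interior peak "
            "(non-two-state behaviour or ladder does not span the transition)"
        )
    # parabola through (t[k-1..k+1], cv[k-1..k+1])
    x0, x1, x2 = t[k - 1], t[k], t[k + 1]
    y0, y1, y2 = cv[k - 1], cv[k], cv[k + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a >= 0:
        return float(x1)
    return float(-b / (2 * a))


def _histogram_counts(traces: list[EnergyTrace], edges: np.ndarray) -> np.ndarray:
    h = np.zeros((len(traces), len(edges) - 1))
    for k, tr in enumerate(traces):
        h[k], _ = np.histogram(tr.energies, bins=edges)
    return h


def wham(
    traces: list[EnergyTrace],
    bin_width: float = 1.0,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> WhamResult:
    """Standard multi-histogram WHAM over the sampled ladder.

    Solves self-consistently for the log density of states g(E) and the
    per-temperature log normalizers f_k:

        g(E) = ln sum_k H_k(E) - ln sum_k N_k exp(f_k - E/T_k)
        f_k  = -ln sum_E exp(g(E) - E/T_k)

    Iteration stops when the max change of the f_k drops below ``tol``.
    Adjacent-temperature histogram overlap is diagnosed; zero overlap
    between neighbouring rungs makes the solution ill-posed and raises.
    """
    if not traces:
        raise ValueError("no traces given")
    traces = sorted(traces, key=lambda tr: tr.temperature)
    temps = np.array([tr.temperature for tr in traces])
    all_e = np.concatenate([tr.energies for tr in traces])
    if len(all_e) == 0:
        raise ValueError("traces carry no samples")
    lo = np.floor(all_e.min() / bin_width) * bin_width
    hi = np.ceil(all_e.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    h = _histogram_counts(traces, edges)
    n_k = h.sum(axis=1)
    occupied = h.sum(axis=0) > 0

    min_overlap = np.inf
    for k in range(len(traces) - 1):
        both = ((h[k] > 0) & (h[k + 1] > 0)).sum()
        frac = both / max(1, (h[k] > 0).sum())
        min_overlap = min(min_overlap, frac)
        if both == 0:
            raise ValueError(
                f"no energy-histogram overlap between T*={temps[k]:.4g} and "
                f"T*={temps[k + 1]:.4g}; densify the ladder"
            )

    centers = 0.5 * (edges[:-1] + edges[1:])
    beta = 1.0 / temps
    log_h_tot = np.where(occupied, np.log(np.maximum(h.sum(axis=0), 1e-300)), -np.inf)
    log_nk = np.log(n_k)
    f = np.zeros(len(traces))
    converged = False
    it = 0
    be = np.outer(beta, centers)               # (K, B)
    for it in range(1, int(max_iter) + 1):
        # g(E_b) = log_h_tot - logsumexp_k(log N_k + f_k - beta_k E_b)
        denom = logsumexp(log_nk[:, None] + f[:, None] - be, axis=0)
        g = log_h_tot - denom
        g = np.where(occupied, g, -np.inf)
        f_new = -logsumexp(g[None, :] - be, axis=1)
        f_new = f_new - f_new[0]
        delta = np.nanmax(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("WHAM did not converge in %d iterations (delta=%.3g)", it, delta)
    return WhamResult(
        bin_edges=edges,
        log_dos=g,
        temperatures=temps,
        log_normalizers=f,
        n_samples=n_k,
        n_iterations=it,
        converged=converged,
        min_adjacent_overlap=float(min_overlap),
    )


def _sample_log_weights(w: WhamResult, traces: list[EnergyTrace], t: float):
    """Per-sample log weights at target temperature t (WHAM reweighting)."""
    traces = sorted(traces, key=lambda tr: tr.temperature)
    temps = np.array([tr.temperature for tr in traces])
    if not np.allclose(temps, w.temperatures):
        raise ValueError("traces do not match the WHAM ladder")
    e = np.concatenate([tr.energies for tr in traces])
    log_nk = np.log(w.n_samples)
    beta = 1.0 / temps
    # log denominator: ln sum_k N_k exp(f_k - beta_k E_n)
    log_den = logsumexp(
        log_nk[:, None] + w.log_normalizers[:, None] - np.outer(beta, e), axis=0
    )
    logw = -e / t - log_den
    return e, logw


def pool_runs(traces_by_run: list[list[EnergyTrace]]) -> list[EnergyTrace]:
    """Concatenate per-temperature traces over independent runs.

    Independent repetitions sample the same equilibrium distribution,
    so their histograms add; pooling before WHAM averages out the slow
    basin-flipping noise of any single run.
    """
    if not traces_by_run:
        raise ValueError("no runs")
    n_t = len(traces_by_run[0])
    pooled = []
    for k in range(n_t):
        ts = [run[k] for run in traces_by_run]
        if len({t.temperature for t in ts}) != 1:
            raise ValueError("runs disagree on the temperature ladder")
        pooled.append(
            EnergyTrace(
                temperature=ts[0].temperature,
                cycles=np.concatenate([t.cycles for t in ts]),
                energies=np.concatenate([t.energies for t in ts]),
                q=np.concatenate([t.q for t in ts]),
                rmsd=np.concatenate([t.rmsd for t in ts]),
                thin=ts[0].thin,
            )
        )
    return pooled


def cv_from_wham(w: WhamResult, t_grid: np.ndarray) -> CvCurve:
    """Cv*(T*) on an arbitrary grid from the WHAM density of states.

    Moments of E at each target temperature follow from the density of
    states, so the fluctuation formula can be evaluated on a grid much
    finer than the sampled ladder — this is how the Cv peak (T_m) is
    located beyond the ladder resolution.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    e = w.bin_centers
    ok = np.isfinite(w.log_dos)
    g, e = w.log_dos[ok], e[ok]
    cv = np.empty(len(t_grid))
    for i, t in enumerate(t_grid):
        logp = g - e / t
        logp = logp - logsumexp(logp)
        pr = np.exp(logp)
        m1 = np.sum(pr * e)
        m2 = np.sum(pr * e * e)
        cv[i] = (m2 - m1 * m1) / t**2
    return CvCurve(temperatures=t_grid, cv=cv)


def reweighted_mean_energy(w: WhamResult, traces: list[EnergyTrace], t: float) -> float:
    """<E*> at temperature t from the WHAM weights."""
    e, logw = _sample_log_weights(w, traces, t)
    logw = logw - logsumexp(logw)
    return float(np.sum(np.exp(logw) * e))


def free_energy_profile(
    w: WhamResult,
    traces: list[EnergyTrace],
    t: float,
    q_bins: np.ndarray | int = 100,
) -> FreeEnergyProfile:
    """F*(Q) = -T* ln p(Q) at temperature t, minimum shifted to zero.

    Q is recorded jointly with E along the traces, so the reweighting
    is exact: each sample contributes its WHAM weight at ``t`` to its
    Q bin.  Bins without any sampled weight are flagged and carry NaN.
    """
    traces = sorted(traces, key=lambda tr: tr.temperature)
    q_all = np.concatenate([tr.q for tr in traces])
    _, logw = _sample_log_weights(w, traces, t)
    logw = logw - logsumexp(logw)
    if isinstance(q_bins, int):
        edges = np.linspace(0.0, 1.0, q_bins + 1)
    else:
        edges = np.asarray(q_bins, dtype=float)
    nb = len(edges) - 1
    idx = np.clip(np.digitize(q_all, edges) - 1, 0, nb - 1)
    weights = np.exp(logw)
    p = np.bincount(idx, weights=weights, minlength=nb)
    empty = p <= 0
    with np.errstate(divide="ignore"):
        fprof = -t * np.log(np.where(empty, np.nan, p))
    fprof = fprof - np.nanmin(fprof)
    if empty.any():
        logger.info("%d empty Q-bins in the reported range", int(empty.sum()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return FreeEnergyProfile(q_centers=centers, f=fprof, temperature=t, empty_bins=empty)
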