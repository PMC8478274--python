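"""First-passage folding kinetics at room temperature.

Trajectories start from unfolded conformations (drawn from the hottest
rungs of the thermodynamic run), evolve with local moves only at
T_r = 0.9 T_m, and stop at the first Monte Carlo cycle whose Cα RMSD
to the native structure drops below the folding threshold — the RMSD
value that frames 90% of the equilibrium conformations at T_r.  The
surviving (not-yet-folded) fraction 1 - P_N versus cycle number is the
kinetic observable; it is fitted with amplitude-weighted sums of
exponentials, with the number of components chosen by information
criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from . import _mc_core as core
from .contacts import ContactMap
from .model import Conformation, ModelParams

logger = logging.getLogger(__name__)

__all__ = [
    "FirstPassageRecord",
    "SurvivalCurve",
    "KineticFit",
    "folding_threshold",
    "folding_threshold_from_traces",
    "run_first_passage",
    "run_kinetics_ensemble",
    "survival_curve",
    "fit_kinetic_model",
    "population_histogram",
]


@dataclass
class FirstPassageRecord:
    trajectory_id: int
    seed: int
    cycles_to_fold: int            # >= 0, or -1 when censored at the cap
    censored: bool
    start_id: int = -1

    def __post_init__(self):
        if not self.censored and self.cycles_to_fold < 0:
            raise ValueError("uncensored record needs cycles_to_fold >= 0")


@dataclass
class SurvivalCurve:
    """Surviving fraction 1 - P_N on a (log-spaced) cycle grid."""

    grid: np.ndarray
    surviving: np.ndarray
    n_trajectories: int
    censored: int = 0

    def __post_init__(self):
        if np.any(np.diff(self.surviving) > 1e-12):
            raise ValueError("survival curve must be non-increasing")


@dataclass
class KineticFit:
    n_components: int
    rates: np.ndarray              # per-cycle rates, > 0
    amplitudes: np.ndarray         # sum to 1 together with the plateau
    plateau: float                 # censored/never-folding fraction
    chi2: float
    n_points: int
    aic: float
    scores: dict[int, float] = field(default_factory=dict)
    single_exponential_chi2: float = float("nan")

    def survival(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        s = np.full_like(t, self.plateau)
        for a, k in zip(self.amplitudes, self.rates):
            s = s + a * np.exp(-k * t)
        return s


def folding_threshold(rmsd_samples: np.ndarray, fraction: float = 0.9) -> float:
    """RMSD quantile framing ``fraction`` of the equilibrium conformations.

    Lower-tail quantile: ``fraction`` of the sampled conformations at
    T_r have RMSD at or below the returned value (usually ~1 Å for a
    folded native state).
    """
    rmsd_samples = np.asarray(rmsd_samples, dtype=float)
    if len(rmsd_samples) < 100:
        raise ValueError(f"need >= 100 equilibrium RMSD samples, got {len(rmsd_samples)}")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return float(rmsd_samples.max())
    return float(np.quantile(rmsd_samples, fraction))


def folding_threshold_from_traces(
    traces: list, t_r: float, fraction: float = 0.9
) -> float:
    """Folding threshold from the replica-exchange rung nearest T_r.

    Replica exchange keeps every rung in equilibrium (no trapping), so
    the RMSD distribution of the rung closest to the target room
    temperature is the natural source for the folding criterion.
    """
    if not traces:
        raise ValueError("no traces")
    best = min(traces, key=lambda tr: abs(tr.temperature - t_r))
    return folding_threshold(best.rmsd, fraction)


def run_first_passage(
    start: Conformation,
    cmap: ContactMap,
    params: ModelParams,
    native_ca: np.ndarray,
    threshold: float,
    t_r: float,
    cap: int,
    seed: int,
    max_angle: float = np.pi / 6,
    sample_every: int = 10,
    trajectory_id: int = 0,
    mirror_symmetric: bool = False,
) -> tuple[FirstPassageRecord, np.ndarray, np.ndarray]:
    """One local-move-only trajectory until RMSD <= threshold or the cap.

    With ``mirror_symmetric`` the folding RMSD is the minimum over the
    native reference and its mirror image: the two enantiomers are
    iso-energetic under a distance-only contact potential, so a chain
    folds into either with equal probability and the criterion treats
    them as one native basin.  Returns the first-passage record plus
    the (Q, RMSD) samples taken every ``sample_every`` cycles for
    population histograms.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    coords = start.coords.copy()
    dnat = cmap.dnat_matrix()
    ref = np.asarray(native_ca, dtype=float)
    cyc, qs, rs, ns = core.first_passage(
        coords, dnat, params.well_halfwidth_a, params.hardsphere_diameter,
        params.epsilon, t_r, max_angle, threshold, cap, sample_every,
        ref, ref * np.array([1.0, 1.0, -1.0]), mirror_symmetric, seed,
    )
    rec = FirstPassageRecord(
        trajectory_id=trajectory_id,
        seed=seed,
        cycles_to_fold=int(cyc),
        censored=cyc < 0,
    )
    return rec, qs[:ns].copy(), rs[:ns].copy()


def run_kinetics_ensemble(
    pool: list[np.ndarray],
    cmap: ContactMap,
    params: ModelParams,
    native_ca: np.ndarray,
    threshold: float,
    t_r: float,
    cap: int,
    n_trajectories: int = 200,
    seed: int = 0,
    max_angle: float = np.pi / 6,
    sample_every: int = 10,
    mirror_symmetric: bool = False,
) -> tuple[list[FirstPassageRecord], np.ndarray, np.ndarray]:
    """Ensemble of first-passage trajectories from an unfolded pool.

    Starting conformations cycle through the pool (each trajectory gets
    its own seed); returns all records plus pooled (Q, RMSD) samples.
    """
    if not pool:
        raise ValueError("empty starting pool")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1, np.uint64)[0] >> 1) or 1 for s in ss.spawn(n_trajectories)]
    records = []
    q_all: list[np.ndarray] = []
    r_all: list[np.ndarray] = []
    for k in range(n_trajectories):
        start = Conformation(pool[k % len(pool)].copy())
        rec, qs, rs = run_first_passage(
            start, cmap, params, native_ca, threshold, t_r, cap, seeds[k],
            max_angle=max_angle, sample_every=sample_every, trajectory_id=k,
            mirror_symmetric=mirror_symmetric,
        )
        rec.start_id = k % len(pool)
        records.append(rec)
        q_all.append(qs)
        r_all.append(rs)
    n_cens = sum(r.censored for r in records)
    if n_cens:
        logger.info("%d/%d trajectories censored at cap=%d", n_cens, n_trajectories, cap)
    return records, np.concatenate(q_all) if q_all else np.zeros(0), \
        np.concatenate(r_all) if r_all else np.zeros(0)


def survival_curve(
    records: list[FirstPassageRecord],
    grid: np.ndarray | None = None,
    n_grid: int = 60,
) -> SurvivalCurve:
    """Fraction of trajectories not yet folded at each grid cycle.

    Censored trajectories count as surviving through the cap.
    """
    if not records:
        raise ValueError("no first-passage records")
    times = np.array(
        [np.inf if r.censored else r.cycles_to_fold for r in records], dtype=float
    )
    if grid is None:
        finite = times[np.isfinite(times) & (times > 0)]
        hi = finite.max() if len(finite) else 1.0
        grid = np.unique(np.round(np.geomspace(1, max(hi, 2), n_grid))).astype(float)
    grid = np.asarray(grid, dtype=float)
    surv = np.array([(times > t).mean() for t in grid])
    return SurvivalCurve(
        grid=grid,
        surviving=surv,
        n_trajectories=len(records),
        censored=int(np.isinf(times).sum()),
    )


def _mixture_params(theta, n_comp, fit_plateau):
    """Unpack (rates, amplitudes, plateau) with S(0) = 1 built in.

    Amplitudes sum to 1 - plateau but are individually unconstrained:
    sequential mechanisms with intermediates give exponential sums with
    negative components (that is what produces a lag phase), so only
    the normalisation is enforced.
    """
    logk = theta[:n_comp]
    rates = np.exp(np.clip(logk, -60.0, 60.0))
    free = theta[n_comp:n_comp + n_comp - 1]
    if fit_plateau:
        plateau = 1.0 / (1.0 + np.exp(-np.clip(theta[-1], -40, 40)))
    else:
        plateau = 0.0
    amps = np.append(free, (1.0 - plateau) - free.sum())
    return rates, amps, plateau


def _mixture_residuals(theta, t, s, se, n_comp, fit_plateau):
    rates, amps, plateau = _mixture_params(theta, n_comp, fit_plateau)
    with np.errstate(over="ignore", under="ignore"):
        model = plateau + np.sum(
            amps[:, None] * np.exp(-rates[:, None] * t[None, :]), axis=0
        )
    return (model - s) / se


def fit_kinetic_model(
    curve: SurvivalCurve,
    max_components: int = 4,
) -> KineticFit:
    """Fit amplitude-weighted exponential sums to the survival curve.

    Candidate models with 1..max_components rates are fitted by
    weighted least squares (binomial standard errors per point) on the
    log-time grid; the reported model minimises the AIC.  The chi² of
    the single-exponential fit is always reported so its inadequacy is
    a measured statistic, not an assumption.
    """
    t, s = curve.grid, curve.surviving
    informative = (s > 0) & (s < 1)
    if informative.sum() < 10:
        if np.all(s >= 1.0 - 1e-12):
            raise ValueError("degenerate survival curve: nothing folds")
        raise ValueError("too few informative points on the survival curve")
    t, s = t[informative], s[informative]
    n = curve.n_trajectories
    se = np.sqrt(np.maximum(s * (1 - s), 0.25 / n) / n)
    fit_plateau = curve.censored > 0

    t_scale = np.median(t[s < 0.5]) if (s < 0.5).any() else t[-1]
    plateau0 = curve.censored / n if fit_plateau else 0.0
    best = None
    scores: dict[int, float] = {}
    chi2_single = np.nan
    for m in range(1, max_components + 1):
        logk0 = np.log(np.logspace(-1, 1, m) / t_scale)
        # two starts: a plain decaying mixture, and a lag-type start with
        # a negative leading amplitude (sequential-intermediate shape)
        starts = [np.full(m - 1, (1.0 - plateau0) / m)]
        if m > 1:
            lag = np.full(m - 1, (1.0 - plateau0) / m)
            lag[0] = -(1.0 - plateau0)
            starts.append(lag)
        res = None
        for amps0 in starts:
            theta0 = np.concatenate([logk0, amps0])
            if fit_plateau:
                p0 = np.clip(plateau0, 1e-3, 1 - 1e-3)
                theta0 = np.append(theta0, np.log(p0 / (1 - p0)))
            # rates outside the resolvable window of the grid are meaningless
            lo = np.concatenate([np.full(m, np.log(0.01 / t[-1])),
                                 np.full(len(theta0) - m, -np.inf)])
            hi = np.concatenate([np.full(m, np.log(10.0 / t[0])),
                                 np.full(len(theta0) - m, np.inf)])
            try:
                cand = least_squares(
                    _mixture_residuals, np.clip(theta0, lo + 1e-9, hi - 1e-9),
                    args=(t, s, se, m, fit_plateau),
                    bounds=(lo, hi), method="trf", max_nfev=20000,
                )
            except Exception as exc:  # pragma: no cover - fit pathology
                logger.warning("fit with %d components failed: %s", m, exc)
                continue
            if res is None or np.sum(cand.fun**2) < np.sum(res.fun**2):
                res = cand
        if res is None:
            continue
        chi2 = float(np.sum(res.fun**2))
        n_par = 2 * m - 1 + (1 if fit_plateau else 0)
        aic = chi2 + 2 * n_par
        scores[m] = aic
        if m == 1:
            chi2_single = chi2
        if best is None or aic < best[0]:
            best = (aic, m, res, chi2)
    if best is None:
        raise RuntimeError("no exponential-mixture fit converged")
    aic, m, res, chi2 = best
    rates, amps, plateau = _mixture_params(res.x, m, fit_plateau)
    order = np.argsort(rates)[::-1]
    return KineticFit(
        n_components=m,
        rates=rates[order],
        amplitudes=np.asarray(amps)[order],
        plateau=float(plateau),
        chi2=chi2,
        n_points=len(t),
        aic=aic,
        scores=scores,
        single_exponential_chi2=chi2_single,
    )


def population_histogram(
    q: np.ndarray,
    rmsd: np.ndarray,
    q_edges: np.ndarray | int = 50,
    rmsd_edges: np.ndarray | int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2D percentage-population histogram over (Q, RMSD).

    Returns (H, q_edges, rmsd_edges) with H summing to 100 over the
    occupied bins; display on a logarithmic colour scale.  The native
    bin never accumulates because trajectories stop at the threshold.
    """
    q = np.asarray(q, dtype=float)
    rmsd = np.asarray(rmsd, dtype=float)
    if len(q) != len(rmsd):
        raise ValueError("Q and RMSD sample arrays differ in length")
    if len(q) == 0:
        raise ValueError("no samples")
    h, qe, re_ = np.histogram2d(q, rmsd, bins=[q_edges, rmsd_edges])
    h = 100.0 * h / h.sum()
    return h, qe, re_
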