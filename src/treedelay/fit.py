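"""Maximum-likelihood estimation of the decision and delay parameters
from a set of genealogies.

The decision threshold x* is discrete, so the likelihood is profiled
over an integer grid of thresholds; for each x* the four continuous
parameters (a0, a1, α, γ) are optimised with a multiple-restart scheme:
a Latin-hypercube sample of start points is screened by likelihood, and
bounded derivative-free local searches are polished from the best of
them.  The local search is nested — the delay parameters (α, γ) form
the outer loop and the cheap decision parameters (a0, a1) the inner
loop — because re-scoring the decision parameters reuses the cached
delay-process messages of the likelihood engine.

GM- and MegE-fated tree sets are fitted independently (call ``fit``
once per fate class).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .decision import DecisionParams
from .delay import DelayParams, sample_first_passage
from .genealogy import Genealogy, EndReason
from .hidden import TreeLikelihoodEngine
from .simulate import CellCycleSpec, SimConfig, simulate_trees

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "FitResult",
    "FitError",
    "fit",
    "mean_delay",
    "onset_distribution_fit",
    "OnsetDistributionFit",
    "empirical_onset_cdf",
]


class FitError(RuntimeError):
    """No restart produced a finite likelihood."""


@dataclass(frozen=True)
class FitConfig:
    """Optimisation settings.

    Default bounds cover hazards up to 1/h, hazard slopes of ±0.05/h²,
    and delays from minutes to days at 12 h cell cycles.  ``n_restarts``
    Latin-hypercube start points are screened per threshold value and
    the best ``n_polish`` are locally optimised.
    """

    a0_bounds: tuple[float, float] = (0.0, 1.0)
    a1_bounds: tuple[float, float] = (-0.05, 0.05)
    alpha_bounds: tuple[float, float] = (0.01, 5.0)
    gamma_bounds: tuple[float, float] = (0.0, 1.0)
    x_star_grid: tuple[int, ...] = (5, 10, 15, 20, 25, 30, 40, 50, 65, 80, 100)
    n_restarts: int = 40
    n_polish: int = 2
    rng_seed: int = 0
    grid_h: float = 0.5
    quad_stride: int = 4
    outer_maxfev: int = 60
    inner_maxfev: int = 40
    xatol: float = 1e-3
    fatol: float = 0.05

    def __post_init__(self):
        for lo, hi in (self.a0_bounds, self.a1_bounds, self.alpha_bounds, self.gamma_bounds):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError("bounds must be finite with lower <= upper")
        if self.n_restarts < 1 or self.n_polish < 1:
            raise ValueError("n_restarts and n_polish must be >= 1")


@dataclass
class FitResult:
    theta_hat: DecisionParams
    eta_hat: DelayParams
    total_log_likelihood: float
    restarts: list[dict] = field(default_factory=list)
    converged: bool = True
    n_trees: int = 0

    def to_dict(self) -> dict:
        return {
            "theta_hat": {"a0": self.theta_hat.a0, "a1": self.theta_hat.a1},
            "eta_hat": {
                "alpha": self.eta_hat.alpha,
                "gamma": self.eta_hat.gamma,
                "x_star": self.eta_hat.x_star,
            },
            "total_log_likelihood": self.total_log_likelihood,
            "converged": self.converged,
            "n_trees": self.n_trees,
            "restarts": self.restarts,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def fit(trees: list[Genealogy], config: FitConfig = FitConfig()) -> FitResult:
    """Maximise Σ_i log L(T_i | θ, η) over (θ, η); see module docstring."""
    trees = list(trees)
    n_onsets = sum(len(t.onset_cells()) for t in trees)
    if n_onsets == 0:
        logger.warning(
            "no marker onsets in any tree: delay parameters are unidentifiable"
        )
    engine = TreeLikelihoodEngine(trees, h=config.grid_h, quad_stride=config.quad_stride)
    rng = np.random.default_rng(config.rng_seed)

    th_b = [config.a0_bounds, config.a1_bounds]
    ag_b = [config.alpha_bounds, config.gamma_bounds]

    def loglik(theta_vec) -> float:
        return engine.loglik(DecisionParams(max(theta_vec[0], 0.0), theta_vec[1]))

    best = {"ll": -np.inf, "theta": None, "eta": None}
    restart_log: list[dict] = []

    # the decision parameters are profiled out at every delay-parameter
    # point: a Nelder-Mead search over (a0, a1) started both from a
    # neutral constant-hazard anchor and (when available) from the best
    # theta seen so far.  The theta surface itself can hold competing
    # local modes (intercept-driven vs slope-driven hazards), so a single
    # warm start is not reliable.
    theta_anchors = [np.array([0.1, 0.0]), np.array([0.02, 0.0])]

    def profile_theta(starts, maxfev) -> tuple[float, np.ndarray]:
        best_f, best_x = np.inf, starts[0]
        for s in starts:
            res = minimize(
                lambda tv: -loglik(tv),
                s,
                method="Nelder-Mead",
                bounds=th_b,
                options={"maxfev": maxfev, "xatol": config.xatol, "fatol": config.fatol},
            )
            if res.fun < best_f:
                best_f, best_x = float(res.fun), res.x
        return best_f, best_x

    for xs in config.x_star_grid:
        sampler = qmc.LatinHypercube(d=2, seed=rng.integers(2**31))
        unit = sampler.random(config.n_restarts)
        # the delay rate alpha is sampled log-uniformly so start points
        # cover slow and fast expression evenly; gamma stays linear
        # (zero degradation is meaningful)
        points = np.empty_like(unit)
        loa = max(config.alpha_bounds[0], 1e-3)
        points[:, 0] = 10 ** (
            np.log10(loa)
            + unit[:, 0] * (np.log10(max(config.alpha_bounds[1], loa)) - np.log10(loa))
        )
        # gamma is also log-sampled (delays require alpha/gamma >= x*, so
        # most of a linear [0, 1] range would be wasted on dead regimes);
        # zero degradation remains reachable through the local search
        log_ = np.log10(max(config.gamma_bounds[0], 1e-3))
        hig = np.log10(max(config.gamma_bounds[1], 2e-3))
        points[:, 1] = 10 ** (log_ + unit[:, 1] * (hig - log_))

        screened = []
        for alpha, gamma in points:
            engine.set_eta(DelayParams(alpha, gamma, xs))
            negf, th = profile_theta(theta_anchors, maxfev=20)
            screened.append((-negf, np.array([th[0], th[1], alpha, gamma])))
        screened.sort(key=lambda s: -s[0])
        logger.info(
            "x*=%d screening: best of %d starts ll=%.2f", xs, len(points), screened[0][0]
        )
        # polish the best point plus the best *mode-diverse* points: the
        # likelihood surface can have competing explanation modes whose
        # delay rates alpha differ by large factors, so later polish
        # candidates must differ from the chosen ones in log(alpha)
        chosen: list[tuple[float, np.ndarray]] = []
        for ll0, p0 in screened:
            if len(chosen) >= config.n_polish:
                break
            if not np.isfinite(ll0):
                continue
            if all(abs(np.log(p0[2]) - np.log(c[1][2])) > 0.5 for c in chosen) or not chosen:
                chosen.append((ll0, p0))
        for ll0, p0 in chosen:
            if not np.isfinite(ll0):
                continue
            theta_cur = np.array(p0[:2])

            def neg_profile(ag) -> float:
                nonlocal theta_cur
                alpha = float(np.clip(ag[0], *config.alpha_bounds))
                gamma = float(np.clip(ag[1], *config.gamma_bounds))
                engine.set_eta(DelayParams(alpha, gamma, xs))
                negf, theta_cur = profile_theta(
                    [theta_cur] + theta_anchors[:1], maxfev=config.inner_maxfev
                )
                return negf

            res = minimize(
                neg_profile,
                p0[2:],
                method="Nelder-Mead",
                bounds=ag_b,
                options={
                    "maxfev": config.outer_maxfev,
                    "xatol": config.xatol,
                    "fatol": config.fatol,
                },
            )
            ll = -float(res.fun)
            entry = {
                "x_star": int(xs),
                "start": [float(v) for v in p0],
                "ll_start": float(ll0),
                "ll_final": ll,
                "theta": [float(v) for v in theta_cur],
                "alpha_gamma": [float(v) for v in res.x],
            }
            restart_log.append(entry)
            logger.info("x*=%d polish: ll %.2f -> %.2f", xs, ll0, ll)
            if ll > best["ll"]:
                best = {
                    "ll": ll,
                    "theta": DecisionParams(max(float(theta_cur[0]), 0.0), float(theta_cur[1])),
                    "eta": DelayParams(
                        float(np.clip(res.x[0], *config.alpha_bounds)),
                        float(np.clip(res.x[1], *config.gamma_bounds)),
                        xs,
                    ),
                }

    if not np.isfinite(best["ll"]) or best["theta"] is None:
        raise FitError(
            f"all restarts failed to produce a finite likelihood "
            f"({len(restart_log)} local searches over x* grid {config.x_star_grid})"
        )
    return FitResult(
        theta_hat=best["theta"],
        eta_hat=best["eta"],
        total_log_likelihood=best["ll"],
        restarts=restart_log,
        converged=True,
        n_trees=len(trees),
    )


# ---------------------------------------------------------------------------
# derived summaries of a fit
# ---------------------------------------------------------------------------

def mean_delay(
    result: FitResult, rng, n_samples: int = 20000, t_cap: float = 5000.0
) -> float:
    """Mean decision-to-onset delay (hours) under the fitted model.

    Monte-Carlo over the delay process from x0 = 0 at the fitted (α, γ,
    x*).  Under the default copy-inheritance rule divisions do not alter
    the expression state, so the generation-spanning delay of a branch
    is exactly the first-passage time of the birth-death process.
    Samples beyond ``t_cap`` (vanishingly rare for fitted parameters)
    are excluded.
    """
    fp = sample_first_passage(result.eta_hat, 0, rng, n_samples, t_max=t_cap)
    fp = fp[np.isfinite(fp)]
    if fp.size == 0:
        return float("inf")
    return float(fp.mean())


def empirical_onset_cdf(trees) -> tuple[np.ndarray, np.ndarray]:
    """Pooled empirical CDF of all observed onset times (step function)."""
    times = np.sort(
        [c.onset_time for t in trees for c in t.onset_cells()]
    )
    if times.size == 0:
        return np.array([]), np.array([])
    return times, np.arange(1, times.size + 1) / times.size


def _ecdf_at(times, x) -> np.ndarray:
    if times.size == 0:
        return np.zeros_like(np.asarray(x, dtype=float))
    return np.searchsorted(times, x, side="right") / times.size


@dataclass
class OnsetDistributionFit:
    sup_distance: float
    observed: tuple[np.ndarray, np.ndarray]
    predicted: tuple[np.ndarray, np.ndarray]


def onset_distribution_fit(
    trees: list[Genealogy],
    result: FitResult,
    rng,
    n_sim_trees: int = 400,
    cellcycle: CellCycleSpec | None = None,
) -> OnsetDistributionFit:
    """Model-predicted vs empirical cumulative onset distribution.

    The prediction is obtained by forward simulation at the fitted
    parameters, matching the observed movie length and (unless given) a
    cell-cycle distribution moment-matched to the observed division
    cells; the sup-norm distance between the two pooled onset-time CDFs
    measures how well the decomposition of onsets into decision CDF and
    expression delay explains the data.
    """
    movie_end = max(c.end_time for t in trees for c in t.cells.values())
    if cellcycle is None:
        lifes = [
            c.lifetime
            for t in trees
            for c in t.cells.values()
            if c.end_reason == EndReason.DIVISION
        ]
        if len(lifes) >= 2:
            cellcycle = CellCycleSpec(mean=float(np.mean(lifes)), sd=float(np.std(lifes)))
        else:
            cellcycle = CellCycleSpec()
    sim = simulate_trees(
        SimConfig(
            theta=result.theta_hat,
            eta=result.eta_hat,
            cellcycle=cellcycle,
            movie_end=movie_end,
            n_trees=n_sim_trees,
        ),
        rng,
    )
    obs_t, obs_v = empirical_onset_cdf(trees)
    pred_t, pred_v = empirical_onset_cdf(sim.trees)
    xs = np.unique(np.concatenate([obs_t, pred_t]))
    if xs.size == 0:
        return OnsetDistributionFit(0.0, (obs_t, obs_v), (pred_t, pred_v))
    d = float(np.max(np.abs(_ecdf_at(obs_t, xs) - _ecdf_at(pred_t, xs))))
    return OnsetDistributionFit(d, (obs_t, obs_v), (pred_t, pred_v))
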