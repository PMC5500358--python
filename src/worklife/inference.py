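"""Simulation-based confidence intervals for occupation probabilities and
restricted mean times.

The sampling distribution of the Nelson-Aalen increments is approximated by
perturbing each increment with independent mean-zero Gaussian noise whose
variance is the estimated variance increment n_jk/Y_j^2.  Each of B
replicate intensity sets is pushed through the same product-limit
propagation as the point estimate, and the empirical percentiles of the
replicated functional give the interval (a normal-theory variant using the
replicate standard deviation is also available).  The point estimate is
always the unperturbed one.

Negative perturbed increments are allowed by default: a single-event
increment has a noise SD equal to the increment itself, so clipping the
draws at zero cuts the lower tail at one SD and shrinks the replicate
spread by roughly 20%, which pushes nominal 95% intervals to ~87-90%
empirical coverage at any cohort size.  The replicates are an inferential
device, not estimates, so validity of each draw as an intensity is not
required; ``truncate=True`` restores the clipped variant for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import CumulativeIntensitySet, integrate_step_curve


@dataclass
class IntervalEstimate:
    """Point estimate with simulation interval; arrays share one shape.

    For the occupation functional the shape is (n_grid_ages, n_states);
    for restricted means it is (n_states,).
    """

    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    functional: str
    B: int

    def __post_init__(self) -> None:
        if not ((self.lower <= self.point + 1e-12).all()
                and (self.point <= self.upper + 1e-12).all()):
            raise AssertionError("point estimate outside its interval")


def perturb_intensities(H: CumulativeIntensitySet,
                        seed: int | np.random.Generator,
                        truncate: bool = False) -> CumulativeIntensitySet:
    """One perturbation replicate of the intensity increments.

    Each increment gets independent N(0, dVar) noise (independent across
    transition types and event times); ``truncate`` clips negative draws
    at zero (see the module note on the coverage cost).  Deterministic
    given the seed.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    new = {}
    for pair in sorted(H.increments):
        idx, dh, dvar = H.increments[pair]
        noise = rng.standard_normal(len(dh)) * np.sqrt(dvar)
        pert = dh + noise
        if truncate:
            pert = np.maximum(pert, 0.0)
        new[pair] = (idx, pert, dvar)
    return H.with_increments(new)


def _draw_increments(H: CumulativeIntensitySet, B: int,
                     rng: np.random.Generator,
                     truncate: bool = False
                     ) -> dict[tuple[int, int], np.ndarray]:
    """(B, n_pair_times) perturbed increments per transition type; the
    B=0 sentinel returns the unperturbed increments with a leading axis."""
    draws = {}
    for pair in sorted(H.increments):
        _, dh, dvar = H.increments[pair]
        if B == 0:
            draws[pair] = dh[None, :].copy()
        else:
            noise = rng.standard_normal((B, len(dh))) * np.sqrt(dvar)
            pert = dh[None, :] + noise
            if truncate:
                pert = np.maximum(pert, 0.0)
            draws[pair] = pert
    return draws


def _propagate(H: CumulativeIntensitySet,
               draws: dict[tuple[int, int], np.ndarray],
               W: np.ndarray, origin: float,
               grid: np.ndarray | None = None,
               integral: tuple[float, float] | None = None
               ) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Propagate B replicate intensity sets through the product limit.

    Walks the pooled event times once, updating all replicates' occupation
    vectors w <- w (I + dH(s)) simultaneously.  Returns occupation values at
    ``grid`` ages (B, n_grid, J) and/or the exact step integral over
    ``integral`` = (t0, t1), shape (B, J).
    """
    J = H.n_states
    pos = {c: i for i, c in enumerate(H.space.codes)}
    B = next(iter(draws.values())).shape[0] if draws else 1

    # active increment entries per pooled time index
    per_time: dict[int, list[tuple[int, int, tuple[int, int], int]]] = {}
    for pair in sorted(H.increments):
        idx, _, _ = H.increments[pair]
        pj, pk = pos[pair[0]], pos[pair[1]]
        for slot, s in enumerate(idx):
            per_time.setdefault(int(s), []).append((pj, pk, pair, slot))

    w = np.tile(W, (B, 1))
    lo = np.searchsorted(H.times, origin, side="right")

    grid_out = None
    g_sorted = None
    g_ptr = 0
    if grid is not None:
        g_sorted = np.sort(np.asarray(grid, dtype=float))
        grid_out = np.empty((B, len(g_sorted), J))
    t0 = t1 = None
    E = None
    if integral is not None:
        t0, t1 = integral
        E = np.zeros((B, J))

    prev_t = origin
    times = H.times
    for s in range(lo, len(times)):
        t_s = times[s]
        if g_sorted is not None:
            while g_ptr < len(g_sorted) and g_sorted[g_ptr] < t_s:
                grid_out[:, g_ptr, :] = w
                g_ptr += 1
        if E is not None:
            seg = min(t_s, t1) - max(prev_t, t0)
            if seg > 0:
                E += seg * w
        entries = per_time.get(s)
        if entries:
            w_old = w.copy()
            for pj, pk, pair, slot in entries:
                delta = w_old[:, pj] * draws[pair][:, slot]
                w[:, pk] += delta
                w[:, pj] -= delta
        prev_t = t_s
    if g_sorted is not None:
        while g_ptr < len(g_sorted):
            grid_out[:, g_ptr, :] = w
            g_ptr += 1
    if E is not None:
        seg = t1 - max(prev_t, t0)
        if seg > 0:
            E += seg * w
    return grid_out, E


def simulation_ci(H: CumulativeIntensitySet, functional: str,
                  origin_age: float, weights: np.ndarray | None = None,
                  grid: np.ndarray | None = None,
                  t0: float | None = None, t1: float | None = None,
                  B: int = 1000, level: float = 0.95,
                  seed: int | np.random.Generator = 0,
                  method: str = "percentile",
                  truncate: bool = False) -> IntervalEstimate:
    """Simulation confidence intervals for a multi-state functional.

    Parameters
    ----------
    functional
        "occupation" (needs ``grid`` of ages) or "restricted_mean"
        (needs ``t0``/``t1``).
    B
        Number of perturbation replicates.
    level
        Two-sided confidence level in (0, 1).
    method
        "percentile" (empirical quantiles of the replicates, default) or
        "normal" (point estimate +/- z * replicate SD).
    truncate
        Clip negative perturbed increments at zero (narrows the intervals
        below nominal coverage; off by default).
    """
    if functional not in ("occupation", "restricted_mean"):
        raise ValueError(f"unknown functional {functional!r}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if B < 2:
        raise ValueError("B must be >= 2")
    if method not in ("percentile", "normal"):
        raise ValueError(f"unknown method {method!r}")
    J = H.n_states
    if weights is None:
        W = np.zeros(J)
        W[0] = 1.0
    else:
        W = np.asarray(weights, dtype=float)
    if abs(W.sum() - 1.0) > 1e-8 or (W < 0).any():
        raise ValueError("weights must be a probability vector")

    if functional == "occupation":
        if grid is None:
            raise ValueError("occupation functional needs a grid of ages")
        grid = np.asarray(grid, dtype=float)
        args = dict(grid=grid, integral=None)
    else:
        if t0 is None or t1 is None:
            raise ValueError("restricted_mean functional needs t0 and t1")
        if t0 >= t1:
            raise ValueError("t0 must be < t1")
        args = dict(grid=None, integral=(t0, t1))

    point_g, point_e = _propagate(H, _draw_increments(H, 0, None), W,
                                  origin_age, **args)
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    draws = _draw_increments(H, B, rng, truncate=truncate)
    rep_g, rep_e = _propagate(H, draws, W, origin_age, **args)

    point = point_g[0] if functional == "occupation" else point_e[0]
    reps = rep_g if functional == "occupation" else rep_e

    alpha = 1.0 - level
    if method == "percentile":
        lower = np.quantile(reps, alpha / 2, axis=0)
        upper = np.quantile(reps, 1 - alpha / 2, axis=0)
        # the point estimate anchors the interval even under truncation skew
        lower = np.minimum(lower, point)
        upper = np.maximum(upper, point)
    else:
        from scipy.stats import norm
        z = norm.ppf(1 - alpha / 2)
        sd = reps.std(axis=0, ddof=1)
        lower, upper = point - z * sd, point + z * sd
    return IntervalEstimate(point=point, lower=lower, upper=upper,
                            level=level, functional=functional, B=B)
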