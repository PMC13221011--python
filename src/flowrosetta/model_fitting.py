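"""Histogram-initialized constrained EM for per-dimension mixtures, with BIC
model selection.

Each cluster dimension is modelled as a weighted mixture of skew-family
components (X axis) or kurtosis-family components (Y axis).  The two
dimensions are fitted jointly: when the component counts match, one shared
weight vector couples them and responsibilities come from the product of the
per-dimension component densities, so skew-induced cross-axis structure is
absorbed coherently; with unequal counts the dimensions fall back to
independent 1-D mixtures.

Fitting details that matter:

* Initialization is deliberately cheap: equal-width histogram bins (one per
  component), a local-peak estimate of each bin's mode for the initial mean,
  the bin SD for the scale, shape 0, bin occupancy for the weight.
* During EM iterations the M-step is moment-profiled: location and scale
  are tied to the responsibility-weighted moments through the family's
  moment relations and only the shape is optimized (1-D, bounded), which
  removes the flat shape direction of the skew likelihood at alpha = 0; a
  final polish phase then maximizes each component's full weighted
  likelihood (L-BFGS-B, warm started, with a moment-matched alternative
  start).
* Component means move at most ``mean_step_limit`` (default 5%) of their
  current scale per iteration — a deliberate brake on large jumps that keeps
  the search near the histogram anchor and prevents oscillation.
* If the data was truncated to a known window (the outlier-removal step
  records one), all likelihoods are renormalized over that window, so the
  fitted parameters describe the *untruncated* population.  This keeps
  analyze -> generate -> analyze loops free of trim-attenuation drift.
* Convergence: the largest scaled parameter change (means and scales in
  units of the component scale, shapes and weights absolute) below
  ``tolerance``, or ``max_iterations`` reached (flagged, not fatal).

BIC uses k ln n - 2 loglik with k = 3 per component + (m - 1) weights per
dimension; the configuration with the lowest full-model BIC wins, ties going
to fewer total components.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from numpy.typing import NDArray
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp

from .distributions import (
    ShapeParams,
    alpha_from_skewness,
    beta_from_excess_kurtosis,
    kurt_excess_kurtosis,
    kurt_gauss_cdf,
    kurt_gauss_logpdf,
    kurt_var_factor,
    skew_gauss_cdf,
    skew_gauss_logpdf,
    skew_mean_offset,
    skew_sd_factor,
    KURT_G2_RANGE,
)
from .preprocessing import RosettaConfig

__all__ = [
    "ComponentParams",
    "DimensionModel",
    "ClusterModel",
    "FitError",
    "init_from_histogram",
    "em_fit",
    "bic_score",
    "select_model",
]

logger = logging.getLogger(__name__)

_BETA_MAX = 8.0  # optimizer bound; beyond this the family is ~normal again


class FitError(RuntimeError):
    """Numerical failure during model fitting."""


@dataclass(frozen=True)
class ComponentParams:
    """One mixture component: weight plus its family parameters."""

    weight: float
    shape: ShapeParams

    def __post_init__(self) -> None:
        if not (0.0 < self.weight <= 1.0):
            raise ValueError(f"weight must be in (0, 1], got {self.weight}")


@dataclass
class DimensionModel:
    """Fitted mixture for one dimension of one cluster."""

    axis: str  # "X" or "Y"
    components: list[ComponentParams]
    loglik: float
    bic: float

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def dominant(self) -> ComponentParams:
        return max(self.components, key=lambda c: c.weight)

    def mixture_mean_sd(self) -> tuple[float, float]:
        """Aggregate mean and SD via the mixture-moment identities.

        Component moments are the *density* moments (the skew family's mean
        includes its location-to-mean offset; both families' variances use
        their scale-to-SD factors).
        """
        w = np.array([c.weight for c in self.components])
        means = np.empty(len(w))
        varis = np.empty(len(w))
        for i, c in enumerate(self.components):
            s = c.shape
            if s.alpha is not None:
                means[i] = s.mu + s.sigma * skew_mean_offset(s.alpha)
                varis[i] = (s.sigma * skew_sd_factor(s.alpha)) ** 2
            else:
                means[i] = s.mu
                varis[i] = s.sigma**2 * kurt_var_factor(s.beta)  # type: ignore[arg-type]
        mean = float(w @ means)
        var = float(w @ (varis + means**2) - mean**2)
        return mean, math.sqrt(max(var, 0.0))


@dataclass
class ClusterModel:
    """Joint fitted model of one cluster (post-alignment, post-trimming)."""

    n_events: int
    rotation_deg: float
    x_model: DimensionModel
    y_model: DimensionModel
    full_bic: float
    silhouette: float
    converged: bool = True
    window: tuple[tuple[float, float], tuple[float, float]] | None = None


def bic_score(loglik: float, k_params: int, n: int) -> float:
    """Bayesian information criterion: k ln(n) - 2 loglik."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return k_params * math.log(n) - 2.0 * loglik


def _dim_k(m: int) -> int:
    return 3 * m + (m - 1)


def init_from_histogram(values: NDArray[np.float64], m: int) -> list[ComponentParams]:
    """Histogram-based initial components for one dimension.

    The range is split into ``m`` equal-width bins (one per requested
    component); each bin contributes a component with mean at the bin's local
    peak (mode of a 32-sub-bin histogram), scale from the bin's sample SD,
    shape 0 and weight equal to the bin's point fraction.  An empty (or
    near-empty) bin reduces the component count with a logged warning.
    """
    v = np.asarray(values, dtype=float)
    if m < 1:
        raise ValueError("component count must be >= 1")
    edges = np.linspace(v.min(), v.max(), m + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)
    comps: list[tuple[float, float, float]] = []  # (weight, mu0, sigma0)
    for i in range(m):
        sel = v[(v >= edges[i]) & (v < edges[i + 1])]
        if sel.size < 3 or sel.std() == 0.0:
            logger.warning("histogram init: bin %d of %d too sparse; reducing components", i + 1, m)
            continue
        counts, sub = np.histogram(sel, bins=32)
        peak = np.argmax(counts)
        mu0 = 0.5 * (sub[peak] + sub[peak + 1])
        comps.append((sel.size / v.size, float(mu0), float(sel.std())))
    if not comps:
        raise FitError("histogram initialization found no usable bins")
    wsum = sum(c[0] for c in comps)
    return [ComponentParams(w / wsum, ShapeParams(mu, sd, alpha=0.0))
            for (w, mu, sd) in comps]


# ---------------------------------------------------------------------------
# internal parameter bookkeeping
# ---------------------------------------------------------------------------

def _logpdf(values, mu, sigma, shape, axis, window):
    if axis == "X":
        lp = skew_gauss_logpdf(values, mu, sigma, shape)
        if window is not None:
            p = ShapeParams(mu, sigma, alpha=shape)
            mass = skew_gauss_cdf(window[1], p) - skew_gauss_cdf(window[0], p)
        else:
            return lp
    else:
        lp = kurt_gauss_logpdf(values, mu, sigma, shape)
        if window is not None:
            p = ShapeParams(mu, sigma, beta=shape)
            mass = kurt_gauss_cdf(window[1], p) - kurt_gauss_cdf(window[0], p)
        else:
            return lp
    mass = float(np.clip(mass, 1e-300, 1.0))
    return lp - math.log(mass)


def _weighted_moments(values, r):
    wsum = r.sum()
    m1 = float(r @ values / wsum)
    var = float(r @ (values - m1) ** 2 / wsum)
    m3 = float(r @ (values - m1) ** 3 / wsum)
    m4 = float(r @ (values - m1) ** 4 / wsum)
    sd = math.sqrt(max(var, 1e-300))
    return m1, sd, m3 / sd**3, m4 / sd**4 - 3.0


def _moment_tied(shape, m1, sd, axis):
    """(mu, sigma) implied by a shape and the weighted mean/SD."""
    if axis == "X":
        sigma = sd / skew_sd_factor(shape)
        return m1 - sigma * skew_mean_offset(shape), sigma
    return m1, sd / math.sqrt(kurt_var_factor(shape))


def _moment_candidate(values, r, axis):
    """Moment-matched (mu, sigma, shape) start for the M-step optimizer."""
    m1, sd, g1, g2 = _weighted_moments(values, r)
    if axis == "X":
        a = alpha_from_skewness(max(min(g1, 0.99), -0.99))
        return (*_moment_tied(a, m1, sd, axis), a)
    lo, hi = KURT_G2_RANGE
    b = beta_from_excess_kurtosis(min(max(g2, lo + 1e-3), hi - 1e-3))
    return (*_moment_tied(b, m1, sd, axis), b)


def _profile_step(values, r, shape, axis, window):
    """Cheap M-step: tie (mu, sigma) to the weighted moments through the
    family's moment relations and maximize the weighted loglik over the
    single shape parameter.

    Profiling out the location/scale removes the flat shape direction of the
    skew likelihood near alpha = 0, which full joint optimization is prone
    to wandering along.
    """
    m1, sd, _, _ = _weighted_moments(values, r)
    # |gamma1| up to 0.992 maps to |alpha| <= 10; below beta ~ -12 the
    # kurtosis family is saturated, so narrow bounds lose nothing
    shape_lo, shape_hi = (-10.0, 10.0) if axis == "X" else (-12.0, _BETA_MAX)

    def nll(sh):
        mu, sigma = _moment_tied(sh, m1, sd, axis)
        val = -(r @ _logpdf(values, mu, sigma, sh, axis, window))
        return val if np.isfinite(val) else 1e300

    res = minimize_scalar(nll, bounds=(shape_lo, shape_hi), method="bounded",
                          options=dict(xatol=1e-5, maxiter=60))
    sh = float(res.x) if res.fun <= nll(shape) else shape
    mu, sigma = _moment_tied(sh, m1, sd, axis)
    return mu, sigma, sh


def _optimize_component(values, r, mu, sigma, shape, axis, window, scale_ref,
                        maxiter, moment_start=False):
    """Full M-step: maximize the responsibility-weighted (truncated) loglik
    of one component over (mu, log sigma, shape), warm-started."""
    shape_hi = _BETA_MAX if axis == "Y" else 60.0
    shape_lo = -60.0

    def nll(p):
        m = p[0] * scale_ref
        s = math.exp(p[1]) * scale_ref
        sh = p[2]
        if not (1e-12 * scale_ref < s < 1e6 * scale_ref) or not (shape_lo <= sh <= shape_hi):
            return 1e300
        lp = _logpdf(values, m, s, sh, axis, window)
        val = -(r @ lp)
        return val if np.isfinite(val) else 1e300

    starts = [(mu / scale_ref, math.log(sigma / scale_ref), shape)]
    if moment_start:
        try:
            mm = _moment_candidate(values, r, axis)
            starts.append((mm[0] / scale_ref, math.log(mm[1] / scale_ref), mm[2]))
        except (ValueError, ZeroDivisionError):
            pass
    bounds = [(None, None), (math.log(1e-9), math.log(1e6)), (shape_lo, shape_hi)]
    best = None
    for x0 in starts:
        res = minimize(nll, np.asarray(x0), method="L-BFGS-B", bounds=bounds,
                       options=dict(maxiter=maxiter, ftol=1e-13, gtol=1e-10))
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    if not np.isfinite(best.fun):
        raise FitError("component optimization produced non-finite likelihood")
    return best.x[0] * scale_ref, math.exp(best.x[1]) * scale_ref, float(best.x[2])


def em_fit(
    x: NDArray[np.float64],
    y: NDArray[np.float64],
    m_x: int,
    m_y: int,
    init: tuple[list[ComponentParams], list[ComponentParams]] | None,
    cfg: RosettaConfig,
    window: tuple[tuple[float, float], tuple[float, float]] | None = None,
    rotation_deg: float = 0.0,
    silhouette: float = math.nan,
) -> ClusterModel:
    """Fit the joint (or per-dimension) mixture by the constrained EM.

    ``init`` supplies (x_components, y_components); ``None`` triggers
    histogram initialization at the requested counts.  ``window`` is the
    per-dimension truncation window recorded by outlier removal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 10 * (m_x + m_y):
        raise ValueError(f"need at least {10 * (m_x + m_y)} points for ({m_x}, {m_y}) components")

    if init is None:
        comps_x = init_from_histogram(x, m_x)
        comps_y = init_from_histogram(y, m_y)
    else:
        comps_x = [replace(c) for c in init[0]]
        comps_y = [replace(c) for c in init[1]]
    m_x, m_y = len(comps_x), len(comps_y)
    joint = m_x == m_y
    wx, wy = window if window is not None else (None, None)

    mu_x = np.array([c.shape.mu for c in comps_x]); sg_x = np.array([c.shape.sigma for c in comps_x])
    sh_x = np.array([c.shape.shape for c in comps_x]); w_x = np.array([c.weight for c in comps_x])
    mu_y = np.array([c.shape.mu for c in comps_y]); sg_y = np.array([c.shape.sigma for c in comps_y])
    sh_y = np.array([c.shape.shape for c in comps_y]); w_y = np.array([c.weight for c in comps_y])
    if joint:
        w_x = w_y = (w_x + w_y) / 2.0  # one shared weight vector

    scale_x = max(float(np.std(x)), 1e-12)
    scale_y = max(float(np.std(y)), 1e-12)
    cap = cfg.mean_step_limit

    def resp(mu, sg, sh, w, vals, axis, win):
        lp = np.stack([_logpdf(vals, mu[j], sg[j], sh[j], axis, win) + math.log(w[j])
                       for j in range(len(w))])
        tot = logsumexp(lp, axis=0)
        return np.exp(lp - tot), tot

    def e_step():
        if joint:
            lp = np.stack([
                _logpdf(x, mu_x[j], sg_x[j], sh_x[j], "X", wx)
                + _logpdf(y, mu_y[j], sg_y[j], sh_y[j], "Y", wy)
                + math.log(w_x[j]) for j in range(m_x)])
            tot = logsumexp(lp, axis=0)
            r = np.exp(lp - tot)
            return r, r
        r_x, _ = resp(mu_x, sg_x, sh_x, w_x, x, "X", wx)
        r_y, _ = resp(mu_y, sg_y, sh_y, w_y, y, "Y", wy)
        return r_x, r_y

    def update_weights(r_x, r_y):
        nonlocal w_x, w_y
        new_wx = r_x.sum(axis=1) / n
        new_wy = r_y.sum(axis=1) / n
        # floor so a dying component cannot produce log(0) in the next E-step
        new_wx = np.maximum(new_wx, 1e-10); new_wx /= new_wx.sum()
        new_wy = np.maximum(new_wy, 1e-10); new_wy /= new_wy.sum()
        if min(new_wx.min(), new_wy.min()) < 1e-3 and (m_x > 1 or m_y > 1):
            raise FitError("a mixture component collapsed (weight < 1e-3)")
        d = max(float(np.max(np.abs(new_wx - w_x))), float(np.max(np.abs(new_wy - w_y))))
        w_x, w_y = new_wx, new_wy
        if joint:
            w_x = w_y = (w_x + w_y) / 2.0
        return d

    def cap_mean(old_mu, new_mu, old_sigma):
        if cap is None:
            return new_mu
        step = max(min(new_mu - old_mu, cap * old_sigma), -cap * old_sigma)
        if step != new_mu - old_mu:
            logger.debug("mean step capped to %.3g", step)
        return old_mu + step

    dims = ((mu_x, sg_x, sh_x, x, "X", wx, scale_x),
            (mu_y, sg_y, sh_y, y, "Y", wy, scale_y))

    # Phase 1: EM iterations with moment-profiled M-steps (fast, stable).
    converged = False
    it = 0
    for it in range(cfg.max_iterations):
        r_x, r_y = e_step()
        if not np.all(np.isfinite(r_x)) or not np.all(np.isfinite(r_y)):
            raise FitError(f"non-finite responsibilities at iteration {it}")
        delta = 0.0
        for (mu, sg, sh, vals, axis, win, sref), r in zip(dims, (r_x, r_y)):
            for j in range(len(mu)):
                nm, ns, nsh = _profile_step(vals, r[j], sh[j], axis, win)
                nm = cap_mean(mu[j], nm, sg[j])
                delta = max(delta, abs(nm - mu[j]) / ns, abs(ns - sg[j]) / ns, abs(nsh - sh[j]))
                mu[j], sg[j], sh[j] = nm, ns, nsh
        delta = max(delta, update_weights(r_x, r_y))
        if delta < cfg.tolerance:
            converged = True
            break

    # Phase 2: polish with full per-component likelihood maximization.  The
    # profiled step ties (mu, sigma) to the truncated weighted moments, which
    # is slightly biased under a truncation window; the polish removes that.
    polish_cycles = max(3, cfg.max_iterations // 20)
    for cycle in range(polish_cycles):
        r_x, r_y = e_step()
        delta = 0.0
        for (mu, sg, sh, vals, axis, win, sref), r in zip(dims, (r_x, r_y)):
            for j in range(len(mu)):
                nm, ns, nsh = _optimize_component(
                    vals, r[j], mu[j], sg[j], sh[j], axis, win, sref,
                    maxiter=500, moment_start=(cycle == 0))
                nm = cap_mean(mu[j], nm, sg[j])
                delta = max(delta, abs(nm - mu[j]) / ns, abs(ns - sg[j]) / ns, abs(nsh - sh[j]))
                mu[j], sg[j], sh[j] = nm, ns, nsh
        delta = max(delta, update_weights(r_x, r_y))
        if delta < cfg.tolerance:
            converged = True
            break
        converged = False
    if not converged:
        logger.warning("EM did not converge within %d iterations (last delta %.3g)",
                       cfg.max_iterations, delta)

    # marginal per-dimension logliks (for the per-axis BICs)
    _, tot_x = resp(mu_x, sg_x, sh_x, w_x, x, "X", wx)
    _, tot_y = resp(mu_y, sg_y, sh_y, w_y, y, "Y", wy)
    ll_x = float(tot_x.sum())
    ll_y = float(tot_y.sum())
    if joint:
        lp = np.stack([
            _logpdf(x, mu_x[j], sg_x[j], sh_x[j], "X", wx)
            + _logpdf(y, mu_y[j], sg_y[j], sh_y[j], "Y", wy)
            + math.log(w_x[j]) for j in range(m_x)])
        ll_full = float(logsumexp(lp, axis=0).sum())
    else:
        ll_full = ll_x + ll_y
    if not np.isfinite(ll_full):
        raise FitError("non-finite likelihood at termination")

    x_model = DimensionModel(
        "X",
        [ComponentParams(float(w_x[j]), ShapeParams(float(mu_x[j]), float(sg_x[j]), alpha=float(sh_x[j])))
         for j in range(m_x)],
        ll_x, bic_score(ll_x, _dim_k(m_x), n))
    y_model = DimensionModel(
        "Y",
        [ComponentParams(float(w_y[j]), ShapeParams(float(mu_y[j]), float(sg_y[j]), beta=float(sh_y[j])))
         for j in range(m_y)],
        ll_y, bic_score(ll_y, _dim_k(m_y), n))
    full_bic = bic_score(ll_full, _dim_k(m_x) + _dim_k(m_y), n)
    return ClusterModel(n_events=n, rotation_deg=rotation_deg,
                        x_model=x_model, y_model=y_model, full_bic=full_bic,
                        silhouette=silhouette, converged=converged, window=window)


def select_model(
    x: NDArray[np.float64],
    y: NDArray[np.float64],
    cfg: RosettaConfig,
    window: tuple[tuple[float, float], tuple[float, float]] | None = None,
    rotation_deg: float = 0.0,
    silhouette: float = math.nan,
) -> ClusterModel:
    """Fit every component configuration in range; lowest full BIC wins.

    Ties (within 1e-9) break toward fewer total components; if every fit
    fails, the individual errors are aggregated into one `FitError`.
    """
    (min_x, min_y) = cfg.min_components_per_cluster
    (max_x, max_y) = cfg.max_components_per_cluster
    best: ClusterModel | None = None
    failures: list[str] = []
    for mx in range(min_x, max_x + 1):
        for my in range(min_y, max_y + 1):
            try:
                model = em_fit(x, y, mx, my, None, cfg, window=window,
                               rotation_deg=rotation_deg, silhouette=silhouette)
            except (FitError, ValueError) as exc:
                failures.append(f"({mx},{my}): {exc}")
                continue
            if best is None:
                best = model
                continue
            cand_m = model.x_model.n_components + model.y_model.n_components
            best_m = best.x_model.n_components + best.y_model.n_components
            if (model.full_bic < best.full_bic - 1e-9
                    or (abs(model.full_bic - best.full_bic) <= 1e-9 and cand_m < best_m)):
                best = model
    if best is None:
        raise FitError("all component configurations failed: " + "; ".join(failures))
    return best
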