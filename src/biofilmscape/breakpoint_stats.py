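"""Segmented (broken-line) regression of landscape metrics against shear.

Model: y = b0 + b1*x + b2*(x - psi)_+ + eps, a continuous piecewise-linear
response with a single breakpoint psi. psi is estimated by exhaustive search
over candidate break positions (the interior observed x values within a
quantile range), fitting ordinary least squares at each candidate and
keeping the residual-sum-of-squares minimizer. Significance of the
breakpoint is assessed by a residual-bootstrap F test against the
straight-line null, and a both-replicates consensus rule mirrors the
requirement that a break be significant in both flumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import FitError

_QRANGE = (0.05, 0.95)


@dataclass
class BreakpointFit:
    psi: float  # breakpoint (units of x, e.g. Pa)
    slope_below: float
    slope_above: float
    intercept: float
    rss_segmented: float
    rss_linear: float
    n: int
    psi_identified: bool = True
    p_value: float | None = None
    psi_ci: tuple[float, float] | None = None


def _clean_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise FitError("x and y must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 8:
        raise FitError(f"need >= 8 finite (x, y) pairs, got {len(x)}")
    if np.ptp(x) == 0:
        raise FitError("x values are all equal")
    return x, y


def _candidates(x: np.ndarray, qrange=_QRANGE) -> np.ndarray:
    """Interior candidate breakpoints: observed x with >=2 distinct x values
    at-or-below and >=2 strictly above, restricted to the quantile range."""
    ux = np.unique(x)
    if len(ux) < 4:
        raise FitError("too few distinct x values for a breakpoint search")
    cand = ux[1:-2]  # >=2 distinct below-or-equal, >=2 strictly above
    lo, hi = np.quantile(x, qrange)
    inside = cand[(cand >= lo) & (cand <= hi)]
    if len(inside) == 0:
        inside = cand  # degenerate quantile range: fall back to all interior
    return inside


def _qr_batch(x: np.ndarray, cand: np.ndarray) -> np.ndarray:
    """Batched thin-QR of the segmented design for every candidate."""
    n, c = len(x), len(cand)
    X = np.empty((c, n, 3))
    X[:, :, 0] = 1.0
    X[:, :, 1] = x
    X[:, :, 2] = np.maximum(x[None, :] - cand[:, None], 0.0)
    q, _ = np.linalg.qr(X)
    return q


def _rss_from_qr(q: np.ndarray, y: np.ndarray) -> np.ndarray:
    """RSS for each candidate design; y may be (n,) or (n, B)."""
    yy = np.sum(y * y, axis=0)
    qty = np.einsum("cnk,n...->ck...", q, y)
    rss = yy - np.sum(qty * qty, axis=1)
    return np.maximum(rss, 0.0)


def _linear_rss(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), X @ beta


def fit_segmented(x, y, qrange=_QRANGE,
                  ci: bool = False, n_boot_ci: int = 199,
                  seed: int | None = None) -> BreakpointFit:
    """Estimate the broken-line model by exhaustive candidate search.

    Set ``ci=True`` for a nonparametric pair-bootstrap percentile interval
    on psi (95%, seeded). When the segmented model does not improve on the
    straight line (e.g. exactly linear data), ``psi_identified`` is False
    and the reported psi is arbitrary within the candidate set.
    """
    x, y = _clean_xy(x, y)
    cand = _candidates(x, qrange)
    q = _qr_batch(x, cand)
    rss = _rss_from_qr(q, y)
    best = int(np.argmin(rss))
    psi = float(cand[best])

    X = np.column_stack([np.ones_like(x), x, np.maximum(x - psi, 0.0)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss_seg = float(rss[best])
    rss_lin, _ = _linear_rss(x, y)

    identified = (rss_lin - rss_seg) > 1e-9 * max(rss_lin, 1e-12)
    fit = BreakpointFit(
        psi=psi, slope_below=float(beta[1]),
        slope_above=float(beta[1] + beta[2]), intercept=float(beta[0]),
        rss_segmented=rss_seg, rss_linear=rss_lin, n=len(x),
        psi_identified=bool(identified),
    )
    if ci:
        fit.psi_ci = bootstrap_psi_ci(x, y, n_boot=n_boot_ci, seed=seed,
                                      qrange=qrange)
    return fit


def bootstrap_psi_ci(x, y, n_boot: int = 199, level: float = 0.95,
                     seed: int | None = None, qrange=_QRANGE,
                     ) -> tuple[float, float]:
    """Percentile interval on psi from a nonparametric pair bootstrap."""
    x, y = _clean_xy(x, y)
    rng = np.random.default_rng(seed)
    psis = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(x), len(x))
        try:
            psis.append(fit_segmented(x[idx], y[idx], qrange=qrange).psi)
        except FitError:
            continue
    if not psis:
        raise FitError("no bootstrap replicate produced a valid fit")
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(psis, [a, 1.0 - a])
    return float(lo), float(hi)


def _f_statistic(rss_lin, rss_seg, n):
    # segmented model spends 2 extra parameters (psi and the slope change)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss_lin - rss_seg) / 2.0) / (rss_seg / (n - 4))
    return np.where(rss_seg > 0, f, np.inf)


def breakpoint_significance(x, y, fit: BreakpointFit | None = None,
                            n_boot: int = 199, seed: int | None = None,
                            qrange=_QRANGE) -> float:
    """Residual-bootstrap p-value for H0: no breakpoint (straight line).

    Bootstrap samples are built from the linear fit plus resampled linear
    residuals; each is refit with both models and the F-improvement compared
    with the observed one. The Monte-Carlo p-value ``(1+k)/(1+B)`` is exact
    under the null for continuous responses.
    """
    x, y = _clean_xy(x, y)
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; p-value resolution is coarse",
                      stacklevel=2)
    if fit is None:
        fit = fit_segmented(x, y, qrange=qrange)
    f_obs = float(_f_statistic(fit.rss_linear, fit.rss_segmented, len(x)))

    rss_lin_obs, yhat = _linear_rss(x, y)
    resid = y - yhat
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(len(x), n_boot))
    ystar = yhat[:, None] + resid[idx]

    cand = _candidates(x, qrange)
    q = _qr_batch(x, cand)
    rss_seg_star = _rss_from_qr(q, ystar).min(axis=0)
    xlin = np.column_stack([np.ones_like(x), x])
    qlin, _ = np.linalg.qr(xlin)
    qty = qlin.T @ ystar
    rss_lin_star = np.maximum(np.sum(ystar * ystar, axis=0)
                              - np.sum(qty * qty, axis=0), 0.0)
    f_star = _f_statistic(rss_lin_star, rss_seg_star, len(x))
    k = int(np.sum(f_star >= f_obs))
    return (1.0 + k) / (1.0 + n_boot)


def replicate_consensus(fits: list[BreakpointFit], alpha: float = 0.05,
                        ) -> tuple[float, float] | None:
    """Range of breakpoint estimates when significant in every replicate.

    Returns [min psi, max psi] if all replicate fits have p < alpha, else
    None (the break is not reported unless both flumes support it).
    """
    if len(fits) < 2:
        raise FitError("consensus needs >= 2 replicate fits")
    if any(f.p_value is None for f in fits):
        raise FitError("all fits need p_value set (run breakpoint_significance)")
    if all(f.p_value < alpha for f in fits):
        psis = [f.psi for f in fits]
        return (float(min(psis)), float(max(psis)))
    return None
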