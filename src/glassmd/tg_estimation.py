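"""Trend-shift (break-point) estimation of the glass transition temperature.

A thermal scan of an observable y(T) — density or self-diffusivity — is
fitted with a continuous two-segment ("hinge") linear model

    y(T) = c + b_L (T - T_b)  for T <  T_b
    y(T) = c + b_R (T - T_b)  for T >= T_b,

where the break temperature T_b is the glass transition estimate: the
liquid branch of the density expands (contracts on cooling) more steeply
than the glass branch, and the self-diffusivity rises from a statistically
zero glassy floor above T_b.  The break is located by an exhaustive search
over interior knots followed by bounded local refinement of the profiled
weighted sum of squares; its standard deviation comes from the delta
method on the full four-parameter Jacobian at the optimum.

An independent-two-lines variant (two unconstrained lines, T_b at their
intersection, closed-form error propagation) is provided both as an
alternative reading of the trend-shift construction and as an analytic
cross-check of the hinge-parameterization uncertainty.

Density- and diffusivity-derived estimates are combined as their plain
average; a consistency flag is raised when they disagree by more than
25 K, the empirical bound observed for well-behaved scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "ThermalScan",
    "BreakpointFit",
    "TgEstimate",
    "CONSISTENCY_GAP_K",
    "fit_two_segment",
    "fit_two_lines",
    "intersection_sd",
    "propagate_uncertainty",
    "tg_from_density",
    "tg_from_diffusivity",
    "combine_tg",
]

CONSISTENCY_GAP_K = 25.0


@dataclass
class ThermalScan:
    """Per-temperature aggregated density and diffusivity with uncertainties.

    ``T`` is strictly increasing (K); ``rho`` in g/cm³, ``D`` in Å²/fs.
    Either observable may be absent (``None``).  ``truth`` optionally
    carries the generating ground truth of synthetic scans.
    """

    T: np.ndarray
    rho: np.ndarray | None = None
    rho_sd: np.ndarray | None = None
    D: np.ndarray | None = None
    D_sd: np.ndarray | None = None
    composition: object | None = None
    truth: object | None = None

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        if np.any(np.diff(self.T) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        # break-point fitting needs >= 2*min_points_per_side points, but a
        # scan as a container may be any length (single-temperature runs)
        for name in ("rho", "rho_sd", "D", "D_sd"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if len(v) != len(self.T):
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, v)

    def __len__(self) -> int:
        return len(self.T)


@dataclass
class BreakpointFit:
    """Continuous two-segment weighted least-squares fit.

    Parameter order in ``cov`` is (level c, left slope b_L, right slope
    b_R, break x_b).  ``no_break`` is set when the two slopes are
    indistinguishable within noise, i.e. the data are consistent with one
    straight line; the fit is still reported.
    """

    x_b: float
    slope_left: float
    slope_right: float
    level: float
    cov: np.ndarray
    resid_sd: float
    n_left: int
    n_right: int
    no_break: bool = False

    @property
    def x_b_sd(self) -> float:
        return propagate_uncertainty(self)


@dataclass
class TgEstimate:
    """Combined glass-transition estimate from the two observables."""

    tg_rho: float | None
    tg_rho_sd: float | None
    tg_D: float | None
    tg_D_sd: float | None
    tg_avg: float
    tg_avg_sd: float
    consistency_gap: float | None
    consistent: bool
    combined: bool


def _hinge_design(x: np.ndarray, x_b: float) -> np.ndarray:
    d = x - x_b
    return np.column_stack([np.ones_like(x),
                            np.minimum(d, 0.0),
                            np.maximum(d, 0.0)])


def _wls(A: np.ndarray, y: np.ndarray, w: np.ndarray
         ) -> tuple[np.ndarray, float]:
    Aw = A * w[:, None]
    beta, *_ = np.linalg.lstsq(Aw.T @ A, Aw.T @ y, rcond=None)
    r = y - A @ beta
    return beta, float(r @ (w * r))


def fit_two_segment(x: np.ndarray, y: np.ndarray,
                    weights: np.ndarray | None = None,
                    min_points_per_side: int = 3) -> BreakpointFit:
    """Fit the continuous hinge model with the break located by search.

    The profiled weighted SSR is evaluated at every admissible interior
    data point, then refined continuously between the neighbours of the
    best knot; SSR ties break toward the lower x (conservative, lower Tg).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if min_points_per_side < 3:
        raise ValueError("min_points_per_side must be >= 3")
    if n < 2 * min_points_per_side:
        raise ValueError("not enough points for two segments")
    order = np.argsort(x)
    x, y = x[order], y[order]
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)[order]
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
    # admissible knots: >= min_points strictly left, >= min_points right
    lo_idx = min_points_per_side
    hi_idx = n - min_points_per_side
    if lo_idx > hi_idx:
        raise ValueError("no admissible interior knot")
    candidates = x[lo_idx:hi_idx + 1]

    def ssr_at(xb: float) -> float:
        return _wls(_hinge_design(x, xb), y, w)[1]

    # profile the SSR: evaluate at every admissible knot, then refine
    # continuously inside every bracketing interval (the profiled SSR is
    # only piecewise smooth, so a single local refinement could miss the
    # global optimum); ties break toward the lower x (conservative Tg)
    best_x = float(candidates[0])
    best_ssr = ssr_at(best_x)
    for c in candidates[1:]:
        s = ssr_at(float(c))
        if s < best_ssr * (1 - 1e-12):
            best_ssr, best_x = s, float(c)
    for k in range(lo_idx, hi_idx):
        a, b = x[k], x[k + 1]
        if b <= a:
            continue
        res = minimize_scalar(ssr_at, bounds=(a, b), method="bounded",
                              options={"xatol": 1e-8})
        if res.fun < best_ssr * (1 - 1e-12) or (
                res.fun < best_ssr * (1 + 1e-12) and res.x < best_x):
            if res.fun < best_ssr * (1 - 1e-12):
                best_ssr, best_x = float(res.fun), float(res.x)
    x_b = best_x
    A = _hinge_design(x, x_b)
    beta, ssr = _wls(A, y, w)
    c, b_l, b_r = beta
    # full Jacobian including the knot position
    dy_dxb = np.where(x < x_b, -b_l, -b_r)
    J = np.column_stack([A, dy_dxb])
    dof = max(n - 4, 1)
    s2 = ssr / dof
    JtWJ = (J * w[:, None]).T @ J
    try:
        cov = np.linalg.inv(JtWJ) * s2
    except np.linalg.LinAlgError:
        cov = np.full((4, 4), np.nan)
    slope_diff_sd = float(np.sqrt(max(cov[1, 1] + cov[2, 2]
                                      - 2 * cov[1, 2], 0.0)))
    no_break = abs(b_r - b_l) <= 2.0 * slope_diff_sd
    return BreakpointFit(
        x_b=x_b, slope_left=float(b_l), slope_right=float(b_r),
        level=float(c), cov=cov, resid_sd=float(np.sqrt(s2)),
        n_left=int(np.sum(x < x_b)), n_right=int(np.sum(x >= x_b)),
        no_break=bool(no_break))


def propagate_uncertainty(fit: BreakpointFit) -> float:
    """Delta-method standard deviation of the break position.

    Reads the (x_b, x_b) element of the four-parameter covariance; NaN
    (singular information matrix) propagates as NaN, flagging the
    uncertainty as undefined.
    """
    v = fit.cov[3, 3]
    if not np.isfinite(v):
        return float("nan")
    return float(np.sqrt(max(v, 0.0)))


def fit_two_lines(x: np.ndarray, y: np.ndarray,
                  weights: np.ndarray | None = None,
                  min_points_per_side: int = 3) -> BreakpointFit:
    """Independent-two-lines variant: unconstrained lines on each side of a
    partition, break at their intersection x* = (a1-a2)/(b2-b1).

    The partition is chosen by exhaustive search over admissible splits;
    the break uncertainty follows from the closed-form gradient of the
    intersection (see :func:`intersection_sd`).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    order = np.argsort(x)
    x, y = x[order], y[order]
    w = (np.ones(n) if weights is None
         else np.asarray(weights, dtype=float)[order])
    m = min_points_per_side
    best = None
    for split in range(m, n - m + 1):
        pl, cl = _line_fit(x[:split], y[:split], w[:split])
        pr, cr = _line_fit(x[split:], y[split:], w[split:])
        rl = y[:split] - (pl[0] + pl[1] * x[:split])
        rr = y[split:] - (pr[0] + pr[1] * x[split:])
        ssr = float(rl @ (w[:split] * rl) + rr @ (w[split:] * rr))
        if best is None or ssr < best[0] - 1e-300:
            best = (ssr, split, pl, cl, pr, cr)
    ssr, split, (a1, b1), cov_l, (a2, b2), cov_r = best
    if abs(b2 - b1) < 1e-300:
        raise ValueError("parallel branch lines: no intersection")
    x_b = (a1 - a2) / (b2 - b1)
    cov_params = np.zeros((4, 4))
    cov_params[:2, :2] = cov_l
    cov_params[2:, 2:] = cov_r
    sd = intersection_sd(a1, b1, a2, b2, cov_params)
    dof = max(n - 4, 1)
    cov = np.full((4, 4), np.nan)
    cov[3, 3] = sd ** 2
    level = a1 + b1 * x_b
    cov[0, 0] = 0.0
    return BreakpointFit(
        x_b=float(x_b), slope_left=float(b1), slope_right=float(b2),
        level=float(level), cov=cov, resid_sd=float(np.sqrt(ssr / dof)),
        n_left=split, n_right=n - split,
        no_break=False)


def _line_fit(x: np.ndarray, y: np.ndarray, w: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
    A = np.column_stack([np.ones_like(x), x])
    Aw = A * w[:, None]
    M = Aw.T @ A
    beta = np.linalg.solve(M, Aw.T @ y)
    r = y - A @ beta
    dof = max(len(x) - 2, 1)
    s2 = float(r @ (w * r)) / dof
    return beta, np.linalg.inv(M) * s2


def intersection_sd(a1: float, b1: float, a2: float, b2: float,
                    cov: np.ndarray) -> float:
    """Closed-form delta-method sd of x* = (a1-a2)/(b2-b1).

    ``cov`` is the 4x4 covariance of (a1, b1, a2, b2).  The analytic
    gradient is (1, x*, -1, -x*) / (b2 - b1).
    """
    db = b2 - b1
    if db == 0:
        raise ValueError("parallel lines have no intersection")
    x_star = (a1 - a2) / db
    grad = np.array([1.0, x_star, -1.0, -x_star]) / db
    var = float(grad @ np.asarray(cov, dtype=float) @ grad)
    return float(np.sqrt(max(var, 0.0)))


def _weights_from_sd(sd: np.ndarray | None, n: int) -> np.ndarray | None:
    if sd is None:
        return None
    sd = np.asarray(sd, dtype=float)
    pos = sd[sd > 0]
    if len(pos) == 0:
        return None
    floor = pos.min()
    sd_eff = np.where(sd > 0, sd, floor)
    return 1.0 / sd_eff ** 2


@dataclass
class BranchResult:
    """Tg from one observable branch, with the underlying fit."""

    tg: float
    sd: float
    fit: BreakpointFit


def tg_from_density(scan: ThermalScan,
                    min_points_per_side: int = 3,
                    method: str = "hinge") -> BranchResult:
    """Density-derived Tg: break point of rho(T), weighted by 1/sd²."""
    if scan.rho is None:
        raise ValueError("scan has no density data")
    fitter = fit_two_segment if method == "hinge" else fit_two_lines
    fit = fitter(scan.T, scan.rho,
                 weights=_weights_from_sd(scan.rho_sd, len(scan)),
                 min_points_per_side=min_points_per_side)
    return BranchResult(tg=fit.x_b, sd=propagate_uncertainty(fit), fit=fit)


def tg_from_diffusivity(scan: ThermalScan,
                        min_points_per_side: int = 3,
                        method: str = "hinge") -> BranchResult:
    """Diffusivity-derived Tg: break point of D(T) on the linear scale.

    The glassy branch is a near-zero floor, so the fit stays on the linear
    D scale (the logarithm of a statistically zero D is undefined).
    """
    if scan.D is None:
        raise ValueError("scan has no diffusivity data")
    if np.all(scan.D == 0):
        raise ValueError("diffusivity identically zero: insufficient signal")
    fitter = fit_two_segment if method == "hinge" else fit_two_lines
    fit = fitter(scan.T, scan.D,
                 weights=_weights_from_sd(scan.D_sd, len(scan)),
                 min_points_per_side=min_points_per_side)
    return BranchResult(tg=fit.x_b, sd=propagate_uncertainty(fit), fit=fit)


def combine_tg(tg_rho: tuple[float, float] | BranchResult | None,
               tg_D: tuple[float, float] | BranchResult | None,
               gap_threshold: float = CONSISTENCY_GAP_K) -> TgEstimate:
    """Average the density- and diffusivity-derived Tg.

    The combined value is the arithmetic mean with quadrature/2 standard
    deviation; the consistency flag trips when the two branches differ by
    more than ``gap_threshold`` (default 25 K).  A single present branch
    is passed through marked uncombined.
    """
    def _unpack(v):
        if v is None:
            return None
        if isinstance(v, BranchResult):
            return v.tg, v.sd
        return float(v[0]), float(v[1])

    r = _unpack(tg_rho)
    d = _unpack(tg_D)
    if r is None and d is None:
        raise ValueError("at least one branch is required")
    if r is None or d is None:
        tg, sd = r if r is not None else d
        return TgEstimate(
            tg_rho=r[0] if r else None, tg_rho_sd=r[1] if r else None,
            tg_D=d[0] if d else None, tg_D_sd=d[1] if d else None,
            tg_avg=tg, tg_avg_sd=sd, consistency_gap=None,
            consistent=True, combined=False)
    gap = abs(r[0] - d[0])
    return TgEstimate(
        tg_rho=r[0], tg_rho_sd=r[1], tg_D=d[0], tg_D_sd=d[1],
        tg_avg=(r[0] + d[0]) / 2.0,
        tg_avg_sd=float(np.hypot(r[1], d[1]) / 2.0),
        consistency_gap=gap, consistent=bool(gap <= gap_threshold),
        combined=True)
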