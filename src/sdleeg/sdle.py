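"""Scale-dependent Lyapunov exponent (SDLE) estimation.

The SDLE λ(ε) measures how fast two phase-space trajectories a distance ε
apart diverge: ε_{t+Δt} = ε_t · exp(λ(ε_t) Δt). It is estimated by

1. collecting vector pairs whose initial separation falls in a thin
   *shell* [ε, ε+Δε),
2. evolving all pairs in a shell forward and recording the mean
   log-separation ln ε_t (the *error-growth curve*),
3. differencing: λ(ε_t) = (ln ε_{t+Δt} − ln ε_t)/Δt, plotted against
   ln ε_t.

Four shells are used, the largest with diameter SD/10 of the signal and
each successive shell half the size, and the four SDLE curves are averaged
on a common ln ε grid. Scalp EEG follows the scaling law λ(ε) ~ −γ ln ε
over a range of scales; the fitted scaling region provides the feature
scales ε₁ (smallest), ε₂ (geometric midpoint), and ε₃ (boundary).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .embedding import EmbeddingParams, PhasePoints, reconstruct

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)
_TINY = np.finfo(float).tiny


class DegenerateSeriesError(ValueError):
    """Raised for constant input where shells cannot be sized."""


@dataclass(frozen=True)
class ShellSpec:
    """Distance band [eps, eps + d_eps) selecting initial pairs.

    Shell ``index`` 0 is the largest; each following shell is smaller by
    the shrink factor. ``d_eps == eps`` by default (one-octave shells), so
    the shrinking cascade tiles the scale axis without gaps. ``eps == 0``
    degenerates to a ball of radius ``d_eps``.
    """

    eps: float
    d_eps: float
    index: int = 0

    def __post_init__(self) -> None:
        if self.eps < 0 or self.d_eps <= 0:
            raise ValueError("shell requires eps >= 0 and d_eps > 0")


@dataclass
class ErrorGrowthCurve:
    """Mean log-separation ln ε_t of within-shell pairs vs time t."""

    t: np.ndarray
    ln_eps_t: np.ndarray
    pair_count: np.ndarray
    shell: ShellSpec


@dataclass
class SDLECurve:
    """λ(ε) sampled on a strictly increasing ln ε grid."""

    ln_eps: np.ndarray
    lam: np.ndarray
    per_shell: list["SDLECurve"] | None = None
    weight: np.ndarray | None = None  # pair counts, for weighted averaging


@dataclass
class ScalingFit:
    """Least-squares fit of λ = −γ ln ε + c over the scaling region."""

    gamma: float
    intercept: float
    region: tuple[float, float]  # (ln eps_min, ln eps_max)
    r2: float
    degraded: bool = False


@dataclass
class SDLEFeatures:
    """Per-epoch SDLE summary at the scaling-region scales."""

    lam1: float
    lam2: float
    lam3: float
    lam_bar: float
    eps1: float
    eps2: float
    eps3: float
    eps_inf: float | None = None
    T_db: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class SDLEConfig:
    """Tunable knobs of the estimator (defaults follow the shell recipe)."""

    m: int = 2
    L: int = 1
    n_shells: int = 4
    first_shell_fraction: float = 0.1
    shrink_factor: float = 0.5
    theiler: int | None = None     # None -> (m-1)L + 1
    dt: int = 1
    t_max: int = 64
    min_pairs: int = 10
    max_pairs: int | None = 200    # deterministic cap per shell
    r2_min: float = 0.95
    ball_smallest: bool = False    # smallest shell as a ball (eps=0)
    count_weighted: bool = False   # weight shell average by pair counts
    grid_points: int = 80          # cross-channel common-grid resolution


def build_shells(x: np.ndarray, n_shells: int = 4,
                 first_fraction: float = 0.1, shrink: float = 0.5,
                 ball_smallest: bool = False) -> list[ShellSpec]:
    """Shell cascade sized from the signal's standard deviation.

    Shell k has diameter ``first_fraction * SD(x) * shrink**k`` and equal
    thickness. Sizes scale with the signal, so the cascade is
    amplitude-equivariant.
    """
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x))
    if sd == 0:
        raise DegenerateSeriesError("constant series: shells cannot be sized")
    shells = []
    for k in range(n_shells):
        size = first_fraction * sd * shrink ** k
        eps = 0.0 if (ball_smallest and k == n_shells - 1) else size
        shells.append(ShellSpec(eps=eps, d_eps=size, index=k))
    return shells


def find_shell_pairs(points: PhasePoints, shell: ShellSpec,
                     theiler: int = 2) -> np.ndarray:
    """All index pairs (i<j) whose vectors lie in the shell, lexicographic.

    Pairs with ``|i - j| <= theiler`` are excluded (Theiler window).
    Returns an (n_pairs, 2) integer array; possibly empty.
    """
    d, ii, jj = _condensed_distances(points.vectors)
    mask = (d >= shell.eps) & (d <= shell.eps + shell.d_eps) \
        & (jj - ii > theiler)
    return np.column_stack([ii[mask], jj[mask]])


def _condensed_distances(vectors: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = vectors.shape[0]
    d = pdist(vectors)  # condensed order == lexicographic (i<j)
    ii = np.repeat(np.arange(n - 1), np.arange(n - 1, 0, -1))
    jj = np.concatenate([np.arange(i + 1, n) for i in range(n - 1)])
    return d, ii, jj


def subsample_pairs(pairs: np.ndarray, max_pairs: int | None) -> np.ndarray:
    """Deterministic evenly-spaced thinning of a pair list."""
    if max_pairs is None or len(pairs) <= max_pairs:
        return pairs
    keep = np.linspace(0, len(pairs) - 1, max_pairs).round().astype(int)
    return pairs[np.unique(keep)]


def error_growth(points: PhasePoints, pairs: np.ndarray,
                 t_max: int = 64, dt: int = 1,
                 shell: ShellSpec | None = None) -> ErrorGrowthCurve:
    """Evolve within-shell pairs and average their log-separations.

    ``ln_eps_t[k]`` is the mean over surviving pairs of
    ``ln ||V_{i+t} - V_{j+t}||`` at ``t = k*dt`` (logarithm taken before
    averaging). Pairs whose evolved indices run past the end of the
    trajectory are dropped at each t; the curve truncates (with a warning)
    if all pairs are exhausted before ``t_max``.
    """
    pairs = np.asarray(pairs)
    if len(pairs) == 0:
        raise ValueError("error_growth requires at least one pair")
    V = points.vectors
    n = V.shape[0]
    I, J = pairs[:, 0], pairs[:, 1]
    ts, lns, counts = [], [], []
    for t in range(0, t_max + 1, dt):
        alive = J + t < n  # j > i, so j is the binding index
        if not alive.any():
            logger.warning("all pairs exhausted at t=%d; curve truncated", t)
            break
        diff = V[I[alive] + t] - V[J[alive] + t]
        dist = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        lns.append(float(np.mean(np.log(np.maximum(dist, _TINY)))))
        counts.append(int(alive.sum()))
        ts.append(t)
    if shell is None:
        shell = ShellSpec(eps=0.0, d_eps=np.inf, index=-1)
    return ErrorGrowthCurve(
        t=np.asarray(ts, dtype=float),
        ln_eps_t=np.asarray(lns),
        pair_count=np.asarray(counts),
        shell=shell,
    )


def sdle_from_growth(curve: ErrorGrowthCurve) -> SDLECurve:
    """Finite-difference the growth curve: λ(ε_t) = Δ ln ε_t / Δt.

    Each λ value is attached to the abscissa ln ε_t of the *earlier* time
    point; λ may be negative where separations shrink. Points are sorted
    by abscissa (duplicates averaged) so the grid is strictly increasing.
    """
    if len(curve.t) < 2:
        raise ValueError("growth curve needs at least two points")
    lam = np.diff(curve.ln_eps_t) / np.diff(curve.t)
    ln_eps = curve.ln_eps_t[:-1]
    weight = curve.pair_count[:-1].astype(float)
    order = np.argsort(ln_eps, kind="stable")
    ln_eps, lam, weight = ln_eps[order], lam[order], weight[order]
    grid, inverse = np.unique(ln_eps, return_inverse=True)
    if len(grid) < len(ln_eps):  # average duplicated abscissae
        lam = np.bincount(inverse, weights=lam) / np.bincount(inverse)
        weight = np.bincount(inverse, weights=weight) / np.bincount(inverse)
        ln_eps = grid
    return SDLECurve(ln_eps=ln_eps, lam=lam, weight=weight)


def average_sdle(curves: list[SDLECurve], grid_points: int | None = None,
                 count_weighted: bool = False) -> SDLECurve:
    """Average several SDLE curves on a common ln ε grid.

    The grid is the union of the curves' abscissae clipped to their
    overlapping range (or a uniform grid of ``grid_points`` over that
    range); each curve is linearly interpolated onto it and the arithmetic
    (optionally pair-count-weighted) mean taken. Disjoint curves fall
    back to plain concatenation with a warning.
    """
    curves = [c for c in curves if len(c.ln_eps) > 0]
    if not curves:
        raise ValueError("no curves to average")
    if len(curves) == 1:
        c = curves[0]
        return SDLECurve(ln_eps=c.ln_eps.copy(), lam=c.lam.copy(),
                         per_shell=curves)
    lo = max(c.ln_eps[0] for c in curves)
    hi = min(c.ln_eps[-1] for c in curves)
    if hi <= lo:
        logger.warning("disjoint SDLE curves; concatenating instead")
        ln_all = np.concatenate([c.ln_eps for c in curves])
        lam_all = np.concatenate([c.lam for c in curves])
        order = np.argsort(ln_all, kind="stable")
        return SDLECurve(ln_eps=ln_all[order], lam=lam_all[order],
                         per_shell=curves)
    if grid_points is None:
        grid = np.unique(np.concatenate(
            [c.ln_eps[(c.ln_eps >= lo) & (c.ln_eps <= hi)] for c in curves]
        ))
        if len(grid) == 0:
            grid = np.array([lo, hi])
    else:
        grid = np.linspace(lo, hi, grid_points)
    lam_stack = np.vstack([np.interp(grid, c.ln_eps, c.lam) for c in curves])
    if count_weighted:
        w_stack = np.vstack([
            np.interp(grid, c.ln_eps,
                      c.weight if c.weight is not None
                      else np.ones_like(c.ln_eps))
            for c in curves
        ])
        lam_mean = (lam_stack * w_stack).sum(axis=0) / w_stack.sum(axis=0)
    else:
        lam_mean = lam_stack.mean(axis=0)
    return SDLECurve(ln_eps=grid, lam=lam_mean, per_shell=curves)


def fit_scaling(curve: SDLECurve, r2_min: float = 0.95,
                min_window_frac: float = 0.4) -> ScalingFit:
    """Fit λ = −γ ln ε + c over the longest high-r² contiguous window.

    Sliding windows of at least ``min_window_frac`` of the curve length
    are scanned; the longest with r² >= ``r2_min`` wins, ties resolved
    toward larger scales. If none qualifies the full curve is fitted and
    flagged ``degraded``. γ is reported as the slope magnitude.
    """
    x, y = curve.ln_eps, curve.lam
    n = len(x)
    if n < 5:
        raise ValueError("scaling fit needs at least 5 curve points")
    min_len = max(5, int(math.ceil(min_window_frac * n)))
    sx = np.concatenate(([0.0], np.cumsum(x)))
    sy = np.concatenate(([0.0], np.cumsum(y)))
    sxx = np.concatenate(([0.0], np.cumsum(x * x)))
    syy = np.concatenate(([0.0], np.cumsum(y * y)))
    sxy = np.concatenate(([0.0], np.cumsum(x * y)))
    y_scale = max(float(np.abs(y).max()), 1e-12)

    def window_stats(length: int):
        starts = np.arange(0, n - length + 1)
        ends = starts + length
        k = float(length)
        mx = (sx[ends] - sx[starts]) / k
        my = (sy[ends] - sy[starts]) / k
        cov = (sxy[ends] - sxy[starts]) / k - mx * my
        vx = (sxx[ends] - sxx[starts]) / k - mx * mx
        vy = (syy[ends] - syy[starts]) / k - my * my
        slope = np.where(vx > 0, cov / np.maximum(vx, 1e-300), 0.0)
        ss_res = np.maximum(vy - slope * cov, 0.0)
        flat = vy <= (1e-12 * y_scale) ** 2
        r2 = np.where(flat, 1.0, 1.0 - ss_res / np.maximum(vy, 1e-300))
        return starts, slope, my - slope * mx, r2

    for length in range(n, min_len - 1, -1):
        starts, slope, intercept, r2 = window_stats(length)
        ok = np.flatnonzero(r2 >= r2_min)
        if len(ok):
            best = ok[-1]  # tie -> larger-scale window
            s = starts[best]
            return ScalingFit(
                gamma=abs(float(slope[best])),
                intercept=float(intercept[best]),
                region=(float(x[s]), float(x[s + length - 1])),
                r2=float(min(r2[best], 1.0)),
            )
    starts, slope, intercept, r2 = window_stats(n)
    logger.info("no window reached r2 >= %.3f; degraded full-curve fit",
                r2_min)
    return ScalingFit(gamma=abs(float(slope[0])), intercept=float(intercept[0]),
                      region=(float(x[0]), float(x[-1])),
                      r2=float(min(r2[0], 1.0)), degraded=True)


def extract_features(curve: SDLECurve, fit: ScalingFit,
                     eps_inf: float | None = None,
                     T_db: float | None = None) -> SDLEFeatures:
    """Read λ at the scaling-region scales ε₁ < ε₂ < ε₃.

    ε₁ and ε₃ are the region's smallest and boundary scales, ε₂ the
    geometric midpoint (arithmetic in ln ε); λ values are interpolated
    from the averaged curve and λ̄ is their mean.
    """
    ln1, ln3 = fit.region
    flags: list[str] = []
    in_region = (curve.ln_eps >= ln1 - 1e-12) & (curve.ln_eps <= ln3 + 1e-12)
    if int(in_region.sum()) < 3:
        flags.append("narrow_region")
    ln2 = 0.5 * (ln1 + ln3)
    lam1, lam2, lam3 = np.interp([ln1, ln2, ln3], curve.ln_eps, curve.lam)
    if fit.degraded:
        flags.append("degraded_fit")
    return SDLEFeatures(
        lam1=float(lam1), lam2=float(lam2), lam3=float(lam3),
        lam_bar=float(np.mean([lam1, lam2, lam3])),
        eps1=float(np.exp(ln1)), eps2=float(np.exp(ln2)),
        eps3=float(np.exp(ln3)),
        eps_inf=eps_inf, T_db=T_db, flags=flags,
    )


def error_doubling_time(curve: ErrorGrowthCurve) -> float | None:
    """Time for the mean separation to double: first crossing of 2ε₀.

    Linear interpolation of ln ε_t to ln ε₀ + ln 2; by the telescoping of
    the finite differences, integrating λ(ε_t) over [0, T_db] returns
    ln 2 to interpolation accuracy. Returns None if the curve never
    doubles.
    """
    target = curve.ln_eps_t[0] + LN2
    above = np.flatnonzero(curve.ln_eps_t >= target)
    if len(above) == 0:
        logger.info("separation never doubles within the curve")
        return None
    k = int(above[0])
    if k == 0:
        return 0.0
    t0, t1 = curve.t[k - 1], curve.t[k]
    y0, y1 = curve.ln_eps_t[k - 1], curve.ln_eps_t[k]
    return float(t0 + (target - y0) * (t1 - t0) / (y1 - y0))


def attractor_size(curve: ErrorGrowthCurve, tail_frac: float = 0.25) -> float:
    """Saturation scale ε_∞: plateau of the growth curve's tail."""
    n = len(curve.ln_eps_t)
    k = max(1, int(round(tail_frac * n)))
    return float(np.exp(np.mean(curve.ln_eps_t[-k:])))


def channel_sdle(x: np.ndarray, cfg: SDLEConfig = SDLEConfig()
                 ) -> tuple[SDLECurve, list[ErrorGrowthCurve]]:
    """Full single-channel chain: shells → pairs → growth → averaged SDLE.

    Shells with fewer than ``min_pairs`` qualifying pairs are dropped
    (logged); pair lists are deterministically capped at ``max_pairs``
    for speed. Returns the shell-averaged SDLE curve (with per-shell
    curves attached) and the per-shell growth curves.
    """
    params = EmbeddingParams(m=cfg.m, L=cfg.L)
    points = reconstruct(x, params)
    theiler = cfg.theiler if cfg.theiler is not None \
        else (cfg.m - 1) * cfg.L + 1
    shells = build_shells(x, cfg.n_shells, cfg.first_shell_fraction,
                          cfg.shrink_factor, cfg.ball_smallest)
    d, ii, jj = _condensed_distances(points.vectors)
    sep_ok = jj - ii > theiler
    growth_curves: list[ErrorGrowthCurve] = []
    sdle_curves: list[SDLECurve] = []
    for shell in shells:
        mask = sep_ok & (d >= shell.eps) & (d <= shell.eps + shell.d_eps)
        pairs = np.column_stack([ii[mask], jj[mask]])
        if len(pairs) < cfg.min_pairs:
            logger.info("shell %d: only %d pairs (< %d); dropped",
                        shell.index, len(pairs), cfg.min_pairs)
            continue
        pairs = subsample_pairs(pairs, cfg.max_pairs)
        growth = error_growth(points, pairs, t_max=cfg.t_max, dt=cfg.dt,
                              shell=shell)
        if len(growth.t) < 2:
            continue
        growth_curves.append(growth)
        sdle_curves.append(sdle_from_growth(growth))
    if not sdle_curves:
        raise EstimationSizeError(
            "no shell produced enough pairs for an SDLE estimate"
        )
    avg = average_sdle(sdle_curves, count_weighted=cfg.count_weighted)
    return avg, growth_curves


class EstimationSizeError(RuntimeError):
    """Raised when no shell holds enough pairs for estimation."""


def epoch_sdle(epoch_data: np.ndarray, cfg: SDLEConfig = SDLEConfig()
               ) -> tuple[SDLEFeatures, SDLECurve, ScalingFit]:
    """Per-epoch SDLE features, averaged across channels.

    Each channel (row) yields a shell-averaged SDLE curve; the channel
    curves are averaged on a uniform common ln ε grid, the scaling law
    fitted, and features extracted. ε_∞ is the geometric mean of the
    per-channel largest-shell plateaus; T_db the mean per-channel error
    doubling time of the smallest usable shell.
    """
    epoch_data = np.atleast_2d(np.asarray(epoch_data, dtype=float))
    channel_curves: list[SDLECurve] = []
    ln_eps_inf: list[float] = []
    t_dbs: list[float] = []
    for row in epoch_data:
        try:
            curve, growths = channel_sdle(row, cfg)
        except (DegenerateSeriesError, EstimationSizeError, ValueError) as exc:
            logger.warning("channel skipped: %s", exc)
            continue
        channel_curves.append(curve)
        largest = min(growths, key=lambda g: g.shell.index)
        smallest = max(growths, key=lambda g: g.shell.index)
        ln_eps_inf.append(math.log(attractor_size(largest)))
        tdb = error_doubling_time(smallest)
        if tdb is not None:
            t_dbs.append(tdb)
    if not channel_curves:
        raise EstimationSizeError("no channel produced an SDLE curve")
    epoch_curve = average_sdle(channel_curves, grid_points=cfg.grid_points)
    fit = fit_scaling(epoch_curve, r2_min=cfg.r2_min)
    eps_inf = float(np.exp(np.mean(ln_eps_inf))) if ln_eps_inf else None
    T_db = float(np.mean(t_dbs)) if t_dbs else None
    feats = extract_features(epoch_curve, fit, eps_inf=eps_inf, T_db=T_db)
    return feats, epoch_curve, fit
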