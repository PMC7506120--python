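"""Delay-coordinate phase-space reconstruction and embedding selection.

A scalar series x(1..n) is embedded as vectors
``V_i = [x(i), x(i+L), ..., x(i+(m-1)L)]`` with dimension ``m`` and delay
``L``. The delay is chosen dynamically: among candidate delays, pick the
one for which initially-close phase points diverge least over short times
(for a sinusoid this recovers the classical L = period/4, which turns the
embedded ellipse into a circle where motion is most uniform). The
dimension is the smallest one beyond which that short-time divergence
stops growing appreciably.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import signal as sps

if TYPE_CHECKING:  # pragma: no cover
    from .sdle import ShellSpec

logger = logging.getLogger(__name__)

#: Fallback short-time window (samples) for the divergence summary.
T_EVAL_CAP = 32


class EstimationError(RuntimeError):
    """Raised when a divergence estimate cannot be formed (e.g. no pairs)."""


@dataclass(frozen=True)
class EmbeddingParams:
    """Embedding dimension ``m`` (>= 2) and delay ``L`` (>= 1, samples)."""

    m: int = 2
    L: int = 1
    min_vectors: int = 100

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("embedding dimension m must be >= 2")
        if self.L < 1:
            raise ValueError("delay L must be >= 1")


@dataclass
class PhasePoints:
    """Embedded trajectory: ``vectors[k] = (x[k], x[k+L], ...)``."""

    vectors: np.ndarray          # (n_points, m)
    origin_index: np.ndarray     # sample index of each vector
    params: EmbeddingParams

    def __len__(self) -> int:
        return self.vectors.shape[0]


def reconstruct(x: np.ndarray, params: EmbeddingParams) -> PhasePoints:
    """Exact sliding-window delay embedding; no normalization applied."""
    x = np.asarray(x, dtype=float).ravel()
    m, L = params.m, params.L
    span = (m - 1) * L
    n_vec = len(x) - span
    if n_vec < 2:
        raise ValueError(
            f"series of length {len(x)} too short for m={m}, L={L}: "
            f"needs at least {span + 2} samples"
        )
    idx = np.arange(n_vec)[:, None] + np.arange(m)[None, :] * L
    return PhasePoints(vectors=x[idx], origin_index=np.arange(n_vec),
                       params=params)


def _default_theiler(params: EmbeddingParams) -> int:
    # exclude temporal neighbors so autocorrelation doesn't mimic convergence
    return (params.m - 1) * params.L + 1


def time_dependent_exponent(x: np.ndarray, params: EmbeddingParams,
                            shell: "ShellSpec", t_max: int = T_EVAL_CAP,
                            theiler: int | None = None,
                            max_pairs: int | None = 2000,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Mean log-separation growth of within-shell pairs vs evolution time.

    Returns ``(t, lam_t)`` where ``lam_t[k] = <ln||V_{i+t}-V_{j+t}||> -
    <ln||V_i-V_j||>`` over pairs whose initial separation lies in the
    shell. Periodic series give bounded oscillating curves; noise
    saturates at the attractor size within a step or two.
    """
    from . import sdle as _sdle

    points = reconstruct(x, params)
    if theiler is None:
        theiler = _default_theiler(params)
    pairs = _sdle.find_shell_pairs(points, shell, theiler=theiler)
    if len(pairs) == 0:
        raise EstimationError(
            f"no pairs in shell [{shell.eps:g}, {shell.eps + shell.d_eps:g}]"
        )
    # keep a fixed ensemble over the whole window: pairs dropping out at
    # late t would otherwise shift the average without any divergence
    alive = pairs[:, 1] + t_max < len(points)
    if alive.any():
        pairs = pairs[alive]
    pairs = _sdle.subsample_pairs(pairs, max_pairs)
    curve = _sdle.error_growth(points, pairs, t_max=t_max, dt=1)
    return curve.t, curve.ln_eps_t - curve.ln_eps_t[0]


def _dominant_period(x: np.ndarray) -> int | None:
    """Period (samples) of the strongest periodogram peak, if any."""
    x = np.asarray(x, dtype=float)
    freqs, pxx = sps.periodogram(x, fs=1.0, detrend="constant")
    if len(pxx) < 3 or pxx[1:].max() <= 0:
        return None
    k = 1 + int(np.argmax(pxx[1:]))
    if freqs[k] <= 0:
        return None
    return int(round(1.0 / freqs[k]))


def _t_eval(x: np.ndarray) -> int:
    period = _dominant_period(x)
    if period is None:
        return T_EVAL_CAP
    return max(2, min(period, T_EVAL_CAP))


def divergence_summary(x: np.ndarray, params: EmbeddingParams,
                       t_eval: int | None = None) -> float:
    """Early-time mean of the time-dependent-exponent curve.

    Pairs are drawn from a broad distance band (0.1-0.4 of the signal's
    SD) rather than a thin estimation shell: the summary only compares
    embeddings, and a wide band keeps it well-populated even when a
    periodic signal's commensurate sampling quantizes pair distances.
    Band edges scale with SD, so the summary is invariant to amplitude
    rescaling of ``x``.
    """
    from . import sdle as _sdle

    if t_eval is None:
        t_eval = _t_eval(x)
    sd = float(np.std(x))
    if sd == 0:
        raise EstimationError("constant series has no divergence")
    # scale the band by sqrt(m/2) so summaries are comparable across
    # dimensions: random-pair distances grow like sqrt(m)
    f = np.sqrt(params.m / 2.0)
    shell = _sdle.ShellSpec(eps=0.1 * sd * f, d_eps=0.3 * sd * f)
    t, lam = time_dependent_exponent(x, params, shell, t_max=t_eval)
    return float(np.mean(lam[1:]))


#: Vector-count cap during embedding selection (speed; the criterion only
#: compares candidates, so a long series is subsampled from the front).
_SELECT_MAX_VECTORS = 2048


def select_delay(x: np.ndarray, m: int,
                 L_candidates: Sequence[int],
                 rel_tol: float = 0.05) -> int:
    """Pick the delay minimizing short-time divergence in phase space.

    The score is the magnitude of the divergence summary: motion on the
    most uniformly unfolded attractor neither diverges nor converges at
    short times (for a sinusoid the score vanishes at L = period/4,
    where the embedded ellipse becomes a circle). Candidates scoring
    within ``rel_tol`` (relative) of the minimum are treated as tied and
    the smallest such delay wins — structureless (i.i.d.) series, whose
    scores are all equal up to sampling noise, therefore select the
    smallest candidate.
    """
    if len(L_candidates) == 0:
        raise ValueError("L_candidates must be non-empty")
    x = np.asarray(x, dtype=float)
    t_eval = _t_eval(x)
    scores: dict[int, float] = {}
    for L in sorted(set(int(c) for c in L_candidates)):
        n_use = _SELECT_MAX_VECTORS + (m - 1) * L
        try:
            scores[L] = abs(divergence_summary(
                x[:n_use], EmbeddingParams(m=m, L=L), t_eval=t_eval))
        except (ValueError, EstimationError):
            continue
    if not scores:
        raise ValueError("no feasible delay candidate (series too short?)")
    best = min(scores.values())
    cutoff = best * (1.0 + rel_tol)
    for L in sorted(scores):  # ascending: smallest near-minimal delay wins
        if scores[L] <= cutoff:
            return L
    return min(scores, key=scores.get)  # pragma: no cover


def select_dimension(x: np.ndarray, L: int,
                     m_candidates: Sequence[int],
                     tol: float = 0.10, atol: float = 0.01) -> int:
    """Smallest dimension whose divergence score is near-minimal.

    Scores are the same banded divergence-summary magnitudes used for
    delay selection (the pair-selection band scales with sqrt(m) so
    dimensions are comparable). A dimension counts as near-minimal if its
    score is within the relative tolerance ``tol`` of the best candidate,
    or within ``atol`` nats absolutely (noise-free periodic signals drive
    the best scores to zero, where relative comparison degenerates).
    Increasing ``m`` past sufficiency leaves the divergence essentially
    unchanged, so the smallest near-minimal dimension is the answer; if
    every extra dimension keeps lowering the divergence appreciably, the
    largest candidate is returned with a warning.
    """
    cands = sorted(set(int(c) for c in m_candidates))
    if not cands:
        raise ValueError("m_candidates must be non-empty")
    if len(cands) == 1:
        return cands[0]
    x = np.asarray(x, dtype=float)
    t_eval = _t_eval(x)
    scores: dict[int, float] = {}
    for m in cands:
        try:
            scores[m] = abs(divergence_summary(
                x, EmbeddingParams(m=m, L=L), t_eval=t_eval))
        except (ValueError, EstimationError):
            continue
    if not scores:
        raise ValueError("no feasible dimension candidate")
    best = min(scores.values())
    cutoff = max(best * (1.0 + tol), best + atol)
    for m in sorted(scores):
        if scores[m] <= cutoff:
            if m == max(scores):
                logger.warning(
                    "divergence still shrinking at largest candidate m=%d",
                    m)
            return m
    return min(scores, key=scores.get)  # pragma: no cover
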