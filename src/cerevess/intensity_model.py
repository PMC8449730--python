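"""Finite mixture model of brain intensities and the volume-fraction threshold.

The brain-masked intensity histogram is modeled as a K-component Gaussian
mixture fitted by expectation-maximization.  The component with the largest
mean is treated as the vessel class (bright-blood angiography), and its
mixing weight W is the estimated intracranial vessel volume fraction.

Given W, the enhancement threshold Q is the value such that exactly a
fraction W of brain voxels have enhancement f_p >= Q, i.e. Q is the m-th
largest enhancement value with m = round(W * S) over the S brain voxels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import ValidationError

__all__ = ["MixtureModel", "ThresholdResult", "fit_fmm", "vessel_fraction",
           "threshold_from_fraction"]

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2 * math.pi)


@dataclass
class MixtureModel:
    """Fitted K-component Gaussian mixture over 1-D intensities."""

    weights: np.ndarray
    means: np.ndarray
    spreads: np.ndarray
    log_likelihood_trace: list[float]
    converged: bool
    n_iter: int

    @property
    def K(self) -> int:
        return len(self.weights)

    @property
    def vessel_index(self) -> int:
        return int(np.argmax(self.means))

    def component_logpdf(self, x: np.ndarray) -> np.ndarray:
        """(n, K) per-component log densities (no mixing weights)."""
        x = np.asarray(x, dtype=float)[..., None]
        z = (x - self.means) / self.spreads
        return -0.5 * (z ** 2 + _LOG_2PI) - np.log(self.spreads)

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        return logsumexp(self.component_logpdf(x) + np.log(self.weights), axis=-1)

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "spreads": self.spreads.tolist(),
            "vessel_index": self.vessel_index,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureModel":
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            means=np.asarray(d["means"], dtype=float),
            spreads=np.asarray(d["spreads"], dtype=float),
            log_likelihood_trace=list(d.get("log_likelihood_trace", [])),
            converged=bool(d.get("converged", True)),
            n_iter=int(d.get("n_iter", 0)),
        )


@dataclass(frozen=True)
class ThresholdResult:
    """Enhancement threshold Q realizing a target volume fraction W."""

    Q: float
    W: float
    S: int
    achieved_fraction: float


def _em_once(x: np.ndarray, weights: np.ndarray, means: np.ndarray,
             spreads: np.ndarray, tol: float, max_iter: int,
             min_spread: float):
    n = x.size
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step
        z = (x[:, None] - means) / spreads
        log_comp = -0.5 * (z ** 2 + _LOG_2PI) - np.log(spreads)
        log_joint = log_comp + np.log(weights)
        log_norm = logsumexp(log_joint, axis=1)
        ll = float(log_norm.sum())
        resp = np.exp(log_joint - log_norm[:, None])
        trace.append(ll)
        # M step
        nk = resp.sum(axis=0)
        keep = nk / n >= 1e-6
        if not np.all(keep):
            logger.warning(
                "pruning %d degenerate mixture component(s) with weight < 1e-6",
                int((~keep).sum()),
            )
            weights, means, spreads = weights[keep], means[keep], spreads[keep]
            weights = weights / weights.sum()
            continue
        weights = nk / n
        means = resp.T @ x / nk
        var = (resp * (x[:, None] - means) ** 2).sum(axis=0) / nk
        spreads = np.sqrt(np.maximum(var, min_spread ** 2))
        if len(trace) > 1:
            prev = trace[-2]
            if abs(ll - prev) <= tol * max(abs(prev), 1.0):
                converged = True
                break
    return weights, means, spreads, trace, converged, it


def fit_fmm(
    intensities: np.ndarray,
    K: int = 3,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
    n_restarts: int = 0,
) -> MixtureModel:
    """Fit a K-component Gaussian mixture to 1-D intensities by EM.

    Initialization is deterministic given the sample and encodes the two
    pieces of vessel knowledge the model rests on: vessels are bright and
    vessels are rare.  The K-1 background components start at evenly spaced
    percentiles of the sample with equal weights; the last component starts
    at the 99.9th percentile with initial weight 0.1, so a small bright
    class can be captured instead of being absorbed into the background.
    Spreads start at the pooled standard deviation.  ``seed`` only matters
    when ``n_restarts`` > 0, in which case additional random starts are
    tried and the best log-likelihood kept.
    The log-likelihood is non-decreasing across EM iterations; degenerate
    components (weight < 1e-6) are pruned with a logged warning.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if K < 2:
        raise ValidationError(f"K: must be >= 2, got {K}")
    if x.size < 10 * K:
        raise ValidationError(f"sample size {x.size} < 10*K = {10 * K}")
    if not np.all(np.isfinite(x)):
        raise ValidationError("intensities: contains non-finite values")

    pooled = float(x.std())
    if pooled == 0:
        raise ValidationError("intensities: zero variance, mixture undefined")
    min_spread = max(1e-6 * (x.max() - x.min()), 1e-12)

    def run(init_means: np.ndarray, init_weights: np.ndarray):
        s0 = np.full(len(init_means), pooled)
        return _em_once(x, init_weights.astype(float), init_means.astype(float),
                        s0, tol, max_iter, min_spread)

    # vessels are bright and rare: last component starts high and small
    vessel_w0 = 0.1
    pct = np.append(100.0 * np.arange(1, K) / K, 99.9)
    w0 = np.append(np.full(K - 1, (1.0 - vessel_w0) / (K - 1)), vessel_w0)
    best = run(np.percentile(x, pct), w0)
    if n_restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            cand = run(np.sort(rng.choice(x, size=K, replace=False)), w0)
            if cand[3][-1] > best[3][-1]:
                best = cand
    weights, means, spreads, trace, converged, it = best
    if len(weights) < 2:
        raise ValidationError("all but one component pruned; lower K or check data")
    return MixtureModel(weights, means, spreads, trace, converged, it)


def vessel_fraction(model: MixtureModel) -> float:
    """Mixing weight W of the vessel (largest-mean) component."""
    W = float(model.weights[model.vessel_index])
    if W <= 0:
        raise ValidationError(
            "vessel component weight is 0; check K or image contrast"
        )
    return W


def threshold_from_fraction(f: np.ndarray, W: float) -> ThresholdResult:
    """Threshold Q such that a fraction W of values satisfy f >= Q.

    Q is the m-th largest value of ``f`` with m = round(W*S) (half-up),
    clamped to [1, S]; with distinct values exactly m of them are >= Q.
    """
    f = np.asarray(f, dtype=float).ravel()
    if f.size == 0:
        raise ValidationError("f: empty")
    if not (0 < W < 1):
        raise ValidationError(f"W: must be in (0, 1), got {W}")
    if np.all(f == f[0]):
        raise ValidationError("f: all values equal, threshold undefined")
    S = f.size
    m = int(math.floor(W * S + 0.5))  # round half-up
    m = min(max(m, 1), S)
    Q = float(np.partition(f, S - m)[S - m])  # m-th largest
    achieved = float(np.count_nonzero(f >= Q)) / S
    return ThresholdResult(Q=Q, W=float(W), S=S, achieved_fraction=achieved)
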