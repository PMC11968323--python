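"""Per-read base-calling error model.

True per-read error probabilities are either exact (every read carries the
configured mean error rate) or drawn from a Beta distribution whose shape
parameters are set by the method of moments from a target mean ``e`` and
variance ``v``.  True probabilities are converted to Phred-scaled integer
qualities, optionally compressed through a platform-specific binning table
(e.g. the four-bin RTA3 scheme of NovaSeq-class instruments).

The crucial wedge simulated here: downstream genotype-likelihood code sees
only the *reported* (rounded, capped, binned) quality, while bases are
corrupted with the *true* error probability.  Quality-score discretization
bias is exactly the gap between the two.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("glsim")

DEFAULT_QS_CAP = 60

__all__ = [
    "BetaShape",
    "ErrorModelConfig",
    "InfeasibleVarianceError",
    "beta_shapes",
    "sample_error_probs",
    "phred",
    "bin_quality",
    "novaseq_bins",
    "parse_bins",
]


class InfeasibleVarianceError(ValueError):
    """Requested Beta variance is not attainable for the requested mean."""


@dataclass(frozen=True)
class BetaShape:
    """Shape parameters of a Beta(alpha, beta) error distribution."""

    alpha: float
    beta: float

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def variance(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s * s * (s + 1.0))


def beta_shapes(e: float, v: float) -> BetaShape:
    """Method-of-moments Beta shape parameters for mean ``e`` and variance ``v``.

    With ``k = e(1-e)/v - 1`` the parameters are ``alpha = e*k`` and
    ``beta = (1-e)*k``; both are positive exactly when ``0 < v < e(1-e)``.

    Raises
    ------
    InfeasibleVarianceError
        If ``v >= e(1-e)`` (no Beta distribution has that mean/variance) or
        ``v <= 0`` (the exact-score path must bypass sampling instead).
    """
    if not 0.0 < e < 1.0:
        raise ValueError(f"mean error must be in (0,1), got {e}")
    if v <= 0.0:
        raise InfeasibleVarianceError(
            "variance must be positive; use exact error probabilities for v=0"
        )
    bound = e * (1.0 - e)
    if v >= bound:
        raise InfeasibleVarianceError(
            f"variance {v} >= e(1-e) = {bound:.6g}; no Beta distribution exists"
        )
    k = bound / v - 1.0
    return BetaShape(alpha=e * k, beta=(1.0 - e) * k)


def sample_error_probs(
    shape: BetaShape | float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` per-read true error probabilities.

    A float ``shape`` means exact scores: every value equals it and the RNG is
    untouched.  A :class:`BetaShape` yields i.i.d. Beta draws (floored at a
    tiny positive value so the Phred transform stays finite).
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if isinstance(shape, BetaShape):
        draws = rng.beta(shape.alpha, shape.beta, size=n)
        return np.maximum(draws, 1e-300)
    e = float(shape)
    if not 0.0 < e < 1.0:
        raise ValueError(f"exact error probability must be in (0,1), got {e}")
    return np.full(n, e)


def phred(p: float, cap: int = DEFAULT_QS_CAP) -> int:
    """Phred transform ``round(-10*log10(p))`` clamped to ``[0, cap]``.

    Rounding is half-away-from-zero so results are bit-reproducible across
    platforms.  Nonpositive ``p`` (a probability-zero guard) maps to ``cap``.
    """
    if p <= 0.0:
        logger.debug("phred: nonpositive probability %r mapped to cap %d", p, cap)
        return cap
    q = math.floor(-10.0 * math.log10(p) + 0.5)
    return min(max(q, 0), cap)


def novaseq_bins(cap: int = DEFAULT_QS_CAP) -> list[tuple[int, int, int]]:
    """Four-bin quality table mirroring the RTA3 (NovaSeq-like) scheme.

    Bins are ``(lo, hi, representative)`` with inclusive bounds:
    [0-2]->2, [3-14]->12, [15-30]->23, [31-cap]->37.
    """
    if cap < 31:
        raise ValueError("qs_cap must be >= 31 for the NovaSeq-like preset")
    return [(0, 2, 2), (3, 14, 12), (15, 30, 23), (31, cap, 37)]


def parse_bins(text: str) -> list[tuple[int, int, int]]:
    """Parse a custom bin table, one ``lo-hi:rep`` triple per line/comma."""
    bins = []
    for chunk in text.replace("\n", ",").split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        rng_part, rep = chunk.split(":")
        lo, hi = rng_part.split("-")
        bins.append((int(lo), int(hi), int(rep)))
    return bins


def _validate_bins(bins: list[tuple[int, int, int]], cap: int) -> None:
    ordered = sorted(bins)
    if ordered[0][0] != 0 or ordered[-1][1] != cap:
        raise ValueError(f"platform bins must span [0, {cap}]")
    for (lo, hi, rep) in ordered:
        if lo > hi:
            raise ValueError(f"bin [{lo},{hi}] is empty")
        if not lo <= rep <= hi:
            raise ValueError(
                f"representative {rep} outside its own bin [{lo},{hi}] "
                "(binning would not be idempotent)"
            )
    for (_, hi, _), (lo2, _, _) in zip(ordered, ordered[1:]):
        if lo2 != hi + 1:
            raise ValueError("platform bins must partition the quality range")


def bin_quality(q: int, bins: list[tuple[int, int, int]] | None) -> int:
    """Map quality ``q`` to its bin's representative score (identity if no bins)."""
    if bins is None:
        return q
    for lo, hi, rep in bins:
        if lo <= q <= hi:
            return rep
    raise ValueError(f"quality {q} outside every configured bin")


@dataclass
class ErrorModelConfig:
    """Full error-model configuration.

    Parameters
    ----------
    mean_error:
        Mean per-base error probability ``e`` in (0,1).  The benchmark setting
        is 0.002 (0.2%).
    beta_variance:
        Variance ``v`` of the Beta error distribution; ``0`` means exact
        (precise) quality scores and never touches the Beta sampler.
    qs_cap:
        Maximum reported Phred score (default 60); bounds the transform for
        vanishingly small error draws.
    platform_bins:
        Optional ordered ``(lo, hi, representative)`` table partitioning
        ``[0, qs_cap]``; ``None`` disables binning.
    """

    mean_error: float = 0.002
    beta_variance: float = 0.0
    qs_cap: int = DEFAULT_QS_CAP
    platform_bins: list[tuple[int, int, int]] | None = None
    _shape: BetaShape | None = field(default=None, init=False, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.mean_error < 1.0:
            raise ValueError("mean_error must be in (0,1)")
        if self.beta_variance < 0.0:
            raise ValueError("beta_variance must be nonnegative")
        if self.beta_variance > 0.0:
            self._shape = beta_shapes(self.mean_error, self.beta_variance)
        if self.platform_bins is not None:
            _validate_bins(self.platform_bins, self.qs_cap)

    @property
    def exact(self) -> bool:
        return self.beta_variance == 0.0

    @property
    def shape(self) -> BetaShape | None:
        return self._shape

    def draw_error_probs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.exact:
            return sample_error_probs(self.mean_error, n, rng)
        return sample_error_probs(self._shape, n, rng)

    def reported_quality(self, p: float) -> int:
        return bin_quality(phred(p, self.qs_cap), self.platform_bins)
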