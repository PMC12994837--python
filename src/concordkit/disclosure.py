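"""Discrete Gaussian count noise and base-10 rounding for released tables.

Released count tables in disclosure-controlled environments carry additive
integer noise with pmf P(X = x) ∝ exp(−x² / 2σ²) (the discrete Gaussian
mechanism) and are then rounded.  This module reproduces that protocol for
fixture realism and privacy demonstrations: the released scale and
post-processing used by statistical agencies for any given product are
unpublished, so the defaults here (σ = 4, rounding base 10 — every released
count ends in 0) are this package's own choice and the module makes **no
certified disclosure-avoidance claim**.

Sampling is exact (Canonne–Kamath–Steinke rejection from a discrete Laplace
base) — integers all the way down, no floating-point normal rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NoiseConfig", "sample_discrete_gaussian", "protect_counts"]


@dataclass(frozen=True)
class NoiseConfig:
    sigma: float = 4.0
    rounding_base: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.rounding_base < 1:
            raise ValueError("rounding_base must be >= 1")


def _discrete_laplace(t: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """Two-sided geometric with pmf ∝ exp(−|x| / t) on the integers."""
    p = 1.0 - np.exp(-1.0 / t)
    g1 = rng.geometric(p, size=size) - 1
    g2 = rng.geometric(p, size=size) - 1
    return g1 - g2


def sample_discrete_gaussian(
    sigma: float,
    size: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> int | np.ndarray:
    """Exact draws from the discrete Gaussian N_Z(0, σ²).

    P(X = x) ∝ exp(−x²/(2σ²)) over the integers; σ = 0 returns 0
    deterministically.  ``rng`` may be a Generator or a seed.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    scalar = size is None
    n = 1 if scalar else int(size)
    if sigma == 0:
        out = np.zeros(n, dtype=np.int64)
        return int(out[0]) if scalar else out
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    t = int(np.floor(sigma)) + 1
    s2 = sigma * sigma
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 64)
        x = _discrete_laplace(t, m, rng)
        # accept with exp(-(|x| - s2/t)^2 / (2 s2)): thins the Laplace tails
        # to the Gaussian profile exactly
        accept = rng.random(m) < np.exp(-((np.abs(x) - s2 / t) ** 2) / (2.0 * s2))
        x = x[accept]
        take = min(len(x), n - filled)
        out[filled : filled + take] = x[:take]
        filled += take
    return int(out[0]) if scalar else out


def protect_counts(
    counts: pd.DataFrame | pd.Series | np.ndarray,
    config: NoiseConfig = NoiseConfig(),
):
    """Apply the release protocol to a table of non-negative integer counts.

    Each count independently receives a discrete Gaussian draw, is clamped at
    zero, then rounded to the nearest multiple of ``rounding_base``
    (clamp-then-round: released tables contain no negative counts).
    Reproducible under the config seed.  Derived percentages must be
    recomputed from the protected counts, never protected directly.
    """
    values = np.asarray(counts, dtype=np.int64)
    if (values < 0).any():
        raise ValueError("counts must be non-negative integers")
    rng = np.random.default_rng(config.seed)
    noise = sample_discrete_gaussian(config.sigma, values.size, rng)
    noisy = np.maximum(values.ravel() + noise, 0)
    base = config.rounding_base
    protected = (np.round(noisy / base) * base).astype(np.int64).reshape(values.shape)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(protected, index=counts.index, columns=counts.columns)
    if isinstance(counts, pd.Series):
        return pd.Series(protected, index=counts.index, name=counts.name)
    return protected
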