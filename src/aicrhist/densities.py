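"""Reference distributions for the simulation study.

Six textbook shapes spanning the difficulty range of univariate density
estimation: a symmetric unimodal density (standard normal), a skewed one
(unit exponential), a compactly supported flat one (uniform on [0,1]), a
well-separated bimodal mixture (0.5·N(0,1) + 0.5·N(4,1)), a heavy-tailed
one (Student t with 3 df) and a smooth compact bump (Beta(1.5, 1.5)).

pdf/cdf are exact closed forms built on scipy.special ufuncs so they are
cheap to call inside adaptive quadrature.  Sampling uses numpy's PCG64
generator through ``numpy.random.default_rng``: ziggurat normals,
inversion exponentials/uniforms, normal-ratio t and Johnk/gamma beta
variates; a given seed reproduces the identical vector on one platform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import special

__all__ = ["ReferenceDistribution", "make_distribution", "sample", "DISTRIBUTION_NAMES"]

_SQRT_2PI = np.sqrt(2.0 * np.pi)


def _phi(x):
    return np.exp(-0.5 * np.square(x)) / _SQRT_2PI


@dataclass(frozen=True)
class ReferenceDistribution:
    """Exact density, distribution function and seeded sampler.

    ``support`` is the closed interval carrying all the mass; infinite
    endpoints are allowed and guide quadrature truncation in the losses.
    """

    name: str
    pdf: Callable[[np.ndarray], np.ndarray]
    cdf: Callable[[np.ndarray], np.ndarray]
    _draw: Callable[[np.random.Generator, int], np.ndarray]
    support: tuple[float, float]

    def sample(self, n: int, seed) -> np.ndarray:
        """n independent draws; identical ``(n, seed)`` gives identical output."""
        if n < 1:
            raise ValueError("n must be at least 1")
        rng = np.random.default_rng(seed)
        return self._draw(rng, int(n))


def _mix_pdf(x):
    x = np.asarray(x, dtype=float)
    return 0.5 * (_phi(x) + _phi(x - 4.0))


def _mix_cdf(x):
    x = np.asarray(x, dtype=float)
    return 0.5 * (special.ndtr(x) + special.ndtr(x - 4.0))


def _mix_draw(rng, n):
    z = rng.standard_normal(n)
    return z + 4.0 * (rng.random(n) < 0.5)


def _t3_pdf(x):
    x = np.asarray(x, dtype=float)
    return 2.0 / (np.pi * np.sqrt(3.0)) / np.square(1.0 + np.square(x) / 3.0)


def _beta_pdf(x):
    x = np.asarray(x, dtype=float)
    inside = (x >= 0.0) & (x <= 1.0)
    # B(1.5, 1.5) = pi / 8
    return np.where(inside, (8.0 / np.pi) * np.sqrt(np.abs(x * (1.0 - x))), 0.0)


def _exp_pdf(x):
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0.0, np.exp(-np.clip(x, 0.0, None)), 0.0)


def _exp_cdf(x):
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0.0, -np.expm1(-np.clip(x, 0.0, None)), 0.0)


def _unif_pdf(x):
    x = np.asarray(x, dtype=float)
    return np.where((x >= 0.0) & (x <= 1.0), 1.0, 0.0)


_REGISTRY: dict[str, ReferenceDistribution] = {
    "normal01": ReferenceDistribution(
        name="normal01",
        pdf=lambda x: _phi(np.asarray(x, dtype=float)),
        cdf=lambda x: special.ndtr(np.asarray(x, dtype=float)),
        _draw=lambda rng, n: rng.standard_normal(n),
        support=(-np.inf, np.inf),
    ),
    "exp1": ReferenceDistribution(
        name="exp1",
        pdf=_exp_pdf,
        cdf=_exp_cdf,
        _draw=lambda rng, n: rng.standard_exponential(n),
        support=(0.0, np.inf),
    ),
    "unif01": ReferenceDistribution(
        name="unif01",
        pdf=_unif_pdf,
        cdf=lambda x: np.clip(np.asarray(x, dtype=float), 0.0, 1.0),
        _draw=lambda rng, n: rng.random(n),
        support=(0.0, 1.0),
    ),
    "mix_2normal": ReferenceDistribution(
        name="mix_2normal",
        pdf=_mix_pdf,
        cdf=_mix_cdf,
        _draw=_mix_draw,
        support=(-np.inf, np.inf),
    ),
    "t3": ReferenceDistribution(
        name="t3",
        pdf=_t3_pdf,
        cdf=lambda x: special.stdtr(3.0, np.asarray(x, dtype=float)),
        _draw=lambda rng, n: rng.standard_t(3.0, n),
        support=(-np.inf, np.inf),
    ),
    "beta_1.5_1.5": ReferenceDistribution(
        name="beta_1.5_1.5",
        pdf=_beta_pdf,
        cdf=lambda x: special.betainc(1.5, 1.5, np.clip(np.asarray(x, dtype=float), 0.0, 1.0)),
        _draw=lambda rng, n: rng.beta(1.5, 1.5, n),
        support=(0.0, 1.0),
    ),
}

DISTRIBUTION_NAMES: tuple[str, ...] = tuple(_REGISTRY)


def make_distribution(name: str) -> ReferenceDistribution:
    """Look up one of the six reference distributions by name."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown distribution {name!r}; choose from {DISTRIBUTION_NAMES}"
        ) from None


def sample(dist: ReferenceDistribution, n: int, seed) -> np.ndarray:
    """Draw n values from ``dist``; thin functional wrapper over ``dist.sample``."""
    return dist.sample(n, seed)
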