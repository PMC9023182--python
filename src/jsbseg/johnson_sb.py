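"""The bounded Johnson (S_B) distribution.

The S_B member of the Johnson curve system describes a continuous variable
``x`` confined to the open interval ``(xi, xi + lam)`` such that

    z = gamma + delta * ln((x - xi) / (xi + lam - x))

is a standard normal variable.  ``gamma`` and ``delta > 0`` are shape
parameters; ``xi`` and ``lam > 0`` locate and scale the support.  On an 8-bit
CT slice ``x`` is a pixel gray value, so the support is a gray-level band.

The family is attractive for gray-level histogram modelling because the sign
of ``gamma`` flips the skew of the density: ``gamma = 0`` gives a symmetric
(normal-like) curve, ``gamma > 0`` a negatively skewed one and ``gamma < 0``
a positively skewed one, while large ``delta`` concentrates the mass.  A
single S_B curve can therefore hug one edge of a histogram — the property the
divided-histogram segmentation strategy in :mod:`jsbseg.thresholding` relies
on.

Everything here is plain vectorised numpy/scipy numerics; the module has no
image or histogram dependencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .errors import DomainError

__all__ = [
    "JohnsonSBParams",
    "logit_transform",
    "inverse_logit_transform",
    "jsb_pdf",
    "jsb_cdf",
    "jsb_sample",
    "jsb_median",
    "skew_direction",
    "support_from_data",
]

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class JohnsonSBParams:
    """Parameters of one Johnson S_B law.

    Attributes
    ----------
    gamma, delta:
        Shape parameters; ``delta`` must be positive, ``gamma`` is free.
    xi, lam:
        Lower bound and width of the open support ``(xi, xi + lam)``,
        both in gray-level units; ``lam`` must be positive.
    """

    gamma: float
    delta: float
    xi: float
    lam: float

    def __post_init__(self):
        if not self.delta > 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")
        if not self.lam > 0:
            raise ValueError(f"lam must be > 0, got {self.lam}")

    @property
    def support(self) -> tuple[float, float]:
        """The open interval carrying all probability mass."""
        return (self.xi, self.xi + self.lam)

    @property
    def median(self) -> float:
        return jsb_median(self)


def _inside(x: np.ndarray, params: JohnsonSBParams) -> np.ndarray:
    lo, hi = params.support
    return (x > lo) & (x < hi)


def logit_transform(x, params: JohnsonSBParams):
    """Map a gray value strictly inside the support to the real line.

    Computes ``f(x) = ln((x - xi) / (xi + lam - x))``, the monotone bounded
    logit whose standardisation ``gamma + delta*f(x)`` is normal.

    Raises
    ------
    DomainError
        If any value sits on or outside the support boundary.
    """
    x = np.asarray(x, dtype=float)
    inside = _inside(x, params)
    if not np.all(inside):
        bad = np.atleast_1d(x)[~np.atleast_1d(inside)][0]
        raise DomainError(
            f"gray value {bad!r} outside open support {params.support}"
        )
    out = np.log((x - params.xi) / (params.xi + params.lam - x))
    return float(out) if out.ndim == 0 else out


def inverse_logit_transform(f, params: JohnsonSBParams):
    """Inverse of :func:`logit_transform`: ``xi + lam * expit(f)``."""
    f = np.asarray(f, dtype=float)
    out = params.xi + params.lam * special.expit(f)
    return float(out) if out.ndim == 0 else out


def jsb_logpdf(x, params: JohnsonSBParams):
    """Log density; ``-inf`` outside the open support."""
    x = np.asarray(x, dtype=float)
    inside = _inside(x, params)
    xs = np.where(inside, x, params.xi + 0.5 * params.lam)  # safe placeholder
    f = np.log((xs - params.xi) / (params.xi + params.lam - xs))
    z = params.gamma + params.delta * f
    out = (
        np.log(params.delta)
        - _HALF_LOG_2PI
        + np.log(params.lam)
        - np.log(xs - params.xi)
        - np.log(params.xi + params.lam - xs)
        - 0.5 * z * z
    )
    out = np.where(inside, out, -np.inf)
    return float(out) if out.ndim == 0 else out


def jsb_pdf(x, params: JohnsonSBParams):
    """Density of the S_B law; 0 outside the open support (never raises)."""
    out = np.exp(jsb_logpdf(x, params))
    return float(out) if np.ndim(out) == 0 else out


def jsb_cdf(x, params: JohnsonSBParams):
    """Distribution function ``Phi(gamma + delta * f(x))`` (0/1 off-support)."""
    x = np.asarray(x, dtype=float)
    inside = _inside(x, params)
    xs = np.where(inside, x, params.xi + 0.5 * params.lam)
    f = np.log((xs - params.xi) / (params.xi + params.lam - xs))
    out = special.ndtr(params.gamma + params.delta * f)
    out = np.where(x <= params.xi, 0.0, np.where(x >= params.xi + params.lam, 1.0, out))
    return float(out) if out.ndim == 0 else out


def jsb_sample(params: JohnsonSBParams, n: int, seed=None, rng=None):
    """Draw ``n`` values by inverting the normalising transform.

    ``x = xi + lam * expit((z - gamma) / delta)`` with ``z ~ N(0, 1)``; all
    draws lie strictly inside the open support.  Pass either a ``seed`` or an
    existing :class:`numpy.random.Generator`.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if rng is None:
        rng = np.random.default_rng(seed)
    z = rng.standard_normal(int(n))
    return params.xi + params.lam * special.expit((z - params.gamma) / params.delta)


def jsb_median(params: JohnsonSBParams) -> float:
    """Closed-form median ``xi + lam * expit(-gamma/delta)`` (where z = 0)."""
    return params.xi + params.lam * float(special.expit(-params.gamma / params.delta))


def skew_direction(params: JohnsonSBParams) -> str:
    """Skew label implied by gamma.

    ``gamma = 0`` gives a symmetric density, ``gamma > 0`` a negatively
    skewed one (mass pushed toward the upper bound) and ``gamma < 0`` a
    positively skewed one.
    """
    if params.gamma == 0:
        return "symmetric"
    return "negative" if params.gamma > 0 else "positive"


def support_from_data(values, pad: float = 0.5) -> tuple[float, float]:
    """Derive ``(xi, lam)`` from observed gray values.

    The natural choice ``xi = min(x)``, ``lam = max(x) - min(x)`` puts the
    extreme observations on the support boundary where the logit diverges,
    so the support is padded by half a gray level on each side:
    ``xi = min - pad``, ``lam = range + 2*pad``.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot derive a support from no data")
    lo = float(values.min())
    hi = float(values.max())
    return lo - pad, (hi - lo) + 2.0 * pad
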