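"""Finite mixtures of Johnson S_B (or Gaussian) components fitted by EM.

All fitting operates on a :class:`GrayHistogram` — integer gray levels with
non-negative counts — rather than on raw pixels.  The discrete log-likelihood

    L(Theta) = sum_i c_i * ln sum_k Phi_k p_k(x_i | theta_k)

is identical to the per-pixel likelihood (counts act as multiplicities) but
costs O(levels * K) per EM sweep instead of O(pixels * K).

For the Johnson S_B family every component shares one fixed support
``(xi, lam)`` derived from the populated gray range; only the mixing weights
``Phi_k`` and the shape pair ``(delta_k, gamma_k)`` are optimised.  Writing
``f_i`` for the logit transform of level ``x_i`` and ``w_ik`` for the E-step
responsibilities, the weighted maximum-likelihood M-step has the closed form

    N_k    = sum_i c_i w_ik
    m_k    = sum_i c_i w_ik f_i / N_k
    v_k    = sum_i c_i w_ik f_i^2 / N_k - m_k^2
    Phi_k  = N_k / sum_i c_i
    delta_k = 1 / sqrt(v_k),        gamma_k = -delta_k * m_k

i.e. the standardised variable ``gamma + delta*f`` is refitted to a unit
normal under the responsibility weights.  These updates are the unique
stationary point of the weighted likelihood in (gamma, delta); the test
suite checks them against a direct numerical maximiser.

The Gaussian branch is the standard weighted-EM baseline with the same even
initialisation, kept deliberately symmetric with the S_B branch so the two
families can be swapped in the segmentation pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special

from .errors import CollapseError, DegenerateLevelError, DomainError
from .johnson_sb import JohnsonSBParams, jsb_logpdf, logit_transform

__all__ = [
    "GrayHistogram",
    "GaussianParams",
    "MixtureModel",
    "EMConfig",
    "FitResult",
    "mixture_pdf",
    "log_likelihood",
    "e_step",
    "m_step",
    "init_model",
    "fit_em",
    "fit_gmm",
]

_COLLAPSE_EPS = 1e-8


@dataclass(frozen=True)
class GrayHistogram:
    """Counts over a contiguous run of integer gray levels."""

    levels: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        levels = np.asarray(self.levels, dtype=int)
        counts = np.asarray(self.counts, dtype=np.int64)
        if levels.shape != counts.shape or levels.ndim != 1:
            raise ValueError("levels and counts must be 1-D arrays of equal length")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if counts.sum() <= 0:
            raise ValueError("histogram must contain at least one pixel")
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def populated_levels(self) -> np.ndarray:
        return self.levels[self.counts > 0]

    @property
    def populated_counts(self) -> np.ndarray:
        return self.counts[self.counts > 0]

    @property
    def n_populated(self) -> int:
        return int(np.count_nonzero(self.counts))

    @property
    def populated_range(self) -> tuple[int, int]:
        pop = self.populated_levels
        return int(pop[0]), int(pop[-1])

    def restrict(self, lo: int, hi: int) -> "GrayHistogram":
        """Sub-histogram over levels in the closed interval [lo, hi]."""
        mask = (self.levels >= lo) & (self.levels <= hi)
        if not mask.any() or self.counts[mask].sum() == 0:
            raise ValueError(f"no pixels in gray range [{lo}, {hi}]")
        return GrayHistogram(self.levels[mask], self.counts[mask])


@dataclass(frozen=True)
class GaussianParams:
    """Mean/variance pair for the Gaussian baseline family."""

    mean: float
    var: float

    def __post_init__(self):
        if not self.var > 0:
            raise ValueError(f"var must be > 0, got {self.var}")

    @property
    def median(self) -> float:
        return self.mean


@dataclass(frozen=True)
class MixtureModel:
    """K weighted components of a single family.

    For the ``johnson_sb`` family all components must share one support
    ``(xi, lam)``; the mixture is then itself supported on that interval.
    """

    family: str
    weights: np.ndarray
    components: tuple

    def __post_init__(self):
        if self.family not in ("johnson_sb", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")
        weights = np.asarray(self.weights, dtype=float)
        components = tuple(self.components)
        if weights.ndim != 1 or len(components) != weights.size:
            raise ValueError("weights and components must have equal length")
        if np.any(weights < -1e-12) or np.any(weights > 1 + 1e-12):
            raise ValueError("weights must lie in [0, 1]")
        if abs(weights.sum() - 1.0) > 1e-10:
            raise ValueError(f"weights must sum to 1, got {weights.sum()!r}")
        if self.family == "johnson_sb":
            supports = {(c.xi, c.lam) for c in components}
            if len(supports) != 1:
                raise ValueError("johnson_sb components must share one support")
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "components", components)

    @property
    def K(self) -> int:
        return self.weights.size

    @property
    def support(self) -> tuple[float, float] | None:
        if self.family == "johnson_sb":
            c = self.components[0]
            return (c.xi, c.xi + c.lam)
        return None

    def medians(self) -> np.ndarray:
        return np.array([c.median for c in self.components])

    def to_dict(self) -> dict:
        comps = []
        for c in self.components:
            if self.family == "johnson_sb":
                comps.append({"gamma": c.gamma, "delta": c.delta, "xi": c.xi, "lam": c.lam})
            else:
                comps.append({"mean": c.mean, "var": c.var})
        return {"family": self.family, "weights": self.weights.tolist(), "components": comps}

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureModel":
        if d["family"] == "johnson_sb":
            comps = tuple(JohnsonSBParams(**c) for c in d["components"])
        else:
            comps = tuple(GaussianParams(**c) for c in d["components"])
        return cls(d["family"], np.asarray(d["weights"], dtype=float), comps)


@dataclass(frozen=True)
class EMConfig:
    """EM settings; K is the cluster number (13 is the pipeline default)."""

    K: int = 13
    max_iter: int = 500
    tol: float = 1e-6
    init_delta: float = 2.0
    seed: int = 0
    family: str = "johnson_sb"
    mode: str = "tdh"

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not self.tol > 0:
            raise ValueError("tol must be > 0")


@dataclass
class FitResult:
    """Outcome of one EM run, with the per-iteration likelihood trace."""

    model: MixtureModel
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    n_rescues: int = 0

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "loglik_trace": np.asarray(self.loglik_trace, dtype=float).tolist(),
            "n_iter": self.n_iter,
            "converged": self.converged,
            "n_rescues": self.n_rescues,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            model=MixtureModel.from_dict(d["model"]),
            loglik_trace=np.asarray(d["loglik_trace"], dtype=float),
            n_iter=d["n_iter"],
            converged=d["converged"],
            n_rescues=d.get("n_rescues", 0),
        )


def _component_logpdfs(x: np.ndarray, model: MixtureModel) -> np.ndarray:
    """(len(x), K) matrix of per-component log densities."""
    x = np.asarray(x, dtype=float)
    out = np.empty((x.size, model.K))
    for k, comp in enumerate(model.components):
        if model.family == "johnson_sb":
            out[:, k] = jsb_logpdf(x, comp)
        else:
            out[:, k] = (
                -0.5 * np.log(2.0 * np.pi * comp.var)
                - 0.5 * (x - comp.mean) ** 2 / comp.var
            )
    return out


def mixture_pdf(x, model: MixtureModel):
    """Mixture density ``sum_k Phi_k p_k(x)`` (0 off-support for S_B)."""
    x = np.asarray(x, dtype=float)
    logp = _component_logpdfs(np.atleast_1d(x), model)
    with np.errstate(divide="ignore"):
        logw = np.log(model.weights)
    out = np.exp(special.logsumexp(logp + logw[None, :], axis=1))
    return float(out[0]) if x.ndim == 0 else out.reshape(x.shape)


def _check_support(hist: GrayHistogram, model: MixtureModel) -> None:
    if model.family != "johnson_sb":
        return
    lo, hi = model.support
    pop = hist.populated_levels
    bad = pop[(pop <= lo) | (pop >= hi)]
    if bad.size:
        raise DomainError(
            f"populated gray level {int(bad[0])} outside model support ({lo}, {hi})"
        )


def log_likelihood(hist: GrayHistogram, model: MixtureModel) -> float:
    """Discrete log-likelihood with histogram counts as multiplicities."""
    _check_support(hist, model)
    x = hist.populated_levels.astype(float)
    c = hist.populated_counts.astype(float)
    logp = _component_logpdfs(x, model)
    with np.errstate(divide="ignore"):
        logw = np.log(model.weights)
    lse = special.logsumexp(logp + logw[None, :], axis=1)
    if not np.all(np.isfinite(lse)):
        bad = x[~np.isfinite(lse)][0]
        raise DegenerateLevelError(f"zero mixture density at populated level {bad}")
    return float(np.sum(c * lse))


def e_step(hist: GrayHistogram, model: MixtureModel) -> np.ndarray:
    """Posterior responsibilities, shape ``(len(hist.levels), K)``.

    Rows of unpopulated levels are left at zero; each populated row sums
    to one.
    """
    _check_support(hist, model)
    resp = np.zeros((hist.levels.size, model.K))
    pop = hist.counts > 0
    x = hist.levels[pop].astype(float)
    logp = _component_logpdfs(x, model)
    with np.errstate(divide="ignore"):
        logw = np.log(model.weights)
    joint = logp + logw[None, :]
    norm = special.logsumexp(joint, axis=1)
    if not np.all(np.isfinite(norm)):
        bad = x[~np.isfinite(norm)][0]
        raise DegenerateLevelError(f"zero mixture density at populated level {bad}")
    resp[pop] = np.exp(joint - norm[:, None])
    return resp


def m_step(
    hist: GrayHistogram,
    resp: np.ndarray,
    support: tuple[float, float] | None = None,
    family: str = "johnson_sb",
    var_floor: bool = False,
) -> MixtureModel:
    """Weighted maximum-likelihood update from responsibilities.

    ``support`` is the fixed open interval ``(lo, hi)`` shared by all S_B
    components (ignored for the Gaussian family).

    Raises
    ------
    CollapseError
        If a component's responsibility-weighted variance (in transform
        space for S_B, gray space for Gaussian) falls below ``1e-8`` —
        the component has locked onto a single gray level.  With
        ``var_floor=True`` the variance is instead clamped from below at
        the value corresponding to a ~0.3-gray-level spread at the
        component's location, and no error is raised; the fitter uses this
        as a last resort when a reseeded component collapses again (a
        single enormous histogram bin, e.g. the boundary bin of a divided
        histogram, is a legitimate spike that must keep a finite-width
        component).
    """
    resp = np.asarray(resp, dtype=float)
    pop = hist.counts > 0
    x = hist.levels[pop].astype(float)
    c = hist.counts[pop].astype(float)
    w = resp[pop]
    K = w.shape[1]

    cw = c[:, None] * w
    N_k = cw.sum(axis=0)
    if np.any(N_k <= 0):
        raise CollapseError(int(np.argmin(N_k)), "component lost all responsibility")
    weights = N_k / c.sum()
    weights = weights / weights.sum()

    if family == "johnson_sb":
        if support is None:
            raise ValueError("johnson_sb m_step needs the shared (lo, hi) support")
        lo, hi = support
        xi, lam = lo, hi - lo
        ref = JohnsonSBParams(0.0, 1.0, xi, lam)
        f = logit_transform(x, ref)
        m = (cw * f[:, None]).sum(axis=0) / N_k
        v = (cw * (f**2)[:, None]).sum(axis=0) / N_k - m**2
        if var_floor:
            # minimum spread ~0.3 gray levels at the component location
            loc = xi + lam * special.expit(m)
            fprime = lam / ((loc - xi) * (xi + lam - loc))
            v = np.maximum(v, (0.3 * fprime) ** 2)
        elif np.any(v <= _COLLAPSE_EPS):
            raise CollapseError(int(np.argmin(v)))
        delta = 1.0 / np.sqrt(v)
        gamma = -delta * m
        comps = tuple(
            JohnsonSBParams(float(g), float(d), xi, lam) for g, d in zip(gamma, delta)
        )
        return MixtureModel("johnson_sb", weights, comps)

    mean = (cw * x[:, None]).sum(axis=0) / N_k
    var = (cw * (x**2)[:, None]).sum(axis=0) / N_k - mean**2
    if var_floor:
        var = np.maximum(var, 0.09)
    elif np.any(var <= _COLLAPSE_EPS):
        raise CollapseError(int(np.argmin(var)))
    comps = tuple(GaussianParams(float(mu), float(s2)) for mu, s2 in zip(mean, var))
    return MixtureModel("gaussian", weights, comps)


def _fit_support(hist: GrayHistogram) -> tuple[float, float]:
    lo, hi = hist.populated_range
    # half-gray-level pad keeps boundary levels strictly inside the support
    return lo - 0.5, (hi - lo) + 1.0


def init_model(
    hist: GrayHistogram,
    config: EMConfig,
    family: str | None = None,
    support: tuple[float, float] | None = None,
) -> MixtureModel:
    """Equal-weight components with medians evenly spaced over the data range.

    The k-th location is ``c_k = lo + k/(K+1) * (hi - lo)`` over the populated
    range ``[lo, hi]``; interior placement keeps every starting component away
    from the support boundary.  S_B components start at ``delta = init_delta``
    with ``gamma`` chosen so the component median sits exactly at ``c_k``.
    ``support`` optionally pins the shared S_B support to a known open
    interval ``(lo, hi)`` instead of deriving it from the populated range.
    """
    family = family or config.family
    K = config.K
    if hist.n_populated < K:
        raise ValueError(
            f"histogram has {hist.n_populated} populated levels; need >= K={K}"
        )
    lo, hi = hist.populated_range
    centers = lo + (np.arange(1, K + 1) / (K + 1)) * (hi - lo)
    weights = np.full(K, 1.0 / K)
    if family == "johnson_sb":
        if support is not None:
            xi, lam = support[0], support[1] - support[0]
        else:
            xi, lam = _fit_support(hist)
        ref = JohnsonSBParams(0.0, 1.0, xi, lam)
        f = logit_transform(centers, ref)
        comps = tuple(
            JohnsonSBParams(float(-config.init_delta * fc), config.init_delta, xi, lam)
            for fc in np.atleast_1d(f)
        )
        return MixtureModel("johnson_sb", weights, comps)
    var = max(((hi - lo) / (K + 1)) ** 2, 1.0)
    comps = tuple(GaussianParams(float(cc), var) for cc in centers)
    return MixtureModel("gaussian", weights, comps)


def _rescue_component(
    hist: GrayHistogram, model: MixtureModel, k: int, init_delta: float
) -> MixtureModel:
    """Reseed component k at the most under-fitted populated gray level."""
    x = hist.populated_levels.astype(float)
    c = hist.populated_counts.astype(float)
    dens = mixture_pdf(x, model)
    target = float(x[np.argmax(c / (dens * hist.total + 1e-300))])
    comps = list(model.components)
    if model.family == "johnson_sb":
        ref = comps[0]
        # nudge the target off the support boundary if it sits there
        lo, hi = model.support
        target = min(max(target, lo + 0.25), hi - 0.25)
        f = logit_transform(target, JohnsonSBParams(0.0, 1.0, ref.xi, ref.lam))
        comps[k] = JohnsonSBParams(-init_delta * f, init_delta, ref.xi, ref.lam)
    else:
        lo_p, hi_p = hist.populated_range
        comps[k] = GaussianParams(target, max(((hi_p - lo_p) / model.K) ** 2, 1.0))
    return replace(model, components=tuple(comps))


def _fit(
    hist: GrayHistogram,
    config: EMConfig,
    family: str,
    support: tuple[float, float] | None = None,
) -> FitResult:
    model = init_model(hist, config, family=family, support=support)
    support = model.support
    trace = [log_likelihood(hist, model)]
    converged = False
    rescued: set[int] = set()
    floored = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        resp = e_step(hist, model)
        try:
            model = m_step(
                hist, resp, support=support, family=family, var_floor=floored
            )
        except CollapseError as err:
            if err.component in rescued:
                # reseeding did not help: the data genuinely contain a
                # one-bin spike, so continue with a variance floor
                floored = True
                model = m_step(hist, resp, support=support, family=family, var_floor=True)
            else:
                rescued.add(err.component)
                model = _rescue_component(hist, model, err.component, config.init_delta)
                trace.append(log_likelihood(hist, model))
                continue
        ll = log_likelihood(hist, model)
        trace.append(ll)
        prev = trace[-2]
        if abs(ll - prev) <= config.tol * max(abs(prev), 1.0):
            converged = True
            break
    return FitResult(
        model=model,
        loglik_trace=np.asarray(trace),
        n_iter=n_iter,
        converged=converged,
        n_rescues=len(rescued),
    )


def fit_em(
    hist: GrayHistogram,
    config: EMConfig,
    support: tuple[float, float] | None = None,
) -> FitResult:
    """Fit a K-component Johnson S_B mixture to a gray-level histogram.

    ``support`` optionally fixes the shared open interval ``(lo, hi)``; by
    default it is the populated range padded by half a gray level per side.
    """
    return _fit(hist, config, "johnson_sb", support=support)


def fit_gmm(hist: GrayHistogram, config: EMConfig) -> FitResult:
    """Fit the Gaussian-mixture baseline with the same initialisation rules."""
    return _fit(hist, config, "gaussian")
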