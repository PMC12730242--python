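"""Step-size distribution modelling.

Single-frame displacement magnitudes of 2D diffusing particles follow a
Rayleigh distribution p(r) = (r / s^2) exp(-r^2 / (2 s^2)), with scale
s = sqrt(2 D tau).  Pooling the consecutive-frame steps of every accepted
trajectory in a cell and fitting a two-component Rayleigh mixture

    p(r) = f1 (r/s1^2) exp(-r^2/2s1^2) + f2 (r/s2^2) exp(-r^2/2s2^2)

separates an immobile population — whose apparent steps are pure
localization error, so s1 estimates the localization precision (~20 nm) —
from a mobile, diffusing population with scale s2.  When a small fraction
of much longer steps from directed transport is present, an optional
zero-truncated Gaussian peak is added as a third component.

s1 and s2 feed the trajectory classifier directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .trajectory import Trajectory

__all__ = [
    "StepSample",
    "GaussianComponent",
    "StepMixtureFit",
    "pool_displacements",
    "fit_rayleigh_mixture",
    "evaluate_mixture_pdf",
]


@dataclass
class StepSample:
    """Consecutive-frame displacement magnitudes pooled over one cell."""

    cell_id: str
    tau: float
    steps: np.ndarray

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, dtype=float)
        if np.any(self.steps < 0):
            raise ValueError("step magnitudes must be >= 0")


@dataclass(frozen=True)
class GaussianComponent:
    """Zero-truncated Gaussian peak for directed steps."""

    f: float
    mu: float
    sigma: float


@dataclass
class StepMixtureFit:
    """Fitted step-size mixture, components sorted by scale (s1 < s2).

    The implied per-component diffusion coefficients follow from
    s_i = sqrt(2 D_i tau).
    """

    f1: float
    s1: float
    f2: float
    s2: float
    tau: float
    gaussian: GaussianComponent | None = None
    converged: bool = True
    loglik: float = float("nan")
    n_steps: int = 0
    n_iter: int = 0
    n_components: int = 2
    loglik_history: list = None

    @property
    def D1(self) -> float:
        return self.s1 ** 2 / (2.0 * self.tau)

    @property
    def D2(self) -> float:
        return self.s2 ** 2 / (2.0 * self.tau)

    def to_dict(self) -> dict:
        out = {
            "f1": self.f1, "s1": self.s1, "f2": self.f2, "s2": self.s2,
            "D1": self.D1, "D2": self.D2, "tau": self.tau,
            "converged": self.converged, "loglik": self.loglik,
            "n_steps": self.n_steps, "n_iter": self.n_iter,
            "n_components": self.n_components,
        }
        if self.gaussian is not None:
            out["gaussian"] = vars(self.gaussian)
        return out


def pool_displacements(trajs: Sequence[Trajectory], tau: float,
                       cell_id: str = "cell") -> StepSample:
    """Pool consecutive-frame step magnitudes over the cell's trajectories.

    Steps spanning detection gaps are excluded (they cover more than one
    frame interval and would contaminate the single-lag distribution).
    """
    parts = [t.step_displacements(1) for t in trajs]
    steps = np.concatenate(parts) if parts else np.empty(0)
    return StepSample(cell_id=cell_id, tau=tau, steps=steps)


def _rayleigh_pdf(r: np.ndarray, s: float) -> np.ndarray:
    return (r / s ** 2) * np.exp(-r ** 2 / (2.0 * s ** 2))


def _truncnorm_pdf(r: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    # normal restricted to r >= 0, renormalized so it integrates to 1 there
    z = norm.sf(-mu / sigma)
    return norm.pdf(r, mu, sigma) / z


_S_FLOOR = 1e-6


def _em_rayleigh(steps: np.ndarray, s_init: np.ndarray, f_init: np.ndarray,
                 gaussian_init: tuple[float, float, float] | None,
                 max_iter: int, tol: float):
    """EM for a Rayleigh mixture with an optional truncated-Gaussian term.

    Rayleigh scale updates are closed-form: s_j^2 = sum(g_ij r_i^2) /
    (2 sum(g_ij)).  The Gaussian term uses weighted-moment updates (exact
    for mu >> sigma, where truncation at zero is immaterial).
    """
    r = steps
    n = r.size
    n_ray = len(s_init)
    s = np.maximum(np.asarray(s_init, dtype=float), _S_FLOOR)
    with_gauss = gaussian_init is not None
    if with_gauss:
        f_g, mu, sigma = gaussian_init
        f = np.append(np.asarray(f_init, dtype=float) * (1 - f_g), f_g)
    else:
        f = np.asarray(f_init, dtype=float)
    f = f / f.sum()

    loglik = -np.inf
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        dens = np.column_stack([_rayleigh_pdf(r, sj) for sj in s])
        if with_gauss:
            dens = np.column_stack([dens, _truncnorm_pdf(r, mu, sigma)])
        weighted = dens * f
        total = weighted.sum(axis=1)
        total = np.maximum(total, 1e-300)
        new_loglik = float(np.sum(np.log(total)))
        history.append(new_loglik)
        resp = weighted / total[:, None]

        nk = resp.sum(axis=0)
        f = nk / n
        for j in range(n_ray):
            if nk[j] > 0:
                s[j] = max(np.sqrt(np.sum(resp[:, j] * r ** 2) / (2.0 * nk[j])),
                           _S_FLOOR)
        if with_gauss and nk[-1] > 0:
            mu = float(np.sum(resp[:, -1] * r) / nk[-1])
            var = float(np.sum(resp[:, -1] * (r - mu) ** 2) / nk[-1])
            sigma = max(np.sqrt(var), _S_FLOOR)

        if new_loglik - loglik < tol * max(1.0, abs(new_loglik)) and it > 1:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik

    gauss = GaussianComponent(float(f[-1]), float(mu), float(sigma)) if with_gauss else None
    return f[:n_ray], s, gauss, loglik, converged, it, history


def fit_rayleigh_mixture(sample: StepSample, with_gaussian: str | bool = "auto",
                         s1_init: float = 0.02, max_iter: int = 500,
                         tol: float = 1e-10,
                         min_steps: int = 50) -> StepMixtureFit:
    """Maximum-likelihood fit of the two-Rayleigh step-size mixture.

    Initialization is deterministic: s1 starts at the localization-precision
    prior (20 nm) and s2 at the RMS step.  With ``with_gaussian="auto"`` the
    zero-truncated Gaussian third component is kept only when it earns its
    three extra parameters — the BIC must improve over the two-component fit
    — and its peak lies beyond the diffusive scale (mu > s2), i.e. it
    captures a genuine population of longer, transport-like steps rather
    than reshaping the diffusive bulk.  Components are returned sorted by
    scale; fewer than ``min_steps`` steps triggers a single-Rayleigh
    fallback (with a warning) since a two-component fit is not reliable.
    """
    steps = sample.steps[sample.steps > 0]
    if steps.size == 0:
        raise ValueError("cannot fit a step-size mixture to all-zero steps")
    n = steps.size
    rms = float(np.sqrt(np.mean(steps ** 2)))

    if n < min_steps:
        warnings.warn(
            f"only {n} steps (< {min_steps}); falling back to a single Rayleigh",
            stacklevel=2,
        )
        s_hat = rms / np.sqrt(2.0)
        ll = float(np.sum(np.log(_rayleigh_pdf(steps, max(s_hat, _S_FLOOR)))))
        return StepMixtureFit(f1=1.0, s1=s_hat, f2=0.0, s2=s_hat,
                              tau=sample.tau, converged=True, loglik=ll,
                              n_steps=n, n_iter=0, n_components=1)

    s_init = np.array([min(s1_init, rms), rms])
    f_init = np.array([0.5, 0.5])
    f2c, s2c, _, ll2, conv2, it2, hist2 = _em_rayleigh(steps, s_init, f_init,
                                                       None, max_iter, tol)

    try_gauss = with_gaussian is True or with_gaussian == "auto"

    best = (f2c, s2c, None, ll2, conv2, it2, 2, hist2)
    if try_gauss:
        q95 = float(np.quantile(steps, 0.95))
        tail = steps[steps > q95]
        mu0 = float(tail.mean()) if tail.size else 2 * rms
        sig0 = float(tail.std()) if tail.size > 1 else rms / 2
        f3c, s3c, g3, ll3, conv3, it3, hist3 = _em_rayleigh(
            steps, s2c, f2c / f2c.sum(), (0.05, mu0, max(sig0, _S_FLOOR)),
            max_iter, tol)
        # likelihood criterion: BIC must improve to justify 3 extra params,
        # and the peak must sit beyond the diffusive scale
        bic2 = -2 * ll2 + 3 * np.log(n)
        bic3 = -2 * ll3 + 6 * np.log(n)
        accept = bic3 < bic2 and g3.mu > float(np.max(s3c))
        if with_gaussian is True or accept:
            best = (f3c, s3c, g3, ll3, conv3, it3, 3, hist3)

    f, s, gauss, ll, conv, iters, ncomp, history = best
    order = np.argsort(s)
    f, s = f[order], s[order]
    return StepMixtureFit(
        f1=float(f[0]), s1=float(s[0]), f2=float(f[1]), s2=float(s[1]),
        tau=sample.tau, gaussian=gauss, converged=bool(conv),
        loglik=float(ll), n_steps=n, n_iter=iters, n_components=ncomp,
        loglik_history=history,
    )


def evaluate_mixture_pdf(fit: StepMixtureFit, r: np.ndarray) -> dict[str, np.ndarray]:
    """Component-wise and total mixture densities on a grid of step sizes.

    The returned curves are the weighted component densities, so they sum
    pointwise to the total, and the total integrates to 1 over [0, inf).
    """
    r = np.asarray(r, dtype=float)
    out: dict[str, np.ndarray] = {}
    if fit.n_components == 1:
        out["rayleigh1"] = _rayleigh_pdf(r, fit.s1)
    else:
        out["rayleigh1"] = fit.f1 * _rayleigh_pdf(r, fit.s1)
        out["rayleigh2"] = fit.f2 * _rayleigh_pdf(r, fit.s2)
    if fit.gaussian is not None:
        g = fit.gaussian
        out["gaussian"] = g.f * _truncnorm_pdf(r, g.mu, g.sigma)
    out["total"] = sum(out.values())
    return out
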