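"""Variational-Bayes equivalent-current-dipole fitting.

Fits a fixed number of current dipoles (two by default, one per
hemisphere) simultaneously to a single-time-point field topography.
Gaussian priors over dipole locations and moments make the fit an
explicit generative model: the variational free energy — expected log
likelihood minus the KL divergence of the posteriors from the priors —
approximates the log model evidence and trades fit accuracy against
model complexity.

Scheme: fixed-form mean-field factorisation q(location) q(moment)
q(noise precision) with Gaussian location/moment factors and a Gamma
noise-precision factor.  Given locations, the moment posterior is the
exact conditional Gaussian; the location mean moves by damped
Gauss-Newton steps on the free energy (steps that would lower it are
shrunk and, failing that, rejected), with the location covariance from
the Gauss-Newton curvature.  Moments are fitted in all three cardinal
directions (no rank reduction); the radial direction is magnetically
silent in a spherical conductor, so its posterior variance stays near
the prior and the scalar dipole magnitude is taken as the projection of
the posterior moment mean onto the plane of the two most precise
(smallest-variance) directions of the moment covariance.

Internally fields are scaled to femtotesla and moments kept in nAm so
all quantities are O(1)-O(100) in double precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma

from .bayesglm import _kl_gamma
from .forward import ConductorModel, GeometryError, SensorArray, leadfield
from .reference import LOCATION_PRIOR_SD_MM, MOMENT_PRIOR_SD_NAM, PRIOR_LOCATIONS_MM

_FT = 1e15  # tesla -> femtotesla
_LF_SCALE = 1e-9 * _FT  # leadfield T/(A m) -> fT/nAm


class VBECDError(ValueError):
    pass


@dataclass
class DipolePrior:
    """Gaussian priors for each fitted dipole.

    ``location_means_mm`` is (n_dipoles, 3); isotropic standard
    deviations apply per cardinal direction.  Moment prior mean is zero.
    """

    location_means_mm: np.ndarray
    location_sd_mm: float = LOCATION_PRIOR_SD_MM
    moment_sd_nAm: float = MOMENT_PRIOR_SD_NAM

    def __post_init__(self):
        self.location_means_mm = np.atleast_2d(np.asarray(self.location_means_mm, float))
        if self.location_means_mm.shape[1] != 3:
            raise VBECDError("location means must be (n_dipoles, 3)")
        if self.location_sd_mm <= 0 or self.moment_sd_nAm <= 0:
            raise VBECDError("prior standard deviations must be positive")

    @property
    def n_dipoles(self) -> int:
        return self.location_means_mm.shape[0]


def auditory_priors() -> DipolePrior:
    """The bilateral auditory-cortex priors: left/right location means,
    10 mm location sd, 0 +/- 100 nAm moments."""
    return DipolePrior(
        location_means_mm=np.vstack(
            [PRIOR_LOCATIONS_MM["left"], PRIOR_LOCATIONS_MM["right"]]
        )
    )


@dataclass
class DipolePosterior:
    """Factorised Gaussian posterior over dipole parameters."""

    location_mean_mm: np.ndarray  # (n_dipoles, 3)
    location_cov_mm2: np.ndarray  # (n_dipoles, 3, 3)
    moment_mean_nAm: np.ndarray  # (n_dipoles, 3)
    moment_cov_nAm2: np.ndarray  # (n_dipoles, 3, 3)
    noise_shape: float  # Gamma posterior on noise precision (1/fT^2)
    noise_rate: float
    free_energy: float
    free_energy_trace: np.ndarray
    variance_explained: float
    n_restarts: int
    winning_restart: int
    converged: bool

    @property
    def n_dipoles(self) -> int:
        return self.location_mean_mm.shape[0]


def _stack_leadfield(locs, conductor, array):
    """fT/nAm leadfield blocks for each dipole, horizontally stacked."""
    blocks = [leadfield(loc, conductor, array).matrix * _LF_SCALE for loc in locs]
    G = np.hstack(blocks)
    if not np.all(np.isfinite(G)):
        raise GeometryError("non-finite leadfield")
    return G


def _jacobian(locs, moments, conductor, array, h_mm=0.05):
    """d(predicted field)/d(location), central differences, N x 3k."""
    k = locs.shape[0]
    n = array.n_channels
    J = np.zeros((n, 3 * k))
    for d in range(k):
        m = moments[d]
        for c in range(3):
            lp = locs.copy()
            lp[d, c] += h_mm
            lm = locs.copy()
            lm[d, c] -= h_mm
            fp = leadfield(lp[d], conductor, array).matrix * _LF_SCALE @ m
            fm = leadfield(lm[d], conductor, array).matrix * _LF_SCALE @ m
            J[:, 3 * d + c] = (fp - fm) / (2 * h_mm)
    return J


def _kl_gauss(mu, Sigma, mu0, prec0_diag):
    d = mu.size
    quad = np.sum(prec0_diag * (mu - mu0) ** 2)
    tr = np.sum(prec0_diag * np.diag(Sigma))
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        raise VBECDError("posterior covariance is not positive definite")
    logdet0 = -np.sum(np.log(prec0_diag))
    return 0.5 * (tr + quad - d + logdet0 - logdet)


def _evaluate(mu_rho, state, y, priors, conductor, array, a0, b0):
    """Full coordinate-update sweep at candidate locations; returns new state."""
    k = priors.n_dipoles
    n = y.size
    Pm = np.full(3 * k, 1.0 / priors.moment_sd_nAm**2)
    Pr = np.full(3 * k, 1.0 / priors.location_sd_mm**2)
    mu_r0 = priors.location_means_mm.ravel()
    lam = state["lam"]

    locs = mu_rho.reshape(k, 3)
    G = _stack_leadfield(locs, conductor, array)
    Sm = np.linalg.inv(lam * G.T @ G + np.diag(Pm))
    mm = lam * Sm @ G.T @ y
    J = _jacobian(locs, mm.reshape(k, 3), conductor, array)
    Sr = np.linalg.inv(lam * J.T @ J + np.diag(Pr))
    resid = y - G @ mm
    S = float(resid @ resid + np.trace(G @ Sm @ G.T) + np.trace(J @ Sr @ J.T))
    a = a0 + n / 2.0
    b = b0 + S / 2.0
    lam_new = a / b
    Elog_lam = digamma(a) - np.log(b)

    F = (
        0.5 * n * (Elog_lam - np.log(2 * np.pi))
        - 0.5 * lam_new * S
        - _kl_gauss(mm, Sm, np.zeros(3 * k), Pm)
        - _kl_gauss(mu_rho, Sr, mu_r0, Pr)
        - _kl_gamma(a, b, a0, b0)
    )
    return {
        "mu_rho": mu_rho, "Sr": Sr, "mm": mm, "Sm": Sm, "G": G, "J": J,
        "lam": lam_new, "a": a, "b": b, "resid": resid, "F": float(F),
    }


def _fit_single_restart(y, init_rho, priors, conductor, array, max_iter, tol, a0, b0):
    k = priors.n_dipoles
    Pr = np.full(3 * k, 1.0 / priors.location_sd_mm**2)
    mu_r0 = priors.location_means_mm.ravel()
    state = {"lam": 1.0 / max(np.var(y), 1e-12)}
    state = _evaluate(init_rho.copy(), state, y, priors, conductor, array, a0, b0)
    trace = [state["F"]]
    converged = False
    for _ in range(max_iter):
        # Gauss-Newton direction on the free energy w.r.t. location means
        J, lam = state["J"], state["lam"]
        rhs = lam * J.T @ state["resid"] - Pr * (state["mu_rho"] - mu_r0)
        H = lam * J.T @ J + np.diag(Pr)
        delta = np.linalg.solve(H, rhs)
        accepted = None
        for step in [1.0 / 2**i for i in range(13)] + [0.0]:
            cand = _evaluate(
                state["mu_rho"] + step * delta, state, y, priors, conductor, array, a0, b0
            )
            if cand["F"] >= state["F"] - 1e-9:
                accepted = cand
                break
        if accepted is None:  # not even a pure hyperparameter sweep helps
            converged = True
            break
        dF = accepted["F"] - state["F"]
        state = accepted
        trace.append(state["F"])
        if abs(dF) < tol:
            converged = True
            break
    return state, np.array(trace), converged


def fit_vb_ecd(
    topography_T: np.ndarray,
    array: SensorArray,
    conductor: ConductorModel,
    priors: DipolePrior | None = None,
    n_restarts: int = 10,
    seed: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    a0: float = 1e-6,
    b0: float = 1e-6,
) -> DipolePosterior:
    """Fit dipoles to a topography by variational Bayes with restarts.

    The first restart initialises at the prior location means; further
    restarts draw initial locations from the location prior.  The
    restart with the highest final free energy wins; identical seed and
    inputs give identical results.
    """
    if priors is None:
        priors = auditory_priors()
    y = np.asarray(topography_T, float) * _FT
    if y.ndim != 1 or y.size != array.n_channels:
        raise VBECDError("topography must be a channel vector matching the array")
    if not np.all(np.isfinite(y)):
        raise VBECDError("topography contains non-finite values")
    if n_restarts < 1:
        raise VBECDError("need at least one restart")

    rng = np.random.default_rng(seed)
    k = priors.n_dipoles
    best = None
    for r in range(n_restarts):
        if r == 0:
            init = priors.location_means_mm.ravel().copy()
        else:
            init = (
                priors.location_means_mm + rng.normal(0, priors.location_sd_mm, (k, 3))
            ).ravel()
        state, trace, conv = _fit_single_restart(
            y, init, priors, conductor, array, max_iter, tol, a0, b0
        )
        if best is None or state["F"] > best[0]["F"]:
            best = (state, trace, conv, r)

    state, trace, conv, r_win = best
    ve = _variance_explained_fT(y, state["G"], state["mm"])
    Sr = state["Sr"].reshape(3 * k, 3 * k)
    Sm = state["Sm"].reshape(3 * k, 3 * k)
    return DipolePosterior(
        location_mean_mm=state["mu_rho"].reshape(k, 3),
        location_cov_mm2=np.stack([Sr[3 * d:3 * d + 3, 3 * d:3 * d + 3] for d in range(k)]),
        moment_mean_nAm=state["mm"].reshape(k, 3),
        moment_cov_nAm2=np.stack([Sm[3 * d:3 * d + 3, 3 * d:3 * d + 3] for d in range(k)]),
        noise_shape=state["a"],
        noise_rate=state["b"],
        free_energy=state["F"],
        free_energy_trace=trace,
        variance_explained=ve,
        n_restarts=n_restarts,
        winning_restart=r_win,
        converged=conv,
    )


def _variance_explained_fT(y, G, mm) -> float:
    yhat = G @ mm
    denom = float(y @ y)
    if denom == 0:
        raise VBECDError("zero-norm topography: variance explained undefined")
    return float(1.0 - np.sum((y - yhat) ** 2) / denom)


def variance_explained(
    topography_T: np.ndarray,
    posterior: DipolePosterior,
    array: SensorArray,
    conductor: ConductorModel,
) -> float:
    """1 - ||y - yhat||^2 / ||y||^2 with yhat the posterior-mean field."""
    y = np.asarray(topography_T, float) * _FT
    G = _stack_leadfield(posterior.location_mean_mm, conductor, array)
    return _variance_explained_fT(y, G, posterior.moment_mean_nAm.ravel())


def _canonical_eigh(C: np.ndarray):
    """Eigendecomposition, ascending eigenvalues, sign fixed so the first
    nonzero component of each eigenvector is positive."""
    vals, vecs = np.linalg.eigh(C)
    for j in range(vecs.shape[1]):
        v = vecs[:, j]
        nz = np.nonzero(np.abs(v) > 1e-12)[0]
        if nz.size and v[nz[0]] < 0:
            vecs[:, j] = -v
    return vals, vecs


def moment_magnitude(posterior: DipolePosterior, dipole_index: int = 0) -> float:
    """Scalar dipole magnitude (nAm): norm of the posterior moment mean
    projected onto the plane of the two smallest-variance directions of
    the posterior moment covariance."""
    C = posterior.moment_cov_nAm2[dipole_index]
    vals, vecs = _canonical_eigh(C)
    if np.any(vals <= 0):
        raise VBECDError("moment covariance is not positive definite")
    m = posterior.moment_mean_nAm[dipole_index]
    plane = vecs[:, :2]  # two smallest eigenvalues = most precise directions
    proj = plane @ (plane.T @ m)
    return float(np.linalg.norm(proj))
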