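"""Variational-Bayes linear models with model evidence and family inference.

Each model regresses dipole moments on one (centred) myelin regressor
plus an intercept.  The variational free energy approximates the log
model evidence, penalising complexity, so models over ROIs / maps /
spatial extents can be compared directly; groups of models are compared
by summing posterior model probabilities within families under uniform
priors (1/3 per map, 1/6 per ROI).

Model: y = X w + e, with w ~ N(0, alpha^-1 I), e ~ N(0, lambda^-1 I),
and broad Gamma hyperpriors on the precisions alpha and lambda.  The
mean-field posterior q(w) q(alpha) q(lambda) has closed-form coordinate
updates, each of which cannot decrease the free energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln

from .reference import MAP_TYPES, ROI_LABELS
from .stats import HemisphereRecord, StatsError


class GLMError(ValueError):
    pass


@dataclass
class GLMModelSpec:
    """Design for one Bayesian GLM: moments on intercept + centred regressors."""

    dependent: np.ndarray
    design: np.ndarray
    label: tuple[str, str] = ("", "")

    def __post_init__(self):
        self.dependent = np.asarray(self.dependent, float).ravel()
        self.design = np.atleast_2d(np.asarray(self.design, float))
        n, p = self.design.shape
        if n != self.dependent.size:
            raise GLMError("design and dependent sizes differ")
        if n < p:
            raise GLMError("need at least as many observations as regressors")
        if np.linalg.matrix_rank(self.design) < p:
            raise GLMError("design matrix is rank deficient")


def _standardise(x: np.ndarray) -> np.ndarray:
    """Centre and scale a regressor to unit variance.

    The three map types carry different physical units (p.u. vs 1/s)
    and very different numerical ranges; without scaling, the weight
    prior's complexity penalty would depend on those units rather than
    on how well the regressor explains the moments, making evidences
    incomparable across maps.
    """
    x = np.asarray(x, float)
    sd = x.std(ddof=0)
    if sd == 0:
        raise GLMError("constant myelin regressor: model evidence undefined")
    return (x - x.mean()) / sd


def design_for(records: list[HemisphereRecord], map_type: str, roi: str) -> GLMModelSpec:
    """Intercept + one standardised myelin regressor for a (map, ROI) cell."""
    y = np.array([rec.moment_nAm for rec in records])
    x = _standardise([rec.myelin[(map_type, roi)] for rec in records])
    return GLMModelSpec(dependent=y, design=np.column_stack([np.ones_like(y), x]),
                        label=(map_type, roi))


@dataclass
class GLMPosterior:
    weight_mean: np.ndarray
    weight_cov: np.ndarray
    alpha_shape: float
    alpha_rate: float
    noise_shape: float
    noise_rate: float
    free_energy: float
    free_energy_trace: np.ndarray
    converged: bool

    @property
    def expected_noise_precision(self) -> float:
        return self.noise_shape / self.noise_rate


def _kl_gamma(a, b, a0, b0) -> float:
    """KL( Gamma(a,b) || Gamma(a0,b0) ), shape/rate parameterisation."""
    return float(
        (a - a0) * digamma(a)
        - gammaln(a)
        + gammaln(a0)
        + a0 * (np.log(b) - np.log(b0))
        + a * (b0 - b) / b
    )


def vb_glm(
    spec: GLMModelSpec,
    a0: float = 1e-6,
    b0: float = 1e-6,
    c0: float = 1e-6,
    d0: float = 1e-6,
    tol: float = 1e-6,
    max_iter: int = 200,
    fixed_alpha: float | None = None,
    fixed_lambda: float | None = None,
) -> GLMPosterior:
    """Mean-field VB for the Bayesian GLM; free energy in nats.

    ``fixed_alpha`` / ``fixed_lambda`` pin the corresponding precision
    (its Gamma factor and KL term drop out), in which case the model is
    conjugate and the converged free energy equals the exact log marginal
    likelihood.
    """
    y, X = spec.dependent, spec.design
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y

    Ea = fixed_alpha if fixed_alpha is not None else a0 / b0 if a0 / b0 > 0 else 1.0
    El = fixed_lambda if fixed_lambda is not None else 1.0 / max(np.var(y), 1e-12)
    a, b, c, d = a0, b0, c0, d0
    if fixed_alpha is None:
        Ea = 1.0
    Elog_a = np.log(Ea)
    Elog_l = np.log(El)

    F_prev = -np.inf
    trace = []
    converged = False
    for _ in range(max_iter):
        # q(w)
        Sw = np.linalg.inv(Ea * np.eye(p) + El * XtX)
        mw = El * Sw @ Xty
        resid2 = float(np.sum((y - X @ mw) ** 2) + np.trace(XtX @ Sw))
        w2 = float(mw @ mw + np.trace(Sw))
        # q(alpha)
        if fixed_alpha is None:
            a = a0 + p / 2.0
            b = b0 + w2 / 2.0
            Ea, Elog_a = a / b, digamma(a) - np.log(b)
        # q(lambda)
        if fixed_lambda is None:
            c = c0 + n / 2.0
            d = d0 + resid2 / 2.0
            El, Elog_l = c / d, digamma(c) - np.log(d)

        F = (
            0.5 * n * (Elog_l - np.log(2 * np.pi))
            - 0.5 * El * resid2
            + 0.5 * p * Elog_a
            - 0.5 * Ea * w2
            + 0.5 * np.linalg.slogdet(Sw)[1]
            + 0.5 * p
        )
        if fixed_alpha is None:
            F -= _kl_gamma(a, b, a0, b0)
        if fixed_lambda is None:
            F -= _kl_gamma(c, d, c0, d0)
        trace.append(F)
        if abs(F - F_prev) < tol:
            converged = True
            break
        F_prev = F

    return GLMPosterior(
        weight_mean=mw,
        weight_cov=Sw,
        alpha_shape=a,
        alpha_rate=b,
        noise_shape=c,
        noise_rate=d,
        free_energy=float(trace[-1]),
        free_energy_trace=np.array(trace),
        converged=converged,
    )


def posterior_odds(delta_log_evidence: float) -> float:
    """Posterior odds between two equal-prior models from their log-evidence gap."""
    return float(np.exp(delta_log_evidence))


def spatial_extent_comparison(
    records: list[HemisphereRecord],
    map_type: str,
    te1_weights: dict[str, float] | None = None,
    **vb_kwargs,
) -> dict:
    """Compare myelin regressors of increasing spatial extent.

    Three models per map: the lateral koniocortex sub-area TE1.2 alone;
    the whole koniocortex TE1 (voxel-count-weighted mean of TE1.0, TE1.1
    and TE1.2; equal weights if counts are not supplied); and the
    GM-masked whole-hemisphere mean (records must carry a ``global``
    myelin entry).  Log Bayes factors are reported relative to the worst
    model (normalised to zero).
    """
    y = np.array([rec.moment_nAm for rec in records])
    need = ["TE1.0", "TE1.1", "TE1.2", "global"]
    for rec in records:
        for ro in need:
            if (map_type, ro) not in rec.myelin:
                raise GLMError(f"record {rec.hemisphere_id} lacks ({map_type}, {ro})")
    te1_rois = ["TE1.0", "TE1.1", "TE1.2"]
    w = np.array([(te1_weights or {}).get(ro, 1.0) for ro in te1_rois], float)
    w = w / w.sum()

    regressors = {
        "TE1.2": _standardise([rec.myelin[(map_type, "TE1.2")] for rec in records]),
        "TE1": _standardise(
            [sum(wi * rec.myelin[(map_type, ro)] for wi, ro in zip(w, te1_rois))
             for rec in records]
        ),
        "global": _standardise([rec.myelin[(map_type, "global")] for rec in records]),
    }
    log_ev = {}
    for name, x in regressors.items():
        spec = GLMModelSpec(y, np.column_stack([np.ones_like(y), x]), (map_type, name))
        log_ev[name] = vb_glm(spec, **vb_kwargs).free_energy
    worst = min(log_ev.values())
    return {
        "log_evidence": log_ev,
        "log_bayes_factor_vs_worst": {k: v - worst for k, v in log_ev.items()},
    }


@dataclass
class EvidenceSet:
    """Log evidences of the maps x ROIs model grid plus family posteriors."""

    log_evidence: dict[tuple[str, str], float]
    model_posterior: dict[tuple[str, str], float] = field(default_factory=dict)
    roi_family_posterior: dict[str, float] = field(default_factory=dict)
    map_family_posterior: dict[str, float] = field(default_factory=dict)


def evidence_grid(
    records: list[HemisphereRecord], maps=MAP_TYPES, rois=ROI_LABELS, **vb_kwargs
) -> dict[tuple[str, str], float]:
    """Fit one single-regressor GLM per (map, ROI) cell; return log evidences."""
    out = {}
    for m in maps:
        for ro in rois:
            out[(m, ro)] = vb_glm(design_for(records, m, ro), **vb_kwargs).free_energy
    return out


def family_comparison(
    log_evidence: dict[tuple[str, str], float], maps=MAP_TYPES, rois=ROI_LABELS
) -> EvidenceSet:
    """Family posteriors over ROIs and over map types.

    Model posteriors are proportional to exp(log evidence) times a
    uniform prior over the complete maps x ROIs grid; each family
    posterior is the sum of its members' posteriors (log-sum-exp
    stabilised).  With the complete grid, a uniform prior over models is
    identical to hierarchically uniform family priors (1/3 per map,
    1/6 per ROI).
    """
    expected = {(m, ro) for m in maps for ro in rois}
    if set(log_evidence) != expected:
        missing = expected - set(log_evidence)
        raise GLMError(f"evidence grid incomplete; missing {sorted(missing)}")
    keys = sorted(expected)
    F = np.array([log_evidence[k] for k in keys])
    if not np.all(np.isfinite(F)):
        raise GLMError("non-finite log evidence")
    logpost = F - F.max()
    post = np.exp(logpost)
    post /= post.sum()
    model_post = dict(zip(keys, post))
    roi_post = {ro: float(sum(model_post[(m, ro)] for m in maps)) for ro in rois}
    map_post = {m: float(sum(model_post[(m, ro)] for ro in rois)) for m in maps}
    return EvidenceSet(
        log_evidence=dict(log_evidence),
        model_posterior={k: float(v) for k, v in model_post.items()},
        roi_family_posterior=roi_post,
        map_family_posterior=map_post,
    )
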