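"""Nonlinear mixed-effects estimation by FOCE with interaction.

The population model for subject i and observation j is

    y_ij = f(t_ij; theta, eta_i) * (1 + eps1_ij) [+ eps2_ij]   (residual form)
    eta_i ~ N(0, Omega),   diagonal Omega of log-normal BSV variances

with f the closed-form one-compartment infusion prediction and the
individual parameters P_i = TV(P) * exp(eta_i).  The marginal
-2 log-likelihood is approximated subject-by-subject with a Laplace
expansion about the conditional mode eta_hat_i (first-order conditional
estimation *with* interaction: the residual variance is evaluated at the
conditional prediction, not at eta = 0):

    OFV = sum_i [ h_i(eta_hat_i) - d*log(2*pi) + log det(H_i/2) ]

where h_i(eta) = -2 log p(y_i | eta) - 2 log p(eta) and H_i is the
curvature of h_i at the mode.  The inner mode search is a vectorised
safeguarded Newton iteration across subjects (finite-difference
derivatives, backtracking line search); the outer fit is a quasi-Newton
(L-BFGS-B) minimisation over transformed parameters, with variance
components log-transformed for positivity.  All estimation is
deterministic given the data and the initial values.

An adaptive Gauss-Hermite quadrature oracle and a Monte-Carlo marginal
likelihood are provided for cross-checking the Laplace approximation on
small problems.

The user-facing surface follows the Model/Results pattern:
`PopPKModel(data, spec).fit()` returns a `PopPKResults` carrying the
estimates, OFV, empirical Bayes etas, shrinkages and diagnostics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp

from .covariates import (
    CovariateModelSpec,
    ResidualErrorSpec,
    load_model_spec,
    published_variability,
)

__all__ = [
    "PopulationParameters",
    "FitResult",
    "PopPKResults",
    "PopPKModel",
    "EstimationError",
    "individual_minus2ll",
    "map_eta",
    "ofv_foce",
    "ofv_quadrature_oracle",
    "mc_oracle_minus2ll",
    "fit_population",
    "compute_shrinkage",
    "jittered_init",
]


class EstimationError(RuntimeError):
    pass


@dataclass(frozen=True)
class PopulationParameters:
    """Fixed effects, BSV variances (as SDs) and residual-error model."""

    theta: tuple
    omega_cl: float
    sigma: ResidualErrorSpec
    omega_v: float = 0.0
    spec: CovariateModelSpec | None = None

    def __post_init__(self) -> None:
        if self.omega_cl < 0 or self.omega_v < 0:
            raise ValueError("omega must be >= 0 (reported as SD)")

    @classmethod
    def published(cls, name: str) -> "PopulationParameters":
        """Published final-model estimates ('model1', 'model2', 'model3')."""
        spec = load_model_spec(name)
        omega, sigma = published_variability(name)
        return cls(
            theta=tuple(spec.theta),
            omega_cl=omega,
            sigma=ResidualErrorSpec("proportional", sigma),
            spec=spec,
        )

    def to_dict(self) -> dict:
        return {
            "theta": list(self.theta),
            "omega_cl": self.omega_cl,
            "omega_v": self.omega_v,
            "sigma": {"form": self.sigma.form, "sigma1": self.sigma.sigma1,
                      "sigma2": self.sigma.sigma2},
            "spec": self.spec.to_dict() if self.spec is not None else None,
        }


# -- dataset packing -----------------------------------------------------------


class _PackedDataset:
    """Flat arrays for vectorised prediction across all subjects.

    Each (observation, dose) pair within a subject becomes one row of
    the pair arrays; the multi-infusion superposition is then a single
    vectorised pass plus a bincount back onto observations.
    """

    def __init__(self, subjects: Sequence, covariate_names: Iterable[str]):
        subjects = list(subjects)
        if not subjects:
            raise ValueError("dataset has no subjects")
        self.subjects = subjects
        self.n_sub = len(subjects)
        self.ids = [s.id for s in subjects]
        cov_rows = [s.covariates.as_dict() for s in subjects]
        names = set(covariate_names) | {"WT"}
        self.cov = {
            name: np.array([row.get(name) for row in cov_rows], dtype=float)
            for name in names
        }
        obs_sub, obs_t, obs_dv, obs_kind = [], [], [], []
        p_obs, p_sub, p_dt, p_dur, p_rate = [], [], [], [], []
        for i, s in enumerate(subjects):
            if len(s.observations) == 0:
                raise ValueError(f"subject {s.id} has no observations")
            for ob in s.observations:
                j = len(obs_t)
                obs_sub.append(i)
                obs_t.append(ob.time)
                obs_dv.append(ob.dv)
                obs_kind.append(getattr(ob, "kind", ""))
                for ev in s.doses:
                    p_obs.append(j)
                    p_sub.append(i)
                    p_dt.append(ob.time - ev.start_time)
                    p_dur.append(ev.duration)
                    p_rate.append(ev.rate)
        self.obs_sub = np.array(obs_sub, dtype=np.intp)
        self.obs_t = np.array(obs_t)
        self.obs_dv = np.array(obs_dv)
        self.obs_kind = np.array(obs_kind)
        self.n_obs = len(obs_t)
        self.pair_obs = np.array(p_obs, dtype=np.intp)
        self.pair_sub = np.array(p_sub, dtype=np.intp)
        dt = np.array(p_dt)
        dur = np.array(p_dur)
        self.pair_rate = np.array(p_rate)
        self.pair_rise_t = np.clip(dt, 0.0, dur)       # time inside the infusion
        self.pair_decay_t = np.clip(dt - dur, 0.0, None)
        self.pair_active = dt > 0.0

    def predict(self, cl: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Concentrations at all observations for per-subject CL/V arrays."""
        k = cl / v
        kp = k[self.pair_sub]
        clp = cl[self.pair_sub]
        rise = (self.pair_rate / clp) * -np.expm1(-kp * self.pair_rise_t)
        contrib = np.where(
            self.pair_active, rise * np.exp(-kp * self.pair_decay_t), 0.0
        )
        return np.bincount(self.pair_obs, weights=contrib, minlength=self.n_obs)

    def subset(self, indices: Sequence[int]) -> "_PackedDataset":
        """Subjects re-selected (with repetition allowed) for the bootstrap."""
        subs = []
        for new_i, i in enumerate(indices):
            s = self.subjects[i]
            subs.append(replace(s, id=f"{s.id}#{new_i}") if hasattr(s, "id") else s)
        return _PackedDataset(subs, self.cov.keys())


def _as_subjects(data) -> list:
    """Accept a cohort list, an AnalysisDataset, or an event DataFrame."""
    if isinstance(data, _PackedDataset):
        return data.subjects
    if isinstance(data, pd.DataFrame):
        from .dataio import AnalysisDataset

        return AnalysisDataset(data).to_subjects()
    if hasattr(data, "to_subjects"):
        return data.to_subjects()
    return list(data)


def _pack(data, spec: CovariateModelSpec) -> _PackedDataset:
    if isinstance(data, _PackedDataset):
        return data
    return _PackedDataset(_as_subjects(data), spec.required_covariates)


# -- inner (conditional) step --------------------------------------------------

_FD_DELTA = 1e-4
_INNER_TOL = 1e-8
_OMEGA_DEGENERATE = 1e-10


class _FoceEngine:
    """Vectorised conditional-mode search and Laplace OFV for one design."""

    def __init__(self, packed: _PackedDataset, spec: CovariateModelSpec,
                 eta_on: Sequence[str] = ("CL",)):
        self.packed = packed
        self.spec = spec
        self.eta_on = tuple(eta_on)
        if not self.eta_on or not set(self.eta_on) <= {"CL", "V"}:
            raise ValueError("eta_on must be a non-empty subset of ('CL', 'V')")
        self.d = len(self.eta_on)
        self._i_cl = self.eta_on.index("CL") if "CL" in self.eta_on else None
        self._i_v = self.eta_on.index("V") if "V" in self.eta_on else None
        self._warm_eta: np.ndarray | None = None

    # parameters ---------------------------------------------------------------

    def set_params(self, theta, omega: np.ndarray, sigma: ResidualErrorSpec) -> None:
        tvcl, tvv = self.spec.typical_cl_v(self.packed.cov, tuple(theta))
        self.tvcl = np.asarray(tvcl, dtype=float)
        self.tvv = np.asarray(tvv, dtype=float) * np.ones(self.packed.n_sub)
        self.omega = np.asarray(omega, dtype=float)
        self.sigma = sigma
        om = np.maximum(self.omega, _OMEGA_DEGENERATE)
        self._prior_const = float(np.sum(np.log(2 * np.pi * om**2)))
        self._inv_om2 = 1.0 / om**2

    @property
    def degenerate(self) -> bool:
        return bool(np.all(self.omega <= _OMEGA_DEGENERATE))

    # likelihood pieces --------------------------------------------------------

    def _cl_v(self, eta: np.ndarray):
        eta_cl = eta[:, self._i_cl] if self._i_cl is not None else 0.0
        eta_v = eta[:, self._i_v] if self._i_v is not None else 0.0
        return self.tvcl * np.exp(eta_cl), self.tvv * np.exp(eta_v)

    def obs_minus2ll(self, eta: np.ndarray) -> np.ndarray:
        """Per-subject -2 log p(y | eta) (Gaussian observation density)."""
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            cl, v = self._cl_v(eta)
            f = self.packed.predict(cl, v)
            var = np.maximum(self.sigma.variance(f), 1e-290)
            terms = np.log(2 * np.pi * var) + (self.packed.obs_dv - f) ** 2 / var
            out = np.bincount(self.packed.obs_sub, weights=terms,
                              minlength=self.packed.n_sub)
        # overflow in degenerate corners of the parameter space: treat as
        # an effectively impossible fit rather than propagating NaN
        return np.where(np.isfinite(out), out, 1e12)

    def h(self, eta: np.ndarray) -> np.ndarray:
        """Joint -2 log [p(y|eta) p(eta)] per subject."""
        prior = np.sum(eta**2 * self._inv_om2, axis=1)
        return self.obs_minus2ll(eta) + prior + self._prior_const

    def predict_at(self, eta: np.ndarray) -> np.ndarray:
        cl, v = self._cl_v(eta)
        return self.packed.predict(cl, v)

    # derivatives --------------------------------------------------------------

    def _grad_hess(self, eta: np.ndarray, h0: np.ndarray):
        n, d = eta.shape
        g = np.empty((n, d))
        H = np.empty((n, d, d))
        hp = np.empty((n, d))
        hm = np.empty((n, d))
        for m in range(d):
            e = np.zeros(d)
            e[m] = _FD_DELTA
            hp[:, m] = self.h(eta + e)
            hm[:, m] = self.h(eta - e)
            g[:, m] = (hp[:, m] - hm[:, m]) / (2 * _FD_DELTA)
            H[:, m, m] = (hp[:, m] - 2 * h0 + hm[:, m]) / _FD_DELTA**2
        if d == 2:
            e0 = np.array([_FD_DELTA, 0.0])
            e1 = np.array([0.0, _FD_DELTA])
            cross = (
                self.h(eta + e0 + e1) - self.h(eta + e0 - e1)
                - self.h(eta - e0 + e1) + self.h(eta - e0 - e1)
            ) / (4 * _FD_DELTA**2)
            H[:, 0, 1] = H[:, 1, 0] = cross
        return g, H

    @staticmethod
    def _newton_step(g: np.ndarray, H: np.ndarray) -> np.ndarray:
        n, d = g.shape
        if d == 1:
            h = H[:, 0, 0]
            hpd = np.where(h > 1e-9, h, np.maximum(np.abs(h), 1.0))
            return (-g[:, 0] / hpd)[:, None]
        # 2x2 with ridge where indefinite
        a, b, c = H[:, 0, 0], H[:, 0, 1], H[:, 1, 1]
        tr = a + c
        det = a * c - b * b
        lam_min = tr / 2 - np.sqrt(np.maximum((tr / 2) ** 2 - det, 0.0))
        ridge = np.where(lam_min < 1e-8, 1e-8 - np.minimum(lam_min, 0.0) + 1e-8, 0.0)
        a = a + ridge
        c = c + ridge
        det = a * c - b * b
        sx = -(c * g[:, 0] - b * g[:, 1]) / det
        sy = -(-b * g[:, 0] + a * g[:, 1]) / det
        return np.stack([sx, sy], axis=1)

    # mode search --------------------------------------------------------------

    def _grid_init(self) -> np.ndarray:
        n = self.packed.n_sub
        eta = np.zeros((n, self.d))
        if self.d != 1:
            return eta
        scale = max(float(np.max(self.omega)), 0.1)
        grid = np.linspace(-4.0, 4.0, 17) * scale
        best = np.full(n, np.inf)
        pick = np.zeros(n)
        for gval in grid:
            hv = self.h(np.full((n, 1), gval))
            better = hv < best
            best = np.where(better, hv, best)
            pick = np.where(better, gval, pick)
        return pick[:, None]

    def map_all(self, eta0: np.ndarray | None = None, tol: float = _INNER_TOL,
                max_iter: int = 60):
        """Conditional modes for all subjects; returns (eta, H, h, converged)."""
        if self.degenerate:
            eta = np.zeros((self.packed.n_sub, self.d))
            h0 = self.h(eta)
            _, H = self._grad_hess(eta, h0)
            return eta, H, h0, np.ones(self.packed.n_sub, dtype=bool)
        eta = self._grid_init() if eta0 is None else np.array(eta0, dtype=float)
        h0 = self.h(eta)
        converged = np.zeros(self.packed.n_sub, dtype=bool)
        g = H = None
        for _ in range(max_iter):
            g, H = self._grad_hess(eta, h0)
            gnorm = np.max(np.abs(g), axis=1)
            converged = gnorm <= tol * (1.0 + np.abs(h0))
            if converged.all():
                break
            step = self._newton_step(g, H)
            lam = np.ones(self.packed.n_sub)
            active = ~converged
            trial = eta
            h1 = h0
            accepted = np.zeros_like(converged)
            for _bt in range(30):
                trial = eta + (lam * active)[:, None] * step
                h1 = self.h(trial)
                ok = h1 <= h0 + 1e-11
                accepted = active & ok
                bad = active & ~ok
                if not bad.any():
                    break
                lam[bad] *= 0.5
            eta = np.where(accepted[:, None], trial, eta)
            h0 = np.where(accepted, h1, h0)
            if not accepted.any():
                break
        if g is None or not converged.all():
            g, H = self._grad_hess(eta, h0)
            gnorm = np.max(np.abs(g), axis=1)
            converged = gnorm <= 100 * tol * (1.0 + np.abs(h0))
        return eta, H, h0, converged

    def map_with_restart(self, eta0: np.ndarray | None = None):
        eta, H, h0, conv = self.map_all(eta0)
        if not conv.all():
            # grid-initialised restart for the stragglers
            eta2, H2, h02, conv2 = self.map_all(None, max_iter=200)
            take = ~conv & (h02 <= h0 + 1e-9)
            eta = np.where(take[:, None], eta2, eta)
            H = np.where(take[:, None, None], H2, H)
            h0 = np.where(take, h02, h0)
            conv = conv | conv2
        return eta, H, h0, conv

    def ofv(self, eta0: np.ndarray | None = None, warm: bool = False,
            strict: bool = True):
        """Laplace/FOCE-I OFV; optionally warm-started from the last call."""
        start = self._warm_eta if (warm and self._warm_eta is not None
                                   and not self.degenerate) else eta0
        if start is not None and start.shape != (self.packed.n_sub, self.d):
            start = None
        eta, H, h0, conv = self.map_with_restart(start)
        self._warm_eta = eta
        if strict and not conv.all():
            bad = [self.packed.ids[i] for i in np.nonzero(~conv)[0]]
            raise EstimationError(
                f"inner step failed to converge for subjects {bad}"
            )
        if self.degenerate:
            return float(np.sum(self.obs_minus2ll(eta))), eta, H
        logdet = self._laplace_logdet(H)
        ofv = float(np.sum(h0 - self.d * np.log(2 * np.pi) + logdet))
        return ofv, eta, H

    def _laplace_logdet(self, H: np.ndarray) -> np.ndarray:
        if self.d == 1:
            return np.log(np.maximum(H[:, 0, 0], 1e-12) / 2.0)
        a, b, c = H[:, 0, 0], H[:, 0, 1], H[:, 1, 1]
        det = np.maximum(a * c - b * b, 1e-24)
        return np.log(det / 4.0)


# -- public operations ---------------------------------------------------------


def _engine_for(subject_or_data, params: PopulationParameters,
                spec: CovariateModelSpec | None) -> _FoceEngine:
    spec = spec or params.spec
    if spec is None:
        raise ValueError("a CovariateModelSpec is required (params.spec is unset)")
    data = subject_or_data if isinstance(subject_or_data, (list, _PackedDataset)) \
        else [subject_or_data]
    packed = _pack(data, spec)
    eta_on = ("CL", "V") if params.omega_v > 0 else ("CL",)
    eng = _FoceEngine(packed, spec, eta_on)
    omega = np.array([params.omega_cl] + ([params.omega_v] if params.omega_v > 0 else []))
    eng.set_params(params.theta, omega, params.sigma)
    return eng


def individual_minus2ll(subject, params: PopulationParameters, eta,
                        spec: CovariateModelSpec | None = None) -> float:
    """-2 log of the Gaussian observation density of one subject given eta."""
    eng = _engine_for(subject, params, spec)
    eta_arr = np.atleast_1d(np.asarray(eta, dtype=float))[None, :]
    if eta_arr.shape[1] != eng.d:
        raise ValueError(f"eta must have length {eng.d}")
    return float(eng.obs_minus2ll(eta_arr)[0])


def map_eta(subject, params: PopulationParameters,
            spec: CovariateModelSpec | None = None):
    """Empirical Bayes mode eta_hat and curvature for one subject.

    Minimises the joint -2 log [p(y|eta) p(eta)]; in the omega -> 0
    limit the prior dominates and eta_hat -> 0.
    """
    eng = _engine_for(subject, params, spec)
    eta, H, _h, conv = eng.map_with_restart(None)
    if not conv.all():
        raise EstimationError(f"conditional mode search failed for {subject.id}")
    return eta[0], H[0]


def ofv_foce(dataset, spec: CovariateModelSpec, params: PopulationParameters) -> float:
    """FOCE-with-interaction objective function value for a dataset."""
    eng = _engine_for(_as_subjects(dataset), params, spec)
    ofv, _eta, _H = eng.ofv()
    return ofv


def ofv_quadrature_oracle(dataset, spec: CovariateModelSpec,
                          params: PopulationParameters, n_nodes: int = 64) -> float:
    """-2 log marginal likelihood by adaptive Gauss-Hermite quadrature.

    One-dimensional eta only; nodes are centred at the conditional mode
    and scaled by its curvature.  Independent oracle for `ofv_foce`.
    """
    if params.omega_v > 0:
        raise ValueError("quadrature oracle supports a 1-D eta only")
    subjects = _as_subjects(dataset)
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    total = 0.0
    for s in subjects:
        eng = _engine_for(s, params, spec)
        if eng.degenerate:
            total += float(eng.obs_minus2ll(np.zeros((1, 1)))[0])
            continue
        eta_hat, H, _h, conv = eng.map_with_restart(None)
        if not conv.all():
            raise EstimationError(f"oracle mode search failed for {s.id}")
        curv = max(float(H[0, 0, 0]), 1e-12)
        sd = math.sqrt(2.0 / curv)
        pts = eta_hat[0, 0] + math.sqrt(2.0) * sd * nodes
        hv = _h_many(eng, pts)
        log_terms = np.log(weights) + nodes**2 - hv / 2.0
        log_l = logsumexp(log_terms) + math.log(math.sqrt(2.0) * sd)
        if not np.isfinite(log_l):
            raise EstimationError(f"quadrature non-finite for subject {s.id}")
        total += -2.0 * log_l
    return total


def _obs_m2ll_many(eng: _FoceEngine, etas: np.ndarray) -> np.ndarray:
    """-2 log p(y|eta) of a single-subject engine at many 1-D eta values."""
    p = eng.packed
    if p.n_sub != 1 or eng.d != 1:
        raise ValueError("vectorised evaluation needs one subject and 1-D eta")
    cl = eng.tvcl[0] * np.exp(etas)          # (n,)
    k = (cl / eng.tvv[0])[:, None]           # (n, 1)
    rise = (p.pair_rate[None, :] / cl[:, None]) * -np.expm1(-k * p.pair_rise_t[None, :])
    contrib = np.where(p.pair_active[None, :],
                       rise * np.exp(-k * p.pair_decay_t[None, :]), 0.0)
    # sum pair contributions onto observations
    f = np.zeros((len(etas), p.n_obs))
    np.add.at(f.T, p.pair_obs, contrib.T)
    var = np.maximum(eng.sigma.variance(f), 1e-290)
    terms = np.log(2 * np.pi * var) + (p.obs_dv[None, :] - f) ** 2 / var
    return terms.sum(axis=1)


def _h_many(eng: _FoceEngine, etas: np.ndarray) -> np.ndarray:
    """Joint -2 log [p(y|eta) p(eta)] at many 1-D eta values (one subject)."""
    prior = etas**2 * eng._inv_om2[0] + eng._prior_const
    return _obs_m2ll_many(eng, etas) + prior


def mc_oracle_minus2ll(subject, params: PopulationParameters,
                       spec: CovariateModelSpec | None = None,
                       n_draws: int = 100_000, seed: int = 0):
    """Monte-Carlo -2 log marginal likelihood for one subject.

    Returns (estimate, approximate MC standard error on the -2 log scale).
    """
    eng = _engine_for(subject, params, spec)
    rng = np.random.default_rng(seed)
    etas = rng.normal(0.0, params.omega_cl, size=n_draws)
    m2 = _obs_m2ll_many(eng, etas)
    logp = -m2 / 2.0
    log_l = logsumexp(logp) - math.log(n_draws)
    # delta-method MC se of -2 log mean
    w = np.exp(logp - logp.max())
    se_mean = np.std(w, ddof=1) / math.sqrt(n_draws) / np.mean(w)
    return -2.0 * log_l, 2.0 * se_mean


# -- parameter transforms ------------------------------------------------------


def _encode(spec, theta, omegas, sigma, sigma_form):
    pos = set(spec.positive_params)
    x = [math.log(v) if n in pos else v for n, v in zip(spec.param_names, theta)]
    x += [math.log(max(o, 1e-6)) for o in omegas]
    x.append(math.log(max(sigma.sigma1, 1e-6)))
    if sigma_form == "mixed":
        x.append(math.log(max(sigma.sigma2, 1e-6)))
    return np.array(x)


_LOG_VAR_FLOOR = math.log(1e-3)  # variance components as SDs never below 0.1%


def _decode(x, spec, n_eta, sigma_form):
    pos = set(spec.positive_params)
    names = spec.param_names
    nt = len(names)
    xt = np.clip(x, -30.0, 30.0)
    theta = tuple(
        math.exp(xt[i]) if names[i] in pos else float(xt[i]) for i in range(nt)
    )
    # a hard scale floor keeps the conditional problem well-posed when a
    # near-interpolating fit pushes a variance toward zero
    var_part = np.clip(xt[nt:], _LOG_VAR_FLOOR, 6.0)
    omegas = np.exp(var_part[:n_eta])
    s1 = math.exp(var_part[n_eta])
    s2 = math.exp(var_part[n_eta + 1]) if sigma_form == "mixed" else 0.0
    sigma = ResidualErrorSpec(sigma_form, s1, s2)
    return theta, omegas, sigma


def jittered_init(params: PopulationParameters, rng, frac: float = 0.2
                  ) -> PopulationParameters:
    """Multiplicative +-frac jitter of every component (refit initialisation)."""
    jit = lambda v: v * (1.0 + rng.uniform(-frac, frac))
    theta = tuple(jit(t) for t in params.theta)
    sigma = ResidualErrorSpec(params.sigma.form, jit(params.sigma.sigma1),
                              jit(params.sigma.sigma2) if params.sigma.sigma2 else 0.0)
    return replace(params, theta=theta, omega_cl=jit(params.omega_cl),
                   omega_v=jit(params.omega_v) if params.omega_v else 0.0,
                   sigma=sigma)


# -- Model / Results -----------------------------------------------------------


class PopPKModel:
    """Population PK model bound to a dataset and a covariate structure.

    Parameters
    ----------
    data : cohort (list of SubjectRecord), AnalysisDataset, or event DataFrame
    spec : CovariateModelSpec
        Structural CL/V covariate equations; its theta values serve as
        the default initialisation.
    residual : str
        Residual-error form: 'additive' | 'proportional' | 'mixed'.
    eta_on : tuple
        Parameters carrying between-subject variability ('CL' and/or
        'V'); the published final models carry BSV on CL only.
    """

    def __init__(self, data, spec: CovariateModelSpec,
                 residual: str = "proportional", eta_on: Sequence[str] = ("CL",)):
        self.spec = spec
        self.residual = residual
        self.eta_on = tuple(eta_on)
        self._packed = _pack(data, spec)
        self._engine = _FoceEngine(self._packed, spec, self.eta_on)
        n_per = np.bincount(self._packed.obs_sub, minlength=self._packed.n_sub)
        if np.any(n_per < 2):
            import warnings

            warnings.warn(
                "some subjects have fewer than 2 observations; the fit may be "
                "poorly identified", stacklevel=2,
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, spec: CovariateModelSpec, **kw):
        return cls(df, spec, **kw)

    @property
    def n_subjects(self) -> int:
        return self._packed.n_sub

    @property
    def n_obs(self) -> int:
        return self._packed.n_obs

    # ------------------------------------------------------------------

    def _params_tuple(self, params: PopulationParameters):
        omegas = [params.omega_cl]
        if "V" in self.eta_on:
            omegas.append(params.omega_v)
        return tuple(params.theta), np.array(omegas), params.sigma

    def ofv(self, params: PopulationParameters) -> float:
        theta, omegas, sigma = self._params_tuple(params)
        self._engine.set_params(theta, omegas, sigma)
        val, _, _ = self._engine.ofv(warm=False)
        return val

    def evaluate(self, params: PopulationParameters) -> "PopPKResults":
        """Results object at fixed parameters (EBEs and OFV, no fitting)."""
        theta, omegas, sigma = self._params_tuple(params)
        self._engine.set_params(theta, omegas, sigma)
        self._engine._warm_eta = None
        ofv, eta, _H = self._engine.ofv(warm=False, strict=False)
        ipred = self._engine.predict_at(eta)
        return PopPKResults(
            model=self, params=params, ofv=float(ofv), ebe=eta, ipred=ipred,
            converged=True, n_iter=0, message="evaluated at fixed parameters",
        )

    def _default_init(self) -> PopulationParameters:
        """Crude initial values from the TDM design.

        Per-subject clearance is guessed from the daily dose rate over
        the trapezoid mean of the observed trough/peak pair; volume from
        a typical infant elimination rate constant.
        """
        packed = self._packed
        cls = []
        for i, s in enumerate(packed.subjects):
            daily = sum(ev.amount for ev in s.doses if ev.start_time < 24.0)
            dv = np.array([ob.dv for ob in s.observations])
            cavg = max(float(np.mean(dv)), 1e-3)
            cls.append(daily / (24.0 * cavg))
        cl_i = np.array(cls)
        wt = packed.cov["WT"]
        th1 = float(np.median(cl_i * (self.spec.wt_median / wt)))
        th1 = min(max(th1, 1e-3), 100.0)
        th2 = th1 / 0.15  # typical infant k ~ 0.15 1/h
        theta = []
        for name in self.spec.param_names:
            if name == "theta1":
                theta.append(th1)
            elif name == "theta2":
                theta.append(th2)
            elif name in ("theta3", "theta4"):
                theta.append(1.0)
            elif name in ("tm50", "k50"):
                theta.append(0.5)
            elif name == "hill":
                theta.append(2.0)
            elif name == "theta0":
                theta.append(1.0)
            elif name == "kmax":
                theta.append(0.5)
            else:  # covariate terms
                theta.append(0.0 if "theta" in name else 0.1)
        return PopulationParameters(
            theta=tuple(theta), omega_cl=0.3,
            omega_v=0.3 if "V" in self.eta_on else 0.0,
            sigma=ResidualErrorSpec(self.residual, 0.3, 0.3 if self.residual == "mixed" else 0.0),
            spec=self.spec,
        )

    def fit(self, init: PopulationParameters | None = None,
            maxiter: int = 300, gtol: float = 1e-6, ftol: float = 1e-10,
            fd_eps: float = 1e-6) -> "PopPKResults":
        """Minimise the FOCE OFV over (theta, omega, sigma).

        Deterministic given the data and `init`; returns a
        `PopPKResults` whether or not the optimiser reports success (the
        convergence status is carried on the result, never silent).
        """
        if init is None:
            init = self._default_init()
        theta0, omegas0, sigma0 = self._params_tuple(init)
        if sigma0.form != self.residual:
            sigma0 = ResidualErrorSpec(self.residual, sigma0.sigma1, sigma0.sigma2 or 0.3)
        x0 = _encode(self.spec, theta0, omegas0, sigma0, self.residual)
        eng = self._engine
        eng._warm_eta = None  # determinism: no state leaks between fits
        n_eta = len(self.eta_on)

        def objective(x):
            theta, omegas, sigma = _decode(x, self.spec, n_eta, self.residual)
            try:
                eng.set_params(theta, omegas, sigma)
                val, _, _ = eng.ofv(warm=True, strict=False)
            except (FloatingPointError, ValueError):
                return 1e12
            return val if np.isfinite(val) else 1e12

        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            f0 = objective(x0)
            res = optimize.minimize(
                objective, x0, method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": ftol, "gtol": gtol,
                         "eps": fd_eps},
            )
        theta, omegas, sigma = _decode(res.x, self.spec, n_eta, self.residual)
        eng.set_params(theta, omegas, sigma)
        ofv, eta, H = eng.ofv(warm=False, strict=False)
        params = PopulationParameters(
            theta=theta, omega_cl=float(omegas[0]),
            omega_v=float(omegas[1]) if n_eta > 1 else 0.0,
            sigma=sigma, spec=self.spec.with_theta(theta),
        )
        # a line search that cannot improve on an initial value already at
        # the optimum terminates "abnormally"; a finite, non-increased OFV
        # still counts as converged
        converged = bool(res.success) or (
            np.isfinite(ofv) and res.fun <= f0 + 1e-6
        )
        ipred = eng.predict_at(eta)
        return PopPKResults(
            model=self, params=params, ofv=float(ofv), ebe=eta,
            ipred=ipred, converged=converged, n_iter=int(res.nit),
            message=str(res.message),
        )


@dataclass
class PopPKResults:
    """Fitted population estimates with their diagnostics.

    Attributes
    ----------
    params : PopulationParameters
    ofv : float
    ebe : ndarray (n_subjects, n_eta)
        Empirical Bayes (conditional-mode) eta estimates.
    eta_shrinkage, eps_shrinkage : percent, see `compute_shrinkage`.
    """

    model: PopPKModel
    params: PopulationParameters
    ofv: float
    ebe: np.ndarray
    ipred: np.ndarray
    converged: bool
    n_iter: int
    message: str = ""
    rse: dict | None = None

    # -- shrinkage -------------------------------------------------------------

    @property
    def iwres(self) -> np.ndarray:
        sd = np.maximum(self.params.sigma.sd(self.ipred), 1e-290)
        return (self.model._packed.obs_dv - self.ipred) / sd

    @property
    def eta_shrinkage(self) -> float:
        if self.params.omega_cl <= 0:
            return float("nan")
        i = self.model.eta_on.index("CL")
        sd = float(np.std(self.ebe[:, i], ddof=1))
        return 100.0 * (1.0 - sd / self.params.omega_cl)

    @property
    def eps_shrinkage(self) -> float:
        return 100.0 * (1.0 - float(np.std(self.iwres, ddof=1)))

    @property
    def param_table(self) -> pd.DataFrame:
        names = list(self.model.spec.param_names)
        values = list(self.params.theta)
        names.append("BSV_CL")
        values.append(self.params.omega_cl)
        if "V" in self.model.eta_on:
            names.append("BSV_V")
            values.append(self.params.omega_v)
        label = {"additive": "ADD_RV", "proportional": "PROP_RV", "mixed": "PROP_RV"}
        names.append(label[self.params.sigma.form])
        values.append(self.params.sigma.sigma1)
        if self.params.sigma.form == "mixed":
            names.append("ADD_RV")
            values.append(self.params.sigma.sigma2)
        df = pd.DataFrame({"parameter": names, "estimate": values})
        if self.rse:
            df["rse_pct"] = [self.rse.get(n, np.nan) for n in names]
        return df

    def ebe_table(self) -> pd.DataFrame:
        cols = {f"eta_{p}": self.ebe[:, i] for i, p in enumerate(self.model.eta_on)}
        return pd.DataFrame({"ID": self.model._packed.ids, **cols})

    def summary(self) -> str:
        lines = [
            "Population PK fit (FOCE with interaction)",
            f"  model spec:     {self.model.spec.name} ({self.model.spec.form})",
            f"  subjects/obs:   {self.model.n_subjects}/{self.model.n_obs}",
            f"  OFV:            {self.ofv:.3f}",
            f"  converged:      {self.converged} ({self.n_iter} iterations)",
            "",
            self.param_table.to_string(index=False,
                                       float_format=lambda v: f"{v:.4g}"),
            "",
            f"  eta-shrinkage (CL):  {self.eta_shrinkage:.1f}%",
            f"  eps-shrinkage:       {self.eps_shrinkage:.1f}%",
        ]
        return "\n".join(lines)

    def compute_rse(self, eps: float = 1e-4) -> dict:
        """Relative standard errors (%) by finite-difference OFV Hessian."""
        spec = self.model.spec
        n_eta = len(self.model.eta_on)
        x = _encode(spec, self.params.theta,
                    [self.params.omega_cl] + ([self.params.omega_v] if n_eta > 1 else []),
                    self.params.sigma, self.params.sigma.form)
        eng = self.model._engine

        def f(xv):
            th, om, sg = _decode(xv, spec, n_eta, self.params.sigma.form)
            eng.set_params(th, om, sg)
            val, _, _ = eng.ofv(warm=True, strict=False)
            return val

        n = len(x)
        Hm = np.zeros((n, n))
        f0 = f(x)
        for i in range(n):
            for j in range(i, n):
                ei = np.zeros(n); ei[i] = eps
                ej = np.zeros(n); ej[j] = eps
                Hm[i, j] = Hm[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * eps * eps)
        try:
            cov = 2.0 * np.linalg.inv(Hm)
            se_t = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se_t = np.full(n, np.nan)
        names = list(spec.param_names) + ["BSV_CL"] \
            + (["BSV_V"] if n_eta > 1 else []) \
            + (["PROP_RV"] if self.params.sigma.form != "additive" else ["ADD_RV"]) \
            + (["ADD_RV"] if self.params.sigma.form == "mixed" else [])
        pos = set(spec.positive_params) | {"BSV_CL", "BSV_V", "PROP_RV", "ADD_RV"}
        values = dict(zip(names, list(self.params.theta)
                          + [self.params.omega_cl]
                          + ([self.params.omega_v] if n_eta > 1 else [])
                          + [self.params.sigma.sigma1]
                          + ([self.params.sigma.sigma2] if self.params.sigma.form == "mixed" else [])))
        rse = {}
        for name, se in zip(names, se_t):
            v = values[name]
            # log-scale se equals relative se for log-transformed parameters
            rse[name] = 100.0 * se if name in pos else (
                100.0 * se / abs(v) if v else np.nan)
        self.rse = rse
        return rse

    # -- delegated diagnostics -------------------------------------------------

    def gof(self) -> pd.DataFrame:
        from .diagnostics import gof_residuals

        return gof_residuals(self)

    def vpc(self, n_sim: int = 500, bins: str = "kind", seed: int = 0):
        from .diagnostics import vpc

        return vpc(self, n_sim=n_sim, bins=bins, seed=seed)

    def bootstrap(self, n_reps: int = 200, seed: int = 0):
        from .diagnostics import bootstrap

        return bootstrap(self, n_reps=n_reps, seed=seed)

    def validate(self, external_data):
        from .diagnostics import external_validation

        return external_validation(self.params, self.model.spec, external_data)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "ofv": self.ofv,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "message": self.message,
            "eta_shrinkage_pct": self.eta_shrinkage,
            "eps_shrinkage_pct": self.eps_shrinkage,
            "rse_pct": self.rse,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


FitResult = PopPKResults


def fit_population(dataset, spec: CovariateModelSpec,
                   init: PopulationParameters | None = None,
                   options: Mapping | None = None,
                   residual: str = "proportional",
                   eta_on: Sequence[str] = ("CL",)) -> PopPKResults:
    """Functional wrapper over `PopPKModel(...).fit(...)`."""
    model = PopPKModel(dataset, spec, residual=residual, eta_on=eta_on)
    return model.fit(init=init, **(dict(options) if options else {}))


def compute_shrinkage(fit: PopPKResults, dataset=None) -> tuple:
    """(eta-shrinkage %, eps-shrinkage %) of the empirical Bayes estimates.

    eta-shrinkage = 100*(1 - SD(eta_hat)/omega); eps-shrinkage
    = 100*(1 - SD(IWRES)) with IWRES = (Y - IPRED)/sd(IPRED).  With
    omega = 0 the eta-shrinkage is undefined and returned as NaN.
    """
    return fit.eta_shrinkage, fit.eps_shrinkage
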