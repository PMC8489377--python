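"""Goodness-of-fit residuals, VPC, bootstrap and external validation.

* `gof_residuals` builds the DV/PRED/IPRED/CWRES table; CWRES follows
  the conditional (FOCE) linearisation — the residual vector is
  decorrelated by the approximate marginal covariance G*Omega*G' + V
  obtained from a first-order expansion about the conditional mode.
* `vpc` simulates replicate datasets under the fitted design and
  compares observed 5th/50th/95th percentiles per bin against the
  simulation distribution of those percentiles (90% prediction
  interval).
* `bootstrap` resamples subjects with replacement and refits, reporting
  medians, 2.5-97.5% percentile intervals, bias% relative to the point
  estimate, and the refit success rate.
* `external_validation` Bayesian-forecasts individual concentrations
  (MAP eta with population parameters fixed) and computes the MPE
  family of predictive metrics; `compare_models_paired` applies the
  Wilcoxon signed-rank test to paired absolute prediction errors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .covariates import CovariateModelSpec, ResidualErrorSpec
from .estimation import (
    PopPKModel,
    PopPKResults,
    PopulationParameters,
    _FoceEngine,
    _pack,
    jittered_init,
)

logger = logging.getLogger(__name__)

__all__ = [
    "gof_residuals",
    "VpcResult",
    "vpc",
    "BootstrapResult",
    "bootstrap",
    "ValidationReport",
    "prediction_metrics",
    "external_validation",
    "PairedComparison",
    "compare_models_paired",
    "plot_gof",
    "plot_vpc",
]


# -- goodness of fit -----------------------------------------------------------


def gof_residuals(fit: PopPKResults) -> pd.DataFrame:
    """Observation table with PRED, IPRED, IWRES and CWRES columns.

    PRED is the population prediction (eta = 0), IPRED the prediction at
    the empirical Bayes eta.  CWRES decorrelates (y - E[y]) with the
    FOCE-linearised marginal covariance; a singular covariance for a
    subject falls back to IWRES with a warning.
    """
    eng = fit.model._engine
    packed = fit.model._packed
    theta, omegas, sigma = fit.model._params_tuple(fit.params)
    eng.set_params(theta, omegas, sigma)
    eta = fit.ebe
    d = eng.d

    pred = eng.predict_at(np.zeros_like(eta))
    ipred = eng.predict_at(eta)
    var_i = np.maximum(sigma.variance(ipred), 1e-290)
    iwres = (packed.obs_dv - ipred) / np.sqrt(var_i)

    # first-order sensitivity of predictions to eta, per dimension
    delta = 1e-4
    G = np.empty((packed.n_obs, d))
    for m in range(d):
        e = np.zeros(d)
        e[m] = delta
        G[:, m] = (eng.predict_at(eta + e) - eng.predict_at(eta - e)) / (2 * delta)

    omega2 = np.maximum(np.asarray(omegas, dtype=float), 1e-12) ** 2
    cwres = np.empty(packed.n_obs)
    for i in range(packed.n_sub):
        mask = packed.obs_sub == i
        Gi = G[mask]
        cov = Gi @ np.diag(omega2) @ Gi.T + np.diag(var_i[mask])
        mean_i = ipred[mask] - Gi @ eta[i]
        resid = packed.obs_dv[mask] - mean_i
        try:
            L = np.linalg.cholesky(cov)
            cwres[mask] = solve_triangular(L, resid, lower=True)
        except np.linalg.LinAlgError:
            warnings.warn(
                f"singular marginal covariance for subject {packed.ids[i]}; "
                "CWRES falls back to IWRES", stacklevel=2)
            cwres[mask] = iwres[mask]
    return pd.DataFrame({
        "ID": np.array(packed.ids)[packed.obs_sub],
        "TIME": packed.obs_t,
        "DV": packed.obs_dv,
        "PRED": pred,
        "IPRED": ipred,
        "IWRES": iwres,
        "CWRES": cwres,
        "KIND": packed.obs_kind,
    })


# -- visual predictive check ---------------------------------------------------


@dataclass
class VpcResult:
    """Per-bin observed vs simulated percentiles with simulation CIs."""

    table: pd.DataFrame
    n_sim: int
    coverage: float     # fraction of observations inside the simulated 90% PI
    bins: str

    def percentile_ordering_ok(self) -> bool:
        t = self.table
        return bool(
            np.all(t["obs_p5"] <= t["obs_p50"]) and np.all(t["obs_p50"] <= t["obs_p95"])
            and np.all(t["sim_p5"] <= t["sim_p50"]) and np.all(t["sim_p50"] <= t["sim_p95"])
        )


def _simulate_replicates(eng: _FoceEngine, params: PopulationParameters,
                         n_sim: int, rng) -> np.ndarray:
    """(n_sim, n_obs) simulated observations under the fitted design."""
    packed = eng.packed
    out = np.empty((n_sim, packed.n_obs))
    sigma = params.sigma
    for r in range(n_sim):
        eta = np.zeros((packed.n_sub, eng.d))
        i = 0
        if "CL" in eng.eta_on:
            eta[:, eng.eta_on.index("CL")] = rng.normal(0, params.omega_cl, packed.n_sub)
        if "V" in eng.eta_on and params.omega_v > 0:
            eta[:, eng.eta_on.index("V")] = rng.normal(0, params.omega_v, packed.n_sub)
        f = eng.predict_at(eta)
        if sigma.form == "mixed":
            y = f * (1 + sigma.sigma1 * rng.standard_normal(packed.n_obs)) \
                + sigma.sigma2 * rng.standard_normal(packed.n_obs)
        elif sigma.form == "additive":
            y = f + sigma.sigma1 * rng.standard_normal(packed.n_obs)
        else:
            y = f * (1 + sigma.sigma1 * rng.standard_normal(packed.n_obs))
        out[r] = y
    return out


def vpc(fit: PopPKResults, n_sim: int = 500, bins: str = "kind",
        n_time_bins: int = 4, seed: int = 0) -> VpcResult:
    """Visual predictive check of a fitted model against its own data.

    Bins default to the sample kind (trough vs peak) — the TDM design
    has exactly two nominal time classes; time-quantile binning is
    available for richer designs.  Deterministic given ``seed``.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    eng = fit.model._engine
    packed = fit.model._packed
    theta, omegas, sigma = fit.model._params_tuple(fit.params)
    eng.set_params(theta, omegas, sigma)
    rng = np.random.default_rng(seed)
    sims = _simulate_replicates(eng, fit.params, n_sim, rng)

    if bins == "kind" and np.any(packed.obs_kind != ""):
        labels = packed.obs_kind
        uniq = [b for b in ("trough", "peak") if b in set(labels)] or sorted(set(labels))
    else:
        edges = np.quantile(packed.obs_t, np.linspace(0, 1, n_time_bins + 1))
        idx = np.clip(np.searchsorted(edges, packed.obs_t, side="right") - 1,
                      0, n_time_bins - 1)
        labels = np.array([f"t{j}" for j in idx])
        uniq = [f"t{j}" for j in range(n_time_bins)]

    rows = []
    inside = 0
    total = 0
    pcts = (5, 50, 95)
    for b in uniq:
        mask = labels == b
        if not mask.any():
            warnings.warn(f"VPC bin {b!r} is empty and was dropped", stacklevel=2)
            continue
        obs = packed.obs_dv[mask]
        obs_p = np.percentile(obs, pcts)
        sim_p = np.percentile(sims[:, mask], pcts, axis=1)  # (3, n_sim)
        med = np.median(sim_p, axis=1)
        lo = np.percentile(sim_p, 2.5, axis=1)
        hi = np.percentile(sim_p, 97.5, axis=1)
        inside += int(np.sum((obs >= med[0]) & (obs <= med[2])))
        total += int(mask.sum())
        rows.append({
            "bin": b, "n_obs": int(mask.sum()),
            "obs_p5": obs_p[0], "obs_p50": obs_p[1], "obs_p95": obs_p[2],
            "sim_p5": med[0], "sim_p50": med[1], "sim_p95": med[2],
            "sim_p5_lo": lo[0], "sim_p5_hi": hi[0],
            "sim_p50_lo": lo[1], "sim_p50_hi": hi[1],
            "sim_p95_lo": lo[2], "sim_p95_hi": hi[2],
        })
    table = pd.DataFrame(rows)
    return VpcResult(table=table, n_sim=n_sim,
                     coverage=inside / total if total else float("nan"), bins=bins)


# -- bootstrap -----------------------------------------------------------------


@dataclass
class BootstrapResult:
    """Parameter stability under subject resampling."""

    table: pd.DataFrame       # parameter, estimate, median, p2.5, p97.5, bias_pct
    success_rate: float       # % of replicates that converged
    n_reps: int
    replicates: pd.DataFrame = field(repr=False, default=None)

    @property
    def max_abs_bias_pct(self) -> float:
        return float(np.nanmax(np.abs(self.table["bias_pct"])))


def _param_vector(params: PopulationParameters, model: PopPKModel) -> dict:
    names = list(model.spec.param_names)
    vec = dict(zip(names, params.theta))
    vec["BSV_CL"] = params.omega_cl
    if "V" in model.eta_on:
        vec["BSV_V"] = params.omega_v
    vec["PROP_RV" if params.sigma.form != "additive" else "ADD_RV"] = params.sigma.sigma1
    if params.sigma.form == "mixed":
        vec["ADD_RV"] = params.sigma.sigma2
    return vec


def bootstrap(fit: PopPKResults, n_reps: int = 200, seed: int = 0,
              n_reps_min_report: int = 50) -> BootstrapResult:
    """Nonparametric bootstrap: resample subjects, refit from the estimate.

    Each replicate redraws subjects with replacement to the original
    count and refits with the point estimate as the initial value.
    Non-converged replicates count as failures and are excluded from
    the percentiles; bias% = 100*(bootstrap median - estimate)/estimate.
    """
    if n_reps < n_reps_min_report:
        raise ValueError(f"n_reps must be >= {n_reps_min_report} for reporting")
    model = fit.model
    packed = model._packed
    rng = np.random.default_rng(seed)
    point = _param_vector(fit.params, model)
    rows = []
    n_ok = 0
    for rep in range(n_reps):
        idx = rng.integers(0, packed.n_sub, size=packed.n_sub)
        sub_packed = packed.subset(idx)
        try:
            sub_model = PopPKModel(sub_packed, model.spec,
                                   residual=model.residual, eta_on=model.eta_on)
            res = sub_model.fit(init=fit.params)
        except Exception as exc:  # noqa: BLE001 - replicate failure is data
            logger.warning("bootstrap replicate %d failed: %s", rep, exc)
            continue
        if not res.converged or not np.isfinite(res.ofv):
            continue
        n_ok += 1
        rows.append(_param_vector(res.params, model))
    reps = pd.DataFrame(rows)
    out = []
    for name, est in point.items():
        if len(reps):
            med = float(reps[name].median())
            lo, hi = np.percentile(reps[name], [2.5, 97.5])
        else:
            med = lo = hi = float("nan")
        out.append({
            "parameter": name, "estimate": est, "median": med,
            "p2.5": float(lo), "p97.5": float(hi),
            "bias_pct": 100.0 * (med - est) / est if est != 0 else float("nan"),
        })
    return BootstrapResult(
        table=pd.DataFrame(out),
        success_rate=100.0 * n_ok / n_reps,
        n_reps=n_reps,
        replicates=reps,
    )


# -- external validation -------------------------------------------------------


@dataclass
class ValidationReport:
    """MPE-family predictive metrics of one model on one external dataset."""

    mpe: float        # mg/L
    mpe_pct: float    # %
    mae: float        # mg/L
    mae_pct: float    # %
    rmse: float       # mg/L
    n: int
    n_excluded: int = 0
    errors: np.ndarray = field(repr=False, default=None)        # IPRED - OBS
    abs_errors: np.ndarray = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {"MPE": self.mpe, "MPE%": self.mpe_pct, "MAE": self.mae,
                "MAE%": self.mae_pct, "RMSE": self.rmse, "n": self.n,
                "n_excluded": self.n_excluded}


def prediction_metrics(ipred, obs) -> ValidationReport:
    """The five predictive metrics from paired predictions and observations.

    MPE and MAE are plain and absolute mean errors in mg/L, MPE%/MAE%
    their relative counterparts in percent, RMSE the root mean squared
    error.  Observations equal to zero are excluded from the relative
    metrics (the count is reported).
    """
    ipred = np.asarray(ipred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    err = ipred - obs
    nz = obs != 0
    rel = err[nz] / obs[nz]
    return ValidationReport(
        mpe=float(np.mean(err)),
        mpe_pct=float(np.mean(rel) * 100.0) if nz.any() else float("nan"),
        mae=float(np.mean(np.abs(err))),
        mae_pct=float(np.mean(np.abs(rel)) * 100.0) if nz.any() else float("nan"),
        rmse=float(np.sqrt(np.mean(err**2))),
        n=len(err),
        n_excluded=int(np.sum(~nz)),
        errors=err,
        abs_errors=np.abs(err),
    )


def external_validation(params: PopulationParameters, spec: CovariateModelSpec,
                        external_data) -> ValidationReport:
    """Bayesian forecasting on an external cohort.

    Individual predictions use the MAP eta of each external subject with
    the population parameters held fixed (all of a subject's
    observations condition the eta jointly); the five predictive
    metrics are then computed from C_IPRED vs C_OBS.  Observations with
    C_OBS = 0 are excluded from the relative metrics and counted.
    """
    packed = _pack(external_data, spec)
    eta_on = ("CL", "V") if params.omega_v > 0 else ("CL",)
    eng = _FoceEngine(packed, spec, eta_on)
    omega = np.array([params.omega_cl] + ([params.omega_v] if params.omega_v > 0 else []))
    eng.set_params(params.theta, omega, params.sigma)
    eta, _H, _h, conv = eng.map_with_restart(None)
    ipred = eng.predict_at(eta)
    return prediction_metrics(ipred, packed.obs_dv)


@dataclass
class PairedComparison:
    statistic: float
    pvalue: float
    n: int
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.pvalue <= 0.05


def compare_models_paired(report_a, report_b) -> PairedComparison:
    """Two-sided Wilcoxon signed-rank on paired absolute prediction errors.

    Accepts two `ValidationReport`s over the same observation set (or
    two raw error arrays).  A p-value above 0.05 is read as "no
    statistical difference"; all-zero differences are reported as
    identical rather than tested.
    """
    a = np.asarray(getattr(report_a, "abs_errors", report_a), dtype=float)
    b = np.asarray(getattr(report_b, "abs_errors", report_b), dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired comparison needs the same observation set")
    diffs = a - b
    if np.all(diffs == 0):
        return PairedComparison(statistic=0.0, pvalue=1.0, n=len(a),
                                note="identical error vectors")
    stat, p = stats.wilcoxon(a, b)
    note = "no statistical difference" if p > 0.05 else "significant difference"
    return PairedComparison(statistic=float(stat), pvalue=float(p), n=len(a), note=note)


# -- plotting ------------------------------------------------------------------


def plot_gof(gof: pd.DataFrame, path=None):
    """Four-panel GOF figure: DV vs PRED/IPRED, CWRES vs PRED/time."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    lim = [0, float(max(gof["DV"].max(), gof["PRED"].max(), gof["IPRED"].max())) * 1.05]
    for ax, xcol in zip(axes[0], ("PRED", "IPRED")):
        ax.scatter(gof[xcol], gof["DV"], s=12, alpha=0.6)
        ax.plot(lim, lim, "k--", lw=1)
        ax.set_xlabel(f"{xcol} (mg/L)")
        ax.set_ylabel("DV (mg/L)")
    for ax, xcol in zip(axes[1], ("PRED", "TIME")):
        ax.scatter(gof[xcol], gof["CWRES"], s=12, alpha=0.6)
        ax.axhline(0, color="k", ls="--", lw=1)
        for yline in (-2, 2):
            ax.axhline(yline, color="grey", ls=":", lw=1)
        ax.set_xlabel(xcol)
        ax.set_ylabel("CWRES")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_vpc(result: VpcResult, path=None):
    """Observed percentiles against simulated percentile ribbons per bin."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    t = result.table
    x = np.arange(len(t))
    fig, ax = plt.subplots(figsize=(7, 5))
    for p, color in zip(("p5", "p50", "p95"), ("tab:blue", "tab:red", "tab:blue")):
        ax.fill_between(x, t[f"sim_{p}_lo"], t[f"sim_{p}_hi"], alpha=0.25, color=color)
        ax.plot(x, t[f"sim_{p}"], color=color, lw=1.5)
        ax.plot(x, t[f"obs_{p}"], "o--", color=color, lw=1)
    ax.set_xticks(x, t["bin"])
    ax.set_ylabel("concentration (mg/L)")
    ax.set_title(f"VPC ({result.n_sim} replicates, 90% PI)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
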