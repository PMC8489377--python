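"""Covariate structures for infant vancomycin clearance and volume.

This module houses the renal-function machinery (modified Schwartz eGFR
and the 30-86 ml/min/1.73 m2 stratification), the published stratified
covariate models (normal renal function, augmented renal clearance, and
pooled), the screened maturation forms I-V, between-subject variability
on the log scale, and the three residual-error forms.

The covariate models share one structural vocabulary:

    CL = theta1 * (WT/WT_median)^theta3 * prod(terms) * MF
    V  = theta2 * (WT/WT_median)^theta4

where each extra clearance term is either a centered power
``(COV/median)^theta`` or an exponential factor ``exp(theta*COV/median)``
(the serum-creatinine term of the stratified models is exponential, and
is deliberately NOT unity at the median: the typical clearance at the
median creatinine includes the factor ``exp(theta5)``, exactly as the
models are parameterised).  ``MF`` is a maturation factor (forms III-V)
or 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .pk import IndividualParameters, InvalidParameterError

__all__ = [
    "Covariates",
    "CovariateTerm",
    "CovariateModelSpec",
    "MaturationSpec",
    "ResidualErrorSpec",
    "SCHWARTZ_K",
    "EGFR_LOWER",
    "EGFR_ARC",
    "egfr_schwartz",
    "schwartz_age_class",
    "classify_renal_function",
    "typical_parameters",
    "maturation_cl",
    "apply_bsv",
    "apply_residual",
    "load_model_spec",
    "published_model_names",
    "published_variability",
]

# Schwartz constants: eGFR = 88.4 * k * HT(cm) / SCR(umol/L)
SCHWARTZ_K = {"preterm_infant": 0.33, "term_infant": 0.45, "child": 0.55}

# renal-function stratification bounds (ml/min/1.73 m2)
EGFR_LOWER = 30.0   # inclusion criterion
EGFR_ARC = 86.0     # augmented renal clearance boundary (owned by ARC)


@dataclass(frozen=True)
class Covariates:
    """One infant's covariates.

    WT kg, HT cm, SCR umol/L, AGE months; auxiliary labs in their usual
    clinical units (ALT/AST U/L, BUN mmol/L, CYSC mg/L, ALB/TP g/L).
    """

    wt: float
    ht: float
    scr: float
    age_months: float
    preterm: bool = False
    sex: str = "M"
    alt: float | None = None
    ast: float | None = None
    bun: float | None = None
    cysc: float | None = None
    alb: float | None = None
    tp: float | None = None
    comed: bool = False

    def __post_init__(self) -> None:
        for name in ("wt", "ht", "scr"):
            val = getattr(self, name)
            if val is not None and not (val > 0):
                raise ValueError(f"{name.upper()} must be strictly positive, got {val}")
        if self.age_months < 0:
            raise ValueError(f"AGE must be >= 0, got {self.age_months}")

    def as_dict(self) -> dict:
        return {
            "WT": self.wt, "HT": self.ht, "SCR": self.scr,
            "AGE": self.age_months, "PRETERM": int(self.preterm),
            "SEX": self.sex, "ALT": self.alt, "AST": self.ast,
            "BUN": self.bun, "CYSC": self.cysc, "ALB": self.alb,
            "TP": self.tp, "COMED": int(self.comed),
        }


def schwartz_age_class(age_months: float, preterm: bool) -> str:
    """Map age/prematurity to the Schwartz constant class.

    Preterm infants under 1 year use k=0.33, other infants under 2 years
    use the term-infant k=0.45, and children from 2 years use k=0.55.
    """
    if preterm and age_months < 12:
        return "preterm_infant"
    if age_months < 24:
        return "term_infant"
    return "child"


def egfr_schwartz(
    cov: Covariates | None = None,
    age_class: str | None = None,
    *,
    ht: float | None = None,
    scr: float | None = None,
) -> float:
    """Estimated GFR (ml/min/1.73 m2) by the modified Schwartz formula.

    ``eGFR = 88.4 * k * HT(cm) / SCR(umol/L)`` with k chosen by age
    class.  Pass either a `Covariates` (age class derived from age and
    the preterm flag when not given) or explicit ``ht``/``scr``.
    """
    if cov is not None:
        ht = cov.ht if ht is None else ht
        scr = cov.scr if scr is None else scr
        if age_class is None:
            age_class = schwartz_age_class(cov.age_months, cov.preterm)
    if age_class not in SCHWARTZ_K:
        raise ValueError(f"unknown age class {age_class!r}; expected one of {sorted(SCHWARTZ_K)}")
    if ht is None or scr is None:
        raise ValueError("HT and SCR are required to compute eGFR")
    if scr <= 0:
        raise ValueError(f"SCR must be > 0, got {scr}")
    if ht <= 0:
        raise ValueError(f"HT must be > 0, got {ht}")
    return 88.4 * SCHWARTZ_K[age_class] * ht / scr


def classify_renal_function(egfr: float) -> str:
    """Stratify eGFR: [30, 86) -> 'normal', >= 86 -> 'augmented', < 30 -> 'excluded'."""
    if not np.isfinite(egfr):
        raise ValueError(f"eGFR must be finite, got {egfr}")
    if egfr < EGFR_LOWER:
        return "excluded"
    if egfr < EGFR_ARC:
        return "normal"
    return "augmented"


@dataclass(frozen=True)
class CovariateTerm:
    """One clearance covariate factor beyond the weight allometry.

    ``power`` form contributes ``(COV/median)^theta``; ``exp`` form
    contributes ``exp(theta * COV/median)``.
    """

    covariate: str
    median: float
    form: str = "power"

    def __post_init__(self) -> None:
        if not (self.median > 0):
            raise ValueError(f"centering median for {self.covariate} must be > 0")
        if self.form not in ("power", "exp"):
            raise ValueError(f"unknown term form {self.form!r}")


@dataclass(frozen=True)
class MaturationSpec:
    """Parameters of the sigmoid maturation forms.

    ``tm50`` is the age (years) at which clearance maturation reaches
    50% of the adult value and ``hill`` its slope (form III).  Forms
    IV/V make the allometric exponent itself a declining sigmoid:
    ``theta0`` the exponent at WT (or age) zero, ``kmax`` the maximum
    decrease, ``k50`` the WT in kg (form IV) or age in years (form V)
    at half the maximum decrease.
    """

    tm50: float | None = None
    hill: float | None = None
    theta0: float | None = None
    kmax: float | None = None
    k50: float | None = None

    def __post_init__(self) -> None:
        for name in ("tm50", "k50"):
            val = getattr(self, name)
            if val is not None and not (val > 0):
                raise ValueError(f"{name} must be > 0, got {val}")
        if self.kmax is not None and self.kmax < 0:
            raise ValueError(f"kmax must be >= 0, got {self.kmax}")


@dataclass(frozen=True)
class ResidualErrorSpec:
    """Residual (within-subject) error model.

    additive:      Y = F + eps,                 var = sigma1^2
    proportional:  Y = F*(1 + eps),             var = (sigma1*F)^2
    mixed:         Y = F*(1 + eps1) + eps2,     var = (sigma1*F)^2 + sigma2^2

    ``sigma1``/``sigma2`` are SDs of the standard-normal scaled draws.
    """

    form: str = "proportional"
    sigma1: float = 0.319
    sigma2: float = 0.0

    def __post_init__(self) -> None:
        if self.form not in ("additive", "proportional", "mixed"):
            raise ValueError(f"unknown residual form {self.form!r}")
        if self.sigma1 < 0 or self.sigma2 < 0:
            raise ValueError("residual SDs must be >= 0")

    def variance(self, f):
        f = np.asarray(f, dtype=float)
        if self.form == "additive":
            return np.full_like(f, self.sigma1**2)
        if self.form == "proportional":
            return (self.sigma1 * f) ** 2
        return (self.sigma1 * f) ** 2 + self.sigma2**2

    def sd(self, f):
        return np.sqrt(self.variance(f))

    @property
    def n_eps(self) -> int:
        return 2 if self.form == "mixed" else 1


MATURATION_FORMS = ("I", "II", "III", "IV", "V")


@dataclass(frozen=True)
class CovariateModelSpec:
    """Structural CL/V covariate equations with their coefficients.

    ``theta`` holds the fixed-effect values in the order given by
    `param_names`: CL coefficient, V coefficient, the free allometric
    exponents, one coefficient per extra clearance term, then any
    estimated maturation parameters.
    """

    name: str
    theta: tuple
    wt_median: float
    form: str = "custom"                  # model-1|model-2|model-3|maturation-I..V|custom
    cl_terms: tuple = ()
    cl_exponent_fixed: float | None = None
    v_exponent_fixed: float | None = None
    maturation_form: str | None = None    # III|IV|V (sigmoid forms)
    maturation: MaturationSpec | None = None
    estimate_maturation: bool = False

    def __post_init__(self) -> None:
        if not (self.wt_median > 0):
            raise ValueError("wt_median must be > 0")
        if self.maturation_form is not None and self.maturation_form not in ("III", "IV", "V"):
            raise ValueError(f"maturation_form must be III, IV or V, got {self.maturation_form!r}")
        n = len(self.param_names)
        if len(self.theta) != n:
            raise ValueError(
                f"spec {self.name!r} expects {n} theta values ({self.param_names}), got {len(self.theta)}"
            )

    # -- parameter bookkeeping -------------------------------------------------

    @property
    def param_names(self) -> tuple:
        names = ["theta1", "theta2"]
        if self.cl_exponent_fixed is None:
            names.append("theta3")
        if self.v_exponent_fixed is None:
            names.append("theta4")
        idx = 5
        for term in self.cl_terms:
            names.append(f"theta{idx}_{term.covariate}")
            idx += 1
        if self.estimate_maturation:
            if self.maturation_form == "III":
                names += ["tm50", "hill"]
            elif self.maturation_form in ("IV", "V"):
                names += ["theta0", "kmax", "k50", "hill"]
        return tuple(names)

    @property
    def positive_params(self) -> tuple:
        """Names of parameters constrained strictly positive."""
        pos = {"theta1", "theta2", "tm50", "hill", "k50", "kmax"}
        return tuple(n for n in self.param_names if n in pos)

    @property
    def required_covariates(self) -> tuple:
        req = ["WT"]
        req += [t.covariate for t in self.cl_terms]
        if self.maturation_form in ("III", "V") or (
            self.maturation_form is None and self.form == "maturation-III"
        ):
            req.append("AGE")
        if self.maturation_form == "IV":
            pass  # WT already required
        return tuple(dict.fromkeys(req))

    def theta_dict(self, theta=None) -> dict:
        theta = self.theta if theta is None else theta
        return dict(zip(self.param_names, theta))

    # -- structural equations --------------------------------------------------

    def typical_cl_v(self, cov: Mapping, theta=None):
        """Typical (population) CL and V arrays for covariate columns.

        ``cov`` maps covariate names ('WT', 'SCR', 'AGE', ...) to scalars
        or arrays.  Missing required covariates raise a `KeyError`-style
        specification error naming the covariate.
        """
        td = self.theta_dict(theta)
        for name in self.required_covariates:
            if name not in cov or cov[name] is None:
                raise InvalidParameterError(
                    f"covariate model {self.name!r} requires covariate {name!r}"
                )
        wt = np.asarray(cov["WT"], dtype=float)
        m = td.get("theta3", self.cl_exponent_fixed)
        n = td.get("theta4", self.v_exponent_fixed)

        if self.maturation_form == "IV":
            mat = self._mat_params(td)
            x = wt**mat["hill"]
            m = mat["theta0"] - mat["kmax"] * x / (mat["k50"] ** mat["hill"] + x)
        elif self.maturation_form == "V":
            mat = self._mat_params(td)
            age_y = np.asarray(cov["AGE"], dtype=float) / 12.0
            x = age_y**mat["hill"]
            m = mat["theta0"] - mat["kmax"] * x / (mat["k50"] ** mat["hill"] + x)

        cl = td["theta1"] * (wt / self.wt_median) ** m
        if self.maturation_form == "III":
            mat = self._mat_params(td)
            age_y = np.asarray(cov["AGE"], dtype=float) / 12.0
            cl = cl * _maturation_factor(age_y, mat["tm50"], mat["hill"])

        idx = 5
        for term in self.cl_terms:
            th = td[f"theta{idx}_{term.covariate}"]
            x = np.asarray(cov[term.covariate], dtype=float) / term.median
            cl = cl * (x**th if term.form == "power" else np.exp(th * x))
            idx += 1

        v = td["theta2"] * (wt / self.wt_median) ** n
        return cl, v * np.ones_like(cl)

    def _mat_params(self, td: dict) -> dict:
        if self.estimate_maturation:
            return td
        if self.maturation is None:
            raise InvalidParameterError(
                f"spec {self.name!r} has maturation form {self.maturation_form} "
                "but no MaturationSpec"
            )
        mat = self.maturation
        return {"tm50": mat.tm50, "hill": mat.hill, "theta0": mat.theta0,
                "kmax": mat.kmax, "k50": mat.k50}

    # -- serialization ---------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "form": self.form,
            "theta": list(self.theta),
            "wt_median": self.wt_median,
            "cl_terms": [
                {"covariate": t.covariate, "median": t.median, "form": t.form}
                for t in self.cl_terms
            ],
            "cl_exponent_fixed": self.cl_exponent_fixed,
            "v_exponent_fixed": self.v_exponent_fixed,
            "maturation_form": self.maturation_form,
            "estimate_maturation": self.estimate_maturation,
        }
        if self.maturation is not None:
            d["maturation"] = {
                k: getattr(self.maturation, k)
                for k in ("tm50", "hill", "theta0", "kmax", "k50")
            }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CovariateModelSpec":
        mat = d.get("maturation")
        return cls(
            name=d["name"],
            form=d.get("form", "custom"),
            theta=tuple(d["theta"]),
            wt_median=d["wt_median"],
            cl_terms=tuple(
                CovariateTerm(t["covariate"], t["median"], t.get("form", "power"))
                for t in d.get("cl_terms", ())
            ),
            cl_exponent_fixed=d.get("cl_exponent_fixed"),
            v_exponent_fixed=d.get("v_exponent_fixed"),
            maturation_form=d.get("maturation_form"),
            maturation=MaturationSpec(**mat) if mat else None,
            estimate_maturation=d.get("estimate_maturation", False),
        )

    def with_theta(self, theta) -> "CovariateModelSpec":
        return replace(self, theta=tuple(np.asarray(theta, dtype=float)))


def _maturation_factor(age_years, tm50: float, hill: float):
    """Increasing sigmoid Age^H / (TM50^H + Age^H); MF(TM50) = 0.5."""
    a = np.asarray(age_years, dtype=float) ** hill
    return a / (tm50**hill + a)


def typical_parameters(spec: CovariateModelSpec, cov: Covariates) -> IndividualParameters:
    """Typical CL/V for one subject per the spec's printed equations."""
    cl, v = spec.typical_cl_v(cov.as_dict())
    return IndividualParameters(cl=float(cl), v=float(v))


def maturation_cl(
    form: str,
    base_tv_cl: float,
    cov: Covariates,
    mat: MaturationSpec | None = None,
    *,
    wt_median: float,
    m: float | None = None,
) -> float:
    """Typical clearance under maturation forms I-V.

    Form I uses the free exponent ``m``; form II fixes m = 0.75 (the
    theoretical allometric value); form III multiplies the fixed-0.75
    allometry by the sigmoid maturation factor in age; forms IV/V make
    the exponent a declining sigmoid in WT (IV) or age (V).
    """
    if form not in MATURATION_FORMS:
        raise ValueError(f"unknown maturation form {form!r}; expected one of {MATURATION_FORMS}")
    wt_ratio = cov.wt / wt_median
    age_y = cov.age_months / 12.0
    if form == "I":
        if m is None:
            raise ValueError("maturation form I needs the free exponent m")
        return base_tv_cl * wt_ratio**m
    if form == "II":
        return base_tv_cl * wt_ratio**0.75
    if form == "III":
        return base_tv_cl * wt_ratio**0.75 * float(_maturation_factor(age_y, mat.tm50, mat.hill))
    x = cov.wt if form == "IV" else age_y
    xh = x**mat.hill
    expo = mat.theta0 - mat.kmax * xh / (mat.k50**mat.hill + xh)
    return base_tv_cl * wt_ratio**expo


def apply_bsv(
    typical: IndividualParameters, eta_cl: float = 0.0, eta_v: float = 0.0
) -> IndividualParameters:
    """Individual parameters P_i = TV(P) * exp(eta_i) (log-normal BSV)."""
    if not np.isfinite(eta_cl) or not np.isfinite(eta_v):
        raise ValueError("eta must be finite")
    return IndividualParameters(cl=typical.cl * math.exp(eta_cl), v=typical.v * math.exp(eta_v))


def apply_residual(f, spec: ResidualErrorSpec, draw):
    """Observed Y from prediction F and standard-normal draw(s).

    For the mixed form ``draw`` must supply two columns (eps1, eps2) in
    its last axis; otherwise a single draw per prediction.
    """
    f = np.asarray(f, dtype=float)
    draw = np.asarray(draw, dtype=float)
    if spec.form == "additive":
        return f + spec.sigma1 * draw
    if spec.form == "proportional":
        return f * (1.0 + spec.sigma1 * draw)
    eps1 = draw[..., 0]
    eps2 = draw[..., 1]
    return f * (1.0 + spec.sigma1 * eps1) + spec.sigma2 * eps2


# -- published model registry --------------------------------------------------
#
# The three final stratified models with their reported coefficients:
#   model1: normal renal function (eGFR 30-86), WT + SCR on CL
#   model2: augmented renal clearance (eGFR >= 86), WT only
#   model3: pooled population, WT + SCR on CL

_PUBLISHED_SPECS = {
    "model1": dict(
        name="model1",
        form="model-1",
        theta=(0.407, 1.86, 1.24, 1.28, -0.533),
        wt_median=2.25,
        cl_terms=(CovariateTerm("SCR", 27.1, "exp"),),
    ),
    "model2": dict(
        name="model2",
        form="model-2",
        theta=(0.756, 4.89, 1.03, 0.918),
        wt_median=4.6,
    ),
    "model3": dict(
        name="model3",
        form="model-3",
        theta=(0.707, 3.39, 1.23, 1.29, -0.377),
        wt_median=3.45,
        cl_terms=(CovariateTerm("SCR", 19.0, "exp"),),
    ),
}

# reported variability: (BSV on CL as SD, proportional residual SD)
_PUBLISHED_VARIABILITY = {
    "model1": (0.315, 0.319),
    "model2": (0.312, 0.319),
    "model3": (0.311, 0.335),
}


def published_model_names() -> tuple:
    return tuple(sorted(_PUBLISHED_SPECS))


def load_model_spec(name: str) -> CovariateModelSpec:
    """Load one of the published final models by name ('model1'..'model3')."""
    try:
        kwargs = _PUBLISHED_SPECS[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {published_model_names()}"
        ) from None
    return CovariateModelSpec(**kwargs)


def published_variability(name: str) -> tuple:
    """Reported (BSV_CL SD, proportional residual SD) for a published model."""
    return _PUBLISHED_VARIABILITY[name]
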