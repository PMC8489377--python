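"""Maturation-model screening and stepwise covariate selection.

The search is driven entirely by an OFV oracle — a callable
``oracle(dataset, descriptor) -> OFV`` — so that the same engine runs
against the real FOCE estimator or against a recorded table of OFVs.
Decisions follow the likelihood-ratio conventions for nested models:

* forward addition: admit the candidate with the largest OFV drop if
  that drop exceeds the chi-square df=1 alpha=0.05 quantile (3.84);
* backward exclusion: remove the in-model covariate whose removal
  raises the OFV the least, if that rise is below the df=1 alpha=0.001
  quantile (10.83); iterate until every removal would cost at least the
  threshold.

Each candidate covariate enters clearance only; weight is structural
(it scales both CL and V through the allometric base) and is removable
only when explicitly listed among the backward candidates.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from scipy import stats

from .covariates import CovariateModelSpec, CovariateTerm

logger = logging.getLogger(__name__)

__all__ = [
    "ModelDescriptor",
    "SelectionConfig",
    "SelectionStep",
    "SelectionTrace",
    "SelectionError",
    "chi2_threshold",
    "select_maturation_model",
    "forward_search",
    "backward_elimination",
    "replay_trace",
    "build_spec_from_descriptor",
]


class SelectionError(RuntimeError):
    pass


def chi2_threshold(df: int = 1, alpha: float = 0.05) -> float:
    """Upper-alpha chi-square quantile: the OFV-difference threshold."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(stats.chi2.ppf(1.0 - alpha, df))


@dataclass(frozen=True)
class ModelDescriptor:
    """A candidate model: maturation form plus the set of CL covariates."""

    maturation_form: str = "I"
    covariates: frozenset = frozenset()

    def add(self, covariate: str) -> "ModelDescriptor":
        return ModelDescriptor(self.maturation_form, self.covariates | {covariate})

    def remove(self, covariate: str) -> "ModelDescriptor":
        return ModelDescriptor(self.maturation_form, self.covariates - {covariate})

    def label(self) -> str:
        covs = "+".join(sorted(self.covariates)) or "none"
        return f"maturation-{self.maturation_form}[{covs}]"


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds and candidate lists for the stepwise search."""

    forward_threshold: float = 3.84
    backward_threshold: float = 10.83
    candidates: tuple = ()
    maturation_forms: tuple = ("I", "II", "III", "IV", "V")
    removable: tuple | None = None   # None: all in-model covariates except WT

    def __post_init__(self) -> None:
        if self.forward_threshold <= 0 or self.backward_threshold <= 0:
            raise ValueError("thresholds must be > 0")
        if self.backward_threshold < self.forward_threshold:
            raise ValueError("backward threshold must be >= forward threshold")


@dataclass(frozen=True)
class SelectionStep:
    action: str            # "maturation" | "add" | "remove"
    target: str
    ofv_before: float
    ofv_after: float
    decision: bool         # retained (add) / excluded (remove) / chosen
    note: str = ""

    @property
    def delta(self) -> float:
        return self.ofv_after - self.ofv_before

    def as_dict(self) -> dict:
        return {
            "action": self.action, "target": self.target,
            "ofv_before": self.ofv_before, "ofv_after": self.ofv_after,
            "delta_ofv": self.delta, "decision": self.decision, "note": self.note,
        }


@dataclass
class SelectionTrace:
    steps: list = field(default_factory=list)
    final: ModelDescriptor | None = None
    final_ofv: float | None = None

    def record(self, step: SelectionStep) -> None:
        self.steps.append(step)

    def to_json(self, path=None) -> str:
        doc = json.dumps(
            {
                "steps": [s.as_dict() for s in self.steps],
                "final_model": self.final.label() if self.final else None,
                "final_covariates": sorted(self.final.covariates) if self.final else None,
                "final_ofv": self.final_ofv,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc

    def to_log(self) -> str:
        lines = []
        for s in self.steps:
            verdict = "KEPT" if s.decision else "rejected"
            lines.append(
                f"{s.action:<10} {s.target:<12} OFV {s.ofv_before:10.3f} -> "
                f"{s.ofv_after:10.3f} (delta {s.delta:+8.3f}) {verdict} {s.note}"
            )
        if self.final is not None:
            lines.append(f"final: {self.final.label()} (OFV {self.final_ofv})")
        return "\n".join(lines)


Oracle = Callable[[object, ModelDescriptor], float]


def select_maturation_model(
    dataset, forms: Sequence[str], ofv_oracle: Oracle,
    covariates: Iterable[str] = (),
) -> tuple:
    """Pick the maturation form with the smallest OFV.

    Ties break toward fewer estimated parameters, then listed order.
    Returns (chosen ModelDescriptor, SelectionTrace).
    """
    # free parameters per form: I has two free exponents; II fixes both;
    # III adds TM50/Hill to the fixed allometry; IV/V estimate a 4-parameter
    # sigmoid exponent
    n_params = {"I": 2, "II": 0, "III": 2, "IV": 4, "V": 4}
    trace = SelectionTrace()
    results = []
    for form in forms:
        desc = ModelDescriptor(form, frozenset(covariates))
        try:
            ofv = ofv_oracle(dataset, desc)
        except Exception as exc:  # noqa: BLE001 - oracle contract
            warnings.warn(f"maturation form {form} failed: {exc}", stacklevel=2)
            continue
        results.append((form, ofv, desc))
    if not results:
        raise SelectionError("no maturation form could be evaluated")
    order = {f: i for i, f in enumerate(forms)}
    best = min(results, key=lambda r: (r[1], n_params.get(r[0], 99), order[r[0]]))
    for form, ofv, _ in results:
        trace.record(SelectionStep("maturation", form, ofv, ofv, form == best[0],
                                   note="smallest OFV" if form == best[0] else ""))
    trace.final = best[2]
    trace.final_ofv = best[1]
    return best[2], trace


def forward_search(
    dataset, base: ModelDescriptor, candidates: Sequence[str],
    config: SelectionConfig, ofv_oracle: Oracle,
    base_ofv: float | None = None,
) -> SelectionTrace:
    """Stepwise forward addition: best qualifying drop per round."""
    trace = SelectionTrace()
    current = base
    current_ofv = ofv_oracle(dataset, base) if base_ofv is None else base_ofv
    remaining = list(candidates)
    while remaining:
        evaluated = []
        for cov in remaining:
            cand = current.add(cov)
            try:
                ofv = ofv_oracle(dataset, cand)
            except Exception as exc:  # noqa: BLE001
                warnings.warn(f"candidate {cov} skipped: {exc}", stacklevel=2)
                logger.warning("forward candidate %s skipped: %s", cov, exc)
                continue
            evaluated.append((cov, ofv))
        if not evaluated:
            break
        best_cov, best_ofv = min(evaluated, key=lambda t: t[1])
        drop = current_ofv - best_ofv
        admitted = drop > config.forward_threshold
        for cov, ofv in evaluated:
            if cov != best_cov:
                trace.record(SelectionStep(
                    "add", cov, current_ofv, ofv,
                    False, note="not the best drop this round"
                    if (current_ofv - ofv) > config.forward_threshold else ""))
        trace.record(SelectionStep(
            "add", best_cov, current_ofv, best_ofv, admitted,
            note="largest drop" if admitted else "largest drop below threshold"))
        if not admitted:
            break
        current = current.add(best_cov)
        current_ofv = best_ofv
        remaining.remove(best_cov)
    trace.final = current
    trace.final_ofv = current_ofv
    return trace


def backward_elimination(
    dataset, full: ModelDescriptor, config: SelectionConfig, ofv_oracle: Oracle,
    full_ofv: float | None = None,
) -> SelectionTrace:
    """Backward exclusion: cheapest removal per round while below threshold.

    The structural weight allometry ('WT') is considered for removal
    only when listed in ``config.removable``.
    """
    trace = SelectionTrace()
    current = full
    current_ofv = ofv_oracle(dataset, full) if full_ofv is None else full_ofv
    while True:
        pool = set(current.covariates)
        if config.removable is not None:
            pool |= set(config.removable) & ({"WT"} | set(current.covariates))
        if not pool:
            break
        evaluated = []
        for cov in sorted(pool):
            reduced = current.remove(cov)
            try:
                ofv = ofv_oracle(dataset, reduced)
            except Exception as exc:  # noqa: BLE001
                warnings.warn(f"removal of {cov} skipped: {exc}", stacklevel=2)
                logger.warning("backward removal of %s skipped: %s", cov, exc)
                continue
            evaluated.append((cov, ofv))
        if not evaluated:
            break
        best_cov, best_ofv = min(evaluated, key=lambda t: t[1])
        rise = best_ofv - current_ofv
        removed = rise < config.backward_threshold
        for cov, ofv in evaluated:
            if cov != best_cov:
                trace.record(SelectionStep("remove", cov, current_ofv, ofv, False,
                                           note="costlier removal"))
        trace.record(SelectionStep(
            "remove", best_cov, current_ofv, best_ofv, removed,
            note="cheapest removal" if removed else "all removals at or above threshold"))
        if not removed:
            break
        current = current.remove(best_cov)
        current_ofv = best_ofv
    trace.final = current
    trace.final_ofv = current_ofv
    return trace


def replay_trace(trace: SelectionTrace, config: SelectionConfig) -> list:
    """Re-derive every decision from the logged OFVs and the thresholds.

    Selection decisions are a pure function of (OFVs, thresholds): this
    recomputes each step's verdict and returns the list of booleans,
    which must equal the recorded ones.
    """
    out = []
    for s in trace.steps:
        if s.action == "add":
            out.append(-s.delta > config.forward_threshold and s.decision)
        elif s.action == "remove":
            out.append(s.delta < config.backward_threshold and s.decision)
        else:
            out.append(s.decision)
    return out


# -- bridging descriptors to fittable specs ------------------------------------

# covariates that enter clearance as exponential factors of COV/median
# (the final models' serum-creatinine vocabulary); binary flags also enter
# exponentially; everything else enters as a centered power term
_EXP_COVARIATES = {"SCR", "PRETERM", "SEX", "COMED"}


def build_spec_from_descriptor(
    desc: ModelDescriptor,
    medians: dict,
    name: str = "candidate",
    theta_init: dict | None = None,
) -> CovariateModelSpec:
    """Fittable spec for a descriptor (maturation forms I/II with CL terms).

    ``medians`` maps covariate names to centering medians (must include
    'WT').  Initial coefficients: 1.0 for the allometric exponents,
    0.0 for covariate terms unless given in ``theta_init``.
    """
    theta_init = theta_init or {}
    terms = tuple(
        CovariateTerm(cov, medians[cov],
                      "exp" if cov in _EXP_COVARIATES else "power")
        for cov in sorted(desc.covariates)
    )
    if desc.maturation_form == "I":
        fixed_m = fixed_n = None
    elif desc.maturation_form == "II":
        fixed_m, fixed_n = 0.75, 1.0
    else:
        raise SelectionError(
            f"real-estimator selection supports maturation forms I/II; "
            f"got {desc.maturation_form}"
        )
    theta = [theta_init.get("theta1", 0.5), theta_init.get("theta2", 3.0)]
    if fixed_m is None:
        theta.append(theta_init.get("theta3", 1.0))
    if fixed_n is None:
        theta.append(theta_init.get("theta4", 1.0))
    for t in terms:
        theta.append(theta_init.get(t.covariate, 0.0))
    return CovariateModelSpec(
        name=name, form=f"maturation-{desc.maturation_form}",
        theta=tuple(theta), wt_median=medians["WT"], cl_terms=terms,
        cl_exponent_fixed=fixed_m, v_exponent_fixed=fixed_n,
    )


def make_foce_oracle(medians: dict, residual: str = "proportional",
                     init: dict | None = None, **fit_options) -> Oracle:
    """OFV oracle backed by the package's FOCE estimator."""
    from .estimation import PopPKModel

    def oracle(dataset, desc: ModelDescriptor) -> float:
        spec = build_spec_from_descriptor(desc, medians, name=desc.label(),
                                          theta_init=init)
        res = PopPKModel(dataset, spec, residual=residual).fit(**fit_options)
        if not res.converged:
            raise SelectionError(f"fit did not converge for {desc.label()}")
        return res.ofv

    return oracle
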