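"""Trait–residual linear mixed models.

The representation residual (one row per state x species) is regressed on
species traits with a random intercept per state, which absorbs the
replication of species across states and each state's overall level of
over/under-representation.  A global model includes all four traits
simultaneously; four single-trait models use each trait alone, which
admits more rows when trait data are missing unevenly.

Estimation is REML by default (ML available).  Confidence intervals are
Wald (estimate +/- z * SE); p-values use the normal approximation to the
Wald statistic, and the method string is recorded in every result.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ConfigError

logger = logging.getLogger(__name__)

TRAIT_PREDICTORS = ("log10_body_mass", "log10_flock_size", "color_index", "iucn_score")


@dataclass(frozen=True)
class ModelSpec:
    """Which predictors to fit, the estimation mode, and the CI level."""

    predictors: tuple = TRAIT_PREDICTORS
    estimation: str = "REML"
    ci_level: float = 0.95

    def __post_init__(self):
        preds = tuple(self.predictors)
        if not preds:
            raise ConfigError("ModelSpec.predictors must be non-empty")
        unknown = [p for p in preds if p not in TRAIT_PREDICTORS]
        if unknown:
            raise ConfigError(
                f"unknown predictor(s) {unknown}; choose from {TRAIT_PREDICTORS}"
            )
        if self.estimation not in ("REML", "ML"):
            raise ConfigError(f"estimation must be 'REML' or 'ML', got {self.estimation!r}")
        if not 0.0 < self.ci_level < 1.0:
            raise ConfigError(f"ci_level must be in (0, 1), got {self.ci_level}")
        object.__setattr__(self, "predictors", preds)


@dataclass
class FixedEffect:
    estimate: float
    std_error: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class MixedModelResult:
    """Fixed effects with Wald CIs plus variance components and fit metadata."""

    fixed_effects: dict  # name -> FixedEffect (includes "intercept")
    random_intercept_variance: float
    residual_variance: float
    n_rows: int
    n_species: int
    n_states: int
    converged: bool
    method: str
    diagnostics: str = ""

    def to_dict(self) -> dict:
        return {
            "fixed_effects": {
                k: vars(v) for k, v in self.fixed_effects.items()
            },
            "random_intercept_variance": self.random_intercept_variance,
            "residual_variance": self.residual_variance,
            "n_rows": self.n_rows,
            "n_species": self.n_species,
            "n_states": self.n_states,
            "converged": self.converged,
            "method": self.method,
            "diagnostics": self.diagnostics,
        }


def assemble_model_frame(
    residuals: pd.DataFrame, trait_vectors: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, dict]:
    """Join residuals to traits and apply per-model completeness.

    Rows missing any of the spec's predictors are dropped for this model
    only, so single-trait models may keep more rows than the global model.
    Returns the frame and a drop report (missing-row count per predictor
    plus totals).
    """
    frame = residuals.merge(trait_vectors, on="species", how="left")
    report = {"n_input": int(len(frame))}
    missing = frame[list(spec.predictors)].isna()
    report["n_missing_by_predictor"] = {
        p: int(missing[p].sum()) for p in spec.predictors
    }
    keep = ~missing.any(axis=1)
    frame = frame.loc[keep].reset_index(drop=True)
    report["n_dropped"] = report["n_input"] - int(len(frame))
    report["n_rows"] = int(len(frame))
    if frame.empty:
        raise ValueError(
            "model frame is empty after dropping rows with missing predictors "
            f"({report['n_missing_by_predictor']})"
        )
    return frame, report


def _package_fit(
    names, params, bses, scale, re_var, frame, spec, converged, method, diagnostics=""
) -> MixedModelResult:
    z = stats.norm.ppf(0.5 + spec.ci_level / 2.0)
    fe = {}
    for name, est, se in zip(names, params, bses):
        with np.errstate(invalid="ignore", divide="ignore"):
            p = 2.0 * stats.norm.sf(abs(est / se)) if se > 0 else np.nan
        fe[name] = FixedEffect(
            estimate=float(est),
            std_error=float(se),
            ci_low=float(est - z * se),
            ci_high=float(est + z * se),
            p_value=float(p),
        )
    return MixedModelResult(
        fixed_effects=fe,
        random_intercept_variance=float(re_var),
        residual_variance=float(scale),
        n_rows=int(len(frame)),
        n_species=int(frame["species"].nunique()),
        n_states=int(frame["state"].nunique()),
        converged=bool(converged),
        method=method,
        diagnostics=diagnostics,
    )


def fit_mixed(frame: pd.DataFrame, spec: ModelSpec | None = None) -> MixedModelResult:
    """Random-intercept-by-state linear mixed model of the residual on traits.

    With a single state the random intercept is unidentifiable and the fit
    degenerates to OLS (random variance reported as 0, method recorded).
    Non-convergence is reported via ``converged=False`` with diagnostics,
    not an exception; a constant predictor raises, naming it.
    """
    spec = spec or ModelSpec()
    preds = list(spec.predictors)
    for p in preds:
        if frame[p].nunique(dropna=True) <= 1:
            raise ValueError(f"predictor {p!r} is constant in the model frame")
    y = frame["residual"].to_numpy(dtype=float)
    X = sm.add_constant(frame[preds].to_numpy(dtype=float))
    names = ["intercept", *preds]
    n_states = int(frame["state"].nunique())

    if n_states < 2:
        res = sm.OLS(y, X).fit()
        return _package_fit(
            names, res.params, res.bse, res.scale, 0.0, frame, spec,
            converged=True, method="ols (single group); wald-normal ci/p",
        )

    model = sm.MixedLM(y, X, groups=frame["state"].to_numpy())
    method = f"mixedlm-{spec.estimation.lower()}; wald-normal ci/p"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=(spec.estimation == "REML"))
            params = np.asarray(res.fe_params)
            bses = np.asarray(res.bse_fe)  # lazy; may warn at a boundary fit
        converged = bool(res.converged)
        diagnostics = "" if converged else "optimizer did not converge"
        re_var = float(np.asarray(res.cov_re)[0, 0])
        scale = float(res.scale)
        # At the boundary (group variance ~ 0) the GLS fit equals OLS but the
        # mixed-model covariance is singular; report OLS standard errors.
        if re_var <= 1e-8 * scale or not np.isfinite(bses).all():
            ols = sm.OLS(y, X).fit()
            params, bses, scale = ols.params, ols.bse, float(ols.scale)
            method += "; boundary re-variance: ols std errors"
        return _package_fit(
            names, params, bses, scale, re_var, frame, spec,
            converged=converged, method=method, diagnostics=diagnostics,
        )
    except (np.linalg.LinAlgError, ValueError) as exc:  # singular fit
        nan = np.full(len(names), np.nan)
        return _package_fit(
            names, nan, nan, np.nan, np.nan, frame, spec,
            converged=False, method=method, diagnostics=f"fit failed: {exc}",
        )


def fit_all(
    residuals: pd.DataFrame,
    trait_vectors: pd.DataFrame,
    spec: ModelSpec | None = None,
) -> dict:
    """Global model plus the four single-trait models, with sign agreement.

    Returns ``{"global": MixedModelResult, "per_trait": {...}, "frames":
    drop reports, "sign_agreement": {...}}``.  A sign disagreement is
    flagged only when both the global and single-trait CIs exclude zero
    with opposite-signed estimates.
    """
    spec = spec or ModelSpec()
    frame, report = assemble_model_frame(residuals, trait_vectors, spec)
    out = {
        "global": fit_mixed(frame, spec),
        "per_trait": {},
        "frames": {"global": report},
        "sign_agreement": {},
    }
    for p in spec.predictors:
        sub_spec = ModelSpec(predictors=(p,), estimation=spec.estimation,
                             ci_level=spec.ci_level)
        sub_frame, sub_report = assemble_model_frame(residuals, trait_vectors, sub_spec)
        out["per_trait"][p] = fit_mixed(sub_frame, sub_spec)
        out["frames"][p] = sub_report

    for p in spec.predictors:
        g = out["global"].fixed_effects.get(p)
        s = out["per_trait"][p].fixed_effects.get(p)
        if g is None or s is None or not np.isfinite(g.estimate * s.estimate):
            out["sign_agreement"][p] = None
            continue
        both_clear = (g.ci_low * g.ci_high > 0) and (s.ci_low * s.ci_high > 0)
        disagree = both_clear and (np.sign(g.estimate) != np.sign(s.estimate))
        out["sign_agreement"][p] = not disagree
        if disagree:
            logger.warning("sign disagreement between global and single-trait model for %s", p)
    return out


def recovery_report(replicates: list, truth) -> dict:
    """Bias, RMSE, CI coverage and rejection rate per trait across replicates.

    ``replicates`` holds MixedModelResult objects from fits of the global
    model on independently simulated datasets; ``truth`` is the
    PlantedEffects the data were generated from.  Machine-readable (JSON
    serialisable) output.
    """
    gammas = truth.gammas
    out: dict = {"n_replicates": len(replicates), "per_trait": {}}
    for trait, true_val in gammas.items():
        ests, covered, rejected = [], [], []
        for res in replicates:
            fe = res.fixed_effects.get(trait)
            if fe is None or not np.isfinite(fe.estimate):
                continue
            ests.append(fe.estimate)
            covered.append(fe.ci_low <= true_val <= fe.ci_high)
            rejected.append(fe.p_value < 0.05)
        if not ests:
            continue
        ests_arr = np.asarray(ests)
        out["per_trait"][trait] = {
            "true_value": float(true_val),
            "mean_estimate": float(ests_arr.mean()),
            "bias": float(ests_arr.mean() - true_val),
            "rmse": float(np.sqrt(np.mean((ests_arr - true_val) ** 2))),
            "ci_coverage": float(np.mean(covered)),
            "rejection_rate": float(np.mean(rejected)),
            "n_fits": int(len(ests)),
        }
    return out
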