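"""Longitudinal severity modelling and genotype classification.

The core analysis asks whether a per-sample outcome (percentage of vacuolated
lymphocytes, or the percentage of affected LAMP-1+ perforin- cells in the
CD4/CD8/CD20 compartments) depends on disease severity class and on age,
given repeated samples per patient.  The model is a linear mixed model

    outcome ~ age + severity_class  (fixed effects)

with a random intercept per patient and, when preferred by AIC, an
additional random age slope.  The random-structure comparison is done under
maximum likelihood (AICs of ML fits are comparable across random structures);
the selected structure is then refit under REML for the reported estimates —
the standard reconciliation of AIC-based selection with REML estimation.

Fixed-effect p-values use Wald t statistics with between-within degrees of
freedom: class contrasts (between-patient effects) use ``n_patients -
n_classes`` df, the age slope (a within-patient effect) uses ``n_obs -
n_patients - 1`` df.

Outcomes are modelled on the raw percentage scale by default (residual
normality is an adequate approximation for mid-range percentages); a logit
option is available for outcomes near the 0/100 boundaries.

Genotype classification maps the two allele severity categories to a
phenotype stratum: two truncating alleles give classical disease; a
truncating plus a "mild" missense allele gives delayed classical disease;
two particularly mild missense alleles give retina-only disease; any other
combination with at least one missense allele gives protracted disease.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logit

import statsmodels.formula.api as smf

from .synth import SeverityClass

__all__ = [
    "AlleleCategory",
    "SeverityFit",
    "OUTCOME_NAMES",
    "classify_genotype",
    "fit_severity_model",
    "severity_trend_report",
]

OUTCOME_NAMES = (
    "pct_vacuolated",
    "pct_affected_T4",
    "pct_affected_T8",
    "pct_affected_B",
)


class AlleleCategory(str, enum.Enum):
    TRUNCATING = "truncating"
    MILD_MISSENSE = "mild_missense"
    PARTICULARLY_MILD_MISSENSE = "particularly_mild_missense"

    @classmethod
    def from_label(cls, label: "AlleleCategory | str") -> "AlleleCategory":
        if isinstance(label, AlleleCategory):
            return label
        try:
            return cls(str(label))
        except ValueError:
            raise ValueError(f"unknown allele category: {label!r}") from None


def classify_genotype(
    allele1: AlleleCategory | str, allele2: AlleleCategory | str
) -> SeverityClass:
    """Severity class implied by the two CLN3 allele categories.

    Symmetric in its arguments and total over the category enum: two
    truncating alleles -> classical; truncating + mild missense -> delayed
    classical; two particularly mild missense alleles -> retina-only; every
    other combination involving a missense allele -> protracted.
    """
    a = AlleleCategory.from_label(allele1)
    b = AlleleCategory.from_label(allele2)
    pair = frozenset([a, b]) if a != b else frozenset([a])
    trunc, mild, pmild = (
        AlleleCategory.TRUNCATING,
        AlleleCategory.MILD_MISSENSE,
        AlleleCategory.PARTICULARLY_MILD_MISSENSE,
    )
    if pair == {trunc}:
        return SeverityClass.CLASSICAL
    if pair == {trunc, mild}:
        return SeverityClass.DELAYED_CLASSICAL
    if pair == {pmild}:
        return SeverityClass.RETINA_ONLY
    return SeverityClass.PROTRACTED


@dataclass
class SeverityFit:
    """Result of one mixed-model severity fit."""

    outcome_name: str
    fixed_effects: dict  # name -> {"estimate", "se", "p"}
    variance_components: dict  # intercept_sd, slope_sd, residual_sd
    fit_method: str
    aic_without_slope: float | None
    aic_with_slope: float | None
    chosen_random_structure: str
    reference_class: str
    n_obs: int
    n_patients: int
    df_within: float
    df_between: float

    def to_dict(self) -> dict:
        return {
            "outcome_name": self.outcome_name,
            "fixed_effects": self.fixed_effects,
            "variance_components": self.variance_components,
            "fit_method": self.fit_method,
            "aic_without_slope": self.aic_without_slope,
            "aic_with_slope": self.aic_with_slope,
            "chosen_random_structure": self.chosen_random_structure,
            "reference_class": self.reference_class,
            "n_obs": self.n_obs,
            "n_patients": self.n_patients,
            "df_within": self.df_within,
            "df_between": self.df_between,
        }


def _pretty_term(name: str) -> str:
    if name == "Intercept":
        return "intercept"
    if name == "_age":
        return "age_slope"
    if "[T." in name:
        return "class[" + name.split("[T.", 1)[1].rstrip("]") + "]"
    return name


def _wald_p(est: float, se: float, dfree: float) -> float:
    if se == 0:
        return 0.0 if est != 0 else 1.0
    return float(2.0 * stats.t.sf(abs(est / se), dfree))


def fit_severity_model(
    data: pd.DataFrame,
    outcome_name: str,
    *,
    logit_scale: bool = False,
    reference: str | None = None,
) -> SeverityFit:
    """Fit the longitudinal severity model for one outcome.

    ``data`` needs columns ``patient_id, age_years, severity_class`` and the
    outcome column (percent scale, 0-100).  Requires at least two patients in
    at least two classes.  Without any repeated measures the random structure
    cannot be selected; the model falls back to a random intercept with a
    warning.  Degenerate fits (zero residual variation) fall back to a
    fixed-effects-only least-squares fit, flagged in
    ``chosen_random_structure``.
    """
    required = {"patient_id", "age_years", "severity_class", outcome_name}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = data.dropna(subset=[outcome_name]).copy()
    df["severity_class"] = [
        SeverityClass.from_label(v).value for v in df["severity_class"]
    ]
    classes = sorted(
        df["severity_class"].unique(),
        key=lambda v: SeverityClass(v).ordinal_rank,
    )
    n_patients = df["patient_id"].nunique()
    if len(classes) < 2 or n_patients < 2:
        raise ValueError("need >= 2 patients in >= 2 severity classes")
    if reference is None:
        reference = (
            SeverityClass.CONTROL.value
            if SeverityClass.CONTROL.value in classes
            else classes[0]
        )

    y = df[outcome_name].to_numpy(dtype=float)
    if logit_scale:
        y = logit(np.clip(y / 100.0, 1e-4, 1 - 1e-4))
    df["_y"] = y
    df["_age"] = df["age_years"].astype(float)

    formula = f"_y ~ _age + C(severity_class, Treatment('{reference}'))"
    n_obs = len(df)
    n_classes = len(classes)
    df_within = float(max(n_obs - n_patients - 1, 1))
    df_between = float(max(n_patients - n_classes, 1))

    def _mixed_fit(re_formula: str, reml: bool):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                formula, df, groups=df["patient_id"], re_formula=re_formula
            )
            return model.fit(reml=reml, maxiter=200)

    has_repeats = df.groupby("patient_id").size().max() >= 2
    aic_int = aic_slope = None
    structure = "random_intercept"
    if not has_repeats:
        warnings.warn(
            "no patient has repeated measures; random-slope structure is not "
            "identifiable — falling back to a random intercept only",
            stacklevel=2,
        )
    else:
        try:
            aic_int = float(_mixed_fit("1", reml=False).aic)
            res_slope_ml = _mixed_fit("~_age", reml=False)
            aic_slope = float(res_slope_ml.aic)
            if np.isfinite(aic_slope) and aic_slope < aic_int:
                structure = "random_intercept_slope"
        except Exception:
            structure = "random_intercept"

    fit_method = "REML"
    result = None
    for re_formula, label in (
        ("~_age", "random_intercept_slope"),
        ("1", "random_intercept"),
    ):
        if label != structure and label != "random_intercept":
            continue
        if structure == "random_intercept" and label == "random_intercept_slope":
            continue
        try:
            result = _mixed_fit(re_formula, reml=True)
            if not np.isfinite(result.fe_params).all() or not np.isfinite(
                np.asarray(result.bse_fe, dtype=float)
            ).all():
                result = None
                raise np.linalg.LinAlgError("non-finite mixed-model fit")
            structure = label
            break
        except Exception:
            if label == "random_intercept":
                result = None
            structure = "random_intercept"
            continue

    if result is not None:
        params = result.fe_params
        bses = result.bse_fe
        cov_re = np.atleast_2d(np.asarray(result.cov_re, dtype=float))
        intercept_sd = float(np.sqrt(max(cov_re[0, 0], 0.0)))
        slope_sd = (
            float(np.sqrt(max(cov_re[1, 1], 0.0))) if cov_re.shape[0] > 1 else 0.0
        )
        residual_sd = float(np.sqrt(max(result.scale, 0.0)))
    else:
        # Degenerate data (e.g. zero residual variance): fixed effects only.
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ols = smf.ols(formula, df).fit()
        params = ols.params
        bses = ols.bse
        intercept_sd = slope_sd = 0.0
        residual_sd = float(np.sqrt(max(ols.scale, 0.0)))
        structure = "fixed_effects_only (degenerate)"
        fit_method = "OLS"

    fixed: dict[str, dict[str, float]] = {}
    for name in params.index:
        est = float(params[name])
        se = float(bses[name])
        pretty = _pretty_term(name)
        dfree = df_within if pretty == "age_slope" else df_between
        fixed[pretty] = {"estimate": est, "se": se, "p": _wald_p(est, se, dfree)}

    return SeverityFit(
        outcome_name=outcome_name,
        fixed_effects=fixed,
        variance_components={
            "intercept_sd": intercept_sd,
            "slope_sd": slope_sd,
            "residual_sd": residual_sd,
        },
        fit_method=fit_method,
        aic_without_slope=aic_int,
        aic_with_slope=aic_slope,
        chosen_random_structure=structure,
        reference_class=reference,
        n_obs=n_obs,
        n_patients=int(n_patients),
        df_within=df_within,
        df_between=df_between,
    )


def severity_trend_report(
    fits: Mapping[str, SeverityFit], alpha: float = 0.05
) -> dict:
    """Tabulate class contrasts, age slopes and stability verdicts per outcome.

    The verdict is "stable" when the age slope's Wald ``(1-alpha)`` confidence
    interval (t with within-patient df) contains 0, i.e. no evidence that the
    outcome drifts with age within severity class, and "changing" otherwise.
    """
    if not fits:
        raise ValueError("no fits supplied")
    report: dict = {}
    for name, fit in fits.items():
        slope = fit.fixed_effects.get("age_slope")
        if slope is None:
            raise ValueError(f"fit {name!r} lacks an age_slope term")
        tcrit = float(stats.t.ppf(1 - alpha / 2, fit.df_within))
        lo = slope["estimate"] - tcrit * slope["se"]
        hi = slope["estimate"] + tcrit * slope["se"]
        contrasts = {
            k: v for k, v in fit.fixed_effects.items() if k.startswith("class[")
        }
        report[name] = {
            "reference_class": fit.reference_class,
            "class_contrasts": contrasts,
            "age_slope": dict(slope),
            "age_slope_ci": [lo, hi],
            "verdict": "stable" if lo <= 0.0 <= hi else "changing",
            "chosen_random_structure": fit.chosen_random_structure,
        }
    return report
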