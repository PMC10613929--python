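"""Synthetic AMI-CS-like cohort generator with planted latent subgroups.

Real registry cohorts of acute myocardial infarction complicated by
cardiogenic shock (AMI-CS) are access-restricted, so every downstream stage of
this package is exercised on simulated cohorts instead.  Patients are drawn
from ``K_true`` latent subgroups; each subgroup has its own distribution of
presentation features, its own treatment-assignment model (treatment depends
on presentation features and on the subgroup — confounding by indication),
and its own logistic outcome model over the full feature vector.  Because the
subgroup-specific outcome coefficients disagree in sign on several features,
a single pooled linear risk model is strictly handicapped relative to the
per-group Bayes oracle — the heterogeneity that motivates a mixture of
experts.

Feature values are on a standardized scale (continuous ~ unit variance,
binary in {0,1}); realistic clinical marginals are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .schema import CohortSchema, CohortTable, FeatureSpec

__all__ = [
    "SyntheticSpec",
    "default_amics_spec",
    "generate_cohort",
    "bayes_risk",
    "bayes_risk_cohort",
    "expected_prevalence",
]

#: Table-style two-tier feature layout: 12 presentation + 15 treatment columns.
_PRESENTATION = [
    ("age", "continuous"),
    ("sex_male", "binary"),
    ("cardiac_arrest_first_contact", "binary"),
    ("cardiac_arrest_prehospital", "binary"),
    ("cardiac_arrest_outside_facility", "binary"),
    ("systolic_bp_first_contact", "continuous"),
    ("stemi", "binary"),
    ("left_main_stenosis", "binary"),
    ("prox_lad_stenosis", "binary"),
    ("multivessel_disease", "binary"),
    ("initial_creatinine", "continuous"),
    ("initial_troponin", "continuous"),
]
_TREATMENT = [
    ("need_mech_support", "binary"),
    ("peak_troponin", "continuous"),
    ("requires_dialysis", "binary"),
    ("dialysis", "binary"),
    ("atrial_fibrillation", "binary"),
    ("vt_vf", "binary"),
    ("lvef", "continuous"),
    ("cerebrovascular_accident", "binary"),
    ("length_of_stay", "continuous"),
    ("other_vascular_complications", "binary"),
    ("mcs_used", "binary"),
    ("mcs_ecmo", "binary"),
    ("mcs_iabp", "binary"),
    ("mcs_lvad", "binary"),
    ("mcs_other", "binary"),
]


def amics_schema() -> CohortSchema:
    """The default two-tier AMI-CS feature schema (12 presentation + 15 treatment)."""
    feats = [FeatureSpec(n, k, "presentation") for n, k in _PRESENTATION]
    feats += [FeatureSpec(n, k, "treatment") for n, k in _TREATMENT]
    return CohortSchema(features=tuple(feats), outcome="mortality")


@dataclass
class SyntheticSpec:
    """Full generative description of a synthetic cohort.

    Attributes
    ----------
    schema:
        Feature layout; generation order follows the schema.
    K_true:
        Number of planted latent subgroups (>= 1).
    mixing:
        Subgroup mixing proportions on the simplex.
    pres_cont_means:
        (K, n_pres_continuous) subgroup means of continuous presentation
        features, in schema order of those features.
    pres_bin_prev:
        (K, n_pres_binary) subgroup Bernoulli probabilities of binary
        presentation features.
    treat_intercepts, treat_weights:
        (K, n_treatment) and (K, n_treatment, n_presentation) linear model of
        each treatment feature given the full presentation vector: binary
        treatment features use the linear predictor as log-odds; continuous
        ones as a conditional mean with ``noise_sd`` Gaussian noise.
    outcome_intercepts, outcome_coefs:
        (K,) and (K, n_features) per-subgroup logistic outcome model over the
        concatenated (presentation, treatment) vector in schema order.
    noise_sd:
        Gaussian noise scale for all continuous features (>= 0).
    missing_rate:
        Missing-completely-at-random rate applied to feature cells (0 =
        complete data).
    """

    schema: CohortSchema
    K_true: int
    mixing: np.ndarray
    pres_cont_means: np.ndarray
    pres_bin_prev: np.ndarray
    treat_intercepts: np.ndarray
    treat_weights: np.ndarray
    outcome_intercepts: np.ndarray
    outcome_coefs: np.ndarray
    noise_sd: float = 1.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        self.mixing = np.asarray(self.mixing, dtype=float)
        for name in (
            "pres_cont_means",
            "pres_bin_prev",
            "treat_intercepts",
            "treat_weights",
            "outcome_intercepts",
            "outcome_coefs",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        K = self.K_true
        if K < 1:
            raise ValueError("K_true must be >= 1")
        if self.mixing.shape != (K,) or abs(self.mixing.sum() - 1.0) > 1e-9 or (self.mixing < 0).any():
            raise ValueError("mixing must be a length-K vector on the simplex")
        n_pc = len(self.schema.names(tier="presentation", kind="continuous"))
        n_pb = len(self.schema.names(tier="presentation", kind="binary"))
        n_p = len(self.schema.presentation)
        n_t = len(self.schema.treatment)
        n_f = len(self.schema.features)
        if self.pres_cont_means.shape != (K, n_pc):
            raise ValueError("pres_cont_means shape mismatch")
        if self.pres_bin_prev.shape != (K, n_pb):
            raise ValueError("pres_bin_prev shape mismatch")
        if ((self.pres_bin_prev < 0) | (self.pres_bin_prev > 1)).any():
            raise ValueError("prevalences must lie in [0,1]")
        if self.treat_intercepts.shape != (K, n_t):
            raise ValueError("treat_intercepts shape mismatch")
        if self.treat_weights.shape != (K, n_t, n_p):
            raise ValueError("treat_weights shape mismatch")
        if self.outcome_intercepts.shape != (K,):
            raise ValueError("outcome_intercepts shape mismatch")
        if self.outcome_coefs.shape != (K, n_f):
            raise ValueError("outcome_coefs shape mismatch")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0,1)")


def _draw_presentation(spec: SyntheticSpec, groups: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw the presentation block (n, n_presentation) in schema order."""
    pres_specs = [f for f in spec.schema.features if f.tier == "presentation"]
    n = len(groups)
    X = np.empty((n, len(pres_specs)))
    ic = ib = 0
    for j, f in enumerate(pres_specs):
        if f.kind == "continuous":
            X[:, j] = rng.normal(spec.pres_cont_means[groups, ic], spec.noise_sd)
            ic += 1
        else:
            X[:, j] = rng.random(n) < spec.pres_bin_prev[groups, ib]
            ib += 1
    return X


def _draw_treatment(
    spec: SyntheticSpec, groups: np.ndarray, X_pres: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    treat_specs = [f for f in spec.schema.features if f.tier == "treatment"]
    n = len(groups)
    X = np.empty((n, len(treat_specs)))
    for j, f in enumerate(treat_specs):
        lin = spec.treat_intercepts[groups, j] + np.einsum(
            "np,np->n", spec.treat_weights[groups, j, :], X_pres
        )
        if f.kind == "binary":
            X[:, j] = rng.random(n) < expit(lin)
        else:
            X[:, j] = rng.normal(lin, spec.noise_sd)
    return X


def generate_cohort(spec: SyntheticSpec, n: int, seed: int) -> CohortTable:
    """Simulate ``n`` patients from ``spec``; bit-reproducible given ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    groups = rng.choice(spec.K_true, size=n, p=spec.mixing)
    X_pres = _draw_presentation(spec, groups, rng)
    X_treat = _draw_treatment(spec, groups, X_pres, rng)
    X = np.hstack([X_pres, X_treat])
    risk = expit(spec.outcome_intercepts[groups] + np.einsum("nf,nf->n", spec.outcome_coefs[groups], X))
    y = (rng.random(n) < risk).astype(int)

    df = pd.DataFrame(X, columns=spec.schema.feature_names)
    mask = None
    if spec.missing_rate > 0:
        holes = rng.random(df.shape) < spec.missing_rate
        mask = pd.DataFrame(holes, columns=df.columns)
        df = df.mask(mask)
    return CohortTable(features=df, outcome=y, schema=spec.schema, latent_labels=groups, missing_mask=mask)


def bayes_risk(
    spec: SyntheticSpec, presentation_row: np.ndarray, treatment_row: np.ndarray, group: int
) -> float:
    """Exact outcome probability of a patient under its subgroup's model.

    This is the generative ground truth (the Bayes-optimal score on synthetic
    data) used as the discrimination/calibration ceiling in tests.
    """
    if not 0 <= group < spec.K_true:
        raise ValueError(f"group {group} out of range [0, {spec.K_true})")
    x = np.concatenate([np.asarray(presentation_row, float), np.asarray(treatment_row, float)])
    if x.shape != (len(spec.schema.features),):
        raise ValueError("feature row length does not match schema")
    return float(expit(spec.outcome_intercepts[group] + spec.outcome_coefs[group] @ x))


def bayes_risk_cohort(spec: SyntheticSpec, table: CohortTable) -> np.ndarray:
    """Vectorized ``bayes_risk`` for a synthetic table carrying latent labels."""
    if table.latent_labels is None:
        raise ValueError("cohort has no latent labels; oracle risk undefined")
    X = table.features.to_numpy(dtype=float)
    g = table.latent_labels
    return expit(spec.outcome_intercepts[g] + np.einsum("nf,nf->n", spec.outcome_coefs[g], X))


def expected_prevalence(spec: SyntheticSpec, n_mc: int = 100_000, seed: int = 0) -> float:
    """Marginal outcome probability, integrated over the feature distribution
    by Monte Carlo (only the outcome draw itself is analytic)."""
    rng = np.random.default_rng(seed)
    groups = rng.choice(spec.K_true, size=n_mc, p=spec.mixing)
    X_pres = _draw_presentation(spec, groups, rng)
    X_treat = _draw_treatment(spec, groups, X_pres, rng)
    X = np.hstack([X_pres, X_treat])
    risk = expit(spec.outcome_intercepts[groups] + np.einsum("nf,nf->n", spec.outcome_coefs[groups], X))
    return float(risk.mean())


# --- default AMI-CS-like specification ------------------------------------

#: Per-subgroup target event rates; mix to ~0.257 overall under (0.55,0.30,0.15).
_GROUP_RATE_TARGETS = (0.32, 0.20, 0.14)
_MIXING = (0.55, 0.30, 0.15)
_CALIBRATION_SEED = 202_304  # internal MC seed for intercept calibration
_CALIBRATION_N = 20_000


def _nz(shape: tuple, entries: dict) -> np.ndarray:
    a = np.zeros(shape)
    for idx, v in entries.items():
        a[idx] = v
    return a


def default_amics_spec() -> SyntheticSpec:
    """Default three-subgroup AMI-CS-like cohort specification.

    Subgroup sketches (coefficients on the standardized feature scale):

    * group 0 (55%) — "older, hemodynamically compromised": higher age and
      creatinine, lower blood pressure; risk driven *up* by age, troponin and
      low ejection fraction; target event rate 0.32.
    * group 1 (30%) — "younger, heavily instrumented": high MCS utilization;
      the signs of the age / blood-pressure / troponin / ejection-fraction
      effects are *opposite* to group 0, so pooling the groups cancels these
      effects in any single linear model; target rate 0.20.
    * group 2 (15%) — "lower-acuity": risk dominated by cardiac arrest at
      first contact and short stays; target rate 0.14.

    Subgroup outcome intercepts are solved numerically (fixed internal Monte
    Carlo sample) so each subgroup hits its target rate; the implied overall
    prevalence is ~0.257.
    """
    schema = amics_schema()
    K = 3
    pres = schema.presentation
    treat = schema.treatment
    feat = schema.feature_names
    p = {n: i for i, n in enumerate(pres)}
    t = {n: i for i, n in enumerate(treat)}
    f = {n: i for i, n in enumerate(feat)}

    # continuous presentation means (age, sbp, creatinine, troponin)
    pres_cont_means = np.array(
        [
            [1.5, -1.2, 0.8, 0.8],
            [-1.2, 0.5, -0.5, 1.5],
            [-0.5, 1.2, -0.8, -1.2],
        ]
    )
    # binary presentation prevalences (sex_male, ca_first, ca_prehosp,
    # ca_outside, stemi, left_main, prox_lad, multivessel)
    pres_bin_prev = np.array(
        [
            [0.55, 0.45, 0.30, 0.20, 0.85, 0.40, 0.45, 0.85],
            [0.95, 0.15, 0.10, 0.05, 0.90, 0.10, 0.70, 0.30],
            [0.80, 0.05, 0.05, 0.03, 0.45, 0.05, 0.20, 0.15],
        ]
    )

    treat_intercepts = np.zeros((K, len(treat)))
    for name, per_group in {
        "need_mech_support": (0.2, 0.8, -1.0),
        "peak_troponin": (0.3, 0.8, -0.4),
        "requires_dialysis": (-1.5, -2.0, -2.5),
        "dialysis": (-1.8, -2.3, -2.8),
        "atrial_fibrillation": (-0.8, -1.5, -1.8),
        "vt_vf": (-1.0, -0.6, -1.5),
        "lvef": (-0.5, 0.2, 0.6),
        "cerebrovascular_accident": (-3.0, -3.2, -3.5),
        "length_of_stay": (0.2, 0.5, -0.3),
        "other_vascular_complications": (-2.5, -2.5, -2.5),
        "mcs_used": (0.0, 1.0, -0.8),
        "mcs_ecmo": (-3.5, -3.0, -4.0),
        "mcs_iabp": (-0.5, 0.6, -1.2),
        "mcs_lvad": (-1.8, -0.8, -2.5),
        "mcs_other": (-4.0, -4.0, -4.0),
    }.items():
        treat_intercepts[:, t[name]] = per_group

    # treatment-assignment dependence on presentation (same for every group;
    # group effects enter through the intercepts above)
    tw = np.zeros((K, len(treat), len(pres)))
    for tname, pname, w in [
        ("mcs_iabp", "systolic_bp_first_contact", -0.6),
        ("mcs_iabp", "initial_troponin", 0.3),
        ("mcs_lvad", "systolic_bp_first_contact", -0.5),
        ("mcs_lvad", "multivessel_disease", 0.4),
        ("mcs_ecmo", "cardiac_arrest_first_contact", 0.5),
        ("mcs_used", "systolic_bp_first_contact", -0.6),
        ("need_mech_support", "systolic_bp_first_contact", -0.8),
        ("requires_dialysis", "initial_creatinine", 0.9),
        ("dialysis", "initial_creatinine", 0.8),
        ("atrial_fibrillation", "age", 0.5),
        ("vt_vf", "cardiac_arrest_first_contact", 0.7),
        ("vt_vf", "stemi", 0.3),
        ("peak_troponin", "initial_troponin", 0.7),
        ("lvef", "multivessel_disease", -0.4),
        ("lvef", "stemi", -0.3),
        ("length_of_stay", "age", 0.3),
    ]:
        tw[:, t[tname], p[pname]] = w

    nf = len(feat)
    outcome_coefs = np.vstack(
        [
            _nz(
                (nf,),
                {
                    f["age"]: 0.9,
                    f["systolic_bp_first_contact"]: -0.7,
                    f["initial_creatinine"]: 0.6,
                    f["initial_troponin"]: 0.5,
                    f["multivessel_disease"]: 0.4,
                    f["peak_troponin"]: 0.6,
                    f["lvef"]: -0.8,
                    f["dialysis"]: 0.7,
                    f["mcs_lvad"]: 0.5,
                },
            ),
            _nz(
                (nf,),
                {
                    f["age"]: -0.6,
                    f["systolic_bp_first_contact"]: 0.5,
                    f["initial_troponin"]: -0.6,
                    f["peak_troponin"]: -0.5,
                    f["lvef"]: 0.6,
                    f["mcs_iabp"]: 0.7,
                    f["vt_vf"]: 0.6,
                    f["cardiac_arrest_first_contact"]: 0.4,
                },
            ),
            _nz(
                (nf,),
                {
                    f["age"]: 0.3,
                    f["initial_creatinine"]: -0.5,
                    f["stemi"]: 0.5,
                    f["lvef"]: -0.4,
                    f["length_of_stay"]: -0.5,
                    f["cardiac_arrest_first_contact"]: 0.8,
                },
            ),
        ]
    )

    spec = SyntheticSpec(
        schema=schema,
        K_true=K,
        mixing=np.array(_MIXING),
        pres_cont_means=pres_cont_means,
        pres_bin_prev=pres_bin_prev,
        treat_intercepts=treat_intercepts,
        treat_weights=tw,
        outcome_intercepts=np.zeros(K),
        outcome_coefs=outcome_coefs,
    )
    return _calibrate_intercepts(spec, _GROUP_RATE_TARGETS)


def _calibrate_intercepts(spec: SyntheticSpec, targets) -> SyntheticSpec:
    """Solve each subgroup's outcome intercept so its expected event rate hits
    the target, using a fixed internal Monte Carlo feature sample."""
    rng = np.random.default_rng(_CALIBRATION_SEED)
    intercepts = np.empty(spec.K_true)
    for k, target in enumerate(targets):
        groups = np.full(_CALIBRATION_N, k)
        Xp = _draw_presentation(spec, groups, rng)
        Xt = _draw_treatment(spec, groups, Xp, rng)
        lin = np.hstack([Xp, Xt]) @ spec.outcome_coefs[k]
        intercepts[k] = brentq(lambda b: expit(b + lin).mean() - target, -20.0, 20.0, xtol=1e-10)
    return replace(spec, outcome_intercepts=intercepts)
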