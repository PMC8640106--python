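"""Phase-coded linear mixed-model analysis of metabolite concentrations.

The model isolates migraine-phase effects on a metabolite measured at
fixed scan sessions: post-GTN concentrations are the outcome, with fixed
effects for diagnosis, scan session, migraine phase (reference level
interictal), the session-diagnosis interaction, age and the subject's
baseline concentration (ANCOVA-style), and a per-subject random structure
over phase.  Random-effect estimation walks a documented fallback ladder:
an unstructured covariance over the observed phase levels first, then a
random intercept (which, with at most two post-GTN observations per
subject, is also the compound-symmetry model).  Wald t intervals use the
residual degrees of freedom.  p-values are reported without multiplicity
correction.

``estimated_marginal_means`` computes session-by-group means at the
covariate means with the phase distribution as observed in each cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .clinical import PHASES
from .simulate import CohortConfig, SubjectTruth, simulate_cohort

POST_SESSIONS = ("GTN-90", "GTN-270")

FIXED_FORMULA = (
    "concentration ~ C(diagnosis, Treatment('control')) + C(session) "
    "+ C(phase, Treatment('interictal')) + C(session):C(diagnosis, Treatment('control')) "
    "+ age + baseline_concentration"
)

_RE_LADDER = ("unstructured", "intercept")


def build_long_table(
    concentrations: pd.DataFrame,
    phases: dict[str, dict[str, str]],
    cohort: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the analysis table: one row per subject x session x metabolite.

    ``concentrations`` needs columns subject_id, session, metabolite,
    concentration; ``phases`` maps subject -> session -> phase; ``cohort``
    needs subject_id, diagnosis, age.  The Baseline measurement of each
    subject/metabolite is propagated into a ``baseline_concentration``
    column; post-GTN rows without one are flagged (``missing_baseline``).
    """
    required = {"subject_id", "session", "metabolite", "concentration"}
    if missing := required - set(concentrations.columns):
        raise ValueError(f"concentrations table lacks columns {sorted(missing)}")
    dup = concentrations.duplicated(["subject_id", "session", "metabolite"])
    if dup.any():
        raise ValueError("duplicate subject x session x metabolite rows")

    table = concentrations.merge(
        cohort[["subject_id", "diagnosis", "age"]], on="subject_id", how="left"
    )
    baseline = (
        table[table["session"] == "Baseline"]
        .set_index(["subject_id", "metabolite"])["concentration"]
        .rename("baseline_concentration")
    )
    table = table.join(baseline, on=["subject_id", "metabolite"])
    table["phase"] = [
        phases.get(s, {}).get(sess, "interictal")
        for s, sess in zip(table["subject_id"], table["session"])
    ]
    table["missing_baseline"] = table["baseline_concentration"].isna() & (
        table["session"] != "Baseline"
    )
    bad_phase = set(table["phase"]) - set(PHASES)
    if bad_phase:
        raise ValueError(f"unknown phases {sorted(bad_phase)}")
    return table


@dataclass
class PhaseModelResult:
    """Mixed-model estimates for one metabolite."""

    metabolite: str
    estimates: pd.DataFrame  # index: term; columns: estimate, se, ci_low, ci_high, p
    preictal: dict[str, float]  # estimate, se, ci_low, ci_high, p (NaN if inestimable)
    ictal: dict[str, float]
    converged: bool
    re_structure: str
    df_resid: float
    n_obs: int
    emm: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)
    _fit: object | None = None
    _data: pd.DataFrame | None = None


def _contrast(estimates: pd.DataFrame, phase: str) -> dict[str, float]:
    term = f"C(phase, Treatment('interictal'))[T.{phase}]"
    if term in estimates.index:
        row = estimates.loc[term]
        return {k: float(row[k]) for k in ("estimate", "se", "ci_low", "ci_high", "p")}
    return {k: float("nan") for k in ("estimate", "se", "ci_low", "ci_high", "p")}


def _try_fit(data: pd.DataFrame, re_structure: str, strict: bool = True):
    re_formula = {
        "unstructured": "0 + C(phase, Treatment('interictal'))",
        "intercept": "1",
    }[re_structure]
    model = smf.mixedlm(FIXED_FORMULA, data, groups=data["subject_id"],
                        re_formula=re_formula)
    with warnings.catch_warnings():
        # a variance component on the boundary triggers a convergence
        # warning although the fixed effects are well determined; only the
        # strict (non-final) rungs treat that as failure
        warnings.simplefilter("error" if strict else "ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        # with <= 2 outcome observations per subject the unstructured rung
        # is rarely identifiable; bound its iterations so the ladder falls
        # through quickly instead of polishing a flat likelihood
        maxiter = 30 if re_structure == "unstructured" else 100
        fit = model.fit(reml=True, maxiter=maxiter)
    k_fe = model.k_fe
    if strict and not fit.converged:
        raise np.linalg.LinAlgError("optimizer did not converge")
    if not np.all(np.isfinite(np.asarray(fit.bse_fe)[:k_fe])):
        raise np.linalg.LinAlgError("non-finite fixed-effect standard errors")
    return fit


def fit_phase_model(
    table: pd.DataFrame,
    metabolite: str,
    re_structure: str = "ladder",
) -> PhaseModelResult:
    """Fit the phase mixed model for one metabolite.

    Outcomes are the post-GTN sessions; rows lacking a baseline value are
    dropped (the model handles missing sessions by likelihood, without
    imputation).  ``re_structure`` is ``"ladder"`` (default), or one rung
    (``"unstructured"`` / ``"intercept"``) to force a structure.
    """
    data = table[
        (table["metabolite"] == metabolite)
        & table["session"].isin(POST_SESSIONS)
        & table["concentration"].notna()
        & table["baseline_concentration"].notna()
    ].copy()
    notes = []
    if data.empty:
        raise ValueError(f"no post-GTN data for {metabolite}")
    for group in ("migraine", "control"):
        if (data["diagnosis"] == group).sum() < 2:
            raise ValueError(f"fewer than 2 {group} observations for {metabolite}")
    observed_phases = sorted(set(data["phase"]))
    if observed_phases == ["interictal"]:
        notes.append("phase constant (interictal only); contrasts inestimable")
    # A rank-deficient fixed design (e.g. every migraine subject responded,
    # so no post-GTN migraine observation is interictal and the ictal dummy
    # aliases diagnosis) makes the phase contrasts unidentifiable; report
    # that per metabolite instead of failing.
    X = np.asarray(patsy.dmatrix(FIXED_FORMULA.split("~", 1)[1], data))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        nan = {k: float("nan") for k in ("estimate", "se", "ci_low", "ci_high", "p")}
        return PhaseModelResult(
            metabolite=metabolite,
            estimates=pd.DataFrame(
                columns=["estimate", "se", "ci_low", "ci_high", "p"]
            ),
            preictal=dict(nan),
            ictal=dict(nan),
            converged=False,
            re_structure="none",
            df_resid=float("nan"),
            n_obs=len(data),
            notes=notes + ["fixed-effect design rank deficient; "
                           "phase contrasts inestimable"],
        )
    postictal_n = (data["phase"] == "postictal").sum()
    if 0 < postictal_n <= 2:
        notes.append(f"postictal level estimated from {postictal_n} observation(s)")

    ladder = _RE_LADDER if re_structure == "ladder" else (re_structure,)
    max_obs = int(data.groupby("subject_id").size().max())
    fit = None
    used = None
    for i, rung in enumerate(ladder):
        final = i == len(ladder) - 1
        if rung == "unstructured" and max_obs < len(observed_phases):
            # a covariance between phase levels never observed jointly
            # within a subject is structurally unidentifiable; skip the rung
            notes.append(
                "unstructured random effects skipped: "
                f"{max_obs} obs/subject < {len(observed_phases)} phase levels"
            )
            continue
        try:
            fit = _try_fit(data, rung, strict=not final)
            used = rung
            break
        except (np.linalg.LinAlgError, ValueError, ConvergenceWarning):
            continue
    if fit is None:
        raise RuntimeError(f"mixed model failed to converge for {metabolite}")

    k_fe = fit.model.k_fe
    params = np.asarray(fit.fe_params)
    se = np.asarray(fit.bse_fe)[:k_fe]
    names = list(fit.model.exog_names)
    df_resid = max(fit.model.nobs - k_fe, 1.0)
    tcrit = sps.t.ppf(0.975, df_resid)
    tvals = np.divide(params, se, out=np.full_like(params, np.nan), where=se > 0)
    pvals = 2.0 * sps.t.sf(np.abs(tvals), df_resid)
    estimates = pd.DataFrame(
        {
            "estimate": params,
            "se": se,
            "ci_low": params - tcrit * se,
            "ci_high": params + tcrit * se,
            "p": pvals,
        },
        index=names,
    )
    result = PhaseModelResult(
        metabolite=metabolite,
        estimates=estimates,
        preictal=_contrast(estimates, "preictal"),
        ictal=_contrast(estimates, "ictal"),
        converged=bool(fit.converged),
        re_structure=used,
        df_resid=float(df_resid),
        n_obs=int(fit.model.nobs),
        notes=notes,
        _fit=fit,
        _data=data,
    )
    result.emm = estimated_marginal_means(result)
    return result


def estimated_marginal_means(result: PhaseModelResult) -> pd.DataFrame:
    """Estimated marginal means per session x diagnosis with 95% Wald-t CIs.

    Covariates (age, baseline concentration) are held at their grand
    means; the phase distribution is the one observed in each session x
    diagnosis cell.  Cells without observations are reported as NaN.
    """
    fit, data = result._fit, result._data
    if fit is None or data is None:
        raise ValueError("model result does not carry its fit")
    design_info = fit.model.data.design_info
    params = np.asarray(fit.fe_params)
    cov = np.asarray(fit.cov_params())[: len(params), : len(params)]
    tcrit = sps.t.ppf(0.975, result.df_resid)

    rows = []
    for diagnosis in sorted(set(data["diagnosis"])):
        for session in POST_SESSIONS:
            cell = data[(data["diagnosis"] == diagnosis) & (data["session"] == session)]
            if cell.empty:
                rows.append(
                    dict(diagnosis=diagnosis, session=session, emm=np.nan,
                         se=np.nan, ci_low=np.nan, ci_high=np.nan, n=0)
                )
                continue
            pseudo = cell.copy()
            pseudo["age"] = data["age"].mean()
            pseudo["baseline_concentration"] = data["baseline_concentration"].mean()
            X = np.asarray(patsy.dmatrix(design_info, pseudo))
            xbar = X.mean(axis=0)
            emm = float(xbar @ params)
            se = float(np.sqrt(xbar @ cov @ xbar))
            rows.append(
                dict(diagnosis=diagnosis, session=session, emm=emm, se=se,
                     ci_low=emm - tcrit * se, ci_high=emm + tcrit * se,
                     n=len(cell))
            )
    return pd.DataFrame(rows)


def sensitivity_suite(
    table: pd.DataFrame,
    metabolite: str,
    exclusion_sets: dict[str, list[str]],
    re_structure: str = "ladder",
) -> dict[str, PhaseModelResult]:
    """Refit the phase model under each subject-exclusion set.

    Mirrors the study's sensitivity analyses (dropping the postictal
    responder, responders without premonitory symptoms, or the anomalous
    control).  Raises if an exclusion empties a diagnosis group.  The
    result under the empty exclusion set equals the primary fit.
    """
    results = {}
    for name, excluded in exclusion_sets.items():
        unknown = set(excluded) - set(table["subject_id"])
        if unknown:
            raise ValueError(f"{name}: unknown subjects {sorted(unknown)}")
        sub = table[~table["subject_id"].isin(excluded)]
        for group in ("migraine", "control"):
            if not (sub["diagnosis"] == group).any():
                raise ValueError(f"{name}: exclusion empties the {group} group")
        results[name] = fit_phase_model(sub, metabolite, re_structure=re_structure)
    return results


def preictal_sign_stability(results: dict[str, PhaseModelResult]) -> bool:
    """True when the preictal contrast has the same sign in every refit."""
    signs = {np.sign(r.preictal["estimate"]) for r in results.values()}
    return len(signs - {0.0}) <= 1


def simulate_measured_table(
    config: CohortConfig,
    seed: int,
    metabolites: list[str] | None = None,
    cohort: list[SubjectTruth] | None = None,
) -> pd.DataFrame:
    """Ground-truth concentrations plus measurement noise, as a long table.

    Draws the cohort (unless one is passed), reads out each true
    per-session concentration with additive Gaussian measurement error
    (``config.residual_sd``), and assembles the analysis table.  This is
    the concentration-level view of the study used for statistical
    calibration; the spectral pipeline provides the same numbers the slow
    way.
    """
    rng = np.random.default_rng(seed)
    if cohort is None:
        cohort = simulate_cohort(config, seed)
    if metabolites is None:
        metabolites = list(config.baseline_concentrations)
    rows = []
    for subj in cohort:
        for metab in metabolites:
            for session, truth in subj.true_concentrations[metab].items():
                rows.append(
                    dict(
                        subject_id=subj.subject_id,
                        session=session,
                        metabolite=metab,
                        concentration=truth + rng.normal(0.0, config.residual_sd),
                    )
                )
    concentrations = pd.DataFrame(rows)
    cohort_df = pd.DataFrame(
        [
            dict(subject_id=s.subject_id, diagnosis=s.diagnosis, age=s.age)
            for s in cohort
        ]
    )
    phases = {s.subject_id: s.session_phases for s in cohort}
    return build_long_table(concentrations, phases, cohort_df)
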