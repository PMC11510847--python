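"""Linear mixed-effects workload model: sRPE on kinematics, contacts, mass.

The model regresses session RPE on athlete mass, contact count, total
distance, the per-acceleration-type distance sums (HA, LD, HD; LA is the
reference type, absorbed into total distance) and the low/high-speed cells
of each non-reference type (MS is the reference speed zone), with a random
intercept per athlete. Because total distance is the sum of all twelve zone
cells, this reference-cell structure is the minimal identifiable design that
still carries a separate main effect for every acceleration type and its
speed interactions.

Fitting is REML via :class:`statsmodels.regression.mixed_linear_model.MixedLM`.
Predictors are z-scored by default for optimizer conditioning (zone
distances span two orders of magnitude); coefficients are reported on both
the standardized and the raw scale, and per-term t statistics are invariant
to that choice. Degrees of freedom for the Wald t tests are the residual
``n_obs - p`` (statsmodels provides no Satterthwaite approximation); this is
recorded in the fit metadata.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import MODEL_TERMS, ModelSpec
from .errors import CollinearityError, FitFailedError
from .features import StudyDataset, design_features

logger = logging.getLogger(__name__)

FIXED_TERMS = MODEL_TERMS  # includes the intercept
N_SLOPES = len(FIXED_TERMS) - 1


@dataclass
class Design:
    """Fixed-effects matrix, grouping vector and scaling metadata."""

    X: pd.DataFrame  # possibly standardized, with intercept column
    y: pd.Series
    groups: pd.Series
    means: pd.Series  # raw-scale column means (zero for intercept)
    sds: pd.Series  # raw-scale column SDs (one for intercept)
    standardized: bool


@dataclass
class WorkloadModelFit:
    """Estimates, tests, variance components and predictions metadata."""

    coefficients: pd.DataFrame  # index=term: estimate, se, t, df, p (+ _std)
    sigma_u_hat: float
    sigma_e_hat: float
    blups: dict[str, float]
    n_obs: int
    n_athletes: int
    converged: bool
    spec: ModelSpec
    means: pd.Series
    sds: pd.Series
    df_method: str = "residual (n_obs - p)"
    notes: list[str] = field(default_factory=list)
    optimizer_trace: object = None

    def coefficient(self, term: str) -> float:
        return float(self.coefficients.loc[term, "estimate"])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "terms": {
                term: {
                    k: (None if pd.isna(v) else float(v))
                    for k, v in row.items()
                }
                for term, row in self.coefficients.iterrows()
            },
            "sigma_u_hat": self.sigma_u_hat,
            "sigma_e_hat": self.sigma_e_hat,
            "n_obs": self.n_obs,
            "n_athletes": self.n_athletes,
            "converged": self.converged,
            "df_method": self.df_method,
            "notes": self.notes,
            "blups": {k: float(v) for k, v in self.blups.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def coefficients_to_csv(self, path: str | Path) -> None:
        self.coefficients.rename_axis("term").to_csv(path)


def _raw_design(records: pd.DataFrame) -> pd.DataFrame:
    """Raw-scale fixed-effects columns, intercept first."""
    X = pd.DataFrame(index=records.index)
    X["intercept"] = 1.0
    X["mass_kg"] = records["mass_kg"].astype(float)
    X["contacts"] = records["contacts"].astype(float)
    X["total_m"] = records["total_m"].astype(float)
    feats = design_features(records)
    for term in FIXED_TERMS[4:]:
        X[term] = feats[term].astype(float)
    return X


def build_design(dataset: StudyDataset | pd.DataFrame, spec: ModelSpec) -> Design:
    """Build the fixed-effects design and athlete grouping vector.

    Standardizes (z-scores) all non-intercept columns when the spec asks for
    it. Columns with no variation, or any further rank deficiency, raise a
    :class:`CollinearityError` naming the offending columns.
    """
    records = dataset.records if isinstance(dataset, StudyDataset) else dataset
    X = _raw_design(records)
    y = records["srpe_au"].astype(float)
    groups = records["athlete_id"]
    if y.isna().any() or X.isna().any().any():
        raise ValueError("design requires complete records; run drop_incomplete first")

    means = X.mean()
    sds = X.std(ddof=0)
    means["intercept"], sds["intercept"] = 0.0, 1.0

    degenerate = [c for c in X.columns if c != "intercept" and sds[c] == 0.0]
    if degenerate:
        raise CollinearityError(
            f"columns without variation: {degenerate}", columns=degenerate
        )
    Xs = X.copy()
    if spec.standardize:
        for c in X.columns:
            if c != "intercept":
                Xs[c] = (X[c] - means[c]) / sds[c]
    rank = np.linalg.matrix_rank(Xs.to_numpy())
    if rank < Xs.shape[1]:
        # identify dependent columns via the QR diagonal
        _, r = np.linalg.qr(Xs.to_numpy())
        diag = np.abs(np.diag(r))
        bad = [Xs.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise CollinearityError(
            f"design matrix is rank deficient (rank {rank} < {Xs.shape[1]}): {bad}",
            columns=bad,
        )
    if not spec.standardize:
        means = pd.Series(0.0, index=X.columns)
        sds = pd.Series(1.0, index=X.columns)
        means["intercept"], sds["intercept"] = 0.0, 1.0
    return Design(
        X=Xs, y=y, groups=groups, means=means, sds=sds, standardized=spec.standardize
    )


def _back_transform(
    beta_std: np.ndarray, cov_std: np.ndarray, means: pd.Series, sds: pd.Series
) -> tuple[np.ndarray, np.ndarray]:
    """Map standardized-scale estimates/SEs to the raw predictor scale."""
    k = len(beta_std)
    # raw_j = std_j / sd_j for slopes; raw intercept subtracts mean/sd terms
    T = np.zeros((k, k))
    T[0, 0] = 1.0
    for j in range(1, k):
        T[j, j] = 1.0 / sds.iloc[j]
        T[0, j] = -means.iloc[j] / sds.iloc[j]
    beta_raw = T @ beta_std
    cov_raw = T @ cov_std @ T.T
    return beta_raw, np.sqrt(np.diag(cov_raw))


def _coef_table(
    terms, est_raw, se_raw, est_std, se_std, df_resid
) -> pd.DataFrame:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se_raw > 0, est_raw / se_raw, np.inf * np.sign(est_raw))
    p = 2.0 * stats.t.sf(np.abs(t), df_resid)
    return pd.DataFrame(
        {
            "estimate": est_raw,
            "se": se_raw,
            "t": t,
            "df": float(df_resid),
            "p": p,
            "estimate_std": est_std,
            "se_std": se_std,
        },
        index=list(terms),
    )


def fit_lmm(dataset: StudyDataset | pd.DataFrame, spec: ModelSpec | None = None) -> WorkloadModelFit:
    """Fit the random-intercept workload model by REML.

    Returns coefficient estimates with Wald t tests (residual df), the
    athlete and residual standard deviations, and per-athlete BLUPs. A
    boundary (zero) athlete variance is returned with a warning note rather
    than an error. If the response is an exact linear function of the design
    (a noise-free simulation), the exact least-squares solution is returned
    with zero variance components, flagged in ``notes``.
    """
    spec = spec or ModelSpec()
    design = build_design(dataset, spec)
    records = dataset.records if isinstance(dataset, StudyDataset) else dataset
    n_athletes = records["athlete_id"].nunique()
    if n_athletes < 2:
        raise ValueError("the mixed model needs at least 2 athletes")
    n, p_total = design.X.shape
    if n <= p_total:
        raise ValueError(f"need more observations ({n}) than fixed terms ({p_total})")
    df_resid = n - p_total

    Xm = design.X.to_numpy()
    ym = design.y.to_numpy()
    beta_ols, ss_res, *_ = np.linalg.lstsq(Xm, ym, rcond=None)
    resid = ym - Xm @ beta_ols
    if float(resid @ resid) <= 1e-10 * max(1.0, float(ym @ ym)):
        # Perfectly deterministic response: REML variance components vanish
        # and the GLS solution coincides with least squares.
        est_raw, se_raw = _back_transform(
            beta_ols, np.zeros((p_total, p_total)), design.means, design.sds
        )
        table = _coef_table(
            design.X.columns, est_raw, se_raw, beta_ols, np.zeros(p_total), df_resid
        )
        return WorkloadModelFit(
            coefficients=table,
            sigma_u_hat=0.0,
            sigma_e_hat=0.0,
            blups={g: 0.0 for g in records["athlete_id"].unique()},
            n_obs=n,
            n_athletes=n_athletes,
            converged=True,
            spec=spec,
            means=design.means,
            sds=design.sds,
            notes=["response is an exact linear function of the design; "
                   "variance components are zero"],
        )

    import statsmodels.api as sm

    md = sm.MixedLM(ym, Xm, groups=design.groups.to_numpy())
    mr, last_exc = None, None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("bfgs", "powell", "cg", "nm"):
            try:
                cand = md.fit(reml=spec.reml, method=method, maxiter=500)
            except Exception as exc:  # pragma: no cover - optimizer blow-up
                last_exc = exc
                continue
            if bool(getattr(cand, "converged", True)):
                mr = cand
                break
            mr = mr or cand
            last_exc = FitFailedError(f"method {method!r} did not converge")
    if mr is None:
        raise FitFailedError(f"mixed-model fit failed: {last_exc}", trace=last_exc)
    notes = []
    converged = bool(getattr(mr, "converged", True))
    if not converged:
        raise FitFailedError(
            "mixed-model optimizer did not converge", trace=getattr(mr, "hist", None)
        )
    sigma_u = float(np.sqrt(max(np.asarray(mr.cov_re)[0, 0], 0.0)))
    sigma_e = float(np.sqrt(mr.scale))
    beta_std = np.asarray(mr.fe_params)
    cov_std = np.asarray(mr.cov_params())[: p_total, : p_total]
    boundary = sigma_u <= 1e-6 * max(sigma_e, 1.0) or not np.all(
        np.isfinite(np.diag(cov_std))
    )
    if boundary:
        # Singular random-effect variance: the REML solution degenerates to
        # ordinary least squares. Return that fit with sigma_u = 0, flagged.
        msg = "athlete variance estimated at the zero boundary; OLS solution returned"
        logger.warning(msg)
        notes.append(msg)
        sigma_u = 0.0
        beta_std = beta_ols
        dof = n - p_total
        s2 = float(resid @ resid) / dof
        sigma_e = float(np.sqrt(s2))
        cov_std = s2 * np.linalg.inv(Xm.T @ Xm)
        blups = {g: 0.0 for g in records["athlete_id"].unique()}
    else:
        blups = {
            g: float(np.asarray(re_).ravel()[0])
            for g, re_ in mr.random_effects.items()
        }
    est_raw, se_raw = _back_transform(beta_std, cov_std, design.means, design.sds)
    table = _coef_table(
        design.X.columns,
        est_raw,
        se_raw,
        beta_std,
        np.sqrt(np.diag(cov_std)),
        df_resid,
    )
    return WorkloadModelFit(
        coefficients=table,
        sigma_u_hat=sigma_u,
        sigma_e_hat=sigma_e,
        blups=blups,
        n_obs=n,
        n_athletes=n_athletes,
        converged=converged,
        spec=spec,
        means=design.means,
        sds=design.sds,
        notes=notes,
        optimizer_trace=None,
    )


def predict_srpe(
    fit: WorkloadModelFit,
    records: StudyDataset | pd.DataFrame,
    include_random: bool = True,
) -> pd.Series:
    """Predicted sRPE, ``X beta`` plus the athlete BLUP when requested.

    Athletes unseen at fitting time receive a zero random part (with a
    warning) so out-of-roster prediction degrades gracefully.
    """
    df = records.records if isinstance(records, StudyDataset) else records
    X = _raw_design(df)
    if X.isna().any().any():
        missing = X.columns[X.isna().any()].tolist()
        raise ValueError(f"records are missing predictors: {missing}")
    est = fit.coefficients["estimate"].reindex(X.columns)
    yhat = pd.Series(X.to_numpy() @ est.to_numpy(), index=df.index, name="predicted_srpe_au")
    if include_random:
        unseen = set(df["athlete_id"]) - set(fit.blups)
        if unseen:
            warnings.warn(
                f"athletes not seen at fitting time get a zero random part: "
                f"{sorted(unseen)}"
            )
        yhat = yhat + df["athlete_id"].map(fit.blups).fillna(0.0).to_numpy()
    return yhat


def adjusted_r2(
    fit: WorkloadModelFit,
    dataset: StudyDataset | pd.DataFrame,
    conditional: bool = True,
) -> float:
    """Adjusted share of sRPE variance the model accounts for.

    R^2 is the squared correlation between observed sRPE and fitted values
    (conditional: fixed effects plus athlete BLUPs; marginal: fixed effects
    only), adjusted as ``1 - (1 - R^2)(n - 1)/(n - p - 1)`` with ``p`` the
    number of non-intercept fixed terms.
    """
    df = dataset.records if isinstance(dataset, StudyDataset) else dataset
    n = len(df)
    p = N_SLOPES
    if n <= p + 1:
        raise ValueError(f"adjusted R^2 needs n > p + 1 = {p + 1}, got n = {n}")
    yhat = predict_srpe(fit, df, include_random=conditional)
    y = df["srpe_au"].astype(float)
    if np.isclose(np.var(yhat.to_numpy()), 0.0) or np.isclose(np.var(y.to_numpy()), 0.0):
        r2 = 1.0 if np.allclose(y, yhat) else 0.0
    else:
        r2 = float(np.corrcoef(y, yhat)[0, 1]) ** 2
    if np.allclose(y, yhat, rtol=0.0, atol=1e-8 * max(1.0, float(np.abs(y).max()))):
        r2 = 1.0
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
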