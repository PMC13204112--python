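"""Random-intercept linear mixed models for the paired Pre/Post design.

All inference flows through one model family,

    y = X beta + u_patient + e,   u ~ N(0, sigma2_u), e ~ N(0, sigma2_e),

fit by REML (the patient random intercept absorbs within-patient
correlation of the paired PreECRS/PostECRS samples). The variance-ratio
profile likelihood is one-dimensional, so the fit is an exact scalar
optimization; fixed-effect degrees of freedom use the Satterthwaite
approximation with a finite-difference information matrix, falling back to
the residual df at a boundary (singular) fit. On one-observation-per-
patient data the model collapses exactly to OLS.

Built on top of the engine:

- group comparisons with all-pairs Tukey HSD contrasts of estimated
  marginal means (studentized-range reference, q = |t| * sqrt(2));
- score-vs-score association with Nakagawa marginal/conditional R^2 and
  the signed marginal correlation Rm = sign(slope) * sqrt(R2_marginal);
- the recovery model: score ~ condition + baseline + condition:baseline
  + (1 | patient), whose interaction term tests whether a patient's
  baseline cytokine interaction score predicts their Post - Pre change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import studentized_range, t as t_dist

from .preprocess import SampleMetadata
from .scoring import ScoreTable

__all__ = [
    "LMMFit",
    "ContrastTable",
    "AssociationResult",
    "RecoveryResult",
    "fit_group_lmm",
    "tukey_contrasts",
    "association_lmm",
    "fit_recovery_lmm",
    "adjusted_recovery_lmm",
]

CROSS_SECTIONAL_GROUPS = ("Ctrl", "nonECRS", "PreECRS")

_SINGULAR_TOL = 1e-8


# ---------------------------------------------------------------------------
# REML engine


class _RandomInterceptREML:
    """Profiled REML for y = X beta + Z u + e with a single grouping factor."""

    def __init__(self, y: np.ndarray, X: np.ndarray, codes: np.ndarray):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.codes = np.asarray(codes)
        self.n, self.p = self.X.shape
        if np.linalg.matrix_rank(self.X) < self.p:
            raise np.linalg.LinAlgError("fixed-effects design is rank deficient")
        self.G = int(self.codes.max()) + 1
        self.n_i = np.bincount(self.codes, minlength=self.G).astype(float)
        # sufficient statistics
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)
        self.Sx = np.zeros((self.G, self.p))
        np.add.at(self.Sx, self.codes, self.X)
        self.Sy = np.bincount(self.codes, weights=self.y, minlength=self.G)

    def _whitened(self, lam: float):
        """X'W^-1 X, X'W^-1 y, y'W^-1 y and log|W| for W = I + lam Z Z'."""
        c = lam / (1.0 + lam * self.n_i)
        A = self.XtX - (self.Sx * c[:, None]).T @ self.Sx
        b = self.Xty - self.Sx.T @ (c * self.Sy)
        q = self.yty - float(c @ (self.Sy**2))
        logdet_w = float(np.sum(np.log1p(lam * self.n_i)))
        return A, b, q, logdet_w

    def _profile_neg2reml(self, lam: float) -> float:
        A, b, q, logdet_w = self._whitened(lam)
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(A, b)
        rss = max(q - float(beta @ b), 1e-300)
        return logdet_w + logdet_a + (self.n - self.p) * np.log(rss / (self.n - self.p))

    def neg2reml(self, s2u: float, s2e: float) -> float:
        """-2 REML log-likelihood (up to a constant) at (sigma2_u, sigma2_e)."""
        lam = s2u / s2e
        A, b, q, logdet_w = self._whitened(lam)
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(A, b)
        rss = max(q - float(beta @ b), 1e-300)
        return (
            self.n * np.log(s2e)
            + logdet_w
            + logdet_a
            - self.p * np.log(s2e)
            + rss / s2e
        )

    def fit(self):
        # profile over log(lambda); also consider the lambda = 0 boundary
        res = minimize_scalar(
            lambda u: self._profile_neg2reml(np.exp(u)),
            bounds=(-14.0, 14.0),
            method="bounded",
            options={"xatol": 1e-10},
        )
        lam = float(np.exp(res.x))
        # prefer the boundary when it is as good as the interior optimum
        # (the profile is exactly flat for singleton groups)
        if self._profile_neg2reml(0.0) <= res.fun + 1e-7 * (1.0 + abs(res.fun)):
            lam = 0.0
        A, b, q, _ = self._whitened(lam)
        beta = np.linalg.solve(A, b)
        rss = max(q - float(beta @ b), 1e-300)
        s2e = rss / (self.n - self.p)
        s2u = lam * s2e
        cov_beta = s2e * np.linalg.inv(A)
        singular = s2u <= _SINGULAR_TOL * s2e
        return beta, cov_beta, s2u, s2e, singular

    def contrast_var(self, c: np.ndarray, s2u: float, s2e: float) -> float:
        lam = s2u / s2e if s2e > 0 else 0.0
        A, _, _, _ = self._whitened(lam)
        return float(s2e * c @ np.linalg.solve(A, c))

    def satterthwaite_df(self, c: np.ndarray, s2u: float, s2e: float, singular: bool) -> float:
        """Satterthwaite df for the contrast c'beta.

        df = 2 f^2 / (g' Cov(theta) g) with f = Var(c'beta_hat) as a
        function of theta = (sigma2_u, sigma2_e), g its finite-difference
        gradient and Cov(theta) = 2 H^-1 from the finite-difference Hessian
        of the -2 REML criterion. Boundary fits use the residual df.
        """
        resid_df = float(self.n - self.p)
        if singular:
            return resid_df
        theta = np.array([s2u, s2e])
        f0 = self.contrast_var(c, s2u, s2e)
        h = 1e-4 * np.maximum(theta, 1e-12)

        def fvar(th):
            return self.contrast_var(c, max(th[0], 0.0), max(th[1], 1e-300))

        grad = np.zeros(2)
        for k in range(2):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h[k]
            tm[k] -= h[k]
            if tm[k] <= 0:
                grad[k] = (fvar(tp) - f0) / h[k]
            else:
                grad[k] = (fvar(tp) - fvar(tm)) / (2 * h[k])

        def ll(th):
            return self.neg2reml(max(th[0], 1e-300), max(th[1], 1e-300))

        H = np.zeros((2, 2))
        f_c = ll(theta)
        for i in range(2):
            for j in range(i, 2):
                ei = np.zeros(2)
                ej = np.zeros(2)
                ei[i] = h[i]
                ej[j] = h[j]
                if i == j:
                    H[i, i] = (ll(theta + ei) - 2 * f_c + ll(theta - ei)) / h[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        ll(theta + ei + ej)
                        - ll(theta + ei - ej)
                        - ll(theta - ei + ej)
                        + ll(theta - ei - ej)
                    ) / (4 * h[i] * h[j])
        try:
            cov_theta = 2.0 * np.linalg.inv(H)
        except np.linalg.LinAlgError:
            warnings.warn("Satterthwaite information matrix singular; using a normal reference")
            return np.inf
        denom = float(grad @ cov_theta @ grad)
        if denom <= 0 or not np.isfinite(denom):
            warnings.warn("Satterthwaite approximation failed; using a normal reference")
            return np.inf
        df = 2.0 * f0**2 / denom
        return float(np.clip(df, 1.0, resid_df))


@dataclass
class LMMFit:
    """A fitted random-intercept LMM with per-coefficient Wald inference."""

    formula: str
    fixed_effects: pd.DataFrame  # index = name; estimate, se, df, t, p
    sigma2_u: float
    sigma2_e: float
    method: str
    n_obs: int
    n_groups: int
    singular: bool
    levels: tuple[str, ...] = ()
    _engine: _RandomInterceptREML | None = field(default=None, repr=False)
    _beta: np.ndarray | None = field(default=None, repr=False)
    _level_patients: dict[str, set] = field(default_factory=dict, repr=False)

    def contrast(self, c: np.ndarray) -> tuple[float, float, float, float, float]:
        """(estimate, se, df, t, p) for the linear contrast c'beta."""
        eng = self._engine
        est = float(c @ self._beta)
        var = eng.contrast_var(c, self.sigma2_u, self.sigma2_e)
        se = np.sqrt(var)
        df = eng.satterthwaite_df(c, self.sigma2_u, self.sigma2_e, self.singular)
        t = est / se
        if np.isinf(df):
            from scipy.stats import norm as _norm

            p = 2 * _norm.sf(abs(t))
        else:
            p = 2 * t_dist.sf(abs(t), df)
        return est, se, df, t, p

    def fitted_fixed(self) -> np.ndarray:
        return self._engine.X @ self._beta

    def nakagawa_r2(self) -> tuple[float, float]:
        """(marginal, conditional) R^2 (fixed-effect fitted-value variance)."""
        s2f = float(np.var(self.fitted_fixed(), ddof=1))
        tot = s2f + self.sigma2_u + self.sigma2_e
        return s2f / tot, (s2f + self.sigma2_u) / tot


def _fit(y, X, codes, names, formula, levels=(), level_patients=None) -> LMMFit:
    eng = _RandomInterceptREML(y, X, codes)
    beta, cov_beta, s2u, s2e, singular = eng.fit()
    fit = LMMFit(
        formula=formula,
        fixed_effects=pd.DataFrame(index=list(names)),
        sigma2_u=s2u,
        sigma2_e=s2e,
        method="REML",
        n_obs=eng.n,
        n_groups=eng.G,
        singular=singular,
        levels=tuple(levels),
        _engine=eng,
        _beta=beta,
        _level_patients=level_patients or {},
    )
    rows = []
    for k, name in enumerate(names):
        c = np.zeros(len(names))
        c[k] = 1.0
        est, se, df, t, p = fit.contrast(c)
        rows.append({"estimate": est, "se": se, "df": df, "t": t, "p": p})
    fit.fixed_effects = pd.DataFrame(rows, index=list(names))
    return fit


# ---------------------------------------------------------------------------
# Group comparison + Tukey


def fit_group_lmm(scores: pd.Series, meta: SampleMetadata) -> LMMFit:
    """score ~ Group + (1 | PatientID), REML, cell-means coding.

    ``scores`` is indexed by sample_id. The fixed effects reported are the
    estimated marginal (group) means; contrasts between them are what
    `tukey_contrasts` adjusts.
    """
    tab = meta.table.set_index("sample_id").loc[scores.index]
    groups = tab["group"]
    levels = [g for g in ("Ctrl", "nonECRS", "PreECRS", "PostECRS") if g in set(groups)]
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    X = np.column_stack([(groups == g).to_numpy(float) for g in levels])
    patients = pd.Categorical(tab["patient_id"])
    level_patients = {
        g: set(tab.loc[groups == g, "patient_id"]) for g in levels
    }
    return _fit(
        scores.to_numpy(float),
        X,
        patients.codes.astype(int),
        levels,
        "score ~ 0 + Group + (1 | PatientID)",
        levels=levels,
        level_patients=level_patients,
    )


@dataclass
class ContrastTable:
    """All-pairs group contrasts with Tukey-adjusted p-values."""

    table: pd.DataFrame  # level_a, level_b, estimate, se, df, t, p, p_tukey, paired

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def tukey_contrasts(fit: LMMFit) -> ContrastTable:
    """Tukey HSD over all pairwise contrasts of estimated marginal means.

    p_tukey = P(Q_{k,df} > |t| * sqrt(2)) from the studentized-range
    distribution; at k = 2 this equals the unadjusted two-sided p. A
    contrast is flagged paired when its two levels share patients.
    """
    levels = list(fit.levels)
    k = len(levels)
    if k < 2:
        raise ValueError("Tukey contrasts need at least 2 group levels")
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            c = np.zeros(k)
            c[i], c[j] = 1.0, -1.0
            est, se, df, t, p = fit.contrast(c)
            if np.isinf(df):
                df_q = 1e6
            else:
                df_q = df
            p_tukey = float(studentized_range.sf(abs(t) * np.sqrt(2.0), k, df_q))
            shared = fit._level_patients.get(levels[i], set()) & fit._level_patients.get(
                levels[j], set()
            )
            rows.append(
                {
                    "level_a": levels[i],
                    "level_b": levels[j],
                    "estimate": est,
                    "se": se,
                    "df": df,
                    "t": t,
                    "p": p,
                    "p_tukey": min(1.0, p_tukey),
                    "paired": bool(shared),
                }
            )
    return ContrastTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Association (Nakagawa Rm)


@dataclass
class AssociationResult:
    slope: float
    se: float
    df: float
    p_lmm: float
    r2_marginal: float
    r2_conditional: float
    rm: float
    n_obs: int
    fit: LMMFit = field(repr=False, default=None)


def association_lmm(
    y: pd.Series,
    x: pd.Series,
    meta: SampleMetadata,
    groups: tuple[str, ...] | None = CROSS_SECTIONAL_GROUPS,
) -> AssociationResult:
    """y ~ x + (1 | PatientID) with Nakagawa marginal R^2 and signed Rm.

    By default restricted to the cross-sectional groups (Ctrl, nonECRS,
    PreECRS) so each patient contributes one sample; pass groups=None to
    use all samples.
    """
    tab = meta.table.set_index("sample_id")
    idx = y.index.intersection(x.index)
    if groups is not None:
        idx = [s for s in idx if tab.loc[s, "group"] in groups]
    yv = y.loc[idx].to_numpy(float)
    xv = x.loc[idx].to_numpy(float)
    if np.var(xv) == 0:
        raise ValueError("predictor has zero variance")
    codes = pd.Categorical(tab.loc[idx, "patient_id"]).codes.astype(int)
    X = np.column_stack([np.ones(len(idx)), xv])
    fit = _fit(yv, X, codes, ["intercept", "slope"], "y ~ x + (1 | PatientID)")
    r2m, r2c = fit.nakagawa_r2()
    slope = fit.fixed_effects.loc["slope"]
    return AssociationResult(
        slope=float(slope["estimate"]),
        se=float(slope["se"]),
        df=float(slope["df"]),
        p_lmm=float(slope["p"]),
        r2_marginal=r2m,
        r2_conditional=r2c,
        rm=float(np.sign(slope["estimate"]) * np.sqrt(r2m)),
        n_obs=fit.n_obs,
        fit=fit,
    )


# ---------------------------------------------------------------------------
# Recovery prediction (baseline cytokine x treatment interaction)


@dataclass
class RecoveryResult:
    beta_condition: float
    beta_baseline: float
    beta_interaction: float
    se_interaction: float
    df_interaction: float
    p_interaction: float
    rm: float
    r2_marginal: float
    r2_conditional: float
    n_patients: int
    covariate_estimates: pd.DataFrame | None = None
    dropped_covariates: tuple[str, ...] = ()
    fit: LMMFit = field(repr=False, default=None)


def _paired_frame(scores: pd.Series, meta: SampleMetadata) -> pd.DataFrame:
    tab = meta.table.set_index("sample_id")
    rows = []
    for s in scores.index:
        if s not in tab.index:
            continue
        grp = tab.loc[s, "group"]
        if grp in ("PreECRS", "PostECRS"):
            rows.append(
                {
                    "sample_id": s,
                    "patient_id": tab.loc[s, "patient_id"],
                    "condition": 0.0 if grp == "PreECRS" else 1.0,
                    "score": float(scores.loc[s]),
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no PreECRS/PostECRS samples found")
    counts = df.pivot_table(index="patient_id", columns="condition", values="score", aggfunc="size")
    bad = counts[(counts.isna().any(axis=1)) | (counts > 1).any(axis=1)]
    if len(bad):
        raise ValueError(
            "each patient needs exactly one Pre and one Post sample; violated by "
            f"patients {sorted(bad.index)}"
        )
    return df


def fit_recovery_lmm(
    scores: pd.Series,
    meta: SampleMetadata,
    baseline_ix: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> RecoveryResult:
    """score ~ condition * baseline_ix (+ covariates) + (1 | PatientID).

    ``scores`` holds the module score for every Pre and Post sample;
    ``baseline_ix`` is the per-patient pre-treatment cytokine interaction
    score (indexed by patient_id), grand-mean-centered internally. The
    condition:baseline interaction coefficient is the per-unit-baseline
    additional Post - Pre change; in the balanced no-covariate case it
    equals the OLS slope of the per-patient difference on the centered
    baseline. Covariates (per patient) are z-standardized; zero-variance
    covariates are dropped with a warning.
    """
    df = _paired_frame(scores, meta)
    patients = sorted(df["patient_id"].unique())
    missing_b = [p for p in patients if p not in baseline_ix.index]
    if missing_b:
        raise ValueError(f"baseline_ix missing for patients: {missing_b}")
    b = baseline_ix.loc[patients].astype(float)
    b_centered = b - b.mean()
    df["baseline"] = df["patient_id"].map(b_centered)

    cols = [np.ones(len(df)), df["condition"].to_numpy(), df["baseline"].to_numpy(),
            (df["condition"] * df["baseline"]).to_numpy()]
    names = ["intercept", "condition", "baseline", "condition:baseline"]
    dropped: list[str] = []
    if covariates is not None:
        missing_rows = covariates.reindex(patients)
        na_pat = missing_rows[missing_rows.isna().any(axis=1)].index.tolist()
        if na_pat:
            raise ValueError(f"missing covariate values for patients: {na_pat}")
        for name in covariates.columns:
            v = missing_rows[name].astype(float)
            sd = v.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                warnings.warn(f"covariate {name!r} has zero variance; dropped")
                dropped.append(name)
                continue
            z = (v - v.mean()) / sd
            cols.append(df["patient_id"].map(z).to_numpy())
            names.append(name)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design is rank deficient (collinear covariates?)")

    codes = pd.Categorical(df["patient_id"]).codes.astype(int)
    fit = _fit(df["score"].to_numpy(), X, codes, names, "score ~ condition * baseline + covariates + (1 | PatientID)")
    ix = fit.fixed_effects.loc["condition:baseline"]
    r2m, r2c = fit.nakagawa_r2()
    cov_est = None
    cov_names = names[4:]
    if cov_names:
        cov_est = fit.fixed_effects.loc[cov_names]
    return RecoveryResult(
        beta_condition=float(fit.fixed_effects.loc["condition", "estimate"]),
        beta_baseline=float(fit.fixed_effects.loc["baseline", "estimate"]),
        beta_interaction=float(ix["estimate"]),
        se_interaction=float(ix["se"]),
        df_interaction=float(ix["df"]),
        p_interaction=float(ix["p"]),
        rm=float(np.sign(ix["estimate"]) * np.sqrt(r2m)),
        r2_marginal=r2m,
        r2_conditional=r2c,
        n_patients=len(patients),
        covariate_estimates=cov_est,
        dropped_covariates=tuple(dropped),
        fit=fit,
    )


def adjusted_recovery_lmm(
    scores: pd.Series,
    meta: SampleMetadata,
    baseline_ix: pd.Series,
    covariate_names: tuple[str, ...] = ("blood_eos", "total_ige", "lund_mackay", "feno", "tissue_eos", "jesrec"),
) -> RecoveryResult:
    """Recovery model adjusted for standardized clinical covariates.

    Covariates are read per patient from the metadata's Pre-treatment rows;
    missing values raise (no imputation).
    """
    tab = meta.table
    pre = tab[tab["group"] == "PreECRS"].set_index("patient_id")
    avail = [c for c in covariate_names if c in tab.columns]
    if not avail:
        raise KeyError(f"none of the covariates {covariate_names} are in the metadata")
    cov = pre[avail].astype(float)
    return fit_recovery_lmm(scores, meta, baseline_ix, covariates=cov)
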