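"""Random-intercept linear mixed models linking working memory to learning.

The association stage regresses behavioral and decision-process outcomes
(block accuracy, maintenance deltas, generalization scores, posterior drift
and boundary summaries) on OSPAN score, block, session, and their
interactions, with a participant random intercept:

    y_ij = x_ij' beta + u_i + e_ij,    u_i ~ N(0, sigma_u^2),  e_ij ~ N(0, sigma_e^2).

Estimation is profiled restricted maximum likelihood: for a given variance
ratio lambda = sigma_u^2 / sigma_e^2 the GLS solve is closed-form (the group
covariance I + lambda J inverts by Woodbury), and the REML criterion is
optimised over lambda by bounded scalar search.  Wald p-values use the
normal approximation to the t statistic.

OSPAN always enters as the raw continuous score; the median split exists
only for grouping/plotting and never appears in these models.  Session is
treatment-coded with session 1 as baseline and block is numeric (1-6).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "LmmResult",
    "RandomInterceptLMM",
    "fit_random_intercept_lmm",
    "accuracy_model",
    "maintenance_model",
    "generalization_model",
    "ddm_parameter_model",
]


class SingularDesignError(ValueError):
    """Raised when fixed-effect columns are aliased, naming the offenders."""


@dataclass
class LmmResult:
    """Fixed effects, variance components and fit metadata of one model."""

    terms: list
    beta: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    sigma2_intercept: float
    sigma2_residual: float
    n_obs: int
    n_participants: int
    converged: bool
    reml_loglik: float
    pvalue_method: str = "normal-approximation"

    def to_frame(self) -> pd.DataFrame:
        """Tidy (term, beta, se, p) table mirroring a regression summary."""
        return pd.DataFrame(
            {"term": self.terms, "beta": self.beta, "se": self.se, "p": self.pvalues}
        )

    def __getitem__(self, term: str) -> tuple[float, float, float]:
        j = self.terms.index(term)
        return float(self.beta[j]), float(self.se[j]), float(self.pvalues[j])


class RandomInterceptLMM(BaseEstimator):
    """Profiled-REML estimator of a linear model with one random intercept.

    Parameters
    ----------
    reml : bool
        Use restricted (default) rather than ordinary profiled likelihood.
    fix_lambda : float or None
        If set, pins the variance ratio sigma_u^2/sigma_e^2 at this value
        instead of optimising it; ``fix_lambda=0`` reproduces OLS exactly.

    Attributes (after fit)
    ----------------------
    params_, bse_, pvalues_ : fixed-effect estimates, SEs, normal-approx p.
    sigma2_u_, sigma2_e_ : intercept and residual variance components.
    result_ : LmmResult
    """

    def __init__(self, reml: bool = True, fix_lambda: float | None = None,
                 max_log_lambda: float = 12.0):
        self.reml = reml
        self.fix_lambda = fix_lambda
        self.max_log_lambda = max_log_lambda

    def fit(self, X, y, groups, feature_names=None):
        if isinstance(X, pd.DataFrame):
            feature_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        if X.ndim != 2 or len(y) != X.shape[0] or len(groups) != X.shape[0]:
            raise ValueError("X, y and groups must be aligned")
        names = feature_names or [f"x{j}" for j in range(X.shape[1])]
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # name aliased columns by pivoted QR
            _, r, piv = np.linalg.qr(X, mode="reduced"), None, None
            q, r = np.linalg.qr(X)
            diag = np.abs(np.diag(r))
            bad = [names[j] for j in np.where(diag < 1e-8 * diag.max())[0]]
            raise SingularDesignError(f"aliased fixed-effect columns: {bad or names}")

        # sort by group for contiguous blocks
        order = np.argsort(groups, kind="stable")
        Xs, ys, gs = X[order], y[order], groups[order]
        _, starts = np.unique(gs, return_index=True)
        bounds = np.r_[starts, len(gs)]
        n_groups = len(starts)
        n, p = Xs.shape

        xtx = Xs.T @ Xs
        xty = Xs.T @ ys
        yty = float(ys @ ys)
        xsum = np.add.reduceat(Xs, starts, axis=0)  # (g, p) group sums
        ysum = np.add.reduceat(ys, starts)
        sizes = np.diff(bounds).astype(float)

        sign, logdet_xtx = np.linalg.slogdet(xtx)

        def profile(lam):
            """Profiled (RE)ML deviance at variance ratio lam, plus GLS pieces."""
            w = lam / (1.0 + lam * sizes)  # Woodbury weights per group
            A = xtx - (xsum.T * w) @ xsum
            c = xty - xsum.T @ (w * ysum)
            q = yty - float(w * ysum @ ysum)
            beta = np.linalg.solve(A, c)
            rss = q - float(beta @ c)
            rss = max(rss, 1e-300)
            logdet_v = float(np.sum(np.log1p(lam * sizes)))
            if self.reml:
                dof = n - p
                _, logdet_a = np.linalg.slogdet(A)
                dev = dof * np.log(rss / dof) + logdet_v + logdet_a - logdet_xtx
            else:
                dof = n
                dev = n * np.log(rss / n) + logdet_v
            return dev, beta, A, rss / dof

        if self.fix_lambda is not None:
            lam = float(self.fix_lambda)
            converged = True
        else:
            obj = lambda t: profile(np.exp(t))[0]
            res = optimize.minimize_scalar(
                obj, bounds=(-self.max_log_lambda, self.max_log_lambda), method="bounded",
                options={"xatol": 1e-10},
            )
            lam = float(np.exp(res.x))
            converged = bool(res.success)
            if profile(0.0)[0] <= res.fun:  # boundary solution: no intercept variance
                lam = 0.0

        dev, beta, A, sigma2_e = profile(lam)
        cov = np.linalg.inv(A) * sigma2_e
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        pvals = 2.0 * stats.norm.sf(np.abs(z))

        self.params_ = beta
        self.bse_ = se
        self.pvalues_ = pvals
        self.lambda_ = lam
        self.sigma2_e_ = float(sigma2_e)
        self.sigma2_u_ = float(lam * sigma2_e)
        self.cov_params_ = cov
        self.feature_names_ = names
        self.converged_ = converged
        self.result_ = LmmResult(
            terms=names,
            beta=beta,
            se=se,
            pvalues=pvals,
            sigma2_intercept=self.sigma2_u_,
            sigma2_residual=self.sigma2_e_,
            n_obs=int(n),
            n_participants=int(n_groups),
            converged=converged,
            reml_loglik=-0.5 * float(dev),
        )
        return self

    def predict(self, X):
        X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        return X @ self.params_


def fit_random_intercept_lmm(outcome, fixed_design, participant_ids,
                             feature_names=None, reml: bool = True) -> LmmResult:
    """Fit y = X beta + u_participant + e by profiled REML; see RandomInterceptLMM."""
    est = RandomInterceptLMM(reml=reml)
    est.fit(fixed_design, outcome, participant_ids, feature_names=feature_names)
    return est.result_


# ---------------------------------------------------------------------------
# design construction for the study's association models
# ---------------------------------------------------------------------------

def _with_interactions(df: pd.DataFrame, continuous: list[str], dummies: list[str]) -> pd.DataFrame:
    """Full factorial fixed-effect design: main effects and all interactions."""
    design = pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)
    base = continuous + dummies
    for name in base:
        design[name] = df[name].to_numpy(dtype=float)
    # two-way and three-way products among one continuous-set and dummy terms
    from itertools import combinations

    for r in range(2, len(base) + 1):
        for combo in combinations(base, r):
            # never interact two dummies of the same factor (e.g. Session2 x Session3)
            if sum(c.startswith("Session") for c in combo) > 1:
                continue
            if sum(c.startswith("Time") for c in combo) > 1:
                continue
            design[":".join(combo)] = np.prod(
                [df[c].to_numpy(dtype=float) for c in combo], axis=0
            )
    return design


def _session_dummies(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Treatment-coded session dummies, baseline session 1; only sessions present."""
    out = df.copy()
    names = []
    for s in sorted(out["session"].unique()):
        if int(s) == 1:
            continue
        name = f"Session{int(s)}"
        out[name] = (out["session"].astype(int) == int(s)).astype(float)
        names.append(name)
    return out, names


def _merge_ospan(df: pd.DataFrame, ospan: pd.DataFrame) -> pd.DataFrame:
    merged = df.merge(ospan[["participant_id", "ospan_score"]], on="participant_id", how="inner")
    merged = merged.rename(columns={"ospan_score": "OSPAN"})
    return merged.dropna(subset=["OSPAN"])


def accuracy_model(
    accuracy: pd.DataFrame,
    ospan: pd.DataFrame,
    learners: pd.DataFrame | None = None,
    learners_only: bool = False,
) -> LmmResult:
    """Accuracy ~ OSPAN * block * session + (1 | participant), training blocks.

    ``accuracy`` is a per participant x session x block table (percent);
    session is categorical with session 1 baseline, block numeric 1-6, OSPAN
    the raw score, so coefficients are percentage points per unit.
    """
    df = accuracy[accuracy["block"].astype(str).str.isdigit()].copy()
    df["Block"] = df["block"].astype(int).astype(float)
    df = _merge_ospan(df, ospan)
    if learners_only:
        if learners is None:
            raise ValueError("learners table required when learners_only=True")
        keep = learners.loc[learners["learner_class"] == "learner", "participant_id"]
        df = df[df["participant_id"].isin(set(keep))]
    df, session_terms = _session_dummies(df)
    design = _with_interactions(df, ["OSPAN", "Block"], session_terms)
    return fit_random_intercept_lmm(
        df["accuracy_pct"].to_numpy(), design, df["participant_id"].to_numpy()
    )


def maintenance_model(deltas: pd.DataFrame, ospan: pd.DataFrame,
                      learners: pd.DataFrame | None = None) -> LmmResult:
    """Adjacent-block delta ~ OSPAN * time * delay + (1 | participant), learners only.

    ``time`` codes the transition (1->2 baseline), ``delay`` codes
    no-delay vs delay with *delay* as baseline, matching the reported model.
    """
    df = deltas.dropna(subset=["delta_pct"]).copy()
    if learners is not None:
        keep = learners.loc[learners["learner_class"] == "learner", "participant_id"]
        df = df[df["participant_id"].isin(set(keep))]
    df = _merge_ospan(df, ospan)
    df["Time2to3"] = (df["transition"] == "2to3").astype(float)
    df["NoDelay"] = (df["delay_type"] == "no_delay").astype(float)
    design = _with_interactions(df, ["OSPAN"], ["Time2to3", "NoDelay"])
    return fit_random_intercept_lmm(
        df["delta_pct"].to_numpy(), design, df["participant_id"].to_numpy()
    )


def generalization_model(scores: pd.DataFrame, ospan: pd.DataFrame,
                         learners: pd.DataFrame | None = None) -> LmmResult:
    """Generalization score ~ OSPAN * session + (1 | participant), learners only."""
    df = scores.dropna(subset=["generalization_score_pct"]).copy()
    if learners is not None:
        keep = learners.loc[learners["learner_class"] == "learner", "participant_id"]
        df = df[df["participant_id"].isin(set(keep))]
    df = _merge_ospan(df, ospan)
    df, session_terms = _session_dummies(df)
    design = _with_interactions(df, ["OSPAN"], session_terms)
    return fit_random_intercept_lmm(
        df["generalization_score_pct"].to_numpy(), design, df["participant_id"].to_numpy()
    )


def ddm_parameter_model(
    summaries: pd.DataFrame,
    ospan: pd.DataFrame,
    parameter: str = "drift",
    learners: pd.DataFrame | None = None,
) -> LmmResult:
    """Posterior drift/boundary summary ~ OSPAN * block * session + (1 | participant).

    ``summaries`` comes from :func:`tonelearn.race_ddm.correct_drift_summary`
    (one row per participant x session x block).  Learners only, per the
    study's analysis; single-session tables simply omit session terms.
    """
    if parameter not in ("drift", "boundary"):
        raise ValueError("parameter must be 'drift' or 'boundary'")
    df = summaries.dropna(subset=[parameter]).copy()
    if learners is not None:
        keep = learners.loc[learners["learner_class"] == "learner", "participant_id"]
        df = df[df["participant_id"].isin(set(keep))]
    df["Block"] = df["block"].astype(int).astype(float)
    df = _merge_ospan(df, ospan)
    if "session" in df.columns and df["session"].notna().any() and df["session"].nunique() > 1:
        df, session_terms = _session_dummies(df)
    else:
        session_terms = []
    design = _with_interactions(df, ["OSPAN", "Block"], session_terms)
    return fit_random_intercept_lmm(
        df[parameter].to_numpy(), design, df["participant_id"].to_numpy()
    )
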