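"""Proportional-odds (cumulative-logit) ordinal regression.

Models complication severity on the Clavien-Dindo scale: for outcome levels
1..J and cutpoints alpha_1 < ... < alpha_{J-1},

    P(y <= j | x) = F(alpha_j - x'beta),   F the standard logistic CDF,

so each covariate carries one common odds ratio exp(beta) for moving to any
higher complication level. The likelihood is maximised by quasi-Newton
iteration on an unconstrained parametrization (beta, alpha_1, log-increments
of the remaining cutpoints), which enforces the cutpoint ordering without a
constrained solver. The covariance is the inverse observed information at
the optimum; inference is Wald throughout. AIC screening and a link test
(refit on the fitted linear predictor and its square) support model checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .cohort import CDGrade, PatientRecord
from .errors import DegenerateTestError, NotConvergedError, ValidationError

__all__ = [
    "OrdinalDesign",
    "OrdinalFit",
    "LinkTestResult",
    "fit_proportional_odds",
    "odds_ratios",
    "aic_screen",
    "link_test",
    "FEATURES",
    "build_design",
]


# ---------------------------------------------------------------------------
# design

# dummy coding per the cohort's reference levels: female, white, no T2D, no
# OSA, non-smoker, primary LSG, district general, <200 beds, <500 procedures
FEATURES: dict = {
    "age": lambda r: float(r.age),
    "male": lambda r: float(r.sex == "M"),
    "bmi": lambda r: float(r.bmi),
    "non_white": lambda r: float(r.ethnicity == "non_white"),
    "t2d_diet": lambda r: float(r.t2d == "diet"),
    "t2d_oral": lambda r: float(r.t2d == "oral"),
    "t2d_insulin": lambda r: float(r.t2d == "insulin"),
    "hypertension": lambda r: float(r.hypertension),
    "osa_no_cpap": lambda r: float(r.osa == "no_cpap"),
    "osa_cpap": lambda r: float(r.osa == "cpap"),
    "hypercholesterolaemia": lambda r: float(r.hypercholesterolaemia),
    "other_comorbidity": lambda r: float(r.other_comorbidity),
    "smoker_ever": lambda r: float(r.smoking in ("current", "ex")),
    "smoking_current": lambda r: float(r.smoking == "current"),
    "smoking_ex": lambda r: float(r.smoking == "ex"),
    "cat_revisional": lambda r: float(r.category == "elective_revisional"),
    "cat_emergency": lambda r: float(r.category == "emergency"),
    "proc_RYGB": lambda r: float(r.procedure == "RYGB"),
    "proc_OAGB": lambda r: float(r.procedure == "OAGB"),
    "proc_other": lambda r: float(r.procedure == "other"),
    "teaching_hospital": lambda r: float(r.hospital_category == "teaching"),
    "university_hospital": lambda r: float(r.hospital_category == "university"),
}


@dataclass
class OrdinalDesign:
    """Covariate matrix plus ordinal outcome coded 0..J-1 (lowest = no event)."""

    X: np.ndarray  # (n, p), p may be 0 for intercept-only
    y: np.ndarray  # (n,), integers 0..J-1
    level_labels: list[str]
    term_names: list[str] = field(default_factory=list)
    row_ids: list[str] | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        self.y = np.asarray(self.y, dtype=int)
        n, p = self.X.shape
        J = len(self.level_labels)
        if len(self.y) != n:
            raise ValidationError("X and y length mismatch")
        if np.any(~np.isfinite(self.X)):
            raise ValidationError("X contains missing/non-finite entries (complete-case upstream)")
        if self.y.min() < 0 or self.y.max() > J - 1:
            raise ValidationError("y outside 0..J-1")
        observed = np.bincount(self.y, minlength=J)
        if np.any(observed == 0):
            missing = [self.level_labels[j] for j in np.flatnonzero(observed == 0)]
            raise ValidationError(f"outcome level(s) never observed: {missing}")
        if p and np.linalg.matrix_rank(self.X) < p:
            raise ValidationError("covariate columns are linearly dependent")
        if not self.term_names:
            self.term_names = [f"x{i}" for i in range(p)]

    @property
    def n_levels(self) -> int:
        return len(self.level_labels)


def build_design(
    records: list[PatientRecord],
    covariates: list[str],
    collapse: dict[str, str] | None = None,
) -> OrdinalDesign:
    """Build an ordinal design from patient records.

    Outcome is the highest CD grade (NONE lowest). ``collapse`` optionally maps
    grade names onto merged labels (e.g. {"IIIa": "III", "IIIb": "III"});
    unobserved collapsed levels are dropped from the coding.
    """
    for name in covariates:
        if name not in FEATURES:
            raise ValidationError(f"unknown covariate {name!r}; known: {sorted(FEATURES)}")
    grade_label = {g.name: (collapse or {}).get(g.name, g.name) for g in CDGrade}
    ordered_labels = list(dict.fromkeys(grade_label[g.name] for g in CDGrade))
    raw = [grade_label[r.highest_grade.name] for r in records]
    levels = [lab for lab in ordered_labels if lab in set(raw)]
    index = {lab: j for j, lab in enumerate(levels)}
    y = np.array([index[lab] for lab in raw])
    X = np.array([[FEATURES[name](r) for name in covariates] for r in records]).reshape(
        len(records), len(covariates)
    )
    ids = [r.patient_id for r in records]
    return OrdinalDesign(X, y, levels, list(covariates), ids)


# ---------------------------------------------------------------------------
# likelihood


def _nll_and_grads(beta: np.ndarray, alphas: np.ndarray, X: np.ndarray, y: np.ndarray, J: int):
    """Negative log-likelihood and its gradient w.r.t. (beta, alphas)."""
    eta = X @ beta if beta.size else np.zeros(len(y))
    alpha_ext = np.concatenate([[-np.inf], alphas, [np.inf]])
    za = alpha_ext[y] - eta
    zb = alpha_ext[y + 1] - eta
    Fa, Fb = expit(za), expit(zb)
    P = np.clip(Fb - Fa, 1e-300, None)
    nll = -float(np.sum(np.log(P)))
    fa, fb = Fa * (1.0 - Fa), Fb * (1.0 - Fb)
    w = (fa - fb) / P
    g_beta = -(X.T @ w) if beta.size else np.zeros(0)
    g_alpha = np.zeros(J - 1)
    upper = y <= J - 2
    np.add.at(g_alpha, y[upper], fb[upper] / P[upper])
    lower = y >= 1
    np.add.at(g_alpha, y[lower] - 1, -fa[lower] / P[lower])
    return nll, g_beta, -g_alpha


def _unpack(theta: np.ndarray, p: int, J: int) -> tuple[np.ndarray, np.ndarray]:
    beta = theta[:p]
    a1 = theta[p]
    if J > 2:
        alphas = a1 + np.concatenate([[0.0], np.cumsum(np.exp(theta[p + 1 :]))])
    else:
        alphas = np.array([a1])
    return beta, alphas


def _start_values(y: np.ndarray, p: int, J: int) -> np.ndarray:
    """Intercept-only analytic cutpoints (logits of empirical cumulative freqs)."""
    freq = np.bincount(y, minlength=J) / len(y)
    cum = np.cumsum(freq)[:-1]
    cum = np.clip(cum, 1e-10, 1 - 1e-10)
    alphas = logit(cum)
    theta = np.zeros(p + J - 1)
    theta[p] = alphas[0]
    if J > 2:
        theta[p + 1 :] = np.log(np.maximum(np.diff(alphas), 1e-8))
    return theta


@dataclass
class OrdinalFit:
    """A fitted proportional-odds model."""

    beta: np.ndarray
    cutpoints: np.ndarray
    loglik: float
    aic: float
    covariance: np.ndarray  # over (beta, cutpoints)
    converged: bool
    n_obs: int
    term_names: list[str]
    level_labels: list[str]

    @property
    def n_params(self) -> int:
        return len(self.beta) + len(self.cutpoints)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.beta

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """(n, J) category probabilities; rows sum to 1."""
        eta = self.linear_predictor(X)
        cum = expit(self.cutpoints[None, :] - eta[:, None])  # (n, J-1)
        ones = np.ones((len(eta), 1))
        return np.diff(np.hstack([np.zeros_like(ones), cum, ones]), axis=1)

    def wald_table(self) -> pd.DataFrame:
        se = self.se[: len(self.beta)]
        z = np.divide(self.beta, se, out=np.zeros_like(self.beta), where=se > 0)
        return pd.DataFrame(
            {
                "term": self.term_names,
                "coef": self.beta,
                "se": se,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            }
        )


def fit_proportional_odds(
    design: OrdinalDesign,
    gtol: float = 1e-8,
    max_iter: int = 500,
) -> OrdinalFit:
    """Maximum-likelihood fit of the cumulative-logit model.

    Quasi-Newton (BFGS) on the unconstrained (beta, alpha_1, log-increment)
    parametrization with an analytic gradient; covariance from the inverse
    observed information, obtained by central finite differences of the
    analytic score in the natural (beta, cutpoints) coordinates.
    """
    X, y, J = design.X, design.y, design.n_levels
    n, p = X.shape
    if J < 2:
        raise ValidationError("need at least 2 outcome levels")
    if n <= p + J - 1:
        raise ValidationError("more parameters than observations")

    def objective(theta):
        beta, alphas = _unpack(theta, p, J)
        nll, g_beta, g_alpha = _nll_and_grads(beta, alphas, X, y, J)
        grad = np.empty_like(theta)
        grad[:p] = g_beta
        grad[p] = g_alpha.sum()
        if J > 2:
            # d_k scales every cutpoint from k upward
            tail = np.cumsum(g_alpha[::-1])[::-1]
            grad[p + 1 :] = np.exp(theta[p + 1 :]) * tail[1:]
        return nll, grad

    theta0 = _start_values(y, p, J)
    res = optimize.minimize(
        objective, theta0, jac=True, method="BFGS",
        options={"gtol": gtol, "maxiter": max_iter},
    )
    if not res.success:  # BFGS can stall on precision loss near the optimum
        res2 = optimize.minimize(
            objective, res.x, jac=True, method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": gtol},
        )
        if res2.fun <= res.fun:
            res = res2
    beta, alphas = _unpack(res.x, p, J)
    grad_norm = float(np.linalg.norm(objective(res.x)[1], ord=np.inf))
    converged = bool(res.success or grad_norm < 1e-4 * max(1.0, abs(res.fun)))
    loglik = -float(res.fun)
    cov = _observed_information_covariance(beta, alphas, X, y, J)
    return OrdinalFit(
        beta=beta,
        cutpoints=alphas,
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * (p + J - 1),
        covariance=cov,
        converged=converged,
        n_obs=n,
        term_names=list(design.term_names),
        level_labels=list(design.level_labels),
    )


def _observed_information_covariance(beta, alphas, X, y, J) -> np.ndarray:
    p = len(beta)
    k = p + J - 1

    def score(v):
        _, gb, ga = _nll_and_grads(v[:p], v[p:], X, y, J)
        return np.concatenate([gb, ga])

    v0 = np.concatenate([beta, alphas])
    H = np.empty((k, k))
    h = 1e-5 * np.maximum(1.0, np.abs(v0))
    for i in range(k):
        e = np.zeros(k)
        e[i] = h[i]
        H[i] = (score(v0 + e) - score(v0 - e)) / (2 * h[i])
    H = (H + H.T) / 2.0
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return (cov + cov.T) / 2.0


def odds_ratios(fit: OrdinalFit, level: float = 0.95) -> pd.DataFrame:
    """Per-covariate odds ratios with Wald confidence intervals."""
    if not fit.converged:
        raise NotConvergedError("refusing odds ratios from a non-converged fit")
    z = stats.norm.ppf(0.5 + level / 2.0)
    tab = fit.wald_table()
    tab["OR"] = np.exp(tab["coef"])
    tab["lower"] = np.exp(tab["coef"] - z * tab["se"])
    tab["upper"] = np.exp(tab["coef"] + z * tab["se"])
    return tab[["term", "OR", "lower", "upper", "p"]]


def aic_screen(design: OrdinalDesign, candidate_variable_sets: list[list[str]]) -> pd.DataFrame:
    """Fit every candidate covariate set; rank by AIC (ascending).

    Returns one row per candidate with its AIC, delta to the best, and any
    fit failure recorded rather than raised.
    """
    name_to_col = {name: i for i, name in enumerate(design.term_names)}
    rows = []
    for cand in candidate_variable_sets:
        try:
            cols = [name_to_col[name] for name in cand]
            sub = OrdinalDesign(
                design.X[:, cols], design.y, design.level_labels, list(cand), design.row_ids
            )
            f = fit_proportional_odds(sub)
            rows.append(
                {"variables": tuple(cand), "aic": f.aic, "loglik": f.loglik,
                 "converged": f.converged, "error": ""}
            )
        except Exception as exc:  # propagate per-set failures as records
            rows.append(
                {"variables": tuple(cand), "aic": np.inf, "loglik": np.nan,
                 "converged": False, "error": str(exc)}
            )
    out = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    best = out["aic"].min()
    out["delta_aic"] = out["aic"] - best
    return out


@dataclass
class LinkTestResult:
    eta2_coefficient: float
    se: float
    p_value: float
    misspecified: bool


def link_test(fit: OrdinalFit, design: OrdinalDesign, alpha: float = 0.05) -> LinkTestResult:
    """Misspecification check: refit on (eta, eta^2), test the squared term.

    A small Wald p for the eta^2 coefficient signals that the single linear
    predictor does not capture the outcome (wrong link or missing
    non-linearity).
    """
    if not fit.converged:
        raise NotConvergedError("link test requires a converged fit")
    eta = fit.linear_predictor(design.X)
    if float(np.std(eta)) < 1e-12:
        raise DegenerateTestError("linear predictor is constant; link test undefined")
    Z = np.column_stack([eta, eta**2])
    refit = fit_proportional_odds(
        OrdinalDesign(Z, design.y, design.level_labels, ["eta", "eta2"])
    )
    se = refit.se[1]
    coef = refit.beta[1]
    z = coef / se if se > 0 else np.inf
    p = float(2 * stats.norm.sf(abs(z)))
    return LinkTestResult(float(coef), float(se), p, bool(p < alpha))
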