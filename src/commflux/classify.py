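"""Disease-status classification from inferred metabolite fluxes.

A logistic regression is fitted by Newton/IRLS and features are chosen by
bidirectional stepwise search minimizing AIC = 2k − 2ℓ, starting from the
intercept-only model and accepting only strictly AIC-decreasing moves.
Features are z-scored before selection and the training standardization is
frozen into the model, so external validation applies the trained
coefficients to new cohorts without any refitting.  ROC curves are built by
threshold sweep with tied scores stepped simultaneously; the default
operating point is Youden's J on the training curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MAX_ITER = 100
SCORE_TOL = 1e-8
#: |coefficient| beyond which a non-converged fit is declared separated
SEPARATION_COEF = 30.0


@dataclass
class LogisticModel:
    feature_ids: list[str]
    intercept: float
    coefficients: np.ndarray
    log_likelihood: float
    aic: float
    wald_p: dict[str, float]
    separated: bool = False
    n_obs: int = 0
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)
    step_trace: list[tuple[str, float]] = field(default_factory=list)
    operating_threshold: float | None = None
    train_auc: float | None = None

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray:
        """Linear predictor for new samples, applying frozen standardization."""
        missing = [f for f in self.feature_ids if f not in X.columns]
        if missing:
            raise ValueError(f"missing selected feature(s): {missing}")
        Z = np.empty((len(X), len(self.feature_ids)))
        for j, f in enumerate(self.feature_ids):
            mean, sd = self.standardization.get(f, (0.0, 1.0))
            Z[:, j] = (X[f].to_numpy(dtype=float) - mean) / sd
        return self.intercept + Z @ self.coefficients

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return _sigmoid(self.decision_scores(X))


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # sum y*eta - log(1+exp(eta)), numerically stable
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def logistic_fit(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    feature_ids: list[str] | None = None,
) -> LogisticModel:
    """Maximum-likelihood logistic regression by Newton/IRLS.

    Converges when the maximal score (gradient) component falls below 1e-8
    or after 100 iterations.  Complete separation is detected (diverging
    coefficients with vanishing curvature) and flagged; the coefficients of
    a separated fit are not identified.
    """
    if isinstance(X, pd.DataFrame):
        feature_ids = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if feature_ids is None:
        feature_ids = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("y contains a single class")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")

    n, p = X.shape
    Xa = np.hstack([np.ones((n, 1)), X])
    beta = np.zeros(p + 1)
    converged = False
    for _ in range(MAX_ITER):
        eta = Xa @ beta
        mu = _sigmoid(eta)
        score = Xa.T @ (y - mu)
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        w = np.clip(mu * (1 - mu), 1e-12, None)
        H = Xa.T @ (Xa * w[:, None])
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, score, rcond=None)[0]
        # step halving keeps the likelihood monotone
        ll0 = _log_likelihood(y, eta)
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            if _log_likelihood(y, Xa @ cand) >= ll0 - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step

    eta = Xa @ beta
    ll = _log_likelihood(y, eta)
    # complete separation: the likelihood approaches its supremum of 0, or the
    # coefficients diverge without the score ever vanishing
    separated = (p > 0 and ll > -1e-4) or (
        (not converged) and np.max(np.abs(beta)) > SEPARATION_COEF
    )
    mu = _sigmoid(eta)
    w = np.clip(mu * (1 - mu), 1e-12, None)
    H = Xa.T @ (Xa * w[:, None])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p + 1, np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    wald = 2.0 * stats.norm.sf(np.abs(z))
    k = p + 1
    return LogisticModel(
        feature_ids=feature_ids,
        intercept=float(beta[0]),
        coefficients=beta[1:].copy(),
        log_likelihood=ll,
        aic=2.0 * k - 2.0 * ll,
        wald_p={f: float(wald[j + 1]) for j, f in enumerate(feature_ids)},
        separated=separated,
        n_obs=n,
    )


def stepwise_aic(
    X: pd.DataFrame,
    y: np.ndarray,
    direction: str = "both",
    max_steps: int = 50,
    standardize: bool = True,
) -> LogisticModel:
    """Bidirectional stepwise feature selection minimizing AIC.

    Starts from the intercept-only model; at each step every single-feature
    addition (and, with ``direction='both'``, removal) is scored and the
    best move is accepted only if it strictly decreases AIC.  The accepted
    trace (move, AIC) is stored on the returned model along with the
    training standardization, Youden-J operating threshold and training
    AUC.
    """
    if direction not in ("both", "forward"):
        raise ValueError("direction must be 'both' or 'forward'")
    y = np.asarray(y, dtype=float)
    features = list(X.columns)
    Z = X.copy().astype(float)
    standardization: dict[str, tuple[float, float]] = {}
    for f in features:
        if standardize:
            mean = float(Z[f].mean())
            sd = float(Z[f].std(ddof=0)) or 1.0
        else:
            mean, sd = 0.0, 1.0
        standardization[f] = (mean, sd)
        Z[f] = (Z[f] - mean) / sd

    current: list[str] = []
    best = logistic_fit(np.empty((len(y), 0)), y, [])
    trace: list[tuple[str, float]] = [("<null>", best.aic)]
    for _ in range(max_steps):
        moves: list[tuple[float, str, list[str]]] = []
        for f in features:
            if f not in current:
                cand = current + [f]
                fit = logistic_fit(Z[cand], y)
                moves.append((fit.aic, f"+{f}", cand))
        if direction == "both":
            for f in current:
                cand = [g for g in current if g != f]
                fit = logistic_fit(Z[cand] if cand else np.empty((len(y), 0)), y, cand)
                moves.append((fit.aic, f"-{f}", cand))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1]))
        best_aic, move, cand = moves[0]
        if best_aic < best.aic - 1e-10:
            current = cand
            best = logistic_fit(Z[current] if current else np.empty((len(y), 0)), y, current)
            trace.append((move, best.aic))
        else:
            break

    model = best
    model.standardization = {f: standardization[f] for f in current}
    model.step_trace = trace
    scores = model.intercept + (
        Z[current].to_numpy() @ model.coefficients if current else np.zeros(len(y))
    )
    roc = roc_auc(scores, y)
    model.train_auc = roc.auc
    model.operating_threshold = roc.youden_threshold()
    return model


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    positive_label: object = 1

    def youden_threshold(self) -> float:
        """Score threshold maximizing TPR − FPR (Youden's J)."""
        j = self.tpr - self.fpr
        return float(self.thresholds[int(np.argmax(j))])


def roc_auc(scores: np.ndarray, y: np.ndarray, positive_label=1) -> ROCResult:
    """ROC curve and trapezoidal AUC with simultaneous steps on tied scores.

    AUC equals (concordant + 0.5·tied) / (n₊·n₋) over all case/control
    pairs and is invariant under strictly monotone score transforms.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = y == positive_label
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s, p = scores[order], pos[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tp = np.cumsum(p)[distinct]
    fp = np.cumsum(~p)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr, tpr, thresholds, auc, positive_label)


@dataclass
class ValidationResult:
    roc: ROCResult
    auc: float
    sensitivity: float
    specificity: float


def validate_external(
    model: LogisticModel,
    X_new: pd.DataFrame,
    y_new: np.ndarray,
    positive_label=1,
) -> ValidationResult:
    """Score an independent cohort with a frozen trained model.

    The training standardization and coefficients are applied as-is (never
    refit).  Sensitivity and specificity are evaluated at the model's
    training operating point (Youden-J by default).
    """
    scores = model.decision_scores(X_new)
    roc = roc_auc(scores, y_new, positive_label)
    thr = model.operating_threshold
    if thr is None:
        thr = roc.youden_threshold()
    y_new = np.asarray(y_new)
    pos = y_new == positive_label
    pred = scores >= thr
    sens = float((pred & pos).sum() / max(1, pos.sum()))
    spec = float((~pred & ~pos).sum() / max(1, (~pos).sum()))
    return ValidationResult(roc, roc.auc, sens, spec)


def batch_correct(
    X_a: pd.DataFrame, X_b: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature per-cohort mean-centering over the shared feature set."""
    shared = [f for f in X_a.columns if f in X_b.columns]
    if not shared:
        raise ValueError("cohorts share no features")
    A = X_a[shared].astype(float)
    B = X_b[shared].astype(float)
    return A - A.mean(axis=0), B - B.mean(axis=0)


@dataclass
class Embedding2D:
    coordinates: pd.DataFrame  # samples × (x, y)
    perplexity: float
    n_iter: int
    seed: int
    kl_divergence: float


def tsne_embed(
    X: pd.DataFrame,
    perplexity: float = 10.0,
    n_iter: int = 1000,
    seed: int | None = None,
) -> Embedding2D:
    """Exact t-SNE to two dimensions (Gaussian affinities matched to the
    requested perplexity, Student-t low-dimensional kernel, early
    exaggeration), seeded; the final KL divergence is reported."""
    from sklearn.manifold import TSNE

    if seed is None:
        raise ValueError("a seed is required for t-SNE")
    n = len(X)
    if n <= 3 * perplexity:
        raise ValueError(f"perplexity {perplexity} infeasible for n={n}")
    ts = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=n_iter,
        random_state=seed,
        method="exact",
        init="pca",
    )
    coords = ts.fit_transform(X.to_numpy(dtype=float))
    return Embedding2D(
        pd.DataFrame(coords, index=X.index, columns=["x", "y"]),
        perplexity,
        n_iter,
        seed,
        float(ts.kl_divergence_),
    )
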