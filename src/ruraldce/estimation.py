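"""Maximum-likelihood estimators for paired discrete choice data.

Three model families, all built on the logit kernel for two-alternative
tasks (P(A) = logistic((x_A - x_B)'beta)):

* conditional logit — homogeneous preferences, analytic Newton;
* latent-class logit — C-component finite mixture over respondents,
  fitted by EM with multiple seeded restarts and AIC-based selection of C;
* mixed logit — respondent-level independent-normal random coefficients,
  fitted by simulated maximum likelihood over quasi-random Halton draws,
  with the panel structure (a respondent's repeated tasks share one draw)
  built into the simulated likelihood.

Attribute x covariate interaction models reuse the conditional logit with
interaction columns appended to the design matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit, logsumexp, ndtri
from scipy.optimize import minimize

from .data import AttributeSchema, ChoiceDataset, paired_differences, respondent_covariates

#: Prime bases handed to the Halton generator, one per random coefficient.
HALTON_PRIMES = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29)

#: Default burn-in: leading Halton elements discarded before use.
HALTON_BURN = 50


# ---------------------------------------------------------------------------
# Conditional logit


@dataclass
class CLogitResult:
    """Conditional logit fit: coefficients, covariance and fit statistics."""

    coefficients: pd.Series
    se: pd.Series
    cov: pd.DataFrame
    loglik: float
    n_observations: int
    converged: bool
    n_iter: int

    @property
    def z(self) -> pd.Series:
        return self.coefficients / self.se

    @property
    def aic(self) -> float:
        return 2 * len(self.coefficients) - 2 * self.loglik

    def summary(self) -> pd.DataFrame:
        from scipy.stats import norm

        z = self.z
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": self.se,
                "z": z,
                "p": 2 * norm.sf(np.abs(z)),
            }
        )


def clogit_loglik(beta, dx, y, weights=None):
    """Log-likelihood, gradient and Hessian of the paired conditional logit.

    ``dx`` holds per-task encoded differences x_A - x_B and ``y`` indicates
    A chosen; optional per-task ``weights`` give the weighted likelihood
    used inside the latent-class M-step.
    """
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("non-finite coefficient vector")
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    v = dx @ beta
    # log P(chosen) = log sigma(v) if A chosen else log sigma(-v)
    s = 2.0 * y - 1.0
    ll = float(np.sum(w * log_expit(s * v)))
    p = expit(v)
    grad = dx.T @ (w * (y - p))
    h = w * p * (1.0 - p)
    hess = -(dx * h[:, None]).T @ dx
    return ll, grad, hess


def _newton_clogit(dx, y, weights=None, tol=1e-6, max_iter=100):
    """Newton maximisation from beta = 0 with step halving."""
    k = dx.shape[1]
    beta = np.zeros(k)
    ll, grad, hess = clogit_loglik(beta, dx, y, weights)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            break
        # step halving keeps the iteration ascent-only
        t = 1.0
        for _ in range(30):
            ll_new, grad_new, hess_new = clogit_loglik(beta + t * step, dx, y, weights)
            if ll_new >= ll - 1e-12:
                break
            t /= 2.0
        beta = beta + t * step
        ll, grad, hess = ll_new, grad_new, hess_new
    else:
        converged = np.max(np.abs(grad)) < tol
    return beta, ll, grad, hess, converged, it


def fit_clogit(
    dataset: ChoiceDataset,
    schema: AttributeSchema | None = None,
    weights=None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> CLogitResult:
    """Fit the conditional logit by Newton's method from beta = 0.

    Convergence at gradient max-norm < ``tol``; the covariance matrix is
    the inverse observed information at the optimum.  Non-convergence
    (e.g. separable data, where the MLE is infinite) is flagged on the
    result, not raised.
    """
    schema = schema or dataset.schema
    dx, y, _ = paired_differences(dataset, schema)
    return _fit_clogit_arrays(dx, y, list(schema.encoded_columns), weights, tol, max_iter)


def _fit_clogit_arrays(dx, y, columns, weights=None, tol=1e-6, max_iter=100):
    beta, ll, grad, hess, converged, it = _newton_clogit(dx, y, weights, tol, max_iter)
    # separation check: utilities this extreme mean the MLE diverges
    if converged and np.max(np.abs(dx @ beta)) > 25.0:
        converged = False
    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        cov = np.full((len(beta), len(beta)), np.nan)
        converged = False
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    return CLogitResult(
        coefficients=pd.Series(beta, index=columns),
        se=pd.Series(se, index=columns),
        cov=pd.DataFrame(cov, index=columns, columns=columns),
        loglik=ll,
        n_observations=len(y),
        converged=bool(converged),
        n_iter=it,
    )


# ---------------------------------------------------------------------------
# Halton draws


def _is_prime(n: int) -> bool:
    if n < 2:
        return False
    return all(n % d for d in range(2, int(n**0.5) + 1))


def halton_sequence(base: int, n: int, burn: int = 0) -> np.ndarray:
    """Radical-inverse Halton sequence in (0, 1).

    Element i is the base-``base`` radical inverse of i + 1; the first
    ``burn`` elements are discarded.
    """
    if not _is_prime(base):
        raise ValueError(f"Halton base must be prime, got {base}")
    if burn < 0:
        raise ValueError("burn must be >= 0")
    idx = np.arange(burn + 1, burn + n + 1, dtype=np.int64)
    out = np.zeros(n)
    f = 1.0
    while idx.any():
        f /= base
        out += f * (idx % base)
        idx //= base
    return out


def halton_normal_draws(
    n_respondents: int,
    R: int,
    n_dims: int,
    burn: int = HALTON_BURN,
    scramble: bool = False,
    seed: int | None = None,
) -> np.ndarray:
    """Standard-normal quasi-random draws of shape (n_respondents, R, n_dims).

    One Halton dimension per random coefficient with distinct prime bases,
    partitioned across respondents (respondent i takes elements
    ``i*R:(i+1)*R`` of each dimension), transformed by the inverse normal
    CDF.  Optional random-shift scrambling (seeded) adds a uniform offset
    modulo 1 per dimension.
    """
    if n_dims > len(HALTON_PRIMES):
        raise ValueError("too many random coefficients for the configured prime list")
    total = n_respondents * R
    dims = []
    rng = np.random.default_rng(seed)
    for d in range(n_dims):
        h = halton_sequence(HALTON_PRIMES[d], total, burn=burn)
        if scramble:
            h = np.mod(h + rng.random(), 1.0)
            h = np.clip(h, 1e-12, 1 - 1e-12)
        dims.append(ndtri(h))
    z = np.stack(dims, axis=-1)  # (total, D)
    return z.reshape(n_respondents, R, n_dims)


# ---------------------------------------------------------------------------
# Mixed logit (panel simulated maximum likelihood)


@dataclass
class MIXLResult:
    """Panel mixed logit fit: coefficient means, SDs and fit statistics."""

    means: pd.Series
    sds: pd.Series  # random coefficients only, reported as magnitudes
    se_means: pd.Series
    se_sds: pd.Series
    cov: pd.DataFrame  # over (means..., sd_...) in parameter order
    loglik: float
    n_draws: int
    draw_type: str
    random: tuple
    n_observations: int
    converged: bool

    def summary(self) -> pd.DataFrame:
        rows = pd.DataFrame({"coef": self.means, "se": self.se_means})
        rows["sd"] = self.sds.reindex(rows.index)
        rows["se_sd"] = self.se_sds.reindex(rows.index)
        return rows


def _panel_index(resp_ids):
    """Group tasks by respondent: sorted order, reduceat boundaries."""
    resp_ids = np.asarray(resp_ids)
    order = np.argsort(resp_ids, kind="stable")
    sorted_ids = resp_ids[order]
    uniq, starts = np.unique(sorted_ids, return_index=True)
    inverse = np.searchsorted(uniq, sorted_ids)
    return order, uniq, starts, inverse


def mixl_simulated_loglik(means, sds, dx, y, resp_inverse, starts, z, random_idx=None):
    """Simulated panel log-likelihood and its analytic gradient.

    Per respondent the R draws' products of task choice probabilities are
    averaged, logged and summed:  SLL = sum_n log (1/R) sum_r prod_t L_ntr.
    ``z`` holds the (n, R, D) standard-normal draws, one dimension per
    random coefficient; coefficient ``random_idx[d]`` of respondent n
    under draw r is means[random_idx[d]] + sds[d] * z[n, r, d].  Returns
    ``(sll, grad_means, grad_sds)``.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    n, R, D = z.shape
    if R == 0:
        raise ValueError("R must be >= 1")
    if random_idx is None:
        random_idx = np.arange(dx.shape[1])
    dxr = dx[:, random_idx]  # (T, D)
    s = (2.0 * y - 1.0)[:, None]  # (T,1)
    zt = z[resp_inverse]  # (T, R, D)
    # utilities per task x draw
    v = (dx @ means)[:, None] + np.einsum("td,trd->tr", dxr * sds, zt)
    logL = log_expit(s * v)  # (T, R)
    logP = np.add.reduceat(logL, starts, axis=0)  # (n, R)
    sll = float(np.sum(logsumexp(logP, axis=1) - np.log(R)))
    # weights: softmax over draws within respondent
    w = np.exp(logP - logsumexp(logP, axis=1, keepdims=True))  # (n, R)
    g = w[resp_inverse] * (1.0 - np.exp(logL)) * s  # (T, R)
    grad_means = np.einsum("tr,tk->k", g, dx)
    grad_sds = np.einsum("tr,trd,td->d", g, zt, dxr)
    return sll, grad_means, grad_sds


def fit_mixl(
    dataset: ChoiceDataset,
    schema: AttributeSchema | None = None,
    random_spec: tuple | None = None,
    R: int = 2000,
    seed: int = 0,
    burn: int = HALTON_BURN,
    scramble: bool = False,
    maxiter: int = 300,
) -> MIXLResult:
    """Fit the panel mixed logit by simulated maximum likelihood.

    ``random_spec`` names the columns with normally distributed random
    coefficients; by default every attribute except salary is random and
    salary is a fixed coefficient.  Draws are Halton with distinct prime
    bases per dimension, burn-in ``burn``, partitioned across respondents.
    SD parameters are unconstrained during optimisation and reported as
    magnitudes.  Standard errors come from the inverse numerical Hessian
    of the simulated log-likelihood at the optimum.
    """
    schema = schema or dataset.schema
    columns = list(schema.encoded_columns)
    dx, y, resp = paired_differences(dataset, schema)
    if random_spec is None:
        random_spec = tuple(c for c in columns if c != "salary")
    random_idx = np.array([columns.index(c) for c in random_spec], dtype=int)
    D = len(random_idx)

    order, uniq, starts, inverse = _panel_index(resp)
    dx_s, y_s = dx[order], y[order]
    z = halton_normal_draws(len(uniq), R, D, burn=burn, scramble=scramble, seed=seed)

    # column scaling so salary (ETB units) optimises on the same footing
    scale = dx_s.std(axis=0)
    scale[scale == 0] = 1.0
    dxn = dx_s / scale

    start = _fit_clogit_arrays(dxn, y_s, columns)
    theta0 = np.concatenate([start.coefficients.to_numpy(), np.full(D, 0.5)])

    def negloglik(theta):
        means, sds = theta[: len(columns)], theta[len(columns):]
        sll, gm, gs = mixl_simulated_loglik(
            means, sds, dxn, y_s, inverse, starts, z, random_idx
        )
        return -sll, -np.concatenate([gm, gs])

    res = minimize(negloglik, theta0, jac=True, method="BFGS",
                   options={"maxiter": maxiter, "gtol": 1e-5})
    theta = res.x
    loglik = -float(res.fun)

    hess = _numeric_hessian(lambda t: negloglik(t)[1], theta)
    hess = 0.5 * (hess + hess.T)
    try:
        cov_n = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov_n = np.full((len(theta), len(theta)), np.nan)

    # map back to raw attribute units
    full_scale = np.concatenate([scale, scale[random_idx]])
    theta_raw = theta / full_scale
    cov_raw = cov_n / np.outer(full_scale, full_scale)
    se_raw = np.sqrt(np.clip(np.diag(cov_raw), 0.0, np.inf))

    names = columns + [f"sd_{c}" for c in random_spec]
    means = pd.Series(theta_raw[: len(columns)], index=columns)
    sds = pd.Series(np.abs(theta_raw[len(columns):]), index=list(random_spec))
    return MIXLResult(
        means=means,
        sds=sds,
        se_means=pd.Series(se_raw[: len(columns)], index=columns),
        se_sds=pd.Series(se_raw[len(columns):], index=list(random_spec)),
        cov=pd.DataFrame(cov_raw, index=names, columns=names),
        loglik=loglik,
        n_draws=R,
        draw_type="halton-scrambled" if scramble else "halton",
        random=tuple(random_spec),
        n_observations=len(y),
        converged=bool(res.success or np.max(np.abs(res.jac)) < 1e-3),
    )


def _numeric_hessian(grad_fn, theta, eps=1e-5):
    """Central finite differences of an analytic gradient."""
    k = len(theta)
    H = np.empty((k, k))
    for i in range(k):
        step = eps * max(1.0, abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += step
        tm[i] -= step
        H[:, i] = (grad_fn(tp) - grad_fn(tm)) / (2 * step)
    return H


# ---------------------------------------------------------------------------
# Latent class logit (EM)


@dataclass
class LCMResult:
    """Latent-class logit fit: per-class coefficients, shares, posteriors."""

    class_coefs: pd.DataFrame  # columns class_1..class_C
    class_ses: pd.DataFrame
    shares: np.ndarray
    loglik: float
    aic: float
    posterior: pd.DataFrame  # respondents x classes
    n_classes: int
    converged: bool
    loglik_trace: list = field(default_factory=list)

    @property
    def membership_constants(self) -> np.ndarray:
        """Constant-only multinomial membership parameters (last class base)."""
        return np.log(self.shares / self.shares[-1])


def _class_logliks(betas, dx, y, starts):
    """log P(respondent's choices | class c) for each respondent, class."""
    s = 2.0 * y - 1.0
    out = []
    for beta in betas:
        logL = log_expit(s * (dx @ beta))
        out.append(np.add.reduceat(logL, starts))
    return np.column_stack(out)  # (n, C)


def fit_lcm(
    dataset: ChoiceDataset,
    schema: AttributeSchema | None = None,
    C: int = 3,
    n_starts: int = 3,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> LCMResult:
    """Fit a C-class latent-class logit by EM with seeded restarts.

    E-step: posterior class probabilities from current shares and
    per-class panel logit likelihoods.  M-step: per-class Newton-weighted
    conditional logit and share update, so the observed log-likelihood is
    non-decreasing.  Restarts perturb the pooled conditional logit
    solution; the best log-likelihood wins.  Classes are reported in
    descending salary-coefficient order (ties by share) so class labels
    are reproducible.  A restart collapsing a class (share < 1e-4) is
    discarded; if all restarts collapse the result is flagged.
    """
    schema = schema or dataset.schema
    columns = list(schema.encoded_columns)
    dx, y, resp = paired_differences(dataset, schema)
    order, uniq, starts, inverse = _panel_index(resp)
    dx_s, y_s = dx[order], y[order]
    n = len(uniq)
    K = dx.shape[1]

    pooled = _fit_clogit_arrays(dx_s, y_s, columns)
    beta_pooled = pooled.coefficients.to_numpy()
    if C == 1:
        post = pd.DataFrame(np.ones((n, 1)), index=uniq, columns=["class_1"])
        aic = 2 * K - 2 * pooled.loglik
        return LCMResult(
            class_coefs=pooled.coefficients.to_frame("class_1"),
            class_ses=pooled.se.to_frame("class_1"),
            shares=np.array([1.0]),
            loglik=pooled.loglik,
            aic=aic,
            posterior=post,
            n_classes=1,
            converged=pooled.converged,
            loglik_trace=[pooled.loglik],
        )

    col_scale = dx_s.std(axis=0)
    col_scale[col_scale == 0] = 1.0
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        betas = [
            beta_pooled + rng.normal(0.0, 0.75, K) / col_scale for _ in range(C)
        ]
        shares = np.full(C, 1.0 / C)
        trace = []
        degenerate = False
        converged = False
        h = None
        for _ in range(max_iter):
            logP = _class_logliks(betas, dx_s, y_s, starts)  # (n, C)
            logj = np.log(shares)[None, :] + logP
            ll = float(np.sum(logsumexp(logj, axis=1)))
            trace.append(ll)
            h = np.exp(logj - logsumexp(logj, axis=1, keepdims=True))
            shares = h.mean(axis=0)
            if np.any(shares < 1e-4):
                degenerate = True
                break
            for c in range(C):
                w = h[inverse, c]
                betas[c], *_ = _newton_clogit(dx_s, y_s, weights=w, tol=1e-8, max_iter=50)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
                converged = True
                break
        if degenerate:
            continue
        logP = _class_logliks(betas, dx_s, y_s, starts)
        logj = np.log(shares)[None, :] + logP
        ll = float(np.sum(logsumexp(logj, axis=1)))
        trace.append(ll)
        if best is None or ll > best["ll"]:
            best = {
                "ll": ll,
                "betas": betas,
                "shares": shares,
                "post": np.exp(logj - logsumexp(logj, axis=1, keepdims=True)),
                "trace": trace,
                "converged": converged,
            }
    if best is None:
        # every restart collapsed a class: return flagged single-class fallback
        aic = 2 * (C * K + (C - 1)) - 2 * pooled.loglik
        post = pd.DataFrame(np.ones((n, 1)), index=uniq, columns=["class_1"])
        return LCMResult(
            class_coefs=pooled.coefficients.to_frame("class_1"),
            class_ses=pooled.se.to_frame("class_1"),
            shares=np.array([1.0]),
            loglik=pooled.loglik,
            aic=aic,
            posterior=post,
            n_classes=C,
            converged=False,
            loglik_trace=[pooled.loglik],
        )

    betas, shares = best["betas"], best["shares"]
    salary_ix = columns.index("salary") if "salary" in columns else 0
    order_c = sorted(
        range(C), key=lambda c: (-betas[c][salary_ix], -shares[c])
    )
    betas = [betas[c] for c in order_c]
    shares = shares[order_c]
    post = best["post"][:, order_c]

    ses = []
    for c in range(C):
        w = post[inverse, c]
        _, _, _, hess, _, _ = _newton_clogit(dx_s, y_s, weights=w, tol=1e-8, max_iter=50)
        try:
            ses.append(np.sqrt(np.clip(np.diag(np.linalg.inv(-hess)), 0, np.inf)))
        except np.linalg.LinAlgError:
            ses.append(np.full(K, np.nan))

    k_params = C * K + (C - 1)
    names = [f"class_{c + 1}" for c in range(C)]
    return LCMResult(
        class_coefs=pd.DataFrame(np.column_stack(betas), index=columns, columns=names),
        class_ses=pd.DataFrame(np.column_stack(ses), index=columns, columns=names),
        shares=shares,
        loglik=best["ll"],
        aic=2 * k_params - 2 * best["ll"],
        posterior=pd.DataFrame(post, index=uniq, columns=names),
        n_classes=C,
        converged=best["converged"],
        loglik_trace=best["trace"],
    )


def select_classes(
    dataset: ChoiceDataset,
    schema: AttributeSchema | None = None,
    C_range=(1, 2, 3, 4),
    seed: int = 0,
    n_starts: int = 3,
    **kwargs,
):
    """Fit each class count and choose the AIC minimiser.

    Returns ``(table, chosen_C, fits)`` where table has one row per C with
    log-likelihood, AIC and convergence flag.
    """
    if not len(C_range):
        raise ValueError("C_range must be nonempty")
    rows, fits = [], {}
    for C in C_range:
        fit = fit_lcm(dataset, schema, C=C, n_starts=n_starts, seed=seed, **kwargs)
        fits[C] = fit
        rows.append(
            {"C": C, "loglik": fit.loglik, "aic": fit.aic, "converged": fit.converged}
        )
    table = pd.DataFrame(rows)
    chosen = int(table.loc[table["aic"].idxmin(), "C"])
    return table, chosen, fits


# ---------------------------------------------------------------------------
# Attribute x covariate interactions


@dataclass
class InteractionResult:
    """Conditional logit with attribute x respondent-dummy interactions."""

    base: pd.Series
    interactions: pd.Series
    se: pd.Series
    cov: pd.DataFrame
    loglik: float
    n_observations: int
    converged: bool

    @property
    def coefficients(self) -> pd.Series:
        return pd.concat([self.base, self.interactions])

    def wald(self) -> pd.DataFrame:
        from scipy.stats import norm

        coefs = self.coefficients
        z = coefs / self.se
        return pd.DataFrame({"coef": coefs, "se": self.se, "z": z, "p": 2 * norm.sf(np.abs(z))})


def fit_interactions(
    dataset: ChoiceDataset,
    schema: AttributeSchema | None = None,
    interaction_spec: tuple = (),
    tol: float = 1e-6,
    max_iter: int = 100,
) -> InteractionResult:
    """Conditional logit with attribute x covariate-dummy interactions.

    ``interaction_spec`` is a sequence of ``(encoded_column, dummy)`` with
    dummy in {"male", "young"}; each adds a column dx_attr * dummy_resp.
    Collinear interaction columns raise, naming the offending columns.
    """
    from .simulate import covariate_dummy

    schema = schema or dataset.schema
    columns = list(schema.encoded_columns)
    dx, y, resp = paired_differences(dataset, schema)
    cov_table = respondent_covariates(dataset)
    extra, extra_names = [], []
    for col, dummy_name in interaction_spec:
        dummy = covariate_dummy(cov_table, dummy_name)
        d = dummy.reindex(resp).to_numpy()
        extra.append(dx[:, columns.index(col)] * d)
        extra_names.append(f"{col}_x_{dummy_name}")
    X = np.column_stack([dx] + extra) if extra else dx
    all_names = columns + extra_names
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"collinear design matrix with interaction columns {extra_names}"
        )
    fit = _fit_clogit_arrays(X, y, all_names, tol=tol, max_iter=max_iter)
    return InteractionResult(
        base=fit.coefficients[columns],
        interactions=fit.coefficients[extra_names],
        se=fit.se,
        cov=fit.cov,
        loglik=fit.loglik,
        n_observations=fit.n_observations,
        converged=fit.converged,
    )
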