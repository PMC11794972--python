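"""REML estimation of variance components with structured random effects.

The model is the standard animal-model form

    y = X beta + sum_k Z_k u_k + e,
    u_k ~ N(0, K_k sigma2_k),   e ~ N(0, I sigma2_e),

where each random term k groups observations into levels (individual
identity, logger, natal section, brood, ...) and K_k is an optional
covariance over levels — the additive relationship matrix A for the
genetic term, a spatial-proximity or environmental-similarity matrix for
the natal terms, or the identity when absent.

Estimation maximises the restricted likelihood by average-information
(AI) updates with expectation-maximisation fallback and step halving;
components are constrained non-negative and pinned at zero when the
likelihood pushes them onto the boundary (their standard errors are then
reported as unavailable). Each structured term is transformed through a
factor L_k of K_k (Cholesky, or eigenvalue square root for singular K)
so that every solve uses identity-structured levels; with n observations
and q total levels all per-iteration algebra is O(q^3 + n q), never
O(n^2).

Derived quantities: variance ratios (repeatability V_ID/V_P or
(V_ID+V_A)/V_P, narrow-sense heritability h2 = V_A/V_P) with
delta-method standard errors, and likelihood-ratio tests between nested
fits against a chi-square with one degree of freedom (optionally the
boundary-corrected half-half mixture).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.linalg import blas as _blas, lapack as _lapack
from scipy.stats import chi2

__all__ = [
    "RandomTerm",
    "ModelSpec",
    "REMLOptions",
    "FitResult",
    "RatioEstimate",
    "reml_fit",
    "variance_ratios",
    "lrt",
    "model_spec_from_config",
]

RESIDUAL = "R"


@dataclass
class RandomTerm:
    """A random effect: a grouping column plus an optional level covariance.

    ``covariance`` is any object with ``ids`` and ``values`` attributes
    (an AMatrix or SimilarityMatrix) covering every level appearing in
    the data; ``None`` means i.i.d. levels (identity covariance).
    """

    name: str
    column: str
    covariance: object | None = None


@dataclass
class ModelSpec:
    response: str
    fixed: list[str] = field(default_factory=list)
    random: list[RandomTerm] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [t.name for t in self.random]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicated random term names: {names}")
        if RESIDUAL in names:
            raise ValueError(f"term name {RESIDUAL!r} is reserved for the residual")


@dataclass
class REMLOptions:
    max_iter: int = 200
    tol_loglik: float = 1e-8
    tol_param: float = 1e-7  # max relative component change
    pin_tol: float = 1e-6  # pin components below pin_tol * V_scale
    max_halvings: int = 30
    verbose: bool = False


@dataclass
class FitResult:
    """REML variance components and everything needed for inference."""

    components: dict[str, float]  # term name -> variance, incl. residual "R"
    se: dict[str, float]  # NaN where unavailable (pinned terms)
    loglik_reml: float
    converged: bool
    n_iter: int
    boundary: set[str]
    n_obs: int
    n_fixed: int
    response: str
    fixed: tuple[str, ...]
    random_names: tuple[str, ...]
    beta: np.ndarray | None = None
    fixed_labels: tuple[str, ...] = ()
    component_cov: pd.DataFrame | None = None  # AI-based covariance of estimates

    @property
    def vp(self) -> float:
        """Total phenotypic variance: the sum of all fitted components."""
        return float(sum(self.components.values()))

    def proportions(self) -> dict[str, float]:
        vp = self.vp
        return {k: v / vp for k, v in self.components.items()}


@dataclass
class RatioEstimate:
    value: float
    se: float
    numerator: tuple[str, ...]
    label: str


# ---------------------------------------------------------------------------
# design construction


def _build_fixed(data: pd.DataFrame, fixed: list[str]) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept; categoricals one-hot (drop first),
    aliased columns dropped with a warning."""
    cols = [np.ones(len(data))]
    names = ["(intercept)"]
    for f in fixed:
        s = data[f]
        if pd.api.types.is_numeric_dtype(s) and not isinstance(
            s.dtype, pd.CategoricalDtype
        ):
            cols.append(s.to_numpy(float))
            names.append(f)
        else:
            levels = pd.unique(s.astype(str))
            for lev in sorted(levels)[1:]:
                cols.append((s.astype(str) == lev).to_numpy(float))
                names.append(f"{f}[{lev}]")
    X = np.column_stack(cols)
    # drop aliased columns by pivoted QR
    _, Rq, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(Rq))
    rank = int(np.sum(diag > diag.max() * len(data) * np.finfo(float).eps))
    if rank < X.shape[1]:
        keep = np.sort(piv[:rank])
        dropped = [names[i] for i in range(X.shape[1]) if i not in set(keep)]
        warnings.warn(f"dropping aliased fixed-effect columns: {dropped}", stacklevel=3)
        X = X[:, keep]
        names = [names[i] for i in keep]
    return X, names


class _TermDesign:
    """Per-term level coding and covariance factor."""

    def __init__(self, term: RandomTerm, data: pd.DataFrame):
        self.name = term.name
        codes, levels = pd.factorize(data[term.column], sort=True)
        if (codes < 0).any():
            raise ValueError(f"term {term.name!r}: missing level values")
        self.levels = list(levels)
        self.q = len(levels)
        if self.q < 2:
            raise ValueError(f"term {term.name!r} has fewer than 2 levels")
        self.L: np.ndarray | None = None
        if term.covariance is not None:
            cov = term.covariance
            cov_index = {v: i for i, v in enumerate(cov.ids)}
            missing = [lv for lv in self.levels if lv not in cov_index]
            if missing:
                raise ValueError(
                    f"term {term.name!r}: {len(missing)} levels missing from "
                    f"its covariance (e.g. {missing[:5]})"
                )
            ix = [cov_index[lv] for lv in self.levels]
            K = np.asarray(cov.values)[np.ix_(ix, ix)]
            self.L = _factor_cov(K, term.name)
        self.idx = codes.astype(np.int64)

    def zt(self, v: np.ndarray) -> np.ndarray:
        """Z_tilde^T v for an n-vector (or n x m matrix) v."""
        if v.ndim == 1:
            c = np.bincount(self.idx, weights=v, minlength=self.q)
        else:
            c = np.zeros((self.q, v.shape[1]))
            np.add.at(c, self.idx, v)
        return c if self.L is None else self.L.T @ c

    def z(self, u: np.ndarray) -> np.ndarray:
        """Z_tilde u expanded to observation space."""
        lu = u if self.L is None else self.L @ u
        return lu[self.idx]


def _factor_cov(K: np.ndarray, name: str) -> np.ndarray:
    """Factor L with L L^T = K; Cholesky, eigen square root if semi-definite."""
    K = 0.5 * (K + K.T)
    try:
        return np.linalg.cholesky(K)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(K)
        if w[0] < -1e-6 * max(w[-1], 1.0):
            raise ValueError(
                f"covariance for term {name!r} is not positive semi-definite "
                f"(min eigenvalue {w[0]:.3g}); repair it first"
            ) from None
        return V * np.sqrt(np.clip(w, 0.0, None))


class _Workspace:
    """Sufficient statistics in level space, shared across iterations."""

    def __init__(self, y, X, terms: list[_TermDesign]):
        self.y, self.X, self.terms = y, X, terms
        self.n, self.p = X.shape
        self.qs = [t.q for t in terms]
        offs = np.concatenate([[0], np.cumsum(self.qs)]).astype(int)
        self.blocks = [slice(offs[i], offs[i + 1]) for i in range(len(terms))]
        self.q = int(offs[-1])
        self.ZtZ = np.empty((self.q, self.q))
        for i, ti in enumerate(terms):
            for j, tj in enumerate(terms):
                if j < i:
                    continue
                N = np.zeros((ti.q, tj.q))
                np.add.at(N, (ti.idx, tj.idx), 1.0)
                if ti.L is not None:
                    N = ti.L.T @ N
                if tj.L is not None:
                    N = N @ tj.L
                self.ZtZ[self.blocks[i], self.blocks[j]] = N
                if j > i:
                    self.ZtZ[self.blocks[j], self.blocks[i]] = N.T
        self.ZtX = np.vstack([t.zt(X) for t in terms]) if terms else np.zeros((0, self.p))
        self.Zty = (
            np.concatenate([t.zt(y) for t in terms]) if terms else np.zeros(0)
        )
        self.XtX = X.T @ X
        self.Xty = X.T @ y

    def expand(self, u: np.ndarray, active: list[int]) -> np.ndarray:
        """Z_tilde u for a stacked active-blocks vector, in observation space."""
        out = np.zeros(self.n if u.ndim == 1 else (self.n, u.shape[1]))
        off = 0
        for i in active:
            t = self.terms[i]
            out += t.z(u[off : off + t.q])
            off += t.q
        return out

    def active_ix(self, active: list[int]) -> np.ndarray:
        return np.concatenate(
            [np.arange(self.blocks[i].start, self.blocks[i].stop) for i in active]
        )


def _cho_solve(Lc: np.ndarray, b: np.ndarray) -> np.ndarray:
    return sla.cho_solve((Lc, True), b, check_finite=False)


@dataclass
class _State:
    loglik: float
    beta: np.ndarray
    grad: np.ndarray  # active terms then residual
    AI: np.ndarray
    tr_PVk: np.ndarray
    yPVkPy: np.ndarray
    tr_P: float
    wPw: float


def _evaluate(ws: _Workspace, active: list[int], sig: np.ndarray, se: float) -> _State:
    """One REML evaluation: restricted log-likelihood, gradient and AI matrix."""
    n, p, X, y = ws.n, ws.p, ws.X, ws.y
    K = len(active)
    ix = ws.active_ix(active) if K else np.empty(0, dtype=int)
    qs = [ws.qs[i] for i in active]
    ZtZ = ws.ZtZ[np.ix_(ix, ix)] if K else np.zeros((0, 0))
    ZtX = ws.ZtX[ix] if K else np.zeros((0, p))
    Zty = ws.Zty[ix] if K else np.zeros(0)
    q = len(ix)
    blocks = []
    off = 0
    for m in qs:
        blocks.append(slice(off, off + m))
        off += m

    dinv = np.concatenate([np.full(m, 1.0 / s) for m, s in zip(qs, sig)]) if K else np.zeros(0)
    C = ZtZ / se
    if q:
        C[np.diag_indices(q)] += dinv
        Lc = sla.cholesky(C, lower=True, check_finite=False)
        logdetC = 2.0 * np.sum(np.log(np.diag(Lc)))
        CiZtX = _cho_solve(Lc, ZtX)
        CiZty = _cho_solve(Lc, Zty)
    else:
        Lc = np.zeros((0, 0))
        logdetC = 0.0
        CiZtX, CiZty = np.zeros((0, p)), np.zeros(0)

    XtVinvX = (ws.XtX - ZtX.T @ CiZtX / se) / se
    XtVinvy = (ws.Xty - ZtX.T @ CiZty / se) / se
    cf_x = sla.cho_factor(XtVinvX, check_finite=False)
    beta = sla.cho_solve(cf_x, XtVinvy, check_finite=False)
    sign, logdetXVX = np.linalg.slogdet(XtVinvX)

    r = y - X @ beta
    Ztr = Zty - ZtX @ beta
    a = _cho_solve(Lc, Ztr) if q else np.zeros(0)
    w = (r - ws.expand(a, active) / se) / se if q else r / se  # w = P y
    yPy = float(r @ w)

    logdetV = n * np.log(se) + logdetC + sum(
        m * np.log(s) for m, s in zip(qs, sig)
    )
    loglik = -0.5 * (logdetV + logdetXVX + yPy + (n - p) * np.log(2 * np.pi))

    # --- traces -----------------------------------------------------------
    if q:
        Lci, info = _lapack.dtrtri(Lc, lower=1)
        if info != 0:
            raise np.linalg.LinAlgError("triangular inversion failed")
        U = _blas.dtrmm(1.0, Lci, ZtZ, lower=1)  # (ZtZ C^-1 ZtZ) = U^T U
        diag_Ci = np.sum(Lci**2, axis=0)
        F = (ZtX - ZtZ @ CiZtX / se) / se  # Z~' V^-1 X
        S = sla.cho_solve(cf_x, F.T, check_finite=False)  # (X'V^-1X)^-1 F'
    tr_PVk = np.empty(K)
    yPVkPy = np.empty(K)
    ts = []
    for kk, i in enumerate(active):
        b = blocks[kk]
        t_k = ws.terms[i].zt(w)
        ts.append(t_k)
        yPVkPy[kk] = float(t_k @ t_k)
        trM = (np.trace(ZtZ[b, b]) - np.sum(U[:, b] ** 2) / se) / se
        trH = float(np.sum(F[b] * S[:, b].T))
        tr_PVk[kk] = trM - trH
    # residual
    Vx = (X - ws.expand(CiZtX, active) / se) / se if q else X / se  # V^-1 X
    tr_Vinv = n / se - (se * (q - float(diag_Ci @ dinv))) / se**2 if q else n / se
    tr_P = tr_Vinv - float(np.trace(sla.cho_solve(cf_x, Vx.T @ Vx)))

    # --- average information ---------------------------------------------
    cols = [ws.terms[i].z(ts[kk]) for kk, i in enumerate(active)] + [w]
    W = np.column_stack(cols)  # n x (K+1), columns V_k P y
    ZtW = np.vstack([ws.terms[i].zt(W) for i in active]) if K else np.zeros((0, K + 1))
    CiZtW = _cho_solve(Lc, ZtW) if q else ZtW
    ViW = (W - ws.expand(CiZtW, active) / se) / se if q else W / se
    XtViW = X.T @ ViW
    PW = ViW - Vx @ sla.cho_solve(cf_x, XtViW, check_finite=False)
    AI = 0.5 * (W.T @ PW)
    AI = 0.5 * (AI + AI.T)
    wPw = float(w @ w)  # y' P V_R P y with V_R = I

    grad = np.empty(K + 1)
    grad[:K] = -0.5 * (tr_PVk - yPVkPy)
    grad[K] = -0.5 * (tr_P - wPw)
    return _State(loglik, beta, grad, AI, tr_PVk, yPVkPy, tr_P, wPw)


def _loglik_only(ws, active, sig, se) -> float:
    """Cheap restricted log-likelihood for step-halving line search."""
    n, p, X, y = ws.n, ws.p, ws.X, ws.y
    K = len(active)
    ix = ws.active_ix(active) if K else np.empty(0, dtype=int)
    qs = [ws.qs[i] for i in active]
    ZtZ = ws.ZtZ[np.ix_(ix, ix)] if K else np.zeros((0, 0))
    ZtX = ws.ZtX[ix] if K else np.zeros((0, p))
    Zty = ws.Zty[ix] if K else np.zeros(0)
    q = len(ix)
    dinv = np.concatenate([np.full(m, 1.0 / s) for m, s in zip(qs, sig)]) if K else np.zeros(0)
    C = ZtZ / se
    if q:
        C[np.diag_indices(q)] += dinv
        Lc = sla.cholesky(C, lower=True, check_finite=False)
        logdetC = 2.0 * np.sum(np.log(np.diag(Lc)))
        CiZtX = _cho_solve(Lc, ZtX)
        CiZty = _cho_solve(Lc, Zty)
    else:
        logdetC, CiZtX, CiZty = 0.0, np.zeros((0, p)), np.zeros(0)
    XtVinvX = (ws.XtX - ZtX.T @ CiZtX / se) / se
    XtVinvy = (ws.Xty - ZtX.T @ CiZty / se) / se
    cf_x = sla.cho_factor(XtVinvX, check_finite=False)
    beta = sla.cho_solve(cf_x, XtVinvy, check_finite=False)
    _, logdetXVX = np.linalg.slogdet(XtVinvX)
    r = y - X @ beta
    Ztr = Zty - ZtX @ beta
    a = _cho_solve(Lc, Ztr) if q else np.zeros(0)
    w = (r - ws.expand(a, active) / se) / se if q else r / se
    yPy = float(r @ w)
    logdetV = n * np.log(se) + logdetC + sum(m * np.log(s) for m, s in zip(qs, sig))
    return -0.5 * (logdetV + logdetXVX + yPy + (n - p) * np.log(2 * np.pi))


def reml_fit(
    data: pd.DataFrame, spec: ModelSpec, options: REMLOptions | None = None
) -> FitResult:
    """Fit a variance-component model by AI-REML.

    Starting values split the raw phenotypic variance (after an ordinary
    least-squares fit of the fixed effects) equally over the random terms
    and the residual. The first update is an EM step; subsequent steps
    use the average-information direction with step halving, falling back
    to EM when the AI step cannot improve the restricted likelihood.
    Components pushed to the boundary are pinned at zero, recorded in
    ``boundary`` and excluded from further updates.
    """
    opt = options or REMLOptions()
    y = data[spec.response].to_numpy(float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    X, fixed_labels = _build_fixed(data, spec.fixed)
    n, p = X.shape
    terms = [_TermDesign(t, data) for t in spec.random]
    names = [t.name for t in terms]

    # raw scale from OLS residuals
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid0 = y - X @ beta0
    vscale = float(resid0 @ resid0) / max(n - p, 1)
    if vscale <= 0:
        vscale = max(float(np.var(y)), 1e-12)

    if not terms:
        # closed form: REML residual variance is RSS / (n - p)
        se2 = vscale
        ll = _loglik_only(_Workspace(y, X, []), [], np.empty(0), se2)
        comp = {RESIDUAL: se2}
        se_map = {RESIDUAL: float(np.sqrt(2.0 * se2**2 / (n - p)))}
        cov = pd.DataFrame([[2.0 * se2**2 / (n - p)]], index=[RESIDUAL], columns=[RESIDUAL])
        return FitResult(
            comp, se_map, ll, True, 0, set(), n, p, spec.response,
            tuple(spec.fixed), (), beta0, tuple(fixed_labels), cov,
        )

    ws = _Workspace(y, X, terms)
    K = len(terms)
    sig = np.full(K, vscale / (K + 1))
    se2 = vscale / (K + 1)
    active = list(range(K))
    floor = 1e-8 * vscale  # boundary clamp; components may climb back up
    pin_at = opt.pin_tol * vscale

    state = _evaluate(ws, active, sig, se2)
    n_iter = 0
    converged = False
    still_count = 0
    for n_iter in range(1, opt.max_iter + 1):
        theta = np.concatenate([sig, [se2]])
        # proposed step: EM on the first iteration, AI after
        if n_iter == 1:
            new_sig, new_se = _em_step(ws, active, sig, se2, state)
            cand = np.concatenate([new_sig, [new_se]])
        else:
            try:
                delta = np.linalg.solve(state.AI, state.grad)
            except np.linalg.LinAlgError:
                delta = None
            cand = None
            if delta is not None and np.all(np.isfinite(delta)):
                frac = 1.0
                for _ in range(opt.max_halvings):
                    trial = np.maximum(theta + frac * delta, floor)
                    ll_t = _safe_loglik(ws, active, trial[:-1], trial[-1])
                    if ll_t is not None and ll_t >= state.loglik - 1e-10:
                        cand = trial
                        break
                    frac *= 0.5
            if cand is None:
                new_sig, new_se = _em_step(ws, active, sig, se2, state)
                cand = np.concatenate([new_sig, [new_se]])

        cand = np.maximum(cand, floor)
        rel_change = np.max(np.abs(cand - theta) / np.maximum(theta, 1e-3 * vscale))
        sig, se2 = cand[:-1], float(cand[-1])

        new_state = _evaluate(ws, active, sig, se2)
        dll = new_state.loglik - state.loglik
        if opt.verbose:
            print(
                f"iter {n_iter}: loglik {new_state.loglik:.8f} "
                f"(d={dll:.2e}, rel={rel_change:.2e}) sig={sig} se={se2:.6g}"
            )
        state = new_state
        # require stationarity on two consecutive iterations so that a
        # single heavily damped line-search step cannot fake convergence
        if abs(dll) < opt.tol_loglik and rel_change < opt.tol_param:
            if still_count >= 1:
                converged = True
                break
            still_count += 1
        else:
            still_count = 0

    if not converged:
        warnings.warn(
            f"REML did not converge in {opt.max_iter} iterations "
            f"(last |dloglik| tolerance not met)",
            stacklevel=2,
        )

    # boundary components: declared zero after convergence, excluded from
    # the information matrix used for the standard errors
    pinned = {names[i] for i in range(K) if sig[i] < pin_at}
    if pinned:
        sig = np.where(sig < pin_at, 0.0, sig)
        active = [i for i in range(K) if names[i] not in pinned]
        state = _evaluate(ws, active, sig[active], se2)

    components = {nm: float(sig[i]) for i, nm in enumerate(names)}
    components[RESIDUAL] = float(se2)

    # SEs and estimate covariance from the inverse AI at the optimum
    order = [names[i] for i in active] + [RESIDUAL]
    se_map = {nm: float("nan") for nm in names}
    cov_full = pd.DataFrame(
        0.0, index=names + [RESIDUAL], columns=names + [RESIDUAL]
    )
    try:
        AIinv = np.linalg.inv(state.AI)
        for a_i, nm in enumerate(order):
            se_map[nm] = float(np.sqrt(max(AIinv[a_i, a_i], 0.0)))
        cov_full.loc[order, order] = AIinv
    except np.linalg.LinAlgError:
        se_map[RESIDUAL] = float("nan")

    return FitResult(
        components=components,
        se=se_map,
        loglik_reml=float(state.loglik),
        converged=converged,
        n_iter=n_iter,
        boundary=pinned,
        n_obs=n,
        n_fixed=p,
        response=spec.response,
        fixed=tuple(spec.fixed),
        random_names=tuple(names),
        beta=state.beta,
        fixed_labels=tuple(fixed_labels),
        component_cov=cov_full,
    )


def _em_step(ws, active, sig_a, se2, state: _State):
    """Expectation-maximisation update (monotone in the restricted likelihood)."""
    qs = np.array([ws.qs[i] for i in active], dtype=float)
    new_sig = sig_a + sig_a**2 * (state.yPVkPy - state.tr_PVk) / qs
    new_se = se2 + se2**2 * (state.wPw - state.tr_P) / ws.n
    return np.maximum(new_sig, 0.0), max(new_se, 1e-12 * (se2 + sig_a.sum()))


def _safe_loglik(ws, active, sig, se):
    if se <= 0 or np.any(sig < 0):
        return None
    try:
        return _loglik_only(ws, active, sig, se)
    except np.linalg.LinAlgError:
        return None


def variance_ratios(
    fit: FitResult, numerator: set[str] | tuple[str, ...], label: str = "proportion"
) -> RatioEstimate:
    """Ratio of a subset of variance components to the total V_P.

    With numerator {ID} (or {ID, A} in an animal model) this is the
    repeatability; with {A} it is the narrow-sense heritability h2. The
    standard error is by the delta method from the AI-based covariance of
    the component estimates.
    """
    numerator = tuple(numerator)
    if not numerator:
        raise ValueError("empty numerator term set")
    unknown = set(numerator) - set(fit.components)
    if unknown:
        raise ValueError(f"terms not in fit: {sorted(unknown)}")
    s_num = sum(fit.components[t] for t in numerator)
    s_tot = fit.vp
    value = s_num / s_tot
    se = float("nan")
    if fit.component_cov is not None:
        names = list(fit.component_cov.index)
        d = np.array(
            [
                (s_tot - s_num) / s_tot**2
                if nm in numerator
                else -s_num / s_tot**2
                for nm in names
            ]
        )
        var = float(d @ fit.component_cov.to_numpy() @ d)
        se = float(np.sqrt(max(var, 0.0)))
    return RatioEstimate(float(value), se, numerator, label)


def model_spec_from_config(path) -> ModelSpec:
    """Load a :class:`ModelSpec` from a YAML/JSON model configuration.

    Expected structure::

        response: group_size
        fixed: [winter]
        random:
          - {name: ID, column: individual}
          - {name: A, column: individual, covariance: amatrix.csv}

    Covariance paths (relative to the config file) point to square CSVs
    with the level ids as header row and first column.
    """
    import yaml

    cfg_path = Path(path)
    with open(cfg_path) as fh:
        cfg = yaml.safe_load(fh)
    terms = []
    for t in cfg.get("random", []):
        cov = None
        if t.get("covariance"):
            cov_path = cfg_path.parent / t["covariance"]
            df = pd.read_csv(cov_path, index_col=0, comment="#")
            cov = _LoadedCov(list(df.index.astype(str)), df.to_numpy(float))
        terms.append(RandomTerm(t["name"], t["column"], covariance=cov))
    return ModelSpec(cfg["response"], list(cfg.get("fixed", [])), terms)


@dataclass
class _LoadedCov:
    ids: list
    values: np.ndarray


def lrt(full: FitResult, reduced: FitResult, mixture: bool = False):
    """Likelihood-ratio test of nested REML fits.

    The statistic 2 (l_full - l_reduced) (floored at zero) is referred to
    a chi-square with 1 degree of freedom; ``mixture=True`` applies the
    half-half boundary correction (halving the p-value), appropriate when
    testing a single variance component against zero.
    """
    if not set(reduced.random_names) <= set(full.random_names):
        raise ValueError(
            "models are not nested: reduced random terms "
            f"{reduced.random_names} not a subset of {full.random_names}"
        )
    if (
        reduced.n_obs != full.n_obs
        or reduced.fixed != full.fixed
        or reduced.response != full.response
    ):
        raise ValueError("models must share data, response and fixed effects")
    stat = max(0.0, 2.0 * (full.loglik_reml - reduced.loglik_reml))
    p = float(chi2.sf(stat, df=1))
    if mixture:
        p = p / 2.0 if stat > 0 else 1.0
    return stat, p
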