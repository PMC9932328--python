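"""Robust linear and beta mixed models with nested random intercepts.

The lobar analyses model one endpoint per row of a subject x region x visit
table with fixed effects (age, severe air trapping A3, visit dummies, or a
baseline endpoint) and two nested random intercepts: one per patient and one
per lung region within patient. Regions are repeated measurements *of a
patient*, hence region-within-patient rather than a crossed region effect.

Two families are provided:

* ``linear`` — Gaussian responses, fitted by REML. The profiled restricted
  log-likelihood is maximized over the log standard deviations
  (patient, region-within-patient, residual) by a derivative-free simplex
  search; fixed effects follow by GLS. The *robust* variant iterates Huber
  weights (c = 1.345) on marginally standardized residuals, downweighting
  outlying observations in the residual covariance, until the weights
  stabilize.
* ``beta`` — responses in (0, 1) with a logit link and Beta(mu*phi,
  (1-mu)*phi) likelihood. Random intercepts are integrated out by a Laplace
  approximation; the inner penalized likelihood is maximized jointly over
  fixed effects and random-effect modes by Fisher-scoring Newton steps, and
  the outer profile over (log phi, log sd_patient, log sd_region) by simplex
  search. The robust variant Huber-weights each observation's log-likelihood
  contribution by its Pearson residual.

Wald standard errors, 95% CIs and two-sided normal P-values are reported
for the fixed effects; variance components at the search boundary are
flagged rather than silently truncated, and non-convergence raises.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

HUBER_C = 1.345
_Z975 = 1.959963984540054


class ConvergenceError(RuntimeError):
    pass


@dataclass
class MixedModelFit:
    """Fixed-effect table, variance components and diagnostics of one fit."""

    params: pd.DataFrame            # index=term; estimate, se, ci_low, ci_high, p
    variance_components: dict[str, float]
    family: str
    robust: bool
    formula: str
    n_obs: int
    n_patients: int
    converged: bool = True
    boundary: list[str] = field(default_factory=list)
    scale_note: str = ""
    loglik: float | None = None
    theta: np.ndarray | None = None   # internal optimizer state, reusable as a warm start

    def estimate(self, term: str) -> float:
        return float(self.params.loc[term, "estimate"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.params.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])

    def to_report(self) -> dict:
        return {
            "formula": self.formula,
            "family": self.family,
            "robust": self.robust,
            "scale_note": self.scale_note,
            "n_obs": self.n_obs,
            "n_patients": self.n_patients,
            "converged": self.converged,
            "boundary": self.boundary,
            "variance_components": {k: float(v) for k, v in self.variance_components.items()},
            "fixed_effects": {
                term: {k: float(v) for k, v in row.items()}
                for term, row in self.params.iterrows()
            },
        }


def _wald_table(names, beta, cov) -> pd.DataFrame:
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "estimate": beta,
            "se": se,
            "ci_low": beta - _Z975 * se,
            "ci_high": beta + _Z975 * se,
            "p": p,
        },
        index=list(names),
    )


def _group_structures(patient, region):
    """Row index lists per patient and region-within-patient design columns."""
    patient = np.asarray(patient)
    patients, pat_idx = np.unique(patient, return_inverse=True)
    blocks = [np.where(pat_idx == g)[0] for g in range(len(patients))]
    if region is None:
        return patients, blocks, None
    region = np.asarray(region)
    bmats = []
    for rows in blocks:
        regs, ridx = np.unique(region[rows], return_inverse=True)
        B = np.zeros((len(rows), len(regs)))
        B[np.arange(len(rows)), ridx] = 1.0
        bmats.append(B)
    return patients, blocks, bmats


# ---------------------------------------------------------------------------
# Linear family (REML, optional Huber weights)
# ---------------------------------------------------------------------------

class _LMMWork:
    def __init__(self, y, X, patient, region, weights):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        self.patients, self.blocks, self.bmats = _group_structures(patient, region)
        self.has_region = region is not None
        self.w = np.ones(self.n) if weights is None else np.asarray(weights, float)

    def _block_cov(self, i, sp2, sr2, se2):
        rows = self.blocks[i]
        ni = len(rows)
        V = np.full((ni, ni), sp2)
        if self.has_region:
            B = self.bmats[i]
            V = V + sr2 * (B @ B.T)
        V[np.diag_indices(ni)] += se2 / self.w[rows]
        return rows, V

    def reml_pieces(self, sp2, sr2, se2):
        """(neg2-REML without constants, beta, cov_beta) at the given variances.

        Blocks of equal size are factorized in one batched Cholesky call.
        """
        sizes = {len(rows) for rows in self.blocks}
        if len(sizes) == 1:
            ni = sizes.pop()
            rows = np.stack(self.blocks)                       # (m, ni)
            V = np.full((len(rows), ni, ni), sp2)
            if self.has_region:
                B = np.stack(self.bmats)                       # (m, ni, q)
                V += sr2 * np.einsum("mik,mjk->mij", B, B)
            idx = np.arange(ni)
            V[:, idx, idx] += se2 / self.w[rows]
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return None
            logdet = 2.0 * float(np.sum(np.log(np.diagonal(L, axis1=1, axis2=2))))
            Xs = self.X[rows]                                  # (m, ni, p)
            ys = self.y[rows][:, :, None]                      # (m, ni, 1)
            sX = np.linalg.solve(L, Xs)
            sy = np.linalg.solve(L, ys)[:, :, 0]
            XtVX = np.einsum("mip,miq->pq", sX, sX)
            XtVy = np.einsum("mip,mi->p", sX, sy)
            ytVy = float(np.sum(sy * sy))
        else:
            XtVX = np.zeros((self.p, self.p))
            XtVy = np.zeros(self.p)
            ytVy = 0.0
            logdet = 0.0
            for i in range(len(self.blocks)):
                rws, V = self._block_cov(i, sp2, sr2, se2)
                try:
                    L = np.linalg.cholesky(V)
                except np.linalg.LinAlgError:
                    return None
                logdet += 2.0 * float(np.sum(np.log(np.diag(L))))
                sX = np.linalg.solve(L, self.X[rws])
                sy = np.linalg.solve(L, self.y[rws])
                XtVX += sX.T @ sX
                XtVy += sX.T @ sy
                ytVy += float(sy @ sy)
        sign, logdet_xtvx = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return None
        beta = np.linalg.solve(XtVX, XtVy)
        quad = ytVy - float(beta @ XtVy)
        neg2 = logdet + logdet_xtvx + quad
        return neg2, beta, np.linalg.inv(XtVX)

    def neg2reml(self, logsd):
        sds = np.exp(logsd)
        if self.has_region:
            sp2, sr2, se2 = sds[0] ** 2, sds[1] ** 2, sds[2] ** 2
        else:
            sp2, sr2, se2 = sds[0] ** 2, 0.0, sds[1] ** 2
        pieces = self.reml_pieces(sp2, sr2, se2)
        return np.inf if pieces is None else pieces[0]


def fit_linear_mixed(
    y,
    X: pd.DataFrame,
    patient,
    region=None,
    robust: bool = False,
    huber_c: float = HUBER_C,
    weights=None,
    formula: str = "",
    max_robust_iter: int = 30,
    theta_start=None,
) -> MixedModelFit:
    """Random-intercept LMM by REML with an optional Huber-weighted variant.

    ``X`` must already contain the intercept column. ``region`` adds a
    region-within-patient intercept. With ``robust=True`` the fit is
    iterated: residuals are standardized by their marginal standard
    deviation, Huber weights w = min(1, c/|r|) enter the residual variance
    as sigma_e^2 / w, and the REML fit is repeated until the weights move by
    less than 1e-4.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(np.shape(X)[1])]
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    if ya.std() == 0:
        raise ValueError("endpoint has zero variance; nothing to model")
    if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")

    w = None if weights is None else np.asarray(weights, float)
    prev_w = np.ones(len(ya)) if w is None else w.copy()
    fit_state = None
    theta0 = theta_start
    for it in range(max_robust_iter if robust else 1):
        fit_state = _fit_lmm_once(ya, Xa, patient, region, prev_w, theta0)
        if not robust:
            break
        work, theta, beta, cov = fit_state
        theta0 = theta
        resid = ya - Xa @ beta
        sd = _marginal_sd(work, theta)
        r = resid / np.maximum(sd, 1e-12)
        new_w = np.minimum(1.0, huber_c / np.maximum(np.abs(r), 1e-12))
        if np.max(np.abs(new_w - prev_w)) < 1e-4:
            prev_w = new_w
            break
        prev_w = new_w
    else:
        if robust:
            # weights still moving after max_robust_iter: refit once more and accept
            fit_state = _fit_lmm_once(ya, Xa, patient, region, prev_w, theta0)

    work, theta, beta, cov = fit_state
    sds = np.exp(theta)
    if work.has_region:
        comps = {"sd_patient": sds[0], "sd_region_within_patient": sds[1], "sd_residual": sds[2]}
    else:
        comps = {"sd_patient": sds[0], "sd_residual": sds[1]}
    sd_y = float(ya.std())
    boundary = [k for k, v in comps.items() if v < 1e-4 * sd_y or v > 1e4 * sd_y]
    return MixedModelFit(
        params=_wald_table(names, beta, cov),
        variance_components=comps,
        family="linear",
        robust=robust,
        formula=formula,
        n_obs=len(ya),
        n_patients=len(work.patients),
        boundary=boundary,
        theta=np.asarray(theta),
    )


def _fit_lmm_once(y, X, patient, region, weights, theta0=None):
    work = _LMMWork(y, X, patient, region, weights)
    sd_y = max(float(np.std(y)), 1e-8)
    k = 3 if work.has_region else 2
    if theta0 is not None:
        starts = (np.asarray(theta0, float),)
    else:
        x0 = np.log(np.full(k, sd_y) * np.array([0.5, 0.4, 0.6][:k]))
        starts = (x0, x0 + np.log(0.2), np.log(np.full(k, sd_y * 0.8)))
    best = None
    for start in starts:
        res = optimize.minimize(
            work.neg2reml, start, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise ConvergenceError("REML optimization failed to find a finite objective")
    theta = best.x
    sds = np.exp(theta)
    if work.has_region:
        pieces = work.reml_pieces(sds[0] ** 2, sds[1] ** 2, sds[2] ** 2)
    else:
        pieces = work.reml_pieces(sds[0] ** 2, 0.0, sds[1] ** 2)
    if pieces is None:
        raise ConvergenceError("REML solution is numerically singular")
    _, beta, cov = pieces
    return work, theta, beta, cov


def _marginal_sd(work: _LMMWork, theta):
    sds = np.exp(theta)
    if work.has_region:
        sp2, sr2, se2 = sds[0] ** 2, sds[1] ** 2, sds[2] ** 2
    else:
        sp2, sr2, se2 = sds[0] ** 2, 0.0, sds[1] ** 2
    out = np.empty(work.n)
    for i, rows in enumerate(work.blocks):
        out[rows] = np.sqrt(sp2 + (sr2 if work.has_region else 0.0) + se2 / work.w[rows])
    return out


def gls_known_variance(y, X: pd.DataFrame, patient, region, sd_patient, sd_region, sd_resid):
    """GLS fixed effects with *known* variance components (oracle helper)."""
    work = _LMMWork(y, np.asarray(X, float), patient, region, None)
    pieces = work.reml_pieces(sd_patient**2, (sd_region or 0.0) ** 2, sd_resid**2)
    if pieces is None:
        raise ValueError("supplied variance components give a singular covariance")
    _, beta, cov = pieces
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    return beta if names is None else pd.Series(beta, index=names)


# ---------------------------------------------------------------------------
# Beta family (logit link, Laplace-approximated random intercepts)
# ---------------------------------------------------------------------------

def shrink_to_open_unit(y01, n: int | None = None) -> np.ndarray:
    """Map [0,1] data strictly inside (0,1): (y*(n-1)+0.5)/n."""
    y01 = np.asarray(y01, dtype=float)
    n = len(y01) if n is None else n
    return (y01 * (n - 1) + 0.5) / n


class _BetaWork:
    """Penalized beta-likelihood machinery exploiting the nested structure.

    Each patient's random effects (one intercept plus its region cells) form
    an independent (1+q)x(1+q) block of the penalized information, so Newton
    steps and the Laplace determinant are computed patient-by-patient via a
    Schur complement on the fixed effects, batched across patients.
    """

    def __init__(self, y, X, patient, region, weights):
        self.y = np.asarray(y, dtype=float)
        if np.any(self.y <= 0) or np.any(self.y >= 1):
            raise ValueError("beta family needs responses strictly inside (0,1); "
                             "apply shrink_to_open_unit first")
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        patient = np.asarray(patient)
        self.patients, self.pat_idx = np.unique(patient, return_inverse=True)
        self.q_p = len(self.patients)
        self.has_region = region is not None
        if self.has_region:
            region = np.asarray(region)
            _, reg_code = np.unique(region, return_inverse=True)
            key = self.pat_idx.astype(np.int64) * (reg_code.max() + 1) + reg_code
            cells, self.cell_idx = np.unique(key, return_inverse=True)
            self.cell_pat = (cells // (reg_code.max() + 1)).astype(int)
            self.q_r = len(cells)
            # cells of each patient, padded to a rectangular (m, qmax) layout
            cells_of = [np.where(self.cell_pat == g)[0] for g in range(self.q_p)]
            self.q_cell = max(len(c) for c in cells_of)
            self.cells_mat = np.zeros((self.q_p, self.q_cell), dtype=int)
            self.cells_mask = np.zeros((self.q_p, self.q_cell), dtype=bool)
            for g, c in enumerate(cells_of):
                self.cells_mat[g, : len(c)] = c
                self.cells_mask[g, : len(c)] = True
        else:
            self.q_r = 0
            self.q_cell = 0
        self.w = np.ones(self.n) if weights is None else np.asarray(weights, float)
        self.ystar = np.log(self.y / (1.0 - self.y))
        self.logy = np.log(self.y)
        self.log1my = np.log1p(-self.y)

    # -- likelihood pieces ---------------------------------------------------

    def eta(self, beta, up, ur):
        e = self.X @ beta + up[self.pat_idx]
        if self.has_region:
            e = e + ur[self.cell_idx]
        return e

    def loglik_terms(self, eta, phi):
        mu = special.expit(eta)
        mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
        a, b = mu * phi, (1.0 - mu) * phi
        ll = (special.gammaln(phi) - special.gammaln(a) - special.gammaln(b)
              + (a - 1.0) * self.logy + (b - 1.0) * self.log1my)
        mustar = special.digamma(a) - special.digamma(b)
        score_eta = phi * mu * (1.0 - mu) * (self.ystar - mustar)
        info_eta = (phi ** 2) * (mu * (1.0 - mu)) ** 2 * (
            special.polygamma(1, a) + special.polygamma(1, b)
        )
        return ll, score_eta, np.maximum(info_eta, 1e-10)

    def _pen_obj(self, beta, up, ur, phi, pp, pr):
        ll, _, _ = self.loglik_terms(self.eta(beta, up, ur), phi)
        pen = 0.5 * pp * float(up @ up)
        if self.has_region:
            pen += 0.5 * pr * float(ur @ ur)
        return float(np.sum(self.w * ll)) - pen

    def _blocks(self, W):
        """Stacked per-patient information blocks and fixed-effect couplings.

        Returns (Hb, Ub) with Hb (m, 1+q, 1+q) the u-blocks before prior
        precision, Ub (m, p, 1+q) the X-to-u couplings.
        """
        q = self.q_cell
        m = self.q_p
        sumW_p = np.bincount(self.pat_idx, weights=W, minlength=m)
        XtW_p = np.stack(
            [np.bincount(self.pat_idx, weights=W * self.X[:, j], minlength=m)
             for j in range(self.p)], axis=0)                    # (p, m)
        Hb = np.zeros((m, 1 + q, 1 + q))
        Ub = np.zeros((m, self.p, 1 + q))
        Hb[:, 0, 0] = sumW_p
        Ub[:, :, 0] = XtW_p.T
        if self.has_region:
            sumW_c = np.bincount(self.cell_idx, weights=W, minlength=self.q_r)
            XtW_c = np.stack(
                [np.bincount(self.cell_idx, weights=W * self.X[:, j], minlength=self.q_r)
                 for j in range(self.p)], axis=0)                # (p, q_r)
            diag = sumW_c[self.cells_mat] * self.cells_mask      # (m, q)
            idx = np.arange(q)
            Hb[:, 1 + idx, 1 + idx] = diag
            Hb[:, 0, 1:] = diag
            Hb[:, 1:, 0] = diag
            Ub[:, :, 1:] = XtW_c[:, self.cells_mat].transpose(1, 0, 2) * self.cells_mask[:, None, :]
        return Hb, Ub

    def inner_newton(self, phi, sp, sr, start=None, max_iter=50, tol=1e-9):
        """Joint (beta, u) maximization by Fisher-scoring with Schur solves."""
        pp = 1.0 / max(sp, 1e-8) ** 2
        pr = 1.0 / max(sr, 1e-8) ** 2
        if start is None:
            beta = np.zeros(self.p)
            up = np.zeros(self.q_p)
            ur = np.zeros(self.q_r)
        else:
            beta, up, ur = (a.copy() for a in start)
        obj = self._pen_obj(beta, up, ur, phi, pp, pr)
        S = None
        for _ in range(max_iter):
            eta = self.eta(beta, up, ur)
            _, score, info = self.loglik_terms(eta, phi)
            s = self.w * score
            W = self.w * info
            gx = self.X.T @ s
            gp = np.bincount(self.pat_idx, weights=s, minlength=self.q_p) - pp * up
            if self.has_region:
                gr = np.bincount(self.cell_idx, weights=s, minlength=self.q_r) - pr * ur
            Hxx = self.X.T @ (self.X * W[:, None])
            Hb, Ub = self._blocks(W)
            Hb[:, 0, 0] += pp
            if self.has_region:
                idx = np.arange(self.q_cell)
                # padded cells get unit diagonal: inert in solves, 0 in logdet
                Hb[:, 1 + idx, 1 + idx] += np.where(self.cells_mask, pr, 1.0)
                gu = np.concatenate(
                    [gp[:, None], gr[self.cells_mat] * self.cells_mask], axis=1)  # (m, 1+q)
            else:
                gu = gp[:, None]
            try:
                T = np.linalg.solve(Hb, np.transpose(Ub, (0, 2, 1)))    # (m, 1+q, p)
                v = np.linalg.solve(Hb, gu[:, :, None])[:, :, 0]        # (m, 1+q)
            except np.linalg.LinAlgError:
                raise ConvergenceError("inner Newton system singular")
            S = Hxx - np.einsum("mpk,mkq->pq", Ub, T)
            rhs = gx - np.einsum("mpk,mk->p", Ub, v)
            try:
                dbeta = np.linalg.solve(S, rhs)
            except np.linalg.LinAlgError:
                # near-collinear fixed effects at extreme variance proposals:
                # a minimum-norm step keeps the search alive
                dbeta = np.linalg.lstsq(S, rhs, rcond=None)[0]
            du = v - np.einsum("mkp,p->mk", T, dbeta)                   # (m, 1+q)
            dup = du[:, 0]
            if self.has_region:
                dur = np.zeros(self.q_r)
                dur[self.cells_mat[self.cells_mask]] = du[:, 1:][self.cells_mask]
            t = 1.0
            for _ in range(30):
                nb, np_, nr = beta + t * dbeta, up + t * dup, (
                    ur + t * dur if self.has_region else ur)
                new_obj = self._pen_obj(nb, np_, nr, phi, pp, pr)
                if new_obj >= obj - 1e-12:
                    break
                t *= 0.5
            improved = new_obj - obj
            beta, up, obj = nb, np_, new_obj
            if self.has_region:
                ur = nr
            if abs(improved) < tol * (1.0 + abs(obj)):
                break
        # log det of the u-block of the penalized information, patient-blocked
        sign, logdets = np.linalg.slogdet(Hb)
        if np.any(sign <= 0):
            raise ConvergenceError("penalized information not positive definite")
        return (beta, up, ur), obj, float(np.sum(logdets)), S

    def laplace_neg(self, theta, state):
        """Negative Laplace marginal log-likelihood at theta = (log phi, log sds)."""
        if np.any(np.abs(np.asarray(theta)) > 16.0):   # keep the simplex in a sane box
            return np.inf
        phi = np.exp(theta[0])
        sp = np.exp(theta[1])
        sr = np.exp(theta[2]) if self.has_region else 0.0
        try:
            coef, pen_obj, logdet_huu, S = self.inner_newton(phi, sp, sr, start=state.get("coef"))
        except ConvergenceError:
            return np.inf
        state["coef"] = coef
        state["S"] = S
        q = self.q_p + self.q_r
        logdet_prior = -2.0 * (self.q_p * np.log(max(sp, 1e-8))
                               + self.q_r * np.log(max(sr, 1e-8)))
        lap = pen_obj + 0.5 * logdet_prior - 0.5 * logdet_huu
        return -lap


def fit_beta_mixed(
    y01,
    X: pd.DataFrame,
    patient,
    region=None,
    robust: bool = False,
    huber_c: float = HUBER_C,
    formula: str = "",
    max_robust_iter: int = 8,
    theta_start=None,
) -> MixedModelFit:
    """Logit-link beta mixed model with Laplace-approximated random intercepts.

    ``y01`` must live strictly inside (0,1) (use :func:`shrink_to_open_unit`
    for percentage endpoints). The robust variant weights each observation's
    log-likelihood by a Huber factor on its Pearson residual. ``theta_start``
    optionally seeds the (log phi, log sd) search, e.g. from a previous fit
    of a same-shaped problem in a simulation loop.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(np.shape(X)[1])]
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y01, dtype=float)
    if ya.std() == 0:
        raise ValueError("endpoint has zero variance; nothing to model")

    weights = np.ones(len(ya))
    result = None
    theta0, coef0 = theta_start, None
    for it in range(max_robust_iter if robust else 1):
        result = _fit_beta_once(ya, Xa, patient, region, weights, theta0, coef0)
        if not robust:
            break
        work, theta, (beta_c, up, ur), S = result
        theta0, coef0 = theta[: 3 if work.has_region else 2], (beta_c, up, ur)
        phi = np.exp(theta[0])
        mu = special.expit(work.eta(beta_c, up, ur))
        pearson = (ya - mu) / np.sqrt(mu * (1.0 - mu) / (1.0 + phi))
        new_w = np.minimum(1.0, huber_c / np.maximum(np.abs(pearson), 1e-12))
        if np.max(np.abs(new_w - weights)) < 1e-3:
            weights = new_w
            break
        weights = new_w

    work, theta, (beta, up, ur), S = result
    try:
        # S is the fixed-effect Schur complement: its inverse is cov(beta)
        cov_beta = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        raise ConvergenceError("information matrix singular at the optimum")
    phi = float(np.exp(theta[0]))
    comps = {
        "dispersion_phi": phi,
        "sd_patient": float(np.exp(theta[1])),
    }
    if work.has_region:
        comps["sd_region_within_patient"] = float(np.exp(theta[2]))
    boundary = [k for k in ("sd_patient", "sd_region_within_patient")
                if k in comps and (comps[k] < 1e-4 or comps[k] > 1e3)]
    return MixedModelFit(
        params=_wald_table(names, beta, cov_beta),
        variance_components=comps,
        family="beta",
        robust=robust,
        formula=formula,
        n_obs=work.n,
        n_patients=len(work.patients),
        boundary=boundary,
        scale_note="coefficients on the logit scale of the proportion endpoint",
        theta=np.asarray(theta[: 3 if work.has_region else 2]),
    )


def _fit_beta_once(y, X, patient, region, weights, theta0=None, coef0=None):
    work = _BetaWork(y, X, patient, region, weights)
    state: dict = {} if coef0 is None else {"coef": coef0}
    k = 3 if work.has_region else 2
    if theta0 is not None:
        x0 = np.asarray(theta0, dtype=float)
        opts = {"xatol": 1e-3, "fatol": 1e-5, "maxiter": 300}
    else:
        # moment start: logit-scale residual spread drives phi
        eta0 = np.log(y / (1 - y))
        spread = max(float(np.std(eta0)), 0.05)
        x0 = np.array([np.log(max(4.0 / spread**2, 2.0)),
                       np.log(0.5 * spread), np.log(0.3 * spread)][:k])
        opts = {"xatol": 1e-4, "fatol": 1e-6, "maxiter": 600}
    res = optimize.minimize(
        lambda th: work.laplace_neg(th, state), x0, method="Nelder-Mead", options=opts,
    )
    if not np.isfinite(res.fun):
        raise ConvergenceError("beta mixed model: Laplace objective not finite")
    theta = res.x if k == 3 else np.append(res.x, -np.inf)
    phi = np.exp(theta[0])
    sp = np.exp(theta[1])
    sr = np.exp(theta[2]) if work.has_region else 0.0
    coef, _, _, S = work.inner_newton(phi, sp, sr, start=state.get("coef"))
    return work, theta, coef, S
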