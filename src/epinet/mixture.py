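"""Covariate-gated Gaussian mixture (latent profile) modelling.

The population density of the indicator traits y given covariates z is
modelled as f(y|z) = sum_k pi_k(z) f(y | x=k, z): a finite mixture of
class-specific Gaussians whose mixing probabilities are a multinomial
logit in the covariates ("gating").  The default configuration is the
conditional-independence latent-profile model (diagonal class
covariance, covariates entering only the gating).  An optional one-factor
variant intersperses a latent variable eta between covariates and
indicators within each class:

    y = nu_k + lambda_k * eta + eps,    eta = gamma_k' z + zeta,

identified by fixing the first loading to 1 and the factor intercept to
0.  Both variants share the same EM skeleton; model choice across class
counts uses the sample-size-adjusted BIC with an entropy tie-break.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from sklearn.cluster import KMeans
from statsmodels.stats.diagnostic import lilliefors, normal_ad

from .panel import PhenotypeTable

__all__ = ["LatentProfileModel", "LatentProfileResults", "PartitionResult",
           "fit_mixture", "adjusted_bic", "entropy", "select_model",
           "class_diagnostics"]


# ---------------------------------------------------------------------------
# information criteria and partition accuracy
# ---------------------------------------------------------------------------

def adjusted_bic(loglik, n_params: int | None = None,
                 nobs: int | None = None) -> float:
    """Sample-size-adjusted BIC: -2 loglik + d * ln((n + 2) / 24).

    Accepts either a fitted :class:`LatentProfileResults` or the triple
    (loglik, d, n).  Lower is better.
    """
    if n_params is None:
        res = loglik
        loglik, n_params, nobs = res.loglik, res.n_params, res.nobs
    return float(-2.0 * loglik + n_params * np.log((nobs + 2) / 24.0))


def entropy(posteriors: np.ndarray) -> float:
    """Relative entropy of a posterior matrix, in [0, 1].

    1 - [sum_i sum_k -p_ik ln p_ik] / (n ln K); 1 means perfectly crisp
    assignment, 0 means uniform (uninformative) posteriors.
    """
    P = np.asarray(posteriors, dtype=float)
    if P.ndim != 2 or P.shape[1] < 2:
        raise ValueError("entropy requires a posterior matrix with K >= 2")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("posterior rows must sum to 1")
    n, K = P.shape
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    return float(1.0 + plogp.sum() / (n * np.log(K)))


# ---------------------------------------------------------------------------
# gating (responsibility-weighted multinomial logit)
# ---------------------------------------------------------------------------

def _log_gating(Z1: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Log class probabilities; B is (K, p+1) with reference row 0 = 0."""
    L = Z1 @ B.T
    return L - logsumexp(L, axis=1, keepdims=True)


def _gating_q(Z1, R, B) -> float:
    return float(np.sum(R * _log_gating(Z1, B)))


def _gating_newton(Z1: np.ndarray, R: np.ndarray, B: np.ndarray,
                   n_steps: int = 3, ridge: float = 1e-9) -> np.ndarray:
    """A few damped Newton steps on the weighted multinomial-logit fit.

    Warm-started from the current coefficients each M-step; step-halving
    guarantees the gating term of the EM Q-function never decreases, so
    the overall EM stays monotone (generalized EM).
    """
    n, K = R.shape
    if K == 1:
        return B
    p1 = Z1.shape[1]
    for _ in range(n_steps):
        logpi = _log_gating(Z1, B)
        P = np.exp(logpi)
        q0 = float(np.sum(R * logpi))
        grad = ((R - P)[:, 1:]).T @ Z1                       # (K-1, p1)
        H = np.empty((K - 1, p1, K - 1, p1))
        for k in range(1, K):
            for l in range(1, K):
                w = P[:, k] * ((1.0 if k == l else 0.0) - P[:, l])
                H[k - 1, :, l - 1, :] = -(Z1 * w[:, None]).T @ Z1
        Hm = -H.reshape((K - 1) * p1, (K - 1) * p1)          # negative Hessian
        Hm[np.diag_indices_from(Hm)] += ridge
        try:
            delta = np.linalg.solve(Hm, grad.ravel()).reshape(K - 1, p1)
        except np.linalg.LinAlgError:
            return B
        step, q_new, B_new = 1.0, -np.inf, B
        for _half in range(30):
            cand = B.copy()
            cand[1:] += step * delta
            q_new = _gating_q(Z1, R, cand)
            if q_new >= q0:
                B_new = cand
                break
            step *= 0.5
        if q_new < q0:
            return B
        improved = q_new - q0
        B = B_new
        if improved < 1e-10 * max(1.0, abs(q0)):
            break
    return B


# ---------------------------------------------------------------------------
# parameter container
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class _Params:
    means: np.ndarray            # (K, q)
    sds: np.ndarray              # (K, q) class residual SDs
    B: np.ndarray                # (K, p+1) gating logits, row 0 == 0
    loadings: np.ndarray | None = None    # (K, q), first element fixed to 1
    factor_coef: np.ndarray | None = None  # (K, p) eta-on-z regression
    factor_var: np.ndarray | None = None   # (K,) Var(zeta)

    def copy(self) -> "_Params":
        return _Params(self.means.copy(), self.sds.copy(), self.B.copy(),
                       None if self.loadings is None else self.loadings.copy(),
                       None if self.factor_coef is None else self.factor_coef.copy(),
                       None if self.factor_var is None else self.factor_var.copy())


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class LatentProfileModel:
    """Covariate-gated finite mixture of Gaussians over indicator traits.

    Parameters
    ----------
    endog
        (n, q) indicator matrix (e.g. diastolic and systolic pressure).
    exog
        (n, p) covariate matrix driving class membership; may be empty
        (pure finite mixture).
    factor
        Fit the one-factor within-class variant instead of the
        conditional-independence latent-profile model.

    Rows with any missing value are dropped (complete-case).
    """

    def __init__(self, endog, exog=None, factor: bool = False,
                 endog_names: Sequence[str] | None = None,
                 exog_names: Sequence[str] | None = None):
        Y = np.atleast_2d(np.asarray(endog, dtype=float))
        if Y.shape[0] == 1 and Y.shape[1] > 1 and np.ndim(endog) == 1:
            Y = Y.T
        Z = np.empty((len(Y), 0)) if exog is None else \
            np.asarray(exog, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        if len(Z) != len(Y):
            raise ValueError("endog and exog differ in length")
        ok = np.isfinite(Y).all(axis=1) & np.isfinite(Z).all(axis=1)
        self.endog = Y[ok]
        self.exog = Z[ok]
        self.n_dropped = int((~ok).sum())
        self.factor = factor
        q, p = Y.shape[1], Z.shape[1]
        self.endog_names = list(endog_names) if endog_names else \
            [f"y{j + 1}" for j in range(q)]
        self.exog_names = list(exog_names) if exog_names else \
            [f"z{j + 1}" for j in range(p)]

    @classmethod
    def from_phenotypes(cls, pheno: PhenotypeTable,
                        factor: bool = False) -> "LatentProfileModel":
        return cls(pheno.indicator_matrix(), pheno.covariate_matrix(),
                   factor=factor, endog_names=pheno.indicators,
                   exog_names=pheno.covariates)

    # -- dimensions ----------------------------------------------------
    @property
    def nobs(self) -> int:
        return len(self.endog)

    @property
    def n_indicators(self) -> int:
        return self.endog.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.exog.shape[1]

    def n_params(self, K: int) -> int:
        q, p = self.n_indicators, self.n_covariates
        d = K * q + K * q + (K - 1) * (p + 1)
        if self.factor:
            d += K * (q - 1) + K * p + K
        return d

    # -- log densities -------------------------------------------------
    def _log_components(self, par: _Params) -> np.ndarray:
        """(n, K) class-conditional log density of the indicators."""
        Y, Z = self.endog, self.exog
        K, q = par.means.shape
        if not self.factor:
            diff = Y[:, None, :] - par.means[None, :, :]
            var = par.sds[None, :, :] ** 2
            return -0.5 * np.sum(np.log(2 * np.pi * var) + diff ** 2 / var,
                                 axis=2)
        out = np.empty((len(Y), K))
        for k in range(K):
            lam = par.loadings[k]
            psi = par.sds[k] ** 2
            phi = par.factor_var[k]
            m = Z @ par.factor_coef[k] if Z.shape[1] else np.zeros(len(Y))
            mean = par.means[k][None, :] + np.outer(m, lam)
            diff = Y - mean
            # Sherman-Morrison on Sigma = phi * lam lam' + diag(psi)
            a = lam / psi
            c = 1.0 + phi * float(lam @ a)
            quad = np.sum(diff ** 2 / psi, axis=1) \
                - (phi / c) * (diff @ a) ** 2
            logdet = float(np.sum(np.log(psi))) + np.log(c)
            out[:, k] = -0.5 * (q * np.log(2 * np.pi) + logdet + quad)
        return out

    def loglike(self, par: _Params) -> float:
        lj = self._log_components(par) + _log_gating(self._Z1, par.B)
        return float(logsumexp(lj, axis=1).sum())

    # -- EM ------------------------------------------------------------
    def fit(self, n_classes: int, *, n_restarts: int = 20, seed: int = 0,
            max_iter: int = 2000, tol: float = 1e-8,
            var_floor_frac: float = 1e-6) -> "LatentProfileResults":
        """Fit by EM with random restarts; the best restart is returned.

        The log-likelihood is monotone non-decreasing across iterations;
        non-convergence within ``max_iter`` is flagged on the result,
        never silent.  Class labels are canonicalized by ascending first
        indicator mean, which makes the output deterministic given the
        seed.
        """
        K = int(n_classes)
        n = self.nobs
        if K < 1:
            raise ValueError("n_classes must be >= 1")
        if n < K:
            raise ValueError(f"n={n} subjects cannot support K={K} classes")
        if n < 10 * self.n_params(K):
            warnings.warn(f"only {n} complete cases for {self.n_params(K)} "
                          "parameters; estimates may be unstable",
                          stacklevel=2)
        self._Z1 = np.column_stack([np.ones(n), self.exog])
        self._var_floor = var_floor_frac * np.var(self.endog, axis=0, ddof=0)
        rng = np.random.default_rng(seed)

        best = None
        restart_lls = []
        for r in range(max(1, n_restarts) if K > 1 else 1):
            par = self._init_params(K, r, rng, seed)
            fitted = self._run_em(par, max_iter, tol, rng)
            restart_lls.append(fitted[1])
            if best is None or fitted[1] > best[1]:
                best = fitted
        par, ll, history, converged, n_rejit = best
        par = self._canonicalize(par)
        logpost = self._log_components(par) + _log_gating(self._Z1, par.B)
        ll_i = logsumexp(logpost, axis=1, keepdims=True)
        posteriors = np.exp(logpost - ll_i)
        return LatentProfileResults(
            model=self, n_classes=K, params=par, loglik=ll,
            loglik_history=history, n_params=self.n_params(K), nobs=n,
            converged=converged, posteriors=posteriors,
            restart_logliks=restart_lls, n_rejitters=n_rejit, seed=seed)

    # -- internals -----------------------------------------------------
    def _init_params(self, K: int, restart: int, rng: np.random.Generator,
                     seed: int) -> _Params:
        Y = self.endog
        n, q = Y.shape
        sd = Y.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        if K == 1:
            means = Y.mean(axis=0, keepdims=True)
        elif restart == 0:
            km = KMeans(n_clusters=K, n_init=10,
                        random_state=int(seed) % (2 ** 31))
            km.fit((Y - Y.mean(0)) / sd)
            means = km.cluster_centers_ * sd + Y.mean(0)
        else:
            idx = rng.choice(n, size=K, replace=False)
            means = Y[idx] + 0.25 * sd * rng.standard_normal((K, q))
        sds = np.tile(sd, (K, 1))
        B = np.zeros((K, self.n_covariates + 1))
        par = _Params(means, sds, B)
        if self.factor:
            par.loadings = np.ones((K, q))
            par.factor_coef = np.zeros((K, self.n_covariates))
            par.factor_var = np.full(K, float(np.mean(sd ** 2)) * 0.5)
            par.sds = np.tile(sd * 0.7, (K, 1))
        return par

    def _run_em(self, par: _Params, max_iter: int, tol: float,
                rng: np.random.Generator):
        n = self.nobs
        history = []
        converged = False
        n_rejit = 0
        prev = -np.inf
        for _ in range(max_iter):
            lj = self._log_components(par) + _log_gating(self._Z1, par.B)
            ll_i = logsumexp(lj, axis=1, keepdims=True)
            ll = float(ll_i.sum())
            R = np.exp(lj - ll_i)
            Nk = R.sum(axis=0)
            if Nk.min() < max(1e-8 * n, 1e-300) and n_rejit < 10:
                # empty class: re-jitter its mean and retry this sweep
                k = int(np.argmin(Nk))
                idx = rng.integers(0, n)
                par.means[k] = self.endog[idx] + \
                    0.5 * self.endog.std(0) * rng.standard_normal(self.n_indicators)
                n_rejit += 1
                continue
            history.append(ll)
            if np.isfinite(prev) and ll - prev < tol * max(1.0, abs(ll)):
                converged = True
                break
            prev = ll
            par = self._m_step(R, par)
        final = self.loglike(par)
        history.append(final)
        return par, final, history, converged, n_rejit

    def _m_step(self, R: np.ndarray, par: _Params) -> _Params:
        Y, Z = self.endog, self.exog
        Nk = R.sum(axis=0)
        par = par.copy()
        if not self.factor:
            means = (R.T @ Y) / Nk[:, None]
            var = np.empty_like(means)
            for k in range(R.shape[1]):
                d = Y - means[k]
                var[k] = (R[:, k] @ (d * d)) / Nk[k]
            par.means = means
            par.sds = np.sqrt(np.maximum(var, self._var_floor))
        else:
            par = self._m_step_factor(R, par)
        par.B = _gating_newton(self._Z1, R, par.B)
        return par

    def _m_step_factor(self, R: np.ndarray, par: _Params) -> _Params:
        """Exact M-step of the one-factor variant given eta posteriors."""
        Y, Z = self.endog, self.exog
        n, q = Y.shape
        K = R.shape[1]
        have_z = Z.shape[1] > 0
        for k in range(K):
            w = R[:, k]
            sw = w.sum()
            lam = par.loadings[k]
            psi = par.sds[k] ** 2
            phi = par.factor_var[k]
            m = Z @ par.factor_coef[k] if have_z else np.zeros(n)
            # posterior moments of eta
            a = lam / psi
            prec = 1.0 / phi + float(lam @ a)
            v = 1.0 / prec
            e = v * ((Y - par.means[k]) @ a + m / phi)
            ee = e * e + v
            # loading/intercept regression per indicator
            S1, Se, See = sw, float(w @ e), float(w @ ee)
            new_mu = par.means[k].copy()
            new_lam = lam.copy()
            new_psi = psi.copy()
            # first indicator: loading fixed at 1
            new_mu[0] = float(w @ (Y[:, 0] - e)) / sw
            resid0 = Y[:, 0] - new_mu[0] - e
            new_psi[0] = (float(w @ (resid0 * resid0)) + v * sw) / sw
            for j in range(1, q):
                Sy = float(w @ Y[:, j])
                Sye = float(w @ (Y[:, j] * e))
                A = np.array([[S1, Se], [Se, See]])
                b = np.array([Sy, Sye])
                try:
                    mu_j, lam_j = np.linalg.solve(A, b)
                except np.linalg.LinAlgError:
                    mu_j, lam_j = Sy / S1, 0.0
                new_mu[j], new_lam[j] = mu_j, lam_j
                rj = Y[:, j] - mu_j - lam_j * e
                new_psi[j] = (float(w @ (rj * rj)) + lam_j ** 2 * v * sw) / sw
            # factor-on-covariate regression (no intercept: identification)
            if have_z:
                ZW = Z * w[:, None]
                A = ZW.T @ Z
                A[np.diag_indices_from(A)] += 1e-10
                gam = np.linalg.solve(A, ZW.T @ e)
                mhat = Z @ gam
            else:
                gam = par.factor_coef[k]
                mhat = np.zeros(n)
            dphi = ee - 2 * e * mhat + mhat * mhat
            new_phi = float(w @ dphi) / sw
            par.means[k] = new_mu
            par.loadings[k] = new_lam
            par.sds[k] = np.sqrt(np.maximum(new_psi, self._var_floor))
            par.factor_coef[k] = gam
            par.factor_var[k] = max(new_phi, 1e-8)
        return par

    def _canonicalize(self, par: _Params) -> _Params:
        order = np.argsort(par.means[:, 0], kind="stable")
        par = par.copy()
        par.means = par.means[order]
        par.sds = par.sds[order]
        B = par.B[order]
        par.B = B - B[0]
        for attr in ("loadings", "factor_coef"):
            v = getattr(par, attr)
            if v is not None:
                setattr(par, attr, v[order])
        if par.factor_var is not None:
            par.factor_var = par.factor_var[order]
        return par


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LatentProfileResults:
    """Fitted covariate-gated mixture: estimates and diagnostics."""

    model: LatentProfileModel
    n_classes: int
    params: _Params
    loglik: float
    loglik_history: list
    n_params: int
    nobs: int
    converged: bool
    posteriors: np.ndarray
    restart_logliks: list
    n_rejitters: int
    seed: int

    # -- parameter views ----------------------------------------------
    @property
    def means(self) -> np.ndarray:
        return self.params.means

    @property
    def sds(self) -> np.ndarray:
        return self.params.sds

    @property
    def gating(self) -> np.ndarray:
        """(K-1, p+1) log-odds coefficients of the non-reference classes."""
        return self.params.B[1:]

    @property
    def modal(self) -> np.ndarray:
        return self.posteriors.argmax(axis=1)

    @property
    def class_sizes(self) -> np.ndarray:
        return np.bincount(self.modal, minlength=self.n_classes)

    @property
    def mixing(self) -> np.ndarray:
        """Average class-membership probability (subpopulation sizes)."""
        return self.posteriors.mean(axis=0)

    @property
    def abic(self) -> float:
        return adjusted_bic(self.loglik, self.n_params, self.nobs)

    @property
    def entropy(self) -> float:
        if self.n_classes < 2:
            return np.nan
        return entropy(self.posteriors)

    def predict_class_probs(self, exog) -> np.ndarray:
        """Gating probabilities pi(x|z) for new covariate rows."""
        Z = np.asarray(exog, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        Z1 = np.column_stack([np.ones(len(Z)), Z])
        return np.exp(_log_gating(Z1, self.params.B))

    def summary(self) -> str:
        q = self.model.n_indicators
        lines = [
            "Covariate-gated latent profile model"
            + (" (one-factor variant)" if self.model.factor else ""),
            f"  classes: {self.n_classes}   n: {self.nobs}   "
            f"params: {self.n_params}",
            f"  loglik: {self.loglik:.3f}   aBIC: {self.abic:.3f}   "
            f"entropy: {self.entropy:.4f}" if self.n_classes > 1 else
            f"  loglik: {self.loglik:.3f}   aBIC: {self.abic:.3f}",
            f"  converged: {self.converged}   "
            f"restarts: {len(self.restart_logliks)}",
            "",
            "  class sizes (modal): " + ", ".join(map(str, self.class_sizes)),
        ]
        head = "  class | " + " | ".join(
            f"{nm} mean (sd)" for nm in self.model.endog_names)
        lines.append(head)
        for k in range(self.n_classes):
            cells = " | ".join(f"{self.means[k, j]:8.3f} ({self.sds[k, j]:.3f})"
                               for j in range(q))
            lines.append(f"  {k:5d} | {cells}")
        if self.n_classes > 1 and self.model.n_covariates:
            lines.append("")
            lines.append("  gating log-odds (vs class 0):")
            names = ["intercept", *self.model.exog_names]
            for k in range(1, self.n_classes):
                coefs = ", ".join(f"{nm}={c:.3f}" for nm, c in
                                  zip(names, self.params.B[k]))
                lines.append(f"    class {k}: {coefs}")
        return "\n".join(lines)

    def plot_indicators(self, ax=None):
        """Scatter of the first two indicators colored by modal class."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        Y = self.model.endog
        j2 = 1 if Y.shape[1] > 1 else 0
        ax.scatter(Y[:, 0], Y[:, j2], c=self.modal, s=8, cmap="tab20")
        ax.set_xlabel(self.model.endog_names[0])
        ax.set_ylabel(self.model.endog_names[j2])
        ax.set_title(f"{self.n_classes}-class partition")
        return ax


def fit_mixture(pheno: PhenotypeTable, n_classes: int, *, factor=False,
                **fit_kw) -> LatentProfileResults:
    """Fit the gated mixture to a phenotype table (convenience wrapper)."""
    return LatentProfileModel.from_phenotypes(pheno, factor=factor) \
        .fit(n_classes, **fit_kw)


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def _select_from_table(table: pd.DataFrame, margin: float) -> int:
    """Index of the chosen row: min aBIC, entropy breaking near-ties."""
    ok = table[table["status"] == "ok"]
    if ok.empty:
        raise RuntimeError("no class count could be fitted")
    lo = ok["abic"].min()
    contenders = ok[ok["abic"] <= lo + margin]
    ent = contenders["entropy"].fillna(-1.0)
    return int(ent.idxmax()) if len(contenders) > 1 else int(contenders.index[0])


def select_model(model: LatentProfileModel, k_range: Iterable[int], *,
                 margin: float = 2.0, **fit_kw
                 ) -> tuple[LatentProfileResults, pd.DataFrame]:
    """Sweep class counts; pick minimum adjusted BIC.

    Models whose aBIC lies within ``margin`` of the minimum are treated
    as equivalent and the one with the higher entropy wins.  Per-K fit
    failures are recorded in the selection table, never abort the sweep.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be non-empty")
    rows, fits = [], {}
    for K in k_range:
        try:
            res = model.fit(K, **fit_kw)
            fits[K] = res
            rows.append({"K": K, "loglik": res.loglik, "n_params": res.n_params,
                         "abic": res.abic, "entropy": res.entropy,
                         "converged": res.converged, "status": "ok"})
        except Exception as exc:  # noqa: BLE001 - failures go into the table
            rows.append({"K": K, "loglik": np.nan, "n_params": np.nan,
                         "abic": np.nan, "entropy": np.nan,
                         "converged": False, "status": f"error: {exc}"})
    table = pd.DataFrame(rows)
    chosen = _select_from_table(table, margin)
    best_k = int(table.loc[chosen, "K"])
    table["selected"] = table["K"] == best_k
    return fits[best_k], table


# ---------------------------------------------------------------------------
# partition diagnostics
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PartitionResult:
    """Partition of the cohort with accuracy and homogeneity diagnostics."""

    posteriors: np.ndarray
    modal: np.ndarray
    class_sizes: np.ndarray
    abic: float
    entropy: float
    correlations: pd.DataFrame   # class, indicator pair, Pearson r, p, flag
    normality: pd.DataFrame      # class, indicator, Shapiro/Lilliefors/AD p
    min_class_size: int

    def to_frame(self, subject_ids: Sequence[str],
                 class_labels: Sequence | None = None) -> pd.DataFrame:
        """Partition table: subject, modal class, posterior columns."""
        K = self.posteriors.shape[1]
        cols = {f"posterior_{k}": self.posteriors[:, k] for k in range(K)}
        return pd.DataFrame({"modal_class": self.modal, **cols},
                            index=pd.Index(subject_ids, name="subject_id"))


def class_diagnostics(results: LatentProfileResults,
                      min_class_size: int = 8) -> PartitionResult:
    """Within-class indicator correlation and normality diagnostics.

    In a perfect classification the indicators decorrelate within every
    class (their population correlation is explained by class structure
    alone).  Classes below ``min_class_size`` are flagged "insufficient"
    and their tests skipped.
    """
    Y = results.model.endog
    names = results.model.endog_names
    modal = results.modal
    K, q = results.n_classes, Y.shape[1]
    corr_rows, norm_rows = [], []
    for k in range(K):
        yk = Y[modal == k]
        nk = len(yk)
        small = nk < min_class_size
        for a in range(q):
            for b in range(a + 1, q):
                if small:
                    corr_rows.append({"class": k, "n": nk,
                                      "indicator_a": names[a],
                                      "indicator_b": names[b],
                                      "r": np.nan, "p": np.nan,
                                      "flag": "insufficient"})
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r, p = stats.pearsonr(yk[:, a], yk[:, b])
                corr_rows.append({"class": k, "n": nk,
                                  "indicator_a": names[a],
                                  "indicator_b": names[b],
                                  "r": float(r), "p": float(p), "flag": ""})
        for j in range(q):
            if small:
                norm_rows.append({"class": k, "n": nk, "indicator": names[j],
                                  "shapiro_p": np.nan, "lilliefors_p": np.nan,
                                  "anderson_darling_p": np.nan,
                                  "flag": "insufficient"})
                continue
            col = yk[:, j]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sw = stats.shapiro(col).pvalue if np.ptp(col) > 0 else np.nan
                try:
                    lf = lilliefors(col, dist="norm")[1]
                except Exception:  # noqa: BLE001 - degenerate column
                    lf = np.nan
                try:
                    ad = normal_ad(col)[1]
                except Exception:  # noqa: BLE001
                    ad = np.nan
            norm_rows.append({"class": k, "n": nk, "indicator": names[j],
                              "shapiro_p": float(sw) if sw == sw else np.nan,
                              "lilliefors_p": float(lf) if lf == lf else np.nan,
                              "anderson_darling_p": float(ad) if ad == ad else np.nan,
                              "flag": ""})
    return PartitionResult(results.posteriors, modal, results.class_sizes,
                           results.abic, results.entropy,
                           pd.DataFrame(corr_rows), pd.DataFrame(norm_rows),
                           min_class_size)
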