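"""REML linear mixed models for multi-trial phenotype analysis.

The model is y = X beta + Z_g u_g + Z_gt u_gt + Z_b u_b + e, with trial as a
fixed effect and genotype, genotype-by-trial and block as independent normal
random effects; genotype effects may carry a pedigree relationship matrix A
(u_g ~ N(0, A sigma2_g)). Residuals are homogeneous across trials and no
spatial (row/column) terms are fitted; both are deliberate simplifications
that keep restricted maximum likelihood estimable from first principles.

Variance components are estimated by direct maximisation of the restricted
log-likelihood with variances parameterised on the log scale. A model with a
single random term uses a one-dimensional profiled likelihood over the
variance ratio via an eigendecomposition of Z G Z'; models with several
terms use Nelder-Mead on the log variances.

Genotype values are reported as BLUPs (genotype random, with prediction
error variances) or BLUEs (genotype fixed). Broad-sense heritability follows
Cullis: H2 = 1 - mean pairwise PEV of genotype differences / (2 sigma2_g).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .pedigree import PedigreeMatrix

__all__ = [
    "PhenoMixedModel",
    "PhenoMixedModelResults",
    "fit_lmm",
    "cullis_h2",
    "SingularDesignError",
]


class SingularDesignError(ValueError):
    """Raised when the design cannot support the requested model."""


@dataclass
class _RandomTerm:
    name: str
    Z: np.ndarray  # n x q indicator matrix
    G: np.ndarray | None  # q x q covariance structure (None = identity)
    levels: list[str]

    def K(self) -> np.ndarray:
        if self.G is None:
            return self.Z @ self.Z.T
        return self.Z @ self.G @ self.Z.T


def _indicator(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((codes.size, n_levels))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


def _sum_to_zero(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Sum-to-zero contrast columns for a factor (n_levels - 1 columns)."""
    X = np.zeros((codes.size, n_levels - 1))
    for j in range(n_levels - 1):
        X[codes == j, j] = 1.0
    X[codes == n_levels - 1, :] = -1.0
    return X


class PhenoMixedModel:
    """Mixed model for a long-format phenotype table.

    Parameters
    ----------
    data : DataFrame
        Long format with columns ``genotype``, the trait column, and
        optionally ``trial`` and ``block``.
    trait_col : str
        Column holding the response.
    genotype_effect : {'random', 'fixed'}
        Random gives BLUPs with prediction-error variances (and supports a
        pedigree A); fixed gives BLUEs.
    A : PedigreeMatrix, optional
        Additive relationship matrix for the genotype effects; must cover
        every genotype in the data.
    include_gxt, include_block : bool, optional
        Whether to fit genotype-by-trial and block random effects. Defaults
        are chosen from the data: genotype-by-trial only when it is
        separable from the residual (replication within trial), block only
        when a block column with more than one level is present.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        trait_col: str = "value",
        genotype_effect: str = "random",
        A: PedigreeMatrix | None = None,
        include_gxt: bool | None = None,
        include_block: bool | None = None,
    ):
        if genotype_effect not in ("random", "fixed"):
            raise ValueError("genotype_effect must be 'random' or 'fixed'")
        data = data.dropna(subset=[trait_col]).reset_index(drop=True)
        if data.empty:
            raise SingularDesignError("no non-missing observations")
        self.data = data
        self.trait_col = trait_col
        self.genotype_effect = genotype_effect

        self.genotypes = sorted(data["genotype"].astype(str).unique())
        if len(self.genotypes) < 2:
            raise SingularDesignError("need at least 2 genotypes")
        g_index = {g: i for i, g in enumerate(self.genotypes)}
        g_codes = data["genotype"].astype(str).map(g_index).to_numpy()

        if "trial" in data.columns:
            self.trials = sorted(data["trial"].astype(str).unique())
        else:
            self.trials = ["T1"]
        t_index = {t: i for i, t in enumerate(self.trials)}
        t_codes = (
            data["trial"].astype(str).map(t_index).to_numpy()
            if "trial" in data.columns
            else np.zeros(len(data), dtype=int)
        )
        n = len(data)
        n_t = len(self.trials)

        if include_gxt is None:
            counts = data.groupby(
                [data["genotype"].astype(str), pd.Series(t_codes, name="t")]
            ).size()
            include_gxt = n_t > 1 and counts.max() > 1
        if include_block is None:
            include_block = (
                "block" in data.columns and data["block"].astype(str).nunique() > 1
            )

        # fixed effects
        if genotype_effect == "fixed":
            X = _indicator(g_codes, len(self.genotypes))
            self.fe_names = [f"genotype[{g}]" for g in self.genotypes]
        else:
            X = np.ones((n, 1))
            self.fe_names = ["intercept"]
        if n_t > 1:
            X = np.hstack([X, _sum_to_zero(t_codes, n_t)])
            self.fe_names += [f"trial[{t}]" for t in self.trials[:-1]]
        self.X = X
        self.y = data[trait_col].to_numpy(dtype=float)
        if n <= X.shape[1]:
            raise SingularDesignError(
                f"no residual degrees of freedom (n={n}, p={X.shape[1]})"
            )

        # random terms
        self.terms: list[_RandomTerm] = []
        self._g_term: _RandomTerm | None = None
        if genotype_effect == "random":
            G = None
            if A is not None:
                G = A.submatrix(self.genotypes)
            self._g_term = _RandomTerm(
                "genotype", _indicator(g_codes, len(self.genotypes)), G, self.genotypes
            )
            self.terms.append(self._g_term)
        if include_gxt and n_t > 1:
            gt_codes = g_codes * n_t + t_codes
            levels = [f"{g}:{t}" for g in self.genotypes for t in self.trials]
            self.terms.append(
                _RandomTerm("genotype_x_trial", _indicator(gt_codes, len(levels)),
                            None, levels)
            )
        if include_block and "block" in data.columns:
            blk = (
                data["trial"].astype(str) + ":" + data["block"].astype(str)
                if "trial" in data.columns
                else data["block"].astype(str)
            )
            levels = sorted(blk.unique())
            b_index = {b: i for i, b in enumerate(levels)}
            self.terms.append(
                _RandomTerm("block", _indicator(blk.map(b_index).to_numpy(),
                                                len(levels)), None, levels)
            )

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, trait: str = "value", **kwargs
                       ) -> "PhenoMixedModel":
        return cls(data, trait_col=trait, **kwargs)

    # --- REML machinery ---------------------------------------------------

    @property
    def _Ks(self) -> list[np.ndarray]:
        if not hasattr(self, "_K_cache"):
            self._K_cache = [t.K() for t in self.terms]
        return self._K_cache

    def _neg2ll(self, variances: np.ndarray) -> float:
        """-2 restricted log-likelihood (up to an additive constant)."""
        n, p = self.X.shape
        V = np.eye(n) * variances[-1]
        for v, K in zip(variances, self._Ks):
            V += v * K
        try:
            c, low = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError:
            return np.inf
        logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
        Vi_y = linalg.cho_solve((c, low), self.y)
        Vi_X = linalg.cho_solve((c, low), self.X)
        XtViX = self.X.T @ Vi_X
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtViX, self.X.T @ Vi_y)
        yPy = float(self.y @ Vi_y - (self.X.T @ Vi_y) @ beta)
        return logdet_v + logdet_x + yPy

    def _fit_profiled_single(self, tol: float):
        """1 random term: profile the residual variance, optimise the ratio."""
        n, p = self.X.shape
        K = self.terms[0].K()
        lam, U = linalg.eigh(K)
        lam = np.maximum(lam, 0.0)
        yt = U.T @ self.y
        Xt = U.T @ self.X

        def neg2ll_profiled(log_gamma: float) -> float:
            w = np.exp(log_gamma) * lam + 1.0
            A = Xt.T @ (Xt / w[:, None])
            b = Xt.T @ (yt / w)
            sign, logdet_a = np.linalg.slogdet(A)
            if sign <= 0:
                return np.inf
            beta = np.linalg.solve(A, b)
            q = float(yt @ (yt / w) - b @ beta)
            if q <= 0:
                return np.inf
            ve = q / (n - p)
            return float(np.sum(np.log(w)) + (n - p) * np.log(ve) + logdet_a)

        res = optimize.minimize_scalar(
            neg2ll_profiled, bounds=(-30.0, 30.0), method="bounded",
            options={"xatol": 1e-12, "maxiter": 500},
        )
        gamma = float(np.exp(res.x))
        w = gamma * lam + 1.0
        A = Xt.T @ (Xt / w[:, None])
        b = Xt.T @ (yt / w)
        beta = np.linalg.solve(A, b)
        ve = float(yt @ (yt / w) - b @ beta) / (n - p)
        variances = np.array([gamma * ve, ve])
        converged = bool(res.success)
        # inverse of V for downstream BLUP/PEV computation
        Vinv = (U / (ve * w)) @ U.T
        return variances, beta, Vinv, converged, int(res.nfev)

    def _fit_general(self, tol: float, maxiter: int):
        vary = float(np.var(self.y))
        if vary <= 0:
            vary = 1.0
        m = len(self.terms) + 1
        theta0 = np.full(m, np.log(vary / m))
        res = optimize.minimize(
            lambda th: self._neg2ll(np.exp(np.clip(th, -30, 30))),
            theta0,
            method="Nelder-Mead",
            options={
                "xatol": 1e-10,
                "fatol": max(tol * 10.0, tol * abs(self._neg2ll(np.exp(theta0)))),
                "maxiter": maxiter * m * 20,
                "maxfev": maxiter * m * 40,
            },
        )
        variances = np.exp(np.clip(res.x, -30, 30))
        n = self.X.shape[0]
        V = np.eye(n) * variances[-1]
        for v, K in zip(variances, self._Ks):
            V += v * K
        c, low = linalg.cho_factor(V, lower=True)
        Vi_X = linalg.cho_solve((c, low), self.X)
        XtViX = self.X.T @ Vi_X
        Vi_y = linalg.cho_solve((c, low), self.y)
        beta = np.linalg.solve(XtViX, self.X.T @ Vi_y)
        Vinv = linalg.cho_solve((c, low), np.eye(n))
        return variances, beta, Vinv, bool(res.success), int(res.nit)

    def fit(self, tol: float = 1e-8, maxiter: int = 200) -> "PhenoMixedModelResults":
        """Estimate variance components by REML and predict genotype values."""
        n, p = self.X.shape
        if not self.terms:
            # pure fixed-effects model: ordinary least squares
            beta, _, rank, _ = np.linalg.lstsq(self.X, self.y, rcond=None)
            if rank < p:
                raise SingularDesignError("fixed-effects design is rank deficient")
            resid = self.y - self.X @ beta
            ve = float(resid @ resid) / (n - p)
            variances = np.array([ve])
            XtX = self.X.T @ self.X
            cov_beta = np.linalg.inv(XtX) * ve
            return self._build_results(
                variances, beta, cov_beta=cov_beta, Vinv=None,
                converged=True, n_iter=0,
            )
        if len(self.terms) == 1:
            variances, beta, Vinv, converged, n_iter = self._fit_profiled_single(tol)
        else:
            variances, beta, Vinv, converged, n_iter = self._fit_general(tol, maxiter)
        Vi_X = Vinv @ self.X
        XtViX = self.X.T @ Vi_X
        cov_beta = np.linalg.inv(XtViX)
        return self._build_results(
            variances, beta, cov_beta=cov_beta, Vinv=Vinv,
            converged=converged, n_iter=n_iter,
        )

    def _build_results(self, variances, beta, cov_beta, Vinv, converged, n_iter):
        varcomp = {t.name: float(v) for t, v in zip(self.terms, variances)}
        varcomp["residual"] = float(variances[-1])
        fe = pd.Series(beta, index=self.fe_names)

        blup = None
        pev_matrix = None
        if self._g_term is not None and Vinv is not None:
            vg = varcomp["genotype"]
            Z = self._g_term.Z
            G = self._g_term.G
            # P = Vinv - Vinv X (X' Vinv X)^-1 X' Vinv
            Vi_X = Vinv @ self.X
            XtViX = self.X.T @ Vi_X
            Py = Vinv @ self.y - Vi_X @ np.linalg.solve(XtViX, Vi_X.T @ self.y)
            PZ = Vinv @ Z - Vi_X @ np.linalg.solve(XtViX, Vi_X.T @ Z)
            ZtPZ = Z.T @ PZ
            if G is None:
                u = vg * (Z.T @ Py)
                C = vg * np.eye(len(self.genotypes)) - vg**2 * ZtPZ
            else:
                u = vg * (G @ (Z.T @ Py))
                C = vg * G - vg**2 * (G @ ZtPZ @ G)
            blup = pd.Series(u, index=self.genotypes, name="blup")
            pev_matrix = C

        blue = None
        blue_se = None
        if self.genotype_effect == "fixed":
            q = len(self.genotypes)
            blue = pd.Series(beta[:q], index=self.genotypes, name="blue")
            blue_se = pd.Series(np.sqrt(np.diag(cov_beta)[:q]),
                                index=self.genotypes, name="se")

        return PhenoMixedModelResults(
            model=self,
            varcomp=varcomp,
            fe_params=fe,
            cov_fe=cov_beta,
            blups=blup,
            blues=blue,
            blue_se=blue_se,
            pev_matrix=pev_matrix,
            converged=converged,
            n_iterations=n_iter,
        )


@dataclass
class PhenoMixedModelResults:
    """Estimates from a fitted phenotype mixed model."""

    model: PhenoMixedModel
    varcomp: dict[str, float]
    fe_params: pd.Series
    cov_fe: np.ndarray
    blups: pd.Series | None
    blues: pd.Series | None
    blue_se: pd.Series | None
    pev_matrix: np.ndarray | None
    converged: bool
    n_iterations: int
    _genotype_means: pd.Series | None = field(default=None, repr=False)

    @property
    def genotype_predictions(self) -> pd.DataFrame:
        """Per-genotype BLUP (with PEV) or BLUE (with standard error)."""
        if self.blups is not None:
            return pd.DataFrame(
                {"blup": self.blups, "pev": np.diag(self.pev_matrix)}
            )
        return pd.DataFrame({"blue": self.blues, "se": self.blue_se})

    def genotype_means(self) -> pd.Series:
        """Arithmetic mean of replicated measurements per genotype."""
        if self._genotype_means is None:
            d = self.model.data
            self._genotype_means = (
                d.groupby(d["genotype"].astype(str))[self.model.trait_col]
                .mean()
                .rename("mean")
            )
        return self._genotype_means

    def mean_pairwise_pev(self) -> float:
        """Average prediction-error variance of genotype-effect differences.

        Exact average of var(g_i_hat - g_j_hat) over all genotype pairs,
        computed from the prediction-error covariance matrix.
        """
        if self.pev_matrix is None:
            raise ValueError("pairwise PEV requires a genotype-random fit")
        C = self.pev_matrix
        q = C.shape[0]
        return float(2.0 * (q * np.trace(C) - C.sum()) / (q * (q - 1)))

    def cullis_h2(self) -> float:
        """Cullis broad-sense heritability 1 - mean PEV / (2 sigma2_g).

        Clamped to [0, 1]; defined as 0 when the genotype variance is 0.
        """
        if self.blups is None:
            raise ValueError("Cullis H2 requires a genotype-random fit")
        vg = self.varcomp.get("genotype", 0.0)
        if vg <= 0:
            return 0.0
        h2 = 1.0 - self.mean_pairwise_pev() / (2.0 * vg)
        return float(np.clip(h2, 0.0, 1.0))

    def summary(self) -> str:
        lines = ["Phenotype mixed model (REML)"]
        lines.append(f"  observations: {len(self.model.data)}")
        lines.append(f"  genotypes: {len(self.model.genotypes)}  "
                     f"trials: {len(self.model.trials)}")
        lines.append(f"  genotype effect: {self.model.genotype_effect}")
        lines.append(f"  converged: {self.converged}  "
                     f"iterations: {self.n_iterations}")
        lines.append("  variance components:")
        for k, v in self.varcomp.items():
            lines.append(f"    {k:<18s} {v:12.6g}")
        if self.blups is not None:
            lines.append(f"  Cullis H2: {self.cullis_h2():.4f}")
        lines.append("  fixed effects:")
        for k, v in self.fe_params.items():
            if len(self.fe_params) > 12 and k.startswith("genotype["):
                continue
            lines.append(f"    {k:<18s} {v:12.6g}")
        if len(self.fe_params) > 12 and self.blues is not None:
            lines.append(f"    ({len(self.blues)} genotype BLUEs omitted)")
        return "\n".join(lines)


def fit_lmm(
    data: pd.DataFrame,
    A: PedigreeMatrix | None = None,
    genotype_as: str = "random",
    trait_col: str = "value",
    **kwargs,
) -> PhenoMixedModelResults:
    """Fit the multi-trial mixed model; see :class:`PhenoMixedModel`."""
    model = PhenoMixedModel(
        data, trait_col=trait_col, genotype_effect=genotype_as, A=A, **kwargs
    )
    return model.fit()


def cullis_h2(fit: PhenoMixedModelResults) -> float:
    """Cullis broad-sense heritability of a genotype-random fit."""
    return fit.cullis_h2()
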