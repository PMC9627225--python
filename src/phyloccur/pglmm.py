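"""Bernoulli phylogenetic generalized linear mixed model, fitted by PQL.

The model, for observation :math:`i` (a species-area pair):

.. math::

    Y_i \\sim \\mathrm{Bernoulli}(p_i), \\qquad
    \\mathrm{logit}(p_i) = x_i' \\beta + a_{spp_i} + b_{spp_i},

with two species-level random effects: an independent effect
:math:`a \\sim N(0, \\sigma_a^2 I_n)` and a phylogenetic effect
:math:`b \\sim N(0, \\sigma_b^2 \\Sigma_{spp})`, where ``Sigma_spp`` is the
Brownian-motion covariance of the phylogeny (shared root-to-MRCA branch
lengths, scaled to unit height).  Fixed effects are, by default, the two
trait composite scores, the environmental-stress score, the spatial
eigenvector, and the four trait-by-environment / trait-by-space interaction
products, plus an intercept.

Fitting uses penalized quasi-likelihood (PQL): the Bernoulli likelihood is
repeatedly linearized at the current linear predictor into a working
Gaussian model, whose variance parameters are updated by restricted maximum
likelihood and whose coefficients by generalized least squares; random-effect
conditional modes feed the next linearization.  All linear algebra works in
the n-species space via the Woodbury identity, so the cost per iteration is
O(n^3 + Np^2) rather than O(N^3).

Inference is by Wald tests on the GLS covariance of the coefficients;
prediction is conditional (fixed effects plus estimated species effects).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .composites import AreaStress, TraitScores
from .io import OccurrenceMatrix

__all__ = [
    "DesignMatrices",
    "PGLMMControl",
    "PGLMMResults",
    "PhyloBinaryGLMM",
    "build_design",
    "wald_table",
]

MAIN_COLUMNS = [
    "intercept", "pc1", "pc2", "stress", "mem",
    "pc1:stress", "pc2:stress", "pc1:mem", "pc2:mem",
]
INTERACTION_COLUMNS = ["intercept", "pc1:stress", "pc2:stress", "pc1:mem", "pc2:mem"]


@dataclass(frozen=True)
class DesignMatrices:
    """Long-format (species-major) response and design for the PGLMM.

    ``y`` is the stacked presence/absence vector of length N = n * m;
    ``X`` the fixed-effect matrix with named columns; ``species_index``
    maps each observation to its species (the indicator matrix Z is never
    materialized); ``species`` the species label order.
    """

    y: np.ndarray
    X: pd.DataFrame
    species_index: np.ndarray
    species: list[str]
    areas: list[str]

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_species(self) -> int:
        return len(self.species)


def build_design(
    occurrence: OccurrenceMatrix,
    trait_scores: TraitScores,
    stress: AreaStress,
    mem: pd.Series,
    include_main_effects: bool = True,
) -> DesignMatrices:
    """Assemble y, X and the species index in species-major order.

    Covariates: ``pc1`` (leaf/fruit size composite) and ``pc2`` (flower size
    vs height) vary by species; ``stress`` and ``mem`` (spatial eigenvector
    theta) vary by area; interactions are elementwise products.  With
    ``include_main_effects=False`` only the intercept and the four
    interactions enter, reproducing the model equation literally.
    """
    species = occurrence.species
    areas = occurrence.areas
    pc = trait_scores.data.loc[species]
    sv = stress.data.loc[areas].to_numpy(dtype=float)
    mv = mem.loc[areas].to_numpy(dtype=float)
    n, m = len(species), len(areas)

    pc1 = np.repeat(pc["pc1_leaf_fruit"].to_numpy(dtype=float), m)
    pc2 = np.repeat(pc["pc2_flower_vs_height"].to_numpy(dtype=float), m)
    stress_l = np.tile(sv, n)
    mem_l = np.tile(mv, n)
    cols = {
        "intercept": np.ones(n * m),
        "pc1": pc1,
        "pc2": pc2,
        "stress": stress_l,
        "mem": mem_l,
        "pc1:stress": pc1 * stress_l,
        "pc2:stress": pc2 * stress_l,
        "pc1:mem": pc1 * mem_l,
        "pc2:mem": pc2 * mem_l,
    }
    names = MAIN_COLUMNS if include_main_effects else INTERACTION_COLUMNS
    X = pd.DataFrame({c: cols[c] for c in names})
    if not np.isfinite(X.to_numpy()).all():
        raise ValueError("non-finite covariate in design matrix")
    y = occurrence.data.loc[species, areas].to_numpy(dtype=float).ravel()
    species_index = np.repeat(np.arange(n), m)
    return DesignMatrices(y=y, X=X, species_index=species_index,
                          species=list(species), areas=list(areas))


@dataclass
class PGLMMControl:
    """Numerical knobs for the PQL fit.

    ``max_outer_iter`` bounds the linearization loop; ``tol`` is the maximum
    absolute change in coefficients and variance components declaring
    convergence; variance components are optimized on the log scale by
    Nelder-Mead within ``variance_bounds``, with ``optimizer_restarts``
    extra starting points on the first outer iteration.
    """

    max_outer_iter: int = 50
    tol: float = 1e-6
    variance_bounds: tuple[float, float] = (0.0, 10.0)
    optimizer_restarts: int = 2
    nm_maxfev: int = 200
    mu_eps: float = 1e-10

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")


class PhyloBinaryGLMM:
    """Binary phylogenetic GLMM (statsmodels-style model object).

    Parameters
    ----------
    endog : array-like of 0/1, length N
    exog : DataFrame or array, N x p fixed-effect design
    species_index : int array, length N, mapping observations to species
    phylo_cov : DataFrame or array, n x n Brownian covariance (PSD,
        species order matching ``species_index`` codes)
    species : optional species labels

    Use :meth:`from_design` to build from a :class:`DesignMatrices`.
    ``fit`` returns a :class:`PGLMMResults`.
    """

    def __init__(self, endog, exog, species_index, phylo_cov, species=None):
        self.endog = np.asarray(endog, dtype=float)
        if not np.isin(self.endog, (0.0, 1.0)).all():
            raise ValueError("endog must be binary 0/1")
        if isinstance(exog, pd.DataFrame):
            self.exog_names = list(exog.columns)
            self.exog = exog.to_numpy(dtype=float)
        else:
            self.exog = np.asarray(exog, dtype=float)
            self.exog_names = [f"x{j}" for j in range(self.exog.shape[1])]
        self.species_index = np.asarray(species_index, dtype=int)
        if isinstance(phylo_cov, pd.DataFrame):
            self.phylo_cov = phylo_cov.to_numpy(dtype=float)
            default_species = list(phylo_cov.index)
        else:
            self.phylo_cov = np.asarray(phylo_cov, dtype=float)
            default_species = None
        self.n_species = self.phylo_cov.shape[0]
        self.species = list(species) if species is not None else (
            default_species or [f"sp{i}" for i in range(self.n_species)]
        )
        if self.species_index.max() >= self.n_species:
            raise ValueError("species_index exceeds phylo_cov dimension")
        if len(self.endog) != self.exog.shape[0] or len(self.endog) != len(self.species_index):
            raise ValueError("endog, exog and species_index lengths differ")
        if not np.allclose(self.phylo_cov, self.phylo_cov.T, atol=1e-8):
            raise ValueError("phylo_cov must be symmetric")

    @classmethod
    def from_design(cls, design: DesignMatrices, phylo_cov) -> "PhyloBinaryGLMM":
        if isinstance(phylo_cov, pd.DataFrame):
            phylo_cov = phylo_cov.loc[design.species, design.species]
        return cls(design.y, design.X, design.species_index, phylo_cov,
                   species=design.species)

    # -- working-model linear algebra (Woodbury, n-species space) ----------

    def _working_quantities(self, w, z):
        """Per-species aggregates of the weighted working model."""
        idx = self.species_index
        n = self.n_species
        X = self.exog
        d = np.bincount(idx, weights=w, minlength=n)            # Z'WZ diag
        XtWX = X.T @ (w[:, None] * X)
        ZtWX = np.zeros((n, X.shape[1]))
        for j in range(X.shape[1]):
            ZtWX[:, j] = np.bincount(idx, weights=w * X[:, j], minlength=n)
        ZtWz = np.bincount(idx, weights=w * z, minlength=n)
        XtWz = X.T @ (w * z)
        ztWz = float(z @ (w * z))
        return d, XtWX, ZtWX, ZtWz, XtWz, ztWz

    def _gls(self, sig_a, sig_b, d, XtWX, ZtWX, ZtWz, XtWz, ztWz):
        """GLS solve and REML pieces for V = W^-1 + Z C Z', C = sa I + sb S.

        Returns (beta, cov_beta, modes, reml_neg2, quad) where ``reml_neg2``
        lacks the log|W^-1| constant (irrelevant within one linearization).
        """
        n = self.n_species
        C = sig_a * np.eye(n) + sig_b * self.phylo_cov
        M = np.eye(n) + d[:, None] * C                    # I + (Z'WZ) C
        sign, logdetM = np.linalg.slogdet(M)
        if sign <= 0:
            return None
        K = C @ np.linalg.inv(M)                          # (C^-1 + D)^-1
        K = (K + K.T) / 2
        XtVX = XtWX - ZtWX.T @ K @ ZtWX
        XtVz = XtWz - ZtWX.T @ (K @ ZtWz)
        try:
            cov_beta = np.linalg.inv(XtVX)
        except np.linalg.LinAlgError:
            return None
        beta = cov_beta @ XtVz
        # r'V^-1 r with r = z - X beta, expanded in the aggregates
        quad = (ztWz - ZtWz @ K @ ZtWz
                - 2 * beta @ XtVz + beta @ XtVX @ beta)
        sign2, logdetXtVX = np.linalg.slogdet(XtVX)
        if sign2 <= 0:
            return None
        reml_neg2 = logdetM + logdetXtVX + quad
        # conditional modes: C Z'V^-1 r = C (I - D K) (Z'W r)
        t = ZtWz - ZtWX @ beta                            # Z'W r
        modes = C @ (t - d * (K @ t))
        return beta, cov_beta, modes, reml_neg2

    def _optimize_variances(self, theta0, free, d, agg, control, first):
        """REML update of the free components of (sigma_a^2, sigma_b^2).

        Optimization is Nelder-Mead on log(sigma^2 + eps) within the
        configured bounds; ``free`` is a boolean mask over (a, b), fixed
        components keep their ``theta0`` value.
        """
        lo, hi = control.variance_bounds
        eps = 1e-8
        free = np.asarray(free, dtype=bool)

        def expand(phi):
            theta = theta0.copy()
            theta[free] = np.clip(np.exp(phi) - eps, lo, hi)
            return theta

        def neg_reml(phi):
            sa, sb = expand(phi)
            out = self._gls(float(sa), float(sb), d, *agg)
            if out is None:
                return 1e10
            return out[3]

        k = int(free.sum())
        bounds = [(np.log(eps), np.log(hi + eps))] * k
        starts = [np.log(np.maximum(theta0[free], 0.0) + eps)]
        if first:
            extra = [0.1, 1.0][: max(control.optimizer_restarts, 0)]
            starts += [np.log(np.full(k, s) + eps) for s in extra]
        best = None
        for s0 in starts:
            res = optimize.minimize(
                neg_reml, s0, method="Nelder-Mead", bounds=bounds,
                options={"maxfev": control.nm_maxfev,
                         "xatol": 1e-8, "fatol": 1e-10},
            )
            if best is None or res.fun < best.fun:
                best = res
        return expand(best.x)

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        control: PGLMMControl | None = None,
        fix_sigma2_a: float | None = None,
        fix_sigma2_b: float | None = None,
    ) -> "PGLMMResults":
        """Run the PQL iteration.

        ``fix_sigma2_a`` / ``fix_sigma2_b`` pin a variance component instead
        of estimating it (both at 0 reduces the model to ordinary logistic
        regression, fitted by IRLS).
        """
        control = control or PGLMMControl()
        y, X, idx = self.endog, self.exog, self.species_index
        p = X.shape[1]
        if np.linalg.matrix_rank(X) < p:
            warnings.warn("design matrix is rank-deficient", stacklevel=2)
        beta = np.zeros(p)
        sig_a = 0.1 if fix_sigma2_a is None else float(fix_sigma2_a)
        sig_b = 0.1 if fix_sigma2_b is None else float(fix_sigma2_b)
        free = np.array([fix_sigma2_a is None, fix_sigma2_b is None])
        modes = np.zeros(self.n_species)
        cov_beta = np.eye(p)
        converged = False
        it = 0
        for it in range(1, control.max_outer_iter + 1):
            eta = X @ beta + modes[idx]
            mu = special.expit(eta)
            mu = np.clip(mu, control.mu_eps, 1 - control.mu_eps)
            w = mu * (1 - mu)
            z = eta + (y - mu) / w
            d, *agg = self._working_quantities(w, z)
            if free.any():
                sa_new, sb_new = self._optimize_variances(
                    np.array([sig_a, sig_b]), free, d, agg, control,
                    first=(it == 1))
            else:
                sa_new, sb_new = sig_a, sig_b
            out = self._gls(sa_new, sb_new, d, *agg)
            if out is None:
                warnings.warn("singular working model; stopping early",
                              stacklevel=2)
                break
            beta_new, cov_beta, modes, _ = out
            delta = max(
                float(np.max(np.abs(beta_new - beta))),
                abs(sa_new - sig_a), abs(sb_new - sig_b),
            )
            beta, sig_a, sig_b = beta_new, sa_new, sb_new
            if delta < control.tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"PQL did not converge in {it} outer iterations", stacklevel=2
            )
        eta = X @ beta + modes[idx]
        fitted_p = np.clip(special.expit(eta), control.mu_eps,
                           1 - control.mu_eps)
        se = np.sqrt(np.diag(cov_beta))
        return PGLMMResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            bse=pd.Series(se, index=self.exog_names),
            cov_params=pd.DataFrame(cov_beta, index=self.exog_names,
                                    columns=self.exog_names),
            sigma2_a=sig_a,
            sigma2_b=sig_b,
            conditional_modes=pd.Series(modes, index=self.species),
            fitted_p=fitted_p,
            converged=converged,
            n_iter=it,
        )


@dataclass
class PGLMMResults:
    """Fitted PGLMM: coefficients, Wald inference, variance components,
    species conditional modes (a-hat + b-hat) and conditional fitted
    probabilities."""

    model: PhyloBinaryGLMM
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    sigma2_a: float
    sigma2_b: float
    conditional_modes: pd.Series
    fitted_p: np.ndarray
    converged: bool
    n_iter: int

    @property
    def wald_z(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        z = self.wald_z
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=z.index)

    def wald_table(self) -> pd.DataFrame:
        """Per-coefficient estimate, SE, z and two-sided normal p."""
        tab = pd.DataFrame({
            "estimate": self.params,
            "std_error": self.bse,
            "z": self.wald_z,
            "p": self.pvalues,
        })
        bad = ~(self.bse > 0)
        if bad.any():
            tab.loc[bad, ["z", "p"]] = np.nan
        return tab

    def predict(self, design: DesignMatrices | None = None) -> np.ndarray:
        """Conditional predicted probabilities, logistic(X beta + modes).

        With no argument, returns the in-sample fitted probabilities; a new
        :class:`DesignMatrices` must reference the fitted species set.
        """
        if design is None:
            return self.fitted_p
        if list(design.X.columns) != list(self.params.index):
            raise ValueError("design columns do not match fitted coefficients")
        if design.n_species != len(self.conditional_modes):
            raise ValueError("design species set does not match the fit")
        eta = (design.X.to_numpy() @ self.params.to_numpy()
               + self.conditional_modes.to_numpy()[design.species_index])
        return special.expit(eta)

    def predict_matrix(self, design: DesignMatrices) -> pd.DataFrame:
        """Conditional predictions reshaped to species x areas."""
        p = self.predict(design)
        return pd.DataFrame(
            p.reshape(design.n_species, len(design.areas)),
            index=design.species, columns=design.areas,
        )

    def summary(self) -> str:
        lines = [
            "Binary phylogenetic GLMM (PQL)",
            "=" * 66,
            f"N obs: {len(self.model.endog):>6}   "
            f"species: {self.model.n_species:>5}   "
            f"converged: {self.converged} ({self.n_iter} iter)",
            f"sigma2_a (iid species): {self.sigma2_a:.4f}   "
            f"sigma2_b (phylogenetic): {self.sigma2_b:.4f}",
            "-" * 66,
            f"{'term':<12}{'estimate':>10}{'std_err':>10}{'z':>9}{'P>|z|':>9}",
        ]
        tab = self.wald_table()
        for name, row in tab.iterrows():
            lines.append(
                f"{name:<12}{row.estimate:>10.4f}{row.std_error:>10.4f}"
                f"{row.z:>9.3f}{row.p:>9.4f}"
            )
        lines.append("=" * 66)
        return "\n".join(lines)


def wald_table(fit: PGLMMResults) -> pd.DataFrame:
    """Functional alias for :meth:`PGLMMResults.wald_table`."""
    return fit.wald_table()
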