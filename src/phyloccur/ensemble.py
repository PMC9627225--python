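"""Rarefied model ensemble: repeated fits on equal-sized species subsets.

Species-rich areas share more species than poor ones simply through sample
size.  To control for this, the model is refitted on randomly drawn species
subsets whose size equals the richness of the least species-rich area
(25 draws by default).  Composite scores, the spatial eigenvector and the
imputed tree are computed once on the full data and subset afterwards; the
phylogenetic covariance of each subset is rescaled to unit maximum diagonal.
Per-coefficient effects and Wald p values are averaged across iterations; an
effect is called significant when its mean p falls below 0.05 (no
multiplicity correction).  Conditional occurrence predictions are averaged
per species over the iterations that sampled it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composites import AreaStress, TraitScores
from .io import OccurrenceMatrix
from .pglmm import PGLMMControl, PhyloBinaryGLMM, build_design

__all__ = [
    "EnsembleResult",
    "RarefiedEnsemble",
    "min_richness",
    "rarefied_ensemble",
    "summarize_ensemble",
]

SIGNIFICANCE_LEVEL = 0.05


def min_richness(occurrence: OccurrenceMatrix) -> int:
    """Richness of the least species-rich area (minimum column sum)."""
    return int(occurrence.richness().min())


@dataclass
class EnsembleResult:
    """Per-iteration and averaged output of the rarefied ensemble."""

    effects: pd.DataFrame          # iterations x coefficients
    pvalues: pd.DataFrame          # iterations x coefficients
    std_errors: pd.DataFrame       # iterations x coefficients
    predicted: pd.DataFrame        # species x areas, mean over iterations
    sampled_count: pd.Series       # iterations containing each species
    seeds: list[int]
    n_subset: int
    converged: pd.Series           # per-iteration flag

    @property
    def mean_effect(self) -> pd.Series:
        return self.effects.mean(axis=0)

    @property
    def mean_p(self) -> pd.Series:
        return self.pvalues.mean(axis=0)

    @property
    def significant(self) -> pd.Series:
        return self.mean_p < SIGNIFICANCE_LEVEL

    def summary(self) -> pd.DataFrame:
        """Coefficient table: mean effect, iteration spread, mean p, call."""
        return pd.DataFrame({
            "mean_effect": self.mean_effect,
            "sd_effect": self.effects.std(axis=0, ddof=1)
            if len(self.effects) > 1
            else pd.Series(0.0, index=self.effects.columns),
            "mean_p": self.mean_p,
            "significant": self.significant,
        })


def rarefied_ensemble(
    occurrence: OccurrenceMatrix,
    trait_scores: TraitScores,
    stress: AreaStress,
    mem: pd.Series,
    phylo_cov: pd.DataFrame,
    n_iter: int = 25,
    base_seed: int = 0,
    include_main_effects: bool = True,
    control: PGLMMControl | None = None,
    n_subset: int | None = None,
) -> EnsembleResult:
    """Fit the PGLMM on ``n_iter`` random species subsets and average.

    Iteration ``t`` seeds its own generator with ``base_seed + t`` and draws
    ``n_subset`` species (default: the minimum area richness) uniformly
    without replacement from the sorted full species pool, so results do not
    depend on input row order.
    """
    species_pool = sorted(occurrence.species)
    if n_subset is None:
        n_subset = min_richness(occurrence)
    n_params = 9 if include_main_effects else 5
    if n_subset < n_params:
        raise ValueError(
            f"subset size {n_subset} is below the number of coefficients "
            f"({n_params}); use fewer model terms"
        )
    effects, pvals, ses, conv = [], [], [], []
    seeds = []
    pred_sum = pd.DataFrame(0.0, index=species_pool,
                            columns=occurrence.areas)
    count = pd.Series(0, index=species_pool)
    for t in range(n_iter):
        seed = base_seed + t
        seeds.append(seed)
        rng = np.random.default_rng(seed)
        subset = sorted(rng.choice(species_pool, size=n_subset,
                                   replace=False))
        occ_sub = OccurrenceMatrix(data=occurrence.data.loc[subset])
        sig_sub = phylo_cov.loc[subset, subset]
        sig_sub = sig_sub / np.diag(sig_sub.to_numpy()).max()
        design = build_design(occ_sub, trait_scores, stress, mem,
                              include_main_effects=include_main_effects)
        fit = PhyloBinaryGLMM.from_design(design, sig_sub).fit(control=control)
        effects.append(fit.params)
        pvals.append(fit.pvalues)
        ses.append(fit.bse)
        conv.append(fit.converged)
        pred_sum.loc[subset] += fit.predict_matrix(design)
        count.loc[subset] += 1
    idx = pd.RangeIndex(n_iter, name="iteration")
    predicted = pred_sum.div(count, axis=0)  # NaN where never sampled
    return EnsembleResult(
        effects=pd.DataFrame(effects, index=idx),
        pvalues=pd.DataFrame(pvals, index=idx),
        std_errors=pd.DataFrame(ses, index=idx),
        predicted=predicted,
        sampled_count=count,
        seeds=seeds,
        n_subset=n_subset,
        converged=pd.Series(conv, index=idx),
    )


def summarize_ensemble(result: EnsembleResult) -> pd.DataFrame:
    """Functional alias for :meth:`EnsembleResult.summary`."""
    return result.summary()


class RarefiedEnsemble:
    """Model-object wrapper around :func:`rarefied_ensemble`.

    Holds the full-data inputs; :meth:`fit` runs the resampling protocol and
    returns an :class:`EnsembleResult`.
    """

    def __init__(self, occurrence, trait_scores, stress, mem, phylo_cov,
                 include_main_effects: bool = True):
        self.occurrence = occurrence
        self.trait_scores = trait_scores
        self.stress = stress
        self.mem = mem
        self.phylo_cov = phylo_cov
        self.include_main_effects = include_main_effects

    def fit(self, n_iter: int = 25, base_seed: int = 0,
            control: PGLMMControl | None = None,
            n_subset: int | None = None) -> EnsembleResult:
        return rarefied_ensemble(
            self.occurrence, self.trait_scores, self.stress, self.mem,
            self.phylo_cov, n_iter=n_iter, base_seed=base_seed,
            include_main_effects=self.include_main_effects,
            control=control, n_subset=n_subset,
        )
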