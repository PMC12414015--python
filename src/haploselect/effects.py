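"""Phenotype adjustment, trial heritability, and RR-BLUP marker effects.

The workflow mirrors a replicated single-site field trial analysed for
genomic selection:

1. :func:`compute_blues` — fixed-effect genotype means (genotype + replicate
   OLS), the per-line phenotypes used to train marker effects.
2. :func:`estimate_heritability` — broad-sense heritability of genotype means
   from a balanced one-way random-effects ANOVA/REML.
3. :func:`fit_rrblup` — ridge-regression BLUP of all marker effects jointly,
   ``(W'W + lambda I) u = W'(y - mu)``, with the shrinkage ratio
   ``lambda = sigma_e^2 / sigma_u^2`` either fixed or chosen by restricted
   maximum likelihood on a log-spaced grid.
4. :func:`gebv` — genomic estimated breeding values, ``mu + D u``.

Trait direction is resolved once, by :func:`desirability_transform`: for a
"lower is better" trait (e.g. a 1-9 disease severity score) marker effects
are negated so every downstream group-fitness function simply maximizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import EffectsTable, HaplotypePanel, PhenotypeTable, dosage_matrix
from .errors import ConfoundingError, ParameterError

__all__ = [
    "MixedModelSpec",
    "HeritabilityEstimate",
    "compute_blues",
    "estimate_heritability",
    "fit_rrblup",
    "gebv",
    "desirability_transform",
]


@dataclass(frozen=True)
class MixedModelSpec:
    """RR-BLUP shrinkage specification and trait direction.

    ``lambda_ratio`` is the residual-to-marker variance ratio; the string
    ``"reml"`` requests a grid REML estimate instead of a fixed value.
    """

    lambda_ratio: float | str = "reml"
    trait_direction: str = "minimize"

    def __post_init__(self) -> None:
        if isinstance(self.lambda_ratio, str):
            if self.lambda_ratio != "reml":
                raise ParameterError("lambda_ratio must be positive or 'reml'")
        elif not (np.isfinite(self.lambda_ratio) and self.lambda_ratio > 0):
            raise ParameterError("lambda_ratio must be finite and > 0")
        if self.trait_direction not in ("minimize", "maximize"):
            raise ParameterError("trait_direction must be minimize|maximize")


@dataclass(frozen=True)
class HeritabilityEstimate:
    sigma2_g: float
    sigma2_e: float
    H2: float  # genotype-mean basis: s2g / (s2g + s2e / mean replicates)


def compute_blues(pheno: PhenotypeTable) -> pd.Series:
    """Least-squares genotype means adjusted for an additive replicate effect.

    Fits ``score ~ genotype + replicate`` (both fixed) and reports, per
    genotype, its fitted value averaged over all replicate levels.  For
    balanced data with no replicate effect this is the arithmetic mean; with
    a single replicate it is the raw score.
    """
    df = pheno.data
    genos = pd.unique(df["individual_id"])
    reps = np.sort(pd.unique(df["replicate"]))
    g_idx = {g: i for i, g in enumerate(genos)}
    r_idx = {r: i for i, r in enumerate(reps)}
    n_obs, n_g, n_r = len(df), len(genos), len(reps)

    # Design: genotype dummies (no global intercept) + replicate deviations
    # (first level as reference).
    x = np.zeros((n_obs, n_g + n_r - 1))
    for row, (g, r) in enumerate(zip(df["individual_id"], df["replicate"])):
        x[row, g_idx[g]] = 1.0
        if r_idx[r] > 0:
            x[row, n_g + r_idx[r] - 1] = 1.0
    expected_rank = n_g + n_r - 1
    if np.linalg.matrix_rank(x) < expected_rank:
        raise ConfoundingError("genotype and replicate effects are confounded")
    beta, *_ = np.linalg.lstsq(x, df["score"].to_numpy(float), rcond=None)
    rep_effects = np.concatenate([[0.0], beta[n_g:]])
    blues = beta[:n_g] + rep_effects.mean()
    return pd.Series(blues, index=pd.Index(genos, name="individual_id"), name="blue")


def estimate_heritability(pheno: PhenotypeTable) -> HeritabilityEstimate:
    """Broad-sense heritability of genotype means from one-way random-effects REML.

    In the balanced case this is the expected-mean-squares closed form:
    ``sigma2_g = max(0, (MSG - MSE) / r)``; H2 is reported on the
    genotype-mean basis ``s2g / (s2g + s2e / r_bar)``.
    """
    df = pheno.data
    groups = df.groupby("individual_id")["score"]
    counts = groups.count()
    n_g = len(counts)
    n = len(df)
    if n_g < 2:
        raise ParameterError("need >= 2 genotypes for heritability")
    if n - n_g < 1:
        raise ParameterError("need replication (> 1 observation somewhere)")
    grand = df["score"].mean()
    means = groups.mean()
    ss_between = float((counts * (means - grand) ** 2).sum())
    ss_within = float(((df["score"] - df["individual_id"].map(means)) ** 2).sum())
    msg = ss_between / (n_g - 1)
    mse = ss_within / (n - n_g)
    r_bar = n / n_g
    # balanced EMS; for mildly unbalanced data use the standard n0 coefficient
    n0 = (n - float((counts**2).sum()) / n) / (n_g - 1)
    sigma2_e = mse
    sigma2_g = max(0.0, (msg - mse) / n0)
    denom = sigma2_g + sigma2_e / r_bar
    if denom <= 0:
        warnings.warn("zero total variance; reporting H2 = 0", stacklevel=2)
        return HeritabilityEstimate(0.0, 0.0, 0.0)
    return HeritabilityEstimate(sigma2_g, sigma2_e, sigma2_g / denom)


def _reml_lambda_grid(
    w: np.ndarray, y: np.ndarray, grid: np.ndarray
) -> float:
    """Restricted likelihood grid search for the ridge ratio lambda.

    Model: y = 1 mu + g + e with g ~ N(0, s2u W W'), e ~ N(0, s2e I) and
    lambda = s2e / s2u.  The restricted likelihood is profiled over the
    variance scale using the eigenvalues of the intercept-projected W W'.
    """
    n = len(y)
    p = np.eye(n) - np.full((n, n), 1.0 / n)  # projection removing the mean
    k = w @ w.T
    pkp = p @ k @ p
    eigval, eigvec = np.linalg.eigh(pkp)
    # drop the single zero eigenvalue from the intercept projection
    order = np.argsort(eigval)[::-1]
    eigval = np.maximum(eigval[order][: n - 1], 0.0)
    eta = (eigvec[:, order][:, : n - 1].T @ (p @ y))
    df = n - 1
    best_ll, best_lam = -np.inf, grid[0]
    for lam in grid:
        d = eigval + lam
        s2 = float(np.sum(eta**2 / d)) / df
        ll = -0.5 * (df * np.log(s2) + float(np.sum(np.log(d))))
        if ll > best_ll:
            best_ll, best_lam = ll, float(lam)
    return best_lam


def fit_rrblup(
    panel: HaplotypePanel,
    blues: pd.Series | np.ndarray,
    spec: MixedModelSpec = MixedModelSpec(),
) -> EffectsTable:
    """Ridge-regression BLUP of marker effects from per-line phenotypes.

    Solves ``(W'W + lambda I) u = W'(y - mu)`` with W the column-centred
    dosage matrix and ``mu`` the phenotype mean.  With ``spec.lambda_ratio ==
    "reml"`` the ratio is chosen by maximizing the restricted likelihood on a
    log-spaced grid.  ``lambda_ratio = 0`` is rejected; pass a small positive
    value for near-OLS behaviour.
    """
    if isinstance(blues, pd.Series):
        blues = blues.reindex(panel.individual_ids)
        if blues.isna().any():
            raise ParameterError("BLUEs missing for some panel individuals")
        y = blues.to_numpy(float)
    else:
        y = np.asarray(blues, dtype=float)
    if len(y) != panel.n_individuals:
        raise ParameterError("phenotype length does not match panel")
    if panel.n_individuals < 2:
        raise ParameterError("need >= 2 individuals for RR-BLUP")

    d = dosage_matrix(panel).astype(float)
    w = d - d.mean(axis=0, keepdims=True)
    mu = float(y.mean())
    yc = y - mu
    if spec.lambda_ratio == "reml":
        grid = np.logspace(-5, 7, 121)
        lam = _reml_lambda_grid(w, yc, grid)
    else:
        lam = float(spec.lambda_ratio)
    m = w.shape[1]
    lhs = w.T @ w + lam * np.eye(m)
    u = np.linalg.solve(lhs, w.T @ yc)
    return EffectsTable(mu, u, panel.map.marker_id.copy())


def gebv(panel: HaplotypePanel, effects: EffectsTable) -> pd.Series:
    """Genomic estimated breeding values: intercept + dosage x effect."""
    effects.check_alignment(panel)
    vals = effects.intercept + dosage_matrix(panel).astype(float) @ effects.effect
    return pd.Series(vals, index=pd.Index(panel.individual_ids, name="individual_id"),
                     name="gebv")


def desirability_transform(effects: EffectsTable, direction: str) -> EffectsTable:
    """Orient effects so that maximizing group fitness favours the trait goal.

    ``maximize`` is the identity; ``minimize`` negates every marker effect
    (intercept untouched), an involution.
    """
    if direction == "maximize":
        return EffectsTable(effects.intercept, effects.effect.copy(),
                            None if effects.marker_ids is None else effects.marker_ids.copy())
    if direction == "minimize":
        return EffectsTable(effects.intercept, -effects.effect,
                            None if effects.marker_ids is None else effects.marker_ids.copy())
    raise ParameterError("direction must be minimize|maximize")
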