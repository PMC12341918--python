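"""Cross evaluation: clonal values, cross means/variances, progeny sizing.

Two clonal-value estimates are used, mirroring how banana hybrids and their
repeated controls must be compared:

* ``yhat`` — BLUE + BLUP composite ``m + D_u + T_v + (DxT)_uv + H_th``; its
  BLUP shrinkage differs strongly between once-planted hybrids and heavily
  replicated controls;
* ``ytilde`` — the mean of the hybrid's phenotypes corrected for block and
  cycle effects, shrinkage-free and therefore comparable across replication
  levels; used for cross means compared against the Cavendish threshold.

``min_progeny_size`` converts a cross's mean and standard deviation into
the minimum number of progeny needed to obtain, with probability ``p``, at
least one offspring beating a reference value under a normal progeny
distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .lmm import ModelFit
from .models import MIN_PROGENY_FOR_CROSS_VARIANCE, ModelBundle
from .traits import trait_direction


@dataclass
class ClonalValues:
    """Per-genotype clonal value estimates for one trait."""

    table: pd.DataFrame  # index: genotype; yhat, ytilde, n_obs, type, parents
    m_hat: float
    trait: str

    def breed(self) -> pd.DataFrame:
        return self.table[self.table["type"] == "breed"]


def estimate_values(fit: ModelFit, bundle: ModelBundle) -> ClonalValues:
    """Clonal values of every phenotyped genotype under a converged fit.

    ``m_hat`` reconstructs the general mean ``mu + mean(alpha) + mean(beta)``
    independently of the identifiability constraint; ``ytilde`` averages the
    genotype's observations corrected by the fitted block and cycle effects
    (controls average over all their replicates).
    """
    beta = fit.fixed_effects
    obs = bundle.obs
    blocks = sorted(obs["block_id"].unique())
    cycles = sorted(obs["cycle"].unique())
    alpha = {b: beta.get(f"block[{b}]", 0.0) for b in blocks}
    gamma = {c: beta.get(f"cycle[{c}]", 0.0) for c in cycles}
    m_hat = (beta["intercept"] + sum(alpha.values()) / len(blocks)
             + sum(gamma.values()) / len(cycles))
    # centre the effect estimates so ytilde does not depend on the
    # identifiability constraint (adding a constant to all alpha and
    # removing it from the intercept leaves the corrections unchanged)
    a_bar = sum(alpha.values()) / len(blocks)
    g_bar = sum(gamma.values()) / len(cycles)
    alpha = {b: a - a_bar for b, a in alpha.items()}
    gamma = {c: g - g_bar for c, g in gamma.items()}

    corrected = (obs["value"]
                 - obs["block_id"].map(alpha)
                 - obs["cycle"].map(gamma))
    ytilde = corrected.groupby(obs["genotype_id"]).mean()
    n_obs = corrected.groupby(obs["genotype_id"]).size()

    gca2 = fit.blups.get("gca2")
    gca4 = fit.blups.get("gca4")
    sca = fit.blups.get("sca")
    sca_dom = fit.blups.get("sca_dom")
    sca_epi = fit.blups.get("sca_epi")
    ctl = fit.blups.get("control")
    coef_F = beta.get("F", 0.0)

    rows = []
    breed_ids = set(obs.loc[obs["type"] == "breed", "plant_id"])
    for h in sorted(breed_ids):
        u, v = bundle.cross_of_hybrid[h]
        yhat = m_hat + gca2[u] + gca4[v]
        if sca is not None:
            yhat += sca[(u, v)]
        if sca_dom is not None:
            yhat += sca_dom[(u, v)] + coef_F * bundle.F_of_cross[(u, v)]
        if sca_epi is not None:
            yhat += sca_epi[(u, v)]
        if fit.absorbed_blups is not None and h in fit.absorbed_blups.index:
            yhat += fit.absorbed_blups[h]
        rows.append((h, "breed", u, v, yhat))
    for g in bundle.levels["control"]:
        rows.append((g, "control", None, None,
                     m_hat + (ctl[g] if ctl is not None else 0.0)))

    table = pd.DataFrame(
        rows, columns=["genotype", "type", "parent2x_id", "parent4x_id",
                       "yhat"],
    ).set_index("genotype")
    table["ytilde"] = ytilde
    table["n_obs"] = n_obs
    return ClonalValues(table=table, m_hat=float(m_hat), trait=bundle.trait)


@dataclass
class CrossSummary:
    """Per-cross means, SDs and progeny counts for one trait."""

    table: pd.DataFrame  # index: (parent2x, parent4x)
    trait: str
    min_progeny: int


def cross_summaries(
    values: ClonalValues,
    fit_cross_specific: ModelFit,
    bundle: ModelBundle,
    min_progeny: int = MIN_PROGENY_FOR_CROSS_VARIANCE,
) -> CrossSummary:
    """Cross means (from ``ytilde``) and cross-specific within-cross SDs.

    ``fit_cross_specific`` must come from a model with one within-cross
    variance per cross holding at least ``min_progeny`` progeny (smaller
    crosses are pooled).  Null variance estimates are reported as 0 with the
    ``variance_on_boundary`` flag set.
    """
    breed = values.breed()
    grp = breed.groupby(["parent2x_id", "parent4x_id"])
    out = grp.agg(
        mean_ytilde=("ytilde", "mean"),
        mean_yhat=("yhat", "mean"),
        n_progeny=("ytilde", "size"),
    )
    v = fit_cross_specific.variances
    lb = 2.0 * 1e-10 * fit_cross_specific.model.scale
    sds, pooled_flag, bnd = [], [], []
    for (u, _v4) in out.index:
        name = f"sigma2_H[{u}x{_v4}]"
        if name in v:
            var = v[name]
            pooled_flag.append(False)
        else:
            var = v.get("sigma2_H[pooled]", v.get("sigma2_H", 0.0))
            pooled_flag.append(True)
        bnd.append(var <= lb)
        sds.append(math.sqrt(max(var, 0.0)))
    out["sd"] = sds
    out["pooled_variance"] = pooled_flag
    out["variance_on_boundary"] = bnd
    out.loc[out["variance_on_boundary"], "sd"] = 0.0
    return CrossSummary(table=out, trait=values.trait,
                        min_progeny=min_progeny)


NOT_ATTAINABLE = float("inf")


def min_progeny_size(
    mu: float, sigma: float, yref: float, p: float = 0.9,
    direction: str = "higher",
) -> float:
    """Minimum progeny size to beat ``yref`` at least once with probability p.

    Progeny values are N(mu, sigma^2); with ``q`` the per-offspring
    probability of *failing* to beat the threshold,
    ``Nmin = ceil(log(1 - p) / log(q))``.  Degenerate cases: ``q = 0`` gives
    1 (a single offspring suffices), ``q = 1`` gives ``inf`` (not
    attainable); ``sigma = 0`` reduces to these according to whether the
    cross mean already beats the threshold.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly between 0 and 1")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if direction not in ("higher", "lower"):
        raise ValueError("direction must be 'higher' or 'lower'")
    if sigma == 0.0:
        better = mu > yref if direction == "higher" else mu < yref
        return 1.0 if better else NOT_ATTAINABLE
    z = (yref - mu) / sigma
    q = stats.norm.cdf(z) if direction == "higher" else stats.norm.sf(z)
    if q <= 0.0:
        return 1.0
    if q >= 1.0:
        return NOT_ATTAINABLE
    return float(math.ceil(math.log(1.0 - p) / math.log(q)))


def min_progeny_table(
    summary: CrossSummary,
    yref: dict[str, float] | float,
    p: float = 0.9,
    trait: str | None = None,
) -> pd.DataFrame:
    """Nmin per cross against a per-trait reference (the Cavendish value)."""
    trait = trait or summary.trait
    direction = trait_direction(trait)
    if direction == "none":
        raise ValueError(
            f"trait {trait!r} is descriptive and carries no ideotype direction"
        )
    ref = yref[trait] if isinstance(yref, dict) else float(yref)
    tab = summary.table.copy()
    tab["yref"] = ref
    tab["direction"] = direction
    tab["n_min"] = [
        min_progeny_size(m, s, ref, p=p, direction=direction)
        for m, s in zip(tab["mean_ytilde"], tab["sd"])
    ]
    return tab


def genotypic_correlations(
    values_by_trait: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pearson correlations between traits over breed-hybrid clonal values.

    Returns (r, p, retained) matrices; the retained mask applies a Holm
    (sequential Bonferroni) correction at family level ``alpha`` across all
    trait pairs.  Pairs with a constant trait vector get NaN and are flagged
    as not retained.
    """
    traits = list(values_by_trait.columns)
    k = len(traits)
    r = pd.DataFrame(np.eye(k), index=traits, columns=traits)
    pmat = pd.DataFrame(np.zeros((k, k)), index=traits, columns=traits)
    pairs, pvals = [], []
    for i in range(k):
        for j in range(i + 1, k):
            x = values_by_trait.iloc[:, i]
            y = values_by_trait.iloc[:, j]
            ok = x.notna() & y.notna()
            if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = stats.pearsonr(x[ok], y[ok])
            r.iloc[i, j] = r.iloc[j, i] = rij
            pmat.iloc[i, j] = pmat.iloc[j, i] = pij
            pairs.append((i, j))
            pvals.append(pij)
    finite = np.isfinite(pvals)
    keep = np.zeros(len(pvals), dtype=bool)
    if finite.any():
        keep[finite] = multipletests(
            np.asarray(pvals)[finite], alpha=alpha, method="holm")[0]
    retained = pd.DataFrame(np.zeros((k, k), dtype=bool),
                            index=traits, columns=traits)
    for (i, j), kp in zip(pairs, keep):
        retained.iloc[i, j] = retained.iloc[j, i] = bool(kp)
    return r, pmat, retained


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained: pd.Series           # percentage of total variance per axis
    trait_correlations: pd.DataFrame


def pca_cross_means(
    mean_matrix: pd.DataFrame, standardize: bool = True, n_components=None
) -> PCAResult:
    """PCA of the cross-mean (and control) performance over all traits.

    Traits are standardised to unit variance before decomposition.  Rows
    with any missing trait mean are rejected with the list of gaps.
    """
    if mean_matrix.isna().any().any():
        gaps = [
            (str(ix), c) for ix, row in mean_matrix.iterrows()
            for c, bad in row.isna().items() if bad
        ]
        raise ValueError(f"missing trait means: {gaps}")
    Xc = mean_matrix - mean_matrix.mean()
    if standardize:
        Xc = Xc / mean_matrix.std(ddof=1)
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(Xc.to_numpy())
    axes = [f"PC{i + 1}" for i in range(scores.shape[1])]
    scores = pd.DataFrame(scores, index=mean_matrix.index, columns=axes)
    loadings = pd.DataFrame(pca.components_.T,
                            index=mean_matrix.columns, columns=axes)
    explained = pd.Series(100.0 * pca.explained_variance_ratio_, index=axes)
    corr = pd.DataFrame(
        {ax: [stats.pearsonr(Xc[t], scores[ax])[0]
              if scores[ax].std() > 0 else np.nan
              for t in mean_matrix.columns] for ax in axes},
        index=mean_matrix.columns,
    )
    return PCAResult(scores=scores, loadings=loadings, explained=explained,
                     trait_correlations=corr)
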