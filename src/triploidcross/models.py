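"""Assembly of the 2x-4x model variants and heritability partitioning.

The observation model for a trait is::

    y_bcuvthr = mu + alpha_b + beta_c + D_u + T_v + (DxT)_uv + H_th + e

with fixed block and crop-cycle effects, random GCA effects of the diploid
(``D``) and tetraploid (``T``) parent, a random SCA effect of the parent
combination, a within-cross hybrid effect ``H`` shared in variance with the
repeated control varieties, and an unstructured residual covariance between
the three crop cycles of a plant.

Variants differ in the covariance structures attached to the genetic terms:

* ``PHENO`` — identity structures everywhere (pedigree information only);
* ``GCA_A`` — GCA terms carry the additive GRMs ``AD`` and ``AT``;
* ``GCA_A_SCA_D`` — adds the dominance SCA term with covariance ``D`` and
  mean ``-F b`` (the expected-inbreeding covariate ``F`` enters the fixed
  design with coefficient ``-b``);
* ``GCA_A_SCA_AA`` — adds the across-population epistasis SCA term with the
  Kronecker-derived covariance instead of dominance;
* ``GCA_A_SCA_D_AA`` — both SCA components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import KinshipSet
from .lmm import AbsorbedTerm, MixedModel, ModelFit, RandomTerm, lr_test
from .tables import StudyTables

VARIANTS = ("PHENO", "GCA_A", "GCA_A_SCA_D", "GCA_A_SCA_AA", "GCA_A_SCA_D_AA")
MIN_PROGENY_FOR_CROSS_VARIANCE = 16  # "more than 15 progenies"


@dataclass
class ModelBundle:
    """A mixed model plus the design metadata needed to interpret its fit."""

    model: MixedModel
    obs: pd.DataFrame
    variant: str
    trait: str
    x_groups: dict[str, list[int]]
    levels: dict[str, list]
    cross_of_hybrid: dict[str, tuple[str, str]]
    F_of_cross: dict[tuple[str, str], float] = field(default_factory=dict)
    kinships: KinshipSet | None = None

    def fit(self, **kwargs) -> ModelFit:
        return self.model.fit(**kwargs)


def _fixed_design(obs: pd.DataFrame, f_values: np.ndarray | None):
    blocks = sorted(obs["block_id"].unique())
    cycles = sorted(obs["cycle"].unique())
    cols = [np.ones(len(obs))]
    names = ["intercept"]
    groups: dict[str, list[int]] = {"intercept": [0], "block": [], "cycle": []}
    for b in blocks[1:]:
        groups["block"].append(len(cols))
        names.append(f"block[{b}]")
        cols.append((obs["block_id"] == b).to_numpy(float))
    for c in cycles[1:]:
        groups["cycle"].append(len(cols))
        names.append(f"cycle[{c}]")
        cols.append((obs["cycle"] == c).to_numpy(float))
    if f_values is not None:
        groups["F"] = [len(cols)]
        names.append("F")
        cols.append(f_values)
    X = np.column_stack(cols)
    return X, names, groups, len(blocks), len(cycles)


def build_model(
    variant: str,
    tables: StudyTables,
    trait: str,
    kinships: KinshipSet | None = None,
    cross_specific_variance: bool = False,
    exclude_crosses: list[tuple[str, str]] | None = None,
    min_progeny: int = MIN_PROGENY_FOR_CROSS_VARIANCE,
) -> ModelBundle:
    """Assemble the mixed model for one trait under a model variant.

    ``exclude_crosses`` drops all phenotypes of the listed crosses from the
    observation vector (their levels remain in the random terms, which is
    how held-out crosses are predicted).  ``cross_specific_variance``
    replaces the common within-cross variance by one parameter per cross
    with at least ``min_progeny`` progeny plus one pooled parameter.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}")
    genomic = variant != "PHENO"
    if genomic and kinships is None:
        raise ValueError(f"variant {variant} requires a KinshipSet")

    obs = tables.trait_observations(trait)
    obs = obs[obs["value"].notna()].copy()
    is_breed = (obs["type"] == "breed").to_numpy()

    ped = tables.pedigree
    cross_of_hybrid = {
        r.hybrid_id: (r.parent2x_id, r.parent4x_id) for r in ped.itertuples()
    }
    if genomic:
        known = set(kinships.crosses)
        orphan = sorted({
            h for h, cr in cross_of_hybrid.items() if cr not in known
        })
        if orphan:
            raise ValueError(
                f"hybrids whose parents lack genomic information: {orphan[:10]}"
                + ("..." if len(orphan) > 10 else "")
            )
        p2_levels = list(kinships.parents2x)
        p4_levels = list(kinships.parents4x)
        cross_levels = list(kinships.crosses)
    else:
        p2_levels = sorted(ped["parent2x_id"].unique())
        p4_levels = sorted(ped["parent4x_id"].unique())
        cross_levels = sorted({cr for cr in cross_of_hybrid.values()})

    if exclude_crosses:
        excl = set(exclude_crosses)
        keep = np.array([
            (not is_breed[i]) or cross_of_hybrid.get(h) not in excl
            for i, h in enumerate(obs["plant_id"])
        ])
        obs = obs[keep].copy()
        is_breed = (obs["type"] == "breed").to_numpy()

    i2 = {p: i for i, p in enumerate(p2_levels)}
    i4 = {p: i for i, p in enumerate(p4_levels)}
    ic = {c: i for i, c in enumerate(cross_levels)}

    cross_arr = [
        cross_of_hybrid.get(h) if b else None
        for h, b in zip(obs["plant_id"], is_breed)
    ]
    zD = np.array([i2[c[0]] if c else -1 for c in cross_arr])
    zT = np.array([i4[c[1]] if c else -1 for c in cross_arr])
    zC = np.array([ic[c] if c else -1 for c in cross_arr])

    F_of_cross: dict[tuple[str, str], float] = {}
    f_values = None
    if variant in ("GCA_A_SCA_D", "GCA_A_SCA_D_AA"):
        F_of_cross = dict(zip(kinships.crosses, kinships.F))
        f_values = np.array([F_of_cross[c] if c else 0.0 for c in cross_arr])

    X, x_names, x_groups, _, _ = _fixed_design(obs, f_values)

    terms = [
        RandomTerm("gca2", p2_levels, zD,
                   G=kinships.AD if genomic else None, variance="sigma2_D"),
        RandomTerm("gca4", p4_levels, zT,
                   G=kinships.AT if genomic else None, variance="sigma2_T"),
    ]
    if variant in ("PHENO", "GCA_A"):
        terms.append(RandomTerm("sca", cross_levels, zC, variance="sigma2_DT"))
    if variant in ("GCA_A_SCA_D", "GCA_A_SCA_D_AA"):
        terms.append(RandomTerm("sca_dom", cross_levels, zC,
                                G=kinships.Dmat, variance="sigma2_DTdom"))
    if variant in ("GCA_A_SCA_AA", "GCA_A_SCA_D_AA"):
        terms.append(RandomTerm("sca_epi", cross_levels, zC,
                                G=kinships.Kepi, variance="sigma2_DTepi"))

    # within-cross hybrid effect: absorbed for breed plants, explicit levels
    # for the repeated control varieties, sharing the same variance
    progeny = ped.groupby(["parent2x_id", "parent4x_id"]).size()
    if cross_specific_variance:
        big = {cr for cr, nn in progeny.items() if nn >= min_progeny}
        group = np.array([
            (f"{c[0]}x{c[1]}" if c in big else "pooled") if c else None
            for c in cross_arr
        ], dtype=object)
        vmap = {g: (f"sigma2_H[{g}]" if g != "pooled" else "sigma2_H[pooled]")
                for g in {x for x in group if x is not None}}
        hyb = AbsorbedTerm("hybrid", group=group, variance_of=vmap)
        ctl_variance = "sigma2_H[pooled]"
    else:
        group = np.array([("all" if c else None) for c in cross_arr],
                         dtype=object)
        hyb = AbsorbedTerm("hybrid", group=group,
                           variance_of={"all": "sigma2_H"})
        ctl_variance = "sigma2_H"

    ctl_levels = sorted(obs.loc[~is_breed, "genotype_id"].unique())
    if ctl_levels:
        ictl = {g: i for i, g in enumerate(ctl_levels)}
        zH = np.array([
            ictl[g] if not b else -1
            for g, b in zip(obs["genotype_id"], is_breed)
        ])
        terms.append(RandomTerm("control", ctl_levels, zH,
                                variance=ctl_variance))

    model = MixedModel(
        y=obs["value"].to_numpy(float),
        X=X,
        plant=obs["unit_id"].to_numpy(),
        cycle=obs["cycle"].to_numpy(int),
        random=terms,
        absorbed=hyb,
        n_cycles=3,
        x_names=x_names,
    )
    return ModelBundle(
        model=model, obs=obs, variant=variant, trait=trait,
        x_groups=x_groups,
        levels={"gca2": p2_levels, "gca4": p4_levels, "cross": cross_levels,
                "control": ctl_levels},
        cross_of_hybrid=cross_of_hybrid,
        F_of_cross=F_of_cross,
        kinships=kinships,
    )


# -- heritability ----------------------------------------------------------


@dataclass
class HeritabilityReport:
    trait: str
    variant: str
    H2: float
    contributions: dict[str, float]
    expected_VG: float
    expected_VE: float
    n_hybrids: int

    def as_series(self) -> pd.Series:
        s = {"trait": self.trait, "variant": self.variant, "H2": self.H2,
             "E_VG": self.expected_VG, "E_VE": self.expected_VE}
        s.update({f"h2_{k}": v for k, v in self.contributions.items()})
        return pd.Series(s)


def _centered_quadratic(Z: np.ndarray, G: np.ndarray | None,
                        mu: np.ndarray | None, N: int) -> float:
    """(Tr(Z'CZ G) + mu'Z'CZ mu) / (N - 1) with C the centering projector."""
    colsum = Z.sum(axis=0)
    ZtZ_c = Z.T @ Z - np.outer(colsum, colsum) / N
    tr = float(np.trace(ZtZ_c)) if G is None else float(np.sum(ZtZ_c * G.T))
    out = tr
    if mu is not None:
        v = Z @ mu
        v = v - v.mean()
        out += float(v @ v)
    return out / (N - 1)


def heritability(fit: ModelFit, bundle: ModelBundle) -> HeritabilityReport:
    """Broad-sense heritability among the evaluated breeding hybrids.

    ``E(VG)`` is the expectation of the empirical variance of each genetic
    component over the N breed hybrids (controls excluded), obtained from
    the quadratic-form identity with plug-in REML estimates; the dominance
    SCA term contributes its mean ``-F b`` as well as its variance.
    ``E(V_Ebar)`` is the variance of the cycle-averaged error,
    ``sum_cc' R_cc' / 9``.
    """
    hybrids = sorted(
        h for h in bundle.cross_of_hybrid
        if h in set(bundle.obs.loc[bundle.obs["type"] == "breed", "plant_id"])
    )
    N = len(hybrids)
    if N < 2:
        raise ValueError("need at least two evaluated hybrids")
    crosses = [bundle.cross_of_hybrid[h] for h in hybrids]
    v = fit.variances
    contribs_raw: dict[str, float] = {}

    def onehot(levels, keys):
        idx = {lv: i for i, lv in enumerate(levels)}
        Z = np.zeros((N, len(levels)))
        for r, k in enumerate(keys):
            Z[r, idx[k]] = 1.0
        return Z

    Z2 = onehot(bundle.levels["gca2"], [c[0] for c in crosses])
    Z4 = onehot(bundle.levels["gca4"], [c[1] for c in crosses])
    Zc = onehot(bundle.levels["cross"], crosses)
    kin = bundle.kinships
    genomic = bundle.variant != "PHENO"

    contribs_raw["gca2"] = v["sigma2_D"] * _centered_quadratic(
        Z2, kin.AD if genomic else None, None, N)
    contribs_raw["gca4"] = v["sigma2_T"] * _centered_quadratic(
        Z4, kin.AT if genomic else None, None, N)
    if "sigma2_DT" in v:
        contribs_raw["sca"] = v["sigma2_DT"] * _centered_quadratic(
            Zc, None, None, N)
    if "sigma2_DTdom" in v:
        coef_F = fit.fixed_effects.get("F", 0.0)  # = -b
        mu_dom = coef_F * np.array(
            [bundle.F_of_cross[c] for c in bundle.levels["cross"]])
        contribs_raw["sca_dom"] = _centered_quadratic(
            Zc, v["sigma2_DTdom"] * kin.Dmat, mu_dom, N)
    if "sigma2_DTepi" in v:
        contribs_raw["sca_epi"] = _centered_quadratic(
            Zc, v["sigma2_DTepi"] * kin.Kepi, None, N)

    # within-cross hybrid component (one level per hybrid, diagonal G)
    hyb_params = [p for p in v if p.startswith("sigma2_H")]
    if len(hyb_params) == 1:
        sig = np.full(N, v[hyb_params[0]])
    else:
        sig = np.array([
            v.get(f"sigma2_H[{c[0]}x{c[1]}]", v.get("sigma2_H[pooled]", 0.0))
            for c in crosses
        ])
    contribs_raw["hybrid"] = float(np.sum(sig) - np.sum(sig) / N) / (N - 1)

    EVG = float(sum(contribs_raw.values()))
    EVE = float(fit.R.sum()) / fit.R.shape[0] ** 2
    H2 = EVG / (EVG + EVE) if EVG + EVE > 0 else 0.0
    denom = EVG + EVE if EVG + EVE > 0 else 1.0
    contributions = {k: val / denom for k, val in contribs_raw.items()}
    return HeritabilityReport(
        trait=bundle.trait, variant=bundle.variant, H2=H2,
        contributions=contributions, expected_VG=EVG, expected_VE=EVE,
        n_hybrids=N,
    )


# -- significance scans ----------------------------------------------------


def significance_scan(
    tables: StudyTables,
    trait: str,
    kinships: KinshipSet | None = None,
    variant: str = "PHENO",
    **fit_kwargs,
) -> pd.DataFrame:
    """Likelihood-ratio scan of the random terms of one trait's model.

    Tests: drop-one for every random genetic term (50:50 chi-square mixture
    reference, since a variance sits on the boundary under the null), the
    common-versus-specific GCA variance comparison, the epistasis term on
    top of a model already carrying dominance (for the full genomic
    variant), and a Wald test of the inbreeding coefficient ``b``.
    """
    bundle = build_model(variant, tables, trait, kinships)
    full = bundle.fit(**fit_kwargs)
    rows = []

    drop_map = {
        "gca2": "sigma2_D", "gca4": "sigma2_T", "sca": "sigma2_DT",
        "sca_dom": "sigma2_DTdom", "sca_epi": "sigma2_DTepi",
    }
    for term_name, vname in drop_map.items():
        if vname not in full.variances:
            continue
        reduced = _refit_without(bundle, drop=term_name, **fit_kwargs)
        stat, df, p = lr_test(full, reduced, boundary=True)
        rows.append((f"drop_{term_name}", stat, df, p))

    # common vs specific GCA variances
    tied = _refit_without(bundle, tie_gca=True, **fit_kwargs)
    stat, df, p = lr_test(full, tied, boundary=False)
    rows.append(("common_vs_specific_gca", stat, df, p))

    if variant == "GCA_A_SCA_D_AA":
        dom_only = build_model("GCA_A_SCA_D", tables, trait, kinships)
        fit_dom = dom_only.fit(**fit_kwargs)
        stat, df, p = lr_test(full, fit_dom, boundary=True)
        rows.append(("epistasis_given_dominance", stat, df, p))

    if "F" in full.x_names:
        from scipy import stats as st

        j = full.x_names.index("F")
        z = full.beta[j] / full.beta_se[j]
        rows.append(("inbreeding_b_wald", float(z**2), 1,
                     float(2 * st.norm.sf(abs(z)))))

    return pd.DataFrame(rows, columns=["test", "statistic", "df", "p_value"])


def _refit_without(bundle: ModelBundle, drop: str | None = None,
                   tie_gca: bool = False, **fit_kwargs) -> ModelFit:
    """Refit the bundle's model with a term dropped or GCA variances tied."""
    m = bundle.model
    terms = []
    for t in m.random:
        if t.name == drop:
            continue
        t2 = RandomTerm(t.name, t.levels, _sorted_z(m, t), G=t.G,
                        variance=t.variance)
        if tie_gca and t.name in ("gca2", "gca4"):
            t2.variance = "sigma2_GCA"
        terms.append(t2)
    absorbed = None
    if m.absorbed is not None:
        group = np.empty(m.n, dtype=object)
        group[:] = None
        for pl in range(m.n_plants):
            gi = m.abs_group_of_plant[pl]
            if gi >= 0:
                rows_pl = m.omat[pl][m.omat[pl] >= 0]
                for r in rows_pl:
                    group[r] = m.abs_group_labels[gi]
        absorbed = AbsorbedTerm(m.absorbed.name, group=group,
                                variance_of={
                                    g: m.abs_group_params[i]
                                    for i, g in enumerate(m.abs_group_labels)
                                })
    m2 = MixedModel(m.y, m.X, m.plant_idx, m.cycle0 + 1, random=terms,
                    absorbed=absorbed, n_cycles=m.n_cycles, x_names=m.x_names)
    return m2.fit(**fit_kwargs)


def _sorted_z(m: MixedModel, t: RandomTerm) -> np.ndarray:
    # the model holds observations internally sorted; reuse the sorted z
    return getattr(t, "_z_sorted")
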