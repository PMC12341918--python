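"""Model variants, heritability partitioning and significance scans."""

import numpy as np
import pandas as pd
import pytest

from triploidcross.lmm import lr_test
from triploidcross.models import (build_model, heritability,
                                  significance_scan)
from triploidcross.simulate import SimulationConfig, simulate_dataset


def _make_fit(bundle, variances, R, beta_overrides=None):
    """A ModelFit shell with chosen parameters (heritability is a pure
    function of the parameter estimates and the design)."""
    from triploidcross.lmm import ModelFit

    m = bundle.model
    beta = np.zeros(m.p)
    names = m.x_names
    if beta_overrides:
        for k, v in beta_overrides.items():
            beta[names.index(k)] = v
    return ModelFit(
        loglik=0.0, neg2_reml=0.0, variances=variances, R=R, beta=beta,
        beta_se=np.ones(m.p), x_names=names, blups={}, absorbed_blups=None,
        n_obs=m.n, n_params=0, converged=True, n_iter=0, grad_norm=0.0,
        boundary={}, method="fixed", model=m,
    )


class TestBuildModel:
    def test_pheno_variant_uses_identity_structures(self, small_dataset):
        b = build_model("PHENO", small_dataset.tables, "trait")
        names = [t.name for t in b.model.random]
        assert names == ["gca2", "gca4", "sca", "control"]
        assert all(t.G is None for t in b.model.random)
        assert b.model.absorbed is not None
        assert "F" not in b.model.x_names

    def test_dominance_variant_attaches_f_and_dmat(self, small_dataset,
                                                   small_kinships):
        b = build_model("GCA_A_SCA_D", small_dataset.tables, "trait",
                        small_kinships)
        assert "F" in b.model.x_names
        names = {t.name: t for t in b.model.random}
        assert "sca_dom" in names and "sca" not in names
        np.testing.assert_array_equal(names["sca_dom"].G,
                                      small_kinships.Dmat)

    def test_genomic_variant_requires_kinships(self, small_dataset):
        with pytest.raises(ValueError, match="KinshipSet"):
            build_model("GCA_A", small_dataset.tables, "trait")

    def test_missing_parent_genotypes_listed(self, small_dataset,
                                             small_kinships):
        tables = small_dataset.tables
        ped = tables.pedigree.copy()
        ped.loc[len(ped)] = ["H_new", "Dxx", "Txx", "FX"]
        from triploidcross.tables import StudyTables

        tables2 = StudyTables(pedigree=ped, phenotypes=tables.phenotypes)
        with pytest.raises(ValueError, match="H_new"):
            build_model("GCA_A", tables2, "trait", small_kinships)

    def test_cross_specific_variance_groups(self, small_dataset):
        b = build_model("PHENO", small_dataset.tables, "trait",
                        cross_specific_variance=True, min_progeny=8)
        hyb_params = [p for p in b.model.param_names
                      if p.startswith("sigma2_H")]
        # every cross has 10 progeny >= 8, so each gets its own parameter;
        # the controls keep the pooled parameter
        assert len(hyb_params) == len(b.levels["cross"]) + 1
        assert "sigma2_H[pooled]" in hyb_params


class TestHeritability:
    def test_single_component_closed_form(self, small_dataset):
        """With only within-cross variance 1 and R = diag(3,3,3):
        E(VG) = 1, E(VEbar) = 1, H2 = 1/2."""
        b = build_model("PHENO", small_dataset.tables, "trait")
        fit = _make_fit(
            b, {"sigma2_D": 0.0, "sigma2_T": 0.0, "sigma2_DT": 0.0,
                "sigma2_H": 1.0}, np.diag([3.0, 3.0, 3.0]))
        rep = heritability(fit, b)
        assert rep.expected_VG == pytest.approx(1.0)
        assert rep.expected_VE == pytest.approx(1.0)
        assert rep.H2 == pytest.approx(0.5)

    def test_zero_genetic_variance_gives_zero_h2(self, small_dataset):
        b = build_model("PHENO", small_dataset.tables, "trait")
        fit = _make_fit(
            b, {"sigma2_D": 0.0, "sigma2_T": 0.0, "sigma2_DT": 0.0,
                "sigma2_H": 0.0}, np.eye(3))
        assert heritability(fit, b).H2 == pytest.approx(0.0)

    def test_average_error_variance_closed_form(self, small_dataset):
        b = build_model("PHENO", small_dataset.tables, "trait")
        fit = _make_fit(
            b, {"sigma2_D": 0.1, "sigma2_T": 0.1, "sigma2_DT": 0.1,
                "sigma2_H": 0.1}, 2.7 * np.eye(3))
        assert heritability(fit, b).expected_VE == pytest.approx(2.7 / 3.0)

    def test_contributions_sum_to_h2(self, pheno_fit):
        fit, bundle = pheno_fit
        rep = heritability(fit, bundle)
        assert sum(rep.contributions.values()) == pytest.approx(rep.H2,
                                                                abs=1e-8)
        assert all(v >= 0 for v in rep.contributions.values())
        assert 0.0 <= rep.H2 <= 1.0

    def test_invariant_to_fixed_effect_reference_level(self, small_dataset):
        """Relabelling blocks changes the corner-point reference but not the
        heritability or the reconstructed general mean."""
        from triploidcross.crosses import estimate_values
        from triploidcross.tables import StudyTables

        tables = small_dataset.tables
        b1 = build_model("PHENO", tables, "trait")
        f1 = b1.fit()
        phe = tables.phenotypes.copy()
        relabel = {b: f"Z{b}" for b in phe["block_id"].unique()[:1]}
        phe["block_id"] = phe["block_id"].replace(relabel)
        tables2 = StudyTables(pedigree=tables.pedigree, phenotypes=phe)
        b2 = build_model("PHENO", tables2, "trait")
        f2 = b2.fit()
        assert heritability(f1, b1).H2 == pytest.approx(
            heritability(f2, b2).H2, abs=1e-4)
        v1 = estimate_values(f1, b1)
        v2 = estimate_values(f2, b2)
        assert v1.m_hat == pytest.approx(v2.m_hat, abs=1e-4)
        pd.testing.assert_series_equal(v1.table["ytilde"],
                                       v2.table["ytilde"], atol=1e-4)

    def test_tetraploid_contribution_dominates_at_3_to_1(self):
        """Simulating sigma_T^2 = 3 sigma_D^2 the 4x-GCA share of H2 exceeds
        the 2x share in nearly every replicate."""
        wins = 0
        reps = 25
        for r in range(reps):
            cfg = SimulationConfig(
                n_parents2x=24, n_parents4x=24, n_crosses=50, family_sizes=8,
                sigma2_D=0.3, sigma2_T=0.9, sigma2_DT=0.1, sigma2_H=0.5,
                seed=500 + r)
            data = simulate_dataset(cfg)
            b = build_model("PHENO", data.tables, "trait")
            rep = heritability(b.fit(), b)
            wins += rep.contributions["gca4"] > rep.contributions["gca2"]
        assert wins / reps >= 0.9


class TestGenomicRecovery:
    def test_both_sca_components_recovered_when_present(self):
        """Phenotypes drawn from the genomic model with sizeable dominance
        and epistasis SCA variances yield positive estimates for both in
        most replicates.  The two structures overlap over a finite cross
        set, so occasional transfer of variance between them is expected."""
        from triploidcross.kinship import build_kinship_set
        from triploidcross.tables import StudyTables

        cfg = SimulationConfig(
            n_parents2x=12, n_parents4x=12, n_crosses=60, family_sizes=6,
            n_markers=400, sigma2_D=0.2, sigma2_T=0.4, sigma2_DT=0.0,
            sigma2_H=0.3, seed=21)
        data = simulate_dataset(cfg)
        ped = data.tables.pedigree
        crosses = sorted(set(zip(ped["parent2x_id"], ped["parent4x_id"])))
        kin = build_kinship_set(data.genotypes, crosses)
        rng = np.random.default_rng(99)
        nc = len(crosses)
        Ld = np.linalg.cholesky(kin.Dmat + 1e-8 * np.eye(nc))
        Lk = np.linalg.cholesky(kin.Kepi + 1e-8 * np.eye(nc))
        # scale each component to contribute ~1.5 units of cross variance
        sd_dom = np.sqrt(1.5 / np.diag(kin.Dmat).mean())
        sd_epi = np.sqrt(1.5 / np.diag(kin.Kepi).mean())
        cross_of = {r.hybrid_id: (r.parent2x_id, r.parent4x_id)
                    for r in ped.itertuples()}
        both_positive = 0
        reps = 12
        for _ in range(reps):
            d = sd_dom * (Ld @ rng.standard_normal(nc))
            i = sd_epi * (Lk @ rng.standard_normal(nc))
            sca = dict(zip(kin.crosses, d + i))
            phe = data.tables.phenotypes.copy()
            phe["value"] = phe["value"] + phe["plant_id"].map(
                lambda h: sca.get(cross_of.get(h), 0.0))
            t2 = StudyTables(pedigree=ped, phenotypes=phe)
            fit = build_model("GCA_A_SCA_D_AA", t2, "trait", kin).fit()
            both_positive += (fit.variances["sigma2_DTdom"] > 1e-7
                              and fit.variances["sigma2_DTepi"] > 1e-7)
        assert both_positive / reps >= 0.75


class TestSignificanceScan:
    def test_scan_reports_all_tests(self, small_dataset, small_kinships):
        scan = significance_scan(small_dataset.tables, "trait",
                                 kinships=small_kinships,
                                 variant="GCA_A_SCA_D_AA")
        tests = set(scan["test"])
        assert {"drop_gca2", "drop_gca4", "drop_sca_dom", "drop_sca_epi",
                "common_vs_specific_gca", "epistasis_given_dominance",
                "inbreeding_b_wald"} <= tests
        assert ((scan["p_value"] >= 0) & (scan["p_value"] <= 1)).all()

    def test_absent_4x_gca_is_rarely_significant(self):
        hits = 0
        reps = 20
        for r in range(reps):
            cfg = SimulationConfig(
                n_parents2x=8, n_parents4x=8, n_crosses=20, family_sizes=6,
                sigma2_D=0.4, sigma2_T=0.0, sigma2_DT=0.1, sigma2_H=0.4,
                seed=700 + r)
            data = simulate_dataset(cfg)
            scan = significance_scan(data.tables, "trait")
            p = scan.loc[scan["test"] == "drop_gca4", "p_value"].iloc[0]
            hits += p < 0.05
        assert hits / reps <= 0.1

    def test_strong_sca_is_detected(self):
        hits = 0
        reps = 12
        for r in range(reps):
            cfg = SimulationConfig(
                n_parents2x=10, n_parents4x=10, n_crosses=40, family_sizes=8,
                sigma2_D=0.2, sigma2_T=0.4, sigma2_DT=0.8, sigma2_H=0.3,
                seed=800 + r)
            data = simulate_dataset(cfg)
            scan = significance_scan(data.tables, "trait")
            p = scan.loc[scan["test"] == "drop_sca", "p_value"].iloc[0]
            hits += p < 0.05
        assert hits / reps > 0.8
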