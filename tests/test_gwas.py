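"""Association-engine tests: filters, kinship, null REML, P3D scan oracle,
effective-marker thresholds, PVE, case-control symmetry."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import envgxe as ex
from envgxe import gwas
from envgxe.errors import DataError, InvalidConfigError
from conftest import polygenic_response


def _toy_dosage(dosages, clones=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    m, n = dosages.shape
    clones = clones or [f"c{j}" for j in range(n)]
    return ex.DosageMatrix(
        [f"m{i}" for i in range(m)],
        np.array(["chr01"] * m),
        np.arange(1, m + 1) * 1000,
        clones, dosages,
    )


class TestMafFilter:
    def test_monomorphic_removed_at_any_positive_threshold(self):
        dm = _toy_dosage([[0] * 10, [1] * 5 + [3] * 5])
        out = ex.maf_filter(dm, 0.01)
        assert out.markers == ["m1"]

    def test_single_carrier_in_100_clones_removed(self):
        row = [0] * 99 + [2]   # f = 2 / 400 = 0.005 < 0.01
        dm = _toy_dosage([row, [1] * 50 + [3] * 50])
        out = ex.maf_filter(dm, 0.01)
        assert out.markers == ["m1"]

    def test_threshold_zero_keeps_polymorphic(self):
        dm = _toy_dosage([[0] * 10, [0] * 9 + [1]])
        out = ex.maf_filter(dm, 0.0)
        assert out.markers == ["m1"]

    def test_all_removed_raises(self):
        dm = _toy_dosage([[0, 0, 0], [4, 4, 4]])
        with pytest.raises(DataError):
            ex.maf_filter(dm, 0.01)


class TestKinship:
    def test_matches_hand_computed_crossproduct(self):
        dm = _toy_dosage([[0, 2, 4], [1, 1, 4]])
        Z = np.array([[0, 2, 4], [1, 1, 4]], dtype=float)
        Z = (Z - Z.mean(axis=1, keepdims=True)).T
        expected = Z @ Z.T
        expected /= np.trace(expected) / 3
        K = ex.kinship(dm)
        assert np.allclose(K.to_numpy(), expected)
        assert np.trace(K.to_numpy()) == pytest.approx(3.0)

    def test_duplicate_clones_have_identical_rows(self, small_panel):
        dm, _, _ = small_panel
        dup = ex.DosageMatrix(
            list(dm.markers), dm.chrom.copy(), dm.pos.copy(),
            list(dm.clones[:-1]) + ["twin"],
            np.hstack([dm.dosages[:, :-1], dm.dosages[:, :1]]),
        )
        K = ex.kinship(dup)
        assert np.allclose(K.loc["twin"], K.loc[dup.clones[0]])

    def test_symmetric_positive_semidefinite(self, small_panel):
        dm, _, _ = small_panel
        K = ex.kinship(dm).to_numpy()
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8


class TestPca:
    def test_two_cluster_panel_separated_on_pc1(self):
        rng = np.random.default_rng(0)
        block = rng.integers(0, 5, size=(50, 1), dtype=np.int8)
        group = np.hstack([np.tile(block, (1, 10)),
                           np.tile(4 - block, (1, 10))])
        dm = _toy_dosage(group)
        scores, frac = ex.pca(dm, 2)
        pc1 = scores["PC1"].to_numpy()
        assert (pc1[:10] * pc1[10:] < 0).all()   # complete separation by sign
        assert frac.sum() <= 1.0 + 1e-12
        assert np.all(np.diff(frac) <= 1e-12)

    def test_unstructured_panel_has_no_dominant_pc(self, default_sites):
        dm, _, _ = ex.simulate_genotypes(100, 1000, default_sites, seed=5)
        _, frac = ex.pca(dm, 5)
        assert frac[0] < 0.10


class TestNullFit:
    def test_identity_kinship_scan_equals_ols(self, default_sites):
        dm, _, _ = ex.simulate_genotypes(50, 30, default_sites, seed=3)
        rng = np.random.default_rng(4)
        y = pd.Series(rng.normal(0, 1, 50), index=dm.clones)
        I = pd.DataFrame(np.eye(50), index=dm.clones, columns=dm.clones)
        res = ex.score_markers(dm, y, ex.fit_null(y, I))
        for i in range(dm.n_markers):
            g = dm.dosages[i].astype(float)
            if g.std() == 0:
                continue
            slope, _, _, p, _ = stats.linregress(g, y.to_numpy())
            assert res.table["P"].iloc[i] == pytest.approx(p, abs=1e-8)
            assert res.table["Effect"].iloc[i] == pytest.approx(slope, abs=1e-8)

    def test_heritability_recovered(self, default_sites):
        dm, _, _ = ex.simulate_genotypes(500, 800, default_sites, seed=6)
        K = ex.kinship(dm)
        h2 = []
        for rep in range(5):
            y = polygenic_response(K, 0.5, seed=rep)
            h2.append(ex.fit_null(y, K).heritability)
        assert np.mean(h2) == pytest.approx(0.5, abs=0.1)

    def test_constant_response_rejected(self, small_panel):
        dm, _, _ = small_panel
        K = ex.kinship(dm)
        with pytest.raises(DataError):
            ex.fit_null(pd.Series(1.0, index=dm.clones), K)


class TestScanOracle:
    def test_matches_dense_gls_on_small_panel(self, default_sites):
        """P3D scan must equal explicit GLS with V = s_poly K + s_e I."""
        dm, _, _ = ex.simulate_genotypes(18, 40, default_sites, seed=8)
        dm = ex.maf_filter(dm, 0.05)
        K = ex.kinship(dm)
        y = polygenic_response(K, 0.4, seed=9)
        null = ex.fit_null(y, K)
        res = ex.score_markers(dm, y, null)
        V = null.sigma2_poly * K.to_numpy() + null.sigma2_e * np.eye(18)
        Vi = np.linalg.inv(V)
        n = 18
        for i in range(dm.n_markers):
            if res.table["monomorphic"].iloc[i]:
                continue
            X = np.column_stack([np.ones(n), dm.dosages[i].astype(float)])
            XtViX = X.T @ Vi @ X
            beta = np.linalg.solve(XtViX, X.T @ Vi @ y.to_numpy())
            resid = y.to_numpy() - X @ beta
            s2 = float(resid @ Vi @ resid) / (n - 2)
            se = np.sqrt(s2 * np.linalg.inv(XtViX)[1, 1])
            p = 2 * stats.t.sf(abs(beta[1] / se), n - 2)
            assert abs(res.table["P"].iloc[i] - p) < 1e-6

    def test_lod_is_minus_log10_p(self):
        assert -np.log10(0.001) == pytest.approx(3.0)
        dm = _toy_dosage(np.random.default_rng(1).integers(0, 5, (5, 30)))
        y = pd.Series(np.random.default_rng(2).normal(size=30), index=dm.clones)
        I = pd.DataFrame(np.eye(30), index=dm.clones, columns=dm.clones)
        res = ex.score_markers(dm, y, ex.fit_null(y, I))
        assert np.allclose(res.table["LOD"], -np.log10(res.table["P"]))

    def test_null_pvalues_uniform(self, default_sites):
        dm, _, _ = ex.simulate_genotypes(300, 1000, default_sites, seed=10)
        dm = ex.maf_filter(dm, 0.01)
        K = ex.kinship(dm)
        y = polygenic_response(K, 0.5, seed=11)
        res = ex.score_markers(dm, y, ex.fit_null(y, K))
        assert stats.kstest(res.table["P"], "uniform").pvalue > 0.01


class TestMeff:
    def test_independent_markers_meff_near_m(self, default_sites):
        dm, _, _ = ex.simulate_genotypes(400, 200, default_sites, seed=12)
        dm = ex.maf_filter(dm, 0.05)
        m_eff, thr = ex.meff_threshold(dm, 0.05)
        assert m_eff == pytest.approx(dm.n_markers, rel=0.10)
        assert thr == pytest.approx(-np.log10(0.05 / m_eff))

    def test_duplicated_markers_do_not_double_meff(self, default_sites):
        dm, _, _ = ex.simulate_genotypes(400, 100, default_sites, seed=13)
        dm = ex.maf_filter(dm, 0.05)
        m_eff, _ = ex.meff_threshold(dm, 0.05)
        idx = np.repeat(np.arange(dm.n_markers), 2)
        names = []
        for i in np.arange(dm.n_markers):
            names += [dm.markers[i], f"{dm.markers[i]}_dup"]
        pos = dm.pos[idx].copy()
        pos[1::2] += 1   # keep per-chromosome sort order
        dup = ex.DosageMatrix(names, dm.chrom[idx], pos, list(dm.clones),
                              dm.dosages[idx])
        m_eff_dup, _ = ex.meff_threshold(dup, 0.05)
        assert m_eff_dup == pytest.approx(m_eff, rel=0.05)

    def test_threshold_arithmetic(self):
        dm = _toy_dosage(np.random.default_rng(0).integers(0, 5, (4, 20)))
        _, thr = ex.meff_threshold(dm, 0.05, method="bonferroni")
        assert thr == pytest.approx(-np.log10(0.05 / 4))
        assert -np.log10(0.05 / 1000) == pytest.approx(4.301, abs=1e-3)

    def test_invalid_alpha_rejected(self, small_panel):
        dm, _, _ = small_panel
        with pytest.raises(InvalidConfigError):
            ex.meff_threshold(dm, 1.5)


class TestPve:
    def test_single_marker_saturates_to_100(self, default_sites):
        dm, _, _ = ex.simulate_genotypes(200, 10, default_sites, seed=14)
        g = dm.dosages[0].astype(float)
        y = pd.Series(g + np.random.default_rng(1).normal(0, 1e-4, 200),
                      index=dm.clones)
        I = pd.DataFrame(np.eye(200), index=dm.clones, columns=dm.clones)
        null = ex.fit_null(y, I)
        rep = ex.pve_backward_elimination(y, [dm.markers[0]], dm, null)
        assert rep.per_marker["PVE"].iloc[0] > 99.0
        assert rep.cumulative_joint > 99.0

    def test_two_orthogonal_planted_markers(self, default_sites):
        rng = np.random.default_rng(15)
        dm, _, _ = ex.simulate_genotypes(2000, 10, default_sites, seed=15)
        g1 = dm.dosages[0].astype(float)
        g2 = dm.dosages[1].astype(float)
        # scale each to contribute 10% of total response variance
        b1 = np.sqrt(0.1 / g1.var())
        b2 = np.sqrt(0.1 / g2.var())
        y = pd.Series(b1 * g1 + b2 * g2 + rng.normal(0, np.sqrt(0.8), 2000),
                      index=dm.clones)
        I = pd.DataFrame(np.eye(2000), index=dm.clones, columns=dm.clones)
        null = ex.fit_null(y, I)
        rep = ex.pve_backward_elimination(y, dm.markers[:2], dm, null)
        assert rep.per_marker["PVE"].to_numpy() == pytest.approx([10, 10], abs=2)
        assert rep.cumulative_joint == pytest.approx(20, abs=2)

    def test_collinear_pair_pruned(self, default_sites):
        dm, _, _ = ex.simulate_genotypes(100, 5, default_sites, seed=16)
        dup = ex.DosageMatrix(
            dm.markers + ["copy"],
            np.concatenate([dm.chrom, np.array(["chr99"])]),
            np.concatenate([dm.pos, dm.pos[:1] + 1]),
            list(dm.clones),
            np.vstack([dm.dosages, dm.dosages[:1]]),
        )
        y = pd.Series(dup.dosages[0] + np.random.default_rng(2).normal(0, 0.5, 100),
                      index=dup.clones)
        I = pd.DataFrame(np.eye(100), index=dup.clones, columns=dup.clones)
        null = ex.fit_null(y, I)
        rep = ex.pve_backward_elimination(y, [dup.markers[0], "copy"], dup, null)
        assert len(rep.dropped_collinear) == 1
        assert len(rep.per_marker) == 1


class TestBinaryResponse:
    def test_case_counts(self):
        prog = pd.Series(["NY"] * 86 + ["MI"] * 754,
                         index=[f"c{i}" for i in range(840)])
        y = ex.binary_response(prog, "NY")
        assert y.sum() == 86

    def test_unknown_program_rejected(self):
        prog = pd.Series(["A", "B"], index=["c1", "c2"])
        with pytest.raises(DataError):
            ex.binary_response(prog, "ZZ")

    def test_complementary_responses_give_identical_tests(self, default_sites):
        dm, _, prog = ex.simulate_genotypes(120, 40, default_sites, seed=17)
        two = prog.copy()
        two[:] = np.where(np.arange(len(two)) % 3 == 0, "A", "B")
        K = ex.kinship(dm)
        ya = ex.binary_response(two, "A")
        yb = ex.binary_response(two, "B")
        ra = ex.score_markers(dm, ya, ex.fit_null(ya, K))
        rb = ex.score_markers(dm, yb, ex.fit_null(yb, K))
        assert np.allclose(ra.table["P"], rb.table["P"], atol=1e-10)
        assert np.allclose(ra.table["Effect"], -rb.table["Effect"], atol=1e-10)
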