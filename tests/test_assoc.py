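"""Discovery-scan behavior: QC rules, HWE, residualization, Wald scan,
LD, locus merging and cis/trans classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pqtlkit import (
    GeneModel,
    PqtlLocus,
    ProteinPanel,
    ValidationError,
    classify_locus,
    hwe_exact_test,
    ld_r2,
    merge_loci,
    qc_genotypes,
    qc_proteins,
    residualize,
    wald_scan,
)
from pqtlkit.assoc import signed_distance_kb
from pqtlkit.io import P_FLOOR

from conftest import hwe_enumeration_oracle, make_gm, make_variant, ols_oracle


def _panel(names, lod, cv, n=4):
    rng = np.random.default_rng(0)
    return ProteinPanel(
        samples=[f"S{i}" for i in range(n)], proteins=list(names),
        values=rng.normal(size=(n, len(names))),
        frac_below_lod=dict(zip(names, lod)),
        cv_interplate=dict(zip(names, cv)),
    )


class TestProteinQc:
    def test_92_assays_with_9_violations_leaves_83(self):
        names = [f"P{k}" for k in range(92)]
        lod = [0.05] * 92
        cv = [0.10] * 92
        for k in range(6):
            lod[k] = 0.30
        for k in range(6, 9):
            cv[k] = 0.26
        panel, log = qc_proteins(_panel(names, lod, cv))
        assert len(panel.proteins) == 83
        reasons = dict(log.removed)
        assert reasons["P0"] == "lod" and reasons["P6"] == "cv"

    def test_boundaries_are_strict(self):
        # exactly 20% below LOD and exactly 25% CV are retained
        panel, log = qc_proteins(_panel(["A", "B"], [0.20, 0.0], [0.0, 0.25]))
        assert panel.proteins == ["A", "B"]
        panel, log = qc_proteins(_panel(["C"], [0.0], [0.26]))
        assert panel.proteins == [] and log.removed == [("C", "cv")]


class TestHweExact:
    def test_all_zero_counts_give_one(self):
        assert hwe_exact_test(0, 0, 0) == 1.0

    @pytest.mark.parametrize("counts", [
        (25, 50, 25), (100, 0, 100), (10, 5, 2), (0, 3, 40), (7, 7, 7),
        (1, 0, 0), (0, 1, 0), (57, 14, 50),
    ])
    def test_matches_exact_enumeration(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), abs=1e-12)

    def test_extreme_het_deficit_fails_filter(self):
        assert hwe_exact_test(100, 0, 100) < 1e-6

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            hwe_exact_test(-1, 2, 3)


class TestGenotypeQc:
    def test_low_call_rate_removed(self):
        rng = np.random.default_rng(1)
        dos = rng.integers(0, 3, size=(100, 2)).astype(float)
        dos[:6, 0] = np.nan  # 94% call rate
        gm = make_gm(dos)
        out, log = qc_genotypes(gm, call_rate=0.95)
        assert [v.id for v in out.variants] == ["rs2"]
        assert ("rs1", "call_rate") in log.removed

    def test_hwe_failure_removed_and_balanced_retained(self):
        # rs1: all hets (HWE p ~ 1e-30 at n=100); rs2: perfect HWE 1:2:1
        dos = np.zeros((100, 2))
        dos[:, 0] = 1.0
        dos[:25, 1] = 0.0
        dos[25:75, 1] = 1.0
        dos[75:, 1] = 2.0
        gm = make_gm(dos)
        out, log = qc_genotypes(gm, hwe_p=1e-6)
        assert [v.id for v in out.variants] == ["rs2"]
        assert ("rs1", "hwe") in log.removed


class TestResidualize:
    def _cov(self, n, rng):
        return pd.DataFrame({
            "age": rng.normal(60, 8, n),
            "sex": rng.integers(0, 2, n),
            "centre": [f"C{c}" for c in rng.integers(0, 3, n)],
            "batch": [f"B{b}" for b in rng.integers(0, 2, n)],
            "smoking": rng.binomial(1, 0.3, n),
            "diabetes": rng.binomial(1, 0.2, n),
            "hypertension": rng.binomial(1, 0.5, n),
        }, index=[f"S{i}" for i in range(n)])

    def test_output_standardized_and_covariate_free(self):
        rng = np.random.default_rng(2)
        n = 500
        cov = self._cov(n, rng)
        y = 2.0 * cov["age"].to_numpy() + rng.normal(size=n)
        panel = ProteinPanel(samples=list(cov.index), proteins=["X"],
                             values=y[:, None], frac_below_lod={"X": 0.0},
                             cv_interplate={"X": 0.0})
        resid = residualize(panel, cov)
        r = resid["X"].to_numpy()
        assert abs(r.mean()) < 1e-12
        assert r.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        assert abs(np.corrcoef(r, cov["age"])[0, 1]) < 1e-10

    def test_orthogonal_covariates_reduce_to_zscore(self):
        rng = np.random.default_rng(3)
        n = 400
        cov = pd.DataFrame({"age": rng.normal(60, 8, n)},
                           index=[f"S{i}" for i in range(n)])
        y = rng.normal(size=n)
        y = y - np.polyval(np.polyfit(cov["age"], y, 1), cov["age"])  # orthogonalize
        panel = ProteinPanel(samples=list(cov.index), proteins=["X"],
                             values=y[:, None], frac_below_lod={"X": 0.0},
                             cv_interplate={"X": 0.0})
        r = residualize(panel, cov)["X"].to_numpy()
        np.testing.assert_allclose(r, (y - y.mean()) / np.std(y - y.mean(), ddof=1),
                                   atol=1e-10)

    def test_duplicated_covariate_rejected(self):
        rng = np.random.default_rng(4)
        n = 50
        cov = self._cov(n, rng)
        cov["age2"] = cov["age"]
        panel = ProteinPanel(samples=list(cov.index), proteins=["X"],
                             values=rng.normal(size=(n, 1)),
                             frac_below_lod={"X": 0.0}, cv_interplate={"X": 0.0})
        with pytest.raises(ValidationError, match="collinear"):
            residualize(panel, cov)


class TestWaldScan:
    def _scan_one(self, g, y, **kw):
        gm = make_gm(g[:, None])
        resid = pd.DataFrame({"X": y}, index=gm.samples)
        records, flagged = wald_scan(resid, gm, **kw)
        return records, flagged

    def test_matches_matrix_ols_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = rng.integers(20, 200)
            m = rng.integers(1, 20)
            g = rng.integers(0, 3, size=(n, m)).astype(float)
            g = g[:, g.std(axis=0) > 0]
            if g.shape[1] == 0:
                continue
            y = rng.normal(size=n)
            gm = make_gm(g)
            resid = pd.DataFrame({"X": y}, index=gm.samples)
            records, _ = wald_scan(resid, gm)
            for j, rec in enumerate(records):
                beta_o, se_o = ols_oracle(g[:, j], y)
                assert rec.beta == pytest.approx(beta_o, rel=1e-10)
                assert rec.se == pytest.approx(se_o, rel=1e-10)

    def test_perfect_fit_clamps_p(self):
        g = np.array([0.0, 1, 2, 0, 1, 2] * 20)
        records, _ = self._scan_one(g, g.copy())
        (rec,) = records
        assert rec.beta == pytest.approx(1.0)
        assert rec.p == P_FLOOR and rec.p_underflowed
        assert rec.r2_explained == pytest.approx(1.0)

    def test_monomorphic_variant_skipped(self):
        g = np.ones(50)
        records, _ = self._scan_one(g, np.random.default_rng(0).normal(size=50))
        assert records == []

    def test_allele_flip_negates_beta_keeps_p_r2(self):
        rng = np.random.default_rng(6)
        g = rng.integers(0, 3, 300).astype(float)
        y = 0.3 * g + rng.normal(size=300)
        (rec,), _ = self._scan_one(g, y)
        (rec_f,), _ = self._scan_one(2.0 - g, y)
        assert rec_f.beta == pytest.approx(-rec.beta, rel=1e-12)
        assert rec_f.p == pytest.approx(rec.p, rel=1e-9)
        assert rec_f.r2_explained == pytest.approx(rec.r2_explained, rel=1e-12)

    def test_null_p_uniform(self):
        # KS test of p-values over replicates of a null variant
        from scipy.stats import kstest
        rng = np.random.default_rng(7)
        n = 200
        g = rng.integers(0, 3, n).astype(float)
        gm = make_gm(g[:, None])
        ps = []
        for _ in range(1000):
            y = rng.normal(size=n)
            resid = pd.DataFrame({"X": y}, index=gm.samples)
            records, _ = wald_scan(resid, gm)
            ps.append(records[0].p)
        assert kstest(ps, "uniform").pvalue > 0.01


class TestLdAndMerge:
    def test_ld_r2_identity_and_flip(self):
        rng = np.random.default_rng(8)
        g = rng.integers(0, 3, 500).astype(float)
        gm = make_gm(np.column_stack([g, g, 2.0 - g]))
        assert ld_r2(gm, "rs1", "rs2") == pytest.approx(1.0)
        assert ld_r2(gm, "rs1", "rs3") == pytest.approx(1.0)

    def test_independent_variants_low_r2(self):
        rng = np.random.default_rng(9)
        gm = make_gm(rng.integers(0, 3, size=(5000, 2)).astype(float))
        assert ld_r2(gm, "rs1", "rs2") < 0.01

    def test_monomorphic_returns_none(self):
        gm = make_gm(np.column_stack([np.ones(10), np.arange(10) % 3]))
        assert ld_r2(gm, "rs1", "rs2") is None

    def _flagged(self, gm, ps):
        from pqtlkit import AssocRecord
        return [
            AssocRecord(variant=v, trait="X", beta=0.1, se=0.01, p=p, n=100,
                        r2_explained=0.01)
            for v, p in zip(gm.variants, ps)
        ]

    def test_correlated_nearby_signals_merge_to_strongest(self):
        rng = np.random.default_rng(10)
        g1 = rng.integers(0, 3, 2000).astype(float)
        noise = rng.integers(0, 3, 2000).astype(float)
        g2 = np.where(rng.random(2000) < 0.7, g1, noise)  # r2 ~ 0.5
        gm = make_gm(np.column_stack([g1, g2]),
                     variants=[make_variant("rs1", "1", 100_000),
                               make_variant("rs2", "1", 200_000)])
        assert ld_r2(gm, "rs1", "rs2") > 0.1
        loci = merge_loci(self._flagged(gm, [1e-10, 1e-9]), 0.1, 250, gm)["X"]
        assert len(loci) == 1
        assert loci[0].index.variant.id == "rs1"
        assert {m.variant.id for m in loci[0].members} == {"rs1", "rs2"}

    def test_low_r2_pairs_stay_separate(self):
        rng = np.random.default_rng(11)
        gm = make_gm(rng.integers(0, 3, size=(2000, 2)).astype(float),
                     variants=[make_variant("rs1", "1", 100_000),
                               make_variant("rs2", "1", 110_000)])
        assert (ld_r2(gm, "rs1", "rs2") or 0) < 0.05
        loci = merge_loci(self._flagged(gm, [1e-10, 1e-9]), 0.1, 250, gm)["X"]
        assert len(loci) == 2

    def test_merge_is_idempotent_and_partitions_input(self):
        rng = np.random.default_rng(12)
        g = rng.integers(0, 3, size=(1000, 5)).astype(float)
        gm = make_gm(g, variants=[make_variant(f"rs{j}", "1", 50_000 * j + 1)
                                  for j in range(5)])
        flagged = self._flagged(gm, [1e-9, 1e-8, 1e-12, 1e-10, 1e-11])
        loci = merge_loci(flagged, 0.1, 250, gm)["X"]
        members = [m for loc in loci for m in loc.members]
        assert sorted(m.variant.id for m in members) == \
            sorted(f.variant.id for f in flagged)
        again = merge_loci([loc.index for loc in loci], 0.1, 250, gm)["X"]
        assert len(again) == len(loci)


class TestClassify:
    gene = GeneModel("G", "G", "1", 1_000_000, 1_050_000)

    def _locus(self, chrom, pos, vid="rsX"):
        from pqtlkit import AssocRecord
        rec = AssocRecord(variant=make_variant(vid, chrom, pos), trait="G",
                          beta=0.5, se=0.05, p=1e-12, n=3394, r2_explained=0.03)
        return PqtlLocus(index=rec, members=[rec])

    def test_snp_inside_gene_is_cis_distance_zero(self):
        loc = classify_locus(self._locus("1", 1_020_000), self.gene)
        assert loc.locus_class == "cis" and loc.distance_kb == 0.0

    def test_signed_distance_convention(self):
        assert signed_distance_kb(900_000, self.gene) == pytest.approx(-100.0)
        assert signed_distance_kb(1_150_000, self.gene) == pytest.approx(100.0)

    def test_cross_chromosome_is_trans_without_distance(self):
        loc = classify_locus(self._locus("9", 500), self.gene)
        assert loc.locus_class == "trans" and loc.distance_kb is None

    def test_override_rescues_slightly_out_of_window_locus(self):
        # 530.7 kb: outside the 500 kb window, cis by named override
        pos = self.gene.end + 530_700
        loc = classify_locus(self._locus("1", pos, "rs_agrp"), self.gene)
        assert loc.locus_class == "ambiguous"
        loc = classify_locus(self._locus("1", pos, "rs_agrp"), self.gene,
                             overrides=["rs_agrp"])
        assert loc.locus_class == "cis"

    def test_far_same_chromosome_is_trans(self):
        loc = classify_locus(self._locus("1", 150_000_000), self.gene)
        assert loc.locus_class == "trans"


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60))
def test_hwe_matches_oracle_property(a, b, c):
    assert hwe_exact_test(a, b, c) == pytest.approx(
        hwe_enumeration_oracle(a, b, c), abs=1e-12)
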