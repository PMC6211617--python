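import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from svase.ase_core import (
    QcThresholds,
    SyntheticRead,
    apply_qc_filters,
    ase_score,
    assign_read,
    call_species_bias,
    compare_group_ase,
    maternal_zygotic_summary,
    score_ase_matrix,
)
from svase.containers import AlleleCountMatrix, EmbryoSpec
from svase.synthetic_data import SvaseGeneSpec, simulate_slice_counts

counts = st.integers(min_value=0, max_value=10**6)


def _read(*alleles):
    return SyntheticRead(read_id="r", gene_id="g", site_alleles=tuple(alleles))


class TestAssignRead:
    @pytest.mark.parametrize(
        "alleles,expected",
        [
            (("sim", "sim"), "sim"),
            (("mel",), "mel"),
            ((), "ambiguous"),
            (("mel", "sim"), "ambiguous"),
            (("other",), "ambiguous"),
            (("mel", "other"), "ambiguous"),
        ],
    )
    def test_assignment_rule(self, alleles, expected):
        assert assign_read(_read(*alleles)) == expected


class TestAseScore:
    @pytest.mark.parametrize(
        "n_sim,n_mel,expected",
        [(10, 0, 1.0), (0, 10, -1.0), (5, 5, 0.0), (30, 10, 0.5)],
    )
    def test_reference_values(self, n_sim, n_mel, expected):
        assert ase_score(n_sim, n_mel) == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ase_score(-1, 5)

    def test_below_floor_is_missing(self):
        assert np.isnan(ase_score(4, 5, min_reads=20))
        assert np.isnan(ase_score(0, 0))

    @given(a=counts, b=counts)
    def test_antisymmetry(self, a, b):
        if a + b > 0:
            assert ase_score(a, b) == pytest.approx(-ase_score(b, a))

    @given(a=counts, b=counts, c=st.integers(min_value=1, max_value=1000))
    def test_scale_invariance_and_bounds(self, a, b, c):
        if a + b > 0:
            s = ase_score(a, b)
            assert -1.0 <= s <= 1.0
            assert ase_score(a * c, b * c) == pytest.approx(s)


class TestScoreMatrix:
    def test_low_coverage_slices_are_missing(self, embryo):
        genes = [
            SvaseGeneSpec(gene_id="hi", base_expression=100.0),
            SvaseGeneSpec(gene_id="lo", base_expression=0.01),
        ]
        acm = simulate_slice_counts(embryo, genes, depth=1000, seed=0)
        ase = score_ase_matrix(acm, min_slice_reads=20)
        assert np.isfinite(ase.values.loc["hi"]).all()
        assert np.isnan(ase.values.loc["lo"]).all()
        # x positions are per-embryo midpoints
        np.testing.assert_allclose(
            ase.x.to_numpy(), embryo.slice_positions(), atol=1e-12
        )


def _two_direction_matrix(n_genes=50, depth=2000, seed=0, maternal_fraction=0.0):
    genes = [
        SvaseGeneSpec(gene_id=f"g{i}", maternal_fraction=maternal_fraction)
        for i in range(n_genes)
    ]
    embryos = [
        EmbryoSpec("m1", mother="mel"),
        EmbryoSpec("s1", mother="sim"),
    ]
    return simulate_slice_counts(embryos, genes, depth=depth, seed=seed)


class TestQcFilters:
    def _stats(self, acm, **overrides):
        stats_df = pd.DataFrame(
            {"total_reads": 3_000_000, "mapping_rate": 0.8},
            index=pd.Index(acm.sample_ids(), name="sample"),
        )
        for sid, vals in overrides.items():
            for k, v in vals.items():
                stats_df.loc[sid, k] = v
        return stats_df

    def test_sample_thresholds_with_inclusive_boundary(self):
        acm = _two_direction_matrix(n_genes=5)
        stats_df = self._stats(
            acm,
            m1_sl1={"total_reads": 900_000},
            m1_sl2={"mapping_rate": 0.51},
            m1_sl3={"mapping_rate": 0.52},  # boundary retained
        )
        filtered, report = apply_qc_filters(acm, stats_df)
        excluded = set(report.loc[report["kind"] == "sample", "item"])
        assert excluded == {"m1_sl1", "m1_sl2"}
        assert report.set_index("item").loc["m1_sl1", "reason"] == "min_sample_reads"
        assert filtered.counts[("m1", 1)].isna().all().all()
        assert filtered.counts[("m1", 3)].notna().all().all()

    def test_x_linked_genes_masked_in_male_embryos(self, embryo):
        genes = [
            SvaseGeneSpec(gene_id="auto", chromosome="autosome"),
            SvaseGeneSpec(gene_id="xg", chromosome="X"),
        ]
        male = EmbryoSpec("boy", mother="mel", sex="male")
        female = EmbryoSpec("girl", mother="mel", sex="female")
        acm = simulate_slice_counts([male, female], genes, depth=1000, seed=1)
        stats_df = self._stats(acm)
        filtered, report = apply_qc_filters(acm, stats_df)
        assert filtered.counts.loc["xg", "boy"].isna().all()
        assert filtered.counts.loc["xg", "girl"].notna().all()
        assert filtered.counts.loc["auto", "boy"].notna().all()
        assert (report["reason"] == "x_linked_male").any()

    def test_genes_without_supported_snps_dropped(self):
        acm = _two_direction_matrix(n_genes=3)
        stats_df = self._stats(acm)
        snp_support = pd.DataFrame(
            {
                "gene": ["g0", "g0", "g1"],
                "mel_reads": [100, 3, 100],
                "sim_reads": [100, 200, 9],
            }
        )
        filtered, report = apply_qc_filters(acm, stats_df, snp_support=snp_support)
        assert "g0" in filtered.counts.index  # one SNP passes
        assert "g1" not in filtered.counts.index  # 9 < 10 on the sim allele
        assert "g2" in filtered.counts.index  # no SNP info -> untouched

    def test_missing_sample_stats_rejected(self):
        acm = _two_direction_matrix(n_genes=2)
        stats_df = self._stats(acm).iloc[:-1]
        with pytest.raises(ValueError, match="missing entries"):
            apply_qc_filters(acm, stats_df)


class TestSpeciesBias:
    def test_strong_concordant_bias_called_against_binomial_oracle(self):
        acm = _two_direction_matrix(n_genes=2000, depth=5000, seed=7)
        c = acm.counts.copy()
        c.loc["g0"] = 0
        for emb in ("m1", "s1"):
            c.loc["g0", (emb, 1, "sim")] = 400
            c.loc["g0", (emb, 1, "mel")] = 100
        res = call_species_bias(
            AlleleCountMatrix(counts=c, embryos=acm.embryos), fdr=0.05
        )
        assert res.loc["g0", "call"] == "sim_biased"
        # direct binomial-CDF oracle: the two-sided p-value must be far
        # below even the most conservative multiple-testing bound
        p_oracle = stats.binomtest(400, 500, 0.5).pvalue
        assert p_oracle < 0.05 / 2000
        assert res.loc["g0", "q_mel"] < 0.05 and res.loc["g0", "q_sim"] < 0.05

    def test_discordant_directions_not_called(self):
        acm = _two_direction_matrix(n_genes=100, depth=5000, seed=8)
        c = acm.counts.copy()
        c.loc["g0"] = 0
        c.loc["g0", ("m1", 1, "sim")] = 400
        c.loc["g0", ("m1", 1, "mel")] = 100
        c.loc["g0", ("s1", 1, "sim")] = 100
        c.loc["g0", ("s1", 1, "mel")] = 400
        res = call_species_bias(
            AlleleCountMatrix(counts=c, embryos=acm.embryos), fdr=0.05
        )
        assert res.loc["g0", "call"] == "none"

    def test_balanced_counts_not_called(self):
        acm = _two_direction_matrix(n_genes=20, depth=2000, seed=9)
        res = call_species_bias(acm, fdr=0.05)
        assert (res["call"] == "none").all()

    def test_single_direction_rejected(self, embryo):
        genes = [SvaseGeneSpec(gene_id="g0")]
        acm = simulate_slice_counts(embryo, genes, depth=100, seed=0)
        with pytest.raises(ValueError, match="sim"):
            call_species_bias(acm)


class TestCompareGroupAse:
    def test_identical_groups_give_p_one(self):
        t, p = compare_group_ase([0.1, 0.2, 0.15], [0.1, 0.2, 0.15])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_separated_groups_significant(self):
        t, p = compare_group_ase([-0.9, -0.8, -0.85], [0.1, 0.2, 0.15])
        assert p < 0.01
        # cross-check against the scipy reference result
        ref = stats.ttest_ind([-0.9, -0.8, -0.85], [0.1, 0.2, 0.15])
        assert t == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))

    def test_swapping_groups_negates_t_keeps_p(self):
        t1, p1 = compare_group_ase([0.0, 0.1, 0.2], [0.5, 0.6])
        t2, p2 = compare_group_ase([0.5, 0.6], [0.0, 0.1, 0.2])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            compare_group_ase([0.1], [0.2, 0.3])


class TestMaternalZygoticSummary:
    def _matrix(self):
        genes = (
            [SvaseGeneSpec(gene_id=f"mat{i}", maternal_fraction=1.0) for i in range(10)]
            + [SvaseGeneSpec(gene_id=f"zyg{i}", maternal_fraction=0.0) for i in range(10)]
        )
        embryos = [EmbryoSpec("m1", mother="mel"), EmbryoSpec("s1", mother="sim")]
        return simulate_slice_counts(embryos, genes, depth=5000, seed=3)

    def test_maternal_genes_rank_above_zygotic(self):
        acm = self._matrix()
        ann = {f"mat{i}": "maternal" for i in range(10)}
        ann.update({f"zyg{i}": "zygotic" for i in range(10)})
        per_gene, summary = maternal_zygotic_summary(acm, ann)
        med = summary.set_index("klass")["median_log2fc"]
        assert med["maternal"] > 3.0
        assert abs(med["zygotic"]) < 0.5
        assert (
            per_gene[per_gene["klass"] == "maternal"]["maternal_log2fc"].min()
            > per_gene[per_gene["klass"] == "zygotic"]["maternal_log2fc"].max()
        )

    def test_low_count_genes_excluded(self, embryo):
        genes = [
            SvaseGeneSpec(gene_id="lo", base_expression=0.001),
            SvaseGeneSpec(gene_id="hi", base_expression=10.0),
        ]
        embryos = [EmbryoSpec("m1", mother="mel"), EmbryoSpec("s1", mother="sim")]
        acm = simulate_slice_counts(embryos, genes, depth=2000, seed=4)
        per_gene, _ = maternal_zygotic_summary(
            acm, {"lo": "zygotic", "hi": "zygotic"}
        )
        assert "lo" not in per_gene.index
        assert "hi" in per_gene.index

    def test_zero_paternal_counts_finite_via_pseudocount(self):
        acm = self._matrix()
        ann = {f"mat{i}": "maternal" for i in range(10)}
        ann.update({f"zyg{i}": "zygotic" for i in range(10)})
        with pytest.warns(UserWarning):
            maternal_zygotic_summary(acm, {"mat0": "maternal"})
        per_gene, _ = maternal_zygotic_summary(acm, ann)
        assert np.isfinite(per_gene["maternal_log2fc"]).all()
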