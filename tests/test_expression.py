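"""Gene assignment, normalisation, DEG calling and the wet-lab formulas."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad

from riescreen.expression import (
    call_degs,
    distance_bins,
    median_profile,
    nearest_gene,
    normalize_counts,
    qpcr_relative,
    read_gene_annotation,
    read_gtf_tss,
    reprogramming_efficiency,
    size_factors,
    two_tailed_p,
    unpaired_t_test,
)
from riescreen.intervals import GenomicInterval, IntervalSet
from riescreen.simulate import SimulationConfig, simulate_null_counts


def genes_df(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])


class TestNearestGene:
    def test_gene_at_distance_zero(self):
        sites = IntervalSet([GenomicInterval("chr1", 900, 1100)])
        genes = genes_df([("g1", "chr1", 1000, "+")])
        out = nearest_gene(sites, genes)
        assert out.loc[0, "gene_id"] == "g1" and out.loc[0, "distance_bp"] == 0

    def test_beyond_max_distance_unassigned(self):
        sites = IntervalSet([GenomicInterval("chr1", 0, 2)])  # midpoint 1
        genes = genes_df([("g1", "chr1", 1 + 2501, "+")])
        out = nearest_gene(sites, genes, max_distance_bp=2500)
        assert out.loc[0, "gene_id"] is None
        out2 = nearest_gene(sites, genes, max_distance_bp=2501)
        assert out2.loc[0, "gene_id"] == "g1"

    def test_tie_breaks_lexicographically(self):
        sites = IntervalSet([GenomicInterval("chr1", 900, 1100)])
        genes = genes_df([("zeta", "chr1", 900, "+"), ("alpha", "chr1", 1100, "-")])
        out = nearest_gene(sites, genes)
        assert out.loc[0, "gene_id"] == "alpha"

    def test_matches_exhaustive_scan(self, rng):
        genes = genes_df(
            [
                (f"g{i:03d}", f"chr{rng.integers(1, 3)}", int(rng.integers(0, 500_000)), "+")
                for i in range(50)
            ]
        )
        sites = IntervalSet(
            [
                GenomicInterval(f"chr{rng.integers(1, 3)}", s, s + 200)
                for s in rng.integers(0, 500_000, size=500)
            ]
        )
        out = nearest_gene(sites, genes, max_distance_bp=100_000)
        for row, iv in zip(out.itertuples(), sites):
            mid = iv.midpoint
            cands = [
                (abs(int(g.tss) - mid), g.gene_id)
                for g in genes.itertuples()
                if g.chrom == iv.chrom
            ]
            best = min(cands) if cands else None
            if best is None or best[0] > 100_000:
                assert row.gene_id is None
            else:
                assert (row.distance_bp, row.gene_id) == best

    def test_adding_genes_never_increases_distance(self, rng):
        sites = IntervalSet(
            [GenomicInterval("chr1", int(s), int(s) + 100) for s in rng.integers(0, 100_000, 50)]
        )
        g1 = genes_df([(f"a{i}", "chr1", int(t), "+") for i, t in enumerate(rng.integers(0, 100_000, 5))])
        extra = genes_df([(f"b{i}", "chr1", int(t), "+") for i, t in enumerate(rng.integers(0, 100_000, 20))])
        d1 = nearest_gene(sites, g1)["distance_bp"]
        d2 = nearest_gene(sites, pd.concat([g1, extra], ignore_index=True))["distance_bp"]
        assert (d2 <= d1).all()


class TestDistanceBins:
    def test_all_zero_distances_in_first_bin(self):
        assignments = pd.DataFrame({"gene_id": ["g"] * 5, "distance_bp": [0] * 5})
        hist = distance_bins(assignments)
        assert hist.iloc[0] == 5 and hist.iloc[1:].sum() == 0

    def test_empty_assignments(self):
        assignments = pd.DataFrame({"gene_id": [None], "distance_bp": [None]})
        assert distance_bins(assignments).sum() == 0

    def test_conservation(self, rng):
        d = rng.integers(0, 999_999, size=200)
        assignments = pd.DataFrame({"gene_id": ["g"] * 200, "distance_bp": d})
        assert distance_bins(assignments).sum() == 200


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self, rng):
        col = rng.integers(1, 1000, size=40)
        raw = pd.DataFrame({"a": col, "b": col, "c": col})
        assert np.allclose(size_factors(raw), 1.0)

    def test_doubled_column_forced_form(self):
        col = np.array([10, 100, 1000, 50])
        raw = pd.DataFrame({"s1": col, "s2": 2 * col})
        f = size_factors(raw)
        assert f["s1"] == pytest.approx(1 / math.sqrt(2))
        assert f["s2"] == pytest.approx(math.sqrt(2))

    def test_matches_definition_on_random_matrix(self, rng):
        raw = pd.DataFrame(
            rng.negative_binomial(10, 0.05, size=(50, 6)),
            columns=[f"s{i}" for i in range(6)],
        )
        f = size_factors(raw)
        # spreadsheet-style recomputation of the median-of-ratios definition
        mat = raw.to_numpy(dtype=float)
        keep = (mat > 0).all(axis=1)
        ref = np.prod(mat[keep], axis=1) ** (1 / mat.shape[1])
        for j, col in enumerate(raw.columns):
            assert f[col] == pytest.approx(np.median(mat[keep, j] / ref))

    def test_matches_deseq2_reference_implementation(self, rng):
        pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
        # odd number of reference genes so the two median conventions coincide
        raw = pd.DataFrame(
            rng.integers(1, 2000, size=(49, 5)), columns=[f"s{i}" for i in range(5)]
        )
        f = size_factors(raw)
        _, ref = pydeseq2.deseq2_norm(raw.T.to_numpy(dtype=float))
        assert np.allclose(f.to_numpy(), ref)

    def test_no_reference_gene_rejected(self):
        raw = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError):
            size_factors(raw)

    def test_global_scaling_absorbed(self, rng):
        raw = pd.DataFrame(
            rng.integers(1, 500, size=(30, 4)), columns=list("abcd")
        )
        scaled = raw.copy()
        scaled["d"] = raw["d"] * 3
        f1 = size_factors(raw)
        f2 = size_factors(scaled)
        # the perturbed sample's factor absorbs the full 3x; every factor also
        # carries the common 3^(1/4) shift of the geometric-mean reference
        shift = 3 ** (1 / 4)
        assert f2["d"] == pytest.approx(3 * f1["d"] / shift)
        for col in "abc":
            assert f2[col] == pytest.approx(f1[col] / shift)
        norm1, _ = normalize_counts(raw)
        norm2, _ = normalize_counts(scaled)
        pd.testing.assert_frame_equal(norm1 * shift, norm2)


class TestMedianProfile:
    def _matrix(self):
        cols = ["D0_1", "D0_2", "ESC_1", "ESC_2"]
        return pd.DataFrame(
            [[4, 4, 4, 4], [0, 0, 0, 0], [2, 4, 6, 10]],
            index=pd.Index(["flat", "silent", "rising"], name="gene_id"),
            columns=cols,
        )

    def test_constant_gene_flat_profile(self):
        prof = median_profile(["flat"], self._matrix())
        assert (prof == 4).all()

    def test_all_zero_gene_excluded(self):
        prof = median_profile(["silent", "rising"], self._matrix())
        assert prof["D0"] == 3.0 and prof["ESC"] == 8.0

    def test_all_silent_set_rejected(self):
        with pytest.raises(ValueError):
            median_profile(["silent"], self._matrix())

    def test_matches_direct_recomputation(self, rng):
        cols = [f"{tp}_{r}" for tp in ("D0", "D3", "ESC") for r in (1, 2)]
        norm = pd.DataFrame(
            rng.random((20, 6)) * 100,
            index=pd.Index([f"g{i}" for i in range(20)], name="gene_id"),
            columns=cols,
        )
        prof = median_profile([f"g{i}" for i in range(20)], norm)
        for tp in ("D0", "D3", "ESC"):
            per_gene = norm[[f"{tp}_1", f"{tp}_2"]].mean(axis=1)
            assert prof[tp] == pytest.approx(np.median(per_gene))


class TestCallDegs:
    def _planted(self, rng, n_genes=100, n_up=20, lfc=3.0, reps=3):
        base = np.exp(rng.uniform(np.log(200), np.log(2000), size=n_genes))
        mean_b = base.copy()
        mean_b[:n_up] *= 2.0 ** lfc
        cols = {}
        for r in range(reps):
            cols[f"A_{r+1}"] = rng.poisson(base)
        for r in range(reps):
            cols[f"B_{r+1}"] = rng.poisson(mean_b)
        raw = pd.DataFrame(cols, index=pd.Index([f"g{i:03d}" for i in range(n_genes)], name="gene_id"))
        return raw, [f"A_{r+1}" for r in range(reps)], [f"B_{r+1}" for r in range(reps)]

    def test_planted_up_genes_recovered(self, rng):
        raw, ga, gb = self._planted(rng)
        degs = call_degs(raw, ga, gb)
        up = set(degs[degs["direction"] == "up"].index)
        assert {f"g{i:03d}" for i in range(20)} <= up

    def test_threshold_boundary_is_strict(self):
        # direction is derived with strict inequalities: a gene at exactly the
        # fold-change bound is excluded
        raw = pd.DataFrame(
            {
                "A_1": [100, 100],
                "A_2": [100, 100],
                "B_1": [100, 100],
                "B_2": [100, 100],
            },
            index=pd.Index(["g0", "g1"], name="gene_id"),
        )
        out = call_degs(raw, ["A_1", "A_2"], ["B_1", "B_2"], lfc_threshold=0.0)
        assert (out["direction"] == "none").all()  # log2fc == 0 is not > 0

    def test_null_data_rarely_called(self):
        rates = []
        for rep in range(50):
            raw = simulate_null_counts(
                SimulationConfig(seed=1000 + rep, replicates=3), n_genes=60
            )
            degs = call_degs(raw, [f"A_{i}" for i in (1, 2, 3)], [f"B_{i}" for i in (1, 2, 3)])
            rates.append((degs["direction"] != "none").mean())
        assert np.mean(rates) <= 0.07

    def test_degenerate_group_sizes_rejected(self):
        raw = pd.DataFrame({"A_1": [1], "B_1": [1], "B_2": [2]}, index=["g"])
        with pytest.raises(ValueError):
            call_degs(raw, ["A_1"], ["B_1", "B_2"])

    def test_bh_adjustment_is_monotone(self, rng):
        raw, ga, gb = self._planted(rng, n_genes=80, n_up=10)
        degs = call_degs(raw, ga, gb)
        ordered = degs.sort_values("pvalue")
        assert ordered["padj"].is_monotonic_increasing


class TestWetLabFormulas:
    @pytest.mark.parametrize(
        "ct_t, ct_r, expected", [(20.0, 20.0, 1.0), (21.0, 20.0, 0.5), (18.0, 20.0, 4.0)]
    )
    def test_qpcr_relative(self, ct_t, ct_r, expected):
        assert qpcr_relative(ct_t, ct_r) == pytest.approx(expected)

    def test_efficiency_formula(self):
        assert reprogramming_efficiency(0, 1000) == 0.0
        assert reprogramming_efficiency(50, 100_000) == pytest.approx(0.05)
        # fold between equal-seeding conditions reduces to the colony ratio
        fold = reprogramming_efficiency(80, 1000) / reprogramming_efficiency(40, 1000)
        assert fold == pytest.approx(80 / 40)
        with pytest.raises(ValueError):
            reprogramming_efficiency(5, 0)

    def test_identical_groups_give_t0_p1(self):
        t, df, p = unpaired_t_test([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert (t, p) == (0.0, 1.0) and df == 4

    def test_reported_statistic_reproduces_printed_p(self):
        # the published efficiency comparison: t = 3.525, df = 4 -> p = 0.024
        assert round(two_tailed_p(3.525, 4), 3) == 0.024

    def test_matches_scipy_and_quadrature(self, rng):
        a = rng.normal(0, 1, size=6)
        b = rng.normal(1, 1.5, size=5)
        t, df, p = unpaired_t_test(a, b)
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(t_ref) and p == pytest.approx(p_ref)
        # numerical integration of the t density as an independent oracle
        dens = lambda x: stats.t.pdf(x, df)
        tail, _ = quad(dens, abs(t), np.inf)
        assert p == pytest.approx(2 * tail, abs=1e-6)


class TestAnnotationReaders:
    def test_tsv_roundtrip(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text("gene_id\tchrom\ttss\tstrand\ng1\tchr1\t100\t+\ng2\tchr2\t500\t-\n")
        df = read_gene_annotation(path)
        assert list(df["gene_id"]) == ["g1", "g2"]
        assert df.loc[1, "tss"] == 500

    def test_duplicate_gene_rejected(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text("g1\tchr1\t100\t+\ng1\tchr1\t200\t+\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gene_annotation(path)

    def test_gtf_tss_strand_convention(self, tmp_path):
        path = tmp_path / "genes.gtf"
        path.write_text(
            'chr1\tsrc\ttranscript\t101\t500\t.\t+\t.\tgene_id "gp";\n'
            'chr1\tsrc\ttranscript\t101\t500\t.\t-\t.\tgene_id "gm";\n'
            'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "gp";\n'
        )
        df = read_gtf_tss(path).set_index("gene_id")
        assert df.loc["gp", "tss"] == 100  # GTF start 101 -> 0-based 100
        assert df.loc["gm", "tss"] == 499  # minus strand: end - 1, 0-based
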