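import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenoheight import association as assoc
from phenoheight import synthetic_field as sf
from phenoheight.genotypes import GenotypeMatrix


def _toy_matrix(dosages, chrom=None, pos=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    chrom = np.array(chrom if chrom is not None else ["A01"] * m, dtype=object)
    pos = np.array(pos if pos is not None else np.arange(1, m + 1) * 100)
    return GenotypeMatrix(
        dosages,
        chrom,
        pos,
        np.array([f"S{i}" for i in range(n)], dtype=object),
        np.array([f"snp{j}" for j in range(m)], dtype=object),
    )


class TestBlue:
    def test_balanced_design_equals_means(self, rng):
        values = rng.uniform(0.5, 1.0, (5, 3))
        records = pd.DataFrame(
            {
                "accession": np.repeat([f"A{i}" for i in range(5)], 3),
                "replicate": np.tile([1, 2, 3], 5),
                "value": values.ravel(),
            }
        )
        blue = assoc.compute_blue(records)
        np.testing.assert_allclose(blue.values, values.mean(axis=1), atol=1e-12)

    def test_replicate_shift_preserves_contrasts(self):
        # 3 accessions x 3 reps; rep 2 shifted +0.1 for everyone
        base = {"A": 0.5, "B": 0.6, "C": 0.8}
        rows = []
        for acc, v in base.items():
            for rep in (1, 2, 3):
                rows.append((acc, rep, v + (0.1 if rep == 2 else 0.0)))
        blue = assoc.compute_blue(pd.DataFrame(rows, columns=["accession", "replicate", "value"]))
        assert blue["B"] - blue["A"] == pytest.approx(0.1, abs=1e-12)
        assert blue["C"] - blue["A"] == pytest.approx(0.3, abs=1e-12)

    def test_single_record_passes_through(self):
        records = pd.DataFrame({"accession": ["X"], "replicate": [1], "value": [0.77]})
        assert assoc.compute_blue(records)["X"] == pytest.approx(0.77)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            assoc.compute_blue(pd.DataFrame(columns=["accession", "replicate", "value"]))


class TestFilterSnps:
    def test_hand_counted_toy(self):
        # SNP 0: dosages (0,0,0,1) -> alt freq 1/8 = 0.125 > 0.05, kept
        # SNP 1: monomorphic, removed
        # SNP 2: common, kept
        G = _toy_matrix(np.column_stack([[0, 0, 0, 1], [0, 0, 0, 0], [1, 1, 0, 2]]))
        out = assoc.filter_snps(G)
        assert list(out.snp_ids) == ["snp0", "snp2"]

    def test_missingness_threshold_strict(self):
        # 2 of 10 missing = 20 % >= 10 %, removed; 0 missing kept
        col_bad = np.array([0, 1, 1, 0, 1, 0, 1, 1, -1, -1])
        col_ok = np.array([0, 1, 1, 0, 1, 0, 1, 1, 0, 1])
        G = _toy_matrix(np.column_stack([col_bad, col_ok]))
        out = assoc.filter_snps(G)
        assert list(out.snp_ids) == ["snp1"]

    def test_idempotent_subset(self, small_genotypes):
        G, _ = small_genotypes
        once = assoc.filter_snps(G)
        twice = assoc.filter_snps(once)
        assert set(once.snp_ids) <= set(G.snp_ids)
        np.testing.assert_array_equal(once.dosages, twice.dosages)


class TestKinship:
    def test_duplicate_sample_similarity_one(self):
        row = np.array([0, 1, 2, 1, 0, 2, 1, 0])
        G = _toy_matrix(np.vstack([row, row, 2 - row]))
        K = assoc.kinship(G)
        assert K[0, 1] == pytest.approx(1.0)
        assert K[0, 2] < 1.0

    def test_matches_pairwise_loop_oracle(self, small_genotypes):
        G, _ = small_genotypes
        sub = G.take_snps(np.arange(100))
        K = assoc.kinship(sub)
        X = sub.imputed()
        n = sub.n_samples
        for i in range(0, n, 7):
            for j in range(0, n, 11):
                expect = 1.0 - np.abs(X[i] - X[j]).mean() / 2.0
                assert K[i, j] == pytest.approx(expect, abs=1e-12)

    def test_symmetric_unit_diagonal(self, small_genotypes):
        G, _ = small_genotypes
        K = assoc.kinship(G)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(K), 1.0)
        assert np.all((K >= 0) & (K <= 1))


class TestMixedScan:
    def test_identity_kinship_equals_ols(self, small_genotypes, rng):
        G, _ = small_genotypes
        y = rng.normal(0.8, 0.1, G.n_samples)
        res = assoc.mixed_scan(y, G, np.eye(G.n_samples))
        X = G.imputed()
        for j in range(0, G.n_snps, 17):
            ols_p = stats.linregress(X[:, j], y).pvalue
            dlog = abs(np.log10(res.table["p_value"].iloc[j]) - np.log10(ols_p))
            assert dlog < 0.01

    def test_covariate_support_and_dim_checks(self, small_genotypes, rng):
        G, _ = small_genotypes
        y = rng.normal(0, 1, G.n_samples)
        cov = rng.normal(0, 1, G.n_samples)
        res = assoc.mixed_scan(y, G, np.eye(G.n_samples), covariates=cov)
        assert len(res.table) == G.n_snps
        with pytest.raises(ValueError):
            assoc.mixed_scan(y[:-1], G, np.eye(G.n_samples))
        with pytest.raises(ValueError):
            assoc.mixed_scan(y, G, np.eye(G.n_samples - 1))

    def test_non_psd_kinship_rejected(self, small_genotypes, rng):
        G, _ = small_genotypes
        n = G.n_samples
        K = -np.eye(n)
        with pytest.raises(ValueError):
            assoc.mixed_scan(rng.normal(0, 1, n), G, K)

    def test_structured_null_is_calibrated(self):
        truth = sf.GenotypeTruth(h2=0.5, n_subpop=2, fst_like=0.1)
        G = sf.generate_genotypes(200, 600, missing_rate=0.02, truth=truth, seed=31)
        Gf = assoc.filter_snps(G)
        K = assoc.kinship(Gf)
        pheno, _ = sf.generate_phenotypes(Gf, truth, n_reps=1, seed=32)
        res = assoc.mixed_scan(pheno["value"].to_numpy(), Gf, K)
        lam = assoc.genomic_control_lambda(res.table["p_value"].to_numpy())
        assert 0.85 < lam < 1.15


class TestPeaks:
    def _result(self, pos_nlp, time_point=0, chrom="A01"):
        pos = np.array([p for p, _ in pos_nlp])
        nlp = np.array([v for _, v in pos_nlp])
        table = pd.DataFrame(
            {
                "snp_id": [f"{chrom}_{p}" for p in pos],
                "chrom": chrom,
                "pos": pos,
                "beta": 0.0,
                "se": 1.0,
                "p_value": 10.0**-nlp,
                "neg_log10_p": nlp,
            }
        )
        return assoc.ScanResult(table, 1.0, 1.0, time_point)

    def test_no_significant_snps_no_peaks(self):
        res = self._result([(100, 2.0), (200, 3.0)])
        assert assoc.significant_peaks([res]) == []

    def test_hand_grouping(self):
        res = self._result(
            [(3_750_000, 6.0), (3_800_000, 7.5), (3_880_000, 5.5), (10_000_000, 6.2)]
        )
        peaks = assoc.significant_peaks([res], merge_window=500_000)
        assert len(peaks) == 2
        assert (peaks[0].start, peaks[0].end) == (3_750_000, 3_880_000)
        assert peaks[0].top_snp == "A01_3800000"
        assert (peaks[1].start, peaks[1].end) == (10_000_000, 10_000_000)

    def test_identical_time_points_all_replicated(self):
        a = self._result([(1_000_000, 6.0)], time_point=0)
        b = self._result([(1_000_100, 6.5)], time_point=1)
        peaks = assoc.significant_peaks([a, b])
        assert all(p.replicated for p in peaks)

    def test_no_overlap_within_time_point(self):
        res = self._result([(i * 100_000, 6.0) for i in range(1, 30)])
        peaks = assoc.significant_peaks([res], merge_window=250_000)
        same_t = [p for p in peaks if p.time_point == 0]
        for i, p in enumerate(same_t):
            for q in same_t[i + 1:]:
                assert not p.overlaps(q)


class TestGenes:
    def _annotation(self):
        return pd.DataFrame(
            {
                "chrom": ["A01", "A01", "A01"],
                "start": [100, 1_000, 5_000],
                "end": [300, 1_200, 5_400],
                "gene_id": ["g1", "g2", "g3"],
                "name": ["g1", "g2", "g3"],
            }
        )

    def _peak(self, start, end):
        return assoc.Peak("A01", start, end, "s", 6.0, 0, {0})

    def test_overlapping_genes_found(self):
        hit = assoc.genes_in_interval(self._annotation(), self._peak(250, 1_100))
        assert list(hit["gene_id"]) == ["g1", "g2"]

    def test_gene_desert_empty(self):
        assert assoc.genes_in_interval(self._annotation(), self._peak(2_000, 3_000)).empty

    def test_abutting_gene_included(self):
        # 1-based inclusive: a gene starting exactly at the peak end overlaps
        hit = assoc.genes_in_interval(self._annotation(), self._peak(400, 1_000))
        assert list(hit["gene_id"]) == ["g2"]

    def test_gff3_round_trip(self, tmp_path):
        ann = self._annotation()
        path = str(tmp_path / "a.gff3")
        sf.write_gff3(ann, path)
        back = assoc.read_gff3_genes(path)
        pd.testing.assert_frame_equal(
            back[["chrom", "start", "end", "gene_id"]],
            ann[["chrom", "start", "end", "gene_id"]],
        )


class TestHaplotypes:
    def _panel(self, rng, n=400):
        d1 = rng.choice([0, 2], n)
        d2 = d1.copy()  # perfectly linked pair forming two haplotypes
        other = rng.integers(0, 3, (n, 3))
        dosages = np.column_stack([d1, other[:, 0], d2, other[:, 1:]])
        return _toy_matrix(dosages), d1

    def test_planted_effect_detected(self, rng):
        G, d1 = self._panel(rng)
        base = rng.normal(0.8, 0.03, (len(d1), 2))
        pheno = pd.DataFrame(
            base + 0.1 * (d1 == 0)[:, None],
            index=G.sample_ids,
            columns=[0, 1],
        )
        out = assoc.haplotype_compare(G, ("snp0", "snp2"), pheno)
        assert np.all(np.abs(np.abs(out["difference"]) - 0.1) < 0.02)
        assert np.all(out["p_value"] < 0.01)

    def test_null_difference_small(self, rng):
        G, d1 = self._panel(rng)
        pheno = pd.DataFrame(
            rng.normal(0.8, 0.05, (len(d1), 1)), index=G.sample_ids, columns=[0]
        )
        out = assoc.haplotype_compare(G, ("snp0", "snp2"), pheno)
        assert abs(out["difference"].iloc[0]) < 0.03

    def test_single_haplotype_rejected(self, rng):
        dosages = np.column_stack([np.zeros(50, int), np.zeros(50, int)])
        G = _toy_matrix(dosages)
        pheno = pd.DataFrame(np.ones((50, 1)), index=G.sample_ids, columns=[0])
        with pytest.raises(ValueError):
            assoc.haplotype_compare(G, ("snp0", "snp1"), pheno)

    def test_missing_snp_rejected(self, rng):
        G, _ = self._panel(rng)
        pheno = pd.DataFrame(np.ones((G.n_samples, 1)), index=G.sample_ids, columns=[0])
        with pytest.raises(ValueError):
            assoc.haplotype_compare(G, ("snp0", "nope"), pheno)


class TestExport:
    def test_qq_expected_quantiles(self, small_genotypes, rng):
        G, _ = small_genotypes
        y = rng.normal(0, 1, G.n_samples)
        res = assoc.mixed_scan(y, G, np.eye(G.n_samples))
        manhattan, qq = assoc.export_scan(res)
        m = len(qq)
        np.testing.assert_allclose(
            qq["expected"], -np.log10((np.arange(1, m + 1) - 0.5) / m)
        )
        assert qq["observed"].is_monotonic_decreasing

    def test_cumulative_coordinates_strictly_increasing(self, small_genotypes, rng):
        G, _ = small_genotypes
        y = rng.normal(0, 1, G.n_samples)
        res = assoc.mixed_scan(y, G, np.eye(G.n_samples))
        manhattan, _ = assoc.export_scan(res)
        assert (np.diff(manhattan["cum_pos"]) > 0).all()

    def test_csv_round_trip(self, tmp_path, small_genotypes, rng):
        G, _ = small_genotypes
        y = rng.normal(0, 1, G.n_samples)
        res = assoc.mixed_scan(y, G, np.eye(G.n_samples))
        path = str(tmp_path / "scan.csv")
        res.table.to_csv(path, index=False)
        back = pd.read_csv(path)
        np.testing.assert_allclose(back["p_value"], res.table["p_value"])
        assert list(back["snp_id"]) == list(res.table["snp_id"])
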