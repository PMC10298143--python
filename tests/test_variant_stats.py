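"""Statistical layer: ANOVA, site selection, germline and heteroplasmy calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mitovar.allele_matrices import AlleleFrequencyMatrix
from mitovar.reference_io import MitoReference, Variant, enumerate_variants
from mitovar.variant_stats import (
    AnalysisParams,
    DonorLabels,
    anova_table,
    discriminative_germline,
    donor_mean_af,
    heteroplasmy_scan,
    informative_variants,
    select_variable_sites,
    site_anova,
)


def af_matrix(rows: np.ndarray, cell_ids=None) -> AlleleFrequencyMatrix:
    """Wrap a raw AF array in a matrix with synthetic variant rows."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    ref = MitoReference("chrM", "A" * rows.shape[0])
    variants = [Variant(position=i + 1, ref="A", alt="G") for i in range(rows.shape[0])]
    cells = cell_ids or [f"c{i}" for i in range(rows.shape[1])]
    return AlleleFrequencyMatrix(values=rows, variants=variants, cell_ids=list(cells))


def two_group_labels(n_a: int, n_b: int) -> DonorLabels:
    mapping = {f"c{i}": ("A" if i < n_a else "B") for i in range(n_a + n_b)}
    return DonorLabels(mapping=mapping)


class TestSiteAnova:
    def test_worked_example_f54(self):
        """{0.1,0.2,0.3} vs {0.7,0.8,0.9}: F = 54 on df (1, 4)."""
        row = pd.Series([0.1, 0.2, 0.3, 0.7, 0.8, 0.9],
                        index=[f"c{i}" for i in range(6)])
        res = site_anova(row, two_group_labels(3, 3))
        assert res.F == pytest.approx(54.0, rel=1e-12)
        assert (res.df_between, res.df_within) == (1, 4)
        # closed form: SSB = 0.54, SSW = 0.04 -> (0.54/1)/(0.04/4)
        assert res.F == pytest.approx((0.54 / 1) / (0.04 / 4), rel=1e-12)
        # independent oracles: scipy one-way ANOVA, and pooled t squared
        f_sp, p_sp = sps.f_oneway([0.1, 0.2, 0.3], [0.7, 0.8, 0.9])
        assert res.F == pytest.approx(f_sp, rel=1e-12)
        assert res.p == pytest.approx(p_sp, rel=1e-9)
        t, _ = sps.ttest_ind([0.1, 0.2, 0.3], [0.7, 0.8, 0.9])
        assert res.F == pytest.approx(t * t, rel=1e-10)
        assert res.group_means == pytest.approx({"A": 0.2, "B": 0.8})

    def test_identical_groups_give_f0_p1(self):
        row = pd.Series([0.2, 0.2, 0.2, 0.2], index=[f"c{i}" for i in range(4)])
        res = site_anova(row, two_group_labels(2, 2))
        assert (res.F, res.p, res.log10_p) == (0.0, 1.0, 0.0)

    def test_zero_within_variance_gives_infinite_f(self):
        row = pd.Series([0, 0, 0, 1, 1, 1], dtype=float,
                        index=[f"c{i}" for i in range(6)])
        res = site_anova(row, two_group_labels(3, 3))
        assert np.isinf(res.F)
        assert res.p == 0.0
        assert res.log10_p == -np.inf

    def test_missing_values_dropped_not_imputed(self):
        row = pd.Series([0.1, 0.2, np.nan, 0.8, 0.9, np.nan],
                        index=[f"c{i}" for i in range(6)])
        res = site_anova(row, two_group_labels(3, 3))
        assert res.group_n == {"A": 2, "B": 2}
        f_sp, _ = sps.f_oneway([0.1, 0.2], [0.8, 0.9])
        assert res.F == pytest.approx(f_sp, rel=1e-12)

    def test_untestable_single_covered_group_raises(self):
        row = pd.Series([0.1, 0.2, np.nan, np.nan],
                        index=[f"c{i}" for i in range(4)])
        with pytest.raises(ValueError, match="untestable"):
            site_anova(row, two_group_labels(2, 2))

    def test_agrees_with_scipy_on_random_datasets(self):
        """1,000 random small layouts vs scipy.stats.f_oneway."""
        rng = np.random.default_rng(202)
        for _ in range(1000):
            k = rng.integers(2, 5)
            groups = [rng.random(rng.integers(2, 8)) for _ in range(k)]
            cells, vals, mapping = [], [], {}
            for gi, g in enumerate(groups):
                for vi, v in enumerate(g):
                    cid = f"g{gi}v{vi}"
                    cells.append(cid)
                    vals.append(v)
                    mapping[cid] = f"d{gi}"
            res = site_anova(pd.Series(vals, index=cells), DonorLabels(mapping))
            f_sp, p_sp = sps.f_oneway(*groups)
            assert res.F == pytest.approx(f_sp, rel=1e-9, abs=1e-12)
            assert res.p == pytest.approx(p_sp, rel=1e-6, abs=1e-12)

    def test_two_group_f_equals_pooled_t_squared(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            a = rng.normal(0.3, 0.1, rng.integers(3, 10))
            b = rng.normal(0.5, 0.1, rng.integers(3, 10))
            cells = [f"a{i}" for i in range(a.size)] + [f"b{i}" for i in range(b.size)]
            mapping = {c: c[0] for c in cells}
            res = site_anova(
                pd.Series(np.concatenate([a, b]), index=cells), DonorLabels(mapping)
            )
            t, _ = sps.ttest_ind(a, b)  # pooled variance by default
            assert res.F == pytest.approx(t * t, rel=1e-10)

    def test_invariant_to_relabeling_and_reordering(self):
        rng = np.random.default_rng(33)
        vals = rng.random(12)
        cells = [f"c{i}" for i in range(12)]
        mapping = {c: f"d{i % 3}" for i, c in enumerate(cells)}
        base = site_anova(pd.Series(vals, index=cells), DonorLabels(mapping))
        perm = rng.permutation(12)
        shuffled = site_anova(
            pd.Series(vals[perm], index=[cells[i] for i in perm]),
            DonorLabels(mapping),
        )
        renamed = site_anova(
            pd.Series(vals, index=cells),
            DonorLabels({c: "x" + d for c, d in mapping.items()}),
        )
        for other in (shuffled, renamed):
            assert other.F == pytest.approx(base.F, rel=1e-12)
            assert other.log10_p == pytest.approx(base.log10_p, rel=1e-12)


class TestSelectVariableSites:
    def test_variance_ordering_and_ties(self):
        rows = np.array(
            [
                [0.5, 0.5, 0.5, 0.5],   # zero variance
                [0.0, 1.0, 0.0, 1.0],   # variance 1/3
                [0.4, 0.6, 0.4, 0.6],   # variance ~0.013
            ]
        )
        af = af_matrix(rows)
        sites = select_variable_sites(af, n=3, min_covered_cells=2)
        assert [v.position for v in sites] == [2, 3, 1]

    def test_min_covered_cells_excludes_sparse_rows(self):
        rows = np.array(
            [
                [0.0, 1.0, np.nan, np.nan],
                [0.4, 0.6, 0.5, 0.5],
            ]
        )
        af = af_matrix(rows)
        sites = select_variable_sites(af, n=5, min_covered_cells=3)
        assert [v.position for v in sites] == [2]

    def test_n_clamps_to_eligible_count(self):
        af = af_matrix(np.array([[0.1, 0.9, 0.5, 0.5]]))
        assert len(select_variable_sites(af, n=100, min_covered_cells=2)) == 1

    def test_no_eligible_raises(self):
        af = af_matrix(np.array([[0.1, np.nan, np.nan, np.nan]]))
        with pytest.raises(ValueError, match="no variant"):
            select_variable_sites(af, n=1, min_covered_cells=2)


class TestInformativeVariants:
    def test_injected_fixed_variant_found_first(self):
        rng = np.random.default_rng(1)
        n = 100  # 50 cells per donor
        noise = rng.random((5, n)) * 0.01
        signal = np.concatenate([np.ones(50), np.zeros(50)])[None, :]
        af = af_matrix(np.vstack([noise[:2], signal, noise[2:]]))
        labels = two_group_labels(50, 50)
        hits = informative_variants(af, labels, AnalysisParams())
        assert hits[0].variant.position == 3
        assert hits[0].p < 1e-100

    def test_duplicated_donor_yields_empty(self):
        rng = np.random.default_rng(2)
        vals = np.tile(rng.random(5)[:, None], (1, 8))
        af = af_matrix(vals)
        labels = two_group_labels(4, 4)
        assert informative_variants(af, labels, AnalysisParams()) == []

    def test_threshold_one_returns_all_testable(self):
        rng = np.random.default_rng(3)
        af = af_matrix(rng.random((6, 10)))
        labels = two_group_labels(5, 5)
        params = AnalysisParams(anova_p_threshold=1.0)
        assert len(informative_variants(af, labels, params)) == 6


class TestDiscriminativeGermline:
    def test_single_carrier_kept_multi_carrier_excluded(self):
        rows = np.array(
            [
                [0.98, 0.97, 0.01, 0.02, 0.01, 0.02],  # donor A fixed
                [0.95, 0.96, 0.95, 0.96, 0.01, 0.02],  # two donors high
                [0.99, 0.99, 0.99, 0.99, 0.99, 0.99],  # all donors high
                [0.01, 0.02, 0.01, 0.02, 0.95, 0.97],  # donor C fixed
            ]
        )
        mapping = {f"c{i}": d for i, d in enumerate("AABBCC")}
        af = af_matrix(rows)
        calls = discriminative_germline(af, DonorLabels(mapping))
        found = {r.variant.position: carrier for r, carrier in calls}
        assert found == {1: "A", 4: "C"}

    def test_sorted_by_p_ascending(self, germline_matrices):
        _, _, af, _, labels = germline_matrices
        calls = discriminative_germline(af, labels)
        logps = [r.log10_p for r, _ in calls]
        assert logps == sorted(logps)

    def test_recovers_all_injected_markers_no_false_positives(
        self, germline_dataset, germline_matrices
    ):
        _, _, af, _, labels = germline_matrices
        calls = discriminative_germline(af, labels)
        truth = {
            (v.label, t.donor_id)
            for t in germline_dataset.truth
            for v in t.germline
        }
        called = {(r.variant.label, carrier) for r, carrier in calls}
        assert called == truth  # all 40 in, nothing extra


class TestHeteroplasmyScan:
    def test_band_rule_and_germline_exclusion(self):
        # donor A: heteroplasmy at 0.10; site 2 is a germline marker of A;
        # site 3 sits above the band for its carrier
        rows = np.array(
            [
                [0.12, 0.08, 0.10, 0.001, 0.0, 0.001],
                [0.98, 0.97, 0.99, 0.01, 0.0, 0.02],
                [0.30, 0.32, 0.31, 0.001, 0.0, 0.001],
            ]
        )
        mapping = {f"c{i}": ("A" if i < 3 else "B") for i in range(6)}
        af = af_matrix(rows)
        cov = _full_coverage_for(af)
        calls = heteroplasmy_scan(af, cov, DonorLabels(mapping))
        assert [c.variant.position for c in calls] == [1]
        assert calls[0].carriers == ["A"]
        assert calls[0].donor_means["A"] == pytest.approx(0.10, abs=0.001)

    def test_fixture_recovery_and_af_accuracy(self, het_dataset, het_matrices):
        _, cov, af, _, labels = het_matrices
        calls = heteroplasmy_scan(af, cov, labels)
        truth = {
            v.label: (t.donor_id, mu)
            for t in het_dataset.truth
            for v, mu, _ in t.heteroplasmies
        }
        called = {c.variant.label: c for c in calls}
        assert set(called) == set(truth)  # all 8, no extras
        germ = {r.variant.label for r, _ in discriminative_germline(af, labels)}
        assert not germ & set(called)
        for label, (donor, mu) in truth.items():
            call = called[label]
            assert call.carriers == [donor]
            assert call.donor_means[donor] == pytest.approx(mu, abs=0.03)


def _full_coverage_for(af):
    import scipy.sparse as sp

    from mitovar.allele_matrices import CoverageMatrix

    L = max(v.position for v in af.variants)
    X = sp.csr_matrix(np.full((L, len(af.cell_ids)), 50, dtype=np.int64))
    return CoverageMatrix(X=X, cell_ids=list(af.cell_ids), contig_name="chrM")


class TestDonorMeans:
    def test_pseudobulk_pools_reads_cell_mean_does_not(self):
        import scipy.sparse as sp

        from mitovar.allele_matrices import CoverageMatrix

        af = af_matrix(np.array([[0.5, 0.0, 0.2, 0.2]]))
        depth = np.array([[30, 10, 50, 50]], dtype=np.int64)
        cov = CoverageMatrix(
            X=sp.csr_matrix(depth), cell_ids=list(af.cell_ids), contig_name="chrM"
        )
        labels = DonorLabels({"c0": "A", "c1": "A", "c2": "B", "c3": "B"})
        cell_mean = donor_mean_af(af, labels, mode="cell_mean")
        pooled = donor_mean_af(af, labels, cov=cov, mode="pseudobulk")
        assert cell_mean.loc["1A>G", "A"] == pytest.approx(0.25)
        assert pooled.loc["1A>G", "A"] == pytest.approx((0.5 * 30 + 0.0 * 10) / 40)
        assert pooled.loc["1A>G", "B"] == pytest.approx(0.2)


class TestDonorLabels:
    def test_tsv_parsing_requires_header(self, tmp_path):
        p = tmp_path / "labels.tsv"
        p.write_text("cell_id\tdonor_id\nc1\td1\nc2\td2\n")
        labels = DonorLabels.from_tsv(p)
        assert labels.donors == ["d1", "d2"]
        bad = tmp_path / "bad.tsv"
        bad.write_text("cell\tdonor\nc1\td1\n")
        with pytest.raises(ValueError, match="cell_id"):
            DonorLabels.from_tsv(bad)

    def test_fewer_than_two_donors_rejected(self):
        with pytest.raises(ValueError, match="2 donors"):
            DonorLabels({"c1": "d1", "c2": "d1"})

    def test_labeled_cell_absent_from_matrix_errors(self):
        af = af_matrix(np.array([[0.1, 0.2]]))
        labels = DonorLabels({"c0": "A", "ghost": "B"})
        with pytest.raises(ValueError, match="absent"):
            site_anova(af.row(af.variants[0]), labels)
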