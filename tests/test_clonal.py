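import numpy as np
import pandas as pd
import pytest

import pairedtumor as pt

from conftest import make_records


def matrix_from_observations(pre_set, post_set, universe, maf=0.3):
    """Build a union matrix where each named locus is observed per the sets."""
    rows = []
    for i, name in enumerate(sorted(universe)):
        pos = 100 * (i + 1)
        pre_alt = 6 if name in pre_set else 0
        post_alt = 6 if name in post_set else 0
        rows.append(("S01_pre", "pre", "chr1", pos, "A", "T", 20 - pre_alt, pre_alt,
                     50.0 if name in pre_set else 1.0))
        rows.append(("S01_post", "post", "chr1", pos, "A", "T", 20 - post_alt, post_alt,
                     50.0 if name in post_set else 1.0))
    return pt.build_union_maf(make_records(rows))


class TestClassify:
    def test_definitional_private_fractions(self):
        m = matrix_from_observations({"A", "B", "C"}, {"A", "B"}, "ABC")
        part = pt.classify_private_shared(m)
        assert part.union_size == 3
        assert part.fraction_for("pre") == pytest.approx(1 / 3)
        assert part.fraction_for("post") == 0.0
        assert set(part.labels) == {"shared", "private:S01_pre"}

    def test_identical_observation_sets_all_shared(self):
        m = matrix_from_observations({"A", "B"}, {"A", "B"}, "AB")
        part = pt.classify_private_shared(m)
        assert (part.labels == "shared").all()
        assert part.fraction_for("pre") == part.fraction_for("post") == 0.0

    def test_partition_conservation(self, small_matrices):
        for m in small_matrices:
            part = pt.classify_private_shared(m)
            n_private = sum(part.private_observed.values())
            n_shared = int((part.labels == "shared").sum())
            assert n_private + n_shared == part.union_size

    def test_selection_reduces_post_private_fraction(self):
        pre_f, post_f = [], []
        for seed in range(10):
            cfg = pt.SimulationConfig(n_subjects=1, seed=500 + seed,
                                      selection_strength=0.5)
            _, rec = pt.simulate_cohort(cfg)
            part = pt.classify_private_shared(pt.build_union_maf(rec))
            pre_f.append(part.fraction_for("pre"))
            post_f.append(part.fraction_for("post"))
        assert np.mean(post_f) < np.mean(pre_f)

    def test_min_alt_tightens_observation(self):
        m = matrix_from_observations({"A", "B"}, {"A"}, "AB")
        loose = pt.classify_private_shared(m, min_alt=1)
        strict = pt.classify_private_shared(m, min_alt=7)
        assert loose.union_size == 2
        assert strict.union_size == 0  # nothing reaches 7 alt reads


class TestCountDelta:
    def test_arithmetic(self):
        m = matrix_from_observations({"A", "B", "C"}, {"A", "B"}, "ABC")
        table = pt.mutation_count_delta([pt.classify_private_shared(m)])
        row = table.iloc[0]
        assert (row.pre_total, row.post_total, row.delta) == (3, 2, -1)

    def test_identical_sets_zero_delta(self):
        m = matrix_from_observations({"A", "B"}, {"A", "B"}, "AB")
        assert pt.mutation_count_delta([pt.classify_private_shared(m)]).delta.iloc[0] == 0


class TestKsPrePost:
    def test_identical_columns_zero_statistic(self):
        m = matrix_from_observations({"A", "B", "C"}, {"A", "B", "C"}, "ABC")
        for mode in ("all", "shared_only"):
            res = pt.ks_pre_post(m, mode)
            assert res.statistic == 0.0 and res.p_value == 1.0

    def test_too_few_loci_degenerate(self):
        m = matrix_from_observations({"A"}, {"B"}, "AB")
        res = pt.ks_pre_post(m, "shared_only")
        assert res.degenerate

    def test_unknown_mode_rejected(self, small_matrices):
        with pytest.raises(ValueError):
            pt.ks_pre_post(small_matrices[0], "weird")

    def test_pure_purity_change_rejected_in_all_mode(self):
        """A cellularity shift alone moves the all-mutations test; composition unchanged."""
        cfg = pt.SimulationConfig(n_subjects=1, seed=77, selection_strength=0.0,
                                  turnover=(0.0, 0.0), purity_pre=0.8, purity_post=0.5)
        _, rec = pt.simulate_cohort(cfg)
        m = pt.build_union_maf(rec)
        res = pt.ks_pre_post(m, "all")
        assert res.p_value < 0.05
        # the shared-only control removes private-mutation zeros, not a
        # genuine purity rescaling of shared MAFs
        assert pt.ks_pre_post(m, "shared_only").p_value < 0.05


class TestDensitySummary:
    def test_point_mass_peaks_at_value(self):
        m = matrix_from_observations({"A", "B", "C"}, {"A", "B", "C"}, "ABC")
        out = pt.density_summary(m)
        d = out["density"]
        pre = d[(d.sample_id == "S01_pre") & (d.subset == "all")]
        peak = pre.loc[pre.density.idxmax(), "maf"]
        assert peak == pytest.approx(0.3, abs=0.02)

    def test_identical_shared_vectors_give_diagonal_qq(self):
        m = matrix_from_observations({"A", "B", "C"}, {"A", "B", "C"}, "ABC")
        qq = pt.density_summary(m)["qq"]
        shared = qq[qq.subset == "shared"]
        assert np.allclose(shared.pre_quantile, shared.post_quantile)

    def test_selection_separates_all_densities_more_than_shared(self):
        cfg = pt.SimulationConfig(n_subjects=1, seed=31, selection_strength=0.75,
                                  equal_purity=True)
        _, rec = pt.simulate_cohort(cfg)
        m = pt.build_union_maf(rec)
        out = pt.density_summary(m)
        d = out["density"]

        def l1(subset):
            pre = d[(d.sample_id == "S01_pre") & (d.subset == subset)].density.to_numpy()
            post = d[(d.sample_id == "S01_post") & (d.subset == subset)].density.to_numpy()
            return np.abs(pre - post).sum()

        assert l1("all") > l1("shared")


class TestClustering:
    def test_identical_columns_merge_first(self):
        m1 = matrix_from_observations({"A", "B", "C"}, {"A", "B", "C"}, "ABC")
        rows = [("S02_pre", "pre", "chr2", 900, "G", "C", 5, 15, 60.0),
                ("S02_post", "post", "chr2", 900, "G", "C", 5, 15, 60.0)]
        rec2 = make_records(rows)
        rec2["subject_id"] = "S02"
        m2 = pt.build_union_maf(rec2)
        res = pt.cluster_samples([m1, m2])
        assert res.pairing_score == 1.0
        assert res.linkage[0, 2] == 0.0  # a pair of identical columns at distance 0

    def test_duplicate_sample_labels_rejected(self, small_matrices):
        with pytest.raises(ValueError):
            pt.cluster_samples([small_matrices[0], small_matrices[0]])

    def test_locus_order_invariance(self, small_cohort):
        _, _, records = small_cohort
        mats, mats_shuffled = [], []
        for _, grp in records.groupby("subject_id"):
            mats.append(pt.build_union_maf(grp))
            mats_shuffled.append(pt.build_union_maf(grp.sample(frac=1.0, random_state=1)))
        a = pt.cluster_samples(mats)
        b = pt.cluster_samples(mats_shuffled)
        assert a.newick == b.newick
        assert np.allclose(a.linkage, b.linkage)

    def test_simulated_cohort_pairs_completely(self, small_matrices):
        res = pt.cluster_samples(small_matrices)
        assert res.pairing_score == 1.0
        assert res.newick.endswith(";") and "S01_pre" in res.newick
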