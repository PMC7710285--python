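import numpy as np
import pandas as pd
import pytest

import pairedtumor as pt
from pairedtumor.signatures import ExpressionMatrix, GeneSetCollection

from oracles import ssgsea_score


def matrix(values, genes=None, samples=None, timepoints=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    n = len(samples)
    ann = pd.DataFrame({
        "subject_id": [f"P{i // 2}" for i in range(n)],
        "timepoint": timepoints or ["pre" if i % 2 == 0 else "post" for i in range(n)],
    }, index=pd.Index(samples, name="sample_id"))
    return ExpressionMatrix(counts=pd.DataFrame(values, index=genes, columns=samples),
                            annotations=ann)


class TestUpperQuartile:
    def test_fixed_point(self):
        m = matrix([[0], [500], [1000], [2000]])
        out = pt.upper_quartile_normalize(m, target=1000.0)
        # nonzero quartile of [500, 1000, 2000] is 1500 -> scaled by 2/3
        nonzero = out.counts.values[out.counts.values > 0]
        assert np.percentile(nonzero, 75) == pytest.approx(1000.0)

    def test_scale_invariance(self):
        m1 = matrix([[1], [10], [20], [40]])
        m2 = matrix([[2], [20], [40], [80]])
        a = pt.upper_quartile_normalize(m1).counts
        b = pt.upper_quartile_normalize(m2).counts
        assert np.allclose(a, b)

    def test_interpolated_percentile_rule(self):
        m = matrix([[0], [10], [20], [40]])
        out = pt.upper_quartile_normalize(m, target=1000.0)
        # nonzero quartile of [10, 20, 40] with linear interpolation = 30
        assert np.allclose(out.counts[out.counts > 0].dropna().to_numpy().ravel(),
                           np.array([10, 20, 40]) * 1000.0 / 30)

    def test_equalizes_quartiles_across_samples(self, rng):
        m = matrix(rng.integers(0, 500, size=(100, 6)))
        out = pt.upper_quartile_normalize(m)
        q = [np.percentile(col[col > 0], 75) for col in out.counts.to_numpy().T]
        assert np.allclose(q, q[0])

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            pt.upper_quartile_normalize(matrix([[0, 1], [0, 2]]))


class TestSignatureScore:
    def test_single_gene_set(self):
        m = matrix([[7], [100]])
        scores = pt.signature_score(m, GeneSetCollection(sets={"one": {"g0"}}))
        assert scores.scores.loc["one"].iloc[0] == pytest.approx(np.log2(8))

    def test_constant_matrix(self):
        m = matrix(np.full((4, 2), 15.0))
        sets = GeneSetCollection(sets={"a": {"g0", "g1"}, "b": {"g2"}})
        scores = pt.signature_score(m, sets).scores
        assert np.allclose(scores, np.log2(16))

    def test_hand_evaluated_mean(self):
        m = matrix([[1], [3], [7]])
        scores = pt.signature_score(m, GeneSetCollection(sets={"s": {"g0", "g1", "g2"}}))
        assert scores.scores.loc["s"].iloc[0] == pytest.approx(2.0)

    def test_gene_order_permutation_invariance(self, rng):
        vals = rng.random((20, 3)) * 100
        m = matrix(vals)
        sets = GeneSetCollection(sets={"s": {f"g{i}" for i in range(0, 20, 3)}})
        a = pt.signature_score(m, sets).scores
        perm = rng.permutation(20)
        m2 = ExpressionMatrix(counts=m.counts.iloc[perm], annotations=m.annotations)
        b = pt.signature_score(m2, sets).scores
        assert np.allclose(a, b)

    def test_empty_intersection_names_the_set(self):
        m = matrix([[1], [2]])
        with pytest.raises(ValueError, match="nothere"):
            pt.signature_score(m, GeneSetCollection(sets={"nothere": {"zz"}}))


class TestSsgsea:
    def test_rank_invariance_under_monotone_transform(self, rng):
        vals = rng.random((30, 1)) * 50
        sets = GeneSetCollection(sets={"s": {f"g{i}" for i in range(5)}})
        a = pt.ssgsea(matrix(vals), sets, normalize=False).scores
        b = pt.ssgsea(matrix(np.exp(vals / 10)), sets, normalize=False).scores
        assert np.allclose(a, b)

    def test_top_ranked_set_beats_bottom_ranked(self):
        vals = np.array([[50], [40], [30], [20], [10]])
        sets = GeneSetCollection(sets={"top": {"g0", "g1"}, "bottom": {"g3", "g4"}})
        scores = pt.ssgsea(matrix(vals), sets, normalize=False).scores
        assert scores.loc["top"].iloc[0] > scores.loc["bottom"].iloc[0]

    def test_matches_brute_force_running_sum(self, rng):
        for _ in range(10):
            vals = rng.random((20, 4)) * 100
            m = matrix(vals)
            genes = list(m.counts.index)
            sets = {}
            for k in range(3):
                picked = rng.choice(genes, size=rng.integers(2, 8), replace=False)
                sets[f"set{k}"] = set(picked)
            got = pt.ssgsea(m, GeneSetCollection(sets=sets), normalize=False).scores
            for name, genes_in in sets.items():
                mask = [g in genes_in for g in genes]
                for j in range(4):
                    expected = ssgsea_score(vals[:, j], mask)
                    assert got.loc[name].iloc[j] == pytest.approx(expected, abs=1e-10)

    def test_degenerate_sets_rejected(self):
        m = matrix(np.arange(8, dtype=float).reshape(4, 2))
        with pytest.raises(ValueError):
            pt.ssgsea(m, GeneSetCollection(sets={"all": {"g0", "g1", "g2", "g3"}}))
        with pytest.raises(ValueError):
            pt.ssgsea(m, GeneSetCollection(sets={"tiny": {"g0"}}))


class TestPairedSignatureTest:
    def test_identical_pre_post_nothing_significant(self):
        vals = np.tile(np.linspace(10, 100, 6)[:, None], (1, 6))
        m = matrix(vals)
        sets = GeneSetCollection(sets={"a": {"g0", "g1"}, "b": {"g2", "g3"}})
        scores = pt.signature_score(m, sets)
        table = pt.paired_signature_test(scores, m.annotations)
        assert (table.q == 1.0).all()
        assert table.degenerate.all()

    def test_q_monotone_in_p(self, rng):
        m, _ = pt.simulate_expression(60, 6, set(), 0.0, seed=12)
        sets = GeneSetCollection(sets={
            f"s{k}": {f"G{i + 1:05d}" for i in range(10 * k, 10 * k + 10)}
            for k in range(6)})
        table = pt.paired_signature_test(pt.signature_score(m, sets), m.annotations)
        srt = table.sort_values("p")
        assert (srt.q.diff().dropna() >= -1e-12).all()

    def test_strong_effect_detected_first(self):
        sig = {f"G{i + 1:05d}" for i in range(20)}
        m, _ = pt.simulate_expression(200, 20, sig, effect_size=2.0, seed=5)
        sets = {"perturbed": sig}
        for k in range(4):
            sets[f"null{k}"] = {f"G{i + 1:05d}" for i in range(30 + 20 * k, 50 + 20 * k)}
        table = pt.paired_signature_test(
            pt.signature_score(pt.upper_quartile_normalize(m), GeneSetCollection(sets=sets)),
            m.annotations)
        assert table.sort_values("p").signature.iloc[0] == "perturbed"

    def test_unpaired_subject_warned_and_excluded(self):
        m, _ = pt.simulate_expression(30, 3, set(), 0.0, seed=2)
        ann = m.annotations.copy()
        ann.loc[ann.index[-1], "timepoint"] = "pre"  # break the last pair
        sets = GeneSetCollection(sets={"s": {f"G{i + 1:05d}" for i in range(5)}})
        with pytest.warns(UserWarning):
            table = pt.paired_signature_test(pt.signature_score(m, sets), ann)
        assert len(table) == 1
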