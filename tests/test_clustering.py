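import numpy as np
import pytest

from her2sig import (
    NON_PCR,
    PCR,
    ExpressionMatrix,
    hierarchical_two_cut,
    maybe_log_transform,
    median_center,
    score_against_labels,
)
from her2sig.errors import Her2SigError


def _matrix(values, scale_hint="unknown", genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(genes=genes, samples=samples, values=values,
                            scale_hint=scale_hint)


def _two_blob_matrix(seed=0, n_per_group=6, n_genes=8, separation=8.0, sd=1.0):
    """Two well-separated sample groups; returns (matrix, true labels)."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, sd, size=(n_genes, n_per_group))
    b = rng.normal(0.0, sd, size=(n_genes, n_per_group)) + separation
    values = np.hstack([a, b])
    samples = [f"s{i:02d}" for i in range(2 * n_per_group)]
    labels = {s: (PCR if i < n_per_group else NON_PCR)
              for i, s in enumerate(samples)}
    return _matrix(values, scale_hint="log2", samples=samples), labels


class TestMaybeLogTransform:
    def test_narrow_unknown_range_left_alone(self):
        m = _matrix([[6.0, 14.0], [8.0, 12.0]])
        out = maybe_log_transform(m)
        np.testing.assert_array_equal(out.values, m.values)
        assert out.scale_hint == "log2"

    def test_wide_unknown_range_transformed(self):
        m = _matrix([[10.0, 50000.0], [200.0, 3000.0]])
        out = maybe_log_transform(m)
        np.testing.assert_allclose(out.values, np.log2(m.values))
        assert out.scale_hint == "log2"

    def test_declared_log2_is_identity_regardless_of_range(self):
        m = _matrix([[1.0, 1e6], [2.0, 4.0]], scale_hint="log2")
        out = maybe_log_transform(m)
        np.testing.assert_array_equal(out.values, m.values)

    def test_declared_linear_always_transformed(self):
        m = _matrix([[2.0, 4.0], [8.0, 16.0]], scale_hint="linear")
        np.testing.assert_allclose(maybe_log_transform(m).values,
                                   [[1.0, 2.0], [3.0, 4.0]])

    def test_nonpositive_values_block_the_transform(self):
        m = _matrix([[-1.0, 4.0], [8.0, 16.0]], scale_hint="linear")
        with pytest.raises(Her2SigError, match="non-positive"):
            maybe_log_transform(m)


class TestMedianCenter:
    def test_constant_matrix_becomes_zero(self):
        m = _matrix(np.full((3, 4), 7.0))
        np.testing.assert_array_equal(median_center(m).values, np.zeros((3, 4)))

    def test_single_row_forced_to_zero(self):
        m = _matrix([[1.0, 2.0, 3.0]])
        np.testing.assert_array_equal(median_center(m).values, [[0.0, 0.0, 0.0]])

    def test_column_medians_exactly_zero_after_pass(self):
        rng = np.random.default_rng(8)
        m = _matrix(rng.normal(size=(5, 4)))
        out = median_center(m)
        np.testing.assert_array_equal(np.median(out.values, axis=0), np.zeros(4))

    def test_idempotent_on_column_median_property(self):
        rng = np.random.default_rng(9)
        m = _matrix(rng.normal(size=(6, 5)))
        once = median_center(m)
        twice = median_center(once)
        np.testing.assert_array_equal(np.median(twice.values, axis=0), np.zeros(5))

    def test_residual_row_medians_reported(self):
        rng = np.random.default_rng(10)
        m = _matrix(rng.normal(size=(5, 4)))
        out, residuals = median_center(m, return_diagnostics=True)
        np.testing.assert_array_equal(residuals, np.median(out.values, axis=1))


class TestHierarchicalTwoCut:
    def test_two_samples_each_their_own_group(self):
        m = _matrix([[0.0, 5.0], [0.0, 5.0], [1.0, 4.0]], scale_hint="log2")
        cr = hierarchical_two_cut(m)
        assert set(cr.assignment.values()) == {"A", "B"}

    def test_single_sample_rejected(self):
        m = _matrix([[1.0], [2.0]], scale_hint="log2")
        with pytest.raises(Her2SigError, match="2 samples"):
            hierarchical_two_cut(m)

    def test_well_separated_blobs_recovered(self):
        m, labels = _two_blob_matrix(seed=4)
        cr = hierarchical_two_cut(m)
        groups = {g: {s for s, gg in cr.assignment.items() if gg == g}
                  for g in "AB"}
        blob_a = {s for s, l in labels.items() if l == PCR}
        blob_b = {s for s, l in labels.items() if l == NON_PCR}
        assert {frozenset(groups["A"]), frozenset(groups["B"])} == {
            frozenset(blob_a), frozenset(blob_b)
        }

    def test_duplicated_samples_co_clustered(self):
        rng = np.random.default_rng(12)
        base = rng.normal(size=(6, 5))
        values = np.hstack([base, base[:, :1]])  # duplicate first sample
        m = _matrix(values, scale_hint="log2",
                    samples=["s0", "s1", "s2", "s3", "s4", "s0dup"])
        cr = hierarchical_two_cut(m)
        assert cr.assignment["s0"] == cr.assignment["s0dup"]

    def test_sample_order_invariance(self):
        m, _ = _two_blob_matrix(seed=6)
        rng = np.random.default_rng(13)
        perm = rng.permutation(len(m.samples))
        shuffled = ExpressionMatrix(
            genes=list(m.genes),
            samples=[m.samples[i] for i in perm],
            values=m.values[:, perm],
            scale_hint=m.scale_hint,
        )
        assert hierarchical_two_cut(m).assignment == \
            hierarchical_two_cut(shuffled).assignment

    def test_gene_order_invariance(self):
        m, _ = _two_blob_matrix(seed=7)
        rng = np.random.default_rng(14)
        perm = rng.permutation(len(m.genes))
        reordered = ExpressionMatrix(
            genes=[m.genes[i] for i in perm],
            samples=list(m.samples),
            values=m.values[perm, :],
            scale_hint=m.scale_hint,
        )
        assert hierarchical_two_cut(m).assignment == \
            hierarchical_two_cut(reordered).assignment

    def test_newick_export_parses_and_covers_all_samples(self):
        import io as _io

        from Bio import Phylo

        m, _ = _two_blob_matrix(seed=5, n_per_group=4)
        cr = hierarchical_two_cut(m)
        tree = Phylo.read(_io.StringIO(cr.to_newick()), "newick")
        leaves = {t.name for t in tree.get_terminals()}
        assert leaves == set(m.samples)


class TestScoreAgainstLabels:
    def test_perfect_blobs_score_one(self):
        m, labels = _two_blob_matrix(seed=4)
        cr = score_against_labels(hierarchical_two_cut(m), labels)
        assert cr.agreement.accuracy_fraction == 1.0
        assert set(cr.label_mapping.values()) == {PCR, NON_PCR}

    def test_mapping_maximises_accuracy_over_both_options(self):
        m, labels = _two_blob_matrix(seed=4)
        inverted = {s: (NON_PCR if l == PCR else PCR) for s, l in labels.items()}
        cr = score_against_labels(hierarchical_two_cut(m), inverted)
        # the other mapping is chosen, accuracy stays 1.0
        assert cr.agreement.accuracy_fraction == 1.0

    def test_permuted_labels_score_near_chance(self):
        """Random label permutations give accuracy about max(p, 1-p)."""
        m, labels = _two_blob_matrix(seed=4, n_per_group=10)
        cr = hierarchical_two_cut(m)
        rng = np.random.default_rng(15)
        names = list(labels)
        values = [labels[s] for s in names]
        accs = []
        for _ in range(200):
            perm = rng.permutation(len(values))
            shuffled = {names[i]: values[perm[i]] for i in range(len(names))}
            accs.append(
                score_against_labels(cr, shuffled).agreement.accuracy_fraction
            )
        # p = 0.5 here: chance level for the better of two mappings is ~0.5+
        assert 0.5 <= np.mean(accs) <= 0.65

    def test_single_class_labels_score_larger_group_fraction(self):
        m, _ = _two_blob_matrix(seed=16, n_per_group=5)
        cr = hierarchical_two_cut(m)
        labels = {s: PCR for s in m.samples}
        scored = score_against_labels(cr, labels)
        sizes = sorted(len(v) for v in scored.groups.values())
        assert scored.agreement.accuracy_fraction == sizes[-1] / len(m.samples)

    def test_missing_label_names_sample(self):
        m, labels = _two_blob_matrix(seed=4)
        labels.pop("s00")
        with pytest.raises(Her2SigError, match="s00"):
            score_against_labels(hierarchical_two_cut(m), labels)
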