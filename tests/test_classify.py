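import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from her2sig import (
    NON_PCR,
    PCR,
    GeneratorConfig,
    ReferenceSet,
    classify_cohort,
    classify_sample,
    make_cohort,
    make_references,
    pearson,
    profile_with_correlations,
)
from her2sig.classify import AMBIGUOUS, TIE_REPORT
from her2sig.errors import ClassificationError
from her2sig.qpcr import ExpressionProfile, to_linear


def brute_force_pearson(x, y):
    """Independent oracle: the covariance formula written out directly."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    vx = sum((a - mx) ** 2 for a in x) / n
    vy = sum((b - my) ** 2 for b in y) / n
    return cov / (vx**0.5 * vy**0.5)


class TestPearson:
    def test_perfect_and_anti_correlation(self):
        x = [1.0, 2.0, 4.0, 8.0]
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_matches_direct_formula_oracle(self):
        x = [1, 2, 3, 4, 5, 6, 7, 8]
        y = [2, 1, 4, 3, 6, 5, 8, 7]
        assert pearson(x, y) == pytest.approx(brute_force_pearson(x, y), abs=1e-14)

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            assert pearson(x, y) == pytest.approx(
                stats.pearsonr(x, y).statistic, abs=1e-12
            )

    def test_preconditions(self):
        with pytest.raises(ClassificationError, match="3 points"):
            pearson([1, 2], [3, 4])
        with pytest.raises(ClassificationError, match="constant"):
            pearson([1, 1, 1], [1, 2, 3])
        with pytest.raises(ClassificationError, match="equal-length"):
            pearson([1, 2, 3], [1, 2])

    @given(
        a=st.floats(min_value=0.1, max_value=10),
        b=st.floats(min_value=-5, max_value=5),
    )
    def test_affine_invariance(self, a, b):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        assert pearson(a * x + b, y) == pytest.approx(pearson(x, y), abs=1e-9)


class TestDecisionRule:
    """Argmax-nearest-to-1 over references, mapped through sensitivity tags."""

    def _two_ref_set(self, sensitive_name, resistant_name, seed=5):
        cfg = GeneratorConfig(seed=seed, panel_size=8, n_informative=4)
        refs = make_references(cfg)
        keep = {sensitive_name, resistant_name}
        return ReferenceSet([r for r in refs.references if r[0] in keep])

    def test_sensitive_tumor_called_pcr(self):
        """Correlations 0.93 (sensitive) / −0.36 (resistant) -> pCR."""
        refs = self._two_ref_set("HCC2218", "HCC1419")
        p = profile_with_correlations(
            refs, {"HCC2218": 0.93, "HCC1419": -0.36}, sample_id="patientA"
        )
        res = classify_sample(p, refs)
        assert res.correlations["HCC2218"] == pytest.approx(0.93, abs=1e-9)
        assert res.correlations["HCC1419"] == pytest.approx(-0.36, abs=1e-9)
        assert res.best_reference == "HCC2218"
        assert res.predicted_label == PCR

    def test_resistant_tumor_called_non_pcr(self):
        """Correlations −0.25 (sensitive) / 0.85 (resistant) -> non-pCR."""
        refs = self._two_ref_set("BT474", "HCC1954")
        p = profile_with_correlations(
            refs, {"BT474": -0.25, "HCC1954": 0.85}, sample_id="patientB"
        )
        res = classify_sample(p, refs)
        assert res.best_reference == "HCC1954"
        assert res.best_correlation == pytest.approx(0.85, abs=1e-9)
        assert res.predicted_label == NON_PCR

    def test_tumor_identical_to_reference_is_self_assigned(self, refs):
        name, _, ref_profile = refs.references[2]  # UACC-812, sensitive
        tumor = ExpressionProfile(
            sample_id="copy", panel=refs.panel,
            values=dict(ref_profile.values), space=ref_profile.space,
        )
        res = classify_sample(tumor, refs)
        assert res.best_reference == name
        assert res.best_correlation == pytest.approx(1.0)
        assert res.predicted_label == PCR

    def test_scale_invariance_in_correlation_space(self, refs, cohort):
        """x -> a*x + b on the log2 profile leaves the call unchanged."""
        profiles, _ = cohort
        p = profiles[0]
        shifted = ExpressionProfile(
            sample_id=p.sample_id, panel=p.panel,
            values={g: 1.7 * v + 3.2 for g, v in p.values.items()}, space="log2",
        )
        r1 = classify_sample(p, refs)
        r2 = classify_sample(shifted, refs)
        assert r1.predicted_label == r2.predicted_label
        assert r1.best_reference == r2.best_reference
        for name in refs.names:
            assert r2.correlations[name] == pytest.approx(r1.correlations[name])

    def test_linear_profile_converted_consistently(self, refs, cohort):
        """A linear-space tumor profile classifies like its log2 original."""
        profiles, _ = cohort
        p = profiles[3]
        linear = to_linear(p)
        r_log = classify_sample(p, refs, space="log2")
        r_lin = classify_sample(linear, refs, space="log2")
        assert r_lin.correlations == pytest.approx(r_log.correlations)

    def test_cross_class_tie_policies(self, refs):
        """A sensitive and a resistant reference with identical profiles tie
        exactly; conservative calls non-pCR, report mode flags ambiguity."""
        panel = refs.panel
        vals = {g: float(i % 5) for i, g in enumerate(panel.genes)}
        twin = lambda name, lab: (
            name, lab,
            ExpressionProfile(sample_id=name, panel=panel, values=dict(vals),
                              space="log2"),
        )
        two = ReferenceSet([twin("S1", "sensitive"), twin("R1", "resistant")])
        tumor = ExpressionProfile(
            sample_id="t", panel=panel,
            values={g: float(i) for i, g in enumerate(panel.genes)}, space="log2",
        )
        assert classify_sample(tumor, two).predicted_label == NON_PCR
        assert (
            classify_sample(tumor, two, tie_policy=TIE_REPORT).predicted_label
            == AMBIGUOUS
        )

    def test_panel_mismatch_lists_missing_genes(self, refs):
        small = refs.panel.subset(refs.panel.genes[:5])
        tumor = ExpressionProfile(
            sample_id="t", panel=small,
            values={g: float(i) for i, g in enumerate(small.genes)}, space="log2",
        )
        with pytest.raises(ClassificationError, match=refs.panel.genes[5]):
            classify_sample(tumor, refs)


class TestCohort:
    def test_empty_cohort(self, refs):
        out = classify_cohort([], refs)
        assert out.results == [] and out.failures == []

    def test_duplicate_profiles_get_identical_results(self, refs, cohort):
        profiles, _ = cohort
        out = classify_cohort([profiles[0], profiles[0]], refs)
        r1, r2 = out.results
        assert r1.correlations == r2.correlations
        assert r1.predicted_label == r2.predicted_label

    def test_per_sample_errors_collected_not_fatal(self, refs, cohort):
        profiles, _ = cohort
        constant = ExpressionProfile(
            sample_id="flat", panel=refs.panel,
            values={g: 0.0 for g in refs.panel.genes}, space="log2",
        )
        out = classify_cohort([profiles[0], constant, profiles[1]], refs)
        assert len(out.results) == 2
        assert out.failures[0][0] == "flat"

    def test_synthetic_ground_truth_mostly_recovered(self):
        """Tumors drawn from archetypes are labelled like their archetype."""
        cfg = GeneratorConfig(seed=11, n_tumors=20, pcr_fraction=0.5)
        refs = make_references(cfg)
        profiles, labels = make_cohort(cfg)
        out = classify_cohort(profiles, refs)
        assert not out.failures
        correct = sum(
            r.predicted_label == labels[r.sample_id] for r in out.results
        )
        assert correct / len(out.results) >= 0.9

    def test_accuracy_improves_as_noise_vanishes(self):
        """Monotone trend of cohort accuracy over a decreasing noise grid."""
        accs = []
        for sd in (4.0, 2.0, 1.0, 0.25):
            cfg = GeneratorConfig(seed=21, n_tumors=40, noise_sd=sd)
            refs = make_references(cfg)
            profiles, labels = make_cohort(cfg)
            out = classify_cohort(profiles, refs)
            accs.append(
                np.mean([r.predicted_label == labels[r.sample_id] for r in out.results])
            )
        assert all(b >= a for a, b in zip(accs, accs[1:]))
        assert accs[-1] == 1.0


def test_spearman_measure_invariant_to_monotone_distortion(refs, cohort):
    """Rank correlation gives the same call after a monotone transform that
    changes Pearson; unknown measures are rejected."""
    import numpy as np

    from her2sig.qpcr import ExpressionProfile

    profiles, _ = cohort
    p = profiles[0]
    warped = ExpressionProfile(
        sample_id=p.sample_id, panel=p.panel,
        values={g: float(np.sign(v) * abs(v) ** 3) for g, v in p.values.items()},
        space="log2",
    )
    r1 = classify_sample(p, refs, measure="spearman")
    r2 = classify_sample(warped, refs, measure="spearman")
    assert r1.correlations == pytest.approx(r2.correlations)
    with pytest.raises(ClassificationError, match="measure"):
        classify_sample(p, refs, measure="kendall")
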