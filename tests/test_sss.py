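import numpy as np
import pandas as pd
import pytest

from sssx.features import assemble_feature_table
from sssx.graph import PairGraph
from sssx.sss import (
    Discretizer,
    Posteriors,
    SSSModel,
    iso_feature,
    label_edges,
    learn_ml_params,
    load_complexes,
    mdl_discretize,
    naive_bayes_posteriors,
    posteriors_to_dict,
    sss_weight,
)
from sssx.synthetic import SynthConfig, generate

from conftest import make_posteriors


class TestLabels:
    def net(self):
        return PairGraph.from_edges(
            [("a", "b", 1.0), ("c", "d", 1.0), ("e", "f", 1.0)]
        )

    def test_small_complex_pair_is_sm(self):
        labels = label_edges(self.net(), [frozenset("ab")])
        assert labels[("a", "b")] == "sm-comp"
        assert labels[("c", "d")] == "non-comp"

    def test_large_complex_takes_precedence_over_small(self):
        complexes = [frozenset("cdxyz"), frozenset({"c", "d", "w"})]
        labels = label_edges(self.net(), complexes)
        assert labels[("c", "d")] == "lg-comp"

    def test_catalogue_rejects_singleton_complex(self):
        with pytest.raises(ValueError):
            load_complexes(["a\ta\n"])


class TestMDL:
    def test_perfect_separation_yields_single_midpoint_cut(self):
        values = [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]
        labels = ["sm-comp"] * 3 + ["non-comp"] * 3
        assert mdl_discretize(values, labels) == [pytest.approx(0.5)]

    def test_shuffled_labels_remove_feature(self):
        rng = np.random.default_rng(42)
        values = rng.uniform(size=200)
        labels = list(rng.choice(["sm-comp", "lg-comp", "non-comp"], size=200))
        assert mdl_discretize(values, labels) is None

    def test_constant_feature_removed(self):
        assert mdl_discretize([1.0] * 50, ["sm-comp", "non-comp"] * 25) is None

    def test_three_class_stepwise_feature_gets_two_cuts(self):
        values = [0.0] * 20 + [0.5] * 20 + [1.0] * 20
        labels = ["sm-comp"] * 20 + ["lg-comp"] * 20 + ["non-comp"] * 20
        cuts = mdl_discretize(values, labels)
        assert cuts == [pytest.approx(0.25), pytest.approx(0.75)]

    def test_two_value_feature_reproduces_information_gain_decision(self):
        # closed form: entropy 1 bit before, 0 after -> gain 1; MDL accepts
        values = [0.0] * 30 + [1.0] * 30
        labels = ["sm-comp"] * 30 + ["non-comp"] * 30
        assert mdl_discretize(values, labels) == [pytest.approx(0.5)]
        # identical class mixture on both values -> zero gain -> removed
        labels_mixed = (["sm-comp", "non-comp"] * 15) * 2
        assert mdl_discretize(values, labels_mixed) is None


def manual_model(cpts, priors, smoothing=0.0):
    disc = Discretizer()
    for f, table in cpts.items():
        disc.cuts_[f] = [0.5] * (np.asarray(table).shape[1] - 1)
    return SSSModel(
        discretizer=disc,
        priors=np.asarray(priors, dtype=float),
        cpt={f: np.asarray(t, dtype=float) for f, t in cpts.items()},
        smoothing=smoothing,
    )


class TestNaiveBayes:
    def test_learned_tables_are_class_conditional_frequencies(self):
        codes = pd.DataFrame({"F": [0, 0, 1, 1, 0, 1]})
        labels = ["sm-comp", "sm-comp", "sm-comp", "sm-comp", "lg-comp", "non-comp"]
        disc = Discretizer()
        disc.cuts_["F"] = [0.5]
        model = learn_ml_params(codes, labels, disc, smoothing=0.0)
        assert model.cpt["F"][0] == pytest.approx([0.5, 0.5])
        assert model.priors == pytest.approx([4 / 6, 1 / 6, 1 / 6])

    def test_missing_class_raises(self):
        codes = pd.DataFrame({"F": [0, 1]})
        disc = Discretizer()
        disc.cuts_["F"] = [0.5]
        with pytest.raises(ValueError, match="no edges"):
            learn_ml_params(codes, ["sm-comp", "lg-comp"], disc)

    def test_identical_tables_return_priors(self):
        model = manual_model({"F": [[0.3, 0.7]] * 3}, priors=[0.2, 0.3, 0.5])
        post = naive_bayes_posteriors(model, pd.DataFrame({"F": [0, 1]}))
        for _, row in post.iterrows():
            assert row.to_numpy() == pytest.approx([0.2, 0.3, 0.5])

    def test_deterministic_feature_gives_certainty(self):
        model = manual_model(
            {"F": [[1.0, 0.0], [0.0, 1.0], [0.0, 1.0]]}, priors=[1 / 3, 1 / 3, 1 / 3]
        )
        post = naive_bayes_posteriors(model, pd.DataFrame({"F": [0]}))
        assert post.iloc[0].to_numpy() == pytest.approx([1.0, 0.0, 0.0])

    def test_all_zero_likelihood_raises(self):
        model = manual_model({"F": [[0.0, 1.0]] * 3}, priors=[1 / 3, 1 / 3, 1 / 3])
        with pytest.raises(ValueError, match="smoothing"):
            naive_bayes_posteriors(model, pd.DataFrame({"F": [0]}))

    def test_matches_exhaustive_joint_enumeration(self):
        """Posteriors equal conditioning of the fully enumerated joint table."""
        rng = np.random.default_rng(3)
        n_bins = {"F1": 3, "F2": 2, "F3": 4}
        cpts = {}
        for f, nb in n_bins.items():
            t = rng.uniform(0.05, 1.0, size=(3, nb))
            cpts[f] = t / t.sum(axis=1, keepdims=True)
        priors = np.array([0.2, 0.3, 0.5])
        model = manual_model(cpts, priors)

        codes = pd.DataFrame(
            {
                "F1": rng.integers(0, 3, size=30),
                "F2": rng.integers(0, 2, size=30),
                "F3": rng.integers(0, 4, size=30),
            }
        )
        post = naive_bayes_posteriors(model, codes)

        # oracle: materialize P(class, f1, f2, f3) over all 3*3*2*4 cells
        joint = np.zeros((3, 3, 2, 4))
        for c in range(3):
            for f1 in range(3):
                for f2 in range(2):
                    for f3 in range(4):
                        joint[c, f1, f2, f3] = (
                            priors[c]
                            * cpts["F1"][c, f1]
                            * cpts["F2"][c, f2]
                            * cpts["F3"][c, f3]
                        )
        for i, row in codes.iterrows():
            cell = joint[:, row.F1, row.F2, row.F3]
            expected = cell / cell.sum()
            assert post.iloc[i].to_numpy() == pytest.approx(expected, abs=1e-12)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(0.01, 1, size=(3, 4))
        model = manual_model({"F": t / t.sum(axis=1, keepdims=True)}, [0.1, 0.4, 0.5])
        post = naive_bayes_posteriors(model, pd.DataFrame({"F": rng.integers(0, 4, 50)}))
        assert post.sum(axis=1).to_numpy() == pytest.approx(np.ones(50), abs=1e-9)


class TestModelSerialization:
    def test_yaml_round_trip_is_exact(self):
        rng = np.random.default_rng(1)
        t = rng.uniform(0.01, 1, size=(3, 3))
        model = manual_model({"F1": t / t.sum(axis=1, keepdims=True)}, [0.25, 0.25, 0.5],
                             smoothing=1.0)
        model.discretizer.cuts_["F1"] = [0.123456789, 0.987654321]
        model.discretizer.removed_ = ["F2"]
        restored = SSSModel.from_yaml(model.to_yaml())
        assert restored.discretizer.cuts_ == model.discretizer.cuts_
        assert restored.discretizer.removed_ == ["F2"]
        np.testing.assert_array_equal(restored.priors, model.priors)
        np.testing.assert_array_equal(restored.cpt["F1"], model.cpt["F1"])
        assert restored.smoothing == 1.0


class TestISO:
    def test_isolated_edge_iso_is_p_sm(self):
        net = PairGraph.from_edges([("a", "b", 1.0)])
        post = make_posteriors({("a", "b"): (0.8, 0.1)})
        assert iso_feature(post, net)[("a", "b")] == pytest.approx(0.8)

    def test_single_adjacent_edge_multiplies_its_p_non(self):
        net = PairGraph.from_edges([("a", "b", 1.0), ("b", "c", 1.0)])
        post = make_posteriors({("a", "b"): (0.8, 0.1), ("b", "c"): (0.3, 0.2)})
        # no common neighbour: ISO3 = 0; ISO2 = 0.8 * P_non(b,c) = 0.8 * 0.5
        assert iso_feature(post, net)[("a", "b")] == pytest.approx(0.4)

    def test_isolated_triangle_combines_iso2_and_iso3(self):
        net = PairGraph.from_edges(
            [("a", "b", 1.0), ("a", "c", 1.0), ("b", "c", 1.0)]
        )
        post = make_posteriors({p: (0.9, 0.05) for p in [("a", "b"), ("a", "c"), ("b", "c")]})
        # ISO2 multiplies P_non of the two in-triangle edges adjacent to (a,b);
        # ISO3 over common neighbour c has no edge leaving the triangle
        expected = 0.9 * 0.05 * 0.05 + 0.9**3
        assert iso_feature(post, net)[("a", "b")] == pytest.approx(expected)

    def test_raising_surrounding_p_non_never_decreases_iso(self):
        net = PairGraph.from_edges(
            [("a", "b", 1.0), ("a", "c", 1.0), ("b", "c", 1.0), ("c", "d", 1.0)]
        )
        base = {("a", "b"): (0.9, 0.05), ("a", "c"): (0.7, 0.1),
                ("b", "c"): (0.7, 0.1), ("c", "d"): (0.4, 0.3)}
        lo = iso_feature(make_posteriors(base), net)
        raised = dict(base)
        raised[("c", "d")] = (0.2, 0.1)  # P_non rises 0.3 -> 0.7
        hi = iso_feature(make_posteriors(raised), net)
        for pair in lo:
            if pair != ("c", "d"):
                assert hi[pair] >= lo[pair]


@pytest.fixture(scope="module")
def dataset():
    data = generate(SynthConfig(seed=11))
    features = assemble_feature_table(data.reliable, data.graphs)
    labels = label_edges(data.reliable, list(data.catalogue))
    return data, features, labels


class TestSSSWeight:

    def test_posteriors_sum_to_one_on_every_edge(self, dataset):
        data, features, labels = dataset
        posteriors, _ = sss_weight(data.reliable, features, labels)
        for p in posteriors.values():
            assert p.sm + p.lg + p.non == pytest.approx(1.0, abs=1e-9)

    def test_no_iso_mode_equals_step_three_posteriors(self, dataset):
        data, features, labels = dataset
        no_iso, model = sss_weight(data.reliable, features, labels, include_iso=False)

        y = [labels[p] for p in features.index]
        disc = Discretizer().fit(features, y)
        codes = disc.transform(features)
        step3 = naive_bayes_posteriors(
            learn_ml_params(codes, y, disc, smoothing=1.0), codes
        )
        expected = posteriors_to_dict(step3)
        assert no_iso == expected
        assert "ISO" not in model.discretizer.features

    def test_iso_included_in_final_model(self, dataset):
        data, features, labels = dataset
        _, model = sss_weight(data.reliable, features, labels, include_iso=True)
        assert "ISO" in model.discretizer.features

    def test_separates_small_from_non_complex_edges(self, dataset):
        data, features, labels = dataset
        posteriors, _ = sss_weight(data.reliable, features, labels)
        sm = [posteriors[p].sm for p, l in labels.items() if l == "sm-comp"]
        non = [posteriors[p].sm for p, l in labels.items() if l == "non-comp"]
        assert np.mean(sm) > np.mean(non)


class TestParameterRecovery:
    def test_conditional_tables_converge_with_sample_size(self):
        """KL(model || truth) on each class-conditional table shrinks with n."""
        rng = np.random.default_rng(5)
        truth = np.array([[0.7, 0.2, 0.1], [0.2, 0.5, 0.3], [0.1, 0.2, 0.7]])
        priors = np.array([0.2, 0.3, 0.5])
        disc = Discretizer()
        disc.cuts_["F"] = [0.5, 1.5]

        def fit_kl(n):
            y_idx = rng.choice(3, size=n, p=priors)
            codes = pd.DataFrame({"F": [rng.choice(3, p=truth[c]) for c in y_idx]})
            labels = [("sm-comp", "lg-comp", "non-comp")[c] for c in y_idx]
            model = learn_ml_params(codes, labels, disc, smoothing=1.0)
            kl = 0.0
            for c in range(3):
                p, q = truth[c], model.cpt["F"][c]
                kl += float((p * np.log(p / q)).sum())
            return kl

        assert fit_kl(4000) < fit_kl(150)
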