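import itertools
import math

import numpy as np
import pandas as pd
import pytest

from emaplink import (
    ComplexCatalog,
    EMapMatrix,
    EpistasisThresholds,
    LinkTestConfig,
    all_links,
    build_combined,
    classify,
    complex_link_test,
    link_delta,
    links_to_graph,
)
from emaplink.complexes import MEASURED, MEASURED_MULTI, PREDICTED, bridge_values
from emaplink.predictor import Prediction, PredictionSet, PredictionSource


def predset_of(scores, name_a="A", name_b="B"):
    preds = [
        Prediction(
            gene_a=a,
            gene_b=b,
            score=s,
            sources=(PredictionSource("m", (a, b), s, "n", 0.9),),
            epistasis_class=classify(s),
        )
        for (a, b), s in scores.items()
    ]
    return PredictionSet(preds, 0.6, 70, EpistasisThresholds(), name_a, name_b)


def normal_background(rng, genes, extra_pairs=None):
    """Fully observed matrix of N(0,1) values, optionally overridden per pair."""
    n = len(genes)
    a = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    a[iu] = rng.normal(0, 1, len(iu[0]))
    a = a + a.T
    np.fill_diagonal(a, np.nan)
    m = EMapMatrix(pd.DataFrame(a, index=genes, columns=genes), name="bg")
    if extra_pairs:
        for (x, y), v in extra_pairs.items():
            m.data.at[x, y] = v
            m.data.at[y, x] = v
    return m


class TestBuildCombined:
    def test_measured_beats_predicted(self):
        a = EMapMatrix.from_pairs(["x", "y"], {("x", "y"): 2.0}, name="A")
        combined = build_combined([a], [predset_of({("x", "y"): 5.0})])
        assert combined.emap.get("x", "y") == 2.0
        assert combined.provenance[("x", "y")] == MEASURED

    def test_multiple_predictions_average(self):
        a = EMapMatrix.from_pairs(["x", "z"], {("x", "z"): 1.0}, name="A")
        combined = build_combined(
            [a],
            [predset_of({("p", "q"): 1.0}), predset_of({("p", "q"): 3.0}, "A", "C")],
        )
        assert combined.emap.get("p", "q") == 2.0
        assert combined.provenance[("p", "q")] == PREDICTED

    def test_measured_in_two_screens_averages(self):
        a = EMapMatrix.from_pairs(["x", "y"], {("x", "y"): 2.0}, name="A")
        b = EMapMatrix.from_pairs(["x", "y"], {("x", "y"): 4.0}, name="B")
        combined = build_combined([a, b], [])
        assert combined.emap.get("x", "y") == 3.0
        assert combined.provenance[("x", "y")] == MEASURED_MULTI


class TestBridgeValues:
    def test_shared_subunits_excluded_from_inter_bridges(self):
        genes = ["a1", "a2", "shared", "b1", "b2"]
        m = EMapMatrix.from_pairs(
            genes,
            {
                ("a1", "b1"): -1.0,
                ("a1", "shared"): -9.0,
                ("shared", "b1"): -9.0,
                ("a2", "b2"): -2.0,
            },
        )
        combined = build_combined([m], [])
        catalog = ComplexCatalog(
            {"CA": frozenset({"a1", "a2", "shared"}), "CB": frozenset({"b1", "b2", "shared"})}
        )
        vals = bridge_values(combined, catalog, "CA", "CB")
        assert sorted(vals) == [-2.0, -1.0]

    def test_intra_uses_within_complex_pairs(self):
        m = EMapMatrix.from_pairs(
            ["a", "b", "c"], {("a", "b"): 1.0, ("a", "c"): 2.0, ("b", "c"): 3.0}
        )
        combined = build_combined([m], [])
        catalog = ComplexCatalog({"C": frozenset({"a", "b", "c"})})
        assert sorted(bridge_values(combined, catalog, "C", "C")) == [1.0, 2.0, 3.0]


class TestComplexLinkTest:
    def planted(self, seed=0, effect=-5.0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:02d}" for i in range(30)]
        block = {
            (a, b): effect + rng.normal(0, 0.2)
            for a in genes[:4]
            for b in genes[4:8]
        }
        m = normal_background(rng, genes, block)
        catalog = ComplexCatalog(
            {
                "CA": frozenset(genes[:4]),
                "CB": frozenset(genes[4:8]),
                "CC": frozenset(genes[8:12]),
            }
        )
        return build_combined([m], []), catalog

    def test_planted_block_hits_p_floor(self):
        combined, catalog = self.planted()
        cfg = LinkTestConfig(n_samples=10_000, alpha=0.001, seed=1)
        link = complex_link_test(combined, catalog, ("CA", "CB"), cfg)
        assert link.polarity == "negative"
        assert link.n_interactions == 16
        assert link.p_value == pytest.approx(1.0 / 10_001, rel=1e-12)

    def test_pair_order_symmetry(self):
        combined, catalog = self.planted()
        cfg = LinkTestConfig(n_samples=2_000, seed=3)
        fwd = complex_link_test(combined, catalog, ("CA", "CB"), cfg)
        rev = complex_link_test(combined, catalog, ("CB", "CA"), cfg)
        assert fwd == rev

    def test_central_single_value_is_insignificant(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i:02d}" for i in range(20)]
        m = normal_background(rng, genes)
        combined = build_combined([m], [])
        pool = combined.pool()
        med = float(np.median(pool))
        combined.emap.data.at[genes[0], genes[1]] = med
        combined.emap.data.at[genes[1], genes[0]] = med
        catalog = ComplexCatalog(
            {"CA": frozenset(genes[:2]), "CB": frozenset({genes[0], genes[2]})}
        )
        link = complex_link_test(
            combined, catalog, ("CA", "CA"), LinkTestConfig(n_samples=4_000, seed=2)
        )
        assert link.n_interactions == 1
        assert 0.3 < link.p_value < 0.7

    def test_missing_bridge_returns_absent(self):
        m = EMapMatrix.from_pairs(["a", "b", "c", "d"], {("a", "b"): 1.0})
        combined = build_combined([m], [])
        catalog = ComplexCatalog({"CA": frozenset({"a", "b"}), "CB": frozenset({"c", "d"})})
        assert complex_link_test(combined, catalog, ("CA", "CB"), LinkTestConfig(n_samples=100)) is None

    def test_unknown_complex_raises(self):
        combined, catalog = self.planted()
        with pytest.raises(KeyError):
            complex_link_test(combined, catalog, ("CA", "nope"), LinkTestConfig(n_samples=10))

    def test_add_one_correction_keeps_p_positive(self):
        combined, catalog = self.planted()
        link = complex_link_test(
            combined, catalog, ("CA", "CB"), LinkTestConfig(n_samples=50, seed=0)
        )
        assert link.p_value >= 1.0 / 51

    def test_converges_to_exhaustive_enumeration(self):
        # small enough pool that every k-subset median can be enumerated
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(7)]
        m = normal_background(rng, genes)
        combined = build_combined([m], [])
        catalog = ComplexCatalog(
            {"CA": frozenset(genes[:2]), "CB": frozenset(genes[2:4])}
        )
        pool = combined.pool()
        vals = bridge_values(combined, catalog, "CA", "CB")
        obs = np.median(vals)
        k = len(vals)
        meds = [np.median(c) for c in itertools.combinations(pool, k)]
        exact_low = sum(1 for x in meds if x <= obs) / len(meds)
        exact_high = sum(1 for x in meds if x >= obs) / len(meds)
        exact = min(exact_low, exact_high)
        n_samples = 20_000
        link = complex_link_test(
            combined, catalog, ("CA", "CB"), LinkTestConfig(n_samples=n_samples, seed=7)
        )
        tol = 3 * math.sqrt(exact * (1 - exact) / n_samples) + 2 / n_samples
        assert abs(link.p_value - exact) <= tol


class TestAllLinks:
    def test_planted_link_is_the_only_discovery(self):
        combined, catalog = (
            TestComplexLinkTest().planted(seed=4)
        )
        cfg = LinkTestConfig(n_samples=5_000, alpha=0.001, seed=9)
        links = all_links(combined, catalog, cfg, mode="inter")
        assert [(l.complex_a, l.complex_b) for l in links] == [("CA", "CB")]
        assert links[0].polarity == "negative"

    def test_intra_positive_block_recovered(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i:02d}" for i in range(30)]
        block = {
            (a, b): 6.0 + rng.normal(0, 0.2)
            for a, b in itertools.combinations(genes[:5], 2)
        }
        m = normal_background(rng, genes, block)
        combined = build_combined([m], [])
        catalog = ComplexCatalog(
            {"CP": frozenset(genes[:5]), "CX": frozenset(genes[5:10])}
        )
        links = all_links(
            combined, catalog, LinkTestConfig(n_samples=5_000, alpha=0.001, seed=2),
            mode="intra",
        )
        assert [(l.complex_a, l.polarity) for l in links] == [("CP", "positive")]

    def test_reproducible_under_fixed_seed(self):
        combined, catalog = TestComplexLinkTest().planted(seed=8)
        cfg = LinkTestConfig(n_samples=1_000, alpha=0.05, seed=13)
        assert all_links(combined, catalog, cfg) == all_links(combined, catalog, cfg)

    def test_scan_agrees_with_single_pair_test(self):
        combined, catalog = TestComplexLinkTest().planted(seed=4)
        cfg = LinkTestConfig(n_samples=2_000, alpha=0.001, seed=9)
        links = all_links(combined, catalog, cfg, mode="inter")
        solo = complex_link_test(combined, catalog, ("CA", "CB"), cfg)
        assert links[0] == solo


class TestLinkDelta:
    def link(self, a, b, n, p=1e-5):
        from emaplink.complexes import ComplexLink

        return ComplexLink(a, b, n, -4.0, p, "negative")

    def test_classification(self):
        before = [self.link("A", "B", 5), self.link("A", "C", 3)]
        after = [
            self.link("A", "B", 8),
            self.link("A", "C", 3),
            self.link("B", "C", 4),
        ]
        delta = link_delta(before, after)
        assert [l.key for l in delta.novel] == [("B", "C")]
        assert [l.key for l in delta.reinforced] == [("A", "B")]
        assert [l.key for l in delta.unchanged] == [("A", "C")]
        assert delta.lost == []

    def test_graph_export(self):
        links = [self.link("A", "B", 5), self.link("C", "C", 2)]
        g = links_to_graph(links)
        assert g.has_edge("A", "B")
        assert g.nodes["C"]["intra_p"] == 1e-5


class TestNullCalibration:
    def test_per_tail_false_positive_rate_near_alpha(self):
        # no planted signal: the lower-tail p fires at ~alpha of repetitions
        reps, alpha, hits = 120, 0.05, 0
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            genes = [f"g{i:02d}" for i in range(24)]
            m = normal_background(rng, genes)
            combined = build_combined([m], [])
            catalog = ComplexCatalog(
                {"CA": frozenset(genes[:4]), "CB": frozenset(genes[4:8])}
            )
            link = complex_link_test(
                combined, catalog, ("CA", "CB"),
                LinkTestConfig(n_samples=400, seed=rep),
            )
            if link.p_negative < alpha:
                hits += 1
        rate = hits / reps
        sd = math.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rate - alpha) <= 3 * sd + 1 / reps
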