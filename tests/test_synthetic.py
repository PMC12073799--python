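"""Synthetic cohort generator: parcellation, templates, sampling."""

import numpy as np
import pytest

from ccdnet import (
    CohortConfig,
    build_parcellation,
    build_template,
    generate_cohort,
    sample_individual,
)
from ccdnet.synthetic import _cc_edges


class TestParcellation:
    def test_cardinality(self, parcellation):
        assert parcellation.n_nodes == 76
        hemis = [n.hemisphere for n in parcellation.nodes]
        assert hemis.count("L") == 38
        assert hemis.count("R") == 38

    def test_abbreviations_unique_per_hemisphere(self, parcellation):
        left = [n.abbreviation for n in parcellation.nodes if n.hemisphere == "L"]
        assert len(set(left)) == 38
        assert left[0] == "Sub" and left[-1] == "Cb"

    def test_homotopic_partner(self, parcellation):
        i = parcellation.index("Fra,L")
        j = parcellation.homotopic_partner(i)
        assert parcellation.nodes[j].label == "Fra,R"
        assert parcellation.homotopic_partner(j) == i

    def test_order_stable(self):
        a, b = build_parcellation(), build_parcellation()
        assert a.labels == b.labels


class TestTemplates:
    @pytest.mark.parametrize("condition", ["complete_ccd", "virtual_callosotomy"])
    def test_no_callosal_edges_in_acallosal_conditions(self, parcellation, condition):
        t = build_template(parcellation, condition, CohortConfig(rng_seed=0))
        assert not t.edges_by_tag("cc")

    def test_normal_has_cc_on_every_cortical_homotopic_pair(self, parcellation):
        t = build_template(parcellation, "normal_cc", CohortConfig(rng_seed=0))
        cc = {(e.i, e.j) for e in t.edges_by_tag("cc")}
        assert cc == {(e.i, e.j) for e in _cc_edges(parcellation)}
        for i, j in cc:
            assert parcellation.nodes[i].hemisphere != parcellation.nodes[j].hemisphere
            assert parcellation.homotopic_partner(i) == j

    def test_commissures_identical_across_conditions(self, parcellation):
        cfg = CohortConfig(rng_seed=0)
        ref = None
        for cond in ("normal_cc", "complete_ccd", "partial_ccd"):
            t = build_template(parcellation, cond, cfg)
            com = sorted(
                (e.i, e.j, e.tract_tag, e.mean_weight)
                for e in t.edges
                if e.tract_tag in ("ac", "pc", "hc")
            )
            if ref is None:
                ref = com
            assert com == ref

    def test_tract_tag_placement(self, parcellation):
        for cond in ("normal_cc", "complete_ccd", "partial_ccd"):
            t = build_template(parcellation, cond, CohortConfig(rng_seed=0))
            inter = parcellation.interhemispheric_mask()
            for e in t.edges:
                assert e.i < e.j
                if e.tract_tag in ("cc", "ac", "pc", "hc", "sigmoid"):
                    assert inter[e.i, e.j]
                elif e.tract_tag in ("intra", "probst"):
                    assert not inter[e.i, e.j]

    def test_sigmoid_edge_endpoints(self, parcellation):
        t = build_template(parcellation, "partial_ccd", CohortConfig(rng_seed=0))
        sig = t.edges_by_tag("sigmoid")
        labels = {
            frozenset(
                (parcellation.nodes[e.i].label, parcellation.nodes[e.j].label)
            )
            for e in sig
        }
        assert frozenset(("Fra,L", "Hp,R")) in labels
        primary = next(
            e
            for e in sig
            if parcellation.nodes[max(e.i, e.j)].label == "Hp,R"
            or parcellation.nodes[min(e.i, e.j)].label == "Hp,R"
        )
        assert primary.presence_prob == pytest.approx(0.5)

    def test_partial_remnant_is_anterior_frontal(self, parcellation):
        t = build_template(parcellation, "partial_ccd", CohortConfig(rng_seed=0))
        remnant = t.edges_by_tag("cc")
        assert 0 < len(remnant) < len(_cc_edges(parcellation))
        for e in remnant:
            assert parcellation.nodes[e.i].lobe == "frontal"

    def test_probst_only_in_dysgenic_conditions(self, parcellation):
        cfg = CohortConfig(rng_seed=0)
        assert not build_template(parcellation, "normal_cc", cfg).edges_by_tag("probst")
        probst = build_template(parcellation, "complete_ccd", cfg).edges_by_tag("probst")
        assert len(probst) == 12  # 6 posterior targets per hemisphere
        for e in probst:
            assert "Fra" in {
                parcellation.nodes[e.i].abbreviation,
                parcellation.nodes[e.j].abbreviation,
            }

    def test_unknown_condition_rejected(self, parcellation):
        with pytest.raises(ValueError):
            build_template(parcellation, "hemispherectomy")


class TestSampling:
    def test_degenerate_noise_reproduces_template(self, parcellation, normal_template):
        cfg = CohortConfig(
            rng_seed=0,
            weight_sd=0.0,
            edge_consistency={t: 1.0 for t in ("cc", "ac", "pc", "hc", "intra")},
        )
        c = sample_individual(normal_template, cfg, 0)
        expected = np.zeros_like(c.weights)
        for e in normal_template.edges:
            expected[e.i, e.j] = expected[e.j, e.i] = e.mean_weight
        np.testing.assert_array_equal(c.weights, expected)

    def test_deterministic_given_seed(self, normal_template):
        cfg = CohortConfig(rng_seed=42)
        a = sample_individual(normal_template, cfg, 3)
        b = sample_individual(normal_template, cfg, 3)
        np.testing.assert_array_equal(a.weights, b.weights)
        c = sample_individual(normal_template, cfg, 4)
        assert not np.array_equal(a.weights, c.weights)

    def test_connectome_invariants(self, cohorts):
        for cohort in cohorts.values():
            for c in cohort.connectomes:
                W = c.weights
                np.testing.assert_array_equal(W, W.T)
                assert np.all(np.diag(W) == 0)
                assert W.min() >= 0 and W.max() <= 1

    def test_retention_fraction_matches_binomial(self, normal_template):
        # uniform consistency 0.8 on an all-presence-1 template: the mean
        # retained fraction over 10 subjects is binomial with p = 0.8
        consistency = 0.8
        cfg = CohortConfig(
            rng_seed=5,
            edge_consistency={
                t: consistency for t in ("cc", "ac", "pc", "hc", "intra")
            },
        )
        n_edges = len(normal_template.edges)
        fractions = []
        for k in range(10):
            c = sample_individual(normal_template, cfg, k)
            fractions.append(np.count_nonzero(c.weights) / 2 / n_edges)
        sd = np.sqrt(consistency * (1 - consistency) / (n_edges * 10))
        assert abs(np.mean(fractions) - consistency) < 3 * sd


class TestCohorts:
    def test_n_subjects_guard(self):
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=1)

    def test_virtual_callosotomy_pairs_with_normal(self, cohorts, parcellation):
        normal = cohorts["normal_cc"]
        vc = cohorts["virtual_callosotomy"]
        cc_pairs = {(e.i, e.j) for e in _cc_edges(parcellation)}
        for cn, cv in zip(normal.connectomes, vc.connectomes):
            diff = cn.weights - cv.weights
            nz = set(zip(*np.nonzero(np.triu(diff))))
            assert nz <= cc_pairs  # only callosal entries may differ
            # intrahemispheric blocks identical
            half = parcellation.n_nodes // 2
            np.testing.assert_array_equal(
                cn.weights[:half, :half], cv.weights[:half, :half]
            )
            np.testing.assert_array_equal(
                cn.weights[half:, half:], cv.weights[half:, half:]
            )
            assert not np.any(
                [cv.weights[i, j] for i, j in cc_pairs]
            )

    def test_sigmoid_carriers_recorded(self, cohorts, parcellation):
        partial = cohorts["partial_ccd"]
        carriers = partial.metadata["sigmoid_carriers"]
        key = "Fra,L-Hp,R"
        assert key in carriers
        i, j = parcellation.index("Fra,L"), parcellation.index("Hp,R")
        observed = [
            k
            for k, c in enumerate(partial.connectomes)
            if c.weights[i, j] > 0
        ]
        assert carriers[key] == observed

    def test_carrier_count_near_penetrance(self):
        # over several seeds, carrier counts average about penetrance * n
        counts = []
        for seed in range(6):
            coh = generate_cohort(
                "partial_ccd", CohortConfig(condition="partial_ccd", rng_seed=seed)
            )
            counts.append(len(coh.metadata["sigmoid_carriers"]["Fra,L-Hp,R"]))
        mean = np.mean(counts)
        sd = np.sqrt(0.5 * 0.5 * 10 / 6)
        assert abs(mean - 5.0) < 3 * sd

    def test_lower_consistency_lowers_similarity(self):
        from ccdnet import pairwise_similarity

        means = []
        for consistency in (0.95, 0.6):
            vals = []
            for seed in range(3):
                cfg = CohortConfig(
                    condition="normal_cc",
                    rng_seed=seed,
                    edge_consistency={
                        t: consistency for t in ("cc", "ac", "pc", "hc", "intra")
                    },
                )
                coh = generate_cohort("normal_cc", cfg)
                vals.append(pairwise_similarity(coh, "whole").mean)
            means.append(np.mean(vals))
        assert means[0] > means[1]
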