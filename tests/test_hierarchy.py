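"""Hierarchy structure, weight composition, allocation, survey pipeline."""

import numpy as np
import pytest

import nbsahp as nb
from nbsahp.ahp import SchemaError
from nbsahp.hierarchy import (
    ROOT,
    CoverageError,
    GlobalWeights,
    LocalWeights,
    _round,
    load_local_weights,
    save_local_weights,
)

# Category point sums of the published allocation, obtained by summing the
# printed per-option integers by hand; the grand total is 1001.
PUBLISHED_CATEGORY_SUMS = {
    "disease_condition": 132,
    "screening_test": 200,
    "intervention": 293,
    "follow_up": 198,
    "economic_evaluation": 178,
}


# -- structure --------------------------------------------------------------

def test_canonical_structure_counts(hierarchy):
    assert hierarchy.n_categories == 5
    assert hierarchy.n_subcategories == 16
    assert hierarchy.n_options == 50


def test_incidence_has_five_ordinal_levels(hierarchy):
    _, sub = hierarchy.subcategory("incidence")
    assert len(sub.options) == 5


def test_economic_evaluation_is_single_subcategory(hierarchy):
    cat = hierarchy.category("economic_evaluation")
    assert len(cat.subcategories) == 1


def test_duplicate_subcategory_id_rejected():
    doc = {
        "categories": [
            {
                "id": "c1",
                "label": "C1",
                "subcategories": [
                    {"id": "s", "label": "S", "options": [{"id": "a", "label": "a"}, {"id": "b", "label": "b"}]},
                    {"id": "s", "label": "S2", "options": [{"id": "a", "label": "a"}, {"id": "b", "label": "b"}]},
                ],
            }
        ]
    }
    with pytest.raises(SchemaError):
        nb.load_hierarchy(doc)


def test_subcategory_needs_two_options():
    doc = {
        "categories": [
            {"id": "c", "label": "C",
             "subcategories": [{"id": "s", "label": "S", "options": [{"id": "a", "label": "a"}]}]}
        ]
    }
    with pytest.raises(SchemaError):
        nb.load_hierarchy(doc)


def test_canonical_config_round_trips(hierarchy, tmp_path):
    path = tmp_path / "h.yaml"
    nb.save_hierarchy(hierarchy, path)
    assert nb.load_hierarchy(path) == hierarchy


def test_full_pairwise_enumeration_counts(hierarchy):
    # The fielded questionnaire asked 10/22/56 pairwise questions; full
    # pairwise enumeration of the canonical hierarchy yields 10/25/57.  The
    # reduced design was never published, so the discrepancy is asserted
    # here rather than silently reconciled.
    q = nb.enumerate_questions(hierarchy)
    assert len(q["category"]) == 10
    assert len(q["subcategory"]) == 25
    assert len(q["criterion"]) == 57


# -- weight composition -----------------------------------------------------

def test_compose_is_multiplicative_chain():
    doc = {
        "categories": [
            {"id": "c1", "label": "C1", "subcategories": [
                {"id": "s1", "label": "S1", "options": [{"id": "o1", "label": "1"},
                                                        {"id": "o2", "label": "2"},
                                                        {"id": "o3", "label": "3"},
                                                        {"id": "o4", "label": "4"}]},
                {"id": "s2", "label": "S2", "options": [{"id": "o1", "label": "1"},
                                                        {"id": "o2", "label": "2"}]},
            ]},
            {"id": "c2", "label": "C2", "subcategories": [
                {"id": "s3", "label": "S3", "options": [{"id": "o1", "label": "1"},
                                                        {"id": "o2", "label": "2"}]},
            ]},
        ]
    }
    h = nb.load_hierarchy(doc)
    lw = LocalWeights({
        ROOT: nb.PriorityVector(("c1", "c2"), np.array([0.5, 0.5])),
        "c1": nb.PriorityVector(("s1", "s2"), np.array([0.4, 0.6])),
        "c2": nb.PriorityVector(("s3",), np.array([1.0])),
        "c1/s1": nb.PriorityVector(("o1", "o2", "o3", "o4"), np.array([0.25] * 4)),
        "c1/s2": nb.PriorityVector(("o1", "o2"), np.array([0.5, 0.5])),
        "c2/s3": nb.PriorityVector(("o1", "o2"), np.array([0.9, 0.1])),
    })
    gw = nb.compose_global_weights(h, lw)
    assert gw["c1/s1/o1"] == pytest.approx(0.5 * 0.4 * 0.25)
    # single-subcategory category passes its weight straight through
    assert gw["c2/s3/o1"] == pytest.approx(0.5 * 0.9)
    assert gw.total() == pytest.approx(1.0, abs=1e-12)


def test_uniform_weights_compose_uniformly(hierarchy):
    gw = nb.compose_global_weights(hierarchy, nb.uniform_local_weights(hierarchy))
    for c in hierarchy.categories:
        m = len(c.subcategories)
        for s in c.subcategories:
            k = len(s.options)
            for o in s.options:
                assert gw[f"{c.id}/{s.id}/{o.id}"] == pytest.approx(1 / (5 * m * k))
    assert gw.total() == pytest.approx(1.0, abs=1e-12)


def test_global_weights_sum_to_one_for_random_local_weights(hierarchy):
    rng = np.random.default_rng(17)
    for _ in range(5):
        vecs = {}
        for node, children in hierarchy.internal_nodes():
            raw = rng.uniform(0.1, 1.0, len(children))
            vecs[node] = nb.PriorityVector(children, raw / raw.sum())
        gw = nb.compose_global_weights(hierarchy, LocalWeights(vecs))
        assert gw.total() == pytest.approx(1.0, abs=1e-12)


def test_missing_node_vector_is_coverage_error(hierarchy):
    lw = nb.uniform_local_weights(hierarchy)
    vecs = dict(lw.vectors)
    del vecs["screening_test"]
    with pytest.raises(CoverageError, match="screening_test"):
        nb.compose_global_weights(hierarchy, LocalWeights(vecs))


# -- allocation -------------------------------------------------------------

def test_rounding_rules():
    assert _round(114.0, "half_up") == 114
    assert _round(37.5, "half_up") == 38
    assert _round(37.5, "bankers") == 38
    assert _round(38.5, "bankers") == 38
    assert _round(38.5, "half_up") == 39


def test_allocate_scores_times_1000_half_up():
    gw = GlobalWeights({"c/s/a": 0.114, "c/s/b": 0.0375, "c/s/c": 0.8485})
    alloc = nb.allocate_scores(gw)
    assert alloc["c/s/a"] == 114
    assert alloc["c/s/b"] == 38  # 37.5 rounds up under half-up
    assert alloc["c/s/c"] == 849


def test_allocation_monotone_in_weight(hierarchy):
    rng = np.random.default_rng(5)
    raw = rng.uniform(0.01, 1.0, hierarchy.n_options)
    paths = hierarchy.option_paths()
    gw = GlobalWeights(dict(zip(paths, raw / raw.sum())))
    alloc = nb.allocate_scores(gw)
    order = sorted(paths, key=lambda p: gw[p])
    pts = [alloc[p] for p in order]
    assert all(a <= b for a, b in zip(pts, pts[1:]))


def test_published_allocation_category_sums(hierarchy, allocation):
    assert allocation.provenance == "published_table3"
    for cid, total in PUBLISHED_CATEGORY_SUMS.items():
        assert allocation.category_total(hierarchy, cid) == total
    assert allocation.grand_total() == 1001


def test_published_points_sorted_descending_within_subcategory(hierarchy, allocation):
    for c in hierarchy.categories:
        for s in c.subcategories:
            pts = [allocation[f"{c.id}/{s.id}/{o.id}"] for o in s.options]
            assert all(a > b for a, b in zip(pts, pts[1:]))
            assert min(pts) >= 1


def test_allocation_csv_round_trip(allocation, tmp_path):
    path = tmp_path / "alloc.csv"
    nb.save_allocation(allocation, path)
    again = nb.load_allocation(path)
    assert again.points == dict(allocation.points)
    assert again.provenance == "published_table3"


def test_local_weights_yaml_round_trip(hierarchy, tmp_path):
    lw = nb.uniform_local_weights(hierarchy)
    path = tmp_path / "lw.yaml"
    save_local_weights(lw, path)
    again = load_local_weights(path)
    for node, _ in hierarchy.internal_nodes():
        assert np.allclose(again[node].weights, lw[node].weights)
        assert again[node].items == lw[node].items


# -- survey -> weights ------------------------------------------------------

def test_all_equal_respondent_gives_uniform_weights(hierarchy, equal_rows):
    lw, reports = nb.weights_from_survey(hierarchy, equal_rows)
    for node, children in hierarchy.internal_nodes():
        assert np.allclose(lw[node].weights, np.full(len(children), 1 / len(children)))
        assert reports[node].ci == 0.0 and reports[node].consistent


def test_noiseless_consistent_panel_recovers_truth_exactly(hierarchy):
    truth = nb.lattice_local_weights(hierarchy)
    cfg = nb.SimulationConfig(truth=truth, n_respondents=3, judgment_noise_sd=0.0,
                              criterion_skip_prob=0.0, seed=9)
    panel = nb.simulate_panel(cfg, hierarchy)
    lw, reports = nb.weights_from_survey(hierarchy, panel.rows)
    for node, _ in hierarchy.internal_nodes():
        assert np.allclose(lw[node].weights, truth[node].weights, atol=1e-14)
        assert reports[node].ci == 0.0


def test_node_without_matrices_is_coverage_error(hierarchy, equal_rows):
    rows = [r for r in equal_rows if r["matrix_id"] != "screening_test"]
    with pytest.raises(CoverageError, match="screening_test"):
        nb.weights_from_survey(hierarchy, rows)


def test_partial_matrix_rejected(hierarchy, equal_rows):
    rows = equal_rows
    victim = next(r for r in rows if r["matrix_id"] == "disease_condition/incidence")
    rows.remove(victim)
    with pytest.raises(SchemaError, match="partial"):
        nb.weights_from_survey(hierarchy, rows)


def test_aip_policy_matches_aij_for_single_respondent(hierarchy, equal_rows):
    rows = equal_rows
    lw_aij, _ = nb.weights_from_survey(hierarchy, rows, policy="aij")
    lw_aip, _ = nb.weights_from_survey(hierarchy, rows, policy="aip")
    for node, _ in hierarchy.internal_nodes():
        assert np.allclose(lw_aij[node].weights, lw_aip[node].weights)
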