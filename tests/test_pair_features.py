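"""Annotation store lookups and identity-blind pair feature assembly."""

import math

import numpy as np
import pandas as pd
import pytest

from afmscreen.consensus_metrics import compute_pair_metrics
from afmscreen.interface_analysis import find_valid_contacts
from afmscreen.pair_features import (
    AnnotationStore,
    DEFAULT_SCHEMA,
    assemble_features,
    biogrid_count,
    coexpression_score,
    colocalization_score,
    depmap_codependency,
    embedding_similarity,
    feature_table,
    impute_and_scale,
    missense_interface_conservation,
    orcs_profile_similarity,
)
from afmscreen.prediction_io import load_prediction_set
from afmscreen.synthetic_fixtures import (
    PairFixtureSpec,
    PlantedContact,
    make_annotation_store,
    make_prediction_set,
)


@pytest.fixture(scope="module")
def store():
    s = AnnotationStore()
    s.biogrid[("P1", "P2")] = 7
    s.depmap["P1"] = np.array([1.0, 2.0, 3.0])
    s.depmap["P2"] = np.array([1.0, 2.0, 4.0])
    s.depmap["P3"] = -np.array([1.0, 2.0, 3.0]) + 4.0  # perfectly anticorrelated
    s.depmap["P4"] = np.full(3, 2.0)  # zero variance
    s.coexpress["P1"] = [("P2", 2.5)]
    s.coexpress["P2"] = [("P1", 3.1)]
    s.deeploc["P1"] = np.eye(10)[0]
    s.deeploc["P2"] = np.eye(10)[0]
    s.deeploc["P3"] = np.eye(10)[1]
    s.deeploc["P4"] = np.r_[0.5, 0.5, np.zeros(8)]
    s.embedding["P1"] = np.r_[1.0, 0.0, 0.0]
    s.embedding["P2"] = np.r_[0.0, 1.0, 0.0]
    s.embedding["P3"] = np.r_[3.0, 4.0, 0.0]
    s.orcs["P1"] = np.isin(np.arange(8), [1, 2, 3]).astype(int)
    s.orcs["P2"] = np.isin(np.arange(8), [2, 3, 4]).astype(int)
    s.orcs["P3"] = np.isin(np.arange(8), [6, 7]).astype(int)
    s.missense["P1"] = np.array([80.0, 60.0, 40.0, 20.0] * 5)
    s.missense["P2"] = np.array([50.0] * 20)
    return s


def test_biogrid_count_symmetric_and_absent(store):
    assert biogrid_count(store, "P1", "P2") == 7
    assert biogrid_count(store, "P2", "P1") == 7
    assert biogrid_count(store, "P1", "P9") == 0


def test_depmap_codependency_values(store):
    assert depmap_codependency(store, "P1", "P1") == pytest.approx(1.0)
    assert depmap_codependency(store, "P1", "P3") == pytest.approx(-1.0)
    # closed-form correlation of (1,2,3) vs (1,2,4)
    assert depmap_codependency(store, "P1", "P2") == pytest.approx(0.9820, abs=1e-4)
    assert depmap_codependency(store, "P1", "P4") is None  # zero variance
    assert depmap_codependency(store, "P1", "P9") is None  # absent


def test_coexpression_max_of_both_directions(store):
    assert coexpression_score(store, "P1", "P2") == 3.1
    assert coexpression_score(store, "P1", "P3") is None
    s = AnnotationStore(coexpress={"A": [("B", 2.5)], "B": []})
    assert coexpression_score(s, "A", "B") == 2.5


def test_colocalization_inner_product(store):
    assert colocalization_score(store, "P1", "P2") == pytest.approx(1.0)
    assert colocalization_score(store, "P1", "P3") == pytest.approx(0.0)
    assert colocalization_score(store, "P4", "P4") == pytest.approx(0.5)


def test_embedding_similarity(store):
    cos, d = embedding_similarity(store, "P1", "P1")
    assert cos == pytest.approx(1.0) and d == pytest.approx(0.0)
    cos, d = embedding_similarity(store, "P1", "P2")
    assert cos == pytest.approx(0.0) and d == pytest.approx(math.sqrt(2))
    cos, d = embedding_similarity(store, "P1", "P3")
    assert cos == pytest.approx(3 / 5) and d == pytest.approx(math.sqrt(4 + 16))


def test_orcs_jaccard(store):
    assert orcs_profile_similarity(store, "P1", "P1") == 1.0
    assert orcs_profile_similarity(store, "P1", "P3") == 0.0
    assert orcs_profile_similarity(store, "P1", "P2") == 0.5  # {2,3}/{1,2,3,4}


@pytest.fixture(scope="module")
def cplus_bundle(tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    spec = PairFixtureSpec(
        len_a=10, len_b=12,
        contacts=[PlantedContact(i, i, 3.0) for i in range(1, 7)],
    )
    make_prediction_set(spec, d)
    pset = load_prediction_set(d, pair_id=("P1", "P2"))
    csets = [find_valid_contacts(m) for m in pset.models]
    metrics = compute_pair_metrics(pset, csets)
    return pset, csets, metrics


def test_missense_interface_means(cplus_bundle, store):
    pset, csets, _ = cplus_bundle
    mean_a, mean_b = missense_interface_conservation(pset, store, csets)
    # interface residues on chain A are planted positions 1..6
    assert mean_a == pytest.approx(np.mean([store.missense["P1"][i] for i in range(6)]))
    assert mean_b == pytest.approx(50.0)


def test_missense_out_of_range_is_missing(cplus_bundle):
    pset, csets, _ = cplus_bundle
    short = AnnotationStore(missense={"P1": np.array([10.0, 20.0]), "P2": np.array([50.0] * 20)})
    with pytest.warns(UserWarning):
        mean_a, _ = missense_interface_conservation(pset, short, csets)
    assert mean_a is None


def test_assemble_features_full_annotations(cplus_bundle):
    pset, csets, metrics = cplus_bundle
    full = make_annotation_store(["P1", "P2"], planted_pairs=[("P1", "P2")], seed=3)
    fv = assemble_features(pset, csets, metrics, full)
    assert set(fv.values) == set(DEFAULT_SCHEMA.names)
    assert not any(fv.missing.values())


def test_assemble_features_missing_biology_flagged(cplus_bundle):
    pset, csets, metrics = cplus_bundle
    fv = assemble_features(pset, csets, metrics, AnnotationStore())
    # structural features present
    assert not fv.missing["avg_models"] and not fv.missing["n_contacts_min"]
    # biological features (except the count-style biogrid default 0) missing
    for name in ("depmap_codependency", "coexpression_score", "colocalization_score",
                 "embedding_cosine", "orcs_jaccard", "missense_interface_min"):
        assert fv.missing[name]
    assert fv.values["biogrid_count"] == 0.0


def test_non_contact_positive_not_featurized(cplus_bundle, tmp_path):
    spec = PairFixtureSpec(len_a=6, len_b=6, contacts=[PlantedContact(1, 1, 3.0)])
    make_prediction_set(spec, tmp_path)
    pset = load_prediction_set(tmp_path, pair_id=("P1", "P2"))
    csets = [find_valid_contacts(m) for m in pset.models]
    metrics = compute_pair_metrics(pset, csets)
    assert not metrics.contact_positive
    with pytest.raises(ValueError):
        assemble_features(pset, csets, metrics, AnnotationStore())


def test_identity_blind_symmetry(store):
    """Every pairwise biological combination is symmetric in its arguments,
    and per-chain structural counts are emitted as sorted (min, max) — no
    feature can encode which protein came first."""
    for op in (biogrid_count, depmap_codependency, coexpression_score,
               colocalization_score, orcs_profile_similarity):
        assert op(store, "P1", "P2") == op(store, "P2", "P1")
    assert embedding_similarity(store, "P1", "P3") == embedding_similarity(store, "P3", "P1")
    assert "n_interface_res_small" in DEFAULT_SCHEMA.names
    assert "n_interface_res_large" in DEFAULT_SCHEMA.names
    assert not any(n.endswith(("_a", "_b")) for n in DEFAULT_SCHEMA.names)


def test_feature_table_and_imputation(cplus_bundle):
    pset, csets, metrics = cplus_bundle
    full = make_annotation_store(["P1", "P2"], planted_pairs=[("P1", "P2")], seed=3)
    fv_full = assemble_features(pset, csets, metrics, full, label="positive", refset="x")
    fv_empty = assemble_features(pset, csets, metrics, AnnotationStore(), label="negative", refset="x")
    tbl = feature_table([fv_full, fv_empty])
    scaled, params = impute_and_scale(tbl, DEFAULT_SCHEMA.names)
    for name in DEFAULT_SCHEMA.names:
        col = scaled[name]
        present = tbl[name].notna()
        assert ((col[present] >= 0) & (col[present] <= 1)).all()
        assert (col[~present] == -1).all()
    # present values never silently replaced: missingness flags preserved
    assert scaled.loc[1, "depmap_codependency_missing"] == 1.0
    assert scaled.loc[0, "depmap_codependency_missing"] == 0.0


def test_store_json_round_trip(tmp_path):
    s = make_annotation_store(["A1", "B2"], planted_pairs=[("A1", "B2")], seed=9)
    p = tmp_path / "store.json"
    s.save(p)
    s2 = AnnotationStore.load(p)
    assert biogrid_count(s2, "A1", "B2") == biogrid_count(s, "A1", "B2")
    assert depmap_codependency(s2, "A1", "B2") == pytest.approx(
        depmap_codependency(s, "A1", "B2")
    )
    bad = AnnotationStore(deeploc={"X": np.ones(3)})
    with pytest.raises(ValueError):
        bad.validate()
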