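import numpy as np
import pandas as pd
import pytest

import sweetgate as sg
from sweetgate.datasets import (
    FingerprintMatrix,
    FingerprintParams,
    NON_SWEET,
    NOT_ASSIGNED,
    SWEET,
)
from sweetgate.expert import (
    CONSENSUS,
    GATE_S1,
    GATE_S2,
    SweetTasteExpertSystem,
    consensus_predict,
    monte_carlo_expert,
    predictions_frame,
)
from sweetgate.similarity import ClusterReference


def vec(bits_on, length=40):
    v = np.zeros(length, dtype=np.uint8)
    v[list(bits_on)] = 1
    return v


def make_ref(name, member_bits, threshold, length=40):
    fps = FingerprintMatrix([f"{name}_m"], vec(member_bits, length)[None, :],
                            FingerprintParams(n_bits=length))
    return ClusterReference(name, fps, threshold)


def gate_system(t1=0.6, t2=0.8, rule="any"):
    system = SweetTasteExpertSystem(s1_threshold=t1, s2_threshold=t2, gate_rule=rule)
    system.references_ = [make_ref("S1", set(range(10)), t1),
                          make_ref("S2", set(range(20, 30)), t2)]
    return system


class TestGate:
    def test_one_satisfied_cluster_gates_under_any_not_all(self):
        # query at distance 0.5 from S1 and 1.0 from S2
        query = vec(set(range(5)))
        pathway, d1, d2 = gate_system(rule="any").gate(query)
        assert (pathway, d1, d2) == (GATE_S1, 0.5, 1.0)
        pathway, _, _ = gate_system(rule="all").gate(query)
        assert pathway is None

    def test_both_distances_above_thresholds_pass_to_consensus(self):
        query = vec(set(range(30, 35)))  # disjoint from S1, d2 = 1 - 5/10... far from both
        for rule in ("any", "all"):
            pathway, d1, d2 = gate_system(t1=0.3, t2=0.3, rule=rule).gate(query)
            assert pathway is None
            assert d1 > 0.3 and d2 > 0.3

    def test_strict_inequality_at_the_threshold(self):
        query = vec(set(range(5)))  # d1 exactly 0.5
        assert gate_system(t1=0.5).gate(query)[0] is None
        assert gate_system(t1=0.5000001).gate(query)[0] == GATE_S1

    def test_s2_pathway_when_only_second_cluster_matches(self):
        query = vec(set(range(20, 25)))  # d2 = 0.5, d1 = 1.0
        pathway, d1, d2 = gate_system().gate(query)
        assert pathway == GATE_S2
        assert (d1, d2) == (1.0, 0.5)

    def test_no_references_always_passes_through(self):
        system = SweetTasteExpertSystem()
        system.references_ = []
        assert system.gate(vec({1, 2})) == (None, None, None)


class TestConsensus:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (SWEET, SWEET, SWEET),
            (NON_SWEET, NON_SWEET, NON_SWEET),
            (SWEET, NON_SWEET, NOT_ASSIGNED),
            (NON_SWEET, SWEET, NOT_ASSIGNED),
            (NON_SWEET, NOT_ASSIGNED, NOT_ASSIGNED),
            (NOT_ASSIGNED, NOT_ASSIGNED, NOT_ASSIGNED),
        ],
    )
    def test_strict_agreement_rule(self, a, b, expected):
        assert consensus_predict(a, b) == expected


class TestPredictWorkflow:
    def test_planted_cluster_members_route_through_gate_as_sweet(self, fitted_system):
        system, (train, _), fps, table, y, meta = fitted_system
        planted = {m for members in meta.cluster_members.values() for m in members}
        predictions = system.predict(fps, table)
        for p in predictions:
            if p.id in planted:
                assert p.pathway in (GATE_S1, GATE_S2)
                assert p.class_label == SWEET
                assert p.in_ad is True

    def test_pathway_counts_sum_to_input_count(self, fitted_system):
        system, _, fps, table, y, _ = fitted_system
        predictions = system.predict(fps, table)
        frame = predictions_frame(predictions)
        assert frame["pathway"].value_counts().sum() == fps.n_molecules

    def test_consensus_pathway_agrees_with_components_or_rejects(self, fitted_system):
        system, _, fps, table, _, _ = fitted_system
        for p in system.predict(fps, table):
            if p.pathway == CONSENSUS:
                if p.class_label != NOT_ASSIGNED:
                    assert p.class_label == p.n3_class == p.plsda_class
                else:
                    assert p.n3_class != p.plsda_class or NOT_ASSIGNED in (
                        p.n3_class, p.plsda_class)

    def test_empty_input_gives_empty_output(self, fitted_system):
        system, _, fps, table, _, _ = fitted_system
        empty = FingerprintMatrix([], np.zeros((0, fps.n_bits)), fps.params)
        assert system.predict(empty, table) == []

    def test_missing_descriptor_row_errors_individually(self, fitted_system):
        system, _, fps, table, _, _ = fitted_system
        predictions = system.predict(fps, None)
        assert len(predictions) == fps.n_molecules
        errored = [p for p in predictions if p.pathway == "error"]
        gated = [p for p in predictions if p.pathway in (GATE_S1, GATE_S2)]
        assert len(errored) + len(gated) == fps.n_molecules
        assert all(p.class_label == NOT_ASSIGNED for p in errored)

    def test_empty_gate_reduces_to_pure_consensus(self, default_dataset):
        fps, table, y, _ = default_dataset
        system = SweetTasteExpertSystem()
        system.fit(fps, table, y, cluster_references=[])
        predictions = system.predict(fps, table)
        assert all(p.pathway == CONSENSUS for p in predictions)
        n3_pred = system.n3_.predict(table.values)
        pls_pred = system.plsda_.predict(table.values)
        for p, a, b in zip(predictions, n3_pred, pls_pred):
            assert p.class_label == consensus_predict(str(a), str(b))


class TestApplicabilityDomain:
    def test_training_centroid_is_in_domain_on_leverage(self, fitted_system):
        system, _, _, _, _, _ = fitted_system
        centroid = system.plsda_.scaler_.mean_
        verdict = system.assess_ad(np.zeros(2048, dtype=np.uint8), centroid)
        assert verdict["leverage"] == pytest.approx(0.0, abs=1e-10)
        assert verdict["leverage_ok"]

    def test_far_outlier_is_out_of_domain(self, fitted_system):
        system, _, _, _, _, _ = fitted_system
        far = system.plsda_.scaler_.mean_ + 100.0 * system.plsda_.scaler_.scale_
        verdict = system.assess_ad(np.zeros(2048, dtype=np.uint8), far)
        assert verdict["leverage"] > verdict["h_star"]
        assert not verdict["in_ad"]

    def test_gate_path_molecules_are_in_domain_by_definition(self, fitted_system):
        system, _, fps, _, _, meta = fitted_system
        member = meta.cluster_members["S1"][0]
        fp = fps.bits[fps.ids.index(member)]
        verdict = system.assess_ad(fp)
        assert verdict["in_ad"] is True
        assert verdict["pathway"].startswith("gate")

    def test_training_molecules_mostly_pass_similarity_branch(self, fitted_system):
        system, _, _, _, _, _ = fitted_system
        sims = system.n3_.average_similarity(
            system.n3_.scaler_.min_ + system.n3_.X_train_ *
            (system.n3_.scaler_.max_ - system.n3_.scaler_.min_)
        )
        frac = np.mean(sims >= system.similarity_cutoff_)
        assert frac >= 0.95


class TestPersistence:
    def test_save_load_roundtrip_preserves_predictions(self, fitted_system, tmp_path):
        system, (train, test), fps, table, y, _ = fitted_system
        system.save(tmp_path / "model")
        loaded = SweetTasteExpertSystem.load(tmp_path / "model")
        a = predictions_frame(system.predict(fps.subset(test), table.subset_rows(test)))
        b = predictions_frame(loaded.predict(fps.subset(test), table.subset_rows(test)))
        pd.testing.assert_frame_equal(a, b)


class TestMonteCarlo:
    def test_cumulative_ner_close_to_single_split_estimate(self, fitted_system,
                                                           monte_carlo_report):
        system, (train, test), fps, table, y, _ = fitted_system
        test_report = system.evaluate(fps.subset(test), table.subset_rows(test),
                                      y[test], context="test")
        assert abs(monte_carlo_report.ner - test_report.ner) <= 0.05
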