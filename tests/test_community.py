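"""Community weight pipeline: normalize, standardize, consolidate, assemble."""

import logging

import numpy as np
import pandas as pd
import pytest

from ecodecnet import (
    NetworkValidationError,
    apply_standardization,
    assemble_community_network,
    consolidate_sources,
    default_node_registry,
    generate_synthetic_community,
    index_report,
    normalize_scores,
)


def raw_table(rows):
    return pd.DataFrame(
        rows, columns=["source", "target", "link_type", "data_source", "raw_score"]
    )


class TestNormalize:
    def test_divide_by_group_maximum(self):
        table = raw_table(
            [
                ("AC01", "S01", "AC-S", "votes", 2.0),
                ("AC02", "S01", "AC-S", "votes", 4.0),
                ("AC03", "S01", "AC-S", "votes", 8.0),
            ]
        )
        out = normalize_scores(table)
        assert out["raw_score"].tolist() == [0.25, 0.5, 1.0]

    def test_groups_normalized_independently(self):
        table = raw_table(
            [
                ("AC01", "S01", "AC-S", "votes", 1.0),
                ("AC02", "S01", "AC-S", "votes", 2.0),
                ("S01", "D1", "S-D", "votes", 5.0),
                ("S02", "D1", "S-D", "votes", 10.0),
            ]
        )
        out = normalize_scores(table)
        assert out["raw_score"].tolist() == [0.5, 1.0, 0.5, 1.0]

    def test_all_zero_group_stays_zero_with_warning(self, caplog):
        table = raw_table([("AC01", "S01", "AC-S", "votes", 0.0)])
        with caplog.at_level(logging.WARNING):
            out = normalize_scores(table)
        assert out["raw_score"].tolist() == [0.0]
        assert "all-zero" in caplog.text

    def test_negative_score_rejected(self):
        table = raw_table([("AC01", "S01", "AC-S", "votes", -1.0)])
        with pytest.raises(ValueError, match="invalid raw score"):
            normalize_scores(table)

    def test_nonzero_groups_have_unit_maximum(self, synthetic_community):
        raw, _ = synthetic_community
        out = normalize_scores(raw)
        maxima = out.groupby(["link_type", "data_source"])["raw_score"].max()
        assert np.allclose(maxima, 1.0)


class TestStandardization:
    def test_factors_then_renormalized(self):
        table = raw_table(
            [
                ("S01", "D1", "S-D", "votes", 1.0),
                ("S02", "D2", "S-D", "votes", 0.5),
            ]
        )
        std = pd.DataFrame(
            [("S01", "D1", 0.5), ("S02", "D2", 1.0)],
            columns=["source", "target", "factor"],
        )
        out = apply_standardization(table, std)
        assert out["raw_score"].tolist() == pytest.approx([1.0, 1.0])

    def test_identity_factors_leave_table_unchanged(self):
        table = raw_table(
            [
                ("AC01", "S01", "AC-S", "votes", 0.8),
                ("S01", "D1", "S-D", "votes", 1.0),
                ("S02", "D2", "S-D", "votes", 0.4),
            ]
        )
        std = pd.DataFrame(
            [("S01", "D1", 1.0), ("S02", "D2", 1.0)],
            columns=["source", "target", "factor"],
        )
        out = apply_standardization(table, std)
        pd.testing.assert_frame_equal(out, table)

    def test_empty_std_table_warns_and_is_identity(self, caplog):
        table = raw_table([("S01", "D1", "S-D", "votes", 0.7)])
        with caplog.at_level(logging.WARNING):
            out = apply_standardization(table, None)
        pd.testing.assert_frame_equal(out, table)
        assert "standardization" in caplog.text

    def test_missing_factor_defaults_to_one_with_warning(self, caplog):
        table = raw_table(
            [
                ("S01", "D1", "S-D", "votes", 1.0),
                ("S02", "D2", "S-D", "votes", 0.5),
            ]
        )
        std = pd.DataFrame([("S01", "D1", 1.0)], columns=["source", "target", "factor"])
        with caplog.at_level(logging.WARNING):
            out = apply_standardization(table, std)
        assert "factor 1 assumed" in caplog.text
        assert out["raw_score"].tolist() == pytest.approx([1.0, 0.5])


class TestConsolidate:
    def test_mean_across_sources(self):
        table = raw_table(
            [
                ("AC01", "S01", "AC-S", "votes", 1.0),
                ("AC01", "S01", "AC-S", "keywords", 0.4),
            ]
        )
        out = consolidate_sources(table)
        assert out["weight"].tolist() == pytest.approx([0.7])

    def test_single_source_passthrough_and_absent_links(self):
        table = raw_table([("AC01", "S01", "AC-S", "votes", 0.6)])
        out = consolidate_sources(table)
        assert len(out) == 1
        assert out.loc[0, "weight"] == pytest.approx(0.6)

    def test_inconsistent_link_typing_rejected(self):
        table = raw_table(
            [
                ("S01", "D1", "S-D", "votes", 0.6),
                ("S01", "D1", "AC-S", "keywords", 0.5),
            ]
        )
        with pytest.raises(ValueError, match="inconsistent link typing"):
            consolidate_sources(table)


class TestAssemble:
    def test_single_link_on_registry(self, registry):
        weights = pd.DataFrame(
            [("AC01", "S01", 1.0)], columns=["source", "target", "weight"]
        )
        net = assemble_community_network(registry, weights)
        assert net.n == 60 and net.L == 1

    def test_zero_weights_excluded(self, registry):
        weights = pd.DataFrame(
            [("AC01", "S01", 0.5), ("AC02", "S01", 0.0)],
            columns=["source", "target", "weight"],
        )
        assert assemble_community_network(registry, weights).L == 1

    def test_forbidden_link_rejected(self, registry):
        weights = pd.DataFrame(
            [("S01", "AC01", 0.5)], columns=["source", "target", "weight"]
        )
        with pytest.raises(NetworkValidationError, match="forbidden link"):
            assemble_community_network(registry, weights)

    def test_overweight_rejected(self, registry):
        weights = pd.DataFrame(
            [("AC01", "S01", 1.2)], columns=["source", "target", "weight"]
        )
        with pytest.raises(NetworkValidationError, match="weight out of range"):
            assemble_community_network(registry, weights)

    def test_empty_table_degenerate(self, registry, caplog):
        weights = pd.DataFrame(columns=["source", "target", "weight"])
        with caplog.at_level(logging.WARNING):
            net = assemble_community_network(registry, weights)
        assert net.is_degenerate


class TestSyntheticGenerator:
    def test_default_shape_and_mean_weight(self, synthetic_community):
        raw, net = synthetic_community
        assert net.L == 287 and net.n == 60
        weights = [l.weight for l in net.links]
        assert 0.65 <= np.mean(weights) <= 0.75
        assert set(raw["data_source"]) == {"workshop_votes", "keyword_counts"}

    def test_structural_constraints(self, synthetic_community):
        _, net = synthetic_community
        for d in net.layer_nodes("D"):
            assert net.link_weight(d.id, "HWBI") > 0
        used_s = {l.target for l in net.links if l.target.startswith("S")}
        for s in used_s:
            assert net.successors(s), f"service {s} has no outbound link"
            assert any(l.target == s for l in net.links), s

    def test_deterministic_under_seed(self):
        raw1, net1 = generate_synthetic_community(seed=5)
        raw2, net2 = generate_synthetic_community(seed=5)
        pd.testing.assert_frame_equal(raw1, raw2)
        assert net1 == net2

    def test_full_link_space(self):
        _, net = generate_synthetic_community(seed=2, n_links=822)
        assert net.L == 822

    def test_infeasible_requests_rejected(self):
        with pytest.raises(NetworkValidationError, match="cannot satisfy structure"):
            generate_synthetic_community(seed=0, n_links=9)
        with pytest.raises(NetworkValidationError, match="cannot satisfy structure"):
            generate_synthetic_community(seed=0, n_links=823)

    def test_pipeline_round_trip_exact(self, synthetic_community):
        """normalize -> consolidate -> assemble reproduces the fixture network."""
        raw, net = synthetic_community
        weights = consolidate_sources(normalize_scores(raw))
        rebuilt = assemble_community_network(default_node_registry(), weights)
        assert rebuilt.node_ids == net.node_ids
        assert len(rebuilt.links) == len(net.links)
        for link in net.links:
            assert rebuilt.link_weight(link.source, link.target) == pytest.approx(
                link.weight, abs=1e-9
            )

    def test_calibration_matches_community_scale(self):
        """A few seeds: C near 6.7 links/node and R in the plausible roles band."""
        for seed in range(8):
            _, net = generate_synthetic_community(seed=seed)
            r = index_report(net)
            assert 6.0 <= r.mean_connectivity <= 7.4
            assert 3.0 <= r.realized_roles <= 7.0
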