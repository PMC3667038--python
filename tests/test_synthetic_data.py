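import numpy as np
import pytest

from disorderscape.disorder_scoring import binarize_track
from disorderscape.io_formats import validate_domains
from disorderscape.network_stats import build_degrees, classify_connectivity
from disorderscape.segmentation_metrics import protein_metrics
from disorderscape.synthetic_data import (
    CohortSpec,
    generate_cohort,
    generate_network,
    inject_effect,
)


def cohort_contents(tracks):
    return [
        protein_metrics(binarize_track(t)).disorder_content for t in tracks.values()
    ]


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        spec = CohortSpec(families={"sRF": 5}, seed=3)
        r1, t1, a1 = generate_cohort(spec)
        r2, t2, a2 = generate_cohort(spec)
        assert [x.sequence for x in r1] == [x.sequence for x in r2]
        assert all(t1[k].scores == t2[k].scores for k in t1)
        assert a1 == a2

    def test_seed_changes_output(self):
        r1, _, _ = generate_cohort(CohortSpec(families={"sRF": 5}, seed=3))
        r2, _, _ = generate_cohort(CohortSpec(families={"sRF": 5}, seed=4))
        assert [x.sequence for x in r1] != [x.sequence for x in r2]

    def test_annotations_validate_and_fit(self):
        records, _, annotations = generate_cohort(CohortSpec(seed=1))
        validate_domains(annotations)
        lengths = {r.id: len(r) for r in records}
        for ann in annotations:
            assert 1 <= ann.start <= ann.end <= lengths[ann.protein_id]

    def test_tracks_match_sequence_lengths(self):
        records, tracks, _ = generate_cohort(CohortSpec(families={"HECT": 4}, seed=2))
        for r in records:
            assert len(tracks[r.id]) == len(r)
            assert all(0.0 <= s <= 1.0 for s in tracks[r.id].scores)

    def test_disorder_target_recovered(self):
        spec = CohortSpec(families={"sRF": 200}, target_disorder=0.20, seed=7)
        _, tracks, _ = generate_cohort(spec)
        mean = np.mean(cohort_contents(tracks))
        assert 18.0 <= mean <= 22.0

    def test_families_and_ids(self):
        records, _, _ = generate_cohort(
            CohortSpec(families={"sRF": 3, "HECT": 2}, seed=0)
        )
        fams = sorted(r.family for r in records)
        assert fams == ["HECT", "HECT", "sRF", "sRF", "sRF"]
        assert len({r.id for r in records}) == 5

    def test_infeasible_spec_is_error(self):
        spec = CohortSpec(
            families={"sRF": 1}, length_mean=120, length_sd=0, min_length=120,
            target_disorder=0.8, seed=0,
        )
        with pytest.raises(ValueError, match="infeasible"):
            generate_cohort(spec)

    def test_baseline_predictor_recovers_block_structure(self):
        """The generated sequences carry the ordered/disordered composition
        signal, so the built-in charge-hydropathy predictor separates the
        two block kinds on average."""
        from disorderscape.disorder_scoring import baseline_fold_score

        spec = CohortSpec(families={"sRF": 10}, target_disorder=0.4, seed=13)
        records, tracks, _ = generate_cohort(spec)
        dis_scores, ord_scores = [], []
        for r in records:
            predicted = baseline_fold_score(r.sequence)
            truth = binarize_track(tracks[r.id]).calls
            for s, is_dis in zip(predicted.scores, truth):
                (dis_scores if is_dis else ord_scores).append(s)
        # low-is-disordered orientation: disordered residues score lower
        assert np.mean(dis_scores) < np.mean(ord_scores)


class TestGenerateNetwork:
    def test_pinned_hub_classified(self):
        edges = generate_network(["A", "B", "C"], seed=1, pinned_degrees={"A": 30})
        deg = build_degrees(edges, ["A"])
        assert deg["A"] == 30
        assert classify_connectivity(deg["A"]).value == "HUB"

    def test_all_pinned_zero_gives_empty(self):
        ids = ["A", "B"]
        edges = generate_network(ids, seed=1, pinned_degrees={"A": 0, "B": 0})
        assert edges == []

    def test_confidences_in_configured_range(self):
        edges = generate_network(["A", "B"], seed=2, pinned_degrees={"A": 50, "B": 10})
        assert all(0.7 <= e.confidence <= 1.0 for e in edges)

    def test_heavy_tail_exponent(self):
        rng_ids = [f"P{i}" for i in range(500)]
        edges = generate_network(rng_ids, seed=4, powerlaw_exponent=2.5)
        deg = np.array(list(build_degrees(edges, rng_ids).values()))
        deg = deg[deg >= 1]
        # CCDF log-log slope should be near -(alpha - 1) = -1.5
        ks = np.unique(deg)
        ccdf = np.array([(deg >= k).mean() for k in ks])
        mask = ks <= np.quantile(deg, 0.99)
        slope = np.polyfit(np.log(ks[mask]), np.log(ccdf[mask]), 1)[0]
        assert -2.0 <= slope <= -1.0

    def test_too_few_ids_is_error(self):
        with pytest.raises(ValueError):
            generate_network(["A"], seed=0)


class TestInjectEffect:
    def test_zero_delta_is_identity(self):
        _, tracks, _ = generate_cohort(CohortSpec(families={"sRF": 4}, seed=5))
        out = inject_effect(tracks, list(tracks), 0.0, seed=1)
        assert all(out[k].scores == tracks[k].scores for k in tracks)

    def test_delta_raises_group_mean(self):
        _, tracks, _ = generate_cohort(CohortSpec(families={"sRF": 50}, seed=6))
        group = list(tracks)[:25]
        out = inject_effect(tracks, group, 10.0, seed=2)
        before = np.mean(
            [protein_metrics(binarize_track(tracks[p])).disorder_content for p in group]
        )
        after = np.mean(
            [protein_metrics(binarize_track(out[p])).disorder_content for p in group]
        )
        assert after - before == pytest.approx(10.0, abs=1.0)

    def test_non_group_tracks_untouched(self):
        _, tracks, _ = generate_cohort(CohortSpec(families={"sRF": 4}, seed=5))
        ids = list(tracks)
        out = inject_effect(tracks, ids[:2], 5.0, seed=1)
        for pid in ids[2:]:
            assert out[pid].scores == tracks[pid].scores

    def test_infeasible_delta_is_error(self):
        _, tracks, _ = generate_cohort(
            CohortSpec(families={"sRF": 2}, target_disorder=0.5, seed=8)
        )
        with pytest.raises(ValueError, match="headroom"):
            inject_effect(tracks, list(tracks), 90.0, seed=1)
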