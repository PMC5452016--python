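import dataclasses

import numpy as np
import pandas as pd
import pytest

from sirscan import (
    SimulationParams,
    classify_sir_positive,
    distance_table,
    score_orfs,
    simulate_expression,
    simulate_genome,
    simulate_tracks,
    sir_position_mask,
    truth_evaluation,
)
from sirscan.simulate import BACKGROUND, HYPERCHIP, NUCDEPLETED, SIR_DOMAIN, SimulationError


class TestSimulateGenome:
    def test_same_seed_reproduces_annotation_and_truth_exactly(self, small_params):
        ann1, truth1 = simulate_genome(small_params)
        ann2, truth2 = simulate_genome(small_params)
        assert [dataclasses.astuple(o) for o in ann1.orfs] == [
            dataclasses.astuple(o) for o in ann2.orfs
        ]
        assert ann1.orc_sites == ann2.orc_sites
        assert ann1.hm_loci == ann2.hm_loci
        pd.testing.assert_frame_equal(truth1.to_frame(), truth2.to_frame())

    def test_zero_offset_plants_a_site_over_an_orf_center(self, small_params):
        ann, truth = simulate_genome(small_params)
        zero_orfs = [oid for oid, d in truth.orc_offset_orfs.items() if d == 0]
        assert zero_orfs
        centers = {o.id: o.center for o in ann.orfs}
        for oid in zero_orfs:
            assert any(
                s.start <= centers[oid] < s.end for s in ann.orc_sites
            )

    def test_orf_count_and_bounds(self):
        params = SimulationParams(
            n_chromosomes=2, chromosome_length_bp=200_000, n_orfs=50,
            n_true_domains=4, n_hyperchip_decoys=2, n_nucdepleted_decoys=2,
            orc_offsets=(0, 100), seed=3,
        )
        ann, _ = simulate_genome(params)
        assert len(ann.orfs) == 50
        lengths = ann.chrom_lengths
        for orf in ann.orfs:
            assert 0 <= orf.start < orf.end <= lengths[orf.chromosome]

    def test_planted_regions_partition_the_orf_set(self, small_params):
        _, truth = simulate_genome(small_params)
        counts = {label: len(truth.orfs_with_label(label))
                  for label in (SIR_DOMAIN, HYPERCHIP, NUCDEPLETED, BACKGROUND)}
        assert counts[SIR_DOMAIN] == small_params.n_true_domains
        assert counts[HYPERCHIP] == small_params.n_hyperchip_decoys
        assert counts[NUCDEPLETED] == small_params.n_nucdepleted_decoys
        assert sum(counts.values()) == small_params.n_orfs

    def test_planted_regions_do_not_overlap(self, small_params):
        _, truth = simulate_genome(small_params)
        by_chrom = {}
        for _, region in truth.regions:
            by_chrom.setdefault(region.chromosome, []).append((region.start, region.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_invalid_parameters_rejected(self):
        with pytest.raises(SimulationError):
            SimulationParams(h4k16ac_fold=0.0)
        with pytest.raises(SimulationError):
            SimulationParams(n_orfs=5, n_true_domains=10)
        with pytest.raises(SimulationError):
            SimulationParams(n_true_domains=2, orc_offsets=(0, 1, 2))

    def test_infeasible_placement_is_fatal_with_advice(self):
        params = SimulationParams(
            n_chromosomes=1, chromosome_length_bp=20_000, n_orfs=30,
            orf_length_range=(900, 1000), n_true_domains=2,
            n_hyperchip_decoys=0, n_nucdepleted_decoys=0, orc_offsets=(0,),
            n_hm_loci=0, clear_of_ends_bp=9_000, seed=1,
        )
        with pytest.raises(SimulationError, match="place"):
            simulate_genome(params)


@pytest.fixture(scope="module")
def scenario():
    params = SimulationParams(seed=2)
    ann, truth = simulate_genome(params)
    tracks = simulate_tracks(ann, truth, params)
    return params, ann, truth, tracks


class TestSimulateTracks:
    def test_background_depth_matches_poisson_mean(self, scenario):
        params, ann, truth, tracks = scenario
        region_chroms = {r.chromosome for _, r in truth.regions}
        quiet = [c for c in ann.chrom_lengths if c not in region_chroms]
        chrom = quiet[0] if quiet else list(ann.chrom_lengths)[0]
        window = tracks["sir2_input"].data[chrom][:10_000]
        se = np.sqrt(params.background_depth / window.size)
        assert abs(window.mean() - params.background_depth) < 3 * se

    def _region_enrichment(self, scenario, label, factor):
        params, ann, truth, tracks = scenario
        ip = tracks[f"{factor}_ip"]
        inp = tracks[f"{factor}_input"]
        ips, inps = [], []
        for lab, region in truth.regions:
            if lab != label:
                continue
            ips.append(ip.data[region.chromosome][region.start:region.end])
            inps.append(inp.data[region.chromosome][region.start:region.end])
        ip_all, inp_all = np.concatenate(ips), np.concatenate(inps)
        return ip_all.mean() / inp_all.mean(), ip_all.size

    def test_sir2_fold_recovered_in_true_domains(self, scenario):
        params = scenario[0]
        ratio, n = self._region_enrichment(scenario, SIR_DOMAIN, "sir2")
        se = ratio * np.sqrt((1 / params.sir2_fold + 1) / (params.background_depth * n))
        assert abs(ratio - params.sir2_fold) < 3 * se

    def test_gfp_stays_flat_over_true_domains(self, scenario):
        params = scenario[0]
        ratio, n = self._region_enrichment(scenario, SIR_DOMAIN, "gfp")
        se = ratio * np.sqrt(2 / (params.background_depth * n))
        assert abs(ratio - params.gfp_fold) < 3 * se

    def test_same_seed_reproduces_tracks_exactly(self, scenario):
        params, ann, truth, tracks = scenario
        again = simulate_tracks(ann, truth, params)
        for name in tracks:
            for chrom in tracks[name].data:
                np.testing.assert_array_equal(
                    tracks[name].data[chrom], again[name].data[chrom]
                )


class TestTruthEvaluation:
    def _table(self, truth, positive_ids):
        ids = list(truth.orf_labels)
        return pd.DataFrame({"id": ids, "positive": [i in positive_ids for i in ids]})

    def test_perfect_labels(self, small_params):
        _, truth = simulate_genome(small_params)
        table = self._table(truth, set(truth.orfs_with_label(SIR_DOMAIN)))
        ev = truth_evaluation(table, truth)
        assert ev["sensitivity"] == 1.0
        assert ev["false_positive_hyperchip"] == 0
        assert ev["false_positive_nucdepleted"] == 0
        assert ev["false_positive_background"] == 0

    def test_all_negative_labels(self, small_params):
        _, truth = simulate_genome(small_params)
        ev = truth_evaluation(self._table(truth, set()), truth)
        assert ev["sensitivity"] == 0.0

    def test_id_mismatch_is_fatal(self, small_params):
        _, truth = simulate_genome(small_params)
        table = self._table(truth, set()).iloc[:-1]
        with pytest.raises(ValueError, match="mismatch"):
            truth_evaluation(table, truth)


def test_planted_positives_land_in_top_expression_quartile(small_params):
    ann, truth = simulate_genome(small_params)
    expr = simulate_expression(ann, truth, small_params)
    planted = set(truth.orfs_with_label(SIR_DOMAIN)) | set(truth.orfs_with_label(HYPERCHIP))
    threshold = np.percentile(expr.to_numpy(), 75)
    assert all(expr[oid] > threshold for oid in planted)


def test_truth_serialization_round_trips(tmp_path, small_params):
    _, truth = simulate_genome(small_params)
    p1, p2 = tmp_path / "t1.tsv", tmp_path / "t2.tsv"
    truth.write(p1)
    truth.write(p2)
    assert p1.read_bytes() == p2.read_bytes()
    back = pd.read_csv(p1, sep="\t", na_values=["NA"])
    assert dict(zip(back["orf_id"], back["label"])) == truth.orf_labels
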