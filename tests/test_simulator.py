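"""Combing/labelling simulator: fragmentation, stretch, labelling, determinism."""

import filecmp

import numpy as np
import pytest

from fluorocode.genome import ENZYMES, find_sites, synthetic_genome_with_sites
from fluorocode.simulate import (
    RISE_NM_PER_BP,
    CombingModel,
    FragmentationParams,
    FRAGMENTATION_PRESETS,
    LabellingParams,
    SimulationParams,
    default_fp_rate_per_bp,
    fragment_molecules,
    project_to_nm,
    simulate_dataset,
    stage_rng,
)
from fluorocode.align import nm_to_bp
from fluorocode.traces import (
    FALSE_POSITIVE,
    TRUE_SITE,
    read_ground_truth_tsv,
    read_traces_tsv,
    write_ground_truth_tsv,
    write_traces_tsv,
)


class TestFragmentation:
    def test_zero_rate_keeps_every_molecule_intact(self):
        frags = fragment_molecules(2686, FragmentationParams(0.0), 200, seed=1)
        assert all(f == [(0, 2686)] for f in frags)

    @pytest.mark.parametrize("mu", [0.5, 1.0, 1.609])
    def test_intact_fraction_matches_poisson_survival(self, mu):
        n = 10_000
        frags = fragment_molecules(2686, FragmentationParams(mu), n, seed=7)
        intact = sum(len(f) == 1 for f in frags) / n
        expected = np.exp(-mu)
        sd = np.sqrt(expected * (1 - expected) / n)
        assert abs(intact - expected) <= 3 * sd

    def test_tbta_preset_calibrated_to_20_percent_survival(self):
        frag = FRAGMENTATION_PRESETS["TBTA/40% DMSO"]
        n = 10_000
        frags = fragment_molecules(2686, frag, n, seed=3)
        intact = sum(len(f) == 1 for f in frags) / n
        assert abs(intact - 0.20) <= 3 * np.sqrt(0.20 * 0.80 / n)

    def test_fragments_partition_molecule(self):
        for frag_list in fragment_molecules(5000, FragmentationParams(3.0), 50, seed=5):
            bounds = [frag_list[0][0]] + [b for _, b in frag_list]
            assert bounds[0] == 0 and bounds[-1] == 5000
            assert all(a == b for (_, a), (b, _) in zip(frag_list, frag_list[1:]))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            FragmentationParams(-0.1)


class TestStretchProjection:
    def test_zero_maps_to_zero(self):
        assert project_to_nm(0, CombingModel(), 1.59) == 0.0

    def test_ten_kb_at_mean_stretch(self):
        assert project_to_nm(10_000, CombingModel(), 1.59) == pytest.approx(5406.0)

    def test_round_trip_with_nm_to_bp(self):
        combing = CombingModel()
        pos = np.array([0.0, 123.0, 9_999.0])
        nm = project_to_nm(pos, combing, 1.59)
        np.testing.assert_allclose(nm_to_bp(nm, 1 / 1.59), pos, rtol=1e-12)

    def test_stretch_draws_truncated_and_centred(self):
        combing = CombingModel()
        rng = stage_rng(0, "stretch-test")
        draws = np.array([combing.draw_stretch(rng) for _ in range(4000)])
        assert np.all(np.abs(draws - 1.59) <= 3 * 0.03 + 1e-12)
        assert abs(draws.mean() - 1.59) < 3 * 0.03 / np.sqrt(len(draws))


@pytest.fixture(scope="module")
def small_genome():
    return synthetic_genome_with_sites(8_000, ENZYMES["M.TaqI"], 30, seed=21, genome_id="g8k")


@pytest.fixture(scope="module")
def small_map(small_genome):
    return find_sites(small_genome, ENZYMES["M.TaqI"])


def noiseless_params(n_molecules=5, seed=0, length=(4_000, 6_000)):
    return SimulationParams(
        n_molecules=n_molecules,
        length_bp_range=length,
        combing=CombingModel(stretch_sd=0.0),
        labelling=LabellingParams(p_label=1.0, fp_rate_per_bp=0.0, sigma_loc_nm=0.0),
        seed=seed,
    )


class TestSimulateDataset:
    def test_noiseless_labels_invert_onto_sites(self, small_genome, small_map):
        traces = simulate_dataset(small_genome, small_map, noiseless_params())
        site_pos = np.array(small_map.positions())
        for t in traces:
            gt = t.ground_truth
            nm = t.positions_nm
            if gt.orientation == "reverse":
                nm = t.length_nm - nm
            bp = nm_to_bp(nm, 1 / 1.59) + gt.origin_start_bp
            expected = site_pos[[lab.site_index for lab in gt.labels]]
            np.testing.assert_allclose(np.sort(bp), np.sort(expected), atol=1e-6)

    def test_labelled_fraction_recovers_p_label(self, small_genome, small_map):
        # >= 1e4 covered sites in total across molecules
        params = SimulationParams(
            n_molecules=500,
            length_bp_range=(6_000, 7_900),
            labelling=LabellingParams(p_label=0.7, fp_rate_per_bp=0.0),
            seed=42,
        )
        traces = simulate_dataset(small_genome, small_map, params)
        site_pos = np.array(small_map.positions())
        n_labels = sum(t.n_labels for t in traces)
        n_covered = sum(
            int(
                np.sum(
                    (site_pos >= t.ground_truth.origin_start_bp)
                    & (site_pos < t.ground_truth.origin_end_bp)
                )
            )
            for t in traces
        )
        assert n_covered >= 10_000
        frac = n_labels / n_covered
        assert abs(frac - 0.7) <= 3 * np.sqrt(0.7 * 0.3 / n_covered)

    def test_fp_share_is_one_third_by_default(self, t7like_genome, taqi_map):
        params = SimulationParams(n_molecules=200, seed=9)
        traces = simulate_dataset(t7like_genome, taqi_map, params)
        classes = [lab.label_class for t in traces for lab in t.ground_truth.labels]
        share = classes.count(FALSE_POSITIVE) / len(classes)
        assert share == pytest.approx(1 / 3, abs=0.02)

    def test_fp_ablation_leaves_only_true_sites(self, small_genome, small_map):
        params = SimulationParams(
            n_molecules=50,
            length_bp_range=(4_000, 6_000),
            labelling=LabellingParams(p_label=0.7, fp_rate_per_bp=0.0),
            seed=2,
        )
        traces = simulate_dataset(small_genome, small_map, params)
        assert all(
            lab.label_class == TRUE_SITE and lab.site_index >= 0
            for t in traces
            for lab in t.ground_truth.labels
        )

    def test_measured_stretch_recovers_mean(self, small_genome, small_map):
        params = SimulationParams(
            n_molecules=400, length_bp_range=(4_000, 6_000), seed=17
        )
        traces = simulate_dataset(small_genome, small_map, params)
        ratios = np.array(
            [
                t.length_nm
                / ((t.ground_truth.origin_end_bp - t.ground_truth.origin_start_bp) * RISE_NM_PER_BP)
                for t in traces
            ]
        )
        sem = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 1.59) <= 3 * sem

    def test_mean_label_count_matches_expectation(self, t7like_genome, taqi_map):
        # 23-36 kb molecules on a 111-site 39.9 kb genome at p=0.7 carry
        # ~58 true labels on average, ~87 including false positives.
        params = SimulationParams(n_molecules=300, seed=23)
        traces = simulate_dataset(t7like_genome, taqi_map, params)
        true_counts = [
            sum(lab.label_class == TRUE_SITE for lab in t.ground_truth.labels)
            for t in traces
        ]
        mean_span = np.mean(
            [t.ground_truth.origin_end_bp - t.ground_truth.origin_start_bp for t in traces]
        )
        expected_true = 0.7 * 111 * mean_span / t7like_genome.length
        assert np.mean(true_counts) == pytest.approx(expected_true, rel=0.06)
        assert np.mean([t.n_labels for t in traces]) == pytest.approx(
            1.5 * expected_true, rel=0.06
        )

    def test_mismatched_sitemap_rejected(self, small_genome, taqi_map):
        with pytest.raises(ValueError, match="does not match genome"):
            simulate_dataset(small_genome, taqi_map, noiseless_params())

    def test_fixed_seed_reproduces_files_byte_for_byte(
        self, small_genome, small_map, tmp_path
    ):
        for d in ("a", "b"):
            traces = simulate_dataset(
                small_genome, small_map, SimulationParams(n_molecules=20, length_bp_range=(4_000, 6_000), seed=77)
            )
            (tmp_path / d).mkdir()
            write_traces_tsv(traces, tmp_path / d / "traces.tsv")
            write_ground_truth_tsv(traces, tmp_path / d / "gt.tsv")
        assert filecmp.cmp(tmp_path / "a" / "traces.tsv", tmp_path / "b" / "traces.tsv", shallow=False)
        assert filecmp.cmp(tmp_path / "a" / "gt.tsv", tmp_path / "b" / "gt.tsv", shallow=False)

    def test_fragmentation_driven_lengths(self, small_genome, small_map):
        params = SimulationParams(
            n_molecules=100,
            length_mode="fragmentation",
            fragmentation=FragmentationParams(2.0),
            seed=5,
        )
        traces = simulate_dataset(small_genome, small_map, params)
        for t in traces:
            gt = t.ground_truth
            assert 0 <= gt.origin_start_bp < gt.origin_end_bp <= small_genome.length


class TestTraceTsvRoundTrip:
    def test_round_trip(self, small_genome, small_map, tmp_path):
        traces = simulate_dataset(
            small_genome, small_map, SimulationParams(n_molecules=8, length_bp_range=(4_000, 6_000), seed=3)
        )
        p = tmp_path / "traces.tsv"
        write_traces_tsv(traces, p)
        back = read_traces_tsv(p)
        assert [t.molecule_id for t in back] == [t.molecule_id for t in traces]
        for a, b in zip(traces, back):
            np.testing.assert_allclose(a.positions_nm, b.positions_nm, atol=1e-4)
            assert b.length_nm == pytest.approx(a.length_nm, abs=1e-4)

    def test_ground_truth_round_trip(self, small_genome, small_map, tmp_path):
        traces = simulate_dataset(
            small_genome, small_map, SimulationParams(n_molecules=8, length_bp_range=(4_000, 6_000), seed=3)
        )
        p = tmp_path / "gt.tsv"
        write_ground_truth_tsv(traces, p)
        back = read_ground_truth_tsv(p)
        for t in traces:
            gt = back[t.molecule_id]
            assert gt.orientation == t.ground_truth.orientation
            assert gt.labels == t.ground_truth.labels


def test_default_fp_rate_yields_half_the_true_rate(taqi_map):
    rate = default_fp_rate_per_bp(taqi_map, 0.7)
    assert rate == pytest.approx(0.5 * 0.7 * 111 / taqi_map.genome_length)
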