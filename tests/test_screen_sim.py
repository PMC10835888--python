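import numpy as np
import pandas as pd
import pytest

from tilescan import (
    ScreenSimConfig,
    frequencies,
    quantify,
    simulate_counts,
    simulate_fastq,
    simulate_library,
)
from tilescan.read_quant import extract_protospacers
from tilescan.screen_sim import sample_pairs


class TestSimulateLibrary:
    def test_default_composition_matches_study_design(self):
        lib = simulate_library(ScreenSimConfig(seed=5))
        assert lib.category_counts() == {
            "tiling": 229, "negative_control": 40, "killing_control": 22,
        }
        assert lib.cds_length_nt == 1686

    def test_tiling_positions_distinct_ordered_in_range(self):
        cfg = ScreenSimConfig(cds_length_nt=300, n_tiling=40, n_neg=4, n_kill=4, seed=1)
        pos = [r.cut_pos_nt for r in simulate_library(cfg).tiling_records()]
        assert len(set(pos)) == 40
        assert pos == sorted(pos)
        assert 0 <= min(pos) and max(pos) < 300

    def test_protospacers_distinct(self):
        lib = simulate_library(ScreenSimConfig(seed=2))
        protos = [r.protospacer for r in lib.records]
        assert len(set(protos)) == len(protos)

    def test_same_seed_reproduces_library(self):
        a = simulate_library(ScreenSimConfig(seed=9))
        b = simulate_library(ScreenSimConfig(seed=9))
        assert a.to_frame().equals(b.to_frame())

    def test_too_many_guides_for_cds_rejected(self):
        with pytest.raises(ValueError, match="n_tiling"):
            simulate_library(ScreenSimConfig(cds_length_nt=30, n_tiling=60, n_neg=1, n_kill=1))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(cds_length_nt=301),
            dict(depth=0),
            dict(planted_regions=[(0, 5, -1.0)]),
            dict(planted_regions=[(1, 600, -1.0)]),
            dict(planted_regions=[(10, 12, 0.5)]),
            dict(read_length=20),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScreenSimConfig(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        cfg = ScreenSimConfig(planted_regions=[(90, 94, -1.0)], seed=7)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert ScreenSimConfig.from_yaml(path) == cfg


class TestSimulateCounts:
    def test_same_seed_reproduces_counts(self, small_sim_config):
        lib = simulate_library(small_sim_config)
        a = simulate_counts(lib, small_sim_config)
        b = simulate_counts(lib, small_sim_config)
        assert a.equals(b)

    def test_columns_one_pair_per_replicate(self, small_screen):
        _, counts, cfg = small_screen
        pairs = sample_pairs(counts)
        assert len(pairs) == cfg.n_replicates
        assert all(d0.endswith("day0") and d30.endswith("day30") for d0, d30 in pairs)

    def test_null_screen_tiling_scores_center_on_zero(self):
        """Without planted effects, mean raw CS of tiling guides ~ 0."""
        from tilescan import combine_replicates, crispr_score, default_pseudofreq

        means = []
        for seed in range(20):
            cfg = ScreenSimConfig(
                cds_length_nt=300, n_tiling=40, n_neg=8, n_kill=6,
                depth=200_000, seed=seed,
            )
            lib = simulate_library(cfg)
            counts = simulate_counts(lib, cfg)
            freqs = frequencies(counts)
            pf = default_pseudofreq(counts)
            tracks = [crispr_score(freqs[a], freqs[b], pf) for a, b in sample_pairs(counts)]
            combined, _ = combine_replicates(tracks)
            tiling_ids = [r.guide_id for r in lib.tiling_records()]
            means.append(combined.loc[tiling_ids].mean())
        assert abs(np.mean(means)) < 0.05

    def test_killing_controls_drop_by_their_planted_effect(self):
        """Mean raw CS of killing controls ~ kill_effect at deep coverage."""
        from tilescan import combine_replicates, crispr_score, default_pseudofreq

        cfg = ScreenSimConfig(depth=1_000_000, seed=3)
        lib = simulate_library(cfg)
        counts = simulate_counts(lib, cfg)
        freqs = frequencies(counts)
        pf = default_pseudofreq(counts)
        tracks = [crispr_score(freqs[a], freqs[b], pf) for a, b in sample_pairs(counts)]
        combined, _ = combine_replicates(tracks)
        kill_ids = [r.guide_id for r in lib.records if r.category == "killing_control"]
        assert combined.loc[kill_ids].mean() == pytest.approx(-1.0, abs=0.1)

    def test_planted_region_guides_depleted_others_not(self):
        cfg = ScreenSimConfig(planted_regions=[(30, 40, -1.0)],
                              cds_length_nt=300, n_tiling=40, n_neg=8, n_kill=6,
                              depth=500_000, seed=4)
        lib = simulate_library(cfg)
        counts = simulate_counts(lib, cfg)
        day0, day30 = counts["clone1_day0"], counts["clone1_day30"]
        ratio = (day30 + 1) / (day0 + 1)
        in_ids = [r.guide_id for r in lib.tiling_records() if 87 <= r.cut_pos_nt < 120]
        out_ids = [r.guide_id for r in lib.tiling_records() if r.cut_pos_nt < 60]
        assert ratio.loc[in_ids].mean() < 0.25
        assert ratio.loc[out_ids].mean() > 0.7


class TestSimulateFastq:
    def test_counts_round_trip_exactly(self, tmp_path, small_screen):
        lib, counts, cfg = small_screen
        paths = simulate_fastq(counts, lib, cfg, tmp_path)
        for sample, path in paths.items():
            col = quantify(extract_protospacers(path), lib)
            assert col.equals(counts[sample].rename("count"))

    def test_each_protospacer_emitted_count_times(self, tmp_path, tiny_library):
        counts = pd.DataFrame(
            {"s": [3, 0, 1, 2, 0]}, index=[r.guide_id for r in tiny_library.records]
        )
        cfg = ScreenSimConfig(cds_length_nt=300, n_tiling=3, n_neg=1, n_kill=1,
                              read_length=40, seed=0)
        (path,) = simulate_fastq(counts, tiny_library, cfg, tmp_path).values()
        text = path.read_text()
        assert text.count("\n") == 4 * counts["s"].sum()
        for rec, n in zip(tiny_library.records, counts["s"]):
            assert text.count("CACCG" + rec.protospacer + "GTTT") == n

    def test_empty_counts_give_empty_fastq(self, tmp_path, tiny_library):
        counts = pd.DataFrame({"s": [0] * 5}, index=[r.guide_id for r in tiny_library.records])
        cfg = ScreenSimConfig(cds_length_nt=300, n_tiling=3, n_neg=1, n_kill=1, seed=0)
        (path,) = simulate_fastq(counts, tiny_library, cfg, tmp_path).values()
        assert path.read_text() == ""

    def test_same_seed_reproduces_fastq_bytes(self, tmp_path, small_screen):
        lib, counts, cfg = small_screen
        p1 = simulate_fastq(counts, lib, cfg, tmp_path / "a")
        p2 = simulate_fastq(counts, lib, cfg, tmp_path / "b")
        for s in counts.columns:
            assert p1[s].read_bytes() == p2[s].read_bytes()
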