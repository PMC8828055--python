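import numpy as np
import pandas as pd
import pytest

import methpath as mp
from methpath.coverage import bin_reads, chip_log2_ratio, mean_track_over_features, srna_rpkm
from methpath.profiles import dyad_profile
from methpath.simulate import TEClassConfig, build_genome, default_config, load_config


@pytest.fixture(scope="module")
def small_cfg():
    """A scaled-down genome so per-test simulations stay fast."""
    cfg = default_config()
    cfg.genome_length = 400_000
    cfg.te_classes = {
        "CMT": TEClassConfig(25, (1500, 3000), 0.44),
        "DRM": TEClassConfig(25, (300, 800), 0.36),
        "intermediate": TEClassConfig(10, (500, 1500), 0.40),
    }
    cfg.srna_depth = 40_000
    cfg.chip_depth = 60_000
    return cfg


@pytest.fixture(scope="module")
def small_world(small_cfg):
    genome, tes, dyads, truth = build_genome(small_cfg, 5)
    return small_cfg, genome, tes, dyads, truth


class TestBuildGenome:
    def test_same_seed_byte_identical(self, small_cfg):
        g1, t1, d1, _ = build_genome(small_cfg, 7)
        g2, t2, d2, _ = build_genome(small_cfg, 7)
        assert g1["chr1"] == g2["chr1"]
        assert [(f.start, f.end, f.id) for f in t1] == [(f.start, f.end, f.id) for f in t2]
        assert [d.start for d in d1["wt"]] == [d.start for d in d2["wt"]]

    def test_class_gc_gap(self, small_world):
        cfg, genome, tes, dyads, truth = small_world
        mean_gc = truth.te_gc.groupby(truth.te_class).mean()
        gap = cfg.te_classes["CMT"].gc_mean - cfg.te_classes["DRM"].gc_mean
        assert abs((mean_gc["CMT"] - mean_gc["DRM"]) - gap) < 0.02

    def test_tes_do_not_overlap(self, small_world):
        _, _, tes, _, _ = small_world
        spans = sorted((f.start, f.end) for f in tes)
        assert all(a_end <= b_start for (_, a_end), (b_start, _) in zip(spans, spans[1:]))

    def test_dyad_spacing_matches_configured_nrl(self, small_world):
        cfg, _, tes, dyads, _ = small_world
        gaps = []
        by_te = {}
        for d in dyads["wt"]:
            by_te.setdefault(d.id.rsplit("_dyad_", 1)[0], []).append(d.start)
        for pos in by_te.values():
            gaps.extend(np.diff(sorted(pos)))
        assert len(gaps) >= 300
        assert abs(np.mean(gaps) - cfg.nrl["wt"]) < 2

    def test_impossible_placement_raises(self, small_cfg):
        import copy

        cfg = copy.deepcopy(small_cfg)
        cfg.genome_length = 10_000
        with pytest.raises(ValueError, match="increase genome_length"):
            build_genome(cfg, 1)


class TestMethylome:
    def test_unmethylated_context_shows_error_floor(self, small_world):
        cfg, genome, tes, _, truth = small_world
        rec = mp.simulate_methylome(genome, tes, cfg, "cmt2", 5)
        cmt_ids = truth.te_class[truth.te_class == "CMT"].index
        cmt_tes = [f for f in tes if f.id in set(cmt_ids)]
        mask = np.zeros(len(rec), dtype=bool)
        pos = rec["pos"].to_numpy()
        for f in cmt_tes:
            mask |= (pos >= f.start) & (pos < f.end)
        chh = rec[mask & (rec["context"] == "CHH").to_numpy()]
        level = chh["count_meth"].sum() / (chh["count_meth"].sum() + chh["count_unmeth"].sum())
        n_reads = (chh["count_meth"] + chh["count_unmeth"]).sum()
        se = np.sqrt(0.005 * 0.995 / n_reads)
        assert abs(level - cfg.error_rate) < 3 * se

    def test_configured_level_recovered(self, small_world):
        cfg, genome, tes, _, truth = small_world
        rec = mp.simulate_methylome(genome, tes, cfg, "wt", 5)
        cmt = [f for f in tes if f.feature_class == "CMT"]
        from methpath.methylation import summarize_features_methylation

        summ = summarize_features_methylation(cmt, rec)
        levels = [summ[f.id].levels["CG"] for f in cmt]
        assert abs(np.nanmean(levels) - cfg.methylation["wt"]["CMT"]["CG"]) < 0.02

    def test_unknown_genotype_lists_available(self, small_world):
        cfg, genome, tes, _, _ = small_world
        with pytest.raises(KeyError, match="available"):
            mp.simulate_methylome(genome, tes, cfg, "nonesuch", 5)

    def test_determinism(self, small_world):
        cfg, genome, tes, _, _ = small_world
        a = mp.simulate_methylome(genome, tes, cfg, "wt", 9)
        b = mp.simulate_methylome(genome, tes, cfg, "wt", 9)
        pd.testing.assert_frame_equal(a, b)


class TestSrna:
    def test_relocation_reverses_class_ranking(self, small_world):
        cfg, genome, tes, dyads, _ = small_world
        rpkm = {}
        for g, dy in (("wt", "wt"), ("h1", "h1")):
            reads = mp.simulate_srna(genome, tes, dyads[dy], cfg, g, 5)
            rpkm[g] = srna_rpkm(reads, tes, 24)
        cls = pd.Series({f.id: f.feature_class for f in tes})
        wt_cmt = rpkm["wt"][cls == "CMT"].mean()
        wt_drm = rpkm["wt"][cls == "DRM"].mean()
        h1_cmt = rpkm["h1"][cls == "CMT"].mean()
        h1_drm = rpkm["h1"][cls == "DRM"].mean()
        assert wt_drm > wt_cmt
        assert h1_cmt > h1_drm

    def test_no_linker_bias_gives_flat_dyad_profile(self, small_world):
        cfg, genome, tes, dyads, _ = small_world
        import copy

        flat_cfg = copy.deepcopy(cfg)
        flat_cfg.linker_multiplier = 1.0
        reads = mp.simulate_srna(genome, tes, dyads["wt"], flat_cfg, "wt", 5)
        # anchor only at dyads with the full window inside a long (CMT) TE,
        # so the profile is not shaped by TE-edge falloff or class mixtures
        bounds = {f.id: (f.start, f.end) for f in tes if f.feature_class == "CMT"}
        inner_dyads = []
        for d in dyads["wt"]:
            te = d.id.rsplit("_dyad_", 1)[0]
            if te in bounds:
                s, e = bounds[te]
                if d.start - 500 >= s and d.start + 500 <= e:
                    inner_dyads.append(d)
        assert len(inner_dyads) > 100
        _, mean = dyad_profile(reads, inner_dyads, window_bp=500, bin_bp=10)
        assert mean.std() / mean.mean() < 0.25

    def test_background_21nt_fraction(self, small_world):
        cfg, genome, tes, dyads, _ = small_world
        reads = mp.simulate_srna(genome, tes, dyads["wt"], cfg, "wt", 5)
        n21 = len(reads.select_length(21))
        n24 = len(reads.select_length(24))
        assert n21 / n24 == pytest.approx(cfg.background_21nt_fraction, rel=0.05)

    def test_determinism(self, small_world):
        cfg, genome, tes, dyads, _ = small_world
        a = mp.simulate_srna(genome, tes, dyads["wt"], cfg, "wt", 3)
        b = mp.simulate_srna(genome, tes, dyads["wt"], cfg, "wt", 3)
        assert np.array_equal(a.start, b.start) and np.array_equal(a.strand, b.strand)


class TestChip:
    def test_configured_ratio_recovered_in_log2(self, small_world):
        cfg, genome, tes, _, truth = small_world
        import copy

        cfg4 = copy.deepcopy(cfg)
        cfg4.chip_sigma = 0.0
        cfg4.chip_enrichment["H3K9me2"] = {"CMT": 4.0, "DRM": 1.0, "intermediate": 1.0}
        chip, inp = mp.simulate_chip(genome, tes, cfg4, "H3K9me2", "wt", 5)
        sizes = genome.lengths()
        track = chip_log2_ratio(
            bin_reads(chip, sizes, 200), bin_reads(inp, sizes, 200),
            input_fraction=1.0, seed=5,
        )
        per_te = mean_track_over_features(track, tes)
        cls = pd.Series({f.id: f.feature_class for f in tes})
        cmt_mean = per_te[cls == "CMT"].mean()
        # genome-wide scaling compresses the ratio: 4x at CMT over a baseline
        # lifted by the enriched fraction of the genome
        assert 1.0 < cmt_mean < 2.2
        drm_mean = per_te[cls == "DRM"].mean()
        assert cmt_mean - drm_mean == pytest.approx(2.0, abs=0.3)

    def test_unknown_mark_rejected(self, small_world):
        cfg, genome, tes, _, _ = small_world
        with pytest.raises(ValueError, match="unknown mark"):
            mp.simulate_chip(genome, tes, cfg, "H3K27me3", "wt", 1)

    def test_h1_mark_follows_gc(self, small_world):
        cfg, genome, tes, _, truth = small_world
        chip, inp = mp.simulate_chip(genome, tes, cfg, "H1", "wt", 5)
        sizes = genome.lengths()
        track = chip_log2_ratio(
            bin_reads(chip, sizes, 200), bin_reads(inp, sizes, 200),
            input_fraction=1.0, seed=5,
        )
        per_te = mean_track_over_features(track, tes)
        cls = pd.Series({f.id: f.feature_class for f in tes})
        assert per_te[cls == "CMT"].mean() > per_te[cls == "DRM"].mean()

    def test_determinism(self, small_world):
        cfg, genome, tes, _, _ = small_world
        a = mp.simulate_chip(genome, tes, cfg, "H1", "wt", 2)
        b = mp.simulate_chip(genome, tes, cfg, "H1", "wt", 2)
        assert np.array_equal(a[0].start, b[0].start)
        assert np.array_equal(a[1].start, b[1].start)


class TestConfigIO:
    def test_default_toml_round_trips(self):
        from importlib import resources

        with resources.as_file(
            resources.files("methpath") / "data" / "default_sim.toml"
        ) as p:
            cfg = load_config(p)
        ref = default_config()
        assert cfg.nrl == ref.nrl
        assert cfg.srna_rate["wt"] == ref.srna_rate["wt"]
        assert cfg.methylation["cmt2"]["CMT"]["CHH"] == 0.0
        assert cfg.te_classes["CMT"].n == ref.te_classes["CMT"].n

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "bad.toml"
        p.write_text("nonsense = 1\n")
        with pytest.raises(KeyError):
            load_config(p)
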