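"""Density quantification: window sums, noiseless recovery, fold changes."""

import numpy as np
import pytest

from pauseflux import steady_state
from pauseflux.quantify import (
    compare_conditions,
    composite_profile,
    summarize,
    window_density,
)
from pauseflux.synthetic import (
    SignalTrack,
    SyntheticConfig,
    build_expected_tracks,
    generate_dataset,
    generate_genes,
)


def noiseless_tracks(config):
    """Expected (mean) tracks as SignalTracks, bypassing Poisson sampling."""
    genes, params = generate_genes(config)
    expected = build_expected_tracks(genes, params, config)
    tracks = {s: SignalTrack(chrom=config.chrom, counts=v) for s, v in expected.items()}
    return genes, params, tracks


@pytest.fixture
def flat_config(example_params):
    return SyntheticConfig(n_genes=8, seed=5, reference=example_params, rate_sigma=0.0)


class TestWindowDensity:
    def test_counts_per_bp_arithmetic(self):
        track = SignalTrack(chrom="chrS", counts=np.full(200, 3))
        assert window_density(track, (0, 100)) == 3.0
        assert window_density(track, (0, 100), scale=2.0) == 1.5

    def test_empty_window_is_zero(self):
        track = SignalTrack(chrom="chrS", counts=np.zeros(100, dtype=int))
        assert window_density(track, (10, 60)) == 0.0

    def test_out_of_bounds_window_rejected(self):
        track = SignalTrack(chrom="chrS", counts=np.zeros(100, dtype=int))
        with pytest.raises(ValueError):
            window_density(track, (50, 150))


class TestSummarize:
    def test_noiseless_expectation_recovers_steady_state_densities(self, flat_config, example_params):
        """On expected tracks at D=100 the raw pause density is 100*p_ss and
        the body density 100*b_ss; the pause index is exactly P_i."""
        genes, _, tracks = noiseless_tracks(flat_config)
        ss = steady_state(example_params)
        df = summarize(tracks, genes, scale="none")
        np.testing.assert_allclose(df["pause_density"], 100 * ss.p_ss)
        np.testing.assert_allclose(df["body_density"], 100 * ss.b_ss)
        np.testing.assert_allclose(df["pause_index"], ss.pause_index, rtol=1e-12)

    def test_identical_tracks_give_identical_summaries(self, flat_config):
        genes, _, tracks = noiseless_tracks(flat_config)
        a = summarize(tracks, genes, condition="A")
        b = summarize(tracks, genes, condition="B")
        np.testing.assert_array_equal(a["pause_density"], b["pause_density"])
        np.testing.assert_array_equal(a["body_density"], b["body_density"])

    def test_missing_strand_track_rejected(self, flat_config):
        genes, _, tracks = noiseless_tracks(flat_config)
        with pytest.raises(ValueError, match="strand"):
            summarize({"+": tracks["+"]}, genes)

    def test_target_genes_track_initiation_increase(self, example_params):
        """+25% k_init at target genes raises both densities ~25% and leaves
        the pause index unchanged, within Poisson noise."""
        cfg = SyntheticConfig(
            n_genes=40,
            seed=9,
            reference=example_params,
            rate_sigma=0.0,
            perturb_parameter="k_init",
            perturb_fold=1.25,
            fraction_targets=0.5,
        )
        ds = generate_dataset(cfg)
        a = summarize(ds.tracks["A"], ds.genes, "A", scale="none")
        b = summarize(ds.tracks["B"], ds.genes, "B", scale="none")
        fc = compare_conditions(a, b)
        t = fc["is_target"]
        assert t.sum() >= 10
        # per-gene log2 pause FC has SD ~ sqrt(2/10000)/ln2 ~ 0.02 at this depth
        assert fc.loc[t, "lfc_pause"].mean() == pytest.approx(np.log2(1.25), abs=0.02)
        assert fc.loc[t, "lfc_body"].mean() == pytest.approx(np.log2(1.25), abs=0.03)
        dpi = fc.loc[t, "delta_pause_index"]
        assert abs(dpi.mean()) < 3 * dpi.std() / np.sqrt(t.sum())


class TestCompositeProfile:
    def test_single_gene_profile_is_its_own_track_segment(self, flat_config):
        genes, _, tracks = noiseless_tracks(flat_config)
        g = genes[0]
        df = composite_profile(tracks, [g], span=(-200, 1000), scale="none")
        seg = tracks[g.strand].counts[g.tss - 200 : g.tss + 1000]
        np.testing.assert_allclose(df["density"], seg)
        assert df["position"].iloc[0] == -200

    def test_averaging_identical_genes_reproduces_single_gene_profile(self, flat_config):
        genes, _, tracks = noiseless_tracks(flat_config)
        one = composite_profile(tracks, genes[:1], span=(-100, 500), scale="none")
        # rate_sigma=0: every gene is statistically identical in expectation
        all_ = composite_profile(tracks, genes, span=(-100, 500), scale="none")
        np.testing.assert_allclose(all_["density"], one["density"])

    def test_minus_strand_genes_are_flipped_downstream_positive(self, flat_config):
        genes, _, tracks = noiseless_tracks(flat_config)
        minus = [g for g in genes if g.strand == "-"]
        df = composite_profile(tracks, minus, span=(0, 100), scale="none")
        # downstream of the TSS is the pause window: density 100*p_ss
        np.testing.assert_allclose(df["density"], 100.0)

    def test_empty_gene_set_rejected(self, flat_config):
        _, _, tracks = noiseless_tracks(flat_config)
        with pytest.raises(ValueError):
            composite_profile(tracks, [], span=(0, 10))

    def test_waveform_composite_matches_rendered_curve_in_expectation(self, example_params):
        from pauseflux import make_waveform, waveform_density

        cfg = SyntheticConfig(
            n_genes=4, seed=2, reference=example_params, rate_sigma=0.0, profile_mode="waveform"
        )
        genes, _, tracks = noiseless_tracks(cfg)
        df = composite_profile(tracks, genes, span=(0, 2000), scale="none")
        ss = steady_state(example_params)
        wf = make_waveform(ss.p_ss, ss.b_ss, tau=cfg.waveform_tau)
        expected = 100 * waveform_density(np.arange(0.0, 2000.0), wf)
        np.testing.assert_allclose(df["density"], expected, rtol=1e-9)


class TestCompareConditions:
    def test_identical_conditions_give_zero_records(self, flat_config):
        genes, _, tracks = noiseless_tracks(flat_config)
        a = summarize(tracks, genes, "A")
        fc = compare_conditions(a, summarize(tracks, genes, "B"))
        np.testing.assert_allclose(fc["lfc_pause"], 0.0)
        np.testing.assert_allclose(fc["lfc_body"], 0.0)
        np.testing.assert_allclose(fc["delta_pause_index"], 0.0)

    def test_noiseless_initiation_increase_has_exact_fold_change(self, example_params):
        cfg = SyntheticConfig(
            n_genes=2,
            seed=0,
            reference=example_params,
            rate_sigma=0.0,
            perturb_parameter="k_init",
            perturb_fold=1.25,
            fraction_targets=1.0,  # every gene a target
        )
        genes, params_a, tracks_a = noiseless_tracks(cfg)
        # build the noiseless B condition explicitly
        params_b = {k: v.perturb("k_init", 1.25) for k, v in params_a.items()}
        expected_b = build_expected_tracks(genes, params_b, cfg)
        tracks_b = {s: SignalTrack(chrom="chrS", counts=v) for s, v in expected_b.items()}
        fc = compare_conditions(
            summarize(tracks_a, genes, "A", scale="none"),
            summarize(tracks_b, genes, "B", scale="none"),
            pseudocount=0.0,
        )
        np.testing.assert_allclose(fc["lfc_pause"], np.log2(1.25), rtol=1e-12)
        np.testing.assert_allclose(fc["lfc_body"], np.log2(1.25), rtol=1e-12)
        np.testing.assert_allclose(fc["delta_pause_index"], 0.0, atol=1e-12)

    def test_swapping_conditions_negates_every_record(self, example_params):
        cfg = SyntheticConfig(n_genes=10, seed=21, reference=example_params)
        ds = generate_dataset(cfg)
        a = summarize(ds.tracks["A"], ds.genes, "A")
        b = summarize(ds.tracks["B"], ds.genes, "B")
        fc = compare_conditions(a, b)
        rev = compare_conditions(b, a)
        np.testing.assert_allclose(rev["lfc_pause"], -fc["lfc_pause"], atol=1e-12)
        np.testing.assert_allclose(rev["lfc_body"], -fc["lfc_body"], atol=1e-12)
        np.testing.assert_allclose(rev["delta_pause_index"], -fc["delta_pause_index"], atol=1e-12)

    def test_mismatched_gene_sets_rejected(self, flat_config):
        genes, _, tracks = noiseless_tracks(flat_config)
        a = summarize(tracks, genes, "A")
        with pytest.raises(ValueError):
            compare_conditions(a, summarize(tracks, genes[:-1], "B"))
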