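"""Ground-truth generator: kinetics, measurement model, UTR construction."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_truth_row, run_pipeline
from tudecay import fitting, motifs, normalize, simulate
from tudecay.errors import ConfigError, GenerationError

LN2 = np.log(2.0)


class TestSampleTrueKinetics:
    def test_degenerate_distribution_gives_identical_halflives(self):
        cfg = simulate.SimConfig(
            n_genes=50,
            seed=0,
            class_fractions={"neural_fate": 1.0, "localized": 0.0, "background": 0.0},
            halflife_params={
                "neural": {"neural_fate": (55.0, 0.0), "localized": (120.0, 0.0), "background": (75.0, 0.0)},
                "nonneural": {"neural_fate": (75.0, 0.0), "localized": (75.0, 0.0), "background": (75.0, 0.0)},
            },
        )
        truth = simulate.sample_true_kinetics(cfg)
        assert (truth["gene_class"] == "neural_fate").all()
        assert np.allclose(truth["true_halflife_neural"], 55.0)

    def test_median_neural_halflife_matches_configured_log_median(self):
        cfg = simulate.SimConfig(n_genes=5000, seed=1)
        truth = simulate.sample_true_kinetics(cfg)
        bg = truth.loc[truth["gene_class"] == "background", "true_halflife_neural"]
        assert abs(bg.median() / 75.0 - 1) < 0.10

    def test_pre_fraction_binomial(self):
        cfg = simulate.SimConfig(n_genes=10000, seed=3)
        truth = simulate.sample_true_kinetics(cfg)
        bg = truth.loc[truth["gene_class"] == "background"]
        p = 0.085
        frac = (bg["pre_count"] >= 1).mean()
        sd = np.sqrt(p * (1 - p) / len(bg))
        assert abs(frac - p) <= 3 * sd

    def test_halflife_k_identity_and_pre_invariant(self):
        truth = simulate.sample_true_kinetics(simulate.SimConfig(n_genes=500, seed=2))
        assert np.allclose(truth["true_halflife_neural"], LN2 / truth["k_neural"], rtol=0, atol=0)
        assert (truth["pre_count"] >= 0).all()

    def test_nonpositive_params_rejected(self):
        cfg = simulate.SimConfig(n_genes=10)
        cfg.halflife_params["neural"]["background"] = (-5.0, 0.3)
        with pytest.raises(ConfigError):
            simulate.sample_true_kinetics(cfg)

    def test_identical_seed_reproduces(self):
        a = simulate.sample_true_kinetics(simulate.SimConfig(n_genes=200, seed=9))
        b = simulate.sample_true_kinetics(simulate.SimConfig(n_genes=200, seed=9))
        pd.testing.assert_frame_equal(a, b)


class TestSimulateLabeledSignal:
    def test_exact_exponential_algebra(self):
        # k = ln2/60, s/k = 1, tau = 60 -> L0 = 0.5; L(60)/L0 = 0.5; L(180)/L0 = 0.125
        cfg = simulate.SimConfig(n_genes=1, noise_sd=0.0, recycling_fraction=0.0)
        truth = make_truth_row(k=LN2 / 60)
        mat = simulate.simulate_labeled_signal(truth, cfg, "neural", "control")
        one_rep = mat.data[mat.data["replicate"] == 1].set_index("timepoint_min")["intensity"]
        assert one_rep[0.0] == pytest.approx(0.5, rel=1e-12)
        assert one_rep[60.0] / one_rep[0.0] == pytest.approx(0.5, rel=1e-12)
        assert one_rep[180.0] / one_rep[0.0] == pytest.approx(0.125, rel=1e-12)

    def test_whole_embryo_equals_neural_for_identical_pools(self):
        cfg = simulate.SimConfig(n_genes=40, seed=4, recycling_fraction=0.0)
        truth = simulate.sample_true_kinetics(cfg)
        truth["k_nonneural"] = truth["k_neural"]
        neural = simulate.simulate_labeled_signal(truth, cfg, "neural", "control")
        whole = simulate.simulate_labeled_signal(truth, cfg, "whole_embryo", "control")
        np.testing.assert_allclose(
            whole.data["intensity"], neural.data["intensity"], rtol=1e-12
        )

    def test_recycling_inflates_fitted_halflife(self):
        cfg = simulate.SimConfig(n_genes=1, recycling_fraction=0.1)
        truth = make_truth_row(k=LN2 / 60)
        ratio_set = run_pipeline(truth, cfg, noisy=False)
        fit = fitting.fit_ratio_table(ratio_set.data)
        assert (fit["t_half"] > 60.0).all()

    def test_actd_chase_cancels_recycling(self):
        cfg = simulate.SimConfig(n_genes=1, recycling_fraction=0.2)
        truth = make_truth_row(k=LN2 / 60)
        ratio_set = run_pipeline(truth, cfg, condition="actd_chase", noisy=False)
        fit = fitting.fit_ratio_table(ratio_set.data)
        assert fit["t_half"].iloc[0] == pytest.approx(60.0, rel=1e-9)

    def test_mixture_bracketing(self):
        cfg = simulate.SimConfig(n_genes=60, seed=5, recycling_fraction=0.0)
        truth = simulate.sample_true_kinetics(cfg)
        fits = {}
        for tissue in ("neural", "whole_embryo"):
            ratio_set = run_pipeline(truth, cfg, tissue=tissue, noisy=False)
            fit = fitting.fit_ratio_table(ratio_set.data)
            fits[tissue] = fit.groupby("gene_id")["t_half"].first()
        t_nonneural = LN2 / truth.set_index("gene_id")["k_nonneural"]
        t_neural = truth.set_index("gene_id")["true_halflife_neural"]
        lo = np.minimum(t_neural, t_nonneural)
        hi = np.maximum(t_neural, t_nonneural)
        whole = fits["whole_embryo"].reindex(lo.index)
        assert ((whole >= lo - 1e-9) & (whole <= hi + 1e-9)).all()

    def test_fitted_halflife_monotone_in_recycling(self):
        fitted = []
        for rho in (0.0, 0.05, 0.1, 0.2):
            cfg = simulate.SimConfig(n_genes=1, recycling_fraction=rho)
            ratio_set = run_pipeline(make_truth_row(k=LN2 / 60), cfg, noisy=False)
            fitted.append(fitting.fit_ratio_table(ratio_set.data)["t_half"].iloc[0])
        assert all(a < b for a, b in zip(fitted, fitted[1:]))

    def test_knockdown_contract(self):
        cfg = simulate.SimConfig(
            n_genes=30, seed=6, recycling_fraction=0.0, knockdown_stabilization=1.5,
            pre_probability={"neural_fate": 0.5, "localized": 0.5, "background": 0.5},
        )
        truth = simulate.sample_true_kinetics(cfg)
        halflives = {}
        for condition in ("control", "knockdown"):
            ratio_set = run_pipeline(truth, cfg, condition=condition, noisy=False)
            fit = fitting.fit_ratio_table(ratio_set.data)
            halflives[condition] = fit.groupby("gene_id")["t_half"].first()
        ratio = (halflives["knockdown"] / halflives["control"]).reindex(truth["gene_id"])
        pre = (truth["pre_count"] >= 1).to_numpy()
        np.testing.assert_allclose(ratio.to_numpy()[pre], 1.5, rtol=1e-9)
        np.testing.assert_allclose(ratio.to_numpy()[~pre], 1.0, rtol=1e-9)

    def test_bad_mixture_weight_rejected(self):
        cfg = simulate.SimConfig(n_genes=1, mixture_weight=1.5)
        with pytest.raises(ConfigError):
            simulate.simulate_labeled_signal(make_truth_row(), cfg, "whole_embryo")


class TestMeasurementModel:
    def test_zero_noise_unit_scale_is_identity_plus_spikeins(self):
        cfg = simulate.SimConfig(n_genes=20, seed=8, noise_sd=0.0, array_scale_sd=0.0)
        truth = simulate.sample_true_kinetics(cfg)
        clean = simulate.simulate_labeled_signal(truth, cfg, "neural", "control")
        noisy = simulate.apply_measurement_model(clean, cfg)
        genes = noisy.gene_rows()
        np.testing.assert_allclose(
            genes["intensity"].to_numpy(), clean.data["intensity"].to_numpy(), rtol=1e-12
        )
        assert noisy.spikein_rows()["gene_id"].nunique() == cfg.spikein_count

    def test_scale_shared_between_genes_and_spikeins(self):
        cfg = simulate.SimConfig(n_genes=15, seed=9, noise_sd=0.0, array_scale_sd=0.4)
        truth = simulate.sample_true_kinetics(cfg)
        clean = simulate.simulate_labeled_signal(truth, cfg, "neural", "control")
        noisy = simulate.apply_measurement_model(clean, cfg)
        scales = noisy.array_scales.set_index(["replicate", "timepoint_min"])["scale"]
        for (rep, t), scale in scales.items():
            block = noisy.data[
                (noisy.data["replicate"] == rep) & (noisy.data["timepoint_min"] == t)
            ]
            spikes = block.loc[block["is_spikein"], "intensity"]
            np.testing.assert_allclose(spikes, cfg.spikein_level * scale, rtol=1e-12)

    def test_fixed_seed_determinism(self):
        cfg = simulate.SimConfig(n_genes=25, seed=11, noise_sd=0.2)
        truth = simulate.sample_true_kinetics(cfg)
        clean = simulate.simulate_labeled_signal(truth, cfg, "neural", "control")
        a = simulate.apply_measurement_model(clean, cfg)
        b = simulate.apply_measurement_model(clean, cfg)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_negative_noise_rejected(self):
        cfg = simulate.SimConfig(n_genes=2, noise_sd=0.1)
        truth = simulate.sample_true_kinetics(cfg)
        clean = simulate.simulate_labeled_signal(truth, cfg, "neural", "control")
        cfg.noise_sd = -0.1
        with pytest.raises(ConfigError):
            simulate.apply_measurement_model(clean, cfg)


class TestGenerateUtrFasta:
    def test_motif_counts_roundtrip_exactly(self):
        cfg = simulate.SimConfig(n_genes=80, seed=12)
        truth = simulate.sample_true_kinetics(cfg)
        records = simulate.generate_utr_fasta(truth, cfg)
        specs = {s.name: s for s in motifs.builtin_motifs()}
        by_id = {r.id: str(r.seq) for r in records}
        for row in truth.itertuples(index=False):
            seq = by_id[row.gene_id]
            assert motifs.scan_motif(seq, specs["PRE"])[0] == row.pre_count
            assert motifs.scan_motif(seq, specs["ARE"])[0] == row.are_count
            assert motifs.scan_motif(seq, specs["miR124_seed"])[0] == row.mir124_site_count

    def test_minimum_length_and_alphabet(self):
        cfg = simulate.SimConfig(n_genes=40, seed=13, utr_length_mean=40, utr_length_sd=30)
        truth = simulate.sample_true_kinetics(cfg)
        records = simulate.generate_utr_fasta(truth, cfg)
        for r in records:
            assert len(r.seq) >= 30
            assert set(str(r.seq)) <= set("ACGU")

    def test_too_short_utr_names_gene(self):
        cfg = simulate.SimConfig(n_genes=1, utr_length_mean=10, utr_length_sd=0)
        truth = make_truth_row(gene_id="gX", pre=1)
        truth["pre_count"] = 5  # 40 nt of motif > 30 nt floor only if length < need
        cfg.utr_length_mean = 31
        with pytest.raises(GenerationError, match="gX"):
            simulate.generate_utr_fasta(truth, cfg)


class TestEndToEndRecovery:
    def test_noisefree_recovery_everywhere(self, small_noisefree_study):
        cfg, truth = small_noisefree_study
        ratio_set = run_pipeline(truth, cfg, noisy=False)
        fits = fitting.fit_ratio_table(ratio_set.data, high_stability_min=np.inf)
        merged = fits.merge(truth, on="gene_id")
        np.testing.assert_allclose(
            merged["t_half"], merged["true_halflife_neural"], rtol=1e-6
        )
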