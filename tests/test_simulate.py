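import numpy as np
import pandas as pd
import pytest

import methdrift as md
from methdrift.simulate import (ArraySignalConfig, SyntheticConfig,
                                generate_array_signals, generate_cohort)


def _pair_frames(matrix, truth):
    pids = list(dict.fromkeys(truth.pair_truth["patient_id"]))
    prim = matrix.data.loc[[f"{p}_P" for p in pids]]
    met = matrix.data.loc[[f"{p}_M" for p in pids]]
    return prim, met


class TestGenerateCohort:
    def test_same_seed_same_output(self):
        cfg = SyntheticConfig(seed=42)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.matrix.data, b.matrix.data)
        pd.testing.assert_frame_equal(a.meta, b.meta)
        pd.testing.assert_frame_equal(a.truth.pair_truth, b.truth.pair_truth)

    def test_no_drift_metastasis_identical_to_primary(self):
        cfg = SyntheticConfig(purity=1.0, noise_sd=0.0, density_inflation=1.0,
                              r_gain=0.0, r_loss=0.0, seed=3)
        m, _, truth = generate_cohort(cfg)
        prim, met = _pair_frames(m, truth)
        np.testing.assert_array_equal(prim.to_numpy(), met.to_numpy())
        assert (truth.pair_truth["event"] == "none").all()

    def test_zero_frequency_all_unmethylated_distribution(self):
        cfg = SyntheticConfig(methylation_freq=0.0, r_gain=0.0, purity=1.0,
                              noise_sd=0.0, seed=4)
        m, _, truth = generate_cohort(cfg)
        assert not truth.pair_truth["primary_state"].any()
        # Beta(1, 30) * 100 stays low: nothing near the methylated regime
        assert m.data.to_numpy().max() < 50

    def test_gain_count_matches_binomial_expectation(self):
        cfg = SyntheticConfig(n_patients=2, n_with_mets=1, n_pairs=1,
                              n_loci=1000, methylation_freq=0.0, r_gain=1e-3,
                              interval_months=(46.0,), seed=5)
        _, _, truth = generate_cohort(cfg)
        n_gain = int((truth.pair_truth["event"] == "frequency_gain").sum())
        expected = 1000 * 1e-3 * 46
        sd = np.sqrt(1000 * 0.046 * (1 - 0.046))
        assert abs(n_gain - expected) <= 3 * sd

    def test_observed_density_mixes_purity_and_baseline(self):
        cfg = SyntheticConfig(purity=0.5, normal_baseline=10.0, noise_sd=0.0,
                              density_inflation=1.0, r_gain=0.0, r_loss=0.0,
                              seed=6)
        m, _, truth = generate_cohort(cfg)
        pt = truth.pair_truth
        obs = np.array([m.data.at[f"{r.patient_id}_P", r.locus_id]
                        for r in pt.itertuples()])
        expect = 0.5 * pt["primary_density_true"].to_numpy() + 0.5 * 10.0
        np.testing.assert_allclose(obs, expect, atol=1e-9)

    def test_values_always_in_range_with_heavy_noise(self):
        cfg = SyntheticConfig(noise_sd=30.0, seed=7)
        m, _, _ = generate_cohort(cfg)
        v = m.data.to_numpy()
        assert v.min() >= 0 and v.max() <= 100

    def test_event_labels_consistent_with_latent_states(self):
        cfg = SyntheticConfig(n_patients=50, n_with_mets=50, n_pairs=50,
                              n_loci=200, r_gain=0.01, r_loss=0.01, seed=8)
        _, _, truth = generate_cohort(cfg)
        pt = truth.pair_truth
        gains = pt[pt["event"] == "frequency_gain"]
        assert (~gains["primary_state"]).all() and gains["metastasis_state"].all()
        losses = pt[pt["event"] == "frequency_loss"]
        assert losses["primary_state"].all() and (~losses["metastasis_state"]).all()
        dens = pt[pt["event"] == "density_increase"]
        assert dens["primary_state"].all() and dens["metastasis_state"].all()
        np.testing.assert_allclose(
            dens["metastasis_density_true"],
            dens["primary_density_true"] * cfg.density_inflation)

    def test_cimp_rate_matches_closed_form_marker_model(self):
        """With independent markers and densities separated across the
        cutoff, the CIMP-positive fraction matches the closed-form
        probability that >= 2 of the 6 panel markers fire."""
        cfg = SyntheticConfig(n_patients=400, n_with_mets=100, n_pairs=10,
                              meth_beta=(5.0, 5.0), purity=1.0, noise_sd=0.0,
                              seed=10)
        m, meta, truth = generate_cohort(cfg)
        prim = m.data.loc[meta.loc[meta["role"] == "primary", "sample_id"]]
        res = md.call_cimp(prim)
        observed = (res["status"] == "positive").mean()

        f = truth.freqs[list(md.DEFAULT_CIMP_PANEL)].to_numpy()
        p0 = np.prod(1 - f)
        p1 = sum(f[i] * np.prod(np.delete(1 - f, i)) for i in range(len(f)))
        p_ge2 = 1 - p0 - p1
        sd = np.sqrt(p_ge2 * (1 - p_ge2) / 400)
        assert abs(observed - p_ge2) <= 3 * sd

    @pytest.mark.parametrize("kwargs", [
        {"purity": 0.0}, {"r_gain": 1.5}, {"density_inflation": 0.5},
        {"meth_beta": (0.0, 1.0)}, {"n_pairs": 50, "n_with_mets": 20},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(**kwargs)


class TestGenerateArraySignals:
    @staticmethod
    def _truth(n_loci=400, seed=9, **kw):
        cfg = SyntheticConfig(n_patients=1, n_with_mets=1, n_pairs=1,
                              n_loci=n_loci, seed=seed, **kw)
        return generate_cohort(cfg).truth

    def test_no_difference_no_bias_median_log_ratio_near_zero(self):
        truth = self._truth(r_gain=0.0, r_loss=0.0, density_inflation=1.0,
                            interval_months=(12.0,))
        tab = generate_array_signals(
            truth, ArraySignalConfig(bias_amplitude=0.0, seed=1))["P001"]
        probes = md.make_probe_table(tab)
        assert abs(np.median(probes["M_raw"])) < 0.05

    def test_full_gain_gene_has_maximal_log_ratio(self):
        truth = self._truth(methylation_freq=0.0, r_gain=0.0,
                            interval_months=(12.0,), purity=1.0, noise_sd=0.0)
        pt = truth.pair_truth
        # hand-craft a single full-gain event: 0 -> 90 percent
        idx = pt.index[0]
        pt.loc[idx, ["primary_density_true", "metastasis_density_true"]] = [0.0, 90.0]
        tab = generate_array_signals(
            truth, ArraySignalConfig(bias_amplitude=0.0, noise_sd=0.05,
                                     seed=2))["P001"]
        probes = md.make_probe_table(tab)
        per_gene = probes.groupby("gene_id")["M_raw"].mean()
        assert per_gene.idxmax() == pt.loc[idx, "locus_id"]

    def test_dye_bias_creates_and_lowess_removes_am_trend(self):
        truth = self._truth(n_loci=2000, r_gain=0.0, r_loss=0.0,
                            density_inflation=1.0, interval_months=(12.0,))
        tab = generate_array_signals(
            truth, ArraySignalConfig(bias_amplitude=0.8, seed=3))["P001"]
        probes = md.make_probe_table(tab)
        raw_corr = np.corrcoef(probes["A"], probes["M_raw"])[0, 1]
        assert abs(raw_corr) > 0.3
        norm = md.lowess_normalize(probes)
        norm_corr = np.corrcoef(norm["A"], norm["M_norm"])[0, 1]
        assert abs(norm_corr) < 0.05

    def test_same_seed_same_signals(self):
        truth = self._truth()
        t1 = generate_array_signals(truth, ArraySignalConfig(seed=5))["P001"]
        t2 = generate_array_signals(truth, ArraySignalConfig(seed=5))["P001"]
        pd.testing.assert_frame_equal(t1, t2)
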