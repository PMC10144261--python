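"""Acquisition model: schedule arithmetic, gating bias, generator determinism."""

import dataclasses

import numpy as np
import pytest

from svatk.simulate import (
    AcquisitionConfig,
    SimSpecies,
    SynthProjectConfig,
    check_scans_per_peak,
    estimate_spike_recovery,
    make_spike_pair,
    scan_schedule,
    scans_per_peak,
    simulate_acquisition,
    synth_project,
    xic_and_quant,
)

MS1_ONLY = AcquisitionConfig(mode="MS1_only", iit_threshold_ppm=100.0)
GATED = AcquisitionConfig(mode="DDA", iit_threshold_ppm=0.75)


class TestSchedule:
    def test_ms1_only_cadence(self):
        cfg = AcquisitionConfig(mode="MS1_only", ms1_scan_s=0.25)
        assert len(scan_schedule(cfg, 10.0)) == 40

    def test_dda_cycle_includes_topn_ms2(self):
        cfg = AcquisitionConfig(mode="DDA", top_n=5, ms1_scan_s=0.25,
                                ms2_scan_s=0.15)
        assert cfg.cycle_s == pytest.approx(1.0)
        assert len(scan_schedule(cfg, 10.0)) == 10

    def test_run_shorter_than_cycle_rejected(self):
        with pytest.raises(ValueError):
            scan_schedule(AcquisitionConfig(mode="MS1_only"), 0.1)

    def test_scans_per_peak_closed_form_and_warning(self):
        dda = AcquisitionConfig(mode="DDA", top_n=5, ms1_scan_s=0.25,
                                ms2_scan_s=0.15)
        # sigma 1.5 s -> 6 s (+/-2 sigma) window at 1.0 s cadence: 6 scans
        assert scans_per_peak(dda, 1.5) == 6
        with pytest.warns(UserWarning, match="MS1 scans per"):
            assert check_scans_per_peak(dda, 1.5) is False
        ms1 = AcquisitionConfig(mode="MS1_only", ms1_scan_s=0.25)
        assert scans_per_peak(ms1, 1.5) == 24
        assert check_scans_per_peak(ms1, 1.5) is True

    def test_check_agrees_with_cadence_arithmetic(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            cfg = AcquisitionConfig(
                mode="DDA", top_n=int(rng.integers(1, 10)),
                ms1_scan_s=float(rng.uniform(0.05, 0.5)),
                ms2_scan_s=float(rng.uniform(0.02, 0.3)))
            sigma = float(rng.uniform(0.5, 5.0))
            expected = int(np.floor(4 * sigma / cfg.cycle_s))
            assert scans_per_peak(cfg, sigma) == expected


class TestAcquisition:
    def test_unbiased_expectation_without_gating(self):
        """With gating off, mean reported intensity equals the flux."""
        sp = SimSpecies("x", 500.0, 2, 30.0, 50.0, 2e5)  # near-flat elution
        rng = np.random.default_rng(0)
        scans = simulate_acquisition([sp], MS1_ONLY, 30.0, rng)
        mid = [s.intensities["x"] for s in scans]
        assert not any(s.gated for s in scans)
        assert np.mean(mid) == pytest.approx(sp.flux(15.0), rel=0.02)

    def test_gated_scan_doubles_dominant_species_only(self):
        """In gated scans the dominant ion reports ~2x; the minor does not."""
        minor, major = make_spike_pair(0.5, total_apex_flux=1e7)
        rng = np.random.default_rng(1)
        scans = simulate_acquisition([minor, major], GATED, 60.0, rng)
        gated = [s for s in scans if s.gated]
        assert gated
        for s in gated:
            t = s.time_s
            assert s.intensities["wildtype"] == pytest.approx(
                2.0 * major.flux(t), rel=0.15)
            if minor.flux(t) > 1e3:
                assert s.intensities["variant"] == pytest.approx(
                    minor.flux(t), rel=0.5)

    def test_zero_flux_species_reports_zero(self):
        quiet = SimSpecies("q", 500.0, 2, 30.0, 2.0, 0.0)
        loud = SimSpecies("l", 501.0, 2, 30.0, 2.0, 1e6)
        scans = simulate_acquisition([quiet, loud], MS1_ONLY, 60.0,
                                     np.random.default_rng(0))
        assert all(s.intensities["q"] == 0.0 for s in scans)

    def test_fill_time_never_exceeds_max_inject(self):
        minor, major = make_spike_pair(0.5, total_apex_flux=1e7)
        scans = simulate_acquisition([minor, major], GATED, 60.0,
                                     np.random.default_rng(3))
        assert all(s.t_actual_ms <= GATED.max_inject_ms + 1e-9 for s in scans)

    def test_symmetric_pair_quantifies_at_fifty_percent(self):
        a = SimSpecies("a", 500.0, 2, 30.0, 2.0, 5e5)
        b = SimSpecies("b", 501.0, 2, 30.0, 2.0, 5e5)
        scans = simulate_acquisition([a, b], MS1_ONLY, 60.0,
                                     np.random.default_rng(4))
        assert round(xic_and_quant(scans, "a", "b"), 1) == 50.0

    def test_too_few_scans_across_peak_rejected(self):
        sharp = SimSpecies("a", 500.0, 2, 5.0, 0.05, 1e6)
        other = SimSpecies("b", 501.0, 2, 5.0, 2.0, 1e6)
        cfg = AcquisitionConfig(mode="MS1_only", ms1_scan_s=0.5,
                                iit_threshold_ppm=100.0)
        scans = simulate_acquisition([sharp, other], cfg, 10.0,
                                     np.random.default_rng(0))
        with pytest.raises(ValueError, match="fewer than 3"):
            xic_and_quant(scans, "a", "b")


class TestSpikeRecovery:
    def test_gating_off_recovers_half_percent(self):
        """0.5:99.5 flux ratio reads 0.5% at one decimal with gating off."""
        assert round(estimate_spike_recovery(0.5, MS1_ONLY, seed=0), 1) == 0.5

    def test_unbiased_across_seeds_and_levels(self):
        """Mean estimate sits within a 3-sigma band of truth (50 seeds)."""
        for level in (0.1, 0.2, 0.5):
            ests = [estimate_spike_recovery(level, MS1_ONLY, seed=s)
                    for s in range(50)]
            z = (np.mean(ests) - level) / (np.std(ests) / np.sqrt(len(ests)))
            assert abs(z) < 3.0

    @pytest.mark.parametrize("gain", [1.6, 2.0])
    def test_gated_mode_under_quantitates(self, gain):
        """Injection-time gating biases a 0.5% spike down into [0.2, 0.35]%."""
        cfg = dataclasses.replace(GATED, dominant_gain=gain)
        ests = [estimate_spike_recovery(0.5, cfg, seed=s,
                                        total_apex_flux=1e7)
                for s in range(5)]
        for est in ests:
            assert 0.2 <= est <= 0.35


class TestSynthProject:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        a = synth_project(seed=9, out_dir=tmp_path / "a")
        b = synth_project(seed=9, out_dir=tmp_path / "b")
        for name in ("project.fasta", "psms.csv", "truth.csv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()

    def test_different_seeds_differ(self):
        a = synth_project(seed=1)
        b = synth_project(seed=2)
        assert [p.sequence for p in a.proteins] != \
               [p.sequence for p in b.proteins]

    def test_planted_composition_matches_config(self, sva7):
        counts = {}
        for row in sva7.truth:
            counts[row["klass"]] = counts.get(row["klass"], 0) + 1
        assert counts == {"true_sv": 7, "fp_semi_nonKR": 20,
                          "fp_terminal_residue": 10, "fp_below_limit": 10,
                          "fp_orthogonal": 10}
        best = {}
        for row in sva7.truth:
            if row["klass"] != "true_sv":
                continue
            scores = [p.score for p in sva7.psms
                      if p.psm_id in row["psm_ids"].split(";")]
            best[row["variant_name"]] = max(scores)
        assert all(s >= 225 for s in best.values())
        assert sum(1 for s in best.values() if 225 <= s < 250) == 3

    def test_psm_table_round_trips_through_disk(self, tmp_path, sva7):
        from svatk.psm_io import read_psm_table
        paths = sva7.write(tmp_path)
        assert read_psm_table(paths["psms"]) == sva7.psms

    def test_infeasible_config_raises(self):
        tiny = SynthProjectConfig(chains=(("LC", 40),))
        with pytest.raises(ValueError, match="infeasible"):
            synth_project(tiny, seed=0)

    def test_zero_fp_project_retains_every_true_variant(self):
        from svatk.psm_io import make_config
        from svatk.quant import quantify_variants
        from svatk.triage import triage_run
        cfg = SynthProjectConfig(n_fp_semi=0, n_fp_terminal=0,
                                 n_fp_sublimit=0, n_fp_orthogonal=0)
        proj = synth_project(cfg, seed=4)
        proteins = {p.id: p for p in proj.proteins}
        quants = {n: q.rel_quant_pct
                  for n, q in quantify_variants(proj.psms).items()}
        _, summary = triage_run(proj.psms, proteins, quants,
                                make_config("high_res"))
        assert set(summary.retained_sites) == proj.true_sites


def test_acquisition_config_validation():
    with pytest.raises(ValueError):
        AcquisitionConfig(mode="SIM")
    with pytest.raises(ValueError):
        AcquisitionConfig(mode="DDA", top_n=0)
    with pytest.raises(ValueError):
        AcquisitionConfig(gating_factor=1.0)
    with pytest.raises(ValueError):
        AcquisitionConfig(dominance_fraction=0.0)
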