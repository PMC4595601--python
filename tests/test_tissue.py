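import numpy as np
import pytest

from drest import tp06
from drest.tissue import (TissueConfig, delineate_t_wave, dynamic_restitution,
                          pseudo_ecg, simulate_strand)


class TestSingleCell:
    def test_resting_stability(self):
        """Unstimulated myocyte: V drifts < 0.5 mV over 10 s."""
        from drest.tp06 import _GKS, _GTO, _run_single

        for ct in range(3):
            y = tp06.initial_state()
            _, v = _run_single(y, ct, 0.02, int(10_000 / 0.02), np.empty(0),
                               1.0, 0.0, 1.0, _GKS[ct], _GTO[ct], 1000)
            assert np.max(np.abs(v - v[0])) < 0.5

    def test_epi_apd90_in_published_range(self):
        t, v, _ = tp06.pace_single_cell("epi", 1000.0, n_beats=10)
        apd = tp06.apd90_from_trace(t, v, 1000.0)
        assert 280.0 <= apd <= 320.0

    def test_ikr_block_prolongs_apd(self):
        t0, v0, _ = tp06.pace_single_cell("epi", 1000.0, n_beats=10)
        t1, v1, _ = tp06.pace_single_cell("epi", 1000.0, n_beats=10,
                                          gkr_scale=0.5)
        a0 = tp06.apd90_from_trace(t0, v0, 1000.0)
        a1 = tp06.apd90_from_trace(t1, v1, 1000.0)
        assert a1 > a0

    def test_m_cell_longest_apd(self):
        apds = {}
        for ct in ("endo", "M", "epi"):
            t, v, _ = tp06.pace_single_cell(ct, 1000.0, n_beats=10)
            apds[ct] = tp06.apd90_from_trace(t, v, 1000.0)
        assert apds["M"] > apds["epi"] and apds["M"] > apds["endo"]

    def test_dt_refinement_consistency(self):
        """Halving dt changes APD90 by < 2 ms at CL 1000 ms."""
        a = {}
        for dt in (0.02, 0.01):
            t, v, _ = tp06.pace_single_cell("epi", 1000.0, n_beats=5, dt=dt)
            a[dt] = tp06.apd90_from_trace(t, v, 1000.0)
        assert abs(a[0.02] - a[0.01]) < 2.0

    def test_invalid_gkr_rejected(self):
        with pytest.raises(ValueError):
            tp06.pace_single_cell("epi", 1000.0, n_beats=2, gkr_scale=0.0)


@pytest.fixture(scope="module")
def hetero_result():
    return simulate_strand(TissueConfig(), 1000.0, n_beats=5)


@pytest.fixture(scope="module")
def homo_result():
    cfg = TissueConfig(endo_fraction=0.0, m_fraction=0.0)  # all epi
    return simulate_strand(cfg, 1000.0, n_beats=5)


class TestStrand:
    def test_activation_monotone_from_stimulated_end(self, hetero_result):
        act = hetero_result.activation_ms
        assert np.all(np.diff(act) >= 0.0)
        assert act[-1] - act[0] > 10.0  # conduction, not simultaneous firing

    def test_homogeneous_strand_small_apd_spread(self, homo_result):
        """Uniform tissue: central-half APD90 spread < 5 ms.  The quarters
        adjacent to the stimulated and sealed ends carry genuine edge
        effects (stimulus electrotonus, sealed-end boundary, and the
        repolarization-wake gradient that scales with activation delay),
        so 'interior' means the central half of the strand."""
        n = len(homo_result.apd90_ms)
        interior = homo_result.apd90_ms[n // 4:-n // 4]
        assert np.ptp(interior) < 5.0

    def test_m_region_longer_apd_than_epi(self, hetero_result):
        tm = hetero_result.config.type_map()
        apd = hetero_result.apd90_ms
        assert (np.mean(apd[tm == tp06.CELL_TYPES["M"]])
                > np.mean(apd[tm == tp06.CELL_TYPES["epi"]]))

    def test_pseudo_ecg_t_end_matches_repolarization(self, hetero_result):
        ts, phi = pseudo_ecg(hetero_result, beat=-1)
        _, t_end = delineate_t_wave(ts, phi)
        assert t_end == pytest.approx(
            np.nanmax(hetero_result.repolarization_ms), abs=15.0)

    def test_heterogeneity_widens_t_wave(self, hetero_result, homo_result):
        """Transmural heterogeneity is what Tpe measures: the heterogeneous
        strand's pseudo-ECG Tpe exceeds the uniform strand's."""
        def tpe(res):
            ts, phi = pseudo_ecg(res, beat=-1)
            t_apex, t_end = delineate_t_wave(ts, phi)
            return t_end - t_apex

        assert tpe(hetero_result) > tpe(homo_result)

    def test_more_m_cells_longer_tpe(self, hetero_result):
        """Raising the M-cell fraction by 10 points widens Tpe."""
        res = simulate_strand(TissueConfig(m_fraction=0.45), 1000.0,
                              n_beats=5)
        ts, phi = pseudo_ecg(res, beat=-1)
        a1, e1 = delineate_t_wave(ts, phi)
        ts0, phi0 = pseudo_ecg(hetero_result, beat=-1)
        a0, e0 = delineate_t_wave(ts0, phi0)
        assert (e1 - a1) > (e0 - a0)

    def test_config_geometry_validated(self):
        with pytest.raises(ValueError):
            TissueConfig(n_nodes=30)
        with pytest.raises(ValueError):
            TissueConfig(n_nodes=100, dx_mm=0.5)  # 50 mm strand
        with pytest.raises(ValueError):
            TissueConfig(gkr_scale=1.5)

    def test_config_file_round_trip(self, tmp_path):
        cfg = TissueConfig(gkr_scale=0.5, n_nodes=120, dx_mm=0.12)
        p = tmp_path / "tissue.cfg"
        cfg.to_file(p)
        back = TissueConfig.from_file(p)
        assert back == cfg


class TestRestitution:
    def test_grid_validation(self):
        with pytest.raises(ValueError):
            dynamic_restitution(TissueConfig(), rr_grid_ms=[500, 700, 900])
        with pytest.raises(ValueError):
            dynamic_restitution(TissueConfig(),
                                rr_grid_ms=[400, 600, 800, 1000])

    def test_invariants_on_fast_profile(self, restitution_pair):
        control, block = restitution_pair
        for rcs in (control, block):
            rcs.check()
            assert rcs.rr_grid_ms[0] >= 500 and rcs.rr_grid_ms[-1] <= 1500
            assert not rcs.blocked_rr_ms

    def test_ecg_and_spatial_dispersion_correlate(self, restitution_pair):
        from scipy import stats as sstats

        control, _ = restitution_pair
        rho = sstats.spearmanr(control.drest_ecg,
                               control.drest_spatial).statistic
        assert rho > 0.8

    def test_drest_higher_at_short_rr_in_control(self, restitution_pair):
        control, _ = restitution_pair
        assert (control.drest_ecg_at(600.0) > control.drest_ecg_at(1100.0))
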