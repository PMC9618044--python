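"""Observables: rendered fluorescence, profile statistics, aggregate and gap
calls, ring tension bookkeeping and mechanical connectivity."""

import numpy as np
import pytest

from ringsim import (
    IntensityProfile,
    ModelParams,
    correlation_length,
    detect_aggregates,
    detect_gaps,
    kymograph,
    mean_separation,
    mechanical_connectivity,
    relative_fluctuation,
    render_fluorescence,
    ring_tension,
    total_intensity,
)
from ringsim.observables import autocorrelation, ring_tension_sections
from ringsim.ring_model import seed_filament
from ringsim.state import Filament, MyosinCluster, RingState

P = ModelParams()
L = P.circumference


def profile_from(fn) -> IntensityProfile:
    n = int(round(L / P.bin_width))
    bw = L / n
    centers = (np.arange(n) + 0.5) * bw
    return IntensityProfile(centers, fn(centers), bw)


def cluster_at_arc(s: float, params: ModelParams = P) -> MyosinCluster:
    phi = s / params.R
    r = params.R - params.d_myo_anchor
    return MyosinCluster(np.array([r * np.cos(phi), r * np.sin(phi), 0.0]))


class TestRenderFluorescence:
    def test_single_cluster_gives_gaussian_of_psf_width(self):
        prof = render_fluorescence(np.array([[3.6, 0, 0]]), P)
        y = prof.intensity
        half = y >= 0.5 * y.max()
        fwhm = half.sum() * prof.bin_width
        assert fwhm == pytest.approx(P.psf_fwhm, abs=2 * prof.bin_width)

    def test_total_intensity_equals_cluster_count(self):
        rng = np.random.default_rng(0)
        phis = rng.uniform(0, 2 * np.pi, size=37)
        pos = np.stack(
            [3.6 * np.cos(phis), 3.6 * np.sin(phis), np.zeros_like(phis)], axis=1
        )
        prof = render_fluorescence(pos, P)
        assert total_intensity(prof) == pytest.approx(37, rel=1e-9)

    def test_two_distant_clusters_resolve_as_equal_peaks(self):
        pos = np.stack([cluster_at_arc(5.0).position, cluster_at_arc(10.0).position])
        prof = render_fluorescence(pos, P)
        peaks = detect_aggregates(prof)
        assert len(peaks) == 2
        assert prof.intensity.max() == pytest.approx(
            np.sort(prof.intensity)[-2], rel=0.02
        )

    def test_bin_width_coarser_than_quarter_psf_rejected(self):
        with pytest.raises(ValueError):
            render_fluorescence(np.array([[3.6, 0, 0]]), P, bin_width=0.2)

    def test_empty_state_renders_zero_profile(self):
        prof = render_fluorescence(np.zeros((0, 3)), P)
        assert np.all(prof.intensity == 0)


class TestRelativeFluctuation:
    def test_constant_profile_has_zero_fluctuation(self):
        assert relative_fluctuation(profile_from(lambda s: np.ones_like(s))) == 0.0

    def test_cosine_profile_matches_analytic_sd(self):
        # I = 1 + 0.5·cos(ks): SD = 0.5/√2 ≈ 0.354
        k = 2 * np.pi / L * 4
        prof = profile_from(lambda s: 1 + 0.5 * np.cos(k * s))
        assert relative_fluctuation(prof) == pytest.approx(0.5 / np.sqrt(2), rel=1e-6)

    def test_zero_profile_rejected(self):
        with pytest.raises(ValueError):
            relative_fluctuation(profile_from(np.zeros_like))

    def test_invariant_under_rescaling_and_rotation(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0.5, 2.0, size=int(round(L / P.bin_width)))
        prof = profile_from(lambda s: base)
        rolled = profile_from(lambda s: 7.0 * np.roll(base, 31))
        assert relative_fluctuation(rolled) == pytest.approx(
            relative_fluctuation(prof), rel=1e-9
        )


class TestCorrelationLength:
    def test_cosine_profile_crosses_half_at_sixth_wavelength(self):
        # I(s) = 1 + cos(2πs/λ): autocorrelation cos(2πd/λ) crosses 0.5 at λ/6
        lam = L / 4  # an integer number of periods fits the ring
        prof = profile_from(lambda s: 1 + np.cos(2 * np.pi * s / lam))
        assert correlation_length(prof) == pytest.approx(lam / 6, rel=0.02)

    def test_white_noise_decorrelates_within_one_bin(self):
        rng = np.random.default_rng(5)
        prof = profile_from(lambda s: rng.uniform(size=len(s)))
        assert correlation_length(prof) <= prof.bin_width

    def test_constant_profile_rejected(self):
        with pytest.raises(ValueError):
            correlation_length(profile_from(lambda s: np.ones_like(s)))

    def test_autocorrelation_is_normalized_and_even_shaped(self):
        lam = L / 2
        prof = profile_from(lambda s: 1 + np.cos(2 * np.pi * s / lam))
        lags, corr = autocorrelation(prof)
        assert corr[0] == pytest.approx(1.0)
        assert np.allclose(corr, np.cos(2 * np.pi * lags / lam), atol=1e-6)

    def test_invariant_under_rescaling_and_rotation(self):
        rng = np.random.default_rng(2)
        base = np.convolve(rng.uniform(size=300), np.ones(20) / 20, "same")
        n = int(round(L / P.bin_width))
        base = np.interp(np.linspace(0, 300, n, endpoint=False), np.arange(300), base)
        a = profile_from(lambda s: 1 + base)
        b = profile_from(lambda s: 3 * (1 + np.roll(base, 57)))
        assert correlation_length(a) == pytest.approx(correlation_length(b), rel=1e-6)


class TestAggregates:
    def test_two_gaussians_two_micron_apart(self):
        prof = profile_from(
            lambda s: np.exp(-0.5 * ((s - 8.0) / 0.25) ** 2)
            + np.exp(-0.5 * ((s - 10.0) / 0.25) ** 2)
        )
        peaks = detect_aggregates(prof)
        assert len(peaks) == 2
        assert mean_separation(peaks, 4.0) == pytest.approx(2.0, abs=0.1)

    def test_uniform_profile_has_no_peaks(self):
        prof = profile_from(lambda s: np.ones_like(s))
        assert len(detect_aggregates(prof)) == 0

    def test_fewer_than_two_peaks_has_undefined_separation(self):
        assert mean_separation(np.array([1.0]), L) is None

    def test_even_spacing_times_count_recovers_circumference(self):
        centers = np.arange(6) * L / 6 + 1.0
        prof = profile_from(
            lambda s: sum(
                np.exp(-0.5 * ((s - c) / 0.2) ** 2) for c in centers
            )
        )
        peaks = detect_aggregates(prof)
        assert len(peaks) == 6
        assert mean_separation(peaks, L) * 6 == pytest.approx(L, rel=1e-6)

    def test_peak_near_the_seam_is_found_once(self):
        prof = profile_from(lambda s: np.exp(-0.5 * (((s - 0.01 + L / 2) % L - L / 2) / 0.3) ** 2))
        peaks = detect_aggregates(prof)
        assert len(peaks) == 1


class TestGaps:
    def test_one_micron_dead_zone_is_one_gap(self):
        prof = profile_from(lambda s: np.where((s > 5) & (s < 6), 0.0, 1.0))
        gaps = detect_gaps(prof, P)
        assert len(gaps) == 1
        start, width = gaps[0]
        assert width == pytest.approx(1.0, abs=2 * prof.bin_width)
        assert start == pytest.approx(5.0, abs=2 * prof.bin_width)

    def test_half_micron_dead_zone_is_below_threshold(self):
        prof = profile_from(lambda s: np.where((s > 5) & (s < 5.5), 0.0, 1.0))
        assert detect_gaps(prof, P) == []

    def test_all_zero_profile_is_one_full_ring_gap(self):
        prof = profile_from(np.zeros_like)
        assert detect_gaps(prof, P) == [(0.0, pytest.approx(L))]

    def test_gap_spanning_the_seam_is_measured_whole(self):
        prof = profile_from(lambda s: np.where((s < 0.5) | (s > L - 0.5), 0.0, 1.0))
        gaps = detect_gaps(prof, P)
        assert len(gaps) == 1
        assert gaps[0][1] == pytest.approx(1.0, abs=2 * prof.bin_width)


class TestRingTension:
    def test_empty_ring_has_zero_tension(self):
        st = RingState()
        assert ring_tension(st, P) == 0.0

    def test_single_spanning_filament_reports_its_multiplier(self):
        from ringsim.constrained_dynamics import StepReport

        p = ModelParams(rho_for=0, rho_myo=0, rho_x=0)
        anchor = np.array([p.R - p.d_for_anchor, 0.0, 0.0])
        fil = seed_filament(anchor, p.circumference - 0.5, "anticlockwise", p)
        st = RingState()
        st.filaments = [fil]
        n_seg = fil.n_subunits - 1
        T = 3.3
        st.last_report = StepReport(
            time=0.0,
            max_constraint_residual=0.0,
            solver_residual=0.0,
            seg_tension=np.full(n_seg, T),
            seg_fil=np.zeros(n_seg, int),
            seg_sub=np.arange(n_seg),
            formin_anchor=np.zeros(1),
            myosin_anchor=np.zeros(0),
        )
        # nearly every cross-section is crossed once by a tangential bond
        sections = ring_tension_sections(st, P)
        crossed = sections[sections != 0]
        assert len(crossed) >= 0.95 * len(sections)
        assert np.allclose(crossed, T, rtol=1e-3)

    def test_mean_matches_per_plane_loop_oracle(self):
        # independent per-plane re-summation of the same multipliers
        from ringsim.constrained_dynamics import step
        from ringsim.ring_model import arc_coordinate, tangent_at
        from ringsim import make_initial_ring

        p = ModelParams(R=1.0, rho_for=3.0, rho_myo=3.0, rho_x=5.0)
        st = make_initial_ring(p, np.random.default_rng(4))
        for _ in range(20):
            st = step(st, p, mode="ghost")
        rep = st.last_report
        Lc = p.circumference
        n_planes = int(round(Lc / 0.1))
        planes = (np.arange(n_planes) + 0.5) * (Lc / n_planes)
        acc = np.zeros(n_planes)
        for lam, fi, si in zip(rep.seg_tension, rep.seg_fil, rep.seg_sub):
            ra = st.filaments[fi].subunits[si]
            rb = st.filaments[fi].subunits[si + 1]
            sa, sb = arc_coordinate(ra, p.R), arc_coordinate(rb, p.R)
            u = (rb - ra) / np.linalg.norm(rb - ra)
            ax = abs(u @ tangent_at(0.5 * (ra + rb)))
            for j, sp in enumerate(planes):
                lo, hi = min(sa, sb), max(sa, sb)
                inside = (lo < sp < hi) if hi - lo <= Lc / 2 else (sp > hi or sp < lo)
                if inside:
                    acc[j] += lam * ax
        assert ring_tension(st, p) == pytest.approx(acc.mean(), rel=1e-9, abs=1e-12)


class TestConnectivity:
    def test_empty_ring_is_disconnected(self):
        connected, comps = mechanical_connectivity(RingState(), P)
        assert not connected and comps == []

    def test_single_full_circle_filament_is_connected(self):
        p = ModelParams(rho_for=0, rho_myo=0, rho_x=0)
        anchor = np.array([p.R - p.d_for_anchor, 0.0, 0.0])
        fil = seed_filament(anchor, p.circumference + 0.2, "anticlockwise", p)
        st = RingState()
        st.filaments = [fil]
        connected, comps = mechanical_connectivity(st, p)
        assert connected
        assert comps == [[("filament", 0)]]

    def test_arc_with_a_hole_is_disconnected_but_one_component(self):
        p = ModelParams(rho_for=0, rho_myo=0, rho_x=0)
        anchor = np.array([p.R - p.d_for_anchor, 0.0, 0.0])
        fil = seed_filament(anchor, 0.5 * p.circumference, "anticlockwise", p)
        st = RingState()
        st.filaments = [fil]
        connected, comps = mechanical_connectivity(st, p)
        assert not connected
        assert len(comps) == 1

    def test_engaged_cluster_bridges_two_filament_arcs(self):
        p = ModelParams(rho_for=0, rho_myo=0, rho_x=0)
        half = 0.5 * p.circumference
        a = np.array([p.R - p.d_for_anchor, 0.0, 0.0])
        f1 = seed_filament(a, half - 0.02, "anticlockwise", p)
        # second filament starts where the first ends, leaving a tiny seam
        # bridged by a cluster engaging both
        phi = (half + 0.05) / p.R
        b = (p.R - p.d_for_anchor) * np.array([np.cos(phi), np.sin(phi), 0.0])
        f2 = seed_filament(b, half - 0.02, "anticlockwise", p)
        st = RingState()
        st.filaments = [f1, f2]
        seam = 0.5 * (f1.subunits[-1] + f2.subunits[0])
        st.myosins = [
            MyosinCluster(seam / np.linalg.norm(seam) * (p.R - p.d_myo_anchor))
        ]
        connected, comps = mechanical_connectivity(st, p)
        assert len(comps) == 1  # cluster links both filaments in the graph
        assert connected


class TestKymograph:
    def test_static_configuration_gives_identical_rows(self):
        prof = render_fluorescence(np.array([[3.6, 0, 0], [0, 3.6, 0]]), P)
        ky = kymograph([(0.0, prof), (60.0, prof), (120.0, prof)])
        assert np.array_equal(ky.data[0], ky.data[1])
        assert np.array_equal(ky.data[0], ky.data[2])

    def test_fewer_than_two_rows_rejected(self):
        prof = render_fluorescence(np.array([[3.6, 0, 0]]), P)
        with pytest.raises(ValueError):
            kymograph([(0.0, prof)])

    def test_inconsistent_binning_rejected(self):
        p2 = ModelParams(bin_width=0.1)
        a = render_fluorescence(np.array([[3.6, 0, 0]]), P)
        b = render_fluorescence(np.array([[3.6, 0, 0]]), p2)
        with pytest.raises(ValueError):
            kymograph([(0.0, a), (60.0, b)])

    def test_total_intensity_decay_tracks_myosin_loss(self):
        # ghost with koff_myo > 0: total intensity decays exponentially
        from ringsim import apply_turnover, make_initial_ring

        p = ModelParams(R=1.0, rho_for=0.0, rho_myo=150.0, rho_x=0.0,
                        koff_myo_ghost=0.05)
        st = make_initial_ring(p, np.random.default_rng(11))
        n0 = total_intensity(render_fluorescence(st, p))
        for _ in range(int(30 / p.dt)):
            st = apply_turnover(st, p, "ghost", p.dt)
        n1 = total_intensity(render_fluorescence(st, p))
        assert n1 / n0 == pytest.approx(np.exp(-p.koff_myo_ghost * 30), rel=0.12)
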