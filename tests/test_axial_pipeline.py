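"""Strike-level measures and cohort statistics."""
import numpy as np
import pytest

from axialkin import (ElevationTrace, JointProgram, JointRamp, NoiseModel,
                      analyze_strike, build_preset, cohort_summary,
                      include_strike, mean_trace, per_centrum_translation,
                      preset_program, simulate_strike, strike_cohort)
from axialkin.axial_pipeline import (curvature_profile, _strike_poses,
                                     elevation_trace_from_poses)
from axialkin.errors import ParameterError
from axialkin.io_formats import PoseMatrixSequence
from conftest import single_joint_strike


# ---------------------------------------------------------------------------
# Elevation
# ---------------------------------------------------------------------------

def test_static_strike_zero_elevation(static_strike):
    res = analyze_strike(static_strike, use_markers=True, filtering=False)
    np.testing.assert_allclose(res.elevation.elevation, 0.0, atol=1e-9)
    assert res.elevation.peak_deg == pytest.approx(0.0, abs=1e-9)
    assert not res.included


def test_single_joint_ramp_peak(mini_trout):
    strike = single_joint_strike(mini_trout, joint=1, amp_deg=12.0)
    res = analyze_strike(strike, use_markers=True, filtering=False)
    assert res.elevation.peak_deg == pytest.approx(12.0, abs=1e-6)
    assert res.included


def test_elevation_invariant_to_whole_fish_motion(mini_trout):
    """Body plane and neurocranium co-rotating (whole-fish pitch and surge)
    produce zero body-referenced elevation."""
    from axialkin._rigid import hom
    from scipy.spatial.transform import Rotation

    strike = simulate_strike(mini_trout, JointProgram({}), duration_s=0.04)
    poses = dict(strike.poses)
    n = strike.n_frames
    moved = {}
    for name, seq in poses.items():
        T = seq.transforms.copy()
        for i in range(n):
            G = hom(Rotation.from_euler("z", 0.5 * i, degrees=True).as_matrix(),
                    [2.0 * i, 0.3 * i, 0.0])
            T[i] = G @ T[i]
        moved[name] = PoseMatrixSequence(name, T)
    trace = elevation_trace_from_poses(moved, strike.config)
    np.testing.assert_allclose(trace.elevation, 0.0, atol=1e-9)


def test_onset_and_duration_bracket_the_ramp(mini_trout):
    strike = single_joint_strike(mini_trout, joint=1, amp_deg=10.0,
                                 onset_s=0.01, rise_s=0.03, duration_s=0.06)
    res = analyze_strike(strike, use_markers=True, filtering=False)
    tr = res.elevation
    assert 0.01 <= tr.onset_frame / tr.frame_rate <= 0.02
    assert tr.duration_ms == pytest.approx(
        (tr.peak_frame - tr.onset_frame) / tr.frame_rate * 1000)


# ---------------------------------------------------------------------------
# Inclusion rule
# ---------------------------------------------------------------------------

def _trace(peak):
    elev = np.linspace(0, peak, 10)
    return ElevationTrace(elev, 500.0, peak, 9, 0, 18.0)


@pytest.mark.parametrize("peak,expected", [(4.99, False), (5.0, True),
                                           (18.6, True)])
def test_include_strike_boundary(peak, expected):
    assert include_strike(_trace(peak)) is expected


def test_include_strike_monotone_in_threshold():
    tr = _trace(7.3)
    decisions = [include_strike(tr, threshold=t) for t in np.linspace(0, 20, 41)]
    assert decisions == sorted(decisions, reverse=True)  # True..True,False..


# ---------------------------------------------------------------------------
# Joint deltas at peak
# ---------------------------------------------------------------------------

def test_static_strike_zero_deltas(static_strike):
    res = analyze_strike(static_strike, use_markers=True, filtering=False)
    np.testing.assert_allclose(res.deltas_deg, 0.0, atol=1e-9)


def test_planar_deltas_equal_programmed_amplitudes(mini_trout):
    prog = JointProgram({1: JointRamp(4.0, onset_s=0.01, rise_s=0.03),
                         2: JointRamp(-2.5, onset_s=0.01, rise_s=0.03),
                         3: JointRamp(6.0, onset_s=0.01, rise_s=0.03)})
    strike = simulate_strike(mini_trout, prog, duration_s=0.06)
    res = analyze_strike(strike, use_markers=True, filtering=False)
    np.testing.assert_allclose(res.deltas_deg, [4.0, -2.5, 6.0], atol=1e-6)


def test_gap_at_peak_flags_joint_missing(mini_trout):
    strike = single_joint_strike(mini_trout, joint=1, amp_deg=8.0)
    # knock out one vertebra's markers around the peak
    res0 = analyze_strike(strike, use_markers=True, filtering=False)
    pf = res0.elevation.peak_frame
    idx = [i for i, m in enumerate(strike.markers.markers) if m.startswith("v02_")]
    strike.markers.positions[pf, idx] = np.nan
    res = analyze_strike(strike, use_markers=True, filtering=False)
    assert np.isnan(res.deltas_deg[1]) and np.isnan(res.deltas_deg[2])
    assert not np.isnan(res.deltas_deg[0])


# ---------------------------------------------------------------------------
# Curvature profile and per-centrum translation
# ---------------------------------------------------------------------------

def test_straight_static_chain_zero_profile(static_strike):
    res = analyze_strike(static_strike, use_markers=True, filtering=False)
    np.testing.assert_allclose(res.curvature_peak.y_rel_mm, 0.0, atol=1e-9)
    np.testing.assert_allclose(res.per_centrum_mm, 0.0, atol=1e-9)


def test_single_joint_profile_closed_form(mini_trout):
    """With only joint 3 rotating by theta, every landmark cranial of the
    pivot rises by (distance to pivot) * sin(theta)."""
    theta = 10.0
    strike = single_joint_strike(mini_trout, joint=3, amp_deg=theta)
    poses = _strike_poses(strike, use_markers=True, filtering=False)
    cfg = strike.config
    res = analyze_strike(strike, use_markers=True, filtering=False)
    prof = res.curvature_peak
    pivot_x = cfg.bone("v03").ref_pose[0, 3] + cfg.bone("v03").acs[3].origin[0]
    sin_t = np.sin(np.deg2rad(theta))
    from axialkin.axial_pipeline import _landmarks
    for pos, (bone, point) in enumerate(_landmarks(cfg)):
        x_world = cfg.bone(bone).ref_pose[:3, 3] + point
        r = x_world[0] - pivot_x
        if r > 0:  # cranial of the rotating joint
            assert prof.y_rel_mm[pos] == pytest.approx(r * sin_t, abs=1e-9)
        else:
            assert prof.y_rel_mm[pos] == pytest.approx(0.0, abs=1e-9)


def test_profile_invariant_under_whole_chain_translation(mini_trout):
    strike = single_joint_strike(mini_trout, joint=2, amp_deg=9.0)
    poses = _strike_poses(strike, use_markers=True, filtering=False)
    prof1 = curvature_profile(poses, strike.config, frame=strike.n_frames - 1)
    G = np.eye(4)
    G[:3, 3] = [40.0, -10.0, 5.0]
    moved = {k: PoseMatrixSequence(k, G[None] @ v.transforms)
             for k, v in poses.items()}
    prof2 = curvature_profile(moved, strike.config, frame=strike.n_frames - 1)
    np.testing.assert_allclose(prof2.y_rel_mm, prof1.y_rel_mm, atol=1e-9)
    np.testing.assert_allclose(prof2.y_mm, prof1.y_mm, atol=1e-9)


def test_per_centrum_translation_arithmetic():
    from axialkin.axial_pipeline import CurvatureProfile

    prof = CurvatureProfile(frame=0, y_mm=np.array([3.0, 1.0, 0.0]),
                            y_rel_mm=np.array([3.0, 1.0, 0.0]))
    np.testing.assert_allclose(per_centrum_translation(prof), [2.0, 1.0])
    uniform = CurvatureProfile(frame=0, y_mm=np.full(4, 2.0),
                               y_rel_mm=np.full(4, 2.0))
    np.testing.assert_allclose(per_centrum_translation(uniform), 0.0)


def test_per_centrum_peaks_at_rotating_joint(mini_trout):
    strike = single_joint_strike(mini_trout, joint=2, amp_deg=10.0)
    res = analyze_strike(strike, use_markers=True, filtering=False)
    deltas = res.per_centrum_mm
    # steps caudal of the rotating joint are zero; steps across and cranial of
    # it equal (landmark spacing) * sin(theta) since that section is rigid
    sin_t = np.sin(np.deg2rad(10.0))
    assert deltas[2] == pytest.approx(0.0, abs=1e-9)
    assert deltas[1] == pytest.approx(2.5 * sin_t, abs=1e-9)
    assert deltas[1] == pytest.approx(np.nanmax(np.abs(deltas)), abs=1e-9)


# ---------------------------------------------------------------------------
# Cohort statistics
# ---------------------------------------------------------------------------

def test_cohort_summary_single_value_flagged():
    s = cohort_summary([7.0])
    assert (s.mean, s.se, s.max, s.n, s.single) == (7.0, 0.0, 7.0, 1, True)


def test_cohort_summary_arithmetic():
    s = cohort_summary([1.0, 2.0, 3.0])
    assert s.mean == pytest.approx(2.0)
    assert s.se == pytest.approx(1.0 / np.sqrt(3))
    assert s.max == 3.0 and s.n == 3


def test_cohort_summary_empty_rejected():
    with pytest.raises(ParameterError):
        cohort_summary([])


def test_cohort_matches_programmed_moments():
    """Sampling oracle: recovered peak elevations of a jittered synthetic
    cohort reproduce the programmed ground-truth moments."""
    chain = build_preset("frogfish", n_vertebrae=6)
    prog = JointProgram({1: JointRamp(18.0, onset_s=0.01, rise_s=0.03),
                         2: JointRamp(24.0, onset_s=0.01, rise_s=0.03)})
    strikes = strike_cohort(chain, prog, n=18, seed=11,
                            amplitude_jitter_frac=0.1)
    peaks, truth = [], []
    for st in strikes:
        res = analyze_strike(st, use_markers=True, filtering=False)
        peaks.append(res.elevation.peak_deg)
        truth.append(st.ground_truth["elevation_deg"].max())
    s = cohort_summary(peaks)
    st_truth = cohort_summary(truth)
    assert s.mean == pytest.approx(st_truth.mean, abs=1e-6)
    assert s.se == pytest.approx(st_truth.se, abs=1e-6)
    assert s.max == pytest.approx(st_truth.max, abs=1e-6)


def _mk_trace(values, onset=0):
    v = np.asarray(values, dtype=float)
    return ElevationTrace(v, 500.0, float(np.max(v)), int(np.argmax(v)),
                          onset, 0.0)


def test_mean_trace_identical_inputs():
    tr = _mk_trace([0, 1, 2, 3])
    t, m = mean_trace([tr, tr])
    np.testing.assert_allclose(m, [0, 1, 2, 3])


def test_mean_trace_scaling():
    a = _mk_trace([0.0, 2.0, 4.0])
    b = _mk_trace([0.0, 4.0, 8.0])
    _, m = mean_trace([a, b])
    np.testing.assert_allclose(m, [0.0, 3.0, 6.0])  # 1.5x the smaller trace


def test_mean_trace_defined_only_where_two_overlap():
    a = _mk_trace([0.0, 1.0, 2.0, 3.0, 4.0])
    b = _mk_trace([0.0, 1.0, 2.0])
    t, m = mean_trace([a, b])
    assert len(m) == 3  # trailing frames covered by one strike are dropped


# ---------------------------------------------------------------------------
# Planar additivity and noise robustness (pipeline invariants)
# ---------------------------------------------------------------------------

def test_planar_additivity_peak_equals_sum(frogfish_chain):
    amps = {1: 18.0, 2: 24.0, 3: 5.0}
    prog = JointProgram({k: JointRamp(a, onset_s=0.01, rise_s=0.03)
                         for k, a in amps.items()})
    strike = simulate_strike(frogfish_chain, prog, duration_s=0.06)
    res = analyze_strike(strike, use_markers=True, filtering=False)
    assert res.elevation.peak_deg == pytest.approx(sum(amps.values()),
                                                   abs=1e-6)


def test_noisy_filtered_recovery_within_half_degree(frogfish_chain):
    """sigma = 0.05 mm markers with filtering on: craniovertebral and first
    intervertebral deltas recovered within 0.5 deg (small replicate count
    here; the full 20-replicate check runs in the acceptance suite)."""
    prog = preset_program("frogfish")
    strikes = strike_cohort(frogfish_chain, prog, n=4, seed=0,
                            amplitude_jitter_frac=0.15,
                            noise=NoiseModel(sigma_mm=0.05))
    for st in strikes:
        res = analyze_strike(st, use_markers=True, filtering=True)
        pf = res.elevation.peak_frame
        for k in (1, 2):
            gt = st.ground_truth["joint_angles_deg"][k]
            truth = gt[pf, 0] - gt[0, 0]
            assert abs(res.deltas_deg[k - 1] - truth) < 0.5
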