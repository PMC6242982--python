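"""Shared synthetic-data fixtures.

Heavy end-to-end runs are session-scoped so the movie is simulated and
analyzed once and reused by the module tests and the acceptance tests.
"""
import numpy as np
import pytest

from pvsflow import pipeline, synthetic
from pvsflow import tracking


@pytest.fixture(scope="session")
def std_run():
    """Standard 30 s pulsatile-flow movie at the reported mean speed, analyzed end to end."""
    scenario = synthetic.FlowScenario(seed=0, duration=30.0, jitter_amplitude=0.5)
    config = pipeline.RunConfig()
    result, truth = pipeline.run_synthetic_experiment(config, scenario)
    return scenario, result, truth


@pytest.fixture(scope="session")
def sparse_movie():
    """Short well-separated movie (no stuck particles, no jitter) for tracking tests."""
    scenario = synthetic.FlowScenario(seed=11, duration=5.0, n_particles=30,
                                      stuck_fraction=0.0, jitter_amplitude=0.0)
    stack, truth = synthetic.generate_flow_movie(scenario)
    return scenario, stack, truth


@pytest.fixture(scope="session")
def tracked_sparse(sparse_movie):
    """Detections and predictive-linked tracks for the sparse movie."""
    scenario, stack, truth = sparse_movie
    frames = stack.channel(1).data.astype(float)
    detections = [tracking.detect_particles(f, 60.0, 3) for f in frames]
    tracks = tracking.link_tracks(detections, max_displacement=5.0, predictive=True)
    tracks = [tracking.compute_velocities(t, scenario.frame_rate, scenario.pixel_size)
              for t in tracks]
    return detections, tracks


@pytest.fixture(scope="session")
def jittered_movie():
    """Short movie with rigid frame jitter for registration round-trips."""
    scenario = synthetic.FlowScenario(seed=5, duration=4.0, jitter_amplitude=0.8)
    stack, truth = synthetic.generate_flow_movie(scenario)
    return scenario, stack, truth


@pytest.fixture(scope="session")
def wall_run():
    """Line scans generated at the reported peak wall velocity and R-peak lag."""
    from pvsflow import wall_kinematics
    scenario = synthetic.WallScenario.for_peak_wall_velocity(
        21.2, wall_lag=0.0345, duration=45.0, seed=0)
    kymo, truth = synthetic.generate_linescan(scenario)
    waveform = wall_kinematics.analyze_kymograph(
        kymo, scenario.linescan_rate, scenario.pixel_size,
        truth.true_peak_times["ecg"])
    return scenario, kymo, truth, waveform


@pytest.fixture(scope="session")
def vrms_run():
    """Synthetic v_rms locked to ECG at the reported modulation depths."""
    from pvsflow import physio_sync
    times, vrms, record, truth = synthetic.generate_vrms_series(seed=0)
    cond = physio_sync.conditional_average(vrms, times, record.r_peak_times,
                                           record.respiration_peak_times)
    return times, vrms, record, truth, cond
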