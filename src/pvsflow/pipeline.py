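"""End-to-end orchestration: registration → tracking → statistics → sync → summary.

A :class:`RunConfig` carries every threshold of the analysis with its
standard default (7.5 px boxes, ≥ 20 measurements per bin, ≥ 80 non-stagnant
bins, ~2 µm/s track filter, 99.5th-percentile stagnant mask, order-8 Fourier
fit), round-trips losslessly through JSON, and seeds all randomness.
Exclusion rules fire exactly as in the source protocol (registration
failure, too few valid bins) and are logged with the triggering rule.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import flow_stats, geometry_scaling, physio_sync, registration, tracking
from . import synthetic, wall_kinematics
from .flow_stats import FlowSummary, VelocityField, VrmsSeries
from .io import ImageStack
from .physio_sync import ConditionalAverage, PhysioRecord
from .wall_kinematics import DiameterWaveform

log = logging.getLogger("pvsflow")


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, with their standard defaults."""

    pixel_size: float = 1.0            # µm/px
    frame_rate: float = 30.0           # Hz
    mask_quantile: float = 0.995       # stagnant-mask threshold quantile
    min_track_speed: float = 2.0       # µm/s, slow-track filter
    box_px: float = 7.5                # velocity-field box size
    min_box_count: int = 20            # measurements per valid bin
    min_valid_bins: int = 80           # QC exclusion rule
    detection_threshold: float | None = None   # None → robust automatic
    min_separation: int = 3            # px between detections
    max_displacement: float = 5.0      # px linking gate
    predictive_linking: bool = True    # extrapolate tracks before matching
    registration_outlier_px: float = 3.0
    registration_upsample: int = 50
    fourier_order: int = 8
    cardiac_bins: int = 25
    respiratory_bins: int = 10
    wall_bins: int = 50
    delay_bin_s: float = 0.010
    pvs_width_um: float = 44.0         # L for Re/Pe when not measured
    seed: int = 0
    output_dir: str | None = None

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(**payload)


@dataclass
class ExperimentResult:
    """Everything one end-to-end run produces."""

    config: RunConfig
    summary: FlowSummary | None = None
    field: VelocityField | None = None
    vrms: VrmsSeries | None = None
    conditional: ConditionalAverage | None = None
    waveform: DiameterWaveform | None = None
    numbers: geometry_scaling.DimensionlessNumbers | None = None
    translations: registration.TranslationSeries | None = None
    measurements: "object | None" = None       # DataFrame
    downstream: np.ndarray | None = None
    excluded: bool = False
    exclusion_rule: str | None = None


@dataclass
class ConditionComparison:
    """Normal-vs-altered condition deltas (e.g. normotensive vs hypertensive)."""

    speed_change_percent: float        # 100 × (B − A)/A on the mean flow speed
    backflow_change_points: float | None
    summary_a: FlowSummary | None = None
    summary_b: FlowSummary | None = None
    waveform_a: DiameterWaveform | None = None
    waveform_b: DiameterWaveform | None = None


def _auto_threshold(frames: np.ndarray) -> float:
    """Robust detection threshold: median + 10 scaled MADs of the first frame."""
    sample = frames[0].astype(float)
    med = np.median(sample)
    mad = np.median(np.abs(sample - med))
    return float(med + 10.0 * 1.4826 * max(mad, 1.0))


def run_experiment(config: RunConfig, stack: ImageStack,
                   physio: PhysioRecord | None = None,
                   kymograph: np.ndarray | None = None,
                   kymograph_rate: float | None = None,
                   register: bool = True) -> ExperimentResult:
    """Execute the full analysis chain on a two-channel movie.

    Stages: rigid registration (vessel channel) → stagnant mask → detection,
    linking, velocities (microsphere channel) → slow-track filter → binned
    velocity field, U, v_rms, downstream components → cardiac/respiratory
    conditional averaging (when a physiological record is given) → wall
    kinematics (when a kymograph is given) → Re/Pe/D. QC failures mark the
    run excluded with the rule name instead of raising.
    """
    result = ExperimentResult(config=config)
    cfg = config

    if register:
        try:
            stack, series = registration.register_stack(
                stack, channel=0, upsample_factor=cfg.registration_upsample,
                outlier_threshold=cfg.registration_outlier_px)
            result.translations = series
        except registration.RegistrationError as err:
            log.warning("run excluded: image registration failed (%s)", err)
            result.excluded = True
            result.exclusion_rule = "registration_failure"
            return result

    spheres = stack.channel(stack.n_channels - 1).data.astype(float)
    mask = tracking.make_stagnant_mask(spheres, cfg.mask_quantile)

    threshold = cfg.detection_threshold or _auto_threshold(spheres)
    detections = [tracking.detect_particles(frame, threshold, cfg.min_separation)
                  for frame in spheres]
    tracks = tracking.link_tracks(detections, cfg.max_displacement,
                                  predictive=cfg.predictive_linking)
    tracks = [tracking.compute_velocities(t, cfg.frame_rate, cfg.pixel_size)
              for t in tracks]
    tracks = tracking.filter_slow_tracks(tracks, cfg.min_track_speed)
    df = tracking.tracks_to_dataframe(tracks)
    df = tracking.exclude_masked(df, mask)
    result.measurements = df
    if len(df) == 0:
        log.warning("run excluded: no velocity measurements")
        result.excluded = True
        result.exclusion_rule = "insufficient_valid_bins"
        return result

    field = flow_stats.bin_velocities(df, cfg.box_px, cfg.min_box_count,
                                      shape_px=spheres.shape[1:])
    result.field = field
    n_bins, qc_ok = flow_stats.qc_nonstagnant_bins(field, mask.mask,
                                                   cfg.min_valid_bins)
    if not qc_ok:
        log.warning("run excluded: %d non-stagnant bins with sufficient "
                    "measurements (< %d required)", n_bins, cfg.min_valid_bins)
        result.excluded = True
        result.exclusion_rule = "insufficient_valid_bins"
        result.summary = FlowSummary(mean_speed=np.nan, pvs_width=None,
                                     backflow_percent=None,
                                     n_valid_bins=n_bins, qc_pass=False)
        return result

    U = flow_stats.mean_flow_speed(field)
    result.vrms = flow_stats.vrms_series(df, stack.n_frames, cfg.frame_rate)
    downstream, n_skipped = flow_stats.downstream_component(df, field)
    if n_skipped:
        log.info("%d measurements outside defined û_avg skipped", n_skipped)
    result.downstream = downstream
    backflow = flow_stats.backflow_percent(downstream)
    result.summary = FlowSummary(mean_speed=U, pvs_width=cfg.pvs_width_um,
                                 backflow_percent=backflow,
                                 n_valid_bins=n_bins, qc_pass=True)
    result.numbers = geometry_scaling.dimensionless_numbers(
        geometry_scaling.ScalingInputs(U=U * 1e-6, L=cfg.pvs_width_um * 1e-6))

    if physio is not None:
        if physio.r_peak_times is None:
            physio.detect_peaks()
        if physio.respiration_peak_times is not None:
            result.conditional = physio_sync.conditional_average(
                result.vrms.vrms, result.vrms.time,
                physio.r_peak_times, physio.respiration_peak_times,
                n_bins=(cfg.cardiac_bins, cfg.respiratory_bins))

    if kymograph is not None:
        if physio is None or physio.r_peak_times is None:
            raise ValueError("wall kinematics requires a physio record with R peaks")
        result.waveform = wall_kinematics.analyze_kymograph(
            kymograph, kymograph_rate or 600.0, cfg.pixel_size,
            physio.r_peak_times, n_bins=cfg.wall_bins,
            fourier_order=cfg.fourier_order)

    return result


def run_synthetic_experiment(config: RunConfig,
                             scenario: synthetic.FlowScenario,
                             wall_scenario: synthetic.WallScenario | None = None
                             ) -> tuple[ExperimentResult, synthetic.GroundTruth]:
    """Generate a synthetic movie from a scenario and analyze it end-to-end.

    The scenario's own pixel size and frame rate override the config copies;
    the R-peak times driving the generator serve as the ECG peak record.
    """
    cfg = dataclasses.replace(config, pixel_size=scenario.pixel_size,
                              frame_rate=scenario.frame_rate)
    stack, truth = synthetic.generate_flow_movie(scenario)
    physio = PhysioRecord(ecg=np.zeros(2001), ecg_rate=1000.0,
                          r_peak_times=truth.true_peak_times["ecg"])
    kymo = None
    rate = None
    if wall_scenario is not None:
        kymo, wall_truth = synthetic.generate_linescan(wall_scenario)
        rate = wall_scenario.linescan_rate
        truth.arrays["wall"] = wall_truth.params
        physio = PhysioRecord(ecg=np.zeros(2001), ecg_rate=1000.0,
                              r_peak_times=wall_truth.true_peak_times["ecg"])
    result = run_experiment(cfg, stack, physio=physio, kymograph=kymo,
                            kymograph_rate=rate,
                            register=scenario.jitter_amplitude > 0)
    return result, truth


def compare_conditions(a: ExperimentResult, b: ExperimentResult) -> ConditionComparison:
    """Percent flow-speed change and backflow-percent difference between conditions.

    Stagnant or nearly stagnant boxes (time-averaged speed below the track
    stagnation threshold) are excluded from the speed change.
    """
    if a.config != b.config:
        raise ValueError("conditions analyzed with different configs are not comparable")
    if a.field is None or b.field is None:
        raise ValueError("both runs must carry velocity fields")
    ua = flow_stats.mean_flow_speed(a.field, min_box_speed=flow_stats.STAGNANT_SPEED)
    ub = flow_stats.mean_flow_speed(b.field, min_box_speed=flow_stats.STAGNANT_SPEED)
    change = 100.0 * (ub - ua) / ua
    backflow_change = None
    if (a.summary and b.summary and a.summary.backflow_percent is not None
            and b.summary.backflow_percent is not None):
        backflow_change = b.summary.backflow_percent - a.summary.backflow_percent
    return ConditionComparison(speed_change_percent=change,
                               backflow_change_points=backflow_change,
                               summary_a=a.summary, summary_b=b.summary,
                               waveform_a=a.waveform, waveform_b=b.waveform)
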