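"""End-to-end orchestration of one participant's processing.

Stages, in protocol order: calibration on pre-resampled raw samples →
uniform resampling with the >5 s gap rule → Euclidean norm → 20 Hz low-pass
→ gravity removal (truncated ENMO by default) → 5-s epochs → non-wear
detection on the calibrated stationary windows → wear flagging → inclusion
check → diurnal imputation → intensity ECDF → participant summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .calibration import (CalibrationModel, CalibrationRegistry,
                          apply_calibration, find_stationary_windows,
                          resolve_calibration)
from .config import PipelineConfig
from .raw_io import RawRecording
from .signal_chain import (lowpass_noise_filter, remove_gravity,
                           resample_with_gaps, vector_magnitude)
from .summaries import ParticipantSummary, summarize_participant
from .wear_epochs import (EpochSeries, InclusionResult, IntensityECDF,
                          check_inclusion, detect_nonwear, flag_wear,
                          impute_nonwear, intensity_ecdf, make_epochs)


@dataclass
class PipelineResult:
    epochs: EpochSeries
    summary: ParticipantSummary
    inclusion: InclusionResult
    calibration: CalibrationModel
    ecdf: IntensityECDF
    nonwear_episodes: list


def run_pipeline(rec: RawRecording,
                 config: PipelineConfig,
                 registry: Optional[CalibrationRegistry] = None,
                 participant_id: Optional[str] = None,
                 gravity_mode: str = "enmo_trunc") -> PipelineResult:
    model = resolve_calibration(rec, registry, config)
    rec_cal = apply_calibration(rec, model, config)
    windows_cal = find_stationary_windows(rec_cal, config)

    tri = resample_with_gaps(rec_cal, config)
    vm = vector_magnitude(tri)
    vm = lowpass_noise_filter(vm, config)
    activity = remove_gravity(vm, gravity_mode, config)

    epochs = make_epochs(activity, config)
    episodes = detect_nonwear(windows_cal, config)
    epochs = flag_wear(epochs, episodes)
    inclusion = check_inclusion(epochs, config)
    epochs = impute_nonwear(epochs, config)
    ecdf = intensity_ecdf(epochs, config)

    summary = summarize_participant(
        epochs,
        participant_id=participant_id or rec.device_id,
        config=config,
        quality=rec_cal.quality,
        ecdf=ecdf,
        inclusion=inclusion,
    )
    return PipelineResult(
        epochs=epochs, summary=summary, inclusion=inclusion,
        calibration=model, ecdf=ecdf, nonwear_episodes=episodes,
    )
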