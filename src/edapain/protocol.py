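"""Heat-pain stimulation protocol: timing constants and temperature calibration.

The emulated protocol follows the BioVid-style design: 90 recruited subjects
(3 excluded for technical reasons), five stimulus classes T0..T4, each
delivered 20 times for 4 s with a randomized 8-12 s pain-free interval, skin
conductance sampled at 512 Hz and segmented into 5.5 s windows of 2,816
samples.

Per subject, the pain threshold temperature ``T_P`` and tolerance ``T_T`` are
determined by calibration and the intermediate stages are spaced by a step
``gamma = (T_T - T_P) / 4``.  The published stage formula
``T_i = T_P + (i - 1) * gamma`` is anchored so that stage 1 equals ``T_P`` and
stage 4 equals ``T_T`` (the two definitions are reconciled by pinning the top
stage to the tolerance temperature; see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field


class OrderingError(ValueError):
    """Calibration temperatures are not strictly increasing."""


@dataclass(frozen=True)
class ProtocolConfig:
    """Stimulation-protocol constants.

    Defaults reproduce the emulated heat-pain study design.
    """

    n_recruited: int = 90
    n_excluded: int = 3
    classes: int = 5
    reps_per_class: int = 20
    sampling_rate: float = 512.0
    segment_duration: float = 5.5
    stimulus_duration: float = 4.0
    interval_range: tuple[float, float] = (8.0, 12.0)
    baseline_temp: float = 32.0

    def __post_init__(self) -> None:
        n = self.sampling_rate * self.segment_duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"sampling_rate * segment_duration must be an integer, got {n}"
            )
        lo, hi = self.interval_range
        if not lo < hi:
            raise ValueError(f"interval_range must satisfy lo < hi, got {lo}, {hi}")
        for name in ("segment_duration", "stimulus_duration", "sampling_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_excluded >= self.n_recruited:
            raise ValueError("n_excluded must be smaller than n_recruited")

    @property
    def n_subjects(self) -> int:
        """Usable subjects after exclusions."""
        return self.n_recruited - self.n_excluded

    @property
    def samples_per_segment(self) -> int:
        return round(self.sampling_rate * self.segment_duration)

    @property
    def segments_per_subject(self) -> int:
        return self.classes * self.reps_per_class


@dataclass(frozen=True)
class TemperatureCalibration:
    """Per-subject stimulus temperatures.

    ``stages[0]`` is the pain-free baseline, ``stages[1] = T_P`` (pain
    threshold) and ``stages[4] = T_T`` (pain tolerance); the interior stages
    step by ``gamma_step = (T_T - T_P) / 4``.
    """

    T_P: float
    T_T: float
    gamma_step: float
    stages: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.stages) != 5:
            raise ValueError("calibration must define exactly 5 stages")
        if any(b < a for a, b in zip(self.stages, self.stages[1:])):
            raise OrderingError(f"stages must be nondecreasing: {self.stages}")


def compute_temperature_stages(
    T_P: float, T_T: float, baseline: float = 32.0
) -> TemperatureCalibration:
    """Compute the five stimulus temperatures from a subject's calibration.

    Parameters
    ----------
    T_P : pain threshold in deg C (stage 1).
    T_T : pain tolerance in deg C (stage 4).
    baseline : pain-free temperature in deg C (stage 0).

    Returns
    -------
    TemperatureCalibration with ``gamma_step = (T_T - T_P) / 4`` and stages
    ``[baseline, T_P, T_P + gamma, T_P + 2*gamma, T_T]``.  The top stage is
    anchored to ``T_T`` rather than ``T_P + 3*gamma`` so that stage 4 is the
    tolerance temperature by definition.

    Raises
    ------
    OrderingError if ``baseline < T_P < T_T`` does not hold.
    """
    if not (T_T > T_P > baseline):
        raise OrderingError(
            f"need T_T > T_P > baseline, got T_T={T_T}, T_P={T_P}, baseline={baseline}"
        )
    gamma = (T_T - T_P) / 4.0
    stages = (baseline, T_P, T_P + gamma, T_P + 2.0 * gamma, T_T)
    return TemperatureCalibration(T_P=T_P, T_T=T_T, gamma_step=gamma, stages=stages)
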