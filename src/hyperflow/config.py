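"""Study-design constants and configuration objects.

``SimConfig`` holds the constants of the hyperscanning study design: trial
structure (30-s rest phase followed by a play phase), task-irrelevant beep
trains (5 beeps at 5 Hz, every 4-8 s), the 256 Hz sampling rate, the 14
region groups per brain, and the condition-dependent neural effects the
generator injects (ERP attenuation, band-power offsets, directed intra-brain
coupling, interbrain phase coupling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

#: The three experimental conditions, in canonical order.
CONDITIONS: tuple[str, str, str] = ("TeamFlow", "TeamOnly", "FlowOnly")

#: Highest analysis frequency (Hz); the combined beta/low-gamma band tops out here.
MAX_ANALYSIS_FREQ = 50.0

#: Region index used as the team-flow marker region ("L-MTC" analogue).
MARKER_REGION = 13


def _default_erp_attenuation() -> dict[str, float]:
    # Deeper flow -> weaker beep response.  Flow is deepest in TeamFlow,
    # intermediate in FlowOnly, absent in TeamOnly.
    return {"TeamFlow": 0.3, "FlowOnly": 0.6, "TeamOnly": 1.0}


def _default_band_power_offsets() -> dict[tuple[str, int], float]:
    # +2 dB beta/low-gamma power at the marker region, TeamFlow only.
    return {("TeamFlow", MARKER_REGION): 2.0}


def _default_intra_coupling() -> dict[str, list[tuple[int, int, int, float]]]:
    # Directed edges (source, target, lag, coefficient).  In TeamFlow the
    # marker region receives from two sender regions, making it the
    # information sink the causality stage should recover.
    return {
        "TeamFlow": [(0, MARKER_REGION, 1, 0.25), (4, MARKER_REGION, 1, 0.25)],
        "TeamOnly": [],
        "FlowOnly": [],
    }


def _default_inter_coupling() -> dict[str, float]:
    # Amplitude of the shared band-limited component added to both brains,
    # in units of the receiving region's standard deviation.
    return {"TeamFlow": 0.8, "TeamOnly": 0.0, "FlowOnly": 0.0}


@dataclass
class SimConfig:
    """Design constants and injected effect sizes for a synthetic study.

    Durations are seconds, rates Hz.  ``erp_attenuation_by_condition`` maps
    condition name to a factor in [0, 1] multiplying the evoked-response
    template during the play phase (rest-phase responses are always at full
    amplitude, mirroring the flow state being confined to play).
    """

    n_pairs: int = 10
    n_songs: int = 6
    sampling_rate: float = 256.0
    rest_duration: float = 30.0
    play_duration: float = 120.0
    beep_interval_range: tuple[float, float] = (4.0, 8.0)
    beep_train_rate: float = 5.0
    beep_train_duration: float = 1.0
    n_regions_per_brain: int = 14
    erp_attenuation_by_condition: dict[str, float] = field(
        default_factory=_default_erp_attenuation
    )
    band_power_offsets: dict[tuple[str, int], float] = field(
        default_factory=_default_band_power_offsets
    )
    intra_coupling: dict[str, list[tuple[int, int, int, float]]] = field(
        default_factory=_default_intra_coupling
    )
    inter_coupling: dict[str, float] = field(default_factory=_default_inter_coupling)
    #: Matched region pairs carrying the shared interbrain component;
    #: ``None`` couples every region to its homologue in the other brain.
    inter_coupling_pairs: Sequence[tuple[int, int]] | None = None
    #: Optional lag (s) of the shared component in brain B relative to
    #: brain A.  Zero (the default) maximises both phase locking and
    #: integrated information of the coupled pair; phase locking is
    #: invariant to the lag (per-frequency phase offsets stay constant in
    #: time).
    inter_coupling_lag: float = 0.0
    #: Amplitude of the per-region band-limited (13-50 Hz) component whose
    #: gain the dB offsets modulate.
    band_component_amplitude: float = 0.5
    erp_amplitude: float = 1.0
    noise_sd: float = 1.0
    sensor_noise_sd: float = 0.3
    n_sensors: int = 32
    emit_sensors: bool = False
    seed: int = 0

    def validate(self) -> None:
        """Raise ``ValueError`` naming the offending field if invalid."""
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")
        if self.n_songs < 0:
            raise ValueError("n_songs must be >= 0")
        for name in ("rest_duration", "play_duration", "beep_train_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        lo, hi = self.beep_interval_range
        if not (0 < lo <= hi):
            raise ValueError("beep_interval_range must satisfy 0 < min <= max")
        if lo < self.beep_train_duration:
            raise ValueError(
                "beep_interval_range min must be >= beep_train_duration"
            )
        if self.sampling_rate <= 2 * MAX_ANALYSIS_FREQ:
            raise ValueError(
                "sampling_rate must exceed twice the highest analysis "
                f"frequency ({MAX_ANALYSIS_FREQ} Hz)"
            )
        if self.n_regions_per_brain < 1:
            raise ValueError("n_regions_per_brain must be >= 1")
        for cond, a in self.erp_attenuation_by_condition.items():
            if not 0.0 <= a <= 1.0:
                raise ValueError(
                    f"erp_attenuation_by_condition[{cond!r}] must be in [0, 1]"
                )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def beeps_per_train(self) -> int:
        """Number of beeps in one train (rate x duration)."""
        return int(round(self.beep_train_rate * self.beep_train_duration))

    @property
    def coupling_pairs(self) -> list[tuple[int, int]]:
        if self.inter_coupling_pairs is not None:
            return list(self.inter_coupling_pairs)
        return [(r, r) for r in range(self.n_regions_per_brain)]


def bonferroni_threshold(alpha: float, n_comparisons: int, digits: int = 5) -> float:
    """Bonferroni-corrected per-comparison threshold, rounded for reporting.

    The source-level ROI analysis corrects alpha = 0.05 across 148 regions,
    giving the printed critical value 0.00034.
    """
    return round(alpha / n_comparisons, digits)


def downsample_step_ms(rate_hz: float, digits: int = 1) -> float:
    """Time step in milliseconds for a down-sampled rate (12.8 Hz -> 78.1 ms)."""
    return round(1000.0 / rate_hz, digits)


DOWNSAMPLE_FACTORS: tuple[int, ...] = (5, 10, 15, 20)
"""Down-sampling factors at 256 Hz giving 51.2, 25.6, 17.1 and 12.8 Hz steps."""


def check_conditions(mapping: Mapping[str, object]) -> None:
    missing = [c for c in CONDITIONS if c not in mapping]
    if missing:
        raise ValueError(f"missing conditions: {missing}")
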