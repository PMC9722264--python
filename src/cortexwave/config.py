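"""Simulation configuration.

:class:`SimConfig` collects every tunable of the synthetic-data generator.
The defaults are the study conditions the analysis pipeline is validated
against: slow waves around 0.1 Hz with a 2-s refractory period, propagation
at 30.5 +/- 5.3 mm/s mostly in the anterior-posterior direction (anterior
origin in 60% of events), a 90% probability that a stimulus delivered
outside the refractory window evokes a wave, modality- and site-specific
evoked onset latencies (e.g. 98 ms for forepaw -> S1, 115 ms for
visual -> V1), and evoked response areas of ~23 mm^2 during slow-wave
activity versus ~7 mm^2 during persistent activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Tuple

import yaml

#: Primary sensory cortex for each stimulus modality.
PRIMARY_SITE: Dict[str, str] = {"somatosensory": "S1", "visual": "V1"}

#: Mean evoked wave-onset latency (ms), keyed (modality, site).  Plain
#: "S1"/"V1" denote the hemisphere contralateral to the stimulus (the
#: simulated configuration); "_ipsi" entries are reference metadata.
EVOKED_LATENCY_MS: Dict[Tuple[str, str], float] = {
    ("somatosensory", "S1"): 98.0,
    ("somatosensory", "V1_ipsi"): 204.0,
    ("somatosensory", "V1"): 228.0,
    ("visual", "V1"): 115.0,
    ("visual", "S1_ipsi"): 263.0,
    ("visual", "S1"): 288.0,
}

#: Per-stimulus latency jitter SD (ms), same keys.
EVOKED_LATENCY_SE_MS: Dict[Tuple[str, str], float] = {
    ("somatosensory", "S1"): 7.0,
    ("somatosensory", "V1_ipsi"): 7.0,
    ("somatosensory", "V1"): 8.0,
    ("visual", "V1"): 4.0,
    ("visual", "S1_ipsi"): 10.0,
    ("visual", "S1"): 11.0,
}

#: Evoked response area (mm^2), keyed (state, modality).
EVOKED_AREA_MM2: Dict[Tuple[str, str], float] = {
    ("SWA", "visual"): 22.8,
    ("SWA", "somatosensory"): 23.1,
    ("PA", "visual"): 6.9,
    ("PA", "somatosensory"): 7.5,
}

#: Mean propagation direction of evoked waves (rad; 0 = anterior,
#: +pi/2 = lateral).  Visual waves run anterolaterally from V1;
#: somatosensory waves run mostly posteromedially from S1.
EVOKED_DIRECTION_RAD: Dict[str, float] = {
    "visual": math.pi / 6,
    "somatosensory": -5 * math.pi / 6,
}


@dataclass
class SimConfig:
    """Generator parameters; defaults reproduce the reference conditions.

    Attributes
    ----------
    state : str
        ``"SWA"`` (bimodal slow-wave activity) or ``"PA"`` (persistent
        activity).
    duration_s : float
        Length of the simulated recording.
    fs_trace_hz : float
        Sampling rate of photometry and LFP traces (Hz).
    frame_rate_hz : float
        Wide-field movie frame rate (Hz).
    wave_rate_per_min : float
        Mean spontaneous slow-wave rate (waves/min); 10/min ~ 0.17 Hz wave
        onsets, i.e. "slow waves around 0.1 Hz".
    refractory_s : float
        Hard refractory period tau_r after each wave (s).
    anterior_origin_prob : float
        Probability that a spontaneous wave originates at the anterior
        (S1-level) band rather than the posterior (V1-level) band.
    speed_mean_mm_s, speed_sd_mm_s : float
        Propagation speed distribution (truncated normal, > 0).
    p_evoke : float
        Probability a stimulus outside the refractory window evokes a wave.
    p_refractory : float
        Success probability inside the refractory window.
    noise_sd : float
        Additive Gaussian noise SD, as a fraction of the event amplitude.
    """

    state: str = "SWA"
    duration_s: float = 600.0
    fs_trace_hz: float = 2000.0
    frame_rate_hz: float = 20.0
    seed: int = 0

    # spontaneous slow-wave process
    wave_rate_per_min: float = 10.0
    refractory_s: float = 2.0
    anterior_origin_prob: float = 0.6
    speed_mean_mm_s: float = 30.5
    speed_sd_mm_s: float = 5.3
    origin_ml_jitter_mm: float = 0.3
    direction_jitter_rad: float = 0.26

    # stimulus-evoked waves
    p_evoke: float = 0.90
    p_refractory: float = 0.2
    evoked_latency_ms: Dict[Tuple[str, str], float] = field(
        default_factory=lambda: dict(EVOKED_LATENCY_MS)
    )
    evoked_latency_se_ms: Dict[Tuple[str, str], float] = field(
        default_factory=lambda: dict(EVOKED_LATENCY_SE_MS)
    )
    evoked_area_mm2: Dict[Tuple[str, str], float] = field(
        default_factory=lambda: dict(EVOKED_AREA_MM2)
    )
    evoked_direction_rad: Dict[str, float] = field(
        default_factory=lambda: dict(EVOKED_DIRECTION_RAD)
    )
    refractory_latency_jitter_factor: float = 3.0

    # calcium kernel (typical OGB-1 / GCaMP6 scale)
    tau_rise_s: float = 0.05
    tau_decay_s: float = 1.0
    amplitude: float = 1.0
    baseline_fluorescence: float = 1.0
    noise_sd: float = 0.05

    # persistent-activity state
    pa_band_hz: float = 15.0
    pa_band_halfwidth_hz: float = 5.0
    pa_fluct_amplitude: float = 0.10
    pa_evoked_amplitude: float = 0.30
    pa_evoked_latency_ms: float = 25.0
    pa_evoked_latency_sd_ms: float = 5.0
    pa_tau_rise_s: float = 0.01
    pa_tau_decay_s: float = 0.15

    # LFP rendering
    lfp_noise_floor: float = 0.02
    lfp_burst_amp: float = 1.0
    lfp_burst_band: Tuple[float, float] = (0.5, 100.0)
    lfp_tau_rise_s: float = 0.02
    lfp_tau_decay_s: float = 0.3
    lfp_gamma_amp: float = 0.5
    lfp_gamma_band: Tuple[float, float] = (35.0, 200.0)
    lfp_pa_narrowband_amp: float = 0.3
    lfp_pa_broadband_amp: float = 0.1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.state not in ("SWA", "PA"):
            raise ValueError(f"state must be 'SWA' or 'PA', got {self.state!r}")
        for name in ("duration_s", "fs_trace_hz", "frame_rate_hz",
                     "wave_rate_per_min", "speed_mean_mm_s", "amplitude",
                     "tau_rise_s", "tau_decay_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("refractory_s", "noise_sd", "speed_sd_mm_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("p_evoke", "p_refractory", "anterior_origin_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if 60.0 / self.wave_rate_per_min <= self.refractory_s:
            raise ValueError("mean inter-wave interval must exceed refractory_s")

    @property
    def mean_iei_s(self) -> float:
        """Mean inter-event interval of the spontaneous wave process (s)."""
        return 60.0 / self.wave_rate_per_min

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("evoked_latency_ms", "evoked_latency_se_ms", "evoked_area_mm2"):
            d[key] = {"/".join(k): v for k, v in d[key].items()}
        d["lfp_burst_band"] = list(d["lfp_burst_band"])
        d["lfp_gamma_band"] = list(d["lfp_gamma_band"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("evoked_latency_ms", "evoked_latency_se_ms", "evoked_area_mm2"):
            if key in d:
                d[key] = {tuple(k.split("/")): v for k, v in d[key].items()}
        for key in ("lfp_burst_band", "lfp_gamma_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
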