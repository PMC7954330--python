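"""Pharmacological condition presets for the synthetic recording generator.

Each preset is a :class:`ConditionSpec` whose parameters encode the summary
statistics observed for that perfusion condition in paired CA3/CA1
hippocampal slice recordings: spontaneous discharges in synaptic-blockers
aCSF (AMPA/NMDA/GABA-A antagonists) at 2.36 min⁻¹ with ~1.07 s duration and
48% of slices bursting; desynchronized nonsynaptic population spikes in
low-Ca²⁺ aCSF; Cd²⁺ blockade of synchronous discharges (45.5% immediate,
otherwise a 4.09 ± 2.60 min latency); mecamylamine/d-tubocurarine blockade
with latency; no-effect antagonists (atropine, MLA, DhβE); and regular
seizure-like activity (SLA) induced by bicuculline or 4-AP.

Quantities the source experiments do not constrain (field-event amplitude
distributions, population-spike rates, coupling delay/jitter, noise level)
are free parameters of the generator; their defaults are documented in
``docs/methods.md``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass(frozen=True)
class ConditionSpec:
    """Generator parameter set for one pharmacological condition.

    Rates are per minute, durations and delays in seconds unless the field
    name says otherwise, amplitudes in mV.  ``sla_frequency > 0`` switches
    the condition into regular-SLA mode (near-periodic event trains) and the
    renewal-process fields are ignored.  A block model is active when
    ``block_immediate_prob > 0`` or ``block_delay_mean_min > 0``.
    """

    name: str
    # --- single-discharge renewal process ---
    discharge_rate: float = 2.36            # events/min
    discharge_duration_mean: float = 1.07   # s
    discharge_duration_sd: float = 0.34     # s
    discharge_amplitude_mean_ca3: float = 2.0   # mV
    discharge_amplitude_sd_ca3: float = 1.0     # mV
    discharge_amplitude_mean_ca1: float = 1.5   # mV
    discharge_amplitude_sd_ca1: float = 0.75    # mV
    # --- bursting (per-slice trait) ---
    burst_probability: float = 0.0          # fraction of slices with bursts
    burst_rate: float = 0.375               # bursts/min within bursting slices
    burst_duration_mean: float = 35.61      # s
    burst_duration_sd: float = 12.67        # s
    intraburst_frequency_mean: float = 0.52  # Hz
    intraburst_frequency_sd: float = 0.28    # Hz
    burst_leader_amplitude_factor: float = 2.0
    # --- CA3 -> CA1 event coupling ---
    coupling_delay: float = 0.005           # s
    coupling_jitter_sd: float = 0.002       # s
    coupling_failure_prob: float = 0.05
    # --- nonsynaptic population spikes (independent per channel) ---
    popspike_rate_ca3: float = 0.0          # events/min
    popspike_rate_ca1: float = 0.0          # events/min
    popspike_duration: float = 0.05         # s
    popspike_amplitude_mean: float = 1.0    # mV
    popspike_amplitude_sd: float = 0.5      # mV
    # --- discharge block model ---
    block_immediate_prob: float = 0.0
    block_delay_mean_min: float = 0.0       # min
    block_delay_sd_min: float = 0.0         # min
    # --- regular seizure-like activity ---
    sla_frequency: float = 0.0              # Hz (0 disables SLA mode)
    sla_frequency_sd: float = 0.0           # Hz (across slices)
    # --- global scaling / noise ---
    amplitude_scale_ca3: float = 1.0
    amplitude_scale_ca1: float = 1.0
    noise_sd: float = 0.45                  # mV, band-limited (100 Hz)

    def __post_init__(self):
        nonneg = (
            "discharge_rate discharge_duration_mean discharge_duration_sd "
            "discharge_amplitude_mean_ca3 discharge_amplitude_sd_ca3 "
            "discharge_amplitude_mean_ca1 discharge_amplitude_sd_ca1 "
            "burst_rate burst_duration_mean burst_duration_sd "
            "intraburst_frequency_mean intraburst_frequency_sd "
            "coupling_delay coupling_jitter_sd popspike_rate_ca3 "
            "popspike_rate_ca1 popspike_duration popspike_amplitude_mean "
            "popspike_amplitude_sd block_delay_mean_min block_delay_sd_min "
            "sla_frequency sla_frequency_sd amplitude_scale_ca3 "
            "amplitude_scale_ca1 noise_sd"
        ).split()
        for f in nonneg:
            if getattr(self, f) < 0:
                raise ValueError(f"ConditionSpec.{f} must be >= 0")
        for f in ("burst_probability", "coupling_failure_prob",
                  "block_immediate_prob"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"ConditionSpec.{f} must be in [0, 1]")
        if self.burst_leader_amplitude_factor < 1.0:
            raise ValueError("burst_leader_amplitude_factor must be >= 1")

    @property
    def has_block(self) -> bool:
        return self.block_immediate_prob > 0 or self.block_delay_mean_min > 0

    @property
    def is_sla(self) -> bool:
        return self.sla_frequency > 0

    def replace(self, **changes) -> "ConditionSpec":
        return dataclasses.replace(self, **changes)

    # --- flat key/value serialization -----------------------------------
    def to_config(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_config(cls, path) -> "ConditionSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict) or "name" not in data:
            raise ValueError(f"{path}: not a condition config (missing 'name')")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
        return cls(**data)


def _presets() -> dict:
    syn = ConditionSpec(
        name="synaptic_blockers",
        burst_probability=0.48,
        popspike_rate_ca1=2.0,
    )
    low_ca = ConditionSpec(
        name="low_ca",
        discharge_rate=0.0,
        burst_probability=0.0,
        coupling_failure_prob=1.0,
        popspike_rate_ca3=20.0,
        popspike_rate_ca1=20.0,
    )
    cd2 = syn.replace(
        name="cd2_15um",
        block_immediate_prob=0.455,
        block_delay_mean_min=4.09,
        block_delay_sd_min=2.60,
        popspike_rate_ca3=10.0,
        popspike_rate_ca1=10.0,
    )
    # the application-period preset models the post-latency steady state
    # (discharges fully blocked from segment start); latency itself is only
    # quantified for the Cd2+ experiment
    mec = syn.replace(
        name="mec_50um",
        block_immediate_prob=1.0,
    )
    bicu = ConditionSpec(
        name="bicuculline",
        discharge_rate=0.0,
        discharge_duration_mean=0.5,
        discharge_duration_sd=0.15,
        discharge_amplitude_mean_ca3=2.04,
        discharge_amplitude_sd_ca3=1.04,
        discharge_amplitude_mean_ca1=3.45,
        discharge_amplitude_sd_ca1=1.87,
        burst_probability=0.0,
        coupling_failure_prob=0.0,
        sla_frequency=0.13,
        sla_frequency_sd=0.07,
    )
    four_ap = bicu.replace(
        name="4ap",
        discharge_amplitude_mean_ca3=3.49,
        discharge_amplitude_sd_ca3=2.09,
        discharge_amplitude_mean_ca1=1.47,
        discharge_amplitude_sd_ca1=0.45,
        sla_frequency=0.36,
        sla_frequency_sd=0.06,
    )
    presets = {
        "synaptic_blockers": syn,
        "low_ca": low_ca,
        "cd2_15um": cd2,
        "mec_50um": mec,
        "d_tubocurarine_50um": mec.replace(name="d_tubocurarine_50um"),
        "surgical_cut": syn.replace(name="surgical_cut",
                                    coupling_failure_prob=1.0),
        "atropine_10um": syn.replace(name="atropine_10um"),
        "mla_100nm": syn.replace(name="mla_100nm"),
        "dhbe_10um": syn.replace(name="dhbe_10um"),
        "bicuculline": bicu,
        "bicuculline_mec": bicu.replace(
            name="bicuculline_mec",
            discharge_amplitude_mean_ca3=1.61,
            discharge_amplitude_sd_ca3=0.95,
            discharge_amplitude_mean_ca1=2.19,
            discharge_amplitude_sd_ca1=1.13,
            sla_frequency=0.15,
            sla_frequency_sd=0.08,
        ),
        "4ap": four_ap,
        "4ap_mec": four_ap.replace(
            name="4ap_mec",
            discharge_amplitude_mean_ca3=2.93,
            discharge_amplitude_sd_ca3=1.58,
            discharge_amplitude_mean_ca1=1.34,
            discharge_amplitude_sd_ca1=0.61,
            sla_frequency=0.33,
            sla_frequency_sd=0.07,
        ),
    }
    return presets


PRESETS = _presets()


def make_condition(name: str) -> ConditionSpec:
    """Return the preset :class:`ConditionSpec` for ``name``.

    Matching is case-insensitive.  Raises ``ValueError`` listing the valid
    preset labels for an unknown name.
    """
    key = str(name).strip().lower()
    if key not in PRESETS:
        raise ValueError(
            f"unknown condition preset {name!r}; valid presets: "
            + ", ".join(sorted(PRESETS))
        )
    return PRESETS[key]
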