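"""Built-in exposure-condition specifications.

Each :class:`ConditionSpec` carries the generative targets for one chloroform
exposure regime: the moments of the spike-amplitude distribution (mV), the
moments and range of the interspike-interval (ISI) distribution (s), the slow
baseline drift, and the additive noise level. The built-in registry encodes
the published per-condition amplitude and ISI statistics for the
L-Glu:L-Arg proteinoid recordings (control, three vapour-phase filter sizes,
and direct solvation at 25 mg/mL), which the synthetic generator reproduces.

Drift and noise are not tabulated in the source study; the defaults emulate a
slow diurnal-scale electrode drift (period 86400 s) and the microvolt-scale
noise floor of a 24-bit laboratory data logger.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class ConditionSpec:
    """Generative parameters for one exposure regime.

    Amplitude targets (mV) parameterise a shifted-gamma law clipped to
    [amp_min, amp_max]; ISI targets (s) parameterise a truncated normal on
    [isi_min, isi_max]. ``drift_amplitude``/``drift_period`` describe the
    sinusoidal baseline, ``noise_sd`` the additive white noise, and
    ``sample_interval`` the logger sampling interval (s).
    """

    label: str
    amp_mean: float
    amp_sd: float
    amp_skew: float
    amp_min: float
    amp_max: float
    isi_mean: float
    isi_sd: float
    isi_min: float
    isi_max: float
    drift_amplitude: float = 0.2
    drift_period: float = 86400.0
    noise_sd: float = 0.003
    sample_interval: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.amp_min < self.amp_mean < self.amp_max):
            raise ValueError("amp_min < amp_mean < amp_max violated")
        if not (self.isi_min < self.isi_mean < self.isi_max):
            raise ValueError("isi_min < isi_mean < isi_max violated")
        for name in ("amp_sd", "isi_sd", "sample_interval"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.noise_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("noise_sd and drift_amplitude must be >= 0")

    def with_seed(self, seed: int) -> "ConditionSpec":
        return replace(self, seed=seed)


def _spec(label, amp, isi, **kw) -> ConditionSpec:
    m, s, g, lo, hi = amp
    im, isd, ilo, ihi = isi
    return ConditionSpec(label=label, amp_mean=m, amp_sd=s, amp_skew=g,
                         amp_min=lo, amp_max=hi, isi_mean=im, isi_sd=isd,
                         isi_min=ilo, isi_max=ihi, **kw)


# Published amplitude moments: (mean mV, SD, skewness, min, max) and ISI
# moments: (mean s, SD, min, max) per condition.
BUILTIN_CONDITIONS: dict[str, ConditionSpec] = {
    "control": _spec("control",
                     (0.895, 0.419, 1.37, 0.361, 1.909),
                     (1392.86, 425.83, 595.24, 1952.38)),
    "0.5 cm^2": _spec("0.5 cm^2",
                      (0.281, 0.059, 0.87, 0.209, 0.412),
                      (1344.85, 321.53, 882.0, 1871.0)),
    "1 cm^2": _spec("1 cm^2",
                    (0.104, 0.037, 0.31, 0.047, 0.173),
                    (923.0, 356.92, 230.0, 1360.0)),
    "3 cm^2": _spec("3 cm^2",
                    (0.085, 0.047, 3.58, 0.049, 0.274),
                    (1008.75, 240.08, 718.0, 1505.0)),
    "25 mg/mL": _spec("25 mg/mL",
                      (0.065, 0.028, 1.39, 0.027, 0.134),
                      (228.2, 223.91, 69.8, 623.0)),
}

#: canonical presentation order (increasing exposure)
CONDITION_ORDER = tuple(BUILTIN_CONDITIONS)

#: published mean chronoamperometric currents (uA) per condition; used as
#: baseline levels by the current-trace generator so that the observed
#: ordering (vapour exposures above control, direct solvation well below)
#: holds by construction.
CURRENT_BASELINE_UA: dict[str, float] = {
    "control": 4305.0,
    "0.5 cm^2": 5931.0,
    "1 cm^2": 6157.0,
    "3 cm^2": 6202.0,
    "25 mg/mL": 3046.0,
}


def get_condition(label: str) -> ConditionSpec:
    """Look up a built-in condition; raises KeyError with the known labels."""
    try:
        return BUILTIN_CONDITIONS[label]
    except KeyError:
        raise KeyError(
            f"unknown condition {label!r}; built-ins: {list(BUILTIN_CONDITIONS)}"
        ) from None
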