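"""Cross-condition dose-response statistics.

Percent changes are expressed as reductions relative to a named reference
condition: ``percent_change(ref, treated) = 100 * (1 - treated/ref)``, so a
positive value means attenuation. Mean interspike periods are also reported
in minutes (half-up rounding to one decimal), the unit used for the headline
rhythm figures.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .spikes import SpikeTrainSummary

__all__ = ["percent_change", "seconds_to_minutes", "DoseResponseReport",
           "build_report"]


def percent_change(reference: float, treated: float) -> float:
    """Percent reduction of ``treated`` relative to ``reference``.

    Positive when treated < reference (attenuation); strictly decreasing in
    ``treated`` for a fixed reference.
    """
    if reference <= 0:
        raise ValueError("reference must be strictly positive")
    return 100.0 * (1.0 - treated / reference)


def seconds_to_minutes(x: float) -> float:
    """Convert seconds to minutes, rounded half-up to one decimal."""
    if x < 0:
        raise ValueError("x must be >= 0")
    return float(Decimal(x / 60.0).quantize(Decimal("0.1"),
                                            rounding=ROUND_HALF_UP))


@dataclass
class DoseResponseReport:
    """Ordered per-condition summaries plus pairwise percent changes."""

    reference: str
    conditions: list[str]
    summaries: dict[str, SpikeTrainSummary]
    amplitude_change_pct: dict[str, float] = field(default_factory=dict)
    isi_change_pct: dict[str, float] = field(default_factory=dict)
    isi_mean_min: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "conditions": self.conditions,
            "amplitude_mean_mV": {c: self.summaries[c].amplitude.mean
                                  for c in self.conditions},
            "isi_mean_s": {c: self.summaries[c].isi.mean
                           for c in self.conditions},
            "isi_mean_min": self.isi_mean_min,
            "amplitude_change_pct": self.amplitude_change_pct,
            "isi_change_pct": self.isi_change_pct,
            "n_spikes": {c: self.summaries[c].n_spikes
                         for c in self.conditions},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_markdown(self) -> str:
        lines = [
            f"# Dose-response report (reference: {self.reference})", "",
            "| Condition | Amp mean (mV) | Amp change (%) | "
            "ISI mean (s) | ISI mean (min) | ISI change (%) | n spikes |",
            "|---|---|---|---|---|---|---|",
        ]
        for c in self.conditions:
            s = self.summaries[c]
            lines.append(
                f"| {c} | {s.amplitude.mean:.3f} | "
                f"{self.amplitude_change_pct[c]:.2f} | {s.isi.mean:.2f} | "
                f"{self.isi_mean_min[c]:.1f} | {self.isi_change_pct[c]:.2f} | "
                f"{s.n_spikes} |")
        return "\n".join(lines) + "\n"


def build_report(summaries: list[SpikeTrainSummary],
                 reference: str = "control") -> DoseResponseReport:
    """Assemble the dose-response report from per-condition summaries."""
    by_label = {s.condition: s for s in summaries}
    if reference not in by_label:
        raise ValueError(f"reference condition {reference!r} not present")
    ref = by_label[reference]
    report = DoseResponseReport(reference=reference,
                                conditions=[s.condition for s in summaries],
                                summaries=by_label)
    for s in summaries:
        c = s.condition
        report.amplitude_change_pct[c] = percent_change(
            ref.amplitude.mean, s.amplitude.mean)
        report.isi_change_pct[c] = percent_change(ref.isi.mean, s.isi.mean)
        report.isi_mean_min[c] = seconds_to_minutes(s.isi.mean)
    return report
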