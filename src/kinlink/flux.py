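"""Extracellular-flux stress-test arithmetic and isotopologue normalization.

The mitochondrial stress test reads an oxygen consumption rate (OCR)
trace punctuated by oligomycin, FCCP and rotenone/antimycin injections;
the glycolysis stress test reads an extracellular acidification rate
(ECAR) trace punctuated by glucose, oligomycin and 2-DG injections.
Metrics are differences of specific rate measurements around those
injections:

* non-mitochondrial respiration = minimum after rotenone/antimycin
* basal respiration             = last before first injection - non-mito
* maximal respiration           = maximum after FCCP - non-mito
* spare capacity                = maximal - basal
* proton leak                   = minimum after oligomycin - non-mito
* ATP-linked respiration        = last before oligomycin - minimum after
* glycolysis                    = maximum after glucose (before
                                  oligomycin) - last before glucose
* glycolytic capacity           = maximum after oligomycin - last before
                                  glucose
* glycolytic reserve            = capacity - glycolysis

Isotopologue fractional abundance divides each mass-shift peak area by
the metabolite's total area; relative metabolite levels are normalized
per sample by total peak intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

OLIGOMYCIN = "oligomycin"
FCCP = "FCCP"
ROT_AA = "rotenone/antimycin"
GLUCOSE = "glucose"
TWO_DG = "2-DG"

MITO_EVENTS = (OLIGOMYCIN, FCCP, ROT_AA)
GLYCO_EVENTS = (GLUCOSE, OLIGOMYCIN, TWO_DG)


@dataclass
class FluxTrace:
    """An OCR or ECAR time series with ordered injection events.

    ``events`` maps injection labels to injection times; measurements at
    times strictly greater than an event time are "after" it.  Rates are
    assumed already normalized to cell number.
    """

    modality: str  # "OCR" or "ECAR"
    times: np.ndarray
    rates: np.ndarray
    events: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.modality not in ("OCR", "ECAR"):
            raise ValidationError(f"modality must be OCR or ECAR, got {self.modality!r}")
        if self.times.shape != self.rates.shape or self.times.ndim != 1:
            raise ValidationError("times and rates must be 1-D arrays of equal length")
        if (np.diff(self.times) <= 0).any():
            raise ValidationError("measurement times must be strictly increasing")
        event_times = [t for _, t in self.events]
        if any(b <= a for a, b in zip(event_times, event_times[1:])):
            raise ValidationError("injection events must be strictly ordered in time")
        for (_, start), (_, end) in zip(self.events, self.events[1:]):
            if not ((self.times > start) & (self.times < end)).any():
                raise ValidationError(
                    "at least one measurement is required between consecutive events"
                )

    def _event_time(self, label: str) -> float:
        for name, t in self.events:
            if name == label:
                return t
        raise ValidationError(f"trace is missing required injection event {label!r}")

    def last_before(self, label: str) -> float:
        t = self._event_time(label)
        mask = self.times < t
        if not mask.any():
            raise ValidationError(f"no measurement before {label!r} injection")
        return float(self.rates[mask][-1])

    def last_before_first_injection(self) -> float:
        if not self.events:
            raise ValidationError("trace has no injection events")
        t = self.events[0][1]
        mask = self.times < t
        if not mask.any():
            raise ValidationError("no measurement before the first injection")
        return float(self.rates[mask][-1])

    def _segment_after(self, label: str) -> np.ndarray:
        """Measurements after an injection and before the next one (or the end)."""
        t = self._event_time(label)
        later = [tt for name, tt in self.events if tt > t]
        end = min(later) if later else np.inf
        mask = (self.times > t) & (self.times < end)
        if not mask.any():
            raise ValidationError(f"no measurement after {label!r} injection")
        return self.rates[mask]

    def min_after(self, label: str) -> float:
        return float(self._segment_after(label).min())

    def max_after(self, label: str) -> float:
        return float(self._segment_after(label).max())


def mito_stress_metrics(trace: FluxTrace) -> dict[str, float]:
    """Mitochondrial stress-test metrics from an OCR trace.

    Requires oligomycin, FCCP and rotenone/antimycin injections (in that
    order).  Non-mitochondrial respiration is the post-rotenone/antimycin
    minimum; maximal respiration the post-FCCP maximum minus non-mito.
    """
    if trace.modality != "OCR":
        raise ValidationError("mitochondrial stress test requires an OCR trace")
    for label in MITO_EVENTS:
        trace._event_time(label)
    non_mito = trace.min_after(ROT_AA)
    basal = trace.last_before_first_injection() - non_mito
    maximal = trace.max_after(FCCP) - non_mito
    proton_leak = trace.min_after(OLIGOMYCIN) - non_mito
    atp_linked = trace.last_before(OLIGOMYCIN) - trace.min_after(OLIGOMYCIN)
    return {
        "non_mito": non_mito,
        "basal": basal,
        "maximal": maximal,
        "spare": maximal - basal,
        "proton_leak": proton_leak,
        "atp_linked": atp_linked,
    }


def glyco_stress_metrics(trace: FluxTrace) -> dict[str, float]:
    """Glycolysis stress-test metrics from an ECAR trace.

    Requires glucose, oligomycin and 2-DG injections.  Glycolysis is the
    maximum rate after glucose and before oligomycin minus the last rate
    before glucose; capacity uses the post-oligomycin maximum; the
    reserve is their difference and may be negative (no clamping).
    """
    if trace.modality != "ECAR":
        raise ValidationError("glycolysis stress test requires an ECAR trace")
    for label in GLYCO_EVENTS:
        trace._event_time(label)
    baseline = trace.last_before(GLUCOSE)
    glycolysis = trace.max_after(GLUCOSE) - baseline
    capacity = trace.max_after(OLIGOMYCIN) - baseline
    return {
        "glycolysis": glycolysis,
        "glycolytic_capacity": capacity,
        "glycolytic_reserve": capacity - glycolysis,
    }


def fractional_abundance(areas) -> np.ndarray:
    """Isotopologue peak areas normalized to fractions summing to 1."""
    arr = np.asarray(areas, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError("isotopologue vector must be 1-D and non-empty")
    if (arr < 0).any() or not np.isfinite(arr).all():
        raise ValidationError("peak areas must be finite and nonnegative")
    total = arr.sum()
    if total <= 0:
        raise ValidationError("isotopologue vector must contain a positive area")
    return arr / total


def total_intensity_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Normalize each sample (row) of a samples x metabolites matrix to unit sum."""
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any() or not np.isfinite(values).all():
        raise ValidationError("metabolite matrix must be finite and nonnegative")
    totals = values.sum(axis=1)
    if (totals <= 0).any():
        bad = list(matrix.index[totals <= 0])
        raise ValidationError(f"samples with zero total intensity: {bad}")
    return matrix.div(totals, axis=0)
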