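"""Morphokinetic aberrance scoring against a clinical reference timeline.

Developmental event times (hours from pronuclei fade, measured by
time-lapse imaging) are compared with a reference timeline built from
clinical donor-egg-derived embryos: per event, the mean and unbiased SD of
the clinical times.  An embryo is morphokinetically aberrant when its
timing deviates from the clinical mean by strictly more than one SD at two
or more events.  Deviation is two-sided (absolute) by default; a one-sided
"late-only" mode is available since delayed development is the common
clinical concern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: The ordered developmental events scored, from pronuclei fade onward.
EVENTS: tuple[str, ...] = (
    "two-cell",
    "three-four-cell",
    "five-eight-cell",
    "morula",
    "early-blastocyst",
    "well-developed-blastocyst",
)


@dataclass
class MorphokineticTimeline:
    """Event -> hours for one embryo; missing events are simply absent."""

    embryo_id: str
    event_times: dict[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.event_times) - set(EVENTS)
        if unknown:
            raise ValueError(f"unknown events: {sorted(unknown)}")
        if any(t < 0 for t in self.event_times.values()):
            raise ValueError("event times must be >= 0 hours")
        present = [e for e in EVENTS if e in self.event_times]
        times = [self.event_times[e] for e in present]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError(
                f"event times for {self.embryo_id} are not nondecreasing "
                f"along the developmental order"
            )


@dataclass
class ReferenceTimeline:
    """Per event: (mean hours, SD hours, n observations)."""

    stats: dict[str, tuple[float, float, int]]

    def __post_init__(self) -> None:
        for event, (mean, sd, n) in self.stats.items():
            if n < 2:
                raise ValueError(f"reference event {event} needs n >= 2")
            if sd < 0:
                raise ValueError(f"negative SD for event {event}")


#: Synthetic stand-in for a clinical donor-egg reference timeline (hours
#: from pronuclei fade); plausible magnitudes for desk-scale fixtures, not
#: measured clinical values.
DEFAULT_CLINICAL_REFERENCE = ReferenceTimeline(
    {
        "two-cell": (2.5, 1.0, 50),
        "three-four-cell": (12.0, 2.0, 50),
        "five-eight-cell": (24.0, 3.0, 50),
        "morula": (65.0, 5.0, 50),
        "early-blastocyst": (78.0, 4.0, 50),
        "well-developed-blastocyst": (90.0, 5.0, 50),
    }
)


def build_reference_timeline(
    timelines: Sequence[MorphokineticTimeline],
) -> ReferenceTimeline:
    """Mean and unbiased SD per event across clinical timelines.

    Events with fewer than two non-null observations are omitted with a
    warning; an input yielding no usable event is an error.
    """
    stats: dict[str, tuple[float, float, int]] = {}
    for event in EVENTS:
        values = [
            t.event_times[event] for t in timelines if event in t.event_times
        ]
        if len(values) < 2:
            if values:
                warnings.warn(
                    f"event {event} has a single observation; omitted",
                    stacklevel=2,
                )
            continue
        arr = np.asarray(values, dtype=float)
        stats[event] = (float(arr.mean()), float(arr.std(ddof=1)), len(values))
    if not stats:
        raise ValueError("no event has the >= 2 observations required")
    return ReferenceTimeline(stats)


def flag_aberrant_embryo(
    timeline: MorphokineticTimeline,
    reference: ReferenceTimeline,
    two_sided: bool = True,
) -> dict:
    """Apply the aberrance rule to one embryo.

    An event is deviant iff its time differs from the reference mean by
    strictly more than one reference SD (absolute by default; only delays
    when ``two_sided`` is False).  The embryo is aberrant iff two or more
    events are deviant — a count rule, so a single extreme deviation does
    not qualify.  Missing events never count.
    """
    deviant = []
    for event, t in timeline.event_times.items():
        if event not in reference.stats:
            raise KeyError(
                f"event {event!r} present in timeline but absent from reference"
            )
        mean, sd, _ = reference.stats[event]
        delta = t - mean
        dev = abs(delta) if two_sided else delta
        if dev > sd:
            deviant.append(event)
    deviant = [e for e in EVENTS if e in deviant]
    return {
        "deviant_events": deviant,
        "n_deviations": len(deviant),
        "aberrant": len(deviant) >= 2,
    }
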