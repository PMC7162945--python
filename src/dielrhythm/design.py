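"""Sampling design for diel (day/night) time-course experiments.

A diel experiment samples a tissue repeatedly across one light/dark cycle.
Times are expressed in Zeitgeber Time (ZT): hours elapsed since dawn, so
ZT0 is dawn and negative values are before dawn.  The design also records
the clock times of dawn and dusk, from which the photoperiod (hours of
light per cycle) is derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class DesignError(ValueError):
    """Raised for inconsistent sampling designs."""


def parse_clock(text: str) -> float:
    """Parse a 24-h clock string like ``"5:45"`` into fractional hours."""
    try:
        hh, mm = text.strip().split(":")
        hours = int(hh) + int(mm) / 60.0
    except (ValueError, AttributeError) as exc:
        raise DesignError(f"cannot parse clock time {text!r}") from exc
    if not 0.0 <= hours < 24.0:
        raise DesignError(f"clock time {text!r} outside 00:00-23:59")
    return hours


@dataclass(frozen=True)
class DielDesign:
    """Sampling clock of a diel time course.

    Parameters
    ----------
    sample_times_zt : tuple of float
        Strictly increasing sampling times in ZT hours (may start before
        dawn, i.e. be negative).
    dawn_clock, dusk_clock : str
        Clock times of dawn and dusk, ``"H:MM"``.
    period_h : float
        Nominal cycle length in hours (24 for a diel cycle).
    """

    sample_times_zt: tuple[float, ...]
    dawn_clock: str = "5:45"
    dusk_clock: str = "19:00"
    period_h: float = 24.0
    photoperiod_h: float = field(init=False)

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.sample_times_zt)
        if len(times) < 2:
            raise DesignError("need at least two sample times")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise DesignError("sample times must be strictly increasing")
        photoperiod = parse_clock(self.dusk_clock) - parse_clock(self.dawn_clock)
        if not 0.0 < photoperiod < self.period_h:
            raise DesignError(
                f"photoperiod must lie in (0, {self.period_h}) h, got {photoperiod}"
            )
        object.__setattr__(self, "sample_times_zt", times)
        object.__setattr__(self, "photoperiod_h", photoperiod)

    @property
    def n_timepoints(self) -> int:
        return len(self.sample_times_zt)

    def time_labels(self) -> list[str]:
        """ZT column labels, e.g. ``["ZT-2", "ZT00", ..., "ZT24"]``."""
        return [format_zt(t) for t in self.sample_times_zt]


def format_zt(t: float) -> str:
    if float(t).is_integer():
        return f"ZT{int(t):02d}"
    return f"ZT{t:g}"


def generate_design(
    n_timepoints: int = 14,
    interval_h: float = 2.0,
    start_offset_h: float = -2.0,
    dawn_clock: str = "5:45",
    dusk_clock: str = "19:00",
    period_h: float = 24.0,
) -> DielDesign:
    """Build a regular sampling design.

    Sample ``i`` is taken at ``start_offset_h + i * interval_h`` ZT hours.
    The defaults reproduce a 26-h course sampled every 2 h starting 2 h
    before dawn (14 points, ZT-2 ... ZT24) with a 13.25-h photoperiod.
    """
    if n_timepoints < 4:
        raise DesignError("need at least 4 time points")
    if interval_h <= 0:
        raise DesignError("interval must be positive")
    times = tuple(start_offset_h + i * interval_h for i in range(n_timepoints))
    return DielDesign(
        sample_times_zt=times,
        dawn_clock=dawn_clock,
        dusk_clock=dusk_clock,
        period_h=period_h,
    )
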