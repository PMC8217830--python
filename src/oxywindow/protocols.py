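"""Time-varying gas composition at the exchange window.

The chamber is supplied by mass-flow-metered gas mixtures, so the oxygen
fraction is a piecewise-constant square wave in time and the model treats
each switch as instantaneous. Fractions convert to boundary PO2 as
fraction x total pressure (dry gas, default 760 mmHg); an optional
water-vapor correction subtracts 47 mmHg (body-temperature saturation)
before multiplying.
"""

from __future__ import annotations

from dataclasses import dataclass

WATER_VAPOR_PRESSURE_37C = 47.0  # mmHg


def percent_to_po2(
    fraction: float, pressure: float = 760.0, vapor_correction: bool = False
) -> float:
    """Convert an O2 fraction (0..1) to partial pressure in mmHg."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"O2 fraction must be within [0, 1], got {fraction}")
    if pressure <= 0:
        raise ValueError("total pressure must be > 0")
    eff = pressure - WATER_VAPOR_PRESSURE_37C if vapor_correction else pressure
    return fraction * eff


@dataclass(frozen=True)
class GasProtocol:
    """Ordered (duration_s, O2_fraction) segments, right-continuous in time.

    At a segment boundary the later segment's value applies — the boundary
    PO2 changes instantaneously when the chamber gas is switched.
    """

    segments: tuple[tuple[float, float], ...]
    pressure: float = 760.0
    vapor_correction: bool = False

    def __post_init__(self) -> None:
        segs = tuple((float(d), float(f)) for d, f in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("protocol needs at least one segment")
        for d, f in segs:
            if d <= 0:
                raise ValueError(f"segment duration must be > 0, got {d}")
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"O2 fraction must be within [0, 1], got {f}")
        if self.pressure <= 0:
            raise ValueError("total pressure must be > 0")

    @property
    def total_duration(self) -> float:
        return sum(d for d, _ in self.segments)

    @property
    def edges(self) -> tuple[float, ...]:
        """Switch times (excluding t=0 and the protocol end)."""
        out, t = [], 0.0
        for d, _ in self.segments[:-1]:
            t += d
            out.append(t)
        return tuple(out)

    def po2_of_fraction(self, fraction: float) -> float:
        return percent_to_po2(fraction, self.pressure, self.vapor_correction)

    def segment_index_at(self, t: float) -> int:
        if t < 0 or t > self.total_duration:
            raise ValueError(
                f"t={t} s outside protocol duration [0, {self.total_duration}] s"
            )
        acc = 0.0
        for i, (d, _) in enumerate(self.segments):
            acc += d
            if t < acc:
                return i
        return len(self.segments) - 1


def window_po2_at(t: float, protocol: GasProtocol) -> float:
    """Boundary PO2 (mmHg) at time t; right-continuous at segment edges."""
    _, frac = protocol.segments[protocol.segment_index_at(t)]
    return protocol.po2_of_fraction(frac)


def standard_square_wave(pressure: float = 760.0, vapor_correction: bool = False) -> GasProtocol:
    """The in vivo oxygen-challenge square wave: 1 min of 5% O2, 2 min of
    12%, 2 min of 2%, 1 min of 5% (360 s total), with static CO2/N2 balance
    that never enters the diffusion model."""
    return GasProtocol(
        segments=((60.0, 0.05), (120.0, 0.12), (120.0, 0.02), (60.0, 0.05)),
        pressure=pressure,
        vapor_correction=vapor_correction,
    )


def constant_protocol(
    fraction: float, duration: float, pressure: float = 760.0, vapor_correction: bool = False
) -> GasProtocol:
    """Single-segment protocol holding one O2 fraction for ``duration`` s."""
    return GasProtocol(((duration, fraction),), pressure, vapor_correction)


def step_protocol(
    frac_before: float,
    frac_after: float,
    t_switch: float,
    duration_after: float,
    pressure: float = 760.0,
    vapor_correction: bool = False,
) -> GasProtocol:
    """Two-segment step change, e.g. the 5% -> 2% challenge."""
    return GasProtocol(
        ((t_switch, frac_before), (duration_after, frac_after)), pressure, vapor_correction
    )

NAMED_PROTOCOLS = {
    "standard_square_wave": standard_square_wave,
}
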