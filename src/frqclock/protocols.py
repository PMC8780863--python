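"""Piecewise-constant light-dark (LD) protocols.

A protocol is an ordered list of ``(duration_h, intensity)`` phases,
repeated indefinitely when periodic.  Intensities are normalized to
``[0, 1]``: 1.0 corresponds to the 5000 lux white light used in the
standard entrainment experiments and 0.2 to the 1000 lux condition
(a linear lux map).  ``t0`` is the time of first lights-on; all phase
angles are referenced to it.

Transitions are right-continuous: the instant of a transition belongs
to the phase it begins, so ``light_at(LD6:6, t=6) == 0.0``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "LDProtocol",
    "symmetric_ld",
    "asymmetric_ld",
    "constant",
    "light_at",
    "parse_protocol",
    "LUX_FULL",
    "LUX_LOW",
]

#: intensity 1.0 in lux (standard high-intensity white light)
LUX_FULL = 5000.0
#: intensity of the low-light condition on the normalized scale
LUX_LOW = 1000.0 / LUX_FULL


@dataclass(frozen=True)
class LDProtocol:
    """A piecewise-constant light schedule.

    Parameters
    ----------
    phases : sequence of (duration_h, intensity)
        Ordered phases; durations in hours, intensities in [0, 1].
    periodic : bool
        If True the phase list repeats with period ``T = sum(durations)``.
        If False the last phase extends to infinity.
    t0 : float
        Time (h) at which the first phase begins (lights-on reference).
    """

    phases: tuple[tuple[float, float], ...]
    periodic: bool = True
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("protocol needs at least one phase")
        object.__setattr__(self, "phases", tuple((float(d), float(i)) for d, i in self.phases))
        for d, i in self.phases:
            if not d > 0:
                raise ValueError(f"phase durations must be > 0, got {d}")
            if not 0.0 <= i <= 1.0:
                raise ValueError(f"intensities must lie in [0, 1], got {i}")

    @property
    def T(self) -> float:
        """Cycle length in hours (sum of phase durations)."""
        return sum(d for d, _ in self.phases)

    @property
    def light_fraction(self) -> float:
        """Duration-weighted mean intensity over one cycle."""
        return sum(d * i for d, i in self.phases) / self.T

    def light_at(self, t: float) -> float:
        return light_at(self, t)

    def transition_times(self, t_end: float) -> list[float]:
        """All phase-boundary times in ``(t0, t_end]``, in order."""
        out: list[float] = []
        t = self.t0
        cycle = 0
        while t < t_end:
            for d, _ in self.phases:
                t = t + d
                if t > t_end:
                    return out
                out.append(t)
            cycle += 1
            if not self.periodic:
                break
        return out

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "phases": [[d, i] for d, i in self.phases],
            "periodic": self.periodic,
            "t0": self.t0,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, doc: dict) -> "LDProtocol":
        return cls(
            phases=tuple((float(d), float(i)) for d, i in doc["phases"]),
            periodic=bool(doc.get("periodic", True)),
            t0=float(doc.get("t0", 0.0)),
        )

    @classmethod
    def from_json(cls, text: str) -> "LDProtocol":
        return cls.from_dict(json.loads(text))

    def label(self) -> str:
        """Human-readable label, e.g. 'LD3:3', 'DD', 'LL'."""
        if not self.periodic and len(self.phases) == 1:
            i = self.phases[0][1]
            if i == 0:
                return "DD"
            return "LL" if i == 1 else f"LL({i:g})"
        if len(self.phases) == 2:
            (dl, _), (dd, _) = self.phases
            return f"LD{dl:g}:{dd:g}"
        return f"protocol(T={self.T:g}h)"


def symmetric_ld(half_period: float, intensity: float = 1.0, t0: float = 0.0) -> LDProtocol:
    """Symmetric LDx:x cycle: ``half_period`` h light then ``half_period`` h dark."""
    if not half_period > 0:
        raise ValueError("half_period must be > 0")
    return LDProtocol(((half_period, intensity), (half_period, 0.0)), periodic=True, t0=t0)


def asymmetric_ld(light_h: float, dark_h: float, intensity: float = 1.0, t0: float = 0.0) -> LDProtocol:
    """Asymmetric LDx:y cycle, e.g. the orbital-flight LD65min:25min regime."""
    if not (light_h > 0 and dark_h > 0):
        raise ValueError("both phase durations must be > 0")
    return LDProtocol(((light_h, intensity), (dark_h, 0.0)), periodic=True, t0=t0)


def constant(intensity: float) -> LDProtocol:
    """Constant condition: DD for intensity 0, LL for intensity 1."""
    return LDProtocol(((1.0, intensity),), periodic=False, t0=0.0)


def light_at(protocol: LDProtocol, t: float) -> float:
    """Light intensity at time ``t`` (right-continuous at transitions)."""
    rel = t - protocol.t0
    T = protocol.T
    if protocol.periodic:
        rel = rel % T
    elif rel < 0:
        rel = 0.0  # constant protocols extend their first phase backwards
    elif rel >= T:
        return protocol.phases[-1][1]
    acc = 0.0
    for d, i in protocol.phases:
        acc += d
        if rel < acc:
            return i
    return protocol.phases[-1][1]


_DUR_RE = re.compile(r"^\s*([\d.]+)\s*(m|min|h)?\s*$", re.IGNORECASE)


def _parse_duration(tok: str) -> float:
    m = _DUR_RE.match(tok)
    if not m:
        raise ValueError(f"cannot parse duration {tok!r}")
    val = float(m.group(1))
    unit = (m.group(2) or "h").lower()
    return val / 60.0 if unit in ("m", "min") else val


def parse_protocol(spec: str, intensity: float = 1.0) -> LDProtocol:
    """Parse shorthand protocol strings.

    Accepted forms: ``"DD"``, ``"LL"``, ``"LD6:6"``, ``"LD65m:25m"``,
    ``"LD0.75:0.75"``.  Durations default to hours; an ``m``/``min``
    suffix selects minutes.
    """
    s = spec.strip()
    if s.upper() == "DD":
        return constant(0.0)
    if s.upper() == "LL":
        return constant(intensity)
    if s.upper().startswith("LD"):
        body = s[2:]
        parts = body.split(":")
        if len(parts) != 2:
            raise ValueError(f"expected 'LDx:y', got {spec!r}")
        light_h = _parse_duration(parts[0])
        dark_h = _parse_duration(parts[1])
        return asymmetric_ld(light_h, dark_h, intensity)
    raise ValueError(f"unrecognized protocol string {spec!r} (use DD, LL, or LDx:y)")
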