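"""Parametric breathing waveforms.

The phantom's surrogate (and the fitting model) moves with a periodic
vertical displacement.  Three waveform families are supported:

``sine``
    y(t) = y0 + A * sin(2*pi*(t - tc) / T) — the model the respiratory
    trace is fitted to, and the standard motion-phantom preset.
``sharkfin``
    An asymmetric breathing surrogate with a prolonged exhale dwell and a
    sharp inhale peak:  y(t) = y0 + A * (2*|sin(pi*(t - tc)/T)|**p - 1)
    with p = 4 by default.  Commercial phantoms ship such a pattern but do
    not publish its analytic form; this is a configurable stand-in with the
    same qualitative shape (T-periodic, half peak-to-peak equal to A,
    asymmetric duty cycle).
``constant``
    y(t) = y0, i.e. a static phantom.

Conventions: ``A`` is the half peak-to-peak amplitude in mm (a "±10 mm"
preset means A = 10), ``T`` the cycle time in seconds, ``tc`` the time of
the upward zero-crossing for the sine, and positive displacement is
anterior motion (inhale, away from the table).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WaveformKind",
    "MotionWaveform",
    "evaluate_waveform",
    "sample_waveform",
]


class WaveformKind(str, enum.Enum):
    SINE = "sine"
    SHARKFIN = "sharkfin"
    CONSTANT = "constant"


#: Exponent of the default shark-fin shape |sin|^p; larger p -> sharper
#: inhale peak and longer exhale dwell.
DEFAULT_SHARKFIN_EXPONENT = 4.0


@dataclass(frozen=True)
class MotionWaveform:
    """A periodic displacement-vs-time function.

    Parameters
    ----------
    kind
        Waveform family.
    amplitude_mm
        Half peak-to-peak amplitude A >= 0 (mm).  Ignored for ``constant``.
    period_s
        Cycle time T > 0 (s).
    tc_s
        Time offset tc (s): upward zero-crossing for ``sine``, start of the
        cycle for ``sharkfin``.
    baseline_mm
        Baseline offset y0 (mm).
    sharkfin_exponent
        Shape exponent p for the shark-fin family.
    """

    kind: WaveformKind
    amplitude_mm: float = 0.0
    period_s: float = 6.0
    tc_s: float = 0.0
    baseline_mm: float = 0.0
    sharkfin_exponent: float = field(default=DEFAULT_SHARKFIN_EXPONENT)

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", WaveformKind(self.kind))
        if not np.isfinite(self.period_s) or self.period_s <= 0:
            raise ValueError(f"period_s must be positive, got {self.period_s}")
        if not np.isfinite(self.amplitude_mm) or self.amplitude_mm < 0:
            raise ValueError(
                f"amplitude_mm must be non-negative, got {self.amplitude_mm}"
            )
        if self.sharkfin_exponent <= 0:
            raise ValueError("sharkfin_exponent must be positive")

    def __call__(self, t):
        return evaluate_waveform(self, t)

    @classmethod
    def from_config(cls, cfg: dict) -> "MotionWaveform":
        """Build a waveform from a YAML-style mapping.

        Expected keys: ``kind`` plus any of ``amplitude_mm``, ``period_s``,
        ``tc_s``, ``baseline_mm``, ``sharkfin_exponent``.
        """
        allowed = {
            "kind",
            "amplitude_mm",
            "period_s",
            "tc_s",
            "baseline_mm",
            "sharkfin_exponent",
        }
        unknown = set(cfg) - allowed
        if unknown:
            raise ValueError(f"unknown waveform config keys: {sorted(unknown)}")
        return cls(**cfg)

    def to_config(self) -> dict:
        return {
            "kind": self.kind.value,
            "amplitude_mm": self.amplitude_mm,
            "period_s": self.period_s,
            "tc_s": self.tc_s,
            "baseline_mm": self.baseline_mm,
            "sharkfin_exponent": self.sharkfin_exponent,
        }


def evaluate_waveform(w: MotionWaveform, t):
    """Displacement (mm) of waveform ``w`` at time(s) ``t`` (s).

    ``t`` may be a scalar or array; non-finite times are rejected.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time values must be finite")
    if w.kind is WaveformKind.CONSTANT:
        out = np.full_like(t, w.baseline_mm)
    else:
        phase = (t - w.tc_s) / w.period_s
        if w.kind is WaveformKind.SINE:
            out = w.baseline_mm + w.amplitude_mm * np.sin(2.0 * np.pi * phase)
        else:  # sharkfin
            u = np.abs(np.sin(np.pi * (phase % 1.0))) ** w.sharkfin_exponent
            out = w.baseline_mm + w.amplitude_mm * (2.0 * u - 1.0)
    return out if out.ndim else float(out)


def sample_waveform(w: MotionWaveform, times) -> np.ndarray:
    """Evaluate ``w`` at an ordered sequence of times.

    Preserves order and length; rejects an empty sequence.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    return np.atleast_1d(evaluate_waveform(w, times))
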