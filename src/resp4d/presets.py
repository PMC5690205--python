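"""Scenario presets and YAML configuration.

The preset table mirrors the twelve phantom studies of the original
bench campaign (surrogate motion only — the internal target's 3D motion
is optional and never feeds the signal pipeline): sinusoidal and
shark-fin surrogate patterns at T = 6 s with half peak-to-peak amplitudes
from ±1 to ±10 mm, including two static baselines.  Studies acquired
helically on the bench are simulated here as cine studies of the same
waveform — only cine acquisitions carry a respiratory signal per slice.

A scenario YAML file has up to four blocks::

    waveform:    {kind, amplitude_mm, period_s, tc_s, baseline_mm}
    geometry:    {z0_mm, zp_mm, bar_length_mm, wire_sep_x_mm}
    acquisition: {n_slabs, slices_per_slab, frame_interval_s, ...}
    slices:      {most_distal_offset_mm}   # or an explicit z list
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import yaml

from .geometry import DEFAULT_GEOMETRY, FrameGeometry
from .motion import MotionWaveform, WaveformKind
from .simulator import AcquisitionConfig, default_slice_zs

__all__ = ["Scenario", "CIRS_PRESETS", "get_preset", "load_scenario"]


@dataclass(frozen=True)
class Scenario:
    name: str
    waveform: MotionWaveform
    geometry: FrameGeometry = DEFAULT_GEOMETRY
    acquisition: AcquisitionConfig = AcquisitionConfig()
    most_distal_offset_mm: float = 200.0
    slice_zs: Optional[tuple] = None

    def resolved_slice_zs(self) -> list:
        if self.slice_zs is not None:
            return list(self.slice_zs)
        return default_slice_zs(
            self.geometry, self.acquisition, self.most_distal_offset_mm
        )


def _sine(a: float) -> MotionWaveform:
    return MotionWaveform(WaveformKind.SINE, amplitude_mm=a, period_s=6.0)


def _sharkfin(a: float) -> MotionWaveform:
    return MotionWaveform(WaveformKind.SHARKFIN, amplitude_mm=a, period_s=6.0)


_STATIC = MotionWaveform(WaveformKind.CONSTANT)

#: Surrogate motion of the twelve bench studies (cycle time 6 s).
CIRS_PRESETS: dict = {
    "CIRS01": Scenario("CIRS01", _STATIC),
    "CIRS02": Scenario("CIRS02", _sine(10.0)),
    "CIRS03": Scenario("CIRS03", _sine(10.0)),
    "CIRS04": Scenario("CIRS04", _sine(6.0)),
    "CIRS05": Scenario("CIRS05", _sharkfin(10.0)),
    "CIRS06": Scenario("CIRS06", _STATIC),
    "CIRS07": Scenario("CIRS07", _sine(10.0)),
    "CIRS08": Scenario(
        "CIRS08",
        _sine(10.0),
        acquisition=AcquisitionConfig(n_slabs=7),
    ),
    "CIRS09": Scenario("CIRS09", _sharkfin(10.0)),
    "CIRS10": Scenario("CIRS10", _sine(2.0)),
    "CIRS11": Scenario("CIRS11", _sine(1.0)),
    "CIRS12": Scenario("CIRS12", _sine(3.0)),
}


def get_preset(name: str) -> Scenario:
    try:
        return CIRS_PRESETS[name.upper()]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(CIRS_PRESETS)}"
        ) from None


def load_scenario(path) -> Scenario:
    """Load a scenario from a YAML file (see module docstring for schema)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    waveform = MotionWaveform.from_config(doc.get("waveform", {"kind": "constant"}))
    geometry = (
        FrameGeometry.from_config(doc["geometry"])
        if "geometry" in doc
        else DEFAULT_GEOMETRY
    )
    acquisition = (
        AcquisitionConfig.from_config(doc["acquisition"])
        if "acquisition" in doc
        else AcquisitionConfig()
    )
    slices = doc.get("slices", {})
    return Scenario(
        name=doc.get("name", str(path)),
        waveform=waveform,
        geometry=geometry,
        acquisition=acquisition,
        most_distal_offset_mm=slices.get("most_distal_offset_mm", 200.0),
        slice_zs=tuple(slices["z_mm"]) if "z_mm" in slices else None,
    )
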