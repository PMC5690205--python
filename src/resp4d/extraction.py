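"""Respiratory-trace reconstruction from wire tracks.

Two steps turn per-frame wire centroids into the displacement of the
central piece on the abdomen:

1. Per frame, the wire displacement at the slice plane (mm), referenced
   to the exhale position (the frame where each wire sits closest to the
   table, i.e. at its maximal image-y):

       Az(t) = ((y1max - y1(t)) + (y2max - y2(t))) / 2 * pixel_spacing

   Averaging the two wires halves the centroid noise and cancels any
   common baseline error.

2. Pointwise lever-arm scaling to the central piece:

       A0(t) = Az(t) * (Z0 - Zp) / (Z - Zp)

   The ratio is one multiplicative constant per slice, so scaling before
   or after sine fitting is equivalent; the trace is scaled first so that
   traces from different slices are directly comparable and can be
   averaged.

The trace is non-negative by construction and exactly zero at the
frame(s) defining the exhale reference.  A capture shorter than two full
breathing cycles may miss true exhale; such traces are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .detection import WireTrack
from .geometry import FrameGeometry, scale_amplitude_to_central

__all__ = ["AzSeries", "RespiratoryTrace", "compute_az_series", "build_respiratory_trace", "average_traces"]


@dataclass
class AzSeries:
    """Wire displacement at the slice plane vs time (valid frames only)."""

    times_s: np.ndarray
    az_mm: np.ndarray
    slice_z_mm: float
    pixel_spacing_mm: float
    frame_ids: np.ndarray


@dataclass
class RespiratoryTrace:
    """Central-piece vertical displacement above the exhale baseline."""

    times_s: np.ndarray
    displacement_mm: np.ndarray
    slice_z_mm: float
    provenance: dict = field(default_factory=dict)
    frame_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        if self.times_s.shape != self.displacement_mm.shape:
            raise ValueError("times and displacements must have equal length")
        if self.frame_ids is None:
            self.frame_ids = np.arange(self.times_s.size)

    def __len__(self) -> int:
        return self.times_s.size

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.times_s,
                "displacement_mm": self.displacement_mm,
                "slice_z_mm": np.full(len(self), self.slice_z_mm),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RespiratoryTrace":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            times_s=df["time_s"].to_numpy(),
            displacement_mm=df["displacement_mm"].to_numpy(),
            slice_z_mm=float(df["slice_z_mm"].iloc[0]) if "slice_z_mm" in df else float("nan"),
            provenance={"source": str(path)},
        )


def compute_az_series(track: WireTrack, pixel_spacing_mm: float = None) -> AzSeries:
    """Per-frame wire displacement at the slice plane (exhale-referenced).

    Each wire is referenced to its own maximal image-y over the slice's
    cine sequence (the exhale frame, closest to the table); the two
    per-wire excursions are averaged and converted to mm.
    """
    if pixel_spacing_mm is None:
        pixel_spacing_mm = track.pixel_spacing_mm
    v = np.asarray(track.valid, dtype=bool)
    if v.sum() < 2:
        raise ValueError("track needs at least two valid frames")
    y1 = track.left_px[v, 1]
    y2 = track.right_px[v, 1]
    y1max = y1.max()
    y2max = y2.max()
    az_px = ((y1max - y1) + (y2max - y2)) / 2.0
    return AzSeries(
        times_s=track.times_s[v].copy(),
        az_mm=az_px * pixel_spacing_mm,
        slice_z_mm=track.slice_z_mm,
        pixel_spacing_mm=pixel_spacing_mm,
        frame_ids=np.asarray(track.frame_ids)[v].copy(),
    )


def build_respiratory_trace(
    az: AzSeries,
    g: FrameGeometry,
    z_mm: float = None,
    min_cycles_s: float = None,
) -> RespiratoryTrace:
    """Scale a wire-plane series to central-piece displacement (pointwise).

    ``min_cycles_s``, when given, is the expected breathing period; a
    capture shorter than two periods may not contain true exhale and
    triggers a warning (the trace is still returned).
    """
    if z_mm is None:
        z_mm = az.slice_z_mm
    disp = scale_amplitude_to_central(az.az_mm, z_mm, g)
    span = az.times_s[-1] - az.times_s[0]
    if min_cycles_s is not None and span < 2.0 * min_cycles_s:
        warnings.warn(
            f"capture spans {span:.1f} s < two breathing cycles; "
            "exhale reference may be unreliable",
            stacklevel=2,
        )
    return RespiratoryTrace(
        times_s=az.times_s.copy(),
        displacement_mm=np.atleast_1d(disp),
        slice_z_mm=z_mm,
        provenance={
            "pixel_spacing_mm": az.pixel_spacing_mm,
            "geometry": g.to_config(),
            "source_slices": [z_mm],
        },
        frame_ids=az.frame_ids.copy(),
    )


def average_traces(traces: Sequence[RespiratoryTrace], time_tol_s: float = 1e-6) -> RespiratoryTrace:
    """Pointwise mean of traces sharing one time base (e.g. one slab).

    Slices of the same slab are exposed simultaneously, so their traces
    are independent measurements of the same displacement; averaging
    reduces detection noise by ~1/sqrt(n_slices).
    """
    traces = list(traces)
    if not traces:
        raise ValueError("no traces to average")
    t0 = traces[0].times_s
    for tr in traces[1:]:
        if tr.times_s.shape != t0.shape or np.any(np.abs(tr.times_s - t0) > time_tol_s):
            raise ValueError("traces do not share a common time base")
    disp = np.mean([tr.displacement_mm for tr in traces], axis=0)
    return RespiratoryTrace(
        times_s=t0.copy(),
        displacement_mm=disp,
        slice_z_mm=float(np.mean([tr.slice_z_mm for tr in traces])),
        provenance={"source_slices": [tr.slice_z_mm for tr in traces]},
        frame_ids=traces[0].frame_ids.copy(),
    )
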