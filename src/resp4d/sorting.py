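"""Retrospective 4D sorting of cine frames into respiratory bins.

Every frame receives a phase (fraction of the fitted breathing cycle in
[0, 1), with phase 0 at the fitted upward zero-crossing t = tc), its
measured displacement amplitude, and a velocity sign (inhale while the
fitted model is rising, exhale while falling).  Frames are then binned by
phase, by amplitude, or by amplitude plus velocity sign, and one
representative frame per (bin, slice) is selected — the frame whose phase
(or amplitude) lies closest to the bin centre, earliest acquisition time
breaking ties.  Empty (bin, slice) cells are reported, never filled by
interpolation: a 16 s cine of a 6 s cycle samples only ~2.7 cycles and
cannot guarantee full coverage, and fabricating slices would be silent
data invention.

Amplitude binning uses the *measured* trace displacement rather than the
fitted model so that irregular breathing degrades gracefully.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np

from .extraction import RespiratoryTrace
from .fitting import SineFitResult
from .simulator import CineStudy

__all__ = [
    "VelocitySign",
    "BinningMode",
    "PhaseAssignment",
    "PhaseBinnedStudy",
    "assign_phases",
    "bin_frames",
    "export_phase_volumes",
]


class VelocitySign(str, enum.Enum):
    INHALE = "inhale"
    EXHALE = "exhale"


class BinningMode(str, enum.Enum):
    PHASE = "phase"
    AMPLITUDE = "amplitude"
    AMPLITUDE_VELOCITY = "amplitude+velocity"


@dataclass(frozen=True)
class PhaseAssignment:
    frame_id: int
    time_s: float
    phase: float  # fraction of cycle in [0, 1)
    amplitude_mm: float
    velocity: VelocitySign


def assign_phases(
    trace: RespiratoryTrace,
    fit: SineFitResult,
    reference_phase_peak_inhale: bool = False,
) -> list:
    """Phase/amplitude/velocity assignment for every sample of a trace.

    phase(t) = ((t - tc)/T) mod 1 from the fitted sine; amplitude is the
    measured trace displacement; the velocity sign comes from the fitted
    model derivative (cos term).  ``reference_phase_peak_inhale`` shifts
    phase 0 to peak inhale (t = tc + T/4) for the clinical convention.

    Requires a converged fit (amplitude-only binning does not, but phases
    are meaningless without a trusted period).
    """
    if not fit.converged or not np.isfinite(fit.period_s):
        raise ValueError("phase assignment requires a converged sine fit")
    t = trace.times_s
    phase = ((t - fit.tc_s) / fit.period_s) % 1.0
    if reference_phase_peak_inhale:
        phase = (phase - 0.25) % 1.0
        rising = (phase >= 0.75) | (phase < 0.25)
    else:
        rising = (phase < 0.25) | (phase >= 0.75)
    out = []
    for fid, ti, ph, amp, ri in zip(
        trace.frame_ids, t, phase, trace.displacement_mm, rising
    ):
        out.append(
            PhaseAssignment(
                frame_id=int(fid),
                time_s=float(ti),
                phase=float(ph),
                amplitude_mm=float(amp),
                velocity=VelocitySign.INHALE if ri else VelocitySign.EXHALE,
            )
        )
    return out


@dataclass
class PhaseBinnedStudy:
    """Result of binning: membership, representatives and coverage."""

    n_bins: int
    mode: BinningMode
    bin_labels: list  # str labels, one per bin
    membership: Dict[int, int]  # frame_id -> bin index
    representatives: Dict[tuple, int]  # (bin index, slice_key) -> frame_id
    slice_keys: list
    empty_cells: list  # (bin index, slice_key) with no frame

    def bin_cardinalities(self) -> np.ndarray:
        counts = np.zeros(len(self.bin_labels), dtype=int)
        for b in self.membership.values():
            counts[b] += 1
        return counts

    def coverage_report(self) -> dict:
        total = len(self.bin_labels) * len(self.slice_keys)
        return {
            "cells_total": total,
            "cells_filled": total - len(self.empty_cells),
            "empty": [
                {"bin": self.bin_labels[b], "slice": list(k)} for b, k in self.empty_cells
            ],
        }


def _circular_distance(phase: float, center: float) -> float:
    d = abs(phase - center) % 1.0
    return min(d, 1.0 - d)


def bin_frames(
    study: CineStudy,
    assignments: Sequence[PhaseAssignment],
    n_bins: int,
    mode: BinningMode = BinningMode.PHASE,
) -> PhaseBinnedStudy:
    """Partition assigned frames into respiratory bins.

    Phase mode: bin k covers [k/n, (k+1)/n).  Amplitude mode: equal-width
    bins over [0, max displacement], top edge inclusive.  With
    amplitude+velocity the amplitude bins are split by velocity sign into
    2n bins (inhale first).  Every assigned frame lands in exactly one
    bin.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    mode = BinningMode(mode)
    by_id = {a.frame_id: a for a in assignments}
    frames = [f for f in study.frames if f.frame_id in by_id]
    missing = [f.frame_id for f in study.frames if f.frame_id not in by_id]
    if missing:
        raise ValueError(
            f"{len(missing)} frame(s) have no phase assignment (e.g. id {missing[0]})"
        )

    amp_max = max((a.amplitude_mm for a in by_id.values()), default=0.0)
    amp_width = amp_max / n_bins if amp_max > 0 else 1.0

    def amp_bin(a: PhaseAssignment) -> int:
        k = int(a.amplitude_mm // amp_width)
        return min(k, n_bins - 1)  # top edge inclusive

    if mode is BinningMode.PHASE:
        labels = [f"phase_{k}" for k in range(n_bins)]

        def bin_of(a):
            return min(int(a.phase * n_bins), n_bins - 1)

        def distance(a, b):
            return _circular_distance(a.phase, (b + 0.5) / n_bins)

    elif mode is BinningMode.AMPLITUDE:
        labels = [f"amp_{k}" for k in range(n_bins)]

        def bin_of(a):
            return amp_bin(a)

        def distance(a, b):
            return abs(a.amplitude_mm - (b + 0.5) * amp_width)

    else:  # amplitude + velocity: 2*n_bins bins, inhale first
        labels = [
            f"amp_{k}_{sign.value}"
            for k in range(n_bins)
            for sign in (VelocitySign.INHALE, VelocitySign.EXHALE)
        ]

        def bin_of(a):
            return 2 * amp_bin(a) + (0 if a.velocity is VelocitySign.INHALE else 1)

        def distance(a, b):
            return abs(a.amplitude_mm - (b // 2 + 0.5) * amp_width)

    membership = {a.frame_id: bin_of(a) for a in by_id.values()}
    slice_keys = study.slice_keys()
    representatives: Dict[tuple, int] = {}
    best: Dict[tuple, tuple] = {}
    for f in frames:
        a = by_id[f.frame_id]
        b = membership[f.frame_id]
        key = (b, f.slice_key)
        cand = (distance(a, b), a.time_s, f.frame_id)
        if key not in best or cand < best[key]:
            best[key] = cand
            representatives[key] = f.frame_id
    empty = [
        (b, k)
        for b in range(len(labels))
        for k in slice_keys
        if (b, k) not in representatives
    ]
    return PhaseBinnedStudy(
        n_bins=n_bins,
        mode=mode,
        bin_labels=labels,
        membership=membership,
        representatives=representatives,
        slice_keys=slice_keys,
        empty_cells=empty,
    )


def export_phase_volumes(
    study: CineStudy,
    binned: PhaseBinnedStudy,
    path,
    format: str = "tiff",
) -> dict:
    """Write one 3D volume per bin (representative slice per Z) plus a
    manifest; returns the manifest.

    TIFF output: ``bin_<label>.tif`` multi-page stacks ordered by slice Z.
    DICOM output: ``bin_<label>/slice_<i>.dcm`` series.  Bins with no
    representative at any slice are skipped and recorded in the manifest.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {"mode": binned.mode.value, "volumes": [], "skipped_bins": [], "cells": []}
    z_sorted = sorted(binned.slice_keys, key=lambda k: study.slice_z(k))
    for b, label in enumerate(binned.bin_labels):
        reps = [(k, binned.representatives.get((b, k))) for k in z_sorted]
        present = [(k, fid) for k, fid in reps if fid is not None]
        if not present:
            manifest["skipped_bins"].append(label)
            continue
        stack = np.stack([study.frame_by_id(fid).pixels for _, fid in present])
        if format == "tiff":
            import tifffile

            out = path / f"bin_{label}.tif"
            tifffile.imwrite(out, stack)
        elif format == "dicom":
            from .studyio import _frame_to_dataset

            out = path / f"bin_{label}"
            out.mkdir(exist_ok=True)
            for i, (_, fid) in enumerate(present):
                ds = _frame_to_dataset(study.frame_by_id(fid), series_number=b + 1)
                ds.save_as(out / f"slice_{i:03d}.dcm", enforce_file_format=True)
        else:
            raise ValueError(f"unknown format: {format}")
        manifest["volumes"].append({"bin": label, "n_slices": len(present), "file": f"bin_{label}"})
        for k, fid in present:
            manifest["cells"].append({"bin": label, "slice": list(k), "frame_id": int(fid)})
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
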