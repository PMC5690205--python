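"""End-to-end convenience chains: study -> trace -> fit -> sorted bins."""

from __future__ import annotations

from typing import Optional, Sequence

from .detection import DEFAULT_PARAMS, DetectionParams, track_wires
from .extraction import (
    RespiratoryTrace,
    average_traces,
    build_respiratory_trace,
    compute_az_series,
)
from .fitting import SineFitResult, fit_sine
from .simulator import CineStudy
from .sorting import BinningMode, PhaseBinnedStudy, assign_phases, bin_frames

__all__ = ["extract_trace", "fit_study", "sort_study"]


def extract_trace(
    study: CineStudy,
    slice_key: Optional[tuple] = None,
    params: DetectionParams = DEFAULT_PARAMS,
) -> RespiratoryTrace:
    """Detect, track and reconstruct the trace for one slice.

    Default slice is the most distal one from the central piece — the
    hardest case: if the signal is recovered there, the closer slices
    with larger wire excursions follow a fortiori.
    """
    if slice_key is None:
        slice_key = study.most_distal_slice()
    frames = study.frames_for_slice(slice_key)
    track = track_wires(frames, params)
    az = compute_az_series(track)
    return build_respiratory_trace(
        az, study.geometry, min_cycles_s=(
            study.ground_truth.period_s if study.ground_truth is not None else None
        ),
    )


def fit_study(
    study: CineStudy,
    slice_key: Optional[tuple] = None,
    params: DetectionParams = DEFAULT_PARAMS,
):
    """Trace + sine fit for one slice; returns ``(trace, fit)``."""
    trace = extract_trace(study, slice_key, params)
    return trace, fit_sine(trace)


def sort_study(
    study: CineStudy,
    n_bins: int = 10,
    mode: BinningMode = BinningMode.PHASE,
    params: DetectionParams = DEFAULT_PARAMS,
    reference_slices: Optional[Sequence[tuple]] = None,
) -> tuple:
    """Retrospectively sort every frame of a study into respiratory bins.

    One sine fit (from the most distal slice) provides the global phase
    model (tc, T); each slice's own trace provides per-frame measured
    amplitudes.  Returns ``(binned, fit)``.
    """
    ref_trace, fit = fit_study(study, params=params)
    if not fit.converged:
        raise RuntimeError("reference sine fit did not converge; cannot phase-sort")
    assignments = []
    keys = reference_slices if reference_slices is not None else study.slice_keys()
    for key in keys:
        trace = extract_trace(study, key, params)
        assignments.extend(assign_phases(trace, fit))
    # frames whose slice was skipped or invalid are excluded before binning
    assigned_ids = {a.frame_id for a in assignments}
    sub = CineStudy(
        frames=[f for f in study.frames if f.frame_id in assigned_ids],
        geometry=study.geometry,
        acquisition=study.acquisition,
        scene=study.scene,
        ground_truth=study.ground_truth,
    )
    binned = bin_frames(sub, assignments, n_bins=n_bins, mode=mode)
    return binned, fit
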