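"""Cohort figures: per-strike grey traces with a dark mean overlay.

Layouts mirror the standard presentation of strike kinematics — elevation
over time, curvature profile per centrum position, and joint-rotation deltas
per joint.
"""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .axial_pipeline import CohortResult  # noqa: E402


def fig_elevation(result: CohortResult):
    """Cranial elevation over time, onset-aligned, per strike plus mean."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for a in result.included:
        t = (np.arange(len(a.elevation.elevation))
             - a.elevation.onset_frame) / a.frame_rate
        ax.plot(t * 1000, a.elevation.elevation, color="0.75", lw=0.8)
    if result.mean_elevation is not None:
        t, m = result.mean_elevation
        ax.plot(t * 1000, m, color="#1f4e79", lw=2.0, label="mean")
        ax.legend(frameon=False)
    ax.set_xlabel("time from onset (ms)")
    ax.set_ylabel("cranial elevation (deg)")
    fig.tight_layout()
    return fig


def fig_curvature(result: CohortResult):
    """Dorsoventral centrum translations at peak elevation, per strike."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    profiles = [a.curvature_peak.y_rel_mm for a in result.included]
    for y in profiles:
        ax.plot(np.arange(len(y)), y, color="0.75", lw=0.8)
    if profiles:
        ax.plot(np.arange(len(profiles[0])), np.nanmean(profiles, axis=0),
                color="#1f4e79", lw=2.0, label="mean")
        ax.legend(frameon=False)
    ax.axhline(0, color="k", lw=0.5, ls="--")
    ax.set_xlabel("position (0 = neurocranium, then centra)")
    ax.set_ylabel("dorsoventral translation (mm)")
    fig.tight_layout()
    return fig


def fig_joint_deltas(result: CohortResult):
    """Dorsoventral joint rotations at peak elevation, per strike plus mean."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    deltas = [a.deltas_deg for a in result.included]
    for d in deltas:
        ax.plot(np.arange(1, len(d) + 1), d, color="0.75", lw=0.8)
    if deltas:
        ax.plot(np.arange(1, len(deltas[0]) + 1), np.nanmean(deltas, axis=0),
                color="#1f4e79", lw=2.0, label="mean")
        ax.legend(frameon=False)
    ax.axhline(0, color="k", lw=0.5, ls="--")
    ax.set_xlabel("joint (1 = craniovertebral)")
    ax.set_ylabel("dorsoventral rotation (deg)")
    fig.tight_layout()
    return fig
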