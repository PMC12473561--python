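"""End-to-end analysis: preprocess → CoM → events → strides → spectra.

This is the library face the CLI, the examples and the acceptance script all
call; each stage is also available individually from its own module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .com_kinematics import (
    PhaseNormalizedStride,
    SpectralSummary,
    bowtie_projection,
    normalize_strides,
    spectral_summary,
)
from .com_model import AnthropometricTable, ComTrajectory, com_trajectory, default_table
from .gait_events import (
    BilateralEvents,
    EventDetectionConfig,
    detect_side_events,
    validate_event_sequence,
)
from .gait_metrics import (
    MetricsConfig,
    StrideRecord,
    SubjectSummary,
    compute_strides,
    stride_metric_values,
    summarize,
)
from .preprocess import QualityReport, exclude_participant_rule, impute_single_frame_gaps, quality_report
from .skeleton_io import SkeletonSequence


@dataclass
class AnalysisResult:
    seq: SkeletonSequence
    com: ComTrajectory
    bilateral: BilateralEvents
    strides: list[StrideRecord]
    summary: SubjectSummary
    quality: QualityReport
    participant_excluded: bool
    normalized: list[PhaseNormalizedStride] = field(default_factory=list)
    spectral: SpectralSummary | None = None

    def stride_values(self) -> dict[str, list[float]]:
        return stride_metric_values(self.strides)


def analyze_sequence(
    seq: SkeletonSequence,
    table: AnthropometricTable | None = None,
    event_config: EventDetectionConfig | None = None,
    metrics_config: MetricsConfig | None = None,
    n_phase: int = 101,
    spectral: bool = True,
) -> AnalysisResult:
    """Run the full pipeline on one recording.

    Preprocessing imputes isolated single-frame gaps; events come from the
    per-side ankle AP velocity; strides, per-stride metrics and the subject
    summary follow; the spectral summary is computed when the valid CoM run is
    long enough (and silently omitted otherwise, since short recordings have
    too coarse a frequency resolution).
    """
    table = table or default_table()
    event_config = event_config or EventDetectionConfig()
    metrics_config = metrics_config or MetricsConfig()

    seq = impute_single_frame_gaps(seq)
    com = com_trajectory(seq, table)
    bilateral = validate_event_sequence(
        detect_side_events(seq, "left", event_config),
        detect_side_events(seq, "right", event_config),
    )
    strides = compute_strides(seq, com, bilateral, "left", metrics_config) + compute_strides(
        seq, com, bilateral, "right", metrics_config
    )
    summary = summarize(strides)
    quality = quality_report(seq, strides, required_joints=metrics_config.required_joints)
    # phase alignment follows the left heel-down convention: left and right
    # strides are ML-antiphase, so averaging both sides would cancel the mean
    left_strides = [s for s in strides if s.side == "left"]
    normalized = normalize_strides(com, left_strides, n_phase=n_phase)

    spec = None
    if spectral:
        try:
            spec = spectral_summary(com)
        except ValueError:
            spec = None

    return AnalysisResult(
        seq=seq,
        com=com,
        bilateral=bilateral,
        strides=strides,
        summary=summary,
        quality=quality,
        participant_excluded=exclude_participant_rule(quality),
        normalized=normalized,
        spectral=spec,
    )


def write_outputs(result: AnalysisResult, out_dir, plots: bool = False, metadata: dict | None = None):
    """Write the stride table, subject summary, quality report, spectral
    summary, normalized-stride matrices and (optionally) figures."""
    import json
    from pathlib import Path

    import pandas as pd

    from .gait_metrics import strides_to_frame

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    strides_to_frame(result.strides).to_csv(out / "strides.csv", index=False)
    result.summary.to_frame().to_csv(out / "subject_summary.csv", index=False)
    qual = result.quality.to_dict()
    qual["participant_excluded"] = result.participant_excluded
    if metadata:
        qual["run_metadata"] = metadata
    with open(out / "quality.json", "w") as fh:
        json.dump(qual, fh, indent=1)
    if result.spectral is not None:
        with open(out / "spectral.json", "w") as fh:
            json.dump(
                {
                    "dominant_hz": result.spectral.dominant_hz,
                    "ml_to_vertical_frequency_ratio": result.spectral.ml_to_vertical_frequency_ratio,
                },
                fh,
                indent=1,
            )
    if result.normalized:
        for k, axis in enumerate(("ml", "ap", "vert")):
            mat = np.column_stack([p.values[:, k] for p in result.normalized])
            pd.DataFrame(
                mat, index=result.normalized[0].phase_grid
            ).to_csv(out / f"normalized_{axis}.csv", index_label="phase")
    if plots and result.normalized:
        _write_plots(result, out)
    return out


def _write_plots(result: AnalysisResult, out) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .com_kinematics import mean_trajectory

    mean, sd = mean_trajectory(result.normalized)
    grid = result.normalized[0].phase_grid
    fig, axes = plt.subplots(3, 1, figsize=(6, 8), sharex=True)
    for k, (axis, label) in enumerate(zip((0, 1, 2), ("medial-lateral", "fore-aft", "vertical"))):
        ax = axes[k]
        for p in result.normalized:
            ax.plot(grid, p.values[:, axis], color="0.8", lw=0.5)
        ax.plot(grid, mean[:, axis], color="k", lw=2)
        ax.set_ylabel(f"{label} (mm)")
    axes[-1].set_xlabel("stride phase")
    fig.tight_layout()
    fig.savefig(out / "com_phase.png", dpi=100)
    plt.close(fig)

    proj = bowtie_projection(result.normalized)
    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    axes[0].plot(proj.ml_vs_vert[:, 0], proj.ml_vs_vert[:, 1], "k-")
    axes[0].set_xlabel("ML (mm)")
    axes[0].set_ylabel("vertical (mm)")
    axes[1].plot(proj.ml_vs_ap[:, 0], proj.ml_vs_ap[:, 1], "k-")
    axes[1].set_xlabel("ML (mm)")
    axes[1].set_ylabel("fore-aft (mm)")
    fig.tight_layout()
    fig.savefig(out / "com_bowtie.png", dpi=100)
    plt.close(fig)
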