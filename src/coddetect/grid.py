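"""Run the detection-parameter grid and build the validity report.

The assessment protocol evaluates every combination of smoothing
percentage and PmI threshold (3 x 3, at each of two approach speeds: 18
configurations) over a set of recordings tagged with participant, device
and speed, sums detected-COD counts per participant, and compares each
device x configuration cell against criterion (video-coded) counts with
the statistics in :mod:`coddetect.stats`.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .detection import DetectionConfig, detect_cods
from .recording import SensorRecording
from .stats import (
    EffectSize,
    GroupSummary,
    between_device_cv,
    cohens_d,
    cv_pct,
    percent_diff,
)

__all__ = ["TaggedRecording", "run_grid", "build_report", "summarize_counts"]

GRID_SMOOTHINGS = (20.0, 30.0, 40.0)
GRID_PMIS = (0.8, 0.9, 1.0)


@dataclass(frozen=True)
class TaggedRecording:
    """A recording plus the trial metadata the grid needs."""

    recording: SensorRecording
    participant_id: str
    device_id: str
    speed_kmh: float


def run_grid(
    recordings: list[TaggedRecording],
    smoothings=GRID_SMOOTHINGS,
    pmis=GRID_PMIS,
    min_peak_separation_s: float = 0.10,
    merge_gap_s: float = 0.50,
) -> pd.DataFrame:
    """Detect CODs in every recording under every (smoothing, PmI) pair.

    Returns a tidy frame with one row per device x speed x smoothing x PmI
    x participant, carrying the summed COD count over that participant's
    recordings. Deterministic for fixed inputs.
    """
    for i, tagged in enumerate(recordings):
        if not tagged.participant_id or not tagged.device_id:
            raise ValueError(f"recording {i} lacks participant/device metadata")
    rows = []
    for smoothing, pmi in product(smoothings, pmis):
        config = DetectionConfig(
            smoothing_pct=smoothing,
            pmi_g=pmi,
            min_peak_separation_s=min_peak_separation_s,
            merge_gap_s=merge_gap_s,
        )
        for tagged in recordings:
            rows.append(
                {
                    "device": tagged.device_id,
                    "speed_kmh": tagged.speed_kmh,
                    "smoothing_pct": smoothing,
                    "pmi_g": pmi,
                    "participant": tagged.participant_id,
                    "cod_count": len(detect_cods(tagged.recording, config)),
                }
            )
    keys = ["device", "speed_kmh", "smoothing_pct", "pmi_g", "participant"]
    if not rows:
        return pd.DataFrame(columns=keys + ["cod_count"])
    df = pd.DataFrame(rows)
    return df.groupby(keys, as_index=False)["cod_count"].sum()


def summarize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean/SD/n of participant counts.

    ``counts`` must have columns device, speed_kmh, smoothing_pct, pmi_g,
    participant, cod_count (one row per participant per cell).
    """
    keys = ["device", "speed_kmh", "smoothing_pct", "pmi_g"]
    return counts.groupby(keys, as_index=False)["cod_count"].agg(
        mean="mean", sd="std", n="count"
    )


def build_report(
    grid: pd.DataFrame, reference_counts: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validity table and between-device CV summary for a grid result.

    Parameters
    ----------
    grid : DataFrame
        Output of :func:`run_grid`.
    reference_counts : DataFrame
        Criterion counts with columns participant, speed_kmh, cod_count —
        one row per participant per speed (e.g. video-coded totals).

    Returns
    -------
    report : DataFrame
        One row per device x configuration: count mean ± SD, percentage
        difference, Cohen's d with 95% CI and magnitude label, CV.
    cv_summary : DataFrame
        Between-device CV per configuration plus rows grouping the
        per-configuration CVs by speed, by smoothing and by PmI.
    """
    missing = set(grid["participant"]) - set(reference_counts["participant"])
    if missing:
        raise ValueError(f"reference counts missing for participant(s): {sorted(missing)}")
    needed = set(grid["speed_kmh"].unique()) - set(reference_counts["speed_kmh"].unique())
    if needed:
        raise ValueError(f"reference counts missing for speed(s): {sorted(needed)}")
    ref_groups = {
        speed: GroupSummary.from_values(sub["cod_count"].to_numpy())
        for speed, sub in reference_counts.groupby("speed_kmh")
    }

    rows = []
    for (device, speed, smoothing, pmi), sub in grid.groupby(
        ["device", "speed_kmh", "smoothing_pct", "pmi_g"]
    ):
        summary = GroupSummary.from_values(sub["cod_count"].to_numpy())
        reference = ref_groups[speed]
        try:
            effect = cohens_d(summary, reference)
        except ValueError:
            # zero pooled SD: counts agree exactly or differ degenerately
            d = 0.0 if summary.mean == reference.mean else np.nan
            label = "trivial" if d == 0.0 else "undefined"
            effect = EffectSize(d=d, ci_low=d, ci_high=d, label=label)
        rows.append(
            {
                "device": device,
                "speed_kmh": speed,
                "smoothing_pct": smoothing,
                "pmi_g": pmi,
                "mean": summary.mean,
                "sd": summary.sd,
                "n": summary.n,
                "pct_diff": percent_diff(summary, reference),
                "d": effect.d,
                "d_ci_low": effect.ci_low,
                "d_ci_high": effect.ci_high,
                "label": effect.label,
                "cv": cv_pct(summary) if summary.mean != 0 else np.nan,
            }
        )
    report = pd.DataFrame(rows)

    per_config = []
    for (speed, smoothing, pmi), sub in report.groupby(
        ["speed_kmh", "smoothing_pct", "pmi_g"]
    ):
        if len(sub) >= 2:
            per_config.append(
                {
                    "speed_kmh": speed,
                    "smoothing_pct": smoothing,
                    "pmi_g": pmi,
                    "cv_between": between_device_cv(sub["mean"].to_numpy()),
                }
            )
    if not per_config:
        return report, pd.DataFrame(columns=["group", "level", "cv_between"])
    per_config = pd.DataFrame(per_config)
    summary_rows = [
        {"group": "configuration", "level": f"{r.speed_kmh:g}/{r.smoothing_pct:g}/{r.pmi_g:g}",
         "cv_between": r.cv_between}
        for r in per_config.itertuples()
    ]
    # grouped views average the per-configuration CVs
    for col, name in (
        ("speed_kmh", "speed"),
        ("smoothing_pct", "smoothing"),
        ("pmi_g", "pmi"),
    ):
        for level, sub in per_config.groupby(col):
            summary_rows.append(
                {"group": name, "level": f"{level:g}", "cv_between": sub["cv_between"].mean()}
            )
    return report, pd.DataFrame(summary_rows)
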