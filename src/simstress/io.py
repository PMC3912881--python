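"""CSV dialects shared across the pipeline.

* RR series: columns ``t_s`` (cumulative seconds, 6 decimals), ``rr_ms``;
  one beat per row, interval paired with its starting beat time.
* Questionnaire responses: ``participant_id``, ``condition``, ``item``,
  ``response`` (long format).
* Segment definitions: ``segment``, ``start_s``, ``end_s``.
* Band-power tracks: ``window_center_s``, ``lf_ms2``, ``hf_ms2``, ``ratio``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .hrv import BandPowerTrack, RRSeries

__all__ = [
    "write_rr_csv",
    "read_rr_csv",
    "write_band_power_csv",
    "read_segments_csv",
    "write_questionnaire_csv",
    "read_questionnaire_csv",
]


def write_rr_csv(rr: RRSeries, path) -> None:
    df = pd.DataFrame(
        {"t_s": np.round(rr.beat_times[:-1], 6), "rr_ms": rr.intervals}
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_rr_csv(path, participant_id: str | None = None,
                segment: str | None = None) -> RRSeries:
    df = pd.read_csv(path)
    if not {"t_s", "rr_ms"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns t_s, rr_ms")
    t = df["t_s"].to_numpy(dtype=float)
    rr = df["rr_ms"].to_numpy(dtype=float)
    beat_times = np.concatenate([t, [t[-1] + rr[-1] / 1000.0]])
    return RRSeries(beat_times, rr, participant_id=participant_id, segment=segment)


def write_band_power_csv(track: BandPowerTrack, path) -> None:
    pd.DataFrame(
        {
            "window_center_s": track.window_centers,
            "lf_ms2": track.lf_power,
            "hf_ms2": track.hf_power,
            "ratio": track.ratio,
        }
    ).to_csv(path, index=False, float_format="%.6f")


def read_segments_csv(path) -> dict[str, tuple[float, float]]:
    df = pd.read_csv(path)
    if not {"segment", "start_s", "end_s"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns segment, start_s, end_s")
    return {
        str(row.segment): (float(row.start_s), float(row.end_s))
        for row in df.itertuples()
    }


def write_questionnaire_csv(table: pd.DataFrame, path) -> None:
    cols = ["participant_id", "condition", "item", "response"]
    missing = set(cols) - set(table.columns)
    if missing:
        raise ValueError(f"questionnaire table missing columns: {sorted(missing)}")
    table[cols].to_csv(path, index=False)


def read_questionnaire_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"participant_id", "condition", "item", "response"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
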