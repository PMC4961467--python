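"""Plain-text (TSV) readers and writers for session inputs and outputs."""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import EyeTrace, SaccadeEvent, SpikeTrain, TimeSeries


def _infer_rate(t: np.ndarray) -> float:
    dt = np.median(np.diff(t))
    return 1.0 / dt


def read_lfp_tsv(path) -> TimeSeries:
    """Two-column TSV: time_s, value."""
    df = pd.read_csv(path, sep="\t")
    t = df.iloc[:, 0].to_numpy(float)
    return TimeSeries(df.iloc[:, 1].to_numpy(float), _infer_rate(t), t0=float(t[0]))


def write_lfp_tsv(path, lfp: TimeSeries) -> None:
    pd.DataFrame({"time_s": lfp.times, "value": lfp.samples}).to_csv(
        path, sep="\t", index=False
    )


def read_eye_tsv(path) -> EyeTrace:
    """Three-column TSV: time_s, x_deg, y_deg."""
    df = pd.read_csv(path, sep="\t")
    t = df.iloc[:, 0].to_numpy(float)
    rate = _infer_rate(t)
    return EyeTrace(
        TimeSeries(df.iloc[:, 1].to_numpy(float), rate, float(t[0])),
        TimeSeries(df.iloc[:, 2].to_numpy(float), rate, float(t[0])),
    )


def write_eye_tsv(path, eye: EyeTrace) -> None:
    pd.DataFrame(
        {
            "time_s": eye.horizontal.times,
            "x_deg": eye.horizontal.samples,
            "y_deg": eye.vertical.samples,
        }
    ).to_csv(path, sep="\t", index=False)


def read_spikes_tsv(path) -> SpikeTrain:
    """TSV with columns time_s[, unit_id], kind."""
    df = pd.read_csv(path, sep="\t")
    kinds = df["kind"].to_numpy(object) if "kind" in df else None
    return SpikeTrain(df["time_s"].to_numpy(float), kinds)


def write_spikes_tsv(path, train: SpikeTrain, unit_id: int = 0) -> None:
    pd.DataFrame(
        {"time_s": train.times, "unit_id": unit_id, "kind": train.kinds}
    ).to_csv(path, sep="\t", index=False)


def read_saccades_tsv(path) -> list[SaccadeEvent]:
    df = pd.read_csv(path, sep="\t")
    return [
        SaccadeEvent(
            onset=r.onset_s,
            offset=r.offset_s,
            angle_theta=r.theta_deg,
            amplitude=r.amplitude_deg,
        )
        for r in df.itertuples()
    ]


def write_saccades_tsv(path, saccades) -> None:
    pd.DataFrame(
        {
            "onset_s": [s.onset for s in saccades],
            "offset_s": [s.offset for s in saccades],
            "theta_deg": [s.angle_theta for s in saccades],
            "amplitude_deg": [s.amplitude for s in saccades],
            "duration_ms": [s.duration_L for s in saccades],
        }
    ).to_csv(path, sep="\t", index=False)


def write_ccf_tsv(path, ccf) -> None:
    pd.DataFrame(
        {
            "lag_ms": ccf.lags_ms,
            "value": ccf.value,
            "control_mean": ccf.control_mean,
            "control_sd": ccf.control_sd,
        }
    ).to_csv(path, sep="\t", index=False)


def write_session(outdir, session) -> None:
    """Write a generated session in the same TSV formats the analysis reads,
    plus a ground-truth sidecar."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_lfp_tsv(out / "lfp.tsv", session.lfp)
    write_eye_tsv(out / "eye.tsv", session.eye)
    write_spikes_tsv(out / "spikes.tsv", session.spikes)
    write_saccades_tsv(out / "saccades_truth.tsv", session.truth.saccades)
    pd.DataFrame(
        {"time_s": session.spikes.times, "true_category": session.truth.category}
    ).to_csv(out / "categories_truth.tsv", sep="\t", index=False)
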