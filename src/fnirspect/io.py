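"""Plain-text I/O: recording CSV + JSON sidecar, HemoSeries CSV, band
table CSV, spectra CSV and JSON reports.

The recording dialect is long-format CSV with columns
``time_s, channel_id, wavelength_nm, intensity_counts`` (wavelength
``dark`` for the dark-current rows) plus a JSON sidecar carrying the
channel map, subject age, condition schedule, sampling rate and a config
echo. All writers are deterministic for fixed inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ChannelMap
from .preprocess import WAVELENGTHS, HemoSeries, OpticalRecording


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def recording_to_frame(rec: OpticalRecording) -> pd.DataFrame:
    t = rec.time
    ids = rec.channel_map.channel_ids
    frames = []
    for i, cid in enumerate(ids):
        for w, lam in enumerate(WAVELENGTHS):
            frames.append(
                pd.DataFrame(
                    {
                        "time_s": t,
                        "channel_id": cid,
                        "wavelength_nm": f"{lam:.0f}",
                        "intensity_counts": rec.intensity[i, w],
                    }
                )
            )
        frames.append(
            pd.DataFrame(
                {
                    "time_s": t,
                    "channel_id": cid,
                    "wavelength_nm": "dark",
                    "intensity_counts": rec.dark[i],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_recording(rec: OpticalRecording, csv_path: str | Path) -> None:
    """Write the long-format CSV plus a ``.json`` sidecar next to it."""
    csv_path = Path(csv_path)
    recording_to_frame(rec).to_csv(csv_path, index=False)
    sidecar = {
        "sampling_rate": rec.sampling_rate,
        "age": rec.age,
        "schedule": [[label, s, e] for label, s, e in rec.schedule],
        "channel_map": rec.channel_map.to_records(),
        "regions": {k: list(v) for k, v in rec.channel_map.regions.items()},
        "baseline_intensity": {f"{k:.0f}": v for k, v in (rec.baseline_intensity or {}).items()},
        "meta": rec.meta,
    }
    write_json(sidecar, csv_path.with_suffix(".json"))


def read_recording(csv_path: str | Path) -> OpticalRecording:
    csv_path = Path(csv_path)
    sidecar = read_json(csv_path.with_suffix(".json"))
    df = pd.read_csv(csv_path, dtype={"wavelength_nm": str}, float_precision="round_trip")
    cmap = ChannelMap.from_records(sidecar["channel_map"], sidecar.get("regions"))
    ids = cmap.channel_ids
    n = df[df["channel_id"] == ids[0]].query("wavelength_nm == 'dark'").shape[0]
    intensity = np.zeros((len(ids), 2, n))
    dark = np.zeros((len(ids), n))
    for i, cid in enumerate(ids):
        sub = df[df["channel_id"] == cid]
        for w, lam in enumerate(WAVELENGTHS):
            intensity[i, w] = sub[sub["wavelength_nm"] == f"{lam:.0f}"][
                "intensity_counts"
            ].to_numpy()
        dark[i] = sub[sub["wavelength_nm"] == "dark"]["intensity_counts"].to_numpy()
    baseline = {
        float(k): float(v) for k, v in (sidecar.get("baseline_intensity") or {}).items()
    } or None
    return OpticalRecording(
        intensity=intensity,
        dark=dark,
        sampling_rate=float(sidecar["sampling_rate"]),
        age=float(sidecar["age"]),
        schedule=[(str(a), float(b), float(c)) for a, b, c in sidecar["schedule"]],
        channel_map=cmap,
        baseline_intensity=baseline,
        meta=sidecar.get("meta", {}),
    )


def hemo_to_frame(hemo: HemoSeries, subject: str | None = None) -> pd.DataFrame:
    t = np.arange(hemo.n_samples) / hemo.sampling_rate
    frames = []
    for region in hemo.regions:
        for biomarker, series in hemo.data[region].items():
            frame = pd.DataFrame(
                {"time_s": t, "region": region, "biomarker": biomarker, "value_uM": series}
            )
            if subject is not None:
                frame.insert(0, "subject", subject)
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def write_hemo(hemo: HemoSeries, path: str | Path, subject: str | None = None) -> None:
    hemo_to_frame(hemo, subject=subject).to_csv(path, index=False)


def write_band_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_band_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, dtype={"subject": str, "condition": str}, float_precision="round_trip"
    )
    required = {"subject", "condition", "sds", "hemisphere", "band", "biomarker", "epsilon", "rel_epsilon"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"band table missing columns: {sorted(missing)}")
    return df


def write_spectrum(freqs: np.ndarray, amplitude: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"frequency_hz": freqs, "mean_amplitude": amplitude}).to_csv(
        path, index=False
    )


def export_scalogram(sg, path: str | Path) -> None:
    """Compressed matrix export with axes and parameters in a JSON header."""
    header = json.dumps(
        {
            "sampling_rate": sg.sampling_rate,
            "f0": sg.f0,
            "n_freqs": len(sg.freqs),
            "n_samples": sg.coeffs.shape[1],
        },
        sort_keys=True,
    )
    np.savez_compressed(
        path,
        header=np.array(header),
        magnitude=sg.magnitude,
        freqs=sg.freqs,
        times=sg.times,
    )
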