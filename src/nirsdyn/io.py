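"""Plain-text interchange: TSV matrices plus a JSON metadata sidecar.

``hbo.tsv`` and ``eeg.tsv`` are samples x channels matrices with a header
of channel/electrode ids.  ``sidecar.json`` carries the layout (ROI
labels, separation class), sampling rates, the generating config and — for
synthetic data — the ground truth.  Analysis stages never read the ground
truth; it exists for parameter-recovery evaluation only.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ChannelLayout, EEGRecording, HemoSeries
from .synthetic import GroundTruth, SynthConfig, SyntheticSubject

SIDECAR_NAME = "sidecar.json"


def write_subject(out_dir: str | Path, subject: SyntheticSubject,
                  config: SynthConfig | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_hemo(out / "hbo.tsv", subject.hemo)
    write_eeg(out / "eeg.tsv", subject.eeg)
    sidecar = {
        "layout": subject.hemo.layout.to_dict(),
        "fnirs_dt_s": subject.hemo.dt_s,
        "eeg_rate_hz": subject.eeg.rate_hz,
        "ground_truth": subject.truth.to_dict(),
    }
    if config is not None:
        sidecar["config"] = dataclasses.asdict(config)
    (out / SIDECAR_NAME).write_text(json.dumps(sidecar))


def read_subject(in_dir: str | Path) -> SyntheticSubject:
    src = Path(in_dir)
    meta = json.loads((src / SIDECAR_NAME).read_text())
    layout = ChannelLayout.from_dict(meta["layout"])
    hemo = read_hemo(src / "hbo.tsv", dt_s=meta["fnirs_dt_s"], layout=layout)
    eeg = read_eeg(src / "eeg.tsv", rate_hz=meta["eeg_rate_hz"])
    truth = GroundTruth.from_dict(meta["ground_truth"])
    return SyntheticSubject(hemo=hemo, eeg=eeg, truth=truth)


def write_hemo(path: str | Path, x: HemoSeries) -> None:
    ids = x.layout.channel_ids if x.layout else [f"CH{i + 1:02d}" for i in range(x.n_channels)]
    pd.DataFrame(x.hbo.T, columns=list(ids)).to_csv(path, sep="\t", index=False,
                                                    float_format="%.8g")


def read_hemo(path: str | Path, dt_s: float, layout: ChannelLayout | None = None) -> HemoSeries:
    df = pd.read_csv(path, sep="\t")
    return HemoSeries(hbo=df.to_numpy().T, dt_s=dt_s, layout=layout)


def write_eeg(path: str | Path, x: EEGRecording) -> None:
    pd.DataFrame(x.v.T, columns=list(x.electrode_ids)).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_eeg(path: str | Path, rate_hz: float) -> EEGRecording:
    df = pd.read_csv(path, sep="\t")
    return EEGRecording(v=df.to_numpy().T, rate_hz=rate_hz,
                        electrode_ids=tuple(df.columns))


def write_matrix(path: str | Path, m: np.ndarray, columns=None) -> None:
    pd.DataFrame(np.asarray(m), columns=columns).to_csv(path, sep="\t", index=False,
                                                        float_format="%.8g")
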