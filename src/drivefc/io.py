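"""Plain-text session dialect: wide time-series CSV, events CSV, montage
CSV, and ground-truth JSON.

One session is four files:

* ``<stem>_series.csv`` — column 1 ``time_s``; per long channel
  ``chN_hbo`` / ``chN_hbr``; per short channel ``scN_hbo`` / ``scN_hbr``.
* ``<stem>_events.csv`` — ``onset_s``, ``type`` in {beep, brake}.
* ``<stem>_montage.csv`` — channel, source, detector, is_short,
  aal_region, network, ssr_partner.
* ``<stem>_truth.json`` — planted edges and coefficients (synthetic only).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import GroundTruth, Session


def session_frame(session: Session) -> pd.DataFrame:
    data = {"time_s": session.time}
    for c in range(session.oxy.shape[1]):
        data[f"ch{c + 1}_hbo"] = session.oxy[:, c]
        data[f"ch{c + 1}_hbr"] = session.deoxy[:, c]
    for s in range(session.short_oxy.shape[1]):
        data[f"sc{s + 1}_hbo"] = session.short_oxy[:, s]
        data[f"sc{s + 1}_hbr"] = session.short_deoxy[:, s]
    return pd.DataFrame(data)


def events_frame(session: Session) -> pd.DataFrame:
    ev = pd.concat(
        [
            pd.DataFrame({"onset_s": session.beep_times, "type": "beep"}),
            pd.DataFrame({"onset_s": session.brake_onsets, "type": "brake"}),
        ]
    )
    return ev.sort_values("onset_s", kind="stable").reset_index(drop=True)


def truth_dict(truth: GroundTruth) -> dict:
    return {
        "planted_pairs": [list(p) for p in truth.planted_pairs],
        "planted_edge_indices": list(truth.planted_edge_indices),
        "target_r": truth.target_r.tolist(),
        "true_coefficients": truth.true_coefficients.tolist(),
        "intercept_ms": truth.intercept_ms,
        "noise_free_brt_ms": truth.noise_free_brt_ms.tolist(),
        "brt_ms": truth.brt_ms.tolist(),
        "outlier_mask": truth.outlier_mask.astype(int).tolist(),
        "latent_state": truth.latent_state.tolist(),
    }


def write_session(
    session: Session, stem: str | Path, truth: GroundTruth | None = None
) -> list[Path]:
    """Write a session (and optional ground truth) to ``<stem>_*`` files."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    p = stem.with_name(stem.name + "_series.csv")
    session_frame(session).to_csv(p, index=False)
    paths.append(p)
    p = stem.with_name(stem.name + "_events.csv")
    events_frame(session).to_csv(p, index=False)
    paths.append(p)
    p = stem.with_name(stem.name + "_montage.csv")
    session.montage.to_csv(p, index=False)
    paths.append(p)
    if truth is not None:
        p = stem.with_name(stem.name + "_truth.json")
        with open(p, "w") as fh:
            json.dump(truth_dict(truth), fh)
        paths.append(p)
    return paths


def read_session(stem: str | Path) -> Session:
    """Read a session written by :func:`write_session`."""
    stem = Path(stem)
    series = pd.read_csv(stem.with_name(stem.name + "_series.csv"))
    events = pd.read_csv(stem.with_name(stem.name + "_events.csv"))
    montage = pd.read_csv(
        stem.with_name(stem.name + "_montage.csv"), keep_default_na=False
    )
    time = series["time_s"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(time)))
    long_names = [
        c[: -len("_hbo")]
        for c in series.columns
        if c.startswith("ch") and c.endswith("_hbo")
    ]
    short_names = [
        c[: -len("_hbo")]
        for c in series.columns
        if c.startswith("sc") and c.endswith("_hbo")
    ]
    oxy = series[[f"{n}_hbo" for n in long_names]].to_numpy()
    deoxy = series[[f"{n}_hbr" for n in long_names]].to_numpy()
    short_oxy = series[[f"{n}_hbo" for n in short_names]].to_numpy()
    short_deoxy = series[[f"{n}_hbr" for n in short_names]].to_numpy()
    beeps = events.loc[events["type"] == "beep", "onset_s"].to_numpy()
    brakes = events.loc[events["type"] == "brake", "onset_s"].to_numpy()
    long_rows = montage.loc[~montage["is_short"].astype(bool)]
    partner_idx = {name: k for k, name in enumerate(short_names)}
    pairing = np.array(
        [partner_idx[p] for p in long_rows["ssr_partner"]], dtype=int
    )
    return Session(
        time=time,
        fs=fs,
        oxy=oxy,
        deoxy=deoxy,
        short_oxy=short_oxy,
        short_deoxy=short_deoxy,
        beep_times=beeps,
        brake_onsets=brakes,
        montage=montage,
        ssr_pairing=pairing,
    )


def read_truth(stem: str | Path) -> GroundTruth:
    stem = Path(stem)
    with open(stem.with_name(stem.name + "_truth.json")) as fh:
        d = json.load(fh)
    return GroundTruth(
        planted_pairs=tuple(tuple(p) for p in d["planted_pairs"]),
        planted_edge_indices=tuple(d["planted_edge_indices"]),
        target_r=np.asarray(d["target_r"]),
        true_coefficients=np.asarray(d["true_coefficients"]),
        intercept_ms=d["intercept_ms"],
        noise_free_brt_ms=np.asarray(d["noise_free_brt_ms"]),
        brt_ms=np.asarray(d["brt_ms"]),
        outlier_mask=np.asarray(d["outlier_mask"], dtype=bool),
        latent_state=np.asarray(d["latent_state"]),
    )
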