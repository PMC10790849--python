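"""Brake reaction times: beep/brake matching and outlier removal.

The brake reaction time (BRT) is the elapsed time, in milliseconds, from a
beep tone to the first subsequent brake onset.  Responses slower than 3 s
are regarded as unrelated to the beep and discarded; remaining BRTs are
screened with a single-pass 3-standard-deviation rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Maximum credited reaction time (s); slower brakes are unrelated braking.
MAX_REACTION_S = 3.0


@dataclass
class BehavioralRecord:
    """One beep and its (possibly absent) brake response."""

    beep_time: float
    brake_time: float | None = None
    brt_ms: float | None = None
    valid: bool = False
    outlier: bool = False

    @property
    def usable(self) -> bool:
        """True when the trial enters the regression dataset."""
        return self.valid and not self.outlier


def match_brakes(
    beep_times,
    brake_onsets,
    max_reaction_s: float = MAX_REACTION_S,
) -> list[BehavioralRecord]:
    """Pair each beep with the earliest following brake onset.

    A brake qualifies if it occurs at or after the beep and strictly before
    the next beep; each brake onset is consumed by at most one beep.  Pairs
    slower than ``max_reaction_s`` are marked invalid with no BRT credited.

    Raises
    ------
    ValueError
        If either input list is not sorted ascending.
    """
    beeps = np.asarray(beep_times, dtype=float)
    brakes = np.asarray(brake_onsets, dtype=float)
    if np.any(np.diff(beeps) < 0) or np.any(np.diff(brakes) < 0):
        raise ValueError("beep and brake times must be sorted ascending")

    records: list[BehavioralRecord] = []
    j = 0
    for k, beep in enumerate(beeps):
        nxt = beeps[k + 1] if k + 1 < len(beeps) else np.inf
        while j < len(brakes) and brakes[j] < beep:
            j += 1
        rec = BehavioralRecord(beep_time=float(beep))
        if j < len(brakes) and brakes[j] < nxt:
            brake = float(brakes[j])
            j += 1
            delay = brake - beep
            rec.brake_time = brake
            if delay <= max_reaction_s:
                rec.brt_ms = delay * 1000.0
                rec.valid = True
        records.append(rec)
    return records


def remove_outliers(brts_ms, k: float = 3.0) -> np.ndarray:
    """Flag BRTs farther than ``k`` sample standard deviations from the mean.

    Single (non-iterative) pass; sample (n-1) SD; strict inequality, so a
    value at exactly mean + k*SD is not flagged.  With zero spread nothing
    is flagged.

    Returns
    -------
    (n,) boolean array, True where the trial is an outlier.
    """
    x = np.asarray(brts_ms, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need at least 2 valid BRTs for outlier screening")
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros(x.size, dtype=bool)
    return np.abs(x - x.mean()) > k * sd


def flag_outliers(records: list[BehavioralRecord], k: float = 3.0) -> None:
    """Apply :func:`remove_outliers` in place over the valid records."""
    valid_idx = [i for i, r in enumerate(records) if r.valid]
    if len(valid_idx) < 2:
        warnings.warn("fewer than 2 valid BRTs; outlier screening skipped")
        return
    flags = remove_outliers([records[i].brt_ms for i in valid_idx], k=k)
    for i, f in zip(valid_idx, flags):
        records[i].outlier = bool(f)


def behavioral_table(records: list[BehavioralRecord]) -> pd.DataFrame:
    """Per-trial behavioral table (beep_s, brake_s, brt_ms, valid, outlier)."""
    return pd.DataFrame(
        {
            "beep_s": [r.beep_time for r in records],
            "brake_s": [r.brake_time for r in records],
            "brt_ms": [r.brt_ms for r in records],
            "valid": [r.valid for r in records],
            "outlier": [r.outlier for r in records],
        }
    )


def analyze_events(beep_times, brake_onsets, k: float = 3.0) -> pd.DataFrame:
    """Match brakes to beeps, flag outliers, and return the trial table."""
    records = match_brakes(beep_times, brake_onsets)
    flag_outliers(records, k=k)
    return behavioral_table(records)
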