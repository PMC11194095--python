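"""FRAP mobile-fraction and DAPI-normalised relative-intensity statistics.

The FRAP protocol modelled here images chromatin-incorporated eGFP-H2B:
a few pre-bleach frames establish the baseline, the spot is bleached, and a
short recovery series follows at fixed intervals. The mobile fraction

    MF = (F_inf - F_0) / (F_pre - F_0)

(with ``F_pre`` the mean pre-bleach intensity, ``F_0`` the first post-bleach
frame and ``F_inf`` the plateau estimated from the last few recovery frames)
indexes how open/exchange-prone the chromatin is: ~1 for freely exchanging
histones, ~0 for fully immobilised ones. No exponential fit is performed.

Immunofluorescence intensities are normalised per embryo against the DAPI
(DNA) signal and reported relative to the control-group mean, which is 1 by
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RecoveryCurve",
    "mobile_fraction",
    "relative_intensity",
    "read_recovery_curve",
    "write_recovery_curve",
]


@dataclass
class RecoveryCurve:
    """A FRAP time series: pre-bleach frames, then a recovery series.

    ``bleach_index`` is the index of the first post-bleach sample; the first
    ``n_pre`` samples are pre-bleach frames.
    """

    time_s: np.ndarray
    intensity: np.ndarray
    bleach_index: int
    n_pre: int = 3

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time_s.shape != self.intensity.shape:
            raise ValueError("time and intensity must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time points must be strictly increasing")
        if self.bleach_index <= self.n_pre - 1:
            raise ValueError("bleach_index must come after the pre-bleach frames")
        if len(self.intensity) - self.bleach_index < 3:
            raise ValueError("need at least 3 post-bleach samples")


def mobile_fraction(curve: RecoveryCurve, plateau_n: int = 3) -> float:
    """Mobile fraction ``(F_inf - F_0) / (F_pre - F_0)`` of a recovery curve.

    ``F_inf`` is the mean of the last ``plateau_n`` recovery frames. The
    result is clipped to the report range [0, 1.5]; values outside it raise a
    warning before clipping. A curve where the first post-bleach frame is not
    below the pre-bleach baseline has no bleach to recover from and is an
    error.
    """
    f_pre = float(curve.intensity[: curve.n_pre].mean())
    f_0 = float(curve.intensity[curve.bleach_index])
    post = curve.intensity[curve.bleach_index :]
    if plateau_n < 1 or plateau_n > len(post):
        raise ValueError("plateau_n out of range for this curve")
    f_inf = float(post[-plateau_n:].mean())
    if f_pre <= f_0:
        raise ValueError(f"no bleach detected: F_pre={f_pre:.4g} <= F_0={f_0:.4g}")
    mf = (f_inf - f_0) / (f_pre - f_0)
    if not (0.0 <= mf <= 1.5):
        if mf < -1e-9 or mf > 1.5 + 1e-9:  # numerical dust is clipped silently
            warnings.warn(f"mobile fraction {mf:.3g} outside [0, 1.5]; clipped", stacklevel=2)
        mf = float(np.clip(mf, 0.0, 1.5))
    return mf


def relative_intensity(
    table: pd.DataFrame, control_group: str = "control"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DAPI-corrected intensities, normalised so the control mean is 1.

    ``table`` needs columns ``group``, ``signal`` and ``dapi`` (one row per
    embryo). Returns ``(per_embryo, group_stats)``: per-embryo signal/DAPI
    ratios and relative values, and mean/SD/n per group.
    """
    for col in ("group", "signal", "dapi"):
        if col not in table.columns:
            raise ValueError(f"intensity table missing column {col!r}")
    bad = table.index[(table["dapi"] <= 0) | (table["signal"] <= 0)]
    if len(bad):
        raise ValueError(f"non-positive intensity in row(s) {list(bad)}")
    out = table.copy()
    out["ratio"] = out["signal"] / out["dapi"]
    ctrl = out.loc[out["group"] == control_group, "ratio"]
    if len(ctrl) == 0:
        raise ValueError(f"control group {control_group!r} is empty")
    out["relative"] = out["ratio"] / ctrl.mean()
    stats = (
        out.groupby("group")["relative"]
        .agg(n="size", mean="mean", sd="std")
        .reset_index()
        .set_index("group")
    )
    return out, stats


# ---------------------------------------------------------------------------
# IO: TSV with a metadata header line "# bleach_index=<i> n_pre=<n>"
# ---------------------------------------------------------------------------


def read_recovery_curve(path: str | Path) -> RecoveryCurve:
    bleach_index = None
    n_pre = 3
    times, values = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("bleach_index="):
                        bleach_index = int(tok.split("=", 1)[1])
                    elif tok.startswith("n_pre="):
                        n_pre = int(tok.split("=", 1)[1])
                continue
            if line.startswith("time_s"):
                continue
            t, v = line.split("\t")
            times.append(float(t))
            values.append(float(v))
    if bleach_index is None:
        raise ValueError(f"{path}: missing '# bleach_index=' header")
    return RecoveryCurve(np.array(times), np.array(values), bleach_index, n_pre=n_pre)


def write_recovery_curve(curve: RecoveryCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# bleach_index={curve.bleach_index} n_pre={curve.n_pre}\n")
        fh.write("time_s\tintensity\n")
        for t, v in zip(curve.time_s, curve.intensity):
            fh.write(f"{t:.6g}\t{v:.8g}\n")
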