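"""Trial tables: one row per discrimination-estimation response pair.

Angles are degrees relative to the discrimination boundary, positive =
clockwise.  A trial is *consistent* when the reported estimate falls on
the side of the boundary named by the reported category (estimates of
exactly 0 lie in neither open half-line and count as inconsistent).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .observer_core import Category

__all__ = ["TrialTable", "read_trials", "write_trials", "REQUIRED_COLUMNS", "GROUND_TRUTH_COLUMNS"]

REQUIRED_COLUMNS = ["experiment", "noise_level", "theta_deg", "report_category", "estimate_deg"]
GROUND_TRUTH_COLUMNS = ["m_deg", "mm_deg", "internal_category", "lapse", "boundary_shift_deg"]

_HEADER_COMMENT = (
    "# One row per trial of a discrimination-estimation sequence.\n"
    "# Angles in degrees relative to the discrimination boundary; positive = cw.\n"
    "# report_category: 'cw' or 'ccw'. Ground-truth columns (m_deg, mm_deg,\n"
    "# internal_category, lapse, boundary_shift_deg) are present only for\n"
    "# simulated tables.\n"
)


@dataclasses.dataclass
class TrialTable:
    """Validated wrapper around a per-trial DataFrame."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"trial table is missing columns: {missing}")
        bad = ~self.df["report_category"].isin(["cw", "ccw"])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"row {row}: report_category must be 'cw' or 'ccw'")
        for col in ("theta_deg", "estimate_deg"):
            vals = pd.to_numeric(self.df[col], errors="coerce")
            if vals.isna().any():
                row = int(np.flatnonzero(vals.isna().to_numpy())[0])
                raise ValueError(f"row {row}: column {col!r} is not numeric")
            self.df[col] = vals.astype(float)
        self.df["noise_level"] = self.df["noise_level"].astype(int)
        self.df["experiment"] = self.df["experiment"].astype(str)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def has_ground_truth(self) -> bool:
        return all(c in self.df.columns for c in ("m_deg", "mm_deg"))

    @property
    def report_sign(self) -> np.ndarray:
        return np.where(self.df["report_category"].to_numpy() == "cw", 1, -1)

    @property
    def consistent_mask(self) -> np.ndarray:
        est = self.df["estimate_deg"].to_numpy()
        return np.sign(est) == self.report_sign

    def categories(self) -> list[Category]:
        return [Category.parse(c) for c in self.df["report_category"]]

    def subset(self, mask: np.ndarray) -> "TrialTable":
        return TrialTable(self.df.loc[mask].reset_index(drop=True).copy())


def write_trials(table: TrialTable, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_HEADER_COMMENT)
        table.df.to_csv(fh, index=False)


def read_trials(path) -> TrialTable:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # noqa: BLE001 - surface parse context
        raise ValueError(f"could not parse trial table {path}: {exc}") from exc
    return TrialTable(df)
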