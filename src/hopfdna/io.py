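"""Structured output: profile CSVs and JSON reports.

CSV is RFC-4180 with a header row, '.' decimal separator and values at
12 significant digits; JSON is used for every non-gridded report.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .hopfion import EnergyProfile

__all__ = ["write_profile_csv", "read_profile_csv", "write_json", "PROFILE_HEADER"]

PROFILE_HEADER = ("P", "F_kBT_per_unit_length")
_SIGFIG = 12


def _fmt(x: float) -> str:
    return f"{x:.{_SIGFIG}g}"


def write_profile_csv(profile: EnergyProfile, path) -> Path:
    """Write an F(P) profile as CSV: one header row plus one row per grid point."""
    if len(profile) == 0:
        raise ValueError("refusing to write an empty profile")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\r\n")
        writer.writerow(PROFILE_HEADER)
        for p, f in zip(profile.p_grid, profile.f_values):
            writer.writerow([_fmt(p), _fmt(f)])
    return path


def read_profile_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read back a profile CSV; returns (p_grid, f_values)."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if tuple(header) != PROFILE_HEADER:
            raise ValueError(f"unexpected CSV header: {header}")
        rows = [(float(a), float(b)) for a, b in reader]
    if not rows:
        raise ValueError("profile CSV has no data rows")
    p, f = (np.array(col) for col in zip(*rows))
    return p, f


def write_json(obj: dict, path=None) -> str:
    """Serialize a report deterministically; write to ``path`` if given."""
    text = json.dumps(obj, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
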