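"""Closed-form assay computations.

* BH3 profiling: mitochondrial cytochrome c release from flow-cytometry
  retention values, with alamethicin (ALA) as the full-release control and
  DMSO as the no-release control.
* Coculture growth series normalized to the start-time signal per well.
* Caliper tumor volume, (length x width^2) / 2, and the relapse rule of two
  consecutive volume increases.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["cytochrome_c_release", "normalize_growth", "tumor_volume",
           "is_relapse"]


def cytochrome_c_release(pep: float, ala: float, dmso: float,
                         clamp: bool = False) -> float:
    """Percent cytochrome c release for one BH3-peptide measurement.

    release = 100 - 100 * (pep - ala) / (dmso - ala); pep == dmso gives 0%
    (no release beyond background), pep == ala gives 100% (full release).
    Invariant under rescaling of all three retentions.  Set ``clamp`` to
    confine the report to [0, 100]; the raw value is primary.
    """
    if dmso == ala:
        raise ValueError("DMSO and ALA retentions are equal: no dynamic "
                         "range to normalize against")
    release = 100.0 - 100.0 * (pep - ala) / (dmso - ala)
    if clamp:
        release = min(max(release, 0.0), 100.0)
    return release


def normalize_growth(series: pd.DataFrame,
                     well_col: str = "well",
                     time_col: str = "time",
                     value_col: str = "value") -> pd.DataFrame:
    """Divide each well's growth series by its first time point.

    Wells with a non-positive start signal are flagged and excluded.  The
    result carries a ``normalized`` column; the first point of every
    retained well equals 1.
    """
    out = []
    for well, sub in series.groupby(well_col):
        sub = sub.sort_values(time_col).copy()
        start = sub[value_col].iloc[0]
        if start <= 0:
            warnings.warn(f"well {well!r} has non-positive start signal; "
                          "excluded")
            continue
        sub["normalized"] = sub[value_col] / start
        out.append(sub)
    if not out:
        return series.iloc[0:0].assign(normalized=np.nan)
    return pd.concat(out, ignore_index=True)


def tumor_volume(length: float, width: float) -> float:
    """Caliper tumor volume in mm^3: (length x width^2) / 2.

    By convention length >= width; swapped inputs are auto-reordered with a
    warning.
    """
    if length <= 0 or width <= 0:
        raise ValueError("tumor dimensions must be positive")
    if width > length:
        warnings.warn("width exceeds length; dimensions reordered")
        length, width = width, length
    return length * width * width / 2.0


def is_relapse(volumes) -> bool:
    """True when a volume series shows two consecutive increases."""
    v = np.asarray(volumes, dtype=float)
    if len(v) < 3:
        return False
    inc = np.diff(v) > 0
    return bool(np.any(inc[1:] & inc[:-1]))
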