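"""Temperature-cycled QCM analysis of collagen reversibility.

A quartz crystal microbalance (QCM) tracks the frequency shift dnu of a
sensor crystal carrying an adsorbed collagen layer while the temperature is
cycled.  If the collagen triple helices survive the excursions, revisiting a
temperature reproduces the same frequency shift; if they denature, the
adlayer changes irreversibly and revisits scatter.  This module formalizes
that criterion:

    a series is *reversible* iff, at every temperature visited at least
    twice, the spread (max - min) of dnu across the revisits is at most
    ``dnu_tol``.

Samples are grouped by temperature within ``temp_match_tol``; isolated
temperatures (visited once) carry no reversibility information and are
ignored.  By default the first visit of each temperature group is dropped
as a baseline-settling point — the initial low-temperature reading precedes
any thermal cycling.  Default tolerances: 100 Hz for dnu (the smallest
round value separating reversible from denatured revisit spreads in the
reference jellyfish-collagen series, 0 Hz vs 450 Hz) and 1 degC for
temperature matching.

The packaged fixture ``table1_qcm.csv`` transcribes the two reference
temperature-cycle series on *Rhopilema esculentum* exumbrella collagen: the
upper series (45 degC excursions, denaturing) and the lower series (37 degC
excursions, fully reversible).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .exceptions import ClassificationError, DomainError

__all__ = [
    "QCMSeries",
    "CycleAssessment",
    "classify_reversibility",
    "load_qcm_table",
    "write_qcm_table",
    "packaged_table_path",
    "DEFAULT_DNU_TOL",
    "DEFAULT_TEMP_TOL",
]

DEFAULT_DNU_TOL = 100.0  # Hz
DEFAULT_TEMP_TOL = 1.0  # degC


@dataclass(frozen=True)
class QCMSeries:
    """One temperature-cycle series of (t [s], T [degC], dnu [Hz]) samples."""

    label: str
    t: np.ndarray
    T: np.ndarray
    dnu: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        T = np.asarray(self.T, dtype=float)
        dnu = np.asarray(self.dnu, dtype=float)
        if not (len(t) == len(T) == len(dnu)):
            raise ValueError("t, T and dnu must have equal length")
        if np.any(np.diff(t) <= 0):
            raise DomainError(f"series {self.label!r}: sample times must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "dnu", dnu)

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class CycleAssessment:
    """Per-temperature revisit spreads and the resulting verdict.

    ``spreads`` maps the representative temperature of each qualifying group
    (>= 2 revisits after optional baseline removal) to the max-min spread of
    dnu across those revisits.  ``verdict`` is "reversible" iff every spread
    is at most ``dnu_tol``.
    """

    label: str
    spreads: dict
    verdict: str
    dnu_tol: float
    temp_match_tol: float
    skipped_initial: bool

    @property
    def reversible(self) -> bool:
        return self.verdict == "reversible"


def _group_by_temperature(T: np.ndarray, tol: float) -> list[np.ndarray]:
    """Cluster sample indices whose temperatures lie within ``tol`` of each
    other (single-linkage along the sorted temperature axis)."""
    order = np.argsort(T, kind="stable")
    groups: list[list[int]] = []
    for idx in order:
        if groups and T[idx] - T[groups[-1][-1]] <= tol:
            groups[-1].append(int(idx))
        else:
            groups.append([int(idx)])
    return [np.array(sorted(g)) for g in groups]


def classify_reversibility(
    series: QCMSeries,
    temp_match_tol: float = DEFAULT_TEMP_TOL,
    dnu_tol: float = DEFAULT_DNU_TOL,
    skip_initial: bool = True,
) -> CycleAssessment:
    """Classify a temperature-cycle series as reversible or irreversible.

    Parameters
    ----------
    series : QCMSeries
        Time-ordered (t, T, dnu) samples.
    temp_match_tol : float
        Two samples count as revisits of the same temperature when their
        temperatures differ by at most this much [degC].
    dnu_tol : float
        Maximum admissible revisit spread of dnu [Hz] for a reversible
        verdict.
    skip_initial : bool
        Drop the chronologically first visit of each temperature group
        (baseline settling) before measuring spreads.

    Raises
    ------
    ClassificationError
        If no temperature has two or more (post-baseline) revisits.
    """
    if temp_match_tol < 0 or dnu_tol < 0:
        raise DomainError("tolerances must be non-negative")
    spreads: dict[float, float] = {}
    for idx in _group_by_temperature(series.T, temp_match_tol):
        # idx is already time-ordered (indices sorted; t strictly increasing)
        use = idx[1:] if skip_initial else idx
        if len(use) < 2:
            continue  # singleton temperatures carry no revisit information
        vals = series.dnu[use]
        spreads[float(np.mean(series.T[idx]))] = float(vals.max() - vals.min())
    if not spreads:
        raise ClassificationError(
            f"series {series.label!r}: no temperature is revisited at least twice; "
            "reversibility is undefined"
        )
    verdict = "reversible" if all(s <= dnu_tol for s in spreads.values()) else "irreversible"
    return CycleAssessment(
        label=series.label,
        spreads=spreads,
        verdict=verdict,
        dnu_tol=dnu_tol,
        temp_match_tol=temp_match_tol,
        skipped_initial=skip_initial,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_COLUMNS = ["series", "t", "T", "dnu"]


def load_qcm_table(path: Union[str, Path]) -> list[QCMSeries]:
    """Read a delimited QCM table (columns series,t,T,dnu) into series.

    Series appear in order of first occurrence.  A malformed row raises a
    parse error naming the line number.
    """
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("t", "T", "dnu"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header line + 1-based
            raise ValueError(f"{path}: malformed value in column {col!r} at line {line}")
        if coerced.isna().any():
            line = int(coerced.isna().idxmax()) + 2
            raise ValueError(f"{path}: missing value in column {col!r} at line {line}")
        df[col] = coerced
    out = []
    for label in df["series"].drop_duplicates():
        sub = df[df["series"] == label]
        out.append(
            QCMSeries(
                label=str(label),
                t=sub["t"].to_numpy(float),
                T=sub["T"].to_numpy(float),
                dnu=sub["dnu"].to_numpy(float),
            )
        )
    return out


def write_qcm_table(series: Iterable[QCMSeries], path: Union[str, Path]) -> None:
    """Write series to a delimited table readable by :func:`load_qcm_table`."""
    frames = [
        pd.DataFrame({"series": s.label, "t": s.t, "T": s.T, "dnu": s.dnu}) for s in series
    ]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=_COLUMNS)
    df.to_csv(path, index=False)


def packaged_table_path() -> Path:
    """Path of the packaged reference temperature-cycle table."""
    return Path(importlib.resources.files("nemadischarge") / "data" / "table1_qcm.csv")
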