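"""Peak lists and ppm-tolerance screening of predicted species.

This is the in-silico analogue of the extracted-ion-chromatogram workflow
used to detect lanthipeptide products in culture extracts: predict the
[M + zH]z+ m/z of each candidate species, then ask whether an observed
peak falls within a ppm tolerance of it.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .formula import ion_mz
from .structure import SpeciesVariant

__all__ = ["PeakList", "MatchReport", "read_peaklist", "screen_species"]

#: Default match tolerance (ppm). Wide enough to cover routine
#: high-resolution instrument error (a few ppm) with margin.
DEFAULT_TOL_PPM = 10.0


class PeakList:
    """Observed (m/z, intensity[, rt]) records, canonically sorted by m/z.

    Intensity defaults to 1.0; retention time (minutes) is carried through
    but never used for matching.
    """

    def __init__(
        self,
        mz: Iterable[float],
        intensity: Iterable[float] | None = None,
        rt: Iterable[float] | None = None,
    ):
        mz = np.asarray(list(mz), dtype=float)
        if mz.ndim != 1:
            raise ValueError("mz must be one-dimensional")
        if np.any(~np.isfinite(mz)) or np.any(mz <= 0):
            raise ValueError("all m/z values must be finite and positive")
        n = mz.size
        intensity = (
            np.ones(n) if intensity is None else np.asarray(list(intensity), dtype=float)
        )
        if intensity.shape != mz.shape or np.any(intensity < 0):
            raise ValueError("intensity must be non-negative and match mz in length")
        frame = pd.DataFrame({"mz": mz, "intensity": intensity})
        if rt is not None:
            rt = np.asarray(list(rt), dtype=float)
            if rt.shape != mz.shape:
                raise ValueError("rt must match mz in length")
            frame["rt"] = rt
        self.frame = frame.sort_values(
            ["mz", "intensity"], kind="mergesort"
        ).reset_index(drop=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PeakList":
        if "mz" not in frame.columns:
            raise ValueError("peak table must have an 'mz' column")
        return cls(
            frame["mz"],
            frame["intensity"] if "intensity" in frame.columns else None,
            frame["rt"] if "rt" in frame.columns else None,
        )

    @property
    def mz(self) -> np.ndarray:
        return self.frame["mz"].to_numpy()

    @property
    def intensity(self) -> np.ndarray:
        return self.frame["intensity"].to_numpy()

    @property
    def rt(self) -> np.ndarray | None:
        return self.frame["rt"].to_numpy() if "rt" in self.frame.columns else None

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:
        return f"PeakList({len(self)} peaks)"

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def read_peaklist(path: str | Path) -> PeakList:
    """Read a peak list from CSV (columns: mz, intensity optional, rt optional).

    Raises on a missing ``mz`` column, non-numeric values, or an empty file.
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty peak list file: {path}") from None
    if "mz" not in frame.columns:
        raise ValueError(f"peak list {path} has no 'mz' column")
    if frame.empty:
        raise ValueError(f"empty peak list file: {path}")
    for col in ("mz", "intensity", "rt"):
        if col in frame.columns:
            values = pd.to_numeric(frame[col], errors="coerce")
            if values.isna().any() and not frame[col].isna().any():
                raise ValueError(f"non-numeric values in column {col!r} of {path}")
            frame[col] = values
    return PeakList.from_frame(frame)


class MatchReport:
    """Per-(species, charge) annotation of a peak list.

    One row per queried ion, detected or not; ``detected`` is true iff the
    nearest peak lies within the ppm tolerance. ``calc_mz`` is reported at
    4 dp and ``eic_mz`` at 2 dp (the precision used for extracted-ion
    chromatogram windows).
    """

    def __init__(self, frame: pd.DataFrame, tol_ppm: float):
        self.frame = frame
        self.tol_ppm = tol_ppm

    @property
    def detected(self) -> pd.DataFrame:
        return self.frame[self.frame["detected"]]

    def __repr__(self) -> str:
        n = int(self.frame["detected"].sum())
        return f"MatchReport({n}/{len(self.frame)} detected at {self.tol_ppm} ppm)"

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def _nearest_peak(peaks: PeakList, calc_mz: float) -> tuple[float, float, float]:
    """(observed m/z, intensity, signed ppm) of the nearest peak.

    Tie-break for equidistant peaks: higher intensity, then lower m/z —
    so reports are deterministic.
    """
    mz = peaks.mz
    intensity = peaks.intensity
    ppm = (mz - calc_mz) / calc_mz * 1e6
    order = np.lexsort((mz, -intensity, np.abs(ppm)))
    best = order[0]
    return float(mz[best]), float(intensity[best]), float(ppm[best])


def screen_species(
    peaks: PeakList,
    variants: Sequence[SpeciesVariant],
    charges: Iterable[int] = (2,),
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> MatchReport:
    """Screen a peak list for every (variant, charge) combination.

    Deterministic given its inputs and invariant to the order of both the
    peak list and the variant list. Tightening ``tol_ppm`` can only shrink
    the detected set.
    """
    variants = list(variants)
    charges = sorted(set(int(z) for z in charges))
    if not variants:
        raise ValueError("empty species variant list")
    if not charges or charges[0] < 1:
        raise ValueError("charges must be positive integers")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")

    rows = []
    for variant in variants:
        formula = variant.formula
        for z in charges:
            calc = ion_mz(formula, z)
            if len(peaks):
                obs, inten, err = _nearest_peak(peaks, calc)
                detected = abs(err) <= tol_ppm
            else:
                obs = inten = err = np.nan
                detected = False
            rows.append(
                {
                    "species": variant.label,
                    "formula": formula.hill(),
                    "charge": z,
                    "calc_mz": round(calc, 4),
                    "eic_mz": round(calc, 2),
                    "observed_mz": obs,
                    "intensity": inten,
                    "ppm": round(err, 2) if np.isfinite(err) else np.nan,
                    "detected": detected,
                }
            )
    return MatchReport(pd.DataFrame(rows), tol_ppm)
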