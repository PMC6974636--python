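"""Synthetic UPLC-MS peak lists and randomised structures for testing.

The generator emulates the statistical structure the screening workflow
assumes: each planted species contributes a peak at its predicted m/z
perturbed by Gaussian relative (ppm) error, overlaid with uniform-random
decoy peaks; intensities are log-normal. The default 2 ppm error scale
matches routine high-resolution instrument accuracy (observed errors on a
calibrated instrument stay within a few ppm). Decoys are kept out of the
±3σ windows around true peaks so recovery statistics are unambiguous.

It does not emulate chromatographic peak shape, isotope envelopes or
charge-state envelopes — matching here is single-peak, monoisotopic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import PeakList
from .formula import ion_mz
from .structure import (
    RESIDUE_FORMULAS,
    LanthipeptideStructure,
    SpeciesVariant,
)

__all__ = ["SimulationConfig", "simulate_peaklist", "simulate_variant_structures"]


@dataclass
class SimulationConfig:
    """Parameters of a synthetic peak-list draw.

    ``species`` is a list of (variant, charge) pairs. ``ppm_sigma`` is the
    Gaussian m/z error scale in ppm; ``dropout`` the per-species
    probability that a true peak is omitted; ``n_decoys`` uniform decoys
    are drawn over ``mz_range`` outside ±3σ of every true peak. Intensity
    is log-normal with log-space mean ``log_intensity_mu`` and sd
    ``log_intensity_sigma``. The single ``seed`` governs all randomness.
    """

    seed: int
    species: Sequence[tuple[SpeciesVariant, int]]
    ppm_sigma: float = 2.0
    n_decoys: int = 50
    mz_range: tuple[float, float] = (200.0, 2000.0)
    log_intensity_mu: float = np.log(1e4)
    log_intensity_sigma: float = 1.0
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if self.ppm_sigma < 0:
            raise ValueError("ppm_sigma must be non-negative")
        if not 0 <= self.dropout <= 1:
            raise ValueError("dropout must be in [0, 1]")
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be non-negative")
        if not self.mz_range[0] < self.mz_range[1]:
            raise ValueError("mz_range must be (low, high) with low < high")
        if not self.species and self.n_decoys == 0:
            raise ValueError("nothing to simulate: no species and no decoys")


def simulate_peaklist(cfg: SimulationConfig) -> tuple[PeakList, pd.DataFrame]:
    """Draw a synthetic peak list and its ground-truth table.

    Returns ``(peaks, truth)`` where ``truth`` has one row per emitted
    peak: m/z, intensity, species label (empty for decoys), charge,
    predicted m/z, applied ppm error, and an ``is_decoy`` flag. With
    ``ppm_sigma=0`` and ``n_decoys=0`` the peak list is exactly the
    predicted m/z values of the planted species.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    true_mz: list[float] = []
    for variant, charge in cfg.species:
        predicted = ion_mz(variant.formula, charge)
        true_mz.append(predicted)
        if rng.random() < cfg.dropout:
            continue
        eps = rng.normal(0.0, cfg.ppm_sigma) if cfg.ppm_sigma > 0 else 0.0
        rows.append(
            {
                "mz": predicted * (1 + eps / 1e6),
                "intensity": float(
                    rng.lognormal(cfg.log_intensity_mu, cfg.log_intensity_sigma)
                ),
                "species": variant.label,
                "charge": charge,
                "predicted_mz": predicted,
                "ppm_applied": eps,
                "is_decoy": False,
            }
        )

    lo, hi = cfg.mz_range
    exclusion = [
        (m * (1 - 3 * cfg.ppm_sigma / 1e6), m * (1 + 3 * cfg.ppm_sigma / 1e6))
        for m in true_mz
    ]
    n_drawn = 0
    while n_drawn < cfg.n_decoys:
        candidate = float(rng.uniform(lo, hi))
        if any(a <= candidate <= b for a, b in exclusion):
            continue
        rows.append(
            {
                "mz": candidate,
                "intensity": float(
                    rng.lognormal(cfg.log_intensity_mu, cfg.log_intensity_sigma)
                ),
                "species": "",
                "charge": 0,
                "predicted_mz": np.nan,
                "ppm_applied": np.nan,
                "is_decoy": True,
            }
        )
        n_drawn += 1

    truth = pd.DataFrame(
        rows,
        columns=[
            "mz",
            "intensity",
            "species",
            "charge",
            "predicted_mz",
            "ppm_applied",
            "is_decoy",
        ],
    ).sort_values("mz", kind="mergesort").reset_index(drop=True)
    peaks = (
        PeakList(truth["mz"], truth["intensity"])
        if len(truth)
        else PeakList([], [])
    )
    return peaks, truth


# -- randomised structures (property-test fuel) --------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_structure(rng: np.random.Generator, index: int) -> LanthipeptideStructure:
    length = int(rng.integers(10, 25))
    seq = [str(_AA[i]) for i in rng.integers(0, len(_AA), size=length)]
    positions = list(rng.permutation(length) + 1)  # 1-based, shuffled

    def take() -> int:
        return int(positions.pop())

    n_bridges = int(rng.integers(0, min(3, length // 4) + 1))
    dehydrations: set[int] = set()
    bridges: list[tuple[int, int]] = []
    for _ in range(n_bridges):
        cys, partner = take(), take()
        seq[cys - 1] = "C"
        seq[partner - 1] = "S" if rng.random() < 0.5 else "T"
        dehydrations.add(partner)
        bridges.append((cys, partner))

    lysinoalanine = None
    if length >= n_bridges * 2 + 3 and rng.random() < 0.7:
        a, b = sorted((take(), take()))
        seq[a - 1] = "S"
        seq[b - 1] = "K"
        dehydrations.add(a)
        lysinoalanine = (a, b)

    hydroxylations = {
        p for p in positions if seq[p - 1] == "D" and rng.random() < 0.5
    }
    return LanthipeptideStructure(
        name=f"synthetic-{index}",
        core_sequence="".join(seq),
        dehydrations=dehydrations,
        thioether_bridges=bridges,
        lysinoalanine=lysinoalanine,
        hydroxylations=hydroxylations,
    )


def simulate_variant_structures(
    base: LanthipeptideStructure | None,
    n: int,
    seed: int,
) -> list[LanthipeptideStructure]:
    """Generate ``n`` random valid structures for property tests.

    ``base`` seeds nothing but the naming (it may be None); topologies are
    resampled from scratch under the structural invariants (bridges pair a
    Cys with a dehydrated Ser/Thr, lysinoalanine pairs a dehydrated Ser
    with a C-terminal-side Lys). Identical ``seed`` reproduces the list.
    """
    rng = np.random.default_rng(seed)
    prefix = base.name if base is not None else "synthetic"
    out = []
    for i in range(n):
        s = _random_structure(rng, i)
        out.append(s.rename(f"{prefix}-{i}") if base is not None else s)
    return out
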