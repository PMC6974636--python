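"""y-ion ladder of the chemically reduced peptide, with the lysinoalanine
rearrangement rule used to read MALDI-TOF LIFT spectra.

Thioether bridges suppress backbone fragmentation, so tandem MS of these
molecules is done after nickel-boride (NaBH4/NiCl2) desulfurization, which
cleaves each bridge with a −S +2H shift. At the whole-molecule level that
shift is apportioned to the two bridge members as

* Cys member  → Ala residue (thiol lost),
* Dhb member  → Abu (α-aminobutyrate) residue,
* Dha member  → Ala residue,

which matches the hydride-reduction chemistry and sums exactly to −S +2H
per bridge. The lysinoalanine cross-link survives the reduction; when a
backbone cleavage severs it, the fragment is observed as if the Dha side
had become a glycine residue and the Lys ε-amine a terminal N=CH2 — an
atom-conserving split of the intact cross-linked pair. y ions are reported
singly protonated (MALDI convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formula import WATER, ElementalFormula, ion_mz, ppm_error
from .structure import RESIDUE_FORMULAS, LanthipeptideStructure

__all__ = [
    "FragmentIon",
    "rearranged_residues",
    "reduced_residue_formulas",
    "y_ion_ladder",
    "match_ladder",
]

_SULFUR = ElementalFormula(S=1)
_2H = ElementalFormula(H=2)
_CARBON = ElementalFormula(C=1)

#: Residue formula observed on the Dha side of a severed lysinoalanine
#: bridge: a glycine residue.
GLYCINE_RESIDUE = RESIDUE_FORMULAS["G"]

#: Residue formula observed on the Lys side of a severed lysinoalanine
#: bridge: lysine with its ε-NH2 turned into N=CH2 (+CH2 −2H, net +C).
REARRANGED_LYSINE_RESIDUE = RESIDUE_FORMULAS["K"] + _CARBON


@dataclass(frozen=True)
class FragmentIon:
    """A single y-series fragment: the C-terminal ``index`` residues + H2O,
    singly protonated."""

    series: str
    index: int
    span: tuple[int, int]  # 1-based inclusive residue positions
    formula: ElementalFormula
    rearranged: bool

    @property
    def mz(self) -> float:
        return ion_mz(self.formula, 1)

    @property
    def mass(self) -> float:
        return self.formula.monoisotopic_mass


def rearranged_residues(
    structure: LanthipeptideStructure,
) -> dict[int, ElementalFormula]:
    """Residue substitutions for a fragment that severs the lysinoalanine.

    Returns ``{dha_position: Gly residue, lys_position: N=CH2-lysine
    residue}``. The two substituted residues together have exactly the atom
    content of the intact cross-linked pair (Dha residue + Lys residue), so
    complementary fragments always sum to the full molecule.
    """
    if structure.lysinoalanine is None:
        raise ValueError(f"{structure.name} has no lysinoalanine bridge")
    a, b = structure.lysinoalanine
    return {a: GLYCINE_RESIDUE, b: REARRANGED_LYSINE_RESIDUE}


def reduced_residue_formulas(
    structure: LanthipeptideStructure,
    k_reduced: int | None = None,
    hydroxylated: bool = True,
) -> list[ElementalFormula]:
    """Per-position residue formulas of the k-fold desulfurized molecule.

    Dehydrated positions are Dha/Dhb (−H2O); the first ``k_reduced``
    bridges (in config order) are in their hydride-reduced forms (Cys→Ala,
    Dhb→Abu, Dha→Ala); hydroxylated positions carry the extra oxygen when
    ``hydroxylated``. The sum over positions plus one water equals
    ``structure.reduced_formula(k_reduced, hydroxylated)`` exactly.
    """
    if k_reduced is None:
        k_reduced = structure.n_bridges
    if not 0 <= k_reduced <= structure.n_bridges:
        raise ValueError(
            f"k_reduced must be in 0..{structure.n_bridges}, got {k_reduced}"
        )
    seq = structure.core_sequence
    residues = [RESIDUE_FORMULAS[c] for c in seq]
    for p in structure.dehydrations:
        residues[p - 1] = residues[p - 1] - WATER
    for p in structure.hydroxylations:
        if hydroxylated:
            residues[p - 1] = residues[p - 1] + ElementalFormula(O=1)
    for cys, dehydrated in list(structure.bridge_members())[:k_reduced]:
        residues[cys - 1] = residues[cys - 1] - _SULFUR  # Cys → Ala
        residues[dehydrated - 1] = residues[dehydrated - 1] + _2H  # Dha/Dhb → Ala/Abu
    return residues


def y_ion_ladder(
    structure: LanthipeptideStructure,
    k_reduced: int | None = None,
    hydroxylated: bool = True,
) -> list[FragmentIon]:
    """The y1..y(L−1) fragment series of the (reduced) peptide.

    Any span that contains the lysinoalanine Lys but not its Dha partner
    gets the rearranged lysine residue; a span containing both partners is
    composition-identical to the intact cross-link either way (the
    substitution pair conserves atoms), so the substitutions are applied
    uniformly. Defaults to the fully desulfurized molecule, which is how
    the spectra are acquired.
    """
    residues = reduced_residue_formulas(structure, k_reduced, hydroxylated)
    subs = (
        rearranged_residues(structure) if structure.lysinoalanine is not None else {}
    )
    length = len(structure)
    # Dha loses H2O before substitution; the Gly substitution replaces the
    # *dehydrated* residue so the pair identity Gly + K+CH2-2H = Dha + Lys holds.
    for pos, repl in subs.items():
        if pos in structure.dehydrations or structure.core_sequence[pos - 1] == "K":
            residues[pos - 1] = repl
    a = structure.lysinoalanine[0] if structure.lysinoalanine else None
    ladder: list[FragmentIon] = []
    for n in range(1, length):
        start = length - n + 1
        formula = WATER
        for f in residues[start - 1 :]:
            formula = formula + f
        severed = a is not None and start > a and structure.lysinoalanine[1] >= start
        ladder.append(
            FragmentIon(
                series="y",
                index=n,
                span=(start, length),
                formula=formula,
                rearranged=severed,
            )
        )
    return ladder


def match_ladder(
    peaks,
    ladder: list[FragmentIon],
    tol_ppm: float = 10.0,
) -> pd.DataFrame:
    """Annotate each fragment with its nearest observed peak within tolerance.

    Parameters
    ----------
    peaks
        A :class:`~lanthimass.annotation.PeakList` (or anything with ``mz``
        and ``intensity`` arrays).
    ladder
        Fragment ions from :func:`y_ion_ladder`.
    tol_ppm
        Match tolerance in ppm (must be positive).

    Returns a frame with one row per fragment: series, n, span, formula,
    calculated m/z, matched m/z (NaN if absent), signed ppm and an
    ``ambiguous`` flag set when one observed peak is the best match of more
    than one fragment.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    mz = np.asarray(peaks.mz, dtype=float)
    if mz.size == 0:
        raise ValueError("empty peak list")
    intensity = np.asarray(peaks.intensity, dtype=float)

    rows = []
    matched_peak_idx: list[int | None] = []
    for ion in ladder:
        calc = ion.mz
        ppm = (mz - calc) / calc * 1e6
        order = np.lexsort((mz, -intensity, np.abs(ppm)))
        best = order[0]
        if abs(ppm[best]) <= tol_ppm:
            matched_peak_idx.append(int(best))
            obs, err = mz[best], ppm[best]
        else:
            matched_peak_idx.append(None)
            obs, err = np.nan, np.nan
        rows.append(
            {
                "series": ion.series,
                "n": ion.index,
                "span": f"{ion.span[0]}-{ion.span[1]}",
                "formula": ion.formula.hill(),
                "calc_mz": round(calc, 4),
                "matched_mz": obs,
                "ppm": round(err, 2) if np.isfinite(err) else np.nan,
                "rearranged": ion.rearranged,
            }
        )
    counts: dict[int, int] = {}
    for idx in matched_peak_idx:
        if idx is not None:
            counts[idx] = counts.get(idx, 0) + 1
    for row, idx in zip(rows, matched_peak_idx):
        row["ambiguous"] = idx is not None and counts[idx] > 1
    return pd.DataFrame(rows)
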