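"""Cross-linked lanthipeptide structure model and species derivation.

A type B (cinnamycin-like) lanthipeptide core is a 19-residue peptide
carrying dehydrations (Ser→Dha, Thr→Dhb, each −H2O), thioether bridges
(Cys thiol addition onto a dehydrated residue — mass-neutral once the
dehydration is counted), an optional lysinoalanine cross-link (Lys ε-amine
addition onto a Dha — also mass-neutral), and optional β-hydroxylation of
an Asp (+O). The elemental formula of the mature molecule is therefore

    linear peptide − n_dehydrations · H2O + n_hydroxylations · O

and nickel-boride desulfurization of k thioether bridges shifts it by
−k·S + 2k·H. Those two identities are the whole mass bookkeeping; the
bridge topology matters only for fragmentation.

Bridge topologies ship as small YAML configuration files (see
:func:`load_structure`); the kyamicin, cinnamycin and duramycin
configurations are packaged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import yaml

from .formula import WATER, ChargedIon, ElementalFormula

__all__ = [
    "RESIDUE_FORMULAS",
    "OXYGEN",
    "LanthipeptideStructure",
    "SpeciesVariant",
    "StructureError",
    "linear_peptide_formula",
    "extract_core",
    "read_precursors",
    "load_structure",
    "packaged_structures",
]

#: Residue (amino acid − H2O) formulas for the 20 canonical amino acids.
#: A linear peptide is the sum of its residues plus one water.
RESIDUE_FORMULAS: dict[str, ElementalFormula] = {
    "G": ElementalFormula(C=2, H=3, N=1, O=1),
    "A": ElementalFormula(C=3, H=5, N=1, O=1),
    "S": ElementalFormula(C=3, H=5, N=1, O=2),
    "P": ElementalFormula(C=5, H=7, N=1, O=1),
    "V": ElementalFormula(C=5, H=9, N=1, O=1),
    "T": ElementalFormula(C=4, H=7, N=1, O=2),
    "C": ElementalFormula(C=3, H=5, N=1, O=1, S=1),
    "L": ElementalFormula(C=6, H=11, N=1, O=1),
    "I": ElementalFormula(C=6, H=11, N=1, O=1),
    "N": ElementalFormula(C=4, H=6, N=2, O=2),
    "D": ElementalFormula(C=4, H=5, N=1, O=3),
    "Q": ElementalFormula(C=5, H=8, N=2, O=2),
    "K": ElementalFormula(C=6, H=12, N=2, O=1),
    "E": ElementalFormula(C=5, H=7, N=1, O=3),
    "M": ElementalFormula(C=5, H=9, N=1, O=1, S=1),
    "H": ElementalFormula(C=6, H=7, N=3, O=1),
    "F": ElementalFormula(C=9, H=9, N=1, O=1),
    "R": ElementalFormula(C=6, H=12, N=4, O=1),
    "Y": ElementalFormula(C=9, H=9, N=1, O=2),
    "W": ElementalFormula(C=11, H=10, N=2, O=1),
}

OXYGEN = ElementalFormula(O=1)
_SULFUR = ElementalFormula(S=1)
_2H = ElementalFormula(H=2)


class StructureError(ValueError):
    """Raised when a structure description violates its invariants."""


def linear_peptide_formula(sequence: str) -> ElementalFormula:
    """Elemental formula of the unmodified linear peptide (Σ residues + H2O).

    Raises :class:`StructureError` for residue codes outside the canonical
    twenty or for an empty sequence.
    """
    if not sequence:
        raise StructureError("empty peptide sequence")
    total = WATER
    for code in sequence:
        try:
            total = total + RESIDUE_FORMULAS[code]
        except KeyError:
            raise StructureError(f"unknown residue code {code!r}") from None
    return total


@dataclass(frozen=True)
class LanthipeptideStructure:
    """Core peptide plus modification and bridge topology, 1-based positions.

    Parameters
    ----------
    name
        Label used in reports (e.g. ``"kyamicin"``).
    core_sequence
        One-letter codes of the core peptide, as ribosomally encoded
        (pre-modification: dehydrated positions carry S/T, the
        hydroxylated position carries D).
    dehydrations
        Positions dehydrated to Dha (from Ser) or Dhb (from Thr).
    thioether_bridges
        Unordered position pairs; each pair contains exactly one Cys and
        one dehydrated partner.
    lysinoalanine
        Optional (Dha position, Lys position) pair.
    hydroxylations
        Positions β-hydroxylated (Asp → β-OH-Asp).
    """

    name: str
    core_sequence: str
    dehydrations: frozenset[int]
    thioether_bridges: tuple[tuple[int, int], ...]
    lysinoalanine: tuple[int, int] | None
    hydroxylations: frozenset[int]

    def __init__(
        self,
        name: str,
        core_sequence: str,
        dehydrations: Iterable[int] = (),
        thioether_bridges: Iterable[Sequence[int]] = (),
        lysinoalanine: Sequence[int] | None = None,
        hydroxylations: Iterable[int] = (),
    ):
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "core_sequence", str(core_sequence))
        object.__setattr__(self, "dehydrations", frozenset(int(p) for p in dehydrations))
        object.__setattr__(
            self,
            "thioether_bridges",
            tuple(tuple(int(p) for p in pair) for pair in thioether_bridges),
        )
        object.__setattr__(
            self,
            "lysinoalanine",
            tuple(int(p) for p in lysinoalanine) if lysinoalanine else None,
        )
        object.__setattr__(self, "hydroxylations", frozenset(int(p) for p in hydroxylations))
        self._validate()

    # -- invariants ----------------------------------------------------------

    def _validate(self) -> None:
        seq = self.core_sequence
        n = len(seq)
        linear_peptide_formula(seq)  # validates residue codes
        all_positions = (
            set(self.dehydrations)
            | {p for pair in self.thioether_bridges for p in pair}
            | set(self.lysinoalanine or ())
            | set(self.hydroxylations)
        )
        for p in all_positions:
            if not 1 <= p <= n:
                raise StructureError(f"position {p} outside 1..{n}")
        for p in self.dehydrations:
            if seq[p - 1] not in "ST":
                raise StructureError(
                    f"dehydration at {p} requires Ser or Thr, found {seq[p - 1]}"
                )
        for p in self.hydroxylations:
            if seq[p - 1] != "D":
                raise StructureError(
                    f"hydroxylation at {p} requires Asp, found {seq[p - 1]}"
                )
        seen: set[int] = set()
        for pair in self.thioether_bridges:
            if len(pair) != 2 or pair[0] == pair[1]:
                raise StructureError(f"bridge {pair} is not a pair of distinct positions")
            cys = [p for p in pair if seq[p - 1] == "C"]
            if len(cys) != 1:
                raise StructureError(
                    f"bridge {pair} must contain exactly one Cys member"
                )
            other = pair[0] if pair[1] == cys[0] else pair[1]
            if other not in self.dehydrations:
                raise StructureError(
                    f"bridge {pair}: non-Cys member {other} must be dehydrated"
                )
            if seen & set(pair):
                raise StructureError(f"position reused across thioether bridges: {pair}")
            seen |= set(pair)
        if self.lysinoalanine is not None:
            a, b = self.lysinoalanine
            if a not in self.dehydrations or seq[a - 1] != "S":
                raise StructureError(
                    f"lysinoalanine position {a} must be a dehydrated Ser"
                )
            if seq[b - 1] != "K":
                raise StructureError(f"lysinoalanine position {b} must be Lys")
            if a in seen or b in seen:
                raise StructureError(
                    "lysinoalanine positions cannot participate in a thioether bridge"
                )

    # -- convenience ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.core_sequence)

    @property
    def n_bridges(self) -> int:
        return len(self.thioether_bridges)

    def bridge_members(self) -> Iterator[tuple[int, int]]:
        """Yield each thioether bridge as an ordered (cys, dehydrated) pair."""
        for pair in self.thioether_bridges:
            if self.core_sequence[pair[0] - 1] == "C":
                yield pair[0], pair[1]
            else:
                yield pair[1], pair[0]

    # -- formulas ------------------------------------------------------------

    def linear_formula(self) -> ElementalFormula:
        """Formula of the unmodified ribosomal core peptide."""
        return linear_peptide_formula(self.core_sequence)

    def mature_formula(self, hydroxylated: bool = True) -> ElementalFormula:
        """Formula of the fully cross-linked molecule.

        Dehydrations each remove one water; cyclisation (thioether and
        lysinoalanine) moves no atoms; hydroxylation adds one oxygen per
        site when ``hydroxylated`` (``False`` gives the "deoxy" species).
        """
        f = self.linear_formula() - WATER * len(self.dehydrations)
        if hydroxylated:
            f = f + OXYGEN * len(self.hydroxylations)
        return f

    def reduced_formula(self, k: int, hydroxylated: bool = True) -> ElementalFormula:
        """Formula after desulfurization of ``k`` thioether bridges (−kS +2kH).

        The lysinoalanine cross-link is not cleaved by the reduction.
        """
        if not 0 <= k <= self.n_bridges:
            raise ValueError(
                f"k must be in 0..{self.n_bridges} (number of thioether bridges), got {k}"
            )
        return self.mature_formula(hydroxylated) - _SULFUR * k + _2H * k

    def variant(
        self, hydroxylated: bool = True, reduced_bridges: int = 0
    ) -> "SpeciesVariant":
        return SpeciesVariant(self, hydroxylated, reduced_bridges)

    def reduction_series(
        self, charge: int = 2, hydroxylated: bool = True
    ) -> list[tuple[int, ChargedIon]]:
        """Ions of the k-fold desulfurized species for k = 0..n_bridges.

        At z = 2 consecutive members are spaced by (m_S − 2·m_H)/2 ≈ 14.9783,
        the signature of successive thioether-bridge reduction.
        """
        return [
            (k, ChargedIon(self.reduced_formula(k, hydroxylated), charge))
            for k in range(self.n_bridges + 1)
        ]

    # -- (de)serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "core_sequence": self.core_sequence,
            "dehydrations": sorted(self.dehydrations),
            "thioether_bridges": [list(p) for p in self.thioether_bridges],
            "hydroxylations": sorted(self.hydroxylations),
        }
        if self.lysinoalanine is not None:
            d["lysinoalanine"] = list(self.lysinoalanine)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LanthipeptideStructure":
        return cls(
            name=d["name"],
            core_sequence=d["core_sequence"],
            dehydrations=d.get("dehydrations", ()),
            thioether_bridges=d.get("thioether_bridges", ()),
            lysinoalanine=d.get("lysinoalanine"),
            hydroxylations=d.get("hydroxylations", ()),
        )

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "LanthipeptideStructure":
        """Load a structure config from a YAML file path or YAML text."""
        p = Path(source)
        try:
            is_file = p.is_file()
        except OSError:  # very long YAML strings are not paths
            is_file = False
        text = p.read_text() if is_file else str(source)
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise StructureError(f"not a structure config: {source!r}")
        return cls.from_dict(data)

    def rename(self, name: str) -> "LanthipeptideStructure":
        return replace(self, name=name)


@dataclass(frozen=True)
class SpeciesVariant:
    """A concrete chemical species derived from a structure.

    ``hydroxylated=False`` is the "deoxy" species (hydroxylase skipped);
    ``reduced_bridges=k`` is the k-fold desulfurized species.
    """

    structure: LanthipeptideStructure
    hydroxylated: bool = True
    reduced_bridges: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.reduced_bridges <= self.structure.n_bridges:
            raise ValueError(
                f"reduced_bridges must be in 0..{self.structure.n_bridges}, "
                f"got {self.reduced_bridges}"
            )

    @property
    def formula(self) -> ElementalFormula:
        return self.structure.reduced_formula(self.reduced_bridges, self.hydroxylated)

    @property
    def label(self) -> str:
        name = self.structure.name
        if not self.hydroxylated:
            name = f"deoxy{name}"
        k = self.reduced_bridges
        if k == self.structure.n_bridges and k > 0:
            name = f"reduced {name}"
        elif k > 0:
            name = f"partially reduced {name} (k={k})"
        return name

    def ion(self, charge: int = 2) -> ChargedIon:
        return ChargedIon(self.formula, charge)


# -- precursor handling --------------------------------------------------------


def extract_core(precursor: str, core_length: int = 19) -> str:
    """C-terminal core peptide of a precursor (leader proteolytically removed).

    Cinnamycin-family cores are the 19 C-terminal residues of their
    precursor peptides, hence a fixed-length C-terminal cut rather than a
    cleavage-motif model.
    """
    precursor = str(precursor)
    if core_length < 1:
        raise ValueError("core_length must be positive")
    if core_length > len(precursor):
        raise ValueError(
            f"core_length {core_length} exceeds precursor length {len(precursor)}"
        )
    return precursor[-core_length:]


def read_precursors(path: str | Path) -> dict[str, str]:
    """Read precursor peptide sequences from a FASTA file, keyed by record id."""
    from Bio import SeqIO

    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


# -- packaged configurations ---------------------------------------------------


def packaged_structures() -> list[str]:
    """Names of the structure configs shipped with the package."""
    root = resources.files("lanthimass.data")
    return sorted(p.name[: -len(".yaml")] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_structure(name_or_path: str | Path) -> LanthipeptideStructure:
    """Load a packaged structure by name, or any structure config by path."""
    candidate = resources.files("lanthimass.data") / f"{name_or_path}.yaml"
    if isinstance(name_or_path, str) and "/" not in name_or_path and candidate.is_file():
        return LanthipeptideStructure.from_yaml(candidate.read_text())
    path = Path(name_or_path)
    if not path.is_file():
        raise FileNotFoundError(
            f"no packaged structure or config file named {name_or_path!r}; "
            f"packaged: {', '.join(packaged_structures())}"
        )
    return LanthipeptideStructure.from_yaml(path)
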