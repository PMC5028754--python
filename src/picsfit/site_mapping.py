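"""Reconstruct cleavage windows by aligning prime-side peptides to a proteome.

MS observes only the prime (C-terminal) side of each scissile bond: the
biotinylated neo-N-terminal peptide.  The non-prime side (P5..P1) is
recovered computationally by locating the peptide in the proteome and
reading off the five preceding residues, following the Schechter-Berger
subsite nomenclature.  When the peptide occurs at several loci with
*distinct* preceding sequences the non-prime side is ambiguous and is
dropped, while the prime side is kept; peptides never found in the
proteome are discarded outright.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .pics_filter import PeptideID
from .synthetic_data import Proteome

GAP = "-"

#: subsite column order used everywhere downstream
SUBSITES = ("P5", "P4", "P3", "P2", "P1", "P1p", "P2p", "P3p", "P4p", "P5p")


@dataclass(frozen=True)
class CleavageWindow:
    """One inferred scissile bond: P5..P1 | P1'..P5'.

    `prime` is always the first five residues of the source peptide (gap-
    padded if shorter); `nonprime` is the five preceding proteome residues
    (gap-padded at protein N-termini) or None when ambiguous.
    `cut_position` is the 1-based index of the P1 residue in the parent
    protein, or None when the bond sits at the protein N-terminus or the
    mapping is ambiguous.
    """

    prime: str
    nonprime: str | None
    source_peptide: str
    protein_id: str = ""
    cut_position: int | None = None

    def __post_init__(self) -> None:
        if len(self.prime) != 5:
            raise ValueError("prime window must hold exactly 5 symbols")
        if self.nonprime is not None and len(self.nonprime) != 5:
            raise ValueError("nonprime window must hold exactly 5 symbols")

    @property
    def ambiguous(self) -> bool:
        return self.nonprime is None

    def window10(self) -> str | None:
        """The concatenated 10-mer P5..P5', or None when nonprime is absent."""
        if self.nonprime is None:
            return None
        return self.nonprime + self.prime


@dataclass
class MappingReport:
    """Bookkeeping for one mapping pass."""

    n_input: int = 0
    n_mapped: int = 0
    n_ambiguous: int = 0
    n_unmapped: int = 0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_mapped": self.n_mapped,
            "n_ambiguous": self.n_ambiguous,
            "n_unmapped": self.n_unmapped,
        }


def _pad_prime(peptide: str) -> str:
    return (peptide[:5] + GAP * 5)[:5]


def _occurrences(peptide: str, proteome: Proteome):
    """All exact occurrences of peptide, sorted by (protein_id, position)
    so the result never depends on proteome entry order."""
    hits = []
    for pid, seq in sorted(proteome.entries):
        start = seq.find(peptide)
        while start != -1:
            hits.append((pid, start))  # 0-based start
            start = seq.find(peptide, start + 1)
    return hits


def map_prime_peptide(peptide: str, proteome: Proteome) -> CleavageWindow | None:
    """Map one prime-side peptide onto the proteome.

    Returns None when the peptide has no exact proteome occurrence.  With a
    single distinct preceding 5-mer the non-prime window is assigned; with
    several distinct ones it is marked ambiguous but the peptide is kept.
    """
    if not peptide:
        raise ValueError("peptide must be non-empty")
    if not proteome.entries:
        raise ValueError("proteome is empty")
    hits = _occurrences(peptide, proteome)
    if not hits:
        return None

    seqs = dict(proteome.entries)
    preceding: dict[str, tuple[str, int]] = {}
    for pid, start in hits:
        prefix = seqs[pid][max(0, start - 5):start]
        window = GAP * (5 - len(prefix)) + prefix
        if window not in preceding:
            preceding[window] = (pid, start)

    prime = _pad_prime(peptide)
    if len(preceding) > 1:
        return CleavageWindow(prime=prime, nonprime=None, source_peptide=peptide)
    nonprime, (pid, start) = next(iter(preceding.items()))
    return CleavageWindow(
        prime=prime,
        nonprime=nonprime,
        source_peptide=peptide,
        protein_id=pid,
        cut_position=start if start > 0 else None,  # 1-based index of P1
    )


def map_all(
    survivors: Iterable[PeptideID], proteome: Proteome
) -> tuple[list[CleavageWindow], MappingReport]:
    """Map every surviving peptide; unmappable ones are dropped and counted."""
    report = MappingReport()
    windows: list[CleavageWindow] = []
    for p in survivors:
        report.n_input += 1
        w = map_prime_peptide(p.sequence, proteome)
        if w is None:
            report.n_unmapped += 1
            continue
        if w.ambiguous:
            report.n_ambiguous += 1
        else:
            report.n_mapped += 1
        windows.append(w)
    return windows, report
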