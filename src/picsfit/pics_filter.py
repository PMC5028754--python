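"""Filter cascade turning raw peptide-identification lists into candidate
cleavage products.

The screen identifies protease cleavage products by their labeled
(biotinylated) neo-N-terminus.  Four identification lists are produced per
experiment: the test enzyme reaction, a catalytically inactive control, a
mock (buffer-only) control, and the unprocessed peptide library.  The
cascade keeps N-terminally biotinylated peptides, applies confidence
thresholds (high for the test run, permissive for controls), subtracts
everything seen in either control, and finally removes peptides already
present in the unprocessed library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

RUN_LABELS = ("test", "inactive", "mock", "library")


@dataclass(frozen=True)
class PeptideID:
    """One identified peptide from one MS run."""

    sequence: str
    nterm_biotin: bool
    confidence: float
    run_label: str = "test"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        bad = set(self.sequence) - set(AA_ALPHABET)
        if bad:
            raise ValueError(f"non-canonical residues in peptide: {sorted(bad)}")
        if not 0.0 <= self.confidence <= 100.0:
            raise ValueError("confidence must be a percentage in [0, 100]")
        if self.run_label not in RUN_LABELS:
            raise ValueError(f"run_label must be one of {RUN_LABELS}")


@dataclass
class RunSet:
    """The four identification lists of one screen."""

    test: list[PeptideID]
    inactive: list[PeptideID]
    mock: list[PeptideID]
    library: list[PeptideID]

    def __post_init__(self) -> None:
        for label in RUN_LABELS:
            for p in getattr(self, label):
                if p.run_label != label:
                    raise ValueError(
                        f"peptide labeled {p.run_label!r} found in {label!r} list"
                    )


@dataclass
class FilterReport:
    """Peptide counts surviving each cascade stage (test run)."""

    input: int = 0
    after_biotin: int = 0
    after_confidence: int = 0
    after_control_subtraction: int = 0
    after_library_removal: int = 0

    def to_dict(self) -> dict:
        return {
            "input": self.input,
            "after_biotin": self.after_biotin,
            "after_confidence": self.after_confidence,
            "after_control_subtraction": self.after_control_subtraction,
            "after_library_removal": self.after_library_removal,
        }


def collapse_duplicates(ids: Iterable[PeptideID]) -> list[PeptideID]:
    """Collapse repeated sequences within one run to the highest-confidence
    instance, preserving first-occurrence order."""
    best: dict[str, PeptideID] = {}
    order: list[str] = []
    for p in ids:
        if p.sequence not in best:
            best[p.sequence] = p
            order.append(p.sequence)
        elif p.confidence > best[p.sequence].confidence:
            best[p.sequence] = p
    return [best[s] for s in order]


def filter_biotinylated(ids: Iterable[PeptideID]) -> list[PeptideID]:
    """Keep exactly the peptides carrying the N-terminal biotin label."""
    return [p for p in ids if p.nterm_biotin]


def apply_confidence_filter(ids: Iterable[PeptideID], threshold: float) -> list[PeptideID]:
    """Keep peptides with confidence strictly greater than `threshold` (percent)."""
    if not 0.0 <= threshold <= 100.0:
        raise ValueError("threshold must be in [0, 100]")
    return [p for p in ids if p.confidence > threshold]


def subtract_controls(
    test: Iterable[PeptideID],
    inactive: Iterable[PeptideID],
    mock: Iterable[PeptideID],
) -> list[PeptideID]:
    """Remove test peptides whose sequence occurs in either control list.

    Matching is exact sequence identity; the control lists are expected to
    already be confidence-filtered at the (permissive) control threshold.
    """
    background = {p.sequence for p in inactive} | {p.sequence for p in mock}
    return [p for p in test if p.sequence not in background]


def remove_library_peptides(
    test: Iterable[PeptideID], library_run: Iterable[PeptideID]
) -> list[PeptideID]:
    """Remove test peptides already identified in the unprocessed library."""
    library_seqs = {p.sequence for p in library_run}
    return [p for p in test if p.sequence not in library_seqs]


def run_cascade(
    runs: RunSet,
    test_threshold: float = 80.0,
    control_threshold: float = 10.0,
) -> tuple[list[PeptideID], FilterReport]:
    """Full filter cascade: biotin -> confidence -> control subtraction ->
    library removal, with a stage-count report.

    Controls are filtered at the permissive `control_threshold` before
    subtraction, so low-confidence control identifications still count as
    background.  Defaults (80 / 10) are the standard screen settings.
    """
    report = FilterReport()
    test = collapse_duplicates(runs.test)
    report.input = len(test)

    test = filter_biotinylated(test)
    report.after_biotin = len(test)

    test = apply_confidence_filter(test, test_threshold)
    report.after_confidence = len(test)

    inactive = apply_confidence_filter(collapse_duplicates(runs.inactive), control_threshold)
    mock = apply_confidence_filter(collapse_duplicates(runs.mock), control_threshold)
    test = subtract_controls(test, inactive, mock)
    report.after_control_subtraction = len(test)

    test = remove_library_peptides(test, runs.library)
    report.after_library_removal = len(test)
    return test, report
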