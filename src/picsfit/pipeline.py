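"""End-to-end composition of the cleavage-site pipeline."""

from __future__ import annotations

from dataclasses import dataclass

from .pics_filter import RunSet, FilterReport, run_cascade
from .site_mapping import MappingReport, map_all
from .specificity import SpecificityMatrix, build_matrix, library_background
from .synthetic_data import Proteome


@dataclass
class PicsResult:
    """Everything one screen produces: survivors, windows, matrix, reports."""

    survivors: list
    windows: list
    matrix: SpecificityMatrix
    filter_report: FilterReport
    mapping_report: MappingReport

    @property
    def no_cleavage_detected(self) -> bool:
        """True when the full cascade yields zero cleavage windows — the
        negative outcome for a protease inactive on the library."""
        return self.matrix.n_windows == 0

    def report_dict(self) -> dict:
        return {
            "filter": self.filter_report.to_dict(),
            "mapping": self.mapping_report.to_dict(),
            "n_windows": self.matrix.n_windows,
            "no_cleavage_detected": self.no_cleavage_detected,
        }


def run_pics(
    runs: RunSet,
    proteome: Proteome,
    test_threshold: float = 80.0,
    control_threshold: float = 10.0,
    background=None,
) -> PicsResult:
    """Filter cascade -> proteome mapping -> specificity matrix."""
    survivors, filter_report = run_cascade(runs, test_threshold, control_threshold)
    windows, mapping_report = map_all(survivors, proteome)
    matrix = build_matrix(windows, background=background)
    return PicsResult(
        survivors=survivors,
        windows=windows,
        matrix=matrix,
        filter_report=filter_report,
        mapping_report=mapping_report,
    )
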