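"""Substrate-specificity matrix: per-subsite amino-acid frequencies.

The matrix tallies, over all reconstructed cleavage windows, how often each
of the 20 amino acids occupies each of the 10 subsites P5..P1, P1'..P5'.
Gap symbols (window truncated at a protein terminus or a short peptide) and
the non-prime half of ambiguous windows are excluded from both counts and
column totals, so each column is a frequency distribution over what was
actually observed there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pics_filter import AA_ALPHABET
from .site_mapping import GAP, SUBSITES, CleavageWindow

AA_LIST = tuple(AA_ALPHABET)


@dataclass
class SpecificityMatrix:
    """20 x 10 counts and column-normalized frequencies.

    Rows are amino acids in alphabetical order, columns are subsites in
    P5..P1, P1'..P5' order.  `empty_columns` flags subsites with zero
    observations (their frequency column is all-zero rather than NaN).
    `background` optionally holds the residue frequencies of the input
    library for enrichment normalization.
    """

    counts: np.ndarray
    frequencies: np.ndarray
    n_windows: int
    background: np.ndarray | None = None
    empty_columns: tuple[str, ...] = field(default_factory=tuple)

    @property
    def is_empty(self) -> bool:
        return self.n_windows == 0

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(AA_LIST), columns=list(SUBSITES))

    def frequencies_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.frequencies, index=list(AA_LIST), columns=list(SUBSITES))


def library_background(peptides) -> np.ndarray:
    """Residue frequencies of a peptide collection (20-vector, alphabet order)."""
    counts = np.zeros(20)
    index = {aa: i for i, aa in enumerate(AA_LIST)}
    for pep in peptides:
        seq = pep.sequence if hasattr(pep, "sequence") else pep
        for res in seq:
            counts[index[res]] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def build_matrix(
    windows: list[CleavageWindow], background: np.ndarray | None = None
) -> SpecificityMatrix:
    """Tally residues per subsite over cleavage windows.

    Skips gap symbols everywhere and the non-prime columns of ambiguous
    windows; empty input yields an all-zero matrix flagged empty.
    """
    index = {aa: i for i, aa in enumerate(AA_LIST)}
    counts = np.zeros((20, 10), dtype=int)
    for w in windows:
        if w.nonprime is not None:
            for j, res in enumerate(w.nonprime):
                if res != GAP:
                    counts[index[res], j] += 1
        for j, res in enumerate(w.prime):
            if res != GAP:
                counts[index[res], 5 + j] += 1

    totals = counts.sum(axis=0)
    freqs = np.zeros((20, 10))
    nonzero = totals > 0
    freqs[:, nonzero] = counts[:, nonzero] / totals[nonzero]
    empty = tuple(SUBSITES[j] for j in range(10) if not nonzero[j])
    return SpecificityMatrix(
        counts=counts,
        frequencies=freqs,
        n_windows=len(windows),
        background=None if background is None else np.asarray(background, dtype=float),
        empty_columns=empty,
    )


def enrichment(matrix: SpecificityMatrix) -> pd.DataFrame:
    """Frequency over library-background frequency, per residue and subsite.

    Residues with zero background frequency are undefined (NaN); columns
    with zero observations are NaN throughout.
    """
    if matrix.background is None:
        raise ValueError("matrix has no background frequencies")
    bg = matrix.background
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = matrix.frequencies / bg[:, None]
    ratio[np.broadcast_to(bg[:, None], ratio.shape) == 0] = np.nan
    for j, label in enumerate(SUBSITES):
        if label in matrix.empty_columns:
            ratio[:, j] = np.nan
    return pd.DataFrame(ratio, index=list(AA_LIST), columns=list(SUBSITES))


def export_matrix(
    matrix: SpecificityMatrix, path, logo_path=None
) -> None:
    """Write the frequency matrix as TSV; optionally draw a stacked-letter
    frequency logo (one column per subsite) to `logo_path`.

    The TSV carries a `# n_windows=` header comment so an empty matrix
    round-trips with its flag.
    """
    frame = matrix.frequencies_frame()
    with open(path, "w") as fh:
        fh.write(f"# n_windows={matrix.n_windows}\n")
        if matrix.empty_columns:
            fh.write(f"# empty_columns={','.join(matrix.empty_columns)}\n")
        frame.to_csv(fh, sep="\t", index_label="aa", float_format="%.10g")
    if logo_path is not None:
        plot_logo(matrix, logo_path)


def read_matrix(path) -> pd.DataFrame:
    """Read a frequency matrix TSV written by `export_matrix`."""
    return pd.read_csv(path, sep="\t", comment="#", index_col="aa")


def plot_logo(matrix: SpecificityMatrix, path) -> None:
    """Per-subsite stacked-letter frequency plot (tallest letter on top)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    for j, label in enumerate(SUBSITES):
        col = matrix.frequencies[:, j]
        order = np.argsort(col)
        y = 0.0
        for i in order:
            f = col[i]
            if f <= 0:
                continue
            ax.text(j, y + f / 2, AA_LIST[i], ha="center", va="center",
                    fontsize=4 + 16 * f, family="monospace")
            y += f
    ax.set_xticks(range(10), [s.replace("p", "'") for s in SUBSITES])
    ax.set_xlim(-0.6, 9.6)
    ax.set_ylim(0, 1.02)
    ax.set_ylabel("frequency")
    ax.axvline(4.5, color="0.6", lw=1, ls="--")  # scissile bond
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
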