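"""Readers and writers for the pipeline's plain-text formats.

Formats: proteome FASTA; peptide runs as TSV (run, peptide, nterm_biotin,
confidence); titrations as TSV (injection_index, volume_uL, heat_ucal) with
the injection protocol in `# key=value` header comments; cleavage windows
as TSV; JSON reports.  Every writer has a matching reader and all formats
round-trip byte-stably.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .itc import InjectionProtocol, Titration
from .pics_filter import PeptideID, RunSet
from .site_mapping import SUBSITES, CleavageWindow
from .synthetic_data import Proteome

RUN_COLUMNS = ["run", "peptide", "nterm_biotin", "confidence"]


class DataError(ValueError):
    """A malformed input file (bad columns, values, or records)."""


def write_proteome(proteome: Proteome, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="")
        for pid, seq in proteome.entries
    ]
    SeqIO.write(records, path, "fasta")


def read_proteome(path) -> Proteome:
    try:
        records = list(SeqIO.parse(path, "fasta"))
    except (ValueError, FileNotFoundError) as exc:
        raise DataError(f"cannot parse FASTA {path}: {exc}") from exc
    if not records:
        raise DataError(f"no FASTA records in {path}")
    try:
        return Proteome(tuple((r.id, str(r.seq).upper()) for r in records))
    except ValueError as exc:
        raise DataError(f"invalid proteome in {path}: {exc}") from exc


def write_runs(runs: RunSet, path) -> None:
    rows = [
        (p.run_label, p.sequence, int(p.nterm_biotin), p.confidence)
        for label in ("test", "inactive", "mock", "library")
        for p in getattr(runs, label)
    ]
    frame = pd.DataFrame(rows, columns=RUN_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_runs(path) -> RunSet:
    try:
        frame = pd.read_csv(path, sep="\t", dtype={"peptide": str})
    except (ValueError, FileNotFoundError) as exc:
        raise DataError(f"cannot parse run TSV {path}: {exc}") from exc
    missing = set(RUN_COLUMNS) - set(frame.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    lists: dict[str, list[PeptideID]] = {k: [] for k in ("test", "inactive", "mock", "library")}
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        if row.run not in lists:
            raise DataError(f"{path}:{i}: unknown run label {row.run!r}")
        try:
            lists[row.run].append(
                PeptideID(row.peptide, bool(row.nterm_biotin),
                          float(row.confidence), run_label=row.run)
            )
        except ValueError as exc:
            raise DataError(f"{path}:{i}: {exc}") from exc
    return RunSet(**lists)


def write_peptides(ids: list[PeptideID], path) -> None:
    """Survivors list (same TSV dialect as a run file)."""
    frame = pd.DataFrame(
        [(p.run_label, p.sequence, int(p.nterm_biotin), p.confidence) for p in ids],
        columns=RUN_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_peptides(path) -> list[PeptideID]:
    runs = read_runs(path)
    return runs.test + runs.inactive + runs.mock + runs.library


def write_windows(windows: list[CleavageWindow], path) -> None:
    cols = ["protein_id", "cut_position", *SUBSITES, "ambiguous_flag", "source_peptide"]
    rows = []
    for w in windows:
        nonprime = w.nonprime if w.nonprime is not None else "-----"
        rows.append(
            (
                w.protein_id,
                "" if w.cut_position is None else w.cut_position,
                *tuple(nonprime),
                *tuple(w.prime),
                int(w.ambiguous),
                w.source_peptide,
            )
        )
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_windows(path) -> list[CleavageWindow]:
    try:
        frame = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    except (ValueError, FileNotFoundError) as exc:
        raise DataError(f"cannot parse windows TSV {path}: {exc}") from exc
    out = []
    for row in frame.itertuples(index=False):
        ambiguous = bool(int(row.ambiguous_flag))
        nonprime = "".join(getattr(row, s) for s in SUBSITES[:5])
        prime = "".join(getattr(row, s) for s in SUBSITES[5:])
        out.append(
            CleavageWindow(
                prime=prime,
                nonprime=None if ambiguous else nonprime,
                source_peptide=row.source_peptide,
                protein_id=row.protein_id,
                cut_position=int(row.cut_position) if row.cut_position else None,
            )
        )
    return out


def write_titration(titration: Titration, path) -> None:
    p = titration.protocol
    with open(path, "w") as fh:
        fh.write(f"# cell_volume_mL={p.cell_volume:.10g}\n")
        fh.write(f"# cell_conc_uM={p.cell_conc:.10g}\n")
        fh.write(f"# syringe_conc_uM={p.syringe_conc:.10g}\n")
        fh.write(f"# temperature_K={p.temperature:.10g}\n")
        fh.write("injection_index\tvolume_uL\theat_ucal\n")
        for i, (dv, q) in enumerate(zip(p.injection_volumes, titration.heats), start=1):
            fh.write(f"{i}\t{dv:.10g}\t{q:.10g}\n")


def read_titration(path) -> Titration:
    meta: dict[str, float] = {}
    try:
        with open(path) as fh:
            lines = fh.readlines()
    except FileNotFoundError as exc:
        raise DataError(f"cannot open titration {path}: {exc}") from exc
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = float(val)
            body_start = i + 1
        else:
            break
    required = {"cell_volume_mL", "cell_conc_uM", "syringe_conc_uM"}
    if not required <= set(meta):
        raise DataError(f"{path}: missing protocol header keys {sorted(required - set(meta))}")
    from io import StringIO

    try:
        frame = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
        vols = tuple(float(v) for v in frame["volume_uL"])
        heats = np.asarray(frame["heat_ucal"], dtype=float)
    except (ValueError, KeyError) as exc:
        raise DataError(f"{path}: malformed titration table: {exc}") from exc
    protocol = InjectionProtocol(
        cell_volume=meta["cell_volume_mL"],
        cell_conc=meta["cell_conc_uM"],
        syringe_conc=meta["syringe_conc_uM"],
        injection_volumes=vols,
        temperature=meta.get("temperature_K", 298.15),
    )
    return Titration(protocol=protocol, heats=heats)
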