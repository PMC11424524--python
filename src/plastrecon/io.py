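"""FASTA / TSV / JSON input and output.

FASTA reading goes through Biopython's SeqIO with a light validation pass on
top (IUPAC alphabet, non-empty records) that reports the offending line
number. Sequences are uppercased on read; writing wraps at 70 columns and
preserves ids verbatim. Circularity travels as a ``circular=true`` token in
the description (FASTA has no standard flag for it); contig truth intervals
and strands travel the same way (``interval=START-END strand=+``).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

from Bio import SeqIO

from ._seq import IUPAC_ALPHABET, chunk_iter
from .compare import ComparisonReport, DifferenceRecord
from .consensus import ResolutionRecord
from .errors import FastaParseError
from .structure import PlastomeSequence, QuadripartitePartition
from .synthetic import Contig, ContigSet, ErrorEvent, ErrorLog

FASTA_WRAP = 70


def _validate_fasta_lines(path: Path) -> None:
    """Cheap structural scan so errors carry a line number."""
    last_header_line = None
    seen_seq = False
    any_records = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if last_header_line is not None and not seen_seq:
                    raise FastaParseError("empty FASTA record", last_header_line)
                if len(line) == 1:
                    raise FastaParseError("FASTA header lacks an identifier", lineno)
                last_header_line, seen_seq, any_records = lineno, False, True
            else:
                if last_header_line is None:
                    raise FastaParseError(
                        "sequence data before any FASTA header", lineno)
                bad = set(line.upper()) - IUPAC_ALPHABET - {"-"}
                if bad:
                    raise FastaParseError(
                        f"non-IUPAC character(s) {sorted(bad)}", lineno)
                seen_seq = True
    if last_header_line is not None and not seen_seq:
        raise FastaParseError("empty FASTA record", last_header_line)
    if not any_records:
        raise FastaParseError("no FASTA records found", 1)


def read_fasta(path: str | Path) -> list[PlastomeSequence]:
    """Read plastome sequences; order and ids preserved, sequences uppercased."""
    path = Path(path)
    _validate_fasta_lines(path)
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        circular = "circular=true" in rec.description.lower()
        out.append(PlastomeSequence(id=rec.id, sequence=str(rec.seq).upper(),
                                    circular=circular))
    return out


def read_contigs(path: str | Path) -> ContigSet:
    """Read a contig FASTA, recovering interval/strand tokens when present."""
    path = Path(path)
    _validate_fasta_lines(path)
    contigs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        interval, strand = (0, len(rec.seq)), "+"
        for token in rec.description.split():
            if token.startswith("interval="):
                s, e = token[len("interval="):].split("-")
                interval = (int(s), int(e))
            elif token.startswith("strand="):
                strand = token[len("strand="):]
        contigs.append(Contig(id=rec.id, sequence=str(rec.seq).upper(),
                              truth_interval=interval, strand=strand))
    return ContigSet(contigs)


def _write_record(fh, header: str, seq: str) -> None:
    fh.write(f">{header}\n")
    for chunk in chunk_iter(seq, FASTA_WRAP):
        fh.write(chunk + "\n")


def write_fasta(path: str | Path, seqs: list[PlastomeSequence]) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            header = s.id + (" circular=true" if s.circular else "")
            _write_record(fh, header, s.sequence)


def write_contigs(path: str | Path, contigs: ContigSet) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            header = (f"{c.id} interval={c.truth_interval[0]}-"
                      f"{c.truth_interval[1]} strand={c.strand}")
            _write_record(fh, header, c.sequence)


def write_error_log(path: str | Path, log: ErrorLog) -> None:
    with open(path, "w") as fh:
        fh.write("position\tkind\tdetail\n")
        for ev in log.events:
            fh.write(f"{ev.position}\t{ev.kind}\t{ev.detail}\n")


def read_error_log(path: str | Path) -> ErrorLog:
    events = []
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            pos, kind, detail = line.rstrip("\n").split("\t")
            events.append(ErrorEvent(int(pos), kind,
                                     int(detail) if kind == "deletion" else detail))
    return ErrorLog(events)


def write_regions_tsv(path: str | Path, partition: QuadripartitePartition) -> None:
    """Region coordinates, 0-based half-open; end may wrap past the length."""
    with open(path, "w") as fh:
        fh.write("region\tstart\tend\tlength\n")
        for name in ("lsc", "irb", "ssc", "ira"):
            s, e = getattr(partition, name)
            fh.write(f"{name}\t{s}\t{e}\t{e - s}\n")
        fh.write(f"# ir_identity\t{partition.ir_identity:.6f}\n")


def write_differences_tsv(path: str | Path, diffs: list[DifferenceRecord]) -> None:
    cols = ("column_start", "kind", "length", "run_base", "run_id")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for d in diffs:
            fh.write("\t".join(
                "" if getattr(d, c) is None else str(getattr(d, c)) for c in cols
            ) + "\n")


def write_resolutions_tsv(path: str | Path, records: list[ResolutionRecord]) -> None:
    cols = ("position", "input_a", "input_b", "rule_applied", "output", "flagged")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write("\t".join(str(getattr(r, c)) for c in cols) + "\n")


_TABLE_SYMBOLS = ["A", "C", "T", "G", "N"]


def write_report(report: ComparisonReport, path: str | Path,
                 format: str = "json") -> None:
    """Write a comparison report as json, tsv, or a human-readable table.

    The table mirrors the conventional assembly-comparison layout: Total
    length, per-base rows, N, any ambiguity codes, Total changes and
    % dissimilarity. JSON round-trips losslessly; the TSV parses to the
    same numbers.
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report.to_dict(), indent=1) + "\n")
        return
    extra = sorted((set(report.counts_a) | set(report.counts_b))
                   - set(_TABLE_SYMBOLS))
    symbols = _TABLE_SYMBOLS + extra
    rows: list[tuple[str, object, object]] = [
        ("Total length", report.len_a, report.len_b)]
    rows += [(sym, report.counts_a.get(sym, 0), report.counts_b.get(sym, 0))
             for sym in symbols]
    rows += [("Total changes", report.total_changes, ""),
             ("% dissimilarity", f"{report.pct_dissimilarity:.3f}", "")]
    if format == "tsv":
        lines = [f"{label}\t{va}\t{vb}" for label, va, vb in rows]
    elif format == "table":
        width = max(len(r[0]) for r in rows)
        lines = [f"{label:<{width}}  {va!s:>12}  {vb!s:>12}" for label, va, vb in rows]
    else:
        raise ValueError(f"unknown report format: {format!r}")
    path.write_text("\n".join(lines) + "\n")


def read_report(path: str | Path) -> ComparisonReport:
    d = json.loads(Path(path).read_text())
    return ComparisonReport(**d)


def read_config(path: str | Path) -> dict:
    """Flat ``key=value`` or JSON configuration file."""
    text = Path(path).read_text()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        return json.loads(text)
    cfg: dict = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"config line {lineno} is not key=value: {line!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        try:
            cfg[key] = json.loads(value)
        except json.JSONDecodeError:
            cfg[key] = value
    return cfg


def write_resolved_config(path: str | Path, cfg: dict) -> None:
    Path(path).write_text(json.dumps(cfg, indent=1, sort_keys=True) + "\n")


def report_from_dicts(d: dict) -> ComparisonReport:
    return ComparisonReport(**d)


def asdict_dataclass(obj) -> dict:
    return asdict(obj)
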