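"""Sample-sheet and sequence-file I/O.

Sequence files are FASTA or FASTQ, plain or gzipped, parsed with Biopython.
A sample sheet is a TSV with a header and columns ``sample_id``, ``path``
(one or more, tab-separated continuation columns allowed) and ``label``
(1 or 2, or empty for unlabelled samples); class 1 maps to label +1 and
class 2 to -1.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from Bio import SeqIO

from .simulate import ReadSet, SampleTruth

__all__ = [
    "SampleSheet",
    "SheetRow",
    "read_sequences",
    "read_sample_sheet",
    "load_samples",
    "write_fasta",
    "write_fastq",
    "write_dataset",
]

_LABEL_MAP = {"1": 1, "2": -1}
_FASTQ_QUALITY = "I"  # uniform Phred 40 for simulated error-free reads


@dataclass
class SheetRow:
    sample_id: str
    paths: list[Path]
    label: Optional[int]  # +1 / -1 / None


@dataclass
class SampleSheet:
    rows: list[SheetRow]

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.rows]


def _open_text(path: Union[str, Path]):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sequence_format(path: Path) -> str:
    name = path.name[: -len(".gz")] if path.name.endswith(".gz") else path.name
    suffix = Path(name).suffix.lower()
    if suffix in (".fa", ".fasta", ".fna"):
        return "fasta"
    if suffix in (".fq", ".fastq"):
        return "fastq"
    raise ValueError(f"cannot infer sequence format from file name: {path}")


def read_sequences(path: Union[str, Path]) -> list[str]:
    """Read all sequences from a FASTA/FASTQ file (optionally gzipped)."""
    path = Path(path)
    fmt = _sequence_format(path)
    with _open_text(path) as handle:
        return [str(rec.seq) for rec in SeqIO.parse(handle, fmt)]


def read_sample_sheet(path: Union[str, Path]) -> SampleSheet:
    """Parse and validate a sample sheet TSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sample sheet not found: {path}")
    rows: list[SheetRow] = []
    seen: set[str] = set()
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if not header or header[0] != "sample_id":
            raise ValueError(
                f"sample sheet must start with a header whose first column is "
                f"'sample_id', got {header!r}"
            )
        for line_no, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"line {line_no}: expected at least sample_id, path, label"
                )
            sample_id, *middle, label_str = fields
            if sample_id in seen:
                raise ValueError(f"line {line_no}: duplicate sample_id {sample_id!r}")
            seen.add(sample_id)
            paths = [Path(p) for p in middle if p.strip()]
            if not paths:
                raise ValueError(f"line {line_no}: no sequence file for {sample_id!r}")
            for p in paths:
                if not p.is_absolute():
                    p = path.parent / p
                if not p.exists():
                    raise FileNotFoundError(
                        f"line {line_no}: sequence file not found: {p}"
                    )
            paths = [p if p.is_absolute() else path.parent / p for p in paths]
            label_str = label_str.strip()
            if label_str == "":
                label = None
            elif label_str in _LABEL_MAP:
                label = _LABEL_MAP[label_str]
            else:
                raise ValueError(
                    f"line {line_no}: label must be 1, 2 or empty, got {label_str!r}"
                )
            rows.append(SheetRow(sample_id=sample_id, paths=paths, label=label))
    if not rows:
        raise ValueError(f"sample sheet {path} contains no samples")
    return SampleSheet(rows=rows)


def load_samples(sheet: SampleSheet) -> list[ReadSet]:
    """Load every sample's reads (concatenating multiple files per sample)."""
    samples = []
    for row in sheet.rows:
        reads: list[str] = []
        for p in row.paths:
            reads.extend(read_sequences(p))
        samples.append(ReadSet(sample_id=row.sample_id, reads=reads, label=row.label))
    return samples


def write_fasta(read_set: ReadSet, path: Union[str, Path]) -> None:
    with open(path, "w") as out:
        for i, read in enumerate(read_set.reads, start=1):
            out.write(f">{read_set.sample_id}_read{i}\n{read}\n")


def write_fastq(read_set: ReadSet, path: Union[str, Path]) -> None:
    with open(path, "w") as out:
        for i, read in enumerate(read_set.reads, start=1):
            out.write(
                f"@{read_set.sample_id}_read{i}\n{read}\n+\n"
                f"{_FASTQ_QUALITY * len(read)}\n"
            )


def write_dataset(
    samples: Sequence[ReadSet],
    truths: Sequence[SampleTruth],
    outdir: Union[str, Path],
    fastq: bool = False,
) -> Path:
    """Write one sequence file per sample, a sample sheet and ground truth.

    Returns the path of the sample sheet.  Ground truth (seed sequence and
    0-based insertion position per event) goes to ``<sample>.truth.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_by_id = {t.sample_id: t for t in truths}
    sheet_path = outdir / "samples.tsv"
    with open(sheet_path, "w") as sheet:
        sheet.write("sample_id\tpath\tlabel\n")
        for sample in samples:
            ext = "fastq" if fastq else "fasta"
            fname = f"{sample.sample_id}.{ext}"
            (write_fastq if fastq else write_fasta)(sample, outdir / fname)
            label = {1: "1", -1: "2", None: ""}[sample.label]
            sheet.write(f"{sample.sample_id}\t{fname}\t{label}\n")
            truth = truth_by_id.get(sample.sample_id)
            if truth is not None:
                with open(outdir / f"{sample.sample_id}.truth.tsv", "w") as th:
                    th.write("seed\tposition\n")
                    for ev in truth.events:
                        th.write(f"{ev.seed}\t{ev.position}\n")
    return sheet_path
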