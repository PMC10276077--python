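"""File formats: FASTQ streaming, count tables and cluster maps as TSV.

TSV (not CSV) is used for all sequence tables to avoid quoting; gzip is
handled transparently for FASTQ by file extension.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from .extraction import ReadRecord


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a FASTQ or gzipped FASTQ file.

    Records are yielded lazily; a malformed record aborts with its position.
    """
    with _open_text(path) as handle:
        n = 0
        try:
            for rec in SeqIO.parse(handle, "fastq"):
                n += 1
                yield ReadRecord(
                    identifier=rec.id,
                    sequence=str(rec.seq).upper(),
                    qualities=tuple(rec.letter_annotations["phred_quality"]),
                )
        except ValueError as exc:
            raise ValueError(
                f"{path}: malformed FASTQ near record {n + 1} "
                f"(approx. line {4 * n + 1}): {exc}"
            ) from exc


def write_fastq(records: Iterable[tuple[str, str, str]], path) -> int:
    """Write (id, sequence, quality-string) triples as FASTQ; returns count."""
    n = 0
    with _open_text(path, "wt") as out:
        for identifier, seq, qual in records:
            out.write(f"@{identifier}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def write_counts(counts, path) -> None:
    """Write a count table as TSV (barcode, reads), highest counts first with
    lexicographic tie-breaking."""
    series = pd.Series(counts, dtype="int64")
    if (series < 0).any():
        raise ValueError("read counts must be non-negative")
    df = series.rename_axis("barcode").rename("reads").reset_index()
    df = df.sort_values(["reads", "barcode"], ascending=[False, True], kind="stable")
    df.to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.Series:
    """Read a (barcode, reads) TSV into a count series; duplicates rejected."""
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str})
    if not {"barcode", "reads"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'barcode' and 'reads'")
    if df["barcode"].duplicated().any():
        dups = df.loc[df["barcode"].duplicated(), "barcode"].tolist()
        raise ValueError(f"{path}: duplicate barcode rows: {dups[:5]}")
    if (df["reads"] < 0).any():
        raise ValueError(f"{path}: negative read counts")
    return pd.Series(df["reads"].values, index=df["barcode"].values, name="reads")


def write_library(lib, path) -> None:
    """Write a TrueLibrary as TSV (barcode, abundance, frequency)."""
    lib.as_frame().to_csv(path, sep="\t", index=False)


def write_truth_table(sim, path) -> None:
    """Write simulated reads as TSV (observed, parent, error_class, reads)."""
    sim.table.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> dict[str, tuple[str, str, str, str]]:
    """Read a sample sheet CSV (sample, i5, i7, inline5, inline3)."""
    df = pd.read_csv(path, dtype=str)
    required = {"sample", "i5", "i7", "inline5", "inline3"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return {
        row.sample: (row.i5, row.i7, row.inline5, row.inline3)
        for row in df.itertuples(index=False)
    }
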