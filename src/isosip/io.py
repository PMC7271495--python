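"""Sequence and table I/O plus the amplicon expected-error filter."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__


@dataclass
class SequenceRecord:
    id: str
    sequence: str
    qualities: list[int] | None = None

    def __post_init__(self):
        if self.qualities is not None and \
                len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: quality length "
                f"{len(self.qualities)} != sequence length "
                f"{len(self.sequence)}")


@dataclass
class QualityFilterParams:
    """Truncation length and maximum expected error (EE = sum 10^(-Q/10))."""

    truncate_len: int = 275
    max_expected_error: float = 2.0

    def __post_init__(self):
        if self.truncate_len <= 0 or self.max_expected_error <= 0:
            raise ValueError("filter parameters must be positive")


def expected_error(qualities: Sequence[int]) -> float:
    q = np.asarray(qualities, dtype=float)
    return float(np.sum(10.0 ** (-q / 10.0)))


def expected_error_filter(reads: Iterable[SequenceRecord],
                          params: QualityFilterParams | None = None
                          ) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Truncate reads and drop those whose expected error exceeds the cap.

    Reads shorter than the truncation length are discarded; retained reads
    are truncated and kept only if EE <= max_expected_error (the strict
    "greater than" rule discards, so an EE exactly at the cap survives).
    Returns the retained reads and a per-read discard log.
    """
    params = params or QualityFilterParams()
    kept = []
    log_rows = []
    for r in reads:
        if r.qualities is None:
            raise ValueError(f"read {r.id!r} has no quality scores")
        if len(r.sequence) < params.truncate_len:
            log_rows.append((r.id, np.nan, "too_short"))
            continue
        trunc = SequenceRecord(r.id, r.sequence[:params.truncate_len],
                               r.qualities[:params.truncate_len])
        ee = expected_error(trunc.qualities)
        if ee > params.max_expected_error:
            log_rows.append((r.id, ee, "expected_error"))
        else:
            kept.append(trunc)
            log_rows.append((r.id, ee, "retained"))
    log = pd.DataFrame(log_rows, columns=["read_id", "expected_error",
                                          "status"])
    return kept, log


# ---------------------------------------------------------------------------
# FASTA / FASTQ / TSV


def read_sequences(path, fmt: str | None = None) -> list[SequenceRecord]:
    """Read FASTA or FASTQ (Phred+33); format inferred from the suffix."""
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {fmt!r}")
    out = []
    for rec in SeqIO.parse(str(path), fmt):
        quals = rec.letter_annotations.get("phred_quality")
        out.append(SequenceRecord(rec.id, str(rec.seq),
                                  list(quals) if quals is not None else None))
    return out


def write_sequences(records: Iterable[SequenceRecord], path,
                    fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    bio = []
    for r in records:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        if fmt == "fastq":
            if r.qualities is None:
                raise ValueError(f"record {r.id!r} has no qualities for FASTQ")
            rec.letter_annotations["phred_quality"] = list(r.qualities)
        bio.append(rec)
    SeqIO.write(bio, str(path), fmt)


def write_table(df: pd.DataFrame, path, *, seed: int | None = None,
                params: dict | None = None, index: bool = False) -> None:
    """TSV with a comment header recording version, seed and parameters."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# isosip {__version__}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        for k, v in (params or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
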