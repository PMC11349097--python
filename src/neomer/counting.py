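"""Demultiplexing and per-module k-mer counting of Neomer sequencing reads.

Reads carry a 6-nt sample barcode ("hex code") at a fixed offset, followed
by the module amplicon. Each read is assigned to a sample by exact barcode
match, aligned substitution-only against the module sub-scaffold, and on
success its k random nucleotides are encoded as a radix-4 integer key and
counted. Frequencies are counts divided by a per-module denominator.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from .scaffold import NeomerScaffold, decode_kmer, encode_kmer, match_template

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SequencingRead:
    id: str
    seq: str
    source_file: str = ""


@dataclass
class BarcodeSpec:
    """Where to look for the sample barcode within a read.

    With the library-prep primer layout used here the sequencing primer ends
    immediately before the hex code, so reads start with the barcode:
    ``offset`` defaults to 0. ``length`` is implied by the barcode map.
    """

    offset: int = 0


@dataclass
class ModuleCountTable:
    """Counts over all 4^k module keys for one sample and one module."""

    sample_id: str
    module: str
    k: int
    counts: np.ndarray
    total_matched: int
    total_reads: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4**self.k,):
            raise ValueError("counts vector must have length 4^k")
        if int(self.counts.sum()) != self.total_matched:
            raise ValueError("counts must sum to total_matched")
        if self.total_matched > self.total_reads:
            raise ValueError("total_matched cannot exceed total_reads")

    def to_frame(self, sparse: bool = True) -> pd.DataFrame:
        """Tabular view: key_index, key_seq, count (nonzero rows if sparse)."""
        idx = np.nonzero(self.counts)[0] if sparse else np.arange(4**self.k)
        return pd.DataFrame(
            {
                "key_index": idx,
                "key_seq": [decode_kmer(int(i), self.k) for i in idx],
                "count": self.counts[idx],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        sample_id: str,
        module: str,
        k: int,
        total_reads: Optional[int] = None,
    ) -> "ModuleCountTable":
        df = pd.read_csv(path, sep="\t")
        counts = np.zeros(4**k, dtype=np.int64)
        counts[df["key_index"].to_numpy()] = df["count"].to_numpy()
        matched = int(counts.sum())
        return cls(sample_id, module, k, counts, matched,
                   total_reads if total_reads is not None else matched)


@dataclass
class FrequencyVector:
    sample_id: str
    module: str
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        if np.any(self.freqs < 0):
            raise ValueError("frequencies must be non-negative")


class EmptySampleError(ValueError):
    """Raised when frequencies are requested from a table with a zero denominator."""


def read_sequences(path: str | Path) -> Iterator[SequencingRead]:
    """Stream reads from a FASTA or FASTQ file (gzip accepted)."""
    path = Path(path)
    name = path.name.removesuffix(".gz")
    fmt = "fastq" if name.endswith((".fastq", ".fq")) else "fasta"
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield SequencingRead(rec.id, str(rec.seq).upper(), str(path))


def demultiplex(
    reads: Iterable[SequencingRead],
    hexcodes: Mapping[str, str],
    barcode_spec: BarcodeSpec | None = None,
) -> tuple[dict[str, list[SequencingRead]], int]:
    """Assign reads to samples by exact barcode match at a fixed offset.

    Returns per-sample read lists plus the count of undetermined reads.
    Matching is exact by design: short barcode sets are not in general
    error-correcting, so no 1-mismatch rescue is attempted.
    """
    spec = barcode_spec or BarcodeSpec()
    lengths = {len(b) for b in hexcodes.values()}
    if len(lengths) != 1:
        raise ValueError("all barcodes must have equal length")
    if len(set(hexcodes.values())) != len(hexcodes):
        raise ValueError("duplicate barcodes in sample map")
    (blen,) = lengths
    lookup = {b: s for s, b in hexcodes.items()}
    out: dict[str, list[SequencingRead]] = {s: [] for s in hexcodes}
    undetermined = 0
    for read in reads:
        code = read.seq[spec.offset : spec.offset + blen]
        sample = lookup.get(code)
        if sample is None:
            undetermined += 1
        else:
            out[sample].append(read)
    return out, undetermined


def count_module(
    reads: Iterable[SequencingRead],
    module: str,
    scaffold: NeomerScaffold,
    sample_id: str = "",
    max_fixed_mismatches: int = 0,
) -> ModuleCountTable:
    """Count module keys by matching each read against the module sub-scaffold.

    Reads that fail the fixed-position match (or whose random positions
    contain N) increment ``total_reads`` but not ``total_matched``.
    """
    template = scaffold.module_template(module)
    k = scaffold.k_module_a if module.upper() == "A" else scaffold.k_module_b
    counts = np.zeros(4**k, dtype=np.int64)
    total_reads = 0
    matched = 0
    for read in reads:
        total_reads += 1
        rand = match_template(read.seq, template, max_fixed_mismatches)
        if rand is not None:
            counts[encode_kmer(rand)] += 1
            matched += 1
    if total_reads == 0:
        logger.warning("count_module(%s, module %s): empty input", sample_id, module)
    return ModuleCountTable(sample_id, module.upper(), k, counts, matched, total_reads)


def to_frequencies(
    table: ModuleCountTable, denominator: str = "matched"
) -> FrequencyVector:
    """Convert counts to frequencies.

    ``denominator='matched'`` (default) divides by the number of
    scaffold-conformant reads, so frequencies sum to 1; ``'all_reads'``
    divides by every read seen for the module.
    """
    if denominator == "matched":
        denom = table.total_matched
    elif denominator == "all_reads":
        denom = table.total_reads
    else:
        raise ValueError("denominator must be 'matched' or 'all_reads'")
    if denom == 0:
        raise EmptySampleError(
            f"sample {table.sample_id!r} module {table.module}: zero denominator"
        )
    return FrequencyVector(table.sample_id, table.module, table.counts / denom)
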