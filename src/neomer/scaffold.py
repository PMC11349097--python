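"""Neomer library scaffold model and 2-bit sequence coding.

A Neomer library is a fixed-length oligonucleotide template in which short
runs of random nucleotides are interspersed among fixed scaffold segments.
The canonical design carries 16 random nt in six runs inside a 73-nt
template; a KasI restriction site (GGCGCC) in the central fixed segment
lets the amplicon be cut into two "modules", each carrying 8 of the 16
random nt, so that each module spans only 4^8 = 65,536 distinct sequences
and can be exhaustively counted from a single sequencing run.

This module provides the scaffold representation, encoding of module
sequences as radix-4 integers (A=0, C=1, G=2, T=3), substitution-only read
matching against the scaffold, and validation of published aptamer/primer
records.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np

CANONICAL_TEMPLATE = (
    "CCAGATACAGACNNGAGGNNNGAATNNNAACCATCGGCGCCAACANNNCATTCNNNCAGANNCAGTAGACAGC"
)
KASI_SITE = "GGCGCC"
FORWARD_PRIMER = "GTTCCCAGATACAGAC"

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains characters outside the expected alphabet."""


def sequence_space(n_random: int) -> int:
    """Number of distinct sequences a library with ``n_random`` random nt spans.

    The split-module design's 16 random nt give 4^16 ~ 4.29e9 sequences,
    each module's 8 give 4^8 = 65,536; a conventional contiguous 40-nt
    random region spans 4^40 ~ 1.2e24 — far beyond the ~1e15-1e16
    oligonucleotides one can physically apply to a sample, which is what
    motivates the interspersed design.
    """
    if n_random < 0:
        raise ValueError("n_random must be non-negative")
    return 4**n_random


def reverse_complement(seq: str) -> str:
    """Watson-Crick complement, reversed. Accepts A/C/G/T/N."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_kmer(seq: str) -> int:
    """Encode a k-mer over {A,C,G,T} as its radix-4 integer (A=0,C=1,G=2,T=3).

    The map is a bijection onto [0, 4^k - 1], lexicographic in A<C<G<T.
    Raises :class:`InvalidSequenceError` on any other character (reads with
    N are discarded upstream, never encoded).
    """
    idx = 0
    for ch in seq:
        code = _BASE_CODE.get(ch)
        if code is None:
            raise InvalidSequenceError(f"non-ACGT character {ch!r} in {seq!r}")
        idx = (idx << 2) | code
    return idx


def decode_kmer(index: int, k: int) -> str:
    """Inverse of :func:`encode_kmer` for a k-mer."""
    if not 0 <= index < 4**k:
        raise ValueError(f"index {index} out of range for k={k}")
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(_BASES[(index >> shift) & 3])
    return "".join(out)


def encode_kmers(seqs: "list[str]") -> np.ndarray:
    """Vectorised :func:`encode_kmer` over a list of equal-length k-mers."""
    return np.array([encode_kmer(s) for s in seqs], dtype=np.int64)


@dataclass(frozen=True)
class NeomerScaffold:
    """The fixed/random template of a Neomer library and its module split.

    Parameters
    ----------
    fixed_segments:
        Ordered fixed nucleotide segments (a leading/trailing random run is
        not supported; the canonical design starts and ends with fixed
        sequence).
    random_run_lengths:
        Lengths of the random runs interleaved between consecutive fixed
        segments.
    restriction_site:
        Recognition site used to split the amplicon into modules; must occur
        exactly once in the concatenated fixed sequence.
    module_boundary:
        Number of leading random runs assigned to module A; the remainder
        belong to module B.
    """

    fixed_segments: tuple[str, ...]
    random_run_lengths: tuple[int, ...]
    restriction_site: str = KASI_SITE
    module_boundary: int = 3

    def __post_init__(self) -> None:
        if len(self.fixed_segments) != len(self.random_run_lengths) + 1:
            raise ValueError("need one more fixed segment than random runs")
        fixed = "".join(self.fixed_segments)
        if fixed.count(self.restriction_site) != 1:
            raise ValueError(
                f"restriction site {self.restriction_site} must occur exactly "
                f"once in the fixed sequence (found {fixed.count(self.restriction_site)})"
            )
        if not 0 < self.module_boundary < len(self.random_run_lengths):
            raise ValueError("module boundary must split the random runs in two")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_template(
        cls,
        template: str = CANONICAL_TEMPLATE,
        restriction_site: str = KASI_SITE,
        module_boundary: Optional[int] = None,
    ) -> "NeomerScaffold":
        """Build a scaffold from an N-run template string.

        With no explicit ``module_boundary`` the runs are split at the
        restriction site: runs upstream of the cut go to module A.
        """
        runs = tuple(len(m) for m in re.findall(r"N+", template))
        segments = tuple(re.split(r"N+", template))
        if module_boundary is None:
            cut = template.find(restriction_site)
            if cut < 0:
                raise ValueError("restriction site absent from template")
            module_boundary = sum(
                1 for m in re.finditer(r"N+", template) if m.start() < cut
            )
        return cls(segments, runs, restriction_site, module_boundary)

    # -- derived views ----------------------------------------------------

    @property
    def template(self) -> str:
        parts = [self.fixed_segments[0]]
        for run, seg in zip(self.random_run_lengths, self.fixed_segments[1:]):
            parts.append("N" * run)
            parts.append(seg)
        return "".join(parts)

    @property
    def total_length(self) -> int:
        return len(self.template)

    @property
    def n_random(self) -> int:
        return sum(self.random_run_lengths)

    @property
    def k_module_a(self) -> int:
        return sum(self.random_run_lengths[: self.module_boundary])

    @property
    def k_module_b(self) -> int:
        return sum(self.random_run_lengths[self.module_boundary :])

    def random_positions(self) -> np.ndarray:
        t = self.template
        return np.array([i for i, c in enumerate(t) if c == "N"], dtype=np.intp)

    def module_template(self, module: str) -> str:
        """Sub-template for one module of the cut amplicon.

        The cut is placed at the restriction enzyme's cleavage position
        within the site (one base into the KasI site, G^GCGCC), so module A
        ends ...AACCATCG and module B starts GCGCCAACA... for the canonical
        design.
        """
        t = self.template
        cut = t.find(self.restriction_site) + 1
        if module.upper() == "A":
            return t[:cut]
        if module.upper() == "B":
            return t[cut:]
        raise ValueError(f"module must be 'A' or 'B', got {module!r}")

    def fill(self, random_nt: str) -> str:
        """Substitute a full random-nt string into the template's N positions."""
        if len(random_nt) != self.n_random:
            raise ValueError(
                f"expected {self.n_random} random nt, got {len(random_nt)}"
            )
        it = iter(random_nt)
        return "".join(next(it) if c == "N" else c for c in self.template)


def match_template(
    read_seq: str, template: str, max_fixed_mismatches: int = 0
) -> Optional[str]:
    """Slide ``template`` (with N wildcards) along ``read_seq`` without indels.

    Returns the nucleotides at the N positions of the best (first, leftmost)
    alignment whose fixed-position mismatch count is within budget and whose
    random positions carry no N; otherwise ``None``. No-match is a value,
    not an error: reads that fail are simply not counted.
    """
    L, W = len(read_seq), len(template)
    if L < W:
        return None
    fixed_idx = [i for i, c in enumerate(template) if c != "N"]
    fixed_nt = [template[i] for i in fixed_idx]
    rand_idx = [i for i, c in enumerate(template) if c == "N"]
    for off in range(L - W + 1):
        mism = 0
        for i, b in zip(fixed_idx, fixed_nt):
            if read_seq[off + i] != b:
                mism += 1
                if mism > max_fixed_mismatches:
                    break
        else:
            rand = "".join(read_seq[off + i] for i in rand_idx)
            if "N" not in rand:
                return rand
    return None


def match_scaffold(
    read_seq: str, scaffold: NeomerScaffold, max_fixed_mismatches: int = 0
) -> Optional[str]:
    """Extract the full random-nt string from a read spanning the whole scaffold."""
    return match_template(read_seq, scaffold.template, max_fixed_mismatches)


def split_random16(random_nt: str, scaffold: NeomerScaffold) -> tuple[str, str]:
    """Split the concatenated random nucleotides into (module A, module B) keys."""
    if len(random_nt) != scaffold.n_random:
        raise ValueError(
            f"expected {scaffold.n_random} random nt, got {len(random_nt)}"
        )
    ka = scaffold.k_module_a
    return random_nt[:ka], random_nt[ka:]


@dataclass
class AptamarkerRecord:
    """A published aptamer ("Aptamarker") with its amplification primers."""

    name: str
    full_seq: str
    contrast: str  # "HAM" (high-amyloid) or "LAM" (low-amyloid)
    reverse_primer: str
    forward_primer: str = FORWARD_PRIMER

    def random16(self, scaffold: NeomerScaffold) -> str:
        rand = match_scaffold(self.full_seq, scaffold, max_fixed_mismatches=0)
        if rand is None:
            raise ValueError(f"{self.name} does not match the scaffold")
        return rand

    def module_keys(self, scaffold: NeomerScaffold) -> tuple[str, str]:
        return split_random16(self.random16(scaffold), scaffold)


def validate_reverse_primer(rec: AptamarkerRecord) -> tuple[bool, int]:
    """Check that the reverse primer's reverse complement sits inside the aptamer.

    Returns ``(ok, offset)`` where offset is the 0-based position of the
    primer's reverse complement within ``full_seq`` (-1 if absent).
    """
    target = reverse_complement(rec.reverse_primer)
    off = rec.full_seq.find(target)
    return off >= 0, off


def load_aptamarkers() -> list[AptamarkerRecord]:
    """Load the packaged table of the eight published Aptamarkers."""
    recs = []
    text = (
        resources.files("neomer").joinpath("data/aptamarkers.tsv").read_text()
    )
    lines = text.strip().splitlines()
    header = lines[0].split("\t")
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        recs.append(
            AptamarkerRecord(
                name=row["name"],
                full_seq=row["full_seq"],
                contrast=row["contrast"],
                reverse_primer=row["reverse_primer"],
            )
        )
    return recs


def make_scaffold(k_per_module: int = 8) -> NeomerScaffold:
    """Canonical scaffold, or a reduced-k analogue for small test libraries.

    The reduced scaffold keeps the canonical fixed segments but shortens the
    random runs so each module carries ``k_per_module`` random nt; run
    lengths are balanced over the three runs of each module (runs of length
    zero are dropped, merging their flanking fixed segments).
    """
    if k_per_module == 8:
        return NeomerScaffold.from_template(CANONICAL_TEMPLATE)
    if not 1 <= k_per_module <= 8:
        raise ValueError("k_per_module must be in [1, 8]")

    def partition(k: int) -> list[int]:
        base, extra = divmod(k, 3)
        return [base + (1 if i < extra else 0) for i in range(3)]

    runs = partition(k_per_module) + partition(k_per_module)
    canonical = NeomerScaffold.from_template(CANONICAL_TEMPLATE)
    segs = list(canonical.fixed_segments)
    # rebuild template, merging fixed segments across zero-length runs
    parts = [segs[0]]
    for run, seg in zip(runs, segs[1:]):
        parts.append("N" * run)
        parts.append(seg)
    template = "".join(parts)
    return NeomerScaffold.from_template(template)
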