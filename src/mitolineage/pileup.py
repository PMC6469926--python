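"""Stranded mitochondrial pileup containers and coverage summaries.

The unit of data is a per-position table of stranded allele counts on the
mitochondrial genome (rCRS coordinates, 1-based, length 16569).  Pileups are
assumed to be produced upstream with base/mapping-quality filtering already
applied; this module only validates, stores and summarises counts.

The on-disk dialect is a tab-separated table::

    pos  ref  A_fwd  A_rev  C_fwd  C_rev  G_fwd  G_rev  T_fwd  T_rev

Positions absent from the table are treated as zero depth (sparse storage).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np

ALLELES = ("A", "C", "G", "T")
ALLELE_INDEX = {a: i for i, a in enumerate(ALLELES)}
STRANDS = ("fwd", "rev")

#: rCRS mitochondrial genome length.
RCRS_LENGTH = 16569

#: Default coverage mask: the window around the rCRS position-3107 'N'
#: placeholder, a strong artefactual depletion region.
DEFAULT_COVERAGE_MASK = ((3105, 3110),)

PILEUP_COLUMNS = (
    "pos", "ref",
    "A_fwd", "A_rev", "C_fwd", "C_rev", "G_fwd", "G_rev", "T_fwd", "T_rev",
)


class PileupError(ValueError):
    """Invalid pileup content (bounds, duplicates, negative counts...)."""


class PileupParseError(PileupError):
    """Malformed pileup text; carries the offending 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class SitePileup:
    """Stranded allele counts at one mtDNA position.

    ``counts`` is a (4, 2) integer array indexed [allele(A,C,G,T), strand(fwd,rev)].
    """

    position: int
    ref_allele: str
    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (4, 2):
            raise PileupError(f"counts must be (4,2), got {c.shape}")
        if (c < 0).any():
            raise PileupError(f"negative count at position {self.position}")
        object.__setattr__(self, "counts", c)
        if self.ref_allele not in ("A", "C", "G", "T", "N"):
            raise PileupError(f"bad ref allele {self.ref_allele!r}")

    @property
    def depth(self) -> int:
        """Total depth: sum over the 8 stranded allele counts."""
        return int(self.counts.sum())

    def allele_count(self, allele: str) -> int:
        return int(self.counts[ALLELE_INDEX[allele]].sum())

    def strand_counts(self, allele: str) -> tuple[int, int]:
        """(forward, reverse) read counts for one allele."""
        row = self.counts[ALLELE_INDEX[allele]]
        return int(row[0]), int(row[1])


@dataclass
class PileupMatrix:
    """Sparse per-position pileup for one sample.

    ``positions`` are unique, sorted, 1-based; ``counts`` has shape
    (n_sites, 4, 2).  Missing positions imply zero depth.  The mitochondrial
    genome is circular but represented linearly (pileups are precomputed
    upstream, so no read-wrapping logic is needed here).
    """

    sample_id: str
    positions: np.ndarray
    refs: np.ndarray
    counts: np.ndarray
    genome_length: int = RCRS_LENGTH
    circular: bool = True

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.refs = np.asarray(self.refs, dtype="U1")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.positions)
        if self.refs.shape != (n,) or self.counts.shape != (n, 4, 2):
            raise PileupError("positions/refs/counts shape mismatch")
        if self.genome_length <= 0:
            raise PileupError("genome_length must be positive")
        if n:
            if (np.diff(self.positions) <= 0).any():
                bad = self.positions[np.where(np.diff(self.positions) <= 0)[0] + 1]
                raise PileupError(f"positions not strictly increasing near {bad[0]}")
            if self.positions[0] < 1 or self.positions[-1] > self.genome_length:
                raise PileupError("position outside [1, genome_length]")
        if (self.counts < 0).any():
            raise PileupError("negative counts")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def depths(self) -> np.ndarray:
        """Per-stored-site total depth (sum of the 8 stranded counts)."""
        return self.counts.sum(axis=(1, 2))

    def site(self, position: int) -> SitePileup | None:
        """The SitePileup at ``position``, or None if not stored (zero depth)."""
        i = int(np.searchsorted(self.positions, position))
        if i < len(self.positions) and self.positions[i] == position:
            return SitePileup(position, str(self.refs[i]), self.counts[i])
        return None

    def sites(self) -> Iterable[SitePileup]:
        for i, pos in enumerate(self.positions):
            yield SitePileup(int(pos), str(self.refs[i]), self.counts[i])

    def depth_vector(self) -> np.ndarray:
        """Dense per-position depth over the whole genome (index 0 = position 1)."""
        v = np.zeros(self.genome_length, dtype=np.int64)
        v[self.positions - 1] = self.depths
        return v

    @classmethod
    def from_sites(cls, sample_id: str, sites: Sequence[SitePileup],
                   genome_length: int = RCRS_LENGTH) -> "PileupMatrix":
        sites = sorted(sites, key=lambda s: s.position)
        return cls(
            sample_id=sample_id,
            positions=np.array([s.position for s in sites], dtype=np.int64),
            refs=np.array([s.ref_allele for s in sites], dtype="U1"),
            counts=(np.stack([s.counts for s in sites])
                    if sites else np.zeros((0, 4, 2), dtype=np.int64)),
            genome_length=genome_length,
        )


@dataclass
class CoverageSummary:
    """Coverage over the mitochondrial genome with masked artefact regions.

    ``mean_depth`` is computed only over unmasked positions.
    """

    mean_depth: float
    per_position_depth: np.ndarray
    masked_intervals: tuple[tuple[int, int], ...]
    mito_read_fraction: float | None = None


def _validate_mask(mask: Sequence[tuple[int, int]], genome_length: int) -> tuple[tuple[int, int], ...]:
    ivs = sorted((int(a), int(b)) for a, b in mask)
    prev_end = 0
    for a, b in ivs:
        if a > b:
            raise PileupError(f"inverted mask interval [{a},{b}]")
        if a < 1 or b > genome_length:
            raise PileupError(f"mask interval [{a},{b}] outside genome bounds")
        if a <= prev_end:
            raise PileupError(f"overlapping mask interval [{a},{b}]")
        prev_end = b
    return tuple(ivs)


def coverage_summary(p: PileupMatrix,
                     mask: Sequence[tuple[int, int]] = DEFAULT_COVERAGE_MASK,
                     mito_reads: int | None = None,
                     nuclear_reads: int | None = None) -> CoverageSummary:
    """Per-position depth and mean depth over unmasked positions.

    ``mask`` is a list of 1-based inclusive [start, end] intervals excluded
    from the mean (default: the rCRS 3107 'N' depletion window).
    """
    ivs = _validate_mask(mask, p.genome_length)
    depth = p.depth_vector()
    keep = np.ones(p.genome_length, dtype=bool)
    for a, b in ivs:
        keep[a - 1:b] = False
    mean = float(depth[keep].mean()) if keep.any() else float("nan")
    frac = None
    if mito_reads is not None and nuclear_reads is not None:
        frac = mito_read_fraction(mito_reads, nuclear_reads)
    return CoverageSummary(mean, depth, ivs, frac)


def mito_read_fraction(mito_reads: int, nuclear_reads: int) -> float:
    """Fraction of reads mapping to the mitochondrial genome.

    ATAC-seq libraries are strongly enriched for mtDNA; this is the
    enrichment summary mito / (mito + nuclear).
    """
    if mito_reads < 0 or nuclear_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = mito_reads + nuclear_reads
    if total == 0:
        raise ValueError("mito_reads and nuclear_reads are both zero")
    return mito_reads / total


def load_pileup(source: str | Path | TextIO,
                genome_length: int = RCRS_LENGTH,
                sample_id: str = "") -> PileupMatrix:
    """Read the pileup TSV dialect into a validated PileupMatrix.

    Raises :class:`PileupParseError` naming the 1-based line number for a
    malformed row, and :class:`PileupError` for duplicate or out-of-range
    positions.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not sample_id:
            sample_id = path.stem
        with open(path, "rt", encoding="utf-8") as fh:
            return _parse_pileup(fh, genome_length, sample_id)
    return _parse_pileup(source, genome_length, sample_id)


def _parse_pileup(fh: TextIO, genome_length: int, sample_id: str) -> PileupMatrix:
    positions: list[int] = []
    refs: list[str] = []
    counts: list[np.ndarray] = []
    seen: set[int] = set()
    header_seen = False
    for lineno, raw in enumerate(fh, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if not header_seen:
            header_seen = True
            if fields[0].lower() in ("pos", "position"):
                if len(fields) != 10:
                    raise PileupParseError(
                        f"expected 10 header columns, got {len(fields)}", lineno)
                continue  # header row consumed
            # headerless stream: fall through and parse as data
        if len(fields) != 10:
            raise PileupParseError(
                f"expected 10 fields, got {len(fields)}", lineno)
        try:
            pos = int(fields[0])
        except ValueError:
            raise PileupParseError(f"bad position {fields[0]!r}", lineno) from None
        ref = fields[1].upper()
        if ref not in ("A", "C", "G", "T", "N"):
            raise PileupParseError(f"bad ref allele {fields[1]!r}", lineno)
        try:
            vals = [int(x) for x in fields[2:]]
        except ValueError:
            raise PileupParseError("non-integer allele count", lineno) from None
        if any(v < 0 for v in vals):
            raise PileupParseError("negative allele count", lineno)
        if pos < 1 or pos > genome_length:
            raise PileupParseError(
                f"position {pos} outside [1, {genome_length}]", lineno)
        if pos in seen:
            raise PileupError(f"duplicate position {pos}")
        seen.add(pos)
        positions.append(pos)
        refs.append(ref)
        counts.append(np.array(vals, dtype=np.int64).reshape(4, 2))
    order = np.argsort(positions) if positions else np.array([], dtype=int)
    return PileupMatrix(
        sample_id=sample_id,
        positions=np.array(positions, dtype=np.int64)[order],
        refs=np.array(refs, dtype="U1")[order] if refs else np.zeros(0, dtype="U1"),
        counts=(np.stack(counts)[order]
                if counts else np.zeros((0, 4, 2), dtype=np.int64)),
        genome_length=genome_length,
    )


def write_pileup(p: PileupMatrix, dest: str | Path | TextIO) -> None:
    """Write a PileupMatrix in the TSV dialect (lossless round trip)."""
    def _emit(fh: TextIO) -> None:
        fh.write("\t".join(PILEUP_COLUMNS) + "\n")
        for i, pos in enumerate(p.positions):
            flat = p.counts[i].reshape(-1)
            fh.write(f"{int(pos)}\t{p.refs[i]}\t" + "\t".join(map(str, flat)) + "\n")

    if isinstance(dest, (str, Path)):
        with open(dest, "wt", encoding="utf-8") as fh:
            _emit(fh)
    else:
        _emit(dest)


def pileup_from_text(text: str, genome_length: int = RCRS_LENGTH,
                     sample_id: str = "") -> PileupMatrix:
    """Convenience wrapper: parse a pileup from an in-memory string."""
    return load_pileup(io.StringIO(text), genome_length, sample_id)
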