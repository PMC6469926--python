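"""Adapter from coordinate-sorted SAM/BAM alignments to stranded pileups.

Applies the quality regime of the upstream pipeline before counting:
mapping quality >= 30 always, base quality > 30 for bulk libraries or
>= 20 for single-cell libraries (where depth is too shallow to recalibrate
scores).  The output is the pileup TSV dialect consumed by the rest of the
package, so the core stays deterministic and testable without alignments.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pysam

from .pileup import ALLELE_INDEX, RCRS_LENGTH, PileupMatrix

#: (min mapping quality, min base quality, strict base-quality inequality)
BULK_QUALITY = (30, 30, True)         # base quality > 30
SINGLE_CELL_QUALITY = (20, 20, False)  # -q 20 -Q 20: base quality >= 20


def pileup_from_alignments(path: str | Path,
                           contig: str = "chrM",
                           genome_length: int = RCRS_LENGTH,
                           min_mapq: int = 30,
                           min_baseq: int = 20,
                           baseq_strict: bool = False,
                           sample_id: str = "") -> PileupMatrix:
    """Count stranded allele support per position from a SAM/BAM file.

    ``baseq_strict`` selects > (bulk convention) vs >= (single-cell
    convention) for the base-quality cut.  Reference alleles are not known
    from the alignment alone, so each site's reference is set to the
    majority allele; callers recounting known candidates never consult it.
    """
    path = Path(path)
    sample_id = sample_id or path.stem
    counts: dict[int, np.ndarray] = {}
    mode = "r" if path.suffix == ".sam" else "rb"
    with pysam.AlignmentFile(str(path), mode) as af:
        for read in af.fetch(contig) if af.has_index() else af:
            if af.has_index() is False and read.reference_name != contig:
                continue
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            seq = read.query_sequence
            quals = read.query_qualities
            if seq is None or quals is None:
                continue
            strand = 1 if read.is_reverse else 0
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                base = seq[qpos].upper()
                if base not in ALLELE_INDEX:
                    continue
                q = quals[qpos]
                if (q <= min_baseq) if baseq_strict else (q < min_baseq):
                    continue
                pos1 = rpos + 1
                if not (1 <= pos1 <= genome_length):
                    continue
                site = counts.setdefault(pos1, np.zeros((4, 2), dtype=np.int64))
                site[ALLELE_INDEX[base], strand] += 1
    positions = np.array(sorted(counts), dtype=np.int64)
    stacked = (np.stack([counts[p] for p in positions])
               if len(positions) else np.zeros((0, 4, 2), dtype=np.int64))
    # majority allele as stand-in reference
    refs = np.array(
        ["ACGT"[int(np.argmax(stacked[i].sum(axis=1)))] for i in range(len(positions))],
        dtype="U1") if len(positions) else np.zeros(0, dtype="U1")
    return PileupMatrix(sample_id, positions, refs, stacked, genome_length)
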