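"""Single-cell genotyping of candidate mtDNA variants.

Candidates called from bulk (or merged single-cell) data are re-counted in
each individual cell: only reads matching the candidate's alternate allele
count as support, and a cell is scored positive when support reaches
``min_support`` reads (default 1, i.e. any read).  Detection rates are then
summarised per variant in site-depth bins of width 10, and the sensitivity
gain from a set of linked variants is the complement-product combined rate
1 - prod(1 - R_i).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import VariantCall
from .pileup import ALLELE_INDEX, PileupMatrix

VariantId = tuple[int, str, str]

CARRIER = "carrier"
WT = "WT"
INSUFFICIENT = "insufficient"


def variant_label(vid: VariantId) -> str:
    pos, ref, alt = vid
    return f"{ref}{pos}{alt}"


@dataclass
class CellGenotypeMatrix:
    """Cells x variants supporting-read and total-depth matrices.

    ``support[c, v]`` counts reads in cell ``c`` matching variant ``v``'s
    alternate allele at its position; ``site_depth[c, v]`` is the total
    depth there.  ``support <= site_depth`` elementwise.
    """

    cell_ids: list[str]
    variant_ids: list[VariantId]
    support: np.ndarray
    site_depth: np.ndarray

    def __post_init__(self):
        self.support = np.asarray(self.support, dtype=np.int64)
        self.site_depth = np.asarray(self.site_depth, dtype=np.int64)
        shape = (len(self.cell_ids), len(self.variant_ids))
        if self.support.shape != shape or self.site_depth.shape != shape:
            raise ValueError("matrix shape does not match cell/variant ids")
        if (self.support < 0).any() or (self.site_depth < 0).any():
            raise ValueError("negative entries")
        if (self.support > self.site_depth).any():
            raise ValueError("support exceeds site depth")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        cols = [variant_label(v) for v in self.variant_ids]
        sup = pd.DataFrame(self.support, index=self.cell_ids, columns=cols)
        dep = pd.DataFrame(self.site_depth, index=self.cell_ids, columns=cols)
        sup.index.name = dep.index.name = "cell_id"
        return sup, dep

    def write(self, support_path: str | Path, depth_path: str | Path) -> None:
        sup, dep = self.to_frames()
        sup.to_csv(support_path, sep="\t")
        dep.to_csv(depth_path, sep="\t")

    def to_triplets(self) -> pd.DataFrame:
        """Sparse triplet form: one row per non-zero-depth (cell, variant)."""
        cells, variants = np.nonzero(self.site_depth)
        return pd.DataFrame({
            "cell_id": [self.cell_ids[i] for i in cells],
            "variant_id": [variant_label(self.variant_ids[j]) for j in variants],
            "support": self.support[cells, variants],
            "depth": self.site_depth[cells, variants],
        })

    @classmethod
    def read(cls, support_path: str | Path, depth_path: str | Path) -> "CellGenotypeMatrix":
        sup = pd.read_csv(support_path, sep="\t", index_col="cell_id")
        dep = pd.read_csv(depth_path, sep="\t", index_col="cell_id")
        if list(sup.columns) != list(dep.columns) or list(sup.index) != list(dep.index):
            raise ValueError("support/depth tables do not align")
        variant_ids = [_parse_variant_label(c) for c in sup.columns]
        return cls([str(i) for i in sup.index], variant_ids,
                   sup.to_numpy(), dep.to_numpy())


def _parse_variant_label(label: str) -> VariantId:
    return (int(label[1:-1]), label[0], label[-1])


def recount_in_cells(per_cell_pileups: Sequence[PileupMatrix],
                     candidates: Sequence[VariantCall],
                     cell_ids: Sequence[str] | None = None) -> CellGenotypeMatrix:
    """Re-count bulk/merged candidates in each individual cell.

    Only reads of the candidate's own alternate allele count as support; a
    different non-reference allele at the same position does not.  A
    position absent from a cell's pileup contributes support 0, depth 0.
    """
    if not candidates:
        raise ValueError("no candidate variants to recount")
    if cell_ids is None:
        cell_ids = [p.sample_id or f"cell_{i}" for i, p in enumerate(per_cell_pileups)]
    if len(cell_ids) != len(per_cell_pileups):
        raise ValueError("cell_ids length mismatch")
    glens = {p.genome_length for p in per_cell_pileups}
    if len(glens) > 1:
        raise ValueError("cell pileups disagree on genome_length")
    vids = [c.variant_id for c in candidates]
    n_c, n_v = len(per_cell_pileups), len(vids)
    support = np.zeros((n_c, n_v), dtype=np.int64)
    depth = np.zeros((n_c, n_v), dtype=np.int64)
    positions = np.array([c.position for c in candidates])
    alt_idx = np.array([ALLELE_INDEX[c.alt_allele] for c in candidates])
    for ci, p in enumerate(per_cell_pileups):
        idx = np.searchsorted(p.positions, positions)
        ok = (idx < len(p.positions))
        ok[ok] &= p.positions[idx[ok]] == positions[ok]
        hit = np.where(ok)[0]
        if hit.size:
            rows = idx[hit]
            depth[ci, hit] = p.counts[rows].sum(axis=(1, 2))
            support[ci, hit] = p.counts[rows, alt_idx[hit]].sum(axis=1)
    return CellGenotypeMatrix(list(cell_ids), vids, support, depth)


def binarize(m: CellGenotypeMatrix, min_support: int = 1) -> np.ndarray:
    """Detection matrix: 1 iff a variant is supported by >= min_support reads."""
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    return (m.support >= min_support).astype(np.int8)


def classify_wt_cells(m: CellGenotypeMatrix,
                      clone_variants: Sequence[set[VariantId] | frozenset[VariantId]],
                      mean_coverage: Sequence[float],
                      min_genome_coverage: float = 40.0,
                      min_support: int = 1) -> list[str]:
    """Label each cell carrier / WT / insufficient.

    A cell is a ``carrier`` as soon as any clone-set variant is detected
    (evidence needs no coverage floor); ``WT`` requires no detection AND
    mean mtDNA coverage above ``min_genome_coverage`` (default 40x) —
    without that depth, absence of evidence is uninformative and the cell
    is ``insufficient``.
    """
    if min_genome_coverage <= 0:
        raise ValueError("min_genome_coverage must be positive")
    mean_coverage = np.asarray(mean_coverage, dtype=float)
    if mean_coverage.shape != (m.n_cells,):
        raise ValueError("mean_coverage must have one entry per cell")
    clone_union = set().union(*clone_variants) if clone_variants else set()
    in_sets = np.array([vid in clone_union for vid in m.variant_ids])
    detected = binarize(m, min_support).astype(bool)
    any_clone_variant = (detected & in_sets).any(axis=1)
    labels = []
    for ci in range(m.n_cells):
        if any_clone_variant[ci]:
            labels.append(CARRIER)
        elif mean_coverage[ci] > min_genome_coverage:
            labels.append(WT)
        else:
            labels.append(INSUFFICIENT)
    return labels


@dataclass
class DetectionRateTable:
    """Per-variant detection rate in site-depth bins.

    Columns: variant, depth_lo, depth_hi (half-open [lo, hi)), n_cells,
    n_detected, rate (NaN for empty bins).
    """

    table: pd.DataFrame
    bin_width: int

    def rate(self, variant: VariantId | str, depth_lo: int) -> float:
        label = variant if isinstance(variant, str) else variant_label(variant)
        sel = self.table[(self.table.variant == label)
                         & (self.table.depth_lo == depth_lo)]
        if sel.empty:
            raise KeyError((label, depth_lo))
        return float(sel.rate.iloc[0])

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def detection_rate_by_depth(m: CellGenotypeMatrix,
                            bin_width: int = 10,
                            min_support: int = 1) -> DetectionRateTable:
    """Bin cells by site depth and compute per-bin detection rates.

    Bins are half-open ``[k*w, (k+1)*w)``; a cell with depth exactly on an
    edge belongs to the upper bin.  Empty intermediate bins are reported
    with n_cells = 0 and undefined (NaN) rate.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    detected = binarize(m, min_support)
    rows = []
    for vi, vid in enumerate(m.variant_ids):
        depths = m.site_depth[:, vi]
        bins = depths // bin_width
        n_bins = int(bins.max()) + 1 if len(bins) else 0
        for b in range(n_bins):
            sel = bins == b
            n = int(sel.sum())
            k = int(detected[sel, vi].sum())
            rows.append((variant_label(vid), b * bin_width, (b + 1) * bin_width,
                         n, k, k / n if n else np.nan))
    return DetectionRateTable(
        pd.DataFrame(rows, columns=["variant", "depth_lo", "depth_hi",
                                    "n_cells", "n_detected", "rate"]),
        bin_width)


def combined_detection_rate(rates: Sequence[float]) -> float:
    """Sensitivity of detecting any of k linked variants: 1 - prod(1 - R_i)."""
    rates = np.asarray(rates, dtype=float)
    if rates.size == 0:
        raise ValueError("need at least one rate")
    if ((rates < 0) | (rates > 1)).any():
        raise ValueError("rates must lie in [0, 1]")
    return float(1.0 - np.prod(1.0 - rates))


def detection_probability(f: float, d: int, min_support: int = 1) -> float:
    """P(Binomial(d, f) >= min_support): chance of detecting cellular VAF f at depth d.

    For min_support = 1 this is the closed form 1 - (1 - f)^d.
    """
    if not (0 <= f <= 1):
        raise ValueError("f must lie in [0, 1]")
    if d < 0:
        raise ValueError("d must be >= 0")
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if d == 0:
        return 0.0
    return float(stats.binom.sf(min_support - 1, d, f))
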