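"""Synthetic clonal mtDNA pileup generator.

Emulates a population of cells partitioned into clones, each clone defined
by a private set of heteroplasmic variants.  Per cell and variant the
cellular VAF is drawn from a Beta distribution (mean + concentration;
concentration ``None`` means a fixed VAF), read depth from a configurable
depth model, alternate reads from Binomial(depth, VAF), and sequencing
errors convert a fraction ``error_rate`` of the remaining reads uniformly
into the three non-reference alleles.  Reads are split between strands with
probability ``strand_prob``.  Doublets (two cells captured in one library)
are additive merges of two independently drawn cells' counts.

Everything is driven by one integer seed; identical configs produce
bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .pileup import ALLELES, ALLELE_INDEX, RCRS_LENGTH, PileupMatrix, write_pileup


@dataclass(frozen=True)
class SimVariant:
    """A clone-defining heteroplasmy: site, substitution, and cellular-VAF law."""

    position: int
    ref: str
    alt: str
    vaf_mean: float
    vaf_concentration: float | None = None  # None: every carrier has exactly vaf_mean

    def __post_init__(self):
        if self.ref not in ALLELES or self.alt not in ALLELES or self.ref == self.alt:
            raise ValueError(f"bad substitution {self.ref}->{self.alt}")
        if not (0 <= self.vaf_mean <= 1):
            raise ValueError("vaf_mean must lie in [0, 1]")
        if self.vaf_concentration is not None and self.vaf_concentration <= 0:
            raise ValueError("vaf_concentration must be positive")

    @property
    def variant_id(self) -> tuple[int, str, str]:
        return (self.position, self.ref, self.alt)


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset."""

    n_cells: int
    clone_fractions: Sequence[float]
    clone_variants: Sequence[Sequence[SimVariant]]
    genome_length: int = RCRS_LENGTH
    depth_model: str = "poisson"  # constant | poisson | lognormal
    depth_mean: float = 50.0
    depth_sigma: float = 0.5  # lognormal shape (log scale)
    error_rate: float = 0.0
    strand_prob: float = 0.5
    doublet_rate: float = 0.0
    background_positions: Sequence[int] = ()
    seed: int = 0

    def __post_init__(self):
        # normalise container types so configs compare equal after round trips
        self.clone_fractions = tuple(float(f) for f in self.clone_fractions)
        self.clone_variants = tuple(tuple(vs) for vs in self.clone_variants)
        self.background_positions = tuple(int(p) for p in self.background_positions)
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        fr = np.asarray(self.clone_fractions, dtype=float)
        if abs(fr.sum() - 1.0) > 1e-9 or (fr < 0).any():
            raise ValueError("clone_fractions must be non-negative and sum to 1")
        if len(self.clone_variants) != len(fr):
            raise ValueError("one variant list per clone required")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must lie in [0, 1)")
        if not (0 < self.strand_prob < 1):
            raise ValueError("strand_prob must lie in (0, 1)")
        if not (0 <= self.doublet_rate < 1):
            raise ValueError("doublet_rate must lie in [0, 1)")
        if self.depth_model not in ("constant", "poisson", "lognormal"):
            raise ValueError(f"unknown depth_model {self.depth_model!r}")
        positions = [v.position for vs in self.clone_variants for v in vs]
        if len(set(positions)) != len(positions):
            raise ValueError("variant positions must be unique across clones")
        for pos in list(positions) + list(self.background_positions):
            if not (1 <= pos <= self.genome_length):
                raise ValueError(f"position {pos} outside genome")

    @property
    def variants(self) -> list[SimVariant]:
        return [v for vs in self.clone_variants for v in vs]

    @property
    def variant_clone(self) -> np.ndarray:
        return np.array([k for k, vs in enumerate(self.clone_variants)
                         for _ in vs], dtype=int)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["clone_fractions"] = list(map(float, self.clone_fractions))
        d["background_positions"] = list(map(int, self.background_positions))
        return d


@dataclass
class SimTruth:
    """Ground truth emitted alongside the synthetic pileups."""

    cell_ids: list[str]
    clone_labels: np.ndarray      # primary clone index per cell
    is_doublet: np.ndarray        # bool per cell
    partner_labels: np.ndarray    # second clone index for doublets, else -1
    cell_vafs: np.ndarray         # cells x variants realized cellular VAF
    variant_ids: list[tuple[int, str, str]]
    variant_clone: np.ndarray     # clone index per variant

    def label(self, ci: int) -> str:
        return "doublet" if self.is_doublet[ci] else f"clone_{self.clone_labels[ci] + 1}"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cell_ids": self.cell_ids,
            "clone_labels": self.clone_labels.tolist(),
            "is_doublet": self.is_doublet.astype(bool).tolist(),
            "partner_labels": self.partner_labels.tolist(),
            "cell_vafs": self.cell_vafs.tolist(),
            "variant_ids": [f"{r}{p}{a}" for p, r, a in self.variant_ids],
            "variant_clone": self.variant_clone.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


def _reference_base(position: int) -> str:
    # deterministic synthetic reference for background sites
    return ALLELES[(position * 2654435761) % 4]


def _draw_depth(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    if cfg.depth_model == "constant":
        return np.full(n, int(round(cfg.depth_mean)), dtype=np.int64)
    if cfg.depth_model == "poisson":
        return rng.poisson(cfg.depth_mean, size=n).astype(np.int64)
    mu = np.log(cfg.depth_mean) - 0.5 * cfg.depth_sigma ** 2
    return np.round(rng.lognormal(mu, cfg.depth_sigma, size=n)).astype(np.int64)


def _draw_vaf(v: SimVariant, rng: np.random.Generator, n: int) -> np.ndarray:
    if v.vaf_concentration is None or v.vaf_mean in (0.0, 1.0):
        return np.full(n, v.vaf_mean)
    a = v.vaf_mean * v.vaf_concentration
    b = (1.0 - v.vaf_mean) * v.vaf_concentration
    return rng.beta(a, b, size=n)


def _allele_counts(depth: np.ndarray, alt_frac: np.ndarray, ref_idx: int,
                   alt_idx: int | None, error_rate: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Per-cell counts (n, 4): true alt reads, then errors off the remainder.

    The non-alt pool splits multinomially into the reference and the three
    non-reference alleles with probabilities (1-e, e/3, e/3, e/3), drawn as
    sequential conditional binomials so totals are conserved exactly.
    """
    n = len(depth)
    counts = np.zeros((n, 4), dtype=np.int64)
    if alt_idx is not None:
        true_alt = rng.binomial(depth, alt_frac)
        counts[:, alt_idx] += true_alt
        pool = depth - true_alt
    else:
        pool = depth.copy()
    e3 = error_rate / 3.0
    remaining_p = 1.0
    others = [i for i in range(4) if i != ref_idx]
    for a in others:
        if remaining_p <= 0 or e3 == 0:
            break
        draw = rng.binomial(pool, min(e3 / remaining_p, 1.0))
        counts[:, a] += draw
        pool = pool - draw
        remaining_p -= e3
    counts[:, ref_idx] += pool
    return counts


def _split_strands(counts: np.ndarray, strand_prob: float,
                   rng: np.random.Generator) -> np.ndarray:
    """(n, 4) -> (n, 4, 2) forward/reverse split."""
    fwd = rng.binomial(counts, strand_prob)
    return np.stack([fwd, counts - fwd], axis=-1)


def simulate_cells(cfg: SimConfig) -> tuple[list[PileupMatrix], SimTruth]:
    """Draw a clonal cell population and per-cell stranded pileups.

    Returns one sparse PileupMatrix per cell (variant plus background sites
    only; all other positions have zero depth) and the ground truth.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells
    k = len(cfg.clone_fractions)
    clone = rng.choice(k, size=n, p=np.asarray(cfg.clone_fractions, float))
    is_doublet = rng.random(n) < cfg.doublet_rate
    partner = np.where(
        is_doublet,
        rng.choice(k, size=n, p=np.asarray(cfg.clone_fractions, float)),
        -1)

    variants = cfg.variants
    vclone = cfg.variant_clone
    positions = sorted({v.position for v in variants}
                       | set(cfg.background_positions))
    ref_of = {v.position: v.ref for v in variants}
    site_ref = {pos: ref_of.get(pos, _reference_base(pos)) for pos in positions}

    # realized cellular VAFs: carriers draw from the Beta law, others 0
    vafs = np.zeros((n, len(variants)))
    partner_vafs = np.zeros((n, len(variants)))
    for vi, v in enumerate(variants):
        draws = _draw_vaf(v, rng, n)
        vafs[:, vi] = np.where(clone == vclone[vi], draws, 0.0)
        pdraws = _draw_vaf(v, rng, n)
        partner_vafs[:, vi] = np.where(
            is_doublet & (partner == vclone[vi]), pdraws, 0.0)

    var_index = {v.position: vi for vi, v in enumerate(variants)}
    all_counts = np.zeros((n, len(positions), 4, 2), dtype=np.int64)
    for si, pos in enumerate(positions):
        ref_idx = ALLELE_INDEX[site_ref[pos]]
        vi = var_index.get(pos)
        alt_idx = ALLELE_INDEX[variants[vi].alt] if vi is not None else None
        d1 = _draw_depth(cfg, rng, n)
        c1 = _allele_counts(d1, vafs[:, vi] if vi is not None else np.zeros(n),
                            ref_idx, alt_idx, cfg.error_rate, rng)
        # doublets: add an independent second cell's counts at its own depth
        if is_doublet.any():
            d2 = np.where(is_doublet, _draw_depth(cfg, rng, n), 0)
            c2 = _allele_counts(
                d2, partner_vafs[:, vi] if vi is not None else np.zeros(n),
                ref_idx, alt_idx, cfg.error_rate, rng)
            c1 = c1 + c2
        all_counts[:, si] = _split_strands(c1, cfg.strand_prob, rng)

    cell_ids = [f"cell_{i:05d}" for i in range(n)]
    pos_arr = np.array(positions, dtype=np.int64)
    ref_arr = np.array([site_ref[p] for p in positions], dtype="U1")
    cells = [
        PileupMatrix(cell_ids[i], pos_arr.copy(), ref_arr.copy(),
                     all_counts[i], cfg.genome_length)
        for i in range(n)
    ]
    truth = SimTruth(cell_ids, clone, is_doublet, partner, vafs,
                     [v.variant_id for v in variants], vclone)
    return cells, truth


def simulate_bulk(cfg: SimConfig, total_depth: int) -> PileupMatrix:
    """Bulk pileup: clone-fraction-weighted mixture of cellular heteroplasmy.

    The expected bulk VAF of a variant is its clone's population fraction
    times the mean cellular VAF; counts are binomial at ``total_depth``.
    """
    if total_depth <= 0:
        raise ValueError("total_depth must be positive")
    rng = np.random.default_rng(cfg.seed + 1)  # decouple from the cell stream
    variants = cfg.variants
    vclone = cfg.variant_clone
    fractions = np.asarray(cfg.clone_fractions, float)
    positions = sorted({v.position for v in variants}
                       | set(cfg.background_positions))
    ref_of = {v.position: v.ref for v in variants}
    var_index = {v.position: vi for vi, v in enumerate(variants)}
    sites_counts = np.zeros((len(positions), 4, 2), dtype=np.int64)
    refs = []
    depth = np.full(1, total_depth, dtype=np.int64)
    for si, pos in enumerate(positions):
        ref = ref_of.get(pos, _reference_base(pos))
        refs.append(ref)
        vi = var_index.get(pos)
        if vi is not None:
            bulk_vaf = float(fractions[vclone[vi]] * variants[vi].vaf_mean)
            alt_idx = ALLELE_INDEX[variants[vi].alt]
        else:
            bulk_vaf, alt_idx = 0.0, None
        c = _allele_counts(depth, np.array([bulk_vaf]), ALLELE_INDEX[ref],
                           alt_idx, cfg.error_rate, rng)
        sites_counts[si] = _split_strands(c, cfg.strand_prob, rng)[0]
    return PileupMatrix("bulk", np.array(positions, dtype=np.int64),
                        np.array(refs, dtype="U1"), sites_counts,
                        cfg.genome_length)


def sim_config_from_dict(data: dict) -> SimConfig:
    """Build a SimConfig from a plain mapping (e.g. parsed YAML/JSON).

    ``clone_variants`` entries may be mappings with the SimVariant field
    names or 4/5-item sequences (position, ref, alt, vaf_mean[, conc]).
    """
    data = dict(data)
    raw = data.pop("clone_variants", None)
    if raw is None:
        raise ValueError("config requires clone_variants")
    clone_variants = []
    for clone in raw:
        vs = []
        for item in clone:
            if isinstance(item, dict):
                vs.append(SimVariant(**item))
            else:
                vs.append(SimVariant(*item))
        clone_variants.append(vs)
    return SimConfig(clone_variants=clone_variants, **data)


def write_dataset(cfg: SimConfig, out_dir: str | Path) -> tuple[list[PileupMatrix], SimTruth]:
    """Simulate and write a dataset directory: per-cell pileups + truth + manifest."""
    out = Path(out_dir)
    (out / "cells").mkdir(parents=True, exist_ok=True)
    cells, truth = simulate_cells(cfg)
    for p in cells:
        write_pileup(p, out / "cells" / f"{p.sample_id}.tsv")
    truth.to_json(out / "truth.json")
    (out / "manifest.json").write_text(
        json.dumps({"config": cfg.to_dict()}, indent=2, default=str))
    return cells, truth
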