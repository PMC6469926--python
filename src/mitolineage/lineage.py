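"""Clonal lineage inference from sparse single-cell mtDNA genotypes.

The statistical backbone: with a per-base mutation rate r (~1e-7) and n
mtDNA copies per cell (100-10000), the chance that a given heteroplasmy
arises independently in one cell is P = n*r (1e-5..1e-3), and the chance
that N cells share it by coincidence is P^N — negligible for N >= 3.  Cells
sharing heteroplasmies therefore inherited them from a common ancestor, and
variants co-detected in far more cells than independence predicts must have
co-existed in that ancestor.

Clone-defining variant sets are recovered algorithmically as connected
components of a co-detection graph: an edge joins two variants whose
observed co-detection count exceeds the upper Poisson quantile of the
expected count under independence (optionally depth-normalised through
per-cell detection probabilities).  Cells are then assigned to the single
clone set their detections fall in; cells mixing two sets are flagged as
doublets and excluded downstream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .calling import VariantCall
from .genotyping import (WT, VariantId,
                         variant_label)

DOUBLET = "doublet"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class LineageParams:
    """Independent-origin model parameters.

    r: average per-base per-generation mtDNA mutation rate (~1e-7).
    n: mtDNA copies per cell (hundreds to >10,000 depending on cell type).
    """

    r: float = 1e-7
    n: int = 1000

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("mutation rate r must be positive")
        if self.n < 1:
            raise ValueError("mtDNA copy number n must be >= 1")


def independent_origin_probability(params: LineageParams) -> float:
    """P = n*r: chance a given site is mutated in one cell, capped at 1."""
    return min(params.n * params.r, 1.0)


def coincidence_probability(p_n: float, n_cells: int) -> float:
    """P^N: chance N cells share one heteroplasmy through independent origins."""
    if not (0 <= p_n <= 1):
        raise ValueError("p_n must lie in [0, 1]")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    return float(p_n ** n_cells)


def expected_cooccurrence(p_v1: float, p_v2: float, n_cells: int,
                          depth_weights: Sequence[float] | None = None) -> float:
    """Expected number of cells detecting both variants under independence.

    Without weights: p_v1 * p_v2 * N.  With per-cell weights (products of
    depth-dependent detection probabilities, the depth normalisation):
    p_v1 * p_v2 * sum(w_c).
    """
    for p in (p_v1, p_v2):
        if not (0 <= p <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
    if depth_weights is None:
        return p_v1 * p_v2 * n_cells
    w = np.asarray(depth_weights, dtype=float)
    if w.shape != (n_cells,):
        raise ValueError("depth_weights must have one entry per cell")
    return float(p_v1 * p_v2 * w.sum())


def _effective_vaf(carrier_freq: float, depths: np.ndarray) -> float:
    """Effective per-read positivity f solving mean_c 1-(1-f)^d_c = carrier_freq.

    Inverts the any-read detection curve so the depth-weighted expected
    detection frequency matches the observed one.
    """
    if carrier_freq <= 0:
        return 0.0
    d = depths[depths > 0]
    if d.size == 0 or carrier_freq >= 1:
        return 1.0

    def gap(f: float) -> float:
        return np.mean(1.0 - (1.0 - f) ** d) - carrier_freq

    if gap(1.0 - 1e-12) < 0:  # carrier_freq unreachable: saturate
        return 1.0
    return float(brentq(gap, 0.0, 1.0 - 1e-12, xtol=1e-12))


def group_variants_into_clone_sets(detected: np.ndarray,
                                   variant_ids: Sequence[VariantId],
                                   site_depth: np.ndarray | None = None,
                                   min_cells: int = 3,
                                   exceedance_quantile: float = 0.99,
                                   depth_adjust: bool = False) -> list[frozenset[VariantId]]:
    """Partition variants into clone-defining sets via co-detection.

    ``detected`` is the cells x variants binary matrix.  Two variants are
    linked when their observed co-detection count exceeds the
    ``exceedance_quantile`` Poisson quantile of the count expected if the
    two were carried by independent clones; clone sets are the connected
    components, kept only when supported by >= ``min_cells`` carrier cells
    (fewer cells cannot exclude coincidental sharing).

    With ``depth_adjust`` the independence expectation is depth-normalised:
    per-cell detection probabilities are derived from each variant's
    effective per-read positivity at the observed depths.
    """
    detected = np.asarray(detected, dtype=bool)
    if detected.ndim != 2 or detected.shape[1] != len(variant_ids):
        raise ValueError("detected must be cells x variants")
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    n_cells, n_var = detected.shape
    if n_cells == 0 or n_var == 0:
        raise ValueError("empty detection matrix")
    carrier_counts = detected.sum(axis=0)
    if (carrier_counts < min_cells).all():
        warnings.warn(f"no variant detected in >= {min_cells} cells; "
                      "nothing to group", stacklevel=2)
        return []
    p_v = carrier_counts / n_cells

    if depth_adjust:
        if site_depth is None:
            raise ValueError("depth_adjust requires site_depth")
        site_depth = np.asarray(site_depth)
        q = np.empty_like(detected, dtype=float)  # q[c,v] = P(detect v in c)
        for vi in range(n_var):
            f_hat = _effective_vaf(p_v[vi], site_depth[:, vi])
            q[:, vi] = 1.0 - (1.0 - f_hat) ** np.maximum(site_depth[:, vi], 0)
            q[site_depth[:, vi] <= 0, vi] = 0.0

    g = nx.Graph()
    g.add_nodes_from(range(n_var))
    co = (detected.astype(np.int64).T @ detected.astype(np.int64))
    for i in range(n_var):
        for j in range(i + 1, n_var):
            observed = int(co[i, j])
            if observed == 0:
                continue
            if depth_adjust:
                mu = float((q[:, i] * q[:, j]).sum())
            else:
                mu = expected_cooccurrence(p_v[i], p_v[j], n_cells)
            if observed > stats.poisson.ppf(exceedance_quantile, mu):
                g.add_edge(i, j)

    sets: list[frozenset[VariantId]] = []
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        member = detected[:, comp].any(axis=1)
        if int(member.sum()) >= min_cells:
            sets.append(frozenset(variant_ids[i] for i in comp))
    sets.sort(key=lambda s: min(v[0] for v in s))
    return sets


@dataclass
class CloneModel:
    """Clone-defining variant sets and per-cell assignments.

    Labels: ``clone_<k>`` (1-based), ``WT``, ``doublet`` (detections from
    >= 2 sets, excluded downstream), ``unassigned``.
    """

    clone_sets: list[frozenset[VariantId]]
    assignments: dict[str, str]
    evidence: dict[str, list[VariantId]]

    def clone_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for label in self.assignments.values():
            sizes[label] = sizes.get(label, 0) + 1
        return sizes

    def cells_in(self, label: str) -> list[str]:
        return [c for c, l in self.assignments.items() if l == label]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "clone_sets": [[variant_label(v) for v in sorted(s)]
                           for s in self.clone_sets],
            "assignments": self.assignments,
            "evidence": {c: [variant_label(v) for v in vs]
                         for c, vs in self.evidence.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def write_assignments(self, path: str | Path) -> None:
        pd.DataFrame(
            {"cell_id": list(self.assignments),
             "label": list(self.assignments.values()),
             "evidence": [",".join(variant_label(v) for v in self.evidence[c])
                          for c in self.assignments]},
        ).to_csv(path, sep="\t", index=False)


def assign_cells(detected: np.ndarray,
                 variant_ids: Sequence[VariantId],
                 clone_sets: Sequence[frozenset[VariantId]],
                 cell_ids: Sequence[str] | None = None,
                 wt_labels: Sequence[str] | None = None) -> CloneModel:
    """Assign each cell to a clone, or flag it WT / doublet / unassigned.

    A cell whose detections fall in exactly one clone set joins that clone;
    detections spanning >= 2 sets mark a doublet (two cells captured in one
    library).  A cell with no detection is WT only when the caller-supplied
    ``wt_labels`` (from the 40x-coverage rule) say so; cells whose only
    detections are in ungrouped variants stay unassigned.
    """
    detected = np.asarray(detected, dtype=bool)
    n_cells, n_var = detected.shape
    if n_var != len(variant_ids):
        raise ValueError("variant_ids length mismatch")
    sets = [frozenset(s) for s in clone_sets]
    for i, a in enumerate(sets):
        for b in sets[i + 1:]:
            if a & b:
                raise ValueError("clone sets must be pairwise disjoint")
    if cell_ids is None:
        cell_ids = [f"cell_{i}" for i in range(n_cells)]
    if wt_labels is not None and len(wt_labels) != n_cells:
        raise ValueError("wt_labels length mismatch")
    set_of_variant = {}
    for k, s in enumerate(sets):
        for v in s:
            set_of_variant[v] = k
    assignments: dict[str, str] = {}
    evidence: dict[str, list[VariantId]] = {}
    for ci, cell in enumerate(cell_ids):
        hits = [variant_ids[vi] for vi in np.where(detected[ci])[0]]
        evidence[cell] = hits
        hit_sets = {set_of_variant[v] for v in hits if v in set_of_variant}
        if len(hit_sets) >= 2:
            assignments[cell] = DOUBLET
        elif len(hit_sets) == 1:
            assignments[cell] = f"clone_{hit_sets.pop() + 1}"
        elif hits:  # detections only in ungrouped variants
            assignments[cell] = UNASSIGNED
        elif wt_labels is not None and wt_labels[ci] == WT:
            assignments[cell] = WT
        else:
            assignments[cell] = UNASSIGNED
    return CloneModel(list(sets), assignments, evidence)


@dataclass
class PopulationLineageTable:
    """Per-variant presence across sorted cell populations.

    A variant present (VAF above the reporting cut) in >= 2 populations is
    ``shared_across_populations`` — inherited from a common ancestor along
    the differentiation hierarchy; a variant confined to one population is
    ``population_specific:<name>``.
    """

    table: pd.DataFrame

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def population_hierarchy(variant_tables: Mapping[str, Sequence[VariantCall]],
                         report_cut: float = 0.01) -> PopulationLineageTable:
    """Categorise variants as shared vs population-specific across populations.

    ``variant_tables`` maps population name (e.g. pHSC, LSC, blast) to its
    called variants.  Presence = passing heteroplasmic call with VAF above
    ``report_cut``.  Output rows are ordered by the number of populations
    sharing the variant (descending), then position.
    """
    if len(variant_tables) < 2:
        raise ValueError("need at least two populations")
    pops = list(variant_tables)
    per_variant: dict[tuple[int, str], dict] = {}
    for pop, calls in variant_tables.items():
        for c in calls:
            key = (c.position, c.alt_allele)
            rec = per_variant.setdefault(key, {"ref": c.ref_allele, "pops": {}})
            if rec["ref"] != c.ref_allele:
                raise ValueError(
                    f"inconsistent ref alleles at position {c.position}: "
                    f"{rec['ref']} vs {c.ref_allele}")
            present = (c.classification == "heteroplasmic" and c.vaf > report_cut)
            rec["pops"][pop] = {"vaf": c.vaf, "depth": c.depth, "present": present}
    rows = []
    for (pos, alt), rec in per_variant.items():
        present_in = [p for p in pops if rec["pops"].get(p, {}).get("present")]
        if not present_in:
            continue
        if len(present_in) >= 2:
            category = "shared_across_populations"
        else:
            category = f"population_specific:{present_in[0]}"
        row = {"pos": pos, "ref": rec["ref"], "alt": alt,
               "n_populations": len(present_in),
               "populations": ",".join(present_in),
               "category": category}
        for p in pops:
            info = rec["pops"].get(p)
            row[f"vaf_{p}"] = info["vaf"] if info else 0.0
            row[f"depth_{p}"] = info["depth"] if info else 0
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["n_populations", "pos"],
                            ascending=[False, True]).reset_index(drop=True)
    return PopulationLineageTable(df)
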