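"""mtDNA variant calling from stranded pileups and the filter cascade.

Candidate substitutions are enumerated directly from allele counts with a
low frequency floor (0.001, the VarScan-equivalent setting), then pass
through four filters:

1. a fixed blacklist of 13 recurrent misalignment artefacts caused by the
   rCRS homopolymer tracts around 302-315 and 513-525 and by the 'N'
   placeholder at 3107;
2. a strand filter requiring >2 supporting reads on each strand and a
   balanced forward fraction strictly between 30% and 70% (guards against
   strand-specific sequencer errors and oxidative G>T / C>A damage);
3. a VAF classification: >0.9 homoplasmic (germline-like, useful to
   distinguish individuals, not clones), otherwise heteroplasmic;
4. a reporting threshold (1% for bulk samples) below which heteroplasmic
   candidates are not reported.

Filters only accumulate reasons, so the final pass/fail set does not depend
on the order they are applied in.  A sample-level contamination screen flags
libraries with an implausibly large number of heteroplasmies, most of which
match common population variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .pileup import ALLELES, ALLELE_INDEX, PileupMatrix

HETEROPLASMIC = "heteroplasmic"
HOMOPLASMIC = "homoplasmic"
FILTERED = "filtered"

#: Candidate frequency floor (VarScan-equivalent --min-var-freq).
DEFAULT_MIN_VAF = 0.001
#: Bulk reporting threshold for heteroplasmic variants.
DEFAULT_REPORT_CUT = 0.01
#: VAF above which a variant is treated as homoplasmic.
DEFAULT_HOMOPLASMIC_CUT = 0.9


@dataclass(frozen=True)
class VariantCall:
    """One candidate substitution with its strand evidence and fate.

    ``classification`` is ``filtered`` iff ``filter_reasons`` is non-empty;
    ``flags`` carries non-filtering annotations (e.g. the suspect
    (0.9, 1) germline band).
    """

    position: int
    ref_allele: str
    alt_allele: str
    vaf: float
    depth: int
    fwd_alt: int
    rev_alt: int
    classification: str = HETEROPLASMIC
    filter_reasons: frozenset[str] = frozenset()
    flags: frozenset[str] = frozenset()

    @property
    def alt_reads(self) -> int:
        return self.fwd_alt + self.rev_alt

    @property
    def variant_id(self) -> tuple[int, str, str]:
        return (self.position, self.ref_allele, self.alt_allele)

    @property
    def label(self) -> str:
        """Field-style substitution label, e.g. ``A302C``."""
        return f"{self.ref_allele}{self.position}{self.alt_allele}"

    def passes(self) -> bool:
        return not self.filter_reasons


def _with_reason(call: VariantCall, reason: str) -> VariantCall:
    reasons = call.filter_reasons | {reason}
    return replace(call, filter_reasons=reasons, classification=FILTERED)


@dataclass(frozen=True)
class Blacklist:
    """Recurrent false-positive substitutions removed outright.

    Keyed on (position, alt allele); ``position_only`` widens removal to any
    alternate allele at a blacklisted position (the underlying mechanism,
    homopolymer misalignment, is positional).
    """

    sites: frozenset[tuple[int, str]]
    provenance: str = ""
    position_only: bool = False

    def matches(self, position: int, alt: str) -> bool:
        if self.position_only:
            return any(p == position for p, _ in self.sites)
        return (position, alt) in self.sites


# The 13 recurrent artefacts: homopolymer tracts at rCRS 302-315
# (A302C..G316C) and 513-525 (C514A..C524G), plus the 3107 'N' placeholder
# neighbourhood (C3106A, T3109C, C3110A).
DEFAULT_BLACKLIST_LABELS = (
    "A302C", "C309T", "C311T", "C312T", "C313T", "G316C",
    "C514A", "A515G", "A523C", "C524G",
    "C3106A", "T3109C", "C3110A",
)


def _parse_label(label: str) -> tuple[int, str, str]:
    ref, alt = label[0], label[-1]
    return int(label[1:-1]), ref, alt


DEFAULT_BLACKLIST = Blacklist(
    sites=frozenset((pos, alt) for pos, _ref, alt in map(_parse_label, DEFAULT_BLACKLIST_LABELS)),
    provenance="rCRS homopolymer tracts (302-315, 513-525) and 3107N neighbourhood",
)


@dataclass
class ContaminationReport:
    """Sample-level screen for cross-individual contamination.

    A contaminated library shows an excess of heteroplasmic calls, most of
    which coincide with common population variants of another individual.
    """

    n_heteroplasmic: int
    n_overlapping_common: int
    flagged: bool
    threshold_used: int
    overlap_fraction: float | None = None


def call_candidates(p: PileupMatrix,
                    min_vaf: float = DEFAULT_MIN_VAF,
                    min_alt_reads: int = 1) -> list[VariantCall]:
    """Enumerate candidate substitutions above the frequency floor.

    One call per (position, non-reference allele) with
    ``vaf >= min_vaf`` and at least ``min_alt_reads`` supporting reads;
    multi-allelic sites yield multiple calls.  Sites whose reference is 'N'
    are skipped (no substitution is definable there).
    """
    if not (0 < min_vaf <= 1):
        raise ValueError("min_vaf must be in (0, 1]")
    if min_alt_reads < 1:
        raise ValueError("min_alt_reads must be >= 1")
    calls: list[VariantCall] = []
    depths = p.depths
    for i, pos in enumerate(p.positions):
        ref = str(p.refs[i])
        if ref == "N":
            continue
        depth = int(depths[i])
        if depth == 0:
            continue
        for alt in ALLELES:
            if alt == ref:
                continue
            fwd, rev = (int(x) for x in p.counts[i, ALLELE_INDEX[alt]])
            n_alt = fwd + rev
            if n_alt < min_alt_reads:
                continue
            vaf = n_alt / depth
            if vaf >= min_vaf:
                calls.append(VariantCall(int(pos), ref, alt, vaf, depth, fwd, rev))
    return calls


def apply_blacklist(calls: Iterable[VariantCall],
                    blacklist: Blacklist = DEFAULT_BLACKLIST) -> list[VariantCall]:
    """Mark blacklisted (position, alt) candidates as filtered."""
    return [
        _with_reason(c, "blacklist") if blacklist.matches(c.position, c.alt_allele) else c
        for c in calls
    ]


def strand_filter(calls: Iterable[VariantCall],
                  min_per_strand: int = 2,
                  low: float = 0.3,
                  high: float = 0.7) -> list[VariantCall]:
    """Strand-evidence filter.

    A call passes iff ``fwd_alt > min_per_strand`` and
    ``rev_alt > min_per_strand`` and ``low < fwd/(fwd+rev) < high`` (all
    inequalities strict).
    """
    if not (0 <= low < high <= 1):
        raise ValueError("require 0 <= low < high <= 1")
    out = []
    for c in calls:
        total = c.fwd_alt + c.rev_alt
        ok = (
            c.fwd_alt > min_per_strand
            and c.rev_alt > min_per_strand
            and total > 0
            and low < c.fwd_alt / total < high
        )
        out.append(c if ok else _with_reason(c, "strand_imbalance"))
    return out


def classify_vaf(calls: Iterable[VariantCall],
                 homoplasmic_cut: float = DEFAULT_HOMOPLASMIC_CUT,
                 report_cut: float = DEFAULT_REPORT_CUT) -> list[VariantCall]:
    """Split calls into homoplasmic / heteroplasmic and apply the reporting floor.

    ``vaf > homoplasmic_cut`` is homoplasmic (VAF exactly 1 included; calls
    strictly inside (homoplasmic_cut, 1) additionally carry the
    ``homoplasmic_band`` flag, a suspect germline/mapping-bias zone).
    ``vaf <= report_cut`` heteroplasmies are filtered as below threshold.
    """
    if not (0 < report_cut < homoplasmic_cut <= 1):
        raise ValueError("require 0 < report_cut < homoplasmic_cut <= 1")
    out = []
    for c in calls:
        if c.vaf > homoplasmic_cut:
            flags = c.flags | ({"homoplasmic_band"} if c.vaf < 1 else set())
            cls = FILTERED if c.filter_reasons else HOMOPLASMIC
            out.append(replace(c, classification=cls, flags=frozenset(flags)))
        elif c.vaf <= report_cut:
            out.append(_with_reason(c, "below_report_threshold"))
        else:
            out.append(c)
    return out


def contamination_screen(calls: Sequence[VariantCall],
                         common_variants: set[tuple[int, str]] | frozenset[tuple[int, str]],
                         max_het: int = 30,
                         max_overlap_frac: float = 0.5) -> ContaminationReport:
    """Flag a sample whose heteroplasmy load suggests contamination.

    Flags when the number of passing heteroplasmic calls reaches ``max_het``
    or when the fraction of them matching common population variants reaches
    ``max_overlap_frac``.  With an empty common-variant set the overlap
    check is skipped with a warning.
    """
    het = [c for c in calls if c.classification == HETEROPLASMIC]
    n_het = len(het)
    n_common = sum(1 for c in het if (c.position, c.alt_allele) in common_variants)
    frac: float | None = None
    flagged = n_het >= max_het
    if not common_variants:
        warnings.warn("empty common-variant set: overlap check skipped",
                      stacklevel=2)
    elif n_het > 0:
        frac = n_common / n_het
        flagged = flagged or frac >= max_overlap_frac
    return ContaminationReport(n_het, n_common, flagged, max_het, frac)


def call_variants(p: PileupMatrix,
                  min_vaf: float = DEFAULT_MIN_VAF,
                  min_alt_reads: int = 1,
                  blacklist: Blacklist = DEFAULT_BLACKLIST,
                  min_per_strand: int = 2,
                  strand_low: float = 0.3,
                  strand_high: float = 0.7,
                  homoplasmic_cut: float = DEFAULT_HOMOPLASMIC_CUT,
                  report_cut: float = DEFAULT_REPORT_CUT) -> list[VariantCall]:
    """Full cascade: candidates -> blacklist -> strand -> VAF classification."""
    calls = call_candidates(p, min_vaf, min_alt_reads)
    calls = apply_blacklist(calls, blacklist)
    calls = strand_filter(calls, min_per_strand, strand_low, strand_high)
    calls = classify_vaf(calls, homoplasmic_cut, report_cut)
    return calls


# ---------------------------------------------------------------------------
# I/O

VARIANT_COLUMNS = ("pos", "ref", "alt", "vaf", "depth", "fwd_alt", "rev_alt",
                   "class", "filters")


def variants_to_frame(calls: Sequence[VariantCall]) -> pd.DataFrame:
    rows = [
        (c.position, c.ref_allele, c.alt_allele, c.vaf, c.depth,
         c.fwd_alt, c.rev_alt, c.classification,
         ";".join(sorted(c.filter_reasons)) or ".")
        for c in calls
    ]
    return pd.DataFrame(rows, columns=list(VARIANT_COLUMNS))


def write_variant_table(calls: Sequence[VariantCall], path: str | Path) -> None:
    variants_to_frame(calls).to_csv(path, sep="\t", index=False,
                                    float_format="%.6g")


def read_variant_table(path: str | Path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype={"ref": str, "alt": str})
    df = df.rename(columns={"class": "classification"})
    calls = []
    for row in df.itertuples(index=False):
        filters = row.filters
        reasons = frozenset() if (pd.isna(filters) or filters in (".", "")) \
            else frozenset(str(filters).split(";"))
        calls.append(VariantCall(
            int(row.pos), str(row.ref), str(row.alt), float(row.vaf),
            int(row.depth), int(row.fwd_alt), int(row.rev_alt),
            str(row.classification), reasons))
    return calls


def write_vcf(calls: Sequence[VariantCall], path: str | Path,
              contig: str = "chrM", genome_length: int = 16569) -> None:
    """Minimal VCF writer (substitutions only; VAF/strand counts in INFO)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={genome_length}>\n")
        fh.write('##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##INFO=<ID=SB,Number=2,Type=Integer,Description="Alt reads fwd,rev">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (c.position, c.alt_allele)):
            filt = "PASS" if c.passes() else ";".join(sorted(c.filter_reasons))
            info = f"VAF={c.vaf:.6g};DP={c.depth};SB={c.fwd_alt},{c.rev_alt}"
            fh.write(f"{contig}\t{c.position}\t.\t{c.ref_allele}\t{c.alt_allele}"
                     f"\t.\t{filt}\t{info}\n")


def read_common_variants(path: str | Path) -> set[tuple[int, str]]:
    """Load a common-population-variant list as {(position, alt)}.

    Accepts a VCF (parsed with cyvcf2; multi-allelic records expanded) or a
    two-column position/alt TSV.
    """
    path = Path(path)
    if path.suffix in (".vcf", ".gz", ".bcf") or path.name.endswith(".vcf.gz"):
        from cyvcf2 import VCF
        out: set[tuple[int, str]] = set()
        for rec in VCF(str(path)):
            for alt in rec.ALT:
                if len(alt) == 1 and len(rec.REF) == 1:  # substitutions only
                    out.add((rec.POS, alt))
        return out
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["pos", "alt"], dtype={"alt": str})
    return {(int(r.pos), str(r.alt)) for r in df.itertuples(index=False)}
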