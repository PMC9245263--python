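"""RNA-editing site identification in organelle protein-coding genes.

Reads (RNA-seq for editing, WGS for DNA-level variants) are aligned to the
spliced coding sequences; per-column base compositions form the pileup.
A site is called as edited when coverage reaches the organelle-specific
minimum (20x for plastid genes, 10x for the low-copy, lower-expressed
mitochondrial genes), the most frequent non-reference base reaches 10% of
the depth, and the position is not a DNA-level SNP in the WGS pileup.
Editing efficiency is the edited-base count over total depth; labels report
RNA T as U ("C to U").
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import edlib
import pandas as pd

from .core import revcomp

BASES = "ACGT"
#: the 12 ordered edit types (DNA alphabet, reported with T as U)
EDIT_TYPES = [(a, b) for a in BASES for b in BASES if a != b]


def type_label(ref: str, alt: str) -> str:
    show = {"T": "U"}
    return f"{show.get(ref, ref)} to {show.get(alt, alt)}"


@dataclass
class PileupColumn:
    gene: str
    cds_pos: int  # 1-based position in the spliced CDS
    ref_base: str
    counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class CallThresholds:
    min_cov_plastid: int = 20
    min_cov_mito: int = 10
    min_support: float = 0.10

    def min_cov(self, organelle: str) -> int:
        if organelle not in ("mito", "plastid"):
            raise ValueError(f"unknown organelle {organelle!r}")
        return self.min_cov_plastid if organelle == "plastid" else self.min_cov_mito


@dataclass
class EditingSite:
    gene: str
    cds_pos: int
    ref_base: str
    edited_base: str
    edit_type: str
    efficiency: float
    depth: int
    codon_pos: int
    snp_excluded: bool = False
    ambiguous: bool = False
    tied_bases: Optional[tuple[str, str]] = None


def pileup_cds(
    reads: Iterable[tuple[str, str]],
    cds: dict[str, str],
    max_divergence: float = 0.25,
) -> list[PileupColumn]:
    """Pileup of reads against spliced CDS sequences.

    Each read is assigned to its best-aligning CDS (edit distance over both
    orientations); ties go to the lexicographically smaller gene id.  Read
    bases at insertion columns are skipped; deleted columns contribute no
    count.  Reads more divergent than ``max_divergence`` from every CDS are
    dropped.
    """
    genes = sorted(cds)
    counts: dict[str, list[dict[str, int]]] = {
        g: [{b: 0 for b in BASES} for _ in cds[g]] for g in genes
    }
    for _rid, seq in reads:
        best = None  # (dist, gene, oriented)
        for g in genes:
            target = cds[g]
            k = int(max_divergence * max(len(seq), len(target)))
            for oriented in (seq, revcomp(seq)):
                res = edlib.align(oriented, target, mode="HW", k=k)
                d = res["editDistance"]
                if d >= 0 and (best is None or d < best[0]):
                    best = (d, g, oriented)
        if best is None:
            continue
        _d, g, oriented = best
        res = edlib.align(oriented, cds[g], mode="HW", task="path")
        tpos = res["locations"][0][0]
        qpos = 0
        col = counts[g]
        for num, op in re.findall(r"(\d+)([=XID])", res["cigar"]):
            num = int(num)
            if op in ("=", "X"):
                for _ in range(num):
                    base = oriented[qpos]
                    if base in col[tpos]:
                        col[tpos][base] += 1
                    tpos += 1
                    qpos += 1
            elif op == "I":  # read base absent from CDS: skip
                qpos += num
            elif op == "D":  # CDS base absent from read: no count
                tpos += num
    out = []
    for g in genes:
        for i, c in enumerate(counts[g]):
            out.append(PileupColumn(gene=g, cds_pos=i + 1, ref_base=cds[g][i], counts=c))
    return out


def pileup_from_sam(path, cds: dict[str, str]) -> list[PileupColumn]:
    """Pileup built from pre-computed alignments in a SAM file whose
    references are the spliced CDS sequences."""
    from .io import read_sam

    counts: dict[str, list[dict[str, int]]] = {
        g: [{b: 0 for b in BASES} for _ in cds[g]] for g in sorted(cds)
    }
    for _rid, ref, tpos, cig, seq in read_sam(path):
        if ref not in counts or seq is None:
            continue
        col = counts[ref]
        qpos = 0
        for op, num in cig:
            if op in (0, 7, 8):  # M/=/X
                for _ in range(num):
                    if tpos < len(col) and seq[qpos] in col[tpos]:
                        col[tpos][seq[qpos]] += 1
                    tpos += 1
                    qpos += 1
            elif op in (1, 4):  # I/S consume query
                qpos += num
            elif op in (2, 3):  # D/N consume reference
                tpos += num
    out = []
    for g in sorted(cds):
        for i, c in enumerate(counts[g]):
            out.append(PileupColumn(gene=g, cds_pos=i + 1, ref_base=cds[g][i], counts=c))
    return out


def call_snps(
    wgs_pileup: list[PileupColumn],
    organelle_of_gene: dict[str, str] | str = "mito",
    thresholds: Optional[CallThresholds] = None,
) -> set[tuple[str, int, str]]:
    """DNA-level variants from the WGS pileup: positions whose most frequent
    non-reference base reaches the support fraction at sufficient coverage."""
    thresholds = thresholds or CallThresholds()
    snps = set()
    for col in wgs_pileup:
        org = organelle_of_gene if isinstance(organelle_of_gene, str) else organelle_of_gene.get(col.gene, "mito")
        if col.depth < thresholds.min_cov(org):
            continue
        alts = {b: n for b, n in col.counts.items() if b != col.ref_base}
        if not alts:
            continue
        alt = max(alts, key=lambda b: (alts[b], b))
        if alts[alt] / col.depth >= thresholds.min_support:
            snps.add((col.gene, col.cds_pos, alt))
    return snps


def call_editing_sites(
    rna_pileup: list[PileupColumn],
    snps: set[tuple[str, int, str]],
    organelle: str = "mito",
    thresholds: Optional[CallThresholds] = None,
) -> list[EditingSite]:
    """Editing sites from the RNA pileup with SNP positions excluded.

    Ties between two non-reference bases are reported once with both
    candidates flagged ambiguous; ambiguous sites are skipped by the type
    summaries.
    """
    thresholds = thresholds or CallThresholds()
    min_cov = thresholds.min_cov(organelle)
    snp_positions = {(g, p) for g, p, _ in snps}
    sites = []
    for col in rna_pileup:
        if col.depth < min_cov:
            continue
        alts = {b: n for b, n in col.counts.items() if b != col.ref_base and n > 0}
        if not alts:
            continue
        top = max(alts.values())
        if top / col.depth < thresholds.min_support:
            continue
        if (col.gene, col.cds_pos) in snp_positions:
            continue
        winners = sorted(b for b, n in alts.items() if n == top)
        ambiguous = len(winners) > 1
        edited = winners[0]
        sites.append(
            EditingSite(
                gene=col.gene,
                cds_pos=col.cds_pos,
                ref_base=col.ref_base,
                edited_base=edited,
                edit_type=type_label(col.ref_base, edited),
                efficiency=top / col.depth,
                depth=col.depth,
                codon_pos=(col.cds_pos - 1) % 3 + 1,
                ambiguous=ambiguous,
                tied_bases=tuple(winners[:2]) if ambiguous else None,
            )
        )
    return sites


#: efficiency histogram bin edges (right-closed last bin)
EFFICIENCY_BINS = [(0.0, 0.5), (0.5, 0.8), (0.8, 0.9), (0.9, 1.0)]


@dataclass
class EditingSummary:
    n_sites: int
    per_gene: dict[str, int]
    per_type: dict[str, int]
    histogram: list[int]  # counts per EFFICIENCY_BINS, low to high
    pct_above_90: float  # percent of sites in the top bin, 2 decimals
    n_ambiguous: int = 0


def summarize_editing(sites: list[EditingSite]) -> EditingSummary:
    """Per-gene and per-type counts plus the efficiency histogram.

    Ambiguous (tied) sites count toward gene totals and the histogram but
    not toward any of the 12 type totals.
    """
    per_gene: dict[str, int] = {}
    per_type = {type_label(a, b): 0 for a, b in EDIT_TYPES}
    hist = [0] * len(EFFICIENCY_BINS)
    n_amb = 0
    for s in sites:
        per_gene[s.gene] = per_gene.get(s.gene, 0) + 1
        if s.ambiguous:
            n_amb += 1
        else:
            per_type[s.edit_type] += 1
        for k, (lo, hi) in enumerate(EFFICIENCY_BINS):
            last = k == len(EFFICIENCY_BINS) - 1
            if (lo <= s.efficiency < hi) or (last and lo <= s.efficiency <= hi):
                hist[k] += 1
                break
    n = len(sites)
    pct = round(100.0 * hist[-1] / n, 2) if n else 0.0
    return EditingSummary(
        n_sites=n,
        per_gene=per_gene,
        per_type=per_type,
        histogram=hist,
        pct_above_90=pct,
        n_ambiguous=n_amb,
    )


def sites_table(sites: list[EditingSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": s.gene,
                "cds_pos": s.cds_pos,
                "ref": s.ref_base,
                "edited": s.edited_base,
                "type": s.edit_type,
                "efficiency": round(s.efficiency, 4),
                "depth": s.depth,
                "codon_pos": s.codon_pos,
                "ambiguous": s.ambiguous,
            }
            for s in sites
        ]
    )


def summary_tables(summary: EditingSummary) -> dict[str, pd.DataFrame]:
    per_gene = pd.DataFrame(
        sorted(summary.per_gene.items()), columns=["gene", "n_sites"]
    )
    per_type = pd.DataFrame(
        [(t, n) for t, n in summary.per_type.items()], columns=["type", "n_sites"]
    )
    hist = pd.DataFrame(
        [
            {"bin_low": lo, "bin_high": hi, "n_sites": c}
            for (lo, hi), c in zip(EFFICIENCY_BINS, summary.histogram)
        ]
    )
    return {"per_gene": per_gene, "per_type": per_type, "histogram": hist}
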