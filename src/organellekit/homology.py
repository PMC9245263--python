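"""Plastid-mitochondrion homologous segment (MTPT) detection and summary.

The plastid genome is searched against each mitochondrial molecule with the
local aligner; hits are ranked by aligned length, labelled mtpt1.., binned by
identity, and annotated with the plastid genes they contain.  Direction of
transfer is deliberately not inferred: hits are reported as homologous
segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .align import AlignmentParams, LocalAlignment, local_align
from .core import Feature, GenomeMolecule


def similarity_class(identity: float) -> str:
    """Identity bins used for hit colouring: exact, >=90%, >=80%, <80%."""
    if identity >= 1.0:
        return "eq100"
    if identity >= 0.9:
        return "ge90lt100"
    if identity >= 0.8:
        return "ge80lt90"
    return "lt80"


@dataclass
class MtptHit:
    id: str
    aligned_length: int
    mt_molecule: str
    mt_start: int  # 0-based half-open on the mt molecule
    mt_end: int
    cp_start: int  # 0-based half-open on the plastid molecule
    cp_end: int
    strand: str
    n_mismatches: int
    n_gaps: int
    identity: float
    contained_genes: list[tuple[str, str]] = field(default_factory=list)

    @property
    def similarity_class(self) -> str:
        return similarity_class(self.identity)


def find_mtpts(
    cp: GenomeMolecule,
    mt_molecules: list[GenomeMolecule],
    params: Optional[AlignmentParams] = None,
) -> list[MtptHit]:
    """Homologous segments between the plastid genome and each mt molecule.

    Hits are sorted by aligned length (descending, ties by coordinates) and
    assigned global ids mtpt1.. across molecules.
    """
    params = params or AlignmentParams()
    raw: list[tuple[str, LocalAlignment]] = []
    for mt in mt_molecules:
        for aln in local_align(cp.sequence, mt.sequence, params):
            raw.append((mt.id, aln))
    raw.sort(key=lambda t: (-t[1].length, t[0], t[1].s_start, t[1].q_start))
    hits = []
    for i, (mol, a) in enumerate(raw, 1):
        hits.append(
            MtptHit(
                id=f"mtpt{i}",
                aligned_length=a.length,
                mt_molecule=mol,
                mt_start=a.s_start,
                mt_end=a.s_end,
                cp_start=a.q_start,
                cp_end=a.q_end,
                strand=a.strand,
                n_mismatches=a.n_mismatch,
                n_gaps=a.n_gap,
                identity=a.identity,
            )
        )
    return hits


def annotate_mtpt(hit: MtptHit, cp_features: list[Feature]) -> list[tuple[str, str]]:
    """Plastid genes contained in the hit's plastid interval.

    A gene is 'complete' iff its full annotated span lies within the hit;
    any partial overlap yields 'fragment'; zero overlap is omitted.  The
    result is stored on the hit and returned.
    """
    out = []
    for f in cp_features:
        ov = min(hit.cp_end, f.end) - max(hit.cp_start, f.start)
        if ov <= 0:
            continue
        if hit.cp_start <= f.start and f.end <= hit.cp_end:
            out.append((f.gene, "complete"))
        else:
            out.append((f.gene, "fragment"))
    hit.contained_genes = out
    return out


def union_length(intervals: list[tuple[int, int]]) -> int:
    """Total bp covered by a set of possibly overlapping intervals."""
    total = 0
    end = -1
    for a, b in sorted(intervals):
        if a > end:
            total += b - a
            end = b
        elif b > end:
            total += b - end
            end = b
    return total


def _intersect_bp(intervals: list[tuple[int, int]], regions: list[tuple[int, int]]) -> int:
    """bp of the union of ``intervals`` that falls inside ``regions``."""
    clipped = []
    for a, b in intervals:
        for ra, rb in regions:
            lo, hi = max(a, ra), min(b, rb)
            if hi > lo:
                clipped.append((lo, hi))
    return union_length(clipped)


@dataclass
class HomologySummary:
    n_hits: int
    total_cp_bp: int
    total_mt_bp: int
    cp_fraction: float  # percent of the plastid genome
    mt_fraction: float  # percent of the summed mt genome
    repeat_region_cp_bp: int
    repeat_region_mt_bp: int
    raw_cp_bp: int  # summed hit lengths, overlaps double-counted
    raw_mt_bp: int


def summarize_homology(
    hits: list[MtptHit],
    cp: GenomeMolecule,
    mt_molecules: list[GenomeMolecule],
    cp_repeat_regions: Optional[list[tuple[int, int]]] = None,
    mt_repeat_regions: Optional[dict[str, list[tuple[int, int]]]] = None,
) -> HomologySummary:
    """Genome-coverage summary of a hit set.

    Coverage is the union of hit intervals per genome (overlaps counted
    once); raw summed lengths are reported alongside because duplicated
    regions (e.g. the plastid IR) legitimately attract two hits.
    """
    cp_iv = [(h.cp_start, h.cp_end) for h in hits]
    mt_iv_by_mol: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        mt_iv_by_mol.setdefault(h.mt_molecule, []).append((h.mt_start, h.mt_end))
    cp_bp = union_length(cp_iv)
    mt_bp = sum(union_length(iv) for iv in mt_iv_by_mol.values())
    mt_total_len = sum(len(m) for m in mt_molecules)
    rep_cp = _intersect_bp(cp_iv, cp_repeat_regions or [])
    rep_mt = 0
    if mt_repeat_regions:
        for mol, iv in mt_iv_by_mol.items():
            rep_mt += _intersect_bp(iv, mt_repeat_regions.get(mol, []))
    return HomologySummary(
        n_hits=len(hits),
        total_cp_bp=cp_bp,
        total_mt_bp=mt_bp,
        cp_fraction=round(100.0 * cp_bp / len(cp), 2),
        mt_fraction=round(100.0 * mt_bp / mt_total_len, 2) if mt_total_len else 0.0,
        repeat_region_cp_bp=rep_cp,
        repeat_region_mt_bp=rep_mt,
        raw_cp_bp=sum(b - a for a, b in cp_iv),
        raw_mt_bp=sum(b - a for a, b in sum(mt_iv_by_mol.values(), [])) if mt_iv_by_mol else 0,
    )


def hits_table(hits: list[MtptHit]) -> pd.DataFrame:
    """Table of hits in reporting coordinates (1-based inclusive; the mt
    interval descends for '-'-strand hits)."""
    rows = []
    for h in hits:
        if h.strand == "+":
            mt_a, mt_b = h.mt_start + 1, h.mt_end
        else:
            mt_a, mt_b = h.mt_end, h.mt_start + 1
        rows.append(
            {
                "fragment": h.id,
                "aligned_length": h.aligned_length,
                "mt_molecule": h.mt_molecule,
                "mt_start": mt_a,
                "mt_end": mt_b,
                "cp_start": h.cp_start + 1,
                "cp_end": h.cp_end,
                "identity": round(h.identity, 4),
                "mismatches": h.n_mismatches,
                "gaps": h.n_gaps,
                "similarity_class": h.similarity_class,
                "contained_genes": "; ".join(
                    g + ("-fra" if kind == "fragment" else "") for g, kind in h.contained_genes
                ),
            }
        )
    return pd.DataFrame(rows)


def hits_bed(hits: list[MtptHit], genome: str) -> str:
    """BED intervals of hits on one genome ('cp' or a mt molecule id)."""
    lines = []
    for h in hits:
        if genome == "cp":
            lines.append(f"cp\t{h.cp_start}\t{h.cp_end}\t{h.id}")
        elif h.mt_molecule == genome:
            lines.append(f"{h.mt_molecule}\t{h.mt_start}\t{h.mt_end}\t{h.id}")
    return "\n".join(lines) + ("\n" if lines else "")
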