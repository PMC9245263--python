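"""Repeat-mediated recombination analysis from long reads.

For each repeat pair, four local reference paths are constructed: m1 and m2
reproduce the assembled (major) arrangement around each repeat copy, while
s1 and s2 are the two crossover (alternative) products.  Each path is the
repeat unit plus a flank (default 1 kb) on both sides, so a read must fully
span repeat and flanks to be informative.  Long reads are aligned to the
four paths in both orientations; a read supports a conformation class only
if it covers the full repeat plus both full flanks at sufficient identity.
Reads whose best major-path and alternative-path identities are nearly tied
are set aside as ambiguous.  Per-repeat support takes, within each class,
the path with the larger read count, and percentages are rounded half-up to
two decimals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import edlib
import pandas as pd

from .core import GenomeMolecule, RepeatPair, revcomp

PATH_NAMES = ("m1", "m2", "s1", "s2")


@dataclass
class FlankInfo:
    requested: int
    length: int
    truncated: bool


@dataclass
class ConformationSet:
    """The four reference paths around one repeat, with provenance."""

    repeat_id: str
    flank: int
    repeat_length: int
    paths: dict[str, str]
    # per path: (upstream FlankInfo, downstream FlankInfo)
    flank_info: dict[str, tuple[FlankInfo, FlankInfo]]
    overlap_warning: bool = False

    def segment_bounds(self, path: str) -> tuple[int, int]:
        """(repeat start, repeat end) within the path string."""
        up, _down = self.flank_info[path]
        return up.length, up.length + self.repeat_length


def _flank_seq(mol: GenomeMolecule, pos: int, flank: int, upstream: bool) -> tuple[str, FlankInfo]:
    """Flank of up to ``flank`` bp adjacent to ``pos``; circular molecules
    wrap, linear molecules truncate (flagged)."""
    n = len(mol)
    if mol.topology == "circular":
        if upstream:
            return mol.fetch(pos - flank, pos), FlankInfo(flank, flank, False)
        return mol.fetch(pos, pos + flank), FlankInfo(flank, flank, False)
    if upstream:
        a = max(0, pos - flank)
        seq = mol.sequence[a:pos]
    else:
        b = min(n, pos + flank)
        seq = mol.sequence[pos:b]
    return seq, FlankInfo(flank, len(seq), len(seq) < flank)


def build_conformations(
    molecules: list[GenomeMolecule], repeat: RepeatPair, flank: int = 1000
) -> ConformationSet:
    """Construct m1/m2/s1/s2 around a repeat.

    With copy A flanks (A_up, A_down) and copy B flanks (B_up, B_down):
    m1 = A_up R A_down, m2 = B_up R B_down, s1 = A_up R B_down,
    s2 = B_up R A_down.  For an inverted copy B the molecule is read on its
    reverse strand, so B_up = revcomp(downstream of B) and
    B_down = revcomp(upstream of B); every path is then a valid linear DNA
    sequence containing R in forward orientation.
    """
    by_id = {m.id: m for m in molecules}
    c1, c2 = repeat.copy1, repeat.copy2
    for c in (c1, c2):
        if c.molecule not in by_id:
            raise ValueError(f"molecule {c.molecule} not supplied")
        mol = by_id[c.molecule]
        if mol.topology == "linear" and (c.start < 0 or c.end > len(mol)):
            raise ValueError(f"repeat copy outside molecule {c.molecule}")
    mol1, mol2 = by_id[c1.molecule], by_id[c2.molecule]
    R = mol1.fetch(c1.start, c1.end)

    a_up, a_up_i = _flank_seq(mol1, c1.start, flank, upstream=True)
    a_dn, a_dn_i = _flank_seq(mol1, c1.end, flank, upstream=False)
    if c2.orientation == "forward":
        b_up, b_up_i = _flank_seq(mol2, c2.start, flank, upstream=True)
        b_dn, b_dn_i = _flank_seq(mol2, c2.end, flank, upstream=False)
    else:
        # copy B holds revcomp(R); view molecule 2 on its reverse strand
        raw_dn, b_up_i = _flank_seq(mol2, c2.end, flank, upstream=False)
        raw_up, b_dn_i = _flank_seq(mol2, c2.start, flank, upstream=True)
        b_up, b_dn = revcomp(raw_dn), revcomp(raw_up)

    overlap = False
    if c1.molecule == c2.molecule:
        gap = min(abs(c2.start - c1.end), abs(c1.start - c2.end))
        if gap < flank:
            overlap = True

    paths = {
        "m1": a_up + R + a_dn,
        "m2": b_up + R + b_dn,
        "s1": a_up + R + b_dn,
        "s2": b_up + R + a_dn,
    }
    flank_info = {
        "m1": (a_up_i, a_dn_i),
        "m2": (b_up_i, b_dn_i),
        "s1": (a_up_i, b_dn_i),
        "s2": (b_up_i, a_dn_i),
    }
    return ConformationSet(
        repeat_id=repeat.id or "repeat",
        flank=flank,
        repeat_length=repeat.length,
        paths=paths,
        flank_info=flank_info,
        overlap_warning=overlap,
    )


@dataclass
class ReadSupportCall:
    read_id: str
    repeat_id: str
    label: str  # major | alternative | ambiguous | none
    best_path: str  # m1 | m2 | s1 | s2 | none
    identity: Optional[float]
    spans: bool


def _segment_identities(path: str, read: str, bounds: tuple[int, int]) -> Optional[tuple[float, list[float]]]:
    """Align the full path into the read (infix); return overall identity and
    identities of the three path segments (upstream flank, repeat, downstream
    flank), or None if no alignment exists."""
    res = edlib.align(path, read, mode="HW", task="path")
    if res["editDistance"] < 0:
        return None
    overall = 1.0 - res["editDistance"] / len(path)
    seg_edges = [0, bounds[0], bounds[1], len(path)]
    seg_err = [0, 0, 0]
    qpos = 0
    for num, op in re.findall(r"(\d+)([=XID])", res["cigar"]):
        num = int(num)
        if op == "=":
            qpos += num
        elif op in ("X", "I"):
            # I consumes query (path) without read: count per path position
            for _ in range(num):
                seg = 0 if qpos < seg_edges[1] else (1 if qpos < seg_edges[2] else 2)
                seg_err[seg] += 1
                qpos += 1
        elif op == "D":
            # read insertion relative to path: attribute to current segment
            seg = 0 if qpos < seg_edges[1] else (1 if qpos < seg_edges[2] else 2)
            seg_err[seg] += num
    lens = [seg_edges[1], seg_edges[2] - seg_edges[1], len(path) - seg_edges[2]]
    seg_ident = [1.0 - e / L if L > 0 else 1.0 for e, L in zip(seg_err, lens)]
    return overall, seg_ident


def classify_spanning_read(
    read: tuple[str, str] | str,
    cs: ConformationSet,
    min_identity: float = 0.85,
    ambiguity_margin: float = 0.02,
) -> ReadSupportCall:
    """Classify one long read against the four conformation paths.

    A path is supported only when the whole path (repeat plus both full
    flanks) aligns within the read and each of the three segments reaches
    ``min_identity``.  The label is major/alternative when exactly one class
    is supported, ambiguous when both classes are supported with best
    identities within ``ambiguity_margin``, none otherwise.
    """
    if isinstance(read, tuple):
        read_id, seq = read
    else:
        read_id, seq = "read", read
    if not seq:
        raise ValueError("empty read")
    rc = revcomp(seq)
    best: dict[str, float] = {}
    for name in PATH_NAMES:
        path = cs.paths[name]
        bounds = cs.segment_bounds(name)
        max_edits = int((1 - min_identity) * len(path))
        cand = []
        for oriented in (seq, rc):
            if len(oriented) < len(path) - max_edits:
                continue
            # cheap distance-only screen before the full alignment path
            if edlib.align(path, oriented, mode="HW", k=max_edits)["editDistance"] < 0:
                continue
            got = _segment_identities(path, oriented, bounds)
            if got is None:
                continue
            overall, seg_ident = got
            if min(seg_ident) >= min_identity and overall >= min_identity:
                cand.append(overall)
        if cand:
            best[name] = max(cand)

    if not best:
        return ReadSupportCall(read_id, cs.repeat_id, "none", "none", None, False)
    best_m = max((best.get(p, -1.0) for p in ("m1", "m2")), default=-1.0)
    best_s = max((best.get(p, -1.0) for p in ("s1", "s2")), default=-1.0)
    best_path = max(best, key=lambda k: (best[k], k))
    identity = best[best_path]
    if best_m >= 0 and best_s >= 0 and abs(best_m - best_s) < ambiguity_margin:
        return ReadSupportCall(read_id, cs.repeat_id, "ambiguous", best_path, identity, True)
    label = "major" if best_m > best_s else "alternative"
    return ReadSupportCall(read_id, cs.repeat_id, label, best_path, identity, True)


def _round2(x: float) -> float:
    return float(Decimal(str(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class RecombinationSupport:
    repeat_id: str
    n_major: int
    n_alternative: int
    n_ambiguous: int
    pct_major: Optional[float]
    pct_alternative: Optional[float]
    active: bool
    path_counts: dict[str, int] = field(default_factory=dict)


def quantify_recombination(calls: list[ReadSupportCall], repeat_id: str) -> RecombinationSupport:
    """Per-repeat support counts and percentages.

    Within each conformation class, the two paths are collapsed by taking
    the path with the larger read count; ambiguous reads are excluded from
    both counts and from the denominator.
    """
    if any(c.repeat_id != repeat_id for c in calls):
        raise ValueError("calls for a different repeat supplied")
    counts = {p: 0 for p in PATH_NAMES}
    n_amb = 0
    for c in calls:
        if c.label == "ambiguous":
            n_amb += 1
        elif c.label in ("major", "alternative"):
            counts[c.best_path] += 1
    n_major = max(counts["m1"], counts["m2"])
    n_alt = max(counts["s1"], counts["s2"])
    total = n_major + n_alt
    if total == 0:
        return RecombinationSupport(repeat_id, 0, 0, n_amb, None, None, False, counts)
    pct_major = _round2(100.0 * n_major / total)
    pct_alt = _round2(100.0 * n_alt / total)
    return RecombinationSupport(
        repeat_id, n_major, n_alt, n_amb, pct_major, pct_alt, n_alt > 0, counts
    )


def support_from_counts(repeat_id: str, n_major: int, n_alternative: int) -> RecombinationSupport:
    """Support record computed directly from per-class read counts (the two
    within-class path maxima already taken)."""
    calls = [
        ReadSupportCall(f"m{i}", repeat_id, "major", "m1", 1.0, True) for i in range(n_major)
    ] + [
        ReadSupportCall(f"s{i}", repeat_id, "alternative", "s1", 1.0, True)
        for i in range(n_alternative)
    ]
    return quantify_recombination(calls, repeat_id)


def support_table(supports: list[RecombinationSupport], repeats: list[RepeatPair]) -> pd.DataFrame:
    """Support table in the reporting layout: repeat, length, the two copy
    locations (1-based, descending = reverse), and counts with percentages."""
    from .io import interval_to_table

    by_id = {r.id: r for r in repeats}
    rows = []
    for s in supports:
        r = by_id.get(s.repeat_id)
        loc1 = loc2 = ""
        length = None
        if r is not None:
            a = interval_to_table(r.copy1.start, r.copy1.end, r.copy1.orientation)
            b = interval_to_table(r.copy2.start, r.copy2.end, r.copy2.orientation)
            loc1 = f"{r.copy1.molecule}: {a[0]}-{a[1]}"
            loc2 = f"{r.copy2.molecule}: {b[0]}-{b[1]}"
            length = r.length
        pm = "NA" if s.pct_major is None else f"{s.pct_major:.2f}%"
        pa = "NA" if s.pct_alternative is None else f"{s.pct_alternative:.2f}%"
        rows.append(
            {
                "repeat": s.repeat_id,
                "length_bp": length,
                "location_copy1": loc1,
                "location_copy2": loc2,
                "reads_major": f"{s.n_major} ({pm})",
                "reads_alternative": f"{s.n_alternative} ({pa})",
                "ambiguous": s.n_ambiguous,
                "active": s.active,
            }
        )
    return pd.DataFrame(rows)


def verify_mtpt_integration(
    reads: list[tuple[str, str]],
    molecules: list[GenomeMolecule],
    mt_molecule: str,
    mtpt_start: int,
    mtpt_end: int,
    flank: int = 1000,
    min_identity: float = 0.85,
) -> tuple[bool, int]:
    """Long-read verification that an MTPT is integrated in mtDNA.

    Counts reads that align across the whole MTPT plus at least ``flank`` bp
    of flanking (mitochondrial) sequence on both sides at ``min_identity``
    per segment.  At a linear molecule end the available flank is used and
    the check becomes one-sided on that side.  Returns (verified, count).
    """
    by_id = {m.id: m for m in molecules}
    if mt_molecule not in by_id:
        raise ValueError(f"molecule {mt_molecule} not supplied")
    mol = by_id[mt_molecule]
    up, up_i = _flank_seq(mol, mtpt_start, flank, upstream=True)
    dn, dn_i = _flank_seq(mol, mtpt_end, flank, upstream=False)
    probe = up + mol.fetch(mtpt_start, mtpt_end) + dn
    bounds = (up_i.length, up_i.length + (mtpt_end - mtpt_start))
    n = 0
    for rid, seq in reads:
        for oriented in (seq, revcomp(seq)):
            got = _segment_identities(probe, oriented, bounds)
            if got is None:
                continue
            overall, seg_ident = got
            if min(seg_ident) >= min_identity and overall >= min_identity:
                n += 1
                break
    return n >= 1, n
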