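"""Repeat discovery in organelle genomes.

Finds maximal repeated segment pairs — direct and inverted, within one
molecule and across molecules — by common k-mer anchoring followed by
maximal exact extension.  Circular molecules are searched across the origin
by doubling the sequence and discarding hits that live entirely in the
second copy.  Near-exact mode re-scores candidate pairs by edit distance and
keeps those at or above an identity floor.

Pairs are reported with both copies in forward coordinates; an inverted pair
carries ``orientation='reverse'`` on copy2.
"""

from __future__ import annotations

from dataclasses import replace

import edlib

from .core import GenomeMolecule, Placement, RepeatPair, revcomp

ANCHOR_K = 21  # seed k-mer size; repeats >= min_len always contain one


def _search_seq(mol: GenomeMolecule) -> tuple[str, int]:
    """Sequence actually scanned (doubled for circular) and true length."""
    if mol.topology == "circular":
        return mol.sequence + mol.sequence, len(mol.sequence)
    return mol.sequence, len(mol.sequence)


def _extend_direct(s1: str, s2: str, i: int, j: int, k: int) -> tuple[int, int, int]:
    """Maximal exact extension of s1[i:i+k] == s2[j:j+k]; returns (i0, j0, L)."""
    a, b = i, j
    while a > 0 and b > 0 and s1[a - 1] == s2[b - 1]:
        a -= 1
        b -= 1
    e1, e2 = i + k, j + k
    n1, n2 = len(s1), len(s2)
    while e1 < n1 and e2 < n2 and s1[e1] == s2[e2]:
        e1 += 1
        e2 += 1
    return a, b, e1 - a


def _extend_inverted(s1: str, s2: str, i: int, j: int, k: int) -> tuple[int, int, int]:
    """Maximal extension where s2[j:j+k] == revcomp(s1[i:i+k]).

    Extending copy1 rightwards extends copy2 leftwards.  Returns
    (i0, j0, L) with s2[j0:j0+L] == revcomp(s1[i0:i0+L]).
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    a, e2 = i, j + k
    n1, n2 = len(s1), len(s2)
    while a > 0 and e2 < n2 and s2[e2] == comp.get(s1[a - 1], "?"):
        a -= 1
        e2 += 1
    e1, b = i + k, j
    while e1 < n1 and b > 0 and s2[b - 1] == comp.get(s1[e1], "?"):
        e1 += 1
        b -= 1
    return a, b, e1 - a


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for p in range(len(seq) - k + 1):
        w = seq[p : p + k]
        idx.setdefault(w, []).append(p)
    return idx


def _norm_pair(m1: str, a: int, m2: str, b: int, length: int, inverted: bool,
               n1: int, n2: int) -> tuple | None:
    """Canonicalise a raw hit from (possibly doubled) search coordinates.

    Returns a hashable tuple key or None when the hit is a doubling artifact
    (entirely inside the second copy, or the trivial self-match of a circular
    molecule against its own shifted image).
    """
    # discard hits living entirely in the second copy of a doubled sequence
    if a >= n1 or b >= n2:
        return None
    if m1 == m2:
        if not inverted and abs(a - b) in (0, n1):
            return None  # self-match / whole-circle shift artifact
        # order copies by start for a canonical representation
        if b < a:
            a, b = b, a
    if length > min(n1, n2):
        return None
    return (m1, a, m2, b, length, inverted)


def find_repeats(
    molecules: list[GenomeMolecule],
    min_len: int = 100,
    mode: str = "exact",
    min_identity: float = 0.9,
) -> list[RepeatPair]:
    """Find maximal repeat pairs of length >= min_len across all molecules.

    exact mode reports identity-1.0 maximal exact pairs; near-exact mode
    additionally merges nearby co-diagonal exact pairs and re-scores them by
    edit-distance identity, keeping pairs at >= ``min_identity``.
    """
    if not molecules:
        raise ValueError("empty molecule list")
    if min_len < 20:
        raise ValueError("min_len must be >= 20")
    k = min(ANCHOR_K, min_len)
    # near-exact pairs are chained from short exact fragments, so collect
    # every maximal fragment down to the anchor size in that mode
    collect_len = min_len if mode == "exact" else k

    seqs = {m.id: _search_seq(m) for m in molecules}
    idx = {mid: _kmer_index(s, k) for mid, (s, _n) in seqs.items()}

    found: set[tuple] = set()
    mol_ids = [m.id for m in molecules]
    for ai in range(len(mol_ids)):
        for bi in range(ai, len(mol_ids)):
            ma, mb = mol_ids[ai], mol_ids[bi]
            s1, n1 = seqs[ma]
            s2, n2 = seqs[mb]
            same = ma == mb
            # direct repeats
            done_diag: dict[int, list[tuple[int, int]]] = {}
            for w, ps1 in idx[ma].items():
                ps2 = idx[mb].get(w)
                if not ps2:
                    continue
                for i in ps1:
                    for j in ps2:
                        if same and j <= i:
                            continue
                        d = j - i
                        if any(lo <= i < hi for lo, hi in done_diag.get(d, ())):
                            continue
                        a, b, L = _extend_direct(s1, s2, i, j, k)
                        done_diag.setdefault(d, []).append((a, a + L))
                        if L >= collect_len:
                            key = _norm_pair(ma, a, mb, b, L, False, n1, n2)
                            if key:
                                found.add(key)
            # inverted repeats: match k-mers of s1 against revcomp k-mers of s2
            done_anti: dict[int, list[tuple[int, int]]] = {}
            for w, ps1 in idx[ma].items():
                ps2 = idx[mb].get(revcomp(w))
                if not ps2:
                    continue
                for i in ps1:
                    for j in ps2:
                        if same and j < i:
                            continue  # (i,j)/(j',i') duplicates collapse later
                        anti = i + j  # constant along an inverted match
                        if any(lo <= i < hi for lo, hi in done_anti.get(anti, ())):
                            continue
                        a, b, L = _extend_inverted(s1, s2, i, j, k)
                        done_anti.setdefault(anti, []).append((a, a + L))
                        if L >= collect_len:
                            key = _norm_pair(ma, a, mb, b, L, True, n1, n2)
                            if key:
                                found.add(key)

    pairs = _dedupe(found, seqs)
    if mode == "near-exact":
        pairs = _near_exact_merge(pairs, molecules, min_len, min_identity)
    pairs = _suppress_contained(pairs)
    pairs.sort(key=lambda p: (-p.length, p.copy1.molecule, p.copy1.start))
    return pairs


def _dedupe(found: set[tuple], seqs) -> list[RepeatPair]:
    """Map raw keys (possibly in doubled coordinates) to RepeatPairs,
    collapsing symmetric duplicates of inverted intra-molecule hits."""
    canon: dict[tuple, RepeatPair] = {}
    for m1, a, m2, b, L, inverted in found:
        n1 = seqs[m1][1]
        n2 = seqs[m2][1]
        a %= n1
        b %= n2
        if m1 == m2:
            key_fwd = (m1, a, m2, b, L, inverted)
            key_sym = (m1, b, m2, a, L, inverted)
            key = min(key_fwd, key_sym)
            m1k, ak, m2k, bk, _, _ = key
            a, b = ak, bk
        key = (m1, a, m2, b, L, inverted)
        if key in canon:
            continue
        canon[key] = RepeatPair(
            copy1=Placement(m1, a, a + L, "forward"),
            copy2=Placement(m2, b, b + L, "reverse" if inverted else "forward"),
            identity=1.0,
        )
    return list(canon.values())


def _contains(outer: Placement, inner: Placement) -> bool:
    return (
        outer.molecule == inner.molecule
        and outer.start <= inner.start
        and inner.end <= outer.end
    )


def _suppress_contained(pairs: list[RepeatPair]) -> list[RepeatPair]:
    """Drop pairs whose both copies are contained in a longer pair's copies."""
    keep = []
    by_len = sorted(pairs, key=lambda p: -p.length)
    for i, p in enumerate(by_len):
        contained = False
        for q in by_len:
            if q is p or q.length <= p.length:
                continue
            for qa, qb in ((q.copy1, q.copy2), (q.copy2, q.copy1)):
                if (_contains(qa, p.copy1) and _contains(qb, p.copy2)) or (
                    _contains(qa, p.copy2) and _contains(qb, p.copy1)
                ):
                    contained = True
                    break
            if contained:
                break
        if not contained:
            keep.append(p)
    return keep


def _near_exact_merge(
    pairs: list[RepeatPair],
    molecules: list[GenomeMolecule],
    min_len: int,
    min_identity: float,
    join_gap: int = 50,
) -> list[RepeatPair]:
    """Chain co-diagonal exact pairs separated by small gaps into one
    near-exact pair and re-score identity by edit distance."""
    by_mol = {m.id: m for m in molecules}
    groups: dict[tuple, list[RepeatPair]] = {}
    for p in pairs:
        inverted = p.copy2.orientation == "reverse"
        diag = (p.copy2.start - p.copy1.start) if not inverted else (p.copy1.start + p.copy2.end)
        groups.setdefault((p.copy1.molecule, p.copy2.molecule, inverted, diag // max(join_gap, 1)), []).append(p)

    merged: list[RepeatPair] = []
    for (m1, m2, inverted, _dg), grp in groups.items():
        grp.sort(key=lambda p: p.copy1.start)
        cur = grp[0]
        chain = [cur]
        out: list[list[RepeatPair]] = []
        for p in grp[1:]:
            if p.copy1.start - chain[-1].copy1.end <= join_gap:
                chain.append(p)
            else:
                out.append(chain)
                chain = [p]
        out.append(chain)
        for chain in out:
            a0 = min(p.copy1.start for p in chain)
            a1 = max(p.copy1.end for p in chain)
            starts2 = [p.copy2.start for p in chain]
            ends2 = [p.copy2.end for p in chain]
            b0, b1 = min(starts2), max(ends2)
            L = max(a1 - a0, b1 - b0)
            if L < min_len:
                continue
            sa = by_mol[m1].fetch(a0, a1)
            sb = by_mol[m2].fetch(b0, b1)
            if inverted:
                sb = revcomp(sb)
            d = edlib.align(sa, sb, mode="NW")["editDistance"]
            ident = 1.0 - d / max(len(sa), len(sb))
            if ident >= min_identity:
                span = min(a1 - a0, b1 - b0)
                merged.append(
                    RepeatPair(
                        copy1=Placement(m1, a0, a0 + span, "forward"),
                        copy2=Placement(m2, b0, b0 + span, "reverse" if inverted else "forward"),
                        identity=round(ident, 4),
                    )
                )
    return merged


def classify_repeats(pairs: list[RepeatPair], long_threshold: int = 1000) -> list[RepeatPair]:
    """Assign long/short class and rank-based ids (LR1.., SR1..).

    Ids descend by length within each class; equal lengths break ties by
    (copy1 molecule, copy1 start).
    """
    if not pairs:
        raise ValueError("no repeat pairs to classify")
    ordered = sorted(pairs, key=lambda p: (-p.length, p.copy1.molecule, p.copy1.start))
    out = []
    counters = {"long": 0, "short": 0}
    for p in ordered:
        klass = "long" if p.length >= long_threshold else "short"
        counters[klass] += 1
        prefix = "LR" if klass == "long" else "SR"
        out.append(replace(p, id=f"{prefix}{counters[klass]}", klass=klass))
    return out
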