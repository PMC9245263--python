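"""Repeat finder: planted truth, brute-force oracle, classification."""

import numpy as np
import pytest

from organellekit.core import GenomeMolecule, Placement, RepeatPair, revcomp
from organellekit.repeats import classify_repeats, find_repeats

from conftest import random_dna


def _runs(eq: np.ndarray, min_len: int):
    """Maximal True-runs of length >= min_len in a boolean vector."""
    if eq.size == 0:
        return
    padded = np.concatenate([[False], eq, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    for a, b in zip(starts, ends):
        if b - a >= min_len:
            yield int(a), int(b - a)


def brute_force_pairs(seqs: dict[str, str], min_len: int):
    """All maximal repeat pairs by exhaustive shift comparison.

    Direct pairs compare every alignment offset of the two sequences; an
    inverted pair of s1 against s2 is a direct match of s1 against
    revcomp(s2) with coordinates mapped back.  Independent of the k-mer
    anchoring used by the implementation.
    """
    found = set()
    ids = sorted(seqs)

    def direct(mol1, mol2):
        a = np.frombuffer(seqs[mol1].encode(), dtype=np.uint8)
        b = np.frombuffer(seqs[mol2].encode(), dtype=np.uint8)
        same = mol1 == mol2
        for off in range(-(len(b) - 1), len(a)):
            lo_a, hi_a = max(0, off), min(len(a), len(b) + off)
            if hi_a - lo_a < min_len or (same and off == 0):
                continue
            eq = a[lo_a:hi_a] == b[lo_a - off : hi_a - off]
            for start, L in _runs(eq, min_len):
                i, j = lo_a + start, lo_a + start - off
                if same:
                    if i == j:
                        continue
                    if j < i:
                        i, j = j, i
                found.add((mol1, i, i + L, mol2, j, j + L, "forward"))

    def inverted(mol1, mol2):
        a = np.frombuffer(seqs[mol1].encode(), dtype=np.uint8)
        rc = np.frombuffer(revcomp(seqs[mol2]).encode(), dtype=np.uint8)
        n2 = len(rc)
        same = mol1 == mol2
        for off in range(-(n2 - 1), len(a)):
            lo_a, hi_a = max(0, off), min(len(a), n2 + off)
            if hi_a - lo_a < min_len:
                continue
            eq = a[lo_a:hi_a] == rc[lo_a - off : hi_a - off]
            for start, L in _runs(eq, min_len):
                i = lo_a + start
                p = lo_a + start - off  # position in revcomp(s2)
                j = n2 - p - L  # forward coordinate in s2
                ii, jj = i, j
                if same and jj < ii:
                    ii, jj = jj, ii
                found.add((mol1, ii, ii + L, mol2, jj, jj + L, "reverse"))

    for x in range(len(ids)):
        for y in range(x, len(ids)):
            direct(ids[x], ids[y])
            inverted(ids[x], ids[y])
    return found


def _suppress_contained_keys(keys):
    keep = set()
    for k in keys:
        m1, a0, a1, m2, b0, b1, o = k
        contained = any(
            q != k
            and q[6] == o
            and q[0] == m1 and q[3] == m2
            and q[1] <= a0 and a1 <= q[2]
            and q[4] <= b0 and b1 <= q[5]
            for q in keys
        )
        if not contained:
            keep.add(k)
    return keep


def _as_keys(pairs):
    return {
        (p.copy1.molecule, p.copy1.start, p.copy1.end,
         p.copy2.molecule, p.copy2.start, p.copy2.end, p.copy2.orientation)
        for p in pairs
    }


def _plant(seq: list, pos: int, unit: str):
    seq[pos : pos + len(unit)] = list(unit)


class TestFindRepeats:
    def test_planted_direct_pair_found_exactly(self, rng):
        bg = list(random_dna(rng, 10_000))
        unit = random_dna(rng, 300)
        _plant(bg, 2_000, unit)
        _plant(bg, 7_000, unit)
        mol = GenomeMolecule(id="m", sequence="".join(bg), topology="linear")
        pairs = find_repeats([mol], min_len=100)
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.copy1.start, p.copy2.start) == (2_000, 7_000)
        assert p.length >= 300  # may extend by chance-matching boundary bases
        assert p.identity == 1.0
        assert p.copy2.orientation == "forward"

    def test_planted_inverted_pair(self, rng):
        bg = list(random_dna(rng, 8_000))
        unit = random_dna(rng, 200)
        _plant(bg, 1_000, unit)
        _plant(bg, 5_000, revcomp(unit))
        mol = GenomeMolecule(id="m", sequence="".join(bg), topology="linear")
        pairs = find_repeats([mol], min_len=100)
        assert len(pairs) == 1
        assert pairs[0].copy2.orientation == "reverse"
        assert pairs[0].copy1.start == 1_000

    def test_inter_molecule_pair(self, rng):
        unit = random_dna(rng, 400)
        a = list(random_dna(rng, 6_000))
        b = list(random_dna(rng, 6_000))
        _plant(a, 3_000, unit)
        _plant(b, 1_000, unit)
        mols = [
            GenomeMolecule(id="m1", sequence="".join(a), topology="linear"),
            GenomeMolecule(id="m2", sequence="".join(b), topology="linear"),
        ]
        pairs = find_repeats(mols, min_len=100)
        assert len(pairs) == 1
        assert {pairs[0].copy1.molecule, pairs[0].copy2.molecule} == {"m1", "m2"}

    def test_circular_repeat_across_origin(self, rng):
        n = 10_000
        bg = list(random_dna(rng, n))
        unit = random_dna(rng, 300)
        # copy crossing the origin: starts at 9,850
        for t, c in enumerate(unit):
            bg[(9_850 + t) % n] = c
        _plant(bg, 4_000, unit)
        mol = GenomeMolecule(id="m", sequence="".join(bg), topology="circular")
        pairs = find_repeats([mol], min_len=100)
        spans_origin = [p for p in pairs if p.copy1.end > n or p.copy2.end > n]
        assert len(spans_origin) == 1
        p = spans_origin[0]
        wrapped = p.copy1 if p.copy1.end > n else p.copy2
        assert wrapped.start <= 9_850 < wrapped.end

    @pytest.mark.parametrize("seed", range(6))
    def test_brute_force_oracle_equivalence(self, seed):
        """Finder output equals the exhaustive shift-scan on small genomes,
        for direct and inverted pairs, intra- and inter-molecule."""
        r = np.random.default_rng(seed)
        n1, n2 = 2_000 + int(r.integers(0, 1_000)), 1_500
        s1 = list(random_dna(r, n1))
        s2 = list(random_dna(r, n2))
        u1 = random_dna(r, 120)
        u2 = random_dna(r, 60)
        u3 = random_dna(r, 45)
        _plant(s1, 100, u1)
        _plant(s1, 1_200, u1)  # intra direct
        _plant(s1, 600, revcomp(u2))
        _plant(s2, 300, u2)  # inter inverted
        _plant(s2, 700, u3)
        _plant(s2, 1_100, u3)  # intra direct, second molecule
        seqs = {"a": "".join(s1), "b": "".join(s2)}
        mols = [GenomeMolecule(id=k, sequence=v, topology="linear") for k, v in seqs.items()]
        got = _as_keys(find_repeats(mols, min_len=40))
        want = _suppress_contained_keys(brute_force_pairs(seqs, 40))
        assert got == want

    def test_revcomp_symmetry(self, rng):
        """Reverse-complementing a molecule maps the pair set through the
        coordinate transform with flipped orientations."""
        bg = list(random_dna(rng, 6_000))
        u = random_dna(rng, 150)
        _plant(bg, 800, u)
        _plant(bg, 3_000, revcomp(u))
        _plant(bg, 4_500, u)
        seq = "".join(bg)
        n = len(seq)
        fwd = _as_keys(find_repeats([GenomeMolecule(id="m", sequence=seq, topology="linear")], min_len=100))
        rev = _as_keys(find_repeats([GenomeMolecule(id="m", sequence=revcomp(seq), topology="linear")], min_len=100))
        mapped = set()
        for m1, a0, a1, m2, b0, b1, o in rev:
            ra0, ra1 = n - a1, n - a0
            rb0, rb1 = n - b1, n - b0
            (x0, x1), (y0, y1) = sorted([(ra0, ra1), (rb0, rb1)])
            mapped.add((m1, x0, x1, m2, y0, y1, o))
        assert mapped == fwd

    def test_near_exact_mode_finds_diverged_copy(self, rng):
        """A 400 bp copy with 10 scattered substitutions is invisible to
        exact mode at min_len=300 but found by near-exact chaining with the
        right identity."""
        bg = list(random_dna(rng, 8_000))
        unit = random_dna(rng, 400)
        _plant(bg, 1_000, unit)
        copy = list(unit)
        for p in range(20, 380, 40):
            copy[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[p]]
        _plant(bg, 5_000, "".join(copy))
        mol = GenomeMolecule(id="m", sequence="".join(bg), topology="linear")
        assert find_repeats([mol], min_len=300, mode="exact") == []
        near = find_repeats([mol], min_len=300, mode="near-exact")
        assert len(near) == 1
        p = near[0]
        assert 0.95 <= p.identity < 1.0
        assert abs(p.copy1.start - 1_000) <= 25 and abs(p.copy2.start - 5_000) <= 25
        assert p.length >= 350

    def test_empty_molecule_list_rejected(self):
        with pytest.raises(ValueError):
            find_repeats([], min_len=100)

    def test_idempotent_re_extraction(self, default_dataset):
        """Coordinates reported by the finder re-extract identical units."""
        _cfg, mts, _cp, _truth = default_dataset
        by = {m.id: m for m in mts}
        for p in find_repeats(mts, min_len=100):
            s1 = by[p.copy1.molecule].fetch(p.copy1.start, p.copy1.end)
            s2 = by[p.copy2.molecule].fetch(p.copy2.start, p.copy2.end)
            assert s2 == (s1 if p.copy2.orientation == "forward" else revcomp(s1))


class TestClassifyRepeats:
    def _pair(self, length, mol="m", start=0):
        return RepeatPair(
            copy1=Placement(mol, start, start + length),
            copy2=Placement(mol, start + length + 10, start + 2 * length + 10),
        )

    def test_study_length_profile_classification(self):
        """Length profile of the study's catalog: 15128/7388/3590 long,
        322 short at a 1 kb threshold."""
        pairs = [self._pair(n, start=i * 40_000) for i, n in enumerate([15_128, 7_388, 3_590, 322])]
        named = classify_repeats(pairs, long_threshold=1_000)
        assert [p.id for p in named] == ["LR1", "LR2", "LR3", "SR1"]
        assert [p.klass for p in named] == ["long", "long", "long", "short"]

    def test_all_short(self):
        named = classify_repeats([self._pair(n, start=i * 2_000) for i, n in enumerate([500, 300])])
        assert [p.id for p in named] == ["SR1", "SR2"]

    def test_equal_length_tie_break_by_coordinates(self):
        a = self._pair(200, start=5_000)
        b = self._pair(200, start=100)
        named = classify_repeats([a, b])
        assert named[0].copy1.start == 100 and named[0].id == "SR1"
        assert named[1].copy1.start == 5_000 and named[1].id == "SR2"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_repeats([])
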