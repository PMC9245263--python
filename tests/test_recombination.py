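"""Conformation construction, spanning-read classification, quantification,
and long-read MTPT integration checks."""

import numpy as np
import pytest

from organellekit import SimConfig, generate_organelle_pair
from organellekit.core import GenomeMolecule, Placement, RepeatPair, revcomp
from organellekit.recombination import (
    build_conformations,
    classify_spanning_read,
    quantify_recombination,
    support_from_counts,
    verify_mtpt_integration,
)
from organellekit.simulate import simulate_spanning_reads

from conftest import random_dna


def _direct_toy(rng, flank=1_000, rep=300):
    U, V, W, X = (random_dna(rng, flank + 200) for _ in range(4))
    R = random_dna(rng, rep)
    mol = GenomeMolecule(id="m", sequence=U + R + V + W + R + X, topology="linear")
    pair = RepeatPair(
        copy1=Placement("m", len(U), len(U) + rep),
        copy2=Placement("m", len(U) + rep + len(V) + len(W), len(U) + 2 * rep + len(V) + len(W)),
        id="R1",
    )
    return mol, pair, (U, R, V, W, X)


class TestBuildConformations:
    def test_direct_repeat_crossover_paths(self, rng):
        mol, pair, (U, R, V, W, X) = _direct_toy(rng)
        cs = build_conformations([mol], pair, flank=1_000)
        assert cs.paths["m1"] == U[-1_000:] + R + V[:1_000]
        assert cs.paths["m2"] == W[-1_000:] + R + X[:1_000]
        assert cs.paths["s1"] == U[-1_000:] + R + X[:1_000]
        assert cs.paths["s2"] == W[-1_000:] + R + V[:1_000]

    def test_inverted_repeat_paths_match_crossover_molecule(self, rng):
        """The s-paths must be substrings of the brute-force crossover
        product (segment between the copies inverted)."""
        U, V, W = (random_dna(rng, 1_500) for _ in range(3))
        R = random_dna(rng, 250)
        mol = GenomeMolecule(id="m", sequence=U + R + V + revcomp(R) + W, topology="linear")
        pair = RepeatPair(
            copy1=Placement("m", len(U), len(U) + 250),
            copy2=Placement("m", len(U) + 250 + len(V), len(U) + 500 + len(V), "reverse"),
            id="R1",
        )
        cs = build_conformations([mol], pair, flank=1_000)
        crossover = U + R + revcomp(V) + revcomp(R) + W
        assert cs.paths["m1"] in mol.sequence
        assert cs.paths["m2"] in revcomp(mol.sequence)
        assert cs.paths["s1"] in crossover
        assert cs.paths["s2"] in revcomp(crossover)
        # s-paths are not substrings of the reference molecule
        assert cs.paths["s1"] not in mol.sequence and cs.paths["s1"] not in revcomp(mol.sequence)

    def test_m_paths_are_reference_substrings(self, default_dataset):
        _cfg, mts, _cp, truth = default_dataset
        by = {m.id: m for m in mts}
        for rp in truth.repeats:
            cs = build_conformations(mts, rp, flank=1_000)
            for name in ("m1", "m2"):
                doubled = {
                    mid: by[mid].sequence + by[mid].sequence for mid in by
                }
                found = any(
                    cs.paths[name] in s or cs.paths[name] in revcomp(s)
                    for s in doubled.values()
                )
                assert found, (rp.id, name)

    def test_circular_flank_wraps_origin(self, rng):
        n = 10_000
        seq = random_dna(rng, n)
        mol = GenomeMolecule(id="m", sequence=seq, topology="circular")
        pair = RepeatPair(
            copy1=Placement("m", 9_900, 9_900 + 150),
            copy2=Placement("m", 4_000, 4_150),
            id="R1",
        )
        cs = build_conformations([mol], pair, flank=1_000)
        assert cs.paths["m1"][:1_000] == (seq + seq)[8_900:9_900]
        assert not cs.flank_info["m1"][0].truncated

    def test_linear_end_truncates_flank_flagged(self, rng):
        mol = GenomeMolecule(id="m", sequence=random_dna(rng, 3_000), topology="linear")
        pair = RepeatPair(
            copy1=Placement("m", 100, 300),
            copy2=Placement("m", 2_000, 2_200),
            id="R1",
        )
        cs = build_conformations([mol], pair, flank=1_000)
        up, _dn = cs.flank_info["m1"]
        assert up.truncated and up.length == 100
        assert len(cs.paths["m1"]) == 100 + 200 + 1_000


class TestClassify:
    def test_exact_m1_read_labelled_major(self, rng):
        mol, pair, _parts = _direct_toy(rng)
        cs = build_conformations([mol], pair, flank=1_000)
        call = classify_spanning_read(("r", cs.paths["m1"]), cs)
        assert call.label == "major" and call.best_path == "m1"
        assert call.identity == 1.0 and call.spans

    def test_reverse_complement_read_handled(self, rng):
        mol, pair, _parts = _direct_toy(rng)
        cs = build_conformations([mol], pair, flank=1_000)
        call = classify_spanning_read(("r", revcomp(cs.paths["s1"])), cs)
        assert call.label == "alternative" and call.best_path == "s1"

    def test_partial_flank_read_is_none(self, rng):
        """A read covering the repeat but only 400 bp of one flank fails the
        spanning rule."""
        mol, pair, _parts = _direct_toy(rng)
        cs = build_conformations([mol], pair, flank=1_000)
        truncated = cs.paths["m1"][600:]  # only 400 bp of the upstream flank
        call = classify_spanning_read(("r", truncated), cs)
        assert call.label == "none" and not call.spans

    def test_errored_alternative_reads_recovered(self):
        """Alternative-origin reads at 5% substitution error are labelled
        alternative, never major."""
        cfg = SimConfig(seed=31)
        cfg.read_params.sub_rate = 0.05
        cfg.read_params.ins_rate = cfg.read_params.del_rate = 0.0
        mts, _cp, truth = generate_organelle_pair(cfg)
        rp = truth.repeats[2]
        reads = simulate_spanning_reads(mts, rp, 1.0, 300, cfg, truth)
        cs = build_conformations(mts, rp, flank=1_000)
        labels = [classify_spanning_read(r, cs).label for r in reads]
        assert labels.count("major") == 0
        assert labels.count("alternative") >= 0.99 * len(reads)

    def test_ambiguity_margin(self, rng):
        """A read that matches an m-path and an s-path almost equally well is
        set aside as ambiguous."""
        mol, pair, (U, R, V, W, X) = _direct_toy(rng)
        cs = build_conformations([mol], pair, flank=1_000)
        call = classify_spanning_read(("r", cs.paths["m1"]), cs, ambiguity_margin=1.01)
        # an exact m1 read under an absurd margin: s-paths are not supported
        # at min_identity, so the label stays major
        assert call.label == "major"


class TestQuantify:
    @pytest.mark.parametrize(
        "n_major,n_alt,pct_major,pct_alt",
        [
            (12, 13, 48.00, 52.00),
            (41, 18, 69.49, 30.51),
            (173, 17, 91.05, 8.95),
            (220, 4, 98.21, 1.79),
            (189, 0, 100.00, 0.00),
        ],
    )
    def test_percentages_half_up_two_decimals(self, n_major, n_alt, pct_major, pct_alt):
        s = support_from_counts("R", n_major, n_alt)
        assert (s.pct_major, s.pct_alternative) == (pct_major, pct_alt)
        assert s.active == (n_alt > 0)

    def test_max_of_same_conformation_paths(self):
        from organellekit.recombination import ReadSupportCall

        calls = (
            [ReadSupportCall(f"a{i}", "R", "major", "m1", 1.0, True) for i in range(7)]
            + [ReadSupportCall(f"b{i}", "R", "major", "m2", 1.0, True) for i in range(10)]
            + [ReadSupportCall(f"c{i}", "R", "alternative", "s1", 1.0, True) for i in range(3)]
            + [ReadSupportCall(f"d{i}", "R", "alternative", "s2", 1.0, True) for i in range(2)]
            + [ReadSupportCall("e", "R", "ambiguous", "m1", 1.0, True)]
            + [ReadSupportCall("f", "R", "none", "none", None, False)]
        )
        s = quantify_recombination(calls, "R")
        assert (s.n_major, s.n_alternative, s.n_ambiguous) == (10, 3, 1)

    def test_percentage_closure(self):
        r = np.random.default_rng(0)
        for _ in range(50):
            nm, na = int(r.integers(0, 500)), int(r.integers(1, 500))
            s = support_from_counts("R", nm, na)
            # two exact-.5 halves may both round up (e.g. 59.38 + 40.63)
            assert abs(s.pct_major + s.pct_alternative - 100.0) <= 0.01 + 1e-9

    def test_zero_support_reports_na(self):
        s = quantify_recombination([], "R")
        assert s.pct_major is None and s.pct_alternative is None and not s.active

    def test_mixture_recovery_binomial(self):
        """Planted 30% alternative fraction recovered within 3 sd on
        error-free spanning reads."""
        cfg = SimConfig(seed=32)
        cfg.read_params.sub_rate = cfg.read_params.ins_rate = cfg.read_params.del_rate = 0.0
        mts, _cp, truth = generate_organelle_pair(cfg)
        rp = truth.repeats[2]
        reads = simulate_spanning_reads(mts, rp, 0.3, 600, cfg, truth)
        cs = build_conformations(mts, rp, flank=1_000)
        calls = [classify_spanning_read(r, cs) for r in reads]
        s = quantify_recombination(calls, rp.id)
        n_eff = s.n_major + s.n_alternative
        est = s.n_alternative / n_eff
        assert abs(est - 0.3) <= 3 * (0.3 * 0.7 / n_eff) ** 0.5

    def test_label_exclusivity(self):
        """No read contributes to both class counts."""
        cfg = SimConfig(seed=33)
        cfg.read_params.sub_rate = cfg.read_params.ins_rate = cfg.read_params.del_rate = 0.0
        mts, _cp, truth = generate_organelle_pair(cfg)
        rp = truth.repeats[3]  # inverted repeat
        reads = simulate_spanning_reads(mts, rp, 0.5, 200, cfg, truth)
        cs = build_conformations(mts, rp, flank=1_000)
        calls = [classify_spanning_read(r, cs) for r in reads]
        for c in calls:
            assert c.label in ("major", "alternative")
            if c.label == "major":
                assert c.best_path in ("m1", "m2")
            else:
                assert c.best_path in ("s1", "s2")


class TestVerifyMtpt:
    def test_spanning_read_verifies_integration(self, rng):
        core = random_dna(rng, 800)
        mt = GenomeMolecule(id="mt1", sequence=random_dna(rng, 3_000) + core + random_dna(rng, 3_000),
                            topology="linear")
        read = mt.sequence[1_800:5_100]
        ok, n = verify_mtpt_integration([("r", read)], [mt], "mt1", 3_000, 3_800, flank=1_000)
        assert ok and n == 1

    def test_plastid_only_reads_do_not_verify(self, rng):
        core = random_dna(rng, 800)
        mt = GenomeMolecule(id="mt1", sequence=random_dna(rng, 3_000) + core + random_dna(rng, 3_000),
                            topology="linear")
        cp_context = random_dna(rng, 1_200) + core + random_dna(rng, 1_200)
        ok, n = verify_mtpt_integration([("r", cp_context)], [mt], "mt1", 3_000, 3_800, flank=1_000)
        assert not ok and n == 0

    def test_errored_spanning_reads_counted(self, default_dataset):
        cfg, mts, cp, truth = default_dataset
        m = truth.mtpts[0]
        mol = {x.id: x for x in mts}[m.mt_molecule]
        rng = np.random.default_rng(7)
        from organellekit.simulate import apply_errors

        reads = []
        for i in range(20):
            raw = mol.fetch(m.mt_start - 1_300, m.mt_end + 1_300)
            reads.append((f"r{i}", apply_errors(raw, rng, 0.05, 0.0, 0.0)))
        ok, n = verify_mtpt_integration(reads, mts, m.mt_molecule, m.mt_start, m.mt_end, flank=1_000)
        assert ok and n == 20
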