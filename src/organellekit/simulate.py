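"""Synthetic organelle genomes, planted truth, and error-bearing reads.

The generator emulates the inputs of an organelle-genome study at desk
scale: a plastid genome and one or two mitochondrial molecules with planted
exact repeat pairs (direct and inverted, within and across molecules),
plastid-derived segments (MTPTs) copied into the mtDNA with an exact number
of substitutions and 1-bp indels, simple open reading frames as
protein-coding genes, planted RNA-editing sites with per-site efficiencies,
planted DNA SNPs, and Nanopore-like long reads plus short RNA/WGS reads
with configurable substitution/indel error.  Everything is driven by one
seed: identical configurations produce byte-identical outputs.

Background sequence is i.i.d. per-base at the configured GC fraction.
Long-read lengths follow a log-normal truncated to [200 bp, molecule
length]; reads are emitted from both strands with probability 0.5; FASTQ
qualities are constant placeholders.  RNA and WGS reads are simulated from
the spliced coding sequences (full-length per read), so the per-gene depth
is exact and planted editing efficiencies are recovered in expectation.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .core import Feature, GenomeMolecule, Placement, RepeatPair, revcomp
from .recombination import build_conformations

STOPS = {"TAA", "TAG", "TGA"}


class PlacementError(ValueError):
    """A planted element could not be placed without overlap."""


@dataclass
class RepeatSpec:
    length: int
    orientation: str = "direct"  # direct | inverted
    placement: str = "intra"  # intra | inter


@dataclass
class MtptSpec:
    length: int
    n_substitutions: int = 0
    n_indels: int = 0


@dataclass
class EditingSpec:
    gene: str
    cds_pos: int  # 1-based in the spliced CDS
    ref_base: str
    edited_base: str
    efficiency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError("efficiency must be in [0, 1]")


@dataclass
class SnpSpec:
    gene: str
    cds_pos: int
    alt_base: str


@dataclass
class ReadParams:
    mean_length: int = 6000
    length_spread: float = 0.4  # sigma of the log-normal
    sub_rate: float = 0.05
    ins_rate: float = 0.015
    del_rate: float = 0.015
    count: Optional[int] = None
    depth: Optional[float] = 20.0

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("error rates must be in [0, 1]")


@dataclass
class SimConfig:
    seed: int = 0
    mt_molecule_lengths: list[int] = field(default_factory=lambda: [60_000, 40_000])
    cp_length: int = 30_000
    gc_fraction: float = 0.45
    mt_gene_count: int = 8
    cp_gene_count: int = 4
    gene_length: int = 300  # spliced CDS length incl. start/stop, multiple of 3
    repeat_specs: list[RepeatSpec] = field(
        default_factory=lambda: [
            RepeatSpec(3590, "direct", "intra"),
            RepeatSpec(1500, "direct", "inter"),
            RepeatSpec(322, "direct", "intra"),
            RepeatSpec(207, "inverted", "intra"),
            RepeatSpec(125, "direct", "intra"),
        ]
    )
    mtpt_specs: list[MtptSpec] = field(
        default_factory=lambda: [
            MtptSpec(5142, 5, 0),
            MtptSpec(1410, 70, 0),
            MtptSpec(800, 30, 5),
            MtptSpec(500, 100, 0),
            MtptSpec(60, 3, 0),
        ]
    )
    conformation_mixture: dict[str, float] = field(default_factory=dict)
    editing_specs: list[EditingSpec] = field(default_factory=list)
    snp_specs: list[SnpSpec] = field(default_factory=list)
    n_auto_editing_mito: int = 0
    n_auto_editing_plastid: int = 0
    n_auto_snps: int = 0
    efficiency_range: tuple[float, float] = (0.2, 1.0)
    read_params: ReadParams = field(default_factory=ReadParams)
    rna_read_params: ReadParams = field(
        default_factory=lambda: ReadParams(sub_rate=0.001, ins_rate=0.0001, del_rate=0.0001)
    )
    rna_depth: int = 50
    wgs_depth: int = 30
    flank: int = 1000  # spanning-path flank used by the mixture simulator
    spanning_margin: int = 200
    spanning_reads_per_repeat: int = 300

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        for rid, f in self.conformation_mixture.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"mixture fraction for {rid} must be in [0, 1]")
        if self.gene_length % 3:
            raise ValueError("gene_length must be a multiple of 3")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        """Load from JSON, or from simple key=value lines for flat fields."""
        text = Path(path).read_text()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            data = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                k, v = line.split("=", 1)
                data[k.strip()] = json.loads(v.strip())
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        kwargs = dict(data)
        if "repeat_specs" in kwargs:
            kwargs["repeat_specs"] = [RepeatSpec(**d) for d in kwargs["repeat_specs"]]
        if "mtpt_specs" in kwargs:
            kwargs["mtpt_specs"] = [MtptSpec(**d) for d in kwargs["mtpt_specs"]]
        if "editing_specs" in kwargs:
            kwargs["editing_specs"] = [EditingSpec(**d) for d in kwargs["editing_specs"]]
        if "snp_specs" in kwargs:
            kwargs["snp_specs"] = [SnpSpec(**d) for d in kwargs["snp_specs"]]
        if "read_params" in kwargs:
            kwargs["read_params"] = ReadParams(**kwargs["read_params"])
        if "rna_read_params" in kwargs:
            kwargs["rna_read_params"] = ReadParams(**kwargs["rna_read_params"])
        if "efficiency_range" in kwargs:
            kwargs["efficiency_range"] = tuple(kwargs["efficiency_range"])
        unknown = set(kwargs) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)


@dataclass
class PlantedMtpt:
    id: str
    cp_start: int
    cp_end: int
    mt_molecule: str
    mt_start: int
    mt_end: int
    n_substitutions: int
    n_indels: int


@dataclass
class PlantedEdit:
    gene: str
    molecule: str
    organelle: str
    cds_pos: int
    genome_pos: int
    ref_base: str
    edited_base: str
    efficiency: float


@dataclass
class PlantedSnp:
    gene: str
    molecule: str
    cds_pos: int
    genome_pos: int
    ref_base: str
    alt_base: str


@dataclass
class ReadOrigin:
    source: str  # molecule id, or "repeat_id/path" for spanning reads
    start: int
    end: int
    strand: str
    kind: str  # long | spanning | rna | wgs


@dataclass
class SimTruth:
    repeats: list[RepeatPair] = field(default_factory=list)
    mtpts: list[PlantedMtpt] = field(default_factory=list)
    mixture: dict[str, float] = field(default_factory=dict)
    editing_sites: list[PlantedEdit] = field(default_factory=list)
    snps: list[PlantedSnp] = field(default_factory=list)
    read_origins: dict[str, ReadOrigin] = field(default_factory=dict)

    def to_json(self) -> str:
        def enc(o):
            if hasattr(o, "__dataclass_fields__"):
                return asdict(o)
            raise TypeError(type(o))

        payload = {
            "repeats": [
                {
                    "id": r.id,
                    "length": r.length,
                    "copy1": asdict(r.copy1),
                    "copy2": asdict(r.copy2),
                    "identity": r.identity,
                }
                for r in self.repeats
            ],
            "mtpts": [asdict(m) for m in self.mtpts],
            "mixture": self.mixture,
            "editing_sites": [asdict(e) for e in self.editing_sites],
            "snps": [asdict(s) for s in self.snps],
            "read_origins": {k: asdict(v) for k, v in sorted(self.read_origins.items())},
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=enc)


# ---------------------------------------------------------------------------
# sequence-level helpers


def random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _random_orf(rng: np.random.Generator, length: int) -> str:
    """ATG + non-stop codons + TAA, total ``length`` bases."""
    n_mid = length // 3 - 2
    codons = []
    while len(codons) < n_mid:
        c = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3)])
        if c not in STOPS:
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


def apply_errors(seq: str, rng: np.random.Generator, sub: float, ins: float, dele: float) -> str:
    """Per-base substitution/insertion/deletion error model."""
    if sub == ins == dele == 0:
        return seq
    bases = "ACGT"
    out = []
    u = rng.random((len(seq), 3))
    for i, b in enumerate(seq):
        if u[i, 2] < dele:
            continue
        if u[i, 0] < sub and b in bases:
            choices = bases.replace(b, "")
            b = choices[rng.integers(0, 3)]
        out.append(b)
        if u[i, 1] < ins:
            out.append(bases[rng.integers(0, 4)])
    return "".join(out)


class _Occupancy:
    """Free-interval bookkeeping for planting elements without overlap."""

    def __init__(self, length: int, margin: int = 50):
        self.length = length
        self.margin = margin
        self.taken: list[tuple[int, int]] = []

    def reserve(self, rng: np.random.Generator, size: int, what: str, tries: int = 400) -> int:
        if size + 2 * self.margin > self.length:
            raise PlacementError(f"{what}: size {size} exceeds molecule length {self.length}")
        for _ in range(tries):
            start = int(rng.integers(0, self.length - size))
            a, b = start - self.margin, start + size + self.margin
            if all(b <= ta or a >= tb for ta, tb in self.taken):
                self.taken.append((start, start + size))
                return start
        raise PlacementError(f"could not place {what} (size {size}) without overlap")


def _mutate_exact(
    seq: str, rng: np.random.Generator, n_sub: int, n_indel: int, end_protect: int = 12
) -> tuple[str, int, int]:
    """Apply exactly n_sub substitutions and n_indel 1-bp indels at distinct
    positions; returns the mutated sequence.

    A short terminus on each side stays exact so that the planted boundary
    is also the local-alignment boundary (divergence clustered at a segment
    end would otherwise be trimmed by any local aligner and make the planted
    interval ill-defined as truth)."""
    interior = len(seq) - 2 * end_protect
    if n_sub + n_indel > interior // 2:
        raise ValueError("too many planted differences for segment length")
    pos = end_protect + rng.choice(interior, size=n_sub + n_indel, replace=False)
    sub_pos = set(int(p) for p in pos[:n_sub])
    indel_pos = set(int(p) for p in pos[n_sub:])
    bases = "ACGT"
    out = []
    for i, b in enumerate(seq):
        if i in sub_pos:
            out.append(bases.replace(b, "")[rng.integers(0, 3)])
        elif i in indel_pos:
            if rng.random() < 0.5:
                out.append(b)
                out.append(bases[rng.integers(0, 4)])  # insertion
            # else: deletion, emit nothing
        else:
            out.append(b)
    return "".join(out), n_sub, n_indel


# ---------------------------------------------------------------------------
# main generator


def generate_organelle_pair(
    config: SimConfig,
) -> tuple[list[GenomeMolecule], GenomeMolecule, SimTruth]:
    """Build the mt molecules, the plastid molecule, and the planted truth."""
    rng = np.random.default_rng([config.seed, 1])
    truth = SimTruth(mixture=dict(config.conformation_mixture))

    cp_seq = list(random_sequence(rng, config.cp_length, config.gc_fraction))
    mt_seqs = [
        list(random_sequence(rng, n, config.gc_fraction)) for n in config.mt_molecule_lengths
    ]
    mt_ids = [f"mt{i+1}" for i in range(len(mt_seqs))]
    occ = {"cp": _Occupancy(config.cp_length)}
    for mid, s in zip(mt_ids, mt_seqs):
        occ[mid] = _Occupancy(len(s))
    seqs = {"cp": cp_seq, **{mid: s for mid, s in zip(mt_ids, mt_seqs)}}

    # --- genes (simple ORFs; every 4th gene is 2-exon, strands alternate)
    features: dict[str, list[Feature]] = {mid: [] for mid in seqs}
    gnum = 0

    def plant_gene(mol_id: str, name: str) -> Feature:
        nonlocal gnum
        gnum += 1
        orf = _random_orf(rng, config.gene_length)
        strand = "+" if gnum % 2 else "-"
        two_exon = gnum % 4 == 0
        # genomic forward-strand image of the spliced CDS
        linear = orf if strand == "+" else revcomp(orf)
        exons = None
        if two_exon:
            intron = random_sequence(rng, 60, config.gc_fraction)
            cut = (config.gene_length // 2 // 3) * 3
            placed = linear[:cut] + intron + linear[cut:]
        else:
            placed = linear
        start = occ[mol_id].reserve(rng, len(placed), f"gene {name}")
        seqs[mol_id][start : start + len(placed)] = list(placed)
        if two_exon:
            exons = [(start, start + cut), (start + cut + 60, start + len(placed))]
        f = Feature(
            gene=name,
            molecule=mol_id,
            start=start,
            end=start + len(placed),
            strand=strand,
            ftype="PCG",
            exons=exons,
        )
        features[mol_id].append(f)
        return f

    for i in range(config.cp_gene_count):
        plant_gene("cp", f"cpg{i+1:02d}")
    for i in range(config.mt_gene_count):
        plant_gene(mt_ids[i % len(mt_ids)], f"mtg{i+1:02d}")

    # --- MTPTs: plastid segments copied into mtDNA with exact differences
    for k, spec in enumerate(config.mtpt_specs, 1):
        src = occ["cp"].reserve(rng, spec.length, f"mtpt spec {k} (cp source)")
        segment = "".join(cp_seq[src : src + spec.length])
        mutated, _, _ = _mutate_exact(segment, rng, spec.n_substitutions, spec.n_indels)
        mol = mt_ids[int(rng.integers(0, len(mt_ids)))]
        dst = occ[mol].reserve(rng, len(mutated), f"mtpt spec {k} (mt target)")
        seqs[mol][dst : dst + len(mutated)] = list(mutated)
        # keep the planted boundary maximal: a few bases flanking the mt copy
        # are forced to mismatch the cp source context, so a local aligner
        # cannot profitably extend past the planted integration boundary
        nmt, ncp = len(seqs[mol]), len(cp_seq)
        for off in range(1, 7):
            for pos, clash in (
                ((dst - off) % nmt, cp_seq[(src - off) % ncp]),
                ((dst + len(mutated) + off - 1) % nmt, cp_seq[(src + spec.length + off - 1) % ncp]),
            ):
                if seqs[mol][pos] == clash:
                    choices = [b for b in "ACGT" if b != clash]
                    seqs[mol][pos] = choices[int(rng.integers(0, 3))]
        truth.mtpts.append(
            PlantedMtpt(
                id=f"pt{k}",
                cp_start=src,
                cp_end=src + spec.length,
                mt_molecule=mol,
                mt_start=dst,
                mt_end=dst + len(mutated),
                n_substitutions=spec.n_substitutions,
                n_indels=spec.n_indels,
            )
        )

    # --- repeats: duplicate a segment within or across mt molecules
    for k, spec in enumerate(config.repeat_specs, 1):
        if spec.placement == "inter" and len(mt_ids) < 2:
            raise PlacementError(f"repeat spec {k}: inter-molecule repeat needs two mt molecules")
        mol1 = mt_ids[int(rng.integers(0, len(mt_ids)))]
        mol2 = mol1 if spec.placement == "intra" else [m for m in mt_ids if m != mol1][0]
        s1 = occ[mol1].reserve(rng, spec.length, f"repeat spec {k} (copy1)")
        s2 = occ[mol2].reserve(rng, spec.length, f"repeat spec {k} (copy2)")
        unit = "".join(seqs[mol1][s1 : s1 + spec.length])
        placed = unit if spec.orientation == "direct" else revcomp(unit)
        seqs[mol2][s2 : s2 + spec.length] = list(placed)
        # make the planted pair maximal: break chance matches just outside
        # the copies so the repeat cannot extend beyond its planted bounds
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        n1, n2 = len(seqs[mol1]), len(seqs[mol2])
        e1, e2 = s1 + spec.length, s2 + spec.length
        if spec.orientation == "direct":
            guards = [((s2 - 1) % n2, seqs[mol1][(s1 - 1) % n1]),
                      (e2 % n2, seqs[mol1][e1 % n1])]
        else:
            guards = [(e2 % n2, comp[seqs[mol1][(s1 - 1) % n1]]),
                      ((s2 - 1) % n2, comp[seqs[mol1][e1 % n1]])]
        for pos, clash in guards:
            if seqs[mol2][pos] == clash:
                choices = [b for b in "ACGT" if b != clash]
                seqs[mol2][pos] = choices[int(rng.integers(0, 3))]
        c1 = Placement(mol1, s1, s1 + spec.length, "forward")
        c2 = Placement(
            mol2, s2, s2 + spec.length,
            "forward" if spec.orientation == "direct" else "reverse",
        )
        if (c2.molecule, c2.start) < (c1.molecule, c1.start):
            c1, c2 = (
                Placement(c2.molecule, c2.start, c2.end, "forward"),
                Placement(c1.molecule, c1.start, c1.end, c2.orientation),
            )
        truth.repeats.append(RepeatPair(copy1=c1, copy2=c2, identity=1.0, id=f"R{k}"))

    molecules = {
        mid: GenomeMolecule(
            id=mid, sequence="".join(seqs[mid]), topology="circular",
            organelle="plastid" if mid == "cp" else "mito", features=features[mid],
        )
        for mid in seqs
    }
    cp = molecules.pop("cp")
    mts = [molecules[mid] for mid in mt_ids]

    # --- editing sites and SNPs (explicit specs plus auto-generated ones)
    _plant_transcript_variants(config, rng, cp, mts, truth)
    return mts, cp, truth


def _gene_index(cp: GenomeMolecule, mts: list[GenomeMolecule]):
    out = {}
    for mol in [cp] + mts:
        for f in mol.features:
            if f.ftype == "PCG":
                out[f.gene] = (mol, f)
    return out


def _cds_genome_pos(f: Feature, cds_pos: int) -> int:
    """Genome coordinate (0-based) of 1-based spliced CDS position."""
    offsets = f.exon_intervals()
    if f.strand == "+":
        remaining = cds_pos - 1
        for a, b in offsets:
            if remaining < b - a:
                return a + remaining
            remaining -= b - a
    else:
        remaining = cds_pos - 1
        for a, b in reversed(offsets):
            if remaining < b - a:
                return b - 1 - remaining
            remaining -= b - a
    raise ValueError(f"cds position {cds_pos} outside gene {f.gene}")


def _plant_transcript_variants(config, rng, cp, mts, truth) -> None:
    genes = _gene_index(cp, mts)
    specs = list(config.editing_specs)

    def auto_specs(pool: list[str], n: int, used: set) -> list[EditingSpec]:
        out = []
        lo, hi = config.efficiency_range
        guard = 0
        while len(out) < n:
            guard += 1
            if guard > 100 * n + 100:
                raise PlacementError("could not auto-place editing sites")
            g = pool[int(rng.integers(0, len(pool)))]
            mol, f = genes[g]
            cds_len = sum(b - a for a, b in f.exon_intervals())
            # codon position 2, away from start/stop codons
            codon = int(rng.integers(1, cds_len // 3 - 1))
            pos = codon * 3 + 2
            if (g, pos) in used:
                continue
            used.add((g, pos))
            eff = float(rng.uniform(lo, hi))
            out.append(EditingSpec(g, pos, "C", "T", eff))
        return out

    used = {(s.gene, s.cds_pos) for s in specs}
    mt_genes = sorted(g for g, (mol, _f) in genes.items() if mol.organelle == "mito")
    cp_genes = sorted(g for g, (mol, _f) in genes.items() if mol.organelle == "plastid")
    if config.n_auto_editing_mito:
        specs += auto_specs(mt_genes, config.n_auto_editing_mito, used)
    if config.n_auto_editing_plastid:
        specs += auto_specs(cp_genes, config.n_auto_editing_plastid, used)

    snp_specs = list(config.snp_specs)
    if config.n_auto_snps:
        pool = mt_genes + cp_genes
        guard = 0
        while len(snp_specs) < len(config.snp_specs) + config.n_auto_snps:
            guard += 1
            if guard > 100 * config.n_auto_snps + 100:
                raise PlacementError("could not auto-place SNPs")
            g = pool[int(rng.integers(0, len(pool)))]
            mol, f = genes[g]
            cds_len = sum(b - a for a, b in f.exon_intervals())
            codon = int(rng.integers(1, cds_len // 3 - 1))
            pos = codon * 3 + 2
            if (g, pos) in used:
                continue
            used.add((g, pos))
            snp_specs.append(SnpSpec(g, pos, "G"))

    # force the reference base at each planted editing site (codon position 2
    # substitutions cannot create an in-frame stop)
    for s in specs:
        if s.gene not in genes:
            raise ValueError(f"editing spec references unknown gene {s.gene}")
        mol, f = genes[s.gene]
        gp = _cds_genome_pos(f, s.cds_pos)
        ref = s.ref_base if f.strand == "+" else revcomp(s.ref_base)
        mol.sequence = mol.sequence[:gp] + ref + mol.sequence[gp + 1 :]
        truth.editing_sites.append(
            PlantedEdit(
                gene=s.gene,
                molecule=mol.id,
                organelle=mol.organelle,
                cds_pos=s.cds_pos,
                genome_pos=gp,
                ref_base=s.ref_base,
                edited_base=s.edited_base,
                efficiency=s.efficiency,
            )
        )
    for s in snp_specs:
        if s.gene not in genes:
            raise ValueError(f"SNP spec references unknown gene {s.gene}")
        mol, f = genes[s.gene]
        gp = _cds_genome_pos(f, s.cds_pos)
        cds = f.spliced(mol.sequence)
        ref = cds[s.cds_pos - 1]
        if ref == s.alt_base:
            s = SnpSpec(s.gene, s.cds_pos, "A" if ref != "A" else "C")
        truth.snps.append(
            PlantedSnp(
                gene=s.gene,
                molecule=mol.id,
                cds_pos=s.cds_pos,
                genome_pos=gp,
                ref_base=ref,
                alt_base=s.alt_base,
            )
        )


# ---------------------------------------------------------------------------
# read simulators


def simulate_long_reads(
    molecules: list[GenomeMolecule], truth: SimTruth, config: SimConfig
) -> list[tuple[str, str]]:
    """Whole-genome long reads plus, for each repeat with a conformation
    mixture entry, a batch of repeat-spanning reads drawn from the stated
    major/alternative mixture.  Origins are recorded in the truth."""
    if not molecules:
        raise ValueError("no molecules to simulate from")
    rng = np.random.default_rng([config.seed, 2])
    rp = config.read_params
    total_len = sum(len(m) for m in molecules)
    count = rp.count
    if count is None:
        count = max(1, int(round((rp.depth or 1.0) * total_len / rp.mean_length)))
    weights = np.array([len(m) for m in molecules], dtype=float)
    weights /= weights.sum()
    reads: list[tuple[str, str]] = []
    for i in range(count):
        mol = molecules[int(rng.choice(len(molecules), p=weights))]
        n = len(mol)
        mean_len = rp.mean_length
        if mol.topology == "linear" and mean_len > n:
            mean_len = n  # warning semantics: truncated to molecule length
        L = int(rng.lognormal(math.log(mean_len), rp.length_spread))
        L = max(200, min(L, n))
        start = int(rng.integers(0, n))
        if mol.topology == "linear":
            start = min(start, n - L)
            seq = mol.sequence[start : start + L]
            end = start + L
        else:
            seq = mol.fetch(start, start + L)
            end = start + L  # may exceed n: wraps
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = revcomp(seq)
        seq = apply_errors(seq, rng, rp.sub_rate, rp.ins_rate, rp.del_rate)
        rid = f"lr{i+1:06d}"
        reads.append((rid, seq))
        truth.read_origins[rid] = ReadOrigin(mol.id, start, end, strand, "long")
    for repeat in truth.repeats:
        frac = truth.mixture.get(repeat.id)
        if frac is None:
            continue
        reads += simulate_spanning_reads(
            molecules, repeat, frac, config.spanning_reads_per_repeat, config, truth
        )
    return reads


def simulate_spanning_reads(
    molecules: list[GenomeMolecule],
    repeat: RepeatPair,
    alt_fraction: float,
    n: int,
    config: SimConfig,
    truth: Optional[SimTruth] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[tuple[str, str]]:
    """Reads guaranteed to span one repeat (with margin beyond the flanks),
    drawn from the alternative conformation with probability ``alt_fraction``
    and from the major conformation otherwise (path uniform within class)."""
    rng = rng if rng is not None else np.random.default_rng(
        [config.seed, 3, zlib.crc32((repeat.id or "repeat").encode())]
    )
    rp = config.read_params
    cs = build_conformations(molecules, repeat, flank=config.flank + config.spanning_margin)
    reads = []
    for i in range(n):
        alt = rng.random() < alt_fraction
        path = ("s1", "s2")[int(rng.integers(0, 2))] if alt else ("m1", "m2")[int(rng.integers(0, 2))]
        seq = cs.paths[path]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = revcomp(seq)
        seq = apply_errors(seq, rng, rp.sub_rate, rp.ins_rate, rp.del_rate)
        rid = f"sp_{repeat.id}_{i+1:05d}"
        reads.append((rid, seq))
        if truth is not None:
            truth.read_origins[rid] = ReadOrigin(
                f"{repeat.id}/{path}", 0, len(seq), strand, "spanning"
            )
    return reads


def simulate_rnaseq_and_wgs(
    cp: GenomeMolecule,
    mts: list[GenomeMolecule],
    truth: SimTruth,
    config: SimConfig,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Transcriptome and WGS reads over the spliced coding sequences.

    Each gene receives exactly ``rna_depth`` RNA reads and ``wgs_depth`` WGS
    reads covering the whole spliced CDS.  Planted SNPs appear in both read
    sets at every read; at each planted editing site the edited base appears
    in each RNA read independently with the site's efficiency."""
    rng = np.random.default_rng([config.seed, 4])
    genes = _gene_index(cp, mts)
    edits_by_gene: dict[str, list[PlantedEdit]] = {}
    for e in truth.editing_sites:
        if e.gene not in genes:
            raise ValueError(f"editing site references unknown gene {e.gene}")
        edits_by_gene.setdefault(e.gene, []).append(e)
    snps_by_gene: dict[str, list[PlantedSnp]] = {}
    for s in truth.snps:
        snps_by_gene.setdefault(s.gene, []).append(s)

    rp = config.rna_read_params
    rna, wgs = [], []
    for g in sorted(genes):
        mol, f = genes[g]
        cds = f.spliced(mol.sequence)
        base = list(cds)
        for s in snps_by_gene.get(g, []):
            base[s.cds_pos - 1] = s.alt_base
        dna_seq = "".join(base)
        for j in range(config.wgs_depth):
            seq = apply_errors(dna_seq, rng, rp.sub_rate, rp.ins_rate, rp.del_rate)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            rid = f"wgs_{g}_{j+1:04d}"
            wgs.append((rid, seq))
            truth.read_origins[rid] = ReadOrigin(g, 0, len(cds), "+", "wgs")
        for j in range(config.rna_depth):
            rseq = list(dna_seq)
            for e in edits_by_gene.get(g, []):
                if rng.random() < e.efficiency:
                    rseq[e.cds_pos - 1] = e.edited_base
            seq = apply_errors("".join(rseq), rng, rp.sub_rate, rp.ins_rate, rp.del_rate)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            rid = f"rna_{g}_{j+1:04d}"
            rna.append((rid, seq))
            truth.read_origins[rid] = ReadOrigin(g, 0, len(cds), "+", "rna")
    return rna, wgs
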