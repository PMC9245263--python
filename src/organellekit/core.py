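"""Core domain types shared across the toolkit.

Coordinates are 0-based half-open internally.  Report writers convert to the
1-based inclusive convention of the output tables, where descending
coordinates encode reverse orientation (see :mod:`organellekit.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N passes through)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Feature:
    """An annotated feature on a genome molecule.

    ``exons`` holds 0-based half-open sub-intervals on the molecule, ordered
    along the forward strand; single-exon features may leave it None.
    """

    gene: str
    molecule: str
    start: int
    end: int
    strand: str = "+"
    ftype: str = "PCG"  # PCG | tRNA | rRNA | MTPT-fragment
    exons: Optional[list[tuple[int, int]]] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad feature interval {self.start}:{self.end} for {self.gene}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.exons:
            if any(b <= a for a, b in self.exons):
                raise ValueError("empty exon interval")
            if sorted(self.exons) != list(self.exons):
                raise ValueError("exon intervals must be ordered")

    def exon_intervals(self) -> list[tuple[int, int]]:
        return list(self.exons) if self.exons else [(self.start, self.end)]

    def spliced(self, sequence: str) -> str:
        """Spliced sense-strand sequence (exons joined, reverse-complemented
        for minus-strand features)."""
        s = "".join(sequence[a:b] for a, b in self.exon_intervals())
        return revcomp(s) if self.strand == "-" else s


@dataclass
class GenomeMolecule:
    """A named DNA molecule with topology and organelle label."""

    id: str
    sequence: str
    topology: str = "circular"  # circular | linear
    organelle: str = "mito"  # mito | plastid
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"molecule {self.id} has empty sequence")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"bad topology {self.topology!r}")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"molecule {self.id}: unexpected characters {sorted(bad)}")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence [start, end); for circular molecules the interval may
        wrap past the origin (end > length, or negative start)."""
        n = len(self.sequence)
        if self.topology == "linear":
            if start < 0 or end > n:
                raise ValueError(
                    f"interval {start}:{end} outside linear molecule {self.id} (len {n})"
                )
            return self.sequence[start:end]
        length = end - start
        if length > n:
            raise ValueError(f"interval {start}:{end} longer than circular molecule {self.id}")
        start %= n
        return (self.sequence + self.sequence)[start : start + length]


@dataclass(frozen=True)
class Placement:
    """One placement of a repeated segment (always in forward coordinates)."""

    molecule: str
    start: int
    end: int
    orientation: str = "forward"  # forward | reverse

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation {self.orientation!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RepeatPair:
    """Two placements of a repeated segment.

    ``copy2.orientation == 'reverse'`` marks an inverted repeat: the sequence
    at copy2 is the reverse complement of the sequence at copy1.
    """

    copy1: Placement
    copy2: Placement
    identity: float = 1.0
    id: Optional[str] = None
    klass: Optional[str] = None  # long | short

    def __post_init__(self) -> None:
        if self.copy1 == self.copy2:
            raise ValueError("repeat copies must differ")
        if self.copy1.length != self.copy2.length:
            raise ValueError("repeat copies must have equal length")

    @property
    def length(self) -> int:
        return self.copy1.length
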