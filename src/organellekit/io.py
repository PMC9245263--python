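"""Reading and writing of the standard formats used by the pipeline.

FASTA/FASTQ go through Biopython's SeqIO.  GFF3 output is written directly
(three-level gene/mRNA-free layout: ``gene`` + ``CDS`` rows); GFF3 input is
parsed with a tolerant reader restricted to that layout.  SAM input (optional,
for pre-computed alignments) goes through pysam.

Table coordinates follow the organelle-genomics reporting convention:
1-based inclusive, with descending start/end encoding reverse orientation.
Internally everything is 0-based half-open plus an orientation flag; the two
helpers below convert and are exercised in both directions by the test suite.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import Feature, GenomeMolecule

logger = logging.getLogger("organellekit")


def setup_logging(level: str = "INFO", logfile: Optional[str] = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )


# ---------------------------------------------------------------------------
# coordinate conventions


def interval_to_table(start: int, end: int, orientation: str = "forward") -> tuple[int, int]:
    """0-based half-open + orientation -> 1-based inclusive table pair.

    Forward intervals ascend (start+1, end); reverse intervals descend
    (end, start+1), e.g. ``7671-7465`` for a reverse placement.
    """
    if orientation == "forward":
        return start + 1, end
    return end, start + 1


def table_to_interval(a: int, b: int) -> tuple[int, int, str]:
    """1-based inclusive table pair -> (start, end, orientation)."""
    if a <= b:
        return a - 1, b, "forward"
    return b - 1, a, "reverse"


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> list[GenomeMolecule]:
    """Load molecules from FASTA.

    ``topology=`` and ``organelle=`` key=value tokens in the description are
    honoured; anything else defaults to circular/mito.  Lowercase sequence is
    normalised to uppercase (logged).
    """
    molecules = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            logger.info("record %s: lowercase bases normalised to uppercase", rec.id)
        meta = dict(
            tok.split("=", 1) for tok in rec.description.split()[1:] if "=" in tok
        )
        molecules.append(
            GenomeMolecule(
                id=rec.id,
                sequence=seq.upper(),
                topology=meta.get("topology", "circular"),
                organelle=meta.get("organelle", "mito"),
            )
        )
    if not molecules:
        raise ValueError(f"no FASTA records in {path}")
    return molecules


def write_fasta(molecules: Iterable[GenomeMolecule], path: str | Path) -> None:
    records = [
        SeqRecord(
            Seq(m.sequence),
            id=m.id,
            description=f"topology={m.topology} organelle={m.organelle}",
        )
        for m in molecules
    ]
    SeqIO.write(records, str(path), "fasta")


def read_reads(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from FASTA or FASTQ (sniffed by extension)."""
    p = str(path)
    fmt = "fastq" if p.endswith((".fastq", ".fq")) else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(p, fmt)]


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, quality: int = 30) -> None:
    """Write reads with a constant placeholder quality (no stage uses quality)."""
    records = []
    for rid, seq in reads:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(molecules: Iterable[GenomeMolecule], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for mol in molecules:
        for feat in mol.features:
            a, b = feat.start + 1, feat.end
            gid = feat.gene
            lines.append(
                "\t".join(
                    [mol.id, "organellekit", "gene", str(a), str(b), ".", feat.strand, ".",
                     f"ID={gid};Name={gid};feature_type={feat.ftype}"]
                )
            )
            for i, (ea, eb) in enumerate(feat.exon_intervals(), 1):
                lines.append(
                    "\t".join(
                        [mol.id, "organellekit", "CDS", str(ea + 1), str(eb), ".",
                         feat.strand, "0", f"ID={gid}.cds{i};Parent={gid}"]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path, molecules: Optional[list[GenomeMolecule]] = None) -> list[Feature]:
    """Parse gene+CDS GFF3 into Features (exons = CDS parts, ordered).

    If ``molecules`` is given, features are attached to them and coordinates
    validated against molecule bounds.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    feats = []
    bounds = {m.id: len(m) for m in molecules} if molecules else {}
    for gene in db.features_of_type("gene", order_by="start"):
        gid = gene.id
        exons = sorted(
            (c.start - 1, c.end)
            for c in db.children(gene, featuretype=("CDS", "exon"))
        ) or None
        if gene.seqid in bounds and gene.end > bounds[gene.seqid]:
            raise ValueError(f"feature {gid} exceeds molecule {gene.seqid} bounds")
        feats.append(
            Feature(
                gene=gid,
                molecule=gene.seqid,
                start=gene.start - 1,
                end=gene.end,
                strand=gene.strand,
                ftype=gene.attributes.get("feature_type", ["PCG"])[0],
                exons=exons,
            )
        )
    if molecules:
        by_id = {m.id: m for m in molecules}
        for f in feats:
            if f.molecule in by_id:
                by_id[f.molecule].features.append(f)
    return feats


# ---------------------------------------------------------------------------
# SAM (optional pre-aligned input for the editing module)


def read_sam(path: str | Path):
    """Yield (read_id, reference_name, reference_start, cigartuples, query_sequence)
    for mapped records of a SAM file."""
    import pysam

    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            yield rec.query_name, rec.reference_name, rec.reference_start, rec.cigartuples, rec.query_sequence


# ---------------------------------------------------------------------------
# reports


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
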