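"""Readers and writers for the formats the pipeline touches.

Sequences are FASTA (via Biopython), trees are Newick (via dendropy
through :class:`~famevol.trees.SpeciesTree`), and gene structures are
either a GFF3 subset (gene/mRNA/CDS features) or a simple TSV dialect
with columns ``gene_id, species, strand, exon_start, exon_end`` (one row
per CDS exon, 1-based inclusive genomic coordinates).

Annotated protein sets in this domain conventionally mark internal stop
codons and frameshifts with an uppercase ``'X'`` and unknown residues
(genome-assembly gaps) with a lowercase ``'x'``; both marker kinds are
recorded on read, but only ``'X'`` counts towards pseudogene calling,
and then only when it falls inside a conserved domain (terminal regions
of these genes are too hard to annotate to trust markers there).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from famevol.trees import SpeciesTree

__all__ = [
    "SequenceRecord",
    "GeneStructure",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "read_gene_structures",
    "write_gene_structures",
    "flag_pseudogene",
]


@dataclass
class SequenceRecord:
    """A named residue or nucleotide sequence.

    ``marker_positions`` holds the 1-based indices of ``'X'`` (internal
    stop/frameshift) and ``'x'`` (unknown residue) markers.
    """

    id: str
    seq: str
    marker_positions: List[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("empty sequence id")
        if not self.seq:
            raise ValueError(f"empty sequence for {self.id!r}")
        if not self.marker_positions:
            self.marker_positions = [
                i + 1 for i, ch in enumerate(self.seq) if ch in "Xx"
            ]
        for p in self.marker_positions:
            if not (1 <= p <= len(self.seq)):
                raise ValueError(f"marker position {p} outside sequence {self.id!r}")

    @property
    def stop_positions(self) -> List[int]:
        """1-based positions of uppercase 'X' markers only."""
        return [p for p in self.marker_positions if self.seq[p - 1] == "X"]


def read_fasta(path: str) -> List[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, in file order.

    Raises ``ValueError`` on duplicate ids or empty sequences.
    """
    records: List[SequenceRecord] = []
    seen = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq)))
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, path, "fasta")


def read_newick(source: str, require_binary: bool = True) -> SpeciesTree:
    """Parse a Newick string or file into a :class:`SpeciesTree`.

    Polytomies are rejected by default: the downstream birth-death
    reconciliation assumes a binary tree, and silently resolving a
    polytomy would fabricate branches with zero length.
    """
    return SpeciesTree.from_newick(source, require_binary=require_binary)


@dataclass
class GeneStructure:
    """CDS exon layout of one gene.

    ``exons`` are 1-based inclusive genomic intervals sorted in genomic
    order; for minus-strand genes coding order is the reverse of genomic
    order.
    """

    gene_id: str
    species: str
    strand: str
    exons: List[Tuple[int, int]]
    functional: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in exons:
            if a > b or a < 1:
                raise ValueError(f"{self.gene_id}: bad exon interval ({a},{b})")
        for (_, b1), (a2, _) in zip(exons, exons[1:]):
            if a2 <= b1:
                raise ValueError(f"{self.gene_id}: overlapping CDS intervals")
        self.exons = exons
        if self.functional and self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3 "
                "for a functional gene"
            )

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.exons)

    @property
    def coding_exons(self) -> List[Tuple[int, int]]:
        """Exons in coding (5'->3' mRNA) order."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1


_TSV_COLUMNS = ["gene_id", "species", "strand", "exon_start", "exon_end", "functional"]


def _read_structures_tsv(path: str) -> List[GeneStructure]:
    import csv

    rows = {}
    order: List[str] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            gid = row["gene_id"]
            if gid not in rows:
                order.append(gid)
                rows[gid] = {
                    "species": row.get("species", ""),
                    "strand": row["strand"],
                    "functional": row.get("functional", "1") not in ("0", "false", "False"),
                    "exons": [],
                }
            rows[gid]["exons"].append((int(row["exon_start"]), int(row["exon_end"])))
    return [
        GeneStructure(
            gene_id=gid,
            species=rows[gid]["species"],
            strand=rows[gid]["strand"],
            exons=rows[gid]["exons"],
            functional=rows[gid]["functional"],
        )
        for gid in order
    ]


def _read_structures_gff3(path: str) -> List[GeneStructure]:
    # Minimal GFF3 subset: CDS features grouped by Parent (mRNA) or ID.
    genes = {}
    order: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                continue
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts[:9]
            if ftype != "CDS":
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gid = attr.get("Parent") or attr.get("ID")
            if gid is None:
                raise ValueError(f"CDS feature without Parent/ID in {path}")
            if gid not in genes:
                order.append(gid)
                genes[gid] = {"species": seqid, "strand": strand, "exons": []}
            genes[gid]["exons"].append((int(start), int(end)))
    return [
        GeneStructure(
            gene_id=gid,
            species=genes[gid]["species"],
            strand=genes[gid]["strand"],
            exons=genes[gid]["exons"],
        )
        for gid in order
    ]


def read_gene_structures(path: str) -> List[GeneStructure]:
    """Read gene structures from GFF3 (``.gff``/``.gff3``) or the TSV dialect."""
    with open(path) as fh:
        head = fh.readline()
    if path.endswith((".gff", ".gff3")) or head.startswith("##gff"):
        return _read_structures_gff3(path)
    return _read_structures_tsv(path)


def write_gene_structures(structures: Sequence[GeneStructure], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for s in structures:
            for a, b in s.exons:
                fh.write(
                    f"{s.gene_id}\t{s.species}\t{s.strand}\t{a}\t{b}\t"
                    f"{1 if s.functional else 0}\n"
                )


def flag_pseudogene(record: SequenceRecord, domain_span: Tuple[int, int]) -> bool:
    """True iff an internal stop/frameshift marker ('X') lies in the domain.

    ``domain_span`` is a 1-based inclusive residue interval delimiting the
    conserved domain; lowercase 'x' (unknown residue) never triggers the
    flag.
    """
    lo, hi = domain_span
    if lo < 1 or hi > len(record.seq) or lo > hi:
        raise ValueError(
            f"domain span ({lo},{hi}) outside sequence {record.id!r} "
            f"of length {len(record.seq)}"
        )
    return any(lo <= p <= hi for p in record.stop_positions)
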