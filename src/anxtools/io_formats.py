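"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates crossing this boundary are GFF3-style 1-based
inclusive; every other module receives them unchanged, so any off-by-one
conversion lives here and nowhere else.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
NUCLEOTIDES = set("ACGT")
# Unknowns are legal residues but are never matched by motif patterns.
AMINO_ALPHABET = AMINO_ACIDS | {"X", "*", "-"}
NUC_ALPHABET = NUCLEOTIDES | {"N", "-"}


class FormatError(ValueError):
    """Malformed input file or violated table invariant."""


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record: identifier, free-text description, residues.

    Residues are case-folded to upper on construction.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise FormatError("sequence record with empty id")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)

    def validate_alphabet(self, kind: str = "protein") -> None:
        allowed = AMINO_ALPHABET if kind == "protein" else NUC_ALPHABET
        bad = set(self.residues) - allowed
        if bad:
            raise FormatError(
                f"record {self.id!r}: residues {sorted(bad)} outside the "
                f"{kind} alphabet"
            )


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (wrapped lines concatenated)."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"empty sequence for id {rec.id!r} in {path}")
        desc = rec.description[len(rec.id):].strip()
        records.append(SequenceRecord(id=rec.id, residues=seq, description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """Coding-exon structure of one transcript.

    ``exons`` are (start, end) pairs, 1-based inclusive genomic coordinates,
    ordered 5'→3' in transcription order (descending start on the minus
    strand). UTR exons are not represented; only coding exons count.
    """

    gene_id: str
    transcript_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise FormatError(f"{self.transcript_id}: strand must be + or -")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise FormatError(
                    f"{self.transcript_id}: overlapping coding exons "
                    f"({s1},{e1}) and ({s2},{e2})"
                )
        expect = tuple(genomic) if self.strand == "+" else tuple(genomic[::-1])
        if tuple(self.exons) != expect:
            raise FormatError(
                f"{self.transcript_id}: exons not in transcription order"
            )

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s + 1 for s, e in self.exons)

    @property
    def coding_length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def is_complete(self) -> bool:
        """True when the summed coding length is a whole number of codons."""
        return self.coding_length % 3 == 0

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)


def read_gff3(path) -> list[GeneModel]:
    """Parse gene/mRNA/CDS features into one GeneModel per mRNA.

    Minus-strand CDS features are reordered into transcription order.
    Raises FormatError for a CDS without a parent mRNA or overlapping CDS
    within one transcript.
    """
    db = gffutils.create_db(
        os.fspath(path), ":memory:", merge_strategy="create_unique",
        keep_order=True,
    )
    mrna_ids = {f.id for f in db.features_of_type("mRNA")}
    models = []
    for mrna in db.features_of_type("mRNA", order_by="start"):
        gene_parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = gene_parents[0].id if gene_parents else mrna.id
        cds = list(db.children(mrna, featuretype="CDS", order_by="start"))
        if not cds:
            continue
        exons = [(c.start, c.end) for c in cds]
        if mrna.strand == "-":
            exons = exons[::-1]
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=mrna.id,
                chromosome=mrna.seqid,
                strand=mrna.strand,
                exons=tuple(exons),
            )
        )
    # orphan CDS check: every CDS must name an mRNA parent that exists
    for c in db.features_of_type("CDS"):
        parents = c.attributes.get("Parent", [])
        if not parents or not any(p in mrna_ids for p in parents):
            raise FormatError(f"CDS at {c.seqid}:{c.start}-{c.end} has no parent mRNA")
    return models


def write_gff3(models: Sequence[GeneModel], path) -> None:
    lines = ["##gff-version 3"]
    for m in models:
        g_start, g_end = m.start, m.end
        lines.append(
            f"{m.chromosome}\tanxtools\tgene\t{g_start}\t{g_end}\t.\t{m.strand}\t.\t"
            f"ID={m.gene_id}"
        )
        lines.append(
            f"{m.chromosome}\tanxtools\tmRNA\t{g_start}\t{g_end}\t.\t{m.strand}\t.\t"
            f"ID={m.transcript_id};Parent={m.gene_id}"
        )
        for s, e in sorted(m.exons):
            lines.append(
                f"{m.chromosome}\tanxtools\tCDS\t{s}\t{e}\t.\t{m.strand}\t0\t"
                f"ID=cds-{m.transcript_id};Parent={m.transcript_id}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# tab-separated tables
# ---------------------------------------------------------------------------

@dataclass
class GenomeOrderTable:
    """Per chromosome, every gene id ordered by ascending start coordinate.

    The order index of a gene is its rank among all genes on its chromosome
    (ties broken by lexicographic gene id), which is the distance unit of the
    tandem-duplication rule.
    """

    by_chromosome: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, int]]) -> "GenomeOrderTable":
        by_chrom: dict[str, list[tuple[str, int]]] = {}
        for chrom, gene_id, start in rows:
            by_chrom.setdefault(chrom, []).append((gene_id, int(start)))
        for chrom in by_chrom:
            by_chrom[chrom].sort(key=lambda t: (t[1], t[0]))
        return cls(by_chromosome=by_chrom)

    def order_index(self, chromosome: str, gene_id: str) -> int:
        genes = self.by_chromosome.get(chromosome, [])
        for i, (gid, _) in enumerate(genes):
            if gid == gene_id:
                return i
        raise KeyError(f"gene {gene_id!r} not in genome order on {chromosome!r}")

    def chromosome_of(self, gene_id: str) -> str:
        for chrom, genes in self.by_chromosome.items():
            if any(gid == gene_id for gid, _ in genes):
                return chrom
        raise KeyError(f"gene {gene_id!r} not in genome order")


@dataclass
class CollinearPairTable:
    """Unordered collinear gene pairs with their block ids; (a,b) ≡ (b,a)."""

    pairs: list[tuple[str, str, str]] = field(default_factory=list)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, str]]) -> "CollinearPairTable":
        seen: set[tuple[str, str]] = set()
        stored = []
        for a, b, block in rows:
            if a == b:
                raise FormatError(f"self-pair {a!r} in collinear pair table")
            key = (min(a, b), max(a, b))
            if key in seen:
                continue
            seen.add(key)
            stored.append((key[0], key[1], block))
        return cls(pairs=stored)


@dataclass
class DomainAnnotationTable:
    """Annexin-domain intervals per protein, 1-based inclusive, ascending."""

    by_protein: dict[str, list[tuple[int, int, int]]] = field(default_factory=dict)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, int, int, int]]) -> "DomainAnnotationTable":
        by_prot: dict[str, list[tuple[int, int, int]]] = {}
        for pid, idx, start, end in rows:
            idx, start, end = int(idx), int(start), int(end)
            if not 1 <= idx <= 4:
                raise FormatError(f"{pid}: domain index {idx} outside 1-4")
            if start > end or start < 1:
                raise FormatError(f"{pid}: bad domain interval ({start},{end})")
            by_prot.setdefault(pid, []).append((idx, start, end))
        for pid, doms in by_prot.items():
            if len(doms) > 4:
                raise FormatError(f"{pid}: more than 4 domains")
            if [d[0] for d in doms] != sorted({d[0] for d in doms}):
                raise FormatError(f"{pid}: domain indices out of order or duplicated")
            for (_, _, e1), (_, s2, _) in zip(doms, doms[1:]):
                if s2 <= e1:
                    raise FormatError(f"{pid}: domains overlap or out of order")
        return cls(by_protein=by_prot)


@dataclass
class ClockRateTable:
    """Species → λ, synonymous substitutions per synonymous site per year."""

    rates: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, float]]) -> "ClockRateTable":
        rates = {}
        for species, lam in rows:
            lam = float(lam)
            if lam <= 0:
                raise FormatError(f"{species}: clock rate λ must be > 0, got {lam}")
            rates[species] = lam
        return cls(rates=rates)


_TABLE_SCHEMAS = {
    "genome_order": (("chromosome", "gene_id", "start"), GenomeOrderTable),
    "collinear_pairs": (("gene_id_a", "gene_id_b", "block_id"), CollinearPairTable),
    "domains": (("protein_id", "domain_index", "start", "end"), DomainAnnotationTable),
    "clock_rates": (("species", "lambda"), ClockRateTable),
}


def read_tables(path, kind: str):
    """Read one of the four TSV table kinds with invariant checks.

    kind ∈ {genome_order, collinear_pairs, domains, clock_rates}.
    """
    if kind not in _TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    columns, cls = _TABLE_SCHEMAS[kind]
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != columns:
            raise FormatError(
                f"{path}: expected header {columns}, got {tuple(header)}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(columns):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(columns)} fields, got {len(parts)}"
                )
            rows.append(tuple(parts))
    try:
        return cls.from_rows(rows)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_table(rows: Sequence[Mapping], columns: Sequence[str], path) -> None:
    """Write rows of dicts as a TSV with the given column order."""
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")
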