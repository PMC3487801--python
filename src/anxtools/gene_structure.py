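"""Intron phases, splicing-pattern cataloguing and intron-loss tests.

The phase of an intron is the cumulative coding length upstream of it mod 3:
phase 0 falls between codons, phase 1 after the first base of a codon and
phase 2 after the second. Genes sharing exon count and intron-phase string
(optionally also an exon-length signature) form one splicing pattern, and a
pattern catalog partitions a gene set into such classes. Pattern B is an
intron-loss derivative of pattern A when every intron of B matches an intron
of A at the same (projected) alignment position and phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .io_formats import FormatError, GeneModel


@dataclass(frozen=True)
class IntronRecord:
    index: int  # ordinal in transcription order, 0-based
    phase: int  # 0 | 1 | 2
    upstream_coding_length: int


@dataclass(frozen=True)
class SplicingPattern:
    exon_count: int
    phase_string: str  # one digit per intron, transcription order
    exon_length_signature: Optional[tuple[int, ...]] = None

    def __post_init__(self):
        if len(self.phase_string) != self.exon_count - 1:
            raise ValueError("phase string length must equal exon_count - 1")


@dataclass
class PatternCatalog:
    """Distinct splicing patterns with their member genes.

    ``patterns`` maps pattern number (1-based, assigned by exon count
    descending then phase string lexicographic) to (pattern, member ids).
    """

    patterns: dict[int, tuple[SplicingPattern, list[str]]] = field(default_factory=dict)

    @property
    def n_patterns(self) -> int:
        return len(self.patterns)

    def members(self, number: int) -> list[str]:
        return self.patterns[number][1]


@dataclass(frozen=True)
class ProjectedIntron:
    column: int  # 1-based alignment column
    phase: int


def compute_intron_phases(model: GeneModel) -> list[IntronRecord]:
    """Phase of every intron of a complete-CDS gene model.

    An intronless model yields an empty list; an incomplete CDS is an error.
    """
    if not model.is_complete:
        raise FormatError(
            f"{model.transcript_id}: coding length {model.coding_length} is not "
            "a whole number of codons; cannot compute intron phases"
        )
    records = []
    upstream = 0
    for i, length in enumerate(model.exon_lengths[:-1]):
        upstream += length
        records.append(IntronRecord(index=i, phase=upstream % 3,
                                    upstream_coding_length=upstream))
    return records


def phase_string(model: GeneModel) -> str:
    return "".join(str(r.phase) for r in compute_intron_phases(model))


def _signatures_match(a: Sequence[int], b: Sequence[int], tolerance: float) -> bool:
    if len(a) != len(b):
        return False
    return all(abs(x - y) <= tolerance * max(x, y) for x, y in zip(a, b))


def catalog_patterns(genes: Iterable[GeneModel],
                     use_length_signature: bool = False,
                     length_tolerance: float = 0.10) -> PatternCatalog:
    """Partition genes into splicing patterns.

    Identity is (exon_count, phase_string); with ``use_length_signature`` the
    exon-length signatures must additionally agree within a relative
    ``length_tolerance`` per exon. Genes are processed in a deterministic
    order so the catalog never depends on input ordering.
    """
    ordered = sorted(
        genes,
        key=lambda g: (len(g.exons), phase_string(g), g.exon_lengths, g.gene_id),
    )
    groups: list[tuple[SplicingPattern, list[str]]] = []
    for g in ordered:
        ps = phase_string(g)
        sig = g.exon_lengths if use_length_signature else None
        placed = False
        for pat, members in groups:
            if pat.exon_count != len(g.exons) or pat.phase_string != ps:
                continue
            if use_length_signature and not _signatures_match(
                    pat.exon_length_signature, sig, length_tolerance):
                continue
            members.append(g.gene_id)
            placed = True
            break
        if not placed:
            groups.append(
                (SplicingPattern(len(g.exons), ps, sig), [g.gene_id])
            )
    groups.sort(key=lambda t: (-t[0].exon_count, t[0].phase_string,
                               t[0].exon_length_signature or ()))
    catalog = PatternCatalog()
    for number, (pat, members) in enumerate(groups, start=1):
        catalog.patterns[number] = (pat, sorted(members))
    return catalog


def project_introns_to_alignment(model: GeneModel,
                                 aligned_protein_row: str,
                                 gap_chars: str = "-.") -> list[ProjectedIntron]:
    """Map each intron to the alignment column of the codon it interrupts.

    A phase-0 intron (between codons) maps to the column of the codon
    immediately upstream of the junction; phase 1/2 introns map to the codon
    the junction splits. The ungapped row must have one residue per codon.
    """
    residues = [c for c in aligned_protein_row if c not in gap_chars]
    n_codons = model.coding_length // 3
    if len(residues) != n_codons:
        raise FormatError(
            f"{model.transcript_id}: aligned row has {len(residues)} residues "
            f"but the CDS encodes {n_codons} codons"
        )
    # column of each residue, 1-based
    col_of_residue = []
    for col, c in enumerate(aligned_protein_row, start=1):
        if c not in gap_chars:
            col_of_residue.append(col)
    out = []
    for rec in compute_intron_phases(model):
        codon_index = -(-rec.upstream_coding_length // 3)  # ceil
        out.append(ProjectedIntron(column=col_of_residue[codon_index - 1],
                                   phase=rec.phase))
    return out


def is_intron_loss_derivative(patternA_projected: Sequence[ProjectedIntron],
                              patternB_projected: Sequence[ProjectedIntron],
                              column_tolerance: int = 1
                              ) -> tuple[bool, list[ProjectedIntron]]:
    """Can B be derived from A purely by losing introns?

    True iff every intron of B matches a distinct intron of A with equal
    phase within ``column_tolerance`` alignment columns. Returns the introns
    of A that are absent from B (the lost set; empty when the test fails).
    """
    remaining = list(patternA_projected)
    for b in patternB_projected:
        candidates = [
            a for a in remaining
            if a.phase == b.phase and abs(a.column - b.column) <= column_tolerance
        ]
        if not candidates:
            return False, []
        best = min(candidates, key=lambda a: abs(a.column - b.column))
        remaining.remove(best)
    return True, remaining
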