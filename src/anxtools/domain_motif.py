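"""Motif scanning over the four annexin core domains.

The annexin tetrad carries, per domain, an optional type II calcium-binding
site (CBS): the anchor G-x-G-T followed by a fixed spacer (38 residues in the
canonical description) and then an acidic residue (D/E). Domains may instead
carry a *degenerate* ("mutated") site — either the anchor without the acidic
residue, or the acidic residue behind an anchor with a single mismatched
position. K/R/HGD tripeptides, the actin-binding IRI tripeptide, the GTPase
DXXG tetrapeptide and a conserved histidine are scanned alongside, and each
tripeptide is related to the nearest CBS (overlapping / adjacent / none).

Scanning is case-insensitive; the unknown residue 'X' never matches any
pattern position, including wildcards.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .io_formats import AMINO_ACIDS, FormatError

GAP_CHARS = {"-", ".", "*"}
ACIDIC = {"D", "E"}
MAX_INFO_BITS = math.log2(20)

DEFAULT_SPACER_MIN = 38
DEFAULT_SPACER_MAX = 38
DEFAULT_ADJACENCY_WINDOW = 5


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence inside one domain slice.

    ``start``/``end`` are 1-based inclusive offsets within the domain.
    ``status`` distinguishes canonical from degenerate CBS; ``detail`` names
    the failing component of a degenerate site. ``cbs_relation`` is filled in
    for K/R/HGD hits only.
    """

    kind: str  # CBS | KGD | RGD | HGD | IRI | DXXG | HIS
    domain_index: int
    start: int
    end: int
    status: str = "canonical"
    detail: str = ""
    cbs_relation: Optional[str] = None


@dataclass(frozen=True)
class AnnexinDomainSet:
    """The tetrad domain slices of one protein.

    ``domains`` maps domain index (1-4) to (residue slice, 1-based protein
    offset of the slice start).
    """

    protein_id: str
    domains: Mapping[int, tuple[str, int]]

    @classmethod
    def from_annotation(cls, protein_id: str, residues: str,
                        intervals: Sequence[tuple[int, int, int]]) -> "AnnexinDomainSet":
        doms = {}
        for idx, start, end in intervals:
            if end > len(residues):
                raise FormatError(
                    f"{protein_id}: domain {idx} interval ({start},{end}) exceeds "
                    f"protein length {len(residues)}"
                )
            doms[idx] = (residues[start - 1:end].upper(), start)
        return cls(protein_id=protein_id, domains=doms)


@dataclass(frozen=True)
class LogoColumn:
    position: int
    frequencies: Mapping[str, float]
    information: float


def _check_protein_alphabet(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - AMINO_ACIDS - {"X"} - GAP_CHARS
    if bad:
        raise FormatError(f"non-amino-acid characters in domain slice: {sorted(bad)}")
    return seq


def _anchor_mismatches(seq: str, i: int) -> Optional[int]:
    """Number of mismatched positions of the G-x-G-T anchor at 0-based i.

    Returns None when the window runs off the sequence. 'X' (and gaps) fail
    every position, including the wildcard.
    """
    if i + 4 > len(seq):
        return None
    window = seq[i:i + 4]
    mism = 0
    for pos, want in enumerate("G.GT"):
        ch = window[pos]
        if ch not in AMINO_ACIDS:
            mism += 1
        elif want != "." and ch != want:
            mism += 1
    return mism


def scan_type2_cbs(domain_slice: str,
                   spacer_min: int = DEFAULT_SPACER_MIN,
                   spacer_max: int = DEFAULT_SPACER_MAX,
                   domain_index: int = 0) -> list[MotifHit]:
    """Scan one domain slice for canonical and degenerate type II CBS.

    Canonical: G-x-G-T, then k residues (spacer_min ≤ k ≤ spacer_max), then
    D or E. Degenerate: (a) intact anchor with no acidic residue anywhere in
    the spacer window, or (b) an acidic residue at canonical distance behind
    an anchor with exactly one mismatched position. Overlapping hits are all
    reported.
    """
    if not (0 < spacer_min <= spacer_max):
        raise ValueError("need 0 < spacer_min <= spacer_max")
    seq = _check_protein_alphabet(domain_slice)
    hits: list[MotifHit] = []
    for i in range(len(seq)):
        mism = _anchor_mismatches(seq, i)
        if mism is None:
            break
        acidic_at = [
            i + 4 + k
            for k in range(spacer_min, spacer_max + 1)
            if i + 4 + k < len(seq) and seq[i + 4 + k] in ACIDIC
        ]
        if mism == 0:
            if acidic_at:
                for j in acidic_at:
                    hits.append(MotifHit("CBS", domain_index, i + 1, j + 1,
                                         status="canonical"))
            elif i + 4 + spacer_min < len(seq):
                # anchor intact but the spacer window carries no acidic residue
                end = min(i + 4 + spacer_max, len(seq) - 1)
                hits.append(MotifHit("CBS", domain_index, i + 1, end + 1,
                                     status="degenerate", detail="missing_acidic"))
        elif mism == 1 and acidic_at:
            for j in acidic_at:
                hits.append(MotifHit("CBS", domain_index, i + 1, j + 1,
                                     status="degenerate", detail="anchor_mismatch"))
    return hits


def classify_domain_cbs(domain_set: AnnexinDomainSet,
                        hits: Iterable[MotifHit]) -> tuple[dict[int, str], int]:
    """Per-domain CBS status (present / degenerate / absent) and the
    protein-level CBS count (domains with status present)."""
    by_domain: dict[int, list[MotifHit]] = {}
    for h in hits:
        if h.kind == "CBS":
            by_domain.setdefault(h.domain_index, []).append(h)
    statuses: dict[int, str] = {}
    for idx in sorted(domain_set.domains):
        dhits = by_domain.get(idx, [])
        if any(h.status == "canonical" for h in dhits):
            statuses[idx] = "present"
        elif dhits:
            statuses[idx] = "degenerate"
        else:
            statuses[idx] = "absent"
    count = sum(1 for s in statuses.values() if s == "present")
    return statuses, count


def scan_alt_motifs(domain_slice: str, domain_index: int = 0,
                    his_region: Optional[tuple[int, int]] = None) -> list[MotifHit]:
    """Report every K/R/HGD tripeptide, IRI tripeptide and DXXG tetrapeptide.

    Conserved-histidine hits are emitted only when the caller supplies the
    expected region (1-based inclusive within the domain), since the His
    check is positional and the scanner itself is region-agnostic.
    """
    seq = _check_protein_alphabet(domain_slice)
    hits: list[MotifHit] = []
    for i in range(len(seq) - 2):
        tri = seq[i:i + 3]
        if tri[0] in "KRH" and tri[1] == "G" and tri[2] == "D":
            hits.append(MotifHit(tri[0] + "GD", domain_index, i + 1, i + 3))
        if tri == "IRI":
            hits.append(MotifHit("IRI", domain_index, i + 1, i + 3))
    for i in range(len(seq) - 3):
        win = seq[i:i + 4]
        if (win[0] == "D" and win[3] == "G"
                and win[1] in AMINO_ACIDS and win[2] in AMINO_ACIDS):
            hits.append(MotifHit("DXXG", domain_index, i + 1, i + 4))
    if his_region is not None:
        lo, hi = his_region
        for i in range(lo - 1, min(hi, len(seq))):
            if seq[i] == "H":
                hits.append(MotifHit("HIS", domain_index, i + 1, i + 1))
    return hits


def relate_motif_to_cbs(tripeptide_hit: MotifHit,
                        cbs_hits: Iterable[MotifHit],
                        adjacency_window: int = DEFAULT_ADJACENCY_WINDOW) -> str:
    """Relation of a tripeptide to the CBS hits of the same domain.

    overlapping — intervals intersect; adjacent — disjoint with at most
    ``adjacency_window`` residues strictly between them; none otherwise.
    """
    relation = "none"
    for cbs in cbs_hits:
        if cbs.kind != "CBS" or cbs.domain_index != tripeptide_hit.domain_index:
            continue
        if tripeptide_hit.start <= cbs.end and cbs.start <= tripeptide_hit.end:
            return "overlapping"
        gap = max(tripeptide_hit.start - cbs.end, cbs.start - tripeptide_hit.end) - 1
        if gap <= adjacency_window:
            relation = "adjacent"
    return relation


def scan_protein(domain_set: AnnexinDomainSet,
                 spacer_min: int = DEFAULT_SPACER_MIN,
                 spacer_max: int = DEFAULT_SPACER_MAX,
                 adjacency_window: int = DEFAULT_ADJACENCY_WINDOW) -> list[MotifHit]:
    """Full scan of one protein: CBS plus alternative motifs, with the
    CBS relation filled in for every K/R/HGD hit."""
    all_hits: list[MotifHit] = []
    for idx, (slc, _offset) in sorted(domain_set.domains.items()):
        cbs = scan_type2_cbs(slc, spacer_min, spacer_max, domain_index=idx)
        alt = scan_alt_motifs(slc, domain_index=idx)
        related = [
            replace(h, cbs_relation=relate_motif_to_cbs(h, cbs, adjacency_window))
            if h.kind in ("KGD", "RGD", "HGD") else h
            for h in alt
        ]
        all_hits.extend(cbs)
        all_hits.extend(related)
    return all_hits


# ---------------------------------------------------------------------------
# sequence-logo information content
# ---------------------------------------------------------------------------

def column_information(alignment_column: Sequence[str], position: int = 0) -> LogoColumn:
    """Shannon information of one alignment column in bits.

    information = log2(20) − H(column), with gaps excluded from the
    frequencies. No small-sample correction is applied.
    """
    residues = [c.upper() for c in alignment_column if c.upper() not in GAP_CHARS]
    if not residues:
        raise FormatError(f"column {position}: all gaps")
    counts = Counter(residues)
    total = len(residues)
    freqs = {aa: n / total for aa, n in counts.items()}
    entropy = -sum(f * math.log2(f) for f in freqs.values())
    info = max(0.0, MAX_INFO_BITS - entropy)
    return LogoColumn(position=position, frequencies=freqs, information=info)


def alignment_information(rows: Sequence[str]) -> list[LogoColumn]:
    """Per-column logo statistics for an aligned set of equal-length rows."""
    if not rows:
        return []
    n = len(rows[0])
    if any(len(r) != n for r in rows):
        raise FormatError("alignment rows differ in length")
    return [
        column_information([r[i] for r in rows], position=i + 1)
        for i in range(n)
        if any(r[i].upper() not in GAP_CHARS for r in rows)
    ]
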