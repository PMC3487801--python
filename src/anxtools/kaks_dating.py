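"""Nei–Gojobori (1986) Ka/Ks estimation and molecular-clock dating.

For an in-frame pair of coding sequences the NG86 method counts, per codon,
the expected numbers of synonymous (S) and nonsynonymous (N) sites — each of
the three positions contributes the fraction of its possible point mutations
that are synonymous, with mutations to stop codons excluded from the
numerator but kept in the denominator of 3 — and, per differing codon pair,
the synonymous/nonsynonymous differences (Sd, Nd) averaged with equal weight
over all substitution orderings, dropping orderings that pass through a stop
codon. The proportions pS = Sd/S and pN = Nd/N are corrected for multiple
hits with the one-parameter (Jukes–Cantor) formula d = −(3/4)·ln(1 − 4p/3).

The age of a duplicate gene pair follows from the synonymous distance and a
species-specific synonymous substitution rate λ (substitutions per
synonymous site per year) as T = Ks / (2λ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Optional

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .io_formats import FormatError

_STANDARD = unambiguous_dna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(GENETIC_CODE))
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# site and difference counting
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Each position contributes (synonymous non-stop mutants)/3 to s; n = 3 − s.
    """
    codon = codon.upper()
    aa = GENETIC_CODE.get(codon)
    if aa is None:
        raise FormatError(f"stop or ambiguous codon {codon!r}")
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if mutant in STOP_CODONS:
                continue  # excluded from the numerator, denominator stays 3
            if GENETIC_CODE[mutant] == aa:
                s += 1.0 / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _pathway_average(codon_a: str, codon_b: str) -> Optional[tuple[float, float]]:
    """(Sd, Nd) between two sense codons, averaged over substitution orderings.

    Orderings passing through a stop codon are dropped and the rest
    re-averaged; None when every ordering is blocked.
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    totals = []
    for order in permutations(diff_positions):
        current = codon_a
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[current]:
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        if not blocked:
            totals.append((sd, nd))
    if not totals:
        return None
    return (sum(t[0] for t in totals) / len(totals),
            sum(t[1] for t in totals) / len(totals))


def pathway_oracle(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Brute-force (Sd, Nd) between two sense codons by exhaustive recursion.

    Enumerates every substitution ordering step by step, classifying each
    step against the current intermediate; orderings through stop codons are
    dropped. Kept independent of the tabulated route used by ``ng86`` so the
    two can be cross-checked.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for c in (codon_a, codon_b):
        if c not in GENETIC_CODE:
            raise FormatError(f"stop or ambiguous codon {c!r}")

    outcomes: list[tuple[float, float]] = []

    def walk(current: str, sd: float, nd: float) -> None:
        remaining = [i for i in range(3) if current[i] != codon_b[i]]
        if not remaining:
            outcomes.append((sd, nd))
            return
        for pos in remaining:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS:
                continue
            if GENETIC_CODE[nxt] == GENETIC_CODE[current]:
                walk(nxt, sd + 1.0, nd)
            else:
                walk(nxt, sd, nd + 1.0)

    walk(codon_a, 0.0, 0.0)
    if not outcomes:
        return math.nan, math.nan
    # weight each completed path by the number of orderings it represents:
    # the recursion yields exactly one leaf per unblocked ordering
    return (sum(o[0] for o in outcomes) / len(outcomes),
            sum(o[1] for o in outcomes) / len(outcomes))


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonAlignment:
    """An in-frame aligned pair of coding sequences, codon-column filtered.

    Columns containing a gap or ambiguous base in either sequence are
    excluded before counting; the number of excluded columns is retained.
    A shared terminal stop column is stripped; an internal stop is an error.
    """

    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]
    excluded_columns: int

    @classmethod
    def from_sequences(cls, seq_a: str, seq_b: str) -> "CodonAlignment":
        seq_a, seq_b = seq_a.upper(), seq_b.upper()
        if len(seq_a) != len(seq_b):
            raise FormatError("aligned sequences differ in length")
        if len(seq_a) % 3:
            raise FormatError("aligned length is not a multiple of 3")
        raw = [(seq_a[i:i + 3], seq_b[i:i + 3]) for i in range(0, len(seq_a), 3)]
        if raw and raw[-1][0] in STOP_CODONS and raw[-1][1] in STOP_CODONS:
            raw = raw[:-1]
        a_list, b_list, excluded = [], [], 0
        for col, (ca, cb) in enumerate(raw, start=1):
            if not (set(ca) <= set(_BASES) and set(cb) <= set(_BASES)):
                excluded += 1
                continue
            if ca in STOP_CODONS or cb in STOP_CODONS:
                raise FormatError(f"internal stop codon at codon column {col}")
            a_list.append(ca)
            b_list.append(cb)
        return cls(tuple(a_list), tuple(b_list), excluded)

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)


@dataclass(frozen=True)
class KaKsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: Optional[float]
    Ka: Optional[float]
    ratio: Optional[float]
    codons_counted: int
    excluded_gap_columns: int
    excluded_stop_pathway: int
    saturated_s: bool
    saturated_n: bool


def jukes_cantor(p: float) -> Optional[float]:
    """One-parameter multiple-hit correction; None at/beyond saturation."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86(alignment: CodonAlignment) -> KaKsResult:
    """Nei–Gojobori Ka/Ks for one aligned coding pair."""
    if alignment.n_codons < 1:
        raise FormatError("alignment has no countable codons")
    S = N = Sd = Nd = 0.0
    counted = 0
    excluded_stop = 0
    for ca, cb in zip(alignment.codons_a, alignment.codons_b):
        diffs = _pathway_average(ca, cb)
        if diffs is None:
            excluded_stop += 1
            continue
        sa, na = codon_site_counts(ca)
        sb, nb = codon_site_counts(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        Sd += diffs[0]
        Nd += diffs[1]
        counted += 1
    if counted == 0:
        raise FormatError("all codon columns excluded")
    if S == 0 and Sd > 0:
        raise FormatError("synonymous differences found with zero synonymous sites")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = jukes_cantor(pS)
    Ka = jukes_cantor(pN)
    ratio = None
    if Ks is not None and Ka is not None and Ks > 0:
        ratio = Ka / Ks
    return KaKsResult(
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, Ks=Ks, Ka=Ka, ratio=ratio,
        codons_counted=counted,
        excluded_gap_columns=alignment.excluded_columns,
        excluded_stop_pathway=excluded_stop,
        saturated_s=Ks is None, saturated_n=Ka is None,
    )


# ---------------------------------------------------------------------------
# dating and selection classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeEstimate:
    species: str
    clock_rate: float
    T_years: float
    T_mya: float  # rounded per the reporting convention


def _round_mya(t_mya: float, mode: str) -> float:
    scaled = t_mya * 100.0
    if mode == "truncate":
        return math.floor(scaled + 1e-9) / 100.0
    if mode == "half_up":
        return math.floor(scaled + 0.5) / 100.0
    raise ValueError(f"unknown rounding mode {mode!r}")


def estimate_age(ks: float, clock_rate: float, species: str = "",
                 rounding: str = "truncate") -> AgeEstimate:
    """Duplication age T = Ks / (2λ).

    ``T_mya`` is reported to two decimals; the default convention truncates
    (the convention of the reference literature values this reproduces),
    half-up rounding is available via ``rounding``.
    """
    if ks < 0:
        raise ValueError("Ks must be >= 0")
    if clock_rate <= 0:
        raise ValueError("clock rate λ must be > 0")
    t_years = ks / (2.0 * clock_rate)
    return AgeEstimate(
        species=species, clock_rate=clock_rate, T_years=t_years,
        T_mya=_round_mya(t_years / 1e6, rounding),
    )


def classify_selection(ratio: float, tolerance: float = 0.0) -> str:
    """Selection regime from Ka/Ks: purifying (<1), neutral (=1), positive (>1)."""
    if ratio < 0:
        raise ValueError("Ka/Ks ratio must be >= 0")
    if abs(ratio - 1.0) <= tolerance:
        return "neutral"
    return "positive" if ratio > 1.0 + tolerance else "purifying"
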