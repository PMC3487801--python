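"""Seeded generators for every input the pipeline consumes, with truth labels.

Each generator draws from its own named pseudo-random stream derived from the
single user seed, so adding or re-running one generator never perturbs the
output of another. The generated data emulate the shapes the analysis is
designed for: four-domain annexin-like proteins with planted canonical or
degenerate calcium-binding sites and K/R/HGD plants, gene models instantiated
from splicing-pattern templates, chromosomes with planted tandem clusters and
collinear (segmental) pairs, and codon-alignment pairs carrying an exact
number of planted synonymous/nonsynonymous substitution events.

Backgrounds are uniform over the 20 amino acids (or 61 sense codons) and are
rejection-sampled so that a scan of the finished entity reports exactly the
planted truth — precision/recall accounting against the truth tables is then
exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import domain_motif as dm
from .duplication import GeneLocus
from .io_formats import (
    CollinearPairTable,
    DomainAnnotationTable,
    GeneModel,
    GenomeOrderTable,
    SequenceRecord,
)
from .kaks_dating import GENETIC_CODE, SENSE_CODONS, STOP_CODONS, _pathway_average

_AA = "ACDEFGHIKLMNPQRSTVWY"
_STREAMS = {"proteins": 11, "gene_models": 23, "genome": 37, "codons": 53}

DOMAIN_LENGTH = 70
SPACER = 38  # canonical anchor-to-acidic spacing
NTERM_LENGTH = 12  # short plant-annexin-style amino-terminal region


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


# ---------------------------------------------------------------------------
# proteins with planted motifs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainPlan:
    """Planted configuration of one protein's tetrad.

    ``cbs`` gives the CBS status per domain (canonical | degenerate | absent);
    ``tripeptides`` plants K/R/HGD motifs as (domain_index, kind, relation)
    with relation in {overlapping, adjacent, none}.
    """

    cbs: tuple[str, str, str, str]
    tripeptides: tuple[tuple[int, str, str], ...] = ()

    def __post_init__(self):
        for status in self.cbs:
            if status not in ("canonical", "degenerate", "absent"):
                raise ValueError(f"unknown CBS status {status!r}")
        for dom, kind, relation in self.tripeptides:
            if kind not in ("KGD", "RGD", "HGD"):
                raise ValueError(f"unknown tripeptide kind {kind!r}")
            if relation not in ("overlapping", "adjacent", "none"):
                raise ValueError(f"unknown relation {relation!r}")
            if relation != "none" and self.cbs[dom - 1] == "absent":
                raise ValueError(
                    f"tripeptide relation {relation!r} planted in domain {dom} "
                    "without a CBS"
                )


@dataclass
class TruthBundle:
    """Generated inputs plus their truth tables."""

    proteins: list[SequenceRecord] = field(default_factory=list)
    domain_table: Optional[DomainAnnotationTable] = None
    motif_truth: list[dict] = field(default_factory=list)
    gene_models: list[GeneModel] = field(default_factory=list)
    structure_truth: list[dict] = field(default_factory=list)
    genome_order: Optional[GenomeOrderTable] = None
    family_loci: list[GeneLocus] = field(default_factory=list)
    pair_table: Optional[CollinearPairTable] = None
    duplication_truth: dict = field(default_factory=dict)


def _expected_hits(plants: list[dict]) -> set[tuple]:
    return {
        (p["kind"], p["start"], p["status"], p.get("relation")) for p in plants
    }


def _build_domain(rng: np.random.Generator, status: str,
                  tripeptides: Sequence[tuple[str, str]],
                  adjacency_window: int) -> tuple[str, list[dict]]:
    """One ~70-residue domain with its plants; rejection-sampled so a scan
    reports exactly the planted truth."""
    for _attempt in range(500):
        seq = list(rng.choice(list(_AA), size=DOMAIN_LENGTH))
        plants: list[dict] = []
        cbs_interval = None
        anchor = None
        if status != "absent":
            # reserve room: adjacent tripeptides sit after the acidic residue,
            # 'none' ones need clearance before the anchor
            lo, hi = 0, DOMAIN_LENGTH - (SPACER + 5)
            if any(rel == "adjacent" for _, rel in tripeptides):
                hi = min(hi, DOMAIN_LENGTH - (SPACER + 5) - adjacency_window - 3)
            if any(rel == "none" for _, rel in tripeptides):
                lo = max(lo, adjacency_window + 7)
            anchor = int(rng.integers(lo, hi + 1))
            wildcard = str(rng.choice(list(_AA)))
            acidic = str(rng.choice(["D", "E"]))
            if status == "canonical":
                seq[anchor:anchor + 4] = list("G" + wildcard + "GT")
                seq[anchor + 4 + SPACER] = acidic
                plants.append({"kind": "CBS", "start": anchor + 1,
                               "status": "canonical"})
                cbs_interval = (anchor + 1, anchor + 4 + SPACER + 1)
            else:
                variant = str(rng.choice(["missing_acidic", "anchor_mismatch"]))
                if variant == "missing_acidic":
                    seq[anchor:anchor + 4] = list("G" + wildcard + "GT")
                    non_acidic = str(rng.choice([a for a in _AA if a not in "DE"]))
                    seq[anchor + 4 + SPACER] = non_acidic
                    end = min(anchor + 4 + SPACER, DOMAIN_LENGTH - 1)
                    cbs_interval = (anchor + 1, end + 1)
                else:
                    pattern = list("G" + wildcard + "GT")
                    mis_pos = int(rng.choice([0, 2, 3]))
                    choices = [a for a in _AA if a != pattern[mis_pos]]
                    pattern[mis_pos] = str(rng.choice(choices))
                    seq[anchor:anchor + 4] = pattern
                    seq[anchor + 4 + SPACER] = acidic
                    cbs_interval = (anchor + 1, anchor + 4 + SPACER + 1)
                plants.append({"kind": "CBS", "start": anchor + 1,
                               "status": "degenerate"})
        for kind, relation in tripeptides:
            if relation == "overlapping":
                # inside the spacer, clear of anchor and acidic position
                pos = int(rng.integers(anchor + 5, anchor + SPACER - 2))
            elif relation == "adjacent":
                gap = int(rng.integers(1, adjacency_window + 1))
                pos = cbs_interval[1] + gap  # 0-based start just past the CBS
            else:
                if anchor is not None:
                    pos = int(rng.integers(0, anchor - adjacency_window - 5))
                else:
                    pos = int(rng.integers(0, DOMAIN_LENGTH - 3))
            seq[pos:pos + 3] = list(kind[0] + "GD")
            plants.append({"kind": kind, "start": pos + 1,
                           "status": "canonical", "relation": relation})
        domain = "".join(seq)
        cbs_hits = dm.scan_type2_cbs(domain, SPACER, SPACER, domain_index=1)
        alt_hits = [
            h for h in dm.scan_alt_motifs(domain, domain_index=1)
            if h.kind in ("KGD", "RGD", "HGD")
        ]
        got = {(h.kind, h.start, h.status, None) for h in cbs_hits} | {
            (h.kind, h.start, h.status,
             dm.relate_motif_to_cbs(h, cbs_hits, adjacency_window))
            for h in alt_hits
        }
        # DXXG / IRI must not occur unless planted (never planted here)
        extra = [h for h in dm.scan_alt_motifs(domain, domain_index=1)
                 if h.kind in ("DXXG", "IRI")]
        if not extra and got == _expected_hits(plants):
            return domain, plants
    raise RuntimeError("could not realise domain plan without accidental motifs")


def gen_proteins(seed: int, n: int,
                 domain_plan: DomainPlan | Sequence[DomainPlan],
                 adjacency_window: int = dm.DEFAULT_ADJACENCY_WINDOW
                 ) -> tuple[list[SequenceRecord], DomainAnnotationTable, list[dict]]:
    """Generate n four-domain proteins realising the given plan(s).

    Plans are cycled over proteins when a sequence of plans is given. Returns
    (records, domain annotation table, truth rows); truth rows carry
    protein_id, domain_index, kind, start (1-based within the domain),
    status, relation and the planned per-domain CBS status.
    """
    plans = [domain_plan] if isinstance(domain_plan, DomainPlan) else list(domain_plan)
    rng = _rng(seed, "proteins")
    records, truth = [], []
    dom_rows = []
    for i in range(n):
        plan = plans[i % len(plans)]
        pid = f"syn{i:04d}"
        nterm = "".join(rng.choice(list(_AA), size=NTERM_LENGTH))
        residues = nterm
        for d in range(1, 5):
            tris = [(kind, rel) for dom, kind, rel in plan.tripeptides if dom == d]
            domain, plants = _build_domain(rng, plan.cbs[d - 1], tris,
                                           adjacency_window)
            start = len(residues) + 1
            residues += domain
            dom_rows.append((pid, d, start, start + DOMAIN_LENGTH - 1))
            for p in plants:
                truth.append({"protein_id": pid, "domain_index": d,
                              "kind": p["kind"], "start": p["start"],
                              "status": p["status"],
                              "relation": p.get("relation"),
                              "planned_cbs": plan.cbs[d - 1]})
            if plan.cbs[d - 1] == "absent" and not tris:
                truth.append({"protein_id": pid, "domain_index": d,
                              "kind": None, "start": None, "status": None,
                              "relation": None, "planned_cbs": "absent"})
        records.append(SequenceRecord(id=pid, residues=residues))
    return records, DomainAnnotationTable.from_rows(dom_rows), truth


# ---------------------------------------------------------------------------
# gene models from splicing-pattern templates
# ---------------------------------------------------------------------------

# Twelve exon-length templates (all totals 600 nt = 200 codons); the first
# intron sits in phase 1 and later ones in phase 0 in most templates, the
# configuration dominating land-plant annexins, with all-phase-0 variants
# and an intronless template completing the catalog.
DEFAULT_TEMPLATES: tuple[tuple[int, ...], ...] = (
    (64, 89, 96, 105, 87, 99, 60),   # phases 100000
    (64, 90, 95, 105, 87, 99, 60),   # phases 110000
    (64, 89, 96, 105, 87, 159),      # phases 10000
    (90, 96, 105, 87, 99, 123),      # phases 00000
    (64, 89, 96, 105, 246),          # phases 1000
    (90, 96, 105, 87, 222),          # phases 0000
    (64, 89, 96, 351),               # phases 100
    (90, 96, 105, 309),              # phases 000
    (64, 89, 447),                   # phases 10
    (90, 96, 414),                   # phases 00
    (64, 536),                       # phases 1
    (600,),                          # intronless
)


def gen_gene_models(seed: int,
                    templates: Sequence[Sequence[int]] = DEFAULT_TEMPLATES,
                    n_per_template: int = 3,
                    n_chromosomes: int = 5
                    ) -> tuple[list[GeneModel], list[dict]]:
    """Instantiate gene models from exon-length templates.

    Each instance gets a random chromosome, strand, genomic offset and
    intron lengths; truth rows record the template index and phase string.
    """
    for t, template in enumerate(templates, start=1):
        if sum(template) % 3:
            raise ValueError(f"template {t}: total exon length not divisible by 3")
    rng = _rng(seed, "gene_models")
    models, truth = [], []
    for t, template in enumerate(templates, start=1):
        phases = []
        upstream = 0
        for length in template[:-1]:
            upstream += length
            phases.append(str(upstream % 3))
        ps = "".join(phases)
        for j in range(n_per_template):
            gene_id = f"t{t:02d}g{j}"
            chrom = f"chr{int(rng.integers(1, n_chromosomes + 1))}"
            strand = str(rng.choice(["+", "-"]))
            start = int(rng.integers(1_000, 5_000_000))
            lengths = template if strand == "+" else tuple(reversed(template))
            spans = []
            pos = start
            for length in lengths:
                spans.append((pos, pos + length - 1))
                pos += length + int(rng.integers(80, 500))
            exons = tuple(spans) if strand == "+" else tuple(spans[::-1])
            models.append(GeneModel(gene_id=gene_id, transcript_id=gene_id + ".1",
                                    chromosome=chrom, strand=strand, exons=exons))
            truth.append({"gene_id": gene_id, "template": t, "phase_string": ps,
                          "exon_count": len(template)})
    return models, truth


# ---------------------------------------------------------------------------
# genome orders with planted tandem clusters and segmental pairs
# ---------------------------------------------------------------------------

def gen_genome_orders(seed: int,
                      n_chrom: int = 5,
                      genes_per_chrom: int = 120,
                      planted_tandem: Sequence[tuple[int, int, int]] = ((1, 2, 0), (2, 3, 5)),
                      planted_segmental: int = 2,
                      n_singletons: int = 2,
                      n_decoy_pairs: int = 1,
                      isolation: int = 12
                      ) -> tuple[GenomeOrderTable, list[GeneLocus], CollinearPairTable, dict]:
    """Background genomes with planted family genes.

    ``planted_tandem`` rows are (chromosome number, cluster size, intervening
    background genes between consecutive members). ``planted_segmental``
    cross-chromosome pairs are emitted into the collinear table together with
    ``n_decoy_pairs`` pairs touching a non-family gene (which a correct
    classifier must ignore). Singleton family genes sit at least
    ``isolation`` background genes away from any other family member.
    """
    rng = _rng(seed, "genome")
    order: dict[int, list[str]] = {c: [] for c in range(1, n_chrom + 1)}
    fam_counter = 0
    bg_counter = 0
    truth = {"tandem_clusters": [], "segmental_pairs": [], "family": []}
    family_chrom: dict[str, int] = {}

    def bg(c: int, k: int) -> None:
        nonlocal bg_counter
        for _ in range(k):
            order[c].append(f"bg{bg_counter:05d}")
            bg_counter += 1

    def fam(c: int) -> str:
        nonlocal fam_counter
        name = f"fam{fam_counter:03d}"
        fam_counter += 1
        order[c].append(name)
        family_chrom[name] = c
        truth["family"].append(name)
        return name

    for chrom, size, spacing in planted_tandem:
        if chrom > n_chrom:
            raise ValueError(f"planted cluster on chromosome {chrom} > {n_chrom}")
        bg(chrom, isolation)
        members = []
        for m in range(size):
            if m:
                bg(chrom, spacing)
            members.append(fam(chrom))
        bg(chrom, isolation)
        truth["tandem_clusters"].append(tuple(members))

    seg_chroms = list(range(1, n_chrom + 1))
    for p in range(planted_segmental):
        c1, c2 = seg_chroms[(2 * p) % n_chrom], seg_chroms[(2 * p + 1) % n_chrom]
        bg(c1, isolation)
        a = fam(c1)
        bg(c1, isolation)
        bg(c2, isolation)
        b = fam(c2)
        bg(c2, isolation)
        truth["segmental_pairs"].append((a, b, f"block{p}"))

    for s in range(n_singletons):
        c = int(rng.integers(1, n_chrom + 1))
        bg(c, isolation)
        fam(c)
        bg(c, isolation)

    for c in range(1, n_chrom + 1):
        deficit = genes_per_chrom - len(order[c])
        if deficit < 0:
            raise ValueError(
                f"chromosome {c} over-packed: {len(order[c])} genes > "
                f"{genes_per_chrom}"
            )
        bg(c, deficit)

    rows, loci = [], []
    start_of: dict[str, int] = {}
    for c in range(1, n_chrom + 1):
        pos = 0
        for gid in order[c]:
            pos += int(rng.integers(2_000, 20_000))
            rows.append((f"chr{c}", gid, pos))
            start_of[gid] = pos
    genome = GenomeOrderTable.from_rows(rows)
    for name, c in family_chrom.items():
        loci.append(GeneLocus(gene_id=name, chromosome=f"chr{c}",
                              start=start_of[name], end=start_of[name] + 1500))

    pair_rows = [(a, b, blk) for a, b, blk in truth["segmental_pairs"]]
    for d in range(n_decoy_pairs):
        fam_gene = truth["family"][d % len(truth["family"])]
        pair_rows.append((fam_gene, f"bg{d:05d}", f"decoy{d}"))
    pairs = CollinearPairTable.from_rows(pair_rows)
    return genome, loci, pairs, truth


# ---------------------------------------------------------------------------
# codon-pair evolution with exact event counts
# ---------------------------------------------------------------------------

def evolve_codon_pair(seed: int, n_codons: int,
                      target_syn_events: int, target_nonsyn_events: int,
                      max_attempts: Optional[int] = None
                      ) -> tuple[str, str, dict]:
    """Evolve a descendant from a random ancestor by planted point events.

    Proposed point mutations are applied only when they do not create a stop
    codon and the corresponding event class is still short of its target,
    classifying each against the current codon at application time. When no
    nonsynonymous events are requested, a synonymous event is additionally
    required to leave the codon's pathway-averaged nonsynonymous difference
    from its *ancestral* state at zero, so the planted nonsynonymous truth
    stays exact under pathway counting.
    """
    if target_syn_events < 0 or target_nonsyn_events < 0:
        raise ValueError("event targets must be >= 0")
    rng = _rng(seed, "codons")
    ancestor = [str(c) for c in rng.choice(SENSE_CODONS, size=n_codons)]
    descendant = list(ancestor)
    syn_done = nonsyn_done = 0
    events: list[dict] = []
    if max_attempts is None:
        max_attempts = 2000 * (target_syn_events + target_nonsyn_events + 1)
    attempts = 0
    strict_syn = target_nonsyn_events == 0
    while syn_done < target_syn_events or nonsyn_done < target_nonsyn_events:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"event targets unreachable after {max_attempts} proposals "
                f"(syn {syn_done}/{target_syn_events}, "
                f"nonsyn {nonsyn_done}/{target_nonsyn_events})"
            )
        ci = int(rng.integers(n_codons))
        pos = int(rng.integers(3))
        current = descendant[ci]
        base = str(rng.choice([b for b in "ACGT" if b != current[pos]]))
        mutated = current[:pos] + base + current[pos + 1:]
        if mutated in STOP_CODONS:
            continue
        synonymous = GENETIC_CODE[mutated] == GENETIC_CODE[current]
        if synonymous:
            if syn_done >= target_syn_events:
                continue
            if strict_syn:
                diffs = _pathway_average(ancestor[ci], mutated)
                if diffs is None or diffs[1] != 0:
                    continue
            syn_done += 1
        else:
            if nonsyn_done >= target_nonsyn_events:
                continue
            nonsyn_done += 1
        descendant[ci] = mutated
        events.append({"codon": ci, "position": pos, "to": base,
                       "class": "syn" if synonymous else "nonsyn"})
    truth = {"syn_events": syn_done, "nonsyn_events": nonsyn_done,
             "events": events}
    return "".join(ancestor), "".join(descendant), truth
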