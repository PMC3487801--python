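import pytest

from anxtools.duplication import GeneLocus
from anxtools.io_formats import CollinearPairTable, GenomeOrderTable


def build_genome(layout):
    """Build a GenomeOrderTable plus family loci from a compact layout.

    ``layout`` maps chromosome name to an ordered list of entries: a family
    gene id, or an int meaning that many background genes.
    """
    rows, loci = [], []
    bg = 0
    for chrom, entries in layout.items():
        pos = 0
        for entry in entries:
            if isinstance(entry, int):
                for _ in range(entry):
                    pos += 1000
                    rows.append((chrom, f"bg{bg:04d}", pos))
                    bg += 1
            else:
                pos += 1000
                rows.append((chrom, entry, pos))
                loci.append(GeneLocus(entry, chrom, pos, pos + 500))
    return GenomeOrderTable.from_rows(rows), loci


@pytest.fixture
def arabidopsis_like():
    """Eight-gene family: two adjacent tandem pairs (chr2 and chr5) and one
    intra-chromosomal segmental pair, the configuration with 4 of 8 genes on
    chromosome 5."""
    genome, loci = build_genome({
        "chr1": [10, "At1g35720", 20, "At1g68090", 10],
        "chr2": [15, "At2g38750", "At2g38760", 15],
        "chr5": [8, "At5g10220", "At5g10230", 10, "At5g12380", 10,
                 "At5g65020", 8],
    })
    pairs = CollinearPairTable.from_rows([
        ("At5g10220", "At5g65020", "blockA"),
    ])
    return genome, loci, pairs


@pytest.fixture
def rice_like():
    """Ten-gene family: one tandem pair on chromosome 5, two segmental pairs
    (chr2-chr6 and chr8-chr9), three genes on chromosome 9."""
    genome, loci = build_genome({
        "chr1": [10, "Os01g64800", 10],
        "chr2": [10, "Os02g51750", 10],
        "chr5": [10, "Os05g31750", "Os05g31760", 10],
        "chr6": [10, "Os06g11800", 10],
        "chr7": [10, "Os07g46550", 10],
        "chr8": [10, "Os08g32970", 10],
        "chr9": [6, "Os09g20330", 10, "Os09g23160", 10, "Os09g27990", 6],
    })
    pairs = CollinearPairTable.from_rows([
        ("Os02g51750", "Os06g11800", "blockA"),
        ("Os08g32970", "Os09g23160", "blockB"),
    ])
    return genome, loci, pairs


@pytest.fixture
def poplar_like():
    """Twelve-gene family: one tandem pair on chromosome 1 and five
    segmental pairs in which one gene partners two others."""
    genome, loci = build_genome({
        "chr1": [8, "Pt01g06020", "Pt01g06030", 10, "Pt01g27650", 8],
        "chr2": [10, "Pt02g09420", 10],
        "chr3": [10, "Pt03g19020", 10],
        "chr5": [10, "Pt05g07550", 10],
        "chr7": [10, "Pt07g05300", 10],
        "chr8": [10, "Pt08g13700", 10],
        "chr10": [10, "Pt10g10090", 10],
        "chr12": [10, "Pt12g03690", 10],
        "chr13": [10, "Pt13g12300", 10],
        "chr15": [10, "Pt15g04350", 10],
    })
    pairs = CollinearPairTable.from_rows([
        ("Pt02g09420", "Pt05g07550", "b1"),
        ("Pt02g09420", "Pt07g05300", "b1"),
        ("Pt08g13700", "Pt10g10090", "b2"),
        ("Pt01g27650", "Pt03g19020", "b3"),
        ("Pt12g03690", "Pt15g04350", "b4"),
    ])
    return genome, loci, pairs
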