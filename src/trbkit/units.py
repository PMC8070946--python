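"""Shared domain types for germline TRB gene units.

Coordinates are 0-based half-open internally; GFF3 output is 1-based
inclusive.  A gene unit carries its coding span(s), the recombination
signal (RS) elements and splice sites that delimit it, and an IMGT-style
functionality call (F / ORF / P).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

# IMGT consensus recombination-signal elements and canonical splice
# dinucleotides.  Configurable wherever they are consumed.
HEPTAMER_CONSENSUS = "CACAGTG"
NONAMER_CONSENSUS = "ACAAAAACC"
DONOR_SITE = "GT"
ACCEPTOR_SITE = "AG"

#: hydrophobic amino acids accepted at IMGT position 89
HYDROPHOBIC_AA = frozenset("AILMFVWYC")

#: defect kinds that force a pseudogene (P) call
P_DEFECTS = frozenset({"stop_codon", "frameshift", "missing_anchor"})

#: defect kinds that force an ORF call when no P defect is present
ORF_DEFECTS = frozenset(
    {
        "noncanonical_heptamer",
        "noncanonical_nonamer",
        "noncanonical_splice",
        "missing_leader",
        "unexpected_length",
        "nonconserved_j_motif",
    }
)

#: defect-spec kind -> recorded defect code
DEFECT_CODE = {
    "stop_codon": "stop_codon",
    "frameshift": "frameshift",
    "heptamer_mutation": "noncanonical_heptamer",
    "nonamer_mutation": "noncanonical_nonamer",
    "splice_mutation": "noncanonical_splice",
    "missing_leader": "missing_leader",
    "j_motif_mutation": "nonconserved_j_motif",
}


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def functionality_from_defects(defects: list[str]) -> str:
    """F / ORF / P from a defect list (IMGT rule ordering)."""
    if any(d in P_DEFECTS for d in defects):
        return "P"
    if defects:
        return "ORF"
    return "F"


@dataclass
class RecombinationSignal:
    """Heptamer/spacer/nonamer element.

    ``side`` states where the RS sits relative to its gene ("five_prime"
    or "three_prime"); the heptamer always abuts the coding end.  ``span``
    is the half-open interval of the whole element on the region's plus
    strand; ``strand`` is the strand of the gene the RS belongs to.
    """

    side: str
    heptamer_seq: str
    nonamer_seq: str
    spacer_len: int
    heptamer_mismatches: int
    nonamer_mismatches: int
    span: tuple[int, int]
    strand: str = "+"

    @property
    def spacer_class(self) -> int:
        return 12 if abs(self.spacer_len - 12) <= abs(self.spacer_len - 23) else 23


@dataclass
class SpliceSite:
    kind: str  # "donor" | "acceptor"
    pos: int  # 0-based start of the dinucleotide on the plus strand
    seq: str
    canonical: bool


@dataclass
class FunctionalityCall:
    label: str
    defects: list[str] = field(default_factory=list)


@dataclass
class GeneUnit:
    """An annotated germline V, D, J or C gene unit."""

    id: str
    gene_type: str  # V | D | J | C
    strand: str = "+"
    coding_spans: list[tuple[int, int]] = field(default_factory=list)
    rs_elements: list[RecombinationSignal] = field(default_factory=list)
    splice_sites: list[SpliceSite] = field(default_factory=list)
    functionality: str = "F"
    defects: list[str] = field(default_factory=list)
    name: Optional[str] = None  # nomenclature label once assigned
    meta: dict = field(default_factory=dict)

    @property
    def start(self) -> int:
        lo = min(s for s, _ in self.coding_spans)
        if self.rs_elements:
            lo = min(lo, min(r.span[0] for r in self.rs_elements))
        return lo

    @property
    def end(self) -> int:
        hi = max(e for _, e in self.coding_spans)
        if self.rs_elements:
            hi = max(hi, max(r.span[1] for r in self.rs_elements))
        return hi

    def coding_seq(self, region: str) -> str:
        parts = [region[s:e] for s, e in sorted(self.coding_spans)]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq

    def copy(self) -> "GeneUnit":
        return replace(
            self,
            coding_spans=list(self.coding_spans),
            rs_elements=[replace(r) for r in self.rs_elements],
            splice_sites=[replace(s) for s in self.splice_sites],
            defects=list(self.defects),
            meta=dict(self.meta),
        )


@dataclass
class GenomicRegion:
    """A genomic sequence plus the 1-based coordinate of its first base
    in the source assembly."""

    id: str
    sequence: str
    assembly_offset: int = 1

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"non-ACGTN characters in region: {sorted(bad)}")
        if self.assembly_offset < 1:
            raise ValueError("assembly_offset must be >= 1")
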