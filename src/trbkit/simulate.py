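"""Synthetic TRB locus and rearranged-repertoire generator.

Emulates the genomic anatomy the downstream annotation assumes: V gene
units with a leader exon (L-PART1 / L-PART2 split by an intron), a
V-REGION under the IMGT framework/CDR architecture with the four
conserved anchors, and a 3' 23-spacer recombination signal (RS); D units
as short G-rich stretches flanked by a 5' 12-RS and a 3' 23-RS; J units
with a 5' 12-RS, an FGXG motif, and a 3' donor splice site; C units of
four exons.  Rearranged cDNA clones are built as
L + V(-trim) + N1 + D(-trims) + N2 + J(-trim) + C-exon1 fragment with a
recorded ground-truth junction decomposition.

Design guarantees (see docs/methods.md):

* germline variation is substitution-only, so planted coordinates are
  exactly recoverable by RS/splice anchoring;
* junction flanks share no 5-mer with the D genes and N nucleotides
  never extend an adjacent germline segment, so the planted junction
  decomposition is the unique one under the >=5-nt D rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .units import (
    ACCEPTOR_SITE,
    DEFECT_CODE,
    DONOR_SITE,
    HEPTAMER_CONSENSUS,
    NONAMER_CONSENSUS,
    GeneUnit,
    RecombinationSignal,
    SpliceSite,
    functionality_from_defects,
    revcomp,
)

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}

# IMGT framework lengths (positions): FR1 1-26, CDR1 27-38, FR2 39-55,
# CDR2 56-65, FR3 66-104.  The simulator builds V-REGIONs from a root
# template at the maximal simulated CDR lengths below.
FR1_AA, FR2_AA, FR3_AA = 26, 17, 39
CDR1_MAX, CDR2_MAX = 6, 7
LEADER_AA = 19  # L-PART1 (46 nt) + L-PART2 (11 nt) = 57 nt
L_PART2_LEN = 11
FR4_NT = 33  # J-REGION from J-PHE 118 through 128 (11 codons)

HYDROPHOBIC_CODONS = ["GTG", "CTG", "ATC", "TTC", "GCC", "ATG"]


def _translate(seq: str) -> str:
    return str(Seq(seq).translate())


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def _rand_codons(rng: np.random.Generator, n_codons: int) -> str:
    out = []
    while len(out) < n_codons:
        c = _rand_dna(rng, 3)
        if c not in STOPS:
            out.append(c)
    return "".join(out)


def _has_kmer_overlap(seq: str, kmers: set[str], k: int = 5) -> bool:
    return any(seq[i : i + k] in kmers for i in range(len(seq) - k + 1))


def _draw_avoiding(rng: np.random.Generator, n: int, forbid_kmers: set[str]) -> str:
    for _ in range(500):
        s = _rand_dna(rng, n)
        if not _has_kmer_overlap(s, forbid_kmers):
            return s
    raise RuntimeError("could not draw sequence avoiding forbidden k-mers")


def _branch_retention(identity: float, other: float = 1.0) -> float:
    """Per-branch eigenvalue of the uniform substitution chain such that
    two leaves separated by this branch (squared) plus ``other`` reach the
    requested expected pairwise identity."""
    lam_sq = ((identity - 0.25) / 0.75) / (other**2)
    if lam_sq <= 0 or lam_sq > 1:
        raise ValueError(f"identity target {identity} infeasible")
    return math.sqrt(lam_sq)


def _mutation_rate(retention: float) -> float:
    return 0.75 * (1.0 - retention)


def _mutate(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    fixed: frozenset[int] = frozenset(),
) -> str:
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        if int(i) in fixed:
            continue
        choices = [b for b in BASES if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return "".join(out)


def _fix_stops(seq: str, rng: np.random.Generator, fixed: frozenset[int] = frozenset()) -> str:
    """Remove stop codons (frame 0) introduced by mutation."""
    out = list(seq)
    for _ in range(100):
        dirty = False
        for i in range(0, len(out) - 2, 3):
            if "".join(out[i : i + 3]) in STOPS:
                movable = [j for j in range(i, i + 3) if j not in fixed]
                if not movable:  # deliberately fixed stop (e.g. terminal TAA)
                    continue
                dirty = True
                j = movable[rng.integers(len(movable))]
                choices = [b for b in BASES if b != out[j]]
                out[j] = choices[rng.integers(3)]
        if not dirty:
            return "".join(out)
    raise RuntimeError("could not remove stop codons")


def _mutate_coding(
    seq: str, rate: float, rng: np.random.Generator, fixed: frozenset[int] = frozenset()
) -> str:
    return _fix_stops(_mutate(seq, rate, rng, fixed), rng, fixed)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class LocusSimConfig:
    """Parameters of the germline locus generator.

    Identity fractions are expected pairwise nucleotide identities of
    V-REGIONs; the partition criterion downstream is >0.75.
    """

    n_v_genes: int = 23
    n_subgroups: int = 20
    subgroup_identity_within: float = 0.90
    subgroup_identity_between: float = 0.60
    n_djc_clusters: int = 3
    d_lengths: tuple[int, ...] = (13, 15)
    d_cluster_indices: tuple[int, ...] = (0, 2)
    j_counts: tuple[int, ...] = (6, 7, 7)
    j_length_range: tuple[int, int] = (40, 53)
    leader_length: int = 46  # L-PART1 nt, ATG included
    v_tail_length: int = 6  # germline V nt 3' of codon 104 (CDR3 start)
    v_intron_length_range: tuple[int, int] = (80, 160)
    c_exon_aa: tuple[int, int, int, int] = (129, 6, 35, 6)
    c_intron_length_range: tuple[int, int] = (80, 160)
    intergenic_length_range: tuple[int, int] = (200, 600)
    gap_length: int = 0  # >0 inserts an N-run in the cluster region
    defect_rates: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if not (0.75 < self.subgroup_identity_within <= 1.0):
            raise ValueError("subgroup_identity_within must be in (0.75, 1.0]")
        if not (0.25 < self.subgroup_identity_between <= 0.75):
            raise ValueError("subgroup_identity_between must be in (0.25, 0.75]")
        if self.subgroup_identity_between > self.subgroup_identity_within:
            raise ValueError("between-identity must not exceed within-identity")
        if self.n_v_genes < self.n_subgroups or self.n_subgroups < 1:
            raise ValueError("need n_v_genes >= n_subgroups >= 1")
        if any(d < 5 for d in self.d_lengths):
            raise ValueError("d_lengths must each be >= 5 bp")
        if len(self.j_counts) != self.n_djc_clusters:
            raise ValueError("j_counts must have one entry per cluster")
        if any(c > self.n_djc_clusters - 1 for c in self.d_cluster_indices):
            raise ValueError("d_cluster_indices out of range")
        if len(self.d_cluster_indices) != len(self.d_lengths):
            raise ValueError("one cluster index per D gene required")
        if (self.leader_length + L_PART2_LEN) % 3 != 0:
            raise ValueError("leader_length + 11 must be a codon multiple")
        if self.j_length_range[0] < FR4_NT + 1:
            raise ValueError("minimum J length must exceed the 33-nt FR4")
        if self.c_exon_aa[3] < 1:
            raise ValueError("C EX4 must encode at least one amino acid")


@dataclass
class RepertoireSimConfig:
    """Parameters of the rearranged-cDNA generator.

    Trim and N-segment draws are uniform on 0..max (configured mean is
    therefore max/2); trims are clamped to the germline part they apply
    to, and a D whose trims consume it is recorded as absent.
    """

    n_clones: int = 45
    n_subjects: int = 2
    v_trim_max: int = 4
    d5_trim_max: int = 6
    d3_trim_max: int = 6
    j_trim_max: int = 4
    n_length_max: int = 6
    allele_mutation_prob: float = 0.5
    allele_identity_floor: float = 0.97
    redundancy_rate: float = 13 / 45
    c_fragment_length: int = 60
    seed: int = 0

    def validate(self) -> None:
        if not (0.97 <= self.allele_identity_floor < 1.0):
            raise ValueError("allele_identity_floor must be in [0.97, 1)")
        for name in ("n_clones", "n_subjects"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("v_trim_max", "d5_trim_max", "d3_trim_max", "j_trim_max", "n_length_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.redundancy_rate < 1.0):
            raise ValueError("redundancy_rate must be in [0, 1)")


@dataclass
class CloneTruth:
    """Ground truth for one simulated clone.

    ``v_trim``/``d5_trim``/``d3_trim``/``j_trim`` and ``d_gene_id`` are
    the raw recombination parameters; ``d_surviving_nt`` is the number
    of consecutive D nucleotides left after trimming.  The junction
    parts (v_part / n1 / d_part / n2 / j_part) are recorded in canonical
    maximal-attribution form — the decomposition an observer of the
    sequence alone can recover — which coincides with the raw parts
    except in the rare coincidental-extension cases.
    """

    clone_id: str
    subject_id: str
    v_gene_id: str
    d_gene_id: Optional[str]
    j_gene_id: str
    c_gene_id: str
    v_trim: int
    d5_trim: int
    d3_trim: int
    j_trim: int
    v_part: str
    n1_seq: str
    d_part: str
    n2_seq: str
    j_part: str
    cdr3_nt: str
    cdr3_aa: str
    cdna_seq: str
    productive: bool
    d_surviving_nt: int = 0
    n1_length: int = 0  # raw drawn N lengths (canonical n1_seq/n2_seq can
    n2_length: int = 0  # absorb a sub-threshold D remnant)
    v_allele: str = "*01"
    v_identity: float = 1.0
    duplicate_of: Optional[str] = None


# ---------------------------------------------------------------------------
# germline locus generation


def _make_d_sequences(lengths: Sequence[int], rng: np.random.Generator) -> list[str]:
    """G-rich D genes, readable in all three frames with 1-3 glycines per
    frame, pairwise sharing no 5-mer (keeps D assignment unambiguous)."""
    seqs: list[str] = []
    taken: set[str] = set()
    for length in lengths:
        for _ in range(10000):
            cand = "".join(rng.choice(list(BASES), size=length, p=[0.13, 0.13, 0.61, 0.13]))
            ok = True
            for frame in range(3):
                codons = [
                    cand[i : i + 3] for i in range(frame, length - 2, 3)
                ]
                if any(c in STOPS for c in codons):
                    ok = False
                    break
                gly = sum(c.startswith("GG") for c in codons)
                if not (1 <= gly <= 3):
                    ok = False
                    break
            if ok and not _has_kmer_overlap(cand, taken):
                seqs.append(cand)
                taken.update(cand[i : i + 5] for i in range(length - 4))
                break
        else:
            raise RuntimeError(f"could not construct a D gene of length {length}")
    return seqs


def _d_kmers(d_seqs: Sequence[str]) -> set[str]:
    kmers: set[str] = set()
    for d in d_seqs:
        kmers.update(d[i : i + 5] for i in range(len(d) - 4))
    return kmers


def _anchor_positions(cdr1: int, cdr2: int) -> dict[str, int]:
    """Codon indices (0-based) of the conserved residues in a V-REGION
    with the given CDR1/CDR2-IMGT lengths.  Position 42 carries the
    tyrosine of the FR2 W41-Y42 motif (kept fixed so the numbering
    anchor search is unambiguous, as in genuine TR V domains)."""
    return {
        "cys23": 22,
        "trp41": 28 + cdr1,
        "tyr42": 29 + cdr1,
        "hydrophobic89": 66 + cdr1 + cdr2,
        "cys104": 81 + cdr1 + cdr2,
    }


def _fixed_nt(codon_indices: Sequence[int]) -> frozenset[int]:
    return frozenset(i * 3 + k for i in codon_indices for k in range(3))


class _VFamily:
    """Root-derived V sequences for one subgroup."""

    def __init__(
        self,
        index: int,
        cdr1: int,
        cdr2: int,
        ancestor_l1: str,
        ancestor_l2: str,
        ancestor_core: str,
        tail: str,
    ):
        self.index = index
        self.cdr1 = cdr1
        self.cdr2 = cdr2
        self.ancestor_l1 = ancestor_l1
        self.ancestor_l2 = ancestor_l2
        self.ancestor_core = ancestor_core
        self.tail = tail

    @property
    def anchors(self) -> dict[str, int]:
        return _anchor_positions(self.cdr1, self.cdr2)


def _build_v_families(cfg: LocusSimConfig, rng: np.random.Generator, d_kmers: set[str]) -> list[_VFamily]:
    lam_w = _branch_retention(cfg.subgroup_identity_within)
    lam_b = _branch_retention(cfg.subgroup_identity_between, other=lam_w)
    m_b = _mutation_rate(lam_b)

    # root template at maximal CDR lengths
    root_codons = FR1_AA + CDR1_MAX + FR2_AA + CDR2_MAX + FR3_AA
    root = _rand_codons(rng, root_codons)
    root_anch = _anchor_positions(CDR1_MAX, CDR2_MAX)
    root = _set_codon(root, root_anch["cys23"], "TGC")
    root = _set_codon(root, root_anch["trp41"], "TGG")
    root = _set_codon(root, root_anch["tyr42"], "TAC")
    root = _set_codon(
        root, root_anch["hydrophobic89"], HYDROPHOBIC_CODONS[rng.integers(len(HYDROPHOBIC_CODONS))]
    )
    root = _set_codon(root, root_anch["cys104"], "TGT")
    root_l1 = "ATG" + _rand_dna(rng, cfg.leader_length - 3)
    root_l2 = _rand_dna(rng, L_PART2_LEN)
    root_l1, root_l2 = _fix_leader(root_l1, root_l2, rng)

    families = []
    for s in range(cfg.n_subgroups):
        a = int(rng.integers(5, CDR1_MAX + 1))
        b = int(rng.integers(5, CDR2_MAX + 1))
        # slice the root down to this subgroup's CDR lengths
        cod = [root[i * 3 : i * 3 + 3] for i in range(root_codons)]
        sub = (
            cod[:FR1_AA]
            + cod[FR1_AA : FR1_AA + a]
            + cod[FR1_AA + CDR1_MAX : FR1_AA + CDR1_MAX + FR2_AA]
            + cod[FR1_AA + CDR1_MAX + FR2_AA : FR1_AA + CDR1_MAX + FR2_AA + b]
            + cod[FR1_AA + CDR1_MAX + FR2_AA + CDR2_MAX :]
        )
        base = "".join(sub)
        fixed = _fixed_nt(list(_anchor_positions(a, b).values()))
        core = _mutate_coding(base, m_b, rng, fixed)
        l1 = _mutate_leader(root_l1, root_l2, m_b, rng)
        tail = _draw_tail(rng, cfg.v_tail_length, d_kmers)
        families.append(_VFamily(s, a, b, l1[0], l1[1], core, tail))
    return families


def _set_codon(seq: str, codon_idx: int, codon: str) -> str:
    i = codon_idx * 3
    return seq[:i] + codon + seq[i + 3 :]


def _fix_leader(l1: str, l2: str, rng: np.random.Generator) -> tuple[str, str]:
    joined = _fix_stops(l1 + l2, rng, fixed=frozenset(range(3)))
    return joined[: len(l1)], joined[len(l1) :]


def _mutate_leader(l1: str, l2: str, rate: float, rng: np.random.Generator) -> tuple[str, str]:
    joined = _mutate(l1 + l2, rate, rng, fixed=frozenset(range(3)))
    joined = _fix_stops(joined, rng, fixed=frozenset(range(3)))
    return joined[: len(l1)], joined[len(l1) :]


def _draw_tail(rng: np.random.Generator, n: int, d_kmers: set[str]) -> str:
    # two codons 3' of the 2nd-CYS; stop-free in the V frame
    for _ in range(500):
        t = _rand_dna(rng, n)
        if _has_kmer_overlap(t, d_kmers):
            continue
        if any(t[i : i + 3] in STOPS for i in range(0, n - 2, 3)):
            continue
        return t
    raise RuntimeError("could not draw V tail")


def _make_j_gene(
    cfg: LocusSimConfig, rng: np.random.Generator, d_kmers: set[str]
) -> tuple[str, int]:
    """Returns (coding sequence, j5 length).  Coding = CDR3-contributing
    5' part + FGXG + FR4 tail; stop-free in the 3'-anchored frame."""
    lo = cfg.j_length_range[0] - FR4_NT
    hi = cfg.j_length_range[1] - FR4_NT
    j5_len = int(rng.integers(lo, hi + 1))
    for _ in range(500):
        j5 = _draw_avoiding(rng, j5_len, d_kmers)
        # 3'-anchored frame: full codons of j5 end where the F codon begins
        off = j5_len % 3
        if any(j5[i : i + 3] in STOPS for i in range(off, j5_len - 2, 3)):
            continue
        fgxg = "TTTGG" + _rand_dna(rng, 1) + _rand_codons(rng, 1) + "GG" + _rand_dna(rng, 1)
        fr4_tail = _rand_codons(rng, 7)
        return j5 + fgxg + fr4_tail, j5_len
    raise RuntimeError("could not draw J gene")


def _make_c_exons(cfg: LocusSimConfig, rng: np.random.Generator) -> list[str]:
    ex = [_rand_codons(rng, aa) for aa in cfg.c_exon_aa]
    ex[3] = ex[3] + "TAA"  # stop codon closes EX4
    return ex


class _Assembler:
    def __init__(self, rng: np.random.Generator):
        self.chunks: list[str] = []
        self.pos = 0
        self.rng = rng

    def add(self, seq: str) -> tuple[int, int]:
        start = self.pos
        self.chunks.append(seq)
        self.pos += len(seq)
        return (start, self.pos)

    def filler(self, lo: int, hi: int) -> None:
        self.add(_rand_dna(self.rng, int(self.rng.integers(lo, hi + 1))))

    def sequence(self) -> str:
        return "".join(self.chunks)


def _rs_record(side, strand, span, spacer_len, heptamer=None, nonamer=None) -> RecombinationSignal:
    return RecombinationSignal(
        side=side,
        heptamer_seq=heptamer or HEPTAMER_CONSENSUS,
        nonamer_seq=nonamer or NONAMER_CONSENSUS,
        spacer_len=spacer_len,
        heptamer_mismatches=0,
        nonamer_mismatches=0,
        span=span,
        strand=strand,
    )


def generate_germline_locus(config: LocusSimConfig) -> tuple[str, list[GeneUnit]]:
    """Build a synthetic TRB locus.

    Returns the genomic plus-strand sequence and ground-truth gene
    units (all functionality F).  Deterministic for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    d_seqs = _make_d_sequences(config.d_lengths, rng)
    dk = _d_kmers(d_seqs)
    families = _build_v_families(config, rng, dk)

    # distribute V genes over subgroups: extras to the lowest-index
    # subgroup not yet holding 3 members (emulates the observed 3+2+1...)
    sizes = [1] * config.n_subgroups
    extras = config.n_v_genes - config.n_subgroups
    i = 0
    while extras > 0:
        if sizes[i] < 3:
            sizes[i] += 1
            extras -= 1
        else:
            i += 1
        if i >= config.n_subgroups:
            i = 0
    member_subgroups = [s for s, n in enumerate(sizes) for _ in range(n)]
    order = rng.permutation(len(member_subgroups))
    member_subgroups = [member_subgroups[i] for i in order]

    lam_w = _branch_retention(config.subgroup_identity_within)
    m_w = _mutation_rate(lam_w)

    asm = _Assembler(rng)
    units: list[GeneUnit] = []
    lo, hi = config.intergenic_length_range

    for vi, s in enumerate(member_subgroups):
        fam = families[s]
        asm.filler(lo, hi)
        fixed = _fixed_nt(list(fam.anchors.values()))
        core = _mutate_coding(fam.ancestor_core, m_w, rng, fixed)
        l1, l2 = _mutate_leader(fam.ancestor_l1, fam.ancestor_l2, m_w, rng)
        l1_span = asm.add(l1)
        donor = SpliceSite("donor", asm.pos, DONOR_SITE, True)
        asm.add(DONOR_SITE)
        asm.add(_rand_dna(rng, int(rng.integers(*config.v_intron_length_range)) - 4))
        acceptor = SpliceSite("acceptor", asm.pos, ACCEPTOR_SITE, True)
        asm.add(ACCEPTOR_SITE)
        vexon_span = asm.add(l2 + core + fam.tail)
        rs_span = asm.add(HEPTAMER_CONSENSUS + _rand_dna(rng, 23) + NONAMER_CONSENSUS)
        units.append(
            GeneUnit(
                id=f"V{vi + 1}",
                gene_type="V",
                coding_spans=[l1_span, vexon_span],
                rs_elements=[_rs_record("three_prime", "+", rs_span, 23)],
                splice_sites=[donor, acceptor],
                meta={
                    "subgroup": s,
                    "cdr1_len": fam.cdr1,
                    "cdr2_len": fam.cdr2,
                    "l1": l1,
                    "l2": l2,
                    "core": core,
                    "tail": fam.tail,
                    "ancestor_core": fam.ancestor_core,
                    "ancestor_l1": fam.ancestor_l1,
                },
            )
        )

    d_by_cluster = dict(zip(config.d_cluster_indices, range(len(d_seqs))))
    d_counter = 0
    for c in range(config.n_djc_clusters):
        asm.filler(lo, hi)
        if c in d_by_cluster:
            d_counter += 1
            d_seq = d_seqs[d_by_cluster[c]]
            rs5 = asm.add(revcomp(NONAMER_CONSENSUS) + _rand_dna(rng, 12) + revcomp(HEPTAMER_CONSENSUS))
            d_span = asm.add(d_seq)
            rs3 = asm.add(HEPTAMER_CONSENSUS + _rand_dna(rng, 23) + NONAMER_CONSENSUS)
            units.append(
                GeneUnit(
                    id=f"D{d_counter}",
                    gene_type="D",
                    coding_spans=[d_span],
                    rs_elements=[
                        _rs_record("five_prime", "+", rs5, 12),
                        _rs_record("three_prime", "+", rs3, 23),
                    ],
                    meta={"cluster": c, "coding": d_seq},
                )
            )
            asm.filler(lo, hi)
        for k in range(config.j_counts[c]):
            j_seq, j5_len = _make_j_gene(config, rng, dk)
            rs5 = asm.add(revcomp(NONAMER_CONSENSUS) + _rand_dna(rng, 12) + revcomp(HEPTAMER_CONSENSUS))
            j_span = asm.add(j_seq)
            donor = SpliceSite("donor", asm.pos, DONOR_SITE, True)
            asm.add(DONOR_SITE)
            units.append(
                GeneUnit(
                    id=f"J{c + 1}-{k + 1}",
                    gene_type="J",
                    coding_spans=[j_span],
                    rs_elements=[_rs_record("five_prime", "+", rs5, 12)],
                    splice_sites=[donor],
                    meta={"cluster": c, "pos": k, "coding": j_seq, "j5_len": j5_len},
                )
            )
            asm.filler(150, 400)
        # constant gene closes the cluster
        exons = _make_c_exons(config, rng)
        spans = []
        sites = []
        asm.filler(lo, hi)
        for e, exon in enumerate(exons):
            sites.append(SpliceSite("acceptor", asm.pos - 2, ACCEPTOR_SITE, True))
            # intron before each exon ends with AG (the first "intron" is
            # the J-to-C splice target region already emitted as filler)
            asm.chunks[-1] = asm.chunks[-1][:-2] + ACCEPTOR_SITE
            spans.append(asm.add(exon))
            if e < 3:
                sites.append(SpliceSite("donor", asm.pos, DONOR_SITE, True))
                asm.add(DONOR_SITE)
                asm.add(_rand_dna(rng, int(rng.integers(*config.c_intron_length_range)) - 4))
        units.append(
            GeneUnit(
                id=f"C{c + 1}",
                gene_type="C",
                coding_spans=spans,
                splice_sites=sites,
                meta={"cluster": c, "exons": exons, "exon_aa": config.c_exon_aa},
            )
        )
    asm.filler(lo, hi)
    if config.gap_length > 0:
        asm.add("N" * config.gap_length)
        asm.filler(lo, hi)
    return asm.sequence(), units


# ---------------------------------------------------------------------------
# defect injection


def inject_defects(
    units: list[GeneUnit],
    sequence: str,
    defect_spec: Sequence[tuple[str, str]],
    seed: int = 0,
) -> tuple[str, list[GeneUnit]]:
    """Plant the requested defects and update the truth functionality.

    ``defect_spec`` is a list of (gene_id, kind) with kind one of
    stop_codon, frameshift, heptamer_mutation, nonamer_mutation,
    splice_mutation, missing_leader, j_motif_mutation.  A frameshift is a
    single-nucleotide deletion; downstream coordinates shift by one.
    """
    rng = np.random.default_rng(seed)
    seq = list(sequence)
    units = [u.copy() for u in units]
    by_id = {u.id: u for u in units}

    def shift_all(pos: int) -> None:
        for u in units:
            u.coding_spans = [
                (s - (s > pos), e - (e > pos)) for s, e in u.coding_spans
            ]
            for r in u.rs_elements:
                r.span = (r.span[0] - (r.span[0] > pos), r.span[1] - (r.span[1] > pos))
            for ss in u.splice_sites:
                if ss.pos > pos:
                    ss.pos -= 1

    for gene_id, kind in defect_spec:
        if gene_id not in by_id:
            raise KeyError(f"unknown defect target gene id: {gene_id}")
        if kind not in DEFECT_CODE:
            raise ValueError(f"unknown defect kind: {kind}")
        u = by_id[gene_id]

        if kind == "stop_codon":
            pos = _stop_codon_position(u)
            seq[pos : pos + 3] = "TAA"
        elif kind == "frameshift":
            pos = _frameshift_position(u)
            del seq[pos]
            shift_all(pos)
        elif kind in ("heptamer_mutation", "nonamer_mutation"):
            rs = u.rs_elements[0]
            n_mm = 1 if kind == "heptamer_mutation" else 2
            _mutate_rs_element(seq, rs, kind, n_mm)
            if kind == "heptamer_mutation":
                rs.heptamer_mismatches += n_mm
            else:
                rs.nonamer_mismatches += n_mm
        elif kind == "splice_mutation":
            site = next(s for s in u.splice_sites if s.kind == "donor")
            seq[site.pos + 1] = "C"  # GT -> GC
            site.canonical = False
        elif kind == "missing_leader":
            if u.gene_type != "V":
                raise ValueError("missing_leader applies to V units only")
            seq[u.coding_spans[0][0]] = "C"  # ATG -> CTG
        elif kind == "j_motif_mutation":
            if u.gene_type != "J":
                raise ValueError("j_motif_mutation applies to J units only")
            start = u.coding_spans[0][0] + u.meta["j5_len"]
            seq[start] = "C"  # TTT -> CTT, J-PHE lost
        u.defects.append(DEFECT_CODE[kind])
        u.functionality = functionality_from_defects(u.defects)
    return "".join(seq), units


def _stop_codon_position(u: GeneUnit) -> int:
    if u.gene_type == "V":
        # a framework-3 codon, clear of every anchor
        exon_start = u.coding_spans[1][0]
        codon = 70  # position ~93 in IMGT numbering, non-anchor
        return exon_start + L_PART2_LEN + codon * 3
    if u.gene_type == "J":
        # FR4 codon 122, just 3' of the FGXG motif
        return u.coding_spans[0][0] + u.meta["j5_len"] + 12
    if u.gene_type == "C":
        return u.coding_spans[0][0] + 150
    if u.gene_type == "D":
        return u.coding_spans[0][0]
    raise ValueError(u.gene_type)


def _frameshift_position(u: GeneUnit) -> int:
    if u.gene_type == "V":
        return u.coding_spans[1][0] + L_PART2_LEN + 120
    if u.gene_type == "J":
        # deep enough into the coding region that an affine-gap aligner
        # pays the gap instead of clipping the exemplar end
        return u.coding_spans[0][0] + 4
    return u.coding_spans[0][0] + 30


def _mutate_rs_element(seq: list[str], rs: RecombinationSignal, kind: str, n_mm: int) -> None:
    """Plant mismatches in the heptamer (outside the invariant CAC) or
    the nonamer, honouring the element's genomic orientation."""
    start, end = rs.span
    # element layout on the plus strand depends on side
    if rs.side == "three_prime":
        hept = range(start, start + 7)  # heptamer first
        nona = range(end - 9, end)
        gene_oriented = True
    else:
        nona = range(start, start + 9)  # rc(nonamer) first
        hept = range(end - 7, end)
        gene_oriented = False
    if kind == "heptamer_mutation":
        targets = list(hept)[3:4]  # 4th base, keeps CAC intact
        if not gene_oriented:
            targets = [list(hept)[6 - 3]]
    else:
        targets = list(nona)[3 : 3 + n_mm]
    for pos in targets:
        seq[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos]]


def sample_defects(
    units: list[GeneUnit], rates: dict[str, float], seed: int = 0
) -> list[tuple[str, str]]:
    """Draw a defect spec from per-kind probabilities (applied to each
    compatible unit independently)."""
    rng = np.random.default_rng(seed)
    spec = []
    for u in units:
        for kind, p in rates.items():
            if kind == "missing_leader" and u.gene_type != "V":
                continue
            if kind == "j_motif_mutation" and u.gene_type != "J":
                continue
            if kind in ("heptamer_mutation", "nonamer_mutation") and not u.rs_elements:
                continue
            if kind == "splice_mutation" and not any(
                s.kind == "donor" for s in u.splice_sites
            ):
                continue
            if rng.random() < p:
                spec.append((u.id, kind))
    return spec


# ---------------------------------------------------------------------------
# repertoire simulation


def _canonical_call(cdr3: str, d_seqs: dict[str, str]):
    """The >=5-nt D call on a junction, via the junction module's rule
    (longest exact substring, leftmost span, ambiguity on ties)."""
    from .junctions import GermlineD, assign_d

    gset = {gid: GermlineD(gid, gid, seq, None) for gid, seq in d_seqs.items()}
    return assign_d(cdr3, gset, min_match=5)


def _content_ok(
    dcall,
    raw_surv: int,
    d_gene: Optional[str],
    want_span: tuple[int, int],
) -> bool:
    """Does the canonical D call recover the raw recombination exactly?"""
    if d_gene is not None and raw_surv >= 5:
        return dcall.d_id == d_gene and dcall.span == want_span
    return dcall.d_id is None


def _draw_n_segment(
    rng: np.random.Generator,
    length: int,
    forbid_first: Optional[str],
    forbid_last: Optional[str],
) -> str:
    if length == 0:
        return ""
    out = list(_rand_dna(rng, length))
    if forbid_first is not None and out[0] == forbid_first:
        out[0] = [b for b in BASES if b != forbid_first][rng.integers(3)]
    if forbid_last is not None and out[-1] == forbid_last:
        choices = [b for b in BASES if b != forbid_last]
        if length == 1 and forbid_first is not None:
            choices = [b for b in choices if b != forbid_first]
        out[-1] = choices[rng.integers(len(choices))]
    return "".join(out)


def simulate_repertoire(
    units: list[GeneUnit], config: RepertoireSimConfig
) -> tuple[list[CloneTruth], list[tuple[str, str]]]:
    """Simulate rearranged cDNA clones from a germline truth.

    Returns the clone truth table and (id, sequence) FASTA records.
    Requires at least one functional V, J and C unit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    v_units = [u for u in units if u.gene_type == "V" and u.functionality == "F"]
    j_units = [u for u in units if u.gene_type == "J" and u.functionality == "F"]
    c_units = [u for u in units if u.gene_type == "C"]
    d_units = [u for u in units if u.gene_type == "D"]
    if not (v_units and j_units and c_units):
        raise ValueError("locus must provide at least one functional V, J and C unit")
    d_seqs = {u.id: u.meta["coding"] for u in d_units}
    c_by_cluster = {u.meta["cluster"]: u for u in c_units}

    allele_cache: dict[tuple[str, str], tuple[str, str, float]] = {}

    def v_coding(subject: str, u: GeneUnit) -> tuple[str, str, float]:
        key = (subject, u.id)
        if key not in allele_cache:
            core = u.meta["core"]
            if rng.random() < config.allele_mutation_prob:
                floor = config.allele_identity_floor
                max_mut = max(1, int((1 - floor) * len(core)))
                fam_anchors = _anchor_positions(u.meta["cdr1_len"], u.meta["cdr2_len"])
                fixed = _fixed_nt(list(fam_anchors.values()))
                mutable = [i for i in range(len(core)) if i not in fixed]
                n_mut = int(rng.integers(1, max_mut + 1))
                while True:  # stop-repair may add changes; stay in band
                    out = list(core)
                    for i in rng.choice(mutable, size=n_mut, replace=False):
                        out[i] = [b for b in BASES if b != out[i]][rng.integers(3)]
                    mutated = _fix_stops("".join(out), rng, fixed)
                    ident = sum(a == b for a, b in zip(mutated, core)) / len(core)
                    if floor <= ident < 1.0:
                        break
                    n_mut = max(1, n_mut - 1)
                allele_cache[key] = (mutated, "*02", ident)
            else:
                allele_cache[key] = (core, "*01", 1.0)
        return allele_cache[key]

    clones: list[CloneTruth] = []
    records: list[tuple[str, str]] = []

    for i in range(config.n_clones):
        subject = f"S{(i % config.n_subjects) + 1}"
        clone_id = f"{subject}-{i + 1:03d}"
        same_subject = [c for c in clones if c.subject_id == subject]
        if same_subject and rng.random() < config.redundancy_rate:
            src = same_subject[int(rng.integers(len(same_subject)))]
            dup = CloneTruth(**{**src.__dict__, "clone_id": clone_id, "duplicate_of": src.clone_id})
            clones.append(dup)
            records.append((clone_id, dup.cdna_seq))
            continue

        vu = v_units[int(rng.integers(len(v_units)))]
        ju = j_units[int(rng.integers(len(j_units)))]
        du = d_units[int(rng.integers(len(d_units)))] if d_units else None
        cu = c_by_cluster.get(ju.meta["cluster"], c_units[-1])

        core, allele, ident = v_coding(subject, vu)
        tail = vu.meta["tail"]
        j5 = ju.meta["coding"][: ju.meta["j5_len"]]
        d_seq = du.meta["coding"] if du else ""

        # trims and N lengths are drawn once, unconditionally, so the
        # configured distributions are exactly what the truth realizes;
        # only N *content* is rejection-sampled (never extending an
        # adjacent germline segment, never creating spurious D matches)
        v_trim = int(rng.integers(0, min(config.v_trim_max, len(tail)) + 1))
        j_trim = int(rng.integers(0, min(config.j_trim_max, len(j5)) + 1))
        d5 = int(rng.integers(0, config.d5_trim_max + 1)) if du else 0
        d3 = int(rng.integers(0, config.d3_trim_max + 1)) if du else 0
        if du and d5 + d3 >= len(d_seq):
            d_gene, d_raw = None, ""
        else:
            d_gene = du.id if du else None
            d_raw = d_seq[d5 : len(d_seq) - d3] if du else ""
        n1_len = int(rng.integers(0, config.n_length_max + 1))
        n2_len = int(rng.integers(0, config.n_length_max + 1)) if d_gene else 0
        v_raw = tail[: len(tail) - v_trim]
        j_raw = j5[j_trim:]
        next_v = tail[len(v_raw)] if v_trim > 0 else None
        prev_j = j5[j_trim - 1] if j_trim > 0 else None
        raw_surv = len(d_raw) if d_gene else 0
        for _attempt in range(60):
            if d_gene is not None:
                n1 = _draw_n_segment(rng, n1_len, next_v, d_seq[d5 - 1] if d5 > 0 else None)
                n2 = _draw_n_segment(
                    rng, n2_len, d_seq[len(d_seq) - d3] if d3 > 0 else None, prev_j
                )
            else:
                n1 = _draw_n_segment(rng, n1_len, next_v, prev_j)
                n2 = ""
            cdr3 = v_raw + n1 + d_raw + n2 + j_raw
            dcall = _canonical_call(cdr3, d_seqs) if d_seqs else None
            want_span = (len(v_raw) + len(n1), len(v_raw) + len(n1) + raw_surv)
            if dcall is None or _content_ok(dcall, raw_surv, d_gene, want_span):
                break
        # record the canonical decomposition (what sequence observers
        # can recover); raw trims stay alongside.  A fully consumed D
        # keeps the raw single-N form by definition.
        if d_gene is not None and d_seqs:
            from .junctions import decompose_junction

            decomp = decompose_junction(cdr3, tail, j5, dcall)
            v_part, n1, d_part, n2, j_part = (
                decomp.v_part, decomp.n1, decomp.d_part, decomp.n2, decomp.j_part,
            )
        else:
            v_part, d_part, n2, j_part = v_raw, "", "", j_raw

        j_rest = ju.meta["coding"][ju.meta["j5_len"] :]
        c_seq = cu.meta["exons"][0][: config.c_fragment_length]
        cdna = vu.meta["l1"] + vu.meta["l2"] + core + cdr3 + j_rest + c_seq
        in_frame = len(cdr3) % 3 == 0
        cdr3_aa = _translate(cdr3) if in_frame else ""
        productive = in_frame and "*" not in cdr3_aa
        clones.append(
            CloneTruth(
                clone_id=clone_id,
                subject_id=subject,
                v_gene_id=vu.id,
                d_gene_id=d_gene,
                j_gene_id=ju.id,
                c_gene_id=cu.id,
                v_trim=v_trim,
                d5_trim=d5,
                d3_trim=d3,
                j_trim=j_trim,
                v_part=v_part,
                n1_seq=n1,
                d_part=d_part,
                n2_seq=n2,
                j_part=j_part,
                cdr3_nt=cdr3,
                cdr3_aa=cdr3_aa,
                cdna_seq=cdna,
                productive=productive,
                d_surviving_nt=raw_surv,
                n1_length=n1_len,
                n2_length=n2_len,
                v_allele=allele,
                v_identity=ident,
            )
        )
        records.append((clone_id, cdna))
    return clones, records


def clone_truth_frame(clones: list[CloneTruth]):
    """Truth table as a pandas DataFrame (one clone per row)."""
    import pandas as pd

    return pd.DataFrame([c.__dict__ for c in clones])


# ---------------------------------------------------------------------------
# reference directory


def make_reference_directory(
    units: list[GeneUnit], seed: int = 0, identity: float = 0.92
) -> list[tuple[str, str]]:
    """Labeled germline exemplars for nomenclature transfer and
    reference-seeded gene location, mutated away from the simulated
    truth to emulate a related species' directory.

    Headers follow ``name|gene_type|subgroup``.  D exemplars are carried
    verbatim (they are located by RS evidence, and mutating a 13-mer
    would destroy its identity).
    """
    rng = np.random.default_rng(seed)
    m = _mutation_rate(_branch_retention(identity, other=1.0))
    records: list[tuple[str, str]] = []
    seen_subgroups: set[int] = set()
    for u in sorted(units, key=lambda u: u.start):
        if u.gene_type == "V":
            s = u.meta["subgroup"]
            if s in seen_subgroups:
                continue
            seen_subgroups.add(s)
            name = f"TRBV{s + 1}"
            anchors = _anchor_positions(u.meta["cdr1_len"], u.meta["cdr2_len"])
            fixed = _fixed_nt(list(anchors.values()))
            records.append(
                (f"{name}|V|{name}", _mutate_coding(u.meta["ancestor_core"], m, rng, fixed))
            )
            l1, _ = _mutate_leader(u.meta["ancestor_l1"], "A" * L_PART2_LEN, m, rng)
            records.append((f"{name}_L|L|{name}", l1))
        elif u.gene_type == "J":
            c, k = u.meta["cluster"], u.meta["pos"]
            name = f"TRBJ{c + 1}-{k + 1}"
            j5 = u.meta["j5_len"]
            fixed = frozenset(
                list(range(j5, j5 + 5)) + list(range(j5 + 9, j5 + 11))
            )  # keep TTTGG..GG of the FGXG motif
            records.append((f"{name}|J|TRBJ{c + 1}", _mutate(u.meta["coding"], m, rng, fixed)))
        elif u.gene_type == "D":
            name = f"TRBD{u.id[1:]}"
            records.append((f"{name}|D|{name}", u.meta["coding"]))
        elif u.gene_type == "C":
            c = u.meta["cluster"]
            name = f"TRBC{c + 1}"
            for e, exon in enumerate(u.meta["exons"]):
                fixed = (
                    frozenset(range(len(exon) - 3, len(exon))) if e == 3 else frozenset()
                )
                records.append(
                    (f"{name}_EX{e + 1}|C|{name}", _mutate_coding(exon[: len(exon) - len(exon) % 3], m, rng, fixed))
                )
    return records
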