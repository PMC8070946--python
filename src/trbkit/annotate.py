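"""Germline TRB locus annotation.

Gene units are delimited by recombination-signal (RS) scanning plus
reference-seeded similarity: V and J coding ends snap to the heptamer of
their flanking RS, exon boundaries snap to canonical GT/AG splice
dinucleotides, and D genes are called purely from facing 12/23 RS pairs.
Functionality is classified with the IMGT-style rule set (leader, RS and
splice canonicality, expected coding length, frameshift/stop scan,
J-motif and V-anchor conservation); V genes are partitioned into
subgroups at >75% V-REGION nucleotide identity.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio import Align
from Bio.Seq import Seq

from .units import (
    ACCEPTOR_SITE,
    DONOR_SITE,
    HEPTAMER_CONSENSUS,
    NONAMER_CONSENSUS,
    GeneUnit,
    GenomicRegion,
    RecombinationSignal,
    SpliceSite,
    functionality_from_defects,
    revcomp,
)
from . import numbering as imgt

L_PART2_LEN = 11
FR4_NT = 33


@dataclass
class AnnotationParams:
    max_heptamer_mm: int = 1
    max_nonamer_mm: int = 3
    spacer_tolerance: int = 1
    require_cac: bool = True
    canonical_heptamer_mm: int = 0
    canonical_nonamer_mm: int = 1
    min_identity: float = 0.80
    min_coverage: float = 0.90
    j_length_range: tuple[int, int] = (40, 53)
    d_length_range: tuple[int, int] = (10, 20)
    subgroup_identity_threshold: float = 0.75
    heptamer: str = HEPTAMER_CONSENSUS
    nonamer: str = NONAMER_CONSENSUS


def _aligner() -> Align.PairwiseAligner:
    # fixed scoring for reproducibility: match +5 / mismatch -4 / open -10 / extend -1
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 5
    a.mismatch_score = -4
    a.open_gap_score = -10
    a.extend_gap_score = -1
    return a


def _global_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 5
    a.mismatch_score = -4
    a.open_gap_score = -10
    a.extend_gap_score = -1
    # free end gaps: terminal overhangs are excluded from the identity
    try:
        a.end_insertion_score = 0
        a.end_deletion_score = 0
    except AttributeError:  # older biopython naming
        a.target_end_gap_score = 0
        a.query_end_gap_score = 0
    return a


def _seq_of(region) -> str:
    return region.sequence if isinstance(region, GenomicRegion) else str(region)


# ---------------------------------------------------------------------------
# recombination-signal scanning


def _mismatch_profile(arr: np.ndarray, motif: str) -> np.ndarray:
    """mm[i] = Hamming mismatches of seq[i:i+len(motif)] vs motif."""
    n, k = len(arr), len(motif)
    if n < k:
        return np.zeros(0, dtype=np.int32)
    out = np.zeros(n - k + 1, dtype=np.int32)
    mot = np.frombuffer(motif.encode(), dtype=np.uint8)
    for j in range(k):
        out += arr[j : n - k + 1 + j] != mot[j]
    return out


def _scan_one_strand(
    seq: str, side: str, spacer_class: int, p: AnnotationParams
) -> list[tuple[int, int, int, int, int]]:
    """Hits as (start, spacer_len, hept_mm, nona_mm, end) on this strand.

    Element layout 5'->3' on the scanned strand:
      three_prime (RS after the gene): heptamer + spacer + nonamer
      five_prime  (RS before the gene): rc(nonamer) + spacer + rc(heptamer)
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    hits = []
    if side == "three_prime":
        first, second = p.heptamer, p.nonamer
    elif side == "five_prime":
        first, second = revcomp(p.nonamer), revcomp(p.heptamer)
    else:
        raise ValueError(side)
    mm1 = _mismatch_profile(arr, first)
    mm2 = _mismatch_profile(arr, second)
    if p.require_cac:
        if side == "three_prime":
            cac_ok = _mismatch_profile(arr, "CAC") == 0
            cac_at = lambda i, sp: cac_ok[i]
        else:
            gtg_ok = _mismatch_profile(arr, revcomp("CAC")) == 0
            cac_at = lambda i, sp: gtg_ok[i + 9 + sp + 4]
    else:
        cac_at = lambda i, sp: True
    l1, l2 = len(first), len(second)
    for spacer in range(spacer_class - p.spacer_tolerance, spacer_class + p.spacer_tolerance + 1):
        total = l1 + spacer + l2
        limit = len(seq) - total + 1
        if limit <= 0:
            continue
        a = mm1[:limit]
        b = mm2[l1 + spacer : l1 + spacer + limit]
        if side == "three_prime":
            hept_mm, nona_mm = a, b
        else:
            nona_mm, hept_mm = a, b
        cand = np.nonzero((hept_mm <= p.max_heptamer_mm) & (nona_mm <= p.max_nonamer_mm))[0]
        for i in cand:
            i = int(i)
            if not cac_at(i, spacer):
                continue
            hits.append((i, spacer, int(hept_mm[i]), int(nona_mm[i]), i + total))
    return hits


def scan_recombination_signals(
    region,
    side: str,
    spacer_class: int,
    max_heptamer_mm: int = 1,
    max_nonamer_mm: int = 3,
    spacer_tolerance: int = 1,
    params: Optional[AnnotationParams] = None,
    strands: str = "both",
) -> list[RecombinationSignal]:
    """Scan for heptamer/spacer/nonamer elements of one side and spacer
    class on one or both strands; hits are sorted by plus-strand
    coordinate.  Returns an empty list when nothing qualifies."""
    p = params or AnnotationParams()
    p = AnnotationParams(
        **{
            **p.__dict__,
            "max_heptamer_mm": max_heptamer_mm,
            "max_nonamer_mm": max_nonamer_mm,
            "spacer_tolerance": spacer_tolerance,
        }
    )
    seq = _seq_of(region)
    out: list[RecombinationSignal] = []
    todo = [("+", seq)]
    if strands == "both":
        todo.append(("-", revcomp(seq)))
    elif strands == "-":
        todo = [("-", revcomp(seq))]
    n = len(seq)
    for strand, s in todo:
        for start, spacer, hmm, nmm, end in _scan_one_strand(s, side, spacer_class, p):
            span = (start, end) if strand == "+" else (n - end, n - start)
            gene_seq = s[start:end]
            if side == "three_prime":
                hept, nona = gene_seq[:7], gene_seq[-9:]
            else:
                hept, nona = revcomp(gene_seq[-7:]), revcomp(gene_seq[:9])
            out.append(
                RecombinationSignal(
                    side=side,
                    heptamer_seq=hept,
                    nonamer_seq=nona,
                    spacer_len=spacer,
                    heptamer_mismatches=hmm,
                    nonamer_mismatches=nmm,
                    span=span,
                    strand=strand,
                )
            )
    out.sort(key=lambda r: (r.span, r.strand))
    return out


# ---------------------------------------------------------------------------
# reference-seeded gene location


@dataclass
class ReferenceEntry:
    name: str
    gene_type: str
    subgroup: str
    seq: str


def parse_reference_records(records: dict[str, str] | list[tuple[str, str]]) -> list[ReferenceEntry]:
    """Reference directory FASTA with ``name|gene_type|subgroup`` headers."""
    if isinstance(records, dict):
        items = list(records.items())
    else:
        items = list(records)
    out = []
    for header, seq in items:
        parts = header.split("|")
        if len(parts) != 3:
            raise ValueError(f"reference header must be name|gene_type|subgroup: {header!r}")
        name, gtype, subgroup = parts
        if gtype not in {"V", "D", "J", "C", "L"}:
            raise ValueError(f"unknown gene_type label {gtype!r} for {name!r}")
        out.append(ReferenceEntry(name, gtype, subgroup, seq.upper()))
    return out


@dataclass
class Candidate:
    ref: ReferenceEntry
    strand: str
    # inferred placement of the *full* reference on the plus strand of the
    # gene-oriented sequence (substitution-only assumption)
    start: int
    end: int
    identity: float
    coverage: float


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return index


def _alignment_stats(aln) -> tuple[int, int, int, int, int, int]:
    """(matches, columns, ref_start, ref_end, tgt_start, tgt_end)."""
    tgt_blocks, ref_blocks = aln.aligned
    matches = cols = 0
    target, query = str(aln.target), str(aln.query)
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(tgt_blocks, ref_blocks):
        if prev_t is not None:
            cols += (ts - prev_t) + (qs - prev_q)
        for a, b in zip(target[ts:te], query[qs:qe]):
            matches += a == b
        cols += te - ts
        prev_t, prev_q = te, qe
    return (
        matches,
        cols,
        int(ref_blocks[0][0]),
        int(ref_blocks[-1][1]),
        int(tgt_blocks[0][0]),
        int(tgt_blocks[-1][1]),
    )


def locate_gene_units(
    region,
    reference_exemplars,
    min_identity: float = 0.80,
    min_coverage: float = 0.90,
    k: int = 11,
) -> list[Candidate]:
    """Seed-and-extend local alignment of labeled exemplars on both
    strands.  Candidate spans are the inferred placement of the whole
    exemplar; overlapping candidates of a type keep the best identity."""
    seq = _seq_of(region)
    refs = (
        reference_exemplars
        if reference_exemplars and isinstance(reference_exemplars[0], ReferenceEntry)
        else parse_reference_records(reference_exemplars)
    )
    index = _kmer_index(seq, k)
    aligner = _aligner()
    n = len(seq)
    cands: list[Candidate] = []
    for ref in refs:
        for strand in "+-":
            q = ref.seq if strand == "+" else revcomp(ref.seq)
            diags: list[int] = []
            for i in range(0, len(q) - k + 1, 3):
                for pos in index.get(q[i : i + k], ()):
                    diags.append(pos - i)
            if not diags:
                continue
            diags.sort()
            groups: list[list[int]] = [[diags[0]]]
            for d in diags[1:]:
                if d - groups[-1][-1] <= 30:
                    groups[-1].append(d)
                else:
                    groups.append([d])
            for g in groups:
                w0 = max(0, g[0] - 25)
                w1 = min(n, g[-1] + len(q) + 25)
                window = seq[w0:w1]
                try:
                    aln = aligner.align(window, q)[0]
                except (IndexError, ValueError):
                    continue
                matches, cols, qs, qe, ts, te = _alignment_stats(aln)
                if cols == 0:
                    continue
                identity = matches / cols
                coverage = (qe - qs) / len(q)
                if identity < min_identity or coverage < min_coverage:
                    continue
                # infer full-exemplar placement (substitution-dominated)
                start_plus = w0 + ts - qs
                end_plus = start_plus + len(q)
                if strand == "+":
                    s, e = start_plus, end_plus
                else:
                    s, e = n - end_plus, n - start_plus
                cands.append(Candidate(ref, strand, max(0, s), min(n, e), identity, coverage))
    # deduplicate overlapping candidates of the same gene type
    cands.sort(key=lambda c: (-c.identity, c.start))
    kept: list[Candidate] = []
    for c in cands:
        clash = any(
            k.ref.gene_type == c.ref.gene_type
            and min(k.end, c.end) - max(k.start, c.start) > 0.5 * (c.end - c.start)
            for k in kept
        )
        if not clash:
            kept.append(c)
    kept.sort(key=lambda c: c.start)
    return kept


# ---------------------------------------------------------------------------
# unit assembly (snapping candidates to RS / splice evidence)


def _oriented(seq: str, strand: str) -> str:
    return seq if strand == "+" else revcomp(seq)


def _map_span(span: tuple[int, int], strand: str, n: int) -> tuple[int, int]:
    return span if strand == "+" else (n - span[1], n - span[0])


def _nearest_rs(hits: list[RecombinationSignal], pos: int, *, key: str, tol: int = 40):
    best = None
    for h in hits:
        anchor = h.span[0] if key == "start" else h.span[1]
        d = abs(anchor - pos)
        if d <= tol and (best is None or d < abs((best.span[0] if key == "start" else best.span[1]) - pos)):
            best = h
    return best


def annotate_locus(
    region,
    reference_records,
    params: Optional[AnnotationParams] = None,
) -> list[GeneUnit]:
    """Full annotation: locate candidates, snap to RS/splice evidence,
    call D genes from facing RS pairs, classify functionality, and name
    units (via :func:`partition_subgroups` / :func:`assign_nomenclature`
    and :func:`build_cluster_layout`)."""
    p = params or AnnotationParams()
    seq = _seq_of(region)
    refs = parse_reference_records(reference_records)
    leaders = {r.subgroup: r for r in refs if r.gene_type == "L"}
    cands = locate_gene_units(region, refs, p.min_identity, p.min_coverage)

    units: list[GeneUnit] = []
    counters = defaultdict(int)
    for c in cands:
        if c.ref.gene_type == "V":
            u = _assemble_v_unit(seq, c, leaders.get(c.ref.subgroup), p)
        elif c.ref.gene_type == "J":
            u = _assemble_j_unit(seq, c, p)
        else:
            u = None
        if u is not None:
            counters[u.gene_type] += 1
            u.id = f"{u.gene_type}{counters[u.gene_type]}"
            units.append(u)

    units.extend(_assemble_c_units(seq, cands, refs, p))
    for i, u in enumerate([u for u in units if u.gene_type == "C"], 1):
        u.id = f"C{i}"
    units.extend(_call_d_units(seq, p))
    for i, u in enumerate([u for u in units if u.gene_type == "D"], 1):
        u.id = f"D{i}"

    units.sort(key=lambda u: u.start)
    # re-number ids in genomic order per type
    counters = defaultdict(int)
    for u in units:
        counters[u.gene_type] += 1
        u.id = f"{u.gene_type}{counters[u.gene_type]}"

    for u in units:
        call = classify_functionality(u, seq, p)
        u.functionality = call.label
        u.defects = call.defects

    v_units = [u for u in units if u.gene_type == "V"]
    for u in v_units:
        u.meta["vregion_seq"] = v_region_sequence(u, seq)
    if v_units:
        partition = partition_subgroups(v_units, seq, p.subgroup_identity_threshold)
        assign_nomenclature(units, partition, refs)
    try:
        clusters = build_cluster_layout(
            [u for u in units if u.gene_type == "D"],
            [u for u in units if u.gene_type == "J"],
            [u for u in units if u.gene_type == "C"],
        )
        _apply_cluster_names(units, clusters, seq, refs)
    except ValueError:
        pass  # layout errors leave positional ids in place
    return units


def _assemble_v_unit(seq, cand: Candidate, leader_ref, p: AnnotationParams) -> Optional[GeneUnit]:
    n = len(seq)
    s = _oriented(seq, cand.strand)
    core_start, core_end = (
        (cand.start, cand.end) if cand.strand == "+" else (n - cand.end, n - cand.start)
    )
    # 3' RS: heptamer should begin at the end of the germline V (core +
    # short CDR3 tail); scan a window downstream of the core
    w0, w1 = max(0, core_end - 5), min(len(s), core_end + 60)
    hits = scan_recombination_signals(
        s[w0:w1], "three_prime", 23, p.max_heptamer_mm, p.max_nonamer_mm, p.spacer_tolerance,
        params=p, strands="+",
    )
    defects_meta = {}
    if hits:
        rs = min(
            hits,
            key=lambda h: (
                h.heptamer_mismatches + h.nonamer_mismatches + abs(h.spacer_len - 23),
                h.span,
            ),
        )
        rs = RecombinationSignal(**{**rs.__dict__, "span": (rs.span[0] + w0, rs.span[1] + w0)})
        exon_end = rs.span[0]
        rs_list = [rs]
    else:
        exon_end = core_end
        rs_list = []
        defects_meta["missing_rs"] = True
    exon_start = core_start - L_PART2_LEN
    if exon_start < 2:
        return None
    net_indel = _net_indels(
        s[core_start : core_start + len(cand.ref.seq) + 8], cand.ref.seq
    )
    splice_sites = []
    acceptor_seq = s[exon_start - 2 : exon_start]
    splice_sites.append(
        SpliceSite("acceptor", exon_start - 2, acceptor_seq, acceptor_seq == ACCEPTOR_SITE)
    )
    # leader exon upstream, located with the subgroup's L exemplar
    l1_span = None
    if leader_ref is not None:
        w0l = max(0, exon_start - 650)
        window = s[w0l:exon_start]
        aligner = _aligner()
        try:
            aln = aligner.align(window, leader_ref.seq)[0]
            matches, cols, qs, qe, ts, te = _alignment_stats(aln)
            if cols and matches / cols >= 0.70 and (qe - qs) / len(leader_ref.seq) >= 0.8:
                l1_start = w0l + ts - qs
                l1_end = l1_start + len(leader_ref.seq)
                l1_span = (l1_start, l1_end)
                donor_seq = s[l1_end : l1_end + 2]
                splice_sites.insert(
                    0, SpliceSite("donor", l1_end, donor_seq, donor_seq == DONOR_SITE)
                )
        except (IndexError, ValueError):
            pass
    spans = ([l1_span] if l1_span else []) + [(exon_start, exon_end)]
    if cand.strand == "-":
        spans = [_map_span(sp, "-", n) for sp in spans]
        rs_list = [
            RecombinationSignal(**{**r.__dict__, "span": _map_span(r.span, "-", n), "strand": "-"})
            for r in rs_list
        ]
        for ss in splice_sites:
            ss.pos = n - ss.pos - 2
    return GeneUnit(
        id="V?",
        gene_type="V",
        strand=cand.strand,
        coding_spans=spans,
        rs_elements=rs_list,
        splice_sites=splice_sites,
        meta={
            "ref_name": cand.ref.name,
            "ref_subgroup": cand.ref.subgroup,
            "ref_len": len(cand.ref.seq),
            "identity": cand.identity,
            "has_leader": l1_span is not None,
            "net_indel": net_indel,
            **defects_meta,
        },
    )


def _assemble_j_unit(seq, cand: Candidate, p: AnnotationParams) -> Optional[GeneUnit]:
    n = len(seq)
    s = _oriented(seq, cand.strand)
    start, end = (cand.start, cand.end) if cand.strand == "+" else (n - cand.end, n - cand.start)
    w0 = max(0, start - 40)
    hits = scan_recombination_signals(
        s[w0 : start + 10], "five_prime", 12, p.max_heptamer_mm, p.max_nonamer_mm,
        p.spacer_tolerance, params=p, strands="+",
    )
    rs_list = []
    if hits:
        rs = min(
            hits,
            key=lambda h: (
                abs((h.span[1] + w0) - start),
                h.heptamer_mismatches + h.nonamer_mismatches + abs(h.spacer_len - 12),
            ),
        )
        rs = RecombinationSignal(**{**rs.__dict__, "span": (rs.span[0] + w0, rs.span[1] + w0)})
        coding_start = rs.span[1]
        rs_list = [rs]
    else:
        coding_start = start
    # snap the 3' end through the exemplar alignment so single-nt indels
    # (frameshifts) keep the donor site in register
    window = s[coding_start : coding_start + len(cand.ref.seq) + 8]
    net_indel = _net_indels(window, cand.ref.seq)
    coding_end = coding_start + len(cand.ref.seq) + net_indel
    donor_seq = s[coding_end : coding_end + 2]
    splice = [SpliceSite("donor", coding_end, donor_seq, donor_seq == DONOR_SITE)]
    spans = [(coding_start, coding_end)]
    if cand.strand == "-":
        spans = [_map_span(sp, "-", n) for sp in spans]
        rs_list = [
            RecombinationSignal(**{**r.__dict__, "span": _map_span(r.span, "-", n), "strand": "-"})
            for r in rs_list
        ]
        for ss in splice:
            ss.pos = n - ss.pos - 2
    return GeneUnit(
        id="J?",
        gene_type="J",
        strand=cand.strand,
        coding_spans=spans,
        rs_elements=rs_list,
        splice_sites=splice,
        meta={"ref_name": cand.ref.name, "ref_subgroup": cand.ref.subgroup,
              "ref_len": len(cand.ref.seq), "identity": cand.identity,
              "net_indel": net_indel},
    )


def _assemble_c_units(
    seq: str, cands: list[Candidate], refs: list[ReferenceEntry], p: AnnotationParams
) -> list[GeneUnit]:
    """C units anchored on their EX1 candidate; later exons are walked
    via acceptor/donor snapping and Hamming identity to the reference
    exon of the same subgroup (short exons need no seed hits)."""
    ex1 = [c for c in cands if c.ref.gene_type == "C" and c.ref.name.endswith("_EX1")]
    ref_exons: dict[str, dict[int, str]] = defaultdict(dict)
    for r in refs:
        if r.gene_type == "C" and "_EX" in r.name:
            ref_exons[r.subgroup][int(r.name.rsplit("_EX", 1)[1])] = r.seq
    units = []
    for c in sorted(ex1, key=lambda c: c.start):
        exons = ref_exons[c.ref.subgroup]
        net_indel = _net_indels(seq[c.start : c.start + len(exons[1]) + 8], exons[1])
        spans = [(c.start, c.start + len(exons[1]) + net_indel)]
        sites = [
            SpliceSite(
                "acceptor", c.start - 2, seq[c.start - 2 : c.start],
                seq[c.start - 2 : c.start] == ACCEPTOR_SITE,
            )
        ]
        ok = True
        for e in range(2, max(exons) + 1):
            prev_end = spans[-1][1]
            d_seq = seq[prev_end : prev_end + 2]
            sites.append(SpliceSite("donor", prev_end, d_seq, d_seq == DONOR_SITE))
            ref_exon = exons[e]
            best = None
            for pos in range(prev_end + 40, min(prev_end + 400, len(seq) - len(ref_exon))):
                if seq[pos - 2 : pos] != ACCEPTOR_SITE:
                    continue
                cand_seq = seq[pos : pos + len(ref_exon)]
                ident = sum(a == b for a, b in zip(cand_seq, ref_exon)) / len(ref_exon)
                if best is None or ident > best[1]:
                    best = (pos, ident)
            if best is None or best[1] < 0.70:
                ok = False
                break
            pos = best[0]
            sites.append(SpliceSite("acceptor", pos - 2, ACCEPTOR_SITE, True))
            spans.append((pos, pos + len(ref_exon)))
        if not ok:
            continue
        units.append(
            GeneUnit(
                id="C?",
                gene_type="C",
                coding_spans=spans,
                splice_sites=sites,
                meta={"ref_name": c.ref.name.rsplit("_EX", 1)[0], "ref_subgroup": c.ref.subgroup,
                      "identity": c.identity, "net_indel": net_indel},
            )
        )
    return units


def _call_d_units(seq: str, p: AnnotationParams) -> list[GeneUnit]:
    five = scan_recombination_signals(
        seq, "five_prime", 12, p.max_heptamer_mm, p.max_nonamer_mm, p.spacer_tolerance,
        params=p, strands="+",
    )
    three = scan_recombination_signals(
        seq, "three_prime", 23, p.max_heptamer_mm, p.max_nonamer_mm, p.spacer_tolerance,
        params=p, strands="+",
    )
    lo, hi = p.d_length_range
    # spacer-tolerance variants of one element share the heptamer edge:
    # keep the best-conserved hit per coding span
    best: dict[tuple[int, int], tuple[int, RecombinationSignal, RecombinationSignal]] = {}
    for f in five:
        for t in three:
            gap = t.span[0] - f.span[1]
            if lo <= gap <= hi:
                span = (f.span[1], t.span[0])
                mm = (
                    f.heptamer_mismatches + f.nonamer_mismatches
                    + t.heptamer_mismatches + t.nonamer_mismatches
                    + abs(f.spacer_len - 12) + abs(t.spacer_len - 23)
                )
                if span not in best or mm < best[span][0]:
                    best[span] = (mm, f, t)
    return [
        GeneUnit(
            id="D?",
            gene_type="D",
            coding_spans=[span],
            rs_elements=[f, t],
            meta={"coding": seq[span[0] : span[1]]},
        )
        for span, (_, f, t) in sorted(best.items())
    ]


# ---------------------------------------------------------------------------
# functionality classification


def classify_functionality(unit: GeneUnit, region, p: Optional[AnnotationParams] = None):
    """IMGT-style call: leader (V), RS canonicality, splice sites,
    expected coding length, frameshift/stop scan, J motif, V anchors.
    Returns a FunctionalityCall-like object with .label and .defects."""
    from .units import FunctionalityCall

    p = p or AnnotationParams()
    seq = _seq_of(region)
    defects: list[str] = []
    gt = unit.gene_type
    coding = unit.coding_seq(seq)

    for rs in unit.rs_elements:
        if rs.heptamer_mismatches > p.canonical_heptamer_mm:
            defects.append("noncanonical_heptamer")
        if rs.nonamer_mismatches > p.canonical_nonamer_mm:
            defects.append("noncanonical_nonamer")
    if not unit.rs_elements and gt in "VDJ":
        defects.append("noncanonical_heptamer")
    if unit.meta.get("missing_rs"):
        pass  # already reflected in empty rs_elements
    if any(not s.canonical for s in unit.splice_sites):
        defects.append("noncanonical_splice")

    if gt == "V":
        if not unit.meta.get("has_leader", len(unit.coding_spans) > 1):
            defects.append("missing_leader")
        elif len(unit.coding_spans) > 1:
            l1_start = sorted(unit.coding_spans)[0][0]
            l1 = seq[l1_start : l1_start + 3] if unit.strand == "+" else revcomp(
                seq[sorted(unit.coding_spans)[0][1] - 3 : sorted(unit.coding_spans)[0][1]]
            )
            if l1 != "ATG":
                defects.append("missing_leader")
        spans = sorted(unit.coding_spans)
        vexon = (
            seq[spans[-1][0] : spans[-1][1]]
            if unit.strand == "+"
            else revcomp(seq[spans[-1][0] : spans[-1][1]])
        )
        if unit.meta.get("net_indel", 0) % 3 != 0:
            defects.append("frameshift")
        if "*" in _translate_frame0(coding):
            defects.append("stop_codon")
        if "frameshift" not in defects and "stop_codon" not in defects:
            aa = _translate_frame0(vexon[L_PART2_LEN:])
            try:
                numbered = imgt.number_v_region(aa)
                report = imgt.validate_anchors(numbered)
                if not (report.anchors["cys23"] and report.anchors["cys104"]):
                    defects.append("missing_anchor")
            except imgt.NumberingError:
                defects.append("missing_anchor")
    elif gt == "J":
        lo, hi = p.j_length_range
        if not (lo <= len(coding) <= hi):
            defects.append("unexpected_length")
        if unit.meta.get("net_indel", 0) % 3 != 0:
            defects.append("frameshift")
        off = len(coding) % 3
        aa = _translate_frame0(coding[off:])
        if "*" in aa:
            defects.append("stop_codon")
        fr4 = coding[-FR4_NT:]
        fr4_aa = _translate_frame0(fr4)
        if not (len(fr4_aa) >= 4 and fr4_aa[0] == "F" and fr4_aa[1] == "G" and fr4_aa[3] == "G"):
            defects.append("nonconserved_j_motif")
    elif gt == "C":
        if len(coding) % 3 != 0 or unit.meta.get("net_indel", 0) % 3 != 0:
            defects.append("frameshift")
        aa = _translate_frame0(coding)
        if "*" in aa[:-1]:
            defects.append("stop_codon")
    elif gt == "D":
        lo, hi = p.d_length_range
        if not (lo <= len(coding) <= hi):
            defects.append("unexpected_length")

    defects = sorted(set(defects))
    return FunctionalityCall(label=functionality_from_defects(defects), defects=defects)


def _translate_frame0(seq: str) -> str:
    usable = seq[: len(seq) - len(seq) % 3]
    return str(Seq(usable).translate())


#: a gapped alignment must beat the gapless placement by this many
#: edits before an indel (frameshift evidence) is believed
_INDEL_EVIDENCE = 5


def _net_indels(target: str, ref_seq: str) -> int:
    """Net indel count (target minus reference aligned span) of the
    exemplar placed at the start of ``target``.

    The exemplar is first placed without gaps (substitution-only
    divergence is the expected case); a gapped infix alignment is
    believed only when it saves at least ``_INDEL_EVIDENCE`` edits,
    which a genuine frameshift always does while end-effect gap
    shuffling does not."""
    import edlib

    L = len(ref_seq)
    gapless = sum(a != b for a, b in zip(ref_seq, target[:L])) + max(0, L - len(target))
    res = edlib.align(ref_seq, target, mode="HW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return 0
    if gapless - res["editDistance"] < _INDEL_EVIDENCE:
        return 0
    start, end = res["locations"][0]
    return (end + 1 - start) - L


def translate_d_frames(d_unit: GeneUnit, region) -> tuple[list[str], bool]:
    """Translations of the three coding phases of a D gene; the flag is
    True when no phase contains a stop (productively read in all three
    frames)."""
    seq = d_unit.coding_seq(_seq_of(region))
    if len(seq) < 3:
        raise ValueError("D coding length must be >= 3")
    peptides = [_translate_frame0(seq[f:]) for f in range(3)]
    return peptides, all("*" not in pep for pep in peptides)


# ---------------------------------------------------------------------------
# subgroup partition and nomenclature


@dataclass
class SubgroupPartition:
    groups: dict[int, list[str]]
    identity_matrix: np.ndarray
    labels: list[str]

    def group_of(self, unit_id: str) -> int:
        for g, members in self.groups.items():
            if unit_id in members:
                return g
        raise KeyError(unit_id)


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment nucleotide identity over aligned columns,
    excluding terminal overhangs; internal gaps count as mismatches."""
    aligner = _global_aligner()
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    # trim terminal overhang columns (gap in either sequence at the ends)
    start = 0
    while start < len(sa) and (sa[start] == "-" or sb[start] == "-"):
        start += 1
    end = len(sa)
    while end > start and (sa[end - 1] == "-" or sb[end - 1] == "-"):
        end -= 1
    cols = end - start
    if cols <= 0:
        return 0.0
    matches = sum(x == y and x != "-" for x, y in zip(sa[start:end], sb[start:end]))
    return matches / cols


def v_region_sequence(unit: GeneUnit, seq: str) -> str:
    """V-REGION nucleotides (V exon minus L-PART2, minus any 3' tail
    beyond the exemplar length when known)."""
    spans = sorted(unit.coding_spans)
    vexon = seq[spans[-1][0] : spans[-1][1]]
    if unit.strand == "-":
        vexon = revcomp(vexon)
    core = vexon[L_PART2_LEN:] if len(spans) > 1 or len(vexon) > 250 else vexon
    ref_len = unit.meta.get("ref_len")
    if ref_len is not None and len(core) > ref_len:
        core = core[:ref_len]
    return core


def partition_subgroups(
    v_units: list[GeneUnit], region, threshold: float = 0.75
) -> SubgroupPartition:
    """Connected components of the graph with an edge where pairwise
    V-REGION identity exceeds the threshold (default >0.75)."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    if not v_units:
        raise ValueError("at least one V unit required")
    seq = _seq_of(region)
    units = sorted(v_units, key=lambda u: u.id)
    seqs = [v_region_sequence(u, seq) for u in units]
    m = len(units)
    ident = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            ident[i, j] = ident[j, i] = pairwise_identity(seqs[i], seqs[j])
    adj = csr_matrix(ident > threshold)
    n_comp, labels = connected_components(adj, directed=False)
    groups: dict[int, list[str]] = defaultdict(list)
    order = {u.id: u.start for u in units}
    for u, lab in zip(units, labels):
        groups[int(lab)].append(u.id)
    for g in groups:
        groups[g].sort(key=lambda uid: order[uid])
    # renumber groups by genomic order of their first member
    renum = {
        old: new
        for new, old in enumerate(
            sorted(groups, key=lambda g: min(order[uid] for uid in groups[g]))
        )
    }
    groups = {renum[g]: members for g, members in groups.items()}
    return SubgroupPartition(dict(sorted(groups.items())), ident, [u.id for u in units])


def _ref_number(name: str) -> tuple[int, str]:
    digits = "".join(ch for ch in name if ch.isdigit())
    return (int(digits) if digits else 10**9, name)


def assign_nomenclature(
    units: list[GeneUnit],
    partition: SubgroupPartition,
    reference_records,
    novel_threshold: float = 0.75,
) -> None:
    """Name V subgroups by their highest-identity reference subgroup;
    multi-member subgroups get hyphenated position numbers in genomic
    order; ties go to the lower-numbered reference (flagged); unmatched
    subgroups get sequential novel names."""
    refs = (
        reference_records
        if reference_records and isinstance(reference_records[0], ReferenceEntry)
        else parse_reference_records(reference_records)
    )
    v_refs = [r for r in refs if r.gene_type == "V"]
    by_id = {u.id: u for u in units}
    region_seqs = {u.id: u.meta.get("vregion_seq") for u in units}
    novel = 0
    used: set[str] = set()
    for g, members in partition.groups.items():
        rep = by_id[members[0]]
        rep_seq = rep.meta.get("vregion_seq")
        best_name, best_ident, tie = None, -1.0, False
        for r in sorted(v_refs, key=lambda r: _ref_number(r.subgroup)):
            ident = pairwise_identity(rep_seq, r.seq) if rep_seq else 0.0
            if ident > best_ident + 1e-12:
                best_name, best_ident, tie = r.subgroup, ident, False
            elif abs(ident - best_ident) <= 1e-12 and best_name is not None:
                tie = True
        if best_name is None or best_ident <= novel_threshold or best_name in used:
            novel += 1
            best_name = f"TRBVN{novel}"
        used.add(best_name)
        for k, uid in enumerate(members, 1):
            u = by_id[uid]
            u.name = best_name if len(members) == 1 else f"{best_name}-{k}"
            u.meta["subgroup_name"] = best_name
            if tie:
                u.meta["naming_tie"] = True


@dataclass
class DJCluster:
    name: str
    index: int
    d_id: Optional[str]
    j_ids: list[str]
    c_id: Optional[str]

    @property
    def member_ids(self) -> list[str]:
        return ([self.d_id] if self.d_id else []) + self.j_ids + ([self.c_id] if self.c_id else [])


def build_cluster_layout(
    d_units: list[GeneUnit], j_units: list[GeneUnit], c_units: list[GeneUnit]
) -> list[DJCluster]:
    """Group D/J/C units into maximal genomically-contiguous D?-J+-C?
    runs, 5'->3'.  Out-of-order arrangements raise with offending ids."""
    everything = sorted(d_units + j_units + c_units, key=lambda u: u.start)
    clusters: list[DJCluster] = []
    cur_d: Optional[str] = None
    cur_j: list[str] = []
    idx = 0

    def flush():
        nonlocal cur_d, cur_j, idx
        if cur_d or cur_j:
            if not cur_j:
                raise ValueError(f"cluster with D {cur_d} has no J genes")
            idx += 1
            clusters.append(DJCluster(f"cluster{idx}", idx, cur_d, cur_j, None))
            cur_d, cur_j = None, []

    for u in everything:
        if u.gene_type == "D":
            flush()
            cur_d = u.id
        elif u.gene_type == "J":
            cur_j.append(u.id)
        else:  # C closes a cluster
            if not cur_j:
                raise ValueError(f"C gene {u.id} not preceded by any J gene")
            idx += 1
            clusters.append(DJCluster(f"cluster{idx}", idx, cur_d, cur_j, u.id))
            cur_d, cur_j = None, []
    flush()
    return clusters


def _apply_cluster_names(units, clusters, seq, refs) -> None:
    """Transfer cluster numbers from best-matching C references when
    available, else fall back to positional numbering, then name D/J/C
    members accordingly (TRBJ<cluster>-<position>)."""
    by_id = {u.id: u for u in units}
    c_refs = defaultdict(dict)
    for r in refs:
        if r.gene_type == "C" and "_EX" in r.name:
            c_refs[r.subgroup][int(r.name.rsplit("_EX", 1)[1])] = r.seq
    for cl in clusters:
        number = cl.index
        if cl.c_id:
            cu = by_id[cl.c_id]
            best = None
            ex1 = cu.coding_seq(seq)[: 400]
            for sub, exons in c_refs.items():
                if 1 in exons:
                    ident = pairwise_identity(ex1[: len(exons[1])], exons[1])
                    if best is None or ident > best[1]:
                        best = (sub, ident)
            if best and best[1] > 0.75:
                digits = "".join(ch for ch in best[0] if ch.isdigit())
                if digits:
                    number = int(digits)
            cu.name = f"TRBC{number}"
            cu.meta["cluster"] = cl.index - 1
        if cl.d_id:
            du = by_id[cl.d_id]
            du.name = f"TRBD{number}"
            du.meta["cluster"] = cl.index - 1
        for k, jid in enumerate(cl.j_ids, 1):
            ju = by_id[jid]
            ju.name = f"TRBJ{number}-{k}"
            ju.meta["cluster"] = cl.index - 1
            ju.meta["pos"] = k - 1
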