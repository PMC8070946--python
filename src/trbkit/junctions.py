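"""Expressed-repertoire junction analysis.

Assigns V/J/C genes (and allele status) to rearranged cDNA by alignment
against the germline set, extracts the CDR3 (codons 105-117, between the
2nd-CYS codon and the J-PHE codon), identifies the D gene by the
>=5-consecutive-nucleotide rule (exact substring, forward strand only),
decomposes the junction into V / N1 / D / N2 / J parts, and classifies
rearrangements as intra- or intercluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import edlib
import pandas as pd
from Bio.Seq import Seq

from .formats import REARRANGEMENT_COLUMNS
from .numbering import NumberingError, number_v_region
from .units import GeneUnit, revcomp

L_PART2_LEN = 11
FR4_NT = 33


def _translate(seq: str) -> str:
    usable = seq[: len(seq) - len(seq) % 3]
    return str(Seq(usable).translate())


# ---------------------------------------------------------------------------
# germline set


@dataclass
class GermlineV:
    id: str
    name: str
    core: str  # V-REGION through the 2nd-CYS codon (104)
    tail: str  # germline 3' continuation into CDR3


@dataclass
class GermlineJ:
    id: str
    name: str
    coding: str
    j5_len: int  # nt 5' of the J-PHE codon
    cluster: Optional[int]

    @property
    def j5(self) -> str:
        return self.coding[: self.j5_len]


@dataclass
class GermlineD:
    id: str
    name: str
    seq: str
    cluster: Optional[int]


@dataclass
class GermlineC:
    id: str
    name: str
    ex1: str
    cluster: Optional[int]


@dataclass
class GermlineSet:
    vs: dict[str, GermlineV]
    js: dict[str, GermlineJ]
    ds: dict[str, GermlineD]
    cs: dict[str, GermlineC]

    @property
    def cluster_of(self) -> dict[str, Optional[int]]:
        out: dict[str, Optional[int]] = {}
        for j in self.js.values():
            out[j.id] = j.cluster
        for d in self.ds.values():
            out[d.id] = d.cluster
        return out


def _j_phe_offset(coding: str) -> int:
    """nt offset of the J-PHE codon: the FGXG motif read in the
    3'-anchored frame, 33 nt from the coding end by construction."""
    cand = len(coding) - FR4_NT
    if cand >= 0:
        aa = _translate(coding[cand:])
        if len(aa) >= 4 and aa[0] in "FW" and aa[1] == "G" and aa[3] == "G":
            return cand
    # fallback: scan for the motif anywhere in the 3' half
    for i in range(len(coding) - 12, -1, -1):
        aa = _translate(coding[i : i + 12])
        if len(aa) == 4 and aa[0] in "FW" and aa[1] == "G" and aa[3] == "G":
            return i
    raise ValueError("no FGXG motif found in J coding sequence")


def build_germline_set(units: list[GeneUnit], region: str) -> GermlineSet:
    """Derive the aligned germline set from annotated (or simulated
    ground-truth) gene units plus the genomic sequence.  V genes that
    cannot be numbered (e.g. frameshifted pseudogenes) are skipped."""
    vs, js, ds, cs = {}, {}, {}, {}
    for u in units:
        label = u.name or u.id
        if u.gene_type == "V":
            spans = sorted(u.coding_spans)
            vexon = region[spans[-1][0] : spans[-1][1]]
            if u.strand == "-":
                vexon = revcomp(vexon)
            vreg = vexon[L_PART2_LEN:] if len(spans) > 1 or len(vexon) > 250 else vexon
            try:
                dom = number_v_region(_translate(vreg))
            except NumberingError:
                continue
            a, b = dom.cdr_lengths[0], dom.cdr_lengths[1]
            core_len = (82 + a + b) * 3
            vs[u.id] = GermlineV(u.id, label, vreg[:core_len], vreg[core_len:])
        elif u.gene_type == "J":
            coding = u.coding_seq(region)
            try:
                j5 = _j_phe_offset(coding)
            except ValueError:
                continue
            js[u.id] = GermlineJ(u.id, label, coding, j5, u.meta.get("cluster"))
        elif u.gene_type == "D":
            ds[u.id] = GermlineD(u.id, label, u.coding_seq(region), u.meta.get("cluster"))
        elif u.gene_type == "C":
            ex1 = region[sorted(u.coding_spans)[0][0] : sorted(u.coding_spans)[0][1]]
            cs[u.id] = GermlineC(u.id, label, ex1, u.meta.get("cluster"))
    return GermlineSet(vs, js, ds, cs)


# ---------------------------------------------------------------------------
# V / J / C assignment


@dataclass
class VAssignment:
    gene_id: str
    allele_status: str  # germline_exact | new_allele | low_identity
    identity: float
    span: tuple[int, int]  # aligned span on the cDNA (half-open)
    end104: int  # cDNA offset just past the 2nd-CYS codon
    tie: bool = False


@dataclass
class JAssignment:
    gene_id: str
    identity: float
    span: tuple[int, int]
    phe_pos: int  # cDNA offset of the J-PHE codon start


def _edlib_identity(query: str, target: str) -> tuple[float, tuple[int, int], str]:
    """(identity over aligned columns, target span, cigar) of an infix
    alignment of query in target."""
    res = edlib.align(query, target, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return 0.0, (0, 0), ""
    start, end = res["locations"][0]
    nice = edlib.getNiceAlignment(res, query, target)
    cols = len(nice["matched_aligned"])
    matches = nice["matched_aligned"].count("|")
    return (matches / cols if cols else 0.0), (start, end + 1), res["cigar"]


def _walk_cigar_to_target(cigar: str, target_start: int, query_offset: int) -> int:
    """Target coordinate reached after consuming ``query_offset`` query
    bases along the alignment path."""
    import re

    q = t = 0
    for num, op in re.findall(r"(\d+)([=XIDM])", cigar):
        n = int(num)
        if op in "=XM":
            if q + n >= query_offset:
                return target_start + t + (query_offset - q)
            q += n
            t += n
        elif op == "I":  # query bases absent from the target
            if q + n >= query_offset:
                return target_start + t
            q += n
        elif op == "D":  # target bases absent from the query
            t += n
    return target_start + t


def assign_v(cdna: str, germline_v_set: dict[str, GermlineV]) -> VAssignment:
    """Best germline V by identity over the aligned V-REGION columns up
    to (not including) codon 105.  Ties break to the lexicographically
    smallest gene id (flagged)."""
    if not germline_v_set:
        raise ValueError("empty germline V set")
    scored = []
    for gid in sorted(germline_v_set):
        g = germline_v_set[gid]
        res = edlib.align(g.core, cdna, mode="HW", task="distance")
        scored.append((res["editDistance"] if res["editDistance"] >= 0 else 10**9, gid))
    scored.sort()
    best_dist = scored[0][0]
    contenders = [gid for d, gid in scored if d <= best_dist + 2]
    best = None
    for gid in contenders:
        g = germline_v_set[gid]
        ident, span, cigar = _edlib_identity(g.core, cdna)
        if best is None or ident > best[0] + 1e-12:
            best = (ident, gid, span, cigar, False)
        elif abs(ident - best[0]) <= 1e-12:
            best = (best[0], best[1], best[2], best[3], True)
    ident, gid, span, cigar, tie = best
    g = germline_v_set[gid]
    end104 = _walk_cigar_to_target(cigar, span[0], len(g.core))
    if ident >= 1.0 - 1e-12:
        status = "germline_exact"
    elif ident >= 0.97:
        status = "new_allele"
    else:
        status = "low_identity"
    return VAssignment(gid, status, ident, span, end104, tie)


def assign_j(cdna: str, germline_j_set: dict[str, GermlineJ], search_from: int = 0) -> JAssignment:
    if not germline_j_set:
        raise ValueError("empty germline J set")
    window = cdna[search_from:]
    best = None
    for gid in sorted(germline_j_set):
        g = germline_j_set[gid]
        ident, span, cigar = _edlib_identity(g.coding, window)
        key = (ident, -span[0])
        if best is None or key > best[0]:
            best = (key, gid, span, cigar)
    _, gid, span, cigar = best
    g = germline_j_set[gid]
    phe = _walk_cigar_to_target(cigar, span[0], g.j5_len) + search_from
    return JAssignment(gid, best[0][0], (span[0] + search_from, span[1] + search_from), phe)


def assign_c(cdna: str, germline_c_set: dict[str, GermlineC]) -> Optional[str]:
    best = None
    for gid in sorted(germline_c_set):
        g = germline_c_set[gid]
        frag = g.ex1[: min(len(g.ex1), 60)]
        res = edlib.align(frag, cdna, mode="HW", task="distance")
        d = res["editDistance"] if res["editDistance"] >= 0 else 10**9
        if best is None or d < best[0]:
            best = (d, gid)
    if best is None or best[0] > 0.3 * 60:
        return None
    return best[1]


# ---------------------------------------------------------------------------
# CDR3 extraction and junction decomposition


class ExtractionError(ValueError):
    """CDR3 not extractable (anchors unlocatable on the cDNA)."""


def extract_cdr3(cdna: str, v_asg: VAssignment, j_asg: JAssignment) -> tuple[str, str]:
    """CDR3 nucleotides between (exclusive) the 2nd-CYS codon and the
    J-PHE codon, plus the translation in the V reading frame ('' when
    out of frame)."""
    if j_asg.phe_pos <= v_asg.end104:
        raise ExtractionError("J-PHE codon precedes the end of the V region")
    cdr3 = cdna[v_asg.end104 : j_asg.phe_pos]
    aa = _translate(cdr3) if len(cdr3) % 3 == 0 else ""
    return cdr3, aa


@dataclass
class DCall:
    d_id: Optional[str]  # gene id, None, or "ambiguous"
    match_len: int
    span: Optional[tuple[int, int]]  # on the CDR3 (half-open)


def _longest_substring_match(cdr3: str, d: str) -> tuple[int, int]:
    """(length, leftmost start in cdr3) of the longest exact shared
    substring, forward orientation only."""
    n = len(cdr3)
    for length in range(min(n, len(d)), 0, -1):
        for start in range(n - length + 1):
            if cdr3[start : start + length] in d:
                return length, start
    return 0, 0


def assign_d(cdr3_nt: str, germline_d_set: dict[str, GermlineD], min_match: int = 5) -> DCall:
    """Longest exact substring shared with any germline D; below
    ``min_match`` -> no call; equal maximal length for two D genes ->
    ambiguous; equal-length matches within one D -> leftmost span."""
    if not cdr3_nt:
        raise ValueError("empty CDR3")
    hits = {
        gid: _longest_substring_match(cdr3_nt, d.seq)
        for gid, d in sorted(germline_d_set.items())
    }
    if not hits:
        return DCall(None, 0, None)
    best_len = max(L for L, _ in hits.values())
    if best_len < min_match:
        return DCall(None, best_len, None)
    winners = [gid for gid, (L, _) in hits.items() if L == best_len]
    if len(winners) > 1:
        return DCall("ambiguous", best_len, None)
    gid = winners[0]
    start = hits[gid][1]
    return DCall(gid, best_len, (start, start + best_len))


@dataclass
class JunctionDecomposition:
    cdr3_nt: str
    cdr3_aa: str
    v_part: str
    n1: str
    d_part: str
    n2: str
    j_part: str
    d_call: Optional[str]
    d_match_len: int

    @property
    def cdr3_len_aa(self) -> int:
        return len(self.cdr3_nt) // 3

    def check(self) -> bool:
        return self.v_part + self.n1 + self.d_part + self.n2 + self.j_part == self.cdr3_nt


def decompose_junction(
    cdr3_nt: str,
    v_tail: str,
    j5: str,
    d_call: DCall,
    cdr3_aa: str = "",
) -> JunctionDecomposition:
    """V prefix first, J suffix next, D constrained to the residual
    window; attributions overlapping the D span are truncated at it.
    The five parts always concatenate back to the CDR3."""
    n = len(cdr3_nt)
    vlen = 0
    while vlen < min(n, len(v_tail)) and cdr3_nt[vlen] == v_tail[vlen]:
        vlen += 1
    jlen = 0
    while jlen < min(n, len(j5)) and cdr3_nt[n - 1 - jlen] == j5[len(j5) - 1 - jlen]:
        jlen += 1
    jlen = min(jlen, n - vlen)

    if d_call.d_id not in (None, "ambiguous") and d_call.span is not None:
        ds, de = d_call.span
        vlen = min(vlen, ds)
        jlen = min(jlen, n - de)
        return JunctionDecomposition(
            cdr3_nt,
            cdr3_aa,
            cdr3_nt[:vlen],
            cdr3_nt[vlen:ds],
            cdr3_nt[ds:de],
            cdr3_nt[de : n - jlen],
            cdr3_nt[n - jlen :],
            d_call.d_id,
            d_call.match_len,
        )
    # no (or ambiguous) D: a single N segment between V and J
    return JunctionDecomposition(
        cdr3_nt,
        cdr3_aa,
        cdr3_nt[:vlen],
        cdr3_nt[vlen : n - jlen],
        "",
        "",
        cdr3_nt[n - jlen :],
        d_call.d_id,
        d_call.match_len,
    )


def classify_rearrangement(
    d_call: DCall, j_gene_id: str, cluster_of: dict[str, Optional[int]]
) -> str:
    """intracluster / intercluster / unknown (no or ambiguous D)."""
    if d_call.d_id in (None, "ambiguous"):
        return "unknown"
    dc = cluster_of.get(d_call.d_id)
    jc = cluster_of.get(j_gene_id)
    if dc is None or jc is None:
        return "unknown"
    return "intracluster" if dc == jc else "intercluster"


# ---------------------------------------------------------------------------
# clone records


@dataclass
class CloneRecord:
    clone_id: str
    subject_id: str
    v_assignment: VAssignment
    j_assignment: JAssignment
    c_gene_id: Optional[str]
    junction: Optional[JunctionDecomposition]
    productive: bool
    rearrangement_class: str
    cdna: str
    v_call: str = ""
    j_call: str = ""
    notes: list[str] = field(default_factory=list)


def analyze_clone(
    clone_id: str,
    cdna: str,
    germline: GermlineSet,
    min_d_match: int = 5,
    subject_id: Optional[str] = None,
) -> CloneRecord:
    subject = subject_id if subject_id is not None else clone_id.split("-")[0]
    v_asg = assign_v(cdna, germline.vs)
    j_asg = assign_j(cdna, germline.js, search_from=v_asg.end104)
    c_id = assign_c(cdna, germline.cs) if germline.cs else None
    notes = []
    if v_asg.identity < 0.90:
        notes.append("low_v_identity")
    if v_asg.tie:
        notes.append("v_tie")
    junction = None
    productive = False
    rclass = "unknown"
    try:
        cdr3, aa = extract_cdr3(cdna, v_asg, j_asg)
        d_call = assign_d(cdr3, germline.ds, min_d_match) if germline.ds else DCall(None, 0, None)
        gv = germline.vs[v_asg.gene_id]
        gj = germline.js[j_asg.gene_id]
        junction = decompose_junction(cdr3, gv.tail, gj.j5, d_call, aa)
        productive = len(cdr3) % 3 == 0 and "*" not in aa and aa != ""
        rclass = classify_rearrangement(d_call, j_asg.gene_id, germline.cluster_of)
    except ExtractionError:
        notes.append("cdr3_extraction_failed")
    return CloneRecord(
        clone_id=clone_id,
        subject_id=subject,
        v_assignment=v_asg,
        j_assignment=j_asg,
        c_gene_id=c_id,
        junction=junction,
        productive=productive,
        rearrangement_class=rclass,
        cdna=cdna,
        v_call=_call_name(germline.vs, v_asg.gene_id, v_asg.allele_status),
        j_call=germline.js[j_asg.gene_id].name,
        notes=notes,
    )


def _call_name(vs: dict[str, GermlineV], gid: str, status: str) -> str:
    base = vs[gid].name
    return f"{base}*01" if status == "germline_exact" else f"{base}*0x"


def analyze_repertoire(
    records: list[tuple[str, str]],
    germline: GermlineSet,
    min_d_match: int = 5,
    subjects: Optional[dict[str, str]] = None,
) -> list[CloneRecord]:
    return [
        analyze_clone(
            cid, seq, germline, min_d_match, subjects.get(cid) if subjects else None
        )
        for cid, seq in records
    ]


def collapse_redundant(records: list[CloneRecord]) -> tuple[dict[str, list[str]], list[CloneRecord]]:
    """Group clones by exact coding-sequence identity; returns
    (representative id -> member ids, unique representatives)."""
    groups: dict[str, list[CloneRecord]] = {}
    for r in records:
        groups.setdefault(r.cdna, []).append(r)
    rep_map: dict[str, list[str]] = {}
    unique: list[CloneRecord] = []
    for members in groups.values():
        rep = members[0]
        rep_map[rep.clone_id] = [m.clone_id for m in members]
        unique.append(rep)
    return rep_map, unique


def records_to_frame(records: list[CloneRecord], germline: GermlineSet) -> pd.DataFrame:
    rows = []
    for r in records:
        j = r.junction
        d_name = ""
        if j is not None and j.d_call not in (None, "ambiguous"):
            d_name = germline.ds[j.d_call].name
        elif j is not None and j.d_call == "ambiguous":
            d_name = "ambiguous"
        rows.append(
            {
                "sequence_id": r.clone_id,
                "subject_id": r.subject_id,
                "v_call": r.v_call,
                "d_call": d_name,
                "j_call": r.j_call,
                "c_call": germline.cs[r.c_gene_id].name if r.c_gene_id else "",
                "v_identity": round(r.v_assignment.identity, 4),
                "allele_status": r.v_assignment.allele_status,
                "junction": j.cdr3_nt if j else "",
                "junction_aa": j.cdr3_aa if j else "",
                "np1": j.n1 if j else "",
                "np2": j.n2 if j else "",
                "d_match_len": j.d_match_len if j else 0,
                "productive": r.productive,
                "rearrangement_class": r.rearrangement_class,
            }
        )
    return pd.DataFrame(rows, columns=REARRANGEMENT_COLUMNS)
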