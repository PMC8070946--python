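"""Annotation: RS scanner vs brute-force oracle, reference-seeded gene
location, functionality rules, subgroup partition, cluster layout."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trbkit.annotate import (
    AnnotationParams,
    build_cluster_layout,
    classify_functionality,
    locate_gene_units,
    pairwise_identity,
    partition_subgroups,
    scan_recombination_signals,
    translate_d_frames,
)
from trbkit.simulate import inject_defects
from trbkit.units import (
    GeneUnit,
    HEPTAMER_CONSENSUS,
    NONAMER_CONSENSUS,
    revcomp,
)

BASES = "ACGT"


def rand_dna(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


# ---------------------------------------------------------------------------
# RS scanner


def brute_force_scan(seq, side, spacer_class, max_h, max_n, tol, strand="+"):
    """Independent oracle: enumerate every window on the given strand."""
    hits = []
    n = len(seq)
    s = seq if strand == "+" else revcomp(seq)
    for spacer in range(spacer_class - tol, spacer_class + tol + 1):
        total = 16 + spacer
        for i in range(n - total + 1):
            win = s[i : i + total]
            if side == "three_prime":
                hept, nona = win[:7], win[-9:]
            else:
                hept, nona = revcomp(win[-7:]), revcomp(win[:9])
            hmm = sum(a != b for a, b in zip(hept, HEPTAMER_CONSENSUS))
            nmm = sum(a != b for a, b in zip(nona, NONAMER_CONSENSUS))
            if hept[:3] != "CAC" or hmm > max_h or nmm > max_n:
                continue
            span = (i, i + total) if strand == "+" else (n - i - total, n - i)
            hits.append((span, spacer, hmm, nmm))
    return sorted(hits)


def test_planted_exact_consensus_found():
    rng = np.random.default_rng(0)
    rs = HEPTAMER_CONSENSUS + rand_dna(rng, 23) + NONAMER_CONSENSUS
    seq = "A" * 60 + rs + "A" * 60
    hits = scan_recombination_signals(seq, "three_prime", 23, strands="+")
    assert len(hits) == 1
    h = hits[0]
    assert h.span == (60, 60 + len(rs))
    assert h.heptamer_mismatches == 0 and h.nonamer_mismatches == 0


@pytest.mark.parametrize("side", ["three_prime", "five_prime"])
@pytest.mark.parametrize("spacer_class", [12, 23])
def test_scanner_equals_brute_force_on_random_sequence(side, spacer_class):
    rng = np.random.default_rng(1)
    seq = rand_dna(rng, 1000)
    # salt with planted signals (some mutated) so hits exist
    rs = HEPTAMER_CONSENSUS + rand_dna(rng, spacer_class) + NONAMER_CONSENSUS
    if side == "five_prime":
        rs = revcomp(rs)
    mutated = "CAT" + rs[3:]
    seq = seq[:200] + rs + seq[200:700] + mutated + seq[700:]
    for strand in "+-":
        got = scan_recombination_signals(
            seq, side, spacer_class, 1, 3, 1, strands=strand
        )
        want = brute_force_scan(seq, side, spacer_class, 1, 3, 1, strand)
        assert [
            (h.span, h.spacer_len, h.heptamer_mismatches, h.nonamer_mismatches)
            for h in sorted(got, key=lambda h: (h.span, h.spacer_len))
        ] == sorted(want)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_scanner_equals_brute_force_property(seed):
    rng = np.random.default_rng(seed)
    seq = rand_dna(rng, 400)
    got = scan_recombination_signals(seq, "three_prime", 12, 1, 3, 1, strands="+")
    want = brute_force_scan(seq, "three_prime", 12, 1, 3, 1, "+")
    assert [
        (h.span, h.spacer_len, h.heptamer_mismatches, h.nonamer_mismatches)
        for h in sorted(got, key=lambda h: (h.span, h.spacer_len))
    ] == sorted(want)


def test_simulated_j_genes_have_12rs(locus):
    _, seq, units = locus
    hits = scan_recombination_signals(seq, "five_prime", 12, strands="+")
    starts = {h.span for h in hits}
    for u in units:
        if u.gene_type == "J":
            assert u.rs_elements[0].span in starts


# ---------------------------------------------------------------------------
# gene location


def test_planted_exact_copy_located():
    rng = np.random.default_rng(2)
    exemplar = rand_dna(rng, 250)
    seq = rand_dna(rng, 800) + exemplar + rand_dna(rng, 800)
    cands = locate_gene_units(seq, [(f"X|V|X", exemplar)])
    assert len(cands) == 1
    c = cands[0]
    assert (c.start, c.end, c.strand) == (800, 1050, "+")
    assert c.identity == 1.0


def test_planted_reverse_complement_located_on_minus_strand():
    rng = np.random.default_rng(3)
    exemplar = rand_dna(rng, 250)
    seq = rand_dna(rng, 500) + revcomp(exemplar) + rand_dna(rng, 500)
    cands = locate_gene_units(seq, [(f"X|V|X", exemplar)])
    assert len(cands) == 1
    assert cands[0].strand == "-"
    assert (cands[0].start, cands[0].end) == (500, 750)


def test_unknown_gene_type_label_rejected():
    with pytest.raises(ValueError):
        locate_gene_units("ACGT" * 100, [("X|Q|X", "ACGTACGTACGTACGT")])


# ---------------------------------------------------------------------------
# round trip (recall/precision of unit coordinates)


def test_round_trip_recall_and_precision(locus, annotated):
    _, _, truth = locus
    t = {(u.gene_type, tuple(sorted(u.coding_spans))) for u in truth}
    a = {(u.gene_type, tuple(sorted(u.coding_spans))) for u in annotated}
    assert t == a  # recall 1.0 and precision 1.0, exact coordinates

    for u in annotated:
        assert u.functionality == "F"
        assert u.defects == []


def test_partition_matches_simulated_grouping(locus, annotated):
    _, seq, truth = locus
    v_units = [u for u in annotated if u.gene_type == "V"]
    part = partition_subgroups(v_units, seq)
    span_of = {u.id: tuple(sorted(u.coding_spans)) for u in annotated}
    got = {frozenset(span_of[m] for m in mem) for mem in part.groups.values()}
    want = {}
    for u in truth:
        if u.gene_type == "V":
            want.setdefault(u.meta["subgroup"], set()).add(tuple(sorted(u.coding_spans)))
    assert got == {frozenset(v) for v in want.values()}


# ---------------------------------------------------------------------------
# functionality rules


def test_classification_over_all_defect_kinds(locus, refdir):
    """Planted coding defects -> P; signal/regulatory defects with
    intact coding -> ORF; defect-free -> F (checked in round trip)."""
    from trbkit.annotate import annotate_locus

    _, seq, truth = locus
    spec = [
        ("V1", "stop_codon"), ("V2", "frameshift"), ("V3", "heptamer_mutation"),
        ("V4", "nonamer_mutation"), ("V5", "splice_mutation"), ("V6", "missing_leader"),
        ("J1-1", "stop_codon"), ("J1-2", "frameshift"), ("J1-3", "heptamer_mutation"),
        ("J1-4", "nonamer_mutation"), ("J1-5", "splice_mutation"),
        ("J1-6", "j_motif_mutation"),
        ("C1", "stop_codon"), ("C2", "frameshift"), ("C3", "splice_mutation"),
    ]
    mseq, mtruth = inject_defects(truth, seq, spec, seed=1)
    units = annotate_locus(mseq, refdir)
    by_start = {min(s for s, _ in u.coding_spans): u for u in mtruth}
    for u in units:
        tu = by_start[min(s for s, _ in u.coding_spans)]
        assert u.functionality == tu.functionality, (tu.id, tu.defects, u.defects)
        if tu.defects:
            assert set(tu.defects) <= set(u.defects)


def test_functionality_monotone_under_added_defects(locus, refdir):
    """Adding a defect never improves the call (P/ORF never become F)."""
    from trbkit.annotate import annotate_locus

    rank = {"F": 0, "ORF": 1, "P": 2}
    _, seq, truth = locus
    mseq, _ = inject_defects(truth, seq, [("J2-1", "nonamer_mutation")], seed=0)
    mseq2, _ = inject_defects(
        truth, seq, [("J2-1", "nonamer_mutation"), ("J2-1", "stop_codon")], seed=0
    )
    base = {u.id: u.functionality for u in annotate_locus(seq, refdir)}
    one = {u.id: u.functionality for u in annotate_locus(mseq, refdir)}
    two = {u.id: u.functionality for u in annotate_locus(mseq2, refdir)}
    for uid in base:
        assert rank[one.get(uid, base[uid])] >= rank[base[uid]]
        assert rank[two.get(uid, base[uid])] >= rank[one.get(uid, base[uid])]


# ---------------------------------------------------------------------------
# subgroup identity / partition semantics


def mutate_at(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


def make_v_unit(uid, seq_str, offset, pool):
    pool[uid] = (offset, seq_str)
    return GeneUnit(
        id=uid, gene_type="V", coding_spans=[(offset, offset + len(seq_str))],
        meta={"ref_len": len(seq_str)},
    )


def test_partition_transitive_closure():
    # identities: (A,B)=0.8, (B,C)=0.8, (A,C)=0.7 -> one connected group
    rng = np.random.default_rng(5)
    base = rand_dna(rng, 100)
    a = base
    # scattered sites keep the global alignment gapless; the first 15
    # sites mutate identically in b and c, so b vs c differ at 20 sites
    # while a vs c differ at 30
    b_sites = [5 * i for i in range(20)]
    c_sites = b_sites[:15] + [5 * i + 2 for i in range(15)]
    b = mutate_at(base, b_sites)
    c = mutate_at(base, c_sites)
    assert abs(pairwise_identity(a, b) - 0.8) < 1e-9
    assert abs(pairwise_identity(b, c) - 0.8) < 1e-9
    assert abs(pairwise_identity(a, c) - 0.7) < 1e-9
    region = a + b + c
    units = [
        GeneUnit(id="A", gene_type="V", coding_spans=[(0, 100)]),
        GeneUnit(id="B", gene_type="V", coding_spans=[(100, 200)]),
        GeneUnit(id="C", gene_type="V", coding_spans=[(200, 300)]),
    ]
    part = partition_subgroups(units, region)
    assert len(part.groups) == 1


def test_identical_sequences_identity_one_and_same_group():
    seq = "ACGT" * 30
    region = seq + seq
    units = [
        GeneUnit(id="A", gene_type="V", coding_spans=[(0, 120)]),
        GeneUnit(id="B", gene_type="V", coding_spans=[(120, 240)]),
    ]
    part = partition_subgroups(units, region)
    assert len(part.groups) == 1
    assert part.identity_matrix[0, 1] == 1.0


def test_partition_invariant_to_input_order(locus, annotated):
    _, seq, _ = locus
    v_units = [u for u in annotated if u.gene_type == "V"]
    p1 = partition_subgroups(v_units, seq)
    p2 = partition_subgroups(list(reversed(v_units)), seq)
    g1 = {frozenset(m) for m in p1.groups.values()}
    g2 = {frozenset(m) for m in p2.groups.values()}
    assert g1 == g2


# ---------------------------------------------------------------------------
# D frames and cluster layout


def test_translate_d_frames_glycine_run():
    d = GeneUnit(id="D", gene_type="D", coding_spans=[(0, 6)])
    peptides, ok = translate_d_frames(d, "GGGGGG")
    assert peptides[0] == "GG" and ok
    assert all(set(p) <= {"G"} for p in peptides)


def test_translate_d_frames_stop_flag():
    d = GeneUnit(id="D", gene_type="D", coding_spans=[(0, 7)])
    peptides, ok = translate_d_frames(d, "GTAGGGG")  # TAG in frame 1
    assert not ok


def test_simulated_d_readable_in_three_frames(locus):
    _, seq, units = locus
    for u in units:
        if u.gene_type == "D":
            peptides, ok = translate_d_frames(u, seq)
            assert ok
            for pep in peptides:
                assert 1 <= pep.count("G") <= 3


def unit_at(uid, gtype, start):
    return GeneUnit(id=uid, gene_type=gtype, coding_spans=[(start, start + 10)])


def test_cluster_layout_complete_and_missing_members():
    d1, j1, j2, c1 = unit_at("D1", "D", 0), unit_at("J1", "J", 20), unit_at("J2", "J", 40), unit_at("C1", "C", 60)
    j3, c2 = unit_at("J3", "J", 100), unit_at("C2", "C", 120)
    clusters = build_cluster_layout([d1], [j1, j2, j3], [c1, c2])
    assert len(clusters) == 2
    assert clusters[0].d_id == "D1" and clusters[0].j_ids == ["J1", "J2"]
    assert clusters[1].d_id is None and clusters[1].j_ids == ["J3"]


def test_cluster_layout_simulated(locus):
    _, _, units = locus
    clusters = build_cluster_layout(
        [u for u in units if u.gene_type == "D"],
        [u for u in units if u.gene_type == "J"],
        [u for u in units if u.gene_type == "C"],
    )
    assert len(clusters) == 3
    assert [len(c.j_ids) for c in clusters] == [6, 7, 7]
    assert [c.d_id is not None for c in clusters] == [True, False, True]


def test_cluster_layout_c_without_j_errors():
    c1, c2, j = unit_at("C1", "C", 0), unit_at("C2", "C", 30), unit_at("J1", "J", 60)
    with pytest.raises(ValueError):
        build_cluster_layout([], [j], [c1, c2])


# ---------------------------------------------------------------------------
# nomenclature (via the full annotation fixture)


def test_nomenclature_multi_member_numbering(locus, annotated):
    _, _, truth = locus
    # the simulated locus holds one 3-member and one 2-member subgroup
    names = sorted(u.name for u in annotated if u.gene_type == "V")
    hyphenated = [n for n in names if "-" in n]
    assert len(hyphenated) == 5
    prefixes = {n.split("-")[0] for n in hyphenated}
    assert len(prefixes) == 2
    singles = [n for n in names if "-" not in n]
    assert len(singles) == 18
    # J genes named by cluster-position
    jnames = [u.name for u in annotated if u.gene_type == "J"]
    assert "TRBJ1-1" in jnames and "TRBJ3-7" in jnames
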