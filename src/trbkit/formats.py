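"""Standard-format I/O: FASTA, GFF3, rearrangement TSV, newick, PDB.

Thin wrappers over biopython / pandas / scikit-bio plus a structural
validator used by the CLI.  GFF3 coordinates are 1-based inclusive.
"""

from __future__ import annotations

import io
import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .units import GeneUnit

REARRANGEMENT_COLUMNS = [
    "sequence_id",
    "subject_id",
    "v_call",
    "d_call",
    "j_call",
    "c_call",
    "v_identity",
    "allele_status",
    "junction",
    "junction_aa",
    "np1",
    "np2",
    "d_match_len",
    "productive",
    "rearrangement_class",
]


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> ordered {id: sequence} (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def units_to_gff3(units: list[GeneUnit], region_id: str) -> str:
    """Serialize gene units to GFF3 (one feature per coding span)."""
    lines = ["##gff-version 3"]
    for u in sorted(units, key=lambda u: u.start):
        attrs = [
            f"ID={u.id}",
            f"gene_type={u.gene_type}",
            f"functionality={u.functionality}",
        ]
        if u.name:
            attrs.append(f"Name={u.name}")
        if u.defects:
            attrs.append("defects=" + ",".join(u.defects))
        if u.rs_elements:
            rs = ";".join(
                f"{r.side}:{r.span[0] + 1}-{r.span[1]}:mm{r.heptamer_mismatches}+{r.nonamer_mismatches}"
                for r in u.rs_elements
            )
            attrs.append(f"rs_elements={rs}")
        for i, (s, e) in enumerate(sorted(u.coding_spans)):
            feat_attrs = list(attrs)
            if len(u.coding_spans) > 1:
                feat_attrs.append(f"exon={i + 1}")
            lines.append(
                "\t".join(
                    [
                        region_id,
                        "trbkit",
                        f"{u.gene_type}_gene_segment",
                        str(s + 1),
                        str(e),
                        ".",
                        u.strand,
                        ".",
                        ";".join(feat_attrs),
                    ]
                )
            )
    return "\n".join(lines) + "\n"


def write_gff3(units: list[GeneUnit], region_id: str, path) -> None:
    with open(path, "w") as fh:
        fh.write(units_to_gff3(units, region_id))


def read_gff3_units(path) -> list[GeneUnit]:
    """Parse GFF3 written by :func:`write_gff3` back into bare gene units
    (coding spans, type, strand, functionality; no RS reconstruction)."""
    by_id: dict[str, GeneUnit] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"line {lineno}: expected 9 GFF3 columns")
            attrs = dict(kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv)
            uid = attrs.get("ID", f"feature{lineno}")
            unit = by_id.get(uid)
            if unit is None:
                unit = GeneUnit(
                    id=uid,
                    gene_type=attrs.get("gene_type", fields[2][:1]),
                    strand=fields[6],
                    functionality=attrs.get("functionality", "F"),
                    name=attrs.get("Name"),
                    defects=attrs.get("defects", "").split(",") if attrs.get("defects") else [],
                )
                by_id[uid] = unit
            unit.coding_spans.append((int(fields[3]) - 1, int(fields[4])))
    return list(by_id.values())


def write_rearrangement_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_rearrangement_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sequence_id": str, "subject_id": str})


# ---------------------------------------------------------------------------
# structural validation


def validate_formats(path, format_name: str) -> list[str]:
    """Return a list of diagnostics (empty = structurally valid).

    Supported: FASTA, GFF3, newick, rearrangement-TSV, PDB.  Never
    mutates the input.
    """
    diags: list[str] = []
    if not os.path.exists(path):
        return [f"{path}: file not found"]
    fmt = format_name.lower()
    if fmt == "fasta":
        try:
            records = list(SeqIO.parse(str(path), "fasta"))
        except Exception as exc:  # pragma: no cover - biopython is lenient
            return [f"FASTA parse error: {exc}"]
        if not records:
            diags.append("no FASTA records found")
        for rec in records:
            if len(rec.seq) == 0:
                diags.append(f"record {rec.id}: empty sequence")
    elif fmt == "gff3":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 9:
                    diags.append(f"line {lineno}: {len(fields)} columns (expected 9)")
                    continue
                try:
                    start, end = int(fields[3]), int(fields[4])
                except ValueError:
                    diags.append(f"line {lineno}: non-integer coordinates")
                    continue
                if end < start:
                    diags.append(f"line {lineno}: end {end} < start {start}")
    elif fmt == "newick":
        import skbio

        try:
            skbio.TreeNode.read(str(path))
        except Exception as exc:
            diags.append(f"newick parse error: {exc}")
    elif fmt in ("rearrangement-tsv", "rearrangement_tsv", "tsv"):
        try:
            df = pd.read_csv(path, sep="\t", nrows=5)
        except Exception as exc:
            return [f"TSV parse error: {exc}"]
        for col in ("sequence_id", "v_call", "j_call", "junction"):
            if col not in df.columns:
                diags.append(f"missing required column: {col}")
    elif fmt == "pdb":
        n_atoms = 0
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if line.startswith(("ATOM", "HETATM")):
                    n_atoms += 1
                    if len(line.rstrip("\n")) < 54:
                        diags.append(f"line {lineno}: truncated ATOM record")
                        continue
                    try:
                        float(line[30:38]), float(line[38:46]), float(line[46:54])
                    except ValueError:
                        diags.append(f"line {lineno}: unparseable coordinates")
        if n_atoms == 0:
            diags.append("no ATOM/HETATM records found")
    else:
        raise ValueError(f"unknown format name: {format_name}")
    return diags
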