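"""Repertoire statistics over rearrangement records.

Everything operates on the AIRR-style rearrangement table produced by
``junctions.records_to_frame`` (or an equivalent TSV), so the stats are
reproducible from files alone.  Tables are invariant to input order;
percentages are rounded only at presentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def _subgroup_of(call: str) -> str:
    base = call.split("*")[0]
    return base.split("-")[0]


def _gene_of(call: str) -> str:
    return call.split("*")[0]


def unique_records(df: pd.DataFrame) -> pd.DataFrame:
    """One representative per exact coding-sequence group (redundancy
    collapse at the nucleotide level)."""
    key = "cdna" if "cdna" in df.columns else "junction"
    return df.sort_values("sequence_id", kind="stable").drop_duplicates(subset=[key])


@dataclass
class UsageTable:
    level: str
    counts: dict[str, int]
    fractions: dict[str, float]
    n: int


def gene_usage(df: pd.DataFrame, level: str = "gene", unique_only: bool = True) -> UsageTable:
    """Clone counts and fractions per subgroup / gene / allele."""
    if level not in ("subgroup", "gene", "allele"):
        raise ValueError(level)
    data = unique_records(df) if unique_only else df
    data = data[data["v_call"].astype(str) != ""]
    if level == "allele":
        names = data["v_call"].astype(str)
    elif level == "gene":
        names = data["v_call"].astype(str).map(_gene_of)
    else:
        names = data["v_call"].astype(str).map(_subgroup_of)
    counts = names.value_counts().sort_index().to_dict()
    total = sum(counts.values())
    fractions = {k: v / total for k, v in counts.items()}
    return UsageTable(level, counts, fractions, total)


@dataclass
class CDR3Stats:
    n: int
    mean_len_aa: float
    min_len_aa: int
    max_len_aa: int
    histogram: dict[int, int]


def cdr3_stats(df: pd.DataFrame, unique_only: bool = True) -> CDR3Stats:
    """Amino-acid length statistics of the CDR3 (codons 105-117 region)."""
    data = unique_records(df) if unique_only else df
    lens = (
        data.loc[data["junction"].astype(str) != "", "junction"]
        .astype(str)
        .map(len)
        .floordiv(3)
    )
    if lens.empty:
        raise ValueError("no records with an extractable CDR3")
    hist = lens.value_counts().sort_index().to_dict()
    return CDR3Stats(
        n=int(lens.size),
        mean_len_aa=float(lens.mean()),
        min_len_aa=int(lens.min()),
        max_len_aa=int(lens.max()),
        histogram={int(k): int(v) for k, v in hist.items()},
    )


def shared_rearrangements(df: pd.DataFrame, level: str = "gene") -> pd.DataFrame:
    """Genes/alleles (or identical junctions) observed in every subject,
    with per-subject clone counts — the public-repertoire report."""
    if df["subject_id"].nunique() < 2:
        raise ValueError("at least two subjects required")
    if level == "allele":
        key = df["v_call"].astype(str)
    elif level == "gene":
        key = df["v_call"].astype(str).map(_gene_of)
    elif level == "junction":
        key = df["junction"].astype(str)
    else:
        raise ValueError(level)
    tab = pd.crosstab(key, df["subject_id"])
    shared = tab[(tab > 0).all(axis=1)]
    shared.index.name = level
    return shared.sort_index()


def j_set_frequencies(df: pd.DataFrame, unique_only: bool = True) -> pd.DataFrame:
    """Unique-clone counts per J set (cluster), e.g. TRBJ2 vs TRBJ3.

    Records with a failed J assignment are excluded from the
    denominator.
    """
    data = unique_records(df) if unique_only else df
    data = data[data["j_call"].astype(str) != ""]
    sets = data["j_call"].astype(str).map(_subgroup_of)
    counts = sets.value_counts().sort_index()
    out = counts.to_frame("count")
    out["fraction"] = out["count"] / out["count"].sum()
    return out


def summary(df: pd.DataFrame) -> dict:
    uniq = unique_records(df)
    stats = cdr3_stats(df)
    d_named = uniq["d_call"].astype(str)
    out = {
        "n_clones": int(len(df)),
        "n_unique": int(len(uniq)),
        "n_redundant": int(len(df) - len(uniq)),
        "cdr3_mean_aa": round(stats.mean_len_aa, 1),
        "cdr3_min_aa": stats.min_len_aa,
        "cdr3_max_aa": stats.max_len_aa,
        "d_identified": int(((d_named != "") & (d_named != "ambiguous")).sum()),
        "rearrangement_classes": uniq["rearrangement_class"].value_counts().to_dict(),
        "v_usage": gene_usage(df, "gene").counts,
        "j_sets": j_set_frequencies(df)["count"].to_dict(),
    }
    return out
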