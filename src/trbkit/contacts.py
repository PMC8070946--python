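"""TR/pMH interface contact analysis.

Residue pairs of two chains are reported as contacts when any
inter-atomic distance is within the cutoff (default 4 Å, all atoms
present in the file — heavy atoms unless hydrogens were deposited).
Contacts can be labeled with IMGT region membership through per-chain
numbering maps, and the standard IMGT pMH contact-site rule maps peptide
length (8-11) to the absent sites among C1-C11.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .numbering import REGION_OF


@dataclass
class Residue:
    index: str  # resseq + insertion code
    name: str
    atoms: dict[str, np.ndarray]

    def coords(self) -> np.ndarray:
        return np.array(list(self.atoms.values()))


@dataclass
class StructureModel:
    chains: dict[str, list[Residue]]

    def chain(self, chain_id: str) -> list[Residue]:
        if chain_id not in self.chains:
            raise KeyError(f"chain {chain_id!r} not in structure")
        return self.chains[chain_id]


def read_structure(coordinate_file) -> StructureModel:
    """Parse a PDB-format file into a StructureModel.

    Waters are skipped; alternate locations resolve to the highest
    occupancy conformer; malformed ATOM records raise with the line
    number.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    # surface malformed records as errors before the lenient parse
    with open(coordinate_file) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(("ATOM", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise ValueError(f"line {lineno}: truncated ATOM record")
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except ValueError as exc:
                    raise ValueError(f"line {lineno}: unparseable coordinates") from exc

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("model", str(coordinate_file))
    model = next(iter(structure))
    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues = []
        for res in chain:
            if res.get_resname() in ("HOH", "WAT"):
                continue
            atoms = {}
            for atom in res:
                if atom.is_disordered():
                    best = max(atom, key=lambda a: a.get_occupancy() or 0.0)
                    atoms[atom.get_id()] = np.asarray(best.get_coord(), dtype=float)
                else:
                    atoms[atom.get_id()] = np.asarray(atom.get_coord(), dtype=float)
            if not atoms:
                continue
            het, resseq, icode = res.get_id()
            residues.append(Residue(f"{resseq}{icode.strip()}", res.get_resname(), atoms))
        if residues:
            chains[chain.id] = residues
    return StructureModel(chains)


@dataclass
class ContactPair:
    chain_a: str
    residue_a: str
    chain_b: str
    residue_b: str
    min_atom_distance: float
    region_a: Optional[str] = None
    region_b: Optional[str] = None


def interface_residues(
    model: StructureModel, chain_a: str, chain_b: str, cutoff: float = 4.0
) -> list[ContactPair]:
    """All residue pairs of the two chains with any inter-atomic
    distance <= cutoff; the minimum distance is recorded.  Symmetric in
    chain order (pairs are reported as given chain order)."""
    res_a = model.chain(chain_a)
    res_b = model.chain(chain_b)
    coords_b = []
    owner_b = []
    for k, r in enumerate(res_b):
        for xyz in r.atoms.values():
            coords_b.append(xyz)
            owner_b.append(k)
    if not coords_b:
        return []
    tree = cKDTree(np.array(coords_b))
    owner_b = np.array(owner_b)
    pairs: dict[tuple[int, int], float] = {}
    for i, ra in enumerate(res_a):
        for xyz in ra.atoms.values():
            idx = tree.query_ball_point(xyz, cutoff)
            if not idx:
                continue
            dists = np.linalg.norm(np.array([coords_b[j] for j in idx]) - xyz, axis=1)
            for j, dist in zip(idx, dists):
                key = (i, int(owner_b[j]))
                if dist <= cutoff and (key not in pairs or dist < pairs[key]):
                    pairs[key] = float(dist)
    out = [
        ContactPair(chain_a, res_a[i].index, chain_b, res_b[k].index, d)
        for (i, k), d in sorted(pairs.items())
    ]
    return out


def label_contacts(
    pairs: list[ContactPair], numbering_maps: dict[str, dict[str, int]]
) -> tuple[list[ContactPair], dict[str, dict[str, int]]]:
    """Annotate pairs with IMGT region labels from per-chain numbering
    maps (residue index -> IMGT position).  V-domain positions map to
    FR/CDR-IMGT regions; other chains are labeled ``G-domain <pos>``.
    Unmapped residues are labeled "unmapped" and excluded from the
    per-region counts."""
    labeled = []
    counts: dict[str, dict[str, int]] = {}
    for p in pairs:
        ra = _region_label(numbering_maps, p.chain_a, p.residue_a)
        rb = _region_label(numbering_maps, p.chain_b, p.residue_b)
        labeled.append(
            ContactPair(
                p.chain_a, p.residue_a, p.chain_b, p.residue_b, p.min_atom_distance, ra, rb
            )
        )
        for chain, region in ((p.chain_a, ra), (p.chain_b, rb)):
            if region == "unmapped":
                continue
            counts.setdefault(chain, {})
            counts[chain][region] = counts[chain].get(region, 0) + 1
    return labeled, counts


def _region_label(maps: dict[str, dict[str, int]], chain: str, residue: str) -> str:
    cmap = maps.get(chain)
    if not cmap or residue not in cmap:
        return "unmapped"
    pos = cmap[residue]
    kind = maps.get(f"{chain}__kind", "V")
    if kind == "G":
        return f"G-domain {pos}"
    return REGION_OF.get(pos, f"position {pos}")


#: IMGT pMH contact sites absent per peptide length in the MH1 groove
PMH_ABSENT = {
    11: frozenset(),
    10: frozenset({"C2"}),
    9: frozenset({"C2", "C7"}),
    8: frozenset({"C2", "C7", "C8"}),
}

ALL_SITES = tuple(f"C{i}" for i in range(1, 12))


@dataclass
class PMHContactSiteSet:
    peptide_length: int
    present: tuple[str, ...]
    absent: tuple[str, ...] = field(default_factory=tuple)


def pmh_contact_sites(peptide_length: int) -> PMHContactSiteSet:
    """Which of the eleven standard IMGT pMH contact sites (C1-C11) a
    peptide of 8-11 residues occupies in the MH1 groove."""
    if peptide_length not in PMH_ABSENT:
        raise ValueError(
            f"unsupported peptide length {peptide_length} (expected 8-11)"
        )
    absent = PMH_ABSENT[peptide_length]
    present = tuple(s for s in ALL_SITES if s not in absent)
    return PMHContactSiteSet(peptide_length, present, tuple(sorted(absent, key=ALL_SITES.index)))
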