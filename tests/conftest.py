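"""Shared fixtures: one simulated locus + repertoire reused across the
suite (session scope keeps the alignment-heavy annotation to one run)."""

from __future__ import annotations

import numpy as np
import pytest

from trbkit.annotate import annotate_locus
from trbkit.junctions import analyze_repertoire, build_germline_set
from trbkit.simulate import (
    LocusSimConfig,
    RepertoireSimConfig,
    generate_germline_locus,
    make_reference_directory,
    simulate_repertoire,
)

LOCUS_SEED = 7
REP_SEED = 11


@pytest.fixture(scope="session")
def locus():
    cfg = LocusSimConfig(seed=LOCUS_SEED)
    seq, truth = generate_germline_locus(cfg)
    return cfg, seq, truth


@pytest.fixture(scope="session")
def refdir(locus):
    _, _, truth = locus
    return make_reference_directory(truth, seed=LOCUS_SEED + 1)


@pytest.fixture(scope="session")
def annotated(locus, refdir):
    _, seq, _ = locus
    return annotate_locus(seq, refdir)


@pytest.fixture(scope="session")
def germline(annotated, locus):
    _, seq, _ = locus
    return build_germline_set(annotated, seq)


@pytest.fixture(scope="session")
def unit_id_map(annotated, locus):
    """annotated unit id -> simulator truth id (matched on coordinates)."""
    _, _, truth = locus
    tmap = {tuple(sorted(u.coding_spans)): u.id for u in truth}
    return {u.id: tmap.get(tuple(sorted(u.coding_spans))) for u in annotated}


@pytest.fixture(scope="session")
def repertoire(locus):
    _, _, truth = locus
    cfg = RepertoireSimConfig(seed=REP_SEED, n_clones=1000, redundancy_rate=0.0)
    clones, records = simulate_repertoire(truth, cfg)
    return cfg, clones, records


@pytest.fixture(scope="session")
def analyzed(repertoire, germline):
    _, _, records = repertoire
    return analyze_repertoire(records, germline)


def write_pdb(path, residues):
    """Minimal PDB writer for fixtures.

    residues: list of (chain, resseq, resname, [(atom_name, x, y, z), ...])
    """
    lines = []
    serial = 1
    for chain, resseq, resname, atoms in residues:
        for name, x, y, z in atoms:
            lines.append(
                f"ATOM  {serial:5d} {name:<4s}{resname:>4s} {chain}{resseq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           {name.strip()[0]}"
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def random_chain(rng: np.random.Generator, chain: str, n_res: int, center):
    out = []
    names = ["N", "CA", "C", "O", "CB"]
    for i in range(1, n_res + 1):
        base = rng.uniform(-15, 15, size=3) + center
        n_atoms = int(rng.integers(1, 6))
        atoms = [
            (names[k], *(base + rng.uniform(-1.5, 1.5, size=3)))
            for k in range(n_atoms)
        ]
        out.append((chain, i, "GLY", atoms))
    return out
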