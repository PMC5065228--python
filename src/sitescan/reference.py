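"""Analyses that run against bundled public reference data.

The package can carry three UniProt sequences (ABCG2_HUMAN, ABCG5_HUMAN,
ABCG8_HUMAN) and the template heterodimer structure (PDB 5DO7) under
``sitescan/data/``.  These files are *not* redistributed with the source
tree by default; ``scripts/fetch_data.py`` downloads them from UniProt and
RCSB on a networked machine.  Every loader raises
:class:`~sitescan.errors.MissingDataError` with instructions when a file is
absent, so the analysis code paths stay importable and testable offline.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np

from .errors import MissingDataError, ValidationError
from .geometry import iterative_superpose, kabsch_superpose
from .seqtools import (
    AlignmentResult,
    align_global,
    identity_similarity_all_denominators,
    scan_crac,
)
from .structio import Structure, read_fasta, read_pdb

__all__ = [
    "data_path",
    "load_sequence",
    "load_template_structure",
    "pairwise_stats",
    "template_chain_rmsd",
    "crac_tyrosines",
    "SEQUENCE_FILES",
    "TEMPLATE_PDB",
]

SEQUENCE_FILES = {
    "ABCG2_HUMAN": "abcg2_human.fasta",
    "ABCG5_HUMAN": "abcg5_human.fasta",
    "ABCG8_HUMAN": "abcg8_human.fasta",
}
TEMPLATE_PDB = "5do7.pdb"

_FETCH_HINT = (
    "bundled reference data file {name!r} is missing; run "
    "`python scripts/fetch_data.py` on a machine with network access to "
    "download it into src/sitescan/data/"
)

_AA3TO1 = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F", "GLY": "G",
    "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L", "MET": "M", "ASN": "N",
    "PRO": "P", "GLN": "Q", "ARG": "R", "SER": "S", "THR": "T", "VAL": "V",
    "TRP": "W", "TYR": "Y", "MSE": "M",
}


def data_path(name: str) -> Path:
    path = Path(str(resources.files("sitescan").joinpath("data", name)))
    if not path.exists():
        raise MissingDataError(_FETCH_HINT.format(name=name))
    return path


def load_sequence(uniprot_name: str) -> str:
    try:
        filename = SEQUENCE_FILES[uniprot_name]
    except KeyError:
        raise ValidationError(f"unknown reference sequence {uniprot_name!r}") from None
    records = read_fasta(data_path(filename))
    return records[0][1]


def load_template_structure() -> Structure:
    return read_pdb(data_path(TEMPLATE_PDB), model_policy="first")


def pairwise_stats(name_a: str, name_b: str) -> tuple[AlignmentResult, dict]:
    """Global alignment of two bundled sequences plus the identity/similarity
    percentages under all three denominator conventions."""
    seq_a = load_sequence(name_a)
    seq_b = load_sequence(name_b)
    result = align_global(seq_a, seq_b)
    sensitivity = identity_similarity_all_denominators(
        result.aligned_a, result.aligned_b
    )
    return result, sensitivity


def _chain_ca(structure: Structure, chain: str) -> tuple[str, np.ndarray]:
    """One-letter sequence and Cα coordinates of one chain, file order."""
    seq: list[str] = []
    coords: list[np.ndarray] = []
    for a in structure.models[0]:
        if a.chain == chain and a.name == "CA" and a.record == "ATOM":
            seq.append(_AA3TO1.get(a.resname, "X"))
            coords.append(a.xyz)
    if not seq:
        raise ValidationError(f"chain {chain!r} has no CA atoms")
    return "".join(seq), np.array(coords, dtype=float)


def template_chain_rmsd(
    chain_a: str = "A",
    chain_b: str = "B",
    reject_factor: float = 2.0,
    max_cycles: int = 5,
) -> dict:
    """Cα RMSD between two chains of the bundled template heterodimer.

    Chains are matched residue-by-residue via a global sequence alignment,
    then superposed with iterative outlier rejection so the divergent
    linker region drops out.  Returns the initial (all matched pairs) and
    final (retained pairs) RMSD plus the pair counts.
    """
    structure = load_template_structure()
    seq_a, ca_a = _chain_ca(structure, chain_a)
    seq_b, ca_b = _chain_ca(structure, chain_b)
    aln = align_global(seq_a, seq_b)
    ia = ib = 0
    idx_a: list[int] = []
    idx_b: list[int] = []
    for ca_char, cb_char in zip(aln.aligned_a, aln.aligned_b):
        if ca_char != "-" and cb_char != "-":
            idx_a.append(ia)
            idx_b.append(ib)
        if ca_char != "-":
            ia += 1
        if cb_char != "-":
            ib += 1
    mobile = ca_a[idx_a]
    ref = ca_b[idx_b]
    _, _, rmsd_all = kabsch_superpose(mobile, ref)
    _, _, rmsd_final, keep = iterative_superpose(
        mobile, ref, reject_factor=reject_factor, max_cycles=max_cycles
    )
    return {
        "n_matched": len(mobile),
        "rmsd_all_pairs": rmsd_all,
        "n_kept": int(keep.sum()),
        "rmsd": rmsd_final,
    }


def crac_tyrosines(uniprot_name: str = "ABCG2_HUMAN") -> list[int]:
    """Tyrosine positions of all CRAC motif hits in a bundled sequence."""
    return [h.tyrosine_pos for h in scan_crac(load_sequence(uniprot_name))]
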