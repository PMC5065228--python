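"""Residue-contact detection and binding-site assignment of docked poses.

A residue is "in contact" with a pose iff any of its heavy atoms lies
within the cutoff (inclusive) of any ligand heavy atom; the default cutoff
of 4.5 Å is a standard protein–ligand contact convention and is exposed as
a parameter everywhere.  A pose is assigned to the site contributing the
most contacted residues; a two-way tie between sites with a defined
overlap region (1–2, 2–3, 1–3) yields that overlap label, any other tie or
an empty contact set yields ``unassigned``.

Counting is over unique residues (not atom pairs) and ignores chain
identity: the four built-in site definitions describe a homodimer in which
the same positions occur on both monomers, so duplicate entries in the
source lists are de-duplicated and matching is by (resname, resid) only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ValidationError
from .structio import Atom, Pose, Structure

__all__ = [
    "SiteDefinition",
    "ContactSet",
    "SiteAssignment",
    "builtin_sites",
    "find_contacts",
    "assign_pose",
    "docking_box",
    "DEFAULT_CUTOFF",
    "OVERLAP_LABELS",
    "UNASSIGNED",
]

DEFAULT_CUTOFF = 4.5
UNASSIGNED = "unassigned"
OVERLAP_LABELS = {
    frozenset({"S1", "S2"}): "S1-2",
    frozenset({"S2", "S3"}): "S2-3",
    frozenset({"S1", "S3"}): "S1-3",
}

_AA1TO3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}

# The four built-in site lists, verbatim including the duplicate entries the
# source tables carry for positions contributed by both monomers.
_RAW_SITES = {
    "S1": (
        "Q126 D127 D128 D128 V129 V129 V130 V130 M131 M131 G132 G132 T133 "
        "T133 L134 V178 V178 G179 G179 T180 T180 Q181 F182 F182 I183 I183 "
        "R191 R191 N387 N387 L388 G390 N391 N391 P392 Q393 Q393 A394 A394 "
        "A397 Q398 S443 A444 E446 L447 L447 F448 V449 V449 V450 V450 E451 "
        "K452 K453 K453 L454 I456 K473 D477"
    ),
    "S2": (
        "L388 A394 A397 Q398 I399 V401 T402 L405 Q437 C438 S440 S441 V442 "
        "S443 A444 V445 E446 L447 F448 V450 K473 D477 L478 M481 R482 P485 "
        "S486 A517 A520 S521 A524"
    ),
    "S3": (
        "A397 V401 F439 F439 S440 V442 V442 S443 S443 V445 V445 E446 E446 "
        "L447 V449 V533 V534 V534 S535 S535 V536 A537 T538 T538 L539 L540 "
        "M541 M541 T542 I543 F545"
    ),
    "S4": (
        "Y413 I423 Q424 Q424 N425 A427 A427 G428 G553 G553 L554 L554 L555 "
        "L555 V556 N557 N557 F578 F586 P602 C603 N604 Y605 A606 T607 L614 "
        "Q617 G618 I619 L621"
    ),
}


@dataclass
class SiteDefinition:
    """A named candidate binding site as a set of (resname, resid)."""

    site_id: str
    residues: frozenset[tuple[str, int]]
    chain_scope: str = "both_chains"

    def __post_init__(self) -> None:
        self.residues = frozenset(self.residues)
        if not self.residues:
            raise ValidationError(f"site {self.site_id}: empty residue set")
        if any(r <= 0 for _, r in self.residues):
            raise ValidationError(f"site {self.site_id}: resids must be positive")

    @property
    def resids(self) -> frozenset[int]:
        return frozenset(r for _, r in self.residues)


@dataclass
class ContactSet:
    """Receptor residues within cutoff of one pose, with min distances."""

    pose_ref: tuple[str, str, int]
    contacts: frozenset[tuple[str, str, int]]  # (chain, resname, resid)
    min_distances: dict[tuple[str, str, int], float]
    cutoff: float = DEFAULT_CUTOFF


@dataclass
class SiteAssignment:
    """Label of one pose under the two-site comparison rule."""

    pose_ref: tuple[str, str, int]
    label: str
    per_site_counts: dict[str, int] = field(default_factory=dict)


def _parse_site(site_id: str, text: str) -> SiteDefinition:
    residues = []
    for token in text.split():
        residues.append((_AA1TO3[token[0]], int(token[1:])))
    return SiteDefinition(site_id=site_id, residues=frozenset(residues))


def builtin_sites() -> list[SiteDefinition]:
    """The four built-in binding-site residue lists, de-duplicated."""
    return [_parse_site(sid, text) for sid, text in _RAW_SITES.items()]


def find_contacts(
    pose: Pose,
    receptor_frame,
    cutoff: float = DEFAULT_CUTOFF,
    pose_ref: tuple[str, str, int] | None = None,
) -> ContactSet:
    """Residues with any heavy atom within ``cutoff`` Å of the pose.

    ``receptor_frame`` is a list of :class:`~sitescan.structio.Atom` or a
    :class:`~sitescan.structio.Structure` (frame 0 is used).  The cutoff is
    inclusive.
    """
    if cutoff <= 0:
        raise ValidationError(f"cutoff must be positive, got {cutoff}")
    if isinstance(receptor_frame, Structure):
        receptor_frame = receptor_frame.models[0]
    lig = np.asarray(pose.coords, dtype=float)
    if lig.size == 0:
        raise ValidationError("pose has no heavy atoms")
    heavy = [a for a in receptor_frame if a.is_heavy]
    if not heavy:
        raise ValidationError("receptor frame has no heavy atoms")
    rec = np.array([a.xyz for a in heavy], dtype=float)
    dmin_per_atom = cdist(rec, lig).min(axis=1)
    min_distances: dict[tuple[str, str, int], float] = {}
    for a, d in zip(heavy, dmin_per_atom):
        key = (a.chain, a.resname, a.resid)
        if d <= cutoff and d < min_distances.get(key, np.inf):
            min_distances[key] = float(d)
    ref = pose_ref if pose_ref is not None else ("", "", pose.rank)
    return ContactSet(
        pose_ref=ref,
        contacts=frozenset(min_distances),
        min_distances=min_distances,
        cutoff=cutoff,
    )


def assign_pose(
    contacts: ContactSet, site_defs: list[SiteDefinition]
) -> SiteAssignment:
    """Assign a pose to a site (or overlap region) by contacted-residue counts."""
    ids = [s.site_id for s in site_defs]
    if len(set(ids)) != len(ids):
        raise ValidationError("site_defs must have pairwise-distinct ids")
    contacted = {(resname, resid) for _, resname, resid in contacts.contacts}
    counts = {
        s.site_id: len(contacted & s.residues) for s in site_defs
    }
    best = max(counts.values(), default=0)
    if best == 0:
        label = UNASSIGNED
    else:
        top = sorted(sid for sid, c in counts.items() if c == best)
        if len(top) == 1:
            label = top[0]
        else:
            label = OVERLAP_LABELS.get(frozenset(top), UNASSIGNED)
    return SiteAssignment(
        pose_ref=contacts.pose_ref, label=label, per_site_counts=counts
    )


def docking_box(
    receptor, selection=None, margin: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned bounding box of selected heavy atoms, grown by ``margin``.

    Returns ``(lower, upper)`` corner coordinates in Å.
    """
    if isinstance(receptor, Structure):
        receptor = receptor.models[0]
    atoms = [a for a in receptor if a.is_heavy]
    if selection is not None:
        atoms = [a for a in atoms if selection(a)]
    if not atoms:
        raise ValidationError("empty selection for docking box")
    coords = np.array([a.xyz for a in atoms], dtype=float)
    return coords.min(axis=0) - margin, coords.max(axis=0) + margin
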