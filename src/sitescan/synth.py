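"""Synthetic-data generator: every input the pipeline consumes, offline.

Produces a two-chain α-helix bundle "receptor" with declared binding
sites, docking-output pose files whose true target site is recorded in a
truth table, and replicate distance time series with scripted mean/SD per
condition.  Everything is deterministic: all randomness flows from one
integer seed, with per-stream sub-seeds, and regenerated files are
byte-identical.

No physical realism is attempted — dummy ligands are rigid octahedra and
helices may overlap; the point is exercising the contact, assignment and
statistics code paths with known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .geometry import DistanceSeries
from .sites import SiteDefinition
from .structio import Atom, Structure, write_pdb, write_pdbqt_poses

__all__ = [
    "LigandPlan",
    "DistancePlan",
    "SynthSpec",
    "default_spec",
    "ideal_helix",
    "helix_bundle",
    "synth_poses",
    "synth_trajectory",
    "synth_distance_traj",
    "simulate_to_dir",
]

# canonical alpha-helix parameters
RISE = 1.5          # Å per residue along the axis
TWIST = 100.0       # degrees per residue
CA_RADIUS = 2.3     # Å from the helix axis

# octahedral dummy ligand vertex distance; sized so a pose at a site
# centroid reaches every seed residue within the default 4.5 Å cutoff
LIGAND_RADIUS = 2.5

# residue names cycled along synthetic helices (no GLY/PRO, so side-chain
# truncation is well-defined everywhere)
_RESNAME_CYCLE = ("LEU", "SER", "VAL", "THR", "ASN", "ILE", "GLN", "MET")

# idealized backbone offsets relative to the helical path: (radius, extra
# twist in degrees, extra rise in Å) per atom name
_BACKBONE_OFFSETS = (
    ("N", 1.60, -28.0, -0.90),
    ("CA", CA_RADIUS, 0.0, 0.0),
    ("C", 2.00, 26.0, 0.55),
    ("O", 2.05, 31.0, 1.75),
    ("CB", 3.84, -5.0, -0.25),
)


@dataclass
class LigandPlan:
    ligand_id: str
    category: str
    n_poses: int
    target_site: str
    jitter_sd: float
    affinity_mean: float
    affinity_sd: float

    def __post_init__(self) -> None:
        if self.n_poses < 1:
            raise ValidationError("n_poses must be >= 1")
        if self.jitter_sd < 0 or self.affinity_sd < 0:
            raise ValidationError("standard deviations must be >= 0")


@dataclass
class DistancePlan:
    mean: float
    sd: float
    n_frames: int
    n_replicates: int
    drift_per_frame: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")
        if self.n_frames < 1 or self.n_replicates < 1:
            raise ValidationError("n_frames and n_replicates must be >= 1")


@dataclass
class SynthSpec:
    """Complete recipe for one synthetic dataset."""

    seed: int
    n_helices: int = 6
    residues_per_helix: int = 30
    bundle_radius: float = 6.0
    site_plan: dict[str, list[int]] = field(default_factory=dict)
    pose_plan: list[LigandPlan] = field(default_factory=list)
    n_conformations: int = 1
    traj_n_frames: int = 50
    traj_jitter_sd: float = 0.3
    distance_plan: dict[str, DistancePlan] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_helices < 1 or self.residues_per_helix < 4:
            raise ValidationError("need >= 1 helix of >= 4 residues")
        if self.n_conformations < 1:
            raise ValidationError("n_conformations must be >= 1")
        if self.traj_jitter_sd < 0:
            raise ValidationError("traj_jitter_sd must be >= 0")


def default_spec(
    seed: int = 0,
    n_substrates: int = 25,
    n_nonsubstrates: int = 14,
    n_poses: int = 20,
    n_conformations: int = 6,
    jitter_sd: float = 0.8,
) -> SynthSpec:
    """A cohort-shaped default: substrates aimed at S2, non-substrates at
    S1/S3, category-shifted affinity distributions."""
    site_plan = {
        "S1": [4, 5, 6, 34, 35, 36],
        "S2": [70, 71, 72, 100, 101, 102],
        "S3": [136, 137, 138, 166, 167, 168],
        "S4": [22, 23, 24, 172, 173, 174],
    }
    pose_plan: list[LigandPlan] = []
    for i in range(n_substrates):
        pose_plan.append(
            LigandPlan(
                ligand_id=f"sub{i:02d}", category="substrate", n_poses=n_poses,
                target_site="S2", jitter_sd=jitter_sd,
                affinity_mean=-9.0, affinity_sd=1.0,
            )
        )
    for i in range(n_nonsubstrates):
        pose_plan.append(
            LigandPlan(
                ligand_id=f"non{i:02d}", category="non-substrate", n_poses=n_poses,
                target_site="S1" if i % 2 == 0 else "S3", jitter_sd=jitter_sd,
                affinity_mean=-7.0, affinity_sd=1.0,
            )
        )
    distance_plan = {
        "WT": DistancePlan(mean=8.0, sd=1.0, n_frames=500, n_replicates=6),
        "MUT": DistancePlan(mean=10.0, sd=2.0, n_frames=500, n_replicates=6),
    }
    return SynthSpec(
        seed=seed,
        site_plan=site_plan,
        pose_plan=pose_plan,
        n_conformations=n_conformations,
        distance_plan=distance_plan,
    )


def _rotation_from_z(axis: np.ndarray) -> np.ndarray:
    """Proper rotation taking +z onto ``axis`` (normalized)."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValidationError("axis must be non-zero")
    axis = axis / norm
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    c = float(np.dot(z, axis))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def ideal_helix(
    n_res: int,
    origin=(0.0, 0.0, 0.0),
    axis=(0.0, 0.0, 1.0),
    chain: str = "A",
    start_resid: int = 1,
) -> Structure:
    """Idealized α-helix (1.5 Å rise, 100° twist, 2.3 Å Cα radius).

    Minimal backbone (N, CA, C, O) plus CB at idealized offsets; fully
    deterministic for fixed arguments.
    """
    if n_res < 4:
        raise ValidationError(f"need n_res >= 4, got {n_res}")
    origin = np.asarray(origin, dtype=float)
    R = _rotation_from_z(axis)
    atoms: list[Atom] = []
    for j in range(n_res):
        resid = start_resid + j
        resname = _RESNAME_CYCLE[j % len(_RESNAME_CYCLE)]
        for name, radius, dtheta, drise in _BACKBONE_OFFSETS:
            theta = math.radians(TWIST * j + dtheta)
            local = np.array(
                [radius * math.cos(theta), radius * math.sin(theta), RISE * j + drise]
            )
            atoms.append(
                Atom(
                    serial=len(atoms) + 1,
                    name=name,
                    resname=resname,
                    chain=chain,
                    resid=resid,
                    xyz=origin + R @ local,
                    element=name[0],
                )
            )
    return Structure([atoms], id=f"helix_{chain}{start_resid}")


def helix_bundle(spec: SynthSpec) -> tuple[Structure, list[SiteDefinition]]:
    """Bundle of parallel helices on a circle, duplicated as a second chain.

    Residues are numbered continuously across helices within a chain; the
    second chain is a translated copy (same numbering, chain B), emulating
    a homodimer.  Every declared site's residues are verified to be
    mutually within 15 Å so one pose can contact all of them.
    """
    atoms: list[Atom] = []
    for h in range(spec.n_helices):
        phi = 2.0 * math.pi * h / spec.n_helices
        origin = np.array(
            [spec.bundle_radius * math.cos(phi), spec.bundle_radius * math.sin(phi), 0.0]
        )
        helix = ideal_helix(
            spec.residues_per_helix,
            origin=origin,
            chain="A",
            start_resid=h * spec.residues_per_helix + 1,
        )
        atoms.extend(helix.models[0])
    # second chain: translated copy well clear of chain A
    shift = np.array([6.0 * spec.bundle_radius + 20.0, 0.0, 0.0])
    chain_b = [
        Atom(
            serial=0, name=a.name, resname=a.resname, chain="B", resid=a.resid,
            xyz=a.xyz + shift, element=a.element,
        )
        for a in atoms
    ]
    all_atoms = atoms + chain_b
    for i, a in enumerate(all_atoms, start=1):
        a.serial = i
    structure = Structure([all_atoms], id="bundle")

    ca = {
        (a.chain, a.resid): a.xyz for a in all_atoms if a.name == "CA"
    }
    resname_of = {a.resid: a.resname for a in atoms}
    site_defs: list[SiteDefinition] = []
    max_resid = spec.n_helices * spec.residues_per_helix
    for site_id, resids in spec.site_plan.items():
        if any(not 1 <= r <= max_resid for r in resids):
            raise ValidationError(f"site {site_id}: resid outside the bundle")
        pts = [ca[("A", r)] for r in resids]
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                if np.linalg.norm(pts[i] - pts[j]) > 15.0:
                    raise ValidationError(
                        f"site {site_id}: residues {resids[i]} and {resids[j]} "
                        "are more than 15 Å apart"
                    )
        site_defs.append(
            SiteDefinition(
                site_id=site_id,
                residues=frozenset((resname_of[r], r) for r in resids),
            )
        )
    return structure, site_defs


_OCTAHEDRON = LIGAND_RADIUS * np.array(
    [
        [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
    ],
    dtype=float,
)


def _site_centroid(structure: Structure, site: SiteDefinition, chain: str = "A") -> np.ndarray:
    pts = [
        a.xyz
        for a in structure.models[0]
        if a.chain == chain and a.name == "CA" and (a.resname, a.resid) in site.residues
    ]
    if not pts:
        raise ValidationError(f"site {site.site_id}: no CA atoms found in chain {chain}")
    return np.mean(pts, axis=0)


def synth_poses(
    structure: Structure,
    site_defs: list[SiteDefinition],
    pose_plan: list[LigandPlan],
    seed: int,
    n_conformations: int = 1,
    out_dir: str | Path | None = None,
):
    """Generate docked-pose clouds around declared site centroids.

    Returns ``(pose_data, truth_rows)`` where ``pose_data`` maps
    ``(conformation_id, ligand_id)`` to ``(coords_per_pose, affinities)``
    (affinities sorted ascending, matching rank order), and each truth row
    is ``(conformation_id, ligand_id, rank, target_site, category)``.  When
    ``out_dir`` is given, one Vina-style PDBQT per (conformation, ligand)
    plus ``truth.tsv`` and ``categories.tsv`` are written there.
    """
    sites_by_id = {s.site_id: s for s in site_defs}
    for plan in pose_plan:
        if plan.target_site not in sites_by_id:
            raise ValidationError(f"unknown target site {plan.target_site!r}")
    pose_data: dict[tuple[str, str], tuple[list[np.ndarray], list[float]]] = {}
    truth: list[tuple[str, str, int, str, str]] = []
    for c in range(n_conformations):
        conf_id = f"conf{c + 1}"
        for li, plan in enumerate(pose_plan):
            rng = np.random.default_rng([seed, c, li])
            centroid = _site_centroid(structure, sites_by_id[plan.target_site])
            coords = []
            for _ in range(plan.n_poses):
                center = centroid + rng.normal(0.0, plan.jitter_sd, size=3)
                coords.append(center + _OCTAHEDRON)
            affinities = np.sort(rng.normal(plan.affinity_mean, plan.affinity_sd, plan.n_poses))
            pose_data[(conf_id, plan.ligand_id)] = (coords, [float(a) for a in affinities])
            for rank in range(1, plan.n_poses + 1):
                truth.append((conf_id, plan.ligand_id, rank, plan.target_site, plan.category))

    if out_dir is not None:
        out_dir = Path(out_dir)
        for (conf_id, ligand_id), (coords, affinities) in pose_data.items():
            d = out_dir / "poses" / conf_id
            d.mkdir(parents=True, exist_ok=True)
            write_pdbqt_poses(d / f"{ligand_id}.pdbqt", coords, affinities)
        lines = ["conformation\tligand\trank\ttarget_site\tcategory"]
        lines += ["\t".join(map(str, row)) for row in truth]
        (out_dir / "truth.tsv").write_text("\n".join(lines) + "\n")
        cat_lines = ["ligand\tcategory"]
        seen = set()
        for plan in pose_plan:
            if plan.ligand_id not in seen:
                seen.add(plan.ligand_id)
                cat_lines.append(f"{plan.ligand_id}\t{plan.category}")
        (out_dir / "categories.tsv").write_text("\n".join(cat_lines) + "\n")
    return pose_data, truth


def synth_trajectory(
    structure: Structure, n_frames: int, jitter_sd: float, seed: int
) -> Structure:
    """Multi-frame copy of frame 0 with i.i.d. Gaussian positional jitter.

    Frame 0 is the unperturbed input frame (so it can serve as the RMSD
    reference); frames 1..n-1 add N(0, jitter_sd²) to every coordinate.
    """
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    rng = np.random.default_rng([seed, 7])
    base = structure.models[0]
    models = [[_copy_atom(a) for a in base]]
    for _ in range(n_frames - 1):
        noise = rng.normal(0.0, jitter_sd, size=(len(base), 3))
        models.append(
            [_copy_atom(a, a.xyz + noise[i]) for i, a in enumerate(base)]
        )
    return Structure(models, id=f"{structure.id}_traj")


def _copy_atom(a: Atom, xyz=None) -> Atom:
    return Atom(
        serial=a.serial, name=a.name, resname=a.resname, chain=a.chain,
        resid=a.resid, xyz=(a.xyz.copy() if xyz is None else xyz),
        element=a.element, icode=a.icode, occupancy=a.occupancy,
        bfactor=a.bfactor, record=a.record,
    )


def synth_distance_traj(
    distance_plan: dict[str, DistancePlan],
    seed: int,
    pair: tuple[tuple[str, int], tuple[str, int]] = (("A", 141), ("A", 382)),
) -> dict[str, list[DistanceSeries]]:
    """Gaussian distance series per condition/replicate at scripted mean/SD.

    An optional linear drift term models diverging helices.  Values are
    floored at zero (distances), which is immaterial for the default plans
    where the mean is many SDs above zero.
    """
    out: dict[str, list[DistanceSeries]] = {}
    for ci, (condition, plan) in enumerate(distance_plan.items()):
        series = []
        for rep in range(plan.n_replicates):
            rng = np.random.default_rng([seed, 1000 + ci, rep])
            values = plan.mean + rng.normal(0.0, plan.sd, plan.n_frames)
            if plan.drift_per_frame:
                values = values + plan.drift_per_frame * np.arange(plan.n_frames)
            series.append(
                DistanceSeries(
                    pair=pair,
                    values=np.maximum(values, 0.0),
                    replicate_id=f"{condition}_rep{rep + 1}",
                )
            )
        out[condition] = series
    return out


def simulate_to_dir(spec: SynthSpec, out_dir: str | Path) -> list[Path]:
    """Emit a full synthetic dataset; returns the list of files written.

    Layout: ``receptor.pdb``, ``sites.tsv``, ``poses/confN/<ligand>.pdbqt``,
    ``categories.tsv``, ``truth.tsv``, ``trajectory.pdb`` and
    ``distances/<condition>_rep<i>.tsv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    structure, site_defs = helix_bundle(spec)
    write_pdb(structure, out_dir / "receptor.pdb")

    lines = ["site\tresname\tresid"]
    for s in site_defs:
        for resname, resid in sorted(s.residues, key=lambda x: x[1]):
            lines.append(f"{s.site_id}\t{resname}\t{resid}")
    (out_dir / "sites.tsv").write_text("\n".join(lines) + "\n")

    synth_poses(
        structure, site_defs, spec.pose_plan, seed=spec.seed,
        n_conformations=spec.n_conformations, out_dir=out_dir,
    )

    traj = synth_trajectory(structure, spec.traj_n_frames, spec.traj_jitter_sd, spec.seed)
    write_pdb(traj, out_dir / "trajectory.pdb")

    dist_dir = out_dir / "distances"
    dist_dir.mkdir(exist_ok=True)
    for condition, series_list in synth_distance_traj(spec.distance_plan, spec.seed).items():
        for s in series_list:
            rows = ["frame\tdistance"]
            rows += [f"{i}\t{v:.6f}" for i, v in enumerate(s.values)]
            (dist_dir / f"{s.replicate_id}.tsv").write_text("\n".join(rows) + "\n")

    return sorted(p for p in out_dir.rglob("*") if p.is_file())
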