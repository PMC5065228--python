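"""Superposition, RMSD, distance series, smoothing and depth annotation.

The trajectory-analysis toolkit: Kabsch least-squares superposition (with
an iterative-outlier-rejection wrapper for comparing divergent chains),
per-frame RMSD against a reference frame, Cα–Cα distance time series,
non-overlapping block averaging, membrane-depth labelling of residues from
a user-supplied hydrophobic slab, and simple side-chain truncation mutants.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError
from .structio import Atom, Structure

__all__ = [
    "DistanceSeries",
    "MembraneSlab",
    "kabsch_superpose",
    "iterative_superpose",
    "rmsd_series",
    "ca_distance_series",
    "block_average",
    "annotate_depth",
    "truncate_sidechain",
]

BACKBONE_NAMES = ("N", "CA", "C", "O", "OXT")


@dataclass
class DistanceSeries:
    """Per-frame Cα–Cα distance between one residue pair, one replicate."""

    pair: tuple[tuple[str, int], tuple[str, int]]
    values: np.ndarray
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("distance values must be a 1-D series")
        if self.values.size and (
            not np.all(np.isfinite(self.values)) or np.any(self.values < 0)
        ):
            raise ValidationError("distances must be finite and non-negative")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class MembraneSlab:
    """Hydrophobic-core boundary planes plus headgroup shell width (Å)."""

    z_lower: float
    z_upper: float
    headgroup_width: float = 8.0

    def __post_init__(self) -> None:
        if not self.z_lower < self.z_upper:
            raise ValidationError("require z_lower < z_upper")
        if not self.headgroup_width > 0:
            raise ValidationError("headgroup_width must be positive")


def kabsch_superpose(
    mobile_coords: np.ndarray, ref_coords: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares optimal rigid superposition of two matched point sets.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` superposes onto ``ref``.  The
    rotation is proper (det +1).
    """
    mobile = np.asarray(mobile_coords, dtype=float)
    ref = np.asarray(ref_coords, dtype=float)
    if mobile.shape != ref.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValidationError(
            f"point sets must be matched (n, 3) arrays, got {mobile.shape} vs {ref.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 points for superposition")
    mob_center = mobile.mean(axis=0)
    ref_center = ref.mean(axis=0)
    P = mobile - mob_center
    Q = ref - ref_center
    if np.linalg.matrix_rank(P, tol=1e-8) < 2:
        raise ValidationError("degenerate (collinear) point set")
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_center - R @ mob_center
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return R, t, rmsd


def iterative_superpose(
    mobile_coords: np.ndarray,
    ref_coords: np.ndarray,
    reject_factor: float = 2.0,
    max_cycles: int = 5,
    min_pairs: int = 3,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Superpose with iterative outlier rejection (PyMOL-align style).

    Each cycle superposes the retained pairs, then drops pairs whose
    residual exceeds ``reject_factor`` × current RMSD; stops when nothing is
    rejected, ``max_cycles`` is reached, or fewer than ``min_pairs`` would
    remain.  Returns ``(rotation, translation, rmsd, kept_mask)`` where the
    RMSD is over the retained pairs only.
    """
    mobile = np.asarray(mobile_coords, dtype=float)
    ref = np.asarray(ref_coords, dtype=float)
    keep = np.ones(len(mobile), dtype=bool)
    R, t, rmsd = kabsch_superpose(mobile, ref)
    for _ in range(max_cycles):
        moved = mobile[keep] @ R.T + t
        residuals = np.sqrt(np.sum((moved - ref[keep]) ** 2, axis=1))
        bad = residuals > reject_factor * rmsd
        if not bad.any():
            break
        if keep.sum() - bad.sum() < min_pairs:
            break
        idx = np.flatnonzero(keep)
        keep[idx[bad]] = False
        R, t, rmsd = kabsch_superpose(mobile[keep], ref[keep])
    return R, t, rmsd, keep


def _selection_indices(structure: Structure, selection) -> list[int]:
    """Resolve a selection (predicate or index list) on frame 0."""
    if callable(selection):
        idx = structure.select(selection, model_index=0)
    else:
        idx = list(selection)
    if not idx:
        raise ValidationError("empty selection")
    return idx


def rmsd_series(
    structure: Structure, ref_frame_index: int = 0, selection=None
) -> np.ndarray:
    """Per-frame RMSD to a reference frame after optimal superposition.

    ``selection`` is a predicate over :class:`~sitescan.structio.Atom` (or a
    list of atom indices); default is all Cα atoms.  The entry at the
    reference index is exactly 0.
    """
    if selection is None:
        selection = lambda a: a.name == "CA"  # noqa: E731
    idx = _selection_indices(structure, selection)
    if not 0 <= ref_frame_index < structure.n_models:
        raise ValidationError(f"reference frame {ref_frame_index} out of range")
    ref = structure.coords(ref_frame_index)[idx]
    out = np.empty(structure.n_models, dtype=float)
    for i in range(structure.n_models):
        if i == ref_frame_index:
            out[i] = 0.0
            continue
        _, _, rmsd = kabsch_superpose(structure.coords(i)[idx], ref)
        out[i] = rmsd
    return out


def _ca_index(structure: Structure, chain: str, resid: int) -> int:
    for i, a in enumerate(structure.models[0]):
        if a.chain == chain and a.resid == resid and a.name == "CA":
            return i
    raise ValidationError(f"residue {chain}:{resid} has no CA atom")


def ca_distance_series(
    structure: Structure,
    pair: tuple[tuple[str, int], tuple[str, int]],
    replicate_id: str = "",
) -> DistanceSeries:
    """Euclidean Cα–Cα distance per frame for one residue pair (Å)."""
    (c1, r1), (c2, r2) = pair
    i1 = _ca_index(structure, c1, r1)
    i2 = _ca_index(structure, c2, r2)
    values = np.empty(structure.n_models, dtype=float)
    for f, model in enumerate(structure.models):
        a1, a2 = model[i1], model[i2]
        for a, (c, r) in ((a1, (c1, r1)), (a2, (c2, r2))):
            if a.name != "CA" or a.chain != c or a.resid != r:
                raise ValidationError(
                    f"frame {f}: residue {c}:{r} CA atom missing or reordered"
                )
        values[f] = float(np.linalg.norm(a1.xyz - a2.xyz))
    return DistanceSeries(pair=pair, values=values, replicate_id=replicate_id)


def block_average(values, window: int = 10) -> np.ndarray:
    """Mean of consecutive non-overlapping blocks of ``window`` values.

    A final partial block is averaged over its actual length; the output
    has ``ceil(n / window)`` entries.  Empty input yields an empty array.
    """
    if window < 1:
        raise ValidationError(f"window must be >= 1, got {window}")
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError("block_average expects a 1-D series")
    n = arr.size
    if n == 0:
        return np.empty(0, dtype=float)
    n_full = n // window
    out = []
    if n_full:
        out.append(arr[: n_full * window].reshape(n_full, window).mean(axis=1))
    if n % window:
        out.append(np.array([arr[n_full * window:].mean()]))
    return np.concatenate(out)


HYDROPHOBIC_CORE = "hydrophobic_core"
HEADGROUP = "headgroup"
AQUEOUS = "aqueous"


def annotate_depth(
    structure: Structure, slab: MembraneSlab, model_index: int = 0
) -> dict[tuple[str, int, str], str]:
    """Label each residue by the membrane region its Cα z-coordinate hits.

    Labels: ``hydrophobic_core`` inside the slab (inclusive), ``headgroup``
    within ``headgroup_width`` outside either boundary plane, ``aqueous``
    beyond that.  Residues without a Cα are skipped.
    """
    labels: dict[tuple[str, int, str], str] = {}
    for a in structure.models[model_index]:
        if a.name != "CA":
            continue
        z = float(a.xyz[2])
        if slab.z_lower <= z <= slab.z_upper:
            label = HYDROPHOBIC_CORE
        elif (
            slab.z_lower - slab.headgroup_width <= z < slab.z_lower
            or slab.z_upper < z <= slab.z_upper + slab.headgroup_width
        ):
            label = HEADGROUP
        else:
            label = AQUEOUS
        labels[a.residue_key] = label
    return labels


def truncate_sidechain(
    structure: Structure, chain: str, resid: int, target: str
) -> Structure:
    """Mutate one residue to GLY or ALA by deleting side-chain atoms.

    GLY keeps only backbone atoms (N, CA, C, O, OXT); ALA additionally
    keeps CB.  Applied to every frame; serials are renumbered.  Proline is
    unsupported (its ring shares backbone atoms).
    """
    target = target.upper()
    if target not in ("GLY", "ALA"):
        raise ValidationError(f"target must be GLY or ALA, got {target!r}")
    hit = [
        a for a in structure.models[0] if a.chain == chain and a.resid == resid
    ]
    if not hit:
        raise ValidationError(f"residue {chain}:{resid} not found")
    resname = hit[0].resname
    if resname == "PRO":
        raise ValidationError("proline truncation unsupported (ring shares backbone)")
    keep_names = set(BACKBONE_NAMES)
    if target == "ALA":
        keep_names.add("CB")
        if not any(a.name == "CB" for a in hit):
            raise ValidationError(
                f"residue {chain}:{resid} ({resname}) has no CB atom for ALA target"
            )

    new_models: list[list[Atom]] = []
    for model in structure.models:
        new_model: list[Atom] = []
        for a in model:
            if a.chain == chain and a.resid == resid:
                if a.name not in keep_names:
                    continue
                a = replace(a, resname=target, xyz=a.xyz.copy())
            else:
                a = replace(a, xyz=a.xyz.copy())
            a.serial = len(new_model) + 1
            new_model.append(a)
        new_models.append(new_model)
    return Structure(new_models, id=structure.id)
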