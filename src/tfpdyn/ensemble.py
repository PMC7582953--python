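"""NMR structural-ensemble superposition and disorder metrics.

A :class:`StructureEnsemble` holds the backbone (N, CA, C') coordinates
of a multi-model NMR ensemble. Superposition performs least-squares
rigid-body (Kabsch) alignment of every model onto an iteratively
refined mean structure over a selected residue set; the disorder
profile then reports per-residue average displacement (the "sausage"
radius) and per-region mean RMSD, both measured against the mean
structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .classify import RegionScheme, RegionMean

BACKBONE_ATOMS = ("N", "CA", "C")


@dataclass
class StructureEnsemble:
    """Backbone coordinates of an NMR ensemble.

    ``coords`` has shape (n_models, n_residues, 3 backbone atoms, 3);
    atom order is N, CA, C'. ``residue_ids`` preserves author numbering
    (Met0 = 0 allowed). All models share composition and numbering by
    construction.
    """

    residue_ids: np.ndarray          # (n_residues,), int
    residue_names: List[str]
    coords: np.ndarray               # (n_models, n_residues, 3, 3), Angstrom
    name: str = "ensemble"

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 4 or self.coords.shape[1] != self.residue_ids.size \
                or self.coords.shape[2:] != (3, 3):
            raise ValueError("coords must have shape (models, residues, 3 atoms, 3)")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def residue_index(self, residue_id: int) -> int:
        idx = np.nonzero(self.residue_ids == residue_id)[0]
        if idx.size == 0:
            raise KeyError(f"residue {residue_id} not in ensemble")
        return int(idx[0])

    def nh_orientations(self, model_index: int = 0) -> Dict[int, np.ndarray]:
        """Approximate unit NH bond vectors from backbone geometry.

        The amide proton is placed opposite the bisector of the
        C'(i-1)->N(i) and CA(i)->N(i) directions (standard construction
        when amide hydrogens are absent from the coordinates). The first
        residue has no preceding carbonyl and is skipped.
        """
        out: Dict[int, np.ndarray] = {}
        xyz = self.coords[model_index]
        for i in range(1, self.n_residues):
            n_pos = xyz[i, 0]
            ca_pos = xyz[i, 1]
            c_prev = xyz[i - 1, 2]
            u1 = c_prev - n_pos
            u2 = ca_pos - n_pos
            u1 /= np.linalg.norm(u1)
            u2 /= np.linalg.norm(u2)
            h_dir = -(u1 + u2)
            norm = np.linalg.norm(h_dir)
            if norm < 1e-9:
                continue
            out[int(self.residue_ids[i])] = h_dir / norm
        return out


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t mapping mobile->target."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    rot = vt.T @ correction @ u.T
    return rot, tc - rot @ mc


def superpose_ensemble(
    ensemble: StructureEnsemble,
    selection: Iterable[int],
    max_rounds: int = 5,
    tol_angstrom: float = 1e-6,
) -> Tuple[StructureEnsemble, np.ndarray]:
    """Superpose all models on the selection backbone; return (aligned, mean).

    Each model is rigidly fitted (rotation with det +1, no reflections)
    onto the current mean structure computed over the selection's
    backbone atoms; the mean is refined iteratively (up to ``max_rounds``
    rounds or until it moves by less than ``tol_angstrom``).
    """
    selection = list(selection)
    if not selection:
        raise ValueError("superposition selection is empty")
    sel_idx = []
    missing = []
    for rid in selection:
        try:
            sel_idx.append(ensemble.residue_index(rid))
        except KeyError:
            missing.append(rid)
    if missing:
        raise ValueError(f"selection residues missing from ensemble: {missing}")
    coords = ensemble.coords.copy()
    n_models = coords.shape[0]
    flat = lambda c: c[:, sel_idx].reshape(n_models, -1, 3)

    mean_sel = flat(coords)[0].copy()
    for _ in range(max_rounds):
        for m in range(n_models):
            rot, trans = _kabsch(flat(coords)[m], mean_sel)
            coords[m] = coords[m] @ rot.T + trans
        new_mean = flat(coords).mean(axis=0)
        shift = float(np.max(np.linalg.norm(new_mean - mean_sel, axis=1)))
        mean_sel = new_mean
        if shift < tol_angstrom:
            break
    aligned = StructureEnsemble(
        residue_ids=ensemble.residue_ids.copy(),
        residue_names=list(ensemble.residue_names),
        coords=coords,
        name=ensemble.name,
    )
    mean_structure = coords.mean(axis=0)
    return aligned, mean_structure


@dataclass
class DisorderProfile:
    """Per-residue displacement and per-region RMSD of an aligned ensemble."""

    residue_ids: np.ndarray
    displacement: np.ndarray          # (n_residues,), mean backbone displacement, A
    region_rmsd: Dict[str, RegionMean]
    scheme_name: str
    selection: Tuple[int, ...]

    def displacement_of(self, residue_id: int) -> float:
        return float(self.displacement[np.nonzero(self.residue_ids == residue_id)[0][0]])


def disorder_profile(
    aligned: StructureEnsemble,
    scheme: RegionScheme,
    selection: Sequence[int] = (),
    all_pairs: bool = False,
) -> DisorderProfile:
    """Disorder metrics of a superposed ensemble.

    Per-residue displacement is the mean over models and backbone atoms
    of the distance to the mean structure (the sausage radius). Region
    RMSD is the root-mean-square backbone deviation from the mean
    structure over models, residues and atoms of the region. With
    ``all_pairs=True`` the RMSD is computed over all model pairs instead
    (cross-check mode; larger by ~sqrt(2) for Gaussian disorder).
    """
    ids = aligned.residue_ids
    for region in scheme.region_names:
        for rid in scheme.residues(region):
            if rid not in ids:
                raise ValueError(
                    f"region scheme {scheme.name!r} names residue {rid} "
                    f"absent from ensemble {aligned.name!r}"
                )
    mean_structure = aligned.coords.mean(axis=0)
    # (models, residues, atoms) distances to the mean
    dists = np.linalg.norm(aligned.coords - mean_structure[None], axis=-1)
    displacement = dists.mean(axis=(0, 2))

    region_rmsd: Dict[str, RegionMean] = {}
    for region in scheme.region_names:
        rids = scheme.residues(region)
        idx = [aligned.residue_index(r) for r in rids]
        if all_pairs:
            n = aligned.n_models
            acc = []
            for a in range(n):
                for b in range(a + 1, n):
                    diff = aligned.coords[a, idx] - aligned.coords[b, idx]
                    acc.append(np.mean(np.sum(diff**2, axis=-1)))
            rmsd = math.sqrt(float(np.mean(acc))) if acc else None
        else:
            rmsd = math.sqrt(float(np.mean(dists[:, idx] ** 2)))
        region_rmsd[region] = RegionMean(region, rmsd, len(idx), len(rids))
    return DisorderProfile(
        residue_ids=ids.copy(),
        displacement=displacement,
        region_rmsd=region_rmsd,
        scheme_name=scheme.name,
        selection=tuple(selection),
    )
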