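"""Synthetic fixtures and independent oracles.

Everything here exists so the rest of the package can be exercised and
cross-checked without downloading real structures:

* :func:`gen_globule` builds pseudo-protein globules — a confined
  self-avoiding Cα walk decorated with satellite heavy atoms — at densities
  comparable to folded proteins, which is the regime the 9-point rough-circle
  stamp is designed for.
* :func:`gen_decoys` perturbs a native structure into an ensemble with known
  RMSDs and a controllable (funneled or anti-funneled) synthetic base-score
  landscape, emulating the decoy sets a sampling protocol would produce.
* :func:`union_disk_area_oracle` measures the exact union area of 2D disks
  (fine sub-grid or Monte Carlo), and :func:`pa_ccs_oracle` runs the full
  projection-approximation protocol with these exact full-disk areas in
  place of the rough stamp, sharing the rotation stream with
  :func:`parcs.core.compute_ccs` so any difference isolates the area
  estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CCSResult, DEFAULT_ROTATIONS, rotation_digest, rotation_matrices
from .structure_io import Atom, RadiusTable, StructureModel, assign_radii

CA_STEP = 3.8  # Å, consecutive-residue Cα distance
_SATELLITE_NAMES = ["CB", "C", "N", "O", "CG", "CD", "OE", "NZ"]
_SATELLITE_ELEMENTS = {"CB": "C", "C": "C", "N": "N", "O": "O",
                       "CG": "C", "CD": "C", "OE": "O", "NZ": "N"}


@dataclass(frozen=True)
class GlobuleSpec:
    """Parameters of a pseudo-protein globule."""

    n_residues: int
    atoms_per_residue: int = 8  # ≈ mean heavy-atom count of real amino acids
    min_separation: float = 1.5
    packing_radius_coeff: float = 3.0  # sphere radius ≈ coeff * n^(1/3) Å
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ValueError("n_residues must be >= 2")
        if self.atoms_per_residue < 1 or self.atoms_per_residue > 1 + len(_SATELLITE_NAMES):
            raise ValueError("atoms_per_residue out of supported range")


class PlacementError(RuntimeError):
    pass


def _random_unit(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def gen_globule(spec: GlobuleSpec) -> StructureModel:
    """Pseudo-protein globule: confined self-avoiding Cα walk plus satellites.

    Cα atoms advance in 3.8 Å steps inside a sphere of radius
    ``packing_radius_coeff * n_residues**(1/3)``; each residue gains
    ``atoms_per_residue - 1`` heavy satellites 1.5–2.5 Å from its Cα.  All
    atoms end up pairwise at least ``min_separation`` apart.  Deterministic
    per seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    radius = spec.packing_radius_coeff * n ** (1.0 / 3.0)
    sep2 = spec.min_separation ** 2
    ca_sep2 = max(spec.min_separation, 3.4) ** 2  # chain self-avoidance

    max_atoms = n * spec.atoms_per_residue
    placed = np.empty((max_atoms, 3))
    n_placed = 0
    ca_positions = np.empty((n, 3))

    def clashes(p: np.ndarray, limit2: float) -> bool:
        if n_placed == 0:
            return False
        d2 = ((placed[:n_placed] - p) ** 2).sum(axis=1)
        return bool((d2 < limit2).any())

    atoms: list[Atom] = []
    backtracks = 0
    i = 0
    while i < n:
        placed_this_residue = None
        for attempt in range(300):
            if i == 0:
                cand = _random_unit(rng)[0] * rng.uniform(0, radius * 0.5)
            else:
                cand = ca_positions[i - 1] + CA_STEP * _random_unit(rng)[0]
            if np.linalg.norm(cand) > radius:
                continue
            d2ca = ((ca_positions[:i] - cand) ** 2).sum(axis=1) if i else np.empty(0)
            if i and (d2ca[:-1] < ca_sep2).any():  # previous Cα is at CA_STEP, fine
                continue
            if clashes(cand, sep2):
                continue
            # satellites for this residue
            sats = []
            ok = True
            for k in range(spec.atoms_per_residue - 1):
                for sat_attempt in range(300):
                    sat = cand + rng.uniform(1.5, 2.5) * _random_unit(rng)[0]
                    if not clashes(sat, sep2) and \
                            not any(((s - sat) ** 2).sum() < sep2 for s in sats) and \
                            ((sat - cand) ** 2).sum() >= sep2:
                        sats.append(sat)
                        break
                else:
                    ok = False
                    break
            if ok:
                placed_this_residue = (cand, sats)
                break
        if placed_this_residue is None:
            # dead end in a dense region: back the walk up a few residues
            backtracks += 1
            if backtracks > 20 * n:
                raise PlacementError(
                    f"could not place residue {i}; try a larger packing_radius_coeff")
            drop = min(5, i)
            if drop == 0:
                raise PlacementError(
                    f"could not place residue {i}; try a larger packing_radius_coeff")
            i -= drop
            n_placed = i * spec.atoms_per_residue
            del atoms[n_placed:]
            continue
        cand, sats = placed_this_residue
        ca_positions[i] = cand
        placed[n_placed] = cand
        n_placed += 1
        atoms.append(Atom(element="C", coords=tuple(cand), residue_index=i,
                          chain_id="A", name="CA", res_name="ALA"))
        for k, sat in enumerate(sats):
            name = _SATELLITE_NAMES[k]
            placed[n_placed] = sat
            n_placed += 1
            atoms.append(Atom(element=_SATELLITE_ELEMENTS[name], coords=tuple(sat),
                              residue_index=i, chain_id="A", name=name,
                              res_name="ALA"))
        i += 1
    return StructureModel(atoms, source_id=f"globule_n{n}_s{spec.seed}")


@dataclass(frozen=True)
class DecoySpec:
    """Parameters of a synthetic decoy ensemble.

    ``funnel_slope`` is score units per Å of RMSD: positive gives a funneled
    base-score landscape (low RMSD scores best), negative an anti-funneled
    one.  Decoys are produced by global expansion of the native plus a small
    coordinate jitter, so RMSD, Rg and CCS all grow together — the regime
    where a size restraint is informative.
    """

    n_decoys: int
    rmsd_range: tuple[float, float] = (0.5, 8.0)
    funnel_slope: float = -10.0
    score_noise_sd: float = 0.0
    jitter_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_decoys < 2:
            raise ValueError("n_decoys must be >= 2")
        lo, hi = self.rmsd_range
        if not 0 <= lo < hi:
            raise ValueError("need 0 <= rmsd_range[0] < rmsd_range[1]")


def gen_decoys(native: StructureModel, spec: DecoySpec):
    """Decoy ensemble with known RMSD ladder and synthetic base scores.

    Returns ``(models, table)`` where ``table`` has columns model_id,
    base_score, rmsd (Cα RMSD to the native, measured after perturbation)
    and rg.  Base scores are ``funnel_slope * rmsd + N(0, score_noise_sd)``.
    """
    from .evaluation import radius_of_gyration, rmsd_ca  # avoid module cycle

    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    ca = native.ca_coordinates()
    rg_ca = float(np.sqrt(((ca - ca.mean(axis=0)) ** 2).sum(axis=1).mean()))
    coords = native.coordinates()
    centroid = coords.mean(axis=0)

    targets = np.linspace(spec.rmsd_range[0], spec.rmsd_range[1], spec.n_decoys)
    models, rows = [], []
    for i, target in enumerate(targets):
        factor = 1.0 + target / rg_ca
        jitter = rng.normal(scale=spec.jitter_fraction * target / np.sqrt(3) + 1e-12,
                            size=coords.shape)
        xyz = centroid + factor * (coords - centroid) + jitter
        model_id = f"decoy_{i:04d}"
        decoy = native.with_coordinates(xyz, source_id=model_id)
        rmsd = rmsd_ca(decoy, native)
        rows.append({"model_id": model_id,
                     "base_score": spec.funnel_slope * rmsd
                     + (rng.normal(scale=spec.score_noise_sd)
                        if spec.score_noise_sd > 0 else 0.0),
                     "rmsd": rmsd,
                     "rg": radius_of_gyration(decoy),
                     "expansion": factor})
        models.append(decoy)
    return models, pd.DataFrame(rows)


@dataclass(frozen=True)
class UnionArea:
    """Union-of-disks area estimate; stderr only for the Monte Carlo method."""

    area: float
    stderr: float | None = None


def union_disk_area_oracle(centers2d: np.ndarray, radii: np.ndarray,
                           method: str = "fine_grid", cell: float = 0.05,
                           n_probes: int = 200_000,
                           seed: int = 0) -> UnionArea:
    """Reference area of a union of 2D disks.

    ``fine_grid`` counts sub-grid cells (default 0.05 Å) whose centers lie
    inside any disk; ``monte_carlo`` rejection-samples the bounding box and
    reports a standard error.  Both converge to the true union area and are
    independent of the rough-circle stamping path.
    """
    centers = np.atleast_2d(np.asarray(centers2d, dtype=float))
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (centers.shape[0],)).copy()
    if centers.shape[0] == 0:
        raise ValueError("need at least one disk")
    if (radii <= 0).any():
        raise ValueError("radii must be positive")
    lo = (centers - radii[:, None]).min(axis=0)
    hi = (centers + radii[:, None]).max(axis=0)

    if method == "fine_grid":
        nx, ny = (np.ceil((hi - lo) / cell).astype(int) + 1)
        filled = np.zeros((nx, ny), dtype=bool)
        xs = lo[0] + (np.arange(nx) + 0.5) * cell
        ys = lo[1] + (np.arange(ny) + 0.5) * cell
        for (cx, cy), r in zip(centers, radii):
            i0 = max(int((cx - r - lo[0]) / cell) - 1, 0)
            i1 = min(int((cx + r - lo[0]) / cell) + 2, nx)
            j0 = max(int((cy - r - lo[1]) / cell) - 1, 0)
            j1 = min(int((cy + r - lo[1]) / cell) + 2, ny)
            dx2 = (xs[i0:i1] - cx) ** 2
            dy2 = (ys[j0:j1] - cy) ** 2
            filled[i0:i1, j0:j1] |= dx2[:, None] + dy2[None, :] <= r * r
        return UnionArea(area=float(filled.sum()) * cell * cell)

    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        box_area = float(np.prod(hi - lo))
        pts = rng.uniform(lo, hi, size=(n_probes, 2))
        inside = np.zeros(n_probes, dtype=bool)
        for (cx, cy), r in zip(centers, radii):
            inside |= (pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2 <= r * r
        p = inside.mean()
        return UnionArea(area=box_area * float(p),
                         stderr=box_area * float(np.sqrt(p * (1 - p) / n_probes)))

    raise ValueError("method must be 'fine_grid' or 'monte_carlo'")


def pa_ccs_oracle(model: StructureModel, gas: str = "nitrogen",
                  rotations: int = DEFAULT_ROTATIONS,
                  seed: int | np.random.Generator = 0,
                  cell: float = 0.05,
                  table: RadiusTable | None = None) -> CCSResult:
    """Full-disk projection-approximation CCS (exact union-of-disks areas).

    Identical rotation/projection protocol to :func:`parcs.core.compute_ccs`
    — same rotation stream for the same seed — but each projection area is
    the exact area of the union of full disks rather than the 9-point stamp.
    Serves as the independent reference the grid estimator is benchmarked
    against.
    """
    if rotations < 1:
        raise ValueError("rotations must be >= 1")
    radii = assign_radii(model, gas=gas, table=table)
    coords = model.coordinates()
    centered = coords - coords.mean(axis=0)
    mats = rotation_matrices(rotations, seed)
    plane_axes = ((0, 1), (0, 2), (1, 2))
    areas = np.empty(3 * rotations)
    for i, mat in enumerate(mats):
        rotated = centered @ mat.T
        for j, axes in enumerate(plane_axes):
            areas[3 * i + j] = union_disk_area_oracle(
                rotated[:, axes], radii, method="fine_grid", cell=cell).area
    return CCSResult(ccs=float(areas.mean()), areas=areas, rotations=rotations,
                     seed=seed if isinstance(seed, int) else None, gas=gas,
                     cell_side=cell, pad=0.0,
                     rotation_fingerprint=rotation_digest(mats))
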