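"""Prediction-quality metrics: RMSD, TM-Score, Rg, funnel quality, neighbor count.

These are the readouts used to judge whether restrained model selection
actually picked a more native-like structure: Cα superposition RMSD and
TM-Score against the reference, radius of gyration and per-residue neighbor
counts as compactness/burial measures, and the Boltzmann funnel metric
P_near which asks whether low energies coincide with low RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import logsumexp

from .structure_io import StructureModel


@dataclass(frozen=True)
class FunnelParams:
    """Boltzmann funnel parameters: kT in score units, lambda in Å."""

    kT: float = 10.0
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.kT <= 0 or self.lam <= 0:
            raise ValueError("kT and lambda must be strictly positive")


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimizing ||(P @ R.T + t) - Q||."""
    Pc, Qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - Pc).T @ (Q - Qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Qc - R @ Pc
    return R, t


def superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Coordinates of ``mobile`` after least-squares rigid fit onto ``target``."""
    R, t = _kabsch(mobile, target)
    return mobile @ R.T + t


def rmsd_ca(model: StructureModel, reference: StructureModel) -> float:
    """Global Cα RMSD after optimal rigid superposition (Å)."""
    P, Q = model.ca_coordinates(), reference.ca_coordinates()
    if P.shape != Q.shape:
        raise ValueError(f"Cα count mismatch: {P.shape[0]} vs {Q.shape[0]}")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 Cα atoms for superposition")
    fitted = superpose(P, Q)
    return float(np.sqrt(((fitted - Q) ** 2).sum(axis=1).mean()))


def _tm_d0(L: int) -> float:
    # small-chain floor: the cube-root formula goes nonpositive below L=19
    if L < 16:
        return 0.5
    return max(1.24 * (L - 15) ** (1.0 / 3.0) - 1.8, 0.5)


def tm_score(model: StructureModel, reference: StructureModel,
             max_iter: int = 20) -> float:
    """Length-normalized topological similarity in [0, 1].

    TM = max over superpositions of (1/L) Σ 1/(1 + (d_i/d0)²) with
    d0 = 1.24 (L−15)^{1/3} − 1.8, residues paired by ordinal.  The maximum is
    searched with the standard heuristic: rigid fits seeded from contiguous
    fragments of lengths L, L/2, L/4 (≥4), each refined by iteratively
    re-fitting on the residue subset currently within a distance cutoff.
    Scores above 0.5 indicate the same fold; random unrelated chains score
    below about 0.17.
    """
    P, Q = model.ca_coordinates(), reference.ca_coordinates()
    if P.shape != Q.shape:
        raise ValueError(f"Cα count mismatch: {P.shape[0]} vs {Q.shape[0]}")
    L = Q.shape[0]
    d0 = _tm_d0(L)

    def score_from(R: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
        d2 = (((P @ R.T + t) - Q) ** 2).sum(axis=1)
        return float((1.0 / (1.0 + d2 / d0 ** 2)).mean()), d2

    best = 0.0
    frag_lens = sorted({L, max(L // 2, 4), max(L // 4, 4)}, reverse=True)
    for flen in frag_lens:
        step = max((L - flen) // 8, 1)
        for start in range(0, L - flen + 1, step):
            sel = np.arange(start, start + flen)
            for _ in range(max_iter):
                R, t = _kabsch(P[sel], Q[sel])
                tm, d2 = score_from(R, t)
                best = max(best, tm)
                d_cut = d0
                new_sel = np.flatnonzero(d2 < d_cut ** 2)
                while new_sel.size < 3:
                    d_cut += 0.5
                    new_sel = np.flatnonzero(d2 < d_cut ** 2)
                if new_sel.size == sel.size and (new_sel == sel).all():
                    break
                sel = new_sel
    return best


def radius_of_gyration(model: StructureModel, mass_weighted: bool = False) -> float:
    """Root-mean-square distance of heavy atoms from their centroid (Å).

    Unweighted by default; ``mass_weighted`` switches to atomic-mass weights.
    """
    heavy = [a for a in model.atoms if a.element != "H"]
    if not heavy:
        raise ValueError("no heavy atoms in selection")
    xyz = np.array([a.coords for a in heavy])
    if mass_weighted:
        masses = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974}
        w = np.array([masses.get(a.element, 12.011) for a in heavy])
    else:
        w = np.ones(len(heavy))
    center = (xyz * w[:, None]).sum(axis=0) / w.sum()
    return float(np.sqrt((w * ((xyz - center) ** 2).sum(axis=1)).sum() / w.sum()))


def rg_rank(table: pd.DataFrame) -> pd.DataFrame:
    """Rank models by compactness (smallest Rg first; ties by model_id)."""
    if len(table) == 0:
        raise ValueError("empty table")
    df = table[["model_id", "rg"]].copy()
    df = df.sort_values(["rg", "model_id"], kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def p_near(scores, rmsds, params: FunnelParams = FunnelParams()) -> float:
    """Boltzmann-weighted funnel quality in [0, 1].

    P_near = Σ exp(−rmsd²/λ²) exp(−E/kT) / Σ exp(−E/kT), evaluated in log
    space after shifting energies by their minimum (the metric is invariant
    to a constant energy shift).
    """
    E = np.asarray(scores, dtype=float)
    r = np.asarray(rmsds, dtype=float)
    if E.shape != r.shape or E.ndim != 1 or E.size == 0:
        raise ValueError("scores and rmsds must be equal-length 1-D arrays")
    logw = -(E - E.min()) / params.kT
    return float(np.exp(logsumexp(logw - r ** 2 / params.lam ** 2) - logsumexp(logw)))


def _representative_coords(model: StructureModel) -> np.ndarray:
    """Cβ coordinate per residue (Cα for glycine / Cβ-less residues)."""
    by_res: dict[tuple[str, int], dict[str, tuple]] = {}
    for a in model.atoms:
        by_res.setdefault((a.chain_id, a.residue_index), {})[a.name] = a.coords
    reps = []
    for key in sorted(by_res):
        names = by_res[key]
        if "CB" in names:
            reps.append(names["CB"])
        elif "CA" in names:
            reps.append(names["CA"])
        else:
            raise ValueError(f"residue {key} has neither CB nor CA")
    return np.array(reps)


def neighbor_count(model: StructureModel, radius: float = 10.0) -> np.ndarray:
    """Per-residue count of other residues within ``radius`` Å (sphere method).

    Distances are between residue representative atoms (Cβ; Cα for glycine).
    """
    reps = _representative_coords(model)
    tree = cKDTree(reps)
    counts = np.array([len(tree.query_ball_point(p, radius)) - 1 for p in reps])
    return counts


def surface_residues(model: StructureModel, percent: float = 20.0,
                     radius: float = 10.0) -> np.ndarray:
    """Indices of the lowest-neighbor-count ``percent`` of residues.

    Low neighbor count approximates solvent exposure; ties at the cutoff
    break by residue order so the selection is deterministic.
    """
    if not 0 < percent <= 100:
        raise ValueError("percent must be in (0, 100]")
    nc = neighbor_count(model, radius)
    k = max(int(round(len(nc) * percent / 100)), 1)
    order = np.argsort(nc, kind="stable")
    return np.sort(order[:k])
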