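"""Mechanical stiffness from an anisotropic network model (ANM).

A Cα bead network with uniform springs of constant ``gamma`` between
residues within a distance cutoff.  The 3n x 3n Hessian has the usual
super-element structure (off-diagonal block ``-gamma r_ij r_ij^T /
|r_ij|^2`` for contacting pairs, diagonal blocks minus the row sums).
The effective spring constant felt between residues i and j under a
stretching perturbation along their separation vector is the inverse
compliance

    C_ij = sum_k (1 / lambda_k) [ (u_k[j] - u_k[i]) . r_hat_ij ]^2
    k_eff(i, j) = 1 / C_ij

summed over all non-zero normal modes.  Stiff, densely packed modules
show large k_eff; soft modules show small k_eff.  Per-domain summaries
bin each residue's mean pairwise constant into soft / moderate / stiff
ranges (defaults k < 12, 12 <= k < 15, k >= 15 in units of gamma).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "ANMModel",
    "StiffnessProfile",
    "build_anm",
    "effective_stiffness",
    "pairwise_stiffness_matrix",
    "stiffness_profile",
    "load_ca_coords",
]


@dataclasses.dataclass
class ANMModel:
    """Elastic network with its eigendecomposition."""

    coords: np.ndarray  # (n, 3) Angstrom
    cutoff: float
    gamma: float
    eigenvalues: np.ndarray  # ascending
    eigenvectors: np.ndarray  # (3n, 3n), columns match eigenvalues
    n_zero: int

    @property
    def n_residues(self) -> int:
        return int(self.coords.shape[0])

    @property
    def zero_tol(self) -> float:
        return 1e-8 * float(self.eigenvalues[-1])


def _hessian(coords: np.ndarray, cutoff: float, gamma: float) -> np.ndarray:
    n = coords.shape[0]
    diff = coords[:, None, :] - coords[None, :, :]
    dist2 = np.sum(diff**2, axis=-1)
    contact = (dist2 <= cutoff**2) & ~np.eye(n, dtype=bool)
    H = np.zeros((3 * n, 3 * n))
    ii, jj = np.nonzero(np.triu(contact, k=1))
    for i, j in zip(ii, jj):
        d = diff[i, j]
        block = -gamma * np.outer(d, d) / dist2[i, j]
        H[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
        H[3 * j:3 * j + 3, 3 * i:3 * i + 3] = block
        H[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        H[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    return H


def build_anm(coords, cutoff: float = 15.0, gamma: float = 1.0) -> ANMModel:
    """Construct the network and diagonalize its Hessian.

    Requires at least 3 residues, finite coordinates and a connected
    contact graph at the given cutoff (the error names the fragment
    sizes otherwise).  Zero modes are eigenvalues below ``1e-8`` of the
    largest; a generic connected 3-D structure has exactly six.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must have shape (n, 3)")
    n = coords.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 residues, got {n}")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    if cutoff <= 0 or gamma <= 0:
        raise ValueError("cutoff and gamma must be positive")

    dist = squareform(pdist(coords))
    adj = (dist <= cutoff) & ~np.eye(n, dtype=bool)
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels).tolist()
        raise ValueError(
            f"contact graph disconnected at cutoff {cutoff} A: "
            f"{n_comp} components of sizes {sizes}"
        )
    H = _hessian(coords, cutoff, gamma)
    evals, evecs = np.linalg.eigh(H)
    tol = 1e-8 * float(evals[-1])
    n_zero = int(np.sum(np.abs(evals) < tol))
    return ANMModel(coords, float(cutoff), float(gamma), evals, evecs, n_zero)


def effective_stiffness(model: ANMModel, i: int, j: int) -> float:
    """Effective spring constant between residues ``i`` and ``j``.

    Symmetric, positive, and invariant under rigid rotation and
    translation of the coordinates.  Modes with eigenvalues below the
    zero tolerance (rigid-body and any degenerate bending modes) are
    excluded from the compliance sum.
    """
    n = model.n_residues
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"residue indices out of range 0..{n - 1}")
    if i == j:
        raise ValueError("effective stiffness requires i != j")
    rij = model.coords[j] - model.coords[i]
    rhat = rij / np.linalg.norm(rij)
    tol = model.zero_tol
    mask = model.eigenvalues > tol
    U = model.eigenvectors[:, mask]
    du = U[3 * j:3 * j + 3, :] - U[3 * i:3 * i + 3, :]
    proj = du.T @ rhat
    compliance = float(np.sum(proj**2 / model.eigenvalues[mask]))
    return 1.0 / compliance


def pairwise_stiffness_matrix(model: ANMModel) -> np.ndarray:
    """k_eff for every residue pair, shape (n, n); the diagonal is nan.

    Vectorized over modes; cost grows as n^3, comfortable up to a few
    hundred residues.
    """
    n = model.n_residues
    tol = model.zero_tol
    mask = model.eigenvalues > tol
    lam = model.eigenvalues[mask]
    U = model.eigenvectors[:, mask].reshape(n, 3, -1)  # (n, 3, m)

    diff = model.coords[None, :, :] - model.coords[:, None, :]
    dist = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(dist, 1.0)
    rhat = diff / dist[:, :, None]

    C = np.zeros((n, n))
    for k in range(lam.size):
        w = U[:, :, k]  # (n, 3)
        dw = w[None, :, :] - w[:, None, :]  # (n, n, 3)
        proj = np.einsum("ija,ija->ij", dw, rhat)
        C += proj**2 / lam[k]
    np.fill_diagonal(C, np.nan)
    K = 1.0 / C
    return K


@dataclasses.dataclass
class StiffnessProfile:
    """Per-residue constants plus per-domain bin fractions."""

    per_residue: np.ndarray  # mean pairwise k_eff per residue
    domain_fractions: pd.DataFrame  # columns soft/moderate/stiff + n_residues + valid
    thresholds: tuple[float, float]
    gamma: float
    note: str = (
        "effective spring constants are in units of the uniform ANM force "
        "constant gamma; bin thresholds depend on gamma and on the "
        "mean-over-partners averaging convention"
    )


def stiffness_profile(
    model: ANMModel,
    domain_labels,
    protected_mask=None,
    thresholds: tuple[float, float] = (12.0, 15.0),
) -> StiffnessProfile:
    """Per-domain soft/moderate/stiff composition.

    ``domain_labels`` assigns every residue to a module; residues where
    ``protected_mask`` is true (e.g. inside an IgC2 disulfide loop,
    which never feels the stretching force) are excluded from their
    domain's bin counts.  A fully masked domain yields nan fractions
    and ``valid=False`` rather than silent zeros.
    """
    labels = np.asarray(domain_labels)
    n = model.n_residues
    if labels.shape[0] != n:
        raise ValueError(f"domain_labels length {labels.shape[0]} != {n} residues")
    if protected_mask is None:
        protected_mask = np.zeros(n, dtype=bool)
    protected_mask = np.asarray(protected_mask, dtype=bool)
    if protected_mask.shape[0] != n:
        raise ValueError("protected_mask length mismatch")

    K = pairwise_stiffness_matrix(model)
    per_res = np.nanmean(K, axis=1)
    t1, t2 = thresholds
    rows = []
    for dom in pd.unique(labels):
        sel = (labels == dom) & ~protected_mask
        m = int(sel.sum())
        if m == 0:
            rows.append({"domain": dom, "soft": np.nan, "moderate": np.nan,
                         "stiff": np.nan, "n_residues": 0, "valid": False})
            continue
        k = per_res[sel]
        rows.append({
            "domain": dom,
            "soft": float(np.mean(k < t1)),
            "moderate": float(np.mean((k >= t1) & (k < t2))),
            "stiff": float(np.mean(k >= t2)),
            "n_residues": m,
            "valid": True,
        })
    frac = pd.DataFrame(rows, columns=["domain", "soft", "moderate", "stiff",
                                       "n_residues", "valid"])
    return StiffnessProfile(per_res, frac, thresholds, model.gamma)


def load_ca_coords(pdb_path: str | Path, chain: str | None = None) -> np.ndarray:
    """Cα coordinates (Angstrom) from a PDB file.

    ``chain`` selects one chain; insertion codes are rejected with a
    message since they make the residue numbering ambiguous.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(pdb_path))
    coords = []
    for model in structure:
        for ch in model:
            if chain is not None and ch.id != chain:
                continue
            for res in ch:
                if "CA" not in res:
                    continue
                het, _, icode = res.id
                if icode.strip():
                    raise ValueError(
                        f"{pdb_path}: insertion code {icode!r} at residue {res.id} "
                        "not supported; renumber the structure first"
                    )
                if het.strip():
                    continue
                coords.append(res["CA"].coord)
        break  # first model only
    if not coords:
        raise ValueError(f"{pdb_path}: no Cα atoms found"
                         + (f" in chain {chain!r}" if chain else ""))
    return np.asarray(coords, dtype=float)
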