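"""Geometric primitives on ensemble coordinates.

Least-squares (Kabsch) superposition, pairwise CA RMSD matrices, backbone
φ/ψ dihedrals, heavy-atom residue contacts and per-residue RMSF.  All
distances are in nm, all angles in radians.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import ConformationalEnsemble, RegionSet, Topology

#: default heavy-atom contact cut-off in nm
CONTACT_CUTOFF = 0.45
#: minimum |res_i - res_j| for a pair to count as a contact
MIN_SEQ_SEP = 2


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def _check_selection(x: np.ndarray, name: str) -> None:
    if x.shape[0] < 3:
        raise ValueError(f"{name}: need at least 3 atoms for superposition")
    centered = x - x.mean(axis=0)
    # rank < 2 means collinear/degenerate: rotation not unique
    if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
        raise ValueError(f"{name}: selection is collinear/degenerate")


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid-body fit of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimises the RMSD over the
    selection.  The rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if selection is not None:
        m, r = mobile[selection], reference[selection]
    else:
        m, r = mobile, reference
    if m.shape != r.shape:
        raise ValueError("mobile and reference selections differ in size")
    _check_selection(m, "mobile")
    _check_selection(r, "reference")
    mc, rc = m.mean(axis=0), r.mean(axis=0)
    X, Y = m - mc, r - rc
    H = X.T @ Y
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    translation = rc - R @ mc
    fitted = X @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - Y) ** 2, axis=1))))
    return R, translation, rmsd


@dataclass(frozen=True)
class RmsdMatrix:
    """Symmetric matrix of pairwise, per-pair-superposed CA RMSD (nm)."""

    values: np.ndarray
    atom_indices: np.ndarray
    region: str | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RMSD matrix must be square")
        if np.abs(np.diagonal(v)).max(initial=0.0) > 1e-9:
            raise ValueError("RMSD matrix diagonal must be zero")
        if np.abs(v - v.T).max(initial=0.0) > 1e-9:
            raise ValueError("RMSD matrix must be symmetric")
        if v.min(initial=0.0) < 0:
            raise ValueError("RMSD values must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def submatrix(self, frame_indices: np.ndarray) -> "RmsdMatrix":
        sub = self.values[np.ix_(frame_indices, frame_indices)]
        return RmsdMatrix(values=sub, atom_indices=self.atom_indices,
                          region=self.region)


def pairwise_rmsd(coords: np.ndarray, chunk: int = 2000) -> np.ndarray:
    """All-pairs minimum RMSD over rigid transforms, batched Kabsch.

    ``coords`` is (n_frames, n_atoms, 3).  Uses the identity
    rmsd²(i,j) = (G_i + G_j - 2 Σ_k σ_k±) / n_atoms with σ the singular
    values of the cross-covariance, the last one sign-flipped for improper
    optima.
    """
    X = np.asarray(coords, dtype=float)
    F, a, _ = X.shape
    Xc = X - X.mean(axis=1, keepdims=True)
    G = np.einsum("fai,fai->f", Xc, Xc)
    out = np.zeros((F, F))
    for i in range(F - 1):
        rest = Xc[i + 1:]
        # process the row in chunks to bound the batched-SVD workspace
        for s in range(0, rest.shape[0], chunk):
            block = rest[s:s + chunk]
            H = np.einsum("ak,nal->nkl", Xc[i], block)
            sv = np.linalg.svd(H, compute_uv=False)
            sign = np.sign(np.linalg.det(H))
            sign[sign == 0] = 1.0
            trace = sv[:, 0] + sv[:, 1] + sign * sv[:, 2]
            msd = (G[i] + G[i + 1 + s:i + 1 + s + block.shape[0]] - 2.0 * trace) / a
            row = np.sqrt(np.maximum(msd, 0.0))
            out[i, i + 1 + s:i + 1 + s + block.shape[0]] = row
    out += out.T
    return out


def rmsd_matrix(
    ensemble: ConformationalEnsemble,
    regions: RegionSet | None = None,
    region: str | None = None,
) -> RmsdMatrix:
    """Pairwise CA RMSD matrix on a region's CA atoms (fit-on-self).

    Each pair is superposed on the same CA set used for the RMSD, matching
    the behaviour of trajectory clustering tools.
    """
    topo = ensemble.topology
    if region is not None:
        if regions is None:
            raise ValueError("a RegionSet is required when region is named")
        residues = regions.residues(region)
    else:
        residues = None
    ca = topo.ca_indices(residues)
    if len(ca) < 3:
        raise ValueError(
            f"region {region!r} has {len(ca)} CA atoms; need at least 3"
        )
    values = pairwise_rmsd(ensemble.frames[:, ca, :])
    return RmsdMatrix(values=values, atom_indices=ca, region=region)


# ---------------------------------------------------------------------------
# Dihedrals
# ---------------------------------------------------------------------------

def dihedral_angle(p0, p1, p2, p3) -> np.ndarray:
    """Signed torsion angle of the bond p1–p2, IUPAC sign convention.

    Accepts stacked arrays (..., 3); returns radians in [-π, π].
    """
    b1 = np.asarray(p1) - np.asarray(p0)
    b2 = np.asarray(p2) - np.asarray(p1)
    b3 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    m1 = np.cross(b2n, n1)
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", m1, n2)
    return np.arctan2(y, x)


def backbone_dihedrals(
    ensemble: ConformationalEnsemble,
    regions: RegionSet | None = None,
    region: str | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame φ/ψ backbone dihedrals for the region's residues.

    Returns ``(residue_ids, phi, psi)`` with angle arrays of shape
    (n_frames, n_residues); undefined angles (chain termini, missing
    backbone atoms, non-consecutive neighbours) are NaN.

    φ_i is the torsion C(i−1)–N(i)–CA(i)–C(i); ψ_i is N(i)–CA(i)–C(i)–N(i+1).
    """
    topo = ensemble.topology
    if region is not None:
        if regions is None:
            raise ValueError("a RegionSet is required when region is named")
        residues = regions.residues(region)
    else:
        residues = topo.residue_ids

    atom_idx: dict[tuple[int, str], int] = {}
    for i, (rid, name) in enumerate(zip(topo.res_id, topo.atom_name)):
        atom_idx.setdefault((int(rid), name), i)

    F = ensemble.n_frames
    frames = ensemble.frames
    phi = np.full((F, len(residues)), np.nan)
    psi = np.full((F, len(residues)), np.nan)
    for k, rid in enumerate(residues):
        rid = int(rid)
        n = atom_idx.get((rid, "N"))
        ca = atom_idx.get((rid, "CA"))
        c = atom_idx.get((rid, "C"))
        if n is None or ca is None or c is None:
            warnings.warn(f"residue {rid}: missing backbone atom; dihedrals undefined")
            continue
        c_prev = atom_idx.get((rid - 1, "C"))
        if c_prev is not None:
            phi[:, k] = dihedral_angle(
                frames[:, c_prev], frames[:, n], frames[:, ca], frames[:, c]
            )
        n_next = atom_idx.get((rid + 1, "N"))
        if n_next is not None:
            psi[:, k] = dihedral_angle(
                frames[:, n], frames[:, ca], frames[:, c], frames[:, n_next]
            )
    return np.asarray(residues, dtype=int), phi, psi


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

def _region_heavy_atoms(topo: Topology, residues: np.ndarray):
    idx = topo.heavy_indices(residues)
    if idx.size == 0:
        raise ValueError("region contains no heavy atoms")
    rids = topo.res_id[idx]
    unique = np.asarray(residues, dtype=int)
    pos = {int(r): k for k, r in enumerate(unique)}
    res_pos = np.array([pos[int(r)] for r in rids])
    return idx, res_pos, unique


def contact_trajectory(
    ensemble_or_frames,
    topology: Topology | None = None,
    regions: RegionSet | None = None,
    region_a: str = "CDR3",
    region_b: str = "CDR3",
    cutoff: float = CONTACT_CUTOFF,
    min_seq_sep: int = MIN_SEQ_SEP,
    chunk_atoms: int = 20_000_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame boolean residue-contact matrices between two regions.

    A residue pair is in contact when any inter-residue heavy-atom distance
    is strictly below ``cutoff`` and the sequence separation is at least
    ``min_seq_sep``.  Returns ``(contacts, residues_a, residues_b)`` with
    contacts of shape (n_frames, n_res_a, n_res_b).
    """
    if isinstance(ensemble_or_frames, ConformationalEnsemble):
        frames = ensemble_or_frames.frames
        topo = ensemble_or_frames.topology
    else:
        frames = np.asarray(ensemble_or_frames, dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        topo = topology
    if topo is None:
        raise ValueError("a topology is required")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if regions is None:
        raise ValueError("a RegionSet is required")

    res_a = regions.residues(region_a)
    res_b = regions.residues(region_b)
    ia, pa, ua = _region_heavy_atoms(topo, res_a)
    ib, pb, ub = _region_heavy_atoms(topo, res_b)
    Ma = np.zeros((len(ia), len(ua)), dtype=np.float32)
    Ma[np.arange(len(ia)), pa] = 1.0
    Mb = np.zeros((len(ib), len(ub)), dtype=np.float32)
    Mb[np.arange(len(ib)), pb] = 1.0
    sep_ok = np.abs(ua[:, None] - ub[None, :]) >= min_seq_sep

    F = frames.shape[0]
    out = np.empty((F, len(ua), len(ub)), dtype=bool)
    per_frame = len(ia) * len(ib)
    step = max(1, chunk_atoms // per_frame)
    c2 = cutoff * cutoff
    A = np.ascontiguousarray(frames[:, ia, :], dtype=np.float32)
    B = np.ascontiguousarray(frames[:, ib, :], dtype=np.float32)
    for s in range(0, F, step):
        a = A[s:s + step]
        b = B[s:s + step]
        d2 = np.sum((a[:, :, None, :] - b[:, None, :, :]) ** 2, axis=-1)
        close = (d2 < c2).astype(np.float32)
        counts = np.einsum("ar,fab,bs->frs", Ma, close, Mb)
        out[s:s + step] = (counts > 0.5) & sep_ok
    return out, ua, ub


def residue_contacts(
    frame: np.ndarray,
    topology: Topology,
    regions: RegionSet,
    region_a: str,
    region_b: str,
    cutoff: float = CONTACT_CUTOFF,
    min_seq_sep: int = MIN_SEQ_SEP,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single-frame residue contact matrix; see :func:`contact_trajectory`."""
    contacts, ua, ub = contact_trajectory(
        frame[None], topology, regions, region_a, region_b, cutoff, min_seq_sep
    )
    return contacts[0], ua, ub


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------

def _batched_superpose_onto(frames: np.ndarray, reference: np.ndarray,
                            fit_idx: np.ndarray) -> np.ndarray:
    """Rigid-fit every frame onto ``reference`` using the fit atom set."""
    X = frames[:, fit_idx, :]
    Y = reference[fit_idx]
    xm = X.mean(axis=1, keepdims=True)
    ym = Y.mean(axis=0)
    H = np.einsum("fak,al->fkl", X - xm, Y - ym)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    d[d == 0] = 1.0
    D = np.zeros_like(H)
    D[:, 0, 0] = D[:, 1, 1] = 1.0
    D[:, 2, 2] = d
    Rt = U @ D @ Vt  # row-vector form: x' = x @ R^T with R = Vt^T D U^T
    return (frames - xm) @ Rt + ym


def rmsf(
    ensemble: ConformationalEnsemble,
    weights: np.ndarray | None = None,
    regions: RegionSet | None = None,
    region: str | None = None,
    fit_region: str = RegionSet.SCAFFOLD,
    n_iterations: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted per-residue CA root-mean-square fluctuation (nm).

    Frames are superposed onto the weighted mean structure (the fit is
    iterated, recomputing the mean) using the fit region's CA atoms, then
    RMSF_r = sqrt(Σ_i w_i |x_i,r − ⟨x_r⟩|²) is taken over each residue's CA.
    Returns ``(residue_ids, rmsf)``.
    """
    topo = ensemble.topology
    w = np.asarray(weights if weights is not None else ensemble.effective_weights(),
                   dtype=float)
    w = w / w.sum()
    if regions is not None:
        fit_idx = topo.ca_indices(regions.residues(fit_region))
        residues = regions.residues(region) if region is not None else topo.residue_ids
    else:
        fit_idx = topo.ca_indices()
        residues = topo.residue_ids
    ca = topo.ca_indices(residues)
    if ensemble.n_frames < 2:
        warnings.warn("RMSF of a single frame is identically zero")
        return np.asarray(residues, dtype=int), np.zeros(len(ca))

    frames = ensemble.frames
    mean = np.einsum("f,fai->ai", w, frames)
    for _ in range(n_iterations):
        frames = _batched_superpose_onto(ensemble.frames, mean, fit_idx)
        mean = np.einsum("f,fai->ai", w, frames)
    dev2 = np.sum((frames[:, ca, :] - mean[ca]) ** 2, axis=2)
    msf = np.einsum("f,fr->r", w, dev2)
    return np.asarray(residues, dtype=int), np.sqrt(msf)
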