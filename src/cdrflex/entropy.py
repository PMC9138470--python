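"""Information entropies of conformational ensembles.

Two entropy notions are used to quantify conformational heterogeneity:

* cluster entropy  S = −Σ_i p_i ln p_i  over normalised cluster populations,
* dihedral (Ramachandran) entropy  S = −Σ_ij p_ij ln p_ij  over a normalised
  2D histogram of a residue's (φ, ψ) angles.

Both are reported in nats.  Uncertainty on the cluster entropy comes from a
weighted bootstrap: samples of frames are drawn with replacement with
probability equal to the statistical weights, each sample is clustered
independently, and the 95th-percentile band of the per-sample entropies is
reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .clustering import gromos_cluster
from .geometry import RmsdMatrix, backbone_dihedrals, rmsd_matrix
from .io import ConformationalEnsemble, RegionSet

#: default bins per dimension of the (φ, ψ) histogram (100×100 grid)
BINS_PER_DIM = 100


def cluster_entropy(populations) -> float:
    """Shannon entropy −Σ p_i ln p_i (nats) of normalised populations.

    Zero-population clusters contribute nothing (0·ln 0 := 0).
    """
    p = np.asarray(populations, dtype=float)
    if p.size == 0:
        raise ValueError("empty population vector")
    if np.any(p < 0):
        raise ValueError("populations must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"populations sum to {p.sum():.8f}, expected 1 within 1e-6")
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def dihedral_entropy(
    phi: np.ndarray,
    psi: np.ndarray,
    weights=None,
    bins_per_dim: int = BINS_PER_DIM,
) -> float:
    """Entropy (nats) of the weighted 2D (φ, ψ) histogram on [−π, π]².

    Frames where either angle is undefined (NaN) are dropped and the weights
    renormalised; if no frame has both angles the result is NaN (missing).
    """
    phi = np.asarray(phi, dtype=float).ravel()
    psi = np.asarray(psi, dtype=float).ravel()
    if phi.shape != psi.shape:
        raise ValueError("phi and psi must have the same length")
    w = (np.full(len(phi), 1.0 / max(len(phi), 1))
         if weights is None else np.asarray(weights, dtype=float).ravel())
    if w.shape != phi.shape:
        raise ValueError("weights length must match the angle arrays")
    ok = np.isfinite(phi) & np.isfinite(psi)
    if not ok.any():
        return float("nan")
    edges = np.linspace(-np.pi, np.pi, bins_per_dim + 1)
    hist, _, _ = np.histogram2d(phi[ok], psi[ok], bins=(edges, edges),
                                weights=w[ok])
    p = hist / hist.sum()
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


@dataclass(frozen=True)
class DihedralEntropyProfile:
    """Per-residue Ramachandran entropies for one region."""

    residue_ids: np.ndarray
    entropies: np.ndarray        # NaN where φ or ψ undefined for all frames
    bins_per_dim: int
    region: str | None

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# region {self.region}  bins_per_dim {self.bins_per_dim}\n")
            fh.write("residue\tentropy_nats\n")
            for rid, s in zip(self.residue_ids, self.entropies):
                fh.write(f"{rid}\t{'NA' if np.isnan(s) else f'{s:.6f}'}\n")


def dihedral_entropy_profile(
    ensemble: ConformationalEnsemble,
    regions: RegionSet | None = None,
    region: str | None = None,
    weights=None,
    bins_per_dim: int = BINS_PER_DIM,
) -> DihedralEntropyProfile:
    """Ramachandran entropy for every residue of a region."""
    rids, phi, psi = backbone_dihedrals(ensemble, regions, region)
    w = weights if weights is not None else ensemble.effective_weights()
    S = np.array([
        dihedral_entropy(phi[:, k], psi[:, k], w, bins_per_dim)
        for k in range(len(rids))
    ])
    return DihedralEntropyProfile(residue_ids=rids, entropies=S,
                                  bins_per_dim=bins_per_dim, region=region)


@dataclass(frozen=True)
class EntropyEstimate:
    """Cluster entropy with weighted-bootstrap uncertainty."""

    value: float                  # whole-ensemble entropy
    bootstrap_mean: float
    band: tuple[float, float]     # 95th-percentile interval of samples
    samples: np.ndarray           # per-sample entropies
    n_bootstrap: int
    frames_per_sample: int
    cutoff: float
    seed: int

    def write(self, path: str | Path) -> None:
        payload = {
            "entropy_nats": self.value,
            "bootstrap_mean_nats": self.bootstrap_mean,
            "band_95_nats": list(self.band),
            "samples": [float(s) for s in self.samples],
            "n_bootstrap": self.n_bootstrap,
            "frames_per_sample": self.frames_per_sample,
            "cutoff_nm": self.cutoff,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def bootstrap_cluster_entropy(
    ensemble: ConformationalEnsemble | None = None,
    regions: RegionSet | None = None,
    region: str | None = None,
    cutoff: float = 0.15,
    weights=None,
    n_samples: int = 20,
    frames_per_sample: int = 10_000,
    seed: int = 0,
    matrix: RmsdMatrix | None = None,
    mode: str = "recluster",
) -> EntropyEstimate:
    """Weighted-bootstrap estimate of the GROMOS cluster entropy.

    Each bootstrap sample draws ``frames_per_sample`` frames with replacement
    with probability equal to the statistical weights, then clusters the
    sample (uniform within-sample weights).  ``mode='recluster'`` re-runs
    GROMOS on the sliced RMSD submatrix of each sample; ``mode='map'`` is a
    fast approximation that reuses the whole-ensemble clustering and only
    recounts populations.

    The reported ``value`` is the whole-ensemble weighted entropy; the band
    is the [2.5, 97.5] percentile interval of the per-sample entropies.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 bootstrap samples")
    if frames_per_sample < 1:
        raise ValueError("frames_per_sample must be >= 1")
    if matrix is None:
        if ensemble is None:
            raise ValueError("either an ensemble or a precomputed matrix is required")
        matrix = rmsd_matrix(ensemble, regions, region)
    n = matrix.n_frames
    if weights is None:
        weights = (ensemble.effective_weights() if ensemble is not None
                   else np.full(n, 1.0 / n))
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()

    whole = gromos_cluster(matrix, cutoff, w)
    value = cluster_entropy(whole.populations)

    rng = np.random.default_rng(seed)
    samples = np.empty(n_samples)
    for s in range(n_samples):
        idx = rng.choice(n, size=frames_per_sample, replace=True, p=w)
        if mode == "recluster":
            sub = matrix.submatrix(idx)
            res = gromos_cluster(sub, cutoff)
            samples[s] = cluster_entropy(res.populations)
        elif mode == "map":
            labels = whole.assignment[idx]
            counts = np.bincount(labels, minlength=whole.n_clusters)
            samples[s] = cluster_entropy(counts / counts.sum())
        else:
            raise ValueError(f"unknown mode {mode!r}")
    lo, hi = np.percentile(samples, [2.5, 97.5])
    return EntropyEstimate(
        value=value, bootstrap_mean=float(samples.mean()),
        band=(float(lo), float(hi)), samples=samples,
        n_bootstrap=n_samples, frames_per_sample=frames_per_sample,
        cutoff=cutoff, seed=seed,
    )


def bootstrap_cluster_populations(
    assignment: np.ndarray,
    weights,
    n_samples: int = 20,
    frames_per_sample: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Per-sample cluster populations under the weighted bootstrap.

    Frames are resampled with probability = weights and populations recounted
    against the fixed whole-ensemble assignment.  Returns an array of shape
    (n_samples, n_clusters).
    """
    if n_samples < 2:
        raise ValueError("need at least 2 bootstrap samples")
    labels = np.asarray(assignment)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    k = labels.max() + 1
    rng = np.random.default_rng(seed)
    out = np.empty((n_samples, k))
    for s in range(n_samples):
        idx = rng.choice(len(labels), size=frames_per_sample, replace=True, p=w)
        counts = np.bincount(labels[idx], minlength=k)
        out[s] = counts / counts.sum()
    return out
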