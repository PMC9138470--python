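"""Contact-based collective variables, free-energy surfaces and contact maps.

The two collective variables characterising loop packing are the relative
proportions of (i) intra-CDR3 residue contacts and (ii) CDR3–scaffold
contacts, each normalised by the maximum contact count of that class
observed over the ensemble, so values lie in [0, 1].  The weighted 2D
histogram of the CVs gives a free-energy surface F = −kB T ln(p/p_max) in
kJ/mol, anchored so the occupied minimum is 0.  Contact-probability maps
report the weighted probability of each residue pair being in contact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import CONTACT_CUTOFF, MIN_SEQ_SEP, contact_trajectory
from .io import KB, ConformationalEnsemble, RegionSet


@dataclass(frozen=True)
class ContactCvSeries:
    """Per-frame (q_intra, q_scaffold) contact collective variables."""

    q_intra: np.ndarray          # intra-CDR3, in [0, 1]
    q_scaffold: np.ndarray       # CDR3–scaffold, in [0, 1]
    norm_intra: float            # ensemble-max raw contact counts
    norm_scaffold: float

    def as_array(self) -> np.ndarray:
        return np.column_stack([self.q_intra, self.q_scaffold])


def contact_cvs(
    ensemble: ConformationalEnsemble,
    regions: RegionSet,
    weights=None,
    cutoff: float = CONTACT_CUTOFF,
    loop_region: str = "CDR3",
    min_seq_sep: int = MIN_SEQ_SEP,
) -> ContactCvSeries:
    """Per-frame relative proportions of intra-loop and loop–scaffold contacts.

    Each frame's residue-pair contact count (within the loop; loop ×
    scaffold) is divided by the maximum count of that class over the
    ensemble.  A class with zero contacts in every frame is reported
    all-zero with a warning.
    """
    intra, _, _ = contact_trajectory(
        ensemble, regions=regions, region_a=loop_region, region_b=loop_region,
        cutoff=cutoff, min_seq_sep=min_seq_sep,
    )
    cross, _, _ = contact_trajectory(
        ensemble, regions=regions, region_a=loop_region,
        region_b=RegionSet.SCAFFOLD, cutoff=cutoff, min_seq_sep=min_seq_sep,
    )
    # intra-region matrices are symmetric: count unordered pairs
    n_intra = np.triu(intra, k=1).sum(axis=(1, 2)).astype(float)
    n_cross = cross.sum(axis=(1, 2)).astype(float)

    def _norm(counts: np.ndarray, label: str) -> tuple[np.ndarray, float]:
        m = counts.max()
        if m == 0:
            warnings.warn(f"no {label} contacts in any frame; CV is all-zero")
            return np.zeros_like(counts), 1.0
        return counts / m, float(m)

    q_intra, norm_i = _norm(n_intra, "intra-loop")
    q_cross, norm_c = _norm(n_cross, "loop-scaffold")
    return ContactCvSeries(q_intra=q_intra, q_scaffold=q_cross,
                           norm_intra=norm_i, norm_scaffold=norm_c)


@dataclass(frozen=True)
class FreeEnergySurface:
    """2D binned free energy over two CVs, kJ/mol, minimum at 0."""

    free_energy: np.ndarray      # (bins, bins); masked bins are NaN
    x_edges: np.ndarray
    y_edges: np.ndarray
    temperature: float

    @property
    def occupied(self) -> np.ndarray:
        return np.isfinite(self.free_energy)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# temperature_K {self.temperature}\n")
            fh.write("# x_edges " + " ".join(f"{e:.6g}" for e in self.x_edges) + "\n")
            fh.write("# y_edges " + " ".join(f"{e:.6g}" for e in self.y_edges) + "\n")
            for row in self.free_energy:
                fh.write("\t".join("NA" if np.isnan(v) else f"{v:.6f}"
                                   for v in row) + "\n")


def free_energy_surface(
    cvs: ContactCvSeries | np.ndarray,
    weights=None,
    bins: int = 50,
    temperature: float = 300.0,
    ranges=((0.0, 1.0), (0.0, 1.0)),
) -> FreeEnergySurface:
    """F = −kB T ln(p_bin / p_max) from the weighted 2D CV histogram.

    Empty bins are masked (NaN), never assigned F = 0; the occupied minimum
    is anchored at 0.
    """
    xy = cvs.as_array() if isinstance(cvs, ContactCvSeries) else np.asarray(cvs)
    if not np.all(np.isfinite(xy)):
        raise ValueError("collective variables contain non-finite values")
    n = xy.shape[0]
    w = (np.full(n, 1.0 / n) if weights is None
         else np.asarray(weights, dtype=float))
    w = w / w.sum()
    hist, xe, ye = np.histogram2d(xy[:, 0], xy[:, 1], bins=bins, range=ranges,
                                  weights=w)
    if hist.sum() == 0:
        raise ValueError("no frame falls inside the CV range")
    p = hist / hist.sum()
    F = np.full_like(p, np.nan)
    occ = p > 0
    F[occ] = -KB * temperature * np.log(p[occ] / p[occ].max())
    return FreeEnergySurface(free_energy=F, x_edges=xe, y_edges=ye,
                             temperature=temperature)


@dataclass(frozen=True)
class ContactProbabilityMap:
    """Weighted residue-pair contact probabilities in [0, 1]."""

    probabilities: np.ndarray
    residues_a: np.ndarray
    residues_b: np.ndarray
    region_a: str
    region_b: str
    cutoff: float

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# regions {self.region_a} x {self.region_b}  "
                     f"cutoff_nm {self.cutoff}\n")
            fh.write("residue\t" + "\t".join(str(r) for r in self.residues_b) + "\n")
            for rid, row in zip(self.residues_a, self.probabilities):
                fh.write(str(rid) + "\t" +
                         "\t".join(f"{v:.6f}" for v in row) + "\n")


def contact_probability_map(
    ensemble: ConformationalEnsemble,
    regions: RegionSet,
    region_a: str,
    region_b: str,
    weights=None,
    cutoff: float = CONTACT_CUTOFF,
    min_seq_sep: int = MIN_SEQ_SEP,
) -> ContactProbabilityMap:
    """Weighted probability of contact for every residue pair A × B."""
    contacts, ua, ub = contact_trajectory(
        ensemble, regions=regions, region_a=region_a, region_b=region_b,
        cutoff=cutoff, min_seq_sep=min_seq_sep,
    )
    n = contacts.shape[0]
    w = (np.full(n, 1.0 / n) if weights is None
         else np.asarray(weights, dtype=float))
    w = w / w.sum()
    prob = np.einsum("f,fab->ab", w, contacts.astype(float))
    return ContactProbabilityMap(probabilities=prob, residues_a=ua,
                                 residues_b=ub, region_a=region_a,
                                 region_b=region_b, cutoff=cutoff)


def state_population(
    cvs: ContactCvSeries | np.ndarray,
    weights=None,
    x_range: tuple[float, float] = (-np.inf, np.inf),
    y_range: tuple[float, float] = (-np.inf, np.inf),
) -> float:
    """Weighted population of a rectangular region of CV space.

    Bounds are inclusive; an empty selection returns 0 with a warning.
    """
    xy = cvs.as_array() if isinstance(cvs, ContactCvSeries) else np.asarray(cvs)
    n = xy.shape[0]
    w = (np.full(n, 1.0 / n) if weights is None
         else np.asarray(weights, dtype=float))
    w = w / w.sum()
    sel = ((xy[:, 0] >= x_range[0]) & (xy[:, 0] <= x_range[1])
           & (xy[:, 1] >= y_range[0]) & (xy[:, 1] <= y_range[1]))
    if not sel.any():
        warnings.warn("state selection contains no frames")
        return 0.0
    return float(w[sel].sum())
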