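"""Ground-truth synthetic ensembles for testing the full pipeline.

Frames are drawn from a small number of metastable basins.  Each basin is a
backbone template built from a φ/ψ dihedral profile with idealised bond
lengths and angles (N, CA, C, O atoms per residue), so that RMSD, dihedral
and heavy-atom-contact machinery all operate on well-defined geometry.  A
flexible loop segment (standing in for a CDR3) takes basin-specific
dihedrals while the rest of the chain — the scaffold — is shared across
basins.  Gaussian coordinate noise models intra-basin fluctuation.

Two sampling modes are supported:

* ``direct``: basins drawn with the target populations, no bias attached;
* ``reweight-to-target``: basins drawn uniformly, and each frame carries a
  bias V = kB T ln(target population of its basin) + constant, so that
  metadynamics reweighting recovers the targets.

Every generator takes an explicit seed and the ground truth (basin labels,
analytic entropies) is returned alongside the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import (KB, ConformationalEnsemble, RegionSet, Topology,
                 write_ensemble, write_regions)
from .reweighting import compute_weights

# idealised backbone geometry (nm / radians)
_BOND_N_CA = 0.1458
_BOND_CA_C = 0.1525
_BOND_C_N = 0.1329
_BOND_C_O = 0.1229
_ANGLE_N_CA_C = np.deg2rad(111.0)
_ANGLE_CA_C_N = np.deg2rad(116.6)
_ANGLE_C_N_CA = np.deg2rad(121.9)
_ANGLE_CA_C_O = np.deg2rad(120.5)
_OMEGA = np.pi  # trans peptide bond

# loose Ramachandran-like (φ, ψ) attractors used for template profiles
_RAMA_BASINS = np.array([
    [-1.05, -0.79],   # helix-like
    [-2.09, 2.27],    # sheet-like
    [-1.31, 2.62],    # polyproline-like
    [0.96, 0.35],     # left-handed helix-like
])


def _place_atom(a, b, c, bond, angle, torsion):
    """Next-atom placement from internal coordinates (NeRF construction).

    Returns D such that |C-D| = bond, angle(B,C,D) = angle and the torsion
    A-B-C-D equals ``torsion``.
    """
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Backbone coordinates (nm) from per-residue φ/ψ, 4 atoms per residue.

    Atom order per residue is N, CA, C, O.  φ of the first residue and ψ of
    the last residue are not encoded in the geometry (chain termini) but the
    arrays must still be full length.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if phi.shape != psi.shape or phi.ndim != 1:
        raise ValueError("phi and psi must be 1-D arrays of equal length")
    n_res = len(phi)
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    coords = np.empty((n_res, 4, 3))
    # seed the first residue in a fixed frame
    coords[0, 0] = np.array([0.0, 0.0, 0.0])                       # N
    coords[0, 1] = np.array([_BOND_N_CA, 0.0, 0.0])                # CA
    coords[0, 2] = coords[0, 1] + _BOND_CA_C * np.array(
        [np.cos(np.pi - _ANGLE_N_CA_C), np.sin(np.pi - _ANGLE_N_CA_C), 0.0]
    )                                                              # C
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = coords[i - 1, 0], coords[i - 1, 1], coords[i - 1, 2]
        n_i = _place_atom(n_prev, ca_prev, c_prev,
                          _BOND_C_N, _ANGLE_CA_C_N, psi[i - 1])
        ca_i = _place_atom(ca_prev, c_prev, n_i,
                           _BOND_N_CA, _ANGLE_C_N_CA, _OMEGA)
        c_i = _place_atom(c_prev, n_i, ca_i,
                          _BOND_CA_C, _ANGLE_N_CA_C, phi[i])
        coords[i, 0], coords[i, 1], coords[i, 2] = n_i, ca_i, c_i
    # carbonyl oxygens: torsion ψ+π from N; last residue uses a fixed stand-in ψ
    for i in range(n_res):
        psi_i = psi[i] if i < n_res - 1 else -0.7
        coords[i, 3] = _place_atom(coords[i, 0], coords[i, 1], coords[i, 2],
                                   _BOND_C_O, _ANGLE_CA_C_O, psi_i + np.pi)
    return coords.reshape(n_res * 4, 3)


def backbone_topology(n_residues: int) -> Topology:
    """Topology matching :func:`build_backbone` (all-ALA, N/CA/C/O atoms)."""
    names = np.tile(["N", "CA", "C", "O"], n_residues)
    elements = np.tile(["N", "C", "C", "O"], n_residues)
    res_id = np.repeat(np.arange(1, n_residues + 1), 4)
    return Topology(
        atom_name=names, element=elements, is_heavy=np.ones(4 * n_residues, bool),
        res_id=res_id, res_name=np.full(4 * n_residues, "ALA"),
        chain_id=np.full(4 * n_residues, "A"),
    )


@dataclass(frozen=True)
class SyntheticEnsembleSpec:
    """Full description of a multi-basin synthetic ensemble.

    ``populations`` are the target basin populations; ``noise_sigma`` the
    per-coordinate Gaussian noise in nm; ``min_separation`` the minimum
    loop-Cα RMSD between any two basin templates.  Basins must be resolvable
    against the noise: min_separation > 4·σ·√3.

    The flexible loop sits at the C-terminal end of the chain by default so
    that basin-specific loop dihedrals do not lever-arm a downstream segment:
    the scaffold stays rigid across basins, as in a folded domain.
    """

    n_residues: int = 40
    populations: tuple[float, ...] = (0.6, 0.3, 0.1)
    noise_sigma: float = 0.02
    n_frames: int = 5000
    temperature: float = 300.0
    seed: int = 0
    bias_mode: str = "none"            # "none" | "reweight-to-target"
    min_separation: float = 0.5
    loop_start: int = 23
    loop_end: int = 40
    bias_offset: float = 100.0         # arbitrary constant added to every bias

    def __post_init__(self) -> None:
        p = np.asarray(self.populations, dtype=float)
        if p.size == 0 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("populations must be non-negative and sum to 1")
        if self.bias_mode not in ("none", "reweight-to-target"):
            raise ValueError(f"unknown bias_mode {self.bias_mode!r}")
        if self.bias_mode == "reweight-to-target" and np.any(p == 0):
            raise ValueError("reweight-to-target requires strictly positive targets")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.n_basins > 1 and self.min_separation <= 4 * self.noise_sigma * np.sqrt(3):
            raise ValueError(
                "basins unresolvable: min_separation must exceed 4·σ·√3 = "
                f"{4 * self.noise_sigma * np.sqrt(3):.4f} nm"
            )
        if not (1 <= self.loop_start < self.loop_end <= self.n_residues):
            raise ValueError("loop range must lie inside the chain")
        if self.loop_end - self.loop_start + 1 < 3:
            raise ValueError("loop must span at least 3 residues")

    @property
    def n_basins(self) -> int:
        return len(self.populations)

    @property
    def cluster_entropy_true(self) -> float:
        p = np.asarray(self.populations, dtype=float)
        nz = p[p > 0]
        return float(-np.sum(nz * np.log(nz)))

    def region_set(self) -> RegionSet:
        topo = backbone_topology(self.n_residues)
        return RegionSet(ranges={"CDR3": (self.loop_start, self.loop_end)},
                         n_residues=self.n_residues,
                         all_residue_ids=topo.residue_ids)


# secondary-structure block patterns (thirds of the loop), ordered so that
# the first k entries are mutually well separated in loop-Cα RMSD
_LOOP_PATTERNS = ("EEE", "HHH", "EHE", "HEH", "EEH", "HEE", "EHH", "HHE")
_HELIX = np.array([-1.05, -0.79])
_SHEET = np.array([-2.09, 2.27])


def _template_profiles(spec: SyntheticEnsembleSpec,
                       rng: np.random.Generator) -> np.ndarray:
    """Per-basin φ/ψ profiles: shared scaffold, basin-specific loop.

    Each basin's loop takes a distinct helix/sheet block pattern (thirds of
    the loop), giving templates that are far apart in loop-Cα RMSD; basins
    beyond the eight stock patterns fall back to random per-residue blocks.
    """
    n = spec.n_residues
    loop = np.arange(spec.loop_start - 1, spec.loop_end)
    L = len(loop)
    scaffold_choice = rng.integers(0, len(_RAMA_BASINS), size=n)
    base = _RAMA_BASINS[scaffold_choice] + rng.normal(0, 0.15, size=(n, 2))
    profiles = np.repeat(base[None], spec.n_basins, axis=0)  # (basins, n, 2)
    thirds = [np.arange(0, L // 3), np.arange(L // 3, 2 * L // 3),
              np.arange(2 * L // 3, L)]
    for b in range(spec.n_basins):
        if b < len(_LOOP_PATTERNS):
            pattern = _LOOP_PATTERNS[b]
        else:
            pattern = "".join(rng.choice(["H", "E"], size=3))
        prof = np.empty((L, 2))
        for sym, idx in zip(pattern, thirds):
            prof[idx] = _HELIX if sym == "H" else _SHEET
        profiles[b, loop] = prof + rng.normal(0, 0.12, size=(L, 2))
    return profiles


def _loop_ca_rmsd(a: np.ndarray, b: np.ndarray, spec: SyntheticEnsembleSpec) -> float:
    from .geometry import superpose

    ca = np.arange(spec.loop_start - 1, spec.loop_end) * 4 + 1
    _, _, value = superpose(a, b, selection=ca)
    return value


def generate_multibasin_ensemble(
    spec: SyntheticEnsembleSpec,
    max_template_tries: int = 50,
) -> tuple[ConformationalEnsemble, np.ndarray]:
    """Draw an ensemble from the spec; returns (ensemble, basin labels).

    Basin templates are resampled until every pair is at least
    ``min_separation`` apart in loop-Cα RMSD; failure after
    ``max_template_tries`` raises.
    """
    rng = np.random.default_rng(spec.seed)
    topo = backbone_topology(spec.n_residues)

    templates = None
    for _ in range(max_template_tries):
        profiles = _template_profiles(spec, rng)
        cand = np.stack([build_backbone(p[:, 0], p[:, 1]) for p in profiles])
        seps = [
            _loop_ca_rmsd(cand[i], cand[j], spec)
            for i in range(spec.n_basins) for j in range(i + 1, spec.n_basins)
        ]
        if not seps or min(seps) >= spec.min_separation:
            templates = cand
            break
    if templates is None:
        raise RuntimeError(
            f"could not draw {spec.n_basins} basin templates separated by "
            f">= {spec.min_separation} nm in {max_template_tries} tries"
        )

    p_target = np.asarray(spec.populations, dtype=float)
    if spec.bias_mode == "reweight-to-target":
        labels = rng.integers(0, spec.n_basins, size=spec.n_frames)
    else:
        labels = rng.choice(spec.n_basins, size=spec.n_frames, p=p_target)
    frames = templates[labels]
    if spec.noise_sigma > 0:
        frames = frames + rng.normal(0.0, spec.noise_sigma, size=frames.shape)

    bias = weights = None
    if spec.bias_mode == "reweight-to-target":
        bias = (KB * spec.temperature * np.log(p_target[labels])
                + spec.bias_offset)
        weights = np.asarray(compute_weights(bias, spec.temperature))
    ensemble = ConformationalEnsemble(
        topology=topo, frames=frames, bias=bias, weights=weights,
        temperature=spec.temperature,
    )
    return ensemble, labels


def export_fixture(
    spec: SyntheticEnsembleSpec,
    directory: str | Path,
) -> dict[str, Path]:
    """Write a complete pipeline input fixture in the external formats.

    Emits ``ensemble.pdb`` (multi-model), ``colvar.dat`` (PLUMED COLVAR
    dialect; only in reweight-to-target mode) and ``regions.txt``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ensemble, labels = generate_multibasin_ensemble(spec)
    paths: dict[str, Path] = {}

    pdb_path = directory / "ensemble.pdb"
    write_ensemble(ensemble, pdb_path)
    paths["ensemble"] = pdb_path

    if ensemble.bias is not None:
        colvar_path = directory / "colvar.dat"
        with open(colvar_path, "w") as fh:
            fh.write("#! FIELDS time pb.bias\n")
            for i, v in enumerate(ensemble.bias):
                fh.write(f"{float(i):.1f} {v:.10f}\n")
        paths["colvar"] = colvar_path

    regions_path = directory / "regions.txt"
    write_regions(spec.region_set(), regions_path)
    paths["regions"] = regions_path

    labels_path = directory / "basin_labels.tsv"
    with open(labels_path, "w") as fh:
        fh.write("frame\tbasin\n")
        for i, b in enumerate(labels):
            fh.write(f"{i}\t{int(b)}\n")
    paths["labels"] = labels_path
    return paths


# ---------------------------------------------------------------------------
# Dihedral mixtures
# ---------------------------------------------------------------------------

def histogram_entropy_oracle(phi, psi, weights=None, bins_per_dim: int = 100) -> float:
    """Naïve double-loop histogram entropy, kept independent of the pipeline.

    Bins [−π, π]² uniformly, accumulates weighted counts sample by sample,
    then sums −p ln p cell by cell.  Slow on purpose; used as the reference
    for the vectorised estimator.
    """
    phi = np.asarray(phi, dtype=float).ravel()
    psi = np.asarray(psi, dtype=float).ravel()
    n = len(phi)
    w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, float)
    width = 2 * np.pi / bins_per_dim
    counts = [[0.0] * bins_per_dim for _ in range(bins_per_dim)]
    total = 0.0
    for k in range(n):
        i = int((phi[k] + np.pi) / width)
        j = int((psi[k] + np.pi) / width)
        i = min(max(i, 0), bins_per_dim - 1)
        j = min(max(j, 0), bins_per_dim - 1)
        counts[i][j] += w[k]
        total += w[k]
    s = 0.0
    for i in range(bins_per_dim):
        for j in range(bins_per_dim):
            p = counts[i][j] / total
            if p > 0:
                s -= p * np.log(p)
    return s


def generate_dihedral_mixture(
    n_components: int,
    concentrations,
    means,
    component_weights=None,
    n_samples: int = 10_000,
    seed: int = 0,
    bins_per_dim: int = 100,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Sample (φ, ψ) from a circular von Mises mixture.

    ``means`` is a sequence of (φ, ψ) centres; ``concentrations`` the von
    Mises κ per component (κ = 0 gives the circular uniform distribution).
    Returns ``(phi, psi, reference_entropy)`` where the reference entropy is
    computed by the naïve histogram oracle on the drawn samples.
    """
    if n_components < 1:
        raise ValueError("need at least one mixture component")
    kappas = np.broadcast_to(np.asarray(concentrations, float),
                             (n_components,)).copy()
    centres = np.asarray(means, dtype=float).reshape(n_components, 2)
    cw = (np.full(n_components, 1.0 / n_components) if component_weights is None
          else np.asarray(component_weights, dtype=float))
    cw = cw / cw.sum()
    rng = np.random.default_rng(seed)
    comp = rng.choice(n_components, size=n_samples, p=cw)
    phi = np.empty(n_samples)
    psi = np.empty(n_samples)
    for c in range(n_components):
        sel = comp == c
        m = int(sel.sum())
        if m == 0:
            continue
        if kappas[c] == 0:
            phi[sel] = rng.uniform(-np.pi, np.pi, size=m)
            psi[sel] = rng.uniform(-np.pi, np.pi, size=m)
        else:
            phi[sel] = rng.vonmises(centres[c, 0], kappas[c], size=m)
            psi[sel] = rng.vonmises(centres[c, 1], kappas[c], size=m)
    ref = histogram_entropy_oracle(phi, psi, bins_per_dim=bins_per_dim)
    return phi, psi, ref


# ---------------------------------------------------------------------------
# Entropy ladder
# ---------------------------------------------------------------------------

def build_entropy_ladder(
    population_sets=((1.0,), (0.7, 0.3), (0.4, 0.3, 0.3)),
    seed: int = 0,
    n_frames: int = 2000,
    noise_sigma: float = 0.02,
    **spec_kwargs,
) -> list[tuple[SyntheticEnsembleSpec, ConformationalEnsemble, np.ndarray]]:
    """Ensembles whose ground-truth cluster entropies are strictly ordered.

    Returns a list of (spec, ensemble, basin labels), one per population
    set.  If the analytic entropies of the requested sets are not strictly
    increasing the ladder is still built but a warning is issued (the
    ordering test is then meaningless).
    """
    if len(population_sets) < 2:
        raise ValueError("a ladder needs at least 2 ensembles")
    truths = []
    for pops in population_sets:
        p = np.asarray(pops, dtype=float)
        nz = p[p > 0]
        truths.append(float(-np.sum(nz * np.log(nz))))
    if any(b - a <= 0 for a, b in zip(truths, truths[1:])):
        warnings.warn("ground-truth entropies are not strictly ordered; "
                      "an ordering test on this ladder is vacuous")
    out = []
    for k, pops in enumerate(population_sets):
        spec = SyntheticEnsembleSpec(
            populations=tuple(pops), n_frames=n_frames,
            noise_sigma=noise_sigma, seed=seed + 1000 * k, **spec_kwargs,
        )
        ensemble, labels = generate_multibasin_ensemble(spec)
        out.append((spec, ensemble, labels))
    return out
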