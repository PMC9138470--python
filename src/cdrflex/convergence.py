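"""Split-half convergence diagnostics for cluster populations.

The ensemble (after discarding an initial equilibration fraction) is
clustered once as a whole; weighted cluster populations are then recomputed
separately over the first and second halves of the remaining frames, with
weights renormalised within each half.  Clusters whose whole-ensemble
population is below a floor (default 10/10,000 = 0.001) are too rare to
judge and are excluded from the verdict.

A cluster counts as converged when its |Δp| between halves lies within the
weighted-bootstrap population error.  The bootstrap draws samples whose size
matches the effective sample size of one half, so its standard deviation
estimates the error of one half-trajectory population; the difference of
two independent halves carries √2 times that error, and the verdict flags a
cluster when |Δp| exceeds three such standard errors.  The 95th-percentile
band is reported alongside for error bars.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .clustering import ClusterResult, gromos_cluster
from .entropy import bootstrap_cluster_populations
from .geometry import RmsdMatrix, rmsd_matrix
from .io import ConformationalEnsemble, RegionSet

#: default fraction of initial frames discarded as equilibration
DISCARD_FRACTION = 0.10
#: default population floor below which convergence is not judged
POPULATION_FLOOR = 10 / 10_000


@dataclass(frozen=True)
class ConvergenceReport:
    """Per-cluster split-half population comparison."""

    cluster_ids: np.ndarray
    population_full: np.ndarray
    population_first: np.ndarray      # each half renormalised to sum 1
    population_second: np.ndarray
    abs_diff: np.ndarray
    band_half_width: np.ndarray       # bootstrap 95% band half-width
    bootstrap_se: np.ndarray          # bootstrap standard deviation
    evaluated: np.ndarray             # population_full >= floor
    converged: np.ndarray             # evaluated and |Δp| <= 3·√2·SE
    discard_fraction: float
    population_floor: float
    n_frames_used: int
    clustering: ClusterResult

    @property
    def all_converged(self) -> bool:
        """True when every evaluated cluster is within its bootstrap band."""
        return bool(np.all(self.converged[self.evaluated]))

    def flagged_clusters(self) -> np.ndarray:
        """Evaluated clusters whose halves disagree beyond the band."""
        return self.cluster_ids[self.evaluated & ~self.converged]

    def write(self, json_path: str | Path,
              table_path: str | Path | None = None) -> None:
        payload = {
            "discard_fraction": self.discard_fraction,
            "population_floor": self.population_floor,
            "n_frames_used": self.n_frames_used,
            "all_converged": self.all_converged,
            "flagged_clusters": [int(c) for c in self.flagged_clusters()],
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
        if table_path is not None:
            with open(table_path, "w") as fh:
                fh.write("cluster\tp_full\tp_first\tp_second\tabs_diff\t"
                         "band_half_width\tevaluated\tconverged\n")
                for k in range(len(self.cluster_ids)):
                    fh.write(
                        f"{int(self.cluster_ids[k])}\t{self.population_full[k]:.6f}\t"
                        f"{self.population_first[k]:.6f}\t"
                        f"{self.population_second[k]:.6f}\t{self.abs_diff[k]:.6f}\t"
                        f"{self.band_half_width[k]:.6f}\t"
                        f"{bool(self.evaluated[k])}\t{bool(self.converged[k])}\n"
                    )


def _half_population(labels: np.ndarray, w: np.ndarray, k: int) -> np.ndarray:
    if w.sum() == 0:
        return np.zeros(k)
    w = w / w.sum()
    return np.bincount(labels, weights=w, minlength=k)


def split_half_convergence(
    ensemble: ConformationalEnsemble | None = None,
    regions: RegionSet | None = None,
    region: str | None = None,
    cutoff: float = 0.15,
    weights=None,
    discard_fraction: float = DISCARD_FRACTION,
    population_floor: float = POPULATION_FLOOR,
    matrix: RmsdMatrix | None = None,
    n_bootstrap: int = 20,
    frames_per_sample: int | None = None,
    seed: int = 0,
) -> ConvergenceReport:
    """Compare weighted cluster populations between trajectory halves.

    The first ``discard_fraction`` of frames is dropped, the remainder is
    GROMOS-clustered once, and populations are recomputed over each half.
    Requires at least 20 post-discard frames.
    """
    if not 0 <= discard_fraction < 1:
        raise ValueError("discard_fraction must be in [0, 1)")
    if matrix is None:
        if ensemble is None:
            raise ValueError("either an ensemble or a precomputed matrix is required")
        matrix = rmsd_matrix(ensemble, regions, region)
    elif not isinstance(matrix, RmsdMatrix):
        matrix = RmsdMatrix(values=np.asarray(matrix, dtype=float),
                            atom_indices=np.array([], dtype=int))
    n_total = matrix.n_frames
    if weights is None:
        weights = (ensemble.effective_weights() if ensemble is not None
                   else np.full(n_total, 1.0 / n_total))
    w_all = np.asarray(weights, dtype=float)

    start = int(np.floor(discard_fraction * n_total))
    kept = np.arange(start, n_total)
    if len(kept) < 20:
        raise ValueError(
            f"only {len(kept)} frames remain after discarding "
            f"{discard_fraction:.0%}; need at least 20"
        )
    sub = matrix.submatrix(kept)
    w = w_all[kept]
    w = w / w.sum()

    result = gromos_cluster(sub, cutoff, w)
    k = result.n_clusters
    half = len(kept) // 2
    labels = result.assignment
    p_first = _half_population(labels[:half], w[:half], k)
    p_second = _half_population(labels[half:], w[half:], k)
    p_full = result.populations
    diff = np.abs(p_first - p_second)

    if frames_per_sample is not None:
        fps = frames_per_sample
    else:
        # match the bootstrap's multinomial variance (p q / m) to that of one
        # weighted half-trajectory estimate (p q / (ESS/2))
        ess = 1.0 / np.sum(w**2)
        fps = max(2, int(round(ess / 2.0)))
    boot = bootstrap_cluster_populations(labels, w, n_samples=n_bootstrap,
                                         frames_per_sample=fps, seed=seed)
    lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
    half_width = (hi - lo) / 2.0
    boot_se = boot.std(axis=0, ddof=1)

    evaluated = p_full >= population_floor
    converged = evaluated & (diff <= 3.0 * np.sqrt(2.0) * boot_se)
    return ConvergenceReport(
        cluster_ids=np.arange(k), population_full=p_full,
        population_first=p_first, population_second=p_second,
        abs_diff=diff, band_half_width=half_width, bootstrap_se=boot_se,
        evaluated=evaluated,
        converged=converged, discard_fraction=discard_fraction,
        population_floor=population_floor, n_frames_used=len(kept),
        clustering=result,
    )
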