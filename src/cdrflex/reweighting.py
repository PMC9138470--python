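"""Metadynamics reweighting: bias potentials → per-frame statistical weights.

A parallel-bias metadynamics run samples a biased distribution; the unbiased
Boltzmann statistics are recovered by weighting frame i with

    w_i = exp(V_PB,i / kB T) / Σ_j exp(V_PB,j / kB T)

where V_PB is the (time-independent) parallel-bias potential of the frame,
kB the Boltzmann constant and T the temperature.  All ensemble observables
downstream are weighted averages under w.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import KB


@dataclass(frozen=True)
class WeightVector:
    """Normalised per-frame statistical weights."""

    weights: np.ndarray
    temperature: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("weights must be a non-empty 1-D array")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1 within 1e-9")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.weights)

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        return np.asarray(self.weights, dtype=dtype)


def compute_weights(bias: np.ndarray, temperature: float = 300.0) -> WeightVector:
    """Normalised weights w_i ∝ exp(V_PB,i / kB T).

    Stabilised by subtracting the maximum reduced bias before exponentiation,
    which makes the result exactly invariant under adding any constant to all
    bias values.
    """
    bias = np.asarray(bias, dtype=float)
    if bias.size == 0:
        raise ValueError("bias vector is empty")
    bad = np.flatnonzero(~np.isfinite(bias))
    if bad.size:
        raise ValueError(f"non-finite bias value at frame {bad[0]}")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    reduced = bias / (KB * temperature)
    reduced -= reduced.max()
    w = np.exp(reduced)
    w /= w.sum()
    return WeightVector(weights=w, temperature=temperature)


def weighted_average(values: np.ndarray, weights: WeightVector | np.ndarray):
    """Weighted ensemble average Σ_i w_i x_i (over axis 0 for arrays)."""
    values = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if values.shape[0] != w.shape[0]:
        raise ValueError(
            f"length mismatch: {values.shape[0]} values vs {w.shape[0]} weights"
        )
    return np.tensordot(w, values, axes=(0, 0))


def effective_sample_size(weights: WeightVector | np.ndarray) -> float:
    """Kish effective sample size 1/Σ w_i² for normalised weights."""
    w = np.asarray(weights, dtype=float)
    return float(1.0 / np.sum(w**2))


def write_weights(weights: WeightVector, path: str | Path) -> None:
    """Checkpoint weights as a two-column (frame, weight) text table."""
    w = np.asarray(weights)
    with open(path, "w") as fh:
        fh.write(f"# temperature_K {weights.temperature}\n")
        for i, wi in enumerate(w):
            fh.write(f"{i}\t{wi:.17g}\n")


def read_weights(path: str | Path) -> WeightVector:
    temperature = 300.0
    frames, vals = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if "temperature_K" in line:
                    temperature = float(line.split()[-1])
                continue
            i, wi = line.split()
            frames.append(int(i))
            vals.append(float(wi))
    order = np.argsort(frames)
    return WeightVector(weights=np.array(vals)[order], temperature=temperature)
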