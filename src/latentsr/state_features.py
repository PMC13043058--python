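"""Per-state feature vectors: exact one-hot codes and a synthetic
image-like generator.

The image-like generator stands in for a pretrained convolutional
embedding of rendered views. It reproduces the two properties the
successor-feature machinery relies on: (i) pairwise cosine similarity
between state features decays with distance in the maze, so nearby
locations look alike, and (ii) the state features are linearly
independent, so the state-to-state occupancy matrix can be recovered
from successor features by least squares. Each feature dimension is a
draw from a spatial Gaussian process over the state coordinates
(squared-exponential kernel), and rows are normalized to unit length.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .maze_env import EnvironmentSpec


class UndefinedInputError(ValueError):
    """Raised for inputs on which an operation is mathematically undefined."""


class DegenerateFeaturesError(ValueError):
    """Raised when a feature matrix cannot support occupancy extraction."""


@dataclass(frozen=True)
class FeatureMap:
    """Feature matrix ``Phi`` of shape (N states, D features)."""

    matrix: np.ndarray
    kind: str  # "onehot" | "image-like"
    seed: int = 0

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def vector(self, state: int) -> np.ndarray:
        return self.matrix[state]

    def gram(self) -> np.ndarray:
        """State-feature Gram matrix ``Phi Phi^T`` (N x N).

        Its invertibility is what makes the occupancy extraction
        well-posed; for one-hot features it is the identity.
        """
        return self.matrix @ self.matrix.T


def onehot_features(env: EnvironmentSpec) -> FeatureMap:
    """Identity feature matrix: one orthonormal code per state."""
    return FeatureMap(matrix=np.eye(env.n_states), kind="onehot", seed=0)


def imagelike_features(
    env: EnvironmentSpec,
    D: int = 2048,
    length_scale: float = 2.0,
    seed: int = 0,
) -> FeatureMap:
    """Synthetic image-like features with distance-decaying similarity.

    Parameters
    ----------
    D
        Feature dimension; must be at least the number of states so the
        features can be linearly independent. The default mirrors the
        flattened 1x4x512 output of a conv-net embedding.
    length_scale
        Kernel length scale in grid units; controls how quickly the
        similarity between state features falls off with distance.
    seed
        Seed for the generative draw; the same seed yields a
        bit-identical matrix.
    """
    n = env.n_states
    if D < n:
        raise DegenerateFeaturesError(
            f"D={D} < {n} states: features cannot be linearly independent"
        )
    coords = env.coords.astype(float)
    sq = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    kernel = np.exp(-sq / (2.0 * length_scale**2))
    # jitter keeps the Cholesky factor well-defined and the rows distinct
    chol = np.linalg.cholesky(kernel + 1e-6 * np.eye(n))
    rng = np.random.default_rng(seed)
    phi = chol @ rng.standard_normal((n, D))
    phi /= np.linalg.norm(phi, axis=1, keepdims=True)
    fm = FeatureMap(matrix=phi, kind="image-like", seed=seed)
    cond = np.linalg.cond(fm.gram())
    if not np.isfinite(cond) or cond > 1e10:
        raise DegenerateFeaturesError(
            f"feature Gram matrix is ill-conditioned (cond={cond:.3g})"
        )
    return fm


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two feature vectors, in [-1, 1]."""
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise UndefinedInputError("cosine similarity is undefined for zero vectors")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def similarity_matrix(features: FeatureMap) -> np.ndarray:
    """All-pairs cosine similarity between state features."""
    phi = features.matrix
    norms = np.linalg.norm(phi, axis=1, keepdims=True)
    unit = phi / norms
    return np.clip(unit @ unit.T, -1.0, 1.0)


def save_features(path, features: FeatureMap, env_name: str) -> None:
    """Store a feature matrix in an HDF5 container keyed by provenance."""
    with h5py.File(path, "a") as f:
        key = f"{env_name}/{features.kind}/seed{features.seed}"
        if key in f:
            del f[key]
        ds = f.create_dataset(key, data=features.matrix)
        ds.attrs["kind"] = features.kind
        ds.attrs["seed"] = features.seed


def load_features(path, env_name: str, kind: str, seed: int = 0) -> FeatureMap:
    with h5py.File(path, "r") as f:
        ds = f[f"{env_name}/{kind}/seed{seed}"]
        return FeatureMap(matrix=ds[...], kind=kind, seed=seed)
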