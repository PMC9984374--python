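"""Frame descriptors: SOAP computation, PCA reduction, farthest point sampling.

The clustering operates in a low-dimensional map of conformer space: SOAP
power spectra per frame (see :mod:`confspec.soap`), reduced by PCA to a few
principal components (default two).  Farthest point sampling provides
landmark selection both for the density grid and for picking spread-out
conformers within a cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .ensemble import ConformerEnsemble
from .soap import DescriptorMatrix, SoapDescriptor

__all__ = [
    "SoapDescriptor",
    "DescriptorMatrix",
    "PcaProjection",
    "compute_soap",
    "pca",
    "farthest_point_sampling",
    "save_descriptors",
    "load_descriptors",
]


def compute_soap(
    ensemble: ConformerEnsemble,
    cutoff: float = 5.0,
    n_max: int = 6,
    l_max: int = 4,
    atom_sigma: float = 0.4,
    species=None,
    normalize: bool = True,
) -> DescriptorMatrix:
    """Averaged per-frame SOAP power spectra (thin wrapper over the
    :class:`~confspec.soap.SoapDescriptor` transformer)."""
    est = SoapDescriptor(
        species=species, cutoff=cutoff, n_max=n_max, l_max=l_max,
        atom_sigma=atom_sigma, normalize=normalize,
    )
    return est.describe(ensemble)


def save_descriptors(path, matrix: DescriptorMatrix) -> None:
    """Persist a descriptor matrix as dense CSV with a JSON sidecar of
    channel labels (``<path>.meta.json``)."""
    import json
    from pathlib import Path

    np.savetxt(path, matrix.values, delimiter=",")
    Path(str(path) + ".meta.json").write_text(
        json.dumps(
            {"feature_meta": matrix.feature_meta,
             "normalized": matrix.normalized}
        )
    )


def load_descriptors(path) -> DescriptorMatrix:
    import json
    from pathlib import Path

    meta = json.loads(Path(str(path) + ".meta.json").read_text())
    values = np.loadtxt(path, delimiter=",", ndmin=2)
    return DescriptorMatrix(values, meta["feature_meta"], meta["normalized"])


@dataclass
class PcaProjection:
    """Principal-component projection of a descriptor matrix."""

    components: np.ndarray  # (D, d)
    projected: np.ndarray  # (n_frames, d)
    explained_variance_ratio: np.ndarray  # (d,)
    mean: np.ndarray  # (D,)


def pca(X, n_components: int = 2) -> PcaProjection:
    """Top principal components of the column-centred covariance.

    Raises on constant input (zero total variance).
    """
    values = X.values if isinstance(X, DescriptorMatrix) else np.asarray(X, float)
    n, D = values.shape
    if not 1 <= n_components <= min(n, D):
        raise ValueError(
            f"n_components must be in [1, {min(n, D)}], got {n_components}"
        )
    if np.allclose(values, values[0], atol=0.0, rtol=0.0) or np.allclose(
        values.var(axis=0), 0.0
    ):
        raise ValueError("descriptor matrix has zero variance; PCA undefined")
    est = PCA(n_components=n_components, svd_solver="full")
    projected = est.fit_transform(values)
    return PcaProjection(
        components=est.components_.T,
        projected=projected,
        explained_variance_ratio=est.explained_variance_ratio_,
        mean=est.mean_,
    )


def farthest_point_sampling(
    X, n_select: int, start_index: int = 0, return_distances: bool = False
):
    """Greedy max-min landmark selection in Euclidean space.

    Starting from ``start_index``, each successive landmark maximises the
    minimum distance to all previously selected ones; ties are broken by
    the lowest index.  Deterministic.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if not 1 <= n_select <= n:
        raise ValueError(f"n_select must be in [1, {n}], got {n_select}")
    if not 0 <= start_index < n:
        raise ValueError("start_index out of range")
    selected = [start_index]
    mindist = np.linalg.norm(X - X[start_index], axis=1)
    mindist[start_index] = -np.inf  # exclude picked points from argmax
    gaps = []
    for _ in range(1, n_select):
        nxt = int(np.argmax(mindist))  # argmax returns the lowest tying index
        gaps.append(float(mindist[nxt]))
        selected.append(nxt)
        mindist = np.minimum(mindist, np.linalg.norm(X - X[nxt], axis=1))
        mindist[nxt] = -np.inf
    if return_distances:
        return selected, np.array(gaps)
    return selected
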