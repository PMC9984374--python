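"""Smooth-overlap (SOAP-style) power-spectrum descriptors.

Each atomic environment is represented by the expansion of its
Gaussian-smeared neighbour density, per chemical species, in a radial basis
times spherical harmonics; contracting the expansion coefficients over the
angular index m yields the rotation-invariant power spectrum

    p^{s1 s2}_{n1 n2 l} = sum_m c^{s1}_{n1 l m} (c^{s2}_{n2 l m})*,

which is also invariant to translations and to permutations of atoms within
a species.  The per-frame (global) descriptor is the arithmetic mean of the
per-atom power spectra over all centres in the frame.

For a neighbour at distance rho the expansion coefficient factorises into an
exact angular part and a one-dimensional radial integral,

    c_nlm += 4 pi  Y*_lm(direction)  I_nl(rho),
    I_nl(rho) = int_0^rcut g_n(r) r^2 exp(-a (r-rho)^2) ilse_l(2 a r rho) dr,

with a = 1/(2 sigma^2) and ilse_l the exponentially-scaled modified
spherical Bessel function of the first kind.  The radial basis g_n is the
orthonormalised polynomial set (rcut - r)^(n+2).  I_nl is evaluated by
Gauss-Legendre quadrature, by default through a dense interpolation table
in rho (set ``radial_interp_points=None`` for exact per-pair quadrature).
"""

from __future__ import annotations

import numpy as np
from scipy.special import ive, sph_harm_y
from sklearn.base import BaseEstimator, TransformerMixin

from .ensemble import ConformerEnsemble

__all__ = ["SoapDescriptor", "DescriptorMatrix"]


def _radial_basis(n_max: int, rcut: float):
    """Orthonormalised (rcut - r)^(n+2) radial basis, n = 1..n_max.

    Returns a function g(r) -> array (n_max, len(r)).
    """
    n = np.arange(1, n_max + 1)
    # overlap S_nm = int_0^rcut (rcut-r)^(n+m+4) r^2 dr, closed form
    nm = n[:, None] + n[None, :]
    S = 2.0 * rcut ** (nm + 7) / ((nm + 5) * (nm + 6) * (nm + 7))
    w, V = np.linalg.eigh(S)
    W = V @ np.diag(1.0 / np.sqrt(w)) @ V.T  # S^{-1/2}

    def g(r):
        r = np.asarray(r, dtype=float)
        phi = np.clip(rcut - r, 0.0, None)[None, :] ** (n[:, None] + 2)
        return W @ phi

    return g


def _ilse(l: int, x: np.ndarray) -> np.ndarray:
    """Exponentially scaled modified spherical Bessel: exp(-x) i_l(x)."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    small = x < 1e-12
    if l == 0:
        out[small] = 1.0
    big = ~small
    if np.any(big):
        xb = x[big]
        out[big] = np.sqrt(np.pi / (2.0 * xb)) * ive(l + 0.5, xb)
    return out


class _RadialIntegrals:
    """I_nl(rho) for all n, l via Gauss-Legendre quadrature."""

    def __init__(self, n_max, l_max, rcut, sigma, n_quad=100, table_points=4096):
        self.n_max, self.l_max, self.rcut = n_max, l_max, rcut
        self.alpha = 1.0 / (2.0 * sigma**2)
        x, w = np.polynomial.legendre.leggauss(n_quad)
        self.r_q = 0.5 * rcut * (x + 1.0)
        self.w_q = 0.5 * rcut * w
        self.g_q = _radial_basis(n_max, rcut)(self.r_q)  # (n_max, nq)
        self.table_points = table_points
        if table_points:
            self.rho_grid = np.linspace(0.0, rcut, table_points)
            self.table = self._exact(self.rho_grid)  # (n_max, l_max+1, P)

    def _exact(self, rho: np.ndarray) -> np.ndarray:
        rho = np.asarray(rho, dtype=float)
        a = self.alpha
        gauss = np.exp(-a * (self.r_q[None, :] - rho[:, None]) ** 2)  # (P, nq)
        out = np.empty((self.n_max, self.l_max + 1, rho.size))
        base = self.g_q * self.r_q**2 * self.w_q  # (n_max, nq)
        x = 2.0 * a * self.r_q[None, :] * rho[:, None]  # (P, nq)
        for l in range(self.l_max + 1):
            kern = gauss * _ilse(l, x)  # (P, nq)
            out[:, l, :] = base @ kern.T
        return out

    def __call__(self, rho: np.ndarray) -> np.ndarray:
        """I_nl at each rho: array (n_max, l_max+1, len(rho))."""
        if not self.table_points:
            return self._exact(rho)
        out = np.empty((self.n_max, self.l_max + 1, rho.size))
        for n in range(self.n_max):
            for l in range(self.l_max + 1):
                out[n, l] = np.interp(rho, self.rho_grid, self.table[n, l])
        return out


_RADIAL_CACHE: dict = {}


def _radial_integrals(n_max, l_max, rcut, sigma, table_points):
    """Memoised radial-integral tables (parameter-only, safe to share)."""
    key = (n_max, l_max, float(rcut), float(sigma), int(table_points))
    if key not in _RADIAL_CACHE:
        _RADIAL_CACHE[key] = _RadialIntegrals(
            n_max, l_max, rcut, sigma, table_points=table_points
        )
    return _RADIAL_CACHE[key]


class DescriptorMatrix:
    """Per-frame descriptor rows with channel labels."""

    def __init__(self, values, feature_meta, normalized):
        self.values = np.asarray(values, dtype=float)
        self.feature_meta = list(feature_meta)
        self.normalized = bool(normalized)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite descriptor entries")

    @property
    def shape(self):
        return self.values.shape


class SoapDescriptor(TransformerMixin, BaseEstimator):
    """Per-frame averaged SOAP power-spectrum transformer.

    Parameters
    ----------
    species:
        Chemical species channels; must cover every element present.
        ``None`` infers (sorted) from the first ensemble seen.
    cutoff:
        Radial cutoff in Å (must exceed ``2 * atom_sigma``).
    n_max, l_max:
        Radial / angular expansion sizes.
    atom_sigma:
        Gaussian smearing width of the neighbour density, Å.
    normalize:
        L2-normalise each frame's descriptor row (default on).
    radial_interp_points:
        Size of the radial-integral interpolation table; ``None`` evaluates
        the quadrature exactly for every neighbour distance.
    """

    def __init__(
        self,
        species=None,
        cutoff: float = 5.0,
        n_max: int = 6,
        l_max: int = 4,
        atom_sigma: float = 0.4,
        normalize: bool = True,
        radial_interp_points: int | None = 4096,
        batch_frames: int = 200,
    ):
        self.species = species
        self.cutoff = cutoff
        self.n_max = n_max
        self.l_max = l_max
        self.atom_sigma = atom_sigma
        self.normalize = normalize
        self.radial_interp_points = radial_interp_points
        self.batch_frames = batch_frames

    # -- helpers ----------------------------------------------------------
    def _check_params(self, ensemble):
        if self.cutoff <= 2.0 * self.atom_sigma:
            raise ValueError("cutoff must exceed 2 * atom_sigma")
        species = self.species
        if species is None:
            species = sorted(set(ensemble.species))
        unknown = sorted(set(ensemble.species) - set(species))
        if unknown:
            raise ValueError(f"species not covered by descriptor: {unknown}")
        return list(species)

    def _lm_index(self):
        pairs = [(l, m) for l in range(self.l_max + 1) for m in range(-l, l + 1)]
        offsets = {}
        off = 0
        for l in range(self.l_max + 1):
            offsets[l] = off
            off += 2 * l + 1
        return pairs, offsets, off

    def _feature_meta(self, species):
        meta = []
        S = len(species)
        for s1 in range(S):
            for s2 in range(s1, S):
                for l in range(self.l_max + 1):
                    for n1 in range(self.n_max):
                        n2_range = range(n1, self.n_max) if s1 == s2 else range(self.n_max)
                        for n2 in n2_range:
                            meta.append(
                                f"{species[s1]}-{species[s2]} l={l} n1={n1} n2={n2}"
                            )
        return meta

    # -- sklearn API ------------------------------------------------------
    def fit(self, X: ConformerEnsemble, y=None):
        self.species_ = self._check_params(X)
        self.feature_meta_ = self._feature_meta(self.species_)
        self.n_features_ = len(self.feature_meta_)
        return self

    def transform(self, X: ConformerEnsemble) -> np.ndarray:
        if not hasattr(self, "species_"):
            self.fit(X)
        species = self.species_
        unknown = sorted(set(X.species) - set(species))
        if unknown:
            raise ValueError(f"species not covered by descriptor: {unknown}")
        radial = _radial_integrals(
            self.n_max, self.l_max, self.cutoff, self.atom_sigma,
            self.radial_interp_points or 0,
        )
        s_of_atom = np.array([species.index(s) for s in X.species])
        rows = []
        for lo in range(0, X.n_frames, self.batch_frames):
            batch = X.coords[lo : lo + self.batch_frames]
            rows.append(self._transform_batch(batch, s_of_atom, radial, len(species)))
        values = np.concatenate(rows) if rows else np.empty((0, self.n_features_))
        if self.normalize:
            norms = np.linalg.norm(values, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            values = values / norms
        return values

    def describe(self, X: ConformerEnsemble) -> DescriptorMatrix:
        """Transform and wrap with channel labels."""
        values = self.fit(X).transform(X)
        return DescriptorMatrix(values, self.feature_meta_, self.normalize)

    # -- core -------------------------------------------------------------
    def _coefficients_batch(self, coords, s_of_atom, radial, S):
        """Expansion coefficients c for a coordinate batch.

        Returns complex array (B, A, S, n_max, n_lm_total).
        """
        B, A, _ = coords.shape
        _, l_offsets, n_lm = self._lm_index()
        rel = coords[:, None, :, :] - coords[:, :, None, :]  # center i -> atom j
        dist = np.linalg.norm(rel, axis=-1)
        mask = (dist <= self.cutoff) & ~np.eye(A, dtype=bool)[None]
        fb, ic, jc = np.nonzero(mask)
        rho = dist[fb, ic, jc]
        vec = rel[fb, ic, jc] / rho[:, None]
        theta = np.arccos(np.clip(vec[:, 2], -1.0, 1.0))
        phi = np.arctan2(vec[:, 1], vec[:, 0])
        sj = s_of_atom[jc]

        group = (fb * A + ic) * S + sj
        order = np.argsort(group, kind="stable")
        group_s = group[order]
        starts = np.flatnonzero(np.r_[True, np.diff(group_s) > 0])
        uniq = group_s[starts]

        I = radial(rho)  # (n_max, l_max+1, P)
        c = np.zeros((B * A * S, self.n_max, n_lm), dtype=complex)
        for l in range(self.l_max + 1):
            off = l_offsets[l]
            for m in range(-l, l + 1):
                y = np.conj(sph_harm_y(l, m, theta, phi))  # (P,)
                contrib = (4.0 * np.pi) * I[:, l, :] * y[None, :]  # (n_max, P)
                seg = np.add.reduceat(contrib[:, order], starts, axis=1)
                c[uniq, :, off + l + m] = seg.T
        return c.reshape(B, A, S, self.n_max, n_lm)

    def _transform_batch(self, coords, s_of_atom, radial, S):
        B, A, _ = coords.shape
        _, l_offsets, _ = self._lm_index()
        c = self._coefficients_batch(coords, s_of_atom, radial, S)
        feats = []
        for s1 in range(S):
            for s2 in range(s1, S):
                for l in range(self.l_max + 1):
                    off = l_offsets[l]
                    c1 = c[:, :, s1, :, off : off + 2 * l + 1]
                    c2 = c[:, :, s2, :, off : off + 2 * l + 1]
                    p = np.einsum("banm,bakm->bank", c1, np.conj(c2)).real
                    if s1 == s2:
                        n1, n2 = np.triu_indices(self.n_max)
                        feats.append(p[:, :, n1, n2])
                    else:
                        feats.append(p.reshape(B, A, -1))
        per_atom = np.concatenate(feats, axis=2)  # (B, A, D)
        return per_atom.mean(axis=1)
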