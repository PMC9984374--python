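"""Continuous hydrogen-bond counting on N-H...O triplets.

A donor-hydrogen-acceptor triplet is scored by a smooth membership function
in [0, 1]: the posterior probability of the hydrogen-bonded component in a
two-component mixture (a Gaussian "bonded" component versus a broad uniform
background) evaluated in the proton-transfer coordinates

    nu = d_DH - d_AH,   mu = d_DH + d_AH,   and d_DA,

so that 1 means a perfect match to the reference H-bond geometry and the
score decays to 0 as the acceptor leaves.  Summing memberships over all
triplets a tagged atom participates in gives the counting observables:
s_D per donor nitrogen, s_A per acceptor oxygen, s_H per hydrogen.  Their
histograms, smoothed with a triangular kernel, give probability surfaces
and free energies F = -k_B T ln P (kcal/mol), integer-cell integrated
probabilities, and per-cluster summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import ConformerEnsemble

__all__ = [
    "KB_KCAL",
    "TripletGeometry",
    "HBondModel",
    "HBondCounts",
    "ProbabilitySurface",
    "enumerate_triplets",
    "count",
    "count_ensemble",
    "surface",
    "integrate_cells",
    "per_cluster_summary",
    "counts_to_frame",
    "surface_to_frame",
]

#: Boltzmann constant, kcal mol^-1 K^-1.
KB_KCAL = 0.0019872

COVALENT_DH_CUTOFF = 1.3  # Å: a hydrogen within this distance is bonded


@dataclass
class TripletGeometry:
    """Distances of one donor-hydrogen-acceptor triplet (Å)."""

    d_DH: float
    d_AH: float
    d_DA: float
    donor_id: int
    hydrogen_id: int
    acceptor_id: int

    def __post_init__(self) -> None:
        if min(self.d_DH, self.d_AH, self.d_DA) <= 0:
            raise ValueError("triplet distances must be positive")


@dataclass
class HBondModel:
    """Two-component bonded-vs-background mixture in (nu, mu, d_DA).

    The bonded component is a diagonal Gaussian at the reference H-bond
    geometry; the background is uniform over a broad box.  All parameters
    are exposed; the defaults describe a canonical N-H...O bond
    (d_DH = 1.0, d_AH = 1.9, d_DA = 2.9 Å ⇒ nu = -0.9, mu = 2.9).
    """

    mean: tuple = (-0.9, 2.9, 2.9)  # (nu, mu, d_DA), Å
    sd: tuple = (0.25, 0.25, 0.25)
    mixing: float = 0.5  # prior weight of the bonded component
    background_box: tuple = ((-4.0, 4.0), (0.0, 8.0), (0.0, 8.0))

    def __post_init__(self) -> None:
        if not 0 < self.mixing < 1:
            raise ValueError("mixing must be in (0, 1)")
        vol = 1.0
        for lo, hi in self.background_box:
            if hi <= lo:
                raise ValueError("degenerate background box")
            vol *= hi - lo
        self._bg_density = 1.0 / vol

    def membership(self, t: TripletGeometry) -> float:
        """Posterior probability that the triplet is hydrogen bonded."""
        x = np.array([t.d_DH - t.d_AH, t.d_DH + t.d_AH, t.d_DA])
        m = np.asarray(self.mean)
        s = np.asarray(self.sd)
        log_g = -0.5 * np.sum(((x - m) / s) ** 2) - np.sum(
            np.log(s * np.sqrt(2.0 * np.pi))
        )
        bonded = self.mixing * np.exp(log_g)
        background = (1.0 - self.mixing) * self._bg_density
        return float(bonded / (bonded + background))


@dataclass
class HBondCounts:
    """Per-frame membership sums for each tagged atom.

    Atoms whose total count falls below ``participation_threshold`` are
    excluded from averages (non-donating nitrogens are ignored, and
    similarly for acceptors and hydrogens).
    """

    s_D: dict  # donor N atom index -> sum of memberships
    s_A: dict  # acceptor O atom index -> sum
    s_H: dict  # hydrogen atom index -> sum
    participation_threshold: float = 0.1

    def participating(self, role: str) -> dict:
        vals = {"D": self.s_D, "A": self.s_A, "H": self.s_H}[role]
        return {k: v for k, v in vals.items() if v > self.participation_threshold}

    def frame_mean(self, role: str) -> float | None:
        part = self.participating(role)
        if not part:
            return None
        return float(np.mean(list(part.values())))


HEAVY_BOND_CUTOFF = 1.8  # Å: heavy-atom pairs closer than this are bonded


def _bond_separations(coords: np.ndarray, species, sources) -> np.ndarray:
    """Graph distance (in bonds) from each source atom to every atom.

    Bonds are inferred from distance: < 1.3 Å when a hydrogen is involved,
    < 1.8 Å between heavy atoms.  Unreachable atoms get a large value.
    """
    n = len(species)
    dist = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    is_h = np.array([s == "H" for s in species])
    thresh = np.where(is_h[:, None] | is_h[None, :],
                      COVALENT_DH_CUTOFF, HEAVY_BOND_CUTOFF)
    bonded = (dist < thresh) & ~np.eye(n, dtype=bool)
    out = np.full((len(sources), n), n + 1, dtype=int)
    for row, src in enumerate(sources):
        seen = {src: 0}
        frontier = [src]
        depth = 0
        while frontier:
            depth += 1
            nxt = []
            for u in frontier:
                for v in np.nonzero(bonded[u])[0]:
                    if v not in seen:
                        seen[v] = depth
                        nxt.append(v)
            frontier = nxt
        for v, k in seen.items():
            out[row, v] = k
    return out


def enumerate_triplets(
    coords: np.ndarray,
    species,
    donor_species: str = "N",
    acceptor_species: str = "O",
    cutoff: float = 4.5,
    min_bond_separation: int = 3,
) -> list:
    """All donor-H...acceptor triplets with d_DA within the cutoff.

    Covalent donor-hydrogen pairs are identified by distance below 1.3 Å.
    Acceptors closer than ``min_bond_separation`` bonds to the donor along
    the covalent network are excluded (1-2 and 1-3 contacts are not
    hydrogen bonds).  Ordering is deterministic: by donor, then hydrogen,
    then acceptor index.  Returns an empty list (not an error) if donors or
    acceptors are absent.
    """
    coords = np.asarray(coords, dtype=float)
    species = list(species)
    donors = [i for i, s in enumerate(species) if s == donor_species]
    acceptors = [i for i, s in enumerate(species) if s == acceptor_species]
    hydrogens = [i for i, s in enumerate(species) if s == "H"]
    sep = _bond_separations(coords, species, donors) if donors else None
    out = []
    for di, d in enumerate(donors):
        for h in hydrogens:
            d_dh = float(np.linalg.norm(coords[d] - coords[h]))
            if d_dh >= COVALENT_DH_CUTOFF:
                continue
            for a in acceptors:
                d_da = float(np.linalg.norm(coords[d] - coords[a]))
                if d_da > cutoff:
                    continue
                if sep[di, a] < min_bond_separation:
                    continue
                d_ah = float(np.linalg.norm(coords[a] - coords[h]))
                out.append(
                    TripletGeometry(
                        d_DH=d_dh, d_AH=d_ah, d_DA=d_da,
                        donor_id=d, hydrogen_id=h, acceptor_id=a,
                    )
                )
    return out


def count(
    coords: np.ndarray,
    species,
    model: HBondModel | None = None,
    cutoff: float = 4.5,
    participation_threshold: float = 0.1,
    min_bond_separation: int = 3,
) -> HBondCounts:
    """Membership-weighted H-bond counts for one frame."""
    if model is None:
        model = HBondModel()
    triplets = enumerate_triplets(coords, species, cutoff=cutoff,
                                  min_bond_separation=min_bond_separation)
    s_D: dict = {}
    s_A: dict = {}
    s_H: dict = {}
    for t in triplets:
        m = model.membership(t)
        s_D[t.donor_id] = s_D.get(t.donor_id, 0.0) + m
        s_A[t.acceptor_id] = s_A.get(t.acceptor_id, 0.0) + m
        s_H[t.hydrogen_id] = s_H.get(t.hydrogen_id, 0.0) + m
    return HBondCounts(s_D=s_D, s_A=s_A, s_H=s_H,
                       participation_threshold=participation_threshold)


def count_ensemble(
    ensemble: ConformerEnsemble,
    model: HBondModel | None = None,
    cutoff: float = 4.5,
    participation_threshold: float = 0.1,
    min_bond_separation: int = 3,
) -> list:
    """H-bond counts for every frame of an ensemble."""
    if model is None:
        model = HBondModel()
    return [
        count(ensemble.coords[f], ensemble.species, model, cutoff,
              participation_threshold, min_bond_separation)
        for f in range(ensemble.n_frames)
    ]


@dataclass
class ProbabilitySurface:
    """Smoothed probability (and free energy) over H-bond count coordinates.

    1-D (a single s axis) or 2-D ((s_A, s_D)); probabilities sum to 1, and
    F = -k_B T ln P wherever P > 0 (NaN elsewhere).  ``f_shifted`` has its
    minimum set to zero for plotting; ``free_energy`` is the raw value.
    """

    edges: tuple  # bin edges per axis
    probability: np.ndarray
    temperature: float
    kernel_width: float
    k_b: float = KB_KCAL

    @property
    def centers(self) -> tuple:
        return tuple(0.5 * (e[1:] + e[:-1]) for e in self.edges)

    @property
    def free_energy(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            f = np.where(
                self.probability > 0,
                -self.k_b * self.temperature * np.log(
                    np.where(self.probability > 0, self.probability, 1.0)
                ),
                np.nan,
            )
        return f

    @property
    def f_shifted(self) -> np.ndarray:
        f = self.free_energy
        return f - np.nanmin(f)


def _triangular_kernel_matrix(edges: np.ndarray, width: float) -> np.ndarray:
    """K[i, j]: mass a triangular kernel centred at bin j deposits in bin i.

    The kernel has half-width ``width``; the matrix columns are normalised
    so smoothing conserves total mass exactly.
    """
    centers = 0.5 * (edges[1:] + edges[:-1])
    lo = edges[:-1][:, None]
    hi = edges[1:][:, None]
    c = centers[None, :]

    def cdf(x):
        # CDF of the triangular kernel centred at c with half-width `width`
        u = np.clip((x - c) / width, -1.0, 1.0)
        return np.where(u < 0, 0.5 * (1.0 + u) ** 2, 1.0 - 0.5 * (1.0 - u) ** 2)

    K = cdf(hi) - cdf(lo)
    col = K.sum(axis=0)
    col[col == 0] = 1.0
    return K / col[None, :]


def surface(
    samples,
    temperature: float = 300.0,
    width: float = 0.025,
    bin_width: float = 0.05,
    value_range: tuple = (0.0, 3.0),
) -> ProbabilitySurface:
    """Histogram samples, smooth with a triangular kernel, normalise.

    ``samples`` is 1-D (values of one s observable) or of shape (n, 2) for
    joint (s_A, s_D) statistics; ``width`` is the kernel half-width in s
    units (0.025 by default, on 0.05-wide bins spanning [0, 3]).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("at least one sample required")
    edges = np.arange(value_range[0], value_range[1] + 0.5 * bin_width, bin_width)
    if samples.ndim == 1:
        hist, _ = np.histogram(samples, bins=edges)
        hist = hist.astype(float)
        if width > 0:
            hist = _triangular_kernel_matrix(edges, width) @ hist
        total = hist.sum()
        if total == 0:
            raise ValueError("no samples fall inside the histogram range")
        return ProbabilitySurface(
            edges=(edges,), probability=hist / total,
            temperature=temperature, kernel_width=width,
        )
    if samples.ndim != 2 or samples.shape[1] != 2:
        raise ValueError("samples must be 1-D or (n, 2)")
    hist, _, _ = np.histogram2d(samples[:, 0], samples[:, 1], bins=(edges, edges))
    if width > 0:
        K = _triangular_kernel_matrix(edges, width)
        hist = K @ hist @ K.T
    total = hist.sum()
    if total == 0:
        raise ValueError("no samples fall inside the histogram range")
    return ProbabilitySurface(
        edges=(edges, edges), probability=hist / total,
        temperature=temperature, kernel_width=width,
    )


def integrate_cells(surf: ProbabilitySurface):
    """Probability mass per integer cell [i-0.5, i+0.5) x [j-0.5, j+0.5).

    Returns ``(cells, (i*, j*), pct)``: a dict mapping integer tuples to
    percentages, the most probable cell, and its percentage.
    """
    if len(surf.edges) != 2:
        raise ValueError("integer-cell integration needs a 2-D surface")
    cx, cy = surf.centers
    ix = np.round(cx).astype(int)
    iy = np.round(cy).astype(int)
    cells: dict = {}
    for a in np.unique(ix):
        for b in np.unique(iy):
            mask = np.outer(ix == a, iy == b)
            mass = float(surf.probability[mask].sum()) * 100.0
            cells[(int(a), int(b))] = mass
    best = max(cells, key=lambda k: (cells[k], -k[0], -k[1]))
    return cells, best, cells[best]


def counts_to_frame(counts_by_frame) -> pd.DataFrame:
    """Long-form per-frame counts: columns (frame, atom_id, role, value)."""
    rows = []
    for f, counts in enumerate(counts_by_frame):
        for role, vals in (("D", counts.s_D), ("A", counts.s_A),
                           ("H", counts.s_H)):
            for atom, v in sorted(vals.items()):
                rows.append(
                    {"frame": f, "atom_id": atom, "role": role, "value": v}
                )
    return pd.DataFrame(rows, columns=["frame", "atom_id", "role", "value"])


def surface_to_frame(surf: ProbabilitySurface) -> pd.DataFrame:
    """Gridded surface as a table of bin centres, P and F."""
    f = surf.free_energy
    if len(surf.edges) == 1:
        c = surf.centers[0]
        return pd.DataFrame(
            {"s": c, "probability": surf.probability, "free_energy": f}
        )
    cx, cy = surf.centers
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    return pd.DataFrame(
        {
            "s_A": gx.ravel(), "s_D": gy.ravel(),
            "probability": surf.probability.ravel(),
            "free_energy": f.ravel(),
        }
    )


def per_cluster_summary(
    counts_by_frame,
    labels,
    weights,
    temperature: float = 300.0,
    kernel_width: float = 0.025,
) -> pd.DataFrame:
    """Per-cluster H-bond table: mean/sd of s_A and s_D, the most probable
    integer (s_A, s_D) cell with its percentage, and the cluster weight.

    Per frame, the s_A (s_D) value is the mean over participating acceptor
    (donor) atoms; cluster statistics are population mean and standard
    deviation over frames.  Clusters where no atom ever participates report
    missing fields (NaN), not zeros.
    """
    labels = np.asarray(labels)
    weights = np.asarray(weights, dtype=float)
    rows = []
    for c in range(weights.size):
        frames = np.where(labels == c)[0]
        sa = [counts_by_frame[f].frame_mean("A") for f in frames]
        sd_ = [counts_by_frame[f].frame_mean("D") for f in frames]
        sa = [v for v in sa if v is not None]
        sd_ = [v for v in sd_ if v is not None]
        row = {"cluster": c + 1}
        row["mean_sA"] = float(np.mean(sa)) if sa else np.nan
        row["sd_sA"] = float(np.std(sa)) if sa else np.nan
        row["mean_sD"] = float(np.mean(sd_)) if sd_ else np.nan
        row["sd_sD"] = float(np.std(sd_)) if sd_ else np.nan
        joint = [
            (counts_by_frame[f].frame_mean("A"), counts_by_frame[f].frame_mean("D"))
            for f in frames
        ]
        joint = [(a, d) for a, d in joint if a is not None and d is not None]
        if joint:
            surf = surface(np.array(joint), temperature=temperature,
                           width=kernel_width)
            _, best, pct = integrate_cells(surf)
            row["mp_tuple"] = f"({best[0]},{best[1]})"
            row["mp_pct"] = pct
        else:
            row["mp_tuple"] = ""
            row["mp_pct"] = np.nan
        row["weight_pct"] = 100.0 * weights[c]
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "cluster", "mean_sA", "sd_sA", "mean_sD", "sd_sD",
            "mp_tuple", "mp_pct", "weight_pct",
        ],
    )
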