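"""Synthetic conformer ensembles with known ground truth.

Real inputs for this kind of analysis are a replica-exchange MD trajectory,
per-conformer harmonic (DFT) stick spectra and a measured action spectrum.
This module replaces all three with a controllable generator: a mixture of
K conformational basins of a small peptide-like chain, each basin defined
by mean backbone torsions, a characteristic donor–acceptor hydrogen-bond
distance, a number of engaged acceptors, and a stick spectrum whose line
positions shift linearly with the H-bond distance.  Every generated
quantity (frame labels, basin populations, representative frames, the
noise-free reference spectrum) is known exactly, so recovery by the
clustering/averaging pipeline can be tested quantitatively.

Geometry is built from a fixed ~20-atom internal-coordinate template with
four free torsions; an N-terminal NH3-like group donates hydrogen bonds to
"probe" acceptor oxygens placed along the N-H directions at the basin's
characteristic distance (unengaged probes are parked far away so that all
frames share one chemical composition).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .ensemble import ConformerEnsemble
from .spectra import GridSpectrum, StickSpectrum, broaden

__all__ = [
    "BasinSpec",
    "SyntheticTruth",
    "generate_ensemble",
    "generate_reference_spectrum",
    "basin_stick_spectrum",
    "frame_stick_spectrum",
    "default_basins",
    "DEFAULT_GRID",
]

#: Default wavenumber grid for broadened spectra (cm^-1).
DEFAULT_GRID = np.arange(500.0, 4000.0 + 0.5, 1.0)

#: Reference donor-acceptor distance about which stick peaks shift (Å).
HBOND_REFERENCE_DISTANCE = 2.9

_CLASH_DISTANCE = 0.5  # Å; below this any atom pair counts as a clash
_MAX_PROBES = 3  # NH3-like donor: at most three N-H directions
_FAR_DISTANCE = 8.0  # Å; parking distance of unengaged probe acceptors


@dataclass
class BasinSpec:
    """One conformational free-energy basin of the synthetic mixture.

    ``stick_peaks`` rows are (wavenumber cm^-1, intensity,
    hbond_shift_slope cm^-1/Å); the basin's line positions are
    wavenumber + slope * (hbond_distance_mean - 2.9 Å).
    """

    id: int
    population: float
    torsion_means: tuple  # degrees, one per free torsion
    torsion_concentrations: tuple  # von-Mises kappa, > 0
    hbond_distance_mean: float  # Å
    stick_peaks: tuple  # ((wavenumber, intensity, shift_slope), ...)
    n_acceptors: int = 1  # probes engaged at hbond_distance_mean (0..3)
    hbond_distance_sd: float = 0.05  # Å
    energy_offset: float = 0.0  # kcal/mol

    def __post_init__(self) -> None:
        if not 0.0 <= self.population <= 1.0:
            raise ValueError("population must lie in [0, 1]")
        if np.any(np.asarray(self.torsion_concentrations) <= 0):
            raise ValueError("torsion concentrations must be positive")
        if any(p[1] < 0 for p in self.stick_peaks):
            raise ValueError("stick intensities must be non-negative")
        if not 0 <= self.n_acceptors <= _MAX_PROBES:
            raise ValueError(f"n_acceptors must be in 0..{_MAX_PROBES}")


@dataclass
class SyntheticTruth:
    """Ground truth attached to a generated ensemble."""

    frame_labels: np.ndarray  # basin id per frame
    basin_specs: list
    seed: int
    probe_distances: np.ndarray  # (n_frames, n_probes) Å, engaged probes only
    reference_spectrum: GridSpectrum | None = None

    def populations(self) -> np.ndarray:
        return np.array([b.population for b in self.basin_specs])

    def empirical_fractions(self) -> np.ndarray:
        ids = [b.id for b in self.basin_specs]
        n = len(self.frame_labels)
        return np.array([np.sum(self.frame_labels == i) / n for i in ids])

    def to_json(self, path) -> None:
        obj = {
            "seed": self.seed,
            "frame_labels": [int(x) for x in self.frame_labels],
            "probe_distances": self.probe_distances.tolist(),
            "basin_specs": [
                {
                    "id": b.id,
                    "population": b.population,
                    "torsion_means": list(b.torsion_means),
                    "torsion_concentrations": list(b.torsion_concentrations),
                    "hbond_distance_mean": b.hbond_distance_mean,
                    "stick_peaks": [list(p) for p in b.stick_peaks],
                    "n_acceptors": b.n_acceptors,
                    "hbond_distance_sd": b.hbond_distance_sd,
                    "energy_offset": b.energy_offset,
                }
                for b in self.basin_specs
            ],
        }
        if self.reference_spectrum is not None:
            obj["reference_spectrum"] = {
                "grid": self.reference_spectrum.grid.tolist(),
                "intensity": self.reference_spectrum.intensity.tolist(),
            }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            obj = json.load(fh)
        ref = None
        if "reference_spectrum" in obj:
            ref = GridSpectrum(
                np.array(obj["reference_spectrum"]["grid"]),
                np.array(obj["reference_spectrum"]["intensity"]),
            )
        return cls(
            frame_labels=np.array(obj["frame_labels"], dtype=int),
            basin_specs=[
                BasinSpec(
                    id=b["id"],
                    population=b["population"],
                    torsion_means=tuple(b["torsion_means"]),
                    torsion_concentrations=tuple(b["torsion_concentrations"]),
                    hbond_distance_mean=b["hbond_distance_mean"],
                    stick_peaks=tuple(tuple(p) for p in b["stick_peaks"]),
                    n_acceptors=b["n_acceptors"],
                    hbond_distance_sd=b["hbond_distance_sd"],
                    energy_offset=b["energy_offset"],
                )
                for b in obj["basin_specs"]
            ],
            seed=obj["seed"],
            probe_distances=np.array(obj["probe_distances"], dtype=float),
            reference_spectrum=ref,
        )


# ---------------------------------------------------------------------------
# internal-coordinate chain template
# ---------------------------------------------------------------------------
# Rows: (species, bond_ref, r/Å, angle_ref, theta/deg, dih_ref, phi/deg,
#        torsion_index).  phi is the fixed part of the dihedral; when
# torsion_index is not None the frame's free torsion is added to it.
# The chain is a glycyl-glycine-like fragment with an NH3+-type N terminus
# (atom 0 with hydrogens 1-3), one amide N-H donor (7-8), a carbonyl, and a
# carboxyl group, giving N-H donors and O acceptors in one molecule.
_TEMPLATE = [
    ("N", None, 0.0, None, 0.0, None, 0.0, None),      # 0  N terminus
    ("H", 0, 1.01, None, 0.0, None, 0.0, None),        # 1
    ("H", 0, 1.01, 1, 107.0, None, 0.0, None),         # 2
    ("H", 0, 1.01, 1, 107.0, 2, 115.0, None),          # 3
    ("C", 0, 1.47, 1, 110.0, 2, -115.0, None),         # 4  C-alpha
    ("C", 4, 1.53, 0, 110.0, 1, 0.0, 0),               # 5  carbonyl C (T0)
    ("O", 5, 1.23, 4, 121.0, 0, 0.0, 1),               # 6  carbonyl O (T1)
    ("N", 5, 1.34, 4, 115.0, 0, 180.0, 1),             # 7  amide N
    ("H", 7, 1.01, 5, 119.0, 4, 180.0, None),          # 8  amide H
    ("C", 7, 1.45, 5, 122.0, 4, 0.0, None),            # 9  C-alpha 2
    ("H", 9, 1.09, 7, 109.0, 5, 120.0, 2),             # 10
    ("H", 9, 1.09, 7, 109.0, 5, -120.0, 2),            # 11
    ("C", 9, 1.53, 7, 110.0, 5, 0.0, 2),               # 12 carboxyl C (T2)
    ("O", 12, 1.23, 9, 121.0, 7, 0.0, 3),              # 13 carboxyl =O (T3)
    ("O", 12, 1.36, 9, 115.0, 7, 180.0, 3),            # 14 hydroxyl O
    ("H", 14, 0.97, 12, 106.0, 9, 0.0, None),          # 15
    ("H", 4, 1.09, 0, 109.5, 5, 120.0, None),          # 16
    ("H", 4, 1.09, 0, 109.5, 5, -120.0, None),         # 17
]

N_TORSIONS = 4
_DONOR_HYDROGENS = (1, 2, 3)  # hydrogens on the NH3-like terminus


def template_species(n_probes: int) -> list[str]:
    return [row[0] for row in _TEMPLATE] + ["O"] * n_probes


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def build_coordinates(torsions_deg: np.ndarray) -> np.ndarray:
    """Cartesian coordinates from the template for each torsion set.

    Parameters
    ----------
    torsions_deg:
        Array ``(n_frames, 4)`` of free torsions in degrees.

    Returns
    -------
    ndarray, shape (n_frames, 18, 3), Å.
    """
    tor = np.deg2rad(np.atleast_2d(np.asarray(torsions_deg, dtype=float)))
    n = tor.shape[0]
    xyz = np.zeros((n, len(_TEMPLATE), 3))
    for i, (_sp, b, r, a, theta, d, phi0, t_idx) in enumerate(_TEMPLATE):
        if i == 0:
            continue
        if i == 1:
            xyz[:, 1, 0] = xyz[:, b, 0] + r
            continue
        theta_r = np.deg2rad(theta)
        if i == 2:
            # in the xy-plane, at angle theta from the bond-ref -> angle-ref axis
            u = _normalize(xyz[:, a] - xyz[:, b])
            perp = np.zeros_like(u)
            perp[:, 1] = 1.0
            xyz[:, 2] = xyz[:, b] + r * (
                np.cos(theta_r) * u + np.sin(theta_r) * perp
            )
            continue
        phi = np.deg2rad(phi0) + (tor[:, t_idx] if t_idx is not None else 0.0)
        phi = np.broadcast_to(np.asarray(phi, dtype=float), (n,))
        B, A, D = xyz[:, b], xyz[:, a], xyz[:, d]
        bc = _normalize(B - A)
        n_vec = _normalize(np.cross(A - D, bc))
        m_vec = np.cross(n_vec, bc)
        ct, st = np.cos(theta_r), np.sin(theta_r)
        cp, sp = np.cos(phi), np.sin(phi)
        xyz[:, i] = (
            B
            - r * ct * bc
            + (r * st * cp)[:, None] * m_vec
            + (r * st * sp)[:, None] * n_vec
        )
    return xyz


def _attach_probes(
    xyz: np.ndarray, n_probes: int, distances: np.ndarray
) -> np.ndarray:
    """Append probe acceptor oxygens along the N-H directions of atom 0.

    ``distances`` has shape ``(n_frames, n_probes)``; probe ``j`` is placed
    at that distance from the donor nitrogen along the axis through
    hydrogen ``j``.
    """
    n_frames = xyz.shape[0]
    probes = np.empty((n_frames, n_probes, 3))
    origin = xyz[:, 0]
    for j in range(n_probes):
        u = _normalize(xyz[:, _DONOR_HYDROGENS[j]] - origin)
        probes[:, j] = origin + distances[:, j, None] * u
    return np.concatenate([xyz, probes], axis=1)


def _has_clash(coords: np.ndarray) -> np.ndarray:
    """Boolean per frame: any pair of atoms closer than the clash distance.

    The shortest bonded distance in the template is 0.97 Å, so a plain
    all-pairs check against 0.5 Å is sufficient.
    """
    diff = coords[:, :, None, :] - coords[:, None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    n_atoms = coords.shape[1]
    iu = np.triu_indices(n_atoms, k=1)
    return np.any(dist[:, iu[0], iu[1]] < _CLASH_DISTANCE, axis=1)


def _wrap_angle(delta_rad: np.ndarray) -> np.ndarray:
    return (delta_rad + np.pi) % (2.0 * np.pi) - np.pi


def generate_ensemble(
    basins,
    n_frames: int,
    temperature: float = 300.0,
    seed: int = 0,
    torsion_stiffness: float = 5.0,
    energy_noise_sd: float = 0.5,
    max_retries: int = 20,
):
    """Draw a labelled synthetic conformer ensemble from a basin mixture.

    Frames are drawn by sampling a basin with probability equal to its
    population, sampling torsions from von Mises distributions about the
    basin means, and rebuilding Cartesian coordinates from the fixed
    internal-coordinate template.  Per-frame energies follow
    ``offset + 0.5 * k * sum(dphi^2) + |N(0, sd)|`` (half-normal noise), and
    one exact basin-mean frame with energy equal to the basin offset is
    appended per basin, so each basin's lowest-energy frame is its appended
    ground-truth representative.

    Returns ``(ConformerEnsemble, SyntheticTruth)``.  Deterministic for a
    fixed ``seed``; all streams derive from one ``SeedSequence``.
    """
    basins = list(basins)
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not basins:
        raise ValueError("at least one basin required")
    pops = np.array([b.population for b in basins])
    if abs(pops.sum() - 1.0) > 1e-12:
        raise ValueError(f"basin populations sum to {pops.sum()}, expected 1")
    for b in basins:
        if len(b.torsion_means) != N_TORSIONS:
            raise ValueError(f"basin {b.id}: expected {N_TORSIONS} torsions")

    ss = np.random.SeedSequence(seed)
    rng_labels, rng_torsion, rng_probe, rng_energy = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    labels_pos = rng_labels.choice(len(basins), size=n_frames, p=pops)
    n_probes = max((b.n_acceptors for b in basins), default=0)

    means = np.deg2rad(np.array([b.torsion_means for b in basins]))
    kappas = np.array([b.torsion_concentrations for b in basins])
    d_means = np.array([b.hbond_distance_mean for b in basins])
    d_sds = np.array([b.hbond_distance_sd for b in basins])
    n_acc = np.array([b.n_acceptors for b in basins])

    def sample(rows):
        """Sample torsions (deg) and probe distances for label rows."""
        tor = rng_torsion.vonmises(means[rows], kappas[rows])
        dist = np.full((len(rows), n_probes), _FAR_DISTANCE)
        if n_probes:
            raw = rng_probe.normal(
                d_means[rows, None], d_sds[rows, None], size=(len(rows), n_probes)
            )
            engaged = np.arange(n_probes)[None, :] < n_acc[rows, None]
            dist = np.where(engaged, raw, _FAR_DISTANCE)
        return np.rad2deg(tor), dist

    torsions, probe_dist = sample(labels_pos)
    coords = _attach_probes(build_coordinates(torsions), n_probes, probe_dist)
    bad = _has_clash(coords)
    tries = 0
    while np.any(bad):
        tries += 1
        if tries > max_retries:
            raise RuntimeError(
                f"{bad.sum()} frames still clash after {max_retries} retries"
            )
        warnings.warn(f"regenerating {bad.sum()} clashing frames")
        rows = np.where(bad)[0]
        t_new, d_new = sample(labels_pos[rows])
        torsions[rows] = t_new
        probe_dist[rows] = d_new
        coords[rows] = _attach_probes(
            build_coordinates(t_new), n_probes, d_new
        )
        bad = _has_clash(coords)

    # energies: harmonic torsion penalty + half-normal noise
    dphi = _wrap_angle(np.deg2rad(torsions) - means[labels_pos])
    penalty = 0.5 * torsion_stiffness * np.sum(dphi**2, axis=1)
    offsets = np.array([b.energy_offset for b in basins])
    noise = np.abs(rng_energy.normal(0.0, energy_noise_sd, size=n_frames))
    energies = offsets[labels_pos] + penalty + noise

    # exact basin-mean frames: the ground-truth representatives
    rep_tor = np.rad2deg(means)
    rep_dist = np.full((len(basins), n_probes), _FAR_DISTANCE)
    if n_probes:
        engaged = np.arange(n_probes)[None, :] < n_acc[:, None]
        rep_dist = np.where(engaged, d_means[:, None], _FAR_DISTANCE)
    rep_coords = _attach_probes(build_coordinates(rep_tor), n_probes, rep_dist)
    if np.any(_has_clash(rep_coords)):
        raise RuntimeError("basin-mean reference geometry clashes")

    all_coords = np.concatenate([coords, rep_coords])
    all_energies = np.concatenate([energies, offsets])
    all_labels_pos = np.concatenate([labels_pos, np.arange(len(basins))])
    all_dist = np.concatenate([probe_dist, rep_dist])

    ids = np.array([b.id for b in basins])
    ensemble = ConformerEnsemble(
        species=template_species(n_probes),
        coords=all_coords,
        energies=all_energies,
        temperature=temperature,
    )
    truth = SyntheticTruth(
        frame_labels=ids[all_labels_pos],
        basin_specs=basins,
        seed=seed,
        probe_distances=all_dist,
    )
    return ensemble, truth


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def _shifted_lines(basin: BasinSpec, distance: float) -> np.ndarray:
    peaks = np.asarray(basin.stick_peaks, dtype=float)
    pos = peaks[:, 0] + peaks[:, 2] * (distance - HBOND_REFERENCE_DISTANCE)
    return np.column_stack([pos, peaks[:, 1]])


def basin_stick_spectrum(basin: BasinSpec) -> StickSpectrum:
    """The basin's stick spectrum at its characteristic H-bond distance."""
    if len(basin.stick_peaks) == 0:
        raise ValueError(f"basin {basin.id} has no stick peaks")
    return StickSpectrum(_shifted_lines(basin, basin.hbond_distance_mean))


def frame_stick_spectrum(truth: SyntheticTruth, frame: int) -> StickSpectrum:
    """Per-frame stick spectrum: basin lines shifted by the frame's actual
    mean engaged-probe distance (basin mean when no probe is engaged)."""
    bid = truth.frame_labels[frame]
    basin = next(b for b in truth.basin_specs if b.id == bid)
    if basin.n_acceptors > 0:
        d = float(np.mean(truth.probe_distances[frame, : basin.n_acceptors]))
    else:
        d = basin.hbond_distance_mean
    return StickSpectrum(_shifted_lines(basin, d))


def generate_reference_spectrum(
    truth: SyntheticTruth,
    fwhm: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> GridSpectrum:
    """Population-weighted broadened sum of the basin spectra, plus noise.

    The noise-free part is ``sum_k population_k * broaden(stick_k)``;
    Gaussian noise of the given standard deviation is added per grid point
    and the result clipped at zero.  Stored in ``truth.reference_spectrum``.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if grid is None:
        grid = DEFAULT_GRID.copy()
    total = np.zeros_like(np.asarray(grid, dtype=float))
    for b in truth.basin_specs:
        total = total + b.population * broaden(
            basin_stick_spectrum(b), fwhm, grid
        ).intensity
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        total = np.clip(total + rng.normal(0.0, noise_sd, total.shape), 0.0, None)
    ref = GridSpectrum(np.asarray(grid, dtype=float), total)
    truth.reference_spectrum = ref
    return ref


def default_basins() -> list:
    """The standard three-basin synthetic study conditions.

    Populations 0.6/0.3/0.1, torsion means separated by >= 90 degrees in
    several torsions (kappa = 80, circular sd ~ 6.4 degrees), distinct
    H-bond distances and engaged-acceptor counts, and per-basin stick peaks
    in the amide fingerprint and N-H stretch regions.
    """
    return [
        BasinSpec(
            id=0, population=0.6,
            torsion_means=(-60.0, -45.0, 180.0, 60.0),
            torsion_concentrations=(80.0, 80.0, 80.0, 80.0),
            hbond_distance_mean=2.85, n_acceptors=1,
            stick_peaks=(
                (1655.0, 1.0, -40.0), (1540.0, 0.7, -25.0),
                (1230.0, 0.4, 0.0), (3320.0, 0.5, -120.0),
            ),
        ),
        BasinSpec(
            id=1, population=0.3,
            torsion_means=(60.0, 120.0, -60.0, 180.0),
            torsion_concentrations=(80.0, 80.0, 80.0, 80.0),
            hbond_distance_mean=2.95, n_acceptors=2,
            stick_peaks=(
                (1680.0, 0.9, -40.0), (1515.0, 0.6, -25.0),
                (1300.0, 0.5, 0.0), (3410.0, 0.45, -120.0),
            ),
        ),
        BasinSpec(
            id=2, population=0.1,
            torsion_means=(180.0, -120.0, 60.0, -60.0),
            torsion_concentrations=(80.0, 80.0, 80.0, 80.0),
            hbond_distance_mean=3.05, n_acceptors=1,
            stick_peaks=(
                (1625.0, 1.1, -40.0), (1560.0, 0.5, -25.0),
                (1150.0, 0.35, 0.0), (3250.0, 0.6, -120.0),
            ),
        ),
    ]
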