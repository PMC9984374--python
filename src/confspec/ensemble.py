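"""Conformer-ensemble container and extended-XYZ trajectory I/O.

A :class:`ConformerEnsemble` holds the frames of a canonical-ensemble
trajectory: one fixed chemical composition, Cartesian coordinates per frame
(in Å) and a per-frame potential energy (kcal/mol) at a stated temperature.
Trajectories are persisted as extended XYZ, with the energy stored as an
``energy=<float>`` key on the comment line of every frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConformerEnsemble", "read_ensemble", "write_ensemble"]


@dataclass
class ConformerEnsemble:
    """Frames of a single molecule sampled at a fixed temperature.

    Parameters
    ----------
    species:
        Chemical element symbol per atom, shared by all frames.
    coords:
        Array of shape ``(n_frames, n_atoms, 3)``, Å.
    energies:
        Potential energy per frame, kcal/mol.
    temperature:
        Ensemble temperature in K.
    """

    species: list[str]
    coords: np.ndarray
    energies: np.ndarray
    temperature: float = 300.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.species):
            raise ValueError(
                f"species length {len(self.species)} does not match "
                f"atom count {self.coords.shape[1]}"
            )
        if self.energies.shape != (self.coords.shape[0],):
            raise ValueError("energies must be one value per frame")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        """Coordinates of frame ``i``, shape ``(n_atoms, 3)``."""
        return self.coords[i]

    def subset(self, indices) -> "ConformerEnsemble":
        idx = np.asarray(indices, dtype=int)
        return ConformerEnsemble(
            species=list(self.species),
            coords=self.coords[idx],
            energies=self.energies[idx],
            temperature=self.temperature,
        )


def write_ensemble(path, ensemble: ConformerEnsemble) -> None:
    """Write an ensemble as extended XYZ with per-frame ``energy=`` keys."""
    with open(path, "w") as fh:
        for f in range(ensemble.n_frames):
            fh.write(f"{ensemble.n_atoms}\n")
            fh.write(
                f"energy={ensemble.energies[f]:.12g} "
                f"temperature={ensemble.temperature:.12g} "
                "Properties=species:S:1:pos:R:3\n"
            )
            for s, (x, y, z) in zip(ensemble.species, ensemble.coords[f]):
                fh.write(f"{s} {x:.8f} {y:.8f} {z:.8f}\n")


def _parse_comment(line: str) -> dict:
    out = {}
    for tok in line.split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            out[k] = v
    return out


def read_ensemble(path) -> ConformerEnsemble:
    """Read an extended-XYZ trajectory written by :func:`write_ensemble`.

    Every frame must carry the same atom count and an ``energy=`` key in its
    comment line; violations raise ``ValueError`` naming the offending frame.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not any(line.strip() for line in lines):
        raise ValueError(f"{path}: empty trajectory file")

    species: list[str] | None = None
    frames: list[np.ndarray] = []
    energies: list[float] = []
    temperature = 300.0
    pos = 0
    frame_idx = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n_atoms = int(lines[pos].strip())
        except ValueError as exc:
            raise ValueError(
                f"{path}: frame {frame_idx}: expected atom count, "
                f"got {lines[pos]!r}"
            ) from exc
        if pos + 1 + n_atoms >= len(lines) + 1 and pos + 1 >= len(lines):
            raise ValueError(f"{path}: frame {frame_idx}: truncated frame")
        meta = _parse_comment(lines[pos + 1])
        if "energy" not in meta:
            raise ValueError(
                f"{path}: frame {frame_idx}: missing 'energy' key in comment line"
            )
        energies.append(float(meta["energy"]))
        if "temperature" in meta:
            temperature = float(meta["temperature"])
        sp = []
        xyz = np.empty((n_atoms, 3))
        body = lines[pos + 2 : pos + 2 + n_atoms]
        if len(body) < n_atoms:
            raise ValueError(f"{path}: frame {frame_idx}: truncated frame")
        for a, line in enumerate(body):
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(
                    f"{path}: frame {frame_idx}: malformed atom line {line!r}"
                )
            sp.append(parts[0])
            xyz[a] = [float(parts[1]), float(parts[2]), float(parts[3])]
        if species is None:
            species = sp
        elif sp != species or n_atoms != len(species):
            raise ValueError(
                f"{path}: frame {frame_idx}: inconsistent atom list "
                f"({n_atoms} atoms vs {len(species)} in frame 0)"
            )
        frames.append(xyz)
        pos += 2 + n_atoms
        frame_idx += 1

    return ConformerEnsemble(
        species=species,
        coords=np.stack(frames),
        energies=np.array(energies),
        temperature=temperature,
    )
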