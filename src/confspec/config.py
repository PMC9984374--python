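"""Validated run configuration (YAML-backed, unknown keys rejected)."""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field

import yaml

__all__ = [
    "RunConfig", "SyntheticConfig", "InputConfig", "DescriptorConfig",
    "ClusteringConfig", "HBondConfig", "SpectraConfig", "load_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticConfig(_Strict):
    """Synthetic-generation block (used when no trajectory is given)."""

    n_frames: int = 3000
    basins: str | list = "default"  # "default" or explicit basin dicts
    noise_sd: float = 0.0  # reference-spectrum noise (intensity units)
    energy_noise_sd: float = 0.5  # kcal/mol (half-normal)
    torsion_stiffness: float = 5.0  # kcal/mol/rad^2


class InputConfig(_Strict):
    """Paths for user-supplied data."""

    trajectory: str | None = None  # extended XYZ with energy= per frame
    reference_spectrum: str | None = None  # two-column text
    stick_spectra: list[str] | None = None  # one file per cluster
    scale_factor: float | None = None  # harmonic frequency scaling


class DescriptorConfig(_Strict):
    cutoff: float = 5.0  # Å
    n_max: int = 6
    l_max: int = 4
    atom_sigma: float = 0.4  # Å
    normalize: bool = True
    n_components: int = 2  # PCA dimensions used for clustering


class ClusteringConfig(_Strict):
    n_grid: int | None = None  # default min(1000, n_frames)
    # global-Silverman probe: appropriate at the ~10^3-frame scale of the
    # synthetic ensembles; small fractions (e.g. 0.008) refine the mode
    # search on much larger trajectories
    f_points: float = 1.0
    alpha: float = 0.9
    start_index: int = 0
    dip_threshold: float | None = 0.5
    # clusters below this fraction of frames are outlier islands and are
    # dissolved into their nearest neighbour
    min_cluster_weight: float = 0.05


class HBondConfig(_Strict):
    cutoff: float = 4.5  # Å donor-acceptor enumeration cutoff
    participation_threshold: float = 0.1
    kernel_width: float = 0.025
    bin_width: float = 0.05


class SpectraConfig(_Strict):
    fwhm: float = 10.0  # cm^-1 Gaussian broadening
    v_oi: float = 5.0  # cm^-1 Pendry Y-function parameter
    grid_min: float = 500.0
    grid_max: float = 4000.0
    grid_step: float = 1.0
    smooth_window: float = 0.0  # cm^-1; 0 disables reference smoothing
    n_fps_consistency: int = 3


class RunConfig(_Strict):
    seed: int = 0
    temperature: float = 300.0
    output_dir: str = "confspec_out"
    synthetic: SyntheticConfig = Field(default_factory=SyntheticConfig)
    input: InputConfig = Field(default_factory=InputConfig)
    descriptor: DescriptorConfig = Field(default_factory=DescriptorConfig)
    clustering: ClusteringConfig = Field(default_factory=ClusteringConfig)
    hbond: HBondConfig = Field(default_factory=HBondConfig)
    spectra: SpectraConfig = Field(default_factory=SpectraConfig)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)
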