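"""End-to-end orchestration: trajectory -> clusters -> statistics -> spectra.

Stage order (synthetic or user data): generate/load ensemble, SOAP
descriptors, PCA projection, density-based clustering with canonical
weights and representative conformers, H-bond statistics, spectral
broadening and population-weighted averaging, the hierarchical-merge
spectrum series, and Pendry reliability factors against the reference
spectrum.  The clustering stage is cached on disk keyed by a hash of the
parameters that affect it, so spectra-only parameter changes reuse the
same clustering.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import hbonds, synth
from .config import RunConfig
from .descriptors import SoapDescriptor, farthest_point_sampling, pca
from .ensemble import read_ensemble, write_ensemble
from .pamm import ClusterSet, MergeTree, PammClustering, merge_hierarchy
from .spectra import (
    GridSpectrum,
    broaden,
    ensemble_average,
    hierarchical_series,
    pendry_r,
    read_stick_spectrum,
    region_report,
    smooth,
)

__all__ = ["run", "RunReport", "within_cluster_consistency", "PipelineError"]


class PipelineError(RuntimeError):
    """Stage failure, naming the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class RunReport:
    """Artifacts of a completed run (all files exist on disk)."""

    output_dir: Path
    cluster_set: ClusterSet
    merge_tree: MergeTree | None
    summary: pd.DataFrame  # per-cluster H-bond/weight table
    ensemble_spectrum: GridSpectrum
    hierarchy_spectra: list
    pendry: list  # PendryResult per region, ensemble vs reference
    hierarchy_pendry: pd.DataFrame  # R_P per level and region
    consistency: pd.DataFrame
    files: dict


def _cluster_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {
            "seed": config.seed,
            "temperature": config.temperature,
            "synthetic": config.synthetic.model_dump(),
            "input": config.input.model_dump(),
            "descriptor": config.descriptor.model_dump(),
            "clustering": config.clustering.model_dump(),
        },
        sort_keys=True,
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:16]


def _resolve_basins(config: RunConfig):
    spec = config.synthetic.basins
    if spec == "default":
        return synth.default_basins()
    return [synth.BasinSpec(**b) for b in spec]


def _spectrum_grid(config: RunConfig) -> np.ndarray:
    s = config.spectra
    return np.arange(s.grid_min, s.grid_max + 0.5 * s.grid_step, s.grid_step)


def within_cluster_consistency(
    cluster_set: ClusterSet,
    X: np.ndarray,
    spectra_provider,
    n_fps: int = 3,
    v_oi: float = 5.0,
    region=None,
):
    """Pendry R between FPS-selected members of each cluster and every
    cluster representative.

    ``spectra_provider(frame_index)`` must return a :class:`GridSpectrum`.
    Returns ``(matrix, summary)``: the long-form R_P table and a per-cluster
    comparison of the mean within-cluster versus cross-cluster R_P.
    """
    X = np.asarray(X, dtype=float)
    rep_spectra = {
        c: spectra_provider(int(f))
        for c, f in enumerate(cluster_set.representative)
    }
    rows = []
    for c in range(cluster_set.n_clusters):
        members = np.where(cluster_set.labels == c)[0]
        k = n_fps
        if k > members.size:
            warnings.warn(
                f"cluster {c}: n_fps={n_fps} capped at size {members.size}"
            )
            k = members.size
        picked = [members[i] for i in farthest_point_sampling(X[members], k)]
        for f in picked:
            sf = spectra_provider(int(f))
            for r in range(cluster_set.n_clusters):
                rp = pendry_r(sf, rep_spectra[r], v_oi=v_oi, region=region).r_p
                rows.append(
                    {"cluster": c, "frame": int(f), "rep_cluster": r, "r_p": rp}
                )
    matrix = pd.DataFrame(rows)
    summary_rows = []
    for c in range(cluster_set.n_clusters):
        sub = matrix[matrix.cluster == c]
        within = sub[sub.rep_cluster == c].r_p
        cross = sub[sub.rep_cluster != c].r_p
        summary_rows.append(
            {
                "cluster": c,
                "within_mean_rp": within.mean(),
                "cross_mean_rp": cross.mean() if len(cross) else np.nan,
            }
        )
    return matrix, pd.DataFrame(summary_rows)


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline; deterministic for a fixed seed."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cache_dir = out / "cache"
    cache_dir.mkdir(exist_ok=True)
    files: dict = {}
    log: list = []

    def stage(name, params=None):
        log.append({"stage": name, "params": params or {}})

    # ------------------------------------------------------------------ data
    truth = None
    try:
        if config.input.trajectory:
            stage("load", {"trajectory": config.input.trajectory})
            ensemble = read_ensemble(config.input.trajectory)
        else:
            basins = _resolve_basins(config)
            stage("generate", {"n_frames": config.synthetic.n_frames,
                               "seed": config.seed, "n_basins": len(basins)})
            ensemble, truth = synth.generate_ensemble(
                basins,
                config.synthetic.n_frames,
                temperature=config.temperature,
                seed=config.seed,
                torsion_stiffness=config.synthetic.torsion_stiffness,
                energy_noise_sd=config.synthetic.energy_noise_sd,
            )
            synth.generate_reference_spectrum(
                truth,
                fwhm=config.spectra.fwhm,
                noise_sd=config.synthetic.noise_sd,
                seed=config.seed,
                grid=_spectrum_grid(config),
            )
            write_ensemble(out / "ensemble.xyz", ensemble)
            truth.to_json(out / "truth.json")
            files["ensemble"] = out / "ensemble.xyz"
            files["truth"] = out / "truth.json"
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("data", str(exc)) from exc

    # ----------------------------------------------------------- clustering
    chash = _cluster_hash(config)
    cache_file = cache_dir / f"cluster_{chash}.json"
    try:
        if cache_file.exists():
            stage("cluster", {"cached": str(cache_file)})
            blob = json.loads(cache_file.read_text())
            projected = np.array(blob["projected"])
            cluster_set = ClusterSet(
                labels=np.array(blob["labels"], dtype=int),
                weights=np.array(blob["weights"], dtype=float),
                representative=np.array(blob["representative"], dtype=int),
                n_clusters=int(blob["n_clusters"]),
            )
            tree = (
                MergeTree(cluster_set.n_clusters, blob["merges"],
                          np.array(blob["leaf_rep_energies"]))
                if blob["merges"] is not None else None
            )
        else:
            dc = config.descriptor
            stage("descriptors", dc.model_dump())
            soap = SoapDescriptor(
                cutoff=dc.cutoff, n_max=dc.n_max, l_max=dc.l_max,
                atom_sigma=dc.atom_sigma, normalize=dc.normalize,
            )
            values = soap.fit(ensemble).transform(ensemble)
            stage("pca", {"n_components": dc.n_components})
            proj = pca(values, n_components=dc.n_components)
            projected = proj.projected
            cc = config.clustering
            stage("pamm", cc.model_dump())
            model = PammClustering(
                n_grid=cc.n_grid, f_points=cc.f_points,
                alpha=cc.alpha, start_index=cc.start_index,
                dip_threshold=cc.dip_threshold,
                min_cluster_weight=cc.min_cluster_weight,
            ).fit(projected, energies=ensemble.energies)
            cluster_set = model.cluster_set(ensemble.energies)
            tree = (
                merge_hierarchy(cluster_set, model, energies=ensemble.energies)
                if cluster_set.n_clusters >= 2 else None
            )
            blob = {
                "projected": projected.tolist(),
                "labels": cluster_set.labels.tolist(),
                "weights": cluster_set.weights.tolist(),
                "representative": cluster_set.representative.tolist(),
                "n_clusters": cluster_set.n_clusters,
                "merges": tree.merges if tree else None,
                "leaf_rep_energies": (
                    tree.leaf_rep_energies.tolist() if tree
                    else ensemble.energies[cluster_set.representative].tolist()
                ),
            }
            cache_file.write_text(json.dumps(blob))
        files["cluster_cache"] = cache_file
        pd.DataFrame(
            {"frame": np.arange(ensemble.n_frames),
             "cluster": cluster_set.labels}
        ).to_csv(out / "labels.csv", index=False)
        files["labels"] = out / "labels.csv"
        if tree is not None:
            (out / "dendrogram.nwk").write_text(tree.to_newick())
            files["dendrogram"] = out / "dendrogram.nwk"
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("cluster", str(exc)) from exc

    # -------------------------------------------------------------- H bonds
    try:
        hb = config.hbond
        stage("hbond", hb.model_dump())
        counts = hbonds.count_ensemble(
            ensemble, cutoff=hb.cutoff,
            participation_threshold=hb.participation_threshold,
        )
        summary = hbonds.per_cluster_summary(
            counts, cluster_set.labels, cluster_set.weights,
            temperature=config.temperature, kernel_width=hb.kernel_width,
        )
        summary.to_csv(out / "cluster_summary.csv", index=False)
        files["summary"] = out / "cluster_summary.csv"
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("hbond", str(exc)) from exc

    # -------------------------------------------------------------- spectra
    try:
        sc = config.spectra
        grid = _spectrum_grid(config)
        stage("spectra", sc.model_dump())
        if truth is not None:
            def provider(f: int) -> GridSpectrum:
                return broaden(synth.frame_stick_spectrum(truth, f), sc.fwhm, grid)
            reference = truth.reference_spectrum
        elif config.input.stick_spectra:
            sticks = [
                read_stick_spectrum(p, scale_factor=config.input.scale_factor or 1.0)
                for p in config.input.stick_spectra
            ]
            if len(sticks) != cluster_set.n_clusters:
                raise ValueError(
                    f"{len(sticks)} stick spectra for "
                    f"{cluster_set.n_clusters} clusters"
                )
            rep_of_frame = {
                int(f): c for c, f in enumerate(cluster_set.representative)
            }

            def provider(f: int) -> GridSpectrum:
                if f not in rep_of_frame:
                    raise ValueError(f"no stick spectrum for frame {f}")
                return broaden(sticks[rep_of_frame[f]], sc.fwhm, grid)
            reference = (
                GridSpectrum.read(config.input.reference_spectrum)
                if config.input.reference_spectrum else None
            )
        else:
            raise ValueError("no spectra available: need synthetic truth or "
                             "input.stick_spectra")

        rep_spectra = {
            c: provider(int(f)) for c, f in enumerate(cluster_set.representative)
        }
        for c, s in rep_spectra.items():
            s.write(out / f"spectrum_cluster_{c}.txt")
            files[f"spectrum_cluster_{c}"] = out / f"spectrum_cluster_{c}.txt"
        ens_spec = ensemble_average(
            [rep_spectra[c] for c in range(cluster_set.n_clusters)],
            cluster_set.weights,
        )
        ens_spec.write(out / "spectrum_ensemble.txt")
        files["spectrum_ensemble"] = out / "spectrum_ensemble.txt"

        if tree is not None:
            series = hierarchical_series(tree, rep_spectra, cluster_set.weights)
        else:
            series = [ens_spec]
        for i, s in enumerate(series):
            level = cluster_set.n_clusters - i
            s.write(out / f"spectrum_level_{level}.txt")
            files[f"spectrum_level_{level}"] = out / f"spectrum_level_{level}.txt"

        pendry_results = []
        hier_rows = []
        if reference is not None:
            ref = smooth(reference, sc.smooth_window) if sc.smooth_window else reference
            pendry_results = region_report(ens_spec, ref, v_oi=sc.v_oi)
            for i, s in enumerate(series):
                level = cluster_set.n_clusters - i
                for res in region_report(s, ref, v_oi=sc.v_oi):
                    hier_rows.append(
                        {"n_clusters": level, "region_lo": res.region[0],
                         "region_hi": res.region[1], "r_p": res.r_p}
                    )
            pd.DataFrame(
                [{"region_lo": r.region[0], "region_hi": r.region[1],
                  "v_oi": r.v_oi, "r_p": r.r_p} for r in pendry_results]
            ).to_csv(out / "pendry.csv", index=False)
            (out / "pendry.json").write_text(json.dumps(
                [{"region": r.region, "v_oi": r.v_oi, "r_p": r.r_p}
                 for r in pendry_results]
            ))
            files["pendry"] = out / "pendry.csv"
        hier_df = pd.DataFrame(hier_rows)
        hier_df.to_csv(out / "pendry_hierarchy.csv", index=False)
        files["pendry_hierarchy"] = out / "pendry_hierarchy.csv"

        matrix, consistency = within_cluster_consistency(
            cluster_set, projected, provider,
            n_fps=sc.n_fps_consistency, v_oi=sc.v_oi,
        )
        matrix.to_csv(out / "consistency_matrix.csv", index=False)
        consistency.to_csv(out / "consistency_summary.csv", index=False)
        files["consistency"] = out / "consistency_summary.csv"
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("spectra", str(exc)) from exc

    (out / "run.json").write_text(json.dumps(
        {"config_hash": chash, "stages": log,
         "config": config.model_dump()}, default=str))
    files["run_log"] = out / "run.json"

    return RunReport(
        output_dir=out,
        cluster_set=cluster_set,
        merge_tree=tree,
        summary=summary,
        ensemble_spectrum=ens_spec,
        hierarchy_spectra=series,
        pendry=pendry_results,
        hierarchy_pendry=hier_df,
        consistency=consistency,
        files=files,
    )
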