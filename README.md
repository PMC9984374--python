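# confspec

Finite-temperature IR spectra of flexible molecules from conformer-ensemble
clustering.

## The problem

A flexible peptide at room temperature is not one structure but a canonical
ensemble of interconverting conformers, and a measured gas-phase IR spectrum
is the population-weighted superposition of their individual spectra.
Comparing a computed spectrum of a single minimum-energy structure against
experiment therefore misses most of the physics. `confspec` implements the
ensemble route:

1. **Describe** every trajectory frame by a rotation/translation/permutation
   invariant structural fingerprint — the averaged SOAP power spectrum
   p<sup>s₁s₂</sup><sub>n₁n₂l</sub> = Σ<sub>m</sub> c<sup>s₁</sup><sub>n₁lm</sub> c<sup>s₂</sup><sub>n₂lm</sub>*
   of the Gaussian-smeared neighbour density — and project it onto its first
   principal components.
2. **Cluster** the conformer map PAMM-style: farthest-point-sampled
   landmarks, a kernel density estimate with a localised Silverman
   bandwidth, quick-shift mode seeking with cutoff α·λ, a density-dip
   postmerge, and canonical weights w<sub>c</sub> = n<sub>c</sub>/n with the
   lowest-energy frame of each cluster as its representative conformer.
3. **Count hydrogen bonds** continuously: each N–H⋯O triplet gets a 0–1
   membership (mixture posterior in (ν, μ, d<sub>DA</sub>) coordinates,
   ν = d<sub>DH</sub>−d<sub>AH</sub>, μ = d<sub>DH</sub>+d<sub>AH</sub>), summed into
   per-atom counts s_D, s_A, s_H, smoothed probability surfaces and free
   energies F = −k_BT ln P.
4. **Average spectra**: per-representative stick spectra are broadened with
   10 cm⁻¹-FWHM Gaussians, combined with the cluster weights, and tracked
   along the Ward-adjacency merge hierarchy from all clusters down to one.
5. **Compare** to a reference spectrum with the Pendry reliability factor
   R_P = Σ(Y_a−Y_b)² / Σ(Y_a²+Y_b²), Y = L/(1+v_oi²L²), L = I′/I, reported
   per spectral window (amide fingerprint 600–1800 cm⁻¹ and stretch
   2700–3600 cm⁻¹). R_P = 0 is a perfect match, R_P = 1 no correlation.

Because raw replica-exchange trajectories, per-conformer harmonic spectra
and action-spectroscopy references are rarely available together, the
package ships a first-class synthetic generator: a ~20-atom peptide-like
chain with four free torsions sampled from a mixture of conformational
basins with prescribed populations, per-basin hydrogen-bond geometry and
stick spectra whose lines shift with H-bond distance — so every pipeline
stage can be validated against known ground truth.

## Worked example

```python
import numpy as np
import confspec as cs

basins = cs.default_basins()          # populations 0.6 / 0.3 / 0.1
ens, truth = cs.generate_ensemble(basins, 3000, seed=0)
ref = cs.generate_reference_spectrum(truth, fwhm=10.0, noise_sd=0.0)

values = cs.SoapDescriptor().fit(ens).transform(ens)
X = cs.pca(values, n_components=2).projected
model = cs.PammClustering(f_points=1.0, alpha=0.9,
                          min_cluster_weight=0.05).fit(X)
cset = model.cluster_set(ens.energies)
print(cset.n_clusters, np.round(np.sort(cset.weights)[::-1], 3))

rep = {c: cs.broaden(cs.frame_stick_spectrum(truth, int(f)), 10.0, ref.grid)
       for c, f in enumerate(cset.representative)}
avg = cs.ensemble_average([rep[c] for c in range(cset.n_clusters)],
                          cset.weights)
rp = cs.pendry_r(avg, ref, v_oi=5.0, region=(600.0, 1800.0))
print(round(rp.r_p, 4))
```

prints

```
3 [0.594 0.3   0.106]
0.0001
```

— the clustering recovers the three generating basins with weights within
±0.01 of the true populations (0.6/0.3/0.1), and the weighted average of
the three representative spectra reproduces the noise-free reference with a
fingerprint-region Pendry factor of ~10⁻⁴ (0 = perfect match).

The same analysis runs from the shell:

```bash
confspec run --seed 0 --output-dir out/
```

which writes the per-cluster weight/H-bond table (`cluster_summary.csv`),
frame labels, the Newick dendrogram, per-cluster / ensemble / per-merge-level
spectra as two-column text, Pendry region reports and the within-cluster
consistency matrix. `confspec synth`, `cluster`, `hbond`, `spectra` and
`report` expose the individual stages.

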