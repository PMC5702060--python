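# puffmapper

Automated detection of Ca²⁺ puffs in TIRF-microscopy movies, assignment of
puffs to immobile release sites, and estimation of the total number of
release sites per cell.

Ca²⁺ puffs are brief (~hundreds of ms), local (~2 µm) cytosolic Ca²⁺
transients produced when a small cluster of IP₃ receptors opens together;
they are the building blocks of IP₃-evoked Ca²⁺ signals. In cells
stimulated through endogenous receptors (e.g. carbachol on HEK293 cells),
puffs appear against a slowly rising global fluorescence that eventually
erupts into a cell-wide wave, and each short stimulation reveals only a
fraction of the sites capable of firing. This package is for researchers
who record such movies (or want to benchmark detection algorithms) and
need a reproducible, scriptable version of the analysis chain:

- **detection** — per-pixel F/F₀ normalisation, frame-to-frame
  differencing (ΔF), subtraction of the per-frame cell-mean (ΔΔF, which
  cancels the creeping global rise), per-pixel thresholds
  T1 = µ + 3.4·σ and T2 = µ + 2.45·σ, candidate 5×5 matrices requiring
  ≥ 18 supra-T2 pixels, boundary expansion to a rectangle, temporal
  merging, and measurement via an elliptical 2D Gaussian fit with
  sub-pixel centroid;
- **site mapping** — greedy amalgamation of puff centroids, ranked by
  signal mass, within a 0.96 µm (6-pixel) radius with iterative
  recentring;
- **site statistics** — puff frequency density (Hz/µm²), site density,
  puffs-per-site histograms, discovery curves, and two estimators of the
  total site number N: capture–recapture, N̂ = n₂/f (sites seen in a
  second challenge divided by the fraction also seen in the first), and a
  zero-truncated Poisson model, µ̂ solving µ/(1−e^(−µ)) = mean observed
  puffs/site and N̂ = observed/(1−e^(−µ̂));
- **synthetic movies** — a generator with full ground truth (immobile
  sites, Poisson firing, one-frame-rise/exponential-decay puffs, creeping
  drift, terminal wave, Gaussian noise) so the whole chain is testable
  without microscope data.

See `docs/methods.md` for the model, parameter meanings and defaults, and
design decisions.

## Worked example

```python
import puffmapper as pm

sim = pm.SimulationConfig(n_frames=300, image_shape=(128, 128), n_sites=20,
                          cell_radius_um=8.0, firing_rate=0.25, rng_seed=42,
                          drift_rate=0.02)
stack, mask, truth = pm.simulate_movie(sim)
roi = pm.CellROI(mask=mask, pixel_size=sim.pixel_size)
result = pm.detect_puffs(stack, roi, pm.PipelineConfig())
sites = pm.assign_sites(result.puffs, merge_radius=0.96)

print(f"cell area: {roi.area:.1f} um^2")
print(f"planted puffs: {len(truth['puffs'])}, detected: {len(result.puffs)}")
p = result.puffs[0]
print(f"first puff: onset frame {p.onset_frame}, centroid "
      f"({p.centroid[0]:.2f}, {p.centroid[1]:.2f}) um, amplitude "
      f"{p.amplitude:.2f} dF/F0, diameter {p.diameter:.2f} um")
est = pm.estimate_N_poisson([s.puff_count for s in sites])
print(f"zero-truncated Poisson: mu = {est.inputs_summary['mu_hat']:.2f}, "
      f"N = {est.N_hat:.1f} (vs {sim.n_sites} planted)")
```

prints

```
cell area: 202.0 um^2
planted puffs: 43, detected: 41
first puff: onset frame 54, centroid (4.97, 9.83) um, amplitude 0.49 dF/F0, diameter 2.59 um
zero-truncated Poisson: mu = 2.31, N = 17.8 (vs 20 planted)
```

41 of 43 planted puffs are recovered (the misses are low-amplitude events
below threshold, and no false positives occur); 16 sites are found,
exactly the planted sites that fired; and the zero-truncated Poisson
extrapolation estimates 17.8 total sites against 20 planted — it can only
see sites with a nonzero chance of firing in the window, so modest
underestimation at low firing rates is expected.

The same pipeline is available from the shell:

```bash
puffmapper simulate --config sim.yaml --out run/ --seed 7
puffmapper all --stack run/movie.tif --mask run/mask.tif --out run/analysis/
```

which writes `puffs.csv`, `sites.csv`, `stats.json`, a site-map overlay
PNG and a log with the config echo.

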