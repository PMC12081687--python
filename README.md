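# bmrisk — brain-metastasis spatial risk analysis

Brain metastases (BM) do not appear uniformly in the brain: clinical series
show them clustering near the gray–white matter junction and in well-perfused
territory, while the deep subcortical structures are relatively spared. Those
regularities matter for two audiences — biologists asking *why* metastases
seed where they do, and radiation oncologists asking whether whole-brain
radiotherapy (WBRT) can spare the functionally critical deep structures
without missing future disease.

`bmrisk` is an analysis pipeline for exactly these questions, built so that
every stage is testable without any external imaging data. It provides:

- a **synthetic brain phantom** (nested-ellipsoid cerebrum/cerebellum with a
  cortical gray shell, deep nuclei, ventricles, brainstem, four label
  atlases — coarse/fine anatomical, functional, vascular — and a perfusion
  field), plus a **cohort simulator** that places lesions by an inhomogeneous
  point process with intensity

  ```
  λ(x) ∝ m(region(x)) · exp(−d_interface(x)/τ) · perfusion(x)^γ
  ```

  restricted to parenchyma, with zero-truncated negative-binomial lesion
  counts (median 2) and log-normal volumes (0.002–62 cc);
- **voxelwise risk maps**: the cumulative lesion count
  `C(x) = Σ_i Σ_l [x ∈ lesion_il]` over patients `i` and lesions `l`, with
  per-region contribution percentages (95% t-intervals over sites) and a
  density enrichment ratio (share of lesions ÷ share of parenchymal volume;
  1 under uniform seeding);
- a **tissue-morphology null test** for interface proximity: the cortical
  ribbon is thin, so tissue itself concentrates near the interface; the test
  compares the lesion-centroid distance histogram against the tissue-volume
  histogram with the 1-D Wasserstein distance and a calibrated Wilcoxon
  signed-rank test;
- **perfusion analyses**: normalized-perfusion joint histograms and the
  fraction of lesion volume inside a perfusion × interface-distance subspace;
- **function-sparing target construction**: Boolean whole-brain targets minus
  isotropically expanded spared-structure unions (WBRT, hippocampal-avoidance
  WBRT-HA, and WBRT-PROTECT = 3 mm expansion of hippocampi + amygdala +
  thalamus + pallidus + caudate + putamen + brainstem + ventricles), each
  scored by expected lesion coverage;
- lesion **morphometrics** (26-connected components, Wadell sphericity
  `π^{1/3}(6V)^{2/3}/A`, centroids, interface distances, atlas memberships),
  contour rasterization, NIfTI/CSV/JSON/SQLite I/O, and a statistics module
  (Welch's t, exact Wilcoxon signed-rank, 1-D Wasserstein, 95% t-intervals).

## Worked example

The numbered scripts under `analysis/` run the full study on a 96³ phantom at
2 mm with a 300-patient, 4-site simulated cohort (τ = 15 mm interface bias,
γ = 1 perfusion weighting, 2.8× cerebellar enrichment, subcortical sparing):

```bash
python analysis/01_build_phantom.py
python analysis/02_simulate_cohort.py
...
python analysis/07_sparing_tradeoff.py
```

Selected output (what the scripts actually print):

```
lesions/patient: median 2, mean 3.57, range 1-21
lesion volume cc: median 0.200, range 0.008-15.94

lesions within 5 mm of interface: 73.9%
tissue volume within 5 mm:        51.7%
over-representation:              +22.1 pp
Wilcoxon p (two-sided):           4.82e-59
-> interface proximity exceeds the tissue-morphology expectation

        plan  spared_volume_fraction  coverage_pct
        wbrt                    0.00        100.00
     wbrt-ha                    0.01         99.44
wbrt-protect                    0.06         96.18
```

Reading this: the simulated cohort reproduces the clinical lesion-count and
volume distributions; 74% of lesions sit within 5 mm of the gray–white
interface versus 52% of tissue volume, so proximity is a real spatial
association, not an artifact of cortical folding (+22 percentage points,
p ≪ 0.05); and sparing the expanded subcortical union (≈6% of brain volume)
still covers ≈96% of expected metastases, versus 100% for plain WBRT.

A `bmrisk` CLI wraps the same stages (`bmrisk simulate|metrics|riskmap|
nulltest|perfusion|coverage|run`), e.g.
`bmrisk coverage --seed 1 --n-patients 100 --out results/`.

## Layout

```
src/bmrisk/        library: phantom, geometry, riskmap, interface_null,
                   perfusion, sparing, stats, io, pipeline, cli
analysis/          numbered narrative drivers (01–07) writing results/
scripts/           acceptance.py
tests/             pytest suite with independent brute-force oracles
docs/methods.md    model, parameters, calibration and limitations
```
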