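# dimerlab

Integrative biophysical analysis of multidomain homodimers that close at
one end.

Many co-chaperones — SGTA is the motivating case — are elongated
homodimers: an obligate dimerization domain at the N-terminus, a central
TPR (tetratricopeptide-repeat) domain, and a substrate-binding C-terminal
region, all connected by flexible linkers.  Whether the two C-terminal
regions also dimerize ("closing" the molecule like tweezers) cannot be
read off any single experiment; it shows up only as a *converging pattern*
across four solution techniques:

1. **SAXS** — the inter-domain peak of the pair-distance distribution
   P(r) is more pronounced, and EOM-style ensemble selection picks
   conformers with a markedly lower radius of gyration than its pool;
2. **NMR relaxation** — the central domain tumbles more slowly
   (larger rotational correlation time τc);
3. **DEER/PELDOR** — distances between spin labels placed at homologous
   TPR sites in the two protomers shorten;
4. **native MS** — the intact dimer (and, in the closed-competent
   constructs, a ladder of small-molecule adducts) survives electrospray.

`dimerlab` implements each analysis from first principles and a
coarse-grained generator that produces open, closed, or mixed dimer
ensembles, so the whole cross-technique argument can be rehearsed — and
tested — on synthetic data with known ground truth.

## The models at the core

* **Conformers**: one bead per residue at the CA position, 0.38 nm virtual
  bonds, 0.34 nm excluded volume; rigid domains are rigid-body copies of
  compact templates, linkers are self-avoiding walks.  A *closed* dimer
  additionally satisfies a C-terminal center-center contact and packs the
  two central domains side by side.
* **SAXS**: Debye sum `I(s) = Σᵢⱼ wᵢwⱼ sinc(s·rᵢⱼ)`; Guinier fit of
  `ln I` vs `s²` with a self-consistent `s·Rg` window; regularized,
  non-negative indirect Fourier transform for P(r) with
  `I(s) = 4π ∫ p(r) sinc(sr) dr`; Porod invariant `Q = ∫ s²I ds` and
  volume `Vp = 2π² I(0)/Q`; genetic-algorithm selection of an ensemble
  whose average curve fits the data (EOM logic).
* **DEER**: powder-averaged dipolar kernel
  `K(t,r) = ∫₀¹ cos[(1−3x²) ω(r) t] dx`, `ω/2π = 52.04 MHz·nm³/r³`;
  homogeneous 3-D background `exp(−kt)`; Tikhonov inversion
  `min ‖KP − S‖² + α²‖LP‖²` with `P ≥ 0` and L-curve α selection.
* **NMR**: per-residue single-exponential T1/T2 fits and the isotropic
  slow-tumbling estimate `τc = (1/4πν_N)·√(6 T1/T2 − 7)`; heteronuclear
  NOE ratios; combined amide shift perturbation
  `Δδ = √(ΔδH² + (0.14·ΔδN)²)`; chemical-shift-index calls from Cα/CO
  deviations from random coil.
* **native MS**: consecutive-charge-series assignment
  `M = z·(m/z − m_p)`, intensity-weighted mass deconvolution, oligomer
  calls, and grid-search detection of repeated-adduct mass ladders
  `Mᵢ ≈ M₀ + kᵢ·a`.

## Worked example

```bash
dimerlab run --out run1      # default config: closed scenario, seed 1234
```

or in Python:

```python
from dimerlab import workbench as wb
cfg = wb.ExperimentConfig({"scenario": "closed", "seed": 1,
                           "ensemble_size": 12, "pool_size": 20,
                           "eom_pick": 5})
print(wb.render_summary(wb.run_virtual_experiment(cfg)))
```

prints

```
dimerlab virtual experiment (config 7f64ed86f5f723a4)
scenario: closed

closed-state signatures (test scenario vs open reference):
  [PASS] interdomain_peak_pronounced: ref=0.14021748807082746 test=0.18852961550537572 effect=1.3446
  [PASS] eom_rg_compaction: ref=3.6365 test=3.3546 effect=0.5064
  [PASS] tpr_tumbling_slowed: ref=9.532 test=12.045 effect=2.513
  [PASS] deer_mode_shorter: ref=4.9 test=3.9225 effect=0.9775

all four signatures: YES
```

Reading the four lines: the closed ensemble's inter-domain P(r) peak is
1.34× the open reference (threshold 1.1); EOM selection drops the mean Rg
from the pool's 3.64 nm to 3.35 nm (0.51 pool-SDs); the TPR-domain τc
rises from 9.5 ns to 12.0 ns; and the C-proximal interlabel DEER mode
shortens by ~1 nm.  Re-running with `"scenario": "open"` turns every
signature off — the same pipelines, fed an open ensemble, find nothing.

Per-technique entry points (`dimerlab saxs guinier`, `dimerlab deer
invert`, `dimerlab nmr tc`, `dimerlab ms deconvolve`, ...) expose the
individual analyses on standard ASCII/TSV files; see `--help`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full virtual experiment from scratch at the given seed — the
closed scenario and its open reference — prints both signature summaries
and their deltas, and writes the results JSON to `--out`.
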