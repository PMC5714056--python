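# marct — metal artifact reduction in CT and its dosimetric consequences

Metal implants corrupt CT images through two distinct physical mechanisms:
**beam hardening** (a polychromatic beam's mean energy rises along its path,
most relevant for low-Z metals such as titanium) and **photon starvation**
(detector bins behind dense high-Z metal such as Cerrobend receive
essentially zero counts, so their log-normalized projections are meaningless).
The resulting streaks do not just look bad — they distort the Hounsfield
units that radiotherapy planning converts to electron density, and therefore
distort computed dose.

`marct` is a desk-scale, fully synthetic phantom study of exactly this
problem, built around a Gammex-467-style cylindrical phantom whose two insert
slots hold 1 cm titanium rods (ρ = 4.540 g/cm³), 3 cm Cerrobend rods
(ρ = 9.760 g/cm³), or 3 cm solid-water rods (ρ = 1.004 g/cm³).  It provides:

* a polychromatic 140 kVp parallel-beam CT simulator (exact Siddon ray
  traversal, Poisson counts, scanner-style water calibration, ramp-filtered
  backprojection onto the fixed HU range [−1024, 3071]);
* a two-stage sinogram-domain **MAR** algorithm: a *physics correction*
  that inverts a two-material lookup `p_poly(t_water, t_metal)` to replace
  metal-crossing projections by their monochromatic equivalent
  `μ_w(E_ref)·t_w + μ_m(E_ref)·t_m`, and an *iterative regularized
  completion* of photon-starved projections that minimizes a sinogram
  Laplacian penalty under the parallel-beam mass-conservation constraint
  (every view's 0th moment equals the clean-view median mass);
* an artifact-free **ground truth** built the same way the study defines
  it: a metal-free scan with the insert voxels substituted in software;
* a 5-beam IMRT-style planning chain (HU → relative electron density via a
  piecewise-linear calibration, beam angles chosen to avoid the metal on
  the way to the target, nonnegative-least-squares fluence optimization to
  a 10 Gy prescription on the *uncorrected* image, kerma-approximation dose
  recomputation with fixed fluence on uncorrected / corrected / ground-truth
  volumes, plus a Compton Monte Carlo cross-check engine);
* the evaluation suite: voxelwise difference statistics, cumulative DVHs,
  D95/D98/D100, the relative accuracy error
  `Acc_x = |D_x − D_x^GT| / D_x^GT · 100`, Wilcoxon–Mann–Whitney tests and
  dose-difference maps, assembled into a deterministic JSON/CSV report.

## Worked example

```python
from marct.io import RunConfig
from marct.study import run_study
from marct.evaluation import accuracy_table

report = run_study(RunConfig(master_seed=1))
for name in ("low_z", "high_z"):
    image = report["configurations"][name]["image"]
    u, c = image["uncorrected_minus_gt"], image["corrected_minus_gt"]
    print(f"{name}: uncorrected-GT {u['mean']:+.1f} +/- {u['std']:.1f} HU | "
          f"corrected-GT {c['mean']:+.1f} +/- {c['std']:.1f} HU")
print(accuracy_table(report).to_string(index=False))
```

prints (about 20 s on one CPU):

```
low_z: uncorrected-GT +0.9 +/- 38.1 HU | corrected-GT -0.1 +/- 12.0 HU
high_z: uncorrected-GT +219.9 +/- 836.2 HU | corrected-GT -1.5 +/- 36.7 HU
configuration  ptv metric  uncorrected_pct  corrected_pct
       high_z PTV1  Acc95            14.24           0.17
       high_z PTV1  Acc98            13.85           0.00
       high_z PTV1 Acc100            12.56           0.48
       high_z PTV2  Acc95            10.05           0.00
       high_z PTV2  Acc98            12.77           0.00
       high_z PTV2 Acc100            13.30           0.49
       high_z PTV3  Acc95             3.54           0.05
       high_z PTV3  Acc98             2.85           0.00
       high_z PTV3 Acc100             4.74           0.00
        low_z PTV1  Acc95             0.00           0.00
        ...
```

Reading: the high-Z (Cerrobend) phantom corrupts the uncorrected image by
±836 HU and biases PTV dose metrics by up to ~14% of their ground-truth
values; after MAR correction the image residual drops to ±37 HU and every
dose metric is within 0.5% of ground truth.  The low-Z (titanium) phantom
produces only mild artifacts (±38 HU) and sub-percent dose errors even
without correction, mirroring the low-Z / high-Z dichotomy the method is
built around.

The same pipeline is scriptable from the shell (`marct study-run --seed 1
--out results/run1`, plus `phantom-build`, `ct-simulate`, `mar-run`,
`plan-optimize`, `dose-compute`, `eval-report` subcommands); every command
takes `--seed` and `--log-level`, and a study directory contains the report
JSON, the accuracy CSV, every intermediate volume as NRRD, the plan fluence
files, and a manifest with SHA-256 hashes.

## Limitations

The simulator is a desk-scale stand-in, not a scanner model: parallel-beam
geometry, a 12-bin spectrum, no scatter, no automatic exposure control, a
kerma-approximation dose engine with monoenergetic 2 MeV photons, and a
128×128 @ 3 mm default grid.  See `docs/methods.md` for the model,
parameter choices, and what the synthetic experiment does and does not
demonstrate about clinical data.
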