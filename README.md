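# condquant

Quantification toolkit for biomolecular-condensate experiments, built for
labs studying liquid-liquid phase separation (LLPS) of RNA-binding
proteins such as YBX1 and its consequences for RNA sorting. It covers the
standard measurements of such a study:

* **Droplet partitioning** (in vitro assays): threshold-based droplet
  masks, the partition coefficient `PC = I_DP / I_LP` (dense-phase over
  light-phase mean intensity) and the relative condensed fraction
  `RC = I_in / (I_in + I_out)`, single- or two-channel (protein mask
  applied to an RNA channel), plus concentration titrations with onset
  detection.
* **FRAP** (molecular mobility): the double normalization
  `BL_corr2 = (BL − BG)/(REF − BG)`, `BL_corr3 = BL_corr2 / BL_corr2(pre-bleach)`,
  single-exponential recovery fits
  `f(t') = plateau − (plateau − f0)·e^(−t'/τ)`, mobile fraction
  `(plateau − f0)/(1 − f0)`, and batch mean ± SE curves.
* **Puncta dissolution** (hexanediol-type treatments): per-frame puncta
  counts, survival normalized to the treatment frame, exponential
  half-life fits.
* **IDR sequence features**: sliding-window net charge per residue
  (NCPR, R/K = +1, D/E = −1, window 5), residue-class composition, and
  construction of substitution (Y→S, RK→G, …) and deletion mutants.
* **Cross-assay statistics**: proteome overlap counts and percentages,
  and exosomal miRNA enrichment from qPCR cycle thresholds
  (`2^(Ct_cell − Ct_exo)`, relative enrichment = condition/control fold
  change).
* **Synthetic data** (`condquant.simulate`): seeded generators for
  droplet fields, FRAP traces, dissolution stacks and gene sets, each
  with analytic ground truth, so every stage is testable without any
  microscope.

See `docs/methods.md` for models, conventions and limitations.

## Worked example

```python
from condquant import droplets, frap, simulate

# a two-channel field with known ground truth (PC = 10 in both channels)
fld = simulate.gen_droplet_field(
    simulate.DropletFieldSpec(seed=7, noise_sd=2.0, camera_offset=5.0,
                              i_dense2=50.0, i_dilute2=5.0))
protein = droplets.subtract_dark_frame(fld.protein, fld.dark)
rna = droplets.subtract_dark_frame(fld.rna, fld.dark)
fq_protein, fq_rna = droplets.field_quant_two_channel(protein, rna)
print(f"protein: n={fq_protein.n_droplets}  PC={fq_protein.pc:.2f}  RC={fq_protein.rc:.4f}")
print(f"miRNA:   n={fq_rna.n_droplets}  PC={fq_rna.pc:.2f}  RC={fq_rna.rc:.4f}")

# a noisy FRAP acquisition (2 s/frame), corrected and fitted
trace, truth = simulate.gen_frap_trace(
    simulate.FRAPTraceSpec(f0=0.25, plateau=0.70, tau_s=20.0,
                           acquisition_bleach_rate=0.002, noise_sd=0.02, seed=7))
fit = frap.fit_recovery(frap.correct_trace(trace))
print(f"tau={fit.tau_s:.1f} s  half-time={fit.half_time_s:.1f} s  "
      f"mobile fraction={fit.mobile_fraction:.2f}")
print(f"recovery at 90 s: {frap.recovery_at(fit, 90.0):.2f}")
```

prints

```
protein: n=8  PC=10.00  RC=0.1417
miRNA:   n=8  PC=10.04  RC=0.1419
tau=20.4 s  half-time=14.1 s  mobile fraction=0.61
recovery at 90 s: 0.70
```

All 8 generated droplets are found; the protein partition coefficient is
exact (noise averages out of the dense/dilute means) and the RNA channel,
quantified against the protein mask, recovers its own tenfold
partitioning. The FRAP fit recovers the generating time constant within
noise, and the fitted curve reaches 70 % of the pre-bleach signal by
90 s — the wild-type-cell scenario.

A `condquant` command-line tool wraps the same functions
(`condquant droplets|frap|puncta|ncpr|mutate|overlap|enrich|simulate …`);
every run writes a manifest JSON recording inputs, parameters, seed and
version. Exit codes: 0 success, 1 usage error, 2 data error.

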