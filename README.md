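# hcnmeter

Data reduction and calibration for field quantification of plant
cyanogenesis with a portable hydrogen cyanide gas meter.

Thousands of plant species (and some arthropods) release HCN gas when their
tissue is crushed, via β-glucosidase hydrolysis of cyanogenic glycosides.
A fast, inexpensive field assay crushes a weighed tissue sample inside a
small closed chamber — a snap-lid plastic cup (0.143 L), an airtight
mortar-pestle unit (0.052 L), or a glass desiccator jar (9.6 L) — and pumps
the headspace through an HCN meter at fixed intervals until readings fall
below the 0.3-ppm detection limit. This package turns those time-stamped
ppm series into calibrated HCN concentrations and release-kinetics
statistics, and provides the calibration machinery and a forward simulator
to validate the whole workflow. It is aimed at chemical ecologists running
such assays and at anyone calibrating one measurement method against
another under a fixed-ratio hypothesis.

## The core quantities

* **ppm → micromoles.** At STP, a mixing ratio of *p* ppm (v/v) in a chamber
  of volume *V* litres holds *p·V/22.4* μmol HCN; dividing by fresh tissue
  mass gives μmol/g. Each evacuation removes the full chamber contents, so a
  sample's total release is the sum of its quantifiable readings converted
  this way.
* **Calibration factor.** The open cup protocol under-recovers chamber HCN;
  regressing log₁₀ closed-jar values on log₁₀ cup values gives a slope ≈ 1
  (fixed ratio) with intercept *b*, and the ratio 10^b ≈ 10.2 multiplies cup
  values onto closed-chamber truth.
* **Weighted mean release duration.** D = Σ tₙ·ppmₙ / Σ ppmₙ over positive
  readings — a scale-free statistic that separates fast (minutes) from slow
  (hour-scale) cyanogen release.
* **Standards.** Amygdalin (457.4 g/mol, one HCN per molecule) gives
  59.09 μg HCN per mg, anchoring standard curves of mass against meter ppm.
* **Forward simulator.** Release is a two-exponential mixture
  Q(t) = q·[f(1−e^(−k_f(t−L))) + (1−f)(1−e^(−k_s(t−L)))]; chamber headspace
  follows dC/dt = Q′(t)/V − λC with an analytic solution, and both meter
  protocols (evacuation cup, closed jar) are emulated with multiplicative
  noise, 0.1-ppm quantization and the detection floor.

## Worked example

Reduce a one-sample study (0.1 g of leaf in the cup; readings 10, 5 and
0.2 ppm at 5, 10 and 15 min — the last is below the 0.3-ppm floor and is
excluded):

```
$ cat samples.csv
sample_id,species,tissue,mass_g,method
a1,P. biflora,leaf,0.1,cup
$ cat readings.csv
sample_id,minutes,ppm
a1,5,10
a1,10,4.9
a1,15,0.2
$ hcnmeter reduce --samples samples.csv --readings readings.csv --out out
reduced 1 samples (0 acyanogenic at the detection limit)
wrote out/concentrations.csv
```

`out/concentrations.csv` then contains total (10+4.9)·0.143/22.4 =
0.0951 μmol, 0.951 μmol/g, and 9.70 μmol/g after the ×10.2 calibration.
The other subcommands follow the same pattern: `duration` (weighted mean
durations, fast/slow classes and per-species summaries), `calibrate`
(fixed-ratio fit of two methods), `standard-curve`, `error-analysis`
(quartic-trend precision), `compare-published` (paired t-test against
converted literature values), `simulate` (scenario-driven synthetic
studies) and `demo`. For example:

```
$ hcnmeter demo --seed 1 --out demo_out
simulated 36 samples; 28 cyanogenic after reduction
mean weighted release duration 5.0 min across cyanogenic samples
cup-vs-jar calibration: slope 1.00 ± 0.02, ratio 10.5 (true inverse recovery 10.2)
published-data check: paired t = -1.29 (df = 7), R² = 0.93
reports written to demo_out
```

The demo simulates a five-stratum community spanning four orders of
magnitude of foliar HCN, reduces it, then runs a split-sample cup-vs-jar
calibration experiment whose fitted ratio recovers the configured 1/10.2
recovery efficiency, and finally reproduces the species-level comparison of
calibrated field means against published laboratory values.

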