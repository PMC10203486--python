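# phenolstress

Untargeted high-resolution mass-spectrometry profiling of cellular phenolic
compounds under metal stress, rebuilt as a tested, fully scriptable pipeline.

Microalgae such as *Euglena gracilis* respond to toxic metal exposure (Cd,
Cu, Co) by remodelling their phenolic metabolome. The workflow this package
implements characterizes that response from direct-infusion negative-mode
ESI peak lists, with a synthetic-data generator providing ground truth for
every stage:

1. **Peak-list cleaning** — S/N > 4 and 0.1 % relative-intensity filters,
   blank subtraction, technical-replicate consensus, chromatographic
   fraction merging (`peaklist`).
2. **Molecular-formula assignment** — exhaustive enumeration of CHNOS
   compositions (C 1–50, H 1–100, O 1–30, N 0–2, S 0–2) whose [M−H]⁻ m/z
   falls within 10 ppm of an observed peak; m/z = M − 1.007276 Da
   (`formulas`).
3. **Phenolic classification & molecular indices** — van Krevelen window
   0.6 < H/C < 1.5 and 0.3 < O/C < 0.85 with modified aromaticity index
   AImod < 0.67, where

   DBE = 1 + C − O − S − ½(N + H)
   AImod = (1 + C − ½O − S − ½(N + H)) / (C − ½O − N − S)

   plus NOSC, the Gini–Simpson abundance diversity
   DA = 1 − Σᵢ pᵢ² over sum-normalized formula intensities, and
   intensity-weighted summaries (weighted average m/z, weighted
   ratios/DBE/AImod) (`descriptors`).
4. **Mass-difference networks** — nodes are phenolic m/z, edges connect
   pairs whose exact mass difference matches a biochemical transformation
   (amino-acid residues, nucleobases, sugar/functional-group increments)
   within ±2 ppm; transformations are grouped by heteroatom content
   (S / N / N+O / O) (`network`).
5. **EC50 dose–response fitting** — four-parameter logistic on log dose,
   log-response least squares, multistart initialization (`dose_response`).
6. **Orchestration & statistics** — per-treatment pipeline runs, Shapiro–Wilk
   screen, pairwise exact Wilcoxon rank-sum tests with compact letter
   display at α = 0.05 (`report`), and a generator for ground-truth-known
   synthetic studies (`synthetic`).

## Worked example

```python
>>> from phenolstress import synthetic, report
>>> exp = synthetic.simulate_experiment(seed=42, n_formulas=300)
>>> res = report.process_experiment(exp)
>>> res["summaries"].groupby("group")["rel_intensity_pct"].mean().round(3)
group
Cd         2.815
Co         4.062
Cu         3.567
control    2.232
Name: rel_intensity_pct, dtype: float64
```

The generator planted phenolic intensity shares of 2.04 % (control), 2.88 %
(Cd), 3.02 % (Cu) and 2.95 % (Co); after filtering, blank subtraction,
consensus, assignment and classification the control culture is recovered
as the clearly lowest group. The absolute values sit slightly above the
planted shares because a few percent of peaks receive a wrong — sometimes
phenolic — formula at 2 ppm mass error (see `docs/methods.md`).

The same study runs as a numbered script sequence:

```sh
python analysis/01_simulate.py          # peak lists + dose-response tables
python analysis/02_fit_ec50.py          # EC50 table, e.g. Cd: 2.71 ± 0.19 ppm
python analysis/03_process_peaklists.py # pipeline + assignment tables
python analysis/04_phenolic_profiles.py # group comparison with letters
python analysis/05_network.py           # transformation-network summaries
```

`02_fit_ec50.py` recovers the generating EC50s (2.7 / 16.0 / 190.7 ppm for
Cd / Cu / Co) within their standard errors, with r² > 0.998; `05_network.py`
reports 24–28 distinct transformations per treatment with oxygen-rich
transformations dominating.

A `phenolstress` console script exposes the same steps
(`simulate`, `process`, `network`, `ec50`, `report`).

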