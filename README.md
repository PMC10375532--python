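# acylseq

Analysis toolkit for sequence-dependent, non-enzymatic RNA aminoacylation
experiments: selection-sequencing screens over randomized acceptor regions,
kinetic modeling of aminoacyl-transfer time courses, and two-state
duplex-melting analysis — plus a synthetic-data generator so every stage can
be validated against planted ground truth.

## The problem

Whether an amino acid becomes attached to a tRNA-like RNA can depend on the
RNA's own sequence — a "second genetic code" written in the acceptor stem
rather than the anticodon. Experimentally this is probed by aminoacyl-transfer
from a short donor strand (carrying an activated amino acid on its
5′-phosphate) to the 2′,3′-diol terminus of an acceptor stem-overhang mimic,
with part of the acceptor sequence fully randomized. A periodate-protection
selection enriches the variants that were aminoacylated: esterified termini
resist oxidation, survive ligation/RT/PCR, and get sequenced; a **blank**
carried through ligation/RT/PCR only captures the procedural sequence bias.

`acylseq` implements the computational side of such a study:

1. **Variant counting** — reads from each condition (amino acid × chemistry,
   plus blank) are matched against the fixed-flank amplicon layout and every
   one of the 4^k randomized-region variants is tallied.
2. **Enrichment and ranking** — pseudocounted frequencies, the
   selection/blank enrichment ratio
   `e(v) = freq_sel(v) / freq_blank(v)`, raw-read ranks and percentiles,
   position probability matrices with information content (bits) for
   sequence logos, Pearson correlations between conditions, and a
   per-variant **selectivity score**
   `score(v, aa) = log2 e_aa(v) − max_{aa′≠aa} log2 e_aa′(v)`.
3. **Transfer kinetics** — pseudo-first-order transfer (rate constant `k_T`,
   weighted by the duplex-bound donor fraction θ) competing with donor
   hydrolysis (`k_H`):
   `Y(t) = Y_max (1 − exp(−k_obs t))`, with `k_obs = θ k_T + k_H` and
   `Y_max = θ k_T / (θ k_T + k_H)`; multistart nonlinear least squares,
   L/D stereoselectivity factors, and the multi-equivalent plateau
   `Y_n = 1 − (1 − Y_1)^n`.
4. **Duplex thermodynamics** — two-state bimolecular hybridization:
   `K(T) = exp(−(ΔH° − TΔS°)/RT)`, the mass-action quadratic for the bound
   fraction θ(T), melting temperature `T_M = ΔH°/(ΔS° + R ln(C_T/4))` for
   equimolar strands, and melting-curve fitting with sloping baselines.

## Worked example

Simulate a three-base stem screen in which the variant 5′-CAG-3′ is a strong
alanylation substrate (true acylation probability 0.9 vs 0.2 background),
with log-normal procedural bias and 0.1% sequencing error, then analyze it:

```python
import numpy as np
from acylseq import *

design = LibraryDesign("GAUUC", 3, "UUCCA", name="stem3")
truth = make_truth(3, bias_sd=0.5,
                   p_spec={**{v: 0.2 for v in enumerate_variants(3)}, "CAG": 0.9},
                   seed=1)
sel, blank = simulate_selection_reads(truth, design, depth=100_000,
                                      error_rate=0.001, seed=2)
write_fastq(sel, "ala_selection.fastq"); write_fastq(blank, "blank.fastq")

tab  = count_fastq("ala_selection.fastq", design, condition_label="L-Ala")
btab = count_fastq("blank.fastq", design, condition_label="blank")
print("matched:", tab.matched, "unmatched:", tab.unmatched)
enr = compute_enrichment(tab, btab)
print(enr.table.sort_values("rank_by_raw_count")
      [["count_sel", "count_blank", "enrichment", "percentile"]].head(3).round(3))
```

```
matched: 99999 unmatched: 1
         count_sel  count_blank  enrichment  percentile
variant
CAG           4367          954       4.574       1.562
CUG           4071         4316       0.943       3.125
GAC           3844         4234       0.908       4.688
```

The planted variant tops the table: 4.6-fold enriched over the blank and in
the 1.6th percentile of the 64 variants (rank 1). The runners-up have
enrichment ≈ 0.9–0.95 — they merely ride the procedural bias. Kinetics and
melting work the same way:

```python
kin = TransferKinetics(k_T=0.5, k_H=0.2, theta=1.0)       # /h
tc  = simulate_time_course(kin, np.linspace(0, 12, 10), noise_sd=0.02, seed=3)
fit = fit_time_course(tc, theta=1.0, seed=0)
# k_T=0.446/h k_H=0.175/h k_obs=0.621/h Y_max=0.718

th = thermo_from_tm(44.0, -60.0, 100e-6)                  # T_M 44 C at 100 uM
mc = simulate_melting_curve(th, np.linspace(5, 85, 40),
                            baselines=(0.0015, 1.0, 0.0004, 0.08),
                            noise_sd=0.005, seed=4)
fit_melting_curve(mc, 100e-6, 100e-6, seed=5).tm          # 44.04 C
fraction_bound(th, 10.0)                                  # 0.9977 at T_R = 10 C
```

The fitted `k_obs` (0.62/h vs true 0.70/h) and plateau (0.72 vs 0.714) come
back within the noise; the melting fit recovers the planted 44 °C midpoint,
and at the 10 °C reaction temperature the duplex is ≈ 99.8% formed.

A `acylseq` console script exposes the same steps as subcommands
(`simulate-reads`, `count`, `enrich`, `logo`, `correlate`, `selectivity`,
`fit-kinetics`, `fit-melt`, `run-screen`); `run-screen --config config.json`
drives the whole per-condition pipeline and writes TSV/JSON reports.

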