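# nerpeseq

Analysis of **nonenzymatic RNA primer-extension sequencing** data.

Chemical (enzyme-free) template copying is studied with a self-priming RNA
hairpin whose random-sequence template region (18 nt) captures its own
extension products in cis.  After an RT handle is ligated to the product,
each paired-end read carries one matched template/product pair:

```
5'- handle5 | template | loop | primer | product | rt_handle -3'
```

`nerpeseq` turns raw paired FASTQ from such an experiment into normalized
product-sequence statistics, for researchers quantifying the sequence bias
and fidelity of prebiotic copying chemistries:

* **extraction** — quality filtering, forward/reverse consensus merging,
  fixed-region anchoring, and template/product pair extraction with a
  conserved per-reason filter report;
* **normalization** — the template region is not perfectly equimolar, so a
  no-extension control defines per-position, per-base factors
  `w(i, b) = 0.25 / f_control(i, b)`; weighting each observation by the
  product of its template-base factors presents every statistic as if the
  template were perfectly random with equal base ratios;
* **statistics** — positional base frequencies F(i, b) of products
  (all or fully complementary), trimer frequency tables at positions 1-2-3
  and 4-5-6 (ideal uniform frequency 1/64 ≈ 0.016; median over all 64
  trimers, fold-difference between extreme represented trimers), the
  per-base **error frequency**, the 12-type `template:product` mismatch
  spectrum by position, product-class fractions (complementary,
  multi-mismatch, terminal-mismatch) and the yield / length / cumulative
  incorporation curves;
* **simulation** — a seeded generator with every statistical lever the
  analysis estimates (template composition, extension fraction, length
  distribution, base-bias/fidelity matrix B(t, p), ligation blocks,
  sequencing error), so the entire pipeline is validated by parameter
  recovery without any external data.

## Worked example

Simulate 20,000 molecules plus the matching no-extension control, then run
the pipeline:

```bash
nerpe simulate --out demo/sim --seed 7 -n 20000 --seq-error-rate 0.001
nerpe run \
  --experiment-r1 demo/sim/experiment_R1.fastq \
  --experiment-r2 demo/sim/experiment_R2.fastq \
  --control-r1    demo/sim/control_R1.fastq \
  --control-r2    demo/sim/control_R2.fastq \
  --out demo/out
```

which prints

```
Primer extension product statistics
========================================
molecules analysed          17656
extended products           4072
yield (fraction extended)   0.231
error frequency             0.063
complementary fraction      0.831
>1-mismatch fraction        0.116
terminal-mismatch fraction  0.388
normalized to control       yes
trimer 1-2-3 median         0.016
trimer 1-2-3 max/min ratio  3
trimer 4-5-6 median         0.015
trimer 4-5-6 max/min ratio  12

tables written to demo/out
```

Reading the numbers: 17,656 of 20,000 read pairs survived filtering (the
rest are tallied by reason in `experiment_filter_report.json`); 23.1% of
hairpin primers were extended and 6.3% of incorporated bases violate
Watson-Crick pairing — both matching the generator's settings (0.23 and
0.063).  The position 1-2-3 trimer median of 0.016 equals the ideal 1/64 of
an unbiased product ensemble, as expected for a simulation with uniform
incorporation.  `demo/out/` holds one TSV per table (positional
frequencies, trimer tables, mismatch spectrum, length distribution,
cumulative incorporation, normalization factors) and `summary.json`.

The same analysis is available as a library, statsmodels-style:

```python
from nerpeseq import PrimerExtensionModel

model = PrimerExtensionModel.from_tsv("demo/out/experiment_pairs.tsv",
                                      "demo/out/control_pairs.tsv")
results = model.fit()
print(results.summary())
results.trimer_123.freq          # 64 trimer frequencies
results.spectrum.M               # mismatch spectrum, 12 types x position
results.plot_cumulative()        # matplotlib axes
```

Two runs are compared statistic-by-statistic with
`nerpe compare a/summary.json b/summary.json`.

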