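# cpgoe

Comparative analysis of gene-body DNA methylation from sequence alone.

In insects (and many other invertebrates), DNA methylation targets CpG
dinucleotides inside gene bodies. Methylated cytosines deaminate to thymine
at an elevated rate, so genes that have been methylated over evolutionary
time become CpG-depleted. The normalised statistic

```
CpG_o/e = f_CpG / (f_C · f_G)
```

— observed CpG frequency over the product of C and G frequencies in a
gene's coding sequence — therefore separates putatively methylated genes
(CpG_o/e well below 1) from unmethylated ones, without any bisulfite data.
In species with active methylation systems the per-gene distribution of
CpG_o/e is clearly bimodal.

`cpgoe` implements the full comparative pipeline around this statistic, for
genomicists studying methylation evolution across species:

- **genome_io** — FASTA/GFF3 reading, longest-CDS-per-gene extraction
  (strand-aware), translation, and assembly contiguity statistics
  (N50/L50, N90/L90).
- **cpg** — per-gene CpG_o/e; a two-component Gaussian mixture fitted by EM
  (`CpGMixtureClassifier`, a scikit-learn style estimator with
  `fit`/`predict`); classification at the intersection point of the two
  scaled component densities: genes below the threshold form the low
  (putatively methylated) bin.
- **orthogroups** — per-orthogroup methylation status across species
  (low / high / mixed / absent), UpSet-style exclusive intersection counts,
  and species-specific gene fractions per bin.
- **selection** — pairwise dN/dS by the Nei–Gojobori (1986) method
  (mutant-enumeration site counts, pathway-averaged differences,
  Jukes–Cantor correction), with a Wilcoxon–Mann–Whitney comparison of
  omega between the low and high bins.
- **enrichment** — GO term enrichment of either bin (true-path propagation
  over is_a/part_of, upper-tail hypergeometric test, minimum node size 10).
- **simulate** — seeded generators for every input with planted ground
  truth: CDS sets with an emergent bimodal CpG_o/e distribution, codon
  pairs diverged under a chosen omega, orthogroup tables with planted
  patterns, and GO annotations with planted enriched terms.

## Worked example

Simulate a 2,000-gene dataset with a planted methylated fraction of 0.45,
then run the extraction → CpG_o/e → mixture → classification chain:

```
$ cpgoe simulate --seed 1 --n-genes 2000 --out demo
simulated 2000 genes (seed 1)
$ cpgoe run-all --seed 1 --n-genes 2000 --out demo_run
fraction_low=0.447 (planted 0.45)
```

`demo_run/run_all_report.json` then contains (abridged):

```json
{
  "mixture": {
    "means":   [0.4149, 1.0226],
    "sds":     [0.1024, 0.1316],
    "weights": [0.4465, 0.5535]
  },
  "threshold": 0.6817,
  "fraction_low": 0.447,
  "planted_fraction": 0.45,
  "truth_agreement": 0.9935
}
```

The two mixture components sit near 0.41 and 1.02 — the two modes of the
generated CpG_o/e distribution. The density-intersection threshold (0.68)
assigns 44.7% of genes to the low bin, recovering the planted 45%
methylated fraction; 99.4% of individual genes are classified in agreement
with the planted truth.

The same stages are available programmatically:

```python
from cpgoe import compute_cpg_oe
from cpgoe.cpg import CpGMixtureClassifier

values = [...]                        # per-gene CpG_o/e, filtered to (0, 2)
clf = CpGMixtureClassifier().fit(values)
labels = clf.predict(values)          # 0 = low / putatively methylated
print(clf.means_, clf.threshold_)
```

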