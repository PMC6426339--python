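# damidkit

Processing toolkit for **DamID-seq** mapping of lamina-associated domains
(LADs), built for experiments in primary cells where mitochondrial
contamination and limited read depth matter.

In LaminB1-DamID, *E. coli* Dam methylase fused to Lamin B1 deposits m6A
at GATC motifs near the nuclear lamina; DpnI/DpnII digestion and PCR then
select genomic fragments flanked by two methylated GATC sites, and
sequencing reads are compared against a soluble Dam-only control.  The
signal per DpnI fragment *f* is

```
value[f] = log2( ((c_L[f] + p) / T_L) / ((c_D[f] + p) / T_D) )
```

where `c_L`, `c_D` are LaminB1-Dam and Dam-only read counts overlapping
the fragment, `T_L`, `T_D` the samples' filtered read totals and `p` a
1-read pseudocount.  After optional quantile normalization and smoothing
over the 20 surrounding fragments, circular binary segmentation (CBS)
partitions each chromosome into runs of quasi-uniform signal, and LADs
are called by the four-step rule: subtract assembly gaps, keep segments
with mean > τ (default 0), merge intervals closer than 5 kb, drop
intervals under 10 kb.

The package covers:

- `damidkit.digest` — in-silico GATC/DpnI digestion, fragment maps,
  fixed-size bins, fragment-size statistics;
- `damidkit.qc` — alignment filtering (mapq, secondary, mitochondrial)
  with a contamination/depth report;
- `damidkit.profiles` — counting, proportion normalization, log2 ratios,
  quantile normalization, fragment-window smoothing;
- `damidkit.segment` — from-scratch CBS with a permutation split test;
- `damidkit.lads` — gap subtraction, thresholding, merging, size
  filtering, LAD-set comparison (base-pair Jaccard, boundary offsets);
- `damidkit.simulate` — a generative simulator (genome → LAD truth →
  site methylation → amplicon selection → reads with chrM contamination)
  so the whole pipeline can be validated against known truth;
- `damidkit.pipeline` / the `damid` CLI — the end-to-end workflow with
  provenance stamping.

See `docs/methods.md` for the model, parameter meanings and limitations.

## Worked example

Simulate a small experiment with known truth, then run the pipeline on
its outputs:

```sh
$ damid simulate --length 4000000 --chromosomes 2 --coverage 0.4 \
      --reads 300000 --seed 42 --outdir sim
simulated 14 LADs, 600102 reads -> sim

$ damid qc --alignments sim/lmnb1.aln.tsv --min-clean 1
n total         : 299520 (0.3 M)
n chrs          : 299520 (0.3 M)
n chrM          : 45054 (0.0 M)
% chrM          : 15.0
n post filter   : 254466 (0.3 M)

$ damid run --fasta sim/genome.fa --lmnb1 sim/lmnb1.aln.tsv \
      --dam sim/dam.aln.tsv --nperm 200 --outdir out --seed 7
20 LADs (1550012 bp); outputs in out
```

The QC block mirrors standard DamID accounting: 15.0% of mapped reads are
mitochondrial (the simulator injected 15%), and 254,466 clean reads
remain for quantitation.  The called LADs land on the simulated truth:

```python
>>> import pandas as pd, damidkit as dk
>>> called = pd.read_csv("out/lads.bed", sep="\t", header=None,
...                      names=["chrom", "start", "end"])
>>> truth = pd.read_csv("sim/truth_lads.bed", sep="\t", header=None,
...                     names=["chrom", "start", "end"])
>>> round(dk.compare_lads(called, truth)["jaccard"], 3)
0.931
```

i.e. 93% base-pair overlap between called and true LADs at this small
scale (at full study scale, 40 Mb and 2 M reads per sample, recovery
exceeds 0.95).  `out/` also contains the fragment map (`fragments.bed`),
the per-fragment profile (`profile.bedGraph`, convertible with
`wigToBigWig` for genome browsers), CBS segments (`segments.bed`) and a
`provenance.json` recording every parameter and the config hash.

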