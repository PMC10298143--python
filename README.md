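# mitovar

Extraction and analysis of mitochondrial genetic variation from aligned
bulk and single-cell RNA-seq data.

Each cell carries hundreds to thousands of mtDNA copies, so different
mitochondrial alleles can coexist within one cell (heteroplasmy), and the
mitochondrial contig is covered far more deeply by RNA-seq reads than any
nuclear locus. `mitovar` exploits this: it piles up BAM files over the
mitochondrial contig, counts A/C/G/T base calls per position per cell, and
turns them into the two core matrices of the analysis — alternative-allele
counts and read coverage (variants × cells / positions × cells). Allele
frequency is AF(v, c) = alt(v, c) / coverage(p_v, c), with entries missing
(never zero-imputed) where a cell has no coverage.

On top of the matrices sit the statistics used for donor demultiplexing and
heteroplasmy discovery:

* **per-site one-way ANOVA** of AF on donor identity (for two donors,
  F = t² of the pooled-variance t-test); p-values are tracked in log10
  space so thresholds as extreme as 10⁻¹⁰⁰ compare exactly;
* **discriminative germline variants** — sites with mean AF > 0.9 in
  exactly one donor, i.e. personal homoplasmic markers, ranked by ANOVA p;
* **heteroplasmy scan** — after excluding the germline set, sites whose
  donor-level mean AF falls strictly inside (1%, 25%) and differs across
  donors (Bonferroni-adjusted 0.05);
* **cell–cell distances** 1 − |Pearson r| between AF profiles over the
  most variable sites, with t-SNE embedding (perplexity 10) and
  random-forest donor classification as delegated scikit-learn contracts.

Both single-cell BAM layouts are supported: *well-based* (one BAM per
cell; cell id = file stem) and *droplet-based* (one BAM with cell-barcode
tags, default `CB`; empty droplets removed by whitelist and/or minimum
read count). A fully seeded simulator generates references, donor
genotypes and valid BAMs with a machine-readable truth table, so the whole
pipeline is testable without any external download.

## Worked example

```python
import pathlib, tempfile
from mitovar import *

d = pathlib.Path(tempfile.mkdtemp())
cfg = SimulationConfig(seed=1, n_donors=3, cells_per_donor=20, reads_per_cell=800,
                       reference_length=2000, n_germline_per_donor=5,
                       n_heteroplasmies_per_donor=1)
ds = simulate_dataset(cfg, d)                       # FASTA + 60 BAMs + truth
tensors, index = pileup_well(ds.bam_paths, ds.reference)
alt, cov = build_matrices(tensors, ds.reference, index)
af = calc_allele_frequency(alt, cov)
labels = DonorLabels.from_tsv(ds.labels_path)

germ = discriminative_germline(af, labels)
print(f"{len(index.cell_ids)} cells, {len(germ)} discriminative germline variants")
for r, carrier in germ[:3]:
    print(f"  {r.variant.label}  carrier={carrier}  F={r.F:.1f}  log10_p={r.log10_p:.1f}")
for c in heteroplasmy_scan(af, cov, labels):
    print(f"heteroplasmy {c.variant.label} in {c.carriers[0]}: "
          f"mean AF {c.donor_means[c.carriers[0]]:.3f}")
pred = classify_donors(af, [r.variant for r, _ in germ], labels, seed=0)
print(f"out-of-bag donor prediction accuracy: {pred.accuracy:.3f}")
```

Output:

```
60 cells, 15 discriminative germline variants
  175C>T  carrier=donor1  F=inf  log10_p=-inf
  271T>G  carrier=donor3  F=inf  log10_p=-inf
  552T>G  carrier=donor3  F=inf  log10_p=-inf
heteroplasmy 186A>G in donor3: mean AF 0.111
heteroplasmy 1616C>A in donor1: mean AF 0.076
heteroplasmy 14A>C in donor2: mean AF 0.093
out-of-bag donor prediction accuracy: 1.000
```

All 15 injected germline markers (5 per donor) are recovered with their
carriers; the three injected μ = 0.10 heteroplasmies are called with donor
mean AF estimates close to truth (the spread reflects the simulated
cell-to-cell Beta variation); and the recovered markers predict the donor
of every held-out cell. An `F=inf` means the within-donor sum of squares
is exactly zero — the allele is fixed in the carrier and absent elsewhere.

The same pipeline is available from the shell:

```bash
mitovar simulate --out fixture --seed 1 --donors 3 --cells-per-donor 20 \
    --reads-per-cell 800 --length 2000 --germline-per-donor 5 --het-per-donor 1
mitovar pileup --bam-dir fixture --fasta fixture/reference.fa --out matrices
mitovar stats --matrices matrices --labels fixture/labels.tsv \
    --mode germline --out germline.tsv
```

Every command writes a `run_manifest.json` (version, command line, seeds,
filter settings, input checksums).

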