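# dgetag

Analysis toolkit for **3′-tag digital gene expression (DGE)** — the
SAGE-style protocol in which poly(A)+ mRNA is anchored at its 3′-most
NlaIII site (`CATG`), MmeI releases a short downstream fragment, and the
resulting 21-nt tags are sequenced in the millions and *counted* as a
proxy for transcript abundance. The package was built for genome/
transcriptome studies of the straw mushroom *Volvariella volvacea* and
similar fungal systems, where expression of two homokaryotic parent
strains and their heterokaryon is profiled in single-replicate tag
libraries, and where the genomic CAZyme (carbohydrate-active enzyme)
repertoire is compared across species. It is equally usable for any
NlaIII/MmeI tag dataset.

## What it computes

**Virtual-tag mapping.** Every `CATG`-anchored window of the predicted
transcripts is indexed; an observed tag is assigned to a gene exactly,
or with one mismatch when no exact hit exists; tags matching several
genes are ambiguous and excluded.

**QC ledger.** Raw tags are cleaned by removing N-containing tags,
adaptor tags, and copy-number-1 tags, with a full accounting table
(including copy-number ≥2, >5, >10, >20, >50, >100 rows) whose
conservation identities are enforced.

**Quantification.** Expression of gene *g* in a library of *N* clean
tags is its unambiguous tag count *x_g*, normalised to tags per million,
TPM = *x_g*/*N* × 10⁶, with undetected genes reported at the floor 0.01.

**Differential expression.** For counts *x*, *y* in libraries of depth
*N₁*, *N₂*, the Audic–Claverie conditional mass

```
p(y | x) = (N₂/N₁)^y · (x+y)! / ( x!·y!·(1 + N₂/N₁)^(x+y+1) )
```

is evaluated in log-space; the two-sided p-value doubles the smaller
inclusive tail (orientation canonicalised so the test is exchangeable in
its libraries). Genes with raw counts ≤ 40 in both libraries are
filtered before testing; Benjamini–Hochberg FDR runs over the tested
set; significance requires p < 0.005, FDR ≤ 0.001 and |log₂ fold
change| > 2 on floored TPM.

**Strain-triad comparison.** Detection Venn partition across (P1, P2,
H), pairwise ≥k-fold gene sets, and heterokaryon-complementation
categories: **A** (silent in P1, high in P2), **B** (mirror), **C** (low
in both parents, boosted in the heterokaryon).

**CAZyme profiling.** Genome × family count matrices with class totals
(GH/GT/PL/CE), lineage averages, genome ranking, and double hierarchical
clustering with Newick and heatmap export.

**Synthetic data.** A seeded generator produces three-strain libraries
with planted silent genes, allele SNPs, complementation boosts,
sequencing errors, N tags, adaptors and junk singletons — with a ground
truth table — so the entire pipeline is testable end to end.

## Worked example

```python
from dgetag.simulate import SimulationParams, simulate_genes, simulate_triad, ADAPTOR_SEQUENCES
from dgetag import extract_virtual_tags, filter_tags, count_genes, expression_table, call_de
from dgetag.strains import venn_partition, complementation_classify

params = SimulationParams(n_genes=2000, library_size=1_000_000, singleton_noise=5000, seed=42)
genes = simulate_genes(params)
libraries, truth = simulate_triad(genes, params)
index = extract_virtual_tags(genes)

tables, totals = {}, {}
for strain, raw in libraries.items():
    clean, ledger = filter_tags(raw, ADAPTOR_SEQUENCES)
    counts = count_genes(clean, index, genes=list(genes))
    tables[strain] = expression_table(counts, ledger.clean_total)
    totals[strain] = ledger.clean_total
    print(strain, "raw", raw.total, "clean", ledger.clean_total,
          "singletons removed", ledger.singleton_total)

de = call_de(tables["P1"]["raw_count"], tables["P2"]["raw_count"], totals["P1"], totals["P2"])
print("significant P1 vs P2:", int(de["significant"].sum()))

venn = venn_partition({s: t["raw_count"] for s, t in tables.items()})
print("expressed in >=1 strain:", venn.pct_expressed_any, "%")

cats = complementation_classify(
    tables["P1"]["tpm"], tables["P2"]["tpm"], tables["H"]["tpm"],
    counts_p1=tables["P1"]["raw_count"], counts_p2=tables["P2"]["raw_count"])
print(cats.value_counts().to_dict())
```

prints

```
P1 raw 989367 clean 959736 singletons removed 26640
P2 raw 991221 clean 962959 singletons removed 25127
H raw 996894 clean 965673 singletons removed 28182
significant P1 vs P2: 313
expressed in >=1 strain: 94.95 %
{'none': 1743, 'A': 119, 'B': 118, 'C': 20}
```

Each library of ~10⁶ raw tags loses its junk singletons in QC; 313
genes pass the exact test at the default thresholds between the two
parents; ~95% of genes are detected somewhere; and the planted
complementation structure (strain-specific silent genes, heterokaryon
boosts) surfaces in the A/B/C counts. The same pipeline is available
from the shell via the `dgetag` command (`dgetag run-all --outdir out`),
which also writes a SHA-256 manifest so reruns are verifiably
byte-identical.

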