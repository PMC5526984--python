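# crosslimb

Cross-species differential-expression analysis for limb-bud RNA-seq, built
around the question of how the vestigial emu wing diverges transcriptionally
from the functional chicken wing. Comparing expression *levels* directly
between a species quantified against a reference genome (chicken) and one
quantified through a de-novo transcriptome assembly (emu) is invalid —
assembly quality, annotation completeness and mapping rates bias every
gene differently between species. What *is* comparable is each species'
forelimb/hindlimb expression **ratio**, because any gene-wise species bias
enters both tissues of that species equally and cancels. `crosslimb`
implements that design end to end, for computational biologists who have
gene-level counts in hand (read trimming, alignment, assembly and read
counting are upstream and out of scope).

## What it does

1. **Annotation transfer** (`crosslimb.annotation`): BLAST hits of assembly
   contigs against reference transcripts are filtered at e-value < 10⁻⁵
   (hits at or above the cutoff are discarded), each contig takes the gene
   of its best surviving hit (minimum e-value; ties by bitscore, then gene
   ID), and contig annotations are lifted to Corset-style loci. Loci naming
   two or more genes are discarded as ambiguous; counts of loci annotated to
   the same gene are summed; the resulting gene-level matrix is intersected
   with the reference species' counts.

2. **Interaction model** (`crosslimb.interaction_de`): both species' counts
   are modeled jointly. With group-mean coefficients EF, EH, CF, CH (emu/
   chicken × fore/hind), the tested contrast is the species-by-tissue
   interaction

   ```
   (EF − EH) − (CF − CH)
   ```

   Counts are transformed to log₂-CPM, observation-level precision weights
   are estimated from the lowess mean–variance trend of the data, per-gene
   weighted least squares is followed by empirical-Bayes moderation of the
   residual variances (shrinkage toward a scaled inverse-χ² prior with
   hyperparameters d₀, s₀² estimated by moment matching on log s²), and the
   moderated t is referred to a t-distribution on d₀ + d_g degrees of
   freedom. P-values are Benjamini–Hochberg adjusted. Genes significant at
   FDR < 0.05 are ranked in descending order of

   ```
   R_g = |log₂FC(emu fore/hind)| − |log₂FC(chicken fore/hind)|
   ```

   so genes whose fore/hind asymmetry is dominated by the emu rise to the
   top. (This engine reproduces limma's `voom` + `lmFit` + `eBayes` to
   ~10⁻¹¹ relative accuracy; see `tests/test_limma_crosscheck.py`.)

3. **Mis-expression analysis** (`crosslimb.misexpression`): for the
   experiment mis-expressing a candidate gene in chick wing buds — genes are
   kept if they have ≥ 10 counts in ≥ 2 samples, embryo sex is inferred from
   the female-specific W-chromosome gene *HINTW* (female iff marker
   CPM > 1), and a treatment + sex linear model is fit with the same
   moderated-t engine.

4. **Phenotype statistics** (`crosslimb.pheno_stats`): percent reduction
   from group means, the two-tailed two-sample Student's t-test from summary
   data (pooled variance; Welch optional), and affected-case proportions
   with a Wilson 95% CI.

5. **Synthetic data with ground truth** (`crosslimb.sim_data`): a
   negative-binomial generator (Var = μ + φμ²) for the full 2×2 design with
   gene-wise species biases, shared tissue effects, planted interaction
   effects, simulated assembly artifacts (locus splitting, chimeric loci,
   unannotatable loci, BLAST-like hit tables) and the mis-expression design
   with a *HINTW* marker — used throughout the tests to verify that the
   pipeline recovers what was planted.

## Worked example

```python
import pandas as pd
from crosslimb import (SimConfig, PlantedEffect, simulate_gene_counts,
                       run_interaction_de, rank_candidates)

cfg = SimConfig(n_genes=5000, seed=7, species_bias_sd=1.0,
                planted=[PlantedEffect(0, 8.0, baseline_log2=-8.0)])
emu, chick, samples, truth = simulate_gene_counts(cfg)
joined = pd.concat([emu, chick], axis=1)
results, info = run_interaction_de(joined, samples)
print(info)
print(rank_candidates(results).head(3))
```

prints

```
{'n_genes_tested': 5000, 'n_significant': 1, 'alpha': 0.05,
 'd0': 196.68841342170106, 's0_2': 1.191301877421017}
  gene_id     score   logFC_E   logFC_C           fdr  rank
0  G00000  7.485518  8.349819 -0.864301  6.419508e-21     1
```

Gene `G00000` carries the planted emu-forelimb-specific effect (log₂
interaction effect 8 on top of a near-zero baseline). It is the only
FDR-significant gene, its emu fore/hind log₂ fold change (~8.3) dwarfs its
chicken fold change (~−0.9, pure noise between near-empty groups), and it
is ranked first — the same route by which a
wing-specific candidate emerges from the real cross-species comparison. The
hyperparameters d₀ (prior degrees of freedom) and s₀² (prior variance)
describe how strongly per-gene variances were shrunk toward the pooled
prior.

The same analyses are scriptable from the shell:

```bash
crosslimb simulate --outdir sim --seed 1 --n-genes 1000
crosslimb annotate --hits sim/hits.tsv --clusters sim/clusters.tsv \
    --locus-counts sim/emu_locus_counts.tsv --out ann
crosslimb de-interaction --counts joined.tsv --samples sim/samples.csv --out de
crosslimb phenostats proportion -k 217 -n 281   # -> 77.2%
crosslimb run --config config.yaml              # full pipeline
```

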