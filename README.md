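# apobecsig

Analysis pipeline for quantifying APOBEC-driven mutagenesis from somatic
variant calls. APOBEC3 cytidine deaminases leave a characteristic scar in
tumor genomes: C>T and C>G substitutions at 5'-TCN trinucleotides, summarized
by the COSMIC signatures SBS2 and SBS13. This package takes called variants
(VCF), builds 96-channel single-base-substitution (SBS) catalogs, removes a
control-derived background, quantifies APOBEC signature activity, and compares
it between experimental conditions or between patient cohorts binned by the
mutation status of a gene of interest. It is aimed at groups doing
CRISPR-perturbation or cell-line mutagenesis experiments read out by reduced-
representation or whole-genome sequencing, and at reanalysis of consortium-
style cohort signature tables.

## What it computes

**Catalogs.** Somatic SNVs are kept if they are caller-PASS, have a variant
allele frequency in the clonal-heterozygous window VAF ∈ [0.3, 0.7], and are
absent from the parental clone. Each SNV is classified into one of the 96
channels `X[R>A]Y` (pyrimidine-stranded substitution R>A with flanks X, Y;
purine-reference calls are reverse-complemented), giving a sample × 96 count
matrix *M*.

**Background correction.** Control samples define a background profile *b*:
every control is down-scaled to the smallest control's total *n*, then for
each control 10,000 multinomial bootstrap draws of size *n* are taken with
the control's channel proportions as weights, and *b* is the mean over all
draws. Corrected counts are `max(M - b, 0)` element-wise.

**Signature refitting.** Given a column-stochastic 96 × K signature matrix
*S*, exposures solve the non-negative least-squares problem
`e* = argmin_{e≥0} ||S e − m||₂` per sample. The strict best-subset rule
starts from the full-K fit and repeatedly descends to the best (k−1)-subset
as long as the reconstruction cosine similarity drops by no more than
`max_delta` (default 0.004), yielding a conservative set of active
signatures. Exposures are reported both on the mutation-count scale and
scaled to one. A multinomial likelihood-ratio test with a parametric-
bootstrap null assesses whether a single signature is present at all.

**Statistics.** The APOBEC fraction of a sample is the share of its
mutations in the eight T[C>T]N / T[C>G]N channels (a stricter TCW option
exists). Group comparisons of APOBEC vs non-APOBEC counts use the two-sided
Fisher exact test (exact enumeration p, conditional-MLE odds ratio, exact
95% CI, optional Bonferroni correction). Cohorts are binned per gene into
wt/mut (mut = at least one variant, SNV or indel, with a non-"Intron"
classification), signature activities are normalized to each sample's total
mutation count, and groups are compared with the two-sided Wilcoxon
rank-sum test. Pentanucleotide context preference is profiled by collecting
the −2..+2 context of all C>T/C>G mutations and keeping NTCNN k-mers.

**Synthetic data.** Because raw inputs of this kind are typically
restricted-access, `apobecsig.synthetic_data` generates every input the
pipeline consumes — reference FASTA, signature shapes (SBS2-like,
SBS13-like, flat and C>A-skewed backgrounds), VCFs with clonal VAFs and
configurable contamination/non-PASS/parental noise, control triplicates,
and cohorts with genotype-dependent activity shifts — each with its own
truth table, so the whole pipeline is testable offline.

## Worked example

```python
import numpy as np
from apobecsig import (
    ApobecDefinition, apobec_fraction, best_subset_refit, bootstrap_background,
    BackgroundConfig, normalize_exposures, subtract_background, fisher_exact_2x2,
    ContingencyTable2x2,
)
from apobecsig.catalogs import MutationCatalog
from apobecsig.synthetic_data import make_signatures, simulate_catalog, simulate_controls

sigs = make_signatures(["sbs2-like", "sbs13-like", "flat", "c-to-a-skewed"], seed=0)

# an experimental sample: 40% SBS2-like, 20% SBS13-like, 40% background
row, _ = simulate_catalog(sigs, [0.4, 0.2, 0.3, 0.1], 2000, seed=1)

# triplicate controls define the background profile
controls = simulate_controls(sigs.profiles[:, 2], totals=[800, 1000, 1200], seed=2)
bg = bootstrap_background(controls, BackgroundConfig(n_boot=10_000, seed=3))
corrected = subtract_background(MutationCatalog(["sample"], row[None, :]), bg)

res = normalize_exposures(best_subset_refit(corrected.counts[0], sigs))
print("selected signatures:", res.selected)
print("exposure fractions: ", {l: round(res.fraction_of(l), 3) for l in res.selected})
print("reconstruction cosine:", round(res.cosine_selected, 4))

fr = apobec_fraction(corrected.counts[0], ApobecDefinition("TCN"))
print(f"APOBEC fraction: {fr.apobec:.0f}/{fr.total:.0f} = {fr.fraction:.3f}")

fisher = fisher_exact_2x2(ContingencyTable2x2(541, 650, 200, 991))
print(f"Fisher OR={fisher.odds_ratio:.3f} CI=[{fisher.ci_low:.3f}, {fisher.ci_high:.3f}] p={fisher.p:.3g}")
```

prints

```
selected signatures: ['sbs2-like', 'sbs13-like', 'c-to-a-skewed']
exposure fractions:  {'sbs2-like': 0.574, 'sbs13-like': 0.287, 'c-to-a-skewed': 0.139}
reconstruction cosine: 0.9973
APOBEC fraction: 1150/1365 = 0.842
Fisher OR=4.122 CI=[3.397, 5.013] p=1.37e-52
```

The best-subset refit drops the flat background (its contribution was
largely absorbed by the subtraction step) and attributes ~86% of the
remaining mutations to the two APOBEC-like signatures, matching the 0.842
channel-based APOBEC fraction. The Fisher line tests pooled APOBEC vs
non-APOBEC counts between two conditions (here: 541/650 vs 200/991): the
odds of a mutation being APOBEC-type are ~4.1-fold higher in the first
group, with an exact p-value of 1.4e-52.

The same stages are scriptable from the shell (`apobecsig simulate`,
`apobecsig catalog`, `apobecsig correct-background`, `apobecsig refit`,
`apobecsig apobec`, `apobecsig pentanuc`, `apobecsig cohort`,
`apobecsig run-all --config cfg.txt`); `run-all` writes every intermediate
TSV plus a manifest with SHA-256 checksums, and reruns with the same config
and seed are bit-identical.

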