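"""Cohort-level wt/mut comparison of signature activities.

Consortium-style cancer cohorts are binned per gene of interest into
"mut" (at least one variant, SNV or indel, whose Variant Classification
is not "Intron") and "wt" (everything else); a combined group is "mut"
if any of several genes is. Per-sample signature activities are
normalized to the sample's total mutation count, and groups are
compared with the two-sided Wilcoxon rank-sum (Mann-Whitney) test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu


@dataclass(frozen=True)
class GenotypeRule:
    """Which variant classifications do NOT count toward "mut" status.

    ``missing_counts_as_mut``: a variant with no classification label is
    treated as non-intronic (and tallied) by default.
    """

    excluded_classifications: frozenset = frozenset({"Intron"})
    missing_counts_as_mut: bool = True


@dataclass
class CohortSample:
    """One cohort sample: genotype per gene, signature activities, total burden."""

    sample_id: str
    genotype: Dict[str, str] = field(default_factory=dict)  # gene -> "wt"/"mut"
    activities: Dict[str, float] = field(default_factory=dict)  # signature -> count scale
    total_mutations: int = 0

    def __post_init__(self) -> None:
        for sig, act in self.activities.items():
            if act < 0:
                raise ValueError(f"negative activity for {sig}")


def classify_gene_status(
    variants: Iterable, gene: str, rule: GenotypeRule = GenotypeRule()
) -> str:
    """"mut" iff >= 1 variant in the gene whose classification is not excluded.

    SNVs and indels both count. Variants with a missing classification
    count as non-intronic under the default rule.
    """
    for v in variants:
        if v.gene != gene:
            continue
        cls = v.classification
        if cls is None:
            if rule.missing_counts_as_mut:
                return "mut"
            continue
        if cls not in rule.excluded_classifications:
            return "mut"
    return "wt"


def combined_status(genotype: Dict[str, str], genes: Sequence[str]) -> str:
    """"mut" iff any listed gene is "mut" (logical OR)."""
    for g in genes:
        if g not in genotype:
            raise KeyError(f"gene {g!r} missing from genotype map")
    return "mut" if any(genotype[g] == "mut" for g in genes) else "wt"


def normalize_activities(sample: CohortSample) -> Dict[str, float]:
    """activity / total_mutations per signature."""
    if sample.total_mutations <= 0:
        raise ValueError(f"sample {sample.sample_id} has non-positive total_mutations")
    return {sig: act / sample.total_mutations for sig, act in sample.activities.items()}


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (W, p) where W is the rank-sum of ``x`` with midranks for
    ties. p is computed from the exact null distribution when
    min(n, m) <= 10 and there are no ties, and from the normal
    approximation with tie and continuity corrections otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (min(x.size, y.size) <= 10 and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0  # U -> rank-sum W
    return w, float(res.pvalue)


@dataclass
class CohortComparison:
    gene: str
    signature: str
    n_wt: int
    n_mut: int
    median_wt: float
    median_mut: float
    statistic: float
    p: float


def compare_cohort(
    cohort: Sequence[CohortSample], gene: str, signature: str
) -> CohortComparison:
    """Wilcoxon comparison of normalized signature fractions, wt vs mut.

    The statistic is the rank-sum of the wt group. Errors if either
    genotype group is empty for the gene.
    """
    wt_vals: List[float] = []
    mut_vals: List[float] = []
    for s in cohort:
        if gene not in s.genotype:
            continue  # samples without a call for this gene are excluded
        frac = normalize_activities(s).get(signature, 0.0)
        (wt_vals if s.genotype[gene] == "wt" else mut_vals).append(frac)
    if not wt_vals:
        raise ValueError(f"empty wt group for gene {gene!r}")
    if not mut_vals:
        raise ValueError(f"empty mut group for gene {gene!r}")
    stat, p = wilcoxon_rank_sum(wt_vals, mut_vals)
    return CohortComparison(
        gene=gene,
        signature=signature,
        n_wt=len(wt_vals),
        n_mut=len(mut_vals),
        median_wt=float(np.median(wt_vals)),
        median_mut=float(np.median(mut_vals)),
        statistic=stat,
        p=p,
    )


def write_cohort_tsv(cohort: Sequence[CohortSample], path) -> None:
    genes = sorted({g for s in cohort for g in s.genotype})
    sigs = sorted({sig for s in cohort for sig in s.activities})
    rows = []
    for s in cohort:
        row = {"sample_id": s.sample_id, "total_mutations": s.total_mutations}
        for g in genes:
            row[f"status_{g}"] = s.genotype.get(g, "")
        for sig in sigs:
            row[f"activity_{sig}"] = s.activities.get(sig, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cohort_tsv(path) -> list[CohortSample]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    status_cols = [c for c in df.columns if c.startswith("status_")]
    act_cols = [c for c in df.columns if c.startswith("activity_")]
    cohort = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        cohort.append(
            CohortSample(
                sample_id=d["sample_id"],
                genotype={c[len("status_"):]: d[c] for c in status_cols if isinstance(d[c], str) and d[c]},
                activities={c[len("activity_"):]: float(d[c]) for c in act_cols},
                total_mutations=int(d["total_mutations"]),
            )
        )
    return cohort


def write_comparisons_tsv(comparisons: Sequence[CohortComparison], path) -> None:
    pd.DataFrame(
        [
            {
                "gene": c.gene,
                "signature": c.signature,
                "n_wt": c.n_wt,
                "n_mut": c.n_mut,
                "median_wt": c.median_wt,
                "median_mut": c.median_mut,
                "statistic": c.statistic,
                "p": c.p,
            }
            for c in comparisons
        ]
    ).to_csv(path, sep="\t", index=False)
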