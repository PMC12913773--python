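"""APOBEC-context mutation fractions, Fisher exact tests, pentanucleotide profiles.

"APOBEC-related" mutations are C>T and C>G substitutions at 5'-TCN
(the kataegis-associated trinucleotide context), i.e. 8 of the 96
channels; a stricter TCW (W = A/T) variant is available. Group
comparisons of APOBEC vs non-APOBEC counts use the two-sided Fisher
exact test with a conditional-MLE odds ratio, exact 95% CI, and
optional Bonferroni adjustment.

The two-sided p-value is computed by exact enumeration of the
hypergeometric support with integer binomial coefficients, summing the
probability of every table (at fixed margins) whose probability does
not exceed the observed table's, with the customary 1 + 1e-7 relative
tolerance for ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

from .catalogs import BASES, CHANNEL_INDEX, N_CHANNELS, revcomp


@dataclass(frozen=True)
class ApobecDefinition:
    """Channel-based operationalization of APOBEC-related mutations.

    context "TCN": T[C>T]A/C/G/T and T[C>G]A/C/G/T (8 channels).
    context "TCW": 3' base restricted to W = {A, T} (4 channels).
    """

    context: str = "TCN"

    def __post_init__(self) -> None:
        if self.context not in ("TCN", "TCW"):
            raise ValueError("context must be 'TCN' or 'TCW'")

    @property
    def channels(self) -> tuple[str, ...]:
        three = "ACGT" if self.context == "TCN" else "AT"
        return tuple(
            f"T[C>{alt}]{b}" for alt in ("T", "G") for b in three
        )

    @property
    def channel_indices(self) -> np.ndarray:
        return np.array([CHANNEL_INDEX[c] for c in self.channels])


@dataclass
class ApobecFraction:
    apobec: float
    total: float
    fraction: Optional[float]  # None when total == 0

    @property
    def defined(self) -> bool:
        return self.fraction is not None


def apobec_fraction(catalog_row: np.ndarray, defn: ApobecDefinition = ApobecDefinition()) -> ApobecFraction:
    """APOBEC-channel mass of one catalog row, as (apobec, total, fraction)."""
    row = np.asarray(catalog_row, dtype=float)
    if row.shape != (N_CHANNELS,):
        raise ValueError("catalog row must be a 96-vector")
    total = float(row.sum())
    apobec = float(row[defn.channel_indices].sum())
    return ApobecFraction(apobec, total, apobec / total if total > 0 else None)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows = groups, columns = (APOBEC, non-APOBEC) counts."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("cells must be nonnegative integers")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class FisherResult:
    table: ContingencyTable2x2
    odds_ratio: float  # conditional-MLE estimate
    odds_ratio_sample: float  # cross-product ad/bc
    ci_low: float
    ci_high: float
    p: float
    p_adjusted: float
    m: int = 1
    method: str = "fisher-exact-conditional-mle"


_TIE_NUM = 10_000_001  # relative tie tolerance 1 + 1e-7, held as an
_TIE_DEN = 10_000_000  # exact integer ratio


def _fisher_p_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided p at fixed margins, by integer enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    if lo == hi:  # degenerate margin: single possible table
        return 1.0
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    observed = weights[a - lo]
    included = sum(w for w in weights if w * _TIE_DEN <= observed * _TIE_NUM)
    return float(Fraction(included, sum(weights)))


def fisher_exact_2x2(
    table: ContingencyTable2x2, m: int = 1, compute_ci: bool = True
) -> FisherResult:
    """Two-sided Fisher exact test with conditional-MLE odds ratio.

    The exact p comes from the in-package hypergeometric enumeration;
    the conditional-MLE odds ratio and its exact 95% CI (one-sided test
    inversion at 2.5% per tail) come from scipy. ``m`` is the Bonferroni
    multiplier: p_adjusted = min(1, m * p). ``compute_ci=False`` skips
    the (comparatively slow) MLE/CI root-finding.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    p = _fisher_p_two_sided(a, b, c, d)
    with np.errstate(divide="ignore", invalid="ignore"):
        sample_or = np.float64(a) * d / (np.float64(b) * c)
    if compute_ci:
        res = _scipy_odds_ratio(table.as_array(), kind="conditional")
        ci = res.confidence_interval(confidence_level=0.95)
        or_mle, ci_low, ci_high = float(res.statistic), float(ci.low), float(ci.high)
    else:
        or_mle, ci_low, ci_high = float(sample_or), float("nan"), float("nan")
    return FisherResult(
        table=table,
        odds_ratio=or_mle,
        odds_ratio_sample=float(sample_or),
        ci_low=ci_low,
        ci_high=ci_high,
        p=p,
        p_adjusted=min(1.0, m * p),
        m=m,
    )


def compare_apobec_fractions(
    groups: Dict[str, tuple], reference: str, m: Optional[int] = None
) -> Dict[str, FisherResult]:
    """Fisher-test every group against the reference group.

    ``groups`` maps a label to pooled (apobec, non_apobec) counts. Each
    non-reference group forms the first row of a 2x2 table against the
    reference; p-values are Bonferroni-adjusted with m = number of tests
    unless ``m`` is given.
    """
    if reference not in groups:
        raise KeyError(f"reference group {reference!r} not in groups")
    treatments = [g for g in groups if g != reference]
    if not treatments:
        raise ValueError("need at least one non-reference group")
    if m is None:
        m = len(treatments)
    ref_ap, ref_non = groups[reference]
    out = {}
    for label in treatments:
        ap, non = groups[label]
        tab = ContingencyTable2x2(int(ap), int(non), int(ref_ap), int(ref_non))
        out[label] = fisher_exact_2x2(tab, m=m)
    return out


PENTA_POSITIONS = (-2, -1, 0, 1, 2)


@dataclass
class PentanucMatrix:
    """Per-position base frequencies over retained NTCNN 5-mers.

    ``frequencies`` is 5 positions (-2..+2) x 4 bases (A,C,G,T); each
    row sums to 1 when any k-mer was retained. By construction position
    -1 is all T and position 0 all C.
    """

    frequencies: np.ndarray  # (5, 4)
    n_kmers: int
    skipped: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.frequencies, index=list(PENTA_POSITIONS), columns=list(BASES))

    def freq(self, position: int, base: str) -> float:
        return float(self.frequencies[PENTA_POSITIONS.index(position), BASES.index(base)])


def pentanucleotide_freq(variants: Iterable, ref_ctx) -> PentanucMatrix:
    """Base frequencies at -2..+2 around C>T / C>G mutations in NTCNN context.

    For every SNV whose pyrimidine-stranded substitution is C>T or C>G,
    the pyrimidine-stranded 5-mer around the mutated base is extracted
    (purine-reference variants are reverse-complemented) and retained if
    it matches N-T-C-N-N. Edge and N-containing contexts are tallied as
    skipped.
    """
    from .variant_io import ContextUnavailable

    counts = np.zeros((5, 4))
    n_kmers = 0
    skipped: dict = {}

    def skip(reason):
        skipped[reason] = skipped.get(reason, 0) + 1

    for v in variants:
        if not v.is_snv:
            skip("not_snv")
            continue
        ref, alt = v.ref.upper(), v.alt.upper()
        if ref == "C" and alt in ("T", "G"):
            flip = False
        elif ref == "G" and alt in ("A", "C"):  # pyrimidine-strand C>T / C>G
            flip = True
        else:
            skip("not_ct_or_cg")
            continue
        try:
            kmer = ref_ctx.get_context(v.chrom, v.pos, flank=2)
        except ContextUnavailable:
            skip("context_unavailable")
            continue
        if "N" in kmer:
            skip("context_has_N")
            continue
        if flip:
            kmer = revcomp(kmer)
        if kmer[2] != "C":
            skip("context_mismatch")
            continue
        if kmer[1] != "T":
            skip("not_ntcnn")
            continue
        for i, base in enumerate(kmer):
            counts[i, BASES.index(base)] += 1
        n_kmers += 1

    freqs = counts / n_kmers if n_kmers > 0 else counts
    return PentanucMatrix(frequencies=freqs, n_kmers=n_kmers, skipped=skipped)


def write_fisher_results(results: Dict[str, FisherResult], path) -> None:
    rows = []
    for label, r in results.items():
        rows.append(
            {
                "comparison": label,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "odds_ratio": r.odds_ratio,
                "odds_ratio_sample": r.odds_ratio_sample,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "p_adjusted": r.p_adjusted,
                "m": r.m,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
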