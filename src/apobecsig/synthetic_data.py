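"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is a pure function of its arguments including the seed,
and each returns its own bookkeeping (true per-channel tallies, truth
tables of which variants should survive filtering) so downstream tests
need no external data.

The signature shapes emulate the APOBEC analysis setting: an SBS2-like
profile (C>T at 5'-TCN), an SBS13-like profile (C>G at 5'-TCN), a flat
background, and a C>A-skewed background standing in for oxidative/
culture backgrounds. Clonal variants get heterozygous VAFs from a Beta
distribution centered at 0.5 and truncated to the passing window, so
that noise is injected only through the explicit contamination,
non-PASS and parental knobs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .catalogs import (
    BASES,
    CHANNELS,
    N_CHANNELS,
    MutationCatalog,
    parse_channel,
    revcomp,
)
from .signature_refit import SignatureMatrix
from .cohort_compare import CohortSample
from .variant_io import ReferenceContext, VariantRecord

SIGNATURE_KINDS = ("sbs2-like", "sbs13-like", "flat", "c-to-a-skewed")

# default clonal VAF model: Beta(50, 50) has mean 0.5, sd ~0.05
CLONAL_BETA = (50.0, 50.0)
VAF_WINDOW = (0.3, 0.7)


def make_reference(
    length: int = 100_000, gc: float = 0.41, seed: int = 0, contig: str = "chrS"
) -> ReferenceContext:
    """Seeded i.i.d. reference sequence at the requested GC content.

    At the default length every trinucleotide occurs many times, so any
    96-channel catalog can be placed on it.
    """
    if length < 1000:
        raise ValueError("reference length must be >= 1000")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])
    return ReferenceContext({contig: seq})


def write_reference(ref_ctx: ReferenceContext, path) -> None:
    """Write the reference as FASTA and build a .fai index."""
    import pyfaidx

    with open(path, "w") as fh:
        for contig, length in ref_ctx.contig_lengths.items():
            fh.write(f">{contig}\n")
            seq = ref_ctx.fetch(contig, 1, length)
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    pyfaidx.Faidx(str(path))


def _signature_profile(kind: str, rng: np.random.Generator) -> np.ndarray:
    p = np.zeros(N_CHANNELS)
    if kind == "flat":
        p[:] = 1.0 / N_CHANNELS
    elif kind == "sbs2-like":
        # 97% of mass on T[C>T]N, 3' preference T > A > C = G
        weights = {"A": 0.30, "C": 0.14, "G": 0.14, "T": 0.39}
        for i, lab in enumerate(CHANNELS):
            five, ref, alt, three = parse_channel(lab)
            if five == "T" and ref == "C" and alt == "T":
                p[i] = 0.97 * weights[three]
        p[p == 0] = 0.03 / (N_CHANNELS - 4)
    elif kind == "sbs13-like":
        weights = {"A": 0.30, "C": 0.14, "G": 0.14, "T": 0.39}
        for i, lab in enumerate(CHANNELS):
            five, ref, alt, three = parse_channel(lab)
            if five == "T" and ref == "C" and alt == "G":
                p[i] = 0.97 * weights[three]
        p[p == 0] = 0.03 / (N_CHANNELS - 4)
    elif kind == "c-to-a-skewed":
        # 90% of mass on C>A channels with an A/T-flank preference,
        # mirroring the concentration of oxidative-damage backgrounds
        weights = {}
        for five in BASES:
            for three in BASES:
                weights[(five, three)] = (2.0 if five in "AT" else 1.0) * (
                    2.0 if three in "AT" else 1.0
                )
        wsum = sum(weights.values())
        for i, lab in enumerate(CHANNELS):
            five, ref, alt, three = parse_channel(lab)
            if ref == "C" and alt == "A":
                p[i] = 0.90 * weights[(five, three)] / wsum
        p[p == 0] = 0.10 / (N_CHANNELS - 16)
    elif kind.startswith("random"):
        p = rng.dirichlet(np.full(N_CHANNELS, 0.3))
    else:
        raise ValueError(f"unknown signature kind {kind!r}")
    return p / p.sum()


def make_signatures(kinds: Sequence[str] = SIGNATURE_KINDS, seed: int = 0) -> SignatureMatrix:
    """Build a synthetic signature matrix from named shapes.

    Kinds: "sbs2-like", "sbs13-like", "flat", "c-to-a-skewed", or
    "random-<n>" for a seeded Dirichlet-drawn spiky profile.
    """
    rng = np.random.default_rng(seed)
    profiles = np.column_stack([_signature_profile(k, rng) for k in kinds])
    return SignatureMatrix(list(kinds), profiles)


def simulate_catalog(
    sigs: SignatureMatrix,
    exposures: Sequence[float],
    n_mutations: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """One multinomial catalog draw of size n_mutations from S.e.

    Returns (counts, tally) where tally is the generator's own record of
    the draw, usable as oracle truth downstream.
    """
    e = np.asarray(exposures, dtype=float)
    if e.shape != (sigs.K,) or np.any(e < 0) or not e.any():
        raise ValueError("exposures must be a nonnegative, nonzero K-vector")
    p = sigs.profiles @ (e / e.sum())
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(int(n_mutations), p).astype(float)
    return counts, counts.copy()


@dataclass
class SimulatedVariants:
    """VCF-shaped variant set plus the generator's truth table."""

    records: list  # VariantRecord, sample variants
    parental: list  # VariantRecord, parental-clone variants
    truth: pd.DataFrame  # one row per emitted variant
    n_expected_survivors: int
    surviving_counts: np.ndarray  # (96,) catalog expected after filtering


def simulate_variants(
    catalog_row: np.ndarray,
    ref_ctx: ReferenceContext,
    sample_id: str = "sample",
    contamination_fraction: float = 0.0,
    parental_fraction: float = 0.0,
    nonpass_fraction: float = 0.0,
    seed: int = 0,
) -> SimulatedVariants:
    """Place each counted channel mutation on the reference as an SNV.

    For every channel, genomic positions whose trinucleotide matches the
    channel context on either strand are sampled without replacement;
    minus-strand placements emit the reverse-complemented alleles, which
    exercises pyrimidine-strand normalization by construction. Clonal
    VAFs are Beta(50, 50) truncated to the passing window; configured
    fractions of variants instead get an out-of-window VAF, a non-PASS
    status, or membership in the parental clone. The truth table records
    which variants should survive PASS + VAF filtering and parental
    subtraction.
    """
    row = np.asarray(catalog_row, dtype=float)
    if row.shape != (N_CHANNELS,):
        raise ValueError("catalog_row must be a 96-vector")
    rng = np.random.default_rng(seed)

    # index reference positions by their trinucleotide
    trinuc_positions: dict[str, list[tuple[str, int]]] = {}
    for contig, length in ref_ctx.contig_lengths.items():
        seq = ref_ctx.fetch(contig, 1, length)
        for i in range(1, length - 1):  # 0-based center; pos = i + 1
            tri = seq[i - 1 : i + 2]
            trinuc_positions.setdefault(tri, []).append((contig, i + 1))

    used: set[tuple[str, int]] = set()
    records: list[VariantRecord] = []
    parental: list[VariantRecord] = []
    truth_rows = []
    surviving = np.zeros(N_CHANNELS)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    for ch_idx, n in enumerate(row):
        n = int(round(n))
        if n == 0:
            continue
        five, ref, alt, three = parse_channel(CHANNELS[ch_idx])
        fwd = five + ref + three
        candidates = [(c, p, "+") for (c, p) in trinuc_positions.get(fwd, [])]
        candidates += [(c, p, "-") for (c, p) in trinuc_positions.get(revcomp(fwd), [])]
        candidates = [t for t in candidates if (t[0], t[1]) not in used]
        if len(candidates) < n:
            raise ValueError(
                f"reference too short: channel {CHANNELS[ch_idx]} needs {n} sites, "
                f"found {len(candidates)}; use a longer reference"
            )
        order = rng.permutation(len(candidates))
        for k in order[:n]:
            contig, pos, strand = candidates[k]
            used.add((contig, pos))
            if strand == "+":
                vref, valt = ref, alt
            else:
                vref, valt = comp[ref], comp[alt]

            contaminated = rng.random() < contamination_fraction
            if contaminated:
                side = rng.random() < 0.5
                vaf = rng.uniform(0.02, VAF_WINDOW[0] - 0.02) if side else rng.uniform(
                    VAF_WINDOW[1] + 0.02, 0.98
                )
            else:
                vaf = float(np.clip(rng.beta(*CLONAL_BETA), VAF_WINDOW[0] + 0.001, VAF_WINDOW[1] - 0.001))
            vaf = round(vaf, 6)
            status = "base_qual" if rng.random() < nonpass_fraction else "PASS"
            in_parental = rng.random() < parental_fraction

            rec = VariantRecord(
                sample_id=sample_id, chrom=contig, pos=pos, ref=vref, alt=valt,
                filter_status=status, vaf=vaf,
            )
            records.append(rec)
            if in_parental:
                parental.append(
                    VariantRecord(
                        sample_id="parental", chrom=contig, pos=pos, ref=vref, alt=valt,
                        filter_status="PASS", vaf=0.5,
                    )
                )
            survives = (
                status == "PASS"
                and VAF_WINDOW[0] <= vaf <= VAF_WINDOW[1]
                and not in_parental
            )
            if survives:
                surviving[ch_idx] += 1
            truth_rows.append(
                {
                    "chrom": contig, "pos": pos, "ref": vref, "alt": valt,
                    "channel": CHANNELS[ch_idx], "strand": strand, "vaf": vaf,
                    "filter_status": status, "in_parental": in_parental,
                    "survives": survives,
                }
            )

    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "pos", "ref", "alt", "channel", "strand", "vaf",
                 "filter_status", "in_parental", "survives"],
    )
    return SimulatedVariants(
        records=records,
        parental=parental,
        truth=truth,
        n_expected_survivors=int(surviving.sum()),
        surviving_counts=surviving,
    )


def write_vcf(records: Sequence[VariantRecord], ref_ctx: ReferenceContext, path) -> None:
    """Write SNV records as a minimal sorted VCF 4.2 with AF in INFO."""
    lines = ["##fileformat=VCFv4.2"]
    for contig, length in ref_ctx.contig_lengths.items():
        lines.append(f"##contig=<ID={contig},length={length}>")
    lines.append('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele fraction">')
    lines.append('##FILTER=<ID=base_qual,Description="Failed base quality model">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    contig_order = {c: i for i, c in enumerate(ref_ctx.contig_lengths)}
    for r in sorted(records, key=lambda r: (contig_order.get(r.chrom, 1 << 30), r.pos)):
        info = f"AF={r.vaf:.6f}" if r.vaf is not None else "."
        lines.append(
            f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t{r.filter_status}\t{info}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def simulate_controls(
    background_probs: np.ndarray,
    totals: Sequence[int] = (800, 1000, 1200),
    seed: int = 0,
    id_prefix: str = "control",
) -> MutationCatalog:
    """Triplicate-style control catalog: multinomial rows at fixed totals."""
    p = np.asarray(background_probs, dtype=float)
    if p.shape != (N_CHANNELS,) or np.any(p < 0) or not p.any():
        raise ValueError("background_probs must be a nonnegative, nonzero 96-vector")
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    rows = [rng.multinomial(int(t), p).astype(float) for t in totals]
    ids = [f"{id_prefix}_{i + 1}" for i in range(len(totals))]
    return MutationCatalog(ids, np.array(rows))


@dataclass(frozen=True)
class CohortConfig:
    """Cohort generator: genotype-dependent shift in one signature's fraction.

    Per-sample signature fractions are Beta-distributed around the group
    mean (concentration nu controls spread; nu=20 gives sd ~0.08 at
    mean 0.15); totals are log-normal around mean_total.
    """

    n_wt: int = 100
    n_mut: int = 100
    gene: str = "UBR5"
    signature: str = "SBS13"
    other_signature: str = "SBS5"
    base_fraction: float = 0.15
    effect: float = 0.0
    concentration: float = 20.0
    mean_total: float = 3000.0
    total_sigma: float = 0.4
    seed: int = 0


def simulate_cohort(cfg: CohortConfig = CohortConfig()) -> list[CohortSample]:
    """Cohort with a genotype-dependent shift in one signature's fraction."""
    rng = np.random.default_rng(cfg.seed)
    samples = []
    group_plan = [("wt", cfg.n_wt), ("mut", cfg.n_mut)]
    i = 0
    for status, n in group_plan:
        mean = cfg.base_fraction + (cfg.effect if status == "mut" else 0.0)
        if not 0.0 < mean < 1.0:
            raise ValueError("group mean fraction must be in (0, 1)")
        a = mean * cfg.concentration
        b = (1.0 - mean) * cfg.concentration
        for _ in range(n):
            i += 1
            total = int(round(np.exp(rng.normal(np.log(cfg.mean_total), cfg.total_sigma))))
            total = max(total, 10)
            frac = float(rng.beta(a, b))
            sig_act = frac * total
            other_act = (1.0 - frac) * total * 0.6  # refit need not be exhaustive
            samples.append(
                CohortSample(
                    sample_id=f"S{i:04d}",
                    genotype={cfg.gene: status},
                    activities={cfg.signature: sig_act, cfg.other_signature: other_act},
                    total_mutations=total,
                )
            )
    return samples


def make_gene_variants(
    sample_id: str,
    gene: str,
    n_variants: int,
    intronic_fraction: float = 0.5,
    indel_fraction: float = 0.2,
    seed: int = 0,
) -> list[VariantRecord]:
    """Annotated variant list for genotype-classification tests.

    A configured fraction of variants are labelled "Intron"; the rest get
    coding classifications. A fraction are indels, which count toward
    "mut" status exactly as SNVs do.
    """
    rng = np.random.default_rng(seed)
    coding = ["Missense_Mutation", "Nonsense_Mutation", "Silent", "Splice_Site"]
    records = []
    for i in range(n_variants):
        intronic = rng.random() < intronic_fraction
        is_indel = rng.random() < indel_fraction
        cls = "Intron" if intronic else coding[rng.integers(len(coding))]
        ref, alt = ("AT", "A") if is_indel else ("C", "T")
        records.append(
            VariantRecord(
                sample_id=sample_id, chrom="chr1", pos=1000 + i, ref=ref, alt=alt,
                filter_status="PASS", vaf=0.5, classification=cls, gene=gene,
            )
        )
    return records
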