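"""96-channel SBS mutation catalogs.

Single-base substitutions are classified into the canonical 96 channels:
six pyrimidine-stranded substitution types (C>A, C>G, C>T, T>A, T>C, T>G)
crossed with the 16 combinations of 5' and 3' flanking bases. Purine-
reference variants are reverse-complemented before classification, so
G>A at TGA and C>T at TCA land in the same channel.

Channel order follows the COSMIC convention: substitution blocks in the
order above, and within each block the 16 contexts ordered by 5' base
(A, C, G, T) then 3' base (A, C, G, T).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
PYRIMIDINES = "CT"
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-tolerant)."""
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _make_channels() -> list[str]:
    labels = []
    for sub in SUBSTITUTIONS:
        ref, alt = sub[0], sub[2]
        for five in BASES:
            for three in BASES:
                labels.append(f"{five}[{ref}>{alt}]{three}")
    return labels


CHANNELS: list[str] = _make_channels()
CHANNEL_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(CHANNELS)}
N_CHANNELS = 96


class ChannelError(ValueError):
    """Raised when a variant cannot be mapped to an SBS channel."""


def channel_label(five: str, ref: str, alt: str, three: str) -> str:
    return f"{five}[{ref}>{alt}]{three}"


def parse_channel(label: str) -> tuple[str, str, str, str]:
    """Split "X[R>A]Y" into (five_prime, ref, alt, three_prime)."""
    if len(label) != 7 or label[1] != "[" or label[3] != ">" or label[5] != "]":
        # canonical form is exactly 7 characters
        raise ChannelError(f"malformed channel label {label!r}")
    return label[0], label[2], label[4], label[6]


def classify_channel(ref: str, alt: str, trinuc: str) -> str:
    """Map an SNV with its genomic trinucleotide context to a channel label.

    Parameters
    ----------
    ref, alt
        Single reference/alternate bases as called on the forward strand.
    trinuc
        The 3-mer of reference sequence centered on the variant position,
        forward strand. ``trinuc[1]`` must equal ``ref``.

    Purine-reference variants are reverse-complemented onto the pyrimidine
    strand before labeling.
    """
    ref, alt, trinuc = ref.upper(), alt.upper(), trinuc.upper()
    if len(ref) != 1 or len(alt) != 1 or len(trinuc) != 3:
        raise ChannelError(f"not an SNV-in-trinucleotide: {ref}>{alt} @ {trinuc}")
    if any(b not in BASES for b in (ref, alt, *trinuc)):
        raise ChannelError(f"non-ACGT base in {ref}>{alt} @ {trinuc}")
    if trinuc[1] != ref:
        raise ChannelError(f"context center {trinuc[1]} does not match ref {ref}")
    if ref == alt:
        raise ChannelError("ref equals alt")
    if ref not in PYRIMIDINES:
        trinuc = revcomp(trinuc)
        ref = _COMPLEMENT[ref]
        alt = _COMPLEMENT[alt]
    label = f"{trinuc[0]}[{ref}>{alt}]{trinuc[2]}"
    if label not in CHANNEL_INDEX:  # pragma: no cover - unreachable by construction
        raise ChannelError(f"unmapped channel {label}")
    return label


@dataclass
class MutationCatalog:
    """Sample x 96-channel nonnegative count matrix in canonical channel order.

    Counts are stored as floats so the same container carries raw integer
    catalogs and background-corrected (fractional) matrices.
    """

    sample_ids: list[str]
    counts: np.ndarray  # (n_samples, 96)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape != (len(self.sample_ids), N_CHANNELS):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"({len(self.sample_ids)}, {N_CHANNELS})"
            )
        if np.any(self.counts < 0):
            raise ValueError("catalog contains negative counts")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, sample_id: str) -> np.ndarray:
        return self.counts[self.sample_ids.index(sample_id)]

    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def copy(self) -> "MutationCatalog":
        return MutationCatalog(list(self.sample_ids), self.counts.copy())

    def to_frame(self) -> pd.DataFrame:
        """Channels as rows (canonical order), samples as columns."""
        return pd.DataFrame(self.counts.T, index=CHANNELS, columns=self.sample_ids)


@dataclass
class CatalogBuildReport:
    """Tally of variants excluded during catalog construction."""

    n_classified: int = 0
    skipped: dict = field(default_factory=dict)

    def skip(self, reason: str) -> None:
        self.skipped[reason] = self.skipped.get(reason, 0) + 1


def build_catalog(variants, ref_ctx, sample_ids=None):
    """Assemble a :class:`MutationCatalog` from filtered variant records.

    Only SNVs with a clean ACGT trinucleotide context enter the matrix;
    indels, N-containing contexts, and contig-edge positions are tallied
    in the returned :class:`CatalogBuildReport` and skipped.

    Parameters
    ----------
    variants
        Iterable of :class:`~apobecsig.variant_io.VariantRecord`.
    ref_ctx
        A :class:`~apobecsig.variant_io.ReferenceContext`.
    sample_ids
        Sample roster fixing row order. Defaults to order of first
        appearance in ``variants``; pass explicitly to include all-zero
        rows for samples with no classifiable variants.

    Returns
    -------
    (MutationCatalog, CatalogBuildReport)
    """
    from .variant_io import ContextUnavailable

    if sample_ids is None:
        seen: list[str] = []
        for v in variants:
            if v.sample_id not in seen:
                seen.append(v.sample_id)
        sample_ids = seen
    index = {s: i for i, s in enumerate(sample_ids)}
    counts = np.zeros((len(sample_ids), N_CHANNELS))
    report = CatalogBuildReport()
    for v in variants:
        if not v.is_snv:
            report.skip("not_snv")
            continue
        if v.sample_id not in index:
            report.skip("sample_not_in_roster")
            continue
        try:
            trinuc = ref_ctx.get_context(v.chrom, v.pos, flank=1)
        except ContextUnavailable:
            report.skip("context_unavailable")
            continue
        if "N" in trinuc:
            report.skip("context_has_N")
            continue
        try:
            label = classify_channel(v.ref, v.alt, trinuc)
        except ChannelError:
            report.skip("context_mismatch")
            continue
        counts[index[v.sample_id], CHANNEL_INDEX[label]] += 1
        report.n_classified += 1
    return MutationCatalog(list(sample_ids), counts), report


def write_catalog(catalog: MutationCatalog, path) -> None:
    """Write a catalog TSV: first column "MutationType", one column per sample."""
    df = catalog.to_frame()
    df.index.name = "MutationType"
    df.to_csv(path, sep="\t")


class CatalogFormatError(ValueError):
    pass


def read_catalog(path) -> MutationCatalog:
    """Read a catalog TSV; rows may be permuted, the reader restores canonical order."""
    df = pd.read_csv(path, sep="\t", index_col="MutationType")
    labels = set(df.index)
    missing = [c for c in CHANNELS if c not in labels]
    if missing:
        raise CatalogFormatError(f"missing channel rows: {missing[:5]}" + ("..." if len(missing) > 5 else ""))
    unknown = sorted(labels - set(CHANNELS))
    if unknown:
        raise CatalogFormatError(f"unknown channel labels: {unknown[:5]}")
    if len(df.index) != N_CHANNELS:
        raise CatalogFormatError("duplicate channel rows")
    df = df.loc[CHANNELS]
    counts = df.to_numpy(dtype=float).T
    return MutationCatalog([str(c) for c in df.columns], counts)
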