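"""Reading, filtering and context lookup for somatic variant calls.

The pipeline starts from called variants (VCF), not reads. Somatic
filtering keeps PASS calls whose variant allele frequency (VAF) lies in
a clonal-heterozygous window (default [0.3, 0.7], inclusive) and removes
calls shared with the parental clone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd


@dataclass(frozen=True)
class VariantRecord:
    """One called variant (one ALT allele) for one sample.

    ``pos`` is the 1-based reference coordinate, as in VCF. ``vaf`` is the
    variant allele frequency in [0, 1], or None when the caller did not
    report one. ``classification`` carries a functional annotation label
    (e.g. "Intron", "Missense") when available; ``gene`` the annotated
    gene symbol. A record is an SNV iff both alleles have length 1.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    filter_status: str = "PASS"
    vaf: Optional[float] = None
    classification: Optional[str] = None
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref equals alt")
        if self.vaf is not None and not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def key(self) -> tuple:
        """Identity used for parental-clone matching (sample ignored)."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterConfig:
    """Somatic-variant filter: call status plus clonal VAF window.

    ``bounds_inclusive`` controls whether VAFs exactly at the window edges
    are retained (default True, reading "between 0.3 and 0.7" inclusively).
    """

    vaf_min: float = 0.3
    vaf_max: float = 0.7
    required_status: str = "PASS"
    bounds_inclusive: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf_min <= self.vaf_max <= 1.0:
            raise ValueError("require 0 <= vaf_min <= vaf_max <= 1")

    def vaf_ok(self, vaf: float) -> bool:
        if self.bounds_inclusive:
            return self.vaf_min <= vaf <= self.vaf_max
        return self.vaf_min < vaf < self.vaf_max


class ContextUnavailable(LookupError):
    """Requested context window falls off the contig (or contig unknown)."""


class ReferenceContext:
    """Uppercase base access over a reference, 1-based inclusive coordinates.

    Wraps either an in-memory dict ``{contig: sequence}`` or an indexed
    FASTA opened with pyfaidx.
    """

    def __init__(self, sequences: dict[str, str]):
        self._seqs = {c: s.upper() for c, s in sequences.items()}

    @classmethod
    def from_fasta(cls, path) -> "ReferenceContext":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path))
        obj = cls.__new__(cls)
        obj._seqs = None
        obj._fasta = fa
        obj._lengths = {name: len(fa[name]) for name in fa.keys()}
        return obj

    @property
    def contig_lengths(self) -> dict[str, int]:
        if self._seqs is not None:
            return {c: len(s) for c, s in self._seqs.items()}
        return dict(self._lengths)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Bases for the 1-based inclusive interval [start, end]."""
        lengths = self.contig_lengths
        if chrom not in lengths:
            raise ContextUnavailable(f"unknown contig {chrom!r}")
        if start < 1 or end > lengths[chrom] or start > end:
            raise ContextUnavailable(
                f"interval {chrom}:{start}-{end} outside contig of length {lengths[chrom]}"
            )
        if self._seqs is not None:
            return self._seqs[chrom][start - 1 : end]
        return str(self._fasta[chrom][start - 1 : end]).upper()

    def get_context(self, chrom: str, pos: int, flank: int) -> str:
        """The (2*flank+1)-mer centered on pos; raises ContextUnavailable at edges."""
        return self.fetch(chrom, pos - flank, pos + flank)


def get_context(ref_ctx: ReferenceContext, chrom: str, pos: int, flank: int) -> str:
    return ref_ctx.get_context(chrom, pos, flank)


class VCFFormatError(ValueError):
    pass


def _variant_vaf(variant, alt_index: int):
    """Pull a per-ALT allele frequency from FORMAT AF/VAF or INFO AF."""
    for tag in ("AF", "VAF"):
        try:
            arr = variant.format(tag)
        except KeyError:
            arr = None
        if arr is not None:
            vals = arr[0]
            v = float(vals[alt_index]) if len(vals) > alt_index else float(vals[0])
            if v == v:  # not NaN
                return v
    for tag in ("AF", "VAF"):
        v = variant.INFO.get(tag)
        if v is not None:
            if isinstance(v, (tuple, list)):
                v = v[alt_index] if len(v) > alt_index else v[0]
            return float(v)
    return None


def read_variants(path, sample_id: str) -> list[VariantRecord]:
    """Read one sample's variants from a VCF (plain or bgzipped).

    Multi-allelic sites are split into one record per ALT allele; VAF is
    taken from the AF/VAF FORMAT field or INFO AF when present, else left
    missing. Coordinates stay 1-based.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise VCFFormatError(f"cannot parse VCF {path}: {exc}") from exc
    records: list[VariantRecord] = []
    for variant in vcf:
        filt = variant.FILTER or "PASS"  # cyvcf2 reports PASS as None
        for i, alt in enumerate(variant.ALT):
            if alt is None or alt.startswith("<"):
                continue  # symbolic allele
            vaf = _variant_vaf(variant, i)
            if vaf is not None:
                vaf = min(max(vaf, 0.0), 1.0)
            records.append(
                VariantRecord(
                    sample_id=sample_id,
                    chrom=variant.CHROM,
                    pos=variant.POS,
                    ref=variant.REF.upper(),
                    alt=alt.upper(),
                    filter_status=filt,
                    vaf=vaf,
                )
            )
    vcf.close()
    return records


@dataclass
class FilterTally:
    """Per-reason drop counts from filter_variants."""

    n_input: int = 0
    n_retained: int = 0
    dropped: dict = field(default_factory=dict)

    def drop(self, reason: str) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + 1

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())


def filter_variants(
    records: Iterable[VariantRecord], cfg: FilterConfig = FilterConfig()
) -> tuple[list[VariantRecord], FilterTally]:
    """Apply the status + VAF filter; returns (retained, per-reason tally).

    Records with missing VAF are dropped (conservative) and tallied under
    their own reason. Input order is preserved; input is not modified.
    """
    kept: list[VariantRecord] = []
    tally = FilterTally()
    for rec in records:
        tally.n_input += 1
        if rec.filter_status != cfg.required_status:
            tally.drop("filter_status")
            continue
        if rec.vaf is None:
            tally.drop("vaf_missing")
            continue
        if not cfg.vaf_ok(rec.vaf):
            tally.drop("vaf_out_of_range")
            continue
        kept.append(rec)
        tally.n_retained += 1
    return kept, tally


def subtract_parental(
    records: Iterable[VariantRecord], parental: Iterable[VariantRecord]
) -> list[VariantRecord]:
    """Drop records whose (chrom, pos, ref, alt) occurs in the parental clone."""
    parental_keys = {p.key for p in parental}
    return [r for r in records if r.key not in parental_keys]


_TSV_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "vaf", "filter_status", "classification", "gene"]


def write_variants_tsv(records: Iterable[VariantRecord], path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "vaf": r.vaf,
            "filter_status": r.filter_status,
            "classification": r.classification,
            "gene": r.gene,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    records = []
    for row in df.itertuples(index=False):
        records.append(
            VariantRecord(
                sample_id=row.sample_id,
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                filter_status=row.filter_status,
                vaf=None if pd.isna(row.vaf) else float(row.vaf),
                classification=None if pd.isna(row.classification) else str(row.classification),
                gene=None if pd.isna(row.gene) else str(row.gene),
            )
        )
    return records


def write_tally_tsv(tally: FilterTally, path) -> None:
    rows = [{"reason": "retained", "count": tally.n_retained}]
    rows += [{"reason": k, "count": v} for k, v in sorted(tally.dropped.items())]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
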