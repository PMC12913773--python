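"""End-to-end orchestration: VCFs -> filtered variants -> catalog ->
background correction -> signature refit -> APOBEC statistics.

Every stage writes its artifact under the output directory and the run
ends with a manifest (JSON) recording inputs, configuration, seed and
SHA-256 checksums of every output, so a rerun with an identical config
is bit-identical and auditably so.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import __version__
from .apobec_stats import (
    ApobecDefinition,
    apobec_fraction,
    compare_apobec_fractions,
    pentanucleotide_freq,
    write_fisher_results,
)
from .background_correction import (
    BackgroundConfig,
    bootstrap_background,
    subtract_background,
    write_background,
)
from .catalogs import MutationCatalog, build_catalog, write_catalog
from .signature_refit import RefitConfig, read_signatures, refit_catalog, write_exposures
from .variant_io import (
    FilterConfig,
    ReferenceContext,
    filter_variants,
    read_variants,
    subtract_parental,
    write_variants_tsv,
)

log = logging.getLogger("apobecsig")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    reference: str = ""
    vcfs: Dict[str, str] = field(default_factory=dict)  # sample_id -> path
    parental_vcf: Optional[str] = None
    signatures: str = ""
    out_dir: str = "apobecsig_out"
    control_samples: List[str] = field(default_factory=list)
    groups: Dict[str, str] = field(default_factory=dict)  # sample_id -> group label
    fisher_reference: Optional[str] = None
    apobec_context: str = "TCN"
    run_pentanuc: bool = True
    vaf_min: float = 0.3
    vaf_max: float = 0.7
    required_status: str = "PASS"
    n_boot: int = 10_000
    max_delta: float = 0.004
    seed: int = 0

    def filter_config(self) -> FilterConfig:
        return FilterConfig(self.vaf_min, self.vaf_max, self.required_status)


def parse_config(path) -> PipelineConfig:
    """Flat key=value config file; 'vcf.<sample>=path' adds a sample VCF,
    'group.<sample>=label' assigns a comparison group."""
    cfg = PipelineConfig()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key.startswith("vcf."):
            cfg.vcfs[key[4:]] = val
        elif key.startswith("group."):
            cfg.groups[key[6:]] = val
        elif key == "control_samples":
            cfg.control_samples = [s.strip() for s in val.split(",") if s.strip()]
        elif key in ("vaf_min", "vaf_max", "max_delta"):
            setattr(cfg, key, float(val))
        elif key in ("n_boot", "seed"):
            setattr(cfg, key, int(val))
        elif key == "run_pentanuc":
            cfg.run_pentanuc = val.lower() in ("1", "true", "yes")
        elif key in ("reference", "parental_vcf", "signatures", "out_dir",
                     "fisher_reference", "apobec_context", "required_status"):
            setattr(cfg, key, val)
        else:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    # -- validation before any stage runs
    for label, p in [("reference", cfg.reference), ("signatures", cfg.signatures)]:
        if not p or not Path(p).exists():
            raise PipelineError("validate", f"{label} path missing or not found: {p!r}")
    for sample, p in cfg.vcfs.items():
        if not Path(p).exists():
            raise PipelineError("validate", f"VCF for sample {sample!r} not found: {p}")
    if cfg.parental_vcf and not Path(cfg.parental_vcf).exists():
        raise PipelineError("validate", f"parental VCF not found: {cfg.parental_vcf}")
    if not cfg.vcfs:
        raise PipelineError("validate", "no sample VCFs configured")

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: Dict[str, Path] = {}
    stage_stats: Dict[str, dict] = {}

    ref_ctx = ReferenceContext.from_fasta(cfg.reference)

    # -- read + filter + parental subtraction
    parental = (
        read_variants(cfg.parental_vcf, "parental") if cfg.parental_vcf else []
    )
    sample_ids = list(cfg.vcfs)
    all_filtered = []
    filter_stats = {}
    for sample in sample_ids:
        records = read_variants(cfg.vcfs[sample], sample)
        kept, tally = filter_variants(records, cfg.filter_config())
        kept = subtract_parental(kept, parental)
        all_filtered.extend(kept)
        filter_stats[sample] = {
            "n_input": tally.n_input,
            "n_after_filter": tally.n_retained,
            "n_after_parental": len(kept),
            "dropped": tally.dropped,
        }
        log.info("filter %s: %d -> %d retained", sample, tally.n_input, len(kept))
    write_variants_tsv(all_filtered, out / "filtered_variants.tsv")
    outputs["filtered_variants"] = out / "filtered_variants.tsv"
    stage_stats["filter"] = filter_stats

    # -- catalog
    catalog, report = build_catalog(all_filtered, ref_ctx, sample_ids=sample_ids)
    write_catalog(catalog, out / "catalog.tsv")
    outputs["catalog"] = out / "catalog.tsv"
    stage_stats["catalog"] = {
        "n_classified": report.n_classified,
        "skipped": report.skipped,
        "totals": dict(zip(sample_ids, catalog.totals().tolist())),
    }

    # -- background correction (controls designated by label)
    if cfg.control_samples:
        missing = [s for s in cfg.control_samples if s not in sample_ids]
        if missing:
            raise PipelineError("background", f"control samples not in roster: {missing}")
        ctrl_rows = [catalog.row(s) for s in cfg.control_samples]
        controls = MutationCatalog(list(cfg.control_samples), np.array(ctrl_rows))
        bg = bootstrap_background(controls, BackgroundConfig(cfg.n_boot, cfg.seed))
        write_background(bg, out / "background.tsv", out / "background.json")
        outputs["background"] = out / "background.tsv"
        outputs["background_meta"] = out / "background.json"
        experimental_ids = [s for s in sample_ids if s not in cfg.control_samples]
        exp_catalog = MutationCatalog(
            experimental_ids, np.array([catalog.row(s) for s in experimental_ids])
        )
        corrected = subtract_background(exp_catalog, bg)
        stage_stats["background"] = {"draw_size": bg.draw_size, "n_boot": bg.n_boot}
    else:
        corrected = catalog
    write_catalog(corrected, out / "corrected_catalog.tsv")
    outputs["corrected_catalog"] = out / "corrected_catalog.tsv"

    # -- signature refit
    sigs = read_signatures(cfg.signatures)
    refit_cfg = RefitConfig(max_delta=cfg.max_delta, seed=cfg.seed)
    results = refit_catalog(corrected, sigs, refit_cfg)
    write_exposures(results, out / "exposures.tsv")
    outputs["exposures"] = out / "exposures.tsv"

    # -- APOBEC fractions and Fisher comparisons
    defn = ApobecDefinition(cfg.apobec_context)
    frac_rows = []
    for sample, row in zip(corrected.sample_ids, corrected.counts):
        fr = apobec_fraction(row, defn)
        frac_rows.append(
            {"sample_id": sample, "apobec": fr.apobec, "total": fr.total,
             "fraction": fr.fraction if fr.defined else float("nan")}
        )
    import pandas as pd

    pd.DataFrame(frac_rows).to_csv(out / "apobec_fractions.tsv", sep="\t", index=False)
    outputs["apobec_fractions"] = out / "apobec_fractions.tsv"

    if cfg.groups and cfg.fisher_reference:
        pooled: Dict[str, np.ndarray] = {}
        for sample, row in zip(corrected.sample_ids, corrected.counts):
            grp = cfg.groups.get(sample)
            if grp is None:
                continue
            pooled.setdefault(grp, np.zeros(2))
            fr = apobec_fraction(row, defn)
            pooled[grp] += [fr.apobec, fr.total - fr.apobec]
        groups = {g: (int(round(v[0])), int(round(v[1]))) for g, v in pooled.items()}
        fisher = compare_apobec_fractions(groups, cfg.fisher_reference)
        write_fisher_results(fisher, out / "fisher.tsv")
        outputs["fisher"] = out / "fisher.tsv"

    # -- pentanucleotide context
    if cfg.run_pentanuc:
        penta = pentanucleotide_freq(all_filtered, ref_ctx)
        df = penta.to_frame()
        df.index.name = "position"
        df.to_csv(out / "pentanucleotide.tsv", sep="\t")
        outputs["pentanucleotide"] = out / "pentanucleotide.tsv"
        stage_stats["pentanucleotide"] = {"n_kmers": penta.n_kmers, "skipped": penta.skipped}

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "stages": stage_stats,
        "outputs": {k: str(v) for k, v in outputs.items()},
        "checksums": {k: _sha256(v) for k, v in sorted(outputs.items())},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
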