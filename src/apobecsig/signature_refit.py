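"""Signature refitting: NNLS, strict best-subset selection, presence test.

A catalog row is decomposed against a fixed 96 x K signature matrix by
non-negative least squares. The strict best-subset rule then prunes
signatures: starting from the full-set fit with reconstruction cosine
c_K, the fit descends to size k-1 whenever the best size-(k-1) subset's
cosine is within ``max_delta`` of the current one (default 0.004). Per
size, the best subset is found exhaustively for K <= 12 and by backward
elimination otherwise. The result is a deliberately conservative
activity estimate: a signature survives only if dropping it costs
reconstruction quality.

The presence test is a multinomial likelihood-ratio test with a
parametric-bootstrap null: an approximation to dedicated signature-
activity tests, not a reimplementation of any of them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .catalogs import CHANNELS, N_CHANNELS, MutationCatalog


@dataclass
class SignatureMatrix:
    """K signature profiles over the 96 channels; columns sum to one."""

    labels: list[str]
    profiles: np.ndarray  # (96, K)

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        K = len(self.labels)
        if K < 1:
            raise ValueError("need at least one signature")
        if self.profiles.shape != (N_CHANNELS, K):
            raise ValueError(f"profiles shape {self.profiles.shape} != (96, {K})")
        if np.any(self.profiles < 0):
            raise ValueError("negative signature entries")
        sums = self.profiles.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError(f"signature columns must sum to 1, got {sums}")
        if len(set(self.labels)) != K:
            raise ValueError("duplicate signature labels")

    @property
    def K(self) -> int:
        return len(self.labels)

    def column(self, label: str) -> np.ndarray:
        return self.profiles[:, self.labels.index(label)]

    def subset(self, labels: Sequence[str]) -> "SignatureMatrix":
        idx = [self.labels.index(l) for l in labels]
        return SignatureMatrix(list(labels), self.profiles[:, idx])


def write_signatures(sigs: SignatureMatrix, path) -> None:
    df = pd.DataFrame(sigs.profiles, index=CHANNELS, columns=sigs.labels)
    df.index.name = "MutationType"
    df.to_csv(path, sep="\t")


def read_signatures(path) -> SignatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col="MutationType")
    missing = [c for c in CHANNELS if c not in df.index]
    if missing:
        raise ValueError(f"signature file missing channels: {missing[:5]}")
    df = df.loc[CHANNELS]
    return SignatureMatrix([str(c) for c in df.columns], df.to_numpy(dtype=float))


@dataclass(frozen=True)
class RefitConfig:
    """max_delta is the tolerated loss in reconstruction cosine per descent."""

    max_delta: float = 0.004
    exhaustive_max_k: int = 12
    presence_test_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_delta <= 1.0:
            raise ValueError("max_delta must be in [0, 1]")


@dataclass
class ExposureResult:
    """Per-sample refit: activities on the mutation-count scale.

    ``exposures`` is a K-vector aligned with the signature labels, zero
    outside ``selected``. ``fractions`` are exposures normalized to sum
    to one ("scaled to one"); all-zero with ``zero_total=True`` when no
    activity was assigned.
    """

    sample_id: str
    signature_labels: list[str]
    exposures: np.ndarray
    selected: list[str]
    cosine_full: float
    cosine_selected: float
    fractions: Optional[np.ndarray] = None
    zero_total: bool = False

    def exposure_of(self, label: str) -> float:
        return float(self.exposures[self.signature_labels.index(label)])

    def fraction_of(self, label: str) -> float:
        if self.fractions is None:
            raise ValueError("call normalize_exposures first")
        return float(self.fractions[self.signature_labels.index(label)])


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """a.b / (|a||b|); zero if either norm is zero."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a @ b / (na * nb))


def nnls_refit(observed: np.ndarray, sigs: SignatureMatrix) -> np.ndarray:
    """Non-negative least-squares exposures: argmin_{e>=0} |S e - observed|_2."""
    observed = np.asarray(observed, dtype=float)
    if observed.shape != (N_CHANNELS,):
        raise ValueError("observed must be a 96-vector")
    if np.any(observed < 0):
        raise ValueError("observed has negative entries")
    if not observed.any():
        return np.zeros(sigs.K)
    exposures, _ = nnls(sigs.profiles, observed)
    return exposures


def _subset_cosine(observed, profiles, idx):
    e, _ = nnls(profiles[:, idx], observed)
    recon = profiles[:, idx] @ e
    na = np.linalg.norm(observed)
    nb = np.linalg.norm(recon)
    if na == 0.0 or nb == 0.0:
        return 0.0, e
    return float(observed @ recon / (na * nb)), e


def _best_subset_of_size(observed, profiles, size, pool):
    """Best (cosine, subset, exposures) among subsets of `pool` of given size.

    Ties broken toward the lexicographically smallest index tuple, which
    combinations() yields first, so strict > keeps the earliest winner.
    """
    best = (-1.0, None, None)
    for idx in combinations(pool, size):
        cos, e = _subset_cosine(observed, profiles, list(idx))
        if cos > best[0] + 1e-12:
            best = (cos, idx, e)
    return best


def best_subset_refit(
    observed: np.ndarray, sigs: SignatureMatrix, cfg: RefitConfig = RefitConfig()
) -> ExposureResult:
    """Strict best-subset NNLS refit with max_delta pruning.

    Descends from the full signature set one size at a time; a descent to
    size k-1 is accepted iff the best size-(k-1) cosine is >= the current
    cosine minus ``max_delta``. Exhaustive search per size when
    K <= ``exhaustive_max_k``; otherwise backward elimination from the
    current subset.
    """
    observed = np.asarray(observed, dtype=float)
    full = nnls_refit(observed, sigs)
    cosine_full = cosine_similarity(observed, sigs.profiles @ full)
    exhaustive = sigs.K <= cfg.exhaustive_max_k

    current_idx = tuple(range(sigs.K))
    current_cos = cosine_full
    current_exp = full
    while len(current_idx) > 1:
        pool = range(sigs.K) if exhaustive else current_idx
        cos, idx, e = _best_subset_of_size(observed, sigs.profiles, len(current_idx) - 1, pool)
        if cos >= current_cos - cfg.max_delta:
            current_idx, current_cos, current_exp = idx, cos, e
        else:
            break

    exposures = np.zeros(sigs.K)
    exposures[list(current_idx)] = current_exp
    selected = [sigs.labels[i] for i in current_idx]
    return ExposureResult(
        sample_id="",
        signature_labels=list(sigs.labels),
        exposures=exposures,
        selected=selected,
        cosine_full=cosine_full,
        cosine_selected=current_cos,
    )


def normalize_exposures(result: ExposureResult) -> ExposureResult:
    """Populate fractions = exposures / sum(exposures) ("scaled to one")."""
    total = result.exposures.sum()
    if total > 0:
        fractions = result.exposures / total
        zero = False
    else:
        fractions = np.zeros_like(result.exposures)
        zero = True
    return replace(result, fractions=fractions, zero_total=zero)


def _multinomial_loglik(counts: np.ndarray, recon: np.ndarray, floor: float = 1e-9) -> float:
    """Log-likelihood of channel counts under the reconstruction's composition.

    The reconstruction is floored then renormalized to probabilities so
    channels with zero reconstructed mass but nonzero counts stay finite.
    Constant terms (multinomial coefficient) cancel in the ratio and are
    omitted.
    """
    p = np.maximum(np.asarray(recon, dtype=float), floor)
    p = p / p.sum()
    return float(counts @ np.log(p))


def presence_test(
    observed: np.ndarray,
    sigs: SignatureMatrix,
    target: str,
    cfg: RefitConfig = RefitConfig(),
) -> tuple[float, float]:
    """Likelihood-ratio test for whether `target` is active in the sample.

    statistic = 2 (l1 - l0), the multinomial log-likelihood ratio between
    NNLS reconstructions with and without the target signature, clipped at
    zero (the models are nested). The p-value comes from a parametric
    bootstrap: ``presence_test_reps`` catalogs are simulated under the
    null reconstruction and p = (1 + #{null stat >= observed stat}) /
    (reps + 1).
    """
    if target not in sigs.labels:
        raise ValueError(f"unknown signature {target!r}")
    observed = np.asarray(observed, dtype=float)
    n = observed.sum()
    if n < 1:
        raise ValueError("need at least one mutation")
    null_labels = [l for l in sigs.labels if l != target]
    if not null_labels:
        raise ValueError("cannot test the only signature in the matrix")
    null_sigs = sigs.subset(null_labels)

    def stat_for(counts: np.ndarray) -> float:
        recon1 = sigs.profiles @ nnls_refit(counts, sigs)
        recon0 = null_sigs.profiles @ nnls_refit(counts, null_sigs)
        s = 2.0 * (_multinomial_loglik(counts, recon1) - _multinomial_loglik(counts, recon0))
        return max(s, 0.0)

    observed_stat = stat_for(observed)
    null_recon = null_sigs.profiles @ nnls_refit(observed, null_sigs)
    p_null = np.maximum(null_recon, 1e-9)
    p_null = p_null / p_null.sum()
    rng = np.random.default_rng(cfg.seed)
    n_draw = int(round(n))
    exceed = 0
    for _ in range(cfg.presence_test_reps):
        sim = rng.multinomial(n_draw, p_null).astype(float)
        if stat_for(sim) >= observed_stat:
            exceed += 1
    p = (1 + exceed) / (cfg.presence_test_reps + 1)
    return observed_stat, p


def refit_catalog(
    catalog: MutationCatalog, sigs: SignatureMatrix, cfg: RefitConfig = RefitConfig()
) -> list[ExposureResult]:
    """best_subset_refit + normalize_exposures for every catalog row."""
    results = []
    for sample_id, row in zip(catalog.sample_ids, catalog.counts):
        if not row.any():
            res = ExposureResult(
                sample_id=sample_id,
                signature_labels=list(sigs.labels),
                exposures=np.zeros(sigs.K),
                selected=[],
                cosine_full=0.0,
                cosine_selected=0.0,
            )
        else:
            res = best_subset_refit(row, sigs, cfg)
            res.sample_id = sample_id
        results.append(normalize_exposures(res))
    return results


def write_exposures(results: Sequence[ExposureResult], path) -> None:
    rows = []
    for r in results:
        for i, label in enumerate(r.signature_labels):
            rows.append(
                {
                    "sample_id": r.sample_id,
                    "signature": label,
                    "exposure": r.exposures[i],
                    "fraction": r.fractions[i] if r.fractions is not None else np.nan,
                    "selected": int(label in r.selected),
                    "cosine_selected": r.cosine_selected,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
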