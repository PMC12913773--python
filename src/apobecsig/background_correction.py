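"""Bootstrapped background-profile estimation and thresholded subtraction.

Control samples (e.g. early-timepoint samples carrying a safe-harbor
control sgRNA) define a background mutational profile. To damp outliers,
each control is down-scaled proportionally to the control with the lowest
mutation count; for each control, ``n_boot`` multinomial bootstrap draws
of that common size are generated with the control's own channel
proportions as weights, and the background profile is the element-wise
mean over all n_controls x n_boot draws (30,000 draws for three controls
at the default n_boot = 10,000). The profile is then subtracted from each
experimental catalog row with thresholding at zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalogs import CHANNELS, N_CHANNELS, MutationCatalog


@dataclass(frozen=True)
class BackgroundConfig:
    n_boot: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")


@dataclass
class BackgroundProfile:
    """Mean bootstrap background profile with its provenance.

    ``profile`` sums to ``draw_size`` exactly (each bootstrap draw does).
    """

    profile: np.ndarray  # (96,)
    n_controls: int
    draw_size: int
    n_boot: int
    seed: int
    control_ids: tuple = ()

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=float)
        if self.profile.shape != (N_CHANNELS,):
            raise ValueError("profile must be a 96-vector")
        if np.any(self.profile < 0):
            raise ValueError("negative background entries")


def downscale_controls(controls: MutationCatalog) -> tuple[MutationCatalog, int]:
    """Scale every control row to the floor of the minimum row total.

    Returns the scaled catalog (fractional counts) and the common total,
    which is the bootstrap draw size.
    """
    totals = controls.totals()
    if np.any(totals <= 0):
        bad = [s for s, t in zip(controls.sample_ids, totals) if t <= 0]
        raise ValueError(f"control sample(s) with zero mutations: {bad}")
    draw_size = int(math.floor(totals.min()))
    scaled = controls.counts * (draw_size / totals)[:, None]
    return MutationCatalog(list(controls.sample_ids), scaled), draw_size


def bootstrap_background(
    controls: MutationCatalog, cfg: BackgroundConfig = BackgroundConfig()
) -> BackgroundProfile:
    """Estimate the mean multinomial-bootstrap background profile.

    Controls are processed in roster order with sequential draws, so the
    seed fully determines the result.
    """
    if controls.n_samples < 1:
        raise ValueError("need at least one control sample")
    _, draw_size = downscale_controls(controls)
    rng = np.random.default_rng(cfg.seed)
    acc = np.zeros(N_CHANNELS)
    for i in range(controls.n_samples):
        p = controls.counts[i] / controls.counts[i].sum()
        draws = rng.multinomial(draw_size, p, size=cfg.n_boot)
        acc += draws.sum(axis=0)
    profile = acc / (controls.n_samples * cfg.n_boot)
    return BackgroundProfile(
        profile=profile,
        n_controls=controls.n_samples,
        draw_size=draw_size,
        n_boot=cfg.n_boot,
        seed=cfg.seed,
        control_ids=tuple(controls.sample_ids),
    )


def expected_background(controls: MutationCatalog) -> np.ndarray:
    """Closed-form expectation of the bootstrap profile.

    Each bootstrap draw for control i has expectation draw_size * p_i, so
    the mean over controls and draws is draw_size * mean_i(p_i).
    """
    _, draw_size = downscale_controls(controls)
    props = controls.counts / controls.totals()[:, None]
    return draw_size * props.mean(axis=0)


def subtract_background(catalog: MutationCatalog, bg: BackgroundProfile) -> MutationCatalog:
    """Element-wise max(count - background, 0); the input is not modified."""
    corrected = np.maximum(catalog.counts - bg.profile[None, :], 0.0)
    return MutationCatalog(list(catalog.sample_ids), corrected)


def write_background(bg: BackgroundProfile, path, sidecar_path=None) -> None:
    df = pd.DataFrame({"MutationType": CHANNELS, "background": bg.profile})
    df.to_csv(path, sep="\t", index=False)
    if sidecar_path is not None:
        meta = {
            "n_controls": bg.n_controls,
            "draw_size": bg.draw_size,
            "n_boot": bg.n_boot,
            "seed": bg.seed,
            "control_ids": list(bg.control_ids),
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_background(path, sidecar_path=None) -> BackgroundProfile:
    df = pd.read_csv(path, sep="\t")
    df = df.set_index("MutationType").loc[CHANNELS]
    meta = {"n_controls": 0, "draw_size": 0, "n_boot": 0, "seed": 0, "control_ids": []}
    if sidecar_path is not None:
        with open(sidecar_path) as fh:
            meta.update(json.load(fh))
    return BackgroundProfile(
        profile=df["background"].to_numpy(dtype=float),
        n_controls=int(meta["n_controls"]),
        draw_size=int(meta["draw_size"]),
        n_boot=int(meta["n_boot"]),
        seed=int(meta["seed"]),
        control_ids=tuple(meta["control_ids"]),
    )
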