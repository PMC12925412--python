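"""Programmatic pipeline glue: specimen images -> feature table -> PCA/LMM.

Used by the CLI subcommands and by simulation studies (parameter recovery,
type-I error) that need many end-to-end runs without touching disk.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from mothwing.colour_channels import RNLParams, convert_channels
from mothwing.morphometrics import orient_wing, wing_size
from mothwing.pattern_metrics import GaborBank, build_gabor_bank, extract_features
from mothwing.stats_analysis import PCAResult, fit_lmm_all, run_pca
from mothwing.synthetic_wings import ConeCatchImage, EffectConfig, generate_dataset

__all__ = ["process_specimen", "feature_table", "simulate_features", "simulate_and_fit", "FAST_SIM"]

#: reduced settings for simulation studies: small frames, 3-scale bank
FAST_SIM = {
    "size_px": (64, 96),
    "px_per_cm": 32.0,
    "scales_cm": (0.0625, 0.125, 0.25),
}


def process_specimen(
    img: ConeCatchImage,
    bank: GaborBank,
    rnl: RNLParams | None = None,
    orient: bool = True,
) -> pd.Series:
    """Orient, measure and featurize a single cone-catch image."""
    if orient:
        img = orient_wing(img)
    size = wing_size(img.mask, img.px_per_cm)
    stack = convert_channels(img, rnl)
    return extract_features(stack, bank, size.as_tuple())


def feature_table(
    images: Sequence[ConeCatchImage],
    ids: Sequence[str],
    bank: GaborBank,
    rnl: RNLParams | None = None,
    orient: bool = True,
) -> pd.DataFrame:
    """Feature rows for a set of specimens, indexed by specimen id."""
    rows = [process_specimen(img, bank, rnl, orient) for img in images]
    out = pd.DataFrame(rows)
    out.index = pd.Index(ids, name="id")
    return out


def simulate_features(
    n: int,
    cfg: EffectConfig | None = None,
    seed: int = 0,
    size_px: tuple[int, int] = FAST_SIM["size_px"],
    px_per_cm: float = FAST_SIM["px_per_cm"],
    scales_cm: tuple[float, ...] = FAST_SIM["scales_cm"],
    orient: bool = True,
    bank: GaborBank | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a synthetic dataset and run it through feature extraction.

    Pass a prebuilt ``bank`` when running many replicates so its kernel FFT
    cache is reused.
    """
    images, meta = generate_dataset(n, cfg, seed=seed, size_px=size_px, px_per_cm=px_per_cm)
    if bank is None:
        bank = build_gabor_bank(scales_cm=scales_cm, px_per_cm=px_per_cm)
    feats = feature_table(images, meta["id"], bank, orient=orient)
    return feats, meta


def simulate_and_fit(
    n: int,
    cfg: EffectConfig | None = None,
    seed: int = 0,
    n_components: int = 3,
    **sim_kwargs,
) -> tuple[PCAResult, pd.DataFrame, pd.DataFrame]:
    """Full simulated analysis: features -> PCA -> mixed-model tables.

    Returns (pca, meta, lmm_table); the lmm_table covers the first
    ``n_components`` principal components.
    """
    feats, meta = simulate_features(n, cfg, seed=seed, **sim_kwargs)
    pca = run_pca(feats, n_components=n_components)
    lmm = fit_lmm_all(pca, meta, components=tuple(range(n_components)))
    return pca, meta, lmm
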