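"""Synthetic cone-catch wing images with known, settable effect magnitudes.

Generates wing-shaped masks carrying a banded colour pattern (basal field,
darker median band, pale terminal field) plus specimen metadata, so that the
whole downstream pipeline — channel conversion, granularity metrics, PCA and
mixed models — can be exercised and validated without museum photographs.

Injected effects (all configurable, all recoverable downstream):

* sex       — males darker (additive luminance offset) and less contrasting
              (multiplicative band-vs-field contrast scale);
* taxon     — ``fennokarelica`` less contrasting (multiplicative scale);
* wear      — stochastic scale loss: a wear-level-dependent fraction of
              in-mask pixels replaced by pale achromatic speckle;
* age       — fading: reflectances relaxed toward the wing mean by a
              per-year rate times specimen age (reference year - capture year).

Every specimen is generated from its own seeded generator: identical
(spec, config, size) inputs give bit-identical images.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "CATCH_FLOOR",
    "WingSpec",
    "EffectConfig",
    "ConeCatchImage",
    "generate_specimen",
    "generate_dataset",
    "default_design",
]

#: Floor applied to cone catches before any logarithm.
CATCH_FLOOR = 1e-6

SEXES = ("male", "female")
TAXA = ("badiata", "fennokarelica", "none")

# Base cone catches (q_L, q_M, q_S) for the three transverse pattern regions.
# Brownish wing: slight L > M > S asymmetry so the chromatic channels are
# exercised, median band darkest, terminal field palest.
_BASAL = np.array([0.38, 0.33, 0.24])
_BAND = np.array([0.20, 0.16, 0.11])
_TERMINAL = np.array([0.56, 0.52, 0.40])
_BACKGROUND = 0.95
_SPECKLE = 0.85


@dataclass(frozen=True)
class WingSpec:
    """Covariates and seed fully determining one synthetic specimen."""

    sex: str
    taxon: str
    wear: int
    collection_year: int
    latitude: float
    longitude: float
    collection_group: str
    seed: int
    id: str = ""

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.taxon not in TAXA:
            raise ValueError(f"taxon must be one of {TAXA}, got {self.taxon!r}")
        if self.wear not in (1, 2, 3):
            raise ValueError(f"wear must be 1, 2 or 3, got {self.wear!r}")
        if self.collection_year > datetime.date.today().year:
            raise ValueError(f"collection_year {self.collection_year} is in the future")


@dataclass(frozen=True)
class EffectConfig:
    """Magnitudes of the injected covariate effects.

    ``reference_year`` anchors specimen age for fading; when ``None`` (the
    default) :func:`generate_dataset` substitutes the maximum collection year
    in the dataset, and :func:`generate_specimen` applies no fading.
    """

    sex_luminance_offset: float = -0.10
    sex_contrast_scale: float = 0.8
    taxon_contrast_scale: float = 0.85
    wear_loss_fraction: tuple[float, float, float] = (0.02, 0.10, 0.30)
    fading_rate: float = 0.002
    noise_sd: float = 0.01
    reference_year: int | None = None

    def __post_init__(self) -> None:
        if self.sex_contrast_scale <= 0 or self.taxon_contrast_scale <= 0:
            raise ValueError("contrast multipliers must be > 0")
        w = self.wear_loss_fraction
        if len(w) != 3 or any(not 0 <= x <= 1 for x in w) or not (w[0] <= w[1] <= w[2]):
            raise ValueError("wear_loss_fraction must be 3 values in [0,1], non-decreasing")
        if self.noise_sd < 0 or self.fading_rate < 0:
            raise ValueError("noise_sd and fading_rate must be >= 0")

    @classmethod
    def null(cls, noise_sd: float = 0.01) -> "EffectConfig":
        """Config with every covariate effect switched off (noise retained)."""
        return cls(
            sex_luminance_offset=0.0,
            sex_contrast_scale=1.0,
            taxon_contrast_scale=1.0,
            wear_loss_fraction=(0.0, 0.0, 0.0),
            fading_rate=0.0,
            noise_sd=noise_sd,
        )


@dataclass
class ConeCatchImage:
    """3-channel cone-catch stack (q_L, q_M, q_S) with mask and scale."""

    q: np.ndarray  # (3, H, W), values in (0, 1]
    mask: np.ndarray  # (H, W) bool
    px_per_cm: float

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.q.ndim != 3 or self.q.shape[0] != 3:
            raise ValueError("q must have shape (3, H, W)")
        if self.q.shape[1:] != self.mask.shape:
            raise ValueError("mask shape must match image shape")
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")


def _half_ellipse_mask(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Wing silhouette: horizontally elongated ellipse truncated below a chord,
    tapering to an apex at the right.  Mildly jittered per specimen."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    a = 0.46 * w * (1 + rng.uniform(-0.04, 0.04))  # semi-major (px)
    b = 0.40 * h * (1 + rng.uniform(-0.04, 0.04))  # semi-minor (px)
    cx, cy = 0.5 * w, 0.52 * h
    ellipse = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    # chord cut: drop the lowest part of the ellipse -> "half-ellipse with apex"
    chord = yy <= cy + 0.72 * b
    return ellipse & chord


def _band_map(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-pixel base cone catches from the three transverse pattern regions."""
    h, w = mask.shape
    cols = np.where(mask.any(axis=0))[0]
    x0, x1 = cols.min(), cols.max()
    span = max(x1 - x0, 1)
    t = (np.arange(w) - x0) / span  # 0 at wing base, 1 at apex
    b1 = 0.40 + rng.uniform(-0.03, 0.03)  # basal/band boundary
    b2 = 0.62 + rng.uniform(-0.03, 0.03)  # band/terminal boundary
    region = np.digitize(t, [b1, b2])  # 0 basal, 1 band, 2 terminal
    palette = np.stack([_BASAL, _BAND, _TERMINAL])  # (3 regions, 3 channels)
    jitter = 1.0 + rng.uniform(-0.05, 0.05, size=3)  # per-specimen region jitter
    v = palette[region].T * jitter[None, region]  # (3, W) broadcast over rows
    return np.broadcast_to(v[:, None, :], (3, h, w)).copy()


def generate_specimen(
    spec: WingSpec,
    cfg: EffectConfig | None = None,
    size_px: tuple[int, int] = (120, 180),
    px_per_cm: float = 64.0,
) -> ConeCatchImage:
    """Render one synthetic cone-catch wing image for ``spec`` under ``cfg``.

    ``size_px`` is (height, width); the wing fills most of the frame, so the
    physical wing size is set jointly by ``size_px`` and ``px_per_cm``.
    """
    cfg = cfg or EffectConfig()
    h, w = size_px
    if h <= 0 or w <= 0:
        raise ValueError("image size must be positive")

    rng = np.random.default_rng(spec.seed)
    mask = _half_ellipse_mask((h, w), rng)
    q = _band_map(mask, rng)

    # pixel noise drawn before any covariate-dependent branch so that the
    # draw sequence is identical across specimens sharing a seed
    noise = rng.normal(0.0, 1.0, size=q.shape) * cfg.noise_sd

    # contrast effects: relax pattern toward the in-mask channel means
    scale = 1.0
    if spec.sex == "male":
        scale *= cfg.sex_contrast_scale
    if spec.taxon == "fennokarelica":
        scale *= cfg.taxon_contrast_scale
    chan_mean = q[:, mask].mean(axis=1)
    q = chan_mean[:, None, None] + scale * (q - chan_mean[:, None, None])

    if spec.sex == "male":
        q = q + cfg.sex_luminance_offset

    # fading: relax toward the overall wing mean, desaturating and flattening
    if cfg.reference_year is not None:
        age = cfg.reference_year - spec.collection_year
        g = float(np.clip(cfg.fading_rate * max(age, 0), 0.0, 1.0))
        overall = q[:, mask].mean()
        q = q + g * (overall - q)

    q = q + noise

    # wear: scale loss thins the scale cover, exposing pale membrane.  Each
    # pixel loses on average the configured fraction of its cover (loss
    # modulated by a heavily smoothed stochastic field), so the banded
    # pattern blends toward pale: pattern energy erodes monotonically with
    # wear at every spatial scale instead of gaining speckle contrast.
    frac = cfg.wear_loss_fraction[spec.wear - 1]
    if frac > 0:
        field = gaussian_filter(rng.normal(size=mask.shape), sigma=1.2 * px_per_cm)
        sd = field.std()
        mod = 1.0 + 0.25 * (field - field.mean()) / sd if sd > 0 else np.ones_like(field)
        alpha = np.clip(frac * mod, 0.0, 1.0)
        q = q * (1.0 - alpha) + alpha * _SPECKLE

    q[:, ~mask] = _BACKGROUND
    q = np.clip(q, CATCH_FLOOR, 1.0)
    return ConeCatchImage(q=q, mask=mask, px_per_cm=px_per_cm)


# ---------------------------------------------------------------------------
# dataset-level generation


def default_design(n: int, seed: int = 0) -> pd.DataFrame:
    """Covariate table mirroring the reference study's group sizes.

    At n=72 the margins are exactly 40 male / 32 female, 29 + 41 annotated to
    the two taxa plus 2 unannotated, and wear levels 28 / 37 / 7; other n
    scale those proportions.  Sex, taxon and wear are assigned independently
    (shuffled), geography comes from a pool of collection groups.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)

    def margins(counts72: list[int]) -> list[int]:
        raw = [c * n / 72 for c in counts72]
        out = [int(np.floor(r)) for r in raw]
        rem = n - sum(out)
        order = np.argsort([o - r for o, r in zip(out, raw)])
        for i in range(rem):
            out[order[i]] += 1
        return out

    n_male, n_female = margins([40, 32])
    n_bad, n_fen, n_none = margins([29, 41, 2])
    n_w1, n_w2, n_w3 = margins([28, 37, 7])

    sex = np.array(["male"] * n_male + ["female"] * n_female)
    taxon = np.array(["badiata"] * n_bad + ["fennokarelica"] * n_fen + ["none"] * n_none)
    wear = np.array([1] * n_w1 + [2] * n_w2 + [3] * n_w3)
    rng.shuffle(sex)
    rng.shuffle(taxon)
    rng.shuffle(wear)

    # 12 collection groups = location x campaign year, jittered coordinates
    locs = [(60.2 + 0.35 * i, 21.5 + 1.05 * i) for i in range(6)]
    years = [1915, 1944, 1968, 1990, 2008, 2021]
    group_pool = [(f"loc{i}_{y}", locs[i % 6], y) for i, y in zip(range(12), years * 2)]
    gidx = rng.integers(0, len(group_pool), size=n)

    seeds = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    rows = []
    for i in range(n):
        gname, (glat, glon), gyear = group_pool[gidx[i]]
        rows.append(
            {
                "id": f"spec{i:03d}",
                "sex": sex[i],
                "taxon": taxon[i],
                "wear": int(wear[i]),
                "collection_year": int(gyear),
                "latitude": float(glat + rng.normal(0, 0.1)),
                "longitude": float(glon + rng.normal(0, 0.3)),
                "collection_group": gname,
                "seed": int(seeds[i]),
            }
        )
    return pd.DataFrame(rows)


def generate_dataset(
    n: int,
    cfg: EffectConfig | None = None,
    design: pd.DataFrame | None = None,
    seed: int = 0,
    size_px: tuple[int, int] = (120, 180),
    px_per_cm: float = 64.0,
) -> tuple[list[ConeCatchImage], pd.DataFrame]:
    """Generate ``n`` specimens plus their metadata table.

    ``design`` may supply an explicit covariate table (one row per specimen,
    :class:`WingSpec` fields as columns); by default :func:`default_design`
    is used.  The fading reference year defaults to the maximum collection
    year in the design.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    cfg = cfg or EffectConfig()
    if design is None:
        design = default_design(n, seed=seed)
    if len(design) != n:
        raise ValueError(f"design has {len(design)} rows, expected n={n}")
    if cfg.reference_year is None:
        cfg = replace(cfg, reference_year=int(design["collection_year"].max()))

    images = []
    meta = design.copy().reset_index(drop=True)
    if "id" not in meta.columns:
        meta.insert(0, "id", [f"spec{i:03d}" for i in range(n)])
    for _, row in meta.iterrows():
        ws = WingSpec(
            sex=row["sex"],
            taxon=row["taxon"],
            wear=int(row["wear"]),
            collection_year=int(row["collection_year"]),
            latitude=float(row["latitude"]),
            longitude=float(row["longitude"]),
            collection_group=str(row["collection_group"]),
            seed=int(row["seed"]),
            id=str(row["id"]),
        )
        images.append(generate_specimen(ws, cfg, size_px=size_px, px_per_cm=px_per_cm))
    meta["px_per_cm"] = [img.px_per_cm for img in images]
    meta["specimen_age"] = cfg.reference_year - meta["collection_year"]
    return images, meta
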