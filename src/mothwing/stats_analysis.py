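"""PCA over standardized features and linear mixed models of PC scores.

The PCA is a correlation-matrix PCA (features z-scored first) computed by
singular-value decomposition, with a deterministic sign rule: any component
whose loadings sum to a negative value is flipped (loadings and scores
multiplied by -1) and flagged.

The mixed models regress a PC on sex, taxon, wear, specimen age, latitude
and longitude (numeric covariates standardized) with a random intercept per
collection group.  Inference uses Wald t statistics on residual degrees of
freedom; the method is recorded in the output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

__all__ = ["PCAResult", "standardize", "run_pca", "fit_lmm", "fit_lmm_all", "luminance_dominated_pc"]

#: fixed-effect display names, keyed by patsy term
EFFECT_LABELS = {
    "C(sex, Treatment('female'))[T.male]": "sex=male",
    "C(taxon, Treatment('badiata'))[T.fennokarelica]": "taxon=fennokarelica",
    "wear_z": "wear",
    "age_z": "age",
    "lat_z": "latitude",
    "lon_z": "longitude",
    "Intercept": "intercept",
}

FORMULA = (
    "pc ~ C(sex, Treatment('female')) + C(taxon, Treatment('badiata'))"
    " + wear_z + age_z + lat_z + lon_z"
)


def standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score every column to mean 0, sd 1 (ddof=1).

    Constant columns cannot be scaled; they are dropped with a logged
    warning and reported via the returned frame's ``attrs['dropped']``.
    """
    means = table.mean(axis=0)
    sds = table.std(axis=0, ddof=1)
    constant = sds.index[(sds == 0) | sds.isna()].tolist()
    if constant:
        logger.warning("dropping %d constant column(s): %s", len(constant), constant)
    kept = table.drop(columns=constant)
    out = (kept - means[kept.columns]) / sds[kept.columns]
    out.attrs["dropped"] = constant
    return out


@dataclass
class PCAResult:
    scores: pd.DataFrame  # specimens x components, columns PC1..PCk
    loadings: pd.DataFrame  # metrics x components
    var_explained: np.ndarray  # fraction per returned component
    flipped: list[bool]
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def run_pca(features: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """Correlation-matrix PCA via SVD with the negative-loading flip rule."""
    if features.shape[0] < 2 or features.shape[1] < 2:
        raise ValueError("need at least 2 specimens and 2 metrics")
    z = standardize(features)
    n, p = z.shape
    rank = min(n - 1, p)
    if n_components is None:
        n_components = rank
    if n_components > rank:
        raise ValueError(f"requested {n_components} components but rank is at most {rank}")
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    lam = s**2
    var_explained = (lam / lam.sum())[:n_components]
    loadings = vt[:n_components].T  # p x k
    scores = z.to_numpy() @ loadings  # equals u * s
    flipped = []
    for k in range(n_components):
        flip = loadings[:, k].sum() < 0
        flipped.append(bool(flip))
        if flip:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=features.index, columns=cols),
        loadings=pd.DataFrame(loadings, index=z.columns, columns=cols),
        var_explained=var_explained,
        flipped=flipped,
        dropped_columns=list(z.attrs.get("dropped", [])),
    )


def luminance_dominated_pc(pca: PCAResult, top: int = 3) -> int:
    """0-based index (among the first ``top`` components) of the PC carrying
    the largest absolute loading mass on luminance-channel metrics."""
    lum_rows = [c for c in pca.loadings.index if c.startswith("Lum_")]
    if not lum_rows:
        raise ValueError("no luminance-channel metrics in the loading table")
    k = min(top, pca.n_components)
    mass = pca.loadings.loc[lum_rows].iloc[:, :k].abs().sum(axis=0)
    # weight by score spread: |loading| x sd(score) is the score-feature
    # correlation scale, so low-variance trailing PCs cannot dominate
    mass = mass * pca.scores.iloc[:, :k].std(ddof=1).to_numpy()
    return int(np.argmax(mass.to_numpy()))


def _prepare_lmm_frame(scores: pd.DataFrame, meta: pd.DataFrame, component: int) -> pd.DataFrame:
    df = meta.reset_index(drop=True).copy()
    df["pc"] = scores.reset_index(drop=True).iloc[:, component]
    df = df[df["taxon"] != "none"].copy()  # unannotated specimens excluded
    if df["taxon"].nunique() < 2 or df["sex"].nunique() < 2:
        raise ValueError("need both sexes and both taxa after exclusions")
    if "specimen_age" not in df.columns:
        df["specimen_age"] = df["collection_year"].max() - df["collection_year"]

    def z(col: pd.Series) -> pd.Series:
        sd = col.std(ddof=1)
        return (col - col.mean()) / sd if sd > 0 else col * 0.0

    df["wear_z"] = z(df["wear"].astype(float))
    df["age_z"] = z(df["specimen_age"].astype(float))
    df["lat_z"] = z(df["latitude"].astype(float))
    df["lon_z"] = z(df["longitude"].astype(float))
    return df


def fit_lmm(scores: pd.DataFrame, meta: pd.DataFrame, component: int = 0) -> pd.DataFrame:
    """Mixed model for one PC: fixed sex/taxon/wear/age/lat/lon effects and a
    random intercept per collection group.

    Returns one row per fixed effect with estimate, SE, df, t, p plus the
    model bookkeeping (component, df method, random-effect variance).  A
    singular fit (group variance at zero) is reported, not raised; if the
    mixed fit fails entirely an OLS fallback is used and flagged.
    """
    df = _prepare_lmm_frame(scores, meta, component)
    n = len(df)
    method = "mixedlm"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(FORMULA, df, groups=df["collection_group"])
            # powell is fast and, unlike lbfgs, does not stall at spurious
            # boundary points on near-singular likelihood surfaces here
            try:
                fit = model.fit(reml=True, method="powell")
            except (np.linalg.LinAlgError, ValueError):
                fit = model.fit(reml=True)
            fe = fit.fe_params
            se = fit.bse_fe
            re_var = float(fit.cov_re.iloc[0, 0])
            k_fixed = len(fe)
        except (np.linalg.LinAlgError, ValueError):
            method = "ols_fallback"
            fit = smf.ols(FORMULA, df).fit()
            fe = fit.params
            se = fit.bse
            re_var = np.nan
            k_fixed = len(fe)
    ddf = n - k_fixed  # residual degrees of freedom
    rows = []
    for term in fe.index:
        est = float(fe[term])
        s = float(se[term])
        t = est / s if s > 0 else np.nan
        p = 2 * sps.t.sf(abs(t), ddf) if np.isfinite(t) else np.nan
        rows.append(
            {
                "component": f"PC{component + 1}",
                "effect": EFFECT_LABELS.get(term, term),
                "df": ddf,
                "estimate": est,
                "se": s,
                "t": t,
                "p": p,
                "df_method": "residual",
                "fit_method": method,
                "group_var": re_var,
            }
        )
    out = pd.DataFrame(rows)
    return out[out["effect"] != "intercept"].reset_index(drop=True)


def fit_lmm_all(
    pca: PCAResult, meta: pd.DataFrame, components: tuple[int, ...] = (0, 1, 2)
) -> pd.DataFrame:
    """Mixed-model tables for several components, concatenated."""
    parts = [fit_lmm(pca.scores, meta, c) for c in components if c < pca.n_components]
    return pd.concat(parts, ignore_index=True)
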