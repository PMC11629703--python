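"""ROI-level inferential statistics for lesion-connectivity effects.

For each ROI, a general linear model relates its LNM score to a cognitive
domain score, adjusted for age, sex and education; input variables are
z-scored beforehand so the ROI coefficient is a standardized beta.
Significance is assessed by permutation (Freedman-Lane: residuals of the
covariates-only model are permuted, re-residualized and refit), two-sided,
with family-wise error control via the single-step max-|t| distribution
across the ROIs of the model family. Cortical effects are aggregated into
the seven canonical resting-state networks and tested against a spin
permutation null — random rotations of the parcel centroids on the sphere
with nearest-neighbour reassignment — which preserves the spatial
autocorrelation of the cortical map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging import Parcellation


def _z(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot z-score a constant variable")
    return (x - x.mean()) / sd


def _design(covariates: pd.DataFrame) -> np.ndarray:
    """Nuisance design [1, z(age), sex, z(education)]."""
    n = len(covariates)
    return np.column_stack(
        [
            np.ones(n),
            _z(covariates["age"].to_numpy()),
            covariates["sex"].to_numpy(float),
            _z(covariates["education"].to_numpy()),
        ]
    )


@dataclass
class GLMResult:
    """Per-ROI standardized betas with permutation p-values."""

    table: pd.DataFrame  # index roi_id: beta, t, p_uncorrected, p_fwe
    metadata: dict = field(default_factory=dict)


@dataclass
class NetworkSummary:
    """Mean cortical beta per network with spin-test p-values."""

    table: pd.DataFrame  # index network: mean_beta, p_spin, n_rois


def standardized_glm(
    y: np.ndarray, x_roi: np.ndarray, covariates: pd.DataFrame
) -> tuple[float, float]:
    """Standardized beta and t of one ROI regressor, OLS with age/sex/
    education as covariates. y, x, age and education are z-scored; binary
    sex enters unscaled."""
    y = np.asarray(y, float)
    x = np.asarray(x_roi, float)
    n = y.size
    if n <= 5:
        raise ValueError("need n > 5")
    if np.std(x) == 0:
        raise ValueError("constant ROI regressor")
    Z = _design(covariates)
    X = np.column_stack([_z(x), Z])
    beta, t = _ols_tstat(X, _z(y))
    return float(beta), float(t)


def _ols_tstat(X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n, p = X.shape
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise ValueError("rank-deficient design")
    resid = y - X @ coef
    sigma2 = float(resid @ resid) / (n - p)
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * XtX_inv[0, 0])
    return coef[0], coef[0] / se


def permutation_glm_fwe(
    y_domain: np.ndarray,
    X_lnm: pd.DataFrame,
    covariates: pd.DataFrame,
    n_perm: int = 5000,
    seed: int = 0,
    metadata: dict | None = None,
) -> GLMResult:
    """Permutation GLM over all ROIs with max-|t| FWE correction.

    The observed t per ROI comes from the full model via Frisch-Waugh
    residualization (exactly equal to the OLS t). The null permutes the
    reduced-model residuals of y (Freedman-Lane), re-residualizes them
    against the covariates and recomputes every ROI's t; p-values carry the
    +1 correction so they are valid and never zero.
    """
    import warnings

    if n_perm < 100:
        warnings.warn("n_perm < 100 gives very coarse p-values", stacklevel=2)
    rng = np.random.default_rng(seed)
    y = _z(np.asarray(y_domain, float))
    n = y.size
    Z = _design(covariates)
    k = Z.shape[1] + 1  # full-model regressor count (ROI + nuisance)
    df = n - k
    H = Z @ np.linalg.solve(Z.T @ Z, Z.T)
    resid_y = y - H @ y

    roi_ids = list(X_lnm.columns)
    Xv = X_lnm.to_numpy(float)
    sds = Xv.std(axis=0, ddof=0)
    valid = sds > 0
    Xz = np.zeros_like(Xv)
    Xz[:, valid] = (Xv[:, valid] - Xv[:, valid].mean(axis=0)) / sds[valid]
    EX = Xz - H @ Xz  # residualized ROI regressors
    exx = (EX**2).sum(axis=0)
    valid &= exx > 1e-12

    def _tstats(ey: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # ey: (n,) residualized outcome(s); returns beta, t per ROI
        num = EX.T @ ey
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = np.where(valid, num / exx, np.nan)
            rss = float(ey @ ey) - np.where(valid, num**2 / exx, 0.0)
            sigma2 = rss / df
            t = np.where(valid, beta / np.sqrt(sigma2 / exx), np.nan)
        return beta, t

    beta_obs, t_obs = _tstats(resid_y)

    # Freedman-Lane null, vectorized over permutations
    exceed = np.zeros(len(roi_ids))
    max_null = np.empty(n_perm)
    abs_t = np.abs(t_obs)
    batch = max(1, min(n_perm, int(5e7 / (n * max(len(roi_ids), 1)))))
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        perms = np.stack([rng.permutation(n) for _ in range(b)])
        E = resid_y[perms]  # (b, n)
        E = E - E @ H.T  # re-residualize against the nuisance space
        num = E @ EX  # (b, R)
        ess = (E**2).sum(axis=1)[:, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            beta_null = num / exx
            rss = ess - np.where(valid, num**2 / exx, 0.0)
            t_null = beta_null / np.sqrt(rss / df / exx)
        t_null = np.where(valid, t_null, np.nan)
        abs_null = np.abs(t_null)
        exceed += np.nansum(abs_null >= abs_t, axis=0)
        max_null[done : done + b] = np.nanmax(
            np.where(valid, abs_null, -np.inf), axis=1
        )
        done += b

    p_unc = np.where(valid, (1.0 + exceed) / (1.0 + n_perm), np.nan)
    p_fwe = np.where(
        valid,
        (1.0 + (max_null[:, None] >= abs_t[None, :]).sum(axis=0)) / (1.0 + n_perm),
        np.nan,
    )
    table = pd.DataFrame(
        {
            "beta": beta_obs,
            "t": t_obs,
            "p_uncorrected": p_unc,
            "p_fwe": np.maximum(p_fwe, p_unc),
        },
        index=pd.Index(roi_ids, name="roi_id"),
    )
    meta = dict(n=n, n_permutations=n_perm, seed=seed, covariates=["age", "sex", "education"])
    meta.update(metadata or {})
    return GLMResult(table, meta)


# ---------------------------------------------------------------------------
# network aggregation & spin test


def network_average_betas(glm: GLMResult, parc: Parcellation) -> pd.DataFrame:
    """Unweighted mean beta over cortical ROIs per network."""
    tab = parc.roi_table
    cort = tab[tab["class"] == "cortical"]
    rows = []
    for net in parc.networks:
        ids = cort.loc[cort["network"] == net, "roi_id"].astype(int)
        present = [i for i in ids if i in glm.table.index]
        if not present:
            raise ValueError(f"network {net} has no tested cortical ROIs")
        rows.append(
            dict(network=net, mean_beta=float(glm.table.loc[present, "beta"].mean()),
                 n_rois=len(present))
        )
    return pd.DataFrame(rows).set_index("network")


def _rotation_matrices(n_spins: int, rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(n_spins, random_state=rng).as_matrix()


def spin_permutation_test(
    beta_map: pd.Series,
    parc: Parcellation,
    n_spins: int = 1000,
    seed: int = 0,
) -> NetworkSummary:
    """Spin permutation test of network mean betas.

    Each spin applies one uniform random rotation to the cortical parcel
    centroids; every parcel is then reassigned the beta of its nearest
    rotated neighbour (ties to the lower roi_id), network means are
    recomputed, and a two-sided p compares |null mean| to |observed mean|,
    with the +1 correction. The toy cortex is a single closed shell, so one
    rotation covers both hemispheres.
    """
    cents = parc.cortical_centroids()
    missing = [i for i in beta_map.index if i not in cents.index]
    if missing or cents.isna().any().any():
        raise ValueError("all cortical ROIs need unit-sphere centroids")
    roi_ids = [i for i in cents.index if i in beta_map.index]
    C = cents.loc[roi_ids].to_numpy(float)
    betas = beta_map.loc[roi_ids].to_numpy(float)
    tab = parc.roi_table.set_index("roi_id")
    networks = parc.networks
    net_members = {
        net: np.array([j for j, rid in enumerate(roi_ids) if tab.loc[rid, "network"] == net])
        for net in networks
    }
    obs = {net: betas[idx].mean() for net, idx in net_members.items()}

    rng = np.random.default_rng(seed)
    rots = _rotation_matrices(n_spins, rng)
    exceed = {net: 0 for net in networks}
    for R in rots:
        rotated = C @ R.T
        # nearest rotated centroid per original parcel; argmax -> lowest index on ties
        sim = C @ rotated.T
        nearest = np.argmax(sim, axis=1)
        spun = betas[nearest]
        for net, idx in net_members.items():
            if abs(spun[idx].mean()) >= abs(obs[net]) - 1e-15:
                exceed[net] += 1
    rows = [
        dict(network=net, mean_beta=float(obs[net]),
             p_spin=(1.0 + exceed[net]) / (1.0 + n_spins),
             n_rois=len(net_members[net]))
        for net in networks
    ]
    return NetworkSummary(pd.DataFrame(rows).set_index("network"))


def tract_level_report(glm: GLMResult, parc: Parcellation, k: int = 10) -> pd.DataFrame:
    """Top-k tracts by |beta| (descending; ties by roi_id), with an FWE
    significance flag."""
    tract_ids = [i for i in parc.tract_ids if i in glm.table.index]
    sub = glm.table.loc[tract_ids].reset_index()
    sub["abs_beta"] = sub["beta"].abs()
    sub = sub.sort_values(["abs_beta", "roi_id"], ascending=[False, True], kind="stable")
    sub = sub.head(k).drop(columns="abs_beta").set_index("roi_id")
    sub["significant_fwe"] = sub["p_fwe"] < 0.05
    names = parc.roi_table.set_index("roi_id")["name"]
    sub.insert(0, "name", names.loc[sub.index])
    return sub
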