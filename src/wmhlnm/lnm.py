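"""Normative seed-connectivity maps and lesion network mapping scores.

Functional LNM (fLNM): for each ROI, the mean ROI time series is
correlated with every brain voxel's series per reference subject; the
correlations are Fisher z-transformed (atanh, after clipping |r| at
1 - 1e-7) and averaged across subjects into a seed map. A lesion's fLNM
score for that ROI is the mean of the sign-selected seed-map values inside
the lesion mask. Scores are computed on the group-mean z map without
back-transforming to r: z is monotone in r, so the sign selection and
ranking of voxels are identical in either unit.

Structural LNM (sLNM): the seed map holds per-voxel streamline counts to
the ROI; the score is the mean count inside the lesion mask.

Thresholded variants keep only the ceil(f * n) highest-intensity voxels in
the mask (lowest for negative polarity) before averaging, f in
{1.0, 0.5, 0.25}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging import (
    BinaryMask,
    Parcellation,
    Volume3D,
    dilate_mask,
    hemisphere_restrict,
    mask_intersection,
    mask_volume_ml,
)
from .synthetic import FunctionalConnectome

CLIP = 1.0 - 1e-7
THRESHOLD_FRACTIONS = (1.0, 0.5, 0.25)


@dataclass
class SeedMap:
    """Voxelwise connectivity of one ROI to the whole brain."""

    roi_id: int
    modality: str  # "functional" | "structural"
    map: Volume3D

    def __post_init__(self):
        if self.modality not in ("functional", "structural"):
            raise ValueError(f"unknown modality {self.modality}")
        data = np.asarray(self.map.data, dtype=float)
        if not np.isfinite(data).all():
            raise ValueError("seed map contains non-finite values")
        if self.modality == "structural" and (data < 0).any():
            raise ValueError("structural seed map has negative streamline counts")


@dataclass
class LNMScoreMatrix:
    """Patients x ROIs score matrix for one modality/polarity/threshold,
    with per-cell provenance flags."""

    modality: str
    polarity: str
    threshold_fraction: float
    scores: pd.DataFrame  # index: patient id, columns: roi_id
    n_voxels_used: pd.DataFrame
    empty_selection: pd.DataFrame

    @property
    def n_patients(self) -> int:
        return len(self.scores)

    @property
    def n_rois(self) -> int:
        return self.scores.shape[1]


# ---------------------------------------------------------------------------
# seed maps


def functional_seed_map(roi_mask: BinaryMask, connectome: FunctionalConnectome) -> np.ndarray:
    """Group-mean Fisher-z seed map values over brain voxels for one ROI.

    Returns the dense (n_brain_voxels,) vector; use
    :func:`functional_seed_maps` to get full SeedMap volumes for a
    parcellation.
    """
    series = connectome.series  # (S, V, T)
    S, V, T = series.shape
    if T < 3:
        raise ValueError("need at least 3 time points")
    roi_flat = roi_mask.flat_indices()
    member = np.isin(connectome.brain_indices, roi_flat)
    if not member.any():
        raise ValueError("ROI is empty or outside the brain mask")
    zsum = np.zeros(V)
    for s in range(S):
        sub = series[s].astype(np.float64)
        roi_ts = sub[member].mean(axis=0)
        zsum += _fisher_z_correlation(sub, roi_ts)
    return zsum / S


def _fisher_z_correlation(voxel_series: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Fisher z of Pearson r between ``ref`` and each row of
    ``voxel_series``; zero-variance rows get z = 0."""
    T = voxel_series.shape[1]
    vc = voxel_series - voxel_series.mean(axis=1, keepdims=True)
    rc = ref - ref.mean()
    vnorm = np.sqrt((vc**2).sum(axis=1))
    rnorm = np.sqrt((rc**2).sum())
    denom = vnorm * rnorm
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vc @ rc) / denom
    r = np.where(denom > 0, r, 0.0)
    r = np.clip(r, -CLIP, CLIP)
    return np.arctanh(r)


def functional_seed_maps(
    parc: Parcellation,
    connectome: FunctionalConnectome,
    roi_ids: Sequence[int] | None = None,
) -> dict[int, SeedMap]:
    """Batch fLNM seed maps for all (or selected) ROIs of a parcellation.

    Computes all ROI-mean series per subject in one pass, which is
    substantially faster than per-ROI calls.
    """
    roi_ids = list(roi_ids) if roi_ids is not None else parc.roi_ids()
    series = connectome.series
    S, V, T = series.shape
    if T < 3:
        raise ValueError("need at least 3 time points")
    membership = []
    for rid in roi_ids:
        flat = parc.roi_mask(rid).flat_indices()
        member = np.isin(connectome.brain_indices, flat)
        if not member.any():
            raise ValueError(f"ROI {rid} empty within the brain mask")
        membership.append(member)
    zsum = np.zeros((len(roi_ids), V))
    for s in range(S):
        sub = series[s].astype(np.float64)
        vc = sub - sub.mean(axis=1, keepdims=True)
        vnorm = np.sqrt((vc**2).sum(axis=1))
        for j, member in enumerate(membership):
            ref = sub[member].mean(axis=0)
            rc = ref - ref.mean()
            rnorm = math.sqrt(float((rc**2).sum()))
            denom = vnorm * rnorm
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (vc @ rc) / denom
            r = np.where(denom > 0, r, 0.0)
            zsum[j] += np.arctanh(np.clip(r, -CLIP, CLIP))
    zmean = zsum / S
    out = {}
    template = connectome.template
    for j, rid in enumerate(roi_ids):
        vol = np.zeros(template.shape, dtype=float).ravel()
        vol[connectome.brain_indices] = zmean[j]
        out[rid] = SeedMap(rid, "functional", template.with_data(vol.reshape(template.shape)))
    return out


def structural_seed_map(roi_id: int, structural: Mapping[int, Volume3D], parc: Parcellation | None = None) -> SeedMap:
    """Validated passthrough of a per-ROI streamline-count volume."""
    if roi_id not in structural:
        raise KeyError(f"no structural map for ROI {roi_id}")
    vol = structural[roi_id]
    if parc is not None:
        parc.label_volume.check_grid(vol)
    return SeedMap(roi_id, "structural", vol)


def structural_seed_maps(parc: Parcellation, structural: Mapping[int, Volume3D]) -> dict[int, SeedMap]:
    return {rid: structural_seed_map(rid, structural, parc) for rid in parc.roi_ids()}


# ---------------------------------------------------------------------------
# scoring


def _select_threshold(values: np.ndarray, idx: np.ndarray, f: float, polarity: str) -> np.ndarray:
    """Keep the ceil(f*n) highest-intensity values (lowest for negative
    polarity); ties broken by stable sort on (value, voxel index)."""
    n = values.size
    k = int(math.ceil(f * n))
    if k >= n:
        return values
    if polarity == "negative":
        order = np.lexsort((idx, values))  # ascending value, then index
    else:
        order = np.lexsort((idx, -values))  # descending value, then index
    return values[order[:k]]


def lnm_score(
    seed: SeedMap,
    mask: BinaryMask,
    polarity: str = "positive",
    threshold_fraction: float = 1.0,
) -> tuple[float, int, bool]:
    """Score one lesion against one seed map.

    Returns ``(score, n_voxels_used, empty_selection)``. An empty lesion
    mask yields ``(nan, 0, True)`` — missing, distinct from an informative
    zero. Functional scores of the requested sign that do not exist in the
    mask yield 0 with the flag set ("no connectivity of that sign").
    """
    if polarity not in ("positive", "negative"):
        raise ValueError("polarity must be 'positive' or 'negative'")
    if seed.modality == "structural" and polarity != "positive":
        raise ValueError("structural scores only support positive polarity")
    if threshold_fraction not in THRESHOLD_FRACTIONS:
        raise ValueError(f"threshold_fraction must be one of {THRESHOLD_FRACTIONS}")
    seed.map.check_grid(mask)
    idx = mask.flat_indices()
    if idx.size == 0:
        return (float("nan"), 0, True)
    values = np.asarray(seed.map.data, dtype=float).ravel()[idx]
    values = _select_threshold(values, idx, threshold_fraction, polarity)
    if seed.modality == "structural":
        return (float(values.mean()), int(values.size), False)
    if polarity == "positive":
        sel = values[values > 0]
    else:
        sel = values[values < 0]
    if sel.size == 0:
        return (0.0, 0, True)
    return (float(sel.mean()), int(sel.size), False)


def _score_block(
    value_rows: np.ndarray,  # (R, m) seed values at mask voxels
    idx: np.ndarray,  # (m,) voxel indices
    modality: str,
    polarity: str,
    f: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised lnm_score over all ROIs for one patient."""
    R, m = value_rows.shape
    k = int(math.ceil(f * m))
    if k < m:
        if polarity == "negative":
            order = np.lexsort((np.broadcast_to(idx, value_rows.shape), value_rows), axis=1)
        else:
            order = np.lexsort((np.broadcast_to(idx, value_rows.shape), -value_rows), axis=1)
        sel = np.take_along_axis(value_rows, order[:, :k], axis=1)
    else:
        sel = value_rows
    if modality == "structural":
        return sel.mean(axis=1), np.full(R, sel.shape[1]), np.zeros(R, dtype=bool)
    if polarity == "positive":
        keep = sel > 0
    else:
        keep = sel < 0
    counts = keep.sum(axis=1)
    sums = np.where(keep, sel, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return scores, counts, counts == 0


def build_lnm_matrix(
    masks: Sequence[BinaryMask] | Mapping[int, BinaryMask],
    seed_maps: Mapping[int, SeedMap],
    polarity: str = "positive",
    threshold_fraction: float = 1.0,
    hemisphere: str | None = None,
    parc: Parcellation | None = None,
    penumbra_mm: float | None = None,
    penumbra_only: bool = False,
) -> LNMScoreMatrix:
    """Full patients x ROIs LNM score matrix.

    ``hemisphere`` restricts lesions to one side and keeps only same-side
    ROIs (bilateral/contralateral ROIs are dropped; requires ``parc``).
    ``penumbra_mm`` dilates each lesion by that radius before scoring
    (optionally excluding the original lesion voxels), modelling the
    normal-appearing white matter adjacent to visible lesions.
    """
    if isinstance(masks, Mapping):
        patient_ids = sorted(masks)
        mask_list = [masks[p] for p in patient_ids]
    else:
        patient_ids = list(range(len(masks)))
        mask_list = list(masks)
    roi_ids = sorted(seed_maps)
    modality = seed_maps[roi_ids[0]].modality
    if hemisphere is not None:
        if parc is None:
            raise ValueError("hemisphere restriction requires the parcellation")
        keep = [
            rid for rid in roi_ids if parc.roi_row(rid)["hemisphere"] == hemisphere
        ]
        roi_ids = keep
        mask_list = [hemisphere_restrict(m, hemisphere) for m in mask_list]
    if penumbra_mm is not None:
        new = []
        for m in mask_list:
            if m.voxel_count == 0:
                new.append(m)
                continue
            dil = dilate_mask(m, penumbra_mm)
            if penumbra_only:
                dil = BinaryMask(dil.data * (1 - m.data), m.voxel_size, m.origin)
            new.append(dil)
        mask_list = new

    template = seed_maps[roi_ids[0]].map
    stack = np.stack(
        [np.asarray(seed_maps[rid].map.data, dtype=float).ravel() for rid in roi_ids]
    )
    R = len(roi_ids)
    scores = np.full((len(mask_list), R), np.nan)
    nvox = np.zeros((len(mask_list), R), dtype=int)
    empty = np.zeros((len(mask_list), R), dtype=bool)
    for i, mask in enumerate(mask_list):
        template.check_grid(mask)
        idx = mask.flat_indices()
        if idx.size == 0:
            empty[i, :] = True
            continue
        s, c, e = _score_block(stack[:, idx], idx, modality, polarity, threshold_fraction)
        scores[i], nvox[i], empty[i] = s, c, e
    mk = lambda arr: pd.DataFrame(arr, index=patient_ids, columns=roi_ids)
    return LNMScoreMatrix(
        modality="fLNM" if modality == "functional" else "sLNM",
        polarity=polarity,
        threshold_fraction=threshold_fraction,
        scores=mk(scores),
        n_voxels_used=mk(nvox),
        empty_selection=mk(empty),
    )


# ---------------------------------------------------------------------------
# volumetric features


@dataclass
class VolumetricFeatures:
    """Total and per-tract lesion volumes (ml)."""

    total_wmh_ml: pd.Series
    tract_wmh_ml: pd.DataFrame  # patients x tract roi_id

    def to_frame(self) -> pd.DataFrame:
        out = self.tract_wmh_ml.copy()
        out.insert(0, "total_wmh_ml", self.total_wmh_ml)
        return out


def volumetric_features(
    masks: Sequence[BinaryMask],
    tract_masks: Mapping[int, BinaryMask],
) -> VolumetricFeatures:
    """Total lesion volume plus lesion volume inside each (possibly
    overlapping) tract."""
    tract_ids = sorted(tract_masks)
    totals = []
    per_tract = np.zeros((len(masks), len(tract_ids)))
    for i, lesion in enumerate(masks):
        totals.append(mask_volume_ml(lesion))
        for j, tid in enumerate(tract_ids):
            per_tract[i, j] = mask_volume_ml(mask_intersection(lesion, tract_masks[tid]))
    idx = pd.RangeIndex(len(masks))
    return VolumetricFeatures(
        pd.Series(totals, index=idx, name="total_wmh_ml"),
        pd.DataFrame(per_tract, index=idx, columns=tract_ids),
    )


# ---------------------------------------------------------------------------
# structure-function coupling


@dataclass
class CouplingSummary:
    """Pearson correlations of fLNM vs sLNM scores, per subject (across
    ROIs) and per ROI (across subjects)."""

    per_subject_r: pd.Series
    per_roi_r: pd.Series
    mean_across_rois: float
    sd_across_rois: float
    n_across_rois: int
    mean_across_subjects: float
    sd_across_subjects: float
    n_across_subjects: int


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 3 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def structure_function_coupling(f: LNMScoreMatrix, s: LNMScoreMatrix) -> CouplingSummary:
    if f.scores.shape != s.scores.shape:
        raise ValueError("score matrices must have matching dimensions")
    fa, sa = f.scores.to_numpy(float), s.scores.to_numpy(float)
    per_subj = np.array([_safe_corr(fa[i], sa[i]) for i in range(fa.shape[0])])
    per_roi = np.array([_safe_corr(fa[:, j], sa[:, j]) for j in range(fa.shape[1])])
    subj_ok = per_subj[np.isfinite(per_subj)]
    roi_ok = per_roi[np.isfinite(per_roi)]
    return CouplingSummary(
        per_subject_r=pd.Series(per_subj, index=f.scores.index),
        per_roi_r=pd.Series(per_roi, index=f.scores.columns),
        mean_across_rois=float(subj_ok.mean()) if subj_ok.size else float("nan"),
        sd_across_rois=float(subj_ok.std(ddof=1)) if subj_ok.size > 1 else float("nan"),
        n_across_rois=int(subj_ok.size),
        mean_across_subjects=float(roi_ok.mean()) if roi_ok.size else float("nan"),
        sd_across_subjects=float(roi_ok.std(ddof=1)) if roi_ok.size > 1 else float("nan"),
        n_across_subjects=int(roi_ok.size),
    )
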