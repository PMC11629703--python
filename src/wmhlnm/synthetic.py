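"""Fully synthetic desk-scale study: toy brain, normative connectomes,
periventricular lesions, demographics and cognition with known ground truth.

The generator emulates the structure of a memory-clinic lesion-network
study without any external data:

* a spherical-shell "cortex" partitioned into contiguous parcels with
  7-network assignments and unit-sphere centroids, interior subcortical
  blobs, and overlapping curved white matter tracts;
* a normative functional connectome (S reference subjects x T time points
  per voxel) with planted within-network correlation;
* per-ROI structural streamline-count maps concentrated in the tract tubes
  geometrically linked to each ROI;
* right-skewed (log-normal) lesion loads with a periventricular spatial
  prior, restricted to white matter so connectivity scores reflect remote
  network embedding rather than direct cortical damage;
* cognitive domain scores built from demographic effects, a network-specific
  lesion-connectivity effect and Gaussian noise.

One master seed fixes every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .imaging import BinaryMask, Parcellation, Volume3D

YEO7_NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default_mode",
)

COGNITIVE_DOMAINS = (
    "attention_executive",
    "processing_speed",
    "language",
    "verbal_memory",
)


@dataclass
class ToyBrainConfig:
    """Geometry of the synthetic brain.

    Defaults give a 24 mm cube with 40 cortical parcels (the cortical count
    is configurable to emulate coarser/finer atlas resolutions), 4
    subcortical blobs and 8 overlapping tracts.
    """

    grid_dims: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 1.0
    n_cortical_rois: int = 40
    n_subcortical_rois: int = 4
    n_tracts: int = 8
    networks: tuple[str, ...] = YEO7_NETWORKS

    def __post_init__(self):
        self.grid_dims = tuple(int(d) for d in self.grid_dims)
        if min(self.grid_dims) < 8:
            raise ValueError("grid too small")
        for name in ("n_cortical_rois", "n_subcortical_rois", "n_tracts"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class FunctionalConnectome:
    """Normative resting-state data: per subject, per brain voxel, a time
    series of length T. Stored densely over brain voxels only."""

    series: np.ndarray  # (S, n_brain_voxels, T) float32
    brain_indices: np.ndarray  # flat C-order indices into the grid
    template: Volume3D  # zero volume carrying the grid
    voxel_network: np.ndarray  # generative network index per brain voxel

    @property
    def n_subjects(self) -> int:
        return self.series.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[2]


@dataclass
class DomainEffect:
    """Ground-truth generative effect for one cognitive domain.

    ``effect_size`` is the standardized coefficient of the (cohort-
    standardized) mean LNM score over the target network's ROIs — or of
    total lesion volume when ``modality == 'volume'``.
    """

    target_network: str | None = "dorsal_attention"
    modality: str = "fLNM"  # fLNM | sLNM | volume
    effect_size: float = -0.4
    beta_age: float = -0.25
    beta_sex: float = 0.1
    beta_education: float = 0.2
    noise_sd: float = 1.0

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.modality not in ("fLNM", "sLNM", "volume"):
            raise ValueError(f"unknown modality {self.modality}")


@dataclass
class EffectSpec:
    """Per-domain generative effects."""

    domains: dict[str, DomainEffect] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "EffectSpec":
        return cls(
            domains={
                "attention_executive": DomainEffect("dorsal_attention", "fLNM", -0.4),
                "processing_speed": DomainEffect("dorsal_attention", "fLNM", -0.3),
                "language": DomainEffect(None, "fLNM", 0.0),
                "verbal_memory": DomainEffect("ventral_attention", "fLNM", -0.4),
            }
        )


@dataclass
class PatientTable:
    """Per-patient demographics, lesion masks and cognitive domain scores."""

    table: pd.DataFrame  # id, age, sex, education, <domain columns>
    masks: list[BinaryMask] = field(default_factory=list)

    @property
    def n_patients(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, masks=None) -> "PatientTable":
        return cls(pd.read_csv(path, sep="\t"), masks or [])


# ---------------------------------------------------------------------------
# geometry helpers


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    polar = np.arccos(1 - 2 * i / n)
    azim = np.pi * (1 + np.sqrt(5)) * i
    return np.stack(
        [np.sin(polar) * np.cos(azim), np.sin(polar) * np.sin(azim), np.cos(polar)],
        axis=1,
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _grid_template(cfg: ToyBrainConfig) -> Volume3D:
    dims = cfg.grid_dims
    vs = float(cfg.voxel_size_mm)
    origin = tuple(-(d - 1) / 2.0 * vs for d in dims)  # midline at x = 0
    return Volume3D(np.zeros(dims, dtype=np.int16), (vs, vs, vs), origin)


def _radii(template: Volume3D) -> tuple[np.ndarray, float, float]:
    coords = template.world_coordinates()
    r = np.linalg.norm(coords, axis=1)
    extent = min(d * v for d, v in zip(template.shape, template.voxel_size))
    r_out = 0.46 * extent
    r_in = 0.73 * r_out
    return r, r_in, r_out


def brain_radii(parc: Parcellation) -> tuple[float, float]:
    """(inner, outer) cortical shell radii recovered from the label volume."""
    lab = np.asarray(parc.label_volume.data).ravel()
    cort = np.isin(lab, parc.cortical_ids)
    r = np.linalg.norm(parc.label_volume.world_coordinates(), axis=1)
    return float(r[cort].min()), float(r[cort].max())


def white_matter_mask(parc: Parcellation) -> BinaryMask:
    """Interior unlabeled voxels (inside the cortical shell)."""
    r_in, _ = brain_radii(parc)
    lab = np.asarray(parc.label_volume.data)
    r = np.linalg.norm(parc.label_volume.world_coordinates(), axis=1).reshape(lab.shape)
    return BinaryMask((r < r_in) & (lab == 0), parc.label_volume.voxel_size, parc.label_volume.origin)


def brain_mask(parc: Parcellation) -> BinaryMask:
    _, r_out = brain_radii(parc)
    lab = parc.label_volume
    r = np.linalg.norm(lab.world_coordinates(), axis=1).reshape(lab.shape)
    return BinaryMask(r <= r_out + 1e-9, lab.voxel_size, lab.origin)


# ---------------------------------------------------------------------------
# toy brain


def make_toy_brain(cfg: ToyBrainConfig, seed: int) -> Parcellation:
    """Build a deterministic toy parcellation.

    Cortical parcels are nearest-direction (spherical Voronoi) patches on a
    shell, hence contiguous; networks are nearest-direction groups of
    parcel centroids, hence spatially coherent — which the spin permutation
    null relies on. Tracts are curved tubes bent through the periventricular
    interior between pairs of cortical parcels.
    """
    rng = np.random.default_rng(seed)
    template = _grid_template(cfg)
    coords = template.world_coordinates()
    r, r_in, r_out = _radii(template)
    shell = (r >= r_in) & (r <= r_out)
    if shell.sum() < cfg.n_cortical_rois * 3:
        raise ValueError("grid too small for requested cortical ROI count")

    # cortical parcels
    rot = _random_rotation(rng)
    dirs = _fibonacci_directions(cfg.n_cortical_rois) @ rot.T
    u = coords[shell] / r[shell, None]
    assign = np.argmax(u @ dirs.T, axis=1)
    counts = np.bincount(assign, minlength=cfg.n_cortical_rois)
    if (counts == 0).any():
        raise ValueError("grid too small: empty cortical parcel")
    centroids = np.zeros((cfg.n_cortical_rois, 3))
    for k in range(cfg.n_cortical_rois):
        m = u[assign == k].mean(axis=0)
        centroids[k] = m / np.linalg.norm(m)

    # network assignment: nearest of 7 seed directions, no network empty
    n_nets = len(cfg.networks)
    net_dirs = _fibonacci_directions(n_nets) @ _random_rotation(rng).T
    sim = centroids @ net_dirs.T
    roi_net = np.argmax(sim, axis=1)
    for k in range(n_nets):
        if not (roi_net == k).any():
            cand = np.argmax(sim[:, k] - 10.0 * (roi_net == -1))
            roi_net[cand] = k

    labels = np.zeros(template.shape, dtype=np.int16).ravel()
    labels[np.flatnonzero(shell)] = assign + 1

    # subcortical blobs in the interior
    sub_dirs = _fibonacci_directions(cfg.n_subcortical_rois) @ _random_rotation(rng).T
    sub_centers = sub_dirs * 0.35 * r_in
    sub_radius = 0.22 * r_in
    d_sub = np.linalg.norm(coords[:, None, :] - sub_centers[None, :, :], axis=2)
    in_sub = (d_sub <= sub_radius) & (r < r_in)[:, None]
    nearest = np.argmin(d_sub, axis=1)
    for k in range(cfg.n_subcortical_rois):
        sel = in_sub[:, k] & (nearest == k) & (labels == 0)
        if not sel.any():
            raise ValueError("grid too small: empty subcortical ROI")
        labels[sel] = cfg.n_cortical_rois + 1 + k

    # tracts: curved tubes between cortical parcel pairs
    cort_ids = np.arange(1, cfg.n_cortical_rois + 1)
    if 2 * cfg.n_tracts <= cfg.n_cortical_rois:
        ends = rng.permutation(cort_ids)[: 2 * cfg.n_tracts].reshape(-1, 2)
    else:
        ends = np.array(
            [rng.choice(cort_ids, size=2, replace=False) for _ in range(cfg.n_tracts)]
        )
    tract_masks: dict[int, BinaryMask] = {}
    tract_endpoints: dict[int, tuple[int, int]] = {}
    tube_radius = 1.8 * cfg.voxel_size_mm
    interiorish = r <= r_in + cfg.voxel_size_mm
    rows = []
    first_tract_id = cfg.n_cortical_rois + cfg.n_subcortical_rois + 1
    for t in range(cfg.n_tracts):
        a, b = int(ends[t, 0]), int(ends[t, 1])
        p0 = centroids[a - 1] * 0.9 * r_in
        p2 = centroids[b - 1] * 0.9 * r_in
        p1 = 0.25 * (p0 + p2) / 2 + rng.normal(scale=0.8, size=3)
        tt = np.linspace(0.0, 1.0, 64)[:, None]
        curve = (1 - tt) ** 2 * p0 + 2 * tt * (1 - tt) * p1 + tt**2 * p2
        dist, _ = cKDTree(curve).query(coords, k=1)
        tube = (dist <= tube_radius) & interiorish
        if not tube.any():
            raise ValueError("grid too small: empty tract tube")
        rid = first_tract_id + t
        tract_masks[rid] = BinaryMask(
            tube.reshape(template.shape), template.voxel_size, template.origin
        )
        tract_endpoints[rid] = (a, b)
        ax, bx = centroids[a - 1][0], centroids[b - 1][0]
        hemi = "L" if (ax < 0 and bx < 0) else ("R" if (ax > 0 and bx > 0) else "bilateral")
        rows.append((rid, f"tract_{t + 1:02d}", "tract", hemi, None, None, None, None))

    table_rows = []
    for k in range(cfg.n_cortical_rois):
        c = centroids[k]
        table_rows.append(
            (
                k + 1,
                f"cortical_{k + 1:02d}",
                "cortical",
                "L" if c[0] < 0 else "R",
                cfg.networks[roi_net[k]],
                c[0],
                c[1],
                c[2],
            )
        )
    for k in range(cfg.n_subcortical_rois):
        c = sub_centers[k]
        table_rows.append(
            (
                cfg.n_cortical_rois + 1 + k,
                f"subcortical_{k + 1:02d}",
                "subcortical",
                "L" if c[0] < 0 else "R",
                None,
                None,
                None,
                None,
            )
        )
    table_rows.extend(rows)
    roi_table = pd.DataFrame(
        table_rows,
        columns=["roi_id", "name", "class", "hemisphere", "network", "cx", "cy", "cz"],
    )
    label_volume = Volume3D(
        labels.reshape(template.shape), template.voxel_size, template.origin
    )
    return Parcellation(label_volume, roi_table, tract_masks, tract_endpoints)


# ---------------------------------------------------------------------------
# normative connectomes


def _voxel_network_assignment(parc: Parcellation, brain_idx: np.ndarray) -> np.ndarray:
    """Generative network index per brain voxel: cortical voxels inherit
    their parcel's network, interior voxels the network whose mean direction
    is closest to the voxel's radial direction."""
    nets = list(YEO7_NETWORKS)
    tab = parc.roi_table
    cort = tab[tab["class"] == "cortical"]
    net_index = {n: i for i, n in enumerate(nets)}
    roi_to_net = {
        int(row.roi_id): net_index[row.network] for row in cort.itertuples()
    }
    net_mean_dirs = np.zeros((len(nets), 3))
    for n, i in net_index.items():
        cents = cort.loc[cort["network"] == n, ["cx", "cy", "cz"]].to_numpy(float)
        if len(cents):
            m = cents.mean(axis=0)
            net_mean_dirs[i] = m / (np.linalg.norm(m) + 1e-12)
    coords = parc.label_volume.world_coordinates()[brain_idx]
    rr = np.linalg.norm(coords, axis=1)
    u = coords / np.maximum(rr, 1e-9)[:, None]
    nearest_net = np.argmax(u @ net_mean_dirs.T, axis=1)
    lab = np.asarray(parc.label_volume.data).ravel()[brain_idx]
    out = nearest_net.copy()
    for v, l in enumerate(lab):
        if l in roi_to_net:
            out[v] = roi_to_net[l]
    return out


def simulate_functional_connectome(
    parc: Parcellation,
    S: int = 20,
    T: int = 100,
    within_network_corr: float = 0.6,
    seed: int = 0,
) -> FunctionalConnectome:
    """Simulate resting-state series with planted network structure.

    Each voxel's series is sqrt(rho) x (its network's latent series) +
    sqrt(1 - rho) x iid noise, so same-network voxel pairs correlate at
    ~rho and cross-network pairs at ~0.
    """
    rho = float(within_network_corr)
    if not 0 <= rho < 1:
        raise ValueError("within_network_corr must be in [0, 1)")
    rng = np.random.default_rng(seed)
    bmask = brain_mask(parc)
    brain_idx = bmask.flat_indices()
    voxel_net = _voxel_network_assignment(parc, brain_idx)
    n_nets = len(YEO7_NETWORKS)
    series = np.empty((S, brain_idx.size, T), dtype=np.float32)
    a, b = np.sqrt(rho), np.sqrt(1 - rho)
    for s in range(S):
        latents = rng.standard_normal((n_nets, T))
        noise = rng.standard_normal((brain_idx.size, T))
        series[s] = (a * latents[voxel_net] + b * noise).astype(np.float32)
    template = parc.label_volume.with_data(
        np.zeros(parc.label_volume.shape, dtype=np.int16)
    )
    return FunctionalConnectome(series, brain_idx, template, voxel_net)


def simulate_structural_streamline_map(
    parc: Parcellation,
    density: float = 40.0,
    decay: float = 1.5,
    seed: int = 0,
) -> dict[int, Volume3D]:
    """Per-ROI streamline-count volumes.

    Counts are Poisson with intensity ``density * exp(-d/decay)`` where d is
    the distance (mm) to the nearest tube of a tract geometrically linked to
    the ROI (a tract's endpoints for grey matter ROIs; the tract's own tube
    for tract ROIs). ROIs with no linked tube get all-zero maps.
    """
    if density <= 0:
        raise ValueError("density must be > 0")
    from scipy.ndimage import distance_transform_edt

    rng = np.random.default_rng(seed)
    template = parc.label_volume
    cutoff = 4.0 * decay
    # distance field per tract
    fields: dict[int, np.ndarray] = {}
    for tid in parc.tract_ids:
        tube = parc.tract_masks[tid].data.astype(bool)
        d = distance_transform_edt(~tube, sampling=template.voxel_size)
        intensity = np.where(d <= cutoff, np.exp(-d / decay), 0.0)
        fields[tid] = intensity
    endpoints = parc.tract_endpoints or {}
    linked: dict[int, list[int]] = {rid: [] for rid in parc.roi_ids()}
    for tid, (a, b) in endpoints.items():
        linked[a].append(tid)
        linked[b].append(tid)
    for tid in parc.tract_ids:
        linked[tid] = [tid]
    out: dict[int, Volume3D] = {}
    for rid in parc.roi_ids():
        tubes = linked.get(rid, [])
        if not tubes:
            counts = np.zeros(template.shape, dtype=np.int64)
        else:
            intensity = sum(fields[t] for t in tubes)
            counts = rng.poisson(density * intensity).astype(np.int64)
        out[rid] = template.with_data(counts)
    return out


# ---------------------------------------------------------------------------
# lesions


def simulate_wmh_masks(
    parc: Parcellation,
    n_patients: int,
    volume_lognorm_params: tuple[float, float] = (np.log(60.0), 0.7),
    periventricular_bias: float = 0.7,
    seed: int = 0,
) -> list[BinaryMask]:
    """Sample periventricular-biased white matter lesion masks.

    Per-patient voxel counts follow a (clipped) log-normal, giving the
    right-skewed lesion-load distribution typical of memory-clinic cohorts.
    Masks are unions of blob lesions whose centres concentrate around the
    central "ventricle" region, restricted to white matter so they never
    touch cortical parcels. Empty draws are resampled.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    template = parc.label_volume
    wm = white_matter_mask(parc).data.astype(bool).ravel()
    allowed_idx = np.flatnonzero(wm)
    coords = template.world_coordinates()
    r_in, _ = brain_radii(parc)
    tree = cKDTree(coords[allowed_idx])
    mu, sigma = volume_lognorm_params
    vent_sd = 0.25 * r_in

    masks = []
    for _ in range(n_patients):
        target = int(np.clip(np.round(rng.lognormal(mu, sigma)), 1, allowed_idx.size))
        chosen: set[int] = set()
        for _attempt in range(500):
            if len(chosen) >= target:
                break
            if rng.random() < periventricular_bias:
                center = rng.normal(scale=vent_sd, size=3)
            else:
                center = coords[rng.choice(allowed_idx)]
            radius = rng.uniform(1.5, 3.5)
            hit = tree.query_ball_point(center, radius)
            new = [i for i in hit if allowed_idx[i] not in chosen]
            if not new:
                continue
            need = target - len(chosen)
            if len(new) > need:
                # trim the blob from its rim inward so counts stay log-normal
                d = np.linalg.norm(coords[allowed_idx[new]] - center, axis=1)
                new = [new[j] for j in np.argsort(d, kind="stable")[:need]]
            chosen.update(allowed_idx[i] for i in new)
        if not chosen:  # pathological draw; resample a single seed voxel
            chosen = {int(rng.choice(allowed_idx))}
        data = np.zeros(template.shape, dtype=np.uint8).ravel()
        data[sorted(chosen)] = 1
        masks.append(
            BinaryMask(data.reshape(template.shape), template.voxel_size, template.origin)
        )
    return masks


# ---------------------------------------------------------------------------
# demographics & cognition


def simulate_demographics(n_patients: int, seed: int = 0) -> pd.DataFrame:
    """Memory-clinic-like demographics: age ~ N(71.7, 8.9), sex ~
    Bernoulli(0.5) coded 0/1, education ~ N(12.9, 4.5) clipped at 0."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "id": np.arange(n_patients),
            "age": rng.normal(71.7, 8.9, n_patients),
            "sex": rng.integers(0, 2, n_patients),
            "education": np.clip(rng.normal(12.9, 4.45, n_patients), 0, None),
        }
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def simulate_cognition(
    patients: PatientTable,
    lnm_scores: Mapping[str, "object"],
    parc: Parcellation,
    effects: EffectSpec,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> PatientTable:
    """Generate cognitive domain scores from demographics + LNM effects.

    domain score = b_age z(age) + b_sex sex + b_edu z(education)
                 + effect_size * z(mean LNM score over target-network ROIs)
                 + N(0, noise_sd)

    ``lnm_scores`` maps modality name ('fLNM'/'sLNM') to an LNMScoreMatrix
    whose rows cover every patient; 'volume' effects use total lesion volume
    from the patient masks instead.
    """
    from .imaging import mask_volume_ml

    rng = np.random.default_rng(seed)
    tab = patients.table.copy()
    n = len(tab)
    z_age = _zscore(tab["age"].to_numpy())
    z_edu = _zscore(tab["education"].to_numpy())
    sex = tab["sex"].to_numpy(dtype=float)

    for domain, eff in effects.domains.items():
        signal = np.zeros(n)
        if eff.effect_size != 0.0 and eff.target_network is not None:
            if eff.modality == "volume":
                vols = np.array([mask_volume_ml(m) for m in patients.masks])
                signal = eff.effect_size * _zscore(vols)
            else:
                mat = lnm_scores[eff.modality]
                net_rois = [
                    int(r.roi_id)
                    for r in parc.roi_table.itertuples()
                    if r.network == eff.target_network
                ]
                if not net_rois:
                    raise ValueError(f"no ROIs in network {eff.target_network}")
                sub = mat.scores[net_rois]
                if sub.isna().any().any():
                    raise ValueError("missing LNM scores for some patients")
                signal = eff.effect_size * _zscore(sub.mean(axis=1).to_numpy())
        score = (
            eff.beta_age * z_age
            + eff.beta_sex * sex
            + eff.beta_education * z_edu
            + signal
            + rng.normal(scale=eff.noise_sd, size=n)
        )
        if missing_rate > 0:
            score = np.where(rng.random(n) < missing_rate, np.nan, score)
        tab[domain] = score
    return PatientTable(tab, patients.masks)


# ---------------------------------------------------------------------------
# one-call cohort


@dataclass
class SyntheticCohort:
    """Everything one desk-scale study needs, from one master seed."""

    parcellation: Parcellation
    functional: FunctionalConnectome
    structural: dict[int, Volume3D]
    patients: PatientTable
    flnm: "object"  # LNMScoreMatrix
    slnm: "object"
    effects: EffectSpec
    seed: int


def _stage_seed(master_seed: int, stage: str) -> int:
    import hashlib

    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def simulate_cohort(
    cfg: ToyBrainConfig | None = None,
    n_patients: int = 200,
    effects: EffectSpec | None = None,
    seed: int = 0,
    S: int = 20,
    T: int = 100,
    within_network_corr: float = 0.6,
    volume_lognorm_params: tuple[float, float] = (np.log(60.0), 0.7),
    periventricular_bias: float = 0.7,
    density: float = 40.0,
    decay: float = 1.5,
    missing_rate: float = 0.0,
) -> SyntheticCohort:
    """Generate a full synthetic cohort (brain, connectomes, lesions,
    LNM score matrices and cognition) from one master seed."""
    from .lnm import build_lnm_matrix, functional_seed_maps, structural_seed_maps

    cfg = cfg or ToyBrainConfig()
    effects = effects or EffectSpec.default()
    parc = make_toy_brain(cfg, _stage_seed(seed, "brain"))
    fc = simulate_functional_connectome(
        parc, S=S, T=T, within_network_corr=within_network_corr,
        seed=_stage_seed(seed, "functional"),
    )
    struct = simulate_structural_streamline_map(
        parc, density=density, decay=decay, seed=_stage_seed(seed, "structural")
    )
    masks = simulate_wmh_masks(
        parc,
        n_patients,
        volume_lognorm_params=volume_lognorm_params,
        periventricular_bias=periventricular_bias,
        seed=_stage_seed(seed, "lesions"),
    )
    demo = simulate_demographics(n_patients, seed=_stage_seed(seed, "demographics"))
    fmaps = functional_seed_maps(parc, fc)
    smaps = structural_seed_maps(parc, struct)
    flnm = build_lnm_matrix(masks, fmaps, polarity="positive")
    slnm = build_lnm_matrix(masks, smaps, polarity="positive")
    patients = simulate_cognition(
        PatientTable(demo, masks),
        {"fLNM": flnm, "sLNM": slnm},
        parc,
        effects,
        seed=_stage_seed(seed, "cognition"),
        missing_rate=missing_rate,
    )
    return SyntheticCohort(parc, fc, struct, patients, flnm, slnm, effects, seed)
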