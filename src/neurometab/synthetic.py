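"""Synthetic cohort, imaging, and metabolomics generator with planted truth.

Every downstream stage of the pipeline has a parameter-recovery test against
the structure planted here: contiguous gray-matter atrophy regions in the
MCI group, LC-MS features whose intensities track region-mean gray matter,
batch shifts, replicate noise, structured missingness, and one metabolic
pathway whose compounds all map to the signal features of one region.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
children, one per generation stage, so identical configs produce
byte-identical outputs regardless of which subset of stages is run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .volumes import GMVolumeSet

# Positive-mode adduct mass offsets (Da). M[1+] loses an electron only.
ADDUCT_DELTAS = {
    "M[1+]": -0.000549,
    "M+H[1+]": 1.007276,
    "M+Na[1+]": 22.989218,
}

MZ_RANGE = (85.0, 1275.0)  # instrument scan range


@dataclass
class SyntheticConfig:
    """Generator settings; defaults define the standard study-like conditions.

    Counts mirror the reference cohort (60 MCI / 85 controls). Imaging and
    coupling defaults are chosen so that planted structure is recoverable by
    the pipeline at its default thresholds while null configurations
    (``atrophy_effect=0``, ``coupling=0``) stay calibrated; the reasoning is
    laid out in the methods note.
    """

    n_mci: int = 60
    n_control: int = 85
    grid_dims: tuple[int, int, int] = (32, 32, 22)
    shell: int = 2                      # low-GM border excluded by the mask
    n_regions: int = 5
    region_size: int = 150              # voxels per planted region
    atrophy_effect: float = 0.10        # fractional GM reduction in cases
    base_gm: float = 0.70               # interior gray-matter probability
    background_gm: float = 0.05         # shell probability (below mask cutoff)
    gm_noise_sd: float = 0.03           # voxel-level noise
    region_effect_sd: float = 0.06      # per-subject, per-region random effect
    n_features: int = 2500
    n_signal_features_per_region: int = 12
    coupling: float = 0.60              # target |r| to region-mean GM
    coupling_spread: float = 0.44       # full width of per-feature coupling
    n_batches: int = 2
    batch_shift: float = 0.8            # log2 offset between batch centers
    replicate_cv: float = 0.15          # within-triplicate CV
    missing_rate_background: float = 0.02
    frac_high_missing: float = 0.05     # features missing in both groups
    high_missing_rate: float = 0.35
    frac_group_missing: float = 0.02    # features missing mostly in MCI
    group_missing_rate: float = 0.30
    frac_high_cv: float = 0.02          # features failing the CV filter
    high_cv: float = 2.5                # population CV; 3-replicate sample CV
                                        # then has median ~0.9, above the 0.75 cut
    censored_missing: bool = False      # left-censor instead of random missing
    n_decoy_compounds: int = 140
    n_annotatable_background: int = 100
    n_pathways: int = 25
    pathway_size: int = 12
    planted_pathway_size: int = 10
    mz_jitter_ppm: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_mci": self.n_mci,
            "n_control": self.n_control,
            "n_regions": self.n_regions,
            "region_size": self.region_size,
            "n_features": self.n_features,
            "n_signal_features_per_region": self.n_signal_features_per_region,
            "n_batches": self.n_batches,
            "n_pathways": self.n_pathways,
            "planted_pathway_size": self.planted_pathway_size,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigurationError(f"{name} must be an integer >= 1, got {value!r}")
        if not (0.0 <= self.atrophy_effect < 1.0):
            raise ConfigurationError("atrophy_effect must lie in [0, 1)")
        if not (0.0 <= self.coupling < 1.0):
            raise ConfigurationError("coupling must lie in [0, 1)")
        lo = self.coupling - self.coupling_spread / 2
        hi = self.coupling + self.coupling_spread / 2
        if self.coupling > 0 and not (0.0 <= lo and hi < 1.0):
            raise ConfigurationError("coupling +/- coupling_spread/2 must stay inside [0, 1)")
        if len(self.grid_dims) != 3 or any(d < 1 for d in self.grid_dims):
            raise ConfigurationError("grid_dims must be a 3-tuple of positive ints")
        if self.n_signal_features_per_region * self.n_regions > self.n_features:
            raise ConfigurationError("more signal features requested than n_features")
        if self.planted_pathway_size > self.n_signal_features_per_region:
            raise ConfigurationError(
                "planted_pathway_size exceeds the compound count of one region"
            )

    def spawn_rngs(self, n: int) -> list[np.random.Generator]:
        seq = np.random.SeedSequence(self.seed)
        return [np.random.default_rng(s) for s in seq.spawn(n)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_dims"] = list(d["grid_dims"])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class GroundTruth:
    """Planted structure: which voxels, features, compounds and pathway."""

    region_voxel_ids: list[np.ndarray] = field(default_factory=list)  # flat grid ids
    signal_feature_ids: list[np.ndarray] = field(default_factory=list)
    feature_compound_map: dict[int, tuple[str, str]] = field(default_factory=dict)
    enriched_pathway_id: str | None = None
    enriched_region: int = 0

    @property
    def all_region_voxels(self) -> np.ndarray:
        if not self.region_voxel_ids:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(self.region_voxel_ids)

    @property
    def all_signal_features(self) -> np.ndarray:
        if not self.signal_feature_ids:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(self.signal_feature_ids)


@dataclass
class RawFeatureTable:
    """Untargeted LC-MS feature table: m/z, retention time, triplicates."""

    mz: np.ndarray                      # (n_features,)
    rt: np.ndarray                      # (n_features,) seconds
    intensities: np.ndarray             # (n_features, n_samples, 3), NaN = missing
    samples: list[str]
    sample_batches: np.ndarray          # (n_samples,) integer labels
    feature_ids: list[str]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def copy(self) -> "RawFeatureTable":
        return RawFeatureTable(
            mz=self.mz.copy(),
            rt=self.rt.copy(),
            intensities=self.intensities.copy(),
            samples=list(self.samples),
            sample_batches=self.sample_batches.copy(),
            feature_ids=list(self.feature_ids),
        )

    def subset_features(self, keep: np.ndarray) -> "RawFeatureTable":
        return RawFeatureTable(
            mz=self.mz[keep],
            rt=self.rt[keep],
            intensities=self.intensities[keep],
            samples=list(self.samples),
            sample_batches=self.sample_batches.copy(),
            feature_ids=[self.feature_ids[i] for i in np.flatnonzero(np.asarray(keep))]
            if np.asarray(keep).dtype == bool
            else [self.feature_ids[i] for i in np.asarray(keep)],
        )

    def subset_samples(self, keep: np.ndarray) -> "RawFeatureTable":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return RawFeatureTable(
            mz=self.mz.copy(),
            rt=self.rt.copy(),
            intensities=self.intensities[:, idx, :],
            samples=[self.samples[i] for i in idx],
            sample_batches=self.sample_batches[idx],
            feature_ids=list(self.feature_ids),
        )


@dataclass
class CompoundDB:
    """Compound masses and pathway memberships (KEGG-like reference)."""

    compounds: pd.DataFrame             # compound_id, mass
    pathways: dict[str, set[str]]       # pathway_id -> compound ids
    pathway_names: dict[str, str]

    def compounds_in(self, pathway_id: str) -> set[str]:
        return self.pathways[pathway_id]


@dataclass
class SyntheticDataset:
    """Bundle of all generated inputs plus the planted truth."""

    config: SyntheticConfig
    cohort: pd.DataFrame
    gm: GMVolumeSet
    raw: RawFeatureTable
    db: CompoundDB
    atlas: np.ndarray
    atlas_names: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Subject metadata: diagnosis, age, sex, batch (balanced per diagnosis)."""
    config.validate()
    rng = config.spawn_rngs(6)[0]
    n = config.n_mci + config.n_control
    subjects = [f"S{i + 1:03d}" for i in range(n)]
    diagnosis = np.array(["MCI"] * config.n_mci + ["CN"] * config.n_control)
    # ages/sex loosely follow the reference cohort's Table-1 margins
    age = np.where(
        diagnosis == "MCI",
        rng.normal(67.1, 9.2, n),
        rng.normal(62.7, 7.1, n),
    ).round(1)
    sex = np.where(
        diagnosis == "MCI",
        rng.choice(["F", "M"], n, p=[0.58, 0.42]),
        rng.choice(["F", "M"], n, p=[0.71, 0.29]),
    )
    # round-robin batch assignment within each diagnosis keeps batches balanced
    batch = np.empty(n, dtype=int)
    for group in ("MCI", "CN"):
        idx = np.flatnonzero(diagnosis == group)
        idx = rng.permutation(idx)
        batch[idx] = np.arange(idx.size) % config.n_batches
    meta = pd.DataFrame(
        {"diagnosis": diagnosis, "age": age, "sex": sex, "batch": batch},
        index=pd.Index(subjects, name="subject"),
    )
    return meta


# ---------------------------------------------------------------------------
# gray-matter volumes


def _region_centers(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Place region centers on an interior lattice with guaranteed spacing."""
    dims = np.array(config.grid_dims)
    radii = _region_radii(config)
    margin = config.shell + np.ceil(radii).astype(int) + 1
    lo, hi = margin, dims - margin
    if np.any(hi <= lo):
        raise ConfigurationError("grid too small to host the requested regions")
    # lattice spacing > 2*max radius + 1 guarantees disjoint regions
    spacing = 2 * np.ceil(radii).astype(int) + 2
    axes = [np.arange(lo[d], hi[d], spacing[d]) for d in range(3)]
    lattice = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T
    if lattice.shape[0] < config.n_regions:
        raise ConfigurationError(
            f"grid fits only {lattice.shape[0]} disjoint regions, "
            f"{config.n_regions} requested"
        )
    pick = rng.choice(lattice.shape[0], size=config.n_regions, replace=False)
    return lattice[np.sort(pick)]


def _region_radii(config: SyntheticConfig) -> np.ndarray:
    """Ellipsoid radii (x, y, z) sized to hold ~1.3x region_size voxels."""
    target = 1.3 * config.region_size
    # volume of ellipsoid = 4/3 pi rx ry rz with rz = 0.75 rx, ry = rx
    rx = (target / (4.0 / 3.0 * np.pi * 0.75)) ** (1.0 / 3.0)
    return np.array([rx, rx, 0.75 * rx])


def _region_voxels(
    center: np.ndarray, radii: np.ndarray, dims: tuple[int, int, int], size: int
) -> np.ndarray:
    """The `size` voxels nearest the center in ellipsoid-normalized distance.

    A discrete ball around its own center is star-shaped, hence 26-connected.
    Flat (C-order) grid indices are returned in sorted order.
    """
    r_int = np.ceil(radii).astype(int) + 1
    slices = [np.arange(center[d] - r_int[d], center[d] + r_int[d] + 1) for d in range(3)]
    ii, jj, kk = np.meshgrid(*slices, indexing="ij")
    d2 = (
        ((ii - center[0]) / radii[0]) ** 2
        + ((jj - center[1]) / radii[1]) ** 2
        + ((kk - center[2]) / radii[2]) ** 2
    )
    order = np.argsort(d2, axis=None, kind="stable")[:size]
    coords = np.stack(
        [ii.ravel()[order], jj.ravel()[order], kk.ravel()[order]], axis=1
    )
    flat = np.ravel_multi_index((coords[:, 0], coords[:, 1], coords[:, 2]), dims)
    return np.sort(flat)


def generate_gm_volumes(
    config: SyntheticConfig, cohort: pd.DataFrame
) -> tuple[GMVolumeSet, GroundTruth]:
    """Per-subject GM probability volumes with planted atrophy regions.

    Interior voxels sit at ``base_gm`` plus noise; within a planted region a
    case's expected GM is ``(1 - atrophy_effect) * base_gm`` while controls
    stay at ``base_gm``. Each (subject, region) pair additionally receives a
    shared random offset (``region_effect_sd``) representing anatomical
    variation; this is what the coupled metabolite features track.
    """
    config.validate()
    rng = config.spawn_rngs(6)[1]
    dims = config.grid_dims
    n = len(cohort)
    is_mci = (cohort["diagnosis"] == "MCI").to_numpy()

    centers = _region_centers(config, rng)
    radii = _region_radii(config)
    regions = [
        _region_voxels(c, radii, dims, config.region_size) for c in centers
    ]

    interior = np.zeros(dims, dtype=bool)
    s = config.shell
    interior[s : dims[0] - s, s : dims[1] - s, s : dims[2] - s] = True

    base = np.where(interior, config.base_gm, config.background_gm)
    data = rng.normal(0.0, config.gm_noise_sd, size=(n,) + dims)
    data += base[None, :, :, :]

    region_effects = rng.normal(0.0, config.region_effect_sd, size=(n, config.n_regions))
    flat = data.reshape(n, -1)
    for r, vox in enumerate(regions):
        flat[:, vox] += region_effects[:, r][:, None]
        flat[np.ix_(is_mci, vox)] -= config.atrophy_effect * config.base_gm
    data = flat.reshape((n,) + dims)
    np.clip(data, 0.0, 1.0, out=data)

    affine = np.diag([1.5, 1.5, 1.5, 1.0])  # nominal 1.5 mm isotropic
    gm = GMVolumeSet(data=data, subjects=list(cohort.index), affine=affine)
    truth = GroundTruth(region_voxel_ids=regions)
    return gm, truth


# ---------------------------------------------------------------------------
# feature table


def _assign_compound_mz(
    rng: np.random.Generator, mass: float, adduct: str, jitter_ppm: float
) -> float:
    mz = mass + ADDUCT_DELTAS[adduct]
    return mz * (1.0 + rng.uniform(-jitter_ppm, jitter_ppm) * 1e-6)


def generate_feature_table(
    config: SyntheticConfig, gm: GMVolumeSet, truth: GroundTruth
) -> RawFeatureTable:
    """Raw LC-MS triplicate table with planted GM-coupled signal features.

    Signal features are tied to one region each: their log2 abundance carries
    a scaled, standardized copy of that region's subject-mean GM, with the
    scale set so the population correlation equals the feature's coupling
    (drawn uniformly in ``coupling +/- coupling_spread/2``). Signal and
    "annotatable background" features get m/z derived from compound masses
    plus adduct offsets with <= ``mz_jitter_ppm`` jitter; everything else is
    uniform across the scan range. `truth` is updated in place with feature
    and compound assignments.
    """
    config.validate()
    rng = config.spawn_rngs(6)[2]
    n_feat, n_samp = config.n_features, gm.data.shape[0]
    n_sig = config.n_signal_features_per_region * config.n_regions

    # --- partition features into roles
    perm = rng.permutation(n_feat)
    signal = perm[:n_sig]
    rest = perm[n_sig:]
    n_hm = int(round(config.frac_high_missing * n_feat))
    n_gm_miss = int(round(config.frac_group_missing * n_feat))
    n_hcv = int(round(config.frac_high_cv * n_feat))
    n_annot = min(config.n_annotatable_background, rest.size - n_hm - n_gm_miss - n_hcv)
    high_missing = rest[:n_hm]
    group_missing = rest[n_hm : n_hm + n_gm_miss]
    high_cv = rest[n_hm + n_gm_miss : n_hm + n_gm_miss + n_hcv]
    annotatable = rest[n_hm + n_gm_miss + n_hcv : n_hm + n_gm_miss + n_hcv + n_annot]

    truth.signal_feature_ids = [
        np.sort(signal[r * config.n_signal_features_per_region : (r + 1) * config.n_signal_features_per_region])
        for r in range(config.n_regions)
    ]

    # --- m/z, retention time, compound assignments
    adduct_names = list(ADDUCT_DELTAS)
    mz = rng.uniform(MZ_RANGE[0], MZ_RANGE[1], n_feat)
    rt = rng.uniform(20.0, 300.0, n_feat).round(1)
    truth.feature_compound_map = {}
    compound_masses: dict[str, float] = {}
    for r, feats in enumerate(truth.signal_feature_ids):
        for j, f in enumerate(feats):
            cid = f"C_SIG_{r:02d}_{j:02d}"
            mass = float(rng.uniform(90.0, 1200.0))
            adduct = adduct_names[rng.integers(len(adduct_names))]
            compound_masses[cid] = mass
            truth.feature_compound_map[int(f)] = (cid, adduct)
            mz[f] = _assign_compound_mz(rng, mass, adduct, config.mz_jitter_ppm)
    decoys = [f"C_BG_{i:03d}" for i in range(config.n_decoy_compounds)]
    for cid in decoys:
        compound_masses[cid] = float(rng.uniform(90.0, 1200.0))
    for f in annotatable:
        cid = decoys[int(rng.integers(len(decoys)))]
        adduct = adduct_names[rng.integers(len(adduct_names))]
        truth.feature_compound_map[int(f)] = (cid, adduct)
        mz[f] = _assign_compound_mz(rng, compound_masses[cid], adduct, config.mz_jitter_ppm)
    truth.compound_masses = compound_masses  # type: ignore[attr-defined]

    # --- subject-level log2 abundances
    mu = rng.normal(16.0, 1.5, n_feat)
    x = mu[:, None] + rng.normal(0.0, 1.0, (n_feat, n_samp))
    if config.coupling > 0:
        region_means = np.stack(
            [gm.data.reshape(n_samp, -1)[:, vox].mean(axis=1) for vox in truth.region_voxel_ids],
            axis=1,
        )  # (n_samp, n_regions)
        z = (region_means - region_means.mean(0)) / region_means.std(0, ddof=0)
        lo = config.coupling - config.coupling_spread / 2
        hi = config.coupling + config.coupling_spread / 2
        for r, feats in enumerate(truth.signal_feature_ids):
            c = rng.uniform(lo, hi, feats.size)
            beta = c / np.sqrt(1.0 - c**2)  # residual sd is 1.0
            sign = rng.choice([-1.0, 1.0], feats.size)
            x[feats] += (sign * beta)[:, None] * z[:, r][None, :]

    # --- batch shifts (per-feature location effects around batch centers)
    centers = config.batch_shift * (
        np.arange(config.n_batches) - (config.n_batches - 1) / 2.0
    )
    gamma = rng.normal(centers[None, :], 0.3, (n_feat, config.n_batches))

    return _finish_feature_table(config, rng, mz, rt, x, gamma, high_missing,
                                 group_missing, high_cv, truth, gm)


def _finish_feature_table(config, rng, mz, rt, x, gamma, high_missing,
                          group_missing, high_cv, truth, gm):
    n_feat, n_samp = x.shape
    # batch labels aligned with the cohort ordering used for the volumes
    cohort_batches = getattr(gm, "_batches", None)
    if cohort_batches is None:
        batches = np.arange(n_samp) % config.n_batches
    else:
        batches = np.asarray(cohort_batches)
    x = x + gamma[:, batches]

    # triplicate replicates with multiplicative lognormal noise
    sigma = np.full(n_feat, np.sqrt(np.log1p(config.replicate_cv**2)))
    sigma[high_cv] = np.sqrt(np.log1p(config.high_cv**2))
    noise = rng.normal(0.0, 1.0, (n_feat, n_samp, 3))
    log_reps = (
        x[:, :, None] * np.log(2.0)
        + sigma[:, None, None] * noise
        - 0.5 * sigma[:, None, None] ** 2
    )
    intensities = np.exp(log_reps)

    # --- missingness
    is_mci = getattr(gm, "_is_mci", None)
    if is_mci is None:
        is_mci = np.zeros(n_samp, dtype=bool)
    # background: replicate-level missing at random
    bg_mask = rng.random((n_feat, n_samp, 3)) < config.missing_rate_background
    intensities[bg_mask] = np.nan
    # high-missing features: whole cells knocked out in both groups
    if high_missing.size:
        cells = rng.random((high_missing.size, n_samp))
        if config.censored_missing:
            # left-censor: drop the lowest-intensity cells up to the rate
            cell_means = np.nanmean(intensities[high_missing], axis=2)
            thresh = np.nanquantile(cell_means, config.high_missing_rate, axis=1)
            drop = cell_means < thresh[:, None]
        else:
            drop = cells < config.high_missing_rate
        for row, f in enumerate(high_missing):
            intensities[f, drop[row], :] = np.nan
    # group-structured: cells missing mostly in the MCI group
    if group_missing.size and is_mci.any():
        cells = rng.random((group_missing.size, n_samp)) < config.group_missing_rate
        cells &= is_mci[None, :]
        for row, f in enumerate(group_missing):
            intensities[f, cells[row], :] = np.nan

    samples = list(gm.subjects)
    feature_ids = [f"F{i + 1:06d}" for i in range(n_feat)]
    return RawFeatureTable(
        mz=mz,
        rt=rt,
        intensities=intensities,
        samples=samples,
        sample_batches=batches,
        feature_ids=feature_ids,
    )


# ---------------------------------------------------------------------------
# pathway database


def generate_pathway_db(config: SyntheticConfig, truth: GroundTruth) -> CompoundDB:
    """Compound/pathway reference with one pathway planted in one region.

    The planted pathway consists of ``planted_pathway_size`` compounds all
    mapped to signal features of the enriched region; decoy pathways draw
    random compounds from the remainder. Every compound lands in >= 1 pathway.
    """
    config.validate()
    if not truth.feature_compound_map:
        raise ConfigurationError("truth has no feature_compound_map; generate features first")
    rng = config.spawn_rngs(6)[3]
    masses: dict[str, float] = truth.compound_masses  # type: ignore[attr-defined]
    all_compounds = sorted(masses)

    region = truth.enriched_region
    region_feats = truth.signal_feature_ids[region]
    region_compounds = sorted(
        truth.feature_compound_map[int(f)][0] for f in region_feats
    )
    if config.planted_pathway_size > len(region_compounds):
        raise ConfigurationError("planted_pathway_size exceeds compound count")
    planted = set(
        rng.choice(region_compounds, config.planted_pathway_size, replace=False)
    )

    pathways: dict[str, set[str]] = {"PW000": planted}
    pathway_names = {"PW000": "Planted pathway"}
    pool = [c for c in all_compounds if c not in planted]
    for i in range(1, config.n_pathways):
        pid = f"PW{i:03d}"
        size = min(config.pathway_size, len(pool))
        members = set(rng.choice(pool, size, replace=False))
        pathways[pid] = members
        pathway_names[pid] = f"Decoy pathway {i}"
    # guarantee every compound belongs somewhere
    assigned = set().union(*pathways.values())
    leftovers = [c for c in all_compounds if c not in assigned]
    decoy_ids = [p for p in pathways if p != "PW000"]
    for j, c in enumerate(leftovers):
        pathways[decoy_ids[j % len(decoy_ids)]].add(c)

    compounds = pd.DataFrame(
        {"compound_id": all_compounds, "mass": [masses[c] for c in all_compounds]}
    )
    truth.enriched_pathway_id = "PW000"
    return CompoundDB(compounds=compounds, pathways=pathways, pathway_names=pathway_names)


# ---------------------------------------------------------------------------
# atlas


def generate_atlas(
    config: SyntheticConfig, truth: GroundTruth
) -> tuple[np.ndarray, pd.DataFrame]:
    """Label volume: planted regions get labels 1..n_regions; the remaining
    interior is split into octant parcels so scattered voxel sets annotate to
    no single majority region."""
    dims = config.grid_dims
    atlas = np.zeros(dims, dtype=np.int16)
    s = config.shell
    # octant parcels over the interior
    mids = [s + (d - 2 * s) // 2 for d in dims]
    label = config.n_regions + 1
    for ox in range(2):
        for oy in range(2):
            for oz in range(2):
                xs = slice(s, mids[0]) if ox == 0 else slice(mids[0], dims[0] - s)
                ys = slice(s, mids[1]) if oy == 0 else slice(mids[1], dims[1] - s)
                zs = slice(s, mids[2]) if oz == 0 else slice(mids[2], dims[2] - s)
                atlas[xs, ys, zs] = label
                label += 1
    flat = atlas.reshape(-1)
    for r, vox in enumerate(truth.region_voxel_ids):
        flat[vox] = r + 1
    names = pd.DataFrame(
        {
            "label": list(range(1, config.n_regions + 1))
            + list(range(config.n_regions + 1, label)),
            "name": [f"planted_region_{r + 1}" for r in range(config.n_regions)]
            + [f"parcel_{i + 1}" for i in range(label - config.n_regions - 1)],
        }
    )
    return atlas, names


# ---------------------------------------------------------------------------
# full dataset + fixtures on disk


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Run every generation stage with deterministic sub-seeds."""
    config.validate()
    cohort = generate_cohort(config)
    gm, truth = generate_gm_volumes(config, cohort)
    # stash cohort alignment used by the feature generator
    gm._batches = cohort["batch"].to_numpy()  # type: ignore[attr-defined]
    gm._is_mci = (cohort["diagnosis"] == "MCI").to_numpy()  # type: ignore[attr-defined]
    raw = generate_feature_table(config, gm, truth)
    db = generate_pathway_db(config, truth)
    atlas, atlas_names = generate_atlas(config, truth)
    return SyntheticDataset(
        config=config,
        cohort=cohort,
        gm=gm,
        raw=raw,
        db=db,
        atlas=atlas,
        atlas_names=atlas_names,
        truth=truth,
    )


def feature_table_frame(raw: RawFeatureTable) -> pd.DataFrame:
    """Tab-delimited layout: mz, time, then <sample>_rep1..rep3 columns."""
    cols = {"mz": raw.mz, "time": raw.rt}
    for j, s in enumerate(raw.samples):
        for r in range(3):
            cols[f"{s}_rep{r + 1}"] = raw.intensities[:, j, r]
    return pd.DataFrame(cols, index=pd.Index(raw.feature_ids, name="feature_id"))


def raw_from_frame(df: pd.DataFrame, sample_batches: pd.Series) -> RawFeatureTable:
    rep_cols = [c for c in df.columns if "_rep" in c]
    samples = sorted({c.rsplit("_rep", 1)[0] for c in rep_cols})
    inten = np.stack(
        [
            np.stack([df[f"{s}_rep{r + 1}"].to_numpy() for r in range(3)], axis=1)
            for s in samples
        ],
        axis=1,
    )
    return RawFeatureTable(
        mz=df["mz"].to_numpy(),
        rt=df["time"].to_numpy(),
        intensities=inten,
        samples=samples,
        sample_batches=sample_batches.loc[samples].to_numpy(),
        feature_ids=list(df.index),
    )


def write_fixture_set(dataset: SyntheticDataset, outdir: str | Path) -> dict:
    """Write NIfTI volumes, delimited tables and a ground-truth manifest.

    Returns the manifest (also written as JSON), which records the seed and a
    hash of the generating config so fixtures are traceable.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataset.config

    vol_dir = out / "volumes"
    vol_dir.mkdir(exist_ok=True)
    for i, subj in enumerate(dataset.gm.subjects):
        img = nib.Nifti1Image(
            dataset.gm.data[i].astype(np.float32), dataset.gm.affine
        )
        nib.save(img, vol_dir / f"{subj}_gm.nii.gz")
    nib.save(
        nib.Nifti1Image(dataset.atlas.astype(np.int16), dataset.gm.affine),
        out / "atlas.nii.gz",
    )
    dataset.atlas_names.to_csv(out / "atlas_labels.tsv", sep="\t", index=False)
    feature_table_frame(dataset.raw).to_csv(out / "feature_table.tsv", sep="\t")
    dataset.cohort.to_csv(out / "metadata.tsv", sep="\t")

    db_rows = []
    masses = dict(
        zip(dataset.db.compounds["compound_id"], dataset.db.compounds["mass"])
    )
    for pid, members in dataset.db.pathways.items():
        for c in sorted(members):
            db_rows.append((c, masses[c], pid, dataset.db.pathway_names[pid]))
    pd.DataFrame(
        db_rows, columns=["compound_id", "mass", "pathway_id", "pathway_name"]
    ).to_csv(out / "compound_db.tsv", sep="\t", index=False)

    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": cfg.to_dict(),
        "ground_truth": {
            "region_voxel_ids": [v.tolist() for v in dataset.truth.region_voxel_ids],
            "signal_feature_ids": [
                v.tolist() for v in dataset.truth.signal_feature_ids
            ],
            "feature_compound_map": {
                str(k): list(v) for k, v in dataset.truth.feature_compound_map.items()
            },
            "enriched_pathway_id": dataset.truth.enriched_pathway_id,
            "enriched_region": dataset.truth.enriched_region,
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def load_fixture_set(fixdir: str | Path) -> SyntheticDataset:
    """Reload a fixture set written by :func:`write_fixture_set`."""
    d = Path(fixdir)
    manifest = json.loads((d / "ground_truth.json").read_text())
    config = SyntheticConfig(**{**manifest["config"], "grid_dims": tuple(manifest["config"]["grid_dims"])})
    cohort = pd.read_csv(d / "metadata.tsv", sep="\t", index_col=0)
    vols, subjects = [], list(cohort.index)
    affine = None
    for subj in subjects:
        img = nib.load(d / "volumes" / f"{subj}_gm.nii.gz")
        vols.append(np.asarray(img.dataobj, dtype=np.float64))
        affine = img.affine
    gm = GMVolumeSet(data=np.stack(vols), subjects=subjects, affine=affine)
    gm._batches = cohort["batch"].to_numpy()  # type: ignore[attr-defined]
    gm._is_mci = (cohort["diagnosis"] == "MCI").to_numpy()  # type: ignore[attr-defined]
    df = pd.read_csv(d / "feature_table.tsv", sep="\t", index_col=0)
    raw = raw_from_frame(df, cohort["batch"])
    # re-order raw samples to cohort order
    order = [raw.samples.index(s) for s in subjects]
    raw = raw.subset_samples(np.array(order))
    dbf = pd.read_csv(d / "compound_db.tsv", sep="\t")
    pathways: dict[str, set[str]] = {}
    pathway_names: dict[str, str] = {}
    for pid, grp in dbf.groupby("pathway_id"):
        pathways[pid] = set(grp["compound_id"])
        pathway_names[pid] = grp["pathway_name"].iloc[0]
    compounds = dbf[["compound_id", "mass"]].drop_duplicates().reset_index(drop=True)
    db = CompoundDB(compounds=compounds, pathways=pathways, pathway_names=pathway_names)
    atlas_img = nib.load(d / "atlas.nii.gz")
    atlas = np.asarray(atlas_img.dataobj, dtype=np.int16)
    atlas_names = pd.read_csv(d / "atlas_labels.tsv", sep="\t")
    gt = manifest["ground_truth"]
    truth = GroundTruth(
        region_voxel_ids=[np.array(v, dtype=np.int64) for v in gt["region_voxel_ids"]],
        signal_feature_ids=[np.array(v, dtype=np.int64) for v in gt["signal_feature_ids"]],
        feature_compound_map={int(k): tuple(v) for k, v in gt["feature_compound_map"].items()},
        enriched_pathway_id=gt["enriched_pathway_id"],
        enriched_region=gt["enriched_region"],
    )
    truth.compound_masses = dict(  # type: ignore[attr-defined]
        zip(compounds["compound_id"], compounds["mass"])
    )
    return SyntheticDataset(
        config=config,
        cohort=cohort,
        gm=gm,
        raw=raw,
        db=db,
        atlas=atlas,
        atlas_names=atlas_names,
        truth=truth,
    )
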