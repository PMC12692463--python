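"""Synthetic multi-site, two-modality cohort simulator.

Emulates the structure of a multi-center MDD resting-state cohort: several
acquisition sites with their own scan lengths and linear scanner effects
(per-region additive offset and multiplicative gain), a binary diagnosis
with group-level effects confined to a subset of regions, ROI time series
with AR(1) temporal autocorrelation standing in for band-limited BOLD, and
smooth 3-D gray-matter-volume images partitioned into parcels so that
region-level attribution has a defined voxel→region mapping.

Generative model (site s, subject i with diagnosis y, region r, time t):

    x_t = g_{s,r} * (a_{i,r} + u_t + y * delta_r) + o_{s,r}

where u_t is a stationary AR(1) process, a_{i,r} a subject-level random
intercept, delta_r the disease amplitude shift (0 off the affected set),
g_{s,r} ~ 1 + N(0, gain_sd) and o_{s,r} ~ N(0, offset_sd) the site effects.
GMV volumes are template + y*Delta on affected parcels + site offset/gain +
subject field + white voxel noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import silhouette_score

from .io_data import SubjectRecord

__all__ = ["SimulationConfig", "GroundTruth", "simulate_cohort",
           "site_separability_probe", "build_parcel_map", "CohortArrays"]


def _default_site_T(n_sites: int, lo: int = 90, hi: int = 140
                    ) -> list[tuple[int, int]]:
    """Per-site scan-length windows (default: short-scan protocols, one
    10-volume window per site spread over [lo, hi])."""
    starts = np.linspace(lo, hi - 10, n_sites).astype(int)
    return [(int(s), int(s) + 10) for s in starts]


@dataclass
class SimulationConfig:
    """Desk-scale defaults: 6 sites × (20 MDD + 20 HC), 32 regions,
    16×20×16 volumes — sized to train on a single CPU in minutes."""

    n_sites: int = 6
    subjects_per_site: tuple[int, int] = (20, 20)  # (MDD, HC)
    d_regions: int = 32
    t_ranges: list[tuple[int, int]] | None = None  # per-site [lo, hi]
    gmv_dims: tuple[int, int, int] = (16, 20, 16)
    affected_regions: tuple[int, ...] | None = None  # default: 4 spread evenly
    ts_disease_shift: float = 0.6   # delta_r, in units of subject-level SD
    gmv_disease_shift: float = 0.6  # Delta on affected parcels
    ts_offset_sd: float = 0.5       # site additive effect SD (per region)
    ts_gain_sd: float = 0.1         # site multiplicative effect SD
    gmv_offset_sd: float = 0.5
    gmv_gain_sd: float = 0.1
    ar_coef: float = 0.5            # AR(1) coefficient of the BOLD stand-in
    ar_innovation_sd: float = 1.0
    subject_sd: float = 1.0         # between-subject intercept SD (both modalities)
    gmv_noise_sd: float = 0.5       # white voxel noise
    seed: int = 0

    def __post_init__(self):
        if self.t_ranges is None:
            self.t_ranges = _default_site_T(self.n_sites)
        if self.affected_regions is None:
            k = min(4, self.d_regions)
            self.affected_regions = tuple(
                int(i) for i in np.linspace(0, self.d_regions - 1, k + 1)[:k])
        if len(self.t_ranges) != self.n_sites:
            raise ValueError("need one T range per site")
        for lo, hi in self.t_ranges:
            if not (90 <= lo <= hi <= 240):
                raise ValueError(f"T range ({lo},{hi}) outside [90, 240]")
        if any(r >= self.d_regions for r in self.affected_regions):
            raise ValueError("affected region index out of range")
        for name in ("ts_offset_sd", "ts_gain_sd", "gmv_offset_sd",
                     "gmv_gain_sd", "ar_innovation_sd", "subject_sd",
                     "gmv_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.subjects_per_site) < 1:
            raise ValueError("every site needs at least one subject per group")


@dataclass
class GroundTruth:
    """Latent quantities actually drawn for a simulated cohort."""

    site_ts_offset: np.ndarray   # S, d
    site_ts_gain: np.ndarray     # S, d
    site_gmv_offset: np.ndarray  # S
    site_gmv_gain: np.ndarray    # S
    affected_regions: tuple[int, ...]
    labels: np.ndarray
    sites: np.ndarray
    parcel_map: np.ndarray = field(repr=False)  # voxel → region index
    gmv_template: np.ndarray = field(repr=False)


@dataclass
class CohortArrays:
    """In-memory cohort: list-of-arrays time series + stacked volumes."""

    records: list[SubjectRecord]
    ts: list[np.ndarray]          # per subject, T_i × d
    gmv: np.ndarray               # N × D × H × W
    labels: np.ndarray
    sites: np.ndarray
    n_sites: int
    parcel_map: np.ndarray

    def __len__(self) -> int:
        return len(self.records)


def build_parcel_map(dims: tuple[int, int, int], d_regions: int) -> np.ndarray:
    """Partition a volume into d contiguous radial-shell parcels.

    Voxels are ranked by distance from the volume center and split into
    equal-size bins, giving every region the same voxel count (±1).
    """
    grid = np.indices(dims).astype(np.float64)
    center = (np.array(dims, dtype=np.float64)[:, None, None, None] - 1) / 2.0
    radius = np.sqrt(((grid - center) ** 2).sum(axis=0))
    order = np.argsort(radius.ravel(), kind="stable")
    parcels = np.empty(int(np.prod(dims)), dtype=np.int64)
    parcels[order] = np.arange(order.size) * d_regions // order.size
    return parcels.reshape(dims)


def _ar1(T: int, phi: float, sd: float, rng: np.random.Generator,
         d: int) -> np.ndarray:
    """Stationary AR(1) traces, T × d."""
    out = np.empty((T, d))
    scale0 = sd / np.sqrt(1.0 - phi ** 2) if abs(phi) < 1 else sd
    out[0] = rng.normal(0.0, scale0, size=d)
    innov = rng.normal(0.0, sd, size=(T - 1, d))
    for t in range(1, T):
        out[t] = phi * out[t - 1] + innov[t - 1]
    return out


def simulate_cohort(config: SimulationConfig | None = None,
                    seed: int | None = None
                    ) -> tuple[CohortArrays, GroundTruth]:
    """Draw a full cohort; identical (config, seed) gives identical payloads."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    S, d = config.n_sites, config.d_regions
    delta = np.zeros(d)
    delta[list(config.affected_regions)] = config.ts_disease_shift

    site_ts_offset = rng.normal(0.0, config.ts_offset_sd, size=(S, d))
    site_ts_gain = 1.0 + rng.normal(0.0, config.ts_gain_sd, size=(S, d))
    site_gmv_offset = rng.normal(0.0, config.gmv_offset_sd, size=S)
    site_gmv_gain = 1.0 + rng.normal(0.0, config.gmv_gain_sd, size=S)

    dims = config.gmv_dims
    parcel_map = build_parcel_map(dims, d)
    grid = np.indices(dims).astype(np.float64)
    center = (np.array(dims, dtype=np.float64)[:, None, None, None] - 1) / 2.0
    radius = np.sqrt(((grid - center) ** 2).sum(axis=0))
    template = np.exp(-(radius / radius.max()) ** 2)  # smooth radial gradient
    gmv_mask = np.isin(parcel_map, list(config.affected_regions))

    records: list[SubjectRecord] = []
    ts_list: list[np.ndarray] = []
    gmv_list: list[np.ndarray] = []
    labels_list: list[int] = []
    sites_list: list[int] = []
    n_mdd, n_hc = config.subjects_per_site
    for s in range(S):
        lo, hi = config.t_ranges[s]
        for y, count in ((1, n_mdd), (0, n_hc)):
            for j in range(count):
                T = int(rng.integers(lo, hi + 1))
                u = _ar1(T, config.ar_coef, config.ar_innovation_sd, rng, d)
                a = rng.normal(0.0, config.subject_sd, size=d)
                x = site_ts_gain[s] * (a + u + y * delta) + site_ts_offset[s]
                subject_field = rng.normal(0.0, config.subject_sd * 0.1,
                                           size=dims)
                vol = (site_gmv_gain[s]
                       * (template
                          + y * config.gmv_disease_shift * gmv_mask
                          + subject_field)
                       + site_gmv_offset[s]
                       + rng.normal(0.0, config.gmv_noise_sd, size=dims))
                sid = f"sub-s{s:02d}n{len(records):04d}"
                records.append(SubjectRecord(subject_id=sid, site_id=s,
                                             label=y, ts=x, gmv=vol))
                ts_list.append(x)
                gmv_list.append(vol)
                labels_list.append(y)
                sites_list.append(s)

    labels = np.array(labels_list, dtype=np.int64)
    sites = np.array(sites_list, dtype=np.int64)
    cohort = CohortArrays(records=records, ts=ts_list,
                          gmv=np.stack(gmv_list), labels=labels, sites=sites,
                          n_sites=S, parcel_map=parcel_map)
    truth = GroundTruth(site_ts_offset=site_ts_offset,
                        site_ts_gain=site_ts_gain,
                        site_gmv_offset=site_gmv_offset,
                        site_gmv_gain=site_gmv_gain,
                        affected_regions=tuple(config.affected_regions),
                        labels=labels, sites=sites, parcel_map=parcel_map,
                        gmv_template=template)
    return cohort, truth


def site_separability_probe(features: np.ndarray, site_ids: np.ndarray
                            ) -> float:
    """Mean silhouette coefficient of site clusters in a feature space.

    Values near (or below) zero mean sites are intermingled; values near one
    mean strong site structure.  Sites represented by a single sample are
    excluded with a warning.
    """
    features = np.asarray(features, dtype=np.float64)
    site_ids = np.asarray(site_ids)
    uniq, counts = np.unique(site_ids, return_counts=True)
    singletons = uniq[counts < 2]
    if singletons.size:
        warnings.warn(f"excluding {singletons.size} single-sample site(s) "
                      "from the silhouette probe", stacklevel=2)
        keep = ~np.isin(site_ids, singletons)
        features, site_ids = features[keep], site_ids[keep]
    if np.unique(site_ids).size < 2:
        raise ValueError("need at least two multi-sample sites")
    return float(silhouette_score(features, site_ids))
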