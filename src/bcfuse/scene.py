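"""Synthetic urban pollution scenes: ground truth plus realistic sampling.

A scene is a gridded street network over a small planar domain, a set of
point-like emission sources, and a sensor network.  Each source carries a
non-negative pollutant signature, an exponential spatial decay kernel, a
weekday/weekend diurnal profile and lognormal day-to-day strengths, so the
truth cube

    conc(i, j, n) = background_i
                    + Σ_src signature[src, i] · exp(−d(j, src)/L_src)
                      · diurnal[src](n) · day_strength[src, day(n)]

is an exact sum of separable non-negative terms: its pollutant × location
and location × time unfoldings have non-negative rank equal to the number
of sources (plus one when a background is present), which is what makes
exact-recovery tests possible.

Sampling emulates the two real-world instruments: drive-by 1-Hz points with
multiplicative lognormal noise and deliberately uneven per-segment visit
counts (so the ≥15-visit filter has work to do), and fixed-site BC series
with per-bin lognormal noise, an additive noise floor that can push raw
readings negative, and injected missing intervals.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from bcfuse.mobile import RoadSegment
from bcfuse.sensors import SensorMatrix

__all__ = [
    "SourceSpec",
    "SceneConfig",
    "SyntheticScene",
    "generate_truth",
    "sample_mobile",
    "sample_sensors",
    "sample_sensor_matrix",
]

_POLLUTANT_NAMES = [
    "bc", "no", "no2", "ufp",
    "pn_0.3_0.5", "pn_0.5_1", "pn_1_2.5", "pn_2.5_5", "pn_5_10", "co2",
]


@dataclass(frozen=True)
class SourceSpec:
    """One emission source: where it sits, what it emits, when it runs."""

    position: tuple[float, float]
    pollutant_signature: np.ndarray  # length p, >= 0, not all zero
    diurnal_weekday: np.ndarray  # one value per bin-of-day, >= 0
    diurnal_weekend: np.ndarray
    day_strengths: np.ndarray  # one multiplier per campaign day
    decay_length: float  # meters

    def __post_init__(self) -> None:
        if not (self.pollutant_signature >= 0).all() or not self.pollutant_signature.any():
            raise ValueError("pollutant signature must be non-negative and not all zero")
        if (self.diurnal_weekday < 0).any() or (self.diurnal_weekend < 0).any():
            raise ValueError("diurnal profiles must be non-negative")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for a synthetic campaign.

    The default scene is a deliberately desk-scale analogue of a dense
    urban campaign: 400 thirty-meter segments on a 600 m grid, 60 sensor
    sites, 10 days of 15-min bins (960 bins), 6 pollutants sharing 4 latent
    sources, 10% multiplicative noise on both samplers.  ``campaign_scale()``
    returns the full-size shape analogue (~4400 locations × 9600 bins).
    """

    n_pollutants: int = 6
    n_streets: int = 10  # streets per axis; 30 m segments along each
    street_length: float = 600.0
    segment_length: float = 30.0
    n_sites: int = 60
    n_sources: int = 4
    background_level: float = 0.15  # fraction of a typical source signature
    source_strength_sigma: float = 0.4  # lognormal spread of source totals; 0 = equal
    signature_alpha: float = 1.2  # Dirichlet concentration of signatures; <1 = sparse/distinct
    decay_length_range: tuple[float, float] = (120.0, 260.0)
    days: int = 10
    bin_width: int = 15
    start: str = "2017-05-19"
    day_strength_sigma: float = 0.3
    mobile_noise_cv: float = 0.10  # lognormal CV on 1-Hz mobile points
    sensor_noise_cv: float = 0.10  # lognormal CV per sensor bin
    sensor_floor_sd: float = 0.15  # additive µg/m³ noise floor per raw sample
    sensor_missing_fraction: float = 0.05
    # mobile schedule
    n_vehicles: int = 2
    drive_window: tuple[int, int] = (9, 16)  # local hours
    dwell_s: int = 4  # seconds (= 1-Hz points) per segment visit
    drive_weekdays_only: bool = True
    drive_day_fraction: float = 1.0  # fraction of eligible days actually driven
    low_coverage_fraction: float = 0.1  # segments visited too rarely to keep
    low_coverage_weight: float = 0.02
    transient_source: bool = False  # model-violating roaming source

    @property
    def n_bins_per_day(self) -> int:
        return 1440 // self.bin_width

    @property
    def n_bins(self) -> int:
        return self.days * self.n_bins_per_day

    @property
    def pollutants(self) -> list[str]:
        if not 2 <= self.n_pollutants <= len(_POLLUTANT_NAMES):
            raise ValueError(f"n_pollutants must be in [2, {len(_POLLUTANT_NAMES)}]")
        return _POLLUTANT_NAMES[: self.n_pollutants]

    @classmethod
    def campaign_scale(cls) -> "SceneConfig":
        # 36 streets × 60 segments × 2 axes = 4320 segments, + 97 sites and
        # 100 days × 96 bins: the shape of a full-size urban campaign
        return cls(
            n_pollutants=10,
            n_streets=36,
            street_length=1800.0,
            n_sites=97,
            days=100,
            n_sources=6,
        )


@dataclass
class SyntheticScene:
    """Ground truth cube plus the geometry and processes used to sample it."""

    config: SceneConfig
    seed: int
    segments: list[RoadSegment]
    segment_coords: np.ndarray  # (n_segments, 2) midpoints
    sites: pd.DataFrame  # site_id, x, y, nearest_segment_id
    sources: list[SourceSpec]
    background: np.ndarray  # per pollutant
    truth: np.ndarray  # p × l × t over segments-then-sites locations
    time_bins: pd.DatetimeIndex

    @property
    def pollutants(self) -> list[str]:
        return self.config.pollutants

    @property
    def segment_ids(self) -> list[str]:
        return [s.segment_id for s in self.segments]

    @property
    def location_ids(self) -> list[str]:
        return self.segment_ids + list(self.sites["site_id"])

    @property
    def location_coords(self) -> np.ndarray:
        return np.vstack([self.segment_coords, self.sites[["x", "y"]].to_numpy()])

    @property
    def bc_index(self) -> int:
        return self.pollutants.index("bc")

    @property
    def bc_truth(self) -> np.ndarray:
        """True BC field, locations × time."""
        return self.truth[self.bc_index]

    @property
    def latent_rank(self) -> int:
        return len(self.sources) + int(self.background.any())

    def map_truth(self) -> np.ndarray:
        """Time-averaged pollutant × location matrix (the noiseless X_M)."""
        return self.truth.mean(axis=2)

    def true_factors(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Exact (H_L, W_S, H_T) spanning the BC truth — the oracle factors.

        H_L rows are the source spatial kernels (plus a flat background
        row); H_T rows are the matching BC-scaled time signals; W_S is
        Φ H_Lᵀ, the spatial patterns read at the sensor sites.
        """
        cfg = self.config
        l = len(self.location_ids)
        spatial = np.empty((self.latent_rank, l))
        temporal = np.empty((self.latent_rank, cfg.n_bins))
        bc = self.bc_index
        for r, src in enumerate(self.sources):
            d = np.linalg.norm(self.location_coords - np.asarray(src.position), axis=1)
            spatial[r] = np.exp(-d / src.decay_length)
            temporal[r] = src.pollutant_signature[bc] * _source_signal(src, self.time_bins, cfg)
        if self.background.any():
            spatial[-1] = 1.0
            temporal[-1] = self.background[bc]
        n_seg = len(self.segments)
        site_idx = n_seg + np.arange(len(self.sites))
        W_S = spatial[:, site_idx].T
        return spatial, W_S, temporal


def _source_signal(src: SourceSpec, time_bins: pd.DatetimeIndex, cfg: SceneConfig) -> np.ndarray:
    """diurnal(bin-of-day, day type) × day_strength(day) for every bin."""
    day = ((time_bins - time_bins[0]) / pd.Timedelta(days=1)).astype(int)
    bod = (time_bins.hour * 60 + time_bins.minute) // cfg.bin_width
    weekend = time_bins.dayofweek >= 5
    prof = np.where(weekend, src.diurnal_weekend[bod], src.diurnal_weekday[bod])
    return prof * src.day_strengths[day]


def _grid_segments(cfg: SceneConfig) -> tuple[list[RoadSegment], np.ndarray]:
    """A square grid of streets cut into fixed-length segments."""
    per_street = int(round(cfg.street_length / cfg.segment_length))
    xs = np.linspace(0.0, cfg.street_length, cfg.n_streets)
    segments: list[RoadSegment] = []
    coords = []
    i = 0
    for y in xs:  # horizontal streets
        for j in range(per_street):
            a, b = j * cfg.segment_length, (j + 1) * cfg.segment_length
            segments.append(RoadSegment(f"seg-{i:05d}", LineString([(a, y), (b, y)])))
            coords.append(((a + b) / 2, y))
            i += 1
    for x in xs:  # vertical streets
        for j in range(per_street):
            a, b = j * cfg.segment_length, (j + 1) * cfg.segment_length
            segments.append(RoadSegment(f"seg-{i:05d}", LineString([(x, a), (x, b)])))
            coords.append((x, (a + b) / 2))
            i += 1
    return segments, np.asarray(coords)


def _diurnal(rng: np.random.Generator, n_bins_per_day: int, peaks: int = 2) -> np.ndarray:
    """Smooth positive profile: baseline plus Gaussian bumps at random hours."""
    h = np.arange(n_bins_per_day) * 24.0 / n_bins_per_day
    prof = np.full(n_bins_per_day, 0.3)
    for _ in range(peaks):
        center = rng.uniform(5.0, 21.0)
        width = rng.uniform(1.5, 4.0)
        amp = rng.uniform(0.8, 2.0)
        prof += amp * np.exp(-0.5 * ((h - center) / width) ** 2)
    return prof


def generate_truth(config: SceneConfig | None = None, seed: int = 0) -> SyntheticScene:
    """Build a scene: geometry, sources, sensor network, and the truth cube."""
    cfg = config or SceneConfig()
    if cfg.n_sources < 1:
        raise ValueError("need at least one source")
    if cfg.n_pollutants < 2 or cfg.days < 1:
        raise ValueError("need p >= 2 and days >= 1")
    rng = np.random.default_rng(seed)
    p = cfg.n_pollutants
    segments, seg_coords = _grid_segments(cfg)

    # sensor sites: distinct segments, jittered off the midpoint but within 30 m
    if cfg.n_sites > len(segments):
        raise ValueError("more sites than segments")
    site_seg = rng.choice(len(segments), size=cfg.n_sites, replace=False)
    theta = rng.uniform(0, 2 * np.pi, cfg.n_sites)
    radius = rng.uniform(3.0, 20.0, cfg.n_sites)
    site_xy = seg_coords[site_seg] + np.c_[radius * np.cos(theta), radius * np.sin(theta)]
    sites = pd.DataFrame(
        {
            "site_id": [f"site-{i:03d}" for i in range(cfg.n_sites)],
            "x": site_xy[:, 0],
            "y": site_xy[:, 1],
            "nearest_segment_id": [segments[j].segment_id for j in site_seg],
        }
    )

    # sources: spread positions (stratified over domain quadrants), distinct signatures
    n_bpd = cfg.n_bins_per_day
    sources = []
    cells = int(np.ceil(np.sqrt(cfg.n_sources)))
    cell_w = cfg.street_length / cells
    order = rng.permutation(cells * cells)[: cfg.n_sources]
    for idx in order:
        cx, cy = (idx % cells) * cell_w, (idx // cells) * cell_w
        pos = (cx + rng.uniform(0.2, 0.8) * cell_w, cy + rng.uniform(0.2, 0.8) * cell_w)
        sig = rng.gamma(shape=cfg.signature_alpha, scale=1.0, size=p)
        sig[sig < 0.05] = 0.05
        sig *= rng.lognormal(0.0, cfg.source_strength_sigma) / sig.sum() * p
        wk = _diurnal(rng, n_bpd)
        we = 0.3 * wk + 0.7 * _diurnal(rng, n_bpd, peaks=1)
        sources.append(
            SourceSpec(
                position=pos,
                pollutant_signature=sig,
                diurnal_weekday=wk,
                diurnal_weekend=we,
                day_strengths=rng.lognormal(0.0, cfg.day_strength_sigma, cfg.days),
                decay_length=rng.uniform(*cfg.decay_length_range),
            )
        )

    background = cfg.background_level * np.mean([s.pollutant_signature for s in sources], axis=0)
    time_bins = pd.date_range(cfg.start, periods=cfg.n_bins, freq=f"{cfg.bin_width}min")
    coords = np.vstack([seg_coords, site_xy])
    l = len(coords)

    truth = np.broadcast_to(background[:, None, None], (p, l, cfg.n_bins)).copy()
    spatial_k = np.stack(
        [
            np.exp(-np.linalg.norm(coords - np.asarray(s.position), axis=1) / s.decay_length)
            for s in sources
        ]
    )  # r × l
    signal_k = np.stack([_source_signal(s, time_bins, cfg) for s in sources])  # r × t
    sig_k = np.stack([s.pollutant_signature for s in sources])  # r × p
    for pi in range(p):
        truth[pi] += (spatial_k.T * sig_k[:, pi]) @ signal_k

    if cfg.transient_source:
        # roaming transient: violates the separable-pattern assumption on purpose
        sig = rng.gamma(1.2, 1.0, p)
        for day in range(cfg.days):
            pos = rng.uniform(0, cfg.street_length, 2)
            d = np.linalg.norm(coords - pos, axis=1)
            spatial = np.exp(-d / 100.0)
            tsl = slice(day * n_bpd, (day + 1) * n_bpd)
            pulse = np.exp(-0.5 * ((np.arange(n_bpd) - rng.integers(n_bpd)) / 4.0) ** 2)
            truth[:, :, tsl] += 0.5 * np.einsum("i,j,n->ijn", sig, spatial, pulse)

    return SyntheticScene(
        config=cfg,
        seed=seed,
        segments=segments,
        segment_coords=seg_coords,
        sites=sites,
        sources=sources,
        background=background,
        truth=truth,
        time_bins=time_bins,
    )


def _drive_days(scene: SyntheticScene, rng: np.random.Generator) -> np.ndarray:
    cfg = scene.config
    days = np.arange(cfg.days)
    dow = (scene.time_bins[:: cfg.n_bins_per_day].dayofweek).to_numpy()
    eligible = days[dow < 5] if cfg.drive_weekdays_only else days
    if eligible.size == 0:
        raise ValueError("drive schedule excludes every campaign day")
    n_drive = max(1, int(round(cfg.drive_day_fraction * eligible.size)))
    return np.sort(rng.choice(eligible, size=n_drive, replace=False))


def sample_mobile(
    scene: SyntheticScene,
    seed: int = 0,
    *,
    drive_days: np.ndarray | None = None,
    vehicle_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Simulate 1-Hz drive logs over the scene's street grid.

    Vehicles drive spatially coherent routes: each 15-min block the vehicle
    works a local neighborhood (a random seed segment plus its nearest
    neighbors) before moving on, emitting ``dwell_s`` one-per-second points
    per segment visit, positioned along the segment.  Values are truth at
    (pollutant, segment, bin) times multiplicative lognormal noise.  A
    configurable fraction of segments is visited with much lower
    probability, so some end up under the 15-visit filter, as in real
    drive campaigns where side streets get few passes.

    Returns a drive-log frame: timestamp, vehicle_id, x, y, one column per
    pollutant.
    """
    cfg = scene.config
    rng = np.random.default_rng(seed)
    if drive_days is None:
        drive_days = _drive_days(scene, rng)
    else:
        drive_days = np.asarray(drive_days, dtype=int)
        if drive_days.size == 0 or drive_days.min() < 0 or drive_days.max() >= cfg.days:
            raise ValueError(f"drive schedule outside the {cfg.days}-day campaign")
    if vehicle_ids is None:
        vehicle_ids = [f"car-{chr(97 + i)}" for i in range(cfg.n_vehicles)]
    n_seg = len(scene.segments)
    n_low = int(round(cfg.low_coverage_fraction * n_seg))
    low = rng.choice(n_seg, size=n_low, replace=False)
    weights = np.ones(n_seg)
    weights[low] = cfg.low_coverage_weight
    weights /= weights.sum()

    start_ts = scene.time_bins[0]
    h0, h1 = cfg.drive_window
    window_s = (h1 - h0) * 3600
    sigma = np.sqrt(np.log(1 + cfg.mobile_noise_cv**2))

    # neighborhoods: each block of the drive the vehicle works one seed
    # segment's nearest neighbors, giving spatially coherent 15-min windows
    from scipy.spatial import cKDTree

    tree = cKDTree(scene.segment_coords)
    hood_size = min(40, n_seg)
    block_s = cfg.bin_width * 60
    visits_per_block = block_s // cfg.dwell_s
    n_blocks = window_s // block_s

    def day_route(rng: np.random.Generator) -> np.ndarray:
        seeds = rng.choice(n_seg, size=n_blocks, p=weights)
        segs = np.empty(n_blocks * visits_per_block, dtype=int)
        for bi, sd in enumerate(seeds):
            _, hood = tree.query(scene.segment_coords[sd], k=hood_size)
            w = weights[hood] / weights[hood].sum()
            segs[bi * visits_per_block : (bi + 1) * visits_per_block] = rng.choice(
                hood, size=visits_per_block, p=w
            )
        return segs

    # pre-compute segment endpoints for positioning
    ends = np.array([np.asarray(s.geometry.coords)[[0, -1]] for s in scene.segments])
    frames = []
    sec_per_bin = cfg.bin_width * 60
    n_visits = n_blocks * visits_per_block
    for day in drive_days:
        for veh in vehicle_ids:
            segs = day_route(rng)
            t_visit = day * 86400 + h0 * 3600 + np.arange(n_visits) * cfg.dwell_s
            seg_rep = np.repeat(segs, cfg.dwell_s)
            t_sec = np.repeat(t_visit, cfg.dwell_s) + np.tile(np.arange(cfg.dwell_s), n_visits)
            frac = (np.tile(np.arange(cfg.dwell_s), n_visits) + 0.5) / cfg.dwell_s
            a, b = ends[seg_rep, 0], ends[seg_rep, 1]
            xy = a + frac[:, None] * (b - a)
            bins = t_sec // sec_per_bin
            base = scene.truth[:, seg_rep, bins]  # p × npts
            noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=base.shape))
            conc = base * noise
            frame = pd.DataFrame(
                {
                    "timestamp": start_ts + pd.to_timedelta(t_sec, unit="s"),
                    "vehicle_id": veh,
                    "x": xy[:, 0],
                    "y": xy[:, 1],
                }
            )
            for pi, pol in enumerate(scene.pollutants):
                frame[pol] = conc[pi]
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def sample_sensors(
    scene: SyntheticScene,
    seed: int = 0,
    *,
    sample_interval_s: float = 60.0,
) -> pd.DataFrame:
    """Simulate raw fixed-site BC series (long format: site_id, timestamp,
    bc_ugm3).

    Each bin draws one lognormal multiplier per (site, bin) — sensor noise
    acts at the averaging scale — and every raw sample inside the bin adds
    an independent Gaussian noise floor, which can push readings negative
    exactly as low-cost optical instruments do.  Missing intervals are
    injected per (site, bin) at the configured rate.
    """
    cfg = scene.config
    rng = np.random.default_rng(seed)
    n_sites = len(scene.sites)
    n_seg = len(scene.segments)
    site_truth = scene.bc_truth[n_seg:]  # sites × t
    sigma = np.sqrt(np.log(1 + cfg.sensor_noise_cv**2))
    bin_mult = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=site_truth.shape))
    bin_vals = site_truth * bin_mult
    missing = rng.random(site_truth.shape) < cfg.sensor_missing_fraction

    per_bin = int(cfg.bin_width * 60 / sample_interval_s)
    t_bins = np.arange(scene.config.n_bins)
    frames = []
    for i, sid in enumerate(scene.sites["site_id"]):
        keep_bins = t_bins[~missing[i]]
        offs = np.arange(per_bin) * sample_interval_s
        t_sec = (keep_bins[:, None] * cfg.bin_width * 60 + offs[None, :]).ravel()
        vals = np.repeat(bin_vals[i, keep_bins], per_bin)
        vals = vals + rng.normal(0.0, cfg.sensor_floor_sd, size=vals.shape)
        frames.append(
            pd.DataFrame(
                {
                    "site_id": sid,
                    "timestamp": scene.time_bins[0] + pd.to_timedelta(t_sec, unit="s"),
                    "bc_ugm3": vals,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def sample_sensor_matrix(scene: SyntheticScene, seed: int = 0) -> SensorMatrix:
    """Directly binned sensor matrix (no gaps): truth at the sites times
    per-bin lognormal noise plus a small bin-averaged noise floor, clipped
    at zero.  The fast path for experiments that do not exercise the raw
    binning/imputation plumbing.
    """
    cfg = scene.config
    rng = np.random.default_rng(seed)
    n_seg = len(scene.segments)
    site_truth = scene.bc_truth[n_seg:]
    sigma = np.sqrt(np.log(1 + cfg.sensor_noise_cv**2))
    mult = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=site_truth.shape))
    per_bin = cfg.bin_width * 60 / 2.0  # native 0.5 Hz samples per bin
    floor = rng.normal(0.0, cfg.sensor_floor_sd / np.sqrt(per_bin), size=site_truth.shape)
    values = np.clip(site_truth * mult + floor, 0.0, None)
    return SensorMatrix(
        sites=list(scene.sites["site_id"]),
        time_bins=scene.time_bins,
        bin_width=cfg.bin_width,
        values=values,
        observed_mask=np.ones(values.shape, dtype=bool),
        imputed_fraction=np.zeros(len(scene.sites)),
    )
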