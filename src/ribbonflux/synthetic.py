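"""Synthetic data with known ground truth for every pipeline stage.

Three generators stand in for live-cell recordings:

* **FCS/FCCS photon traces** — Brownian dynamics of point emitters in a
  periodic box, detected through a 3D Gaussian confocal volume with
  Poisson photon statistics, optional triplet blinking, two spectral
  channels and green-into-red crosstalk.  Co-labelled species (positive
  brightness in both channels) produce genuine cross-correlation.
* **FRAP recovery curves** — a single-exponential recovery with an
  immobile fraction and additive Gaussian noise.
* **TIRF movies** — a fluorescent footprint with ribbon puncta, planted
  vesicle-fusion hotspots (radial distances peaking ~0.4 um from ribbon
  centres, double-exponential decay) and clathrin accumulation/loss
  regions (~0.8 um, onset within one frame of the stimulus, recovery
  over 10-20 s), blurred by a Gaussian PSF and corrupted by Poisson plus
  Gaussian read noise.

All randomness flows through explicit integer seeds; identical seeds
yield bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .correlation import IntensityTrace
from .frap import FrapTrace
from .geometry import RibbonMap
from .tirf import TirfMovie

__all__ = [
    "SpeciesSpec", "BeamGeometry", "FcsSimConfig", "FcsGroundTruth",
    "simulate_fcs_trace",
    "simulate_frap_trace",
    "FusionEventSpec", "ClathrinEventSpec", "MovieSimConfig",
    "MovieEventTruth", "MovieGroundTruth", "simulate_tirf_movie",
]


# ---------------------------------------------------------------------------
# FCS / FCCS


@dataclass(frozen=True)
class SpeciesSpec:
    """One diffusing labelled species.

    ``n_mean`` is the expected number of molecules in the effective
    detection volume ``V_eff = pi^(3/2) r0^2 z`` (so the autocorrelation
    amplitude is 1/n_mean under the apparent-N convention); ``D`` in
    um^2/s; brightnesses are mean counts per molecule per bin at the beam
    centre.  A species bright in both channels co-diffuses and therefore
    cross-correlates.
    """

    n_mean: float
    D: float
    brightness_g: float = 0.0
    brightness_r: float = 0.0
    triplet_fraction: float = 0.0
    triplet_tau: float | None = None

    def __post_init__(self) -> None:
        if self.n_mean <= 0 or self.D <= 0:
            raise ValueError("n_mean and D must be positive")
        if self.brightness_g < 0 or self.brightness_r < 0:
            raise ValueError("brightnesses must be >= 0")
        if self.brightness_g == 0 and self.brightness_r == 0:
            raise ValueError("at least one channel brightness must be positive")
        if not (0 <= self.triplet_fraction < 1):
            raise ValueError("triplet fraction must lie in [0, 1)")
        if self.triplet_fraction > 0 and (self.triplet_tau is None
                                          or self.triplet_tau <= 0):
            raise ValueError("triplet_fraction > 0 requires triplet_tau > 0")


@dataclass(frozen=True)
class BeamGeometry:
    """Confocal detection volume: lateral and axial 1/e^2 radii in um."""

    r0: float = 0.2
    z: float = 1.0

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.z <= 0:
            raise ValueError("beam radii must be positive")

    @property
    def v_eff(self) -> float:
        return float(np.pi**1.5 * self.r0**2 * self.z)


@dataclass(frozen=True)
class FcsSimConfig:
    """Brownian-dynamics photon-trace simulation settings.

    ``dt`` is the correlator bin width in seconds (instrument hardware
    bins at sub-us; desk-scale runs coarsen it to us-ms, which leaves the
    correlation shape at lags >> dt unchanged); ``box_half_widths`` are
    per-axis half-widths of the periodic box (>= 3x the beam radii);
    ``crosstalk_q`` is the fraction of the green molecular signal leaking
    into the red channel; ``background`` is a per-channel count rate per
    bin.
    """

    species: tuple[SpeciesSpec, ...]
    beam: BeamGeometry = BeamGeometry()
    box_half_widths: tuple[float, float, float] = (0.6, 0.6, 3.0)
    dt: float = 1e-3
    duration: float = 20.0
    crosstalk_q: float = 0.0
    background: tuple[float, float] = (0.0, 0.0)
    seed: int = 0
    allow_empty: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        if not (0 <= self.crosstalk_q < 1):
            raise ValueError("crosstalk_q must lie in [0, 1)")
        if any(b < 0 for b in self.background):
            raise ValueError("background rates must be >= 0")
        hw = self.box_half_widths
        if len(hw) != 3 or any(h <= 0 for h in hw):
            raise ValueError("box_half_widths must be three positive numbers")
        tol = 1 - 1e-9
        if hw[0] < 3 * self.beam.r0 * tol or hw[1] < 3 * self.beam.r0 * tol \
                or hw[2] < 3 * self.beam.z * tol:
            raise ValueError("box half-widths must be >= 3x the beam radii")
        if not self.species and not any(self.background) \
                and not self.allow_empty:
            raise ValueError("no species and zero background would give an "
                             "all-zero trace; set allow_empty=True to permit")
        slow = max((self.beam.r0**2 / (4 * s.D) for s in self.species),
                   default=0.0)
        if slow > 0 and self.duration < 100 * slow * (1 - 1e-9):
            warnings.warn("duration < 100x the slowest diffusion time; "
                          "correlation estimates will be noisy", stacklevel=2)


@dataclass(frozen=True)
class FcsGroundTruth:
    """Generator truth: per-species parameters as realised in the box."""

    seed: int
    dt: float
    duration: float
    crosstalk_q: float
    r0: float
    z: float
    species_table: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        df = self.species_table.copy()
        for k in ("seed", "dt", "duration", "crosstalk_q", "r0", "z"):
            df[k] = getattr(self, k)
        return df

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "FcsGroundTruth":
        meta = {k: df[k].iloc[0] for k in
                ("seed", "dt", "duration", "crosstalk_q", "r0", "z")}
        table = df.drop(columns=list(meta)).reset_index(drop=True)
        return FcsGroundTruth(seed=int(meta["seed"]), dt=float(meta["dt"]),
                              duration=float(meta["duration"]),
                              crosstalk_q=float(meta["crosstalk_q"]),
                              r0=float(meta["r0"]), z=float(meta["z"]),
                              species_table=table)


def _telegraph_states(rng: np.random.Generator, n_steps: int, n_part: int,
                      T: float, tau_t: float, dt: float) -> np.ndarray:
    """Two-state blinking: 1 = bright, 0 = dark; stationary dark prob T."""
    p_to_dark = -np.expm1(-dt * T / tau_t)
    p_to_bright = -np.expm1(-dt * (1 - T) / tau_t)
    state = (rng.random(n_part) >= T).astype(np.float64)
    out = np.empty((n_steps, n_part))
    u = rng.random((n_steps, n_part))
    for i in range(n_steps):
        flip_dark = (state == 1) & (u[i] < p_to_dark)
        flip_bright = (state == 0) & (u[i] < p_to_bright)
        state = np.where(flip_dark, 0.0, np.where(flip_bright, 1.0, state))
        out[i] = state
    return out


def simulate_fcs_trace(config: FcsSimConfig
                       ) -> tuple[IntensityTrace, IntensityTrace, FcsGroundTruth]:
    """Simulate dual-channel photon-count traces from diffusing emitters.

    Each species contributes ``N = round(c * V_box)`` particles at
    concentration ``c = n_mean / V_eff``; positions take Gaussian steps of
    variance ``2 D dt`` per axis with periodic re-entry at the box faces
    (constant concentration).  The detection weight is
    ``exp(-2(x^2+y^2)/r0^2 - 2 z_ax^2/z^2)``; photon counts per bin are
    Poisson around the deterministic molecular rate plus background, and
    the red channel additionally receives ``crosstalk_q`` times the green
    molecular rate.
    """
    rng = np.random.default_rng(config.seed)
    n_steps = int(round(config.duration / config.dt))
    hw = np.asarray(config.box_half_widths, dtype=float)
    v_box = float(np.prod(2 * hw))
    beam = config.beam

    rate_g = np.zeros(n_steps)
    rate_r = np.zeros(n_steps)
    rows = []
    for spec in config.species:
        c = spec.n_mean / beam.v_eff
        n_part = max(1, int(round(c * v_box)))
        n_eff = n_part * beam.v_eff / v_box
        rows.append({**asdict(spec), "n_particles": n_part, "n_eff": n_eff,
                     "tau_d": beam.r0**2 / (4 * spec.D)})
        pos = rng.uniform(-hw, hw, size=(n_part, 3))
        sigma = np.sqrt(2 * spec.D * config.dt)
        chunk = max(1, int(4e6 / max(n_part, 1)))
        states = None
        done = 0
        while done < n_steps:
            m = min(chunk, n_steps - done)
            disp = rng.normal(0.0, sigma, size=(m, n_part, 3))
            traj = pos[None, :, :] + np.cumsum(disp, axis=0)
            traj = (traj + hw) % (2 * hw) - hw  # periodic re-entry
            pos = traj[-1]
            w = np.exp(-2 * (traj[:, :, 0]**2 + traj[:, :, 1]**2) / beam.r0**2
                       - 2 * traj[:, :, 2]**2 / beam.z**2)
            if spec.triplet_fraction > 0:
                states = _telegraph_states(rng, m, n_part,
                                           spec.triplet_fraction,
                                           spec.triplet_tau, config.dt)
                w = w * states
            tot = w.sum(axis=1)
            rate_g[done:done + m] += spec.brightness_g * tot
            rate_r[done:done + m] += spec.brightness_r * tot
            done += m

    counts_g = rng.poisson(rate_g + config.background[0]).astype(float)
    counts_r = rng.poisson(rate_r + config.crosstalk_q * rate_g
                           + config.background[1]).astype(float)
    truth = FcsGroundTruth(
        seed=config.seed, dt=config.dt, duration=config.duration,
        crosstalk_q=config.crosstalk_q, r0=beam.r0, z=beam.z,
        species_table=pd.DataFrame(rows))
    return (IntensityTrace(counts_g, config.dt, "green"),
            IntensityTrace(counts_r, config.dt, "red"),
            truth)


# ---------------------------------------------------------------------------
# FRAP


def simulate_frap_trace(tau: float, mobile_fraction: float,
                        noise_sigma: float = 0.0, dt: float = 0.1,
                        duration: float = 40.0, seed: int = 0) -> FrapTrace:
    """Synthetic post-bleach recovery: mobile*(1 - e^(-t/tau)) + noise."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if not (0 <= mobile_fraction <= 1):
        raise ValueError("mobile_fraction must lie in [0, 1]")
    if duration < 3 * tau:
        raise ValueError("duration must span at least 3x tau")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + dt / 2, dt)
    f = mobile_fraction * (1 - np.exp(-t / tau))
    if noise_sigma > 0:
        f = f + rng.normal(0.0, noise_sigma, t.size)
    return FrapTrace(t=t, f=f, prebleach_reference=1.0)


# ---------------------------------------------------------------------------
# TIRF movies


@dataclass(frozen=True)
class FusionEventSpec:
    """Vesicle-fusion hotspots: radial offsets from ribbon centres drawn
    around ``radial_mean`` um; double-exponential decay after a fast rise.

    ``amplitude_sd`` is the peak amplitude in multiples of the expected
    per-pixel noise SD at the footprint baseline.
    """

    count: int = 6
    radial_mean: float = 0.4
    radial_sigma: float = 0.05
    amplitude_sd: float = 8.0
    rise_time: float = 0.3
    frac_fast: float = 0.3
    tau_fast: float = 2.5
    tau_slow: float = 13.0


@dataclass(frozen=True)
class ClathrinEventSpec:
    """Clathrin accumulation (positive) and loss (negative) regions.

    Onset is within one frame of stimulus onset (``onset_delay`` s);
    recovery decays over 10-20 s (``decay_tau``).
    """

    count: int = 4
    loss_count: int = 3
    radial_mean: float = 0.8
    radial_sigma: float = 0.05
    amplitude_sd: float = 8.0
    onset_delay: float = 0.0
    rise_time: float = 0.5
    decay_tau: float = 15.0


@dataclass(frozen=True)
class MovieSimConfig:
    """TIRF movie simulation settings (times s, lengths um).

    The footprint is an ellipse of plateau intensity
    ``footprint_intensity`` over a dim surround; ribbons are static
    Gaussian puncta rendered into a separate ribbon-channel image.  Events
    are isotropic Gaussian spots (the evanescent-field axial decay is
    folded into their amplitude) modulated by their class time course.
    Noise is Poisson on the clean rate plus Gaussian read noise.
    """

    shape: tuple[int, int, int] = (250, 96, 96)
    frame_interval: float = 0.1
    pixel_size: float = 0.1
    footprint_intensity: float = 100.0
    surround_intensity: float = 10.0
    footprint_radii: tuple[float, float] | None = None   # um (x, y)
    ribbon_centers: tuple[tuple[float, float], ...] | None = None  # um
    ribbon_amplitude: float = 400.0
    ribbon_sigma: float = 0.1
    stimulus_onset_frame: int = 30
    stimulus_duration: float = 0.5
    fusion: FusionEventSpec = FusionEventSpec()
    clathrin: ClathrinEventSpec = ClathrinEventSpec()
    psf_sigma: float = 0.15
    read_noise_sigma: float = 2.0
    offset: float = 0.0
    min_event_separation: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        frames, h, w = self.shape
        if frames < 2 or h < 8 or w < 8:
            raise ValueError("shape must be (frames >= 2, H >= 8, W >= 8)")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval and pixel_size must be positive")
        if self.stimulus_duration not in (0.5, 3.0) \
                and not (0 < self.stimulus_duration <= 10):
            raise ValueError("stimulus_duration must be a short positive time")
        movie_t = frames * self.frame_interval
        need = (self.stimulus_onset_frame * self.frame_interval
                + self.stimulus_duration + 20.0)
        if movie_t < need:
            raise ValueError("movie must cover stimulus + >= 20 s recovery "
                             f"(need {need:.1f} s, have {movie_t:.1f} s)")

    @property
    def field_um(self) -> tuple[float, float]:
        return (self.shape[2] * self.pixel_size,
                self.shape[1] * self.pixel_size)


@dataclass(frozen=True)
class MovieEventTruth:
    event_id: int
    event_class: str              # fusion | accumulation | loss
    x_um: float
    y_um: float
    ribbon_index: int
    distance_um: float
    amplitude: float              # absolute peak intensity (counts)
    onset_frame: int
    rise_time: float
    tau_fast: float               # single decays store tau in tau_slow
    tau_slow: float
    frac_fast: float


@dataclass(frozen=True)
class MovieGroundTruth:
    seed: int
    events: tuple[MovieEventTruth, ...]
    ribbon_image: np.ndarray
    noise_sd: float               # expected per-pixel SD at footprint plateau

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(e) for e in self.events])

    @staticmethod
    def events_from_frame(df: pd.DataFrame) -> tuple[MovieEventTruth, ...]:
        return tuple(MovieEventTruth(**{k: (int(v) if k in
                                            ("event_id", "ribbon_index",
                                             "onset_frame") else v)
                                        for k, v in row.items()})
                     for row in df.to_dict(orient="records"))


def _gaussian_spot(h: int, w: int, cx_px: float, cy_px: float,
                   sigma_px: float) -> np.ndarray:
    y = np.arange(h)[:, None]
    x = np.arange(w)[None, :]
    return np.exp(-((x - cx_px)**2 + (y - cy_px)**2) / (2 * sigma_px**2))


def _place_events(rng: np.random.Generator, cfg: MovieSimConfig,
                  ribbons: np.ndarray, n: int, radial_mean: float,
                  radial_sigma: float, footprint, taken: list[np.ndarray]
                  ) -> list[tuple[np.ndarray, int, float]]:
    """Sample event centres on rings around ribbons, inside the footprint."""
    placed = []
    for i in range(n):
        rib = i % ribbons.shape[0]
        for _ in range(200):
            r = abs(rng.normal(radial_mean, radial_sigma))
            th = rng.uniform(0, 2 * np.pi)
            pos = ribbons[rib] + r * np.array([np.cos(th), np.sin(th)])
            if not footprint(pos):
                continue
            if any(np.linalg.norm(pos - p) < cfg.min_event_separation
                   for p in taken):
                continue
            break
        else:
            raise ValueError("could not place an event inside the footprint; "
                             "reduce counts or min_event_separation")
        taken.append(pos)
        d = float(np.min(np.linalg.norm(ribbons - pos[None, :], axis=1)))
        placed.append((pos, rib, d))
    return placed


def simulate_tirf_movie(config: MovieSimConfig
                        ) -> tuple[TirfMovie, RibbonMap, MovieGroundTruth]:
    """Render a synthetic TIRF movie with planted, ground-truthed events."""
    rng = np.random.default_rng(config.seed)
    frames, h, w = config.shape
    px = config.pixel_size
    fw, fh = config.field_um
    cx, cy = fw / 2, fh / 2
    rx, ry = config.footprint_radii or (0.42 * fw, 0.42 * fh)

    yy = (np.arange(h)[:, None] + 0.5) * px
    xx = (np.arange(w)[None, :] + 0.5) * px
    ellipse = ((xx - cx) / rx)**2 + ((yy - cy) / ry)**2
    fp_mask = ellipse <= 1.0

    def inside_footprint(pos: np.ndarray) -> bool:
        return ((pos[0] - cx) / rx)**2 + ((pos[1] - cy) / ry)**2 <= 0.8**2

    base = np.where(fp_mask, config.footprint_intensity,
                    config.surround_intensity).astype(float)
    noise_sd = float(np.sqrt(config.footprint_intensity
                             + config.read_noise_sigma**2))

    if config.ribbon_centers is not None:
        ribbons = np.asarray(config.ribbon_centers, dtype=float)
    else:
        ribbons = np.array([[cx - 0.45 * rx, cy - 0.35 * ry],
                            [cx + 0.45 * rx, cy - 0.25 * ry],
                            [cx, cy + 0.40 * ry]])
    for r in ribbons:
        if not inside_footprint(r):
            raise ValueError(f"ribbon centre {tuple(r)} outside the footprint")

    t = np.arange(frames) * config.frame_interval
    onset_t = config.stimulus_onset_frame * config.frame_interval
    sigma_px = config.psf_sigma / px

    def shape_fusion(t0: float, spec: FusionEventSpec) -> np.ndarray:
        rel = np.clip(t - t0, 0, None)
        s = (1 - np.exp(-rel / spec.rise_time)) * (
            spec.frac_fast * np.exp(-rel / spec.tau_fast)
            + (1 - spec.frac_fast) * np.exp(-rel / spec.tau_slow))
        s[t < t0] = 0.0
        m = s.max()
        return s / m if m > 0 else s

    def shape_clathrin(t0: float, spec: ClathrinEventSpec) -> np.ndarray:
        rel = np.clip(t - t0, 0, None)
        s = (1 - np.exp(-rel / spec.rise_time)) * np.exp(-rel / spec.decay_tau)
        s[t < t0] = 0.0
        m = s.max()
        return s / m if m > 0 else s

    clean = np.broadcast_to(base, (frames, h, w)).copy()
    events: list[MovieEventTruth] = []
    taken: list[np.ndarray] = []
    eid = 0

    fus = config.fusion
    for pos, rib, dist in _place_events(rng, config, ribbons, fus.count,
                                        fus.radial_mean, fus.radial_sigma,
                                        inside_footprint, taken):
        t0 = onset_t + rng.uniform(0, config.stimulus_duration)
        amp = fus.amplitude_sd * noise_sd
        spot = _gaussian_spot(h, w, pos[0] / px - 0.5, pos[1] / px - 0.5,
                              sigma_px)
        course = shape_fusion(t0, fus)
        clean += amp * course[:, None, None] * spot[None, :, :]
        events.append(MovieEventTruth(
            event_id=eid, event_class="fusion", x_um=float(pos[0]),
            y_um=float(pos[1]), ribbon_index=rib, distance_um=dist,
            amplitude=amp, onset_frame=int(np.ceil(t0 / config.frame_interval)),
            rise_time=fus.rise_time, tau_fast=fus.tau_fast,
            tau_slow=fus.tau_slow, frac_fast=fus.frac_fast))
        eid += 1

    cla = config.clathrin
    for kind, count, sign in (("accumulation", cla.count, +1),
                              ("loss", cla.loss_count, -1)):
        for pos, rib, dist in _place_events(rng, config, ribbons, count,
                                            cla.radial_mean, cla.radial_sigma,
                                            inside_footprint, taken):
            t0 = onset_t + cla.onset_delay
            amp = cla.amplitude_sd * noise_sd
            spot = _gaussian_spot(h, w, pos[0] / px - 0.5, pos[1] / px - 0.5,
                                  sigma_px)
            course = shape_clathrin(t0, cla)
            clean += sign * amp * course[:, None, None] * spot[None, :, :]
            events.append(MovieEventTruth(
                event_id=eid, event_class=kind, x_um=float(pos[0]),
                y_um=float(pos[1]), ribbon_index=rib, distance_um=dist,
                amplitude=sign * amp,
                onset_frame=int(np.ceil(t0 / config.frame_interval)),
                rise_time=cla.rise_time, tau_fast=np.nan,
                tau_slow=cla.decay_tau, frac_fast=np.nan))
            eid += 1

    np.clip(clean, 1e-6, None, out=clean)
    stack = (rng.poisson(clean).astype(float)
             + rng.normal(0.0, config.read_noise_sigma, clean.shape)
             + config.offset)

    rib_clean = base.copy()
    for r in ribbons:
        rib_clean += config.ribbon_amplitude * _gaussian_spot(
            h, w, r[0] / px - 0.5, r[1] / px - 0.5, config.ribbon_sigma / px)
    ribbon_image = (rng.poisson(rib_clean).astype(float)
                    + rng.normal(0.0, config.read_noise_sigma, rib_clean.shape))

    movie = TirfMovie(stack=stack, frame_interval=config.frame_interval,
                      pixel_size=px,
                      stimulus_onset_frame=config.stimulus_onset_frame,
                      stimulus_duration=config.stimulus_duration)
    rmap = RibbonMap(centers=ribbons,
                     intensities=np.full(len(ribbons),
                                         config.ribbon_amplitude),
                     radii=np.full(len(ribbons), 2 * config.ribbon_sigma))
    truth = MovieGroundTruth(seed=config.seed, events=tuple(events),
                             ribbon_image=ribbon_image, noise_sd=noise_sd)
    return movie, rmap, truth
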