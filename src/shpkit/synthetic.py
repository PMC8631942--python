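"""Synthetic-data generators with known ground truth.

Produces every input the analysis pipeline consumes: equilibrium SPR
isotherms, two-state binding trajectories, sparse two-channel
single-molecule movies, and two-channel microcluster cell images.

Randomness: each generator draws from a single ``numpy`` Generator seeded
as ``default_rng([seed, crc32(artifact_tag)])`` — the splitting rule that
makes artifact streams independent while keeping byte-identical outputs
for a fixed seed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DensityError, InvalidParameterError
from .hmm import BOUND, UNBOUND, Trajectory
from .spr import Isotherm, langmuir

#: the six analyte injection concentrations (nM) used for every isotherm
DEFAULT_CONCENTRATIONS_NM = (20.0, 50.0, 100.0, 200.0, 500.0, 1000.0)

DEFAULT_FRAME_RATE_HZ = 20.0
DEFAULT_N_FRAMES = 2000


@dataclass
class NoiseModel:
    """Additive Gaussian noise, with optional Poisson shot noise."""

    gaussian_sd: float = 0.0
    poisson_scaling: float | None = None

    def apply(self, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = image
        if self.poisson_scaling:
            out = rng.poisson(np.clip(out * self.poisson_scaling, 0, None)) / self.poisson_scaling
        if self.gaussian_sd > 0:
            out = out + rng.normal(0.0, self.gaussian_sd, size=image.shape)
        return np.asarray(out, dtype=float)


@dataclass
class SimConfig:
    """Shared simulation configuration."""

    seed: int = 0
    frame_rate: float = DEFAULT_FRAME_RATE_HZ
    pixel_size_nm: float = 160.0
    image_shape: tuple[int, int] = (64, 64)
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self):
        if self.frame_rate <= 0:
            raise InvalidParameterError("frame_rate must be positive")
        if min(self.image_shape) < 16:
            raise InvalidParameterError("image dimensions must be >= 16 px")

    def rng(self, artifact_tag: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, zlib.crc32(artifact_tag.encode())])

    @property
    def frame_interval(self) -> float:
        return 1.0 / self.frame_rate


@dataclass
class GroundTruth:
    """Generating parameters attached to every synthetic artifact."""

    artifact: str
    params: dict

    def __post_init__(self):
        for key, value in self.params.items():
            if isinstance(value, (int, float)) and not np.isfinite(value):
                raise InvalidParameterError(f"non-finite ground-truth value for {key}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"artifact": self.artifact, "params": _jsonable(self.params)},
                      fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(artifact=doc["artifact"], params=doc["params"])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# SPR isotherms
# ---------------------------------------------------------------------------

def gen_isotherm(
    kd_nM: float,
    r_max: float,
    concentrations_nM=DEFAULT_CONCENTRATIONS_NM,
    noise_sd: float = 0.0,
    seed: int = 0,
    analyte_id: str = "analyte",
    ligand_id: str = "ligand",
) -> tuple[Isotherm, GroundTruth]:
    """Langmuir equilibrium responses with additive Gaussian noise.

    response_i = r_max * C_i / (kd + C_i) + Normal(0, noise_sd^2).
    """
    conc = np.asarray(concentrations_nM, dtype=float)
    if not (kd_nM > 0):
        raise InvalidParameterError("kd must be positive")
    if conc.size < 4 or np.any(conc <= 0):
        raise InvalidParameterError("need >= 4 strictly positive concentrations")
    rng = np.random.default_rng([seed, zlib.crc32(b"isotherm")])
    responses = langmuir(conc, r_max, kd_nM)
    if noise_sd > 0:
        responses = responses + rng.normal(0.0, noise_sd, size=conc.size)
    iso = Isotherm(analyte_id=analyte_id, ligand_id=ligand_id,
                   concentrations_nM=conc, responses=responses)
    gt = GroundTruth("isotherm", {
        "kd_nM": kd_nM, "r_max": r_max, "noise_sd": noise_sd,
        "concentrations_nM": conc.tolist(), "seed": seed,
    })
    return iso, gt


# ---------------------------------------------------------------------------
# two-state telegraph trajectories
# ---------------------------------------------------------------------------

def _sample_telegraph(
    rng: np.random.Generator,
    k_on: float,
    k_off: float,
    duration: float,
    start_state: int | None = None,
):
    """Continuous-time two-state chain over [0, duration].

    Returns (switch_times, states) where states[i] holds on
    [switch_times[i], switch_times[i+1]).  Zero rates make the
    corresponding state absorbing.
    """
    if k_on < 0 or k_off < 0:
        raise InvalidParameterError("rates must be non-negative")
    if start_state is None:
        total = k_on + k_off
        p_bound = k_on / total if total > 0 else 0.0
        state = BOUND if rng.random() < p_bound else UNBOUND
    else:
        state = start_state
    times = [0.0]
    states = [state]
    t = 0.0
    while True:
        rate = k_off if state == BOUND else k_on
        if rate <= 0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            break
        state = UNBOUND if state == BOUND else BOUND
        times.append(t)
        states.append(state)
    return np.asarray(times), np.asarray(states, dtype=np.int8)


def _frame_states(times, states, n_frames: int, frame_interval: float) -> np.ndarray:
    """Majority-occupancy state per camera frame.

    A frame is labeled BOUND when the chain spends more than half of that
    frame interval in the bound state (camera-integration model; biases
    dwell times predictably when rates approach the frame rate).
    """
    edges = np.arange(n_frames + 1) * frame_interval
    bounds = np.concatenate((times, [edges[-1]]))
    occ = np.zeros(n_frames)
    for i in range(len(states)):
        if states[i] != BOUND:
            continue
        a, b = bounds[i], min(bounds[i + 1], edges[-1])
        if b <= a:
            continue
        first = int(a / frame_interval)
        last = min(int(np.ceil(b / frame_interval)), n_frames)
        for f in range(first, last):
            lo = max(a, edges[f])
            hi = min(b, edges[f + 1])
            if hi > lo:
                occ[f] += hi - lo
    return (occ > 0.5 * frame_interval).astype(np.int8)


def gen_trajectory(
    k_on_eff: float,
    k_off: float,
    mu_unbound: float,
    mu_bound: float,
    sigma: float,
    duration_s: float,
    config: SimConfig,
    bleach_rate: float | None = None,
    molecule_id: str = "mol0",
    rng: np.random.Generator | None = None,
) -> tuple[Trajectory, GroundTruth]:
    """Two-state telegraph intensity trajectory with Gaussian emission noise.

    The continuous-time chain is integrated within each frame and the frame
    takes the majority state.  Optional photobleaching terminates the bound
    fluorophore after an exponential cumulative-bound lifetime
    (1/bleach_rate); bleached frames emit at the unbound level.
    """
    if mu_bound <= mu_unbound:
        raise InvalidParameterError("mu_bound must exceed mu_unbound")
    if k_on_eff < 0 or k_off < 0:
        raise InvalidParameterError("rates must be non-negative")
    n_frames = int(round(duration_s * config.frame_rate))
    if n_frames < 10:
        raise InvalidParameterError("duration * frame_rate must be >= 10 frames")
    if rng is None:
        rng = config.rng(f"trajectory/{molecule_id}")

    times, states = _sample_telegraph(rng, k_on_eff, k_off, duration_s)
    frame_states = _frame_states(times, states, n_frames, config.frame_interval)

    bleach_frame = None
    if bleach_rate is not None and bleach_rate > 0:
        bleach_budget = rng.exponential(1.0 / bleach_rate)
        cum_bound = np.cumsum(frame_states) * config.frame_interval
        over = np.flatnonzero(cum_bound >= bleach_budget)
        if over.size:
            bleach_frame = int(over[0])
            frame_states = frame_states.copy()
            frame_states[bleach_frame:] = UNBOUND

    emission = np.where(frame_states == BOUND, mu_bound, mu_unbound).astype(float)
    if sigma > 0:
        emission = emission + rng.normal(0.0, sigma, size=n_frames)

    traj = Trajectory(intensities=emission,
                      frame_interval=config.frame_interval,
                      molecule_id=molecule_id)
    gt = GroundTruth("trajectory", {
        "k_on_eff": k_on_eff, "k_off": k_off,
        "mu_unbound": mu_unbound, "mu_bound": mu_bound, "sigma": sigma,
        "duration_s": duration_s, "states": frame_states,
        "bleach_frame": bleach_frame, "seed": config.seed,
    })
    return traj, gt


# ---------------------------------------------------------------------------
# two-channel single-molecule movies
# ---------------------------------------------------------------------------

def _render_spot(image: np.ndarray, x: float, y: float, amplitude: float,
                 sigma: float) -> None:
    """Add a 2-D Gaussian to ``image`` in place (local window for speed)."""
    h, w = image.shape
    r = int(np.ceil(4 * sigma))
    x0, x1 = max(int(x) - r, 0), min(int(x) + r + 1, w)
    y0, y1 = max(int(y) - r, 0), min(int(y) + r + 1, h)
    if x1 <= x0 or y1 <= y0:
        return
    xs = np.arange(x0, x1)
    ys = np.arange(y0, y1)[:, None]
    image[y0:y1, x0:x1] += amplitude * np.exp(
        -((xs - x) ** 2 + (ys - y) ** 2) / (2 * sigma**2))


def _place_spots(rng, n: int, shape, min_dist: float, margin: float,
                 max_attempts: int = 20000) -> np.ndarray:
    h, w = shape
    if w - 1 - 2 * margin <= 0 or h - 1 - 2 * margin <= 0:
        raise DensityError("image too small for the requested margin")
    positions: list[tuple[float, float]] = []
    attempts = 0
    while len(positions) < n:
        attempts += 1
        if attempts > max_attempts:
            raise DensityError(
                f"could not place {n} spots with min distance {min_dist:.1f} px")
        x = rng.uniform(margin, w - 1 - margin)
        y = rng.uniform(margin, h - 1 - margin)
        if all((x - px) ** 2 + (y - py) ** 2 > min_dist**2 for px, py in positions):
            positions.append((x, y))
    return np.asarray(positions)


def gen_two_channel_movie(
    n_receptors: int,
    k_on_eff: float,
    k_off: float,
    config: SimConfig,
    n_frames: int = 100,
    psf_sigma: float = 1.5,
    receptor_amplitude: float = 100.0,
    ligand_amplitude: float = 100.0,
    receptor_bleach_rate: float | None = None,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Sparse static receptor channel plus a blinking ligand channel.

    Receptor spots are constant 2-D Gaussians (optional single-step bleach
    with an exponential lifetime); the ligand channel lights the same
    positions only during the bound intervals of independent per-receptor
    two-state chains.  Returns (receptor_stack, ligand_stack, GroundTruth).
    """
    rng = config.rng("movie")
    h, w = config.image_shape
    min_dist = 4 * psf_sigma
    positions = (_place_spots(rng, n_receptors, (h, w), min_dist, margin=min_dist)
                 if n_receptors else np.zeros((0, 2)))

    duration = n_frames * config.frame_interval
    state_matrix = np.zeros((n_receptors, n_frames), dtype=np.int8)
    for i in range(n_receptors):
        times, states = _sample_telegraph(rng, k_on_eff, k_off, duration)
        state_matrix[i] = _frame_states(times, states, n_frames,
                                        config.frame_interval)

    bleach_frames = np.full(n_receptors, -1, dtype=int)
    if receptor_bleach_rate is not None and receptor_bleach_rate > 0:
        lifetimes = rng.exponential(1.0 / receptor_bleach_rate, size=n_receptors)
        bleach_frames = np.minimum(
            (lifetimes / config.frame_interval).astype(int), n_frames)

    receptor = np.zeros((n_frames, h, w))
    ligand = np.zeros((n_frames, h, w))
    for f in range(n_frames):
        for i, (x, y) in enumerate(positions):
            if bleach_frames[i] < 0 or f < bleach_frames[i]:
                _render_spot(receptor[f], x, y, receptor_amplitude, psf_sigma)
            if state_matrix[i, f] == BOUND:
                _render_spot(ligand[f], x, y, ligand_amplitude, psf_sigma)
        receptor[f] = config.noise.apply(receptor[f], rng)
        ligand[f] = config.noise.apply(ligand[f], rng)

    gt = GroundTruth("movie", {
        "positions": positions, "k_on_eff": k_on_eff, "k_off": k_off,
        "psf_sigma": psf_sigma, "n_frames": n_frames,
        "receptor_amplitude": receptor_amplitude,
        "ligand_amplitude": ligand_amplitude,
        "states": state_matrix, "bleach_frames": bleach_frames,
        "seed": config.seed,
    })
    return receptor, ligand, gt


# ---------------------------------------------------------------------------
# microcluster cell images
# ---------------------------------------------------------------------------

def gen_cluster_image(
    n_clusters: int,
    enrichment: float,
    config: SimConfig,
    footprint_level: float = 20.0,
    effector_background: float = 10.0,
    blob_amplitude: float = 100.0,
    blob_sigma: float = 2.0,
    blob_zone_frac: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """Cell-footprint image pair with co-enriched microclusters.

    Receptor channel: diffuse disk footprint plus bright Gaussian blobs.
    Effector channel: flat background plus ``enrichment`` times the blob
    signal.  Blobs are confined to the central ``blob_zone_frac`` of the
    footprint radius so that rolling-ball estimates near the footprint
    edge do not overlap the clusters.  Returns
    (receptor, effector, footprint_mask, GroundTruth).
    """
    if enrichment < 0:
        raise InvalidParameterError("enrichment must be >= 0")
    rng = config.rng("clusters")
    h, w = config.image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = 0.46 * min(h, w)
    footprint = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2

    # place blobs in the footprint interior
    blob_signal = np.zeros((h, w))
    r_allowed = blob_zone_frac * radius
    min_dist = 7 * blob_sigma  # thresholded blob skirts must not touch
    placed: list[tuple[float, float]] = []
    attempts = 0
    while len(placed) < n_clusters:
        attempts += 1
        if attempts > 20000:
            raise DensityError(f"could not place {n_clusters} clusters")
        x = rng.uniform(cx - r_allowed, cx + r_allowed)
        y = rng.uniform(cy - r_allowed, cy + r_allowed)
        if (x - cx) ** 2 + (y - cy) ** 2 > r_allowed**2:
            continue
        if all((x - px) ** 2 + (y - py) ** 2 > min_dist**2 for px, py in placed):
            placed.append((x, y))
    positions = np.asarray(placed).reshape(-1, 2)
    for x, y in positions:
        _render_spot(blob_signal, x, y, blob_amplitude, blob_sigma)

    receptor = footprint * footprint_level + blob_signal
    effector = effector_background + enrichment * blob_signal
    receptor = config.noise.apply(receptor, rng)
    effector = config.noise.apply(effector, rng)

    gt = GroundTruth("cluster_image", {
        "n_clusters": n_clusters, "enrichment": enrichment,
        "positions": positions, "blob_amplitude": blob_amplitude,
        "blob_sigma": blob_sigma, "footprint_level": footprint_level,
        "effector_background": effector_background, "seed": config.seed,
    })
    return receptor, effector, footprint, gt
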