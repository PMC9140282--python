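"""Synthetic inputs with the statistical structure the pipeline assumes.

No fly recordings or micrographs ship with the package, so every stage is
exercised against generated data whose ground truth is known:

* **Behaviour** — each fly jumps at trial ``t`` with probability
  ``p0 * exp(-lambda_eff * (t-1))`` where ``lambda_eff`` is the genotype's
  response-decay rate scaled by multiplicative testing-day and recording-
  system factors.  Exponential-in-trial decay is the simplest monotone
  habituation model consistent with monotonically waning group curves; it
  is a stand-in, not a mechanistic claim.  The fatigue protocol (50 trials,
  5 s spacing) uses decay 0 by default: the jump response stays high, which
  is the behavioural signature that separates learning from exhaustion.
* **NMJ images** — a smooth random backbone with perpendicular side
  branches is rendered as a tube in the membrane channel; disk-shaped
  boutons along the backbone fill the vesicle channel.  Scenes are sampled
  in micrometre coordinates and rasterised at a requested pixel size, so
  one scene can be rendered at several resolutions.
* **Gene universes** — synthetic identifiers partitioned so each category's
  realised overlap counts (a, b, c, d) equal the planted values exactly.

Every generator is a pure function of its config and seed.  Child seeds
derive from the master seed by the fixed rule ``default_rng([seed, i, j])``
(genotype/fly or scene indices), so any subset regenerates identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import cos, pi, sin
from typing import Mapping, Sequence

import numpy as np
import scipy.ndimage as ndi
from skimage import measure

from .errors import ConfigError, GenerationError
from .nmj_morphometry import MorphometryResult, NmjImage
from .trial_data import FATIGUE, HABITUATION, AmplitudeTrace, FlySession, Protocol

__all__ = [
    "GenotypeParams",
    "BehaviorSimConfig",
    "NmjSimConfig",
    "NmjScene",
    "GeneUniverseConfig",
    "simulate_habituation",
    "simulate_fatigue",
    "sample_scene",
    "render_scene",
    "generate_nmj_image",
    "generate_gene_universe",
]


# ---------------------------------------------------------------------------
# behaviour


@dataclass(frozen=True)
class GenotypeParams:
    """Initial jump probability and per-trial response-decay rate.

    Defaults emulate a control genotype: about two thirds of flies jump to
    the first pulse and the response decays fast enough that the mean TTC
    lands in the low single digits, as healthy controls show.
    """

    p0: float = 0.65
    decay: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= 1.0:
            raise ConfigError("p0 must lie in [0, 1]")
        if self.decay < 0:
            raise ConfigError("decay must be >= 0")


@dataclass
class BehaviorSimConfig:
    """Cohort layout and generative parameters for the jump assay.

    96 flies per genotype reflects the standard triplicate design (three
    testing days of 32 flies, 16 per recording system).  Day and system
    factors multiply the decay rate, mimicking batch effects the linear
    model must absorb.
    """

    genotypes: Mapping[str, GenotypeParams]
    n_flies: int = 96
    protocol: Protocol = HABITUATION
    day_effects: tuple[float, ...] = (1.0, 0.9, 1.1)
    system_effects: tuple[float, ...] = (1.0, 1.15)
    emit_traces: bool = False
    noise_amplitude: float = 0.2
    jump_amplitude: float = 2.0
    sample_rate_hz: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flies < 1:
            raise ConfigError("n_flies must be >= 1")
        if any(f <= 0 for f in self.day_effects + self.system_effects):
            raise ConfigError("day/system factors must be positive")
        if self.noise_amplitude < 0 or self.jump_amplitude <= self.noise_amplitude:
            raise ConfigError("jump_amplitude must exceed noise_amplitude >= 0")


def _jump_probabilities(params: GenotypeParams, lam_scale: float, n_trials: int) -> np.ndarray:
    t = np.arange(n_trials, dtype=float)
    return np.clip(params.p0 * np.exp(-params.decay * lam_scale * t), 0.0, 1.0)


def _synthesize_trace(
    fly_id: str,
    trial_index: int,
    jumped: bool,
    cfg: BehaviorSimConfig,
    rng: np.random.Generator,
) -> AmplitudeTrace:
    n = max(2, int(round(cfg.sample_rate_hz * HABITUATION.record_window_ms / 1000.0)))
    samples = np.abs(rng.normal(0.0, cfg.noise_amplitude / 3.0, size=n))
    if jumped:
        start = rng.integers(0, max(1, n - 10))
        burst = cfg.jump_amplitude * (0.8 + 0.4 * rng.random(min(10, n - start)))
        samples[start : start + burst.size] += burst
    return AmplitudeTrace(fly_id, trial_index, samples, cfg.sample_rate_hz)


def simulate_habituation(
    config: BehaviorSimConfig,
) -> tuple[list[FlySession], list[AmplitudeTrace] | None]:
    """Draw one cohort of fly sessions (and optionally raw traces).

    Flies cycle deterministically through days, systems and chambers; each
    fly's Bernoulli draws come from its own child generator, so the cohort
    is reproducible fly-by-fly from the master seed.
    """
    n_days = len(config.day_effects)
    n_sys = len(config.system_effects)
    sessions: list[FlySession] = []
    traces: list[AmplitudeTrace] | None = [] if config.emit_traces else None
    for g_idx, (genotype, params) in enumerate(config.genotypes.items()):
        for f_idx in range(config.n_flies):
            rng = np.random.default_rng([config.seed, g_idx, f_idx])
            day = f_idx % n_days
            system = (f_idx // n_days) % n_sys
            chamber = 1 + (f_idx // (n_days * n_sys)) % 16
            lam_scale = config.day_effects[day] * config.system_effects[system]
            p = _jump_probabilities(params, lam_scale, config.protocol.n_trials)
            jumps = rng.random(config.protocol.n_trials) < p
            fly_id = f"{genotype}_f{f_idx:03d}"
            sessions.append(
                FlySession(
                    fly_id=fly_id,
                    genotype=genotype,
                    day=f"day{day + 1}",
                    system=f"sys{system + 1}",
                    chamber=chamber,
                    protocol=config.protocol,
                    jumps=tuple(bool(j) for j in jumps),
                )
            )
            if traces is not None:
                for t_idx, j in enumerate(jumps, start=1):
                    traces.append(_synthesize_trace(fly_id, t_idx, bool(j), config, rng))
    return sessions, traces


def simulate_fatigue(
    config: BehaviorSimConfig,
    fatigue_decay: float = 0.0,
) -> list[FlySession]:
    """Fatigue-protocol cohort: 50 trials at 5 s spacing, flat response.

    The 5 s inter-trial interval is too long for habituation, so by default
    the response does not decay (``fatigue_decay=0``) and the per-trial
    jump fraction stays near ``p0`` to the last trial.  A positive
    ``fatigue_decay`` models a genotype whose response genuinely wanes
    under this protocol, i.e. true motor fatigue.
    """
    fat_cfg = BehaviorSimConfig(
        genotypes={
            g: GenotypeParams(p0=p.p0, decay=fatigue_decay)
            for g, p in config.genotypes.items()
        },
        n_flies=config.n_flies,
        protocol=FATIGUE,
        day_effects=config.day_effects,
        system_effects=config.system_effects,
        emit_traces=False,
        noise_amplitude=config.noise_amplitude,
        jump_amplitude=config.jump_amplitude,
        sample_rate_hz=config.sample_rate_hz,
        seed=config.seed,
    )
    sessions, _ = simulate_habituation(fat_cfg)
    return sessions


# ---------------------------------------------------------------------------
# NMJ scenes


@dataclass
class NmjSimConfig:
    """Geometry and rendering parameters of a synthetic NMJ scene.

    Pixel-valued fields are interpreted at ``pixel_size_um`` and converted
    to micrometres when the scene is sampled, so the same configuration
    rendered at a finer pixel size yields the same physical scene.
    """

    shape: tuple[int, int] = (320, 320)
    margin_px: int = 24
    tube_width_px: float = 5.0
    step_px: float = 8.0
    n_backbone_steps: int = 32
    n_side_branches: int = 3
    branch_len_px: float = 40.0
    n_boutons: int = 10
    bouton_radius_px: float = 3.0
    min_bouton_spacing_px: float = 14.0
    pixel_size_um: float = 0.25
    noise_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.shape
        if min(h, w) <= 2 * self.margin_px:
            raise ConfigError("margin leaves no interior")
        if self.tube_width_px <= 0 or self.pixel_size_um <= 0:
            raise ConfigError("tube width and pixel size must be positive")
        if self.n_boutons > 0 and self.min_bouton_spacing_px <= 2 * self.bouton_radius_px:
            raise ConfigError("bouton spacing must exceed the bouton diameter")


@dataclass
class NmjScene:
    """A sampled scene in micrometre coordinates (x, y pairs)."""

    backbone_um: np.ndarray  # (n, 2) polyline vertices
    branches_um: list[np.ndarray] = field(default_factory=list)
    bouton_centers_um: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    tube_width_um: float = 1.25
    bouton_radius_um: float = 0.75

    @property
    def polyline_length_um(self) -> float:
        total = float(np.sum(np.hypot(*np.diff(self.backbone_um, axis=0).T)))
        for br in self.branches_um:
            total += float(np.sum(np.hypot(*np.diff(br, axis=0).T)))
        return total


def sample_scene(config: NmjSimConfig, rng: np.random.Generator | None = None) -> NmjScene:
    """Draw a random branched-tube scene that fits the frame.

    The backbone is a gently curving left-to-right random walk; side
    branches leave perpendicular to the local heading from well-separated
    interior vertices.  Placement is retried a bounded number of times.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h, w = config.shape
    ps = config.pixel_size_um
    margin = config.margin_px
    for _attempt in range(200):
        x = float(margin + 2)
        y = float(h / 2 + rng.uniform(-h / 8, h / 8))
        heading = rng.uniform(-0.15, 0.15)
        verts = [(x, y)]
        ok = True
        for _ in range(config.n_backbone_steps):
            heading = float(np.clip(heading + rng.normal(0, 0.12), -0.45, 0.45))
            x += config.step_px * cos(heading)
            y += config.step_px * sin(heading)
            if not (margin < x < w - margin):
                ok = False
                break
            if not (margin < y < h - margin):
                heading = -heading
                y = float(np.clip(y, margin + 1, h - margin - 1))
            verts.append((x, y))
        if not ok or len(verts) < config.n_backbone_steps + 1:
            continue
        backbone = np.asarray(verts)

        interior = np.arange(3, len(backbone) - 3)
        if config.n_side_branches > 0:
            if len(interior) < 4 * config.n_side_branches:
                raise ConfigError("backbone too short for the requested branches")
            attach = []
            for idx in rng.permutation(interior):
                if all(abs(idx - a) >= 4 for a in attach):
                    attach.append(int(idx))
                if len(attach) == config.n_side_branches:
                    break
            if len(attach) < config.n_side_branches:
                continue
        else:
            attach = []
        branches = []
        feasible = True
        for b_i, idx in enumerate(attach):
            local = backbone[idx + 1] - backbone[idx - 1]
            ang = float(np.arctan2(local[1], local[0]))
            side = 1 if (b_i + rng.integers(0, 2)) % 2 == 0 else -1
            bang = ang + side * (pi / 2 + rng.normal(0, 0.2))
            end = backbone[idx] + config.branch_len_px * np.array([cos(bang), sin(bang)])
            if not (margin < end[0] < w - margin and margin < end[1] < h - margin):
                feasible = False
                break
            branches.append(np.vstack([backbone[idx], end]))
        if not feasible:
            continue

        if config.n_boutons > 0:
            sites: list[np.ndarray] = []
            for idx in rng.permutation(np.arange(1, len(backbone) - 1)):
                cand = backbone[idx]
                if all(
                    np.hypot(*(cand - s)) >= config.min_bouton_spacing_px for s in sites
                ):
                    sites.append(cand)
                if len(sites) == config.n_boutons:
                    break
            if len(sites) < config.n_boutons:
                continue
            bouton_centers = np.asarray(sites)
        else:
            bouton_centers = np.empty((0, 2))

        return NmjScene(
            backbone_um=backbone * ps,
            branches_um=[br * ps for br in branches],
            bouton_centers_um=bouton_centers * ps,
            tube_width_um=config.tube_width_px * ps,
            bouton_radius_um=config.bouton_radius_px * ps,
        )
    raise GenerationError("could not place a feasible scene in 200 attempts")


def _segment_distance_field(
    segments: Sequence[tuple[np.ndarray, np.ndarray]],
    shape: tuple[int, int],
    pixel_size_um: float,
) -> np.ndarray:
    """Min distance (µm) from each pixel centre to a set of line segments."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    px = (xx + 0.5) * pixel_size_um
    py = (yy + 0.5) * pixel_size_um
    dist = np.full(shape, np.inf)
    for p0, p1 in segments:
        d = p1 - p0
        denom = float(d @ d)
        if denom == 0:
            dd = np.hypot(px - p0[0], py - p0[1])
        else:
            t = np.clip(((px - p0[0]) * d[0] + (py - p0[1]) * d[1]) / denom, 0.0, 1.0)
            dd = np.hypot(px - (p0[0] + t * d[0]), py - (p0[1] + t * d[1]))
        np.minimum(dist, dd, out=dist)
    return dist


def render_scene(
    scene: NmjScene,
    pixel_size_um: float,
    shape: tuple[int, int],
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> NmjImage:
    """Rasterise a scene at the requested pixel size.

    Membrane channel: unit intensity inside the tube (pixel centres within
    half the tube width of the polyline).  Vesicle channel: unit-intensity
    disks at the bouton sites.  Gaussian noise is added to both channels
    and clipped at zero.
    """
    segs: list[tuple[np.ndarray, np.ndarray]] = []
    for poly in [scene.backbone_um, *scene.branches_um]:
        for i in range(len(poly) - 1):
            segs.append((poly[i], poly[i + 1]))
    dist = _segment_distance_field(segs, shape, pixel_size_um)
    membrane = (dist <= scene.tube_width_um / 2).astype(float)

    vesicle = np.zeros(shape)
    if len(scene.bouton_centers_um):
        h, w = shape
        yy, xx = np.mgrid[0:h, 0:w]
        px = (xx + 0.5) * pixel_size_um
        py = (yy + 0.5) * pixel_size_um
        for cx, cy in scene.bouton_centers_um:
            vesicle[np.hypot(px - cx, py - cy) <= scene.bouton_radius_um] = 1.0

    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        membrane = np.clip(membrane + rng.normal(0, noise_sigma, shape), 0, None)
        vesicle = np.clip(vesicle + rng.normal(0, noise_sigma, shape), 0, None)
    return NmjImage(membrane, vesicle, pixel_size_um)


def _scene_ground_truth(
    scene: NmjScene, pixel_size_um: float, shape: tuple[int, int]
) -> MorphometryResult:
    clean = render_scene(scene, pixel_size_um, shape, noise_sigma=0.0)
    mask = clean.membrane_channel > 0.5
    area = float(mask.sum()) * pixel_size_um**2
    perim = 0.0
    padded = np.pad(mask.astype(float), 1)
    for contour in measure.find_contours(padded, 0.5):
        perim += float(np.sum(np.hypot(*np.diff(contour, axis=0).T)))
    g = len(scene.branches_um)
    return MorphometryResult(
        boutons=len(scene.bouton_centers_um),
        length_um=scene.polyline_length_um,
        area_um2=area,
        perimeter_um=perim * pixel_size_um,
        branches=2 * g + 1 if g else 1,
        branching_points=g,
    )


def generate_nmj_image(config: NmjSimConfig) -> tuple[NmjImage, MorphometryResult]:
    """Sample and render one synthetic NMJ with its ground-truth metrics.

    Ground truth: bouton count and branch topology from the construction;
    length as the generating polyline length; area and perimeter measured
    on the noiseless rendering.
    """
    rng = np.random.default_rng(config.seed)
    scene = sample_scene(config, rng)
    image = render_scene(
        scene, config.pixel_size_um, config.shape, config.noise_sigma, rng
    )
    truth = _scene_ground_truth(scene, config.pixel_size_um, config.shape)
    return image, truth


# ---------------------------------------------------------------------------
# gene universes


@dataclass
class GeneUniverseConfig:
    """Planted overlap design: universe size d, focal size b, per-category (a, c)."""

    d: int = 2000
    b: int = 43
    categories: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"cat1": (9, 120)}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.b <= self.d:
            raise ConfigError("need 0 < b <= d")
        for name, (a, c) in self.categories.items():
            if not (0 <= a <= min(self.b, c) and c <= self.d and a >= self.b + c - self.d):
                raise ConfigError(
                    f"category {name!r}: infeasible counts a={a}, c={c} "
                    f"for b={self.b}, d={self.d}"
                )


def generate_gene_universe(
    config: GeneUniverseConfig,
) -> tuple[list[str], dict[str, list[str]], list[str]]:
    """Synthetic (focal list, category map, universe list) with exact counts.

    Universe identifiers are ``G000000``-style labels; the focal set is a
    random b-subset and each category draws its planted ``a`` genes from
    the focal set and ``c - a`` from the remainder.
    """
    rng = np.random.default_rng(config.seed)
    universe = [f"G{i:06d}" for i in range(config.d)]
    order = rng.permutation(config.d)
    focal = [universe[i] for i in order[: config.b]]
    non_focal = [universe[i] for i in order[config.b :]]
    category_map: dict[str, list[str]] = {}
    for name, (a, c) in config.categories.items():
        inside = rng.choice(len(focal), size=a, replace=False)
        outside = rng.choice(len(non_focal), size=c - a, replace=False)
        genes = [focal[i] for i in inside] + [non_focal[i] for i in outside]
        category_map[name] = sorted(genes)
    return focal, category_map, universe
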