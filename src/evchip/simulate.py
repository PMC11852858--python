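"""Synthetic study generator with known ground truth.

Emulates the two data streams of the biochip study so that every
downstream stage can be exercised end-to-end without instrument data:

* **Sensorgrams** — per-ROI 1:1 Langmuir-style binding curves:
  ``R(t) = Rmax_spot * (1 - exp(-k_obs * t))`` during the injection and
  exponential dissociation at ``k_off`` afterwards, with per-spot
  amplitude variability, a weak nonspecific response on the
  negative-control spots, optional linear baseline drift and i.i.d.
  Gaussian read noise. Ground truth records the noise-free, drift-free
  end-point response of every ROI evaluated on the same sample grid and
  analysis windows that the extraction stage uses.

* **Topographies** — height images of spherical-cap particles on a
  tilted, rough background plane. A particle with footprint diameter D
  and apex height h is a cap of a sphere of radius
  ``R = D^2/(8h) + h/2``. Caps are placed uniformly at random without
  footprint overlap (rejection sampling). Diameters follow a two-
  component log-normal mixture (small-EV bulk plus a large-EV tail);
  heights follow ``h = alpha * D + eps``. Ground truth lists every
  placed particle's true D, h and centroid.

* **Studies** — paired control/treated bundles (five control and four
  treated sensorgram experiments, plus AFM images per ligand and
  condition) under a named effect scenario; the manifest records every
  programmed effect. The null scenario draws both conditions from
  identical distributions.

All randomness flows from a single integer seed; identical
configurations give bit-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .afm import TopographyImage, write_topography
from .errors import ConfigurationError, PlacementError
from .layout import BiochipLayout, build_layout, default_panel
from .spri import Sensorgram, default_windows, write_sensorgram

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LigandBinding:
    """Binding-curve parameters of one capture ligand."""

    rmax_pct: float  # reflectivity % at saturation
    k_obs_per_min: float = 0.25  # observed association rate
    k_off_per_min: float = 0.0  # dissociation rate after injection

    def __post_init__(self) -> None:
        if self.rmax_pct < 0:
            raise ConfigurationError(f"Rmax must be >= 0, got {self.rmax_pct}")
        if self.k_obs_per_min <= 0:
            raise ConfigurationError(f"k_obs must be > 0, got {self.k_obs_per_min}")
        if self.k_off_per_min < 0:
            raise ConfigurationError(f"k_off must be >= 0, got {self.k_off_per_min}")


@dataclass(frozen=True)
class BindingParams:
    """Per-ligand binding parameters plus chip-wide variability.

    ``spot_cv`` is the fractional spot-to-spot amplitude variability;
    ``nonspecific_rmax_pct`` is the weak amplitude assigned to the
    negative-control spots (and serves as the nonspecific floor).
    """

    ligands: dict[str, LigandBinding]
    spot_cv: float = 0.08
    nonspecific_rmax_pct: float = 0.05
    nonspecific_k_obs_per_min: float = 0.25

    def __post_init__(self) -> None:
        if not (0 <= self.spot_cv < 1):
            raise ConfigurationError(f"spot_cv must be in [0, 1), got {self.spot_cv}")
        if self.nonspecific_rmax_pct < 0:
            raise ConfigurationError("nonspecific response must be >= 0")


@dataclass(frozen=True)
class ParticlePopulation:
    """Two-component log-normal diameter mixture with a linear
    diameter-to-height map.

    The small-EV component dominates; the large-EV component supplies
    the >200 nm tail whose weight differs between conditions. Heights
    are ``alpha * D`` plus Gaussian noise, truncated to stay positive.
    ``density_per_um2`` controls how many particles land on a scan.
    """

    small_median_nm: float = 120.0
    small_log_sd: float = 0.35
    large_median_nm: float = 350.0
    large_log_sd: float = 0.40
    large_weight: float = 0.10
    height_slope: float = 0.12
    height_noise_nm: float = 1.5
    density_per_um2: float = 6.25  # 25 particles on a 2x2 um scan
    #: Field-of-view truncation: diameters above this are redrawn. A
    #: vesicle approaching the scan size cannot sit in a usable field
    #: (two such footprints cannot even coexist on one 2x2 um scan);
    #: the truncated tail mass is < 2% for every population used here.
    max_diameter_nm: float = 900.0

    def __post_init__(self) -> None:
        if not (0 <= self.large_weight <= 1):
            raise ConfigurationError("mixture weight must be in [0, 1]")
        if self.density_per_um2 < 0:
            raise ConfigurationError("density must be >= 0")
        if self.small_median_nm <= 0 or self.large_median_nm <= 0:
            raise ConfigurationError("medians must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Draw ``n`` (diameter, height) pairs, redrawing diameters
        above the field-of-view truncation bound."""
        is_large = rng.random(n) < self.large_weight
        med = np.where(is_large, self.large_median_nm, self.small_median_nm)
        sd = np.where(is_large, self.large_log_sd, self.small_log_sd)
        diameters = np.exp(np.log(med) + sd * rng.standard_normal(n))
        for _ in range(100):
            over = diameters > self.max_diameter_nm
            if not over.any():
                break
            diameters[over] = np.exp(
                np.log(med[over]) + sd[over] * rng.standard_normal(int(over.sum()))
            )
        else:
            raise ConfigurationError(
                "diameter distribution lies almost entirely above the "
                f"{self.max_diameter_nm} nm field-of-view bound"
            )
        heights = self.height_slope * diameters + self.height_noise_nm * rng.standard_normal(n)
        heights = np.maximum(heights, 0.5)  # physical floor, keeps heights > 0
        return diameters, heights

    def scaled(self, diameter_scale: float = 1.0, large_weight: float | None = None) -> "ParticlePopulation":
        """Population expressing a treatment effect on the large-EV
        subpopulation: the large-component median diameter is multiplied
        by ``diameter_scale`` and/or its mixture weight replaced. The
        small-EV bulk is left untouched — the treatment shifts the
        population toward (and within) the large-vesicle tail."""
        return replace(
            self,
            large_median_nm=self.large_median_nm * diameter_scale,
            large_weight=self.large_weight if large_weight is None else large_weight,
        )


@dataclass(frozen=True)
class SynthConfig:
    """Scan geometry, injection timing and noise levels."""

    seed: int = 0
    condition: str = "control"
    image_size_px: int = 512
    pixel_size_nm: float = 2000.0 / 512.0  # 2 x 2 um scans
    background_roughness_nm: float = 1.0
    tilt_nm_per_px: tuple[float, float] = (0.01, 0.005)
    injection_start_min: float = 2.0
    injection_end_min: float = 22.0  # 20 min injection
    total_time_min: float = 30.0
    sampling_interval_min: float = 0.1
    noise_sd_pct: float = 0.005
    drift_pct_per_min: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ConfigurationError("pixel size must be positive")
        if self.injection_end_min <= self.injection_start_min:
            raise ConfigurationError("injection window must have positive length")
        if self.injection_start_min < 0 or self.total_time_min < self.injection_end_min:
            raise ConfigurationError("injection window must lie inside the time range")


def default_binding_params(layout: BiochipLayout) -> BindingParams:
    """Plausible per-ligand amplitudes spanning the sub-percent
    reflectivity range typical of vesicle capture, distinct per ligand."""
    amplitudes = {}
    base = [0.9, 0.7, 0.8, 1.1, 0.6, 1.0, 0.5, 0.02, 0.75, 0.65]
    for i, name in enumerate(layout.capture_ligands):
        amplitudes[name] = LigandBinding(rmax_pct=base[i % len(base)])
    return BindingParams(ligands=amplitudes)


# ---------------------------------------------------------------------------
# Sensorgram simulation
# ---------------------------------------------------------------------------

def _binding_trace(
    t: np.ndarray, rmax: float, k_obs: float, k_off: float, t_start: float, t_end: float
) -> np.ndarray:
    """Noise-free binding curve on the sample grid ``t``."""
    r = np.zeros_like(t)
    during = (t >= t_start) & (t <= t_end)
    r[during] = rmax * (1.0 - np.exp(-k_obs * (t[during] - t_start)))
    r_end = rmax * (1.0 - np.exp(-k_obs * (t_end - t_start)))
    after = t > t_end
    r[after] = r_end * np.exp(-k_off * (t[after] - t_end))
    return r


def simulate_sensorgram(
    layout: BiochipLayout,
    params: BindingParams,
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
) -> tuple[Sensorgram, pd.DataFrame]:
    """Simulate one experiment's sensorgram.

    Returns the sensorgram and a ground-truth table with one row per
    ROI: the ligand, the spot's realized amplitude and the noise-free
    end-point response as the extraction stage would measure it on the
    default analysis windows (drift and noise excluded).
    """
    missing = [l for l in layout.capture_ligands if l not in params.ligands]
    if missing:
        raise ConfigurationError(f"no binding parameters for ligands: {missing}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    t = np.arange(0.0, cfg.total_time_min + 1e-9, cfg.sampling_interval_min)

    roi_ids = []
    traces = []
    truth_rows = []
    control = layout.negative_control
    # Provisional sensorgram to resolve the default analysis windows.
    (b0, b1), (p0, p1) = default_windows(
        Sensorgram(
            time_min=t,
            reflectivity_pct=np.zeros((t.size, 1)),
            roi_ids=["_"],
            injection_start_min=cfg.injection_start_min,
            injection_end_min=cfg.injection_end_min,
        )
    )
    base_mask = (t >= b0) & (t <= b1)
    plat_mask = (t >= p0) & (t <= p1)

    for r, c, ligand in sorted(layout.spots):
        roi = layout.roi_id(r, c)
        if ligand == control:
            rmax = params.nonspecific_rmax_pct
            k_obs = params.nonspecific_k_obs_per_min
            k_off = 0.0
        else:
            lb = params.ligands[ligand]
            rmax, k_obs, k_off = lb.rmax_pct, lb.k_obs_per_min, lb.k_off_per_min
        rmax_spot = rmax * max(0.0, 1.0 + params.spot_cv * rng.standard_normal())
        clean = _binding_trace(
            t, rmax_spot, k_obs, k_off, cfg.injection_start_min, cfg.injection_end_min
        )
        trace = clean + cfg.drift_pct_per_min * t
        if cfg.noise_sd_pct > 0:
            trace = trace + cfg.noise_sd_pct * rng.standard_normal(t.size)
        roi_ids.append(roi)
        traces.append(trace)
        truth_rows.append(
            {
                "roi_id": roi,
                "ligand": ligand,
                "rmax_spot_pct": rmax_spot,
                "true_response_pct": float(
                    clean[plat_mask].mean() - clean[base_mask].mean()
                ),
            }
        )

    sg = Sensorgram(
        time_min=t,
        reflectivity_pct=np.column_stack(traces),
        roi_ids=roi_ids,
        injection_start_min=cfg.injection_start_min,
        injection_end_min=cfg.injection_end_min,
    )
    return sg, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Topography simulation
# ---------------------------------------------------------------------------

def _render_cap(
    heights: np.ndarray, cx_nm: float, cy_nm: float, d_nm: float, h_nm: float, px: float
) -> None:
    """Add one spherical cap (footprint diameter d, apex h) centered at
    (cx, cy) nm. Pixel centers are at (i + 0.5) * px."""
    sphere_r = d_nm * d_nm / (8.0 * h_nm) + h_nm / 2.0
    half = d_nm / 2.0
    i0 = max(int((cy_nm - half) / px) - 1, 0)
    i1 = min(int((cy_nm + half) / px) + 2, heights.shape[0])
    j0 = max(int((cx_nm - half) / px) - 1, 0)
    j1 = min(int((cx_nm + half) / px) + 2, heights.shape[1])
    yy = (np.arange(i0, i1) + 0.5) * px - cy_nm
    xx = (np.arange(j0, j1) + 0.5) * px - cx_nm
    r2 = yy[:, None] ** 2 + xx[None, :] ** 2
    inside = r2 <= half * half
    z = np.zeros_like(r2)
    z[inside] = np.sqrt(sphere_r**2 - r2[inside]) - (sphere_r - h_nm)
    region = heights[i0:i1, j0:j1]
    np.maximum(region, z, out=region)


def compose_surface(
    particles_layer: np.ndarray, cfg: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """Combine a rendered particle layer with the substrate.

    The substrate is a tilted plane plus Gaussian roughness; particles
    sit on the plane and occlude the substrate texture within their
    footprint (a vesicle membrane is smooth relative to the bare
    surface), so roughness applies only where no particle covers the
    surface.
    """
    rr, cc = np.meshgrid(
        np.arange(particles_layer.shape[0]),
        np.arange(particles_layer.shape[1]),
        indexing="ij",
    )
    tilt_x, tilt_y = cfg.tilt_nm_per_px
    plane = tilt_y * rr + tilt_x * cc
    if cfg.background_roughness_nm > 0:
        noise = cfg.background_roughness_nm * rng.standard_normal(particles_layer.shape)
    else:
        noise = np.zeros_like(particles_layer)
    return np.where(particles_layer > 0, plane + particles_layer, plane + noise)


def cap_volume_nm3(d_nm: float, h_nm: float) -> float:
    """Analytic spherical-cap volume pi*h^2*(3R - h)/3 for a cap of
    footprint diameter d and apex height h."""
    sphere_r = d_nm * d_nm / (8.0 * h_nm) + h_nm / 2.0
    return np.pi * h_nm**2 * (3.0 * sphere_r - h_nm) / 3.0


def above_threshold_chord_nm(d_nm: float, h_nm: float, threshold_nm: float) -> float:
    """Diameter of the cap cross-section at the detection threshold:
    2*sqrt(h'(2R - h')) with h' = h - threshold. Zero if the cap does
    not reach the threshold."""
    if h_nm <= threshold_nm:
        return 0.0
    sphere_r = d_nm * d_nm / (8.0 * h_nm) + h_nm / 2.0
    h_eff = h_nm - threshold_nm
    return 2.0 * np.sqrt(h_eff * (2.0 * sphere_r - h_eff))


def simulate_topography(
    pop: ParticlePopulation,
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
    n_particles: int | None = None,
    ligand: str = "",
    source: str = "",
    max_retries_per_particle: int = 500,
) -> tuple[TopographyImage, pd.DataFrame]:
    """Render one AFM scan plus its ground-truth particle table.

    The particle count defaults to a Poisson draw at the population
    density. Footprints are placed fully inside the image and without
    mutual overlap; exceeding the retry budget raises
    :class:`PlacementError`. Ground truth columns: diameter_nm,
    height_nm, x_nm, y_nm.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    px = cfg.pixel_size_nm
    size_nm = cfg.image_size_px * px
    area_um2 = (size_nm / 1000.0) ** 2

    # A draw from the heavy large-EV tail can produce a particle set
    # that no arrangement can pack without overlap (several near-micron
    # footprints on a 2 x 2 um field). Mirroring how an operator selects
    # usable scan fields, such fields are redrawn wholesale a bounded
    # number of times before erroring out.
    max_field_restarts = 20
    fixed_n = n_particles
    for attempt in range(max_field_restarts):
        n = (
            fixed_n
            if fixed_n is not None
            else int(rng.poisson(pop.density_per_um2 * area_um2))
        )
        diameters, heights_true = (
            pop.sample(n, rng) if n else (np.array([]), np.array([]))
        )
        # Oversized footprints cannot fit, and fields packed beyond the
        # random-sequential-adsorption jamming regime never place.
        if n and (
            diameters.max() >= size_nm
            or (np.pi / 4.0 * diameters**2).sum() > 0.5 * size_nm**2
        ):
            continue
        # Place the largest footprints first: greedy rejection sampling
        # then succeeds at much higher packing fractions.
        if n:
            order = np.argsort(-diameters)
            diameters = diameters[order]
            heights_true = heights_true[order]
        placed_x: list[float] = []
        placed_y: list[float] = []
        failed = False
        for i in range(n):
            half = diameters[i] / 2.0
            ok = False
            for _ in range(max_retries_per_particle):
                x = rng.uniform(half, size_nm - half)
                y = rng.uniform(half, size_nm - half)
                if all(
                    (x - px_) ** 2 + (y - py_) ** 2
                    > (half + diameters[j] / 2.0) ** 2
                    for j, (px_, py_) in enumerate(zip(placed_x, placed_y))
                ):
                    ok = True
                    break
            if not ok:
                failed = True
                break
            placed_x.append(x)
            placed_y.append(y)
        if not failed:
            n_particles = n
            break
    else:
        raise PlacementError(
            f"could not place {n} particles without overlap after "
            f"{max_field_restarts} field redraws x {max_retries_per_particle} "
            "retries (density too high)"
        )

    particles_layer = np.zeros((cfg.image_size_px, cfg.image_size_px))
    for x, y, d, h in zip(placed_x, placed_y, diameters, heights_true):
        _render_cap(particles_layer, x, y, d, h, px)
    img = TopographyImage(
        heights_nm=compose_surface(particles_layer, cfg, rng),
        pixel_size_nm=px,
        ligand=ligand,
        condition=cfg.condition,
        source=source,
    )
    truth = pd.DataFrame(
        {
            "diameter_nm": diameters,
            "height_nm": heights_true,
            "x_nm": placed_x,
            "y_nm": placed_y,
        }
    )
    return img, truth


# ---------------------------------------------------------------------------
# Study scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """Named specification of the true treatment effects.

    ``response_scale`` multiplies the treated-condition binding
    amplitude of the named ligands; ``diameter_scale`` multiplies the
    treated-condition particle diameters; ``treated_large_weight``
    overrides the large-EV mixture weight for those same ligands in the
    treated condition. Ligands not named get no effect.
    """

    name: str
    response_scale: dict[str, float] = field(default_factory=dict)
    diameter_scale: dict[str, float] = field(default_factory=dict)
    treated_large_weight: dict[str, float] = field(default_factory=dict)


def named_scenario(name: str) -> Scenario:
    """Built-in scenarios: ``null`` (no effects) and ``cd36-shift``
    (treated Anti-CD36 vesicles larger: diameters x1.25 and the
    large-EV weight raised from 0.10 to 0.25)."""
    scenarios = {
        "null": Scenario(name="null"),
        "cd36-shift": Scenario(
            name="cd36-shift",
            response_scale={"Anti-CD36": 1.5},
            diameter_scale={"Anti-CD36": 1.25},
            treated_large_weight={"Anti-CD36": 0.25},
        ),
    }
    if name not in scenarios:
        raise ConfigurationError(
            f"unknown scenario {name!r}; available: {sorted(scenarios)}"
        )
    return scenarios[name]


@dataclass
class StudyBundle:
    """In-memory paired study: layout, per-experiment sensorgrams and
    per-ligand AFM image stacks for both conditions, plus a manifest of
    every programmed effect."""

    layout: BiochipLayout
    sensorgrams: dict[str, Sensorgram]  # experiment id -> sensorgram
    sensorgram_truth: dict[str, pd.DataFrame]
    conditions: dict[str, str]  # experiment id -> condition
    images: dict[tuple[str, str], list[TopographyImage]]  # (ligand, condition)
    image_truth: dict[tuple[str, str], list[pd.DataFrame]]
    manifest: dict

    def save(self, out_dir: str | Path) -> Path:
        """Write the bundle as a directory tree: layout.json,
        sensorgrams/<exp>.csv (+ manifests), images/<ligand>/<cond>/*.tif
        (+ sidecars), manifest.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.layout.to_json(out / "layout.json")
        sg_dir = out / "sensorgrams"
        sg_dir.mkdir(exist_ok=True)
        for exp, sg in sorted(self.sensorgrams.items()):
            write_sensorgram(sg, sg_dir / f"{exp}.csv")
        img_dir = out / "images"
        for (ligand, cond), imgs in sorted(self.images.items()):
            d = img_dir / ligand.replace("/", "_") / cond
            d.mkdir(parents=True, exist_ok=True)
            for i, img in enumerate(imgs):
                write_topography(img, d / f"scan{i:03d}.tif")
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=1, sort_keys=True))
        return out


def simulate_study(
    scenario: Scenario | str,
    seed: int,
    layout: BiochipLayout | None = None,
    binding: BindingParams | None = None,
    population: ParticlePopulation = ParticlePopulation(),
    cfg: SynthConfig = SynthConfig(),
    n_control_experiments: int = 5,
    n_treated_experiments: int = 4,
    images_per_ligand: int = 4,
    image_ligands: list[str] | None = None,
) -> StudyBundle:
    """Generate a full paired study under a scenario.

    Defaults mirror the study design: five control and four treated
    sensorgram experiments on the standard panel, plus AFM image stacks
    per capture ligand and condition. ``images_per_ligand=0`` skips the
    imaging arm (useful for profile-only studies); ``image_ligands``
    restricts imaging to a subset of the panel.
    """
    if isinstance(scenario, str):
        scenario = named_scenario(scenario)
    if layout is None:
        layout = build_layout(default_panel(), 10, 10)
    if binding is None:
        binding = default_binding_params(layout)
    for effect in (scenario.response_scale, scenario.diameter_scale, scenario.treated_large_weight):
        unknown = sorted(set(effect) - set(layout.capture_ligands))
        if unknown:
            raise ConfigurationError(f"scenario names unknown ligands: {unknown}")
    rng = np.random.default_rng(seed)

    treated_binding = BindingParams(
        ligands={
            name: replace(
                lb, rmax_pct=lb.rmax_pct * scenario.response_scale.get(name, 1.0)
            )
            for name, lb in binding.ligands.items()
        },
        spot_cv=binding.spot_cv,
        nonspecific_rmax_pct=binding.nonspecific_rmax_pct,
        nonspecific_k_obs_per_min=binding.nonspecific_k_obs_per_min,
    )

    sensorgrams: dict[str, Sensorgram] = {}
    truths: dict[str, pd.DataFrame] = {}
    conditions: dict[str, str] = {}
    plan = [("control", i, binding) for i in range(n_control_experiments)]
    plan += [("treated", i, treated_binding) for i in range(n_treated_experiments)]
    for cond, i, bp in plan:
        exp = f"{cond}{i + 1}"
        sg, truth = simulate_sensorgram(
            layout, bp, replace(cfg, condition=cond), rng=rng
        )
        sensorgrams[exp] = sg
        truths[exp] = truth
        conditions[exp] = cond

    images: dict[tuple[str, str], list[TopographyImage]] = {}
    image_truth: dict[tuple[str, str], list[pd.DataFrame]] = {}
    targets = image_ligands if image_ligands is not None else list(layout.capture_ligands)
    if images_per_ligand > 0:
        for ligand in targets:
            for cond in ("control", "treated"):
                if cond == "treated":
                    pop = population.scaled(
                        scenario.diameter_scale.get(ligand, 1.0),
                        scenario.treated_large_weight.get(ligand),
                    )
                else:
                    pop = population
                stack, stack_truth = [], []
                for i in range(images_per_ligand):
                    img, truth = simulate_topography(
                        pop,
                        replace(cfg, condition=cond),
                        rng=rng,
                        ligand=ligand,
                        source=f"{ligand}_{cond}_scan{i:03d}",
                    )
                    stack.append(img)
                    stack_truth.append(truth)
                images[(ligand, cond)] = stack
                image_truth[(ligand, cond)] = stack_truth

    manifest = {
        "scenario": scenario.name,
        "seed": seed,
        "n_control_experiments": n_control_experiments,
        "n_treated_experiments": n_treated_experiments,
        "images_per_ligand": images_per_ligand,
        "experiments": {exp: cond for exp, cond in sorted(conditions.items())},
        "true_effects": {
            ligand: {
                "response_scale": scenario.response_scale.get(ligand, 1.0),
                "diameter_scale": scenario.diameter_scale.get(ligand, 1.0),
                "treated_large_weight": scenario.treated_large_weight.get(
                    ligand, population.large_weight
                ),
            }
            for ligand in layout.capture_ligands
        },
    }
    return StudyBundle(
        layout=layout,
        sensorgrams=sensorgrams,
        sensorgram_truth=truths,
        conditions=conditions,
        images=images,
        image_truth=image_truth,
        manifest=manifest,
    )
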