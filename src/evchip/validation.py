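"""Monte-Carlo calibration and recovery checks for the pipeline.

These helpers re-run the package on synthetic data with known ground
truth and measure operating characteristics: type-I error of the
size-shift test under the null, power against a programmed diameter
shift, detection fidelity of the AFM metrology against rendered caps,
exactness of the SPRi response chain, and the end-to-end shift-label
recovery rate. They are ordinary library code — the same functions back
the test suite and the acceptance report.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .afm import DetectionConfig, detect_particles
from .layout import LigandSpec, build_layout
from .profile import cv_table, normalize_profile, response_matrix_from_tables, select_reference
from .simulate import (
    BindingParams,
    LigandBinding,
    ParticlePopulation,
    Scenario,
    SynthConfig,
    above_threshold_chord_nm,
    simulate_sensorgram,
    simulate_study,
    simulate_topography,
)
from .sizestats import LEV_MIN_DIAMETER_NM, mann_whitney_u
from .spri import extract_response, ligand_response_table, subtract_negative_control
from .pipeline import PipelineConfig, analyze_study


def sample_levs(
    pop: ParticlePopulation, n: int, rng: np.random.Generator,
    min_diameter_nm: float = LEV_MIN_DIAMETER_NM,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw exactly ``n`` large-EV (diameter > cut) particles from a
    population by batched rejection sampling."""
    d_out: list[np.ndarray] = []
    h_out: list[np.ndarray] = []
    got = 0
    while got < n:
        d, h = pop.sample(max(4 * n, 256), rng)
        keep = d > min_diameter_nm
        d_out.append(d[keep])
        h_out.append(h[keep])
        got += int(keep.sum())
    d_all = np.concatenate(d_out)[:n]
    h_all = np.concatenate(h_out)[:n]
    return d_all, h_all


def type_one_error_rate(
    n_per_group: int = 150,
    replicates: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    pop: ParticlePopulation = ParticlePopulation(),
) -> dict[str, float]:
    """Null calibration: both groups drawn from the identical large-EV
    population; returns the per-parameter rejection rate at ``alpha``."""
    rng = np.random.default_rng(seed)
    rej_d = rej_h = 0
    for _ in range(replicates):
        d1, h1 = sample_levs(pop, n_per_group, rng)
        d2, h2 = sample_levs(pop, n_per_group, rng)
        if mann_whitney_u(d1, d2).p_value < alpha:
            rej_d += 1
        if mann_whitney_u(h1, h2).p_value < alpha:
            rej_h += 1
    return {
        "diameter": rej_d / replicates,
        "height": rej_h / replicates,
        "replicates": replicates,
        "n_per_group": n_per_group,
    }


def size_shift_power(
    scale: float = 1.25,
    n_per_group: int = 150,
    replicates: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    median_nm: float = 350.0,
    log_sd: float = 0.40,
) -> float:
    """Power of the diameter test against a multiplicative shift of a
    log-normal size distribution (treated = control x ``scale``)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(replicates):
        control = np.exp(np.log(median_nm) + log_sd * rng.standard_normal(n_per_group))
        treated = scale * np.exp(
            np.log(median_nm) + log_sd * rng.standard_normal(n_per_group)
        )
        if mann_whitney_u(control, treated).p_value < alpha:
            rejections += 1
    return rejections / replicates


# ---------------------------------------------------------------------------
# AFM metrology fidelity
# ---------------------------------------------------------------------------

def afm_detection_fidelity(
    seed: int = 0,
    n_images: int = 8,
    cfg: DetectionConfig = DetectionConfig(),
) -> dict[str, float]:
    """Render scans of well-detectable caps (apex >= 12 nm, footprint
    comfortably above the area floor) and score detection against the
    ground truth.

    Matching: a detected particle and a true particle match when their
    centroids are within one true footprint radius. Returns recall,
    precision, the worst diameter error in pixels relative to the
    analytic above-threshold chord, and the worst apex-height error
    in nm.
    """
    # Diameters >= ~55 nm guarantee footprint >= 2x the 200 nm^2 floor;
    # the height map keeps every apex >= 12 nm.
    pop = ParticlePopulation(
        small_median_nm=150.0,
        small_log_sd=0.25,
        large_median_nm=400.0,
        large_log_sd=0.30,
        large_weight=0.3,
        height_slope=0.12,
        height_noise_nm=0.0,
        density_per_um2=5.0,
    )
    synth = SynthConfig(seed=seed, background_roughness_nm=1.0)
    rng = np.random.default_rng(seed)
    n_true = n_detected = n_matched = 0
    worst_d_err_px = 0.0
    worst_h_err_nm = 0.0
    for i in range(n_images):
        img, truth = simulate_topography(pop, synth, rng=rng, source=f"fidelity{i}")
        # enforce the advertised detectability floor
        truth = truth.copy()
        lo = np.maximum(truth["height_nm"], 12.0)
        redo = lo.to_numpy() != truth["height_nm"].to_numpy()
        if redo.any():  # re-render with clamped heights
            truth.loc[:, "height_nm"] = lo
            img, truth = _render_from_truth(truth, synth, rng)
        detected = detect_particles(img, cfg)
        n_true += len(truth)
        n_detected += len(detected)
        for _, t in truth.iterrows():
            dist = np.hypot(
                detected["centroid_x_nm"] - t["x_nm"],
                detected["centroid_y_nm"] - t["y_nm"],
            )
            if len(dist) == 0:
                continue
            j = int(dist.idxmin())
            if dist[j] <= t["diameter_nm"] / 2.0:
                n_matched += 1
                chord = above_threshold_chord_nm(
                    t["diameter_nm"], t["height_nm"], cfg.height_threshold_nm
                )
                d_err = abs(detected.loc[j, "max_diameter_nm"] - chord) / img.pixel_size_nm
                h_err = abs(detected.loc[j, "height_nm"] - t["height_nm"])
                worst_d_err_px = max(worst_d_err_px, d_err)
                worst_h_err_nm = max(worst_h_err_nm, h_err)
    return {
        "recall": n_matched / n_true if n_true else float("nan"),
        "precision": n_matched / n_detected if n_detected else float("nan"),
        "max_diameter_error_px": worst_d_err_px,
        "max_height_error_nm": worst_h_err_nm,
        "n_true": n_true,
        "n_detected": n_detected,
    }


def _render_from_truth(truth, synth: SynthConfig, rng: np.random.Generator):
    """Re-render an image from an explicit truth table (same placement)."""
    from .afm import TopographyImage
    from .simulate import _render_cap, compose_surface

    n_px = synth.image_size_px
    px = synth.pixel_size_nm
    layer = np.zeros((n_px, n_px))
    for _, t in truth.iterrows():
        _render_cap(layer, t["x_nm"], t["y_nm"], t["diameter_nm"], t["height_nm"], px)
    img = TopographyImage(
        heights_nm=compose_surface(layer, synth, rng),
        pixel_size_nm=px,
        condition=synth.condition,
    )
    return img, truth


# ---------------------------------------------------------------------------
# SPRi exactness
# ---------------------------------------------------------------------------

def spri_exactness(seed: int = 0) -> dict[str, float]:
    """Noise-free, drift-free simulation: the extracted responses must
    equal ground truth to floating-point accuracy, the adjusted
    negative-control mean must be exactly zero, and the reference
    ligand's normalized value exactly one."""
    layout = _small_layout()
    params = BindingParams(
        ligands={
            "Anti-CD36": LigandBinding(rmax_pct=1.2),
            "Anti-CD44": LigandBinding(rmax_pct=0.8),
        },
        spot_cv=0.10,
        nonspecific_rmax_pct=0.05,
    )
    cfg = SynthConfig(seed=seed, noise_sd_pct=0.0, drift_pct_per_min=0.0)
    rng = np.random.default_rng(seed)

    max_rel_err = 0.0
    tables = []
    for cond, n_exp in (("control", 2), ("treated", 2)):
        for i in range(n_exp):
            sg, truth = simulate_sensorgram(layout, params, cfg, rng=rng)
            responses = extract_response(sg)
            truth_map = truth.set_index("roi_id")["true_response_pct"]
            for r in responses:
                expected = truth_map[r.roi_id]
                denom = max(abs(expected), 1e-30)
                max_rel_err = max(max_rel_err, abs(r.raw_response - expected) / denom)
            tables.append(
                ligand_response_table(sg, layout, cond, f"{cond}{i + 1}")
            )
            adjusted = subtract_negative_control(responses, layout)
            control_ids = {
                layout.roi_id(r_, c_)
                for r_, c_, name in layout.spots
                if name == layout.negative_control
            }
            ctrl_mean = float(
                np.mean(
                    [a.adjusted_response for a in adjusted if a.roi_id in control_ids]
                )
            )
    rm = response_matrix_from_tables(tables).drop_ligands([layout.negative_control])
    reference = select_reference(cv_table(rm))
    profiles = normalize_profile(rm, reference)
    ref_vals = (rm.responses[reference] / rm.responses[reference]).to_numpy()
    return {
        "max_relative_response_error": max_rel_err,
        "control_mean_after_subtraction": abs(ctrl_mean),
        "reference_normalized_deviation": float(np.abs(ref_vals - 1.0).max()),
        "reference": reference,
    }


def _small_layout():
    panel = (
        LigandSpec("Anti-CD36"),
        LigandSpec("Anti-CD44"),
        LigandSpec("Anti-OVA", "negative_control"),
    )
    return build_layout(panel, 5, 4)


# ---------------------------------------------------------------------------
# End-to-end shift recovery
# ---------------------------------------------------------------------------

def pipeline_shift_detection_rate(
    n_seeds: int = 20,
    seed: int = 0,
    images_per_ligand: int = 80,
    shifted_ligand: str = "Anti-CD36",
) -> dict[str, float]:
    """Run the full pipeline on paired studies carrying a diameter shift
    on one ligand and report how often the summary labels it ``+`` or
    ``++``.

    Uses a reduced two-capture-ligand chip so each replicate stays
    cheap, at a sparser capture density (12 particles per scan) so the
    enlarged treated vesicles still place without overlap; 80 scans per
    ligand and condition pool on the order of 150 control large EVs,
    the group size at which the shift test is well powered.
    """
    layout = _small_layout()
    scenario = Scenario(
        name="shift",
        response_scale={shifted_ligand: 1.5},
        diameter_scale={shifted_ligand: 1.25},
        treated_large_weight={shifted_ligand: 0.25},
    )
    population = replace(ParticlePopulation(), density_per_um2=3.0)
    cfg = PipelineConfig(seed=seed)
    seed_rng = np.random.default_rng(seed)
    hits = 0
    labels = []
    for _ in range(n_seeds):
        study_seed = int(seed_rng.integers(0, 2**31 - 1))
        bundle = simulate_study(
            scenario,
            study_seed,
            layout=layout,
            population=population,
            images_per_ligand=images_per_ligand,
            image_ligands=[shifted_ligand],
        )
        result = analyze_study(bundle, cfg)
        summary = result.comparison.summary.set_index("ligand")
        label = summary.loc[shifted_ligand, "combined"]
        labels.append(label)
        if label in ("+", "++"):
            hits += 1
    return {
        "detection_rate": hits / n_seeds,
        "n_seeds": n_seeds,
        "labels": labels,
    }
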