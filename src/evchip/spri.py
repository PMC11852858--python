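"""SPRi sensorgram parsing and end-point response extraction.

A sensorgram is the reflectivity (%) vs time (min) trace of every ROI on
the biochip during a sample injection. The per-ROI response is the
end-point difference "end signal minus start signal": the mean
reflectivity in a stabilized post-injection plateau window minus the
mean in a pre-injection baseline window. Responses are corrected for
nonspecific binding by subtracting the mean response of the
negative-control ROIs, then aggregated per ligand family (mean, sample
sd over that ligand's spots).

Plasmon curves (reflectivity vs incidence angle) quantify ligand
grafting through the angular shift of the reflectivity minimum; the
minimum is located by parabolic interpolation around the discrete
minimum.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    FormatError,
    QCError,
    StatisticsError,
    WindowError,
)
from .layout import BiochipLayout, LigandNotFoundError, ligand_roi_ids

log = logging.getLogger(__name__)

# Default analysis windows relative to the injection markers (minutes).
# The baseline ends where the injection starts; the plateau starts after
# a settling delay so the "stabilized reflectivity variation after the
# injection" is sampled, not the dissociation transient.
BASELINE_BEFORE_MIN = 2.0
PLATEAU_DELAY_MIN = 5.0
PLATEAU_LENGTH_MIN = 2.0


@dataclass
class Sensorgram:
    """Reflectivity traces for all ROIs of one experiment.

    ``reflectivity`` has one row per time point and one column per ROI,
    aligned with ``roi_ids``.
    """

    time_min: np.ndarray
    reflectivity_pct: np.ndarray
    roi_ids: list[str]
    injection_start_min: float
    injection_end_min: float

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.reflectivity_pct = np.asarray(self.reflectivity_pct, dtype=float)
        if self.time_min.ndim != 1:
            raise FormatError("time axis must be one-dimensional")
        if np.any(np.diff(self.time_min) <= 0):
            raise FormatError("time axis must be strictly increasing")
        if self.reflectivity_pct.shape != (self.time_min.size, len(self.roi_ids)):
            raise FormatError(
                f"reflectivity shape {self.reflectivity_pct.shape} does not match "
                f"{self.time_min.size} time points x {len(self.roi_ids)} ROIs"
            )
        if not (
            self.time_min[0] <= self.injection_start_min
            < self.injection_end_min <= self.time_min[-1]
        ):
            raise FormatError("injection window must lie inside the time range")

    def column(self, roi_id: str) -> np.ndarray:
        try:
            j = self.roi_ids.index(roi_id)
        except ValueError:
            raise LigandNotFoundError(f"ROI {roi_id!r} not in sensorgram") from None
        return self.reflectivity_pct[:, j]


@dataclass(frozen=True)
class PlasmonCurve:
    """Reflectivity vs incidence angle for one ROI."""

    angle_deg: np.ndarray
    reflectivity_pct: np.ndarray
    roi_id: str = ""


@dataclass
class ROIResponse:
    roi_id: str
    raw_response: float
    baseline_value: float
    plateau_value: float
    adjusted_response: float | None = None


@dataclass
class LigandResponse:
    ligand: str
    mean_response: float
    sd_response: float
    n_spots: int
    condition: str = ""
    experiment: str = ""


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_sensorgram(sg: Sensorgram, path: str | Path) -> None:
    """CSV with a ``time_min`` column plus one column per ROI, and a
    companion ``<stem>.manifest.json`` holding the injection window."""
    path = Path(path)
    df = pd.DataFrame(sg.reflectivity_pct, columns=sg.roi_ids)
    df.insert(0, "time_min", sg.time_min)
    df.to_csv(path, index=False, float_format="%.9g")
    manifest = {
        "injection_start_min": sg.injection_start_min,
        "injection_end_min": sg.injection_end_min,
    }
    _manifest_path(path).write_text(json.dumps(manifest, sort_keys=True))


def _manifest_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".manifest.json")


def read_sensorgram(path: str | Path, layout: BiochipLayout | None = None) -> Sensorgram:
    """Read a sensorgram CSV plus its injection-window manifest.

    When a layout is given, every layout ROI must be present as a column;
    missing ROIs are reported by id.
    """
    path = Path(path)
    mpath = _manifest_path(path)
    if not mpath.exists():
        raise FormatError(f"missing injection-window manifest {mpath}")
    manifest = json.loads(mpath.read_text())
    for key in ("injection_start_min", "injection_end_min"):
        if key not in manifest:
            raise FormatError(f"manifest {mpath} missing {key!r}")
    df = pd.read_csv(path)
    if "time_min" not in df.columns:
        raise FormatError(f"{path}: first column must be 'time_min'")
    roi_ids = [c for c in df.columns if c != "time_min"]
    if layout is not None:
        missing = sorted(set(layout.roi_ids) - set(roi_ids))
        if missing:
            raise FormatError(
                f"{path}: missing ROI columns for layout spots: {', '.join(missing)}"
            )
        unknown = sorted(set(roi_ids) - set(layout.roi_ids))
        if unknown:
            raise FormatError(f"{path}: ROI columns not in layout: {', '.join(unknown)}")
    return Sensorgram(
        time_min=df["time_min"].to_numpy(),
        reflectivity_pct=df[roi_ids].to_numpy(),
        roi_ids=roi_ids,
        injection_start_min=float(manifest["injection_start_min"]),
        injection_end_min=float(manifest["injection_end_min"]),
    )


# ---------------------------------------------------------------------------
# Response extraction
# ---------------------------------------------------------------------------

def default_windows(sg: Sensorgram) -> tuple[tuple[float, float], tuple[float, float]]:
    """(baseline, plateau) windows derived from the injection markers."""
    baseline = (sg.injection_start_min - BASELINE_BEFORE_MIN, sg.injection_start_min)
    plateau = (
        sg.injection_end_min + PLATEAU_DELAY_MIN,
        sg.injection_end_min + PLATEAU_DELAY_MIN + PLATEAU_LENGTH_MIN,
    )
    return baseline, plateau


def extract_response(
    sg: Sensorgram,
    baseline_window: tuple[float, float] | None = None,
    plateau_window: tuple[float, float] | None = None,
) -> list[ROIResponse]:
    """Per-ROI end-point response: plateau-window mean minus
    baseline-window mean of the reflectivity trace.

    Window bounds are inclusive. The baseline window must end at or
    before the injection start, the plateau window must begin at or
    after the injection end, and each must contain at least one sample.
    """
    if baseline_window is None or plateau_window is None:
        dflt_base, dflt_plat = default_windows(sg)
        baseline_window = baseline_window or dflt_base
        plateau_window = plateau_window or dflt_plat
    b0, b1 = baseline_window
    p0, p1 = plateau_window
    if b1 > sg.injection_start_min:
        raise WindowError(
            f"baseline window ends at {b1} min, after injection start "
            f"{sg.injection_start_min} min"
        )
    if p0 < sg.injection_end_min:
        raise WindowError(
            f"plateau window starts at {p0} min, before injection end "
            f"{sg.injection_end_min} min"
        )
    base_mask = (sg.time_min >= b0) & (sg.time_min <= b1)
    plat_mask = (sg.time_min >= p0) & (sg.time_min <= p1)
    if not base_mask.any():
        raise WindowError(f"baseline window [{b0}, {b1}] min contains no samples")
    if not plat_mask.any():
        raise WindowError(f"plateau window [{p0}, {p1}] min contains no samples")

    base = sg.reflectivity_pct[base_mask].mean(axis=0)
    plat = sg.reflectivity_pct[plat_mask].mean(axis=0)
    return [
        ROIResponse(
            roi_id=roi,
            raw_response=float(plat[j] - base[j]),
            baseline_value=float(base[j]),
            plateau_value=float(plat[j]),
        )
        for j, roi in enumerate(sg.roi_ids)
    ]


def subtract_negative_control(
    responses: list[ROIResponse], layout: BiochipLayout
) -> list[ROIResponse]:
    """Fill ``adjusted_response`` = raw minus the mean raw response of
    the negative-control ROIs. Control ROIs are adjusted too, so their
    adjusted mean is exactly zero."""
    control_ids = set(ligand_roi_ids(layout, layout.negative_control))
    control_raw = [r.raw_response for r in responses if r.roi_id in control_ids]
    if not control_raw:
        raise ConfigurationError("no negative-control ROIs present in responses")
    offset = float(np.mean(control_raw))
    out = [replace(r, adjusted_response=r.raw_response - offset) for r in responses]
    n_neg = sum(1 for r in out if r.adjusted_response is not None and r.adjusted_response < 0)
    if n_neg:
        log.info("%d ROIs have negative adjusted responses (kept, not clipped)", n_neg)
    return out


def aggregate_ligand(
    responses: list[ROIResponse],
    layout: BiochipLayout,
    ligand: str,
    condition: str = "",
    experiment: str = "",
) -> LigandResponse:
    """Mean and sample sd of adjusted responses over a ligand's spots."""
    ids = set(ligand_roi_ids(layout, ligand))
    vals = [
        r.adjusted_response if r.adjusted_response is not None else r.raw_response
        for r in responses
        if r.roi_id in ids
    ]
    if not vals:
        raise ConfigurationError(f"ligand {ligand!r} has no analysis ROIs in responses")
    if len(vals) == 1:
        log.warning("ligand %s aggregated from a single ROI; sd reported as 0", ligand)
        sd = 0.0
    else:
        sd = float(np.std(vals, ddof=1))
    return LigandResponse(
        ligand=ligand,
        mean_response=float(np.mean(vals)),
        sd_response=sd,
        n_spots=len(vals),
        condition=condition,
        experiment=experiment,
    )


def ligand_response_table(
    sg: Sensorgram,
    layout: BiochipLayout,
    condition: str = "",
    experiment: str = "",
    baseline_window: tuple[float, float] | None = None,
    plateau_window: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Full per-experiment chain: extract responses, subtract the
    negative control, aggregate every panel ligand. One row per ligand
    with columns ligand, condition, experiment, mean, sd, n."""
    responses = extract_response(sg, baseline_window, plateau_window)
    responses = subtract_negative_control(responses, layout)
    rows = []
    for ligand in layout.ligand_names:
        lr = aggregate_ligand(responses, layout, ligand, condition, experiment)
        rows.append(
            {
                "ligand": lr.ligand,
                "condition": lr.condition,
                "experiment": lr.experiment,
                "mean_response_pct": lr.mean_response,
                "sd_response_pct": lr.sd_response,
                "n_spots": lr.n_spots,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Plasmon curves and specificity
# ---------------------------------------------------------------------------

def _interpolated_minimum(curve: PlasmonCurve) -> float:
    """Angle of the reflectivity minimum, refined by fitting a parabola
    through the discrete minimum and its two neighbours."""
    r = np.asarray(curve.reflectivity_pct, dtype=float)
    a = np.asarray(curve.angle_deg, dtype=float)
    if r.size < 3:
        raise QCError(f"plasmon curve {curve.roi_id!r}: fewer than 3 samples")
    i = int(np.argmin(r))
    if i == 0 or i == r.size - 1:
        raise QCError(
            f"plasmon curve {curve.roi_id!r}: minimum at the edge of the angle "
            "range (curve truncated)"
        )
    # Parabola through three points; vertex in closed form.
    x0, x1, x2 = a[i - 1 : i + 2]
    y0, y1, y2 = r[i - 1 : i + 2]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    A = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    B = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if A <= 0:
        return float(x1)
    return float(-B / (2 * A))


def plasmon_shift(before: PlasmonCurve, after: PlasmonCurve) -> float:
    """Angular shift (degrees) of the plasmon minimum: after minus
    before. Used as a grafting-level QC quantity."""
    return _interpolated_minimum(after) - _interpolated_minimum(before)


def specificity_ratio(ligand_mean: float, control_mean_raw: float) -> float:
    """Percent difference of a ligand's mean response over the raw
    negative-control mean: 100 * (ligand - control) / control."""
    if control_mean_raw <= 0:
        raise StatisticsError(
            f"control mean {control_mean_raw} is not positive; ratio undefined "
            f"(absolute difference = {ligand_mean - control_mean_raw})"
        )
    return 100.0 * (ligand_mean - control_mean_raw) / control_mean_raw
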