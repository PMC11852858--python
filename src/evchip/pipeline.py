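"""End-to-end study orchestration.

Flow: (simulated or on-disk) study bundle -> per-experiment SPRi
response extraction and negative-control subtraction -> cross-experiment
phenotype profile with CV-selected reference -> AFM particle metrology
per ligand/condition -> large-EV size statistics and the ++/+/= summary
-> report bundle on disk (TSV tables + JSON manifest with a config hash
for provenance).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .afm import (
    DetectionConfig,
    detect_particles,
    pool_particles,
    read_topography,
    write_particle_table,
)
from .errors import EvChipError, PipelineError
from .layout import BiochipLayout
from .profile import (
    compare_profiles,
    cv_table,
    normalize_profile,
    profile_table,
    response_matrix_from_tables,
    select_reference,
)
from .simulate import StudyBundle, simulate_study
from .sizestats import (
    DEFAULT_ALPHA,
    DEFAULT_BIN_WIDTH_NM,
    DEFAULT_WINDOWS_NM,
    compare_conditions,
    heatmap_table,
)
from .spri import ligand_response_table, read_sensorgram

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, serializable to YAML/JSON."""

    dataset_dir: str = ""
    out_dir: str = "evchip_out"
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    windows_nm: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS_NM
    bin_width_nm: float = DEFAULT_BIN_WIDTH_NM
    alpha: float = DEFAULT_ALPHA
    reference_override: str | None = None
    exclude_ligands: tuple[str, ...] = ()
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["windows_nm"] = [list(w) for w in self.windows_nm]
        d["exclude_ligands"] = list(self.exclude_ligands)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "detection" in d and isinstance(d["detection"], dict):
            d["detection"] = DetectionConfig(**d["detection"])
        if "windows_nm" in d:
            d["windows_nm"] = tuple(tuple(w) for w in d["windows_nm"])
        if "exclude_ligands" in d:
            d["exclude_ligands"] = tuple(d["exclude_ligands"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class StudyResult:
    """In-memory result of a full study analysis."""

    response_tables: pd.DataFrame  # per experiment x ligand
    cv: pd.DataFrame
    reference: str
    profiles: dict
    profile_comparison: pd.DataFrame
    particles: dict  # (ligand, condition) -> pooled particle table
    comparison: object  # sizestats.ConditionComparison
    warnings: list[str]


# ---------------------------------------------------------------------------
# Loading a saved study
# ---------------------------------------------------------------------------

def load_study(dataset_dir: str | Path) -> StudyBundle:
    """Read a study bundle written by :meth:`StudyBundle.save`."""
    root = Path(dataset_dir)
    if not root.is_dir():
        raise PipelineError("load", f"dataset directory not found: {root}")
    layout_path = root / "layout.json"
    if not layout_path.exists():
        raise PipelineError("load", f"missing layout file: {layout_path}")
    layout = BiochipLayout.from_json(layout_path)
    manifest = json.loads((root / "manifest.json").read_text())
    sensorgrams = {}
    conditions = dict(manifest.get("experiments", {}))
    for csv in sorted((root / "sensorgrams").glob("*.csv")):
        sensorgrams[csv.stem] = read_sensorgram(csv, layout)
    images: dict[tuple[str, str], list] = {}
    img_root = root / "images"
    if img_root.is_dir():
        for ligand_dir in sorted(img_root.iterdir()):
            for cond_dir in sorted(p for p in ligand_dir.iterdir() if p.is_dir()):
                stack = [
                    read_topography(t) for t in sorted(cond_dir.glob("*.tif"))
                ] + [read_topography(t) for t in sorted(cond_dir.glob("*.txt"))]
                if stack:
                    images[(stack[0].ligand or ligand_dir.name, cond_dir.name)] = stack
    return StudyBundle(
        layout=layout,
        sensorgrams=sensorgrams,
        sensorgram_truth={},
        conditions=conditions,
        images=images,
        image_truth={},
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# Analysis
# ---------------------------------------------------------------------------

def analyze_study(bundle: StudyBundle, cfg: PipelineConfig) -> StudyResult:
    """Run the full analysis chain on an in-memory bundle."""
    warnings: list[str] = []

    # --- SPRi stage -----------------------------------------------------
    try:
        tables = [
            ligand_response_table(
                sg, bundle.layout, bundle.conditions.get(exp, ""), exp
            )
            for exp, sg in sorted(bundle.sensorgrams.items())
        ]
        responses = pd.concat(tables, ignore_index=True)
    except EvChipError as e:
        raise PipelineError("spri", str(e)) from e

    # --- Phenotype profile ---------------------------------------------
    try:
        rm = response_matrix_from_tables(tables)
        drop = list(cfg.exclude_ligands) + [bundle.layout.negative_control]
        rm = rm.drop_ligands(drop)
        for lig in cfg.exclude_ligands:
            warnings.append(f"ligand {lig} excluded from profile by configuration")
        cv = cv_table(rm)
        reference = select_reference(cv, override=cfg.reference_override)
        profiles = normalize_profile(rm, reference)
        conds = sorted(profiles)
        if len(conds) == 2:
            profile_cmp = compare_profiles(profiles[conds[0]], profiles[conds[1]])
        else:
            profile_cmp = pd.DataFrame()
    except EvChipError as e:
        raise PipelineError("profile", str(e)) from e

    # --- AFM metrology --------------------------------------------------
    try:
        particles = {}
        for (ligand, cond), stack in sorted(bundle.images.items()):
            pooled = pool_particles(
                [detect_particles(img, cfg.detection) for img in stack], ligand
            )
            particles[(ligand, cond)] = pooled
    except EvChipError as e:
        raise PipelineError("afm", str(e)) from e

    # --- Size statistics ------------------------------------------------
    try:
        control_tables = {
            lig: t for (lig, cond), t in particles.items() if cond == "control"
        }
        treated_tables = {
            lig: t for (lig, cond), t in particles.items() if cond == "treated"
        }
        comparison = compare_conditions(
            control_tables,
            treated_tables,
            alpha=cfg.alpha,
            windows_nm=cfg.windows_nm,
            bin_width_nm=cfg.bin_width_nm,
        )
    except EvChipError as e:
        raise PipelineError("stats", str(e)) from e

    return StudyResult(
        response_tables=responses,
        cv=cv,
        reference=reference,
        profiles=profiles,
        profile_comparison=profile_cmp,
        particles=particles,
        comparison=comparison,
        warnings=warnings,
    )


def write_report(result: StudyResult, cfg: PipelineConfig) -> Path:
    """Write the report bundle: TSV tables plus a JSON manifest carrying
    the package version, config hash, seed and accumulated warnings."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.response_tables.to_csv(out / "ligand_responses.tsv", sep="\t", index=False, float_format="%.9g")
    result.cv.to_csv(out / "cv_table.tsv", sep="\t", float_format="%.9g")
    profile_table(result.profiles).to_csv(
        out / "phenotype_profile.tsv", sep="\t", index=False, float_format="%.9g"
    )
    result.profile_comparison.to_csv(
        out / "profile_comparison.tsv", sep="\t", index=False, float_format="%.9g"
    )
    particles_dir = out / "particles"
    particles_dir.mkdir(exist_ok=True)
    for (ligand, cond), table in sorted(result.particles.items()):
        write_particle_table(
            table, particles_dir / f"{ligand.replace('/', '_')}_{cond}.csv"
        )
    heatmap_table(result.comparison.histograms).to_csv(
        out / "size_heatmap.tsv", sep="\t", index=False, float_format="%.9g"
    )
    if result.comparison.window_tables:
        windows = pd.concat(
            [t.assign(ligand=lig) for lig, t in sorted(result.comparison.window_tables.items())],
            ignore_index=True,
        )
    else:
        windows = pd.DataFrame()
    windows.to_csv(out / "window_differences.tsv", sep="\t", index=False, float_format="%.9g")
    result.comparison.summary.to_csv(
        out / "significance_summary.tsv", sep="\t", index=False, float_format="%.9g"
    )
    manifest = {
        "evchip_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "reference_ligand": result.reference,
        "warnings": result.warnings,
    }
    (out / "report_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def run_pipeline(cfg: PipelineConfig) -> StudyResult:
    """Load the dataset named in the config, analyze, write the report."""
    bundle = load_study(cfg.dataset_dir)
    result = analyze_study(bundle, cfg)
    write_report(result, cfg)
    return result


def simulate_to_dir(scenario: str, seed: int, out_dir: str | Path, **kwargs) -> Path:
    """Generate a study bundle under ``scenario`` and save it."""
    bundle = simulate_study(scenario, seed, **kwargs)
    return bundle.save(out_dir)
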