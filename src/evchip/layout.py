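"""Biochip spot-grid model.

A multiplexed SPRi biochip carries a rectangular grid of antibody/protein
spots. Capture ligands sit in vertical columns, interleaved column-wise
with an irrelevant-IgG negative control (anti-ovalbumin) that samples
nonspecific binding across the whole chip. This module builds such
layouts, maps regions of interest (ROIs, one per spot) to ligand
families, and serializes layouts to JSON/TSV.

The canonical panel is ten capture ligands plus anti-OVA on a 10 x 10
grid: each of the five capture columns hosts two ligands (five spots
each, in consecutive row blocks), the five interleaved columns are all
negative control — 100 spots, 50 of them control, 5 analysis spots per
ligand family.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ConfigurationError, LigandNotFoundError

ROLE_CAPTURE = "capture"
ROLE_NEGATIVE_CONTROL = "negative_control"
ROLE_REFERENCE_CANDIDATE = "reference_candidate"
_VALID_ROLES = {ROLE_CAPTURE, ROLE_NEGATIVE_CONTROL, ROLE_REFERENCE_CANDIDATE}


@dataclass(frozen=True)
class LigandSpec:
    """One member of the grafted ligand panel.

    ``grafting_ph`` is carried as metadata only; it documents the buffer
    used when spotting the ligand and plays no computational role.
    """

    name: str
    role: str = ROLE_CAPTURE
    grafting_ph: float | None = None

    def __post_init__(self) -> None:
        if self.role not in _VALID_ROLES:
            raise ConfigurationError(
                f"ligand {self.name!r}: unknown role {self.role!r}; "
                f"expected one of {sorted(_VALID_ROLES)}"
            )


@dataclass(frozen=True)
class BiochipLayout:
    """A spot grid with a ligand name at every (row, col) position."""

    n_rows: int
    n_cols: int
    panel: tuple[LigandSpec, ...]
    spots: tuple[tuple[int, int, str], ...]  # (row, col, ligand name)
    spot_diameter_um: float = 200.0
    pitch_um: float = 600.0

    def __post_init__(self) -> None:
        # canonical row-major spot order, whatever the build order was
        object.__setattr__(self, "spots", tuple(sorted(self.spots)))
        names = [l.name for l in self.panel]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate ligand names in panel")
        controls = [l for l in self.panel if l.role == ROLE_NEGATIVE_CONTROL]
        if len(controls) != 1:
            raise ConfigurationError(
                f"panel must contain exactly one negative control, found {len(controls)}"
            )
        if len(self.spots) != self.n_rows * self.n_cols:
            raise ConfigurationError(
                f"{len(self.spots)} spots for a {self.n_rows}x{self.n_cols} grid"
            )
        known = set(names)
        positions = set()
        for r, c, name in self.spots:
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise ConfigurationError(f"spot ({r},{c}) outside grid")
            if (r, c) in positions:
                raise ConfigurationError(f"duplicate spot position ({r},{c})")
            positions.add((r, c))
            if name not in known:
                raise ConfigurationError(f"spot ({r},{c}) carries unknown ligand {name!r}")

    # -- lookups ---------------------------------------------------------

    @property
    def negative_control(self) -> str:
        return next(l.name for l in self.panel if l.role == ROLE_NEGATIVE_CONTROL)

    @property
    def capture_ligands(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.panel if l.role != ROLE_NEGATIVE_CONTROL)

    @property
    def ligand_names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.panel)

    def spot_index(self, row: int, col: int) -> int:
        """Row-major linear index of a grid position."""
        return row * self.n_cols + col

    def roi_id(self, row: int, col: int) -> str:
        return f"r{row:02d}c{col:02d}"

    @property
    def roi_ids(self) -> list[str]:
        """ROI ids for all spots in row-major order."""
        return [self.roi_id(r, c) for r, c, _ in sorted(self.spots)]

    def ligand_of_roi(self, roi_id: str) -> str:
        for r, c, name in self.spots:
            if self.roi_id(r, c) == roi_id:
                return name
        raise LigandNotFoundError(f"unknown ROI id {roi_id!r}")

    # -- serialization ---------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "spot_diameter_um": self.spot_diameter_um,
            "pitch_um": self.pitch_um,
            "panel": [
                {"name": l.name, "role": l.role, "grafting_ph": l.grafting_ph}
                for l in self.panel
            ],
            "spots": [list(s) for s in sorted(self.spots)],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "BiochipLayout":
        payload = json.loads(Path(path).read_text())
        return cls(
            n_rows=payload["n_rows"],
            n_cols=payload["n_cols"],
            panel=tuple(
                LigandSpec(p["name"], p["role"], p.get("grafting_ph"))
                for p in payload["panel"]
            ),
            spots=tuple((r, c, n) for r, c, n in payload["spots"]),
            spot_diameter_um=payload.get("spot_diameter_um", 200.0),
            pitch_um=payload.get("pitch_um", 600.0),
        )

    def to_tsv(self, path: str | Path) -> None:
        lines = ["row\tcol\tligand"]
        lines += [f"{r}\t{c}\t{n}" for r, c, n in sorted(self.spots)]
        Path(path).write_text("\n".join(lines) + "\n")


def default_panel() -> tuple[LigandSpec, ...]:
    """The endothelial-EV capture panel: ten capture ligands (tetraspanins,
    endothelial markers, stress-related targets, ApoA, Annexin-V for
    phosphatidylserine) plus anti-OVA as the irrelevant negative control.
    Grafting pH is metadata.
    """
    rows = [
        ("Annexin-V", 7.0),
        ("Anti-CD63", 5.5),
        ("Anti-CD9", 6.0),
        ("Anti-CD81", 4.0),
        ("Anti-CD44", 4.5),
        ("Anti-CD36", 4.5),
        ("Anti-NOX2", 4.5),
        ("Anti-Enolase", 7.0),
        ("Anti-ApoA", 4.0),
        ("Anti-VEGFR1", 6.0),
    ]
    panel = [LigandSpec(name, ROLE_CAPTURE, ph) for name, ph in rows]
    panel.append(LigandSpec("Anti-OVA", ROLE_NEGATIVE_CONTROL, 4.5))
    return tuple(panel)


def build_layout(
    panel: Sequence[LigandSpec],
    n_rows: int,
    n_cols: int,
    scheme: str = "alternating_columns",
) -> BiochipLayout:
    """Place a panel on an ``n_rows`` x ``n_cols`` grid.

    Under the ``alternating_columns`` scheme capture ligands occupy the
    even-indexed columns while the negative control fills every odd
    column. The capture ligands are distributed over the capture columns
    in panel order, ``k = n_capture / (n_cols/2)`` ligands per column,
    each holding a block of ``n_rows / k`` consecutive rows. With ten
    capture ligands on a 10 x 10 grid this yields two ligands per
    capture column and five spots per ligand family, and the control
    holds half the chip (50 spots).

    The function is pure: identical inputs give identical layouts.
    """
    if scheme != "alternating_columns":
        raise ConfigurationError(f"unknown placement scheme {scheme!r}")
    capture = [l for l in panel if l.role != ROLE_NEGATIVE_CONTROL]
    controls = [l for l in panel if l.role == ROLE_NEGATIVE_CONTROL]
    if len(controls) != 1:
        raise ConfigurationError(
            f"panel must contain exactly one negative control, found {len(controls)}"
        )
    if n_rows <= 0 or n_cols <= 0:
        raise ConfigurationError("grid dimensions must be positive")
    if n_cols % 2 != 0:
        raise ConfigurationError(
            f"alternating_columns needs an even column count, got {n_cols}"
        )
    n_capture_cols = n_cols // 2
    if not capture:
        raise ConfigurationError("panel has no capture ligands")
    if len(capture) % n_capture_cols != 0:
        raise ConfigurationError(
            f"{len(capture)} capture ligands do not fill {n_capture_cols} "
            f"capture columns evenly"
        )
    per_col = len(capture) // n_capture_cols
    if n_rows % per_col != 0:
        raise ConfigurationError(
            f"{n_rows} rows cannot be split among {per_col} ligands per column"
        )
    block = n_rows // per_col

    control_name = controls[0].name
    spots: list[tuple[int, int, str]] = []
    for col in range(n_cols):
        if col % 2 == 1:
            spots += [(row, col, control_name) for row in range(n_rows)]
            continue
        col_idx = col // 2
        ligands = capture[col_idx * per_col : (col_idx + 1) * per_col]
        for i, lig in enumerate(ligands):
            spots += [(row, col, lig.name) for row in range(i * block, (i + 1) * block)]

    return BiochipLayout(n_rows=n_rows, n_cols=n_cols, panel=tuple(panel), spots=tuple(spots))


def ligand_rois(layout: BiochipLayout, ligand: str) -> list[int]:
    """All spot indices (row-major) carrying ``ligand``.

    The union over the panel partitions the grid: every spot belongs to
    exactly one ligand family.
    """
    if ligand not in layout.ligand_names:
        raise LigandNotFoundError(f"ligand {ligand!r} not in layout panel")
    return sorted(
        layout.spot_index(r, c) for r, c, name in layout.spots if name == ligand
    )


def ligand_roi_ids(layout: BiochipLayout, ligand: str) -> list[str]:
    """ROI-id variant of :func:`ligand_rois` (same spots, string ids)."""
    if ligand not in layout.ligand_names:
        raise LigandNotFoundError(f"ligand {ligand!r} not in layout panel")
    return [
        layout.roi_id(r, c)
        for r, c, name in sorted(layout.spots)
        if name == ligand
    ]
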