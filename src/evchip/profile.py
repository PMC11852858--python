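"""Cross-experiment phenotype profiling of EV surface markers.

Each SPRi experiment yields one adjusted mean response per ligand. To
compare experiments run on different days/preparations, responses are
normalized within each experiment by a reference ligand, chosen as the
ligand whose response is most reproducible across experiments: the one
minimizing the worse of its two per-condition coefficients of variation
(sample sd / mean over experiments). Normalized responses are then
averaged per condition into a phenotype profile, and control vs treated
profiles are compared ligand by ligand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ComparisonError, ConfigurationError, NormalizationError, SelectionError

log = logging.getLogger(__name__)


@dataclass
class ResponseMatrix:
    """Adjusted mean responses: one row per experiment, one column per
    ligand, with a condition label per experiment."""

    responses: pd.DataFrame  # index: experiment id, columns: ligands
    condition: pd.Series  # index: experiment id -> "control" | "treated"

    def __post_init__(self) -> None:
        if not self.responses.index.equals(self.condition.index):
            raise ConfigurationError("responses and condition must share experiment ids")
        counts = self.condition.value_counts()
        if (counts < 1).any() or counts.empty:
            raise ConfigurationError("need >= 1 experiment per condition")

    @property
    def conditions(self) -> list[str]:
        return sorted(self.condition.unique())

    def subset(self, condition: str) -> pd.DataFrame:
        return self.responses.loc[self.condition[self.condition == condition].index]

    def drop_ligands(self, ligands: list[str]) -> "ResponseMatrix":
        present = [l for l in ligands if l in self.responses.columns]
        if present:
            log.info("excluding ligands from profile: %s", ", ".join(present))
        return ResponseMatrix(
            responses=self.responses.drop(columns=present), condition=self.condition
        )


@dataclass
class PhenotypeProfile:
    """Per-condition normalized marker profile. The reference ligand's
    normalized value is 1 in every experiment, hence mean 1 and sd 0."""

    condition: str
    reference_ligand: str
    mean: pd.Series  # per ligand, over experiments
    sd: pd.Series
    n_experiments: int


def response_matrix_from_tables(tables: list[pd.DataFrame]) -> ResponseMatrix:
    """Build a ResponseMatrix from per-experiment ligand-response tables
    (as produced by :func:`evchip.spri.ligand_response_table`)."""
    long = pd.concat(tables, ignore_index=True)
    wide = long.pivot(index="experiment", columns="ligand", values="mean_response_pct")
    cond = long.drop_duplicates("experiment").set_index("experiment")["condition"]
    return ResponseMatrix(responses=wide, condition=cond.loc[wide.index])


def cv_table(rm: ResponseMatrix) -> pd.DataFrame:
    """Per-ligand, per-condition coefficient of variation
    (sample sd / mean over that condition's experiments).

    Requires >= 2 experiments per condition. Ligands whose mean response
    is not positive in some condition are flagged ineligible (their CV
    is reported as NaN for that condition).
    """
    rows = {}
    eligible = {}
    for cond in rm.conditions:
        sub = rm.subset(cond)
        if len(sub) < 2:
            raise ConfigurationError(
                f"CV undefined: condition {cond!r} has only {len(sub)} experiment(s)"
            )
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        cv = sd / mean
        cv[mean <= 0] = np.nan
        rows[cond] = cv
        eligible[cond] = mean > 0
    out = pd.DataFrame(rows)
    out["eligible"] = pd.DataFrame(eligible).all(axis=1)
    return out


def select_reference(cvs: pd.DataFrame, override: str | None = None) -> str:
    """Reference ligand: the eligible ligand minimizing the maximum of
    its per-condition CVs; ties broken by lower mean CV, then by name.

    ``override`` forces a specific (eligible) ligand, bypassing the
    criterion.
    """
    cond_cols = [c for c in cvs.columns if c != "eligible"]
    eligible = cvs[cvs["eligible"]] if "eligible" in cvs.columns else cvs
    if override is not None:
        if override not in cvs.index:
            raise SelectionError(f"forced reference {override!r} not in CV table")
        log.info("reference forced to %s by configuration", override)
        return override
    if eligible.empty:
        raise SelectionError("no ligand has a positive mean response in all conditions")
    worst = eligible[cond_cols].max(axis=1)
    mean_cv = eligible[cond_cols].mean(axis=1)
    order = sorted(eligible.index, key=lambda l: (worst[l], mean_cv[l], l))
    chosen = order[0]
    runners = ", ".join(f"{l} (max CV {worst[l]:.3f})" for l in order[1:4])
    log.info(
        "reference ligand %s (max CV %.3f); runners-up: %s", chosen, worst[chosen], runners
    )
    return chosen


def normalize_profile(rm: ResponseMatrix, reference: str) -> dict[str, PhenotypeProfile]:
    """Divide each experiment's responses by that experiment's reference
    response, then summarize per condition (mean and sample sd over
    experiments of the normalized values)."""
    if reference not in rm.responses.columns:
        raise NormalizationError(f"reference ligand {reference!r} not in matrix")
    ref = rm.responses[reference]
    bad = ref[ref <= 0]
    if len(bad):
        raise NormalizationError(
            f"reference {reference!r} response not positive in experiment(s): "
            f"{', '.join(map(str, bad.index))}"
        )
    normalized = rm.responses.div(ref, axis=0)
    out = {}
    for cond in rm.conditions:
        sub = normalized.loc[rm.condition[rm.condition == cond].index]
        sd = sub.std(axis=0, ddof=1) if len(sub) > 1 else sub.iloc[0] * 0.0
        out[cond] = PhenotypeProfile(
            condition=cond,
            reference_ligand=reference,
            mean=sub.mean(axis=0),
            sd=sd,
            n_experiments=len(sub),
        )
    return out


def compare_profiles(
    control: PhenotypeProfile, treated: PhenotypeProfile
) -> pd.DataFrame:
    """Per-ligand treated-minus-control normalized difference and
    treated/control ratio, with the sd of the difference propagated in
    quadrature, ordered by decreasing |difference|."""
    if set(control.mean.index) != set(treated.mean.index):
        raise ComparisonError("profiles cover different ligand sets")
    ligands = control.mean.index
    diff = treated.mean[ligands] - control.mean[ligands]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = treated.mean[ligands] / control.mean[ligands]
    sd = np.sqrt(control.sd[ligands] ** 2 + treated.sd[ligands] ** 2)
    out = pd.DataFrame(
        {
            "ligand": ligands,
            "control_mean": control.mean[ligands].to_numpy(),
            "treated_mean": treated.mean[ligands].to_numpy(),
            "difference": diff.to_numpy(),
            "ratio": ratio.to_numpy(),
            "difference_sd": sd.to_numpy(),
        }
    )
    return out.reindex(out["difference"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )


def profile_table(profiles: dict[str, PhenotypeProfile]) -> pd.DataFrame:
    """Long-form (ligand, condition, normalized mean, sd) table for TSV
    export."""
    rows = []
    for cond, prof in sorted(profiles.items()):
        for ligand in prof.mean.index:
            rows.append(
                {
                    "ligand": ligand,
                    "condition": cond,
                    "normalized_mean": prof.mean[ligand],
                    "normalized_sd": prof.sd[ligand],
                    "reference": prof.reference_ligand,
                    "n_experiments": prof.n_experiments,
                }
            )
    return pd.DataFrame(rows)
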