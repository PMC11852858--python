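"""Large-EV size statistics and condition comparison.

Large EVs (lEVs) are operationally defined as particles with maximum
diameter strictly greater than 200 nm. Their per-ligand size structure
is summarized three ways:

* a 100 nm-binned histogram over [200, 1000) nm with an overflow bin,
  expressed as percentages of that ligand/condition's lEVs;
* window differences (treated minus control percentage of lEVs) over
  the four diameter windows 200-400, 400-600, 600-800, 800-1000 nm —
  positive means more lEVs in the treated condition;
* a two-sided Mann-Whitney U test per ligand, run separately on maximum
  diameter and on height, with the per-ligand result classified as
  ``++`` (both parameters significant), ``+`` (exactly one) or ``=``
  (neither) at alpha = 0.05.

The U statistic uses midranks for ties. The p-value is exact (full
enumeration of group assignments) for small tie-free samples and a
tie- and continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import ComparisonError, StatisticsError

log = logging.getLogger(__name__)

LEV_MIN_DIAMETER_NM = 200.0
DEFAULT_WINDOWS_NM = ((200.0, 400.0), (400.0, 600.0), (600.0, 800.0), (800.0, 1000.0))
DEFAULT_BIN_WIDTH_NM = 100.0
DEFAULT_RANGE_NM = (200.0, 1000.0)
DEFAULT_ALPHA = 0.05

#: Largest group size for which the tie-free exact p-value is used
#: automatically.
EXACT_MAX_N = 8
#: Cap on C(n+m, n) when exact mode is forced on tied data.
EXACT_MAX_COMBINATIONS = 200_000


@dataclass(frozen=True)
class SizeDistribution:
    ligand: str
    condition: str
    bin_labels: tuple[str, ...]
    bin_edges_nm: tuple[float, ...]  # interior edges incl. range bounds
    counts: tuple[int, ...]
    percentages: tuple[float, ...]

    @property
    def n_particles(self) -> int:
        return int(sum(self.counts))


@dataclass(frozen=True)
class MWUResult:
    u_statistic: float  # U of the first sample
    p_value: float
    n_x: int
    n_y: int
    method: str  # "exact" | "normal_tie_corrected"
    ligand: str = ""
    parameter: str = ""


@dataclass(frozen=True)
class SignificanceLabel:
    ligand: str
    label_diameter: str  # "+" | "="
    label_height: str
    combined: str  # "++" | "+" | "="


@dataclass
class ConditionComparison:
    """Bundle of all per-ligand control-vs-treated size statistics."""

    summary: pd.DataFrame
    histograms: dict[tuple[str, str], SizeDistribution]
    window_tables: dict[str, pd.DataFrame]


# ---------------------------------------------------------------------------
# Filtering and histograms
# ---------------------------------------------------------------------------

def filter_levs(
    particles: pd.DataFrame, min_diameter_nm: float = LEV_MIN_DIAMETER_NM
) -> pd.DataFrame:
    """Keep particles with max diameter strictly greater than the cut."""
    out = particles[particles["max_diameter_nm"] > min_diameter_nm].reset_index(drop=True)
    if len(out) == 0:
        log.warning("no particles above %.0f nm after lEV filtering", min_diameter_nm)
    return out


def size_histogram(
    particles: pd.DataFrame,
    ligand: str = "",
    condition: str = "",
    bin_width_nm: float = DEFAULT_BIN_WIDTH_NM,
    range_nm: tuple[float, float] = DEFAULT_RANGE_NM,
) -> SizeDistribution:
    """Half-open 100 nm bins over [200, 1000) plus an overflow bin for
    particles at or above the upper range bound. Percentages are over
    all included particles of this ligand/condition."""
    lo, hi = range_nm
    n_bins = int(round((hi - lo) / bin_width_nm))
    edges = [lo + i * bin_width_nm for i in range(n_bins + 1)]
    d = particles["max_diameter_nm"].to_numpy(dtype=float)
    counts = []
    labels = []
    for i in range(n_bins):
        a, b = edges[i], edges[i + 1]
        counts.append(int(((d >= a) & (d < b)).sum()))
        labels.append(f"{a:g}-{b:g}")
    counts.append(int((d >= hi).sum()))
    labels.append(f">={hi:g}")
    total = sum(counts)
    if total == 0:
        log.warning("empty size distribution for %s/%s", ligand, condition)
        pct = [0.0] * len(counts)
    else:
        pct = [100.0 * c / total for c in counts]
    return SizeDistribution(
        ligand=ligand,
        condition=condition,
        bin_labels=tuple(labels),
        bin_edges_nm=tuple(edges),
        counts=tuple(counts),
        percentages=tuple(pct),
    )


def window_difference(
    control_particles: pd.DataFrame,
    treated_particles: pd.DataFrame,
    windows_nm: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS_NM,
) -> pd.DataFrame:
    """Per diameter window, the percentage of each condition's lEVs and
    the difference treated minus control (positive = more lEVs in the
    treated condition). Both inputs must already be lEV-filtered."""
    dc = control_particles["max_diameter_nm"].to_numpy(dtype=float)
    dt = treated_particles["max_diameter_nm"].to_numpy(dtype=float)
    if dc.size == 0 or dt.size == 0:
        raise StatisticsError(
            "window percentages undefined: a condition has zero large EVs "
            f"(control n={dc.size}, treated n={dt.size})"
        )
    rows = []
    for a, b in windows_nm:
        pc = 100.0 * ((dc >= a) & (dc < b)).sum() / dc.size
        pt = 100.0 * ((dt >= a) & (dt < b)).sum() / dt.size
        rows.append(
            {
                "window": f"{a:g}-{b:g}",
                "pct_control": pc,
                "pct_treated": pt,
                "difference": pt - pc,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_from_ranks(ranks_x: np.ndarray, n_x: int) -> float:
    return float(ranks_x.sum() - n_x * (n_x + 1) / 2.0)


def _exact_p_two_sided(values: np.ndarray, n_x: int, u_obs: float) -> float:
    """Two-sided exact p by full enumeration of group assignments.

    Enumerates every way to assign ``n_x`` of the pooled observations to
    the first group, computing the midrank U for each. The two-sided
    p-value exploits the symmetry of the null U distribution about
    n_x*n_y/2: p = P(U <= u_low) + P(U >= n_x*n_y - u_low) with
    u_low = min(u, n_x*n_y - u), clamped to 1.
    """
    n = values.size
    n_y = n - n_x
    ranks = rankdata(values)  # midranks
    total = math.comb(n, n_x)
    if total > EXACT_MAX_COMBINATIONS:
        raise StatisticsError(
            f"exact enumeration over {total} assignments exceeds the "
            f"{EXACT_MAX_COMBINATIONS} cap"
        )
    nm = n_x * n_y
    u_low = min(u_obs, nm - u_obs)
    eps = 1e-9
    hits = 0
    offset = n_x * (n_x + 1) / 2.0
    for idx in itertools.combinations(range(n), n_x):
        u = ranks[list(idx)].sum() - offset
        if u <= u_low + eps or u >= nm - u_low - eps:
            hits += 1
    return min(1.0, hits / total)


def _normal_p_two_sided(values: np.ndarray, n_x: int, u_obs: float) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    n = values.size
    n_y = n - n_x
    nm = n_x * n_y
    mu = nm / 2.0
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = nm / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0  # all observations identical
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return min(1.0, 2.0 * float(norm.sf(z)))


def mann_whitney_u(
    x,
    y,
    mode: str = "auto",
    ligand: str = "",
    parameter: str = "",
) -> MWUResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    ``mode='auto'`` uses the exact enumeration when both groups have at
    most 8 observations and the pooled sample is tie-free, and the
    tie-corrected normal approximation with continuity correction
    otherwise. ``mode='exact'`` forces enumeration (with midranks when
    ties are present); ``mode='normal'`` forces the approximation.
    The reported U is the U of ``x``; U_x + U_y = n_x * n_y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatisticsError("Mann-Whitney requires non-empty samples")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_x = _u_from_ranks(ranks[: x.size], x.size)
    has_ties = np.unique(pooled).size < pooled.size

    if mode == "auto":
        use_exact = x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N and not has_ties
    elif mode == "exact":
        use_exact = True
    elif mode == "normal":
        use_exact = False
    else:
        raise StatisticsError(f"unknown Mann-Whitney mode {mode!r}")

    if use_exact:
        p = _exact_p_two_sided(pooled, x.size, u_x)
        method = "exact"
    else:
        p = _normal_p_two_sided(pooled, x.size, u_x)
        method = "normal_tie_corrected"
    p = max(p, np.nextafter(0.0, 1.0))  # p is in (0, 1]
    return MWUResult(
        u_statistic=u_x,
        p_value=p,
        n_x=int(x.size),
        n_y=int(y.size),
        method=method,
        ligand=ligand,
        parameter=parameter,
    )


# ---------------------------------------------------------------------------
# Classification and the full comparison
# ---------------------------------------------------------------------------

def classify_significance(
    p_diameter: float,
    p_height: float,
    alpha: float = DEFAULT_ALPHA,
    ligand: str = "",
) -> SignificanceLabel:
    """Map the two per-parameter p-values to the ++/+/= scheme:
    ``+`` per parameter iff p < alpha; combined ``++`` iff both,
    ``+`` iff exactly one, ``=`` iff neither."""
    for name, p in (("diameter", p_diameter), ("height", p_height)):
        if not (0 < p <= 1):
            raise StatisticsError(f"invalid {name} p-value {p}")
    ld = "+" if p_diameter < alpha else "="
    lh = "+" if p_height < alpha else "="
    n_sig = (ld == "+") + (lh == "+")
    combined = {2: "++", 1: "+", 0: "="}[n_sig]
    return SignificanceLabel(
        ligand=ligand, label_diameter=ld, label_height=lh, combined=combined
    )


def compare_conditions(
    control_tables: dict[str, pd.DataFrame],
    treated_tables: dict[str, pd.DataFrame],
    alpha: float = DEFAULT_ALPHA,
    windows_nm: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS_NM,
    bin_width_nm: float = DEFAULT_BIN_WIDTH_NM,
    range_nm: tuple[float, float] = DEFAULT_RANGE_NM,
    mwu_mode: str = "auto",
    holm: bool = False,
) -> ConditionComparison:
    """Full per-ligand comparison of pooled particle tables.

    Per ligand present in both conditions: lEV filter, size histograms,
    window differences, Mann-Whitney on max diameter and on height, and
    the ++/+/= label. Ligands present in only one condition are skipped
    with a warning. ``holm`` optionally applies a Holm step-down
    correction across ligands per parameter (off by default).
    """
    ligands = sorted(set(control_tables) & set(treated_tables))
    skipped = sorted(set(control_tables) ^ set(treated_tables))
    for lig in skipped:
        log.warning("ligand %s present in only one condition; skipped", lig)

    histograms: dict[tuple[str, str], SizeDistribution] = {}
    window_tables: dict[str, pd.DataFrame] = {}
    raw: list[dict] = []
    for lig in ligands:
        c_lev = filter_levs(control_tables[lig])
        t_lev = filter_levs(treated_tables[lig])
        histograms[(lig, "control")] = size_histogram(
            c_lev, lig, "control", bin_width_nm, range_nm
        )
        histograms[(lig, "treated")] = size_histogram(
            t_lev, lig, "treated", bin_width_nm, range_nm
        )
        if len(c_lev) == 0 or len(t_lev) == 0:
            log.warning("ligand %s has zero lEVs in a condition; tests skipped", lig)
            continue
        window_tables[lig] = window_difference(c_lev, t_lev, windows_nm)
        res_d = mann_whitney_u(
            c_lev["max_diameter_nm"], t_lev["max_diameter_nm"], mwu_mode, lig, "max_diameter"
        )
        res_h = mann_whitney_u(
            c_lev["height_nm"], t_lev["height_nm"], mwu_mode, lig, "height"
        )
        raw.append(
            {
                "ligand": lig,
                "n_control": res_d.n_x,
                "n_treated": res_d.n_y,
                "p_diameter": res_d.p_value,
                "p_height": res_h.p_value,
                "u_diameter": res_d.u_statistic,
                "u_height": res_h.u_statistic,
                "method": res_d.method,
            }
        )

    if holm and raw:
        for key in ("p_diameter", "p_height"):
            adj = _holm(np.array([r[key] for r in raw]))
            for r, p in zip(raw, adj):
                log.info("Holm %s for %s: %.4g -> %.4g", key, r["ligand"], r[key], p)
                r[key] = float(p)

    rows = []
    for r in raw:
        label = classify_significance(r["p_diameter"], r["p_height"], alpha, r["ligand"])
        rows.append(
            {
                **r,
                "label_diameter": label.label_diameter,
                "label_height": label.label_height,
                "combined": label.combined,
            }
        )
    summary = pd.DataFrame(
        rows,
        columns=[
            "ligand",
            "n_control",
            "n_treated",
            "p_diameter",
            "p_height",
            "u_diameter",
            "u_height",
            "method",
            "label_diameter",
            "label_height",
            "combined",
        ],
    )
    return ConditionComparison(summary=summary, histograms=histograms, window_tables=window_tables)


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def heatmap_table(
    histograms: dict[tuple[str, str], SizeDistribution]
) -> pd.DataFrame:
    """Long-form ligand x bin percentage table (one row per ligand,
    condition, bin) ready for TSV export or plotting."""
    rows = []
    for (lig, cond), dist in sorted(histograms.items()):
        for label, pct, count in zip(dist.bin_labels, dist.percentages, dist.counts):
            rows.append(
                {
                    "ligand": lig,
                    "condition": cond,
                    "bin": label,
                    "count": count,
                    "percentage": pct,
                }
            )
    return pd.DataFrame(rows)
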