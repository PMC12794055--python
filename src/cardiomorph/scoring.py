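"""Well-level aggregation, percent-of-control normalization, the
Hypertrophy Score, toxicity flags and inhibitor-efficacy metrics.

The Hypertrophy Score is the equally-weighted arithmetic mean of the three
phenotype parameters most consistently altered by hypertrophic
stimulation — CM area, CM nuclear area and alpha-actinin intensity — each
expressed as percent of the vehicle (DMSO) control:

    score = (cm_area_pct + nuc_area_pct + intensity_pct) / 3

Inhibitor efficacy at a dose is window-normalized inhibition,

    I(dose) = 100 * (score_stim - score_dose) / (score_stim - score_vehicle),

so 0 means no effect and 100 means full return to vehicle baseline; the
effect at 8 uM (I_8uM) serves for cross-compound comparison and a
four-parameter logistic fit of I versus log-dose yields the cellular IC50.
Toxicity is flagged from raw counts (CM and non-CM nuclei versus control)
because dying cells shrink and can falsely mimic an antihypertrophic
response — the score of a flagged well is reported but marked.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io import PlateLayout, ValidationError

#: Phenotype parameters normalized to vehicle control, in the fixed order
#: used by radar exports.
PROFILE_PARAMETERS = (
    "mean_cm_area_um2",
    "mean_cm_nuclear_area_um2",
    "mean_cm_actinin_intensity",
    "mean_nuclearity",
    "cm_count",
    "noncm_nucleus_count",
    "total_nucleus_count",
)

SCORE_COMPONENTS = (
    "mean_cm_area_um2",
    "mean_cm_nuclear_area_um2",
    "mean_cm_actinin_intensity",
)

RADAR_AXIS_RANGE = (50.0, 350.0)


class NormalizationError(ValueError):
    pass


class WindowError(ValueError):
    """No hypertrophic window (stimulated score <= vehicle score)."""


class InsufficientDataError(ValueError):
    pass


@dataclass
class WellSummary:
    """Per-well aggregate: raw counts, phenotype means and percent-of-control
    values (filled in by :func:`normalize_to_control`)."""

    well_id: str
    n_fields: int
    treatment_label: str = ""
    role: str = ""
    concentration_uM: float = 0.0
    # Raw counts are border-inclusive.
    cm_count: int = 0
    cm_nucleus_count: int = 0
    noncm_nucleus_count: int = 0
    total_nucleus_count: int = 0
    # Morphometrics over interior (non-border) objects pooled across fields.
    mean_cm_area_um2: float = float("nan")
    mean_cm_nuclear_area_um2: float = float("nan")
    mean_cm_actinin_intensity: float = float("nan")
    mean_nuclearity: float = float("nan")
    pct: dict[str, float] = field(default_factory=dict)

    def raw(self, name: str) -> float:
        return float(getattr(self, name))


@dataclass
class ScoreResult:
    label: str
    hypertrophy_score: float
    cm_area_pct: float
    nuc_area_pct: float
    intensity_pct: float
    toxicity_flag: str = "none"
    replicate_sem: float = float("nan")
    n_replicates: int = 1


@dataclass
class EfficacyResult:
    """Dose-response fit outcome for one compound."""

    compound_label: str
    i_8uM: float = float("nan")
    cellular_ic50_uM: float | None = None
    hill: float = float("nan")
    top: float = float("nan")
    residual_norm: float = float("nan")
    converged: bool = False


def aggregate_well(
    object_tables: Sequence[pd.DataFrame],
    layout_row: Mapping | None = None,
    zero_cm_warning: bool = True,
) -> WellSummary:
    """Pool one well's per-field object tables into a :class:`WellSummary`.

    Counts are summed across fields (border objects included); phenotype
    parameters are means over all qualifying (interior) objects pooled
    across the well's fields.  A well with zero CMs keeps its counts but
    gets missing phenotype parameters with a warning.
    """
    if not object_tables:
        raise InsufficientDataError("no fields supplied for well")
    table = pd.concat(list(object_tables), ignore_index=True)
    well_id = str(table["well_id"].iloc[0]) if len(table) else ""

    cells = table[table["object_class"] == "cm_cell"]
    cm_nuc = table[table["object_class"] == "cm_nucleus"]
    noncm_nuc = table[table["object_class"] == "noncm_nucleus"]

    cells_in = cells[~cells["touches_border"].astype(bool)]
    cm_nuc_in = cm_nuc[~cm_nuc["touches_border"].astype(bool)]

    summary = WellSummary(
        well_id=well_id,
        n_fields=len(object_tables),
        cm_count=len(cells),
        cm_nucleus_count=len(cm_nuc),
        noncm_nucleus_count=len(noncm_nuc),
        total_nucleus_count=len(cm_nuc) + len(noncm_nuc),
    )
    if layout_row is not None:
        summary.treatment_label = str(layout_row.get("treatment_label", ""))
        summary.role = str(layout_row.get("role", ""))
        summary.concentration_uM = float(layout_row.get("concentration_uM", 0.0))

    if len(cells_in):
        summary.mean_cm_area_um2 = float(cells_in["area_um2"].mean())
        summary.mean_cm_actinin_intensity = float(cells_in["mean_intensity"].mean())
        summary.mean_nuclearity = float(cells_in["nuclearity"].mean())
    elif zero_cm_warning:
        warnings.warn(
            f"well {well_id!r}: no interior CM; phenotype parameters missing",
            stacklevel=2,
        )
    if len(cm_nuc_in):
        summary.mean_cm_nuclear_area_um2 = float(cm_nuc_in["area_um2"].mean())
    return summary


def normalize_to_control(
    summaries: Sequence[WellSummary], layout: PlateLayout
) -> list[WellSummary]:
    """Fill percent-of-control values: each parameter divided by its mean
    over the plate's vehicle wells, times 100.

    By construction the mean of each normalized parameter over vehicle
    wells is exactly 100.
    """
    vehicle_ids = set(layout.vehicle_wells)
    vehicle = [s for s in summaries if s.well_id in vehicle_ids]
    if not vehicle:
        raise ValidationError("no vehicle well among summaries")
    for s in summaries:
        for name in PROFILE_PARAMETERS:
            ref_vals = [v.raw(name) for v in vehicle if np.isfinite(v.raw(name))]
            if not ref_vals:
                s.pct[name] = float("nan")
                continue
            ref = float(np.mean(ref_vals))
            if ref <= 0:
                raise NormalizationError(
                    f"vehicle mean of {name} is {ref}; normalization undefined"
                )
            s.pct[name] = 100.0 * s.raw(name) / ref
    return list(summaries)


def hypertrophy_score(
    cm_area_pct: float, nuc_area_pct: float, intensity_pct: float
) -> float:
    """Equally-weighted mean of the three percent-of-control components.

    A missing (non-finite) component yields a missing score with a warning —
    components are never silently reweighted.
    """
    comps = (cm_area_pct, nuc_area_pct, intensity_pct)
    if not all(np.isfinite(c) for c in comps):
        warnings.warn("missing score component; score set to missing", stacklevel=2)
        return float("nan")
    if any(c <= 0 for c in comps):
        raise ValueError("score components must be positive percent values")
    # fsum: exactly-rounded, so the score is permutation-invariant bit-for-bit
    return math.fsum(comps) / 3.0


def score_well(summary: WellSummary) -> ScoreResult:
    """Hypertrophy Score of one normalized well."""
    a = summary.pct.get("mean_cm_area_um2", float("nan"))
    n = summary.pct.get("mean_cm_nuclear_area_um2", float("nan"))
    i = summary.pct.get("mean_cm_actinin_intensity", float("nan"))
    return ScoreResult(
        label=summary.well_id,
        hypertrophy_score=hypertrophy_score(a, n, i),
        cm_area_pct=a,
        nuc_area_pct=n,
        intensity_pct=i,
    )


def aggregate_scores(results: Sequence[ScoreResult], label: str) -> ScoreResult:
    """Mean +/- SEM of replicate-well scores for one condition."""
    vals = np.array([r.hypertrophy_score for r in results], dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise InsufficientDataError(f"no finite scores for condition {label!r}")
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan")
    mean3 = lambda attr: float(  # noqa: E731
        np.nanmean([getattr(r, attr) for r in results])
    )
    flags = [r.toxicity_flag for r in results]
    flag = "cm_loss" if "cm_loss" in flags else (
        "noncm_loss" if "noncm_loss" in flags else "none"
    )
    return ScoreResult(
        label=label,
        hypertrophy_score=float(vals.mean()),
        cm_area_pct=mean3("cm_area_pct"),
        nuc_area_pct=mean3("nuc_area_pct"),
        intensity_pct=mean3("intensity_pct"),
        toxicity_flag=flag,
        replicate_sem=sem,
        n_replicates=int(vals.size),
    )


def toxicity_flag(
    summary: WellSummary,
    control_cm_count: float,
    control_noncm_count: float,
    threshold_fraction: float = 0.7,
) -> str:
    """Count-based cardiotoxicity flag versus vehicle-control reference.

    ``cm_loss`` (dominant) when the CM count falls below
    ``threshold_fraction`` of the control mean; ``noncm_loss`` when the
    non-CM nucleus count does.  Wells flagged ``cm_loss`` must be excluded
    from efficacy ranking (their scores stay reported but marked).
    """
    if control_cm_count <= 0 or control_noncm_count <= 0:
        raise ValidationError("control reference counts must be > 0")
    if summary.cm_count < threshold_fraction * control_cm_count:
        return "cm_loss"
    if summary.noncm_nucleus_count < threshold_fraction * control_noncm_count:
        return "noncm_loss"
    return "none"


def inhibition_at_dose(
    score_at_dose: float, score_stimulated: float, score_vehicle: float
) -> float:
    """Window-normalized percent inhibition.

    100 = score fully restored to vehicle baseline; 0 = no effect; values
    below 0 (score above stimulated) and above 100 (overshoot below
    vehicle) are possible and reported as-is.
    """
    window = score_stimulated - score_vehicle
    if window <= 0:
        raise WindowError(
            "no hypertrophic window: stimulated score must exceed vehicle score"
        )
    # divide first: the full-rescue case is then exactly 100
    return 100.0 * ((score_stimulated - score_at_dose) / window)


def _logistic(log_dose: np.ndarray, top: float, log_ic50: float, hill: float) -> np.ndarray:
    return top / (1.0 + 10 ** ((log_ic50 - log_dose) * hill))


def fit_dose_response(
    doses_uM: Sequence[float],
    inhibitions: Sequence[float],
    compound_label: str = "",
    top_max: float = 100.0,
) -> EfficacyResult:
    """Fit percent inhibition versus log dose with a 4-parameter logistic
    (bottom fixed at 0, top free up to *top_max*).

    Requires >= 4 distinct positive doses.  The IC50 is reported only when
    the fit converges with an IC50 inside [min_dose/10, max_dose*10];
    otherwise ``cellular_ic50_uM`` is None with ``converged`` False.
    """
    doses = np.asarray(doses_uM, dtype=float)
    inh = np.asarray(inhibitions, dtype=float)
    pos = doses > 0
    doses, inh = doses[pos], inh[pos]
    if len(np.unique(doses)) < 4:
        raise InsufficientDataError("need >= 4 distinct positive doses")
    log_d = np.log10(doses)
    result = EfficacyResult(compound_label=compound_label)
    if np.ptp(inh) < 1e-9 or np.nanmax(inh) <= 0:
        return result  # flat / no signal: nothing to fit
    try:
        p0 = (min(max(np.max(inh), 10.0), top_max), float(np.median(log_d)), 1.0)
        popt, _ = curve_fit(
            _logistic,
            log_d,
            inh,
            p0=p0,
            bounds=([1e-6, np.min(log_d) - 2.0, 0.1], [top_max, np.max(log_d) + 2.0, 10.0]),
            maxfev=10000,
        )
    except RuntimeError:
        return result
    top, log_ic50, hill = (float(v) for v in popt)
    ic50 = 10.0**log_ic50
    result.residual_norm = float(np.linalg.norm(inh - _logistic(log_d, *popt)))
    result.top = top
    result.hill = hill
    if doses.min() / 10.0 <= ic50 <= doses.max() * 10.0:
        result.cellular_ic50_uM = ic50
        result.converged = True
    return result


def phenotype_profile(summary: WellSummary | Mapping[str, float]) -> pd.Series:
    """Ordered percent-of-control vector for radar display/export.

    Values are NOT clipped here; the radar axes clip to [50, 350] only at
    plot time.
    """
    pct = summary.pct if isinstance(summary, WellSummary) else dict(summary)
    return pd.Series(
        [float(pct.get(p, float("nan"))) for p in PROFILE_PARAMETERS],
        index=list(PROFILE_PARAMETERS),
        name=getattr(summary, "well_id", "profile"),
    )


def plot_radar(profiles: Mapping[str, pd.Series], path: str) -> None:
    """Radar plot of phenotype profiles; axes span 50-350% of control."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(PROFILE_PARAMETERS)
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    lo, hi = RADAR_AXIS_RANGE
    for label, prof in profiles.items():
        vals = np.clip(prof.to_numpy(dtype=float), lo, hi)
        closed = np.concatenate([vals, vals[:1]])
        ang = np.concatenate([angles, angles[:1]])
        ax.plot(ang, closed, label=label)
        ax.fill(ang, closed, alpha=0.1)
    ax.set_ylim(lo, hi)
    ax.set_xticks(angles)
    ax.set_xticklabels(PROFILE_PARAMETERS, fontsize=7)
    ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1), fontsize=8)
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)


def summaries_to_frame(summaries: Sequence[WellSummary]) -> pd.DataFrame:
    """Flatten summaries (raw + pct columns) into a well_summary table."""
    rows = []
    for s in summaries:
        row = {
            "well_id": s.well_id,
            "treatment_label": s.treatment_label,
            "role": s.role,
            "concentration_uM": s.concentration_uM,
            "n_fields": s.n_fields,
            "cm_count": s.cm_count,
            "cm_nucleus_count": s.cm_nucleus_count,
            "noncm_nucleus_count": s.noncm_nucleus_count,
            "total_nucleus_count": s.total_nucleus_count,
            "mean_cm_area_um2": s.mean_cm_area_um2,
            "mean_cm_nuclear_area_um2": s.mean_cm_nuclear_area_um2,
            "mean_cm_actinin_intensity": s.mean_cm_actinin_intensity,
            "mean_nuclearity": s.mean_nuclearity,
        }
        for p in PROFILE_PARAMETERS:
            row[f"{p}_pct"] = s.pct.get(p, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)
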