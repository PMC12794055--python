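"""Group statistics versus control and potency/lipophilicity correlations.

Conditions are compared to the vehicle control by one-way ANOVA followed
by Dunnett's many-to-one adjustment (the default; unadjusted or Bonferroni
t-tests are available), or by a plain unpaired t-test when exactly two
groups are present.  Significance stars follow the four-tier banding
* p<=0.05, ** p<=0.01, *** p<=0.001, **** p<=0.0001.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

STAR_THRESHOLDS = (0.05, 0.01, 0.001, 0.0001)


class InsufficientReplicatesError(ValueError):
    pass


@dataclass
class GroupComparison:
    condition: str
    n: int
    mean: float
    sem: float
    p_value: float
    test: str
    stars: str


@dataclass
class CorrelationReport:
    x_name: str
    y_name: str
    labels: list[str]
    x: list[float]
    y: list[float]
    pearson_r: float
    pearson_p: float
    spearman_r: float
    spearman_p: float
    excluded: dict[str, str]
    degenerate: bool = False


def significance_stars(p: float) -> str:
    """Map a p-value to the four-tier star banding."""
    if not np.isfinite(p):
        return ""
    stars = ""
    for t in STAR_THRESHOLDS:
        if p <= t:
            stars += "*"
    return stars


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    control: str,
    method: str = "one_way_anova_dunnett",
) -> list[GroupComparison]:
    """Compare each condition's replicate scores to the control group.

    ``one_way_anova_dunnett`` runs a one-way ANOVA and Dunnett-adjusted
    many-to-one comparisons; with exactly two groups it falls back to an
    unpaired t-test.  ``unpaired_t`` and ``bonferroni_t`` use unadjusted /
    Bonferroni-adjusted pairwise t-tests.  Every group needs >= 2
    replicates.
    """
    if control not in groups:
        raise KeyError(f"control group {control!r} missing")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise InsufficientReplicatesError(
                f"group {k!r} has {v.size} replicate(s); need >= 2"
            )
    treat_names = [k for k in arrays if k != control]
    ctrl = arrays[control]

    if method == "unpaired_t" or (method == "one_way_anova_dunnett" and len(treat_names) == 1):
        pvals = {
            k: float(sps.ttest_ind(arrays[k], ctrl, equal_var=True).pvalue)
            for k in treat_names
        }
        test_name = "unpaired_t"
    elif method == "bonferroni_t":
        m = len(treat_names)
        pvals = {
            k: min(1.0, m * float(sps.ttest_ind(arrays[k], ctrl, equal_var=True).pvalue))
            for k in treat_names
        }
        test_name = "bonferroni_t"
    elif method == "one_way_anova_dunnett":
        res = sps.dunnett(*(arrays[k] for k in treat_names), control=ctrl)
        pvals = dict(zip(treat_names, (float(p) for p in res.pvalue)))
        test_name = "one_way_anova_dunnett"
    else:
        raise ValueError(f"unknown method {method!r}")

    out = []
    for name in [control] + treat_names:
        v = arrays[name]
        p = 1.0 if name == control else pvals[name]
        out.append(
            GroupComparison(
                condition=name,
                n=int(v.size),
                mean=float(v.mean()),
                sem=float(v.std(ddof=1) / math.sqrt(v.size)),
                p_value=p,
                test=test_name if name != control else "control",
                stars="" if name == control else significance_stars(p),
            )
        )
    return out


def correlate_efficacy(
    annotations,
    efficacies,
    x_attr: str = "pic50_grk5",
    exclusions: Mapping[str, str] | Sequence[str] | None = None,
) -> CorrelationReport:
    """Correlate a biochemical descriptor (pIC50 or cLogP) with cellular
    efficacy (I_8uM).

    *exclusions* maps compound labels to a human-stated reason (e.g.
    cytotoxicity); excluded compounds are listed but not used.  Requires
    >= 3 paired points after exclusions; a constant vector gives a
    degenerate report (NaN coefficients) rather than an error.
    """
    if exclusions is None:
        excluded: dict[str, str] = {}
    elif isinstance(exclusions, Mapping):
        excluded = dict(exclusions)
    else:
        excluded = {str(label): "excluded" for label in exclusions}

    eff_by_label = {e.compound_label: e for e in efficacies}
    labels, xs, ys = [], [], []
    for ann in annotations:
        lbl = ann.compound_label
        if lbl in excluded or lbl not in eff_by_label:
            continue
        x = float(getattr(ann, x_attr))
        y = float(eff_by_label[lbl].i_8uM)
        if np.isfinite(x) and np.isfinite(y):
            labels.append(lbl)
            xs.append(x)
            ys.append(y)
    if len(labels) < 3:
        raise InsufficientReplicatesError(
            f"need >= 3 compounds after exclusions, have {len(labels)}"
        )
    x_arr, y_arr = np.asarray(xs), np.asarray(ys)
    if np.ptp(x_arr) == 0 or np.ptp(y_arr) == 0:
        return CorrelationReport(
            x_name=x_attr,
            y_name="i_8uM",
            labels=labels,
            x=xs,
            y=ys,
            pearson_r=float("nan"),
            pearson_p=float("nan"),
            spearman_r=float("nan"),
            spearman_p=float("nan"),
            excluded=excluded,
            degenerate=True,
        )
    pr = sps.pearsonr(x_arr, y_arr)
    sr = sps.spearmanr(x_arr, y_arr)
    return CorrelationReport(
        x_name=x_attr,
        y_name="i_8uM",
        labels=labels,
        x=xs,
        y=ys,
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_r=float(sr.statistic),
        spearman_p=float(sr.pvalue),
        excluded=excluded,
    )
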