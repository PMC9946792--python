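"""Network-level inference over per-electrode permutation outcomes.

Four families of questions, mirroring how intracranial mapping studies
summarize electrode-level effects:

* proportions — what fraction of electrodes in each network group shows
  a significant power increase/decrease, per band and contrast;
* mixed-effects contrasts — is the percent change larger inside one
  network than another, with electrodes nested in subjects (random
  intercept per subject, REML);
* spatial focality — are the significant electrodes of one band packed
  more tightly (smaller pairwise distances) than those of another;
* anterior-posterior shift — do the significant electrodes of two
  contrasts differ in their MNI y-coordinate (rank-based test).

Degrees of freedom for the mixed model follow the residual convention
``dof = n_observations - n_fixed_params``.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .data_model import ElectrodeTable, UNASSIGNED, ValidationError

__all__ = [
    "proportion_table",
    "lme_contrast",
    "distance_separation_test",
    "ap_shift_test",
    "fdr_correct",
]


def _apply_motor_exclusion(df: pd.DataFrame) -> pd.DataFrame:
    """Drop electrodes on motor cortex: gyrus label 'motor' when present,
    otherwise the somato-motor network label."""
    if "gyrus" in df.columns and df["gyrus"].notna().any():
        return df[df["gyrus"].fillna("") != "motor"]
    return df[df["network"] != "MOT"]


def proportion_table(
    results: pd.DataFrame,
    electrodes: ElectrodeTable,
    grouping: str = "fpn_vs_rest",
    focus_network: str = "FPN",
    exclude_motor: bool = False,
) -> pd.DataFrame:
    """Percent of electrodes significant per band x direction x group.

    ``results`` is a tidy frame with columns electrode, band, contrast,
    significant, direction (one row per electrode/band/contrast).
    ``grouping`` is ``"fpn_vs_rest"`` (inside vs outside
    ``focus_network``) or ``"network"`` (one group per network label).
    Counts are carried alongside every percentage so each figure is
    re-derivable as ``100 * n_sig / n_group``; empty groups report NA.
    """
    elec = electrodes.contacts[["name", "network", "gyrus"]].rename(columns={"name": "electrode"})
    merged = results.merge(elec, on="electrode", how="left", validate="many_to_one")
    if exclude_motor:
        merged = _apply_motor_exclusion(merged)
    if grouping == "fpn_vs_rest":
        merged["group"] = np.where(merged["network"] == focus_network,
                                   focus_network, f"non-{focus_network}")
    elif grouping == "network":
        merged["group"] = merged["network"].fillna(UNASSIGNED)
    else:
        raise ValidationError(f"unknown grouping {grouping!r}")
    rows = []
    for (band, contrast, group), grp in merged.groupby(["band", "contrast", "group"]):
        n_group = grp["electrode"].nunique()
        for direction in ("increase", "decrease"):
            n_sig = grp.loc[(grp["significant"]) & (grp["direction"] == direction),
                            "electrode"].nunique()
            rows.append({
                "band": band, "contrast": contrast, "group": group,
                "direction": direction, "n_group": n_group, "n_sig": n_sig,
                "percent": 100.0 * n_sig / n_group if n_group else np.nan,
            })
    return pd.DataFrame(rows)


def lme_contrast(
    percent_changes: np.ndarray,
    group_indicator: np.ndarray,
    subject_ids: np.ndarray,
    tail: str = "one",
) -> tuple[float, int, float]:
    """Mixed-effects contrast of percent change between two groups.

    Fits ``percent_change ~ 1 + group`` with a random intercept per
    subject by REML and returns ``(t, dof, p)`` for the group fixed
    effect, where ``group_indicator`` is 1 for the group predicted to be
    larger.  ``dof = n - 2`` (observations minus fixed-effect
    parameters).  One-tailed p is the upper tail of the t distribution
    (directional prediction that the indicated group is larger).

    When the between-subject variance collapses to zero (singular fit),
    the model degenerates to pooled ordinary least squares, which is
    then used directly with a warning.
    """
    y = np.asarray(percent_changes, dtype=float)
    g = np.asarray(group_indicator, dtype=float)
    subj = np.asarray(subject_ids)
    if y.shape != g.shape or y.shape != subj.shape:
        raise ValidationError("percent_changes, group_indicator and subject_ids must align")
    if len(np.unique(subj)) < 2:
        raise ValidationError("need at least two subjects for a mixed model")
    if len(np.unique(g)) < 2:
        raise ValidationError("need two groups for a contrast")
    exog = sm.add_constant(g)
    coef, se, t_val, _ = _fit_mixed(y, exog, subj)
    dof = y.size - exog.shape[1]
    p = _t_pvalue(t_val, dof, tail)
    return float(t_val), int(dof), float(p)


def lme_contrast_full(
    percent_changes: np.ndarray,
    group_indicator: np.ndarray,
    subject_ids: np.ndarray,
    tail: str = "one",
) -> dict:
    """As :func:`lme_contrast`, also exposing the fixed-effect estimate
    and its standard error (for effect-recovery and interval checks)."""
    y = np.asarray(percent_changes, dtype=float)
    exog = sm.add_constant(np.asarray(group_indicator, dtype=float))
    coef, se, t_val, used_ols = _fit_mixed(y, exog, np.asarray(subject_ids))
    dof = y.size - exog.shape[1]
    return {"coef": coef, "se": se, "t": t_val, "dof": dof,
            "p": _t_pvalue(t_val, dof, tail), "pooled_fallback": used_ols}


def _fit_mixed(y: np.ndarray, exog: np.ndarray, subj: np.ndarray) -> tuple[float, float, float, bool]:
    """Fixed-effect (last exog column) estimate, se and t from a
    random-intercept model, falling back to pooled OLS on singular fits."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        try:
            model = sm.MixedLM(y, exog, groups=subj)
            res = model.fit(reml=True)
            var_re = float(np.asarray(res.cov_re)[0, 0])
            coef = float(res.fe_params[-1])
            se = float(res.bse_fe[-1])
            if np.isfinite(se) and se > 0 and var_re > 1e-6 * max(res.scale, 1e-12):
                return coef, se, coef / se, False
        except Exception:
            pass
    warnings.warn("singular mixed-model fit; using pooled regression")
    ols = sm.OLS(y, exog).fit()
    return float(ols.params[-1]), float(ols.bse[-1]), float(ols.tvalues[-1]), True


def _t_pvalue(t_val: float, dof: int, tail: str) -> float:
    if tail == "one":
        return float(stats.t.sf(t_val, dof))
    if tail == "two":
        return float(2.0 * stats.t.sf(abs(t_val), dof))
    raise ValidationError(f"tail must be 'one' or 'two', got {tail!r}")


def network_lme_table(
    contrasts: pd.DataFrame,
    electrodes: ElectrodeTable,
    focus_network: str = "FPN",
    per_network: bool = False,
    tail: str = "one",
    exclude_motor: bool = False,
) -> pd.DataFrame:
    """Mixed-model contrasts of ``focus_network`` against the rest
    (default) or against each other network, per band and contrast.

    ``contrasts`` needs columns electrode, band, contrast,
    percent_change, subject.  Requires an electrode table with networks
    assigned.
    """
    elec = electrodes.contacts[["name", "network", "gyrus"]].rename(columns={"name": "electrode"})
    merged = contrasts.merge(elec, on="electrode", how="left", validate="many_to_one")
    if exclude_motor:
        merged = _apply_motor_exclusion(merged)
    merged = merged[merged["network"].notna() & (merged["network"] != UNASSIGNED)]
    rows = []
    for (band, contrast), grp in merged.groupby(["band", "contrast"]):
        others = ([n for n in grp["network"].unique() if n != focus_network]
                  if per_network else [None])
        for other in others:
            sub = grp if other is None else grp[grp["network"].isin([focus_network, other])]
            ind = (sub["network"] == focus_network).to_numpy(dtype=float)
            if len(np.unique(ind)) < 2 or sub["subject"].nunique() < 2:
                rows.append({"band": band, "contrast": contrast,
                             "versus": other or "all-others", "t": np.nan,
                             "dof": np.nan, "p": np.nan, "n": len(sub)})
                continue
            t, dof, p = lme_contrast(sub["percent_change"].to_numpy(), ind,
                                     sub["subject"].to_numpy(), tail=tail)
            rows.append({"band": band, "contrast": contrast,
                         "versus": other or "all-others",
                         "t": t, "dof": dof, "p": p, "n": len(sub)})
    return pd.DataFrame(rows)


def distance_separation_test(
    sig_coords: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Compare spatial focality of significant electrodes across bands.

    For each band, all pairwise Euclidean distances among its
    significant electrodes are computed; each band pair is then compared
    with an unpaired two-sample t-test on the distance sets.  Smaller
    mean distance = more focal.  Bands with fewer than two significant
    electrodes report NA.
    """
    dists = {}
    for band, coords in sig_coords.items():
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        dists[band] = pdist(coords) if len(coords) >= 2 else None
    rows = []
    for a, b in combinations(sig_coords.keys(), 2):
        if dists[a] is None or dists[b] is None:
            rows.append({"band_a": a, "band_b": b, "t": np.nan, "dof": np.nan,
                         "p": np.nan, "mean_dist_a": np.nan, "mean_dist_b": np.nan})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(dists[a], dists[b], equal_var=True)
        rows.append({
            "band_a": a, "band_b": b, "t": float(t),
            "dof": int(dists[a].size + dists[b].size - 2), "p": float(p),
            "mean_dist_a": float(dists[a].mean()), "mean_dist_b": float(dists[b].mean()),
        })
    return pd.DataFrame(rows)


def ap_shift_test(
    y_a: np.ndarray,
    y_b: np.ndarray,
    paired: bool = False,
) -> tuple[float, float, str]:
    """Rank-based comparison of anterior-posterior (MNI y) coordinates of
    two significant-electrode sets.

    Default is the unpaired Wilcoxon rank-sum test (the two sets need
    not share electrodes); when the sets coincide electrode-for-electrode
    a paired signed-rank variant is available.  Returns
    ``(statistic, p, direction)`` with direction ``"posterior"`` when
    set B sits at smaller y than set A, ``"anterior"`` when larger, and
    ``"none"`` for identical locations.  Degenerate sets (< 2 points,
    or unequal lengths for the paired variant) return NaN with a warning.
    """
    y_a = np.asarray(y_a, dtype=float)
    y_b = np.asarray(y_b, dtype=float)
    if min(y_a.size, y_b.size) < 2:
        warnings.warn("rank test undefined for sets with fewer than 2 electrodes")
        return float("nan"), float("nan"), "none"
    if paired:
        if y_a.size != y_b.size:
            warnings.warn("paired variant needs equal-length sets")
            return float("nan"), float("nan"), "none"
        diffs = y_b - y_a
        if np.allclose(diffs, 0):
            return 0.0, 1.0, "none"
        stat, p = stats.wilcoxon(y_b, y_a)
    else:
        stat, p = stats.ranksums(y_b, y_a)
    delta = float(np.median(y_b) - np.median(y_a))
    direction = "posterior" if delta < 0 else ("anterior" if delta > 0 else "none")
    return float(stat), float(p), direction


def fdr_correct(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg layer for the per-network contrasts (off by
    default in the pipeline; provided for completeness)."""
    from statsmodels.stats.multitest import multipletests

    reject, p_adj, _, _ = multipletests(p_values, alpha=alpha, method="fdr_bh")
    return reject, p_adj
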