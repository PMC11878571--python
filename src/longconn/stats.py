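"""Longitudinal statistics: paired tests, effect sizes, subgroup tests and
the end-to-end early-versus-late analysis.

The comparisons mirror a paired design: each patient contributes an early
and a late scan, and per-metric changes are tested with a two-sided paired
Wilcoxon signed-rank test at a fixed multiple-comparison threshold
(default P < 0.01). Effect sizes are paired Cohen's d on the difference
scores. Subgroup heterogeneity of the changes uses Kruskal–Wallis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .io import Cohort
from .metrics import (
    GLOBAL_METRIC_NAMES,
    NODAL_METRIC_NAMES,
    global_metrics,
    nodal_metrics,
)
from .normative import (
    NormativeModelSet,
    abnormal_burden,
    fit_normative_models,
)
from .thalamic import affected_lobe_z_of_z, lobe_keys, thalamocortical_connectivity

__all__ = [
    "LongitudinalResult",
    "LongitudinalAnalysis",
    "paired_wilcoxon",
    "cohens_d_paired",
    "subgroup_kruskal",
    "one_sample_t",
    "global_feature_table",
    "nodal_feature_table",
    "thalamic_feature_table",
    "run_longitudinal_analysis",
    "sensitivity_across_scales",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LongitudinalResult:
    """Paired early-vs-late comparison for one metric."""

    metric: str
    scale: int
    n_pairs: int
    median_early: float
    median_late: float
    p_value: float
    cohens_d: float
    significant: bool


def paired_wilcoxon(early: np.ndarray, late: np.ndarray) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped before ranking (Wilcoxon's original
    treatment). The exact null distribution is used for n ≤ 25 without tied
    absolute differences; otherwise the normal approximation with continuity
    correction. At least 5 nonzero differences are required.
    """
    early = np.asarray(early, dtype=float)
    late = np.asarray(late, dtype=float)
    if early.shape != late.shape:
        raise ValueError("early and late vectors must have equal length")
    diff = late - early
    nz = diff[diff != 0]
    if nz.size == 0:
        raise ValueError("degenerate pairs: all differences are zero")
    if nz.size < 5:
        raise ValueError(
            f"need at least 5 nonzero differences, got {nz.size}"
        )
    has_ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= 25 and not has_ties) else "approx"
    res = scipy.stats.wilcoxon(
        nz, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    return float(res.pvalue)


def cohens_d_paired(
    early: np.ndarray, late: np.ndarray, denominator: str = "diff"
) -> float:
    """Paired Cohen's d.

    Default ``diff``: mean(late − early) / SD(late − early) with the n−1
    denominator. The ``average`` variant divides by the pooled average of
    the two timepoint SDs instead.
    """
    early = np.asarray(early, dtype=float)
    late = np.asarray(late, dtype=float)
    if early.size < 2 or early.shape != late.shape:
        raise ValueError("need at least 2 pairs of equal length")
    diff = late - early
    if denominator == "diff":
        sd = diff.std(ddof=1)
    elif denominator == "average":
        sd = np.sqrt((early.std(ddof=1) ** 2 + late.std(ddof=1) ** 2) / 2.0)
    else:
        raise ValueError(f"unknown denominator variant {denominator!r}")
    if sd == 0:
        raise ValueError("zero standard deviation of differences")
    return float(diff.mean() / sd)


def subgroup_kruskal(changes: np.ndarray, labels) -> float:
    """Kruskal–Wallis p-value for heterogeneity of changes across subgroups.

    Groups with fewer than 2 members are dropped with a warning; at least
    two usable groups are required.
    """
    changes = np.asarray(changes, dtype=float)
    labels = np.asarray(labels)
    groups = []
    for lab in pd.unique(labels):
        vals = changes[labels == lab]
        if vals.size < 2:
            warnings.warn(f"subgroup {lab!r} has {vals.size} member(s); dropped", stacklevel=2)
            continue
        groups.append(vals)
    if len(groups) < 2:
        raise ValueError("fewer than 2 usable subgroups")
    return float(scipy.stats.kruskal(*groups).pvalue)


def one_sample_t(values: np.ndarray, mu: float = 0.0) -> tuple[float, float]:
    """Two-sided one-sample t-test of the mean against ``mu``.

    Returns (sample mean, p-value).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 observations")
    if values.std(ddof=1) == 0:
        raise ValueError("zero standard deviation")
    res = scipy.stats.ttest_1samp(values, popmean=mu)
    return float(values.mean()), float(res.pvalue)


# ---------------------------------------------------------------------------
# feature extraction


def _subject_scan_rows(cohort: Cohort, scale: int):
    for subj in cohort.subjects:
        for tp in subj.timepoints:
            yield subj, tp, cohort.connectome(subj.subject_id, tp, scale)


def global_feature_table(
    cohort: Cohort, scale: int, gamma: float = 1.0, seed: int = 0
) -> pd.DataFrame:
    """One row per subject-scan with the six global metrics as columns."""
    rows = []
    for subj, tp, conn in _subject_scan_rows(cohort, scale):
        gm = global_metrics(conn, gamma=gamma, seed=seed)
        rows.append(
            {
                "subject_id": subj.subject_id,
                "timepoint": tp,
                "group": subj.group,
                "age": subj.ages[tp],
                "sex": subj.sex,
                **gm.as_dict(),
            }
        )
    return pd.DataFrame(rows)


def nodal_feature_table(
    cohort: Cohort, scale: int, gamma: float = 1.0, seed: int = 0
) -> pd.DataFrame:
    """One row per subject-scan; one column per (metric, parcel) feature,
    named ``<metric>|<parcel_id>``."""
    rows = []
    for subj, tp, conn in _subject_scan_rows(cohort, scale):
        table = nodal_metrics(conn, gamma=gamma, seed=seed)
        row = {
            "subject_id": subj.subject_id,
            "timepoint": tp,
            "group": subj.group,
            "age": subj.ages[tp],
            "sex": subj.sex,
        }
        for metric in NODAL_METRIC_NAMES:
            vals = table[metric].to_numpy()
            for pid, v in zip(table["parcel_id"], vals):
                row[f"{metric}|{pid}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def thalamic_feature_table(cohort: Cohort, scale: int) -> pd.DataFrame:
    """One row per subject-scan; 10 thalamocortical lobe-sum columns named
    ``thal_<hemisphere>_<lobe>``."""
    parc = cohort.parcellations[scale]
    rows = []
    for subj, tp, conn in _subject_scan_rows(cohort, scale):
        profile = thalamocortical_connectivity(conn, parc)
        row = {
            "subject_id": subj.subject_id,
            "timepoint": tp,
            "group": subj.group,
            "age": subj.ages[tp],
            "sex": subj.sex,
        }
        for _, r in profile.iterrows():
            row[f"thal_{r['hemisphere']}_{r['lobe']}"] = r["streamline_sum"]
        rows.append(row)
    return pd.DataFrame(rows)


def _fit_on_controls(
    table: pd.DataFrame, include_age2: bool = False
) -> NormativeModelSet:
    controls = table[table["group"] == "control"]
    feature_cols = [
        c for c in table.columns
        if c not in ("subject_id", "timepoint", "group", "age", "sex")
    ]
    return fit_normative_models(
        controls[feature_cols],
        controls["age"].to_numpy(dtype=float),
        controls["sex"].to_numpy(),
        include_age2=include_age2,
    )


def _zscore_table(table: pd.DataFrame, models: NormativeModelSet) -> pd.DataFrame:
    """Z-score every feature column of a subject-scan table in place-like copy."""
    out = table[["subject_id", "timepoint", "group", "age", "sex"]].copy()
    ages = table["age"].to_numpy(dtype=float)
    sexes = table["sex"].to_numpy()
    for col in table.columns:
        if col in out.columns or str(col) not in models:
            continue
        out[col] = models[str(col)].zscore(table[col].to_numpy(), ages, sexes)
    return out


def _paired_frames(table: pd.DataFrame, patients) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align early and late rows over patients (same subject order)."""
    sids = [p.subject_id for p in patients]
    early = table[table["timepoint"] == "early"].set_index("subject_id").loc[sids]
    late = table[table["timepoint"] == "late"].set_index("subject_id").loc[sids]
    return early, late


def _compare(
    metric: str, scale: int, early: np.ndarray, late: np.ndarray, alpha: float,
    d_denominator: str = "diff",
) -> LongitudinalResult:
    try:
        p = paired_wilcoxon(early, late)
    except ValueError as exc:
        log.warning("%s: paired test degenerate (%s)", metric, exc)
        p = np.nan
    try:
        d = cohens_d_paired(early, late, denominator=d_denominator)
    except ValueError:
        d = np.nan
    return LongitudinalResult(
        metric=metric,
        scale=scale,
        n_pairs=len(early),
        median_early=float(np.median(early)),
        median_late=float(np.median(late)),
        p_value=p,
        cohens_d=d,
        significant=bool(p < alpha) if np.isfinite(p) else False,
    )


@dataclass
class LongitudinalAnalysis:
    """Bundle of every table the early-vs-late analysis produces."""

    scale: int
    n_pairs: int
    global_results: pd.DataFrame = field(default_factory=pd.DataFrame)
    global_residuals: pd.DataFrame = field(default_factory=pd.DataFrame)
    subgroup_results: pd.DataFrame = field(default_factory=pd.DataFrame)
    burden_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    burden_results: pd.DataFrame = field(default_factory=pd.DataFrame)
    thalamic_z: pd.DataFrame = field(default_factory=pd.DataFrame)
    thalamic_results: pd.DataFrame = field(default_factory=pd.DataFrame)
    z_of_z_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    z_of_z_mean: float = np.nan
    z_of_z_p: float = np.nan
    thalamic_modal_z: pd.DataFrame = field(default_factory=pd.DataFrame)
    thalamic_modal_results: pd.DataFrame = field(default_factory=pd.DataFrame)

    def results_frame(self, results: list[LongitudinalResult]) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in results])


def run_longitudinal_analysis(
    cohort: Cohort,
    scale: int = 3,
    *,
    z_threshold: float = 2.0,
    alpha: float = 0.01,
    gamma: float = 1.0,
    seed: int = 0,
    include_age2: bool = False,
    d_denominator: str = "diff",
    stages: tuple[str, ...] = ("global", "nodal", "thalamic"),
) -> LongitudinalAnalysis:
    """Run the full paired early-vs-late analysis at one parcellation scale.

    Stages: ``global`` — GLM residuals of the six global metrics compared
    with paired Wilcoxon, plus subgroup Kruskal–Wallis; ``nodal`` — per-node
    Z-scores, abnormal-node burden (total, > +threshold, < −threshold per
    metric) compared between scans; ``thalamic`` — per-lobe thalamocortical
    Z-scores, the affected-lobe z-of-z one-sample t-test, and thalamic modal
    controllability Z-scores.
    """
    patients = cohort.patients
    if len(patients) < 5:
        raise ValueError(f"need at least 5 complete patient pairs, got {len(patients)}")
    out = LongitudinalAnalysis(scale=scale, n_pairs=len(patients))

    if "global" in stages:
        table = global_feature_table(cohort, scale, gamma=gamma, seed=seed)
        models = _fit_on_controls(table, include_age2=include_age2)
        resid_rows = []
        ages = table["age"].to_numpy(dtype=float)
        sexes = table["sex"].to_numpy()
        resid = table[["subject_id", "timepoint", "group"]].copy()
        for m in GLOBAL_METRIC_NAMES:
            resid[m] = models[m].residual(table[m].to_numpy(), ages, sexes)
        out.global_residuals = resid
        early, late = _paired_frames(resid, patients)
        results = [
            _compare(m, scale, early[m].to_numpy(), late[m].to_numpy(), alpha,
                     d_denominator)
            for m in GLOBAL_METRIC_NAMES
        ]
        out.global_results = out.results_frame(results)

        sub_rows = []
        for m in GLOBAL_METRIC_NAMES:
            change = late[m].to_numpy() - early[m].to_numpy()
            for grouping, labels in (
                ("histopathology", [p.histopathology for p in patients]),
                ("seizure_free", [p.seizure_free for p in patients]),
            ):
                if any(l is None for l in labels):
                    continue
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        p_val = subgroup_kruskal(change, np.asarray(labels, dtype=object))
                except ValueError:
                    p_val = np.nan
                sub_rows.append(
                    {
                        "metric": m,
                        "grouping": grouping,
                        "p_value": p_val,
                        "significant": bool(p_val < alpha) if np.isfinite(p_val) else False,
                    }
                )
        out.subgroup_results = pd.DataFrame(sub_rows)

    if "nodal" in stages or "thalamic" in stages:
        nodal_table = nodal_feature_table(cohort, scale, gamma=gamma, seed=seed)
        nodal_models = _fit_on_controls(nodal_table, include_age2=include_age2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z_table = _zscore_table(nodal_table, nodal_models)

    if "nodal" in stages:
        burden_rows = []
        feature_cols = [c for c in z_table.columns if "|" in str(c)]
        for _, row in z_table.iterrows():
            for metric in NODAL_METRIC_NAMES:
                cols = [c for c in feature_cols if str(c).startswith(metric + "|")]
                b = abnormal_burden(row[cols].to_numpy(dtype=float), z_threshold)
                burden_rows.append(
                    {
                        "subject_id": row["subject_id"],
                        "timepoint": row["timepoint"],
                        "group": row["group"],
                        "metric": metric,
                        "n_abnormal_total": b.n_abnormal_total,
                        "n_above": b.n_above,
                        "n_below": b.n_below,
                    }
                )
        out.burden_table = pd.DataFrame(burden_rows)
        results = []
        for metric in NODAL_METRIC_NAMES:
            sub = out.burden_table[out.burden_table["metric"] == metric]
            early, late = _paired_frames(sub, patients)
            for count in ("n_abnormal_total", "n_above", "n_below"):
                results.append(
                    _compare(
                        f"{metric}:{count}", scale,
                        early[count].to_numpy(dtype=float),
                        late[count].to_numpy(dtype=float),
                        alpha, d_denominator,
                    )
                )
        out.burden_results = out.results_frame(results)

    if "thalamic" in stages:
        parc = cohort.parcellations[scale]
        thal_table = thalamic_feature_table(cohort, scale)
        thal_models = _fit_on_controls(thal_table, include_age2=include_age2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            thal_z = _zscore_table(thal_table, thal_models)
        out.thalamic_z = thal_z
        early, late = _paired_frames(thal_z, patients)
        results = []
        for hemi, lobe in lobe_keys(parc):
            col = f"thal_{hemi}_{lobe}"
            results.append(
                _compare(col, scale, early[col].to_numpy(), late[col].to_numpy(),
                         alpha, d_denominator)
            )
        out.thalamic_results = out.results_frame(results)

        zz_rows = []
        for p_rec in patients:
            deltas = []
            affected_idx = None
            for i, (hemi, lobe) in enumerate(lobe_keys(parc)):
                col = f"thal_{hemi}_{lobe}"
                deltas.append(
                    float(late.loc[p_rec.subject_id, col] - early.loc[p_rec.subject_id, col])
                )
                if hemi == p_rec.affected_hemisphere and lobe == p_rec.affected_lobe:
                    affected_idx = i
            if affected_idx is None:
                raise ValueError(
                    f"patient {p_rec.subject_id}: affected lobe "
                    f"({p_rec.affected_hemisphere}, {p_rec.affected_lobe}) "
                    "not in lobe taxonomy"
                )
            zz = affected_lobe_z_of_z(np.asarray(deltas), affected_index=affected_idx)
            zz_rows.append(
                {
                    "subject_id": p_rec.subject_id,
                    "z_of_z": zz.z_of_z,
                    "delta_z_affected": zz.delta_z_affected,
                }
            )
        out.z_of_z_table = pd.DataFrame(zz_rows)
        out.z_of_z_mean, out.z_of_z_p = one_sample_t(
            out.z_of_z_table["z_of_z"].to_numpy(), 0.0
        )

        # thalamic modal controllability Z-scores, paired per thalamic parcel
        thal_parcels = [
            parc.parcel_ids[i]
            for hemi in ("left", "right")
            for i in parc.thalamic_indices(hemi)
        ]
        modal_cols = [f"modal_controllability|{pid}" for pid in thal_parcels]
        modal_z = z_table[["subject_id", "timepoint", "group", "age", "sex"] + modal_cols]
        out.thalamic_modal_z = modal_z
        early_m, late_m = _paired_frames(modal_z, patients)
        results = [
            _compare(col, scale, early_m[col].to_numpy(), late_m[col].to_numpy(),
                     alpha, d_denominator)
            for col in modal_cols
        ]
        out.thalamic_modal_results = out.results_frame(results)

    return out


def sensitivity_across_scales(
    cohort: Cohort,
    scales: tuple[int, ...] = (1, 2, 3, 4, 5),
    exclude_age_below: float | None = None,
    *,
    stages: tuple[str, ...] = ("global", "nodal"),
    **kwargs,
) -> pd.DataFrame:
    """Repeat the analysis at several parcellation scales; emit a −log10 P grid.

    ``exclude_age_below`` drops patients whose early-scan age is below the
    threshold (sensitivity against extrapolating the normative model to ages
    younger than any control).
    """
    available = set(cohort.scales())
    missing = [s for s in scales if s not in available]
    if missing:
        raise ValueError(f"no connectomes at scales {missing}")
    work = cohort
    if exclude_age_below is not None:
        keep = [
            s for s in cohort.subjects
            if s.group == "control" or s.ages["early"] >= exclude_age_below
        ]
        dropped = len(cohort.subjects) - len(keep)
        if dropped:
            log.info("sensitivity: excluded %d patients younger than %s",
                     dropped, exclude_age_below)
        sids = {s.subject_id for s in keep}
        work = Cohort(
            subjects=keep,
            connectomes={k: v for k, v in cohort.connectomes.items() if k[0] in sids},
            parcellations=cohort.parcellations,
        )
    rows = []
    with np.errstate(divide="ignore"):
        for scale in scales:
            res = run_longitudinal_analysis(work, scale, stages=stages, **kwargs)
            frames = []
            if "global" in stages:
                frames.append(res.global_results.assign(analysis="global"))
            if "nodal" in stages:
                frames.append(res.burden_results.assign(analysis="nodal_burden"))
            if "thalamic" in stages:
                frames.append(res.thalamic_results.assign(analysis="thalamic"))
            for f in frames:
                for _, r in f.iterrows():
                    rows.append(
                        {
                            "scale": scale,
                            "analysis": r["analysis"],
                            "metric": r["metric"],
                            "n_pairs": r["n_pairs"],
                            "p_value": r["p_value"],
                            "neg_log10_p": float(-np.log10(r["p_value"]))
                            if np.isfinite(r["p_value"]) and r["p_value"] > 0 else np.nan,
                        }
                    )
    return pd.DataFrame(rows)
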