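"""Synthetic cohorts with the statistical structure the analysis assumes.

Connectomes are drawn from a weighted stochastic-block template: parcels
group into lobe-wise cortical communities plus thalamic, hippocampal,
other-subcortical and brainstem blocks, with inflated within-community
weights, elevated ipsilateral thalamocortical weight, and fixed per-edge
lognormal heterogeneity. Subject scans modulate the template
multiplicatively on the log scale,

    W_ij = T_ij · exp(β_age (age − age_ref) + β_sex · female
                      + s_subject + s_scan + σ_edge ε_ij),

where ``s_subject`` is a stable individual trait shared by a patient's two
scans, ``s_scan`` is per-scan (test–retest) variability, and ε_ij is
symmetric edge noise. Multiplicative lognormal factors keep weights
nonnegative while inducing approximately linear metric–age relations that a
Gaussian identity-link normative model can recover.

Ground-truth longitudinal effects are injected per :class:`EffectSpec` in
units of the between-subject control SD on the log-weight scale
(``σ_ref = sqrt(σ_subject² + σ_scan²)``), so a magnitude of 1 shifts
scale-dependent features by roughly one control SD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import (
    DEFAULT_LOBES,
    Cohort,
    Connectome,
    ParcellationInfo,
    SubjectRecord,
    write_connectome,
    write_parcellation,
)

__all__ = [
    "EffectSpec",
    "SimulationManifest",
    "synthetic_parcellation",
    "generate_control_cohort",
    "generate_patient_pairs",
    "generate_study_cohort",
    "merge_cohorts",
    "write_fixture_suite",
]

#: cortical parcels per lobe per hemisphere at each atlas scale
CORTICAL_PER_LOBE = {1: 2, 2: 3, 3: 5, 4: 8, 5: 12}

HISTOPATHOLOGIES = ("FCD", "tumour", "other")


@dataclass(frozen=True)
class EffectSpec:
    """One injectable ground-truth longitudinal effect.

    target:
        ``global_strength`` — uniform weight change;
        ``nodal_strength_subset`` — weight change on edges incident to the
        parcels named in ``selector`` (list of parcel ids);
        ``participation_structure`` — redistribute the selected parcels'
        within-community weight toward other communities (raises their
        participation coefficient for positive magnitude);
        ``thalamocortical_lobe`` — weight change on ipsilateral
        thalamus-to-lobe edges; ``selector`` = (hemisphere, lobe);
        ``thalamic_modal`` — weaken the selected hemisphere's thalamic
        edges (raises thalamic modal controllability for positive
        magnitude); ``selector`` = hemisphere.
    magnitude:
        effect size in control-SD units on the log-weight scale.
    apply_to:
        ``late_only`` (default) or ``both`` scans.
    """

    target: str
    magnitude: float
    selector: object = None
    apply_to: str = "late_only"

    def __post_init__(self) -> None:
        if self.target not in (
            "global_strength",
            "nodal_strength_subset",
            "participation_structure",
            "thalamocortical_lobe",
            "thalamic_modal",
        ):
            raise ValueError(f"unknown effect target {self.target!r}")
        if self.apply_to not in ("late_only", "both"):
            raise ValueError(f"unknown apply_to {self.apply_to!r}")
        if not np.isfinite(self.magnitude):
            raise ValueError("effect magnitude must be finite")


@dataclass(frozen=True)
class SimulationManifest:
    """Generative parameters; together with a seed this fully determines a
    cohort (same seed → identical cohorts)."""

    n_controls: int = 57
    n_patients: int = 23
    control_age_range: tuple[float, float] = (6.0, 18.0)
    patient_age_range: tuple[float, float] = (3.0, 16.0)
    #: lognormal inter-scan interval; median 1.15 y, IQR ≈ 0.78–1.93 y
    interval_median: float = 1.15
    interval_log_sigma: float = 0.6714
    age_ref: float = 12.0
    beta_age: float = 0.015
    beta_sex: float = 0.05
    sigma_subject: float = 0.08
    sigma_scan: float = 0.04
    sigma_edge: float = 0.5
    baseline_patient_shift: float = 0.0
    template_seed: int = 2018

    @property
    def sigma_ref(self) -> float:
        """Between-subject control SD on the log-weight scale."""
        return float(np.hypot(self.sigma_subject, self.sigma_scan))


def synthetic_parcellation(scale: int) -> ParcellationInfo:
    """A parcellation honouring every structural invariant at one scale:
    7 thalamic and 3 hippocampal parcels per hemisphere, 4 brainstem parcels,
    3 other-subcortical parcels per hemisphere, and lobe-wise cortical
    parcels (count per lobe grows with scale)."""
    if scale not in CORTICAL_PER_LOBE:
        raise ValueError(f"scale must be in 1..5, got {scale}")
    per_lobe = CORTICAL_PER_LOBE[scale]
    ids, names, hemis, lobes, classes = [], [], [], [], []

    def add(pid, name, hemi, lobe, cls):
        ids.append(pid)
        names.append(name)
        hemis.append(hemi)
        lobes.append(lobe)
        classes.append(cls)

    for hemi in ("left", "right"):
        h = hemi[0]
        for lobe in DEFAULT_LOBES:
            for k in range(per_lobe):
                add(f"{h}_{lobe}_{k}", f"{hemi} {lobe} parcel {k}", hemi, lobe, "cortical")
        for k in range(7):
            add(f"{h}_thal_{k}", f"{hemi} thalamic subregion {k}", hemi, None, "thalamic")
        for k in range(3):
            add(f"{h}_hipp_{k}", f"{hemi} hippocampus part {k}", hemi, None, "hippocampal")
        for k in range(3):
            add(f"{h}_subc_{k}", f"{hemi} subcortical {k}", hemi, None, "other-subcortical")
    for k in range(4):
        add(f"m_bstem_{k}", f"brainstem parcel {k}", "midline", None, "brainstem")
    return ParcellationInfo(
        scale=scale,
        parcel_ids=tuple(ids),
        names=tuple(names),
        hemispheres=tuple(hemis),
        lobes=tuple(lobes),
        structure_classes=tuple(classes),
    )


def _block_labels(parc: ParcellationInfo) -> list[str]:
    """Template community of each parcel (lobe-wise cortical + subcortical blocks)."""
    labels = []
    for hemi, lobe, cls in zip(parc.hemispheres, parc.lobes, parc.structure_classes):
        if cls == "cortical":
            labels.append(f"{hemi}_{lobe}")
        elif cls == "brainstem":
            labels.append("brainstem")
        elif cls == "thalamic":
            labels.append(f"{hemi}_thal")
        else:
            labels.append(f"{hemi}_deep")
    return labels


def _base_template(parc: ParcellationInfo, manifest: SimulationManifest) -> np.ndarray:
    """Deterministic weighted stochastic-block template for one scale."""
    rng = np.random.default_rng(manifest.template_seed + parc.scale)
    n = parc.n_parcels
    labels = _block_labels(parc)
    hemis = parc.hemispheres
    lobes = parc.lobes
    classes = parc.structure_classes

    mean = np.zeros((n, n))
    keep_p = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            same_block = labels[i] == labels[j]
            same_hemi = hemis[i] == hemis[j]
            thal_pair = {classes[i], classes[j]} == {"thalamic", "cortical"}
            if same_block:
                w, p = 30.0, 0.95
            elif thal_pair and same_hemi:
                w, p = 12.0, 0.9
            elif thal_pair:
                w, p = 1.0, 0.4
            elif "brainstem" in (classes[i], classes[j]):
                other = classes[j] if classes[i] == "brainstem" else classes[i]
                w, p = (6.0, 0.8) if other != "cortical" else (0.5, 0.3)
            elif not same_hemi and lobes[i] is not None and lobes[i] == lobes[j]:
                w, p = 10.0, 0.8  # homologous lobes across hemispheres
            elif same_hemi:
                w, p = 6.0, 0.6
            else:
                w, p = 2.0, 0.4
            mean[i, j] = mean[j, i] = w
            keep_p[i, j] = keep_p[j, i] = p
    iu = np.triu_indices(n, k=1)
    jitter = np.zeros((n, n))
    jitter[iu] = rng.normal(0.0, 0.4, size=len(iu[0]))
    mask = np.zeros((n, n))
    mask[iu] = rng.random(len(iu[0])) < keep_p[iu]
    t = mean * np.exp(jitter) * mask
    t = t + t.T
    np.fill_diagonal(t, 0.0)
    return t


def _subject_matrix(
    template: np.ndarray,
    manifest: SimulationManifest,
    age: float,
    sex: str,
    s_subject: float,
    rng: np.random.Generator,
    extra_log_shift: float = 0.0,
) -> np.ndarray:
    n = template.shape[0]
    s_scan = rng.normal(0.0, manifest.sigma_scan)
    iu = np.triu_indices(n, k=1)
    eps = np.zeros((n, n))
    eps[iu] = rng.normal(0.0, manifest.sigma_edge, size=len(iu[0]))
    eps = eps + eps.T
    log_factor = (
        manifest.beta_age * (age - manifest.age_ref)
        + manifest.beta_sex * (1.0 if sex == "female" else 0.0)
        + s_subject
        + s_scan
        + extra_log_shift
    )
    w = template * np.exp(log_factor + eps)
    np.fill_diagonal(w, 0.0)
    return w


def _apply_effect(
    w: np.ndarray,
    effect: EffectSpec,
    parc: ParcellationInfo,
    manifest: SimulationManifest,
) -> np.ndarray:
    f = float(np.exp(effect.magnitude * manifest.sigma_ref))
    w = w.copy()
    if effect.target == "global_strength":
        return w * f
    if effect.target == "nodal_strength_subset":
        sel = [parc.parcel_ids.index(pid) for pid in effect.selector]
        if not sel:
            raise ValueError("empty parcel selector")
        mask = np.zeros(w.shape[0], dtype=bool)
        mask[sel] = True
        incident = mask[:, None] | mask[None, :]
        w[incident] *= f
        return w
    if effect.target == "thalamocortical_lobe":
        hemi, lobe = effect.selector
        thal = parc.thalamic_indices(hemi)
        cort = parc.indices(structure_class="cortical", hemisphere=hemi, lobe=lobe)
        if cort.size == 0:
            raise ValueError(f"selector resolves to no parcels: {effect.selector}")
        w[np.ix_(thal, cort)] *= f
        w[np.ix_(cort, thal)] *= f
        return w
    if effect.target == "thalamic_modal":
        thal = parc.thalamic_indices(effect.selector)
        mask = np.zeros(w.shape[0], dtype=bool)
        mask[thal] = True
        incident = mask[:, None] | mask[None, :]
        # weaker connectivity raises modal controllability
        w[incident] /= f
        return w
    if effect.target == "participation_structure":
        sel = [parc.parcel_ids.index(pid) for pid in effect.selector]
        labels = _block_labels(parc)
        same = np.asarray(
            [[labels[i] == labels[j] for j in range(len(labels))] for i in range(len(labels))]
        )
        for i in sel:
            row_mask = same[i].copy()
            row_mask[i] = False
            # shrink within-community weight; raises participation coefficient
            w[i, row_mask] /= f
            w[row_mask, i] = w[i, row_mask]
        return w
    raise AssertionError(effect.target)


def generate_control_cohort(
    n: int = 57,
    scale: int = 3,
    seed: int = 0,
    manifest: SimulationManifest | None = None,
) -> Cohort:
    """n cross-sectional controls with age- and sex-dependent connectomes."""
    manifest = manifest or SimulationManifest()
    if n < 10:
        raise ValueError(f"need at least 10 controls, got {n}")
    parc = synthetic_parcellation(scale)
    template = _base_template(parc, manifest)
    subjects, connectomes = [], {}
    lo, hi = manifest.control_age_range
    for k in range(n):
        sid = f"ctrl{k:03d}"
        # subject attributes come from a subject-keyed stream so the same
        # subject is identical across scales; matrix noise from a
        # (subject, scale)-keyed stream
        srng = np.random.default_rng([seed, 1, k])
        age = float(srng.uniform(lo, hi))
        sex = "female" if srng.random() < 0.5 else "male"
        s_subj = srng.normal(0.0, manifest.sigma_subject)
        mrng = np.random.default_rng([seed, 1, k, scale])
        w = _subject_matrix(template, manifest, age, sex, s_subj, mrng)
        subjects.append(
            SubjectRecord(subject_id=sid, group="control", ages={"control": age}, sex=sex)
        )
        connectomes[(sid, "control", scale)] = Connectome(
            matrix=w, parcel_ids=parc.parcel_ids, scale=scale,
            subject_id=sid, timepoint="control",
        )
    return Cohort(subjects=subjects, connectomes=connectomes, parcellations={scale: parc})


def _default_affected(effects: list[EffectSpec]) -> tuple[str, str] | None:
    for e in effects:
        if e.target == "thalamocortical_lobe":
            return tuple(e.selector)
    return None


def generate_patient_pairs(
    n: int = 23,
    scale: int = 3,
    seed: int = 0,
    manifest: SimulationManifest | None = None,
    effects: list[EffectSpec] | None = None,
) -> Cohort:
    """n patients with paired early/late scans and optional injected effects.

    The early scan follows the control-generating process (plus any
    ``baseline_patient_shift`` in the manifest); the inter-scan interval is
    lognormal with the manifest's median. When an effect targets a specific
    (hemisphere, lobe), every patient's recorded affected lobe is that one;
    otherwise affected lobes are assigned at random.
    """
    manifest = manifest or SimulationManifest()
    effects = list(effects or [])
    if n < 5:
        raise ValueError(f"need at least 5 patients, got {n}")
    parc = synthetic_parcellation(scale)
    template = _base_template(parc, manifest)
    forced_affected = _default_affected(effects)
    subjects, connectomes = [], {}
    lo, hi = manifest.patient_age_range
    base_shift = manifest.baseline_patient_shift * manifest.sigma_ref
    for k in range(n):
        sid = f"pat{k:03d}"
        srng = np.random.default_rng([seed, 2, k])
        age_early = float(srng.uniform(lo, hi))
        interval = float(
            np.exp(srng.normal(np.log(manifest.interval_median), manifest.interval_log_sigma))
        )
        age_late = age_early + interval
        sex = "female" if srng.random() < 0.5 else "male"
        s_subj = srng.normal(0.0, manifest.sigma_subject)
        aff_hemi = "left" if srng.random() < 0.5 else "right"
        aff_lobe = DEFAULT_LOBES[srng.integers(len(DEFAULT_LOBES))]
        if forced_affected is not None:
            # the recorded affected lobe follows the injected focal effect;
            # the draws above still happen so rng streams stay aligned
            aff_hemi, aff_lobe = forced_affected
        histo = HISTOPATHOLOGIES[srng.integers(len(HISTOPATHOLOGIES))]
        szf = bool(srng.random() < 0.6)
        mats = {}
        for t_idx, (tp, age) in enumerate((("early", age_early), ("late", age_late))):
            mrng = np.random.default_rng([seed, 2, k, scale, t_idx])
            w = _subject_matrix(template, manifest, age, sex, s_subj, mrng,
                                extra_log_shift=base_shift)
            for e in effects:
                if e.apply_to == "both" or tp == "late":
                    w = _apply_effect(w, e, parc, manifest)
            mats[tp] = w
        subjects.append(
            SubjectRecord(
                subject_id=sid, group="patient",
                ages={"early": age_early, "late": age_late}, sex=sex,
                histopathology=histo, seizure_free=szf,
                affected_lobe=aff_lobe, affected_hemisphere=aff_hemi,
            )
        )
        for tp, w in mats.items():
            connectomes[(sid, tp, scale)] = Connectome(
                matrix=w, parcel_ids=parc.parcel_ids, scale=scale,
                subject_id=sid, timepoint=tp,
            )
    return Cohort(subjects=subjects, connectomes=connectomes, parcellations={scale: parc})


def merge_cohorts(*cohorts: Cohort) -> Cohort:
    """Combine cohorts sharing parcellations (controls + patients, or the
    same subjects at several scales). Duplicate subject records must agree."""
    subjects, connectomes, parcellations = [], {}, {}
    seen: dict[str, SubjectRecord] = {}
    for c in cohorts:
        for s in c.subjects:
            if s.subject_id in seen:
                if seen[s.subject_id] != s:
                    raise ValueError(
                        f"conflicting records for subject {s.subject_id}"
                    )
                continue
            seen[s.subject_id] = s
            subjects.append(s)
        connectomes.update(c.connectomes)
        for sc, p in c.parcellations.items():
            if sc in parcellations and parcellations[sc].parcel_ids != p.parcel_ids:
                raise ValueError(f"conflicting parcellations at scale {sc}")
            parcellations[sc] = p
    return Cohort(subjects=subjects, connectomes=connectomes, parcellations=parcellations)


def generate_study_cohort(
    n_controls: int = 57,
    n_patients: int = 23,
    scale: int = 3,
    seed: int = 0,
    manifest: SimulationManifest | None = None,
    effects: list[EffectSpec] | None = None,
) -> Cohort:
    """Controls plus paired patients in one analysable cohort.

    Control and patient streams use sub-seeds derived from ``seed`` so the
    whole cohort is reproducible from a single integer.
    """
    manifest = manifest or SimulationManifest()
    controls = generate_control_cohort(n_controls, scale, seed * 2 + 1, manifest)
    patients = generate_patient_pairs(n_patients, scale, seed * 2 + 2, manifest, effects)
    return merge_cohorts(controls, patients)


def write_fixture_suite(
    out_dir: str | Path,
    seed: int = 0,
    n_controls: int = 12,
    n_patients: int = 6,
    scales: tuple[int, ...] = (1, 3),
    effects: list[EffectSpec] | None = None,
    manifest: SimulationManifest | None = None,
) -> dict:
    """Write a small complete on-disk fixture in the pipeline's file formats.

    Produces, under ``out_dir``: per-scale parcellation TSVs, one matrix CSV
    per subject-scan named ``<subject>_<timepoint>_scale<k>.csv``, a cohort
    metadata TSV, and a ground-truth JSON recording the manifest, seed and
    every injected effect. Returns the file manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = manifest or SimulationManifest()
    effects = list(effects or [])
    files: dict[str, object] = {"matrices": []}
    meta_rows = []
    for i, scale in enumerate(scales):
        cohort = generate_study_cohort(
            n_controls, n_patients, scale, seed, manifest, effects
        )
        parc_path = out_dir / f"parcellation_scale{scale}.tsv"
        write_parcellation(cohort.parcellations[scale], parc_path)
        files[f"parcellation_scale{scale}"] = parc_path.name
        for (sid, tp, sc), conn in sorted(cohort.connectomes.items()):
            path = out_dir / f"{sid}_{tp}_scale{sc}.csv"
            write_connectome(conn, path)
            files["matrices"].append(path.name)
        if i == 0:
            for subj in cohort.subjects:
                for tp in subj.timepoints:
                    meta_rows.append(
                        {
                            "subject_id": subj.subject_id,
                            "group": subj.group,
                            "timepoint": tp,
                            "age_at_scan": f"{subj.ages[tp]:.4f}",
                            "sex": subj.sex,
                            "histopathology": subj.histopathology or "",
                            "seizure_free": "" if subj.seizure_free is None else str(subj.seizure_free).lower(),
                            "affected_lobe": subj.affected_lobe or "",
                            "affected_hemisphere": subj.affected_hemisphere or "",
                        }
                    )
    import pandas as pd

    meta_path = out_dir / "cohort.tsv"
    pd.DataFrame(meta_rows).to_csv(meta_path, sep="\t", index=False)
    files["metadata"] = meta_path.name
    truth = {
        "seed": seed,
        "n_controls": n_controls,
        "n_patients": n_patients,
        "scales": list(scales),
        "manifest": {k: v for k, v in vars(manifest).items()},
        "effects": [
            {
                "target": e.target,
                "magnitude": e.magnitude,
                "selector": list(e.selector) if isinstance(e.selector, (tuple, list)) else e.selector,
                "apply_to": e.apply_to,
            }
            for e in effects
        ],
    }
    truth_path = out_dir / "ground_truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, default=list))
    files["ground_truth"] = truth_path.name
    return files
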