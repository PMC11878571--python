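"""Thalamocortical connectivity profiling and affected-lobe statistics.

For each hemisphere the total streamline weight between the seven thalamic
parcels and the ipsilateral cortical parcels of each lobe gives a 10-entry
(hemisphere × lobe) connectivity profile per scan. Profiles are Z-scored
against control normative models; the within-patient "z-of-z" statistic asks
whether the epilepsy-affected lobe's Z-score change stands out from the
other nine lobes of the same patient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Connectome, ParcellationInfo
from .normative import NormativeModelSet

__all__ = [
    "thalamocortical_connectivity",
    "lobe_z_changes",
    "affected_lobe_z_of_z",
    "lobe_keys",
]


def lobe_keys(parcellation: ParcellationInfo) -> list[tuple[str, str]]:
    """The 10 (hemisphere, lobe) keys, ordered left-then-right, taxonomy order."""
    return [
        (hemi, lobe)
        for hemi in ("left", "right")
        for lobe in parcellation.lobe_taxonomy
    ]


def thalamocortical_connectivity(
    c: Connectome, parcellation: ParcellationInfo
) -> pd.DataFrame:
    """Streamline sum from each thalamus to each ipsilateral cortical lobe.

    Only ipsilateral connections count: the left thalamic parcels against
    left cortical parcels and likewise on the right. Returns a 10-row frame
    with columns hemisphere, lobe, streamline_sum.
    """
    w = c.matrix
    rows = []
    for hemi, lobe in lobe_keys(parcellation):
        thal = parcellation.thalamic_indices(hemi)
        cort = parcellation.indices(
            structure_class="cortical", hemisphere=hemi, lobe=lobe
        )
        if cort.size == 0:
            raise ValueError(f"no cortical parcels for {hemi} {lobe}")
        rows.append(
            {
                "hemisphere": hemi,
                "lobe": lobe,
                "streamline_sum": float(w[np.ix_(thal, cort)].sum()),
            }
        )
    return pd.DataFrame(rows)


def lobe_z_changes(
    early: pd.DataFrame,
    late: pd.DataFrame,
    models: NormativeModelSet,
    age_early: float,
    age_late: float,
    sex: str,
) -> pd.DataFrame:
    """Per-lobe Z-score change Δz = z_late − z_early for one patient.

    ``early``/``late`` are thalamocortical profiles from
    :func:`thalamocortical_connectivity`; the models are per-lobe normative
    fits of control streamline sums (feature key ``thal_<hemi>_<lobe>``).
    """
    merged = early.merge(late, on=["hemisphere", "lobe"], suffixes=("_early", "_late"))
    out = []
    for _, r in merged.iterrows():
        key = f"thal_{r['hemisphere']}_{r['lobe']}"
        m = models[key]
        z_early = float(m.zscore(r["streamline_sum_early"], age_early, sex))
        z_late = float(m.zscore(r["streamline_sum_late"], age_late, sex))
        out.append(
            {
                "hemisphere": r["hemisphere"],
                "lobe": r["lobe"],
                "z_early": z_early,
                "z_late": z_late,
                "delta_z": z_late - z_early,
            }
        )
    return pd.DataFrame(out)


@dataclass(frozen=True)
class ZofZ:
    """Within-patient standardized Z-score change of the affected lobe."""

    z_of_z: float
    delta_z_affected: float
    mean_delta_z: float
    sd_delta_z: float


def affected_lobe_z_of_z(
    delta_z: pd.DataFrame | np.ndarray,
    affected_hemisphere: str | None = None,
    affected_lobe: str | None = None,
    affected_index: int | None = None,
) -> ZofZ:
    """Standardize the 10 per-lobe Δz values within the patient and return
    the affected lobe's standardized value.

    The affected lobe's own Δz is included in the mean/SD (all 10 lobes enter
    the normalization). SD uses the n−1 denominator. Zero spread across the
    10 lobes leaves the statistic undefined and raises.
    """
    if isinstance(delta_z, pd.DataFrame):
        values = delta_z["delta_z"].to_numpy(dtype=float)
        if affected_index is None:
            match = (delta_z["hemisphere"] == affected_hemisphere) & (
                delta_z["lobe"] == affected_lobe
            )
            idx = np.flatnonzero(match.to_numpy())
            if idx.size != 1:
                raise ValueError(
                    f"affected lobe ({affected_hemisphere}, {affected_lobe}) "
                    f"matched {idx.size} profile rows"
                )
            affected_index = int(idx[0])
    else:
        values = np.asarray(delta_z, dtype=float)
        if affected_index is None:
            raise ValueError("affected_index required for a bare vector")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite lobe z-changes")
    mu = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        raise ValueError("zero spread across lobes: z-of-z undefined")
    return ZofZ(
        z_of_z=(float(values[affected_index]) - mu) / sd,
        delta_z_affected=float(values[affected_index]),
        mean_delta_z=mu,
        sd_delta_z=sd,
    )
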