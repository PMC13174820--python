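"""Subject-level feature extraction from voxel maps and pAs components.

Aggregates the voxelwise bi-tensor maps into the features the downstream
statistics consume: per-ROI pAs-FWAD/FWVF (mean over the voxels of the
selected components), per-ROI WM-FWVF (mean over WM voxels after excluding
WMH and pAs), whole-brain composites, the ALPS index, and the named feature
sets used for amyloid-positivity classification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bitensor import ScalarMapSet
from .exceptions import InputError
from .pas import PasComponent

__all__ = [
    "SubjectFeatures",
    "pas_roi_metrics",
    "wm_fwvf",
    "build_feature_sets",
    "FEATURE_SET_DEFS",
]

# Canonical analysis regions: precuneus, AD-signature composite, whole brain.
ANALYSIS_REGIONS = ("precuneus", "ad_signature", "whole_brain")


@dataclass
class SubjectFeatures:
    """Per-subject glymphatic feature bundle.

    ``pas_fwad``/``pas_fwvf``/``wm_fwvf`` map ROI name -> value (NaN when the
    ROI had no usable voxels — missing is explicit, never silently zero).
    ``n_components`` records how many selected components fed each ROI.
    """

    subject_id: str
    pas_fwad: dict[str, float] = field(default_factory=dict)
    pas_fwvf: dict[str, float] = field(default_factory=dict)
    wm_fwvf: dict[str, float] = field(default_factory=dict)
    alps_index: float = float("nan")
    n_components: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d in (self.pas_fwvf, self.wm_fwvf):
            for roi, v in d.items():
                if np.isfinite(v) and not (0.0 <= v <= 1.0):
                    raise InputError(f"FWVF out of [0,1] for ROI {roi}: {v}")

    def to_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {"subject": self.subject_id,
                                       "alps_index": self.alps_index}
        for roi, v in self.pas_fwad.items():
            row[f"pas_fwad_{roi}"] = v
        for roi, v in self.pas_fwvf.items():
            row[f"pas_fwvf_{roi}"] = v
        for roi, v in self.wm_fwvf.items():
            row[f"wm_fwvf_{roi}"] = v
        return row


def pas_roi_metrics(
    maps: ScalarMapSet,
    selected: Mapping[int, Sequence[PasComponent]],
    roi_names: Mapping[int, str] | None = None,
) -> tuple[dict[str, float], dict[str, float], dict[str, int]]:
    """Per-ROI pAs FWAD and FWVF: unweighted mean over selected-component voxels.

    The whole-brain value pools the voxels of every selected component across
    ROIs (no global re-selection).  ROIs with no selected components are
    reported as NaN and logged in the returned component-count dict.
    """
    fwad_map = maps["FWAD"]
    fwvf_map = maps["FWVF"]
    fwad: dict[str, float] = {}
    fwvf: dict[str, float] = {}
    counts: dict[str, int] = {}
    all_vox: list[np.ndarray] = []
    for roi, comps in sorted(selected.items()):
        name = roi_names[roi] if roi_names else str(roi)
        counts[name] = len(comps)
        if not comps:
            fwad[name] = np.nan
            fwvf[name] = np.nan
            continue
        vox = np.vstack([c.voxels for c in comps])
        all_vox.append(vox)
        idx = tuple(vox.T)
        fwad[name] = float(np.nanmean(fwad_map[idx]))
        fwvf[name] = float(np.nanmean(fwvf_map[idx]))
    if all_vox:
        idx = tuple(np.vstack(all_vox).T)
        fwad["whole_brain"] = float(np.nanmean(fwad_map[idx]))
        fwvf["whole_brain"] = float(np.nanmean(fwvf_map[idx]))
        counts["whole_brain"] = sum(counts.values())
    else:
        fwad["whole_brain"] = np.nan
        fwvf["whole_brain"] = np.nan
        counts["whole_brain"] = 0
    return fwad, fwvf, counts


def wm_fwvf(
    maps: ScalarMapSet,
    wm_mask: np.ndarray,
    wmh_mask: np.ndarray | None,
    pas_mask: np.ndarray | None,
    roi_label_volume: np.ndarray | None = None,
    roi_names: Mapping[int, str] | None = None,
) -> dict[str, float]:
    """Per-ROI WM-FWVF over white matter with WMH and pAs voxels excluded.

    Effective mask = WM AND NOT WMH AND NOT pAs.  ``whole_brain`` averages
    over all effective WM voxels; per-ROI values follow the superficial-WM
    label volume.  Empty effective ROIs are NaN.
    """
    fwvf_map = maps["FWVF"]
    wm = np.asarray(wm_mask).astype(bool)
    if wm.shape != fwvf_map.shape:
        raise InputError("wm_mask grid does not match maps")
    eff = wm.copy()
    if wmh_mask is not None:
        eff &= ~np.asarray(wmh_mask).astype(bool)
    if pas_mask is not None:
        eff &= ~np.asarray(pas_mask).astype(bool)
    out: dict[str, float] = {}
    vals = fwvf_map[eff]
    vals = vals[np.isfinite(vals)]
    out["whole_brain"] = float(vals.mean()) if vals.size else np.nan
    if roi_label_volume is not None:
        labels = np.asarray(roi_label_volume)
        for roi in np.unique(labels[labels > 0]):
            name = roi_names[int(roi)] if roi_names else str(int(roi))
            v = fwvf_map[eff & (labels == roi)]
            v = v[np.isfinite(v)]
            out[name] = float(v.mean()) if v.size else np.nan
    return out


# Feature-set definitions for amyloid-positivity classification: the three
# glymphatic compartments (periarterial, WM parenchyma, perivenous) plus PET
# benchmarks on the same regions.
FEATURE_SET_DEFS: dict[str, tuple[str, ...]] = {
    "pAs": tuple(f"pas_{m}_{r}" for m in ("fwvf", "fwad") for r in ANALYSIS_REGIONS),
    "WM": tuple(f"wm_fwvf_{r}" for r in ANALYSIS_REGIONS),
    "pVs": ("alps_index",),
    "abeta_pet": tuple(f"abeta_suvr_{r}" for r in ANALYSIS_REGIONS),
    "tau_pet": tuple(f"tau_suvr_{r}" for r in ANALYSIS_REGIONS),
}
FEATURE_SET_DEFS["pAs+WM"] = FEATURE_SET_DEFS["pAs"] + FEATURE_SET_DEFS["WM"]
FEATURE_SET_DEFS["all"] = (FEATURE_SET_DEFS["pAs"] + FEATURE_SET_DEFS["WM"]
                           + FEATURE_SET_DEFS["pVs"])


def build_feature_sets(
    table: pd.DataFrame,
    pet: pd.DataFrame | None = None,
    sets: Sequence[str] = ("pAs", "WM", "pVs", "pAs+WM", "all"),
    dropna: bool = True,
) -> dict[str, pd.DataFrame]:
    """Assemble named feature matrices with deterministic column order.

    ``table`` is a subject feature table (one row per subject, columns as in
    :meth:`SubjectFeatures.to_row`); ``pet`` optionally supplies SUVR columns
    for the PET benchmark sets.  Missing values are handled by listwise
    deletion per feature set (default), so a subject missing only ALPS is
    dropped from pVs analyses but retained elsewhere.
    """
    merged = table
    if pet is not None:
        merged = table.merge(pet, on="subject", how="left")
    out: dict[str, pd.DataFrame] = {}
    for name in sets:
        if name not in FEATURE_SET_DEFS:
            raise InputError(f"unknown feature set {name!r}")
        cols = list(FEATURE_SET_DEFS[name])
        missing_cols = [c for c in cols if c not in merged.columns]
        if missing_cols:
            raise InputError(f"feature set {name!r} missing columns {missing_cols}")
        sub = merged[["subject", *cols]]
        if dropna:
            sub = sub.dropna(subset=cols)
        if sub.shape[0] == 0:
            raise InputError(f"feature set {name!r} is fully missing")
        out[name] = sub.reset_index(drop=True)
    return out


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the feature table as TSV with a JSON data dictionary sidecar."""
    path = Path(path)
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
    dd = {
        "columns": {
            c: ("subject identifier" if c == "subject" else
                "DTI-ALPS index (dimensionless)" if c == "alps_index" else
                "free-water volume fraction [0,1]" if "fwvf" in c else
                "free-water axial diffusivity (mm^2/s)" if "fwad" in c else
                "value")
            for c in table.columns
        }
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(dd, indent=2))
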