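"""DVH featurization: per-zone PCA scores plus the ten scalar indicators.

Each of the 48 zone DVHs is a 401-point vector; across the cohort the first
two principal components of each zone's mean-centered DVH matrix capture the
bulk of the inter-patient variation, giving two scores per zone per patient
(96 spatial features with the full catalogue). Ten further columns carry the
whole-organ DVH metrics (prostate D90/V100/V150, urethra D5/D30/V150), the
implant surrogates (needle count, seed count, prostate volume) and baseline
IPSS — 106 columns in total before collinearity pruning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .dosimetry import DoseGrid
from .dvh import DVHCurve, compute_dvh, dvh_metric
from .geometry import ZoneCatalogue

__all__ = [
    "ZonePCAModel",
    "FeatureTable",
    "INDICATOR_NAMES",
    "fit_zone_pca",
    "project",
    "assemble_indicators",
    "assemble_feature_table",
    "scale_and_prune",
    "zone_feature_proxies",
]

INDICATOR_NAMES = (
    "Prostate_D90",
    "Prostate_V100",
    "Prostate_V150",
    "Urethra_D5",
    "Urethra_D30",
    "Urethra_V150",
    "Needles",
    "Seeds",
    "ProstateVolume",
    "BaselineIPSS",
)

_INDICATOR_CATEGORY = dict(
    Prostate_D90="dvh_metric", Prostate_V100="dvh_metric", Prostate_V150="dvh_metric",
    Urethra_D5="dvh_metric", Urethra_D30="dvh_metric", Urethra_V150="dvh_metric",
    Needles="implant", Seeds="implant", ProstateVolume="implant",
    BaselineIPSS="clinical",
)


@dataclass
class ZonePCAModel:
    """Cohort PCA of one zone's DVHs (mean curve + first two loadings)."""

    zone_name: str
    mean_curve: np.ndarray  # (n_bins,)
    components: np.ndarray  # (2, n_bins), orthonormal rows
    explained_variance_ratio: np.ndarray  # (2,)


@dataclass
class FeatureTable:
    """Patient-by-feature matrix with per-column category metadata."""

    values: pd.DataFrame  # index: patient ids; columns: feature names
    categories: dict[str, str]
    scaling_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    #: dropped column -> the surviving column it was collinear with
    pruned_to_keeper: dict[str, str] = field(default_factory=dict)
    constant_columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        unknown = set(self.values.columns) - set(self.categories)
        if unknown:
            raise ValueError(f"columns without category metadata: {sorted(unknown)}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def representative(self, name: str) -> str:
        """The surviving column standing in for ``name`` after pruning."""
        seen = set()
        while name in self.pruned_to_keeper:
            if name in seen:  # defensive; pruning order precludes cycles
                break
            seen.add(name)
            name = self.pruned_to_keeper[name]
        return name


def fit_zone_pca(
    curves: np.ndarray,
    zone_name: str = "",
    empty: np.ndarray | None = None,
) -> ZonePCAModel | None:
    """Fit the two-component PCA of one zone's cohort DVH matrix.

    ``curves`` is (n_patients, n_bins); rows flagged ``empty`` are excluded
    from the fit. Returns None (with a warning) when the zone is empty for
    everyone. Component signs are fixed so each loading sums non-negative.
    """
    curves = np.asarray(curves, dtype=float)
    keep = np.ones(len(curves), dtype=bool) if empty is None else ~np.asarray(empty)
    fit_rows = curves[keep]
    if fit_rows.shape[0] == 0:
        warnings.warn(f"zone {zone_name!r} empty for all patients; dropped", stacklevel=2)
        return None
    if fit_rows.shape[0] < 3:
        raise ValueError(f"zone {zone_name!r}: need >= 3 non-empty patients for PCA")

    mean = fit_rows.mean(axis=0)
    centered = fit_rows - mean
    if np.allclose(centered, 0):
        # identical DVHs: variance is zero along any direction; use fixed
        # orthonormal loadings so projections are all-zero
        comps = np.zeros((2, curves.shape[1]))
        comps[0, 0] = 1.0
        comps[1, 1] = 1.0
        evr = np.zeros(2)
    else:
        n_comp = min(2, fit_rows.shape[0] - 1, curves.shape[1])
        p = PCA(n_components=n_comp, svd_solver="full")
        p.fit(fit_rows)
        comps = np.zeros((2, curves.shape[1]))
        comps[:n_comp] = p.components_
        if n_comp < 2:  # rank-1 cohort: second loading arbitrary orthonormal
            comps[1] = _orthonormal_complement(comps[0])
        evr = np.zeros(2)
        evr[:n_comp] = p.explained_variance_ratio_[:n_comp]
    for i in range(2):
        if comps[i].sum() < 0:
            comps[i] = -comps[i]
    return ZonePCAModel(zone_name, mean, comps, evr)


def _orthonormal_complement(v: np.ndarray) -> np.ndarray:
    e = np.zeros_like(v)
    e[int(np.argmin(np.abs(v)))] = 1.0
    w = e - v * (v @ e)
    return w / np.linalg.norm(w)


def project(
    curves: np.ndarray,
    model: ZonePCAModel,
    empty: np.ndarray | None = None,
) -> np.ndarray:
    """PCA scores ``loadings @ (curve - mean)`` for one or many patients.

    Patients with an empty zone are imputed at the cohort mean (score 0).
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    scores = (curves - model.mean_curve) @ model.components.T
    if empty is not None:
        scores[np.asarray(empty)] = 0.0
    return scores


def assemble_indicators(
    dose: DoseGrid,
    zones: ZoneCatalogue,
    clinical: dict,
) -> dict[str, float]:
    """The ten scalar indicators for one patient.

    ``clinical`` must provide ``needles``, ``seeds`` and ``baseline_ipss``;
    a missing field raises an error naming the patient and field.
    """
    pid = clinical.get("patient_id", "?")
    for fieldname in ("needles", "seeds", "baseline_ipss"):
        if fieldname not in clinical or clinical[fieldname] is None:
            raise ValueError(f"patient {pid}: missing clinical field {fieldname!r}")

    prostate = compute_dvh(dose, zones.zone_masks["Prostate"], "Prostate")
    urethra = compute_dvh(dose, zones.zone_masks["Urethra"], "Urethra")
    return {
        "Prostate_D90": dvh_metric(prostate, "D90"),
        "Prostate_V100": dvh_metric(prostate, "V100"),
        "Prostate_V150": dvh_metric(prostate, "V150"),
        "Urethra_D5": dvh_metric(urethra, "D5"),
        "Urethra_D30": dvh_metric(urethra, "D30"),
        "Urethra_V150": dvh_metric(urethra, "V150"),
        "Needles": float(clinical["needles"]),
        "Seeds": float(clinical["seeds"]),
        "ProstateVolume": zones.volume_cc("Prostate"),
        "BaselineIPSS": float(clinical["baseline_ipss"]),
    }


def assemble_feature_table(
    zone_curves: dict[str, np.ndarray],
    indicators: pd.DataFrame,
    zone_empty: dict[str, np.ndarray] | None = None,
) -> tuple[FeatureTable, dict[str, ZonePCAModel]]:
    """Fit the per-zone PCAs on the cohort and assemble the full table.

    ``zone_curves`` maps zone name -> (n_patients, n_bins) DVH matrix in a
    fixed patient order matching ``indicators.index``. Returns the unscaled
    table (2 columns per surviving zone, catalogue order, then the ten
    indicators) together with the fitted PCA models.
    """
    patients = indicators.index
    cols: dict[str, np.ndarray] = {}
    cats: dict[str, str] = {}
    models: dict[str, ZonePCAModel] = {}
    for zone, curves in zone_curves.items():
        empty = None if zone_empty is None else zone_empty.get(zone)
        model = fit_zone_pca(curves, zone, empty)
        if model is None:
            continue
        models[zone] = model
        scores = project(curves, model, empty)
        for j in (0, 1):
            name = f"{zone}_PCA{j + 1}"
            cols[name] = scores[:, j]
            cats[name] = "spatial_pca"
    for name in INDICATOR_NAMES:
        cols[name] = indicators[name].to_numpy(dtype=float)
        cats[name] = _INDICATOR_CATEGORY[name]
    values = pd.DataFrame(cols, index=patients)
    return FeatureTable(values=values, categories=cats), models


def zone_feature_proxies(table: FeatureTable, zone: str) -> set[str]:
    """Surviving feature columns that carry dose information from ``zone``.

    A PCA feature of any zone whose mask overlaps ``zone`` contains that
    region's voxels in its DVH; a column pruned as collinear is represented
    by the kept column it collided with. The returned set restricts to
    columns present in the (pruned) table.
    """
    from .geometry import enumerate_zone_names, zones_overlap

    names = set(table.feature_names)
    proxies = set()
    for other in enumerate_zone_names():
        if zones_overlap(other, zone):
            for j in (1, 2):
                rep = table.representative(f"{other}_PCA{j}")
                if rep in names:
                    proxies.add(rep)
    return proxies


def scale_and_prune(table: FeatureTable, r_threshold: float = 0.9) -> FeatureTable:
    """Min–max scale every column to [0, 1], then drop collinear columns.

    Pruning walks the columns in catalogue order; when a later column's
    absolute Pearson correlation with an already-kept column exceeds the
    threshold, the later column is dropped and mapped to that keeper.
    Constant columns scale to all-zero and are flagged (they carry no
    correlation and are never treated as collinear).
    """
    if len(table.values) < 2:
        raise ValueError("scaling and pruning need at least 2 patients")
    X = table.values.to_numpy(dtype=float)
    names = table.feature_names
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = hi - lo
    constant = span <= 0
    scaled = np.zeros_like(X)
    nz = ~constant
    scaled[:, nz] = (X[:, nz] - lo[nz]) / span[nz]

    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(scaled, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)

    kept: list[int] = []
    pruned: dict[str, str] = {}
    for j in range(len(names)):
        if constant[j]:
            kept.append(j)
            continue
        hit = next((k for k in kept if abs(corr[j, k]) > r_threshold), None)
        if hit is None:
            kept.append(j)
        else:
            pruned[names[j]] = names[hit]

    kept_names = [names[j] for j in kept]
    values = pd.DataFrame(scaled[:, kept], index=table.values.index, columns=kept_names)
    chain = dict(table.pruned_to_keeper)
    chain.update(pruned)
    return FeatureTable(
        values=values,
        categories={n: table.categories[n] for n in kept_names},
        scaling_params={n: (float(lo[j]), float(hi[j])) for n, j in zip(kept_names, kept)},
        pruned_to_keeper=chain,
        constant_columns=tuple(n for n, c in zip(names, constant) if c and n in kept_names),
    )
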