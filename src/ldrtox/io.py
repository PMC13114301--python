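"""File schemas for cohort exchange.

* ``contours.json`` — ``{patient_id: [{"z_mm": z, "prostate": [[x, y], ...],
  "urethra_center": [x, y]}, ...], ...}``; any extra keys (e.g. a rectum
  polygon) are ignored.
* ``seeds.csv`` — ``patient_id, seed_index, x_mm, y_mm, z_mm,
  air_kerma_strength_U``.
* ``cohort.csv`` — ``patient_id, baseline_ipss, needles, seeds``; follow-ups
  live in the companion long-format ``ipss_followups.csv`` with columns
  ``patient_id, t_months, ipss``.
* ``zones.npz`` — boolean mask archive, one array per zone name plus the
  grid origin/spacing/dims.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dosimetry import SeedImplant, SourceModel, BEST_2301
from .geometry import ProstateAnatomy, VoxelGrid, ZoneCatalogue
from .outcome import IPSSRecord

__all__ = [
    "write_contours",
    "read_contours",
    "write_seeds",
    "read_seeds",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_zone_masks",
    "read_zone_masks",
    "write_cohort_dir",
]


def write_contours(anatomies: dict[str, ProstateAnatomy], path: str | Path) -> None:
    payload = {
        pid: [
            {
                "z_mm": float(z),
                "prostate": np.asarray(poly, dtype=float).tolist(),
                "urethra_center": [float(c) for c in center],
            }
            for (z, poly), center in zip(a.slices, a.urethra_centers)
        ]
        for pid, a in anatomies.items()
    }
    Path(path).write_text(json.dumps(payload))


def read_contours(path: str | Path) -> dict[str, ProstateAnatomy]:
    raw = json.loads(Path(path).read_text())
    out = {}
    for pid, slices in raw.items():
        out[pid] = ProstateAnatomy(
            slices=[(s["z_mm"], np.asarray(s["prostate"], dtype=float)) for s in slices],
            urethra_centers=[tuple(s["urethra_center"]) for s in slices],
        )
    return out


def write_seeds(implants: dict[str, SeedImplant], path: str | Path) -> None:
    rows = []
    for pid, imp in implants.items():
        for j, (x, y, z) in enumerate(imp.seeds):
            rows.append((pid, j, x, y, z, imp.air_kerma_strength))
    pd.DataFrame(
        rows,
        columns=["patient_id", "seed_index", "x_mm", "y_mm", "z_mm", "air_kerma_strength_U"],
    ).to_csv(path, index=False)


def read_seeds(
    path: str | Path, source_model: SourceModel = BEST_2301
) -> dict[str, SeedImplant]:
    df = pd.read_csv(path)
    out = {}
    for pid, grp in df.groupby("patient_id", sort=False):
        grp = grp.sort_values("seed_index")
        out[str(pid)] = SeedImplant(
            seeds=grp[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
            air_kerma_strength=float(grp["air_kerma_strength_U"].iloc[0]),
            source_model=source_model,
        )
    return out


def write_cohort_csv(
    records: list[IPSSRecord],
    needles: dict[str, int],
    seeds: dict[str, int],
    path: str | Path,
) -> None:
    path = Path(path)
    pd.DataFrame(
        [
            (r.patient_id, r.baseline_ipss, needles[r.patient_id], seeds[r.patient_id])
            for r in records
        ],
        columns=["patient_id", "baseline_ipss", "needles", "seeds"],
    ).to_csv(path, index=False)
    long_rows = [
        (r.patient_id, t, s) for r in records for t, s in r.followups
    ]
    pd.DataFrame(long_rows, columns=["patient_id", "t_months", "ipss"]).to_csv(
        path.with_name("ipss_followups.csv"), index=False
    )


def read_cohort_csv(path: str | Path) -> tuple[pd.DataFrame, list[IPSSRecord]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort file not found: {path}")
    table = pd.read_csv(path)
    fu_path = path.with_name("ipss_followups.csv")
    if not fu_path.exists():
        raise FileNotFoundError(f"follow-up file not found: {fu_path}")
    fu = pd.read_csv(fu_path)
    records = []
    for _, row in table.iterrows():
        pid = str(row["patient_id"])
        mine = fu[fu["patient_id"].astype(str) == pid].sort_values("t_months")
        records.append(
            IPSSRecord(
                patient_id=pid,
                baseline_ipss=int(row["baseline_ipss"]),
                followups=[(float(t), int(s)) for t, s in zip(mine["t_months"], mine["ipss"])],
            )
        )
    return table, records


def write_zone_masks(zones: ZoneCatalogue, path: str | Path) -> None:
    arrays = {f"mask:{name}": m for name, m in zones.zone_masks.items()}
    np.savez_compressed(
        path,
        origin=np.array(zones.grid.origin),
        spacing=np.array(zones.grid.spacing),
        dims=np.array(zones.grid.dims),
        axial_boundaries=np.array(zones.axial_boundaries),
        **arrays,
    )


def read_zone_masks(path: str | Path) -> ZoneCatalogue:
    with np.load(path) as z:
        grid = VoxelGrid(
            origin=tuple(z["origin"]),
            spacing=tuple(z["spacing"]),
            dims=tuple(int(d) for d in z["dims"]),
        )
        from .geometry import enumerate_zone_names

        masks = {name: z[f"mask:{name}"] for name in enumerate_zone_names()}
        return ZoneCatalogue(
            grid=grid,
            zone_masks=masks,
            axial_boundaries=tuple(z["axial_boundaries"]),
        )


def write_cohort_dir(cohort, outdir: str | Path) -> Path:
    """Write a generated cohort in the pipeline's input schemas."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_contours({p.patient_id: p.anatomy for p in cohort.patients}, outdir / "contours.json")
    write_seeds({p.patient_id: p.implant for p in cohort.patients}, outdir / "seeds.csv")
    write_cohort_csv(
        cohort.records,
        {p.patient_id: p.implant.needle_count for p in cohort.patients},
        {p.patient_id: p.implant.n_seeds for p in cohort.patients},
        outdir / "cohort.csv",
    )
    return outdir
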