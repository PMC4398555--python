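"""End-to-end orchestration: annotations -> model -> region -> report.

`run_eye` composes the full measurement for one eye and returns an
:class:`EyeReport`; `run_reproducibility` repeats it over several annotation
sets of the same eye and reports per-metric coefficients of variation;
`run_cohort` runs the group-comparison statistics over a cohort table.
Everything is deterministic given its inputs, and each stage's parameters are
echoed into the report so a run can be reproduced from the report alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import region_thickness as rt
from . import stats as st
from .annotations import AnnotationSet, load_annotations, validate_annotations
from .surface_model import DEFAULT_N, build_lc_model

__all__ = ["EyeReport", "run_eye", "run_reproducibility", "run_cohort"]

log = logging.getLogger("lc3d")

GROUPS = ("normal", "PPG", "NTG")


@dataclass
class EyeReport:
    """Per-eye measurement summary (the quantities a reader compares across eyes)."""

    avg_lct_um: float
    unweighted_avg_lct_um: float
    reliable_area_mm2: float
    bmo_area_mm2: float | None
    area_ratio_pct: float | None
    M: int
    N: int
    delta_theta_deg: float
    n_reliable_nodes: int
    annotation_hash: str | None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_eye(
    annotations: AnnotationSet | str | Path,
    M: int | None = None,
    N: int = DEFAULT_N,
    out_dir: str | Path | None = None,
    write_png: bool = False,
) -> EyeReport:
    """Measure one eye from its annotation set.

    Stages: validate marks, build the two-pass spline LC model, close the
    reliable boundary, mask the polar grid, compute the thickness map and
    avgLCT, and (when BMO edges are marked) the BMO area and area ratio.
    With ``out_dir`` set, writes ``report.json`` and ``map.csv`` (and
    ``map.png`` if requested).
    """
    ann_hash = None
    if not isinstance(annotations, AnnotationSet):
        ann_hash = _file_hash(annotations)
        annotations = load_annotations(annotations)

    issues = validate_annotations(annotations)
    if issues:
        raise ValueError("invalid annotations: " + "; ".join(issues))

    log.info("model: M=%d N=%d", annotations.M if M is None else M, N)
    model = build_lc_model(annotations, M=M, N=N)
    for w in model.warnings:
        log.warning("model: %s", w)

    boundary = rt.boundary_from_bounds(
        annotations.reliable, model.bmo_center, model.delta_theta
    )
    mask = rt.mask_polar_grid(model, annotations.reliable, boundary)
    tmap = rt.compute_thickness_map(model, mask)
    avg = rt.average_thickness(tmap)
    reliable_area = rt.curve_area(boundary)

    bmo_area = ratio = None
    if len(annotations.bmo.edge_points) == annotations.M:
        bmo_area = rt.curve_area(rt.boundary_from_bmo(annotations))
        ratio = rt.area_ratio(reliable_area, bmo_area)

    report = EyeReport(
        avg_lct_um=avg,
        unweighted_avg_lct_um=rt.average_thickness(tmap, weighted=False),
        reliable_area_mm2=reliable_area,
        bmo_area_mm2=bmo_area,
        area_ratio_pct=ratio,
        M=model.anterior.M,
        N=model.anterior.N,
        delta_theta_deg=math.degrees(model.delta_theta),
        n_reliable_nodes=int(mask.mask.sum()),
        annotation_hash=ann_hash,
        warnings=list(model.warnings),
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report.to_dict(), indent=1))
        _write_map_csv(model, tmap, out_dir / "map.csv")
        if write_png:
            _write_map_png(model, tmap, out_dir / "map.png")
    return report


def _write_map_csv(model, tmap, path) -> None:
    grid = model.anterior
    cx, cy = model.bmo_center
    rows = []
    for i in range(grid.M):
        th = i * grid.delta_theta
        for j in range(grid.N + 1):
            r = grid.r_grid[i, j]
            rows.append({
                "axis_index": i, "j": j, "r_um": r,
                "x_um": cx + r * math.cos(th), "y_um": cy + r * math.sin(th),
                "thickness_um": tmap.thickness[i, j],
                "masked": bool(tmap.mask.mask[i, j]),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def _write_map_png(model, tmap, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = model.anterior
    theta = np.append(grid.theta(), 2 * math.pi)
    r = grid.r_grid[0]
    t = np.vstack([tmap.thickness, tmap.thickness[:1]])
    m = np.vstack([tmap.mask.mask, tmap.mask.mask[:1]])
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 4))
    pc = ax.pcolormesh(theta, r, np.where(m, t, np.nan).T, shading="auto", cmap="viridis")
    fig.colorbar(pc, label="LC thickness (um)")
    ax.set_title("LC thickness map (reliable region)")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_reproducibility(
    annotation_sets, M: int | None = None, N: int = DEFAULT_N
) -> dict:
    """Intrasession reproducibility: repeated markings of one eye.

    Returns per-set avgLCT values plus the coefficient of variation of
    avgLCT and of the reliable area across the repeats.
    """
    if len(annotation_sets) < 2:
        raise ValueError("need >= 2 annotation sets")
    reports = [run_eye(a, M=M, N=N) for a in annotation_sets]
    avgs = [r.avg_lct_um for r in reports]
    areas = [r.reliable_area_mm2 for r in reports]
    return {
        "avg_lct_um": avgs,
        "cv_avg_lct_pct": st.coefficient_of_variation(avgs),
        "reliable_area_mm2": areas,
        "cv_reliable_area_pct": st.coefficient_of_variation(areas),
        "n_runs": len(reports),
    }


def run_cohort(
    cohort: pd.DataFrame | str | Path,
    roc_positive: tuple[str, ...] = ("PPG", "NTG"),
) -> dict:
    """Group comparison, correlations and ROC over a per-eye cohort table.

    Expects columns ``id, group, avgLCT_um, cpRNFLT_um, MD_dB, age_y, sex,
    IOP_mmHg, refraction_D`` with ``group`` in {normal, PPG, NTG}.  The ROC
    contrasts normal eyes against ``roc_positive`` (default: all glaucoma)
    using avgLCT with lower-is-positive orientation.
    """
    if not isinstance(cohort, pd.DataFrame):
        cohort = pd.read_csv(cohort)
    unknown = set(cohort["group"]) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group label(s): {sorted(unknown)}")
    present = [g for g in GROUPS if (cohort["group"] == g).any()]
    if len(present) < 2:
        raise ValueError("need at least 2 groups in the cohort")

    by_group = {g: cohort[cohort["group"] == g] for g in present}
    out: dict = {"n": len(cohort), "groups": {}}
    for g, sub in by_group.items():
        out["groups"][g] = {
            "n": len(sub),
            **{
                col: {"mean": float(sub[col].mean()), "sd": float(sub[col].std(ddof=1))}
                for col in ("avgLCT_um", "cpRNFLT_um", "MD_dB", "age_y", "IOP_mmHg",
                            "refraction_D")
            },
        }

    kw = {}
    for col in ("avgLCT_um", "cpRNFLT_um", "MD_dB", "age_y", "IOP_mmHg", "refraction_D"):
        h, p = st.kruskal_wallis([by_group[g][col].to_numpy() for g in present])
        kw[col] = {"H": h, "p": p}
    out["kruskal_wallis"] = kw

    if len(present) >= 3:
        sd = st.steel_dwass([by_group[g]["avgLCT_um"].to_numpy() for g in present])
        out["steel_dwass_avgLCT"] = {
            f"{present[i]}_vs_{present[j]}": {"z": z, "p": p}
            for (i, j), (z, p) in sd.items()
        }

    sex_table = np.array([
        [int((by_group[g]["sex"] == "M").sum()), int((by_group[g]["sex"] == "F").sum())]
        for g in present
    ]).T
    chi2, p = st.chi_square_independence(sex_table)
    out["sex_chi_square"] = {"chi2": chi2, "p": p}

    lct = cohort["avgLCT_um"].to_numpy()
    rho, p = st.spearman(lct, cohort["cpRNFLT_um"].to_numpy())
    out["spearman_avgLCT_cpRNFLT"] = {"rho": rho, "p": p}
    rho, p = st.spearman(lct, cohort["MD_dB"].to_numpy())
    out["spearman_avgLCT_MD"] = {"rho": rho, "p": p}
    age = cohort["age_y"].to_numpy()
    out["partial_spearman_age_corrected"] = {
        "avgLCT_cpRNFLT": st.partial_spearman(lct, cohort["cpRNFLT_um"].to_numpy(), age),
        "avgLCT_MD": st.partial_spearman(lct, cohort["MD_dB"].to_numpy(), age),
    }

    pos = cohort["group"].isin(roc_positive).to_numpy()
    if pos.any() and (~pos).any():
        roc = st.roc_youden(lct, pos, direction="lower_is_positive")
        out["roc_avgLCT"] = {
            "positive_groups": list(roc_positive),
            "auc": roc.auc, "cutoff_um": roc.cutoff,
            "sensitivity": roc.sensitivity, "specificity": roc.specificity,
        }
    return out
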