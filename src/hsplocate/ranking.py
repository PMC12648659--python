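"""Solvent ranking, Δδ decomposition and report/plot-data export.

Given a material location in Hansen space, every panel solvent gets its
Hansen distance R and per-axis deltas (ΔδD, ΔδP, ΔδH); solvents are sorted
by ascending R (best solvent first), ties broken alphabetically. Reports
are CSV-first (diff- and round-trip-friendly) with an optional XLSX mirror,
plus a flat scatter-record table for 3D Hansen-space plotting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Tuple, Union

import pandas as pd

from .core import HspVector, as_hsp, component_deltas, hansen_distance
from .database import SolventRecord
from .errors import InvalidInputError
from .locator import LocateResult, MeasurementSet

__all__ = [
    "RankedSolvent",
    "SolventRanking",
    "rank_solvents",
    "rank_candidates",
    "decomposition_table",
    "plot_data",
    "export_report",
    "render_plot",
]

RANKING_COLUMNS = ["solvent", "absorbance", "lambda_max", "dD", "dP", "dH", "R", "ddD", "ddP", "ddH"]


@dataclass(frozen=True)
class RankedSolvent:
    name: str
    hsp: HspVector
    distance: float  # Hansen distance R to the material
    ddD: float
    ddP: float
    ddH: float
    absorbance: Optional[float] = None
    lambda_max: Optional[float] = None


@dataclass(frozen=True)
class SolventRanking:
    """Panel solvents sorted by ascending Hansen distance to ``material``."""

    material: HspVector
    rows: Tuple[RankedSolvent, ...]

    def to_frame(self, decimals: Optional[int] = None) -> pd.DataFrame:
        """Tabulate; ``decimals`` rounds the numeric columns for display."""
        df = pd.DataFrame(
            [
                {
                    "solvent": r.name,
                    "absorbance": r.absorbance,
                    "lambda_max": r.lambda_max,
                    "dD": r.hsp.dD,
                    "dP": r.hsp.dP,
                    "dH": r.hsp.dH,
                    "R": r.distance,
                    "ddD": r.ddD,
                    "ddP": r.ddP,
                    "ddH": r.ddH,
                }
                for r in self.rows
            ],
            columns=RANKING_COLUMNS,
        )
        if decimals is not None:
            num = df.columns.drop("solvent")
            df[num] = df[num].round(decimals)
        return df


Candidate = Union[SolventRecord, Tuple[str, HspVector]]


def _ranked(material: HspVector, name: str, hsp: HspVector, absorbance=None, lambda_max=None):
    dd, dp, dh = component_deltas(material, hsp)
    return RankedSolvent(
        name=name,
        hsp=hsp,
        distance=hansen_distance(material, hsp),
        ddD=dd,
        ddP=dp,
        ddH=dh,
        absorbance=absorbance,
        lambda_max=lambda_max,
    )


def rank_solvents(material, ms: MeasurementSet) -> SolventRanking:
    """Rank a measurement panel by Hansen distance to ``material``.

    A solvent coincident with the material ranks first with R = 0; exact
    distance ties fall back to alphabetical order.
    """
    material = as_hsp(material)
    rows = [
        _ranked(material, m.solvent, m.hsp, m.absorbance, m.lambda_max)
        for m in ms.measurements
    ]
    rows.sort(key=lambda r: (r.distance, r.name.lower()))
    return SolventRanking(material=material, rows=tuple(rows))


def rank_candidates(material, candidates: Iterable[Candidate]) -> SolventRanking:
    """Rank bare (name, HSP) candidates or database records (no absorbances)."""
    material = as_hsp(material)
    rows = []
    for c in candidates:
        if isinstance(c, SolventRecord):
            rows.append(_ranked(material, c.name, c.hsp))
        else:
            name, hsp = c
            rows.append(_ranked(material, name, as_hsp(hsp)))
    if not rows:
        raise InvalidInputError("no candidates to rank")
    rows.sort(key=lambda r: (r.distance, r.name.lower()))
    return SolventRanking(material=material, rows=tuple(rows))


def decomposition_table(material, candidates: Iterable[Candidate]) -> pd.DataFrame:
    """Per-solvent (R, ΔδD, ΔδP, ΔδH) in the given candidate order.

    The interpretation aid: which individual interaction axis drives the
    mismatch between material and solvent.
    """
    material = as_hsp(material)
    rows = []
    for c in candidates:
        name, hsp = (c.name, c.hsp) if isinstance(c, SolventRecord) else (c[0], as_hsp(c[1]))
        dd, dp, dh = component_deltas(material, hsp)
        rows.append(
            {"solvent": name, "R": hansen_distance(material, hsp), "ddD": dd, "ddP": dp, "ddH": dh}
        )
    if not rows:
        raise InvalidInputError("no candidates to decompose")
    return pd.DataFrame(rows, columns=["solvent", "R", "ddD", "ddP", "ddH"])


def plot_data(material, ranking: SolventRanking) -> pd.DataFrame:
    """Flat scatter records for the 3D Hansen-space plot.

    One row per solvent plus one ``role='material'`` row (the star in the
    plot) carrying R = 0 to itself. Rendering is a thin optional layer on
    top of these records (:func:`render_plot`).
    """
    material = as_hsp(material)
    rows = [
        {
            "dD": material.dD,
            "dP": material.dP,
            "dH": material.dH,
            "label": "material",
            "role": "material",
            "R": hansen_distance(material, ranking.material),
        }
    ]
    for r in ranking.rows:
        rows.append(
            {
                "dD": r.hsp.dD,
                "dP": r.hsp.dP,
                "dH": r.hsp.dH,
                "label": r.name,
                "role": "solvent",
                "R": r.distance,
            }
        )
    return pd.DataFrame(rows, columns=["dD", "dP", "dH", "label", "role", "R"])


def export_report(
    result: LocateResult,
    ranking: SolventRanking,
    outdir,
    decimals: int = 2,
    xlsx: bool = False,
) -> dict:
    """Write the report triplet under ``outdir``; returns the paths.

    * ``report_summary.csv`` — estimate, init, iterations, convergence flag,
      objective and the rounding-derived global error;
    * ``report_ranking.csv`` — the full-precision ranking (re-loading it
      reproduces every number exactly; use ``decimals`` only for display);
    * ``plot_data.csv`` — scatter records for the Hansen-space plot.

    With ``xlsx=True`` an ``report.xlsx`` mirror (one sheet per table,
    numbers rounded to ``decimals``) is written too.
    """
    if decimals < 0:
        raise InvalidInputError(f"decimals must be >= 0, got {decimals}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    est, ini = result.estimate, result.init
    summary = pd.DataFrame(
        [
            ("estimate_dD", est.dD), ("estimate_dP", est.dP), ("estimate_dH", est.dH),
            ("init_dD", ini.dD), ("init_dP", ini.dP), ("init_dH", ini.dH),
            ("iterations", result.iterations),
            ("converged", result.converged),
            ("objective", result.objective_value),
            ("global_error", round(result.config.tol, decimals)),
            ("alpha", result.config.alpha),
            ("tol", result.config.tol),
            ("max_iter", result.config.max_iter),
        ],
        columns=["key", "value"],
    )
    ranking_df = ranking.to_frame()
    plot_df = plot_data(ranking.material, ranking)
    paths = {
        "summary": outdir / "report_summary.csv",
        "ranking": outdir / "report_ranking.csv",
        "plot_data": outdir / "plot_data.csv",
    }
    summary.to_csv(paths["summary"], index=False)
    ranking_df.to_csv(paths["ranking"], index=False)
    plot_df.to_csv(paths["plot_data"], index=False)
    if xlsx:
        paths["xlsx"] = outdir / "report.xlsx"
        with pd.ExcelWriter(paths["xlsx"], engine="openpyxl") as writer:
            summary.to_excel(writer, sheet_name="summary", index=False)
            ranking.to_frame(decimals=decimals).to_excel(writer, sheet_name="ranking", index=False)
            plot_df.round(decimals).to_excel(writer, sheet_name="plot_data", index=False)
    return paths


def render_plot(plot_df: pd.DataFrame, path) -> None:
    """Optional 3D scatter of the Hansen space (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    solvents = plot_df[plot_df["role"] == "solvent"]
    material = plot_df[plot_df["role"] == "material"]
    sc = ax.scatter(
        solvents["dD"], solvents["dP"], solvents["dH"],
        c=solvents["R"], cmap="viridis", s=40, label="solvents",
    )
    ax.scatter(
        material["dD"], material["dP"], material["dH"],
        marker="*", s=300, c="red", label="material",
    )
    fig.colorbar(sc, ax=ax, shrink=0.6, label="Hansen distance R / MPa$^{1/2}$")
    ax.set_xlabel(r"$\delta_D$ / MPa$^{1/2}$")
    ax.set_ylabel(r"$\delta_P$ / MPa$^{1/2}$")
    ax.set_zlabel(r"$\delta_H$ / MPa$^{1/2}$")
    ax.legend()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
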