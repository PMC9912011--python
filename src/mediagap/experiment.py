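"""Reconstruction-by-simulation experiment grid.

Reconstruct every cohort model under each gap-fill medium, profile its
amino-acid auxotrophies under each simulation medium, and aggregate into
a grid of (reconstruction medium x simulation medium) cells — the
experiment that exposes how the gap-fill medium, more than genome
completeness, determines the auxotrophies a reconstructed model appears
to have.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .auxotrophy import (
    MODE_OMISSION,
    MODE_PRECURSOR,
    omission_auxotrophies,
    precursor_auxotrophies,
)
from .fba import can_grow
from .gapfill import (
    STATUS_INFEASIBLE,
    GapFillResult,
    gapfill,
    integrate,
)
from .network import Medium, MetabolicNetwork
from .synth import GenomeSample, Universe, draft_network


@dataclass
class ReconstructedModel:
    """One gap-filled model: a (genome sample, reconstruction medium) pair."""

    sample: GenomeSample
    medium_id: str
    network: Optional[MetabolicNetwork]
    result: GapFillResult


@dataclass
class GridCell:
    reconstruction_medium: str
    simulation_medium: str
    mean_auxotrophies: float
    sd_auxotrophies: float
    growth_fraction: float
    n_models: int


@dataclass
class ModelRecord:
    """Per-model bookkeeping across all simulation media."""

    model_id: str
    completeness: float
    contamination: float
    reconstruction_medium: str
    n_gapfilled: int
    gapfilled_fraction: float
    auxotrophy_counts: Dict[str, float] = field(default_factory=dict)
    growth: Dict[str, bool] = field(default_factory=dict)


def reconstruct_cohort(
    cohort: Sequence[GenomeSample],
    universe: Universe,
    media: Sequence[Medium],
    epsilon: float = 1e-3,
) -> List[ReconstructedModel]:
    """Gap fill every genome sample on every reconstruction medium.

    Infeasible gap fills are recorded (with network None), never dropped.
    """
    if not media:
        raise ValueError("at least one reconstruction medium is required")
    out: List[ReconstructedModel] = []
    for sample in cohort:
        draft = draft_network(universe, sample)
        for medium in media:
            result = gapfill(draft, universe.database, medium, epsilon=epsilon)
            network = (
                integrate(draft, universe.database, result)
                if result.status != STATUS_INFEASIBLE
                else None
            )
            out.append(ReconstructedModel(sample, medium.id, network, result))
    return out


def run_grid(
    reconstructed: Sequence[ReconstructedModel],
    simulation_media: Sequence[Medium],
    universe: Universe,
    mode: str = MODE_PRECURSOR,
    tol: float = 1e-6,
    epsilon: float = 1e-3,
) -> Tuple[List[GridCell], List[ModelRecord]]:
    """Profile every reconstructed model under every simulation medium.

    Auxotrophy means/sds per cell are taken over models whose gap fill
    succeeded (plus, in omission mode, models that grow on the simulation
    medium — the omission test is undefined otherwise); growth fractions
    use all models in the cell as denominator, counting failed gap fills
    as non-growing.  Standard deviations use the n-1 denominator.
    """
    biomass = universe.biomass
    records: Dict[Tuple[str, str], ModelRecord] = {}
    counts: Dict[Tuple[str, str], List[float]] = {}
    growth: Dict[Tuple[str, str], List[bool]] = {}
    recon_media_order: List[str] = []

    for rm in reconstructed:
        if rm.medium_id not in recon_media_order:
            recon_media_order.append(rm.medium_id)
        record = ModelRecord(
            model_id=rm.sample.model_id,
            completeness=rm.sample.completeness,
            contamination=rm.sample.contamination,
            reconstruction_medium=rm.medium_id,
            n_gapfilled=len(rm.result.added_ids),
            gapfilled_fraction=rm.result.gapfilled_fraction,
        )
        records[(rm.sample.model_id, rm.medium_id)] = record
        for sim in simulation_media:
            key = (rm.medium_id, sim.id)
            counts.setdefault(key, [])
            growth.setdefault(key, [])
            if rm.network is None:
                growth[key].append(False)
                record.growth[sim.id] = False
                record.auxotrophy_counts[sim.id] = float("nan")
                continue
            grows = can_grow(rm.network, sim, epsilon)
            growth[key].append(grows)
            record.growth[sim.id] = grows
            if mode == MODE_PRECURSOR:
                profile = precursor_auxotrophies(
                    rm.network, sim, biomass, tol=tol, model_id=rm.sample.model_id
                )
            elif mode == MODE_OMISSION:
                if not grows:
                    record.auxotrophy_counts[sim.id] = float("nan")
                    continue
                profile = omission_auxotrophies(
                    rm.network, sim, biomass, epsilon=epsilon, model_id=rm.sample.model_id
                )
            else:
                raise ValueError(f"unknown auxotrophy mode {mode!r}")
            counts[key].append(float(profile.count))
            record.auxotrophy_counts[sim.id] = float(profile.count)

    cells: List[GridCell] = []
    for recon_id in recon_media_order:
        for sim in simulation_media:
            key = (recon_id, sim.id)
            vals = np.asarray(counts[key], dtype=float)
            grow = growth[key]
            cells.append(
                GridCell(
                    reconstruction_medium=recon_id,
                    simulation_medium=sim.id,
                    mean_auxotrophies=float(vals.mean()) if vals.size else float("nan"),
                    sd_auxotrophies=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                    growth_fraction=float(np.mean(grow)) if grow else float("nan"),
                    n_models=len(grow),
                )
            )
    return cells, list(records.values())


_GRID_COLUMNS = [
    "reconstruction_medium",
    "simulation_medium",
    "mean_auxotrophies",
    "sd_auxotrophies",
    "growth_fraction",
    "n_models",
]

_RECORD_COLUMNS = [
    "model_id",
    "completeness",
    "contamination",
    "reconstruction_medium",
    "n_gapfilled",
    "gapfilled_fraction",
]


def grid_frame(cells: Sequence[GridCell]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "reconstruction_medium": c.reconstruction_medium,
                "simulation_medium": c.simulation_medium,
                "mean_auxotrophies": c.mean_auxotrophies,
                "sd_auxotrophies": c.sd_auxotrophies,
                "growth_fraction": c.growth_fraction,
                "n_models": c.n_models,
            }
            for c in cells
        ],
        columns=_GRID_COLUMNS,
    )


def records_frame(records: Sequence[ModelRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "model_id": r.model_id,
            "completeness": r.completeness,
            "contamination": r.contamination,
            "reconstruction_medium": r.reconstruction_medium,
            "n_gapfilled": r.n_gapfilled,
            "gapfilled_fraction": r.gapfilled_fraction,
        }
        for sim_id, count in sorted(r.auxotrophy_counts.items()):
            row[f"auxotrophies_{sim_id}"] = count
        for sim_id, grows in sorted(r.growth.items()):
            row[f"grows_{sim_id}"] = bool(grows)
        rows.append(row)
    return pd.DataFrame(rows, columns=_RECORD_COLUMNS if not rows else None)


def completeness_analysis(records: Sequence[ModelRecord]) -> Dict[str, float]:
    """Rank correlations of genome quality with gap filling, plus group means.

    Group means split the cohort at 90% completeness (high vs medium
    quality) and average auxotrophy counts over every simulation medium
    present in the records.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    completeness = np.array([r.completeness for r in records])
    contamination = np.array([r.contamination for r in records])
    fraction = np.array([r.gapfilled_fraction for r in records])
    if np.all(completeness == completeness[0]):
        raise ValueError("all completeness values identical; correlation undefined")

    if np.all(fraction == fraction[0]):
        # a constant has no rank association with anything
        rho_c, p_c = 0.0, 1.0
    else:
        rho_c, p_c = stats.spearmanr(completeness, fraction)
    if np.all(contamination == contamination[0]) or np.all(fraction == fraction[0]):
        rho_x, p_x = 0.0, 1.0
    else:
        rho_x, p_x = stats.spearmanr(contamination, fraction)

    def _group_mean(selector) -> float:
        vals = [
            c
            for r in records
            if selector(r.completeness)
            for c in r.auxotrophy_counts.values()
            if not np.isnan(c)
        ]
        return float(np.mean(vals)) if vals else float("nan")

    return {
        "spearman_completeness_vs_gapfill_fraction": float(rho_c),
        "spearman_completeness_pvalue": float(p_c),
        "spearman_contamination_vs_gapfill_fraction": float(rho_x),
        "spearman_contamination_pvalue": float(p_x),
        "mean_auxotrophies_high_completeness": _group_mean(lambda c: c >= 0.90),
        "mean_auxotrophies_medium_completeness": _group_mean(lambda c: c < 0.90),
    }


def summarize(
    cells: Sequence[GridCell],
    records: Sequence[ModelRecord],
    outdir: str | Path,
) -> Dict[str, Path]:
    """Write the grid, growth-fraction and per-model tables as TSV.

    Floats are written with full repr precision so that re-reading the
    files reproduces the in-memory values exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = grid_frame(cells)
    paths = {
        "grid": outdir / "grid_auxotrophies.tsv",
        "growth": outdir / "grid_growth.tsv",
        "models": outdir / "model_records.tsv",
    }
    try:
        grid.to_csv(paths["grid"], sep="\t", index=False)
        grid[
            ["reconstruction_medium", "simulation_medium", "growth_fraction", "n_models"]
        ].to_csv(paths["growth"], sep="\t", index=False)
        records_frame(records).to_csv(paths["models"], sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"failed writing summary under {outdir}: {exc}") from exc
    return paths
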