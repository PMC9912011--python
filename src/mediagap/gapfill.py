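"""Medium-conditioned parsimonious gap filling.

Given a draft network and a universal reaction database, find a
minimum-cost set of database reactions whose addition lets the draft
produce biomass on a reconstruction medium.  The core is a mixed-integer
program (HiGHS via :func:`scipy.optimize.milp`):

    minimize    sum_j w_j * y_j          over candidates j in U \\ draft
    subject to  S v = 0
                lb_j * y_j <= v_j <= ub_j * y_j     (candidates)
                lb_j <= v_j <= ub_j                 (draft reactions)
                v_biomass >= epsilon
                exchange bounds set by the medium

With uniform weights this is parsimonious gap filling: the solver prefers
a single transport reaction over a multi-step biosynthesis pathway
whenever the medium supplies the compound — the mechanism by which the
gap-fill medium imprints auxotrophies on the finished model.

A brute-force subset-enumeration oracle is provided for verification on
small instances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .fba import LPSystem, _get_system, can_grow
from .network import (
    KIND_TRANSPORT,
    Medium,
    MetabolicNetwork,
    subnetwork,
)

STATUS_OPTIMAL = "optimal"
STATUS_INFEASIBLE = "infeasible"
STATUS_ALREADY_GROWING = "already_growing"

#: binary variables within this distance of 1 count as selected
INTEGRALITY_TOL = 1e-6

#: marker returned by the brute-force oracle when no subset works
INFEASIBLE = math.inf


@dataclass
class UniversalDatabase:
    """The candidate reaction pool for gap filling.

    ``decoy_ids`` marks reactions usable as simulated contaminants; they
    are metabolically disconnected from biomass.
    """

    network: MetabolicNetwork
    decoy_ids: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        unknown = self.decoy_ids - set(self.network.reactions)
        if unknown:
            raise ValueError(f"decoy ids not in universal network: {sorted(unknown)[:5]}")


@dataclass
class GapFillResult:
    status: str
    added_ids: Set[str]
    cost: float
    gapfilled_fraction: float


def _fraction(draft: MetabolicNetwork, n_added: int) -> float:
    """Share of genome-encoded reactions in the final model that were added."""
    n_genome = len(draft.genome_encoded_ids()) + n_added
    return n_added / n_genome if n_genome else 0.0


def gapfill(
    draft: MetabolicNetwork,
    universal: UniversalDatabase,
    medium: Medium,
    epsilon: float = 1e-3,
    weights: Optional[Dict[str, float]] = None,
) -> GapFillResult:
    """Parsimonious gap filling of ``draft`` on ``medium``.

    Parameters
    ----------
    epsilon
        Minimum biomass flux (1/h) the integrated model must reach.
    weights
        Optional positive per-reaction costs; default 1 for every
        candidate (minimum reaction count).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    uni = universal.network
    missing = set(draft.reactions) - set(uni.reactions)
    if missing:
        raise ValueError(f"draft reactions not in universal database: {sorted(missing)[:5]}")
    if can_grow(draft, medium, epsilon):
        return GapFillResult(STATUS_ALREADY_GROWING, set(), 0.0, 0.0)

    system: LPSystem = _get_system(uni)
    n = len(system.reaction_ids)
    lb, ub = system.medium_bounds(medium)
    # growth requirement as a variable bound on the biomass column
    b = system.rxn_index[uni.biomass_id]
    lb[b] = max(lb[b], epsilon)

    candidates = [
        rid for rid in system.reaction_ids if rid not in draft.reactions
    ]
    cand_cols = np.array([system.rxn_index[r] for r in candidates], dtype=int)
    k = len(candidates)

    # variables: v (n fluxes) then y (k binaries)
    c = np.zeros(n + k)
    for i, rid in enumerate(candidates):
        w = 1.0 if weights is None else weights.get(rid, 1.0)
        if w <= 0:
            raise ValueError(f"non-positive gap-fill weight for {rid!r}")
        c[n + i] = w

    var_lb = np.concatenate([lb, np.zeros(k)])
    var_ub = np.concatenate([ub, np.ones(k)])
    constraints = [
        LinearConstraint(
            sp.hstack([system.S, sp.csr_matrix((system.S.shape[0], k))], format="csr"),
            0.0,
            0.0,
        )
    ]
    if k:
        rows = np.arange(k)
        sel = sp.csr_matrix((np.ones(k), (rows, cand_cols)), shape=(k, n))
        ymat = sp.eye(k, format="csr")
        # v_j - ub_j y_j <= 0  and  v_j - lb_j y_j >= 0
        upper = sp.hstack([sel, -sp.diags(ub[cand_cols]) @ ymat], format="csr")
        lower = sp.hstack([sel, -sp.diags(lb[cand_cols]) @ ymat], format="csr")
        constraints.append(LinearConstraint(upper, -np.inf, 0.0))
        constraints.append(LinearConstraint(lower, 0.0, np.inf))
        # candidates may only carry flux when selected, so their own bound
        # rows can stay wide; the big-M is the reaction bound itself
        var_lb[cand_cols] = np.minimum(var_lb[cand_cols], 0.0)
        var_ub[cand_cols] = np.maximum(var_ub[cand_cols], 0.0)

    integrality = np.concatenate([np.zeros(n), np.ones(k)])
    res = milp(
        c,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(var_lb, var_ub),
    )
    if res.status != 0 or res.x is None:
        return GapFillResult(STATUS_INFEASIBLE, set(), INFEASIBLE, 0.0)
    y = res.x[n:]
    added = {candidates[i] for i in range(k) if y[i] > 1 - INTEGRALITY_TOL}
    cost = sum(
        1.0 if weights is None else weights.get(rid, 1.0) for rid in added
    )
    return GapFillResult(STATUS_OPTIMAL, added, cost, _fraction(draft, len(added)))


def gapfill_bruteforce(
    draft: MetabolicNetwork,
    universal: UniversalDatabase,
    medium: Medium,
    epsilon: float = 1e-3,
    max_size: int = 4,
) -> float:
    """Exact minimum number of additions enabling growth, by enumeration.

    Tries all candidate subsets of size 0..max_size in increasing size and
    returns the first (hence minimal) cardinality that makes the draft
    grow on the medium; :data:`INFEASIBLE` (inf) if none works.  Only
    usable when the candidate pool is small; serves as the independent
    oracle for the MILP.
    """
    if can_grow(draft, medium, epsilon):
        return 0.0
    candidates = sorted(set(universal.network.reactions) - set(draft.reactions))
    draft_ids = set(draft.reactions)
    for size in range(1, max_size + 1):
        for subset in itertools.combinations(candidates, size):
            candidate_net = subnetwork(universal.network, draft_ids | set(subset))
            if can_grow(candidate_net, medium, epsilon):
                return float(size)
    return INFEASIBLE


def integrate(
    draft: MetabolicNetwork,
    universal: UniversalDatabase,
    result: GapFillResult,
) -> MetabolicNetwork:
    """Union of the draft with the gap-filled reactions.

    Added reactions carry ``origin="gapfilled"`` so downstream analysis
    can tell database additions from genome-derived content.
    """
    if result.status == STATUS_INFEASIBLE:
        raise ValueError("cannot integrate an infeasible gap-fill result")
    out = draft.copy()
    for rid in sorted(result.added_ids):
        rxn = universal.network.reactions[rid].copy()
        rxn.origin = "gapfilled"
        out.add_reaction(rxn)
        for mid in rxn.stoichiometry:
            if mid not in out.metabolites:
                out.add_metabolite(universal.network.metabolites[mid])
    return out


def classify_additions(
    result: GapFillResult, universal: UniversalDatabase
) -> Dict[str, int]:
    """Partition gap-filled reactions into transport / biosynthesis / other.

    The transport-versus-biosynthesis split is the mechanistic readout of
    media-conditioned gap filling: rich media lead to transporter
    additions, minimal media to whole biosynthesis pathways.
    """
    counts = {"transport": 0, "biosynthesis": 0, "other": 0}
    for rid in result.added_ids:
        rxn = universal.network.reactions[rid]
        if rxn.pathway_tag == "decoy":
            counts["other"] += 1
        elif rxn.pathway_tag.endswith("_biosynthesis"):
            counts["biosynthesis"] += 1
        elif rxn.kind == KIND_TRANSPORT:
            counts["transport"] += 1
        else:
            counts["other"] += 1
    return counts


def result_table_row(
    result: GapFillResult,
    universal: UniversalDatabase,
    model_id: str,
    medium_id: str,
) -> Dict[str, object]:
    """Flatten a result for the TSV report format."""
    cls = classify_additions(result, universal) if result.status != STATUS_INFEASIBLE else {
        "transport": 0,
        "biosynthesis": 0,
        "other": 0,
    }
    return {
        "model_id": model_id,
        "medium_id": medium_id,
        "status": result.status,
        "n_added": len(result.added_ids),
        "n_transport_added": cls["transport"],
        "n_biosynthesis_added": cls["biosynthesis"],
        "gapfilled_fraction": result.gapfilled_fraction,
    }
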