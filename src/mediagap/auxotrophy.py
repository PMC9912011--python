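"""Medium-conditional amino-acid auxotrophy profiling.

An organism is auxotrophic for an amino acid when it cannot make that
biomass precursor itself — but whether a *model* is called auxotrophic
depends on the medium: uptake from the environment can substitute for
synthesis.  Two call modes are offered:

``precursor_check``
    an amino acid is auxotrophic iff its maximal production flux under
    the medium (synthesis or uptake) is below a small tolerance.  This
    is the primary mode and the one used throughout the experiment grid.

``omission``
    classic single-omission test: the model must grow on the full
    medium, and an amino acid is auxotrophic iff zeroing its uptake
    abolishes growth.  On media containing no amino acids the two modes
    agree (there is nothing to omit).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

from .fba import can_grow, max_producibility
from .network import (
    BiomassComposition,
    Medium,
    MetabolicNetwork,
    extracellular_id,
)

MODE_PRECURSOR = "precursor_check"
MODE_OMISSION = "omission"

#: producibility below this flux counts as "cannot be made"; a feasibility
#: tolerance, deliberately smaller than the growth threshold epsilon
DEFAULT_TOL = 1e-6


@dataclass
class AuxotrophyProfile:
    model_id: str
    medium_id: str
    mode: str
    calls: Dict[str, bool]

    @property
    def count(self) -> int:
        return sum(self.calls.values())

    def auxotrophic_for(self) -> list:
        return sorted(a for a, v in self.calls.items() if v)


def precursor_auxotrophies(
    network: MetabolicNetwork,
    medium: Medium,
    biomass: BiomassComposition,
    tol: float = DEFAULT_TOL,
    model_id: str = "",
) -> AuxotrophyProfile:
    """Call auxotrophies by maximal precursor producibility.

    The amino acid's own exchange keeps its medium-set bound during the
    check, so a transporter plus an amino-acid-containing medium rescues
    a missing pathway — auxotrophy is a property of (model, medium).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    missing = [a for a in biomass.amino_acid_ids if a not in network.metabolites]
    if missing:
        raise KeyError(f"amino acids absent from network metabolites: {missing}")
    calls = {
        aa: max_producibility(network, medium, aa) < tol
        for aa in biomass.amino_acid_ids
    }
    return AuxotrophyProfile(model_id, medium.id, MODE_PRECURSOR, calls)


def omission_auxotrophies(
    network: MetabolicNetwork,
    medium: Medium,
    biomass: BiomassComposition,
    epsilon: float = 1e-3,
    model_id: str = "",
) -> AuxotrophyProfile:
    """Call auxotrophies by single amino-acid omission from the medium."""
    if not can_grow(network, medium, epsilon):
        raise ValueError(
            f"model {model_id or '<unnamed>'} does not grow on medium {medium.id!r}; "
            "omission testing is undefined"
        )
    calls: Dict[str, bool] = {}
    for aa in biomass.amino_acid_ids:
        ext = extracellular_id(aa)
        if medium.limit(ext) == 0.0:
            calls[aa] = False  # nothing to omit; growth already holds without it
            continue
        reduced = Medium(
            id=f"{medium.id}-minus-{ext}",
            uptake_limits={c: v for c, v in medium.uptake_limits.items() if c != ext},
        )
        calls[aa] = not can_grow(network, reduced, epsilon)
    return AuxotrophyProfile(model_id, medium.id, MODE_OMISSION, calls)
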