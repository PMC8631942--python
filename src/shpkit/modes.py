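"""Tandem-SH2 binding-mode energetics.

Converts pairwise pY:SH2 dissociation constants into free energies of the
six candidate modes by which a tandem-SH2 phosphatase can engage a
dual-phosphorylated ITIM/ITSM receptor, and ranks them.

The bivalent modes use the standard effective-concentration avidity cycle

    dG_biv = dG1 + dG2 - R*T*ln(C_eff / 1 M)

so that parallel-vs-antiparallel ordering is independent of C_eff and
equals the ordering of the Kd products of the constituent arms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .exceptions import EmptyRankingError, IncompleteTableError, InvalidParameterError
from .spr import (
    DEFAULT_TEMPERATURE_K,
    GAS_CONSTANT_KCAL,
    AffinityTable,
    NotDetected,
    delta_g,
)

#: Default effective concentration for the pseudo-intramolecular second
#: binding event (M); configurable everywhere it is used.
DEFAULT_C_EFF_M = 1e-3


class BindingMode(Enum):
    MONO_NSH2_ITIM = "MONO_nSH2_ITIM"
    MONO_NSH2_ITSM = "MONO_nSH2_ITSM"
    MONO_CSH2_ITIM = "MONO_cSH2_ITIM"
    MONO_CSH2_ITSM = "MONO_cSH2_ITSM"
    BIVALENT_PARALLEL = "BIVALENT_PARALLEL"
    BIVALENT_ANTIPARALLEL = "BIVALENT_ANTIPARALLEL"

    @property
    def constituents(self) -> tuple[tuple[str, str], ...]:
        """(sh2, motif) pairs engaged in this mode."""
        return _CONSTITUENTS[self]

    @property
    def bivalent(self) -> bool:
        return len(self.constituents) == 2


_CONSTITUENTS = {
    BindingMode.MONO_NSH2_ITIM: (("nSH2", "ITIM"),),
    BindingMode.MONO_NSH2_ITSM: (("nSH2", "ITSM"),),
    BindingMode.MONO_CSH2_ITIM: (("cSH2", "ITIM"),),
    BindingMode.MONO_CSH2_ITSM: (("cSH2", "ITSM"),),
    # parallel: nSH2 on the N-terminal ITIM, cSH2 on the C-terminal ITSM
    BindingMode.BIVALENT_PARALLEL: (("nSH2", "ITIM"), ("cSH2", "ITSM")),
    BindingMode.BIVALENT_ANTIPARALLEL: (("nSH2", "ITSM"), ("cSH2", "ITIM")),
}


@dataclass
class ModeEnergy:
    """Free energy of one binding mode; infeasible modes carry no number."""

    mode: BindingMode
    delta_g: float | None
    feasible: bool
    c_eff: float
    temperature: float

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        dg = "infeasible" if not self.feasible else f"{self.delta_g:.3f} kcal/mol"
        return f"ModeEnergy({self.mode.value}: {dg})"


def _four_kds(table: AffinityTable, receptor: str, phosphatase: str) -> dict:
    kds = {}
    for sh2 in ("nSH2", "cSH2"):
        for motif in ("ITIM", "ITSM"):
            if not table.has(receptor, motif, phosphatase, sh2):
                raise IncompleteTableError(
                    f"affinity table lacks ({phosphatase}-{sh2}, {receptor}-{motif})"
                )
            kds[(sh2, motif)] = table.kd(receptor, motif, phosphatase, sh2)
    return kds


def enumerate_modes(
    table: AffinityTable,
    receptor: str,
    phosphatase: str,
    c_eff: float = DEFAULT_C_EFF_M,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> list[ModeEnergy]:
    """Free energies of all six candidate modes for one receptor:phosphatase pair.

    Any mode containing a NOT_DETECTED constituent is flagged infeasible.
    """
    if c_eff <= 0:
        raise InvalidParameterError("c_eff must be positive")
    kds = _four_kds(table, receptor, phosphatase)

    out = []
    for mode in BindingMode:
        arms = mode.constituents
        if any(isinstance(kds[a], NotDetected) for a in arms):
            out.append(ModeEnergy(mode, None, False, c_eff, temperature))
            continue
        dg = sum(delta_g(kds[a], temperature).delta_g for a in arms)
        if mode.bivalent:
            dg -= GAS_CONSTANT_KCAL * temperature * math.log(c_eff / 1.0)
        out.append(ModeEnergy(mode, dg, True, c_eff, temperature))
    return out


def rank_modes(modes: Sequence[ModeEnergy]) -> list[ModeEnergy]:
    """Ascending free energy (favored first); infeasible modes last."""
    feasible = [m for m in modes if m.feasible]
    if not feasible:
        raise EmptyRankingError("no feasible binding mode")
    feasible.sort(key=lambda m: m.delta_g)
    infeasible = [m for m in modes if not m.feasible]
    return feasible + infeasible


def mode_occupancy(
    modes: Sequence[ModeEnergy],
    free_phosphatase_conc_M: float,
    unbound_delta_g: float = 0.0,
) -> dict:
    """Equilibrium partition over the feasible modes plus the unbound state.

    Each bound mode is a single phosphatase molecule engaging the receptor,
    so every statistical weight is linear in the free phosphatase
    concentration: w_mode = C * exp(-(dG_mode - dG_unbound)/(R*T)).
    Returns a dict mapping BindingMode (and the key ``"unbound"``) to
    fractions that sum to exactly 1.
    """
    if free_phosphatase_conc_M <= 0:
        raise InvalidParameterError("concentration must be positive")
    feasible = [m for m in modes if m.feasible]
    if not feasible:
        raise EmptyRankingError("no feasible binding mode")
    temperature = feasible[0].temperature
    rt = GAS_CONSTANT_KCAL * temperature
    # subtract the minimum exponent for numerical stability
    exponents = np.array([-(m.delta_g - unbound_delta_g) / rt for m in feasible])
    shift = exponents.max()
    weights = free_phosphatase_conc_M * np.exp(exponents - shift)
    w_unbound = math.exp(-shift)
    total = w_unbound + weights.sum()
    occ = {m.mode: float(w / total) for m, w in zip(feasible, weights)}
    occ["unbound"] = float(w_unbound / total)
    return occ


def min_ceff_for_bivalent_advantage(
    table: AffinityTable,
    receptor: str,
    phosphatase: str,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """Smallest C_eff (M) making the bivalent-parallel mode beat every monovalent one.

    Closed form: C_eff* = Kd1 * Kd2 / Kd_best_mono (all in M), where Kd1,
    Kd2 are the parallel-arm constants and Kd_best_mono the tightest
    measurable monovalent constant.
    """
    kds = _four_kds(table, receptor, phosphatase)
    kd1 = kds[("nSH2", "ITIM")]
    kd2 = kds[("cSH2", "ITSM")]
    if isinstance(kd1, NotDetected) or isinstance(kd2, NotDetected):
        raise InvalidParameterError("parallel mode infeasible; C_eff* undefined")
    mono = [v for v in kds.values() if not isinstance(v, NotDetected)]
    kd_best = min(mono)
    return (kd1 * 1e-6) * (kd2 * 1e-6) / (kd_best * 1e-6)
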