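"""Equilibrium SPR analysis.

Langmuir isotherm fitting (Kd, Rmax), affinity tables of pY-motif:SH2
dissociation constants, fold-ratio arithmetic, standard binding free
energies, and a closed-form 1:1 sensorgram simulator.

Units: analyte concentrations are carried in nM, fitted Kd values are
reported in uM, free energies in kcal/mol with a 1 M standard state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import InvalidParameterError, UndefinedRatioError

#: Gas constant in kcal/(mol*K).
GAS_CONSTANT_KCAL = 1.987e-3

#: Default assay temperature (K). Room-temperature handling assumed.
DEFAULT_TEMPERATURE_K = 298.0


class NotDetected:
    """Sentinel for a binding pair with no measurable response."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "NOT_DETECTED"


#: Singleton sentinel used throughout for censored Kd records.
NOT_DETECTED = NotDetected()


def langmuir(concentration, r_max, kd):
    """1:1 equilibrium response R = Rmax*C/(Kd + C); units of C and Kd must agree."""
    c = np.asarray(concentration, dtype=float)
    return r_max * c / (kd + c)


@dataclass
class Isotherm:
    """Equilibrium concentration-response data for one analyte:ligand pair."""

    analyte_id: str
    ligand_id: str
    concentrations_nM: np.ndarray
    responses: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.concentrations_nM, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if c.size != r.size:
            raise InvalidParameterError("concentration and response lengths differ")
        if c.size < 4:
            raise InvalidParameterError("an isotherm needs at least 4 points")
        if np.any(c <= 0):
            raise InvalidParameterError("concentrations must be strictly positive")
        order = np.argsort(c)
        c, r = c[order], r[order]
        if np.any(np.diff(c) <= 0):
            raise InvalidParameterError("concentrations must be distinct")
        self.concentrations_nM = c
        self.responses = r

    def __len__(self) -> int:
        return self.concentrations_nM.size


@dataclass
class IsothermFit:
    """Result of a nonlinear Langmuir fit."""

    kd_uM: float
    r_max: float
    kd_stderr_uM: float
    r_max_stderr: float
    rss: float
    converged: bool
    not_detected: bool = False
    noise_estimate: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "kd_uM": self.kd_uM,
            "r_max": self.r_max,
            "kd_stderr_uM": self.kd_stderr_uM,
            "r_max_stderr": self.r_max_stderr,
            "rss": self.rss,
            "converged": self.converged,
            "not_detected": self.not_detected,
        }


def _initial_guess(iso: Isotherm) -> tuple[float, float]:
    """Rmax <- 1.1*max(R); Kd <- concentration nearest half of that."""
    r_max0 = 1.1 * float(np.max(iso.responses))
    if r_max0 <= 0:
        r_max0 = 1.0
    half = 0.5 * r_max0
    idx = int(np.argmin(np.abs(iso.responses - half)))
    kd0 = float(iso.concentrations_nM[idx])
    return r_max0, kd0


def fit_isotherm(
    iso: Isotherm,
    init_strategy: str = "heuristic",
    init: tuple[float, float] | None = None,
    noise_sd: float | None = None,
    nd_factor: float = 3.0,
) -> IsothermFit:
    """Unweighted nonlinear least squares of the 1:1 Langmuir model.

    Parameters
    ----------
    iso:
        Concentration-response data (concentrations in nM).
    init_strategy:
        ``"heuristic"`` (default) or ``"explicit"`` with ``init=(r_max0, kd0_nM)``.
    noise_sd:
        Known response noise (RU).  When omitted it is estimated from the
        fit residuals.  Used only for the NOT_DETECTED classification:
        a maximum response below ``nd_factor`` times the noise estimate is
        treated as no detectable binding.

    Returns
    -------
    IsothermFit with Kd reported in uM. Non-convergence is flagged, not raised.
    """
    if init_strategy == "explicit":
        if init is None:
            raise InvalidParameterError("init_strategy='explicit' requires init")
        p0 = (float(init[0]), float(init[1]))
    elif init_strategy == "heuristic":
        p0 = _initial_guess(iso)
    else:
        raise InvalidParameterError(f"unknown init_strategy {init_strategy!r}")

    c = iso.concentrations_nM
    r = iso.responses
    try:
        popt, pcov = curve_fit(
            langmuir, c, r, p0=p0, maxfev=20000,
            bounds=((0.0, 0.0), (np.inf, np.inf)),
        )
        converged = bool(np.all(np.isfinite(popt)))
    except (RuntimeError, ValueError):
        return IsothermFit(
            kd_uM=float("nan"), r_max=float("nan"),
            kd_stderr_uM=float("nan"), r_max_stderr=float("nan"),
            rss=float("nan"), converged=False,
        )

    resid = r - langmuir(c, *popt)
    rss = float(np.sum(resid**2))
    dof = max(len(iso) - 2, 1)
    noise = float(noise_sd) if noise_sd is not None else math.sqrt(rss / dof)
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    not_detected = float(np.max(r)) < nd_factor * noise

    return IsothermFit(
        kd_uM=float(popt[1]) / 1e3,
        r_max=float(popt[0]),
        kd_stderr_uM=float(perr[1]) / 1e3,
        r_max_stderr=float(perr[0]),
        rss=rss,
        converged=converged,
        not_detected=not_detected,
        noise_estimate=noise,
    )


def fold_ratio(kd_a: float, kd_b: float) -> float:
    """Fold difference kd_a/kd_b; "x-fold higher affinity of B over A".

    Both operands must be positive measured Kd values (same units);
    a NOT_DETECTED operand has no defined ratio.
    """
    for name, kd in (("kd_a", kd_a), ("kd_b", kd_b)):
        if isinstance(kd, NotDetected):
            raise UndefinedRatioError(f"{name} is NOT_DETECTED; fold ratio undefined")
        if not (float(kd) > 0):
            raise UndefinedRatioError(f"{name} must be positive, got {kd!r}")
    return float(kd_a) / float(kd_b)


def fold_ratio_int(kd_a: float, kd_b: float) -> int:
    """Nearest-integer rendering of :func:`fold_ratio`."""
    return int(round(fold_ratio(kd_a, kd_b)))


@dataclass
class FreeEnergy:
    """Standard binding free energy dG = R*T*ln(Kd / 1 M)."""

    delta_g: float | None
    temperature: float = DEFAULT_TEMPERATURE_K
    gas_constant: float = GAS_CONSTANT_KCAL
    censored: bool = False
    #: for censored records: dG is bounded below by this value (from the
    #: weakest measurable Kd) but is otherwise unknown.
    lower_bound: float | None = None


def delta_g(
    kd_uM: float | NotDetected,
    temperature: float = DEFAULT_TEMPERATURE_K,
    detection_limit_uM: float | None = None,
) -> FreeEnergy:
    """Free energy of binding from a Kd in uM (standard state 1 M).

    A NOT_DETECTED Kd yields a censored marker, never a number; if a
    detection limit is supplied the marker carries the corresponding
    lower bound on dG.
    """
    if isinstance(kd_uM, NotDetected):
        lb = None
        if detection_limit_uM is not None:
            lb = GAS_CONSTANT_KCAL * temperature * math.log(detection_limit_uM * 1e-6)
        return FreeEnergy(delta_g=None, temperature=temperature,
                          censored=True, lower_bound=lb)
    if not (float(kd_uM) > 0):
        raise InvalidParameterError("kd must be positive")
    dg = GAS_CONSTANT_KCAL * temperature * math.log(float(kd_uM) * 1e-6)
    return FreeEnergy(delta_g=dg, temperature=temperature)


def simulate_sensorgram(
    k_on: float,
    k_off: float,
    concentration_M: float,
    times_s: np.ndarray,
    r_max: float = 100.0,
    t_dissociation_s: float | None = None,
) -> np.ndarray:
    """Closed-form pseudo-first-order 1:1 sensorgram.

    Association: R(t) = Req*(1 - exp(-(kon*C + koff)*t)) with
    Req = Rmax*C/(Kd + C), Kd = koff/kon.  If ``t_dissociation_s`` is
    given, later times decay single-exponentially with rate koff.
    """
    if k_on <= 0 or k_off <= 0:
        raise InvalidParameterError("rate constants must be positive")
    if concentration_M < 0:
        raise InvalidParameterError("concentration must be non-negative")
    t = np.asarray(times_s, dtype=float)
    kd = k_off / k_on
    r_eq = r_max * concentration_M / (kd + concentration_M)
    k_obs = k_on * concentration_M + k_off
    r = r_eq * (1.0 - np.exp(-k_obs * t))
    if t_dissociation_s is not None:
        after = t > t_dissociation_s
        r_at = r_eq * (1.0 - math.exp(-k_obs * t_dissociation_s))
        r[after] = r_at * np.exp(-k_off * (t[after] - t_dissociation_s))
    return r


# ---------------------------------------------------------------------------
# Affinity table
# ---------------------------------------------------------------------------

#: CSV sentinel for censored Kd records.
ND_SENTINEL = "ND"


@dataclass(frozen=True)
class AffinityRecord:
    """One Kd for a (receptor motif, SH2 domain) pair."""

    receptor: str
    motif: str          # "ITIM" | "ITSM"
    phosphatase: str    # "SHP1" | "SHP2"
    sh2: str            # "nSH2" | "cSH2"
    kd_uM: float | NotDetected
    source: str = "printed"

    def __post_init__(self):
        if not isinstance(self.kd_uM, NotDetected) and not (float(self.kd_uM) > 0):
            raise InvalidParameterError("kd_uM must be positive or NOT_DETECTED")


class AffinityTable:
    """Collection of affinity records, unique per (receptor, motif, phosphatase, sh2)."""

    def __init__(self, records: Iterable[AffinityRecord]):
        self._records: dict[tuple[str, str, str, str], AffinityRecord] = {}
        for rec in records:
            key = (rec.receptor, rec.motif, rec.phosphatase, rec.sh2)
            if key in self._records:
                raise InvalidParameterError(f"duplicate affinity record for {key}")
            self._records[key] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def get(self, receptor: str, motif: str, phosphatase: str, sh2: str) -> AffinityRecord:
        key = (receptor, motif, phosphatase, sh2)
        try:
            return self._records[key]
        except KeyError:
            raise KeyError(f"no affinity record for {key}") from None

    def kd(self, receptor: str, motif: str, phosphatase: str, sh2: str):
        return self.get(receptor, motif, phosphatase, sh2).kd_uM

    def has(self, receptor: str, motif: str, phosphatase: str, sh2: str) -> bool:
        return (receptor, motif, phosphatase, sh2) in self._records

    # -- serialization ------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in self:
            kd = ND_SENTINEL if isinstance(rec.kd_uM, NotDetected) else rec.kd_uM
            rows.append({
                "receptor": rec.receptor, "motif": rec.motif,
                "phosphatase": rec.phosphatase, "sh2": rec.sh2,
                "kd_uM": kd, "source": rec.source,
            })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dataframe().to_dict(orient="records"), fh, indent=1)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AffinityTable":
        records = []
        for _, row in df.iterrows():
            raw = row["kd_uM"]
            if isinstance(raw, str) and raw.strip().upper() == ND_SENTINEL:
                kd: float | NotDetected = NOT_DETECTED
            else:
                kd = float(raw)
            records.append(AffinityRecord(
                receptor=str(row["receptor"]), motif=str(row["motif"]),
                phosphatase=str(row["phosphatase"]), sh2=str(row["sh2"]),
                kd_uM=kd, source=str(row.get("source", "file")),
            ))
        return cls(records)

    @classmethod
    def from_csv(cls, path) -> "AffinityTable":
        return cls.from_dataframe(pd.read_csv(path))

    @classmethod
    def from_json(cls, path) -> "AffinityTable":
        with open(path) as fh:
            return cls.from_dataframe(pd.DataFrame(json.load(fh)))


def load_reference_affinities() -> AffinityTable:
    """Load the bundled PD-1/BTLA vs SHP1/SHP2 SH2 affinity fixture.

    Records with ``source == "printed"`` are measured dissociation
    constants; ``source == "ordinal"`` records are placeholders that only
    preserve the qualitatively established motif preferences (see the CSV
    header comment) and must not be used for quantitative claims.
    """
    with resources.files("shpkit.data").joinpath("affinity_reference.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    return AffinityTable.from_dataframe(df)
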