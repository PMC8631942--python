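"""ITIM/ITSM motif scanning and pY+1 residue analyses.

Consensus matching (ITIM: [SIVL]xYxx[IVL]; ITSM: TxYxx[VI]), tyrosine
spacing between motifs, hexamer mismatch comparison, and the quadratic
fit of recruitment signal against pY+1 residue molecular volume.

Positions use 1-based full-protein numbering; each motif window covers
pY-2..pY+3 with the tyrosine in slot 3.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import InvalidParameterError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: consensus character classes, window = pY-2..pY+3
ITIM_PATTERN = re.compile(r"(?=([SIVL].Y..[IVL]))")
ITSM_PATTERN = re.compile(r"(?=(T.Y..[VI]))")

#: Amino-acid molecular volumes (A^3), Zamyatnin (1972).
RESIDUE_VOLUMES_A3: dict[str, float] = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

#: tyrosine slot within the 6-residue window (0-based)
Y_SLOT = 2


@dataclass(frozen=True)
class MotifHit:
    """One consensus match, positioned in full-protein numbering."""

    motif_type: str     # "ITIM" | "ITSM"
    y_position: int     # 1-based position of the tyrosine
    window: str         # 6-mer pY-2..pY+3

    def __post_init__(self):
        if self.window[Y_SLOT] != "Y":
            raise InvalidParameterError("window must carry Y in the consensus slot")

    @property
    def py_plus_1(self) -> str:
        return self.window[Y_SLOT + 1]


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    for i, ch in enumerate(seq):
        if ch not in AMINO_ACIDS:
            raise InvalidParameterError(
                f"illegal residue {ch!r} at position {i + 1}")
    return seq


def scan_motifs(sequence: str, offset: int = 1) -> list[MotifHit]:
    """All ITIM and ITSM consensus matches in a protein sequence.

    ``offset`` is the full-protein number of the first residue of
    ``sequence``. Matches sharing a tyrosine are reported once per motif
    type; hits are returned sorted by tyrosine position.
    """
    if offset < 1:
        raise InvalidParameterError("offset must be >= 1")
    seq = _validate_sequence(sequence)

    hits = []
    for motif_type, pattern in (("ITIM", ITIM_PATTERN), ("ITSM", ITSM_PATTERN)):
        seen_y = set()
        for m in pattern.finditer(seq):
            window = m.group(1)
            y_pos = offset + m.start() + Y_SLOT
            if y_pos in seen_y:
                continue
            seen_y.add(y_pos)
            hits.append(MotifHit(motif_type=motif_type, y_position=y_pos,
                                 window=window))
    hits.sort(key=lambda h: (h.y_position, h.motif_type))
    return hits


def tyrosine_spacing(itim_hit: MotifHit, itsm_hit: MotifHit) -> int:
    """Residues separating the ITIM tyrosine from the ITSM tyrosine.

    The ITSM tyrosine must lie C-terminal to the ITIM tyrosine (the
    arrangement in all known dual-motif receptors except SLAMF5).
    """
    if itim_hit.motif_type != "ITIM" or itsm_hit.motif_type != "ITSM":
        raise InvalidParameterError("expected (ITIM hit, ITSM hit)")
    if itsm_hit.y_position <= itim_hit.y_position:
        raise InvalidParameterError(
            "ITSM tyrosine must be C-terminal to the ITIM tyrosine")
    return itsm_hit.y_position - itim_hit.y_position


def motif_hamming(window_a: str, window_b: str, exclude_y: bool = False) -> int:
    """Position-wise mismatches between two motif windows of equal length.

    With ``exclude_y`` the consensus tyrosine slot is skipped, comparing
    only the flanking residues.
    """
    if len(window_a) != len(window_b):
        raise InvalidParameterError("windows must have equal length")
    a, b = window_a.upper(), window_b.upper()
    count = 0
    for i, (ra, rb) in enumerate(zip(a, b)):
        if exclude_y and i == Y_SLOT:
            continue
        if ra != rb:
            count += 1
    return count


@dataclass
class VolumeCurve:
    """Quadratic fit of recruitment signal vs pY+1 molecular volume."""

    coefficients: np.ndarray      # highest order first (a2, a1, a0)
    peak_volume: float | None     # vertex; None when concave-up
    peak_residues: tuple[str, ...]
    has_peak: bool
    in_data_range: bool
    residues: tuple[str, ...]
    volumes: np.ndarray
    signal: np.ndarray


def py1_volume_curve(
    variants: Sequence[tuple[str, float]],
    volume_table: dict[str, float] | None = None,
) -> VolumeCurve:
    """Fit signal vs pY+1 residue volume with a quadratic and locate the peak.

    ``variants`` is a sequence of (residue one-letter code, mean signal).
    The vertex of a concave-down parabola is reported as the peak volume
    together with the residues nearest to it (ties, e.g. Leu/Ile, are
    reported jointly). A concave-up fit yields a no-peak result.
    """
    table = volume_table or RESIDUE_VOLUMES_A3
    if len(variants) < 4:
        raise InvalidParameterError("need >= 4 distinct residues")
    residues = tuple(r.upper() for r, _ in variants)
    if len(set(residues)) != len(residues):
        raise InvalidParameterError("residues must be distinct")
    try:
        volumes = np.array([table[r] for r in residues], dtype=float)
    except KeyError as exc:
        raise InvalidParameterError(f"no volume for residue {exc}") from None
    signal = np.array([s for _, s in variants], dtype=float)

    coeff = np.polyfit(volumes, signal, deg=2)
    a2 = coeff[0]
    # require genuinely concave-down curvature: the quadratic term must
    # contribute non-negligibly over the sampled volume range
    curvature_scale = abs(a2) * (np.ptp(volumes) / 2.0) ** 2
    signal_scale = max(float(np.ptp(signal)), 1e-12)
    if a2 >= 0 or curvature_scale < 1e-8 * signal_scale:
        return VolumeCurve(coefficients=coeff, peak_volume=None,
                           peak_residues=(), has_peak=False, in_data_range=False,
                           residues=residues, volumes=volumes, signal=signal)
    vertex = -coeff[1] / (2.0 * a2)
    dist = {r: abs(v - vertex) for r, v in table.items()}
    dmin = min(dist.values())
    nearest = tuple(sorted(r for r, d in dist.items() if np.isclose(d, dmin)))
    in_range = bool(volumes.min() <= vertex <= volumes.max())
    return VolumeCurve(coefficients=coeff, peak_volume=float(vertex),
                       peak_residues=nearest, has_peak=True,
                       in_data_range=in_range, residues=residues,
                       volumes=volumes, signal=signal)
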