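"""Per-residue titration observables: peak matching, combined chemical-shift
perturbations, and intensity ratios.

The combined CSP between two states of an amide peak is

    CSP = sqrt((dH * 6.5)^2 + dN^2)        [ppm]

i.e. the proton difference scaled by 6.5 combined in quadrature with the
nitrogen difference.  Note that this convention up-weights the proton axis
(many packages instead down-weight nitrogen); it is a uniform rescaling of
the common form, so per-residue patterns are identical up to scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ShiftTable, TitrationDesign, ValidationError

logger = logging.getLogger("nmrbind")

#: proton scaling factor of the combined-CSP formula
H_WEIGHT = 6.5

DEFAULT_TOL_H = 0.05   # ppm
DEFAULT_TOL_N = 0.5    # ppm


@dataclass
class TitrationSeries:
    """Matched per-residue observables across titration points.

    ``shift_tables`` and/or ``intensity_maps`` are keyed by the design's
    point labels; ``reference_label`` names the zero-partner point.
    """

    design: TitrationDesign
    reference_label: str
    shift_tables: dict[str, ShiftTable] = field(default_factory=dict)
    intensity_maps: dict[str, dict[int, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reference_label not in self.design.labels:
            raise ValidationError(
                f"reference point {self.reference_label!r} not in design"
            )
        for label in list(self.shift_tables) + list(self.intensity_maps):
            if label not in self.design.labels:
                raise ValidationError(f"unknown titration point {label!r}")

    @property
    def non_reference_labels(self) -> list[str]:
        return [lab for lab in self.design.labels if lab != self.reference_label]


def match_peaks(
    reference: ShiftTable,
    titrated: ShiftTable,
    tol_h: float = DEFAULT_TOL_H,
    tol_n: float = DEFAULT_TOL_N,
    by_assignment: bool = True,
) -> pd.DataFrame:
    """Correspond residues between two states.

    With ``by_assignment`` (transferred assignments, the default) residues
    are matched by identical residue number.  Otherwise nearest-neighbour
    matching pairs each reference peak with the closest titrated peak inside
    the (tol_h, tol_n) ellipse; two reference peaks claiming the same
    titrated peak (or two candidates inside one ellipse) are flagged
    ambiguous and excluded.

    Returns ``residue_number, matched_residue, status`` with status in
    {matched, unmatched, ambiguous}.
    """
    ref_h, ref_n = reference.atom_vector("H"), reference.atom_vector("N")
    tit_h, tit_n = titrated.atom_vector("H"), titrated.atom_vector("N")
    ref_res = sorted(set(ref_h.index) & set(ref_n.index))
    tit_res = sorted(set(tit_h.index) & set(tit_n.index))

    rows = []
    if by_assignment:
        tit_set = set(tit_res)
        for r in ref_res:
            if r in tit_set:
                rows.append((r, r, "matched"))
            else:
                rows.append((r, None, "unmatched"))
        return pd.DataFrame(rows, columns=["residue_number", "matched_residue", "status"])

    claims: dict[int, list[int]] = {}
    candidates: dict[int, list[int]] = {}
    for r in ref_res:
        d = np.sqrt(
            ((tit_h[tit_res].to_numpy() - ref_h[r]) / tol_h) ** 2
            + ((tit_n[tit_res].to_numpy() - ref_n[r]) / tol_n) ** 2
        )
        inside = [tit_res[i] for i in np.flatnonzero(d <= 1.0)]
        candidates[r] = sorted(inside, key=lambda t: d[tit_res.index(t)])
        for t in inside:
            claims.setdefault(t, []).append(r)

    for r in ref_res:
        cands = candidates[r]
        if not cands:
            rows.append((r, None, "unmatched"))
        elif len(cands) > 1 or len(claims[cands[0]]) > 1:
            rows.append((r, None, "ambiguous"))
        else:
            rows.append((r, cands[0], "matched"))
    return pd.DataFrame(rows, columns=["residue_number", "matched_residue", "status"])


def combined_csp(delta_h: float, delta_n: float) -> float:
    """CSP = sqrt((dH * 6.5)^2 + dN^2); symmetric in the sign of both inputs."""
    return float(np.hypot(H_WEIGHT * delta_h, delta_n))


def compute_csp(series: TitrationSeries) -> pd.DataFrame:
    """Combined CSPs of every matched residue at every non-reference point.

    Returns ``residue_number, point_label, delta_h, delta_n, csp`` (ppm).
    Residues missing H or N in either state are skipped with a log entry.
    """
    ref = series.shift_tables.get(series.reference_label)
    if ref is None:
        raise ValidationError("reference point has no shift table")
    ref_h, ref_n = ref.atom_vector("H"), ref.atom_vector("N")
    rows = []
    for label in series.non_reference_labels:
        table = series.shift_tables.get(label)
        if table is None:
            continue
        h, n = table.atom_vector("H"), table.atom_vector("N")
        for r in sorted(set(ref_h.index) & set(ref_n.index)):
            if r not in h.index or r not in n.index:
                logger.info("residue %d missing H/N at point %s; skipped", r, label)
                continue
            dh = float(h[r] - ref_h[r])
            dn = float(n[r] - ref_n[r])
            rows.append((r, label, dh, dn, combined_csp(dh, dn)))
    return pd.DataFrame(
        rows, columns=["residue_number", "point_label", "delta_h", "delta_n", "csp"]
    )


def intensity_ratios(series: TitrationSeries) -> pd.DataFrame:
    """I/I0 per residue per point.

    Peaks present in the reference but absent at a point are reported with
    ratio 0 and ``disappeared=True`` so that broadening beyond detection
    maps onto the profile.  Reference intensities <= 0 exclude the residue.
    Returns ``residue_number, point_label, i_over_i0, disappeared``.
    """
    ref = series.intensity_maps.get(series.reference_label)
    if ref is None:
        raise ValidationError("reference point has no intensities")
    rows = []
    for label in series.non_reference_labels:
        imap = series.intensity_maps.get(label)
        if imap is None:
            continue
        for r, i0 in sorted(ref.items()):
            if i0 <= 0:
                logger.info("residue %d: non-positive reference intensity; excluded", r)
                continue
            if r in imap:
                rows.append((r, label, imap[r] / i0, False))
            else:
                rows.append((r, label, 0.0, True))
    return pd.DataFrame(
        rows, columns=["residue_number", "point_label", "i_over_i0", "disappeared"]
    )
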