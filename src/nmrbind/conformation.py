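"""Secondary chemical shifts (SCS) and secondary-structure propensities (SSP).

SCS = observed - random coil (positive CA SCS indicates helix).  SSP maps
windowed carbon SCSs onto a single propensity in [-1, 1]: +1 for a window
that exactly matches the bundled fully-formed-helix deviations, -1 for a
full strand, linear in amplitude in between.

The SSP estimator projects each SCS component onto its reference deviation
with |reference|-weighted averaging: for residue i and window W,

    SSP_i = sum_{j in W, atom a} w_ja * v_ja / sum w_ja

where v_ja = scs_ja / helix_ref_ja when the component points helix-ward
(quotient >= 0), v_ja = -scs_ja / strand_ref_ja otherwise, and
w_ja = |reference used|.  With this weighting the numerator reduces to
sum(dCA) - sum(dCB), so the propensity's sign always equals the sign of the
window-mean CA-minus-CB secondary shift.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SequenceRecord, ShiftTable, ValidationError

CARBON_ATOMS = ("CA", "CB", "CO")


def _load_packaged(name: str) -> pd.DataFrame:
    with resources.files("nmrbind.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_random_coil(path: str | Path | None = None) -> pd.DataFrame:
    """Random-coil reference (columns residue_type, atom, shift_ppm)."""
    return pd.read_csv(path) if path is not None else _load_packaged("random_coil.csv")


def load_structure_refs(path: str | Path | None = None) -> pd.DataFrame:
    """Full-helix/strand deviations (residue_type, atom, helix_ppm, strand_ppm)."""
    return pd.read_csv(path) if path is not None else _load_packaged("structure_refs.csv")


def compute_scs(
    shift_table: ShiftTable,
    sequence: SequenceRecord,
    rc_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Secondary chemical shifts: observed minus random coil, per (residue, atom).

    Returns a frame with columns ``residue_number, residue_type, atom, scs``.
    Defined only where both an observed carbon shift and a random-coil
    reference exist (so Gly CB is simply absent).  A residue-type mismatch
    between the table and the sequence is an error naming the residue.
    """
    rc = load_random_coil() if rc_table is None else rc_table
    rc_map = {(r.residue_type, r.atom): r.shift_ppm for r in rc.itertuples()}
    rows = []
    obs = shift_table.frame
    obs = obs[obs["atom"].isin(CARBON_ATOMS)]
    for row in obs.itertuples():
        num = int(row.residue_number)
        if not sequence.first_residue_number <= num <= sequence.last_residue_number:
            continue
        seq_type = sequence.residue_type(num)
        if row.residue_type != seq_type:
            raise ValidationError(
                f"residue {num}: shift table says {row.residue_type!r} "
                f"but sequence says {seq_type!r}"
            )
        ref = rc_map.get((seq_type, row.atom))
        if ref is None:
            continue
        rows.append((num, seq_type, row.atom, row.shift - ref))
    return pd.DataFrame(rows, columns=["residue_number", "residue_type", "atom", "scs"])


def compute_ssp(
    scs_profile: pd.DataFrame,
    window: int = 5,
    atoms: tuple[str, ...] = ("CA", "CB"),
    struct_refs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Window-averaged secondary-structure propensity per residue.

    Parameters
    ----------
    scs_profile:
        Output of :func:`compute_scs`.
    window:
        Odd window length (residues) for smoothing; default 5.
    atoms:
        Carbon atoms entering the propensity; CA/CB by default (CO can be
        added).
    struct_refs:
        Replacement full-helix/strand reference table.

    Returns a frame ``residue_number, ssp, n_components``; residues whose
    window holds no usable carbon SCS are absent (undefined propensity).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    refs = load_structure_refs() if struct_refs is None else struct_refs
    ref_map = {
        (r.residue_type, r.atom): (r.helix_ppm, r.strand_ppm) for r in refs.itertuples()
    }

    prof = scs_profile[scs_profile["atom"].isin(atoms)]
    if prof.empty:
        return pd.DataFrame(columns=["residue_number", "ssp", "n_components"])

    # per-component helix-normalised value and weight
    comp_num: dict[int, list[float]] = {}
    comp_w: dict[int, list[float]] = {}
    for row in prof.itertuples():
        ref = ref_map.get((row.residue_type, row.atom))
        if ref is None:
            continue
        h, s = ref
        v_h = row.scs / h
        if v_h >= 0:
            v, w = v_h, abs(h)
        else:
            v, w = -row.scs / s, abs(s)
        num = int(row.residue_number)
        comp_num.setdefault(num, []).append(v * w)
        comp_w.setdefault(num, []).append(w)

    residues = sorted(comp_num)
    half = window // 2
    out = []
    for num in residues:
        total, weight, n = 0.0, 0.0, 0
        for j in range(num - half, num + half + 1):
            if j in comp_num:
                total += sum(comp_num[j])
                weight += sum(comp_w[j])
                n += len(comp_num[j])
        if n == 0 or weight == 0:
            continue
        out.append((num, total / weight, n))
    return pd.DataFrame(out, columns=["residue_number", "ssp", "n_components"])
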