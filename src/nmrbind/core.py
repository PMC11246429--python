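"""Core data model: sequences, shift tables, titration designs, and the
tabular containers consumed by the analysis stages.

All concentrations are micromolar (uM) internally.  Residue numbering is
1-based and always refers to the full-length protein; a construct knows the
number of its first residue so that segment-local tables can be placed on the
full-length axis explicitly rather than implicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: one-letter alphabet accepted in sequences ('X' = unknown residue)
SEQUENCE_ALPHABET = AMINO_ACIDS + "X"

#: backbone atoms handled throughout
ATOMS = ("H", "N", "CA", "CB", "CO")

#: plausibility windows for amide shifts (ppm); outside -> warning, not error
H_SHIFT_RANGE = (5.0, 13.0)
N_SHIFT_RANGE = (100.0, 140.0)


class ValidationError(ValueError):
    """An input table or sequence violates a structural invariant."""


@dataclass(frozen=True)
class SequenceRecord:
    """A protein (sub)sequence anchored on full-length numbering.

    Parameters
    ----------
    id:
        Identifier (FASTA header word).
    residues:
        One-letter amino-acid string, uppercase, from the 20-letter
        alphabet plus ``X``.
    first_residue_number:
        Full-length-protein number of the first residue (1-based).
    """

    id: str
    residues: str
    first_residue_number: int = 1

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValidationError("sequence must contain at least one residue")
        for i, aa in enumerate(self.residues):
            if aa not in SEQUENCE_ALPHABET:
                raise ValidationError(
                    f"illegal residue {aa!r} at position "
                    f"{self.first_residue_number + i} of sequence {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def residue_numbers(self) -> np.ndarray:
        return np.arange(
            self.first_residue_number, self.first_residue_number + len(self.residues)
        )

    @property
    def last_residue_number(self) -> int:
        return self.first_residue_number + len(self.residues) - 1

    def residue_type(self, residue_number: int) -> str:
        """One-letter type of the residue with the given full-length number."""
        i = residue_number - self.first_residue_number
        if not 0 <= i < len(self.residues):
            raise KeyError(
                f"residue {residue_number} outside {self.id!r} "
                f"({self.first_residue_number}-{self.last_residue_number})"
            )
        return self.residues[i]

    def subsequence(self, start: int, end: int) -> "SequenceRecord":
        """Inclusive slice by full-length residue numbers."""
        i0 = start - self.first_residue_number
        i1 = end - self.first_residue_number + 1
        if i0 < 0 or i1 > len(self.residues) or i0 >= i1:
            raise KeyError(f"range {start}-{end} outside sequence {self.id!r}")
        return SequenceRecord(self.id, self.residues[i0:i1], start)


class ShiftTable:
    """Per-residue, per-atom chemical shifts for one sample state.

    Thin wrapper around a DataFrame with columns
    ``residue_number, residue_type, atom, shift`` (ppm).  At most one record
    per (residue, atom).  Peak intensities, when available (e.g. from Sparky
    lists), live in :attr:`intensities` keyed by residue number.
    """

    COLUMNS = ["residue_number", "residue_type", "atom", "shift"]

    def __init__(self, frame: pd.DataFrame, intensities: dict[int, float] | None = None):
        frame = frame.loc[:, self.COLUMNS].copy()
        frame["residue_number"] = frame["residue_number"].astype(int)
        frame["atom"] = frame["atom"].astype(str)
        frame["shift"] = frame["shift"].astype(float)
        bad = set(frame["atom"]) - set(ATOMS)
        if bad:
            raise ValidationError(f"unknown atom names: {sorted(bad)}")
        if not np.isfinite(frame["shift"]).all():
            raise ValidationError("non-finite chemical shift")
        dup = frame.duplicated(subset=["residue_number", "atom"])
        if dup.any():
            pairs = frame.loc[dup, ["residue_number", "atom"]].values.tolist()
            raise ValidationError(f"duplicate (residue, atom) records: {pairs}")
        for atom, (lo, hi) in (("H", H_SHIFT_RANGE), ("N", N_SHIFT_RANGE)):
            sel = frame[frame["atom"] == atom]
            out = sel[(sel["shift"] < lo) | (sel["shift"] > hi)]
            for _, row in out.iterrows():
                warnings.warn(
                    f"{atom} shift {row['shift']:.2f} ppm of residue "
                    f"{row['residue_number']} outside [{lo}, {hi}] ppm",
                    stacklevel=2,
                )
        self.frame = frame.sort_values(["residue_number", "atom"]).reset_index(drop=True)
        self.intensities = dict(intensities or {})

    @classmethod
    def from_records(
        cls,
        records: list[tuple[int, str, str, float]],
        intensities: dict[int, float] | None = None,
    ) -> "ShiftTable":
        frame = pd.DataFrame(records, columns=cls.COLUMNS)
        return cls(frame, intensities)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ShiftTable):
            return NotImplemented
        return self.frame.equals(other.frame) and self.intensities == other.intensities

    @property
    def residue_numbers(self) -> np.ndarray:
        return np.unique(self.frame["residue_number"].to_numpy())

    def get(self, residue_number: int, atom: str) -> float | None:
        sel = self.frame[
            (self.frame["residue_number"] == residue_number) & (self.frame["atom"] == atom)
        ]
        if sel.empty:
            return None
        return float(sel["shift"].iloc[0])

    def atom_vector(self, atom: str) -> pd.Series:
        """Shifts of one atom indexed by residue number."""
        sel = self.frame[self.frame["atom"] == atom]
        return pd.Series(
            sel["shift"].to_numpy(), index=sel["residue_number"].to_numpy(), name=atom
        )


@dataclass(frozen=True)
class TitrationDesign:
    """Concentration design of a titration.

    ``a_total`` is the observed (labeled) protein concentration in uM;
    ``points`` are (label, b_total_uM) for the partner admixtures.  Percent
    admixtures are converted to uM at load time (percent * a_total / 100);
    see :func:`nmrbind.io.read_design`.
    """

    a_total: float
    points: tuple[tuple[str, float], ...]
    partner_id: str = "partner"

    def __post_init__(self) -> None:
        if self.a_total <= 0:
            raise ValidationError("a_total must be positive")
        labels = [lab for lab, _ in self.points]
        if len(set(labels)) != len(labels):
            raise ValidationError("titration point labels must be unique")
        for lab, b in self.points:
            if b < 0:
                raise ValidationError(f"negative partner concentration at {lab!r}")

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.points]

    @property
    def b_totals(self) -> np.ndarray:
        return np.array([b for _, b in self.points], dtype=float)

    def b_total(self, label: str) -> float:
        for lab, b in self.points:
            if lab == label:
                return b
        raise KeyError(f"no titration point labeled {label!r}")


class DecayTable:
    """Magnetization decay series: (residue_number, delay_s, intensity, error)."""

    COLUMNS = ["residue_number", "delay_s", "intensity", "error"]

    def __init__(self, frame: pd.DataFrame):
        frame = frame.loc[:, self.COLUMNS].copy()
        frame["residue_number"] = frame["residue_number"].astype(int)
        for col in self.COLUMNS[1:]:
            frame[col] = frame[col].astype(float)
        if (frame["delay_s"] <= 0).any():
            raise ValidationError("delays must be positive")
        if (frame["error"] <= 0).any():
            raise ValidationError("intensity errors must be positive")
        counts = frame.groupby("residue_number")["delay_s"].nunique()
        thin = counts[counts < 3]
        if not thin.empty:
            raise ValidationError(
                f"fewer than 3 distinct delays for residues {list(thin.index)}"
            )
        self.frame = frame.sort_values(["residue_number", "delay_s"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DecayTable):
            return NotImplemented
        return self.frame.equals(other.frame)

    @property
    def residue_numbers(self) -> np.ndarray:
        return np.unique(self.frame["residue_number"].to_numpy())

    def residue(self, residue_number: int) -> pd.DataFrame:
        return self.frame[self.frame["residue_number"] == residue_number]


class DispersionTable:
    """CPMG dispersion records across residues and static fields.

    Columns: ``residue_number, field_mhz, t_relax_s, nu_cpmg_hz, r2eff,
    error``.  The error floor (default 0.5 s^-1) is applied on
    construction: every error below the floor is raised to it.
    """

    COLUMNS = ["residue_number", "field_mhz", "t_relax_s", "nu_cpmg_hz", "r2eff", "error"]
    DEFAULT_ERROR_FLOOR = 0.5

    def __init__(self, frame: pd.DataFrame, error_floor: float = DEFAULT_ERROR_FLOOR):
        frame = frame.loc[:, self.COLUMNS].copy()
        frame["residue_number"] = frame["residue_number"].astype(int)
        for col in self.COLUMNS[1:]:
            frame[col] = frame[col].astype(float)
        if (frame["t_relax_s"] <= 0).any():
            raise ValidationError("t_relax must be positive")
        if (frame["nu_cpmg_hz"] <= 0).any():
            raise ValidationError("nu_cpmg must be positive")
        cycles = frame["nu_cpmg_hz"] * frame["t_relax_s"]
        if (np.round(cycles) < 1).any():
            raise ValidationError("nu_cpmg * t_relax must round to >= 1 CPMG cycle")
        frame["error"] = np.maximum(frame["error"], error_floor)
        self.error_floor = error_floor
        self.frame = frame.sort_values(
            ["residue_number", "field_mhz", "nu_cpmg_hz"]
        ).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DispersionTable):
            return NotImplemented
        return self.frame.equals(other.frame)

    @property
    def residue_numbers(self) -> np.ndarray:
        return np.unique(self.frame["residue_number"].to_numpy())

    @property
    def fields_mhz(self) -> np.ndarray:
        return np.unique(self.frame["field_mhz"].to_numpy())

    def profile(self, residue_number: int, field_mhz: float) -> pd.DataFrame:
        """One residue's dispersion profile at one field, sorted by nu_cpmg."""
        sel = self.frame[
            (self.frame["residue_number"] == residue_number)
            & np.isclose(self.frame["field_mhz"], field_mhz)
        ]
        return sel.sort_values("nu_cpmg_hz").reset_index(drop=True)


@dataclass
class ItcTable:
    """ITC titration: cell/syringe composition and per-injection heats.

    Concentrations in uM, volumes in uL, heats in ucal.  ``exclude_first``
    marks the customary discard of the first (diffusion-contaminated)
    injection.
    """

    cell_conc_um: float
    syringe_conc_um: float
    cell_volume_ul: float
    injections: pd.DataFrame = field(repr=False)  # columns volume_ul, heat_ucal
    exclude_first: bool = True

    def __post_init__(self) -> None:
        if self.cell_conc_um <= 0 or self.syringe_conc_um <= 0:
            raise ValidationError("concentrations must be positive")
        if self.cell_volume_ul <= 0:
            raise ValidationError("cell volume must be positive")
        inj = self.injections.loc[:, ["volume_ul", "heat_ucal"]].astype(float)
        if (inj["volume_ul"] <= 0).any():
            raise ValidationError("injection volumes must be positive")
        self.injections = inj.reset_index(drop=True)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ItcTable):
            return NotImplemented
        return (
            self.cell_conc_um == other.cell_conc_um
            and self.syringe_conc_um == other.syringe_conc_um
            and self.cell_volume_ul == other.cell_volume_ul
            and self.exclude_first == other.exclude_first
            and self.injections.equals(other.injections)
        )

    @property
    def n_injections(self) -> int:
        return len(self.injections)

    @property
    def volumes_ul(self) -> np.ndarray:
        return self.injections["volume_ul"].to_numpy()

    @property
    def heats_ucal(self) -> np.ndarray:
        return self.injections["heat_ucal"].to_numpy()
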