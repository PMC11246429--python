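"""Readers and writers for the tabular formats used throughout.

Dialects
--------
* FASTA sequences (Biopython).
* Chemical shifts: plain CSV/TSV (``residue,residue_type,atom,shift``),
  Sparky-style ``.list`` peak lists (``D435N-H  119.2  8.31  1.2e6``), and a
  minimal NMR-STAR v3 atom-chemical-shift loop.
* Decay tables: ``residue,delay_s,intensity,error``.
* Dispersion tables: ``residue,field_mhz,t_relax_s,nu_cpmg_hz,r2eff,error``.
* ITC: CSV with ``volume_ul,heat_ucal`` plus ``# key: value`` header lines
  carrying cell/syringe concentrations and the cell volume.
* Titration designs: YAML with either percent or uM admixtures.

Delimiters for CSV/TSV are auto-detected; decimals use a point.  Writers emit
TSV with fixed headers and JSON summaries; write -> read round-trips are the
identity for every table type.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .core import (
    ATOMS,
    DecayTable,
    DispersionTable,
    ItcTable,
    SequenceRecord,
    ShiftTable,
    TitrationDesign,
    ValidationError,
)

logger = logging.getLogger("nmrbind")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: NMR-STAR atom names mapped onto the internal atom vocabulary
_STAR_ATOMS = {"H": "H", "HN": "H", "N": "N", "CA": "CA", "CB": "CB", "C": "CO", "CO": "CO"}


class ParseError(ValueError):
    """A file failed to parse; the message names the offending location."""


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def read_sequence(path: str | Path, first_residue_number: int = 1) -> SequenceRecord:
    """Read the first record of a FASTA file as a :class:`SequenceRecord`.

    Lowercase letters are uppercased with a warning; letters outside the
    20-letter alphabet plus X raise :class:`ParseError` naming the position.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    rec = records[0]
    raw = str(rec.seq)
    if raw != raw.upper():
        logger.warning("%s: lowercase residues uppercased", path)
        raw = raw.upper()
    try:
        return SequenceRecord(rec.id, raw, first_residue_number)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_sequence(record: SequenceRecord, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f">{record.id} first_residue={record.first_residue_number}\n")
        for i in range(0, len(record.residues), 60):
            fh.write(record.residues[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# chemical shifts
# ---------------------------------------------------------------------------

def _read_table(path: Path) -> pd.DataFrame:
    """CSV/TSV with auto-detected delimiter and '#' comments."""
    return pd.read_csv(path, sep=None, engine="python", comment="#")


def read_shift_table(path: str | Path, dialect: str = "csv") -> ShiftTable:
    """Read chemical shifts in one of the dialects {csv, sparky_list, nmrstar_loop}."""
    path = Path(path)
    if dialect == "csv":
        return _read_shift_csv(path)
    if dialect == "sparky_list":
        return _read_sparky_list(path)
    if dialect == "nmrstar_loop":
        return _read_nmrstar_loop(path)
    raise ValueError(f"unknown shift-table dialect {dialect!r}")


def _read_shift_csv(path: Path) -> ShiftTable:
    frame = _read_table(path)
    cols = {c.lower().strip(): c for c in frame.columns}
    try:
        sel = pd.DataFrame(
            {
                "residue_number": frame[cols.get("residue_number", cols.get("residue"))],
                "residue_type": frame[cols["residue_type"]],
                "atom": frame[cols["atom"]].astype(str).str.upper(),
                "shift": frame[cols["shift"]],
            }
        )
    except KeyError as exc:
        raise ParseError(f"{path}: missing column {exc}") from exc
    try:
        return ShiftTable(sel)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


_SPARKY_LABEL = re.compile(r"^([A-Z])(\d+)([A-Z]+\d*)-([A-Z]+\d*)$")


def _read_sparky_list(path: Path) -> ShiftTable:
    """Sparky .list lines like ``D435N-H  119.2  8.31  1.2e6``.

    The w1/w2 columns map onto the two atoms of the assignment label; an
    optional fourth column is the peak intensity (stored per residue).
    """
    records: list[tuple[int, str, str, float]] = []
    intensities: dict[int, float] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.lower().startswith(("assignment", "w1", "#")):
                continue
            parts = line.split()
            m = _SPARKY_LABEL.match(parts[0])
            if m is None:
                raise ParseError(f"{path}:{lineno}: unparsable assignment {parts[0]!r}")
            res_type, res_num, atom1, atom2 = m.group(1), int(m.group(2)), m.group(3), m.group(4)
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected two shift columns")
            for atom, valstr in ((atom1, parts[1]), (atom2, parts[2])):
                atom = _STAR_ATOMS.get(atom, atom)
                if atom not in ATOMS:
                    raise ParseError(f"{path}:{lineno}: unknown atom name {atom!r}")
                try:
                    records.append((res_num, res_type, atom, float(valstr)))
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad shift {valstr!r}") from exc
            if len(parts) >= 4:
                try:
                    intensities[res_num] = float(parts[3])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad intensity {parts[3]!r}") from exc
    try:
        return ShiftTable.from_records(records, intensities)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _read_nmrstar_loop(path: Path) -> ShiftTable:
    """Minimal NMR-STAR v3 reader restricted to the atom-chemical-shift loop.

    Looks for the first ``loop_`` whose tags include
    ``_Atom_chem_shift.Seq_ID``-style names and reads rows until ``stop_``.
    Tag prefixes are matched case-insensitively so deposition variants parse.
    """
    wanted = {
        "seq_id": None, "comp_id": None, "atom_id": None, "val": None,
    }
    records: list[tuple[int, str, str, float]] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if lines[i].strip().lower() == "loop_":
            tags: list[str] = []
            j = i + 1
            while j < len(lines) and lines[j].strip().startswith("_"):
                tags.append(lines[j].strip().lower())
                j += 1
            idx = {}
            for k, tag in enumerate(tags):
                name = tag.split(".")[-1]
                if name in wanted:
                    idx[name] = k
            if {"seq_id", "comp_id", "atom_id", "val"} <= set(idx):
                while j < len(lines):
                    row = lines[j].strip()
                    j += 1
                    if row.lower() == "stop_":
                        break
                    if not row or row.startswith("#"):
                        continue
                    parts = row.split()
                    if len(parts) < len(tags):
                        raise ParseError(f"{path}:{j}: short chemical-shift row")
                    comp = parts[idx["comp_id"]].upper()
                    res_type = THREE_TO_ONE.get(comp, comp if len(comp) == 1 else None)
                    if res_type is None:
                        raise ParseError(f"{path}:{j}: unknown residue type {comp!r}")
                    atom = _STAR_ATOMS.get(parts[idx["atom_id"]].upper())
                    if atom is None:
                        continue  # side-chain atoms are outside the model
                    try:
                        records.append(
                            (int(parts[idx["seq_id"]]), res_type, atom,
                             float(parts[idx["val"]]))
                        )
                    except ValueError as exc:
                        raise ParseError(f"{path}:{j}: bad row {row!r}") from exc
                try:
                    return ShiftTable.from_records(records)
                except ValidationError as exc:
                    raise ParseError(f"{path}: {exc}") from exc
            i = j
        else:
            i += 1
    raise ParseError(f"{path}: no atom-chemical-shift loop found")


# ---------------------------------------------------------------------------
# designs, decays, dispersions, ITC
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> TitrationDesign:
    """YAML titration design.

    Schema::

        a_total_um: 100.0
        partner_id: CHC_TD
        points:
          - {label: "0%",  percent: 0}
          - {label: "50%", percent: 50}
          - {label: "x",   b_total_um: 150.0}

    Percent admixtures convert to uM as ``percent * a_total / 100``.
    """
    path = Path(path)
    with path.open() as fh:
        doc = yaml.safe_load(fh)
    try:
        a_total = float(doc["a_total_um"])
        pts = []
        for p in doc["points"]:
            if "percent" in p:
                b = float(p["percent"]) * a_total / 100.0
            else:
                b = float(p["b_total_um"])
            pts.append((str(p["label"]), b))
        return TitrationDesign(a_total, tuple(pts), str(doc.get("partner_id", "partner")))
    except (KeyError, TypeError, ValidationError) as exc:
        raise ParseError(f"{path}: invalid titration design ({exc})") from exc


def read_decay_table(path: str | Path) -> DecayTable:
    frame = _read_table(Path(path))
    frame = frame.rename(columns={"residue": "residue_number"})
    try:
        return DecayTable(frame)
    except (KeyError, ValidationError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_dispersion_table(
    path: str | Path, error_floor: float = DispersionTable.DEFAULT_ERROR_FLOOR
) -> DispersionTable:
    frame = _read_table(Path(path))
    frame = frame.rename(columns={"residue": "residue_number"})
    try:
        return DispersionTable(frame, error_floor=error_floor)
    except (KeyError, ValidationError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_itc_table(path: str | Path) -> ItcTable:
    """ITC CSV: ``# key: value`` header lines then ``volume_ul,heat_ucal`` rows."""
    path = Path(path)
    meta: dict[str, float] = {}
    body: list[str] = []
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                m = re.match(r"#\s*([\w.]+)\s*[:=]\s*(\S+)", line)
                if m:
                    meta[m.group(1)] = m.group(2)
            else:
                body.append(line)
    frame = pd.read_csv(pd.io.common.StringIO("".join(body)), sep=None, engine="python")
    try:
        return ItcTable(
            cell_conc_um=float(meta["cell_conc_um"]),
            syringe_conc_um=float(meta["syringe_conc_um"]),
            cell_volume_ul=float(meta["cell_volume_ul"]),
            injections=frame,
            exclude_first=str(meta.get("exclude_first", "true")).lower() != "false",
        )
    except (KeyError, ValidationError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_shift_table(table: ShiftTable, path: str | Path) -> None:
    frame = table.frame.rename(columns={"residue_number": "residue"})
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    if len(table) == 0:
        logger.warning("%s: wrote header-only shift table", path)


def read_shift_table_tsv(path: str | Path) -> ShiftTable:
    return _read_shift_csv(Path(path))


def write_decay_table(table: DecayTable, path: str | Path) -> None:
    frame = table.frame.rename(columns={"residue_number": "residue"})
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_dispersion_table(table: DispersionTable, path: str | Path) -> None:
    frame = table.frame.rename(columns={"residue_number": "residue"})
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_itc_table(table: ItcTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# cell_conc_um: {table.cell_conc_um:.10g}\n")
        fh.write(f"# syringe_conc_um: {table.syringe_conc_um:.10g}\n")
        fh.write(f"# cell_volume_ul: {table.cell_volume_ul:.10g}\n")
        fh.write(f"# exclude_first: {str(table.exclude_first).lower()}\n")
        table.injections.to_csv(fh, index=False, float_format="%.10g")


def write_frame(frame: pd.DataFrame, path: str | Path) -> None:
    """Generic TSV writer for result frames (fixed headers, 6 significant digits)."""
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    if frame.empty:
        logger.warning("%s: wrote header-only table", path)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
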