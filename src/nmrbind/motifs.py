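"""Short-linear-motif scanning and rate-driven interaction-window extraction.

Three endocytic motif classes are scanned: the clathrin-box DLL/DLF
(``D-L-[LF]``), and the adaptor-appendage motifs DPF (``D-P-F``) and FxDxF
(``F-x-D-x-F``).  Overlapping hits are all reported.  An optional relaxed
clathrin pattern ``D-[LI]-[LF]`` also admits degenerate DIF-type variants.

Interaction windows are 21-residue stretches centred on the hydrophobic
residue carrying the highest relaxation-rate increase within a contiguous
region of elevated rates; windows are gap-padded ('-') at chain termini,
ranked by their central rate, and summarised as a position-frequency matrix
suitable for logo rendering.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AMINO_ACIDS, SequenceRecord

logger = logging.getLogger("nmrbind")

#: motif classes and their patterns (overlap-tolerant via lookahead)
MOTIF_PATTERNS = {
    "DLL_DLF": r"DL[LF]",
    "DPF": r"DPF",
    "FxDxF": r"F.D.F",
}
RELAXED_DLL = r"D[LI][LF]"

#: window-anchor hydrophobic residues (A excluded: a flanking, not anchoring,
#: preference)
DEFAULT_HYDROPHOBIC = frozenset("LFIVMWY")

WINDOW_WIDTH = 21


@dataclass(frozen=True)
class MotifHit:
    motif_class: str
    start: int        # full-length numbering, inclusive
    end: int          # inclusive
    matched: str


@dataclass(frozen=True)
class InteractionWindow:
    center: int       # residue number of the hydrophobic anchor
    sequence: str     # exactly `width` letters, '-' padded at termini
    center_rate: float
    rank: int | None = None


def scan_motifs(
    sequence: SequenceRecord, relaxed_dll: bool = False
) -> list[MotifHit]:
    """All (possibly overlapping) motif matches with full-length numbering."""
    patterns = dict(MOTIF_PATTERNS)
    if relaxed_dll:
        patterns["DLL_DLF"] = RELAXED_DLL
    hits: list[MotifHit] = []
    for cls, pat in patterns.items():
        rx = re.compile(f"(?=({pat}))")
        for m in rx.finditer(sequence.residues):
            s = m.start() + sequence.first_residue_number
            matched = m.group(1)
            hits.append(MotifHit(cls, s, s + len(matched) - 1, matched))
    hits.sort(key=lambda h: (h.start, h.motif_class))
    return hits


def motif_hits_frame(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.motif_class, h.start, h.end, h.matched) for h in hits],
        columns=["motif_class", "start", "end", "seq"],
    )


def _padded_window(sequence: SequenceRecord, center: int, width: int) -> str:
    half = width // 2
    out = []
    for num in range(center - half, center + half + 1):
        if sequence.first_residue_number <= num <= sequence.last_residue_number:
            out.append(sequence.residue_type(num))
        else:
            out.append("-")
    return "".join(out)


def extract_windows(
    rate_increase: pd.Series,
    sequence: SequenceRecord,
    width: int = WINDOW_WIDTH,
    hydrophobic_set: frozenset[str] = DEFAULT_HYDROPHOBIC,
    min_prominence: float = 2.0,
) -> list[InteractionWindow]:
    """Interaction windows from a per-residue rate-increase profile.

    ``rate_increase`` is indexed by residue number and holds the titration
    rate minus the reference (free-state) rate in s^-1.  Contiguous runs of
    residues exceeding ``min_prominence`` define candidate regions; in each,
    the hydrophobic residue with the highest rate becomes the window centre
    (one window per region).  Regions without a hydrophobic residue are
    skipped with a log entry.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be odd")
    rates = rate_increase.dropna().sort_index()
    above = rates[rates > min_prominence]
    if above.empty:
        return []
    # contiguous residue-number runs
    nums = above.index.to_numpy()
    breaks = np.flatnonzero(np.diff(nums) > 1)
    regions = np.split(nums, breaks + 1)

    windows = []
    for region in regions:
        cands = [
            n for n in region
            if sequence.first_residue_number <= n <= sequence.last_residue_number
            and sequence.residue_type(int(n)) in hydrophobic_set
        ]
        if not cands:
            logger.info(
                "region %d-%d has no hydrophobic residue; skipped",
                region[0], region[-1],
            )
            continue
        center = int(max(cands, key=lambda n: rates[n]))
        windows.append(
            InteractionWindow(
                center=center,
                sequence=_padded_window(sequence, center, width),
                center_rate=float(rates[center]),
            )
        )
    return windows


def rank_and_logo(
    windows: list[InteractionWindow],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank windows by central rate and build the position-frequency matrix.

    Returns ``(ranked, pfm)``: the ranked table (descending centre rate,
    ties by residue number ascending) and a ``width x 20`` count matrix
    (rows = window positions 1..width, columns = amino acids, gaps
    excluded), whose column sums never exceed the number of windows.
    """
    if not windows:
        raise ValueError("no interaction windows to rank")
    ordered = sorted(windows, key=lambda w: (-w.center_rate, w.center))
    ranked = pd.DataFrame(
        [
            (i + 1, w.center, w.center_rate, w.sequence)
            for i, w in enumerate(ordered)
        ],
        columns=["rank", "center", "center_rate", "sequence"],
    )
    width = len(ordered[0].sequence)
    pfm = pd.DataFrame(
        0, index=pd.RangeIndex(1, width + 1, name="position"),
        columns=list(AMINO_ACIDS),
    )
    for w in ordered:
        for pos, aa in enumerate(w.sequence, start=1):
            if aa in pfm.columns:
                pfm.loc[pos, aa] += 1
    return ranked, pfm
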