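"""Core domain records: annotated contigs, paired cells, and filtered repertoires.

A :class:`ChainRecord` is one V(D)J-annotated contig (amino-acid level,
germline pre-trimmed to the variable region upstream). A :class:`CellRecord`
pairs exactly one heavy and one light chain under a cell barcode. A
:class:`Repertoire` is the filtered, clonotyped collection used by every
downstream stage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import DataError

HEAVY = "heavy"
LIGHT = "light"

# IGH -> heavy; IGK / IGL -> light
_LOCUS_MAP = {"IGH": HEAVY, "IGK": LIGHT, "IGL": LIGHT, "heavy": HEAVY, "light": LIGHT}

_ISOTYPE_BY_CGENE_PREFIX = {
    "IGHM": "IgM",
    "IGHD": "IgD",
    "IGHG": "IgG",
    "IGHA": "IgA",
    "IGHE": "IgE",
}

_V_FAMILY_RE = re.compile(r"^(IG[HKL]V\d+)")


def locus_class(raw: str) -> str:
    """Normalize a locus/chain annotation (IGH, IGK, IGL, heavy, light)."""
    try:
        return _LOCUS_MAP[raw.strip()]
    except KeyError:
        raise DataError(f"unrecognized locus annotation: {raw!r}") from None


def isotype_from_c_call(c_call: str) -> str:
    """Collapse a heavy-chain C-gene call to its isotype class.

    Subclasses are merged (IGHG1..4 -> IgG, IGHA1/2 -> IgA). Unknown or empty
    calls map to "unknown".
    """
    for prefix, iso in _ISOTYPE_BY_CGENE_PREFIX.items():
        if c_call.startswith(prefix):
            return iso
    return "unknown"


def v_family(v_call: str) -> str:
    """Gene-family prefix of a V call: "IGHV1-26*01" -> "IGHV1".

    Calls that do not match the IG[HKL]V pattern yield "unknown".
    """
    m = _V_FAMILY_RE.match(v_call)
    return m.group(1) if m else "unknown"


@dataclass
class ChainRecord:
    """One annotated contig: amino-acid V(D)J sequence plus germline and CDR3."""

    cell_id: str
    locus: str  # "heavy" | "light"
    sequence_aa: str
    germline_aa: str
    v_call: str
    c_call: str
    cdr3_aa: str
    cdr3_span: tuple[int, int] | None  # 0-based half-open into sequence_aa
    sample_id: str = ""

    def validate(self) -> None:
        if not self.sequence_aa:
            raise DataError(f"{self.cell_id}: empty sequence")
        if self.locus not in (HEAVY, LIGHT):
            raise DataError(f"{self.cell_id}: bad locus {self.locus!r}")
        if self.cdr3_span is not None:
            s, e = self.cdr3_span
            if not (0 <= s < e <= len(self.sequence_aa)):
                raise DataError(f"{self.cell_id}: CDR3 span {self.cdr3_span} outside sequence")
            if self.cdr3_aa and self.sequence_aa[s:e] != self.cdr3_aa:
                raise DataError(f"{self.cell_id}: CDR3 coordinates disagree with cdr3_aa")


@dataclass
class CellRecord:
    """A single B cell: one heavy chain, one light chain, isotype from the heavy C gene."""

    cell_id: str
    heavy: ChainRecord
    light: ChainRecord
    sample_id: str = ""

    @property
    def isotype(self) -> str:
        return isotype_from_c_call(self.heavy.c_call)

    def chain(self, locus: str) -> ChainRecord:
        if locus == HEAVY:
            return self.heavy
        if locus == LIGHT:
            return self.light
        raise DataError(f"bad locus {locus!r}")


@dataclass
class Repertoire:
    """Filtered cells with clone assignment and an auditable filter log."""

    cells: list[CellRecord]
    clone_assignment: dict[str, str]  # cell_id -> clone_id
    filter_log: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.cells)

    def clones(self) -> dict[str, list[CellRecord]]:
        out: dict[str, list[CellRecord]] = {}
        for cell in self.cells:
            out.setdefault(self.clone_assignment[cell.cell_id], []).append(cell)
        return out

    def clone_of(self, cell_id: str) -> str:
        return self.clone_assignment[cell_id]
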