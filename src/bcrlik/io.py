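"""Reading, filtering, clonotyping, and SHM quantification of V(D)J tables.

Two tabular dialects are supported: AIRR Rearrangement TSV and a
CellRanger-style filtered-contig CSV. Both carry 1-based inclusive CDR3
coordinates on disk; records are normalized to 0-based half-open spans in
memory.

Filtering follows the standard single-cell hygiene rules, applied in order:

1. cells with more than one transcript per locus are removed,
2. cells missing either a heavy or a light chain are removed,
3. cells without an annotated heavy-chain germline are removed,
4. cells without a heavy-chain C-gene call are removed,
5. barcodes occurring under more than one sample are removed entirely.

SHM is quantified as the Hamming distance between a chain and its germline;
chains whose germline has a different length (indels) are flagged as excluded
from SHM analyses rather than aligned.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from pathlib import Path

import pandas as pd

from .alphabet import is_canonical
from .errors import DataError
from .records import (
    HEAVY,
    LIGHT,
    CellRecord,
    ChainRecord,
    Repertoire,
    locus_class,
    v_family,
)

logger = logging.getLogger(__name__)

AIRR_COLUMNS = [
    "cell_id",
    "locus",
    "sequence_aa",
    "germline_alignment_aa",
    "v_call",
    "c_call",
    "cdr3_aa",
    "cdr3_start",
    "cdr3_end",
]

CONTIG_COLUMNS = [
    "barcode",
    "chain",
    "vdj_aa",
    "germline_aa",
    "v_gene",
    "c_gene",
    "cdr3",
    "cdr3_start",
    "cdr3_end",
]

FILTER_RULES = [
    "multiple_transcripts",
    "incomplete_cell",
    "missing_germline",
    "missing_c_gene",
    "duplicated_barcode",
]


def _span_from_one_based(start, end) -> tuple[int, int] | None:
    """1-based inclusive (start, end) -> 0-based half-open, or None if absent."""
    if pd.isna(start) or pd.isna(end):
        return None
    return int(start) - 1, int(end)


def read_repertoire(path: str | Path, dialect: str = "airr_tsv") -> list[ChainRecord]:
    """Read one contig table into raw :class:`ChainRecord` objects.

    Rows with non-canonical residues (X, *, gaps) in the V(D)J or CDR3
    sequence, or with internally inconsistent CDR3 coordinates, are skipped
    with a logged count. Missing required columns raise :class:`DataError`.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if dialect == "airr_tsv":
        df = pd.read_csv(path, sep="\t")
        required = AIRR_COLUMNS
        col = {c: c for c in required}
    elif dialect == "contig_csv":
        df = pd.read_csv(path)
        required = CONTIG_COLUMNS
        col = dict(
            zip(
                AIRR_COLUMNS,
                ["barcode", "chain", "vdj_aa", "germline_aa", "v_gene", "c_gene", "cdr3", "cdr3_start", "cdr3_end"],
            )
        )
    else:
        raise DataError(f"unknown dialect: {dialect!r}")

    for c in required:
        if c not in df.columns:
            raise DataError(f"missing required column {c!r} in {path.name}")

    records: list[ChainRecord] = []
    n_skipped = 0
    for _, row in df.iterrows():
        try:
            seq = str(row[col["sequence_aa"]])
            cdr3 = row[col["cdr3_aa"]]
            cdr3 = "" if pd.isna(cdr3) else str(cdr3)
            germ = row[col["germline_alignment_aa"]]
            germ = "" if pd.isna(germ) else str(germ)
            if not is_canonical(seq) or not is_canonical(cdr3) or (germ and not is_canonical(germ)):
                raise DataError("non-canonical residues")
            c_call = row[col["c_call"]]
            rec = ChainRecord(
                cell_id=str(row[col["cell_id"]]),
                locus=locus_class(str(row[col["locus"]])),
                sequence_aa=seq,
                germline_aa=germ,
                v_call=str(row[col["v_call"]]),
                c_call="" if pd.isna(c_call) else str(c_call),
                cdr3_aa=cdr3,
                cdr3_span=_span_from_one_based(row[col["cdr3_start"]], row[col["cdr3_end"]]),
                sample_id=str(row["sample_id"]) if "sample_id" in df.columns and not pd.isna(row.get("sample_id")) else "",
            )
            rec.validate()
        except DataError as exc:
            n_skipped += 1
            logger.warning("skipping row (%s)", exc)
            continue
        records.append(rec)
    if n_skipped:
        logger.warning("%d rows skipped while reading %s", n_skipped, path.name)
    return records


def filter_cells(
    records: list[ChainRecord],
    clonotype: str = "cdr3_identity",
    existing_clones: dict[str, str] | None = None,
) -> Repertoire:
    """Group contigs by barcode, apply the five filter rules, assign clones.

    ``clonotype`` is either ``"cdr3_identity"`` (clone = identical heavy and
    light V family + CDR3 amino-acid sequence) or ``"existing"`` with a
    pre-computed ``existing_clones`` map (e.g. carried in a clone_id column).
    Filtering never fails; an all-filtered repertoire is valid and empty.
    """
    log = dict.fromkeys(FILTER_RULES, 0)

    groups: dict[tuple[str, str], list[ChainRecord]] = {}
    order: list[tuple[str, str]] = []
    for rec in records:
        key = (rec.sample_id, rec.cell_id)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)

    survivors: list[tuple[tuple[str, str], ChainRecord, ChainRecord]] = []
    for key in order:
        chains = groups[key]
        by_locus = Counter(c.locus for c in chains)
        if by_locus[HEAVY] > 1 or by_locus[LIGHT] > 1:
            log["multiple_transcripts"] += 1
            continue
        if by_locus[HEAVY] == 0 or by_locus[LIGHT] == 0:
            log["incomplete_cell"] += 1
            continue
        heavy = next(c for c in chains if c.locus == HEAVY)
        light = next(c for c in chains if c.locus == LIGHT)
        if not heavy.germline_aa:
            log["missing_germline"] += 1
            continue
        if not heavy.c_call:
            log["missing_c_gene"] += 1
            continue
        survivors.append((key, heavy, light))

    barcode_samples: dict[str, set[str]] = {}
    for (sample, barcode), _, _ in survivors:
        barcode_samples.setdefault(barcode, set()).add(sample)
    cells: list[CellRecord] = []
    for (sample, barcode), heavy, light in survivors:
        if len(barcode_samples[barcode]) > 1:
            log["duplicated_barcode"] += 1
            continue
        cells.append(CellRecord(cell_id=barcode, heavy=heavy, light=light, sample_id=sample))

    if clonotype == "existing":
        if existing_clones is None:
            raise DataError("clonotype='existing' requires an existing_clones map")
        assignment = {c.cell_id: existing_clones[c.cell_id] for c in cells}
    elif clonotype == "cdr3_identity":
        assignment = _assign_clones(cells)
    else:
        raise DataError(f"unknown clonotype strategy: {clonotype!r}")

    return Repertoire(cells=cells, clone_assignment=assignment, filter_log=log)


def _assign_clones(cells: list[CellRecord]) -> dict[str, str]:
    """Clone = identical (heavy V family, light V family, heavy CDR3, light CDR3)."""
    keys = {
        cell.cell_id: (
            v_family(cell.heavy.v_call),
            v_family(cell.light.v_call),
            cell.heavy.cdr3_aa,
            cell.light.cdr3_aa,
        )
        for cell in cells
    }
    sizes = Counter(keys.values())
    clone_ids = {
        key: f"clone_{i + 1}"
        for i, (key, _) in enumerate(sorted(sizes.items(), key=lambda kv: (-kv[1], kv[0])))
    }
    return {cell_id: clone_ids[key] for cell_id, key in keys.items()}


def hamming_shm(sequence_aa: str, germline_aa: str) -> int | None:
    """Hamming distance to the germline, or None when lengths differ.

    Unequal lengths indicate indels relative to the germline; such chains are
    excluded from SHM (and edge-substitution) analyses rather than aligned.
    """
    if len(sequence_aa) != len(germline_aa):
        return None
    return sum(a != b for a, b in zip(sequence_aa, germline_aa))


def normalized_expansion(rep: Repertoire) -> dict[str, float]:
    """Cells per clone divided by total retained cells; sums to 1 over clones."""
    if not rep.cells:
        raise DataError("normalized_expansion of an empty repertoire")
    total = len(rep.cells)
    return {clone: len(members) / total for clone, members in rep.clones().items()}


def write_airr(
    cells: list[CellRecord],
    path: str | Path,
    clone_assignment: dict[str, str] | None = None,
) -> None:
    """Write cells as AIRR Rearrangement TSV (one row per contig)."""
    rows = []
    for cell in cells:
        for chain in (cell.heavy, cell.light):
            span = chain.cdr3_span
            rows.append(
                {
                    "cell_id": cell.cell_id,
                    "locus": "IGH" if chain.locus == HEAVY else "IGK",
                    "sequence_aa": chain.sequence_aa,
                    "germline_alignment_aa": chain.germline_aa,
                    "v_call": chain.v_call,
                    "c_call": chain.c_call,
                    "cdr3_aa": chain.cdr3_aa,
                    "cdr3_start": span[0] + 1 if span else "",
                    "cdr3_end": span[1] if span else "",
                    "clone_id": (clone_assignment or {}).get(cell.cell_id, ""),
                    "sample_id": cell.sample_id,
                }
            )
    columns = AIRR_COLUMNS + ["clone_id", "sample_id"]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def write_repertoire(rep: Repertoire, out_dir: str | Path) -> dict[str, Path]:
    """Write the filtered repertoire (AIRR TSV) plus a JSON filter report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    airr = out_dir / "repertoire.airr.tsv"
    report = out_dir / "filter_report.json"
    write_airr(rep.cells, airr, rep.clone_assignment)
    report.write_text(
        json.dumps({"retained": len(rep.cells), "removed": rep.filter_log}, indent=2)
    )
    return {"airr": airr, "filter_report": report}


def read_filtered_repertoire(path: str | Path) -> Repertoire:
    """Read back a repertoire written by :func:`write_repertoire`.

    Uses the clone_id column when present, otherwise re-derives clonotypes.
    """
    records = read_repertoire(path, dialect="airr_tsv")
    df = pd.read_csv(path, sep="\t")
    if "clone_id" in df.columns and df["clone_id"].notna().all():
        clones = {
            str(row["cell_id"]): str(row["clone_id"]) for _, row in df.iterrows()
        }
        return filter_cells(records, clonotype="existing", existing_clones=clones)
    return filter_cells(records)
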