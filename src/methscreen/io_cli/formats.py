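"""Readers and writers for all interchange formats.

Tables are CSV/TSV via pandas, sequences FASTA via Biopython, reports JSON
(+ TSV twins for tabular parts).  Coordinates in sequence sidecar files are
0-based; every reader validates the type invariants and names the offending
record in its error message.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .. import __version__
from ..array_screen import BetaMatrix, IslandRelation, ProbeAnnotation
from ..cobra import MethylatedSequence
from ..cohort_stats import CallRecord, CallTable, DifferentialResult, GeneFrequency
from ..methylation_index import CloneMatrix, MIResult
from ..paired_analysis import MatchedPair, TimingSummary

__all__ = [
    "read_annotation",
    "write_annotation",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_amplicons",
    "write_amplicons",
    "read_clone_matrix",
    "read_clone_dir",
    "write_clone_matrix",
    "read_call_table",
    "write_call_table",
    "read_pairs",
    "write_pairs",
    "write_report",
]

_ANNOTATION_COLUMNS = ("probe_id", "gene_symbols", "tss_groups", "island_relation")
_ISLAND_LOOKUP = {r.value.lower(): r for r in IslandRelation} | {
    "open_sea": IslandRelation.OPEN_SEA,
    "open sea": IslandRelation.OPEN_SEA,
}


def _split(cell) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return ()
    return tuple(part for part in str(cell).split(";") if part)


def read_annotation(path: str | Path) -> dict[str, ProbeAnnotation]:
    """Load a probe annotation CSV into a probe_id -> record map.

    Required columns: probe_id, gene_symbols (';'-separated), tss_groups
    (';'-separated), island_relation (case-insensitive).  Malformed rows are
    collected and reported together in a single hard error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")

    records: dict[str, ProbeAnnotation] = {}
    errors: list[str] = []
    for idx, row in df.iterrows():
        probe_id = row["probe_id"].strip()
        try:
            if not probe_id:
                raise ValueError("empty probe_id")
            if probe_id in records:
                raise ValueError(f"duplicate probe_id {probe_id!r}")
            island_raw = row["island_relation"].strip().lower()
            if island_raw not in _ISLAND_LOOKUP:
                raise ValueError(f"unknown island_relation {row['island_relation']!r}")
            records[probe_id] = ProbeAnnotation(
                probe_id=probe_id,
                gene_symbols=_split(row["gene_symbols"]),
                tss_groups=_split(row["tss_groups"]),
                island_relation=_ISLAND_LOOKUP[island_raw],
            )
        except ValueError as exc:
            errors.append(f"row {idx + 2}: {exc}")  # +2: header + 1-based
    if errors:
        raise ValueError(f"{path}: {len(errors)} malformed row(s):\n" + "\n".join(errors))
    return records


def write_annotation(annotation: Iterable[ProbeAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_ANNOTATION_COLUMNS)
        for probe in annotation:
            writer.writerow(
                [
                    probe.probe_id,
                    ";".join(probe.gene_symbols),
                    ";".join(probe.tss_groups),
                    probe.island_relation.value,
                ]
            )


def read_beta_matrix(path: str | Path, cohort_label: str) -> BetaMatrix:
    """Load a TSV beta matrix (first column probe_id, one column per sample).

    Empty fields and "NA" are missing; any value outside [0, 1] is a hard
    error naming the probe and sample.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA", ""], keep_default_na=False
    )
    values = df.to_numpy(dtype=float)
    bad = np.argwhere(~np.isnan(values) & ((values < 0) | (values > 1)))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{path}: beta value {values[i, j]} outside [0, 1] at probe "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return BetaMatrix(
        cohort_label=cohort_label,
        probe_ids=[str(p) for p in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=values,
    )


def write_beta_matrix(matrix: BetaMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        matrix.values, index=matrix.probe_ids, columns=matrix.sample_ids
    )
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", na_rep="NA")


# -- amplicons: FASTA + per-CpG state sidecar CSV (0-based positions) --------

def write_amplicons(
    amplicons: Mapping[str, MethylatedSequence],
    fasta_path: str | Path,
    states_path: str | Path,
) -> None:
    SeqIO.write(
        [SeqRecord(Seq(ms.seq), id=name, description="") for name, ms in amplicons.items()],
        str(fasta_path),
        "fasta",
    )
    with open(states_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "cpg_positions", "states"])  # 0-based positions
        for name, ms in amplicons.items():
            writer.writerow(
                [
                    name,
                    ";".join(str(p) for p in ms.cpg_positions),
                    ";".join(s[0].upper() for s in ms.methyl_states),
                ]
            )


def read_amplicons(
    fasta_path: str | Path, states_path: str | Path
) -> dict[str, MethylatedSequence]:
    """Join a FASTA of amplicons with its methylation-state sidecar CSV.

    States are single letters: M = methylated, U = unmethylated.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    out: dict[str, MethylatedSequence] = {}
    state_map = {"M": "methylated", "U": "unmethylated"}
    with open(states_path, newline="") as fh:
        for row in csv.DictReader(fh):
            name = row["record_id"]
            if name not in seqs:
                raise ValueError(f"{states_path}: record {name!r} absent from FASTA")
            positions = tuple(int(p) for p in _split(row["cpg_positions"]))
            letters = _split(row["states"])
            try:
                states = tuple(state_map[s.upper()] for s in letters)
            except KeyError as exc:
                raise ValueError(f"{states_path}: record {name!r}: bad state {exc}") from None
            out[name] = MethylatedSequence(
                seq=seqs[name], cpg_positions=positions, methyl_states=states
            )
    missing = sorted(set(seqs) - set(out))
    if missing:
        raise ValueError(f"{states_path}: no states for FASTA record(s) {missing}")
    return out


# -- clone matrices: one CSV per gene/sample amplicon ------------------------

_CLONE_CELL = {"M": 1.0, "U": 0.0, ".": np.nan}


def read_clone_matrix(path: str | Path, gene: str, sample: str) -> CloneMatrix:
    """Read a clones x CpG matrix of M/U/. cells (no header)."""
    rows: list[list[float]] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row:
                continue
            try:
                rows.append([_CLONE_CELL[c.strip()] for c in row])
            except KeyError as exc:
                raise ValueError(f"{path}: line {lineno}: bad cell {exc}") from None
    if not rows:
        raise ValueError(f"{path}: empty clone matrix")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged rows (widths {sorted(widths)})")
    return CloneMatrix(gene=gene, sample=sample, states=np.array(rows))


def write_clone_matrix(cm: CloneMatrix, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for row in cm.states:
            writer.writerow(
                ["." if np.isnan(v) else ("M" if v else "U") for v in row]
            )


def read_clone_dir(directory: str | Path) -> list[CloneMatrix]:
    """Read every ``<gene>__<sample>.csv`` clone matrix in a directory."""
    directory = Path(directory)
    out = []
    for path in sorted(directory.glob("*.csv")):
        stem = path.stem
        gene, _, sample = stem.partition("__")
        out.append(read_clone_matrix(path, gene=gene, sample=sample or stem))
    if not out:
        raise ValueError(f"no clone CSV files found in {directory}")
    return out


# -- call tables and matched pairs -------------------------------------------

def read_call_table(path: str | Path) -> CallTable:
    df = pd.read_csv(path, dtype=str)
    required = ["sample_id", "cohort", "gene", "call"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    records = [
        CallRecord(row.sample_id, row.cohort, row.gene, row.call)
        for row in df.itertuples(index=False)
    ]
    return CallTable(records=records)


def write_call_table(table: CallTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "cohort", "gene", "call"])
        for rec in table.records:
            writer.writerow([rec.sample_id, rec.cohort, rec.gene, rec.call])


def read_pairs(path: str | Path) -> list[MatchedPair]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["patient_id", "gene", "primary_call", "metastasis_call"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    has_normal = "normal_call" in df.columns
    pairs = []
    for row in df.itertuples(index=False):
        normal = getattr(row, "normal_call", "") if has_normal else ""
        pairs.append(
            MatchedPair(
                patient_id=row.patient_id,
                gene=row.gene,
                primary_call=row.primary_call,
                metastasis_call=row.metastasis_call,
                normal_call=normal or None,
            )
        )
    return pairs


def write_pairs(pairs: Sequence[MatchedPair], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "gene", "primary_call", "metastasis_call", "normal_call"])
        for p in pairs:
            writer.writerow(
                [p.patient_id, p.gene, p.primary_call, p.metastasis_call, p.normal_call or ""]
            )


# -- reports -----------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (GeneFrequency, DifferentialResult, MIResult, TimingSummary, CallRecord)):
        return {k: _jsonable(v) for k, v in vars(obj).items()}
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def write_report(
    results,
    path: str | Path,
    parameters: Mapping | None = None,
    seed: int | None = None,
) -> None:
    """Write a JSON report plus TSV twins for any list-of-record payloads."""
    path = Path(path)
    payload = {
        "tool": "methscreen",
        "version": __version__,
        "seed": seed,
        "parameters": _jsonable(parameters or {}),
        "results": _jsonable(results),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=False)
        fh.write("\n")

    results_block = payload["results"]
    if isinstance(results_block, Mapping):
        for key, value in results_block.items():
            if (
                isinstance(value, list)
                and value
                and all(isinstance(v, Mapping) for v in value)
            ):
                twin = path.with_name(f"{path.stem}.{key}.tsv")
                pd.DataFrame(value).to_csv(twin, sep="\t", index=False)
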