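"""Delimited-text readers and writers for expression matrices and reports.

Expression matrices are TSV/CSV with a header of identifiers; orientation is
declared by the caller and normalised to samples x genes internally.  Labels
are a two-column table mapping sample id to class name.  The class listed
first under ``class_order`` (default: lexicographic) becomes the positive
class for TP/FP bookkeeping; the MCC itself is invariant to the swap.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import DatasetError, ExpressionDataset, SelectionResult

_ORIENTATIONS = ("samples_by_genes", "genes_by_samples")


def _sniff_sep(path: Path) -> str:
    with open(path) as handle:
        first = handle.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def _read_table(path: Path) -> pd.DataFrame:
    # delimiter autodetected (tab or comma); round_trip parsing so written
    # matrices read back bit-identically
    return pd.read_csv(
        path, sep=_sniff_sep(path), index_col=0, float_precision="round_trip"
    )


def read_dataset(
    matrix_path,
    labels_path,
    orientation: str = "samples_by_genes",
    class_order: Sequence[str] | None = None,
) -> ExpressionDataset:
    """Read an expression matrix and a sample-label table into a dataset.

    Parameters
    ----------
    matrix_path, labels_path : path-like
        Delimited text files (tab or comma, autodetected).  The matrix must
        carry sample and gene identifiers in its header/index; the labels
        file maps ``sample_id`` to a class name in its first two columns.
    orientation : {"samples_by_genes", "genes_by_samples"}
        Layout of the matrix file; ``genes_by_samples`` input is transposed.
    class_order : pair of class names, optional
        The first entry is treated as the positive class.  Defaults to the
        lexicographically first class name.
    """
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}")
    matrix_path, labels_path = Path(matrix_path), Path(labels_path)
    frame = _read_table(matrix_path)
    if orientation == "genes_by_samples":
        frame = frame.T
    if frame.isna().any().any():
        col = frame.columns[frame.isna().any().to_numpy()][0]
        row = frame.index[frame[col].isna().to_numpy()][0]
        raise DatasetError(
            f"missing value in {matrix_path} at sample {row!r}, gene {col!r}"
        )

    labels_frame = pd.read_csv(labels_path, sep=None, engine="python")
    if labels_frame.shape[1] < 2:
        raise DatasetError(f"labels file {labels_path} needs (sample_id, class) columns")
    label_map = dict(
        zip(labels_frame.iloc[:, 0].astype(str), labels_frame.iloc[:, 1].astype(str))
    )
    sample_ids = [str(s) for s in frame.index]
    missing = [s for s in sample_ids if s not in label_map]
    extra = [s for s in label_map if s not in set(sample_ids)]
    if missing or extra:
        raise DatasetError(
            f"sample ids differ between matrix and labels: "
            f"missing labels for {missing[:5]}, unmatched labels {extra[:5]}"
        )

    classes = sorted(set(label_map[s] for s in sample_ids))
    if len(classes) != 2:
        raise DatasetError(
            f"expected exactly 2 classes, found {len(classes)}: {classes}"
        )
    if class_order is not None:
        order = [str(c) for c in class_order]
        if sorted(order) != classes:
            raise DatasetError(
                f"class_order {order} does not match classes in data {classes}"
            )
        positive, negative = order
    else:
        positive, negative = classes
    labels = np.array([1 if label_map[s] == positive else -1 for s in sample_ids])

    return ExpressionDataset(
        matrix=frame.to_numpy(dtype=float),
        sample_ids=tuple(sample_ids),
        gene_ids=tuple(str(g) for g in frame.columns),
        labels=labels,
        class_names=(positive, negative),
    )


def write_dataset(dataset: ExpressionDataset, matrix_path, labels_path) -> None:
    """Write a dataset back to delimited text (samples x genes + label table)."""
    frame = pd.DataFrame(
        dataset.matrix, index=list(dataset.sample_ids), columns=list(dataset.gene_ids)
    )
    frame.index.name = "sample_id"
    # %.17g round-trips IEEE doubles exactly
    frame.to_csv(matrix_path, sep="\t", float_format="%.17g")
    pos, neg = dataset.class_names
    with open(labels_path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["sample_id", "class"])
        for sid, lab in zip(dataset.sample_ids, dataset.labels):
            writer.writerow([sid, pos if lab == 1 else neg])


def write_selection_report(result: SelectionResult, path) -> None:
    """Write the selection report: genes in importance order with p-values.

    The per-round log, if present, is appended as commented lines so the
    data section stays machine-readable.
    """
    path = Path(path)
    if not result.genes:
        warnings.warn("selection result is empty; writing header-only report")
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["rank", "gene_id", "p_value"])
        for rank, gene in enumerate(result.genes, start=1):
            p = result.p_values[rank - 1] if result.p_values else ""
            writer.writerow([rank, gene, p])
    if result.round_log:
        with open(path, "a") as handle:
            handle.write("# round\tK\tgenes_in\tgenes_out\tmu_before\tmu_after\n")
            for rec in result.round_log:
                handle.write(
                    "# {round}\t{K}\t{genes_in}\t{genes_out}\t{mu_before:.6f}\t{mu_after:.6f}\n".format(
                        **rec
                    )
                )


def read_selection_report(path) -> SelectionResult:
    """Read back a report written by :func:`write_selection_report`."""
    genes: list[str] = []
    p_values: list[float] = []
    with open(path) as handle:
        reader = csv.reader(
            (line for line in handle if not line.startswith("#")), delimiter="\t"
        )
        header = next(reader, None)
        if header is None or header[:2] != ["rank", "gene_id"]:
            raise ValueError(f"{path} is not a selection report")
        for row in reader:
            if not row:
                continue
            genes.append(row[1])
            if len(row) > 2 and row[2] != "":
                p_values.append(float(row[2]))
    return SelectionResult(genes=genes, p_values=p_values if p_values else [])


def write_round_log(records, path) -> None:
    """Write one TSV row per filtering round."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["round", "K", "genes_in", "genes_out", "mu_before", "mu_after"])
        for rec in records:
            writer.writerow(
                [
                    rec.round_index,
                    rec.K_used,
                    len(rec.eliminated) + len(rec.survivors),
                    len(rec.survivors),
                    f"{rec.mu_before:.6f}",
                    f"{rec.mu_after:.6f}",
                ]
            )
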