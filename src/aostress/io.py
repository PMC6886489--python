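"""Reading and writing of the pipeline's tabular interchange formats.

All files are plain TSV: one genes x samples matrix per experiment, a
pooled ``samples.tsv`` sheet (experiment_id, platform, condition,
stress_type, tissue, time_point), a ``genes.tsv`` sheet (enzyme_class,
clade, housekeeping, length), and for qPCR either a long per-cycle
fluorescence table or a wells sheet with precomputed Cq values.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .types import ExpressionStudy, NormalizedPanel, QpcrPlate, ValidationError


def read_expression_study(matrix_path: str | Path, samples_path: str | Path,
                          genes_path: str | Path,
                          experiment_id: str | None = None) -> ExpressionStudy:
    """Read one experiment's matrix plus metadata sheets and validate.

    ``samples.tsv`` may cover several experiments; rows are selected by
    ``experiment_id`` (defaulting to the matrix file's stem before
    ``.matrix``).
    """
    matrix_path = Path(matrix_path)
    if experiment_id is None:
        experiment_id = matrix_path.name.split(".")[0]
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    try:
        matrix = matrix.astype(float)
    except ValueError as exc:
        raise ValidationError(
            f"{experiment_id}: non-numeric cells in {matrix_path.name}: {exc}"
        ) from exc
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    if "experiment_id" in samples.columns:
        samples = samples[samples["experiment_id"] == experiment_id]
    if samples.empty:
        raise ValidationError(
            f"{experiment_id}: no rows in sample sheet for this experiment")
    platforms = samples["platform"].unique() if "platform" in samples else ["intensity"]
    if len(platforms) != 1:
        raise ValidationError(
            f"{experiment_id}: mixed platform labels {list(platforms)}")
    missing = set(matrix.columns) - set(samples.index)
    if missing:
        raise ValidationError(
            f"{experiment_id}: sample sheet missing matrix columns "
            f"{sorted(missing)}")
    samples = samples.loc[list(matrix.columns)]
    genes = pd.read_csv(genes_path, sep="\t", index_col=0)
    if "housekeeping" not in genes.columns:
        raise ValidationError("gene sheet lacks a housekeeping column")
    genes["housekeeping"] = genes["housekeeping"].astype(bool)
    missing_genes = set(matrix.index) - set(genes.index)
    if missing_genes:
        raise ValidationError(
            f"{experiment_id}: gene sheet missing ids {sorted(missing_genes)}")
    genes = genes.loc[list(matrix.index)]
    return ExpressionStudy(
        experiment_id=experiment_id,
        platform=str(platforms[0]),
        matrix=matrix,
        samples=samples.drop(columns=[c for c in ("experiment_id", "platform")
                                      if c in samples.columns]),
        genes=genes,
    )


def read_meta_directory(data_dir: str | Path) -> list[ExpressionStudy]:
    """Read every ``*.matrix.tsv`` experiment in a directory."""
    data_dir = Path(data_dir)
    samples = data_dir / "samples.tsv"
    genes = data_dir / "genes.tsv"
    paths = sorted(data_dir.glob("*.matrix.tsv"))
    if not paths:
        raise ValidationError(f"no *.matrix.tsv files under {data_dir}")
    return [read_expression_study(p, samples, genes) for p in paths]


def write_panel(panel: NormalizedPanel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel.values.to_csv(out / "panel.tsv", sep="\t")
    panel.provenance.to_csv(out / "panel_provenance.tsv", sep="\t")
    panel.control_means.to_csv(out / "control_means.tsv", sep="\t")


def read_qpcr_plate(wells_path: str | Path,
                    curves_path: str | Path | None = None,
                    n_cycles: int | None = None) -> QpcrPlate:
    """Read a wells sheet and, optionally, a long per-cycle curve table."""
    wells = pd.read_csv(wells_path, sep="\t")
    curves = None
    if curves_path is not None:
        long = pd.read_csv(curves_path, sep="\t")
        curves = long.pivot(index="cycle", columns="well_id",
                            values="fluorescence").sort_index()
        if n_cycles is None:
            n_cycles = int(curves.index.max())
    if n_cycles is None:
        n_cycles = int(pd.to_numeric(wells.get("cq"), errors="coerce")
                       .max() // 1 + 5) if "cq" in wells else 45
    return QpcrPlate(wells=wells, n_cycles=n_cycles, curves=curves)
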