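"""The three-stage normalization cascade.

Counts are first converted to FPKM (fragments per kilobase of transcript
per million mapped reads); every sample is then divided by its
housekeeping-gene value to remove per-sample scale; finally each gene is
divided, within each experiment, by the mean of its control replicates.
The result is a panel of dimensionless fold changes in which every
gene x experiment control mean equals 1 by construction, making profiles
comparable across platforms and batches.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .types import ExpressionStudy, NormalizedPanel, ValidationError

logger = logging.getLogger(__name__)


def fpkm_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """FPKM-normalize a counts-platform study; intensity studies pass through.

    value(g, s) = 1e9 * c(g, s) / (length(g) * total_counts(s)).
    """
    if study.platform != "counts":
        return study
    counts = study.matrix.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    zero = study.matrix.columns[totals == 0]
    if len(zero):
        raise ValidationError(
            f"{study.experiment_id}: zero total counts in sample(s) "
            f"{list(zero)}")
    lengths = study.genes["length"].to_numpy(dtype=float)[:, None]
    fpkm = 1.0e9 * counts / (lengths * totals[None, :])
    matrix = pd.DataFrame(fpkm, index=study.matrix.index,
                          columns=study.matrix.columns)
    return study.copy_with(matrix, platform="intensity")


def housekeeping_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Divide every sample by its housekeeping-gene value.

    The housekeeping row becomes all ones; the operation is idempotent.
    """
    hk = study.housekeeping_gene
    hk_values = study.matrix.loc[hk]
    zero = study.matrix.columns[hk_values.to_numpy() == 0]
    if len(zero):
        raise ValidationError(
            f"{study.experiment_id}: housekeeping gene {hk} is zero in "
            f"replicate(s) {list(zero)}")
    matrix = study.matrix / hk_values
    return study.copy_with(matrix)


def control_relative_normalize(studies: Sequence[ExpressionStudy]
                               ) -> NormalizedPanel:
    """Divide each gene, per experiment, by its control-replicate mean.

    Pools all experiments into one genes x replicates panel of fold
    changes (replicate columns are ``experiment_id:sample_id``).  Genes
    whose control mean is zero in an experiment cannot be normalized
    there: they are set to NaN for that experiment's replicates, logged,
    and listed in ``panel.excluded``.  The housekeeping gene is dropped
    from the panel (it is 1 everywhere after the previous stage and
    carries no biology).
    """
    if not studies:
        raise ValidationError("empty study list")
    hk = studies[0].housekeeping_gene
    blocks: list[pd.DataFrame] = []
    prov_rows: list[pd.DataFrame] = []
    control_means: dict[str, pd.Series] = {}
    excluded: list[tuple[str, str]] = []
    for study in studies:
        ctrl = study.control_samples
        means = study.matrix[ctrl].mean(axis=1)
        zero_genes = means.index[means == 0]
        for g in zero_genes:
            excluded.append((str(g), study.experiment_id))
            logger.warning("gene %s has zero control mean in %s; excluded",
                           g, study.experiment_id)
        safe = means.replace(0, np.nan)
        values = study.matrix.div(safe, axis=0)
        values.columns = [f"{study.experiment_id}:{s}"
                          for s in study.matrix.columns]
        blocks.append(values.drop(index=hk, errors="ignore"))
        control_means[study.experiment_id] = means.drop(index=hk,
                                                        errors="ignore")
        prov = pd.DataFrame(
            {
                "experiment_id": study.experiment_id,
                "condition": study.samples["condition"].to_numpy(),
                "stress_type": study.samples["stress_type"].to_numpy(),
            },
            index=pd.Index(values.columns, name="replicate"),
        )
        prov_rows.append(prov)
    panel_values = pd.concat(blocks, axis=1)
    return NormalizedPanel(
        values=panel_values,
        provenance=pd.concat(prov_rows),
        control_means=pd.DataFrame(control_means),
        excluded=excluded,
    )


def normalize_cascade(studies: Sequence[ExpressionStudy]) -> NormalizedPanel:
    """FPKM (counts only) -> housekeeping -> control-relative."""
    prepared = [housekeeping_normalize(fpkm_normalize(s)) for s in studies]
    return control_relative_normalize(prepared)
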