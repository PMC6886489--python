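"""Core data containers shared by all pipeline stages.

The pipeline carries expression data as pandas objects wrapped in light
dataclasses that enforce the structural invariants each stage relies on:
an :class:`ExpressionStudy` is one experiment's genes x replicates matrix
with sample and gene annotation; a :class:`NormalizedPanel` is the pooled,
control-relative fold-change matrix across experiments; a
:class:`ClusterModel` holds the Ward merge history and flat assignment;
a :class:`QpcrPlate` holds amplification curves or Cq values per well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

CONDITIONS = ("control", "stress")
STRESS_TYPES = ("cold", "water_deficiency", "none")
ENZYME_CLASSES = ("APX", "CAT", "SOD", "GPX", "GR", "DHAR", "MDHAR", "other")
PLATFORMS = ("counts", "intensity")

#: label given to clusters dominated by cold-stress replicates
COLD_RESPONSE = "CR"
#: label given to clusters dominated by water-deficiency replicates
WATER_DEFICIENCY_RESPONSE = "WDR"


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


@dataclass
class ExpressionStudy:
    """One experiment: a genes x replicates expression matrix plus metadata.

    Parameters
    ----------
    experiment_id : str
        Unique label for the experiment (e.g. a GEO series accession).
    platform : {"counts", "intensity"}
        Sequencing platforms carry raw counts and are FPKM-normalized;
        array platforms carry intensities assumed pre-processed.
    matrix : DataFrame
        Non-negative expression values, index = gene ids, columns = sample
        ids matching ``samples.index``.
    samples : DataFrame
        Per-replicate metadata with columns ``condition`` (control/stress),
        ``stress_type`` (cold/water_deficiency/none), ``tissue``,
        ``time_point``.
    genes : DataFrame
        Per-gene metadata with columns ``enzyme_class``, ``clade``,
        ``housekeeping`` (bool, exactly one True), ``length`` (bp).
    """

    experiment_id: str
    platform: str
    matrix: pd.DataFrame
    samples: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValidationError(
                f"{self.experiment_id}: unknown platform {self.platform!r}"
            )
        if self.matrix.index.duplicated().any():
            dups = self.matrix.index[self.matrix.index.duplicated()].tolist()
            raise ValidationError(f"{self.experiment_id}: duplicated gene ids {dups}")
        if list(self.matrix.columns) != list(self.samples.index):
            missing = set(self.matrix.columns) ^ set(self.samples.index)
            raise ValidationError(
                f"{self.experiment_id}: matrix columns and sample sheet disagree "
                f"on {sorted(missing)}"
            )
        if list(self.matrix.index) != list(self.genes.index):
            missing = set(self.matrix.index) ^ set(self.genes.index)
            raise ValidationError(
                f"{self.experiment_id}: matrix rows and gene sheet disagree "
                f"on {sorted(missing)}"
            )
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise ValidationError(
                f"{self.experiment_id}: unknown condition labels {sorted(bad)}"
            )
        bad = set(self.samples["stress_type"]) - set(STRESS_TYPES)
        if bad:
            raise ValidationError(
                f"{self.experiment_id}: unknown stress_type labels {sorted(bad)}"
            )
        if not np.issubdtype(self.matrix.to_numpy().dtype, np.number):
            raise ValidationError(f"{self.experiment_id}: non-numeric matrix cells")
        if (self.matrix.to_numpy() < 0).any():
            raise ValidationError(f"{self.experiment_id}: negative expression values")
        if int(self.n_control) < 2:
            raise ValidationError(
                f"{self.experiment_id}: needs >=2 control replicates, "
                f"found {self.n_control}"
            )
        n_hk = int(self.genes["housekeeping"].sum())
        if n_hk != 1:
            raise ValidationError(
                f"{self.experiment_id}: exactly one housekeeping gene must be "
                f"flagged, found {n_hk}"
            )
        if self.platform == "counts":
            if "length" not in self.genes or (self.genes["length"] <= 0).any():
                raise ValidationError(
                    f"{self.experiment_id}: counts platform requires positive "
                    "gene lengths"
                )

    @property
    def n_control(self) -> int:
        return int((self.samples["condition"] == "control").sum())

    @property
    def n_stress(self) -> int:
        return int((self.samples["condition"] == "stress").sum())

    @property
    def housekeeping_gene(self) -> str:
        return str(self.genes.index[self.genes["housekeeping"]][0])

    @property
    def control_samples(self) -> list[str]:
        return list(self.samples.index[self.samples["condition"] == "control"])

    @property
    def stress_samples(self) -> list[str]:
        return list(self.samples.index[self.samples["condition"] == "stress"])

    def copy_with(self, matrix: pd.DataFrame, platform: Optional[str] = None
                  ) -> "ExpressionStudy":
        return ExpressionStudy(
            experiment_id=self.experiment_id,
            platform=platform or self.platform,
            matrix=matrix,
            samples=self.samples.copy(),
            genes=self.genes.copy(),
        )


@dataclass
class NormalizedPanel:
    """Control-relative fold changes pooled across experiments.

    ``values`` is a genes x replicates matrix of dimensionless fold
    changes; replicate columns are ``"<experiment_id>:<sample_id>"``.  For
    every gene and experiment the mean of control-replicate values is 1 by
    construction.  Genes whose control mean was zero in an experiment are
    NaN in that experiment's columns and listed in ``excluded``; the
    housekeeping gene is dropped entirely.
    """

    values: pd.DataFrame
    provenance: pd.DataFrame  # index = replicate, cols experiment_id/condition/stress_type
    control_means: pd.DataFrame  # genes x experiments, the divisors used
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (gene, experiment)

    @property
    def replicates(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def control_replicates(self) -> list[str]:
        return list(self.provenance.index[self.provenance["condition"] == "control"])

    def stress_replicates(self) -> list[str]:
        return list(self.provenance.index[self.provenance["condition"] == "stress"])

    def subset(self, replicates: list[str]) -> "NormalizedPanel":
        keep = [r for r in self.values.columns if r in set(replicates)]
        return NormalizedPanel(
            values=self.values[keep],
            provenance=self.provenance.loc[keep],
            control_means=self.control_means,
            excluded=list(self.excluded),
        )

    def complete_genes(self) -> pd.DataFrame:
        """Values restricted to genes without any missingness."""
        return self.values.dropna(axis=0, how="any")


@dataclass
class ClusterModel:
    """Ward clustering of replicate fold-change profiles."""

    assignment: pd.Series  # replicate -> cluster index (1..n_clusters)
    n_clusters: int
    linkage: np.ndarray  # scipy linkage matrix (merge history: pairs + heights)
    distance_space: str  # "log2" or "linear"
    cluster_types: dict[int, str] = field(default_factory=dict)
    dropped_genes: list[str] = field(default_factory=list)

    def members(self, cluster: int) -> list[str]:
        return list(self.assignment.index[self.assignment == cluster])

    @property
    def clusters(self) -> list[int]:
        return sorted(self.assignment.unique())


@dataclass
class QpcrPlate:
    """A qPCR plate: well annotations plus curves or Cq values.

    ``wells`` columns: well_id, target, role (target/reference/ntc),
    cultivar, treatment, bio_rep, tech_rep, and (in Cq mode) ``cq``.
    ``curves`` (curve mode) is a cycles x wells DataFrame of fluorescence,
    index = cycle number starting at 1.
    """

    wells: pd.DataFrame
    n_cycles: int
    curves: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        required = {"well_id", "target", "role", "cultivar", "treatment",
                    "bio_rep", "tech_rep"}
        missing = required - set(self.wells.columns)
        if missing:
            raise ValidationError(f"well sheet missing columns {sorted(missing)}")
        if self.curves is None and "cq" not in self.wells.columns:
            raise ValidationError("plate needs either curves or a cq column")
        if self.curves is not None:
            unknown = set(self.wells["well_id"]) - set(self.curves.columns)
            if unknown:
                raise ValidationError(f"wells without curves: {sorted(unknown)}")
        if "cq" in self.wells.columns and self.curves is None:
            cq = self.wells.loc[self.wells["role"] != "ntc", "cq"].dropna()
            if ((cq < 1) | (cq > self.n_cycles)).any():
                raise ValidationError("Cq values outside [1, n_cycles]")
        # every annotated sample must carry reference wells
        samples = self.wells[self.wells["role"] == "target"]
        refs = self.wells[self.wells["role"] == "reference"]
        ref_keys = set(map(tuple, refs[["cultivar", "treatment", "bio_rep"]]
                           .itertuples(index=False)))
        for key in set(map(tuple, samples[["cultivar", "treatment", "bio_rep"]]
                           .itertuples(index=False))):
            if key not in ref_keys:
                raise ValidationError(
                    f"sample {key} has no reference-gene wells"
                )

    @property
    def has_curves(self) -> bool:
        return self.curves is not None

    @property
    def reference_target(self) -> str:
        refs = self.wells.loc[self.wells["role"] == "reference", "target"].unique()
        if len(refs) != 1:
            raise ValidationError(
                f"expected exactly one reference amplicon, found {list(refs)}"
            )
        return str(refs[0])


@dataclass
class RatioEstimate:
    """Efficiency-corrected relative expression for one target x condition.

    ``ratio`` is E_target^dcq_target / E_reference^dcq_reference with
    dcq = mean control Cq - mean treated Cq, so ratio > 1 means higher
    expression under treatment.
    """

    target: str
    cultivar: str
    treatment: str
    ratio: float
    e_target: float
    e_reference: float
    dcq_target: float
    dcq_reference: float
    n_bio: int = 0

    def __post_init__(self) -> None:
        if not (self.ratio > 0):
            raise ValidationError("ratio must be positive")
        for e in (self.e_target, self.e_reference):
            if not (1.0 < e <= 2.05):  # +0.05 tolerance for estimation noise
                raise ValidationError(f"efficiency {e} outside (1, 2.05]")
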