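"""Model/Results objects tying the pipeline stages together.

:class:`StressMetaAnalysis` is constructed from a list of experiments
and :meth:`~StressMetaAnalysis.fit` runs the full meta-analysis:
normalization cascade -> Ward clustering -> experiment QC filter ->
re-clustering of the retained sample -> cluster-vs-control (or
per-experiment) differential calls -> fold-change summary.  The returned
:class:`MetaAnalysisResults` carries every intermediate artifact, a
``summary()`` table, and writers/plots.

:class:`QpcrRelativeExpression` does the same for a qPCR plate:
efficiency/Cq estimation -> efficiency-corrected ratios -> two-way
ANOVA on dCq.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cluster import (cluster_replicates, filter_experiments, label_clusters,
                      pca_profiles, retained_experiments)
from .differential import (compare_many, summarize_panel, summary_html,
                           summary_marks)
from .io import read_meta_directory, write_panel
from .normalize import normalize_cascade
from .qpcr import aggregate_ratios, anova_dcq, dcq_table, ratios_frame
from .types import (ClusterModel, ExpressionStudy, NormalizedPanel, QpcrPlate,
                    ValidationError)


def _manifest(out: Path, config: dict, seed: Optional[int]) -> None:
    payload = json.dumps(config, sort_keys=True, default=str)
    digest = hashlib.sha256(payload.encode()).hexdigest()[:16]
    out.joinpath("manifest.json").write_text(json.dumps(
        {"package": "aostress", "version": __version__, "seed": seed,
         "config_hash": digest, "config": json.loads(payload)},
        indent=1, sort_keys=True))


class StressMetaAnalysis:
    """Cross-experiment meta-analysis of stress fold-change profiles.

    Parameters
    ----------
    studies : sequence of ExpressionStudy
        The experiment bundle (mixed counts/intensity platforms).
    n_clusters : int, optional
        Ward cut size; ``None`` selects k by maximum mean silhouette.
    alpha : float
        Significance level applied to BY-adjusted p-values.
    apply_filter : bool
        Whether to run the experiment QC filter between the two
        clustering passes.
    comparison_mode : {"cluster", "experiment"}
        ``cluster``: each stress cluster vs all control replicates (the
        pooled-sample workflow).  ``experiment``: stress vs control
        within each experiment (the small-sample workflow, no filter).
    """

    def __init__(self, studies: Sequence[ExpressionStudy], *,
                 n_clusters: Optional[int] = None, alpha: float = 0.05,
                 apply_filter: bool = True, space: str = "log2",
                 test: str = "welch", use_adjusted: bool = True,
                 control_cluster_rule: str = "any",
                 comparison_mode: str = "cluster",
                 aggregate_clades: bool = False,
                 seed: Optional[int] = None):
        if not studies:
            raise ValidationError("at least one study is required")
        if comparison_mode not in ("cluster", "experiment"):
            raise ValidationError(
                f"unknown comparison mode {comparison_mode!r}")
        self.studies = list(studies)
        self.n_clusters = n_clusters
        self.alpha = alpha
        self.apply_filter = apply_filter
        self.space = space
        self.test = test
        self.use_adjusted = use_adjusted
        self.control_cluster_rule = control_cluster_rule
        self.comparison_mode = comparison_mode
        self.aggregate_clades = aggregate_clades
        self.seed = seed

    @classmethod
    def from_directory(cls, data_dir: str | Path, **kwargs
                       ) -> "StressMetaAnalysis":
        return cls(read_meta_directory(data_dir), **kwargs)

    def config(self) -> dict:
        return {"n_clusters": self.n_clusters, "alpha": self.alpha,
                "apply_filter": self.apply_filter, "space": self.space,
                "test": self.test, "use_adjusted": self.use_adjusted,
                "control_cluster_rule": self.control_cluster_rule,
                "comparison_mode": self.comparison_mode,
                "aggregate_clades": self.aggregate_clades,
                "n_experiments": len(self.studies)}

    def fit(self) -> "MetaAnalysisResults":
        panel = normalize_cascade(self.studies)

        prefilter = label_clusters(
            cluster_replicates(panel, self.n_clusters, self.space), panel)
        if self.apply_filter:
            report = filter_experiments(prefilter, panel,
                                        rule=self.control_cluster_rule)
            retained = retained_experiments(report)
        else:
            report = filter_experiments(prefilter, panel,
                                        rule=self.control_cluster_rule)
            report = report.assign(excluded=False)
            retained = list(report.index)

        # second pass: retained experiments' stress replicates + all controls
        prov = panel.provenance
        keep = list(prov.index[
            (prov["condition"] == "control")
            | prov["experiment_id"].isin(retained)])
        panel2 = panel.subset(keep)
        clusters = label_clusters(
            cluster_replicates(panel2, self.n_clusters, self.space), panel2)

        controls = panel2.control_replicates()
        comparisons: dict[str, tuple[list[str], list[str]]] = {}
        if self.comparison_mode == "cluster":
            counters: dict[str, int] = {}
            for c in clusters.clusters:
                ctype = clusters.cluster_types[c]
                if ctype == "control":
                    continue
                counters[ctype] = counters.get(ctype, 0) + 1
                comparisons[f"{ctype}{counters[ctype]}"] = (
                    clusters.members(c), controls)
        else:
            for exp in retained:
                sub = prov[prov["experiment_id"] == exp]
                stress = list(sub.index[sub["condition"] == "stress"])
                ctrl = list(sub.index[sub["condition"] == "control"])
                if stress:
                    comparisons[exp] = (stress, ctrl)
        if not comparisons:
            raise ValidationError(
                "no stress comparisons available after filtering")

        table = compare_many(panel2, comparisons, alpha=self.alpha,
                             test=self.test, use_adjusted=self.use_adjusted,
                             mode=self.comparison_mode)
        genes_meta = self.studies[0].genes
        summary_folds = summarize_panel(table, genes_meta,
                                        self.aggregate_clades)
        marks = summary_marks(table)
        scores, evr = pca_profiles(panel2, self.space)
        return MetaAnalysisResults(
            model=self, panel=panel, panel_retained=panel2,
            prefilter_clusters=prefilter, clusters=clusters,
            filter_report=report, retained=retained,
            differential=table, summary_folds=summary_folds,
            summary_calls=marks, pca_scores=scores,
            pca_explained=evr, comparisons=comparisons)


@dataclass
class MetaAnalysisResults:
    """Fitted meta-analysis: panels, clusterings, filter report, calls."""

    model: StressMetaAnalysis
    panel: NormalizedPanel
    panel_retained: NormalizedPanel
    prefilter_clusters: ClusterModel
    clusters: ClusterModel
    filter_report: pd.DataFrame
    retained: list[str]
    differential: pd.DataFrame
    summary_folds: pd.DataFrame
    summary_calls: pd.DataFrame
    pca_scores: pd.DataFrame
    pca_explained: np.ndarray
    comparisons: dict[str, tuple[list[str], list[str]]] = field(
        default_factory=dict)

    def significant(self) -> pd.DataFrame:
        return self.differential[self.differential["call"] != "ns"]

    def summary(self) -> str:
        m = self.model
        lines = [
            "Stress meta-analysis results",
            "=" * 60,
            f"experiments: {len(m.studies)}  retained: {len(self.retained)}"
            f"  excluded: {len(m.studies) - len(self.retained)}",
            f"replicates (retained panel): {len(self.panel_retained.replicates)}"
            f"  genes: {len(self.panel_retained.genes)}",
            f"clusters: {self.clusters.n_clusters} "
            f"({', '.join(f'{c}:{t}' for c, t in sorted(self.clusters.cluster_types.items()))})",
            f"comparisons: {len(self.comparisons)} "
            f"[{m.comparison_mode} mode, {m.test} t-test, "
            f"alpha={m.alpha} on "
            f"{'BY-adjusted' if m.use_adjusted else 'raw'} p]",
            f"significant calls: "
            f"{int((self.differential['call'] == 'up').sum())} up, "
            f"{int((self.differential['call'] == 'down').sum())} down "
            f"of {len(self.differential)} gene x comparison tests",
            f"PCA: PC1 {self.pca_explained[0] * 100:.1f}%, "
            f"PC2 {self.pca_explained[1] * 100:.1f}% of variance",
            "",
            "Per-experiment QC filter:",
            self.filter_report.to_string(),
        ]
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        """Write every stage artifact as TSV plus a run manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_panel(self.panel, out)
        assign = self.clusters.assignment.rename("cluster").to_frame()
        assign = assign.join(self.panel_retained.provenance)
        assign["cluster_type"] = assign["cluster"].map(
            self.clusters.cluster_types)
        assign.to_csv(out / "assignment.tsv", sep="\t")
        pd.DataFrame(self.clusters.linkage,
                     columns=["left", "right", "height", "size"]
                     ).to_csv(out / "linkage.tsv", sep="\t", index=False)
        self.pca_scores.assign().to_csv(out / "pca_scores.tsv", sep="\t")
        pd.DataFrame({"component": [f"PC{i+1}" for i in
                                    range(len(self.pca_explained))],
                      "explained_fraction": self.pca_explained}
                     ).to_csv(out / "pca_explained.tsv", sep="\t",
                              index=False)
        self.filter_report.to_csv(out / "filter_report.tsv", sep="\t")
        self.differential.to_csv(out / "differential.tsv", sep="\t",
                                 index=False)
        self.summary_folds.to_csv(out / "summary.tsv", sep="\t")
        out.joinpath("summary.html").write_text(
            summary_html(self.summary_folds, self.summary_calls))
        _manifest(out, self.model.config(), self.model.seed)

    def plot_dendrogram(self, ax=None):
        from .plotting import plot_dendrogram
        return plot_dendrogram(self, ax=ax)

    def plot_pca(self, ax=None):
        from .plotting import plot_pca
        return plot_pca(self, ax=ax)


class QpcrRelativeExpression:
    """Efficiency-corrected relative expression from a qPCR plate.

    For curve plates, per-well efficiencies and Cq values come from the
    window-of-linearity estimator; Cq-only plates need per-amplicon
    ``efficiencies``.  ``fit()`` computes one ratio per
    target x cultivar x treatment and, when both factors have two or
    more levels, the two-way ANOVA on dCq.
    """

    def __init__(self, plate: QpcrPlate,
                 efficiencies: Optional[dict[str, float]] = None,
                 control_treatment: str = "control",
                 seed: Optional[int] = None):
        self.plate = plate
        self.efficiencies = efficiencies
        self.control_treatment = control_treatment
        self.seed = seed

    def config(self) -> dict:
        return {"efficiencies": self.efficiencies,
                "control_treatment": self.control_treatment,
                "n_wells": len(self.plate.wells),
                "mode": "curves" if self.plate.has_curves else "cq"}

    def fit(self) -> "QpcrResults":
        estimates = aggregate_ratios(self.plate, self.efficiencies,
                                     self.control_treatment)
        dcq = dcq_table(self.plate, self.efficiencies)
        anova = None
        if (dcq["cultivar"].nunique() >= 2
                and dcq["treatment"].nunique() >= 2):
            anova = anova_dcq(dcq)
        return QpcrResults(model=self, ratios=ratios_frame(estimates),
                           estimates=estimates, dcq=dcq, anova=anova)


@dataclass
class QpcrResults:
    """Fitted qPCR quantification: ratios, dCq table, ANOVA."""

    model: QpcrRelativeExpression
    ratios: pd.DataFrame
    estimates: list
    dcq: pd.DataFrame
    anova: Optional[pd.DataFrame] = None

    def summary(self) -> str:
        lines = ["qPCR relative expression (efficiency-corrected)",
                 "=" * 60,
                 self.ratios.to_string(index=False,
                                       float_format=lambda v: f"{v:.4f}")]
        if self.anova is not None:
            lines += ["", "Two-way ANOVA on dCq (type II SS):",
                      self.anova.to_string(index=False,
                                           float_format=lambda v: f"{v:.4g}")]
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.ratios.to_csv(out / "ratios.tsv", sep="\t", index=False)
        self.dcq.to_csv(out / "dcq.tsv", sep="\t", index=False)
        if self.anova is not None:
            self.anova.to_csv(out / "anova.tsv", sep="\t", index=False)
        _manifest(out, self.model.config(), self.model.seed)

    def plot_ratios(self, ax=None):
        from .plotting import plot_ratio_bars
        return plot_ratio_bars(self, ax=ax)
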