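"""Ward clustering of replicate profiles, PCA views, and the QC filter.

Replicate fold-change profiles are clustered with Ward's
minimum-variance criterion on Euclidean distances, by default in
log2(fold + eps) space since fold changes are multiplicative.  Clusters
are labeled control / CR (cold response) / WDR (water-deficiency
response) / mixed by their majority composition.  The experiment-level
quality filter drops any experiment whose stress replicates mostly land
in control-containing clusters — such an experiment shows no explicit
stress response, or noisy data.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .types import (COLD_RESPONSE, WATER_DEFICIENCY_RESPONSE, ClusterModel,
                    NormalizedPanel, ValidationError)

logger = logging.getLogger(__name__)

LOG_EPS = 1.0e-6


def _profile_matrix(panel: NormalizedPanel, space: str
                    ) -> tuple[np.ndarray, list[str], list[str]]:
    """Replicates x genes matrix in the configured distance space.

    Genes with any missing value across replicates are dropped (and
    reported) so every profile lives in the same space.
    """
    complete = panel.complete_genes()
    dropped = [g for g in panel.values.index if g not in complete.index]
    if dropped:
        logger.info("dropping %d gene(s) with missing values: %s",
                    len(dropped), dropped)
    X = complete.to_numpy(dtype=float).T  # replicates x genes
    if space == "log2":
        X = np.log2(X + LOG_EPS)
    elif space != "linear":
        raise ValidationError(f"unknown distance space {space!r}")
    return X, list(complete.columns), dropped


def choose_n_clusters(X: np.ndarray, k_min: int = 3, k_max: int = 15
                      ) -> int:
    """Pick k maximizing the mean silhouette of the Ward cut.

    The floor defaults to 3: the pipeline always needs the control
    profile separated from each stress type, and a 2-cluster cut cannot
    do that, which would make the downstream experiment filter vacuous.
    """
    Z = linkage(X, method="ward")
    best_k, best_s = k_min, -np.inf
    for k in range(k_min, min(k_max, X.shape[0] - 1) + 1):
        labels = fcluster(Z, k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(X, labels)
        if s > best_s + 1.0e-12:
            best_k, best_s = k, s
    return best_k


def cluster_replicates(panel: NormalizedPanel, n_clusters: int | None = None,
                       space: str = "log2") -> ClusterModel:
    """Agglomerative Ward clustering of replicate profiles.

    ``n_clusters=None`` selects k by maximum mean silhouette over
    k in [2, 15].  Raises on degenerate input (all profiles identical).
    """
    X, replicates, dropped = _profile_matrix(panel, space)
    if n_clusters is not None and n_clusters > len(replicates):
        raise ValidationError(
            f"n_clusters={n_clusters} exceeds {len(replicates)} replicates")
    if np.allclose(X, X[0], atol=1.0e-12):
        raise ValidationError(
            "all replicate profiles are identical; clustering is degenerate")
    Z = linkage(X, method="ward")
    if n_clusters is None:
        n_clusters = choose_n_clusters(X)
    labels = fcluster(Z, n_clusters, criterion="maxclust")
    assignment = pd.Series(labels, index=pd.Index(replicates,
                                                  name="replicate"))
    return ClusterModel(assignment=assignment,
                        n_clusters=int(len(np.unique(labels))),
                        linkage=Z, distance_space=space,
                        dropped_genes=dropped)


def pca_profiles(panel: NormalizedPanel, space: str = "log2",
                 scale: bool = False) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of replicate profiles; returns (scores, explained-variance fractions).

    Profiles are centered (and optionally unit-scaled per gene); all
    components are kept so the explained-variance fractions sum to 1 and
    the score space preserves pairwise Euclidean distances.
    """
    X, replicates, _ = _profile_matrix(panel, space)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValidationError("PCA needs >=2 replicates and >=2 genes")
    if np.allclose(X.std(axis=0), 0.0):
        raise ValidationError("constant matrix; PCA undefined")
    if scale:
        sd = X.std(axis=0, ddof=0)
        X = X / np.where(sd == 0, 1.0, sd)
    pca = PCA(n_components=min(X.shape))
    scores = pca.fit_transform(X)
    frac = pca.explained_variance_ratio_
    frac = frac / frac.sum()  # all retained components span the data
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (pd.DataFrame(scores, index=pd.Index(replicates, name="replicate"),
                         columns=cols), frac)


def label_clusters(model: ClusterModel, panel: NormalizedPanel
                   ) -> ClusterModel:
    """Label each cluster control / CR / WDR / mixed by its composition.

    A cluster is ``control`` if it contains at least one control
    replicate and controls are its strict majority; otherwise it takes
    the strict-majority stress type (CR for cold, WDR for water
    deficiency); ties are ``mixed``.
    """
    prov = panel.provenance.loc[model.assignment.index]
    types: dict[int, str] = {}
    for cluster in model.clusters:
        members = model.members(cluster)
        sub = prov.loc[members]
        n = len(members)
        n_control = int((sub["condition"] == "control").sum())
        if n_control >= 1 and n_control > n / 2:
            types[cluster] = "control"
            continue
        stress = sub.loc[sub["condition"] == "stress", "stress_type"]
        n_cold = int((stress == "cold").sum())
        n_wd = int((stress == "water_deficiency").sum())
        if n_cold > n_wd:
            types[cluster] = COLD_RESPONSE
        elif n_wd > n_cold:
            types[cluster] = WATER_DEFICIENCY_RESPONSE
        else:
            types[cluster] = "mixed"
    model.cluster_types = types
    return model


def control_containing_clusters(model: ClusterModel, panel: NormalizedPanel,
                                rule: str = "any") -> set[int]:
    """Clusters that count as 'control' for the QC filter.

    ``rule="any"``: any cluster containing >=1 control replicate (the
    literal reading); ``rule="majority"``: clusters whose members are
    majority-control.
    """
    prov = panel.provenance.loc[model.assignment.index]
    out = set()
    for cluster in model.clusters:
        sub = prov.loc[model.members(cluster)]
        n_control = int((sub["condition"] == "control").sum())
        if rule == "any" and n_control >= 1:
            out.add(cluster)
        elif rule == "majority" and n_control > len(sub) / 2:
            out.add(cluster)
        elif rule not in ("any", "majority"):
            raise ValidationError(f"unknown control-cluster rule {rule!r}")
    return out


def filter_experiments(model: ClusterModel, panel: NormalizedPanel,
                       rule: str = "any") -> pd.DataFrame:
    """Apply the experiment-exclusion rule.

    An experiment is excluded iff strictly more than 50% of its stress
    replicates fall into control-containing clusters (exactly 50% is
    retained).  Experiments without stress replicates are retained with
    an undefined fraction and flagged.  Returns a per-experiment report
    with columns n_stress, n_in_control_clusters, fraction, excluded,
    flag.
    """
    ctrl_clusters = control_containing_clusters(model, panel, rule)
    prov = panel.provenance.loc[model.assignment.index]
    rows = []
    for exp_id, sub in prov.groupby("experiment_id", sort=True):
        stress = sub.index[sub["condition"] == "stress"]
        n_stress = len(stress)
        if n_stress == 0:
            rows.append({"experiment_id": exp_id, "n_stress": 0,
                         "n_in_control_clusters": 0, "fraction": np.nan,
                         "excluded": False, "flag": "no-stress-replicates"})
            continue
        in_ctrl = int(model.assignment.loc[stress].isin(ctrl_clusters).sum())
        frac = in_ctrl / n_stress
        rows.append({"experiment_id": exp_id, "n_stress": n_stress,
                     "n_in_control_clusters": in_ctrl, "fraction": frac,
                     "excluded": bool(frac > 0.5), "flag": ""})
    return pd.DataFrame(rows).set_index("experiment_id")


def retained_experiments(report: pd.DataFrame) -> list[str]:
    return list(report.index[~report["excluded"]])
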