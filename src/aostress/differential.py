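"""Group comparisons, Benjamini-Yekutieli correction, and the summary table.

Stress groups (clusters, or stress replicates of a single experiment)
are compared against control replicates gene by gene with a two-sample
t-test on log2 fold changes (Welch by default).  P-values are adjusted
with the Benjamini-Yekutieli step-up procedure, which controls the false
discovery rate under arbitrary dependence at the price of the harmonic
factor c(m) = sum_{j<=m} 1/j.  Significant genes are called up or down
by their mean fold change, and the calls are assembled into a wide
fold-change summary matrix with significance marks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import NormalizedPanel, ValidationError

LOG_EPS = 1.0e-6
P_FLOOR = np.nextafter(0.0, 1.0)


def compare_groups(panel: NormalizedPanel, stress_replicates: list[str],
                   control_replicates: list[str],
                   test: str = "welch") -> pd.DataFrame:
    """Per-gene mean fold change and raw p for stress vs control.

    The t-test runs on log2(fold + eps) values; ``mean_fold`` is the
    geometric-mean ratio 2^(mean log2 stress - mean log2 control) and
    ``fold_arith`` the ratio of arithmetic means.  Genes with fewer than
    two finite values in either group get NaN p-values.  Degenerate
    zero-variance cases: identical groups give p = 1; unequal means with
    zero variance in both groups give the machine-minimum p and a flag.
    """
    if test not in ("welch", "student"):
        raise ValidationError(f"unknown test variant {test!r}")
    sv = panel.values[stress_replicates].to_numpy(dtype=float)
    cv = panel.values[control_replicates].to_numpy(dtype=float)
    rows = []
    for i, gene in enumerate(panel.values.index):
        s = sv[i][np.isfinite(sv[i])]
        c = cv[i][np.isfinite(cv[i])]
        row = {"gene": gene, "n_stress": len(s), "n_control": len(c),
               "flag": ""}
        if len(s) < 2 or len(c) < 2:
            row.update(mean_fold=np.nan, fold_arith=np.nan,
                       log2_mean_fold=np.nan, raw_p=np.nan,
                       flag="insufficient-replicates")
            rows.append(row)
            continue
        ls = np.log2(s + LOG_EPS)
        lc = np.log2(c + LOG_EPS)
        log2_fold = ls.mean() - lc.mean()
        row["log2_mean_fold"] = log2_fold
        row["mean_fold"] = 2.0 ** log2_fold
        row["fold_arith"] = s.mean() / c.mean() if c.mean() > 0 else np.nan
        if ls.var(ddof=1) == 0.0 and lc.var(ddof=1) == 0.0:
            if ls.mean() == lc.mean():
                row["raw_p"] = 1.0
            else:
                row["raw_p"] = P_FLOOR
                row["flag"] = "zero-variance-unequal-means"
        else:
            res = stats.ttest_ind(ls, lc, equal_var=(test == "student"))
            row["raw_p"] = float(res.pvalue)
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


def by_adjust(p_values) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values, in input order.

    With m finite p-values sorted ascending, a_i = p_(i) * m * c(m) / i
    where c(m) = sum_{j=1..m} 1/j; the adjusted value at rank i is
    min_{j>=i} a_j, capped at 1.  NaN entries pass through unchanged and
    do not count toward m.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = int(mask.sum())
    if m == 0:
        return out
    valid = p[mask]
    order = np.argsort(valid, kind="mergesort")
    ranks = np.arange(1, m + 1, dtype=float)
    c_m = (1.0 / ranks).sum()
    a = valid[order] * m * c_m / ranks
    adj = np.minimum(np.minimum.accumulate(a[::-1])[::-1], 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[mask] = restored
    return out


def call_regulation(table: pd.DataFrame, alpha: float = 0.05,
                    use_adjusted: bool = True) -> pd.DataFrame:
    """Attach BY-adjusted p and up/down/ns calls to a comparison table.

    ``call`` is up if the (adjusted) p is below alpha and mean_fold > 1,
    down if below alpha and mean_fold < 1, else ns.  A significant gene
    with mean_fold exactly 1 is a degenerate case: called ns and flagged.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must be in (0, 1)")
    out = table.copy()
    out["adj_p"] = by_adjust(out["raw_p"].to_numpy())
    crit = out["adj_p"] if use_adjusted else out["raw_p"]
    sig = crit < alpha
    call = np.where(sig & (out["mean_fold"] > 1), "up",
                    np.where(sig & (out["mean_fold"] < 1), "down", "ns"))
    degenerate = sig & (out["mean_fold"] == 1)
    out.loc[degenerate, "flag"] = "significant-at-fold-1"
    out["call"] = call
    return out


def compare_many(panel: NormalizedPanel,
                 comparisons: dict[str, tuple[list[str], list[str]]],
                 alpha: float = 0.05, test: str = "welch",
                 use_adjusted: bool = True,
                 mode: str = "cluster") -> pd.DataFrame:
    """Run several stress-vs-control comparisons and stack the long table.

    ``comparisons`` maps a comparison id to (stress replicates, control
    replicates).  The BY family is the set of genes within one
    comparison.
    """
    frames = []
    for cid, (stress, control) in comparisons.items():
        t = compare_groups(panel, stress, control, test=test)
        t = call_regulation(t, alpha=alpha, use_adjusted=use_adjusted)
        t.insert(0, "comparison_id", cid)
        t.insert(1, "mode", mode)
        frames.append(t.reset_index())
    if not frames:
        raise ValidationError("no comparisons supplied")
    return pd.concat(frames, ignore_index=True)


def summarize_panel(table: pd.DataFrame, gene_metadata: pd.DataFrame,
                    aggregate_clades: bool = False) -> pd.DataFrame:
    """Wide fold-change summary: genes (grouped by enzyme class and clade)
    x comparisons, with significance marks.

    Cell values are mean fold changes; significant cells (per the long
    table's calls) are marked with ``*`` in the companion ``*_sig``
    columns produced by :func:`summary_marks`.  Genes absent from a
    comparison stay NaN ("no data").  With ``aggregate_clades`` the rows
    are clade-level arithmetic means of the member genes' folds (the view
    needed when probes report whole homeologue groups).
    """
    folds = table.pivot(index="gene", columns="comparison_id",
                        values="mean_fold")
    meta = gene_metadata.reindex(folds.index)
    folds.insert(0, "enzyme_class", meta["enzyme_class"])
    folds.insert(1, "clade", meta["clade"])
    folds = folds.sort_values(["enzyme_class", "clade"],
                              kind="mergesort")
    if aggregate_clades:
        value_cols = [c for c in folds.columns
                      if c not in ("enzyme_class", "clade")]
        folds = (folds.groupby(["enzyme_class", "clade"], sort=True)
                 [value_cols].mean().reset_index()
                 .set_index("clade"))
    return folds


def summary_marks(table: pd.DataFrame) -> pd.DataFrame:
    """Genes x comparisons matrix of calls (up/down/ns; NaN = no data)."""
    return table.pivot(index="gene", columns="comparison_id", values="call")


def summary_html(folds: pd.DataFrame, marks: pd.DataFrame | None = None,
                 title: str = "Fold-change summary") -> str:
    """Heat-styled HTML rendering of the summary matrix.

    Up-regulation shades red, down-regulation green, missing cells
    yellow; significant cells are bold.
    """
    value_cols = [c for c in folds.columns
                  if c not in ("enzyme_class", "clade")]

    def cell(gene: str, comp: str, v: float) -> str:
        if pd.isna(v):
            return '<td style="background:#ffff99">n/a</td>'
        l2 = np.log2(max(v, 1e-9))
        t = min(abs(l2) / 3.0, 1.0)
        if l2 > 0:
            color = f"rgb(255,{int(255 - 155 * t)},{int(255 - 155 * t)})"
        else:
            color = f"rgb({int(255 - 155 * t)},255,{int(255 - 155 * t)})"
        bold = ""
        if marks is not None and gene in marks.index and comp in marks.columns:
            if marks.loc[gene, comp] in ("up", "down"):
                bold = "font-weight:bold;"
        return f'<td style="background:{color};{bold}">{v:.2f}</td>'

    head = "".join(f"<th>{c}</th>" for c in folds.columns)
    body = []
    for gene, row in folds.iterrows():
        cells = []
        for c in folds.columns:
            if c in value_cols:
                cells.append(cell(str(gene), str(c), row[c]))
            else:
                cells.append(f"<td>{row[c]}</td>")
        body.append(f"<tr><th>{gene}</th>{''.join(cells)}</tr>")
    return (f"<html><head><title>{title}</title></head><body>"
            f"<h1>{title}</h1><table border='1' style='border-collapse:"
            f"collapse'><tr><th></th>{head}</tr>{''.join(body)}</table>"
            f"</body></html>")
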