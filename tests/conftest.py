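"""Shared fixtures and independent oracle implementations.

The oracles (brute-force BY step-up, textbook Welch t-test, classic
balanced two-way ANOVA sums of squares) are deliberately naive and
independent of the package's code paths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings
from scipy import stats

from aostress.types import ExpressionStudy

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


def make_study(matrix, conditions, experiment_id="EXP1", platform="intensity",
               stress_type="cold", gene_ids=None, hk_index=0, lengths=None):
    """Small hand-built ExpressionStudy for unit tests."""
    matrix = np.asarray(matrix, dtype=float)
    n_genes, n_samples = matrix.shape
    if gene_ids is None:
        gene_ids = [f"G{i}" for i in range(n_genes)]
    samples = pd.DataFrame(
        {"condition": conditions,
         "stress_type": [stress_type if c == "stress" else "none"
                         for c in conditions],
         "tissue": "shoot", "time_point": "24h"},
        index=pd.Index([f"S{j}" for j in range(n_samples)], name="sample_id"))
    genes = pd.DataFrame(
        {"enzyme_class": ["other"] * n_genes,
         "clade": [f"clade{i}" for i in range(n_genes)],
         "housekeeping": [i == hk_index for i in range(n_genes)],
         "length": lengths if lengths is not None else [1000.0] * n_genes},
        index=pd.Index(gene_ids, name="gene_id"))
    return ExpressionStudy(
        experiment_id=experiment_id, platform=platform,
        matrix=pd.DataFrame(matrix, index=genes.index, columns=samples.index),
        samples=samples, genes=genes)


def by_adjust_brute(p):
    """Brute-force BY step-up straight from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    c_m = sum(1.0 / j for j in range(1, m + 1))
    order = np.argsort(p, kind="mergesort")
    a = np.minimum(p[order] * m * c_m / np.arange(1, m + 1), 1.0)
    adj = np.empty(m)
    for rank_pos in range(m):  # adj at rank i = min over ranks j >= i
        adj[order[rank_pos]] = a[rank_pos:].min()
    return adj


def welch_p_oracle(a, b):
    """Textbook Welch two-sample t-test (two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2.0 * stats.t.sf(abs(t), df)


def anova2_balanced_oracle(df, value="dcq", fa="cultivar", fb="treatment"):
    """Classic sums-of-squares two-way ANOVA for a balanced layout.

    Returns dict effect -> (F, p).  For balanced data this coincides
    with type II sums of squares.
    """
    y = df[value].to_numpy(dtype=float)
    grand = y.mean()
    a_levels = sorted(df[fa].unique())
    b_levels = sorted(df[fb].unique())
    a, b = len(a_levels), len(b_levels)
    n = len(df) // (a * b)
    ssa = sum(b * n * (df.loc[df[fa] == la, value].mean() - grand) ** 2
              for la in a_levels)
    ssb = sum(a * n * (df.loc[df[fb] == lb, value].mean() - grand) ** 2
              for lb in b_levels)
    ssab = 0.0
    sse = 0.0
    for la in a_levels:
        for lb in b_levels:
            cell = df.loc[(df[fa] == la) & (df[fb] == lb), value]
            ma = df.loc[df[fa] == la, value].mean()
            mb = df.loc[df[fb] == lb, value].mean()
            ssab += n * (cell.mean() - ma - mb + grand) ** 2
            sse += ((cell - cell.mean()) ** 2).sum()
    dfa, dfb = a - 1, b - 1
    dfab = dfa * dfb
    dfe = a * b * (n - 1)
    out = {}
    for name, ss, d in (("cultivar", ssa, dfa), ("treatment", ssb, dfb),
                        ("cultivar:treatment", ssab, dfab)):
        F = (ss / d) / (sse / dfe)
        out[name] = (F, stats.f.sf(F, d, dfe))
    return out


@pytest.fixture
def two_group_panel():
    """Zero-noise bundle with a planted 8-fold signature: two clean groups."""
    import aostress as a
    from aostress.normalize import normalize_cascade
    cfg = a.MetaSimConfig(
        n_experiments=2, n_genes=8, n_control_reps=[4, 4],
        n_stress_reps=[4, 4], platform_per_experiment=["intensity"] * 2,
        stress_type_per_experiment=["cold", "cold"],
        replicate_noise_sd=0.0, batch_scale_sd=0.0, signature_jitter_sd=0.0,
        count_dispersion=0.0,
        signature_fold={"cold": {1: 8.0, 2: 8.0, 3: 8.0}},
        seed=7)
    studies, truth = a.generate_meta_experiments(cfg)
    return normalize_cascade(studies), truth
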