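"""Synthetic multi-experiment expression data and qPCR plates.

The meta-analysis pipeline was designed around pooled public stress
experiments (mixed microarray / RNA-seq platforms, heterogeneous batch
scales, a shared antioxidant gene panel).  :func:`generate_meta_experiments`
emulates that structure with known ground truth: per-experiment batch
scales, planted per-stress-type fold-change signatures, a housekeeping
gene that tracks only the per-sample scale, and an optional fraction of
"noisy" experiments whose stress replicates carry no signature at all —
the failure mode the clustering-based QC filter is meant to catch.

:func:`generate_qpcr_plate` emulates a 96-well real-time PCR run:
four-parameter-logistic amplification curves with an exponential early
phase F(c) ~ N0 * E^c, planted per-amplicon efficiencies and expression
ratios, and replicate noise applied on the Cq (cycle) scale.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import ENZYME_CLASSES, ExpressionStudy, QpcrPlate, ValidationError

# ---------------------------------------------------------------------------
# meta-analysis simulation


def _default_rep_counts(n_experiments: int) -> tuple[list[int], list[int]]:
    """Replicate counts matching the pooled-sample shape the pipeline targets.

    For 13 experiments this yields 70 control + 130 stress replicates in
    total; other experiment counts get 5-6 controls and 10 stress each.
    """
    controls = [6 if i < 5 else 5 for i in range(n_experiments)]
    if n_experiments == 13:
        assert sum(controls) == 70
    stress = [10] * n_experiments
    return controls, stress


def default_signatures(n_genes: int, housekeeping_index: int = 0,
                       up_fold: float = 5.0, down_fold: float = 0.2
                       ) -> dict[str, dict[int, float]]:
    """Planted fold-change maps per stress type.

    Eight up- and eight down-regulated genes per stress type (disjoint
    between the two stress types where the panel is large enough), the
    rest null.  The housekeeping gene is always null.
    """
    idx = [i for i in range(n_genes) if i != housekeeping_index]
    quarters = [idx[i::4] for i in range(4)]
    sig: dict[str, dict[int, float]] = {"cold": {}, "water_deficiency": {}}
    for g in quarters[0][:8]:
        sig["cold"][g] = up_fold
    for g in quarters[1][:8]:
        sig["cold"][g] = down_fold
    for g in quarters[2][:8]:
        sig["water_deficiency"][g] = up_fold
    for g in quarters[3][:8]:
        sig["water_deficiency"][g] = down_fold
    return sig


@dataclass
class MetaSimConfig:
    """Study conditions for the multi-experiment generator.

    Defaults mirror the pooled sample the meta-analysis retains: 13
    experiments, 35 panel genes, 70 control + 130 stress replicates,
    mixed count/intensity platforms, batch scale sd 1 log2 unit,
    replicate noise sd 0.25 log2 units.
    """

    n_experiments: int = 13
    n_genes: int = 35
    n_control_reps: Optional[Sequence[int]] = None
    n_stress_reps: Optional[Sequence[int]] = None
    platform_per_experiment: Optional[Sequence[str]] = None
    stress_type_per_experiment: Optional[Sequence[str]] = None
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5
    batch_scale_sd: float = 1.0
    replicate_noise_sd: float = 0.25
    signature_fold: Optional[Mapping[str, Mapping[int, float]]] = None
    signature_jitter_sd: float = 0.1
    count_dispersion: float = 0.1
    gene_lengths: Optional[Sequence[float]] = None
    library_size_mean: float = 1.0e6
    housekeeping_index: int = 0
    noisy_fraction: float = 0.0
    seed: int = 0

    def resolved(self) -> "MetaSimConfig":
        """Fill derived defaults and validate."""
        cfg = dataclasses.replace(self)
        if cfg.n_experiments < 1 or cfg.n_genes < 2:
            raise ValidationError("need >=1 experiment and >=2 genes")
        ctrl, strs = _default_rep_counts(cfg.n_experiments)
        if cfg.n_control_reps is None:
            cfg.n_control_reps = ctrl
        if cfg.n_stress_reps is None:
            cfg.n_stress_reps = strs
        for n in cfg.n_control_reps:
            if n < 2:
                raise ValidationError(
                    "every experiment needs >=2 control replicates "
                    "(control mean and t-test require it)"
                )
        for n in cfg.n_stress_reps:
            if n < 1:
                raise ValidationError("replicate counts must be >=1")
        if cfg.platform_per_experiment is None:
            cfg.platform_per_experiment = [
                "counts" if i % 2 == 0 else "intensity"
                for i in range(cfg.n_experiments)
            ]
        if cfg.stress_type_per_experiment is None:
            cfg.stress_type_per_experiment = [
                "cold" if i % 2 == 0 else "water_deficiency"
                for i in range(cfg.n_experiments)
            ]
        if cfg.signature_fold is None:
            cfg.signature_fold = default_signatures(
                cfg.n_genes, cfg.housekeeping_index)
        for st, folds in cfg.signature_fold.items():
            for g, f in folds.items():
                if f <= 0:
                    raise ValidationError(f"signature fold for gene {g} "
                                          f"({st}) must be > 0, got {f}")
                if g == cfg.housekeeping_index and f != 1.0:
                    raise ValidationError(
                        "housekeeping gene's true fold must be 1")
        if cfg.gene_lengths is None:
            cfg.gene_lengths = [800.0 + 120.0 * (i % 17)
                                for i in range(cfg.n_genes)]
        if not 0.0 <= cfg.noisy_fraction <= 1.0:
            raise ValidationError("noisy_fraction must be in [0, 1]")
        return cfg


@dataclass
class MetaGroundTruth:
    """Planted truth for a simulated experiment bundle."""

    signature_fold: dict[str, dict[int, float]]
    noisy_experiments: list[str]
    stress_type: dict[str, str]
    replicate_condition: dict[str, str]  # "exp:sample" -> control/stress
    gene_ids: list[str]
    housekeeping_gene: str
    seed: int

    def regulated_sets(self, stress_type: str) -> tuple[set[str], set[str]]:
        """Planted (up, down) gene-id sets for one stress type."""
        folds = self.signature_fold.get(stress_type, {})
        up = {self.gene_ids[g] for g, f in folds.items() if f > 1}
        down = {self.gene_ids[g] for g, f in folds.items() if f < 1}
        return up, down

    def to_json(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["signature_fold"] = {
            st: {str(g): f for g, f in folds.items()}
            for st, folds in self.signature_fold.items()
        }
        Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))


_CLASS_CLADES = ("A", "B", "C", "D", "E", "F")


def _gene_table(cfg: MetaSimConfig) -> pd.DataFrame:
    ids, classes, clades, hk = [], [], [], []
    for i in range(cfg.n_genes):
        if i == cfg.housekeeping_index:
            ids.append("UBQ_HK")
            classes.append("other")
            clades.append("housekeeping")
            hk.append(True)
        else:
            cls = ENZYME_CLASSES[i % 7]
            clade = _CLASS_CLADES[(i // 7) % len(_CLASS_CLADES)]
            ids.append(f"{cls}_{clade}_{i:02d}")
            classes.append(cls)
            clades.append(f"{cls} {clade}")
            hk.append(False)
    return pd.DataFrame(
        {"enzyme_class": classes, "clade": clades, "housekeeping": hk,
         "length": list(cfg.gene_lengths)},
        index=pd.Index(ids, name="gene_id"),
    )


def generate_meta_experiments(config: MetaSimConfig
                              ) -> tuple[list[ExpressionStudy], MetaGroundTruth]:
    """Simulate a bundle of stress experiments with known ground truth.

    Each replicate's expected log2 expression is
    ``baseline(gene) + batch(experiment) + scale(replicate)
    + planted log2 fold (stress replicates of non-noisy experiments)
    + N(0, replicate_noise_sd)``;
    the housekeeping gene receives neither fold nor replicate noise, so it
    tracks exactly the per-sample scale the normalization cascade removes.
    Count platforms then draw negative-binomial counts around
    ``mu * length * library_size / 1e9`` (``count_dispersion = 0`` emits
    rounded expected counts, a noiseless mode used by exactness tests);
    intensity platforms emit the log-normal values directly.
    """
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_table(cfg)
    gene_ids = list(genes.index)
    hk = cfg.housekeeping_index

    n_noisy = int(round(cfg.noisy_fraction * cfg.n_experiments))
    noisy = set(rng.choice(cfg.n_experiments, size=n_noisy, replace=False).tolist())

    log2_folds = {
        st: np.array([np.log2(folds.get(g, 1.0)) for g in range(cfg.n_genes)])
        for st, folds in cfg.signature_fold.items()
    }

    studies: list[ExpressionStudy] = []
    replicate_condition: dict[str, str] = {}
    stress_type_of: dict[str, str] = {}
    lengths = np.asarray(cfg.gene_lengths, dtype=float)

    for e in range(cfg.n_experiments):
        exp_id = f"SIM{e:03d}"
        platform = cfg.platform_per_experiment[e]
        st = cfg.stress_type_per_experiment[e]
        stress_type_of[exp_id] = st
        n_c = int(cfg.n_control_reps[e])
        n_s = int(cfg.n_stress_reps[e])

        baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd,
                              cfg.n_genes)
        # reference genes are picked for abundance: fixed high baseline
        baseline[hk] = cfg.baseline_log2_mean + 6.0
        batch = rng.normal(0.0, cfg.batch_scale_sd)
        jitter = rng.normal(0.0, cfg.signature_jitter_sd, cfg.n_genes)
        fold = np.zeros(cfg.n_genes)
        if e not in noisy:
            base = log2_folds.get(st, np.zeros(cfg.n_genes))
            fold = np.where(base != 0.0, base + jitter, 0.0)
        fold[hk] = 0.0

        cols, data = [], []
        conditions = ["control"] * n_c + ["stress"] * n_s
        for s, cond in enumerate(conditions):
            sample_id = f"S{s:02d}"
            rep_scale = rng.normal(0.0, cfg.batch_scale_sd / 2.0)
            noise = rng.normal(0.0, cfg.replicate_noise_sd, cfg.n_genes)
            noise[hk] = 0.0
            log2_mu = baseline + batch + rep_scale + noise
            if cond == "stress":
                log2_mu = log2_mu + fold
            mu = np.exp2(log2_mu)
            if platform == "counts":
                lib = cfg.library_size_mean * np.exp2(
                    rng.normal(0.0, cfg.batch_scale_sd / 2.0))
                expected = mu * lengths * lib / 1.0e9
                if cfg.count_dispersion > 0:
                    n_param = 1.0 / cfg.count_dispersion
                    p_param = n_param / (n_param + expected)
                    values = rng.negative_binomial(n_param, p_param).astype(float)
                    # the reference gene tracks the per-sample scale only:
                    # no counting noise, or dividing by it would re-inject
                    # a shared per-replicate error into every other gene
                    values[hk] = np.rint(expected[hk])
                else:
                    values = np.rint(expected)
            else:
                values = mu
            cols.append(sample_id)
            data.append(values)
            replicate_condition[f"{exp_id}:{sample_id}"] = cond

        matrix = pd.DataFrame(np.column_stack(data), index=genes.index,
                              columns=cols)
        samples = pd.DataFrame(
            {
                "condition": conditions,
                "stress_type": [st if c == "stress" else "none"
                                for c in conditions],
                "tissue": "shoot",
                "time_point": "24h",
            },
            index=pd.Index(cols, name="sample_id"),
        )
        studies.append(ExpressionStudy(exp_id, platform, matrix, samples,
                                       genes.copy()))

    truth = MetaGroundTruth(
        signature_fold={st: dict(f) for st, f in cfg.signature_fold.items()},
        noisy_experiments=sorted(f"SIM{e:03d}" for e in noisy),
        stress_type=stress_type_of,
        replicate_condition=replicate_condition,
        gene_ids=gene_ids,
        housekeeping_gene=gene_ids[hk],
        seed=cfg.seed,
    )
    return studies, truth


def write_meta_experiments(studies: Sequence[ExpressionStudy],
                           out_dir: str | Path) -> None:
    """One TSV matrix per experiment plus shared samples/genes sheets."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sample_rows = []
    for study in studies:
        study.matrix.to_csv(out / f"{study.experiment_id}.matrix.tsv", sep="\t")
        sheet = study.samples.copy()
        sheet.insert(0, "experiment_id", study.experiment_id)
        sheet.insert(1, "platform", study.platform)
        sample_rows.append(sheet)
    pd.concat(sample_rows).to_csv(out / "samples.tsv", sep="\t")
    studies[0].genes.to_csv(out / "genes.tsv", sep="\t")


# ---------------------------------------------------------------------------
# qPCR simulation


@dataclass
class QpcrSimConfig:
    """Study conditions for the qPCR plate generator.

    Defaults follow the experimental design the quantification targets:
    three biological x three technical replicates per group, 45 cycles,
    two cultivars, cold treatments at two time points against a control,
    one reference amplicon shared by all samples.
    """

    targets: Sequence[str] = ("CAT_B", "SOD_A")
    treatments: Sequence[str] = ("control", "cold_6h", "cold_24h")
    cultivars: Sequence[str] = ("S29", "YP")
    true_ratio: Optional[Mapping[str, Mapping[str, float]]] = None
    true_efficiency: Optional[Mapping[str, float]] = None
    reference_target: str = "UBQ"
    reference_efficiency: float = 2.0
    n_bio: int = 3
    n_tech: int = 3
    cq_noise_sd: float = 0.2
    baseline_fluorescence: float = 0.05
    plateau: float = 10.0
    template_proxy: float = 1.0e-7  # initial-template fluorescence equivalent
    n_cycles: int = 45
    mode: str = "curves"  # or "cq"
    include_ntc: bool = True
    seed: int = 0

    def resolved(self) -> "QpcrSimConfig":
        cfg = dataclasses.replace(self)
        if cfg.n_cycles < 30:
            raise ValidationError("n_cycles must be >= 30")
        if cfg.n_bio < 1 or cfg.n_tech < 1:
            raise ValidationError("replicate counts must be >= 1")
        if cfg.true_ratio is None:
            cfg.true_ratio = {
                "CAT_B": {"cold_6h": 4.0, "cold_24h": 6.0},
                "SOD_A": {"cold_6h": 0.65, "cold_24h": 0.45},
            }
        if cfg.true_efficiency is None:
            cfg.true_efficiency = {t: e for t, e in
                                   zip(cfg.targets, (1.9, 1.8, 2.0, 1.85))}
        for t in cfg.targets:
            e = cfg.true_efficiency.get(t)
            if e is None or not (1.0 < e <= 2.0):
                raise ValidationError(
                    f"true efficiency for {t} must be in (1, 2], got {e}")
        if not (1.0 < cfg.reference_efficiency <= 2.0):
            raise ValidationError("reference efficiency must be in (1, 2]")
        for t, ratios in cfg.true_ratio.items():
            for tr, r in ratios.items():
                if r <= 0:
                    raise ValidationError(
                        f"true ratio for {t}/{tr} must be > 0, got {r}")
        if cfg.mode not in ("curves", "cq"):
            raise ValidationError(f"unknown mode {cfg.mode!r}")
        return cfg


@dataclass
class QpcrGroundTruth:
    true_ratio: dict[str, dict[str, float]]
    true_efficiency: dict[str, float]
    reference_efficiency: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1,
                                         sort_keys=True))


def logistic_curve(cycles: np.ndarray, n0: float, efficiency: float,
                   plateau: float, baseline: float) -> np.ndarray:
    """Saturating amplification curve with an exact exponential early phase.

    F(c) = baseline + P * x / (1 + x) with x = n0 * E^c / P, so for
    x << 1 the baseline-corrected signal is ~ n0 * E^c.
    """
    x = n0 * efficiency ** cycles / plateau
    return baseline + plateau * x / (1.0 + x)


def _true_cq(n0: float, efficiency: float, threshold: float) -> float:
    return (np.log(threshold) - np.log(n0)) / np.log(efficiency)


def generate_qpcr_plate(config: QpcrSimConfig
                        ) -> tuple[QpcrPlate, QpcrGroundTruth]:
    """Simulate a plate with planted ratios and efficiencies.

    Replicate noise is applied on the cycle scale: each well's effective
    initial template is ``N0 * E^(-d)`` with ``d ~ N(0, cq_noise_sd)``,
    which shifts its Cq by exactly ``d`` cycles.  The reference amplicon's
    template is identical across treatments, so its Cq is independent of
    treatment in expectation.
    """
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed)
    cycles = np.arange(1, cfg.n_cycles + 1, dtype=float)
    threshold = 0.01 * cfg.plateau  # reporting threshold for cq mode

    rows = []
    curve_cols: dict[str, np.ndarray] = {}
    widx = 0

    def add_well(target: str, role: str, cultivar: str, treatment: str,
                 bio: int, tech: int, n0: float, eff: float,
                 shift: float) -> None:
        nonlocal widx
        well_id = f"W{widx:03d}"
        widx += 1
        n0_eff = n0 * eff ** (-shift)
        row = {"well_id": well_id, "target": target, "role": role,
               "cultivar": cultivar, "treatment": treatment,
               "bio_rep": bio, "tech_rep": tech}
        if cfg.mode == "curves":
            curve_cols[well_id] = logistic_curve(
                cycles, n0_eff, eff, cfg.plateau, cfg.baseline_fluorescence)
        else:
            row["cq"] = _true_cq(n0_eff, eff, threshold)
        rows.append(row)

    amplicons = [(t, "target", cfg.true_efficiency[t]) for t in cfg.targets]
    amplicons.append((cfg.reference_target, "reference",
                      cfg.reference_efficiency))

    for cultivar in cfg.cultivars:
        for treatment in cfg.treatments:
            for target, role, eff in amplicons:
                if role == "reference" or treatment == "control":
                    ratio = 1.0
                else:
                    ratio = cfg.true_ratio.get(target, {}).get(treatment, 1.0)
                n0 = cfg.template_proxy * ratio
                for bio in range(1, cfg.n_bio + 1):
                    for tech in range(1, cfg.n_tech + 1):
                        shift = rng.normal(0.0, cfg.cq_noise_sd) \
                            if cfg.cq_noise_sd > 0 else 0.0
                        add_well(target, role, cultivar, treatment,
                                 bio, tech, n0, eff, shift)

    if cfg.include_ntc and cfg.mode == "curves":
        for target, _, _ in amplicons:
            well_id = f"W{widx:03d}"
            widx += 1
            rows.append({"well_id": well_id, "target": target, "role": "ntc",
                         "cultivar": "none", "treatment": "control",
                         "bio_rep": 0, "tech_rep": 1})
            curve_cols[well_id] = np.full_like(cycles,
                                               cfg.baseline_fluorescence)

    wells = pd.DataFrame(rows)
    curves = None
    if cfg.mode == "curves":
        curves = pd.DataFrame(curve_cols,
                              index=pd.Index(cycles.astype(int), name="cycle"))
    plate = QpcrPlate(wells=wells, n_cycles=cfg.n_cycles, curves=curves)
    truth = QpcrGroundTruth(
        true_ratio={t: dict(r) for t, r in cfg.true_ratio.items()},
        true_efficiency=dict(cfg.true_efficiency),
        reference_efficiency=cfg.reference_efficiency,
        seed=cfg.seed,
    )
    return plate, truth


def write_qpcr_plate(plate: QpcrPlate, out_dir: str | Path) -> None:
    """Long-format TSV: wells sheet plus per-cycle fluorescence if present."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    plate.wells.to_csv(out / "wells.tsv", sep="\t", index=False)
    if plate.curves is not None:
        long = plate.curves.reset_index().melt(
            id_vars="cycle", var_name="well_id", value_name="fluorescence")
        long = long.merge(
            plate.wells[["well_id", "target", "cultivar", "treatment"]],
            on="well_id")
        long.to_csv(out / "curves.tsv", sep="\t", index=False)
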