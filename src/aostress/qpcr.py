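"""Amplification-curve analysis and efficiency-corrected quantification.

Per-well amplification efficiency and Cq are estimated from the raw
fluorescence curve by a window-of-linearity fit: after baseline
subtraction, a short window of consecutive cycles in the exponential
phase (where log fluorescence is maximally linear) is selected, the
baseline is refined to maximize that linearity, and the efficiency is
10^slope of the log10(F) vs cycle regression.  Cq is the fractional
cycle at which the fitted exponential crosses a threshold shared by all
wells of an amplicon.

Relative expression is the efficiency-corrected ratio

    ratio = E_target^dCq_target / E_reference^dCq_reference,

with dCq = mean control Cq - mean treated Cq for each gene, so a ratio
above 1 means higher expression under treatment.  Treatment effects on
dCq (= Cq_target - Cq_reference) are tested with a fixed-effects
two-way ANOVA (cultivar x treatment, type II sums of squares).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

import statsmodels.api as sm
import statsmodels.formula.api as smf

from .types import QpcrPlate, RatioEstimate, ValidationError

MIN_SLOPE = np.log10(1.05)  # reject windows ambiguously flat (E < 1.05)
WINDOW_SIZES = (6, 5, 4)


@dataclass
class EfficiencyFit:
    """Window-of-linearity fit for one well."""

    efficiency: float
    cq: float
    fit_quality: float  # R^2 of the log-linear window fit
    slope: float
    intercept: float
    baseline: float
    threshold: float
    window: tuple[int, int]  # first and last cycle of the window
    negative: bool = False

    def cq_at(self, threshold: float) -> float:
        """Fractional cycle where the fitted exponential crosses ``threshold``."""
        return (np.log10(threshold) - self.intercept) / self.slope


def _linfit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS slope, intercept, R^2."""
    xm, ym = x.mean(), y.mean()
    dx, dy = x - xm, y - ym
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    sxy = float(dx @ dy)
    slope = sxy / sxx
    intercept = ym - slope * xm
    r2 = 1.0 if syy == 0.0 else sxy * sxy / (sxx * syy)
    return slope, intercept, r2


def _candidate_windows(cycles: np.ndarray, corrected: np.ndarray,
                       top_k: int = 10
                       ) -> list[tuple[int, int, float, float, float]]:
    """Top candidate log-linear windows as (start, size, slope, intercept, r2).

    Candidates are ranked by the R^2 of the log10 fit at the provisional
    baseline; the final window is picked after per-window baseline
    refinement, since a poor provisional baseline distorts the ranking.
    """
    cands = []
    for w in WINDOW_SIZES:
        for start in range(len(cycles) - w + 1):
            seg = corrected[start:start + w]
            if (seg <= 0).any():
                continue
            slope, intercept, r2 = _linfit(cycles[start:start + w],
                                           np.log10(seg))
            if slope < MIN_SLOPE:
                continue
            cands.append((start, w, slope, intercept, r2))
    cands.sort(key=lambda c: -c[4])
    return cands[:top_k]


def estimate_efficiency(curve, n_cycles: int | None = None,
                        threshold: float | None = None) -> EfficiencyFit:
    """Estimate amplification efficiency and Cq from one fluorescence curve.

    The baseline is first set just below the curve minimum, the most
    log-linear 4-6-cycle window is located, and the baseline is then
    refined (bounded scalar search) to maximize the window's R^2 —
    a noiseless exponential curve is recovered exactly.  Efficiency is
    10^slope of the refined fit; Cq is the fractional threshold-crossing
    cycle, with the threshold defaulting to the geometric midpoint of the
    window's corrected fluorescence.  Flat curves (e.g. no-template
    controls) are flagged ``negative`` with NaN efficiency and Cq.
    """
    f = np.asarray(curve, dtype=float)
    if n_cycles is not None:
        f = f[:n_cycles]
    if len(f) < 15:
        raise ValidationError("curve must cover at least 15 cycles")
    cycles = np.arange(1, len(f) + 1, dtype=float)

    span = f.max() - f.min()
    if not np.isfinite(span) or f.max() <= 0 or span < 0.02 * abs(f.max()):
        return EfficiencyFit(np.nan, np.nan, 0.0, np.nan, np.nan,
                             float(f.min()), np.nan, (0, 0), negative=True)

    b0 = f.min() - 1.0e-6 * span
    candidates = _candidate_windows(cycles, f - b0)
    if not candidates or candidates[0][4] < 0.8:
        return EfficiencyFit(np.nan, np.nan, 0.0, np.nan, np.nan,
                             float(b0), np.nan, (0, 0), negative=True)

    # the baseline can never exceed the curve's global minimum; a larger
    # bound would let saturated windows fake log-linearity
    b_hi = float(f.min()) * (1.0 - 1.0e-9)

    def refine(start: int, w: int) -> tuple[float, float, float, float]:
        x = cycles[start:start + w]
        seg = f[start:start + w]

        def neg_r2(b: float) -> float:
            y = seg - b
            if (y <= 0).any():
                return np.inf
            return -_linfit(x, np.log10(y))[2]

        res = minimize_scalar(neg_r2, bounds=(0.0, max(b_hi, 1.0e-12)),
                              method="bounded",
                              options={"xatol": 1.0e-10})
        b = float(res.x) if np.isfinite(res.fun) else max(b0, 0.0)
        slope, intercept, r2 = _linfit(x, np.log10(seg - b))
        return b, slope, intercept, r2

    best = None
    for start_c, w_c, *_ in candidates:
        b_c, slope_c, intercept_c, r2_c = refine(start_c, w_c)
        if best is None or r2_c > best[5] + 1.0e-12:
            best = (start_c, w_c, b_c, slope_c, intercept_c, r2_c)
        if best[5] > 1.0 - 1.0e-8:  # an exact exponential window; done
            break
    start, w, b, slope, intercept, r2 = best

    corrected = f - b
    if threshold is None:
        threshold = float(np.sqrt(corrected[start] * corrected[start + w - 1]))
    cq = (np.log10(threshold) - intercept) / slope
    return EfficiencyFit(
        efficiency=float(10.0 ** slope),
        cq=float(cq),
        fit_quality=float(r2),
        slope=float(slope),
        intercept=float(intercept),
        baseline=float(b),
        threshold=float(threshold),
        window=(start + 1, start + w),
    )


def pfaffl_ratio(e_target: float, dcq_target: float,
                 e_reference: float, dcq_reference: float) -> float:
    """Efficiency-corrected relative expression ratio.

    ratio = e_target^dcq_target / e_reference^dcq_reference, where each
    dCq is mean control Cq minus mean treated Cq for that gene.  With
    both efficiencies equal to 2 this reduces to the classical
    2^-ddCq form.
    """
    for e in (e_target, e_reference):
        if e <= 0:
            raise ValidationError(f"efficiency must be positive, got {e}")
        if e <= 1.0:
            raise ValidationError(f"efficiency must exceed 1, got {e}")
    if not (np.isfinite(dcq_target) and np.isfinite(dcq_reference)):
        raise ValidationError("dCq must be finite")
    return float(e_target ** dcq_target / e_reference ** dcq_reference)


def fit_wells(plate: QpcrPlate) -> pd.DataFrame:
    """Window-of-linearity fits for every non-NTC well of a curve plate."""
    if not plate.has_curves:
        raise ValidationError("plate carries no amplification curves")
    rows = []
    for _, well in plate.wells.iterrows():
        if well["role"] == "ntc":
            continue
        fit = estimate_efficiency(plate.curves[well["well_id"]].to_numpy(),
                                  plate.n_cycles)
        rows.append({"well_id": well["well_id"], "target": well["target"],
                     "role": well["role"], "cultivar": well["cultivar"],
                     "treatment": well["treatment"],
                     "bio_rep": well["bio_rep"], "tech_rep": well["tech_rep"],
                     "efficiency": fit.efficiency, "cq": fit.cq,
                     "fit_quality": fit.fit_quality, "slope": fit.slope,
                     "intercept": fit.intercept,
                     "threshold": fit.threshold,
                     "negative": fit.negative})
    return pd.DataFrame(rows)


def well_cq_table(plate: QpcrPlate,
                  efficiencies: dict[str, float] | None = None
                  ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-well Cq values plus per-amplicon pooled efficiencies.

    Curve plates: efficiencies are per-amplicon means of per-well
    window-of-linearity estimates, and every well's Cq is recomputed at
    the amplicon's common threshold (geometric mean of the per-well
    window midpoints).  Cq-only plates require ``efficiencies`` (one per
    amplicon, reference included).
    """
    if plate.has_curves:
        fits = fit_wells(plate)
        bad = fits[fits["negative"]]
        if len(bad):
            raise ValidationError(
                f"non-NTC wells without amplification: "
                f"{list(bad['well_id'])}")
        eff = fits.groupby("target")["efficiency"].mean().to_dict()
        out = []
        for target, sub in fits.groupby("target"):
            common = float(np.exp(np.log(sub["threshold"]).mean()))
            cq = (np.log10(common) - sub["intercept"]) / sub["slope"]
            block = sub.copy()
            block["cq"] = cq
            out.append(block)
        table = pd.concat(out, ignore_index=True)
        return table[["target", "role", "cultivar", "treatment", "bio_rep",
                      "tech_rep", "cq"]], eff
    if efficiencies is None:
        raise ValidationError(
            "Cq-only plate: per-amplicon efficiencies must be supplied")
    table = plate.wells[plate.wells["role"] != "ntc"][
        ["target", "role", "cultivar", "treatment", "bio_rep", "tech_rep",
         "cq"]].copy()
    missing = set(table["target"]) - set(efficiencies)
    if missing:
        raise ValidationError(f"no efficiency supplied for {sorted(missing)}")
    return table, dict(efficiencies)


def bio_rep_cq(cq_table: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates into one Cq per biological replicate."""
    return (cq_table.groupby(["target", "role", "cultivar", "treatment",
                              "bio_rep"], sort=True)["cq"]
            .mean().reset_index())


def aggregate_ratios(plate: QpcrPlate,
                     efficiencies: dict[str, float] | None = None,
                     control_treatment: str = "control"
                     ) -> list[RatioEstimate]:
    """Efficiency-corrected expression ratios for every
    target x cultivar x treatment.

    Technical replicates are averaged into biological-replicate Cq
    values; MEAN_control and MEAN_treat are means over biological
    replicates; the control treatment's own ratio is 1 by construction.
    """
    cq_table, eff = well_cq_table(plate, efficiencies)
    bio = bio_rep_cq(cq_table)
    ref = plate.reference_target
    e_ref = eff[ref]

    means = (bio.groupby(["target", "cultivar", "treatment"], sort=True)
             ["cq"].agg(["mean", "size"]))
    estimates: list[RatioEstimate] = []
    targets = sorted(t for t in bio["target"].unique() if t != ref)
    for cultivar in sorted(bio["cultivar"].unique()):
        try:
            ref_ctrl = means.loc[(ref, cultivar, control_treatment), "mean"]
        except KeyError as exc:
            raise ValidationError(
                f"missing reference control wells for cultivar {cultivar}"
            ) from exc
        for target in targets:
            e_t = eff[target]
            try:
                t_ctrl = means.loc[(target, cultivar, control_treatment),
                                   "mean"]
            except KeyError as exc:
                raise ValidationError(
                    f"missing control biological replicates for "
                    f"{target}/{cultivar}") from exc
            sub = means.loc[(target, cultivar)]
            for treatment in sub.index:
                dcq_t = float(t_ctrl - means.loc[(target, cultivar,
                                                  treatment), "mean"])
                dcq_r = float(ref_ctrl - means.loc[(ref, cultivar, treatment),
                                                   "mean"])
                if treatment == control_treatment:
                    dcq_t = dcq_r = 0.0  # control vs itself
                estimates.append(RatioEstimate(
                    target=target, cultivar=cultivar, treatment=treatment,
                    ratio=pfaffl_ratio(e_t, dcq_t, e_ref, dcq_r),
                    e_target=float(e_t), e_reference=float(e_ref),
                    dcq_target=dcq_t, dcq_reference=dcq_r,
                    n_bio=int(means.loc[(target, cultivar, treatment),
                                        "size"]),
                ))
    return estimates


def ratios_frame(estimates: list[RatioEstimate]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in estimates])


def dcq_table(plate: QpcrPlate,
              efficiencies: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-sample dCq = Cq_target - Cq_reference, tech reps averaged."""
    cq, _ = well_cq_table(plate, efficiencies)
    bio = bio_rep_cq(cq)
    ref = plate.reference_target
    refs = bio[bio["target"] == ref].set_index(
        ["cultivar", "treatment", "bio_rep"])["cq"]
    rows = []
    for _, r in bio[bio["target"] != ref].iterrows():
        key = (r["cultivar"], r["treatment"], r["bio_rep"])
        if key not in refs.index:
            raise ValidationError(f"no reference Cq for sample {key}")
        rows.append({"target": r["target"], "cultivar": r["cultivar"],
                     "treatment": r["treatment"], "bio_rep": r["bio_rep"],
                     "dcq": r["cq"] - refs.loc[key]})
    return pd.DataFrame(rows)


def anova_dcq(dcq: pd.DataFrame) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA on dCq per gene (type II SS).

    Factors are cultivar and treatment; returns one row per
    gene x effect with sum_sq, df, F and p.  Both factors need at least
    two levels and every cell at least two replicates.
    """
    results = []
    for target, sub in dcq.groupby("target", sort=True):
        for factor in ("cultivar", "treatment"):
            if sub[factor].nunique() < 2:
                raise ValidationError(
                    f"{target}: factor {factor!r} has a single level")
        cell_sizes = sub.groupby(["cultivar", "treatment"]).size()
        if (cell_sizes < 2).any():
            raise ValidationError(
                f"{target}: every cultivar x treatment cell needs >=2 "
                "replicates")
        model = smf.ols("dcq ~ C(cultivar) * C(treatment)", data=sub).fit()
        table = sm.stats.anova_lm(model, typ=2)
        table = table.rename(index={
            "C(cultivar)": "cultivar",
            "C(treatment)": "treatment",
            "C(cultivar):C(treatment)": "cultivar:treatment",
            "Residual": "residual",
        })
        table.insert(0, "target", target)
        results.append(table.reset_index(names="effect"))
    return pd.concat(results, ignore_index=True)[
        ["target", "effect", "sum_sq", "df", "F", "PR(>F)"]
    ].rename(columns={"PR(>F)": "p"})
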