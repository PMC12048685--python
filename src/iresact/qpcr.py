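"""Ct-based quantification workflows.

All computations that start from qPCR quantification cycles (Ct): relative
levels by the 2^(-dCt) transform against a reference amplicon, RNase R
circular/linear enrichment ratios, no-RT background checks, serial-dilution
standard curves with absolute quantification, spike-in-normalized polysome
gradient distributions, and dual-luciferase reporter activity.

Tables are long-format pandas DataFrames with columns
``sample, amplicon, treatment, fraction, replicate, ct`` (see
:data:`CT_COLUMNS`); ``treatment`` is one of ``none``, ``rnaser``, ``no_rt``
and a missing Ct (NaN) encodes "undetermined". Replicates are aggregated as
the arithmetic mean of Cts, i.e. the geometric mean of linear levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CT_COLUMNS",
    "StandardCurve",
    "GradientProfile",
    "rel_quantity",
    "rnaser_enrichment",
    "no_rt_delta",
    "fit_standard_curve",
    "absolute_quantify",
    "polysome_distribution",
    "reporter_activity",
]

CT_COLUMNS = ["sample", "amplicon", "treatment", "fraction", "replicate", "ct"]

#: Default instrument ceiling used when a no-RT control is undetermined.
MAX_CYCLES = 40.0


def rel_quantity(ct: float, ref_ct: float) -> float:
    """Relative level 2^(-(ct - ref_ct)) of an amplicon vs a reference amplicon.

    One cycle earlier than the reference means twice the template. Returns NaN
    (propagating "undetermined") if either Ct is missing.
    """
    if ct is None or ref_ct is None or math.isnan(ct) or math.isnan(ref_ct):
        return float("nan")
    return float(2.0 ** (-(ct - ref_ct)))


def _mean_ct(df: pd.DataFrame) -> float:
    """Replicate aggregation: arithmetic mean of Cts (geometric mean of levels)."""
    cts = df["ct"].dropna()
    if cts.empty:
        return float("nan")
    return float(cts.mean())


def rnaser_enrichment(
    table: pd.DataFrame,
    circ_amplicons: list[str],
    linear_amplicons: list[str],
    ref_amplicon: str,
) -> pd.DataFrame:
    """Circular/linear RNase R enrichment report, one row per sample.

    Within each treatment arm (untreated ``none`` vs ``rnaser``), each
    amplicon's level is 2^(-dCt) against the reference amplicon of the same
    arm. The enrichment of an amplicon class is its level after digestion
    divided by its level before; because RNase R degrades linear RNAs but
    spares circles, the circ/linear ratio

        (circ level +RNaseR / circ level -RNaseR)
        -----------------------------------------
        (lin  level +RNaseR / lin  level -RNaseR)

    measures how strongly the circle resists digestion relative to its
    linear counterpart. With noiseless decay factors d_lin and d_circ this
    ratio equals d_lin / d_circ regardless of the reference's own decay.

    Samples lacking a matched +/- RNase R pair are skipped with a warning
    column rather than raising.
    """
    rows = []
    for sample, sdf in table.groupby("sample", sort=False):
        row: dict[str, object] = {"sample": sample, "warning": ""}
        levels: dict[tuple[str, str], float] = {}
        ok = True
        for treatment in ("none", "rnaser"):
            tdf = sdf[sdf["treatment"] == treatment]
            ref_ct = _mean_ct(tdf[tdf["amplicon"] == ref_amplicon])
            if math.isnan(ref_ct):
                row["warning"] = f"missing reference amplicon for treatment {treatment!r}"
                ok = False
                break
            for amp in list(circ_amplicons) + list(linear_amplicons):
                ct = _mean_ct(tdf[tdf["amplicon"] == amp])
                levels[(amp, treatment)] = rel_quantity(ct, ref_ct)
        if not ok:
            rows.append(row)
            continue

        def class_enrichment(amps: list[str]) -> float:
            enr = []
            for amp in amps:
                before = levels[(amp, "none")]
                after = levels[(amp, "rnaser")]
                if math.isnan(before) or math.isnan(after) or before == 0:
                    continue
                enr.append(after / before)
            if not enr:
                return float("nan")
            # geometric mean across amplicons of the same class
            return float(np.exp(np.mean(np.log(enr))))

        circ_enr = class_enrichment(list(circ_amplicons))
        lin_enr = class_enrichment(list(linear_amplicons))
        if math.isnan(circ_enr) or math.isnan(lin_enr):
            row["warning"] = "missing +/-RNase R pair for circ or linear amplicon"
            rows.append(row)
            continue
        row.update(
            circ_enrichment=circ_enr,
            linear_enrichment=lin_enr,
            circ_linear_ratio=circ_enr / lin_enr,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def no_rt_delta(table: pd.DataFrame, max_cycles: float = MAX_CYCLES) -> pd.DataFrame:
    """Per-amplicon dCt between the no-RT control and the reverse-transcribed sample.

    dCt = Ct(no-RT) - Ct(sample), computed per replicate then averaged with
    SD. Large positive values mean the signal requires reverse transcription,
    i.e. it comes from RNA and not from residual DNA template. An
    undetermined no-RT Ct is replaced by the instrument ceiling
    ``max_cycles`` and the row flagged, so the reported dCt is then a lower
    bound.
    """
    rows = []
    for (sample, amplicon), adf in table.groupby(["sample", "amplicon"], sort=False):
        sample_cts = adf[adf["treatment"] == "none"].set_index("replicate")["ct"]
        nort_cts = adf[adf["treatment"] == "no_rt"].set_index("replicate")["ct"]
        if sample_cts.empty or nort_cts.empty:
            continue
        deltas = []
        ceiling_used = False
        for rep, ct in sample_cts.items():
            if math.isnan(ct):
                continue
            nort = nort_cts.get(rep, float("nan"))
            if math.isnan(nort):
                nort = max_cycles
                ceiling_used = True
            deltas.append(nort - ct)
        if not deltas:
            continue
        arr = np.asarray(deltas, dtype=float)
        rows.append(
            {
                "sample": sample,
                "amplicon": amplicon,
                "delta_ct_mean": float(arr.mean()),
                "delta_ct_sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                "n": int(arr.size),
                "ceiling_used": ceiling_used,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line Ct vs log10(starting quantity) for one amplicon.

    ``efficiency`` is the per-cycle amplification factor 10^(-1/slope); a
    perfect doubling assay gives slope -1/log10(2) = -3.3219 and efficiency
    2.0. Curves with efficiency outside [1.8, 2.1] carry a warning.
    """

    amplicon: str
    slope: float
    intercept: float
    efficiency: float
    r_squared: float
    quantity_range: tuple[float, float]
    warning: str = ""


def fit_standard_curve(
    dilution_cts: list[tuple[float, float]], amplicon: str = ""
) -> StandardCurve:
    """Fit a standard curve from (starting quantity, Ct) pairs of a dilution series.

    Requires at least three distinct positive quantities. The fit is ordinary
    least squares of Ct on log10(quantity).
    """
    pairs = [(q, ct) for q, ct in dilution_cts if not math.isnan(ct)]
    if any(q <= 0 for q, _ in pairs):
        raise ValueError("quantities must be positive")
    if len({q for q, _ in pairs}) < 3:
        raise ValueError("need at least 3 distinct quantities for a standard curve")
    log_q = np.log10([q for q, _ in pairs])
    cts = np.asarray([ct for _, ct in pairs], dtype=float)
    fit = stats.linregress(log_q, cts)
    slope = float(fit.slope)
    if slope >= 0:
        raise ValueError("standard curve slope must be negative (more template, lower Ct)")
    efficiency = float(10.0 ** (-1.0 / slope))
    warning = ""
    if not (1.8 <= efficiency <= 2.1):
        warning = f"efficiency {efficiency:.3f} outside [1.8, 2.1]"
    qs = [q for q, _ in pairs]
    return StandardCurve(
        amplicon=amplicon,
        slope=slope,
        intercept=float(fit.intercept),
        efficiency=efficiency,
        r_squared=float(fit.rvalue) ** 2,
        quantity_range=(min(qs), max(qs)),
        warning=warning,
    )


def absolute_quantify(ct: float, curve: StandardCurve) -> tuple[float, bool]:
    """Starting quantity 10^((ct - intercept)/slope) from a fitted standard curve.

    Returns ``(quantity, extrapolated)``; ``extrapolated`` is True when the
    quantity falls outside the range the curve was fitted on. Missing Ct
    yields NaN.
    """
    if ct is None or math.isnan(ct):
        return float("nan"), False
    quantity = float(10.0 ** ((ct - curve.intercept) / curve.slope))
    lo, hi = curve.quantity_range
    # round-off guard so standards at the curve boundary are not flagged
    return quantity, not (lo * (1 - 1e-9) <= quantity <= hi * (1 + 1e-9))


@dataclass
class GradientProfile:
    """Distribution of one amplicon's mRNA across sucrose-gradient fractions.

    ``abundance`` is the spike-in-normalized linear level per fraction,
    renormalized to sum to 1 (fraction of total mRNA). ``portion_map``
    groups fractions into named gradient portions (free mRNP, 40S/60S, 80S,
    light polysome, heavy polysome); ``portion_totals`` sums the
    distribution within each portion and ``peak_portion`` is the argmax.
    """

    amplicon: str
    fractions: list[int]
    abundance: np.ndarray
    portion_map: dict[int, str] = field(default_factory=dict)

    @property
    def portion_totals(self) -> dict[str, float]:
        totals: dict[str, float] = {}
        for frac, level in zip(self.fractions, self.abundance):
            portion = self.portion_map.get(frac, f"fraction {frac}")
            totals[portion] = totals.get(portion, 0.0) + float(level)
        return totals

    @property
    def peak_portion(self) -> str:
        totals = self.portion_totals
        return max(totals, key=totals.get)  # type: ignore[arg-type]


def polysome_distribution(
    table: pd.DataFrame,
    spike_amplicon: str,
    portion_map: dict[int, str] | None = None,
) -> dict[str, GradientProfile]:
    """Spike-in-normalized fraction-of-total distribution per amplicon.

    Per fraction, the amplicon Ct is first normalized to the Ct of the
    exogenous spike-in RNA added in equal amount to every fraction (this
    cancels fraction-to-fraction differences in recovery and RT efficiency),
    converted from the log2 Ct scale to a linear level 2^(-dCt), and then
    normalized to the summed level across all fractions. Adding any constant
    to all spike Cts therefore leaves the distribution unchanged.

    Amplicons with a missing spike-in Ct in any of their fractions are
    rejected (omitted from the result).
    """
    portion_map = portion_map or {}
    gdf = table[table["fraction"].notna()]
    spike = (
        gdf[gdf["amplicon"] == spike_amplicon]
        .groupby("fraction")["ct"]
        .mean()
    )
    profiles: dict[str, GradientProfile] = {}
    for amplicon, adf in gdf.groupby("amplicon", sort=False):
        if amplicon == spike_amplicon:
            continue
        per_fraction = adf.groupby("fraction")["ct"].mean()
        fractions = sorted(int(f) for f in per_fraction.index)
        levels = []
        ok = True
        for frac in fractions:
            spike_ct = spike.get(frac, float("nan"))
            amp_ct = per_fraction.loc[frac]
            if math.isnan(spike_ct) or math.isnan(amp_ct):
                ok = False
                break
            levels.append(rel_quantity(amp_ct, spike_ct))
        if not ok:
            continue
        arr = np.asarray(levels, dtype=float)
        total = arr.sum()
        if total <= 0:
            continue
        profiles[amplicon] = GradientProfile(
            amplicon=amplicon,
            fractions=fractions,
            abundance=arr / total,
            portion_map=dict(portion_map),
        )
    return profiles


def reporter_activity(
    nluc: "float | np.ndarray | dict[str, float]",
    fluc: "float | np.ndarray | dict[str, float]",
    mrna_ratio: "float | np.ndarray | dict[str, float] | None" = None,
    reference: str | None = None,
):
    """Dual-luciferase activity Nluc/Fluc, optionally mRNA-normalized.

    Nluc is the cap-independent readout, Fluc the co-transfected
    cap-dependent control; dividing by an mRNA ratio (reporter mRNA over a
    housekeeping mRNA) converts activity per cell to activity per
    transcript. With dict inputs keyed by construct and a ``reference``
    construct given, all activities are scaled so the reference equals 1.
    """
    if isinstance(nluc, dict):
        if not isinstance(fluc, dict):
            raise TypeError("nluc and fluc must both be dicts or both array-like")
        acts = {}
        for name in nluc:
            ratio = None if mrna_ratio is None else mrna_ratio[name]
            acts[name] = reporter_activity(nluc[name], fluc[name], ratio)
        if reference is not None:
            ref = acts[reference]
            if ref == 0:
                raise ValueError("reference activity is zero")
            acts = {k: v / ref for k, v in acts.items()}
        return acts
    fluc_arr = np.asarray(fluc, dtype=float)
    if np.any(fluc_arr <= 0):
        raise ValueError("fluc must be positive")
    activity = np.asarray(nluc, dtype=float) / fluc_arr
    if mrna_ratio is not None:
        ratio = np.asarray(mrna_ratio, dtype=float)
        if np.any(ratio <= 0):
            raise ValueError("mrna_ratio must be positive")
        activity = activity / ratio
    if activity.ndim == 0:
        return float(activity)
    return activity
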