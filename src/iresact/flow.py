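"""circRNA-reporter flow-cytometry quantification.

Per-event tables carry forward/side scatter (FSC-A, FSC-H, SSC-A) and two
fluorescence channels: mRuby, translated cap-dependently from the linear
reporter mRNA (transfection control), and EGFP, translated only from the
backspliced circRNA via the inserted IRES (activity readout).

The analysis chain mirrors a standard manual gating scheme: (1) QC exclusion
of events acquired during instrument anomalies such as clogs, (2) a
viable-cell gate (robust ellipse on log scatter, excluding a low-FSC debris
floor), (3) a singlet gate on the FSC-H/FSC-A ratio, (4) an mRuby-positive
gate thresholded on a control sample, (5) the median EGFP fluorescence
intensity (MFI) of the mRuby+ subfraction, and (6) fold activity normalized
to the empty-vector control with replicate statistics and a Welch two-tailed
t-test.

Gate masks are nested by construction: mruby_pos ⊆ singlet ⊆ viable ⊆ qc_pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EVENT_COLUMNS",
    "GateParams",
    "GateChain",
    "ActivityResult",
    "qc_exclude",
    "gate_viable_singlets",
    "gate_mruby",
    "gate_chain",
    "egfp_mfi",
    "fold_activity",
    "significance_tier",
]

EVENT_COLUMNS = ["fsc_a", "fsc_h", "ssc_a", "mruby", "egfp"]


@dataclass(frozen=True)
class GateParams:
    """Gating geometry parameters.

    The viable gate is an ellipse on (log10 FSC-A, log10 SSC-A) centered at
    the channel medians with semi-axes ``k_mad`` local MADs, after removing
    events below ``debris_floor_fraction`` of the median FSC-A. The singlet
    gate keeps events whose FSC-H/FSC-A ratio lies within ``singlet_band``
    of the median ratio of viable events (doublets sit near half the
    ratio). ``mruby_percentile`` sets the positivity threshold on the
    control sample. ``rate_factor`` flags acquisition windows whose event
    rate deviates from the run median by more than this factor.
    """

    k_mad: float = 4.0
    debris_floor_fraction: float = 0.25
    singlet_band: float = 0.12
    mruby_percentile: float = 99.9
    rate_factor: float = 3.0
    rate_bins: int = 50
    min_events: int = 50


@dataclass
class GateChain:
    """Nested boolean masks and counts along the gating chain."""

    qc_pass: np.ndarray
    viable: np.ndarray
    singlet: np.ndarray
    mruby_pos: np.ndarray

    def __post_init__(self) -> None:
        if not (
            np.all(self.viable <= self.qc_pass)
            and np.all(self.singlet <= self.viable)
            and np.all(self.mruby_pos <= self.singlet)
        ):
            raise ValueError("gate masks must be nested: mruby_pos ⊆ singlet ⊆ viable ⊆ qc_pass")

    @property
    def counts(self) -> dict[str, int]:
        return {
            "total": int(self.qc_pass.size),
            "qc_pass": int(self.qc_pass.sum()),
            "viable": int(self.viable.sum()),
            "singlet": int(self.singlet.sum()),
            "mruby_pos": int(self.mruby_pos.sum()),
        }


def _validate(events: pd.DataFrame) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")


def qc_exclude(
    events: pd.DataFrame,
    params: GateParams | None = None,
    method: str = "both",
) -> np.ndarray:
    """QC pass mask: drop flagged events and anomalous-rate acquisition windows.

    With ``method`` "flag" (or "both"), events carrying an ``anomaly`` flag
    are excluded directly. With "rate" (or "both"), if a ``time_s`` column
    is present the acquisition is binned and whole bins whose event rate
    deviates from the run median by more than ``rate_factor`` (in either
    direction) are excluded — the signature of a clog is a rate excursion.
    Returns a boolean keep-mask.
    """
    if method not in ("flag", "rate", "both"):
        raise ValueError("method must be flag|rate|both")
    params = params or GateParams()
    n = len(events)
    keep = np.ones(n, dtype=bool)
    if n == 0:
        return keep
    if method in ("flag", "both") and "anomaly" in events.columns:
        keep &= ~events["anomaly"].to_numpy(dtype=bool)
    if method in ("rate", "both") and "time_s" in events.columns and n >= params.rate_bins * 4:
        t = events["time_s"].to_numpy(dtype=float)
        edges = np.linspace(t.min(), t.max() + 1e-9, params.rate_bins + 1)
        which = np.digitize(t, edges) - 1
        which = np.clip(which, 0, params.rate_bins - 1)
        counts = np.bincount(which, minlength=params.rate_bins)
        median_rate = np.median(counts[counts > 0])
        bad_bins = (counts > params.rate_factor * median_rate) | (
            (counts > 0) & (counts * params.rate_factor < median_rate)
        )
        keep &= ~bad_bins[which]
    return keep


def gate_viable_singlets(
    events: pd.DataFrame,
    params: GateParams | None = None,
    qc_pass: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Viable and singlet masks from scatter channels.

    Viable: inside a robust ellipse on (log10 FSC-A, log10 SSC-A) — center
    at the medians, semi-axes ``k_mad`` times the scaled MAD of qc-passing
    events — and above the debris floor (``debris_floor_fraction`` of median
    FSC-A). Small debris sits at low scatter and falls outside both.
    Singlet: viable events whose FSC-H/FSC-A ratio is within
    ``singlet_band`` of the viable-population median ratio; doublets have
    roughly double area for the same height, so their ratio is near half.
    Returns ``(viable, singlet)``, both nested within ``qc_pass``.
    """
    params = params or GateParams()
    _validate(events)
    n = len(events)
    if n < params.min_events:
        raise ValueError(f"need at least {params.min_events} events, got {n}")
    if qc_pass is None:
        qc_pass = qc_exclude(events, params)
    fsc = events["fsc_a"].to_numpy(dtype=float)
    ssc = events["ssc_a"].to_numpy(dtype=float)
    fsc_h = events["fsc_h"].to_numpy(dtype=float)
    if np.any(fsc[qc_pass] <= 0) or np.any(ssc[qc_pass] <= 0):
        raise ValueError("scatter channels must be positive for log gating")

    lf = np.log10(fsc)
    ls = np.log10(ssc)
    ref = qc_pass
    c_f, c_s = np.median(lf[ref]), np.median(ls[ref])
    # 1.4826 scales the MAD to an SD-equivalent for normal data
    mad_f = 1.4826 * np.median(np.abs(lf[ref] - c_f)) or 1e-6
    mad_s = 1.4826 * np.median(np.abs(ls[ref] - c_s)) or 1e-6
    r_f, r_s = params.k_mad * mad_f, params.k_mad * mad_s
    inside = ((lf - c_f) / r_f) ** 2 + ((ls - c_s) / r_s) ** 2 <= 1.0
    floor = params.debris_floor_fraction * np.median(fsc[ref])
    viable = qc_pass & inside & (fsc > floor)

    ratio = np.divide(fsc_h, fsc, out=np.zeros_like(fsc), where=fsc > 0)
    if viable.sum() == 0:
        return viable, viable.copy()
    med_ratio = np.median(ratio[viable])
    singlet = viable & (np.abs(ratio - med_ratio) <= params.singlet_band * med_ratio)
    return viable, singlet


def gate_mruby(
    events: pd.DataFrame,
    control_events: pd.DataFrame,
    q: float | None = None,
    params: GateParams | None = None,
    within: np.ndarray | None = None,
) -> np.ndarray:
    """mRuby-positive mask thresholded on a control sample.

    The threshold is the ``q``-th percentile (default 99.9) of mRuby among
    the control's viable singlets — the control being untransfected cells or
    the empty vector, whichever is designated. Events above threshold (and
    within ``within``, normally the singlet mask) are positive.
    """
    params = params or GateParams()
    if q is None:
        q = params.mruby_percentile
    if control_events is None or len(control_events) == 0:
        raise ValueError("control events are required to set the mRuby threshold")
    _, ctrl_singlet = gate_viable_singlets(control_events, params)
    ctrl_mruby = control_events["mruby"].to_numpy(dtype=float)[ctrl_singlet]
    if ctrl_mruby.size == 0:
        raise ValueError("control has no viable singlets to threshold on")
    threshold = np.percentile(ctrl_mruby, q)
    mask = events["mruby"].to_numpy(dtype=float) > threshold
    if within is not None:
        mask &= within
    return mask


def gate_chain(
    events: pd.DataFrame,
    control_events: pd.DataFrame,
    params: GateParams | None = None,
) -> GateChain:
    """Run the full QC → viable → singlet → mRuby+ chain on one sample."""
    params = params or GateParams()
    qc = qc_exclude(events, params)
    viable, singlet = gate_viable_singlets(events, params, qc_pass=qc)
    mruby = gate_mruby(events, control_events, params=params, within=singlet)
    return GateChain(qc_pass=qc, viable=viable, singlet=singlet, mruby_pos=mruby)


def egfp_mfi(events: pd.DataFrame, mask: np.ndarray) -> float:
    """Median EGFP fluorescence intensity of the masked (mRuby+) subfraction.

    Uses the standard median (mean-of-middle for even counts). An empty mask
    has no defined MFI and raises.
    """
    vals = events["egfp"].to_numpy(dtype=float)[np.asarray(mask, dtype=bool)]
    if vals.size == 0:
        raise ValueError("MFI undefined: mask selects no events")
    return float(np.median(vals))


def significance_tier(p: float) -> str:
    """Map a p-value to the conventional tier: ns / * / ** / *** / ****."""
    if np.isnan(p):
        return "ns"
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass
class ActivityResult:
    """Fold activity of one construct vs the empty-vector reference."""

    construct: str
    folds: np.ndarray            # per-replicate fold values
    mean: float
    sem: float
    n: int
    p_value: float
    tier: str
    timepoint_h: float | None = None
    comparator: str = ""


def fold_activity(
    mfis: dict[str, "list[float] | np.ndarray"],
    reference: str,
    comparator: str | None = None,
) -> list[ActivityResult]:
    """Empty-vector-normalized fold activity with replicate statistics.

    Each replicate MFI is divided by the mean reference MFI, so the
    reference construct's mean fold is exactly 1 and all folds are invariant
    to rescaling every MFI by a common positive factor. Constructs are
    compared to ``comparator`` (default: the reference) with a Welch
    two-tailed t-test on the replicate folds; p-values map onto the
    ns/*/**/***/**** tiers at 0.05/0.01/0.001/0.0001.
    """
    if reference not in mfis:
        raise ValueError(f"reference construct {reference!r} missing from MFI map")
    ref_vals = np.asarray(mfis[reference], dtype=float)
    if ref_vals.size == 0:
        raise ValueError("reference has no replicates")
    ref_mean = float(ref_vals.mean())
    if ref_mean == 0:
        raise ValueError("reference MFI mean is zero")
    comparator = comparator or reference
    folds_by_construct = {
        name: np.asarray(vals, dtype=float) / ref_mean for name, vals in mfis.items()
    }
    comp_folds = folds_by_construct[comparator]

    results = []
    for name, folds in folds_by_construct.items():
        n = int(folds.size)
        mean = float(folds.mean())
        sem = float(folds.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        if name == comparator:
            p = 1.0
        else:
            p = float(stats.ttest_ind(folds, comp_folds, equal_var=False).pvalue)
        results.append(
            ActivityResult(
                construct=name,
                folds=folds,
                mean=mean,
                sem=sem,
                n=n,
                p_value=p,
                tier=significance_tier(p),
                comparator=comparator,
            )
        )
    return results
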