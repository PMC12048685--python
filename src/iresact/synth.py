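"""Synthetic inputs with planted ground truth for every assay stage.

Three generators emulate the raw data the analysis modules consume:

* :func:`make_smfish_image` — two-channel smFISH images with
  diffraction-limited spots. A planted fraction of CDS spots carry an IRES
  spot displaced by at most one pixel, so colocalization-based isoform
  calling has an exact ground truth.
* :func:`make_facs_events` — cytometry event tables mixing debris, doublets
  and transfected/untransfected singlets, with EGFP scaled by a planted
  activity fold and an optional clog window of anomalous events.
* :func:`make_ct_table` — long-format Ct tables from true template
  quantities under a fixed amplification-efficiency model, with RNase R
  linear decay, no-RT leak-through, serial dilutions and gradient fractions
  with a spike-in channel.

Every generator draws from one ``numpy.random.default_rng(seed)`` per call;
identical truth objects give byte-identical outputs, and planted counts and
fractions are recoverable exactly from the returned truth metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .smfish import ImageStack
from .qpcr import CT_COLUMNS

__all__ = [
    "SmfishTruth",
    "FacsTruth",
    "QpcrTruth",
    "AssayDesign",
    "make_smfish_image",
    "make_facs_events",
    "make_ct_table",
    "smfish_preset",
    "facs_preset",
    "qpcr_preset",
    "DEFAULT_PORTION_MAP",
]


# ---------------------------------------------------------------------------
# smFISH images

@dataclass(frozen=True)
class SmfishTruth:
    """Planted ground truth for one synthetic smFISH image.

    ``long_fraction`` of the ``n_spots`` CDS spots receive an IRES partner
    spot whose center is displaced at most ``coloc_offset`` pixels (default
    1 px, so masks share pixels under any reasonable threshold). The number
    of colocalized pairs is ``round(long_fraction * n_spots)`` exactly.
    Centers are filled in by the generator under ``spot_centers_per_channel``.
    """

    n_spots: int = 40
    long_fraction: float = 0.5
    psf_sigma: float = 1.2          # px
    background_level: float = 100.0
    noise_sd: float = 5.0
    amplitude: float = 800.0        # median peak height above background
    amplitude_log_sd: float = 0.25
    neg_false_spots: int = 2
    image_shape: tuple[int, int] = (192, 192)
    min_separation: float = 8.0     # px between CDS centers
    coloc_offset: float = 1.0       # px max IRES displacement
    seed: int = 0
    spot_centers_per_channel: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.long_fraction <= 1.0):
            raise ValueError("long_fraction must be in [0, 1]")
        if self.n_spots < 0:
            raise ValueError("n_spots must be >= 0")
        if self.n_spots <= 0 and self.long_fraction > 0:
            raise ValueError("positive long_fraction requires positive n_spots")
        if min(self.image_shape) < 4 * self.psf_sigma:
            raise ValueError("image dimensions must be >= 4 * psf_sigma")

    @property
    def n_colocalized(self) -> int:
        return int(round(self.long_fraction * self.n_spots))


def _place_centers(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    margin: float,
    min_separation: float,
    max_attempts: int = 20000,
) -> np.ndarray:
    """Rejection-sample n centers with a minimum pairwise separation."""
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n:
        if attempts >= max_attempts:
            raise ValueError(
                f"could not place {n} spots with separation {min_separation} "
                f"in image {shape} within {max_attempts} attempts"
            )
        attempts += 1
        r = rng.uniform(margin, shape[0] - margin)
        c = rng.uniform(margin, shape[1] - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_separation**2 for r0, c0 in centers):
            centers.append((r, c))
    return np.asarray(centers, dtype=float).reshape(n, 2)


def _render(
    rng: np.random.Generator,
    shape: tuple[int, int],
    centers: np.ndarray,
    truth: SmfishTruth,
) -> np.ndarray:
    """Render isotropic Gaussian spots with log-normal amplitudes plus noise."""
    img = np.full(shape, truth.background_level, dtype=float)
    sigma = truth.psf_sigma
    half = int(math.ceil(4 * sigma))
    for r0, c0 in centers:
        amp = truth.amplitude * math.exp(rng.normal(0.0, truth.amplitude_log_sd))
        r_lo = max(0, int(r0) - half)
        r_hi = min(shape[0], int(r0) + half + 1)
        c_lo = max(0, int(c0) - half)
        c_hi = min(shape[1], int(c0) + half + 1)
        rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        img[r_lo:r_hi, c_lo:c_hi] += amp * np.exp(
            -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2)
        )
    if truth.noise_sd > 0:
        img += rng.normal(0.0, truth.noise_sd, size=shape)
    return np.clip(img, 0.0, None)


def make_smfish_image(
    truth: SmfishTruth,
    embryo_id: str = "",
    region_label: str = "",
) -> tuple[ImageStack, SmfishTruth]:
    """Generate a CDS/IRES/NEG image stack with planted colocalization.

    The first ``round(long_fraction * n_spots)`` CDS centers (in the order
    recorded in the truth metadata) receive an IRES spot displaced at most
    ``coloc_offset`` px. The negative-control channel contains only
    background plus ``neg_false_spots`` spurious spots. Identical truth
    (including seed) yields bit-identical images.
    """
    rng = np.random.default_rng(truth.seed)
    shape = truth.image_shape
    margin = max(4.0 * truth.psf_sigma, 2.0)
    cds_centers = _place_centers(
        rng, truth.n_spots, shape, margin, truth.min_separation
    )
    n_coloc = truth.n_colocalized
    order = rng.permutation(truth.n_spots)
    coloc_idx = order[:n_coloc]
    ires_centers = np.empty((n_coloc, 2), dtype=float)
    for j, i in enumerate(coloc_idx):
        angle = rng.uniform(0, 2 * math.pi)
        radius = truth.coloc_offset * math.sqrt(rng.uniform())
        ires_centers[j] = cds_centers[i] + [radius * math.cos(angle), radius * math.sin(angle)]
    neg_centers = _place_centers(
        rng, truth.neg_false_spots, shape, margin, truth.min_separation
    )

    channels = {
        "CDS": _render(rng, shape, cds_centers, truth),
        "IRES": _render(rng, shape, ires_centers, truth),
        "NEG": _render(rng, shape, neg_centers, truth),
    }
    stack = ImageStack(
        channels=channels, region_label=region_label, embryo_id=embryo_id
    )
    filled = replace(
        truth,
        spot_centers_per_channel={
            "CDS": [tuple(map(float, c)) for c in cds_centers],
            "IRES": [tuple(map(float, c)) for c in ires_centers],
            "NEG": [tuple(map(float, c)) for c in neg_centers],
        },
    )
    return stack, filled


_SMFISH_PRESETS = {
    # long 5' UTR isoform dominates in posterior somites (~80% of molecules);
    # the anterior neural tube expresses predominantly the short isoform.
    "somite": {"long_fraction": 0.80},
    "neural_tube": {"long_fraction": 0.20},
}


def smfish_preset(name: str, seed: int = 0, **overrides) -> SmfishTruth:
    """Named smFISH study conditions; see ``_SMFISH_PRESETS`` for values."""
    if name not in _SMFISH_PRESETS:
        raise KeyError(f"unknown smFISH preset {name!r}; have {sorted(_SMFISH_PRESETS)}")
    kwargs = {**_SMFISH_PRESETS[name], "seed": seed, **overrides}
    return SmfishTruth(**kwargs)


# ---------------------------------------------------------------------------
# Flow cytometry events

@dataclass(frozen=True)
class FacsTruth:
    """Planted population structure for a synthetic cytometry acquisition.

    ``debris_fraction`` and ``doublet_fraction`` partition the events
    together with viable singlets; ``transfected_fraction`` applies within
    singlets. ``activity_fold`` multiplies transfected EGFP relative to the
    empty vector. ``clog_window`` is an event-index interval flagged
    anomalous and acquired at a 10x rate. Setting both CVs to zero gives
    noiseless closed-form populations.
    """

    n_events: int = 20000
    debris_fraction: float = 0.10
    doublet_fraction: float = 0.05
    transfected_fraction: float = 0.5
    activity_fold: float = 1.0
    clog_window: tuple[int, int] | None = None
    scatter_cv: float = 0.25
    fluor_cv: float = 0.35
    ratio_cv: float = 0.02
    fsc_viable: float = 1.0e5
    ssc_viable: float = 5.0e4
    debris_scale: float = 0.1
    mruby_negative: float = 50.0
    mruby_positive: float = 2.0e4
    egfp_negative: float = 100.0
    egfp_base: float = 200.0       # transfected EGFP at fold 1
    event_rate_hz: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("debris_fraction", "doublet_fraction", "transfected_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.debris_fraction + self.doublet_fraction > 1.0:
            raise ValueError("debris + doublet fractions exceed 1")
        if self.activity_fold <= 0:
            raise ValueError("activity_fold must be positive")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")


def make_facs_events(truth: FacsTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a per-event table (FSC-A, FSC-H, SSC-A, mRuby, EGFP).

    Debris sits at ``debris_scale`` of viable scatter; doublets have
    FSC-A ≈ 2·FSC-H; transfected singlets have high mRuby and EGFP scaled
    by ``activity_fold``. Events inside ``clog_window`` are flagged
    anomalous and compressed in time (10x event rate). Returns the event
    table and a per-event truth table with the planted category of each row.
    """
    rng = np.random.default_rng(truth.seed)
    n = truth.n_events
    n_debris = int(round(truth.debris_fraction * n))
    n_doublet = int(round(truth.doublet_fraction * n))
    n_singlet = n - n_debris - n_doublet
    n_transfected = int(round(truth.transfected_fraction * n_singlet))

    category = np.array(
        ["debris"] * n_debris
        + ["doublet"] * n_doublet
        + ["transfected"] * n_transfected
        + ["untransfected"] * (n_singlet - n_transfected)
    )
    rng.shuffle(category)

    def ln(base: float, cv: float, size: int) -> np.ndarray:
        if cv <= 0:
            return np.full(size, base)
        return base * np.exp(rng.normal(0.0, cv, size))

    fsc_a = np.empty(n)
    fsc_h = np.empty(n)
    ssc_a = np.empty(n)
    mruby = np.empty(n)
    egfp = np.empty(n)

    for cat in ("debris", "doublet", "transfected", "untransfected"):
        idx = np.flatnonzero(category == cat)
        m = idx.size
        if m == 0:
            continue
        if cat == "debris":
            fa = ln(truth.fsc_viable * truth.debris_scale, truth.scatter_cv, m)
            sa = ln(truth.ssc_viable * truth.debris_scale, truth.scatter_cv, m)
            fh = fa * ln(1.0, truth.ratio_cv, m)
        elif cat == "doublet":
            fh = ln(truth.fsc_viable, truth.scatter_cv, m)
            fa = 2.0 * fh * ln(1.0, truth.ratio_cv, m)
            sa = ln(2.0 * truth.ssc_viable, truth.scatter_cv, m)
        else:
            fa = ln(truth.fsc_viable, truth.scatter_cv, m)
            sa = ln(truth.ssc_viable, truth.scatter_cv, m)
            fh = fa * ln(1.0, truth.ratio_cv, m)
        fsc_a[idx], fsc_h[idx], ssc_a[idx] = fa, fh, sa
        if cat == "transfected":
            mruby[idx] = ln(truth.mruby_positive, truth.fluor_cv, m)
            egfp[idx] = ln(truth.egfp_base * truth.activity_fold, truth.fluor_cv, m)
        else:
            mruby[idx] = ln(truth.mruby_negative, truth.fluor_cv, m)
            egfp[idx] = ln(truth.egfp_negative, truth.fluor_cv, m)

    anomaly = np.zeros(n, dtype=bool)
    dt = np.full(n, 1.0 / truth.event_rate_hz)
    if truth.clog_window is not None:
        lo, hi = truth.clog_window
        if not (0 <= lo <= hi <= n):
            raise ValueError(f"clog_window {truth.clog_window} outside [0, {n}]")
        anomaly[lo:hi] = True
        dt[lo:hi] /= 10.0  # clog: burst of events at 10x rate
    time_s = np.cumsum(dt)

    events = pd.DataFrame(
        {
            "fsc_a": fsc_a,
            "fsc_h": fsc_h,
            "ssc_a": ssc_a,
            "mruby": mruby,
            "egfp": egfp,
            "time_s": time_s,
            "anomaly": anomaly,
        }
    )
    truth_table = pd.DataFrame({"category": category, "anomaly": anomaly})
    return events, truth_table


_FACS_PRESETS = {
    # activity folds vs the empty vector, spanning the viral-IRES range the
    # reporter resolves: CVB3 drives ~13-fold, HCV ~4.5-fold, EMCV ~1-fold.
    # "untransfected" is the mRuby-gating control (no reporter at all).
    "untransfected": {"activity_fold": 1.0, "transfected_fraction": 0.0},
    "empty_vector": {"activity_fold": 1.0},
    "emcv": {"activity_fold": 1.2},
    "hcv": {"activity_fold": 4.5},
    "cvb3": {"activity_fold": 13.0},
}


def facs_preset(name: str, seed: int = 0, **overrides) -> FacsTruth:
    if name not in _FACS_PRESETS:
        raise KeyError(f"unknown FACS preset {name!r}; have {sorted(_FACS_PRESETS)}")
    kwargs = {**_FACS_PRESETS[name], "seed": seed, **overrides}
    return FacsTruth(**kwargs)


# ---------------------------------------------------------------------------
# qPCR Ct tables

#: Ct anchoring: 1 unit of quantity (1 pg) amplifies to threshold at cycle 20.
CT_BASELINE = 20.0

#: Ten-fraction sucrose gradient grouped into the five canonical portions.
DEFAULT_PORTION_MAP = {
    1: "free", 2: "free",
    3: "40S/60S", 4: "40S/60S",
    5: "80S", 6: "80S",
    7: "light polysome", 8: "light polysome",
    9: "heavy polysome", 10: "heavy polysome",
}


@dataclass(frozen=True)
class QpcrTruth:
    """True template quantities and the Ct-generating model parameters.

    Ct = 20 - log(quantity) / log(efficiency) + N(0, ct_noise_sd), with
    quantity in pg (the anchor puts 1 pg at Ct 20). RNase R treatment
    divides linear-class (and reference) quantities by
    ``rnaser_linear_decay`` and circular-class quantities by
    ``rnaser_circ_decay``; no-RT samples retain ``no_rt_leak`` of the
    template. Gradient designs weight each amplicon's quantity by
    ``gradient_weights`` per fraction, add ``spike_quantity`` of spike-in
    to every fraction, and multiply everything in a fraction by a common
    log-normal recovery factor (sd ``recovery_log2_sd`` in log2 units) that
    spike normalization must cancel.
    """

    true_quantities: dict = field(default_factory=dict)  # amplicon -> pg
    efficiency: float = 2.0
    ct_noise_sd: float = 0.0
    rnaser_linear_decay: float = 1.0
    rnaser_circ_decay: float = 1.0
    no_rt_leak: float = 2.0**-10
    gradient_weights: dict = field(default_factory=dict)  # amplicon -> weights
    spike_quantity: float = 0.1
    recovery_log2_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1.0 < self.efficiency <= 2.0):
            raise ValueError("efficiency must be in (1, 2]")
        if self.rnaser_linear_decay < 1.0 or self.rnaser_circ_decay < 1.0:
            raise ValueError("RNase R decay factors must be >= 1")
        for amp, w in self.gradient_weights.items():
            arr = np.asarray(w, dtype=float)
            if np.any(arr < 0) or arr.sum() <= 0:
                raise ValueError(f"gradient weights for {amp!r} must be nonnegative, not all zero")


@dataclass(frozen=True)
class AssayDesign:
    """Which samples, amplicons, treatments, fractions and dilutions to emit.

    ``amplicon_class`` maps each amplicon to one of ``circular``, ``linear``,
    ``reference`` or ``spike``; the class decides how RNase R and gradient
    logic apply. ``dilution_series`` maps an amplicon to explicit standard
    quantities (pg). ``fractions`` switches on the gradient design.
    """

    samples: tuple[str, ...] = ("sample",)
    amplicon_class: dict = field(default_factory=dict)
    treatments: tuple[str, ...] = ("none",)
    replicates: int = 3
    fractions: tuple[int, ...] | None = None
    dilution_series: dict = field(default_factory=dict)


def _ct(quantity: float, efficiency: float) -> float:
    if quantity <= 0:
        return float("nan")  # undetermined
    return CT_BASELINE - math.log(quantity) / math.log(efficiency)


def make_ct_table(truth: QpcrTruth, design: AssayDesign) -> tuple[pd.DataFrame, QpcrTruth]:
    """Generate a long-format Ct table under the truth's amplification model.

    Zero noise gives exact closed-form Cts; zero or negative quantities emit
    missing ("undetermined") Cts. Identical truth and design give identical
    tables.
    """
    rng = np.random.default_rng(truth.seed)
    rows = []

    def emit(sample, amplicon, treatment, fraction, replicate, quantity):
        ct = _ct(quantity, truth.efficiency)
        if not math.isnan(ct) and truth.ct_noise_sd > 0:
            ct += rng.normal(0.0, truth.ct_noise_sd)
        rows.append((sample, amplicon, treatment, fraction, replicate, ct))

    classes = design.amplicon_class

    for sample in design.samples:
        if design.fractions is not None:
            for frac in design.fractions:
                recovery = (
                    2.0 ** rng.normal(0.0, truth.recovery_log2_sd)
                    if truth.recovery_log2_sd > 0
                    else 1.0
                )
                for rep in range(1, design.replicates + 1):
                    for amp, cls in classes.items():
                        if cls == "spike":
                            q = truth.spike_quantity
                        else:
                            weights = np.asarray(
                                truth.gradient_weights.get(amp, ()), dtype=float
                            )
                            i = design.fractions.index(frac)
                            if weights.size <= i:
                                continue
                            q = truth.true_quantities.get(amp, 1.0) * float(weights[i])
                        emit(sample, amp, "none", frac, rep, q * recovery)
            continue
        for treatment in design.treatments:
            for rep in range(1, design.replicates + 1):
                for amp, cls in classes.items():
                    base_q = truth.true_quantities.get(amp, 1.0)
                    if amp in design.dilution_series:
                        continue
                    q = base_q
                    if treatment == "rnaser":
                        if cls == "circular":
                            q /= truth.rnaser_circ_decay
                        elif cls in ("linear", "reference"):
                            q /= truth.rnaser_linear_decay
                    elif treatment == "no_rt":
                        q *= truth.no_rt_leak
                    emit(sample, amp, treatment, None, rep, q)
        # dilution series are per-sample, treatment "none"
        for amp, quantities in design.dilution_series.items():
            for rep in range(1, design.replicates + 1):
                for q in quantities:
                    emit(sample, f"{amp}@{q:g}", "none", None, rep, q)

    table = pd.DataFrame(rows, columns=CT_COLUMNS)
    return table, truth


_QPCR_PRESETS = {
    # circRNA reporter: circle resists RNase R, linear mRNA depleted 8-fold
    # (within the 4-14-fold enrichment window the assay resolves)
    "rnaser": dict(
        true_quantities={"circ_junction": 0.5, "linear_egfp": 2.0, "nupl1": 1.0},
        rnaser_linear_decay=8.0,
        rnaser_circ_decay=1.0,
    ),
    # tenfold serial dilution standard curve, 1 pg down to 0.1 fg
    "dilution": dict(true_quantities={"hoxa9_ires": 1.0}),
    # gradient distribution peaking in the light polysome portion
    "polysome_light": dict(
        true_quantities={"hoxa9_ires": 1.0, "nupl1": 1.0},
        gradient_weights={
            "hoxa9_ires": (1, 1, 2, 2, 3, 4, 9, 8, 4, 2),
            "nupl1": (1, 1, 1, 2, 3, 4, 6, 7, 9, 8),
        },
        spike_quantity=0.1,
        recovery_log2_sd=0.5,
    ),
}

#: Standard-curve quantities: tenfold steps from 1 pg to 0.1 fg (5 points).
DILUTION_SERIES_PG = tuple(10.0 ** -k for k in range(5))


def qpcr_preset(name: str, seed: int = 0, **overrides) -> tuple[QpcrTruth, AssayDesign]:
    """Named qPCR study conditions: truth plus a matching assay design."""
    if name not in _QPCR_PRESETS:
        raise KeyError(f"unknown qPCR preset {name!r}; have {sorted(_QPCR_PRESETS)}")
    truth = QpcrTruth(**{**_QPCR_PRESETS[name], "seed": seed, **overrides})
    if name == "rnaser":
        design = AssayDesign(
            samples=("construct",),
            amplicon_class={
                "circ_junction": "circular",
                "linear_egfp": "linear",
                "nupl1": "reference",
            },
            treatments=("none", "rnaser"),
        )
    elif name == "dilution":
        design = AssayDesign(
            samples=("standard",),
            amplicon_class={"hoxa9_ires": "linear"},
            dilution_series={"hoxa9_ires": list(DILUTION_SERIES_PG)},
            replicates=1,
        )
    else:  # polysome
        design = AssayDesign(
            samples=("embryo",),
            amplicon_class={
                "hoxa9_ires": "linear",
                "nupl1": "linear",
                "rluc_spike": "spike",
            },
            fractions=tuple(range(1, 11)),
            replicates=1,
        )
    return truth, design
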