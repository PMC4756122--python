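"""qPCR assay evaluation: standard curves, efficiency, LOD/ROQ,
binary detection, sensitivity/specificity, and marker quantity profiles.

Conventions
-----------
* The standard curve regresses Ct on log10(copies); the slope of a working
  assay is negative and is stored as a positive magnitude (Ct per 10-fold
  dilution).  Amplification efficiency is
  ``(10^(1/slope_magnitude) - 1) * 100`` percent.
* The limit of detection (LOD) is the smallest tested copy level detected
  in at least 90% of replicates.
* Reported sensitivity/specificity percentages are floor-truncated
  (76.47 -> 76); efficiencies are truncated at the precision they are
  reported at.  Raw fractions are always retained alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

AVOGADRO = 6.022e23
#: average molar mass of a DNA base pair, g/mol/bp
BP_MASS = 660.0


def truncate(value: float, decimals: int = 0) -> float:
    """Floor-truncation at a given number of decimals (87.99 -> 87 at 0)."""
    factor = 10.0 ** decimals
    return math.floor(value * factor) / factor


@dataclass
class StandardCurve:
    """Fitted dilution-series calibration for one assay."""

    assay_id: str
    slope_magnitude: float  # Ct per log10 copies (positive magnitude)
    intercept: float        # Ct at 1 copy
    r_squared: float
    efficiency_percent: float
    roq: Tuple[float, float] = (math.nan, math.nan)
    lod_copies: Optional[float] = None

    def ct_at(self, copies: float) -> float:
        return self.intercept - self.slope_magnitude * math.log10(copies)


@dataclass
class DetectionMatrix:
    """Binary detection calls (and optional quantities) per assay x sample."""

    assays: List[str]
    samples: List[Tuple[str, str]]  # (sample_id, host_group)
    calls: np.ndarray               # bool, shape (n_assays, n_samples)
    quantities: Optional[np.ndarray] = None  # copies per ng DNA

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=bool)
        if self.calls.shape != (len(self.assays), len(self.samples)):
            raise ValueError("calls shape inconsistent with assay/sample lists")
        if self.quantities is not None:
            self.quantities = np.asarray(self.quantities, dtype=float)
            if self.quantities.shape != self.calls.shape:
                raise ValueError("quantities shape inconsistent")

    @property
    def host_groups(self) -> Set[str]:
        return {g for _, g in self.samples}

    @classmethod
    def from_table(cls, df: pd.DataFrame,
                   call_column: str = "call") -> "DetectionMatrix":
        """Build from a long table with columns assay, sample, host_group,
        and a 0/1 ``call`` column (plus optional ``quantity``)."""
        assays = list(dict.fromkeys(df["assay"]))
        sample_rows = df[["sample", "host_group"]].drop_duplicates()
        samples = list(sample_rows.itertuples(index=False, name=None))
        a_ix = {a: i for i, a in enumerate(assays)}
        s_ix = {s: i for i, (s, _) in enumerate(samples)}
        calls = np.zeros((len(assays), len(samples)), dtype=bool)
        quant = None
        if "quantity" in df.columns:
            quant = np.full(calls.shape, math.nan)
        for row in df.itertuples(index=False):
            i, j = a_ix[row.assay], s_ix[row.sample]
            calls[i, j] = bool(getattr(row, call_column))
            if quant is not None:
                quant[i, j] = float(row.quantity)
        return cls(assays=assays, samples=samples, calls=calls,
                   quantities=quant)


@dataclass
class ConfusionSummary:
    """TP/FN/TN/FP tallies and floor-truncated percentages for one assay."""

    assay_id: str
    target_groups: Set[str]
    TP: int
    FN: int
    TN: int
    FP: int
    sensitivity_percent: float
    specificity_percent: float
    sensitivity_fraction: float
    specificity_fraction: float


def fit_standard_curve(points: Sequence[Tuple[float, float]],
                       assay_id: str = "assay",
                       lod_copies: Optional[float] = None) -> StandardCurve:
    """Ordinary least squares of Ct on log10(copies).

    ``points`` are (copies, ct) pairs; at least three distinct copy levels
    are required, all positive.  The reported ROQ is the copy range of the
    fitted points.
    """
    pts = [(c, t) for c, t in points if not math.isnan(t)]
    if any(c <= 0 for c, _ in pts):
        raise ValueError("copy numbers must be positive")
    levels = {c for c, _ in pts}
    if len(levels) < 3:
        raise ValueError("need at least 3 distinct copy levels")
    x = np.log10([c for c, _ in pts])
    y = np.array([t for _, t in pts])
    res = stats.linregress(x, y)
    slope_mag = abs(res.slope)
    return StandardCurve(
        assay_id=assay_id, slope_magnitude=slope_mag,
        intercept=float(res.intercept), r_squared=float(res.rvalue ** 2),
        efficiency_percent=efficiency_from_slope(slope_mag),
        roq=(min(levels), max(levels)), lod_copies=lod_copies)


def efficiency_from_slope(slope_magnitude: float) -> float:
    """Amplification efficiency in percent from the slope magnitude:
    (10^(1/|slope|) - 1) * 100; 3.32193 (perfect doubling) -> 100%."""
    if slope_magnitude <= 0:
        raise ValueError("slope magnitude must be positive")
    return (10.0 ** (1.0 / slope_magnitude) - 1.0) * 100.0


@dataclass
class LodResult:
    """LOD estimate; ``copies`` is None when no level qualifies."""

    copies: Optional[float]
    detection_rate: float
    rates: Dict[float, float] = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return self.copies is not None


def estimate_lod(replicate_calls: Mapping[float, Tuple[int, int]],
                 detection_rate: float = 0.90) -> LodResult:
    """Smallest copy level with positive fraction >= ``detection_rate``
    (boundary inclusive).  No qualifying level yields an explicit
    undefined-LOD result, not an exception."""
    rates = {}
    for copies, (n_pos, n_total) in replicate_calls.items():
        if n_total <= 0 or n_pos > n_total:
            raise ValueError(f"bad replicate counts at {copies}")
        rates[float(copies)] = n_pos / n_total
    qualifying = [c for c in sorted(rates) if rates[c] >= detection_rate]
    return LodResult(copies=qualifying[0] if qualifying else None,
                     detection_rate=detection_rate, rates=rates)


def confusion(dm: DetectionMatrix, assay_id: str,
              target_groups: Iterable[str]) -> ConfusionSummary:
    """Confusion tallies for one assay given its target host groups.

    Sensitivity = TP/(TP+FN) over samples in the target groups;
    specificity = TN/(TN+FP) over the rest of the panel.  Percentages are
    floor-truncated for reporting; raw fractions retained.  Target groups
    absent from the panel simply contribute no samples (sensitivity is nan
    when the panel has no target samples, e.g. a non-target-only
    specificity panel).
    """
    targets = set(target_groups)
    if not targets:
        raise ValueError("target_groups must be non-empty")
    try:
        i = dm.assays.index(assay_id)
    except ValueError:
        raise KeyError(f"assay {assay_id!r} not in detection matrix")
    in_target = np.array([g in targets for _, g in dm.samples])
    calls = dm.calls[i]
    TP = int(np.sum(calls & in_target))
    FN = int(np.sum(~calls & in_target))
    FP = int(np.sum(calls & ~in_target))
    TN = int(np.sum(~calls & ~in_target))
    sens = TP / (TP + FN) if TP + FN else math.nan
    spec = TN / (TN + FP) if TN + FP else math.nan
    return ConfusionSummary(
        assay_id=assay_id, target_groups=targets,
        TP=TP, FN=FN, TN=TN, FP=FP,
        sensitivity_percent=truncate(100 * sens) if TP + FN else math.nan,
        specificity_percent=truncate(100 * spec) if TN + FP else math.nan,
        sensitivity_fraction=sens, specificity_fraction=spec)


def copies_from_plasmid_mass(mass_ng: float, construct_length_bp: int) -> float:
    """Gene copies in a plasmid aliquot quantified by mass:
    copies = mass[g] / (length * 660 g/mol/bp) * Avogadro."""
    if mass_ng <= 0 or construct_length_bp <= 0:
        raise ValueError("mass and construct length must be positive")
    moles = mass_ng * 1e-9 / (construct_length_bp * BP_MASS)
    return moles * AVOGADRO


def detection_calls_from_ct(ct_wells: Sequence[float],
                            curve: StandardCurve,
                            dnq_positive: bool = True) -> bool:
    """Binary call from duplicate-well Ct values.

    Positive iff every well amplified (non-NaN) with Ct at or below the Ct
    of the assay's LOD level on its standard curve.  With
    ``dnq_positive=False``, wells amplifying beyond the quantifiable range
    (Ct above the Ct of roq.min) count as negative instead.
    """
    if curve.lod_copies is None:
        raise ValueError("curve has no LOD level")
    limit = curve.ct_at(curve.lod_copies)
    if not dnq_positive and not math.isnan(curve.roq[0]):
        limit = curve.ct_at(curve.roq[0])
    return all((not math.isnan(ct)) and ct <= limit for ct in ct_wells)


def profile_stats(dm: DetectionMatrix, group: str) -> pd.DataFrame:
    """Per-assay marker-quantity distribution summaries for one host group.

    Median and quartiles use the linear-interpolation quantile definition;
    outliers are points beyond 1.5 x IQR from the quartiles.  Quantities
    are expected to be marker copies normalized per ng of DNA.
    """
    if dm.quantities is None:
        raise ValueError("detection matrix has no quantities")
    cols = [j for j, (_, g) in enumerate(dm.samples) if g == group]
    rows = []
    for i, assay in enumerate(dm.assays):
        vals = dm.quantities[i, cols]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            continue
        q25, med, q75 = np.percentile(vals, [25, 50, 75])
        iqr = q75 - q25
        lo, hi = q25 - 1.5 * iqr, q75 + 1.5 * iqr
        outliers = sorted(float(v) for v in vals[(vals < lo) | (vals > hi)])
        rows.append({"assay": assay, "group": group, "n": int(vals.size),
                     "median": float(med), "q25": float(q25),
                     "q75": float(q75), "outliers": outliers})
    return pd.DataFrame(rows)


def profile_boxplot(dm: DetectionMatrix, group: str, path: str) -> None:
    """Box-plot of per-assay marker quantities for one group (matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if dm.quantities is None:
        raise ValueError("detection matrix has no quantities")
    cols = [j for j, (_, g) in enumerate(dm.samples) if g == group]
    data, labels = [], []
    for i, assay in enumerate(dm.assays):
        vals = dm.quantities[i, cols]
        vals = vals[~np.isnan(vals)]
        if vals.size:
            data.append(vals)
            labels.append(assay)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot(data, tick_labels=labels, sym="+")
    ax.set_yscale("log")
    ax.set_ylabel("marker copies / ng DNA")
    ax.set_title(group)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
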