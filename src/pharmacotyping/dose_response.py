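"""Censored LC50 estimation from six-point ex vivo viability curves.

Each sample x drug assay yields viability fractions (relative to vehicle
control) at six increasing concentrations.  A four-parameter logistic (4PL)
curve is fitted in log10-concentration space and the LC50 is read off as the
concentration at which the fitted curve crosses absolute viability 0.5, i.e.
the dose killing half of the leukemia cells.  Censoring is decided on the
observed endpoint viabilities before any curve evaluation: if even the lowest
dose kills more than half the cells the LC50 is left-censored at half the
minimum tested concentration; if more than half survive the highest dose it
is right-censored at twice the maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DrugConcentrationGrid",
    "ViabilityAssayRecord",
    "FourPlFit",
    "Lc50Estimate",
    "qc_filter",
    "four_pl",
    "fit_four_pl",
    "estimate_lc50",
]

CENSOR_LEFT = "left"
CENSOR_RIGHT = "right"
CENSOR_INTERVAL = "interval"


@dataclass(frozen=True)
class DrugConcentrationGrid:
    """Six strictly increasing positive test concentrations for one drug."""

    drug_id: str
    concentrations: np.ndarray
    units: str = ""

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        if conc.shape != (6,):
            raise ValueError(f"{self.drug_id}: exactly 6 concentrations required")
        if not np.all(conc > 0):
            raise ValueError(f"{self.drug_id}: concentrations must be positive")
        if not np.all(np.diff(conc) > 0):
            raise ValueError(f"{self.drug_id}: concentrations must be strictly increasing")

    @property
    def left_bound(self) -> float:
        return self.concentrations[0] / 2.0

    @property
    def right_bound(self) -> float:
        return 2.0 * self.concentrations[-1]


@dataclass
class ViabilityAssayRecord:
    """One sample-drug viability curve plus assay-specific QC readouts.

    ``assay_kind`` is either ``"MTT"`` (4-day MTT assay; QC on blast
    percentage and optical density in control wells) or ``"coculture"``
    (MSC co-culture with flow cytometry; QC on viable blast count in the
    drug-free control).
    """

    sample_id: str
    drug_id: str
    viabilities: np.ndarray
    assay_kind: str = "MTT"
    qc_blast_fraction: float | None = None
    qc_optical_density: float | None = None
    qc_viable_blasts: float | None = None

    def __post_init__(self):
        v = np.asarray(self.viabilities, dtype=float)
        self.viabilities = v
        if v.ndim != 1 or v.size != 6:
            raise ValueError("one viability value per grid concentration (6) required")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("viabilities must be finite and non-negative")
        if self.assay_kind not in ("MTT", "coculture"):
            raise ValueError(f"unknown assay_kind: {self.assay_kind!r}")


@dataclass
class FourPlFit:
    """Fitted 4PL parameters.  ``ec50`` is in grid concentration units."""

    bottom: float
    top: float
    hill: float
    ec50: float
    converged: bool
    rss: float

    def __post_init__(self):
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.bottom > self.top:
            raise ValueError("bottom must not exceed top")
        if self.rss < 0:
            raise ValueError("rss must be non-negative")


@dataclass
class Lc50Estimate:
    sample_id: str
    drug_id: str
    raw_lc50: float
    censor: str
    qc_pass: bool = True
    used_fallback: bool = False
    fit: FourPlFit | None = field(default=None, repr=False)


def qc_filter(record: ViabilityAssayRecord) -> bool:
    """Assay quality control.

    MTT passes with more than 70% leukemic blasts in the control wells and a
    control optical density above 0.050 absorbance units (both strict).
    Co-culture passes with at least 1,000 viable blast cells in the drug-free
    control wells.
    """
    if record.assay_kind == "MTT":
        if record.qc_blast_fraction is None or record.qc_optical_density is None:
            raise ValueError(
                f"{record.sample_id}/{record.drug_id}: MTT record requires "
                "qc_blast_fraction and qc_optical_density"
            )
        if not 0 <= record.qc_blast_fraction <= 1:
            raise ValueError("qc_blast_fraction must be in [0, 1]")
        return record.qc_blast_fraction > 0.70 and record.qc_optical_density > 0.050
    if record.qc_viable_blasts is None:
        raise ValueError(
            f"{record.sample_id}/{record.drug_id}: coculture record requires qc_viable_blasts"
        )
    return record.qc_viable_blasts >= 1000


def four_pl(log10_conc, bottom, top, hill, log10_ec50):
    """4PL response in log10-concentration space.

    Positive ``hill`` gives a curve decreasing from ``top`` toward ``bottom``
    as concentration rises (the usual shape for a cytotoxic agent).
    """
    x = np.asarray(log10_conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (x - log10_ec50)))


def _fit_direction(x, v, hill_starts, hill_bounds, grid):
    """Bounded least squares with fixed multi-starts on the hill slope."""
    lo_ec, hi_ec = np.log10(grid.concentrations[0] / 10.0), np.log10(grid.concentrations[-1] * 10.0)
    top0 = float(np.clip(v.max(), 0.5, 1.5))
    bot0 = float(np.clip(v.min(), 0.0, 0.5))
    ec0 = float(np.clip(x[np.argmin(np.abs(v - 0.5))], lo_ec, hi_ec))
    best = None
    for h0 in hill_starts:
        res = least_squares(
            lambda p: four_pl(x, *p) - v,
            x0=[bot0, top0, h0, ec0],
            bounds=([0.0, 0.5, hill_bounds[0], lo_ec], [0.5, 1.5, hill_bounds[1], hi_ec]),
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        if best is None or res.cost < best.cost:
            best = res
    return best


def fit_four_pl(grid: DrugConcentrationGrid, viabilities) -> FourPlFit:
    """Deterministic bounded 4PL least-squares fit.

    Fitted in log10-concentration space with bottom in [0, 0.5], top in
    [0.5, 1.5] and the hill slope sign fixed by the observed curve direction
    (no sign flip within one fit); three multi-starts on |hill| in
    {0.5, 1, 2}.  No randomness is involved, so refitting the same curve is
    bit-reproducible.
    """
    v = np.asarray(viabilities, dtype=float)
    if v.size != 6 or not np.all(np.isfinite(v)):
        raise ValueError("six finite viability values required")
    x = np.log10(grid.concentrations)

    decreasing = v[:3].mean() >= v[3:].mean()
    if decreasing:
        res = _fit_direction(x, v, (0.5, 1.0, 2.0), (1e-3, 10.0), grid)
    else:
        res = _fit_direction(x, v, (-0.5, -1.0, -2.0), (-10.0, -1e-3), grid)

    bottom, top, hill, log_ec50 = res.x
    rss = float(2.0 * res.cost)
    # a fit explaining no more variance than the best flat line is degenerate
    flat_rss = float(np.sum((v - v.mean()) ** 2))
    converged = bool(res.success) and (rss <= flat_rss + 1e-12) and (top - bottom) > 1e-6
    return FourPlFit(float(bottom), float(top), float(hill), float(10.0 ** log_ec50),
                     converged, rss)


def _interp_crossing(grid: DrugConcentrationGrid, v: np.ndarray) -> float | None:
    """Fallback: 0.5-crossing of the monotonized viability curve.

    Viabilities are made non-increasing by a running minimum, then the first
    bracketing segment is interpolated linearly in log10 concentration.
    """
    x = np.log10(grid.concentrations)
    vm = np.minimum.accumulate(np.asarray(v, dtype=float))
    for i in range(5):
        v0, v1 = vm[i], vm[i + 1]
        if v0 >= 0.5 >= v1:
            if v0 == v1:  # flat segment sitting exactly at 0.5
                return float(10.0 ** x[i])
            t = (v0 - 0.5) / (v0 - v1)
            return float(10.0 ** (x[i] + t * (x[i + 1] - x[i])))
    return None


def estimate_lc50(
    grid: DrugConcentrationGrid,
    viabilities,
    sample_id: str = "",
    drug_id: str | None = None,
    fit: FourPlFit | None = None,
    qc_pass: bool = True,
) -> Lc50Estimate:
    """LC50 with explicit censoring.

    Censoring is decided on the observed endpoint viabilities first: below
    0.5 at the lowest dose is left-censored at ``min/2``; above 0.5 at the
    highest dose is right-censored at ``2*max``.  Otherwise the fitted 4PL
    curve is solved for the absolute 0.5 crossing; if the fit is degenerate
    or the crossing falls outside the open censor interval, a monotone
    piecewise log-linear interpolation of the observed curve is used and the
    estimate is flagged as a fallback.
    """
    v = np.asarray(viabilities, dtype=float)
    drug_id = drug_id or grid.drug_id
    lo, hi = grid.left_bound, grid.right_bound

    if v[0] < 0.5:
        return Lc50Estimate(sample_id, drug_id, lo, CENSOR_LEFT, qc_pass)
    if v[-1] > 0.5:
        return Lc50Estimate(sample_id, drug_id, hi, CENSOR_RIGHT, qc_pass)

    if fit is None:
        fit = fit_four_pl(grid, v)

    lc50 = None
    if fit.converged and fit.bottom < 0.5 < fit.top and abs(fit.hill) > 1e-3:
        # bottom + (top-bottom)/(1+r) = 0.5  =>  r = (top-0.5)/(0.5-bottom)
        r = (fit.top - 0.5) / (0.5 - fit.bottom)
        lc50 = float(fit.ec50 * r ** (1.0 / fit.hill))

    used_fallback = False
    if lc50 is None or not np.isfinite(lc50):
        lc50 = _interp_crossing(grid, v)
        used_fallback = True

    if lc50 is None:
        # endpoints straddle 0.5 yet no crossing found: nearer bound, flagged
        lc50 = lo if abs(v[0] - 0.5) < abs(v[-1] - 0.5) else hi
        censor = CENSOR_LEFT if lc50 == lo else CENSOR_RIGHT
        warnings.warn(f"{sample_id}/{drug_id}: no 0.5 crossing; assigned {censor} bound")
        return Lc50Estimate(sample_id, drug_id, lc50, censor, qc_pass, used_fallback=True, fit=fit)

    if lc50 <= lo:
        return Lc50Estimate(sample_id, drug_id, lo, CENSOR_LEFT, qc_pass,
                            used_fallback=used_fallback, fit=fit)
    if lc50 >= hi:
        return Lc50Estimate(sample_id, drug_id, hi, CENSOR_RIGHT, qc_pass,
                            used_fallback=used_fallback, fit=fit)
    return Lc50Estimate(sample_id, drug_id, lc50, CENSOR_INTERVAL, qc_pass,
                        used_fallback=used_fallback, fit=fit)
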