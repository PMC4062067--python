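"""Validation statistics for individual resistance candidates.

Candidates from a pooled screen are validated one by one: cells carrying an
inducible copy of the gene are exposed to a drug dilution series with and
without induction, viability is read out (e.g. by SRB total-protein stain)
relative to a no-drug control, and the rescue is quantified three ways:

* a variable-slope (four-parameter logistic, 4PL) dose-response fit and the
  fold shift in IC50 between conditions (>1: resistance; <1: sensitization);
* rescue efficiency — the fraction of the drug-induced viability loss that
  induction restores;
* for DNA-damaging drugs, the relative drop in gamma-H2A.X focus counts per
  nucleus (a direct DNA-damage readout).

The 4PL is fit in the GraphPad-style log-IC50 parameterization

    V(c) = bottom + (top - bottom) / (1 + 10**(hill * (log10 c - log10 IC50)))

which makes the fit equivariant under rescaling of the concentration axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DegenerateDataError, ParameterError

__all__ = [
    "FourPLFit",
    "percent_viability",
    "four_pl",
    "fit_dose_response",
    "ic50_fold_shift",
    "rescue_efficiency",
    "foci_rescue",
    "summarize_foci",
]


@dataclass(frozen=True)
class FourPLFit:
    """Result of a variable-slope dose-response fit.

    ``hill`` is positive for viability that falls with dose. ``trusted`` is
    False when the fitted IC50 lies more than 10x outside the tested
    concentration range (extrapolated IC50s should not be compared).
    """

    bottom: float
    top: float
    ic50: float
    hill: float
    converged: bool
    trusted: bool
    rss: float
    n_points: int

    def predict(self, conc) -> np.ndarray:
        return four_pl(np.asarray(conc, dtype=float),
                       self.bottom, self.top, self.ic50, self.hill)


def percent_viability(signal_treated: float, signal_untreated: float) -> float:
    """Viability as percent of the no-drug control (100% = untreated)."""
    if signal_untreated <= 0:
        raise ParameterError("untreated control signal must be > 0")
    return 100.0 * signal_treated / signal_untreated


def four_pl(conc, bottom, top, ic50, hill):
    """Variable-slope dose-response curve V(c); decreasing when hill > 0."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (
        1.0 + 10.0 ** (hill * (np.log10(conc) - np.log10(ic50)))
    )


def _4pl_logistic(logc, bottom, top, logic50, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - logic50)))


def fit_dose_response(data: pd.DataFrame) -> FourPLFit:
    """Least-squares 4PL fit to a viability dilution series.

    ``data`` needs columns ``concentration`` (> 0, any consistent unit) and
    ``viability_pct``; replicate rows are simply pooled. Preconditions: at
    least 4 distinct concentrations, viability spanning more than 10
    percentage points, and a falling overall trend (monotone-increasing
    "viability" means the series is mislabeled, not fittable).

    Initialization is deterministic — top = max viability, bottom = min
    viability, IC50 = geometric mid-range concentration, hill = 1 — so the
    fit is reproducible without global optimization. Non-convergence is
    reported in the ``converged`` flag, never raised.
    """
    conc = data["concentration"].to_numpy(dtype=float)
    viab = data["viability_pct"].to_numpy(dtype=float)
    if (conc <= 0).any():
        raise ParameterError("concentrations must be > 0")
    if np.unique(conc).size < 4:
        raise ParameterError("need at least 4 distinct concentrations")
    if np.ptp(viab) <= 10.0:
        raise DegenerateDataError(
            "viability varies by <= 10 percentage points: curve is flat"
        )
    logc = np.log10(conc)
    slope = np.polyfit(logc, viab, 1)[0]
    if slope > 0:
        raise DegenerateDataError(
            "viability increases with dose: not a toxicity dilution series"
        )
    p0 = (viab.min(), viab.max(), float(logc.mean()), 1.0)
    try:
        popt, _ = optimize.curve_fit(
            _4pl_logistic, logc, viab, p0=p0, maxfev=20000,
            bounds=([-np.inf, -np.inf, -np.inf, 1e-3],
                    [np.inf, np.inf, np.inf, 50.0]),
        )
        bottom, top, logic50, hill = map(float, popt)
        resid = viab - _4pl_logistic(logc, *popt)
        rss = float(resid @ resid)
        converged = np.isfinite(popt).all() and bottom <= top
    except RuntimeError:
        bottom, top, logic50, hill = p0
        rss = float("nan")
        converged = False
    ic50 = 10.0 ** logic50
    trusted = bool(
        converged and conc.min() / 10.0 <= ic50 <= conc.max() * 10.0
    )
    return FourPLFit(
        bottom=bottom, top=top, ic50=ic50, hill=hill,
        converged=bool(converged), trusted=trusted, rss=rss,
        n_points=int(conc.size),
    )


def ic50_fold_shift(ic50_reference: float, ic50_test: float) -> float:
    """IC50 fold change, test over reference.

    > 1 means the test condition is more resistant (IC50 shifted up);
    < 1 means sensitization (e.g. after knocking the gene down).
    """
    if ic50_reference <= 0 or ic50_test <= 0:
        raise ParameterError("IC50 values must be > 0")
    return ic50_test / ic50_reference


def rescue_efficiency(
    viab_induced: float,
    viab_uninduced: float,
    definition: str = "normalized_gain",
) -> float:
    """Fraction of the drug-induced viability loss restored by induction.

    Default ``normalized_gain``: 100 * (induced - uninduced) / (100 -
    uninduced) — 0 at no effect, 100 at full restoration to the no-drug
    control, clamped to [-100, 100]. ``absolute_difference`` returns the raw
    percentage-point gain instead. The uninduced viability must be below
    100% (otherwise there is no toxicity to rescue).
    """
    if not 0.0 <= viab_uninduced < 100.0:
        raise ParameterError("uninduced viability must lie in [0, 100)")
    if definition == "normalized_gain":
        val = 100.0 * (viab_induced - viab_uninduced) / (100.0 - viab_uninduced)
    elif definition == "absolute_difference":
        val = viab_induced - viab_uninduced
    else:
        raise ParameterError(f"unknown rescue definition {definition!r}")
    return float(np.clip(val, -100.0, 100.0))


def foci_rescue(mean_induced: float, mean_uninduced: float) -> float:
    """Percent reduction in mean foci per nucleus on induction.

    100 * (uninduced - induced) / uninduced: 0 at no change, 100 when
    induction abolishes foci entirely.
    """
    if mean_uninduced <= 0:
        raise ParameterError("uninduced mean focus count must be > 0")
    return 100.0 * (mean_uninduced - mean_induced) / mean_uninduced


def summarize_foci(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean ± SEM of per-nucleus focus counts.

    ``counts`` needs columns ``condition`` and ``focus_count``; every
    condition must have n >= 2 nuclei (SEM undefined otherwise).
    """
    if counts.empty:
        raise ParameterError("no focus counts supplied")
    if (counts["focus_count"] < 0).any():
        raise ParameterError("focus counts must be non-negative")
    rows = []
    for cond, grp in counts.groupby("condition", sort=True):
        vals = grp["focus_count"].to_numpy(dtype=float)
        if vals.size < 2:
            raise ParameterError(
                f"condition {cond!r} has n={vals.size}; SEM needs n >= 2"
            )
        rows.append(
            {
                "condition": cond,
                "n": int(vals.size),
                "mean": float(vals.mean()),
                "sem": float(stats.sem(vals)),
            }
        )
    return pd.DataFrame(rows)
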