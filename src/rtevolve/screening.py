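"""Screening analysis: death rates, hit calling, dose-response/IC50, tests.

The screen measures viability (an MTT/OD570-style signal) of clonal cell
populations over a Gemcitabine concentration grid. Per clone and experiment
the death rate at a concentration c is

    death = 1 - readout(c) / readout(0),

clamped to [0, 1]. A clone is a hit when its death rate at the screening
concentration exceeds that of BOTH control populations (untransduced cells
and cells carrying the unmutated transgene) in at least ``min_experiments``
independent experiments (default 1).

Dose-response curves are fitted with a four-parameter log-logistic model

    v(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill),

with the top left free because normalized transduced populations need not
reach viability exactly 1 at concentration 0. The reported IC50 is the
inflection concentration of the fitted curve (relative IC50); the absolute
50%-viability crossing is available separately for transparency.
Sensitization is the fold reduction in IC50 between a reference and a test
population, with a seeded residual-bootstrap percentile interval.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

PLATE_COLUMNS = ("clone_id", "experiment_id", "concentration_nM", "readout")
#: screening concentration (nM) and the alternates that proved too strong
DEFAULT_SCREENING_CONC_NM = 10.0
ALTERNATE_SCREENING_CONCS_NM = (35.0, 70.0)
VIABILITY_CEILING = 1.5  # MTT noise can push normalized viability above 1


class ViabilityPlate:
    """Clone x concentration x experiment viability readouts.

    Wraps a tidy DataFrame with columns clone_id, experiment_id,
    concentration_nM, readout. Every (clone, experiment) pair must include a
    0-concentration row — death rates are undefined without it.
    """

    def __init__(self, data: pd.DataFrame) -> None:
        missing = [c for c in PLATE_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"plate is missing column(s) {missing}")
        df = data.loc[:, list(PLATE_COLUMNS)].copy()
        df["concentration_nM"] = pd.to_numeric(df["concentration_nM"])
        df["readout"] = pd.to_numeric(df["readout"])
        if (df["readout"] < 0).any():
            raise ValueError("readouts must be non-negative")
        if (df["concentration_nM"] < 0).any():
            raise ValueError("concentrations must be non-negative")
        has_zero = df.groupby(["clone_id", "experiment_id"])["concentration_nM"].agg(
            lambda c: (c == 0).any()
        )
        if not has_zero.all():
            bad = has_zero[~has_zero].index[0]
            raise ValueError(
                f"missing 0-concentration rows for clone {bad[0]!r} in experiment "
                f"{bad[1]!r}; the 0-Gemcitabine reference is required"
            )
        self.data = df.reset_index(drop=True)

    @property
    def clone_ids(self) -> list[str]:
        return sorted(self.data["clone_id"].unique())

    @property
    def experiment_ids(self) -> list[str]:
        return sorted(self.data["experiment_id"].unique())

    @property
    def concentrations(self) -> np.ndarray:
        return np.sort(self.data["concentration_nM"].unique())

    def readout(self, clone_id: str, experiment_id: str, concentration: float) -> float:
        """Mean readout over replicate wells for one condition."""
        sel = self.data[
            (self.data["clone_id"] == clone_id)
            & (self.data["experiment_id"] == experiment_id)
            & (self.data["concentration_nM"] == concentration)
        ]
        if sel.empty:
            raise KeyError(
                f"no wells for clone {clone_id!r}, experiment {experiment_id!r}, "
                f"{concentration} nM"
            )
        return float(sel["readout"].mean())

    def __len__(self) -> int:
        return len(self.data)


def death_rate(readout_at_conc: float, readout_at_zero: float) -> float:
    """1 - readout(c)/readout(0), clamped to [0, 1]; clamping is logged."""
    if readout_at_zero <= 0:
        raise ValueError("0-concentration readout must be positive")
    if readout_at_conc < 0:
        raise ValueError("readouts must be non-negative")
    raw = 1.0 - readout_at_conc / readout_at_zero
    if raw < 0.0:
        logger.info("death rate %.4f clamped to 0 (readout above the 0-Gem reference)", raw)
        return 0.0
    return raw


def death_rate_table(plate: ViabilityPlate, concentration: float) -> pd.DataFrame:
    """Death rates per (clone, experiment) at one concentration."""
    rows = []
    for (clone, exp), grp in plate.data.groupby(["clone_id", "experiment_id"]):
        zero = grp.loc[grp["concentration_nM"] == 0, "readout"].mean()
        at_c = grp.loc[grp["concentration_nM"] == concentration, "readout"]
        if at_c.empty:
            raise ValueError(
                f"concentration {concentration} nM absent for clone {clone!r} "
                f"in experiment {exp!r}"
            )
        rows.append({
            "clone_id": clone, "experiment_id": exp,
            "death_rate": death_rate(float(at_c.mean()), float(zero)),
        })
    return pd.DataFrame(rows)


def call_hits(plate: ViabilityPlate,
              clone_ids: Sequence[str] | None = None,
              control_ids: tuple[str, str] = ("untransduced", "wt-dCK"),
              screening_conc: float = DEFAULT_SCREENING_CONC_NM,
              min_experiments: int = 1) -> pd.DataFrame:
    """Replicate-wise hit calling against two control populations.

    Per experiment, a clone scores when its death rate at the screening
    concentration exceeds the death rates of BOTH controls; it is a hit when
    it scores in at least ``min_experiments`` experiments. Returns a frame
    with clone_id, n_exceed, hit, sorted by clone_id (invariant under input
    order).
    """
    if len(control_ids) != 2:
        raise ValueError("exactly two control populations are required")
    if min_experiments < 1:
        raise ValueError("min_experiments must be >= 1")
    dr = death_rate_table(plate, screening_conc)
    wide = dr.pivot(index="clone_id", columns="experiment_id", values="death_rate")
    for ctrl in control_ids:
        if ctrl not in wide.index or wide.loc[ctrl].isna().any():
            raise ValueError(f"control {ctrl!r} missing from at least one experiment")
    threshold = wide.loc[list(control_ids)].max(axis=0)
    if clone_ids is None:
        clone_ids = [c for c in wide.index if c not in control_ids]
    exceed = wide.loc[list(clone_ids)].gt(threshold, axis=1)
    out = pd.DataFrame({
        "clone_id": list(clone_ids),
        "n_exceed": exceed.sum(axis=1).to_numpy(dtype=int),
    }).sort_values("clone_id", kind="stable", ignore_index=True)
    out["hit"] = out["n_exceed"] >= min_experiments
    return out


# ---------------------------------------------------------------------------
# Dose-response fitting
# ---------------------------------------------------------------------------

def _predict(params: np.ndarray, conc: np.ndarray) -> np.ndarray:
    bottom, span, log_ic50, hill = params
    ratio = np.zeros_like(conc, dtype=float)
    pos = conc > 0
    ratio[pos] = (conc[pos] / 10.0 ** log_ic50) ** hill
    return bottom + span / (1.0 + ratio)


class DoseResponseModel:
    """Four-parameter log-logistic viability model for one population.

    Parameters
    ----------
    concentrations : array-like, nM
        Must contain at least 4 distinct values including 0.
    viability : array-like
        Viability fractions (readout normalized to the 0-concentration
        readout); values outside [0, 1.5] are rejected as plate errors.
    """

    def __init__(self, concentrations, viability) -> None:
        c = np.asarray(concentrations, dtype=float)
        v = np.asarray(viability, dtype=float)
        if c.shape != v.shape or c.ndim != 1:
            raise ValueError("concentrations and viability must be equal-length 1-D")
        if (c < 0).any():
            raise ValueError("concentrations must be non-negative")
        if np.unique(c).size < 4:
            raise ValueError("need at least 4 distinct concentrations")
        if not (c == 0).any():
            raise ValueError("the 0-concentration reference point is required")
        if ((v < 0) | (v > VIABILITY_CEILING)).any():
            raise ValueError(
                f"viability outside [0, {VIABILITY_CEILING}] — rejected as a plate error"
            )
        order = np.argsort(c, kind="stable")
        self.conc = c[order]
        self.viability = v[order]

    @classmethod
    def from_plate(cls, plate: ViabilityPlate, clone_id: str,
                   experiment_id: str | None = None) -> "DoseResponseModel":
        """Viability fractions for one clone, normalized per experiment."""
        df = plate.data[plate.data["clone_id"] == clone_id]
        if df.empty:
            raise KeyError(f"clone {clone_id!r} not on the plate")
        if experiment_id is not None:
            df = df[df["experiment_id"] == experiment_id]
        concs, fracs = [], []
        for exp, grp in df.groupby("experiment_id"):
            zero = grp.loc[grp["concentration_nM"] == 0, "readout"].mean()
            per_conc = grp.groupby("concentration_nM")["readout"].mean()
            concs.extend(per_conc.index.to_numpy())
            fracs.extend(np.clip(per_conc.to_numpy() / zero, 0.0, VIABILITY_CEILING))
        return cls(np.asarray(concs), np.asarray(fracs))

    def _bounds(self) -> tuple[np.ndarray, np.ndarray]:
        pos = self.conc[self.conc > 0]
        llo = np.log10(pos.min()) - 2.0
        lhi = np.log10(pos.max()) + 2.0
        return (np.array([0.0, 0.0, llo, 0.05]),
                np.array([VIABILITY_CEILING, VIABILITY_CEILING, lhi, 10.0]))

    def fit(self, n_starts: int = 8, start: np.ndarray | None = None) -> "DoseResponseResults":
        """Least-squares fit with multi-start initialization.

        Non-convergence (including degenerate flat data, for which the IC50 is
        unidentifiable) is flagged on the result, never silent.
        """
        lo, hi = self._bounds()
        v = self.viability
        bottom0 = float(np.clip(v.min(), lo[0], hi[0]))
        span0 = float(np.clip(v.max() - v.min(), 0.01, hi[1]))
        pos = self.conc[self.conc > 0]
        if start is not None:
            starts = [np.clip(np.asarray(start, dtype=float), lo + 1e-9, hi - 1e-9)]
        else:
            log_grid = np.linspace(np.log10(pos.min()), np.log10(pos.max()),
                                   max(2, n_starts // 2))
            starts = [np.array([bottom0, span0, lg, h])
                      for lg in log_grid for h in (1.0, 2.0)][:max(n_starts, 1)]

        best = None
        for x0 in starts:
            try:
                res = optimize.least_squares(
                    lambda th: _predict(th, self.conc) - v, x0,
                    bounds=(lo, hi), method="trf",
                )
            except Exception:  # pragma: no cover - defensive
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:  # pragma: no cover - least_squares is robust
            return DoseResponseResults(self, np.full(4, np.nan), np.nan, np.inf, False)

        bottom, span, log_ic50, hill = best.x
        rss = float(2 * best.cost)
        margin = 1e-3
        identifiable = (
            span > 0.02
            and lo[2] + margin < log_ic50 < hi[2] - margin
        )
        converged = bool(best.success) and identifiable
        ic50 = float(10.0 ** log_ic50) if identifiable else float("nan")
        if not converged:
            logger.warning(
                "dose-response fit not converged/identifiable (span=%.3g, log_ic50=%.3g)",
                span, log_ic50,
            )
        return DoseResponseResults(self, best.x.copy(), ic50, rss, converged)


class DoseResponseResults:
    """Fitted log-logistic curve: IC50, slope, asymptotes, fit diagnostics."""

    def __init__(self, model: DoseResponseModel, params: np.ndarray,
                 ic50: float, rss: float, converged: bool) -> None:
        self.model = model
        self.params = params
        self.ic50 = ic50
        self.rss = rss
        self.converged = converged

    @property
    def bottom(self) -> float:
        return float(self.params[0])

    @property
    def top(self) -> float:
        return float(self.params[0] + self.params[1])

    @property
    def hill(self) -> float:
        return float(self.params[3])

    def predict(self, conc) -> np.ndarray:
        return _predict(self.params, np.asarray(conc, dtype=float))

    def fitted(self) -> np.ndarray:
        return self.predict(self.model.conc)

    def residuals(self) -> np.ndarray:
        return self.model.viability - self.fitted()

    def absolute_ic50(self) -> float | None:
        """Concentration where the fitted curve crosses viability 0.5.

        Complements the relative (inflection) IC50; None when the fitted
        curve never crosses 0.5 in an extended concentration window.
        """
        if not self.converged:
            return None
        pos = self.model.conc[self.model.conc > 0]
        lo, hi = pos.min() / 100.0, pos.max() * 100.0
        f = lambda c: float(self.predict(np.array([c]))[0] - 0.5)
        if f(lo) * f(hi) > 0:
            return None
        return float(optimize.brentq(f, lo, hi))

    def summary(self) -> str:
        lines = [
            "Dose-response fit (4-parameter log-logistic)",
            "=" * 46,
            f"converged      {self.converged}",
            f"IC50 (nM)      {self.ic50:.6g}",
            f"hill slope     {self.hill:.4g}",
            f"top / bottom   {self.top:.4g} / {self.bottom:.4g}",
            f"RSS            {self.rss:.3e}",
        ]
        abs_ic50 = self.absolute_ic50()
        lines.append(f"50%-viability crossing (nM)  "
                     f"{abs_ic50:.6g}" if abs_ic50 is not None else
                     "50%-viability crossing (nM)  not reached")
        return "\n".join(lines)


class FoldChangeResult(NamedTuple):
    ratio: float
    ci_low: float
    ci_high: float
    n_boot: int


def fold_change(fit_reference: DoseResponseResults, fit_test: DoseResponseResults,
                n_boot: int = 200, *, seed: int, alpha: float = 0.05) -> FoldChangeResult:
    """IC50(reference)/IC50(test) with a seeded residual-bootstrap interval.

    Both fits must have converged. Residuals of each fit are resampled with
    replacement, added back to the fitted curves, and both models refitted
    (initialized at the point estimates); the interval is the percentile
    interval of the resulting ratios.
    """
    for name, fit in (("reference", fit_reference), ("test", fit_test)):
        if not fit.converged:
            raise ValueError(f"{name} fit did not converge; fold change undefined")
    ratio = fit_reference.ic50 / fit_test.ic50
    rng = np.random.default_rng(seed)
    ratios = []
    for _ in range(n_boot):
        pair = []
        for fit in (fit_reference, fit_test):
            resid = fit.residuals()
            y = fit.fitted() + rng.choice(resid, size=resid.size, replace=True)
            y = np.clip(y, 0.0, VIABILITY_CEILING)
            boot = DoseResponseModel(fit.model.conc, y).fit(start=fit.params)
            pair.append(boot)
        if pair[0].converged and pair[1].converged:
            ratios.append(pair[0].ic50 / pair[1].ic50)
    if not ratios:
        raise RuntimeError("no bootstrap replicate converged")
    lo, hi = np.percentile(ratios, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return FoldChangeResult(float(ratio), float(lo), float(hi), len(ratios))


class TTestResult(NamedTuple):
    statistic: float
    pvalue: float


def compare_populations(group_a, group_b) -> TTestResult:
    """Welch two-sample t-test on viability fractions at one concentration.

    Welch's unequal-variance form is the safer default and reduces to
    Student's test under equal variances. The fully degenerate case (both
    groups constant with equal means) returns t=0, p=1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            logger.info("degenerate t-test (zero variance, equal means): p = 1 by convention")
            return TTestResult(0.0, 1.0)
        return TTestResult(float(np.sign(a.mean() - b.mean()) * np.inf), 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(float(t), float(p))


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment for the optional multiple-testing flag."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    adjusted = np.empty_like(p)
    running = 0.0
    m = p.size
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted
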