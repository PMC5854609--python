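"""Functional T-cell assay analysis.

Four assay readouts are handled:

* **ELISpot positivity** — a condition is positive when its mean spot count
  strictly exceeds the negative-control ("No Ag") mean plus a multiple
  (default 3) of the negative control's sample standard deviation.
* **ICS polyfunctionality** — background-subtracted frequencies of the 7
  non-empty IFNγ/TNFα/IL-2 combinations among cytokine-producing CD8 cells.
* **Functional avidity** — EC50 of a four-parameter log-logistic (4PL)
  dose–response curve, with a residual-bootstrap confidence interval.
* **Specific lysis** — the chromium-release formula
  100 × (experimental − spontaneous) / (total − spontaneous).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

CYTOKINES = ("IFNg", "TNFa", "IL2")
#: the 7 non-empty subsets of {IFNγ, TNFα, IL-2}, triple first
COMBINATIONS: tuple[tuple[str, ...], ...] = tuple(
    combo
    for size in (3, 2, 1)
    for combo in itertools.combinations(CYTOKINES, size)
)


@dataclass(frozen=True)
class ElispotPlate:
    """Replicate spot counts for one stimulation condition."""

    condition_label: str
    replicate_spot_counts: tuple[int, ...]
    cells_per_well: int = 100_000

    def __post_init__(self):
        object.__setattr__(self, "replicate_spot_counts", tuple(int(c) for c in self.replicate_spot_counts))
        if any(c < 0 for c in self.replicate_spot_counts):
            raise ValueError(f"{self.condition_label}: negative spot count")
        if self.cells_per_well <= 0:
            raise ValueError("cells_per_well must be positive")


@dataclass(frozen=True)
class ResponseCall:
    condition_label: str
    mean_spots: float
    neg_mean: float
    neg_sd: float
    threshold: float
    positive: bool
    warning: str | None = None


def call_elispot(
    conditions: Iterable[ElispotPlate],
    negative_label: str = "No Ag",
    multiplier: float = 3.0,
    viability_label: str = "PHA",
) -> list[ResponseCall]:
    """Call positivity per condition against the plate's negative control.

    The threshold is neg_mean + multiplier * sd(neg), with the sample
    (n-1 denominator) standard deviation; positivity is the strict
    inequality mean > threshold, so an all-zero plate is never positive.
    The viability control (PHA) is reported but excluded from calling, as is
    the negative control itself. Conditions with fewer than 2 replicates
    receive a call flagged with a warning.
    """
    plates = list(conditions)
    negatives = [p for p in plates if p.condition_label == negative_label]
    if not negatives:
        raise ValueError(f"no negative control condition {negative_label!r} found")
    neg_counts = np.concatenate([np.asarray(p.replicate_spot_counts, dtype=float) for p in negatives])
    if neg_counts.size < 2:
        raise ValueError("negative control must have at least 2 replicates")
    neg_mean = float(neg_counts.mean())
    neg_sd = float(neg_counts.std(ddof=1))
    threshold = neg_mean + multiplier * neg_sd

    calls = []
    for plate in plates:
        if plate.condition_label == negative_label:
            continue
        counts = np.asarray(plate.replicate_spot_counts, dtype=float)
        mean = float(counts.mean())
        warning = None
        if plate.condition_label == viability_label:
            warning = "viability control, excluded from response calling"
            positive = False
        else:
            if counts.size < 2:
                warning = "fewer than 2 replicates"
            positive = mean > threshold
        calls.append(
            ResponseCall(
                condition_label=plate.condition_label,
                mean_spots=mean,
                neg_mean=neg_mean,
                neg_sd=neg_sd,
                threshold=threshold,
                positive=positive,
                warning=warning,
            )
        )
    return calls


@dataclass(frozen=True)
class IcsSummary:
    """Background-subtracted cytokine-combination frequencies.

    ``frequencies`` maps each of the 7 non-empty IFNγ/TNFα/IL-2 subsets
    (keys like ``"IFNg+TNFa+IL2"``) to its fraction of responding cells;
    they sum to 1 unless the summary is flagged empty.
    """

    frequencies: dict
    total_events: int
    n_triple: int
    n_double: int
    n_single: int
    empty: bool = False


def _combo_key(combo: tuple[str, ...]) -> str:
    return "+".join(combo)


def _combo_fractions(events: np.ndarray) -> dict[tuple[str, ...], float]:
    n = len(events)
    fractions = {}
    for combo in COMBINATIONS:
        mask = np.ones(n, dtype=bool)
        for i, cyt in enumerate(CYTOKINES):
            want = cyt in combo
            mask &= events[:, i] == want
        fractions[combo] = mask.sum() / n if n else 0.0
    return fractions


def decompose_polyfunctionality(
    events: np.ndarray,
    background_events: np.ndarray,
) -> IcsSummary:
    """Decompose stimulated-well events into the 7 cytokine combinations.

    ``events`` and ``background_events`` are boolean tables of shape
    (n_cells, 3) with columns (IFNγ, TNFα, IL-2). Per combination, the
    unstimulated fraction is subtracted from the stimulated one, negative
    values are floored at zero, and the result renormalized over the 7
    non-empty combinations. If nothing survives subtraction the summary is
    flagged empty.
    """
    events = np.asarray(events, dtype=bool)
    background_events = np.asarray(background_events, dtype=bool)
    for name, arr in (("events", events), ("background_events", background_events)):
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(f"{name} must have shape (n_cells, 3)")

    stim = _combo_fractions(events)
    bg = _combo_fractions(background_events)
    adjusted = {combo: max(stim[combo] - bg[combo], 0.0) for combo in COMBINATIONS}
    total = sum(adjusted.values())
    if total <= 0.0:
        return IcsSummary(
            frequencies={_combo_key(c): 0.0 for c in COMBINATIONS},
            total_events=int(len(events)),
            n_triple=0, n_double=0, n_single=0, empty=True,
        )
    freqs = {_combo_key(c): adjusted[c] / total for c in COMBINATIONS}
    by_size = {size: sum(adjusted[c] for c in COMBINATIONS if len(c) == size) for size in (1, 2, 3)}
    n_events = int(len(events))
    return IcsSummary(
        frequencies=freqs,
        total_events=n_events,
        n_triple=int(round(by_size[3] * n_events)),
        n_double=int(round(by_size[2] * n_events)),
        n_single=int(round(by_size[1] * n_events)),
    )


@dataclass(frozen=True)
class DoseResponseSeries:
    """Concentration/response pairs for one avidity titration.

    Concentrations are strictly positive and carry an opaque unit tag
    (no µg/mL↔molar conversion is attempted); at least 4 distinct
    concentrations are required for fitting.
    """

    concentrations: tuple[float, ...]
    responses: tuple[float, ...]
    unit: str = "ug/mL"
    series_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "concentrations", tuple(float(c) for c in self.concentrations))
        object.__setattr__(self, "responses", tuple(float(r) for r in self.responses))
        if len(self.concentrations) != len(self.responses):
            raise ValueError("concentrations and responses must have equal length")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be strictly positive")
        if any(r < 0 for r in self.responses):
            raise ValueError("responses must be non-negative")


@dataclass(frozen=True)
class AvidityEstimate:
    """EC50 and 4PL fit diagnostics; ``unit`` matches the input series."""

    ec50: float | None
    hill_slope: float | None
    lower: float | None
    upper: float | None
    bootstrap_ci: tuple[float, float] | None
    converged: bool
    unit: str = "ug/mL"
    extrapolated: bool = False
    unreliable: bool = False
    series_id: str = ""


def four_pl(log10_conc: np.ndarray, lower: float, upper: float,
            log10_ec50: float, hill: float) -> np.ndarray:
    """Four-parameter log-logistic curve on log10 concentration."""
    return lower + (upper - lower) / (1.0 + 10.0 ** ((log10_ec50 - log10_conc) * hill))


def _fit_4pl_params(x: np.ndarray, y: np.ndarray, pin_lower: bool):
    """Coarse grid over (EC50, slope) followed by local least squares."""
    span = y.max() - y.min()
    lo0 = 0.0 if pin_lower else float(y.min())
    up0 = float(y.max())
    grid_ec50 = np.linspace(x.min() - 1.0, x.max() + 1.0, 25)
    grid_hill = (0.3, 0.5, 1.0, 2.0, 4.0)
    best, best_sse = None, np.inf
    for le in grid_ec50:
        for h in grid_hill:
            pred = four_pl(x, lo0, up0, le, h)
            sse = float(((y - pred) ** 2).sum())
            if sse < best_sse:
                best_sse, best = sse, (le, h)
    le0, h0 = best

    if pin_lower:
        def resid(p):
            return four_pl(x, 0.0, p[0], p[1], p[2]) - y
        p0 = np.array([up0, le0, h0])
        lb = np.array([1e-12, x.min() - 6.0, 1e-3])
        ub = np.array([np.inf, x.max() + 6.0, 50.0])
    else:
        def resid(p):
            return four_pl(x, p[0], p[1], p[2], p[3]) - y
        p0 = np.array([lo0, up0, le0, h0])
        lb = np.array([-np.inf, 1e-12, x.min() - 6.0, 1e-3])
        ub = np.array([np.inf, np.inf, x.max() + 6.0, 50.0])
    sol = optimize.least_squares(resid, p0, bounds=(lb, ub), method="trf")
    if pin_lower:
        lower, (upper, log_ec50, hill) = 0.0, sol.x
    else:
        lower, upper, log_ec50, hill = sol.x
    return lower, upper, log_ec50, hill, sol.success


def fit_ec50(
    series: DoseResponseSeries,
    n_bootstrap: int = 1000,
    seed: int | None = None,
    pin_lower: bool = False,
    min_response_fraction: float = 0.2,
) -> AvidityEstimate:
    """Estimate functional avidity (EC50) from a dose–response titration.

    A 4PL curve is fitted on log10 concentration: coarse grid search over
    EC50 and Hill slope for initialization, then bounded least squares.
    The bootstrap CI resamples residuals with the given seed (percentile
    method). Series whose response range is below ``min_response_fraction``
    of the maximum response are flagged unreliable and not fitted;
    non-convergence is reported via ``converged``, never as a silent NaN.
    """
    x = np.log10(np.asarray(series.concentrations, dtype=float))
    y = np.asarray(series.responses, dtype=float)
    if len(set(series.concentrations)) < 4:
        raise ValueError("at least 4 distinct concentrations are required for fitting")

    ymax = y.max()
    if ymax <= 0 or (ymax - y.min()) < min_response_fraction * ymax:
        return AvidityEstimate(
            ec50=None, hill_slope=None, lower=None, upper=None,
            bootstrap_ci=None, converged=False, unit=series.unit,
            unreliable=True, series_id=series.series_id,
        )

    lower, upper, log_ec50, hill, ok = _fit_4pl_params(x, y, pin_lower)
    ec50 = float(10.0 ** log_ec50)
    extrapolated = not (min(series.concentrations) <= ec50 <= max(series.concentrations))

    ci = None
    if ok and n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        fitted = four_pl(x, lower, upper, log_ec50, hill)
        residuals = y - fitted
        boot = []
        for _ in range(n_bootstrap):
            y_star = fitted + rng.choice(residuals, size=len(residuals), replace=True)
            y_star = np.clip(y_star, 0.0, None)
            try:
                _, _, le_star, _, ok_star = _fit_4pl_params(x, y_star, pin_lower)
            except Exception:
                continue
            if ok_star:
                boot.append(10.0 ** le_star)
        if len(boot) >= max(10, n_bootstrap // 2):
            ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))

    return AvidityEstimate(
        ec50=ec50, hill_slope=float(hill), lower=float(lower), upper=float(upper),
        bootstrap_ci=ci, converged=bool(ok), unit=series.unit,
        extrapolated=extrapolated, series_id=series.series_id,
    )


def compare_avidity(
    groups: dict[str, Sequence[AvidityEstimate | float]],
    normality_alpha: float = 0.05,
) -> dict:
    """Compare functional avidity between labeled groups (e.g. TIL vs PBL).

    EC50s are compared on the log10 scale with a two-tailed t-test; if a
    Shapiro normality pre-check fails for either group (at
    ``normality_alpha``) the Mann–Whitney U test is used instead. Reports
    the median EC50 per group and, for two groups, their ratio in insertion
    order.
    """
    def _ec50s(values):
        out = []
        for v in values:
            ec = v.ec50 if isinstance(v, AvidityEstimate) else float(v)
            if ec is None:
                continue
            out.append(ec)
        return np.asarray(out, dtype=float)

    data = {label: _ec50s(vals) for label, vals in groups.items()}
    for label, vals in data.items():
        if len(vals) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 estimates")
    if len(data) != 2:
        raise ValueError("exactly two groups are required")
    (la, a), (lb, b) = data.items()
    log_a, log_b = np.log10(a), np.log10(b)

    normal = True
    for arr in (log_a, log_b):
        if len(arr) >= 3 and np.ptp(arr) > 0:
            if stats.shapiro(arr).pvalue < normality_alpha:
                normal = False
    if normal:
        test_name = "t-test"
        if np.ptp(log_a) == 0 and np.ptp(log_b) == 0 and log_a.mean() == log_b.mean():
            pvalue = 1.0  # identical degenerate groups
        else:
            pvalue = float(stats.ttest_ind(log_a, log_b).pvalue)
    else:
        test_name = "mann-whitney"
        pvalue = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)

    med_a, med_b = float(np.median(a)), float(np.median(b))
    return {
        "test": test_name,
        "pvalue": pvalue,
        "medians": {la: med_a, lb: med_b},
        "median_ratio": med_a / med_b if med_b > 0 else float("inf"),
    }


@dataclass(frozen=True)
class KillingAssay:
    """Chromium-release counts for one specific-lysis measurement."""

    experimental_release: float
    spontaneous_release: float
    total_release: float

    def __post_init__(self):
        if not self.total_release > self.spontaneous_release:
            raise ValueError("total_release must exceed spontaneous_release")


@dataclass(frozen=True)
class LysisResult:
    percent: float
    out_of_range: bool


def specific_lysis(assay: KillingAssay) -> LysisResult:
    """Percent specific lysis: 100 × (exp − spont) / (total − spont).

    Values outside [0, 100] can occur through measurement noise; they are
    returned as-is but flagged.
    """
    pct = 100.0 * (assay.experimental_release - assay.spontaneous_release) / (
        assay.total_release - assay.spontaneous_release
    )
    return LysisResult(percent=pct, out_of_range=not 0.0 <= pct <= 100.0)
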