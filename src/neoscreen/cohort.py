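"""Cohort-level aggregation: response prevalence, PBL/TIL discordance and
association statistics.

A *validated response* is a neo-epitope that is ELISpot-positive in at least
one compartment and confirmed by at least one orthogonal assay (multimer
staining and/or ICS); the orthogonal requirement can be relaxed for
exploratory runs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

COMPARTMENTS = ("PBL", "TIL_conventional", "TIL_primed")
ORTHOGONAL_ASSAYS = ("multimer", "ICS")


@dataclass(frozen=True)
class NeoepitopeResponse:
    """One validated neo-epitope response in one patient."""

    patient_id: str
    label: str
    compartments_positive: frozenset
    validation_assays: frozenset

    def __post_init__(self):
        object.__setattr__(self, "compartments_positive", frozenset(self.compartments_positive))
        object.__setattr__(self, "validation_assays", frozenset(self.validation_assays))
        if not self.compartments_positive:
            raise ValueError(f"{self.patient_id}/{self.label}: no positive compartment")
        bad = self.compartments_positive - set(COMPARTMENTS)
        if bad:
            raise ValueError(f"unknown compartments {sorted(bad)}")


def build_validated_responses(
    elispot_positive: Iterable[tuple[str, str, str]],
    orthogonal: Iterable[tuple[str, str, str]],
    require_orthogonal: bool = True,
) -> list[NeoepitopeResponse]:
    """Combine ELISpot positives with orthogonal confirmations.

    ``elispot_positive`` holds (patient, neo-epitope label, compartment)
    triples; ``orthogonal`` holds (patient, label, assay) with assay in
    {multimer, ICS}. With ``require_orthogonal`` (the default), a response is
    listed only when both an ELISpot-positive compartment and at least one
    orthogonal assay exist for the (patient, label) pair.
    """
    compartments: dict[tuple[str, str], set] = {}
    for patient, label, compartment in elispot_positive:
        if compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {compartment!r}")
        compartments.setdefault((patient, label), set()).add(compartment)
    validations: dict[tuple[str, str], set] = {}
    for patient, label, assay in orthogonal:
        if assay not in ORTHOGONAL_ASSAYS:
            raise ValueError(f"unknown orthogonal assay {assay!r}")
        validations.setdefault((patient, label), set()).add(assay)

    responses = []
    for key in sorted(compartments):
        assays = validations.get(key, set())
        if require_orthogonal and not assays:
            continue
        patient, label = key
        responses.append(NeoepitopeResponse(
            patient_id=patient, label=label,
            compartments_positive=frozenset(compartments[key]),
            validation_assays=frozenset({"ELISpot"} | assays),
        ))
    return responses


def summarize_prevalence(
    responses: Iterable[NeoepitopeResponse],
    roster: dict[str, set],
) -> dict:
    """Patients with >=1 validated response per compartment, over the roster.

    The roster maps compartment -> the set of patients actually evaluated in
    it; denominators come from the roster, never from the response list
    (blood and tumor compartments are typically evaluated in different
    numbers of patients). A response for a patient absent from the roster of
    its compartment is an error.
    """
    responders: dict[str, set] = {c: set() for c in roster}
    for resp in responses:
        for compartment in resp.compartments_positive:
            if compartment not in roster:
                raise ValueError(f"compartment {compartment!r} missing from roster")
            if resp.patient_id not in roster[compartment]:
                raise ValueError(
                    f"patient {resp.patient_id!r} has a {compartment} response "
                    "but is not on that compartment's roster"
                )
            responders[compartment].add(resp.patient_id)
    out = {}
    for compartment, evaluated in roster.items():
        n_pos = len(responders[compartment])
        n_eval = len(evaluated)
        out[compartment] = {
            "responders": n_pos,
            "evaluated": n_eval,
            "fraction": n_pos / n_eval if n_eval else 0.0,
        }
    return out


def discordance_landscape(
    responses: Iterable[NeoepitopeResponse],
    til_compartments: Sequence[str] = ("TIL_conventional",),
) -> dict:
    """Categorize each neo-epitope response as PBL-only / TIL-only / both.

    ``til_compartments`` selects which TIL culture counts as the TIL arm;
    passing ("TIL_conventional", "TIL_primed") gives the primed-culture
    variant of the landscape. Categories are mutually exclusive and
    exhaustive over the responses.
    """
    categories = {}
    for resp in responses:
        pbl = "PBL" in resp.compartments_positive
        til = bool(resp.compartments_positive & set(til_compartments))
        if pbl and til:
            cat = "both"
        elif pbl:
            cat = "PBL-only"
        elif til:
            cat = "TIL-only"
        else:
            cat = "none"
        categories[(resp.patient_id, resp.label)] = cat
    counts = Counter(categories.values())
    return {
        "per_response": categories,
        "counts": {cat: counts.get(cat, 0) for cat in ("PBL-only", "TIL-only", "both", "none")},
        "n_both": counts.get("both", 0),
        "n_exclusive": counts.get("PBL-only", 0) + counts.get("TIL-only", 0),
    }


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def fisher_exact(table: ContingencyTable2x2, compute_odds_ratio: bool = True) -> dict:
    """Two-sided Fisher's exact test with conditional odds ratio.

    The two-sided p-value follows the point-probability convention: the sum
    of hypergeometric probabilities of all tables with the observed margins
    that are no more probable than the observed one. Tables whose
    probability equals the observed one up to a relative slack of 1e-7 are
    included, so floating-point ties in symmetric tables resolve the way
    exact-test software conventionally resolves them. A zero margin makes
    the table degenerate: p = 1 and the odds ratio is flagged undefined.
    The conditional (non-central hypergeometric MLE) odds ratio is computed
    unless ``compute_odds_ratio`` is off.
    """
    arr = table.as_array()
    row = arr.sum(axis=1)
    col = arr.sum(axis=0)
    if 0 in row or 0 in col:
        return {"pvalue": 1.0, "odds_ratio": None, "odds_ratio_defined": False}
    n = int(arr.sum())
    r1, c1, a = int(row[0]), int(col[0]), int(arr[0, 0])
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    pvalue = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    pvalue = min(pvalue, 1.0)
    out = {"pvalue": pvalue, "odds_ratio": None, "odds_ratio_defined": True}
    if compute_odds_ratio:
        out["odds_ratio"] = float(stats.contingency.odds_ratio(arr, kind="conditional").statistic)
    return out


def load_association(
    mutational_load: Sequence[float],
    neoepitope_load: Sequence[float],
    n_permutations: int = 999,
    seed: int | None = None,
) -> dict:
    """Association between mutational load and predicted neo-epitope load.

    Ordinary least squares of neo-epitope load on mutational load with the
    usual two-sided t-test on the slope, plus a seeded permutation p-value
    (proportion of label permutations with |slope| >= observed, with the
    +1 correction) as a distribution-free companion.
    """
    x = np.asarray(mutational_load, dtype=float)
    y = np.asarray(neoepitope_load, dtype=float)
    if len(x) != len(y):
        raise ValueError("input lengths differ")
    if len(x) < 3:
        raise ValueError("at least 3 patients are required")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in mutational load")
    fit = stats.linregress(x, y)
    rng = np.random.default_rng(seed)
    observed = abs(fit.slope)
    hits = 0
    for _ in range(n_permutations):
        perm_slope = stats.linregress(x, rng.permutation(y)).slope
        if abs(perm_slope) >= observed:
            hits += 1
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "pvalue": float(fit.pvalue),
        "r": float(fit.rvalue),
        "permutation_pvalue": (hits + 1) / (n_permutations + 1),
        "n_permutations": n_permutations,
    }
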