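"""End-to-end orchestration: table-level wrappers chaining the stages.

These functions operate on the tabular representations the I/O layer reads
and writes, so the CLI subcommands and programmatic use share one code path:
enumerate -> filter -> call ELISpot -> validate -> cohort report.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .assays import ElispotPlate, call_elispot
from .cohort import (
    NeoepitopeResponse,
    build_validated_responses,
    discordance_landscape,
    load_association,
    summarize_prevalence,
)
from .config import RunConfig
from .io import ProteomeRecord
from .neoepitope import (
    AllelePrediction,
    FilteredCandidate,
    SomaticMutation,
    apply_affinity_filter,
    candidates_to_frame,
    enumerate_mutant_peptides,
    predicted_load,
)


def enumerate_cohort(
    proteome: dict[str, ProteomeRecord],
    mutations: Iterable[SomaticMutation],
    lengths: Iterable[int] = (9, 10),
) -> tuple[dict[str, list], dict[str, int]]:
    """Enumerate candidates per patient; returns (by_patient, tallies)."""
    by_patient: dict[str, list] = {}
    tallies = {"rejected_nonstandard": 0}
    for mut in mutations:
        protein = proteome.get(mut.protein_id)
        if protein is None:
            raise ValueError(f"mutation {mut.label}: unknown protein {mut.protein_id}")
        cands, n_rej = enumerate_mutant_peptides(protein, mut, lengths)
        tallies["rejected_nonstandard"] += n_rej
        by_patient.setdefault(mut.patient_id, []).extend(cands)
    return by_patient, tallies


def filter_cohort(
    candidates_by_patient: dict[str, list],
    predictions: Iterable[AllelePrediction],
    patient_alleles: dict[str, set],
    threshold_nm: float = 500.0,
) -> tuple[dict[str, list[FilteredCandidate]], dict]:
    """Apply the affinity filter per patient and summarize predicted load."""
    predictions = list(predictions)
    filtered: dict[str, list[FilteredCandidate]] = {}
    for patient, cands in candidates_by_patient.items():
        hits, _ = apply_affinity_filter(
            cands, predictions, patient_alleles[patient], threshold_nm
        )
        filtered[patient] = hits
    return filtered, predicted_load(filtered)


def elispot_calls_from_frame(
    df: pd.DataFrame,
    multiplier: float = 3.0,
    negative_label: str = "No Ag",
) -> pd.DataFrame:
    """Call ELISpot positivity for every (patient, compartment) plate.

    ``df`` holds one row per replicate well with columns patient_id,
    compartment, condition, replicate, spots, cells_per_well.
    """
    rows = []
    for (patient, compartment), group in df.groupby(["patient_id", "compartment"], sort=True):
        plates = [
            ElispotPlate(
                condition_label=str(cond),
                replicate_spot_counts=tuple(sub["spots"].astype(int)),
                cells_per_well=int(sub["cells_per_well"].iloc[0]),
            )
            for cond, sub in group.groupby("condition", sort=True)
        ]
        for call in call_elispot(plates, negative_label=negative_label, multiplier=multiplier):
            rows.append({
                "patient_id": patient, "compartment": compartment,
                "condition": call.condition_label, "mean_spots": call.mean_spots,
                "neg_mean": call.neg_mean, "neg_sd": call.neg_sd,
                "threshold": call.threshold, "positive": call.positive,
                "warning": call.warning or "",
            })
    return pd.DataFrame(rows)


def validated_responses_from_frames(
    calls: pd.DataFrame,
    validations: pd.DataFrame | None,
    require_orthogonal: bool = True,
    viability_label: str = "PHA",
) -> list[NeoepitopeResponse]:
    """Cross ELISpot-positive conditions with the orthogonal-assay table."""
    positives = [
        (str(r.patient_id), str(r.condition), str(r.compartment))
        for r in calls.itertuples()
        if r.positive and r.condition != viability_label
    ]
    orthogonal = []
    if validations is not None and len(validations):
        orthogonal = [
            (str(r.patient_id), str(r.label), str(r.assay))
            for r in validations.itertuples()
        ]
    return build_validated_responses(positives, orthogonal, require_orthogonal=require_orthogonal)


def cohort_report(
    proteome: dict[str, ProteomeRecord],
    mutations: list[SomaticMutation],
    predictions: list[AllelePrediction],
    patient_alleles: dict[str, set],
    elispot: pd.DataFrame,
    validations: pd.DataFrame | None,
    roster: pd.DataFrame,
    config: RunConfig,
) -> dict:
    """Run the full chain and assemble the cohort-level JSON report."""
    by_patient, enum_tallies = enumerate_cohort(proteome, mutations, config.peptide_lengths)
    filtered, load = filter_cohort(by_patient, predictions, patient_alleles,
                                   config.affinity_threshold_nm)
    calls = elispot_calls_from_frame(elispot, multiplier=config.elispot_sd_multiplier)
    responses = validated_responses_from_frames(calls, validations)
    roster_map = {
        str(c): set(sub["patient_id"].astype(str))
        for c, sub in roster.groupby("compartment")
    }
    prevalence = summarize_prevalence(responses, roster_map)
    landscape = discordance_landscape(responses)

    mut_load = {}
    for mut in mutations:
        mut_load[mut.patient_id] = mut_load.get(mut.patient_id, 0) + 1
    patients = sorted(mut_load)
    association = None
    if len(patients) >= 3:
        association = load_association(
            [mut_load[p] for p in patients],
            [load["per_patient"].get(p, {"unique_peptides": 0})["unique_peptides"] for p in patients],
            seed=config.seed,
        )

    return {
        "config": config.to_dict(),
        "enumeration": {"rejected_nonstandard": enum_tallies["rejected_nonstandard"]},
        "predicted_load": load,
        "responses": [
            {"patient_id": r.patient_id, "label": r.label,
             "compartments_positive": sorted(r.compartments_positive),
             "validation_assays": sorted(r.validation_assays)}
            for r in responses
        ],
        "prevalence": prevalence,
        "discordance": {
            "counts": landscape["counts"],
            "n_both": landscape["n_both"],
            "n_exclusive": landscape["n_exclusive"],
        },
        "load_association": association,
    }
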