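"""Synthetic cohort generator.

Produces a fully self-contained cohort with the statistical structure the
pipeline assumes: ~19 patients carrying 10–129 somatic missense mutations
each, a random proteome, deterministic toy peptide–HLA affinities in which a
small minority of candidates pass the 500 nM filter, ELISpot plates with
planted responder and null wells, ICS event tables, 4PL dose–response series
with known EC50s, chromium-release counts with planted lysis, and
multi-compartment TCR repertoires with neo-epitope-specific clonotypes
spiked at controlled frequencies spanning the assay's limit of detection.

Every planted quantity is recorded in a truth document so each pipeline
stage can be checked against what was simulated. All randomness flows from
a single seed; reruns are byte-identical.

The toy affinity model is an arbitrary fixed scoring scheme with no
biological content: it exists so the filtering stage has deterministic,
realistic-looking inputs, not to predict binding.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .assays import CYTOKINES
from .io import ProteomeRecord, write_affinity_table, write_repertoire_table
from .neoepitope import (
    STANDARD_AA,
    AllelePrediction,
    SomaticMutation,
    enumerate_mutant_peptides,
)
from .repertoire import ClonotypeRead, SegmentReference

AA_LIST = sorted(STANDARD_AA)
AA_INDEX = {aa: i for i, aa in enumerate(AA_LIST)}

_FWD = CodonTable.standard_dna_table.forward_table
CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in sorted(_FWD.items()):
    CODONS_BY_AA.setdefault(aa, []).append(codon)
STOP_CODONS = tuple(sorted(CodonTable.standard_dna_table.stop_codons))


class ToyAffinityModel:
    """Deterministic stand-in scoring of (peptide, allele) -> IC50-like nM.

    Each (allele, length) pair owns a position-specific residue score matrix
    drawn once from a seeded generator; the IC50 is
    ``median_nm * exp(sum of scores)`` so log-IC50 is centered on
    log(median_nm) with standard deviation ``log_sigma``. With the defaults
    (median 12 µM, sigma 1.22 natural-log units) about 0.5% of random
    (peptide, allele) pairs fall at or under 500 nM, i.e. a few percent of
    peptides bind at least one of six patient alleles — a minority, as in
    real missense candidate sets. The same inputs always give the same
    value.
    """

    def __init__(self, seed: int = 0, median_nm: float = 12000.0, log_sigma: float = 1.22):
        self.seed = seed
        self.median_nm = median_nm
        self.log_sigma = log_sigma
        self._matrices: dict[tuple[str, int], np.ndarray] = {}

    def _matrix(self, allele: str, length: int) -> np.ndarray:
        key = (allele, length)
        if key not in self._matrices:
            h = zlib.crc32(f"{self.seed}:{allele}:{length}".encode()) & 0x7FFFFFFF
            rng = np.random.default_rng(h)
            self._matrices[key] = rng.normal(
                0.0, self.log_sigma / np.sqrt(length), size=(length, len(AA_LIST))
            )
        return self._matrices[key]

    def ic50(self, peptide: str, allele: str) -> float:
        mat = self._matrix(allele, len(peptide))
        z = sum(mat[i, AA_INDEX[aa]] for i, aa in enumerate(peptide))
        return float(self.median_nm * np.exp(z))


@dataclass
class SyntheticCohortConfig:
    """Knobs of the synthetic cohort.

    Defaults mirror the study conditions the pipeline targets: 19 patients,
    10–129 mutations each, 9/10-mer candidates, six HLA alleles per patient,
    triplicate ELISpot wells with a No Ag negative and PHA viability
    control, dose–response titrations from 30 µg/mL down to 0.3 pg/mL, and
    three repertoire compartments at 1e5 reads (a desk-scale stand-in for
    the study's 1e6–3e6 read depth; LOD checks scale accordingly).
    """

    seed: int = 0
    n_patients: int = 19
    mutation_bounds: tuple = (10, 129)
    mutation_distribution: str = "uniform"  # or "lognormal" (median ~69)
    n_proteins: int = 80
    protein_length_range: tuple = (150, 500)
    peptide_lengths: tuple = (9, 10)
    alleles_per_patient: int = 6
    allele_pool_size: int = 12
    affinity_threshold_nm: float = 500.0
    affinity_median_nm: float = 12000.0
    affinity_log_sigma: float = 1.22
    # ELISpot
    elispot_neg_mean: float = 3.0
    elispot_dispersion: float = 5.0
    elispot_effect: float = 60.0
    elispot_replicates: int = 3
    cells_per_well: int = 100_000
    # planted responders
    n_pbl_responders: int = 6
    n_til_patients: int = 14
    n_til_responders: int = 4
    max_epitopes_per_responder: int = 3
    # ICS
    ics_events: int = 5000
    ics_responding_fraction: float = 0.05
    ics_background_fraction: float = 0.005
    # dose-response
    dose_max_ugml: float = 30.0
    n_doses: int = 9  # 10-fold dilutions: 30 ug/mL .. 0.3 pg/mL
    ec50_range_ugml: tuple = (1e-4, 1.0)
    response_max: float = 100.0
    response_noise_cv: float = 0.10
    # killing
    lysis_fractions: tuple = (0.2, 0.5, 0.8)
    # repertoires
    repertoire_compartments: tuple = ("PBL", "tumor", "TIL")
    reads_per_compartment: int = 100_000
    n_background_clonotypes: int = 300
    spike_frequencies: tuple = (1e-6, 1e-5, 1e-4, 1e-3, 1e-2)
    synonymous_variant_rate: float = 0.3
    outframe_fraction: float = 0.05
    n_injected_singletons: int = 20
    n_v_segments: int = 12
    n_j_segments: int = 6

    def __post_init__(self):
        if self.n_patients < 1 or self.n_proteins < 1:
            raise ValueError("counts must be positive")
        lo, hi = self.mutation_bounds
        if not 1 <= lo <= hi:
            raise ValueError("invalid mutation_bounds")
        if hi > self.n_proteins * self.protein_length_range[0]:
            raise ValueError("more mutations requested than available residues")
        for f in self.spike_frequencies:
            if not 0.0 < f < 1.0:
                raise ValueError("spike frequencies must lie in (0, 1)")
        if self.mutation_distribution not in ("uniform", "lognormal"):
            raise ValueError("mutation_distribution must be 'uniform' or 'lognormal'")


@dataclass
class SyntheticCohort:
    """In-memory synthetic cohort plus the ground-truth document."""

    config: SyntheticCohortConfig
    proteome: dict[str, ProteomeRecord]
    mutations: list[SomaticMutation]
    patient_alleles: dict[str, set]
    predictions: list[AllelePrediction]
    truth: dict
    elispot: pd.DataFrame | None = None
    ics: pd.DataFrame | None = None
    dose_response: pd.DataFrame | None = None
    killing: pd.DataFrame | None = None
    validations: pd.DataFrame | None = None
    roster: pd.DataFrame | None = None
    repertoires: dict[str, list[ClonotypeRead]] | None = None
    segment_reference: SegmentReference | None = None

    @property
    def patients(self) -> list[str]:
        return sorted(self.patient_alleles)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AA_LIST, size=length))


def _mutation_counts(rng: np.random.Generator, cfg: SyntheticCohortConfig) -> np.ndarray:
    lo, hi = cfg.mutation_bounds
    if cfg.mutation_distribution == "uniform":
        return rng.integers(lo, hi + 1, size=cfg.n_patients)
    # discretized lognormal with median ~69, clipped to the bounds
    draws = np.exp(rng.normal(np.log(69.0), 0.55, size=cfg.n_patients))
    return np.clip(np.round(draws).astype(int), lo, hi)


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate proteome, mutations, alleles, affinities and the truth doc.

    Truth records, per patient: HLA alleles, mutation labels, the planted
    binder list (every enumerated mutant peptide scoring <= the threshold on
    a patient allele), and the planted validated responses with their
    compartments and orthogonal assays.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    lengths = rng.integers(cfg.protein_length_range[0], cfg.protein_length_range[1] + 1,
                           size=cfg.n_proteins)
    proteome = {}
    for i in range(cfg.n_proteins):
        pid = f"PROT{i:03d}"
        proteome[pid] = ProteomeRecord(protein_id=pid, sequence=_random_protein(rng, int(lengths[i])))
    protein_ids = sorted(proteome)

    allele_pool = [f"HLA-{chr(65 + i % 3)}*{i + 1:02d}:01" for i in range(cfg.allele_pool_size)]
    patients = [f"P{i + 1:02d}" for i in range(cfg.n_patients)]
    patient_alleles = {
        p: {str(a) for a in rng.choice(allele_pool, size=cfg.alleles_per_patient, replace=False)}
        for p in patients
    }

    counts = _mutation_counts(rng, cfg)
    mutations: list[SomaticMutation] = []
    for patient, n_mut in zip(patients, counts):
        seen: set[tuple[str, int]] = set()
        while len(seen) < n_mut:
            pid = protein_ids[rng.integers(len(protein_ids))]
            pos = int(rng.integers(1, len(proteome[pid]) + 1))
            if (pid, pos) in seen:
                continue
            seen.add((pid, pos))
            ref = proteome[pid].sequence[pos - 1]
            alt = AA_LIST[rng.integers(len(AA_LIST))]
            while alt == ref:
                alt = AA_LIST[rng.integers(len(AA_LIST))]
            mutations.append(SomaticMutation(
                patient_id=patient, gene=pid.replace("PROT", "GENE"),
                protein_id=pid, position=pos, ref_aa=ref, alt_aa=alt,
            ))

    model = ToyAffinityModel(seed=cfg.seed, median_nm=cfg.affinity_median_nm,
                             log_sigma=cfg.affinity_log_sigma)
    predictions: list[AllelePrediction] = []
    seen_pairs: set[tuple[str, str]] = set()
    binders: dict[str, list[dict]] = {p: [] for p in patients}
    candidates_per_patient: dict[str, int] = {p: 0 for p in patients}
    for mut in mutations:
        cands, _ = enumerate_mutant_peptides(proteome[mut.protein_id], mut, cfg.peptide_lengths)
        candidates_per_patient[mut.patient_id] += len(cands)
        for cand in cands:
            for allele in sorted(patient_alleles[mut.patient_id]):
                pair = (cand.mutant_seq, allele)
                ic50 = model.ic50(cand.mutant_seq, allele)
                if pair not in seen_pairs:
                    seen_pairs.add(pair)
                    predictions.append(AllelePrediction(peptide=cand.mutant_seq,
                                                        allele=allele, ic50_nm=ic50))
                if ic50 <= cfg.affinity_threshold_nm:
                    binders[mut.patient_id].append({
                        "label": mut.label, "peptide": cand.mutant_seq,
                        "allele": allele, "ic50_nm": ic50,
                    })

    truth = {
        "schema_version": "1.0",
        "seed": int(cfg.seed),
        "patients": patients,
        "alleles": {p: sorted(patient_alleles[p]) for p in patients},
        "mutations_per_patient": {p: int(c) for p, c in zip(patients, counts)},
        "candidates_per_patient": candidates_per_patient,
        "binders": binders,
        "binder_peptides_per_patient": {
            p: sorted({b["peptide"] for b in binders[p]}) for p in patients
        },
    }
    _plant_responses(cfg, rng, truth)
    return SyntheticCohort(
        config=cfg, proteome=proteome, mutations=mutations,
        patient_alleles=patient_alleles, predictions=predictions, truth=truth,
    )


def _plant_responses(cfg: SyntheticCohortConfig, rng: np.random.Generator, truth: dict) -> None:
    """Choose responder patients/epitopes and the compartment landscape.

    The landscape mirrors the discordance structure of interest: one planted
    response positive in both blood and TIL, all others exclusive to one
    compartment.
    """
    patients = truth["patients"]
    til_roster = patients[:cfg.n_til_patients]
    labels_by_patient = {
        p: sorted({b["label"] for b in truth["binders"][p]}) for p in patients
    }
    eligible = [p for p in patients if labels_by_patient[p]]
    eligible_til = [p for p in til_roster if labels_by_patient[p]]

    responses: list[dict] = []
    used: set[tuple[str, str]] = set()

    def _pick_labels(patient: str, k: int) -> list[str]:
        avail = [l for l in labels_by_patient[patient] if (patient, l) not in used]
        k = min(k, len(avail))
        return [str(l) for l in rng.choice(avail, size=k, replace=False)] if k else []

    # the shared (both-compartment) response, when feasible
    overlap_patient = None
    if eligible_til and cfg.n_pbl_responders and cfg.n_til_responders:
        overlap_patient = eligible_til[int(rng.integers(len(eligible_til)))]
        shared = _pick_labels(overlap_patient, 1)
        if shared:
            used.add((overlap_patient, shared[0]))
            responses.append({"patient_id": overlap_patient, "label": shared[0],
                              "compartments": ["PBL", "TIL_conventional"]})

    def _fill(compartment: str, n_target: int, pool: list[str]) -> None:
        chosen = [overlap_patient] if overlap_patient else []
        others = [p for p in pool if p != overlap_patient]
        k = min(n_target - len(chosen), len(others))
        chosen += list(rng.choice(others, size=k, replace=False)) if k else []
        for patient in chosen:
            # the overlap patient already holds its shared response
            n_extra = int(rng.integers(1, cfg.max_epitopes_per_responder + 1))
            if patient == overlap_patient:
                n_extra -= 1
            for label in _pick_labels(patient, n_extra):
                used.add((patient, label))
                responses.append({"patient_id": patient, "label": label,
                                  "compartments": [compartment]})

    _fill("PBL", cfg.n_pbl_responders, eligible)
    _fill("TIL_conventional", cfg.n_til_responders, eligible_til)

    for resp in responses:
        choices = (["multimer"], ["ICS"], ["multimer", "ICS"])
        resp["orthogonal"] = list(choices[int(rng.integers(3))])

    truth["til_roster"] = til_roster
    truth["responses"] = responses
    truth["responder_set"] = sorted({(r["patient_id"], r["label"]) for r in responses})


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative-binomial counts with the given mean and size (dispersion) r."""
    r = dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def generate_assays(cohort: SyntheticCohort) -> None:
    """Generate ELISpot, ICS, dose–response and killing tables in place.

    ELISpot wells for non-responder conditions (and the No Ag negative) are
    overdispersed negative-binomial counts around the negative mean;
    planted responder wells are shifted by the configured effect, in the
    compartment(s) where the response was planted. Every planted response
    receives an ICS event table, one dose–response series with a known EC50,
    and one killing triple with a planted lysis fraction.
    """
    cfg = cohort.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    truth = cohort.truth
    positive = {(r["patient_id"], r["label"], c): True
                for r in truth["responses"] for c in r["compartments"]}

    rows = []
    compartment_rosters = {"PBL": truth["patients"], "TIL_conventional": truth["til_roster"]}
    for compartment, roster in compartment_rosters.items():
        for patient in roster:
            labels = sorted({b["label"] for b in truth["binders"][patient]})
            conditions = ["No Ag", "PHA"] + labels
            for condition in conditions:
                if condition == "PHA":
                    mean = 10 * cfg.elispot_effect
                elif positive.get((patient, condition, compartment)):
                    mean = cfg.elispot_neg_mean + cfg.elispot_effect
                else:
                    mean = cfg.elispot_neg_mean
                spots = _nb_draw(rng, mean, cfg.elispot_dispersion, cfg.elispot_replicates)
                for rep_i, s in enumerate(spots, start=1):
                    rows.append({"patient_id": patient, "compartment": compartment,
                                 "condition": condition, "replicate": rep_i,
                                 "spots": int(s), "cells_per_well": cfg.cells_per_well})
    cohort.elispot = pd.DataFrame(rows)

    # ICS: per planted response, per-combination event counts for the
    # stimulated and unstimulated (No Ag) wells
    ics_rows = []
    combo_bits = [(i, t, l) for i in (0, 1) for t in (0, 1) for l in (0, 1)]
    for resp in truth["responses"]:
        n = cfg.ics_events
        # stimulated: responding cells mostly polyfunctional
        combo_probs = {(1, 1, 1): 0.55, (1, 1, 0): 0.15, (1, 0, 1): 0.08,
                       (0, 1, 1): 0.05, (1, 0, 0): 0.10, (0, 1, 0): 0.04, (0, 0, 1): 0.03}
        for condition, responding in (("stim", cfg.ics_responding_fraction),
                                      ("No Ag", cfg.ics_background_fraction)):
            n_resp = rng.binomial(n, responding)
            combos = list(combo_probs)
            draws = rng.multinomial(n_resp, [combo_probs[c] for c in combos])
            counts = dict(zip(combos, draws))
            counts[(0, 0, 0)] = n - n_resp
            for (i, t, l) in combo_bits:
                ics_rows.append({"patient_id": resp["patient_id"], "label": resp["label"],
                                 "condition": condition, "ifng": i, "tnfa": t, "il2": l,
                                 "event_count": int(counts.get((i, t, l), 0))})
    cohort.ics = pd.DataFrame(ics_rows)

    # dose-response: 10-fold dilutions from dose_max, planted 4PL EC50s
    doses = cfg.dose_max_ugml / (10.0 ** np.arange(cfg.n_doses))
    dr_rows = []
    truth["ec50"] = {}
    lo_ec, hi_ec = cfg.ec50_range_ugml
    for resp in truth["responses"]:
        sid = f"{resp['patient_id']}:{resp['label']}"
        ec50 = float(np.exp(rng.uniform(np.log(lo_ec), np.log(hi_ec))))
        hill = 1.0
        clean = cfg.response_max / (1.0 + (ec50 / doses) ** hill)
        noisy = clean * (1.0 + cfg.response_noise_cv * rng.standard_normal(len(doses)))
        noisy = np.clip(noisy, 0.0, None)
        truth["ec50"][sid] = ec50
        for c, r in zip(doses, noisy):
            dr_rows.append({"series_id": sid, "concentration": float(c),
                            "unit": "ug/mL", "response": float(r)})
    cohort.dose_response = pd.DataFrame(dr_rows)

    # killing: planted lysis fractions, noise-free counts
    # orthogonal validation table (multimer / ICS confirmations) and the
    # per-compartment evaluation roster, as the cohort stage consumes them
    cohort.validations = pd.DataFrame(
        [{"patient_id": r["patient_id"], "label": r["label"], "assay": a}
         for r in truth["responses"] for a in r["orthogonal"]]
    )
    cohort.roster = pd.DataFrame(
        [{"compartment": "PBL", "patient_id": p} for p in truth["patients"]]
        + [{"compartment": "TIL_conventional", "patient_id": p} for p in truth["til_roster"]]
    )

    kill_rows = []
    truth["lysis"] = {}
    for k, resp in enumerate(truth["responses"]):
        sid = f"{resp['patient_id']}:{resp['label']}"
        frac = cfg.lysis_fractions[k % len(cfg.lysis_fractions)]
        spont, total = 200.0, 1200.0
        experimental = spont + frac * (total - spont)
        truth["lysis"][sid] = 100.0 * frac
        kill_rows.append({"series_id": sid, "experimental": experimental,
                          "spontaneous": spont, "total": total})
    cohort.killing = pd.DataFrame(kill_rows)


def _random_cdr3_nt(rng: np.random.Generator, existing: set) -> tuple[str, str]:
    """A random in-frame CDR3-like nucleotide sequence and its translation."""
    while True:
        length = int(rng.integers(10, 17))
        aa = "".join(rng.choice(AA_LIST, size=length))
        if aa in existing:
            continue
        existing.add(aa)
        nt = "".join(CODONS_BY_AA[a][rng.integers(len(CODONS_BY_AA[a]))] for a in aa)
        return nt, aa


def _synonymous_variant(rng: np.random.Generator, nt: str) -> str:
    """Re-pick one codon of an in-frame sequence synonymously (if possible)."""
    codons = [nt[i:i + 3] for i in range(0, len(nt), 3)]
    order = rng.permutation(len(codons))
    for idx in order:
        aa = _FWD[codons[idx]]
        alts = [c for c in CODONS_BY_AA[aa] if c != codons[idx]]
        if alts:
            codons[int(idx)] = alts[rng.integers(len(alts))]
            return "".join(codons)
    return nt


def generate_repertoires(cohort: SyntheticCohort) -> None:
    """Generate multi-compartment TCR repertoires with planted spike-ins.

    A shared pool of background clonotypes receives compartment-specific
    Zipf-like weights. Specific clonotypes are spiked at controlled
    frequencies, including deliberate absences that plant the blood/TIL
    discordance patterns: one clone present in tumor and TIL but absent from
    blood, one present in blood and tumor but absent from expanded TIL, one
    present everywhere, plus a ladder of tumor spikes spanning the
    configured frequencies around the limit of detection. Reads are sampled
    multinomially; synonymous nucleotide variants, out-of-frame reads and
    single-read clonotypes are injected to exercise the corresponding
    filters.
    """
    cfg = cohort.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    truth = cohort.truth

    v_names = [f"TRBV{i + 1}" for i in range(cfg.n_v_segments)]
    j_names = [f"TRBJ{i + 1}" for i in range(cfg.n_j_segments)]
    segment_ref = SegmentReference(
        v_order={n: i for i, n in enumerate(v_names)},
        j_order={n: i for i, n in enumerate(j_names)},
        chain="beta",
    )

    existing_aa: set = set()
    background = [_random_cdr3_nt(rng, existing_aa) for _ in range(cfg.n_background_clonotypes)]
    vj_of: dict[str, tuple[str, str]] = {}
    for _, aa in background:
        vj_of[aa] = (v_names[rng.integers(len(v_names))], j_names[rng.integers(len(j_names))])

    # spikes: named discordance scenarios + an LOD ladder in tumor
    spikes: list[dict] = []

    def _add_spike(name: str, freq_by_compartment: dict) -> None:
        nt, aa = _random_cdr3_nt(rng, existing_aa)
        vj_of[aa] = (v_names[rng.integers(len(v_names))], j_names[rng.integers(len(j_names))])
        spikes.append({"name": name, "nt": nt, "protein_seq": aa,
                       "frequencies": freq_by_compartment})

    _add_spike("til_tumor_only", {"PBL": 0.0, "tumor": 1e-2, "TIL": 1e-3})
    _add_spike("pbl_tumor_only", {"PBL": 1e-3, "tumor": 1e-4, "TIL": 0.0})
    _add_spike("shared_all", {"PBL": 1e-4, "tumor": 1e-4, "TIL": 1e-4})
    for i, f in enumerate(cfg.spike_frequencies):
        _add_spike(f"lod_ladder_{i}", {"PBL": 0.0, "tumor": float(f), "TIL": 0.0})

    repertoires: dict[str, list[ClonotypeRead]] = {}
    sampled_counts: dict[str, dict[str, int]] = {}
    for compartment in cfg.repertoire_compartments:
        depth = cfg.reads_per_compartment
        n_oof = int(rng.binomial(depth, cfg.outframe_fraction))
        n_singleton = min(cfg.n_injected_singletons, depth - n_oof)
        n_body = depth - n_oof - n_singleton

        spike_freqs = np.array([s["frequencies"].get(compartment, 0.0) for s in spikes])
        total_spike = spike_freqs.sum()
        zipf = 1.0 / (np.arange(1, len(background) + 1) ** 1.1)
        weights = rng.permutation(zipf)
        bg_probs = weights / weights.sum() * (1.0 - total_spike)
        probs = np.concatenate([bg_probs, spike_freqs])
        counts = rng.multinomial(n_body, probs / probs.sum())

        reads: list[ClonotypeRead] = []
        comp_sampled: dict[str, int] = {}
        pool = background + [(s["nt"], s["protein_seq"]) for s in spikes]
        for (nt, aa), count in zip(pool, counts):
            if count == 0:
                continue
            comp_sampled[aa] = int(count)
            v, j = vj_of[aa]
            if count >= 4 and rng.random() < cfg.synonymous_variant_rate:
                minor = int(count * 0.3)
                variants = [(nt, count - minor), (_synonymous_variant(rng, nt), minor)]
            else:
                variants = [(nt, count)]
            for seq, c in variants:
                if c > 0:
                    reads.append(ClonotypeRead(sequence_nt=seq, read_count=int(c),
                                               chain="beta", compartment=compartment,
                                               v_segment=v, j_segment=j))

        # out-of-frame reads: in-frame body with an early stop codon
        oof_left = n_oof
        while oof_left > 0:
            nt, aa = _random_cdr3_nt(rng, existing_aa)
            stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
            broken = nt[:3] + stop + nt[6:]
            chunk = int(min(oof_left, rng.integers(2, 200)))
            reads.append(ClonotypeRead(sequence_nt=broken, read_count=chunk,
                                       chain="beta", compartment=compartment))
            oof_left -= chunk

        for _ in range(n_singleton):
            nt, aa = _random_cdr3_nt(rng, existing_aa)
            v, j = vj_of.setdefault(aa, (v_names[rng.integers(len(v_names))],
                                         j_names[rng.integers(len(j_names))]))
            reads.append(ClonotypeRead(sequence_nt=nt, read_count=1,
                                       chain="beta", compartment=compartment,
                                       v_segment=v, j_segment=j))

        repertoires[compartment] = reads
        sampled_counts[compartment] = comp_sampled

    cohort.repertoires = repertoires
    cohort.segment_reference = segment_ref
    truth["spikes"] = [
        {"name": s["name"], "protein_seq": s["protein_seq"],
         "frequencies": s["frequencies"]} for s in spikes
    ]
    truth["repertoire"] = {
        "depth": cfg.reads_per_compartment,
        "outframe_fraction": cfg.outframe_fraction,
        "n_injected_singletons": cfg.n_injected_singletons,
        "sampled_spike_counts": {
            comp: {s["protein_seq"]: sampled_counts[comp].get(s["protein_seq"], 0)
                   for s in spikes}
            for comp in cfg.repertoire_compartments
        },
    }


def generate_all(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Full generation: cohort tables, assay tables and repertoires."""
    cohort = generate_cohort(config)
    generate_assays(cohort)
    generate_repertoires(cohort)
    return cohort


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write every generated table in the formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = outdir / "proteome.fasta"
    with open(fasta, "w") as fh:
        for pid in sorted(cohort.proteome):
            seq = cohort.proteome[pid].sequence
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    paths["proteome"] = fasta

    mut = outdir / "mutations.tsv"
    pd.DataFrame(
        {"patient_id": [m.patient_id for m in cohort.mutations],
         "gene": [m.gene for m in cohort.mutations],
         "protein_id": [m.protein_id for m in cohort.mutations],
         "position": [m.position for m in cohort.mutations],
         "ref_aa": [m.ref_aa for m in cohort.mutations],
         "alt_aa": [m.alt_aa for m in cohort.mutations]}
    ).to_csv(mut, sep="\t", index=False)
    paths["mutations"] = mut

    aff = outdir / "affinities.tsv"
    write_affinity_table(cohort.predictions, aff)
    paths["affinities"] = aff

    alleles = outdir / "alleles.tsv"
    pd.DataFrame(
        [{"patient_id": p, "allele": a}
         for p in sorted(cohort.patient_alleles) for a in sorted(cohort.patient_alleles[p])]
    ).to_csv(alleles, sep="\t", index=False)
    paths["alleles"] = alleles

    for name, df in (("elispot", cohort.elispot), ("ics", cohort.ics),
                     ("dose_response", cohort.dose_response), ("killing", cohort.killing),
                     ("validations", cohort.validations), ("roster", cohort.roster)):
        if df is not None:
            path = outdir / f"{name}.tsv"
            df.to_csv(path, sep="\t", index=False)
            paths[name] = path

    if cohort.repertoires is not None:
        for compartment, reads in cohort.repertoires.items():
            path = outdir / f"repertoire_{compartment}.tsv"
            write_repertoire_table(reads, path)
            paths[f"repertoire_{compartment}"] = path
        seg = outdir / "segments.tsv"
        ref = cohort.segment_reference
        pd.DataFrame(
            [{"segment": n, "segment_class": "V", "order_index": i}
             for n, i in sorted(ref.v_order.items(), key=lambda kv: kv[1])]
            + [{"segment": n, "segment_class": "J", "order_index": i}
               for n, i in sorted(ref.j_order.items(), key=lambda kv: kv[1])]
        ).to_csv(seg, sep="\t", index=False)
        paths["segments"] = seg

    tr = outdir / "truth.json"
    truth = dict(cohort.truth)
    truth["responder_set"] = [list(t) for t in truth["responder_set"]]
    tr.write_text(json.dumps(truth, indent=2) + "\n")
    paths["truth"] = tr
    return paths
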