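"""Run configuration shared across pipeline stages.

All thresholds that the pipeline hard-wires as defaults live here so a single
config file governs a run: the 500 nM MHC-I binding cutoff, the 9/10-mer
peptide lengths, the two-read clonotype floor, the repertoire limit of
detection, and the ELISpot 3-SD positivity multiplier.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

_ALLOWED_PEPTIDE_LENGTHS = frozenset(range(8, 12))


@dataclass(frozen=True)
class RunConfig:
    """Pipeline-wide constants.

    Parameters
    ----------
    seed
        Seed for every source of randomness in a run; recorded in reports.
    affinity_threshold_nm
        Predicted IC50 cutoff in nM. Peptides with IC50 <= threshold
        (inclusive) are retained as candidate binders.
    peptide_lengths
        Candidate peptide lengths enumerated around each mutation.
    min_reads_per_clonotype
        Clonotypes with fewer pooled reads are discarded (singleton rule
        with the default of 2).
    lod_fraction
        Limit of detection of the repertoire assay as a read fraction
        (default 1e-5, i.e. 10 cells per million, 0.001%).
    elispot_sd_multiplier
        Positivity requires mean spots > negative mean + multiplier * SD.
    """

    seed: int
    affinity_threshold_nm: float = 500.0
    peptide_lengths: frozenset = field(default_factory=lambda: frozenset({9, 10}))
    min_reads_per_clonotype: int = 2
    lod_fraction: float = 1e-5
    elispot_sd_multiplier: float = 3.0

    def __post_init__(self):
        object.__setattr__(self, "peptide_lengths", frozenset(int(l) for l in self.peptide_lengths))
        if self.affinity_threshold_nm <= 0:
            raise ValueError("affinity_threshold_nm must be strictly positive")
        if self.min_reads_per_clonotype <= 0:
            raise ValueError("min_reads_per_clonotype must be strictly positive")
        if self.lod_fraction <= 0:
            raise ValueError("lod_fraction must be strictly positive")
        if self.elispot_sd_multiplier <= 0:
            raise ValueError("elispot_sd_multiplier must be strictly positive")
        if not self.peptide_lengths:
            raise ValueError("peptide_lengths must be non-empty")
        if not self.peptide_lengths <= _ALLOWED_PEPTIDE_LENGTHS:
            raise ValueError(f"peptide_lengths must be a subset of {sorted(_ALLOWED_PEPTIDE_LENGTHS)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["peptide_lengths"] = sorted(self.peptide_lengths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a JSON key/value config file."""
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def lod_percent(cells: int, total_cells: int) -> float:
    """Limit of detection expressed as a percentage.

    ``lod_percent(10, 1_000_000)`` is 0.001 (%), the 10-cells-per-million
    sensitivity at which the repertoire assay was validated.
    """
    if total_cells <= 0:
        raise ValueError("total_cells must be positive")
    return 100.0 * cells / total_cells
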