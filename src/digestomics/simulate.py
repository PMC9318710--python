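"""Synthetic timepoint-resolved digestion peptidomics generator.

Emulates the peptide-observation tables produced by searching LC-MS/MS data
of a progressive multi-phase in vitro digestion: per-molecule independent
Bernoulli cutting at predicted protease sites accumulating across an
oral/gastric/duodenal phase structure, rare "alternative" cleavage at
Gln-adjacent bonds the specificity models do not predict, a hard
detectability length window standing in for MS acquisition limits, and
optional Poisson count noise. A full ground-truth record (which bond was cut
in which molecule by which enzyme, and where every emitted peptide came from)
supports parameter-recovery tests of the downstream analysis.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import digestion
from .mapping import PeptideObservation
from .sequence_db import AMINO_ACIDS, ProteinRecord, load_fasta, packaged_path

ALTERNATIVE = "alternative"

#: Residue pool for random flanking sequence: the 20 residues minus Gln, so
#: generated flanks never add alternative-cleavage candidates by accident.
_FLANK_POOL = "".join(c for c in AMINO_ACIDS if c != "Q")


@dataclass(frozen=True)
class Phase:
    """One digestion phase: label, active specificity models, step count.

    ``sample_steps`` maps sample labels to the step (1-based, within the
    phase) at which an aliquot is profiled.
    """

    label: str
    enzymes: tuple[str, ...]
    steps: int
    sample_steps: dict[str, int] = field(default_factory=dict)


def default_phases() -> tuple[Phase, ...]:
    """Oral (no proteolysis), gastric pepsin, then duodenal trypsin+chymotrypsin.

    Gastric and duodenal timepoints G0/G60/G120 and D0/D60/D120 (0.3, 60 and
    120 min) map to steps 1, 4 and 8 of an 8-step phase.
    """
    return (
        Phase("oral", (), 0),
        Phase("gastric", ("pepsin_ph2",), 8, {"G0": 1, "G60": 4, "G120": 8}),
        Phase(
            "duodenal",
            ("trypsin", "chymotrypsin_low"),
            8,
            {"D0": 1, "D60": 4, "D120": 8},
        ),
    )


def default_proteins() -> list[ProteinRecord]:
    """The packaged synthetic LMW glutenin stand-in (see its FASTA header)."""
    return load_fasta(packaged_path("lmw_gs_synthetic.fasta"))


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world of the generator.

    Defaults: 5000 molecules per protein; pepsin cut probability 0.15 per
    site per step over 8 gastric steps, then trypsin and chymotrypsin at 0.2
    per step over 8 duodenal steps; alternative Gln-adjacent cleavage at 0.01
    per step; detectable peptide length window [6, 40]; Poisson count noise.
    """

    proteins: tuple[ProteinRecord, ...]
    phases: tuple[Phase, ...] = field(default_factory=default_phases)
    p_cleave: dict[str, float] = field(
        default_factory=lambda: {
            "pepsin_ph2": 0.15,
            "trypsin": 0.2,
            "chymotrypsin_low": 0.2,
        }
    )
    p_alternative: float = 0.01
    n_molecules: int = 5000
    min_detect_len: int = 6
    max_detect_len: int | None = 40
    count_noise: str = "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError("at least one protein is required")
        if not self.phases:
            raise ValueError("at least one phase is required")
        for enzyme, p in self.p_cleave.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_cleave[{enzyme!r}]={p} outside [0, 1]")
        if not 0.0 <= self.p_alternative <= 1.0:
            raise ValueError("p_alternative outside [0, 1]")
        if self.max_detect_len is not None and self.min_detect_len > self.max_detect_len:
            raise ValueError("min_detect_len > max_detect_len")
        if self.count_noise not in ("none", "poisson"):
            raise ValueError("count_noise must be 'none' or 'poisson'")
        for phase in self.phases:
            for enzyme in phase.enzymes:
                if enzyme not in self.p_cleave:
                    raise ValueError(f"no p_cleave for enzyme {enzyme!r}")

    @classmethod
    def default(cls, seed: int = 0) -> "SimulationConfig":
        return cls(proteins=tuple(default_proteins()), seed=seed)


@dataclass
class ProteinTruth:
    """Ground truth for one protein: realized cuts and their provenance."""

    accession: str
    sequence: str
    site_positions: np.ndarray        # (n_sites,) bond indices, ascending
    provenance_names: tuple[str, ...]  # code -> name ("alternative" or enzyme)
    cut_step: np.ndarray              # (n_molecules, n_sites); 0 = never cut
    provenance: np.ndarray            # (n_molecules, n_sites) codes; -1 = none
    sample_global_step: dict[str, int]
    phase_of_step: dict[int, str]
    predicted: dict[str, frozenset[int]]

    def realized_fraction(self) -> dict[int, float]:
        """site -> fraction of molecules in which it was cut by the end."""
        frac = (self.cut_step > 0).mean(axis=0)
        return {int(k): float(f) for k, f in zip(self.site_positions, frac)}

    def majority_provenance(self) -> dict[int, str]:
        """site -> most frequent cutter among molecules that realized it."""
        out: dict[int, str] = {}
        for j, site in enumerate(self.site_positions):
            codes = self.provenance[:, j]
            codes = codes[codes >= 0]
            if codes.size == 0:
                continue
            counts = np.bincount(codes, minlength=len(self.provenance_names))
            out[int(site)] = self.provenance_names[int(np.argmax(counts))]
        return out

    def site_summary(self) -> pd.DataFrame:
        frac = self.realized_fraction()
        majority = self.majority_provenance()
        rows = [
            {
                "accession": self.accession,
                "site": site,
                "realized_fraction": frac[site],
                "provenance": majority.get(site, ""),
            }
            for site in map(int, self.site_positions)
        ]
        return pd.DataFrame(
            rows, columns=["accession", "site", "realized_fraction", "provenance"]
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-form ``molecule  phase  site  provenance`` of realized cuts."""
        molecules, cols = np.nonzero(self.cut_step > 0)
        rows = {
            "molecule": molecules,
            "phase": [
                self.phase_of_step[int(self.cut_step[m, j])]
                for m, j in zip(molecules, cols)
            ],
            "site": self.site_positions[cols],
            "provenance": [
                self.provenance_names[int(self.provenance[m, j])]
                for m, j in zip(molecules, cols)
            ],
        }
        return pd.DataFrame(rows)


@dataclass
class TruthRecord:
    """Ground truth across proteins plus the emitted-observation locations."""

    proteins: dict[str, ProteinTruth]
    observation_locations: pd.DataFrame  # sample accession start end spectral_count

    def write_tsv(self, path: str | Path) -> None:
        frames = [t.to_frame().assign(accession=acc) for acc, t in self.proteins.items()]
        table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["molecule", "phase", "site", "provenance", "accession"]
        )
        table.to_csv(path, sep="\t", index=False)


def alternative_candidate_bonds(
    sequence: str, predicted_union: frozenset[int]
) -> list[int]:
    """Bonds with Gln at P1 or P1' that no specificity model predicts."""
    return [
        k
        for k in range(1, len(sequence))
        if (sequence[k - 1] == "Q" or sequence[k] == "Q") and k not in predicted_union
    ]


def _simulate_protein(
    protein: ProteinRecord, config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[PeptideObservation], ProteinTruth, list[dict]]:
    sequence = protein.sequence
    enzymes = sorted({e for phase in config.phases for e in phase.enzymes})
    predicted = {
        e: digestion.predict_sites(sequence, e, protein.accession).sites for e in enzymes
    }
    predicted_union: frozenset[int] = frozenset().union(*predicted.values()) if predicted else frozenset()
    alt_bonds = alternative_candidate_bonds(sequence, predicted_union)
    site_positions = np.array(sorted(predicted_union | set(alt_bonds)), dtype=np.int64)
    site_index = {int(k): j for j, k in enumerate(site_positions)}
    n_sites = len(site_positions)

    provenance_names = tuple(enzymes) + (ALTERNATIVE,)
    prov_code = {name: i for i, name in enumerate(provenance_names)}
    enzyme_masks = {
        e: np.isin(site_positions, sorted(predicted[e])) for e in enzymes
    }
    alt_mask = np.isin(site_positions, alt_bonds)

    n_mol = config.n_molecules
    cut_step = np.zeros((n_mol, n_sites), dtype=np.int32)
    provenance = np.full((n_mol, n_sites), -1, dtype=np.int16)

    sample_global_step: dict[str, int] = {}
    phase_of_step: dict[int, str] = {}
    global_step = 0
    for phase in config.phases:
        for step in range(1, phase.steps + 1):
            global_step += 1
            phase_of_step[global_step] = phase.label
            uncut = cut_step == 0
            for enzyme in phase.enzymes:
                applicable = uncut & enzyme_masks[enzyme][None, :]
                hits = applicable & (
                    rng.random((n_mol, n_sites)) < config.p_cleave[enzyme]
                )
                cut_step[hits] = global_step
                provenance[hits] = prov_code[enzyme]
                uncut = cut_step == 0
            if phase.enzymes and config.p_alternative > 0:
                applicable = uncut & alt_mask[None, :]
                hits = applicable & (
                    rng.random((n_mol, n_sites)) < config.p_alternative
                )
                cut_step[hits] = global_step
                provenance[hits] = prov_code[ALTERNATIVE]
        for sample, step in phase.sample_steps.items():
            if not 1 <= step <= max(phase.steps, 1):
                raise ValueError(
                    f"sample {sample!r} at step {step} outside phase {phase.label!r}"
                )
            sample_global_step[sample] = global_step - phase.steps + step

    observations: list[PeptideObservation] = []
    location_rows: list[dict] = []
    L = len(sequence)
    for sample, t in sorted(sample_global_step.items(), key=lambda kv: kv[1]):
        fragment_counts: Counter[tuple[int, int]] = Counter()
        realized = (cut_step > 0) & (cut_step <= t)
        for m in range(n_mol):
            cuts = site_positions[realized[m]]
            bounds = np.concatenate(([0], cuts, [L]))
            lengths = np.diff(bounds)
            keep = lengths >= config.min_detect_len
            if config.max_detect_len is not None:
                keep &= lengths <= config.max_detect_len
            for i in np.nonzero(keep)[0]:
                fragment_counts[(int(bounds[i]) + 1, int(bounds[i + 1]))] += 1
        for (start, end), count in sorted(fragment_counts.items()):
            if config.count_noise == "poisson":
                count = int(rng.poisson(count))
                if count == 0:
                    continue
            observations.append(
                PeptideObservation(
                    peptide=sequence[start - 1 : end],
                    sample=sample,
                    spectral_count=count,
                    claimed_accession=protein.accession,
                )
            )
            location_rows.append(
                {
                    "sample": sample,
                    "accession": protein.accession,
                    "start": start,
                    "end": end,
                    "spectral_count": count,
                }
            )

    truth = ProteinTruth(
        accession=protein.accession,
        sequence=sequence,
        site_positions=site_positions,
        provenance_names=provenance_names,
        cut_step=cut_step,
        provenance=provenance,
        sample_global_step=sample_global_step,
        phase_of_step=phase_of_step,
        predicted=predicted,
    )
    return observations, truth, location_rows


def simulate(config: SimulationConfig) -> tuple[list[PeptideObservation], TruthRecord]:
    """Run the generator; a fixed seed gives bit-identical output."""
    rng = np.random.default_rng(config.seed)
    observations: list[PeptideObservation] = []
    truths: dict[str, ProteinTruth] = {}
    location_rows: list[dict] = []
    for protein in config.proteins:
        obs, truth, locations = _simulate_protein(protein, config, rng)
        observations.extend(obs)
        truths[protein.accession] = truth
        location_rows.extend(locations)
    locations_frame = pd.DataFrame(
        location_rows, columns=["sample", "accession", "start", "end", "spectral_count"]
    )
    return observations, TruthRecord(proteins=truths, observation_locations=locations_frame)


def make_repeat_protein(
    unit: str,
    n_repeats: int,
    flank_n: str | int = "",
    flank_c: str | int = "",
    seed: int | None = None,
    accession: str = "REPEAT_SYN",
) -> ProteinRecord:
    """Build a repetitive-domain protein: flank_n + unit*n_repeats + flank_c.

    Integer flanks are drawn (deterministically for a given seed) from a
    fixed Gln-free residue pool so the repeats alone carry the ambiguity.
    """
    if not unit:
        raise ValueError("unit must be non-empty")
    rng = np.random.default_rng(seed)

    def _flank(spec: str | int) -> str:
        if isinstance(spec, int):
            return "".join(rng.choice(list(_FLANK_POOL), size=spec))
        return spec

    sequence = _flank(flank_n) + unit * n_repeats + _flank(flank_c)
    if not sequence:
        raise ValueError("resulting protein is empty; supply flanks or n_repeats >= 1")
    return ProteinRecord(
        accession=accession,
        sequence=sequence,
        description=f"synthetic repeat protein unit={unit} n={n_repeats}",
        source_tag="synthetic",
    )
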