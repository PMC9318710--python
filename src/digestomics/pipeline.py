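"""Configuration-driven orchestration of the full digestomics workflow.

Ties the modules together: predicted cleavage sites per enzyme model,
peptide mapping with per-residue spectral-count profiles and coverage,
observed-site classification per sample (predicted vs experimentally
determined layout), Gln-adjacency of alternative sites, motif tallies and
length summaries — all written as fixed-column TSVs plus a reproducible run
manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cleavage import (
    ENZYME_CLASSES,
    PHASE_ENZYMES,
    classification_table,
    classify_sites,
    infer_observed_sites,
    residue_adjacency_summary,
)
from .digestion import common_sites, load_ruleset, predict_sites, union_sites
from .mapping import (
    PeptideObservation,
    build_profile,
    coverage,
    length_summary,
    profile_table,
    read_peptide_table,
)
from .motifs import MotifLibrary, instance_table, scan_observations, tally_by_sample
from .sequence_db import attach_signal_ranges, load_fasta, load_signal_ranges

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, enzyme models, sample phases and options of one pipeline run."""

    fasta: str
    peptide_table: str
    out_dir: str
    motif_library: str | None = None
    signal_ranges: str | None = None
    enzymes: tuple[str, ...] = ("pepsin_ph2", "chymotrypsin_low", "trypsin")
    sample_phase: dict[str, str] = field(
        default_factory=lambda: {
            "G0": "gastric", "G60": "gastric", "G120": "gastric",
            "D0": "duodenal", "D60": "duodenal", "D120": "duodenal",
        }
    )
    min_site_count: int = 1
    coverage_denominator: str = "full"
    il_equivalent: bool = False
    dedupe_peptides: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if "enzymes" in raw:
            raw["enzymes"] = tuple(raw["enzymes"])
        return cls(**raw)

    def canonical(self) -> str:
        payload = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in sorted(self.__dict__.items())
        }
        return json.dumps(payload, sort_keys=True)


def _write(table: pd.DataFrame, path: Path) -> None:
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full workflow; returns the paths of every written report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    stage = "load-inputs"
    try:
        proteins = load_fasta(config.fasta)
        if config.signal_ranges:
            proteins = attach_signal_ranges(proteins, load_signal_ranges(config.signal_ranges))
        observations = read_peptide_table(config.peptide_table)
        if not observations:
            log.warning("empty peptide table %s; reports will be all-zero", config.peptide_table)
        unknown = {o.sample for o in observations} - set(config.sample_phase)
        if unknown:
            raise ValueError(f"samples not declared in sample_phase: {sorted(unknown)}")
        library = (
            MotifLibrary.from_tsv(config.motif_library)
            if config.motif_library
            else MotifLibrary.demo()
        )

        stage = "digest-predict"
        site_rows = []
        per_protein_sites = {}
        for protein in proteins:
            sets = {e: predict_sites(protein.sequence, e, protein.accession) for e in config.enzymes}
            per_protein_sites[protein.accession] = sets
            for enzyme, site_set in sets.items():
                for k in sorted(site_set.sites):
                    site_rows.append(
                        {
                            "accession": protein.accession,
                            "enzyme": enzyme,
                            "site": k,
                            "p1": protein.sequence[k - 1],
                            "p1prime": protein.sequence[k],
                        }
                    )
        outputs["predicted_sites"] = out_dir / "predicted_sites.tsv"
        _write(
            pd.DataFrame(site_rows, columns=["accession", "enzyme", "site", "p1", "p1prime"]),
            outputs["predicted_sites"],
        )

        stage = "map"
        profile_rows, coverage_rows = [], []
        for protein in proteins:
            protein_obs = [
                o for o in observations
                if o.claimed_accession in (None, protein.accession)
            ]
            profile = build_profile(
                protein_obs, protein,
                denominator=config.coverage_denominator,
                il_equivalent=config.il_equivalent,
            )
            profile_rows.append(profile_table(profile, protein))
            coverage_rows.append(
                {
                    "accession": protein.accession,
                    "coverage_fraction": round(coverage(profile), 6),
                    "ambiguous_spectral_count": profile.ambiguous_spectral_count,
                    "n_unmapped": profile.n_unmapped,
                }
            )
        outputs["residue_profiles"] = out_dir / "residue_profiles.tsv"
        _write(
            pd.concat(profile_rows, ignore_index=True)
            if profile_rows
            else pd.DataFrame(columns=["accession", "position", "residue", "count"]),
            outputs["residue_profiles"],
        )
        outputs["coverage"] = out_dir / "coverage.tsv"
        _write(
            pd.DataFrame(
                coverage_rows,
                columns=["accession", "coverage_fraction", "ambiguous_spectral_count", "n_unmapped"],
            ),
            outputs["coverage"],
        )

        stage = "classify-cleavages"
        per_site_frames, summary_rows, adjacency_frames = [], [], []
        samples = sorted({o.sample for o in observations})
        for protein in proteins:
            for sample in samples:
                sample_obs = [
                    o for o in observations
                    if o.sample == sample
                    and o.claimed_accession in (None, protein.accession)
                ]
                observed = infer_observed_sites(
                    sample_obs, protein, il_equivalent=config.il_equivalent
                )
                phase = config.sample_phase[sample]
                in_phase = {
                    name: sites
                    for name, sites in per_protein_sites[protein.accession].items()
                    if ENZYME_CLASSES[name] in PHASE_ENZYMES[phase]
                }
                records, summary = classify_sites(
                    observed, in_phase, protein,
                    phase=phase, min_site_count=config.min_site_count,
                )
                frame = classification_table(records)
                frame.insert(1, "sample", sample)
                per_site_frames.append(frame)
                summary_rows.append(
                    {"accession": protein.accession, "sample": sample, "phase": phase, **summary}
                )
                adjacency = residue_adjacency_summary(records)
                adjacency.insert(0, "sample", sample)
                adjacency.insert(0, "accession", protein.accession)
                adjacency_frames.append(adjacency)
        outputs["observed_sites"] = out_dir / "observed_sites.tsv"
        _write(
            pd.concat(per_site_frames, ignore_index=True)
            if per_site_frames
            else classification_table([]),
            outputs["observed_sites"],
        )
        outputs["site_summary"] = out_dir / "site_summary.tsv"
        _write(
            pd.DataFrame(
                summary_rows,
                columns=[
                    "accession", "sample", "phase", "peptic", "chymotryptic",
                    "common", "tryptic", "alternative", "total_distinct", "inclusive_sum",
                ],
            ),
            outputs["site_summary"],
        )
        outputs["gln_adjacency"] = out_dir / "gln_adjacency.tsv"
        _write(
            pd.concat(adjacency_frames, ignore_index=True)
            if adjacency_frames
            else pd.DataFrame(columns=["accession", "sample", "context", "n_alternative", "fraction"]),
            outputs["gln_adjacency"],
        )

        stage = "scan-motifs"
        instances = scan_observations(
            observations, library, dedupe_peptides=config.dedupe_peptides
        )
        tally, motif_lengths = tally_by_sample(
            observations, library, dedupe_peptides=config.dedupe_peptides
        )
        outputs["motif_instances"] = out_dir / "motif_instances.tsv"
        _write(instance_table(instances), outputs["motif_instances"])
        outputs["motif_tally"] = out_dir / "motif_tally.tsv"
        _write(tally, outputs["motif_tally"])
        outputs["motif_lengths"] = out_dir / "motif_lengths.tsv"
        _write(motif_lengths, outputs["motif_lengths"])

        stage = "length-summary"
        if observations:
            summary, tests = length_summary(observations)
        else:
            summary = pd.DataFrame(columns=["sample", "n", "median", "q1", "q3"])
            tests = pd.DataFrame(columns=["sample_a", "sample_b", "statistic", "p_value"])
        outputs["length_summary"] = out_dir / "length_summary.tsv"
        _write(summary, outputs["length_summary"])
        outputs["length_tests"] = out_dir / "length_tests.tsv"
        _write(tests, outputs["length_tests"])

        stage = "manifest"
        manifest = {
            "tool": "digestomics",
            "version": __version__,
            "config_sha256": hashlib.sha256(config.canonical().encode()).hexdigest(),
            "config": json.loads(config.canonical()),
            "outputs": {name: path.name for name, path in outputs.items()},
        }
        outputs["manifest"] = out_dir / "manifest.json"
        with open(outputs["manifest"], "w") as handle:
            json.dump(manifest, handle, indent=2, sort_keys=True)
            handle.write("\n")
    except Exception:
        log.error("pipeline failed at stage %s", stage)
        raise

    return outputs
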