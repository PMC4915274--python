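"""End-to-end orchestration: FASTA -> screening -> tracks -> annotations ->
CD features -> sequence parameters -> database.

The pipeline computes everything in memory first and only then writes the
database, so a stage failure never leaves a partial file behind.  Score
tracks come either from the built-in charge-hydropathy predictor (all four
slots, at distinct window sizes) or from per-protein IUPred/DisEMBL output
files resolved by a directory convention (``<dir>/<accession>.iupred`` and
``<dir>/<accession>.disembl``).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import yaml

from . import cd_features, consensus, database, predictors, sequence_io
from .charge_patterning import compute_sequence_parameters
from .errors import ConfigurationError, DisorderDBError, PipelineError

logger = logging.getLogger("disorderdb")

__all__ = ["OrganismInput", "RunConfig", "RunReport", "run_pipeline"]


@dataclass(frozen=True)
class OrganismInput:
    label: str
    fasta_path: str
    proteome_id: str = ""
    accession_date: str = ""
    scores_dir: str | None = None  # required in external mode


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    ``predictor_mode`` is ``"builtin"`` or ``"external"``; in external mode
    every organism needs a ``scores_dir`` holding one IUPred and one DisEMBL
    output file per eligible protein.
    """

    organisms: tuple[OrganismInput, ...]
    output_path: str
    predictor_mode: str = "builtin"
    threshold_overrides: dict[str, float] = field(default_factory=dict)
    tie_disordered: bool = True
    builtin_windows: dict[str, int] = field(default_factory=dict)
    builtin_boundary: tuple[float, float] = (2.785, 1.151)
    blob_sizes: tuple[int, ...] = (5, 6)
    kappa_max_arrangements: int = 100_000
    overwrite: bool = False

    def __post_init__(self) -> None:
        if self.predictor_mode not in ("builtin", "external"):
            raise ConfigurationError(
                f"predictor_mode must be 'builtin' or 'external', "
                f"got {self.predictor_mode!r}")
        if not self.organisms:
            raise ConfigurationError("at least one organism input is required")
        if self.predictor_mode == "external":
            for org in self.organisms:
                if not org.scores_dir:
                    raise ConfigurationError(
                        f"organism {org.label!r}: external mode needs scores_dir")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        organisms = tuple(OrganismInput(**o) for o in raw.pop("organisms", []))
        if "builtin_boundary" in raw:
            raw["builtin_boundary"] = tuple(raw["builtin_boundary"])
        if "blob_sizes" in raw:
            raw["blob_sizes"] = tuple(raw["blob_sizes"])
        return cls(organisms=organisms, **raw)


@dataclass
class RunReport:
    """Per-run bookkeeping mirroring the organism-level summary tables."""

    per_organism: list[dict] = field(default_factory=list)

    @property
    def total_annotated_residues(self) -> int:
        return sum(o["n_annotated_residues"] for o in self.per_organism)


def _external_tracks(record: sequence_io.ProteinRecord,
                     scores_dir: str) -> dict[str, predictors.PredictorTrack]:
    iupred_path = os.path.join(scores_dir, f"{record.accession}.iupred")
    disembl_path = os.path.join(scores_dir, f"{record.accession}.disembl")
    for p in (iupred_path, disembl_path):
        if not os.path.exists(p):
            raise PipelineError(f"missing predictor output file {p}",
                                accession=record.accession, stage="predict")
    with open(iupred_path) as fh:
        track_i = predictors.parse_iupred_long(fh, record.length)
    with open(disembl_path) as fh:
        track_c, track_h, track_r = predictors.parse_disembl_scores(fh, record.length)
    return {"I": track_i, "C": track_c, "H": track_h, "R": track_r}


def _process_protein(record: sequence_io.ProteinRecord, config: RunConfig,
                     org: OrganismInput,
                     threshold_config: predictors.ThresholdConfig
                     ) -> database.ProteinResult:
    if config.predictor_mode == "builtin":
        windows = {**predictors.DEFAULT_BUILTIN_WINDOWS, **config.builtin_windows}
        tracks = predictors.builtin_track_set(record.sequence, windows,
                                              config.builtin_boundary)
    else:
        tracks = _external_tracks(record, org.scores_dir)

    calls = {m: consensus.binarize_track(tracks[m], threshold_config)
             for m in predictors.METHOD_IDS}
    scores = {m: tracks[m].scores for m in predictors.METHOD_IDS}
    ann = consensus.annotation_frame(record, calls, scores)

    consensus_mask = ann["dcc"].to_numpy() == 4
    pct = {m: consensus.percent_disorder(calls[m]) for m in predictors.METHOD_IDS}
    pct["consensus"] = consensus.percent_disorder(consensus_mask)

    regions = {m: cd_features.extract_cd_regions(calls[m], m)
               for m in predictors.METHOD_IDS}
    regions["consensus"] = cd_features.extract_cd_regions(consensus_mask, "consensus")
    cd = cd_features.summarize_cd(regions, record.length)

    params = compute_sequence_parameters(
        record.sequence, blob_sizes=config.blob_sizes,
        max_arrangements=config.kappa_max_arrangements)
    return database.ProteinResult(record=record, tracks=tracks,
                                  annotations=ann, percent_disorder=pct,
                                  cd=cd, params=params)


def _effective_thresholds(config: RunConfig,
                          sample: dict[str, predictors.PredictorTrack] | None
                          ) -> dict[str, float]:
    out = {}
    for m in predictors.METHOD_IDS:
        if m in config.threshold_overrides:
            out[m] = config.threshold_overrides[m]
        elif config.predictor_mode == "builtin":
            out[m] = 0.5
        elif sample is not None:
            out[m] = sample[m].threshold
        else:
            out[m] = predictors.DEFAULT_THRESHOLDS[m]
    return out


def run_pipeline(config: RunConfig) -> tuple[str, RunReport]:
    """Execute the full workflow and write the database.

    Returns the database path and a :class:`RunReport`.  Any stage error is
    re-raised as :class:`PipelineError` naming the organism, accession and
    stage, and nothing is written in that case.
    """
    threshold_config = predictors.ThresholdConfig(
        overrides=dict(config.threshold_overrides),
        tie_disordered=config.tie_disordered)
    report = RunReport()
    organism_results: list[database.OrganismResult] = []

    for org in config.organisms:
        logger.info("organism %s: parsing %s", org.label, org.fasta_path)
        try:
            with open(org.fasta_path) as fh:
                records = sequence_io.parse_uniprot_fasta(fh)
        except (OSError, DisorderDBError) as exc:
            raise PipelineError(str(exc), organism=org.label, stage="parse") from exc

        part = sequence_io.screen_eligibility(records)
        logger.info("organism %s: %d eligible, %d excluded",
                    org.label, part.n_eligible, part.n_excluded)

        included: list[database.ProteinResult] = []
        thresholds = None
        for record in part.eligible:
            try:
                result = _process_protein(record, config, org, threshold_config)
            except PipelineError:
                raise
            except DisorderDBError as exc:
                raise PipelineError(str(exc), organism=org.label,
                                    accession=record.accession,
                                    stage="annotate") from exc
            if thresholds is None:
                thresholds = _effective_thresholds(config, result.tracks)
            included.append(result)
        if thresholds is None:
            thresholds = _effective_thresholds(config, None)

        summary = database.OrganismSummary(
            organism=org.label, proteome_id=org.proteome_id,
            fasta_file=os.path.basename(org.fasta_path),
            accession_date=org.accession_date,
            predictor_source=config.predictor_mode,
            thresholds=thresholds)
        organism_results.append(database.OrganismResult(
            summary=summary, included=included, excluded=part.excluded))
        report.per_organism.append({
            "organism": org.label,
            "n_included": part.n_eligible,
            "n_excluded": part.n_excluded,
            "n_annotated_residues": sum(p.record.length for p in included),
            "n_cd_proteins": sum(1 for p in included if p.cd.has_cd),
            "n_undefined_kappa": sum(1 for p in included if p.params.kappa is None),
        })

    database.write_database(organism_results, config.output_path,
                            overwrite=config.overwrite)
    logger.info("wrote %s (%d annotated residues)",
                config.output_path, report.total_annotated_residues)
    return config.output_path, report
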