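"""End-to-end orchestration: variants -> database -> search -> FDR -> reports.

Every stage is a pure function of (inputs, config, seed); rerunning with the
same configuration reproduces each output byte for byte.  Stages log the
thresholds they actually apply to stderr with machine-parsable markers, and
any failure aborts with the stage name in the message.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import error_model, ligandome_stats, personal_db, peptide_space
from . import spectra_search, variant_calling

logger = logging.getLogger("neoligand")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "read_cds_fasta", "write_cds_fasta"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage:{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All stage parameters plus I/O paths; defaults are the published
    operating point of the method."""

    pileup_path: str | Path = "pileup.tsv"
    cds_path: str | Path = "cds.fasta"
    mgf_path: str | Path = "spectra.mgf"
    ligandome_path: str | Path | None = None
    out_dir: str | Path = "results"
    thresholds: variant_calling.CallerThresholds = field(
        default_factory=variant_calling.CallerThresholds
    )
    expansion: peptide_space.ExpansionConfig = field(
        default_factory=peptide_space.ExpansionConfig
    )
    tolerances: spectra_search.SearchTolerances = field(
        default_factory=spectra_search.SearchTolerances
    )
    fdr: error_model.FDRConfig = field(default_factory=error_model.FDRConfig)
    enabled_mods: tuple[str, ...] = ("ac", "ox", "ph")
    mz_range: tuple[float, float] = (100.0, 1700.0)
    hotspot_min_patients: int = 3
    seed: int = 0


def read_cds_fasta(path) -> list[personal_db.TranscriptRecord]:
    """CDS FASTA with headers ``>TRANSCRIPT protein=PROTEIN``."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        protein_id = rec.id
        for token in rec.description.split():
            if token.startswith("protein="):
                protein_id = token.split("=", 1)[1]
        records.append(
            personal_db.TranscriptRecord(rec.id, protein_id, str(rec.seq))
        )
    return records


def write_cds_fasta(transcripts, path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.transcript_id} protein={t.protein_id}\n{t.cds}\n")


def _psm_frame(psms) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "spectrum_id": [p.spectrum_id for p in psms],
            "sequence": [p.sequence for p in psms],
            "modified_sequence": [p.modified_sequence for p in psms],
            "peptide_class": [p.peptide_class for p in psms],
            "is_decoy": [p.is_decoy for p in psms],
            "score": [p.score for p in psms],
            "delta_score": [p.delta_score for p in psms],
            "precursor_error_ppm": [p.precursor_error_ppm for p in psms],
            "pep": [p.pep for p in psms],
            "max_localization": [p.max_localization for p in psms],
            "n_matched": [p.n_matched for p in psms],
            "n_theoretical": [p.n_theoretical for p in psms],
        }
    )


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute call-variants -> build-db -> digest -> search -> fdr ->
    phospho-filter -> windows -> stats; returns the written output paths."""
    for stage, path in (
        ("inputs", config.pileup_path),
        ("inputs", config.cds_path),
        ("inputs", config.mgf_path),
    ):
        if not Path(path).exists():
            raise PipelineError(stage, f"missing input path: {path}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    try:
        logger.info("[stage:call-variants] thresholds=%s", config.thresholds)
        columns = variant_calling.read_pileup(config.pileup_path)
        calls = variant_calling.call_promiscuous(columns, config.thresholds)
        outputs["calls"] = out / "calls.vcf"
        variant_calling.write_vcf(calls, outputs["calls"])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("call-variants", str(exc)) from exc

    try:
        transcripts = read_cds_fasta(config.cds_path)
        by_tid = {t.transcript_id: t for t in transcripts}
        proteome = {t.protein_id: personal_db.translate(t.cds) for t in transcripts}
        variants = []
        for call in calls:
            t = by_tid.get(call.chrom)
            if t is None:
                continue
            pv = personal_db.map_snv_to_protein(t, call)
            if pv is not None:
                variants.append(pv)
        variants = personal_db.dedupe_variants(variants)
        logger.info("[stage:build-db] %d amino-acid variants", len(variants))
        outputs["personalized"] = out / "personalized.fasta"
        personal_db.build_personalized_fasta(
            proteome, variants, outputs["personalized"]
        )
        windows = [
            personal_db.extract_context_window(proteome[v.protein_id], v)
            for v in variants
            if v.alt_aa != "*"
        ]
        outputs["windows"] = out / "windows.tsv"
        personal_db.write_windows_tsv(windows, outputs["windows"])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("build-db", str(exc)) from exc

    try:
        logger.info("[stage:digest] %s", config.expansion)
        targets = peptide_space.build_search_space(
            proteome, variants, config.expansion
        )
        decoys = peptide_space.build_decoys(
            proteome, variants, config.expansion, target_space=targets
        )
    except Exception as exc:
        raise PipelineError("digest", str(exc)) from exc

    try:
        logger.info("[stage:search] tolerances=%s", config.tolerances)
        spectra = spectra_search.read_mgf(config.mgf_path)
        index = spectra_search.PeptideIndex(targets, decoys, config.enabled_mods)
        psms = spectra_search.search_spectra(
            spectra, index, config.tolerances, config.mz_range
        )
    except Exception as exc:
        raise PipelineError("search", str(exc)) from exc

    try:
        logger.info(
            "[stage:fdr] global=%g variant=%g",
            config.fdr.global_fdr, config.fdr.variant_fdr,
        )
        model = error_model.fit_pep(psms)
        error_model.assign_peps(psms, model)
        outputs["psms"] = out / "psms.tsv"
        _psm_frame(psms).to_csv(outputs["psms"], sep="\t", index=False)
        peptides = error_model.peptide_rollup(psms)
        outputs["peptides"] = out / "peptides.tsv"
        error_model.global_report(peptides, config.fdr).to_csv(
            outputs["peptides"], sep="\t", index=False
        )
        outputs["variant_peptides"] = out / "variant_peptides.tsv"
        error_model.variant_report(peptides, config.fdr).to_csv(
            outputs["variant_peptides"], sep="\t", index=False
        )
        logger.info(
            "[stage:phospho-filter] delta>%g locprob>%g",
            config.fdr.phospho_delta_min_exclusive,
            config.fdr.phospho_locprob_min_exclusive,
        )
        outputs["phosphopeptides"] = out / "phosphopeptides.tsv"
        error_model.filter_phospho(
            error_model.global_report(peptides, config.fdr), config.fdr
        ).to_csv(outputs["phosphopeptides"], sep="\t", index=False)
    except Exception as exc:
        raise PipelineError("fdr", str(exc)) from exc

    if config.ligandome_path is not None:
        try:
            logger.info("[stage:stats] hotspot_min_patients=%d",
                        config.hotspot_min_patients)
            table = pd.read_csv(config.ligandome_path, sep="\t")
            ld = ligandome_stats.length_distribution(table)
            outputs["length_distribution"] = out / "length_distribution.tsv"
            ld.rename("count").to_csv(outputs["length_distribution"], sep="\t")
            profiles = ligandome_stats.coverage_profile(
                table, proteome, config.hotspot_min_patients
            )
            outputs["coverage"] = out / "coverage.tsv"
            with open(outputs["coverage"], "w") as fh:
                fh.write("protein\tstart\tend\tcount\tpatients\n")
                for pid, prof in sorted(profiles.items()):
                    for i, (c, np_) in enumerate(
                        zip(prof.ligand_count, prof.patient_count)
                    ):
                        if c:
                            fh.write(f"{pid}\t{i}\t{i + 1}\t{c}\t{np_}\n")
        except Exception as exc:
            raise PipelineError("stats", str(exc)) from exc

    return outputs
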