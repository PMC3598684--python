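"""End-to-end orchestration: simulate -> dedupe -> map -> quantify -> DE
-> compare -> report, with a machine-readable summary scoring every
recovered quantity against the simulator's ground truth.

Every stage writes its outputs under the run directory and is re-runnable
from those files; a MANIFEST lists each artifact with its record count.
The whole run is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import assembly_postprocess as ap
from . import comparative as cmp
from . import diffexpr as de
from . import quantification as quant
from . import read_mapping as rm
from .io_formats import SequenceRecord, write_fasta, write_fastq, write_hit_table
from .synthetic_data import (
    CONTROL,
    STARVED,
    TREATMENTS,
    GroundTruth,
    SimulationConfig,
    derive_contig_set,
    simulate_cross_species,
    simulate_library,
    simulate_promoters,
    simulate_transcriptome,
)

__all__ = ["PipelineConfig", "validate_config", "run_demo"]

log = logging.getLogger("pistarv")


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, embedding the simulation config."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    containment_identity: float = 0.90
    containment_cover: float = 0.90
    reconstruction_identity: float = 0.90
    reconstruction_coverages: tuple[float, float] = (0.50, 0.90)
    seed_k: int = 21
    max_mismatches_per_mate: int = 2
    insert_sd_multiple: float = 4.0
    count_unit: str = "reads"
    fdr: float = 0.01
    rbh_evalue: float = 1e-6
    ortholog_identity: float = 60.0
    ortholog_coverage: float = 60.0
    p1bs_window: int = 1000

    @property
    def insert_bounds(self) -> tuple[int, int]:
        lo = self.sim.insert_mean - self.insert_sd_multiple * self.sim.insert_sd
        hi = self.sim.insert_mean + self.insert_sd_multiple * self.sim.insert_sd
        return (max(int(lo), self.sim.read_length), int(hi))


_RANGES: dict[str, tuple[float, float]] = {
    "containment_identity": (0.0, 1.0),
    "containment_cover": (0.0, 1.0),
    "reconstruction_identity": (0.0, 1.0),
    "fdr": (0.0, 1.0),
    "ortholog_identity": (0.0, 100.0),
    "ortholog_coverage": (0.0, 100.0),
}


def validate_config(raw: dict[str, Any] | None) -> tuple[PipelineConfig, list[str]]:
    """Build a normalized config from a parsed mapping, filling defaults.

    Returns the config plus the complete list of violations (field paths
    included); the config is usable only when the list is empty.
    Normalization is idempotent.
    """
    raw = dict(raw or {})
    errors: list[str] = []
    sim_raw = raw.pop("sim", {}) or {}
    sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    for key in sim_raw:
        if key not in sim_fields:
            errors.append(f"sim.{key}: unknown field")
    known = {k: v for k, v in sim_raw.items() if k in sim_fields}
    for key in ("tissues", "de_fold_range", "containment_span",
                "ortholog_identity_range", "ortholog_coverage_range"):
        if key in known and isinstance(known[key], list):
            known[key] = tuple(known[key])
    sim = SimulationConfig(**known)
    errors.extend(f"sim.{e}" for e in sim.validate())
    pipe_fields = {f.name for f in dataclasses.fields(PipelineConfig)} - {"sim"}
    for key in raw:
        if key not in pipe_fields:
            errors.append(f"{key}: unknown field")
    cfg = PipelineConfig(sim=sim, **{k: v for k, v in raw.items() if k in pipe_fields})
    for name, (lo, hi) in _RANGES.items():
        v = getattr(cfg, name)
        if not lo < v <= hi:
            errors.append(f"{name}: {v} outside ({lo}, {hi}]")
    if cfg.count_unit not in ("reads", "pairs"):
        errors.append(f"count_unit: {cfg.count_unit!r} not in {{reads, pairs}}")
    if cfg.p1bs_window < 8:
        errors.append("p1bs_window: must be >= 8")
    if not 11 <= cfg.seed_k <= cfg.sim.read_length:
        errors.append("seed_k: must be between 11 and the read length")
    return cfg, errors


def load_config(path: str | Path) -> tuple[PipelineConfig, list[str]]:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def _stage(name: str, n_in: int | None = None, n_out: int | None = None) -> None:
    parts = [f"stage={name}"]
    if n_in is not None:
        parts.append(f"in={n_in}")
    if n_out is not None:
        parts.append(f"out={n_out}")
    log.info(" ".join(parts))


def run_demo(config: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Run the full synthetic pipeline and score it against ground truth.

    Returns the summary dict (also written to ``summary.json``). Raises on
    stage failure after logging the stage name; partial outputs remain on
    disk.
    """
    t0 = time.time()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[tuple[str, int]] = []
    summary: dict[str, Any] = {"seed": config.sim.seed}
    stage = "simulate"
    try:
        # --- simulate -------------------------------------------------
        transcripts, truth = simulate_transcriptome(config.sim)
        write_fasta(transcripts, out / "transcripts.fasta")
        manifest.append(("transcripts.fasta", len(transcripts)))
        contigs = derive_contig_set(transcripts, truth, config.sim)
        write_fasta(contigs, out / "contigs.fasta")
        manifest.append(("contigs.fasta", len(contigs)))
        _stage(stage, len(transcripts), len(contigs))

        # --- dedupe ---------------------------------------------------
        stage = "dedupe"
        nonred = ap.remove_contained(
            contigs, config.containment_identity, config.containment_cover
        )
        dropped = {c.id for c in contigs} - {c.id for c in nonred}
        planted = {cid for cid, _, ident in truth.containment_pairs
                   if ident >= config.containment_identity}
        nonred = ap.select_longest_isoform(nonred)
        write_fasta(nonred, out / "nonredundant.fasta")
        manifest.append(("nonredundant.fasta", len(nonred)))
        tp = len(dropped & planted)
        summary["containment"] = {
            "planted": len(planted),
            "dropped": len(dropped),
            "recall": round(tp / len(planted), 4) if planted else 1.0,
            "precision": round(tp / len(dropped), 4) if dropped else 1.0,
        }
        _stage(stage, len(contigs), len(nonred))

        # --- stats / assess ------------------------------------------
        stage = "assess"
        stats = ap.contig_stats(contigs)
        summary["contig_stats"] = dataclasses.asdict(stats)
        recon = ap.assess_reconstruction(
            contigs, transcripts, config.reconstruction_identity,
            config.reconstruction_coverages,
        )
        recon.per_reference.to_csv(out / "reconstruction.tsv", sep="\t", index=False)
        manifest.append(("reconstruction.tsv", len(recon.per_reference)))
        summary["reconstruction"] = {
            f"fraction_cov{int(g * 100)}": round(f, 4)
            for g, f in recon.fractions.items()
        }
        _stage(stage, len(transcripts), len(recon.per_reference))

        # --- map + quantify ------------------------------------------
        stage = "map"
        index = rm.build_index(nonred, config.seed_k)
        lengths = pd.Series({r.id: len(r) for r in nonred})
        counts_by_lib: dict[tuple[str, str, int], pd.Series] = {}
        align_by_lib: dict[tuple[str, str, int], list] = {}
        map_rows = []
        for tissue in config.sim.tissues:
            for treatment in TREATMENTS:
                for rep in range(1, config.sim.n_replicates + 1):
                    r1, r2, _ = simulate_library(
                        transcripts, truth, tissue, treatment, rep, config.sim
                    )
                    lib = f"{tissue}_{treatment}_rep{rep}"
                    write_fastq(r1, out / f"{lib}_R1.fastq")
                    write_fastq(r2, out / f"{lib}_R2.fastq")
                    manifest.append((f"{lib}_R1.fastq", len(r1)))
                    manifest.append((f"{lib}_R2.fastq", len(r2)))
                    records, msum = rm.map_library(
                        zip(r1, r2), index,
                        config.max_mismatches_per_mate, config.insert_bounds,
                    )
                    key = (tissue, treatment, rep)
                    align_by_lib[key] = records
                    counts_by_lib[key] = quant.count_unique(
                        records, list(lengths.index), config.count_unit
                    )
                    map_rows.append((lib, msum.total, msum.unique, msum.pct_unique,
                                     msum.multi, msum.pct_multi,
                                     msum.unaligned, msum.pct_unaligned))
        map_df = pd.DataFrame(map_rows, columns=[
            "library", "total", "unique", "pct_unique", "multi", "pct_multi",
            "unaligned", "pct_unaligned"])
        map_df.to_csv(out / "mapping_summary.tsv", sep="\t", index=False)
        manifest.append(("mapping_summary.tsv", len(map_df)))
        summary["mapping"] = {
            "mean_pct_unique": round(float(map_df["pct_unique"].mean()), 2),
            "mean_pct_unaligned": round(float(map_df["pct_unaligned"].mean()), 2),
        }
        _stage(stage, int(map_df["total"].sum()), int(map_df["unique"].sum()))

        # --- quantify + DE per tissue --------------------------------
        stage = "quantify"
        de_summary: dict[str, Any] = {}
        expr_frames = []
        for tissue in config.sim.tissues:
            merged: dict[str, pd.Series] = {}
            totals: dict[str, int] = {}
            for treatment in TREATMENTS:
                reps = [counts_by_lib[(tissue, treatment, r)]
                        for r in range(1, config.sim.n_replicates + 1)]
                merged[treatment] = quant.merge_replicates(reps)
                totals[treatment] = int(merged[treatment].sum())
            rpkm_ctrl = quant.compute_rpkm(merged[CONTROL], totals[CONTROL], lengths)
            rpkm_trt = quant.compute_rpkm(merged[STARVED], totals[STARVED], lengths)
            table = pd.DataFrame({
                "count_ctrl": merged[CONTROL],
                "count_trt": merged[STARVED],
                "rpkm_ctrl": rpkm_ctrl["rpkm_reported"],
                "rpkm_trt": rpkm_trt["rpkm_reported"],
            })
            table["total_ctrl"] = totals[CONTROL]
            table["total_trt"] = totals[STARVED]
            result = de.call_de(table, config.fdr)
            result.insert(0, "tissue", tissue)
            expr_frames.append(result)
            de_summary[tissue] = _score_de(result, truth, tissue)
        de_table = pd.concat(expr_frames)
        de_out = de_table.round({"rpkm_ctrl": 2, "rpkm_trt": 2, "fold_change": 2,
                                 "g_stat": 3})
        de_out.to_csv(out / "de_results.tsv", sep="\t",
                      index_label="transcript_id")
        manifest.append(("de_results.tsv", len(de_out)))
        summary["de"] = de_summary
        _stage(stage, len(de_table), int((de_table["call"] != "ns").sum()))

        # --- compare (orthology + overlap) ---------------------------
        stage = "compare"
        proteins, hits_ab, hits_ba = simulate_cross_species(
            transcripts, truth, config.sim
        )
        write_fasta(proteins, out / "speciesB_proteins.fasta")
        write_hit_table(hits_ab, out / "hits_ab.tsv")
        write_hit_table(hits_ba, out / "hits_ba.tsv")
        manifest.append(("hits_ab.tsv", len(hits_ab)))
        manifest.append(("hits_ba.tsv", len(hits_ba)))
        pairs = cmp.reciprocal_best_hits(
            hits_ab, hits_ba, config.rbh_evalue, truth.lengths
        )
        recovered = {(p.id_a, p.id_b) for p in pairs}
        summary["orthology"] = {
            "planted": len(truth.ortholog_pairs),
            "recovered": len(recovered),
            "exact": recovered == set(truth.ortholog_pairs),
        }
        kept = cmp.filter_orthologs(pairs, config.ortholog_identity,
                                    config.ortholog_coverage)
        summary["orthology"]["passing_60_60"] = len(kept)
        omap = {p.id_a: {p.id_b} for p in kept}
        up_a = {t: set(de_table[(de_table["tissue"] == t)
                                & (de_table["call"] == "up")].index)
                for t in config.sim.tissues}
        b_of = dict(truth.ortholog_pairs)
        up_b = {t: {b_of[a] for a in truth.de_labels[t]
                    if truth.de_labels[t][a][0] == "up" and a in b_of}
                for t in config.sim.tissues}
        overlap = cmp.de_overlap(up_a, up_b, omap)
        summary["de_overlap"] = {
            t: len(s) for t, s in overlap.per_tissue.items()
        } | {"all_tissues": len(overlap.intersection)}
        _stage(stage, len(pairs), len(kept))

        # --- promoters / P1BS ----------------------------------------
        stage = "scan-p1bs"
        promoters, motif_truth = simulate_promoters(
            config.sim.n_promoters, config.sim, truth
        )
        write_fasta(promoters, out / "promoters.fasta")
        manifest.append(("promoters.fasta", len(promoters)))
        hit_rows = []
        recovered_exact = True
        for rec in promoters:
            hits = cmp.scan_p1bs(rec.sequence, rec.id, config.p1bs_window)
            found = sorted({h.start for h in hits})
            if found != sorted(p for p, _ in motif_truth[rec.id]):
                recovered_exact = False
            for h in hits:
                hit_rows.append((h.sequence_id, h.start, h.start + 8, h.strand,
                                 h.matched_octamer))
        pd.DataFrame(hit_rows, columns=["sequence", "start", "end", "strand",
                                        "octamer"]).to_csv(
            out / "p1bs_hits.tsv", sep="\t", index=False)
        manifest.append(("p1bs_hits.tsv", len(hit_rows)))
        summary["p1bs"] = {
            "planted": sum(len(v) for v in motif_truth.values()),
            "exact_recovery": recovered_exact,
        }
        _stage(stage, len(promoters), len(hit_rows))
    except Exception:
        log.error("stage %s failed", stage)
        raise

    summary["runtime_s"] = round(time.time() - t0, 1)
    with open(out / "MANIFEST.tsv", "w") as fh:
        fh.write("artifact\trecords\n")
        for name, n in manifest:
            fh.write(f"{name}\t{n}\n")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _score_de(result: pd.DataFrame, truth: GroundTruth, tissue: str) -> dict[str, Any]:
    """Sensitivity/FDR of the DE calls against planted labels.

    Sensitivity is reported overall and for the well-powered stratum
    (true fold >= 4, mean >= 50 reads across conditions)."""
    labels = truth.de_labels.get(tissue, {})
    called = result[result["call"] != "ns"]
    true_ids = set(labels)
    called_ids = set(called.index)
    tp = sum(1 for t in called_ids
             if t in labels and labels[t][0] == called.loc[t, "call"])
    mean_reads = (result["count_ctrl"] + result["count_trt"]) / 2.0
    strong = [t for t, (lab, fold) in labels.items()
              if max(fold, 1 / fold) >= 4.0 and t in result.index
              and mean_reads.loc[t] >= 50]
    strong_tp = sum(1 for t in strong if t in called_ids
                    and called.loc[t, "call"] == labels[t][0])
    fp = len(called_ids - true_ids)
    return {
        "n_called": len(called_ids),
        "n_planted": len(true_ids),
        "sensitivity": round(tp / len(true_ids), 4) if true_ids else 1.0,
        "sensitivity_strong": round(strong_tp / len(strong), 4) if strong else 1.0,
        "n_strong": len(strong),
        "false_discovery_rate": round(fp / len(called_ids), 4) if called_ids else 0.0,
    }
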