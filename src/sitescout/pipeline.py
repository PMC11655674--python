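"""End-to-end pipeline: DE filter -> regulon subtraction -> operons ->
promoters -> (optional ortholog harvest) -> motif discovery or loading ->
PWM scan -> hit aggregation, with a JSON summary of every stage."""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

from . import motifs, regulon, scan, seq

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All thresholds default to the pipeline's published operating point."""

    de_table: str = ""
    regulon_list: Optional[str] = None
    genome_fasta: str = ""
    annotation: str = ""              # .gff3/.gff or 5-column TSV
    motif_meme: Optional[str] = None  # load a PWM instead of discovering one
    out_dir: str = "pipeline_out"

    lfc_min: float = 2.0
    padj_max: float = 0.01
    operon_max_gap: int = 50
    promoter_up: int = 300
    promoter_down: int = 10
    rbh_min_cov: float = 0.70
    rbh_min_id: float = 0.35
    scan_p_cut: float = 1e-4
    motif_width: int = 22
    motif_restarts: int = 20
    cut_bind: float = 35.0
    cut_hth: float = 20.0
    cut_synth: float = 50.0
    both_strands: bool = True
    palindrome_constraint: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.padj_max <= 1.0):
            raise ValueError("padj_max must be in [0, 1]")
        if self.lfc_min < 0 or self.operon_max_gap < 0:
            raise ValueError("lfc_min and operon_max_gap must be nonnegative")
        if not (0.0 < self.scan_p_cut <= 1.0):
            raise ValueError("scan_p_cut must be in (0, 1]")
        for name in ("rbh_min_cov", "rbh_min_id"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.motif_width < 1:
            raise ValueError("motif_width must be positive")


def _read_annotation(path: str):
    if str(path).endswith((".gff", ".gff3")):
        return regulon.read_gff3(path)
    return regulon.read_annotation_tsv(path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the summary dict (also written to
    ``<out_dir>/summary.json``). All inputs are checked before any stage
    runs; a stage failure aborts with the stage named."""
    config.validate()
    required = {
        "de_table": config.de_table,
        "genome_fasta": config.genome_fasta,
        "annotation": config.annotation,
    }
    optional = {
        "regulon_list": config.regulon_list,
        "motif_meme": config.motif_meme,
    }
    missing = [k for k, v in required.items() if not v or not Path(v).exists()]
    missing += [k for k, v in optional.items() if v and not Path(v).exists()]
    if missing:
        raise FileNotFoundError(f"missing input(s): {', '.join(missing)}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": asdict(config), "stages": {}}

    def _stage(name):
        logger.info("stage: %s", name)
        return name

    try:
        stage = _stage("filter_de")
        de_records = regulon.read_de_table(config.de_table)
        de_genes = regulon.filter_de(
            de_records, lfc_min=config.lfc_min, padj_max=config.padj_max
        )
        summary["stages"]["filter_de"] = {
            "n_records": len(de_records),
            "n_de_genes": len(de_genes),
        }

        stage = _stage("subtract_regulon")
        if config.regulon_list:
            regulon_genes = regulon.read_regulon(config.regulon_list)
            remaining, removed = regulon.subtract_regulon(de_genes, regulon_genes)
        else:
            remaining, removed = list(de_genes), 0
        (out / "genes.txt").write_text("\n".join(remaining) + "\n")
        summary["stages"]["subtract_regulon"] = {
            "n_removed": removed,
            "n_remaining": len(remaining),
        }

        stage = _stage("call_operons")
        genes = _read_annotation(config.annotation)
        keep = set(remaining)
        selected = [g for g in genes if g.gene_id in keep]
        operons = regulon.call_operons(selected, max_gap=config.operon_max_gap)
        regulon.write_operons_tsv(operons, out / "operons.tsv")
        summary["stages"]["call_operons"] = {
            "n_genes_with_coordinates": len(selected),
            "n_operons": len(operons),
        }

        stage = _stage("extract_promoters")
        genome = seq.read_fasta(config.genome_fasta)
        promoters = regulon.extract_promoters(
            genome, operons, selected,
            up=config.promoter_up, down=config.promoter_down,
        )
        seq.write_fasta([p.seq for p in promoters], out / "promoters.fasta")
        regulon.write_promoters_bed(promoters, out / "promoters.bed")
        summary["stages"]["extract_promoters"] = {
            "n_promoters": len(promoters),
            "n_clipped": sum(p.clipped for p in promoters),
        }

        stage = _stage("motif")
        if config.motif_meme:
            pwm = motifs.read_meme(config.motif_meme)
            summary["stages"]["motif"] = {
                "source": "loaded",
                "width": pwm.width,
                "consensus": motifs.consensus_from_pwm(pwm).symbols,
            }
        else:
            scannable = [
                p for p in promoters if len(p.seq) >= config.motif_width
            ]
            model = motifs.discover_motif(
                scannable,
                w=config.motif_width,
                restarts=config.motif_restarts,
                seed=config.seed,
                both_strands=config.both_strands,
                palindrome_constraint=config.palindrome_constraint,
            )
            pwm = model.pwm
            motifs.write_motif_json(model, out / "motif.json")
            summary["stages"]["motif"] = {
                "source": "discovered",
                "width": pwm.width,
                "consensus": model.consensus.symbols,
                "occupancy": list(model.occupancy),
                "llr": model.llr,
            }
        motifs.write_meme(pwm, out / "motif.meme")

        stage = _stage("scan")
        hits = scan.scan_regions(
            pwm, promoters,
            p_cut=config.scan_p_cut, both_strands=config.both_strands,
        )
        scan.write_hits_tsv(hits, out / "hits.tsv")
        scan.write_hits_bed(hits, pwm.width, out / "hits.bed")
        summaries = scan.aggregate_hits(hits)
        summary["stages"]["scan"] = {
            "n_hits": len(hits),
            "n_regions_with_hits": len(summaries),
            "n_paired_sites": sum(
                sum(1 for s in r.sites if s.paired) for r in summaries
            ),
            "regions_ranked": [
                {"region": r.region_id, "best_pvalue": r.best_pvalue,
                 "n_hits": r.n_hits}
                for r in summaries
            ],
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    summary["seed"] = config.seed
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
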