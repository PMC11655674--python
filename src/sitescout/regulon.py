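"""Gene-set construction: DE thresholding, regulon subtraction, operon
collapsing, promoter-window extraction and domain-score classification.

Coordinates are 0-based half-open internally; GFF3 I/O converts from the
1-based inclusive convention.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import gffutils
import pandas as pd

from .seq import NucSequence, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "DERecord",
    "Operon",
    "PromoterRegion",
    "DomainScoreRecord",
    "filter_de",
    "subtract_regulon",
    "call_operons",
    "extract_promoters",
    "classify_domains",
    "read_gff3",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "read_de_table",
    "write_de_table",
    "read_regulon",
    "read_domain_scores",
    "write_domain_scores",
    "write_operons_tsv",
    "read_operons_tsv",
    "write_promoters_bed",
]


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    product: Optional[str] = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class DERecord:
    gene_id: str
    log2fc: float
    padj: Optional[float]

    def __post_init__(self):
        if self.padj is not None and not (0.0 <= self.padj <= 1.0):
            raise ValueError(f"gene {self.gene_id}: padj {self.padj} outside [0, 1]")
        if not math.isfinite(self.log2fc):
            raise ValueError(f"gene {self.gene_id}: log2fc must be finite")


@dataclass(frozen=True)
class Operon:
    operon_id: str
    gene_ids: tuple[str, ...]
    strand: str
    leader_gene: str
    contig: str
    overlap_flagged: bool = False

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class PromoterRegion:
    region_id: str
    source_operon: str
    contig: str
    start: int
    end: int
    strand: str
    seq: NucSequence
    clipped: bool = False


LABEL_LUXR_FULL = "LuxR_full"
LABEL_LUXR_TRUNCATED = "LuxR_truncated"
LABEL_LUXI = "LuxI"
LABEL_UNCLASSIFIED = "unclassified"


@dataclass
class DomainScoreRecord:
    protein_id: str
    score_autoind_bind: Optional[float] = None
    score_gere_hth: Optional[float] = None
    score_autoind_synth: Optional[float] = None
    label: str = LABEL_UNCLASSIFIED
    conflict: bool = False


# ---------------------------------------------------------------------------
# operations


def filter_de(
    records: Sequence[DERecord],
    lfc_min: float = 2.0,
    padj_max: float = 0.01,
) -> list[str]:
    """Genes with ``|log2fc| >= lfc_min`` and ``padj <= padj_max``.

    Both bounds are inclusive. Records with a missing adjusted p-value are
    skipped with a warning.
    """
    kept: list[str] = []
    n_missing = 0
    for rec in records:
        if rec.padj is None:
            n_missing += 1
            continue
        if abs(rec.log2fc) >= lfc_min and rec.padj <= padj_max:
            kept.append(rec.gene_id)
    if n_missing:
        warnings.warn(
            f"{n_missing} DE record(s) skipped: missing adjusted p-value",
            stacklevel=2,
        )
    return kept


def subtract_regulon(
    de_genes: Sequence[str], regulon: Iterable[str]
) -> tuple[list[str], int]:
    """Remove regulon members from a gene list, preserving order.

    Returns ``(remaining_genes, removed_count)``.
    """
    regulon_set = set(regulon)
    remaining = [g for g in de_genes if g not in regulon_set]
    removed = len(de_genes) - len(remaining)
    logger.info("regulon subtraction removed %d of %d genes", removed, len(de_genes))
    return remaining, removed


def call_operons(genes: Sequence[GeneRecord], max_gap: int = 50) -> list[Operon]:
    """Collapse genes into transcriptional units.

    Consecutive genes on the same contig and strand whose intergenic gap
    (``next.start - prev.end``) is strictly less than ``max_gap`` are chained
    transitively. Overlapping genes (negative gap) are treated as gap 0,
    chained, and the operon is flagged. The output partitions the input.
    """
    ordered = sorted(genes, key=lambda g: (g.contig, g.start, g.end, g.gene_id))
    operons: list[Operon] = []
    chain: list[GeneRecord] = []
    flagged = False

    def _flush():
        nonlocal chain, flagged
        if not chain:
            return
        strand = chain[0].strand
        leader = chain[0] if strand == "+" else chain[-1]
        operons.append(
            Operon(
                operon_id=f"op{len(operons):04d}",
                gene_ids=tuple(g.gene_id for g in chain),
                strand=strand,
                leader_gene=leader.gene_id,
                contig=chain[0].contig,
                overlap_flagged=flagged,
            )
        )
        chain = []
        flagged = False

    for gene in ordered:
        if chain:
            prev = chain[-1]
            gap = gene.start - prev.end
            same_unit = (
                gene.contig == prev.contig
                and gene.strand == prev.strand
                and max(gap, 0) < max_gap
            )
            if same_unit and gap < 0:
                flagged = True
            if not same_unit:
                _flush()
        chain.append(gene)
    _flush()
    return operons


def extract_promoters(
    genome: Union[Mapping[str, NucSequence], Sequence[NucSequence]],
    operons: Sequence[Operon],
    genes: Sequence[GeneRecord],
    up: int = 300,
    down: int = 10,
    circular_wrap: bool = False,
) -> list[PromoterRegion]:
    """One promoter window per operon, taken from its leader gene.

    For a ``+`` leader starting at ``s`` the window is ``[s-up, s+down)`` on
    the forward strand; for a ``-`` leader ending at ``e`` it is
    ``[e-down, e+up)`` reverse-complemented. The returned sequence is
    strand-oriented 5'->3' toward the start codon. Windows that run off a
    contig edge are clipped and flagged unless ``circular_wrap`` is set and
    the contig is circular.
    """
    contigs = (
        {s.id: s for s in genome} if not isinstance(genome, Mapping) else dict(genome)
    )
    by_id = {g.gene_id: g for g in genes}
    regions: list[PromoterRegion] = []
    for op in operons:
        if op.leader_gene not in by_id:
            raise KeyError(
                f"operon {op.operon_id}: leader gene {op.leader_gene!r} "
                "absent from annotation"
            )
        gene = by_id[op.leader_gene]
        if gene.contig not in contigs:
            raise KeyError(
                f"operon {op.operon_id}: contig {gene.contig!r} absent from genome"
            )
        contig = contigs[gene.contig]
        L = len(contig)
        if gene.strand == "+":
            lo, hi = gene.start - up, gene.start + down
        else:
            lo, hi = gene.end - down, gene.end + up
        wrap = circular_wrap and contig.circular
        if wrap:
            window = "".join(contig.seq[i % L] for i in range(lo, hi))
            clipped = False
            lo_c, hi_c = lo % L, lo % L + (hi - lo)
        else:
            lo_c, hi_c = max(lo, 0), min(hi, L)
            clipped = (lo_c != lo) or (hi_c != hi)
            window = contig.seq[lo_c:hi_c]
        if gene.strand == "-":
            window = revcomp(window)
        region_id = f"{op.operon_id}|{gene.gene_id}"
        regions.append(
            PromoterRegion(
                region_id=region_id,
                source_operon=op.operon_id,
                contig=gene.contig,
                start=lo_c,
                end=hi_c,
                strand=gene.strand,
                seq=NucSequence(region_id, window),
                clipped=clipped,
            )
        )
    return regions


def classify_domains(
    scores: Sequence[DomainScoreRecord],
    cut_bind: float = 35.0,
    cut_hth: float = 20.0,
    cut_synth: float = 50.0,
) -> list[DomainScoreRecord]:
    """Label proteins by domain scores.

    ``LuxR_full`` requires the autoinducer-binding score at/above
    ``cut_bind`` and the HTH score at/above ``cut_hth``; ``LuxR_truncated``
    has the binding domain but no qualifying HTH; ``LuxI`` requires the
    synthase score at/above ``cut_synth``. A protein qualifying as both
    LuxR and LuxI keeps the LuxR label with ``conflict=True``.
    """
    out: list[DomainScoreRecord] = []
    for rec in scores:
        bind = rec.score_autoind_bind
        hth = rec.score_gere_hth
        synth = rec.score_autoind_synth
        is_luxr = bind is not None and bind >= cut_bind
        is_luxi = synth is not None and synth >= cut_synth
        if is_luxr:
            label = (
                LABEL_LUXR_FULL
                if (hth is not None and hth >= cut_hth)
                else LABEL_LUXR_TRUNCATED
            )
        elif is_luxi:
            label = LABEL_LUXI
        else:
            label = LABEL_UNCLASSIFIED
        out.append(
            DomainScoreRecord(
                protein_id=rec.protein_id,
                score_autoind_bind=bind,
                score_gere_hth=hth,
                score_autoind_synth=synth,
                label=label,
                conflict=is_luxr and is_luxi,
            )
        )
    return out


# ---------------------------------------------------------------------------
# I/O


def read_gff3(path, id_attribute: str = "ID", feature_types=("gene",)) -> list[GeneRecord]:
    """Read gene coordinates from GFF3 (1-based inclusive -> half-open)."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneRecord] = []
    for ftype in feature_types:
        for feat in db.features_of_type(ftype):
            attrs = feat.attributes
            if id_attribute in attrs:
                gid = attrs[id_attribute][0]
            elif "locus_tag" in attrs:
                gid = attrs["locus_tag"][0]
            else:
                gid = feat.id
            product = attrs["product"][0] if "product" in attrs else None
            genes.append(
                GeneRecord(
                    gene_id=gid,
                    contig=feat.seqid,
                    start=feat.start - 1,
                    end=feat.end,
                    strand=feat.strand,
                    product=product,
                )
            )
    return genes


def read_annotation_tsv(path) -> list[GeneRecord]:
    """Read a 5-column TSV (gene_id, contig, start, end, strand); 0-based half-open."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "contig": str})
    required = {"gene_id", "contig", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation TSV missing columns: {sorted(missing)}")
    return [
        GeneRecord(
            gene_id=row.gene_id,
            contig=row.contig,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
        )
        for row in df.itertuples()
    ]


def write_annotation_tsv(genes: Sequence[GeneRecord], path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "contig": [g.contig for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_de_table(records: Sequence[DERecord], path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "log2fc": [r.log2fc for r in records],
            "padj": [r.padj for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_de_table(path) -> list[DERecord]:
    """Read a DE table TSV with columns gene_id, log2fc, padj."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples():
        padj = None if pd.isna(row.padj) else float(row.padj)
        records.append(DERecord(str(row.gene_id), float(row.log2fc), padj))
    return records


def read_regulon(path) -> list[str]:
    """Read a gene list, one id per line; blank lines and # comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


_SCORE_COLUMNS = ("score_autoind_bind", "score_gere_hth", "score_autoind_synth")


def read_domain_scores(path) -> list[DomainScoreRecord]:
    df = pd.read_csv(path, sep="\t")
    if "protein_id" not in df.columns:
        raise ValueError("domain score TSV requires a protein_id column")
    records = []
    for row in df.itertuples():
        kwargs = {}
        for col in _SCORE_COLUMNS:
            val = getattr(row, col, None)
            kwargs[col] = None if val is None or pd.isna(val) else float(val)
        records.append(DomainScoreRecord(protein_id=str(row.protein_id), **kwargs))
    return records


def write_domain_scores(records: Sequence[DomainScoreRecord], path) -> None:
    df = pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in records],
            "score_autoind_bind": [r.score_autoind_bind for r in records],
            "score_gere_hth": [r.score_gere_hth for r in records],
            "score_autoind_synth": [r.score_autoind_synth for r in records],
            "label": [r.label for r in records],
            "conflict": [r.conflict for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_operons_tsv(operons: Sequence[Operon], path) -> None:
    df = pd.DataFrame(
        {
            "operon_id": [o.operon_id for o in operons],
            "contig": [o.contig for o in operons],
            "strand": [o.strand for o in operons],
            "leader_gene": [o.leader_gene for o in operons],
            "n_genes": [len(o) for o in operons],
            "gene_ids": [",".join(o.gene_ids) for o in operons],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_operons_tsv(path) -> list[Operon]:
    df = pd.read_csv(path, sep="\t")
    return [
        Operon(
            operon_id=row.operon_id,
            gene_ids=tuple(row.gene_ids.split(",")),
            strand=row.strand,
            leader_gene=row.leader_gene,
            contig=row.contig,
        )
        for row in df.itertuples()
    ]


def write_promoters_bed(regions: Sequence[PromoterRegion], path) -> None:
    """Write promoter windows as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.contig}\t{r.start}\t{r.end}\t{r.region_id}\t0\t{r.strand}\n"
            )
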