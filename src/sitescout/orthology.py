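"""Reciprocal-best-hit ortholog detection from pairwise local alignment.

Alignment scoring follows the common protein-search defaults: BLOSUM62,
and an affine gap of length L costing ``gap_open + L * gap_extend``
(defaults 11/1). The alignment engine is Biopython's PairwiseAligner; an
independent quadratic dynamic-programming oracle lives in the test suite.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .regulon import GeneRecord, Operon, PromoterRegion, extract_promoters
from .seq import NucSequence

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinSequence",
    "AlignmentResult",
    "OrthologPair",
    "SpeciesBundle",
    "align_pair",
    "reciprocal_best_hits",
    "harvest_ortholog_promoters",
    "read_protein_fasta",
]

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinSequence:
    id: str
    seq: str

    def __post_init__(self):
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.seq:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.seq) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.id!r}: invalid residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignmentResult:
    query_id: str
    subject_id: str
    score: float
    identity: float       # matches / aligned columns (gap columns included)
    coverage_q: float     # aligned span on query / query length
    coverage_s: float     # aligned span on subject / subject length


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    mutual: bool
    forward: AlignmentResult   # a -> b
    reverse: AlignmentResult   # b -> a
    tie_flagged: bool = False


def _make_aligner(substitution_matrix, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if substitution_matrix is None:
        substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.substitution_matrix = substitution_matrix
    # Biopython charges open for the first gap position and extend thereafter;
    # open+extend reproduces the "open + L*extend" convention.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_pair(
    a: ProteinSequence,
    b: ProteinSequence,
    mode: str = "local",
    substitution_matrix=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> AlignmentResult:
    """Optimal affine-gap local alignment of two proteins.

    Identity is matches over aligned columns (internal gap columns count);
    coverage of each sequence is its aligned span over its length.
    """
    if mode != "local":
        raise ValueError("only local alignment is supported")
    aligner = _make_aligner(substitution_matrix, gap_open, gap_extend)
    alignments = aligner.align(a.seq, b.seq)
    if len(alignments) == 0 or alignments.score <= 0:
        return AlignmentResult(a.id, b.id, 0.0, 0.0, 0.0, 0.0)
    aln = alignments[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    tc, qc = aln.coordinates[0], aln.coordinates[1]
    span_a = int(tc[-1] - tc[0])
    span_b = int(qc[-1] - qc[0])
    return AlignmentResult(
        query_id=a.id,
        subject_id=b.id,
        score=float(alignments.score),
        identity=identity,
        coverage_q=span_a / len(a),
        coverage_s=span_b / len(b),
    )


def reciprocal_best_hits(
    proteome_a: Sequence[ProteinSequence],
    proteome_b: Sequence[ProteinSequence],
    min_cov: float = 0.70,
    min_id: float = 0.35,
    **align_kwargs,
) -> list[OrthologPair]:
    """All-vs-all RBH between two proteomes.

    ``(a, b)`` is reported iff b is a's top-scoring hit in B, a is b's
    top-scoring hit in A, and both directions pass ``identity >= min_id``
    and query coverage ``>= min_cov``. Score ties are broken by
    lexicographic id and flagged.
    """
    for name, prot in (("A", proteome_a), ("B", proteome_b)):
        ids = [p.id for p in prot]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate ids in proteome {name}")
    if not proteome_a or not proteome_b:
        warnings.warn("empty proteome: no reciprocal best hits", stacklevel=2)
        return []

    # local alignment score is symmetric; coverage is direction-specific
    fwd: dict[tuple[str, str], AlignmentResult] = {}
    for a in proteome_a:
        for b in proteome_b:
            fwd[(a.id, b.id)] = align_pair(a, b, **align_kwargs)

    def _best(hits: list[AlignmentResult]) -> tuple[AlignmentResult, bool]:
        top = max(hits, key=lambda r: (r.score, r.subject_id))
        best = min(
            (r for r in hits if r.score == top.score),
            key=lambda r: r.subject_id,
        )
        tie = sum(1 for r in hits if r.score == top.score) > 1
        return best, tie

    best_a: dict[str, tuple[str, bool]] = {}
    for a in proteome_a:
        hit, tie = _best([fwd[(a.id, b.id)] for b in proteome_b])
        best_a[a.id] = (hit.subject_id, tie)
    b_by_id = {p.id: p for p in proteome_b}
    a_by_id = {p.id: p for p in proteome_a}
    best_b: dict[str, tuple[str, bool]] = {}
    for b in proteome_b:
        hits = [fwd[(a.id, b.id)] for a in proteome_a]
        top_score = max(h.score for h in hits)
        cands = sorted(h.query_id for h in hits if h.score == top_score)
        best_b[b.id] = (cands[0], len(cands) > 1)

    pairs: list[OrthologPair] = []
    for a in proteome_a:
        b_id, tie_a = best_a[a.id]
        a_back, tie_b = best_b[b_id]
        if a_back != a.id:
            continue
        f = fwd[(a.id, b_id)]
        r = align_pair(b_by_id[b_id], a_by_id[a.id], **align_kwargs)
        ok = (
            f.identity >= min_id
            and f.coverage_q >= min_cov
            and r.identity >= min_id
            and r.coverage_q >= min_cov
        )
        if ok:
            pairs.append(
                OrthologPair(
                    gene_a=a.id,
                    gene_b=b_id,
                    mutual=True,
                    forward=f,
                    reverse=r,
                    tie_flagged=tie_a or tie_b,
                )
            )
    return pairs


@dataclass
class SpeciesBundle:
    """Per-species inputs for ortholog promoter harvesting."""

    name: str
    genome: Sequence[NucSequence]
    annotation: Sequence[GeneRecord]
    proteome: Sequence[ProteinSequence]


def harvest_ortholog_promoters(
    target_gene: str,
    species_bundles: Sequence[SpeciesBundle],
    reference_proteome: Sequence[ProteinSequence],
    up: int = 300,
    down: int = 10,
    min_cov: float = 0.70,
    min_id: float = 0.35,
    **align_kwargs,
) -> tuple[list[PromoterRegion], dict[str, str]]:
    """Promoter windows of a gene's reciprocal-best-hit orthologs.

    For each species with an RBH to ``target_gene`` the ortholog's promoter
    window is extracted; the report maps species name to the ortholog gene
    id, or to an explanatory status for species lacking one.
    """
    ref_ids = {p.id for p in reference_proteome}
    if target_gene not in ref_ids:
        raise KeyError(f"target gene {target_gene!r} absent from reference proteome")

    promoters: list[PromoterRegion] = []
    report: dict[str, str] = {}
    for bundle in species_bundles:
        try:
            pairs = reciprocal_best_hits(
                reference_proteome,
                list(bundle.proteome),
                min_cov=min_cov,
                min_id=min_id,
                **align_kwargs,
            )
            match = next((p for p in pairs if p.gene_a == target_gene), None)
            if match is None:
                report[bundle.name] = "no-reciprocal-best-hit"
                continue
            ortholog = match.gene_b
            gene = next(
                (g for g in bundle.annotation if g.gene_id == ortholog), None
            )
            if gene is None:
                report[bundle.name] = f"ortholog {ortholog} absent from annotation"
                continue
            singleton = Operon(
                operon_id=f"{bundle.name}|{ortholog}",
                gene_ids=(ortholog,),
                strand=gene.strand,
                leader_gene=ortholog,
                contig=gene.contig,
            )
            regions = extract_promoters(
                list(bundle.genome), [singleton], [gene], up=up, down=down
            )
            promoters.extend(regions)
            report[bundle.name] = ortholog
        except (KeyError, ValueError) as exc:
            logger.error("species %s skipped: %s", bundle.name, exc)
            report[bundle.name] = f"error: {exc}"
    return promoters, report


def read_protein_fasta(path) -> list[ProteinSequence]:
    from Bio import SeqIO

    records = [
        ProteinSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    ids = [r.id for r in records]
    if len(ids) != len(set(ids)):
        raise ValueError(f"duplicate ids in protein FASTA {path}")
    return records
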