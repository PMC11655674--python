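"""Synthetic-data generators with ground-truth sidecars.

Every generator is deterministic under its seed and emits enough ground
truth to score recovery without re-reading generator internals. Non-DE
log2 fold changes are drawn from Normal(0, 0.5) truncated to (-2, 2); DE
values from +/-(2 + Exponential(1)).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .motifs import PWM, BASES, build_pwm
from .regulon import DERecord, GeneRecord, PromoterRegion
from .seq import NucSequence, revcomp

__all__ = [
    "GroundTruth",
    "gen_genome",
    "gen_de_table",
    "plant_sites",
    "gen_ortholog_family",
    "build_artificial_promoter",
    "random_pwm",
    "random_sequence",
]


@dataclass
class GroundTruth:
    """Sidecar recording what a generator planted."""

    seed: int
    planted_sites: dict[str, dict] = field(default_factory=dict)
    true_pwm: Optional[list[list[float]]] = None
    de_genes: list[str] = field(default_factory=list)
    regulon_genes: list[str] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _gc_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    codes = rng.choice(4, size=length, p=_gc_probs(gc))
    return "".join(BASES[c] for c in codes)


def random_pwm(
    w: int,
    seed: int,
    min_dom: float = 0.75,
    max_dom: float = 0.95,
    background: Optional[np.ndarray] = None,
) -> PWM:
    """An informative PWM: each column has one dominant base."""
    rng = np.random.default_rng(seed)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    freq = np.empty((w, 4))
    for i in range(w):
        dom = rng.integers(4)
        p = rng.uniform(min_dom, max_dom)
        rest = rng.dirichlet(np.ones(3)) * (1 - p)
        row = np.empty(4)
        row[dom] = p
        row[[b for b in range(4) if b != dom]] = rest
        freq[i] = row
    return PWM(freq, bg / bg.sum())


def _draw(law, rng: np.random.Generator) -> int:
    """Resolve a distribution spec: int constant, (lo, hi) uniform, or callable."""
    if callable(law):
        return int(law(rng))
    if isinstance(law, tuple):
        lo, hi = law
        return int(rng.integers(lo, hi + 1))
    return int(law)


def gen_genome(
    n_genes: int,
    gap_law: Union[int, tuple[int, int], Callable] = 100,
    strand_law: Union[float, Callable] = 0.8,
    mean_gene_len: int = 900,
    gc: float = 0.69,
    seed: int = 0,
    contig_id: str = "chr1",
) -> tuple[NucSequence, list[GeneRecord]]:
    """A single-contig genome with controllable intergenic gaps and strands.

    ``gap_law`` gives the gap after each gene (constant, uniform range or
    callable); ``strand_law`` is the probability of '+' or a callable. Gaps
    may not push a gene start before the previous one.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    genes: list[GeneRecord] = []
    pos = _draw(gap_law, rng)
    if pos < 0:
        raise ValueError("leading gap must be nonnegative")
    for i in range(n_genes):
        length = max(90, int(round(rng.normal(mean_gene_len, mean_gene_len * 0.1))))
        if callable(strand_law):
            strand = strand_law(rng)
        else:
            strand = "+" if rng.random() < strand_law else "-"
        start, end = pos, pos + length
        genes.append(
            GeneRecord(
                gene_id=f"g{i:05d}", contig=contig_id, start=start, end=end,
                strand=strand,
            )
        )
        gap = _draw(gap_law, rng)
        nxt = end + gap
        if nxt <= start:
            raise ValueError(
                f"gap {gap} after gene {i} places the next gene before the "
                "current one (impossible geometry)"
            )
        pos = nxt
    total = genes[-1].end + 100
    contig = NucSequence(contig_id, random_sequence(total, gc, rng))
    return contig, genes


def gen_de_table(
    n_genes: int,
    n_de: int,
    n_regulon_overlap: int,
    lfc_law: Optional[Callable] = None,
    seed: int = 0,
    n_regulon_extra: int = 0,
) -> tuple[list[DERecord], list[str], GroundTruth]:
    """A DE table with an exact number of threshold-passing genes and an
    exact overlap with a generated regulon list.

    DE genes pass ``|log2fc| >= 2 and padj <= 0.01`` by construction;
    non-DE genes fail the fold-change bound. ``n_regulon_extra`` pads the
    regulon with additional non-DE genes.
    """
    if not (0 <= n_regulon_overlap <= n_de <= n_genes):
        raise ValueError("need 0 <= n_regulon_overlap <= n_de <= n_genes")
    if n_regulon_extra > n_genes - n_de:
        raise ValueError("n_regulon_extra exceeds available non-DE genes")
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    de_set = set(de_idx.tolist())

    records: list[DERecord] = []
    for i, gid in enumerate(gene_ids):
        if i in de_set:
            if lfc_law is not None:
                lfc = float(lfc_law(rng))
            else:
                lfc = float((2.0 + rng.exponential(1.0)) * rng.choice([-1.0, 1.0]))
            padj = float(rng.uniform(1e-8, 0.01))
        else:
            lfc = float(np.clip(rng.normal(0.0, 0.5), -1.999, 1.999))
            padj = float(rng.uniform(0.0, 1.0))
        records.append(DERecord(gid, lfc, padj))

    de_gene_ids = [gene_ids[i] for i in sorted(de_set)]
    overlap = rng.choice(len(de_gene_ids), size=n_regulon_overlap, replace=False)
    regulon = [de_gene_ids[i] for i in sorted(overlap.tolist())]
    if n_regulon_extra:
        non_de = [i for i in range(n_genes) if i not in de_set]
        extra = rng.choice(len(non_de), size=n_regulon_extra, replace=False)
        regulon += [gene_ids[non_de[i]] for i in sorted(extra.tolist())]

    truth = GroundTruth(
        seed=seed,
        de_genes=de_gene_ids,
        regulon_genes=regulon,
        extras={
            "n_genes": n_genes,
            "n_de": n_de,
            "n_regulon_overlap": n_regulon_overlap,
            "expected_after_subtraction": n_de - n_regulon_overlap,
        },
    )
    return records, regulon, truth


def _sample_site(pwm: PWM, rng: np.random.Generator) -> str:
    return "".join(
        BASES[rng.choice(4, p=pwm.freq[i])] for i in range(pwm.width)
    )


def plant_sites(
    regions: Sequence,
    pwm: PWM,
    occupancy: Union[float, int],
    strand_law: Union[float, Callable] = 1.0,
    seed: int = 0,
) -> tuple[list[PromoterRegion], GroundTruth]:
    """Plant one PWM-sampled site per selected region at a uniform offset.

    ``occupancy`` is either a fraction (each region receives a site
    independently with that probability) or an integer (exactly that many
    regions, chosen uniformly, receive a site). Ground truth records the
    offset, strand and planted word per region.
    """
    rng = np.random.default_rng(seed)
    w = pwm.width
    items = []
    for r in regions:
        if isinstance(r, PromoterRegion):
            items.append((r.region_id, r.seq.seq, r))
        elif isinstance(r, NucSequence):
            items.append((r.id, r.seq, None))
        else:
            raise TypeError("regions must be PromoterRegion or NucSequence")
    for rid, s, _ in items:
        if len(s) < w:
            raise ValueError(f"region {rid!r} shorter than PWM width {w}")

    if isinstance(occupancy, (int, np.integer)) and not isinstance(occupancy, bool):
        if occupancy > len(items):
            raise ValueError("occupancy count exceeds number of regions")
        chosen = set(
            rng.choice(len(items), size=int(occupancy), replace=False).tolist()
        )
        receives = [i in chosen for i in range(len(items))]
    else:
        receives = [bool(rng.random() < float(occupancy)) for _ in items]

    truth = GroundTruth(
        seed=seed,
        true_pwm=[list(map(float, row)) for row in pwm.freq],
    )
    out: list[PromoterRegion] = []
    for i, (rid, s, orig) in enumerate(items):
        if receives[i]:
            word = _sample_site(pwm, rng)
            offset = int(rng.integers(0, len(s) - w + 1))
            if callable(strand_law):
                strand = strand_law(rng)
            else:
                strand = "+" if rng.random() < float(strand_law) else "-"
            inserted = word if strand == "+" else revcomp(word)
            s = s[:offset] + inserted + s[offset + w :]
            truth.planted_sites[rid] = {
                "offset": offset, "strand": strand, "word": word,
            }
        seq = NucSequence(rid, s)
        if orig is not None:
            out.append(
                PromoterRegion(
                    region_id=orig.region_id,
                    source_operon=orig.source_operon,
                    contig=orig.contig,
                    start=orig.start,
                    end=orig.end,
                    strand=orig.strand,
                    seq=seq,
                    clipped=orig.clipped,
                )
            )
        else:
            out.append(
                PromoterRegion(
                    region_id=rid, source_operon=rid, contig=rid,
                    start=0, end=len(s), strand="+", seq=seq,
                )
            )
    return out, truth


def gen_ortholog_family(
    base_promoter: NucSequence,
    n_species: int,
    divergence: float,
    conserve: Sequence[tuple[int, int]] = (),
    seed: int = 0,
) -> list[PromoterRegion]:
    """Diverged copies of a promoter with conserved intervals untouched.

    Substitutions occur i.i.d. at rate ``divergence`` outside the conserved
    (0-based half-open) intervals, uniformly over the three alternative
    bases. Overlapping conserve intervals are merged with a warning.
    """
    L = len(base_promoter)
    ivals = sorted((int(a), int(b)) for a, b in conserve)
    for a, b in ivals:
        if not (0 <= a < b <= L):
            raise ValueError(f"conserve interval [{a}, {b}) outside promoter")
    merged: list[list[int]] = []
    for a, b in ivals:
        if merged and a < merged[-1][1]:
            warnings.warn("overlapping conserve intervals merged", stacklevel=2)
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    protected = np.zeros(L, dtype=bool)
    for a, b in merged:
        protected[a:b] = True

    rng = np.random.default_rng(seed)
    base = base_promoter.seq
    out: list[PromoterRegion] = []
    for k in range(n_species):
        chars = list(base)
        mutate = (rng.random(L) < divergence) & ~protected
        for pos in np.flatnonzero(mutate):
            alternatives = [b for b in BASES if b != chars[pos]]
            chars[pos] = alternatives[rng.integers(3)]
        rid = f"sp{k:02d}|{base_promoter.id}"
        seq = NucSequence(rid, "".join(chars))
        out.append(
            PromoterRegion(
                region_id=rid, source_operon=rid, contig=rid,
                start=0, end=L, strand="+", seq=seq,
            )
        )
    return out


def build_artificial_promoter(
    bs: str = "TATCCAAAAAGACAG",
    minus35: str = "TTGACA",
    minus10: str = "TATAAT",
    pad5: int = 1,
    pad3: int = 1,
    flank_len: int = 20,
    flank_gc: float = 0.5,
    seed: int = 0,
) -> tuple[NucSequence, dict[str, tuple[int, int]]]:
    """A promoter construct: flank, -35 element, spacer, binding site,
    spacer, -10 element, flank.

    Default pads give the canonical 17-bp spacing between the -35 and -10
    hexamers around a 15-bp insert. Returns the sequence and 0-based
    half-open coordinates of every element.
    """
    if pad5 < 0 or pad3 < 0:
        raise ValueError("pads must be nonnegative")
    rng = np.random.default_rng(seed)
    f5 = random_sequence(flank_len, flank_gc, rng)
    f3 = random_sequence(flank_len, flank_gc, rng)
    s5 = random_sequence(pad5, flank_gc, rng)
    s3 = random_sequence(pad3, flank_gc, rng)
    parts = [f5, minus35, s5, bs, s3, minus10, f3]
    names = ["flank5", "minus35", "spacer5", "bs", "spacer3", "minus10", "flank3"]
    coords: dict[str, tuple[int, int]] = {}
    pos = 0
    for name, part in zip(names, parts):
        coords[name] = (pos, pos + len(part))
        pos += len(part)
    return NucSequence("artificial_promoter", "".join(parts)), coords
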