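"""PWM scanning with exact p-values.

The score of a word is the summed per-position log2-odds of the PWM
frequencies against a 0-order background. P-values are exact tail
probabilities of that score for a background-generated word, computed by
dynamic programming over positions on an epsilon-discretized score axis
(conservative rounding: reported p-values are taken at the floor bin, so a
claimed p is never smaller than the true tail at the discretized score).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .motifs import PWM, _encode
from .regulon import PromoterRegion
from .seq import NucSequence

__all__ = [
    "ScoreDistribution",
    "ScanHit",
    "SiteSummary",
    "RegionSummary",
    "logodds",
    "score_distribution",
    "pvalue",
    "score_for_pvalue",
    "scan_region",
    "scan_regions",
    "aggregate_hits",
    "write_hits_tsv",
    "write_hits_bed",
]


def logodds(pwm: PWM) -> np.ndarray:
    """Per-position, per-base log2(f/pi) matrix of shape (w, 4)."""
    if (pwm.background <= 0).any():
        raise ValueError("background entries must all be positive")
    if (pwm.freq <= 0).any():
        raise ValueError(
            "PWM frequencies must all be positive (apply a pseudocount first)"
        )
    return np.log2(pwm.freq / pwm.background[None, :])


@dataclass
class ScoreDistribution:
    """Exact background distribution of a PWM's discretized log-odds score.

    Integer score k corresponds to real score ``k * eps``. ``tail[j]`` is
    ``P(S >= kmin + j)`` for the integer score axis ``kmin .. kmax``.
    """

    eps: float
    kmin: int
    pmf: np.ndarray
    tail: np.ndarray
    kmatrix: np.ndarray  # (w, 4) integer-discretized log-odds

    @property
    def kmax(self) -> int:
        return self.kmin + len(self.tail) - 1

    def pvalue_int(self, k: int) -> float:
        """Exact tail at an integer discretized score."""
        if k < self.kmin:
            return 1.0
        if k > self.kmax:
            return float(self.tail[-1])
        return float(self.tail[k - self.kmin])

    def word_score_int(self, codes: np.ndarray) -> int:
        w = self.kmatrix.shape[0]
        return int(self.kmatrix[np.arange(w), codes].sum())


def score_distribution(
    pwm: PWM, eps: float = 1e-3, max_bins: int = 20_000_000
) -> ScoreDistribution:
    """Exact score distribution under the PWM's background by convolution.

    Discretization error in score is at most ``w * eps / 2`` (entries are
    rounded to the nearest multiple of ``eps``).
    """
    lo = logodds(pwm)
    K = np.round(lo / eps).astype(np.int64)
    kmin = int(K.min(axis=1).sum())
    kmax = int(K.max(axis=1).sum())
    nbins = kmax - kmin + 1
    if nbins > max_bins:
        raise ValueError(
            f"score axis needs {nbins} bins (> {max_bins}); "
            f"increase eps (currently {eps})"
        )
    pi = pwm.background
    pmf = np.array([1.0])
    lo_off = 0  # integer score of pmf[0]
    for i in range(pwm.width):
        ks = K[i]
        new_lo = lo_off + int(ks.min())
        new_hi = lo_off + int(ks.max()) + len(pmf) - 1
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            start = lo_off + int(ks[b]) - new_lo
            new[start : start + len(pmf)] += pi[b] * pmf
        pmf = new
        lo_off = new_lo
    assert lo_off == kmin and len(pmf) == nbins
    tail = np.cumsum(pmf[::-1])[::-1]
    tail = np.minimum(tail, 1.0)
    return ScoreDistribution(eps=eps, kmin=kmin, pmf=pmf, tail=tail, kmatrix=K)


def pvalue(dist: ScoreDistribution, s: float) -> float:
    """Exact tail probability at the nearest discretized score at-or-below s."""
    k = math.floor(s / dist.eps + 1e-9)
    return dist.pvalue_int(k)


def score_for_pvalue(dist: ScoreDistribution, p: float) -> float:
    """Smallest discretized score whose exact tail is at most p.

    Returns ``inf`` (with a warning) when even the maximum achievable
    score has a tail above p.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must be in (0, 1], got {p}")
    # tail is non-increasing; find first index with tail <= p
    idx = np.searchsorted(-dist.tail, -p, side="left")
    if idx >= len(dist.tail):
        warnings.warn(
            f"no achievable score has tail <= {p}", stacklevel=2
        )
        return math.inf
    return (dist.kmin + int(idx)) * dist.eps


@dataclass(frozen=True)
class ScanHit:
    region_id: str
    offset: int       # 0-based forward-coordinate start of the matched window
    strand: str
    score: float      # real (un-discretized) log2-odds
    pvalue: float
    word: str         # forward-strand subsequence of the window


def _region_parts(region) -> tuple[str, str]:
    if isinstance(region, PromoterRegion):
        return region.region_id, region.seq.seq
    if isinstance(region, NucSequence):
        return region.id, region.seq
    return getattr(region, "id", "region"), str(region).upper()


def scan_region(
    pwm: PWM,
    region,
    p_cut: float = 1e-4,
    both_strands: bool = True,
    dist: Optional[ScoreDistribution] = None,
    eps: float = 1e-3,
) -> list[ScanHit]:
    """All PWM matches in a region with exact p-value at or below ``p_cut``.

    Minus-strand hits are reported at the forward-coordinate start of the
    matched window. Windows containing N are skipped. A region shorter than
    the PWM yields an empty list with a warning.
    """
    region_id, s = _region_parts(region)
    w = pwm.width
    if len(s) < w:
        warnings.warn(
            f"region {region_id!r} (length {len(s)}) shorter than PWM width {w}",
            stacklevel=2,
        )
        return []
    if dist is None:
        dist = score_distribution(pwm, eps=eps)
    lo = logodds(pwm)
    codes = _encode(s)
    view = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = ~(view >= 4).any(axis=1)
    m = view.shape[0]
    pos = np.arange(w)[None, :]

    K5 = np.hstack([dist.kmatrix, np.zeros((w, 1), dtype=np.int64)])
    lo5 = np.hstack([lo, np.zeros((w, 1))])

    hits: list[ScanHit] = []

    def _collect(window_view: np.ndarray, strand: str) -> None:
        kscores = K5[pos, window_view].sum(axis=1)
        rscores = lo5[pos, window_view].sum(axis=1)
        for j in np.flatnonzero(valid):
            p = dist.pvalue_int(int(kscores[j]))
            if p <= p_cut:
                hits.append(
                    ScanHit(
                        region_id=region_id,
                        offset=int(j),
                        strand=strand,
                        score=float(rscores[j]),
                        pvalue=p,
                        word=s[j : j + w],
                    )
                )

    _collect(view, "+")
    if both_strands:
        rc = np.where(codes[::-1] == 4, 4, 3 - codes[::-1])
        rcview = np.lib.stride_tricks.sliding_window_view(rc, w)[::-1]
        _collect(rcview, "-")
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_regions(
    pwm: PWM,
    regions: Sequence,
    p_cut: float = 1e-4,
    both_strands: bool = True,
    eps: float = 1e-3,
) -> list[ScanHit]:
    """Scan many regions, sharing one score distribution."""
    dist = score_distribution(pwm, eps=eps)
    hits: list[ScanHit] = []
    for region in regions:
        hits.extend(
            scan_region(pwm, region, p_cut=p_cut, both_strands=both_strands, dist=dist)
        )
    return hits


@dataclass(frozen=True)
class SiteSummary:
    offset: int
    strands: tuple[str, ...]
    paired: bool          # +/- hits at the same forward offset
    best_pvalue: float
    best_score: float
    word: str


@dataclass(frozen=True)
class RegionSummary:
    region_id: str
    n_hits: int
    sites: tuple[SiteSummary, ...]
    best_pvalue: float


def aggregate_hits(hits: Sequence[ScanHit]) -> list[RegionSummary]:
    """Collapse strand-paired hits into sites and rank regions.

    Hits on opposite strands at the same forward offset collapse into one
    site flagged as a palindromic pair. Regions are ordered by their best
    (smallest) p-value.
    """
    by_region: dict[str, dict[int, list[ScanHit]]] = {}
    for h in hits:
        by_region.setdefault(h.region_id, {}).setdefault(h.offset, []).append(h)
    summaries: list[RegionSummary] = []
    for region_id, offsets in by_region.items():
        sites = []
        for off in sorted(offsets):
            group = offsets[off]
            strands = tuple(sorted({h.strand for h in group}))
            best = min(group, key=lambda h: h.pvalue)
            sites.append(
                SiteSummary(
                    offset=off,
                    strands=strands,
                    paired=("+" in strands and "-" in strands),
                    best_pvalue=best.pvalue,
                    best_score=best.score,
                    word=best.word,
                )
            )
        summaries.append(
            RegionSummary(
                region_id=region_id,
                n_hits=sum(len(g) for g in offsets.values()),
                sites=tuple(sites),
                best_pvalue=min(s.best_pvalue for s in sites),
            )
        )
    summaries.sort(key=lambda r: (r.best_pvalue, r.region_id))
    return summaries


def write_hits_tsv(hits: Sequence[ScanHit], path) -> None:
    df = pd.DataFrame(
        {
            "region": [h.region_id for h in hits],
            "offset": [h.offset for h in hits],
            "strand": [h.strand for h in hits],
            "score": [h.score for h in hits],
            "pvalue": [h.pvalue for h in hits],
            "word": [h.word for h in hits],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_hits_bed(hits: Sequence[ScanHit], width: int, path, cap: float = 1000.0) -> None:
    """BED6 output; score column is -10*log10(pvalue), capped."""
    with open(path, "w") as fh:
        for h in hits:
            bed_score = min(cap, -10.0 * math.log10(max(h.pvalue, 1e-300)))
            fh.write(
                f"{h.region_id}\t{h.offset}\t{h.offset + width}\t"
                f"site\t{bed_score:.1f}\t{h.strand}\n"
            )
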