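"""Motif models: PWM construction, ZOOPS EM discovery, degenerate
consensus derivation, significance estimation and MEME-minimal I/O.

The discovery model is zero-or-one-occurrence-per-sequence: each sequence
carries a site with probability ``q`` at a latent position uniform over its
windows (both strands by default). EM maximizes the smoothed (Dirichlet
pseudocount) log posterior, which is non-decreasing per iteration.
"""
from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .seq import IUPACPattern, NucSequence, SET_TO_IUPAC

__all__ = [
    "PWM",
    "SiteSet",
    "MotifModel",
    "build_pwm",
    "discover_motif",
    "consensus_from_pwm",
    "motif_significance",
    "estimate_background",
    "write_meme",
    "read_meme",
    "write_motif_json",
    "plot_logo",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
UNIFORM = np.full(4, 0.25)


def _as_strings(seqs) -> list[str]:
    out = []
    for s in seqs:
        if hasattr(s, "seq"):
            s = s.seq
        if hasattr(s, "seq"):  # PromoterRegion.seq is a NucSequence
            s = s.seq
        out.append(str(s).upper())
    return out


def _encode(s: str) -> np.ndarray:
    """A=0 C=1 G=2 T=3, N=4."""
    return np.frombuffer(
        s.translate(str.maketrans("ACGTN", "\x00\x01\x02\x03\x04")).encode("latin1"),
        dtype=np.uint8,
    ).astype(np.int64)


@dataclass(frozen=True)
class PWM:
    """Position frequency matrix with background and pseudocount."""

    freq: np.ndarray          # (w, 4), rows sum to 1
    background: np.ndarray    # (4,), sums to 1
    alpha: float = 0.25

    def __post_init__(self):
        freq = np.asarray(self.freq, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "freq", freq)
        object.__setattr__(self, "background", bg)
        if freq.ndim != 2 or freq.shape[1] != 4:
            raise ValueError("freq must have shape (w, 4)")
        if not np.allclose(freq.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must each sum to 1")
        if not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")
        if self.alpha < 0:
            raise ValueError("pseudocount must be nonnegative")

    @property
    def width(self) -> int:
        return self.freq.shape[0]

    def revcomp(self) -> "PWM":
        return PWM(self.freq[::-1, ::-1].copy(), self.background.copy(), self.alpha)


@dataclass
class SiteSet:
    """Aligned equal-length sites with provenance."""

    sequences: list[str]
    sources: Optional[list[str]] = None
    offsets: Optional[list[int]] = None

    def __post_init__(self):
        widths = {len(s) for s in self.sequences}
        if len(widths) > 1:
            raise ValueError(f"sites have unequal lengths: {sorted(widths)}")

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class MotifModel:
    pwm: PWM
    occupancy: tuple[int, int]   # (sites found, sequences searched)
    llr: float
    consensus: IUPACPattern
    q: float
    loglik: float
    objective_history: list[float]
    evalue_approx: Optional[float] = None
    settings: dict = field(default_factory=dict)
    site_posteriors: Optional[list[float]] = None
    best_sites: Optional[list[tuple[int, str, float]]] = None  # per-seq (offset, strand, posterior)


def estimate_background(seqs) -> np.ndarray:
    """0-order background frequencies from sequences (N excluded)."""
    counts = np.zeros(4)
    for s in _as_strings(seqs):
        codes = _encode(s)
        counts += np.bincount(codes[codes < 4], minlength=4)
    total = counts.sum()
    if total == 0:
        return UNIFORM.copy()
    return counts / total


def build_pwm(
    sites: Union[SiteSet, Sequence[str]],
    alpha: float = 0.25,
    background: Optional[np.ndarray] = None,
) -> PWM:
    """Frequency matrix from aligned sites with background-weighted smoothing.

    ``f[i,b] = (count[i,b] + alpha*4*pi[b]) / (n + alpha*4)``.
    """
    seqs = sites.sequences if isinstance(sites, SiteSet) else list(sites)
    if not seqs:
        raise ValueError("at least one site is required")
    widths = {len(s) for s in seqs}
    if len(widths) > 1:
        raise ValueError(f"sites have unequal lengths: {sorted(widths)}")
    bg = UNIFORM.copy() if background is None else np.asarray(background, float)
    w = widths.pop()
    counts = np.zeros((w, 4))
    for s in seqs:
        codes = _encode(s.upper())
        if (codes >= 4).any():
            raise ValueError(f"site {s!r} contains non-ACGT characters")
        counts[np.arange(w), codes] += 1
    freq = (counts + alpha * 4.0 * bg) / (len(seqs) + alpha * 4.0)
    if alpha == 0:
        freq = counts / len(seqs)
    return PWM(freq, bg, alpha)


def consensus_from_pwm(pwm: PWM, rule_threshold: float = 0.25) -> IUPACPattern:
    """Degenerate consensus: per column the IUPAC symbol of the base set
    ``{b : f[b] >= rule_threshold}`` when that set captures at least 0.75
    of the column's frequency; N otherwise."""
    symbols = []
    for row in pwm.freq:
        included = frozenset(BASES[b] for b in range(4) if row[b] >= rule_threshold)
        if included and row[[_BASE_INDEX[c] for c in included]].sum() >= 0.75:
            symbols.append(SET_TO_IUPAC[included])
        else:
            symbols.append("N")
    return IUPACPattern("".join(symbols))


# ---------------------------------------------------------------------------
# ZOOPS EM


class _WindowIndex:
    """Pre-extracted scan windows for a sequence set."""

    def __init__(self, seqs: list[str], w: int, both_strands: bool):
        self.w = w
        self.both_strands = both_strands
        windows = []
        seq_idx = []
        strands = []
        offsets = []
        self.n_windows_per_seq = []
        for si, s in enumerate(seqs):
            codes = _encode(s)
            if len(codes) < w:
                raise ValueError(
                    f"sequence #{si} (length {len(codes)}) shorter than width {w}"
                )
            view = np.lib.stride_tricks.sliding_window_view(codes, w)
            m = view.shape[0]
            windows.append(view)
            seq_idx.append(np.full(m, si))
            strands.append(np.zeros(m, dtype=np.int8))
            offsets.append(np.arange(m))
            count = m
            if both_strands:
                rc = np.where(codes[::-1] == 4, 4, 3 - codes[::-1])
                rcview = np.lib.stride_tricks.sliding_window_view(rc, w)
                windows.append(rcview[::-1])  # forward-coordinate order
                seq_idx.append(np.full(m, si))
                strands.append(np.ones(m, dtype=np.int8))
                offsets.append(np.arange(m))
                count += m
            self.n_windows_per_seq.append(count)
        self.X = np.ascontiguousarray(np.concatenate(windows, axis=0))
        self.seq_idx = np.concatenate(seq_idx)
        self.strand = np.concatenate(strands)
        self.offset = np.concatenate(offsets)
        self.valid = ~(self.X >= 4).any(axis=1)
        self.n_seqs = len(seqs)
        # per-seq slices (windows are grouped by sequence)
        bounds = np.cumsum([0] + self.n_windows_per_seq)
        self.slices = [slice(bounds[i], bounds[i + 1]) for i in range(self.n_seqs)]
        self.onehot = [self.X == b for b in range(4)]

    def log_ratios(self, freq: np.ndarray, background: np.ndarray) -> np.ndarray:
        """Natural-log likelihood ratio of each window under f vs background."""
        lo = np.log(freq) - np.log(background)[None, :]
        lo5 = np.hstack([lo, np.full((self.w, 1), -np.inf)])
        scores = lo5[np.arange(self.w)[None, :], self.X].sum(axis=1)
        return scores


def _em_run(
    idx: _WindowIndex,
    freq0: np.ndarray,
    q0: float,
    background: np.ndarray,
    pseudo: np.ndarray,
    palindrome_constraint: bool,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, list[float]]:
    freq = freq0.copy()
    q = q0
    history: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        lr = idx.log_ratios(freq, background)
        post = np.zeros(len(lr))
        present = np.zeros(idx.n_seqs)
        ll = 0.0
        for si, sl in enumerate(idx.slices):
            lr_s = lr[sl]
            m = len(lr_s)
            with np.errstate(divide="ignore"):
                terms = np.log(q) - np.log(m) + lr_s
            log_site = logsumexp(terms)
            log_none = np.log1p(-q) if q < 1 else -np.inf
            denom = np.logaddexp(log_none, log_site)
            post[sl] = np.exp(terms - denom)
            present[si] = math.exp(log_site - denom)
            ll += denom
        obj = ll + float((pseudo[None, :] * np.log(freq)).sum())
        history.append(obj)
        if obj - prev < tol * (1.0 + abs(obj)):
            break
        prev = obj
        # M-step
        counts = np.zeros((idx.w, 4))
        for b in range(4):
            counts[:, b] = post @ idx.onehot[b]
        counts += pseudo[None, :]
        freq = counts / counts.sum(axis=1, keepdims=True)
        if palindrome_constraint:
            freq = 0.5 * (freq + freq[::-1, ::-1])
        q = float(np.clip(present.mean(), 1e-6, 1 - 1e-6))
    return freq, q, history


def _shift_freq(freq: np.ndarray, delta: int, background: np.ndarray) -> np.ndarray:
    """Shift matrix columns by delta, filling vacated columns with background."""
    w = freq.shape[0]
    out = np.tile(background, (w, 1))
    if delta >= 0:
        out[: w - delta] = freq[delta:]
    else:
        out[-delta:] = freq[:delta]
    return out


def _phase_refine(
    idx: _WindowIndex,
    freq: np.ndarray,
    q: float,
    history: list[float],
    background: np.ndarray,
    pseudo: np.ndarray,
    palindrome_constraint: bool,
    max_iter: int,
    tol: float,
    max_shift_rounds: int = 6,
) -> tuple[np.ndarray, float, list[float]]:
    """Phase-shift refinement of a converged EM solution.

    Motif EM is prone to register errors: a run can converge with the true
    site straddling the window edge. Shifted copies of the matrix
    (background-filled) are re-fit briefly; the best is adopted when it
    improves the objective, and the process repeats until stable.
    """
    w = freq.shape[0]
    deltas = [d for k in range(1, max(2, w // 4) + 1) for d in (k, -k)]
    for _ in range(max_shift_rounds):
        best_cand = None
        for delta in deltas:
            f_try = _shift_freq(freq, delta, background)
            cand = _em_run(
                idx, f_try, q, background, pseudo, palindrome_constraint,
                min(25, max_iter), tol,
            )
            if cand[2][-1] > history[-1] + 1e-9 and (
                best_cand is None or cand[2][-1] > best_cand[2][-1]
            ):
                best_cand = cand
        if best_cand is None:
            break
        # continue the winning shifted solution to convergence
        freq, q, history = _em_run(
            idx, best_cand[0], best_cand[1], background, pseudo,
            palindrome_constraint, max_iter, tol,
        )
    return freq, q, history


def discover_motif(
    seqs,
    w: int = 22,
    restarts: int = 20,
    seed: int = 0,
    both_strands: bool = True,
    palindrome_constraint: bool = False,
    alpha: float = 0.25,
    background: Optional[np.ndarray] = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    q_init: float = 0.5,
    phase_refine: bool = True,
) -> MotifModel:
    """ZOOPS EM motif discovery, best of ``restarts`` seeded restarts.

    Occupancy counts sequences whose posterior probability of carrying a
    site is at least 0.5. Results are deterministic under ``seed`` and
    invariant to the order of the input sequences.
    """
    raw = _as_strings(seqs)
    if not raw:
        raise ValueError("no sequences provided")
    for i, s in enumerate(raw):
        if len(s) < w:
            raise ValueError(f"sequence #{i} (length {len(s)}) is shorter than w={w}")
    # canonical internal order makes the fit order-invariant under a seed
    order = sorted(range(len(raw)), key=lambda i: raw[i])
    canon = [raw[i] for i in order]

    bg = estimate_background(canon) if background is None else np.asarray(background, float)
    bg = np.clip(bg, 1e-9, None)
    bg = bg / bg.sum()
    pseudo = alpha * 4.0 * bg

    idx = _WindowIndex(canon, w, both_strands)
    valid_windows = np.flatnonzero(idx.valid)
    if len(valid_windows) == 0:
        raise ValueError("no windows free of N; cannot seed EM")

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(restarts, 1)):
        j = int(rng.choice(valid_windows))
        f0 = np.full((w, 4), 0.0) + 0.3 * bg[None, :]
        f0[np.arange(w), idx.X[j]] += 0.7
        f0 = f0 / f0.sum(axis=1, keepdims=True)
        freq, q, history = _em_run(
            idx, f0, q_init, bg, pseudo, palindrome_constraint, max_iter, tol
        )
        if best is None or history[-1] > best[2][-1]:
            best = (freq, q, history)
    if phase_refine:
        best = _phase_refine(
            idx, *best, bg, pseudo, palindrome_constraint, max_iter, tol
        )
    freq, q, history = best

    pwm = PWM(freq, bg, alpha)
    # final E-step for reporting
    lr = idx.log_ratios(freq, bg)
    present = np.zeros(idx.n_seqs)
    llr = 0.0
    best_sites_canon: list[tuple[int, str, float]] = []
    for si, sl in enumerate(idx.slices):
        lr_s = lr[sl]
        m = len(lr_s)
        terms = np.log(q) - np.log(m) + lr_s
        log_site = logsumexp(terms)
        denom = np.logaddexp(np.log1p(-q), log_site)
        post = np.exp(terms - denom)
        present[si] = math.exp(log_site - denom)
        llr += float((post * np.where(np.isfinite(lr_s), lr_s, 0.0)).sum())
        k = int(np.argmax(post))
        strand = "-" if idx.strand[sl][k] == 1 else "+"
        best_sites_canon.append((int(idx.offset[sl][k]), strand, float(post[k])))

    # map per-sequence outputs back to input order
    inv = np.empty(len(order), dtype=int)
    inv[order] = np.arange(len(order))
    site_posteriors = [float(present[inv[i]]) for i in range(len(raw))]
    best_sites = [best_sites_canon[inv[i]] for i in range(len(raw))]

    n_found = int((present >= 0.5).sum())
    return MotifModel(
        pwm=pwm,
        occupancy=(n_found, idx.n_seqs),
        llr=llr,
        consensus=consensus_from_pwm(pwm),
        q=q,
        loglik=history[-1],
        objective_history=history,
        settings=dict(
            w=w,
            restarts=restarts,
            seed=seed,
            both_strands=both_strands,
            palindrome_constraint=palindrome_constraint,
            alpha=alpha,
            max_iter=max_iter,
            phase_refine=phase_refine,
        ),
        site_posteriors=site_posteriors,
        best_sites=best_sites,
    )


def motif_significance(
    model: MotifModel,
    seqs,
    n_shuffles: int = 200,
    seed: int = 0,
    null_restarts: Optional[int] = None,
    null_max_iter: int = 30,
) -> tuple[float, float]:
    """Approximate significance of a discovered motif.

    The observed statistic is the model's posterior-weighted log-likelihood
    ratio. The null distribution is obtained by refitting the same model on
    background-generated sequence sets of identical shape (Monte-Carlo,
    seeded); a normal upper tail is multiplied by the number of candidate
    (sequence, offset, strand) start configurations to give an e-value-like
    quantity. Returns ``(llr, evalue_approx)``.
    """
    raw = _as_strings(seqs)
    settings = model.settings
    w = settings.get("w", model.pwm.width)
    both = settings.get("both_strands", True)
    restarts = null_restarts if null_restarts is not None else min(
        settings.get("restarts", 3), 3
    )
    bg = model.pwm.background
    lengths = [len(s) for s in raw]
    n_configs = sum((L - w + 1) * (2 if both else 1) for L in lengths)

    rng = np.random.default_rng(seed)
    null_llr = np.empty(n_shuffles)
    for k in range(n_shuffles):
        fake = [
            "".join(np.array(list(BASES))[rng.choice(4, size=L, p=bg)])
            for L in lengths
        ]
        m = discover_motif(
            fake,
            w=w,
            restarts=restarts,
            seed=int(rng.integers(2**31)),
            both_strands=both,
            palindrome_constraint=settings.get("palindrome_constraint", False),
            alpha=settings.get("alpha", 0.25),
            background=bg,
            max_iter=null_max_iter,
            phase_refine=settings.get("phase_refine", False),
        )
        null_llr[k] = m.llr
    mu, sd = float(null_llr.mean()), float(null_llr.std(ddof=1))
    sd = max(sd, 1e-9)
    p_tail = float(norm.sf(model.llr, loc=mu, scale=sd))
    evalue = n_configs * p_tail
    model.evalue_approx = evalue
    return model.llr, evalue


# ---------------------------------------------------------------------------
# I/O


def write_meme(pwm: PWM, path, name: str = "motif_1", nsites: Optional[int] = None,
               evalue: Optional[float] = None) -> None:
    """Write a PWM in MEME minimal text format."""
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        " ".join(f"{b} {p:.6f}" for b, p in zip(BASES, pwm.background)),
        "",
        f"MOTIF {name}",
        "letter-probability matrix: alength= 4 w= {w} nsites= {n} E= {e}".format(
            w=pwm.width, n=nsites if nsites is not None else 20,
            e=f"{evalue:.3g}" if evalue is not None else "0",
        ),
    ]
    for row in pwm.freq:
        lines.append(" " + " ".join(f"{x:.6f}" for x in row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_meme(path) -> PWM:
    """Read the first motif from a MEME minimal format file."""
    text = open(path).read()
    bg = UNIFORM.copy()
    m = re.search(
        r"Background letter frequencies.*?\n([ACGT0-9.\seE+-]+)\n", text
    )
    if m:
        toks = m.group(1).split()
        vals = {toks[i]: float(toks[i + 1]) for i in range(0, len(toks) - 1, 2)
                if toks[i] in set(BASES)}
        if len(vals) == 4:
            bg = np.array([vals[b] for b in BASES])
    m = re.search(
        r"letter-probability matrix:[^\n]*w=\s*(\d+)[^\n]*\n((?:\s*[\d.eE+-]+[ \t]*)+)",
        text,
    )
    if not m:
        raise ValueError(f"no letter-probability matrix found in {path}")
    w = int(m.group(1))
    nums = [float(x) for x in m.group(2).split()]
    freq = np.array(nums[: 4 * w]).reshape(w, 4)
    freq = freq / freq.sum(axis=1, keepdims=True)
    return PWM(freq, bg / bg.sum())


def write_motif_json(model: MotifModel, path) -> None:
    payload = {
        "width": model.pwm.width,
        "consensus": model.consensus.symbols,
        "occupancy": {"sites": model.occupancy[0], "sequences": model.occupancy[1]},
        "q": model.q,
        "llr": model.llr,
        "evalue_approx": model.evalue_approx,
        "loglik": model.loglik,
        "background": list(map(float, model.pwm.background)),
        "freq": [list(map(float, row)) for row in model.pwm.freq],
        "settings": model.settings,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def plot_logo(pwm: PWM, path) -> None:
    """Information-content sequence logo (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}
    w = pwm.width
    fig, ax = plt.subplots(figsize=(max(4, w * 0.45), 2.4))
    for i, row in enumerate(pwm.freq):
        ic = 2.0 + float((row * np.log2(np.clip(row, 1e-12, None))).sum())
        y = 0.0
        for b in np.argsort(row):
            h = float(row[b]) * ic
            if h < 1e-3:
                continue
            ax.text(
                i + 0.5, y + h / 2, BASES[b],
                ha="center", va="center",
                fontsize=14, fontweight="bold",
                color=colors[BASES[b]],
                stretch="expanded",
            )
            y += h
    ax.set_xlim(0, w)
    ax.set_ylim(0, 2)
    ax.set_ylabel("bits")
    ax.set_xticks(np.arange(w) + 0.5, labels=[str(i + 1) for i in range(w)], fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
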