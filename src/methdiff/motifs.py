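"""Motif scanning and enrichment for hyper- vs hypomethylated intron DMRs.

Motifs are IUPAC degenerate consensus strings (e.g. the 16-bp PAX5 site
GCAGCCAAGCGTGACC) or position weight matrices.  Consensus scanning reports
every offset, on either strand, where all positions match their IUPAC
class; an N in the *sequence* matches nothing (conservative).  PWM scanning
scores log-odds in bits against a background base composition and keeps
offsets whose exact per-position p-value (computed by dynamic programming
over discretized column scores) is at or below a threshold.

Set-level enrichment dichotomizes each sequence as with/without >= 1 hit
and compares the target rate against a background set with a one-sided
hypergeometric tail (a cumulative binomial is available as an option).  The
background can be sampled from a pool matched to the targets' CpG count or
GC fraction distribution, because methylation changes concentrate in
CpG-rich sequence and an unmatched background would confound the test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MotifModel",
    "MotifHit",
    "enrichment_test",
    "heatmap_profile",
    "matched_background",
    "parse_motif",
    "pwm_exact_pvalue",
    "pwm_from_counts",
    "read_motif_library",
    "score_matrix_pvalue",
    "reverse_complement",
    "scan",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class MotifModel:
    """A named motif: IUPAC consensus and/or PWM with scanning threshold."""

    name: str
    consensus: str | None = None
    pwm: np.ndarray | None = None  # shape (w, 4), rows sum to 1
    background: np.ndarray | None = None  # length 4
    p_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.consensus is None and self.pwm is None:
            raise ValueError("motif needs a consensus or a PWM")
        if self.pwm is not None:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
                raise ValueError("pwm must have shape (width, 4)")
            if not np.allclose(self.pwm.sum(axis=1), 1.0):
                raise ValueError("pwm rows must sum to 1")
        if self.background is None:
            self.background = np.full(4, 0.25)
        else:
            self.background = np.asarray(self.background, dtype=float)

    @property
    def width(self) -> int:
        if self.consensus is not None:
            return len(self.consensus)
        return self.pwm.shape[0]

    def degeneracy(self) -> list[int]:
        """Number of allowed bases per consensus position (N=4, V=3, ...)."""
        if self.consensus is None:
            raise ValueError("degeneracy is defined for consensus motifs")
        return [len(IUPAC[c]) for c in self.consensus]

    def to_pwm(self, pseudo: float = 0.0) -> np.ndarray:
        """Uniform-weight PWM over the allowed bases of each position."""
        if self.pwm is not None:
            return self.pwm
        w = len(self.consensus)
        pwm = np.full((w, 4), pseudo)
        for i, c in enumerate(self.consensus):
            for b in IUPAC[c]:
                pwm[i, _BASE_INDEX[b]] += 1.0
        return pwm / pwm.sum(axis=1, keepdims=True)

    def log_odds(self, pseudo: float = 0.0) -> np.ndarray:
        """Log-odds score matrix in bits: log2(p_ij / background_j)."""
        pwm = self.to_pwm() if self.pwm is None else self.pwm
        if pseudo:
            pwm = (pwm + pseudo) / (1 + 4 * pseudo)
        with np.errstate(divide="ignore"):
            lo = np.log2(pwm / self.background)
        if not np.isfinite(lo).all() and pseudo == 0:
            raise ValueError(
                "PWM has zero-probability cells; pass a pseudocount to log_odds"
            )
        return lo


def parse_motif(consensus: str, name: str | None = None, p_threshold: float = 0.01) -> MotifModel:
    """Build a MotifModel from an IUPAC consensus string.

    Raises ValueError naming the 1-based position of any illegal character.
    """
    if not consensus:
        raise ValueError("empty consensus")
    consensus = consensus.upper()
    for i, c in enumerate(consensus):
        if c not in IUPAC:
            raise ValueError(f"illegal IUPAC character {c!r} at position {i + 1}")
    return MotifModel(name=name or consensus, consensus=consensus, p_threshold=p_threshold)


def pwm_from_counts(counts: np.ndarray, name: str = "pwm", pseudo: float = 0.5, **kw) -> MotifModel:
    """MotifModel from a JASPAR-style 4 x w count matrix (rows A,C,G,T)."""
    counts = np.asarray(counts, dtype=float).T + pseudo  # -> (w, 4)
    return MotifModel(name=name, pwm=counts / counts.sum(axis=1, keepdims=True), **kw)


def read_motif_library(path: str | Path) -> list[MotifModel]:
    """Read a motif library: lines of ``name<TAB>IUPAC_consensus``.

    Blank lines and ``#`` comments are skipped.
    """
    motifs = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, consensus = line.split("\t")[:2]
        motifs.append(parse_motif(consensus, name=name))
    return motifs


@dataclass
class MotifHit:
    sequence_id: str
    offset: int  # 0-based, forward-strand coordinates
    strand: str  # '+' or '-'
    score: float  # log-odds bits (PWM mode) or 1.0 (consensus match)
    p: float


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _consensus_hits_one_strand(enc: np.ndarray, consensus: str) -> np.ndarray:
    L, w = len(enc), len(consensus)
    if L < w:
        return np.array([], dtype=int)
    ok = np.ones(L - w + 1, dtype=bool)
    for j, c in enumerate(consensus):
        allowed = np.zeros(5, dtype=bool)  # index 4 unused; -1 wraps to 4? handle below
        for b in IUPAC[c]:
            allowed[_BASE_INDEX[b]] = True
        window = enc[j : L - w + 1 + j]
        ok &= (window >= 0) & allowed[np.clip(window, 0, 3)]
    return np.flatnonzero(ok)


def scan(
    seq: str,
    m: MotifModel,
    both_strands: bool = True,
    sequence_id: str = "seq",
) -> list[MotifHit]:
    """Scan a sequence for motif occurrences.

    Consensus mode matches IUPAC classes exactly (sequence N never
    matches).  PWM mode reports offsets whose log-odds score has exact
    p <= ``m.p_threshold``.  Reverse-strand hits are reported with
    forward-strand offsets.  A sequence shorter than the motif yields an
    empty list.
    """
    w = m.width
    L = len(seq)
    hits: list[MotifHit] = []
    if L < w:
        return hits
    if m.consensus is not None and m.pwm is None:
        per_pos_p = float(np.prod([len(IUPAC[c]) / 4 for c in m.consensus]))
        enc = _encode(seq)
        for off in _consensus_hits_one_strand(enc, m.consensus):
            hits.append(MotifHit(sequence_id, int(off), "+", 1.0, per_pos_p))
        if both_strands:
            enc_rc = _encode(reverse_complement(seq))
            for off in _consensus_hits_one_strand(enc_rc, m.consensus):
                hits.append(MotifHit(sequence_id, int(L - w - off), "-", 1.0, per_pos_p))
    else:
        lo = m.log_odds()
        granularity = 1e-3
        dist, offset = _score_distribution(_discretize(lo, granularity), m.background)
        tail = np.cumsum(dist[::-1])[::-1]
        threshold = _threshold_from_tail(tail, offset, m.p_threshold, granularity)
        enc = _encode(seq)
        for strand in ("+", "-") if both_strands else ("+",):
            e = enc if strand == "+" else _encode(reverse_complement(seq))
            valid = e >= 0
            scores = np.zeros(L - w + 1)
            ok = np.ones(L - w + 1, dtype=bool)
            for j in range(w):
                window = e[j : L - w + 1 + j]
                ok &= valid[j : L - w + 1 + j]
                scores += np.where(ok, lo[j, np.clip(window, 0, 3)], -np.inf)
            for off in np.flatnonzero(ok & (scores >= threshold)):
                fwd_off = int(off) if strand == "+" else int(L - w - off)
                idx = int(np.round(scores[off] / granularity)) - offset
                p = float(tail[min(max(idx, 0), len(tail) - 1)]) if idx < len(tail) else 0.0
                hits.append(MotifHit(sequence_id, fwd_off, strand, float(scores[off]), p))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def _discretize(lo: np.ndarray, granularity: float) -> np.ndarray:
    return np.round(lo / granularity).astype(np.int64)


def _score_distribution(int_scores: np.ndarray, background: np.ndarray) -> tuple[np.ndarray, int]:
    """Exact distribution of the summed integer score under iid background.

    Returns (probabilities, offset) where probabilities[i] is the mass of
    integer score i + offset.
    """
    w = int_scores.shape[0]
    lo_total = int(int_scores.min(axis=1).sum())
    hi_total = int(int_scores.max(axis=1).sum())
    dist = np.zeros(hi_total - lo_total + 1)
    dist[0] = 1.0
    cur_lo = 0
    for j in range(w):
        nxt = np.zeros_like(dist)
        col = int_scores[j]
        col_lo = int(col.min())
        for b in range(4):
            shift = int(col[b]) - col_lo
            nxt[shift:] += background[b] * dist[: len(dist) - shift] if shift else background[b] * dist
        dist = nxt
        cur_lo += col_lo
    return dist, lo_total


def score_matrix_pvalue(
    score_matrix: np.ndarray,
    threshold: float,
    background: np.ndarray | None = None,
    granularity: float = 1e-3,
) -> float:
    """P(sum of per-position scores >= ``threshold``) for one word drawn
    i.i.d. from ``background``, for an arbitrary (width, 4) score matrix.

    Computed by exact dynamic programming over scores discretized to
    ``granularity``; the score-grid error is at most width*granularity/2.
    """
    score_matrix = np.asarray(score_matrix, dtype=float)
    if not np.isfinite(score_matrix).all():
        raise ValueError(
            "score matrix has non-finite entries (zero-probability PWM cell?); "
            "add a pseudocount before computing exact p-values"
        )
    background = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    dist, offset = _score_distribution(_discretize(score_matrix, granularity), background)
    idx = int(np.round(threshold / granularity)) - offset
    if idx <= 0:
        return 1.0
    if idx >= len(dist):
        return 0.0
    return float(dist[idx:].sum())


def pwm_exact_pvalue(m: MotifModel, score: float, granularity: float = 1e-3) -> float:
    """P(log-odds score >= ``score``) for one background-drawn word.

    Uses the exact DP of :func:`score_matrix_pvalue` on the motif's
    log-odds matrix.  A PWM with zero-probability cells raises; rebuild it
    with a pseudocount (see :func:`pwm_from_counts`).
    """
    try:
        lo = m.log_odds()
    except ValueError as err:
        raise ValueError(str(err)) from None
    return score_matrix_pvalue(lo, score, m.background, granularity)


def _threshold_from_tail(tail: np.ndarray, offset: int, p: float, granularity: float) -> float:
    """Smallest score on the discretized grid with tail probability <= p."""
    ok = np.flatnonzero(tail <= p)
    if len(ok) == 0:
        return np.inf
    return (ok[0] + offset) * granularity


def cpg_count(seq: str) -> int:
    return seq.upper().count("CG")


def gc_fraction(seq: str) -> float:
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s) if s else 0.0


def matched_background(
    targets: Mapping[str, str],
    pool: Mapping[str, str],
    feature: str = "cpg_count",
    n_strata: int = 10,
    size: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> dict[str, str]:
    """Sample a background set from ``pool`` matching the targets'
    distribution of a sequence feature (CpG count or GC fraction).

    Strata are decile (by default) bins of the pooled feature values;
    background draws are allocated to strata proportionally to the target
    histogram, without replacement where the pool stratum is large enough
    and with replacement (with a warning) otherwise.  Deterministic given
    the rng seed.
    """
    if feature == "cpg_count":
        fn = cpg_count
    elif feature == "gc_fraction":
        fn = gc_fraction
    else:
        raise ValueError("feature must be cpg_count or gc_fraction")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    shared = set(targets) & set(pool)
    if shared:
        raise ValueError(f"pool must be disjoint from targets; shared ids: {sorted(shared)[:5]}")
    t_ids = sorted(targets)
    p_ids = sorted(pool)
    t_feat = np.array([fn(targets[i]) for i in t_ids], dtype=float)
    p_feat = np.array([fn(pool[i]) for i in p_ids], dtype=float)
    size = len(t_ids) if size is None else size
    edges = np.quantile(np.concatenate([t_feat, p_feat]), np.linspace(0, 1, n_strata + 1))
    edges = np.unique(edges)
    t_strat = np.clip(np.searchsorted(edges, t_feat, side="right") - 1, 0, len(edges) - 2)
    p_strat = np.clip(np.searchsorted(edges, p_feat, side="right") - 1, 0, len(edges) - 2)
    out: dict[str, str] = {}
    counts = np.bincount(t_strat, minlength=len(edges) - 1)
    alloc = np.floor(counts / counts.sum() * size).astype(int)
    # distribute the remainder to the largest strata
    for s in np.argsort(-counts)[: size - alloc.sum()]:
        alloc[s] += 1
    for s, k in enumerate(alloc):
        if k == 0:
            continue
        members = [p_ids[i] for i in np.flatnonzero(p_strat == s)]
        if not members:
            warnings.warn(f"empty pool stratum {s}; sampling from the whole pool instead")
            members = p_ids
        replace = len(members) < k
        if replace:
            warnings.warn(f"pool stratum {s} short ({len(members)} < {k}); sampling with replacement")
        chosen = rng.choice(members, size=k, replace=replace)
        for i, cid in enumerate(chosen):
            key = cid if cid not in out else f"{cid}__dup{i}"
            out[key] = pool[cid]
    return out


@dataclass
class EnrichmentResult:
    motif: str
    target_with_hit: int
    target_total: int
    background_with_hit: int
    background_total: int
    p: float
    direction_set: str = ""

    @property
    def target_rate(self) -> float:
        return self.target_with_hit / self.target_total

    @property
    def background_rate(self) -> float:
        return self.background_with_hit / self.background_total


def _has_hit(seq: str, m: MotifModel) -> bool:
    return len(scan(seq, m)) > 0


def enrichment_test(
    m: MotifModel,
    targets: Mapping[str, str] | Sequence[str],
    background: Mapping[str, str] | Sequence[str],
    method: str = "hypergeom",
    direction_set: str = "",
) -> EnrichmentResult:
    """One-sided over-representation test of motif-bearing sequences.

    A sequence "has" the motif if scanning finds >= 1 hit on either
    strand.  ``hypergeom`` (default) conditions on the pooled 2x2 table:
    p = P(X >= k) for X hypergeometric with the pooled hit count drawn
    into the target set.  ``binom`` is the cumulative binomial with the
    background rate as the success probability.
    """
    t_seqs = list(targets.values()) if isinstance(targets, Mapping) else list(targets)
    b_seqs = list(background.values()) if isinstance(background, Mapping) else list(background)
    if not t_seqs or not b_seqs:
        raise ValueError("both sequence sets must be non-empty")
    k = sum(_has_hit(s, m) for s in t_seqs)
    kb = sum(_has_hit(s, m) for s in b_seqs)
    nt, nb = len(t_seqs), len(b_seqs)
    if method == "hypergeom":
        p = float(stats.hypergeom.sf(k - 1, nt + nb, k + kb, nt))
    elif method == "binom":
        rate = max(kb / nb, 1.0 / (2 * nb))  # guard a zero background rate
        p = float(stats.binom.sf(k - 1, nt, rate))
    else:
        raise ValueError("method must be hypergeom or binom")
    return EnrichmentResult(
        motif=m.name,
        target_with_hit=int(k),
        target_total=nt,
        background_with_hit=int(kb),
        background_total=nb,
        p=min(max(p, np.nextafter(0, 1)), 1.0),
        direction_set=direction_set,
    )


def enrichment_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results with BH-adjusted q-values."""
    from statsmodels.stats.multitest import multipletests

    rows = [
        {
            "motif": r.motif,
            "direction_set": r.direction_set,
            "target_with_hit": r.target_with_hit,
            "target_total": r.target_total,
            "background_with_hit": r.background_with_hit,
            "background_total": r.background_total,
            "target_rate": r.target_rate,
            "background_rate": r.background_rate,
            "p": r.p,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def heatmap_profile(
    centers: Sequence[tuple[str, int]],
    m,
    flank: int = 5000,
) -> np.ndarray:
    """Mean tumor-normal signal around motif occurrences.

    ``centers`` are (chrom, position) motif centers; ``m`` is a normalized
    BinMatrix.  Each row is one occurrence; columns are the bins spanning
    +/- ``flank`` around the center (2*flank/window + 1 columns).  Bins
    absent from the matrix give NaN.  Rows are sorted by the central
    column, descending.
    """
    window = int((m.bins["end"] - m.bins["start"]).mode()[0])
    n_side = flank // window
    t_idx, n_idx, _ = m.paired_columns()
    diff = m.counts[:, t_idx].mean(axis=1) - m.counts[:, n_idx].mean(axis=1)
    index = {(c, int(s)): i for i, (c, s) in enumerate(zip(m.bins["chrom"], m.bins["start"]))}
    prof = np.full((len(centers), 2 * n_side + 1), np.nan)
    for r, (chrom, pos) in enumerate(centers):
        center_start = (int(pos) // window) * window
        for j in range(-n_side, n_side + 1):
            key = (chrom, center_start + j * window)
            if key in index:
                prof[r, j + n_side] = diff[index[key]]
    order = np.argsort(-np.nan_to_num(prof[:, n_side], nan=-np.inf))
    return prof[order]
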