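"""Position weight matrices, log-odds scanning, and exact score p-values.

The "motif quality score" of a W-mer is the log2-odds of the W-mer under
the position-specific frequency model versus a 0-order background, in
bits.  Score p-values are exact tail probabilities of the discretized
score distribution under the background, computed by dynamic programming
over a fixed score grid (default step 1/1000 bit), FIMO-style.  A
higher-order Markov background may be attached for discovery context but
p-values always use the 0-order background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import ChromSizes, GenomicInterval, RegionSet

__all__ = [
    "PWM",
    "MotifHit",
    "score_site",
    "score_pvalue",
    "score_threshold",
    "scan_genome",
    "annotate_hits",
    "occupancy_curve",
    "read_meme",
    "read_pwm_tsv",
    "write_pwm_tsv",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}

DEFAULT_PRECISION = 1e-3  # score-grid step, bits


class PWM:
    """Position-specific frequency matrix with a 0-order background.

    ``freq`` is W x 4 over (A, C, G, T); every row sums to 1 and all
    entries are > 0 after the construction pseudocount.
    """

    def __init__(
        self,
        motif_id: str,
        freq: np.ndarray,
        background: Optional[Sequence[float]] = None,
        pseudocount: float = 0.0,
        markov_background: Optional[object] = None,
    ):
        freq = np.asarray(freq, dtype=np.float64)
        if freq.ndim != 2 or freq.shape[1] != 4:
            raise ValueError("freq must be W x 4")
        if pseudocount > 0:
            freq = freq + pseudocount
            freq = freq / freq.sum(axis=1, keepdims=True)
        if not np.allclose(freq.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each freq row must sum to 1")
        if (freq <= 0).any():
            raise ValueError("all probabilities must be > 0 (use a pseudocount)")
        bg = (
            np.full(4, 0.25)
            if background is None
            else np.asarray(background, dtype=np.float64)
        )
        if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must be 4 probabilities summing to 1")
        if (bg <= 0).any():
            raise ValueError("background probabilities must be > 0")
        self.motif_id = motif_id
        self.freq = freq
        self.background = bg
        self.pseudocount = pseudocount
        self.markov_background = markov_background

    @property
    def width(self) -> int:
        return self.freq.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """W x 4 log2(freq / background), bits."""
        return np.log2(self.freq / self.background[None, :])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freq.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.motif_id + "_rc",
            self.freq[::-1, ::-1].copy(),
            background=self.background[[3, 2, 1, 0]],
        )


@dataclass
class MotifHit:
    interval: GenomicInterval
    score: float  # bits
    p_value: float
    in_open_chromatin: Optional[bool] = None
    bound: Optional[bool] = None


def encode(sequence: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3; anything else as -1."""
    table = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def score_site(pwm: PWM, sequence: str) -> float:
    """Log2-odds score of a single W-mer, in bits.

    Raises on ambiguous bases; scanners skip such windows instead.
    """
    if len(sequence) != pwm.width:
        raise ValueError(f"sequence length {len(sequence)} != width {pwm.width}")
    codes = encode(sequence)
    if (codes < 0).any():
        raise ValueError(f"ambiguous base in {sequence!r}")
    lo = pwm.log_odds
    return float(lo[np.arange(pwm.width), codes].sum())


def _score_distribution(
    pwm: PWM, precision: float
) -> Tuple[int, np.ndarray, np.ndarray]:
    """Distribution of the grid-rounded score under the 0-order background.

    Returns (min_index, probabilities, per-position integer scores); the
    score at ``min_index + k`` grid units is ``(min_index + k) * precision``.
    """
    if precision <= 0:
        raise ValueError("precision must be > 0")
    ints = np.round(pwm.log_odds / precision).astype(np.int64)  # W x 4
    lo_sum = int(ints.min(axis=1).sum())
    hi_sum = int(ints.max(axis=1).sum())
    dist = np.zeros(hi_sum - lo_sum + 1)
    # running support [cur_lo, cur_lo + len(cur) - 1]
    cur = np.array([1.0])
    cur_lo = 0
    for i in range(pwm.width):
        width = len(cur) + int(ints[i].max() - ints[i].min())
        nxt = np.zeros(width)
        base = int(ints[i].min())
        for b in range(4):
            off = int(ints[i, b]) - base
            nxt[off : off + len(cur)] += pwm.background[b] * cur
        cur = nxt
        cur_lo += base
    dist[cur_lo - lo_sum : cur_lo - lo_sum + len(cur)] = cur
    return lo_sum, dist, ints


def _tail(pwm: PWM, precision: float) -> Tuple[int, np.ndarray]:
    lo_sum, dist, _ = _score_distribution(pwm, precision)
    return lo_sum, np.cumsum(dist[::-1])[::-1]


def score_pvalue(
    pwm: PWM, score: float, precision: float = DEFAULT_PRECISION
) -> float:
    """Exact P(grid score >= ``score``) under the 0-order background."""
    lo_sum, tail = _tail(pwm, precision)
    k = int(np.floor(score / precision + 0.5)) - lo_sum
    if k <= 0:
        return 1.0
    if k >= len(tail):
        # per-position rounding can leave the grid maximum half a step
        # below the rounded float maximum; attainable scores clamp to it
        if score <= pwm.max_score + precision:
            k = len(tail) - 1
        else:
            return 0.0
    return float(min(tail[k], 1.0))


def score_threshold(
    pwm: PWM, p_threshold: float, precision: float = DEFAULT_PRECISION
) -> float:
    """Smallest grid score whose tail probability is <= ``p_threshold``."""
    if not (0.0 < p_threshold <= 1.0):
        raise ValueError("p_threshold must be in (0, 1]")
    lo_sum, tail = _tail(pwm, precision)
    ks = np.nonzero(tail <= p_threshold)[0]
    if len(ks) == 0:
        return float("inf")  # unattainable
    return float((int(ks[0]) + lo_sum) * precision)


def _window_scores(lo: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Score every window of length W; windows containing an ambiguous
    base get -inf."""
    w = lo.shape[0]
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0)
    clipped = np.clip(codes, 0, 3)
    scores = np.zeros(n)
    for i in range(w):
        scores += lo[i, clipped[i : i + n]]
    bad = codes < 0
    if bad.any():
        bad_windows = np.convolve(bad.astype(np.int64), np.ones(w, dtype=np.int64))[
            w - 1 : w - 1 + n
        ]
        scores[bad_windows > 0] = -np.inf
    return scores


def scan_genome(
    pwm: PWM,
    sequences: Mapping[str, str],
    p_threshold: float = 1e-4,
    genome: Optional[ChromSizes] = None,
    precision: float = DEFAULT_PRECISION,
) -> List[MotifHit]:
    """Scan both strands of every sequence for motif matches.

    A position is reported when its exact score p-value is <=
    ``p_threshold``.  Overlapping hits are all kept; hits on opposite
    strands at the same position are distinct.  Coordinates are 0-based
    half-open over the forward strand.
    """
    if genome is not None:
        for chrom in sequences:
            if chrom not in genome:
                raise ValueError(f"chromosome {chrom!r} absent from genome")
    cutoff = score_threshold(pwm, p_threshold, precision)
    lo_sum, tail = _tail(pwm, precision)
    lo_fwd = pwm.log_odds
    lo_rev = lo_fwd[::-1, ::-1]  # scores the reverse-complement in place
    hits: List[MotifHit] = []
    w = pwm.width
    for chrom in sequences:
        codes = encode(sequences[chrom])
        for strand, lo in (("+", lo_fwd), ("-", lo_rev)):
            scores = _window_scores(lo, codes)
            for pos in np.nonzero(scores >= cutoff)[0]:
                s = float(scores[pos])
                k = int(np.floor(s / precision + 0.5)) - lo_sum
                p = 1.0 if k <= 0 else float(min(tail[min(k, len(tail) - 1)], 1.0))
                hits.append(
                    MotifHit(
                        interval=GenomicInterval(
                            chrom, int(pos), int(pos) + w, strand=strand
                        ),
                        score=s,
                        p_value=p,
                    )
                )
    hits.sort(
        key=lambda h: (h.interval.chrom, h.interval.start, h.interval.strand)
    )
    return hits


def annotate_hits(
    hits: Sequence[MotifHit], peaks: RegionSet, open_regions: RegionSet
) -> List[MotifHit]:
    """Set ``bound`` (>= 1 bp overlap with a peak) and
    ``in_open_chromatin`` (>= 1 bp overlap with an open region) flags."""
    for h in hits:
        h.bound = peaks.any_overlap(h.interval)
        h.in_open_chromatin = open_regions.any_overlap(h.interval)
    return list(hits)


def occupancy_curve(
    hits: Sequence[MotifHit], bin_width: float = 1.0
) -> pd.DataFrame:
    """Fraction of hits bound by the factor, per score bin, stratified by
    open-chromatin membership.

    Hits must already be annotated (see :func:`annotate_hits`).  Bins
    with zero hits in a stratum report NaN, not 0.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    for h in hits:
        if h.bound is None or h.in_open_chromatin is None:
            raise ValueError("hits must be annotated before binning")
    if not hits:
        return pd.DataFrame(
            columns=[
                "bin_left",
                "n_in_open",
                "frac_bound_in_open",
                "n_outside",
                "frac_bound_outside",
            ]
        )
    scores = np.array([h.score for h in hits])
    in_open = np.array([h.in_open_chromatin for h in hits], dtype=bool)
    bound = np.array([h.bound for h in hits], dtype=bool)
    bins = np.floor(scores / bin_width).astype(np.int64)
    rows = []
    for b in range(int(bins.min()), int(bins.max()) + 1):
        sel = bins == b
        n_in = int((sel & in_open).sum())
        n_out = int((sel & ~in_open).sum())
        rows.append(
            {
                "bin_left": b * bin_width,
                "n_in_open": n_in,
                "frac_bound_in_open": (
                    float(bound[sel & in_open].mean()) if n_in else float("nan")
                ),
                "n_outside": n_out,
                "frac_bound_outside": (
                    float(bound[sel & ~in_open].mean()) if n_out else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)


def read_meme(path: str) -> List[PWM]:
    """Parse MEME minimal motif format (letter-probability matrices)."""
    pwms: List[PWM] = []
    background = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.lower().startswith("background letter frequencies"):
            i += 1
            toks = lines[i].split()
            freqs = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks), 2)}
            background = [freqs.get(b, 0.25) for b in BASES]
        elif line.startswith("MOTIF"):
            toks = line.split()
            motif_id = toks[1] if len(toks) > 1 else f"motif_{len(pwms) + 1}"
            # find the letter-probability header
            i += 1
            while i < len(lines) and "letter-probability matrix" not in lines[i]:
                i += 1
            if i >= len(lines):
                raise ValueError(f"motif {motif_id}: missing probability matrix")
            header = lines[i]
            w = None
            if "w=" in header:
                w = int(header.split("w=")[1].split()[0])
            rows = []
            i += 1
            while i < len(lines):
                toks = lines[i].split()
                if len(toks) == 4:
                    try:
                        rows.append([float(t) for t in toks])
                    except ValueError:
                        break
                    i += 1
                    if w is not None and len(rows) == w:
                        break
                else:
                    break
            freq = np.array(rows)
            # renormalize rows (MEME files are printed at limited precision)
            freq = np.clip(freq, 1e-9, None)
            freq = freq / freq.sum(axis=1, keepdims=True)
            pwms.append(PWM(motif_id, freq, background=background))
        i += 1
    return pwms


def read_pwm_tsv(path: str, motif_id: Optional[str] = None) -> PWM:
    """Read a plain W x 4 probability matrix (optional A/C/G/T header)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.iloc[0].astype(str).str.upper().tolist() == list(BASES):
        df = df.iloc[1:].reset_index(drop=True)
    freq = df.astype(float).to_numpy()
    freq = np.clip(freq, 1e-9, None)
    freq = freq / freq.sum(axis=1, keepdims=True)
    return PWM(motif_id or path, freq)


def write_pwm_tsv(pwm: PWM, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(BASES) + "\n")
        for row in pwm.freq:
            fh.write("\t".join(repr(float(x)) for x in row) + "\n")
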