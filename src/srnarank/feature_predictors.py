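"""Promoter sites, intrinsic terminators and folding energies.

The seven-feature representation needs three kinds of evidence that, in a
full production setting, come from external predictors: a secondary-structure
stability score, -10 promoter boxes, and Rho-independent terminators. This
module provides both *parsers* for the external tools' report formats (BPROM
plain text, TransTermHP predictions) and *built-in algorithms* so the whole
pipeline runs with no third-party binaries:

* :func:`fold_mfe` — a weighted Nussinov minimization over nested structures
  (dimensionless score; lower = more stable);
* :func:`scan_minus10` — a position-weight-matrix scan for TATAAT-like boxes;
* :func:`detect_terminators` — a hairpin + U-tract detector on both strands.

The built-ins are exchangeable with externally supplied sites: downstream
feature code only needs site coordinates and one stability number per
sequence, not the external tools' exact scores.
"""

from __future__ import annotations

import re
import sys
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .genome_io import (
    AnnotationSet,
    GenomeSequence,
    GenomicInterval,
    reverse_complement,
)

# ---------------------------------------------------------------------------
# Types


@dataclass(frozen=True)
class PromoterSite:
    """A predicted -10 box (6 nt) with its predictor score."""

    interval: GenomicInterval
    score: float

    def __post_init__(self) -> None:
        if self.interval.length != 6:
            raise ValueError("-10 box must span exactly 6 nt")
        if not np.isfinite(self.score):
            raise ValueError("promoter score must be finite")


@dataclass(frozen=True)
class TerminatorSite:
    """A predicted Rho-independent terminator (hairpin + U-tract span)."""

    interval: GenomicInterval
    confidence: float


@dataclass(frozen=True)
class FoldResult:
    structure: str
    energy: float


@dataclass(frozen=True)
class PWM:
    """4 x width log-odds matrix (rows A, C, G, T) with a reporting threshold."""

    matrix: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != 4 or not np.all(np.isfinite(self.matrix)):
            raise ValueError("PWM must be a finite 4 x width matrix")
        if not np.isfinite(self.threshold):
            raise ValueError("PWM threshold must be finite")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def load_default_pwm() -> PWM:
    """The packaged TATAAT-consensus -10 model (log2-odds vs uniform)."""
    rows: dict[str, list[float]] = {}
    threshold = None
    text = resources.files("srnarank").joinpath("data/minus10_pwm.tsv").read_text()
    for line in text.splitlines():
        if line.startswith("#threshold"):
            threshold = float(line.split("\t")[1])
        elif line.startswith("#") or not line.strip():
            continue
        else:
            fields = line.split("\t")
            rows[fields[0]] = [float(v) for v in fields[1:]]
    if threshold is None or set(rows) != set("ACGT"):
        raise ValueError("malformed packaged PWM file")
    matrix = np.array([rows[b] for b in "ACGT"])
    return PWM(matrix=matrix, threshold=threshold)


# ---------------------------------------------------------------------------
# Secondary-structure fold (weighted Nussinov)

DEFAULT_PAIR_WEIGHTS = {("G", "C"): -3.0, ("A", "U"): -2.0, ("G", "U"): -1.0}


def _weight_matrix(pair_weights: dict[tuple[str, str], float]) -> np.ndarray:
    """5x5 (AUGCN) pair-weight lookup; +inf marks a disallowed pair."""
    order = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}
    w = np.full((5, 5), np.inf)
    for (a, b), e in pair_weights.items():
        w[order[a], order[b]] = e
        w[order[b], order[a]] = e
    return w


def _encode_rna(seq: str) -> np.ndarray:
    s = seq.upper().replace("T", "U")
    order = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}
    try:
        return np.array([order[c] for c in s], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid residue {exc.args[0]!r} in sequence") from exc


def fold_mfe(
    seq: str,
    pair_weights: dict[tuple[str, str], float] | None = None,
    min_loop: int = 3,
    structure: bool = True,
) -> FoldResult:
    """Minimum-score nested secondary structure of ``seq``.

    Dynamic program over all pseudoknot-free structures whose hairpin loops
    contain at least ``min_loop`` unpaired bases. The reported energy is the
    minimum achievable sum of pair weights (default GC -3, AU -2, GU -1;
    dimensionless). Ties are broken toward fewer pairs, then toward the
    lexicographically smallest dot-bracket string. With ``structure=False``
    only the energy is computed (the traceback is skipped), which is what the
    feature pipeline uses.
    """
    if pair_weights is None:
        pair_weights = DEFAULT_PAIR_WEIGHTS
    code = _encode_rna(seq)
    n = len(code)
    if n == 0:
        raise ValueError("empty sequence")
    wmat = _weight_matrix(pair_weights)
    W = wmat[code[:, None], code[None, :]]  # W[i, k]

    # E[i, j] / P[i, j]: min energy / pairs-at-min-energy of s[i:j).
    E = np.zeros((n + 2, n + 2))
    P = np.zeros((n + 2, n + 2), dtype=np.int64)
    for d in range(min_loop + 2, n + 1):
        m = n - d + 1
        i_idx = np.arange(m)
        # candidate 0: leftmost base unpaired
        e_stack = [E[i_idx + 1, i_idx + d]]
        p_stack = [P[i_idx + 1, i_idx + d]]
        for t in range(min_loop + 1, d):
            # pair (i, i+t); inner s[i+1:i+t), right s[i+t+1:i+d)
            e_stack.append(
                (W[i_idx, i_idx + t] + E[i_idx + 1, i_idx + t]) + E[i_idx + t + 1, i_idx + d]
            )
            p_stack.append(1 + P[i_idx + 1, i_idx + t] + P[i_idx + t + 1, i_idx + d])
        e_cand = np.stack(e_stack)
        p_cand = np.stack(p_stack)
        best_e = e_cand.min(axis=0)
        masked_p = np.where(e_cand == best_e[None, :], p_cand, np.iinfo(np.int64).max)
        E[i_idx, i_idx + d] = best_e
        P[i_idx, i_idx + d] = masked_p.min(axis=0)

    energy = float(E[0, n])
    if not structure:
        return FoldResult(structure="", energy=energy)

    memo: dict[tuple[int, int], str] = {}

    def trace(i: int, j: int) -> str:
        if j - i <= 0:
            return ""
        key = (i, j)
        if key in memo:
            return memo[key]
        te, tp = E[i, j], P[i, j]
        best: str | None = None
        for t in range(min_loop + 1, j - i):
            k = i + t
            w = W[i, k]
            if not np.isfinite(w):
                continue
            if (w + E[i + 1, k]) + E[k + 1, j] == te and 1 + P[i + 1, k] + P[k + 1, j] == tp:
                cand = "(" + trace(i + 1, k) + ")" + trace(k + 1, j)
                if best is None or cand < best:
                    best = cand
        if best is None:
            # '(' < '.', so an unpaired leftmost base only wins by default
            best = "." + trace(i + 1, j)
        memo[key] = best
        return best

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 4 * n + 100))
    try:
        struct = trace(0, n)
    finally:
        sys.setrecursionlimit(old_limit)
    return FoldResult(structure=struct, energy=energy)


# ---------------------------------------------------------------------------
# PWM promoter scan


def scan_minus10(
    window: str, pwm: PWM | None = None, chrom: str = "window"
) -> list[PromoterSite]:
    """Score every offset of ``window`` against the -10 PWM.

    The window must already be strand-oriented (5'->3' of the candidate).
    Returns one window-relative :class:`PromoterSite` per offset whose
    log-odds score reaches the PWM threshold.
    """
    if pwm is None:
        pwm = load_default_pwm()
    w = pwm.width
    if len(window) < w:
        raise ValueError(f"window shorter than PWM width {w}")
    seq = window.upper().replace("U", "T")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid residues in window: {sorted(bad)}")
    sites = []
    for off in range(len(seq) - w + 1):
        kmer = seq[off : off + w]
        if "N" in kmer:
            continue
        score = sum(pwm.matrix[_BASE_INDEX[b], i] for i, b in enumerate(kmer))
        if score >= pwm.threshold:
            sites.append(
                PromoterSite(GenomicInterval(chrom, off, off + w, "+"), float(score))
            )
    return sites


# ---------------------------------------------------------------------------
# Intrinsic terminator detection

# WC + GU wobble pairing over A,C,G,T,N codes
_PAIR_TABLE = np.zeros((5, 5), dtype=bool)
for _a, _b in (("A", "T"), ("G", "C"), ("G", "T")):
    _PAIR_TABLE[_BASE_INDEX[_a], _BASE_INDEX[_b]] = True
    _PAIR_TABLE[_BASE_INDEX[_b], _BASE_INDEX[_a]] = True


def _encode_dna(seq: str) -> np.ndarray:
    lut = np.full(256, 4, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _scan_terminators_one_strand(
    seq: str,
    min_pairs: int,
    max_mismatch: int,
    loop_range: tuple[int, int],
    max_stem: int,
    tail_window: int,
    min_tail_t: int,
    max_gap: int,
) -> list[tuple[int, int, float]]:
    """(start, end, score) of raw hairpin+tail candidates on the given strand."""
    code = _encode_dna(seq.upper())
    n = len(code)
    is_t = (code == _BASE_INDEX["T"]).astype(np.int64)
    # T count in the tail window starting at each position (truncated at the end)
    cum = np.concatenate([[0], np.cumsum(is_t)])
    t_count = cum[np.minimum(np.arange(n) + tail_window, n)] - cum[np.arange(n)]

    out: list[tuple[int, int, float]] = []
    for stem in range(min_pairs, max_stem + 1):
        for loop in range(loop_range[0], loop_range[1] + 1):
            span = 2 * stem + loop
            m = n - span + 1
            if m <= 0:
                continue
            i_idx = np.arange(m)
            pairs = np.zeros(m, dtype=np.int64)
            for j in range(stem):
                pairs += _PAIR_TABLE[code[i_idx + j], code[i_idx + span - 1 - j]]
            ok_stem = (pairs >= min_pairs) & (stem - pairs <= max_mismatch)
            if not ok_stem.any():
                continue
            for gap in range(max_gap + 1):
                tail_start = i_idx + span + gap
                valid = ok_stem & (tail_start < n)
                tc = np.where(valid, t_count[np.minimum(tail_start, n - 1)], 0)
                hits = valid & (tc >= min_tail_t)
                for i in np.nonzero(hits)[0]:
                    end = min(int(tail_start[i]) + tail_window, n)
                    out.append((int(i), end, float(pairs[i] + tc[i])))
    return out


def _merge_calls(
    calls: list[tuple[int, int, float]]
) -> list[tuple[int, int, float]]:
    """Greedy highest-score-first merge: drop calls overlapping a kept one."""
    kept: list[tuple[int, int, float]] = []
    for start, end, score in sorted(calls, key=lambda c: (-c[2], c[0], c[1])):
        if all(end <= ks or ke <= start for ks, ke, _ in kept):
            kept.append((start, end, score))
    return sorted(kept)


def detect_terminators(
    genome: GenomeSequence,
    min_pairs: int = 6,
    max_mismatch: int = 1,
    loop_range: tuple[int, int] = (3, 8),
    max_stem: int = 12,
    tail_window: int = 8,
    min_tail_t: int = 4,
    max_gap: int = 2,
) -> AnnotationSet:
    """Find hairpin + U-tract loci on both strands of ``genome``.

    A call requires a stem of at least ``min_pairs`` Watson-Crick/GU pairs
    with at most ``max_mismatch`` mismatches, a loop of ``loop_range`` nt,
    and, within ``max_gap`` nt downstream of the stem, at least
    ``min_tail_t`` T residues in the first ``tail_window`` nt. Overlapping
    calls on the same strand are merged keeping the higher-scoring one
    (score = stem pairs + tail T count).
    """
    kwargs = dict(
        min_pairs=min_pairs,
        max_mismatch=max_mismatch,
        loop_range=loop_range,
        max_stem=max_stem,
        tail_window=tail_window,
        min_tail_t=min_tail_t,
        max_gap=max_gap,
    )
    n = len(genome)
    sites: list[TerminatorSite] = []
    fwd = _merge_calls(_scan_terminators_one_strand(genome.residues, **kwargs))
    for start, end, score in fwd:
        sites.append(
            TerminatorSite(GenomicInterval(genome.id, start, end, "+"), score)
        )
    rev = _merge_calls(
        _scan_terminators_one_strand(reverse_complement(genome.residues), **kwargs)
    )
    for start, end, score in rev:
        sites.append(
            TerminatorSite(GenomicInterval(genome.id, n - end, n - start, "-"), score)
        )
    return AnnotationSet(
        (s.interval for s in sorted(sites, key=lambda s: (s.interval.start, s.interval.strand))),
        role="terminator",
    )


def detect_terminator_sites(genome: GenomeSequence, **kwargs) -> list[TerminatorSite]:
    """Like :func:`detect_terminators` but keeping scores with the intervals."""
    n = len(genome)
    sites: list[TerminatorSite] = []
    for start, end, score in _merge_calls(
        _scan_terminators_one_strand(genome.residues, **_term_kwargs(kwargs))
    ):
        sites.append(TerminatorSite(GenomicInterval(genome.id, start, end, "+"), score))
    for start, end, score in _merge_calls(
        _scan_terminators_one_strand(
            reverse_complement(genome.residues), **_term_kwargs(kwargs)
        )
    ):
        sites.append(
            TerminatorSite(GenomicInterval(genome.id, n - end, n - start, "-"), score)
        )
    return sorted(sites, key=lambda s: (s.interval.start, s.interval.strand))


def _term_kwargs(overrides: dict) -> dict:
    base = dict(
        min_pairs=6,
        max_mismatch=1,
        loop_range=(3, 8),
        max_stem=12,
        tail_window=8,
        min_tail_t=4,
        max_gap=2,
    )
    base.update(overrides)
    return base


# ---------------------------------------------------------------------------
# External predictor report parsers

_BPROM_BOX = re.compile(
    r"-10 box at pos\.?\s+(\d+)\s+(\S+)\s+[Ss]core\s+(-?\d+(?:\.\d+)?)"
)
_TRANSTERM = re.compile(
    r"^\s*TERM\s+\d+\s+(\d+)\s*\.\.\s*(\d+)\s+([+-])\s+(\S+)\s+(\d+(?:\.\d+)?)"
)


def parse_bprom(report: str, window: GenomicInterval) -> list[PromoterSite]:
    """Extract "-10 box at pos." records from BPROM plain-text output.

    ``window`` is the genomic region whose extracted (strand-oriented)
    sequence was submitted to BPROM. BPROM positions are 1-based and
    window-relative; on the + strand position ``p`` maps to genome
    coordinate ``window.start + p - 1`` (the box's 5'-most base), on the
    - strand to ``window.end - p``.
    """
    sites: list[PromoterSite] = []
    for lineno, line in enumerate(report.splitlines(), start=1):
        if "-10 box" not in line:
            continue
        m = _BPROM_BOX.search(line)
        if not m:
            raise ValueError(f"unparseable BPROM -10 record at line {lineno}: {line!r}")
        pos = int(m.group(1))
        score = float(m.group(3))
        if pos < 1 or pos > window.length:
            raise ValueError(
                f"BPROM position {pos} outside window of length {window.length} "
                f"(line {lineno})"
            )
        if window.strand == "+":
            five = window.start + pos - 1
            iv = GenomicInterval(window.chrom, five, five + 6, "+")
        else:
            five = window.end - pos
            iv = GenomicInterval(window.chrom, five - 5, five + 1, "-")
        sites.append(PromoterSite(iv, score))
    return sites


def parse_transterm(report: str, default_chrom: str = "genome") -> list[TerminatorSite]:
    """Parse TransTermHP "TERM" prediction records.

    Coordinates are converted from TransTermHP's 1-based inclusive
    convention to 0-based half-open; a record with start > end is a
    - strand call and is normalized. Confidence must lie in [0, 100].
    """
    sites: list[TerminatorSite] = []
    chrom = default_chrom
    for lineno, line in enumerate(report.splitlines(), start=1):
        if line.startswith("SEQUENCE"):
            parts = line.split()
            if len(parts) > 1:
                chrom = parts[1]
            continue
        if "TERM" not in line:
            continue
        m = _TRANSTERM.match(line)
        if not m:
            raise ValueError(f"unparseable TERM record at line {lineno}: {line!r}")
        a, b = int(m.group(1)), int(m.group(2))
        strand = m.group(3)
        conf = float(m.group(5))
        if not (0 <= conf <= 100):
            raise ValueError(f"confidence {conf} outside [0,100] at line {lineno}")
        if a > b:
            a, b = b, a
            strand = "-"
        sites.append(TerminatorSite(GenomicInterval(chrom, a - 1, b, strand), conf))
    return sites
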