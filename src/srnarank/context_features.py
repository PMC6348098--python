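"""The seven-feature genomic-context representation of a candidate sRNA.

Each candidate is summarized by:

1. ``energy`` — stability score of its predicted secondary structure;
2. ``distPromoter`` — distance from the sRNA 5' start to the closest -10
   box found between 150 nt upstream and the sRNA 3' end (sentinel -1000
   when no box is found in that region);
3. ``distTerminator`` — distance from the sRNA 3' end to the closest
   same-strand Rho-independent terminator, clamped to [0, 1000] (sentinel
   1000 when none is within range);
4./5. ``distLeftORF`` (<= 0) and ``sameStrandLeft`` — gap to the annotated
   ORF at lower genomic coordinates (0 when overlapping) and whether the
   sRNA shares its strand;
6./7. ``distRightORF`` (>= 0) and ``sameStrandRight`` — the mirror for the
   ORF at higher genomic coordinates.

"Left"/"right" are genome-axis notions (lower/higher coordinates),
independent of the sRNA's own strand; overlap clamps either distance to 0.
The promoter distance is signed: d > 0 means the box sits upstream of the
5' start (at most 150), d <= 0 means it lies inside the sRNA, so the -1000
sentinel is strictly outside the attainable range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Protocol, Sequence

import numpy as np
import pandas as pd

from .feature_predictors import (
    PWM,
    PromoterSite,
    TerminatorSite,
    detect_terminator_sites,
    fold_mfe,
    load_default_pwm,
    scan_minus10,
)
from .genome_io import (
    AnnotationSet,
    GenomeSequence,
    GenomicInterval,
    extract_sequence,
)

logger = logging.getLogger(__name__)

PROMOTER_SENTINEL = -1000
TERMINATOR_SENTINEL = 1000
UPSTREAM_FLANK = 150

FEATURE_COLUMNS = [
    "energy",
    "distPromoter",
    "distTerminator",
    "distLeftORF",
    "sameStrandLeft",
    "distRightORF",
    "sameStrandRight",
]
TABLE_COLUMNS = ["name"] + FEATURE_COLUMNS


@dataclass(frozen=True)
class Window:
    """A possibly-unnormalized region: start may be negative and end may
    exceed the genome length on circular genomes (the extractor wraps)."""

    chrom: str
    start: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


def upstream_window(
    srna: GenomicInterval, genome: GenomeSequence, flank: int = UPSTREAM_FLANK
) -> Window:
    """Region from ``flank`` nt upstream of the sRNA 5' start to its 3' end.

    On the + strand this is ``[start - flank, end)``; on the - strand
    ``[start, end + flank)``. Windows wrap on circular genomes and are
    truncated (with a logged note) at the edges of linear ones.
    """
    n = len(genome)
    if srna.strand == "+":
        start, end = srna.start - flank, srna.end
    else:
        start, end = srna.start, srna.end + flank
    if not genome.circular:
        if start < 0 or end > n:
            logger.info("upstream window of %s truncated at genome edge", srna.name)
        start, end = max(start, 0), min(end, n)
    return Window(srna.chrom, start, end, srna.strand)


# ---------------------------------------------------------------------------
# ORF distances


def _orf_candidates(
    orfs: Sequence[GenomicInterval], genome_length: int | None, circular: bool
) -> list[tuple[int, int, str, str]]:
    """(start, end, strand, name) of direct plus, when circular, wrapped copies."""
    cands = [(o.start, o.end, o.strand, o.name) for o in orfs]
    if circular and genome_length:
        cands += [
            (o.start - genome_length, o.end - genome_length, o.strand, o.name)
            for o in orfs
        ]
        cands += [
            (o.start + genome_length, o.end + genome_length, o.strand, o.name)
            for o in orfs
        ]
    return cands


def closest_left_orf(
    srna: GenomicInterval,
    orfs: AnnotationSet,
    genome_length: int | None = None,
    circular: bool = True,
) -> tuple[int, int]:
    """(distLeftORF, sameStrandLeft) for the ORF at lower coordinates.

    The left ORF is the one with the greatest end among ORFs starting
    before the sRNA; the distance is ``min(0, orf.end - srna.start)`` so
    any overlap yields 0. On circular genomes the search wraps around the
    origin. Ties on the gap are broken by name for determinism.
    """
    chrom_orfs = orfs.by_chrom(srna.chrom)
    if not chrom_orfs:
        raise ValueError(f"no ORF annotated on chromosome {srna.chrom!r}")
    best: tuple[int, str, str] | None = None  # (end, name, strand)
    for start, end, strand, name in _orf_candidates(chrom_orfs, genome_length, circular):
        if start < srna.start:
            key = (end, name)
            if best is None or (key[0], key[1]) > (best[0], best[1]):
                best = (end, name, strand)
    if best is None:
        raise ValueError(
            f"no ORF leftward of {srna.name} on a linear genome; "
            "supply genome_length with circular=True to wrap"
        )
    dist = min(0, best[0] - srna.start)
    return dist, int(best[2] == srna.strand)


def closest_right_orf(
    srna: GenomicInterval,
    orfs: AnnotationSet,
    genome_length: int | None = None,
    circular: bool = True,
) -> tuple[int, int]:
    """(distRightORF, sameStrandRight): mirror of :func:`closest_left_orf`.

    The right ORF has the smallest start among ORFs ending after the sRNA;
    distance ``max(0, orf.start - srna.end)``.
    """
    chrom_orfs = orfs.by_chrom(srna.chrom)
    if not chrom_orfs:
        raise ValueError(f"no ORF annotated on chromosome {srna.chrom!r}")
    best: tuple[int, str, str] | None = None  # (start, name, strand)
    for start, end, strand, name in _orf_candidates(chrom_orfs, genome_length, circular):
        if end > srna.end:
            if best is None or (start, name) < (best[0], best[1]):
                best = (start, name, strand)
    if best is None:
        raise ValueError(
            f"no ORF rightward of {srna.name} on a linear genome; "
            "supply genome_length with circular=True to wrap"
        )
    dist = max(0, best[0] - srna.end)
    return dist, int(best[2] == srna.strand)


# ---------------------------------------------------------------------------
# Promoter / terminator distances


def _site_positions_in_window(
    site: PromoterSite, win: Window, genome_length: int | None
) -> int | None:
    """5'-most genome coordinate of ``site`` if its box lies fully inside
    ``win`` (allowing for origin wrap), else None. Coordinates returned in
    the window's unnormalized frame."""
    iv = site.interval
    if iv.chrom != win.chrom:
        return None
    shifts = [0]
    if genome_length:
        shifts += [-genome_length, genome_length]
    for shift in shifts:
        s, e = iv.start + shift, iv.end + shift
        if s >= win.start and e <= win.end:
            return s if win.strand == "+" else e - 1
    return None


def promoter_distance(
    srna: GenomicInterval,
    sites: Iterable[PromoterSite],
    genome: GenomeSequence | None = None,
    flank: int = UPSTREAM_FLANK,
) -> int:
    """Signed distance from the sRNA 5' start to the closest in-window -10 box.

    Only boxes lying fully inside the upstream window count. d > 0 means
    the box is upstream of the 5' start; d <= 0 inside the sRNA. Among
    candidates the minimum |d| wins, ties preferring the upstream
    (positive) one; with no in-window box the sentinel -1000 is returned.
    """
    if genome is not None:
        win = upstream_window(srna, genome, flank)
        glen = len(genome) if genome.circular else None
    else:
        if srna.strand == "+":
            win = Window(srna.chrom, srna.start - flank, srna.end, "+")
        else:
            win = Window(srna.chrom, srna.start, srna.end + flank, "-")
        glen = None
    five = srna.start if srna.strand == "+" else srna.end - 1
    best: int | None = None
    for site in sites:
        pos = _site_positions_in_window(site, win, glen)
        if pos is None:
            continue
        d = five - pos if srna.strand == "+" else pos - five
        if best is None or (abs(d), -d) < (abs(best), -best):
            best = d
    return PROMOTER_SENTINEL if best is None else int(best)


def terminator_distance(
    srna: GenomicInterval,
    terminators: Iterable[GenomicInterval | TerminatorSite],
    genome_length: int | None = None,
    circular: bool = True,
    max_dist: int = TERMINATOR_SENTINEL,
) -> int:
    """Distance from the sRNA 3' end to the nearest same-strand terminator.

    Only terminators overlapping the sRNA (distance 0) or downstream of its
    3' end are considered — intrinsic termination acts in cis at the 3'
    end. Distances above ``max_dist`` (or no candidate at all) return the
    sentinel ``max_dist``.
    """
    best: int | None = None
    for term in terminators:
        iv = term.interval if isinstance(term, TerminatorSite) else term
        if iv.chrom != srna.chrom or iv.strand != srna.strand:
            continue
        if iv.overlaps(srna):
            return 0
        if srna.strand == "+":
            gaps = [iv.start - srna.end]
            if circular and genome_length:
                gaps.append(iv.start + genome_length - srna.end)
        else:
            gaps = [srna.start - iv.end]
            if circular and genome_length:
                gaps.append(srna.start - (iv.end - genome_length))
        for g in gaps:
            if g >= 0 and (best is None or g < best):
                best = g
    if best is None or best > max_dist:
        return max_dist
    return int(best)


# ---------------------------------------------------------------------------
# Providers


class PromoterProvider(Protocol):
    def sites_for(
        self, srna: GenomicInterval, genome: GenomeSequence
    ) -> list[PromoterSite]: ...


class PwmPromoterScanner:
    """Fallback provider: scan each candidate's upstream window with a PWM."""

    def __init__(self, pwm: PWM | None = None, flank: int = UPSTREAM_FLANK) -> None:
        self.pwm = pwm if pwm is not None else load_default_pwm()
        self.flank = flank

    def sites_for(
        self, srna: GenomicInterval, genome: GenomeSequence
    ) -> list[PromoterSite]:
        win = upstream_window(srna, genome, self.flank)
        seq = extract_sequence(genome, win)
        sites = []
        for s in scan_minus10(seq, self.pwm, chrom=srna.chrom):
            off = s.interval.start
            if win.strand == "+":
                start = win.start + off
            else:
                start = win.end - off - 6
            n = len(genome)
            start_norm = start % n if genome.circular else start
            if start_norm + 6 > n:
                # box straddles the origin and has no single-interval
                # representation; such calls are dropped
                continue
            sites.append(
                PromoterSite(
                    GenomicInterval(srna.chrom, start_norm, start_norm + 6, win.strand),
                    s.score,
                )
            )
        return sites


class FixedPromoterSites:
    """Provider backed by externally supplied sites (BED or BPROM parse)."""

    def __init__(self, sites: Iterable[PromoterSite]) -> None:
        self.sites = list(sites)

    def sites_for(
        self, srna: GenomicInterval, genome: GenomeSequence
    ) -> list[PromoterSite]:
        return [s for s in self.sites if s.interval.strand == srna.strand]


class TerminatorProvider(Protocol):
    def terminators_for(self, genome: GenomeSequence) -> list[GenomicInterval]: ...


class HairpinTerminatorDetector:
    """Fallback provider: built-in hairpin + U-tract scan, cached per genome."""

    def __init__(self, **params) -> None:
        self.params = params
        self._cache: dict[str, list[GenomicInterval]] = {}

    def terminators_for(self, genome: GenomeSequence) -> list[GenomicInterval]:
        if genome.id not in self._cache:
            self._cache[genome.id] = [
                s.interval for s in detect_terminator_sites(genome, **self.params)
            ]
        return self._cache[genome.id]


class FixedTerminators:
    def __init__(self, terminators: Iterable[GenomicInterval | TerminatorSite]) -> None:
        self.terminators = [
            t.interval if isinstance(t, TerminatorSite) else t for t in terminators
        ]

    def terminators_for(self, genome: GenomeSequence) -> list[GenomicInterval]:
        return self.terminators


EnergyProvider = Callable[[GenomicInterval, GenomeSequence], float]


class NussinovEnergy:
    """Fallback provider: weighted Nussinov fold score of the sRNA sequence."""

    def __init__(self, min_loop: int = 3) -> None:
        self.min_loop = min_loop

    def __call__(self, srna: GenomicInterval, genome: GenomeSequence) -> float:
        seq = extract_sequence(genome, srna)
        return fold_mfe(seq, min_loop=self.min_loop, structure=False).energy


class PrecomputedEnergies:
    """Provider backed by a name -> energy mapping (e.g. a two-column TSV)."""

    def __init__(self, energies: dict[str, float]) -> None:
        self.energies = dict(energies)

    @classmethod
    def from_tsv(cls, path) -> "PrecomputedEnergies":
        df = pd.read_csv(path, sep="\t", header=None, names=["name", "energy"])
        return cls(dict(zip(df["name"], df["energy"].astype(float))))

    def __call__(self, srna: GenomicInterval, genome: GenomeSequence) -> float:
        if srna.name not in self.energies:
            raise KeyError(f"no precomputed energy for {srna.name!r}")
        return float(self.energies[srna.name])


# ---------------------------------------------------------------------------
# Characterize


def characterize(
    srnas: Iterable[GenomicInterval],
    genome: GenomeSequence,
    orfs: AnnotationSet,
    promoter_provider: PromoterProvider | None = None,
    terminator_provider: TerminatorProvider | None = None,
    energy_provider: EnergyProvider | None = None,
    flank: int = UPSTREAM_FLANK,
) -> pd.DataFrame:
    """Compute the seven-feature table, one row per candidate in input order.

    Providers default to the built-in fallbacks (PWM scan, hairpin
    detector, Nussinov fold). The output is the hand-off contract with the
    classifiers: columns ``name`` + :data:`FEATURE_COLUMNS`, no missing
    values. Provider errors are re-raised with the candidate name attached.
    """
    if promoter_provider is None:
        promoter_provider = PwmPromoterScanner(flank=flank)
    if terminator_provider is None:
        terminator_provider = HairpinTerminatorDetector()
    if energy_provider is None:
        energy_provider = NussinovEnergy()

    glen = len(genome)
    rows = []
    for srna in srnas:
        try:
            energy = energy_provider(srna, genome)
            sites = promoter_provider.sites_for(srna, genome)
            d_prom = promoter_distance(srna, sites, genome=genome, flank=flank)
            terms = terminator_provider.terminators_for(genome)
            d_term = terminator_distance(
                srna, terms, genome_length=glen, circular=genome.circular
            )
            d_left, same_left = closest_left_orf(
                srna, orfs, genome_length=glen, circular=genome.circular
            )
            d_right, same_right = closest_right_orf(
                srna, orfs, genome_length=glen, circular=genome.circular
            )
        except Exception as exc:
            raise type(exc)(f"while characterizing {srna.name!r}: {exc}") from exc
        rows.append(
            {
                "name": srna.name,
                "energy": float(energy),
                "distPromoter": d_prom,
                "distTerminator": d_term,
                "distLeftORF": d_left,
                "sameStrandLeft": same_left,
                "distRightORF": d_right,
                "sameStrandRight": same_right,
            }
        )
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    _validate_feature_table(df)
    return df


def _validate_feature_table(df: pd.DataFrame) -> None:
    if df.empty:
        return
    if df[FEATURE_COLUMNS].isna().any().any():
        raise ValueError("feature table contains missing values")
    assert (df["distLeftORF"] <= 0).all()
    assert (df["distRightORF"] >= 0).all()
    assert df["distTerminator"].between(0, TERMINATOR_SENTINEL).all()
    assert df["sameStrandLeft"].isin([0, 1]).all()
    assert df["sameStrandRight"].isin([0, 1]).all()


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    return df
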