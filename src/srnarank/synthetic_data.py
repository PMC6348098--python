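"""Seeded toy genomes with planted annotation geometry.

The generator emulates the statistical structure the feature pipeline
assumes about real bacterial chromosomes: a dense array of protein-coding
ORFs separated by intergenic gaps, with each planted "bona fide" sRNA
sitting inside a gap, flanked by an exact TATAAT -10 box a fixed offset
upstream of its 5' start and a canonical GC-hairpin + 8T intrinsic
terminator a fixed offset downstream of its 3' end. Random loci sampled
from such a genome overlap ORFs at high frequency, while the planted
positives never do — mirroring the contrast that makes genomic-context
features discriminative on real data.

Because random background sequence also contains spurious TATAAT-like
boxes and hairpin/U-tract loci, the generator runs a deterministic
*scrub* pass after planting: any background motif that would displace a
planted element as the closest call is mutated (never touching planted
coordinates) until the built-in predictors recover exactly the planted
promoter and terminator distances for every positive. The scrub is part
of the fixture's determinism contract: identical configs give
byte-identical FASTA/BED output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .context_features import (
    PwmPromoterScanner,
    promoter_distance,
    terminator_distance,
)
from .feature_predictors import detect_terminator_sites, load_default_pwm
from .genome_io import (
    AnnotationSet,
    GenomeSequence,
    GenomicInterval,
    reverse_complement,
)

PROMOTER_MOTIF = "TATAAT"
# 8 bp GC-rich stem, 4 nt loop, complementary stem, 8 T tail
_TERM_STEM = "GGCAGCGC"
TERMINATOR_MOTIF = _TERM_STEM + "TTCA" + reverse_complement(_TERM_STEM) + "TTTTTTTT"


@dataclass
class SimulationConfig:
    genome_length: int = 50_000
    n_orfs: int = 40
    orf_length_range: tuple[int, int] = (400, 1200)
    n_positives: int = 20
    promoter_offset: int = 35
    terminator_offset: int = 20
    srna_length_range: tuple[int, int] = (50, 300)
    gc_content: float = 0.5
    seed: int = 0
    chrom: str = "synthchr"
    margin: int = 10
    scrub_iterations: int = 200

    def __post_init__(self) -> None:
        if self.promoter_offset < len(PROMOTER_MOTIF):
            raise ValueError("promoter_offset must be >= motif length")
        if self.terminator_offset < 0:
            raise ValueError("terminator_offset must be >= 0")
        if not (0 < self.gc_content < 1):
            raise ValueError("gc_content must be in (0, 1)")
        for lo, hi in (self.orf_length_range, self.srna_length_range):
            if lo < 1 or hi < lo:
                raise ValueError("length ranges must be positive and ordered")


@dataclass
class SimulatedGenome:
    genome: GenomeSequence
    orfs: AnnotationSet
    positives: AnnotationSet
    truth: pd.DataFrame


def _random_bases(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=probs)


def simulate_genome(cfg: SimulationConfig) -> SimulatedGenome:
    """Generate a genome, its ORF annotation, planted positives and truth table."""
    rng = np.random.default_rng(cfg.seed)
    cassette_pad = cfg.promoter_offset + len(TERMINATOR_MOTIF) + cfg.terminator_offset

    orf_lens = rng.integers(
        cfg.orf_length_range[0], cfg.orf_length_range[1] + 1, cfg.n_orfs
    )
    srna_lens = rng.integers(
        cfg.srna_length_range[0], cfg.srna_length_range[1] + 1, cfg.n_positives
    )
    srna_strands = ["+" if i % 2 == 0 else "-" for i in range(cfg.n_positives)]

    n_gaps = cfg.n_orfs + 1
    if cfg.n_positives > n_gaps:
        raise ValueError("more positives than intergenic gaps")
    host_gaps = np.sort(
        rng.choice(n_gaps, size=cfg.n_positives, replace=False)
    )
    gap_sizes = rng.integers(60, 201, n_gaps)
    cassette_lens = srna_lens + cassette_pad + 2 * cfg.margin
    for gi, cl in zip(host_gaps, cassette_lens):
        gap_sizes[gi] = cl + int(rng.integers(20, 101))

    total = int(orf_lens.sum() + gap_sizes.sum())
    leftover = cfg.genome_length - total
    if leftover < 0:
        raise ValueError(
            f"infeasible geometry: planted content needs {total} nt but "
            f"genome_length is {cfg.genome_length}"
        )
    non_host = [g for g in range(n_gaps) if g not in set(host_gaps.tolist())] or list(
        range(n_gaps)
    )
    per, rem = divmod(leftover, len(non_host))
    for j, g in enumerate(non_host):
        gap_sizes[g] += per + (1 if j < rem else 0)

    # lay out coordinates: gap0, ORF0, gap1, ORF1, ..., ORF(n-1), gap(n)
    seq = _random_bases(rng, cfg.genome_length, cfg.gc_content)
    orfs: list[GenomicInterval] = []
    gap_coords: list[tuple[int, int]] = []
    pos = 0
    for i in range(cfg.n_orfs):
        gap_coords.append((pos, pos + int(gap_sizes[i])))
        pos += int(gap_sizes[i])
        strand = "+" if rng.random() < 0.5 else "-"
        orfs.append(
            GenomicInterval(cfg.chrom, pos, pos + int(orf_lens[i]), strand, f"orf{i:03d}")
        )
        pos += int(orf_lens[i])
    gap_coords.append((pos, pos + int(gap_sizes[-1])))
    assert gap_coords[-1][1] == cfg.genome_length

    positives: list[GenomicInterval] = []
    locked = np.zeros(cfg.genome_length, dtype=bool)
    truth_rows = []
    for j, (gi, length, strand) in enumerate(zip(host_gaps, srna_lens, srna_strands)):
        g_start, g_end = gap_coords[gi]
        length = int(length)
        cassette = length + cassette_pad
        if strand == "+":
            left_ext = cfg.promoter_offset  # promoter box upstream of 5' start
            slack = (g_end - g_start) - cassette - 2 * cfg.margin
            offset = int(rng.integers(0, slack + 1))
            start = g_start + cfg.margin + left_ext + offset
            end = start + length
            prom_start = start - cfg.promoter_offset
            seq[prom_start : prom_start + 6] = np.frombuffer(
                PROMOTER_MOTIF.encode(), dtype="S1"
            )
            term_start = end + cfg.terminator_offset
            seq[term_start : term_start + len(TERMINATOR_MOTIF)] = np.frombuffer(
                TERMINATOR_MOTIF.encode(), dtype="S1"
            )
        else:
            left_ext = cfg.terminator_offset + len(TERMINATOR_MOTIF)
            slack = (g_end - g_start) - cassette - 2 * cfg.margin
            offset = int(rng.integers(0, slack + 1))
            start = g_start + cfg.margin + left_ext + offset
            end = start + length
            prom_start = end + cfg.promoter_offset - 6
            seq[prom_start : prom_start + 6] = np.frombuffer(
                reverse_complement(PROMOTER_MOTIF).encode(), dtype="S1"
            )
            term_start = start - cfg.terminator_offset - len(TERMINATOR_MOTIF)
            seq[term_start : term_start + len(TERMINATOR_MOTIF)] = np.frombuffer(
                reverse_complement(TERMINATOR_MOTIF).encode(), dtype="S1"
            )
        locked[prom_start : prom_start + 6] = True
        locked[term_start : term_start + len(TERMINATOR_MOTIF)] = True
        srna = GenomicInterval(cfg.chrom, start, end, strand, f"srna{j:03d}")
        positives.append(srna)
        truth_rows.append(
            {
                "name": srna.name,
                "start": start,
                "end": end,
                "strand": strand,
                "promoter_start": prom_start,
                "terminator_start": term_start,
                "host_gap": int(gi),
            }
        )

    genome = GenomeSequence(cfg.chrom, seq.tobytes().decode(), circular=True)
    genome = _scrub(genome, positives, locked, cfg)

    for row in truth_rows:
        row["length"] = row["end"] - row["start"]
    truth = pd.DataFrame(truth_rows)
    return SimulatedGenome(
        genome=genome,
        orfs=AnnotationSet(orfs, role="ORF"),
        positives=AnnotationSet(positives, role="sRNA"),
        truth=truth,
    )


def _planted_terminator_span(
    srna: GenomicInterval, cfg: SimulationConfig
) -> tuple[int, int]:
    tlen = len(TERMINATOR_MOTIF)
    if srna.strand == "+":
        start = srna.end + cfg.terminator_offset
    else:
        start = srna.start - cfg.terminator_offset - tlen
    return start, start + tlen


def _scrub(
    genome: GenomeSequence,
    positives: list[GenomicInterval],
    locked: np.ndarray,
    cfg: SimulationConfig,
) -> GenomeSequence:
    """Mutate background motifs that would displace a planted element.

    Repeats until, for every positive, the built-in predictors return
    exactly (promoter_offset, terminator_offset). Mutations are
    deterministic given the config seed and never touch locked (planted)
    positions.
    """
    pwm = load_default_pwm()
    seq = np.frombuffer(genome.residues.encode(), dtype="S1").copy()
    glen = len(genome)
    rng = np.random.default_rng(cfg.seed + 1)

    bases = np.frombuffer(b"ACGT", dtype="S1")

    def rewrite(span_start: int, span_end: int) -> bool:
        """Re-randomize every unlocked base in [span_start, span_end).

        Re-randomization is memoryless: each pass redraws the offending
        region until no qualifying motif survives there, which converges
        quickly because a fresh random span rarely recreates one. Returns
        False if the whole span is locked (planted)."""
        touched = False
        for p in range(span_start, span_end):
            q = p % glen
            if not locked[q]:
                seq[q] = bases[int(rng.integers(0, 4))]
                touched = True
        return touched

    for _ in range(cfg.scrub_iterations):
        g = GenomeSequence(genome.id, seq.tobytes().decode(), circular=True)
        scanner = PwmPromoterScanner(pwm)
        terms = detect_terminator_sites(g)
        term_ivs = [t.interval for t in terms]
        dirty = False
        for srna in positives:
            sites = scanner.sites_for(srna, g)
            d = promoter_distance(srna, sites, genome=g)
            if d != cfg.promoter_offset:
                # mutate every in-window box closer than the planted one
                five = srna.start if srna.strand == "+" else srna.end - 1
                fixed = False
                for site in sites:
                    iv = site.interval
                    pos5 = iv.start if srna.strand == "+" else iv.end - 1
                    delta = five - pos5 if srna.strand == "+" else pos5 - five
                    closer = abs(delta) < cfg.promoter_offset or (
                        delta == -cfg.promoter_offset
                    )
                    if closer and rewrite(iv.start, iv.end):
                        fixed = True
                if not fixed:
                    raise RuntimeError(
                        f"cannot scrub promoter neighbourhood of {srna.name}"
                    )
                dirty = True
            td = terminator_distance(
                srna, term_ivs, genome_length=glen, circular=True
            )
            if td != cfg.terminator_offset:
                fixed = False
                planted = _planted_terminator_span(srna, cfg)
                for iv in term_ivs:
                    if iv.strand != srna.strand or iv.chrom != srna.chrom:
                        continue
                    if iv.overlaps(srna):
                        gap = -1
                    elif srna.strand == "+" and iv.start >= srna.end:
                        gap = iv.start - srna.end
                    elif srna.strand == "-" and iv.end <= srna.start:
                        gap = srna.start - iv.end
                    else:
                        continue
                    # a call closer than the planted one, or an overlapping
                    # competitor that swallowed the planted call in merging
                    offending = gap < cfg.terminator_offset or (
                        gap != cfg.terminator_offset
                        and iv.start < planted[1]
                        and planted[0] < iv.end
                    )
                    if offending and rewrite(iv.start, iv.end):
                        fixed = True
                if not fixed:
                    raise RuntimeError(
                        f"cannot scrub terminator neighbourhood of {srna.name}"
                    )
                dirty = True
        if not dirty:
            return g
    raise RuntimeError("scrub did not converge; geometry too crowded")
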