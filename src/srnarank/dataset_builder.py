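"""Labelled dataset construction.

Negatives are random genomic loci matched in length and strand to the
positive (bona fide) sRNAs, rejected if they share any base with a
positive; they may overlap each other and annotated ORFs — which is the
point: random loci mostly fall inside coding regions, so genomic-context
features separate them from genuine intergenic sRNAs. Shuffled-sequence
negatives are deliberately unsupported (shuffling preserves genomic
context, making such negatives uninformative for these features).

The default sampling generates a pool of 10 negatives per positive; the
training draw takes 3 per *training* positive and everything left over
goes to the test set. Positives are split 80/20 (round-half-up) into
train/test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .context_features import FEATURE_COLUMNS, TABLE_COLUMNS
from .genome_io import AnnotationSet, GenomeSequence, GenomicInterval


@dataclass
class SamplingConfig:
    """Negative-sampling parameters.

    ratio_train: negatives drawn per training positive (default 3:1).
    pool_ratio: total negatives generated per positive (default 10).
    max_attempts: rejection-sampling cap per negative.
    """

    ratio_train: int = 3
    pool_ratio: int = 10
    seed: int = 0
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        if self.ratio_train < 1 or self.pool_ratio < self.ratio_train:
            raise ValueError("require ratio_train >= 1 and pool_ratio >= ratio_train")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")


@dataclass
class LabeledDataset:
    """Feature table + binary labels (1 = bona fide sRNA, 0 = random locus)."""

    features: pd.DataFrame
    labels: np.ndarray
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.features):
            raise ValueError("labels must align 1:1 with feature rows")
        missing = [c for c in TABLE_COLUMNS if c not in self.features.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def X(self) -> pd.DataFrame:
        return self.features[FEATURE_COLUMNS]

    @property
    def y(self) -> np.ndarray:
        return self.labels


def make_dataset(
    positives: pd.DataFrame,
    negatives: pd.DataFrame,
    species: str = "",
    partition: str = "",
    seed: int | None = None,
) -> LabeledDataset:
    """Stack positive and negative feature tables into a LabeledDataset."""
    features = pd.concat([positives, negatives], ignore_index=True)
    labels = np.concatenate(
        [np.ones(len(positives), dtype=int), np.zeros(len(negatives), dtype=int)]
    )
    prov = pd.DataFrame(
        {
            "name": features["name"],
            "species": species,
            "partition": partition,
            "seed": seed if seed is not None else -1,
        }
    )
    return LabeledDataset(features, labels, prov)


def sample_negatives(
    positives: AnnotationSet,
    genome: GenomeSequence,
    cfg: SamplingConfig,
) -> AnnotationSet:
    """Draw ``pool_ratio`` random loci per positive, matched in length and strand.

    No negative shares a base with any positive; negatives may overlap one
    another. Fully reproducible from ``cfg.seed``. A positive whose length
    cannot be placed within ``max_attempts`` rejections raises an error.
    """
    n = len(genome)
    pos_list = list(positives)
    if pos_list and max(p.length for p in pos_list) >= n:
        raise ValueError("genome shorter than the longest positive")
    trees: dict[str, IntervalTree] = {}
    for p in pos_list:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p.name)
    rng = np.random.default_rng(cfg.seed)
    negatives: list[GenomicInterval] = []
    for p in pos_list:
        for k in range(cfg.pool_ratio):
            for _ in range(cfg.max_attempts):
                start = int(rng.integers(0, n - p.length + 1))
                if not trees[p.chrom].overlaps(start, start + p.length):
                    negatives.append(
                        GenomicInterval(
                            p.chrom, start, start + p.length, p.strand,
                            name=f"{p.name}|neg{k}",
                        )
                    )
                    break
            else:
                raise RuntimeError(
                    f"could not place a negative for {p.name} "
                    f"(length {p.length}) after {cfg.max_attempts} attempts"
                )
    return AnnotationSet(negatives, role="negative")


def split_train_test(
    positives: AnnotationSet, frac: float = 0.8, seed: int = 0
) -> tuple[AnnotationSet, AnnotationSet]:
    """Seeded disjoint split of positives; train size = round-half-up(frac*n)."""
    if not (0 < frac < 1):
        raise ValueError("frac must be in (0, 1)")
    items = list(positives)
    npos = len(items)
    if npos < 2:
        raise ValueError("need at least 2 positives to split")
    n_train = int(np.floor(frac * npos + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(npos)
    train_idx = set(perm[:n_train].tolist())
    train = [iv for i, iv in enumerate(items) if i in train_idx]
    test = [iv for i, iv in enumerate(items) if i not in train_idx]
    return (
        AnnotationSet(train, role=positives.role),
        AnnotationSet(test, role=positives.role),
    )


def split_counts(n_positives: int, frac: float = 0.8) -> tuple[int, int]:
    """(train, test) sizes under the round-half-up convention."""
    n_train = int(np.floor(frac * n_positives + 0.5))
    return n_train, n_positives - n_train


def combine_datasets(parts: list[LabeledDataset]) -> LabeledDataset:
    """Row-wise concatenation of identically-schemed datasets."""
    if not parts:
        raise ValueError("no datasets to combine")
    schema = list(parts[0].features.columns)
    for p in parts[1:]:
        if list(p.features.columns) != schema:
            raise ValueError(
                f"schema mismatch: {list(p.features.columns)} vs {schema}"
            )
    features = pd.concat([p.features for p in parts], ignore_index=True)
    labels = np.concatenate([p.labels for p in parts])
    prov = pd.concat([p.provenance for p in parts], ignore_index=True)
    return LabeledDataset(features, labels, prov)


def dedup_intervals(
    rows: pd.DataFrame,
    subset: tuple[str, ...] = ("start", "end", "strand", "genome"),
) -> pd.DataFrame:
    """Drop rows duplicating an earlier (start, end, strand, genome) tuple.

    Used when assembling benchmark tables transcribed from publications,
    which commonly contain duplicated coordinate entries. Order is stable.
    """
    missing = [c for c in subset if c not in rows.columns]
    if missing:
        raise ValueError(f"missing columns for deduplication: {missing}")
    return rows.drop_duplicates(subset=list(subset), keep="first").reset_index(
        drop=True
    )
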