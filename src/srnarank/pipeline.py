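"""Orchestration shared by the CLI, the test suite and the scripts.

Nothing here adds behaviour: these helpers wire the module stages
(simulate -> characterize -> sample negatives -> split -> train ->
evaluate) together with consistent seeding.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import classifiers, context_features, dataset_builder, evaluation
from .dataset_builder import LabeledDataset, SamplingConfig, make_dataset
from .genome_io import AnnotationSet, GenomeSequence
from .synthetic_data import SimulatedGenome, SimulationConfig, simulate_genome


@dataclass
class FixtureDatasets:
    sim: SimulatedGenome
    features_pos: pd.DataFrame
    features_neg: pd.DataFrame
    negatives: AnnotationSet
    train: LabeledDataset
    test: LabeledDataset


def build_fixture_datasets(
    sim_cfg: SimulationConfig | None = None,
    sampling: SamplingConfig | None = None,
    split_seed: int = 0,
    species: str = "synthetic",
) -> FixtureDatasets:
    """Simulated genome -> feature tables -> matched negatives -> 80/20 split.

    The training set takes ``sampling.ratio_train`` negatives per training
    positive (the first ones drawn for each positive, so the training
    negatives of a lower ratio are a proper subset of a higher one); all
    remaining negatives go to the test set.
    """
    sim_cfg = sim_cfg or SimulationConfig()
    sampling = sampling or SamplingConfig(seed=sim_cfg.seed)
    sim = simulate_genome(sim_cfg)

    negatives = dataset_builder.sample_negatives(sim.positives, sim.genome, sampling)
    features_pos = context_features.characterize(sim.positives, sim.genome, sim.orfs)
    features_neg = context_features.characterize(negatives, sim.genome, sim.orfs)

    train_pos, test_pos = dataset_builder.split_train_test(
        sim.positives, frac=0.8, seed=split_seed
    )
    train_names = {iv.name for iv in train_pos}
    fpos = features_pos.set_index("name", drop=False)
    train_pos_feats = fpos.loc[[iv.name for iv in train_pos]].reset_index(drop=True)
    test_pos_feats = fpos.loc[[iv.name for iv in test_pos]].reset_index(drop=True)

    fneg = features_neg.copy()
    fneg["_parent"] = fneg["name"].str.rsplit("|", n=1).str[0]
    fneg["_k"] = fneg["name"].str.rsplit("neg", n=1).str[1].astype(int)
    is_train_neg = fneg["_parent"].isin(train_names) & (fneg["_k"] < sampling.ratio_train)
    train_neg_feats = fneg[is_train_neg].drop(columns=["_parent", "_k"]).reset_index(drop=True)
    test_neg_feats = fneg[~is_train_neg].drop(columns=["_parent", "_k"]).reset_index(drop=True)

    train = make_dataset(
        train_pos_feats, train_neg_feats, species=species, partition="train",
        seed=sampling.seed,
    )
    test = make_dataset(
        test_pos_feats, test_neg_feats, species=species, partition="test",
        seed=sampling.seed,
    )
    return FixtureDatasets(
        sim=sim,
        features_pos=features_pos,
        features_neg=features_neg,
        negatives=negatives,
        train=train,
        test=test,
    )


def train_and_score(
    fixture: FixtureDatasets, family: str = "RF", seed: int = 0
) -> tuple[classifiers.TrainedModel, float]:
    """Train one family on the fixture's training set; return test AUPRC."""
    model = classifiers.train(classifiers.default_config(family), fixture.train, seed=seed)
    scores = classifiers.predict_proba(model, fixture.test.features)
    return model, evaluation.pr_curve(scores, fixture.test.y).auprc
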