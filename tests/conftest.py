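import numpy as np
import pytest

from enhancerxai.fuzzy import FuzzyRule, RuleBase, default_partition
from enhancerxai.synth import SyntheticConfig, generate_tracks
from enhancerxai.tracks import (
    LabelTrack,
    SignalTrack,
    build_dataset,
    sample_training_set,
)


def dataset_from_generator(config: SyntheticConfig):
    """Build a BinDataset (plus truth and bins) straight from the
    generator's per-bin arrays; generator signals are already in [0, 1]."""
    tracks, enhancers, truth, y, bins = generate_tracks(config)
    dataset = build_dataset(
        bins,
        {m: SignalTrack(m, v, normalized=True) for m, v in tracks.items()},
        LabelTrack(y),
        config.marks,
    )
    return dataset, enhancers, truth, bins


@pytest.fixture(scope="session")
def small_synth():
    """Zero-noise 300 kb genome with planted rules; used across modules."""
    config = SyntheticConfig(
        chrom_sizes={"chrA": 300_000},
        enhancer_density=100.0,
        enhancer_width_range=(300, 600),
        noise_sd=0.0,
        label_noise_rate=0.0,
        seed=7,
    )
    dataset, enhancers, truth, bins = dataset_from_generator(config)
    return {
        "config": config,
        "dataset": dataset,
        "enhancers": enhancers,
        "truth": truth,
        "bins": bins,
    }


@pytest.fixture(scope="session")
def trained_small(small_synth):
    """A quick trained model on the small synthetic genome."""
    from enhancerxai.induction import InductionConfig, induce_rulebase

    train, test = sample_training_set(small_synth["dataset"], 8000, 0.3, seed=1)
    config = InductionConfig(population_size=40, generations=40, seed=3)
    rulebase = induce_rulebase(train, config)
    return {"rulebase": rulebase, "train": train, "test": test, "config": config}


@pytest.fixture
def ramp_partitions():
    """Partitions whose 'high' membership equals x (linear ramp), handy
    for constructing rules with exact firing strengths."""
    from enhancerxai.fuzzy import FuzzyPartition, FuzzySet, Trapezoid

    def make(mark):
        low = FuzzySet("low", Trapezoid(0, 0, 0, 1), Trapezoid(0, 0, 0, 1))
        med = FuzzySet("medium", Trapezoid(0, 0.5, 0.5, 1), Trapezoid(0, 0.5, 0.5, 1))
        high = FuzzySet("high", Trapezoid(0, 1, 1, 1), Trapezoid(0, 1, 1, 1))
        return FuzzyPartition(mark, {"low": low, "medium": med, "high": high})

    return {m: make(m) for m in ("m1", "m2", "m3")}


@pytest.fixture
def two_rule_base(ramp_partitions):
    """One enhancer rule and one non-enhancer rule on ramp partitions."""
    rules = [
        FuzzyRule((("m1", "high"),), "enhancer", 1.0),
        FuzzyRule((("m2", "high"),), "non_enhancer", 1.0),
    ]
    return RuleBase(rules, ramp_partitions)


@pytest.fixture
def quartile_rulebase():
    """A rule base on the canonical quartile partitions over four marks."""
    marks = ["mark01", "mark02", "mark03", "mark04"]
    partitions = {m: default_partition(m) for m in marks}
    rules = [
        FuzzyRule((("mark01", "high"), ("mark02", "high")), "enhancer", 2.0),
        FuzzyRule((("mark03", "low"),), "non_enhancer", 1.5),
        FuzzyRule((("mark02", "medium"),), "non_enhancer", 1.0),
    ]
    return RuleBase(rules, partitions)
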