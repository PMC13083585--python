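"""Shared fixtures: synthetic study conditions reused across test modules.

The heavier simulations are session-scoped so the suite pays for each one
once; configurations are fixed study conditions, not per-test knobs.
"""

from __future__ import annotations

import pytest

from dystosignal import synth
from dystosignal.case_mapping import DrugNormalizer, PTQuery
from dystosignal.dedup import dedup_bundles

BACKGROUND_PTS = [("nausea", 0.50), ("headache", 0.45)]


def pooled(bundles):
    """Concatenate record lists across quarterly bundles."""
    demo = [d for b in bundles for d in b.demo]
    reac = [r for b in bundles for r in b.reac]
    drug = [r for b in bundles for r in b.drug]
    ther = [r for b in bundles for r in b.ther]
    return demo, reac, drug, ther


def identity_norm(config):
    return DrugNormalizer.identity([d.name for d in config.drug_catalog])


def target_query(config):
    return PTQuery(name="target", scope="narrow",
                   pts=set(config.target_event_pts))


@pytest.fixture(scope="session")
def medium_sim():
    """8,000 cases with heavy duplication and deletions, mixed signals.

    Used by the deduplication, case-mapping and interaction oracle tests.
    """
    catalog = [
        synth.DrugSpec("metoclopramide", 0.05),
        synth.DrugSpec("aripiprazole", 0.05),
        synth.DrugSpec("risperidone", 0.05),
        synth.DrugSpec("ibuprofen", 0.20),
        synth.DrugSpec("metformin", 0.20),
        synth.DrugSpec("omeprazole", 0.20),
    ]
    config = synth.SynthConfig(
        n_cases=8000,
        drug_catalog=catalog,
        pt_catalog=[("dystonia", 0.03), ("torticollis", 0.01)] + BACKGROUND_PTS,
        target_event_pts=["dystonia", "torticollis"],
        signal_pairs={"metoclopramide": 10.0, "aripiprazole": 5.0,
                      "risperidone": 5.0},
        interaction_triplets=[("aripiprazole", "risperidone", 3.0)],
        duplicate_rate=0.3,
        deletion_rate=0.1,
        missing_date_rate=0.3,
        seed=5,
    )
    bundles, ledger = synth.simulate(config)
    return config, bundles, ledger


@pytest.fixture(scope="session")
def medium_retained(medium_sim):
    _, bundles, _ = medium_sim
    result, demo_all = dedup_bundles(bundles)
    return result, demo_all


@pytest.fixture(scope="session")
def signal_sim_50k():
    """50,000 cases, one drug injected at odds multiplier 10, 30 nulls."""
    catalog = [synth.DrugSpec(f"null{i:02d}", 0.03) for i in range(30)]
    catalog.append(synth.DrugSpec("signalx", 0.03))
    config = synth.SynthConfig(
        n_cases=50_000,
        drug_catalog=catalog,
        pt_catalog=[("dystonia", 0.05)] + BACKGROUND_PTS,
        target_event_pts=["dystonia"],
        signal_pairs={"signalx": 10.0},
        duplicate_rate=0.0,
        deletion_rate=0.0,
        missing_date_rate=0.3,
        seed=11,
    )
    bundles, ledger = synth.simulate(config)
    return config, bundles, ledger


@pytest.fixture(scope="session")
def null_sim_50k():
    """50,000 cases, every multiplier 1: the global null."""
    catalog = [synth.DrugSpec(f"drug{i:02d}", 0.08) for i in range(10)]
    config = synth.SynthConfig(
        n_cases=50_000,
        drug_catalog=catalog,
        pt_catalog=[("dystonia", 0.05)] + BACKGROUND_PTS,
        target_event_pts=["dystonia"],
        duplicate_rate=0.0,
        deletion_rate=0.0,
        seed=17,
    )
    bundles, ledger = synth.simulate(config)
    return config, bundles, ledger


@pytest.fixture(scope="session")
def tto_sim():
    """Strong-signal drugs with known onset medians and complete dates."""
    catalog = [
        synth.DrugSpec("fastonset", 0.30),
        synth.DrugSpec("slowonset", 0.30),
        synth.DrugSpec("filler", 0.40),
    ]
    config = synth.SynthConfig(
        n_cases=6000,
        drug_catalog=catalog,
        pt_catalog=[("dystonia", 0.05)] + BACKGROUND_PTS,
        target_event_pts=["dystonia"],
        signal_pairs={"fastonset": 50.0, "slowonset": 50.0},
        tto_models={
            "fastonset": synth.TTOModel("exponential", 2.0),
            "slowonset": synth.TTOModel("lognormal", 20.0, 0.8),
        },
        duplicate_rate=0.0,
        deletion_rate=0.0,
        missing_date_rate=0.0,
        seed=23,
    )
    bundles, ledger = synth.simulate(config)
    return config, bundles, ledger


def lawyer_bias_config(seed: int) -> synth.SynthConfig:
    """Litigation-bias study condition: one drug whose event reporting is
    dominated by lawyer submissions, masking two genuine weaker signals."""
    catalog = [
        synth.DrugSpec("biased", 0.04),
        synth.DrugSpec("weak1", 0.04),
        synth.DrugSpec("weak2", 0.04),
        synth.DrugSpec("null1", 0.30),
        synth.DrugSpec("null2", 0.30),
        synth.DrugSpec("null3", 0.30),
    ]
    return synth.SynthConfig(
        n_cases=4000,
        drug_catalog=catalog,
        pt_catalog=[("dystonia", 0.02)] + BACKGROUND_PTS,
        target_event_pts=["dystonia"],
        signal_pairs={"biased": 10.0, "weak1": 10.0, "weak2": 10.0},
        lawyer_bias={"biased": 15.0},
        duplicate_rate=0.0,
        deletion_rate=0.0,
        seed=seed,
    )
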