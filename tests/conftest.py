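"""Shared fixtures: small synthetic studies and manifests."""

import numpy as np
import pytest

from mbfusion import BlockSpec, SampleManifest, SyntheticSpec, generate_study


def sparse_study_spec(seed: int, effect_size: float = 2.0) -> SyntheticSpec:
    """Four tabular blocks with sparse, evenly split planted signal.

    Each platform contributes 2 informative features out of 100, so no
    single block suffices on its own — the scenario multi-block fusion
    is meant for.  A per-sample offset (sd 0.5) emulates block-level
    batch/dilution nuisance.
    """
    return SyntheticSpec(
        seed=seed,
        groups=[("YN", 35), ("GX", 35)],
        external_groups=[("GD", 4), ("FJ", 4), ("MD", 3), ("LQS", 3)],
        blocks=[
            BlockSpec(
                p,
                n_features=100,
                n_informative=2,
                effect_size=effect_size,
                noise_sd=1.0,
                sample_effect_sd=0.5,
            )
            for p in ("LCMS", "GCMS", "NMR", "MIR")
        ],
    )


@pytest.fixture(scope="session")
def paper_manifest() -> SampleManifest:
    """The 84-sample layout: 70 model (YN, GX) + 14 external (GD, FJ, MD, LQS)."""
    return SampleManifest.from_counts(
        [("YN", 35), ("GX", 35)], [("GD", 4), ("FJ", 4), ("MD", 3), ("LQS", 3)]
    )


@pytest.fixture(scope="session")
def sparse_study():
    """One realisation of the sparse four-block study (seed 7)."""
    return generate_study(sparse_study_spec(7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
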