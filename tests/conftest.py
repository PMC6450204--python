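import numpy as np
import pytest

from meles.genetics import Locus, LocusPanel
from meles.simgen import (
    SimConfig,
    random_panel,
    simulate_genotypes,
    simulate_observation,
    simulate_population,
)


@pytest.fixture(scope="session")
def tiny_panel() -> LocusPanel:
    """Three small loci with known frequencies, no genotyping error."""
    return LocusPanel(
        [
            Locus("La", [1, 2], np.array([0.5, 0.5]), e1=0.0, e2=0.0),
            Locus("Lb", [1, 2, 3], np.array([0.2, 0.3, 0.5]), e1=0.0, e2=0.0),
            Locus("Lc", [1, 2, 3, 4], np.array([0.1, 0.2, 0.3, 0.4]), e1=0.0, e2=0.0),
        ]
    )


@pytest.fixture(scope="session")
def small_world():
    """A fully-sampled, error-free simulated population with genotypes.

    Capture probability 1 and e1 = e2 = 0 make ground truth exactly
    recoverable, which the parentage and pedigree tests rely on.
    """
    cfg = SimConfig(n_years=10, seed=11, capture_prob={"F": 1.0, "M": 1.0})
    truth = simulate_population(cfg)
    panel = random_panel(22, seed=5, e1=0.0, e2=0.0)
    true_gt, obs_gt = simulate_genotypes(truth, panel, seed=7)
    captures = simulate_observation(truth, cfg)
    return {
        "config": cfg,
        "truth": truth,
        "panel": panel,
        "true_genotypes": true_gt,
        "genotypes": obs_gt,
        "captures": captures,
    }
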