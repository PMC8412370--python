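import numpy as np
import pandas as pd
import pytest

from breedload.io_model import BreedPanel, PolarizedDataset
from breedload import simulate


def make_dataset(
    genotypes: dict[str, np.ndarray],
    phylop100=None,
    phylop46=None,
    effect=None,
    polarity=None,
    chrom="chr1",
    spacing=100,
):
    """Hand-built polarized dataset: genotype codes are ALT counts and, by
    default, every site is oriented derived=ALT."""
    n_sites = next(iter(genotypes.values())).shape[0]
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(n_sites) * spacing + 1,
            "ref": "A",
            "alt": "G",
            "vtype": "SNV",
            "locus_id": np.arange(n_sites),
            "alt_index": 1,
            "n_alts": 1,
        }
    )
    panels = {
        b: BreedPanel(b, [f"{b}_{i}" for i in range(g.shape[1])], g)
        for b, g in genotypes.items()
    }
    ann = pd.DataFrame(
        {
            "effect_category": effect if effect is not None else ["INTERGENIC"] * n_sites,
            "phylop100": phylop100 if phylop100 is not None else np.zeros(n_sites),
            "phylop46": phylop46 if phylop46 is not None else np.zeros(n_sites),
            "phastcon_hit": False,
        }
    )
    pol = np.ones(n_sites, dtype=np.int8) if polarity is None else np.asarray(polarity, dtype=np.int8)
    return PolarizedDataset(sites=sites, panels=panels, polarity=pol, annotations=ann)


@pytest.fixture(scope="session")
def small_study():
    """Three-breed neutral-plus-selected study used across modules."""
    cfg = simulate.SimulationConfig(
        seed=11,
        breed_names=("alpha", "bravo", "charlie"),
        n_sites={"synonymous": 1500, "nonsynonymous": 600, "lof": 200, "moderate": 600, "high": 600},
    )
    return simulate.simulate_breed_panels(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with age-driven affection only (no genotype effect)."""
    cfg = simulate.CohortConfig()
    return simulate.simulate_cohort(cfg, seed=42)


def write_lines(path, text):
    path.write_text(text.lstrip())
    return str(path)
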