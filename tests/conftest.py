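import numpy as np
import pandas as pd
import pytest

from selfpred.geno_io import GenotypeMatrix, Pedigree, impute_mean
from selfpred.simdata import (
    SimConfig,
    simulate_founders,
    simulate_phenotypes,
    simulate_progeny,
)


@pytest.fixture(scope="session")
def small_config():
    """Small but structured population: 10 parents, 180 offspring, 400
    markers on 4 chromosomes, 15 orchard individuals."""
    return SimConfig(
        n_parents=10,
        offspring_per_parent=(18, 18),
        n_markers=400,
        n_chromosomes=4,
        n_orchard=15,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_population(small_config):
    founders = simulate_founders(small_config)
    progeny, ped, truth = simulate_progeny(founders, small_config)
    pheno = simulate_phenotypes(progeny, truth, small_config)
    return founders, progeny, ped, truth, pheno


@pytest.fixture(scope="session")
def small_bundle(small_population):
    from selfpred.blup import DataBundle

    founders, progeny, ped, truth, pheno = small_population
    all_g = GenotypeMatrix(
        ids=founders.ids + progeny.ids,
        marker_ids=list(founders.marker_ids),
        dosage=np.vstack([founders.dosage, progeny.dosage]),
        marker_map=founders.marker_map.copy(),
    )
    return DataBundle(genotypes=impute_mean(all_g), pedigree=ped, phenotypes=pheno)


@pytest.fixture()
def tiny_genotypes():
    """3 individuals x 4 markers with one missing call."""
    dosage = np.array(
        [
            [0.0, 1.0, 2.0, 1.0],
            [1.0, np.nan, 2.0, 0.0],
            [2.0, 1.0, 2.0, 1.0],
        ]
    )
    mids = ["M1", "M2", "M3", "M4"]
    return GenotypeMatrix(
        ids=["a", "b", "c"],
        marker_ids=mids,
        dosage=dosage,
        marker_map=pd.DataFrame(
            {"marker": mids, "chrom": [1, 1, 2, 2], "pos_bp": [100, 200, 100, 500]}
        ),
    )


@pytest.fixture()
def selfing_pedigree():
    """Founder P, selfed child S1, selfed grandchild S2, outcross O."""
    return Pedigree(
        pd.DataFrame(
            {
                "id": ["P", "Q", "S1", "S2", "O"],
                "sire": [None, None, "P", "S1", "P"],
                "dam": [None, None, "P", "S1", "Q"],
            }
        )
    )
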