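import numpy as np
import pytest

from neoligand import error_model as em
from neoligand import peptide_space as ps
from neoligand import spectra_search as ss
from neoligand.fixtures import (
    CohortConfig,
    make_reference,
    plant_truth,
    simulate_peptidome_and_spectra,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small seeded cohort with planted variants, phospho and noise."""
    config = CohortConfig(
        n_transcripts=4,
        cds_length=180,
        n_variants=3,
        n_peptides=80,
        n_noise_spectra=60,
        phospho_fraction=0.15,
        seed=11,
    )
    transcripts, proteome = make_reference(config)
    truth = plant_truth(transcripts, config)
    spectra, table, truth = simulate_peptidome_and_spectra(proteome, truth, config)
    return {
        "config": config,
        "transcripts": transcripts,
        "proteome": proteome,
        "truth": truth,
        "spectra": spectra,
        "table": table,
    }


@pytest.fixture(scope="session")
def searched_cohort(small_cohort):
    """PSMs from searching the small cohort against its own search space."""
    proteome = small_cohort["proteome"]
    truth = small_cohort["truth"]
    variants = [v.as_protein_variant() for v in truth.variants]
    targets = ps.build_search_space(proteome, variants)
    decoys = ps.build_decoys(proteome, variants, target_space=targets)
    index = ss.PeptideIndex(targets, decoys)
    psms = ss.search_spectra(small_cohort["spectra"], index)
    model = em.fit_pep(psms)
    em.assign_peps(psms, model)
    return {**small_cohort, "targets": targets, "decoys": decoys,
            "index": index, "psms": psms, "model": model}


def modified_sequence(true_peptide):
    """Truth-side rendering matching SpectrumMatch.modified_sequence."""
    if not true_peptide.placements:
        return true_peptide.sequence
    tags = ",".join(
        f"{n}@{p}" for n, p in sorted(true_peptide.placements, key=lambda x: x[1])
    )
    return f"{true_peptide.sequence}[{tags}]"


@pytest.fixture
def rng():
    return np.random.default_rng(42)
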