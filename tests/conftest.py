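import pytest

from seroneo.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort_bundle(tmp_path_factory):
    """Default synthetic cohort, generated once per session (seed 7)."""
    outdir = tmp_path_factory.mktemp("cohort")
    return generate_cohort(CohortConfig(seed=7), outdir)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """Small cohort for fast end-to-end and CLI tests."""
    outdir = tmp_path_factory.mktemp("small_cohort")
    cfg = CohortConfig(
        seed=11,
        n_patients_per_group=4,
        n_features=120,
        n_controls=20,
        n_shared_responders=10,
        n_enriched_responders=8,
        n_private_responders=6,
        n_true_snv=8,
        n_decoy_wes_only=2,
        n_decoy_rna_only=2,
        n_decoy_high_popaf=2,
        n_decoy_low_vaf=2,
        n_proteins=60,
        n_map_patients=2,
        n_maps_per_patient=20,
        n_known_epitopes=5,
        n_cta_genes=10,
        n_tantigen_genes=10,
    )
    return generate_cohort(cfg, outdir)
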