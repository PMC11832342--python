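import pytest

from psifinder import simdata as sd


@pytest.fixture(scope="session")
def tiny_spec() -> sd.ReferenceSpec:
    return sd.ReferenceSpec(
        mirna=sd.ClassSpec(12, 20, 24),
        te=sd.ClassSpec(6, 60, 90),
        trna=sd.ClassSpec(3, 72, 78),
        other=sd.ClassSpec(3, 25, 60),
        rrna_len=400,
        n_rrna_known_sites=3,
        n_te_families=2,
    )


@pytest.fixture(scope="session")
def tiny_ref(tiny_spec) -> sd.ToyReference:
    return sd.build_toy_reference(tiny_spec, seed=5)


@pytest.fixture(scope="session")
def tiny_truth(tiny_ref) -> sd.PsiGroundTruth:
    return sd.assign_psi_sites(tiny_ref, n_modified=6, stoich_range=(0.5, 1.0),
                               five_prime_bias=0.5, seed=5)


@pytest.fixture(scope="session")
def tiny_sim(tiny_ref, tiny_truth) -> sd.SimResult:
    cfg = sd.SimConfig(master_seed=5, molecules_per_library=3000,
                       n_ip_pairs=2, n_cmc_pairs=2, n_mn_pairs=2,
                       emit_input=True)
    return sd.simulate_libraries(tiny_ref, tiny_truth, cfg)
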