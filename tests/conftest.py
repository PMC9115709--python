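import pytest
from hypothesis import settings

from spheropv.chem_data import DrugDescriptorRecord
from spheropv import synthetic

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def make_record():
    """Factory for fully populated descriptor records with overridable fields."""

    defaults = dict(
        drug_id="demo",
        mw=300.0,
        logp=2.5,
        logs=-3.5,
        hba_count=5,
        hbd_count=1,
        psa=70.0,
        rotatable_bonds=4,
        refractivity=80.0,
        polarizability=30.0,
        pka=8.0,
        sa_ha_fraction=0.2,
        sa_hd_fraction=0.05,
        atom_count=22,
        aromatic_ring_count=2,
        alerts_count=0,
        ic50_monolayer=1.0,
    )

    def _make(**overrides):
        kwargs = dict(defaults)
        kwargs.update(overrides)
        rec = DrugDescriptorRecord(**kwargs)
        rec.validate()
        return rec

    return _make


@pytest.fixture(scope="session")
def default_config():
    return synthetic.SyntheticConfig(seed=1234)


@pytest.fixture(scope="session")
def synthetic_records(default_config):
    return synthetic.generate_descriptor_table(default_config)


@pytest.fixture(scope="session")
def synthetic_design(default_config, synthetic_records):
    _, reps = synthetic.generate_pv_ground_truth(synthetic_records, default_config)
    return synthetic.generate_qsar_design(synthetic_records, reps)
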