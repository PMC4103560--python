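import pytest

from cladeamp import seqcore, synthdata


@pytest.fixture(scope="session")
def panel():
    """The published primer panel, keyed by name."""
    return {p.name: p for p in seqcore.table1_primers()}


@pytest.fixture(scope="session")
def reference():
    """Synthetic stand-in reference template with planted primer sites."""
    return synthdata.synthetic_reference()


@pytest.fixture(scope="session")
def small_family():
    """A small planted family reused across matching/design tests."""
    spec = synthdata.FamilySpec(
        n_target=12,
        n_nontarget=6,
        sequence_length=300,
        planted_sites=(
            synthdata.PlantedSite(position=101, oligo="GGAAACTCATCAGGRCAAGAAGATT"),
        ),
        substitution_rate=0.05,
        seed=7,
    )
    return synthdata.generate_family(spec)
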