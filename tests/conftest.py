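import pytest

from sigpepvar import GeneratorParams, SignalPeptide, generate_signal_peptides, table1_fixture


@pytest.fixture(scope="session")
def table1():
    """The bundled 15-row literature validation set."""
    return table1_fixture()


@pytest.fixture()
def toy_peptide():
    """A hand-built 22-residue signal peptide (+1 residue appended) with
    regions N=1..3, H=4..17, C=18..22."""
    return SignalPeptide(
        protein_id="TOY1",
        gene="TOYG1",
        sequence="MKR" + "LLVLLALLLPLLFL" + "SSVHA" + "D",
        n_end=3,
        h_end=17,
        sp_len=22,
    )


@pytest.fixture()
def toy_collection():
    """Four tiny annotated peptides for hand-count oracles."""
    return [
        SignalPeptide("P1", "G1", "MKR" + "LLLLLLLLLL" + "SAHA" + "S", 3, 13, 17),
        SignalPeptide("P2", "G2", "MR" + "VLVLVLVLVLVL" + "GGSVA" + "A", 2, 14, 19),
        SignalPeptide("P3", "G3", "MKKR" + "ALALALALALALAL" + "SSA" + "G", 4, 18, 21),
        SignalPeptide("P4", "G4", "MRP" + "FLFLFLFLFLFLFL" + "AGSCA" + "T", 3, 17, 22),
    ]


@pytest.fixture(scope="session")
def synthetic_cohort():
    """A moderately sized generated collection shared across tests."""
    return generate_signal_peptides(GeneratorParams(n_peptides=500, seed=11))
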